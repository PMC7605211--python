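"""Synthetic cohorts, populations and pedigrees for the triallelic panel.

Everything the discovery pipeline and the simulators consume can be
generated here, with known truth: a multi-species discovery cohort with
planted true markers and per-filter decoys, Hardy-Weinberg population
genotype matrices with a rare cattle-associated allele, and hybrid
pedigrees (F1 followed by repeated yak backcrosses).

The generated cohort emulates the study design the panel was built
around: two reference yaks heterozygous at every true site, five
outgroup animals (gaur/banteng/bison) homozygous for a shared ancestral
allele, and a 96-animal beef-cattle diversity panel nearly fixed for the
reference allele.  Markers are unlinked; there is no recombination map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .discovery import FineFilterConfig, MaskConfig
from .genotypes import (
    ANCESTRAL,
    CATTLE,
    MISSING,
    YAK,
    CandidateSite,
    CohortGenotypes,
    GenotypeCall,
    GenotypeMatrix,
    SpeciesRole,
)

_BASES = np.array(list("ACGT"))

#: truth-table classes and the pipeline stage expected to remove them
DECOY_CLASSES = {
    "outgroup_het": "coarse",
    "cattle_low_ref": "fine",
    "flank_masked": "mask",
    "multi_mapping": "unique",
    "monomorphic": "monomorphic",
}

_DEFAULT_FLANK_SPEC = (
    (12, "cattle", 9 / 192),   # masked: at the 5% cattle threshold
    (-30, "cattle", 8 / 192),  # below threshold: stays unmasked
    (45, "yak", 0.10),         # yak variants mask at any frequency
)


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic discovery cohort."""

    n_markers: int
    n_decoys_per_class: int = 0
    n_reference_yaks: int = 2
    n_outgroup: int = 5
    n_cattle: int = 96
    cattle_ref_allele_freq: float = 0.99
    flank_variant_spec: tuple = _DEFAULT_FLANK_SPEC
    n_population: int = 170
    population_maf: float = 0.296
    population_missing_rate: float = 0.0048
    seed: int = 0

    def __post_init__(self):
        for name in ("n_markers", "n_decoys_per_class", "n_reference_yaks",
                     "n_outgroup", "n_cattle", "n_population"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        _require(0.0 <= self.cattle_ref_allele_freq <= 1.0,
                 "cattle_ref_allele_freq", "must be in [0,1]")
        _require(0.0 <= self.population_missing_rate <= 1.0,
                 "population_missing_rate", "must be in [0,1]")
        _require(0.0 <= self.population_maf <= 0.5, "population_maf",
                 "must be in [0, 0.5]")
        for off, pop, freq in self.flank_variant_spec:
            _require(pop in ("cattle", "yak"), "flank_variant_spec",
                     f"unknown population {pop!r}")
            _require(off != 0, "flank_variant_spec", "offset 0 is the marker itself")
            _require(0.0 <= freq <= 1.0, "flank_variant_spec", "frequency in [0,1]")


@dataclass(frozen=True)
class PopulationSpec:
    """HW population genotypes at stated per-marker MAFs.

    ``per_marker_maf`` is the minor-allele frequency over the two
    parentage alleles; the cattle-associated allele keeps its own low
    background frequency (0.0043 as estimated in North American yak) and
    the three per-marker frequencies sum to 1.
    """

    per_marker_maf: Sequence
    n_animals: int
    cattle_allele_freq: float = 0.0043
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        mafs = np.asarray(self.per_marker_maf, dtype=float)
        _require(mafs.ndim == 1 and len(mafs) >= 1, "per_marker_maf", "need >= 1 marker")
        _require(bool(((mafs >= 0) & (mafs <= 0.5)).all()), "per_marker_maf",
                 "entries must be in [0, 0.5]")
        _require(0.0 <= self.cattle_allele_freq < 1.0, "cattle_allele_freq",
                 "must be in [0, 1)")
        _require(0.0 <= self.missing_rate <= 1.0, "missing_rate", "must be in [0,1]")
        _require(self.n_animals >= 1, "n_animals", "must be >= 1")


@dataclass(frozen=True)
class PedigreeSpec:
    """F1 hybridization followed by repeated yak backcrosses.

    Generation 0 is the F1 itself (one cattle-associated allele at every
    panel site); each later generation transmits one uniformly chosen
    allele per site and receives a non-cattle allele drawn from the yak
    parentage frequencies.  Five backcross generations past the F1 is
    the default horizon.
    """

    panel_size: int
    n_backcross_generations: int = 5
    n_replicates: int = 1
    yak_allele_freqs: Union[float, Sequence] = 0.296
    seed: int = 0

    def __post_init__(self):
        _require(self.panel_size >= 1, "panel_size", "must be >= 1")
        _require(self.n_backcross_generations >= 0, "n_backcross_generations",
                 "must be >= 0 (0 = the F1 itself)")
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        mafs = np.atleast_1d(np.asarray(self.yak_allele_freqs, dtype=float))
        _require(bool(((mafs >= 0) & (mafs <= 0.5)).all()), "yak_allele_freqs",
                 "MAF entries must be in [0, 0.5]")


@dataclass
class DiscoveryCohort:
    """Bundle of everything one discovery run needs, plus the truth."""

    cohort: CohortGenotypes
    reference: dict            # contig -> sequence string
    flank_variants: pd.DataFrame
    hits: dict                 # marker id -> alignment hit count
    population: GenotypeMatrix
    truth: pd.DataFrame        # site_id, class, expected_fate


def _site_alleles(rng: np.random.Generator) -> tuple:
    """Three distinct bases for (ancestral, yak, cattle)."""
    return tuple(rng.choice(_BASES, size=3, replace=False))


def _cattle_calls(
    rng: np.random.Generator,
    names: Sequence[str],
    ref: str,
    alt: str,
    n_nonref: int,
) -> dict:
    slots = np.full(2 * len(names), ref, dtype=object)
    n_nonref = min(n_nonref, len(slots))
    if n_nonref:
        idx = rng.choice(len(slots), size=n_nonref, replace=False)
        slots[idx] = alt
    return {
        name: GenotypeCall(slots[2 * i], slots[2 * i + 1])
        for i, name in enumerate(names)
    }


def generate_discovery_cohort(spec: CohortSpec) -> DiscoveryCohort:
    """Generate a discovery cohort with planted markers and decoys.

    Planted true sites satisfy every discovery filter by construction
    (the cattle non-reference allele count is truncated at the fine
    threshold).  Each decoy class violates exactly one filter, all
    others satisfied, so every discovery rule is testable in isolation.
    """
    rng = np.random.default_rng(spec.seed)
    classes = ["true"] * spec.n_markers
    for cls in DECOY_CLASSES:
        classes += [cls] * spec.n_decoys_per_class
    rng.shuffle(classes)
    n_sites = len(classes)

    spacing = 10_000
    contig = "chr1"
    contig_len = spacing * (n_sites + 1)
    seq = rng.choice(_BASES, size=contig_len)

    ref_yaks = [f"refyak{i+1}" for i in range(spec.n_reference_yaks)]
    outgroups = [f"outgroup{i+1}" for i in range(spec.n_outgroup)]
    cattle = [f"cattle{i+1:03d}" for i in range(spec.n_cattle)]
    roles = {a: SpeciesRole.REFERENCE_YAK for a in ref_yaks}
    roles.update({a: SpeciesRole.OUTGROUP for a in outgroups})
    roles.update({a: SpeciesRole.CATTLE_PANEL for a in cattle})

    fine = FineFilterConfig.from_panel_size(spec.n_cattle) if spec.n_cattle else None
    max_nonref = (fine.possible_alleles - fine.min_ref_alleles) if fine else 0
    mask_cfg = MaskConfig()

    sites, truth_rows, fv_rows = [], [], []
    hits: dict = {}
    marker_meta = []
    pop_mafs = []
    for i, cls in enumerate(classes):
        pos = spacing * (i + 1)
        anc, yak, cat = _site_alleles(rng)
        seq[pos - 1] = cat
        genotypes = {}
        for a in ref_yaks:
            genotypes[a] = GenotypeCall(anc, yak)
        for a in outgroups:
            genotypes[a] = GenotypeCall(anc, anc)
        if cls == "outgroup_het" and outgroups:
            genotypes[outgroups[int(rng.integers(len(outgroups)))]] = GenotypeCall(anc, yak)
        if cattle:
            if cls == "cattle_low_ref":
                n_nonref = max_nonref + 1 + int(rng.integers(0, 10))
            else:
                drawn = rng.binomial(2 * spec.n_cattle, 1.0 - spec.cattle_ref_allele_freq)
                n_nonref = min(int(drawn), max_nonref)
            genotypes.update(_cattle_calls(rng, cattle, cat, anc, n_nonref))
        site_id = f"ty{i+1:04d}"
        sites.append(
            CandidateSite(
                chrom=contig, pos=pos, ref_allele=cat,
                genotypes=genotypes, species_role=roles, site_id=site_id,
            )
        )
        for off, pop, freq in spec.flank_variant_spec:
            count = int(round(freq * fine.possible_alleles)) if pop == "cattle" else (1 if freq > 0 else 0)
            fv_rows.append((contig, pos + off, pop, count))
        if cls == "flank_masked":
            # enough extra yak flank variants to breach the feasibility cap
            n_extra = int(mask_cfg.max_masked_fraction * 2 * mask_cfg.flank_bp) + 8
            offsets = rng.choice(
                np.concatenate([np.arange(-mask_cfg.flank_bp, 0), np.arange(1, mask_cfg.flank_bp + 1)]),
                size=n_extra, replace=False,
            )
            for off in offsets:
                fv_rows.append((contig, pos + int(off), "yak", 1))
        hits[site_id] = int(rng.choice([0, 2, 3])) if cls == "multi_mapping" else 1
        truth_rows.append((site_id, cls, "retained" if cls == "true" else DECOY_CLASSES[cls]))
        marker_meta.append((site_id, contig, pos, anc, yak, cat))
        pop_mafs.append(0.0 if cls == "monomorphic" else spec.population_maf)

    reference = {contig: "".join(seq)}
    flank_variants = pd.DataFrame(
        fv_rows, columns=["chrom", "pos", "population", "allele_count"]
    )
    truth = pd.DataFrame(truth_rows, columns=["site_id", "class", "expected_fate"])
    markers = pd.DataFrame(
        marker_meta, columns=["marker_id", "chrom", "pos", "ancestral", "yak", "cattle"]
    ).set_index("marker_id")
    if n_sites and spec.n_population:
        pop_spec = PopulationSpec(
            per_marker_maf=pop_mafs,
            n_animals=spec.n_population,
            missing_rate=spec.population_missing_rate,
            seed=int(rng.integers(2**31 - 1)),
        )
        population = generate_population_genotypes(pop_spec, markers=markers)
    else:
        population = GenotypeMatrix(
            np.empty((0, n_sites, 2), dtype=np.int8), [], markers
        )
    cohort = CohortGenotypes(sites=sites, roles=roles)
    return DiscoveryCohort(
        cohort=cohort, reference=reference, flank_variants=flank_variants,
        hits=hits, population=population, truth=truth,
    )


def generate_population_genotypes(
    spec: PopulationSpec, markers: Optional[pd.DataFrame] = None
) -> GenotypeMatrix:
    """Draw an animals x markers genotype matrix from HW proportions.

    Alleles are sampled independently per slot from the three role
    frequencies (minor parentage allele = yak by convention); missing
    calls are inserted at ``spec.missing_rate`` per genotype.
    """
    rng = np.random.default_rng(spec.seed)
    mafs = np.asarray(spec.per_marker_maf, dtype=float)
    n_markers = len(mafs)
    if markers is None:
        bases = [
            tuple(rng.choice(_BASES, size=3, replace=False)) for _ in range(n_markers)
        ]
        markers = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [10_000 * (j + 1) for j in range(n_markers)],
                "ancestral": [b[0] for b in bases],
                "yak": [b[1] for b in bases],
                "cattle": [b[2] for b in bases],
            },
            index=pd.Index([f"M{j+1:04d}" for j in range(n_markers)], name="marker_id"),
        )
    if len(markers) != n_markers:
        raise ValueError("markers table does not match per_marker_maf length")
    c = spec.cattle_allele_freq
    f_yak = (1.0 - c) * mafs
    f_anc = (1.0 - c) * (1.0 - mafs)
    calls = np.empty((spec.n_animals, n_markers, 2), dtype=np.int8)
    for j in range(n_markers):
        p = np.array([f_anc[j], f_yak[j], c])
        p = p / p.sum()
        calls[:, j, :] = rng.choice(3, size=(spec.n_animals, 2), p=p)
    if spec.missing_rate > 0:
        miss = rng.random((spec.n_animals, n_markers)) < spec.missing_rate
        calls[miss] = MISSING
    animals = [f"yak{i+1:04d}" for i in range(spec.n_animals)]
    return GenotypeMatrix(calls, animals, markers)


@dataclass
class PedigreeResult:
    """Per-generation genotypes of simulated backcross lineages.

    ``generations[g]`` has shape (n_replicates, panel_size, 2) with role
    codes; generation 0 is the F1.  Replicate r of generation g+1 is the
    offspring of replicate r of generation g.
    """

    generations: list

    def cattle_allele_counts(self, generation: int) -> np.ndarray:
        g = self.generations[generation]
        return (g == CATTLE).sum(axis=(1, 2))


def generate_pedigree_genotypes(spec: PedigreeSpec) -> PedigreeResult:
    """Simulate F1 hybrids and successive yak backcross offspring."""
    rng = np.random.default_rng(spec.seed)
    mafs = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.yak_allele_freqs, dtype=float)),
        (spec.panel_size,),
    )

    def yak_alleles(shape):
        # non-cattle allele from the parentage frequencies
        return np.where(rng.random(shape) < mafs, YAK, ANCESTRAL).astype(np.int8)

    shape = (spec.n_replicates, spec.panel_size)
    f1 = np.empty(shape + (2,), dtype=np.int8)
    f1[:, :, 0] = CATTLE
    f1[:, :, 1] = yak_alleles(shape)
    generations = [f1]
    for _ in range(spec.n_backcross_generations):
        parent = generations[-1]
        which = rng.integers(0, 2, size=shape)
        transmitted = np.take_along_axis(parent, which[:, :, None], axis=2)[:, :, 0]
        child = np.empty_like(parent)
        child[:, :, 0] = transmitted
        child[:, :, 1] = yak_alleles(shape)
        generations.append(child)
    return PedigreeResult(generations=generations)
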