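"""Discovery pipeline for triallelic yak/cattle markers.

Candidate sites come from multi-species variant calls against a
cattle-like reference.  A true marker has three role-labelled alleles:

* ancestral — every outgroup animal (gaur, banteng, bison) homozygous
  for it, and it differs from the reference base;
* yak — the second allele of the heterozygous reference yaks, absent
  from the outgroups and from the reference assembly;
* cattle — the reference base, nearly fixed in a beef-cattle diversity
  panel.

The pipeline stages: coarse species filter -> cattle fine filter ->
flank masking (+ assay-feasibility drop) -> unique-mapping filter ->
monomorphic filter -> bin assignment.  Each stage is a pure predicate on
a site, so the surviving set is order-independent even though the staged
counts are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import CandidateSite, CohortGenotypes, GenotypeMatrix, SpeciesRole
from .stats import estimate_panel_frequencies

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FineFilterConfig:
    """Cattle-panel near-fixation threshold.

    The reference (cattle) allele must account for ``min_ref_alleles`` of
    the ``possible_alleles`` in the panel (183 of 192 = >95% for 96
    animals).  The denominator is fixed, so missing calls count against
    passing.
    """

    min_ref_alleles: int = 183
    possible_alleles: int = 192

    def __post_init__(self):
        if not 0 <= self.min_ref_alleles <= self.possible_alleles:
            raise ValueError("need 0 <= min_ref_alleles <= possible_alleles")

    @classmethod
    def from_panel_size(cls, n_cattle: int, min_fraction: float = 183 / 192):
        possible = 2 * n_cattle
        import math

        return cls(min_ref_alleles=math.ceil(min_fraction * possible), possible_alleles=possible)


@dataclass(frozen=True)
class MaskConfig:
    """Flank extraction and masking parameters.

    100 bases either side of the marker are extracted; cattle flanking
    variants seen in >= ``cattle_mask_min_count`` of
    ``cattle_possible_alleles`` (9/192 = 5%) are masked to N, yak
    flanking variants at any nonzero frequency likewise.  Markers whose
    flanks end up more than ``max_masked_fraction`` N are dropped as
    assay-infeasible.
    """

    flank_bp: int = 100
    cattle_mask_min_count: int = 9
    cattle_possible_alleles: int = 192
    max_masked_fraction: float = 0.10

    def __post_init__(self):
        if self.flank_bp < 1:
            raise ValueError("flank_bp must be >= 1")


@dataclass(frozen=True)
class BinConfig:
    """Marker clustering: <= ``cluster_gap_bp`` joins a bin; panel aims
    for ``target_spacing_bp`` between bins."""

    cluster_gap_bp: int = 1_000_000
    target_spacing_bp: int = 5_000_000

    def __post_init__(self):
        if not self.cluster_gap_bp < self.target_spacing_bp:
            raise ValueError("cluster_gap_bp must be < target_spacing_bp")


@dataclass
class TriallelicMarker:
    """A surviving panel marker with masked flanks and bin assignment."""

    marker_id: str
    chrom: str
    pos: int
    ancestral_allele: str
    yak_allele: str
    cattle_allele: str
    masked_left: str = ""
    masked_right: str = ""
    bin_id: Optional[int] = None
    yak_chrom: Optional[str] = None
    yak_pos: Optional[int] = None

    @property
    def masked_flanks(self) -> str:
        center = f"[{self.ancestral_allele}/{self.yak_allele}/{self.cattle_allele}]"
        return self.masked_left + center + self.masked_right


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: Optional[str] = None
    ancestral_allele: Optional[str] = None
    yak_allele: Optional[str] = None


def site_is_snv(site: CandidateSite) -> FilterResult:
    """Pre-filter: single-base alleles and at most three observed alleles."""
    obs = site.observed_alleles() | {site.ref_allele}
    if any(len(a) != 1 or a == "*" for a in obs):
        return FilterResult(False, "indel or symbolic allele")
    if len(obs) > 3:
        return FilterResult(False, "more than three observed alleles")
    return FilterResult(True)


def coarse_filter_site(site: CandidateSite) -> FilterResult:
    """Species filter; infers the ancestral and yak alleles on pass.

    Pass requires: every outgroup animal called and homozygous for one
    shared ancestral allele that differs from the reference base; every
    reference yak called and heterozygous ancestral/yak with one common
    yak allele; and the yak allele absent from outgroups and from the
    reference.  A fourth allele anywhere in the outgroup fails (an
    outgroup heterozygote cannot satisfy homozygosity).
    """
    ref_yaks = site.animals_with_role(SpeciesRole.REFERENCE_YAK)
    outgroups = site.animals_with_role(SpeciesRole.OUTGROUP)
    if len(ref_yaks) < 2 or len(outgroups) < 5:
        return FilterResult(False, "insufficient calls")
    out_calls = [site.genotypes.get(a) for a in outgroups]
    yak_calls = [site.genotypes.get(a) for a in ref_yaks]
    if any(c is None or c.is_missing for c in out_calls + yak_calls):
        return FilterResult(False, "insufficient calls")
    out_alleles = {c.alleles[0] for c in out_calls} | {c.alleles[1] for c in out_calls}
    if any(c.is_het for c in out_calls) or len(out_alleles) != 1:
        return FilterResult(False, "outgroup not homozygous for one allele")
    ancestral = next(iter(out_alleles))
    if ancestral == site.ref_allele:
        return FilterResult(False, "ancestral allele equals reference base")
    yak_alleles = set()
    for c in yak_calls:
        if not c.is_het or ancestral not in c.alleles:
            return FilterResult(False, "reference yak not heterozygous ancestral/yak")
        yak_alleles.add(c.alleles[0] if c.alleles[1] == ancestral else c.alleles[1])
    if len(yak_alleles) != 1:
        return FilterResult(False, "reference yaks disagree on the yak allele")
    yak = next(iter(yak_alleles))
    if yak == site.ref_allele:
        return FilterResult(False, "yak allele equals reference base")
    if yak in out_alleles:
        return FilterResult(False, "yak allele present in outgroup")
    return FilterResult(True, ancestral_allele=ancestral, yak_allele=yak)


def fine_filter_cattle(site: CandidateSite, cfg: FineFilterConfig = FineFilterConfig()) -> bool:
    """Near-fixation of the reference allele in the beef-cattle panel.

    Counts reference-base alleles among cattle-panel calls against the
    fixed ``possible_alleles`` denominator; missing calls contribute
    nothing, so they count against passing.
    """
    cattle = site.animals_with_role(SpeciesRole.CATTLE_PANEL)
    if not cattle:
        raise ValueError("no cattle panel animals on site " + str(site.site_id))
    n_ref = 0
    for a in cattle:
        call = site.genotypes.get(a)
        if call is None or call.is_missing:
            continue
        n_ref += sum(1 for al in call.alleles if al == site.ref_allele)
    return n_ref >= cfg.min_ref_alleles


def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Slice [start0, end0) from a dict of strings or a pyfaidx Fasta."""
    seq = reference[chrom]
    if isinstance(seq, str):
        if start0 < 0 or end0 > len(seq):
            raise ValueError("flank out of range")
        return seq[start0:end0]
    if start0 < 0 or end0 > len(seq):
        raise ValueError("flank out of range")
    return str(seq[start0:end0])


def extract_masked_flanks(
    site: CandidateSite,
    reference,
    flank_variants: Optional[pd.DataFrame],
    cfg: MaskConfig = MaskConfig(),
) -> tuple:
    """Extract the flanks and mask disruptive neighboring variants.

    ``flank_variants`` columns: chrom, pos (1-based), population
    ('cattle' or 'yak'), allele_count.  Cattle variants are masked when
    their allele count reaches ``cfg.cattle_mask_min_count``; yak
    variants are masked at any nonzero count.  Returns
    (left_flank, right_flank) strings of length ``cfg.flank_bp``.
    """
    left = _fetch(reference, site.chrom, site.pos - 1 - cfg.flank_bp, site.pos - 1)
    right = _fetch(reference, site.chrom, site.pos, site.pos + cfg.flank_bp)
    if flank_variants is None or len(flank_variants) == 0:
        return left, right
    near = flank_variants[
        (flank_variants["chrom"] == site.chrom)
        & (flank_variants["pos"] >= site.pos - cfg.flank_bp)
        & (flank_variants["pos"] <= site.pos + cfg.flank_bp)
        & (flank_variants["pos"] != site.pos)
    ]
    left_l, right_l = list(left), list(right)
    for _, v in near.iterrows():
        count = int(v["allele_count"])
        if count <= 0:
            continue
        pop = str(v["population"])
        if pop == "cattle" and count < cfg.cattle_mask_min_count:
            continue
        if pop not in ("cattle", "yak"):
            raise ValueError(f"unknown flanking-variant population {pop!r}")
        offset = int(v["pos"]) - site.pos
        if offset < 0:
            left_l[cfg.flank_bp + offset] = "N"
        else:
            right_l[offset - 1] = "N"
    return "".join(left_l), "".join(right_l)


def flanks_assay_feasible(left: str, right: str, cfg: MaskConfig = MaskConfig()) -> bool:
    """False when the masked fraction exceeds ``cfg.max_masked_fraction``."""
    n = left.count("N") + right.count("N")
    return n <= cfg.max_masked_fraction * (len(left) + len(right))


def unique_mapping_filter(
    markers: Sequence[TriallelicMarker], hits: Mapping[str, int]
) -> list:
    """Keep markers whose flank sequence maps exactly once to the yak assembly."""
    missing = [m.marker_id for m in markers if m.marker_id not in hits]
    if missing:
        raise KeyError(f"markers absent from hits table: {missing}")
    return [m for m in markers if hits[m.marker_id] == 1]


def drop_monomorphic(
    markers: Sequence[TriallelicMarker], population: GenotypeMatrix
) -> list:
    """Drop markers with zero parentage-allele MAF (or no calls) in the
    genotyped population."""
    if not markers:
        return []
    ids = [m.marker_id for m in markers]
    missing = [i for i in ids if i not in population.markers.index]
    if missing:
        raise KeyError(f"population matrix lacks markers: {missing}")
    freqs = estimate_panel_frequencies(population).per_marker
    kept = []
    for m in markers:
        row = freqs.loc[m.marker_id]
        if row["n_called"] == 0:
            logger.info("marker %s removed: no calls", m.marker_id)
            continue
        if row["maf"] > 0:
            kept.append(m)
    return kept


@dataclass
class BinSummary:
    n_bins: int
    mean_interbin_distance_bp: Optional[float]


def assign_bins(
    markers: Sequence[TriallelicMarker], cfg: BinConfig = BinConfig()
) -> tuple:
    """Greedy left-to-right clustering of markers into bins.

    Within a chromosome a marker joins the current bin when its gap to
    the previous marker is <= ``cfg.cluster_gap_bp``, else a new bin
    opens.  The summary reports the bin count and the mean distance
    between consecutive bin representatives (median marker position per
    bin) within chromosomes.
    """
    markers = list(markers)
    order = [(m.chrom, m.pos) for m in markers]
    if order != sorted(order):
        raise ValueError("markers must be sorted by (chrom, pos)")
    bin_id = 0
    prev_chrom, prev_pos = None, None
    bin_positions: dict = {}
    out = []
    for m in markers:
        if m.chrom != prev_chrom or m.pos - prev_pos > cfg.cluster_gap_bp:
            bin_id += 1
        m = replace(m, bin_id=bin_id)
        out.append(m)
        bin_positions.setdefault(bin_id, (m.chrom, []))[1].append(m.pos)
        prev_chrom, prev_pos = m.chrom, m.pos
    reps: dict = {}
    for b, (chrom, positions) in bin_positions.items():
        reps.setdefault(chrom, []).append(float(np.median(positions)))
    gaps = []
    for chrom, positions in reps.items():
        positions.sort()
        gaps.extend(np.diff(positions))
    summary = BinSummary(
        n_bins=bin_id,
        mean_interbin_distance_bp=float(np.mean(gaps)) if gaps else None,
    )
    return out, summary


def tiling_bin_count(
    genome_bp: int = 2_479_000_000,
    spacing_bp: int = 5_000_000,
    n_chromosomes: int = 29,
) -> tuple:
    """(interior, end) bin counts for a perfectly tiled genome.

    Interior bins tile the autosomes at the target spacing (rounded to
    the nearest integer); each chromosome contributes one end bin.
    """
    interior = int(round(genome_bp / spacing_bp))
    return interior, n_chromosomes


@dataclass
class DiscoveryResult:
    panel: list  # of TriallelicMarker
    stage_counts: dict
    bin_summary: Optional[BinSummary] = None
    skipped: dict = field(default_factory=dict)  # site id -> reason


def run_discovery(
    cohort: CohortGenotypes,
    population: GenotypeMatrix,
    hits: Mapping[str, int],
    reference=None,
    flank_variants: Optional[pd.DataFrame] = None,
    fine_cfg: FineFilterConfig = FineFilterConfig(),
    mask_cfg: MaskConfig = MaskConfig(),
    bin_cfg: BinConfig = BinConfig(),
) -> DiscoveryResult:
    """Run the full filter cascade and bin the survivors.

    Stages run coarse -> fine -> mask -> unique -> monomorphic -> bins
    and per-stage survivor counts are logged and returned.
    """
    counts = {}
    skipped = {}
    sites = []
    for s in cohort.sites:
        snv = site_is_snv(s)
        if snv.passed:
            sites.append(s)
        else:
            skipped[s.site_id] = snv.reason
            logger.info("site %s skipped: %s", s.site_id, snv.reason)
    counts["input"] = len(cohort.sites)

    coarse_pass = []
    for s in sites:
        res = coarse_filter_site(s)
        if res.passed:
            s.ancestral_allele = res.ancestral_allele
            s.yak_allele = res.yak_allele
            coarse_pass.append(s)
    counts["coarse"] = len(coarse_pass)

    fine_pass = [s for s in coarse_pass if fine_filter_cattle(s, fine_cfg)]
    counts["fine"] = len(fine_pass)

    masked = []
    for s in fine_pass:
        marker = TriallelicMarker(
            marker_id=s.site_id,
            chrom=s.chrom,
            pos=s.pos,
            ancestral_allele=s.ancestral_allele,
            yak_allele=s.yak_allele,
            cattle_allele=s.ref_allele,
        )
        if reference is not None:
            left, right = extract_masked_flanks(s, reference, flank_variants, mask_cfg)
            if not flanks_assay_feasible(left, right, mask_cfg):
                logger.info("marker %s dropped: flanks too masked", s.site_id)
                continue
            marker.masked_left, marker.masked_right = left, right
        masked.append(marker)
    counts["mask"] = len(masked)

    unique = unique_mapping_filter(masked, hits) if masked else []
    counts["unique"] = len(unique)

    poly = drop_monomorphic(unique, population) if unique else []
    counts["monomorphic"] = len(poly)

    poly.sort(key=lambda m: (m.chrom, m.pos))
    binned, summary = assign_bins(poly, bin_cfg) if poly else ([], BinSummary(0, None))
    counts["binned"] = len(binned)
    for stage, n in counts.items():
        logger.info("discovery stage %-12s: %d sites", stage, n)
    return DiscoveryResult(panel=binned, stage_counts=counts, bin_summary=summary, skipped=skipped)
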