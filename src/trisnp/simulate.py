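"""Monte-Carlo studies of panel power, plus the introgression classifier.

Three simulators:

* random calf/adult pairs — the exclusion-count distribution for
  non-parents (opposing homozygotes at unlinked HW markers);
* true sire/offspring pairs with allelic dropout — the false-exclusion
  distribution caused by genotyping error in a real parent;
* backcross lineages — the decay of cattle-associated allele counts
  over generations after an F1 hybridization event.

The cattle-associated allele is rare enough in yak to be ignored in the
parentage simulations, which therefore run on the two parentage alleles
only.  All simulators are vectorized and chunked, and are byte-for-byte
reproducible for a given config + seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import binom

_CHUNK = 100_000


@dataclass(frozen=True)
class ExclusionSimConfig:
    """Config for the pairwise exclusion simulators.

    ``maf`` may be a scalar or a per-marker sequence; ``dropout_rate``
    is the per-genotype probability that one uniformly chosen allele is
    omitted from the call (a heterozygote then appears homozygous; on a
    homozygote the omission changes nothing).
    """

    n_markers: int
    maf: Union[float, Sequence] = 0.296
    n_pairs: int = 1_000_000
    dropout_rate: float = 0.0
    relationship: str = "random_pair"
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0,1]")
        if self.relationship not in ("random_pair", "parent_offspring"):
            raise ValueError("relationship must be random_pair or parent_offspring")
        mafs = np.atleast_1d(np.asarray(self.maf, dtype=float))
        if not ((mafs >= 0) & (mafs <= 0.5)).all():
            raise ValueError("maf entries must be in [0, 0.5]")

    def maf_vector(self) -> np.ndarray:
        return np.broadcast_to(
            np.atleast_1d(np.asarray(self.maf, dtype=float)), (self.n_markers,)
        )


@dataclass(frozen=True)
class BackcrossSimConfig:
    """Config for the backcross introgression-decay simulator."""

    panel_size: int
    n_generations: int = 5
    n_replicates: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class CountHistogram:
    """Histogram of integer counts (exclusions or cattle alleles)."""

    counts: np.ndarray  # counts[k] = number of observations equal to k
    n: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.sum() != self.n:
            raise ValueError("histogram frequencies must sum to n")

    @classmethod
    def from_values(cls, values: np.ndarray, support_max: int) -> "CountHistogram":
        return cls(np.bincount(values, minlength=support_max + 1), int(len(values)))

    def fraction(self, k: int) -> float:
        if k >= len(self.counts):
            return 0.0
        return float(self.counts[k]) / self.n

    def fraction_at_most(self, k: int) -> float:
        return float(self.counts[: k + 1].sum()) / self.n

    def mean(self) -> float:
        k = np.arange(len(self.counts))
        return float((k * self.counts).sum() / self.n)

    def modes(self) -> list:
        m = self.counts.max()
        return [int(k) for k in np.flatnonzero(self.counts == m)]

    @property
    def smallest_mode(self) -> int:
        return self.modes()[0]

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, name="frequency").rename_axis("count")


def _hw_genotypes(rng, mafs, n) -> np.ndarray:
    """Minor-allele dosage (0/1/2) per animal per marker under HW."""
    return rng.binomial(2, mafs, size=(n, len(mafs))).astype(np.int8)


def _apply_dropout(rng, g: np.ndarray, rate: float) -> np.ndarray:
    """Omit one uniformly chosen allele per affected genotype.

    A heterozygote (dosage 1) collapses to either homozygote with equal
    probability; losing one allele of a homozygote leaves the call
    unchanged.
    """
    if rate == 0.0:
        return g
    out = g.copy()
    affected = (rng.random(g.shape) < rate) & (g == 1)
    out[affected] = np.where(rng.random(int(affected.sum())) < 0.5, 0, 2)
    return out


def simulate_random_pairs(cfg: ExclusionSimConfig) -> CountHistogram:
    """Exclusion counts between independent random animals.

    Both animals are drawn from HW proportions; an exclusion is a site
    where the two are homozygous for different alleles.
    """
    if cfg.relationship != "random_pair":
        raise ValueError("cfg.relationship must be 'random_pair'")
    rng = np.random.default_rng(cfg.seed)
    mafs = cfg.maf_vector()
    hist = np.zeros(cfg.n_markers + 1, dtype=np.int64)
    done = 0
    while done < cfg.n_pairs:
        n = min(_CHUNK, cfg.n_pairs - done)
        a = _apply_dropout(rng, _hw_genotypes(rng, mafs, n), cfg.dropout_rate)
        b = _apply_dropout(rng, _hw_genotypes(rng, mafs, n), cfg.dropout_rate)
        opposing = ((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
        hist += np.bincount(opposing.sum(axis=1), minlength=cfg.n_markers + 1)
        done += n
    return CountHistogram(hist, cfg.n_pairs)


def simulate_true_parent_dropout(cfg: ExclusionSimConfig) -> CountHistogram:
    """False-exclusion counts between a true sire and its offspring.

    The sire is HW; the offspring inherits one uniformly chosen sire
    allele plus one population allele.  Allelic dropout is applied to
    both animals' genotypes independently at ``cfg.dropout_rate``; with
    no dropout a true pair can never show an exclusion.
    """
    if cfg.relationship != "parent_offspring":
        raise ValueError("cfg.relationship must be 'parent_offspring'")
    rng = np.random.default_rng(cfg.seed)
    mafs = cfg.maf_vector()
    hist = np.zeros(cfg.n_markers + 1, dtype=np.int64)
    done = 0
    while done < cfg.n_pairs:
        n = min(_CHUNK, cfg.n_pairs - done)
        sire = _hw_genotypes(rng, mafs, n)
        transmitted = (rng.random((n, cfg.n_markers)) < sire / 2.0).astype(np.int8)
        population = (rng.random((n, cfg.n_markers)) < mafs).astype(np.int8)
        offspring = transmitted + population
        sc = _apply_dropout(rng, sire, cfg.dropout_rate)
        oc = _apply_dropout(rng, offspring, cfg.dropout_rate)
        opposing = ((sc == 0) & (oc == 2)) | ((sc == 2) & (oc == 0))
        hist += np.bincount(opposing.sum(axis=1), minlength=cfg.n_markers + 1)
        done += n
    return CountHistogram(hist, cfg.n_pairs)


def simulate_backcross(cfg: BackcrossSimConfig) -> list:
    """Cattle-allele counts per generation after an F1 hybridization.

    Returns one :class:`CountHistogram` per generation, generation 0
    being the F1 (exactly one cattle allele at every panel site).  Each
    backcross transmits each remaining cattle allele with probability
    1/2, so generation g counts follow Binomial(panel_size, 2^-g).
    """
    rng = np.random.default_rng(cfg.seed)
    counts = np.full(cfg.n_replicates, cfg.panel_size, dtype=np.int64)
    out = [CountHistogram.from_values(counts, cfg.panel_size)]
    for _ in range(cfg.n_generations):
        counts = rng.binomial(counts, 0.5)
        out.append(CountHistogram.from_values(counts, cfg.panel_size))
    return out


def backcross_modal_counts(
    panel_size: int, generation: int, rtol: float = 1e-9
) -> list:
    """Exact modal cattle-allele counts of Binomial(panel, 2^-g).

    Returns every count whose pmf ties the maximum to within ``rtol``;
    e.g. an 87-marker panel at generation 3 has tied modes 10 and 11.
    """
    if generation < 0:
        raise ValueError("generation must be >= 0")
    pmf = binom.pmf(np.arange(panel_size + 1), panel_size, 0.5**generation)
    mx = pmf.max()
    return [int(k) for k in np.flatnonzero(np.isclose(pmf, mx, rtol=rtol))]




@dataclass
class IntrogressionCall:
    label: str
    likelihoods: dict


def classify_introgression(
    cattle_allele_count: int,
    n_called_sites: int,
    background_freq: float = 0.0043,
    max_backcross: int = 3,
) -> IntrogressionCall:
    """Maximum-likelihood ancestry call from a cattle-allele count.

    Hypotheses: fullblood (count ~ Binomial(2n, background)); F1
    (exactly one cattle allele per site, count = n); backcross
    generation g = 1..``max_backcross`` (count ~ Binomial(n, 2^-g)).
    Flat priors; ties go to the more recent hybridization, the
    conservative choice when screening breeding stock.
    """
    if not 0.0 <= background_freq < 1.0:
        raise ValueError("background_freq must be in [0, 1)")
    if not 0 <= cattle_allele_count <= 2 * n_called_sites:
        raise ValueError("count must be in [0, 2 * n_called_sites]")
    n = n_called_sites
    like = {"fullblood": float(binom.pmf(cattle_allele_count, 2 * n, background_freq)),
            "F1": 1.0 if cattle_allele_count == n else 0.0}
    for g in range(1, max_backcross + 1):
        like[f"B{g}"] = float(binom.pmf(cattle_allele_count, n, 0.5**g))
    # most recent hybridization first: the tie-break order
    labels = ["F1"] + [f"B{g}" for g in range(1, max_backcross + 1)] + ["fullblood"]
    best = max(like[h] for h in labels)
    label = next(h for h in labels if like[h] == best)
    return IntrogressionCall(label=label, likelihoods=like)
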