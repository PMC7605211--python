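"""Closed-form identity and exclusion statistics for parentage panels.

All formulas assume Hardy-Weinberg genotype proportions and unlinked
markers.  For a biallelic parentage marker with minor allele frequency
``p`` (and ``q = 1 - p``):

* probability of identity      P_I  = (q^2)^2 + (2pq)^2 + (p^2)^2
* probability of exclusion     P_E  = P_OH = 2 p^2 q^2

``P_OH`` is the probability of opposing homozygotes between a random
offspring and a random candidate parent, the only informative
configuration when just one parent is genotyped.  Combined statistics
multiply (P_I) or accumulate the unexcluded remainder (P_E).  The
cattle-associated third allele is treated as negligible for these
statistics and tracked separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genotypes import ANCESTRAL, CATTLE, MISSING, YAK, GenotypeMatrix

UNBOUNDED = math.inf


@dataclass(frozen=True)
class GenotypeFreqsHW:
    """HW genotype frequencies (chi11, chi12, chi22) for two alleles."""

    chi11: float
    chi12: float
    chi22: float

    def __post_init__(self):
        for name in ("chi11", "chi12", "chi22"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if abs(self.chi11 + self.chi12 + self.chi22 - 1.0) > 1e-12:
            raise ValueError("genotype frequencies must sum to 1")

    @classmethod
    def from_maf(cls, maf: float) -> "GenotypeFreqsHW":
        _check_maf(maf)
        p, q = maf, 1.0 - maf
        return cls(chi11=q * q, chi12=2.0 * p * q, chi22=p * p)


@dataclass(frozen=True)
class RelatednessCoefficient:
    """Coefficient of relatedness between the candidate parents.

    Conventional values are 0.5 (full sib / parent-offspring), 0.25
    (half sib), 0.125 (first cousin); any value in (0, 1] is accepted.
    """

    r: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.r <= 1.0:
            raise ValueError(f"relatedness must be in (0,1], got {self.r}")


def _check_maf(maf: float) -> None:
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must be in [0, 0.5], got {maf}")


def _check_probs(values: Iterable[float], what: str) -> list:
    vals = list(values)
    for v in vals:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{what} values must be probabilities, got {v}")
    return vals


def pi_single(maf: float) -> float:
    """Per-marker probability that two random animals match genotypes."""
    _check_maf(maf)
    g = GenotypeFreqsHW.from_maf(maf)
    return g.chi11**2 + g.chi12**2 + g.chi22**2


def pi_combined(pi_values: Iterable[float]) -> float:
    """Panel probability of identity: product of per-marker P_I."""
    vals = _check_probs(pi_values, "P_I")
    out = 1.0
    for v in vals:
        out *= v
    return out


def pe_single(maf: float) -> float:
    """Per-marker one-parent exclusion probability, 2 p^2 q^2 under HW."""
    _check_maf(maf)
    p, q = maf, 1.0 - maf
    return 2.0 * p * p * q * q


def pe_combined(
    pe_values: Iterable[float],
    r: Union[float, RelatednessCoefficient] = 1.0,
) -> float:
    """Combined exclusion probability over markers.

    Accumulates marker by marker: each marker excludes a fraction
    ``r * P_E`` of the adults still unexcluded after the previous
    markers.  For unrelated adults (r = 1) this equals
    ``1 - prod(1 - P_E_i)``.
    """
    if isinstance(r, RelatednessCoefficient):
        r = r.r
    else:
        RelatednessCoefficient(r)  # validate
    vals = _check_probs(pe_values, "P_E")
    total = 0.0
    for p in vals:
        remaining = 1.0 - total
        total += r * remaining * p
    return total


def bulls_excludable(
    per_bull_nonexclusion: float, confidence: float = 0.99
) -> Union[int, float]:
    """How many random bulls can all be excluded at the given confidence.

    With per-bull non-exclusion probability ``u`` the chance that every
    one of B bulls is excluded is ``(1 - u)^B``; the largest B keeping
    that above ``confidence`` is ``ln(confidence) / ln(1 - u)``, reported
    rounded to the nearest integer.  Returns ``UNBOUNDED`` as u -> 0.
    """
    if not 0.0 <= per_bull_nonexclusion < 1.0:
        raise ValueError("non-exclusion probability must be in [0, 1)")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if per_bull_nonexclusion == 0.0:
        return UNBOUNDED
    return int(round(math.log(confidence) / math.log1p(-per_bull_nonexclusion)))


def snps_required(
    n_bulls: int,
    confidence: float,
    pe_per_snp: float,
    max_snps: int = 1_000_000,
) -> Union[int, float]:
    """Smallest marker count excluding all of ``n_bulls`` random bulls.

    Finds the least n with ``(1 - (1 - pe)^n)^n_bulls >= confidence`` by
    direct scan.  Returns ``UNBOUNDED`` if no n up to ``max_snps`` works.
    """
    if n_bulls < 1:
        raise ValueError("n_bulls must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if not 0.0 <= pe_per_snp < 1.0:
        raise ValueError("pe_per_snp must be in [0, 1)")
    if pe_per_snp == 0.0:
        return UNBOUNDED
    for n in range(1, max_snps + 1):
        combined = -math.expm1(n * math.log1p(-pe_per_snp))  # 1-(1-pe)^n
        if combined**n_bulls >= confidence:
            return n
    return UNBOUNDED


@dataclass
class PanelFrequencies:
    """Per-marker allele frequencies and panel-level summaries.

    ``per_marker`` columns: f_ancestral, f_yak, f_cattle, maf, call_rate,
    n_called.  Markers with zero calls have NaN frequencies and are
    excluded from the panel means (``n_flagged`` counts them).
    """

    per_marker: pd.DataFrame
    mean_maf: float
    mean_cattle_freq: float
    overall_call_rate: float
    n_flagged: int = 0


def estimate_panel_frequencies(matrix: GenotypeMatrix) -> PanelFrequencies:
    """Estimate role-allele frequencies, MAF and call rate per marker.

    Frequencies use called alleles only.  MAF is computed over the two
    parentage alleles (ancestral vs yak); the cattle-associated allele is
    excluded from that denominator and reported separately.
    """
    if matrix.n_animals == 0 or matrix.n_markers == 0:
        raise ValueError("genotype matrix is empty")
    calls = matrix.calls
    called = matrix.called_mask()
    rows = []
    for j in range(matrix.n_markers):
        col = calls[called[:, j], j, :]
        n_called = col.shape[0]
        if n_called == 0:
            rows.append((np.nan, np.nan, np.nan, np.nan, 0.0, 0))
            continue
        flat = col.ravel()
        n_anc = int((flat == ANCESTRAL).sum())
        n_yak = int((flat == YAK).sum())
        n_cat = int((flat == CATTLE).sum())
        tot = 2 * n_called
        f_anc, f_yak, f_cat = n_anc / tot, n_yak / tot, n_cat / tot
        parentage = n_anc + n_yak
        maf = min(n_anc, n_yak) / parentage if parentage else np.nan
        rows.append((f_anc, f_yak, f_cat, maf, n_called / matrix.n_animals, n_called))
    per_marker = pd.DataFrame(
        rows,
        index=matrix.markers.index,
        columns=["f_ancestral", "f_yak", "f_cattle", "maf", "call_rate", "n_called"],
    )
    ok = per_marker["n_called"] > 0
    return PanelFrequencies(
        per_marker=per_marker,
        mean_maf=float(per_marker.loc[ok, "maf"].mean()),
        mean_cattle_freq=float(per_marker.loc[ok, "f_cattle"].mean()),
        overall_call_rate=float(called.mean()),
        n_flagged=int((~ok).sum()),
    )


def best_per_chromosome_pi(
    per_marker: pd.DataFrame,
    markers: pd.DataFrame,
    n_best: int = 28,
) -> float:
    """Combined P_I from the highest-MAF marker on each chromosome.

    Picks the top-MAF marker per chromosome, keeps the ``n_best`` best of
    those, and multiplies their per-marker P_I.  This is the panel-design
    rule behind "one fingerprinting marker per autosome".
    """
    if "chrom" not in markers.columns:
        raise ValueError("markers table needs a 'chrom' column")
    maf = per_marker["maf"].dropna()
    chrom = markers.loc[maf.index, "chrom"]
    best = maf.groupby(chrom).max().sort_values(ascending=False).head(n_best)
    return pi_combined([pi_single(m) for m in best])
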