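"""The triallelic exclusion calculus.

A candidate parent is excluded at a marker when it shares no allele with
the offspring.  With two alleles only opposing homozygotes exclude; a
third allele makes heterozygous sites informative too (calf A1/A1 vs
adult A2/A3 excludes).  When the dam's genotype is available, the
obligate paternal allele — the calf allele the dam cannot have supplied
— excludes every adult not carrying it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .genotypes import GenotypeCall


class ObligateStatus(enum.Enum):
    DETERMINED = "determined"
    INDETERMINATE = "indeterminate"
    DAM_INCONSISTENT = "dam_inconsistent"


@dataclass(frozen=True)
class ObligateAllele:
    status: ObligateStatus
    allele: Optional[object] = None


class Verdict(str, enum.Enum):
    CONSISTENT = "consistent"
    EXCLUDED = "excluded"
    INSUFFICIENT = "insufficient"


@dataclass
class PairResult:
    """Exclusion tally for one calf/adult comparison.

    ``n_sites`` is the panel size, ``n_compared`` the sites where both
    animals (and the dam, in trio mode, when she is called) had calls.
    Sites where the calf and dam share no allele are reported in
    ``dam_inconsistent_sites`` and never counted as exclusions of the
    adult — they signal a pedigree or sample problem upstream.
    """

    n_sites: int
    n_compared: int
    n_exclusions: int
    excluded_sites: list = field(default_factory=list)
    dam_inconsistent_sites: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_exclusions > self.n_compared:
            raise ValueError("n_exclusions cannot exceed n_compared")


def pair_excludes(calf: GenotypeCall, adult: GenotypeCall) -> bool:
    """True iff the two calls share no allele (symmetric)."""
    if calf.is_missing or adult.is_missing:
        raise ValueError("incomparable site: missing call")
    return not calf.shares_allele(adult)


def obligate_paternal_allele(calf: GenotypeCall, dam: GenotypeCall) -> ObligateAllele:
    """Infer which calf allele must have come from the sire.

    If exactly one calf allele could be maternal the other is obligate
    paternal; if neither calf allele occurs in the dam the pair is
    flagged dam-inconsistent; if both could be maternal the site is
    indeterminate for sire exclusion beyond the shared-allele rule.
    """
    if calf.is_missing or dam.is_missing:
        raise ValueError("incomparable site: missing call")
    a, b = calf.alleles
    dam_set = dam.allele_set()
    if a == b:
        if a in dam_set:
            return ObligateAllele(ObligateStatus.DETERMINED, a)
        return ObligateAllele(ObligateStatus.DAM_INCONSISTENT)
    a_maternal, b_maternal = a in dam_set, b in dam_set
    if a_maternal and b_maternal:
        return ObligateAllele(ObligateStatus.INDETERMINATE)
    if a_maternal:
        return ObligateAllele(ObligateStatus.DETERMINED, b)
    if b_maternal:
        return ObligateAllele(ObligateStatus.DETERMINED, a)
    return ObligateAllele(ObligateStatus.DAM_INCONSISTENT)


def count_exclusions(
    calf: Mapping[str, GenotypeCall],
    adult: Mapping[str, GenotypeCall],
    dam: Optional[Mapping[str, GenotypeCall]] = None,
) -> PairResult:
    """Tally exclusions between a calf and a candidate parent.

    One-parent mode counts sites with an empty allele-set intersection.
    Trio mode additionally excludes the adult at sites where the obligate
    paternal allele is determined and absent from the adult.  Sites with
    any missing call fall back (dam missing) or are skipped entirely
    (calf/adult missing) and do not enter ``n_compared``.
    """
    if set(calf) != set(adult):
        raise ValueError("calf and adult profiles cover different panels")
    if dam is not None and not set(dam) <= set(calf):
        raise ValueError("dam profile covers markers outside the panel")
    n_compared = 0
    excluded, dam_bad = [], []
    for mid in calf:
        c, a = calf[mid], adult[mid]
        if c.is_missing or a.is_missing:
            continue
        n_compared += 1
        if pair_excludes(c, a):
            excluded.append(mid)
            continue
        if dam is not None:
            d = dam.get(mid)
            if d is None or d.is_missing:
                continue
            ob = obligate_paternal_allele(c, d)
            if ob.status is ObligateStatus.DAM_INCONSISTENT:
                dam_bad.append(mid)
            elif ob.status is ObligateStatus.DETERMINED and ob.allele not in a.allele_set():
                excluded.append(mid)
    return PairResult(
        n_sites=len(calf),
        n_compared=n_compared,
        n_exclusions=len(excluded),
        excluded_sites=excluded,
        dam_inconsistent_sites=dam_bad,
    )


def classify_parentage(
    result: PairResult,
    allowed_false_exclusions: int = 2,
    min_compared_fraction: float = 0.94,
) -> Verdict:
    """Error-tolerant parentage verdict for one pair.

    ``allowed_false_exclusions`` absorbs genotyping artifacts (allelic
    dropout); the default of 2 suits a ~1% per-genotype error rate on an
    87-marker panel.  Pairs compared at fewer than
    ``min_compared_fraction`` of panel sites are ruled insufficient —
    with a 97% per-animal call rate at least 94% of sites have calls for
    both animals of a pair.
    """
    if result.n_compared < min_compared_fraction * result.n_sites:
        return Verdict.INSUFFICIENT
    if result.n_exclusions <= allowed_false_exclusions:
        return Verdict.CONSISTENT
    return Verdict.EXCLUDED
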