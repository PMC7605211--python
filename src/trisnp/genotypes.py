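"""Core containers for triallelic-marker genotype data.

Every marker in a triallelic panel carries three role-labelled alleles:
the *Bos* ancestral allele (shared by the outgroup species), the
yak-associated allele used for parentage, and the *B. taurus*-associated
allele used to flag cattle introgression.  Roles, not bases, drive all
downstream logic; bases are retained only for file IO.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

MISSING = -1

#: Role codes used in integer-encoded genotype matrices.
ANCESTRAL, YAK, CATTLE = 0, 1, 2

ROLE_NAMES = {ANCESTRAL: "ancestral", YAK: "yak", CATTLE: "cattle"}


class SpeciesRole(str, enum.Enum):
    """Which group an animal belongs to in the discovery cohort."""

    REFERENCE_YAK = "reference_yak"
    OUTGROUP = "outgroup"
    CATTLE_PANEL = "cattle_panel"
    POPULATION_YAK = "population_yak"


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid genotype, or a missing call.

    ``alleles`` is a sorted 2-tuple of hashables (bases or role labels),
    or ``None`` for a missing call.  Equality is order-insensitive.
    """

    alleles: Optional[tuple]

    def __init__(self, a=None, b=None, *, alleles=None):
        if alleles is None and a is not None:
            if b is None:
                raise ValueError("a diploid call needs two alleles")
            alleles = (a, b)
        if alleles is not None:
            if len(alleles) != 2:
                raise ValueError("a diploid call has exactly two alleles")
            alleles = tuple(sorted(alleles, key=str))
        object.__setattr__(self, "alleles", alleles)

    @classmethod
    def missing(cls) -> "GenotypeCall":
        return cls()

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]

    def allele_set(self) -> frozenset:
        if self.alleles is None:
            raise ValueError("missing call has no alleles")
        return frozenset(self.alleles)

    def shares_allele(self, other: "GenotypeCall") -> bool:
        return bool(self.allele_set() & other.allele_set())

    def __repr__(self) -> str:  # compact, for test diffs
        if self.alleles is None:
            return "GenotypeCall(missing)"
        return f"GenotypeCall({self.alleles[0]}/{self.alleles[1]})"


@dataclass
class CandidateSite:
    """One candidate triallelic site with per-animal diploid calls.

    ``ref_allele`` is the base in the cattle-like reference assembly (the
    cattle-associated allele of a true marker).  ``ancestral_allele`` and
    ``yak_allele`` may be unknown before the coarse filter infers them.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    genotypes: dict  # animal id -> GenotypeCall (base alleles)
    species_role: Mapping[str, SpeciesRole]
    ancestral_allele: Optional[str] = None
    yak_allele: Optional[str] = None
    site_id: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.site_id is None:
            self.site_id = f"{self.chrom}_{self.pos}"
        alleles = [self.ref_allele, self.ancestral_allele, self.yak_allele]
        known = [a for a in alleles if a is not None]
        if len(set(known)) != len(known):
            raise ValueError(f"site {self.site_id}: role alleles must be distinct")

    def animals_with_role(self, role: SpeciesRole) -> list:
        return [a for a, r in self.species_role.items() if r == role]

    def observed_alleles(self) -> set:
        out = set()
        for call in self.genotypes.values():
            if not call.is_missing:
                out.update(call.alleles)
        return out


@dataclass
class CohortGenotypes:
    """Per-animal calls at candidate sites, with species-role labels."""

    sites: list  # of CandidateSite
    roles: dict  # animal id -> SpeciesRole
    samples: list = field(default_factory=list)

    def __post_init__(self):
        if not self.samples:
            self.samples = list(self.roles)

    def __len__(self) -> int:
        return len(self.sites)


class GenotypeMatrix:
    """Animals x markers diploid genotypes, role-encoded.

    ``calls`` has shape (n_animals, n_markers, 2) with entries in
    {ANCESTRAL, YAK, CATTLE} or MISSING (both slots MISSING for a no-call).
    ``markers`` is a DataFrame indexed by marker id with at least the
    columns ``ancestral``, ``yak``, ``cattle`` (bases) and optionally
    ``chrom``/``pos``.
    """

    def __init__(self, calls: np.ndarray, animals: Iterable[str], markers: pd.DataFrame):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 3 or calls.shape[2] != 2:
            raise ValueError("calls must have shape (n_animals, n_markers, 2)")
        self.calls = calls
        self.animals = list(animals)
        self.markers = markers
        if calls.shape[0] != len(self.animals):
            raise ValueError("animal count does not match calls")
        if calls.shape[1] != len(markers):
            raise ValueError("marker count does not match calls")
        # a call is all-or-nothing: no half-calls at this layer
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-calls are not representable here")
        # genotypes are unordered: store each pair in canonical order
        self.calls = np.sort(self.calls, axis=2)

    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def marker_ids(self) -> list:
        return list(self.markers.index)

    def called_mask(self) -> np.ndarray:
        """Boolean (n_animals, n_markers): genotype present."""
        return self.calls[:, :, 0] != MISSING

    def call_rate(self) -> float:
        return float(self.called_mask().mean())

    def to_strings(self) -> pd.DataFrame:
        """Render calls as unordered base pairs ('CT'), '--' for missing."""
        base_lut = self.markers[["ancestral", "yak", "cattle"]].to_numpy()
        out = np.full((self.n_animals, self.n_markers), "--", dtype=object)
        for j in range(self.n_markers):
            bases = base_lut[j]
            col = self.calls[:, j, :]
            for i in range(self.n_animals):
                a, b = col[i]
                if a == MISSING:
                    continue
                pair = sorted((bases[a], bases[b]))
                out[i, j] = pair[0] + pair[1]
        return pd.DataFrame(out, index=self.animals, columns=self.markers.index)

    @classmethod
    def from_strings(cls, table: pd.DataFrame, markers: pd.DataFrame) -> "GenotypeMatrix":
        """Inverse of :meth:`to_strings`; unknown bases raise."""
        table = table[list(markers.index)]
        calls = np.full((table.shape[0], table.shape[1], 2), MISSING, dtype=np.int8)
        for j, mid in enumerate(markers.index):
            row = markers.loc[mid]
            code = {row["ancestral"]: ANCESTRAL, row["yak"]: YAK, row["cattle"]: CATTLE}
            for i, val in enumerate(table.iloc[:, j]):
                if val in ("--", "", None) or pd.isna(val):
                    continue
                if len(val) != 2 or val[0] not in code or val[1] not in code:
                    raise ValueError(
                        f"marker {mid}, animal {table.index[i]}: bad call {val!r}"
                    )
                pair = sorted((code[val[0]], code[val[1]]))
                calls[i, j] = pair
        return cls(calls, list(table.index), markers)

    def profile(self, animal: str) -> dict:
        """Marker id -> GenotypeCall (role codes) for one animal."""
        i = self.animals.index(animal)
        out = {}
        for j, mid in enumerate(self.markers.index):
            a, b = self.calls[i, j]
            out[mid] = GenotypeCall.missing() if a == MISSING else GenotypeCall(int(a), int(b))
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.animals == other.animals
            and list(self.markers.index) == list(other.markers.index)
            and np.array_equal(self.calls, other.calls)
        )
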