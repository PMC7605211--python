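"""Readers and writers for the formats the pipeline touches.

Multi-sample VCF v4.2 (1-based, GT only) and FASTA carry the discovery
cohort; tab-separated tables carry genotype matrices (assay-style calls
like "CT", "--" for missing), marker metadata, truth tables, alignment
hit counts and the final panel; assay loci go out as BED (0-based,
half-open).  VCF reading uses cyvcf2, FASTA reading pyfaidx.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .discovery import TriallelicMarker
from .genotypes import (
    CandidateSite,
    CohortGenotypes,
    GenotypeCall,
    GenotypeMatrix,
    SpeciesRole,
)

_VALID_BASES = set("ACGT")


# --- coordinates ---------------------------------------------------------

def pos_to_zero_based(pos: int) -> int:
    """1-based VCF position -> 0-based coordinate."""
    if pos < 1:
        raise ValueError("1-based position must be >= 1")
    return pos - 1


def zero_based_to_pos(start0: int) -> int:
    """0-based coordinate -> 1-based VCF position."""
    if start0 < 0:
        raise ValueError("0-based coordinate must be >= 0")
    return start0 + 1


def assay_interval(pos: int, flank: int = 1000) -> tuple:
    """BED interval (0-based half-open) of the 2001-base assay locus
    centered on a 1-based marker position; clamped at the contig start."""
    start = max(0, pos - flank - 1)
    return start, pos + flank


# --- FASTA ---------------------------------------------------------------

def write_fasta(reference: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict:
    """Load contigs as plain strings (via pyfaidx)."""
    from pyfaidx import Fasta

    with Fasta(path) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


# --- roles table ---------------------------------------------------------

def write_roles_table(roles: Mapping[str, SpeciesRole], path: str) -> None:
    pd.DataFrame(
        {"animal": list(roles), "role": [SpeciesRole(r).value for r in roles.values()]}
    ).to_csv(path, sep="\t", index=False)


def read_roles_table(path: str) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {row.animal: SpeciesRole(row.role) for row in df.itertuples()}


# --- VCF -----------------------------------------------------------------

def write_cohort_vcf(
    cohort: CohortGenotypes,
    path: str,
    reference: Optional[Mapping[str, str]] = None,
) -> None:
    """Emit the cohort as a plain-text multi-sample VCF v4.2."""
    samples = cohort.samples
    lines = ["##fileformat=VCFv4.2", "##source=trisnp"]
    if reference:
        for name, seq in reference.items():
            lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for site in sorted(cohort.sites, key=lambda s: (s.chrom, s.pos)):
        alts = sorted(site.observed_alleles() - {site.ref_allele})
        if not alts:
            alts = ["."]
        index = {site.ref_allele: 0}
        index.update({a: i + 1 for i, a in enumerate(alts) if a != "."})
        gts = []
        for animal in samples:
            call = site.genotypes.get(animal)
            if call is None or call.is_missing:
                gts.append("./.")
            else:
                a, b = sorted(index[x] for x in call.alleles)
                gts.append(f"{a}/{b}")
        lines.append(
            "\t".join(
                [site.chrom, str(site.pos), site.site_id, site.ref_allele,
                 ",".join(alts), ".", ".", ".", "GT"] + gts
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cohort_vcf(path: str, roles: Mapping[str, SpeciesRole]) -> tuple:
    """Read diploid calls per site per animal from a VCF.

    Records containing indel or symbolic alleles are skipped and
    counted.  Every sample in the VCF must appear in the roles table.
    Returns (CohortGenotypes, n_skipped_indels).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in roles]
    if unknown:
        raise KeyError(f"samples missing from roles table: {unknown}")
    sites, n_skipped = [], 0
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        alleles = [a for a in alleles if a != "."]
        if any(len(a) != 1 or a not in _VALID_BASES for a in alleles):
            n_skipped += 1
            continue
        genotypes = {}
        for sample, gt in zip(samples, var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                genotypes[sample] = GenotypeCall.missing()
            else:
                genotypes[sample] = GenotypeCall(alleles[a], alleles[b])
        sites.append(
            CandidateSite(
                chrom=var.CHROM, pos=var.POS, ref_allele=var.REF,
                genotypes=genotypes, species_role=dict(roles),
                site_id=var.ID if var.ID not in (None, ".") else None,
            )
        )
    vcf.close()
    cohort = CohortGenotypes(sites=sites, roles=dict(roles), samples=samples)
    return cohort, n_skipped


# --- genotype tables -----------------------------------------------------

def write_markers_table(markers: pd.DataFrame, path: str) -> None:
    markers.rename_axis("marker_id").to_csv(path, sep="\t")


def read_markers_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}).set_index("marker_id")
    return df


def write_genotype_table(matrix: GenotypeMatrix, path: str) -> None:
    matrix.to_strings().rename_axis("animal").to_csv(path, sep="\t")


def read_genotype_table(path: str, markers: pd.DataFrame) -> GenotypeMatrix:
    """Read an assay-style genotype table (animals x markers).

    Calls are unordered base pairs ("CT" == "TC"), missing "--".  Ragged
    rows raise with the offending row number.
    """
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"{path}: empty genotype table")
    width = len(rows[0])
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row at line {i}")
    header = rows[0]
    df = pd.DataFrame(rows[1:], columns=header).set_index(header[0])
    return GenotypeMatrix.from_strings(df, markers)


# --- panel + BED ---------------------------------------------------------

PANEL_COLUMNS = [
    "marker_id", "chrom", "pos", "yak_chrom", "yak_pos", "bin",
    "allele_ancestral", "allele_yak", "allele_cattle", "masked_flanks",
]


def write_panel(
    markers: Sequence[TriallelicMarker], panel_path: str, bed_path: Optional[str] = None
) -> None:
    """Write the panel table and the BED of 2001-base assay loci."""
    rows = []
    for m in markers:
        if m.bin_id is None:
            raise ValueError(f"marker {m.marker_id} has no bin assignment")
        rows.append(
            (m.marker_id, m.chrom, m.pos, m.yak_chrom or ".",
             m.yak_pos if m.yak_pos is not None else ".", m.bin_id,
             m.ancestral_allele, m.yak_allele, m.cattle_allele, m.masked_flanks)
        )
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(panel_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for m in markers:
                start, end = assay_interval(m.pos)
                fh.write(f"{m.chrom}\t{start}\t{end}\t{m.marker_id}\n")


def read_panel(path: str) -> list:
    """Read a panel table back into TriallelicMarker records."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "yak_chrom": str})
    out = []
    for row in df.itertuples(index=False):
        flanks = str(row.masked_flanks)
        if "[" in flanks and "]" in flanks:
            left, rest = flanks.split("[", 1)
            _, right = rest.split("]", 1)
        else:
            left = right = ""
        out.append(
            TriallelicMarker(
                marker_id=row.marker_id, chrom=row.chrom, pos=int(row.pos),
                ancestral_allele=row.allele_ancestral, yak_allele=row.allele_yak,
                cattle_allele=row.allele_cattle, masked_left=left, masked_right=right,
                bin_id=int(row.bin),
                yak_chrom=None if row.yak_chrom in (".", "nan") else row.yak_chrom,
                yak_pos=None if str(row.yak_pos) in (".", "nan") else int(row.yak_pos),
            )
        )
    return out


def write_hits_table(hits: Mapping[str, int], path: str) -> None:
    pd.DataFrame({"marker_id": list(hits), "hits": list(hits.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_hits_table(path: str) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["marker_id"], df["hits"].astype(int)))


def write_histogram(hist, path: str) -> None:
    hist.to_series().to_csv(path, sep="\t")
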