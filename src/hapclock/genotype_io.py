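"""Genotype, phenotype and results I/O.

Conventions used throughout the package:

* Coordinates are 1-based physical positions in bp, inclusive, as in VCF.
* Genotype codes count copies of the alt allele: 0 = homozygous ref,
  1 = heterozygous, 2 = homozygous alt, :data:`MISSING` (-1) = no call.
* Any phase information present in an input VCF is discarded; phasing of
  heterozygotes is done downstream against the homozygote template, so
  upstream phase must not leak in.
* Missing calls are preserved as ``MISSING`` and excluded from allele
  counts; they are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Sentinel genotype code for a missing call.
MISSING: int = -1

CASE = "case"
CONTROL = "control"


class GenotypeIOError(ValueError):
    """Raised for malformed genotype, phenotype or map files."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant: identifier, coordinate and allele pair."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenotypeIOError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise GenotypeIOError(f"variant {self.id}: ref and alt alleles are identical")


@dataclass
class GenotypeMatrix:
    """Variants x individuals matrix of genotype codes.

    ``calls[i, j]`` is the genotype of individual ``j`` at variant ``i``,
    coded as copies of the alt allele (0/1/2) or :data:`MISSING`.
    """

    variants: list[VariantRecord]
    individuals: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.individuals)):
            raise GenotypeIOError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.individuals)} individuals"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeIOError(
                f"invalid genotype code {self.calls[i, j]} at variant "
                f"{self.variants[i].id}, individual {self.individuals[j]}"
            )
        if len(set(v.id for v in self.variants)) != len(self.variants):
            raise GenotypeIOError("duplicated variant id")
        if len(set(self.individuals)) != len(self.individuals):
            raise GenotypeIOError("duplicated individual id")
        prev: tuple[str, int] | None = None
        for v in self.variants:
            if prev is not None and prev[0] == v.chrom and v.pos <= prev[1]:
                raise GenotypeIOError(
                    f"variants not sorted by position: {v.id} at {v.chrom}:{v.pos} "
                    f"follows position {prev[1]}; sort the input by (chrom, pos)"
                )
            prev = (v.chrom, v.pos)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def variant_index(self, variant_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.id == variant_id:
                return i
        raise KeyError(f"variant {variant_id!r} not in matrix")

    def individual_index(self, individual_id: str) -> int:
        try:
            return self.individuals.index(individual_id)
        except ValueError:
            raise KeyError(f"individual {individual_id!r} not in matrix") from None

    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def subset_window(self, chrom: str, start: int, end: int) -> "GenotypeMatrix":
        """Restrict to variants on ``chrom`` with start <= pos <= end."""
        keep = [i for i, v in enumerate(self.variants)
                if v.chrom == chrom and start <= v.pos <= end]
        if not keep:
            raise GenotypeIOError(f"no variants in window {chrom}:{start}-{end}")
        return GenotypeMatrix(
            [self.variants[i] for i in keep], list(self.individuals), self.calls[keep]
        )


@dataclass
class PhenotypeTable:
    """Mapping of individual id to case/control label."""

    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind, g in self.groups.items():
            if g not in (CASE, CONTROL):
                raise GenotypeIOError(f"individual {ind}: unknown group label {g!r}")

    def ids(self, group: str) -> list[str]:
        return [i for i, g in self.groups.items() if g == group]

    @property
    def n_case(self) -> int:
        return len(self.ids(CASE))

    @property
    def n_control(self) -> int:
        return len(self.ids(CONTROL))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, split_multiallelic: bool = False) -> GenotypeMatrix:
    """Read an unphased genotype matrix from a VCF 4.x file.

    Phase separators (``|`` vs ``/``) are ignored. ``./.`` becomes
    :data:`MISSING`. Multiallelic records are rejected unless
    ``split_multiallelic`` is set, in which case the first alt allele is
    kept and genotypes carrying any other alt become MISSING.
    """
    path = str(path)
    vcf = VCF(path)
    individuals = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1:
            if not split_multiallelic:
                raise GenotypeIOError(
                    f"multiallelic record at {rec.CHROM}:{rec.POS} ({rec.ID or '.'}): "
                    "this analysis is strictly biallelic; pass split_multiallelic=True "
                    "to keep the first alt allele"
                )
            if not alts:
                continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        variants.append(VariantRecord(vid, rec.CHROM, rec.POS, rec.REF, alts[0]))
        row = np.empty(len(individuals), dtype=np.int8)
        for j, gt in enumerate(rec.genotypes):
            a = gt[:-1]  # last element is the phased flag, discarded
            if any(x < 0 for x in a):
                row[j] = MISSING
            elif any(x > 1 for x in a):
                row[j] = MISSING  # genotype involves a dropped alt allele
            else:
                row[j] = sum(a)
        rows.append(row)
    vcf.close()
    calls = np.vstack(rows) if rows else np.empty((0, len(individuals)), dtype=np.int8)
    return GenotypeMatrix(variants, individuals, calls)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal unphased VCF 4.2 file (deterministic bytes)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##source=hapclock\n")
        for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.individuals) + "\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for v, row in zip(matrix.variants, matrix.calls):
            gts = "\t".join(gt_strings[int(c)] for c in row)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# TSV genotype matrix
# ---------------------------------------------------------------------------

_TSV_META = ["id", "chrom", "pos", "ref", "alt"]


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect: meta columns (id, chrom, pos, ref, alt) then
    one column per individual with cells in {0, 1, 2, NA}."""
    df = pd.DataFrame(
        {
            "id": [v.id for v in matrix.variants],
            "chrom": [v.chrom for v in matrix.variants],
            "pos": [v.pos for v in matrix.variants],
            "ref": [v.ref_allele for v in matrix.variants],
            "alt": [v.alt_allele for v in matrix.variants],
        }
    )
    calls = matrix.calls.astype(object)
    for j, ind in enumerate(matrix.individuals):
        col = calls[:, j].copy()
        col[col == MISSING] = "NA"
        df[ind] = col
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the TSV dialect written by :func:`write_genotype_tsv`.

    Round-trips bit-exactly with the writer. Duplicated variant ids and
    unsorted positions are rejected (the matrix constructor enforces both).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"],
                     keep_default_na=False)
    missing_cols = [c for c in _TSV_META if c not in df.columns]
    if missing_cols:
        raise GenotypeIOError(f"genotype TSV lacks required columns: {missing_cols}")
    variants = [
        VariantRecord(str(r.id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]
    individuals = [c for c in df.columns if c not in _TSV_META]
    body = df[individuals].to_numpy(dtype=object)
    calls = np.empty(body.shape, dtype=np.int8)
    isna = pd.isna(body.astype(float))
    calls[isna] = MISSING
    calls[~isna] = body[~isna].astype(np.int8)
    return GenotypeMatrix(variants, individuals, calls)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path,
                    matrix: GenotypeMatrix | None = None) -> PhenotypeTable:
    """Read a two-column (id, group) TSV of case/control labels.

    Group labels must be ``case`` or ``control``. Duplicate ids are an
    error. Ids absent from ``matrix`` (when given) are kept with a logged
    warning so a phenotype file can cover a superset of genotyped samples.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise GenotypeIOError(f"phenotype file {path} is empty") from None
    if df.empty:
        raise GenotypeIOError(f"phenotype file {path} is empty")
    if df.shape[1] < 2:
        raise GenotypeIOError("phenotype TSV needs two columns: id, group")
    ids = df.iloc[:, 0].tolist()
    labels = df.iloc[:, 1].tolist()
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise GenotypeIOError(f"duplicate individual id(s) in phenotype file: {dup}")
    table = PhenotypeTable(dict(zip(ids, labels)))
    if matrix is not None:
        absent = [i for i in ids if i not in set(matrix.individuals)]
        if absent:
            logger.warning("%d phenotype id(s) absent from genotype matrix "
                           "(kept): %s ...", len(absent), absent[:5])
    return table


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgroup\n")
        for ind, g in table.groups.items():
            fh.write(f"{ind}\t{g}\n")
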