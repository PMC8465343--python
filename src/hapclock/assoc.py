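"""Case/control allelic association scan.

For every polymorphic variant: genotype counts per group, pooled minor
allele frequency, a two-sided Fisher exact test on the 2x2 major/minor
allele-count table, and an exact Hardy-Weinberg test per group.

The minor allele is oriented on the case+control pooled non-missing calls
(ties broken toward the alt allele); missing genotypes are excluded from
all counts. The two-sided Fisher p-value uses the point-probability-sum
definition: the sum of hypergeometric probabilities of every table with
the observed margins whose probability does not exceed that of the
observed table (the convention of mainstream statistical software).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import CASE, CONTROL, MISSING, GenotypeMatrix, PhenotypeTable, VariantRecord

logger = logging.getLogger(__name__)

#: Informal genome-wide highlight threshold used when flagging results.
SIGNIFICANCE_THRESHOLD = 5e-7

#: Relative tolerance for float ties between point probabilities.
_REL_TOL = 1e-7


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-group genotype counts oriented by the pooled minor allele."""

    case: tuple[int, int, int]      # (n_hom_major, n_het, n_hom_minor)
    control: tuple[int, int, int]

    def __post_init__(self) -> None:
        for grp in (self.case, self.control):
            if any(c < 0 for c in grp):
                raise ValueError(f"negative genotype count in {grp}")


@dataclass(frozen=True)
class AssociationResult:
    variant: VariantRecord
    counts: GenotypeCounts
    maf: float
    fisher_p: float
    hwe_p_case: float
    hwe_p_control: float

    @property
    def significant(self) -> bool:
        return self.fisher_p < SIGNIFICANCE_THRESHOLD


def allele_counts(counts: GenotypeCounts) -> np.ndarray:
    """2x2 (major, minor) allele counts by group: rows (case, control)."""
    table = np.array(
        [
            [2 * counts.case[0] + counts.case[1], 2 * counts.case[2] + counts.case[1]],
            [2 * counts.control[0] + counts.control[1],
             2 * counts.control[2] + counts.control[1]],
        ],
        dtype=np.int64,
    )
    if table.sum() == 0:
        raise ValueError("all genotype counts are zero")
    return table


def maf(counts: GenotypeCounts) -> float:
    """Pooled minor allele frequency over non-missing calls of both groups."""
    table = allele_counts(counts)
    total = int(table.sum())
    minor = int(table[:, 1].sum())
    f = minor / total
    # counts are minor-oriented upstream; guard against mis-oriented input
    return min(f, 1.0 - f)


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def fisher_allelic(table: np.ndarray | list) -> float:
    """Two-sided Fisher exact p for a 2x2 allele-count table.

    Sums hypergeometric point probabilities over all tables with the
    observed margins whose probability is <= that of the observed table
    (within relative tolerance 1e-7 for float ties). Degenerate margins
    (an empty row or column) give p = 1 with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer entries")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1, c2 = int(t[:, 0].sum()), int(t[:, 1].sum())
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        logger.warning("degenerate 2x2 table margins %s: p = 1", t.tolist())
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = (
        _log_comb(c1, support)
        + _log_comb(c2, r1 - support)
        - _log_comb(n, r1)
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    return min(p, 1.0)


def hwe_exact(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg test p-value.

    Uses the conditional distribution of the heterozygote count given the
    allele counts (Levene-Haldane): configurations with point probability
    <= the observed one (relative tolerance 1e-7) are summed. The
    distribution is built in log space via the ratio recurrence
    ``w(h+2)/w(h) = 4*hom_major(h)*hom_minor(h) / ((h+1)(h+2))``, which
    stays stable for cohort-scale counts. Monomorphic samples give p = 1.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)
    if n_minor == 0:
        return 1.0
    support = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - support) // 2
    hom_maj = n - support - hom_min
    # log w(h) by cumulative sum of log ratios between successive h
    h = support[:-1].astype(np.float64)
    log_ratio = (
        np.log(4.0) + np.log(hom_maj[:-1]) + np.log(hom_min[:-1])
        - np.log(h + 1.0) - np.log(h + 2.0)
    )
    logw = np.concatenate([[0.0], np.cumsum(log_ratio)])
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    w_obs = w[np.flatnonzero(support == n_het)[0]]
    return float(min(1.0, w[w <= w_obs * (1.0 + _REL_TOL)].sum()))


def _group_counts(codes: np.ndarray) -> tuple[int, int, int]:
    """(n_hom_ref, n_het, n_hom_alt) among non-missing codes."""
    return (
        int((codes == 0).sum()),
        int((codes == 1).sum()),
        int((codes == 2).sum()),
    )


def scan(matrix: GenotypeMatrix, phenotypes: PhenotypeTable) -> list[AssociationResult]:
    """Allelic association scan over all polymorphic variants.

    Returns one result per polymorphic variant, sorted ascending by
    Fisher p-value; monomorphic variants are skipped with a log entry.
    """
    present = set(matrix.individuals)
    case_idx = [matrix.individual_index(i) for i in phenotypes.ids(CASE) if i in present]
    ctrl_idx = [matrix.individual_index(i) for i in phenotypes.ids(CONTROL) if i in present]
    if not case_idx or not ctrl_idx:
        raise ValueError("phenotype table and genotype matrix share no usable "
                         "case/control individuals")
    results: list[AssociationResult] = []
    n_mono = 0
    for i, variant in enumerate(matrix.variants):
        row = matrix.calls[i]
        case_codes = row[case_idx]
        ctrl_codes = row[ctrl_idx]
        pooled = np.concatenate([case_codes, ctrl_codes])
        pooled = pooled[pooled != MISSING]
        if pooled.size == 0:
            n_mono += 1
            continue
        alt_count = int(pooled.sum())
        total = 2 * pooled.size
        if alt_count == 0 or alt_count == total:
            n_mono += 1
            logger.debug("skipping monomorphic variant %s", variant.id)
            continue
        # orient by pooled minor allele; ties toward alt
        minor_is_alt = alt_count <= total - alt_count
        ca = _group_counts(case_codes[case_codes != MISSING])
        co = _group_counts(ctrl_codes[ctrl_codes != MISSING])
        if not minor_is_alt:
            ca, co = ca[::-1], co[::-1]
        counts = GenotypeCounts(case=tuple(ca), control=tuple(co))
        results.append(
            AssociationResult(
                variant=variant,
                counts=counts,
                maf=maf(counts),
                fisher_p=fisher_allelic(allele_counts(counts)),
                hwe_p_case=hwe_exact(*counts.case),
                hwe_p_control=hwe_exact(*counts.control),
            )
        )
    if n_mono:
        logger.info("skipped %d monomorphic/empty variants", n_mono)
    results.sort(key=lambda r: (r.fisher_p, r.variant.chrom, r.variant.pos))
    return results


def write_results(results: list[AssociationResult], path: str | Path) -> None:
    """Write the association results TSV (one row per variant, sorted by p)."""
    rows = []
    for r in results:
        rows.append(
            {
                "id": r.variant.id,
                "chrom": r.variant.chrom,
                "pos": r.variant.pos,
                "case_hom_major": r.counts.case[0],
                "case_het": r.counts.case[1],
                "case_hom_minor": r.counts.case[2],
                "control_hom_major": r.counts.control[0],
                "control_het": r.counts.control[1],
                "control_hom_minor": r.counts.control[2],
                "maf": round(r.maf, 6),
                "fisher_p": f"{r.fisher_p:.6g}",
                "hwe_p_case": f"{r.hwe_p_case:.6g}",
                "hwe_p_control": f"{r.hwe_p_control:.6g}",
                "significant": r.significant,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
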