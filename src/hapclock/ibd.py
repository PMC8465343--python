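"""Allele-carrying haplotype detection among homozygotes and template phasing.

The procedure works on unphased genotypes and exploits the fact that an
individual homozygous for a focal allele exposes its haplotype directly
wherever both chromosomes still carry the ancestral segment:

1. **Core region** — starting from the focal variant, extend left and
   right one variant at a time while *every* carrier is homozygous and
   all carriers share the same homozygous genotype. The maximal such run
   is the core shared by all carriers.
2. **Per-individual extension** — beyond the core, carriers disagree.
   Stepping outward one variant at a time over the currently "extending"
   carriers, the majority homozygous allele among them is determined; a
   carrier keeps extending iff it is homozygous for that majority allele,
   otherwise its boundary is the last agreeing variant. A direction
   terminates when no majority exists (in particular when the last two
   extending carriers disagree) or the window end is reached.
3. **Template** — the longest haplotype, joining the deepest-reaching
   left and right arms across the core, serves as a phasing template.
4. **Heterozygote phasing** — walking outward from the focal variant, a
   heterozygote stays consistent with the template while its genotype
   contains the template allele; the first homozygous-non-template call
   (or a missing call, conservatively) ends the segment.

Missing genotypes always stop extension for the individual concerned:
this shortens haplotypes but never fabricates sharing.

Boundary convention: a boundary is the *last agreeing variant*; physical
length is ``right_pos - left_pos`` (not +1), and genetic length is later
measured between the same two positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

HOM_CODES = (0, 2)


def _hom_allele(code: int) -> int:
    """Allele index (0 = ref, 1 = alt) of a homozygous genotype code."""
    return 0 if code == 0 else 1


@dataclass(frozen=True)
class CoreRegion:
    """Contiguous run of variants at which all carriers are identically homozygous."""

    left_index: int
    right_index: int
    focal_index: int
    allele_vector: tuple[int, ...]  # allele index (0/1) per core variant

    def __post_init__(self) -> None:
        if not (self.left_index <= self.focal_index <= self.right_index):
            raise ValueError("core region must contain the focal variant")
        if len(self.allele_vector) != self.right_index - self.left_index + 1:
            raise ValueError("allele_vector length does not match core span")

    @property
    def n_variants(self) -> int:
        return self.right_index - self.left_index + 1


@dataclass(frozen=True)
class HaplotypeSegment:
    """One allele-carrying haplotype with its outermost variant boundaries."""

    individual: str
    chrom: str
    left_index: int
    right_index: int
    left_pos: int
    right_pos: int
    carrying_allele: int  # allele index at the focal variant (0 = ref, 1 = alt)
    zygosity: str         # "hom" or "het"

    @property
    def phys_length(self) -> int:
        return self.right_pos - self.left_pos

    @property
    def n_variants(self) -> int:
        return self.right_index - self.left_index + 1


@dataclass(frozen=True)
class TemplateHaplotype:
    """Allele sequence over the maximal extended span among homozygotes."""

    left_index: int
    right_index: int
    alleles: tuple[int, ...]  # allele index per variant over [left, right]
    source: tuple[str, ...]   # contributing individual per variant (for logging)

    def allele_at(self, index: int) -> int:
        if not self.left_index <= index <= self.right_index:
            raise IndexError(f"variant index {index} outside template span "
                             f"[{self.left_index}, {self.right_index}]")
        return self.alleles[index - self.left_index]


def homozygous_carriers(matrix: GenotypeMatrix, focal: int, minor_allele: int) -> list[str]:
    """Ids of individuals homozygous for the focal minor allele."""
    code = 0 if minor_allele == 0 else 2
    row = matrix.calls[focal]
    return [matrix.individuals[j] for j in np.flatnonzero(row == code)]


def heterozygous_carriers(matrix: GenotypeMatrix, focal: int) -> list[str]:
    row = matrix.calls[focal]
    return [matrix.individuals[j] for j in np.flatnonzero(row == 1)]


def find_core(matrix: GenotypeMatrix, focal: int, carriers: list[str]) -> CoreRegion:
    """Maximal contiguous run around ``focal`` where every carrier is
    homozygous and all carriers share the same homozygous genotype.

    Returns at minimum the focal variant itself. All carriers must be
    homozygous (and mutually identical) at the focal variant.
    """
    if not carriers:
        raise ValueError("at least one carrier is required")
    idx = [matrix.individual_index(c) for c in carriers]
    calls = matrix.calls[:, idx]

    def shared_hom_code(i: int) -> int | None:
        col = calls[i]
        first = int(col[0])
        if first not in HOM_CODES or not (col == first).all():
            return None
        return first

    focal_code = shared_hom_code(focal)
    if focal_code is None:
        raise ValueError("carriers are not identically homozygous at the focal variant")

    left = focal
    while left - 1 >= 0 and shared_hom_code(left - 1) is not None:
        left -= 1
    right = focal
    while right + 1 < matrix.n_variants and shared_hom_code(right + 1) is not None:
        right += 1
    alleles = tuple(_hom_allele(int(calls[i, 0])) for i in range(left, right + 1))
    return CoreRegion(left, right, focal, alleles)


def _extend_direction(
    calls: np.ndarray,
    start: int,
    step: int,
    limit: int,
    n_carriers: int,
) -> np.ndarray:
    """Per-carrier boundary indices for one direction.

    ``start`` is the core edge (all carriers agree there); ``step`` is -1
    (left) or +1 (right); ``limit`` is the last valid index in that
    direction. Returns the boundary index for each carrier.
    """
    boundaries = np.full(n_carriers, start, dtype=np.int64)
    extending = np.ones(n_carriers, dtype=bool)
    i = start
    while extending.any() and i != limit:
        i += step
        col = calls[i]
        sub = col[extending]
        n_ref = int((sub == 0).sum())
        n_alt = int((sub == 2).sum())
        if n_ref == n_alt:
            # no majority allele determinable (covers the 2-carrier
            # disagreement rule and the degenerate all-het/missing step)
            break
        major_code = 0 if n_ref > n_alt else 2
        agrees = extending & (col == major_code)
        boundaries[agrees] = i
        extending = agrees
    return boundaries


def extend_homozygotes(
    matrix: GenotypeMatrix,
    core: CoreRegion,
    carriers: list[str],
) -> list[HaplotypeSegment]:
    """Extend each homozygous carrier's haplotype outward from the core.

    At each step the majority homozygous allele among still-extending
    carriers is required; heterozygous or missing calls stop the
    individual. One segment per carrier, in input order.
    """
    if not carriers:
        raise ValueError("at least one carrier is required")
    idx = [matrix.individual_index(c) for c in carriers]
    calls = matrix.calls[:, idx]
    n = len(carriers)
    left_b = _extend_direction(calls, core.left_index, -1, 0, n)
    right_b = _extend_direction(calls, core.right_index, +1, matrix.n_variants - 1, n)
    focal_allele = core.allele_vector[core.focal_index - core.left_index]
    chrom = matrix.variants[core.focal_index].chrom
    positions = matrix.positions()
    segments = []
    for k, ind in enumerate(carriers):
        li, ri = int(left_b[k]), int(right_b[k])
        segments.append(
            HaplotypeSegment(
                individual=ind,
                chrom=chrom,
                left_index=li,
                right_index=ri,
                left_pos=int(positions[li]),
                right_pos=int(positions[ri]),
                carrying_allele=focal_allele,
                zygosity="hom",
            )
        )
    return segments


def longest_template(
    segments: list[HaplotypeSegment],
    matrix: GenotypeMatrix,
) -> TemplateHaplotype:
    """Join the deepest-extending left and right arms across the core.

    At every variant of the maximal span the allele is taken from the
    deepest-extending covering segment (ties broken by input order, and
    logged when covering individuals disagree — which cannot happen for
    segments produced by :func:`extend_homozygotes`).
    """
    if not segments:
        raise ValueError("at least one segment is required")
    left = min(s.left_index for s in segments)
    right = max(s.right_index for s in segments)
    col_idx = {s.individual: matrix.individual_index(s.individual) for s in segments}
    alleles: list[int] = []
    source: list[str] = []
    # deepest-extending first on each arm; stable sort keeps input order on ties
    by_left = sorted(segments, key=lambda s: s.left_index)
    by_right = sorted(segments, key=lambda s: -s.right_index)
    for i in range(left, right + 1):
        chosen = None
        candidates = by_left if i < (left + right) // 2 else by_right
        seen_alleles = set()
        for s in candidates:
            if s.left_index <= i <= s.right_index:
                code = int(matrix.calls[i, col_idx[s.individual]])
                if code in HOM_CODES:
                    seen_alleles.add(_hom_allele(code))
                    if chosen is None:
                        chosen = (s.individual, _hom_allele(code))
        if chosen is None:  # pragma: no cover - unreachable for extend output
            raise ValueError(f"no homozygous covering segment at variant index {i}")
        if len(seen_alleles) > 1:
            logger.info("discordant covering alleles at variant index %d; "
                        "keeping first-in-order individual %s", i, chosen[0])
        source.append(chosen[0])
        alleles.append(chosen[1])
    return TemplateHaplotype(left, right, tuple(alleles), tuple(source))


def phase_heterozygote(
    matrix: GenotypeMatrix,
    individual: str,
    focal: int,
    template: TemplateHaplotype,
) -> HaplotypeSegment:
    """Phase one heterozygote against the template.

    Walking outward from the focal variant, the individual is consistent
    at a variant iff its genotype contains the template allele there (a
    heterozygous or homozygous-template call). The boundary is the last
    consistent variant before the first homozygous-non-template call; a
    missing call also stops extension (conservative). Extension never
    exceeds the template span.
    """
    j = matrix.individual_index(individual)
    if int(matrix.calls[focal, j]) != 1:
        raise ValueError(f"individual {individual} is not heterozygous at the "
                         "focal variant")

    def consistent(i: int) -> bool:
        code = int(matrix.calls[i, j])
        if code == MISSING:
            return False
        if code == 1:
            return True
        return _hom_allele(code) == template.allele_at(i)

    left = focal
    while left - 1 >= template.left_index and consistent(left - 1):
        left -= 1
    right = focal
    while right + 1 <= template.right_index and consistent(right + 1):
        right += 1
    positions = matrix.positions()
    return HaplotypeSegment(
        individual=individual,
        chrom=matrix.variants[focal].chrom,
        left_index=left,
        right_index=right,
        left_pos=int(positions[left]),
        right_pos=int(positions[right]),
        carrying_allele=template.allele_at(focal),
        zygosity="het",
    )


def segment_lengths(segments: list[HaplotypeSegment]) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Physical lengths in bp and the (median, min, max) summary."""
    if not segments:
        raise ValueError("at least one segment is required")
    lengths = np.array([s.phys_length for s in segments], dtype=np.int64)
    return lengths, (float(np.median(lengths)), float(lengths.min()), float(lengths.max()))


def write_segments(segments: list[HaplotypeSegment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "individual": s.individual,
                "chrom": s.chrom,
                "left_pos": s.left_pos,
                "right_pos": s.right_pos,
                "phys_length_bp": s.phys_length,
                "n_variants": s.n_variants,
                "zygosity": s.zygosity,
            }
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"individual", "chrom", "left_pos", "right_pos", "zygosity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segments TSV lacks columns: {sorted(missing)}")
    return df
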