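"""Recombination map handling: physical (bp) to genetic (cM, Morgan) conversion.

Maps are the four-column HapMap genetic-map text format: chromosome,
position (bp), recombination rate (cM/Mb), cumulative map position (cM).
Between map points the cumulative map is linearly interpolated in
physical position; positions outside the mapped interval are clamped to
the nearest map end (with a warning) rather than extrapolated.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class GeneticMapError(ValueError):
    """Raised for malformed or non-monotone genetic maps."""


@dataclass
class GeneticMap:
    """Per-chromosome arrays of (position bp, cumulative cM)."""

    chrom_maps: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, (pos, cm) in self.chrom_maps.items():
            pos = np.asarray(pos, dtype=np.int64)
            cm = np.asarray(cm, dtype=np.float64)
            if pos.size != cm.size or pos.size == 0:
                raise GeneticMapError(f"chromosome {chrom}: empty or mismatched arrays")
            if not (np.diff(pos) > 0).all():
                k = int(np.flatnonzero(np.diff(pos) <= 0)[0]) + 1
                raise GeneticMapError(
                    f"chromosome {chrom}: positions not strictly increasing at "
                    f"row {k} (pos {pos[k]})"
                )
            if not (np.diff(cm) >= 0).all():
                k = int(np.flatnonzero(np.diff(cm) < 0)[0]) + 1
                raise GeneticMapError(
                    f"chromosome {chrom}: cumulative map decreases at row {k} "
                    f"(map {cm[k]} cM)"
                )
            self.chrom_maps[chrom] = (pos, cm)

    def chromosomes(self) -> list[str]:
        return list(self.chrom_maps)


def read_map(path: str | Path) -> GeneticMap:
    """Read a HapMap-format genetic map (header + 4 whitespace-delimited columns)."""
    df = pd.read_csv(path, sep=r"\s+", header=0)
    if df.shape[1] < 4:
        raise GeneticMapError("genetic map needs 4 columns: chromosome, "
                              "position(bp), rate(cM/Mb), map(cM)")
    df.columns = ["chrom", "pos", "rate", "cm"] + list(df.columns[4:])
    chrom_maps = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        chrom_maps[str(chrom)] = (
            grp["pos"].to_numpy(dtype=np.int64),
            grp["cm"].to_numpy(dtype=np.float64),
        )
    return GeneticMap(chrom_maps)


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Chromosome\tPosition(bp)\tRate(cM/Mb)\tMap(cM)\n")
        for chrom, (pos, cm) in gmap.chrom_maps.items():
            rate = np.zeros_like(cm)
            if pos.size > 1:
                rate[:-1] = np.diff(cm) / np.diff(pos) * 1e6
                rate[-1] = rate[-2] if pos.size > 2 else rate[0]
            for p, r, c in zip(pos, rate, cm):
                fh.write(f"{chrom}\t{p}\t{r:.8g}\t{c:.10g}\n")


def constant_rate_map(chrom: str, start: int, end: int,
                      rate_cm_per_mb: float = 1.0) -> GeneticMap:
    """Two-point map with a uniform recombination rate over [start, end]."""
    if end <= start:
        raise GeneticMapError("end must exceed start")
    length_cm = (end - start) / 1e6 * rate_cm_per_mb
    return GeneticMap({chrom: (np.array([start, end]),
                               np.array([0.0, length_cm]))})


def interpolate_cm(gmap: GeneticMap, chrom: str, pos) -> float | np.ndarray:
    """Cumulative genetic position (cM) at physical position(s) ``pos``.

    Linear interpolation between flanking map points; positions outside
    the map interval are clamped to the first/last map value with a
    warning.
    """
    if chrom not in gmap.chrom_maps:
        raise GeneticMapError(f"chromosome {chrom!r} absent from genetic map")
    mpos, mcm = gmap.chrom_maps[chrom]
    arr = np.asarray(pos)
    if (arr < mpos[0]).any() or (arr > mpos[-1]).any():
        logger.warning("position(s) outside map interval [%d, %d] on %s: clamped",
                       mpos[0], mpos[-1], chrom)
    out = np.interp(arr, mpos, mcm)
    return float(out) if np.isscalar(pos) or arr.ndim == 0 else out


def physical_position(gmap: GeneticMap, chrom: str, cm) -> float | np.ndarray:
    """Inverse lookup: physical position (bp) at cumulative map position ``cm``.

    Linear inverse interpolation; flat (zero-rate) intervals resolve to
    their left edge. Used by the simulator to place recombination
    breakpoints drawn in genetic units.
    """
    if chrom not in gmap.chrom_maps:
        raise GeneticMapError(f"chromosome {chrom!r} absent from genetic map")
    mpos, mcm = gmap.chrom_maps[chrom]
    arr = np.asarray(cm)
    out = np.interp(arr, mcm, mpos)
    return float(out) if np.isscalar(cm) or arr.ndim == 0 else out


def genetic_length(gmap: GeneticMap, segment) -> float:
    """Genetic length of a haplotype segment in Morgans.

    ``(cM(right_pos) - cM(left_pos)) / 100``, using the same boundary
    positions as the physical length.
    """
    left = interpolate_cm(gmap, segment.chrom, segment.left_pos)
    right = interpolate_cm(gmap, segment.chrom, segment.right_pos)
    return (right - left) / 100.0
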