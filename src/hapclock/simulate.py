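"""Synthetic founder-haplotype cohorts with ground-truth labels.

The generator produces the statistical structure the downstream analysis
assumes: a dense SNP-array-like variant grid across one genomic window, a
focal biallelic variant whose minor allele descends from a single founder
haplotype, and carrier haplotypes whose flanks around the focal allele
are independent exponentials with rate ``tau_true`` — so the two-sided
carrier-segment length is gamma(shape 2, rate tau_true), the premise of
the gamma age method. Non-focal ("background") variants are drawn
independently per site (linkage equilibrium), so any long shared segment
among carriers is attributable to the founder alone.

Default cohort conditions mirror the study design the package targets: a
71-case / 126-control cohort, a focal minor allele at frequency 0.272
enriched in controls (homozygous-minor individuals are never cases), and
roughly one variant per 4.5 kb over a ~2 Mb window.

Homozygous carriers are modeled as autozygous for the founder segment:
both copies share one pair of flank breakpoints, so the observed
homozygous run corresponds to a single two-flank length draw — the same
treatment the age model applies when it counts one length per homozygous
individual.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genmap import GeneticMap, constant_rate_map, interpolate_cm, physical_position, write_map
from .genotype_io import (
    CASE,
    CONTROL,
    GenotypeMatrix,
    PhenotypeTable,
    VariantRecord,
    write_phenotypes,
    write_vcf,
)

FOCAL_ID = "focal"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the targeted cohort: 197 individuals (71 case / 126
    control), focal minor allele frequency 0.272, ~448 variants over the
    ~2 Mb window around the focal site, founder age 317.4 generations,
    and a uniform 1 cM/Mb recombination rate.
    """

    tau_true: float = 317.4
    n_variants: int = 448
    chrom: str = "12"
    window: tuple[int, int] = (110_912_851, 112_927_816)
    focal_pos: int = 111_803_962
    target_maf: float = 0.272
    n_case: int = 71
    n_control: int = 126
    recomb_rate: float = 1.0  # cM/Mb, used when no map is supplied
    background_freq_range: tuple[float, float] = (0.05, 0.95)
    #: P(case | focal genotype) for (hom-major, het, hom-minor); the
    #: default makes the minor allele protective and hom-minor never case.
    penetrance: tuple[float, float, float] = (0.544, 0.185, 0.0)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_true <= 0:
            raise ValueError("tau_true must be positive")
        if not (self.window[0] <= self.focal_pos <= self.window[1]):
            raise ValueError("focal_pos must lie inside the window")
        if not (0 < self.target_maf <= 0.5):
            raise ValueError("target_maf must be in (0, 0.5]")
        if self.n_case + self.n_control < 1:
            raise ValueError("cohort must contain at least one individual")
        lo, hi = self.background_freq_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("background_freq_range must satisfy 0 <= lo <= hi <= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_individuals(self) -> int:
        return self.n_case + self.n_control


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort, for oracle tests."""

    focal_id: str
    focal_pos: int
    tau_true: float
    founder_alleles: np.ndarray  # allele index per variant (0/1)
    #: per carrier haplotype: (individual, hap in {0,1}, left_bp, right_bp)
    carrier_haplotypes: list[tuple[str, int, int, int]]
    #: individual -> number of founder-allele copies (0/1/2)
    diplotype: dict[str, int] = field(default_factory=dict)

    def carriers(self, n_copies: int) -> list[str]:
        return [i for i, c in self.diplotype.items() if c == n_copies]

    def breakpoints(self, individual: str) -> list[tuple[int, int]]:
        return [(l, r) for ind, _, l, r in self.carrier_haplotypes if ind == individual]

    def to_json(self, path: str | Path) -> None:
        out = {
            "focal_id": self.focal_id,
            "focal_pos": self.focal_pos,
            "tau_true": self.tau_true,
            "founder_alleles": [int(a) for a in self.founder_alleles],
            "carrier_haplotypes": [
                {"individual": i, "hap": h, "left_bp": l, "right_bp": r}
                for i, h, l, r in self.carrier_haplotypes
            ],
            "diplotype": self.diplotype,
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            focal_id=d["focal_id"],
            focal_pos=d["focal_pos"],
            tau_true=d["tau_true"],
            founder_alleles=np.array(d["founder_alleles"], dtype=np.int8),
            carrier_haplotypes=[
                (h["individual"], h["hap"], h["left_bp"], h["right_bp"])
                for h in d["carrier_haplotypes"]
            ],
            diplotype={k: int(v) for k, v in d["diplotype"].items()},
        )


def simulate_arm_lengths(
    tau: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Left/right flank lengths in Morgans after ``tau`` generations.

    Each flank survives recombination independently, so its length is
    exponential with rate tau; the two-sided total is gamma(2, tau).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return (rng.exponential(1.0 / tau, size=n), rng.exponential(1.0 / tau, size=n))


def default_map(config: SimConfig) -> GeneticMap:
    return constant_rate_map(config.chrom, config.window[0], config.window[1],
                             config.recomb_rate)


def _variant_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniformly placed distinct positions including the focal site."""
    start, end = config.window
    need = config.n_variants - 1
    pos: set[int] = set()
    while len(pos) < need:
        draw = rng.integers(start, end + 1, size=need - len(pos))
        pos.update(int(p) for p in draw if p != config.focal_pos)
    out = np.array(sorted(pos | {config.focal_pos}), dtype=np.int64)
    return out


def simulate_cohort(
    config: SimConfig, gmap: GeneticMap | None = None
) -> tuple[GenotypeMatrix, PhenotypeTable, SimTruth]:
    """Simulate one cohort: genotypes, phenotypes and ground truth.

    Each of the 2N haplotypes carries the founder allele with probability
    ``target_maf`` (so the realized focal MAF is binomial around the
    target). Carrier haplotypes copy the founder haplotype over
    ``[focal - left_arm, focal + right_arm]`` (arms drawn in Morgans and
    converted to bp through the genetic map, clipped to the window) and
    background alleles elsewhere. Exactly ``n_case`` individuals are
    labeled cases, chosen by penetrance-weighted sampling without
    replacement over the focal genotype.
    """
    rng = np.random.default_rng(config.seed)
    if gmap is None:
        gmap = default_map(config)
    positions = _variant_positions(config, rng)
    m = positions.size
    focal_idx = int(np.searchsorted(positions, config.focal_pos))
    n = config.n_individuals
    individuals = [f"I{k:04d}" for k in range(n)]

    lo, hi = config.background_freq_range
    freqs = rng.uniform(lo, hi, size=m)
    freqs[focal_idx] = 0.0  # focal minor allele exists only on founder copies

    founder = (rng.random(m) < freqs).astype(np.int8)
    founder[focal_idx] = 1

    # background alleles for every haplotype, independent across sites
    haps = (rng.random((m, n, 2)) < freqs[:, None, None]).astype(np.int8)

    carrier_flags = rng.random((n, 2)) < config.target_maf

    cm_focal = interpolate_cm(gmap, config.chrom, config.focal_pos)
    truth_haps: list[tuple[str, int, int, int]] = []
    diplotype: dict[str, int] = {}

    def paste_founder(ind_idx: int, hap_ids: list[int], left_m: float, right_m: float) -> tuple[int, int]:
        left_bp = int(round(physical_position(gmap, config.chrom,
                                              max(0.0, cm_focal - 100.0 * left_m))))
        right_bp = int(round(physical_position(gmap, config.chrom,
                                               cm_focal + 100.0 * right_m)))
        left_bp = max(left_bp, config.window[0])
        right_bp = min(right_bp, config.window[1])
        inside = (positions >= left_bp) & (positions <= right_bp)
        for h in hap_ids:
            haps[inside, ind_idx, h] = founder[inside]
        return left_bp, right_bp

    for k, ind in enumerate(individuals):
        flags = carrier_flags[k]
        n_copies = int(flags.sum())
        diplotype[ind] = n_copies
        if n_copies == 0:
            continue
        if n_copies == 2:
            # autozygous founder segment: both copies share one breakpoint pair
            (l,), (r,) = simulate_arm_lengths(config.tau_true, 1, rng)
            left_bp, right_bp = paste_founder(k, [0, 1], l, r)
            truth_haps.append((ind, 0, left_bp, right_bp))
            truth_haps.append((ind, 1, left_bp, right_bp))
        else:
            h = int(np.flatnonzero(flags)[0])
            (l,), (r,) = simulate_arm_lengths(config.tau_true, 1, rng)
            left_bp, right_bp = paste_founder(k, [h], l, r)
            truth_haps.append((ind, h, left_bp, right_bp))

    calls = haps.sum(axis=2).astype(np.int8)
    if config.missing_rate > 0:
        drop = rng.random(calls.shape) < config.missing_rate
        calls[drop] = -1

    variants = []
    for i, p in enumerate(positions):
        if i == focal_idx:
            variants.append(VariantRecord(FOCAL_ID, config.chrom, int(p), "G", "A"))
        else:
            variants.append(VariantRecord(f"v{i:05d}", config.chrom, int(p), "A", "G"))
    matrix = GenotypeMatrix(variants, individuals, calls)

    # penetrance-weighted case assignment with fixed group sizes
    weights = np.array([config.penetrance[int(c)] if c >= 0 else
                        np.mean(config.penetrance)
                        for c in calls[focal_idx]], dtype=np.float64)
    if (weights > 0).sum() < config.n_case:
        raise ValueError(
            f"cannot assign {config.n_case} cases: only {(weights > 0).sum()} "
            "individuals have positive case probability under the penetrance model"
        )
    case_ids = _weighted_sample_without_replacement(individuals, weights,
                                                    config.n_case, rng)
    labels = {ind: (CASE if ind in case_ids else CONTROL) for ind in individuals}
    phen = PhenotypeTable(labels)

    truth = SimTruth(
        focal_id=FOCAL_ID,
        focal_pos=config.focal_pos,
        tau_true=config.tau_true,
        founder_alleles=founder,
        carrier_haplotypes=truth_haps,
        diplotype=diplotype,
    )
    return matrix, phen, truth


def _weighted_sample_without_replacement(
    items: list[str], weights: np.ndarray, k: int, rng: np.random.Generator
) -> set[str]:
    """Efraimidis-Spirakis exponential-key sampling; zero weights never drawn."""
    if k == 0:
        return set()
    keys = np.full(len(items), np.inf)
    positive = weights > 0
    keys[positive] = rng.exponential(1.0, size=int(positive.sum())) / weights[positive]
    order = np.argsort(keys, kind="stable")
    return {items[i] for i in order[:k]}


def write_fixture(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    truth: SimTruth,
    out_dir: str | Path,
    gmap: GeneticMap | None = None,
) -> dict[str, Path]:
    """Write cohort.vcf, phenotypes.tsv, truth.json (and map.txt when a
    map is given). Bytes are deterministic for a given simulation seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.json",
    }
    write_vcf(matrix, paths["vcf"])
    write_phenotypes(phenotypes, paths["phenotypes"])
    truth.to_json(paths["truth"])
    if gmap is not None:
        paths["map"] = out / "map.txt"
        write_map(gmap, paths["map"])
    return paths


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
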