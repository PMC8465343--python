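"""End-to-end orchestration: ingest -> assoc -> corehap -> phase -> age.

Every stage writes a machine-readable artifact into the output directory
(association TSV, segments TSV, age JSON) plus a run report
(``report.json``) with the seed, per-stage counts and the package
version. Outputs contain no timestamps, so a rerun with the same inputs
and seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .age import AgeModelConfig, LengthSample, bootstrap_age
from .assoc import scan, write_results
from .genmap import GeneticMap, genetic_length, read_map
from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    read_genotype_tsv,
    read_phenotypes,
    read_vcf,
)
from .ibd import (
    extend_homozygotes,
    find_core,
    heterozygous_carriers,
    homozygous_carriers,
    longest_template,
    phase_heterozygote,
    write_segments,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage could not run on the given inputs."""


@dataclass
class PipelineConfig:
    genotypes: str | Path          # VCF (*.vcf) or genotype TSV
    phenotypes: str | Path
    genetic_map: str | Path
    out_dir: str | Path
    focal_id: str | None = None    # default: strongest association
    window: tuple[str, int, int] | None = None  # (chrom, start, end)
    include_het_haplotypes: bool = False
    age_config: AgeModelConfig = field(default_factory=AgeModelConfig)


def _load_matrix(path: str | Path) -> GenotypeMatrix:
    p = Path(path)
    if p.suffix in {".vcf", ".gz", ".bcf"}:
        return read_vcf(p)
    return read_genotype_tsv(p)


def _minor_allele(matrix: GenotypeMatrix, focal: int) -> int:
    row = matrix.calls[focal]
    row = row[row != MISSING]
    if row.size == 0:
        raise PipelineError("focal variant has no genotype calls")
    alt = int(row.sum())
    total = 2 * row.size
    if alt == 0 or alt == total:
        raise PipelineError(
            f"focal variant {matrix.variants[focal].id} is monomorphic; "
            "no carrier haplotypes exist to date"
        )
    return 1 if alt <= total - alt else 0


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the run report (also written to report.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "seed": config.age_config.seed,
        "stages": [],
        "counts": {},
    }

    def stage(name: str) -> None:
        report["stages"].append(name)
        logger.info("stage %s done (%.2fs elapsed)", name, time.perf_counter() - t0)

    t0 = time.perf_counter()

    # 1. ingest
    matrix = _load_matrix(config.genotypes)
    if config.window is not None:
        matrix = matrix.subset_window(*config.window)
    phen = read_phenotypes(config.phenotypes, matrix)
    gmap = read_map(config.genetic_map)
    report["counts"]["n_variants"] = matrix.n_variants
    report["counts"]["n_individuals"] = matrix.n_individuals
    report["counts"]["n_case"] = phen.n_case
    report["counts"]["n_control"] = phen.n_control
    stage("ingest")

    # 2. association scan
    results = scan(matrix, phen)
    write_results(results, out / "assoc.tsv")
    report["counts"]["n_polymorphic"] = len(results)
    if config.focal_id is not None:
        focal_id = config.focal_id
    else:
        if not results:
            raise PipelineError("no polymorphic variants; cannot pick focal variant")
        focal_id = results[0].variant.id
        logger.info("focal variant defaulted to strongest association: %s", focal_id)
    focal = matrix.variant_index(focal_id)
    report["focal"] = {"id": focal_id, "chrom": matrix.variants[focal].chrom,
                       "pos": matrix.variants[focal].pos}
    stage("assoc")

    # 3. core haplotype + homozygote extension
    minor = _minor_allele(matrix, focal)
    hom = homozygous_carriers(matrix, focal, minor)
    het = heterozygous_carriers(matrix, focal)
    report["counts"]["n_hom_carriers"] = len(hom)
    report["counts"]["n_het_carriers"] = len(het)
    segments = []
    template = None
    if hom:
        core = find_core(matrix, focal, hom)
        report["core"] = {
            "left_pos": matrix.variants[core.left_index].pos,
            "right_pos": matrix.variants[core.right_index].pos,
            "n_variants": core.n_variants,
        }
        segments = extend_homozygotes(matrix, core, hom)
        template = longest_template(segments, matrix)
    else:
        logger.warning("no homozygous carriers of the focal minor allele")
    stage("corehap")

    # 4. template phasing of heterozygotes
    het_segments = []
    if template is not None:
        for ind in het:
            het_segments.append(phase_heterozygote(matrix, ind, focal, template))
    all_segments = segments + het_segments
    if all_segments:
        write_segments(all_segments, out / "segments.tsv")
    report["counts"]["n_segments"] = len(all_segments)
    stage("phase")

    # 5. age estimation (homozygote lengths by default)
    age_input = segments + (het_segments if config.include_het_haplotypes else [])
    lengths = np.array([genetic_length(gmap, s) for s in age_input])
    usable = lengths[lengths > 0]
    n_zero = int((lengths <= 0).sum())
    if n_zero:
        logger.warning("%d zero-length segment(s) excluded from age estimation", n_zero)
    report["counts"]["n_lengths_used"] = int(usable.size)
    report["counts"]["n_zero_length_excluded"] = n_zero
    if usable.size == 0:
        report["age"] = None
        report["age_skipped"] = ("no homozygous carrier haplotypes with positive "
                                 "genetic length; age stage skipped")
        logger.warning(report["age_skipped"])
    else:
        estimate = bootstrap_age(LengthSample(usable), config.age_config)
        estimate.to_json(out / "age.json", config.age_config)
        report["age"] = estimate.to_dict()
        stage("age")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
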