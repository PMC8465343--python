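import numpy as np
import pytest

from hapclock.genotype_io import GenotypeMatrix, PhenotypeTable, VariantRecord
from hapclock.simulate import SimConfig, default_map, simulate_cohort


def make_matrix(codes, positions=None, chrom="1", individuals=None):
    """Build a GenotypeMatrix from a variants x individuals code array."""
    codes = np.asarray(codes, dtype=np.int8)
    nv, ni = codes.shape
    if positions is None:
        positions = [1000 + 100 * i for i in range(nv)]
    if individuals is None:
        individuals = [f"I{j}" for j in range(ni)]
    variants = [VariantRecord(f"v{i}", chrom, int(p), "A", "G")
                for i, p in enumerate(positions)]
    return GenotypeMatrix(variants, individuals, codes)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (197 individuals, ~2 Mb window)."""
    config = SimConfig(seed=11)
    gmap = default_map(config)
    matrix, phen, truth = simulate_cohort(config, gmap)
    return config, gmap, matrix, phen, truth


# published genotype counts used as worked-example inputs:
# id -> (chrom, case (hom_major, het, hom_minor), control (...), maf, fisher_p)
PUBLISHED_COUNTS = {
    "rs116369005": ("6", (38, 26, 0), (113, 7, 0), 0.090, 7.54e-8),
    "rs671": ("12", (56, 15, 0), (47, 66, 13), 0.272, 8.75e-9),
    "rs77768175": ("12", (56, 15, 0), (48, 65, 13), 0.269, 1.56e-8),
    "rs78069066": ("12", (54, 17, 0), (45, 68, 13), 0.282, 2.96e-8),
    "rs3782886": ("12", (53, 18, 0), (46, 67, 13), 0.282, 1.20e-7),
    "rs11066280": ("12", (52, 18, 1), (43, 70, 13), 0.294, 3.05e-7),
    "rs541300736": ("16", (36, 25, 0), (112, 8, 0), 0.091, 2.62e-7),
}


def counts_to_matrix_and_phenotypes(published=PUBLISHED_COUNTS, n_case=71, n_control=126):
    """Expand per-group genotype counts into a genotype matrix + phenotype
    table whose per-variant group counts equal the published ones (counts
    short of the group size become missing calls)."""
    from hapclock.genotype_io import CASE, CONTROL, MISSING

    case_ids = [f"case{j}" for j in range(n_case)]
    ctrl_ids = [f"ctrl{j}" for j in range(n_control)]
    variants, rows = [], []
    pos = {c: 10_000 for c in ("6", "12", "16")}
    for vid, (chrom, case, ctrl, _, _) in published.items():
        pos[chrom] += 50_000
        variants.append(VariantRecord(vid, chrom, pos[chrom], "G", "A"))
        row = np.full(n_case + n_control, MISSING, dtype=np.int8)

        def fill(offset, counts):
            k = offset
            for code, cnt in zip((0, 1, 2), counts):
                row[k:k + cnt] = code
                k += cnt

        fill(0, case)
        fill(n_case, ctrl)
        rows.append(row)
    matrix = GenotypeMatrix(variants, case_ids + ctrl_ids, np.vstack(rows))
    phen = PhenotypeTable({**{i: CASE for i in case_ids},
                           **{i: CONTROL for i in ctrl_ids}})
    return matrix, phen
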