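import numpy as np
import pytest

from hapclock.genmap import genetic_length
from hapclock.genotype_io import MISSING
from hapclock.ibd import (
    extend_homozygotes,
    find_core,
    homozygous_carriers,
    longest_template,
    phase_heterozygote,
    read_segments,
    segment_lengths,
    write_segments,
)

from conftest import make_matrix


def bruteforce_core(matrix, focal, carriers):
    """Independent oracle: widest contiguous window containing the focal
    variant at which all carriers are homozygous and mutually identical,
    found by scanning every candidate window."""
    idx = [matrix.individual_index(c) for c in carriers]
    best = (focal, focal)
    for l in range(focal + 1):
        for r in range(focal, matrix.n_variants):
            sub = matrix.calls[l:r + 1][:, idx]
            ok = (np.isin(sub, (0, 2)).all()
                  and (sub == sub[:, :1]).all())
            if ok and (r - l) > (best[1] - best[0]):
                best = (l, r)
    return best


def random_carrier_matrix(rng, max_variants=50, max_individuals=10):
    nv = int(rng.integers(3, max_variants + 1))
    ni = int(rng.integers(1, max_individuals + 1))
    codes = rng.choice([0, 1, 2, MISSING], size=(nv, ni),
                       p=[0.35, 0.25, 0.35, 0.05]).astype(np.int8)
    focal = int(rng.integers(0, nv))
    n_car = int(rng.integers(1, ni + 1))
    carriers = [f"I{j}" for j in rng.choice(ni, size=n_car, replace=False)]
    m = make_matrix(codes)
    for c in carriers:
        codes[focal, m.individual_index(c)] = 2
    return make_matrix(codes), focal, sorted(carriers)


# ---------------------------------------------------------------------------
# core region
# ---------------------------------------------------------------------------

def test_core_single_carrier_is_its_homozygosity_run():
    codes = np.array([[1], [0], [0], [2], [2], [0], [1], [0]])
    m = make_matrix(codes)
    core = find_core(m, 3, ["I0"])
    assert (core.left_index, core.right_index) == (1, 5)
    assert core.allele_vector == (0, 0, 1, 1, 0)


def test_core_two_carriers_intersection():
    """Carriers identically homozygous at indices 10..20, differing at 9 and 21."""
    rng = np.random.default_rng(5)
    codes = np.zeros((30, 2), dtype=np.int8)
    codes[10:21] = rng.choice([0, 2], size=(11, 1))
    codes[9] = [0, 2]
    codes[21] = [2, 0]
    m = make_matrix(codes)
    core = find_core(m, 15, ["I0", "I1"])
    assert (core.left_index, core.right_index) == (10, 20)
    assert bruteforce_core(m, 15, ["I0", "I1"]) == (10, 20)


def test_core_matches_bruteforce_on_random_matrices():
    rng = np.random.default_rng(99)
    for _ in range(40):
        m, focal, carriers = random_carrier_matrix(rng)
        core = find_core(m, focal, carriers)
        assert (core.left_index, core.right_index) == bruteforce_core(m, focal, carriers)


def test_core_monotone_under_carrier_removal():
    """Dropping a carrier can only keep or widen the core (intersection)."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        m, focal, carriers = random_carrier_matrix(rng, max_individuals=6)
        if len(carriers) < 2:
            continue
        full = find_core(m, focal, carriers)
        sub = find_core(m, focal, carriers[:-1])
        assert sub.left_index <= full.left_index
        assert sub.right_index >= full.right_index


def test_core_requires_carriers_and_homozygosity():
    m = make_matrix(np.array([[1, 1]]))
    with pytest.raises(ValueError, match="carrier"):
        find_core(m, 0, [])
    with pytest.raises(ValueError, match="homozygous"):
        find_core(m, 0, ["I0"])


# ---------------------------------------------------------------------------
# homozygote extension
# ---------------------------------------------------------------------------

def test_extension_all_identical_spans_window():
    codes = np.tile(np.array([[2], [0], [2], [0], [2]]), (1, 4))
    m = make_matrix(codes)
    core = find_core(m, 2, [f"I{j}" for j in range(4)])
    segs = extend_homozygotes(m, core, [f"I{j}" for j in range(4)])
    assert all((s.left_index, s.right_index) == (0, 4) for s in segs)
    assert all(s.left_pos == 1000 and s.right_pos == 1400 for s in segs)


def test_extension_minority_member_stops_majority_continues():
    """Hand-traced walk: three carriers share the core (bounded by
    disagreements); at each core edge the minority homozygote stops with
    its boundary at the last agreeing variant while the majority
    continues."""
    codes = np.zeros((30, 3), dtype=np.int8)
    codes[10:16] = 2          # core for all three
    codes[9] = [2, 0, 0]      # left edge: I0 is the minority homozygote
    codes[16] = [0, 0, 2]     # right edge: I2 is the minority homozygote
    m = make_matrix(codes)
    carriers = ["I0", "I1", "I2"]
    core = find_core(m, 12, carriers)
    assert (core.left_index, core.right_index) == (10, 15)
    segs = {s.individual: s for s in extend_homozygotes(m, core, carriers)}
    assert segs["I0"].left_index == 10 and segs["I0"].right_index == 29
    assert segs["I1"].left_index == 0 and segs["I1"].right_index == 29
    assert segs["I2"].left_index == 0 and segs["I2"].right_index == 15


def test_extension_two_way_disagreement_terminates_direction():
    codes = np.zeros((10, 2), dtype=np.int8)
    codes[4:6] = 2
    codes[6] = [0, 2]     # the two disagree: no majority, direction stops
    m = make_matrix(codes)
    core = find_core(m, 4, ["I0", "I1"])
    segs = extend_homozygotes(m, core, ["I0", "I1"])
    assert all(s.right_index == 5 for s in segs)
    assert all(s.left_index == 0 for s in segs)


def test_extension_het_or_missing_stops_individual():
    codes = np.full((7, 2), 2, dtype=np.int8)
    codes[5, 0] = 1
    codes[1, 1] = MISSING
    m = make_matrix(codes)
    core = find_core(m, 3, ["I0", "I1"])
    segs = {s.individual: s for s in extend_homozygotes(m, core, ["I0", "I1"])}
    assert segs["I0"].right_index == 4
    assert segs["I1"].left_index == 2
    assert segs["I1"].right_index == 6


def test_segments_contain_core_and_reordering_preserves_lengths():
    rng = np.random.default_rng(21)
    for _ in range(10):
        m, focal, carriers = random_carrier_matrix(rng, max_individuals=8)
        core = find_core(m, focal, carriers)
        segs = extend_homozygotes(m, core, carriers)
        for s in segs:
            assert s.left_index <= core.left_index
            assert s.right_index >= core.right_index
            assert 0 <= s.left_index <= s.right_index < m.n_variants
        reordered = list(reversed(carriers))
        segs2 = {s.individual: s for s in
                 extend_homozygotes(m, find_core(m, focal, reordered), reordered)}
        for s in segs:
            assert (segs2[s.individual].left_index,
                    segs2[s.individual].right_index) == (s.left_index, s.right_index)


# ---------------------------------------------------------------------------
# template and phasing
# ---------------------------------------------------------------------------

def test_template_single_homozygote_is_its_own_sequence():
    codes = np.array([[2], [0], [2], [2], [0]])
    m = make_matrix(codes)
    core = find_core(m, 2, ["I0"])
    segs = extend_homozygotes(m, core, ["I0"])
    tpl = longest_template(segs, m)
    assert (tpl.left_index, tpl.right_index) == (0, 4)
    assert tpl.alleles == (1, 0, 1, 1, 0)


def test_template_spans_deepest_arms():
    codes = np.zeros((30, 3), dtype=np.int8)
    codes[10:16] = 2
    codes[20, 2] = 2
    m = make_matrix(codes)
    carriers = ["I0", "I1", "I2"]
    core = find_core(m, 12, carriers)
    segs = extend_homozygotes(m, core, carriers)
    tpl = longest_template(segs, m)
    assert tpl.left_index == min(s.left_index for s in segs)
    assert tpl.right_index == max(s.right_index for s in segs)


def test_phase_het_identical_to_template_spans_template():
    codes = np.column_stack([np.full(9, 2), np.full(9, 2)]).astype(np.int8)
    codes[4, 1] = 1  # the heterozygote at the focal variant
    m = make_matrix(codes)
    core = find_core(m, 4, ["I0"])
    tpl = longest_template(extend_homozygotes(m, core, ["I0"]), m)
    seg = phase_heterozygote(m, "I1", 4, tpl)
    assert (seg.left_index, seg.right_index) == (tpl.left_index, tpl.right_index)
    assert seg.zygosity == "het"


def test_phase_het_stops_at_homozygous_nontemplate_and_missing():
    codes = np.full((11, 2), 2, dtype=np.int8)
    codes[5, 1] = 1           # focal het
    codes[8, 1] = 0           # hom-non-template at offset +3 -> boundary +2
    codes[2, 1] = MISSING     # missing at offset -3 -> boundary -2
    m = make_matrix(codes)
    core = find_core(m, 5, ["I0"])
    tpl = longest_template(extend_homozygotes(m, core, ["I0"]), m)
    seg = phase_heterozygote(m, "I1", 5, tpl)
    assert seg.right_index == 7
    assert seg.left_index == 3


def test_phase_requires_heterozygote():
    codes = np.full((3, 2), 2, dtype=np.int8)
    m = make_matrix(codes)
    core = find_core(m, 1, ["I0"])
    tpl = longest_template(extend_homozygotes(m, core, ["I0"]), m)
    with pytest.raises(ValueError, match="not heterozygous"):
        phase_heterozygote(m, "I0", 1, tpl)


# ---------------------------------------------------------------------------
# lengths and round trip
# ---------------------------------------------------------------------------

def test_segment_lengths_summary(tmp_path):
    codes = np.full((5, 3), 2, dtype=np.int8)
    m = make_matrix(codes, positions=[100, 400, 600, 1100, 3100])
    core = find_core(m, 2, ["I0", "I1", "I2"])
    segs = extend_homozygotes(m, core, ["I0", "I1", "I2"])
    lengths, (med, lo, hi) = segment_lengths(segs)
    assert list(lengths) == [3000, 3000, 3000]
    assert (med, lo, hi) == (3000, 3000, 3000)
    path = tmp_path / "segments.tsv"
    write_segments(segs, path)
    df = read_segments(path)
    assert df.shape[0] == 3
    assert (df["phys_length_bp"] == 3000).all()


# ---------------------------------------------------------------------------
# simulator-truth oracle
# ---------------------------------------------------------------------------

def test_detected_homozygote_segments_bracket_simulated_truth(default_cohort):
    """Each homozygote's detected segment must contain its true founder
    segment snapped inward to the variant grid, and may overshoot it only
    by the short chance-homozygosity runs expected beyond the breakpoints."""
    config, gmap, matrix, phen, truth = default_cohort
    focal = matrix.variant_index(truth.focal_id)
    hom = truth.carriers(2)
    assert set(homozygous_carriers(matrix, focal, 1)) == set(hom)
    core = find_core(matrix, focal, hom)
    segs = extend_homozygotes(matrix, core, hom)
    positions = matrix.positions()
    overshoots = []
    for s in segs:
        (left_bp, right_bp) = truth.breakpoints(s.individual)[0]
        snap_left = positions[np.searchsorted(positions, left_bp, side="left")]
        snap_right = positions[np.searchsorted(positions, right_bp, side="right") - 1]
        assert s.left_pos <= snap_left
        assert s.right_pos >= snap_right
        overshoots.append(np.searchsorted(positions, snap_left) - s.left_index)
        overshoots.append(s.right_index - (np.searchsorted(positions, snap_right)))
    assert np.median(overshoots) <= 2
    assert np.mean(overshoots) < 4


def test_genetic_lengths_close_to_truth_lengths(default_cohort):
    """Detected genetic lengths track the simulated founder-segment
    lengths to within a few inter-variant gaps per side."""
    config, gmap, matrix, phen, truth = default_cohort
    focal = matrix.variant_index(truth.focal_id)
    hom = truth.carriers(2)
    core = find_core(matrix, focal, hom)
    segs = extend_homozygotes(matrix, core, hom)
    gap_morgans = (config.window[1] - config.window[0]) / config.n_variants \
        * config.recomb_rate / 1e8
    for s in segs:
        left_bp, right_bp = truth.breakpoints(s.individual)[0]
        true_len = (right_bp - left_bp) * config.recomb_rate / 1e8
        assert genetic_length(gmap, s) == pytest.approx(
            true_len, abs=8 * gap_morgans)
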