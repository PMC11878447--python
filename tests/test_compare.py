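"""Circular peak detection, Pearson CC and per-column scoring."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import brute_force_peaks, closed_form_pearson
from ringeralign.compare import (
    CompareParams,
    circular_smooth,
    column_profiles,
    detect_peaks,
    peak_subtract,
    pearson_cc,
    score_columns,
    scores_to_frame,
    _median,
)
from ringeralign.msa import align
from ringeralign.ringer_io import (
    AngleGrid,
    ChiProfile,
    ResidueId,
    StructureProfileSet,
    parse_ringer_csv,
)
from ringeralign.seqextract import extract_sequence
from ringeralign.synthetic import PeakSpec, wrapped_gaussian

GRID = AngleGrid(n_samples=72)
ANGLES = GRID.angles()


# ------------------------------------------------------------------ pearson


def test_pearson_exact_one_on_identical():
    a = np.array([0.1, 0.7, 0.3, 0.9, 0.2])
    assert pearson_cc(a, a.copy()) == 1.0


def test_pearson_exact_minus_one_on_negated_affine():
    a = np.array([0.1, 0.7, 0.3, 0.9, 0.2])
    assert pearson_cc(a, -a) == -1.0
    # a general negative affine image rounds in its own construction
    assert pearson_cc(a, -2.0 * a + 3.0) == pytest.approx(-1.0, abs=1e-12)


def test_pearson_worked_example():
    assert pearson_cc(np.array([0, 1, 2, 3.0]),
                      np.array([1, 2, 4, 3.0])) == pytest.approx(0.8, abs=1e-15)


def test_pearson_undefined_cases():
    assert pearson_cc(np.ones(10), np.arange(10.0)) is None
    assert pearson_cc(np.arange(10.0), np.full(10, 2.0)) is None
    assert pearson_cc(np.array([1.0, 2.0]), np.array([1.0, 3.0])) is None
    with pytest.raises(ValueError, match="length mismatch"):
        pearson_cc(np.arange(5.0), np.arange(6.0))


@pytest.mark.parametrize("seed", range(10))
def test_pearson_matches_closed_form(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=50)
    b = rng.normal(size=50)
    assert pearson_cc(a, b) == pytest.approx(closed_form_pearson(a, b), abs=1e-12)
    # symmetry and positive-affine invariance
    assert pearson_cc(a, b) == pearson_cc(b, a)
    assert pearson_cc(2.5 * a + 1.0, b) == pytest.approx(pearson_cc(a, b), abs=1e-12)
    assert abs(pearson_cc(a, b)) <= 1 + 1e-12


# -------------------------------------------------------------------- peaks


def _bump(center, height, width=20.0):
    return wrapped_gaussian(ANGLES, PeakSpec(center, height, width))


def test_all_zero_profile_has_no_peaks():
    assert detect_peaks(np.zeros(72), grid=GRID).count == 0


def test_single_bump_detected_at_center():
    ps = detect_peaks(_bump(300.0, 1.0, 20.0), grid=GRID)
    assert ps.angles == [300.0]
    assert ps.peaks[0].height_sigma == pytest.approx(1.0, abs=1e-6)


def test_threshold_selects_peaks():
    y = _bump(60.0, 0.5) + _bump(180.0, 0.4)
    assert detect_peaks(y, grid=GRID, threshold_sigma=0.3).angles == [60.0, 180.0]
    assert detect_peaks(y, grid=GRID, threshold_sigma=0.45).angles == [60.0]


def test_bump_across_seam_counts_once():
    y = _bump(358.0, 1.0, 15.0)
    ps = detect_peaks(y, grid=GRID)
    assert ps.count == 1
    assert ps.angles == brute_force_peaks(y, ANGLES)


def test_plateau_reports_leftmost_sample():
    y = np.zeros(72)
    y[10:14] = 1.0  # flat top: 50..65 deg
    ps = detect_peaks(y, grid=GRID)
    assert ps.angles == [50.0]


def test_plateau_wrapping_the_seam():
    y = np.zeros(72)
    y[70:] = 1.0
    y[:2] = 1.0  # plateau 350..5 deg, leftmost sample going clockwise is 350
    ps = detect_peaks(y, grid=GRID)
    assert ps.count == 1
    assert ps.angles == [350.0]


def test_merge_keeps_higher_tie_smaller_angle():
    y = np.zeros(72)
    y[12] = 0.8  # 60 deg
    y[16] = 0.9  # 80 deg, within 30 deg of 60
    assert detect_peaks(y, grid=GRID).angles == [80.0]
    y2 = np.zeros(72)
    y2[12] = 0.8
    y2[16] = 0.8  # tie -> keep smaller angle
    assert detect_peaks(y2, grid=GRID).angles == [60.0]


def test_min_separation_validation():
    with pytest.raises(ValueError, match="180"):
        detect_peaks(np.zeros(72), grid=GRID, min_separation_deg=180.0)


def test_smoothing_window_validation_and_effect():
    with pytest.raises(ValueError, match="odd"):
        circular_smooth(np.zeros(8), 2)
    y = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])
    sm = circular_smooth(y, 3)
    assert sm == pytest.approx(np.array([1, 1, 1, 0, 0, 0]) / 3.0)


@pytest.mark.parametrize("seed", range(6))
def test_detect_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    for _ in range(50):
        y = rng.normal(0.3, 0.5, 72)
        got = detect_peaks(y, grid=GRID).angles
        assert got == brute_force_peaks(y, ANGLES)


@pytest.mark.parametrize("seed", range(4))
def test_rotation_equivariance(seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(0.3, 0.5, 72)
    base = detect_peaks(y, grid=GRID).angles
    k = int(rng.integers(1, 72))
    shifted = detect_peaks(np.roll(y, k), grid=GRID).angles
    expected = sorted((a + k * 5.0) % 360.0 for a in base)
    assert shifted == pytest.approx(expected)


@given(st.integers(0, 10_000))
def test_threshold_monotonicity(seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(0.3, 0.5, 36)
    grid = AngleGrid(n_samples=36)
    counts = [detect_peaks(y, grid=grid, threshold_sigma=t).count
              for t in (0.0, 0.3, 0.6, 1.0)]
    assert counts == sorted(counts, reverse=True)


def test_peak_subtract_antisymmetric_and_threshold_guard():
    a = detect_peaks(_bump(60, 1.0) + _bump(180, 0.8), grid=GRID)
    b = detect_peaks(_bump(60, 1.0), grid=GRID)
    assert peak_subtract(a, b) == 1
    assert peak_subtract(b, a) == -1
    assert peak_subtract(a, a) == 0
    c = detect_peaks(_bump(60, 1.0), grid=GRID, threshold_sigma=0.5)
    with pytest.raises(ValueError, match="threshold"):
        peak_subtract(a, c)


# ------------------------------------------------------------------ columns


def _two_models(tmp_path, seed=11):
    from ringeralign.synthetic import default_pair_spec, generate_pair

    spec = default_pair_spec(seed=seed, n_residues=8, renumber_offset=0,
                             n_extra_rotamers=0, noise_sigma=0.0)
    pair = generate_pair(spec, tmp_path)
    sets = parse_ringer_csv(pair.csv_a) + parse_ringer_csv(pair.csv_b)
    seqs = [extract_sequence(s) for s in sets]
    return sets, align(seqs)


def test_column_profiles_respect_lookup_and_chi(tmp_path):
    grid = AngleGrid(n_samples=36)
    a = StructureProfileSet(model_label="a", grid=grid)
    rid_s = ResidueId("A", 1, res_name="SER")
    a.add(rid_s, ChiProfile(rid_s, 1, np.zeros(36)))
    b = StructureProfileSet(model_label="b", grid=grid)
    rid_f = ResidueId("A", 1, res_name="PHE")
    for chi in (1, 2):
        b.add(rid_f, ChiProfile(rid_f, chi, np.zeros(36)))
    ai = align([extract_sequence(a), extract_sequence(b)])
    profs = column_profiles(ai, [a, b], 1, 2)
    assert profs["a"] is None  # Ser has no chi2
    assert profs["b"] is not None and profs["b"].residue == rid_f


def test_column_profiles_grid_mismatch_is_error(tmp_path):
    g36, g72 = AngleGrid(36), AngleGrid(72)
    a = StructureProfileSet(model_label="a", grid=g36)
    rid = ResidueId("A", 1, res_name="SER")
    a.add(rid, ChiProfile(rid, 1, np.zeros(36)))
    b = StructureProfileSet(model_label="b", grid=g72)
    b.add(rid, ChiProfile(rid, 1, np.zeros(72)))
    ai = align([extract_sequence(a), extract_sequence(b)])
    with pytest.raises(ValueError, match="grids"):
        column_profiles(ai, [a, b], 1, 1)


def test_identical_models_score_perfectly(tmp_path):
    sets, ai = _two_models(tmp_path)
    scores = score_columns(ai, sets, CompareParams())
    for sc in scores:
        assert sc.median_cc == 1.0
        for v in sc.peak_diff.values():
            assert v in (0, None)
        for v in sc.cc.values():
            assert v in (1.0, None)


def test_scores_frame_columns(tmp_path):
    sets, ai = _two_models(tmp_path)
    df = scores_to_frame(score_columns(ai, sets, CompareParams(chis=(1,))))
    assert list(df.columns) == ["msa_pos", "chi", "model_a", "model_b", "cc",
                                "peaks_a", "peaks_b", "peak_diff", "median_cc"]
    assert len(df) == ai.column_count


def test_median_even_count_rule():
    assert _median([0.9, 0.5, 0.7]) == pytest.approx(0.7)
    assert _median([0.9, 0.5]) == pytest.approx(0.7)
    assert _median([]) is None
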