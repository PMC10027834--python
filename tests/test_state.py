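import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from groupsync import (
    DegenerateSignalError,
    ParameterError,
    discretize_terciles,
    recurrence_matrix,
    rqa_metrics,
    symbolic_entropy,
    tune_radius,
)


def brute_force_recurrence(values, radius, normalize=False):
    """Independent O(n^2) recurrence oracle over raw joint states."""
    values = np.asarray(values, dtype=float)
    if normalize:
        values = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, keepdims=True
        )
    n = values.shape[1]
    cells = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            d = np.sqrt(((values[:, i] - values[:, j]) ** 2).sum())
            cells[i, j] = d <= radius
    return cells


def brute_force_rqa(cells, min_line):
    """Independent diagonal-scan oracle for %REC/%DET/ADL/maxL."""
    n = cells.shape[0]
    off = sum(cells[i, j] for i in range(n) for j in range(n) if i != j)
    rec = 100.0 * off / (n * n - n)
    runs = []
    for k in list(range(-n + 1, 0)) + list(range(1, n)):
        diag = [cells[i, i + k] for i in range(max(0, -k), min(n, n - k))]
        length = 0
        for cell in diag + [False]:
            if cell:
                length += 1
            elif length:
                runs.append(length)
                length = 0
    qualifying = [r for r in runs if r >= min_line]
    det = 100.0 * sum(qualifying) / off if off else 0.0
    adl = float(np.mean(qualifying)) if qualifying else 0.0
    maxl = max(runs) if runs else 0
    return rec, det, adl, maxl


class TestTerciles:
    def test_permutation_of_nine_gives_exact_thirds(self, rng):
        values = np.vstack([rng.permutation(np.arange(1.0, 10.0)) for _ in range(2)])
        seq = discretize_terciles(values)
        for row in seq.levels:
            assert np.bincount(row, minlength=3).tolist() == [3, 3, 3]

    def test_identical_variables_use_at_most_three_symbols(self, rng):
        base = rng.normal(size=100)
        seq = discretize_terciles(np.vstack([base] * 4))
        assert len(np.unique(seq.symbols)) <= 3

    def test_toy_encoding_matches_hand_computation(self):
        # var0 terciles of [1..6]: q1=2, q2=4 -> levels 0,0,1,1,2,2
        # var1 terciles of [6..1]: levels 2,2,1,1,0,0
        values = np.array([[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1]], dtype=float)
        seq = discretize_terciles(values)
        expected = np.array([0 * 3 + 2, 0 * 3 + 2, 1 * 3 + 1, 1 * 3 + 1, 2 * 3 + 0, 2 * 3 + 0])
        assert np.array_equal(seq.symbols, expected)
        assert seq.alphabet_size == 9

    def test_constant_variable_rejected(self):
        with pytest.raises(DegenerateSignalError):
            discretize_terciles(np.vstack([np.ones(10), np.arange(10.0)]))


class TestSymbolicEntropy:
    def test_identical_variables_reach_ln3(self, rng):
        base = rng.normal(size=9999)
        h = symbolic_entropy(np.vstack([base] * 5))
        assert h == pytest.approx(np.log(3), abs=1e-6)

    def test_independent_variables_approach_five_ln3(self, rng):
        h = symbolic_entropy(rng.normal(size=(5, 200_000)))
        assert h == pytest.approx(5 * np.log(3), abs=0.05)

    def test_matches_counting_oracle(self, toy_series):
        seq = discretize_terciles(toy_series)
        counts = {}
        for s in seq.symbols:
            counts[s] = counts.get(s, 0) + 1
        total = len(seq.symbols)
        expected = -sum((c / total) * np.log(c / total) for c in counts.values())
        assert symbolic_entropy(toy_series) == pytest.approx(expected, abs=1e-12)

    @given(
        power=st.floats(0.2, 3.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_strictly_monotone_transforms(self, power, scale):
        rng = np.random.default_rng(11)
        values = rng.uniform(0.5, 2.0, size=(3, 120))
        transformed = scale * values**power
        assert symbolic_entropy(transformed) == pytest.approx(
            symbolic_entropy(values), abs=1e-12
        )


class TestRecurrenceMatrix:
    def test_saturation_and_isolation(self, rng):
        values = rng.normal(size=(2, 12))
        big = recurrence_matrix(values, radius=1e6, normalize=False)
        assert big.cells.all()
        dist_floor = 1e-9
        small = recurrence_matrix(values, radius=dist_floor, normalize=False)
        assert np.array_equal(small.cells, np.eye(12, dtype=bool))

    def test_matches_brute_force_on_toy(self, rng):
        values = rng.normal(size=(2, 5))
        rm = recurrence_matrix(values, radius=1.0, normalize=False)
        assert np.array_equal(rm.cells, brute_force_recurrence(values, 1.0))

    def test_rec_pct_non_decreasing_in_radius(self, rng):
        values = rng.normal(size=(3, 40))
        radii = np.linspace(0.1, 5.0, 12)
        recs = [
            rqa_metrics(recurrence_matrix(values, r)).rec_pct for r in radii
        ]
        assert np.all(np.diff(recs) >= 0)

    def test_embedding_reduces_points_and_stacks_lags(self, rng):
        values = rng.normal(size=(2, 20))
        rm = recurrence_matrix(values, radius=1.0, normalize=False, embedding=(3, 2))
        assert rm.n_points == 20 - 2 * 2
        # state 0 is (x(0), y(0), x(2), y(2), x(4), y(4)); check against manual distance
        s0 = np.r_[values[:, 0], values[:, 2], values[:, 4]]
        s1 = np.r_[values[:, 1], values[:, 3], values[:, 5]]
        expected = np.sqrt(((s0 - s1) ** 2).sum()) <= 1.0
        assert rm.cells[0, 1] == expected

    def test_parameter_errors(self, rng):
        values = rng.normal(size=(2, 10))
        with pytest.raises(ParameterError):
            recurrence_matrix(values, radius=-1.0)
        with pytest.raises(ParameterError):
            recurrence_matrix(values, radius=1.0, embedding=(6, 2))


class TestRQAMetrics:
    def test_identity_matrix_is_all_zero(self):
        m = rqa_metrics(np.eye(8, dtype=bool))
        assert (m.rec_pct, m.det_pct, m.adl, m.maxl) == (0.0, 0.0, 0.0, 0)

    def test_full_matrix(self):
        m = rqa_metrics(np.ones((10, 10), dtype=bool))
        # 90 off-diagonal recurrent cells; the two corner diagonals are runs
        # of length 1 and do not qualify at min_line=2, leaving 88
        assert m.rec_pct == 100.0
        assert m.det_pct == pytest.approx(100.0 * 88 / 90)
        assert m.adl == pytest.approx(5.5)
        assert m.maxl == 9

    def test_hand_built_runs(self):
        # upper triangle: one run of 4 on diagonal k=1, one run of 2 on k=3
        cells = np.eye(6, dtype=bool)
        for i in range(4):
            cells[i, i + 1] = cells[i + 1, i] = True
        cells[0, 3] = cells[3, 0] = True
        cells[1, 4] = cells[4, 1] = True
        m = rqa_metrics(cells, min_line=2)
        assert m.rec_pct == pytest.approx(100.0 * 12 / 30)
        assert m.det_pct == pytest.approx(100.0)  # every off-diag cell is on a run >= 2
        assert m.adl == pytest.approx(3.0)  # runs of 4 and 2 per triangle
        assert m.maxl == 4

    def test_min_line_below_two_rejected(self):
        with pytest.raises(ParameterError):
            rqa_metrics(np.eye(5, dtype=bool), min_line=1)

    def test_matches_diagonal_scan_oracle_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(8, 21))
            values = rng.normal(size=(int(rng.integers(2, 4)), n))
            radius = float(rng.uniform(0.3, 3.0))
            rm = recurrence_matrix(values, radius, normalize=False)
            assert np.array_equal(rm.cells, brute_force_recurrence(values, radius))
            got = rqa_metrics(rm, min_line=2)
            rec, det, adl, maxl = brute_force_rqa(rm.cells, 2)
            assert got.rec_pct == pytest.approx(rec, abs=1e-12)
            assert got.det_pct == pytest.approx(det, abs=1e-12)
            assert got.adl == pytest.approx(adl, abs=1e-12)
            assert got.maxl == maxl


def test_tune_radius_hits_target_band(rng):
    values = rng.normal(size=(4, 300))
    radius = tune_radius(values, target_rec=3.0, tolerance=2.0)
    rec = rqa_metrics(recurrence_matrix(values, radius)).rec_pct
    assert 1.0 <= rec <= 5.0
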