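"""Pressure-parameter definitions against hand-computed and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from ipmap import (
    FrameSequence,
    NoContactError,
    PARAMETER_NAMES,
    PressureFrame,
    ValidationError,
    contact_area,
    contact_count,
    cop,
    decimate,
    extract_all,
    parameters_frame,
    peak_pressure,
    peak_pressure_gradient,
    simulate_sequence,
)
from tests.conftest import SHORT_SCRIPT

small_grids = arrays(
    float,
    st.tuples(st.integers(2, 6), st.integers(2, 6)),
    elements=st.one_of(st.just(0.0), st.floats(5.0, 200.0, allow_nan=False, width=16)),
)


class TestCop:
    def test_point_mass_at_cell_center(self):
        grid = np.zeros((5, 5))
        grid[2, 3] = 80.0
        f = PressureFrame(grid, pitch=10.0)
        assert cop(f) == (25.0, 35.0)

    def test_two_equal_cells_average(self):
        grid = np.zeros((6, 3))
        grid[2, 1] = 40.0
        grid[4, 1] = 40.0
        f = PressureFrame(grid, pitch=10.0)
        longitudinal, _ = cop(f)
        assert longitudinal == pytest.approx(35.0)  # midpoint of 25 and 45

    def test_uniform_frame_centers_on_mat(self):
        f = PressureFrame(np.full((4, 6), 50.0), pitch=10.0)
        assert cop(f) == (pytest.approx(20.0), pytest.approx(30.0))

    @given(small_grids, st.floats(0.1, 10.0))
    def test_invariant_under_positive_scaling(self, grid, scale):
        if grid.sum() == 0:
            return
        f = PressureFrame(grid, floored=False)
        g = PressureFrame(grid * scale, floored=False, ceiling=2000.0)
        np.testing.assert_allclose(cop(f), cop(g), rtol=1e-9)

    def test_no_contact_raises(self):
        with pytest.raises(NoContactError):
            cop(PressureFrame(np.zeros((3, 3))))


class TestContactArea:
    def test_zero_frame(self):
        assert contact_area(PressureFrame(np.zeros((3, 3))), 5.0) == 0.0

    def test_threshold_is_inclusive_and_physical(self):
        grid = np.zeros((3, 3))
        grid[[0, 1, 2], [0, 1, 2]] = 20.0
        f = PressureFrame(grid, pitch=15.9)
        assert contact_count(f, 20.0) == 3
        assert contact_area(f, 20.0) == pytest.approx(3 * 1.59**2)  # 7.5843 cm^2

    def test_cell_area_grows_under_pooling(self):
        from ipmap import block_pool

        f = PressureFrame(np.full((4, 4), 50.0), pitch=15.9)
        pooled = block_pool(f, 2)
        assert contact_area(pooled, 5.0) == pytest.approx(contact_area(f, 5.0))

    @given(small_grids)
    def test_monotone_in_threshold(self, grid):
        f = PressureFrame(grid, floored=False)
        a5, a10, a20 = (contact_area(f, t) for t in (5.0, 10.0, 20.0))
        assert a5 >= a10 >= a20

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValidationError):
            contact_area(PressureFrame(np.zeros((2, 2))), -1.0)


class TestPeakPressure:
    def test_definition_and_zero_frame(self):
        grid = np.zeros((3, 3))
        grid[1, 1] = 87.2
        assert peak_pressure(PressureFrame(grid)) == 87.2
        assert peak_pressure(PressureFrame(np.zeros((2, 2)))) == 0.0


class TestPeakPressureGradient:
    def brute_force(self, grid):
        rows, cols = grid.shape
        best = 0.0
        for i in range(rows):
            for j in range(cols):
                for di, dj in ((0, 1), (1, 0)):
                    if i + di < rows and j + dj < cols:
                        best = max(best, abs(grid[i, j] - grid[i + di, j + dj]))
        return best

    def test_uniform_frame(self):
        assert peak_pressure_gradient(PressureFrame(np.full((3, 3), 42.0))) == 0.0

    def test_hand_example(self):
        f = PressureFrame(np.array([[0.0, 10.0], [0.0, 0.0]]))
        assert peak_pressure_gradient(f) == 10.0

    @given(small_grids)
    def test_matches_exhaustive_pair_enumeration(self, grid):
        f = PressureFrame(grid, floored=False)
        assert peak_pressure_gradient(f) == pytest.approx(self.brute_force(grid))

    @given(small_grids)
    def test_bounded_by_pressure_range(self, grid):
        f = PressureFrame(grid, floored=False)
        assert peak_pressure_gradient(f) <= grid.max() - grid.min() + 1e-12

    def test_per_mm_mode_divides_by_pitch(self):
        f = PressureFrame(np.array([[0.0, 10.0]]), pitch=15.9)
        assert peak_pressure_gradient(f, per_mm=True) == pytest.approx(10.0 / 15.9)

    def test_single_cell_rejected(self):
        with pytest.raises(ValidationError):
            peak_pressure_gradient(PressureFrame(np.array([[10.0]])))


class TestExtractAll:
    def test_seven_series_of_sequence_length(self, small_cohort):
        seq = small_cohort[0]
        series = extract_all(seq)
        assert [s.name for s in series] == list(PARAMETER_NAMES)
        assert all(len(s) == len(seq) for s in series)

    def test_decimate_commutes_with_extraction(self, small_cohort):
        seq = small_cohort[0]
        direct = extract_all(decimate(seq, 3))
        subsampled = [s.values[::3] for s in extract_all(seq)]
        for d, sub in zip(direct, subsampled):
            np.testing.assert_allclose(d.values, sub, rtol=1e-12)

    def test_static_noiseless_sequence_gives_constant_series(self, body, foam):
        from ipmap import SimulationScript

        script = SimulationScript(segments=(("supine", 10.0),))
        seq = simulate_sequence(body, foam, script, noise_sd=0.0, seed=0)
        for s in extract_all(seq):
            assert np.all(s.values == s.values[0])

    def test_all_zero_frame_yields_nan_cop(self):
        frames = (
            PressureFrame(np.full((3, 3), 50.0)),
            PressureFrame(np.zeros((3, 3))),
        )
        seq = FrameSequence(frames, 1.0, ("supine", "supine"))
        series = {s.name: s for s in extract_all(seq)}
        assert np.isnan(series["cop_long"].values[1])
        assert np.isnan(series["cop_trans"].values[1])
        assert series["peak_pressure"].values[1] == 0.0

    def test_tidy_table_shape(self, small_cohort):
        seq = small_cohort[0]
        df = parameters_frame(seq)
        assert set(df.columns) == {"time_s", "parameter", "value", "units"}
        assert len(df) == 7 * len(seq)
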