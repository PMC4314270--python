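"""Stand-in spread model, fire-grid I/O, and the severity index."""

import numpy as np
import pytest

from firebiorisk.fire import (
    FireResult,
    FuelModel,
    SpreadModel,
    WeatherScenario,
    read_fire_grids,
    severity,
    simulate_fire,
    write_fire_grids,
)
from firebiorisk.landscape import LandscapeGrid


def uniform_grid(n=15, unit="a"):
    return LandscapeGrid(unit_ids=(unit,), composition=np.ones((1, n, n)))


FUEL = FuelModel(base_ros={"a": 10.0}, intensity_coeff={"a": 100.0})
CALM = WeatherScenario()


def patch_mask(fire):
    m = np.zeros(fire.shape, bool)
    m.ravel()[fire.burnt_cells] = True
    return m


class TestSpread:
    def test_calm_fire_is_a_symmetric_ball_around_ignition(self):
        g = uniform_grid(15)
        f = simulate_fire(g, FUEL, CALM, (7, 7), max_duration=90)
        m = patch_mask(f)
        assert m[7, 7]
        np.testing.assert_array_equal(m, m[::-1, :])  # N-S mirror
        np.testing.assert_array_equal(m, m[:, ::-1])  # E-W mirror
        np.testing.assert_array_equal(m, m.T)  # diagonal

    def test_radius_grows_with_duration(self):
        g = uniform_grid(21)
        sizes = [
            simulate_fire(g, FUEL, CALM, (10, 10), max_duration=t).n_burnt
            for t in (30, 60, 90)
        ]
        assert sizes[0] < sizes[1] < sizes[2]

    @pytest.mark.parametrize("seed", range(5))
    def test_drier_fuel_burns_at_least_as_much(self, seed):
        rng = np.random.default_rng(seed)
        comp = rng.uniform(0.2, 1.0, size=(1, 12, 12))
        g = LandscapeGrid(unit_ids=("a",), composition=comp)
        ign = (int(rng.integers(12)), int(rng.integers(12)))
        wet = simulate_fire(g, FUEL, WeatherScenario(moisture_factor=0.4), ign, max_duration=60)
        dry = simulate_fire(g, FUEL, WeatherScenario(moisture_factor=0.8), ign, max_duration=60)
        assert wet.n_burnt <= dry.n_burnt

    def test_fire_confined_to_flammable_corridor(self):
        comp = np.zeros((2, 9, 9))
        comp[0, 4, :] = 1.0  # flammable row corridor
        comp[1] = 1.0 - comp[0]  # non-flammable elsewhere
        g = LandscapeGrid(unit_ids=("a", "rock"), composition=comp)
        fuel = FuelModel(
            base_ros={"a": 10.0, "rock": 0.0},
            intensity_coeff={"a": 100.0, "rock": 0.0},
            flammable={"rock": False},
        )
        f = simulate_fire(g, fuel, CALM, (4, 4), max_duration=1000)
        rows = f.burnt_cells // 9
        assert set(rows.tolist()) == {4}

    def test_identical_inputs_give_identical_fires(self):
        g = uniform_grid(10)
        f1 = simulate_fire(g, FUEL, WeatherScenario(wind_speed=4, wind_direction=90), (5, 5))
        f2 = simulate_fire(g, FUEL, WeatherScenario(wind_speed=4, wind_direction=90), (5, 5))
        np.testing.assert_array_equal(f1.burnt_cells, f2.burnt_cells)
        np.testing.assert_allclose(f1.intensity, f2.intensity, rtol=1e-12)
        np.testing.assert_allclose(f1.ros, f2.ros, rtol=1e-12)

    def test_patch_is_8_connected(self):
        from scipy.ndimage import label

        g = uniform_grid(15)
        f = simulate_fire(g, FUEL, WeatherScenario(wind_speed=8, wind_direction=200), (3, 11))
        _, n = label(patch_mask(f), structure=np.ones((3, 3)))
        assert n == 1

    def test_wind_pushes_fire_downwind(self):
        g = uniform_grid(21)
        # wind from the north -> spread biased southward (increasing row)
        f = simulate_fire(
            g, FUEL, WeatherScenario(wind_speed=10, wind_direction=0), (10, 10), max_duration=60
        )
        rows = f.burnt_cells // 21
        south = (rows > 10).sum()
        north = (rows < 10).sum()
        assert south > north

    def test_nonflammable_ignition_degenerates_with_warning(self):
        g = uniform_grid(5)
        fuel = FuelModel(base_ros={"a": 0.0}, intensity_coeff={"a": 100.0})
        with pytest.warns(UserWarning, match="not flammable"):
            f = simulate_fire(g, fuel, CALM, (2, 2))
        assert f.burnt_cells.tolist() == [g.flat(2, 2)]
        assert f.ros[0] == 0 and f.intensity[0] == 0

    def test_leakage_scorches_adjacent_nonflammable_vegetation(self):
        comp = np.zeros((2, 7, 7))
        comp[0, :, :4] = 1.0
        comp[1, :, 4:] = 1.0
        g = LandscapeGrid(unit_ids=("a", "b"), composition=comp)
        fuel = FuelModel(
            base_ros={"a": 10.0, "b": 0.0},
            intensity_coeff={"a": 100.0, "b": 200.0},
            flammable={"b": False},
        )
        m = SpreadModel(g, fuel, CALM, max_duration=1000, leak_into_nonflammable=True)
        f = m.simulate((3, 3))
        cols = f.burnt_cells % 7
        assert cols.max() == 4  # one-cell scorch into b, no further spread
        assert (f.intensity > 0).all() and (f.ros > 0).all()


class TestSeverity:
    def test_intensity_times_residence_time(self):
        f = FireResult(0, [0], intensity=[100.0], ros=[4.0], shape=(1, 1))
        assert severity(f)[0] == pytest.approx(25.0)

    def test_linear_in_intensity(self):
        f1 = FireResult(0, [0, 1], [50.0, 80.0], [2.0, 4.0], shape=(1, 2))
        f2 = FireResult(0, [0, 1], [100.0, 160.0], [2.0, 4.0], shape=(1, 2))
        np.testing.assert_allclose(severity(f2), 2 * severity(f1))

    def test_zero_intensity_gives_zero_severity(self):
        f = FireResult(0, [0], intensity=[0.0], ros=[4.0], shape=(1, 1))
        assert severity(f)[0] == 0.0

    def test_zero_ros_on_burnt_cell_is_an_error(self):
        f = FireResult(0, [0], intensity=[0.0], ros=[0.0], shape=(1, 1))
        with pytest.raises(ValueError, match="residence time"):
            severity(f)


class TestFireGridIO:
    def test_round_trip_preserves_fire(self, tmp_path):
        g = uniform_grid(9)
        f = simulate_fire(g, FUEL, CALM, (4, 4), max_duration=45)
        ip, rp = write_fire_grids(f, g, tmp_path, 0)
        f2 = read_fire_grids(ip, rp, ignition=f.ignition_cell)
        np.testing.assert_array_equal(f.burnt_cells, f2.burnt_cells)
        np.testing.assert_array_equal(f.intensity, f2.intensity)
        np.testing.assert_array_equal(f.ros, f2.ros)

    def test_single_positive_cell(self, tmp_path):
        from firebiorisk.landscape import write_ascii_grid

        a = np.zeros((3, 3))
        a[1, 1] = 5.0
        write_ascii_grid(a, tmp_path / "i.asc")
        write_ascii_grid(a, tmp_path / "r.asc")
        f = read_fire_grids(tmp_path / "i.asc", tmp_path / "r.asc")
        assert f.burnt_cells.tolist() == [4] and f.ignition_cell == 4

    def test_shape_mismatch_rejected(self, tmp_path):
        from firebiorisk.landscape import write_ascii_grid

        write_ascii_grid(np.ones((3, 3)), tmp_path / "i.asc")
        write_ascii_grid(np.ones((4, 4)), tmp_path / "r.asc")
        with pytest.raises(ValueError, match="mismatch"):
            read_fire_grids(tmp_path / "i.asc", tmp_path / "r.asc")

    def test_positive_ros_with_zero_intensity_rejected(self, tmp_path):
        from firebiorisk.landscape import write_ascii_grid

        write_ascii_grid(np.zeros((2, 2)), tmp_path / "i.asc")
        write_ascii_grid(np.ones((2, 2)), tmp_path / "r.asc")
        with pytest.raises(ValueError, match="non-positive intensity"):
            read_fire_grids(tmp_path / "i.asc", tmp_path / "r.asc")

    def test_all_zero_grids_warn_empty_fire(self, tmp_path):
        from firebiorisk.landscape import write_ascii_grid

        write_ascii_grid(np.zeros((2, 2)), tmp_path / "i.asc")
        write_ascii_grid(np.zeros((2, 2)), tmp_path / "r.asc")
        with pytest.warns(UserWarning, match="empty fire"):
            f = read_fire_grids(tmp_path / "i.asc", tmp_path / "r.asc", ignition=3)
        assert f.n_burnt == 1 and f.ros[0] == 0
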