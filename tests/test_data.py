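"""Data model, composition arithmetic, CSV round-trip, built-in fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import terpsol as ts
from terpsol.data import DataError, save_dataset, load_dataset


class TestCompositionArithmetic:
    @pytest.mark.parametrize(
        "masses, molar_masses, expected",
        [
            ((0.0, 10.0), (300.442, 134.218), 0.0),
            ((1.0, 10.0), (300.442, 134.218), 0.0427631),  # hand: n1=1/300.442, n2=10/134.218
            ((2.0, 1.0), (2.0, 1.0), 0.5),  # equal mole amounts
            ((1.0, 5.0, 5.0), (300.442, 134.218, 204.351), None),  # 3-component, checked below
        ],
    )
    def test_mole_fraction(self, masses, molar_masses, expected):
        x = ts.mole_fraction_solubility(masses, molar_masses)
        if expected is not None:
            assert x == pytest.approx(expected, abs=1e-6)
        else:
            n = [m / M for m, M in zip(masses, molar_masses)]
            assert x == pytest.approx(n[0] / sum(n), rel=1e-12)

    @given(
        m=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=3),
        M=st.lists(st.floats(10.0, 500.0), min_size=3, max_size=3),
    )
    @settings(max_examples=50, deadline=None)
    def test_mole_fractions_sum_to_one(self, m, M):
        M = M[: len(m)]
        total = sum(
            ts.mole_fraction_solubility(m[i:] + m[:i], M[i:] + M[:i])
            for i in range(len(m))
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("m1, m2, w", [(5, 5, 0.5), (1, 0, 1.0), (3, 7, 0.3)])
    def test_solvent_mass_fraction(self, m1, m2, w):
        assert ts.solvent_mass_fraction(m1, m2) == pytest.approx(w, rel=1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(DataError):
            ts.mole_fraction_solubility((-1.0, 1.0), (10.0, 10.0))
        with pytest.raises(DataError):
            ts.mole_fraction_solubility((1.0, 1.0), (0.0, 10.0))
        with pytest.raises(DataError):
            ts.mole_fraction_solubility((0.0, 0.0), (10.0, 10.0))
        with pytest.raises(DataError):
            ts.solvent_mass_fraction(0.0, 0.0)


class TestFixtures:
    def test_inventory(self, fixtures):
        # 3 monosolvents + 3 equal-mass binaries (12 points) + 3 scans (9 points)
        assert len(fixtures) == 9
        assert sum(len(ds) for ds in fixtures.values()) == 99

    def test_known_points(self, fixtures):
        ap = fixtures["(-)-alpha-pinene"]
        assert (ap.points[0].T, ap.points[0].x_exp) == (299.45, 0.09417)
        pc = fixtures["p-cymene"]
        assert (pc.points[-1].T, pc.points[-1].x_exp) == (336.16, 0.26287)
        mix = fixtures["(-)-alpha-pinene (w1=0.5) + (-)-beta-caryophyllene"]
        assert (mix.points[0].T, mix.points[0].x_exp) == (295.15, 0.08338)

    def test_point_invariants(self, fixtures):
        for ds in fixtures.values():
            T, x = ds.T, ds.x_exp
            assert np.all(T > 0) and np.all((x > 0) & (x < 1))
            if ds.system.w1 is not None:
                assert np.all(np.diff(T) > 0)  # strictly increasing after sort

    def test_solubility_ordering(self, fixtures):
        # p-cymene dissolves the acid best among the monosolvents at comparable T
        pc = fixtures["p-cymene"].x_exp.mean()
        ap = fixtures["(-)-alpha-pinene"].x_exp.mean()
        bc = fixtures["(-)-beta-caryophyllene"].x_exp.mean()
        assert pc > ap and pc > bc


class TestCSV:
    def test_round_trip(self, tmp_path, fixtures):
        for label in ("(-)-alpha-pinene", "(-)-alpha-pinene (w1 scan) + p-cymene"):
            ds = fixtures[label]
            path = tmp_path / "ds.csv"
            save_dataset(ds, path)
            back = load_dataset(path, system=ds.system)
            assert back.T.tolist() == ds.T.tolist()
            assert back.x_exp.tolist() == ds.x_exp.tolist()

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(DataError, match="empty"):
            load_dataset(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("system,w1,temperature,x_exp\na,,300,0.1\n")
        with pytest.raises(DataError, match="missing required column"):
            load_dataset(path)

    def test_non_numeric_cell_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("system,w1,T_K,x_exp\na,,300,0.1\na,,oops,0.2\n")
        with pytest.raises(DataError, match=":3:"):
            load_dataset(path)

    def test_duplicate_temperature_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("system,w1,T_K,x_exp\na,,300,0.1\na,,300,0.2\n")
        with pytest.raises(DataError, match="duplicate"):
            load_dataset(path)

    def test_out_of_range_value_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("system,w1,T_K,x_exp\na,,300,1.5\n")
        with pytest.raises(DataError, match=":2:"):
            load_dataset(path)
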