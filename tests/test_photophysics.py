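"""Radiative rates, Boltzmann-averaged lifetimes and the sublevel TSV contract."""

import math

import numpy as np
import pytest

from irphos.periodic import HARTREE_EV
from irphos.photophysics import (
    TripletSublevel,
    TripletSublevelSet,
    boltzmann_lifetime,
    lifetime_table,
    mean_emission_energy,
    radiative_rate,
    read_sublevel_table,
    strickler_berg_correct,
    sublevel_lifetime,
)


def sub(e_ev, dipole):
    return TripletSublevel.from_ev(e_ev, dipole)


class TestRadiativeRate:
    def test_zero_dipole_is_dark(self):
        s = sub(2.4, (0.0, 0.0, 0.0))
        assert radiative_rate(s) == 0.0
        assert sublevel_lifetime(s) == math.inf

    def test_quadratic_in_dipole(self):
        k1 = radiative_rate(sub(2.4, (0.1, 0.02, 0.0)))
        k2 = radiative_rate(sub(2.4, (0.2, 0.04, 0.0)))
        assert k2 == pytest.approx(4 * k1)

    def test_cubic_in_energy(self):
        k1 = radiative_rate(sub(1.2, (0.1, 0.0, 0.0)))
        k2 = radiative_rate(sub(2.4, (0.1, 0.0, 0.0)))
        assert k2 == pytest.approx(8 * k1)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        m = np.array([0.07, -0.02, 0.11])
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert radiative_rate(sub(2.0, tuple(q @ m))) == pytest.approx(
            radiative_rate(sub(2.0, tuple(m)))
        )

    def test_microsecond_scale_for_typical_phosphor(self):
        # a bright iridium emitter: ~2.5 eV, |M| ~ 0.1 a.u.
        k = radiative_rate(sub(2.5, (0.1, 0.0, 0.0)))
        assert 1e4 < k < 1e7  # lifetime between 0.1 us and 100 us

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            TripletSublevel(-0.1, (0.1, 0.0, 0.0))


class TestBoltzmannLifetime:
    def degenerate(self, k_dipole):
        s = TripletSublevel(0.09, k_dipole)
        return TripletSublevelSet((s, s, s))

    def test_degenerate_limit_is_single_sublevel(self):
        sset = self.degenerate((0.1, 0.0, 0.0))
        k = radiative_rate(sset.sublevels[0])
        assert boltzmann_lifetime(sset) == pytest.approx(1 / k)

    def test_low_temperature_limit(self):
        sset = TripletSublevelSet(
            (sub(2.40, (0.05, 0, 0)), sub(2.41, (0.2, 0, 0)), sub(2.42, (0.3, 0, 0)))
        )
        k1 = radiative_rate(sset.sublevels[0])
        assert boltzmann_lifetime(sset, temperature=1e-2) == pytest.approx(1 / k1)

    def test_high_temperature_limit(self):
        sset = TripletSublevelSet(
            (sub(2.40, (0.05, 0, 0)), sub(2.41, (0.2, 0, 0)), sub(2.42, (0.3, 0, 0)))
        )
        ks = [radiative_rate(s) for s in sset.sublevels]
        assert boltzmann_lifetime(sset, temperature=1e9) == pytest.approx(
            3 / sum(ks), rel=1e-4
        )

    def test_bounded_by_temperature_limits_for_monotone_rates(self):
        # finite-T lifetime lies between the T->0 and T->infinity limits when
        # the sublevel rates are monotone in energy (either direction); with
        # non-monotone rates the average can legitimately overshoot
        rng = np.random.default_rng(4)
        for _ in range(50):
            e0 = rng.uniform(1.5, 3.0)
            gaps = np.sort(rng.uniform(0, 0.02, size=2))
            mags = np.sort(rng.uniform(0.01, 0.3, size=3))
            if rng.uniform() < 0.5:
                mags = mags[::-1]
            subs = tuple(
                sub(e0 + g, (m, 0.0, 0.0)) for g, m in zip((0, *gaps), mags)
            )
            sset = TripletSublevelSet(subs)
            tau = boltzmann_lifetime(sset, 300.0)
            lo_t = boltzmann_lifetime(sset, 1e-3)
            hi_t = boltzmann_lifetime(sset, 1e9)
            assert min(lo_t, hi_t) <= tau * (1 + 1e-9)
            assert tau <= max(lo_t, hi_t) * (1 + 1e-9)

    def test_faster_sublevel_shortens_lifetime(self):
        base = TripletSublevelSet(
            (sub(2.40, (0.05, 0, 0)), sub(2.41, (0.1, 0, 0)), sub(2.42, (0.1, 0, 0)))
        )
        faster = TripletSublevelSet(
            (sub(2.40, (0.05, 0, 0)), sub(2.41, (0.3, 0, 0)), sub(2.42, (0.1, 0, 0)))
        )
        assert boltzmann_lifetime(faster) < boltzmann_lifetime(base)

    def test_all_dark_flagged_non_emissive(self):
        z = (0.0, 0.0, 0.0)
        sset = TripletSublevelSet((sub(2.4, z), sub(2.41, z), sub(2.42, z)))
        assert boltzmann_lifetime(sset) == math.inf


class TestStricklerBerg:
    def test_vacuum_identity(self):
        assert strickler_berg_correct(5.0, 1.0) == 5.0

    def test_quadratic_division(self):
        assert strickler_berg_correct(8.0, 2.0) == 2.0

    def test_dmso_default(self):
        assert strickler_berg_correct(1.0) == pytest.approx(1 / 1.4793**2)

    def test_invalid_index_rejected(self):
        with pytest.raises(ValueError):
            strickler_berg_correct(1.0, 0.0)


class TestMeanEmission:
    def test_arithmetic_mean_and_order_invariance(self):
        subs = (sub(2.0, (0.1, 0, 0)), sub(2.1, (0.1, 0, 0)), sub(2.2, (0.1, 0, 0)))
        a = mean_emission_energy(TripletSublevelSet(subs))
        b = mean_emission_energy(TripletSublevelSet(subs[::-1]))
        assert a == pytest.approx(2.1)
        assert a == b

    def test_unit_round_trip(self):
        e_ev = 2.3456789
        assert sub(e_ev, (0, 0, 0)).energy * HARTREE_EV == pytest.approx(
            e_ev, rel=1e-12
        )


class TestSublevelTable:
    HEADER = "complex_id\tsublevel\tenergy\tunit\tmx\tmy\tmz\n"

    def write(self, tmp_path, body):
        p = tmp_path / "subs.tsv"
        p.write_text(self.HEADER + body)
        return p

    def test_well_formed_record(self, tmp_path):
        p = self.write(
            tmp_path,
            "c1\t1\t0.0882\thartree\t0.1\t0.0\t0.0\n"
            "c1\t2\t0.0883\thartree\t0.0\t0.1\t0.0\n"
            "c1\t3\t0.0884\thartree\t0.0\t0.0\t0.1\n",
        )
        sets = read_sublevel_table(p)
        assert len(sets) == 1
        assert sets[0].complex_id == "c1"
        assert sets[0].gaps[0] == pytest.approx(0.0001)

    def test_ev_rows_converted(self, tmp_path):
        p = self.write(
            tmp_path,
            "c1\t1\t2.40\teV\t0.1\t0\t0\n"
            "c1\t2\t2.41\teV\t0.1\t0\t0\n"
            "c1\t3\t2.42\teV\t0.1\t0\t0\n",
        )
        sset = read_sublevel_table(p)[0]
        assert sset.sublevels[0].energy == pytest.approx(2.40 / HARTREE_EV)

    def test_wrong_sublevel_count_rejected(self, tmp_path):
        p = self.write(
            tmp_path,
            "c1\t1\t0.088\thartree\t0.1\t0\t0\nc1\t2\t0.089\thartree\t0.1\t0\t0\n",
        )
        with pytest.raises(ValueError, match="3 sublevels"):
            read_sublevel_table(p)

    def test_unknown_unit_rejected(self, tmp_path):
        p = self.write(tmp_path, "c1\t1\t2.4\tkcal\t0.1\t0\t0\n")
        with pytest.raises(ValueError, match="unit"):
            read_sublevel_table(p)

    def test_lifetime_table_columns(self, tmp_path):
        p = self.write(
            tmp_path,
            "c1\t1\t2.40\teV\t0.1\t0\t0\n"
            "c1\t2\t2.41\teV\t0.1\t0\t0\n"
            "c1\t3\t2.42\teV\t0.1\t0\t0\n",
        )
        table = lifetime_table(read_sublevel_table(p))
        row = table.iloc[0]
        assert row["mean_emission_eV"] == pytest.approx(2.41)
        assert row["lifetime_us"] > 0
        assert list(table.columns) == [
            "complex_id", "k1_s", "k2_s", "k3_s", "lifetime_us", "mean_emission_eV",
        ]
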