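"""Void records, deposition-rate derivation and cumulative excretion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dehtp_pbpk.urine import (
    DepositionObs,
    UrineVoid,
    cumulative_excretion,
    read_voids_csv,
    voids_to_rates,
    write_voids_csv,
)


def make_void(t, vol, c5oh=0.0, c2cx=0.0, c5cx=0.0, who="V1"):
    return UrineVoid(
        volunteer=who, time=t, volume=vol,
        concentration={"5OH": c5oh, "2cx": c2cx, "5cx": c5cx},
    )


class TestVoidsToRates:
    def test_single_interval_arithmetic(self):
        voids = [make_void(2.0, 0.25, c5cx=2.0), make_void(4.0, 0.1, c5cx=0.0)]
        obs = [o for o in voids_to_rates(voids) if o.metabolite == "5cx"]
        # 2 mg/L * 0.25 L over the 2 h since dosing
        assert obs[0].rate == pytest.approx(0.25)
        assert obs[0].midpoint == pytest.approx(1.0)
        assert obs[1].rate == 0.0

    def test_first_interval_anchored_at_dose_time(self):
        voids = [make_void(3.0, 1.0, c5cx=1.5), make_void(5.0, 1.0, c5cx=1.0)]
        obs = [o for o in voids_to_rates(voids) if o.metabolite == "5cx"]
        assert obs[0].t_start == 0.0 and obs[0].rate == pytest.approx(0.5)

    def test_five_void_fixture_matches_brute_force(self):
        rng = np.random.default_rng(3)
        times = np.cumsum(rng.uniform(0.5, 3.0, size=5))
        vols = rng.uniform(0.1, 0.5, size=5)
        concs = rng.uniform(0.0, 2.0, size=5)
        voids = [make_void(t, v, c5cx=c) for t, v, c in zip(times, vols, concs)]
        obs = [o for o in voids_to_rates(voids) if o.metabolite == "5cx"]
        prev = 0.0
        for o, t, v, c in zip(obs, times, vols, concs):
            assert o.rate == pytest.approx(c * v / (t - prev))
            assert o.midpoint == pytest.approx((t + prev) / 2)
            prev = t

    def test_mass_conservation_of_the_transformation(self):
        rng = np.random.default_rng(8)
        times = np.cumsum(rng.uniform(0.5, 3.0, size=8))
        voids = [
            make_void(t, rng.uniform(0.1, 0.4), c5cx=rng.uniform(0, 3)) for t in times
        ]
        obs = [o for o in voids_to_rates(voids) if o.metabolite == "5cx"]
        recovered = sum(o.rate * (o.t_end - o.t_start) for o in obs)
        assert recovered == pytest.approx(cumulative_excretion(voids, 1e9)["5cx"])

    def test_unit_consistent_rescaling_is_invariant(self):
        # ml with mg/ml gives identical rates to L with mg/L
        voids_l = [make_void(1.0, 0.25, c5cx=2.0), make_void(2.5, 0.4, c5cx=1.0)]
        voids_ml = [make_void(1.0, 250.0, c5cx=0.002), make_void(2.5, 400.0, c5cx=0.001)]
        r_l = [o.rate for o in voids_to_rates(voids_l)]
        r_ml = [o.rate for o in voids_to_rates(voids_ml)]
        assert r_l == pytest.approx(r_ml)

    def test_non_increasing_times_rejected(self):
        voids = [make_void(2.0, 0.1), make_void(2.0, 0.1)]
        with pytest.raises(ValueError):
            voids_to_rates(voids)

    def test_fewer_than_two_voids_rejected(self):
        with pytest.raises(ValueError):
            voids_to_rates([make_void(1.0, 0.1)])


class TestCumulativeExcretion:
    def test_scaled_synthetic_total(self):
        # three voids scaled so the total 5cx mass is a chosen 2.88 mg
        voids = [make_void(t, 0.5, c5cx=c) for t, c in [(8, 2.0), (24, 2.4), (40, 1.36)]]
        assert cumulative_excretion(voids, 48.0)["5cx"] == pytest.approx(2.88)

    def test_empty_set_gives_zero(self):
        assert cumulative_excretion([], 48.0)["5cx"] == 0.0

    def test_window_additivity(self):
        rng = np.random.default_rng(5)
        voids = [
            make_void(t, 0.2, c5cx=rng.uniform(0, 2))
            for t in np.cumsum(rng.uniform(1, 4, size=12))
        ]
        full = cumulative_excretion(voids, 48.0)["5cx"]
        first = cumulative_excretion(voids, 24.0)["5cx"]
        tail = sum(
            v.concentration["5cx"] * v.volume for v in voids if 24.0 < v.time <= 48.0
        )
        assert full == pytest.approx(first + tail)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            cumulative_excretion([], 0.0)


class TestCsvRoundTrip:
    def test_round_trip_preserves_rates(self, tmp_path):
        rng = np.random.default_rng(2)
        voids = [
            make_void(t, rng.uniform(0.1, 0.4), c5oh=rng.uniform(0, 0.1),
                      c2cx=rng.uniform(0, 0.02), c5cx=rng.uniform(0, 2))
            for t in np.cumsum(rng.uniform(0.5, 3, size=6))
        ]
        path = tmp_path / "voids.csv"
        write_voids_csv(voids, path)
        back = read_voids_csv(path)["V1"]
        orig = voids_to_rates(voids)
        again = voids_to_rates(back)
        for a, b in zip(orig, again):
            assert a.rate == pytest.approx(b.rate, rel=1e-9)

    def test_missing_values_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "volunteer,time_h,volume_L,conc_5OH,conc_2cx,conc_5cx\nV1,1.0,0.2,,0.1,0.2\n"
        )
        with pytest.raises(ValueError, match="missing"):
            read_voids_csv(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("volunteer,time_h\nV1,1.0\n")
        with pytest.raises(ValueError, match="columns"):
            read_voids_csv(path)


class TestVoidInvariants:
    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            make_void(1.0, 0.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            make_void(1.0, 0.2, c5cx=-0.1)
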