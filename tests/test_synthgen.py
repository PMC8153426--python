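"""Seeded generators: determinism, noise models, round-trip structure."""

import numpy as np
import pandas as pd
import pytest

from formstress import (
    HillModel, SeededConfig, ToleranceModel,
    gen_competition, gen_growth_curve, gen_itc_thermogram, gen_mst_curve,
    gen_spot_series, gen_tolerance_counts,
)
from formstress.errors import ValidationError


class TestDeterminism:
    """Fixed seed implies bit-identical output for every generator."""

    def test_spot_series(self, plate_geometry):
        a = gen_spot_series(2e8, plate_geometry.dilution_exponents, 0.010, SeededConfig(7))
        b = gen_spot_series(2e8, plate_geometry.dilution_exponents, 0.010, SeededConfig(7))
        assert [s.counts for s in a] == [s.counts for s in b]

    def test_tolerance_counts(self, plate_geometry):
        model = ToleranceModel(2.0, -1.0)
        kw = dict(concentrations=[0.0, 2.0, 4.0], base_density=2e8, plating=plate_geometry)
        a = gen_tolerance_counts(model, cfg=SeededConfig(9), **kw)
        b = gen_tolerance_counts(model, cfg=SeededConfig(9), **kw)
        assert {c: [s.counts for s in ss] for c, ss in a.items()} == \
               {c: [s.counts for s in ss] for c, ss in b.items()}

    def test_competition(self):
        a = gen_competition(0.5, 64.0, 64.0, 5000, SeededConfig(11))
        b = gen_competition(0.5, 64.0, 64.0, 5000, SeededConfig(11))
        assert (a.positives_t0, a.positives_t1) == (b.positives_t0, b.positives_t1)

    def test_mst_and_itc_and_growth(self, itc_protocol):
        m = HillModel(1.0, 0.0, 8.0, 1.0)
        c = [1.0, 2.0, 4.0, 8.0, 16.0]
        pd.testing.assert_frame_equal(
            gen_mst_curve(m, c, SeededConfig(13, 2, 0.05)),
            gen_mst_curve(m, c, SeededConfig(13, 2, 0.05)),
        )
        e1 = gen_itc_thermogram(itc_protocol, 1.0, 8.0, -22.65, -2.0, SeededConfig(15, 1, 1.0))
        e2 = gen_itc_thermogram(itc_protocol, 1.0, 8.0, -22.65, -2.0, SeededConfig(15, 1, 1.0))
        assert np.array_equal(e1.sample_heats, e2.sample_heats)
        assert np.array_equal(e1.blank_heats, e2.blank_heats)
        t = np.arange(0, 10, 0.5)
        pd.testing.assert_frame_equal(
            gen_growth_curve(2.0, 0.3, 1.0, t, SeededConfig(17, 2, 0.01)),
            gen_growth_curve(2.0, 0.3, 1.0, t, SeededConfig(17, 2, 0.01)),
        )

    def test_different_seeds_differ(self, plate_geometry):
        a = gen_spot_series(2e8, plate_geometry.dilution_exponents, 0.010, SeededConfig(1))
        b = gen_spot_series(2e8, plate_geometry.dilution_exponents, 0.010, SeededConfig(2))
        assert [s.counts for s in a] != [s.counts for s in b]


class TestSpotSeries:
    def test_poisson_mean_within_monte_carlo_error(self):
        # density 2e8, exponent -5, 10 uL -> Poisson mean 20
        series = gen_spot_series(2e8, [-5], 0.010, SeededConfig(23, 1000))
        counts = np.array([s.counts[0] for s in series])
        se = np.sqrt(20 / 1000)
        assert abs(counts.mean() - 20.0) < 3 * se

    def test_zero_density_gives_all_zero(self, plate_geometry):
        series = gen_spot_series(0.0, plate_geometry.dilution_exponents, 0.010, SeededConfig(3))
        assert all(c == 0 for s in series for c in s.counts)

    def test_negative_density_rejected(self):
        with pytest.raises(ValidationError):
            gen_spot_series(-1.0, [-5], 0.010, SeededConfig(3))

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValidationError):
            gen_spot_series(1e8, [-5], 0.0, SeededConfig(3))


class TestToleranceModel:
    def test_flat_below_breakpoint(self):
        model = ToleranceModel(2.0, -1.0)
        assert model.frequency(0.0) == model.frequency(2.0) == 1.0

    def test_log_linear_decline(self):
        model = ToleranceModel(2.0, -1.0, 1e-9)
        assert model.frequency(4.0) == pytest.approx(1e-2)

    def test_floor_applies(self):
        model = ToleranceModel(2.0, -1.0, 1e-3)
        assert model.frequency(20.0) == 1e-3

    def test_positive_slope_rejected(self):
        with pytest.raises(ValidationError):
            ToleranceModel(2.0, 0.5)

    def test_counts_track_model_frequency(self, plate_geometry):
        model = ToleranceModel(2.0, -1.0)
        counts = gen_tolerance_counts(model, [0.0, 4.0], 2e8, plate_geometry,
                                      SeededConfig(29, 200))
        # at 4 mM the tolerant density is 2e6: undiluted 10 uL spots
        # carry Poisson mean 2e4; at 0 mM the -5 spot carries mean 20
        mean_at4 = np.mean([s.counts[0] for s in counts[4.0]])
        assert mean_at4 == pytest.approx(2e4, rel=0.02)
        mean_at0 = np.mean([s.counts[5] for s in counts[0.0]])
        assert mean_at0 == pytest.approx(20, rel=0.15)

    def test_requires_zero_and_sorted(self, plate_geometry):
        model = ToleranceModel(2.0, -1.0)
        with pytest.raises(ValidationError):
            gen_tolerance_counts(model, [1.0, 2.0], 2e8, plate_geometry, SeededConfig(1))
        with pytest.raises(ValidationError):
            gen_tolerance_counts(model, [2.0, 0.0], 2e8, plate_geometry, SeededConfig(1))


class TestCompetitionGenerator:
    def test_equal_folds_keep_fraction(self):
        raws = [gen_competition(0.5, 64.0, 64.0, 20000, SeededConfig(31 + i))
                for i in range(50)]
        frac = np.mean([1 - r.positives_t1 / r.total_t1 for r in raws])
        assert frac == pytest.approx(0.5, abs=0.005)

    def test_f0_bounds(self):
        with pytest.raises(ValidationError):
            gen_competition(1.0, 64.0, 64.0, 2000, SeededConfig(1))

    def test_event_floor(self):
        with pytest.raises(ValidationError):
            gen_competition(0.5, 64.0, 64.0, 500, SeededConfig(1))


class TestSignalGenerators:
    def test_mst_noise_free_values(self):
        model = HillModel(1.0, 0.2, 8.0, 1.0)
        df = gen_mst_curve(model, [0.0, 8.0], SeededConfig(37, 1, 0.0))
        at0 = df.loc[df.concentration_mM == 0.0, "f_norm"].iloc[0]
        atkd = df.loc[df.concentration_mM == 8.0, "f_norm"].iloc[0]
        assert at0 == pytest.approx(0.2)
        assert atkd == pytest.approx(0.6)  # midpoint at c = Kd

    def test_itc_zero_enthalpy_sample_equals_blank(self, itc_protocol):
        exp = gen_itc_thermogram(itc_protocol, 1.0, 8.0, 0.0, -2.0, SeededConfig(41, 1, 0.0))
        assert np.allclose(exp.sample_heats, exp.blank_heats)

    def test_growth_constant_before_lag_and_saturates(self):
        t = np.arange(0, 80, 0.5)
        df = gen_growth_curve(5.0, 0.4, 1.0, t, SeededConfig(43, 1, 0.0))
        od = df["od600"].to_numpy()
        assert np.allclose(od[t < 5.0], od[0])
        assert od[-1] == pytest.approx(1.0, rel=1e-3)

    def test_growth_unsorted_times_rejected(self):
        with pytest.raises(ValidationError):
            gen_growth_curve(1.0, 0.2, 1.0, [0, 2, 1], SeededConfig(1))
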