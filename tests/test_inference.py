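"""Accumulation-ratio inference: back-calculation of cytosolic
concentrations, observed/predicted AR profiles and the equilibrium fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from symporteq import (
    AccumulationRatioModel,
    ConcentrationSeries,
    TransmembraneState,
    accumulation_ratio_profile,
    deviation_report,
    equilibrium_external_concentration,
    infer_cytosolic_concentration,
    recover_parameters,
)
from symporteq.exceptions import ExtrapolationError, InsufficientDataError


def equilibrium_series(metabolite, c_in, pH_in, pHs, replicates=("r1",)):
    """Noise-free series lying exactly on the equilibrium curve."""
    rows = [
        (pH, equilibrium_external_concentration(c_in, TransmembraneState(pH_in, pH)), r)
        for pH in pHs
        for r in replicates
    ]
    return ConcentrationSeries.from_points(metabolite, rows)


class TestConcentrationSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            ConcentrationSeries.from_points("x", [(3.0, 1.0), (7.0, 1.0)])
        with pytest.raises(ValueError):
            ConcentrationSeries.from_points("x", [(7.0, -1.0), (6.5, 1.0)])
        with pytest.raises(ValueError):
            ConcentrationSeries.from_points("x", [(7.0, 1.0), (7.0, 2.0)])

    def test_unit_conversion_g_per_L(self):
        df = pd.DataFrame(
            {
                "metabolite": ["lactate", "lactate"],
                "pH_out": [6.5, 7.0],
                "concentration": [0.09008, 0.04504],  # g/L
                "unit": ["g/L", "g/L"],
                "replicate_id": ["r1", "r1"],
            }
        )
        series = ConcentrationSeries.from_dataframe(df, metabolite="lactate")
        assert series.data["concentration"].tolist() == pytest.approx([1.0, 0.5])

    def test_mixed_unit_equivalence(self):
        """The same measurements in mM and in g/L give identical series."""
        mm = pd.DataFrame(
            {
                "metabolite": "lactate",
                "pH_out": [6.5, 6.75, 7.0],
                "concentration": [0.2, 0.35, 0.62],
                "unit": "mM",
                "replicate_id": "r1",
            }
        )
        gl = mm.copy()
        gl["concentration"] = gl["concentration"] * 90.08 / 1000.0
        gl["unit"] = "g/L"
        a = ConcentrationSeries.from_dataframe(mm, metabolite="lactate")
        b = ConcentrationSeries.from_dataframe(gl, metabolite="lactate")
        assert np.allclose(
            a.data["concentration"], b.data["concentration"], rtol=1e-12
        )


class TestInferCytosolicConcentration:
    def test_exact_point_returns_replicate_mean(self):
        series = ConcentrationSeries.from_points(
            "lactate",
            [(6.75, 0.30, "r1"), (6.75, 0.40, "r2"), (7.0, 0.60, "r1"), (7.0, 0.64, "r2")],
        )
        assert infer_cytosolic_concentration(series, 7.0) == pytest.approx(0.62)

    def test_linear_interpolation_midpoint(self):
        series = ConcentrationSeries.from_points("x", [(6.9, 0.5), (7.1, 0.7)])
        assert infer_cytosolic_concentration(series, 7.0) == pytest.approx(0.6)

    def test_extrapolation_refused(self):
        series = ConcentrationSeries.from_points("x", [(6.0, 0.1), (6.5, 0.2)])
        with pytest.raises(ExtrapolationError):
            infer_cytosolic_concentration(series, 7.0)

    def test_invariant_to_replicate_ordering(self):
        pts = [(6.9, 0.5, "r1"), (7.1, 0.7, "r1"), (6.9, 0.52, "r2"), (7.1, 0.68, "r2")]
        a = ConcentrationSeries.from_points("x", pts)
        b = ConcentrationSeries.from_points("x", pts[::-1])
        assert infer_cytosolic_concentration(a, 7.0) == pytest.approx(
            infer_cytosolic_concentration(b, 7.0)
        )


class TestARProfile:
    def test_equilibrium_round_trip(self):
        """Series generated from the equilibrium law reproduce predicted AR."""
        pHs = np.round(np.arange(5.0, 7.51, 0.25), 2)
        series = equilibrium_series("lactate", 0.62, 7.0, pHs)
        profile = accumulation_ratio_profile(series, 7.0, 0.62)
        assert np.allclose(
            profile.table["observed_ar"], profile.table["predicted_ar"], rtol=1e-9
        )

    def test_hundredfold_accumulation_at_pH5(self):
        series = ConcentrationSeries.from_points("x", [(5.0, 0.0062), (7.0, 0.62)])
        profile = accumulation_ratio_profile(series, 7.0, 0.62)
        row = profile.table.set_index("pH_out")
        assert row.loc[5.0, "observed_ar"] == pytest.approx(100.0)
        assert row.loc[7.0, "observed_ar"] == pytest.approx(1.0)

    def test_zero_measurements_dropped(self, caplog):
        series = ConcentrationSeries.from_points("x", [(6.5, 0.0), (7.0, 0.62)])
        with caplog.at_level("WARNING"):
            profile = accumulation_ratio_profile(series, 7.0, 0.62)
        assert len(profile.table) == 1
        assert "dropping" in caplog.text

    def test_all_zero_series_raises(self):
        series = ConcentrationSeries.from_points("x", [(6.5, 0.0), (7.0, 0.0)])
        with pytest.raises(InsufficientDataError):
            accumulation_ratio_profile(series, 7.0, 0.62)

    @given(
        c_outs=st.lists(
            st.floats(1e-3, 10.0), min_size=2, max_size=8, unique=True
        )
    )
    def test_observed_ar_monotone_decreasing_in_c_out(self, c_outs):
        pHs = 6.0 + 0.1 * np.arange(len(c_outs))
        series = ConcentrationSeries.from_points("x", list(zip(pHs, sorted(c_outs))))
        profile = accumulation_ratio_profile(series, 7.0, 1.0)
        obs = profile.table.sort_values("c_out")["observed_ar"].to_numpy()
        assert (np.diff(obs) < 0).all()


class TestDeviationReport:
    def test_flags(self):
        table = pd.DataFrame(
            {
                "pH_out": [6.75, 7.0, 7.25],
                "c_out": [0.35, 0.62, 1.2],
                "observed_ar": [1.7, 1.0, 0.5],
                "predicted_ar": [1.78, 1.0, 1.0],
            }
        )
        from symporteq.inference import ARProfile

        profile = ARProfile("x", 7.0, 0.62, table)
        report = deviation_report(profile, rel_tol=0.2)
        assert report["flag"].tolist() == [
            "at-equilibrium",
            "at-equilibrium",
            "below-equilibrium",
        ]

    def test_above_equilibrium_flagged(self):
        from symporteq.inference import ARProfile

        table = pd.DataFrame(
            {
                "pH_out": [6.5],
                "c_out": [0.1],
                "observed_ar": [2.0],
                "predicted_ar": [1.0],
            }
        )
        report = deviation_report(ARProfile("x", 7.0, 0.62, table), rel_tol=0.2)
        assert report["flag"].tolist() == ["above-equilibrium"]

    def test_invalid_tolerance(self):
        from symporteq.inference import ARProfile

        profile = ARProfile(
            "x", 7.0, 0.62,
            pd.DataFrame({"pH_out": [7.0], "c_out": [0.62],
                          "observed_ar": [1.0], "predicted_ar": [1.0]}),
        )
        with pytest.raises(ValueError):
            deviation_report(profile, rel_tol=1.5)


class TestAccumulationRatioModel:
    def make_series(self, c_in=0.62, pH_in=7.0, n=10):
        pHs = np.linspace(6.0, 7.0, n)
        rows = [
            (pH, c_in * 10.0 ** (pH - pH_in)) for pH in pHs
        ]
        return ConcentrationSeries.from_points("lactate", rows)

    def test_noise_free_recovery_is_exact(self):
        series = self.make_series()
        res = AccumulationRatioModel(series, max_pH=7.0).fit(assume_c_in=0.62)
        assert res.pH_in_hat == pytest.approx(7.0, abs=1e-10)
        assert res.resid_se == pytest.approx(0.0, abs=1e-10)
        res2 = AccumulationRatioModel(series, max_pH=7.0).fit(assume_pH_in=7.0)
        assert res2.c_in_hat == pytest.approx(0.62, rel=1e-10)
        assert res2.diag_slope == pytest.approx(1.0, abs=1e-8)

    def test_alpha_is_the_only_joint_identifiable_quantity(self):
        """Different (pH_in, c_in) pairs with equal alpha fit identically."""
        a = self.make_series(c_in=0.62, pH_in=7.0)
        b = self.make_series(c_in=0.62 * 10**-0.2, pH_in=6.8)
        fit_a = AccumulationRatioModel(a).fit()
        fit_b = AccumulationRatioModel(b).fit()
        assert fit_a.alpha == pytest.approx(fit_b.alpha, abs=1e-12)

    def test_default_anchor_is_literature_pH(self):
        res = AccumulationRatioModel(self.make_series()).fit()
        assert res.anchored == "pH_in"
        assert res.pH_in_hat == 7.0

    def test_both_anchors_rejected(self):
        with pytest.raises(ValueError):
            AccumulationRatioModel(self.make_series()).fit(
                assume_pH_in=7.0, assume_c_in=0.62
            )

    def test_too_few_points(self):
        series = ConcentrationSeries.from_points(
            "x", [(6.5, 0.2), (6.6, 0.25), (6.7, 0.3)]
        )
        with pytest.raises(InsufficientDataError):
            AccumulationRatioModel(series)

    def test_max_pH_restriction_excludes_internalized_regime(self):
        """Points above the cut (off the equilibrium line) must not bias the fit."""
        good = self.make_series()
        rows = list(zip(good.data["pH_out"], good.data["concentration"]))
        rows += [(7.3, 5.0), (7.4, 8.0)]  # strongly off-equilibrium
        contaminated = ConcentrationSeries.from_points("lactate", rows)
        res = AccumulationRatioModel(contaminated, max_pH=7.0).fit(assume_c_in=0.62)
        assert res.pH_in_hat == pytest.approx(7.0, abs=1e-10)

    def test_summary_mentions_estimates(self):
        res = recover_parameters(self.make_series(), assume_pH_in=7.0)
        text = res.summary()
        assert "c_in" in text and "0.62" in text

    def test_predict_on_fitted_line(self):
        res = recover_parameters(self.make_series(), assume_pH_in=7.0)
        assert res.predict(7.0) == pytest.approx(0.62, rel=1e-9)
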