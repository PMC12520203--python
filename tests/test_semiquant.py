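"""Calibration fitting, quantitation, censoring, and the river-batch grid."""

import numpy as np
import pytest

from tpscreen.pipeline import PipelineConfig, quantify_batch, render_concentration_table
from tpscreen.semiquant import (
    SamplePrepFactors,
    fit_calibration,
    quantify,
    quantify_tp,
)
from tpscreen.synthetic import (
    LOQ_NG_L,
    RiverBatchScenario,
    SITES,
    TABLE3_TRUTH,
    generate_river_batch,
)

LEVELS = np.array([1.0, 5.0, 10.0, 50.0, 100.0, 250.0, 500.0, 750.0])


class TestCalibration:
    def test_exact_linear_fit(self):
        curve = fit_calibration(LEVELS, 2.0 * LEVELS)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration(np.array([5.0] * 6), np.arange(6.0))

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration(LEVELS, -2.0 * LEVELS)

    def test_noise_tuned_preset_limits_near_published(self):
        """LOD/LOQ from the noisy calibration preset land within a factor 2
        of the published 0.40 / 1 ng/L for haloperidol."""
        calibrations, _, _ = generate_river_batch(
            RiverBatchScenario(seed=5, noise_sigma_area=0.12)
        )
        df = calibrations["haloperidol"]
        curve = fit_calibration(df["level_ng_l"].to_numpy(), df["area"].to_numpy())
        assert 0.20 <= curve.lod <= 0.80
        assert 0.5 <= curve.loq <= 2.0
        assert curve.lod < curve.loq


class TestQuantify:
    def _curve(self):
        return fit_calibration(
            LEVELS, 100.0 * LEVELS + 10.0,
            lod_override=0.40, loq_override=1.0,
        )

    def test_round_trip_above_loq(self):
        curve = self._curve()
        prep = SamplePrepFactors()
        for c in (1.0, 5.0, 27.0, 750.0 / 1000.0 * 1000):
            area = 100.0 * (c * prep.enrichment) + 10.0
            out = quantify(area, curve, prep)
            assert not out.censored
            assert out.concentration_ng_l == pytest.approx(c, rel=1e-3)

    def test_intercept_area_censored(self):
        curve = self._curve()
        out = quantify(curve.intercept, curve, SamplePrepFactors())
        assert out.censored and out.display == "n.d."

    def test_censoring_monotone(self):
        curve = self._curve()
        prep = SamplePrepFactors()
        cs = np.linspace(0, 3, 31)
        censored = [
            quantify(100.0 * c * prep.enrichment + 10.0, curve, prep).censored
            for c in cs
        ]
        # once quantifiable, never censored again at higher concentration
        first_quant = censored.index(False)
        assert all(not c for c in censored[first_quant:])

    def test_scale_invariance(self):
        prep = SamplePrepFactors()
        c_true = 12.0
        for scale in (1.0, 3.7):
            curve = fit_calibration(
                LEVELS, scale * (100.0 * LEVELS + 10.0),
                lod_override=0.40, loq_override=1.0,
            )
            area = scale * (100.0 * c_true * prep.enrichment + 10.0)
            out = quantify(area, curve, prep)
            assert out.concentration_ng_l == pytest.approx(c_true, rel=1e-9)

    def test_recovery_correction_divides(self):
        curve = self._curve()
        prep = SamplePrepFactors(recovery=0.77, apply_recovery=True)
        area = 100.0 * (7.7 * 1000.0) + 10.0
        out = quantify(area, curve, prep)
        assert out.concentration_ng_l == pytest.approx(10.0, rel=1e-9)

    def test_negative_back_calculation_warns_and_zeroes(self):
        curve = self._curve()
        with pytest.warns(UserWarning):
            out = quantify(0.0, curve, SamplePrepFactors())
        assert out.concentration_ng_l == 0.0 and out.censored

    def test_enrichment_from_volumes(self):
        assert SamplePrepFactors().enrichment == 1000.0
        assert SamplePrepFactors(enrichment_override=2500.0).enrichment == 2500.0

    def test_tp_not_censored_at_parent_loq(self):
        curve = self._curve()
        prep = SamplePrepFactors()
        area = 100.0 * (0.47 * 1000.0) + 10.0
        out = quantify_tp(area, curve, prep)
        assert not out.censored
        assert out.concentration_ng_l == pytest.approx(0.47, rel=1e-6)
        assert out.semi_quantitative


class TestRiverBatchGrid:
    def test_full_grid_reproduced(self, river_batch):
        calibrations, batch, truth = river_batch
        quant = quantify_batch(calibrations, batch)
        merged = quant.merge(truth, on=["site", "month", "analyte"])
        for row in merged.itertuples():
            loq = LOQ_NG_L.get(row.analyte, 0.005)
            if row.true_ng_l >= loq or (row.semi_quantitative and row.true_ng_l > 0):
                assert not row.censored, (row.analyte, row.site, row.month)
                assert row.concentration_ng_l == pytest.approx(
                    row.true_ng_l, rel=1e-3
                )
            else:
                assert row.censored

    def test_maxima_match_published_abstract_values(self, river_batch):
        calibrations, batch, _ = river_batch
        quant = quantify_batch(calibrations, batch)
        ok = quant[~quant.censored]
        ha = ok[ok.analyte == "haloperidol"].concentration_ng_l.max()
        ar = ok[ok.analyte == "aripiprazole"].concentration_ng_l.max()
        assert ha == pytest.approx(27.0, rel=1e-6)
        assert ar == pytest.approx(67.0, rel=1e-6)

    def test_june_all_censored(self, river_batch):
        calibrations, batch, _ = river_batch
        quant = quantify_batch(calibrations, batch)
        june = quant[quant.month == "June"]
        assert june.censored.all()

    def test_tp_values_in_august_po_river(self, river_batch):
        calibrations, batch, _ = river_batch
        quant = quantify_batch(calibrations, batch)
        po_august = quant[
            (quant.month == "August") & (quant.site == SITES[0])
        ].set_index("analyte")
        for tp, expected in (("TP314-F", 0.16), ("TP388-B", 0.25),
                             ("TP392-D", 0.47)):
            assert po_august.loc[tp, "concentration_ng_l"] == pytest.approx(
                expected, rel=1e-6
            )

    def test_rendered_table_shape_and_markers(self, river_batch):
        calibrations, batch, _ = river_batch
        grid = render_concentration_table(quantify_batch(calibrations, batch))
        assert grid.shape == (len(TABLE3_TRUTH), 9)
        assert (grid.loc[:, ("June",)] == "n.d.").all().all()

    def test_recovery_flag_changes_only_uncensored_cells(self, river_batch):
        calibrations, batch, _ = river_batch
        plain = quantify_batch(calibrations, batch)
        corrected = quantify_batch(
            calibrations, batch, PipelineConfig(apply_recovery=True)
        )
        merged = plain.merge(
            corrected, on=["site", "month", "analyte"], suffixes=("", "_rec")
        )
        from tpscreen.synthetic import QUANT_PARENT, RECOVERY

        for row in merged.itertuples():
            rec = RECOVERY[QUANT_PARENT[row.analyte]]
            if row.censored and row.censored_rec:
                continue
            assert row.concentration_ng_l_rec == pytest.approx(
                row.concentration_ng_l / rec, rel=1e-9
            )
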