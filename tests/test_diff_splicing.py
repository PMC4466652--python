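"""Screen criteria, t-test oracle, tallies and the expression side-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cansplice.diff_splicing import (
    ScreenParams,
    direction_tally,
    expression_change_fraction,
    screen_events,
    significant_events,
)
from cansplice.io_formats import (
    AsEvent,
    ExpressionMatrix,
    PsiMatrix,
    SampleMeta,
    ValidationError,
)


def _cohort(n_tumor, n_normal, psi_rows, prefix="s"):
    cols = [f"{prefix}t{i}" for i in range(n_tumor)] + \
           [f"{prefix}n{i}" for i in range(n_normal)]
    meta = [SampleMeta(c, "X", "tumor" if c.startswith(f"{prefix}t") else "normal")
            for c in cols]
    df = pd.DataFrame(psi_rows, columns=cols)
    df.index = [f"e{i}" for i in range(len(df))]
    return PsiMatrix(df), meta


class TestScreenCriteria:
    def test_detection_filter_blocks_sparse_events(self):
        # 9 non-missing normals, 50 tumors: detection fails whatever the values
        row = [0.9] * 50 + [0.1] * 9 + [np.nan] * 41
        psi, meta = _cohort(50, 50, [row])
        res = screen_events(psi, meta)
        assert not res.loc["e0", "passes_detection"]
        assert not res.loc["e0", "significant"]
        assert np.isnan(res.loc["e0", "p_value"])

    def test_identical_constant_groups_not_significant(self):
        row = [0.5] * 40
        psi, meta = _cohort(20, 20, [row])
        res = screen_events(psi, meta)
        assert res.loc["e0", "delta_psi"] == 0
        assert res.loc["e0", "p_value"] == 1.0
        assert not res.loc["e0", "significant"]

    def test_welch_p_matches_scipy_on_planted_event(self, rng):
        mu, delta, kappa, n = 0.5, 0.25, 100.0, 40
        tum = rng.beta((mu + delta) * kappa / 4, (1 - mu - delta) * kappa / 4, n)
        nor = rng.beta(mu * kappa, (1 - mu) * kappa, n)
        psi, meta = _cohort(n, n, [np.concatenate([tum, nor])])
        res = screen_events(psi, meta)
        expected = stats.ttest_ind(tum, nor, equal_var=False)
        assert res.loc["e0", "p_value"] == pytest.approx(expected.pvalue, abs=1e-12)
        assert res.loc["e0", "significant"]

    def test_monotone_in_thresholds(self, small_bundle):
        b = small_bundle
        strict = screen_events(b.psi["CAN1"], b.meta, ScreenParams())
        relaxed = screen_events(
            b.psi["CAN1"], b.meta,
            ScreenParams(min_detected=5, p_threshold=0.2, delta_threshold=0.05))
        assert set(significant_events(strict)) <= set(significant_events(relaxed))

    def test_invariant_to_sample_permutation(self, small_bundle, rng):
        b = small_bundle
        psi = b.psi["CAN1"]
        perm = list(rng.permutation(psi.sample_ids))
        res_a = screen_events(psi, b.meta)
        res_b = screen_events(psi.subset_samples(perm), b.meta)
        pd.testing.assert_frame_equal(res_a, res_b)

    def test_missing_metadata_sample_is_error(self):
        psi, meta = _cohort(12, 12, [[0.5] * 24])
        with pytest.raises(ValidationError, match="without metadata"):
            screen_events(psi, meta[:-1])


class TestDirectionTally:
    def test_counts_by_sign(self):
        res = pd.DataFrame({
            "mode": ["RI"] * 3 + ["SE"],
            "delta_psi": [0.2, 0.15, -0.3, 0.5],
            "significant": [True, True, True, False],
        }, index=["a", "b", "c", "d"])
        tally = direction_tally(res)
        assert (tally.loc["RI", "n_up"], tally.loc["RI", "n_down"]) == (2, 1)
        assert (tally.loc["SE", "n_up"], tally.loc["SE", "n_down"]) == (0, 0)

    def test_no_significant_events_all_zero(self):
        res = pd.DataFrame({"mode": ["SE"], "delta_psi": [0.4],
                            "significant": [False]}, index=["a"])
        assert direction_tally(res).to_numpy().sum() == 0

    def test_planted_ri_bias_recovered(self, default_bundle, default_screen):
        b = default_bundle
        planted_ri = {e for e, d in b.truth.planted_shared.items()
                      if e.startswith("RI")}
        tally = direction_tally(default_screen["CAN2"])
        up, down = tally.loc["RI", "n_up"], tally.loc["RI", "n_down"]
        frac_up = up / (up + down)
        se = np.sqrt(0.8 * 0.2 / (up + down))
        assert abs(frac_up - 0.8) < 2.5 * se
        assert len(planted_ri) > 0  # the construction actually planted RIs


class TestExpressionChange:
    def _fixture(self, tumor_factor=1.0, noise=0.0, rng=None):
        n = 40
        psi_row = [0.9] * n + [0.4] * n
        psi, meta = _cohort(n, n, [psi_row])
        events = [AsEvent("e0", "SE", "G1", "chr1", "+", 0, 90)]
        base = np.full(2 * n, 8.0)
        base[:n] *= tumor_factor
        if rng is not None and noise > 0:
            base = base * np.exp(rng.normal(0, noise, 2 * n))
        expr = ExpressionMatrix(pd.DataFrame(
            [base], index=["G1"], columns=[m.sample_id for m in meta]))
        return psi, meta, events, expr

    def test_identical_expression_fraction_one(self, rng):
        psi, meta, events, expr = self._fixture(rng=rng, noise=0.3)
        res = screen_events(psi, meta)
        frac, table = expression_change_fraction(res, expr, events, meta)
        assert frac == 1.0
        assert table.loc["G1", "p_value"] > 0.05

    def test_doubled_expression_counted_as_changed(self):
        psi, meta, events, expr = self._fixture(tumor_factor=2.0)
        res = screen_events(psi, meta)
        frac, _ = expression_change_fraction(res, expr, events, meta)
        assert frac == 0.0

    def test_empty_significant_set_is_error(self):
        psi, meta, events, expr = self._fixture()
        res = screen_events(psi, meta)
        res["significant"] = False
        with pytest.raises(ValidationError, match="nothing to test"):
            expression_change_fraction(res, expr, events, meta)

    def test_null_expression_fraction_near_type_one_error(self, default_bundle,
                                                          default_screen):
        # expression independent of condition for non-regulator genes:
        # the unchanged fraction should be ~ 1 - alpha
        b = default_bundle
        res = default_screen["CAN1"]
        meta1 = [m for m in b.meta if m.cancer_type == "CAN1"]
        frac, table = expression_change_fraction(res, b.expression,
                                                 b.events, meta1)
        n = table["p_value"].notna().sum()
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.95) < 4 * se + 0.01
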