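"""PSI standard deviations, matched-control sampling, SD rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cansplice.io_formats import PsiMatrix, SampleMeta, ValidationError
from cansplice.variability import (
    compare_variability,
    matched_control_sample,
    psi_sd,
)

from conftest import null_config
from cansplice.synthetic_cohort import generate_cohort


def _simple(rows, n_t=10, n_n=10):
    cols = [f"t{i}" for i in range(n_t)] + [f"n{i}" for i in range(n_n)]
    meta = [SampleMeta(c, "X", "tumor" if c.startswith("t") else "normal")
            for c in cols]
    df = pd.DataFrame(rows, columns=cols,
                      index=[f"e{i}" for i in range(len(rows))])
    return PsiMatrix(df), meta


class TestPsiSd:
    def test_constant_vector_sd_zero(self):
        psi, meta = _simple([[0.5] * 20])
        sd = psi_sd(psi, meta)
        assert sd.loc["e0", "sd_tumor"] == 0.0
        assert sd.loc["e0", "sd_normal"] == 0.0

    def test_bernoulli_closed_form(self):
        # {0,1} x 10 each within one condition: SD = sqrt(0.25 * 20/19)
        row = [0.0, 1.0] * 10
        psi, meta = _simple([row], n_t=20, n_n=0)
        meta = [SampleMeta(f"t{i}", "X", "tumor") for i in range(20)] + \
               [SampleMeta(f"x{i}", "X", "normal") for i in range(3)]
        psi = PsiMatrix(pd.DataFrame(
            [row + [np.nan] * 3], columns=[f"t{i}" for i in range(20)]
            + [f"x{i}" for i in range(3)], index=["e0"]))
        sd = psi_sd(psi, meta)
        assert sd.loc["e0", "sd_tumor"] == pytest.approx(
            np.sqrt(0.25 * 20 / 19), abs=1e-12)

    def test_beta_variance_closed_form(self, rng):
        mu, kappa, n = 0.3, 50.0, 8000
        vals = rng.beta(mu * kappa, (1 - mu) * kappa, n)
        meta = [SampleMeta(f"t{i}", "X", "tumor") for i in range(n)]
        psi = PsiMatrix(pd.DataFrame([vals], columns=[m.sample_id for m in meta],
                                     index=["e0"]))
        meta.append(SampleMeta("n0", "X", "normal"))
        psi.data["n0"] = np.nan
        sd = psi_sd(PsiMatrix(psi.data), meta)
        expected = np.sqrt(mu * (1 - mu) / (kappa + 1))
        assert sd.loc["e0", "sd_tumor"] == pytest.approx(expected, rel=0.05)

    def test_sparse_condition_gets_nan(self):
        row = [0.5, 0.6] + [np.nan] * 8 + [0.5] * 10
        psi, meta = _simple([row])
        sd = psi_sd(psi, meta)
        assert np.isnan(sd.loc["e0", "sd_tumor"])
        assert sd.loc["e0", "sd_normal"] == 0.0


class TestMatchedControl:
    def test_pool_equal_to_target_returns_permutation(self, small_bundle):
        b = small_bundle
        target = b.psi["CAN1"].event_ids[:40]
        out = matched_control_sample(target, target, b.psi["CAN1"], b.meta,
                                     seed=1)
        assert sorted(out) == sorted(target)

    def test_forced_choice_single_bin(self):
        # all targets and exactly enough candidates in one mean-PSI bin
        rows = [[0.52 + 0.001 * i] * 20 for i in range(6)]
        psi, meta = _simple(rows)
        target = ["e0", "e1", "e2"]
        pool = ["e3", "e4", "e5"]
        out = matched_control_sample(target, pool, psi, meta, n_bins=20, seed=0)
        assert sorted(out) == pool

    def test_deficient_bin_error_names_bins(self):
        rows = [[0.1] * 20, [0.1] * 20, [0.9] * 20]
        psi, meta = _simple(rows)
        with pytest.raises(ValidationError, match="bin"):
            matched_control_sample(["e0", "e1"], ["e2"], psi, meta, seed=0)

    def test_histogram_match_and_ks(self):
        b = generate_cohort(null_config(11, n_cancers=1,
                                        n_events_per_mode={"SE": 2200}))
        psi = b.psi["CAN1"]
        rng = np.random.default_rng(0)
        target = list(rng.choice(psi.event_ids, 200, replace=False))
        pool = [e for e in psi.event_ids if e not in set(target)]
        mean_psi = psi_sd(psi, b.meta)["mean_psi"]
        bins = np.linspace(0, 1, 21)
        for seed in range(5):
            ctrl = matched_control_sample(target, pool, psi, b.meta,
                                          n_bins=20, seed=seed)
            assert len(ctrl) == len(target)
            ht, _ = np.histogram(mean_psi[target], bins)
            hc, _ = np.histogram(mean_psi[ctrl], bins)
            np.testing.assert_array_equal(ht, hc)
            ks = stats.ks_2samp(mean_psi[target], mean_psi[ctrl]).statistic
            assert ks < 0.1


class TestCompareVariability:
    def test_identical_sd_distributions_p_half(self, rng):
        rows = [list(rng.beta(5, 5, 30)) for _ in range(40)]
        psi, meta = _simple(rows, n_t=15, n_n=15)
        t = compare_variability([f"e{i}" for i in range(20)],
                                [f"e{i}" for i in range(20, 40)], psi, meta)
        assert 0.05 < t.p_target_vs_control_tumor < 0.95

    def test_complete_separation_minimal_u_tail(self, rng):
        # every target SD > every control SD: p equals the exact minimal tail
        rows = [list(0.5 + 0.4 * (rng.random(30) - 0.5)) for _ in range(12)] \
            + [list(0.5 + 0.01 * (rng.random(30) - 0.5)) for _ in range(12)]
        psi, meta = _simple(rows, n_t=15, n_n=15)
        target = [f"e{i}" for i in range(12)]
        control = [f"e{i}" for i in range(12, 24)]
        t = compare_variability(target, control, psi, meta)
        # exact one-sided p for complete separation: 1 / C(24, 12)
        from math import comb
        assert t.p_target_vs_control_tumor == pytest.approx(
            1 / comb(24, 12), rel=1e-6)

    def test_inflation_detected_on_synthetic(self, small_bundle):
        b = small_bundle
        target = list(b.truth.planted_shared)
        pool = [e for e in b.psi["CAN1"].event_ids if e not in set(target)]
        ctrl = matched_control_sample(target, pool, b.psi["CAN1"], b.meta,
                                      seed=2)
        t = compare_variability(target, ctrl, b.psi["CAN1"], b.meta)
        assert t.p_tumor_vs_normal_target < 0.01
        assert t.p_target_vs_control_tumor < 0.01

    def test_too_few_events_is_error(self):
        rows = [[0.5] * 20] * 4
        psi, meta = _simple(rows)
        with pytest.raises(ValidationError, match="too few"):
            compare_variability(["e0"], ["e1"], psi, meta)
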