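"""Per-cancer differential-splicing screen.

An AS event is called significant in a cancer type when all three criteria
hold: (i) a PSI estimate exists in at least ``min_detected`` tumor and
``min_detected`` normal samples; (ii) tumor and normal PSI distributions
differ by a two-sided Welch t-test at ``p_threshold``; (iii) the absolute
difference of group mean PSI exceeds ``delta_threshold``.

Welch (unequal-variance) form is used because tumor PSI variance is
systematically inflated relative to normal tissue, which breaks the pooled
variance assumption.  p-values are deliberately uncorrected — the screen's
specificity device is the downstream cross-cancer intersection — but a
Benjamini-Hochberg option is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    AsEvent,
    ExpressionMatrix,
    PsiMatrix,
    SampleMeta,
    ValidationError,
)


@dataclass
class ScreenParams:
    min_detected: int = 10
    p_threshold: float = 0.05
    delta_threshold: float = 0.1
    bh_fdr: bool = False   # apply Benjamini-Hochberg before the p criterion

    def __post_init__(self) -> None:
        if self.min_detected < 2:
            raise ValidationError("min_detected must be >= 2")
        for name in ("p_threshold", "delta_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")


def _condition_masks(psi: PsiMatrix, meta: Sequence[SampleMeta]
                     ) -> Tuple[np.ndarray, np.ndarray]:
    cond = {m.sample_id: m.condition for m in meta}
    missing = [s for s in psi.sample_ids if s not in cond]
    if missing:
        raise ValidationError(
            f"samples without metadata: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    conds = np.array([cond[s] for s in psi.sample_ids])
    tumor = conds == "tumor"
    normal = conds == "normal"
    if not tumor.any() or not normal.any():
        raise ValidationError("both tumor and normal samples are required")
    return tumor, normal


def _nan_mean_var(v: np.ndarray, n: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Row-wise mean and ddof=1 variance ignoring NaNs, without slice warnings."""
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nansum(v, axis=1) / n
        ss = np.nansum((v - mean[:, None]) ** 2, axis=1)
        var = np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan)
    mean = np.where(n > 0, mean, np.nan)
    return mean, var


def welch_ttest(a_mean, a_var, a_n, b_mean, b_var, b_n):
    """Vectorized two-sided Welch t-test from group summaries.

    Degenerate case: both groups constant -> p = 1 if means equal (no
    evidence), else p = 0 (infinite separation).
    """
    a_se2 = a_var / a_n
    b_se2 = b_var / b_n
    denom2 = a_se2 + b_se2
    diff = a_mean - b_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(denom2)
        df = denom2 ** 2 / (a_se2 ** 2 / (a_n - 1) + b_se2 ** 2 / (b_n - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = denom2 == 0
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    return p


def screen_events(psi: PsiMatrix, meta: Sequence[SampleMeta],
                  params: Optional[ScreenParams] = None,
                  events: Optional[Sequence[AsEvent]] = None) -> pd.DataFrame:
    """Apply the three screen criteria to every event of one cancer type.

    Returns a DataFrame indexed by event_id with columns ``mode``,
    ``n_normal_detected``, ``n_tumor_detected``, ``mean_normal``,
    ``mean_tumor``, ``delta_psi``, ``p_value``, ``passes_detection``,
    ``passes_p``, ``passes_delta``, ``significant``.  Events failing the
    detection filter keep ``p_value`` = NaN and are never significant.
    """
    params = params or ScreenParams()
    tumor, normal = _condition_masks(psi, meta)
    vals = psi.values
    vt, vn = vals[:, tumor], vals[:, normal]

    n_t = np.sum(~np.isnan(vt), axis=1)
    n_n = np.sum(~np.isnan(vn), axis=1)
    detected = (n_t >= params.min_detected) & (n_n >= params.min_detected)

    mean_t, var_t = _nan_mean_var(vt, n_t)
    mean_n, var_n = _nan_mean_var(vn, n_n)
    delta = mean_t - mean_n

    p = np.full(vals.shape[0], np.nan)
    if detected.any():
        p[detected] = welch_ttest(
            mean_t[detected], var_t[detected], n_t[detected],
            mean_n[detected], var_n[detected], n_n[detected])

    p_crit = p.copy()
    if params.bh_fdr and detected.any():
        adj = np.full_like(p, np.nan)
        adj[detected] = _bh_adjust(p[detected])
        p_crit = adj

    passes_p = np.where(np.isnan(p_crit), False, p_crit < params.p_threshold)
    passes_delta = np.where(np.isnan(delta), False,
                            np.abs(delta) > params.delta_threshold)
    significant = detected & passes_p & passes_delta

    mode_of = {e.event_id: e.mode for e in events} if events else {}
    out = pd.DataFrame({
        "mode": [mode_of.get(e, e.split("_")[0]) for e in psi.event_ids],
        "n_normal_detected": n_n,
        "n_tumor_detected": n_t,
        "mean_normal": mean_n,
        "mean_tumor": mean_t,
        "delta_psi": delta,
        "p_value": p,
        "passes_detection": detected,
        "passes_p": passes_p.astype(bool),
        "passes_delta": passes_delta.astype(bool),
        "significant": significant,
    }, index=pd.Index(psi.event_ids, name="event_id"))
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def significant_events(results: pd.DataFrame) -> List[str]:
    return list(results.index[results["significant"]])


def direction_tally(results: pd.DataFrame) -> pd.DataFrame:
    """Counts of significant events with positive vs negative delta PSI, per mode."""
    sig = results[results["significant"] & (results["delta_psi"] != 0)]
    modes = sorted(results["mode"].unique())
    rows = []
    for m in modes:
        d = sig.loc[sig["mode"] == m, "delta_psi"]
        rows.append({"mode": m, "n_up": int((d > 0).sum()),
                     "n_down": int((d < 0).sum())})
    return pd.DataFrame(rows).set_index("mode")


def expression_change_fraction(results: pd.DataFrame, expr: ExpressionMatrix,
                               events: Sequence[AsEvent],
                               meta: Sequence[SampleMeta],
                               p_threshold: float = 0.05
                               ) -> Tuple[float, pd.DataFrame]:
    """Fraction of significant-AS genes with no significant expression change.

    Per gene hosting a significant event: two-sided Welch t-test on
    log2(expression + 1), tumor vs normal, over the metadata samples present
    in the expression matrix.  Returns (fraction with p >= threshold,
    per-gene table).  Genes absent from the expression matrix are reported
    in the table with NaN p and excluded from the fraction.
    """
    sig_ids = set(significant_events(results))
    if not sig_ids:
        raise ValidationError("nothing to test: no significant events")
    genes = sorted({e.gene for e in events if e.event_id in sig_ids})

    cond = {m.sample_id: m.condition for m in meta}
    cols = [s for s in expr.sample_ids if s in cond]
    if not cols:
        raise ValidationError("no metadata samples present in expression matrix")
    sub = expr.data[cols]
    conds = np.array([cond[s] for s in cols])
    logx = np.log2(sub.to_numpy() + 1.0)
    t_mask, n_mask = conds == "tumor", conds == "normal"

    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = []
    for g in genes:
        i = gene_pos.get(g)
        if i is None:
            rows.append({"gene": g, "p_value": np.nan, "log2_fc": np.nan})
            continue
        a, b = logx[i, t_mask], logx[i, n_mask]
        p = float(welch_ttest(np.array([a.mean()]), np.array([a.var(ddof=1)]),
                              np.array([a.size]), np.array([b.mean()]),
                              np.array([b.var(ddof=1)]), np.array([b.size]))[0])
        rows.append({"gene": g, "p_value": p,
                     "log2_fc": float(a.mean() - b.mean())})
    table = pd.DataFrame(rows).set_index("gene")
    tested = table["p_value"].dropna()
    if tested.empty:
        raise ValidationError("no significant-AS genes found in expression matrix")
    fraction = float((tested >= p_threshold).mean())
    return fraction, table


def paired_delta_psi(psi: PsiMatrix, meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Per-event tumor-minus-normal PSI for matched sample pairs (plot export).

    Diagnostic companion to the group-wise screen; pairs are taken from
    ``paired_sample_id`` on tumor records.
    """
    pairs = [(m.sample_id, m.paired_sample_id) for m in meta
             if m.condition == "tumor" and m.paired_sample_id]
    cols = {}
    sset = set(psi.sample_ids)
    for t, n in pairs:
        if t in sset and n in sset:
            cols[f"{t}-vs-{n}"] = psi.data[t] - psi.data[n]
    return pd.DataFrame(cols, index=psi.data.index)
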