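"""Splicing-expression correlation screen and regulator-candidate extraction.

Every (core event, gene) pair is tested with tie-corrected Spearman rank
correlation on pairwise-complete samples; pairs with |rho| >= 0.4 and
p <= 0.005 count as highly correlated, and genes correlated with strictly
more than 30 core events are reported as regulator candidates.  p-values
come from the t approximation t = rho * sqrt((n-2)/(1-rho^2)), two-sided,
and are deliberately uncorrected (a Benjamini-Hochberg option exists).

The all-pairs screen is vectorized: for each event, the expression matrix
restricted to that event's non-missing samples is rank-transformed once and
all gene correlations are obtained with a single matrix product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .diff_splicing import _bh_adjust
from .io_formats import ExpressionMatrix, PsiMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ScreenThresholds:
    rho_min: float = 0.4
    p_max: float = 0.005
    min_events: int = 30          # candidates need strictly more than this
    min_samples: int = 30
    bh_fdr: bool = False


def spearman(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Tie-corrected Spearman rho with two-sided t-approximation p.

    Pairs with a missing value in either vector are dropped.  Raises on
    fewer than 3 complete pairs; zero variance in either vector yields
    rho = NaN (the pair is unusable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": float("nan"), "p": float("nan"), "n": int(x.size)}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": int(x.size)}


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1)


def correlation_screen(psi: PsiMatrix, expr: ExpressionMatrix,
                       thresholds: Optional[ScreenThresholds] = None
                       ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """All event x gene Spearman correlations, filtered pairs and candidates.

    Returns (pairs, candidates): ``pairs`` holds every pair passing the
    rho/p thresholds, ``candidates`` the per-gene counts for genes passing
    the >min_events criterion.
    """
    th = thresholds or ScreenThresholds()
    shared = [s for s in psi.sample_ids if s in set(expr.sample_ids)]
    if len(shared) < th.min_samples:
        raise ValidationError(
            f"only {len(shared)} shared samples (need >= {th.min_samples})")
    pv = psi.subset_samples(shared).values                  # events x samples
    xv = expr.data[shared].to_numpy()                       # genes x samples
    genes = np.array(expr.gene_ids)
    events = np.array(psi.event_ids)

    gene_const = np.ptp(xv, axis=1) == 0
    pair_rows = []
    for i, eid in enumerate(events):
        ok = ~np.isnan(pv[i])
        n = int(ok.sum())
        if n < th.min_samples:
            continue
        e_rank = stats.rankdata(pv[i, ok])
        if np.ptp(e_rank) == 0:
            continue
        g = xv[:, ok]
        g_rank = _rank_rows(g)
        # Pearson on ranks, vectorized over genes
        e_c = e_rank - e_rank.mean()
        g_c = g_rank - g_rank.mean(axis=1, keepdims=True)
        denom = np.sqrt((e_c ** 2).sum()) * np.sqrt((g_c ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (g_c @ e_c) / denom
        rho[gene_const] = np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
        p = np.where(np.abs(rho) >= 1.0, 0.0, p)

        usable = ~np.isnan(rho)
        p_crit = _bh_adjust(p[usable]) if th.bh_fdr else p[usable]
        sel = (np.abs(rho[usable]) >= th.rho_min) & (p_crit <= th.p_max)
        for gi, r, pval in zip(np.flatnonzero(usable)[sel],
                               rho[usable][sel], p[usable][sel]):
            pair_rows.append({"event_id": eid, "gene_id": genes[gi],
                              "rho": float(r), "p_value": float(pval),
                              "n_samples": n})

    pairs = pd.DataFrame(pair_rows,
                         columns=["event_id", "gene_id", "rho", "p_value",
                                  "n_samples"])
    if pairs.empty:
        candidates = pd.DataFrame(
            columns=["n_correlated_events", "n_positive", "n_negative"])
        candidates.index.name = "gene_id"
        return pairs, candidates

    grp = pairs.groupby("gene_id")
    summary = pd.DataFrame({
        "n_correlated_events": grp["event_id"].nunique(),
        "n_positive": grp["rho"].apply(lambda r: int((r > 0).sum())),
        "n_negative": grp["rho"].apply(lambda r: int((r < 0).sum())),
    })
    candidates = summary[summary["n_correlated_events"] > th.min_events] \
        .sort_values("n_correlated_events", ascending=False)
    candidates.index.name = "gene_id"
    return pairs, candidates
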