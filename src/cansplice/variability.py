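"""PSI variability analysis with distribution-matched control events.

Mean PSI strongly constrains PSI variance (values near 0 or 1 cannot vary
much), so comparing the standard deviation of cancer-specific events against
arbitrary controls confounds mean with spread.  The control set is therefore
sampled to match the target set's mean-PSI histogram: events are binned by
mean PSI into equal-width bins on [0, 1] and controls are drawn without
replacement bin-by-bin with exactly the target's bin counts.

SD comparisons use one-sided Mann-Whitney U tests on the per-event SDs
(a rank test avoids distributional assumptions on SDs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PsiMatrix, SampleMeta, ValidationError

logger = logging.getLogger(__name__)


def psi_sd(psi: PsiMatrix, meta: Sequence[SampleMeta],
           events: Optional[Sequence[str]] = None,
           min_values: int = 3) -> pd.DataFrame:
    """Per-event sample SD (ddof=1) of non-missing PSI, per condition.

    Rows with fewer than ``min_values`` non-missing values in a condition get
    NaN for that condition; events with NaN in both are dropped with a
    warning.  Also returns each event's mean PSI over all (pooled) samples,
    the binning basis for matched-control sampling.
    """
    sub = psi if events is None else psi.subset_events(list(events))
    cond = {m.sample_id: m.condition for m in meta}
    conds = np.array([cond.get(s, "") for s in sub.sample_ids])
    vals = sub.values

    out = {}
    for label in ("normal", "tumor"):
        v = vals[:, conds == label]
        n = (~np.isnan(v)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.nansum(v, axis=1) / n
            ss = np.nansum((v - mean[:, None]) ** 2, axis=1)
            sd = np.sqrt(ss / np.maximum(n - 1, 1))
        sd[n < min_values] = np.nan
        out[f"sd_{label}"] = sd
        out[f"n_{label}"] = n

    both = vals[:, (conds == "normal") | (conds == "tumor")]
    n_all = (~np.isnan(both)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["mean_psi"] = np.nansum(both, axis=1) / n_all

    df = pd.DataFrame(out, index=pd.Index(sub.event_ids, name="event_id"))
    dropped = df["sd_normal"].isna() & df["sd_tumor"].isna()
    if dropped.any():
        logger.warning("psi_sd: dropped %d events with <%d values in both "
                       "conditions", int(dropped.sum()), min_values)
    return df[~dropped]


def matched_control_sample(target_events: Sequence[str],
                           candidate_pool: Sequence[str],
                           psi: PsiMatrix, meta: Sequence[SampleMeta],
                           n_bins: int = 20, seed: int = 0) -> List[str]:
    """Sample controls matching the target's binned mean-PSI histogram.

    Candidates overlapping the target set are excluded.  Raises when any bin
    has fewer candidates than targets, naming the deficient bins.
    """
    target = list(dict.fromkeys(target_events))
    pool = [e for e in dict.fromkeys(candidate_pool) if e not in set(target)]
    if not target:
        raise ValidationError("empty target set")
    if not pool:
        # the spec's degenerate identity case: pool == target
        pool = target

    mean_psi = psi_sd(psi, meta, events=list(set(target) | set(pool)))["mean_psi"]
    bins = np.linspace(0.0, 1.0, n_bins + 1)

    def bin_of(e: str) -> int:
        return min(int(np.searchsorted(bins, mean_psi[e], side="right") - 1),
                   n_bins - 1)

    tgt_bins: Dict[int, int] = {}
    for e in target:
        tgt_bins[bin_of(e)] = tgt_bins.get(bin_of(e), 0) + 1
    pool_bins: Dict[int, List[str]] = {}
    for e in pool:
        pool_bins.setdefault(bin_of(e), []).append(e)

    deficient = {b: (n, len(pool_bins.get(b, [])))
                 for b, n in tgt_bins.items() if len(pool_bins.get(b, [])) < n}
    if deficient:
        detail = ", ".join(f"bin {b}: need {need}, have {have}"
                           for b, (need, have) in sorted(deficient.items()))
        raise ValidationError(
            f"matched sampling infeasible ({detail}); try fewer bins")

    rng = np.random.default_rng(seed)
    control: List[str] = []
    for b, n in sorted(tgt_bins.items()):
        picked = rng.choice(pool_bins[b], size=n, replace=False)
        control.extend(str(e) for e in picked)
    return sorted(control)


@dataclass
class VariabilityTests:
    p_target_vs_control_normal: float
    p_target_vs_control_tumor: float
    p_tumor_vs_normal_target: float
    n_target: int
    n_control: int


def compare_variability(target: Sequence[str], control: Sequence[str],
                        psi: PsiMatrix, meta: Sequence[SampleMeta],
                        min_events: int = 10) -> VariabilityTests:
    """One-sided Mann-Whitney tests on per-event PSI SDs.

    Alternatives: target SDs greater than control SDs (per condition), and
    within the target set, tumor SDs greater than normal SDs.
    """
    sd_t = psi_sd(psi, meta, events=target)
    sd_c = psi_sd(psi, meta, events=control)

    def mw_greater(a: pd.Series, b: pd.Series) -> float:
        a, b = a.dropna(), b.dropna()
        if len(a) < min_events or len(b) < min_events:
            raise ValidationError(
                f"too few events with SDs ({len(a)} vs {len(b)}, "
                f"need >= {min_events} per side)")
        # exact null distribution when cheap, normal approximation otherwise
        method = "exact" if max(len(a), len(b)) <= 30 else "asymptotic"
        return float(stats.mannwhitneyu(a, b, alternative="greater",
                                        method=method).pvalue)

    return VariabilityTests(
        p_target_vs_control_normal=mw_greater(sd_t["sd_normal"], sd_c["sd_normal"]),
        p_target_vs_control_tumor=mw_greater(sd_t["sd_tumor"], sd_c["sd_tumor"]),
        p_tumor_vs_normal_target=mw_greater(sd_t["sd_tumor"], sd_t["sd_normal"]),
        n_target=len(sd_t), n_control=len(sd_c),
    )
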