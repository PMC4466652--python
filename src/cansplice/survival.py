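"""Kaplan-Meier / log-rank screen of core events against overall survival.

For each core event, patients with a PSI estimate are split at the median
PSI (ties to the low group; the quantile is a parameter) and the two groups
are compared with the standard 1-df log-rank test: at each distinct death
time the observed deaths in group A are compared with the hypergeometric
expectation given the risk sets, chi-square = (O - E)^2 / V with the
hypergeometric variance V summed over death times.

Both the product-limit estimator and the log-rank statistic are implemented
directly (a screen over hundreds of events needs sub-millisecond tests);
the test suite cross-checks them against lifelines.
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


def km_estimate(times: Sequence[float], events: Sequence[bool]
                ) -> List[Tuple[float, float]]:
    """Product-limit survival estimate as (time, survival) step pairs.

    Starts at (0, 1); survival drops only at observed death times and is
    non-increasing.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if (t < 0).any():
        raise ValidationError("negative survival times")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    steps = [(0.0, 1.0)]
    s = 1.0
    n_at_risk = t.size
    i = 0
    while i < t.size:
        j = i
        deaths = 0
        while j < t.size and t[j] == t[i]:
            deaths += int(e[j])
            j += 1
        if deaths:
            s *= 1.0 - deaths / n_at_risk
            steps.append((float(t[i]), s))
        n_at_risk -= j - i
        i = j
    return steps


def logrank(times_a, events_a, times_b, events_b) -> Dict[str, float]:
    """Two-group 1-df log-rank test: {'chi_square', 'p'}.

    With no observed deaths (or zero variance) the statistic is undefined;
    chi-square = 0 / p = 1 is returned with a warning.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if not ea.any() and not eb.any():
        logger.warning("log-rank: no death events in either group; p = 1")
        return {"chi_square": 0.0, "p": 1.0}

    death_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_a = e_a = v = 0.0
    for t in death_times:
        n1 = float((ta >= t).sum())
        n2 = float((tb >= t).sum())
        d1 = float(((ta == t) & ea).sum())
        d2 = float(((tb == t) & eb).sum())
        n, d = n1 + n2, d1 + d2
        o_a += d1
        e_a += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if v == 0:
        logger.warning("log-rank: zero variance; p = 1")
        return {"chi_square": 0.0, "p": 1.0}
    chi2 = (o_a - e_a) ** 2 / v
    return {"chi_square": float(chi2), "p": float(stats.chi2.sf(chi2, 1))}


@dataclass
class SurvivalScreenParams:
    alpha: float = 0.05
    split_quantile: float = 0.5    # "high vs low PSI" cut point
    min_patients: int = 20
    min_group: int = 5


def survival_screen(psi: PsiMatrix, meta: Sequence[SampleMeta],
                    core_events: Sequence[str],
                    params: Optional[SurvivalScreenParams] = None
                    ) -> Tuple[pd.DataFrame, int]:
    """Log-rank screen over core events; returns (table sorted by p, n hits).

    Patients = samples with survival annotation; per event, patients with
    missing PSI are excluded, the rest are split at the ``split_quantile``
    of their PSI (ties to the low group).  Events whose split leaves fewer
    than ``min_group`` patients on either side are skipped.
    """
    params = params or SurvivalScreenParams()
    surv = {m.sample_id: (m.survival_days, m.survival_event)
            for m in meta if m.survival_days is not None}
    patients = [s for s in psi.sample_ids if s in surv]
    if len(patients) < params.min_patients:
        raise ValidationError(
            f"only {len(patients)} patients with survival data "
            f"(need >= {params.min_patients})")
    sub = psi.subset_samples(patients)
    times = np.array([surv[s][0] for s in patients])
    deaths = np.array([surv[s][1] for s in patients], dtype=bool)

    rows = []
    skipped = 0
    for eid in core_events:
        if eid not in sub.data.index:
            skipped += 1
            continue
        v = sub.data.loc[eid].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.sum() < params.min_patients:
            skipped += 1
            continue
        cut = float(np.quantile(v[ok], params.split_quantile))
        low = ok & (v <= cut)
        high = ok & (v > cut)
        if low.sum() < params.min_group or high.sum() < params.min_group:
            skipped += 1
            continue
        res = logrank(times[high], deaths[high], times[low], deaths[low])
        worse = _worse_group(times[high], deaths[high], times[low], deaths[low])
        rows.append({
            "event_id": eid, "n_high": int(high.sum()), "n_low": int(low.sum()),
            "chi_square": res["chi_square"], "p_value": res["p"],
            "worse_group": worse,
        })
    if skipped:
        logger.warning("survival_screen: skipped %d events (missing, sparse "
                       "or degenerate split)", skipped)
    if not rows:
        raise ValidationError("no core events usable for the survival screen")
    table = pd.DataFrame(rows).set_index("event_id").sort_values("p_value")
    n_hits = int((table["p_value"] < params.alpha).sum())
    return table, n_hits


def _worse_group(t_high, d_high, t_low, d_low) -> str:
    """Group with lower restricted mean survival up to the common horizon."""
    horizon = float(min(t_high.max(), t_low.max()))
    rm_high = _restricted_mean(t_high, d_high, horizon)
    rm_low = _restricted_mean(t_low, d_low, horizon)
    return "high" if rm_high < rm_low else "low"


def _restricted_mean(times, deaths, horizon: float) -> float:
    steps = km_estimate(times, deaths)
    area, prev_t, prev_s = 0.0, 0.0, 1.0
    for t, s in steps[1:]:
        t = min(t, horizon)
        area += prev_s * (t - prev_t)
        prev_t, prev_s = t, s
        if t >= horizon:
            break
    if prev_t < horizon:
        area += prev_s * (horizon - prev_t)
    return area
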