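"""Cross-cancer intersection of significant AS events and its null model.

The core cancer-specific set is the intersection of per-cancer significant
sets.  Its size is benchmarked against a permutation null: each replicate
draws, from each cancer's own detectable-event universe, a random set the
same size as that cancer's significant set, and counts the k-way
intersection.  Significance is a rank test with the +1 pseudo-count
convention.  A hypergeometric test quantifies overlap between core genes and
a list of frequently mutated cancer genes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class OverlapNull:
    mode: str
    observed_overlap: int
    sim_mean: float
    sim_min: int
    sim_max: int
    n_replicates: int
    rank_p: float


@dataclass
class ConsistencyReport:
    n_core_events: int
    n_consistent: int
    fraction_consistent: float
    directions: pd.DataFrame     # core events x cancers, sign of delta PSI


def intersect_significant(per_cancer: Mapping[str, pd.DataFrame]
                          ) -> Tuple[pd.DataFrame, List[str]]:
    """Venn counts per mode over per-cancer significant sets, plus the core set.

    Returns (venn table, core event ids).  The venn table has one row per
    (mode, cancer subset) with the count of events significant in exactly
    that subset of cancers.
    """
    if len(per_cancer) < 2:
        raise ValidationError("need results from at least 2 cancers")
    sig: Dict[str, Set[str]] = {}
    mode_of: Dict[str, str] = {}
    for cancer, res in per_cancer.items():
        ids = set(res.index[res["significant"]])
        if not ids:
            raise ValidationError(f"no significant events for cancer {cancer!r}")
        sig[cancer] = ids
        mode_of.update(res["mode"].to_dict())

    cancers = sorted(per_cancer)
    union = set().union(*sig.values())
    membership = {e: frozenset(c for c in cancers if e in sig[c]) for e in union}

    rows = []
    modes = sorted({mode_of[e] for e in union})
    for mode in modes:
        for r in range(1, len(cancers) + 1):
            for combo in itertools.combinations(cancers, r):
                combo_set = frozenset(combo)
                n = sum(1 for e in union
                        if mode_of[e] == mode and membership[e] == combo_set)
                rows.append({"mode": mode, "cancers": "+".join(combo),
                             "n_cancers": r, "count": n})
    venn = pd.DataFrame(rows)
    core = sorted(e for e in union if len(membership[e]) == len(cancers))
    return venn, core


def overlap_permutation_null(universe: Mapping[str, Sequence[str]],
                             draw_sizes: Mapping[str, int],
                             observed: int,
                             n_replicates: int = 1000,
                             seed: int = 0,
                             mode: str = "all") -> OverlapNull:
    """Simulated null for the k-way intersection of significant sets.

    Each replicate samples ``draw_sizes[c]`` events uniformly without
    replacement from ``universe[c]`` (that cancer's detectable events) and
    counts the events common to every cancer.
    """
    cancers = sorted(universe)
    if sorted(draw_sizes) != cancers:
        raise ValidationError("universe and draw_sizes must cover the same cancers")
    # map ids to a common integer space
    all_ids = sorted(set().union(*[set(universe[c]) for c in cancers]))
    pos = {e: i for i, e in enumerate(all_ids)}
    uni_idx = {}
    for c in cancers:
        ids = universe[c]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate events in universe of {c!r}")
        if draw_sizes[c] > len(ids):
            raise ValidationError(
                f"draw size {draw_sizes[c]} exceeds universe of {c!r} ({len(ids)})")
        uni_idx[c] = np.array([pos[e] for e in ids])

    rng = np.random.default_rng(seed)
    overlaps = np.empty(n_replicates, dtype=int)
    counts = np.zeros(len(all_ids), dtype=np.int32)
    for r in range(n_replicates):
        counts[:] = 0
        for c in cancers:
            picked = rng.choice(uni_idx[c], size=draw_sizes[c], replace=False)
            counts[picked] += 1
        overlaps[r] = int((counts == len(cancers)).sum())

    rank_p = (int((overlaps >= observed).sum()) + 1) / (n_replicates + 1)
    return OverlapNull(
        mode=mode, observed_overlap=int(observed),
        sim_mean=float(overlaps.mean()), sim_min=int(overlaps.min()),
        sim_max=int(overlaps.max()), n_replicates=n_replicates,
        rank_p=float(rank_p),
    )


def direction_consistency(core: Sequence[str],
                          per_cancer: Mapping[str, pd.DataFrame]
                          ) -> ConsistencyReport:
    """Fraction of core events whose delta-PSI sign agrees across all cancers."""
    cancers = sorted(per_cancer)
    if not core:
        raise ValidationError("empty core set")
    signs = pd.DataFrame(index=pd.Index(core, name="event_id"),
                         columns=cancers, dtype=float)
    for c in cancers:
        res = per_cancer[c]
        missing = [e for e in core if e not in res.index]
        if missing:
            raise ValidationError(
                f"core events missing from results of {c!r}: {missing[:3]}")
        d = res.loc[core, "delta_psi"]
        if d.isna().any():
            raise ValidationError(f"core event without delta PSI in {c!r}")
        signs[c] = np.sign(d)
    has_zero = (signs == 0).any(axis=1)
    if has_zero.any():
        logger.warning("%d core events with delta PSI exactly 0 counted "
                       "inconsistent", int(has_zero.sum()))
    consistent = (~has_zero) & (signs.nunique(axis=1) == 1)
    n = len(core)
    return ConsistencyReport(
        n_core_events=n,
        n_consistent=int(consistent.sum()),
        fraction_consistent=float(consistent.sum() / n),
        directions=signs,
    )


def hypergeom_tail(k: int, universe: int, n_marked: int, n_drawn: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe, n_marked, n_drawn)."""
    return float(min(stats.hypergeom.sf(k - 1, universe, n_marked, n_drawn), 1.0))


def mutated_gene_overlap(core_genes: Set[str], mutated_genes: Set[str],
                         universe_size: int) -> Dict[str, float]:
    """Hypergeometric upper tail P(X >= k) for the observed gene overlap."""
    if universe_size < len(core_genes | mutated_genes):
        raise ValidationError("universe smaller than the union of the gene sets")
    k = len(core_genes & mutated_genes)
    p = hypergeom_tail(k, universe_size, len(mutated_genes), len(core_genes))
    return {"k": float(k), "p": p}


def detectable_universe(results: pd.DataFrame,
                        mode: Optional[str] = None) -> List[str]:
    """Event ids passing the detection filter (optionally one AS mode)."""
    sel = results["passes_detection"]
    if mode is not None:
        sel = sel & (results["mode"] == mode)
    return list(results.index[sel])


def per_mode_overlap_nulls(per_cancer: Mapping[str, pd.DataFrame],
                           core: Sequence[str],
                           n_replicates: int = 1000,
                           seed: int = 0) -> List[OverlapNull]:
    """Run the permutation null separately for each AS mode, as the figure does."""
    cancers = sorted(per_cancer)
    any_res = per_cancer[cancers[0]]
    modes = sorted(any_res["mode"].unique())
    core_set = set(core)
    out = []
    rng = np.random.default_rng(seed)
    for mode in modes:
        universe = {c: detectable_universe(per_cancer[c], mode) for c in cancers}
        sizes = {c: int((per_cancer[c]["significant"]
                         & (per_cancer[c]["mode"] == mode)).sum())
                 for c in cancers}
        observed = sum(1 for e in core_set
                       if any_res.loc[e, "mode"] == mode) if core_set else 0
        out.append(overlap_permutation_null(
            universe, sizes, observed, n_replicates=n_replicates,
            seed=int(rng.integers(2 ** 31)), mode=mode))
    return out
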