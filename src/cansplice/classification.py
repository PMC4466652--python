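"""PCA of core-event PSI vectors as a tumor/normal and subtype classifier.

Each sample is a vector of PSI values over the core cancer-specific events.
Missing PSI is mean-imputed per event (reported transparently), columns are
centered but not scaled (PSI already shares the [0, 1] scale), and the
decomposition is a plain SVD.  Component signs are fixed by making the
largest-magnitude loading of each component positive so outputs are
reproducible.  Separation of label groups on the first two components is
quantified with silhouette scores and centroid distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .io_formats import PsiMatrix, SampleMeta, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # events x components
    variance_fraction: np.ndarray   # per retained component
    all_variance_fraction: np.ndarray  # over every component (sums to 1)
    imputed_fraction: pd.Series     # per event, fraction of samples imputed


def pca_psi(psi: PsiMatrix, n_components: int = 2) -> PcaResult:
    """PCA of the samples-by-events PSI matrix with mean imputation."""
    data = psi.data
    n_events, n_samples = data.shape
    if n_samples < 2 or n_events < 2:
        raise ValidationError("PCA needs at least 2 samples and 2 events")

    n_missing = data.isna().sum(axis=1)
    usable = n_missing < n_samples
    if not usable.all():
        logger.warning("pca_psi: dropping %d events with no PSI values",
                       int((~usable).sum()))
        data = data[usable]
        n_missing = n_missing[usable]
    max_rank = min(data.shape[1], data.shape[0])
    if n_components > max_rank:
        raise ValidationError(
            f"n_components ({n_components}) exceeds min(dims) = {max_rank}")

    imputed_fraction = (n_missing / n_samples).rename("imputed_fraction")
    row_means = data.mean(axis=1)
    filled = data.T.fillna(row_means).to_numpy()      # samples x events
    centered = filled - filled.mean(axis=0, keepdims=True)

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(s.size):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0

    var = s ** 2
    all_frac = var / var.sum() if var.sum() > 0 else var
    scores = u[:, :n_components] * s[:n_components]
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=data.columns, columns=comp_names),
        loadings=pd.DataFrame(vt[:n_components].T, index=data.index,
                              columns=comp_names),
        variance_fraction=all_frac[:n_components],
        all_variance_fraction=all_frac,
        imputed_fraction=imputed_fraction,
    )


@dataclass
class SeparationReport:
    silhouette: float
    centroid_distances: pd.DataFrame
    labels_used: Tuple[str, ...]


def separation_report(scores: pd.DataFrame,
                      labels: Dict[str, str]) -> SeparationReport:
    """Silhouette and centroid distances of label groups on the first 2 PCs.

    ``labels`` maps sample_id -> label; samples without a label and labels
    with fewer than 2 samples are excluded (with a warning).
    """
    xy = scores.iloc[:, :2]
    lab = pd.Series({s: labels.get(s) for s in xy.index}).dropna()
    counts = lab.value_counts()
    keep = counts[counts >= 2].index
    if len(keep) < len(counts):
        logger.warning("separation_report: excluding singleton labels %s",
                       sorted(set(counts.index) - set(keep)))
    lab = lab[lab.isin(keep)]
    if lab.nunique() < 2:
        raise ValidationError("need at least 2 labels with >= 2 samples each")
    pts = xy.loc[lab.index].to_numpy()
    sil = float(silhouette_score(pts, lab.to_numpy()))

    cents = {g: pts[(lab == g).to_numpy()].mean(axis=0) for g in sorted(keep)}
    names = sorted(cents)
    dist = pd.DataFrame(
        [[float(np.linalg.norm(cents[a] - cents[b])) for b in names]
         for a in names],
        index=names, columns=names)
    return SeparationReport(silhouette=sil, centroid_distances=dist,
                            labels_used=tuple(names))
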