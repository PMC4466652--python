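"""Sequence-level characterization of cancer-specific skipped exons.

Covers four analyses: reading-frame phase of the alternative exon
(length mod 3, with a Fisher exact test for phase-0 enrichment), a
positional conservation meta-profile over fixed windows around the exon,
5-mer Z-score enrichment in exon-proximal windows against a control
background, and single-linkage clustering of enriched 5-mers into candidate
motifs with degenerate-consensus strings.

Window geometry defaults: 150-nt intronic flanks plus 50-nt exon ends for
the conservation profile; 200-nt intronic flanks plus the full exon for
motif counting.  Both are parameters — the biologically "right" width for
splicing-regulatory elements is not sharply defined.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AsEvent, ConservationTrack, ValidationError

logger = logging.getLogger(__name__)

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


# ---------------------------------------------------------------------------
# exon phase
# ---------------------------------------------------------------------------

def classify_phase(alt_length: int) -> int:
    """Reading-frame phase of an alternative region: its length mod 3."""
    if alt_length < 1:
        raise ValidationError(f"alt_length must be positive, got {alt_length}")
    return alt_length % 3


@dataclass
class PhaseTable:
    target_counts: Tuple[int, int, int]    # phase 0/1/2 in the target set
    control_counts: Tuple[int, int, int]
    fisher_p: float                        # one-sided, phase-0 enrichment in target

    @property
    def target_fractions(self) -> Tuple[float, float, float]:
        n = sum(self.target_counts)
        return tuple(c / n for c in self.target_counts)

    @property
    def control_fractions(self) -> Tuple[float, float, float]:
        n = sum(self.control_counts)
        return tuple(c / n for c in self.control_counts)


def fisher_exact_greater(table: Sequence[Sequence[int]]) -> float:
    """One-sided (enrichment) Fisher exact p for a 2x2 count table."""
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)


def phase_enrichment(target_events: Sequence[AsEvent],
                     control_events: Sequence[AsEvent]) -> PhaseTable:
    """One-sided Fisher exact test for phase-0 enrichment among target SEs."""
    for name, evs in (("target", target_events), ("control", control_events)):
        if not evs:
            raise ValidationError(f"{name} event set is empty")
        bad = [e.event_id for e in evs if e.mode != "SE"]
        if bad:
            raise ValidationError(
                f"phase analysis is defined for SE events only; non-SE in "
                f"{name}: {bad[:3]}")

    def counts(evs):
        phases = [classify_phase(e.alt_length) for e in evs]
        return tuple(phases.count(k) for k in (0, 1, 2))

    tc, cc = counts(target_events), counts(control_events)
    table = [[tc[0], sum(tc) - tc[0]], [cc[0], sum(cc) - cc[0]]]
    return PhaseTable(target_counts=tc, control_counts=cc,
                      fisher_p=fisher_exact_greater(table))


# ---------------------------------------------------------------------------
# conservation meta-profile
# ---------------------------------------------------------------------------

@dataclass
class ProfileWindows:
    upstream_intron: int = 150
    exon_edge: int = 50
    downstream_intron: int = 150


@dataclass
class ConservationProfile:
    upstream_intron: np.ndarray    # 5' intronic flank, transcript orientation
    exon_start: np.ndarray
    exon_end: np.ndarray
    downstream_intron: np.ndarray
    n_events: int

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.upstream_intron, self.exon_start,
                               self.exon_end, self.downstream_intron])


def event_conservation_windows(event: AsEvent, track: ConservationTrack,
                               windows: ProfileWindows
                               ) -> Optional[Tuple[np.ndarray, ...]]:
    """Per-event window scores in transcript orientation, or None if uncovered."""
    w = windows
    if event.alt_length < w.exon_edge:
        return None
    lo = event.alt_start - max(w.upstream_intron, w.downstream_intron)
    hi = event.alt_end + max(w.upstream_intron, w.downstream_intron)
    if lo < 0 or event.chrom not in track.chroms or hi > track.length(event.chrom):
        return None
    # genomic-orientation windows
    up_g = track.fetch(event.chrom, event.alt_start - w.upstream_intron,
                       event.alt_start)
    exon = track.fetch(event.chrom, event.alt_start, event.alt_end)
    down_g = track.fetch(event.chrom, event.alt_end,
                         event.alt_end + w.downstream_intron)
    if event.strand == "-":
        up_g, down_g = down_g[::-1], up_g[::-1]
        exon = exon[::-1]
    return (up_g, exon[:w.exon_edge], exon[-w.exon_edge:], down_g)


def conservation_profile(events: Sequence[AsEvent], track: ConservationTrack,
                         windows: Optional[ProfileWindows] = None
                         ) -> ConservationProfile:
    """Average per-position conservation over SE events, strand-aware."""
    windows = windows or ProfileWindows()
    parts = [[], [], [], []]
    skipped = 0
    for e in events:
        if e.mode != "SE":
            raise ValidationError(f"conservation profile expects SE events, "
                                  f"got {e.mode} for {e.event_id!r}")
        got = event_conservation_windows(e, track, windows)
        if got is None:
            skipped += 1
            continue
        for lst, arr in zip(parts, got):
            lst.append(arr)
    if skipped:
        logger.warning("conservation profile: skipped %d events not covered "
                       "by the track", skipped)
    if not parts[0]:
        raise ValidationError("no events covered by the conservation track")
    means = [np.vstack(p).mean(axis=0) for p in parts]
    return ConservationProfile(
        upstream_intron=means[0], exon_start=means[1], exon_end=means[2],
        downstream_intron=means[3], n_events=len(parts[0]),
    )


def mean_flank_conservation(events: Sequence[AsEvent], track: ConservationTrack,
                            windows: Optional[ProfileWindows] = None
                            ) -> pd.Series:
    """Per-event mean conservation over the two intronic flank windows."""
    windows = windows or ProfileWindows()
    out = {}
    for e in events:
        got = event_conservation_windows(e, track, windows)
        if got is None:
            continue
        out[e.event_id] = float(np.concatenate([got[0], got[3]]).mean())
    return pd.Series(out, name="mean_flank_conservation")


# ---------------------------------------------------------------------------
# k-mer Z-scores
# ---------------------------------------------------------------------------

@dataclass
class MotifResult:
    kmer: str
    observed_count: int
    expected_count: float
    z_score: float                 # NaN when the expected count is 0
    cluster_id: Optional[int] = None


def count_kmers(seqs: Iterable[str], k: int) -> Tuple[Dict[str, int], int]:
    """Sliding-window k-mer counts (stride 1, overlaps counted).

    Windows containing a non-ACGT character are skipped but still add to
    nothing; the returned total is the number of counted (valid) windows.
    """
    counts: Dict[str, int] = {}
    total = 0
    valid = set("ACGT")
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            word = seq[i:i + k]
            if set(word) <= valid:
                counts[word] = counts.get(word, 0) + 1
                total += 1
    return counts, total


def kmer_zscores(target_seqs: Sequence[str], background_seqs: Sequence[str],
                 k: int = 5) -> List[MotifResult]:
    """Z-score of each k-mer's target count against background frequencies.

    With p_w the background frequency of word w and N the total number of
    valid target windows: E_w = p_w * N and
    Z_w = (O_w - E_w) / sqrt(E_w * (1 - p_w))  (binomial approximation).
    """
    if not target_seqs or not background_seqs:
        raise ValidationError("target and background sequence sets must be non-empty")
    tgt, n_tgt = count_kmers(target_seqs, k)
    bg, n_bg = count_kmers(background_seqs, k)
    if n_tgt == 0 or n_bg == 0:
        raise ValidationError("no valid k-mer windows in target or background")
    out = []
    for word in ("".join(t) for t in itertools.product("ACGT", repeat=k)):
        o = tgt.get(word, 0)
        p = bg.get(word, 0) / n_bg
        e = p * n_tgt
        z = (o - e) / np.sqrt(e * (1 - p)) if e > 0 else float("nan")
        out.append(MotifResult(kmer=word, observed_count=o,
                               expected_count=float(e), z_score=float(z)))
    return out


# ---------------------------------------------------------------------------
# motif clustering
# ---------------------------------------------------------------------------

def kmers_link(a: str, b: str, min_match: int = 4,
               offsets: Sequence[int] = (-1, 0, 1)) -> bool:
    """Two k-mers link if some offset aligns >= min_match identical positions."""
    for off in offsets:
        matches = sum(1 for i in range(len(a))
                      if 0 <= i + off < len(b) and a[i] == b[i + off])
        if matches >= min_match:
            return True
    return False


def cluster_kmers(hits: Sequence[MotifResult],
                  z_threshold: float = 2.5) -> List[Dict[str, object]]:
    """Single-linkage clustering of enriched k-mers; per-cluster consensus.

    Only hits with Z > ``z_threshold`` enter the clustering.  Consensus is
    the per-position majority over members aligned at their best offset to
    the cluster's highest-Z seed, with IUPAC degenerate codes on ties.
    """
    enriched = [h for h in hits
                if np.isfinite(h.z_score) and h.z_score > z_threshold]
    if not enriched:
        raise ValidationError("no k-mers above the Z threshold")
    n = len(enriched)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if kmers_link(enriched[i].kmer, enriched[j].kmer):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for cid, members in enumerate(sorted(groups.values(),
                                         key=lambda ms: -max(enriched[m].z_score
                                                             for m in ms))):
        hits_m = sorted((enriched[m] for m in members),
                        key=lambda h: -h.z_score)
        for h in hits_m:
            h.cluster_id = cid
        clusters.append({
            "cluster_id": cid,
            "members": [h.kmer for h in hits_m],
            "max_z": float(hits_m[0].z_score),
            "consensus": _consensus([h.kmer for h in hits_m]),
        })
    return clusters


def _best_offset(seed: str, other: str, offsets=(-1, 0, 1)) -> int:
    best, best_off = -1, 0
    for off in offsets:
        matches = sum(1 for i in range(len(seed))
                      if 0 <= i + off < len(other) and seed[i] == other[i + off])
        if matches > best:
            best, best_off = matches, off
    return best_off


def _consensus(kmers: List[str]) -> str:
    """Majority consensus over members aligned to the first (seed) k-mer."""
    seed = kmers[0]
    k = len(seed)
    columns: List[List[str]] = [[] for _ in range(k)]
    for word in kmers:
        off = 0 if word == seed else _best_offset(seed, word)
        for i in range(k):
            if 0 <= i + off < k:
                columns[i].append(word[i + off])
    out = []
    for col in columns:
        counts = pd.Series(col).value_counts()
        top = counts[counts == counts.max()].index
        out.append(_IUPAC[frozenset(top)] if len(top) > 1 else top[0])
    return "".join(out)
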