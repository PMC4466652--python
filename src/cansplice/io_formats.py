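"""Readers, writers and validated containers for every tabular and sequence format.

All tables are plain TSV (tab-separated, no quoting, UTF-8, header row
required).  Missing PSI values are written as the literal string ``NA`` and
held internally as NaN — never as a sentinel number.  Genomic coordinates are
0-based half-open (BED convention); sequence extraction for minus-strand
events returns the plus-strand interval reverse-complemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PathLike = Union[str, Path]

AS_MODES = ("SE", "RI", "A3SS", "A5SS")

_NA = "NA"
_FLOAT_FMT = "%.6g"


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class PsiMatrix:
    """AS events × samples matrix of PSI values in [0, 1], NaN = missing."""

    data: pd.DataFrame  # index: event_id, columns: sample_id, dtype float

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate event id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        vals = df.to_numpy(dtype=float)
        bad = np.where((vals < 0) | (vals > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"PSI value {vals[i, j]} outside [0, 1] for event "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )
        self.data = df.astype(float)

    @property
    def event_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_events(self, event_ids: Sequence[str]) -> "PsiMatrix":
        return PsiMatrix(self.data.loc[list(event_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "PsiMatrix":
        return PsiMatrix(self.data[list(sample_ids)])


@dataclass
class SampleMeta:
    """Annotation for one sample: cancer type, condition, optional extras."""

    sample_id: str
    cancer_type: str
    condition: str  # "tumor" | "normal"
    subtype: Optional[str] = None
    paired_sample_id: Optional[str] = None
    survival_days: Optional[float] = None
    survival_event: Optional[bool] = None

    def __post_init__(self) -> None:
        cond = self.condition.strip().lower()
        if cond not in ("tumor", "normal"):
            raise ValidationError(
                f"condition must be tumor or normal, got {self.condition!r}"
            )
        self.condition = cond
        if (self.survival_days is None) != (self.survival_event is None):
            raise ValidationError(
                f"sample {self.sample_id!r}: survival_days and survival_event "
                "must be present together"
            )
        if self.survival_days is not None and self.survival_days < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative survival_days"
            )


def validate_meta(meta: Sequence[SampleMeta]) -> None:
    """Cross-record checks: unique ids; pairing is condition-opposed, same cancer."""
    by_id = {}
    for m in meta:
        if m.sample_id in by_id:
            raise ValidationError(f"duplicate sample id {m.sample_id!r}")
        by_id[m.sample_id] = m
    for m in meta:
        if m.paired_sample_id is None:
            continue
        other = by_id.get(m.paired_sample_id)
        if other is None:
            raise ValidationError(
                f"sample {m.sample_id!r} paired with unknown sample "
                f"{m.paired_sample_id!r}"
            )
        if other.condition == m.condition or other.cancer_type != m.cancer_type:
            raise ValidationError(
                f"sample {m.sample_id!r}: pair {m.paired_sample_id!r} must have "
                "opposite condition and same cancer_type"
            )


@dataclass
class AsEvent:
    """One annotated alternative-splicing event.

    ``alt_start``/``alt_end`` delimit the alternative region (the cassette
    exon for SE, the retained intron for RI, the extended segment for
    A3SS/A5SS) in 0-based half-open coordinates.
    """

    event_id: str
    mode: str
    gene: str
    chrom: str
    strand: str
    alt_start: int
    alt_end: int
    alt_length: int = field(init=False)

    def __post_init__(self) -> None:
        if self.mode not in AS_MODES:
            raise ValidationError(
                f"event {self.event_id!r}: unknown AS mode {self.mode!r} "
                f"(expected one of {AS_MODES})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"event {self.event_id!r}: strand must be + or -, got {self.strand!r}"
            )
        if not self.alt_start < self.alt_end:
            raise ValidationError(
                f"event {self.event_id!r}: alt_start ({self.alt_start}) must be "
                f"< alt_end ({self.alt_end})"
            )
        self.alt_length = self.alt_end - self.alt_start


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of non-negative normalized expression."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValidationError("duplicate gene or sample ids in expression matrix")
        vals = df.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError("expression matrix contains missing values")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative expression {vals[i, j]} for gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        self.data = df.astype(float)

    @property
    def gene_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)


class ConservationTrack:
    """Per-base conservation scores in [0, 1] (phastCons-like), per chromosome.

    Coordinates are 0-based; lookups outside the covered range raise.
    """

    def __init__(self, scores: Mapping[str, np.ndarray]):
        self._scores: Dict[str, np.ndarray] = {}
        for chrom, arr in scores.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValidationError(f"track for {chrom!r} must be 1-D")
            if arr.size and ((arr < 0) | (arr > 1)).any():
                raise ValidationError(
                    f"conservation scores for {chrom!r} outside [0, 1]"
                )
            self._scores[chrom] = arr

    @property
    def chroms(self) -> List[str]:
        return list(self._scores)

    def length(self, chrom: str) -> int:
        return self._scores[chrom].size

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> np.ndarray:
        """Scores on [start, end); reversed for minus strand so index 0 is 5'."""
        if chrom not in self._scores:
            raise KeyError(f"chromosome {chrom!r} not in conservation track")
        arr = self._scores[chrom]
        if start < 0 or end > arr.size or start >= end:
            raise ValidationError(
                f"conservation lookup {chrom}:{start}-{end} outside covered "
                f"range [0, {arr.size})"
            )
        window = arr[start:end]
        return window[::-1].copy() if strand == "-" else window.copy()


# ---------------------------------------------------------------------------
# PSI matrix I/O
# ---------------------------------------------------------------------------

def read_psi_matrix(path: PathLike) -> PsiMatrix:
    """Read an events × samples PSI TSV; ``NA`` cells become missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA],
                     keep_default_na=False, dtype=str)
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric PSI cell in {path}: {exc}") from exc
    return PsiMatrix(df)


def write_psi_matrix(psi: PsiMatrix, path: PathLike) -> None:
    psi.data.to_csv(path, sep="\t", na_rep=_NA, index_label="event_id",
                    float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Event table I/O
# ---------------------------------------------------------------------------

_EVENT_COLS = ["event_id", "mode", "gene", "chrom", "strand", "alt_start", "alt_end"]


def read_event_table(path: PathLike) -> List[AsEvent]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _EVENT_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"event table {path} missing columns {missing}")
    events = []
    seen = set()
    for row in df.itertuples(index=False):
        if row.event_id in seen:
            raise ValidationError(f"duplicate event id {row.event_id!r}")
        seen.add(row.event_id)
        events.append(AsEvent(
            event_id=row.event_id, mode=row.mode, gene=row.gene,
            chrom=row.chrom, strand=row.strand,
            alt_start=int(row.alt_start), alt_end=int(row.alt_end),
        ))
    return events


def write_event_table(events: Sequence[AsEvent], path: PathLike) -> None:
    df = pd.DataFrame(
        [(e.event_id, e.mode, e.gene, e.chrom, e.strand, e.alt_start, e.alt_end)
         for e in events],
        columns=_EVENT_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample metadata I/O
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "cancer_type", "condition", "subtype",
              "paired_sample_id", "survival_days", "survival_event"]


def read_sample_meta(path: PathLike) -> List[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[_NA, ""],
                     keep_default_na=False)
    for col in ("sample_id", "cancer_type", "condition"):
        if col not in df.columns:
            raise ValidationError(f"sample metadata {path} missing column {col!r}")
    meta = []
    for row in df.itertuples(index=False):
        def opt(name):
            v = getattr(row, name, None)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else v

        days = opt("survival_days")
        ev = opt("survival_event")
        meta.append(SampleMeta(
            sample_id=row.sample_id,
            cancer_type=row.cancer_type,
            condition=row.condition,
            subtype=opt("subtype"),
            paired_sample_id=opt("paired_sample_id"),
            survival_days=None if days is None else float(days),
            survival_event=None if ev is None else _parse_bool(ev),
        ))
    validate_meta(meta)
    return meta


def _parse_bool(s: str) -> bool:
    s = str(s).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ValidationError(f"cannot parse boolean value {s!r}")


def write_sample_meta(meta: Sequence[SampleMeta], path: PathLike) -> None:
    rows = []
    for m in meta:
        rows.append({
            "sample_id": m.sample_id,
            "cancer_type": m.cancer_type,
            "condition": m.condition,
            "subtype": m.subtype if m.subtype is not None else _NA,
            "paired_sample_id": m.paired_sample_id or _NA,
            "survival_days": _NA if m.survival_days is None else _FLOAT_FMT % m.survival_days,
            "survival_event": _NA if m.survival_event is None else int(m.survival_event),
        })
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)


def meta_frame(meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Convenience: metadata list as a DataFrame indexed by sample_id."""
    df = pd.DataFrame([vars(m) for m in meta]).set_index("sample_id")
    return df


# ---------------------------------------------------------------------------
# Expression I/O
# ---------------------------------------------------------------------------

def read_expression(path: PathLike) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: PathLike) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id",
                     float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Conservation (bedGraph)
# ---------------------------------------------------------------------------

def read_conservation(path: PathLike) -> ConservationTrack:
    """Read a bedGraph of per-base scores into dense per-chromosome arrays.

    Intervals may not overlap; uncovered gaps inside the covered range are an
    error (the track must be contiguous from 0 for each chromosome).
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "score"])
    tracks: Dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(dtype=int)
        ends = grp["end"].to_numpy(dtype=int)
        if starts[0] != 0 or (starts[1:] != ends[:-1]).any():
            raise ValidationError(
                f"bedGraph track for {chrom!r} is not contiguous from 0"
            )
        arr = np.empty(ends[-1], dtype=float)
        for s, e, v in zip(starts, ends, grp["score"].to_numpy(dtype=float)):
            arr[s:e] = v
        tracks[str(chrom)] = arr
    return ConservationTrack(tracks)


def write_conservation(track: ConservationTrack, path: PathLike) -> None:
    """Write run-length-encoded bedGraph (adjacent equal scores merged)."""
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in track.chroms:
            arr = track.fetch(chrom, 0, track.length(chrom))
            # run-length encode
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{_FLOAT_FMT % arr[s]}\n")


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path: PathLike) -> List[str]:
    """One gene symbol per line; blank lines ignored."""
    genes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line:
            genes.append(line)
    if len(genes) != len(set(genes)):
        raise ValidationError(f"duplicate genes in list {path}")
    return genes


def write_gene_list(genes: Iterable[str], path: PathLike) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")
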