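"""End-to-end orchestration: screen -> intersect -> downstream analyses.

``run_pipeline`` executes the stages in dependency order from a single
:class:`RunConfig`, writes each stage's outputs as TSV/JSON into the output
directory, and finishes with a ``summary.json`` recording seeds, per-stage
counts and wall times.  Stages are cached on a content hash of their inputs
and parameters, so re-runs with unchanged inputs skip completed work (the
correlation screen is the slow stage).  Optional analyses degrade
gracefully: stages whose inputs are absent (no expression matrix, no
survival annotation, no sequences) are skipped with a logged reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .classification import pca_psi, separation_report
from .correlation_screen import ScreenThresholds, correlation_screen
from .cross_cancer import (
    direction_consistency,
    intersect_significant,
    mutated_gene_overlap,
    per_mode_overlap_nulls,
)
from .diff_splicing import (
    ScreenParams,
    direction_tally,
    expression_change_fraction,
    screen_events,
)
from .io_formats import (
    PsiMatrix,
    ValidationError,
    meta_frame,
    read_conservation,
    read_event_table,
    read_expression,
    read_fasta,
    read_gene_list,
    read_psi_matrix,
    read_sample_meta,
)
from .seq_features import (
    ProfileWindows,
    cluster_kmers,
    conservation_profile,
    kmer_zscores,
    phase_enrichment,
)
from .survival import SurvivalScreenParams, survival_screen
from .variability import compare_variability, matched_control_sample, psi_sd

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    psi: Dict[str, str]                 # cancer -> PSI TSV path
    meta: str
    events: str
    out_dir: str
    seed: int
    expression: Optional[str] = None
    fasta: Optional[str] = None
    conservation: Optional[str] = None
    mutated_genes: Optional[str] = None
    gene_universe_size: Optional[int] = None
    screen: ScreenParams = field(default_factory=ScreenParams)
    n_replicates: int = 1000
    profile_windows: ProfileWindows = field(default_factory=ProfileWindows)
    motif_k: int = 5
    motif_z_threshold: float = 2.5
    variability_bins: int = 20
    pca_components: int = 5
    survival: SurvivalScreenParams = field(default_factory=SurvivalScreenParams)
    correlation: ScreenThresholds = field(default_factory=ScreenThresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        for key, sub in (("screen", ScreenParams),
                         ("profile_windows", ProfileWindows),
                         ("survival", SurvivalScreenParams),
                         ("correlation", ScreenThresholds)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def input_paths(self) -> List[str]:
        paths = list(self.psi.values()) + [self.meta, self.events]
        for p in (self.expression, self.fasta, self.conservation,
                  self.mutated_genes):
            if p:
                paths.append(p)
        return paths


def _hash_inputs(paths: List[str], params: object) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(Path(p).read_bytes())
    h.update(repr(params).encode())
    return h.hexdigest()[:16]


class _StageCache:
    def __init__(self, out_dir: Path):
        self.path = out_dir / ".stage_cache.json"
        self.state = {}
        if self.path.exists():
            try:
                self.state = json.loads(self.path.read_text())
            except json.JSONDecodeError:
                self.state = {}

    def fresh(self, stage: str, key: str, outputs: List[Path]) -> bool:
        return (self.state.get(stage) == key
                and all(p.exists() for p in outputs))

    def record(self, stage: str, key: str) -> None:
        self.state[stage] = key
        self.path.write_text(json.dumps(self.state, indent=1))


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_jsonable),
                    encoding="utf-8")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, pd.DataFrame):
        return o.to_dict()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run every applicable stage; returns the run summary (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = _StageCache(out)
    t0 = time.time()
    summary: Dict[str, object] = {
        "version": __version__, "seed": config.seed, "stages": {}}

    meta = read_sample_meta(config.meta)
    events = read_event_table(config.events)
    psi = {c: read_psi_matrix(p) for c, p in config.psi.items()}
    cancers = sorted(psi)
    shared_events = set(psi[cancers[0]].event_ids)
    for c in cancers[1:]:
        if set(psi[c].event_ids) != shared_events:
            raise ValidationError("per-cancer PSI matrices must share one "
                                  "event universe")

    def stage(name, fn, inputs, outputs):
        key = _hash_inputs(inputs, (name, _param_repr(config)))
        outs = [out / o for o in outputs]
        t = time.time()
        if cache.fresh(name, key, outs):
            logger.info("stage %s: cached, skipping", name)
            summary["stages"][name] = {"cached": True}
            return None
        try:
            info = fn()
        except Exception as exc:   # annotate and abort, partial outputs kept
            raise PipelineError(name, exc) from exc
        cache.record(name, key)
        info = info or {}
        info["seconds"] = round(time.time() - t, 2)
        summary["stages"][name] = info
        logger.info("stage %s: %s", name, info)
        return info

    # ---- screen ----------------------------------------------------------
    results: Dict[str, pd.DataFrame] = {}

    def do_screen():
        counts = {}
        for c in cancers:
            res = screen_events(psi[c], meta, config.screen, events)
            res.to_csv(out / f"diff_{c}.tsv", sep="\t")
            direction_tally(res).to_csv(out / f"direction_{c}.tsv", sep="\t")
            results[c] = res
            counts[c] = int(res["significant"].sum())
        return {"n_significant": counts}

    stage("screen", do_screen, config.input_paths(),
          [f"diff_{c}.tsv" for c in cancers])
    if not results:   # cached: reload
        for c in cancers:
            results[c] = pd.read_csv(out / f"diff_{c}.tsv", sep="\t",
                                     index_col=0)

    # ---- intersect -------------------------------------------------------
    core: List[str] = []

    def do_intersect():
        venn, core_ids = intersect_significant(results)
        core.extend(core_ids)
        venn.to_csv(out / "venn.tsv", sep="\t", index=False)
        Path(out / "core_events.txt").write_text(
            "".join(f"{e}\n" for e in core_ids))
        nulls = per_mode_overlap_nulls(results, core_ids,
                                       n_replicates=config.n_replicates,
                                       seed=config.seed)
        _write_json([dataclasses.asdict(n) for n in nulls], out / "overlap_null.json")
        rep = direction_consistency(core_ids, results)
        _write_json({"n_core_events": rep.n_core_events,
                     "n_consistent": rep.n_consistent,
                     "fraction_consistent": rep.fraction_consistent},
                    out / "consistency.json")
        info = {"n_core": len(core_ids),
                "fraction_consistent": rep.fraction_consistent}
        if config.mutated_genes:
            mut = set(read_gene_list(config.mutated_genes))
            core_genes = {e.gene for e in events if e.event_id in set(core_ids)}
            universe = config.gene_universe_size or len({e.gene for e in events})
            ov = mutated_gene_overlap(core_genes, mut, universe)
            _write_json(ov, out / "mutated_overlap.json")
            info["mutated_overlap_p"] = ov["p"]
        return info

    stage("intersect", do_intersect, config.input_paths(),
          ["core_events.txt", "venn.tsv", "overlap_null.json"])
    if not core:
        core.extend((out / "core_events.txt").read_text().split())

    events_by_id = {e.event_id: e for e in events}
    core_se = [e for e in core if events_by_id[e].mode == "SE"]
    all_se = [e.event_id for e in events if e.mode == "SE"]
    control_se = [e for e in all_se if e not in set(core_se)]

    # ---- sequence features ----------------------------------------------
    if config.fasta and config.conservation:
        def do_seqfeat():
            flanks = read_fasta(config.fasta)
            track = read_conservation(config.conservation)
            info = {}
            if core_se and control_se:
                pt = phase_enrichment([events_by_id[e] for e in core_se],
                                      [events_by_id[e] for e in control_se])
                _write_json({"target_counts": pt.target_counts,
                             "control_counts": pt.control_counts,
                             "fisher_p": pt.fisher_p}, out / "phase.json")
                info["phase_fisher_p"] = pt.fisher_p
                prof = conservation_profile(
                    [events_by_id[e] for e in core_se if e in track.chroms],
                    track, config.profile_windows)
                ctrl_prof = conservation_profile(
                    [events_by_id[e] for e in control_se if e in track.chroms],
                    track, config.profile_windows)
                pd.DataFrame({"core": prof.concatenated(),
                              "control": ctrl_prof.concatenated()}) \
                    .to_csv(out / "conservation_profile.tsv", sep="\t",
                            index_label="position")
                tgt_seqs = [flanks[e] for e in core_se if e in flanks]
                bg_seqs = [flanks[e] for e in control_se if e in flanks]
                motifs = kmer_zscores(tgt_seqs, bg_seqs, k=config.motif_k)
                pd.DataFrame([dataclasses.asdict(m) for m in motifs]) \
                    .to_csv(out / "motifs.tsv", sep="\t", index=False)
                try:
                    clusters = cluster_kmers(motifs, config.motif_z_threshold)
                    _write_json(clusters, out / "motif_clusters.json")
                    info["n_motif_clusters"] = len(clusters)
                except ValidationError:
                    info["n_motif_clusters"] = 0
            return info

        stage("seqfeat", do_seqfeat, config.input_paths(), ["motifs.tsv"])
    else:
        logger.info("stage seqfeat: skipped (no fasta/conservation input)")
        summary["stages"]["seqfeat"] = {"skipped": "no fasta/conservation input"}

    # ---- variability ------------------------------------------------------
    def do_variability():
        info = {}
        for c in cancers:
            pool = [e for e in results[c].index[results[c]["passes_detection"]]
                    if e not in set(core)]
            controls = matched_control_sample(
                core, pool, psi[c], meta, n_bins=config.variability_bins,
                seed=config.seed)
            sd = psi_sd(psi[c], meta, events=core)
            sd.to_csv(out / f"sd_{c}.tsv", sep="\t")
            tests = compare_variability(core, controls, psi[c], meta)
            _write_json(dataclasses.asdict(tests), out / f"variability_{c}.json")
            info[c] = tests.p_tumor_vs_normal_target
        return {"p_tumor_vs_normal": info}

    stage("variability", do_variability, config.input_paths(),
          [f"variability_{c}.json" for c in cancers])

    # ---- PCA --------------------------------------------------------------
    def do_pca():
        mf = meta_frame(meta)
        info = {}
        for c in cancers:
            res = pca_psi(psi[c].subset_events(core),
                          n_components=min(config.pca_components, len(core)))
            res.scores.to_csv(out / f"pca_scores_{c}.tsv", sep="\t")
            res.loadings.to_csv(out / f"pca_loadings_{c}.tsv", sep="\t")
            labels = mf.loc[res.scores.index, "condition"].to_dict()
            rep = separation_report(res.scores, labels)
            _write_json({"variance_fraction": res.variance_fraction,
                         "silhouette_condition": rep.silhouette},
                        out / f"pca_{c}.json")
            info[c] = rep.silhouette
        return {"condition_silhouette": info}

    stage("pca", do_pca, config.input_paths(),
          [f"pca_scores_{c}.tsv" for c in cancers])

    # ---- survival ----------------------------------------------------------
    have_survival = any(m.survival_days is not None for m in meta)
    if have_survival:
        def do_survival():
            info = {}
            for c in cancers:
                with_surv = [m for m in meta
                             if m.cancer_type == c and m.survival_days is not None]
                if len(with_surv) < config.survival.min_patients:
                    continue
                table, n_hits = survival_screen(psi[c], meta, core,
                                                config.survival)
                table.to_csv(out / f"survival_{c}.tsv", sep="\t")
                info[c] = n_hits
            return {"n_survival_hits": info}

        stage("survival", do_survival, config.input_paths(), [])
    else:
        logger.info("stage survival: skipped (no survival annotation)")
        summary["stages"]["survival"] = {"skipped": "no survival annotation"}

    # ---- correlation screen ------------------------------------------------
    if config.expression:
        def do_correlate():
            expr = read_expression(config.expression)
            combined = pd.concat([psi[c].data.loc[core] for c in cancers], axis=1)
            pairs, candidates = correlation_screen(
                PsiMatrix(combined), expr, config.correlation)
            pairs.to_csv(out / "correlated_pairs.tsv", sep="\t", index=False)
            candidates.to_csv(out / "regulator_candidates.tsv", sep="\t")
            # side analysis: expression change of significant-AS genes
            frac = {}
            for c in cancers:
                f, table = expression_change_fraction(
                    results[c], expr, events,
                    [m for m in meta if m.cancer_type == c])
                table.to_csv(out / f"expression_change_{c}.tsv", sep="\t")
                frac[c] = f
            _write_json(frac, out / "expression_unchanged_fraction.json")
            return {"n_pairs": len(pairs), "n_candidates": len(candidates),
                    "expression_unchanged_fraction": frac}

        stage("correlate", do_correlate, config.input_paths(),
              ["correlated_pairs.tsv", "regulator_candidates.tsv"])
    else:
        logger.info("stage correlate: skipped (no expression matrix)")
        summary["stages"]["correlate"] = {"skipped": "no expression matrix"}

    summary["wall_seconds"] = round(time.time() - t0, 2)
    _write_json(summary, out / "summary.json")
    return summary


def _param_repr(config: RunConfig) -> str:
    d = dataclasses.asdict(config)
    d.pop("out_dir", None)
    return repr(sorted(d.items()))
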