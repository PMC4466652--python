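"""Synthetic multi-cancer cohort generator with known planted structure.

Emulates the statistical structure of a TCGA-style splicing study: per-cancer
PSI matrices (beta-distributed, group-shifted for planted events, tumor
variance inflation, missingness), log-normal gene expression with regulator
genes coupled to planted splicing, survival times with PSI-linked hazard,
flanking sequences with a planted 5-mer motif, and a conservation track
elevated around planted exons.  Everything planted is recorded in
:class:`SyntheticTruth` so each pipeline stage can be scored against ground
truth.

PSI values follow Beta(mu*kappa, (1-mu)*kappa): ``mu`` is the group mean and
``kappa`` the concentration, so tumor variance inflation is a single divisor
on ``kappa``.  Planted events receive baseline means in the mid range
(0.15-0.85) so that the planted shift of ``delta_psi_planted`` survives the
[0.02, 0.98] clamp on group means; background events span (0.05, 0.95).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AsEvent,
    ConservationTrack,
    ExpressionMatrix,
    PsiMatrix,
    SampleMeta,
    ValidationError,
    write_conservation,
    write_event_table,
    write_expression,
    write_fasta,
    write_gene_list,
    write_psi_matrix,
    write_sample_meta,
)

_NUCS = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    seed: int
    n_cancers: int = 3
    n_tumor: int = 40
    n_normal: int = 40
    n_events_per_mode: Dict[str, int] = field(
        default_factory=lambda: {"SE": 2000, "RI": 300, "A3SS": 250, "A5SS": 250}
    )
    n_planted_shared: int = 150
    n_planted_specific: int = 50          # per cancer
    delta_psi_planted: float = 0.25
    psi_concentration: float = 100.0
    tumor_variance_inflation: float = 4.0
    missing_rate: float = 0.10
    consistent_direction_fraction: float = 0.85
    ri_positive_fraction: float = 0.80
    # expression / regulators
    n_genes: int = 2000
    n_planted_regulators: int = 20
    regulator_coupling: float = 0.6       # target population Spearman rho
    regulator_subset_size: int = 40       # planted events coupled per regulator
    # survival (tumor samples only)
    survival_coupled_events: int = 2
    survival_hazard_slope: float = 0.7    # log-hazard per tumor-PSI SD of a coupled event
    survival_median_days: float = 1500.0
    censoring_fraction: float = 0.30
    # subtype structure (first cancer only)
    n_subtypes: int = 2
    n_subtype_events: int = 50
    subtype_delta: float = 0.15
    # sequence / conservation
    planted_motif: str = "TGTGT"
    motif_extra_rate: float = 3.0         # Poisson mean of extra motif copies per flank pair
    flank_length: int = 200
    phase0_fraction_planted: float = 0.53
    phase0_fraction_background: float = 0.42

    def __post_init__(self) -> None:
        probs = {
            "missing_rate": (self.missing_rate, 0.0, 0.999999),
            "consistent_direction_fraction": (self.consistent_direction_fraction, 0, 1),
            "ri_positive_fraction": (self.ri_positive_fraction, 0, 1),
            "phase0_fraction_planted": (self.phase0_fraction_planted, 0, 1),
            "phase0_fraction_background": (self.phase0_fraction_background, 0, 1),
            "censoring_fraction": (self.censoring_fraction, 0, 0.999999),
        }
        for name, (v, lo, hi) in probs.items():
            if not lo <= v <= hi:
                raise ValidationError(f"{name}={v} outside [{lo}, {hi}]")
        if not 0 < self.delta_psi_planted <= 1:
            raise ValidationError("delta_psi_planted must be in (0, 1]")
        if self.psi_concentration <= 0 or self.tumor_variance_inflation < 1:
            raise ValidationError("bad concentration/inflation parameters")
        if not 0 < self.regulator_coupling < 1:
            raise ValidationError("regulator_coupling must be in (0, 1)")
        if (self.n_planted_regulators > 0
                and self.regulator_subset_size > max(self.n_planted_shared, 0)):
            raise ValidationError(
                f"regulator_subset_size ({self.regulator_subset_size}) exceeds "
                f"n_planted_shared ({self.n_planted_shared})"
            )
        total = sum(self.n_events_per_mode.values())
        if self.n_planted_shared + self.n_planted_specific * self.n_cancers > total:
            raise ValidationError("more planted events requested than events exist")
        if self.survival_coupled_events > self.n_planted_shared:
            raise ValidationError(
                "survival_coupled_events exceeds n_planted_shared"
            )
        if len(self.planted_motif) != 5 or set(self.planted_motif) - set("ACGT"):
            raise ValidationError("planted_motif must be a 5-mer over ACGT")

    @property
    def cancer_names(self) -> List[str]:
        return [f"CAN{i + 1}" for i in range(self.n_cancers)]


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator planted."""

    planted_shared: Dict[str, int]                # event_id -> direction (+1/-1)
    flipped_cancer: Dict[str, str]                # event_id -> cancer with flipped sign
    planted_specific: Dict[str, List[str]]        # cancer -> event ids
    planted_regulators: Dict[str, List[str]]      # regulator gene -> coupled event ids
    survival_coupled: List[str]
    subtype_events: List[str]
    planted_motif: str
    alt_length: Dict[str, int]
    tumor_mean: Dict[str, Dict[str, float]]       # cancer -> event_id -> planted tumor mean

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1),
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class CohortBundle:
    """Everything :func:`generate_cohort` produces, in memory."""

    config: SyntheticConfig
    psi: Dict[str, PsiMatrix]                     # cancer -> events x samples
    meta: List[SampleMeta]
    events: List[AsEvent]
    expression: ExpressionMatrix
    flanks: Dict[str, str]                        # SE event_id -> window sequence
    conservation: ConservationTrack
    truth: SyntheticTruth
    mutated_genes: List[str]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cancer, mat in self.psi.items():
            write_psi_matrix(mat, outdir / f"psi_{cancer}.tsv")
        write_sample_meta(self.meta, outdir / "meta.tsv")
        write_event_table(self.events, outdir / "events.tsv")
        write_expression(self.expression, outdir / "expression.tsv")
        write_fasta(self.flanks, outdir / "flanks.fa")
        write_conservation(self.conservation, outdir / "conservation.bedGraph")
        write_gene_list(self.mutated_genes, outdir / "mutated_genes.txt")
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _allocate_by_mode(n: int, sizes: Mapping[str, int]) -> Dict[str, int]:
    """Largest-remainder proportional allocation of n picks across modes."""
    total = sum(sizes.values())
    raw = {m: n * c / total for m, c in sizes.items()}
    alloc = {m: int(np.floor(v)) for m, v in raw.items()}
    leftover = n - sum(alloc.values())
    order = sorted(sizes, key=lambda m: raw[m] - alloc[m], reverse=True)
    for m in order[:leftover]:
        alloc[m] += 1
    for m, a in alloc.items():
        if a > sizes[m]:
            raise ValidationError(f"cannot plant {a} events in mode {m} "
                                  f"(only {sizes[m]} exist)")
    return alloc


def _draw_alt_length(rng: np.random.Generator, mode: str, phase0_p: float) -> int:
    if mode == "SE":
        lo, hi = 60, 240
    elif mode == "RI":
        lo, hi = 100, 500
    else:
        lo, hi = 12, 120
    length = int(rng.integers(lo, hi + 1))
    rem = length % 3
    if rng.random() < phase0_p:
        length -= rem                     # force phase 0
    elif rem == 0:
        length += int(rng.integers(1, 3))  # force phase 1 or 2
    return max(length, lo - 2)


def _calibrate_coupling(z: np.ndarray, noise: np.ndarray,
                        target: float, margin: float = 0.02) -> float:
    """Smallest mixing weight a for which Spearman(a*z + sqrt(1-a^2)*noise, z)
    reaches target + margin on the realized vectors.

    The coupled signal is a tumor/normal mixture (not Gaussian), so the
    bivariate-normal Pearson-Spearman relation under-delivers; a short
    bisection on the actual data guarantees the documented coupling.
    """
    from scipy import stats as _stats
    lo, hi = 0.0, 1.0
    for _ in range(25):
        a = 0.5 * (lo + hi)
        g = a * z + np.sqrt(1 - a * a) * noise
        if _stats.spearmanr(g, z).statistic < target + margin:
            lo = a
        else:
            hi = a
    return hi


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_cohort(config: SyntheticConfig) -> CohortBundle:
    """Generate the full synthetic cohort bundle. Deterministic given the seed."""
    ss = np.random.SeedSequence(config.seed)
    (ss_events, ss_psi, ss_expr, ss_surv, ss_seq, ss_cons, ss_mut) = ss.spawn(7)
    rng_e = np.random.default_rng(ss_events)

    cancers = config.cancer_names
    modes = [m for m, n in config.n_events_per_mode.items() if n > 0]

    # --- event annotation --------------------------------------------------
    n_reg = config.n_planted_regulators
    n_event_genes = max(config.n_genes - n_reg, 1)
    events: List[AsEvent] = []
    event_mode: Dict[str, str] = {}
    by_mode: Dict[str, List[str]] = {m: [] for m in modes}
    idx = 0
    for m in modes:
        for _ in range(config.n_events_per_mode[m]):
            eid = f"{m}_{idx:05d}"
            by_mode[m].append(eid)
            event_mode[eid] = m
            idx += 1

    # planted shared / specific selection, proportional to mode sizes
    shared_alloc = _allocate_by_mode(config.n_planted_shared,
                                     config.n_events_per_mode)
    planted_shared: List[str] = []
    remaining: Dict[str, List[str]] = {}
    for m in modes:
        ids = list(by_mode[m])
        rng_e.shuffle(ids)
        planted_shared.extend(ids[:shared_alloc[m]])
        remaining[m] = ids[shared_alloc[m]:]
    planted_shared.sort()

    planted_specific: Dict[str, List[str]] = {}
    spec_alloc = _allocate_by_mode(config.n_planted_specific,
                                   config.n_events_per_mode) \
        if config.n_planted_specific else {m: 0 for m in modes}
    for cancer in cancers:
        picks: List[str] = []
        for m in modes:
            take = min(spec_alloc[m], len(remaining[m]))
            picks.extend(remaining[m][:take])
            remaining[m] = remaining[m][take:]
        planted_specific[cancer] = sorted(picks)

    shared_set = set(planted_shared)

    # directions: RI biased toward intron retention (PSI up), others symmetric
    directions: Dict[str, int] = {}

    def _draw_direction(eid: str) -> int:
        p_up = config.ri_positive_fraction if event_mode[eid] == "RI" else 0.5
        return 1 if rng_e.random() < p_up else -1

    for eid in planted_shared:
        directions[eid] = _draw_direction(eid)
    for cancer in cancers:
        for eid in planted_specific[cancer]:
            directions[eid] = _draw_direction(eid)
    # a (1 - consistent_direction_fraction) slice gets one cancer sign-flipped
    flipped_cancer: Dict[str, str] = {}
    if config.n_cancers >= 2:
        n_flip = int(round((1 - config.consistent_direction_fraction)
                           * len(planted_shared)))
        flip_ids = rng_e.choice(planted_shared, size=n_flip, replace=False) \
            if n_flip else np.array([], dtype=object)
        for eid in flip_ids:
            flipped_cancer[str(eid)] = cancers[int(rng_e.integers(config.n_cancers))]

    # geometry: each event sits on its own contig, alt region flanked by
    # flank_length nt on either side
    alt_length: Dict[str, int] = {}
    for eid in sorted(event_mode):
        m = event_mode[eid]
        p0 = (config.phase0_fraction_planted if eid in shared_set
              else config.phase0_fraction_background)
        alt_length[eid] = _draw_alt_length(rng_e, m, p0)
    gene_of: Dict[str, str] = {}
    for i, eid in enumerate(sorted(event_mode)):
        gene_of[eid] = f"G{i % n_event_genes:04d}"
    fl = config.flank_length
    for eid in sorted(event_mode):
        events.append(AsEvent(
            event_id=eid, mode=event_mode[eid], gene=gene_of[eid],
            chrom=eid, strand="+" if rng_e.random() < 0.5 else "-",
            alt_start=fl, alt_end=fl + alt_length[eid],
        ))
    events_by_id = {e.event_id: e for e in events}
    all_event_ids = sorted(event_mode)
    n_events = len(all_event_ids)

    # --- samples -----------------------------------------------------------
    meta: List[SampleMeta] = []
    sample_cols: Dict[str, List[str]] = {}
    subtype_names = [f"SUB{i + 1}" for i in range(max(config.n_subtypes, 1))]
    for ci, cancer in enumerate(cancers):
        cols = []
        for i in range(config.n_normal):
            sid = f"{cancer}_N{i:03d}"
            cols.append(sid)
            meta.append(SampleMeta(sid, cancer, "normal"))
        for i in range(config.n_tumor):
            sid = f"{cancer}_T{i:03d}"
            cols.append(sid)
            subtype = None
            if ci == 0 and config.n_subtypes >= 2:
                subtype = subtype_names[i % config.n_subtypes]
            meta.append(SampleMeta(sid, cancer, "tumor", subtype=subtype))
        sample_cols[cancer] = cols

    # subtype-shifted events (first cancer, second subtype)
    subtype_events: List[str] = []
    if config.n_subtypes >= 2 and config.n_subtype_events > 0:
        k = min(config.n_subtype_events, len(planted_shared))
        subtype_events = sorted(
            str(e) for e in rng_e.choice(planted_shared, size=k, replace=False))

    # --- PSI ---------------------------------------------------------------
    rng_p = np.random.default_rng(ss_psi)
    kappa = config.psi_concentration
    kappa_t_planted = kappa / config.tumor_variance_inflation
    delta = config.delta_psi_planted
    psi: Dict[str, PsiMatrix] = {}
    clean_psi: Dict[str, np.ndarray] = {}   # pre-missingness, for couplings
    tumor_mean_truth: Dict[str, Dict[str, float]] = {c: {} for c in cancers}
    eid_index = {e: i for i, e in enumerate(all_event_ids)}

    for cancer in cancers:
        cols = sample_cols[cancer]
        is_tumor = np.array([c.split("_")[-1].startswith("T") for c in cols])
        subtype_b = np.array([
            m.subtype == subtype_names[1] if config.n_subtypes >= 2 else False
            for m in meta if m.sample_id in set(cols)
        ]) if cancer == cancers[0] else np.zeros(len(cols), bool)

        planted_here = shared_set | set(planted_specific[cancer])
        base_mu = rng_p.uniform(0.05, 0.95, size=n_events)
        planted_mask = np.array([e in planted_here for e in all_event_ids])
        base_mu[planted_mask] = rng_p.uniform(0.15, 0.85, size=planted_mask.sum())

        mu = np.tile(base_mu[:, None], (1, len(cols)))
        kap = np.full((n_events, len(cols)), kappa)
        for eid in sorted(planted_here):
            i = eid_index[eid]
            d = directions[eid]
            if eid in shared_set and flipped_cancer.get(eid) == cancer:
                d = -d
            tm = float(np.clip(base_mu[i] + d * delta, 0.02, 0.98))
            mu[i, is_tumor] = tm
            kap[i, is_tumor] = kappa_t_planted
            tumor_mean_truth[cancer][eid] = tm
        if cancer == cancers[0] and subtype_events:
            for eid in subtype_events:
                i = eid_index[eid]
                shift_mask = is_tumor & subtype_b
                mu[i, shift_mask] = np.clip(
                    mu[i, shift_mask] + config.subtype_delta, 0.02, 0.98)

        vals = rng_p.beta(mu * kap, (1 - mu) * kap)
        clean_psi[cancer] = vals.copy()
        if config.missing_rate > 0:
            mask = rng_p.random(vals.shape) < config.missing_rate
            vals = vals.copy()
            vals[mask] = np.nan
        psi[cancer] = PsiMatrix(pd.DataFrame(vals, index=all_event_ids,
                                             columns=cols))

    all_samples = [s for c in cancers for s in sample_cols[c]]
    clean_all = np.concatenate([clean_psi[c] for c in cancers], axis=1)

    # --- expression with planted regulators --------------------------------
    rng_x = np.random.default_rng(ss_expr)
    gene_ids = [f"G{i:04d}" for i in range(n_event_genes)] + \
               [f"REG{i:03d}" for i in range(n_reg)]
    gene_ids = gene_ids[:config.n_genes] if n_reg == 0 else gene_ids
    gene_mean = rng_x.uniform(3.0, 8.0, size=len(gene_ids))
    log2x = gene_mean[:, None] + rng_x.normal(size=(len(gene_ids), len(all_samples)))

    planted_regulators: Dict[str, List[str]] = {}
    if n_reg and planted_shared:
        for r in range(n_reg):
            gname = f"REG{r:03d}"
            subset = sorted(str(e) for e in rng_x.choice(
                planted_shared, size=config.regulator_subset_size, replace=False))
            planted_regulators[gname] = subset
            rows = [eid_index[e] for e in subset]
            signs = np.array([directions[e] for e in subset], dtype=float)
            # direction-aligned mean PSI of the coupled subset, standardized
            z = (signs[:, None] * clean_all[rows, :]).mean(axis=0)
            z = (z - z.mean()) / z.std()
            gi = len(gene_ids) - n_reg + r
            noise = rng_x.normal(size=len(all_samples))
            a = _calibrate_coupling(z, noise, config.regulator_coupling)
            log2x[gi] = gene_mean[gi] + a * z + np.sqrt(1 - a ** 2) * noise

    expression = ExpressionMatrix(pd.DataFrame(
        np.power(2.0, log2x), index=gene_ids, columns=all_samples))

    # --- survival (tumor samples, hazard linked to coupled events) ---------
    rng_s = np.random.default_rng(ss_surv)
    survival_coupled = planted_shared[:config.survival_coupled_events]
    coup_rows = [eid_index[e] for e in survival_coupled]
    coup_signs = np.array([directions[e] for e in survival_coupled], dtype=float) \
        if survival_coupled else np.zeros(0)
    base_rate = np.log(2.0) / config.survival_median_days
    cens_rate = base_rate * config.censoring_fraction / (1 - config.censoring_fraction)
    sample_pos = {s: j for j, s in enumerate(all_samples)}
    tumor_meta = [m for m in meta if m.condition == "tumor"]
    if tumor_meta:
        cols_idx = np.array([sample_pos[m.sample_id] for m in tumor_meta])
        if survival_coupled:
            aligned = coup_signs[:, None] * clean_all[np.ix_(coup_rows, cols_idx)]
            # standardize within each cancer: hazard tracks the deviation from
            # the cancer-specific baseline inclusion in units of that event's
            # tumor-PSI SD, so detectability does not depend on where the
            # event's mean sits in [0, 1]
            tum_cancer = np.array([m.cancer_type for m in tumor_meta])
            z = aligned.copy()
            for c in cancers:
                sel = tum_cancer == c
                if sel.any():
                    block = aligned[:, sel]
                    sd = block.std(axis=1, keepdims=True)
                    z[:, sel] = (block - block.mean(axis=1, keepdims=True)) \
                        / np.where(sd > 0, sd, 1.0)
            eta = config.survival_hazard_slope * z.sum(axis=0)
        else:
            eta = np.zeros(len(tumor_meta))
        t_death = rng_s.exponential(1.0 / (base_rate * np.exp(eta)))
        t_cens = rng_s.exponential(1.0 / cens_rate, size=len(tumor_meta))
        for m, td, tc in zip(tumor_meta, t_death, t_cens):
            m.survival_days = float(round(min(td, tc), 1))
            m.survival_event = bool(td <= tc)

    # --- flank sequences + planted motif (SE events) ------------------------
    rng_q = np.random.default_rng(ss_seq)
    motif = config.planted_motif
    flanks: Dict[str, str] = {}
    for eid in by_mode.get("SE", []):
        L = 2 * fl + alt_length[eid]
        seq = rng_q.choice(_NUCS, size=L)
        if eid in shared_set:
            n_extra = int(rng_q.poisson(config.motif_extra_rate))
            for _ in range(n_extra):
                # insert into one of the two intronic flanks
                if rng_q.random() < 0.5:
                    pos = int(rng_q.integers(0, fl - len(motif) + 1))
                else:
                    pos = int(rng_q.integers(L - fl, L - len(motif) + 1))
                seq[pos:pos + len(motif)] = list(motif)
        flanks[eid] = "".join(seq)

    # --- conservation track (one contig per SE event) ----------------------
    rng_c = np.random.default_rng(ss_cons)
    tracks: Dict[str, np.ndarray] = {}
    for eid in by_mode.get("SE", []):
        L = 2 * fl + alt_length[eid]
        scores = rng_c.beta(1.0, 3.0, size=L)
        if eid in shared_set:
            scores = rng_c.beta(5.0, 1.0, size=L)   # boosted toward 1
        tracks[eid] = np.round(scores, 4)
    conservation = ConservationTrack(tracks)

    # --- mutated-gene list: genes of some planted events + random genes ----
    rng_m = np.random.default_rng(ss_mut)
    mut: List[str] = []
    if planted_shared:
        chosen = rng_m.choice(planted_shared, size=min(10, len(planted_shared)),
                              replace=False)
        mut = sorted({gene_of[str(e)] for e in chosen})
    pool = [g for g in gene_ids[:n_event_genes] if g not in set(mut)]
    extra = rng_m.choice(pool, size=min(40, len(pool)), replace=False)
    mutated_genes = sorted(set(mut) | {str(g) for g in extra})

    truth = SyntheticTruth(
        planted_shared={e: directions[e] for e in planted_shared},
        flipped_cancer=flipped_cancer,
        planted_specific=planted_specific,
        planted_regulators=planted_regulators,
        survival_coupled=list(survival_coupled),
        subtype_events=subtype_events,
        planted_motif=motif,
        alt_length=alt_length,
        tumor_mean=tumor_mean_truth,
    )
    return CohortBundle(
        config=config, psi=psi, meta=meta, events=events,
        expression=expression, flanks=flanks, conservation=conservation,
        truth=truth, mutated_genes=mutated_genes,
    )
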