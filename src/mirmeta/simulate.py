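"""Synthetic corpora, expression, Ct and survival data with known truth.

The corpus generator emulates the structure of a published-literature
meta-analysis corpus: M studies with heterogeneous platform sizes,
variable list lengths, a planted up/down signature whose members rank
near the top of the studies that report them (normalized ranks drawn
from a Beta concentration distribution), and uniformly drawn filler
elsewhere — an exchangeable null, which is exactly what the rank
aggregation null assumes. The expression, Ct and survival generators
emulate a paired tumor/normal validation cohort, a qPCR plate, and an
exponential survival cohort with marker-dependent hazard.

All generators are pure functions of their parameters: the same seed
reproduces the same output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import Corpus, ListEntry, StudyRecord
from .validation import CT_COLUMNS, PairedExpression

__all__ = [
    "CorpusSimParams",
    "ExprSimParams",
    "CtSimParams",
    "SurvSimParams",
    "simulate_corpus",
    "null_corpus",
    "simulate_paired_expression",
    "simulate_ct",
    "simulate_survival",
]


def _universe(n: int) -> list[str]:
    return [f"miR-s{i:04d}" for i in range(n)]


@dataclass(frozen=True)
class CorpusSimParams:
    """Settings for a synthetic differential-expression-list corpus.

    Defaults mirror a 26-study liver-cancer literature corpus: platform
    sizes spanning 114 to 208,818 probes, list lengths from ten to about
    a hundred, sample sizes around a median of 21 pairs, and an
    etiology mix with an 8-study HBV-only subset plus one HCV study.
    The concentration parameters (a, b) = (1, 19) place planted
    normalized ranks in the top ~5% in expectation.
    """

    n_studies: int = 26
    universe_size: int = 500
    n_planted_up: int = 5
    n_planted_down: int = 8
    detect_prob: float = 0.5
    rank_concentration: tuple = (1.0, 19.0)
    list_length_range: tuple = (10, 100)
    platform_size_range: tuple = (114, 208_818)
    n_pairs_range: tuple = (8, 241)
    median_pairs: float = 21.0
    etiology_mix: dict = field(default_factory=lambda: {"HBV": 8, "HCV": 1, "mixed": 17})
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.detect_prob <= 1:
            raise ValueError("detect_prob must be in (0, 1]")
        a, b = self.rank_concentration
        if a >= b:
            raise ValueError("rank_concentration (a, b) needs a < b for top-concentration")
        if self.list_length_range[1] > self.universe_size:
            raise ValueError("maximum list length exceeds the miRNA universe")
        if self.n_planted_up + self.n_planted_down > self.universe_size:
            raise ValueError("planted sets exceed the universe")


def _etiology_tags(params: CorpusSimParams) -> list[frozenset]:
    """Deterministic tag assignment proportional to the etiology mix."""
    total = sum(params.etiology_mix.values())
    tags: list[frozenset] = []
    for tag, weight in params.etiology_mix.items():
        count = round(weight / total * params.n_studies)
        tags.extend([frozenset({tag})] * count)
    tags = tags[: params.n_studies]
    while len(tags) < params.n_studies:
        tags.append(frozenset({next(iter(params.etiology_mix))}))
    return tags


def _planted_ranks(rng, planted: list[str], length: int, detect_prob: float,
                   concentration: tuple) -> dict[str, int]:
    """Integer list positions for the planted miRNAs detected by a study."""
    a, b = concentration
    taken: dict[str, int] = {}
    used: set[int] = set()
    for name in planted:
        if rng.random() >= detect_prob:
            continue
        if len(used) == length:  # list full: further planted items cannot fit
            break
        u = rng.beta(a, b)
        rank = min(length, max(1, math.ceil(u * length)))
        while rank in used:  # collision: push down to the next free slot
            rank = rank + 1 if rank < length else 1
        taken[name] = rank
        used.add(rank)
    return taken


def _simulate_direction(rng, params: CorpusSimParams, planted: list[str],
                        forbidden: set[str], pool: list[str]) -> tuple:
    lo, hi = params.list_length_range
    length = int(rng.integers(lo, hi + 1))
    placed = _planted_ranks(rng, planted, length, params.detect_prob,
                            params.rank_concentration)
    n_fill = length - len(placed)
    candidates = [m for m in pool if m not in forbidden]
    fill = list(rng.choice(candidates, size=n_fill, replace=False))
    slots = [r for r in range(1, length + 1) if r not in set(placed.values())]
    entries: dict[int, str] = {rank: name for name, rank in placed.items()}
    for rank, name in zip(slots, fill):
        entries[rank] = name
    ordered = tuple(ListEntry(mirna=entries[r]) for r in sorted(entries))
    return ordered, placed


def simulate_corpus(params: CorpusSimParams) -> tuple[Corpus, dict]:
    """Generate a corpus with a planted signature and its ground truth.

    Planted miRNAs enter each study's list with probability
    ``detect_prob`` at a top-concentrated normalized rank; remaining
    slots are uniform draws (without replacement) from the non-planted
    universe, excluding names already used by the study's other
    direction. The truth record holds the planted sets and each study's
    realized planted ranks.
    """
    rng = np.random.default_rng(params.seed)
    universe = _universe(params.universe_size)
    planted_up = universe[: params.n_planted_up]
    planted_down = universe[params.n_planted_up:
                            params.n_planted_up + params.n_planted_down]
    null_pool = universe[params.n_planted_up + params.n_planted_down:]
    tags = _etiology_tags(params)
    sigma = 0.8  # log-scale spread reproducing an 8-241, median-21 cohort mix
    studies = []
    truth_ranks: dict[str, dict] = {}
    for i in range(params.n_studies):
        up_list, up_ranks = _simulate_direction(rng, params, planted_up, set(), null_pool)
        used = {e.mirna for e in up_list}
        down_list, down_ranks = _simulate_direction(rng, params, planted_down,
                                                    used, null_pool)
        lo_n, hi_n = params.n_pairs_range
        n_pairs = int(np.clip(round(params.median_pairs * math.exp(rng.normal(0.0, sigma))),
                              lo_n, hi_n))
        lo_p, hi_p = params.platform_size_range
        platform = int(round(math.exp(rng.uniform(math.log(lo_p), math.log(hi_p)))))
        sid = f"S{i + 1:02d}"
        studies.append(StudyRecord(study_id=sid, year=2006 + i % 8,
                                   etiology_tags=tags[i], n_pairs=n_pairs,
                                   platform_size=platform,
                                   up_list=up_list, down_list=down_list))
        truth_ranks[sid] = {"up": up_ranks, "down": down_ranks}
    truth = {
        "planted_up": set(planted_up),
        "planted_down": set(planted_down),
        "per_study_ranks": truth_ranks,
    }
    return Corpus(studies=tuple(studies), alias_version="synthetic"), truth


def null_corpus(params: CorpusSimParams) -> Corpus:
    """Exchangeable null corpus: the same generator with nothing planted."""
    from dataclasses import replace

    corpus, _ = simulate_corpus(replace(params, n_planted_up=0, n_planted_down=0))
    return corpus


# ---------------------------------------------------------------------------
# Expression / Ct / survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExprSimParams:
    """Paired tumor/normal expression generator settings.

    ``log2_fold_changes`` maps miRNA name -> planted tumor/normal log2
    fold (0 for nulls). Defaults emulate a small paired validation
    cohort of 11 patients.
    """

    n_pairs: int = 11
    log2_fold_changes: dict = field(default_factory=lambda: {"miR-x1": 1.0, "miR-x2": -1.0,
                                                             "miR-x3": 0.0})
    between_sd: float = 1.0
    noise_sd: float = 0.5
    missing_rate: float = 0.0
    baseline_log2_mean: float = 6.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.between_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def simulate_paired_expression(params: ExprSimParams) -> tuple[PairedExpression, dict]:
    """Log-normal paired expression with planted log2 fold changes.

    Normal-tissue values vary log-normally around per-patient, per-miRNA
    baselines; tumor = normal x 2^(fold + noise). Missing entries are
    masked (NaN) at ``missing_rate`` independently per cell.
    """
    rng = np.random.default_rng(params.seed)
    mirnas = list(params.log2_fold_changes)
    patients = [f"P{i + 1:03d}" for i in range(params.n_pairs)]
    shape = (params.n_pairs, len(mirnas))
    base = (params.baseline_log2_mean
            + rng.normal(0.0, params.between_sd, size=shape))
    folds = np.array([params.log2_fold_changes[m] for m in mirnas])
    normal_log2 = base + rng.normal(0.0, params.noise_sd, size=shape)
    tumor_log2 = base + folds + rng.normal(0.0, params.noise_sd, size=shape)
    tumor = pd.DataFrame(2.0 ** tumor_log2, index=patients, columns=mirnas)
    normal = pd.DataFrame(2.0 ** normal_log2, index=patients, columns=mirnas)
    if params.missing_rate > 0:
        tumor = tumor.mask(rng.random(shape) < params.missing_rate)
        normal = normal.mask(rng.random(shape) < params.missing_rate)
    truth = {"log2_fold_changes": dict(params.log2_fold_changes)}
    return PairedExpression(tumor=tumor, normal=normal), truth


@dataclass(frozen=True)
class CtSimParams:
    """qPCR Ct-table generator settings.

    ``log2_folds`` maps miRNA -> planted tumor/normal log2 fold change
    (so the planted ddCt is its negative and the true fold is
    2^log2_fold). The reference assay (e.g. U6) is constant per tissue.
    """

    n_pairs: int = 11
    log2_folds: dict = field(default_factory=lambda: {"miR-x1": 1.0, "miR-x2": -1.0})
    ref_ct: float = 18.0
    baseline_dct: float = 5.0
    noise_sd: float = 0.25
    seed: int | None = None


def simulate_ct(params: CtSimParams) -> tuple[pd.DataFrame, dict]:
    """Long-format Ct table with planted fold changes.

    Target Ct in tumor = reference + baseline dCt - log2 fold + noise;
    in normal tissue the fold term is absent. Ground-truth folds
    (2^log2_fold) are returned alongside.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for i in range(params.n_pairs):
        for mirna, lf in params.log2_folds.items():
            noise = rng.normal(0.0, params.noise_sd, size=2)
            rows.append({
                "patient": f"P{i + 1:03d}",
                "mirna": mirna,
                "ct_target_tumor": params.ref_ct + params.baseline_dct - lf + noise[0],
                "ct_target_normal": params.ref_ct + params.baseline_dct + noise[1],
                "ct_ref_tumor": params.ref_ct,
                "ct_ref_normal": params.ref_ct,
            })
    truth = {"folds": {m: 2.0 ** lf for m, lf in params.log2_folds.items()}}
    return pd.DataFrame(rows, columns=["patient", "mirna", *CT_COLUMNS]), truth


@dataclass(frozen=True)
class SurvSimParams:
    """Exponential survival generator with marker-dependent hazard."""

    n: int = 300
    baseline_hazard: float = 0.02  # events per month at marker 0
    log_hazard_ratio: float = math.log(2.0)  # per marker unit
    censoring_rate: float = 0.3
    marker_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")


def simulate_survival(params: SurvSimParams) -> tuple[pd.DataFrame, dict]:
    """Survival table (patient, time_months, event, marker) plus truth.

    Event times are exponential with hazard
    baseline x exp(logHR x marker); censoring is an independent
    exponential whose rate is tuned so that roughly ``censoring_rate``
    of baseline-hazard patients are censored.
    """
    rng = np.random.default_rng(params.seed)
    marker = rng.normal(0.0, params.marker_sd, size=params.n)
    hazard = params.baseline_hazard * np.exp(params.log_hazard_ratio * marker)
    event_time = rng.exponential(1.0 / hazard)
    if params.censoring_rate > 0:
        c_rate = params.baseline_hazard * params.censoring_rate / (1 - params.censoring_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=params.n)
    else:
        censor_time = np.full(params.n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    table = pd.DataFrame({
        "patient": [f"P{i + 1:04d}" for i in range(params.n)],
        "time_months": np.maximum(time, 1e-6),
        "event": event,
        "marker": marker,
    })
    truth = {"log_hazard_ratio": params.log_hazard_ratio}
    return table, truth
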