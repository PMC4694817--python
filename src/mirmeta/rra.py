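"""Robust rank aggregation (RRA) of ranked miRNA lists.

The method scores how consistently an item ranks near the top of M ranked
lists under the null hypothesis that the lists are uncorrelated. Each item's
normalized ranks r_(1) <= ... <= r_(M) are compared against order statistics
of M independent Uniform(0,1) draws: the k-th Beta score is
P(U_(k) <= r_(k)) = Beta(k, M-k+1).cdf(r_(k)), the rho score is the minimum
over k, and p = min(1, rho * M) is a Bonferroni-style bound on the
significance of that minimum.

Published DE lists are partial: most studies do not assay or report most
miRNAs. Two policies handle an item missing from some lists:

* ``"drop"`` (default, matching standard robust-rank-aggregation
  practice): the order statistics are computed over only the n lists
  that report the item, and the bound is p = min(1, rho * n). Under the
  null an unreported list carries no rank information, so conditioning
  on the reporting set keeps the p-value valid.
* ``"bottom"``: unreported entries count as worst-ranked (normalized
  rank 1.0) and the order statistics run over all M lists — a strictly
  more conservative reading that treats absence as evidence against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import DIRECTIONS, UP, Corpus

__all__ = [
    "RankMatrix",
    "build_rank_matrix",
    "build_combined_matrix",
    "beta_scores",
    "rho_score",
    "rra_pvalue",
    "mc_pvalue",
    "correct_pvalues",
    "loo_stability",
    "aggregate",
]


@dataclass
class RankMatrix:
    """miRNA x study matrix of normalized ranks for one direction.

    Reported cells hold rank/L in (0, 1] where L is that study's list
    length for the direction; unreported cells hold ``missing_value``
    (1.0 = worst possible rank). ``reported`` distinguishes a true rank of
    1.0 (last list position) from the fill.
    """

    direction: str
    mirnas: list
    studies: list
    values: np.ndarray
    reported: np.ndarray
    missing_value: float = 1.0

    def row(self, mirna: str) -> np.ndarray:
        return self.values[self.mirnas.index(mirna)]

    @property
    def n_studies(self) -> int:
        return len(self.studies)


def build_rank_matrix(corpus: Corpus, direction: str) -> RankMatrix:
    """Normalized rank matrix over all miRNAs reported in *direction*.

    Rows are the union of miRNAs appearing in the direction's list of at
    least one study (sorted for determinism); a reported cell is
    rank / list-length, an unreported cell is 1.0.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    names: set[str] = set()
    for s in corpus.studies:
        names.update(e.mirna for e in s.direction_list(direction))
    if not names:
        raise ValueError(f"no study reports any miRNA in direction {direction!r}")
    mirnas = sorted(names)
    index = {m: i for i, m in enumerate(mirnas)}
    studies = [s.study_id for s in corpus.studies]
    values = np.ones((len(mirnas), len(studies)))
    reported = np.zeros_like(values, dtype=bool)
    for j, s in enumerate(corpus.studies):
        entries = s.direction_list(direction)
        L = len(entries)
        for rank, e in enumerate(entries, start=1):
            i = index[e.mirna]
            values[i, j] = rank / L
            reported[i, j] = True
    return RankMatrix(direction=direction, mirnas=mirnas, studies=studies,
                      values=values, reported=reported, missing_value=1.0)


def build_combined_matrix(corpus: Corpus) -> RankMatrix:
    """Single matrix encoding both directions around the neutral value 0.5.

    An up-reported cell holds 1 - r (values above 0.5 mean upregulated), a
    down-reported cell holds r (below 0.5 means downregulated), and 0.5
    means the miRNA was not reported in that study. A miRNA reported in
    both directions by the same study is an inconsistency in the source
    lists and raises.
    """
    names: set[str] = set()
    for s in corpus.studies:
        names.update(e.mirna for e in s.up_list)
        names.update(e.mirna for e in s.down_list)
    if not names:
        raise ValueError("corpus reports no miRNA in either direction")
    mirnas = sorted(names)
    index = {m: i for i, m in enumerate(mirnas)}
    studies = [s.study_id for s in corpus.studies]
    values = np.full((len(mirnas), len(studies)), 0.5)
    reported = np.zeros_like(values, dtype=bool)
    for j, s in enumerate(corpus.studies):
        up_names = {e.mirna for e in s.up_list}
        both = up_names & {e.mirna for e in s.down_list}
        if both:
            raise ValueError(
                f"study {s.study_id!r} reports {sorted(both)[0]!r} both up and down"
            )
        for direction, sign in ((UP, True), ("down", False)):
            entries = s.direction_list(direction)
            L = len(entries)
            for rank, e in enumerate(entries, start=1):
                r = rank / L
                values[index[e.mirna], j] = 1.0 - r if sign else r
                reported[index[e.mirna], j] = True
    return RankMatrix(direction="combined", mirnas=mirnas, studies=studies,
                      values=values, reported=reported, missing_value=0.5)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def _check_unit(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise ValueError("rank vector must be non-empty")
    if np.any((r < 0) | (r > 1)) or np.any(np.isnan(r)):
        raise ValueError("normalized ranks must lie in [0, 1]")
    return r


def beta_scores(r) -> np.ndarray:
    """Order-statistic probabilities for a vector of normalized ranks.

    With r sorted ascending, the k-th output is the probability that the
    k-th smallest of M independent Uniform(0,1) variables is <= r_(k),
    i.e. the Beta(k, M-k+1) CDF at r_(k).
    """
    r = np.sort(_check_unit(r))
    m = r.size
    k = np.arange(1, m + 1)
    return stats.beta.cdf(r, k, m - k + 1)


def rho_score(r) -> float:
    """Minimum order-statistic probability: the RRA score of one item."""
    return float(beta_scores(r).min())


def _rho_rows(values: np.ndarray) -> np.ndarray:
    """Row-wise rho for a 2-D array of normalized ranks (vectorized)."""
    m = values.shape[1]
    k = np.arange(1, m + 1)
    sorted_rows = np.sort(values, axis=1)
    return stats.beta.cdf(sorted_rows, k, m - k + 1).min(axis=1)


def _row_stats(values: np.ndarray, reported: np.ndarray,
               missing_policy: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (rho, analytic p) under the chosen missing-entry policy.

    ``bottom``: rho over all M entries (fills included), p = rho * M.
    ``drop``: rho over the n reported entries only, p = rho * n; a row
    with n = 0 gets rho = p = 1.
    """
    m = values.shape[1]
    if missing_policy == "bottom":
        rho = _rho_rows(values)
        return rho, np.minimum(1.0, rho * m)
    if missing_policy != "drop":
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    work = np.where(reported, values, np.nan)
    work = np.sort(work, axis=1)  # NaNs sort last
    n = reported.sum(axis=1)
    k = np.arange(1, m + 1)[None, :]
    with np.errstate(invalid="ignore"):
        scores = stats.beta.cdf(work, k, n[:, None] - k + 1)
    scores = np.where(k <= n[:, None], scores, 1.0)
    scores = np.where(np.isnan(scores), 1.0, scores)
    rho = scores.min(axis=1)
    rho[n == 0] = 1.0
    return rho, np.minimum(1.0, rho * np.maximum(n, 1))


def rra_pvalue(rho: float, m: int) -> float:
    """Bonferroni bound over the M order statistics: p = min(1, rho * M)."""
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    return min(1.0, rho * m)


def mc_pvalue(matrix: RankMatrix, mirna: str, b: int = 10_000,
              seed=None, missing_policy: str = "drop") -> float:
    """Monte-Carlo p-value for one miRNA's aggregation score.

    Each replicate independently permutes every study column across rows
    (preserving each study's multiset of normalized ranks and its
    reported/unreported pattern) and recomputes the target row's
    analytic score; p = (1 + #{null score <= observed}) / (B + 1).
    Only the target row matters, so each replicate row is drawn
    directly: one uniform pick from each column's value multiset.
    """
    if b < 1:
        raise ValueError("B must be >= 1")
    i0 = matrix.mirnas.index(mirna)
    _, obs = _row_stats(matrix.values[i0:i0 + 1], matrix.reported[i0:i0 + 1],
                        missing_policy)
    rng = np.random.default_rng(seed)
    n_rows, n_cols = matrix.values.shape
    idx = rng.integers(0, n_rows, size=(b, n_cols))
    cols = np.arange(n_cols)
    _, null_p = _row_stats(matrix.values[idx, cols], matrix.reported[idx, cols],
                           missing_policy)
    return (1 + int(np.sum(null_p <= obs[0]))) / (b + 1)


def correct_pvalues(p, n_tests: int) -> np.ndarray:
    """Bonferroni correction: min(1, p * n_tests), elementwise.

    ``n_tests`` may exceed the vector length (e.g. a platform-universe
    test count) but not undercut it.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if n_tests < p.size:
        raise ValueError(f"n_tests ({n_tests}) smaller than number of p-values ({p.size})")
    return np.minimum(1.0, p * n_tests)


# ---------------------------------------------------------------------------
# Aggregation pipeline
# ---------------------------------------------------------------------------

def aggregate(corpus: Corpus, direction: str, p_mode: str = "analytic",
              b: int = 10_000, seed=None, n_tests: int | None = None,
              missing_policy: str = "drop") -> pd.DataFrame:
    """Full RRA table for one direction.

    Per miRNA: rho over its row of normalized ranks, a p-value (analytic
    bound or Monte-Carlo, per ``p_mode``), Bonferroni-corrected p with
    ``n_tests`` (default: number of aggregated miRNAs; set larger for a
    platform-universe correction), and the count of reporting studies.
    Sorted by corrected p ascending, ties by name.
    """
    matrix = build_rank_matrix(corpus, direction)
    rho, p = _row_stats(matrix.values, matrix.reported, missing_policy)
    if p_mode == "monte_carlo":
        child = np.random.SeedSequence(seed).spawn(len(matrix.mirnas))
        p = np.array([
            mc_pvalue(matrix, mirna, b=b, seed=child[i],
                      missing_policy=missing_policy)
            for i, mirna in enumerate(matrix.mirnas)
        ])
    elif p_mode != "analytic":
        raise ValueError(f"unknown p_mode {p_mode!r}")
    if n_tests is None:
        n_tests = len(matrix.mirnas)
    corrected = correct_pvalues(p, n_tests)
    out = pd.DataFrame(
        {
            "mirna": matrix.mirnas,
            "direction": direction,
            "rho": rho,
            "p_value": p,
            "corrected_p": corrected,
            "n_reporting": matrix.reported.sum(axis=1),
        }
    )
    return out.sort_values(["corrected_p", "mirna"], kind="stable").reset_index(drop=True)


def loo_stability(corpus: Corpus, direction: str, b: int = 10_000,
                  seed=None, exhaustive: bool = False,
                  missing_policy: str = "drop") -> pd.Series:
    """Leave-one-out stability of the analytic aggregation p-values.

    Each repetition drops one uniformly chosen study, re-runs the
    aggregation on the remaining M-1 lists, and records each miRNA's
    p-value (1.0 for a miRNA absent from the reduced corpus); the mean
    over B repetitions is returned. Because only M distinct sub-corpora
    exist, the M per-drop p-vectors are computed once and averaged with
    multinomial weights — identical in distribution to the naive loop.
    ``exhaustive=True`` drops each study exactly once (uniform mean).
    """
    m = len(corpus)
    if m < 2:
        raise ValueError("leave-one-out requires at least two studies")
    if b < 1:
        raise ValueError("B must be >= 1")
    matrix = build_rank_matrix(corpus, direction)
    n_rows = len(matrix.mirnas)
    per_drop = np.ones((m, n_rows))
    for j in range(m):
        keep = [c for c in range(m) if c != j]
        sub_vals = matrix.values[:, keep]
        sub_rep = matrix.reported[:, keep]
        present = sub_rep.any(axis=1)
        _, p = _row_stats(sub_vals[present], sub_rep[present], missing_policy)
        per_drop[j, present] = p
    if exhaustive:
        weights = np.full(m, 1.0 / m)
    else:
        rng = np.random.default_rng(seed)
        weights = rng.multinomial(b, np.full(m, 1.0 / m)) / b
    averaged = weights @ per_drop
    return pd.Series(averaged, index=matrix.mirnas, name="loo_mean_p")
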