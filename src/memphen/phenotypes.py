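"""Behavioural phenotypes from raw recall logs and PM tables.

Covers the scoring rule that turns typed free-recall responses into the
eight performance measures, classical emotional-contrast phenotypes
(e.g. negative-minus-neutral recall), principal component analysis of the
PM table, and a Monte-Carlo Lilliefors normality screen that decides
whether downstream association should be rank-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import edlib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .task_model import PerformanceMeasures, TaskDesign, WordTrace

__all__ = [
    "RecallLog",
    "PCAResult",
    "score_recall",
    "match_responses",
    "compute_performance_measures",
    "emotional_contrast",
    "pca_performance",
    "normality_screen",
    "log_from_traces",
]

IMMEDIATE = "immediate"
DELAYED = "delayed"


@dataclass(frozen=True)
class RecallLog:
    """Raw recall record of one subject.

    ``study_list`` holds (word, valence, series) triples;
    ``responses`` maps a phase to typed responses — per-series lists for
    the immediate phase, one pooled list for the delayed phase.
    """

    subject_id: str
    study_list: tuple[tuple[str, str, int], ...]
    immediate_responses: dict[int, tuple[str, ...]]
    delayed_responses: tuple[str, ...]


@dataclass(frozen=True)
class PCAResult:
    """PCA of the cohort PM table: orthonormal loadings (8 x k), variance
    fractions summing to 1 over all 8 components, and subject scores."""

    loadings: np.ndarray
    variance_fractions: np.ndarray
    scores: np.ndarray


def _distance(a: str, b: str, metric: str) -> int:
    if metric == "levenshtein":
        return edlib.align(a, b, task="distance")["editDistance"]
    if metric == "damerau":
        return _damerau(a, b)
    raise ValueError(f"unknown typo metric {metric!r}")


def _damerau(a: str, b: str) -> int:
    # restricted Damerau-Levenshtein (adjacent transposition costs 1)
    la, lb = len(a), len(b)
    d = np.zeros((la + 1, lb + 1), dtype=int)
    d[:, 0] = np.arange(la + 1)
    d[0, :] = np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i, j] = min(d[i - 1, j] + 1, d[i, j - 1] + 1, d[i - 1, j - 1] + cost)
            if (i > 1 and j > 1 and a[i - 1] == b[j - 2]
                    and a[i - 2] == b[j - 1]):
                d[i, j] = min(d[i, j], d[i - 2, j - 2] + 1)
    return int(d[la, lb])


def score_recall(
    target_words: Sequence[str],
    response: str,
    lexicon: Iterable[str] = (),
    metric: Literal["levenshtein", "damerau"] = "levenshtein",
) -> str | None:
    """Match one typed response against the study targets.

    A response matches a target iff it is spelled exactly, or lies at edit
    distance 1 from it *and* is not itself a different valid word of the
    lexicon (study list plus any supplied dictionary) — a single-letter
    typo must not turn the response into another real word.  Returns the
    matched target or ``None``.  Inputs are lowercase-normalised.
    """
    response = response.strip().lower()
    if not response:
        return None
    targets = [t.strip().lower() for t in target_words]
    if response in targets:
        return targets[targets.index(response)]
    valid_words = set(targets) | {w.strip().lower() for w in lexicon}
    if response in valid_words:
        return None  # a different valid word, not a typo
    for t in targets:
        if _distance(response, t, metric) == 1:
            return t
    return None


def match_responses(
    target_words: Sequence[str],
    responses: Sequence[str],
    lexicon: Iterable[str] = (),
    metric: Literal["levenshtein", "damerau"] = "levenshtein",
) -> tuple[list[str], int]:
    """Match a batch of responses; each target is credited at most once.

    Returns (matched targets, number of confabulative errors).  Duplicate
    responses hitting an already-matched target count as errors.
    """
    matched: list[str] = []
    errors = 0
    for resp in responses:
        hit = score_recall(target_words, resp, lexicon, metric)
        if hit is not None and hit not in matched:
            matched.append(hit)
        else:
            errors += 1
    return matched, errors


def compute_performance_measures(
    log: RecallLog,
    design: TaskDesign | None = None,
    lexicon: Iterable[str] = (),
) -> PerformanceMeasures:
    """Score a recall log into the eight performance measures.

    Immediate responses are matched within their own series (recall was
    taken after each series); delayed responses against the whole list.
    """
    design = design or TaskDesign()
    valence_of = {w: v for (w, v, _) in log.study_list}
    words_by_series: dict[int, list[str]] = {}
    for w, _, srs in log.study_list:
        words_by_series.setdefault(srs, []).append(w)
    full_lexicon = set(lexicon) | set(valence_of)

    imm_correct: dict[str, int] = {"positive": 0, "negative": 0, "neutral": 0}
    imm_errors = 0
    for srs, responses in log.immediate_responses.items():
        if srs not in words_by_series:
            raise ValueError(f"log {log.subject_id!r}: unknown series {srs}")
        matched, errs = match_responses(words_by_series[srs], responses, full_lexicon)
        imm_errors += errs
        for w in matched:
            imm_correct[valence_of[w]] += 1

    all_words = [w for (w, _, _) in log.study_list]
    del_matched, del_errors = match_responses(all_words, log.delayed_responses,
                                              full_lexicon)
    del_correct: dict[str, int] = {"positive": 0, "negative": 0, "neutral": 0}
    for w in del_matched:
        del_correct[valence_of[w]] += 1

    pms = PerformanceMeasures(
        pm1=imm_correct["positive"], pm2=imm_correct["negative"],
        pm3=imm_correct["neutral"], pm4=imm_errors,
        pm5=del_correct["positive"], pm6=del_correct["negative"],
        pm7=del_correct["neutral"], pm8=del_errors,
    )
    pms.validate(design)
    return pms


def log_from_traces(
    subject_id: str,
    traces: Sequence[WordTrace],
    error_prefix: str = "xq",
) -> RecallLog:
    """Synthesise the recall log implied by simulated word traces.

    Correct recalls reproduce the studied word; each confabulative error
    becomes a token guaranteed to be neither a study word nor within one
    edit of any study word, so rescoring the log reproduces the
    simulator's PM vector exactly.
    """
    study = tuple((t.word, t.valence, t.series) for t in traces)
    imm: dict[int, list[str]] = {t.series: [] for t in traces}
    delayed: list[str] = []
    err = 0
    for t in traces:
        if t.recalled_immediate:
            imm[t.series].append(t.word)
        elif t.errored_immediate:
            err += 1
            imm[t.series].append(f"{error_prefix}{err:03d}zzz")
        if t.recalled_delayed:
            delayed.append(t.word)
        elif t.errored_delayed:
            err += 1
            delayed.append(f"{error_prefix}{err:03d}zzz")
    return RecallLog(
        subject_id=subject_id,
        study_list=study,
        immediate_responses={k: tuple(v) for k, v in imm.items()},
        delayed_responses=tuple(delayed),
    )


def emotional_contrast(values: dict[str, float], valence_a: str,
                       valence_b: str) -> float:
    """Recall difference between two valence categories (counts or
    proportions, whichever the caller supplies)."""
    for v in (valence_a, valence_b):
        if v not in values:
            raise KeyError(f"valence {v!r} not present")
    return float(values[valence_a] - values[valence_b])


def pca_performance(pm_table: np.ndarray | pd.DataFrame,
                    n_components: int | None = None) -> PCAResult:
    """Correlation-matrix PCA of the subjects x 8 PM table.

    PMs are z-scored first since they mix counts on different scales; a
    variance floor keeps constant columns finite (with a warning).
    Components are ordered by explained variance.
    """
    arr = np.asarray(pm_table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 8:
        raise ValueError("PM table must be subjects x 8")
    if arr.shape[0] < 9:
        raise ValueError("at least 9 subjects required for an 8-PM PCA")
    if not np.all(np.isfinite(arr)):
        raise ValueError("PM table contains non-finite values")
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        import warnings

        warnings.warn("constant PM column; variance floored for scaling")
        sd = np.where(sd == 0, 1.0, sd)
    z = (arr - arr.mean(axis=0)) / sd
    k = n_components or 8
    pca = PCA(n_components=8, svd_solver="full")
    scores = pca.fit_transform(z)
    return PCAResult(
        loadings=pca.components_.T[:, :k],
        variance_fractions=pca.explained_variance_ratio_[:k],
        scores=scores[:, :k],
    )


def _ks_stats(z: np.ndarray) -> np.ndarray:
    """Row-wise Lilliefors KS statistics of standardised samples."""
    z = np.sort(z, axis=1)
    n = z.shape[1]
    mean = z.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, ddof=1, keepdims=True)
    from scipy.stats import norm

    cdf = norm.cdf((z - mean) / sd)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d_plus = np.max(grid_hi[None, :] - cdf, axis=1)
    d_minus = np.max(cdf - grid_lo[None, :], axis=1)
    return np.maximum(d_plus, d_minus)


def normality_screen(
    values: Sequence[float],
    n_resamples: int = 10000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> tuple[float, str]:
    """Lilliefors normality test with a seeded Monte-Carlo null.

    The KS statistic against a normal law with estimated mean and SD is
    compared with its null distribution obtained from ``n_resamples``
    Gaussian samples of the same size.  Returns (p-value,
    recommendation): ``"rank"`` when normality is rejected at ``alpha``
    (use Spearman rank association), else ``"parametric"``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ValueError("normality screen requires n >= 20")
    if np.std(x, ddof=1) == 0:
        return 0.0, "rank"
    stat = float(_ks_stats(x[None, :])[0])
    rng = np.random.default_rng(seed)
    null = _ks_stats(rng.standard_normal((n_resamples, x.size)))
    p = float((np.sum(null >= stat) + 1) / (n_resamples + 1))
    return p, ("rank" if p < alpha else "parametric")
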