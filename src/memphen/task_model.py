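"""Generative model of an emotional verbal free-recall task.

The task presents six series of five nouns (10 neutral, 10 positive,
10 negative words in total) and tests free recall twice: immediately after
each series and again after a five-minute delay.  Behaviour is summarised
by eight performance measures (PMs): correctly recalled words per valence
category at each time point, plus the number of confabulative errors
(recalled words that were never presented) at each time point.

The model tracks a latent *memory strength* ``m`` per word.  At encoding

    m0 = eps_v * (alpha + N(0, sigma))          (multiplicative variant)

where ``alpha`` is the learning rate, ``sigma`` the encoding-noise standard
deviation and ``eps_v`` the emotional modulation factor of the word's
valence (``eps_pos`` for positive, ``eps_neg`` for negative, 1 for
neutral).  A word is *attempted* in free recall iff ``m > beta`` (decision
threshold); an attempted word is recalled correctly with probability

    g(m) = 1 / (1 + exp(-s * (m - m50)))

(sigmoid steepness ``s``, centre ``m50 = 1``), and an attempted-but-failed
recall produces exactly one confabulative error.  Correctly recalled words
have their strength multiplied by the repetition-based improvement
``c >= 1``; the five-minute delay multiplies every strength by the
forgetting rate ``gamma < 1``.  The delayed recall applies the same
attempt/success rule to the decayed strengths.

Expected PMs are computed exactly by numerical integration over the
encoding distribution; :func:`simulate_subject` is the stochastic
counterpart used as an oracle and as the synthetic-data engine.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats
from scipy.special import expit

__all__ = [
    "PARAM_NAMES",
    "VALENCES",
    "Interval",
    "ParameterRanges",
    "ModelParameters",
    "TaskDesign",
    "PerformanceMeasures",
    "WordTrace",
    "recall_probability",
    "encoding_distribution",
    "expected_performance",
    "expected_pms_batch",
    "simulate_subject",
    "simulate_many",
    "build_word_list",
    "QuadratureError",
]

#: Canonical parameter order used by every array interface in the package.
PARAM_NAMES = ("alpha", "beta", "gamma", "eps_pos", "eps_neg", "sigma", "c", "s")

#: Valence categories of the stimuli.
VALENCES = ("neutral", "positive", "negative")

EncodingMode = Literal["multiplicative", "additive_noise"]


class QuadratureError(RuntimeError):
    """Raised when the expected-PM quadrature fails to converge."""


@dataclass(frozen=True)
class Interval:
    """A parameter search interval with open/closed end markers."""

    lo: float
    hi: float
    lo_open: bool = False
    hi_open: bool = False

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, x: float) -> bool:
        above = x > self.lo if self.lo_open else x >= self.lo
        below = x < self.hi if self.hi_open else x <= self.hi
        return bool(above and below)

    def clip(self, x: float) -> float:
        # open ends are nudged inward by a sliver of the range so that a
        # clipped hill-climbing step never lands exactly on an open bound
        eps = 1e-9 * self.width
        lo = self.lo + eps if self.lo_open else self.lo
        hi = self.hi - eps if self.hi_open else self.hi
        return float(min(max(x, lo), hi))


@dataclass(frozen=True)
class ParameterRanges:
    """Search ranges for the eight model parameters.

    Defaults: (alpha, beta, eps_pos, eps_neg, sigma) in [0.3, 3.5],
    c in [1, 4.2] (repetition must not weaken memories), gamma in (0, 0.8]
    and s in (0, 16].
    """

    intervals: dict[str, Interval] = field(
        default_factory=lambda: {
            "alpha": Interval(0.3, 3.5),
            "beta": Interval(0.3, 3.5),
            "gamma": Interval(0.0, 0.8, lo_open=True),
            "eps_pos": Interval(0.3, 3.5),
            "eps_neg": Interval(0.3, 3.5),
            "sigma": Interval(0.3, 3.5),
            "c": Interval(1.0, 4.2),
            "s": Interval(0.0, 16.0, lo_open=True),
        }
    )

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.intervals)
        if missing:
            raise ValueError(f"ranges missing parameters: {sorted(missing)}")

    def __getitem__(self, name: str) -> Interval:
        return self.intervals[name]

    def fraction(self, name: str, frac: float) -> float:
        """The value at fraction ``frac`` of the parameter's range."""
        iv = self.intervals[name]
        return iv.lo + frac * iv.width

    def contains(self, params: "ModelParameters") -> bool:
        return all(
            self.intervals[n].contains(getattr(params, n)) for n in PARAM_NAMES
        )


@dataclass(frozen=True)
class ModelParameters:
    """The eight cognitive parameters of one subject.

    alpha: learning rate; beta: decision threshold; gamma: forgetting rate
    (multiplier per 5-min delay); eps_pos / eps_neg: emotional modulation
    multipliers; sigma: encoding-noise SD; c: repetition-based memory
    improvement multiplier; s: sigmoid steepness.

    All parameters must be strictly positive.  Range enforcement against
    :class:`ParameterRanges` is applied when ``check=True`` (the default)
    and can be switched off for analytic limit computations (e.g.
    ``gamma -> 1``).
    """

    alpha: float
    beta: float
    gamma: float
    eps_pos: float
    eps_neg: float
    sigma: float
    c: float
    s: float
    check: dataclasses.InitVar[bool] = True
    ranges: dataclasses.InitVar[ParameterRanges | None] = None

    def __post_init__(self, check: bool, ranges: ParameterRanges | None) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name}={v!r} must be strictly positive")
        if check:
            rng = ranges if ranges is not None else ParameterRanges()
            for name in PARAM_NAMES:
                if not rng[name].contains(getattr(self, name)):
                    iv = rng[name]
                    raise ValueError(
                        f"parameter {name}={getattr(self, name)} outside "
                        f"[{iv.lo}, {iv.hi}]"
                    )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float], check: bool = True,
                   ranges: ParameterRanges | None = None) -> "ModelParameters":
        if len(values) != len(PARAM_NAMES):
            raise ValueError("expected 8 parameter values")
        kw = dict(zip(PARAM_NAMES, map(float, values)))
        return cls(**kw, check=check, ranges=ranges)

    def replace(self, check: bool = True, **changes: float) -> "ModelParameters":
        kw = {n: getattr(self, n) for n in PARAM_NAMES}
        kw.update(changes)
        return ModelParameters(**kw, check=check)

    def modulation(self, valence: str) -> float:
        if valence == "positive":
            return self.eps_pos
        if valence == "negative":
            return self.eps_neg
        if valence == "neutral":
            return 1.0
        raise ValueError(f"unknown valence {valence!r}")


@dataclass(frozen=True)
class TaskDesign:
    """Structure of the word-list task.

    Six series of five words; ten words per valence category; at most
    three words of the same valence within one series; sigmoid centre
    ``m50 = 1`` (any positive constant would do — the model is invariant
    under rescaling m50 together with alpha, beta, sigma and 1/s).
    """

    n_series: int = 6
    words_per_series: int = 5
    n_per_valence: dict[str, int] = field(
        default_factory=lambda: {"neutral": 10, "positive": 10, "negative": 10}
    )
    max_per_valence_per_series: int = 3
    m50: float = 1.0

    def __post_init__(self) -> None:
        if self.m50 <= 0:
            raise ValueError("m50 must be positive")
        if self.max_per_valence_per_series > self.words_per_series:
            raise ValueError("per-series valence cap exceeds series length")
        total = self.n_series * self.words_per_series
        if total != sum(self.n_per_valence.values()):
            raise ValueError(
                f"{self.n_series}x{self.words_per_series} words but "
                f"{sum(self.n_per_valence.values())} valence slots"
            )

    @property
    def n_words(self) -> int:
        return self.n_series * self.words_per_series


@dataclass(frozen=True)
class PerformanceMeasures:
    """The eight performance measures of one subject.

    pm1/pm2/pm3: positive/negative/neutral words correct at immediate
    recall; pm4: confabulative errors at immediate recall; pm5/pm6/pm7:
    positive/negative/neutral correct at delayed recall; pm8: errors at
    delayed recall.  Expected values are real numbers; observed or
    simulated values are integers.
    """

    pm1: float
    pm2: float
    pm3: float
    pm4: float
    pm5: float
    pm6: float
    pm7: float
    pm8: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.pm1, self.pm2, self.pm3, self.pm4,
             self.pm5, self.pm6, self.pm7, self.pm8], dtype=float
        )

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "PerformanceMeasures":
        if len(values) != 8:
            raise ValueError("expected 8 performance measures")
        return cls(*map(float, values))

    def validate(self, design: TaskDesign) -> None:
        caps = {"pm1": "positive", "pm2": "negative", "pm3": "neutral",
                "pm5": "positive", "pm6": "negative", "pm7": "neutral"}
        for name, val in caps.items():
            v = getattr(self, name)
            if not 0 <= v <= design.n_per_valence[val]:
                raise ValueError(f"{name}={v} outside [0, {design.n_per_valence[val]}]")
        for name in ("pm4", "pm8"):
            v = getattr(self, name)
            if not 0 <= v <= design.n_words:
                raise ValueError(f"{name}={v} outside [0, {design.n_words}]")


@dataclass(frozen=True)
class WordTrace:
    """Latent trajectory of one word through both recall phases."""

    word: str
    valence: str
    series: int
    m0: float
    recalled_immediate: bool
    errored_immediate: bool
    m_delayed: float
    recalled_delayed: bool
    errored_delayed: bool


# ---------------------------------------------------------------------------
# core probability machinery


def recall_probability(m, s: float, m50: float = 1.0):
    """Probability that an attempted recall succeeds, g(m) = expit(s*(m-m50)).

    Strictly increasing in ``m`` and equal to 0.5 at ``m = m50``.
    """
    if s <= 0:
        raise ValueError("sigmoid steepness s must be positive")
    if m50 <= 0:
        raise ValueError("sigmoid centre m50 must be positive")
    return expit(s * (np.asarray(m, dtype=float) - m50))


def encoding_distribution(
    params: ModelParameters,
    valence: str,
    mode: EncodingMode = "multiplicative",
):
    """The normal law of the initial memory strength m0 for a valence.

    In the default multiplicative variant the emotional modulation scales
    the whole encoded strength, m0 = eps_v*(alpha + N(0, sigma)), i.e.
    Normal(eps_v*alpha, eps_v*sigma).  The ``additive_noise`` variant keeps
    the noise unmodulated: m0 = eps_v*alpha + N(0, sigma).
    """
    eps = params.modulation(valence)
    if mode == "multiplicative":
        return stats.norm(loc=eps * params.alpha, scale=eps * params.sigma)
    if mode == "additive_noise":
        return stats.norm(loc=eps * params.alpha, scale=params.sigma)
    raise ValueError(f"unknown encoding mode {mode!r}")


def _phase_probs(mu, sd, beta, gamma, c, s, m50, m, w):
    """Per-word probabilities from quadrature nodes ``m`` with weights ``w``.

    All inputs broadcast; ``m``/``w`` carry the node axis last.  Returns
    (p_att, p_corr_imm, p_corr_del, p_err_del); p_err_imm follows as
    p_att - p_corr_imm.
    """
    phi = np.exp(-0.5 * ((m - mu) / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))
    g0 = expit(s * (m - m50))
    att0 = m > beta
    a = np.where(att0, g0, 0.0)  # P(recalled immediately | m0 = m)

    m_rec = gamma * c * m
    m_not = gamma * m
    g_rec = expit(s * (m_rec - m50))
    g_not = expit(s * (m_not - m50))
    att_rec = m_rec > beta
    att_not = m_not > beta

    corr_imm = a * phi
    corr_del = (a * np.where(att_rec, g_rec, 0.0)
                + (1.0 - a) * np.where(att_not, g_not, 0.0)) * phi
    err_del = (a * np.where(att_rec, 1.0 - g_rec, 0.0)
               + (1.0 - a) * np.where(att_not, 1.0 - g_not, 0.0)) * phi

    axis = -1
    p_corr_imm = np.sum(w * corr_imm, axis=axis)
    p_corr_del = np.sum(w * corr_del, axis=axis)
    p_err_del = np.sum(w * err_del, axis=axis)
    return p_corr_imm, p_corr_del, p_err_del


def _segment_edges(mu, sd, beta, gamma, c, half_width: float = 8.0):
    """Integration edges: +/- 8 SD around the mean, split at the attempt
    discontinuities beta, beta/gamma and beta/(gamma*c)."""
    lo = mu - half_width * sd
    hi = mu + half_width * sd
    brk = np.stack(
        [np.broadcast_to(beta, np.shape(mu)),
         beta / gamma * np.ones_like(np.asarray(mu, dtype=float)),
         beta / (gamma * c) * np.ones_like(np.asarray(mu, dtype=float))],
        axis=-1,
    )
    brk = np.clip(brk, lo[..., None], hi[..., None])
    brk = np.sort(brk, axis=-1)
    return np.concatenate([lo[..., None], brk, hi[..., None]], axis=-1)


def _valence_probs_adaptive(mu, sd, beta, gamma, c, s, m50,
                            tol: float = 1e-7, max_doublings: int = 12):
    """Scalar per-word probabilities by panel-doubling Gauss-Legendre.

    Each of the four segments between discontinuities is integrated with a
    composite 24-node Gauss-Legendre rule whose panel count is doubled
    until successive estimates differ by less than ``tol``.
    """
    edges = _segment_edges(np.float64(mu), sd, beta, gamma, c)
    x0, w0 = leggauss(24)

    def integrate() -> np.ndarray:
        total = np.zeros(3)
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a <= 0:
                continue
            prev = None
            for k in range(max_doublings + 1):
                n_panels = 2**k
                seg = np.linspace(a, b, n_panels + 1)
                mid = 0.5 * (seg[:-1] + seg[1:])[:, None]
                half = 0.5 * (seg[1] - seg[0])
                m = mid + half * x0[None, :]
                w = np.broadcast_to(half * w0[None, :], m.shape)
                vals = np.array(_phase_probs(
                    mu, sd, beta, gamma, c, s, m50,
                    m.ravel()[None, :], w.ravel()[None, :],
                )).ravel()
                if prev is not None and np.max(np.abs(vals - prev)) < tol:
                    total += vals
                    break
                prev = vals
            else:
                raise QuadratureError(
                    "expected-PM quadrature did not converge for parameters "
                    f"mu={mu}, sd={sd}, beta={beta}, gamma={gamma}, c={c}, s={s}"
                )
        return total

    p_corr_imm, p_corr_del, p_err_del = integrate()
    p_att = float(stats.norm.sf(beta, loc=mu, scale=sd))
    p_err_imm = max(p_att - p_corr_imm, 0.0)
    return p_att, float(p_corr_imm), p_err_imm, float(p_corr_del), float(p_err_del)


def expected_performance(
    params: ModelParameters,
    design: TaskDesign | None = None,
    mode: EncodingMode = "multiplicative",
    tol: float = 1e-7,
) -> PerformanceMeasures:
    """Exact expected performance measures under the model.

    For each valence the encoding law of m0 is integrated against the
    attempt/recall rules of both phases.  The quadrature splits the
    integration range at the decision discontinuities (beta, beta/gamma,
    beta/(gamma*c)) and doubles panel counts until successive estimates
    agree to ``tol``, giving absolute PM errors well below 1e-6.
    """
    design = design or TaskDesign()
    per_valence: dict[str, tuple[float, ...]] = {}
    for valence in VALENCES:
        law = encoding_distribution(params, valence, mode)
        per_valence[valence] = _valence_probs_adaptive(
            law.mean(), law.std(), params.beta, params.gamma, params.c,
            params.s, design.m50, tol=tol,
        )
    n = design.n_per_valence
    pm4 = sum(n[v] * per_valence[v][2] for v in VALENCES)
    pm8 = sum(n[v] * per_valence[v][4] for v in VALENCES)
    return PerformanceMeasures(
        pm1=n["positive"] * per_valence["positive"][1],
        pm2=n["negative"] * per_valence["negative"][1],
        pm3=n["neutral"] * per_valence["neutral"][1],
        pm4=pm4,
        pm5=n["positive"] * per_valence["positive"][3],
        pm6=n["negative"] * per_valence["negative"][3],
        pm7=n["neutral"] * per_valence["neutral"][3],
        pm8=pm8,
    )


_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def expected_pms_batch(
    theta: np.ndarray,
    design: TaskDesign | None = None,
    mode: EncodingMode = "multiplicative",
    nodes: int = 96,
) -> np.ndarray:
    """Expected PMs for a batch of parameter vectors, shape (k, 8) -> (k, 8).

    Fixed-order Gauss-Legendre on the four discontinuity-split segments,
    fully vectorised over parameter sets; used by the fitting grids and
    hill climbs where millions of evaluations are needed.  Agreement with
    :func:`expected_performance` is at the 1e-6 level per PM.

    Columns of ``theta`` follow :data:`PARAM_NAMES`.
    """
    design = design or TaskDesign()
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[1] != len(PARAM_NAMES):
        raise ValueError("theta must have 8 columns")
    k = theta.shape[0]
    alpha, beta, gamma = theta[:, 0], theta[:, 1], theta[:, 2]
    eps_pos, eps_neg, sigma = theta[:, 3], theta[:, 4], theta[:, 5]
    c, s = theta[:, 6], theta[:, 7]

    if nodes not in _GL_CACHE:
        _GL_CACHE[nodes] = leggauss(nodes)
    x0, w0 = _GL_CACHE[nodes]

    out = np.empty((k, 8))
    pm4 = np.zeros(k)
    pm8 = np.zeros(k)
    slots = {"positive": (0, 4), "negative": (1, 5), "neutral": (2, 6)}
    for valence, (i_imm, i_del) in slots.items():
        eps = {"positive": eps_pos, "negative": eps_neg,
               "neutral": np.ones(k)}[valence]
        mu = eps * alpha
        sd = eps * sigma if mode == "multiplicative" else sigma
        edges = _segment_edges(mu, sd, beta, gamma, c)  # (k, 5)
        mid = 0.5 * (edges[:, 1:] + edges[:, :-1])      # (k, 4)
        half = 0.5 * (edges[:, 1:] - edges[:, :-1])
        m = mid[:, :, None] + half[:, :, None] * x0[None, None, :]
        w = half[:, :, None] * w0[None, None, :]
        m = m.reshape(k, -1)
        w = w.reshape(k, -1)
        bc = lambda v: v[:, None]
        p_corr_imm, p_corr_del, p_err_del = _phase_probs(
            bc(mu), bc(sd), bc(beta), bc(gamma), bc(c), bc(s), design.m50, m, w
        )
        p_att = stats.norm.sf(beta, loc=mu, scale=sd)
        p_err_imm = np.maximum(p_att - p_corr_imm, 0.0)
        n_v = design.n_per_valence[valence]
        out[:, i_imm] = n_v * p_corr_imm
        out[:, i_del] = n_v * p_corr_del
        pm4 += n_v * p_err_imm
        pm8 += n_v * p_err_del
    out[:, 3] = pm4
    out[:, 7] = pm8
    return out


# ---------------------------------------------------------------------------
# stochastic simulation


def build_word_list(
    design: TaskDesign | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str, int]]:
    """Word tokens with valence tags assigned to series.

    Honours the cap of at most ``max_per_valence_per_series`` words of one
    valence per series.  With the default 6x5 design each series receives a
    (2, 2, 1)-type valence split rotated across series so that every
    valence totals ten words.  A generator shuffles word order within each
    series; without one the layout is deterministic.
    """
    design = design or TaskDesign()
    if (design.n_series, design.words_per_series) == (6, 5) and all(
        v == 10 for v in design.n_per_valence.values()
    ):
        layout = [(2, 2, 1), (2, 1, 2), (1, 2, 2)] * 2
    else:
        layout = _greedy_layout(design)
    counters = {v: 0 for v in VALENCES}
    prefixes = {"neutral": "neu", "positive": "pos", "negative": "neg"}
    words: list[tuple[str, str, int]] = []
    for series, counts in enumerate(layout):
        series_words = []
        for valence, n in zip(VALENCES, counts):
            for _ in range(n):
                counters[valence] += 1
                series_words.append(
                    (f"{prefixes[valence]}{counters[valence]:02d}", valence, series)
                )
        if rng is not None:
            order = rng.permutation(len(series_words))
            series_words = [series_words[i] for i in order]
        words.extend(series_words)
    return words


def _greedy_layout(design: TaskDesign) -> list[tuple[int, int, int]]:
    remaining = {v: design.n_per_valence.get(v, 0) for v in VALENCES}
    layout = []
    for _ in range(design.n_series):
        counts = {v: 0 for v in VALENCES}
        for _ in range(design.words_per_series):
            # most-remaining-first keeps the per-series caps satisfiable
            pick = max(
                (v for v in VALENCES
                 if remaining[v] > 0
                 and counts[v] < design.max_per_valence_per_series),
                key=lambda v: remaining[v],
                default=None,
            )
            if pick is None:
                raise ValueError("cannot satisfy per-series valence caps")
            counts[pick] += 1
            remaining[pick] -= 1
        layout.append(tuple(counts[v] for v in VALENCES))
    return layout


def simulate_many(
    params: ModelParameters,
    design: TaskDesign | None = None,
    n_simulations: int = 1,
    seed: int | np.random.SeedSequence | None = None,
    mode: EncodingMode = "multiplicative",
) -> np.ndarray:
    """Many independent task realisations at once; returns (n, 8) integer PMs.

    Vectorised over simulations (its random stream differs from looping
    :func:`simulate_subject`); used for Monte-Carlo averages against
    :func:`expected_performance`.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    design = design or TaskDesign()
    rng = np.random.default_rng(seed)
    words = build_word_list(design)
    valences = np.array([v for (_, v, _) in words])
    eps = np.array([params.modulation(v) for v in valences])
    shape = (n_simulations, len(words))
    noise = rng.normal(0.0, params.sigma, size=shape)
    if mode == "multiplicative":
        m0 = eps[None, :] * (params.alpha + noise)
    elif mode == "additive_noise":
        m0 = eps[None, :] * params.alpha + noise
    else:
        raise ValueError(f"unknown encoding mode {mode!r}")

    g = expit(params.s * (m0 - design.m50))
    attempted = m0 > params.beta
    recalled_imm = attempted & (rng.random(shape) < g)
    errored_imm = attempted & ~recalled_imm
    m_del = params.gamma * np.where(recalled_imm, params.c, 1.0) * m0
    g_del = expit(params.s * (m_del - design.m50))
    attempted_del = m_del > params.beta
    recalled_del = attempted_del & (rng.random(shape) < g_del)
    errored_del = attempted_del & ~recalled_del

    out = np.empty((n_simulations, 8), dtype=int)
    for col, (flags, val) in enumerate([
        (recalled_imm, "positive"), (recalled_imm, "negative"),
        (recalled_imm, "neutral"),
    ]):
        out[:, col] = flags[:, valences == val].sum(axis=1)
    out[:, 3] = errored_imm.sum(axis=1)
    for col, val in zip((4, 5, 6), ("positive", "negative", "neutral")):
        out[:, col] = recalled_del[:, valences == val].sum(axis=1)
    out[:, 7] = errored_del.sum(axis=1)
    return out


def simulate_subject(
    params: ModelParameters,
    design: TaskDesign | None = None,
    seed: int | np.random.SeedSequence | None = None,
    mode: EncodingMode = "multiplicative",
) -> tuple[PerformanceMeasures, list[WordTrace]]:
    """One stochastic realisation of the task for one subject.

    Draws m0 per word from the encoding law, applies the attempt rule
    (m > beta), the sigmoidal success rule, the repetition boost c for
    correctly recalled words, the forgetting factor gamma, and the same
    rules again at delayed recall.  Attempted-but-failed recalls each count
    one confabulative error.  Reproducible given ``seed``.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    design = design or TaskDesign()
    rng = np.random.default_rng(seed)
    words = build_word_list(design)
    n = len(words)
    valences = [v for (_, v, _) in words]
    eps = np.array([params.modulation(v) for v in valences])
    if mode == "multiplicative":
        m0 = eps * (params.alpha + rng.normal(0.0, params.sigma, size=n))
    elif mode == "additive_noise":
        m0 = eps * params.alpha + rng.normal(0.0, params.sigma, size=n)
    else:
        raise ValueError(f"unknown encoding mode {mode!r}")

    g = np.asarray(recall_probability(m0, params.s, design.m50))
    attempted = m0 > params.beta
    recalled_imm = attempted & (rng.random(n) < g)
    errored_imm = attempted & ~recalled_imm

    m_del = params.gamma * np.where(recalled_imm, params.c, 1.0) * m0
    g_del = np.asarray(recall_probability(m_del, params.s, design.m50))
    attempted_del = m_del > params.beta
    recalled_del = attempted_del & (rng.random(n) < g_del)
    errored_del = attempted_del & ~recalled_del

    def count(flags: np.ndarray, valence: str) -> int:
        return int(sum(f for f, v in zip(flags, valences) if v == valence))

    pms = PerformanceMeasures(
        pm1=count(recalled_imm, "positive"),
        pm2=count(recalled_imm, "negative"),
        pm3=count(recalled_imm, "neutral"),
        pm4=int(errored_imm.sum()),
        pm5=count(recalled_del, "positive"),
        pm6=count(recalled_del, "negative"),
        pm7=count(recalled_del, "neutral"),
        pm8=int(errored_del.sum()),
    )
    traces = [
        WordTrace(
            word=w, valence=v, series=srs, m0=float(m0[i]),
            recalled_immediate=bool(recalled_imm[i]),
            errored_immediate=bool(errored_imm[i]),
            m_delayed=float(m_del[i]),
            recalled_delayed=bool(recalled_del[i]),
            errored_delayed=bool(errored_del[i]),
        )
        for i, (w, v, srs) in enumerate(words)
    ]
    return pms, traces
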