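"""Chi-square parameter estimation for the free-recall model.

A model specification declares five *free* parameters (estimated per
subject) and three *fixed* parameters (shared by the whole cohort).  With
eight performance measures per subject the goodness-of-fit is

    chi2 = sum_i (PM_i_obs - PM_i_mod)^2 / var_i

where var_i is the across-cohort variance of PM_i, and the fit is judged
by the upper tail P(chi2, nu) of the chi-square law with nu = 8 - 5 = 3
degrees of freedom.

Estimation proceeds in stages: a regular grid over the free parameters
(8^5 = 32768 sets at full resolution) selects ten starting points per
subject for deterministic first-improvement hill climbing (5% steps,
then 1% refinement, plus the average of the climb endpoints); fixed
parameters are screened on a 4^3 = 64 grid, hill-climbed against the
cohort-mean chi2, and finally refined by evaluating the component-wise
averages of all 2^10 - 1 = 1023 subsets of the ten best fixed sets.
Model selection compares all C(8,3) = 56 free/fixed partitions by
cohort-mean chi2.  A bootstrap over each subject's ten best endpoint sets
propagates estimation uncertainty into downstream statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task_model import (
    PARAM_NAMES,
    Interval,
    ModelParameters,
    ParameterRanges,
    PerformanceMeasures,
    TaskDesign,
    expected_pms_batch,
)

__all__ = [
    "ParameterRanges",
    "Interval",
    "ModelSpec",
    "PMDispersion",
    "FitResult",
    "FitConfig",
    "chi_square",
    "fit_quality",
    "grid_candidates",
    "hill_climb",
    "fit_subject",
    "fit_cohort",
    "fits_to_frame",
    "estimate_fixed",
    "enumerate_model_specs",
    "select_model",
    "combination_average",
    "bootstrap_parameter_sets",
]

N_PMS = 8


@dataclass(frozen=True)
class ModelSpec:
    """Partition of the eight parameters into five free and three fixed."""

    free_names: tuple[str, ...]
    fixed_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        free = tuple(self.free_names)
        if len(free) != 5 or len(set(free)) != 5:
            raise ValueError("exactly 5 distinct free parameters required")
        unknown = set(free) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        overlap = set(free) & set(self.fixed_values)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        extra = set(self.fixed_values) - set(self.fixed_names)
        if extra:
            raise ValueError(f"fixed values for non-fixed parameters: {sorted(extra)}")

    @property
    def fixed_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if n not in self.free_names)

    @property
    def nu(self) -> int:
        """Degrees of freedom of the chi-square fit test: 8 PMs - 5 free."""
        return N_PMS - len(self.free_names)

    def with_fixed(self, values: Sequence[float] | dict[str, float]) -> "ModelSpec":
        if not isinstance(values, dict):
            values = dict(zip(self.fixed_names, map(float, values)))
        return ModelSpec(self.free_names, dict(values))

    def full_vector(self, free_values: Sequence[float]) -> np.ndarray:
        """Assemble the 8-vector in PARAM_NAMES order."""
        if len(self.fixed_values) != 3:
            raise ValueError("fixed parameter values not set")
        lookup = dict(zip(self.free_names, map(float, free_values)))
        lookup.update(self.fixed_values)
        return np.array([lookup[n] for n in PARAM_NAMES], dtype=float)

    def full_matrix(self, free_values: np.ndarray) -> np.ndarray:
        free_values = np.atleast_2d(free_values)
        out = np.empty((free_values.shape[0], len(PARAM_NAMES)))
        for j, name in enumerate(PARAM_NAMES):
            if name in self.fixed_values:
                out[:, j] = self.fixed_values[name]
            else:
                out[:, j] = free_values[:, self.free_names.index(name)]
        return out


@dataclass(frozen=True)
class PMDispersion:
    """Across-cohort variances of the eight PMs, used as chi-square weights."""

    variances: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.variances, dtype=float)
        object.__setattr__(self, "variances", v)
        if v.shape != (N_PMS,):
            raise ValueError("dispersion must hold 8 variances")
        if not np.all(v > 0):
            raise ValueError(
                "PM variances must be strictly positive; apply a variance "
                "floor (PMDispersion.from_cohort uses 0.25) for degenerate "
                "cohorts"
            )

    @classmethod
    def from_cohort(cls, pm_table: np.ndarray | pd.DataFrame,
                    floor: float = 0.25) -> "PMDispersion":
        """Cohort variances with a floor guarding against degenerate columns."""
        arr = np.asarray(pm_table, dtype=float)
        return cls(np.maximum(arr.var(axis=0, ddof=1), floor))


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one subject."""

    best_params: ModelParameters
    chi2: float
    p_fit: float
    nu: int
    modeled_pms: PerformanceMeasures
    top_sets: tuple[tuple[np.ndarray, float], ...]  # (8-vector, chi2), ascending
    n_evaluations: int = 0

    @property
    def good_fit(self) -> bool:
        return self.p_fit > 0.05


@dataclass(frozen=True)
class FitConfig:
    """Resolution and seeding knobs of the estimation pipeline.

    The ``paper`` preset runs the procedure at full resolution
    (8^5 free grid, 4^3 fixed grid, 20 fixed sets kept, all 56 models);
    ``desk`` is a scaled-down profile (4^5 grid, 3^3 fixed sets, 5 kept,
    8 models fully evaluated) that runs in minutes.
    """

    preset: str = "desk"
    free_levels: int = 4
    fixed_levels: int = 3
    n_fixed_keep: int = 5
    n_models_evaluate: int = 8
    n_starts: int = 10
    coarse_step: float = 0.05
    fine_step: float = 0.01
    seed: int = 0
    quad_nodes: int = 96
    mode: str = "multiplicative"
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    design: TaskDesign = field(default_factory=TaskDesign)

    @classmethod
    def from_preset(cls, name: str, seed: int = 0, **overrides) -> "FitConfig":
        presets = {
            "paper": dict(free_levels=8, fixed_levels=4, n_fixed_keep=20,
                          n_models_evaluate=56),
            "desk": dict(free_levels=4, fixed_levels=3, n_fixed_keep=5,
                         n_models_evaluate=8),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        kw = dict(presets[name])
        kw.update(overrides)
        return cls(preset=name, seed=seed, **kw)


# ---------------------------------------------------------------------------
# goodness of fit


def chi_square(
    observed: PerformanceMeasures | np.ndarray,
    modeled: PerformanceMeasures | np.ndarray,
    dispersion: PMDispersion,
) -> float:
    """Sum over the 8 PMs of squared residuals over cohort variances."""
    obs = observed.as_array() if isinstance(observed, PerformanceMeasures) else np.asarray(observed, float)
    mod = modeled.as_array() if isinstance(modeled, PerformanceMeasures) else np.asarray(modeled, float)
    return float(np.sum((obs - mod) ** 2 / dispersion.variances))


def fit_quality(chi2: float, nu: int) -> float:
    """Upper-tail probability P(chi2, nu); > 0.05 flags an adequate fit."""
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if nu < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.chi2.sf(chi2, df=nu))


# ---------------------------------------------------------------------------
# grids and hill climbing


def _level_fractions(levels: int) -> np.ndarray:
    """Odd fractions (2i+1)/(2*levels): 1/16, 3/16, ... for 8 levels."""
    return (2 * np.arange(levels) + 1) / (2 * levels)


def grid_candidates(
    spec: ModelSpec,
    ranges: ParameterRanges | None = None,
    free_levels: int = 8,
    fixed_levels: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian candidate grids for the free and fixed parameters.

    Free parameters take ``free_levels`` values at odd-sixteenth-type
    fractions of their range (8 levels: 1/16, 3/16, ..., 15/16); fixed
    parameters take ``fixed_levels`` values at odd-eighth-type fractions
    (4 levels: 1/8, 3/8, 5/8, 7/8).  Returns arrays of shape
    (free_levels^5, 5) and (fixed_levels^3, 3), columns ordered as
    ``spec.free_names`` / ``spec.fixed_names``.
    """
    ranges = ranges or ParameterRanges()
    free_axes = [
        ranges[name].lo + _level_fractions(free_levels) * ranges[name].width
        for name in spec.free_names
    ]
    fixed_axes = [
        ranges[name].lo + _level_fractions(fixed_levels) * ranges[name].width
        for name in spec.fixed_names
    ]
    free = np.stack(np.meshgrid(*free_axes, indexing="ij"), axis=-1).reshape(-1, 5)
    fixed = np.stack(np.meshgrid(*fixed_axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return free, fixed


def hill_climb(
    start: np.ndarray,
    objective: Callable[[np.ndarray], float],
    step_fraction: float,
    ranges: ParameterRanges,
    order_seed: int,
    names: Sequence[str],
    max_sweeps: int = 2000,
) -> tuple[np.ndarray, float, int]:
    """Deterministic first-improvement coordinate search.

    Candidate moves are one step of ``step_fraction`` of the respective
    range along each parameter in both directions.  The order in which
    moves are examined is drawn from a seeded pseudorandom generator, so a
    rerun with the same seed follows the same trajectory.  A move is
    accepted as soon as it improves the objective; the search stops when a
    full sweep finds no improvement.  Steps are clipped to the ranges.
    """
    rng = np.random.default_rng(order_seed)
    x = np.asarray(start, dtype=float).copy()
    steps = np.array([step_fraction * ranges[n].width for n in names])
    moves = [(i, d) for i in range(len(names)) for d in (+1.0, -1.0)]
    fx = objective(x)
    n_evals = 1
    for _ in range(max_sweeps):
        improved = False
        for j in rng.permutation(len(moves)):
            i, d = moves[j]
            xi = ranges[names[i]].clip(x[i] + d * steps[i])
            if xi == x[i]:
                continue
            y = x.copy()
            y[i] = xi
            fy = objective(y)
            n_evals += 1
            if fy < fx:
                x, fx = y, fy
                improved = True
                break
        if not improved:
            break
    return x, fx, n_evals


# ---------------------------------------------------------------------------
# per-subject fitting


class _GridCache:
    """Expected PMs of the free-parameter grid for one fixed-parameter set.

    Modeled PMs depend only on the parameter vector, never on the subject,
    so one batch evaluation of the grid serves the whole cohort.
    """

    def __init__(self, spec: ModelSpec, config: FitConfig):
        self.spec = spec
        self.free_sets, _ = grid_candidates(
            spec, config.ranges, config.free_levels, config.fixed_levels
        )
        theta = spec.full_matrix(self.free_sets)
        self.pms = expected_pms_batch(
            theta, config.design, mode=config.mode, nodes=config.quad_nodes
        )


def _make_objective(
    spec: ModelSpec,
    observed: np.ndarray,
    dispersion: PMDispersion,
    config: FitConfig,
    counter: list[int],
):
    cache: dict[tuple, float] = {}
    inv_var = 1.0 / dispersion.variances

    def objective(free_values: np.ndarray) -> float:
        key = tuple(np.round(free_values, 12))
        hit = cache.get(key)
        if hit is not None:
            return hit
        theta = spec.full_vector(free_values)[None, :]
        mod = expected_pms_batch(theta, config.design, mode=config.mode,
                                 nodes=config.quad_nodes)[0]
        val = float(np.sum((observed - mod) ** 2 * inv_var))
        cache[key] = val
        counter[0] += 1
        return val

    return objective


def _top_k_indices(chi2: np.ndarray, free_sets: np.ndarray, k: int) -> list[int]:
    """Smallest-chi2 indices; ties broken lexicographically on parameters."""
    take = min(4 * k, chi2.size)
    part = np.argpartition(chi2, take - 1)[:take]
    order = sorted(part, key=lambda i: (chi2[i], tuple(free_sets[i])))
    return order[:k]


def fit_subject(
    observed: PerformanceMeasures | np.ndarray,
    spec: ModelSpec,
    dispersion: PMDispersion,
    config: FitConfig | None = None,
    grid: "_GridCache | None" = None,
    subject_seed: int | None = None,
) -> FitResult:
    """Estimate the five free parameters of one subject.

    Grid scan -> ten best starts (deterministic tie-break) -> 5%-step hill
    climbs -> 1%-step refinement of each endpoint -> the component-wise
    average of the refined endpoints is also evaluated and kept if it beats
    every single endpoint.
    """
    config = config or FitConfig()
    obs = observed.as_array() if isinstance(observed, PerformanceMeasures) else np.asarray(observed, float)
    if grid is None:
        grid = _GridCache(spec, config)
    counter = [0]
    objective = _make_objective(spec, obs, dispersion, config, counter)

    chi2_grid = np.sum(
        (grid.pms - obs[None, :]) ** 2 / dispersion.variances[None, :], axis=1
    )
    starts = _top_k_indices(chi2_grid, grid.free_sets, config.n_starts)
    base_seed = config.seed if subject_seed is None else subject_seed

    endpoints: list[tuple[np.ndarray, float]] = []
    for rank, idx in enumerate(starts):
        x, fx, _ = hill_climb(
            grid.free_sets[idx], objective, config.coarse_step,
            config.ranges, order_seed=base_seed * 1009 + rank,
            names=spec.free_names,
        )
        x, fx, _ = hill_climb(
            x, objective, config.fine_step,
            config.ranges, order_seed=base_seed * 1013 + rank,
            names=spec.free_names,
        )
        endpoints.append((x, fx))
    endpoints.sort(key=lambda e: (e[1], tuple(e[0])))

    best_free, best_chi2 = endpoints[0]
    if len(endpoints) > 1:
        avg = np.mean([e[0] for e in endpoints], axis=0)
        f_avg = objective(avg)
        if f_avg < best_chi2:
            best_free, best_chi2 = avg, f_avg

    theta_best = spec.full_vector(best_free)
    modeled = expected_pms_batch(theta_best[None, :], config.design,
                                 mode=config.mode, nodes=config.quad_nodes)[0]
    nu = spec.nu
    return FitResult(
        best_params=ModelParameters.from_array(theta_best, check=False),
        chi2=best_chi2,
        p_fit=fit_quality(best_chi2, nu),
        nu=nu,
        modeled_pms=PerformanceMeasures.from_array(modeled),
        top_sets=tuple((spec.full_vector(x), fx) for x, fx in endpoints),
        n_evaluations=counter[0],
    )


def fit_cohort(
    pm_table: np.ndarray | pd.DataFrame,
    spec: ModelSpec,
    dispersion: PMDispersion | None = None,
    config: FitConfig | None = None,
) -> list[FitResult]:
    """Fit every subject of a PM table, sharing one grid evaluation."""
    config = config or FitConfig()
    arr = np.asarray(pm_table, dtype=float)
    dispersion = dispersion or PMDispersion.from_cohort(arr)
    grid = _GridCache(spec, config)
    return [
        fit_subject(arr[i], spec, dispersion, config, grid=grid,
                    subject_seed=config.seed * 100003 + i)
        for i in range(arr.shape[0])
    ]


def fits_to_frame(fits: Sequence[FitResult],
                  subject_ids: Sequence | None = None) -> pd.DataFrame:
    """Tabular view of per-subject fits (one row per subject)."""
    ids = list(subject_ids) if subject_ids is not None else list(range(len(fits)))
    rows = []
    for sid, fr in zip(ids, fits):
        row = {"subject_id": sid}
        row.update({n: getattr(fr.best_params, n) for n in PARAM_NAMES})
        row.update({"chi2": fr.chi2, "p_fit": fr.p_fit, "good_fit": fr.good_fit})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixed-parameter estimation and model selection


@dataclass(frozen=True)
class FixedEstimate:
    """Cohort-level estimate of the three fixed parameters."""

    spec: ModelSpec
    mean_chi2: float
    fits: tuple[FitResult, ...]
    screening: pd.DataFrame


def _grid_only_mean_chi2(pm_arr: np.ndarray, spec: ModelSpec,
                         dispersion: PMDispersion, config: FitConfig) -> float:
    """Cheap cohort score: per-subject best grid chi2, averaged."""
    grid = _GridCache(spec, config)
    chi2 = np.sum(
        (grid.pms[None, :, :] - pm_arr[:, None, :]) ** 2
        / dispersion.variances[None, None, :],
        axis=2,
    )
    return float(chi2.min(axis=1).mean())


def estimate_fixed(
    cohort_pms: np.ndarray | pd.DataFrame,
    spec: ModelSpec,
    config: FitConfig | None = None,
    dispersion: PMDispersion | None = None,
) -> FixedEstimate:
    """Estimate the three population-level (fixed) parameters.

    Alternation: screen the fixed-parameter grid by best-grid cohort-mean
    chi2, fully fit subjects for the best-screened candidates, hill-climb
    the fixed parameters at 5% steps against cohort-mean chi2 (holding the
    individual estimates), then re-fit subjects with 1% steps under the
    winning fixed values.
    """
    config = config or FitConfig()
    pm_arr = np.asarray(cohort_pms, dtype=float)
    if pm_arr.shape[0] == 0:
        raise ValueError("cohort is empty")
    dispersion = dispersion or PMDispersion.from_cohort(pm_arr)

    _, fixed_sets = grid_candidates(
        spec, config.ranges, config.free_levels, config.fixed_levels
    )
    screen_rows = []
    for values in fixed_sets:
        cand = spec.with_fixed(values)
        screen_rows.append(
            {"fixed_values": tuple(values),
             "mean_chi2_grid": _grid_only_mean_chi2(pm_arr, cand, dispersion, config)}
        )
    screening = pd.DataFrame(screen_rows).sort_values(
        "mean_chi2_grid", kind="stable"
    ).reset_index(drop=True)

    kept = screening.head(config.n_fixed_keep)
    best_values: np.ndarray | None = None
    best_mean = np.inf
    best_fits: list[FitResult] | None = None
    for values in kept["fixed_values"]:
        cand = spec.with_fixed(np.asarray(values))
        fits = fit_cohort(pm_arr, cand, dispersion, config)
        mean = float(np.mean([f.chi2 for f in fits]))
        if mean < best_mean:
            best_mean, best_values, best_fits = mean, np.asarray(values), fits

    assert best_fits is not None and best_values is not None
    free_estimates = np.array(
        [[getattr(f.best_params, n) for n in spec.free_names] for f in best_fits]
    )
    inv_var = 1.0 / dispersion.variances

    def cohort_objective(fixed_values: np.ndarray) -> float:
        cand = spec.with_fixed(fixed_values)
        theta = cand.full_matrix(free_estimates)
        mod = expected_pms_batch(theta, config.design, mode=config.mode,
                                 nodes=config.quad_nodes)
        return float(np.mean(np.sum((pm_arr - mod) ** 2 * inv_var, axis=1)))

    climbed, climbed_mean, _ = hill_climb(
        best_values, cohort_objective, config.coarse_step, config.ranges,
        order_seed=config.seed * 977 + 1, names=spec.fixed_names,
    )
    final_spec = spec.with_fixed(climbed)
    fine_cfg = replace(config, coarse_step=config.fine_step)
    final_fits = fit_cohort(pm_arr, final_spec, dispersion, fine_cfg)
    final_mean = float(np.mean([f.chi2 for f in final_fits]))
    if final_mean > best_mean:  # keep the better alternation state
        final_spec, final_fits, final_mean = (
            spec.with_fixed(best_values), best_fits, best_mean
        )
    return FixedEstimate(
        spec=final_spec, mean_chi2=final_mean,
        fits=tuple(final_fits), screening=screening,
    )


def enumerate_model_specs() -> list[ModelSpec]:
    """All C(8,3) = 56 partitions into five free and three fixed parameters."""
    specs = []
    for fixed in itertools.combinations(PARAM_NAMES, 3):
        free = tuple(n for n in PARAM_NAMES if n not in fixed)
        specs.append(ModelSpec(free_names=free))
    return specs


def select_model(
    cohort_pms: np.ndarray | pd.DataFrame,
    ranges: ParameterRanges | None = None,
    config: FitConfig | None = None,
    evaluator: Callable[[ModelSpec], float] | None = None,
) -> pd.DataFrame:
    """Rank the 56 candidate free/fixed partitions by cohort-mean chi2.

    A cheap grid-only screening scores every partition; the best
    ``config.n_models_evaluate`` are then scored with the full
    fixed-parameter estimation (or a caller-supplied ``evaluator``).  The
    returned table is sorted ascending by the evaluated mean chi2 with the
    top two partitions flagged for refinement.
    """
    config = config or FitConfig()
    if ranges is not None:
        config = replace(config, ranges=ranges)
    pm_arr = np.asarray(cohort_pms, dtype=float)
    if pm_arr.shape[0] == 0:
        raise ValueError("cohort is empty")
    dispersion = PMDispersion.from_cohort(pm_arr)
    specs = enumerate_model_specs()

    screen = [
        _grid_only_mean_chi2(pm_arr, s, dispersion, config) for s in specs
    ] if evaluator is None else [np.nan] * len(specs)

    rows = []
    for s, sc in zip(specs, screen):
        rows.append({"free": s.free_names, "fixed": s.fixed_names,
                     "screen_chi2": sc, "mean_chi2": np.nan})
    table = pd.DataFrame(rows)

    if evaluator is None:
        order = table.sort_values("screen_chi2", kind="stable").index
        chosen = list(order[: config.n_models_evaluate])
        def evaluate(spec: ModelSpec) -> float:
            return estimate_fixed(pm_arr, spec, config, dispersion).mean_chi2
    else:
        chosen = list(table.index)
        evaluate = evaluator

    for i in chosen:
        table.loc[i, "mean_chi2"] = evaluate(specs[i])
    table = table.sort_values(
        ["mean_chi2", "screen_chi2"], kind="stable", na_position="last"
    ).reset_index(drop=True)
    table["refine"] = False
    table.loc[:1, "refine"] = True
    return table


def combination_average(
    top_fixed_sets: Sequence[np.ndarray],
    evaluator: Callable[[np.ndarray], float],
) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Best component-wise average over all non-empty subsets.

    With k input sets all 2^k - 1 subset averages are evaluated (1023 for
    the ten best fixed sets).  Returns the best average, its score, and
    the full evaluation table.
    """
    sets = [np.asarray(v, dtype=float) for v in top_fixed_sets]
    if not 1 <= len(sets) <= 10:
        raise ValueError("between 1 and 10 input sets required")
    rows = []
    best_avg, best_score = None, np.inf
    for r in range(1, len(sets) + 1):
        for combo in itertools.combinations(range(len(sets)), r):
            avg = np.mean([sets[i] for i in combo], axis=0)
            score = float(evaluator(avg))
            rows.append({"members": combo, "score": score})
            if score < best_score:
                best_avg, best_score = avg, score
    assert best_avg is not None
    return best_avg, best_score, pd.DataFrame(rows)


def bootstrap_parameter_sets(
    per_subject_top_sets: Sequence[Sequence[np.ndarray]],
    n_samples: int = 10000,
    seed: int | None = None,
) -> Iterator[np.ndarray]:
    """Resample cohorts from each subject's stored best parameter sets.

    Each sample assigns one uniformly drawn stored set per subject;
    downstream statistics are computed per sample and summarised by their
    median.  Yields arrays of shape (n_subjects, 8).
    """
    stacked = [np.asarray(sets, dtype=float) for sets in per_subject_top_sets]
    for i, s in enumerate(stacked):
        if s.ndim != 2 or s.shape[0] < 1:
            raise ValueError(f"subject {i} has no stored parameter sets")
    rng = np.random.default_rng(seed)
    n_subjects = len(stacked)
    counts = np.array([s.shape[0] for s in stacked])
    for _ in range(n_samples):
        picks = rng.integers(0, counts)
        yield np.stack([stacked[i][picks[i]] for i in range(n_subjects)])
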