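"""Synthetic cohorts for end-to-end pipeline testing.

Generates genotypes in Hardy-Weinberg equilibrium, true cognitive
parameters with a genotype-dependent negative-modulation effect, and full
stochastic task realisations (recall logs and PM tables), so that every
stage — scoring, fitting, model selection, association — can be exercised
without any external data.

The default ``table1`` calibration emulates a reference verbal-memory
cohort: 1239 genotyped subjects, effect-allele frequency ~0.325
(genotype groups of roughly 137/532/570), per-genotype negative-modulation
means 1.20/1.14/1.08 with common SD 0.23 (the group SEMs times sqrt(n)),
and the remaining free parameters centred on reference cohort means
(alpha 1.93, beta 1.27, c 1.95, eps_pos 1.09).  The population-level
parameters are held at sigma = 0.7, gamma = 0.5, s = 4.133.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .association import GenotypeMatrix
from .phenotypes import RecallLog, log_from_traces
from .task_model import (
    PARAM_NAMES,
    ModelParameters,
    ParameterRanges,
    TaskDesign,
    simulate_subject,
)

__all__ = [
    "ParameterLaw",
    "CausalMarker",
    "CohortSpec",
    "SyntheticTruth",
    "generate_genotypes",
    "generate_parameters",
    "generate_cohort",
    "child_rng",
]


def child_rng(master_seed: int, *spawn_key: int) -> np.random.Generator:
    """Deterministic child generator from a master seed and a key path.

    Counter-based splitting: any subject or stage can be regenerated in
    isolation from the master seed plus its key.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=spawn_key)
    )


@dataclass(frozen=True)
class ParameterLaw:
    """Truncated normal background law of one cognitive parameter."""

    mean: float
    sd: float

    def sample(self, n: int, lo: float, hi: float,
               rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            if not lo <= self.mean <= hi:
                raise ValueError(f"degenerate law mean {self.mean} outside range")
            return np.full(n, self.mean)
        from scipy.stats import norm

        mass = norm.cdf(hi, self.mean, self.sd) - norm.cdf(lo, self.mean, self.sd)
        if mass < 1e-6:
            raise ValueError(
                f"truncation leaves mass {mass:.2e} inside [{lo}, {hi}] for "
                f"Normal({self.mean}, {self.sd})"
            )
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean, self.sd, size=max(n - filled, 16))
            good = draw[(draw >= lo) & (draw <= hi)]
            take = min(good.size, n - filled)
            out[filled:filled + take] = good[:take]
            filled += take
        return out


@dataclass(frozen=True)
class CausalMarker:
    """The causal SNP: allele frequency and dosage-group phenotype means."""

    marker_id: str = "rs_causal"
    effect_allele_freq: float = 0.325
    group_means: tuple[float, float, float] = (1.08, 1.14, 1.20)  # dosage 0/1/2
    group_sd: float = 0.23

    def __post_init__(self) -> None:
        if not 0 < self.effect_allele_freq < 1:
            raise ValueError("effect-allele frequency must be in (0, 1)")
        if self.group_sd <= 0:
            raise ValueError("group SD must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort."""

    n_subjects: int = 1239
    causal: CausalMarker = field(default_factory=CausalMarker)
    background: dict[str, ParameterLaw] = field(
        default_factory=lambda: {
            "alpha": ParameterLaw(1.93, 0.45),
            "beta": ParameterLaw(1.27, 0.35),
            "gamma": ParameterLaw(0.5, 0.0),
            "eps_pos": ParameterLaw(1.09, 0.20),
            "sigma": ParameterLaw(0.7, 0.0),
            "c": ParameterLaw(1.95, 0.35),
            "s": ParameterLaw(4.133, 0.0),
        }
    )
    n_null_markers: int = 0
    null_freq_range: tuple[float, float] = (0.1, 0.5)
    site_labels: tuple[str, ...] = ("zurich", "basel")
    site_proportions: tuple[float, ...] = (0.47, 0.53)
    master_seed: int = 0
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    design: TaskDesign = field(default_factory=TaskDesign)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("cohort must have at least one subject")
        eps_lo, eps_hi = self.ranges["eps_neg"].lo, self.ranges["eps_neg"].hi
        for m in self.causal.group_means:
            if not eps_lo <= m <= eps_hi:
                raise ValueError(f"group mean {m} outside eps_neg range")
        missing = set(PARAM_NAMES) - {"eps_neg"} - set(self.background)
        if missing:
            raise ValueError(f"background laws missing: {sorted(missing)}")

    @classmethod
    def table1(cls, n_subjects: int = 1239, master_seed: int = 0,
               **overrides) -> "CohortSpec":
        """The default calibration described in the module docstring."""
        return cls(n_subjects=n_subjects, master_seed=master_seed, **overrides)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    parameters: tuple[ModelParameters, ...]
    causal_marker_id: str
    dosage: np.ndarray
    site: tuple[str, ...]

    def parameter_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{n: getattr(p, n) for n in PARAM_NAMES} for p in self.parameters]
        )


def generate_genotypes(
    spec: CohortSpec,
    seed: int | None = None,
) -> GenotypeMatrix:
    """HWE genotypes for the causal marker and any null markers.

    Dosages are drawn with probabilities ((1-p)^2, 2p(1-p), p^2); null
    markers are independent of everything else.
    """
    master = spec.master_seed if seed is None else seed
    rng = child_rng(master, 0)
    n = spec.n_subjects
    freqs = [spec.causal.effect_allele_freq]
    ids = [spec.causal.marker_id]
    if spec.n_null_markers:
        lo, hi = spec.null_freq_range
        freqs.extend(rng.uniform(lo, hi, size=spec.n_null_markers))
        ids.extend(f"rs_null{i:05d}" for i in range(spec.n_null_markers))
    dosages = np.empty((n, len(freqs)))
    for j, p in enumerate(freqs):
        probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        dosages[:, j] = rng.choice([0.0, 1.0, 2.0], size=n, p=probs)
    markers = pd.DataFrame({
        "marker_id": ids,
        "effect_allele": "A",
        "other_allele": "G",
        "chrom": "17",
        "pos": np.arange(len(ids)) + 1_000_000,
    })
    sample_ids = tuple(f"S{i:05d}" for i in range(n))
    return GenotypeMatrix(sample_ids=sample_ids, markers=markers, dosages=dosages)


def generate_parameters(
    spec: CohortSpec,
    genotypes: GenotypeMatrix | np.ndarray,
    seed: int | None = None,
) -> SyntheticTruth:
    """True cognitive parameters with the genotype -> eps_neg effect.

    eps_neg is a truncated normal whose mean depends on the causal-marker
    dosage group; every other parameter follows its background law.  All
    draws are truncated to the parameter ranges by rejection.
    """
    master = spec.master_seed if seed is None else seed
    rng = child_rng(master, 1)
    if isinstance(genotypes, GenotypeMatrix):
        dosage = genotypes.marker_dosage(spec.causal.marker_id)
    else:
        dosage = np.asarray(genotypes, dtype=float)
    n = dosage.size
    if n != spec.n_subjects:
        raise ValueError("dosage length differs from cohort size")

    iv = spec.ranges["eps_neg"]
    eps_neg = np.empty(n)
    for dose in (0, 1, 2):
        mask = dosage == dose
        law = ParameterLaw(spec.causal.group_means[dose], spec.causal.group_sd)
        eps_neg[mask] = law.sample(int(mask.sum()), iv.lo, iv.hi,
                                   child_rng(master, 1, 10 + dose))
    columns = {"eps_neg": eps_neg}
    for name, law in spec.background.items():
        iv = spec.ranges[name]
        lo = iv.lo if not iv.lo_open else iv.lo + 1e-9 * iv.width
        columns[name] = law.sample(n, lo, iv.hi, child_rng(master, 1, hash_name(name)))

    params = tuple(
        ModelParameters(**{k: float(columns[k][i]) for k in PARAM_NAMES})
        for i in range(n)
    )
    site_rng = child_rng(master, 2)
    site = tuple(
        site_rng.choice(spec.site_labels, p=spec.site_proportions)
        for _ in range(n)
    )
    return SyntheticTruth(
        parameters=params,
        causal_marker_id=spec.causal.marker_id,
        dosage=dosage,
        site=site,
    )


def hash_name(name: str) -> int:
    """Stable small integer key for a parameter name (seed spawning)."""
    return 100 + PARAM_NAMES.index(name)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[GenotypeMatrix, list[RecallLog], pd.DataFrame, SyntheticTruth]:
    """A complete cohort: genotypes, recall logs, PM table and the truth.

    Each subject's task realisation uses a child seed derived from the
    master seed, so any subject is reproducible in isolation.  The PM
    table round-trips exactly through the recall-scoring rule.
    """
    genotypes = generate_genotypes(spec)
    truth = generate_parameters(spec, genotypes)
    logs: list[RecallLog] = []
    pm_rows = []
    for i, params in enumerate(truth.parameters):
        seed = np.random.SeedSequence(entropy=spec.master_seed, spawn_key=(3, i))
        pms, traces = simulate_subject(params, spec.design, seed=seed)
        logs.append(log_from_traces(genotypes.sample_ids[i], traces))
        pm_rows.append(pms.as_array())
    pm_table = pd.DataFrame(
        np.array(pm_rows),
        columns=[f"pm{i}" for i in range(1, 9)],
        index=pd.Index(genotypes.sample_ids, name="subject_id"),
    )
    return genotypes, logs, pm_table, truth
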