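"""Marker QC and genetic association for model-based phenotypes.

Genotypes are coded additively as the dosage (0/1/2) of an effect allele.
Markers are filtered on call rate, minor allele frequency and a
Hardy-Weinberg equilibrium test before testing.  Because fitted cognitive
parameters are generally non-normal, association uses Spearman rank
correlation, with Bonferroni family-wise control over the number of
markers analysed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "AssociationResult",
    "qc_filter",
    "hwe_test",
    "hwe_exact_test",
    "spearman_association",
    "bonferroni",
    "genotype_summary",
    "subsample_consistency",
]


@dataclass(frozen=True)
class GenotypeMatrix:
    """Samples x markers additive dosage matrix.

    ``dosages`` stores the effect-allele count as float with NaN for
    missing calls; ``markers`` is a metadata frame with at least columns
    ``marker_id``, ``effect_allele``, ``other_allele`` (``chrom``/``pos``
    optional).
    """

    sample_ids: tuple[str, ...]
    markers: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        object.__setattr__(self, "dosages", d)
        if d.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {d.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        valid = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = d[~valid][0]
            raise ValueError(f"invalid dosage code {bad!r}; expected 0/1/2/missing")
        if "marker_id" not in self.markers.columns:
            raise ValueError("marker metadata requires a marker_id column")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_dosage(self, marker_id: str) -> np.ndarray:
        idx = self.markers.index[self.markers["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"marker {marker_id!r} not found")
        return self.dosages[:, self.markers.index.get_loc(idx[0])]

    def select(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            markers=self.markers.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, np.asarray(mask)],
        )


@dataclass(frozen=True)
class AssociationResult:
    """Spearman association of one marker with one phenotype."""

    marker_id: str
    n: int
    rho: float
    p_nominal: float
    p_bonferroni: float
    genotype_stats: pd.DataFrame
    valid: bool = True


def genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """Counts of (hom other, het, hom effect) among non-missing calls."""
    d = np.asarray(dosage, dtype=float)
    d = d[~np.isnan(d)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def hwe_test(counts: Sequence[int]) -> float:
    """Pearson chi-square (1 df) test of Hardy-Weinberg proportions.

    ``counts`` are (hom_ref, het, hom_alt).  Expected genotype counts come
    from the sample allele frequency; a monomorphic marker returns p = 1
    with a warning.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("no genotyped samples")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        warnings.warn("monomorphic marker; HWE test undefined, returning p=1")
        return 1.0
    expected = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(counts: Sequence[int]) -> float:
    """Exact Hardy-Weinberg test (sum of probabilities <= observed).

    Conditional on allele counts, the number of heterozygotes follows the
    Levene-Haldane distribution; the p-value sums configurations no more
    probable than the observed one.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("no genotyped samples")
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    def logprob(h):
        a = (rare - h) // 2
        b = (2 * n - rare - h) // 2
        return (h * np.log(2) + gammaln(n + 1)
                - gammaln(a + 1) - gammaln(h + 1) - gammaln(b + 1)
                + gammaln(rare + 1) + gammaln(2 * n - rare + 1)
                - gammaln(2 * n + 1))

    logs = logprob(hets)
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_ab][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_p_min: float = 0.05,
    hwe_exact: bool = False,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers failing call-rate, MAF or HWE thresholds.

    Returns the filtered matrix and a per-marker report listing every
    failed rule.  Filtering is idempotent and order-independent: all
    three rules are evaluated on the input matrix.
    """
    d = genotypes.dosages
    n = genotypes.n_samples
    rows = []
    keep = np.ones(genotypes.n_markers, dtype=bool)
    test = hwe_exact_test if hwe_exact else hwe_test
    for j in range(genotypes.n_markers):
        col = d[:, j]
        called = ~np.isnan(col)
        call_rate = called.sum() / n
        reasons = []
        if call_rate < call_rate_min:
            reasons.append("call_rate")
        if called.sum() > 0:
            freq = col[called].sum() / (2 * called.sum())
            maf = min(freq, 1 - freq)
            if maf < maf_min:
                reasons.append("maf")
            counts = genotype_counts(col)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hwe_p = test((counts[2], counts[1], counts[0]))
            if hwe_p < hwe_p_min:
                reasons.append("hwe")
        else:
            maf, hwe_p = np.nan, np.nan
            reasons.append("maf")
        keep[j] = not reasons
        rows.append({
            "marker_id": genotypes.markers["marker_id"].iloc[j],
            "call_rate": call_rate, "maf": maf, "hwe_p": hwe_p,
            "excluded": bool(reasons), "reasons": ",".join(reasons),
        })
    return genotypes.select(keep), pd.DataFrame(rows)


def spearman_association(
    phenotype: Sequence[float],
    dosage: Sequence[float],
    n_tests: int = 1,
    marker_id: str = "",
) -> AssociationResult:
    """Spearman rank correlation of a phenotype with additive dosage.

    Missing values are dropped pairwise; ties get average ranks; the
    p-value uses the t approximation (exact null enumeration is
    impractical with the heavy genotype ties at cohort scale).  A constant
    phenotype or dosage yields a flagged null result.
    """
    x = np.asarray(phenotype, dtype=float)
    g = np.asarray(dosage, dtype=float)
    if x.shape != g.shape:
        raise ValueError("phenotype and dosage lengths differ")
    ok = ~(np.isnan(x) | np.isnan(g))
    x, g = x[ok], g[ok]
    n = x.size
    stats_table = genotype_summary(x, g)
    if n < 10:
        raise ValueError(f"need >= 10 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(g == g[0]):
        return AssociationResult(marker_id, n, np.nan, np.nan, np.nan,
                                 stats_table, valid=False)
    rho, p = stats.spearmanr(x, g)
    return AssociationResult(
        marker_id=marker_id, n=n, rho=float(rho), p_nominal=float(p),
        p_bonferroni=bonferroni(float(p), n_tests),
        genotype_stats=stats_table,
    )


def bonferroni(p_nominal: float, n_tests: int) -> float:
    """Family-wise corrected p-value, min(1, p * n_tests)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(min(1.0, p_nominal * n_tests))


def genotype_summary(
    phenotype: Sequence[float],
    dosage: Sequence[float],
) -> pd.DataFrame:
    """Per-genotype n, mean and SEM of the phenotype (dosage groups 0/1/2)."""
    x = np.asarray(phenotype, dtype=float)
    g = np.asarray(dosage, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(g))
    x, g = x[ok], g[ok]
    rows = []
    for dose in (0, 1, 2):
        vals = x[g == dose]
        n = vals.size
        rows.append({
            "dosage": dose,
            "n": n,
            "mean": float(vals.mean()) if n else np.nan,
            "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else
                   (0.0 if n == 1 else np.nan),
        })
    return pd.DataFrame(rows)


def subsample_consistency(
    phenotype: Sequence[float],
    dosage: Sequence[float],
    labels: Sequence[str],
    n_tests: int = 1,
    marker_id: str = "",
) -> dict[str, AssociationResult]:
    """Association per subsample plus pooled, with sign agreement.

    Returns a mapping label -> result including a ``"pooled"`` entry; the
    pooled result is computed on the simply concatenated samples.  Sign
    disagreement between subsamples is detectable by comparing rho signs.
    """
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two subsample labels")
    x = np.asarray(phenotype, dtype=float)
    g = np.asarray(dosage, dtype=float)
    out: dict[str, AssociationResult] = {}
    for lab in uniq:
        mask = labels == lab
        out[str(lab)] = spearman_association(x[mask], g[mask], n_tests,
                                             marker_id=marker_id)
    out["pooled"] = spearman_association(x, g, n_tests, marker_id=marker_id)
    return out


def associate_markers(
    phenotype: Sequence[float],
    genotypes: GenotypeMatrix,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Spearman association of a phenotype against every marker.

    ``n_tests`` defaults to the number of markers in the (already
    QC-filtered) matrix.  Returns a frame sorted by nominal p-value.
    """
    n_tests = n_tests or genotypes.n_markers
    rows = []
    for j in range(genotypes.n_markers):
        res = spearman_association(
            phenotype, genotypes.dosages[:, j], n_tests,
            marker_id=str(genotypes.markers["marker_id"].iloc[j]),
        )
        rows.append({
            "marker_id": res.marker_id, "n": res.n, "rho": res.rho,
            "p_nominal": res.p_nominal, "p_bonferroni": res.p_bonferroni,
            "valid": res.valid,
        })
    return (pd.DataFrame(rows)
            .sort_values("p_nominal", na_position="last", kind="stable")
            .reset_index(drop=True))
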