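"""Condition-contrast inference for band power spectra.

Implements the dependent-samples cluster-based permutation test over
frequency bins (threshold per-bin paired t values, sum them within
contiguous supra-threshold clusters, and compare the maximum cluster mass
against a sign-flip permutation null), its degenerate single-bin variant
for band-averaged power, paired Cohen's d, and the behavioural statistics
(paired t on per-condition correct-trial counts and power-performance
Pearson correlations).

Exchangeability under the within-subject null is realised by randomly
flipping the sign of each subject's whole difference vector, which swaps
that subject's condition labels while preserving the within-subject
correlation structure.  Monte-Carlo p values use the add-one estimator
``(1 + #{null >= observed}) / (1 + n_perm)`` so that p can never be zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._rng import STAGE_CLUSTER, child_rng

__all__ = [
    "ClusterTestResult",
    "BehaviorStats",
    "dependent_t",
    "cluster_permutation_test",
    "band_permutation_test",
    "cohens_d_paired",
    "behavior_stats",
]


@dataclass
class ClusterTestResult:
    """Outcome of a (possibly single-bin) sign-flip permutation test."""

    band: str
    cluster_masses: list[float]
    cluster_bins: list[np.ndarray]
    null_distribution: np.ndarray
    p_value: float
    effect_size_d: float
    tail: str
    n_permutations: int
    t_per_bin: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class BehaviorStats:
    """Behavioural summary: paired t on correct counts, power-performance r."""

    paired_t: float
    df: int
    p: float
    d: float
    power_performance: dict[str, tuple[float, float]]  # condition -> (r, p)


def dependent_t(cond_a: np.ndarray, cond_b: np.ndarray) -> np.ndarray:
    """Per-bin paired t statistic, ``mean(diff) / (sd(diff)/sqrt(n))``.

    The SD uses an n-1 denominator.  Bins with zero difference variance
    yield ``+/-inf`` (or ``nan`` when the mean is also zero) and a warning,
    flagging the statistic as undefined there.
    """
    a = np.atleast_2d(np.asarray(cond_a, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("conditions must have matching subjects x bins shapes")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    diff = a - b
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    degenerate = (sd == 0) & (mean != 0)
    if np.any(degenerate):
        warnings.warn("zero difference variance in some bins; t undefined there", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[(sd == 0) & (mean == 0)] = 0.0  # identical conditions: no effect
    return t


def _clusters_1d(supra: np.ndarray) -> list[np.ndarray]:
    """Indices of contiguous runs of True in a 1-D boolean mask."""
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return np.split(idx, splits)


def _max_mass(t_vals: np.ndarray, threshold: float, sign: float) -> float:
    """Largest cluster mass of ``sign * t`` above ``threshold`` (0 if none)."""
    t = sign * t_vals
    clusters = _clusters_1d(t > threshold)
    if not clusters:
        return 0.0
    return max(float(t[c].sum()) for c in clusters)


def _perm_t(diff: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Paired t of sign-flipped differences for many flip patterns at once.

    ``diff`` is subjects x bins, ``signs`` is permutations x subjects of
    +/-1.  Flipping changes only the mean term: the sum of squares is
    sign-invariant, so the flipped variance is recovered from it.
    """
    n = diff.shape[0]
    ssq = (diff**2).sum(axis=0)  # bins
    mean = signs @ diff / n  # perms x bins
    var = np.clip((ssq[None, :] - n * mean**2) / (n - 1), 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[(var == 0) & (mean == 0)] = 0.0  # all-zero differences: no effect
    return t


def _tail_sign(tail: str) -> float:
    if tail in ("greater", "one-tailed-greater"):
        return 1.0
    if tail == "less":
        return -1.0
    raise ValueError(f"unsupported tail {tail!r}; use 'greater' or 'less'")


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_perm: int = 10_000,
    cluster_alpha: float = 0.05,
    tail: str = "greater",
    band: str = "broadband",
    seed: int = 0,
) -> ClusterTestResult:
    """Cluster-based dependent-samples permutation test over ordered bins.

    Per-bin paired t values exceeding the one-tailed critical value at
    ``cluster_alpha`` are grouped into contiguous frequency clusters whose
    masses (summed t) are compared against the permutation distribution of
    the maximum cluster mass under whole-vector sign flips.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    a = np.atleast_2d(np.asarray(cond_a, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b, dtype=float))
    t_obs = dependent_t(a, b)
    n = a.shape[0]
    sign = _tail_sign(tail)
    threshold = stats.t.ppf(1 - cluster_alpha, df=n - 1)

    clusters = _clusters_1d(sign * t_obs > threshold)
    masses = [float((sign * t_obs)[c].sum()) for c in clusters]

    diff = a - b
    rng = child_rng(seed, STAGE_CLUSTER)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    t_null = _perm_t(diff, signs)
    null = np.array([_max_mass(row, threshold, sign) for row in t_null])

    if masses:
        obs_max = max(masses)
        p = (1.0 + np.sum(null >= obs_max)) / (1.0 + n_perm)
    else:
        p = 1.0

    # effect size over the detected cluster (all bins if none survived)
    d_bins = clusters[int(np.argmax(masses))] if masses else np.arange(a.shape[1])
    d = cohens_d_paired(a[:, d_bins].mean(axis=1), b[:, d_bins].mean(axis=1))

    return ClusterTestResult(
        band=band,
        cluster_masses=masses,
        cluster_bins=clusters,
        null_distribution=null,
        p_value=float(p),
        effect_size_d=d,
        tail=tail,
        n_permutations=n_perm,
        t_per_bin=t_obs,
    )


def band_permutation_test(
    band_values_a: np.ndarray,
    band_values_b: np.ndarray,
    n_perm: int | str = 10_000,
    tail: str = "greater",
    band: str = "theta",
    seed: int = 0,
) -> ClusterTestResult:
    """Sign-flip permutation test of a single band-averaged paired contrast.

    ``n_perm="exhaustive"`` enumerates all ``2**n`` sign patterns (n <= 20)
    and reports the exact proportion of patterns with a t at least as
    extreme as observed (the identity pattern makes the minimum ``2**-n``).
    """
    a = np.asarray(band_values_a, dtype=float).reshape(-1, 1)
    b = np.asarray(band_values_b, dtype=float).reshape(-1, 1)
    if a.shape != b.shape:
        raise ValueError("mismatched subject counts")
    n = a.shape[0]
    sign = _tail_sign(tail)
    diff = a - b
    t_obs = float(dependent_t(a, b)[0])

    if n_perm == "exhaustive":
        if n > 20:
            raise ValueError("exhaustive enumeration limited to n <= 20 subjects")
        patterns = np.array(np.meshgrid(*([(-1.0, 1.0)] * n), indexing="ij")).reshape(n, -1).T
        t_null = _perm_t(diff, patterns)[:, 0]
        p = float(np.mean(sign * t_null >= sign * t_obs))
        null = sign * t_null
        n_used = patterns.shape[0]
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        rng = child_rng(seed, STAGE_CLUSTER)
        signs = rng.choice((-1.0, 1.0), size=(int(n_perm), n))
        t_null = _perm_t(diff, signs)[:, 0]
        p = (1.0 + np.sum(sign * t_null >= sign * t_obs)) / (1.0 + int(n_perm))
        null = sign * t_null
        n_used = int(n_perm)

    return ClusterTestResult(
        band=band,
        cluster_masses=[sign * t_obs],
        cluster_bins=[np.array([0])],
        null_distribution=null,
        p_value=float(p),
        effect_size_d=cohens_d_paired(a[:, 0], b[:, 0]),
        tail=tail,
        n_permutations=n_used,
        t_per_bin=np.array([t_obs]),
    )


def cohens_d_paired(a: np.ndarray, b: np.ndarray) -> float:
    """Paired Cohen's d: mean(a - b) / sd(a - b), n-1 denominator."""
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if diff.ndim != 1:
        raise ValueError("cohens_d_paired expects per-subject scalars")
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0  # identical conditions: no effect
        raise ValueError("zero variance of paired differences; d undefined")
    return float(diff.mean() / sd)


def behavior_stats(
    correct_counts: np.ndarray,
    theta_power: np.ndarray | None = None,
    proportion_correct: np.ndarray | None = None,
    conditions: tuple[str, str] = ("auditory", "visual"),
) -> BehaviorStats:
    """Behavioural summary statistics across subjects.

    ``correct_counts`` is a subjects x 2 matrix of correct-trial counts per
    condition (column order given by ``conditions``); a two-sided paired t
    compares the conditions.  If per-subject ``theta_power`` and
    ``proportion_correct`` (both subjects x 2) are given, the Pearson
    power-performance correlation is reported per condition.
    """
    counts = np.asarray(correct_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("correct_counts must be subjects x 2")
    n = counts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    diff = counts[:, 0] - counts[:, 1]
    if diff.std(ddof=1) == 0:
        if np.allclose(diff, 0):
            t_stat, p = 0.0, 1.0
        else:
            raise ValueError("degenerate count differences")
        d = 0.0
    else:
        t_stat, p = stats.ttest_rel(counts[:, 0], counts[:, 1])
        d = cohens_d_paired(counts[:, 0], counts[:, 1])

    corr: dict[str, tuple[float, float]] = {}
    if theta_power is not None and proportion_correct is not None:
        power = np.asarray(theta_power, dtype=float)
        perf = np.asarray(proportion_correct, dtype=float)
        if power.shape != (n, 2) or perf.shape != (n, 2):
            raise ValueError("theta_power and proportion_correct must be subjects x 2")
        if n < 3:
            raise ValueError("need at least 3 subjects for correlations")
        for j, cond in enumerate(conditions):
            r, rp = stats.pearsonr(power[:, j], perf[:, j])
            corr[cond] = (float(r), float(rp))

    return BehaviorStats(
        paired_t=float(t_stat), df=n - 1, p=float(p), d=float(d), power_performance=corr
    )
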