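"""Single-trial decoding of attended modality from power spectra.

A k-nearest-neighbour classifier on standardised per-trial band power
(Euclidean metric) is evaluated with stratified, shuffled two-fold
cross-validation.  The neighbour count is grid-searched over odd values
from 1 to 10% of the trial count; chance level is the mean accuracy over
label-permutation runs of the identical CV procedure, and significance is
the add-one permutation p value.  Group-level inference compares observed
and chance accuracies per band with one-sided paired t tests and a
two-factor (band x type) repeated-measures ANOVA with partial eta squared.

The full-dataset standardisation and the reuse of the same data for grid
search and evaluation follow the published procedure; both are mildly
optimistic, and a within-fold standardisation option is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from ._rng import STAGE_DECODE_FOLDS, STAGE_DECODE_PERM, child_int, child_rng
from .cluster_stats import cohens_d_paired
from .spectral import BANDS, FOIBand, PowerSpectrum

__all__ = [
    "DecodingConfig",
    "DecodingResult",
    "GroupDecodingStats",
    "build_features",
    "standardize",
    "make_k_grid",
    "grid_search_k",
    "knn_predict",
    "permutation_decode",
    "decode_subject",
    "group_stats",
]


@dataclass(frozen=True)
class DecodingConfig:
    """Settings of the decoding procedure."""

    foi: str = "broadband"
    n_permutations: int = 1000
    n_folds: int = 2
    shuffle_folds: bool = True
    standardize_mode: str = "population"  # "population" | "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.standardize_mode not in ("population", "sample"):
            raise ValueError("standardize_mode must be 'population' or 'sample'")


@dataclass
class DecodingResult:
    subject_id: str
    foi: str
    best_k: int
    observed_accuracy: float
    permutation_scores: np.ndarray
    chance_level: float
    p_value: float


@dataclass
class GroupDecodingStats:
    """Group-level decoding statistics across subjects and bands."""

    per_foi_t: dict[str, dict[str, float]]  # foi -> {t, df, p, d}
    anova: pd.DataFrame  # two-way within-subject ANOVA table
    n_subjects_significant: int
    table: pd.DataFrame = field(repr=False, default=None)


def build_features(
    spectra: list[PowerSpectrum], cues: list[str], foi: FOIBand | str = "broadband"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial feature matrix of the band's power bins, labels from cues.

    Labels are 1 for attend-auditory, 0 for attend-visual trials.
    """
    if isinstance(foi, str):
        foi = BANDS[foi]
    if len(spectra) != len(cues):
        raise ValueError("one cue per spectrum required")
    freqs = spectra[0].freqs
    mask = (freqs >= foi.low) & (freqs <= foi.high)
    if int(mask.sum()) != int(foi.high - foi.low + 1):
        raise ValueError(f"spectrum is missing bins of band {foi.name}")
    X = np.stack([s.power[mask] for s in spectra])
    y = np.array([1 if c == "auditory" else 0 for c in cues])
    return X, y


def standardize(X: np.ndarray, mode: str = "population") -> np.ndarray:
    """Scale each column to zero mean, unit variance over all trials.

    ``mode`` selects the SD denominator: "population" (n, the scikit-learn
    convention used here by default) or "sample" (n-1).
    """
    X = np.asarray(X, dtype=float)
    ddof = {"population": 0, "sample": 1}[mode]
    sd = X.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature column; cannot standardize")
    return (X - X.mean(axis=0)) / sd


def make_k_grid(n_trials: int) -> list[int]:
    """Odd neighbour counts from 1 to 10% of the trial count, step 2."""
    if n_trials < 10:
        return [1]
    top = n_trials // 10
    return list(range(1, top + 1, 2)) or [1]


def knn_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    k: int,
) -> np.ndarray:
    """Majority vote among the k Euclidean-nearest training points.

    ``k`` must be odd (no two-class voting ties); distance ties are broken
    in favour of the lowest training index, making predictions fully
    deterministic.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd in a two-class problem")
    train = np.atleast_2d(np.asarray(train_features, dtype=float))
    test = np.atleast_2d(np.asarray(test_features, dtype=float))
    y = np.asarray(train_labels)
    if k > len(train):
        raise ValueError("k exceeds the number of training points")
    dist = cdist(test, train)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    votes = (y[order] == 1).sum(axis=1)
    return (votes * 2 > k).astype(int)


def _folds(labels: np.ndarray, n_folds: int, shuffle: bool, seed: int):
    """Stratified fold index pairs; each class must fill every fold."""
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("each class needs at least n_folds members")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=shuffle, random_state=seed if shuffle else None)
    return list(skf.split(np.zeros(len(labels)), labels))


def _cv_accuracies(D: np.ndarray, labels: np.ndarray, folds, ks: list[int]) -> np.ndarray:
    """Mean CV accuracy for every neighbour count in ``ks`` at once.

    ``D`` is the precomputed all-pairs distance matrix; per fold, each test
    row's training distances are stably argsorted (ties -> lowest training
    index) and cumulative vote counts give the accuracy at every k.
    """
    ks_arr = np.asarray(ks)
    acc = np.zeros((len(folds), len(ks)))
    for fi, (tr, te) in enumerate(folds):
        order = np.argsort(D[np.ix_(te, tr)], axis=1, kind="stable")
        pos = np.cumsum(labels[tr][order] == 1, axis=1)  # test x rank
        votes = pos[:, ks_arr - 1]  # positives among first k neighbours
        pred = votes * 2 > ks_arr[None, :]
        acc[fi] = (pred == (labels[te] == 1)[:, None]).mean(axis=0)
    return acc.mean(axis=0)


def grid_search_k(
    features: np.ndarray,
    labels: np.ndarray,
    grid: list[int] | None = None,
    config: DecodingConfig = DecodingConfig(),
    distances: np.ndarray | None = None,
) -> tuple[int, float]:
    """Best neighbour count by stratified two-fold CV score (ties -> smallest k)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if grid is None:
        grid = make_k_grid(len(y))
    if distances is None:
        distances = cdist(X, X)
    folds = _folds(y, config.n_folds, config.shuffle_folds, child_int(config.seed, STAGE_DECODE_FOLDS))
    scores = _cv_accuracies(distances, y, folds, grid)
    best = int(np.argmax(scores))  # argmax takes the first = smallest k on ties
    return grid[best], float(scores[best])


def permutation_decode(
    features: np.ndarray,
    labels: np.ndarray,
    best_k: int,
    config: DecodingConfig = DecodingConfig(),
    subject_id: str = "S01",
) -> DecodingResult:
    """Observed CV accuracy at ``best_k`` against a label-permutation null.

    Labels are globally shuffled for each permutation; the stratified
    shuffled two-fold CV (fresh fold assignment per permutation) is re-run
    and scored at the same ``best_k``.  Chance level is the mean permuted
    accuracy, p the add-one permutation probability.
    """
    if best_k % 2 == 0 or best_k < 1:
        raise ValueError("best_k must be a positive odd integer")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    D = cdist(X, X)

    folds = _folds(y, config.n_folds, config.shuffle_folds, child_int(config.seed, STAGE_DECODE_FOLDS))
    observed = float(_cv_accuracies(D, y, folds, [best_k])[0])

    rng = child_rng(config.seed, STAGE_DECODE_PERM)
    scores = np.empty(config.n_permutations)
    for i in range(config.n_permutations):
        y_perm = rng.permutation(y)
        perm_folds = _folds(
            y_perm, config.n_folds, config.shuffle_folds, child_int(config.seed, STAGE_DECODE_PERM, i)
        )
        scores[i] = _cv_accuracies(D, y_perm, perm_folds, [best_k])[0]

    p = (1.0 + np.sum(scores >= observed)) / (1.0 + config.n_permutations)
    return DecodingResult(
        subject_id=subject_id,
        foi=config.foi,
        best_k=int(best_k),
        observed_accuracy=observed,
        permutation_scores=scores,
        chance_level=float(scores.mean()),
        p_value=float(p),
    )


def decode_subject(
    spectra: list[PowerSpectrum],
    cues: list[str],
    config: DecodingConfig = DecodingConfig(),
    subject_id: str = "S01",
) -> DecodingResult:
    """Full per-subject pipeline: features -> standardise -> grid search -> permutation test."""
    X, y = build_features(spectra, cues, config.foi)
    X = standardize(X, config.standardize_mode)
    best_k, _ = grid_search_k(X, y, config=config)
    return permutation_decode(X, y, best_k, config=config, subject_id=subject_id)


def group_stats(results: list[DecodingResult], alpha: float = 0.05) -> GroupDecodingStats:
    """Group statistics over a complete subjects x bands table of results.

    Per band: one-sided paired t (observed > chance) with paired Cohen's d.
    Across bands: two-factor repeated-measures ANOVA (band x type) with
    partial eta squared.  Also counts subjects whose per-subject permutation
    p is below ``alpha`` in at least one band.
    """
    rows = [
        {
            "subject": r.subject_id,
            "foi": r.foi,
            "observed": r.observed_accuracy,
            "chance": r.chance_level,
            "p": r.p_value,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    fois = list(dict.fromkeys(df["foi"]))
    subjects = list(dict.fromkeys(df["subject"]))
    if len(df) != len(fois) * len(subjects):
        raise ValueError("need one result per subject x band")

    per_foi: dict[str, dict[str, float]] = {}
    for foi in fois:
        sub = df[df["foi"] == foi].set_index("subject").loc[subjects]
        diff = sub["observed"].to_numpy() - sub["chance"].to_numpy()
        if np.allclose(diff, 0):
            t, p = 0.0, 0.5  # identical accuracies: no evidence either way
        else:
            t, p = stats.ttest_rel(sub["observed"], sub["chance"], alternative="greater")
        per_foi[foi] = {
            "t": float(t),
            "df": len(subjects) - 1,
            "p": float(p),
            "d": cohens_d_paired(sub["observed"].to_numpy(), sub["chance"].to_numpy()),
        }

    long = df.melt(
        id_vars=["subject", "foi"],
        value_vars=["observed", "chance"],
        var_name="type",
        value_name="accuracy",
    )
    anova = pg.rm_anova(
        data=long, dv="accuracy", within=["foi", "type"], subject="subject", effsize="np2"
    )

    n_sig = int((df.groupby("subject")["p"].min() < alpha).sum())
    return GroupDecodingStats(per_foi_t=per_foi, anova=anova, n_subjects_significant=n_sig, table=df)
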