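"""Intra- vs inter-individual identifiability statistics.

Given the N x N cross-subject similarity matrix r, intra-individual
similarity is its diagonal, r_intra(i) = r_ii, and inter-individual
similarity is the per-subject mean over others,
r_inter(i) = sum_{j != i} r_ij / (N - 1).  Predictions carry
individual-specific information when r_intra exceeds r_inter on average
(or falls below it, for distance measures).  Four inferential routes are
provided:

- a naive one-tailed one-sample t test on the paired differences
  d_i = r_intra(i) - r_inter(i), df = N - 1 (ignores any dependence induced
  by cross-validation);
- a fold-constrained permutation test that permutes similarity-matrix
  columns only within cross-validation folds, preserving between-fold
  dependence while using the t statistic as a pivotal quantity;
- the corrected resampled t test for comparing two predictors across K
  folds, whose standard error is inflated by the train/test overlap factor
  (1/K + n_test/n_train), df = K - 1;
- per-fold bootstrap lower confidence bounds on the paired fold-wise
  performance difference.

All headline tests are one-tailed: the alternative is that predictions are
*more* similar to their own subject's empirical matrix than to others'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from fcbench.data_model import FoldPartition
from fcbench.similarity import SimilarityMatrix

__all__ = [
    "IdentifiabilityResult",
    "FoldDelta",
    "intra_inter",
    "naive_identifiability_test",
    "fold_constrained_permutation_test",
    "compute_fold_deltas",
    "corrected_resampled_t",
    "fold_bootstrap_comparison",
    "percent_improvement",
    "differential_identifiability",
]


@dataclass(frozen=True)
class IdentifiabilityResult:
    """Summary of an intra- vs inter-individual similarity test."""

    r_intra: np.ndarray
    r_inter: np.ndarray
    scope: str  # "global" | "within_fold"
    direction: str
    mean_intra: float
    mean_inter: float
    t_statistic: float
    p_value: float
    df: float
    cohen_d: float
    method: str  # "naive_t" | "permutation" | "corrected_resampled_t"
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "scope": self.scope,
            "direction": self.direction,
            "mean_intra": self.mean_intra,
            "mean_inter": self.mean_inter,
            "t": self.t_statistic,
            "df": self.df,
            "p": self.p_value,
            "cohen_d": self.cohen_d,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class FoldDelta:
    """Per-fold prediction-performance vector delta(k) = r_intra(k) - r_inter(k).

    Computed from the n x n similarity submatrix of the n subjects in fold k
    only, so that fold-wise comparisons never mix test sets.  Entries are
    sign-oriented so positive always means "more individual-specific",
    regardless of the measure's direction.
    """

    fold: int
    delta: np.ndarray


def _signed_differences(r_intra: np.ndarray, r_inter: np.ndarray, direction: str) -> np.ndarray:
    d = np.asarray(r_intra, dtype=float) - np.asarray(r_inter, dtype=float)
    if direction == "lower_is_more_similar":
        return -d
    if direction == "higher_is_more_similar":
        return d
    raise ValueError(f"unknown direction {direction!r}")


def intra_inter(
    similarity: SimilarityMatrix,
    folds: FoldPartition | None = None,
    scope: str = "global",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject intra- and inter-individual similarity.

    With ``scope="global"`` each r_inter(i) averages the N-1 off-diagonal
    entries of row i.  With ``scope="within_fold"`` both quantities are read
    off the fold's own n x n similarity submatrix, so r_inter(i) averages the
    n-1 same-fold subjects only.
    """
    values = similarity.values
    n = values.shape[0]
    r_intra = np.diagonal(values).astype(float).copy()
    if scope == "global":
        r_inter = (values.sum(axis=1) - r_intra) / (n - 1)
    elif scope == "within_fold":
        if folds is None:
            raise ValueError("within_fold scope requires a fold partition")
        if folds.n_subjects != n:
            raise ValueError("fold partition does not match similarity matrix size")
        r_inter = np.empty(n)
        for k in range(1, folds.n_folds + 1):
            members = folds.members(k)
            if members.size < 2:
                raise ValueError(f"fold {k} has {members.size} subject(s); need >= 2 for within_fold scope")
            block = values[np.ix_(members, members)]
            diag = np.diagonal(block)
            r_inter[members] = (block.sum(axis=1) - diag) / (members.size - 1)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return r_intra, r_inter


def _one_tailed_t(d: np.ndarray) -> tuple[float, float, float, float, bool]:
    """One-sample one-tailed t on differences; returns (t, p, df, cohen_d, degenerate)."""
    d = np.asarray(d, dtype=float)
    n = d.size
    if n < 3:
        raise ValueError(f"need at least 3 paired differences, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = float(n - 1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 0.5, df, 0.0, True
        t = np.inf if mean > 0 else -np.inf
        return float(t), 0.0 if mean > 0 else 1.0, df, np.sign(mean) * np.inf, True
    t = mean / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df))
    return float(t), p, df, mean / sd, False


def naive_identifiability_test(
    r_intra: np.ndarray,
    r_inter: np.ndarray,
    direction: str = "higher_is_more_similar",
    scope: str = "global",
) -> IdentifiabilityResult:
    """One-tailed one-sample t test of H0: mean_i [r_intra(i) - r_inter(i)] = 0.

    The alternative is directional: intra more similar than inter.  For
    distance measures (``lower_is_more_similar``) the differences are
    sign-flipped, so the test operates on r_inter - r_intra.  Cohen's d is
    the one-sample d on the paired differences, mean(d)/sd(d).
    """
    d = _signed_differences(r_intra, r_inter, direction)
    t, p, df, cohen_d, degenerate = _one_tailed_t(d)
    return IdentifiabilityResult(
        r_intra=np.asarray(r_intra, dtype=float),
        r_inter=np.asarray(r_inter, dtype=float),
        scope=scope,
        direction=direction,
        mean_intra=float(np.mean(r_intra)),
        mean_inter=float(np.mean(r_inter)),
        t_statistic=t,
        p_value=p,
        df=df,
        cohen_d=cohen_d,
        method="naive_t",
        degenerate=degenerate,
    )


def fold_constrained_permutation_test(
    similarity: SimilarityMatrix,
    folds: FoldPartition,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Permutation test of the identifiability null, constrained within folds.

    Columns of the similarity matrix are permuted independently within each
    cross-validation fold — never across folds — so the null distribution
    preserves between-fold dependence.  The test statistic is the one-tailed
    t from :func:`naive_identifiability_test` (global scope), a pivotal
    quantity under permutation.  Returns the add-one permutation p value
    (1 + #{t_perm >= t_obs}) / (1 + n_perm) and its normal-approximation
    binomial 95% confidence interval.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    values = similarity.values
    n = values.shape[0]
    if folds.n_subjects != n:
        raise ValueError("fold partition does not match similarity matrix size")
    sizes = folds.fold_sizes()
    if (sizes < 2).any():
        raise ValueError("every fold must contain at least 2 subjects to permute")
    rng = np.random.default_rng(seed)

    def t_of(vals: np.ndarray) -> float:
        diag = np.diagonal(vals)
        r_inter = (vals.sum(axis=1) - diag) / (n - 1)
        d = _signed_differences(diag, r_inter, similarity.direction)
        return _one_tailed_t(d)[0]

    t_obs = t_of(values)
    fold_members = [folds.members(k) for k in range(1, folds.n_folds + 1)]
    count = 0
    col_idx = np.arange(n)
    for _ in range(n_perm):
        perm = col_idx.copy()
        for members in fold_members:
            perm[members] = rng.permutation(members)
        if t_of(values[:, perm]) >= t_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    half = 1.959963984540054 * np.sqrt(p * (1 - p) / n_perm)
    ci = (max(0.0, p - half), min(1.0, p + half))
    return float(p), ci


def compute_fold_deltas(similarity: SimilarityMatrix, folds: FoldPartition) -> list[FoldDelta]:
    """Per-fold performance vectors delta(k), from fold-local similarity submatrices.

    Values are sign-oriented so that positive means more individual-specific,
    which lets distance-based similarities share the downstream machinery.
    """
    out = []
    for k in range(1, folds.n_folds + 1):
        members = folds.members(k)
        if members.size < 2:
            raise ValueError(f"fold {k} has fewer than 2 subjects")
        sub = similarity.submatrix(members)
        r_intra, r_inter = intra_inter(sub, scope="global")
        out.append(FoldDelta(fold=k, delta=_signed_differences(r_intra, r_inter, similarity.direction)))
    return out


def _central(f: str):
    if f == "median":
        return np.median
    if f == "mean":
        return np.mean
    raise ValueError(f"central tendency f must be 'median' or 'mean', got {f!r}")


def corrected_resampled_t(
    delta_model: list[FoldDelta],
    delta_benchmark: list[FoldDelta],
    n_test: int,
    n_train: int,
    f: str = "median",
) -> tuple[float, float, float]:
    """Corrected resampled t test comparing two predictors across K folds.

    For each fold k a summary s_k = f(delta_model(k) - delta_benchmark(k))
    is computed (f is the median by default, robust to the skew of the
    per-subject differences).  The statistic is

        t = mean_k(s_k) / sqrt((1/K + n_test/n_train) * var(s)),

    with var(s) the unbiased variance over folds, distributed as t with
    K - 1 degrees of freedom under H0.  The (1/K + n_test/n_train) factor
    corrects the naive 1/K standard error for the overlap between
    cross-validation training sets.  Returns (t, one-tailed p, df).
    """
    if len(delta_model) != len(delta_benchmark):
        raise ValueError("fold lists have different lengths")
    k_folds = len(delta_model)
    if k_folds < 2:
        raise ValueError(f"need K >= 2 folds, got {k_folds}")
    if n_test <= 0 or n_train <= 0:
        raise ValueError("n_test and n_train must be positive")
    central = _central(f)
    s = np.empty(k_folds)
    for i, (dm, db) in enumerate(zip(delta_model, delta_benchmark)):
        if dm.fold != db.fold:
            raise ValueError(f"fold indices misaligned: {dm.fold} vs {db.fold}")
        if dm.delta.size != db.delta.size:
            raise ValueError(f"fold {dm.fold}: delta vectors have different lengths")
        s[i] = central(dm.delta - db.delta)
    df = float(k_folds - 1)
    var = float(s.var(ddof=1))
    mean = float(s.mean())
    if var == 0.0:
        if mean == 0.0:
            return 0.0, 0.5, df
        return (np.inf, 0.0, df) if mean > 0 else (-np.inf, 1.0, df)
    t = mean / np.sqrt((1.0 / k_folds + n_test / n_train) * var)
    p = float(stats.t.sf(t, df))
    return float(t), p, df


def fold_bootstrap_comparison(
    delta_model: list[FoldDelta],
    delta_benchmark: list[FoldDelta],
    n_boot: int = 10_000,
    seed: int = 0,
    f: str = "median",
) -> tuple[list[tuple[float, bool]], int]:
    """Per-fold bootstrap lower bound on f(delta_model - delta_benchmark).

    For each fold, the n paired per-subject differences are resampled with
    replacement n_boot times; the 5th percentile of the bootstrap f(.)
    distribution is a one-sided 95% lower confidence bound.  A fold is
    flagged significant when its bound exceeds zero.  Returns the per-fold
    (lower bound, significant) list and the count of significant folds.
    """
    if n_boot < 1000:
        raise ValueError(f"n_boot must be >= 1000, got {n_boot}")
    central = _central(f)
    rng = np.random.default_rng(seed)
    results: list[tuple[float, bool]] = []
    n_significant = 0
    for dm, db in zip(delta_model, delta_benchmark):
        if dm.fold != db.fold:
            raise ValueError(f"fold indices misaligned: {dm.fold} vs {db.fold}")
        diff = dm.delta - db.delta
        n = diff.size
        if n < 3:
            raise ValueError(f"fold {dm.fold} has n={n} subjects; need >= 3 to bootstrap")
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = central(diff[idx], axis=1)
        lower = float(np.percentile(boot, 5.0))
        sig = lower > 0.0
        results.append((lower, sig))
        n_significant += int(sig)
    return results, n_significant


def percent_improvement(r_model: float, r_reference: float) -> float:
    """Relative improvement of the model over a reference, in percent.

    (r_model - r_reference) / r_model * 100.  Conventionally applied to mean
    intra-individual similarities of the prediction and of the noisy-mean
    benchmark.
    """
    if r_model == 0:
        raise ValueError("percent improvement undefined for r_model = 0")
    return (r_model - r_reference) / r_model * 100.0


def differential_identifiability(similarity: SimilarityMatrix) -> float:
    """Difference between mean intra- and mean inter-individual similarity.

    mean(diag) - mean(all off-diagonal entries), sign-oriented so positive
    means more individual-specific.  Provided as a descriptive convenience
    only, without a significance test: its two-sample formulation assumes
    independence that cross-validated predictions do not satisfy, which is
    why the paired tests above are preferred.
    """
    values = similarity.values
    n = values.shape[0]
    diag = np.diagonal(values)
    off_mean = (values.sum() - diag.sum()) / (n * (n - 1))
    d = float(diag.mean() - off_mean)
    return -d if similarity.direction == "lower_is_more_similar" else d
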