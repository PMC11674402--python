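"""One-to-one subject matching between predictions and empirical matrices.

A stronger claim than a mean intra/inter gap: can each subject's prediction
be *matched* to their own empirical matrix?  The Hungarian algorithm solves
the optimal one-to-one assignment on the similarity matrix (negated, so the
solver's cost minimization maximizes similarity; distances are used as costs
directly).  The trace of the resulting binary assignment matrix counts
correct matches.

Because matching accuracy falls with the number of candidates, accuracy is
traced over subset sizes n = 2..n_max: for each n, M random same-fold
subsets are matched under the model condition and under a chance condition
in which similarity-matrix columns are randomly permuted first.  Per-n
two-sample t tests compare the two conditions, with Benjamini-Hochberg
control of the false discovery rate across subset sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from fcbench.data_model import FoldPartition
from fcbench.similarity import SimilarityMatrix

__all__ = [
    "MatchingCurve",
    "optimal_assignment",
    "chance_assignment",
    "matching_curve",
    "improvement_vs_chance",
    "write_matching_curve",
]


@dataclass(frozen=True)
class MatchingCurve:
    """Matching accuracy versus subset size, model against chance."""

    subset_sizes: np.ndarray
    accuracy_model: np.ndarray  # mean percent correct per n
    accuracy_null: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray  # Benjamini-Hochberg adjusted
    significant: np.ndarray
    n_subsets: int
    fdr_level: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.subset_sizes,
                "accuracy_model": self.accuracy_model,
                "accuracy_null": self.accuracy_null,
                "t": self.t_statistics,
                "p": self.p_values,
                "q": self.q_values,
                "significant": self.significant,
                "improvement": self.accuracy_model - self.accuracy_null,
            }
        )


def _cost_matrix(similarity: SimilarityMatrix) -> np.ndarray:
    # Hungarian minimizes cost: negate similarities, keep distances as-is.
    if similarity.direction == "higher_is_more_similar":
        return -similarity.values
    return similarity.values


def optimal_assignment(similarity: SimilarityMatrix) -> tuple[np.ndarray, int]:
    """Optimal one-to-one prediction-to-reference assignment (Hungarian).

    Returns the assignment as a permutation array (prediction i is matched
    to reference ``perm[i]``) and the number of correct matches, i.e. the
    count of fixed points perm[i] == i — the trace of the binary assignment
    matrix.
    """
    rows, cols = linear_sum_assignment(_cost_matrix(similarity))
    perm = np.empty_like(cols)
    perm[rows] = cols
    n_correct = int(np.sum(perm == np.arange(perm.size)))
    return perm, n_correct


def chance_assignment(similarity: SimilarityMatrix, seed: int | np.random.Generator = 0) -> int:
    """Fixed-point count after randomly permuting similarity columns.

    Destroys the subject correspondence before solving the assignment, which
    gives the chance condition: the expected number of correct matches of a
    uniformly random permutation is 1 for any n.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = similarity.n_subjects
    shuffle = rng.permutation(n)
    cost = _cost_matrix(similarity)[:, shuffle]
    rows, cols = linear_sum_assignment(cost)
    # the shuffled column labels are taken at face value: the trace of the
    # binary assignment matrix on the permuted similarity is the chance count
    perm = np.empty(n, dtype=int)
    perm[rows] = cols
    return int(np.sum(perm == np.arange(n)))


def matching_curve(
    similarity: SimilarityMatrix,
    folds: FoldPartition,
    n_max: int = 20,
    n_subsets: int = 2500,
    seed: int = 0,
    fdr_level: float = 0.05,
) -> MatchingCurve:
    """Matching accuracy for subset sizes n = 2..n_max, model vs chance.

    For each n, ``n_subsets`` subsets are drawn without replacement within a
    uniformly chosen cross-validation fold (subsets never straddle folds, so
    matching is evaluated under the dependence structure training induced).
    Each subset's n x n sub-similarity matrix is solved exactly (model) and
    after random column permutation (chance).  Per-n equal-variance
    two-sample t tests (df = 2 * n_subsets - 2) compare per-subset percent
    correct between conditions; Benjamini-Hochberg controls the FDR across
    the n_max - 1 sizes.
    """
    sizes = folds.fold_sizes()
    if n_max > int(sizes.min()):
        raise ValueError(
            f"n_max={n_max} exceeds the smallest fold size {int(sizes.min())}"
        )
    if n_max < 2:
        raise ValueError("n_max must be at least 2")
    if n_subsets < 1:
        raise ValueError("n_subsets must be at least 1")
    rng = np.random.default_rng(seed)
    fold_members = [folds.members(k) for k in range(1, folds.n_folds + 1)]

    subset_sizes = np.arange(2, n_max + 1)
    acc_model = np.empty(subset_sizes.size)
    acc_null = np.empty(subset_sizes.size)
    t_stats = np.empty(subset_sizes.size)
    p_vals = np.empty(subset_sizes.size)
    for a, n in enumerate(subset_sizes):
        eligible = [m for m in fold_members if m.size >= n]
        pc_model = np.empty(n_subsets)
        pc_null = np.empty(n_subsets)
        for s in range(n_subsets):
            members = eligible[rng.integers(len(eligible))]
            subset = rng.choice(members, size=n, replace=False)
            sub = similarity.submatrix(subset)
            _, n_correct = optimal_assignment(sub)
            pc_model[s] = 100.0 * n_correct / n
            pc_null[s] = 100.0 * chance_assignment(sub, rng) / n
        acc_model[a] = pc_model.mean()
        acc_null[a] = pc_null.mean()
        t_stats[a], p_two = stats.ttest_ind(pc_model, pc_null, equal_var=True)
        if np.isnan(t_stats[a]):  # both conditions constant (zero variance)
            t_stats[a], p_vals[a] = 0.0, 1.0
        else:
            # one-tailed: model > chance
            p_vals[a] = p_two / 2.0 if t_stats[a] > 0 else 1.0 - p_two / 2.0
    significant, q_vals, _, _ = multipletests(p_vals, alpha=fdr_level, method="fdr_bh")
    return MatchingCurve(
        subset_sizes=subset_sizes,
        accuracy_model=acc_model,
        accuracy_null=acc_null,
        t_statistics=t_stats,
        p_values=p_vals,
        q_values=q_vals,
        significant=significant,
        n_subsets=n_subsets,
        fdr_level=fdr_level,
        seed=seed,
    )


def improvement_vs_chance(curve: MatchingCurve) -> tuple[np.ndarray, float, float]:
    """Accuracy improvement over chance, per subset size and pooled.

    Returns (per-n improvement in percentage points, pooled mean, pooled
    standard deviation across subset sizes).
    """
    per_n = curve.accuracy_model - curve.accuracy_null
    return per_n, float(per_n.mean()), float(per_n.std(ddof=1))


def write_matching_curve(curve: MatchingCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(Path(path), sep="\t", index=False)
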