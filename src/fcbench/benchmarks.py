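"""Fold-respecting benchmark predictions and standardization.

Two control conditions calibrate any claim that predictions carry
individual-specific information:

- the *group-mean* benchmark substitutes each subject's prediction with the
  elementwise mean eFC over that subject's training set (all subjects outside
  their cross-validation fold);
- the *noisy-mean* benchmark adds independent zero-mean Gaussian noise to the
  group mean, with per-element standard deviations matched to those observed
  in the training-set eFC.  This mimics inter-individual variability without
  injecting individual information.

``fold_zscore`` standardizes matrices across participants using training-set
moments only, so that group-average structure — which dominates raw FC
correlations — is removed without leaking test-fold data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fcbench.data_model import Cohort, FoldPartition

__all__ = ["FoldMoments", "compute_fold_moments", "fold_mean_prediction",
           "noisy_mean_prediction", "fold_zscore"]

ZSCORE_STD_FLOOR = 1e-12


@dataclass(frozen=True)
class FoldMoments:
    """Training-set elementwise moments of a matrix stack for one fold.

    ``mean`` and ``std`` are p x p matrices computed across the subjects
    outside fold ``fold``; ``n_train`` is the training-set size.  ``std``
    uses the unbiased (n-1) denominator.
    """

    fold: int
    mean: np.ndarray
    std: np.ndarray
    n_train: int


def compute_fold_moments(stack: np.ndarray, folds: FoldPartition) -> list[FoldMoments]:
    """Per-fold elementwise training mean and standard deviation of a stack."""
    stack = np.asarray(stack, dtype=float)
    out = []
    for k in range(1, folds.n_folds + 1):
        train = folds.complement(k)
        if train.size < 2:
            raise ValueError(
                f"training set of fold {k} has {train.size} subjects; need >= 2"
            )
        sub = stack[train]
        out.append(
            FoldMoments(
                fold=k,
                mean=sub.mean(axis=0),
                std=sub.std(axis=0, ddof=1),
                n_train=int(train.size),
            )
        )
    return out


def fold_mean_prediction(cohort: Cohort) -> np.ndarray:
    """Group-mean benchmark: each subject receives their training-set mean eFC.

    The diagonal is set to 1 (correlation scale).  Uses no information from
    the subject's own fold.
    """
    moments = compute_fold_moments(cohort.efc, cohort.folds)
    out = np.empty_like(cohort.efc)
    for m in moments:
        pred = m.mean.copy()
        np.fill_diagonal(pred, 1.0)
        out[cohort.folds.members(m.fold)] = pred
    return out


def noisy_mean_prediction(cohort: Cohort, seed: int) -> np.ndarray:
    """Noisy group-mean benchmark: training mean plus matched Gaussian noise.

    Independent zero-mean Gaussian noise is added to each off-diagonal
    element, with standard deviation equal to that element's training-set
    standard deviation; noise is drawn once per upper-triangle element and
    mirrored, keeping the matrix symmetric.  Noise is not clipped to [-1, 1]
    so the matched-variance property holds exactly.
    """
    rng = np.random.default_rng(seed)
    base = fold_mean_prediction(cohort)
    moments = {m.fold: m for m in compute_fold_moments(cohort.efc, cohort.folds)}
    p = cohort.n_nodes
    iu = np.triu_indices(p, k=1)
    out = base.copy()
    for i in range(cohort.n_subjects):
        std_upper = moments[int(cohort.folds.assignment[i])].std[iu]
        noise = rng.standard_normal(iu[0].size) * std_upper
        mat = out[i]
        mat[iu] += noise
        mat.T[iu] = mat[iu]
    return out


def fold_zscore(
    stack: np.ndarray,
    folds: FoldPartition,
    moments_source: np.ndarray | None = None,
) -> np.ndarray:
    """Standardize each off-diagonal element across participants, fold-wise.

    For a subject in fold k, each off-diagonal element e becomes
    (e - mean) / std with moments computed over the training complement of
    fold k from ``moments_source`` (the stack itself by default, i.e. each
    modality is standardized with its own moments).  Elements whose training
    standard deviation is below 1e-12 are set to 0; the diagonal is set to 0.
    """
    stack = np.asarray(stack, dtype=float)
    if moments_source is None:
        moments_source = stack
    moments_source = np.asarray(moments_source, dtype=float)
    if moments_source.shape != stack.shape:
        raise ValueError(
            f"moments_source shape {moments_source.shape} differs from stack {stack.shape}"
        )
    out = np.empty_like(stack)
    for m in compute_fold_moments(moments_source, folds):
        members = folds.members(m.fold)
        std = m.std
        degenerate = std < ZSCORE_STD_FLOOR
        safe_std = np.where(degenerate, 1.0, std)
        z = (stack[members] - m.mean) / safe_std
        z[:, degenerate] = 0.0
        out[members] = z
    idx = np.arange(stack.shape[1])
    out[:, idx, idx] = 0.0
    return out
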