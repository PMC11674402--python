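"""Synthetic cohorts with known group/individual covariance structure.

Resting-state functional networks are dominated by a common group-level
organization with smaller but stable individual effects.  The generator
reproduces that regime structurally: each subject's empirical FC is the
sample correlation matrix of ``t_samples`` latent Gaussian observations
whose covariance mixes a shared group component (weight 1 - alpha) with a
subject-specific component (weight alpha).  Predicted FC is built the same
way from the subject's individual component blended, with fidelity beta,
against a fresh nuisance component — so beta = 0 yields predictions with
realistic inter-individual variability but *no* individual information (the
null condition), and beta = 1 yields predictions whose latent covariance
matches the subject's exactly.  Sparse nonnegative structural connectomes
are coupled to the same latent covariance: edges are thresholded at the top
``sc_density`` fraction and surviving weights rank-transformed to a normal
distribution (mirroring how streamline counts are conventionally
renormalized).

Realizing correlation matrices through latent samples (rather than
perturbing a template matrix elementwise) guarantees symmetric, unit
diagonal, positive semidefinite output by construction, and with
t_samples > n_nodes every matrix is full rank, so Riemannian distances need
no more than numerically negligible eigenvalue flooring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import stats

from fcbench.data_model import Cohort, FoldPartition

__all__ = ["SyntheticSpec", "GroundTruth", "generate_cohort", "null_cohort"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_subjects : int
        Cohort size N (>= 4).
    n_nodes : int
        Parcellation size p (>= 5); default 68, a standard cortical atlas.
    t_samples : int
        Latent observations per subject; must exceed ``n_nodes`` so sample
        correlation matrices are full rank.  Default 300.
    alpha : float in [0, 1]
        Share of each subject's latent covariance contributed by their
        individual component; 1 - alpha is the group share.  Default 0.05:
        individual differences in resting-state FC are small relative to
        the shared group organization (on the order of a few percent of
        variance in healthy cohorts).
    beta : float in [0, 1]
        Fidelity of the prediction to the subject's individual component;
        beta = 0 is the null condition (no individual information).
    sc_density : float in (0, 1]
        Fraction of off-diagonal edges retained in the structural connectome.
    sc_noise : float >= 0
        Scale of symmetric Gaussian noise added to the SC edge scores before
        thresholding, relative to the latent covariance scale.
    n_folds : int
        Cross-validation fold count K; folds are assigned by blocked
        round-robin over the subject order.
    seed : int
        Seed for all randomness; cohorts are bit-reproducible given a spec.
    factor_rank : int or None
        Rank of the random factor matrices behind each covariance component;
        None selects max(1, n_nodes // 4), giving realistic eigenvalue decay.
    """

    n_subjects: int = 100
    n_nodes: int = 68
    t_samples: int = 300
    alpha: float = 0.05
    beta: float = 0.75
    sc_density: float = 0.35
    sc_noise: float = 0.5
    n_folds: int = 10
    seed: int = 0
    factor_rank: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError(f"n_subjects must be >= 4, got {self.n_subjects}")
        if self.n_nodes < 5:
            raise ValueError(f"n_nodes must be >= 5, got {self.n_nodes}")
        if self.t_samples <= self.n_nodes:
            raise ValueError(
                f"t_samples ({self.t_samples}) must exceed n_nodes ({self.n_nodes}) "
                "for full-rank sample correlation matrices"
            )
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 < self.sc_density <= 1.0:
            raise ValueError(f"sc_density must be in (0, 1], got {self.sc_density}")
        if self.sc_noise < 0:
            raise ValueError(f"sc_noise must be nonnegative, got {self.sc_noise}")
        if self.n_folds < 1 or self.n_folds > self.n_subjects // 2:
            raise ValueError(
                f"n_folds must be in 1..{self.n_subjects // 2} so each fold has >= 2 subjects"
            )

    @property
    def rank(self) -> int:
        return self.factor_rank if self.factor_rank is not None else max(1, self.n_nodes // 4)


@dataclass(frozen=True)
class GroundTruth:
    """Latent structure behind a generated cohort, for recovery testing."""

    alpha: float
    beta: float
    group_covariance: np.ndarray
    individual_covariances: np.ndarray  # (N, p, p)
    folds: FoldPartition

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "beta": self.beta,
            "group_covariance": self.group_covariance.tolist(),
            "individual_covariances": self.individual_covariances.tolist(),
            "fold_assignment": self.folds.assignment.tolist(),
            "n_folds": self.folds.n_folds,
        }
        Path(path).write_text(json.dumps(payload) + "\n")


def _random_covariance(rng: np.random.Generator, p: int, rank: int) -> np.ndarray:
    """A A' + I from a random p x rank factor; well conditioned, decaying spectrum."""
    a = rng.standard_normal((p, rank))
    return a @ a.T + np.eye(p)


def _sample_correlation(rng: np.random.Generator, cov: np.ndarray, t: int) -> np.ndarray:
    chol = np.linalg.cholesky(cov)
    x = rng.standard_normal((t, cov.shape[0])) @ chol.T
    return np.corrcoef(x, rowvar=False)


def _rank_to_normal(values: np.ndarray) -> np.ndarray:
    """Map values to standard normal quantiles by rank (Blom-style), then shift >= 0."""
    order = stats.rankdata(values, method="average")
    z = stats.norm.ppf((order - 0.375) / (values.size + 0.25))
    return z - z.min() + 0.05  # strictly positive weights; zeros mean absent edges


def _blocked_folds(n: int, k: int) -> FoldPartition:
    assignment = np.concatenate(
        [np.full(block.size, i + 1) for i, block in enumerate(np.array_split(np.arange(n), k))]
    )
    return FoldPartition(n_folds=k, assignment=assignment)


def generate_cohort(spec: SyntheticSpec) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort (eFC, pFC, SC stacks) with known latent structure.

    eFC_i is the sample correlation of t draws with latent covariance
    (1-alpha) Sigma_G + alpha Sigma_i; pFC_i uses an independent draw with
    the individual part replaced by beta Sigma_i + (1-beta) Sigma_tilde_i
    (Sigma_tilde_i a fresh nuisance component); SC_i scores edges by the
    subject's latent covariance plus noise, keeps the densest sc_density
    fraction, and rank-transforms surviving weights to a normal shape.
    Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, t, r = spec.n_subjects, spec.n_nodes, spec.t_samples, spec.rank

    sigma_g = _random_covariance(rng, p, r)
    sigma_i = np.stack([_random_covariance(rng, p, r) for _ in range(n)])
    sigma_nuisance = np.stack([_random_covariance(rng, p, r) for _ in range(n)])

    efc = np.empty((n, p, p))
    pfc = np.empty((n, p, p))
    sc = np.empty((n, p, p))
    iu = np.triu_indices(p, k=1)
    n_edges = iu[0].size
    n_keep = max(3, int(round(spec.sc_density * n_edges)))

    for i in range(n):
        cov_e = (1 - spec.alpha) * sigma_g + spec.alpha * sigma_i[i]
        cov_p = (1 - spec.alpha) * sigma_g + spec.alpha * (
            spec.beta * sigma_i[i] + (1 - spec.beta) * sigma_nuisance[i]
        )
        efc[i] = _sample_correlation(rng, cov_e, t)
        pfc[i] = _sample_correlation(rng, cov_p, t)

        score = cov_e[iu] + spec.sc_noise * rng.standard_normal(n_edges)
        keep = np.argsort(score)[-n_keep:]
        weights = np.zeros(n_edges)
        weights[keep] = _rank_to_normal(score[keep])
        mat = np.zeros((p, p))
        mat[iu] = weights
        sc[i] = mat + mat.T

    # exact symmetry and unit diagonals for the correlation stacks
    efc = (efc + efc.transpose(0, 2, 1)) / 2.0
    pfc = (pfc + pfc.transpose(0, 2, 1)) / 2.0
    idx = np.arange(p)
    efc[:, idx, idx] = 1.0
    pfc[:, idx, idx] = 1.0

    folds = _blocked_folds(n, spec.n_folds)
    cohort = Cohort(
        subject_ids=[f"sub-{i + 1:04d}" for i in range(n)],
        efc=efc,
        pfc=pfc,
        sc=sc,
        folds=folds,
    )
    truth = GroundTruth(
        alpha=spec.alpha,
        beta=spec.beta,
        group_covariance=sigma_g,
        individual_covariances=sigma_i,
        folds=folds,
    )
    return cohort, truth


def null_cohort(spec: SyntheticSpec) -> tuple[Cohort, GroundTruth]:
    """Convenience: the same generator with beta forced to 0.

    Predictions are then statistically exchangeable across subjects given
    the group component — the regime in which identifiability tests should
    reject only at their nominal rate.
    """
    return generate_cohort(replace(spec, beta=0.0))
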