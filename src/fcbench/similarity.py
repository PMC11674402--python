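"""Similarity and distance measures between connectivity matrices.

Two measures are provided.  The Pearson measure vectorizes the strict upper
triangle of each matrix (the diagonal of an FC matrix is an uninformative
constant) and correlates the two vectors; higher values mean more similar.
The log-Euclidean Riemannian metric (LERM) treats correlation matrices as
points on the manifold of symmetric positive-definite (SPD) matrices and
measures the Frobenius norm of the difference of their matrix logarithms;
lower values mean more similar.

``build_similarity`` assembles the N x N cross-subject similarity matrix
whose (i, j) entry compares the *prediction* of subject i against the
*empirical* matrix of subject j.  Its diagonal holds intra-individual
similarities and its off-diagonal entries inter-individual similarities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

__all__ = [
    "SimilarityMatrix",
    "vectorize_offdiag",
    "pearson_similarity",
    "masked_pearson",
    "spd_project",
    "lerm_distance",
    "build_similarity",
    "write_similarity",
    "read_similarity",
]

DEFAULT_SPD_FLOOR = 1e-6


class SimilarityError(ValueError):
    pass


@dataclass(frozen=True)
class SimilarityMatrix:
    """N x N cross-subject similarity under a named measure.

    ``values[i, j]`` compares the prediction of subject i with the empirical
    reference of subject j.  ``direction`` records whether larger entries mean
    more similar (Pearson) or less similar (LERM distance).
    """

    values: np.ndarray
    measure: str  # "pearson" | "lerm"
    direction: str  # "higher_is_more_similar" | "lower_is_more_similar"
    subject_ids: list[str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise SimilarityError(f"similarity matrix must be square, got {values.shape}")
        if len(self.subject_ids) != values.shape[0]:
            raise SimilarityError("subject_ids length must match matrix size")
        if not np.isfinite(values).all():
            raise SimilarityError("similarity matrix contains non-finite entries")
        if self.measure not in ("pearson", "lerm"):
            raise SimilarityError(f"unknown measure {self.measure!r}")
        expected = "higher_is_more_similar" if self.measure == "pearson" else "lower_is_more_similar"
        if self.direction != expected:
            raise SimilarityError(f"measure {self.measure!r} requires direction {expected!r}")

    @property
    def n_subjects(self) -> int:
        return int(self.values.shape[0])

    def submatrix(self, indices: np.ndarray) -> "SimilarityMatrix":
        idx = np.asarray(indices, dtype=int)
        return SimilarityMatrix(
            values=self.values[np.ix_(idx, idx)],
            measure=self.measure,
            direction=self.direction,
            subject_ids=[self.subject_ids[i] for i in idx],
        )


def vectorize_offdiag(matrix: np.ndarray) -> np.ndarray:
    """Strict upper-triangle entries of a square matrix, row-major, diagonal excluded.

    For a p x p matrix the result has length p(p-1)/2 (p = 68 gives 2278).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise SimilarityError(f"expected a square matrix, got shape {matrix.shape}")
    p = matrix.shape[0]
    if p < 3:
        raise SimilarityError(f"need p >= 3 nodes, got p={p}")
    iu = np.triu_indices(p, k=1)
    return matrix[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    nx = float(np.sqrt(x @ x))
    ny = float(np.sqrt(y @ y))
    if nx == 0.0 or ny == 0.0:
        raise SimilarityError("correlation undefined: zero-variance off-diagonal vector")
    return float(np.clip((x @ y) / (nx * ny), -1.0, 1.0))


def pearson_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of the off-diagonal vectors of two matrices."""
    va = vectorize_offdiag(a)
    vb = vectorize_offdiag(b)
    if va.size != vb.size:
        raise SimilarityError("matrices have different dimensions")
    return _pearson(va, vb)


def masked_pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation restricted to off-diagonal positions where ``mask`` is true.

    Used to constrain SC-to-eFC correlations to the nonzero SC edges of an
    individual.  Requires at least 3 selected upper-triangle positions and
    non-constant masked vectors.
    """
    va = vectorize_offdiag(a)
    vb = vectorize_offdiag(b)
    vm = vectorize_offdiag(np.asarray(mask, dtype=float)) > 0.5
    if va.size != vb.size or va.size != vm.size:
        raise SimilarityError("matrix/mask dimensions disagree")
    if int(vm.sum()) < 3:
        raise SimilarityError(f"mask selects {int(vm.sum())} off-diagonal entries; need >= 3")
    return _pearson(va[vm], vb[vm])


def spd_project(matrix: np.ndarray, floor: float = DEFAULT_SPD_FLOOR) -> np.ndarray:
    """Project a symmetric matrix onto the SPD cone by flooring eigenvalues.

    Eigenvalues below ``floor * max(lambda_max, 1)`` are raised to that level
    and the matrix reconstructed.  Idempotent on SPD inputs whose spectrum
    already clears the floor.  Predicted FC matrices are not guaranteed
    positive definite; this makes the matrix logarithm well defined.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise SimilarityError(f"expected a square matrix, got shape {matrix.shape}")
    if float(np.abs(matrix - matrix.T).max()) > 1e-8:
        raise SimilarityError("spd_project requires a symmetric input")
    if floor <= 0:
        raise SimilarityError("floor must be positive")
    sym = (matrix + matrix.T) / 2.0
    eigval, eigvec = np.linalg.eigh(sym)
    cutoff = floor * max(float(eigval[-1]), 1.0)
    if eigval[0] >= cutoff:
        return sym
    clipped = np.maximum(eigval, cutoff)
    out = (eigvec * clipped) @ eigvec.T
    return (out + out.T) / 2.0


def _spd_logm(matrix: np.ndarray) -> np.ndarray:
    eigval, eigvec = np.linalg.eigh(matrix)
    if eigval[0] <= 0:
        raise SimilarityError(
            f"matrix logarithm undefined: non-positive eigenvalue {eigval[0]:.3g} "
            "(apply spd_project first)"
        )
    return (eigvec * np.log(eigval)) @ eigvec.T


def lerm_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Log-Euclidean Riemannian metric between two SPD matrices.

    d(A, B) = || Log(A) - Log(B) ||_F, with Log the matrix logarithm.  A true
    metric on SPD matrices; callers are expected to pass inputs through
    :func:`spd_project`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise SimilarityError("matrices have different dimensions")
    return float(np.linalg.norm(_spd_logm(a) - _spd_logm(b), ord="fro"))


def lerm_distance_logm_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """LERM via scipy's general (Schur-based) matrix logarithm.

    Independent of the eigendecomposition route in :func:`lerm_distance`;
    retained as a cross-check.
    """
    la = scipy.linalg.logm(np.asarray(a, dtype=float))
    lb = scipy.linalg.logm(np.asarray(b, dtype=float))
    return float(np.linalg.norm(np.real(la) - np.real(lb), ord="fro"))


def _pearson_cross(pred_vecs: np.ndarray, ref_vecs: np.ndarray) -> np.ndarray:
    """Row-wise standardization + matmul: (i, j) = corr(pred i, ref j)."""
    def standardize(v: np.ndarray) -> np.ndarray:
        c = v - v.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(c, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise SimilarityError("correlation undefined: zero-variance off-diagonal vector")
        return c / norms

    return np.clip(standardize(pred_vecs) @ standardize(ref_vecs).T, -1.0, 1.0)


def build_similarity(
    predictions: np.ndarray,
    references: np.ndarray,
    subject_ids: list[str] | None = None,
    measure: str = "pearson",
    mask_policy: str = "none",
    spd_floor: float = DEFAULT_SPD_FLOOR,
) -> SimilarityMatrix:
    """Build the N x N cross-subject similarity matrix.

    Parameters
    ----------
    predictions, references : ndarray, shape (N, p, p)
        Aligned stacks; entry (i, j) of the result compares prediction i with
        reference j.
    measure : {"pearson", "lerm"}
    mask_policy : {"none", "per_prediction_nonzero"}
        With ``per_prediction_nonzero`` (Pearson only), row i restricts every
        correlation to the nonzero off-diagonal pattern of prediction i — the
        convention for sparse SC-to-eFC comparison.
    spd_floor : float
        Relative eigenvalue floor applied (LERM only) before the matrix log.
    """
    predictions = np.asarray(predictions, dtype=float)
    references = np.asarray(references, dtype=float)
    if predictions.shape != references.shape or predictions.ndim != 3:
        raise SimilarityError(
            f"stacks must be aligned (N, p, p); got {predictions.shape} vs {references.shape}"
        )
    n = predictions.shape[0]
    if subject_ids is None:
        subject_ids = [f"s{i:04d}" for i in range(n)]
    if mask_policy not in ("none", "per_prediction_nonzero"):
        raise SimilarityError(f"unknown mask_policy {mask_policy!r}")
    if mask_policy == "per_prediction_nonzero" and measure != "pearson":
        raise SimilarityError("mask_policy per_prediction_nonzero requires measure='pearson'")

    if measure == "pearson":
        pred_vecs = np.stack([vectorize_offdiag(m) for m in predictions])
        ref_vecs = np.stack([vectorize_offdiag(m) for m in references])
        if mask_policy == "none":
            values = _pearson_cross(pred_vecs, ref_vecs)
        else:
            values = np.empty((n, n))
            for i in range(n):
                mask = pred_vecs[i] != 0
                if int(mask.sum()) < 3:
                    raise SimilarityError(
                        f"prediction {subject_ids[i]!r} has {int(mask.sum())} nonzero "
                        "off-diagonal entries; need >= 3 for masked correlation"
                    )
                values[i] = _pearson_cross(pred_vecs[i : i + 1, mask], ref_vecs[:, mask])[0]
        direction = "higher_is_more_similar"
    elif measure == "lerm":
        logs_pred = [_spd_logm(spd_project(m, spd_floor)) for m in predictions]
        logs_ref = [_spd_logm(spd_project(m, spd_floor)) for m in references]
        lp = np.stack(logs_pred).reshape(n, -1)
        lr = np.stack(logs_ref).reshape(n, -1)
        sq = (
            np.sum(lp**2, axis=1)[:, None]
            + np.sum(lr**2, axis=1)[None, :]
            - 2.0 * lp @ lr.T
        )
        values = np.sqrt(np.maximum(sq, 0.0))
        direction = "lower_is_more_similar"
    else:
        raise SimilarityError(f"unknown measure {measure!r}")

    return SimilarityMatrix(
        values=values, measure=measure, direction=direction, subject_ids=list(subject_ids)
    )


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write the matrix as tab-delimited text plus a JSON sidecar with metadata."""
    path = Path(path)
    np.savetxt(path, sim.values, delimiter="\t", fmt="%.17g")
    sidecar = {
        "measure": sim.measure,
        "direction": sim.direction,
        "subject_ids": sim.subject_ids,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar) + "\n")


def read_similarity(path: str | Path) -> SimilarityMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return SimilarityMatrix(values=values, subject_ids=meta["subject_ids"],
                            measure=meta["measure"], direction=meta["direction"])
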