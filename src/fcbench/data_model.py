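"""Cohort data structures, manifest/matrix I/O, and validation.

A cohort is an aligned stack of per-subject square connectivity matrices:
empirical functional connectivity (eFC, Pearson-correlation scale, unit
diagonal), predicted functional connectivity (pFC), and optionally a
structural connectome (SC, nonnegative weights, zeros meaning absent edges),
together with a cross-validation fold partition over subjects.

Matrices are exchanged as headerless delimited text (comma or tab,
auto-detected), one file per subject per modality, tied together by a
tab-separated manifest.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-8

MANIFEST_COLUMNS = ["subject_id", "fold", "efc_path", "pfc_path", "sc_path"]


class CohortValidationError(ValueError):
    """Base class for cohort validation failures."""


class MissingFileError(CohortValidationError):
    pass


class NonSquareMatrixError(CohortValidationError):
    pass


class DimensionMismatchError(CohortValidationError):
    pass


class NonFiniteEntriesError(CohortValidationError):
    pass


class DuplicateSubjectError(CohortValidationError):
    pass


class FoldLabelError(CohortValidationError):
    pass


class AsymmetryError(CohortValidationError):
    pass


@dataclass(frozen=True)
class FoldPartition:
    """Cross-validation partition: ``assignment[i]`` is subject i's fold in 1..K."""

    n_folds: int
    assignment: np.ndarray

    def __post_init__(self) -> None:
        assignment = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", assignment)
        if self.n_folds < 1:
            raise FoldLabelError("fold count must be a positive integer")
        present = set(np.unique(assignment).tolist())
        expected = set(range(1, self.n_folds + 1))
        if present != expected:
            raise FoldLabelError(
                f"fold labels must cover 1..{self.n_folds} exactly; found {sorted(present)}"
            )

    @property
    def n_subjects(self) -> int:
        return int(self.assignment.size)

    def members(self, k: int) -> np.ndarray:
        """Indices of subjects in fold ``k`` (test set of fold k)."""
        return np.flatnonzero(self.assignment == k)

    def complement(self, k: int) -> np.ndarray:
        """Indices of subjects outside fold ``k`` (training set of fold k)."""
        return np.flatnonzero(self.assignment != k)

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_folds + 1)[1:]


@dataclass(frozen=True)
class ValidationFinding:
    code: str
    subject: str | None
    message: str


@dataclass
class Cohort:
    """Aligned per-subject connectivity stacks with a fold partition.

    Attributes
    ----------
    subject_ids : list of str
        Unique labels, in manifest order.
    efc : ndarray, shape (N, p, p)
        Empirical FC; symmetric, unit diagonal, off-diagonals in [-1, 1].
    pfc : ndarray, shape (N, p, p)
        Predicted FC; symmetric (diagonal ignored by all measures).
    sc : ndarray, shape (N, p, p), optional
        Structural connectome; symmetric, nonnegative, zeros = absent edges.
    folds : FoldPartition
    """

    subject_ids: list[str]
    efc: np.ndarray
    pfc: np.ndarray
    folds: FoldPartition
    sc: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.efc = np.asarray(self.efc, dtype=float)
        self.pfc = np.asarray(self.pfc, dtype=float)
        if self.sc is not None:
            self.sc = np.asarray(self.sc, dtype=float)
        findings = validate_cohort(self)
        fatal = [f for f in findings if f.code in _FATAL_CODES]
        if fatal:
            raise CohortValidationError(
                "; ".join(f"[{f.code}] {f.message}" for f in fatal)
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_nodes(self) -> int:
        return int(self.efc.shape[1])

    def stacks(self) -> dict[str, np.ndarray]:
        out = {"efc": self.efc, "pfc": self.pfc}
        if self.sc is not None:
            out["sc"] = self.sc
        return out


_FATAL_CODES = {
    "too_few_subjects",
    "too_few_nodes",
    "shape_mismatch",
    "duplicate_subject",
    "fold_mismatch",
    "non_finite",
}


def validate_cohort(cohort: Cohort) -> list[ValidationFinding]:
    """Check all cohort invariants; return structured findings (empty iff valid).

    Reported codes: too_few_subjects, too_few_nodes, shape_mismatch,
    duplicate_subject, fold_mismatch, non_finite, diagonal, range, symmetry,
    negative_sc.
    """
    findings: list[ValidationFinding] = []
    ids = cohort.subject_ids
    n = len(ids)
    if n < 2:
        findings.append(
            ValidationFinding("too_few_subjects", None, f"cohort has N={n}, need N >= 2")
        )
    if len(set(ids)) != n:
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        findings.append(
            ValidationFinding("duplicate_subject", dupes[0], f"duplicate subject ids: {dupes}")
        )

    stacks = cohort.stacks()
    shapes = {name: s.shape for name, s in stacks.items()}
    ref = cohort.efc.shape
    if len(ref) != 3 or ref[1] != ref[2] or any(s != (ref[0], ref[1], ref[2]) for s in shapes.values()):
        findings.append(
            ValidationFinding("shape_mismatch", None, f"stack shapes disagree: {shapes}")
        )
        return findings
    if ref[0] != n:
        findings.append(
            ValidationFinding("shape_mismatch", None, f"{ref[0]} matrices for {n} subject ids")
        )
        return findings
    p = ref[1]
    if p < 3:
        findings.append(ValidationFinding("too_few_nodes", None, f"p={p}, need p >= 3"))
    if cohort.folds.n_subjects != n:
        findings.append(
            ValidationFinding("fold_mismatch", None, "fold assignment length differs from N")
        )

    for name, stack in stacks.items():
        bad = ~np.isfinite(stack)
        if bad.any():
            for i in np.flatnonzero(bad.any(axis=(1, 2))):
                findings.append(
                    ValidationFinding("non_finite", ids[i], f"{name} of {ids[i]} has NaN/Inf entries")
                )
        asym = np.abs(stack - stack.transpose(0, 2, 1)).max(axis=(1, 2))
        for i in np.flatnonzero(asym > SYMMETRY_TOL):
            findings.append(
                ValidationFinding(
                    "symmetry", ids[i], f"{name} of {ids[i]} asymmetric by {asym[i]:.3g}"
                )
            )

    diag = np.abs(np.diagonal(cohort.efc, axis1=1, axis2=2) - 1.0).max(axis=1)
    for i in np.flatnonzero(diag > SYMMETRY_TOL):
        findings.append(
            ValidationFinding("diagonal", ids[i], f"efc diagonal of {ids[i]} deviates from 1 by {diag[i]:.3g}")
        )
    off = ~np.eye(p, dtype=bool)
    with np.errstate(invalid="ignore"):
        out_of_range = np.abs(cohort.efc[:, off]) > 1.0 + SYMMETRY_TOL
    for i in np.flatnonzero(out_of_range.any(axis=1)):
        findings.append(
            ValidationFinding("range", ids[i], f"efc of {ids[i]} has off-diagonal entries outside [-1, 1]")
        )
    if cohort.sc is not None:
        with np.errstate(invalid="ignore"):
            neg = cohort.sc < -SYMMETRY_TOL
        for i in np.flatnonzero(neg.any(axis=(1, 2))):
            findings.append(
                ValidationFinding("negative_sc", ids[i], f"sc of {ids[i]} has negative weights")
            )
    return findings


def _read_matrix(path: Path, subject: str, modality: str) -> np.ndarray:
    if not path.is_file():
        raise MissingFileError(f"{modality} file for subject {subject!r} not found: {path}")
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        mat = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise NonSquareMatrixError(
            f"{modality} file for subject {subject!r} is not a rectangular numeric matrix: {path} ({exc})"
        ) from exc
    if mat.shape[0] != mat.shape[1]:
        raise NonSquareMatrixError(
            f"{modality} matrix for subject {subject!r} is {mat.shape[0]}x{mat.shape[1]}, not square"
        )
    if not np.isfinite(mat).all():
        raise NonFiniteEntriesError(
            f"{modality} matrix for subject {subject!r} contains NaN/Inf entries"
        )
    asym = float(np.abs(mat - mat.T).max())
    if asym > SYMMETRY_TOL:
        raise AsymmetryError(
            f"{modality} matrix for subject {subject!r} asymmetric by {asym:.3g} (> {SYMMETRY_TOL})"
        )
    if asym > 0:
        warnings.warn(
            f"symmetrized {modality} matrix of subject {subject!r} (asymmetry {asym:.3g})",
            stacklevel=3,
        )
        mat = (mat + mat.T) / 2.0
    return mat


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a tab-separated manifest.

    The manifest has a header row with columns ``subject_id``, ``fold``,
    ``efc_path``, ``pfc_path`` and optionally ``sc_path``; paths are resolved
    relative to the manifest's directory.  Subject order follows manifest row
    order.  Matrices with asymmetry at most 1e-8 are symmetrized as
    (M + M')/2; larger asymmetry is an error.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.is_file():
        raise MissingFileError(f"manifest not found: {manifest_path}")
    table = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"subject_id", "fold", "efc_path", "pfc_path"}
    missing = required - set(table.columns)
    if missing:
        raise CohortValidationError(f"manifest missing columns: {sorted(missing)}")

    ids = table["subject_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise DuplicateSubjectError(f"duplicate subject ids in manifest: {dupes}")
    try:
        fold_labels = table["fold"].astype(int).to_numpy()
    except ValueError as exc:
        raise FoldLabelError(f"non-integer fold labels in manifest: {exc}") from exc

    base = manifest_path.parent
    has_sc = "sc_path" in table.columns and table["sc_path"].notna().all()

    def read_stack(column: str, modality: str) -> np.ndarray:
        mats, p = [], None
        for sid, rel in zip(ids, table[column]):
            mat = _read_matrix(base / rel, sid, modality)
            if p is None:
                p = mat.shape[0]
            elif mat.shape[0] != p:
                raise DimensionMismatchError(
                    f"{modality} matrix for subject {sid!r} is {mat.shape[0]}x{mat.shape[0]}, "
                    f"expected {p}x{p}"
                )
            mats.append(mat)
        return np.stack(mats)

    efc = read_stack("efc_path", "efc")
    pfc = read_stack("pfc_path", "pfc")
    if pfc.shape != efc.shape:
        raise DimensionMismatchError(
            f"pfc stack shape {pfc.shape} differs from efc stack shape {efc.shape}"
        )
    sc = None
    if has_sc:
        sc = read_stack("sc_path", "sc")
        if sc.shape != efc.shape:
            raise DimensionMismatchError(
                f"sc stack shape {sc.shape} differs from efc stack shape {efc.shape}"
            )
    folds = FoldPartition(n_folds=int(fold_labels.max()), assignment=fold_labels)
    return Cohort(subject_ids=ids, efc=efc, pfc=pfc, sc=sc, folds=folds)


def _safe_name(subject_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", subject_id)


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write one matrix file per subject per modality plus a manifest.

    File names derive deterministically from subject ids.  Returns the
    manifest path; ``load_cohort`` on that path reproduces the cohort.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(cohort.subject_ids):
        stem = _safe_name(sid)
        row = {"subject_id": sid, "fold": int(cohort.folds.assignment[i])}
        for modality, stack in cohort.stacks().items():
            fname = f"{stem}_{modality}.tsv"
            np.savetxt(directory / fname, stack[i], delimiter="\t", fmt="%.17g")
            row[f"{modality}_path"] = fname
        rows.append(row)
    columns = [c for c in MANIFEST_COLUMNS if c in rows[0]]
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows)[columns].to_csv(manifest, sep="\t", index=False)
    return manifest
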