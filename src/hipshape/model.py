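"""PCA point-distribution model: hip shape modes scored in SD units.

After generalized Procrustes alignment, shape variation is modelled by
principal component analysis of the aligned coordinate vectors: each
mode (eigenvector of the coordinate covariance) is a linearly
independent pattern of shape variation, and an individual's raw
projection on a mode is standardized by the training cohort's mean and
SD so that scores are expressed in cohort SD units.  Shapes can be
reconstructed from any score vector as mean + sum of de-standardized
scores times eigenvectors, which is how the +/-2 SD mode outlines are
drawn.

Eigen-sign convention: every eigenvector is oriented so that its
largest-magnitude loading is positive (ties broken by lowest index).
Mode signs out of a plain eigendecomposition are arbitrary, and
association odds ratios flip with the sign, so a fixed convention keeps
results reproducible across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .procrustes import AlignedShapeSet

__all__ = [
    "PointDistributionModel",
    "ModeScores",
    "RankError",
    "fit_shape_model",
    "score_shapes",
    "reconstruct",
    "variance_explained",
    "flag_outliers",
]

# Similarity alignment (translation x2, rotation, scale) removes 4 degrees
# of freedom from 2P coordinates.
_SIMILARITY_DOF = 4


class RankError(ValueError):
    """Requested more modes than the aligned data can support."""


@dataclass(frozen=True)
class ModeScores:
    """Per-individual mode scores in cohort SD units."""

    image_id: str
    scores: np.ndarray


def _to_matrix(aligned) -> np.ndarray:
    if isinstance(aligned, AlignedShapeSet):
        return aligned.shapes
    return np.asarray(aligned, dtype=float)


def _ids(aligned, n: int) -> tuple:
    if isinstance(aligned, AlignedShapeSet) and aligned.image_ids:
        return aligned.image_ids
    return tuple(str(i) for i in range(n))


class PointDistributionModel(BaseEstimator, TransformerMixin):
    """Point-distribution model of aligned landmark coordinates.

    Parameters
    ----------
    n_modes : int or None
        Number of modes retained for ``transform``/scores.  ``None``
        keeps the full achievable rank.  The association battery uses
        the top 10 by variance explained.

    Attributes
    ----------
    mean_ : (2P,) mean aligned shape.
    components_ : (k, 2P) orthonormal eigenvector rows, variance-ordered.
    eigenvalues_ : (k,) covariance eigenvalues, non-increasing.
    variance_fraction_ : (k,) eigenvalue over the trace of the *full*
        covariance, so fractions over all achievable modes sum to 1.
    score_mean_, score_scale_ : per-mode mean and SD of the raw training
        projections; ``transform`` standardizes by these so training
        scores have mean 0 and SD 1 per mode.
    n_train_ : training cohort size.
    """

    def __init__(self, n_modes: int | None = 10):
        self.n_modes = n_modes

    def fit(self, X, y=None) -> "PointDistributionModel":
        M = _to_matrix(X)
        n, twoP = M.shape
        max_rank = min(n - 1, twoP - _SIMILARITY_DOF)
        if self.n_modes is not None and self.n_modes > max_rank:
            raise RankError(
                f"n_modes={self.n_modes} exceeds achievable rank {max_rank} "
                f"(n={n}, 2P={twoP}; similarity alignment removes "
                f"{_SIMILARITY_DOF} degrees of freedom)"
            )
        mean = M.mean(axis=0)
        C = M - mean
        # SVD of centered data: eigenvalues of the covariance are s^2/(n-1)
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        eigvals = s**2 / (n - 1)
        total = eigvals.sum()
        if self.n_modes is None:
            # keep every mode with genuinely nonzero variance (achievable rank);
            # the 2P-4 cap only constrains *requested* mode counts, since
            # non-aligned coordinate data can carry variance in all directions
            keep = max(1, int(min(min(n - 1, twoP), (eigvals > total * 1e-15).sum())))
        else:
            keep = int(self.n_modes)
        comps = Vt[:keep]
        eigvals_k = eigvals[:keep]

        # deterministic sign: largest-|loading| coordinate positive, ties
        # broken by lowest index (np.argmax returns the first maximum)
        for j in range(keep):
            i = int(np.argmax(np.abs(comps[j])))
            if comps[j, i] < 0:
                comps[j] = -comps[j]

        raw = C @ comps.T
        score_mean = raw.mean(axis=0)
        score_scale = raw.std(axis=0, ddof=1)
        if np.any(score_scale <= 0):
            raise RankError("a retained mode has zero training variance")

        self.mean_ = mean
        self.components_ = comps
        self.eigenvalues_ = eigvals_k
        self.variance_fraction_ = eigvals_k / total if total > 0 else eigvals_k
        self.score_mean_ = score_mean
        self.score_scale_ = score_scale
        self.n_train_ = n
        self.n_points_ = twoP // 2
        return self

    def transform(self, X) -> np.ndarray:
        """Project aligned shapes onto the modes; returns n x k SD-unit scores."""
        check_is_fitted(self, "components_")
        M = _to_matrix(X)
        if M.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"dimension mismatch: model has 2P={self.mean_.shape[0]}, "
                f"data has {M.shape[1]}"
            )
        raw = (M - self.mean_) @ self.components_.T
        return (raw - self.score_mean_) / self.score_scale_

    def inverse_transform(self, sd_scores) -> np.ndarray:
        """Reconstruct aligned shapes from SD-unit scores (mean + modes)."""
        check_is_fitted(self, "components_")
        S = np.asarray(sd_scores, dtype=float)
        squeeze = S.ndim == 1
        S = np.atleast_2d(S)
        if S.shape[1] != self.components_.shape[0]:
            raise ValueError(
                f"expected {self.components_.shape[0]} scores, got {S.shape[1]}"
            )
        raw = S * self.score_scale_ + self.score_mean_
        out = self.mean_ + raw @ self.components_
        return out[0] if squeeze else out

    def variance_explained(self, mode_subset: Sequence[int] | None = None) -> float:
        """Percentage of total shape variance carried by a set of modes.

        Modes are numbered from 1 (the field's convention for naming
        shape modes).  ``None`` means all retained modes.
        """
        check_is_fitted(self, "variance_fraction_")
        if mode_subset is None:
            return float(100.0 * self.variance_fraction_.sum())
        idx = np.asarray(list(mode_subset), dtype=int)
        if idx.size == 0:
            return 0.0
        if np.any(idx < 1) or np.any(idx > self.variance_fraction_.size):
            raise IndexError(f"mode index out of range 1..{self.variance_fraction_.size}")
        return float(100.0 * self.variance_fraction_[idx - 1].sum())

    def to_json(self, path: str | Path, metadata: dict | None = None) -> Path:
        check_is_fitted(self, "components_")
        payload = {
            "mean_shape": self.mean_.tolist(),
            "eigenvectors": self.components_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "variance_fraction": self.variance_fraction_.tolist(),
            "score_mean": self.score_mean_.tolist(),
            "score_scale": self.score_scale_.tolist(),
            "n_train": int(self.n_train_),
            "metadata": metadata or {},
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PointDistributionModel":
        payload = json.loads(Path(path).read_text())
        model = cls(n_modes=len(payload["eigenvalues"]))
        model.mean_ = np.asarray(payload["mean_shape"])
        model.components_ = np.asarray(payload["eigenvectors"])
        model.eigenvalues_ = np.asarray(payload["eigenvalues"])
        model.variance_fraction_ = np.asarray(payload["variance_fraction"])
        model.score_mean_ = np.asarray(payload["score_mean"])
        model.score_scale_ = np.asarray(payload["score_scale"])
        model.n_train_ = payload["n_train"]
        model.n_points_ = model.mean_.size // 2
        return model


def fit_shape_model(aligned, k: int | None = 10) -> PointDistributionModel:
    """Fit a point-distribution model to an aligned shape set."""
    if isinstance(aligned, AlignedShapeSet) and not aligned.converged:
        import warnings

        warnings.warn("aligning did not converge; shape model may be unstable")
    return PointDistributionModel(n_modes=k).fit(aligned)


def score_shapes(model: PointDistributionModel, aligned) -> list[ModeScores]:
    """Score shapes in SD units on each mode of a fitted model."""
    M = _to_matrix(aligned)
    scores = model.transform(M)
    ids = _ids(aligned, M.shape[0])
    return [ModeScores(image_id=i, scores=s) for i, s in zip(ids, scores)]


def reconstruct(model: PointDistributionModel, sd_scores) -> np.ndarray:
    """Reconstruct an aligned 2P shape vector from SD-unit mode scores."""
    return model.inverse_transform(sd_scores)


def variance_explained(model: PointDistributionModel, mode_subset=None) -> float:
    """Percentage of total variance carried by the given 1-based mode subset."""
    return model.variance_explained(mode_subset)


def flag_outliers(scores: Sequence[ModeScores], threshold: float = 4.0) -> list[tuple]:
    """Flag (image_id, mode_number, score) where |score| exceeds the threshold.

    Shape-mode scores more extreme than 4 SD usually indicate landmark
    placement errors; flagged images are meant for manual review, not
    automatic exclusion.
    """
    flagged = []
    for ms in scores:
        (idx,) = np.where(np.abs(ms.scores) > threshold)
        for j in idx:
            flagged.append((ms.image_id, int(j) + 1, float(ms.scores[j])))
    return flagged
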