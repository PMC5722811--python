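"""Pairwise and generalized Procrustes superimposition in 2D.

Shapes are superimposed by similarity transforms only — scaling,
rotation and translation.  Reflections are excluded: anatomical
chirality must be preserved (left hips are mirrored into the right-hip
frame *before* alignment, not by the alignment).

The 2D problem has a closed form in complex notation: writing a centered
shape as a complex vector z and the centered reference as w, the optimal
scale-rotation is the complex scalar a = <z, w> / <z, z>, with
scale = |a| and rotation = arg(a).  The generalized (many-shape)
alignment iterates pairwise alignment to the current mean, mean
recomputation, and renormalization of the mean to unit centroid size.

The converged Procrustes mean is only defined up to a global rotation;
to make results independent of input order the fitted frame is
canonicalized by rotating the mean so its first landmark lies at zero
angle from the centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import LandmarkConfiguration

__all__ = [
    "SimilarityTransform",
    "AlignedShapeSet",
    "DegenerateShapeError",
    "GeneralizedProcrustesAlignment",
    "align_pair",
    "gpa",
    "procrustes_distance",
]


class DegenerateShapeError(ValueError):
    """All landmarks coincide: the shape has zero centroid size."""


@dataclass(frozen=True)
class SimilarityTransform:
    """A 2D similarity transform x -> scale * R(rotation) @ x + translation."""

    scale: float
    rotation: float  # radians, in (-pi, pi]
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        rot = float(np.arctan2(np.sin(self.rotation), np.cos(self.rotation)))
        if rot == -np.pi:
            rot = np.pi
        object.__setattr__(self, "rotation", rot)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (P, 2) point array or 2P vector; returns same shape."""
        pts = np.asarray(points, dtype=float)
        flat = pts.ndim == 1
        xy = pts.reshape(-1, 2)
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        R = np.array([[c, -s], [s, c]])
        out = self.scale * xy @ R.T + np.asarray(self.translation)
        return out.reshape(-1) if flat else out

    def inverse(self) -> "SimilarityTransform":
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        R = np.array([[c, -s], [s, c]])
        t = -(R @ np.asarray(self.translation)) / self.scale
        return SimilarityTransform(1.0 / self.scale, -self.rotation, (t[0], t[1]))


@dataclass(frozen=True)
class AlignedShapeSet:
    """The output of generalized Procrustes alignment.

    ``shapes`` is the n x 2P matrix of aligned coordinates; ``mean_shape``
    has centroid at the origin and unit centroid size; ``transforms[i]``
    maps the i-th *input* shape onto ``shapes[i]``.
    """

    shapes: np.ndarray
    mean_shape: np.ndarray
    transforms: tuple
    iterations: int
    converged: bool
    image_ids: tuple = ()

    @property
    def n_shapes(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_points(self) -> int:
        return self.shapes.shape[1] // 2


def _as_complex(shape) -> np.ndarray:
    """Coerce a LandmarkConfiguration / (P,2) array / 2P vector to complex P-vector."""
    if isinstance(shape, LandmarkConfiguration):
        xy = shape.points
    else:
        xy = np.asarray(shape, dtype=float)
        if xy.ndim == 1:
            xy = xy.reshape(-1, 2)
    return xy[:, 0] + 1j * xy[:, 1]


def _from_complex(z: np.ndarray) -> np.ndarray:
    return np.column_stack([z.real, z.imag]).reshape(-1)


def _centroid_size(z: np.ndarray) -> float:
    return float(np.linalg.norm(z - z.mean()))


def align_pair(shape, reference) -> tuple[np.ndarray, SimilarityTransform]:
    """Ordinary (pairwise) Procrustes: superimpose ``shape`` on ``reference``.

    Returns the aligned 2P coordinate vector and the similarity
    transform that produced it.  The alignment minimizes the sum of
    squared point distances over all rotation+scale+translation
    transforms (closed form; reflections excluded).
    """
    z = _as_complex(shape)
    w = _as_complex(reference)
    if z.shape != w.shape:
        raise ValueError(f"point counts differ: {z.shape[0]} vs {w.shape[0]}")
    cz, cw = z.mean(), w.mean()
    zt, wt = z - cz, w - cw
    nz = np.vdot(zt, zt).real
    if not nz > 0 or not np.vdot(wt, wt).real > 0:
        raise DegenerateShapeError("zero centroid size")
    a = np.vdot(zt, wt) / nz  # vdot conjugates the first argument
    if abs(a) == 0:
        # perpendicular degenerate case: any rotation is optimal; pick identity
        a = 1e-300
    aligned = a * zt + cw
    scale = abs(a)
    rot = float(np.angle(a))
    t = cw - a * cz
    tr = SimilarityTransform(scale, rot, (t.real, t.imag))
    return _from_complex(aligned), tr


def procrustes_distance(a, b) -> float:
    """Full Procrustes distance between two configurations.

    Both shapes are centered and scaled to unit centroid size, then the
    residual after optimal rotation+scale superimposition is returned.
    Symmetric in its arguments; zero iff the shapes differ by a
    similarity transform.
    """
    z = _as_complex(a)
    w = _as_complex(b)
    if z.shape != w.shape:
        raise ValueError("point counts differ")
    zt, wt = z - z.mean(), w - w.mean()
    nz, nw = np.linalg.norm(zt), np.linalg.norm(wt)
    if not nz > 0 or not nw > 0:
        raise DegenerateShapeError("zero centroid size")
    zt, wt = zt / nz, wt / nw
    # residual of the optimal rotation+scale fit of zt onto wt; computing the
    # residual vector directly avoids the cancellation in sqrt(1 - |<z,w>|^2)
    res = wt - np.vdot(zt, wt) * zt
    return float(np.linalg.norm(res))


class GeneralizedProcrustesAlignment(BaseEstimator, TransformerMixin):
    """Generalized Procrustes analysis as a scikit-learn transformer.

    ``fit`` iteratively superimposes a set of shapes on their evolving
    mean until the mean stabilizes; ``transform`` superimposes shapes
    (the training set or new ones) on the fitted mean.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the RMS change of the mean shape
        between iterations.
    max_iter : int
        Iteration cap; ``converged_`` records whether ``tol`` was met.

    Attributes
    ----------
    mean_shape_ : ndarray of shape (2P,)
        Procrustes mean, centroid at origin, unit centroid size,
        canonically rotated (first landmark at zero angle).
    transforms_ : tuple of SimilarityTransform
        Per-training-shape input -> aligned maps.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _to_matrix(shapes) -> tuple[np.ndarray, tuple]:
        ids = []
        rows = []
        if isinstance(shapes, np.ndarray) and shapes.ndim == 2:
            return np.asarray(shapes, dtype=float), ()
        for i, s in enumerate(shapes):
            if isinstance(s, LandmarkConfiguration):
                ids.append(s.image_id)
                rows.append(s.as_vector())
            else:
                ids.append(str(i))
                rows.append(np.asarray(s, dtype=float).reshape(-1))
        return np.vstack(rows), tuple(ids)

    @staticmethod
    def _canonical_rotation(mean_z: np.ndarray) -> complex:
        """Unit complex scalar rotating the mean so landmark 0 sits at angle 0."""
        v = mean_z[0] - mean_z.mean()
        if abs(v) == 0:
            return 1.0 + 0j
        return np.conj(v) / abs(v)

    def fit(self, X, y=None) -> "GeneralizedProcrustesAlignment":
        M, ids = self._to_matrix(X)
        n = M.shape[0]
        if n < 2:
            raise ValueError("generalized alignment needs at least 2 shapes")
        Z = M[:, 0::2] + 1j * M[:, 1::2]
        sizes = np.linalg.norm(Z - Z.mean(axis=1, keepdims=True), axis=1)
        if np.any(sizes == 0):
            raise DegenerateShapeError("degenerate shape in input set")

        mean = Z[0] - Z[0].mean()
        mean = mean / np.linalg.norm(mean)
        aligned = np.empty_like(Z)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            Zc = Z - Z.mean(axis=1, keepdims=True)
            # optimal a_i per shape against the current mean, vectorized
            num = (np.conj(Zc) * mean).sum(axis=1)
            den = (np.conj(Zc) * Zc).sum(axis=1).real
            a = num / den
            aligned = a[:, None] * Zc
            new_mean = aligned.mean(axis=0)
            new_mean = new_mean - new_mean.mean()
            new_mean = new_mean / np.linalg.norm(new_mean)
            delta = np.sqrt(np.mean(np.abs(new_mean - mean) ** 2))
            mean = new_mean
            if delta < self.tol:
                converged = True
                break

        rot = self._canonical_rotation(mean)
        mean = rot * (mean - mean.mean())
        num = (np.conj(Z - Z.mean(axis=1, keepdims=True)) * mean).sum(axis=1)
        den = np.linalg.norm(Z - Z.mean(axis=1, keepdims=True), axis=1) ** 2
        a = num / den
        cz = Z.mean(axis=1)
        aligned = a[:, None] * (Z - cz[:, None])
        t = -a * cz
        transforms = tuple(
            SimilarityTransform(abs(ai), float(np.angle(ai)), (ti.real, ti.imag))
            for ai, ti in zip(a, t)
        )

        self.mean_shape_ = _from_complex(mean)
        self.shapes_ = self._interleave(aligned)
        self.transforms_ = transforms
        self.image_ids_ = ids
        self.n_iter_ = it
        self.converged_ = converged
        return self

    @staticmethod
    def _interleave(Zc: np.ndarray) -> np.ndarray:
        out = np.empty((Zc.shape[0], 2 * Zc.shape[1]))
        out[:, 0::2] = Zc.real
        out[:, 1::2] = Zc.imag
        return out

    def transform(self, X) -> np.ndarray:
        """Superimpose shapes on the fitted mean; returns n x 2P aligned matrix."""
        check_is_fitted(self, "mean_shape_")
        M, _ = self._to_matrix(X)
        out = np.empty_like(M, dtype=float)
        for i in range(M.shape[0]):
            out[i], _ = align_pair(M[i], self.mean_shape_)
        return out

    def aligned_set_(self) -> AlignedShapeSet:
        """Package the fitted training alignment as an AlignedShapeSet."""
        check_is_fitted(self, "mean_shape_")
        return AlignedShapeSet(
            shapes=self.shapes_,
            mean_shape=self.mean_shape_,
            transforms=self.transforms_,
            iterations=self.n_iter_,
            converged=self.converged_,
            image_ids=self.image_ids_,
        )


def gpa(
    shapes: Sequence, tol: float = 1e-8, max_iter: int = 100
) -> AlignedShapeSet:
    """Generalized Procrustes alignment of a shape set (functional wrapper)."""
    est = GeneralizedProcrustesAlignment(tol=tol, max_iter=max_iter)
    est.fit(shapes)
    return est.aligned_set_()
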