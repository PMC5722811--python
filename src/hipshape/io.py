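"""Landmark configurations, the hip point template, and file I/O.

Coordinate convention: image pixel frame, origin top-left, x increasing
to the right, y increasing downward (the usual raster convention of DXA
landmark tools).  Under this convention a right hip has its lateral
structures (greater trochanter, lateral acetabular rim) at larger x than
its medial structures.

Landmark files are long-format CSV with header
``image_id,point_index,x,y,side``; ``point_index`` is 0-based and every
image must carry exactly one row per template index.  Point indices are
anatomical: index k marks the same anatomical locus on a left and a
right hip, so harmonizing a left scan into the right-hip frame is a pure
reflection with no re-indexing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "PointTemplate",
    "LandmarkValidationError",
    "LandmarkParseError",
    "read_landmarks",
    "write_landmarks",
    "mirror_to_right",
]


class LandmarkValidationError(ValueError):
    """A landmark configuration violates the template invariants."""


class LandmarkParseError(ValueError):
    """A landmark file contains rows that cannot be parsed."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One hip's ordered 2D landmark set in pixel coordinates.

    Parameters
    ----------
    image_id : str
        Identifier of the source image (and hence participant).
    side : {"left", "right"}
        Which hip the landmarks were placed on.
    points : ndarray of shape (P, 2)
        Ordered (x, y) landmark coordinates in pixels.  Point order
        follows the template's anatomical ordering.
    """

    image_id: str
    side: str
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise LandmarkValidationError(
                f"{self.image_id}: points must be (P, 2), got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise LandmarkValidationError(f"{self.image_id}: non-finite coordinate")
        if self.side not in ("left", "right"):
            raise LandmarkValidationError(
                f"{self.image_id}: side must be 'left' or 'right', got {self.side!r}"
            )
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def as_vector(self) -> np.ndarray:
        """Flatten to a 2P vector ordered (x0, y0, x1, y1, ...)."""
        return self.points.reshape(-1)


@dataclass(frozen=True)
class PointTemplate:
    """The anatomical template the landmark indices refer to.

    ``roles`` labels every point as a named key point or ``"intermediate"``;
    ``key_points`` maps anatomical key-point names to indices;
    ``segments`` maps bone-contour names to half-open index ranges that
    partition ``0..P-1``; ``reference`` holds the drawn template
    coordinates (right hip, pixel frame).
    """

    P: int
    roles: tuple
    key_points: dict
    segments: dict
    reference: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        if ref.shape != (self.P, 2):
            raise ValueError(f"reference must be ({self.P}, 2), got {ref.shape}")
        if len(self.roles) != self.P:
            raise ValueError("roles must label every point")
        covered = sorted(i for lo, hi in self.segments.values() for i in range(lo, hi))
        if covered != list(range(self.P)):
            raise ValueError("segments must partition 0..P-1")
        for name, idx in self.key_points.items():
            if not (0 <= idx < self.P):
                raise ValueError(f"key point {name} index {idx} out of range")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "roles", tuple(self.roles))

    def validate(self, config: LandmarkConfiguration) -> None:
        """Raise LandmarkValidationError unless ``config`` matches this template."""
        if config.n_points != self.P:
            raise LandmarkValidationError(
                f"{config.image_id}: expected {self.P} points, got {config.n_points}"
            )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "P": self.P,
            "roles": list(self.roles),
            "key_points": self.key_points,
            "segments": {k: list(v) for k, v in self.segments.items()},
            "reference": self.reference.tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PointTemplate":
        payload = json.loads(Path(path).read_text())
        return cls(
            P=payload["P"],
            roles=tuple(payload["roles"]),
            key_points=payload["key_points"],
            segments={k: tuple(v) for k, v in payload["segments"].items()},
            reference=np.asarray(payload["reference"], dtype=float),
        )


_COLUMNS = ["image_id", "point_index", "x", "y", "side"]


def read_landmarks(
    path: str | Path,
    template: PointTemplate | None = None,
    n_points: int | None = None,
    on_error: str = "raise",
) -> list[LandmarkConfiguration]:
    """Read landmark configurations from a long-format CSV.

    One configuration is returned per distinct ``image_id``, points
    sorted by ``point_index``.  Images with missing or duplicated point
    indices are rejected: with ``on_error="raise"`` (default) a
    :class:`LandmarkValidationError` naming the image and offending
    index is raised; with ``on_error="skip"`` the image is dropped with
    a warning.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    expected = template.P if template is not None else n_points
    df = pd.read_csv(path, dtype={"image_id": str}, float_precision="round_trip")
    missing_cols = {"image_id", "point_index", "x", "y"} - set(df.columns)
    if missing_cols:
        raise LandmarkParseError(f"missing columns: {sorted(missing_cols)}")
    try:
        df["x"] = df["x"].astype(float)
        df["y"] = df["y"].astype(float)
        df["point_index"] = df["point_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise LandmarkParseError(f"non-numeric coordinate or index in {path}: {exc}") from exc
    if "side" not in df.columns:
        df["side"] = "right"

    configs: list[LandmarkConfiguration] = []
    for image_id, grp in df.groupby("image_id", sort=False):
        idx = grp["point_index"].to_numpy()
        P = expected if expected is not None else len(idx)
        want = set(range(P))
        have = set(idx.tolist())
        try:
            if len(idx) != len(have):
                dup = int(idx[pd.Series(idx).duplicated().to_numpy()][0])
                raise LandmarkValidationError(
                    f"{image_id}: duplicated point_index {dup}"
                )
            if have != want:
                miss = sorted(want - have) or sorted(have - want)
                raise LandmarkValidationError(
                    f"{image_id}: missing/unexpected point_index {miss[0]}"
                )
            grp = grp.sort_values("point_index")
            side = str(grp["side"].iloc[0])
            cfg = LandmarkConfiguration(
                image_id=str(image_id), side=side, points=grp[["x", "y"]].to_numpy()
            )
            if template is not None:
                template.validate(cfg)
        except LandmarkValidationError:
            if on_error == "raise":
                raise
            warnings.warn(f"skipping invalid image {image_id}", stacklevel=2)
            continue
        configs.append(cfg)
    return configs


def write_landmarks(
    configs: Sequence[LandmarkConfiguration], path: str | Path
) -> Path:
    """Write configurations to long-format CSV, re-readable bit-exactly.

    Coordinates are written with repr-roundtrip precision so that
    ``read_landmarks(write_landmarks(cs)) == cs`` on the coordinates.
    """
    path = Path(path)
    rows = []
    for cfg in configs:
        for i, (x, y) in enumerate(cfg.points):
            rows.append((cfg.image_id, i, x, y, cfg.side))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    # default float formatting is shortest-repr, which round-trips exactly
    df.to_csv(path, index=False)
    return path


def mirror_to_right(
    config: LandmarkConfiguration, axis_x: float = 0.0
) -> LandmarkConfiguration:
    """Reflect a left-hip configuration into the right-hip frame.

    x-coordinates are reflected about the vertical line ``x = axis_x``
    and the side label set to ``"right"``.  Point indices are anatomical
    (index k is the same locus on either side), so no re-indexing is
    needed.  Called on an already-right configuration this is a no-op
    with a warning.
    """
    if config.side == "right":
        warnings.warn(
            f"{config.image_id}: already right-sided; mirror_to_right is a no-op",
            stacklevel=2,
        )
        return config
    pts = config.points.copy()
    pts[:, 0] = 2.0 * axis_x - pts[:, 0]
    return replace(config, side="right", points=pts)
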