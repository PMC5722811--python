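"""Inter-operator landmark placement accuracy.

Before marking up a study cohort, operators landmark a shared training
set of images.  For each operator, the point-to-point accuracy is the
median Euclidean distance between that operator's placement of a point
and the average placement over *all* operators (the scored operator's
own placement included — excluding it would change the value), pooled
over every (image, point) pair.  A median of at most 3 pixels denotes
acceptable accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LandmarkConfiguration

__all__ = ["OperatorPlacementSet", "point_to_point_accuracy", "qc_report"]


@dataclass(frozen=True)
class OperatorPlacementSet:
    """All operators' landmark placements for one image.

    ``placements`` maps operator id to that operator's
    LandmarkConfiguration of the image; all configurations must share
    the image id and point count, and at least two operators are
    required for a meaningful consensus.
    """

    image_id: str
    placements: dict

    def __post_init__(self) -> None:
        if len(self.placements) < 2:
            raise ValueError(
                f"{self.image_id}: need >= 2 operators, got {len(self.placements)}"
            )
        counts = {c.n_points for c in self.placements.values()}
        if len(counts) != 1:
            raise ValueError(f"{self.image_id}: operators disagree on point count")
        for op, cfg in self.placements.items():
            if cfg.image_id != self.image_id:
                raise ValueError(
                    f"operator {op} placement is for image {cfg.image_id}, "
                    f"not {self.image_id}"
                )

    @property
    def operators(self) -> set:
        return set(self.placements)

    def consensus(self) -> np.ndarray:
        """Average point positions over all operators, shape (P, 2)."""
        return np.mean([c.points for c in self.placements.values()], axis=0)


def _operator_distances(placements, operator) -> np.ndarray:
    dists = []
    for ps in placements:
        if operator not in ps.placements:
            raise KeyError(f"operator {operator!r} missing for image {ps.image_id}")
        diff = ps.placements[operator].points - ps.consensus()
        dists.append(np.hypot(diff[:, 0], diff[:, 1]))
    return np.concatenate(dists)


def point_to_point_accuracy(placements, operator) -> float:
    """Median distance (pixels) from an operator's points to the consensus.

    The median is taken over all pooled (image, point) pairs for that
    operator.
    """
    return float(np.median(_operator_distances(placements, operator)))


def qc_report(placements, threshold: float = 3.0) -> pd.DataFrame:
    """Per-operator accuracy table with a pass flag (median <= threshold)."""
    operators = sorted(set.intersection(*(ps.operators for ps in placements)))
    rows = [
        {
            "operator": op,
            "median_distance_px": point_to_point_accuracy(placements, op),
        }
        for op in operators
    ]
    df = pd.DataFrame(rows)
    df["pass"] = df["median_distance_px"] <= threshold
    return df
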