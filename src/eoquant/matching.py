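"""Reconciliation of two annotation sets for the same section.

When two image-analysis platforms segment the same slide, their object
tables carry different ids and slightly different geometry.  Objects are
paired one-to-one by a geometric score — the centroid distance plus the
summed absolute differences of the four bounding-box coordinates — using
a greedy ascending-score assignment.  Pairs whose size bins differ by
more than 1 are rejected as mismatches, and agreement is reported as the
coefficient of determination (R²) of the B areas regressed on the A
areas, before and after that filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import assign_bin

__all__ = ["MatchResult", "match_annotations"]

_REQUIRED = ["object_id", "centroid_x", "centroid_y",
             "bbox_x0", "bbox_y0", "bbox_x1", "bbox_y1", "area_um2"]

#: column aliases accepted for the pixel/μm naming used elsewhere
_ALIASES = {
    "centroid_x": ("centroid_x", "centroid_x_px", "centroid_x_um"),
    "centroid_y": ("centroid_y", "centroid_y_px", "centroid_y_um"),
}


@dataclass
class MatchResult:
    """Outcome of matching two object tables."""

    pairs: pd.DataFrame  # id_A, id_B, sum_distance, bin_A, bin_B, rejected
    r_squared_before: float
    r_squared_after: float
    n_matched: int = 0
    n_rejected: int = 0

    @property
    def retained(self) -> pd.DataFrame:
        return self.pairs[~self.pairs["rejected"]]

    @property
    def rejected(self) -> pd.DataFrame:
        return self.pairs[self.pairs["rejected"]]

    def summary(self) -> dict:
        return {
            "n_matched": int(self.n_matched),
            "n_rejected": int(self.n_rejected),
            "r_squared_before": self.r_squared_before,
            "r_squared_after": self.r_squared_after,
        }


def _normalise(df: pd.DataFrame, label: str) -> pd.DataFrame:
    df = df.copy()
    for canon, names in _ALIASES.items():
        for name in names:
            if name in df.columns:
                df[canon] = df[name]
                break
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"table {label} is missing columns: {missing}")
    return df.reset_index(drop=True)


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """R² of y regressed on x (1.0 for a degenerate but exact match)."""
    if len(x) == 0:
        return float("nan")
    if np.allclose(x, y):
        return 1.0
    if np.var(x) == 0 or np.var(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def match_annotations(set_a: pd.DataFrame, set_b: pd.DataFrame,
                      max_score: float | None = None,
                      bin_difference_limit: int = 1) -> MatchResult:
    """Greedy one-to-one matching of two object tables.

    score(a, b) = |centroid_a − centroid_b| + Σ |bbox coord differences|
    (four coordinates, equal weight).  Candidate pairs are processed in
    ascending score order; each id is used at most once.  Pairs with
    ``|bin_A − bin_B| > bin_difference_limit`` are flagged rejected.

    ``max_score`` gates implausible pairs; the default is twice the 95th
    percentile of nearest-neighbour centroid distances within set A.
    A gross disagreement of area scales (median ratio outside
    [0.25, 4]) triggers a unit-mismatch warning.
    """
    a = _normalise(set_a, "A")
    b = _normalise(set_b, "B")
    empty = pd.DataFrame(columns=["id_A", "id_B", "sum_distance",
                                  "bin_A", "bin_B", "rejected"])
    if len(a) == 0 or len(b) == 0:
        return MatchResult(pairs=empty, r_squared_before=float("nan"),
                           r_squared_after=float("nan"))

    med_a, med_b = a["area_um2"].median(), b["area_um2"].median()
    if med_a > 0 and not 0.25 <= med_b / med_a <= 4.0:
        warnings.warn("median areas disagree by >4x; possible unit mismatch")

    ca = a[["centroid_x", "centroid_y"]].to_numpy(float)
    cb = b[["centroid_x", "centroid_y"]].to_numpy(float)
    boxes_a = a[["bbox_x0", "bbox_y0", "bbox_x1", "bbox_y1"]].to_numpy(float)
    boxes_b = b[["bbox_x0", "bbox_y0", "bbox_x1", "bbox_y1"]].to_numpy(float)

    cen_d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    box_d = np.abs(boxes_a[:, None, :] - boxes_b[None, :, :]).sum(-1)
    score = cen_d + box_d

    if max_score is None:
        if len(a) > 1:
            self_d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
            np.fill_diagonal(self_d, np.inf)
            nn = self_d.min(axis=1)
            max_score = 2.0 * float(np.percentile(nn, 95))
        else:
            max_score = float("inf")

    order = np.argsort(score, axis=None, kind="stable")
    used_a = np.zeros(len(a), dtype=bool)
    used_b = np.zeros(len(b), dtype=bool)
    rows = []
    for flat in order:
        i, j = divmod(int(flat), len(b))
        s = float(score[i, j])
        if s > max_score:
            break
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        # unclamped bins: the 0-9 cap is for reporting, and clamping
        # would let two huge, very different areas evade the filter
        bin_a = assign_bin(float(a.loc[i, "area_um2"]), clamp=False)
        bin_b = assign_bin(float(b.loc[j, "area_um2"]), clamp=False)
        rows.append({
            "id_A": a.loc[i, "object_id"],
            "id_B": b.loc[j, "object_id"],
            "area_A": float(a.loc[i, "area_um2"]),
            "area_B": float(b.loc[j, "area_um2"]),
            "sum_distance": s,
            "bin_A": bin_a,
            "bin_B": bin_b,
            "rejected": abs(bin_a - bin_b) > bin_difference_limit,
        })
    pairs = pd.DataFrame(rows) if rows else empty.assign(area_A=[], area_B=[])

    area_a = pairs["area_A"].to_numpy(float) if len(pairs) else np.array([])
    area_b = pairs["area_B"].to_numpy(float) if len(pairs) else np.array([])
    keep = ~pairs["rejected"].to_numpy(bool) if len(pairs) else np.array([], bool)
    return MatchResult(
        pairs=pairs,
        r_squared_before=_r_squared(area_a, area_b),
        r_squared_after=_r_squared(area_a[keep], area_b[keep]),
        n_matched=int(len(pairs)),
        n_rejected=int(len(pairs) - keep.sum()),
    )
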