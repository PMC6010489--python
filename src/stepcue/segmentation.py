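"""Segmentation of digitized 2-D search trajectories into straight steps.

A path recorded on gridded paper and digitized to a polyline is cut into
straight runs using two criteria: a reorientation counts as a new segment
only when (1) the turn angle exceeds a threshold (default 45 degrees) and
(2) the path continues for at least a minimum run (default 4 cm) beyond
the turn, which discards on-the-spot turns.  Analysis stops once the
walker first exceeds a radius cap (default 4 m) from the release point.

Turn angles are measured run-to-run by default: the direction of the
current straight run (start to current vertex) against the mean outgoing
direction over the next `min_run` of path.  Hand-digitized polylines carry
jitter well below the threshold that must not fragment runs; criterion (2)
exists precisely to ignore it.  A vertex-to-vertex convention is available
via `turn_convention="vertex"`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Trajectory",
    "Segment",
    "PathSegmenter",
    "segment_path",
    "segment_metrics",
    "first_k_summary",
]


@dataclass
class Trajectory:
    """Ordered (x, y) positions in meters, origin at the release point."""

    points: np.ndarray
    id: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        # drop consecutive duplicates introduced by digitization
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
        pts = pts[keep]
        if len(pts) < 2:
            raise ValueError("trajectory needs at least 2 distinct points")
        self.points = pts


@dataclass(frozen=True)
class Segment:
    """A straight run: endpoints, arc length, heading, turn to next run."""

    start: tuple[float, float]
    end: tuple[float, float]
    length: float          # polyline arc length of the run (m)
    heading_deg: float     # direction of the end-start chord
    turn_deg: float | None  # absolute turn to the next segment; None for last
    dist_from_origin: float  # Euclidean distance of `end` from (0, 0)


def _arc_lengths(pts: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(pts, axis=0), axis=1)


def _clip_at_radius(pts: np.ndarray, radius: float) -> np.ndarray:
    """Truncate the polyline at its first crossing of the origin-centred circle."""
    r = np.linalg.norm(pts, axis=1)
    outside = np.nonzero(r > radius)[0]
    if outside.size == 0:
        return pts
    i = outside[0]
    if i == 0:
        raise ValueError("trajectory starts outside the analysis radius")
    p, q = pts[i - 1], pts[i]
    d = q - p
    # smallest t in (0, 1] with |p + t d| = radius
    a = d @ d
    b = 2.0 * (p @ d)
    c = p @ p - radius**2
    t = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
    crossing = p + t * d
    return np.vstack([pts[:i], crossing])


def _outgoing_direction(pts: np.ndarray, i: int, min_run: float):
    """Mean direction over the next >= min_run of path from vertex i.

    Returns None when less than min_run of path remains.
    """
    acc = 0.0
    for j in range(i + 1, len(pts)):
        step = np.linalg.norm(pts[j] - pts[j - 1])
        if acc + step >= min_run:
            t = (min_run - acc) / step
            endpoint = pts[j - 1] + t * (pts[j] - pts[j - 1])
            v = endpoint - pts[i]
            nv = np.linalg.norm(v)
            return v / nv if nv > 0 else None
        acc += step
    return None


def _angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return math.degrees(math.acos(c))


class PathSegmenter(TransformerMixin, BaseEstimator):
    """Transformer turning a Trajectory into a list of straight Segments.

    Parameters
    ----------
    angle_threshold_deg : float, default 45
        Strict threshold: a turn qualifies only when the angle exceeds it.
    min_run : float, default 0.04 (m)
        Minimum continuation of path beyond a qualifying turn.
    radius_cap : float, default 4.0 (m)
        Analysis stops at the first crossing of this radius from the origin.
    turn_convention : {"run", "vertex"}
        Reference direction for the turn test (see module docstring).
    length_convention : {"arc", "chord"}
        Report the polyline arc length of each run (sub-threshold wiggle is
        traveled path) or the straight-line chord.
    """

    def __init__(self, angle_threshold_deg: float = 45.0, min_run: float = 0.04,
                 radius_cap: float = 4.0, turn_convention: str = "run",
                 length_convention: str = "arc"):
        self.angle_threshold_deg = angle_threshold_deg
        self.min_run = min_run
        self.radius_cap = radius_cap
        self.turn_convention = turn_convention
        self.length_convention = length_convention

    def fit(self, X=None, y=None):
        if self.angle_threshold_deg <= 0 or self.min_run <= 0 or self.radius_cap <= 0:
            raise ValueError("thresholds must be positive")
        if self.turn_convention not in ("run", "vertex"):
            raise ValueError("turn_convention must be 'run' or 'vertex'")
        if self.length_convention not in ("arc", "chord"):
            raise ValueError("length_convention must be 'arc' or 'chord'")
        return self

    def transform(self, X):
        """Segment one Trajectory or a list of them."""
        self.fit()
        if isinstance(X, Trajectory):
            return self._segment_one(X)
        return [self._segment_one(t) for t in X]

    def _segment_one(self, traj: Trajectory) -> list[Segment]:
        pts = _clip_at_radius(traj.points, self.radius_cap)
        if len(pts) < 2:
            pts = traj.points[:2]
        total_arc = float(_arc_lengths(pts).sum())
        if total_arc < self.min_run:
            warnings.warn(
                f"trajectory {traj.id!r} shorter than min_run; "
                "reporting a single degenerate segment",
                stacklevel=2,
            )
            return self._build_segments(pts, [0, len(pts) - 1])

        breakpoints = [0]
        run_start = 0
        for i in range(1, len(pts) - 1):
            if self.turn_convention == "run":
                ref = pts[i] - pts[run_start]
            else:
                ref = pts[i] - pts[i - 1]
            nr = np.linalg.norm(ref)
            if nr == 0.0:
                continue
            ref = ref / nr
            out = _outgoing_direction(pts, i, self.min_run)
            if out is None:  # criterion (2): path must continue >= min_run
                break
            # strict ">" with a float-noise guard so an exact-threshold turn
            # does not qualify through rounding
            if _angle_between_deg(ref, out) > self.angle_threshold_deg + 1e-9:
                breakpoints.append(i)
                run_start = i
        breakpoints.append(len(pts) - 1)
        return self._build_segments(pts, breakpoints)

    def _build_segments(self, pts: np.ndarray, breakpoints: list[int]) -> list[Segment]:
        arcs = _arc_lengths(pts)
        cum = np.concatenate([[0.0], np.cumsum(arcs)])
        segs: list[Segment] = []
        chords = []
        for s, e in zip(breakpoints[:-1], breakpoints[1:]):
            chord = pts[e] - pts[s]
            chords.append(chord)
            length = (
                float(cum[e] - cum[s])
                if self.length_convention == "arc"
                else float(np.linalg.norm(chord))
            )
            segs.append(
                Segment(
                    start=(float(pts[s][0]), float(pts[s][1])),
                    end=(float(pts[e][0]), float(pts[e][1])),
                    length=length,
                    heading_deg=math.degrees(math.atan2(chord[1], chord[0])),
                    turn_deg=None,
                    dist_from_origin=float(np.linalg.norm(pts[e])),
                )
            )
        # absolute turn angle between consecutive chord directions
        out: list[Segment] = []
        for j, seg in enumerate(segs):
            turn = None
            if j + 1 < len(segs):
                u = chords[j] / np.linalg.norm(chords[j])
                v = chords[j + 1] / np.linalg.norm(chords[j + 1])
                turn = _angle_between_deg(u, v)
            out.append(
                Segment(
                    start=seg.start, end=seg.end, length=seg.length,
                    heading_deg=seg.heading_deg, turn_deg=turn,
                    dist_from_origin=seg.dist_from_origin,
                )
            )
        return out


def segment_path(traj: Trajectory, angle_threshold_deg: float = 45.0,
                 min_run: float = 0.04, radius_cap: float = 4.0,
                 **kwargs) -> list[Segment]:
    """Functional wrapper over PathSegmenter for a single trajectory."""
    return PathSegmenter(
        angle_threshold_deg=angle_threshold_deg, min_run=min_run,
        radius_cap=radius_cap, **kwargs,
    ).transform(traj)


def segment_metrics(segments: list[Segment]) -> pd.DataFrame:
    """Per-segment metrics table: index, |turn angle|, length, distance from start."""
    if not segments:
        raise ValueError("no segments")
    return pd.DataFrame(
        {
            "seg_index": np.arange(1, len(segments) + 1),
            "turn_deg": [s.turn_deg for s in segments],
            "length_m": [s.length for s in segments],
            "dist_m": [s.dist_from_origin for s in segments],
        }
    )


def first_k_summary(groups: dict[str, list[pd.DataFrame]], k: int = 20,
                    metrics: tuple[str, ...] = ("turn_deg", "length_m", "dist_m"),
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Across-individual mean and 95% t-interval of the first k segments.

    Individuals with fewer than k segments are excluded; the number
    excluded per condition is returned alongside the summary table.
    """
    rows = []
    excluded: dict[str, int] = {}
    for condition, tables in groups.items():
        kept = [t for t in tables if len(t) >= k]
        excluded[condition] = len(tables) - len(kept)
        if not kept:
            raise ValueError(
                f"no individual with >= {k} segments in condition {condition!r}"
            )
        for metric in metrics:
            data = np.array([t[metric].to_numpy()[:k] for t in kept], dtype=float)
            m = np.nanmean(data, axis=0)
            n_ind = data.shape[0]
            if n_ind > 1:
                se = np.nanstd(data, axis=0, ddof=1) / math.sqrt(n_ind)
                tcrit = stats.t.ppf(0.975, n_ind - 1)
                half = tcrit * se
            else:
                half = np.full(k, np.nan)
            for idx in range(k):
                rows.append(
                    {
                        "condition": condition,
                        "metric": metric,
                        "seg_index": idx + 1,
                        "mean": m[idx],
                        "ci_low": m[idx] - half[idx],
                        "ci_high": m[idx] + half[idx],
                        "n_individuals": n_ind,
                    }
                )
    return pd.DataFrame(rows), excluded
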