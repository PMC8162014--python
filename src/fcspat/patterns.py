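"""Point patterns in rectangular observation windows.

A :class:`PointPattern` is a finite set of planar points (meters) observed
inside a rectangular :class:`ObservationWindow`. These two types, together
with the elementary distance computations below, are the shared substrate of
every statistic in the package: nearest-neighbor summaries, Ripley's K, the
pair-correlation function, and the Monte-Carlo null-model machinery.

Coordinates are planar meters throughout. Geographic (lon/lat) input must be
projected before use; every formula here assumes Euclidean geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DuplicatePointsError,
    EmptyInputError,
    OutOfWindowError,
    TooFewPointsError,
)

__all__ = [
    "ObservationWindow",
    "PointPattern",
    "WINDOW_PRESETS",
    "window_preset",
    "make_pattern",
    "intensity",
    "nn_distances",
    "pairwise_distances",
    "expected_csr_mean_nn",
]


@dataclass(frozen=True)
class ObservationWindow:
    """Axis-aligned rectangular observation window.

    Parameters
    ----------
    x_min, y_min : float
        Coordinates of the lower-left corner (m).
    width, height : float
        Side lengths (m); both must be positive.
    """

    x_min: float
    y_min: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"window sides must be positive, got {self.width} x {self.height}"
            )

    @property
    def x_max(self) -> float:
        return self.x_min + self.width

    @property
    def y_max(self) -> float:
        return self.y_min + self.height

    @property
    def area(self) -> float:
        """Window area A = width x height (m^2)."""
        return self.width * self.height

    @property
    def shorter_side(self) -> float:
        return min(self.width, self.height)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside or on the boundary of the window."""
        pts = np.asarray(points, dtype=float)
        return (
            (pts[:, 0] >= self.x_min)
            & (pts[:, 0] <= self.x_max)
            & (pts[:, 1] >= self.y_min)
            & (pts[:, 1] <= self.y_max)
        )

    def anchored_at(self, x_min: float, y_min: float) -> "ObservationWindow":
        """Same-size window translated to a new lower-left corner."""
        return replace(self, x_min=x_min, y_min=y_min)


#: Study-plot window presets (origin at (0, 0); re-anchor as needed).
#: The five 25-ha plots are 500 m x 500 m; the two interdune-valley plots
#: are 800 m x 330 m (26.4 ha) and 800 m x 400 m (32 ha).
WINDOW_PRESETS: dict[str, ObservationWindow] = {
    "Gir-1": ObservationWindow(0.0, 0.0, 500.0, 500.0),
    "Gir-3": ObservationWindow(0.0, 0.0, 500.0, 500.0),
    "Bra-1": ObservationWindow(0.0, 0.0, 500.0, 500.0),
    "Bra-2": ObservationWindow(0.0, 0.0, 500.0, 500.0),
    "Bra-3": ObservationWindow(0.0, 0.0, 500.0, 500.0),
    "Gar-1": ObservationWindow(0.0, 0.0, 800.0, 330.0),
    "Gar-2": ObservationWindow(0.0, 0.0, 800.0, 400.0),
}


def window_preset(name: str) -> ObservationWindow:
    """Look up a study-plot window preset by name (case-insensitive)."""
    key = name.strip()
    for preset_name, win in WINDOW_PRESETS.items():
        if preset_name.lower() == key.lower():
            return win
    raise KeyError(
        f"unknown window preset {name!r}; available: {sorted(WINDOW_PRESETS)}"
    )


@dataclass(frozen=True)
class PointPattern:
    """A validated set of planar points inside an observation window.

    Build instances through :func:`make_pattern`, which enforces the
    invariants (points in window, no exact duplicates, finite coordinates).
    """

    points: np.ndarray  # shape (n, 2), float64
    window: ObservationWindow
    label: str = ""

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def translated(self, dx: float, dy: float) -> "PointPattern":
        """Rigid translation of points and window together."""
        return PointPattern(
            points=self.points + np.array([dx, dy]),
            window=self.window.anchored_at(
                self.window.x_min + dx, self.window.y_min + dy
            ),
            label=self.label,
        )

    def scaled(self, c: float) -> "PointPattern":
        """Multiply all coordinates and window dimensions by c > 0."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        win = self.window
        return PointPattern(
            points=self.points * c,
            window=ObservationWindow(
                win.x_min * c, win.y_min * c, win.width * c, win.height * c
            ),
            label=self.label,
        )


def make_pattern(
    points,
    window: ObservationWindow,
    label: str = "",
    *,
    allow_empty: bool = False,
) -> PointPattern:
    """Validate coordinates and build a :class:`PointPattern`.

    Parameters
    ----------
    points : array-like of shape (n, 2)
        Planar coordinates in meters.
    window : ObservationWindow
        Rectangle that must contain every point (boundary inclusive).
    label : str
        Free-text label carried through results (e.g. ``"Gir-1 Fairy Circles"``).
    allow_empty : bool
        Permit n = 0 (needed for conditional simulations of empty patterns).

    Raises
    ------
    EmptyInputError, OutOfWindowError, DuplicatePointsError
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        pts = pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must have shape (n, 2), got {pts.shape}")
    if pts.shape[0] == 0:
        if not allow_empty:
            raise EmptyInputError(
                "empty point set; pass allow_empty=True if intentional"
            )
        return PointPattern(points=pts, window=window, label=label)
    if not np.all(np.isfinite(pts)):
        bad = np.nonzero(~np.isfinite(pts).all(axis=1))[0]
        raise ValueError(f"non-finite coordinates at rows {bad.tolist()}")
    inside = window.contains(pts)
    if not inside.all():
        offending = np.nonzero(~inside)[0]
        raise OutOfWindowError(
            f"{offending.size} point(s) outside the window at indices "
            f"{offending.tolist()[:20]}"
        )
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] != pts.shape[0]:
        raise DuplicatePointsError(
            f"{pts.shape[0] - uniq.shape[0]} exact duplicate coordinate(s); "
            "duplicate mapped objects indicate digitization faults"
        )
    return PointPattern(points=pts, window=window, label=label)


def intensity(pattern: PointPattern) -> float:
    """Point intensity lambda = n / A (points per m^2)."""
    if pattern.n == 0:
        raise EmptyInputError("intensity undefined for an empty pattern")
    return pattern.n / pattern.window.area


def _require_pairs(pattern: PointPattern, op: str) -> None:
    if pattern.n < 2:
        raise TooFewPointsError(f"{op} needs at least 2 points, got {pattern.n}")


def nn_distances(pattern: PointPattern) -> np.ndarray:
    """Per-point nearest-neighbor distances (m), no edge correction.

    Element i is the minimum Euclidean distance from point i to any other
    point of the same pattern.
    """
    _require_pairs(pattern, "nn_distances")
    tree = cKDTree(pattern.points)
    dist, _ = tree.query(pattern.points, k=2)
    return dist[:, 1]


def pairwise_distances(pattern: PointPattern) -> np.ndarray:
    """Full symmetric n x n Euclidean distance matrix."""
    _require_pairs(pattern, "pairwise_distances")
    return squareform(pdist(pattern.points))


def expected_csr_mean_nn(lam: float) -> float:
    """CSR expectation of the mean nearest-neighbor distance, 1 / (2 sqrt(lambda))."""
    if lam <= 0:
        raise ValueError("intensity must be positive")
    return 0.5 / math.sqrt(lam)
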