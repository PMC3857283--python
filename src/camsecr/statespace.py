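"""State-space construction: the discretised set of candidate activity centres.

The SECR state space S is the rectangle bounding the trap array, extended by
a buffer wide enough that animals outside it have effectively zero chance of
being photographed, and discretised to a regular mesh.  Each mesh point is a
candidate activity (home-range) centre, carrying a habitat-suitability flag;
unsuitable points (e.g. arable land offering no hunting cover) are excluded
from the centre prior and from the area used to convert abundance to density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .captures import CaptureFormatError, TrapStation

__all__ = ["StateSpace", "build_statespace", "apply_habitat_mask",
           "read_statespace", "write_statespace"]


@dataclass
class StateSpace:
    points: np.ndarray          # (P, 2) planar km
    suitable: np.ndarray        # (P,) bool
    spacing: float              # km between adjacent mesh points
    buffer: float               # km added around the trap rectangle
    shape: tuple[int, int] = field(default=None)  # (nx, ny) grid dimensions

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.suitable = np.asarray(self.suitable, dtype=bool)
        if len(self.points) != len(self.suitable):
            raise ValueError("points and suitability flags differ in length")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def suitable_area(self) -> float:
        """km² represented by the suitable mesh points."""
        return float(self.suitable.sum()) * self.spacing ** 2

    @property
    def suitable_points(self) -> np.ndarray:
        return self.points[self.suitable]


def build_statespace(
    stations: list[TrapStation], buffer_km: float = 20.0, spacing_km: float = 1.0
) -> StateSpace:
    """Mesh the buffered trap rectangle at a regular spacing.

    The grid is anchored at (xmin - B, ymin - B) with inclusive endpoints,
    so a trap extent of 6 x 5 km with a 10 km buffer at 1 km spacing yields
    27 x 26 = 702 points.  All points start suitable.  Buffers that differ
    by a multiple of the spacing produce nested grids.
    """
    if buffer_km <= 0 or spacing_km <= 0:
        raise ValueError("buffer_km and spacing_km must be positive")
    if spacing_km > 2 * buffer_km:
        warnings.warn(
            f"mesh spacing {spacing_km} km is coarse relative to buffer {buffer_km} km",
            stacklevel=2,
        )
    xy = np.array([[s.x, s.y] for s in stations])
    x0, y0 = xy.min(axis=0) - buffer_km
    x1, y1 = xy.max(axis=0) + buffer_km
    nx = int(np.floor((x1 - x0) / spacing_km + 1e-9)) + 1
    ny = int(np.floor((y1 - y0) / spacing_km + 1e-9)) + 1
    gx = x0 + spacing_km * np.arange(nx)
    gy = y0 + spacing_km * np.arange(ny)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    return StateSpace(pts, np.ones(len(pts), bool), spacing_km, buffer_km, (nx, ny))


def apply_habitat_mask(ss: StateSpace, mask) -> StateSpace:
    """Flag mesh points inside ``mask`` as unsuitable habitat.

    ``mask`` is a shapely geometry, an iterable of geometries, or a boolean
    array (True = unsuitable).  Trap locations are untouched: masking removes
    candidate activity centres, never detectors.
    """
    unsuitable = np.zeros(ss.n_points, bool)
    if isinstance(mask, np.ndarray) and mask.dtype == bool:
        if len(mask) != ss.n_points:
            raise ValueError("boolean mask length must equal the point count")
        unsuitable = mask.copy()
    else:
        geoms = [mask] if isinstance(mask, shapely.Geometry) else list(mask)
        for g in geoms:
            unsuitable |= shapely.contains_xy(g, ss.points[:, 0], ss.points[:, 1])
    suitable = ss.suitable & ~unsuitable
    if not suitable.any():
        raise ValueError("habitat mask covers every mesh point: no suitable habitat")
    return StateSpace(ss.points.copy(), suitable, ss.spacing, ss.buffer, ss.shape)


def write_statespace(ss: StateSpace, path) -> None:
    """Write the X, Y, HABITAT table (HABITAT 1 = suitable)."""
    pd.DataFrame(
        {"X": ss.points[:, 0], "Y": ss.points[:, 1], "HABITAT": ss.suitable.astype(int)}
    ).to_csv(path, index=False)


def read_statespace(
    ss_or_path, spacing_km: float | None = None, buffer_km: float | None = None,
    units: str = "km",
) -> StateSpace:
    """Read an X, Y, HABITAT table back into a StateSpace.

    The mesh spacing is inferred from the coordinate lattice when not given.
    ``units='m'`` converts metre coordinates (typical of raw UTM exports) to
    the package's working km.
    """
    df = pd.read_csv(ss_or_path)
    required = {"X", "Y", "HABITAT"}
    if not required <= set(df.columns):
        raise CaptureFormatError(f"state-space file must have columns {sorted(required)}")
    hab = df["HABITAT"].to_numpy()
    if not np.isin(hab, (0, 1)).all():
        raise CaptureFormatError("HABITAT values must be 0 or 1")
    scale = 1e-3 if units == "m" else 1.0
    pts = df[["X", "Y"]].to_numpy(float) * scale
    if spacing_km is None:
        ux = np.unique(pts[:, 0])
        uy = np.unique(pts[:, 1])
        cand = np.concatenate([np.diff(ux), np.diff(uy)])
        cand = cand[cand > 1e-9]
        if len(cand) == 0:
            raise CaptureFormatError("cannot infer mesh spacing from a single point")
        spacing_km = float(cand.min())
    return StateSpace(pts, hab.astype(bool), spacing_km, buffer_km or np.nan, None)
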