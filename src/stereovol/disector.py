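"""Physical disector counting with unbiased counting frames.

A particle is counted ("a top", Q⁻) when its profile appears in the
reference section but not in the adjacent look-up section, and the reference
profile is selected by the unbiased counting frame: it must intersect the
frame and touch neither the forbidden (left + bottom) edges nor their
infinite extensions (upward from the top-left corner, downward from the
bottom-right corner).  Tiling the plane with such frames counts every
profile exactly once.

Numerical density: Nv = sum(Q⁻) / sum(a * h), with ``a`` the frame area
actually examined per reference section and ``h`` the disector height (the
section thickness for physical disectors on consecutive sections).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from shapely.geometry import LineString, Polygon, box

from .cavalieri import VolumeEstimate
from .phantom import UM3_PER_MM3
from .sectioning import SectionStack

__all__ = [
    "CountingFrame",
    "DisectorCount",
    "DensityEstimate",
    "frame_select",
    "frame_select_circles",
    "count_Q_minus",
    "numerical_density",
    "total_number",
    "tile_frames",
    "disector_pair_counts",
]


@dataclass(frozen=True)
class CountingFrame:
    """Unbiased counting frame at (x, y) with admission top/right edges and
    forbidden left/bottom edges plus their extensions."""

    x: float
    y: float
    width: float
    height: float
    extension_um: float = 1e6   # finite stand-in for the infinite extensions

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be > 0")

    @property
    def area_um2(self) -> float:
        return self.width * self.height

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.x + self.width, self.y + self.height)

    def forbidden_line(self) -> LineString:
        """Forbidden polyline: down from below the bottom-right corner,
        along the bottom and left edges, up beyond the top-left corner."""
        e = self.extension_um
        return LineString(
            [
                (self.x + self.width, self.y - e),
                (self.x + self.width, self.y),
                (self.x, self.y),            # bottom edge (right to left)
                (self.x, self.y + self.height),
                (self.x, self.y + self.height + e),  # up from top-left
            ]
        )


def frame_select(profiles: Iterable[Polygon], frame: CountingFrame) -> list[int]:
    """Indices of profiles selected by the counting-frame rule.

    A profile is selected iff it intersects the (closed) frame and does not
    intersect the forbidden line or its extensions.
    """
    fbox = box(*frame.bounds)
    forbidden = frame.forbidden_line()
    out = []
    for k, geom in enumerate(profiles):
        if geom.is_empty:
            continue
        if geom.intersects(fbox) and not geom.intersects(forbidden):
            out.append(k)
    return out


def _dist_point_segment(
    px: np.ndarray, py: np.ndarray, ax: float, ay: float, bx: float, by: float
) -> np.ndarray:
    vx, vy = bx - ax, by - ay
    vv = vx * vx + vy * vy
    tt = np.clip(((px - ax) * vx + (py - ay) * vy) / vv, 0.0, 1.0) if vv > 0 else 0.0
    dx = px - (ax + tt * vx)
    dy = py - (ay + tt * vy)
    return np.hypot(dx, dy)


def frame_select_circles(
    cx: np.ndarray, cy: np.ndarray, r: np.ndarray, frame: CountingFrame
) -> np.ndarray:
    """Vectorized counting-frame rule for circular profiles.

    Returns a boolean mask.  A circle intersects the closed frame iff the
    distance from its centre to the rectangle is <= r; it touches the
    forbidden line iff the distance to the polyline is <= r.  Degenerate
    (r = 0) profiles are points: inside-the-frame counts, on the forbidden
    line rejects (measure zero in practice).
    """
    cx = np.asarray(cx, float)
    cy = np.asarray(cy, float)
    r = np.asarray(r, float)
    x0, y0, x1, y1 = frame.bounds
    dx = np.maximum(np.maximum(x0 - cx, 0.0), cx - x1)
    dy = np.maximum(np.maximum(y0 - cy, 0.0), cy - y1)
    hits_frame = np.hypot(dx, dy) <= r + 0.0
    e = frame.extension_um
    segs = (
        (x1, y0 - e, x1, y0),
        (x1, y0, x0, y0),
        (x0, y0, x0, y1),
        (x0, y1, x0, y1 + e),
    )
    d_forb = np.full(cx.shape, np.inf)
    for ax, ay, bx, by in segs:
        d_forb = np.minimum(d_forb, _dist_point_segment(cx, cy, ax, ay, bx, by))
    return hits_frame & (d_forb > r)


def tile_frames(
    width: float,
    height: float,
    frame_w: float,
    frame_h: float,
    x0: float = 0.0,
    y0: float = 0.0,
) -> list[CountingFrame]:
    """Contiguous tiling of [x0, x0+width) x [y0, y0+height) with frames."""
    nx = max(int(round(width / frame_w)), 1)
    ny = max(int(round(height / frame_h)), 1)
    return [
        CountingFrame(x=x0 + i * frame_w, y=y0 + j * frame_h, width=frame_w, height=frame_h)
        for i in range(nx)
        for j in range(ny)
    ]


def count_Q_minus(
    reference: pd.DataFrame,
    lookup: pd.DataFrame,
    frame: CountingFrame,
    reference_index: int | None = None,
    lookup_index: int | None = None,
) -> int:
    """Tops: frame-selected reference profiles whose cell is absent from the
    look-up section.

    ``reference``/``lookup`` are profile tables (columns cell_id, u, v, ru,
    rv[, ghost]) as produced by :meth:`SectionStack.profiles`.  Sections must
    be consecutive when indices are given.  Circular profiles use the exact
    vectorized rule; elliptic ones are treated via their mean radius (the
    profile tables of axis-aligned phantoms are circles whenever cells are
    spheres).
    """
    if reference_index is not None and lookup_index is not None:
        if abs(reference_index - lookup_index) != 1:
            raise ValueError("disector sections must be consecutive")
    if reference.empty:
        return 0
    lookup_ids = set(lookup["cell_id"].tolist())
    r_eff = np.sqrt(reference["ru"].to_numpy() * reference["rv"].to_numpy())
    sel = frame_select_circles(
        reference["u"].to_numpy(), reference["v"].to_numpy(), r_eff, frame
    )
    ids = reference["cell_id"].to_numpy()[sel]
    return int(sum(1 for cid in ids if cid not in lookup_ids))


@dataclass(frozen=True)
class DisectorCount:
    """Q⁻ tally for one frame on one ordered section pair."""

    pair_id: int
    Q_minus: int
    frame_area_um2: float
    height_um: float
    direction: int = 0   # 0: lower section is reference; 1: upper

    def __post_init__(self) -> None:
        if self.Q_minus < 0:
            raise ValueError("Q_minus must be >= 0")
        if self.frame_area_um2 <= 0 or self.height_um <= 0:
            raise ValueError("frame area and height must be > 0")


@dataclass(frozen=True)
class DensityEstimate:
    """Numerical density with its sampling bookkeeping."""

    Nv_per_mm3: float
    total_Q: int
    total_volume_mm3: float

    @property
    def Nv_per_1e3_mm3(self) -> float:
        """Nv in the reporting unit ×10³/mm³."""
        return self.Nv_per_mm3 / 1e3

    def to_dict(self) -> dict:
        return {
            "Nv_per_mm3": self.Nv_per_mm3,
            "Nv_per_1e3_mm3": self.Nv_per_1e3_mm3,
            "total_Q": self.total_Q,
            "total_volume_mm3": self.total_volume_mm3,
        }


def numerical_density(counts: Sequence[DisectorCount]) -> DensityEstimate:
    """Nv = sum(Q⁻) / sum(a * h), converted to cells per mm³."""
    if not counts:
        raise ValueError("need at least one disector count")
    h0 = counts[0].height_um
    for c in counts:
        if c.height_um != h0:
            raise ValueError("disector heights differ across counts")
    total_q = sum(c.Q_minus for c in counts)
    vol_um3 = sum(c.frame_area_um2 * c.height_um for c in counts)
    if vol_um3 <= 0:
        raise ValueError("sampled volume is zero")
    vol_mm3 = vol_um3 / UM3_PER_MM3
    return DensityEstimate(
        Nv_per_mm3=total_q / vol_mm3, total_Q=int(total_q), total_volume_mm3=vol_mm3
    )


def total_number(
    density: DensityEstimate,
    volume: VolumeEstimate | float,
    decimals: int | None = 3,
) -> float:
    """Total particle number N = Nv x Vref, in units of 10⁶.

    ``volume`` is a Cavalieri estimate (or a plain mm³ value) for the same
    reference space as the density estimate.  ``decimals`` rounds the 10⁶
    value for report parity with printed tables (3 decimals); pass None to
    keep full precision (e.g. for small phantoms).
    """
    v_mm3 = volume.V_mm3 if isinstance(volume, VolumeEstimate) else float(volume)
    if v_mm3 < 0:
        raise ValueError("reference volume must be >= 0")
    n = density.Nv_per_mm3 * v_mm3 / 1e6
    return round(n, decimals) if decimals is not None else n


def disector_pair_counts(
    stack: SectionStack,
    pairs: Sequence[tuple[int, int]],
    frame_w: float,
    frame_h: float,
    both_directions: bool = True,
) -> list[DisectorCount]:
    """Run counting frames tiled over the footprint on each sampled pair.

    For each pair, the lower section serves as reference against the upper
    look-up (direction 0) and, when ``both_directions``, the roles are
    swapped (direction 1).  Ghost profiles from the lateral wrap make the
    tiling edge-exact, so each top is counted once.
    """
    if stack.footprint_uv is None:
        raise ValueError("stack has no rectangular footprint to tile")
    lu, lv = stack.footprint_uv
    frames = tile_frames(lu, lv, frame_w, frame_h)
    h = stack.thickness_um
    out: list[DisectorCount] = []
    for pid, (i, j) in enumerate(pairs):
        if abs(i - j) != 1:
            raise ValueError("disector pairs must be consecutive sections")
        prof_i = stack.profiles(i, missing_ok=True)
        prof_j = stack.profiles(j, missing_ok=True)
        directions = ((0, i, prof_i, prof_j),) if not both_directions else (
            (0, i, prof_i, prof_j),
            (1, j, prof_j, prof_i),
        )
        for d, ref_idx, ref, look in directions:
            # a reference plane outside the exhaustively cut block is not
            # examined area: it contributes neither counts nor volume
            if not 0 <= ref_idx < stack.n_sections:
                continue
            look_ids = set(look["cell_id"].tolist())
            u = ref["u"].to_numpy()
            v = ref["v"].to_numpy()
            r_eff = np.sqrt(ref["ru"].to_numpy() * ref["rv"].to_numpy())
            ids = ref["cell_id"].to_numpy()
            is_top = np.fromiter(
                (cid not in look_ids for cid in ids), count=len(ids), dtype=bool
            )
            for f in frames:
                if not len(u):
                    q = 0
                else:
                    sel = frame_select_circles(u, v, r_eff, f)
                    q = int(np.count_nonzero(sel & is_top))
                out.append(
                    DisectorCount(
                        pair_id=pid,
                        Q_minus=q,
                        frame_area_um2=f.area_um2,
                        height_um=h,
                        direction=d,
                    )
                )
    return out
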