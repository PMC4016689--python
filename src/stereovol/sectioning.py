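"""Virtual microtome: serial sections and vertical sections from a phantom.

Serial ("coronal") sections are slabs of thickness ``t`` along the phantom's
z axis.  Slab ``i`` covers the half-open interval ``[i*t, (i+1)*t)`` so slab
boundaries are attributed exactly once.  A cell *appears* in a slab when its
body intersects the slab with positive extent; its *profile* geometry (area,
in-plane boundary) is taken at the slab mid-plane, matching how a semi-thin
section is treated as a plane for area measurement but as a slab of height
``h = t`` for the disector.

Vertical sections: the phantom's z axis is the designated vertical axis.
The phantom is split into bars (blocks) along x; each block independently
receives a uniform random azimuth in [0, pi) and is cut into serial slabs
whose planes contain the vertical axis direction.  The in-plane direction of
the vertical axis is recorded for every section, which is what the nucleator
needs for sine-weighted ray directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

from .phantom import Phantom

__all__ = [
    "SectionPlan",
    "SectionStack",
    "VerticalBlock",
    "cut_serial_sections",
    "sample_section_pairs",
    "cut_vertical_sections",
]


@dataclass(frozen=True)
class SectionPlan:
    """Sectioning and sampling design.

    thickness_um: section (slab) thickness t, default the 2 µm of semi-thin
    sectioning.  period: number of sections between sampled items in the
    systematic uniform random (SUR) scheme.  random_start, if given, must lie
    in [0, period); otherwise it is drawn uniformly at sampling time.
    """

    thickness_um: float = 2.0
    axis: str = "z"
    period: int = 200
    random_start: int | None = None
    paired: bool = True

    def validate(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("section thickness must be > 0")
        if self.axis not in ("x", "y", "z"):
            raise ValueError(f"degenerate sectioning axis {self.axis!r}")
        if self.period < 1:
            raise ValueError("sampling period must be >= 1")
        if self.random_start is not None and not 0 <= self.random_start < self.period:
            raise ValueError("random_start must lie in [0, period)")


_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass
class SectionStack:
    """Ordered serial sections of one phantom (or one vertical block).

    Holds per-cell slab spans; per-section profile tables are computed on
    demand.  ``first_slab``/``last_slab`` are inclusive slab indices of each
    cell's appearance span along the cutting axis.
    """

    phantom: Phantom
    plan: SectionPlan
    n_sections: int
    axis_index: int
    # per-cell geometry in the cutting frame: s = coordinate along the
    # cutting normal, (u, v) in-plane; for serial sections u, v are the two
    # remaining box axes and wrap metadata is carried through
    s_center: np.ndarray
    s_extent: np.ndarray          # caliper semi-extent along the normal
    first_slab: np.ndarray
    last_slab: np.ndarray
    uv_centers: np.ndarray        # (n, 2)
    uv_semi_axes: np.ndarray      # (n, 2) profile semi-axes scale at centre plane
    s_nucleolus: np.ndarray
    uv_nucleoli: np.ndarray
    footprint_uv: tuple[float, float] | None   # rectangle (Lu, Lv) or None
    wrap_lengths: tuple[float | None, float | None] = (None, None)
    vertical_axis_uv: tuple[float, float] | None = None
    azimuth: float | None = None
    cell_ids: np.ndarray | None = None         # row -> phantom cell id
    axis_length_um: float | None = None

    @property
    def thickness_um(self) -> float:
        return self.plan.thickness_um

    def appearance_counts(self) -> np.ndarray:
        """Number of consecutive sections each cell appears in."""
        return self.last_slab - self.first_slab + 1

    def cells_in_section(self, i: int) -> np.ndarray:
        return np.flatnonzero((self.first_slab <= i) & (self.last_slab >= i))

    def profiles(
        self, i: int, include_ghosts: bool = True, missing_ok: bool = False
    ) -> pd.DataFrame:
        """Mid-plane profile table for section ``i``.

        Columns: cell_id, u, v (profile centre), ru, rv (profile semi-axes,
        0 where the mid-plane misses a cell that still intersects the slab),
        area_um2, nucleolus_hit (nucleolus inside this slab), ghost (lateral
        periodic duplicate).  Ghost copies of profiles within one profile
        diameter of a wrapped edge are appended so counting-frame rules see
        the same neighbourhood as an interior field.
        """
        if not 0 <= i < self.n_sections:
            if missing_ok:
                # a plane outside the exhaustively cut block: empty section
                idx = np.empty(0, dtype=int)
            else:
                raise IndexError(f"section index {i} out of range")
        else:
            idx = self.cells_in_section(i)
        z_mid = (i + 0.5) * self.thickness_um
        dz = z_mid - self.s_center[idx]
        # profile semi-axes shrink with distance from the centre plane:
        # scale = sqrt(1 - (dz/extent)^2), clipped at 0 when the mid-plane
        # misses the cell (appearance via slab overlap only)
        with np.errstate(invalid="ignore"):
            scale = np.sqrt(np.clip(1.0 - (dz / self.s_extent[idx]) ** 2, 0.0, None))
        ru = self.uv_semi_axes[idx, 0] * scale
        rv = self.uv_semi_axes[idx, 1] * scale
        nuc_slab = np.floor(self.s_nucleolus[idx] / self.thickness_um).astype(int)
        ids = idx if self.cell_ids is None else self.cell_ids[idx]
        df = pd.DataFrame(
            {
                "cell_id": ids,
                "u": self.uv_centers[idx, 0],
                "v": self.uv_centers[idx, 1],
                "ru": ru,
                "rv": rv,
                "area_um2": np.pi * ru * rv,
                "nucleolus_hit": nuc_slab == i,
                "ghost": False,
            }
        )
        if include_ghosts:
            df = self._add_ghosts(df)
        return df

    def _add_ghosts(self, df: pd.DataFrame) -> pd.DataFrame:
        frames = [df]
        for k, col in ((0, "u"), (1, "v")):
            L = self.wrap_lengths[k]
            if L is None:
                continue
            rmax = df["ru"].max() if col == "u" else df["rv"].max()
            if not np.isfinite(rmax):
                continue
            margin = float(rmax) + 1e-9
            for shift in (-L, L):
                pos = df[col] + shift
                keep = (pos > -margin) & (pos < L + margin)
                if keep.any():
                    g = df.loc[keep].copy()
                    g[col] = pos[keep]
                    g["ghost"] = True
                    frames.append(g)
        return pd.concat(frames, ignore_index=True) if len(frames) > 1 else df

    def region_profile_area_um2(self, i: int) -> float:
        """Exact area of the layer-region footprint on section ``i``."""
        if self.footprint_uv is None:
            raise ValueError("stack has no rectangular footprint")
        if not 0 <= i < self.n_sections:
            return 0.0
        if self.axis_length_um is not None:
            z_mid = (i + 0.5) * self.thickness_um
            if z_mid > self.axis_length_um:
                return 0.0
        return self.footprint_uv[0] * self.footprint_uv[1]


def _slab_span(
    s_lo: np.ndarray, s_hi: np.ndarray, t: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive slab index span intersected by [s_lo, s_hi] with positive
    measure, slabs being [i t, (i+1) t)."""
    lo = s_lo / t
    hi = s_hi / t
    first = np.floor(lo).astype(int)
    # a span starting exactly on a boundary leaves zero measure in the slab
    # below it; tolerance is absolute in slab units
    on_edge = np.isclose(lo, np.round(lo), rtol=0.0, atol=1e-9)
    first = np.where(on_edge, np.round(lo).astype(int), first)
    last = np.ceil(hi).astype(int) - 1
    hi_edge = np.isclose(hi, np.round(hi), rtol=0.0, atol=1e-9)
    last = np.where(hi_edge, np.round(hi).astype(int) - 1, last)
    return first, np.maximum(last, first)


def cut_serial_sections(phantom: Phantom, plan: SectionPlan) -> SectionStack:
    """Exhaustively cut the phantom into serial slabs along ``plan.axis``.

    The slab structure starts at coordinate 0 (the region's face), and
    ``n_sections = ceil(Lz / t)`` tiles the region with no gaps or overlaps.
    """
    plan.validate()
    if phantom.true_cell_count == 0:
        raise ValueError("phantom has no cells")
    ax = _AXIS[plan.axis]
    L_axis = phantom.region_size_um[ax]
    if L_axis <= 0:
        raise ValueError("region has zero extent along the sectioning axis")
    t = plan.thickness_um
    n_sections = int(math.ceil(L_axis / t - 1e-12))

    uv_axes = [k for k in range(3) if k != ax]
    s_center = phantom.centers[:, ax].astype(float)
    s_extent = phantom.semi_axes[:, ax].astype(float)
    first, last = _slab_span(s_center - s_extent, s_center + s_extent, t)

    wrap: list[float | None] = [None, None]
    if phantom.periodic_lateral and plan.axis == "z":
        wrap = [phantom.region_size_um[uv_axes[0]], phantom.region_size_um[uv_axes[1]]]

    return SectionStack(
        phantom=phantom,
        plan=plan,
        n_sections=n_sections,
        axis_index=ax,
        s_center=s_center,
        s_extent=s_extent,
        first_slab=first,
        last_slab=last,
        uv_centers=phantom.centers[:, uv_axes].astype(float),
        uv_semi_axes=phantom.semi_axes[:, uv_axes].astype(float),
        s_nucleolus=phantom.nucleoli[:, ax].astype(float),
        uv_nucleoli=phantom.nucleoli[:, uv_axes].astype(float),
        footprint_uv=(phantom.region_size_um[uv_axes[0]], phantom.region_size_um[uv_axes[1]]),
        wrap_lengths=(wrap[0], wrap[1]),
        axis_length_um=L_axis,
    )


def sample_section_pairs(
    total_sections: int,
    period: int,
    seed: int | np.random.Generator | None = None,
    random_start: int | None = None,
    include_leading_pair: bool = False,
) -> list[tuple[int, int]]:
    """Systematic uniform random sampling of consecutive section pairs.

    The first pair starts at a uniform random index in [0, period); each
    subsequent pair starts ``period`` sections later, up to the last cut
    section.  The series is exhaustive, so the look-up partner of the final
    section is the empty plane just past the block (index ``total_sections``)
    — nothing of the specimen lies there.  With ``include_leading_pair`` the
    systematic lattice is extended one step below the block (pair
    ``(start - period, start - period + 1)`` when that reaches index -1 or
    0), which gives both disector directions exactly equal coverage of every
    slab; reference slabs outside the block are empty.
    """
    if total_sections < 2:
        raise ValueError("need at least 2 sections to form a pair")
    if not 1 <= period <= total_sections:
        raise ValueError("period must lie in [1, total_sections]")
    if random_start is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        start = int(rng.integers(0, period))
    else:
        if not 0 <= random_start < period:
            raise ValueError("random_start must lie in [0, period)")
        start = random_start
    pairs = [(i, i + 1) for i in range(start, total_sections, period)]
    if include_leading_pair and start - period >= -1:
        pairs.insert(0, (start - period, start - period + 1))
    return pairs


@dataclass
class VerticalBlock:
    """One bar of the phantom cut as a vertical-section series.

    ``azimuth`` is the uniform random rotation of the section plane about the
    vertical (z) axis; ``stack`` holds the serial slabs along the rotated
    normal.  In the stack's in-plane (u, v) frame, u is the horizontal
    direction ``(cos azimuth, sin azimuth, 0)`` and v is the vertical axis,
    so ``vertical_axis_uv = (0, 1)``.
    """

    block_id: int
    azimuth: float
    stack: SectionStack
    cell_ids: np.ndarray


def cut_vertical_sections(
    phantom: Phantom,
    plan: SectionPlan,
    n_blocks: int = 4,
    seed: int | np.random.Generator | None = None,
) -> list[VerticalBlock]:
    """Cut the phantom into ``n_blocks`` bars along x; section each bar
    vertically with an independent uniform azimuth in [0, pi).

    Within a block, cells are assigned by centre position.  Slab coordinates
    are measured along the rotated normal from the block's own origin, offset
    so that slab 0 is the first slab intersecting any cell of the block.
    """
    plan.validate()
    if phantom.true_cell_count == 0:
        raise ValueError("phantom has no cells")
    if n_blocks < 1:
        raise ValueError("need at least one block")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = plan.thickness_um
    lx = phantom.region_size_um[0]
    edges = np.linspace(0.0, lx, n_blocks + 1)
    block_of_cell = np.clip(
        np.searchsorted(edges, phantom.centers[:, 0], side="right") - 1, 0, n_blocks - 1
    )

    blocks: list[VerticalBlock] = []
    for b in range(n_blocks):
        ids = np.flatnonzero(block_of_cell == b)
        azimuth = float(rng.uniform(0.0, math.pi))
        if ids.size == 0:
            continue
        h = np.array([math.cos(azimuth), math.sin(azimuth), 0.0])
        normal = np.array([-math.sin(azimuth), math.cos(azimuth), 0.0])
        centers = phantom.centers[ids]
        nucleoli = phantom.nucleoli[ids]
        semi = phantom.semi_axes[ids]
        s_center = centers @ normal
        # caliper semi-extent of an axis-aligned ellipsoid along the normal
        s_extent = np.sqrt(((semi * normal) ** 2).sum(axis=1))
        s_nuc = nucleoli @ normal
        # shift so slab indices start at 0 with a random phase inside one slab
        origin = float((s_center - s_extent).min()) - float(rng.uniform(0.0, t))
        s_center = s_center - origin
        s_nuc = s_nuc - origin
        first, last = _slab_span(s_center - s_extent, s_center + s_extent, t)
        n_sections = int(last.max()) + 1
        u_c = centers @ h
        v_c = centers[:, 2]
        # in-plane profile semi-axes at the centre plane
        ru = np.sqrt(((semi * h) ** 2).sum(axis=1))
        rv = semi[:, 2]
        stack = SectionStack(
            phantom=phantom,
            plan=plan,
            n_sections=n_sections,
            axis_index=-1,
            s_center=s_center,
            s_extent=s_extent,
            first_slab=first,
            last_slab=last,
            uv_centers=np.column_stack([u_c, v_c]),
            uv_semi_axes=np.column_stack([ru, rv]),
            s_nucleolus=s_nuc,
            uv_nucleoli=np.column_stack([nucleoli @ h, nucleoli[:, 2]]),
            footprint_uv=None,
            wrap_lengths=(None, None),
            vertical_axis_uv=(0.0, 1.0),
            azimuth=azimuth,
            cell_ids=ids,
        )
        blocks.append(VerticalBlock(block_id=b, azimuth=azimuth, stack=stack, cell_ids=ids))
    return blocks
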