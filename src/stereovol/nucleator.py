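"""Nucleator estimation of individual somal volume on vertical sections.

For a cell sampled with its nucleolus in a section, rays are drawn from the
nucleolus to the cell boundary within the section plane.  Under the vertical
design the section plane contains the fixed vertical axis and has a uniform
random azimuth; isotropy of ray directions in 3D is restored by drawing the
in-plane angle ``alpha`` to the vertical axis sine-weighted
(density ∝ sin(alpha)).  The mean somal volume is then

    v_cell = (4 pi / 3) * mean_over_rays(l^3)

averaged over sampled cells.  Rays come in antipodal pairs (the
"bidirectional ruler"), and are measured in the plane through the nucleolus
parallel to the section faces, which makes the estimator exact for spheres
with centred nucleoli.

Tissue shrinkage: processing shrinks the embedded bar; the volumetric
shrinkage fraction is ``1 - (volume after / volume before)`` and measured
somal volumes are corrected per cell by dividing by ``(1 - shrinkage)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import math

import numpy as np

from .phantom import Phantom
from .sectioning import VerticalBlock

__all__ = [
    "RaySampleSet",
    "SomalVolumeEstimate",
    "sample_rays",
    "sample_rays_study",
    "nucleator_mean_volume",
    "shrinkage",
    "tissue_volume_before_cm3",
    "correct_for_shrinkage",
    "sine_weighted_alpha",
]

FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


@dataclass(frozen=True)
class RaySampleSet:
    """Nucleator ray lengths for one sampled cell.

    ``lengths_um`` holds one entry per ray (antipodal rays are separate
    entries); ``alphas`` are the in-plane angles to the vertical axis.
    """

    cell_id: int
    lengths_um: np.ndarray
    alphas: np.ndarray
    section_index: int = -1
    block_id: int = -1

    def __post_init__(self) -> None:
        if len(self.lengths_um) < 1:
            raise ValueError("need at least one ray per sampled cell")
        if np.any(np.asarray(self.lengths_um) < 0):
            raise ValueError("ray lengths must be >= 0")

    @property
    def volume_um3(self) -> float:
        l3 = np.asarray(self.lengths_um, dtype=float) ** 3
        return FOUR_THIRDS_PI * float(l3.mean())


def sine_weighted_alpha(rng: np.random.Generator, size: int) -> np.ndarray:
    """Angles to the vertical axis in [0, pi], density sin(alpha)/2.

    Inverse-CDF sampling: alpha = arccos(1 - 2u).  Together with a uniform
    azimuth of the section plane this makes the (alpha, azimuth) direction
    uniform on the sphere.
    """
    u = rng.uniform(0.0, 1.0, size=size)
    return np.arccos(1.0 - 2.0 * u)


def _ray_length_ellipsoid(
    p: np.ndarray, u: np.ndarray, semi_axes: np.ndarray
) -> np.ndarray:
    """Distance from interior point(s) p to the ellipsoid along direction u.

    p: (k, 3) offsets from the cell centre; u: (k, 3) unit directions;
    semi_axes: (3,).  Solves |(p + l u) / a| = 1 for the positive root.
    """
    q = p / semi_axes
    w = u / semi_axes
    a = np.einsum("ij,ij->i", w, w)
    b = np.einsum("ij,ij->i", q, w)
    c = np.einsum("ij,ij->i", q, q) - 1.0
    disc = b * b - a * c
    if np.any(disc < 0):
        raise ValueError("ray origin lies outside the cell")
    return (-b + np.sqrt(disc)) / a


def sample_rays(
    phantom: Phantom,
    block: VerticalBlock,
    local_index: int,
    n_rays: int,
    rng: np.random.Generator,
    shrink_linear: float = 1.0,
    weighting: str = "sine",
) -> RaySampleSet:
    """Measure ``n_rays`` nucleator rays for one cell of a vertical block.

    ``local_index`` indexes the block's cell arrays.  Rays lie in the
    vertical plane through the cell's nucleolus (the plane spanned by the
    vertical axis z and the block's in-plane horizontal direction); the
    angle to the vertical axis is sine-weighted and each drawn direction is
    paired with its antipode, so ``n_rays`` must be even.
    ``shrink_linear`` scales measured lengths (processing shrinkage).
    ``weighting="uniform"`` replaces the sine weighting with a uniform
    in-plane angle — a deliberately biased negative control for anisotropic
    cells (it over-samples directions near the vertical axis).
    """
    if n_rays < 2 or n_rays % 2:
        raise ValueError("n_rays must be an even number >= 2")
    if weighting not in ("sine", "uniform"):
        raise ValueError("weighting must be 'sine' or 'uniform'")
    stack = block.stack
    cell_id = int(stack.cell_ids[local_index])
    center = phantom.centers[cell_id]
    semi = phantom.semi_axes[cell_id]
    nucleolus = phantom.nucleoli[cell_id]
    p_rel = nucleolus - center
    if np.any(((p_rel / semi) ** 2).sum() >= 1.0):
        raise ValueError("nucleolus lies outside the cell profile")

    az = block.azimuth
    h_dir = np.array([math.cos(az), math.sin(az), 0.0])
    z_dir = np.array([0.0, 0.0, 1.0])

    n_pairs = n_rays // 2
    if weighting == "sine":
        alphas = sine_weighted_alpha(rng, n_pairs)
    else:
        alphas = rng.uniform(0.0, math.pi, size=n_pairs)
    side = rng.choice([-1.0, 1.0], size=n_pairs)
    u = (
        np.cos(alphas)[:, None] * z_dir[None, :]
        + (np.sin(alphas) * side)[:, None] * h_dir[None, :]
    )
    dirs = np.vstack([u, -u])
    p = np.broadcast_to(p_rel, dirs.shape)
    lengths = _ray_length_ellipsoid(p, dirs, semi) * shrink_linear
    alpha_all = np.concatenate([alphas, math.pi - alphas])
    nuc_slab = int(np.floor(stack.s_nucleolus[local_index] / stack.thickness_um))
    return RaySampleSet(
        cell_id=cell_id,
        lengths_um=lengths,
        alphas=alpha_all,
        section_index=nuc_slab,
        block_id=block.block_id,
    )


def sample_rays_study(
    phantom: Phantom,
    blocks: Sequence[VerticalBlock],
    period: int,
    n_rays: int,
    rng: np.random.Generator,
    shrink_linear: float = 1.0,
    weighting: str = "sine",
) -> list[RaySampleSet]:
    """Number-weighted nucleator sampling across vertical blocks.

    Cells are sampled by the nucleolus-as-counting-unit disector: a cell is
    measured when its nucleolus falls in a systematically sampled slab
    (period ``period``, uniform random start per block).  Every cell's
    nucleolus lies in exactly one slab, so each cell has probability
    1/period of being sampled, independent of its size.
    """
    out: list[RaySampleSet] = []
    for block in blocks:
        stack = block.stack
        t = stack.thickness_um
        nuc_slab = np.floor(stack.s_nucleolus / t).astype(int)
        start = int(rng.integers(0, period))
        sampled = (nuc_slab - start) % period == 0
        for local_index in np.flatnonzero(sampled):
            out.append(
                sample_rays(
                    phantom, block, int(local_index), n_rays, rng, shrink_linear, weighting
                )
            )
    return out


@dataclass(frozen=True)
class SomalVolumeEstimate:
    """Mean somal volume with the per-cell distribution."""

    mean_volume_um3: float
    n_cells: int
    cell_volumes_um3: np.ndarray
    cell_ids: np.ndarray
    histogram_counts: np.ndarray
    histogram_edges_um3: np.ndarray

    @property
    def cv(self) -> float:
        if self.n_cells < 2:
            return float("nan")
        v = self.cell_volumes_um3
        return float(np.std(v, ddof=1) / np.mean(v))

    def to_dict(self) -> dict:
        return {
            "mean_volume_um3": self.mean_volume_um3,
            "n_cells": self.n_cells,
            "cv": self.cv,
            "cell_volumes_um3": [float(v) for v in self.cell_volumes_um3],
            "histogram_counts": [int(c) for c in self.histogram_counts],
            "histogram_edges_um3": [float(e) for e in self.histogram_edges_um3],
        }


def nucleator_mean_volume(
    samples: Sequence[RaySampleSet],
    bin_width_um3: float | None = None,
    bin_range: tuple[float, float] | None = None,
) -> SomalVolumeEstimate:
    """Aggregate per-cell nucleator volumes into a population estimate.

    Histogram bins are fixed-width; by default the width is chosen so at
    least 10 bins span the observed range.
    """
    if not samples:
        raise ValueError("no cells sampled")
    vols = np.array([s.volume_um3 for s in samples], dtype=float)
    ids = np.array([s.cell_id for s in samples], dtype=int)
    lo, hi = (bin_range if bin_range is not None else (0.0, float(vols.max()) or 1.0))
    if bin_width_um3 is None:
        bin_width_um3 = max((hi - lo) / 10.0, 1e-12)
    n_bins = max(int(math.ceil((hi - lo) / bin_width_um3)), 1)
    edges = lo + bin_width_um3 * np.arange(n_bins + 1)
    counts, _ = np.histogram(vols, bins=edges)
    return SomalVolumeEstimate(
        mean_volume_um3=float(vols.mean()),
        n_cells=len(vols),
        cell_volumes_um3=vols,
        cell_ids=ids,
        histogram_counts=counts,
        histogram_edges_um3=edges,
    )


def shrinkage(volume_before_cm3: float, volume_after_cm3: float) -> float:
    """Volumetric shrinkage fraction: 1 - after/before.

    A negative value (swelling) is physically possible and is flagged with a
    warning rather than an error.
    """
    if volume_before_cm3 <= 0 or volume_after_cm3 <= 0:
        raise ValueError("volumes must be > 0")
    s = 1.0 - volume_after_cm3 / volume_before_cm3
    if s < 0:
        warnings.warn("volume after exceeds volume before: negative shrinkage (swelling)")
    return s


TISSUE_DENSITY_CM3_PER_G = 1.04


def tissue_volume_before_cm3(weight_g: float) -> float:
    """Fresh-tissue volume from weight via the volume/weight ratio 1.04 cm³/g."""
    if weight_g <= 0:
        raise ValueError("weight must be > 0")
    return weight_g * TISSUE_DENSITY_CM3_PER_G


def correct_for_shrinkage(
    estimate: SomalVolumeEstimate, shrinkage_fraction: float
) -> SomalVolumeEstimate:
    """Divide every per-cell volume by (1 - shrinkage) and re-aggregate."""
    if not 0.0 <= shrinkage_fraction < 1.0:
        raise ValueError("shrinkage fraction must lie in [0, 1)")
    f = 1.0 / (1.0 - shrinkage_fraction)
    vols = estimate.cell_volumes_um3 * f
    edges = estimate.histogram_edges_um3 * f
    return SomalVolumeEstimate(
        mean_volume_um3=float(vols.mean()),
        n_cells=estimate.n_cells,
        cell_volumes_um3=vols,
        cell_ids=estimate.cell_ids,
        histogram_counts=estimate.histogram_counts,
        histogram_edges_um3=edges,
    )
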