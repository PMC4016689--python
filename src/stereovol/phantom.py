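"""Synthetic 3D tissue phantoms with fully known ground truth.

A phantom stands in for a neuronal cell layer (here, a hippocampal pyramidal
layer): a bounded axis-aligned box of known volume containing a known number
of convex cells (spheres or axis-aligned ellipsoids) with a log-normal-like
somal size distribution.  Each cell carries a nucleolus point strictly inside
its boundary, so every downstream estimator (Cavalieri, physical disector,
nucleator) can be validated against exact truth.

Lateral boundary conditions are periodic by default (x and y wrap): the box
then behaves like a field deep inside a much larger layer, and counting-frame
edge effects vanish exactly.  The sectioning axis (z) is never wrapped.

All internal lengths are in micrometres (µm) and volumes in µm³; reporting
code converts layer volumes to mm³ (1 mm³ = 1e9 µm³).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import json
import math

import numpy as np
import pandas as pd

UM3_PER_MM3 = 1e9

__all__ = [
    "Cell",
    "Phantom",
    "PhantomParams",
    "StudyScenario",
    "PackingError",
    "generate_phantom",
    "generate_study",
    "lognormal_radius_params",
]


class PackingError(RuntimeError):
    """Requested cell count cannot be placed under the overlap rule."""


@dataclass(frozen=True)
class Cell:
    """A single convex cell: centre, semi-axes and its nucleolus point.

    ``semi_axes`` are aligned with the coordinate axes; a sphere has all
    three equal.  The nucleolus must lie strictly inside the boundary.
    """

    cell_id: int
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    nucleolus: tuple[float, float, float]
    group_label: str | None = None

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("all semi-axes must be > 0")
        p = np.subtract(self.nucleolus, self.center) / np.asarray(self.semi_axes)
        if float(p @ p) >= 1.0:
            raise ValueError("nucleolus must lie strictly inside the cell")

    @property
    def volume_um3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass(frozen=True)
class PhantomParams:
    """Parameters for one phantom (one animal's cell layer).

    mean_somal_volume_um3 / somal_cv
        Mean and coefficient of variation of the per-cell somal volume
        distribution (log-normal in volume).  CV = 0 gives monodisperse cells.
    region_size_um
        Box edge lengths (Lx, Ly, Lz); sections are cut along z.
    shape
        "sphere" or "ellipsoid".  Ellipsoids use ``aspect`` as relative
        semi-axis ratios (normalised so the volume matches the drawn size).
    nucleolus_eccentricity
        Upper bound of the uniform radial eccentricity fraction: the
        nucleolus sits at a uniform random direction and a radial fraction
        drawn uniformly in [0, e) of the boundary distance.  0 = centred.
    min_center_spacing_um
        Minimum allowed distance between cell centres (the overlap rule);
        cells may otherwise interpenetrate, but a candidate placement whose
        nucleolus falls inside an existing cell (or vice versa) is rejected.
    """

    n_cells: int = 500
    region_size_um: tuple[float, float, float] = (240.0, 120.0, 200.0)
    mean_somal_volume_um3: float = 3588.0
    somal_cv: float = 0.25
    shape: Literal["sphere", "ellipsoid"] = "sphere"
    aspect: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nucleolus_eccentricity: float = 0.0
    min_center_spacing_um: float = 0.0
    periodic_lateral: bool = True
    max_attempts_per_cell: int = 200

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("requested cell count must be > 0")
        if min(self.region_size_um) <= 0:
            raise ValueError("region volume must be > 0")
        if self.mean_somal_volume_um3 <= 0:
            raise ValueError("mean somal volume must be > 0")
        if self.somal_cv < 0:
            raise ValueError("size-distribution CV must be >= 0")
        if not 0.0 <= self.nucleolus_eccentricity < 1.0:
            raise ValueError("nucleolus eccentricity must be in [0, 1)")
        if min(self.aspect) <= 0:
            raise ValueError("aspect ratios must be > 0")


@dataclass
class Phantom:
    """A generated cell layer with its ground truth bookkeeping.

    Cell geometry is stored as dense arrays (fast paths downstream operate on
    them directly); :meth:`cells` yields :class:`Cell` views.
    """

    region_size_um: tuple[float, float, float]
    centers: np.ndarray            # (n, 3) µm
    semi_axes: np.ndarray          # (n, 3) µm
    nucleoli: np.ndarray           # (n, 3) µm
    seed: int | None
    periodic_lateral: bool = True
    group_label: str | None = None

    # -- ground truth -----------------------------------------------------
    @property
    def true_cell_count(self) -> int:
        return int(self.centers.shape[0])

    @property
    def true_layer_volume_mm3(self) -> float:
        return float(np.prod(self.region_size_um)) / UM3_PER_MM3

    @property
    def cell_volumes_um3(self) -> np.ndarray:
        return 4.0 / 3.0 * np.pi * np.prod(self.semi_axes, axis=1)

    @property
    def true_mean_somal_volume_um3(self) -> float:
        return float(self.cell_volumes_um3.mean())

    @property
    def true_numerical_density_per_mm3(self) -> float:
        return self.true_cell_count / self.true_layer_volume_mm3

    @property
    def is_spherical(self) -> bool:
        return bool(
            np.allclose(self.semi_axes[:, 0], self.semi_axes[:, 1])
            and np.allclose(self.semi_axes[:, 0], self.semi_axes[:, 2])
        )

    def cells(self) -> Iterator[Cell]:
        for i in range(self.true_cell_count):
            yield Cell(
                cell_id=i,
                center=tuple(self.centers[i]),
                semi_axes=tuple(self.semi_axes[i]),
                nucleolus=tuple(self.nucleoli[i]),
                group_label=self.group_label,
            )

    # -- serialization ----------------------------------------------------
    def cell_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": np.arange(self.true_cell_count),
                "cx": self.centers[:, 0],
                "cy": self.centers[:, 1],
                "cz": self.centers[:, 2],
                "sa": self.semi_axes[:, 0],
                "sb": self.semi_axes[:, 1],
                "sc": self.semi_axes[:, 2],
                "nx": self.nucleoli[:, 0],
                "ny": self.nucleoli[:, 1],
                "nz": self.nucleoli[:, 2],
            }
        )
        return df

    def to_json(self) -> str:
        return json.dumps(
            {
                "region_size_um": list(self.region_size_um),
                "seed": self.seed,
                "periodic_lateral": self.periodic_lateral,
                "group_label": self.group_label,
                "true_layer_volume_mm3": self.true_layer_volume_mm3,
                "true_cell_count": self.true_cell_count,
                "true_mean_somal_volume_um3": self.true_mean_somal_volume_um3,
                "cells": self.cell_table().to_dict(orient="list"),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Phantom":
        d = json.loads(text)
        t = d["cells"]
        centers = np.column_stack([t["cx"], t["cy"], t["cz"]]).astype(float)
        semi = np.column_stack([t["sa"], t["sb"], t["sc"]]).astype(float)
        nuc = np.column_stack([t["nx"], t["ny"], t["nz"]]).astype(float)
        return cls(
            region_size_um=tuple(d["region_size_um"]),
            centers=centers,
            semi_axes=semi,
            nucleoli=nuc,
            seed=d.get("seed"),
            periodic_lateral=bool(d.get("periodic_lateral", True)),
            group_label=d.get("group_label"),
        )


def lognormal_radius_params(mean_volume_um3: float, volume_cv: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal *equivalent-radius* distribution.

    Volumes v = (4/3) pi r^3 are log-normal with the requested mean and CV;
    radii are then log-normal with sigma_r = sigma_v / 3.
    """
    sigma_v2 = math.log1p(volume_cv**2)
    mu_v = math.log(mean_volume_um3) - sigma_v2 / 2.0
    mu_r = (mu_v - math.log(4.0 * math.pi / 3.0)) / 3.0
    sigma_r = math.sqrt(sigma_v2) / 3.0
    return mu_r, sigma_r


def _min_image_sq_dist(delta: np.ndarray, region: np.ndarray, periodic: bool) -> np.ndarray:
    """Squared distances under the lateral minimum-image convention."""
    if periodic:
        delta = delta.copy()
        for k in (0, 1):
            L = region[k]
            delta[:, k] -= L * np.round(delta[:, k] / L)
    return np.einsum("ij,ij->i", delta, delta)


def generate_phantom(
    params: PhantomParams, seed: int | np.random.SeedSequence | None = None
) -> Phantom:
    """Place ``params.n_cells`` cells uniformly in the box.

    Placement is sequential random insertion: a candidate is rejected if it
    violates the minimum centre-spacing rule, if its boundary would contain
    an existing nucleolus, or if its nucleolus would fall inside an existing
    cell.  Raises :class:`PackingError` after
    ``max_attempts_per_cell * n_cells`` total rejected candidates.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_cells
    region = np.asarray(params.region_size_um, dtype=float)

    # sizes: log-normal volumes -> equivalent radii
    if params.somal_cv == 0:
        radii = np.full(n, (3.0 * params.mean_somal_volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0))
    else:
        mu_r, sigma_r = lognormal_radius_params(
            params.mean_somal_volume_um3, params.somal_cv
        )
        radii = rng.lognormal(mu_r, sigma_r, size=n)

    aspect = np.asarray(params.aspect, dtype=float)
    aspect = aspect / np.prod(aspect) ** (1.0 / 3.0)  # volume-preserving
    semi_axes = radii[:, None] * aspect[None, :]

    # cells lie fully inside the layer along z (a somal layer contains its
    # somata), so every cell's slab span stays within the exhaustive series
    z_margin = semi_axes[:, 2]
    if np.any(2.0 * z_margin >= region[2]):
        raise PackingError("region too thin along z for the drawn cell sizes")

    # nucleolus offsets relative to the centre: centred, or a uniform
    # eccentricity fraction along a uniform random direction
    if params.nucleolus_eccentricity == 0:
        offsets = np.zeros((n, 3))
    else:
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        frac = rng.uniform(0.0, params.nucleolus_eccentricity, size=n)
        # centre-to-boundary distance along u: 1 / sqrt(sum((u_k / a_k)^2))
        denom = np.sqrt(((u / semi_axes) ** 2).sum(axis=1))
        offsets = (frac / denom)[:, None] * u

    # sequential random insertion under the overlap rule: cells may touch or
    # interpenetrate, but no cell may contain another's nucleolus, and an
    # optional minimum centre spacing applies
    centers = np.empty((n, 3))
    nucleoli = np.empty((n, 3))
    max_total = params.max_attempts_per_cell * n
    failures = 0
    placed = 0
    spacing2 = params.min_center_spacing_um**2
    while placed < n:
        cand = rng.uniform(0.0, 1.0, size=3) * region
        m = z_margin[placed]
        cand[2] = m + cand[2] / region[2] * (region[2] - 2.0 * m)
        nuc_cand = cand + offsets[placed]
        ok = True
        if placed:
            delta = centers[:placed] - cand[None, :]
            if spacing2 > 0:
                d2 = _min_image_sq_dist(delta.copy(), region, params.periodic_lateral)
                if np.any(d2 < spacing2):
                    ok = False
            if ok:
                # would an existing cell contain the candidate's nucleolus?
                dn = centers[:placed] - nuc_cand[None, :]
                if params.periodic_lateral:
                    for k in (0, 1):
                        L = region[k]
                        dn[:, k] -= L * np.round(dn[:, k] / L)
                if np.any(((dn / semi_axes[:placed]) ** 2).sum(axis=1) < 1.0):
                    ok = False
            if ok:
                # would the candidate contain an existing nucleolus?
                dm = nucleoli[:placed] - cand[None, :]
                if params.periodic_lateral:
                    for k in (0, 1):
                        L = region[k]
                        dm[:, k] -= L * np.round(dm[:, k] / L)
                if np.any(((dm / semi_axes[placed]) ** 2).sum(axis=1) < 1.0):
                    ok = False
        if ok:
            centers[placed] = cand
            nucleoli[placed] = nuc_cand
            placed += 1
        else:
            failures += 1
            if failures > max_total:
                raise PackingError(
                    f"could not place cell {placed + 1}/{n} after {failures} rejections"
                )

    seed_repr = seed if isinstance(seed, int) else None
    return Phantom(
        region_size_um=tuple(region),
        centers=centers,
        semi_axes=semi_axes,
        nucleoli=nucleoli,
        seed=seed_repr,
        periodic_lateral=params.periodic_lateral,
    )


@dataclass(frozen=True)
class StudyScenario:
    """Two-group study design: per-animal phantoms drawn around group means.

    ``between_animal_cv`` scales the animal-to-animal variability of the mean
    somal volume and layer volume (log-normal multipliers, independent per
    animal); cell count covaries with layer volume so numerical density stays
    near the group value, mirroring a treatment that shrinks cells and layer
    without neuron loss.
    """

    n_per_group: int = 8
    control_params: PhantomParams = field(default_factory=PhantomParams)
    treated_params: PhantomParams = field(
        default_factory=lambda: PhantomParams(
            mean_somal_volume_um3=3037.0,
            region_size_um=(240.0, 120.0, 183.6),
        )
    )
    between_animal_cv: float = 0.08
    control_label: str = "control"
    treated_label: str = "treated"

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 animals per group")
        if self.between_animal_cv < 0:
            raise ValueError("between-animal CV must be >= 0")
        self.control_params.validate()
        self.treated_params.validate()


@dataclass(frozen=True)
class StudyAnimal:
    animal_id: str
    group_label: str
    phantom: Phantom


def _scaled_params(
    base: PhantomParams, rng: np.random.Generator, cv: float
) -> PhantomParams:
    if cv == 0:
        return base
    sigma = math.sqrt(math.log1p(cv**2))
    f_soma = float(rng.lognormal(-sigma**2 / 2.0, sigma))
    f_layer = float(rng.lognormal(-sigma**2 / 2.0, sigma))
    lx, ly, lz = base.region_size_um
    # scale layer volume along z only; cell count follows volume
    n = max(2, int(round(base.n_cells * f_layer)))
    return replace(
        base,
        mean_somal_volume_um3=base.mean_somal_volume_um3 * f_soma,
        region_size_um=(lx, ly, lz * f_layer),
        n_cells=n,
    )


def generate_study(
    scenario: StudyScenario, seed: int | np.random.SeedSequence | None = None
) -> list[StudyAnimal]:
    """Emit ``2 * n_per_group`` phantoms, balanced across groups.

    Deterministic given ``seed``: child seeds are spawned hierarchically, one
    per animal, so inserting animals in one group cannot perturb the other.
    """
    scenario.validate()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(2 * scenario.n_per_group)
    animals: list[StudyAnimal] = []
    groups = (
        (scenario.control_label, scenario.control_params),
        (scenario.treated_label, scenario.treated_params),
    )
    k = 0
    for label, base in groups:
        for i in range(scenario.n_per_group):
            child = children[k]
            k += 1
            param_rng = np.random.default_rng(child)
            params = _scaled_params(base, param_rng, scenario.between_animal_cv)
            phantom = generate_phantom(params, np.random.SeedSequence(entropy=child.entropy, spawn_key=child.spawn_key + (1,)))
            phantom.group_label = label
            animals.append(
                StudyAnimal(animal_id=f"{label}_{i + 1}", group_label=label, phantom=phantom)
            )
    return animals
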