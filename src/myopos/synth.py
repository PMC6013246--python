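"""Synthetic cell populations with the statistical structure of VL muscles.

Emulates the measured morphometrics of the two ventral longitudinal muscles
of the third-instar Drosophila larva: cell lengths ~ 499.2 +- 57.7 um (VL3)
and 491.8 +- 57.1 um (VL4), widths 80.4 +- 17.5 um (VL3, wide) and
51.7 +- 11.3 um (VL4, narrow), nucleus counts 15.3 +- 2.9 and 9.3 +- 1.6,
nuclear radius 7 um.  Lengths and widths are truncated normals (at 3 SD and
at positivity); counts are rounded and floored at 2.  Nuclear positions are
either uniform random (the null model) or model equilibria plus Gaussian
jitter, standing in for measured centroids so the whole pipeline (screen,
calibration, metrics, shape fitting) is testable without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
from scipy import stats

from .dynamics import CellGeometry, initial_conditions, relax_to_equilibrium
from .forces import ModelSpec
from .metrics import NuclearEllipse
from .strip import StripParams, aspect_ratio_predicted, df_equilibrium, sf_is_stable, shape_forces

PlacementMode = Literal["uniform_random", "model_equilibrium"]


@dataclass(frozen=True)
class PopulationParams:
    """Mean/SD morphometrics of one cell type plus placement jitter."""

    length_mean: float
    length_sd: float
    width_mean: float
    width_sd: float
    count_mean: float
    count_sd: float
    jitter_sd: float = 2.0
    nuclear_radius: float = 7.0
    count_width_coupling: float = 0.0  # optional nuclei-per-um-width slope

    def __post_init__(self) -> None:
        for name in ("length_sd", "width_sd", "count_sd", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Wide cell type (VL3-like).
VL3 = PopulationParams(499.2, 57.7, 80.4, 17.5, 15.3, 2.9)

#: Narrow cell type (VL4-like).
VL4 = PopulationParams(491.8, 57.1, 51.7, 11.3, 9.3, 1.6)


def _trunc_normal(rng, mean, sd, n):
    """Normal truncated at +-3 SD and at positivity."""
    if sd == 0:
        return np.full(n, mean)
    lo = max(mean - 3 * sd, 1e-9)
    hi = mean + 3 * sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_population(p: PopulationParams, n_cells: int, seed=0) -> list[CellGeometry]:
    """Draw ``n_cells`` cell geometries; deterministic for a given seed."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = _trunc_normal(rng, p.length_mean, p.length_sd, n_cells)
    widths = _trunc_normal(rng, p.width_mean, p.width_sd, n_cells)
    counts = p.count_mean + p.count_width_coupling * (widths - p.width_mean)
    if p.count_sd > 0:
        counts = counts + rng.normal(0.0, p.count_sd, n_cells)
    counts = np.maximum(np.rint(counts).astype(int), 2)
    return [
        CellGeometry(w / 2.0, L / 2.0, int(n), p.nuclear_radius)
        for w, L, n in zip(widths, lengths, counts)
    ]


def place_nuclei(
    geom: CellGeometry,
    mode: PlacementMode,
    model: Optional[ModelSpec] = None,
    jitter_sd: float = 0.0,
    seed=0,
    max_retries: int = 5,
) -> np.ndarray:
    """Nuclear centroids for one cell.

    uniform_random
        i.i.d. uniform positions with an interior margin of one radius.
    model_equilibrium
        Relax the model from a random start, then add i.i.d. Gaussian
        jitter of SD ``jitter_sd`` (clipped to the rectangle).  Rare
        non-convergent starts are resampled up to ``max_retries`` times.
    """
    rng = np.random.default_rng(seed)
    if mode == "uniform_random":
        return initial_conditions(geom, "random", seed=rng)
    if mode != "model_equilibrium":
        raise ValueError(f"unknown mode {mode!r}")
    if model is None:
        raise ValueError("model_equilibrium placement requires a model")
    for _ in range(max_retries):
        cfg0 = initial_conditions(geom, "random", seed=rng)
        res = relax_to_equilibrium(cfg0, model, geom)
        if res.converged:
            pos = res.final
            if jitter_sd > 0:
                pos = pos + rng.normal(0.0, jitter_sd, pos.shape)
                eps = 1e-9
                pos[:, 0] = np.clip(pos[:, 0], -geom.half_width + eps, geom.half_width - eps)
                pos[:, 1] = np.clip(pos[:, 1], -geom.half_length + eps, geom.half_length - eps)
            return pos
    raise RuntimeError(f"no converged equilibrium in {max_retries} attempts for {geom}")


def attach_shapes(
    positions: np.ndarray,
    geom: CellGeometry,
    model: ModelSpec,
    kappa: float,
    noise_sd: float = 0.0,
    seed=0,
    variant: str = "long",
) -> list[NuclearEllipse]:
    """Emit nuclear ellipses whose aspect ratios follow the shape model.

    The cell-level aspect ratio comes from the strip-model stress
    anisotropy at stiffness ``kappa``; multiplicative lognormal noise of
    sigma ``noise_sd`` is applied per nucleus.  Areas are fixed at
    pi * (7 um)^2 and orientations chosen so the oriented aspect ratio of
    the emitted ellipse reproduces the modelled value exactly at zero noise.
    """
    rng = np.random.default_rng(seed)
    p = StripParams.from_geometry(geom, model)
    pattern = "SF" if sf_is_stable(p).stable else "DF"
    fx, fy = shape_forces(p, pattern, variant)
    ar_cell = aspect_ratio_predicted(fx, fy, kappa)
    ellipses = []
    for cx, cy in np.asarray(positions, dtype=float):
        ar = ar_cell * (math.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0)
        if ar >= 1.0:
            major, minor, phi = 14.0 * math.sqrt(ar), 14.0 / math.sqrt(ar), math.pi / 2
        else:
            major, minor, phi = 14.0 / math.sqrt(ar), 14.0 * math.sqrt(ar), 0.0
        ellipses.append(NuclearEllipse((cx, cy), major, minor, phi))
    return ellipses


def synthesize_cells(
    params: PopulationParams,
    n_cells: int,
    model: Optional[ModelSpec] = None,
    mode: PlacementMode = "model_equilibrium",
    seed=0,
) -> list[tuple[CellGeometry, np.ndarray]]:
    """Convenience: sample geometries and place nuclei in one call."""
    ss = np.random.SeedSequence(seed)
    geo_seed, *cell_seeds = ss.spawn(n_cells + 1)
    geoms = sample_population(params, n_cells, seed=geo_seed)
    return [
        (g, place_nuclei(g, mode, model=model, jitter_sd=params.jitter_sd if mode == "model_equilibrium" else 0.0, seed=s))
        for g, s in zip(geoms, cell_seeds)
    ]
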