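"""Distance-dependent force laws acting on myonuclei.

Every interaction in the positioning model — nucleus-nucleus, nucleus-side
and nucleus-pole — is a scalar power law of the separation ``d``::

    F(d) = sigma * M * (d / d_ref)**alpha * H(c - d)

where ``sigma = +1`` (repulsive, directed away from the source) or ``-1``
(attractive), ``M >= 0`` is the amplitude relative to the internuclear force
(whose amplitude defines the force unit and is fixed to 1), ``alpha`` sets
whether the force falls (<0), is constant (0) or grows (>0) with distance,
``c`` is a finite reach (cut-off) and ``d_ref = 40 um`` is the typical
internuclear spacing used to non-dimensionalise distances.  ``H`` is the
Heaviside function, taken to be 0 at the cut-off itself so the force
vanishes at and beyond ``c``.

A *model* fixes the sign and exponent of all three laws (2**3 * 3**3 = 216
combinations); a *model class* fixes only the internuclear and side laws
(36 combinations).  On top of the smooth laws, a divergent short-range size
exclusion keeps nuclei (radius ``r = 7 um``) from overlapping each other or
the cell boundary.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

#: Reference internuclear distance (um) scaling all force laws.
D_REF = 40.0

#: Default strength of the short-range size-exclusion force.
Q_SE = 2000.0

#: Nuclear radius (um).
NUCLEAR_RADIUS = 7.0

#: Exponents and signs admitted by the screening grids.
SCREEN_EXPONENTS = (-1, 0, 1)
SCREEN_SIGNS = (-1, 1)


@dataclass(frozen=True)
class ForceLaw:
    """One scalar, isotropic, distance-dependent force.

    Parameters
    ----------
    sign
        +1 for repulsion (force directed away from the source), -1 for
        attraction.
    exponent
        Power-law exponent ``alpha``.  The screens use {-1, 0, 1}; other
        values are accepted by the library.
    magnitude
        Non-negative amplitude ``M`` in internuclear-force units.
    cutoff
        Finite reach ``c`` in um, ``math.inf`` for unlimited reach.
    ref_distance
        Scaling distance ``d_ref`` in um.
    """

    sign: int
    exponent: float
    magnitude: float = 1.0
    cutoff: float = math.inf
    ref_distance: float = D_REF

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError(f"sign must be -1 or +1, got {self.sign}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if not self.ref_distance > 0:
            raise ValueError("ref_distance must be positive")

    def __call__(self, d):
        return evaluate_force(d, self)

    def derivative(self, d: float) -> float:
        """d/dd of the smooth branch (cut-off discontinuity not included)."""
        if d <= 0:
            raise ValueError("distance must be positive")
        if d >= self.cutoff:
            return 0.0
        return (
            self.sign
            * self.magnitude
            * self.exponent
            * (d / self.ref_distance) ** (self.exponent - 1)
            / self.ref_distance
        )

    def without_cutoff(self) -> "ForceLaw":
        return replace(self, cutoff=math.inf)


def evaluate_force(d, law: ForceLaw):
    """Evaluate a force law at separation(s) ``d`` (um).

    Positive values are repulsive (directed away from the source).  The force
    is exactly zero at and beyond the cut-off.  ``d`` may be a scalar or an
    array; all entries must be strictly positive (coincident points are the
    caller's job, via size exclusion).
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise ValueError("distance must be strictly positive")
    out = law.sign * law.magnitude * (d_arr / law.ref_distance) ** law.exponent
    out = np.where(d_arr < law.cutoff, out, 0.0)
    if np.isscalar(d) or d_arr.ndim == 0:
        return float(out)
    return out


def evaluate_size_exclusion(d, effective_diameter: float, Q: float = Q_SE):
    """Divergent short-range repulsion preventing overlap.

    ``F = Q * (1/d^2 - 1/D^2)`` for ``d < D`` and 0 otherwise, where the
    effective diameter ``D`` is ``2r`` for nucleus-nucleus contacts and ``r``
    for nucleus-boundary contacts.  Always repulsive; diverges as d -> 0+.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise ValueError("distance must be strictly positive")
    out = Q * (1.0 / d_arr**2 - 1.0 / effective_diameter**2)
    out = np.where(d_arr < effective_diameter, out, 0.0)
    if np.isscalar(d) or d_arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ModelSpec:
    """A full positioning model: three force laws plus size exclusion.

    The internuclear amplitude is the force unit and must equal 1.  The
    ``class_key`` — (sigma_N, alpha_N, sigma_S, alpha_S) — identifies the
    model class, which is insensitive to the pole law and to cut-offs.
    """

    internuclear: ForceLaw
    side: ForceLaw
    pole: ForceLaw
    exclusion_strength: float = Q_SE
    nuclear_radius: float = NUCLEAR_RADIUS

    def __post_init__(self) -> None:
        if self.internuclear.magnitude != 1.0:
            raise ValueError("internuclear amplitude defines the force unit and must be 1")
        if self.exclusion_strength < 0:
            raise ValueError("exclusion_strength must be non-negative")
        if not self.nuclear_radius > 0:
            raise ValueError("nuclear_radius must be positive")

    def class_key(self) -> tuple:
        n, s = self.internuclear, self.side
        return (n.sign, n.exponent, s.sign, s.exponent)

    # -- flat serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        n, s, p = self.internuclear, self.side, self.pole
        return {
            "sign_N": n.sign, "alpha_N": n.exponent, "c_N": n.cutoff,
            "sign_S": s.sign, "alpha_S": s.exponent, "M_S": s.magnitude, "c_S": s.cutoff,
            "sign_P": p.sign, "alpha_P": p.exponent, "M_P": p.magnitude, "c_P": p.cutoff,
            "d_ref": n.ref_distance, "Q_SE": self.exclusion_strength,
            "r": self.nuclear_radius,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d_ref = float(d.pop("d_ref", D_REF))
        Q = float(d.pop("Q_SE", Q_SE))
        r = float(d.pop("r", NUCLEAR_RADIUS))
        laws = {}
        for key, tag in (("internuclear", "N"), ("side", "S"), ("pole", "P")):
            laws[key] = ForceLaw(
                sign=int(d.pop(f"sign_{tag}")),
                exponent=float(d.pop(f"alpha_{tag}")),
                magnitude=float(d.pop(f"M_{tag}", 1.0)),
                cutoff=float(d.pop(f"c_{tag}", math.inf)),
                ref_distance=d_ref,
            )
        if d:
            raise ValueError(f"unknown model keys: {sorted(d)}")
        return cls(exclusion_strength=Q, nuclear_radius=r, **laws)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        return cls.from_dict(json.loads(text))


def make_model(
    sign_N: int, alpha_N: float, sign_S: int, alpha_S: float,
    sign_P: int = 1, alpha_P: float = -1.0,
    M_S: float = 1.0, M_P: float = 1.0,
    c_N: float = math.inf, c_S: float = math.inf, c_P: float = math.inf,
    Q: float = Q_SE, r: float = NUCLEAR_RADIUS, d_ref: float = D_REF,
) -> ModelSpec:
    """Convenience constructor from flat screen parameters."""
    return ModelSpec(
        internuclear=ForceLaw(sign_N, alpha_N, 1.0, c_N, d_ref),
        side=ForceLaw(sign_S, alpha_S, M_S, c_S, d_ref),
        pole=ForceLaw(sign_P, alpha_P, M_P, c_P, d_ref),
        exclusion_strength=Q,
        nuclear_radius=r,
    )


def enumerate_models() -> list[ModelSpec]:
    """All 216 sign/exponent combinations of the three force laws.

    Amplitudes are 1 and cut-offs infinite; the screen varies those on grids.
    """
    models = []
    for (sN, sS, sP), (aN, aS, aP) in itertools.product(
        itertools.product(SCREEN_SIGNS, repeat=3),
        itertools.product(SCREEN_EXPONENTS, repeat=3),
    ):
        models.append(make_model(sN, aN, sS, aS, sP, aP))
    return models


def enumerate_classes() -> list[tuple]:
    """All 36 model-class keys (sigma_N, alpha_N, sigma_S, alpha_S)."""
    return [
        (sN, aN, sS, aS)
        for sN in SCREEN_SIGNS
        for aN in SCREEN_EXPONENTS
        for sS in SCREEN_SIGNS
        for aS in SCREEN_EXPONENTS
    ]


# Internal: pack a model into the flat float vector used by the numba kernels.
def _pack(model: ModelSpec) -> np.ndarray:
    n, s, p = model.internuclear, model.side, model.pole
    return np.array(
        [
            n.sign, n.exponent, n.cutoff,
            s.sign, s.exponent, s.magnitude, s.cutoff,
            p.sign, p.exponent, p.magnitude, p.cutoff,
            n.ref_distance, model.exclusion_strength, model.nuclear_radius,
        ],
        dtype=np.float64,
    )
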