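"""Closed-form diffusion models of tracer penetration into brain tissue.

Two source geometries cover the experimental situations:

* a constant-concentration reservoir at the brain surface feeding a
  semi-infinite parenchyma, for which the relative concentration is
  ``C/C0 = erfc(x / (2 sqrt(D t)))`` — used to predict how far a
  cisternally applied tracer penetrates from the cortical surface;
* an instantaneous point source in free space, for which
  ``C(r, t) = dose (4 pi D t)^(-3/2) exp(-r^2 / (4 D t))`` — used for
  intraparenchymal bolus injections.

Both predict that penetration distance at fixed time scales as
``sqrt(D)``, the signature that distinguishes diffusive from convective
transport across tracers of different hydrodynamic radius.

Hindrance by the extracellular matrix enters through the tortuosity
``lambda`` (``D_eff = D_free / lambda^2``); the extracellular volume
fraction ``alpha`` rescales tissue-averaged (absolute) uptake but
leaves surface-normalized profiles untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import erfc, erfcinv

from .errors import InvalidParameterError

__all__ = [
    "TransportParams",
    "Tracer",
    "SpatialProfile",
    "halfspace_profile",
    "decay_distance",
    "point_source_profile",
    "effective_diffusion",
    "relative_penetration",
    "alpha_adjusted_uptake",
]


@dataclass(frozen=True)
class TransportParams:
    """Physical transport parameters of one tracer in brain ECS.

    Parameters
    ----------
    D : float
        Diffusion coefficient in the tissue, um^2/s.
    v : tuple of float
        Convective velocity vector, um/min (zero for pure diffusion).
    tortuosity : float
        Hindrance factor lambda >= 1; relates free and effective
        diffusion via ``D_eff = D_free / lambda**2``.
    alpha : float
        Extracellular-space volume fraction, in (0, 1).
    clearance : float
        First-order clearance rate k, 1/s; applied as a multiplicative
        ``exp(-k t)`` on absolute concentration.
    """

    D: float
    v: tuple[float, ...] = (0.0, 0.0)
    tortuosity: float = 1.0
    alpha: float = 0.2
    clearance: float = 0.0

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise InvalidParameterError(f"D must be > 0, got {self.D}")
        if self.tortuosity < 1:
            raise InvalidParameterError(
                f"tortuosity must be >= 1, got {self.tortuosity}"
            )
        if not 0 < self.alpha < 1:
            raise InvalidParameterError(
                f"alpha must be in (0, 1), got {self.alpha}"
            )
        if self.clearance < 0:
            raise InvalidParameterError(
                f"clearance must be >= 0, got {self.clearance}"
            )

    @property
    def v_um_per_s(self) -> tuple[float, ...]:
        return tuple(vi / 60.0 for vi in self.v)


@dataclass(frozen=True)
class Tracer:
    """A fluorescent tracer and its diffusion coefficients.

    ``D_free`` is the aqueous-solution value, ``D_ecs`` the value in
    brain extracellular space; both in um^2/s. ``hydrodynamic_radius``
    in nm, ``molecular_mass`` in kDa.
    """

    name: str
    molecular_mass: float
    hydrodynamic_radius: float
    D_free: float | None = None
    D_ecs: float | None = None

    def __post_init__(self) -> None:
        if not self.hydrodynamic_radius > 0:
            raise InvalidParameterError("hydrodynamic_radius must be > 0")
        if (
            self.D_free is not None
            and self.D_ecs is not None
            and self.D_ecs > self.D_free * (1 + 1e-12)
        ):
            raise InvalidParameterError("D_ecs cannot exceed D_free")


@dataclass
class SpatialProfile:
    """Relative intensity/concentration versus distance.

    ``distances`` (um) start at 0 and increase strictly; ``intensities``
    are normalized so that the value at distance 0 is 1. ``amplitude``
    carries the absolute (tissue-averaged) scale that normalization
    divides out, so alpha- or clearance-rescaling survives round trips.
    """

    distances: np.ndarray
    intensities: np.ndarray
    kind: Literal["depth", "radial", "line"] = "depth"
    amplitude: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.distances.ndim != 1 or self.distances.shape != self.intensities.shape:
            raise InvalidParameterError("distances/intensities must be 1-D and equal length")
        if self.distances[0] != 0:
            raise InvalidParameterError("profile must start at distance 0")
        if np.any(np.diff(self.distances) <= 0):
            raise InvalidParameterError("distances must be strictly increasing")

    def normalized(self) -> "SpatialProfile":
        """Return a copy normalized to the value at distance 0."""
        v0 = self.intensities[0]
        if v0 == 0:
            raise InvalidParameterError("cannot normalize: zero intensity at distance 0")
        return replace(
            self,
            intensities=self.intensities / v0,
            amplitude=self.amplitude * v0,
        )

    def decay_distance(self, fraction: float) -> float | None:
        """Distance at which the normalized profile first falls to
        ``fraction`` of its value at 0, by linear interpolation.
        Returns None if the profile never reaches the fraction."""
        if not 0 < fraction < 1:
            raise InvalidParameterError(f"fraction must be in (0, 1), got {fraction}")
        rel = self.intensities / self.intensities[0]
        below = np.nonzero(rel <= fraction)[0]
        if below.size == 0:
            return None
        j = below[0]
        if j == 0:
            return 0.0
        x0, x1 = self.distances[j - 1], self.distances[j]
        y0, y1 = rel[j - 1], rel[j]
        if y0 == y1:
            return float(x1)
        return float(x0 + (y0 - fraction) * (x1 - x0) / (y0 - y1))


def _check_time(t: float) -> None:
    if not t > 0:
        raise InvalidParameterError(f"time must be > 0, got {t}")


def halfspace_profile(
    params: TransportParams,
    t: float,
    depths: Sequence[float],
    source: Literal["constant", "bolus"] = "constant",
) -> SpatialProfile:
    """Relative concentration below a surface tracer source at time t.

    With ``source="constant"`` (default) the surface is held at fixed
    concentration — a tracer-filled subpial reservoir — and
    ``C/C0 = erfc(x / (2 sqrt(D t)))``.  With ``source="bolus"`` an
    instantaneous plane source gives ``C/C0 = exp(-x^2 / (4 D t))``.
    Clearance multiplies the absolute amplitude by ``exp(-k t)`` and
    leaves the surface-normalized shape unchanged.
    """
    _check_time(t)
    depths = np.asarray(depths, dtype=float)
    if np.any(depths < 0):
        raise InvalidParameterError("depths must be >= 0")
    scale = 2.0 * np.sqrt(params.D * t)
    if source == "constant":
        rel = erfc(depths / scale)
    elif source == "bolus":
        rel = np.exp(-(depths**2) / scale**2)
    else:
        raise InvalidParameterError(f"unknown source model {source!r}")
    amplitude = float(np.exp(-params.clearance * t))
    return SpatialProfile(
        distances=depths,
        intensities=rel,
        kind="depth",
        amplitude=amplitude,
        metadata={"D": params.D, "t": t, "source": source},
    )


def decay_distance(
    params: TransportParams,
    t: float,
    fraction: float,
    source: Literal["constant", "bolus"] = "constant",
    tol: float = 1e-3,
) -> float:
    """Depth at which the surface-normalized halfspace profile equals
    ``fraction``, found by bracketing + bisection to ``tol`` um.

    Scales exactly as sqrt(D t); for the constant source the closed
    form is ``2 sqrt(D t) erfcinv(fraction)``.
    """
    _check_time(t)
    if not 0 < fraction < 1:
        raise InvalidParameterError(f"fraction must be in (0, 1), got {fraction}")
    scale = 2.0 * np.sqrt(params.D * t)
    if source == "constant":
        f = lambda x: erfc(x / scale) - fraction  # noqa: E731
        guess = scale * float(erfcinv(fraction))
    elif source == "bolus":
        f = lambda x: np.exp(-(x / scale) ** 2) - fraction  # noqa: E731
        guess = scale * float(np.sqrt(-np.log(fraction)))
    else:
        raise InvalidParameterError(f"unknown source model {source!r}")
    lo, hi = 0.5 * guess, 2.0 * guess + scale
    while f(hi) > 0:
        hi *= 2.0
    return float(brentq(f, lo, hi, xtol=tol))


def point_source_profile(
    params: TransportParams,
    t: float,
    radii: Sequence[float],
    dose: float = 1.0,
) -> SpatialProfile:
    """Radial concentration profile of an instantaneous point source.

    The free-space solution ``C(r,t) = dose (4 pi D t)^{-3/2}
    exp(-r^2/(4 D t))`` is normalized to its value at r = 0; the
    absolute peak concentration is kept in ``amplitude``.  The
    10%-decay radius is ``sqrt(4 D t ln 10)``.
    """
    _check_time(t)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii < 0):
        raise InvalidParameterError("radii must be >= 0")
    four_dt = 4.0 * params.D * t
    rel = np.exp(-(radii**2) / four_dt)
    peak = dose * (np.pi * four_dt) ** -1.5 * np.exp(-params.clearance * t)
    return SpatialProfile(
        distances=radii,
        intensities=rel,
        kind="radial",
        amplitude=float(peak),
        metadata={"D": params.D, "t": t, "dose": dose},
    )


def effective_diffusion(D_free: float, tortuosity: float) -> float:
    """Effective diffusion coefficient in a tortuous medium,
    ``D_eff = D_free / lambda**2``."""
    if not D_free > 0:
        raise InvalidParameterError(f"D_free must be > 0, got {D_free}")
    if tortuosity < 1:
        raise InvalidParameterError(f"tortuosity must be >= 1, got {tortuosity}")
    return D_free / tortuosity**2


def relative_penetration(tracers: Sequence[Tracer], t: float = 3600.0) -> np.ndarray:
    """Predicted penetration distances relative to the fastest tracer.

    For purely diffusive transport the decay distance at fixed time and
    fraction is proportional to sqrt(D), so the relative distances are
    ``sqrt(D_i / D_max)`` independent of t and of the decay fraction.
    ``t`` is accepted for interface symmetry; the ratio cancels it.
    """
    if len(tracers) == 0:
        raise InvalidParameterError("need at least one tracer")
    ds = []
    for tr in tracers:
        if tr.D_ecs is None:
            raise InvalidParameterError(f"tracer {tr.name!r} has no D_ecs")
        ds.append(
            decay_distance(TransportParams(D=tr.D_ecs), t=t, fraction=0.5)
        )
    ds = np.asarray(ds)
    return ds / ds.max()


def alpha_adjusted_uptake(profile: SpatialProfile, alpha: float) -> SpatialProfile:
    """Rescale a profile's absolute (tissue-averaged) uptake by the ECS
    volume fraction alpha.

    Tissue-averaged concentration is ``alpha * C_ecs``, so a larger ECS
    holds proportionally more tracer, but the surface-normalized shape
    is unchanged — genotype differences in shape can only enter through
    D_eff.
    """
    if not 0 < alpha <= 1:
        raise InvalidParameterError(f"alpha must be in (0, 1], got {alpha}")
    return replace(profile, amplitude=profile.amplitude * alpha)
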