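"""Reusable rate-law primitives.

These are the small set of nonlinear kinetic forms the cell-cycle model is
assembled from: the Goldbeter–Koshland zero-order ultrasensitive switch, the
Hill activation function, volume-consistent nucleocytoplasmic transport, and
exponential mass growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GKArgs",
    "goldbeter_koshland",
    "hill_activation",
    "transport_flux",
    "mass_growth",
]

#: floor applied to the GK discriminant so round-off under Va ~ Vi can never
#: produce a negative argument to sqrt
_GK_DISC_FLOOR = 1e-12


@dataclass(frozen=True)
class GKArgs:
    """Arguments of the Goldbeter–Koshland switch.

    Va, Vi are the activation/inactivation rates (per min) of a push–pull
    modification cycle; Ja, Ji the corresponding dimensionless Michaelis
    constants.  Small J values put the cycle in the zero-order (ultrasensitive)
    regime.
    """

    Va: float
    Vi: float
    Ja: float
    Ji: float

    def __post_init__(self) -> None:
        if self.Va < 0 or self.Vi < 0:
            raise ValueError("GK rates must be non-negative")
        if self.Ja <= 0 or self.Ji <= 0:
            raise ValueError("GK Michaelis constants must be positive")


def goldbeter_koshland(Va: float, Vi: float, Ja: float, Ji: float) -> float:
    """Steady-state active fraction of a covalent-modification cycle.

    Solves ``Va (1-G)/(Ja + 1 - G) = Vi G/(Ji + G)`` for G in [0, 1] using the
    numerically stable surd form

        G = 2 Va Ji / (B + sqrt(B^2 - 4 (Vi - Va) Va Ji)),
        B = Vi - Va + Va Ji + Vi Ja,

    which avoids cancellation when ``Vi`` is close to ``Va``.

    Raises
    ------
    ValueError
        If both rates vanish (the steady state is then undefined) or the
        Michaelis constants are not positive.
    """
    if Ja <= 0 or Ji <= 0:
        raise ValueError("GK Michaelis constants must be positive")
    if Va < 0 or Vi < 0:
        raise ValueError("GK rates must be non-negative")
    if Va == 0.0 and Vi == 0.0:
        raise ValueError("Goldbeter-Koshland switch undefined for Va = Vi = 0")
    if Va == 0.0:
        return 0.0
    B = Vi - Va + Va * Ji + Vi * Ja
    disc = B * B - 4.0 * (Vi - Va) * Va * Ji
    if disc < _GK_DISC_FLOOR:
        disc = _GK_DISC_FLOOR
    G = 2.0 * Va * Ji / (B + math.sqrt(disc))
    # clamp pure round-off excursions
    if G < 0.0:
        return 0.0
    if G > 1.0:
        return 1.0
    return G


def gk(args: GKArgs) -> float:
    """:func:`goldbeter_koshland` taking a :class:`GKArgs` bundle."""
    return goldbeter_koshland(args.Va, args.Vi, args.Ja, args.Ji)


def hill_activation(x: float, K: float, n: float) -> float:
    """Hill activation ``x^n / (K^n + x^n)``.

    Strictly increasing in ``x`` with half-saturation at ``x = K``.  Evaluated
    through ``n*log(x/K)`` when the exponent is extreme so that strongly
    overexpressed inputs cannot overflow.
    """
    if K <= 0:
        raise ValueError("half-saturation constant K must be positive")
    if n < 1:
        raise ValueError("Hill coefficient must be >= 1")
    if x < 0:
        raise ValueError("activator level must be non-negative")
    if x == 0.0:
        return 0.0
    t = n * math.log(x / K)
    if t > 50.0:
        return 1.0
    if t < -50.0:
        return math.exp(t)
    r = math.exp(t)
    return r / (1.0 + r)


def transport_flux(
    c_from: float,
    c_to: float,
    k_export: float,
    k_import: float,
    v_from: float,
    v_to: float,
) -> tuple[float, float]:
    """Concentration derivatives of a reversible transport step.

    First-order export (``k_export * c_from``) and import
    (``k_import * c_to``) between two compartments of constant relative
    volumes ``v_from`` and ``v_to``.  The returned pair
    ``(dc_from/dt, dc_to/dt)`` satisfies molecule-number conservation,

        v_from * dc_from/dt + v_to * dc_to/dt = 0,

    because the molecular flux computed in the source compartment is rescaled
    by the volume ratio on arrival.
    """
    if v_from <= 0 or v_to <= 0:
        raise ValueError("compartment volumes must be positive")
    if k_export < 0 or k_import < 0:
        raise ValueError("transport rates must be non-negative")
    flux = k_export * c_from - k_import * c_to * (v_to / v_from)
    # `flux` is the net concentration change rate seen by the source side
    return -flux, flux * (v_from / v_to)


def mass_growth(mass: float, mu: float) -> float:
    """Exponential growth ``d(mass)/dt = mu * mass``.

    With ``mu = ln 2 / MDT`` the mass doubles every mass-doubling-time
    minutes between division events.
    """
    if mass < 0:
        raise ValueError("mass must be non-negative")
    if mu < 0:
        raise ValueError("growth rate must be non-negative")
    return mu * mass
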