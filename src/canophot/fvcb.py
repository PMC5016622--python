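"""Farquhar–von Caemmerer–Berry (FvCB) leaf photosynthesis at 25 °C.

Net assimilation is the minimum of the Rubisco-limited rate ``Av`` and the
RuBP-regeneration (electron-transport) limited rate ``Aj``, minus mitochondrial
(dark) respiration ``Rl``:

    Al = min{Av, Aj} − Rl
    Av = Vl (ci − Γ*) / (ci + K′),          K′ = Kc (1 + O/Ko)
    Aj = J  (ci − Γ*) / (4 (ci + 2 Γ*))
    θl J² − (Ile + Jm) J + Ile Jm = 0,      Ile = Il (1 − f) / 2

with ``ci`` the internal CO2 partial pressure (Pa), ``Il`` the absorbed PPFD
(μmol m⁻² s⁻¹), ``Vl`` the maximum Rubisco carboxylation capacity and ``Jm``
the maximum electron-transport rate (both at 25 °C).  All temperatures are
fixed at 25 °C; no temperature-response functions are applied, and no
triose-phosphate-utilisation limitation is modelled.

Two respiration rules are available: a fixed coefficient (Rl = 0.0089 Vl) and
the compensation-point ratio Rl/Vl = (Γ − Γ*)/(Γ + K′).  The two differ by
about 2% at the default constants; both are exposed because the calibration
literature uses both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FvCBConstants",
    "FvCBParams",
    "LeafState",
    "effective_km",
    "rubisco_limited",
    "effective_irradiance",
    "electron_transport",
    "rubp_limited",
    "respiration",
    "net_assimilation",
    "nrh_light_response",
]


@dataclass(frozen=True)
class FvCBConstants:
    """Kinetic constants of the FvCB model at 25 °C (pressure-based units).

    Attributes
    ----------
    Kc, Ko : float
        Michaelis–Menten constants of Rubisco for CO2 and O2 [Pa].
    O : float
        Oxygen partial pressure [Pa].
    gamma : float
        CO2 compensation point of net photosynthesis Γ [Pa].
    gamma_star : float
        CO2 compensation point in the absence of mitochondrial
        respiration Γ* [Pa].
    f : float
        Spectral correction factor (fraction of absorbed PPFD lost before
        PSII) [-].
    respiration_coefficient : float
        Ratio Rl/Vl used by the fixed-coefficient respiration rule [-].
    """

    Kc: float = 40.4
    Ko: float = 24.8e3
    O: float = 20.5e3
    gamma: float = 4.4
    gamma_star: float = 3.69
    f: float = 0.15
    respiration_coefficient: float = 0.0089

    def __post_init__(self) -> None:
        vals = (self.Kc, self.Ko, self.O, self.gamma, self.gamma_star)
        if any(v <= 0 for v in vals):
            raise ValueError("all FvCB constants must be positive")
        if self.gamma <= self.gamma_star:
            raise ValueError("gamma must exceed gamma_star")
        if not 0.0 <= self.f < 1.0:
            raise ValueError("spectral correction factor f must be in [0, 1)")


#: Default constants at 25 °C.
DEFAULT_CONSTANTS = FvCBConstants()

#: Admissible range of the electron-transport curvature θl observed across
#: canopy layers; 0.75 is the midpoint used when no layer-specific fit exists.
THETA_RANGE = (0.68, 0.83)


@dataclass(frozen=True)
class FvCBParams:
    """Leaf-level capacities at 25 °C.

    ``vl`` (Vcmax) and ``jm`` (Jmax) in μmol m⁻² s⁻¹, curvature ``theta``
    dimensionless, ``respiration_rule`` one of ``"table_coefficient"``
    (Rl = coefficient · Vl) or ``"compensation_ratio"``
    (Rl = Vl (Γ − Γ*)/(Γ + K′)).
    """

    vl: float
    jm: float
    theta: float = 0.75
    respiration_rule: str = "table_coefficient"

    def __post_init__(self) -> None:
        if self.vl <= 0 or self.jm <= 0:
            raise ValueError("vl and jm must be positive")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        if self.respiration_rule not in ("table_coefficient", "compensation_ratio"):
            raise ValueError(f"unknown respiration rule {self.respiration_rule!r}")


@dataclass(frozen=True)
class LeafState:
    """Instantaneous leaf environment: absorbed PPFD and internal CO2."""

    il: float  # absorbed PPFD, μmol m⁻² s⁻¹
    ci: float  # internal CO2 partial pressure, Pa

    def __post_init__(self) -> None:
        if self.il < 0 or self.ci < 0:
            raise ValueError("il and ci must be non-negative")


def effective_km(constants: FvCBConstants = DEFAULT_CONSTANTS) -> float:
    """Effective Michaelis–Menten constant K′ = Kc (1 + O/Ko) [Pa]."""
    return constants.Kc * (1.0 + constants.O / constants.Ko)


def rubisco_limited(vl, ci, constants: FvCBConstants = DEFAULT_CONSTANTS):
    """Rubisco-limited gross carboxylation Av = Vl (ci − Γ*)/(ci + K′).

    Negative below the gross compensation point Γ*; saturates at Vl for
    large ci.  Vectorised over ``ci``.
    """
    ci = np.asarray(ci, dtype=float)
    if np.any(ci < 0):
        raise ValueError("ci must be non-negative")
    kp = effective_km(constants)
    out = vl * (ci - constants.gamma_star) / (ci + kp)
    return float(out) if out.ndim == 0 else out


def effective_irradiance(il, f: float | None = None,
                         constants: FvCBConstants = DEFAULT_CONSTANTS):
    """PPFD effectively absorbed by PSII: Ile = Il (1 − f) / 2."""
    if f is None:
        f = constants.f
    il = np.asarray(il, dtype=float)
    out = il * (1.0 - f) / 2.0
    return float(out) if out.ndim == 0 else out


def electron_transport(ile, jm: float, theta: float):
    """Electron-transport rate J: smaller root of θ J² − (Ile+Jm) J + Ile Jm = 0.

    Uses the cancellation-free quadratic form 2c / (−b + √(b² − 4ac)) so the
    low-light limit J → Ile is computed without loss of precision.  The
    discriminant (Ile+Jm)² − 4θ Ile Jm is non-negative for θ ≤ 1; tiny
    negative round-off is clamped.  J ≤ min(Ile, Jm) always.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    ile = np.asarray(ile, dtype=float)
    b = ile + jm
    disc = b * b - 4.0 * theta * ile * jm
    disc = np.maximum(disc, 0.0)
    denom = b + np.sqrt(disc)
    with np.errstate(invalid="ignore"):
        j = np.where(denom > 0.0, 2.0 * ile * jm / np.where(denom == 0, 1, denom), 0.0)
    return float(j) if j.ndim == 0 else j


def rubp_limited(j, ci, constants: FvCBConstants = DEFAULT_CONSTANTS):
    """RuBP-regeneration limited rate Aj = J (ci − Γ*)/(4 (ci + 2 Γ*))."""
    ci = np.asarray(ci, dtype=float)
    gs = constants.gamma_star
    out = np.asarray(j, dtype=float) * (ci - gs) / (4.0 * (ci + 2.0 * gs))
    return float(out) if out.ndim == 0 else out


def respiration(vl: float, rule: str = "table_coefficient",
                constants: FvCBConstants = DEFAULT_CONSTANTS) -> float:
    """Dark respiration Rl for a leaf of capacity Vl, by the chosen rule."""
    if rule == "table_coefficient":
        return constants.respiration_coefficient * vl
    if rule == "compensation_ratio":
        kp = effective_km(constants)
        return vl * (constants.gamma - constants.gamma_star) / (constants.gamma + kp)
    raise ValueError(f"unknown respiration rule {rule!r}")


def net_assimilation(params: FvCBParams, state: LeafState,
                     constants: FvCBConstants = DEFAULT_CONSTANTS,
                     return_limitation: bool = False):
    """Net leaf assimilation Al = min{Av, Aj} − Rl [μmol m⁻² s⁻¹].

    With ``return_limitation=True`` also returns ``"rubisco"`` or ``"rubp"``
    naming the active limb (ties report ``"rubisco"``).
    """
    av = rubisco_limited(params.vl, state.ci, constants)
    ile = effective_irradiance(state.il, constants=constants)
    j = electron_transport(ile, params.jm, params.theta)
    aj = rubp_limited(j, state.ci, constants)
    rl = respiration(params.vl, params.respiration_rule, constants)
    al = min(av, aj) - rl
    if return_limitation:
        return al, ("rubisco" if av <= aj else "rubp")
    return al


def net_assimilation_curve(params: FvCBParams, il, ci,
                           constants: FvCBConstants = DEFAULT_CONSTANTS):
    """Vectorised Al over arrays of absorbed PPFD and internal CO2."""
    il = np.asarray(il, dtype=float)
    ci = np.asarray(ci, dtype=float)
    av = rubisco_limited(params.vl, ci, constants)
    ile = effective_irradiance(il, constants=constants)
    j = electron_transport(ile, params.jm, params.theta)
    aj = rubp_limited(j, ci, constants)
    rl = respiration(params.vl, params.respiration_rule, constants)
    return np.minimum(av, aj) - rl


def nrh_light_response(i, a_max: float, phi: float, theta: float, r_d: float):
    """Non-rectangular hyperbola light response.

    A(I) = [φI + Amax − √((φI + Amax)² − 4 θ φ I Amax)] / (2θ) − Rd

    interpolating between the Blackman (θ→1) and rectangular-hyperbola (θ→0)
    limits; the θ→0 case is evaluated by its closed-form limit
    φ I Amax / (φ I + Amax) − Rd.
    """
    i = np.asarray(i, dtype=float)
    s = phi * i + a_max
    if theta < 1e-9:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(s > 0, phi * i * a_max / np.where(s == 0, 1, s), 0.0) - r_d
        return float(out) if out.ndim == 0 else out
    disc = np.maximum(s * s - 4.0 * theta * phi * i * a_max, 0.0)
    out = (s - np.sqrt(disc)) / (2.0 * theta) - r_d
    return float(out) if out.ndim == 0 else out
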