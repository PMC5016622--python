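"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the measurement protocols end to end: LI-6400-style 20-point A/Ci
curves (external CO2 0–120 Pa at PPFD 1000) and light curves (PPFD 50–1000
at external CO2 100 Pa), half-sine weather days sampled half-hourly from
09:00 to 18:00, and sawtooth closed-chamber CO2 logs with injection events.
Every generator is seed-deterministic and returns its generating truth so
round-trip (generate → fit/invert → compare) tests are exact.

Measurement noise is additive Gaussian on the assimilation rate (σ default
0.5 μmol m⁻² s⁻¹, chosen to put replicate standard errors in the range the
gas-exchange literature reports for this protocol); the CO2 injection is a
first-order ramp (time constant 60 s) rather than a step so the log-masking
logic is genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import yaml
from importlib import resources

from . import fvcb
from .canopy import ChamberGeometry
from .fvcb import FvCBConstants, FvCBParams, DEFAULT_CONSTANTS
from .fitting import GasExchangeCurve

__all__ = [
    "GeneratorConfig",
    "gen_aci_curve",
    "gen_light_curve",
    "gen_weather_day",
    "gen_chamber_log",
    "structure_table",
    "fvcb_constants",
    "capacity_profile",
    "AMAX_TOP",
    "AMAX_BOTTOM",
]

#: Measured light-saturated maximum assimilation at the canopy top (layer 15)
#: and bottom (layer 1), μmol m⁻² s⁻¹.
AMAX_TOP = 37.04
AMAX_BOTTOM = 12.41

#: Protocol grids.
ACI_CA_RANGE = (0.0, 120.0)     # external CO2 partial pressure, Pa
LIGHT_PPFD_RANGE = (50.0, 1000.0)
ACI_PPFD = 1000.0               # PPFD during A/Ci measurement
LIGHT_CA = 100.0                # external CO2 during light-curve measurement
N_POINTS = 20


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs shared by the curve generators.

    ``noise_sd`` is the Gaussian σ on the assimilation rate [μmol m⁻² s⁻¹];
    ``ci_ratio`` the internal:external CO2 ratio used to derive ci from the
    protocol's ca grid.
    """

    n_points: int = N_POINTS
    noise_sd: float = 0.5
    seed: int = 0
    ci_ratio: float = 0.7

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_points < 4:
            raise ValueError("n_points must be at least 4")
        if not 0 < self.ci_ratio <= 1:
            raise ValueError("ci_ratio must lie in (0, 1]")


def gen_aci_curve(params: FvCBParams, config: GeneratorConfig = GeneratorConfig(),
                  constants: FvCBConstants = DEFAULT_CONSTANTS,
                  layer_index: int = 0, replicate_id: int = 0,
                  limb: str = "net") -> tuple[GasExchangeCurve, dict]:
    """Synthesize an A/Ci curve; returns (curve, truth).

    ``limb`` selects the generating model: ``"net"`` (full min{Av,Aj} − Rl),
    ``"rubisco"`` (Av − Rl only) or ``"rubp"`` (Aj − Rl only) — the
    single-limb modes produce curves whose partitioned fits are exactly
    invertible over the whole window.
    """
    rng = np.random.default_rng(config.seed)
    ca = np.linspace(*ACI_CA_RANGE, config.n_points)
    ci = config.ci_ratio * ca
    rl = fvcb.respiration(params.vl, params.respiration_rule, constants)
    if limb == "net":
        a = fvcb.net_assimilation_curve(params, ACI_PPFD, ci, constants)
    elif limb == "rubisco":
        a = fvcb.rubisco_limited(params.vl, ci, constants) - rl
    elif limb == "rubp":
        ile = fvcb.effective_irradiance(ACI_PPFD, constants=constants)
        j = fvcb.electron_transport(ile, params.jm, params.theta)
        a = fvcb.rubp_limited(j, ci, constants) - rl
    else:
        raise ValueError(f"unknown limb {limb!r}")
    a = a + rng.normal(0.0, config.noise_sd, size=len(a))
    pts = pd.DataFrame({"ppfd": ACI_PPFD, "ca_pa": ca, "ci_pa": ci, "a_net": a})
    curve = GasExchangeCurve(points=pts, curve_kind="aci_curve",
                             layer_index=layer_index, replicate_id=replicate_id)
    truth = {"vl": params.vl, "jm": params.jm, "theta": params.theta,
             "rl": rl, "limb": limb, "ppfd": ACI_PPFD,
             "ci_ratio": config.ci_ratio, "seed": config.seed,
             "noise_sd": config.noise_sd}
    return curve, truth


def gen_light_curve(a_max: float, phi: float = 0.06, theta: float = 0.75,
                    r_d: float = 1.0,
                    config: GeneratorConfig = GeneratorConfig(),
                    layer_index: int = 0, replicate_id: int = 0
                    ) -> tuple[GasExchangeCurve, dict]:
    """Synthesize a light curve from the non-rectangular hyperbola."""
    rng = np.random.default_rng(config.seed)
    ppfd = np.linspace(*LIGHT_PPFD_RANGE, config.n_points)
    a = fvcb.nrh_light_response(ppfd, a_max, phi, theta, r_d)
    a = a + rng.normal(0.0, config.noise_sd, size=len(a))
    pts = pd.DataFrame({"ppfd": ppfd, "ca_pa": LIGHT_CA,
                        "ci_pa": config.ci_ratio * LIGHT_CA, "a_net": a})
    curve = GasExchangeCurve(points=pts, curve_kind="light_curve",
                             layer_index=layer_index, replicate_id=replicate_id)
    truth = {"a_max": a_max, "phi": phi, "theta": theta, "r_d": r_d,
             "seed": config.seed, "noise_sd": config.noise_sd}
    return curve, truth


def gen_weather_day(peak_ppfd: float = 1200.0, diffuse_fraction=0.3,
                    date: datetime | None = None,
                    start_hour: float = 9.0, end_hour: float = 18.0,
                    step_minutes: int = 30) -> pd.DataFrame:
    """Half-sine PPFD day sampled on a fixed half-hour grid.

    Defaults reproduce the validation protocol: 09:00–18:00 at 30-minute
    steps (19 samples) on an autumn day.  ``diffuse_fraction`` may be a
    scalar or a callable of fractional hour.  The half-sine peaks at the
    middle of the measurement span and is zero at its ends.
    """
    if date is None:
        date = datetime(2014, 10, 15)
    hours = np.arange(start_hour, end_hour + 1e-9, step_minutes / 60.0)
    frac = (hours - start_hour) / (end_hour - start_hour)
    ppfd = peak_ppfd * np.sin(np.pi * frac)
    ppfd = np.clip(ppfd, 0.0, None)
    if callable(diffuse_fraction):
        dfr = np.array([float(diffuse_fraction(h)) for h in hours])
    else:
        dfr = np.full_like(hours, float(diffuse_fraction))
    ts = [datetime(date.year, date.month, date.day) + timedelta(hours=float(h))
          for h in hours]
    return pd.DataFrame({"timestamp": ts, "ppfd": ppfd,
                         "diffuse_fraction": dfr})


def gen_chamber_log(true_rate_series: pd.DataFrame,
                    geometry: ChamberGeometry = ChamberGeometry(),
                    co2_init_pa: float = 200.0,
                    injection_trigger_pa: float = 100.0,
                    injection_target_pa: float = 200.0,
                    injection_tau_s: float = 60.0,
                    injection_duration_s: float = 300.0,
                    sampling_s: float = 10.0,
                    sensor_noise_pa: float = 0.0,
                    seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Forward-simulate the closed-chamber CO2 mass balance to a 10-s log.

    ``true_rate_series`` has columns timestamp, rate (plant uptake,
    μmol s⁻¹), piecewise-constant between entries.  CO2 falls by
    (uptake + leak)·RT/(PV); when it crosses ``injection_trigger_pa`` the
    supply valve opens for ``injection_duration_s`` seconds, refilling toward
    ``injection_target_pa`` with a first-order ramp (time constant
    ``injection_tau_s``) — a fixed valve-open time, as a real solenoid timer
    would behave, so the refill always terminates even when uptake balances
    the ramp tail.  This produces the sawtooth the inversion has to mask.
    Returns (log, truth) where truth records the per-sample plant uptake and
    the leak.
    """
    ts = pd.to_datetime(true_rate_series["timestamp"])
    rates = true_rate_series["rate"].to_numpy(float)
    t_start, t_end = ts.iloc[0], ts.iloc[-1]
    n_air = geometry.air_moles  # mol
    rng = np.random.default_rng(seed)

    times, co2s, true_uptake = [], [], []
    co2 = float(co2_init_pa)
    valve_open_samples = 0
    n_valve = max(int(round(injection_duration_s / sampling_s)), 1)
    t = t_start
    k = 0
    while t <= t_end:
        while k + 1 < len(ts) and ts.iloc[k + 1] <= t:
            k += 1
        u = rates[k]
        times.append(t)
        noise = rng.normal(0.0, sensor_noise_pa) if sensor_noise_pa > 0 else 0.0
        co2s.append(co2 + noise)
        true_uptake.append(u)
        # mole-fraction drop from uptake + leak, expressed back in Pa
        dp_uptake = -(u + geometry.leak_rate) / n_air * 1e-6 \
            * geometry.pressure_pa * sampling_s
        if co2 <= injection_trigger_pa and valve_open_samples == 0:
            valve_open_samples = n_valve
        if valve_open_samples > 0:
            dp_inj = max(injection_target_pa - co2, 0.0) * (
                1.0 - np.exp(-sampling_s / injection_tau_s))
            valve_open_samples -= 1
        else:
            dp_inj = 0.0
        co2 = co2 + dp_uptake + dp_inj
        t = t + timedelta(seconds=sampling_s)
    log_df = pd.DataFrame({"timestamp": times, "co2_pa": co2s})
    truth = {"uptake": np.asarray(true_uptake),
             "leak_rate": geometry.leak_rate,
             "timestamps": pd.Series(times)}
    return log_df, truth


# --------------------------------------------------------------------------
# Packaged measurement tables


def structure_table() -> pd.DataFrame:
    """Per-layer structural table of the reference paprika plant."""
    from .architecture import default_structure_table
    return default_structure_table()


def fvcb_constants() -> FvCBConstants:
    """Packaged FvCB kinetic constants at 25 °C."""
    text = resources.files("canophot.data").joinpath(
        "fvcb_constants_25c.yaml").read_text()
    raw = yaml.safe_load(text)
    return FvCBConstants(Kc=raw["Kc"], Ko=raw["Ko"], O=raw["O"],
                         gamma=raw["gamma"], gamma_star=raw["gamma_star"],
                         f=raw["f"],
                         respiration_coefficient=raw["respiration_coefficient"])


def capacity_profile() -> pd.DataFrame:
    """Measured per-layer Vcmax/Jmax profile (mean ± SE, n, R²)."""
    text = resources.files("canophot.data").joinpath(
        "photosynthetic_capacity_profile.csv").read_text()
    import io
    return pd.read_csv(io.StringIO(text))
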