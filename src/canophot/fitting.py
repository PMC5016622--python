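"""Estimation of leaf photosynthetic capacities from gas-exchange curves.

Two curve protocols are supported, matching a LI-6400-style auto program:

* **light curves** — net assimilation vs PPFD (50–1000 μmol m⁻² s⁻¹) at
  saturating CO2; fitted with the non-rectangular hyperbola to give Amax, the
  apparent quantum yield φ, the curvature θ and dark respiration Rd;
* **A/Ci curves** — net assimilation vs internal CO2 (ca 0–120 Pa) at
  PPFD 1000; partitioned fitting gives Vcmax (``fit_vl``, Rubisco-limited
  window ci < 30 Pa) and Jmax (``fit_jm``, RuBP-limited window ci > 40 Pa,
  per-point algebraic inversion of the electron-transport quadratic).

The Vcmax objective treats the measurements as *net* rates and couples
respiration to Vcmax inside the fit (Rl = r·Vl with the active respiration
coefficient); a fixed-respiration mode is available since calibration
protocols differ on this point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import fvcb
from .fvcb import FvCBConstants, DEFAULT_CONSTANTS

__all__ = [
    "GasExchangeCurve",
    "FitResult",
    "fit_light_curve",
    "fit_vl",
    "fit_jm",
    "fit_layer_profile",
    "read_curves_csv",
]

log = logging.getLogger(__name__)


@dataclass
class GasExchangeCurve:
    """One measured (or synthetic) response curve.

    ``points`` is a DataFrame with columns ppfd, ca_pa, ci_pa, a_net;
    ``curve_kind`` is ``"light_curve"`` or ``"aci_curve"``.  A/Ci curves must
    be measured at a single PPFD; internal CO2 cannot exceed external CO2.
    """

    points: pd.DataFrame
    curve_kind: str
    layer_index: int = 0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        req = {"ppfd", "ca_pa", "ci_pa", "a_net"}
        if not req.issubset(self.points.columns):
            raise ValueError(f"curve points need columns {sorted(req)}")
        if len(self.points) < 4:
            raise ValueError("a gas-exchange curve needs at least 4 points")
        if self.curve_kind not in ("light_curve", "aci_curve"):
            raise ValueError(f"unknown curve kind {self.curve_kind!r}")
        if (self.points["ci_pa"] > self.points["ca_pa"] + 1e-9).any():
            raise ValueError("ci must not exceed ca")
        if self.curve_kind == "aci_curve":
            if self.points["ppfd"].nunique() > 1:
                raise ValueError("an A/Ci curve must be at a single PPFD")

    @property
    def ppfd(self) -> float:
        return float(self.points["ppfd"].iloc[0])


@dataclass
class FitResult:
    """Point estimate with its uncertainty and fitting-window bookkeeping."""

    estimate: float
    standard_error: float
    r_squared: float
    n_points_used: int
    window: tuple
    converged: bool
    extra: dict = field(default_factory=dict)


def _r_squared(y, yhat) -> float:
    y = np.asarray(y, float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def _nls_se(res) -> np.ndarray:
    """Parameter SEs from the Gauss-Newton curvature at the optimum."""
    m, n = res.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


# Fixed multi-start perturbation seeds for the trust-region optimiser.
_START_SEEDS = (0, 1, 2)


def fit_light_curve(curve: GasExchangeCurve) -> dict:
    """Fit the non-rectangular hyperbola A(I) to a light curve.

    Returns a dict of :class:`FitResult` for ``a_max``, ``phi``, ``theta``
    and ``r_d``.  Bounds: Amax > 0, φ ∈ (0, 0.125] (the quantum-requirement
    ceiling), θ ∈ (0, 1), Rd ≥ 0.  Non-convergence (or a degenerate flat
    curve) is reported through ``converged=False``, never raised.
    """
    if curve.curve_kind != "light_curve":
        raise ValueError("fit_light_curve needs a light curve")
    if len(curve.points) < 5:
        raise ValueError("light-curve fitting needs at least 5 points")
    i = curve.points["ppfd"].to_numpy(float)
    a = curve.points["a_net"].to_numpy(float)
    window = (float(i.min()), float(i.max()))

    if np.ptp(a) < 1e-10:  # flat response: NRH parameters unidentifiable
        nanres = FitResult(np.nan, np.nan, 0.0, len(i), window, False)
        return {k: nanres for k in ("a_max", "phi", "theta", "r_d")}

    def resid(p):
        return fvcb.nrh_light_response(i, p[0], p[1], p[2], p[3]) - a

    lo = [1e-6, 1e-6, 1e-6, 0.0]
    hi = [200.0, 0.125, 1.0 - 1e-9, 20.0]
    amax0 = max(float(a.max()) - float(a.min()), 1.0)
    best = None
    rng = np.random.default_rng(12345)
    for k in _START_SEEDS:
        jit = 1.0 if k == 0 else float(rng.uniform(0.5, 1.5))
        x0 = np.clip([amax0 * jit, 0.05 * jit, 0.75, max(-a.min(), 0.5) * jit],
                     lo, hi)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        nanres = FitResult(np.nan, np.nan, 0.0, len(i), window, False)
        return {k: nanres for k in ("a_max", "phi", "theta", "r_d")}
    se = _nls_se(best)
    r2 = _r_squared(a, a + best.fun)
    names = ("a_max", "phi", "theta", "r_d")
    return {name: FitResult(float(best.x[j]), float(se[j]), r2, len(i),
                            window, True)
            for j, name in enumerate(names)}


def fit_vl(aci_curve: GasExchangeCurve, ci_window_max: float = 30.0,
           constants: FvCBConstants = DEFAULT_CONSTANTS,
           respiration_rule: str = "table_coefficient",
           fixed_rl: float | None = None) -> FitResult:
    """Estimate Vcmax from the Rubisco-limited window of an A/Ci curve.

    Fits A_net = Vl·[(ci − Γ*)/(ci + K′) − r] over Γ* < ci < ``ci_window_max``
    (default 30 Pa), with r the active respiration coefficient; or
    A_net = Vl·(ci − Γ*)/(ci + K′) − Rl with ``fixed_rl`` given.  Points
    outside the window never influence the estimate.
    """
    if aci_curve.curve_kind != "aci_curve":
        raise ValueError("fit_vl needs an A/Ci curve")
    pts = aci_curve.points
    mask = (pts["ci_pa"] > constants.gamma_star) & (pts["ci_pa"] < ci_window_max)
    used = pts[mask]
    if len(used) < 3:
        raise ValueError(
            f"fit_vl needs >= 3 points with {constants.gamma_star} < ci < "
            f"{ci_window_max} Pa; got {len(used)}")
    ci = used["ci_pa"].to_numpy(float)
    a = used["a_net"].to_numpy(float)
    kp = fvcb.effective_km(constants)
    g = (ci - constants.gamma_star) / (ci + kp)
    if fixed_rl is None:
        r = fvcb.respiration(1.0, respiration_rule, constants)
        design = g - r
        offset = 0.0
    else:
        design = g
        offset = fixed_rl
    # The model is linear in Vl: closed-form least squares with exact SE.
    denom = float(design @ design)
    if denom <= 0:
        raise ValueError("degenerate Rubisco-limited window")
    vl = float(design @ (a + offset)) / denom
    resid = a - (vl * design - offset)
    dof = max(len(a) - 1, 1)
    se = float(np.sqrt(np.sum(resid ** 2) / dof / denom))
    return FitResult(vl, se, _r_squared(a, vl * design - offset), len(a),
                     (float(constants.gamma_star), ci_window_max), True)


def fit_jm(aci_curve: GasExchangeCurve, ci_window_min: float = 40.0,
           theta: float = 0.75, measurement_ppfd: float | None = None,
           vl: float | None = None,
           constants: FvCBConstants = DEFAULT_CONSTANTS,
           respiration_rule: str = "table_coefficient") -> FitResult:
    """Estimate Jmax from the RuBP-limited window of an A/Ci curve.

    Per point with ci > ``ci_window_min``: gross Aj = A_net + Rl, then
    J = 4 Aj (ci + 2Γ*)/(ci − Γ*) and Jm = J (Ile − θJ)/(Ile − J) — the exact
    algebraic inversion of the electron-transport quadratic.  The estimate is
    the mean of the per-point Jm values, the SE their standard error.  Points
    with J ≥ Ile are unphysical (light cannot sustain them) and are dropped
    with a warning.

    ``vl`` feeds the respiration correction; by default it is fitted from the
    same curve with :func:`fit_vl`.  ``measurement_ppfd`` defaults to the
    curve's recorded PPFD.
    """
    if aci_curve.curve_kind != "aci_curve":
        raise ValueError("fit_jm needs an A/Ci curve")
    pts = aci_curve.points
    used = pts[pts["ci_pa"] > ci_window_min]
    if len(used) < 3:
        raise ValueError(
            f"fit_jm needs >= 3 points with ci > {ci_window_min} Pa; "
            f"got {len(used)}")
    if vl is None:
        vl = fit_vl(aci_curve, constants=constants,
                    respiration_rule=respiration_rule).estimate
    rl = fvcb.respiration(vl, respiration_rule, constants)
    ppfd = measurement_ppfd if measurement_ppfd is not None else aci_curve.ppfd
    ile = fvcb.effective_irradiance(ppfd, constants=constants)
    ci = used["ci_pa"].to_numpy(float)
    aj = used["a_net"].to_numpy(float) + rl
    gs = constants.gamma_star
    j = 4.0 * aj * (ci + 2.0 * gs) / (ci - gs)
    ok = j < ile - 1e-9
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("fit_jm: dropped %d points with J >= Ile", n_dropped)
    if not ok.any():
        raise ValueError("fit_jm: no usable points (all have J >= Ile)")
    j = j[ok]
    jm_points = j * (ile - theta * j) / (ile - j)
    est = float(np.mean(jm_points))
    se = float(np.std(jm_points, ddof=1) / np.sqrt(len(jm_points))) \
        if len(jm_points) > 1 else 0.0
    return FitResult(est, se, np.nan, int(ok.sum()),
                     (ci_window_min, float(ci.max())), True,
                     extra={"jm_per_point": jm_points, "n_dropped": n_dropped})


def fit_layer_profile(curves: list[GasExchangeCurve],
                      constants: FvCBConstants = DEFAULT_CONSTANTS,
                      respiration_rule: str = "table_coefficient") -> dict:
    """Per-layer capacity profile plus its vertical (linear) trend.

    Groups curves by ``layer_index``; per layer reports mean ± SE of Vcmax,
    Jmax (from A/Ci replicates) and Amax (from light-curve replicates).  The
    vertical trend of each mean vs layer index is summarised by an OLS line
    (slope, intercept, R²).  Returns ``{"profile": DataFrame, "trends": dict}``.
    """
    rows = []
    layers = sorted({c.layer_index for c in curves})
    for layer in layers:
        group = [c for c in curves if c.layer_index == layer]
        vls, jms, amaxes, thetas = [], [], [], []
        for c in group:
            if c.curve_kind == "light_curve":
                fit = fit_light_curve(c)
                if fit["a_max"].converged:
                    amaxes.append(fit["a_max"].estimate)
                    thetas.append(fit["theta"].estimate)
        theta = float(np.mean(thetas)) if thetas else 0.75
        for c in group:
            if c.curve_kind == "aci_curve":
                try:
                    v = fit_vl(c, constants=constants,
                               respiration_rule=respiration_rule)
                    jm = fit_jm(c, theta=theta, vl=v.estimate,
                                constants=constants,
                                respiration_rule=respiration_rule)
                    vls.append(v.estimate)
                    jms.append(jm.estimate)
                except ValueError as err:
                    log.warning("layer %s replicate skipped: %s", layer, err)

        def mean_se(vals):
            if not vals:
                return np.nan, np.nan, 0
            arr = np.asarray(vals)
            se = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
            return float(arr.mean()), float(se), len(arr)

        vm, vse, vn = mean_se(vls)
        jm_m, jm_se, jn = mean_se(jms)
        am, ase, an = mean_se(amaxes)
        rows.append({"layer": layer, "vlo": vm, "vlo_se": vse, "vlo_n": vn,
                     "jmo": jm_m, "jmo_se": jm_se, "jmo_n": jn,
                     "amax": am, "amax_se": ase, "amax_n": an,
                     "theta": theta})
    profile = pd.DataFrame(rows)

    trends = {}
    for col in ("vlo", "jmo", "amax"):
        sub = profile.dropna(subset=[col])
        if len(sub) >= 2:
            x = sub["layer"].to_numpy(float)
            y = sub[col].to_numpy(float)
            slope, intercept = np.polyfit(x, y, 1)
            trends[col] = {"slope": float(slope),
                           "intercept": float(intercept),
                           "r_squared": _r_squared(y, slope * x + intercept)}
    return {"profile": profile, "trends": trends}


def read_curves_csv(path) -> list[GasExchangeCurve]:
    """Read curves from CSV `layer,replicate,kind,ppfd,ca_pa,ci_pa,a_net`."""
    df = pd.read_csv(path)
    req = {"layer", "replicate", "kind", "ppfd", "ca_pa", "ci_pa", "a_net"}
    if not req.issubset(df.columns):
        raise ValueError(f"curves CSV needs columns {sorted(req)}")
    curves = []
    for (layer, rep, kind), g in df.groupby(["layer", "replicate", "kind"]):
        curves.append(GasExchangeCurve(
            points=g[["ppfd", "ca_pa", "ci_pa", "a_net"]].reset_index(drop=True),
            curve_kind=kind, layer_index=int(layer), replicate_id=int(rep)))
    return curves
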