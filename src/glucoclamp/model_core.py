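"""GI and GIG feedback models of clamp-test glucose dynamics.

Two coupled ODE systems describe a subject during a hyperinsulinemic-
euglycemic clamp:

* **GI model** (states ``Gc, Y, I``): blood glucose and insulin linked
  through insulin-proportional glucose uptake (``k4 I Gc``), a delayed
  effective-glucose signal ``Y`` driving thresholded beta-cell secretion
  ``X = max(Y - k6, 0)``, and first-order insulin clearance ``k7``.
  Urinary glucose loss enters as a first-order flux ``k8 Gc`` (the SGLT2
  inhibitor term; ``k8`` is fixed from the measured urinary glucose
  integral rather than estimated).

* **GIG model** (states ``Gc, Y, I, Gg, CP``): adds glucagon-driven
  glucose production ``kGN Gg``, insulin-suppressed glucagon secretion
  ``kGgS / I`` with clearance ``kGgC``, and C-peptide sharing the
  pre-hepatic secretion flux ``k5 X`` (insulin scaled by the posthepatic
  molar ratio ``kratio``).

Exogenous forcing comes from a :class:`ClampProtocol`: a glucose
infusion ``f1(t)`` and insulin infusion ``f2(t)`` sampled on a 1-min
grid (piecewise constant over each minute), converted to concentration
fluxes through the subject's per-kg blood volume.

The right-hand sides are pluggable: glucagon-secretion suppression can
be switched between insulin, glucose, or joint suppression (used by the
reduced-model variant family), so alternative structural assumptions
slot in without touching estimation or metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, IntegrationError
from . import units

__all__ = [
    "ClampProtocol",
    "GIParameters",
    "GIGParameters",
    "StateTrajectory",
    "gi_rhs",
    "gig_rhs",
    "simulate",
    "fasting_state",
    "SUPPRESSION_MODES",
]

SUPPRESSION_MODES = ("I", "Gc", "both")

#: estimation bounds, log10 space
GI_BOUNDS_LOG10 = (-4.0, 4.0)
GIG_BOUNDS_LOG10 = (-4.0, 6.0)
KRATIO_BOUNDS_LOG10 = (-10.0, 0.0)


@dataclass
class ClampProtocol:
    """Infusion protocol and subject-level conversion constants.

    Parameters
    ----------
    duration : float
        Protocol length in minutes.
    f1 : ndarray
        Glucose infusion, mg kg^-1 min^-1, sampled on the 1-min grid
        ``t = 0 .. duration`` (length ``duration + 1``); piecewise
        constant over each minute.
    f2 : ndarray
        Insulin infusion, mU kg^-1 min^-1, same grid.
    target_glucose : float
        Clamp target, mmol/L (used only by the synthetic controller).
    body_weight : float
        kg.
    bv_dl : float
        Blood volume, dL.
    """

    duration: float
    f1: np.ndarray
    f2: np.ndarray
    target_glucose: float
    body_weight: float
    bv_dl: float

    def __post_init__(self):
        self.f1 = np.asarray(self.f1, dtype=float)
        self.f2 = np.asarray(self.f2, dtype=float)
        if self.duration <= 0:
            raise DomainError("protocol duration must be positive")
        if self.bv_dl <= 0 or self.body_weight <= 0:
            raise DomainError("blood volume and body weight must be positive")
        n = int(round(self.duration)) + 1
        for name, arr in (("f1", self.f1), ("f2", self.f2)):
            if arr.ndim != 1 or len(arr) < n:
                raise DomainError(f"{name} must cover the 1-min grid 0..duration")
            if np.any(arr < 0):
                raise DomainError(f"{name} must be non-negative everywhere")

    @property
    def bv_norm(self) -> float:
        """Blood volume per body weight, dL/kg."""
        return self.bv_dl / self.body_weight

    def _idx(self, t: float) -> int:
        return min(int(t), len(self.f1) - 1)

    def glucose_flux(self, t: float) -> float:
        """f1 converted to mmol/L/min at time t (piecewise constant)."""
        return units.glucose_infusion_to_flux(self.f1[self._idx(t)], self.bv_norm)

    def insulin_flux(self, t: float) -> float:
        """f2 converted to pmol/L/min at time t (piecewise constant)."""
        return units.insulin_infusion_to_flux(self.f2[self._idx(t)], self.bv_norm)

    def flux_arrays(self):
        """Per-minute concentration-flux arrays (mmol/L/min, pmol/L/min)."""
        return (
            units.glucose_infusion_to_flux(self.f1, self.bv_norm),
            units.insulin_infusion_to_flux(self.f2, self.bv_norm),
        )

    @classmethod
    def zero(cls, duration=120.0, target_glucose=5.2, body_weight=65.0, bv_dl=None):
        """Protocol with no infusions (fasting dynamics)."""
        if bv_dl is None:
            bv_dl = units.blood_volume_dl(body_weight)
        n = int(round(duration)) + 1
        return cls(duration, np.zeros(n), np.zeros(n), target_glucose, body_weight, bv_dl)


@dataclass
class GIParameters:
    """Rate constants of the GI model (all >= 0).

    k1 : basal glucose production, mmol/L/min
    k2 : insulin-independent glucose removal, 1/min
    k3 : glucose-sensing rate of Y, 1/min
    k4 : insulin sensitivity, per pmol/L per min
    k5 : insulin secretion gain, pmol/L per mmol/L per min
    k6 : secretion threshold, mmol/L
    k7 : insulin clearance, 1/min
    k8 : urinary excretion rate constant, 1/min (fixed from data, alias ku)
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float = 0.0

    FREE_NAMES = ("k1", "k2", "k3", "k4", "k5", "k6", "k7")

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise DomainError(f"parameter {f.name} must be non-negative, got {v}")

    @property
    def ku(self) -> float:
        """Alias: ku and k8 are the same quantity."""
        return self.k8

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class GIGParameters(GIParameters):
    """GI parameters plus the glucagon / C-peptide block.

    kGN    : glucagon sensitivity, mmol/L/min per ng/L
    kGgS   : glucagon secretion gain (units depend on suppression mode)
    kGgC   : glucagon clearance, 1/min
    kratio : molar ratio of posthepatic insulin to C-peptide, in [1e-10, 1]
    kCPC   : C-peptide clearance, 1/min
    insulin_floor / glucose_floor : epsilon floors for the 1/I (1/Gc)
        suppression denominators; default 1e-6 of a typical maximum
        (configurable; fitting sets insulin_floor to 1e-6 x the
        subject's maximum observed insulin).

    In the GIG model the pre-hepatic secretion ``k5 X`` is expressed in
    C-peptide units (nmol/L/min); insulin receives
    ``1000 * kratio * k5 * X`` pmol/L/min so that kratio stays the
    dimensionless molar ratio.
    """

    kGN: float = 0.0
    kGgS: float = 0.0
    kGgC: float = 1e-4
    kratio: float = 0.5
    kCPC: float = 0.025
    insulin_floor: float = field(default=1e-3, compare=False)
    glucose_floor: float = field(default=1e-5, compare=False)

    FREE_NAMES = (
        "k1", "k2", "k3", "k4", "k5", "k6", "k7",
        "kGN", "kGgS", "kGgC", "kratio", "kCPC",
    )

    def __post_init__(self):
        super().__post_init__()
        if not (0 <= self.kratio <= 1.0):
            raise DomainError("kratio must lie in [0, 1] (molar ratio)")

    def as_dict(self) -> dict:
        d = super().as_dict()
        d.pop("insulin_floor", None)
        d.pop("glucose_floor", None)
        return d

    def to_gi(self) -> GIParameters:
        """Matched GI parameters: direct insulin secretion 1000*kratio*k5."""
        return GIParameters(
            k1=self.k1, k2=self.k2, k3=self.k3, k4=self.k4,
            k5=units.PMOL_PER_NMOL * self.kratio * self.k5,
            k6=self.k6, k7=self.k7, k8=self.k8,
        )


@dataclass
class StateTrajectory:
    """Simulated state sampled on a strictly increasing minute grid."""

    t: np.ndarray
    Gc: np.ndarray
    Y: np.ndarray
    I: np.ndarray
    X: np.ndarray
    Gg: np.ndarray | None = None
    CP: np.ndarray | None = None

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise DomainError("trajectory time grid must be strictly increasing")

    @property
    def variables(self) -> dict:
        out = {"Gc": self.Gc, "Y": self.Y, "I": self.I, "X": self.X}
        if self.Gg is not None:
            out["Gg"] = self.Gg
        if self.CP is not None:
            out["CP"] = self.CP
        return out

    def to_frame(self, subject_id: str = "subject"):
        """Tidy long-format DataFrame (subject_id, t_min, variable, value, units)."""
        import pandas as pd

        unit_map = {"Gc": "mmol/L", "Y": "mmol/L", "I": "pmol/L",
                    "X": "mmol/L", "Gg": "ng/L", "CP": "nmol/L"}
        rows = []
        for var, vals in self.variables.items():
            rows.append(pd.DataFrame({
                "subject_id": subject_id, "t_min": self.t,
                "variable": var, "value": vals, "units": unit_map[var],
            }))
        return pd.concat(rows, ignore_index=True)


def _check_state(state, t, protocol):
    if np.any(np.asarray(state) < 0):
        raise DomainError(f"negative state component: {state}")
    if not (0.0 <= t <= protocol.duration):
        raise DomainError(f"t={t} outside protocol [0, {protocol.duration}]")


def _gi_rhs_raw(state, t, p: GIParameters, g_in: float, i_in: float):
    Gc, Y, I = state
    X = max(Y - p.k6, 0.0)
    dGc = g_in + p.k1 - (p.k2 + p.k4 * I + p.k8) * Gc
    dY = p.k3 * (Gc - Y)
    dI = i_in + p.k5 * X - p.k7 * I
    return (dGc, dY, dI)


def gi_rhs(state: Sequence[float], t: float, params: GIParameters,
           protocol: ClampProtocol):
    """Time derivative of the GI model state ``(Gc, Y, I)``."""
    _check_state(state, t, protocol)
    return _gi_rhs_raw(state, t, params,
                       protocol.glucose_flux(t), protocol.insulin_flux(t))


def _suppression_denominator(I, Gc, p: GIGParameters, mode: str):
    if mode == "I":
        return max(I, p.insulin_floor)
    if mode == "Gc":
        return max(Gc, p.glucose_floor)
    if mode == "both":
        return max(I, p.insulin_floor) * max(Gc, p.glucose_floor)
    raise DomainError(f"unknown suppression mode {mode!r}")


def _gig_rhs_raw(state, t, p: GIGParameters, g_in: float, i_in: float,
                 suppression: str = "I"):
    Gc, Y, I, Gg, CP = state
    X = max(Y - p.k6, 0.0)
    sec = p.k5 * X  # pre-hepatic secretion, nmol/L/min
    dGc = g_in + p.k1 + p.kGN * Gg - (p.k2 + p.k4 * I + p.k8) * Gc
    dY = p.k3 * (Gc - Y)
    dI = i_in + units.PMOL_PER_NMOL * p.kratio * sec - p.k7 * I
    dGg = p.kGgS / _suppression_denominator(I, Gc, p, suppression) - p.kGgC * Gg
    dCP = sec - p.kCPC * CP
    return (dGc, dY, dI, dGg, dCP)


def gig_rhs(state: Sequence[float], t: float, params: GIGParameters,
            protocol: ClampProtocol, suppression: str = "I"):
    """Time derivative of the GIG model state ``(Gc, Y, I, Gg, CP)``."""
    _check_state(state, t, protocol)
    return _gig_rhs_raw(state, t, params,
                        protocol.glucose_flux(t), protocol.insulin_flux(t),
                        suppression)


def simulate(model_id: str, params, protocol: ClampProtocol,
             initial_state: Sequence[float], t_grid: Sequence[float],
             suppression: str = "I", rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA") -> StateTrajectory:
    """Integrate the GI or GIG model over ``t_grid`` (reference solver).

    Uses a stiff-capable solver (LSODA by default) at tight tolerances;
    the parameter ranges explored during estimation span many orders of
    magnitude.  Small negative excursions at solver-tolerance scale are
    clipped to zero; larger ones trigger a warning.

    Raises
    ------
    IntegrationError
        If the solver fails or the trajectory contains NaN/Inf.
    DomainError
        If ``t_grid`` leaves the protocol window or the model id is
        unknown.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] < 0 or t_grid[-1] > protocol.duration + 1e-9:
        raise DomainError("t_grid must lie within the protocol duration")
    y0 = np.asarray(initial_state, dtype=float)
    if np.any(~np.isfinite(y0)):
        raise DomainError("initial state must be finite")

    if model_id.upper() == "GI":
        if y0.shape != (3,):
            raise DomainError("GI initial state must be (Gc, Y, I)")
        def fun(t, y):
            return _gi_rhs_raw(y, t, params, protocol.glucose_flux(t),
                               protocol.insulin_flux(t))
    elif model_id.upper() == "GIG":
        if y0.shape != (5,):
            raise DomainError("GIG initial state must be (Gc, Y, I, Gg, CP)")
        def fun(t, y):
            return _gig_rhs_raw(y, t, params, protocol.glucose_flux(t),
                                protocol.insulin_flux(t), suppression)
    else:
        raise DomainError(f"unknown model_id {model_id!r}")

    if np.any(~np.isfinite(fun(t_grid[0], y0))):
        raise DomainError("RHS is not finite at the initial state")

    sol = solve_ivp(fun, (t_grid[0], t_grid[-1]), y0, method=method,
                    t_eval=t_grid, rtol=rtol, atol=atol, max_step=1.0)
    if not sol.success:
        raise IntegrationError(f"{method} failed: {sol.message}")
    y = sol.y
    if np.any(~np.isfinite(y)):
        raise IntegrationError("non-finite values in the integrated trajectory")
    neg = y.min()
    if neg < 0:
        if neg < -1e3 * atol:
            warnings.warn(
                f"trajectory clipped: negative excursion {neg:.3g} exceeds "
                "solver tolerance scale", RuntimeWarning)
        y = np.clip(y, 0.0, None)

    if model_id.upper() == "GI":
        Gc, Y, I = y
        return StateTrajectory(t=sol.t, Gc=Gc, Y=Y, I=I,
                               X=np.maximum(Y - params.k6, 0.0))
    Gc, Y, I, Gg, CP = y
    return StateTrajectory(t=sol.t, Gc=Gc, Y=Y, I=I,
                           X=np.maximum(Y - params.k6, 0.0), Gg=Gg, CP=CP)


# ---------------------------------------------------------------------------
# unforced steady states


def _gi_equilibrium_residual(G0, p: GIParameters):
    X0 = max(G0 - p.k6, 0.0)
    I0 = p.k5 * X0 / p.k7 if p.k7 > 0 else 0.0
    return p.k1 - (p.k2 + p.k4 * I0 + p.k8) * G0


def _gig_equilibrium_residual(G0, p: GIGParameters, suppression: str):
    X0 = max(G0 - p.k6, 0.0)
    sec = p.k5 * X0
    I0 = units.PMOL_PER_NMOL * p.kratio * sec / p.k7 if p.k7 > 0 else 0.0
    Gg0 = p.kGgS / (_suppression_denominator(I0, G0, p, suppression) * p.kGgC) \
        if p.kGgC > 0 else 0.0
    return p.k1 + p.kGN * Gg0 - (p.k2 + p.k4 * I0 + p.k8) * G0


def fasting_state(params, model_id: str = "GIG", suppression: str = "I"):
    """Unforced (fasting) equilibrium of the model.

    Solves the steady-state balance for fasting glucose ``G0`` by
    bisection and back-substitutes the remaining states.  For the GI
    model with no secretion above threshold this reduces to
    ``G0 = k1 / (k2 + k8)``.

    Returns the state vector in simulation order.
    """
    from scipy.optimize import brentq

    p = params
    if p.k7 <= 0 or (p.k2 + p.k8) <= 0:
        raise DomainError("fasting state requires positive clearances")
    resid = (
        (lambda g: _gi_equilibrium_residual(g, p))
        if model_id.upper() == "GI"
        else (lambda g: _gig_equilibrium_residual(g, p, suppression))
    )
    # below-threshold branch: no secretion, glucose balance is linear
    g_lin = p.k1 / (p.k2 + p.k8)
    if model_id.upper() == "GI" and g_lin <= p.k6:
        return np.array([g_lin, g_lin, 0.0])

    # the residual is valid on all of (0, inf) (X0 = max(G0-k6, 0)) and
    # monotonically decreasing, so one bracket covers both the below-
    # and above-threshold equilibria
    lo = 1e-12
    hi = max(10.0 * g_lin, 50.0)
    flo, fhi = resid(lo), resid(hi)
    tries = 0
    while flo * fhi > 0 and tries < 60:
        hi *= 2.0
        fhi = resid(hi)
        tries += 1
    if flo * fhi > 0:
        raise DomainError("no fasting equilibrium found in bracket")
    G0 = brentq(resid, lo, hi, xtol=1e-12, rtol=1e-14)
    X0 = max(G0 - p.k6, 0.0)
    if model_id.upper() == "GI":
        I0 = p.k5 * X0 / p.k7
        return np.array([G0, G0, I0])
    sec = p.k5 * X0
    I0 = units.PMOL_PER_NMOL * p.kratio * sec / p.k7
    Gg0 = p.kGgS / (_suppression_denominator(I0, G0, p, suppression) * p.kGgC)
    CP0 = sec / p.kCPC if p.kCPC > 0 else 0.0
    return np.array([G0, G0, I0, Gg0, CP0])
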