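"""Virtual-cohort generator: clamp and OGTT time series with the
statistical structure the cohort analyses assume.

Each synthetic subject is a GI or GIG parameter set drawn log-uniformly
from physiologic sub-ranges of the estimation bounds, placed at its
fasting equilibrium, and pushed through

* a **hyperinsulinemic-euglycemic clamp**: constant insulin infusion,
  glucose infusion adjusted every 5 min by a discrete
  proportional-integral controller toward the glycemic target (the
  stand-in for the bedside artificial endocrine pancreas), sparse
  hormone sampling, quasi-continuous glucose sampling;
* a **75-g OGTT**: a gamma-shaped systemic glucose appearance flux,
  sampled at the standard 0/30/60/90/120-min points (PG120 is the
  120-min glucose).

Group structure drives where cohort-level glycemic variance comes
from: *control* cohorts draw the insulin-related parameters
(k4, k5, k7) from wide ranges and the glucagon block from narrow ones
(variance in PG120 is insulin-driven, so DI/cle correlates negatively
with PG120); *SGLT2i* cohorts reverse the dispersion and add an
elevated urinary-excretion constant k8 matching clamp urinary losses
of roughly 0.5-1.5 mg kg^-1 min^-1 (variance is glucagon-driven, so
PI/cle correlates positively with PG120).

Measurement noise is multiplicative lognormal per sample with
per-variable CVs.  Everything is reproducible from the config seed;
subject ``i`` uses an independent child stream so cohorts of different
sizes share their leading subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.integrate import solve_ivp

from . import fastsim, units
from .errors import ConfigError, DomainError
from .metrics import di_cle, pi_cle_analytic, pi_cle_numeric
from .model_core import (GI_BOUNDS_LOG10, GIG_BOUNDS_LOG10,
                         KRATIO_BOUNDS_LOG10, GIGParameters, GIParameters,
                         _gi_rhs_raw, _gig_rhs_raw, fasting_state)
from .preprocess import ClampTimeSeries, SubjectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig", "sample_parameters", "simulate_clamp_with_controller",
    "simulate_ogtt", "add_noise", "generate_cohort", "Cohort",
    "ClampSimResult", "OGTTSimResult",
]

# log10 centers of the physiologic parameter anchors (internal units);
# chosen once from fasting/steady-state balances at typical T2DM values
# (G0 ~ 7.5 mmol/L, I0 ~ 50 pmol/L, Gg0 ~ 150 ng/L, CP0 ~ 0.5 nmol/L,
# clamp insulin ~ 600 pmol/L at 1.25 mU/kg/min).
_GIG_CENTERS = {
    "k1": 0.07,      # basal glucose production, mmol/L/min
    "k2": 5e-3,      # insulin-independent removal, 1/min
    "k3": 0.05,      # glucose sensing of Y, 1/min
    "k4": 2.2e-4,    # insulin sensitivity, per pmol/L per min
    "k5": 2.5e-3,    # pre-hepatic secretion gain, nmol/L per mmol/L per min
    "k6": 4.0,       # secretion threshold, mmol/L
    "k7": 0.15,      # insulin clearance, 1/min (t1/2 ~ 4.6 min)
    "kGN": 3.5e-4,   # glucagon sensitivity, mmol/L/min per ng/L
    "kGgS": 900.0,   # glucagon secretion gain
    "kGgC": 0.12,    # glucagon clearance, 1/min
    "kratio": 0.5,   # posthepatic insulin / C-peptide molar ratio
    "kCPC": 0.025,   # C-peptide clearance, 1/min
}

_WIDE = 0.35   # dex half-width for the dispersion-carrying block
# Per-parameter overrides of the wide width: k4 sits near the lower
# estimation bound; within the glucagon block most interindividual
# variance is carried by the secretion/clearance axis (kGgS, kGgC),
# with a tighter spread on sensitivity (kGN), mirroring the dominant
# role of secretion-to-clearance balance in circulating glucagon.
_WIDE_BY_NAME = {"k4": 0.30, "kGN": 0.15, "kGgS": 0.45, "kGgC": 0.30}
_NARROW = 0.06
_FIXEDISH = {"k1": 0.10, "k2": 0.15, "k3": 0.15, "k6": 0.04,
             "kratio": 0.08, "kCPC": 0.10}

_INSULIN_BLOCK = ("k4", "k5", "k7")
_GLUCAGON_BLOCK = ("kGN", "kGgS", "kGgC")

K8_RANGES = {"control": (1e-5, 1e-4), "sglt2i": (5e-3, 2e-2)}


def default_log_ranges(group: str, model_id: str = "GIG") -> dict:
    """Per-parameter (lo, hi) log10 sampling ranges for a study arm."""
    if group not in ("control", "sglt2i"):
        raise ConfigError(f"unknown group {group!r}")
    ranges = {}
    names = GIGParameters.FREE_NAMES if model_id.upper() == "GIG" \
        else GIParameters.FREE_NAMES
    for name in names:
        center = _GIG_CENTERS[name]
        if model_id.upper() == "GI" and name == "k5":
            # GI secretion feeds insulin directly (pmol/L units)
            center = units.PMOL_PER_NMOL * _GIG_CENTERS["kratio"] * center
        c = np.log10(center)
        if name in _FIXEDISH:
            w = _FIXEDISH[name]
        elif name in _INSULIN_BLOCK:
            w = _WIDE_BY_NAME.get(name, _WIDE) if group == "control" \
                else _NARROW
        elif name in _GLUCAGON_BLOCK:
            w = _WIDE_BY_NAME.get(name, _WIDE) if group == "sglt2i" \
                else _NARROW
        else:
            w = _NARROW
        ranges[name] = (c - w, c + w)
    lo8, hi8 = K8_RANGES[group]
    ranges["k8"] = (np.log10(lo8), np.log10(hi8))
    return ranges


@dataclass
class SyntheticConfig:
    """Study-condition settings for one synthetic cohort."""

    n_subjects: int = 20
    seed: int = 0
    group: str = "control"                   # "control" | "sglt2i"
    model_id: str = "GIG"                    # "GIG" | "GI"
    param_log_ranges: dict | None = None     # defaults per group/model
    noise_cvs: dict = field(default_factory=lambda: {
        "Gc": 0.02, "I": 0.07, "Gg": 0.10, "CP": 0.07})
    # clamp protocol
    clamp_duration: int = 120
    insulin_infusion: float = 1.25           # mU/kg/min, constant
    target_glucose: float = 5.2              # mmol/L
    steady_window: int = 30                  # final window for fg/Gss/Iss
    # discrete PI controller (glucose infusion, mg/kg/min)
    controller_kp: float = 3.0
    controller_ki: float = 0.4
    controller_interval: int = 5
    f1_max: float = 30.0
    hormone_times: tuple = (0, 5, 10, 15, 20, 30, 45, 60, 75, 90, 105, 120)
    # OGTT
    ogtt_dose_g: float = 75.0
    ogtt_appearance_fraction: float = 0.12
    ogtt_gamma_shape: float = 2.0
    ogtt_gamma_scale: float = 20.0           # minutes
    ogtt_duration: int = 180
    ogtt_times: tuple = (0, 30, 60, 90, 120)
    body_weight_range: tuple = (55.0, 85.0)
    integrator: str = "lsoda"                # "lsoda" | "rk4"
    # optional reduced-model structure imposed on the sampled parameters
    # (used by the variant-selection studies); None = full GIG
    variant: object | None = None

    def __post_init__(self):
        if self.param_log_ranges is None:
            self.param_log_ranges = default_log_ranges(self.group,
                                                       self.model_id)
        self._validate_ranges()
        for var, cv in self.noise_cvs.items():
            if cv < 0:
                raise ConfigError(f"noise CV for {var} must be >= 0")

    def _validate_ranges(self):
        lo_b, hi_b = (GIG_BOUNDS_LOG10 if self.model_id.upper() == "GIG"
                      else GI_BOUNDS_LOG10)
        for name, (lo, hi) in self.param_log_ranges.items():
            if lo > hi:
                raise ConfigError(f"{name}: lo > hi")
            if name == "kratio":
                lo_b_, hi_b_ = KRATIO_BOUNDS_LOG10
            elif name == "k8":
                continue  # fixed from data, not an estimated parameter
            else:
                lo_b_, hi_b_ = lo_b, hi_b
            if lo < lo_b_ - 1e-9 or hi > hi_b_ + 1e-9:
                raise ConfigError(
                    f"{name}: sampling range [{lo}, {hi}] outside the "
                    f"estimation bounds [{lo_b_}, {hi_b_}]")


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), index]))


def _draw_subject(config: SyntheticConfig, index: int):
    """Draw one subject's parameters and body weight (child stream)."""
    rng = _subject_rng(config.seed, index)
    draws = {}
    for name, (lo, hi) in config.param_log_ranges.items():
        draws[name] = float(10.0 ** rng.uniform(lo, hi))
    w_lo, w_hi = config.body_weight_range
    weight = float(rng.uniform(w_lo, w_hi))
    if config.model_id.upper() == "GI":
        params = GIParameters(**{k: draws[k]
                                 for k in GIParameters.FREE_NAMES},
                              k8=draws["k8"])
    else:
        v = config.variant
        if v is not None:
            if not v.glucagon_action:
                draws["kGN"] = 0.0
            if not v.threshold:
                draws["k6"] = 0.0
            if v.cpc_shared:
                draws["kCPC"] = draws["k7"]
        params = GIGParameters(**{k: draws[k]
                                  for k in GIGParameters.FREE_NAMES},
                               k8=draws["k8"])
    return params, weight, rng


def sample_parameters(config: SyntheticConfig, n: int | None = None):
    """True parameter sets (and body weights) for subjects 0..n-1."""
    n = config.n_subjects if n is None else n
    out = []
    for i in range(n):
        params, weight, _ = _draw_subject(config, i)
        out.append((params, weight))
    return out


# ---------------------------------------------------------------------------
# forward simulation


#: insulin scale used to pick RK4 substep counts in "rk4" generation
#: mode; ~2x a typical clamp steady-state insulin, so that generation
#: and estimation (which uses 2x the observed maximum) land in the
#: same substep bucket for physiologic parameters
RK4_RATE_REF_I = 1500.0


def _integrate_block(params, model_id, y0, t0, t1, g_in, i_in,
                     integrator, suppression="I"):
    """Integrate one constant-infusion block, returning per-min states."""
    n_min = int(round(t1 - t0))
    if integrator == "rk4":
        theta = np.array([[getattr(params, k) for k in
                           (fastsim.GI_ORDER if model_id == "GI"
                            else fastsim.GIG_ORDER)]])
        g = np.full(n_min, g_in)
        s = np.full(n_min, i_in)
        if model_id == "GI":
            res = fastsim.integrate_gi_batch(theta, g, s, y0, n_min,
                                             RK4_RATE_REF_I)
        else:
            res = fastsim.integrate_gig_batch(
                theta, g, s, y0, n_min, RK4_RATE_REF_I, suppression,
                params.insulin_floor, params.glucose_floor)
        return np.stack([r[0] for r in res])  # (n_states, n_min+1)
    if model_id == "GI":
        def fun(t, y):
            return _gi_rhs_raw(y, t, params, g_in, i_in)
    else:
        def fun(t, y):
            return _gig_rhs_raw(y, t, params, g_in, i_in, suppression)
    sol = solve_ivp(fun, (t0, t1), y0, method="LSODA",
                    t_eval=np.arange(t0, t1 + 0.5), rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise DomainError(f"clamp block integration failed: {sol.message}")
    return sol.y


@dataclass
class ClampSimResult:
    """Noiseless clamp trajectory plus realized steady-state observables."""

    t: np.ndarray
    states: dict                 # var -> per-min array
    f1: np.ndarray               # mg/kg/min, per-min grid
    f2: np.ndarray
    fg: float                    # mean f1 over the steady window
    Gss: float
    Iss: float
    urinary_glucose_mg: float
    ok: bool
    y0: np.ndarray


def simulate_clamp_with_controller(params, body_weight: float,
                                   config: SyntheticConfig,
                                   model_id: str | None = None,
                                   suppression: str = "I") -> ClampSimResult:
    """Closed-loop clamp: fixed insulin infusion, PI-controlled glucose.

    The controller reads blood glucose at each update instant (every
    ``controller_interval`` min), and sets the glucose infusion for the
    next block by a discrete proportional-integral rule toward the
    target, with conditional anti-windup at the actuator limits.
    """
    model_id = (model_id or config.model_id).upper()
    bv = units.blood_volume_dl(body_weight)
    bv_norm = bv / body_weight
    T = config.clamp_duration
    dt_c = config.controller_interval
    if T % dt_c:
        raise ConfigError("clamp duration must be a multiple of the "
                          "controller interval")

    y0 = fasting_state(params, model_id, suppression)
    i_in = units.insulin_infusion_to_flux(config.insulin_infusion, bv_norm)

    n_states = 3 if model_id == "GI" else 5
    traj = np.empty((n_states, T + 1))
    traj[:, 0] = y0
    f1 = np.zeros(T + 1)

    f1_val, integ = 0.0, 0.0
    y = y0.copy()
    for k in range(T // dt_c):
        t0, t1 = k * dt_c, (k + 1) * dt_c
        g_in = units.glucose_infusion_to_flux(f1_val, bv_norm)
        block = _integrate_block(params, model_id, y, t0, t1, g_in, i_in,
                                 config.integrator, suppression)
        traj[:, t0 + 1:t1 + 1] = block[:, 1:]
        f1[t0:t1] = f1_val
        y = block[:, -1]

        err = config.target_glucose - y[0]
        integ_new = integ + err * dt_c
        u_raw = config.controller_kp * err + config.controller_ki * integ_new
        if 0.0 <= u_raw <= config.f1_max:
            f1_val, integ = u_raw, integ_new
        else:
            f1_val = float(np.clip(u_raw, 0.0, config.f1_max))
    f1[T] = f1_val

    t = np.arange(T + 1, dtype=float)
    names = ("Gc", "Y", "I") if model_id == "GI" else \
        ("Gc", "Y", "I", "Gg", "CP")
    states = {n: traj[i] for i, n in enumerate(names)}

    win = t >= T - config.steady_window
    gc_win = states["Gc"][win]
    ok = bool(np.max(np.abs(gc_win - config.target_glucose))
              / config.target_glucose < 0.05)
    gc_mgdl = units.glucose_mmoll_to_mgdl(states["Gc"])
    urinary = float(np.trapezoid(params.k8 * gc_mgdl * bv, t))

    return ClampSimResult(
        t=t, states=states, f1=f1,
        f2=np.full(T + 1, config.insulin_infusion),
        fg=float(f1[win].mean()), Gss=float(gc_win.mean()),
        Iss=float(states["I"][win].mean()),
        urinary_glucose_mg=urinary, ok=ok, y0=y0)


@dataclass
class OGTTSimResult:
    t: np.ndarray
    states: dict
    appearance: np.ndarray       # mg/kg/min on the 1-min grid
    pg120: float


def simulate_ogtt(params, body_weight: float, config: SyntheticConfig,
                  model_id: str | None = None,
                  suppression: str = "I") -> OGTTSimResult:
    """Oral glucose tolerance test from the fasting equilibrium.

    The oral load appears in blood as a gamma-shaped flux integrating
    to ``dose x appearance_fraction`` over the test; the fraction lumps
    incomplete absorption and first-pass hepatic uptake, which the
    clamp-oriented model does not resolve.
    """
    model_id = (model_id or config.model_id).upper()
    bv = units.blood_volume_dl(body_weight)
    bv_norm = bv / body_weight
    T = config.ogtt_duration
    t = np.arange(T + 1, dtype=float)

    total_mg_kg = config.ogtt_dose_g * 1e3 * config.ogtt_appearance_fraction \
        / body_weight
    pdf = sps.gamma.pdf(t + 0.5, a=config.ogtt_gamma_shape,
                        scale=config.ogtt_gamma_scale)
    appearance = total_mg_kg * pdf  # mg/kg/min, piecewise constant per min

    y0 = fasting_state(params, model_id, suppression)
    g_flux = units.glucose_infusion_to_flux(appearance, bv_norm)

    if model_id == "GI":
        def fun(tt, y):
            return _gi_rhs_raw(y, tt, params,
                               g_flux[min(int(tt), T)], 0.0)
    else:
        def fun(tt, y):
            return _gig_rhs_raw(y, tt, params,
                                g_flux[min(int(tt), T)], 0.0, suppression)
    sol = solve_ivp(fun, (0.0, float(T)), y0, method="LSODA", t_eval=t,
                    rtol=1e-8, atol=1e-10, max_step=1.0)
    if not sol.success:
        raise DomainError(f"OGTT integration failed: {sol.message}")
    names = ("Gc", "Y", "I") if model_id == "GI" else \
        ("Gc", "Y", "I", "Gg", "CP")
    states = {n: sol.y[i] for i, n in enumerate(names)}
    return OGTTSimResult(t=t, states=states, appearance=appearance,
                         pg120=float(states["Gc"][120]))


def add_noise(values: np.ndarray, cv: float,
              rng: np.random.Generator) -> np.ndarray:
    """Mean-preserving multiplicative lognormal noise at the given CV."""
    values = np.asarray(values, dtype=float)
    if cv < 0:
        raise ConfigError("CV must be >= 0")
    if cv == 0:
        return values.copy()
    sigma = np.sqrt(np.log1p(cv * cv))
    z = rng.standard_normal(values.shape)
    return values * np.exp(sigma * z - 0.5 * sigma * sigma)


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class Cohort:
    """Synthetic cohort: records + series + ground-truth sidecar."""

    config: SyntheticConfig
    records: list                       # SubjectRecord, accepted subjects
    series: dict                        # subject_id -> ClampTimeSeries
    ground_truth: pd.DataFrame
    n_excluded: int = 0

    def record_map(self) -> dict:
        return {r.subject_id: r for r in self.records}


def _truth_row(sid, params, weight, clamp: ClampSimResult,
               ogtt: OGTTSimResult, model_id: str) -> dict:
    row = {"subject_id": sid, "body_weight": weight}
    row.update({f"true_{k}": v for k, v in params.as_dict().items()})
    row["true_DI_cle"] = di_cle(params.k4, params.k5, params.k7)
    if model_id == "GIG":
        for e in (1, 2, 3):
            row[f"true_PI_cle_exp{e}"] = pi_cle_numeric(
                params.kGN, params.kGgS, params.kGgC, e)
    g0 = clamp.y0[0]
    row.update(G0_true=g0, I0_true=clamp.y0[2],
               Gss_true=clamp.Gss, Iss_true=clamp.Iss, fg_true=clamp.fg,
               urinary_glucose_mg=clamp.urinary_glucose_mg,
               PG120_true=ogtt.pg120)
    if model_id == "GIG":
        row["Gg0_true"] = clamp.y0[3]
        try:
            pi, ggsen, ggsec = pi_cle_analytic(clamp.y0[3], g0, clamp.fg,
                                               clamp.Gss, clamp.Iss)
            row.update(PI_cle_analytic_true=pi, Ggsen_true=ggsen,
                       Ggsec_cle_true=ggsec)
        except DomainError:
            pass
    return row


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """End-to-end cohort generation in the preprocess input formats.

    Subjects whose clamp controller fails the steady-glycemia check are
    excluded (with a log entry) and replaced by further draws from the
    subject stream, so the returned cohort has ``n_subjects`` members.
    """
    model_id = config.model_id.upper()
    suppression = config.variant.suppression if config.variant is not None \
        else "I"
    records, series, truths = [], {}, []
    n_excluded = 0
    index = 0
    max_draws = 20 * config.n_subjects + 50

    while len(records) < config.n_subjects and index < max_draws:
        params, weight, rng = _draw_subject(config, index)
        sid = f"{config.group}_{index:04d}"
        index += 1
        try:
            clamp = simulate_clamp_with_controller(params, weight, config,
                                                   model_id, suppression)
        except DomainError as exc:
            logger.info("subject %s excluded: %s", sid, exc)
            n_excluded += 1
            continue
        if not clamp.ok:
            logger.info("subject %s excluded: controller failed to hold "
                        "the glycemic target", sid)
            n_excluded += 1
            continue
        ogtt = simulate_ogtt(params, weight, config, model_id, suppression)

        cv = config.noise_cvs
        gc_noisy = add_noise(clamp.states["Gc"], cv["Gc"], rng)
        hrm_t = np.asarray(config.hormone_times, dtype=float)
        hrm_idx = hrm_t.astype(int)
        samples = {"Gc": (clamp.t, gc_noisy)}
        hormone_vars = ["I"] if model_id == "GI" else ["I", "Gg", "CP"]
        noisy_h = {}
        for var in hormone_vars:
            noisy_h[var] = add_noise(clamp.states[var][hrm_idx], cv[var], rng)
            samples[var] = (hrm_t, noisy_h[var])
        ts = ClampTimeSeries(subject_id=sid, samples=samples,
                             f1=clamp.f1, f2=clamp.f2)

        ot = np.asarray(config.ogtt_times, dtype=float)
        oi = ot.astype(int)
        ogtt_g = add_noise(ogtt.states["Gc"][oi], cv["Gc"], rng)
        ogtt_i = add_noise(ogtt.states["I"][oi], cv["I"], rng)

        win = clamp.t >= config.clamp_duration - config.steady_window
        iss_meas = float(np.mean(noisy_h["I"][hrm_t >= config.clamp_duration
                                             - config.steady_window]))
        rec = SubjectRecord(
            subject_id=sid,
            body_weight=weight,
            bv_dl=units.blood_volume_dl(weight),
            urinary_glucose_0_120=clamp.urinary_glucose_mg,
            G0=float(gc_noisy[0]),
            I0=float(noisy_h["I"][0]),
            Gg0=float(noisy_h["Gg"][0]) if "Gg" in noisy_h else float("nan"),
            Gss=float(gc_noisy[win].mean()),
            Iss=iss_meas,
            fg=clamp.fg,
            PG120=float(ogtt_g[oi == 120][0]) if 120 in oi else float("nan"),
            group=config.group,
            CP0=float(noisy_h["CP"][0]) if "CP" in noisy_h else float("nan"),
            ogtt_t=ot, ogtt_glucose=ogtt_g, ogtt_insulin=ogtt_i,
        )
        records.append(rec)
        series[sid] = ts
        truths.append(_truth_row(sid, params, weight, clamp, ogtt, model_id))

    if len(records) < config.n_subjects:
        raise ConfigError(
            f"could only generate {len(records)} of {config.n_subjects} "
            "subjects; controller or equilibrium failures dominate")
    return Cohort(config=config, records=records, series=series,
                  ground_truth=pd.DataFrame(truths), n_excluded=n_excluded)
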