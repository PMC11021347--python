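"""Per-subject parameter estimation: weighted RSS objectives, global
meta-evolutionary programming, and local least-squares refinement.

The fit minimizes a count-weighted residual sum of squares between the
normalized measured time courses and the normalized simulation.  For
the GI model::

    RSS_GI = nI/(nGc+nI) * sum (Gc - Gc_sim)^2
           + nGc/(nGc+nI) * sum (I - I_sim)^2

and for the GIG model each of the four variables is weighted by
``(N - n_own) / N`` with ``N = nGc + nI + nGg + nCP`` (the four weights
sum to 3), so sparsely sampled hormones are not drowned out by the
quasi-continuous glucose trace.

Both the measured and the simulated glucose pass through the same
trailing 5-min window average, and simulated values are normalized by
the *observed* maxima so that the objective is a fixed function of the
parameters.

The global stage is self-adaptive evolutionary programming in log10
parameter space (each individual carries per-coordinate mutation
scales, themselves mutated -- the "meta" level), with (mu + mu)
survivor selection by stochastic q-tournament.  The local stage is
bound-constrained least squares on the stacked weighted residual
vector, whose squared norm equals the RSS above; refinement never
returns a worse point than its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import fastsim, units
from .errors import AlignmentError, DomainError
from .model_core import (GI_BOUNDS_LOG10, GIG_BOUNDS_LOG10,
                         KRATIO_BOUNDS_LOG10, GIParameters, GIGParameters)
from .model_selection import ModelVariant, full_gig_variant
from .preprocess import (ClampTimeSeries, SubjectRecord, WINDOW_MIN,
                         k8_from_series, normalize_series)

__all__ = [
    "rss_gi", "rss_gig", "FitConfig", "FitResult", "ClampObjective",
    "meta_ep", "MetaEPResult", "local_refine", "fit_subject",
    "DESK_BUDGET", "FULL_BUDGET",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# objective functions


def _check_aligned(sim, obs, name):
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape[-1] != obs.shape[-1]:
        raise AlignmentError(
            f"{name}: simulated and observed series are misaligned "
            f"({sim.shape[-1]} vs {obs.shape[-1]} points)")
    return sim, obs


def rss_gi(sim_gc, obs_gc, sim_i, obs_i, n_gc: int | None = None,
           n_i: int | None = None):
    """Count-weighted GI residual sum of squares (batch-aware).

    Simulated arrays may carry a leading batch axis; the observed
    series are 1-D.  Weights are ``nI/(nGc+nI)`` for glucose and
    ``nGc/(nGc+nI)`` for insulin and sum to one.
    """
    sim_gc, obs_gc = _check_aligned(sim_gc, obs_gc, "Gc")
    sim_i, obs_i = _check_aligned(sim_i, obs_i, "I")
    n_gc = len(obs_gc) if n_gc is None else n_gc
    n_i = len(obs_i) if n_i is None else n_i
    tot = n_gc + n_i
    return (n_i / tot) * np.sum((obs_gc - sim_gc) ** 2, axis=-1) \
        + (n_gc / tot) * np.sum((obs_i - sim_i) ** 2, axis=-1)


def rss_gig(sim_gc, obs_gc, sim_i, obs_i, sim_gg, obs_gg, sim_cp, obs_cp,
            n_gc=None, n_i=None, n_gg=None, n_cp=None):
    """Count-weighted GIG residual sum of squares (batch-aware).

    Each variable's squared-error sum is weighted by
    ``(N - n_own) / N``; the four weights sum to 3.
    """
    pairs = [(_check_aligned(sim_gc, obs_gc, "Gc")),
             (_check_aligned(sim_i, obs_i, "I")),
             (_check_aligned(sim_gg, obs_gg, "Gg")),
             (_check_aligned(sim_cp, obs_cp, "CP"))]
    counts = [n if n is not None else len(obs)
              for (sim, obs), n in zip(pairs, (n_gc, n_i, n_gg, n_cp))]
    total = sum(counts)
    out = 0.0
    for (sim, obs), n_own in zip(pairs, counts):
        w = (total - n_own) / total
        out = out + w * np.sum((obs - sim) ** 2, axis=-1)
    return out


def _gig_weights(counts: dict) -> dict:
    total = sum(counts[v] for v in ("Gc", "I", "Gg", "CP"))
    return {v: (total - counts[v]) / total for v in ("Gc", "I", "Gg", "CP")}


def _gi_weights(counts: dict) -> dict:
    total = counts["Gc"] + counts["I"]
    return {"Gc": counts["I"] / total, "I": counts["Gc"] / total}


# ---------------------------------------------------------------------------
# fit configuration


@dataclass
class FitConfig:
    """Optimizer budget and numerical knobs for one subject fit."""

    n_parents: int = 40
    n_generations: int = 300
    q: int = 10
    seed: int = 0
    immigrant_fraction: float = 0.1
    refine: bool = True
    n_refine_starts: int = 4      # distinct EP survivors refined locally
    refine_max_nfev: int = 400    # final polish of the best candidate
    warm_starts: bool = True      # steady-state-derived extra starts
    warm_k6_fracs: tuple = (0.3, 0.5, 0.7, 0.85)
    warm_k3: tuple = (0.02, 0.08)
    warm_glucagon_shares: tuple = (0.2, 0.5, 0.8)
    warm_refine_max_nfev: int = 60   # coarse tournament stage
    n_polish: int = 2                # best candidates polished deeply
    # soft fasting-steady-state constraint on the initial glucose
    # derivative (fraction of G0 per minute regarded as tolerable
    # drift); subjects enter the clamp fasted, and without this the
    # first unobserved minutes admit degenerate fast-transient fits
    eq_weight: float = 1.0
    eq_tol: float = 0.02
    # declared run-to-run tolerance for independent-seed fits
    # of the same noisy subject (relative RSS)
    run_to_run_rtol: float = 0.05
    max_substeps: int = 4
    clip_max: float = 1e7


DESK_BUDGET = dict(n_parents=40, n_generations=300)
#: the original full-scale study budget
FULL_BUDGET = dict(n_parents=400, n_generations=4000)


@dataclass
class FitResult:
    """Outcome of one subject x model(-variant) fit."""

    subject_id: str
    model_id: str
    variant_id: str | None
    params: dict
    free_log10: np.ndarray
    free_names: tuple
    rss: float
    counts: dict
    n_points: int
    K: int
    seed: int
    budget: tuple
    converged: bool
    n_evaluations: int

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "model_id": self.model_id,
            "variant_id": self.variant_id,
            "params": {k: float(v) for k, v in self.params.items()},
            "rss": float(self.rss),
            "counts": dict(self.counts),
            "n_points": int(self.n_points),
            "K": int(self.K),
            "seed": int(self.seed),
            "budget": list(self.budget),
            "converged": bool(self.converged),
            "n_evaluations": int(self.n_evaluations),
        }


# ---------------------------------------------------------------------------
# the per-subject objective


class ClampObjective:
    """Weighted-RSS objective over log10 free parameters for one subject.

    Callable on a ``(m, d)`` batch of log10 free-parameter vectors,
    returning ``(m,)`` RSS values; also exposes the stacked weighted
    residual vector used by local refinement.  ``k8`` is fixed from the
    urinary-glucose integral and excluded from the free set; reduced
    GIG variants fix masked parameters to zero or tie them.
    """

    def __init__(self, series: ClampTimeSeries, record: SubjectRecord,
                 model_id: str, variant: ModelVariant | None = None,
                 config: FitConfig | None = None):
        self.config = config or FitConfig()
        self.model_id = model_id.upper()
        if self.model_id == "GIG":
            self.variant = variant or full_gig_variant()
        else:
            self.variant = None
        self.subject_id = series.subject_id

        norm = normalize_series(series, window_glucose=True)
        self.scales = norm.scales
        self.obs = {}
        self.obs_idx = {}
        self.duration = int(round(series.samples["Gc"][0][-1]))
        for var, (t, v) in norm.values.items():
            ti = np.rint(t).astype(int)
            if np.any(np.abs(t - ti) > 1e-6):
                raise AlignmentError(f"{var}: sampling times must sit on the "
                                     "1-min grid")
            self.obs[var] = v
            self.obs_idx[var] = ti
        self.counts = norm.counts()

        self.k8 = record.k8 if np.isfinite(record.k8) else \
            k8_from_series(record, series)
        bv_norm = record.bv_dl / record.body_weight
        self.g_in = units.glucose_infusion_to_flux(series.f1, bv_norm)
        self.i_in = units.insulin_infusion_to_flux(series.f2, bv_norm)

        i_raw_max = self.scales["I"]
        self.rate_ref_I = 2.0 * i_raw_max
        self.insulin_floor = 1e-6 * i_raw_max
        self.glucose_floor = 1e-6 * self.scales["Gc"]

        if self.model_id == "GI":
            cp0 = None
            self.y0 = np.array([record.G0, record.G0, record.I0])
            self.free_names = GIParameters.FREE_NAMES
            lo, hi = GI_BOUNDS_LOG10
            self.lower = np.full(len(self.free_names), lo)
            self.upper = np.full(len(self.free_names), hi)
            self.weights = _gi_weights(self.counts)
            self._order = fastsim.GI_ORDER
        elif self.model_id == "GIG":
            cp0 = record.CP0
            if not np.isfinite(cp0):
                cp_t, cp_v = series.samples["CP"]
                cp0 = cp_v[0]
            self.y0 = np.array([record.G0, record.G0, record.I0,
                                record.Gg0, cp0])
            self.free_names = tuple(self.variant.free_names)
            lo, hi = GIG_BOUNDS_LOG10
            self.lower = np.full(len(self.free_names), lo)
            self.upper = np.full(len(self.free_names), hi)
            if "kratio" in self.free_names:
                j = self.free_names.index("kratio")
                self.lower[j], self.upper[j] = KRATIO_BOUNDS_LOG10
            self.weights = _gig_weights(self.counts)
            self._order = fastsim.GIG_ORDER
        else:
            raise DomainError(f"unknown model_id {model_id!r}")

        self._col = {name: i for i, name in enumerate(self._order)}
        self._var_order = ("Gc", "I") if self.model_id == "GI" else \
            ("Gc", "I", "Gg", "CP")
        self._sqrt_w = {v: np.sqrt(self.weights[v]) for v in self._var_order}

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def _expand(self, L: np.ndarray) -> np.ndarray:
        """Map (m, d) log10 free parameters to full natural-scale theta."""
        L = np.atleast_2d(np.asarray(L, dtype=float))
        m = L.shape[0]
        theta = np.zeros((m, len(self._order)))
        theta[:, self._col["k8"]] = self.k8
        for j, name in enumerate(self.free_names):
            theta[:, self._col[name]] = 10.0 ** L[:, j]
        if self.variant is not None:
            if self.variant.cpc_shared:
                theta[:, self._col["kCPC"]] = theta[:, self._col["k7"]]
            # masked parameters stay at their structural zeros
        return theta

    def simulate_minutes(self, L: np.ndarray) -> dict:
        """Raw per-minute simulated trajectories for a batch of candidates."""
        theta = self._expand(L)
        T = self.duration
        if self.model_id == "GI":
            Gc, Y, I = fastsim.integrate_gi_batch(
                theta, self.g_in, self.i_in, self.y0, T, self.rate_ref_I,
                self.config.max_substeps, self.config.clip_max)
            return {"Gc": Gc, "Y": Y, "I": I}
        Gc, Y, I, Gg, CP = fastsim.integrate_gig_batch(
            theta, self.g_in, self.i_in, self.y0, T, self.rate_ref_I,
            self.variant.suppression, self.insulin_floor, self.glucose_floor,
            self.config.max_substeps, self.config.clip_max)
        return {"Gc": Gc, "Y": Y, "I": I, "Gg": Gg, "CP": CP}

    def predict_normalized(self, L: np.ndarray) -> dict:
        """Normalized simulated values at the observation times.

        The simulated glucose passes through the same trailing window
        average as the measurements before sampling.
        """
        sims = self.simulate_minutes(L)
        out = {}
        for var in self._var_order:
            arr = sims[var]
            if var == "Gc":
                kernel = np.full(WINDOW_MIN, 1.0 / WINDOW_MIN)
                # trailing mean on the minute grid; index j -> minute j+WINDOW
                sm = np.apply_along_axis(
                    lambda r: np.convolve(r, kernel, mode="valid")[1:], -1, arr)
                idx = self.obs_idx[var] - WINDOW_MIN
                out[var] = sm[..., idx] / self.scales[var]
            else:
                out[var] = arr[..., self.obs_idx[var]] / self.scales[var]
        return out

    def _eq_residual(self, L: np.ndarray) -> np.ndarray:
        """Initial glucose-balance drift scaled by the tolerated rate.

        Clamp subjects arrive fasted, i.e. near glycemic steady state,
        so the model's initial dGc/dt should be small; the windowed
        glucose series starts at t = 5 min and cannot itself exclude
        degenerate large-production / large-removal solutions whose
        transients play out in the first unobserved minutes.
        """
        theta = self._expand(L)
        col = self._col
        G0, I0 = self.y0[0], self.y0[2]
        prod = self.g_in[0] + theta[:, col["k1"]]
        if self.model_id == "GIG":
            prod = prod + theta[:, col["kGN"]] * self.y0[3]
        removal = (theta[:, col["k2"]] + theta[:, col["k4"]] * I0
                   + theta[:, col["k8"]]) * G0
        scale = np.sqrt(self.config.eq_weight) / (self.config.eq_tol * G0)
        return (prod - removal) * scale

    def printed_rss(self, L: np.ndarray) -> np.ndarray:
        """The count-weighted RSS exactly as printed (no regularizer)."""
        pred = self.predict_normalized(L)
        if self.model_id == "GI":
            rss = rss_gi(pred["Gc"], self.obs["Gc"], pred["I"], self.obs["I"],
                         self.counts["Gc"], self.counts["I"])
        else:
            rss = rss_gig(pred["Gc"], self.obs["Gc"], pred["I"], self.obs["I"],
                          pred["Gg"], self.obs["Gg"], pred["CP"], self.obs["CP"],
                          self.counts["Gc"], self.counts["I"],
                          self.counts["Gg"], self.counts["CP"])
        return np.atleast_1d(np.asarray(rss, dtype=float))

    def __call__(self, L: np.ndarray) -> np.ndarray:
        """Batch objective: printed RSS plus the steady-state penalty.

        NaN evaluations are mapped to +inf (logged).
        """
        rss = self.printed_rss(L)
        if self.config.eq_weight > 0:
            rss = rss + self._eq_residual(L) ** 2
        bad = ~np.isfinite(rss)
        if np.any(bad):
            logger.debug("%s: %d non-finite objective evaluations mapped to "
                         "+inf", self.subject_id, int(bad.sum()))
            rss[bad] = np.inf
        return rss

    def residuals_batch(self, L: np.ndarray) -> np.ndarray:
        """Stacked weighted residual vectors, (m, n_res); ||r||^2 equals
        the optimized objective (printed RSS + steady-state penalty)."""
        pred = self.predict_normalized(L)
        parts = [self._sqrt_w[v] * (self.obs[v] - pred[v])
                 for v in self._var_order]
        if self.config.eq_weight > 0:
            parts.append(self._eq_residual(L)[..., None])
        return np.concatenate(parts, axis=-1)

    def residuals(self, L: np.ndarray) -> np.ndarray:
        return self.residuals_batch(np.atleast_2d(L))[0]


# ---------------------------------------------------------------------------
# meta-evolutionary programming


@dataclass
class MetaEPResult:
    x: np.ndarray
    fun: float
    n_evaluations: int
    n_nan: int = 0
    population: np.ndarray | None = None   # final survivors, best first
    population_f: np.ndarray | None = None


def meta_ep(objective, lower, upper, n_parents: int, n_generations: int,
            seed=None, q: int = 10, init_sigma_frac: float = 0.2,
            sigma_min: float = 1e-8, immigrant_fraction: float = 0.1,
            vectorized: bool = True) -> MetaEPResult:
    """Self-adaptive evolutionary programming on a box in log10 space.

    Each individual carries per-coordinate mutation scales sigma that
    are themselves log-normally mutated before being applied (the
    "meta" level); survivors of the (mu + mu) union are chosen by a
    stochastic q-tournament (each individual scores wins against q
    random opponents).  A small fraction of each offspring batch is
    replaced by fresh log-uniform draws (random immigrants), which
    keeps small desk-scale populations from collapsing onto one basin
    of the multimodal objective.  The best-ever candidate is tracked
    separately and returned together with the final survivor
    population (useful for multi-start local refinement).  Identical
    seeds give bitwise-identical results.

    ``objective`` is called on an ``(m, d)`` array and must return
    ``(m,)`` values unless ``vectorized=False``.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or np.any(lower >= upper):
        raise DomainError("bounds must satisfy lower < upper elementwise")
    if not np.all(np.isfinite(lower)) or not np.all(np.isfinite(upper)):
        raise DomainError("bounds must be finite in log space")
    if n_parents < 2:
        raise DomainError("need at least 2 parents")
    d = len(lower)
    mu = n_parents
    rng = np.random.default_rng(seed)

    def evaluate(X):
        if vectorized:
            f = np.asarray(objective(X), dtype=float)
        else:
            f = np.array([float(objective(x)) for x in X])
        n_nan = int(np.sum(~np.isfinite(f)))
        if n_nan:
            logger.debug("meta_ep: %d non-finite evaluations -> +inf", n_nan)
        f = np.where(np.isfinite(f), f, np.inf)
        return f, n_nan

    span = upper - lower
    X = rng.uniform(lower, upper, size=(mu, d))
    S = np.full((mu, d), init_sigma_frac) * span
    F, nn = evaluate(X)
    n_eval, n_nan = mu, nn

    ib = int(np.argmin(F))
    best_x, best_f = X[ib].copy(), float(F[ib])

    tau = 1.0 / np.sqrt(2.0 * np.sqrt(d))
    tau_p = 1.0 / np.sqrt(2.0 * d)

    n_imm = int(round(immigrant_fraction * mu))
    for _ in range(n_generations):
        Sp = S * np.exp(tau_p * rng.standard_normal((mu, 1))
                        + tau * rng.standard_normal((mu, d)))
        np.clip(Sp, sigma_min, span, out=Sp)
        Xp = X + Sp * rng.standard_normal((mu, d))
        np.clip(Xp, lower, upper, out=Xp)
        if n_imm:
            Xp[-n_imm:] = rng.uniform(lower, upper, size=(n_imm, d))
            Sp[-n_imm:] = init_sigma_frac * span
        Fp, nn = evaluate(Xp)
        n_eval += mu
        n_nan += nn

        ib = int(np.argmin(Fp))
        if Fp[ib] < best_f:
            best_x, best_f = Xp[ib].copy(), float(Fp[ib])

        allX = np.vstack([X, Xp])
        allS = np.vstack([S, Sp])
        allF = np.concatenate([F, Fp])
        opp = rng.integers(0, 2 * mu, size=(2 * mu, q))
        wins = np.sum(allF[:, None] <= allF[opp], axis=1)
        order = np.lexsort((allF, -wins))[:mu]
        X, S, F = allX[order], allS[order], allF[order]

    order = np.argsort(F, kind="stable")
    return MetaEPResult(x=best_x, fun=best_f, n_evaluations=n_eval,
                        n_nan=n_nan, population=X[order],
                        population_f=F[order])


# ---------------------------------------------------------------------------
# local refinement


def local_refine(x0, residual_fn, lower, upper, residual_batch_fn=None,
                 max_nfev: int = 120, fd_step: float = 1e-6):
    """Bound-constrained least squares from a candidate; never worsens.

    The jacobian is built by forward differences; when a batched
    residual function is available all columns are evaluated in a
    single vectorized call.  Returns ``(x, rss, converged)``; on any
    failure or non-improvement the input candidate is returned.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    x0 = np.clip(np.asarray(x0, dtype=float), lower + 1e-12, upper - 1e-12)
    r0 = np.asarray(residual_fn(x0), dtype=float)
    rss0 = float(np.dot(r0, r0))
    if not np.isfinite(rss0):
        return x0, np.inf, False

    d = len(x0)

    if residual_batch_fn is not None:
        def jac(x):
            h = fd_step * np.maximum(1.0, np.abs(x))
            # step inward at the upper bound
            h = np.where(x + h > upper, -h, h)
            batch = np.vstack([x, x + np.diag(h)])
            R = np.asarray(residual_batch_fn(batch), dtype=float)
            return (R[1:] - R[0]).T / h
    else:
        jac = "2-point"

    try:
        res = least_squares(residual_fn, x0, jac=jac, bounds=(lower, upper),
                            method="trf", max_nfev=max_nfev)
    except Exception as exc:  # noqa: BLE001 - refinement must not crash a fit
        logger.warning("local refinement failed (%s); keeping candidate", exc)
        return x0, rss0, False

    rss1 = float(2.0 * res.cost)
    if np.isfinite(rss1) and rss1 <= rss0:
        return res.x, rss1, bool(res.status > 0)
    return x0, rss0, False


# ---------------------------------------------------------------------------
# composition


def _steady_state_warm_starts(obj: ClampObjective, record: SubjectRecord,
                              series: ClampTimeSeries,
                              config: FitConfig) -> list:
    """Initial candidates from the subject's own steady-state balances.

    Fasting and clamp steady states pin down first guesses for the
    clearances and sensitivities (``k7 ~ insulin flux / Iss``,
    ``k4 ~ (glucose flux / Gss - k2 - k8) / Iss``, fasting production
    balance for ``k1``...); the poorly determined secretion threshold
    and sensing rate are gridded.  These give the local stage a
    handful of structurally informed basins to compete against the
    global-search candidates at desk-scale budgets.
    """
    rec = record
    needed = (rec.G0, rec.I0, rec.Iss, rec.Gss, rec.fg)
    if not all(np.isfinite(v) and v > 0 for v in needed):
        return []
    bvn = rec.bv_dl / rec.body_weight
    i_flux = units.insulin_infusion_to_flux(float(np.mean(series.f2[-31:])),
                                            bvn)
    g_flux = units.glucose_infusion_to_flux(rec.fg, bvn)
    if i_flux <= 0 or g_flux <= 0:
        return []
    k7 = i_flux / rec.Iss
    k2 = 5e-3
    k8 = obj.k8
    k4 = max(g_flux / rec.Gss - k2 - k8, 1e-4) / rec.Iss
    removal0 = k2 + k4 * rec.I0 + k8

    gig = obj.model_id == "GIG"
    cp0 = obj.y0[4] if gig else float("nan")
    gg0 = rec.Gg0 if gig else float("nan")
    if gig and not (np.isfinite(cp0) and cp0 > 0
                    and np.isfinite(gg0) and gg0 > 0):
        return []
    has_k6 = "k6" in obj.free_names
    fracs = config.warm_k6_fracs if has_k6 else (0.0,)

    kggc = 0.1
    if gig:
        # glucagon clearance from the observed early decay toward the
        # insulin-suppressed plateau
        gg_t, gg_v = series.samples["Gg"]
        plateau = float(np.mean(gg_v[gg_t >= 60])) if np.any(gg_t >= 60) \
            else 0.0
        early = gg_v[:3] - plateau
        if len(early) >= 2 and early[0] > 0 and early[1] > 0 \
                and early[1] < early[0]:
            kggc = float(np.log(early[0] / early[1])
                         / (gg_t[1] - gg_t[0]))
        kggc = float(np.clip(kggc, 0.02, 1.0))

    shares = config.warm_glucagon_shares \
        if gig and "kGN" in obj.free_names else (0.0,)

    starts = []
    for frac in fracs:
        x0 = rec.G0 * (1.0 - frac)
        if x0 <= 0:
            continue
        for k3 in config.warm_k3:
            for share in shares:
                p = {"k2": k2, "k3": k3, "k4": k4, "k7": k7}
                if has_k6:
                    p["k6"] = frac * rec.G0
                if gig:
                    kcpc = 0.03
                    p["kCPC"] = kcpc
                    p["k5"] = kcpc * cp0 / x0
                    p["kratio"] = min(max(
                        rec.I0 * k7 / (units.PMOL_PER_NMOL * p["k5"] * x0),
                        1e-9), 1.0 - 1e-9)
                    p["kGgC"] = kggc
                    supp = obj.variant.suppression
                    denom = {"I": rec.I0, "Gc": rec.G0,
                             "both": rec.I0 * rec.G0}[supp]
                    p["kGgS"] = gg0 * kggc * denom
                    if "kGN" in obj.free_names:
                        p["kGN"] = share * removal0 * rec.G0 / gg0
                        p["k1"] = (1.0 - share) * removal0 * rec.G0
                    else:
                        p["k1"] = removal0 * rec.G0
                else:
                    p["k5"] = k7 * rec.I0 / x0
                    p["k1"] = removal0 * rec.G0
                vec = np.array([np.log10(max(p[name], 1e-300))
                                for name in obj.free_names])
                starts.append(np.clip(vec, obj.lower + 1e-9,
                                      obj.upper - 1e-9))
    return starts


def fit_subject(series: ClampTimeSeries, record: SubjectRecord,
                model_id: str, variant: ModelVariant | None = None,
                config: FitConfig | None = None) -> FitResult:
    """Global + local fit of one subject; reproducible given the config."""
    config = config or FitConfig()
    obj = ClampObjective(series, record, model_id, variant, config)
    ep = meta_ep(obj, obj.lower, obj.upper, config.n_parents,
                 config.n_generations, seed=config.seed, q=config.q,
                 immigrant_fraction=config.immigrant_fraction)
    x, rss, converged = ep.x, ep.fun, False
    n_eval = ep.n_evaluations
    if config.refine and np.isfinite(ep.fun):
        # refine from the best-ever point, from distinct finalists of
        # the global stage, and from steady-state warm starts; the
        # cheap local stage decides between the basins
        starts = [ep.x]
        if ep.population is not None:
            seen = {tuple(np.round(ep.x, 1))}
            for cand, f in zip(ep.population, ep.population_f):
                if len(starts) >= config.n_refine_starts:
                    break
                key = tuple(np.round(cand, 1))
                if key not in seen and np.isfinite(f):
                    seen.add(key)
                    starts.append(cand)
        if config.warm_starts:
            starts.extend(_steady_state_warm_starts(obj, record, series,
                                                    config))
        # coarse refinement tournament over all starts ...
        coarse = []
        for x0 in starts:
            xr, rssr, convr = local_refine(
                x0, obj.residuals, obj.lower, obj.upper,
                residual_batch_fn=obj.residuals_batch,
                max_nfev=config.warm_refine_max_nfev)
            coarse.append((rssr, xr, convr))
        coarse.sort(key=lambda c: c[0])
        # ... then deep polish of the leaders
        for rss0, x0, _ in coarse[:config.n_polish]:
            xr, rssr, convr = local_refine(
                x0, obj.residuals, obj.lower, obj.upper,
                residual_batch_fn=obj.residuals_batch,
                max_nfev=config.refine_max_nfev)
            if rssr < rss:
                x, rss, converged = xr, rssr, convr
        for rss0, x0, conv0 in coarse:
            if rss0 < rss:
                x, rss, converged = x0, rss0, conv0

    theta = obj._expand(x)[0]
    params = {name: float(theta[obj._col[name]]) for name in obj._order}
    rss = float(obj.printed_rss(np.atleast_2d(x))[0])  # report sans penalty
    return FitResult(
        subject_id=series.subject_id,
        model_id=obj.model_id,
        variant_id=None if obj.variant is None else obj.variant.variant_id,
        params=params,
        free_log10=np.asarray(x, dtype=float),
        free_names=tuple(obj.free_names),
        rss=float(rss),
        counts=dict(obj.counts),
        n_points=int(sum(obj.counts.values())),
        K=len(obj.free_names),
        seed=config.seed,
        budget=(config.n_parents, config.n_generations),
        converged=converged,
        n_evaluations=n_eval,
    )
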