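"""Composite endocrine indices derived from fits and clamp/OGTT scalars.

The two headline composites mirror each other across the insulin and
glucagon axes:

* disposition index over clearance, ``DI/cle = k4 k5 / k7^2`` --
  insulin sensitivity x secretion / clearance^2, the glucose-handling
  capacity of insulin;
* production index over clearance, ``PI/cle`` -- glucagon sensitivity
  x (secretion / clearance); numerically ``kGN kGgS / kGgC^p`` with
  exponent p in {1, 2, 3} (p = 2 is the primary definition), and
  analytically from fasting/steady-state clamp observables:

      PI/cle = (Gg0 * G0 * fg) / (Gss * Iss)

  decomposed as ``Ggsec/cle = Gg0 * Iss`` (no glycemia-related index in
  its numerator) and ``Ggsen = G0 * fg / (Gss * Iss^2)`` so that the
  product identity holds exactly.

Also provided: the clamp insulin-sensitivity index ISI, tissue glucose
uptake rate TGUR, OGTT indices (PG120, insulinogenic, Matsuda), and the
first-order insulin half-life ln 2 / k7.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError, InsufficientDataError
from . import units

__all__ = [
    "di_cle", "pi_cle_numeric", "pi_cle_analytic", "isi", "tgur",
    "ogtt_indices", "OGTTIndices", "insulin_half_life", "MetricSet",
    "isi_simulated", "compute_metric_set",
]


def di_cle(k4: float, k5: float, k7: float) -> float:
    """Disposition index over clearance, ``k4 k5 / k7^2``."""
    if k7 <= 0:
        raise DomainError("k7 must be positive")
    return k4 * k5 / k7 ** 2


def pi_cle_numeric(kGN: float, kGgS: float, kGgC: float,
                   exponent: int = 2) -> float:
    """Numerically estimated PI/cle, ``kGN kGgS / kGgC^exponent``."""
    if exponent not in (1, 2, 3):
        raise ConfigError("exponent must be 1, 2 or 3")
    if kGgC <= 0:
        raise DomainError("kGgC must be positive")
    return kGN * kGgS / kGgC ** exponent


def pi_cle_analytic(Gg0: float, G0: float, fg: float,
                    Gss: float, Iss: float):
    """Analytic PI/cle from fasting/steady-state clamp observables.

    Returns ``(PI/cle, Ggsen, Ggsec_cle)`` with
    ``PI/cle = Gg0 G0 fg / (Gss Iss)``, ``Ggsec_cle = Gg0 Iss`` and
    ``Ggsen = G0 fg / (Gss Iss^2)``; the product identity
    ``Ggsen * Ggsec_cle = PI/cle`` holds to machine precision.
    """
    vals = dict(Gg0=Gg0, G0=G0, fg=fg, Gss=Gss, Iss=Iss)
    for name, v in vals.items():
        if not (v > 0):
            raise DomainError(f"{name} must be positive, got {v}")
    ggsec_cle = Gg0 * Iss
    ggsen = G0 * fg / (Gss * Iss ** 2)
    return ggsen * ggsec_cle, ggsen, ggsec_cle


def isi(uptake_rate: float, g_end_mgdl: float, i_end_microu_ml: float) -> float:
    """Insulin sensitivity index from end-of-clamp values.

    ``ISI = 100 * uptake / (G_end [mg/dL] / I_end [uU/mL])``.  The
    uptake rate is TGUR (infusion minus urinary loss) for subjects on
    an SGLT2 inhibitor and the plain glucose infusion rate otherwise;
    both in mg kg^-1 min^-1.
    """
    for name, v in (("uptake_rate", uptake_rate), ("g_end", g_end_mgdl),
                    ("i_end", i_end_microu_ml)):
        if not (v > 0):
            raise DomainError(f"{name} must be positive, got {v}")
    return 100.0 * uptake_rate / (g_end_mgdl / i_end_microu_ml)


def tgur(gir: float, uger: float) -> float:
    """Tissue glucose uptake rate, ``GIR - UGER`` (mg kg^-1 min^-1)."""
    if gir < 0 or uger < 0:
        raise DomainError("rates must be non-negative")
    if uger > gir:
        warnings.warn("UGER exceeds GIR; TGUR is negative", RuntimeWarning)
    return gir - uger


@dataclass
class OGTTIndices:
    pg120_mgdl: float
    insulinogenic: float        # NaN when undefined (G30 == G0)
    matsuda: float
    insulinogenic_defined: bool = True

    @property
    def pg120_mmoll(self) -> float:
        return units.glucose_mgdl_to_mmoll(self.pg120_mgdl)


def ogtt_indices(t: np.ndarray, glucose_mgdl: np.ndarray,
                 insulin_microu_ml: np.ndarray) -> OGTTIndices:
    """OGTT-derived indices from a (t, glucose, insulin) series.

    PG120 is the glucose at 120 min; the insulinogenic index is
    ``(I30 - I0)/(G30 - G0)`` (flagged undefined when G30 = G0); the
    Matsuda index is ``10000 / sqrt(G0 * I0 * Gmean * Imean)`` with the
    means taken over all available OGTT samples.  Units are mg/dL and
    uU/mL as in the standard definitions.
    """
    t = np.asarray(t, dtype=float)
    g = np.asarray(glucose_mgdl, dtype=float)
    i = np.asarray(insulin_microu_ml, dtype=float)

    def _at(minute):
        idx = np.flatnonzero(np.abs(t - minute) < 1e-6)
        if len(idx) == 0:
            raise InsufficientDataError(f"OGTT series lacks t={minute} min")
        return g[idx[0]], i[idx[0]]

    g0, i0 = _at(0)
    g30, i30 = _at(30)
    g120, _ = _at(120)
    if g0 <= 0 or i0 <= 0:
        raise DomainError("fasting OGTT values must be positive")

    defined = not math.isclose(g30, g0, rel_tol=0.0, abs_tol=1e-12)
    insulinogenic = (i30 - i0) / (g30 - g0) if defined else float("nan")
    matsuda = 1e4 / math.sqrt(g0 * i0 * g.mean() * i.mean())
    return OGTTIndices(pg120_mgdl=float(g120), insulinogenic=insulinogenic,
                       matsuda=matsuda, insulinogenic_defined=defined)


def isi_simulated(params, record, series, model_id: str = "GI",
                  suppression: str = "I") -> float:
    """ISI computed from the fitted model's own end-of-clamp state.

    The subject's recorded infusions drive a forward simulation from
    the observed fasting state; end-of-clamp glucose and insulin (and,
    for SGLT2i subjects, the simulated urinary loss) replace the
    measured values in the ISI formula.  Comparing this against the
    measured ISI checks that a fit reproduces the physiology the index
    summarizes, not just the residuals.
    """
    import numpy as np

    from .model_core import (ClampProtocol, GIGParameters, GIParameters,
                             simulate)

    duration = float(series.samples["Gc"][0][-1])
    proto = ClampProtocol(duration, series.f1, series.f2, float("nan"),
                          record.body_weight, record.bv_dl)
    if model_id.upper() == "GI":
        p = GIParameters(**{k: params[k] for k in
                            ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8")})
        y0 = [record.G0, record.G0, record.I0]
    else:
        p = GIGParameters(**{k: params[k] for k in
                             ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8",
                              "kGN", "kGgS", "kGgC", "kratio", "kCPC")})
        y0 = [record.G0, record.G0, record.I0, record.Gg0, record.CP0]
    t_grid = np.arange(0.0, duration + 0.5)
    traj = simulate(model_id, p, proto, y0, t_grid, suppression=suppression)
    win = t_grid >= duration - 30.0
    g_end = float(traj.Gc[win].mean())
    i_end = float(traj.I[win].mean())
    uptake = float(series.f1[win].mean())
    if record.group == "sglt2i":
        uger_sim = p.k8 * units.glucose_mmoll_to_mgdl(g_end) \
            * record.bv_dl / record.body_weight
        uptake = tgur(uptake, uger_sim)
    return isi(uptake, units.glucose_mmoll_to_mgdl(g_end),
               units.insulin_pmoll_to_microu_ml(i_end))


def insulin_half_life(k7: float) -> float:
    """First-order insulin half-life, ``ln 2 / k7`` minutes."""
    if k7 <= 0:
        raise DomainError("k7 must be positive")
    return math.log(2.0) / k7


@dataclass
class MetricSet:
    """All composite indices for one subject (NaN where not computed)."""

    subject_id: str
    DI_cle: float = float("nan")
    PI_cle_numeric_exp1: float = float("nan")
    PI_cle_numeric_exp2: float = float("nan")
    PI_cle_numeric_exp3: float = float("nan")
    PI_cle_analytic: float = float("nan")
    Ggsen: float = float("nan")
    Ggsec_cle: float = float("nan")
    ISI_measured: float = float("nan")
    ISI_simulated: float = float("nan")
    TGUR: float = float("nan")
    insulinogenic_index: float = float("nan")
    matsuda_index: float = float("nan")
    PG120: float = float("nan")
    insulin_half_life_GI: float = float("nan")
    insulin_half_life_GIG: float = float("nan")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compute_metric_set(record, gi_fit=None, gig_fit=None,
                       isi_simulated: float = float("nan")) -> MetricSet:
    """Assemble a subject's MetricSet from its record and fits.

    ``record`` is a :class:`~glucoclamp.preprocess.SubjectRecord`; GI
    and GIG fits are optional -- missing pieces stay NaN.
    """
    m = MetricSet(subject_id=record.subject_id, PG120=record.PG120)

    uger = record.urinary_glucose_0_120 / 120.0 / record.body_weight \
        if record.body_weight > 0 else float("nan")
    if np.isfinite(record.fg):
        m.TGUR = tgur(record.fg, uger)
        uptake = m.TGUR if record.group == "sglt2i" else record.fg
        if uptake > 0 and record.Gss > 0 and record.Iss > 0:
            m.ISI_measured = isi(
                uptake,
                units.glucose_mmoll_to_mgdl(record.Gss),
                units.insulin_pmoll_to_microu_ml(record.Iss))
    m.ISI_simulated = isi_simulated

    try:
        pi, ggsen, ggsec = pi_cle_analytic(record.Gg0, record.G0, record.fg,
                                           record.Gss, record.Iss)
        m.PI_cle_analytic, m.Ggsen, m.Ggsec_cle = pi, ggsen, ggsec
    except DomainError:
        pass

    if record.ogtt_t is not None:
        try:
            idx = ogtt_indices(
                record.ogtt_t,
                units.glucose_mmoll_to_mgdl(np.asarray(record.ogtt_glucose)),
                units.insulin_pmoll_to_microu_ml(np.asarray(record.ogtt_insulin)))
            m.insulinogenic_index = idx.insulinogenic
            m.matsuda_index = idx.matsuda
        except (InsufficientDataError, DomainError):
            pass

    if gi_fit is not None:
        p = gi_fit.params
        m.DI_cle = di_cle(p["k4"], p["k5"], p["k7"])
        m.insulin_half_life_GI = insulin_half_life(p["k7"])
    if gig_fit is not None:
        p = gig_fit.params
        for e in (1, 2, 3):
            setattr(m, f"PI_cle_numeric_exp{e}",
                    pi_cle_numeric(p["kGN"], p["kGgS"], p["kGgC"], e))
        m.insulin_half_life_GIG = insulin_half_life(p["k7"])
    return m
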