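"""Raw clamp measurements -> the windowed, normalized series the
objective functions consume, plus the urinary-glucose fixing of k8.

Three transformations are applied to each subject before fitting:

1. the quasi-continuous (1-min) glucose trace is replaced by its
   trailing 5-min window average (the concentration reported at minute
   ``t`` is the mean of the samples in ``(t-5, t]``);
2. every variable is normalized by its own maximum, retaining the scale
   factors for de-normalization;
3. the urinary excretion rate constant ``k8`` is fixed from the
   measured 0-120 min urinary glucose via
   ``UrinaryGlucose = integral_0^120 k8 * Gc * BV dt``
   (trapezoidal quadrature, exact for piecewise-linear traces), so it
   is never part of the estimated parameter set.

Missing samples are dropped, not imputed: the RSS weights are based on
the per-variable counts, which therefore reflect the data actually
present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (DegenerateInputError, DomainError, InsufficientDataError)
from . import units

__all__ = [
    "ClampTimeSeries",
    "NormalizedSeries",
    "SubjectRecord",
    "window_average_glucose",
    "normalize_series",
    "estimate_k8",
]

WINDOW_MIN = 5  # trailing window length, minutes

VARIABLES = ("Gc", "I", "Gg", "CP")


@dataclass
class ClampTimeSeries:
    """One subject's sampled clamp concentrations plus infusion records.

    ``samples`` maps variable name -> (t, value) arrays; times are
    non-negative and strictly increasing per variable.  ``f1``/``f2``
    are the infusion records on the 1-min grid (mg kg^-1 min^-1 and
    mU kg^-1 min^-1).
    """

    subject_id: str
    samples: dict = field(default_factory=dict)
    f1: np.ndarray | None = None
    f2: np.ndarray | None = None

    def __post_init__(self):
        for var, (t, v) in self.samples.items():
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            if len(t) != len(v):
                raise DomainError(f"{var}: time/value length mismatch")
            if len(t) and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
                raise DomainError(f"{var}: times must be non-negative and "
                                  "strictly increasing")
            if np.any(v < 0):
                raise DomainError(f"{var}: values must be non-negative")
            self.samples[var] = (t, v)

    def counts(self) -> dict:
        """Numbers of measurement time points per variable (nGc, nI, ...)."""
        return {var: len(self.samples[var][0]) for var in self.samples}

    def n_total(self) -> int:
        return sum(self.counts().values())


@dataclass
class NormalizedSeries:
    """Per-variable values divided by that variable's maximum."""

    values: dict            # var -> (t, normalized values)
    scales: dict            # var -> maximum used for normalization

    def denormalize(self) -> dict:
        return {var: (t, v * self.scales[var])
                for var, (t, v) in self.values.items()}

    def counts(self) -> dict:
        return {var: len(self.values[var][0]) for var in self.values}


@dataclass
class SubjectRecord:
    """Per-subject scalars used by fitting, metrics and cohort analyses.

    Concentrations in internal units (glucose mmol/L, insulin pmol/L,
    glucagon ng/L); ``urinary_glucose_0_120`` in mg excreted over the
    first 120 min of the clamp; ``fg`` in mg kg^-1 min^-1.
    """

    subject_id: str
    body_weight: float
    bv_dl: float
    urinary_glucose_0_120: float
    G0: float
    I0: float
    Gg0: float
    Gss: float
    Iss: float
    fg: float
    PG120: float
    group: str = "control"
    CP0: float = float("nan")
    k8: float = float("nan")
    ogtt_t: np.ndarray | None = None
    ogtt_glucose: np.ndarray | None = None   # mmol/L
    ogtt_insulin: np.ndarray | None = None   # pmol/L

    def __post_init__(self):
        for name in ("body_weight", "bv_dl", "G0", "Gss", "Iss"):
            v = getattr(self, name)
            if v is not None and np.isfinite(v) and v <= 0:
                raise DomainError(f"{name} must be positive where measured")
        if self.urinary_glucose_0_120 < 0:
            raise DomainError("urinary glucose must be non-negative")


def window_average_glucose(t: np.ndarray, values: np.ndarray,
                           window: int = WINDOW_MIN):
    """Trailing window mean of a 1-min sampled glucose series.

    ``output(t) = mean of raw samples in (t - window, t]`` (five samples
    at ``t-4 .. t`` on the integer grid).  Output times start at
    ``t[0] + window``; output length is input length - window.

    Raises
    ------
    InsufficientDataError
        If the series is shorter than ``window + 1`` points.
    DomainError
        If sampling is not uniform 1-min.
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(t) < window + 1:
        raise InsufficientDataError(
            f"need at least {window + 1} samples, got {len(t)}")
    if not np.allclose(np.diff(t), 1.0):
        raise DomainError("window averaging expects uniform 1-min sampling")
    kernel = np.full(window, 1.0 / window)
    avg = np.convolve(values, kernel, mode="valid")  # starts at t[0]+window-1
    return t[window:], avg[1:]


def normalize_series(series: ClampTimeSeries,
                     window_glucose: bool = True) -> NormalizedSeries:
    """Normalize each measured variable by its own maximum.

    The glucose trace is window-averaged first (when ``window_glucose``)
    so that the normalization scale matches the series the objective
    actually compares against.

    Raises
    ------
    DegenerateInputError
        If a variable has no strictly positive value.
    """
    values, scales = {}, {}
    for var, (t, v) in series.samples.items():
        if var == "Gc" and window_glucose:
            t, v = window_average_glucose(t, v)
        m = v.max(initial=0.0)
        if m <= 0:
            raise DegenerateInputError(f"variable {var} is all zero")
        values[var] = (t, v / m)
        scales[var] = float(m)
    return NormalizedSeries(values=values, scales=scales)


def estimate_k8(urinary_glucose_mg: float, t: np.ndarray,
                gc_mgdl: np.ndarray, bv_dl: float) -> float:
    """Fix k8 from the 0-120 min urinary glucose integral.

    ``k8 = UG / (BV * integral_0^120 Gc dt)`` with the integral taken by
    trapezoid on the sampling grid (exact for piecewise-linear traces).
    Glucose enters in mg/dL and BV in dL so that the balance is in mg.
    """
    if urinary_glucose_mg < 0:
        raise DomainError("urinary glucose must be non-negative")
    if bv_dl <= 0:
        raise DomainError("blood volume must be positive")
    t = np.asarray(t, dtype=float)
    gc = np.asarray(gc_mgdl, dtype=float)
    if t[0] > 1e-9 or t[-1] < 120.0 - 1e-9:
        raise InsufficientDataError("glucose series must cover [0, 120] min")
    mask = (t >= 0.0) & (t <= 120.0)
    integral = np.trapezoid(gc[mask], t[mask])
    if integral <= 0:
        raise DegenerateInputError("zero glucose integral")
    return urinary_glucose_mg / (bv_dl * integral)


def k8_from_series(record: SubjectRecord, series: ClampTimeSeries) -> float:
    """Convenience: estimate k8 from a record + its raw glucose trace."""
    t, gc = series.samples["Gc"]
    return estimate_k8(record.urinary_glucose_0_120, t,
                       units.glucose_mmoll_to_mgdl(gc), record.bv_dl)
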