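"""Reduced GIG model variants and AIC-based cohort model selection.

A variant family is defined by structural toggles on the GIG model:
whether glucagon acts on glucose (``kGN`` free or fixed to zero), how
glucagon secretion is suppressed (by insulin, by glucose, or by both),
whether the beta-cell secretion threshold ``k6`` is present, and
whether C-peptide clearance is tied to insulin clearance
(``kCPC = k7``) or free.  Every variant is fitted to every subject,
scored with

    AIC = N log(RSS) + 2 K          (natural logarithm)

where ``N`` is the subject's total number of data points (constant
across compared variants) and ``K`` the number of estimated
parameters, and the cohort-level model is the variant that is
AIC-optimal for the greatest number of subjects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DomainError, IncompleteGridError

__all__ = [
    "aic", "ModelVariant", "full_gig_variant", "enumerate_variants",
    "DEFAULT_FAMILY", "SelectionReport", "select_cohort_variant",
]

#: RSS below this is treated as a numerically perfect fit (see `aic`).
RSS_FLOOR = 1e-12

_BASE_FREE = ("k1", "k2", "k3", "k4", "k5", "k7", "kratio", "kGgS", "kGgC")


def aic(rss: float, n_points: int, k: int, rss_floor: float = RSS_FLOOR) -> float:
    """Akaike information criterion ``N ln(RSS) + 2K``.

    RSS values at or below ``rss_floor`` are floored (with a warning):
    below the integration-accuracy floor, residual differences carry no
    information and the parameter-count penalty should decide.
    """
    if n_points < 1 or k < 1:
        raise DomainError("need n_points >= 1 and k >= 1")
    if rss < 0:
        raise DomainError("RSS must be non-negative")
    if rss <= rss_floor:
        warnings.warn(
            f"RSS={rss:.3g} at/below floor {rss_floor:.1g}; flooring for AIC",
            RuntimeWarning)
        rss = rss_floor
    return n_points * float(np.log(rss)) + 2 * k


@dataclass(frozen=True)
class ModelVariant:
    """One member of the reduced-GIG family.

    ``K`` counts the estimated parameters (k8 is always fixed from
    data and never counted).
    """

    variant_id: str
    glucagon_action: bool
    suppression: str
    threshold: bool
    cpc_shared: bool

    def __post_init__(self):
        if self.suppression not in ("I", "Gc", "both"):
            raise ConfigError(f"unknown suppression mode {self.suppression!r}")

    @property
    def free_names(self) -> tuple:
        names = list(_BASE_FREE)
        if self.glucagon_action:
            names.insert(3, "kGN")
        if self.threshold:
            names.insert(names.index("k7"), "k6")
        if not self.cpc_shared:
            names.append("kCPC")
        return tuple(names)

    @property
    def K(self) -> int:
        return len(self.free_names)


def _variant_id(action: bool, supp: str, thr: bool, cpc_shared: bool) -> str:
    return "gN{}-sup{}-thr{}-cp{}".format(
        int(action), supp, int(thr), "S" if cpc_shared else "F")


def full_gig_variant() -> ModelVariant:
    """The unreduced GIG model (all structural terms present, kCPC free)."""
    return ModelVariant(_variant_id(True, "I", True, False),
                        glucagon_action=True, suppression="I",
                        threshold=True, cpc_shared=False)


DEFAULT_FAMILY = {
    "glucagon_action": [True, False],
    "suppression": ["I", "Gc", "both"],
    "threshold": [True, False],
    "cpc_shared": [True],
}
"""Default 12-variant family; extend the option lists (e.g.
``cpc_shared: [True, False]``) for richer families."""


def enumerate_variants(family_config: dict | None = None) -> list:
    """Deterministic, duplicate-free enumeration of a variant family."""
    cfg = dict(DEFAULT_FAMILY if family_config is None else family_config)
    keys = ("glucagon_action", "suppression", "threshold", "cpc_shared")
    for key in keys:
        if not cfg.get(key):
            raise ConfigError(f"variant family option {key!r} is empty")
    variants = []
    seen = set()
    for action, supp, thr, cpc in itertools.product(
            cfg["glucagon_action"], cfg["suppression"],
            cfg["threshold"], cfg["cpc_shared"]):
        vid = _variant_id(action, supp, thr, cpc)
        if vid in seen:
            continue
        seen.add(vid)
        variants.append(ModelVariant(vid, glucagon_action=action,
                                     suppression=supp, threshold=thr,
                                     cpc_shared=cpc))
    return variants


@dataclass
class SelectionReport:
    """Per-subject AIC winners and the cohort-level selected variant."""

    per_subject: dict                 # subject_id -> winning variant_id
    counts: dict                      # variant_id -> number of subjects won
    mean_aic: dict                    # variant_id -> mean AIC over subjects
    cohort_variant: str
    aic_table: dict = field(default_factory=dict)  # (subject, variant) -> AIC

    def to_frame(self):
        import pandas as pd
        rows = [{"variant_id": vid, "n_subjects_optimal": self.counts.get(vid, 0),
                 "mean_AIC": self.mean_aic[vid]} for vid in self.mean_aic]
        return pd.DataFrame(rows).sort_values(
            ["n_subjects_optimal", "mean_AIC"],
            ascending=[False, True]).reset_index(drop=True)


def select_cohort_variant(fits: dict, rss_floor: float = RSS_FLOOR
                          ) -> SelectionReport:
    """AIC-score a complete subject x variant fit grid.

    ``fits`` maps ``(subject_id, variant_id)`` to an object with
    ``rss``, ``n_points`` and ``K`` attributes (e.g. ``FitResult``).
    The per-subject ``N`` must be identical across the variants
    compared for that subject.  Per-subject winner is the argmin-AIC
    variant; the cohort variant is the modal winner, ties broken by
    lower mean AIC, then by enumeration order.
    """
    subjects = sorted({s for s, _ in fits})
    variant_ids = sorted({v for _, v in fits})
    missing = [(s, v) for s in subjects for v in variant_ids
               if (s, v) not in fits]
    if missing:
        raise IncompleteGridError(
            f"missing fits for {len(missing)} subject x variant cells, "
            f"first: {missing[0]}")

    aic_table = {}
    per_subject = {}
    for s in subjects:
        n_ref = fits[(s, variant_ids[0])].n_points
        best_v, best_a = None, np.inf
        for v in variant_ids:
            fit = fits[(s, v)]
            if fit.n_points != n_ref:
                raise IncompleteGridError(
                    f"subject {s}: N differs across variants "
                    f"({fit.n_points} vs {n_ref})")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                a = aic(fit.rss, fit.n_points, fit.K, rss_floor)
            aic_table[(s, v)] = a
            if a < best_a:
                best_v, best_a = v, a
        per_subject[s] = best_v

    counts = {v: sum(1 for s in subjects if per_subject[s] == v)
              for v in variant_ids}
    mean_aic = {v: float(np.mean([aic_table[(s, v)] for s in subjects]))
                for v in variant_ids}
    cohort = min(variant_ids,
                 key=lambda v: (-counts[v], mean_aic[v], variant_ids.index(v)))
    return SelectionReport(per_subject=per_subject, counts=counts,
                           mean_aic=mean_aic, cohort_variant=cohort,
                           aic_table=aic_table)
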