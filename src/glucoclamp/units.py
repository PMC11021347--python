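"""Unit conventions and single-sourced converters.

Internal units used throughout the package:

* blood glucose ``Gc`` -- mmol/L  (1 mmol/L = 18.016 mg/dL)
* blood insulin ``I`` -- pmol/L   (1 uU/mL = 6.0 pmol/L)
* blood glucagon ``Gg`` -- ng/L
* C-peptide ``CP`` -- nmol/L      (1 nmol/L = 1000 pmol/L)
* time -- minutes
* glucose infusion ``f1`` -- mg kg^-1 min^-1
* insulin infusion ``f2`` -- mU kg^-1 min^-1

Infusions are converted to concentration fluxes by dividing by the
per-kg blood volume ``BV_norm = BV[dL] / weight[kg]``.
"""

MGDL_PER_MMOLL = 18.016
"""mg/dL of glucose per mmol/L."""

PMOLL_PER_MICROU_ML = 6.0
"""pmol/L of insulin per uU/mL."""

PMOL_PER_NMOL = 1000.0

BV_DL_PER_KG = 0.75
"""Default blood volume per body weight, dL/kg (typical adult)."""


def glucose_mmoll_to_mgdl(x):
    return x * MGDL_PER_MMOLL


def glucose_mgdl_to_mmoll(x):
    return x / MGDL_PER_MMOLL


def insulin_pmoll_to_microu_ml(x):
    return x / PMOLL_PER_MICROU_ML


def insulin_microu_ml_to_pmoll(x):
    return x * PMOLL_PER_MICROU_ML


def blood_volume_dl(body_weight_kg: float, per_kg: float = BV_DL_PER_KG) -> float:
    """Blood volume in dL from body weight, using a per-kg coefficient."""
    return per_kg * body_weight_kg


def glucose_infusion_to_flux(f1_mg_kg_min, bv_norm_dl_kg):
    """mg kg^-1 min^-1 -> mmol/L/min of blood glucose."""
    return f1_mg_kg_min / bv_norm_dl_kg / MGDL_PER_MMOLL


def insulin_infusion_to_flux(f2_mu_kg_min, bv_norm_dl_kg):
    """mU kg^-1 min^-1 -> pmol/L/min of blood insulin.

    mU/dL = 10 uU/mL, and 1 uU/mL = 6 pmol/L, hence the factor 60.
    """
    return f2_mu_kg_min / bv_norm_dl_kg * 10.0 * PMOLL_PER_MICROU_ML
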