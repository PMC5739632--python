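"""Derived clinical covariates and unit conversions for neonatal records."""

from __future__ import annotations

__all__ = [
    "bsa",
    "schwartz_gfr",
    "pma",
    "creatinine_umol_to_mgdl",
    "creatinine_mgdl_to_umol",
    "SCHWARTZ_K_TERM",
    "SCHWARTZ_K_PRETERM",
    "CREATININE_UMOL_PER_MGDL",
]

#: umol/L of creatinine per mg/dL.
CREATININE_UMOL_PER_MGDL = 88.4

#: Schwartz constants for full-term and preterm infants.
SCHWARTZ_K_TERM = 0.45
SCHWARTZ_K_PRETERM = 0.33


def bsa(weight_kg: float, height_cm: float) -> float:
    """Body surface area (m^2) from a paediatric power formula.

    ``BSA = weight^0.5378 * height^0.3964 * 0.024265`` with weight in kg and
    height in cm.
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be > 0")
    return weight_kg**0.5378 * height_cm**0.3964 * 0.024265


def creatinine_umol_to_mgdl(scr_umol_per_l: float) -> float:
    return scr_umol_per_l / CREATININE_UMOL_PER_MGDL


def creatinine_mgdl_to_umol(scr_mg_per_dl: float) -> float:
    return scr_mg_per_dl * CREATININE_UMOL_PER_MGDL


def schwartz_gfr(height_cm: float, scr_umol_per_l: float, preterm: bool = False) -> float:
    """Schwartz estimate of GFR (mL/min/1.73 m^2) for infants.

    ``GFR = k * height(cm) / SCr(mg/dL)`` with k = 0.45 for full-term and
    0.33 for preterm infants.  Serum creatinine is accepted in umol/L and
    converted internally (88.4 umol/L per mg/dL).
    """
    if scr_umol_per_l <= 0:
        raise ValueError("serum creatinine must be > 0")
    if height_cm <= 0:
        raise ValueError("height must be > 0")
    k = SCHWARTZ_K_PRETERM if preterm else SCHWARTZ_K_TERM
    return k * height_cm / creatinine_umol_to_mgdl(scr_umol_per_l)


def pma(ga_weeks: float, pna_days: float) -> float:
    """Postmenstrual age (weeks) = gestational age + postnatal age / 7."""
    if ga_weeks <= 0:
        raise ValueError("gestational age must be > 0")
    if pna_days < 0:
        raise ValueError("postnatal age must be >= 0")
    return ga_weeks + pna_days / 7.0
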