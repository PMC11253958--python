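"""Serum-creatinine GFR estimating equations used as comparators.

Implements the 2009 CKD-EPI creatinine equation (race-inclusive form) and
the IDMS-traceable 4-variable MDRD equation.  Both return values already
normalized to 1.73 m^2 of body surface area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .pk_clearance import PatientCovariates

__all__ = ["EgfrEstimate", "ckd_epi", "mdrd"]


@dataclass(frozen=True)
class EgfrEstimate:
    equation: Literal["ckd_epi_2009", "mdrd_idms_4var"]
    value_mL_min_173: float


def _check(cov: PatientCovariates) -> None:
    if cov.serum_creatinine_mg_dL <= 0:
        raise ValueError("serum creatinine must be positive")
    if cov.age_years <= 0:
        raise ValueError("age must be positive")


def ckd_epi(cov: PatientCovariates) -> EgfrEstimate:
    """2009 CKD-EPI creatinine equation, mL/min/1.73 m^2.

    141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^Age
    * 1.018 [female] * 1.159 [black],
    with k = 0.7 (F) / 0.9 (M) and a = -0.329 (F) / -0.411 (M).
    """
    _check(cov)
    scr = cov.serum_creatinine_mg_dL
    if cov.sex == "female":
        kappa, a = 0.7, -0.329
    else:
        kappa, a = 0.9, -0.411
    value = (
        141.0
        * min(scr / kappa, 1.0) ** a
        * max(scr / kappa, 1.0) ** -1.209
        * 0.993**cov.age_years
    )
    if cov.sex == "female":
        value *= 1.018
    if cov.race_black:
        value *= 1.159
    return EgfrEstimate("ckd_epi_2009", value)


def mdrd(cov: PatientCovariates) -> EgfrEstimate:
    """IDMS-traceable 4-variable MDRD equation, mL/min/1.73 m^2.

    175 * Scr^-1.154 * Age^-0.203 * 0.742 [female] * 1.212 [black].
    """
    _check(cov)
    value = 175.0 * cov.serum_creatinine_mg_dL**-1.154 * cov.age_years**-0.203
    if cov.sex == "female":
        value *= 0.742
    if cov.race_black:
        value *= 1.212
    return EgfrEstimate("mdrd_idms_4var", value)


def mdrd_invert_creatinine(
    gfr_mL_min_173: float,
    age_years: float,
    female: bool,
    black: bool,
) -> float:
    """Serum creatinine (mg/dL) that makes MDRD return the given GFR.

    Used by the cohort simulator to generate realistic creatinine values;
    a modelling convenience, not a physiological claim.
    """
    if gfr_mL_min_173 <= 0 or age_years <= 0:
        raise ValueError("gfr and age must be positive")
    base = 175.0 * age_years**-0.203
    if female:
        base *= 0.742
    if black:
        base *= 1.212
    return (base / gfr_mL_min_173) ** (1.0 / 1.154)
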