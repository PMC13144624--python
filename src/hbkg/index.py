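"""Hemoglobin-mass-balance blood-loss index (Hb/kg).

The index quantifies perioperative blood loss in cardiac surgery as the
hemoglobin mass lost per kilogram of body weight:

    Hb/kg = (Hb loss intra-op + Hb loss via chest tubes - Hb transfused) / weight

It is built from five steps:

1. estimated blood volume (EBV) from the Nadler height/weight/sex polynomial,
2. initial circulating Hb mass = EBV x preoperative Hb concentration,
3. intraoperative Hb mass loss from the pre/post concentration difference,
4. Hb mass evacuated via chest-tube drainage (CTD) over the first 18 h,
5. a correction for packed-red-blood-cell (PRBC) units transfused.

All concentrations are g/L, volumes are litres (drainage recorded in mL and
converted internally), masses are grams, and the index is g/kg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "InvalidInputError",
    "MissingDataError",
    "ConfigurationError",
    "EBVCoefficients",
    "MALE_NADLER",
    "FEMALE_NADLER",
    "nadler_coefficients",
    "HbKgResult",
    "compute_ebv",
    "compute_initial_hb_mass",
    "compute_intraop_loss",
    "compute_ctd_loss",
    "compute_transfused_hb",
    "compute_hbkg_index",
    "compute_index_table",
    "classify_bmi_group",
    "classify_ctd_group",
    "CTD_HOUR_COLUMNS",
]


class InvalidInputError(ValueError):
    """A physically impossible input (negative volume, non-positive height...)."""


class MissingDataError(ValueError):
    """A required field is absent; the message names the field."""


class ConfigurationError(ValueError):
    """An unknown mode or otherwise invalid configuration value."""


@dataclass(frozen=True)
class EBVCoefficients:
    """Coefficients of the Nadler blood-volume polynomial.

    EBV(L) = k1 * height(m)^3 + k2 * weight(kg) + k3

    Units: k1 L/m^3, k2 L/kg, k3 L.
    """

    k1: float
    k2: float
    k3: float


#: Sex-specific Nadler coefficients.
MALE_NADLER = EBVCoefficients(k1=0.3669, k2=0.03219, k3=0.6041)
FEMALE_NADLER = EBVCoefficients(k1=0.3561, k2=0.03308, k3=0.1833)

#: Hourly chest-tube drainage column names, 1..18 h post-op.
CTD_HOUR_COLUMNS = tuple(f"ctd_{h:02d}h" for h in range(1, 19))


def nadler_coefficients(sex: str) -> EBVCoefficients:
    """Return the sex-specific Nadler coefficients ('male' or 'female')."""
    s = str(sex).strip().lower()
    if s in ("male", "m"):
        return MALE_NADLER
    if s in ("female", "f"):
        return FEMALE_NADLER
    raise InvalidInputError(f"unknown sex {sex!r}; expected 'male' or 'female'")


def compute_ebv(
    height_m: float,
    weight_kg: float,
    sex: str | None = None,
    coeffs: EBVCoefficients | None = None,
) -> float:
    """Estimated blood volume in litres from the Nadler polynomial.

    Either ``sex`` (which selects the standard coefficients) or an explicit
    ``coeffs`` override must be given.
    """
    if coeffs is None:
        if sex is None:
            raise ConfigurationError("either sex or explicit coefficients required")
        coeffs = nadler_coefficients(sex)
    if not height_m > 0:
        raise InvalidInputError(f"height must be positive, got {height_m}")
    if not weight_kg > 0:
        raise InvalidInputError(f"weight must be positive, got {weight_kg}")
    return coeffs.k1 * height_m**3 + coeffs.k2 * weight_kg + coeffs.k3


def compute_initial_hb_mass(ebv_l: float, hb0_g_per_l: float) -> float:
    """Circulating Hb mass (g) = EBV (L) x Hb concentration (g/L)."""
    if not ebv_l > 0:
        raise InvalidInputError(f"EBV must be positive, got {ebv_l}")
    if hb0_g_per_l < 0:
        raise InvalidInputError(f"Hb concentration must be >= 0, got {hb0_g_per_l}")
    return ebv_l * hb0_g_per_l


def compute_intraop_loss(
    hb_pre: float,
    hb_post: float,
    ebv_l: float,
    mode: str = "consistent",
) -> float:
    """Intraoperative Hb mass loss (g) from the pre/post concentration change.

    mode="consistent" (default): (hb_pre - hb_post) x EBV — the concentration
    drop over one blood volume, in grams.
    mode="literal": (hb_pre*EBV - hb_post*EBV) x EBV, the mass difference
    multiplied by EBV once more. Dimensionally g*L; retained only for
    fidelity to the source formula as printed.

    A negative value (hemoconcentration, hb_post > hb_pre) is passed through
    with a warning, never clamped: clamping would bias the index.
    """
    if hb_pre < 0 or hb_post < 0:
        raise InvalidInputError("Hb concentrations must be >= 0")
    if not ebv_l > 0:
        raise InvalidInputError(f"EBV must be positive, got {ebv_l}")
    if mode == "consistent":
        loss = (hb_pre - hb_post) * ebv_l
    elif mode == "literal":
        loss = (hb_pre * ebv_l - hb_post * ebv_l) * ebv_l
    else:
        raise ConfigurationError(f"unknown intraop-loss mode {mode!r}")
    if loss < 0:
        warnings.warn(
            f"negative intraoperative Hb loss ({loss:.2f}): post-op Hb exceeds "
            "pre-op Hb (hemoconcentration); value propagated unclamped",
            stacklevel=2,
        )
    return loss


def compute_ctd_loss(
    hourly_volumes_ml: Sequence[float] | float,
    drain_hb_g_per_l: float | Sequence[float],
) -> float:
    """Hb mass (g) evacuated via chest tubes.

    ``hourly_volumes_ml`` is the 18-vector of hourly drainage volumes (a bare
    total in mL is also accepted); ``drain_hb_g_per_l`` is the aliquot Hb
    concentration applied to the whole volume, or optionally a per-interval
    concentration vector, in which case a volume-weighted sum is used.
    """
    vols = np.atleast_1d(np.asarray(hourly_volumes_ml, dtype=float))
    if np.any(vols < 0):
        raise InvalidInputError("drainage volumes must be >= 0")
    conc = np.asarray(drain_hb_g_per_l, dtype=float)
    if np.any(conc < 0):
        raise InvalidInputError("drain Hb concentration must be >= 0")
    if conc.ndim == 0:
        return float(conc) * vols.sum() / 1000.0
    if conc.shape != vols.shape:
        raise InvalidInputError(
            "per-interval drain Hb vector must match the volume vector length"
        )
    return float(np.dot(conc, vols)) / 1000.0


def compute_transfused_hb(units: int, grams_per_unit: float = 43.0) -> float:
    """Hb mass (g) supplied by PRBC transfusion: units x grams per unit.

    The default 43 g/unit follows the national blood-product standard used by
    the index's authors; the literature value 52 g/unit is configurable.
    """
    if units < 0 or units != int(units):
        raise InvalidInputError(f"PRBC units must be a non-negative integer, got {units}")
    if not grams_per_unit > 0:
        raise InvalidInputError("grams_per_unit must be positive")
    return int(units) * grams_per_unit


@dataclass(frozen=True)
class HbKgResult:
    """Decomposed Hb/kg index for one patient."""

    ebv: float  # L
    initial_hb_mass: float  # g
    intraop_loss: float  # g
    ctd_loss: float  # g
    transfused_hb: float  # g
    index: float  # g/kg
    weight_kg: float = field(default=float("nan"))


_REQUIRED_FIELDS = ("sex", "height_m", "weight_kg", "hb_t0", "hb_t1", "drain_hb", "prbc_units")


def compute_hbkg_index(
    record: Mapping[str, object],
    mode: str = "consistent",
    grams_per_unit: float = 43.0,
    coeffs: EBVCoefficients | None = None,
) -> HbKgResult:
    """Compute the fully decomposed Hb/kg index for one patient record.

    ``record`` is any mapping (dict, pandas Series) with the documented
    columns: sex, height_m, weight_kg, hb_t0, hb_t1, drain_hb, prbc_units and
    either the hourly ``ctd_01h``..``ctd_18h`` columns or ``ctd_total_ml``.
    Raises :class:`MissingDataError` naming the first absent field.
    """
    for name in _REQUIRED_FIELDS:
        val = record.get(name) if hasattr(record, "get") else record[name]
        if val is None or (isinstance(val, float) and np.isnan(val)):
            raise MissingDataError(f"required field {name!r} is missing")

    if all(c in record for c in CTD_HOUR_COLUMNS):
        vols = [float(record[c]) for c in CTD_HOUR_COLUMNS]
        if any(np.isnan(vols)):
            raise MissingDataError("required hourly drainage volume is missing")
    elif "ctd_total_ml" in record:
        vols = float(record["ctd_total_ml"])
    else:
        raise MissingDataError("required field 'ctd_01h..ctd_18h' (or 'ctd_total_ml') is missing")

    weight = float(record["weight_kg"])
    ebv = compute_ebv(float(record["height_m"]), weight, sex=str(record["sex"]), coeffs=coeffs)
    initial_mass = compute_initial_hb_mass(ebv, float(record["hb_t0"]))
    intraop = compute_intraop_loss(float(record["hb_t0"]), float(record["hb_t1"]), ebv, mode=mode)
    ctd = compute_ctd_loss(vols, float(record["drain_hb"]))
    transfused = compute_transfused_hb(int(record["prbc_units"]), grams_per_unit)
    index = (intraop + ctd - transfused) / weight
    return HbKgResult(
        ebv=ebv,
        initial_hb_mass=initial_mass,
        intraop_loss=intraop,
        ctd_loss=ctd,
        transfused_hb=transfused,
        index=index,
        weight_kg=weight,
    )


def compute_index_table(df, mode: str = "consistent", grams_per_unit: float = 43.0):
    """Apply :func:`compute_hbkg_index` to every row of a cohort table.

    Returns ``(results, exclusions)`` where ``results`` is a DataFrame of the
    HbKgResult fields indexed like ``df`` and ``exclusions`` is a DataFrame
    of excluded rows with a machine-readable reason. Rows with missing
    step-required fields are excluded and reported, never silently dropped.
    """
    import pandas as pd

    rows, excluded = {}, []
    for idx, rec in df.iterrows():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = compute_hbkg_index(rec, mode=mode, grams_per_unit=grams_per_unit)
        except MissingDataError as err:
            excluded.append({"row": idx, "reason": str(err)})
            continue
        rows[idx] = {
            "ebv_l": res.ebv,
            "initial_hb_mass_g": res.initial_hb_mass,
            "intraop_loss_g": res.intraop_loss,
            "ctd_loss_g": res.ctd_loss,
            "transfused_hb_g": res.transfused_hb,
            "hbkg_index": res.index,
        }
    results = pd.DataFrame.from_dict(rows, orient="index")
    exclusions = pd.DataFrame(excluded, columns=["row", "reason"])
    return results, exclusions


def classify_bmi_group(bmi: float) -> str:
    """BMI stratum: I below 25, II 25-30, III at or above 30 kg/m^2.

    Half-open WHO cuts close the [24.9, 25) gap left by the printed strata.
    """
    if not bmi > 0:
        raise InvalidInputError(f"BMI must be positive, got {bmi}")
    if bmi < 25.0:
        return "I"
    if bmi < 30.0:
        return "II"
    return "III"


def classify_ctd_group(total_volume_ml: float) -> str:
    """Drainage stratum: I below 500 mL over 18 h, II at or above 500 mL."""
    if total_volume_ml < 0:
        raise InvalidInputError("total drainage volume must be >= 0")
    return "I" if total_volume_ml < 500.0 else "II"
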