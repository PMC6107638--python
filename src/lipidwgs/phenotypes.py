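"""Lipid phenotype harmonization.

LDL-C is derived with the Friedewald equation when triglycerides are
below 400 mg/dl, otherwise a directly measured value must be supplied.
On lipid-lowering (statin) therapy the pre-treatment level is estimated
by dividing total cholesterol by 0.8 and LDL-C by 0.7. Triglycerides are
natural-log transformed for analysis. All units are mg/dl.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

FRIEDEWALD_TG_LIMIT = 400.0  # mg/dl; above this the equation is invalid
STATIN_TC_FACTOR = 0.8
STATIN_LDL_FACTOR = 0.7


class FriedewaldInvalid(ValueError):
    """Triglycerides at or above 400 mg/dl: use directly measured LDL-C."""


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float:
    """LDL-C = TC - HDL-C - TG/5 (mg/dl), valid for TG < 400 mg/dl.

    Raises :class:`FriedewaldInvalid` when TG >= 400; propagates NaN for
    missing inputs.
    """
    if any(x is None for x in (tc, hdl, tg)):
        return math.nan
    if math.isnan(tc) or math.isnan(hdl) or math.isnan(tg):
        return math.nan
    if tg >= FRIEDEWALD_TG_LIMIT:
        raise FriedewaldInvalid(
            f"TG {tg:g} mg/dl >= {FRIEDEWALD_TG_LIMIT:g}: use directly measured LDL-C"
        )
    return tc - hdl - tg / 5.0


def adjust_for_statin(tc: float, ldl: float, on_statin: bool) -> tuple[float, float]:
    """Undo the average statin effect: TC/0.8 and LDL-C/0.7 for treated samples."""
    if on_statin:
        return tc / STATIN_TC_FACTOR, ldl / STATIN_LDL_FACTOR
    return tc, ldl


def transform_triglycerides(tg: float) -> float:
    """Natural log of TG; non-positive or missing values map to NaN."""
    if tg is None or math.isnan(tg) or tg <= 0:
        return math.nan
    return math.log(tg)


def prepare_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Harmonize a raw lipid table into analysis-ready traits.

    Expects columns ``tc``, ``hdl``, ``tg``, ``on_statin`` and optionally
    ``ldl_measured``. Adds:

    - ``ldl``: Friedewald-derived when TG < 400, else the measured value
      (``ldl_source`` records which); NaN when neither is available.
    - ``tc_adj``, ``ldl_adj``: statin-adjusted levels.
    - ``ln_tg``: natural-log triglycerides.
    - ``adjusted``: provenance flag, set to 1.

    Re-running on an already-prepared table (``adjusted == 1``) raises,
    so the statin correction can never be applied twice.
    """
    if "adjusted" in table.columns and (table["adjusted"] == 1).any():
        raise ValueError("phenotype table already carries adjusted == 1; refusing to re-adjust")
    for col in ("tc", "hdl", "tg", "on_statin"):
        if col not in table.columns:
            raise KeyError(f"phenotype table lacks required column {col!r}")

    out = table.copy()
    tc = out["tc"].to_numpy(dtype=float)
    hdl = out["hdl"].to_numpy(dtype=float)
    tg = out["tg"].to_numpy(dtype=float)
    measured = (
        out["ldl_measured"].to_numpy(dtype=float)
        if "ldl_measured" in out.columns
        else np.full(len(out), np.nan)
    )

    derivable = (tg < FRIEDEWALD_TG_LIMIT) & ~np.isnan(tc) & ~np.isnan(hdl) & ~np.isnan(tg)
    ldl = np.where(derivable, tc - hdl - tg / 5.0, measured)
    source = np.where(derivable, "friedewald", np.where(~np.isnan(measured), "measured", "missing"))

    on_statin = out["on_statin"].to_numpy().astype(bool)
    tc_adj = np.where(on_statin, tc / STATIN_TC_FACTOR, tc)
    ldl_adj = np.where(on_statin, ldl / STATIN_LDL_FACTOR, ldl)

    with np.errstate(divide="ignore", invalid="ignore"):
        ln_tg = np.where(tg > 0, np.log(tg), np.nan)

    out["ldl"] = ldl
    out["ldl_source"] = source
    out["tc_adj"] = tc_adj
    out["ldl_adj"] = ldl_adj
    out["ln_tg"] = ln_tg
    out["adjusted"] = 1
    return out
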