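"""Unit conversions for glycaemic measurements.

HbA1c is reported on two scales: IFCC (mmol/mol) and NGSP (%). The two are
related by the NGSP master-equation linear map, which this module applies in
both directions. OGTT analytes are converted from SI units (mmol/l glucose,
pmol/l insulin) to the conventional units (mg/dl, uU/ml) in which the
insulin-sensitivity index literature states its formulas.
"""

from __future__ import annotations

# NGSP master equation: % = 0.09148 * (mmol/mol) + 2.152
NGSP_SLOPE = 0.09148
NGSP_INTERCEPT = 2.152

# glucose molar mass 180.16 g/mol -> mmol/l * 18.016 = mg/dl
GLUCOSE_MMOL_L_TO_MG_DL = 18.016
# insulin: 1 uU/ml = 6.0 pmol/l (conventional conversion; literature spans 6.0-6.945)
INSULIN_PMOL_L_PER_UU_ML = 6.0


def hba1c_mmol_to_percent(x: float) -> float:
    """Convert HbA1c from IFCC mmol/mol to NGSP percent.

    Parameters
    ----------
    x : float
        HbA1c in mmol/mol; must be positive.

    Returns
    -------
    float
        HbA1c on the NGSP % scale.
    """
    if x <= 0:
        raise ValueError(f"HbA1c must be positive, got {x} mmol/mol")
    return NGSP_SLOPE * x + NGSP_INTERCEPT


def hba1c_percent_to_mmol(x: float) -> float:
    """Convert HbA1c from NGSP percent to IFCC mmol/mol (inverse linear map)."""
    if x <= 0:
        raise ValueError(f"HbA1c must be positive, got {x} %")
    return (x - NGSP_INTERCEPT) / NGSP_SLOPE


def glucose_mmol_to_mgdl(x: float) -> float:
    """Convert plasma glucose from mmol/l to mg/dl."""
    return x * GLUCOSE_MMOL_L_TO_MG_DL


def insulin_pmol_to_uu_ml(x: float) -> float:
    """Convert plasma insulin from pmol/l to uU/ml."""
    return x / INSULIN_PMOL_L_PER_UU_ML
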