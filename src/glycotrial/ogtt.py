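"""Insulin-sensitivity and secretion indices from 2-hour OGTT curves.

Glucose and insulin are sampled every 30 minutes for 2 hours after a glucose
load. The Matsuda index estimates whole-body insulin sensitivity from the
fasting values and the mean of all sampled values; the insulinogenic index
estimates early-phase insulin secretion from the 0-30 min increments; their
product is the disposition index, beta-cell output relative to the
prevailing insulin resistance. Formulas are stated in conventional units
(glucose mg/dl, insulin uU/ml); SI inputs are converted first and the
constants used are recorded so results are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import units

EXPECTED_TIMES = (0, 30, 60, 90, 120)


class UndefinedIndexError(ArithmeticError):
    """An index is undefined for this curve (zero or degenerate inputs)."""


@dataclass(frozen=True)
class OGTTCurve:
    """Timed glucose/insulin samples from one OGTT.

    ``glucose`` in mmol/l and ``insulin`` in pmol/l unless
    ``si_units=False``, in which case mg/dl and uU/ml.
    """

    times: tuple[float, ...]
    glucose: tuple[float, ...]
    insulin: tuple[float, ...]
    si_units: bool = True
    units_note: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, float)
        g = np.asarray(self.glucose, float)
        i = np.asarray(self.insulin, float)
        if not (len(t) == len(g) == len(i)):
            raise ValueError("times, glucose and insulin must have equal length")
        if len(t) < 3:
            raise ValueError("need the fasting sample and at least 2 post-load samples")
        if t[0] != 0:
            raise ValueError("fasting sample (t=0) required")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(g <= 0):
            raise ValueError("glucose must be positive everywhere")
        if np.any(i < 0):
            raise ValueError("insulin must be non-negative")


def convert_units(curve: OGTTCurve) -> OGTTCurve:
    """Convert an SI curve to conventional units (mg/dl, uU/ml).

    Idempotent: a curve already in conventional units passes through. The
    conversion constants are recorded in ``units_note``.
    """
    if not curve.si_units:
        return curve
    g = tuple(units.glucose_mmol_to_mgdl(x) for x in curve.glucose)
    i = tuple(units.insulin_pmol_to_uu_ml(x) for x in curve.insulin)
    note = {
        "glucose": f"mg/dl = mmol/l x {units.GLUCOSE_MMOL_L_TO_MG_DL}",
        "insulin": f"uU/ml = pmol/l / {units.INSULIN_PMOL_L_PER_UU_ML}",
    }
    return OGTTCurve(times=curve.times, glucose=g, insulin=i, si_units=False, units_note=note)


def matsuda_index(curve: OGTTCurve) -> float:
    """Whole-body insulin-sensitivity index.

    10000 / sqrt(G0 * I0 * Gmean * Imean) in conventional units, with
    Gmean/Imean arithmetic means over all sampled values including t=0.
    """
    c = convert_units(curve)
    g = np.asarray(c.glucose, float)
    i = np.asarray(c.insulin, float)
    g0, i0 = g[0], i[0]
    gm, im = g.mean(), i.mean()
    product = g0 * i0 * gm * im
    if product <= 0:
        raise UndefinedIndexError("Matsuda index undefined: zero glucose or insulin term")
    return 10000.0 / float(np.sqrt(product))


def insulinogenic_index(curve: OGTTCurve) -> float:
    """Early-phase secretion: (I30 - I0) / (G30 - G0) in conventional units."""
    c = convert_units(curve)
    times = list(c.times)
    if 30 not in times:
        raise UndefinedIndexError("insulinogenic index requires a 30 min sample")
    k = times.index(30)
    dg = c.glucose[k] - c.glucose[0]
    if dg == 0:
        raise UndefinedIndexError("insulinogenic index undefined: G30 equals G0")
    return (c.insulin[k] - c.insulin[0]) / dg


def auc_ratio_secretion(curve: OGTTCurve) -> float:
    """Alternative secretion measure: AUC(insulin) / AUC(glucose), trapezoidal, 0-120 min."""
    c = convert_units(curve)
    t = np.asarray(c.times, float)
    auc_i = float(np.trapezoid(np.asarray(c.insulin, float), t))
    auc_g = float(np.trapezoid(np.asarray(c.glucose, float), t))
    if auc_g <= 0:
        raise UndefinedIndexError("glucose AUC is non-positive")
    return auc_i / auc_g


def disposition_index(curve: OGTTCurve, secretion_measure: str = "insulinogenic") -> float:
    """Matsuda index x a secretion measure.

    ``secretion_measure`` is ``"insulinogenic"`` (default, 0-30 min
    increment ratio) or ``"auc_ratio"`` (trapezoidal insulin/glucose AUC
    ratio over 0-120 min).
    """
    measures = {"insulinogenic": insulinogenic_index, "auc_ratio": auc_ratio_secretion}
    if secretion_measure not in measures:
        raise ValueError(f"unknown secretion measure {secretion_measure!r}; choose from {sorted(measures)}")
    return matsuda_index(curve) * measures[secretion_measure](curve)


def curve_from_columns(
    glucose: Sequence[float], insulin: Sequence[float], times: Sequence[float] = EXPECTED_TIMES
) -> OGTTCurve:
    """Build a curve from per-timepoint columns, dropping missing post-load samples."""
    keep = [
        (t, g, i)
        for t, g, i in zip(times, glucose, insulin)
        if not (np.isnan(g) or np.isnan(i))
    ]
    if not keep or keep[0][0] != 0:
        raise ValueError("fasting sample (t=0) required")
    t, g, i = zip(*keep)
    return OGTTCurve(times=t, glucose=g, insulin=i)
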