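"""Mixing study and modified Bethesda titration for ADAMTS13 inhibitors.

Heat-inactivated patient plasma is mixed 1:1 with pooled normal plasma (PNP)
and the residual ADAMTS13 activity (RA, percent of the PNP control) is
measured.  One Bethesda unit (BU) is the amount of inhibitor that reduces
activity by half, giving the classical relation

    RA = 100 * 2**(-BU)    i.e.    BU = log2(100 / RA)

which is quantitative in the band 25% <= RA <= 75% (inclusive).  Samples
with strong inhibitors are pre-diluted with saline; the titre in BU/mL is
the in-band BU multiplied by the fold-dilution.  Three-tier classification:
below 0.5 BU/mL non-inhibitory, 0.5-5 low, above 5 strong (exactly 5 counts
as low).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import AssayError

#: Quantifiable residual-activity band (percent, inclusive).
RA_BAND = (25.0, 75.0)

#: BU/mL class boundaries: < 0.5 non-inhibitory, <= 5 low, > 5 strong.
CLASS_BOUNDARIES = (0.5, 5.0)

CLASSES = ("non_inhibitory", "low", "strong")


@dataclass(frozen=True)
class MixingMeasurement:
    """One mixing-study measurement at a given saline pre-dilution."""

    patient_id: str
    dilution: float           # fold-dilution of patient plasma before the 1:1 mix
    mix_activity: float       # % of normal, measured on the mix
    pnp_activity: float       # % of normal, PNP control run alongside

    def __post_init__(self) -> None:
        if self.dilution < 1:
            raise AssayError("bad_dilution", "dilution must be >= 1")


@dataclass(frozen=True)
class BethesdaResult:
    """Inhibitor titre for one patient."""

    patient_id: str
    residual_activity: float      # % at the chosen dilution
    chosen_dilution: float
    bu_per_ml: float
    classification: str           # non_inhibitory | low | strong
    interpretation: str           # inhibitor_present | no_significant_inhibitor


def residual_activity(mix_activity: float, pnp_activity: float) -> float:
    """Residual activity RA = 100 * mix / control, in percent.

    Raises
    ------
    AssayError
        ``"invalid_control"`` when the PNP control activity is <= 0.
    """
    if pnp_activity <= 0:
        raise AssayError("invalid_control", f"pnp_activity {pnp_activity} <= 0")
    return 100.0 * mix_activity / pnp_activity


def bu_from_residual(ra: float) -> float:
    """Bethesda units at the tested dilution: BU = log2(100 / RA).

    ``bu_from_residual(50.0) == 1.0`` exactly; RA 100% gives 0 BU.

    Raises
    ------
    AssayError
        ``"no_residual_activity"`` when RA <= 0 (titre not quantifiable
        at this dilution; dilute further).
    """
    if ra <= 0:
        raise AssayError("no_residual_activity", "RA <= 0; dilute further")
    return math.log2(100.0 / ra)


def residual_from_bu(bu: float) -> float:
    """Inverse of :func:`bu_from_residual`: RA = 100 * 2**(-BU)."""
    return 100.0 * 2.0 ** (-bu)


def classify_inhibitor(bu_per_ml: float) -> str:
    """Three-tier class: < 0.5 non-inhibitory, 0.5-5 low (inclusive), > 5 strong."""
    if bu_per_ml < 0:
        raise AssayError("bad_titre", "BU/mL must be >= 0")
    lo, hi = CLASS_BOUNDARIES
    if bu_per_ml < lo:
        return "non_inhibitory"
    if bu_per_ml <= hi:
        return "low"
    return "strong"


def bethesda_titre(series: Sequence[MixingMeasurement]) -> BethesdaResult:
    """Pick the quantifiable dilution and compute the titre in BU/mL.

    Among dilutions whose RA lies in the inclusive 25-75% band, the one with
    RA closest to 50% wins (ties go to the lower dilution); the titre is
    ``bu_from_residual(RA) * dilution``.  When every RA exceeds 75% there is
    no clinically significant inhibitor (0 BU/mL).  When every RA falls below
    25% the ladder did not reach the quantifiable band.

    Raises
    ------
    AssayError
        ``"empty_series"``; ``"duplicate_dilution"``;
        ``"needs_further_dilution"`` when all RA < 25%.
    """
    if not series:
        raise AssayError("empty_series", "no mixing measurements")
    dilutions = [m.dilution for m in series]
    if len(set(dilutions)) != len(dilutions):
        raise AssayError("duplicate_dilution", "dilutions must be distinct")
    pid = series[0].patient_id

    ras = [(m, residual_activity(m.mix_activity, m.pnp_activity)) for m in series]
    lo, hi = RA_BAND
    in_band = [(m, ra) for m, ra in ras if lo <= ra <= hi]
    if in_band:
        m, ra = min(in_band, key=lambda t: (abs(t[1] - 50.0), t[0].dilution))
        bu = bu_from_residual(ra) * m.dilution
        return BethesdaResult(
            patient_id=pid,
            residual_activity=ra,
            chosen_dilution=m.dilution,
            bu_per_ml=bu,
            classification=classify_inhibitor(bu),
            interpretation="inhibitor_present",
        )
    if all(ra > hi for _, ra in ras):
        m, ra = min(ras, key=lambda t: t[0].dilution)
        return BethesdaResult(
            patient_id=pid,
            residual_activity=ra,
            chosen_dilution=m.dilution,
            bu_per_ml=0.0,
            classification="non_inhibitory",
            interpretation="no_significant_inhibitor",
        )
    raise AssayError(
        "needs_further_dilution",
        f"patient {pid}: all residual activities below {lo}%; extend the ladder",
    )


def titrate_cohort(mixing: pd.DataFrame) -> pd.DataFrame:
    """Run :func:`bethesda_titre` per patient over a mixing-series table.

    ``mixing`` columns: ``patient_id, dilution, mix_activity, pnp_activity``.
    Returns one row per patient: RA, chosen dilution, BU/mL and class.
    """
    rows = []
    for pid, sub in mixing.groupby("patient_id", sort=True):
        series = [
            MixingMeasurement(
                patient_id=str(pid),
                dilution=float(r.dilution),
                mix_activity=float(r.mix_activity),
                pnp_activity=float(r.pnp_activity),
            )
            for r in sub.itertuples(index=False)
        ]
        res = bethesda_titre(series)
        rows.append({
            "patient_id": res.patient_id,
            "residual_activity": res.residual_activity,
            "dilution": res.chosen_dilution,
            "bu_per_ml": res.bu_per_ml,
            "classification": res.classification,
            "interpretation": res.interpretation,
        })
    return pd.DataFrame(rows)
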