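"""Plate-ELISA processing: blank subtraction, duplicate averaging, cut-off
positivity calling, and standard-curve quantification.

The peptide ELISA measures antibody binding to each library peptide as an
optical density (OD).  Processing follows standard serology practice:

1. subtract the per-plate mean of the blank wells from every other well;
2. average duplicate wells, flagging discordant pairs;
3. derive a per-plate cut-off from negative-control wells as
   ``mean(NC) + k * SD(NC)`` (k = 3 by default);
4. call a sample positive when its corrected OD strictly exceeds the cut-off
   (a value exactly at the cut-off is negative).

Total-immunoglobulin plates are quantified against a four-parameter-logistic
(4PL) standard curve fitted per plate, with log-linear interpolation as a
fallback when the 4PL fit does not converge.

Well tables are plain :class:`pandas.DataFrame` objects with the columns of
:data:`PLATE_COLUMNS`; ``role`` is one of ``blank``, ``negative_control``,
``standard``, ``sample``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ElisaError
from .library import Peptide

PLATE_COLUMNS = (
    "plate_id", "well", "role", "patient_id", "analyte",
    "replicate_group", "od", "standard_conc",
)

ROLES = {"blank", "negative_control", "standard", "sample"}

#: Plasma reference ranges for total immunoglobulins (mg/mL).
IG_REFERENCE_RANGES = {"IgA": (1.1, 2.6), "IgM": (0.23, 1.4)}


def validate_plate_table(wells: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, roles and OD non-negativity; returns a copy."""
    missing = [c for c in PLATE_COLUMNS if c not in wells.columns]
    if missing:
        raise ElisaError("bad_plate_table", f"missing columns: {missing}")
    df = wells.copy()
    bad_roles = set(df["role"].unique()) - ROLES
    if bad_roles:
        raise ElisaError("bad_plate_table", f"unknown roles: {sorted(bad_roles)}")
    if (df["od"] < 0).any():
        raise ElisaError("bad_plate_table", "negative OD values")
    std = df["role"] == "standard"
    if std.any() and df.loc[std, "standard_conc"].isna().any():
        raise ElisaError("bad_plate_table", "standards without standard_conc")
    return df


def subtract_blanks(wells: pd.DataFrame) -> pd.DataFrame:
    """Subtract each plate's mean blank OD from every other well on the plate.

    Corrected values are floored at zero (with a warning when flooring
    occurs); blank wells themselves are set to exactly 0, which makes the
    operation idempotent.

    Raises
    ------
    ElisaError
        ``"missing_blanks"`` when a plate carries no blank well.
    """
    df = wells.copy()
    corrected = df["od"].astype(float).copy()
    n_floored = 0
    for plate, idx in df.groupby("plate_id").groups.items():
        sub = df.loc[idx]
        blanks = sub.index[sub["role"] == "blank"]
        if len(blanks) == 0:
            raise ElisaError("missing_blanks", f"plate {plate!r} has no blank wells")
        mean_blank = float(df.loc[blanks, "od"].mean())
        others = sub.index.difference(blanks)
        vals = df.loc[others, "od"].astype(float) - mean_blank
        n_floored += int((vals < 0).sum())
        corrected.loc[others] = vals.clip(lower=0.0)
        corrected.loc[blanks] = 0.0
    if n_floored:
        warnings.warn(
            f"{n_floored} wells fell below the blank mean; floored at 0",
            stacklevel=2,
        )
    df["od"] = corrected
    return df


def average_duplicates(
    wells: pd.DataFrame, spread_tolerance: float = 0.20
) -> pd.DataFrame:
    """Collapse replicate wells to per-group means with a discordance flag.

    Groups are ``(plate_id, replicate_group)``.  ``spread`` is the relative
    range ``(max - min) / mean``; a group is flagged ``discordant`` when its
    spread exceeds ``spread_tolerance`` (default 20%).  Discordant groups are
    kept, not dropped.  Singleton groups have spread 0.
    """
    rows = []
    for (plate, group), sub in wells.groupby(["plate_id", "replicate_group"],
                                             sort=True):
        ods = sub["od"].to_numpy(dtype=float)
        mean = float(ods.mean())
        rng = float(ods.max() - ods.min())
        spread = 0.0 if len(ods) == 1 or rng == 0 else (
            np.inf if mean == 0 else rng / mean
        )
        first = sub.iloc[0]
        rows.append({
            "plate_id": plate,
            "replicate_group": group,
            "role": first["role"],
            "patient_id": first["patient_id"],
            "analyte": first["analyte"],
            "standard_conc": first["standard_conc"],
            "mean_od": mean,
            "n_wells": len(ods),
            "spread": spread,
            "discordant": bool(spread > spread_tolerance),
        })
    return pd.DataFrame(rows)


def compute_cutoff(negative_controls: Sequence[float], k: float = 3.0) -> float:
    """Positivity cut-off ``mean(NC) + k * SD(NC)`` from corrected NC values.

    The standard deviation is the sample SD (ddof=1), taken as 0 for a single
    control.

    Raises
    ------
    ElisaError
        ``"missing_negative_controls"`` for an empty input.
    """
    nc = np.asarray(list(negative_controls), dtype=float)
    if nc.size == 0:
        raise ElisaError("missing_negative_controls", "no negative-control values")
    sd = float(nc.std(ddof=1)) if nc.size > 1 else 0.0
    return float(nc.mean()) + k * sd


@dataclass(frozen=True)
class BindingCall:
    """One patient x peptide positivity decision."""

    patient_id: str
    peptide: Peptide
    mean_od: float
    corrected_od: float
    cutoff: float
    positive: bool


def call_binding(
    patient_id: str, peptide: Peptide, mean_od: float, corrected_od: float,
    cutoff: float,
) -> BindingCall:
    """Positive iff the corrected OD *strictly* exceeds the cut-off."""
    return BindingCall(
        patient_id=patient_id,
        peptide=peptide,
        mean_od=mean_od,
        corrected_od=corrected_od,
        cutoff=cutoff,
        positive=bool(corrected_od > cutoff),
    )


def call_plates(
    wells: pd.DataFrame,
    library: Sequence[Peptide],
    k: float = 3.0,
    spread_tolerance: float = 0.20,
) -> pd.DataFrame:
    """Full peptide-ELISA calling: blanks -> duplicates -> cut-off -> calls.

    Returns one row per (patient, peptide) with columns ``patient_id,
    peptide, start, end, plate_id, corrected_od, cutoff, positive,
    discordant``.  The cut-off is computed per plate from that plate's
    negative-control wells (after blank subtraction, before averaging).
    """
    df = validate_plate_table(wells)
    df = subtract_blanks(df)
    by_name = {p.name: p for p in library}

    cutoffs = {}
    for plate, sub in df.groupby("plate_id"):
        nc = sub.loc[sub["role"] == "negative_control", "od"]
        if nc.empty:
            raise ElisaError(
                "missing_negative_controls", f"plate {plate!r} has no negative controls"
            )
        cutoffs[plate] = compute_cutoff(nc.to_numpy(), k=k)

    means = average_duplicates(df, spread_tolerance=spread_tolerance)
    samples = means[means["role"] == "sample"]
    rows = []
    for rec in samples.itertuples(index=False):
        pep = by_name.get(rec.analyte)
        if pep is None:
            raise ElisaError("unknown_peptide", f"analyte {rec.analyte!r} not in library")
        cut = cutoffs[rec.plate_id]
        rows.append({
            "patient_id": rec.patient_id,
            "peptide": pep.name,
            "start": pep.start,
            "end": pep.end,
            "plate_id": rec.plate_id,
            "corrected_od": rec.mean_od,
            "cutoff": cut,
            "positive": bool(rec.mean_od > cut),
            "discordant": rec.discordant,
        })
    out = pd.DataFrame(rows)
    return out.sort_values(["patient_id", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Standard-curve quantification (total IgM / IgA)
# ---------------------------------------------------------------------------

def four_pl(conc, bottom, top, ec50, hill):
    """Four-parameter logistic: OD as a saturating function of concentration."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / np.maximum(conc, 1e-12)) ** hill)


@dataclass
class StandardCurve:
    """A fitted, invertible calibration curve over a standard range."""

    kind: str                       # "4pl" or "loglinear"
    params: tuple[float, ...]       # 4PL parameters when kind == "4pl"
    conc_range: tuple[float, float]
    od_range: tuple[float, float]
    _standards: tuple[tuple[float, float], ...] = ()

    def od(self, conc: float) -> float:
        """Predicted OD at a concentration (forward direction)."""
        if self.kind == "4pl":
            return float(four_pl(conc, *self.params))
        logc = np.log([c for c, _ in self._standards])
        ods = [o for _, o in self._standards]
        return float(np.interp(np.log(max(conc, 1e-12)), logc, ods))

    def quantify(self, od: float) -> tuple[float, str]:
        """Invert the curve: ``(concentration, flag)``.

        ``flag`` is ``"ok"`` inside the standard range, ``"above_range"`` /
        ``"below_range"`` when the OD falls beyond the calibrated ODs
        (the returned value is then a clipped/extrapolated estimate).
        """
        lo_od, hi_od = self.od_range
        flag = "ok"
        if od > hi_od:
            flag = "above_range"
        elif od < lo_od:
            flag = "below_range"
        if self.kind == "4pl":
            bottom, top, ec50, hill = self.params
            od_c = float(np.clip(od, bottom + 1e-9, top - 1e-9))
            conc = ec50 / ((top - bottom) / (od_c - bottom) - 1.0) ** (1.0 / hill)
        else:
            logc = np.log([c for c, _ in self._standards])
            ods = np.asarray([o for _, o in self._standards])
            conc = float(np.exp(np.interp(od, ods, logc)))
        return float(conc), flag


def fit_standard_curve(
    standards: Sequence[tuple[float, float]]
) -> StandardCurve:
    """Fit a monotone 4PL calibration to ``(concentration, od)`` pairs.

    Requires at least four distinct concentrations whose mean ODs increase
    monotonically with concentration.  Falls back to log-linear interpolation
    when the nonlinear fit fails to converge.

    Raises
    ------
    ElisaError
        ``"bad_standards"`` for too few points or non-monotone standards.
    """
    pts = sorted((float(c), float(o)) for c, o in standards)
    concs = [c for c, _ in pts]
    if len(set(concs)) < 4:
        raise ElisaError("bad_standards", "need >= 4 distinct standard concentrations")
    # collapse replicate standards to their mean OD
    df = pd.DataFrame(pts, columns=["conc", "od"]).groupby("conc", as_index=False).mean()
    c = df["conc"].to_numpy()
    o = df["od"].to_numpy()
    diffs = np.diff(o)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ElisaError("bad_standards", "standard ODs are not monotone in concentration")
    if np.all(diffs < 0):
        raise ElisaError("bad_standards", "standard ODs decrease with concentration")

    mean_pts = tuple(zip(c.tolist(), o.tolist()))
    p0 = (float(o.min()), float(o.max()) * 1.05, float(np.median(c)), 1.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                four_pl, c, o, p0=p0, maxfev=20000,
                bounds=([0.0, 0.0, 1e-9, 0.1], [np.inf, np.inf, np.inf, 10.0]),
            )
        curve = StandardCurve(
            kind="4pl",
            params=tuple(float(x) for x in popt),
            conc_range=(float(c.min()), float(c.max())),
            od_range=(float(four_pl(c.min(), *popt)), float(four_pl(c.max(), *popt))),
            _standards=mean_pts,
        )
    except RuntimeError:
        curve = StandardCurve(
            kind="loglinear",
            params=(),
            conc_range=(float(c.min()), float(c.max())),
            od_range=(float(o.min()), float(o.max())),
            _standards=mean_pts,
        )
    return curve


@dataclass(frozen=True)
class IgQuantification:
    """Total-immunoglobulin concentration for one patient and Ig class."""

    patient_id: str
    ig_class: str
    concentration: float  # mg/mL
    in_reference_range: bool
    flag: str = "ok"


def quantify_ig_plates(wells: pd.DataFrame) -> list[IgQuantification]:
    """Quantify total-Ig sample wells against each plate's standard curve.

    ``analyte`` must name the Ig class (``IgM`` / ``IgA``); each plate must
    carry its own standards.  Blank subtraction and duplicate averaging are
    applied before fitting.
    """
    df = subtract_blanks(validate_plate_table(wells))
    means = average_duplicates(df)
    out = []
    for plate, sub in means.groupby("plate_id"):
        std = sub[sub["role"] == "standard"]
        if std.empty:
            raise ElisaError("bad_standards", f"plate {plate!r} has no standards")
        curve = fit_standard_curve(
            list(zip(std["standard_conc"].astype(float), std["mean_od"]))
        )
        for rec in sub[sub["role"] == "sample"].itertuples(index=False):
            conc, flag = curve.quantify(rec.mean_od)
            lo, hi = IG_REFERENCE_RANGES.get(rec.analyte, (np.nan, np.nan))
            out.append(IgQuantification(
                patient_id=rec.patient_id,
                ig_class=rec.analyte,
                concentration=conc,
                in_reference_range=bool(lo <= conc <= hi),
                flag=flag,
            ))
    return out
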