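"""Synthetic serology-cohort generator and recovery scoring.

Generates everything the analysis pipeline consumes — peptide-ELISA plate
tables, total-Ig plates, and Bethesda mixing series — from a latent truth
that is stored alongside, so every stage can be tested end to end without
patient data.

The generative model mirrors the structure the analysis assumes:

* each patient independently carries each catalog epitope with its
  population frequency (the default catalog is the set of shared epitope
  regions reported for an HIV-associated TTP cohort, with the published
  per-region positivity percentages as frequencies);
* a peptide's expected OD steps up by ``od_amplitude`` when it overlaps a
  carried epitope by at least ``min(min_overlap_for_signal, epitope length)``
  residues (a graded linear-overlap mode is available); Gaussian plate noise
  is added and wells are duplicated;
* each plate carries blank and negative-control wells; negative controls are
  sero-negative-plasma-like (baseline signal) by default, or plain buffer;
* inhibitor titres follow a three-component log-normal mixture
  (non-inhibitory / low / strong) and the mixing series obeys
  ``RA = 100 * 2**(-BU / dilution)`` plus activity noise;
* total IgM/IgA concentrations are log-normal and read out through a
  four-parameter-logistic plate response with its own standards.

All randomness flows from a single seed through one numpy Generator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .bethesda import classify_inhibitor
from .elisa import four_pl
from .errors import CohortError
from .epitope import EpitopeRegion
from .library import Peptide
from .reference import proximal_library

#: Default latent-epitope catalog: (start, end, population frequency).
#: Intervals are the cohort-shared epitope regions of the source study;
#: frequencies are the published positivity percentages of the matching
#: peptide-table rows (rounded to 2 dp).
DEFAULT_EPITOPE_CATALOG: tuple[tuple[int, int, float], ...] = (
    (75, 80, 1.00), (125, 139, 1.00), (169, 189, 0.70), (200, 224, 0.19),
    (260, 284, 0.49), (320, 345, 0.07), (340, 379, 0.09), (350, 379, 0.09),
    (445, 479, 0.43), (455, 469, 0.11), (475, 504, 0.21),
    (595, 619, 0.75), (625, 649, 0.51), (650, 669, 1.00),
)

#: Inhibitor-titre mixture: weights follow the published 17/17/19 of 53
#: split; medians 0.15 / 1.85 / 9.74 BU/mL (the two inhibitory medians are
#: the published ones; the non-inhibitory median is only bounded, < 0.5).
DEFAULT_BU_WEIGHTS = (17 / 53, 17 / 53, 19 / 53)
DEFAULT_BU_LOGNORMAL = (
    (float(np.log(0.15)), 0.50),
    (float(np.log(1.85)), 0.45),
    (float(np.log(9.74)), 0.30),
)

#: 4PL plate response used for the synthetic total-Ig ELISA.
IG_4PL = (0.05, 3.0, 1.2, 1.4)  # bottom OD, top OD, EC50 (mg/mL), Hill slope
IG_STANDARD_CONCS = (0.05, 0.15, 0.4, 1.0, 2.5, 6.0, 15.0)  # mg/mL

WELL_LABELS = tuple(f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13))


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic cohort (defaults are the study conditions)."""

    n_patients: int = 53
    seed: int = 0
    epitope_catalog: tuple[tuple[int, int, float], ...] = DEFAULT_EPITOPE_CATALOG
    # peptide-ELISA OD model (OD units at 490 nm)
    od_blank: float = 0.05          # instrument/substrate background
    od_baseline: float = 0.03       # nonspecific binding above blank
    od_amplitude: float = 0.90      # specific epitope signal
    noise_sd: float = Field(default=0.05, ge=0.0)
    min_overlap_for_signal: int = 10  # residues; halved peptide length
    signal_model: str = "step"      # "step" | "graded"
    nc_mode: str = "seronegative"   # "seronegative" | "buffer" negative controls
    nc_wells_per_plate: int = 8     # a 3*SD cut-off needs a stable SD estimate
    peptides_per_plate: int = 43    # 2 blanks + 8 NCs + 43 duplicated peptides = 96
    # inhibitor titres
    bu_weights: tuple[float, float, float] = DEFAULT_BU_WEIGHTS
    bu_lognormal: tuple[tuple[float, float], ...] = DEFAULT_BU_LOGNORMAL
    dilutions: tuple[float, ...] = (1, 2, 4, 8, 16, 32, 64, 128)
    activity_noise_sd: float = 2.0  # %-activity measurement noise
    pnp_mean: float = 100.0
    pnp_sd: float = 5.0
    # total immunoglobulins (mg/mL, log-normal)
    ig_median: Mapping[str, float] = {"IgM": 1.6, "IgA": 1.85}
    ig_sigma: Mapping[str, float] = {"IgM": 0.20, "IgA": 0.26}
    ig_noise_sd: float = 0.02       # OD noise on the Ig plates

    model_config = {"frozen": True}


@dataclass(frozen=True)
class PatientTruth:
    """Latent state planted for one synthetic patient."""

    patient_id: str
    epitopes: tuple[tuple[int, int], ...]
    bu_per_ml: float
    bu_component: int               # 0 non-inhibitory, 1 low, 2 strong
    ig_mg_ml: Mapping[str, float]

    @property
    def bu_class(self) -> str:
        return classify_inhibitor(self.bu_per_ml)


@dataclass(frozen=True)
class SyntheticTruth:
    patients: tuple[PatientTruth, ...]

    def to_json(self) -> str:
        return json.dumps(
            {"patients": [asdict(p) for p in self.patients]}, indent=1
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        return cls(patients=tuple(
            PatientTruth(
                patient_id=p["patient_id"],
                epitopes=tuple((int(s), int(e)) for s, e in p["epitopes"]),
                bu_per_ml=float(p["bu_per_ml"]),
                bu_component=int(p["bu_component"]),
                ig_mg_ml=dict(p["ig_mg_ml"]),
            )
            for p in raw["patients"]
        ))


@dataclass
class SyntheticCohort:
    """Generated cohort: plate tables, mixing series, and the planted truth."""

    config: SyntheticConfig
    library: list[Peptide]
    peptide_plates: pd.DataFrame
    ig_plates: pd.DataFrame
    mixing: pd.DataFrame
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the CSV dialects the elisa/bethesda modules read + truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peptide_plates": outdir / "peptide_plates.csv",
            "ig_plates": outdir / "ig_plates.csv",
            "mixing": outdir / "mixing.csv",
            "truth": outdir / "truth.json",
        }
        # %.17g keeps float64 values exact through the CSV round trip
        self.peptide_plates.to_csv(paths["peptide_plates"], index=False,
                                   float_format="%.17g")
        self.ig_plates.to_csv(paths["ig_plates"], index=False, float_format="%.17g")
        self.mixing.to_csv(paths["mixing"], index=False, float_format="%.17g")
        paths["truth"].write_text(self.truth.to_json())
        return paths


def _signal_fraction(pep: Peptide, epitopes, cfg: SyntheticConfig) -> float:
    """Specific-binding fraction of ``od_amplitude`` for one peptide."""
    best = 0.0
    for (es, ee) in epitopes:
        ov = pep.overlap(es, ee)
        if ov == 0:
            continue
        e_len = ee - es + 1
        if cfg.signal_model == "graded":
            best = max(best, ov / pep.length)
        elif ov >= min(cfg.min_overlap_for_signal, e_len):
            return 1.0
    return best if cfg.signal_model == "graded" else 0.0


def generate_cohort(
    config: SyntheticConfig, library: Sequence[Peptide] | None = None
) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``config`` (reproducible from seed).

    Raises
    ------
    CohortError
        ``"empty_cohort"`` when ``n_patients`` < 1; ``"bad_mixture"`` when
        the BU mixture weights do not sum to 1.
    """
    if config.n_patients < 1:
        raise CohortError("empty_cohort", "n_patients must be >= 1")
    if abs(sum(config.bu_weights) - 1.0) > 1e-9:
        raise CohortError("bad_mixture", "bu_weights must sum to 1")
    lib = list(library) if library is not None else proximal_library()
    rng = np.random.default_rng(config.seed)
    cfg = config

    # --- latent truth, one patient at a time (fixed draw order) ----------
    patients = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        carried = tuple(
            (s, e) for (s, e, f) in cfg.epitope_catalog if rng.random() < f
        )
        comp = int(rng.choice(3, p=cfg.bu_weights))
        mu, sigma = cfg.bu_lognormal[comp]
        bu = float(rng.lognormal(mu, sigma))
        igs = {
            cls: float(rng.lognormal(np.log(cfg.ig_median[cls]), cfg.ig_sigma[cls]))
            for cls in ("IgM", "IgA")
        }
        patients.append(PatientTruth(pid, carried, bu, comp, igs))
    truth = SyntheticTruth(patients=tuple(patients))

    # --- peptide-ELISA plates --------------------------------------------
    def noisy(mean: float, sd: float) -> float:
        return float(max(0.0, mean + rng.normal(0.0, sd)))

    nc_mean = cfg.od_blank + (cfg.od_baseline if cfg.nc_mode == "seronegative" else 0.0)
    plate_rows = []
    for pt in patients:
        chunks = [
            lib[j : j + cfg.peptides_per_plate]
            for j in range(0, len(lib), cfg.peptides_per_plate)
        ]
        for ci, chunk in enumerate(chunks, start=1):
            plate = f"{pt.patient_id}_pep{ci}"
            wells = iter(WELL_LABELS)
            for b in (1, 2):
                plate_rows.append((plate, next(wells), "blank", "", "",
                                   f"blank{b}", noisy(cfg.od_blank, cfg.noise_sd / 4), ""))
            for n in range(1, cfg.nc_wells_per_plate + 1):
                plate_rows.append((plate, next(wells), "negative_control", "", "",
                                   f"nc{(n + 1) // 2}", noisy(nc_mean, cfg.noise_sd), ""))
            for pep in chunk:
                mean_od = (cfg.od_blank + cfg.od_baseline
                           + cfg.od_amplitude * _signal_fraction(pep, pt.epitopes, cfg))
                for _ in (1, 2):
                    plate_rows.append((
                        plate, next(wells), "sample", pt.patient_id, pep.name,
                        f"{pt.patient_id}|{pep.name}",
                        noisy(mean_od, cfg.noise_sd), "",
                    ))
    peptide_plates = pd.DataFrame(
        plate_rows,
        columns=["plate_id", "well", "role", "patient_id", "analyte",
                 "replicate_group", "od", "standard_conc"],
    )

    # --- total-Ig plates ---------------------------------------------------
    bottom, top, ec50, hill = IG_4PL
    ig_rows = []
    per_plate = 40  # 2 blanks + 14 standards + 80 sample wells = 96
    for cls in ("IgM", "IgA"):
        groups = [patients[j : j + per_plate] for j in range(0, len(patients), per_plate)]
        for ci, group in enumerate(groups, start=1):
            plate = f"{cls}_plate{ci}"
            wells = iter(WELL_LABELS)
            for b in (1, 2):
                ig_rows.append((plate, next(wells), "blank", "", "",
                                f"blank{b}", noisy(bottom, cfg.ig_noise_sd / 4), ""))
            for sc in IG_STANDARD_CONCS:
                for _ in (1, 2):
                    ig_rows.append((plate, next(wells), "standard", "", cls,
                                    f"std{sc}", noisy(float(four_pl(sc, *IG_4PL)) ,
                                                      cfg.ig_noise_sd), sc))
            for pt in group:
                mean_od = float(four_pl(pt.ig_mg_ml[cls], *IG_4PL))
                for _ in (1, 2):
                    ig_rows.append((plate, next(wells), "sample", pt.patient_id, cls,
                                    f"{pt.patient_id}|{cls}",
                                    noisy(mean_od, cfg.ig_noise_sd), ""))
    ig_plates = pd.DataFrame(
        ig_rows,
        columns=["plate_id", "well", "role", "patient_id", "analyte",
                 "replicate_group", "od", "standard_conc"],
    )

    # --- mixing series -----------------------------------------------------
    # Heat inactivation removes endogenous patient activity, so the mix
    # activity is PNP activity attenuated by the diluted inhibitor alone.
    mix_rows = []
    for pt in patients:
        pnp = float(np.clip(rng.normal(cfg.pnp_mean, cfg.pnp_sd), 60.0, 140.0))
        for d in cfg.dilutions:
            mix = pnp * 2.0 ** (-pt.bu_per_ml / d)
            mix = float(max(0.0, mix + rng.normal(0.0, cfg.activity_noise_sd)))
            mix_rows.append((pt.patient_id, float(d), mix, pnp))
    mixing = pd.DataFrame(
        mix_rows, columns=["patient_id", "dilution", "mix_activity", "pnp_activity"]
    )

    return SyntheticCohort(
        config=cfg, library=lib, peptide_plates=peptide_plates,
        ig_plates=ig_plates, mixing=mixing, truth=truth,
    )


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpitopeRecovery:
    patient_id: str
    planted: tuple[int, int]
    recovered: bool
    midpoint_distance: float  # 0 when the planted midpoint lies inside a core


@dataclass
class RecoveryReport:
    """Pipeline-output vs planted-truth comparison for a synthetic cohort."""

    epitopes: list[EpitopeRecovery]
    epitope_recovery_rate: float
    region_sensitivity: float   # planted epitopes overlapped by >= 1 region
    region_precision: float     # inferred regions overlapping >= 1 planted epitope
    bu_class_accuracy: float
    bu_relative_errors: dict[str, float]   # quantifiable patients only
    ig_relative_error: float
    midpoint_tolerance: float

    def to_dict(self) -> dict:
        return {
            "epitope_recovery_rate": self.epitope_recovery_rate,
            "region_sensitivity": self.region_sensitivity,
            "region_precision": self.region_precision,
            "bu_class_accuracy": self.bu_class_accuracy,
            "bu_median_relative_error": (
                float(np.median(list(self.bu_relative_errors.values())))
                if self.bu_relative_errors else float("nan")
            ),
            "ig_relative_error": self.ig_relative_error,
            "midpoint_tolerance": self.midpoint_tolerance,
            "n_planted_epitopes": len(self.epitopes),
        }


def _interval_distance(x: float, lo: int, hi: int) -> float:
    if lo <= x <= hi:
        return 0.0
    return lo - x if x < lo else x - hi


def score_recovery(
    truth: SyntheticTruth,
    regions_by_patient: Mapping[str, Sequence[EpitopeRegion]],
    bethesda: pd.DataFrame | None = None,
    ig_quants: Sequence | None = None,
    midpoint_tolerance: float = 5.0,
) -> RecoveryReport:
    """Score pipeline output against the planted truth.

    A planted epitope is *recovered* when an inferred region overlaps it and
    the planted midpoint lies inside — or within ``midpoint_tolerance``
    residues of — that region's core interval.  (Adjacent planted epitopes
    fuse into one positive run, so the recovered core is compared as an
    interval rather than midpoint-to-midpoint.)  BU titres are scored by
    class accuracy over all patients and relative error over patients with a
    quantifiable inhibitor; Ig concentrations by mean relative error.
    """
    recoveries = []
    n_overlapped = 0
    n_regions = 0
    n_matched_regions = 0
    for pt in truth.patients:
        regs = list(regions_by_patient.get(pt.patient_id, ()))
        n_regions += len(regs)
        for reg in regs:
            if any(min(reg.end, ee) >= max(reg.start, es) for es, ee in pt.epitopes):
                n_matched_regions += 1
        for (es, ee) in pt.epitopes:
            mid = (es + ee) / 2.0
            overlapping = [
                r for r in regs if min(r.end, ee) >= max(r.start, es)
            ]
            if overlapping:
                n_overlapped += 1
                dist = min(
                    _interval_distance(mid, r.core_start, r.core_end)
                    for r in overlapping
                )
            else:
                dist = float("inf")
            recoveries.append(EpitopeRecovery(
                patient_id=pt.patient_id, planted=(es, ee),
                recovered=bool(dist <= midpoint_tolerance),
                midpoint_distance=dist,
            ))

    n_planted = len(recoveries)
    rate = (sum(r.recovered for r in recoveries) / n_planted) if n_planted else 1.0
    sensitivity = (n_overlapped / n_planted) if n_planted else 1.0
    precision = (n_matched_regions / n_regions) if n_regions else 1.0

    bu_acc = float("nan")
    bu_errs: dict[str, float] = {}
    if bethesda is not None and not bethesda.empty:
        by_pid = bethesda.set_index("patient_id")
        hits = 0
        for pt in truth.patients:
            row = by_pid.loc[pt.patient_id]
            if row["classification"] == pt.bu_class:
                hits += 1
            if row["interpretation"] == "inhibitor_present" and pt.bu_per_ml > 0:
                bu_errs[pt.patient_id] = abs(row["bu_per_ml"] - pt.bu_per_ml) / pt.bu_per_ml
        bu_acc = hits / len(truth.patients)

    ig_err = float("nan")
    if ig_quants:
        true_ig = {p.patient_id: p.ig_mg_ml for p in truth.patients}
        errs = [
            abs(q.concentration - true_ig[q.patient_id][q.ig_class])
            / true_ig[q.patient_id][q.ig_class]
            for q in ig_quants
            if q.patient_id in true_ig
        ]
        ig_err = float(np.mean(errs)) if errs else float("nan")

    return RecoveryReport(
        epitopes=recoveries,
        epitope_recovery_rate=rate,
        region_sensitivity=sensitivity,
        region_precision=precision,
        bu_class_accuracy=bu_acc,
        bu_relative_errors=bu_errs,
        ig_relative_error=ig_err,
        midpoint_tolerance=midpoint_tolerance,
    )
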