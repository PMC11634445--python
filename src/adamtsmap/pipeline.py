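"""End-to-end orchestration: design -> simulate/ingest -> call -> map ->
bethesda -> report, reproducible from a single config and seed.

Every artifact lands in one run directory together with a machine-readable
manifest recording the package version, the full configuration and the files
written.  Reruns of the same config produce byte-identical outputs (the
manifest carries no timestamps; log lines go to stderr only).
"""

from __future__ import annotations

import json
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd
from pydantic import BaseModel

from . import __version__
from .bethesda import titrate_cohort
from .elisa import call_plates, quantify_ig_plates
from .epitope import (
    category_counts,
    classify_domains,
    cohort_summary,
    domain_reactivity_table,
    merge_positive_peptides,
    region_table,
    report_markdown,
)
from .errors import PipelineStageError
from .library import Peptide, read_library, write_library
from .reference import DOMAIN_TABLE, proximal_library
from .simulate import SyntheticConfig, generate_cohort, score_recovery


class RunConfig(BaseModel):
    """Configuration of one pipeline run.

    When ``plates_csv`` (and friends) are set the run ingests measured data;
    otherwise a synthetic cohort is generated from ``synthetic``.
    """

    out_dir: str
    seed: int = 0
    cutoff_k: float = 3.0
    shared_threshold: float = 0.5
    core_mode: str = "max_coverage"
    spread_tolerance: float = 0.20
    peptide_length: int = 20
    peptide_offset: int = 5
    # ingest mode (optional)
    plates_csv: str | None = None
    mixing_csv: str | None = None
    ig_plates_csv: str | None = None
    library_tsv: str | None = None
    # simulation mode
    synthetic: SyntheticConfig | None = None


def _log(msg: str) -> None:
    ts = datetime.now(timezone.utc).strftime("%H:%M:%S")
    print(f"[adamtsmap {ts}] {msg}", file=sys.stderr)


def _stage(name: str, fn: Callable):
    try:
        return fn()
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineStageError(name, exc) from exc


def regions_and_profiles(
    calls: pd.DataFrame,
    domains: Sequence[tuple[str, int, int]] = DOMAIN_TABLE,
    core_mode: str = "max_coverage",
):
    """Per-patient epitope regions and domain-reactivity profiles."""
    regions_by_patient = {}
    profiles = []
    for pid, sub in calls.groupby("patient_id", sort=True):
        regions_by_patient[str(pid)] = merge_positive_peptides(sub, core_mode)
        profiles.append(classify_domains(sub, domains, patient_id=str(pid)))
    return regions_by_patient, profiles


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute the whole pipeline; returns the paths of every artifact."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # -- design ------------------------------------------------------------
    def _design() -> list[Peptide]:
        if config.library_tsv:
            if not Path(config.library_tsv).exists():
                raise FileNotFoundError(config.library_tsv)
            return read_library(config.library_tsv)
        return proximal_library(config.peptide_length, config.peptide_offset)

    library = _stage("design", _design)
    paths["library_fasta"] = out / "library.fasta"
    paths["library_tsv"] = out / "library.tsv"
    write_library(library, paths["library_fasta"], paths["library_tsv"])
    _log(f"design: {len(library)} peptides")

    # -- simulate / ingest ---------------------------------------------------
    truth = None
    if config.plates_csv:
        def _ingest():
            frames = {}
            for key, p in (
                ("plates", config.plates_csv),
                ("mixing", config.mixing_csv),
                ("ig", config.ig_plates_csv),
            ):
                if p is None:
                    frames[key] = None
                    continue
                if not Path(p).exists():
                    raise FileNotFoundError(p)
                frames[key] = pd.read_csv(p, keep_default_na=False,
                                          na_values=[""],
                                          float_precision="round_trip")
            return frames

        frames = _stage("ingest", _ingest)
        plates, mixing, ig_plates = frames["plates"], frames["mixing"], frames["ig"]
        _log(f"ingest: {len(plates)} plate wells")
    else:
        syn_cfg = config.synthetic or SyntheticConfig(seed=config.seed)
        if syn_cfg.seed != config.seed:
            syn_cfg = syn_cfg.model_copy(update={"seed": config.seed})
        cohort = _stage("simulate", lambda: generate_cohort(syn_cfg, library))
        written = cohort.write(out)
        paths.update({f"sim_{k}": v for k, v in written.items()})
        plates, mixing, ig_plates = (
            cohort.peptide_plates, cohort.mixing, cohort.ig_plates
        )
        truth = cohort.truth
        _log(f"simulate: {syn_cfg.n_patients} patients, seed {syn_cfg.seed}")

    # -- call ----------------------------------------------------------------
    calls = _stage(
        "call",
        lambda: call_plates(plates, library, k=config.cutoff_k,
                            spread_tolerance=config.spread_tolerance),
    )
    paths["calls"] = out / "calls.tsv"
    calls.to_csv(paths["calls"], sep="\t", index=False)
    _log(f"call: {int(calls['positive'].sum())} positive of {len(calls)} calls")

    # -- map -----------------------------------------------------------------
    def _map():
        regions_by_patient, profiles = regions_and_profiles(
            calls, DOMAIN_TABLE, config.core_mode
        )
        summary = cohort_summary(regions_by_patient, config.shared_threshold)
        return regions_by_patient, profiles, summary

    regions_by_patient, profiles, summary = _stage("map", _map)
    paths["regions"] = out / "regions.tsv"
    region_table(summary).to_csv(paths["regions"], sep="\t", index=False)
    paths["categories"] = out / "categories.tsv"
    category_counts(profiles).to_csv(paths["categories"], sep="\t", index=False)
    paths["domain_reactivity"] = out / "domain_reactivity.tsv"
    domain_reactivity_table(profiles).to_csv(
        paths["domain_reactivity"], sep="\t", index=False
    )
    _log(f"map: {len(summary)} cohort regions")

    # -- bethesda ------------------------------------------------------------
    if mixing is not None:
        bu = _stage("bethesda", lambda: titrate_cohort(mixing))
        paths["bethesda"] = out / "bethesda.tsv"
        bu.to_csv(paths["bethesda"], sep="\t", index=False)
        _log(f"bethesda: {len(bu)} titres")
    else:
        bu = None

    # -- total Ig ------------------------------------------------------------
    if ig_plates is not None:
        ig = _stage("ig_quant", lambda: quantify_ig_plates(ig_plates))
        paths["ig"] = out / "ig.tsv"
        pd.DataFrame([
            {"patient_id": q.patient_id, "ig_class": q.ig_class,
             "concentration_mg_ml": q.concentration,
             "in_reference_range": q.in_reference_range, "flag": q.flag}
            for q in ig
        ]).to_csv(paths["ig"], sep="\t", index=False)
    else:
        ig = None

    # -- report + recovery ----------------------------------------------------
    paths["report"] = out / "report.md"
    paths["report"].write_text(report_markdown(summary, profiles))
    if truth is not None:
        rec = _stage(
            "recovery", lambda: score_recovery(truth, regions_by_patient, bu, ig)
        )
        paths["recovery"] = out / "recovery.json"
        paths["recovery"].write_text(json.dumps(rec.to_dict(), indent=1))
        _log(f"recovery: epitope rate {rec.epitope_recovery_rate:.3f}, "
             f"BU class accuracy {rec.bu_class_accuracy:.3f}")

    # -- manifest (no timestamps: reruns must be byte-identical) -------------
    manifest_config = json.loads(config.model_dump_json())
    manifest_config.pop("out_dir", None)  # run-specific, not part of the science
    manifest = {
        "package": "adamtsmap",
        "version": __version__,
        "config": manifest_config,
        "artifacts": {k: str(v.name) for k, v in paths.items()},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    _log(f"done: {len(paths)} artifacts in {out}")
    return paths
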