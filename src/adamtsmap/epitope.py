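"""Epitope-region deconvolution from peptide-binding calls.

A linear epitope shows up in an overlapping-peptide scan as a run of
consecutive positive peptides.  This module merges each patient's positive
peptides into maximal residue-overlapping regions, extracts a *core* epitope
per region (the sub-span covered by the most supporting peptides), classifies
per-patient domain reactivity, and pools regions across a cohort into
shared / non-shared summaries.

Merging is purely interval-based: two positive peptides join the same region
iff they share at least one residue (adjacency without overlap does not
merge).  For a tiling with offset *o* and length *L*, a single epitope yields
a region whose interior residues are covered by up to ``L // o`` peptides;
the maximal-coverage core therefore narrows the region towards the epitope.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AdamtsMapError
from .library import Peptide
from .reference import PROXIMAL_DOMAINS

CORE_MODES = ("max_coverage", "strict_intersection")

#: Reactivity categories.  The first seven mirror the published per-side
#: layout (N-side pair MP/Dis, C-side pair Cys/Spa, all-four); ``mixed``
#: covers patterns spanning both sides without hitting all four domains,
#: so that the categories partition every possible reactivity subset.
CATEGORIES = (
    "MP_only", "Dis_only", "MP_and_Dis",
    "Cys_only", "Spa_only", "Cys_and_Spa",
    "all_four", "mixed", "none",
)


@dataclass(frozen=True)
class EpitopeRegion:
    """A merged run of overlapping positive peptides with its core sub-span."""

    start: int
    end: int
    supporting_peptides: tuple[str, ...]
    peptide_intervals: tuple[tuple[int, int], ...]
    core_start: int
    core_end: int
    patients_positive: int = 1
    cohort_size: int = 1
    shared: bool = False

    @property
    def frequency(self) -> float:
        return self.patients_positive / self.cohort_size

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def core_midpoint(self) -> float:
        return (self.core_start + self.core_end) / 2.0


@dataclass(frozen=True)
class DomainReactivityProfile:
    """Which proximal domains a patient's positive peptides touch."""

    patient_id: str
    reactive_domains: frozenset[str]
    category: str


def _coverage_counts(intervals: Sequence[tuple[int, int]]) -> Counter:
    counts: Counter = Counter()
    for s, e in intervals:
        for r in range(s, e + 1):
            counts[r] += 1
    return counts


def _core_from_intervals(
    intervals: Sequence[tuple[int, int]], mode: str = "max_coverage"
) -> tuple[int, int]:
    """Core sub-span of a set of chain-overlapping intervals.

    ``max_coverage``: the span of the residues covered by the maximal number
    of intervals.  A region tiling a single epitope has one contiguous argmax
    plateau; a region that fuses several epitopes (runs bridged by a shared
    residue) can have several plateaus, and the core then brackets all of
    them — a deliberately conservative interval.

    ``strict_intersection``: the common intersection of all intervals; falls
    back to ``max_coverage`` when the intersection is empty (runs longer than
    length/offset peptides have no common residue).
    """
    if mode not in CORE_MODES:
        raise AdamtsMapError("bad_core_mode", f"unknown core mode {mode!r}")
    if mode == "strict_intersection":
        s = max(i[0] for i in intervals)
        e = min(i[1] for i in intervals)
        if s <= e:
            return (s, e)
        # empty intersection: fall back to the coverage definition
    counts = _coverage_counts(intervals)
    cmax = max(counts.values())
    argmax = [r for r, c in counts.items() if c == cmax]
    return (min(argmax), max(argmax))


def merge_positive_peptides(
    calls: pd.DataFrame | Sequence, core_mode: str = "max_coverage"
) -> list[EpitopeRegion]:
    """Merge one patient's positive peptides into epitope regions.

    ``calls`` is either a DataFrame with columns ``peptide, start, end,
    positive`` or a sequence of :class:`~adamtsmap.elisa.BindingCall`.
    Maximal sets of positive peptides whose intervals chain-overlap (each
    shares >= 1 residue with the next) become one region; the region span is
    the union of member intervals.  Regions are returned sorted by start.
    The result is independent of input order and idempotent.
    """
    if isinstance(calls, pd.DataFrame):
        pos = [
            (str(r.peptide), int(r.start), int(r.end))
            for r in calls.itertuples(index=False)
            if bool(r.positive)
        ]
    else:
        pos = [
            (c.peptide.name, c.peptide.start, c.peptide.end)
            for c in calls
            if c.positive
        ]
    pos.sort(key=lambda t: (t[1], t[2], t[0]))

    regions: list[EpitopeRegion] = []
    cur: list[tuple[str, int, int]] = []
    cur_end = None
    for name, s, e in pos:
        if cur and s <= cur_end:  # >= 1 shared residue with the running union
            cur.append((name, s, e))
            cur_end = max(cur_end, e)
        else:
            if cur:
                regions.append(_finish_region(cur, core_mode))
            cur = [(name, s, e)]
            cur_end = e
    if cur:
        regions.append(_finish_region(cur, core_mode))
    return regions


def _finish_region(members: list[tuple[str, int, int]], core_mode: str) -> EpitopeRegion:
    intervals = tuple((s, e) for _, s, e in members)
    cs, ce = _core_from_intervals(intervals, core_mode)
    return EpitopeRegion(
        start=min(s for s, _ in intervals),
        end=max(e for _, e in intervals),
        supporting_peptides=tuple(n for n, _, _ in members),
        peptide_intervals=intervals,
        core_start=cs,
        core_end=ce,
    )


def core_epitope(region: EpitopeRegion, mode: str = "max_coverage") -> tuple[int, int]:
    """Recompute the core of an existing region under the given mode."""
    return _core_from_intervals(region.peptide_intervals, mode)


def classify_domains(
    calls: pd.DataFrame,
    domains: Sequence[tuple[str, int, int]],
    patient_id: str | None = None,
) -> DomainReactivityProfile:
    """Per-patient domain reactivity over the four proximal domains.

    A domain is reactive iff at least one positive peptide overlaps it;
    peptides straddling a boundary count for every domain they touch.
    The category partitions reactivity patterns: patterns confined to the
    N-side pair {MP, Dis} or the C-side pair {Cys, Spa} get the pairwise
    labels, all four domains give ``all_four``, anything else spanning both
    sides is ``mixed``.
    """
    if patient_id is None:
        ids = calls["patient_id"].unique() if "patient_id" in calls.columns else ["?"]
        if len(ids) != 1:
            raise AdamtsMapError("ambiguous_patient", "pass patient_id explicitly")
        patient_id = str(ids[0])

    reactive = set()
    for r in calls.itertuples(index=False):
        if not bool(r.positive):
            continue
        for label, ds, de in domains:
            if label in PROXIMAL_DOMAINS and min(int(r.end), de) >= max(int(r.start), ds):
                reactive.add(label)
    return DomainReactivityProfile(
        patient_id=patient_id,
        reactive_domains=frozenset(reactive),
        category=_category(frozenset(reactive)),
    )


def _category(reactive: frozenset[str]) -> str:
    n_side = reactive & {"MP", "Dis"}
    c_side = reactive & {"Cys", "Spa"}
    if not reactive:
        return "none"
    if len(reactive) == 4:
        return "all_four"
    if not c_side:
        return {frozenset({"MP"}): "MP_only",
                frozenset({"Dis"}): "Dis_only"}.get(n_side, "MP_and_Dis")
    if not n_side:
        return {frozenset({"Cys"}): "Cys_only",
                frozenset({"Spa"}): "Spa_only"}.get(c_side, "Cys_and_Spa")
    return "mixed"


def cohort_summary(
    regions_by_patient: Mapping[str, Sequence[EpitopeRegion]],
    shared_threshold: float = 0.5,
) -> list[EpitopeRegion]:
    """Pool per-patient regions into cohort-level epitope regions.

    Regions with identical supporting-peptide sets are pooled into one entry.
    A patient counts as positive for an entry when their positive-peptide set
    contains *all* of the entry's supporting peptides (so a patient whose own
    region is a superset still counts).  ``frequency`` is that count over the
    cohort size and an entry is ``shared`` iff frequency >= shared_threshold.
    Entries are sorted by start, then frequency descending.
    """
    if not regions_by_patient:
        raise AdamtsMapError("empty_cohort", "no patients")
    cohort_size = len(regions_by_patient)
    positive_sets = {
        pid: set().union(*(set(r.supporting_peptides) for r in regs)) if regs else set()
        for pid, regs in regions_by_patient.items()
    }
    pooled: dict[frozenset[str], EpitopeRegion] = {}
    for regs in regions_by_patient.values():
        for reg in regs:
            pooled.setdefault(frozenset(reg.supporting_peptides), reg)

    out = []
    for key, proto in pooled.items():
        n_pos = sum(1 for s in positive_sets.values() if key <= s)
        freq = n_pos / cohort_size
        out.append(replace(
            proto,
            patients_positive=n_pos,
            cohort_size=cohort_size,
            shared=bool(freq >= shared_threshold),
        ))
    out.sort(key=lambda r: (r.start, -r.frequency, r.end))
    return out


def category_counts(profiles: Iterable[DomainReactivityProfile]) -> pd.DataFrame:
    """Counts of each partition category over a cohort (sums to cohort size)."""
    counts = Counter(p.category for p in profiles)
    return pd.DataFrame(
        {"category": list(CATEGORIES), "n": [counts.get(c, 0) for c in CATEGORIES]}
    )


def percent(numerator: int, denominator: int) -> int:
    """Whole-number percentage as printed in cohort tables (53/59 -> 90)."""
    if denominator == 0:
        return 0
    return int(round(100.0 * numerator / denominator))


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

#: Published-style domain-reactivity rows, computed per side: the N-side rows
#: partition patients by their {MP, Dis} reactivity, the C-side rows by
#: {Cys, Spa}, and the all-four row is independent (rows sum to >100%).
PAPER_STYLE_ROWS = (
    ("Metalloprotease domain only", lambda r: r & {"MP", "Dis"} == {"MP"}),
    ("Disintegrin-like domain only", lambda r: r & {"MP", "Dis"} == {"Dis"}),
    ("Both metalloprotease and disintegrin-like domains together",
     lambda r: r >= {"MP", "Dis"}),
    ("Cysteine-rich domain only", lambda r: r & {"Cys", "Spa"} == {"Cys"}),
    ("Spacer domain only", lambda r: r & {"Cys", "Spa"} == {"Spa"}),
    ("Both cysteine-rich and spacer domains together",
     lambda r: r >= {"Cys", "Spa"}),
    ("All four domains together", lambda r: r >= {"MP", "Dis", "Cys", "Spa"}),
)


def domain_reactivity_table(
    profiles: Sequence[DomainReactivityProfile]
) -> pd.DataFrame:
    """The 7-row published-style domain-reactivity table with n/N and %."""
    n = len(profiles)
    rows = []
    for label, pred in PAPER_STYLE_ROWS:
        k = sum(1 for p in profiles if pred(p.reactive_domains))
        rows.append({"domains": label, "n_positive": k, "cohort_size": n,
                     "percent": percent(k, n)})
    return pd.DataFrame(rows)


def region_table(summary: Sequence[EpitopeRegion]) -> pd.DataFrame:
    """Cohort epitope-region table (deterministic ordering, whole percents)."""
    rows = []
    for r in sorted(summary, key=lambda r: (r.start, -r.frequency, r.end)):
        rows.append({
            "start": r.start,
            "end": r.end,
            "core_start": r.core_start,
            "core_end": r.core_end,
            "peptides": ",".join(r.supporting_peptides),
            "n_positive": r.patients_positive,
            "cohort_size": r.cohort_size,
            "percent": percent(r.patients_positive, r.cohort_size),
            "shared": r.shared,
        })
    return pd.DataFrame(
        rows,
        columns=["start", "end", "core_start", "core_end", "peptides",
                 "n_positive", "cohort_size", "percent", "shared"],
    )


def report_markdown(
    summary: Sequence[EpitopeRegion],
    profiles: Sequence[DomainReactivityProfile],
) -> str:
    """Markdown rendition of the region and domain-reactivity tables."""
    lines = ["# Epitope mapping report", "", "## Domain reactivity", ""]
    dom = domain_reactivity_table(profiles)
    lines.append("| Domains | n/N | % |")
    lines.append("| --- | --- | --- |")
    for r in dom.itertuples(index=False):
        lines.append(f"| {r.domains} | {r.n_positive}/{r.cohort_size} | {r.percent}% |")
    lines += ["", "## Epitope regions", ""]
    reg = region_table(summary)
    lines.append("| Region | Core | Peptides | n/N | % | Shared |")
    lines.append("| --- | --- | --- | --- | --- | --- |")
    for r in reg.itertuples(index=False):
        lines.append(
            f"| {r.start}-{r.end} | {r.core_start}-{r.core_end} | {r.peptides} "
            f"| {r.n_positive}/{r.cohort_size} | {r.percent}% | "
            f"{'yes' if r.shared else 'no'} |"
        )
    return "\n".join(lines) + "\n"
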