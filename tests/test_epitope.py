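"""Epitope deconvolution: merging, cores, domain classes, cohort pooling.

Region merging and core extraction are validated against an independent
per-residue coverage oracle (paint every positive peptide onto an array;
regions are maximal covered runs; cores are the argmax-coverage span).
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adamtsmap.epitope import (
    CATEGORIES,
    category_counts,
    classify_domains,
    cohort_summary,
    core_epitope,
    domain_reactivity_table,
    merge_positive_peptides,
    percent,
    region_table,
    report_markdown,
)
from adamtsmap.reference import DOMAIN_TABLE

from conftest import make_peptides


def calls_frame(peptides, positives):
    return pd.DataFrame({
        "patient_id": "pt1",
        "peptide": [p.name for p in peptides],
        "start": [p.start for p in peptides],
        "end": [p.end for p in peptides],
        "positive": [p.name in positives for p in peptides],
    })


def coverage_oracle(intervals, span=1000):
    """Brute-force oracle, independent of the sweep implementation: group
    intervals into connected components of the residue-overlap graph (BFS
    over all pairs), then take per-component spans and argmax-coverage cores
    from a per-residue paint array.  Adjacency without a shared residue does
    not connect."""
    n = len(intervals)
    seen = [False] * n
    components = []
    for i in range(n):
        if seen[i]:
            continue
        queue, comp = [i], []
        seen[i] = True
        while queue:
            a = queue.pop()
            comp.append(a)
            for b in range(n):
                if not seen[b] and min(intervals[a][1], intervals[b][1]) >= max(
                    intervals[a][0], intervals[b][0]
                ):
                    seen[b] = True
                    queue.append(b)
        components.append([intervals[j] for j in comp])

    regions = []
    for comp in components:
        cov = np.zeros(span + 2, dtype=int)
        for s, e in comp:
            cov[s : e + 1] += 1
        arg = np.flatnonzero(cov == cov.max())
        regions.append((
            min(s for s, _ in comp), max(e for _, e in comp),
            int(arg.min()), int(arg.max()),
        ))
    return sorted(regions)


class TestMerging:
    def test_two_overlapping_peptides_one_region(self):
        peps = make_peptides([115, 120])  # 115-134, 120-139
        regions = merge_positive_peptides(calls_frame(peps, {"pep1", "pep2"}))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (115, 139)
        assert regions[0].supporting_peptides == ("pep1", "pep2")

    def test_single_positive_peptide_region_is_its_span(self):
        peps = make_peptides([115, 120])
        (region,) = merge_positive_peptides(calls_frame(peps, {"pep1"}))
        assert (region.start, region.end) == (115, 134)
        assert (region.core_start, region.core_end) == (115, 134)

    def test_gap_without_residue_overlap_splits_regions(self):
        peps = make_peptides([100, 120, 140])  # 100-119 / 120-139 share nothing
        regions = merge_positive_peptides(calls_frame(peps, {"pep1", "pep3"}))
        assert [(r.start, r.end) for r in regions] == [(100, 119), (140, 159)]

    def test_adjacent_but_not_overlapping_not_merged(self):
        peps = make_peptides([100, 120])
        regions = merge_positive_peptides(calls_frame(peps, {"pep1", "pep2"}))
        assert len(regions) == 2

    @given(st.permutations(list(range(8))))
    def test_order_independent_and_idempotent(self, order):
        starts = [75, 80, 90, 140, 145, 150, 155, 300]
        peps = make_peptides(starts)
        df = calls_frame(peps, {p.name for p in peps}).iloc[list(order)]
        regions = merge_positive_peptides(df)
        canonical = merge_positive_peptides(calls_frame(peps, {p.name for p in peps}))
        assert [(r.start, r.end, r.supporting_peptides) for r in regions] == [
            (r.start, r.end, r.supporting_peptides) for r in canonical
        ]


class TestCore:
    def test_pairwise_intersection_core(self):
        peps = make_peptides([115, 120])
        (region,) = merge_positive_peptides(calls_frame(peps, {"pep1", "pep2"}))
        assert (region.core_start, region.core_end) == (120, 134)

    def test_five_consecutive_peptides_max_coverage_core(self):
        peps = make_peptides([645, 650, 655, 660, 665])
        (region,) = merge_positive_peptides(
            calls_frame(peps, {p.name for p in peps})
        )
        assert (region.start, region.end) == (645, 684)
        assert (region.core_start, region.core_end) == (660, 669)

    def test_strict_intersection_mode(self):
        peps = make_peptides([115, 120])
        (region,) = merge_positive_peptides(
            calls_frame(peps, {"pep1", "pep2"}), core_mode="strict_intersection"
        )
        assert (region.core_start, region.core_end) == (120, 134)
        # long runs have empty intersections; falls back to max coverage
        peps5 = make_peptides([645, 650, 655, 660, 665])
        (r5,) = merge_positive_peptides(
            calls_frame(peps5, {p.name for p in peps5}),
            core_mode="strict_intersection",
        )
        assert (r5.core_start, r5.core_end) == (660, 669)

    def test_core_lies_inside_region(self):
        peps = make_peptides([100, 105, 110, 130, 135])
        for region in merge_positive_peptides(calls_frame(peps, {p.name for p in peps})):
            assert region.start <= region.core_start <= region.core_end <= region.end
            assert core_epitope(region) == (region.core_start, region.core_end)

    @settings(max_examples=200)
    @given(
        starts=st.lists(st.integers(1, 400), min_size=1, max_size=30),
        length=st.integers(5, 30),
    )
    def test_matches_coverage_oracle(self, starts, length):
        intervals = [(s, s + length - 1) for s in starts]
        peps = make_peptides(starts, length=length)
        df = calls_frame(peps, {p.name for p in peps})
        got = [
            (r.start, r.end, r.core_start, r.core_end)
            for r in merge_positive_peptides(df)
        ]
        assert got == coverage_oracle(intervals)


class TestDomainClassification:
    def _frame(self, intervals):
        return pd.DataFrame({
            "patient_id": "pt1",
            "peptide": [f"p{i}" for i in range(len(intervals))],
            "start": [s for s, _ in intervals],
            "end": [e for _, e in intervals],
            "positive": True,
        })

    def test_mp_only(self):
        prof = classify_domains(self._frame([(75, 94), (100, 119)]), DOMAIN_TABLE)
        assert prof.reactive_domains == {"MP"}
        assert prof.category == "MP_only"

    def test_straddler_counts_for_both_domains(self):
        prof = classify_domains(self._frame([(275, 294)]), DOMAIN_TABLE)  # MP/Dis41
        assert prof.reactive_domains == {"MP", "Dis"}
        assert prof.category == "MP_and_Dis"

    def test_all_four(self):
        prof = classify_domains(
            self._frame([(75, 94), (290, 309), (445, 464), (600, 619)]), DOMAIN_TABLE
        )
        assert prof.category == "all_four"

    def test_mixed_pattern_gets_mixed_category(self):
        prof = classify_domains(
            self._frame([(75, 94), (600, 619)]), DOMAIN_TABLE
        )
        assert prof.reactive_domains == {"MP", "Spa"}
        assert prof.category == "mixed"

    def test_no_positives_none(self):
        df = self._frame([(75, 94)])
        df["positive"] = False
        assert classify_domains(df, DOMAIN_TABLE).category == "none"

    @given(st.sets(st.sampled_from(["MP", "Dis", "Cys", "Spa"])))
    def test_category_partitions_all_subsets(self, domains):
        anchor = {"MP": (80, 99), "Dis": (290, 309), "Cys": (450, 469),
                  "Spa": (560, 579)}
        df = self._frame([anchor[d] for d in sorted(domains)] or [(75, 94)])
        if not domains:
            df["positive"] = False
        cat = classify_domains(df, DOMAIN_TABLE).category
        assert cat in CATEGORIES


class TestCohortSummary:
    def _cohort(self, patient_positives, starts=(645, 650, 655, 660, 665)):
        peps = make_peptides(list(starts))
        return {
            pid: merge_positive_peptides(calls_frame(peps, set(pos)))
            for pid, pos in patient_positives.items()
        }

    def test_everyone_positive_frequency_one(self):
        names = {f"pep{i}" for i in range(1, 6)}
        regions = self._cohort({f"pt{i}": names for i in range(5)})
        (summary,) = cohort_summary(regions)
        assert (summary.start, summary.end) == (645, 684)
        assert summary.frequency == 1.0
        assert summary.shared

    def test_cohort_of_one_all_frequencies_one(self):
        regions = self._cohort({"pt1": {"pep1", "pep2"}})
        for r in cohort_summary(regions):
            assert r.frequency == 1.0

    def test_partial_frequency_not_shared(self):
        pos = {"pep1", "pep2", "pep3", "pep4", "pep5"}
        patients = {f"pt{i}": (pos if i < 3 else set()) for i in range(10)}
        (summary,) = cohort_summary(self._cohort(patients))
        assert summary.frequency == pytest.approx(0.3)
        assert not summary.shared

    def test_superset_patients_count_as_positive(self):
        # pt2's region uses a superset of pt1's peptides; pt2 still counts
        # towards the smaller region's frequency
        regions = self._cohort({
            "pt1": {"pep1", "pep2"},
            "pt2": {"pep1", "pep2", "pep3"},
        })
        summary = cohort_summary(regions)
        small = next(r for r in summary if r.supporting_peptides == ("pep1", "pep2"))
        assert small.patients_positive == 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(Exception, match="empty_cohort"):
            cohort_summary({})


class TestReportTables:
    def test_seven_paper_style_rows(self):
        profiles = [
            classify_domains(pd.DataFrame({
                "patient_id": "pt1", "peptide": ["a"], "start": [80],
                "end": [99], "positive": [True],
            }), DOMAIN_TABLE)
        ]
        table = domain_reactivity_table(profiles)
        assert len(table) == 7

    def test_percent_rounding_53_of_59(self):
        assert percent(53, 59) == 90
        assert percent(31, 53) == 58
        assert percent(0, 53) == 0

    def test_category_counts_sum_to_cohort_size(self):
        frames = {
            "pt1": [(75, 94)], "pt2": [(290, 309)], "pt3": [(600, 619)],
            "pt4": [(75, 94), (290, 309), (450, 469), (560, 579)],
        }
        profiles = [
            classify_domains(pd.DataFrame({
                "patient_id": pid,
                "peptide": [f"p{i}" for i in range(len(iv))],
                "start": [s for s, _ in iv],
                "end": [e for _, e in iv],
                "positive": True,
            }), DOMAIN_TABLE, patient_id=pid)
            for pid, iv in frames.items()
        ]
        assert category_counts(profiles)["n"].sum() == 4

    def test_empty_cohort_tables_are_empty(self):
        assert region_table([]).empty
        text = report_markdown([], [])
        assert "Epitope mapping report" in text

    def test_region_table_ordering_deterministic(self):
        peps = make_peptides([100, 200, 300])
        regions = {
            "pt1": merge_positive_peptides(calls_frame(peps, {"pep1", "pep3"})),
            "pt2": merge_positive_peptides(calls_frame(peps, {"pep2"})),
        }
        table = region_table(cohort_summary(regions))
        assert list(table["start"]) == sorted(table["start"])
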