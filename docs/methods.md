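# Methods

This note documents the models, conventions and design choices behind
`adamtsmap`, in the spirit of a statistical-methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and the reference fixture

All coordinates are 1-based and inclusive on the full-length ADAMTS13
numbering ("75–94" is a 20-mer).  The packaged reference
(`adamtsmap.reference`) is a *consensus reconstruction* of the two probed
proximal-domain blocks, assembled at import time from curated transcriptions
of the published peptide-table rows.  The published rows contain evident
typographical defects (spans whose length disagrees with the printed
sequence, duplicated substrings); each curated row records its correction,
and the assembly cross-checks every overlapping pair residue-for-residue —
any disagreement raises at import.  Two spans are covered by no published
peptide and are filled with `X`: residues 150–159 inside the
metalloprotease block and the untiled first thrombospondin repeat 385–439.
Nothing downstream depends on their identity, and the `ProteinRecord`
alphabet therefore admits `X` alongside the 20 amino acids.

The effective tiled regions are **75–384** and **440–684**.  The published
domain-grouping table prints 75–383 and 440–680, but the published peptide
coordinates (final peptides being full 20-mers ending at 384 and 684) fix
the tiled spans; 20-mers at offset 5 then reproduce the published
59 + 46 = 105 peptides exactly.

Domain boundaries were reconciled from the published compound peptide names
(MP 75–285, Dis 286–383, TSP1 384–439, Cys 440–549, Spa 550–680, TSP2
681–684): with these, peptides 40–43 of the first block straddle MP|Dis,
peptide 59 is Dis/TSP1, peptide 20 of the second block is Cys/Spa and
peptide 46 is Spa/TSP2 — matching every printed straddle name.

## Tiling and naming

Peptide *k* starts at `region.start + (k−1)·offset`; every peptide is full
length and the final peptide ends exactly at `region.end`, emitted with a
warning when the region length puts it off the offset grid (the packaged
geometry is on-grid).  Naming is domain-derived with continuous numbering
across a region; straddlers get compound labels with the N-terminal domain
first, including exact half-splits.

## ELISA processing

* **Blank subtraction** removes the per-plate mean blank OD from every other
  well, flooring at 0 with a warning; blank wells are set to exactly 0 so
  the operation is idempotent.
* **Duplicates** are averaged per `(plate, replicate_group)`; the relative
  range `(max−min)/mean` above 20 % (configurable) flags the pair
  discordant, which keeps but marks the value.
* **Cut-off**: `mean(NC) + k·SD(NC)` with k = 3 and the sample SD (0 for a
  single control).  The source protocol states that a per-plate cut-off and
  negative control exist but not the formula; mean + 3 SD is the standard
  serology convention.  A well is positive only when its corrected OD
  *strictly* exceeds the cut-off (ties are negative, per "greater than").
* **Standard curves** are four-parameter logistic
  `OD(c) = bottom + (top−bottom)/(1+(EC50/c)^h)`, fitted per plate by
  least squares with a log-linear interpolation fallback; inversion is
  analytic and values beyond the calibrated OD span are flagged
  `above_range`/`below_range`.  Reference ranges: IgA 1.1–2.6, IgM
  0.23–1.4 mg/mL.

## Epitope deconvolution

Positive peptides merge into a region iff they share at least one residue
(adjacency without overlap does not merge).  The **core** of a region is the
span of the residues covered by the maximal number of supporting peptides
(`max_coverage`, default).  For a single epitope on an offset-*o*,
length-*L* tiling this plateau has width ≥ *o* and narrows the region to
roughly the epitope's centre; for a region that fuses several epitopes the
coverage profile can carry several maximal plateaus and the core brackets
all of them — a deliberately conservative interval.  A
`strict_intersection` mode returns the common intersection of all
supporting peptides, falling back to max-coverage when the run is longer
than *L*/*o* peptides and the intersection is empty.  (The source study
highlights a 30-residue spacer epitope sequence against a 20-position
span — internally inconsistent; this package reports both core flavours
rather than guessing intent.)

Cohort pooling keys regions by their supporting-peptide set; a patient
counts toward a region when their positive set contains all of its
supporting peptides, so supersets count.  `shared` means frequency ≥ 0.5
(configurable; the published shared/non-shared criterion is unstated).
Domain reactivity marks a domain when any positive peptide overlaps it
(straddlers count for both sides).  The per-patient category partitions all
16 reactivity subsets: the published 8 labels cannot (e.g. {MP, Spa} has no
slot), so a ninth value `mixed` covers patterns spanning both the MP/Dis and
Cys/Spa pairs without being all-four; the published-style 7-row table is
additionally emitted, computed per side exactly as the published arithmetic
implies (N-side rows sum to the N-reactive patients, C-side rows likewise,
all-four independent).

## Bethesda titration

The classical relation RA = 100·2^(−BU) is adopted, consistent with the
definition that 1 BU halves ADAMTS13 activity in pooled normal plasma.
The quantifiable band is 25 % ≤ RA ≤ 75 % inclusive; among in-band
dilutions the RA closest to 50 % wins (ties to the lower dilution) and the
titre is BU × fold-dilution.  All-RA > 75 % means no significant inhibitor
(0 BU/mL); all-RA < 25 % raises `needs_further_dilution`.  Classification:
< 0.5 BU/mL non-inhibitory, 0.5–5 low, > 5 strong; exactly 5 is assigned to
low (the published table leaves 5 unassigned between "<5" and ">5").  The
reported dilution is the saline pre-dilution of the heat-inactivated
patient plasma before the 1:1 mix; heat inactivation is modelled in the
generator as zero endogenous patient activity, not as an assay-side
correction.

## Synthetic cohort model

The generator emulates the data *shape* the analysis assumes, not assay
biophysics.  Defaults (all in `SyntheticConfig`):

* **Epitope catalog** — the cohort-shared epitope regions of the source
  study, each carried independently per patient with the published
  per-region positivity percentage as its population frequency (the two
  100 % regions guarantee every patient at least two epitopes).
* **OD model** — OD = blank (0.05) + baseline (0.03) + amplitude (0.90) ·
  1[overlap ≥ min(10, epitope length)] + N(0, 0.05), floored at 0,
  duplicated into two wells.  The step threshold of 10 residues (half a
  peptide) reproduces the run-of-consecutive-positives structure of
  published peptide tables; the `min(·)` keeps epitopes shorter than 10
  residues detectable by the peptides that contain them.  A graded mode
  scales amplitude by overlap/length instead.  Plates hold 43 peptides in
  duplicate plus 2 blanks and 8 negative controls (sero-negative-like by
  default, buffer-like optionally); 8 NC wells because a 3·SD cut-off needs
  a stable SD estimate (the sample-SD CV is ≈ 39 % at n = 4 vs ≈ 26 % at
  n = 8, and an under-estimated SD inflates false-positive calls).
* **Inhibitors** — a three-component log-normal mixture with weights
  17/53, 17/53, 19/53 and medians 0.15 / 1.85 / 9.74 BU/mL (the two
  inhibitory medians are published; the non-inhibitory median is only
  bounded below 0.5), sigmas 0.50 / 0.45 / 0.30 back-fitted to the
  published ranges.  Mixing series follow RA = 100·2^(−BU/d) over the
  ladder d ∈ {1, 2, …, 128} plus N(0, 2) activity noise; the PNP control is
  N(100, 5) clipped to the assay's normal span.
* **Immunoglobulins** — log-normal with medians 1.6 (IgM) and 1.85 (IgA)
  mg/mL, sigmas matched to the published ranges, read out through a fixed
  4PL response with its own standards and N(0, 0.02) OD noise.

All randomness flows from one seed through a single numpy `Generator`;
same-seed runs are byte-identical on disk.

What the generator does **not** emulate — graded affinity, inter-plate
drift, edge effects, cross-reactivity, conformational epitopes, antigen
levels — bounds what passing tests show: they validate the *computational*
pipeline under the assumed data model, not assay performance on real
plasma.

## Recovery scoring

A planted epitope is *recovered* when an inferred region overlaps it and
the planted midpoint lies inside, or within 5 residues of, that region's
core interval.  The comparison is interval-based deliberately: adjacent or
overlapping planted epitopes (e.g. the spacer pair 625–649 and 650–669,
co-carried in about half the patients) fuse into one positive run at the
binary-call level, so no single recovered midpoint can represent both — the
fused core, however, brackets both planted centres, and distance-to-core is
the faithful form of the ±5-residue question.  The report also carries
region sensitivity and precision, BU class accuracy over all patients, BU
relative error over patients with a quantifiable (in-band) titre, and mean
Ig relative error.

## Numerical and interface choices

* Sample SD uses ddof = 1 throughout; a single negative control yields
  SD 0.
* Percentages in report tables are rounded to whole numbers (53/59 → 90 %).
* Plate tables carry a `patient_id` column beside `replicate_group`; sample
  identity is needed by the binding calls and cannot be recovered from the
  listed assay columns alone.
* CSVs written by the generator use `%.17g` and are read with
  round-trip float parsing, so simulate→write→ingest equals the in-memory
  path bit-for-bit.
* The run manifest records the package version, configuration (minus the
  run-specific output directory) and artifact list, and contains no
  timestamps: rerunning a config reproduces every artifact byte-for-byte.

## Problem sizes

The default synthetic cohort is 53 patients × 105 peptides in duplicate
(≈ 15 000 wells across 159 plates) plus an 8-point mixing ladder and two Ig
classes per patient; a full `run-all` completes in about a second, and the
complete test suite — including a 1 000-tiling oracle-equivalence sweep and
a 53-patient recovery run — in well under a minute.

## Known limitations

* The reference sequence is a curated reconstruction from printed tables,
  with two `X`-filled gaps; it is not a deposited accession.
* Cohort-level published percentages derive from patient plasma that is not
  public; they are emulated, not reproduced.
* The cut-off formula, shared/non-shared threshold and core definition are
  field conventions chosen where the source protocol is silent; all are
  configurable.
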