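"""Packaged ADAMTS13 proximal-domain reference fixture.

The epitope-mapping study this package supports probed two spans of human
ADAMTS13 — the metalloprotease–disintegrin block and the cysteine-rich–spacer
block — with a 105-peptide overlapping library.  No sequence accession was
deposited, so the reference shipped here is a *consensus reconstruction*: the
published peptide rows (name, printed coordinates, printed sequence) were
transcribed, obvious typographical defects reconciled against overlapping
neighbours, and the pieces overlaid into one numbered sequence.

Every curated row below is cross-checked at import time: wherever two rows
overlap they must agree residue-for-residue, and each row's length must match
its span.  Residues 150-159 are covered by no published peptide and are
filled with ``X`` placeholders; nothing downstream depends on their identity.

The effective tiled regions are 75-384 and 440-684.  The domain table prints
75-383 and 440-680, but the published peptide coordinates (last peptides
ending at 384 and 684) fix the tiled spans; 20-mers at offset 5 over those
spans reproduce the published 59 + 46 = 105 peptides exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .library import Peptide, ProteinRecord, TilingRegion, design_library


@dataclass(frozen=True)
class CuratedRow:
    """One published peptide-table row after curation.

    ``corrected`` marks rows whose printed span or sequence contained a
    typographical defect (length/span mismatch, duplicated substring); the
    curation applied is described in ``note``.
    """

    name: str
    start: int
    end: int
    sequence: str
    corrected: bool = False
    note: str = ""


# Metalloprotease / disintegrin-like block (published peptide rows).
_MP_DIS_ROWS = (
    CuratedRow("MP1", 75, 94, "AAGGILHLELLVAVGPDVFQ"),
    CuratedRow("MP1-MP8", 80, 129, "LHLELLVAVGPDVFQAHQEDTERYVLTNLNIGAELLRDPSLGAQFRVHLV"),
    CuratedRow("MP9-MP10", 115, 139, "LRDPSLGAQFRVHLVKMVILTEPEG"),
    CuratedRow(
        "MP9-MP12", 115, 149, "LRDPSLGAQFRVHLVKMVILTEPEGAPNITANLTS",
        corrected=True, note="printed span 125-149 is 25 residues for a 35-mer; "
        "the sequence extends MP9-MP10, so the span is 115-149",
    ),
    CuratedRow("MP18-MP21", 160, 194, "TINPEDDTDPGHADLVLYITRFDLELPDGNRQVRG"),
    CuratedRow("MP19-MP20", 165, 189, "DDTDPGHADLVLYITRFDLELPDGN"),
    CuratedRow("MP19-MP21", 165, 194, "DDTDPGHADLVLYITRFDLELPDGNRQVRG"),
    CuratedRow(
        "MP25-MP28", 195, 229, "VTQLGGACSPTWSCLITEDTGFDLGVTIAHEIGHS",
        corrected=True, note="printed 'GFDLGG' (36 chars for a 35-mer); the single-G "
        "form agrees with the MP29 row overlap",
    ),
    CuratedRow(
        "MP29-MP37", 215, 259, "GFDLGVTIAHEIGHSFGLEHDGAPGSGCGPSGHVMASDGAAPRAG",
        corrected=True, note="printed as MP29-MP34 215-249, but the 45-char sequence "
        "is overlap-consistent with both neighbours at span 215-259",
    ),
    CuratedRow("MP33-MP36", 235, 269, "DGAPGSGCGPSGHVMASDGAAPRAGLAWSPCSRRQ"),
    CuratedRow("MP37-MP39", 255, 284, "APRAGLAWSPCSRRQLLSLLSAGRARCVWD"),
    CuratedRow("MP37-MP/Dis40", 255, 289, "APRAGLAWSPCSRRQLLSLLSAGRARCVWDPPRPQ"),
    CuratedRow(
        "MP/Dis40-MP/Dis44", 270, 309, "LLSLLSAGRARCVWDPPRPQPGSAGHPPDAQPGLYYSANE",
        corrected=True, note="printed span 270-304 is 35 residues for a 40-mer; "
        "overlap with the 275-309 row fixes the span at 270-309",
    ),
    CuratedRow("MP/Dis41-Dis44", 275, 309, "SAGRARCVWDPPRPQPGSAGHPPDAQPGLYYSANE"),
    CuratedRow("MP/Dis43-Dis46", 285, 319, "PPRPQPGSAGHPPDAQPGLYYSANEQCRVAFGPKA"),
    CuratedRow("Dis44-Dis47", 290, 324, "PGSAGHPPDAQPGLYYSANEQCRVAFGPKAVACTF"),
    CuratedRow(
        "Dis45-Dis48", 295, 329, "HPPDAQPGLYYSANEQCRVAFGPKAVACTFAREHL",
        corrected=True, note="printed span 295-334 is 40 residues for a 35-mer",
    ),
    CuratedRow("Dis49-Dis52", 315, 349, "FGPKAVACTFAREHLDMCQALSCHTDPLDQSSCSR"),
    CuratedRow(
        "Dis49-Dis/TSP1 59", 315, 384,
        "FGPKAVACTFAREHLDMCQALSCHTDPLDQSSCSRLLVPLDGTECCGVEKWCSKGRCRSLVELTPIAAVH",
        corrected=True, note="printed end 383; the 70-char sequence and the final "
        "20-mer anchor force 315-384",
    ),
    CuratedRow(
        "Dis53-Dis/TSP1 59", 335, 384,
        "LSCHTDPLDQSSCSRLLVPLDGTECCGVEKWCSKGRCRSLVELTPIAAVH",
        corrected=True, note="printed end 383; 50 chars force 335-384",
    ),
    CuratedRow(
        "Dis/TSP1 59", 365, 384, "WCSKGRCRSLVELTPIAAVH",
        corrected=True, note="printed position '365-33'; a 20-mer from 365 ends at 384",
    ),
)

# Cysteine-rich / spacer block (published peptide rows).
_CYS_SPA_ROWS = (
    CuratedRow("Cys1-Cys4", 440, 474, "KTQLEFMSQQCARTDGQPLRSSPGGASFYHWGAAV"),
    CuratedRow("Cys2-Cys5", 445, 479, "FMSQQCARTDGQPLRSSPGGASFYHWGAAVPHSQG"),
    CuratedRow(
        "Cys3-Cys6", 450, 484, "CARTDGQPLRSSPGGASFYHWGAAVPHSQGDALCR",
        corrected=True, note="printed 'PHSQGG' (36 chars for a 35-mer); single-G form "
        "agrees with the Cys2-Cys5 and Cys7-Cys10 overlaps",
    ),
    CuratedRow(
        "Cys7-Cys10", 470, 504, "WGAAVPHSQGDALCRHMCRAIGESFIMKRGDSFLD",
        corrected=True, note="printed sequence carries a duplicated "
        "'DALCRHMCRAIGESF' block (50 chars for a 35-mer); deduplicated",
    ),
    CuratedRow("Cys13-Cys16", 500, 534, "DSFLDGTRCMPSGPREDGTLSLCVSGSCRTFGCDG"),
    CuratedRow(
        "Cys13-Cys/Spa20", 500, 554,
        "DSFLDGTRCMPSGPREDGTLSLCVSGSCRTFGCDGRMDSQQVWDRCQVCGGDNST",
    ),
    CuratedRow("Cys18-Cys/Spa20", 525, 554, "GSCRTFGCDGRMDSQQVWDRCQVCGGDNST"),
    CuratedRow("Spa24-Spa28", 555, 594, "CSPRKGSFTAGRAREYVTFLTVTPNLTSVYIANHRPLFTH"),
    CuratedRow("Spa31-Spa34", 590, 624, "PLFTHLAVRIGGRYVVAGKMSISPNTTYPSLLEDG"),
    CuratedRow(
        "Spa31-Spa39", 590, 649,
        "PLFTHLAVRIGGRYVVAGKMSISPNTTYPSLLEDGRVEYRVALTEDRLPRLEEIRIWGPL",
    ),
    CuratedRow("Spa37-Spa40", 620, 654, "LLEDGRVEYRVALTEDRLPRLEEIRIWGPLQEDAD"),
    CuratedRow(
        "Spa42-Spa/TSP2 46", 645, 684, "IWGPLQEDADIQVYRRYGEEYGNLTRPDITFTYFQPKPRQ"
    ),
)

CURATED_ROWS: tuple[CuratedRow, ...] = _MP_DIS_ROWS + _CYS_SPA_ROWS

#: Span covered by the reference record (full-length ADAMTS13 numbering).
REFERENCE_SPAN = (75, 684)

#: Positions inside the reference span resolved by no published row; filled
#: with 'X'.  150-159 sits inside the tiled MP block, 385-439 is the untiled
#: first thrombospondin repeat between the two blocks.
UNRESOLVED_SPANS = ((150, 159), (385, 439))

#: Domain boundaries (full-length numbering) reconciled from the published
#: peptide names: MP/Dis straddlers are peptides 40-43 of the first block,
#: the Cys/Spa straddlers are peptides 20-22 of the second.
DOMAIN_TABLE = (
    ("MP", 75, 285),
    ("Dis", 286, 383),
    ("TSP1", 384, 439),
    ("Cys", 440, 549),
    ("Spa", 550, 680),
    ("TSP2", 681, 684),
)

#: The four proximal domains used for reactivity classification (the
#: thrombospondin repeats only appear as straddle labels).
PROXIMAL_DOMAINS = ("MP", "Dis", "Cys", "Spa")


def _clip_domains(start: int, end: int) -> tuple[tuple[str, int, int], ...]:
    out = []
    for label, ds, de in DOMAIN_TABLE:
        s, e = max(ds, start), min(de, end)
        if s <= e:
            out.append((label, s, e))
    return tuple(out)


def proximal_regions() -> list[TilingRegion]:
    """The two tiled regions with their clipped domain annotations."""
    return [
        TilingRegion("MP-Dis", 75, 384, domains=_clip_domains(75, 384)),
        TilingRegion("Cys-Spa", 440, 684, domains=_clip_domains(440, 684)),
    ]


def assemble_consensus(
    rows: tuple[CuratedRow, ...] = CURATED_ROWS,
    span: tuple[int, int] = REFERENCE_SPAN,
) -> ProteinRecord:
    """Overlay curated rows into one numbered consensus sequence.

    Raises
    ------
    ValueError
        If any two rows disagree at a shared position (the curation is
        internally inconsistent) or a row's length does not match its span.
    """
    lo, hi = span
    residues: list[str | None] = [None] * (hi - lo + 1)
    for row in rows:
        if len(row.sequence) != row.end - row.start + 1:
            raise ValueError(
                f"{row.name}: {len(row.sequence)} chars for span "
                f"{row.start}-{row.end}"
            )
        for pos, aa in zip(range(row.start, row.end + 1), row.sequence):
            cur = residues[pos - lo]
            if cur is not None and cur != aa:
                raise ValueError(f"conflict at {pos}: {cur} vs {aa} ({row.name})")
            residues[pos - lo] = aa
    filled = "".join(aa if aa is not None else "X" for aa in residues)
    return ProteinRecord(id="ADAMTS13_proximal_consensus", residues=filled,
                         numbering_offset=lo)


def proximal_protein() -> ProteinRecord:
    """The packaged ADAMTS13 proximal-domain consensus record."""
    return assemble_consensus()


def proximal_library(length: int = 20, offset: int = 5) -> list[Peptide]:
    """The packaged 105-peptide library (59 MP-Dis + 46 Cys-Spa 20-mers)."""
    return design_library(proximal_protein(), proximal_regions(), length, offset)
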