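"""Overlapping peptide library design (pepscan tiling).

Linear B-cell epitopes are localized by synthesizing fixed-length peptides
tiled across a protein at a constant offset and probing each one for antibody
binding.  The default geometry is 20-mer peptides advanced 5 residues at a
time, so consecutive peptides share 15 residues and every epitope shorter
than the overlap is contained in at least one peptide.

Coordinates are 1-based and inclusive throughout, matching the convention of
protein domain tables ("75-94" names the 20 residues 75..94).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DesignError

#: The 20 standard one-letter amino-acid codes, plus 'X' for positions a
#: reference sequence leaves unresolved.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_ALPHABET = AMINO_ACIDS | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein (or protein fragment) with explicit residue numbering.

    ``numbering_offset`` is the coordinate of ``residues[0]`` on the
    full-length protein, so a fragment can keep full-length numbering.
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise DesignError("empty_protein", "protein has no residues")
        bad = set(self.residues.upper()) - EXTENDED_ALPHABET
        if bad:
            raise DesignError(
                "bad_alphabet", f"non-amino-acid characters: {sorted(bad)}"
            )
        if self.numbering_offset < 1:
            raise DesignError("bad_offset", "numbering_offset must be >= 1")

    @property
    def start(self) -> int:
        return self.numbering_offset

    @property
    def end(self) -> int:
        return self.numbering_offset + len(self.residues) - 1

    def subsequence(self, start: int, end: int) -> str:
        """Residues ``start..end`` (1-based, inclusive, full-length numbering)."""
        if start < self.start or end > self.end or start > end:
            raise DesignError(
                "out_of_span",
                f"[{start}, {end}] outside protein span [{self.start}, {self.end}]",
            )
        i = start - self.numbering_offset
        return self.residues[i : i + (end - start + 1)]


@dataclass(frozen=True)
class TilingRegion:
    """A protein span selected for tiling, with ordered domain sub-annotations.

    ``domains`` holds ``(label, start, end)`` triples, non-overlapping and in
    N→C order, each lying inside ``[start, end]``.  They drive peptide naming
    and downstream domain-reactivity classification.
    """

    name: str
    start: int
    end: int
    domains: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DesignError("bad_region", f"start {self.start} > end {self.end}")
        prev_end = None
        for label, ds, de in self.domains:
            if ds > de or ds < self.start or de > self.end:
                raise DesignError(
                    "bad_annotation", f"{label} [{ds}, {de}] outside region"
                )
            if prev_end is not None and ds <= prev_end:
                raise DesignError(
                    "bad_annotation", f"{label} overlaps preceding annotation"
                )
            prev_end = de

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Peptide:
    """One tiled peptide with full-length protein coordinates.

    ``sequence`` may be ``None`` when a peptide is reconstructed from a
    coordinate-only manifest; when present it must match the span length.
    """

    name: str
    start: int
    end: int
    sequence: str | None = None
    biotinylated: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DesignError("bad_peptide", f"start {self.start} > end {self.end}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise DesignError(
                "bad_peptide",
                f"{self.name}: sequence length {len(self.sequence)} != span "
                f"{self.length}",
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlap(self, start: int, end: int) -> int:
        """Number of residues shared with the interval ``[start, end]``."""
        return max(0, min(self.end, end) - max(self.start, start) + 1)


def tile_peptides(
    protein: ProteinRecord,
    region: TilingRegion,
    length: int = 20,
    offset: int = 5,
) -> list[Peptide]:
    """Tile ``region`` with full-length ``length``-mers advanced by ``offset``.

    Peptide *k* (1-based) starts at ``region.start + (k-1)*offset``.  The final
    peptide always ends exactly at ``region.end``; if the region length puts
    that last window off the offset grid it is emitted anyway with a warning.
    Consecutive on-grid peptides overlap by ``length - offset`` residues.

    Raises
    ------
    DesignError
        ``"region_too_short"`` when the region cannot hold one full window;
        ``"region_outside_protein"`` when the region leaves the numbered span.
    """
    if not (1 <= offset <= length):
        raise DesignError("bad_geometry", "need length >= offset >= 1")
    if region.length < length:
        raise DesignError(
            "region_too_short",
            f"{region.name}: {region.length} residues < window {length}",
        )
    if region.start < protein.start or region.end > protein.end:
        raise DesignError(
            "region_outside_protein",
            f"{region.name} [{region.start}, {region.end}] not inside "
            f"[{protein.start}, {protein.end}]",
        )

    last_start = region.end - length + 1
    starts = list(range(region.start, last_start + 1, offset))
    if starts[-1] != last_start:
        warnings.warn(
            f"region {region.name}: final window {last_start}-{region.end} is "
            f"off the {offset}-residue grid; emitted anyway",
            stacklevel=2,
        )
        starts.append(last_start)

    peptides = []
    for k, s in enumerate(starts, start=1):
        e = s + length - 1
        peptides.append(
            Peptide(
                name=f"{region.name}_{k}",
                start=s,
                end=e,
                sequence=protein.subsequence(s, e),
            )
        )
    return peptides


def _label_with_number(label: str, k: int) -> str:
    # "MP" + 7 -> "MP7"; labels ending in a digit get a separating space,
    # "Dis/TSP1" + 59 -> "Dis/TSP1 59".
    sep = " " if label and label[-1].isdigit() else ""
    return f"{label}{sep}{k}"


def name_peptides(
    peptides: Sequence[Peptide], region: TilingRegion
) -> list[Peptide]:
    """Assign domain-derived names, numbered continuously across the region.

    A peptide lying inside one domain annotation is named ``<label><k>``;
    a peptide straddling a boundary gets a compound label joining every
    domain it touches, N-terminal first ("MP/Dis41").

    Raises
    ------
    DesignError
        ``"unannotated_span"`` when a peptide overlaps no annotation.
    """
    if not region.domains:
        raise DesignError("unannotated_span", "region has no domain annotations")
    if any(
        peptides[i].start > peptides[i + 1].start for i in range(len(peptides) - 1)
    ):
        raise DesignError("unsorted_peptides", "peptides must be sorted by start")

    named = []
    for k, pep in enumerate(peptides, start=1):
        touched = [
            label
            for (label, ds, de) in region.domains
            if pep.overlap(ds, de) > 0
        ]
        if not touched:
            raise DesignError(
                "unannotated_span", f"peptide {pep.start}-{pep.end} in no domain"
            )
        label = touched[0] if len(touched) == 1 else "/".join(touched)
        named.append(replace(pep, name=_label_with_number(label, k)))
    return named


def design_library(
    protein: ProteinRecord,
    regions: Iterable[TilingRegion],
    length: int = 20,
    offset: int = 5,
) -> list[Peptide]:
    """Tile and name every region; the concatenated, named peptide library."""
    out: list[Peptide] = []
    for region in regions:
        out.extend(name_peptides(tile_peptides(protein, region, length, offset), region))
    return out


# ---------------------------------------------------------------------------
# Library I/O: FASTA records named by peptide, TSV manifest with coordinates.
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("name", "start", "end", "sequence")


def write_library(
    peptides: Sequence[Peptide], fasta_path: str | Path, tsv_path: str | Path
) -> None:
    """Write the library as FASTA plus a TSV manifest (name, start, end, sequence)."""
    if not peptides:
        raise DesignError("empty_library", "no peptides to write")
    names = [p.name for p in peptides]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise DesignError("name_collision", f"duplicate peptide names: {dupes}")

    records = [
        SeqRecord(Seq(p.sequence or "X" * p.length), id=p.name, description=f"{p.start}-{p.end}")
        for p in peptides
    ]
    SeqIO.write(records, str(fasta_path), "fasta")

    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MANIFEST_COLUMNS)
        for p in peptides:
            w.writerow([p.name, p.start, p.end, p.sequence or ""])


def read_library(tsv_path: str | Path) -> list[Peptide]:
    """Read a TSV manifest back into :class:`Peptide` objects (lossless)."""
    peptides = []
    with open(tsv_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            peptides.append(
                Peptide(
                    name=row["name"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    sequence=row["sequence"] or None,
                )
            )
    return peptides


def read_protein_fasta(path: str | Path, numbering_offset: int = 1) -> ProteinRecord:
    """First record of a FASTA file as a :class:`ProteinRecord`."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return ProteinRecord(id=rec.id, residues=str(rec.seq).upper(), numbering_offset=numbering_offset)


def read_regions_tsv(path: str | Path) -> list[TilingRegion]:
    """Read tiling regions with optional domain annotations.

    Expected columns: ``name, start, end`` for regions; rows with a
    ``parent`` column value attach a domain annotation ``(name, start, end)``
    to the named parent region, in file order.
    """
    regions: dict[str, dict] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            parent = (row.get("parent") or "").strip()
            if not parent:
                regions[row["name"]] = {
                    "name": row["name"],
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "domains": [],
                }
                order.append(row["name"])
            else:
                if parent not in regions:
                    raise DesignError("bad_annotation", f"unknown parent region {parent!r}")
                regions[parent]["domains"].append(
                    (row["name"], int(row["start"]), int(row["end"]))
                )
    return [
        TilingRegion(
            name=r["name"], start=r["start"], end=r["end"], domains=tuple(r["domains"])
        )
        for r in (regions[n] for n in order)
    ]
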