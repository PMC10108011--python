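"""Marker panel definition, validation and in-silico bisulfite conversion.

A marker is a short amplicon over a genomic locus whose CpG sites are
unmethylated specifically in colon epithelium and methylated in the blood
cfDNA background.  The panel bundles eight such markers together with the
barcodes used to demultiplex a pooled sequencing run.

Coordinates are 0-based and intervals half-open throughout; amplicons are
given in sequencing orientation (reverse-strand handling is out of scope for
an amplicon assay that reads a fixed strand).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MarkerDefinition",
    "MarkerPanel",
    "PanelError",
    "PanelFormatError",
    "PanelValidationError",
    "find_cpg_sites",
    "bisulfite_convert",
    "bisulfite_convert_reference",
    "load_panel",
    "write_panel",
    "export_reference_fasta",
    "default_panel",
    "DEFAULT_MARKER_NAMES",
]

_DNA_RE = re.compile(r"^[ACGT]+$")

#: The eight colorectal-specific marker loci of the assay.  Sequences shipped
#: with :func:`default_panel` are synthetic stand-ins for these loci.
DEFAULT_MARKER_NAMES = (
    "FGFRL1",
    "Col1",
    "ECH1",
    "cg10900049",
    "cg23460250",
    "cg12462916",
    "cg09094964",
    "cg15139063",
)


class PanelError(ValueError):
    """Base class for panel problems."""


class PanelFormatError(PanelError):
    """The panel file could not be parsed."""


class PanelValidationError(PanelError):
    """A marker or panel invariant is violated."""


def find_cpg_sites(seq: str) -> list[int]:
    """Return the 0-based offsets ``p`` with ``seq[p:p+2] == "CG"``, ascending.

    Raises :class:`PanelError` if *seq* contains characters outside A/C/G/T.
    """
    if not _DNA_RE.match(seq or ""):
        raise PanelError(f"sequence is not plain A/C/G/T DNA: {seq!r}")
    return [m.start() for m in re.finditer("(?=CG)", seq)]


def bisulfite_convert(seq: str, retained_positions: Iterable[int] = ()) -> str:
    """Convert every cytosine to thymine except those at *retained_positions*.

    Bisulfite treatment deaminates unmethylated C to U (sequenced as T) and
    leaves methylated C intact; *retained_positions* are therefore the offsets
    of methylated cytosines.
    """
    retained = set(retained_positions)
    return "".join(
        "T" if (b == "C" and i not in retained) else b for i, b in enumerate(seq)
    )


@dataclass(frozen=True)
class MarkerDefinition:
    """One amplicon target: reference sequence, CpG map, primers, barcode."""

    name: str
    reference_seq: str
    cpg_positions: tuple[int, ...]
    primer_fwd_span: tuple[int, int]
    primer_rev_span: tuple[int, int]
    barcode: str

    MIN_LENGTH = 40
    MIN_PRIMER_CH = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpg_positions", tuple(self.cpg_positions))
        object.__setattr__(self, "primer_fwd_span", tuple(self.primer_fwd_span))
        object.__setattr__(self, "primer_rev_span", tuple(self.primer_rev_span))

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        """Check every marker invariant; raise PanelValidationError on the
        first violation, naming the marker and the rule."""
        seq = self.reference_seq
        if not _DNA_RE.match(seq or ""):
            raise PanelValidationError(
                f"marker {self.name}: reference_seq is not plain A/C/G/T DNA"
            )
        if len(seq) < self.MIN_LENGTH:
            raise PanelValidationError(
                f"marker {self.name}: reference length {len(seq)} < {self.MIN_LENGTH}"
            )
        if not _DNA_RE.match(self.barcode or ""):
            raise PanelValidationError(f"marker {self.name}: barcode must be A/C/G/T")
        for span, label in (
            (self.primer_fwd_span, "primer_fwd"),
            (self.primer_rev_span, "primer_rev"),
        ):
            s, e = span
            if not (0 <= s < e <= len(seq)):
                raise PanelValidationError(
                    f"marker {self.name}: {label} span {span} outside sequence"
                )
        prev = -1
        for p in self.cpg_positions:
            if seq[p : p + 2] != "CG":
                raise PanelValidationError(
                    f"marker {self.name}: cpg_position {p} is not on a CG dinucleotide"
                )
            if p <= prev:
                raise PanelValidationError(
                    f"marker {self.name}: cpg_positions not strictly increasing at {p}"
                )
            if self._in_primer(p):
                raise PanelValidationError(
                    f"marker {self.name}: cpg_position {p} lies inside a primer span"
                )
            prev = p
        interior_cpgs = [
            p for p in find_cpg_sites(seq) if not self._in_primer(p)
        ]
        if not interior_cpgs:
            raise PanelValidationError(
                f"marker {self.name}: no CpG outside primer spans"
            )
        for span, label in (
            (self.primer_fwd_span, "primer_fwd"),
            (self.primer_rev_span, "primer_rev"),
        ):
            n_ch = self._count_ch(span)
            if n_ch < self.MIN_PRIMER_CH:
                raise PanelValidationError(
                    f"marker {self.name}: {label} has {n_ch} CH cytosines, "
                    f"needs >= {self.MIN_PRIMER_CH} (CH design rule)"
                )

    def _in_primer(self, pos: int) -> bool:
        (fs, fe), (rs, re_) = self.primer_fwd_span, self.primer_rev_span
        return fs <= pos < fe or rs <= pos < re_

    def _count_ch(self, span: tuple[int, int]) -> int:
        s, e = span
        seq = self.reference_seq
        return sum(
            1
            for i in range(s, e)
            if seq[i] == "C" and (i + 1 >= len(seq) or seq[i + 1] != "G")
        )

    # -- derived sequences ----------------------------------------------

    def converted_reference(self) -> str:
        """The reference after in-silico bisulfite conversion with all marker
        CpGs unmethylated (the alignment reference: every C becomes T)."""
        return bisulfite_convert(self.reference_seq)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.reference_seq)


def bisulfite_convert_reference(marker: MarkerDefinition, cpg_methylated: bool) -> str:
    """Expected read template for a fully methylated or fully unmethylated
    molecule of *marker*: non-CpG cytosines always convert to T; cytosines at
    the marker's CpG positions are retained iff *cpg_methylated*."""
    retained = marker.cpg_positions if cpg_methylated else ()
    return bisulfite_convert(marker.reference_seq, retained)


@dataclass(frozen=True)
class MarkerPanel:
    markers: tuple[MarkerDefinition, ...]
    version: str = "1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))

    def validate(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise PanelValidationError(f"duplicate marker names: {dup}")
        barcodes = [m.barcode for m in self.markers]
        if len(set(barcodes)) != len(barcodes):
            dup = sorted({b for b in barcodes if barcodes.count(b) > 1})
            raise PanelValidationError(f"duplicate barcodes: {dup}")
        for m in self.markers:
            m.validate()

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def get(self, name: str) -> MarkerDefinition:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]


# ---------------------------------------------------------------------------
# Panel file I/O: TSV with one record per marker plus a keyed header line.
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = [
    "name",
    "barcode",
    "reference_seq",
    "cpg_positions",
    "primer_fwd",
    "primer_rev",
]


def _parse_span(text: str, line_no: int, label: str) -> tuple[int, int]:
    m = re.match(r"^(\d+)-(\d+)$", text.strip())
    if not m:
        raise PanelFormatError(
            f"line {line_no}: {label} must look like 'start-end', got {text!r}"
        )
    return int(m.group(1)), int(m.group(2))


def load_panel(path: str | Path) -> MarkerPanel:
    """Load and validate a panel TSV.

    Format: an optional ``#version=<tag>`` line, a header row with the columns
    name, barcode, reference_seq, cpg_positions (comma-joined 0-based),
    primer_fwd and primer_rev (``start-end``, half-open), then one row per
    marker.
    """
    path = Path(path)
    version = "1"
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            m = re.match(r"#\s*version\s*=\s*(\S+)", line)
            if m:
                version = m.group(1)
            body_start = i + 1
        else:
            break
    reader = csv.DictReader(lines[body_start:], delimiter="\t")
    if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _PANEL_COLUMNS:
        raise PanelFormatError(
            f"line {body_start + 1}: header must be {_PANEL_COLUMNS}, "
            f"got {reader.fieldnames}"
        )
    markers = []
    for row_idx, row in enumerate(reader):
        line_no = body_start + 2 + row_idx
        if any(row.get(c) in (None, "") for c in _PANEL_COLUMNS if c != "cpg_positions"):
            raise PanelFormatError(f"line {line_no}: missing field(s)")
        cpg_text = (row["cpg_positions"] or "").strip()
        try:
            cpgs = tuple(int(x) for x in cpg_text.split(",")) if cpg_text else ()
        except ValueError:
            raise PanelFormatError(
                f"line {line_no}: cpg_positions must be comma-joined integers"
            ) from None
        markers.append(
            MarkerDefinition(
                name=row["name"].strip(),
                barcode=row["barcode"].strip(),
                reference_seq=row["reference_seq"].strip(),
                cpg_positions=cpgs,
                primer_fwd_span=_parse_span(row["primer_fwd"], line_no, "primer_fwd"),
                primer_rev_span=_parse_span(row["primer_rev"], line_no, "primer_rev"),
            )
        )
    panel = MarkerPanel(markers=tuple(markers), version=version)
    panel.validate()
    return panel


def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    buf = io.StringIO()
    buf.write(f"#version={panel.version}\n")
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(_PANEL_COLUMNS)
    for m in panel:
        writer.writerow(
            [
                m.name,
                m.barcode,
                m.reference_seq,
                ",".join(str(p) for p in m.cpg_positions),
                f"{m.primer_fwd_span[0]}-{m.primer_fwd_span[1]}",
                f"{m.primer_rev_span[0]}-{m.primer_rev_span[1]}",
            ]
        )
    Path(path).write_text(buf.getvalue())


def export_reference_fasta(
    panel: MarkerPanel, path: str | Path, converted: bool = False
) -> None:
    """Write the (optionally bisulfite-converted, all-C-to-T) references as
    FASTA for inspection."""
    records = [
        SeqRecord(
            Seq(m.converted_reference() if converted else m.reference_seq),
            id=m.name,
            description="bisulfite-converted" if converted else "",
        )
        for m in panel
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Deterministic fixture panel
# ---------------------------------------------------------------------------

_FIXTURE_SEED = 20170301  # fixed: the fixture panel is a constant of the package


def _random_primer(rng: np.random.Generator, length: int = 20) -> str:
    """Primer with >= 4 CH cytosines and no CG dinucleotide."""
    while True:
        bases = rng.choice(list("ACGT"), size=length)
        seq = "".join(bases)
        if "CG" in seq:
            continue
        n_ch = sum(1 for i, b in enumerate(seq) if b == "C")
        if n_ch >= MarkerDefinition.MIN_PRIMER_CH:
            return seq


def _random_interior(rng: np.random.Generator, n_cpg: int) -> tuple[str, list[int]]:
    """Interior segment carrying exactly n_cpg CpGs separated by CG-free filler."""
    parts: list[str] = []
    positions: list[int] = []
    offset = 0
    for _ in range(n_cpg):
        gap_len = int(rng.integers(4, 9))
        gap = ""
        while True:
            gap = "".join(rng.choice(list("AT"), size=gap_len))
            break
        parts.append(gap)
        offset += gap_len
        positions.append(offset)
        parts.append("CG")
        offset += 2
    tail = "".join(rng.choice(list("AT"), size=int(rng.integers(4, 9))))
    parts.append(tail)
    return "".join(parts), positions


def _fixture_barcodes(rng: np.random.Generator, n: int, length: int = 8) -> list[str]:
    """Barcodes over A/G/T (no cytosine: immune to bisulfite chemistry) with
    pairwise Hamming distance >= 3."""
    chosen: list[str] = []
    while len(chosen) < n:
        cand = "".join(rng.choice(list("AGT"), size=length))
        if all(sum(a != b for a, b in zip(cand, c)) >= 3 for c in chosen):
            chosen.append(cand)
    return chosen


def default_panel() -> MarkerPanel:
    """The 8-marker colorectal fixture panel.

    Marker names follow the real assay; sequences are deterministic synthetic
    stand-ins (4-8 CpGs each) because the real amplicon sequences are not
    publicly deposited.  Calling this twice always yields an identical panel.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    barcodes = _fixture_barcodes(rng, len(DEFAULT_MARKER_NAMES))
    markers = []
    for name, barcode in zip(DEFAULT_MARKER_NAMES, barcodes):
        n_cpg = int(rng.integers(4, 9))
        primer_f = _random_primer(rng)
        primer_r = _random_primer(rng)
        interior, rel_positions = _random_interior(rng, n_cpg)
        # avoid creating a CpG at either primer/interior junction
        if primer_f.endswith("C") and interior.startswith("G"):
            interior = "A" + interior
            rel_positions = [p + 1 for p in rel_positions]
        if interior.endswith("C") and primer_r.startswith("G"):
            interior = interior + "A"
        seq = primer_f + interior + primer_r
        cpgs = tuple(len(primer_f) + p for p in rel_positions)
        markers.append(
            MarkerDefinition(
                name=name,
                reference_seq=seq,
                cpg_positions=cpgs,
                primer_fwd_span=(0, len(primer_f)),
                primer_rev_span=(len(seq) - len(primer_r), len(seq)),
                barcode=barcode,
            )
        )
    panel = MarkerPanel(markers=tuple(markers), version="fixture-8")
    panel.validate()
    return panel
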