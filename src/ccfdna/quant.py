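"""Molecule-level methylation readout and colon-derived cfDNA quantification.

The pipeline: demultiplex reads by barcode, align each read to its amplicon
reference with bisulfite-aware scoring, read out every CpG as CG (methylated)
or TG (unmethylated), classify molecules as fully unmethylated, estimate the
per-marker fully-unmethylated fraction, and convert it to tissue-derived
genome equivalents per ml of plasma.

Alignment is end-to-end against the converted reference with a conversion-
tolerant asymmetry: a read T opposite a reference C scores as a match (the
C->T chemistry of the sequenced strand), while a read C opposite a reference
T is a mismatch.  Scoring is match 0, mismatch -6, gap open -5, gap extend
-3; a read is accepted iff its score is at least -0.2 x read length (base
qualities are never consulted).

The ng/ml -> genome-equivalents/ml conversion uses the 3.3 pg mass of a
haploid human genome: 1 ng/ml = 303 GE/ml.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .panel import MarkerDefinition, MarkerPanel
from .readsim import read_fastq

__all__ = [
    "GE_PER_NG",
    "CpGCall",
    "AlignmentResult",
    "MarkerCounts",
    "SampleQuant",
    "QCReport",
    "AlignmentScoring",
    "demultiplex",
    "align_read",
    "call_cpgs",
    "classify_molecule",
    "marker_fraction",
    "copies_per_ml",
    "combine_markers",
    "quantify_sample",
]

#: genome equivalents per ng of DNA (haploid genome mass 3.3 pg)
GE_PER_NG = 303.0

DEFAULT_SCORE_THRESHOLD_FACTOR = -0.2
DEFAULT_MIN_READ_LENGTH = 30


class CpGCall(enum.Enum):
    METHYLATED = "M"
    UNMETHYLATED = "U"
    AMBIGUOUS = "A"


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 0.0
    mismatch: float = -6.0
    gap_open: float = -5.0
    gap_extend: float = -3.0


@dataclass
class AlignmentResult:
    """Outcome of aligning one read to one marker reference.

    ``ref_to_read`` maps each reference offset to the read offset aligned to
    it, or -1 for a deletion in the read; it is None for rejected reads.
    """

    marker: str
    score: float
    accepted: bool
    ref_to_read: np.ndarray | None
    read: str
    reject_reason: str | None = None


@dataclass
class MarkerCounts:
    marker: str
    total_molecules: int
    unmethylated_molecules: int

    @property
    def fraction(self) -> float:
        """Fully-unmethylated fraction; NaN (undefined) when no molecules."""
        if self.total_molecules == 0:
            return float("nan")
        return self.unmethylated_molecules / self.total_molecules

    @property
    def defined(self) -> bool:
        return self.total_molecules > 0


@dataclass
class SampleQuant:
    sample_id: str
    cfdna_ng_per_ml: float | None
    marker_counts: dict[str, MarkerCounts]
    copies: dict[str, float]          # per-marker GE/ml (NaN when undefined)
    combined_score: float             # mean GE/ml over defined markers (NaN if none)
    contributing_markers: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, mc in self.marker_counts.items():
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "marker": name,
                    "total_molecules": mc.total_molecules,
                    "unmethylated_molecules": mc.unmethylated_molecules,
                    "fraction": mc.fraction,
                    "copies_per_ml": self.copies.get(name, float("nan")),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class QCReport:
    """Per-marker coverage and quality statistics for one sample."""

    sample_id: str
    n_reads: int
    n_unassigned: int
    per_marker: pd.DataFrame  # marker, total_reads, accepted, rejected_score,
    #                           rejected_short, ambiguous_call_rate
    flags: list[str] = field(default_factory=list)

    def conservation_holds(self) -> bool:
        """accepted + rejected + unassigned account for every input read."""
        attributed = int(
            self.per_marker[
                ["accepted", "rejected_score", "rejected_short", "rejected_ch"]
            ]
            .to_numpy()
            .sum()
        )
        return attributed + self.n_unassigned == self.n_reads


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(x != y or x == "N" for x, y in zip(a, b))


def _as_id_seq(rec) -> tuple[str | None, str]:
    """Accept a SeqRecord, a plain string, or an (id, seq) pair."""
    if hasattr(rec, "seq"):
        return getattr(rec, "id", None), str(rec.seq)
    if isinstance(rec, str):
        return None, rec
    rid, seq = rec
    return rid, str(seq)


def demultiplex(
    reads: Iterable, panel: MarkerPanel, max_barcode_mismatch: int = 1
) -> tuple[dict[str, list], list]:
    """Partition reads by barcode prefix.

    A read is assigned to the unique barcode within ``max_barcode_mismatch``
    Hamming distance of its prefix; a tie between two barcodes is never
    guessed — the read goes to the unassigned bin.  N bases always count as
    mismatches.  Returns (marker -> list of (read_id, barcode-trimmed seq),
    unassigned reads).
    """
    if max_barcode_mismatch < 0:
        raise ValueError("max_barcode_mismatch must be >= 0")
    barcodes = [(m.name, m.barcode) for m in panel]
    exact = {m.barcode: m.name for m in panel}
    bc_lengths = sorted({len(m.barcode) for m in panel})
    # the exact-match shortcut is only unambiguous when all barcodes share one
    # length (an exact hit then has distance 0, strictly better than any other)
    uniform_len = bc_lengths[0] if len(bc_lengths) == 1 else None
    assigned: dict[str, list] = {m.name: [] for m in panel}
    unassigned: list = []
    for rec in reads:
        rid, seq = _as_id_seq(rec)
        if uniform_len is not None:
            hit = exact.get(seq[:uniform_len])
            if hit is not None:
                assigned[hit].append((rid, seq[uniform_len:]))
                continue
        best_name, best_len, best_d, tie = None, 0, None, False
        for name, bc in barcodes:
            prefix = seq[: len(bc)]
            if len(prefix) < len(bc):
                continue
            d = _hamming(prefix, bc)
            if d > max_barcode_mismatch:
                continue
            if best_d is None or d < best_d:
                best_name, best_len, best_d, tie = name, len(bc), d, False
            elif d == best_d:
                tie = True
        if best_name is None or tie:
            unassigned.append(rec)
        else:
            assigned[best_name].append((rid, seq[best_len:]))
    return assigned, unassigned


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

_ALPHABET = "ACGTN"


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = scoring.match if (a == b and a != "N") else scoring.mismatch
    # bisulfite asymmetry: reference C may legitimately be read as T
    m["C", "T"] = scoring.match
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _gapless_score(read: str, reference: str, scoring: AlignmentScoring) -> float:
    r = np.frombuffer(read.encode(), dtype="S1")
    t = np.frombuffer(reference.encode(), dtype="S1")
    match = (r == t) & (r != b"N")
    match |= (t == b"C") & (r == b"T")
    n_mismatch = int((~match).sum())
    return n_mismatch * scoring.mismatch + match.sum() * scoring.match


def align_read(
    read: str,
    marker: MarkerDefinition,
    scoring: AlignmentScoring = AlignmentScoring(),
    score_threshold_factor: float = DEFAULT_SCORE_THRESHOLD_FACTOR,
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
) -> AlignmentResult:
    """End-to-end bisulfite-aware alignment of a barcode-trimmed read.

    Accepted iff score >= score_threshold_factor x read length (inclusive:
    the threshold is an attainable minimum).  Reads shorter than
    ``min_read_length`` are rejected outright with reason ``too_short``.
    """
    read = read.upper()
    if len(read) < min_read_length:
        return AlignmentResult(marker.name, -math.inf, False, None, read, "too_short")
    reference = marker.reference_seq
    threshold = score_threshold_factor * len(read)

    if len(read) == len(reference):
        score = _gapless_score(read, reference, scoring)
        if score >= threshold:
            return AlignmentResult(
                marker.name, score, True, np.arange(len(reference)), read
            )
        # gaps might still rescue a borderline read: fall through to full DP

    aligner = _make_aligner(scoring)
    aln = aligner.align(reference, read)[0]
    score = float(aln.score)
    if score < threshold:
        return AlignmentResult(marker.name, score, False, None, read, "low_score")
    indices = np.asarray(aln.indices)  # 2 x n_columns; -1 marks gaps
    ref_to_read = np.full(len(reference), -1, dtype=int)
    cols = indices[0] >= 0
    ref_to_read[indices[0, cols]] = indices[1, cols]
    return AlignmentResult(marker.name, score, True, ref_to_read, read)


# ---------------------------------------------------------------------------
# CpG calling and molecule classification
# ---------------------------------------------------------------------------


def call_cpgs(aln: AlignmentResult, marker: MarkerDefinition) -> list[CpGCall]:
    """Read out each marker CpG from the aligned read.

    CG -> methylated, TG -> unmethylated; anything else — a gap, an N, an
    uncovered position or any other dinucleotide — is ambiguous, never
    silently dropped.
    """
    if not aln.accepted or aln.ref_to_read is None:
        raise ValueError("call_cpgs requires an accepted alignment")
    calls: list[CpGCall] = []
    read = aln.read
    for p in marker.cpg_positions:
        i = aln.ref_to_read[p]
        j = aln.ref_to_read[p + 1] if p + 1 < len(aln.ref_to_read) else -1
        if i < 0 or j < 0 or i >= len(read) or j >= len(read):
            calls.append(CpGCall.AMBIGUOUS)
            continue
        dinuc = read[i] + read[j]
        if dinuc == "CG":
            calls.append(CpGCall.METHYLATED)
        elif dinuc == "TG":
            calls.append(CpGCall.UNMETHYLATED)
        else:
            calls.append(CpGCall.AMBIGUOUS)
    return calls


def classify_molecule(calls: Sequence[CpGCall]) -> bool:
    """True iff the molecule is fully unmethylated: every CpG read as TG.

    A methylated or ambiguous call anywhere makes the molecule not fully
    unmethylated (it stays in the denominator), which can only deflate — never
    inflate — the colon-derived signal.
    """
    if len(calls) == 0:
        raise ValueError("empty CpG call vector")
    return all(c is CpGCall.UNMETHYLATED for c in calls)


def marker_fraction(
    marker: str, classifications: Sequence[bool]
) -> MarkerCounts:
    """Fully-unmethylated fraction among accepted molecules of one marker."""
    total = len(classifications)
    unmeth = int(sum(bool(c) for c in classifications))
    return MarkerCounts(marker=marker, total_molecules=total, unmethylated_molecules=unmeth)


def copies_per_ml(fraction: float, cfdna_ng_per_ml: float) -> float:
    """Tissue-derived genome equivalents per ml: fraction x ng/ml x 303."""
    if cfdna_ng_per_ml < 0:
        raise ValueError("cfDNA concentration must be >= 0")
    if math.isnan(fraction):
        return float("nan")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    return fraction * cfdna_ng_per_ml * GE_PER_NG


def combine_markers(per_marker_copies: Mapping[str, float]) -> tuple[float, int]:
    """Per-sample c-cfDNA score: arithmetic mean of the defined per-marker
    copies/ml.  Undefined (NaN) markers are dropped and the count of
    contributing markers reported; no defined marker at all yields NaN."""
    defined = [v for v in per_marker_copies.values() if not math.isnan(v)]
    if not defined:
        return float("nan"), 0
    return float(np.mean(defined)), len(defined)


# ---------------------------------------------------------------------------
# batch gapless fast path
# ---------------------------------------------------------------------------


def count_retained_ch(read: str, marker: MarkerDefinition, ref_to_read) -> int:
    """Number of non-CpG reference cytosines read as C — retained CH
    cytosines flag incomplete bisulfite conversion."""
    n = 0
    for p in _ch_positions(marker):
        i = ref_to_read[p]
        if 0 <= i < len(read) and read[i] == "C":
            n += 1
    return n


def _ch_positions(marker: MarkerDefinition) -> np.ndarray:
    ref = marker.reference_seq
    cpg = set(marker.cpg_positions)
    return np.asarray(
        [
            i
            for i, b in enumerate(ref)
            if b == "C" and i not in cpg and not (i + 1 < len(ref) and ref[i : i + 2] == "CG")
        ],
        dtype=int,
    )


def _tally(calls: Sequence[CpGCall]) -> tuple[bool, int, bool]:
    """(fully unmethylated, n ambiguous sites, ambiguous-only molecule)."""
    fully_u = all(c is CpGCall.UNMETHYLATED for c in calls)
    n_amb = sum(c is CpGCall.AMBIGUOUS for c in calls)
    amb_only = n_amb > 0 and not any(c is CpGCall.METHYLATED for c in calls)
    return fully_u, n_amb, amb_only


def _batch_quantify_marker(
    entries: list[tuple[str | None, str]],
    marker: MarkerDefinition,
    scoring: AlignmentScoring,
    score_threshold_factor: float,
    min_read_length: int,
    max_retained_ch: int | None = None,
) -> dict[str, int]:
    """Process all reads of one marker.

    Reads with the reference length go through a vectorised gapless scorer
    (optimal whenever no indel occurred); the rest, and gapless-rejected
    borderline reads, use the full affine DP via :func:`align_read`.  When
    ``max_retained_ch`` is set, accepted reads with more retained CH
    cytosines (incomplete conversion) are discarded; the filter is off by
    default.
    """
    ref = marker.reference_seq
    L = len(ref)
    cpgs = np.asarray(marker.cpg_positions, dtype=int)
    ch_pos = _ch_positions(marker) if max_retained_ch is not None else None

    same_len: list[str] = []
    odd: list[str] = []
    out = dict(
        accepted=0, unmethylated=0, rejected_score=0, rejected_short=0,
        rejected_ch=0, ambiguous_molecules=0, ambiguous_sites=0,
    )
    for _, read in entries:
        read = read.upper()
        if len(read) < min_read_length:
            out["rejected_short"] += 1
        elif len(read) == L:
            same_len.append(read)
        else:
            odd.append(read)

    def _tally_single(res: AlignmentResult) -> None:
        if not res.accepted:
            out["rejected_score"] += 1
            return
        if max_retained_ch is not None and count_retained_ch(
            res.read, marker, res.ref_to_read
        ) > max_retained_ch:
            out["rejected_ch"] += 1
            return
        fully_u, n_amb, amb_only = _tally(call_cpgs(res, marker))
        out["accepted"] += 1
        out["unmethylated"] += int(fully_u)
        out["ambiguous_sites"] += n_amb
        out["ambiguous_molecules"] += int(amb_only)

    if same_len:
        mat = np.frombuffer("".join(same_len).encode(), dtype="S1").reshape(-1, L)
        refv = np.frombuffer(ref.encode(), dtype="S1")
        match = (mat == refv) & (mat != b"N")
        match |= (refv == b"C") & (mat == b"T")
        scores = (~match).sum(axis=1) * scoring.mismatch + match.sum(axis=1) * scoring.match
        thresh = score_threshold_factor * L
        ok = scores >= thresh
        # borderline: gapless failed; give the full DP a chance
        for i in np.nonzero(~ok)[0]:
            _tally_single(
                align_read(same_len[i], marker, scoring, score_threshold_factor, min_read_length)
            )
        acc = mat[ok]
        if ch_pos is not None and acc.size:
            retained = (acc[:, ch_pos] == b"C").sum(axis=1) if ch_pos.size else np.zeros(acc.shape[0], dtype=int)
            ch_ok = retained <= max_retained_ch
            out["rejected_ch"] += int((~ch_ok).sum())
            acc = acc[ch_ok]
        if acc.size:
            first = acc[:, cpgs]
            second = acc[:, cpgs + 1]
            is_u = (first == b"T") & (second == b"G")
            is_m = (first == b"C") & (second == b"G")
            fully_u = is_u.all(axis=1)
            amb = ~(is_u | is_m)
            out["accepted"] += acc.shape[0]
            out["unmethylated"] += int(fully_u.sum())
            out["ambiguous_sites"] += int(amb.sum())
            out["ambiguous_molecules"] += int((amb.any(axis=1) & ~is_m.any(axis=1)).sum())

    for read in odd:
        _tally_single(
            align_read(read, marker, scoring, score_threshold_factor, min_read_length)
        )
    return out


# ---------------------------------------------------------------------------
# end-to-end sample quantification
# ---------------------------------------------------------------------------


def quantify_sample(
    fastq_path: str | Path | None,
    panel: MarkerPanel,
    sample_id: str = "sample",
    cfdna_ng_per_ml: float | None = None,
    reads: Iterable | None = None,
    max_barcode_mismatch: int = 1,
    scoring: AlignmentScoring = AlignmentScoring(),
    score_threshold_factor: float = DEFAULT_SCORE_THRESHOLD_FACTOR,
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
    max_retained_ch: int | None = None,
) -> tuple[SampleQuant, QCReport]:
    """Full pipeline for one sample: demultiplex -> align -> call -> classify
    -> fraction -> copies/ml -> combined score.

    Pass either ``fastq_path`` or an iterable of ``reads``.  When the total
    cfDNA concentration is missing the copies/ml stage is skipped with an
    explicit QC flag; fractions are still reported.  ``max_retained_ch``
    (default off) discards accepted reads whose retained non-CpG cytosines
    indicate incomplete bisulfite conversion.
    """
    if reads is None:
        if fastq_path is None:
            raise ValueError("either fastq_path or reads is required")
        reads = read_fastq(fastq_path)
    reads = list(reads)
    assigned, unassigned = demultiplex(reads, panel, max_barcode_mismatch)

    marker_counts: dict[str, MarkerCounts] = {}
    qc_rows = []
    for marker in panel:
        entries = assigned[marker.name]
        tally = _batch_quantify_marker(
            entries, marker, scoring, score_threshold_factor, min_read_length,
            max_retained_ch,
        )
        mc = MarkerCounts(marker.name, tally["accepted"], tally["unmethylated"])
        marker_counts[marker.name] = mc
        n_cpg = len(marker.cpg_positions)
        qc_rows.append(
            {
                "marker": marker.name,
                "total_reads": len(entries),
                "accepted": tally["accepted"],
                "rejected_score": tally["rejected_score"],
                "rejected_short": tally["rejected_short"],
                "rejected_ch": tally["rejected_ch"],
                "ambiguous_molecules": tally["ambiguous_molecules"],
                "ambiguous_call_rate": (
                    tally["ambiguous_sites"] / (tally["accepted"] * n_cpg)
                    if tally["accepted"]
                    else float("nan")
                ),
            }
        )

    flags = []
    for name, mc in marker_counts.items():
        if not mc.defined:
            flags.append(f"marker {name}: no accepted molecules, fraction undefined")

    if cfdna_ng_per_ml is None:
        copies = {name: float("nan") for name in marker_counts}
        combined, contributing = float("nan"), 0
        flags.append("cfdna_ng_per_ml missing: copies/ml stage skipped")
    else:
        copies = {
            name: copies_per_ml(mc.fraction, cfdna_ng_per_ml)
            for name, mc in marker_counts.items()
        }
        combined, contributing = combine_markers(copies)
        if contributing == 0:
            flags.append("no marker with a defined fraction: combined score undefined")

    quant = SampleQuant(
        sample_id=sample_id,
        cfdna_ng_per_ml=cfdna_ng_per_ml,
        marker_counts=marker_counts,
        copies=copies,
        combined_score=combined,
        contributing_markers=contributing,
    )
    qc = QCReport(
        sample_id=sample_id,
        n_reads=len(reads),
        n_unassigned=len(unassigned),
        per_marker=pd.DataFrame(qc_rows),
        flags=flags,
    )
    return quant, qc
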