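"""Synthetic multiplexed bisulfite-amplicon sequencing reads.

Emulates the plasma input of the assay: a mixture in which a small fraction of
molecules at each marker locus derives from colon (CpGs unmethylated) against
a background of blood-derived molecules (CpGs methylated).  Molecules pass
through bisulfite conversion with imperfect efficiency, PCR/sequencing
substitution error, and barcode tagging, and are emitted as FASTQ with known
per-molecule ground truth.

Base qualities are constant dummies; the downstream pipeline never consults
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .panel import MarkerDefinition, MarkerPanel

__all__ = [
    "PlasmaMixtureConfig",
    "GroundTruth",
    "simulate_molecules",
    "simulate_sample_reads",
    "write_fastq",
    "read_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
DUMMY_QUALITY = 40  # 'I'


@dataclass(frozen=True)
class PlasmaMixtureConfig:
    """Mixture and noise model for one simulated plasma sample.

    Parameters
    ----------
    colon_fraction
        Probability a molecule is colon-derived (unmethylated at all marker
        CpGs).  Clinically relevant values are small (~1e-3 .. 0.2).
    n_molecules_per_marker
        Sequenced molecules per amplicon.
    conversion_efficiency
        Probability an unmethylated cytosine is converted to T.
    inappropriate_conversion_rate
        Probability a methylated CpG cytosine is wrongly converted.
    seq_error_rate
        Per-base substitution probability (applied to the insert, not the
        barcode).
    indel_rate
        Per-base probability of a 1-bp insertion or deletion; 0 by default so
        the alignment acceptance property stays analytic.
    seed
        Seeds all randomness; a fixed seed makes the output bit-identical.
    """

    colon_fraction: float = 0.05
    n_molecules_per_marker: int = 5000
    conversion_efficiency: float = 0.995
    inappropriate_conversion_rate: float = 0.002
    seq_error_rate: float = 0.001
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "colon_fraction",
            "conversion_efficiency",
            "inappropriate_conversion_rate",
            "seq_error_rate",
            "indel_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_molecules_per_marker < 0:
            raise ValueError("n_molecules_per_marker must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Per-molecule origin labels and per-marker origin counts."""

    molecules: pd.DataFrame  # columns: read_id, marker, origin ('colon'|'background')

    @property
    def per_marker_counts(self) -> pd.DataFrame:
        tab = (
            self.molecules.groupby(["marker", "origin"])
            .size()
            .unstack(fill_value=0)
            .reindex(columns=["colon", "background"], fill_value=0)
        )
        tab["total"] = tab.sum(axis=1)
        return tab

    def colon_fraction(self, marker: str) -> float:
        sub = self.molecules[self.molecules["marker"] == marker]
        if len(sub) == 0:
            return float("nan")
        return float((sub["origin"] == "colon").mean())

    def write_csv(self, path: str | Path) -> None:
        self.molecules.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "GroundTruth":
        return cls(molecules=pd.read_csv(path))


def _simulate_marker_matrix(
    marker: MarkerDefinition, cfg: PlasmaMixtureConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised molecule simulation for one marker.

    Returns (reads byte-matrix of shape (n, L) without barcode, origin bool
    array: True = colon).  Substitution noise only; indels are applied later,
    per-read, because they change read length.
    """
    n = cfg.n_molecules_per_marker
    ref = np.frombuffer(marker.reference_seq.encode(), dtype="S1")
    L = ref.size
    mat = np.tile(ref, (n, 1))
    is_colon = rng.random(n) < cfg.colon_fraction

    c_mask = ref == b"C"
    cpg_mask = np.zeros(L, dtype=bool)
    cpg_mask[list(marker.cpg_positions)] = True
    ch_mask = c_mask & ~cpg_mask

    # CH cytosines are unmethylated in every molecule
    conv = rng.random((n, L)) < cfg.conversion_efficiency
    mat[np.broadcast_to(ch_mask, (n, L)) & conv] = b"T"

    # CpG cytosines: unmethylated in colon molecules, methylated in background
    cpg_conv = np.where(
        is_colon[:, None],
        rng.random((n, L)) < cfg.conversion_efficiency,
        rng.random((n, L)) < cfg.inappropriate_conversion_rate,
    )
    mat[np.broadcast_to(cpg_mask, (n, L)) & cpg_conv] = b"T"

    # substitution sequencing error: replace by a uniformly random *other* base
    if cfg.seq_error_rate > 0:
        err = rng.random((n, L)) < cfg.seq_error_rate
        idx = np.nonzero(err)
        if idx[0].size:
            cur = mat[idx]
            offs = rng.integers(1, 4, size=idx[0].size)
            cur_codes = np.searchsorted(_BASES, cur)
            mat[idx] = _BASES[(cur_codes + offs) % 4]
    return mat, is_colon


def _apply_indels(
    read: str, rng: np.random.Generator, indel_rate: float
) -> str:
    if indel_rate <= 0:
        return read
    out = []
    for b in read:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        out.append(b)
        if indel_rate / 2 <= r < indel_rate:
            out.append(str(rng.choice(list("ACGT"))))  # insertion after base
    return "".join(out)


def simulate_molecules(
    panel: MarkerPanel, cfg: PlasmaMixtureConfig
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Simulate one multiplexed sample as ``(read_id, sequence)`` pairs.

    Each molecule is drawn colon-origin with probability ``colon_fraction``;
    colon molecules start from the all-CpG-unmethylated template and
    background molecules from the all-CpG-methylated one.  Conversion and
    sequencing noise are applied per base and the marker barcode is
    prepended.  This is the cheap representation; use
    :func:`simulate_sample_reads` for FASTQ records.
    """
    rng = np.random.default_rng(cfg.seed)
    pairs: list[tuple[str, str]] = []
    truth_rows: list[tuple[str, str, str]] = []
    for marker in panel:
        mat, is_colon = _simulate_marker_matrix(marker, cfg, rng)
        inserts = [row.tobytes().decode() for row in mat]
        for i, insert in enumerate(inserts):
            if cfg.indel_rate > 0:
                insert = _apply_indels(insert, rng, cfg.indel_rate)
            read_id = f"{marker.name}_{i:06d}"
            pairs.append((read_id, marker.barcode + insert))
            truth_rows.append(
                (read_id, marker.name, "colon" if is_colon[i] else "background")
            )
    truth = GroundTruth(
        molecules=pd.DataFrame(truth_rows, columns=["read_id", "marker", "origin"])
    )
    return pairs, truth


def simulate_sample_reads(
    panel: MarkerPanel, cfg: PlasmaMixtureConfig
) -> tuple[list[SeqRecord], GroundTruth]:
    """Simulate one multiplexed sample as FASTQ records with dummy qualities.

    See :func:`simulate_molecules` for the mixture and noise model.
    """
    pairs, truth = simulate_molecules(panel, cfg)
    records: list[SeqRecord] = []
    for read_id, seq in pairs:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [DUMMY_QUALITY] * len(seq)
        records.append(rec)
    return records, truth


def write_fastq(records: list[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    yield from SeqIO.parse(str(path), "fastq")
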