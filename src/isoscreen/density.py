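"""Mapping coverage tracks onto spliced CDS coordinates and the
characteristic ribosome-density statistic.

The characteristic density of a gene is the arithmetic mean of per-base
densities over the first 150 codons of its CDS (truncated for shorter CDSs).
A composite over several tracks is either the density of the per-base sum of
the tracks (``sum_tracks``, the default — emulating a composite coverage
track aggregated over many studies) or the mean of per-track densities
(``mean_tracks``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import CoverageTrack, TranscriptModel

DEFAULT_WINDOW_CODONS = 150

AGGREGATION_MODES = ("sum_tracks", "mean_tracks")


@dataclass(frozen=True)
class RiboDensity:
    """A gene's characteristic ribosome density over the 5' window."""

    gene_id: str
    transcript_id: str
    characteristic_density: float
    codons_used: int
    track_ids: tuple[str, ...]
    aggregation_mode: str

    def __post_init__(self) -> None:
        if self.characteristic_density < 0:
            raise ValueError("density must be non-negative")
        if self.aggregation_mode not in AGGREGATION_MODES:
            raise ValueError(f"unknown mode {self.aggregation_mode!r}")


def spliced_cds_coverage(
    track: CoverageTrack, tx: TranscriptModel
) -> np.ndarray:
    """Per-base densities in spliced CDS coordinates.

    Position 0 is the first base of the start codon; exon junctions are
    seamless; minus-strand transcripts are read in transcript orientation.
    A chromosome absent from the track yields an all-zero vector.
    """
    pieces: list[np.ndarray] = []
    for start, end in tx.cds_segments:
        vals = track.region_values(tx.chromosome, start, end)
        if tx.strand == "-":
            vals = vals[::-1]
        pieces.append(vals)
    return np.concatenate(pieces) if pieces else np.zeros(0)


def characteristic_density(
    cds_vector: np.ndarray | Sequence[float],
    n_codons: int = DEFAULT_WINDOW_CODONS,
) -> float:
    """Mean per-base density over the first ``min(n_codons*3, len)`` bases."""
    vec = np.asarray(cds_vector, dtype=np.float64)
    if vec.size < 3:
        raise ValueError("CDS vector shorter than one codon")
    window = min(n_codons * 3, vec.size)
    return float(vec[:window].mean())


def window_codons(cds_length: int, n_codons: int = DEFAULT_WINDOW_CODONS) -> int:
    """Number of codons actually covered by the 5' window."""
    return min(n_codons, cds_length // 3)


def composite_density(
    tracks: Sequence[CoverageTrack],
    tx: TranscriptModel,
    mode: str = "sum_tracks",
    n_codons: int = DEFAULT_WINDOW_CODONS,
) -> RiboDensity:
    """Characteristic density aggregated over several tracks."""
    if not tracks:
        raise ValueError("need at least one coverage track")
    if mode not in AGGREGATION_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    vectors = [spliced_cds_coverage(t, tx) for t in tracks]
    if mode == "sum_tracks":
        value = characteristic_density(np.sum(vectors, axis=0), n_codons)
    else:
        value = float(
            np.mean([characteristic_density(v, n_codons) for v in vectors])
        )
    return RiboDensity(
        gene_id=tx.gene_id,
        transcript_id=tx.transcript_id,
        characteristic_density=value,
        codons_used=window_codons(tx.cds_length, n_codons),
        track_ids=tuple(t.track_id for t in tracks),
        aggregation_mode=mode,
    )
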