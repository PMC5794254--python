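"""Readers/writers for FASTA, GFF3 (CDS features) and bedGraph, plus the
coordinate-backbone domain types.

All internal coordinates are 0-based half-open; conversion to/from file
conventions (GFF3 is 1-based inclusive, bedGraph is already 0-based half-open)
happens only in this module.  Sequences are stored uppercase; input case is
ignored.  All readers transparently accept gzip-compressed files.

The FASTA and GFF3 readers are implemented directly (rather than delegating to
a parsing library) because the pipeline's contracts require strict per-line
validation — illegal residues, missing transcript attribution and overlapping
CDS segments must fail loudly with the offending line number.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

_ALPHABETS = {"nucleotide": NUCLEOTIDE_ALPHABET, "protein": PROTEIN_ALPHABET}


class FormatError(ValueError):
    """A file violated its declared format; message names file and line."""


def _open_text(path: str | Path) -> io.TextIOBase:
    """Open plain or gzip-compressed text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


# ---------------------------------------------------------------------------
# Sequence records
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """A named sequence with a declared alphabet (stored uppercase)."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.residues = self.residues.upper()
        bad = set(self.residues) - _ALPHABETS[self.alphabet]
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal {self.alphabet} characters "
                f"{sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into SequenceRecords.

    Line wrapping is removed and record order preserved.  Malformed headers or
    residues outside the IUPAC set for *alphabet* raise :class:`FormatError`
    naming the offending line.
    """
    allowed = _ALPHABETS.get(alphabet)
    if allowed is None:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list[SequenceRecord] = []
    header: str | None = None
    description = ""
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FormatError(
                f"{path}:{header_line}: record {header!r} has no sequence"
            )
        records.append(
            SequenceRecord(header, residues, description=description, alphabet=alphabet)
        )

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                head = line[1:].strip()
                if not head:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                parts = head.split(None, 1)
                header = parts[0]
                description = parts[1] if len(parts) > 1 else ""
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                seq = line.strip().upper()
                bad = set(seq) - allowed
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: illegal {alphabet} characters "
                        f"{sorted(bad)!r}"
                    )
                chunks.append(seq)
    flush()
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as wrapped FASTA (gzip if *path* ends in .gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:  # type: ignore[operator]
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Transcript / locus models
# ---------------------------------------------------------------------------


@dataclass
class TranscriptModel:
    """A transcript's CDS as ordered genomic segments.

    ``cds_segments`` are 0-based half-open genomic intervals sorted 5'->3' in
    transcript orientation: ascending genomic order on '+', descending on '-'.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    cds_segments: list[tuple[int, int]]
    gene_symbol: str = ""
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if not self.cds_segments:
            raise ValueError(f"{self.transcript_id}: no CDS segments")
        for start, end in self.cds_segments:
            if not (0 <= start < end):
                raise ValueError(
                    f"{self.transcript_id}: bad segment [{start},{end})"
                )
        by_start = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping CDS segments "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        want = by_start if self.strand == "+" else by_start[::-1]
        if self.cds_segments != want:
            raise ValueError(
                f"{self.transcript_id}: segments not in transcript orientation"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_segments)

    @property
    def in_frame(self) -> bool:
        """True when the spliced CDS length is divisible by 3."""
        return self.cds_length % 3 == 0


@dataclass
class GeneLocus:
    """A gene with its transcripts and (optionally) annotated proteins."""

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    proteins: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"locus {self.gene_id}: no transcripts")
        for tx in self.transcripts:
            if tx.gene_id != self.gene_id:
                raise ValueError(
                    f"locus {self.gene_id}: transcript {tx.transcript_id} "
                    f"belongs to {tx.gene_id}"
                )


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            continue
        key, value = item.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3_cds(path: str | Path) -> list[GeneLocus]:
    """Parse CDS features from GFF3 into GeneLocus objects.

    Coordinates are converted from 1-based inclusive to 0-based half-open and
    segments ordered 5'->3' in transcript orientation.  Transcript attribution
    comes from ``transcript_id`` or ``Parent``; gene attribution from
    ``gene_id``, ``gene`` or (as a fallback) the transcript id.  A CDS feature
    with neither transcript attribute is a :class:`FormatError`.
    """
    # transcript_id -> accumulated state
    tx_info: dict[str, dict] = {}
    order: list[str] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = cols
            if ftype != "CDS":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise FormatError(f"{path}:{lineno}: bad interval {start1}-{end1}")
            if strand not in {"+", "-"}:
                raise FormatError(f"{path}:{lineno}: CDS needs explicit strand")
            attrs = _parse_gff3_attributes(attr_s)
            tx_id = attrs.get("transcript_id") or attrs.get("Parent")
            if not tx_id:
                raise FormatError(
                    f"{path}:{lineno}: CDS feature lacks transcript_id/Parent"
                )
            gene_id = attrs.get("gene_id") or attrs.get("gene") or tx_id
            info = tx_info.setdefault(
                tx_id,
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "strand": strand,
                    "segments": [],
                    "gene_symbol": attrs.get("gene_symbol", ""),
                    "protein_id": attrs.get("protein_id", ""),
                },
            )
            if tx_id not in order:
                order.append(tx_id)
            if info["chrom"] != chrom or info["strand"] != strand:
                raise FormatError(
                    f"{path}:{lineno}: transcript {tx_id} mixes "
                    "chromosomes or strands"
                )
            info["segments"].append((start1 - 1, end1))  # to 0-based half-open
            if not info["protein_id"] and attrs.get("protein_id"):
                info["protein_id"] = attrs["protein_id"]

    loci: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tx_id in order:
        info = tx_info[tx_id]
        segments = sorted(info["segments"])
        if info["strand"] == "-":
            segments = segments[::-1]
        tx = TranscriptModel(
            transcript_id=tx_id,
            gene_id=info["gene_id"],
            chromosome=info["chrom"],
            strand=info["strand"],
            cds_segments=segments,
            gene_symbol=info["gene_symbol"],
            protein_id=info["protein_id"],
        )
        if tx.gene_id not in loci:
            gene_order.append(tx.gene_id)
        loci.setdefault(tx.gene_id, []).append(tx)
    return [GeneLocus(gene_id, loci[gene_id]) for gene_id in gene_order]


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------


class CoverageTrack:
    """Per-chromosome, per-base non-negative read density.

    Stored as sorted non-overlapping intervals per chromosome; positions not
    covered by any interval have density 0.
    """

    def __init__(self, track_id: str = "") -> None:
        self.track_id = track_id
        # chrom -> (starts, ends, values) as numpy arrays sorted by start
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._data)

    def add_intervals(
        self, chrom: str, intervals: Sequence[tuple[int, int, float]]
    ) -> None:
        """Register (start, end, value) intervals; overlaps raise ValueError."""
        existing: list[tuple[int, int, float]] = []
        if chrom in self._data:
            s, e, v = self._data[chrom]
            existing = list(zip(s.tolist(), e.tolist(), v.tolist()))
        merged = sorted(existing + list(intervals))
        for (s1, e1, _), (s2, e2, _) in zip(merged, merged[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{chrom}: overlapping intervals [{s1},{e1}) and [{s2},{e2})"
                )
        for start, end, value in merged:
            if value < 0:
                raise ValueError(f"{chrom}:{start}-{end}: negative density {value}")
            if end <= start or start < 0:
                raise ValueError(f"{chrom}: bad interval [{start},{end})")
        self._data[chrom] = (
            np.array([m[0] for m in merged], dtype=np.int64),
            np.array([m[1] for m in merged], dtype=np.int64),
            np.array([m[2] for m in merged], dtype=np.float64),
        )

    def density_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and starts[i] <= pos < ends[i]:
            return float(values[i])
        return 0.0

    def region_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base densities over [start, end) in genomic orientation."""
        if end < start:
            raise ValueError(f"bad region [{start},{end})")
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self._data or end == start:
            return out
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(int(starts[i]), start)
            b = min(int(ends[i]), end)
            if a < b:
                out[a - start : b - start] = values[i]
        return out

    def total_mass(self) -> float:
        """Sum of density over all bases: sum of value * (end - start)."""
        return float(
            sum(
                float(((e - s) * v).sum())
                for s, e, v in self._data.values()
            )
        )

    def scaled(self, factor: float) -> "CoverageTrack":
        """Return a copy with every density multiplied by *factor* (>= 0)."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        out = CoverageTrack(self.track_id)
        for chrom, (s, e, v) in self._data.items():
            out._data[chrom] = (s.copy(), e.copy(), v * factor)
        return out

    def intervals(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._data:
            return []
        s, e, v = self._data[chrom]
        return list(zip(s.tolist(), e.tolist(), v.tolist()))


def read_bedgraph(path: str | Path, track_id: str | None = None) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) into a CoverageTrack.

    Negative values and overlapping intervals are rejected — densities must be
    pre-aggregated to one value per base per track.
    """
    track = CoverageTrack(track_id or str(path))
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
                value = float(cols[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad numeric field") from exc
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative value {value}")
            if end <= start or start < 0:
                raise FormatError(f"{path}:{lineno}: bad interval [{start},{end})")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    for chrom, intervals in per_chrom.items():
        try:
            track.add_intervals(chrom, intervals)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a CoverageTrack as 4-column bedGraph, chromosomes sorted."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:  # type: ignore[operator]
        for chrom in track.chromosomes:
            for start, end, value in track.intervals(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def sha256_of(path: str | Path) -> str:
    """Hex SHA-256 of a file, for run manifests."""
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
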