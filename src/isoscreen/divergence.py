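"""Codon-aligned comparison of two homologous CDSs.

Every compared codon pair is classified as identical, silent-only (nucleotide
change(s) but the same amino acid) or replacement (amino acid differs; a codon
with both silent and replacement characters counts as replacement so the
classes partition).  Stop codons are trimmed before comparison — the
percent-of-codons figures refer to sense codons.

Codon pairing is protein-guided: both CDSs are translated, the proteins are
globally aligned, and gaps are mapped back onto codons; gapped columns are
excluded from the counts but reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

from Bio.Data import CodonTable

from . import alignment
from .genome_io import SequenceRecord

log = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
STOP_CODONS = frozenset(_STANDARD.stop_codons)


class InternalStopError(ValueError):
    """A CDS contains a premature stop codon."""


def translate_codon(codon: str, table: CodonTable.CodonTable | None = None) -> str:
    """Single-codon translation; '*' for stop; ValueError on ambiguity."""
    table = table or _STANDARD
    codon = codon.upper().replace("U", "T")
    if codon in table.stop_codons:
        return "*"
    try:
        return table.forward_table[codon]
    except KeyError as exc:
        raise ValueError(f"cannot translate codon {codon!r}") from exc


def _residues(seq: SequenceRecord | str) -> str:
    if isinstance(seq, SequenceRecord):
        return seq.residues
    return str(seq).upper()


def split_codons(cds: SequenceRecord | str, trim_stop: bool = True) -> list[str]:
    """Split a CDS into codons, optionally trimming one trailing stop codon.

    Length must be divisible by 3; an internal stop raises
    :class:`InternalStopError` naming the 1-based codon position.
    """
    seq = _residues(cds).replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if trim_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for i, codon in enumerate(codons, start=1):
        if codon in STOP_CODONS:
            raise InternalStopError(f"internal stop codon {codon} at codon {i}")
    return codons


@dataclass(frozen=True)
class CodonAlignment:
    """Paired codons from a protein-guided alignment of two CDSs."""

    pairs: tuple[tuple[str, str], ...]
    excluded_gap_columns: int


def codon_align(
    cds_a: SequenceRecord | str, cds_b: SequenceRecord | str
) -> CodonAlignment:
    """Pair codons of two CDSs via global alignment of their translations."""
    codons_a = split_codons(cds_a)
    codons_b = split_codons(cds_b)
    prot_a = "".join(translate_codon(c) for c in codons_a)
    prot_b = "".join(translate_codon(c) for c in codons_b)
    aln = alignment.global_align(prot_a, prot_b)

    pairs: list[tuple[str, str]] = []
    excluded = 0
    ia = ib = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca == alignment.GAP:
            ib += 1
            excluded += 1
        elif cb == alignment.GAP:
            ia += 1
            excluded += 1
        else:
            pairs.append((codons_a[ia], codons_b[ib]))
            ia += 1
            ib += 1
    return CodonAlignment(pairs=tuple(pairs), excluded_gap_columns=excluded)


@dataclass(frozen=True)
class SubstitutionReport:
    """Per-codon classification of differences between two aligned CDSs."""

    n_codons_compared: int
    codons_identical: int
    codons_silent_only: int
    codons_replacement: int
    nt_differences: int
    aa_differences: int
    pct_nt_difference: float
    pct_codons_affected: float
    pct_codons_silent_only: float
    excluded_gap_columns: int = 0
    excluded_ambiguous: int = 0

    def __post_init__(self) -> None:
        total = self.codons_identical + self.codons_silent_only + self.codons_replacement
        if total != self.n_codons_compared:
            raise ValueError("codon classes do not partition the compared codons")

    def to_dict(self) -> dict:
        return asdict(self)


def classify_substitutions(
    codon_aln: CodonAlignment,
) -> SubstitutionReport:
    """Classify every paired codon and tally nucleotide/amino-acid differences.

    Pairs containing a non-ACGT base are excluded with a logged warning.
    """
    identical = silent = replacement = 0
    nt_diffs = 0
    ambiguous = 0
    for ca, cb in codon_aln.pairs:
        if set(ca + cb) - set("ACGT"):
            ambiguous += 1
            log.warning("ambiguous codon pair %s/%s excluded", ca, cb)
            continue
        diffs = sum(1 for x, y in zip(ca, cb) if x != y)
        if diffs == 0:
            identical += 1
            continue
        nt_diffs += diffs
        if translate_codon(ca) == translate_codon(cb):
            silent += 1
        else:
            replacement += 1
    n = identical + silent + replacement
    return SubstitutionReport(
        n_codons_compared=n,
        codons_identical=identical,
        codons_silent_only=silent,
        codons_replacement=replacement,
        nt_differences=nt_diffs,
        aa_differences=replacement,
        pct_nt_difference=100.0 * nt_diffs / (3 * n) if n else 0.0,
        pct_codons_affected=100.0 * (silent + replacement) / n if n else 0.0,
        pct_codons_silent_only=100.0 * silent / n if n else 0.0,
        excluded_gap_columns=codon_aln.excluded_gap_columns,
        excluded_ambiguous=ambiguous,
    )


def compare_cds(
    cds_a: SequenceRecord | str, cds_b: SequenceRecord | str
) -> SubstitutionReport:
    """codon_align + classify_substitutions in one call."""
    return classify_substitutions(codon_align(cds_a, cds_b))
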