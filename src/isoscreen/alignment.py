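"""Global pairwise alignment and identity metrics.

The screen needs identity fractions, not homology-search sensitivity, so the
scoring is deliberately simple (match +1, mismatch -1, linear gap -2 for both
alphabets) — simple enough that a brute-force enumeration oracle over tiny
strings is exact, which is how the implementation is tested.

Traceback is deterministic: ties are broken diagonal > up > left, where "up"
consumes a base of sequence *a* (gap in *b*).
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import SequenceRecord

GAP = "-"

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2


@dataclass(frozen=True)
class Alignment:
    """A global alignment of two sequences with summary counts."""

    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    mismatches: int
    gap_columns: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        if self.matches + self.mismatches + self.gap_columns != len(self.aligned_a):
            raise ValueError("column counts do not sum to alignment length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)


def _as_residues(seq: SequenceRecord | str) -> tuple[str, str | None]:
    if isinstance(seq, SequenceRecord):
        return seq.residues, seq.alphabet
    return str(seq).upper(), None


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    match: float = MATCH_SCORE,
    mismatch: float = MISMATCH_SCORE,
    gap: float = GAP_SCORE,
) -> Alignment:
    """Needleman-Wunsch global alignment with linear gap penalty.

    Raises ValueError on empty input or mixed alphabets.
    """
    sa, alph_a = _as_residues(a)
    sb, alph_b = _as_residues(b)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    if alph_a is not None and alph_b is not None and alph_a != alph_b:
        raise ValueError(f"mixed alphabets: {alph_a} vs {alph_b}")

    n, m = len(sa), len(sb)
    # score[i][j] = best score aligning sa[:i] with sb[:j]
    prev = [j * gap for j in range(m + 1)]
    # pointers: 0=diag, 1=up (consume a), 2=left (consume b)
    ptr = [[0] * (m + 1) for _ in range(n + 1)]
    for j in range(1, m + 1):
        ptr[0][j] = 2
    for i in range(1, n + 1):
        cur = [i * gap] + [0.0] * m
        ptr[i][0] = 1
        ca = sa[i - 1]
        row_ptr = ptr[i]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ca == sb[j - 1] else mismatch)
            up = prev[j] + gap
            left = cur[j - 1] + gap
            # tie-break priority: diagonal > up > left
            best, which = diag, 0
            if up > best:
                best, which = up, 1
            if left > best:
                best, which = left, 2
            cur[j] = best
            row_ptr[j] = which
        prev = cur

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        which = ptr[i][j]
        if i > 0 and j > 0 and which == 0:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and (which == 1 or j == 0):
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))

    matches = mismatches = gap_columns = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP or y == GAP:
            gap_columns += 1
        elif x == y:
            matches += 1
        else:
            mismatches += 1
    return Alignment(aligned_a, aligned_b, float(prev[m]), matches, mismatches, gap_columns)


def percent_identity(aln: Alignment, denominator: str = "longer_sequence") -> float:
    """100 * matches / denominator.

    *denominator* is ``longer_sequence`` (default; conservative for the
    "identical over their entire length" semantics) or ``alignment_length``.
    """
    if denominator == "longer_sequence":
        len_a = sum(1 for c in aln.aligned_a if c != GAP)
        len_b = sum(1 for c in aln.aligned_b if c != GAP)
        denom = max(len_a, len_b)
    elif denominator == "alignment_length":
        denom = aln.length
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * aln.matches / denom


def length_ratio(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """min(len)/max(len) in [0, 1]; zero-length input is an error."""
    la = len(a.residues) if isinstance(a, SequenceRecord) else len(a)
    lb = len(b.residues) if isinstance(b, SequenceRecord) else len(b)
    if la == 0 or lb == 0:
        raise ValueError("length ratio undefined for empty sequence")
    return min(la, lb) / max(la, lb)
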