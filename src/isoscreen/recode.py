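"""Minimal-substitution CRISPR knock-in recoding and restriction genotyping.

``minimal_recode`` edits a source CDS so it encodes a given target protein
using the fewest possible single-base substitutions: for each codon whose
amino acid must change, the synonymous codon of the target residue at minimum
Hamming distance from the source codon is chosen (ties broken
lexicographically); codons already encoding the target residue are untouched.

A realized knock-in design may deliberately exceed the minimum — e.g. to
destroy the guide/PAM match and prevent re-cutting.  That is modeled as an
explicit ``disrupt:<motif>[:<min_edits>]`` constraint forcing at least
*min_edits* substitutions within every window where the motif matches the
source CDS, never assumed.

Restriction utilities cover exact-motif site scanning (both strands for
non-palindromic motifs) and linear digest simulation; a small built-in enzyme
table includes EcoRV (GATATC, blunt cut at offset 3).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Sequence

from .divergence import split_codons, translate_codon, _STANDARD
from .genome_io import SequenceRecord

#: enzyme -> (recognition motif, cut offset from motif start on the top strand)
ENZYMES: dict[str, tuple[str, int]] = {
    "EcoRV": ("GATATC", 3),
    "EcoRI": ("GAATTC", 1),
    "BamHI": ("GGATCC", 1),
    "HindIII": ("AAGCTT", 1),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _codons_for(aa: str) -> list[str]:
    """Sense codons encoding amino acid *aa*, sorted lexicographically."""
    codons = sorted(c for c, a in _STANDARD.forward_table.items() if a == aa)
    if not codons:
        raise ValueError(f"no codon encodes residue {aa!r}")
    return codons


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass(frozen=True)
class Substitution:
    """One single-base edit in CDS coordinates (codon_index is 1-based)."""

    cds_position: int
    ref_base: str
    alt_base: str
    codon_index: int


@dataclass
class RecodePlan:
    """An edited CDS with its substitution list and applied constraints."""

    substitutions: list[Substitution]
    edited_cds: str
    constraints_applied: list[str] = field(default_factory=list)

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    def to_dict(self) -> dict:
        return {
            "n_substitutions": self.n_substitutions,
            "substitutions": [asdict(s) for s in self.substitutions],
            "edited_cds": self.edited_cds,
            "constraints_applied": list(self.constraints_applied),
        }


def _diff_substitutions(source: str, edited: str) -> list[Substitution]:
    subs = [
        Substitution(i, s, e, i // 3 + 1)
        for i, (s, e) in enumerate(zip(source, edited))
        if s != e
    ]
    return subs


def parse_constraint(text: str) -> tuple[str, str, int]:
    """Parse ``disrupt:<motif>[:<min_edits>]`` into (kind, motif, min_edits)."""
    parts = text.split(":")
    if parts[0] != "disrupt" or len(parts) not in (2, 3) or not parts[1]:
        raise ValueError(f"unsupported constraint {text!r}")
    motif = parts[1].upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"constraint motif must be over ACGT: {text!r}")
    min_edits = int(parts[2]) if len(parts) == 3 else 1
    if min_edits < 1:
        raise ValueError("min_edits must be >= 1")
    return "disrupt", motif, min_edits


def minimal_recode(
    source_cds: SequenceRecord | str,
    target_protein: SequenceRecord | str,
    constraints: Sequence[str] = (),
) -> RecodePlan:
    """Minimal-substitution recoding of *source_cds* to encode *target_protein*.

    The source may carry a trailing stop codon (kept untouched); its sense
    length must match the target protein exactly.
    """
    src = (
        source_cds.residues
        if isinstance(source_cds, SequenceRecord)
        else str(source_cds).upper()
    ).replace("U", "T")
    tgt = (
        target_protein.residues
        if isinstance(target_protein, SequenceRecord)
        else str(target_protein).upper()
    )
    codons = split_codons(src)  # validates frame, trims stop, rejects internal stops
    if len(codons) != len(tgt):
        raise ValueError(
            f"target protein length {len(tgt)} != source sense codons {len(codons)}"
        )
    tail = src[3 * len(codons) :]  # trailing stop codon, if any

    edited_codons: list[str] = []
    for codon, aa in zip(codons, tgt):
        if translate_codon(codon) == aa:
            edited_codons.append(codon)
        else:
            candidates = _codons_for(aa)
            best = min(candidates, key=lambda c: (_hamming(codon, c), c))
            edited_codons.append(best)
    edited = "".join(edited_codons) + tail

    applied: list[str] = []
    for text in constraints:
        kind, motif, min_edits = parse_constraint(text)
        edited = _apply_disrupt(src, edited, tgt, motif, min_edits)
        applied.append(text)

    return RecodePlan(
        substitutions=_diff_substitutions(src, edited),
        edited_cds=edited,
        constraints_applied=applied,
    )


def _apply_disrupt(
    source: str, edited: str, target_protein: str, motif: str, min_edits: int
) -> str:
    """Force >= min_edits substitutions within every source window matching motif.

    Extra edits are synonymous in the edited reading frame, chosen to add the
    fewest additional substitutions, preferring windows' 3'-most codons
    (deterministic).  Raises ValueError when the requirement cannot be met
    synonymously.
    """
    n_sense = len(target_protein) * 3
    windows = [
        (i, i + len(motif)) for i in range(len(source) - len(motif) + 1)
        if source[i : i + len(motif)] == motif
    ]
    for w_start, w_end in windows:
        current = sum(
            1 for i in range(w_start, min(w_end, len(edited)))
            if edited[i] != source[i]
        )
        if current >= min_edits:
            continue
        needed = min_edits - current
        # candidate synonymous codon swaps overlapping the window, 3'-most first
        codon_lo = w_start // 3
        codon_hi = min((w_end - 1) // 3, n_sense // 3 - 1)
        progressed = True
        while needed > 0 and progressed:
            progressed = False
            for ci in range(codon_hi, codon_lo - 1, -1):
                cur_codon = edited[3 * ci : 3 * ci + 3]
                aa = translate_codon(cur_codon)
                options = []
                for alt in _codons_for(aa):
                    if alt == cur_codon:
                        continue
                    gain = sum(
                        1
                        for k in range(3)
                        if 3 * ci + k in range(w_start, w_end)
                        and alt[k] != source[3 * ci + k]
                        and cur_codon[k] == source[3 * ci + k]
                    )
                    if gain > 0:
                        extra = _hamming(cur_codon, alt)
                        options.append((extra, alt, gain))
                if options:
                    options.sort(key=lambda o: (o[0], o[1]))
                    extra, alt, gain = options[0]
                    edited = edited[: 3 * ci] + alt + edited[3 * ci + 3 :]
                    needed -= gain
                    progressed = True
                    if needed <= 0:
                        break
        if needed > 0:
            raise ValueError(
                f"cannot place {min_edits} synonymous edits in window "
                f"[{w_start},{w_end})"
            )
    return edited


def count_substitutions(
    seq_a: SequenceRecord | str,
    seq_b: SequenceRecord | str,
    window: tuple[int, int] | None = None,
) -> int:
    """Number of differing positions, optionally restricted to [start, end)."""
    a = seq_a.residues if isinstance(seq_a, SequenceRecord) else str(seq_a).upper()
    b = seq_b.residues if isinstance(seq_b, SequenceRecord) else str(seq_b).upper()
    if window is not None:
        start, end = window
        a, b = a[start:end], b[start:end]
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return _hamming(a, b)


@dataclass(frozen=True)
class RestrictionSite:
    position: int
    strand: str


def find_restriction_sites(
    seq: SequenceRecord | str, motif: str
) -> list[RestrictionSite]:
    """All exact motif matches; non-palindromic motifs are scanned on both strands.

    Positions are 0-based starts on the top strand.  For a palindromic motif a
    single scan suffices (strand '+').
    """
    s = seq.residues if isinstance(seq, SequenceRecord) else str(seq).upper()
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over ACGT")
    sites = [
        RestrictionSite(i, "+")
        for i in range(len(s) - len(motif) + 1)
        if s[i : i + len(motif)] == motif
    ]
    rc = reverse_complement(motif)
    if rc != motif:
        sites += [
            RestrictionSite(i, "-")
            for i in range(len(s) - len(rc) + 1)
            if s[i : i + len(rc)] == rc
        ]
        sites.sort(key=lambda x: (x.position, x.strand))
    return sites


@dataclass(frozen=True)
class DigestResult:
    """Fragments of a linear molecule after cutting at every motif site."""

    enzyme_name: str
    recognition_motif: str
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.cut_positions) != len(self.fragment_lengths) - 1:
            raise ValueError("cut count must be fragment count - 1")


def digest_fragments(
    amplicon: SequenceRecord | str,
    motif: str | None = None,
    cut_offset: int | None = None,
    enzyme: str | None = None,
) -> DigestResult:
    """Simulate a restriction digest of a linear amplicon.

    Either give *enzyme* (looked up in :data:`ENZYMES`) or an explicit
    *motif* + *cut_offset*.  Cuts fall at ``site_start + cut_offset`` (top
    strand) for every site; fragment lengths are returned 5'->3' and always
    sum to the amplicon length.
    """
    if enzyme is not None:
        if enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {enzyme!r}")
        motif, cut_offset = ENZYMES[enzyme]
        name = enzyme
    else:
        if motif is None or cut_offset is None:
            raise ValueError("need enzyme or motif + cut_offset")
        name = f"custom({motif})"
    seq = (
        amplicon.residues
        if isinstance(amplicon, SequenceRecord)
        else str(amplicon).upper()
    )
    cuts = sorted(
        {site.position + cut_offset for site in find_restriction_sites(seq, motif)}
    )
    for cut in cuts:
        if not (0 < cut < len(seq)):
            raise ValueError(f"cut position {cut} outside sequence")
    bounds = [0] + cuts + [len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(
        enzyme_name=name,
        recognition_motif=motif,
        cut_positions=tuple(cuts),
        fragment_lengths=fragments,
    )
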