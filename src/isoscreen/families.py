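"""Clustering of near-identical proteins from different genes into families.

A family is a connected component of the graph whose edges join gene pairs
passing both the length-ratio and percent-identity thresholds
(single-linkage, so chains of similarity merge).  Singletons are discarded:
the screen statistic needs at least two members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import alignment
from .genome_io import GeneLocus, SequenceRecord

log = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 90.0
DEFAULT_LENGTH_RATIO_THRESHOLD = 0.9


@dataclass(frozen=True)
class SimilarityEdge:
    """An undirected above-threshold link between two genes' proteins."""

    gene_a: str
    gene_b: str
    identity: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("self-edges are not allowed")


@dataclass
class IsoformFamily:
    """A cluster of >=2 near-identical proteins encoded by different genes."""

    family_id: str
    member_gene_ids: tuple[str, ...]
    member_protein_ids: tuple[str, ...]
    identity_min: float
    identity_mean: float
    identity_max: float

    def __post_init__(self) -> None:
        if len(self.member_gene_ids) < 2:
            raise ValueError(f"{self.family_id}: a family needs >=2 members")
        if len(set(self.member_gene_ids)) != len(self.member_gene_ids):
            raise ValueError(f"{self.family_id}: duplicate gene ids")


def longest_protein_per_locus(
    loci: Iterable[GeneLocus],
) -> dict[str, SequenceRecord]:
    """Pick one protein per gene: the longest, ties broken by smallest id.

    Loci without any annotated protein are skipped with a logged warning.
    """
    chosen: dict[str, SequenceRecord] = {}
    for locus in loci:
        if not locus.proteins:
            log.warning("locus %s has no protein; skipped", locus.gene_id)
            continue
        best = min(locus.proteins, key=lambda p: (-len(p.residues), p.id))
        chosen[locus.gene_id] = best
    return chosen


def similarity_edges(
    proteins: Mapping[str, SequenceRecord],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    length_ratio_threshold: float = DEFAULT_LENGTH_RATIO_THRESHOLD,
    strict: bool = False,
    identity_denominator: str = "longer_sequence",
) -> list[SimilarityEdge]:
    """All gene pairs whose proteins pass both thresholds.

    Thresholds are inclusive (>=) by default; ``strict=True`` switches to
    strict (>) inequalities.  Pairs failing the cheap length-ratio check are
    never aligned.
    """

    def passes(value: float, threshold: float) -> bool:
        return value > threshold if strict else value >= threshold

    gene_ids = sorted(proteins)
    edges: list[SimilarityEdge] = []
    for i, ga in enumerate(gene_ids):
        for gb in gene_ids[i + 1 :]:
            pa, pb = proteins[ga], proteins[gb]
            if not passes(alignment.length_ratio(pa, pb), length_ratio_threshold):
                continue
            aln = alignment.global_align(pa, pb)
            ident = alignment.percent_identity(aln, identity_denominator)
            if passes(ident, identity_threshold):
                edges.append(SimilarityEdge(ga, gb, ident))
    return edges


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_families(
    edges: Sequence[SimilarityEdge],
    proteins: Mapping[str, SequenceRecord] | None = None,
) -> list[IsoformFamily]:
    """Single-linkage families = connected components of the edge graph.

    Families are sorted by member tuple and numbered F0001, F0002, ...; the
    identity summary is over the family's above-threshold edges.  When
    *proteins* is given, member protein ids are taken from it.
    """
    uf = _UnionFind()
    for e in edges:
        uf.union(e.gene_a, e.gene_b)
    components: dict[str, list[str]] = {}
    for e in edges:
        for g in (e.gene_a, e.gene_b):
            root = uf.find(g)
            members = components.setdefault(root, [])
            if g not in members:
                members.append(g)

    families: list[IsoformFamily] = []
    ordered = sorted(tuple(sorted(m)) for m in components.values())
    for idx, members in enumerate(ordered, start=1):
        mset = set(members)
        idents = [e.identity for e in edges if e.gene_a in mset and e.gene_b in mset]
        protein_ids = tuple(
            proteins[g].id if proteins and g in proteins else "" for g in members
        )
        families.append(
            IsoformFamily(
                family_id=f"F{idx:04d}",
                member_gene_ids=tuple(members),
                member_protein_ids=protein_ids,
                identity_min=min(idents),
                identity_mean=sum(idents) / len(idents),
                identity_max=max(idents),
            )
        )
    return families


def build_families(
    proteins: Mapping[str, SequenceRecord],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    length_ratio_threshold: float = DEFAULT_LENGTH_RATIO_THRESHOLD,
    strict: bool = False,
) -> list[IsoformFamily]:
    """Convenience: similarity_edges + cluster_families."""
    edges = similarity_edges(
        proteins,
        identity_threshold=identity_threshold,
        length_ratio_threshold=length_ratio_threshold,
        strict=strict,
    )
    return cluster_families(edges, proteins)


def write_families_tsv(
    families: Sequence[IsoformFamily],
    proteins: Mapping[str, SequenceRecord],
    path: str | Path,
) -> None:
    """One row per family member: family_id, gene, protein, length, identities."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "family_id\tgene_id\tprotein_id\tprotein_length\t"
            "identity_min\tidentity_mean\tidentity_max\n"
        )
        for fam in families:
            for gene_id, protein_id in zip(
                fam.member_gene_ids, fam.member_protein_ids
            ):
                length = len(proteins[gene_id]) if gene_id in proteins else 0
                fh.write(
                    f"{fam.family_id}\t{gene_id}\t{protein_id}\t{length}\t"
                    f"{fam.identity_min:.3f}\t{fam.identity_mean:.3f}\t"
                    f"{fam.identity_max:.3f}\n"
                )
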