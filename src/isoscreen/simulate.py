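"""Fully synthetic genomes, annotations, proteomes and coverage tracks with
planted isoform families and controlled density ratios.

Every pipeline stage is testable without downloads: each family is an
ancestral protein mutated to a requested identity per member, reverse
translated with randomized synonymous codons (creating silent divergence),
embedded as a multi-exon gene on a random strand, and covered by per-base
read counts drawn from a negative binomial around the member's planted mean
density.  A truth TSV records everything that was planted, so tests never
reverse-engineer the simulation.

All randomness flows from a single ``numpy`` generator seeded once; the same
spec + seed yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import actin
from .genome_io import (
    CoverageTrack,
    SequenceRecord,
    write_bedgraph,
    write_fasta,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# sense codons per amino acid, lexicographic (standard code)
from .divergence import _STANDARD  # noqa: E402

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)


@dataclass
class SyntheticDatasetSpec:
    """Knobs of the generator; see module docstring for semantics.

    ``density_ratios`` has one entry per family (max member mean / min member
    mean); ``family_densities`` optionally overrides it with explicit member
    means per family (used e.g. to plant a family proportional to the
    published actin densities).
    """

    seed: int = 0
    n_families: int = 2
    members_per_family: int = 2
    protein_length: int = 80
    within_family_identity: float = 95.0
    density_ratios: list[float] = field(default_factory=lambda: [1000.0, 1.0])
    base_density: float = 2.0
    noise_dispersion: float = 5.0
    n_exons_range: tuple[int, int] = (1, 3)
    minus_strand_fraction: float = 0.5
    n_tracks: int = 1
    family_densities: list[list[float]] | None = None

    def validate(self) -> None:
        if self.members_per_family < 2:
            raise ValueError("members_per_family must be >= 2")
        if not (85.0 <= self.within_family_identity <= 100.0):
            raise ValueError("within_family_identity must be in [85, 100]")
        if self.protein_length < 10:
            raise ValueError("protein_length must be >= 10")
        if self.base_density <= 0:
            raise ValueError("base_density must be positive")
        if self.noise_dispersion <= 0:
            raise ValueError("noise_dispersion must be positive")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if not (0 <= self.minus_strand_fraction <= 1):
            raise ValueError("minus_strand_fraction must be in [0, 1]")
        lo, hi = self.n_exons_range
        if lo < 1 or hi < lo:
            raise ValueError("bad n_exons_range")
        if self.family_densities is not None:
            if len(self.family_densities) != self.n_families:
                raise ValueError("family_densities must have n_families entries")
            for means in self.family_densities:
                if len(means) != self.members_per_family:
                    raise ValueError(
                        "each family_densities entry needs members_per_family values"
                    )
                if any(m <= 0 for m in means):
                    raise ValueError("planted densities must be positive")
        else:
            if len(self.density_ratios) != self.n_families:
                raise ValueError("density_ratios must have n_families entries")
            if any(r < 1 for r in self.density_ratios):
                raise ValueError("density ratios are max/min and must be >= 1")
        n_mut = round((1 - self.within_family_identity / 100) * self.protein_length)
        if n_mut > self.protein_length - 1:
            raise ValueError("identity too low for protein length")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlantedGene:
    gene_id: str
    family_id: str
    protein: SequenceRecord
    cds: str
    mean_density: float
    chromosome: str
    strand: str
    # genomic CDS segments in transcript orientation, 0-based half-open
    cds_segments: list[tuple[int, int]]
    chromosome_seq: str


@dataclass
class SyntheticDataset:
    spec: SyntheticDatasetSpec
    genes: list[PlantedGene]
    tracks: list[CoverageTrack]


def _mutate_protein(
    ancestral: str, identity: float, rng: np.random.Generator
) -> str:
    """Substitute enough positions (never the initial M) to hit *identity*."""
    n_mut = round((1 - identity / 100) * len(ancestral))
    if n_mut == 0:
        return ancestral
    positions = rng.choice(np.arange(1, len(ancestral)), size=n_mut, replace=False)
    residues = list(ancestral)
    for pos in sorted(positions.tolist()):
        alternatives = [a for a in AMINO_ACIDS if a != residues[pos]]
        residues[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(residues)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous codon per residue, plus a TAA stop."""
    codons = []
    for aa in protein:
        options = _CODONS_BY_AA[aa]
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons) + "TAA"


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _member_means(spec: SyntheticDatasetSpec, fam_index: int) -> list[float]:
    if spec.family_densities is not None:
        return list(spec.family_densities[fam_index])
    ratio = spec.density_ratios[fam_index]
    m = spec.members_per_family
    lo = spec.base_density
    hi = spec.base_density * ratio
    if m == 1:
        return [hi]
    # geometric interpolation from max down to min
    return [
        float(hi * (lo / hi) ** (i / (m - 1))) for i in range(m)
    ]


def build_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Generate the dataset in memory (see :func:`generate_dataset` for files)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes: list[PlantedGene] = []

    for f in range(spec.n_families):
        family_id = f"fam{f + 1:03d}"
        ancestral = "M" + "".join(
            AMINO_ACIDS[i]
            for i in rng.integers(0, len(AMINO_ACIDS), size=spec.protein_length - 1)
        )
        means = _member_means(spec, f)
        for m in range(spec.members_per_family):
            gene_id = f"{family_id}_g{m + 1}"
            prot = _mutate_protein(ancestral, spec.within_family_identity, rng)
            cds = _reverse_translate(prot, rng)
            strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
            n_exons = int(rng.integers(spec.n_exons_range[0], spec.n_exons_range[1] + 1))
            n_exons = min(n_exons, len(cds) // 3)

            # split the spliced CDS into n_exons chunks of >= 3 nt
            if n_exons == 1:
                exon_lens = [len(cds)]
            else:
                cuts = sorted(
                    (3 * rng.choice(
                        np.arange(1, len(cds) // 3), size=n_exons - 1, replace=False
                    )).tolist()
                )
                bounds = [0] + cuts + [len(cds)]
                exon_lens = [b - a for a, b in zip(bounds, bounds[1:])]
            intron_lens = [int(rng.integers(20, 101)) for _ in range(n_exons - 1)]
            flank = 50

            # sense-orientation cassette: flank + exon/intron alternation + flank
            parts = [_random_dna(flank, rng)]
            sense_exon_intervals: list[tuple[int, int]] = []
            offset = flank
            pos = 0
            for i, elen in enumerate(exon_lens):
                parts.append(cds[pos : pos + elen])
                sense_exon_intervals.append((offset, offset + elen))
                offset += elen
                pos += elen
                if i < n_exons - 1:
                    intron = _random_dna(intron_lens[i], rng)
                    parts.append(intron)
                    offset += len(intron)
            parts.append(_random_dna(flank, rng))
            cassette = "".join(parts)

            chrom = f"chr_{gene_id}"
            if strand == "+":
                chrom_seq = cassette
                segments = sense_exon_intervals
            else:
                chrom_seq = _revcomp(cassette)
                total = len(cassette)
                segments = [(total - e, total - s) for s, e in sense_exon_intervals]
                # transcript orientation on '-' = descending genomic order
            genes.append(
                PlantedGene(
                    gene_id=gene_id,
                    family_id=family_id,
                    protein=SequenceRecord(
                        f"{gene_id}_p1", prot, alphabet="protein"
                    ),
                    cds=cds,
                    mean_density=means[m],
                    chromosome=chrom,
                    strand=strand,
                    cds_segments=segments,
                    chromosome_seq=chrom_seq,
                )
            )

    tracks: list[CoverageTrack] = []
    for t in range(spec.n_tracks):
        track = CoverageTrack(track_id=f"track{t + 1}")
        for gene in genes:
            mu = gene.mean_density / spec.n_tracks
            r = spec.noise_dispersion
            p = r / (r + mu)
            n_bases = sum(e - s for s, e in gene.cds_segments)
            counts = rng.negative_binomial(r, p, size=n_bases).astype(float)
            # lay counts onto genomic coordinates in transcript order
            intervals: list[tuple[int, int, float]] = []
            i = 0
            for s, e in gene.cds_segments:
                chunk = counts[i : i + (e - s)]
                i += e - s
                if gene.strand == "-":
                    chunk = chunk[::-1]  # genomic orientation within segment
                for k, value in enumerate(chunk.tolist()):
                    if value > 0:
                        intervals.append((s + k, s + k + 1, value))
            if intervals:
                track.add_intervals(gene.chromosome, _merge_runs(intervals))
        tracks.append(track)

    return SyntheticDataset(spec=spec, genes=genes, tracks=tracks)


def _merge_runs(
    intervals: list[tuple[int, int, float]]
) -> list[tuple[int, int, float]]:
    """Merge adjacent equal-valued per-base intervals to keep files small."""
    merged: list[tuple[int, int, float]] = []
    for start, end, value in sorted(intervals):
        if merged and merged[-1][1] == start and merged[-1][2] == value:
            merged[-1] = (merged[-1][0], end, value)
        else:
            merged.append((start, end, value))
    return merged


def _write_gff3(dataset: SyntheticDataset, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for gene in dataset.genes:
            segs = sorted(gene.cds_segments)
            g_start, g_end = segs[0][0] + 1, segs[-1][1]
            tx_id = f"{gene.gene_id}_t1"
            fh.write(
                f"{gene.chromosome}\tisoscreen\tgene\t{g_start}\t{g_end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id};gene_id={gene.gene_id}\n"
            )
            fh.write(
                f"{gene.chromosome}\tisoscreen\tmRNA\t{g_start}\t{g_end}\t.\t"
                f"{gene.strand}\t.\tID={tx_id};Parent={gene.gene_id};"
                f"gene_id={gene.gene_id}\n"
            )
            for s, e in segs:
                fh.write(
                    f"{gene.chromosome}\tisoscreen\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t0\tID=cds_{tx_id};Parent={tx_id};"
                    f"gene_id={gene.gene_id};transcript_id={tx_id};"
                    f"protein_id={gene.protein.id}\n"
                )


def generate_dataset(
    spec: SyntheticDatasetSpec, outdir: str | Path
) -> dict[str, Path]:
    """Write the full file bundle and return the path of each artifact.

    Bundle: genome.fna, annotation.gff3, proteins.faa, cds.fna, one bedGraph
    per track, and truth.tsv with the planted values.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = build_dataset(spec)

    paths: dict[str, Path] = {}
    genome_records = [
        SequenceRecord(g.chromosome, g.chromosome_seq) for g in dataset.genes
    ]
    paths["genome"] = outdir / "genome.fna"
    write_fasta(genome_records, paths["genome"])

    paths["proteins"] = outdir / "proteins.faa"
    write_fasta(
        [
            SequenceRecord(
                g.protein.id,
                g.protein.residues,
                description=f"gene_id={g.gene_id}",
                alphabet="protein",
            )
            for g in dataset.genes
        ],
        paths["proteins"],
    )

    paths["cds"] = outdir / "cds.fna"
    write_fasta(
        [
            SequenceRecord(f"{g.gene_id}_t1", g.cds, description=f"gene_id={g.gene_id}")
            for g in dataset.genes
        ],
        paths["cds"],
    )

    paths["annotation"] = outdir / "annotation.gff3"
    _write_gff3(dataset, paths["annotation"])

    track_paths = []
    for track in dataset.tracks:
        p = outdir / f"{track.track_id}.bedgraph"
        write_bedgraph(track, p)
        track_paths.append(p)
    paths["tracks"] = track_paths  # type: ignore[assignment]

    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write(
            "gene_id\tfamily_id\tprotein_id\tprotein_length\tstrand\t"
            "planted_identity\tplanted_mean_density\tfamily_density_ratio\n"
        )
        by_family: dict[str, list[PlantedGene]] = {}
        for g in dataset.genes:
            by_family.setdefault(g.family_id, []).append(g)
        for g in dataset.genes:
            sibs = by_family[g.family_id]
            ratio = max(s.mean_density for s in sibs) / min(
                s.mean_density for s in sibs
            )
            fh.write(
                f"{g.gene_id}\t{g.family_id}\t{g.protein.id}\t"
                f"{len(g.protein)}\t{g.strand}\t"
                f"{spec.within_family_identity:g}\t{g.mean_density:g}\t{ratio:g}\n"
            )
    return paths


def plant_actin_like_family(
    seed: int = 0,
    protein_length: int = 120,
    scale: float = 1.0,
    n_tracks: int = 1,
    noise_dispersion: float = 5.0,
    equal_densities: bool = False,
) -> SyntheticDatasetSpec:
    """Spec for one six-member family with the published actin density profile.

    Member mean densities are proportional to the six published composite
    ribosome densities (optionally rescaled by *scale*, or replaced by their
    common mean when ``equal_densities``); protein identities are planted at
    >= 90% so the family clusters.
    """
    means = [d * scale for d in actin.ACTIN_COMPOSITE_DENSITIES]
    if equal_densities:
        mean = sum(means) / len(means)
        means = [mean] * len(means)
    return SyntheticDatasetSpec(
        seed=seed,
        n_families=1,
        members_per_family=6,
        protein_length=protein_length,
        within_family_identity=96.0,
        density_ratios=[max(means) / min(means)],
        base_density=min(means),
        noise_dispersion=noise_dispersion,
        n_tracks=n_tracks,
        family_densities=[means],
    )
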