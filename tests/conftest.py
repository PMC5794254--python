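from __future__ import annotations

from pathlib import Path

import pytest

from isoscreen import genome_io, simulate

REPO_ROOT = Path(__file__).resolve().parent.parent

#: Optional directory of RefSeq sequences fetched by accession (not bundled;
#: see README).  Tests needing them skip when the files are absent.
REFSEQ_DIR = REPO_ROOT / "data" / "refseq"


def load_refseq(accession: str, alphabet: str) -> genome_io.SequenceRecord:
    suffix = ".faa" if alphabet == "protein" else ".fna"
    path = REFSEQ_DIR / f"{accession}{suffix}"
    if not path.exists():
        pytest.skip(
            f"{accession} not available offline (fetch it into {path} to enable)"
        )
    return genome_io.read_fasta(path, alphabet=alphabet)[0]


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """One high-ratio and one near-flat planted family, written to disk."""
    spec = simulate.SyntheticDatasetSpec(
        seed=11,
        n_families=2,
        members_per_family=2,
        protein_length=60,
        within_family_identity=95.0,
        density_ratios=[1000.0, 1.5],
        base_density=2.0,
        n_tracks=2,
    )
    outdir = tmp_path_factory.mktemp("fixture")
    paths = simulate.generate_dataset(spec, outdir)
    return spec, paths


def proteins_by_gene(path) -> dict[str, genome_io.SequenceRecord]:
    out = {}
    for rec in genome_io.read_fasta(path, alphabet="protein"):
        gene = rec.description.split("gene_id=")[1].split()[0]
        out[gene] = rec
    return out
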