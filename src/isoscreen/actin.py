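"""Published reference constants for the mouse actin isoform family.

The six cytoplasmic/muscle actins are the motivating example for the screen:
near-identical proteins encoded by different genes whose composite ribosome
densities (GWIPS-Viz aggregation over 26 profiling studies, mean per-base
density over the first 150 codons) span roughly 3600-fold.

Also included are the published sequences of the *Actbc-g* knock-in design:
the homology-directed-repair donor template, the sgRNA protospacer, and the
EcoRV motif used for genotyping.  The wild-type *Actb* N-terminal codons are
reconstructed here from three independent published constraints (see
``ACTB_CDS_FIRST10_CODONS``); the full CDS is not bundled and must be fetched
by accession for whole-CDS analyses.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ActinGene:
    """One member of the mouse actin family with its composite ribosome density."""

    name: str
    gene_symbol: str
    protein_accession: str
    mrna_accession: str
    composite_density: float


ACTIN_FAMILY: tuple[ActinGene, ...] = (
    ActinGene("beta-cytoplasmic actin", "Actb", "NP_031419", "NM_007393", 1351.607),
    ActinGene("alpha-smooth muscle actin", "Acta2", "NP_031418", "NM_007392", 53.781),
    ActinGene("alpha-skeletal actin", "Acta1", "NP_033736", "NM_009606", 10.267),
    ActinGene("alpha-cardiac actin", "Actc1", "NP_033738", "NM_009608", 3.872),
    ActinGene("gamma-cytoplasmic actin", "Actg1", "NP_033739", "NM_009609", 1.289),
    ActinGene("gamma-enteric smooth muscle actin", "Actg2", "NP_033740", "NM_009610", 0.377),
)

#: Composite ribosome densities in the table order above (Actb ... Actg2).
ACTIN_COMPOSITE_DENSITIES: tuple[float, ...] = tuple(
    g.composite_density for g in ACTIN_FAMILY
)

#: HDR donor template for the Actbc-g edit (sense strand, 5'->3', as published).
#: Carries the five point mutations that recode the beta-actin N-terminus to
#: the gamma-actin decapeptide and destroy both the EcoRV site and the guide
#: protospacer.
ACTBCG_DONOR_TEMPLATE = (
    "CGGCTGTTGGCGGCCCCGAGGTGACTATAGCCTTCTTTTGTGTCTTGATAGTAGTTCGCC"
    "ATGGAAGAGGAAATCGCTGCGCTGGTCATTGACAACGGCTCCGGCATGTGCAAAGCCGGC"
    "TTCGCGGGCGACGATGCTCCCCGGGCTGTA"
)

#: sgRNA protospacer targeting wild-type Actb (published lowercase; stored
#: uppercase per package convention), followed by the CGG PAM in the genome.
ACTBCG_GUIDE = "GCTGCGCTGGTCGTCGACAA"
ACTBCG_PAM = "CGG"

#: EcoRV recognition motif; the wild-type Actb N-terminus contains one site
#: (codons 4-5, GAT|ATC) which the edit destroys.
ECORV_MOTIF = "GATATC"

#: Wild-type mouse Actb CDS, first 10 codons.  Not printed verbatim in the
#: source publications but pinned by three independent published facts:
#: (1) the protospacer GCTGCGCTGGTCGTCGACAA is the wild-type sense strand over
#:     codons 6-12 (A-A-L-V-V-D + 2 nt),
#: (2) the EcoRV site GATATC spans codons 4-5 and is present in the wild type,
#: (3) the beta-actin N-terminal decapeptide is MDDDIAALVV and the donor
#:     differs from the wild type by exactly five point substitutions, all
#:     third-position or codon-10 changes (so every Asp codon differs from the
#:     donor's Glu codon by exactly one base regardless of GAT/GAC choice).
ACTB_CDS_FIRST10_CODONS = "ATGGATGACGATATCGCTGCGCTGGTCGTC"

#: Gamma-actin N-terminal decapeptide (the recoding target of Actbc-g).
ACTG1_NTERM_DECAPEPTIDE = "MEEEIAALVI"

#: Beta-actin N-terminal decapeptide.
ACTB_NTERM_DECAPEPTIDE = "MDDDIAALVV"


def donor_coding_region() -> str:
    """Return the donor template from its start codon onward.

    The donor carries 5' homology arm sequence before the ATG; the coding
    portion starts at the (unique) ``ATGGAAGAG`` match.
    """
    idx = ACTBCG_DONOR_TEMPLATE.index("ATGGAAGAG")
    return ACTBCG_DONOR_TEMPLATE[idx:]


def donor_first10_codons() -> str:
    """First 10 codons (30 nt) of the donor's recoded reading frame."""
    return donor_coding_region()[:30]
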