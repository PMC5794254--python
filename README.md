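# isoscreen

A ribosome-density divergence screen for families of near-identical protein
isoforms encoded by different genes.

The package:

1. clusters a proteome into **isoform families** — proteins at least 90%
   identical over at least 90% of their length, encoded by different genes
   (single-linkage over pairwise global alignments);
2. quantifies each gene's **characteristic ribosome density** — the mean
   per-base profiling density over the first 150 codons of its CDS, mapped
   from genomic coverage tracks through spliced, strand-aware CDS
   coordinates, optionally aggregated over many tracks;
3. ranks families by the **normalized SD** (sample coefficient of variation)
   of member densities, discards families whose best-translated member has
   density < 1, and selects the top 100 families with normalized SD >= 1.4;
4. provides supporting tools: codon-aligned **silent vs. replacement**
   substitution classification of two CDSs, **minimal-substitution CRISPR
   recoding** of a CDS to encode a different protein (with an optional
   guide-disruption constraint), restriction-site scanning and **digest
   genotyping** simulation, and a fully **synthetic data generator** with
   planted families and controlled density ratios.

## Layout

| module                  | purpose                                             |
| ----------------------- | --------------------------------------------------- |
| `isoscreen.genome_io`   | FASTA / GFF3-CDS / bedGraph I/O, coordinate types   |
| `isoscreen.alignment`   | Needleman–Wunsch global alignment, identity metrics |
| `isoscreen.families`    | longest-protein-per-locus, similarity edges, single-linkage families |
| `isoscreen.density`     | spliced CDS coverage, characteristic/composite density |
| `isoscreen.screen`      | normalized SD, filters, ranking, end-to-end screen  |
| `isoscreen.divergence`  | codon alignment, silent/replacement classification  |
| `isoscreen.recode`      | minimal recoding plans, restriction sites, digests  |
| `isoscreen.simulate`    | synthetic genomes/annotations/tracks with planted truth |
| `isoscreen.cli`         | `isoscreen` command with all subcommands            |
| `isoscreen.actin`       | published reference constants (densities, donor/guide sequences) |

## CLI

```bash
# synthetic dataset with planted families
isoscreen simulate --seed 7 --outdir fixtures/

# end-to-end screen
isoscreen screen --proteins fixtures/proteins.faa \
    --gff3 fixtures/annotation.gff3 --tracks fixtures/track1.bedgraph \
    --identity 90 --length-ratio 0.9 --min-max-density 1.0 \
    --sd-threshold 1.4 --top 100 --out report.tsv

# individual stages
isoscreen density --gff3 ann.gff3 --tracks a.bedgraph,b.bedgraph \
    --mode sum_tracks --out densities.tsv
isoscreen cluster --proteins proteome.faa --out families.tsv
isoscreen diverge --cds-a beta.fna --cds-b gamma.fna --out report.json
isoscreen recode --source-cds wt.fna --target-protein target.faa \
    --constraints disrupt:GCTGCGCTGGTCGTCGACAA:2 --out plan.json
isoscreen digest --amplicon amp.fna --enzyme EcoRV --out digest.json
```

Every subcommand writes a `.manifest.json` next to its report recording the
tool version, input checksums and all thresholds.  Reports themselves are
deterministic given the manifest inputs.

## Reference sequences (optional, network required once)

```bash
mkdir -p data/refseq
base="https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
curl "$base?db=nuccore&id=NM_007393&rettype=fasta_cds_na&retmode=text" > data/refseq/NM_007393.fna
curl "$base?db=nuccore&id=NM_009609&rettype=fasta_cds_na&retmode=text" > data/refseq/NM_009609.fna
curl "$base?db=protein&id=NP_031419&rettype=fasta&retmode=text"        > data/refseq/NP_031419.faa
curl "$base?db=protein&id=NP_033739&rettype=fasta&retmode=text"        > data/refseq/NP_033739.faa
```

With these in place the two skipped tests run and `scripts/acceptance.py`
emits the `t3`/`t4` targets.
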