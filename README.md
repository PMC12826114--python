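# jumbophage

A toolkit for discovering **jumbo bacteriophages** (genomes > 200 kb) in gut
metagenome assemblies and analysing their ecology: CRISPR-spacer interaction
networks, alternative genetic codes, crAss-like phage classification,
proteome-based family demarcation, and compositional co-abundance networks.
It is aimed at virome researchers who have assembled contigs and per-gene
annotation tables and want a reproducible, fully tested implementation of the
rule set used to build jumbo-phage catalogues from pig (or other mammalian)
gut metagenomes.

## What it computes

**Discovery.** A contig is screened with four viral signatures and called a
phage when it has ≥ 2 genes with virus-specific product keywords
(*capsid, terminase, portal, …*), no prokaryote-specific term
(*ribosomal protein, DNA gyrase subunit A, …*), and at least one CRISPR
spacer match from a prokaryote genome. Bacterial false positives are removed
with the **BUSCO ratio** r = (genes hitting bacterial universal single-copy
orthologs) / (total genes), retaining genomes with r < 0.067; genomes
> 200 kb form the jumbo catalogue. Lifestyle is assigned from a lysogeny
score s (virulent s < 0.5, uncertain 0.5 ≤ s ≤ 0.9, temperate s > 0.9, with
provirus evidence overriding to temperate).

**Alternative genetic codes.** Coding density d(c) (fraction of the genome
covered by six-frame ORFs, minimum 90 nt) is computed under the standard
code 11 and under stop-codon reassignments 15 (TAG), 90 (TAA), 91 (TGA); a
genome is recoded iff d(c) ≥ 1.10 · d(11).

**crAss-like phages.** Genomes > 70 kb are crAss-like if a translated search
against the crAssphage polymerase/terminase markers scores E < 1e-10
(Karlin–Altschul ungapped statistics), or if ≥ 95 % nucleotide identity
covers ≥ 80 % of the genome against a crAssphage reference.

**CRISPR interaction networks.** Repeat-spacer arrays are detected with a
CRT-style scan (≥ 3 repeat copies of 23–47 nt, spacers 26–50 nt); a spacer
hits a target genome when an ungapped alignment covers ≥ 95 % of the spacer
with ≤ 1 mismatch. Directed spacer edges define phage–phage and phage–host
networks; pairs with edges both ways are *mutual*, spacer-linked pairs whose
predicted host phyla intersect are *competitive*.

**Family demarcation.** Orthologues are reciprocal best hits (E ≤ 1e-5,
identity ≥ 30 %, coverage ≥ 50 % of the shorter protein). Two genomes are
split into different families only when their patristic distance on the
whole-proteome neighbour-joining tree is ≥ 0.05 **and** they share < 10 % of
orthologous protein clusters; families are connected components of the
complementary relation.

**Co-abundance networks.** Abundance is mean read depth, zeroed when breadth
(positions at ≥ 1×) is ≤ 0.25. SparCC basis correlations are estimated from
log-ratio variances t_ij = Var(log x_i/x_j) via the linear system
Σ_j t_ij = (D−2)ω_i + Σ_k ω_k, ρ_ij = (ω_i+ω_j−t_ij)/(2√(ω_i ω_j)), with
Dirichlet resampling, strong-pair exclusion, and a 1,000-iteration
permutation bootstrap; edges with p < 0.001 form the signed network.

## Worked example

Every stage runs on synthetic communities with planted, ground-truthed
signals — no downloads needed:

```bash
jpa synth --seed 5 --outdir demo --n-phage 3 --n-contaminant 1
jpa discover --genomes demo/genomes.fasta --annotations demo/annotations.tsv \
    --prokaryotes demo/prokaryotes.fasta --outdir demo/disc
head -4 demo/disc/phage_calls.tsv
```

prints

```
genome_id	is_phage	is_jumbo	n_keyword_genes	busco_ratio	reason
phage_000	True	True	6	0.0	retained
phage_001	True	True	3	0.0	retained
phage_002	True	True	6	0.0	retained
```

— the three planted phages are retained (≥ 2 keyword genes, BUSCO ratio 0.0,
spacer evidence from the prokaryote genomes), while the planted bacterial
contaminant is removed with a machine-readable reason code. The same library
calls are available in Python via `jumbophage.pipeline.run_pipeline`, and
`jpa run` executes all stages (discovery → genetic codes/crAss → CRISPR
network → families → co-abundance) writing TSV intermediates and a JSON
report.

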