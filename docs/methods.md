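# Methods

This note documents the models, rules and numerical choices implemented in
`jumbophage`, the assumptions behind the synthetic data, and the limits of
what the test suite demonstrates.

## Discovery rules

A contig enters the jumbo catalogue when it passes four gates, in order:

1. **Keyword rule.** ≥ 2 genes whose free-text product contains a
   virus-specific keyword (the comma-delimited list in
   `config.VIRUS_KEYWORDS`, kept verbatim from the screening protocol —
   including the compound token "tapemeasure neck"), no gene containing a
   prokaryote-specific exclusion term, and ≥ 1 CRISPR spacer match whose
   source is a prokaryote genome. Matching is case-insensitive substring:
   "tail" inside "tailless" counts, a documented limitation inherent to
   keyword-list screening. When no prokaryote reference genomes are
   supplied, the spacer-evidence requirement cannot be evaluated and is
   waived (logged in the report).
2. **BUSCO ratio** = bacterial-marker hits / total predicted genes, with a
   strict boundary: ratio < 0.067 passes, exactly 0.067 fails. The
   denominator is the genome's own gene count, not the size of the marker
   set: a per-gene fraction is the only dimensionless form of "quantifying
   hits" per genome, and the 0–0.067 reference benchmark is itself a ratio.
3. **Jumbo size**: length > 200,000 bp, strict.
4. **Lifestyle** (reported, not filtering): virulent < 0.5,
   uncertain [0.5, 0.9] (closed — the printed inequalities for the other
   two classes are open), temperate > 0.9; a provirus flag overrides any
   score to temperate, merging integrated-prophage evidence with the
   score-based call.

The four *viral signatures* (viral protein families present, microbial
families absent, nucleotide signature, long same-strand gene runs) are
scored for reporting with conservative documented thresholds — ≥ 10 % viral
family hits, ≤ 2 % microbial family hits, a same-strand run of ≥ 10 genes —
because the upstream protocol cites no numbers. The nucleotide-signature
predicate is pluggable and defaults to "always false": no trained sequence
model ships with the package. All thresholds live in `RunConfig`.

Host breadth: *generalist* = predicted hosts span ≥ 2 phyla, *archaeal* =
any archaeal host, with generalist taking priority when both apply (the
overlap is otherwise undefined); *unknown* = no predictions.

## Alternative genetic codes

The ORF caller is a deterministic six-frame maximal-ORF scan: starts
{ATG, GTG, TTG}, stop set {TAA, TAG, TGA} minus the code's reassigned codon,
minimum span 90 nt including the stop codon, codons containing N never act
as start or stop. ORFs that run into a frame boundary without a stop are
kept (open ORFs). This choice is deliberate: it makes coding density
monotone under stop-codon reassignment — removing a stop can only merge or
extend ORFs, never delete one — which is both the biologically intended
behaviour and a tested invariant; it also mirrors how edge genes are
handled by standard gene callers. Coding density is the length of the union
of all qualifying ORF spans on both strands divided by genome length,
without overlap resolution; the 10 % density *ratio* the assignment rule
needs is robust to the caller's exact gene set. A genome is assigned the
densest alternative code whose density is ≥ 1.10 × the code-11 density,
else code 11; a genome with zero code-11 density is reported as code 11
with an `density_undefined` flag.

Translation of recoded genes uses the field conventions 15: TAG→Q,
90: TAA→Q, 91: TGA→W; the density computation never depends on the amino
acid chosen.

## crAss-like classification

Criterion 1 is a translated (BLASTx-like) search of the genome against the
polymerase and terminase markers: exact 5-peptide seeds followed by
ungapped X-drop extension along the seed diagonal, scored with BLOSUM62 and
assessed with ungapped Karlin–Altschul statistics (λ = 0.318, K = 0.13,
search space = genome length × marker length × 6 frames); hit iff
E < 1e-10. Seeded extension is the standard equivalent of full dynamic
programming at these score scales — any homologue passing the E-value gate
shares exact seeds. Criterion 2 cuts the genome into 1,000-nt fragments and
aligns each to the reference with banded semi-global edit distance (edlib),
counting a fragment as aligned at ≥ 95 % identity; the genome passes at
aligned fraction ≥ 0.80 (an ANI-style, deterministic reading of "≥95 %
identity over ≥80 % of the genome"; the denominator is the query genome).
The bundled marker FASTA contains *synthetic stand-ins* (the file says so);
real crAssphage markers can be supplied via flag. The 70 kb gate is local
to this classifier; the pipeline applies it to the full candidate pool and
reports which crAss-like genomes are also in the jumbo catalogue.

## CRISPR arrays and spacer matching

Array detection is a CRT-style scan with MinCED's default bounds: an 8-nt
window is chased for exact recurrences at repeat+spacer spacing (49–97 nt),
the repeat is extended column-wise across all copies, and the array is
validated against ≥ 3 copies, repeat 23–47 nt, spacers 26–50 nt. Detection
operates on the forward strand; a repeat-spacer structure is
strand-symmetric, so no separate reverse scan is needed.

A spacer matches a target locus when an ungapped alignment covers ≥ 95 % of
the spacer with ≤ 1 substitution; indels are not tolerated and N matches
nothing. End-trimming implements the coverage allowance (≤ 2 positions at
these spacer lengths). The production matcher seeds candidate offsets with
four exact quarter-slices — pigeonhole-lossless for ≤ 1 substitution plus
≤ 2 trimmed ends — and is tested for exact agreement with an exhaustive
sliding-window scan. Self-matches (spacer against its own genome) are
excluded; overlapping windows at one locus are merged keeping the best
(max coverage, then fewest mismatches).

Network semantics: a directed edge A→B means a spacer carried by A matches
B. Mutual pairs have edges both ways. *Competitive* is not defined by the
source protocol; the implemented interpretation — spacer-linked in either
direction **and** intersecting predicted host phylum sets — encodes
"competition requires a shared host" and is flagged as an interpretation.
One-target vs multi-target pairs are reported as spacer-locus multiplicity.
The summary reports both normalisations of the competitive fraction (over
all spacer pairs, which matches the published 16.94 %, and over phage–phage
pairs) and both directed-edge and unordered-pair counts, because the
published counts do not disambiguate them.

## Orthologues, proteomic tree, families

Orthologues are reciprocal best hits under Smith–Waterman (BLOSUM62, gap
open 11 / extend 1) with E ≤ 1e-5 (ungapped Karlin–Altschul parameters as a
documented approximation for gapped scores), identity ≥ 30 %, and coverage
≥ 50 % of the shorter protein — the coverage gate is an addition that
prevents domain-only spurious orthologues and is configurable. A
shared-5-peptide prefilter (BLAST-like seeding) skips hopeless pairs.
"Orthologous protein clusters" are realised as pairwise RBH sets rather
than global clusters — a documented simplification. The shared fraction
divides by the smaller proteome and is clamped to [0, 1].

Proteome similarity S = Σ orthologue-pair bit scores / min(self bit
scores), distance D = 1 − S. The tree is neighbour joining (scikit-bio)
with negative branch lengths clamped to zero; for additive matrices the
patristic distances reproduce the input exactly (tested to 1e-9). This
distance+NJ construction is a deterministic surrogate for a
maximum-likelihood whole-proteome tree; the 0.05 divergence threshold is
applied to **patristic distance** (the natural reading when the published
threshold names a log-scale branch-length separation without fixing
node depth vs path length) and is configurable.

Demarcation: genomes a, b stay together iff patristic(a,b) < 0.05 **or**
shared(a,b) ≥ 0.10 (a split requires both divergence ≥ 0.05 and sharing
< 10 %); families are connected components of the together-relation,
labelled by their lexicographically smallest member. The boundary sharing
value of exactly 0.10 keeps a pair together.

## Abundance and co-abundance

Abundance per genome and sample is the mean per-base depth, set to zero
when breadth (fraction of positions with depth ≥ 1) is ≤ 0.25 — the
boundary is inclusive: exactly 75 % of the genome below 1× still zeroes.
Coverage input accepts per-base rows (1-based, like `bedtools genomecov
-d`) or run-length intervals (0-based half-open, like `-bga`); both parsers
are cross-checked on one fixture and densification conserves depth mass.

The correlation stage implements the SparCC estimator: per estimation
iteration, sample fractions are drawn from a Dirichlet(counts+1) posterior;
t_ij = Var(log x_i/x_j); basis variances solve Σ_{j∈N(i)} t_ij =
deg_i·ω_i + Σ_{j∈N(i)} ω_j; ρ_ij = (ω_i+ω_j−t_ij)/(2√(ω_iω_j)) clamped to
[−1, 1]; the strongest pair above the exclusion threshold (default 0.1) is
excluded and the system re-solved for up to 10 rounds; the final ρ is the
element-wise median over 20 iterations. Defaults follow SparCC/FastSpar
conventions and are configurable. A taxon with identical counts in every
sample has no compositional signal: its correlations are reported as NaN,
never fabricated. Significance is a permutation bootstrap (each taxon's
counts shuffled independently across samples, ρ recomputed per dataset from
a single estimation iteration, 1,000 iterations); with p = exceedances/n,
"p < 0.001" at n = 1000 demands zero exceedances — the strict reading —
and a (count+1)/(n+1) estimator is available behind `pvalue_add_one`.
Because the abundance matrix is real-valued after the zero rule, it is
scaled to integer pseudo-counts (×100, rounded) so the Dirichlet resampling
is defined; whether the original analysis correlated raw mean depths or
transformed counts is not stated, so this transform is an explicit,
configurable decision.

## Synthetic data: what it emulates and what it does not

The generators plant every signal the pipeline detects, with truth labels
and brute-force self-validation at generation time (`RunConfig.
self_validate`): keyword-bearing jumbo genomes (200–300 kb) with
sequence-consistent gene tables; contaminants with BUSCO hits on ~20 % of
genes and exclusion terms; stop-codon-recoded genomes whose gene bodies
interleave the reassigned codon with cassettes planting stop codons of two
flavours in every shifted/reverse frame (so the planted code's density gain
is large and specific — the cassette order is permuted per cycle so the
body is not periodic and cannot mimic a CRISPR repeat); crAss-marker
genomes carrying exact in-frame marker CDS copies; CRISPR arrays whose
spacers copy target substrings with an exact number of substitutions
(placed ≥ 3 nt from the spacer ends so boundary trimming cannot change the
planted mismatch count, with filler-spacer boundary bases chosen to pin
repeat-boundary detection); proteome families as ≥ 95 %-identical copies of
family cores; and log-normal compositional count matrices with ±0.9
latent correlations on disjoint planted pairs at total depth 1e5 per
sample, so resampling noise is small relative to planted effects.

The background sequence model is iid uniform nucleotides, adequate because
no stage relies on composition beyond stop-codon statistics. Not emulated:
read-level noise and assembly artefacts, GC/codon bias, phylogenetically
realistic protein evolution, partial/fragmented genomes, and real CRISPR
repeat diversity. Passing the end-to-end suite therefore demonstrates that
the rules are implemented correctly and recover signals that respect their
thresholds with clean margins — not that the thresholds themselves are
optimal for noisy real assemblies.

Default study-community conditions (20 phages, 5 contaminants, 2 recoded
genomes, 1 crAss genome, 3 host genomes, 10 phage–phage spacer edges of
which two are 2-mismatch negative controls, 3 families, 4 planted
correlations, 200 samples) were chosen once to exercise every rule with
its planted margin; the problem sizes keep a full end-to-end run in the
low minutes on one CPU.

## Numerical choices and degenerate inputs

* Percentages are computed as 100·count/total with half-up rounding to two
  decimals (`decimal.Decimal`), matching how summary tables print.
* BUSCO ratio of a zero-gene genome is an error (undefined), not 0.
* ORF calling on sequences shorter than 90 nt returns an empty set with
  density 0; all-N sequences yield no ORFs.
* NJ requires ≥ 3 genomes; correlation inference requires ≥ 3 taxa and ≥ 3
  samples.
* Basis variances are floored at 1e-12 before the square root; ρ is clamped
  to [−1, 1]; exclusion stops when it would leave a taxon with < 2
  partners.
* Empty pipelines (no input genomes) report zeros and exit successfully;
  a missing required input for an enabled stage is a configuration error
  raised before any work starts.
* Determinism: every stochastic component takes a seed; identical seeds
  give byte-identical outputs (tested).

## Known limitations

* The keyword rule inherits the false-positive surface of substring
  matching; the verbatim keyword list contains the token "tapemeasure
  neck" as printed in the protocol it reproduces.
* E-values for gapped protein alignments reuse ungapped Karlin–Altschul
  parameters; at the 1e-5/1e-10 gates with near-identical planted homologues
  this is inconsequential, but E-values near the gate should not be
  over-interpreted.
* The proteomic tree is a distance-based surrogate, not maximum likelihood;
  the 0.05 demarcation is calibrated to that surrogate's scale through the
  D = 1 − S distance.
* RBH orthology has no global clustering by default (a greedy global mode
  would change shared fractions for paralogue-rich proteomes).
* The CRT-style detector targets arrays with near-identical repeat copies;
  highly degenerate repeats found by specialised tools may be missed.
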