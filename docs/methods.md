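# Methods

## Scope and data model

`viralrp` analyses ribosomal-protein (RP) genes carried on viral contigs.
It consumes standard artifacts produced upstream — contigs (FASTA), gene
calls (GFF3 with `ID` attributes), profile-search hits (hmmsearch
per-domain tabular format), variant evidence (TSV or minimal VCF),
candidate host genomes and CRISPR spacer sets (FASTA), and per-contig
sample metadata (TSV) — and produces detection, lifestyle, host, selection
and ecology tables. Profile–profile search itself, alignment construction,
gene prediction and phylogenetics are out of scope: hit tables and gene
calls are inputs.

All internal coordinates are 0-based half-open; 1-based formats (GFF3,
VCF POS) are converted at the parse boundary. The one deliberate
exception is `DomainHit.ali_from/ali_to`, which keeps the 1-based
inclusive convention of the HMMER table for format fidelity and is
converted where used. Sequences are uppercased on read; `N` is allowed in
contigs but rejected inside coding genes by the selection stage.

## Screening

A hit is a confident RP detection when its per-domain (independent)
E-value is ≤ `rp_evalue_max` (default 1e-5) and its domain is in the
shipped RP profile table (`data/rp_domains.tsv`, editable) and not on the
exclusion list. The S1 domain is excluded by default: it is repeated
within bS1 and widespread in non-ribosomal RNA-binding proteins, so an S1
match alone cannot establish a ribosomal identity. Domain names map to
the unified nomenclature, in which the leading lowercase letter marks the
taxonomic range (b/e/u) and the capital letter the subunit (S/L); HPF,
the ribosome hibernation promotion factor (Ribosomal_S30AE domain), is a
ribosome-associated factor rather than a subunit protein and maps to
"other". Per-contig RP content is the set of distinct RP names; a
protein with several RP hits keeps all of them.

`pairwise_identity` is a global alignment under BLOSUM62 with gap
open −11 / extend −1 (Biopython `PairwiseAligner`); identity is identical
aligned positions divided by the *query* length (the viral protein), so a
truncated subject cannot inflate the percentage. Alignment-length
denominators are available via an argument.

## Lifestyle

A contig is putatively temperate when it carries ≥ 1 hit on an
integrase-family marker (Mu-transpos_C, Phage_int_SAM_5, Phage_integrase)
with bit score ≥ 30. Absence of evidence is a lytic-presumed call, not a
lytic proof: most metagenomic contigs are fragments and the integrase may
be off-fragment. The call count is monotone non-increasing in the bit
threshold by construction.

## Host prediction

Two routes, with spacer evidence taking precedence because a CRISPR
spacer is a near-literal sequence record of infection:

* **Spacers.** Every placement of every spacer (≥ 20 nt; both strands) on
  a contig with ≤ 1 mismatch is reported; the host with most matches wins.
  The stringency defaults follow common virus–host linkage practice and
  are configurable.
* **k-mer likelihood.** Each candidate host genome trains an order-k
  Markov model (default k = 8, pseudocount 1, both strands; contexts
  never observed fall back to uniform). A contig's score under a model is
  its mean per-nucleotide log-likelihood, skipping windows containing
  ambiguous bases. The best-scoring candidate is called only if its score
  is significant against a Gaussian fitted to the same contig's scores
  under ≥ 5 decoy models (one-sided upper tail, p ≤ 0.001 by default).
  Decoys should be genomes comparable to, but disjoint from, the
  candidates; when none are supplied the pipeline builds them by seeded
  per-nucleotide shuffles of the candidate genomes (composition preserved,
  higher-order structure erased).

An external BLAST-style homology route is not implemented; tabular
results from one can be merged downstream by the caller.

## Selection: pN/pS

Expected site counts use unweighted Nei–Gojobori enumeration: for each
sense codon and each of its 9 possible single-nucleotide changes, the
change is classified against the genetic code (standard table by default;
the bacterial table is identical at the codon→amino-acid level), and each
codon position contributes syn/3 to S and (3−syn)/3 to N. Consequences:
N + S = 3 per sense codon exactly; stop-creating changes are
non-synonymous; the terminal stop codon is excluded from sites and from
observed counts. Counting is in exact rational arithmetic
(`fractions.Fraction`), so the toy example ATG TTT GGG yields N = 23/3,
S = 4/3 and, with one synonymous and one non-synonymous SNP,
pN/pS = (3/23)/(3/4) = 4/23 with no floating-point slack.

SNP usability: inside the gene span; alt allele supported by ≥ 4 reads at
≥ 1% frequency (package defaults, not taken from any published screen —
they are echoed in output headers); multiallelic sites keep the record
with the largest alt count; a reference base disagreeing with the contig
is an error. Minus-strand genes map positions into CDS frame and
complement alleles before classification, and a minus-strand gene is
exactly equivalent to its plus-strand reverse-complement twin (tested).

Inclusion ("well-sampled"): mean per-gene coverage ≥ 10× (per-site
minimum available via `coverage_rule="per_site"`) and ≥ 1 usable SNP.
The coverage boundary is inclusive (≥), exposed as a config value. With
s_obs = 0 and n_obs > 0 the ratio is undefined and the gene is excluded
from ratio aggregation (`zero_ps`); no pseudocount is applied by default
(an optional +1/+1 mode exists and is labelled in output). The dataset
summary reports the mean per-gene ratio over included genes with defined
ratios and the fraction ≤ 0.20.

## Synthetic virome generator

The generator exists so every stage can be validated against known truth.
What it emulates, and how:

* **Hosts** are order-2 Markov sources whose 16 transition rows are drawn
  from Dirichlet(3,3,3,3) per host — enough divergence that order-8
  likelihoods separate hosts. Genome segments default to 300 kb, which
  exceeds the 4^8 context space several-fold so transition estimates are
  data- rather than pseudocount-dominated.
* **Contigs** (default 50 × 20 kb) are drawn from the true host's source,
  so the k-mer route has signal; each carries an RP ORF with probability
  0.5 (a second with probability 0.05 given the first, mirroring the
  rarity of two-RP contigs), embedded at a random position and strand.
  ORFs are ATG + random sense codons + stop (default 100 sense codons —
  the detected viral RPs are small proteins).
* **Hit tables** plant RP hits at E ≤ 1e-6 and lifestyle hits at bit ≥ 35
  (clear of the screening margins), and also plant decoys a correct screen
  must reject: strong-E S1 rows, weak-E RP rows, sub-threshold integrase
  rows. Temperate carriage defaults to 0.2, a typical lysogen fraction in
  surveyed viromes.
* **Spacers** are literal 30-nt copies (half reverse-complemented) from a
  contig into its true host's spacer set for half the contigs.
* **SNPs** come from acceptance thinning: K ~ Poisson(snp_rate × coding
  length) proposals uniform over (position, alt base) in the sense codons;
  synonymous proposals are always accepted, non-synonymous with
  probability min(ω, 1) (roles swap above 1); at most one SNP per site.
  Coverage is Poisson(mean 50), alt counts Binomial(coverage, f) with
  f ~ U[0.05, 0.5] so the contig consensus stays the major allele.
  Because proposals hit synonymous sites in proportion S/(N+S), the
  *count-level* non-synonymous/synonymous ratio converges to ω·N/S, and
  the site-normalized pN/pS identifies ω. Defaults ω = 0.1 (the strong
  purifying regime typical of functional auxiliary genes) and snp_rate =
  0.01 per coding nucleotide.

All randomness flows from a single `numpy` generator seeded by
`rng_seed`; identical configs give byte-identical datasets.

What the generator does **not** emulate: real read-level error and
mapping bias (variant evidence enters as a clean table), indels and
recombination, gene-content heterogeneity beyond the planted RP/integrase
structure, genuine phylogenetic relatedness among hosts (sources are
independent, making host assignment easier than for related taxa), and
profile-search score distributions (hits are planted relative to
thresholds, so screening tests validate the thresholding logic, not
remote-homology detection). Passing recovery tests therefore demonstrates
correctness of the pipeline's logic and estimators under the stated
statistical structure, not field performance on real viromes.

## Calibration results and a known estimator bias

`scripts/acceptance.py --seed N --out f.json` reruns, from scratch:
exact site-count verification over all 61 sense codons against brute-force
enumeration; the 4/23 worked example; pN/pS recovery at ω ∈ {0.1, 0.5,
1.0} over 200 genes of 300 codons at 50× (the desk-scale stand-in for a
survey-scale selection analysis); screening sensitivity/specificity on a
planted 100-row table; spacer and k-mer host recovery on a 10-host /
50-contig survey; the k-mer null call rate over 5000 exchangeable decoy
trials; and temperate-fraction recovery over 500 contigs.

One bias deserves explicit mention. The dataset summary averages
*per-gene* ratios, as selection surveys commonly do. With ~2 synonymous
SNPs per gene (300 codons at snp_rate 0.01), E[1/s | s ≥ 1] exceeds
1/E[s], inflating the mean of ratios by a factor of roughly
λ·E[1/s | s ≥ 1] ≈ 1.1–1.2 at these counts. At ω = 0.1 the absolute
inflation is negligible (≈ 0.11 recovered), but near ω = 1 the recovered
mean sits around 1.1–1.2 depending on seed. This is a property of
mean-of-ratio aggregation at low SNP counts, not of the site counting or
classification (the count-level ratio test at high SNP density recovers
N/S within a few percent). Deeper coverage of SNPs per gene, pooled
(sum-then-divide) estimators, or median aggregation would remove it; the
per-gene mean is kept because it matches standard practice.

## Numerical and degenerate-input choices

Exact rationals for site counts and per-gene ratios; float conversion
only at output. Unseen k-mer contexts are uniform; decoy Gaussian fits
require ≥ 5 finite decoy scores and a positive standard deviation, else
no call. All-N contigs, contigs shorter than the model order, and empty
SNP tables produce explicit no-calls or flagged exclusions, never
exceptions. Fisher odds ratios use the Haldane 0.5 correction only when
a cell is zero; BH correction runs across all (RP, ecosystem) tests of a
report. Ties in spacer-vote host assignment break lexicographically for
determinism. Every stage logs in/out counts and active thresholds at
INFO level, making reported counts auditable.
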