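# Methods

`rrbspipe` models a reduced-representation bisulfite sequencing (RRBS)
case/control study — trisomy-21 (Down syndrome) versus euploid placenta
is the motivating design — end to end on synthetic data with known
ground truth: genome and methylome simulation, in-silico restriction
digestion, paired bisulfite read generation, three-letter alignment,
methylation calling, differential methylation, and RPKM-based
expression integration. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic experiments
do and do not demonstrate.

## The simulator

### Genome and annotations

Chromosomes are i.i.d. base draws at a configurable GC content
(default 0.40), with CpG islands (CGIs) planted as CG-rich intervals
(per-base C/G probability 0.35 inside islands, giving roughly a
three-fold CG-dinucleotide enrichment over background). One chromosome
(default `chr21`, 500 kb of the 2.0 Mb default genome) is designated
the trisomic surrogate. Gene models are placed uniformly (2–8 kb
spans, random strand) with log-normal exonic lengths around
`exonic_length_bp` (default 1500 bp); by default gene counts per
chromosome are proportional to length, with an explicit
`genes_per_chrom` override for designs that need a fixed trisomic gene
count.

### Truth methylome

Methylation probabilities are assigned per CpG dinucleotide (shared by
the two strand-specific sites of the dinucleotide) from a three-part
mixture: a near-zero component Beta(1, c), a near-one component
Beta(c, 1) and a partially methylated component Beta(2, 2), with
weights (0.30, 0.10, 0.60) and concentration c = 30. This reproduces
the bimodal shape seen in RRBS methylomes — roughly 30% of sites at
0–5% and 10% at 95–100% methylation. CpGs inside promoters that
overlap a CGI are drawn almost entirely (weight 0.90) from the
near-zero component, reflecting the unmethylated state of
promoter-CGIs.

The case group's truth equals the control truth except at *spiked*
sites: a fraction `spike_fraction` (default 5%) of promoter CpGs gets
`p_case = clip(p_control + spike_delta, 0, 1)` with `spike_delta` =
0.20. Spiked sites whose baseline lies above 0.8 are clipped and
therefore carry a smaller true effect; they are retained in the truth
table (and counted against sensitivity) rather than silently replaced.

Heterozygous CpG-destroying SNPs are planted at rate `snp_rate`
(default 1% of CpG dinucleotides): the alternative haplotype replaces
the C with T or the G with A (equal probability), and each simulated
molecule draws its haplotype fairly. This gives the polymorphic-CpG
filter a real signal: a destroyed CpG produces non-CG/TG dinucleotides
in about half of the covering reads.

### Digestion and reads

Digestion by MspI (C^CGG) and TaqαI (T^CGA) is modelled as complete;
both motifs are their own reverse complements, so a forward-strand
scan finds every site. Cuts fall after the first base; fragments
between consecutive cuts are retained by a hard size window (defaults
150–197 and 207–230 bp). A hard window is a deliberate simplification
of gel size-selection: it keeps the retained set exactly recomputable,
which the structural invariants rely on.

Each retained fragment receives Poisson(2 × `target_depth`) read
pairs. A pair samples one parental strand uniformly; mate 1 reads the
molecule's 5′ end, mate 2 the reverse complement of its 3′ end (2 × 36
bp by default, so mates of retained fragments never overlap; fragments
shorter than the read length are skipped with a warning, and an
overlapping mate 2's bases would be dropped during calling in favour
of mate 1). Methylation states are per-molecule Bernoulli draws from
the *group* truth probability — there is no extra per-sample
biological variance layer, so per-sample levels vary only by binomial
sampling. That choice makes calling fidelity exactly binomial and is
what the fidelity checks assume; it also means the inter-individual
variability summaries quantify sampling noise, not biology (see
Limitations). Unmethylated cytosines convert to T with probability
`conversion_efficiency` (default 0.995); methylated cytosines never
convert. Sequencing errors are independent uniform substitutions at
`base_error_rate` (default 0.001); quality strings encode that error
rate (Q30 at the default, Q40 when the error rate is zero), so the
default reads sit exactly at the Phred-30 filter boundary and are
kept.

### Expression counts

Per-gene abundances are log-normal (σ = 0.8), drawn once from the
config seed and shared by both groups. Expected counts scale with
abundance and exonic length around `expression_mean_count` (default
500); case-group genes on the trisomic chromosome are multiplied by
`trisomy_expression_factor` (default 1.5, the three-copy dosage).
Counts are negative binomial with shape 20 plus log-normal
library-size variation (σ = 0.10) over 5 control and 4 case libraries.

## Read processing

Quality filtering masks bases below Phred 30 (error probability
10⁻³) and drops reads with more than 50% of bases masked; masked
bases are excluded from methylation evidence but do not alter
alignment.

Alignment is the three-letter strategy: two references (all C→T; all
G→A), reads converted in silico by their C/G count ratio (ties are
ambiguous and tried both ways), candidate loci from exact 16-mer seeds
at read offsets 0 and 16, full ungapped verification in converted
space with at most 2 mismatches, and a unique-best-hit rule across
both references and orientations — any tie leaves the read unmapped.
This is a deliberately small seed-and-extend engine: the scientific
content of the stage is the conversion and calling logic, and the
alignment contract (unique best ungapped hit, ≤ 2 mismatches) is
documented so a production aligner could be slotted in behind the same
interface. Exact seeding means a read with a mismatch in both seed
windows is lost; at the simulated error rate this affects well under
1% of reads.

Calling reads original bases back over the reference: C2T alignments
feed forward-strand CpG cytosines (C methylated, T unmethylated,
anything else "other"); G2A alignments mirror this with G/A over
reverse-strand CpG cytosines. Strand-specific sites are never pooled.
The bisulfite conversion rate is estimated from non-CpG cytosines as
converted / (converted + unconverted). A site is excluded as
polymorphic for a sample when more than 20% (strict) of its covering
reads show a dinucleotide other than CG or TG.

## Differential methylation

Analyzable CpGs need depth ≥ 10 in at least 3 control and 6 case
samples; sex chromosomes are excluded (the female inactive X is
hypermethylated and would dominate any sex-unbalanced contrast). A
site (or region) is called hyper-/hypomethylated when the
case-minus-control difference of group means is at least 0.10
methylation fraction — an absolute 10-percentage-point difference,
not a relative change — and the two-sided Wilcoxon rank-sum p-value
is below 0.05. Group means use whichever samples meet the depth rule
at that site, so per-site group sizes are unbalanced. No
multiple-testing correction enters the call, mirroring the modelled
design; a BH column is emitted alongside for users.

The rank-sum test uses the exact tie-free null distribution (computed
by a subset-sum recursion and cached per group-size pair) when the
combined sample size is ≤ 20 and the data have no ties, and mid-ranks
with the tie-corrected, continuity-corrected normal approximation
otherwise. Near-zero methylation sites frequently tie at level 0
across samples, so in practice tied sites take the normal path; fully
separated 6-vs-11 groups remain far below α either way. All-tied data
return p = 1.

Region-level analysis aggregates per-sample unweighted means over CpGs
with depth ≥ 10 (read-weighted means would couple the region level to
coverage; the unweighted mean matches the "average region methylation"
reading and is switchable), requires ≥ 6 covered CpGs per region per
sample (3 for coverage reporting), and then applies the identical
differential rule to the per-sample region means. Promoters are
−1000/+500 bp around the TSS in transcription direction, TTRs
−500/+500 bp around the termination site, shores the 2-kb CGI flanks
minus the islands. On the minus strand these windows are the
forward-coordinate reflections (e.g. TSS 5000 → [4500, 6001)).
Overlapping positional classes resolve by precedence promoter > TTR >
intragenic > intergenic, which makes the classes a partition of
annotated sites.

## Expression analysis

RPKM = 10⁹ · count / (total mapped reads · exonic length). Group
averages below 0.5 are floored at 0.5; only genes with an (unfloored)
group average ≥ 0.5 in at least one group are included. Differential
expression uses a pooled-count exact binomial test — pooled case
count against pooled total with p₀ = the case share of summed library
sizes — with BH < 0.01 and a floored-average ratio ≥ 1.25 or ≤ 0.8.
The binomial construction is exactly calibrated when counts are
Poisson given library sizes and is anti-conservative under biological
overdispersion; the null-calibration test therefore simulates under
the binomial model's own null, and analyses of the default
(overdispersed) generator should read the DE list as a
library-dosage contrast, not an FDR-controlled gene list.

The average dosage change for a gene set is reported as
100 · (mean of per-gene floored-ratio − 1) (mean of ratios); the
ratio-of-means alternative is available behind a flag. Because RPKM
normalises per million mapped reads, boosting the trisomic genes
inflates the case library and deflates every ratio by
1/(1 + 0.5 · s), where s is the trisomic share of the library — with
~220 trisomic genes among ~3000 (s ≈ 0.07) the planted 1.5× recovers
as ≈ 45–50%. Set-versus-background shift tests are two-sided rank-sum
on log2 ratios; the promoter-hypermethylation integration joins
region-level hyper calls to genes by id and reports the Spearman
correlation between baseline (control) promoter methylation and log2
expression ratio.

## Enrichment statistics

Cross-study overlap uses an upper-tail binomial: k shared genes among
n tested, with the null success probability the product of the two
studies' differential rates. Gene-set enrichment uses a permutation
test (default 1000 permutations over a 15,203-gene universe) with the
add-one p-value estimator (1 + #{overlap ≥ observed}) / (1 + B), so p
is never exactly zero and the smallest attainable value is ~1/B.

## Problem sizes and defaults used in the shipped experiments

The default study configuration is a 2.0 Mb three-chromosome genome,
150 CGIs, 6 control + 11 case methylomes at target depth 30 (≈ 1500
retained fragments, ≈ 90k read pairs per sample, ≈ 10k analyzable
strand-specific CpGs), chosen as the smallest design at which the
6-vs-11 exact rank-sum has full resolution and the spiked-site count
is in the hundreds. The expression experiment uses ~3000 genes with
220 on the trisomic surrogate so the trisomic library share stays
small (see above). `scripts/acceptance.py` re-runs exactly these
configurations from a command-line seed.

## Known limitations

* No per-sample biological variance in the methylome: sample-to-sample
  spread is binomial only, so passing power/calibration checks bound
  the pipeline's behaviour under sampling noise, not under real
  inter-individual heterogeneity.
* The aligner is ungapped with exact seeds; indels, adapters, PCR
  duplicates and quality drift along reads are all out of scope of the
  read model.
* Digestion is complete and size selection sharp; real RRBS libraries
  have partial digestion and soft gel cuts, so real coverage is
  noisier than simulated coverage.
* Bisulfite chemistry cannot distinguish 5-methylcytosine from
  5-hydroxymethylcytosine; "methylation" here means their sum.
* BH-adjusted p-values are not idempotent under re-adjustment (a
  property of the step-up itself); downstream code should treat them
  as adjusted significance levels, not as p-values to re-correct.
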