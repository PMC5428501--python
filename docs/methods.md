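# Methods

## Setting and data model

pedscan targets re-sequenced breeding pedigrees of fully inbred lines. Each
variety is treated as a single haploid genome: diploid homozygous VCF
genotypes collapse to allele codes REF=0 / ALT=1 at load time, and residual
heterozygous calls — noise in fixed lines — default to missing (`het_policy`
also allows `ref`, `alt`, or `fail`). Only biallelic SNPs are kept;
multiallelic and INDEL records are dropped with a logged count rather than
split, because every downstream statistic is defined on biallelic sites.
Internal coordinates are 1-based inclusive (VCF/GFF native); conversion to
0-based half-open BED happens only in the writer. A site with no non-missing
call carries no information and is dropped at load.

The pedigree table distinguishes *immediate* varieties (the direct line of
descent, one per generation, each naming its predecessor as a parent) from
*collateral* varieties (side branches that act as donors). Low-diversity,
zero-diversity and signature scans run on immediate chains; collaterals
contribute to pedigree-level SNP sets and LD.

## Nucleotide diversity and low-diversity regions

Window π uses the unbiased per-site estimator 2c(n−c)/(n(n−1)) summed over
sites and divided by the **full window length** — monomorphic positions count
in the denominator, which is what puts genome-wide values on the familiar
10⁻³ scale. Missing data adjust n per site; sites with fewer than two calls
contribute zero. The grid is 100-kb windows / 10-kb steps by default;
terminal windows are kept, flagged as truncated, and use their actual length.

Low-diversity regions are windows with π at or below the empirical quantile
(default 1 %, linear interpolation, ties included) merged when they overlap
or abut. An absolute threshold can be supplied instead, since published scans
often report the realized cutoff rather than the quantile rule. Zero-
diversity genes have no segregating site in the transcript span nor in the
1-kb strand-aware flank upstream of the TSS; a gene qualifies only if all its
transcripts do.

## Breeding signatures

Along a generation-ordered immediate chain (length ≥ 3), a site is a
breeding signature iff its genotype string has exactly one state change and
both blocks are non-empty — the incoming allele appears once and persists to
the terminal variety. Monomorphic chains are rejected by default (no
selection event is evidenced); `allow_monomorphic` admits them for
sensitivity analysis. Either allele may be the incoming one, and no minimum
block length is imposed. Missing calls disqualify a site under the default
`exclude` policy; the `impute-bridge` policy treats missing calls as
wildcards and classifies the observed subsequence, dating the transition at
the first observed derived call. Gene-level summaries count signature SNPs
within CDS by default (interval semantics: a SNP in overlapping CDS of two
genes counts in both), and the intergenic fraction is measured against gene
spans plus 1-kb upstream flanks.

## Divergence scans

Window Fst is the Hudson ratio-of-sums: per site, between-group
heterozygosity Hb = p_a(1−p_b) + p_b(1−p_a) and within-group
Hw = [2p_a(1−p_a)n_a/(n_a−1) + 2p_b(1−p_b)n_b/(n_b−1)]/2, with
Fst = Σ(Hb−Hw)/ΣHb over the window. The ratio-of-sums form is robust to
uneven sample sizes and is standard for window scans; sites need ≥ 2
non-missing calls per group, and windows with ΣHb = 0 are dropped and logged.
ZFst standardizes window Fst genome-wide with the sample standard deviation.

The π ratio compares group diversity on the same grid as log2(π_a/π_b),
conventionally conventional-group over restorer-group. Windows where either
π is zero are dropped by default (a planted zero-diversity window would
otherwise contribute an infinite ratio and dominate the quantiles); an `inf`
policy retains one-sided zeros. Sweep candidates are windows strictly above
the (1−tail) empirical quantiles of **both** log2 ratio and ZFst (default
tail 5 %), merged into regions. The thresholds are empirical tail values of
the realized window set, not parametric quantiles.

A consequence worth noting: a window where both groups are completely fixed
for opposite alleles has Fst = 1 but undefined π ratio, so complete fixed
differences are visible to the Fst tail yet invisible to the ratio — the
joint rule therefore lights up where the restorer group has lost diversity
while the conventional group retains it, which is the biological signature
of a sweep confined to one breeding group.

## SNP effects

Effects are classified from transcript geometry and the standard genetic
code (translation via Biopython): coding changes become synonymous /
missense / stop_gained / stop_lost, any change in an ATG initiator codon is
start_lost, and splice sites are the canonical first/last 2 bp of each intron
(the annotation tools this mirrors do not publish their exact window; 2 bp is
the canonical GT–AG core). Non-coding positions map to 5′/3′ UTR, intron,
non-coding exon, a 1-kb strand-aware upstream class, or intergenic; the
partition is exhaustive and disjoint. When a SNP hits several transcripts the
most severe category wins (splice/start/stop classes > missense > synonymous
> UTR > non-coding exon > intron > upstream). Transcripts whose concatenated
CDS length is not divisible by 3 are flagged, excluded from effect calls, but
retained for zero-diversity scans. Large-effect SNPs are the five disabling
classes; dn/ds is a raw count ratio (missense + stop_gained + stop_lost +
start_lost over synonymous) — not a per-site rate — and start_lost sits in
the numerator because it is a nonsynonymous change.

## Linkage disequilibrium

r² between two sites is D²/(p_i(1−p_i)p_j(1−p_j)) with D = P(ALT,ALT) −
p_i p_j over samples non-missing at both sites (pairwise deletion, consistent
with the per-site estimators elsewhere). Because calls are haploid,
haplotype frequencies are direct counts; a Hardy–Weinberg filter is
meaningless for inbred-line data and is deliberately not applied. Defaults
mirror common practice for such scans: 500-kb maximum distance, MAF ≥ 0.005.
The decay curve is the binned mean (1-kb bins), and the half-decay distance
is the midpoint of the first bin whose mean falls to half the maximum binned
mean — curves start at their maximum, and the reference publications do not
define the quantity more precisely; a not-reached signal reports the final
r² instead.

## The simulator

`pedsim` emulates pedigree breeding, not long-term population genetics.
Founders carry standing variation only: sites placed uniformly, allele
frequencies ~ U(0.1, 0.9) (mean per-site diversity 0.3933), and site density
chosen so the expected per-bp π equals `founder_pi`. Each cross performs one
meiosis — crossovers ~ Poisson(`recomb_rate`) per chromosome, uniform
breakpoints, no interference — and the recombinant is fixed immediately,
matching fully inbred varieties and keeping truth exact. No mutation occurs
after founding. Defaults reflect the study conditions the package is tested
under: founder π 0.002 (the conventional-pedigree range), 2 crossovers per
5-Mb chromosome per meiosis, three pedigrees of 11/18/23 varieties (52
total, ~50k SNPs over 2 × 5 Mb) in `standard_config`.

Planted truth:

* **Low-diversity regions** thin founder site density by `diversity_scale`
  (0 ⇒ no segregating sites inside).
* **Introgressions** force a single-transition pattern along a chain: the
  root allele up to `transition_generation`, the opposite allele thereafter.
  The site must segregate among the founders (the donor pool), else an error.
  With `signature_noiseless` (default), accidental two-block patterns at
  non-planted sites are scrubbed by flipping the terminal variety's call —
  a flip at a two-block site always yields either a second transition or a
  monomorphic chain, never a new signature — so the planted set is exactly
  the signature truth and precision/recall can be asserted at 1.0.
* **Sweep regions** fix the restorer-side group, per site with probability
  `divergence_boost`, for the allele opposite the other group's majority
  (maximizing between-group heterozygosity), leaving the conventional group
  untouched — diversity loss in one group, the detectable π-ratio signal. An
  optional central `both_fixed_frac` core also fixes the conventional group,
  creating complete fixed differences whose fully interior windows have
  Fst = 1.0 exactly. A symmetric fixed-difference planting alone would be
  invisible to the π ratio (both groups lose diversity equally), which is
  why the asymmetric construction is the primary mechanism.

Determinism: all randomness flows from one `numpy` Generator seeded by the
config; identical seeds give byte-identical outputs, including emitted files.

What the simulator does **not** model — and hence what passing tests do not
establish about real data: genotyping error and missingness structure,
coalescent founder relatedness, mutation, crossover interference, selfing
generations with residual heterozygosity, segregation distortion, and gene
conversion. Recovery results on simulated data demonstrate correctness of
the detectors under their stated models, not field performance.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 2 × 5 Mb genomes,
~50k SNPs, 52 samples for the end-to-end run; 1 × 1 Mb (~5k SNPs) for
signature recovery. These sizes keep every stage comfortably fast while
leaving hundreds of windows per scan, enough for 1 %/5 % empirical quantiles
to be meaningful. Quantiles use numpy's default linear interpolation.
Low-diversity calling includes ties (≤ threshold); sweep calling is strict
(> threshold), so `tail=0` selects nothing. Zero-variance Fst, chains
shorter than 3, overlapping groups, and `min_maf ≥ 0.5` are rejected with
errors rather than guessed at. Low-diversity recovery is asserted on the
founder panel, where planted density reduction is the only π signal; bred
chains additionally contain long identity-by-descent blocks — real, but not
planted — that would dominate the left tail.
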