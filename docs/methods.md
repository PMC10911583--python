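# Methods

This note documents the models, procedures, parameter choices and known
limitations of `tyhybrid`, stage by stage.

## Subgenome read phasing

A hybrid read library is sorted into parental subgenomes using informative
variants — sites where the two parents differ. Each read accumulates
support counts (n1, n2) from the alleles it covers; it is called for a
parent iff n1 + n2 ≥ 2 and the winning side has at least twice the
support of the other. Ties and sub-threshold reads stay unclassified and
are never arbitrated by read length. The ≥ 2 threshold is interpreted as
*total* informative observations per read; an alternative reading (≥ 2 on
the winning side) is available via `min_support_mode="winner"`. Alleles
that match neither parent (sequencing miscalls) count toward neither.
Library summaries are base-weighted: percent of sequenced bases per call
and the classified P1:P2 base ratio, which tracks ploidy (a triploid line
with a duplicated subgenome phases near 2:1).

## Copy-number tracts and genome-size change

Depth of subgenome-sorted reads on the haploid parental reference is
summarized in non-overlapping windows. For tract calling, 30-kb window
medians are divided by the genome-wide median and quantized to the
nearest multiple of 0.5 (ties round half up); runs of equal level merge
into tracts. The 0.5 grid resolves the half-integer ratios that arise in
triploids. A locus takes the copy number of the tract containing its
midpoint, scaled by the subgenome's baseline copy count from ploidy
metadata — median normalization cancels whole-genome ploidy, so ploidy
must come from external metadata (in the emulated study design, flow
cytometry), not from depth. Trailing partial windows are retained with
their true length. Genome-size change uses 10-kb bins: normalized bin
values strictly below the 1st or above the 99th percentile are excluded
(percentiles taken *after* normalization), and Δ = Σ(r − 1) × bin length
over retained bins, in Mb. With strict inequalities, a noise-free uniform
genome excludes nothing and a genuine segmental gain is not clipped away.

## Orthologous Ty clusters

Evolved-line annotations are projected to parental coordinates through
per-chromosome alignment blocks. Interval ends are projected
independently through their containing blocks, so a span that encloses a
line-side deletion (a truncated element) projects onto the full parental
span. A span lying wholly inside a line-only insertion — exactly what a
de novo element is — snaps to the junction point between the flanking
blocks and is flagged (`projection="junction"`); annotations with no
flanking block at all are reported unmapped, never dropped.

Projected annotations cluster within (chromosome, family, strand)
partitions by single-linkage chaining with an interval-gap threshold of
500 bp (connected components of the ≤ 500 bp gap graph; equivalently,
density clustering with a minimum cluster size of one, so there are no
noise points). Interval gap was chosen over midpoint distance because a
330-bp solo LTR projected inside the span of a 5.9-kb full-length copy
has a midpoint ~2.8 kb away — midpoints can never co-cluster an excision
locus with its parental element, and excision calls require exactly that
co-clustering. Clusters with more than one member from a single genome
are flagged complex. Solo LTRs and full-length copies of one family may
share a cluster by design; completeness never partitions.

## SV classification

Each cluster in each line subgenome is reduced to a locus state: parent
and line annotation-type multisets, quantized locus copy number (cn_ma)
versus the parental baseline (cn_parent), and assembly presence — both
500-bp windows flanking the parental span must project into the evolved
assembly, with a window counting as mapped when ≥ 90% of it is covered
(TSD-sized gaps at a deleted element must not mask an intact flank; a
single mapping flank is conservatively absent). Loci with contradictory
evidence (CN 0 but present, or CN > 0 but absent) are excluded before
classification.

The rule hierarchy runs in fixed order:

1. same content and same CN → **no change**;
2. CN differs, and either content is identical or the locus region is
   entirely missing (no annotation and no assembly) → **CN change**,
   sub-classified below;
3. parental full-length vs line truncated → **truncation**;
4. parental full-length vs line solo LTR → **excision**;
5. one additional full-length copy in the line → **de novo candidate**;
6. parental annotation, no line annotation, assembly present →
   **deletion**;
7. otherwise **unclassified**.

CN changes resolve to **polyploidy** when ploidy metadata shows a
genome-wide gain; else **aneuploidy** when the containing tract spans
≥ 95% of its chromosome; else **LOH** when the homologous subgenome shows
an opposite-sign tract overlapping ≥ 50% of the tract (copy-neutral
inter-homolog conversion leaves exactly this reciprocal signature); else
segmental aneuploidy by default. The 95% and 50% thresholds separate
whole-chromosome from segmental events without breakpoint calling.

`cn_delta` counts full-length copies, cn_ma × n_full(line) − cn_parent ×
n_full(parent), making the per-line identity Σgains − Σlosses = net
change exact. Per-cross inference uses a two-sided Wilcoxon signed-rank
test of per-line net change against zero with Benjamini–Hochberg
correction across crosses (all-zero crosses are reported not applicable),
and a Spearman rank correlation of net CN change against subgenome size
change (a deliberately assumption-light replacement for mixed linear
models, which are out of scope here).

## De novo curation

A genuine Ty1 integration leaves an exact 5–6 nt target-site duplication.
`find_tsd` compares the last k bases of the 5′ flank with the first k of
the 3′ flank for k = 6 then 5, longest match first; no mismatches are
tolerated (MA spans ~770 generations — far too short for TSD decay) and
non-ACGT junction bases reject the candidate rather than erroring.
Uniqueness filters then require (a) the junction context — 20 bp of flank
on each side with the TSD doubled, i.e. the element-free reconstruction
of the evolved locus — to occur nowhere in any parental genome (a hit
marks a pre-existing polymorphic insertion, not a new event), (b) the TSD
motif to be absent from the TSD set of all parental full-length copies,
and (c) optionally, the junction not to recur in another line. Every
rejection records exactly one reason. Statistics: per-line mean =
confirmed / lines (2 decimals); per-cross rate = confirmed / (lines ×
generations × mean parental full-length count of the mobilizable family),
per line per generation per element. The element-count denominator uses
the mean across the two parental subgenomes; it is configurable because
"per element" admits more than one reading.

## Fluctuation analysis

The Lea–Coulson distribution is the compound-Poisson law of mutant counts
under exponential growth: Poisson(m) mutation events, each founding a
clone whose final size follows q_k = 1/(k(k+1)). Probabilities come from
the Ma–Sandri–Sarkar (Panjer) recursion p_n = (m/n) Σ p_i/(n−i+1) with
p_0 = e^{−m}. Counts at or above a cap (default 512) enter the likelihood
as the folded right tail — exact right-censoring, which leaves the MLE
and interval calibration untouched while keeping the O(n²) recursion
short in jackpot experiments. The MLE is located by a coarse logarithmic
grid scan (robust to the −inf plateaus where every observed count has
underflowed probability) followed by bounded scalar refinement to 10⁻⁸
relative tolerance; all-zero counts return m̂ = 0 at the boundary. The
95% CI is the profile-likelihood set {m : ℓ(m) ≥ ℓ(m̂) − 1.9207}, with
endpoints by root bracketing and Brent's method; a lower endpoint below 0
clips to 0. All-zero experiments are inflated by a single mutant and the
estimate flagged as an upper bound. Rates are μ = m̂ / N_t with N_t the
mean of dilution-plating records (colonies × dilution / plated fraction,
per culture after dividing out the pool size); no plating-efficiency,
partial-plating or post-plating-growth corrections are applied because
entire culture resuspensions are plated in the emulated protocol.
Verified calibration: simulated counts pass a χ² goodness-of-fit against
the pmf, CI coverage sits in [0.93, 0.97] for m ∈ {0.5, 2, 8} at 48
cultures, and median m̂/m bias is within a percent at m ∈ {1, 4}.

Group comparisons report pairwise rate ratios with significance called by
non-overlap of 95% CIs — a conservative, assumption-free criterion;
ratios involving upper-bound estimates are flagged as bounds.

## Synthetic data: what it emulates, and what it does not

The generator builds two parents as random DNA with planted Ty elements
(two exact-duplicate LTRs flanking a random internal region; solo LTRs;
family identity is metadata, not sequence homology) at shared coordinates,
each flanked by an exact 5–6 nt TSD sampled from the insertion site.
Parental divergence is uniform substitution outside element/TSD spans
(tunable from ~0.05% to ~10%), mirroring the repeat-masked variant sets a
real analysis would use; coordinates stay directly comparable because
substitutions are length-neutral. SV planting edits sequences, annotations
and line→parent alignment blocks jointly: excision keeps the first LTR
and deletes the rest; truncation removes a central fraction (default 50%)
of the internal region; deletion removes the element plus one TSD copy,
restoring the empty site; de novo copies a parental donor into a fresh
site with a new TSD (sites are resampled so planted TSD motifs never
collide with parental ones, keeping planted insertions curatable; nested
insertion into a host LTR is supported via a flag); LOH removes the tract
from the losing subgenome's phased representation — its reads would sort
to the homolog — and doubles the homolog's copy number over the tract.
LOH tract sizes default to a few hundred kb, configurable, as no
empirical distribution constrains them.

Reads carry variant observations rather than bases (phasing consumes only
variant support); lengths are lognormal (σ = 0.6) around the mean, and
each observed allele flips to the wrong parent with a configurable error
probability. Depth tracks are mean depth × haplotype copies at the window
midpoint plus Gaussian noise, floored at zero. Fluctuation cultures grow
by discrete doublings with per-generation binomial mutation in non-mutant
cells; each mutant clone expands from a random time within its birth
generation drawn with the exponential-growth density, which reproduces
the 1/(k(k+1)) clone-size law exactly in distribution (synchronous clone
doubling would concentrate counts on sums of powers of two and is not
Luria–Delbrück).

Not emulated: base-level nanopore error profiles, sequence evolution
beyond uniform SNPs, assembly fragmentation, mappability and GC bias,
within-tract read sampling for LOH regions (reads are weighted per
chromosome), and the MA propagation regime itself. Passing tests
therefore demonstrate the correctness of the decision logic and
estimators under clean and moderately noisy conditions, not robustness to
every artifact of real long-read data.

## Study conditions and problem sizes

The default synthetic cross is 2 × 12 Mb parents (8 chromosomes of
1.5 Mb), 1% divergence, 40 Ty1 loci (30 full-length, 10 solo), and 12
evolved lines covering all seven SV classes, with 400 reads per line at
30× mean depth; fluctuation experiments default to 48 cultures of ~500
starting cells, matching the emulated assay design. The acceptance script
measures rate recovery at the three reference transposition rates
(1.73 × 10⁻⁶, 9.77 × 10⁻⁸, 5.34 × 10⁻⁷ per cell per generation) over
25 replicate 48-culture experiments each, CI coverage over 500 replicates,
and runs the full cross twice (noise-free, and with 5% variant error plus
0.1× depth noise).

## Known limitations

- The classification hierarchy assumes one SV class per locus per line;
  genuinely compound loci (e.g. a truncation inside an LOH tract) are
  excluded by the planner and would classify by whichever rule fires
  first.
- LOH detection needs the reciprocal signature in the homolog; LOH in a
  region where both haplotypes already carry equal CN, or homozygous-to-
  homozygous conversion, is invisible to depth and would default to
  segmental aneuploidy.
- Junction uniqueness uses exact substring search of the doubled-TSD
  context rather than whole-chromosome alignment; diverged-but-homologous
  junctions are not detected as non-unique.
- The per-element rate denominator and the ≥ 2-variant phasing threshold
  each admit alternative readings; both are implemented behind documented
  switches with the defaults stated above.
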