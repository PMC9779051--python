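# Methods notes

This note records the models behind `medipchip`, the defaults that matter,
the places where the design was genuinely open and what was decided, and
what the synthetic-data validation does and does not demonstrate.

## Promoter model

A promoter is the stranded −700/+200 bp window around a TSS (0-based
half-open coordinates; the TSS is the position of the first transcribed
base; minus-strand windows are mirrored and reverse-complemented so
classification always reads the gene strand). CpG-density classes follow
the windowed scheme used for mammalian promoter arrays:

* HCP — some 500-bp window with GC ≥ 0.55 **and** CpG O/E ≥ 0.6;
* LCP — no 500-bp window with CpG O/E ≥ 0.4;
* ICP — the remainder.

Open choices and their resolutions:

* **O/E formula.** (#CpG × N)/(#C × #G), with N the number of unambiguous
  bases; defined as 0 when C or G is absent.
* **Window step.** 1 bp (exhaustive scan). The implementation uses
  cumulative sums; the test suite checks exact agreement with a plain
  string-slicing enumeration on 1000 random sequences.
* **The LCP wording.** "no 500-bp interval with O/E ≥ 0.4" is read as a
  universal condition over windows, which makes {HCP, ICP, LCP} a
  partition (verified by property test).
* **Ambiguity codes.** Excluded from numerator and denominator alike;
  windows more than half ambiguous are skipped; promoters clipped at
  contig edges are flagged and evaluated on their available sequence.

## MeDIP-chip differential enrichment

Input is a probe table of per-array log2(MeDIP/Input) values. Three
normalization steps, in order: per-array median centering; quantile
normalization (ties get the mean pooled quantile); 3-probe centered moving
average along each chromosome ("linear smoothing" — the lightest
parameter-free reading of that term).

**Quantile normalization is applied within each condition's replicate
arrays, not across conditions.** Forcing all arrays of both conditions onto
one distribution also equalizes genuine group-level enrichment differences
— exactly the signal the differential statistic M′ measures. On planted
data, cross-condition quantile normalization attenuated a 1.0 log2 planted
difference to ≈ 0.3; within-condition normalization leaves it intact while
still removing array-to-array scale effects, which is what replicate-level
normalization is for.

**Peak calling.** Every probe is scored with the 1500-bp window centered on
it: a one-sided two-sample KS test of in-window values against all
out-of-window values on the track (the statistic D⁺ = sup[F_out − F_in];
the p-value uses Hodges' asymptotic approximation, the same formula scipy's
one-sided test applies, verified probe-for-probe against
`scipy.stats.ks_2samp` in the tests). A Wilcoxon rank-sum variant is
available via `window_test="wilcoxon"`. Peaks are maximal runs of ≥ 2
consecutive probes with −log10 p ≥ 2. Because a centered window still
overlaps the enriched region from up to 750 bp away, a raw run extends
beyond the signal on both sides; each run is therefore refined to
half-maximum boundaries (edge probes below half the summit value are
dropped), the standard width convention in peak calling. Without this
refinement every peak statistic — the peak median M′ and the in-peak group
medians — is diluted by flanking background probes and the filters below
stop separating signal from noise. Peaks within 500 bp merge (score = max).

**Differential peaks and filters.** M′ is the difference of group-mean
log-ratios per probe. The peak finder runs on the M′ track and its
negation, giving hyper- and hypomethylation DEPs. A DEP is retained iff

1. at least one group's in-peak values have median ≥ 0.3 and the in-peak
   median M′ agrees in sign with the peak's direction (the in-peak
   probe-level M′ values stand in for the otherwise-undefined secondary
   M statistic this filter is usually quoted with); and
2. at least half the probes have coefficient of variation ≤ 0.8 across
   arrays in both groups. CV is computed on linear-scale ratios 2^value —
   on the log scale the mean can cross zero and CV is ill-defined. With a
   single array per group CV is taken as 0 (no replicate variability is
   measurable).

A gene is a DMG when a retained DEP overlaps its promoter by ≥ 1 bp with
peak p < 0.01 and |peak DM value| > 0.4; if several DEPs hit one promoter
the largest |DM| wins. The peak p-value reported for the gate is the merged
peak's best window p.

## Rank-product differential expression

With nA and nB arrays, all nA×nB pairwise log2 fold-change vectors B−A are
formed; the design generalizes the 1-vs-1 array-per-group case (one vector)
that motivated the method. Ranks use average tie-breaking so the statistic
is defined under duplicated values; the rank product is the geometric mean
across vectors, invariant under any per-vector monotone transform.

pfp (percentage of false predictions) comes from permutations that shuffle
each vector's gene labels independently:
pfp(g) = E(g) / rank(g), with E(g) the mean per-permutation count of null
rank products ≤ RP_g. Tiny instances can be enumerated exhaustively
(`exhaustive=True`), which the suite checks against a direct
brute-force oracle. pfp is not monotonized; DEG decisions use pfp ≤ 0.05
directly, plus a linear fold-change gate at 1.5 (up) or 1/1.5 (down), the
latter reading "decreased fold change < 1.5" as the reciprocal bound. A
Benjamini–Hochberg mode over the permutation p-values exists but is off by
default. Monte-Carlo mode requires an explicit seed; the default is
n_perm = 1000 (the fixture studies use 200, ample for effects this large).

## Integration

The synergy join keeps only discordant pairs — transcription down with
promoter hypermethylation, or up with hypomethylation — because promoter
methylation is expected to act repressively; concordant pairs are counted
out by construction. Persistence intersects two DEG tables on gene_id with
equal direction; it is symmetric and idempotent. Gene matching is
exact-string; no alias resolution. Enrichment uses the array's gene
universe (not the genome), one-sided hypergeometric tails, BH correction
across the collection, and the conventional log2(q) < −2 gate.

## Synthetic data: what it emulates, and what it does not

The generator builds a one-contig genome with one promoter per 3000-bp
slot, alternating strands. Promoter sequences come from three first-order
Markov archetypes: CpG-rich (GC 0.60, CpG-enriched ×1.6 → HCP),
intermediate (GC 0.45, unbiased → ICP), CpG-poor (GC 0.35, CpG-depleted
×0.10 → LCP); background is GC 0.40 with mild CpG depletion. The 3000-bp
slot keeps adjacent promoters ≥ 1600 bp apart, past the reach of one scan
window. Probes tile the genome every 100 bp (50-mers), i.i.d. Gaussian
noise (default SD 0.2 log2 units) per probe and array.

Planted differentially methylated promoters carry a **baseline enrichment
of 1.0 log2 in both groups** plus ±1.0 (the effect) in the treatment group
only. The baseline exists because a DMR is a region that is methylated
somewhere: a hypomethylation event is a loss from an enriched baseline, not
"negative methylation", and without it no hypomethylated region could ever
satisfy the ≥ 0.3 median-enrichment filter — the filter's whole point is to
demand genuine enrichment in one group. 1.0 log2 (2-fold over input) is a
typical level for a robustly methylated region on MeDIP arrays.

Expression is generated at gene level (probe-set summarization is upstream
and out of scope): baselines Uniform(4, 12) log2 units shared across the
four feeding groups (CN, LP, CN-R, LP-R), noise SD 0.1, planted shifts of
±1.0 log2 in LP, and in LP-R as well when the effect is persistent. The
MeDIP noise default (0.2) and expression noise default (0.1) differ because
probe-level tiling signals are substantially noisier than summarized
gene-level expression. All generators draw from deterministic per-stream
substreams of one seed; fixed seed ⇒ byte-identical output.

Two fixtures reproduce published gene tables: the 17 genes whose
expression change persists through rebound feeding (6 up, 11 down) and the
27 genes with discordant expression/methylation status (13 down+hyper, 14
up+hypo, each with its published promoter class, which the fixture maps to
the matching archetype). The study runners spread planted genes evenly
among 200 null genes — differentially methylated genes scatter across a
genome; packing them into adjacent slots would merge neighbouring DMRs into
single peaks, a layout no real study presents.

What passing these tests does **not** show: robustness to spatially
correlated probe noise, dye or GC bias, probe-affinity effects, partial or
boundary-shifted methylation changes, non-promoter DMRs, or the n = 1
array-per-group design of small animal studies (the generator defaults to
n = 3 so group statistics are well-posed). The real-data totals of the
motivating study (e.g. ~1000 DEGs, ~1000 differential promoters) depend on
raw arrays and are outside what synthetic fixtures can or should reproduce.

## Numerical and engineering choices

* Coordinates are 0-based half-open BED everywhere; BED→internal→BED is
  identity.
* KS p-values are computed from a vectorized D⁺ with searchsorted against
  the pooled sorted track — exact for tie-free continuous values — then
  Hodges' approximation; scores are capped only by floating-point range.
* The asymptotic KS p is anti-conservative for very small windows, so
  occasional noise runs clear the −log10 p ≥ 2 cutoff; the downstream
  median/CV/DM gates are what control the DMG false-positive rate (held
  below the nominal 0.01 in 40-replicate null simulations in the suite).
* Problem sizes in the fixture studies (≈ 227 genes, ≈ 7000 probes, 200
  permutations) were chosen so a full study runs in seconds while leaving
  every statistical margin wide; all thresholds are the published operating
  point and are recorded per run in `manifest.json`.
* Degenerate inputs fail loudly: empty sequences, empty groups, unknown
  gene ids, unsorted probes, duplicate gene ids in join tables, missing
  strands in BED records.

## Known limitations

* The window test's out-of-window reference pools all chromosomes; strong
  global enrichment shifts the reference (partially mitigated by
  normalization).
* `peak_dm_value` is the median of in-peak probe M′ — summaries like the
  summit value would be less conservative for broad, partially methylated
  regions.
* No support for bisulfite data, probe remapping, multi-factor expression
  designs, or live GO/KEGG services (enrichment takes user-supplied GMT
  collections).
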