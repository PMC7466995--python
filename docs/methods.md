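# Methods

This note records the models behind `covsize`, the parameter choices that
matter, what the simulator does and does not emulate, and the numerical
decisions a maintainer would want spelled out.

## The Lander–Waterman conversion

Both estimators reduce genome-size estimation to coverage estimation. If a
library of `N` reads with mean length `L = B/N` (total bases `B`) covers a
haploid genome of size `G` at mean depth `C`, then `G = L·N/C = B/C`. The
implementation is defined on `B` directly, so variable-length libraries
need no special case; `G·C = B_effective` holds to float precision, and
the reported integer size is rounded half-up. When mitochondrial reads
are excluded, `B_effective = B − mito_bases`: the mitochondrion is
sequenced at a depth unrelated to the nuclear genome, so its bases inflate
`B` without contributing to nuclear coverage. On simulations with a 2%
mitochondrial read fraction this correction removes a ≈2% overestimate.

## Read-depth estimator (gsec)

**Model.** The mean depth of a truly single-copy locus is an unbiased
estimate of genome-wide depth. Two artifacts break the naive mean:

* *Flank ramps.* A mapper that requires a minimum overlap between read
  and reference cannot place reads hanging off a locus end, so expected
  depth at offset `x` from a locus end rises linearly as
  `C·min(x+1, L)/L` (for a full-overlap contract). The estimator trims
  `t` bases from each end before averaging. The default `t = 75` suits
  ~100–150 bp reads, where the observable drop-off concentrates in the
  outer ~60–75 bases; it is a user parameter, not a constant.
  With `t = 75` and `L = 100` a residual ramp of 24 positions per flank
  survives, worth ≈0.4% downward bias in `C` on 1.5 kb loci — measured
  across seeded simulations, trimming removes well over 90% of the ≈7%
  size inflation the untrimmed profiles produce.
* *Non-single-copy loci.* A duplicated or contaminated reference gene
  collects reads from several genomic sources and can carry coverage an
  order of magnitude above the rest; a handful of such loci can halve the
  implied genome size. Loci are therefore kept only when their trimmed
  mean coverage *and* trimmed length lie within `m` interquartile ranges
  of the respective medians (`m = 3` by default, two-sided).

**Pipeline order and conventions.** Trim first, then filter on the
*trimmed* quantities — they are what the estimator consumes, and when all
loci are trimmable, filtering on raw lengths (which differ by the constant
`2t`) selects the same set. Quartiles use linear interpolation between
order statistics (numpy's default); no quartile convention is canonical
and the choice only matters within one IQR of the fences. A locus failing
both filters is reported once, as a coverage outlier (coverage > length
priority) — reporting detail only, the kept set is unaffected. With fewer
than 4 loci quartiles are meaningless: everything is kept and a warning
issued. Degenerate all-equal input has IQR 0 and zero deviations, so it
passes whole.

**Averaging.** "Average coverage across loci" admits two readings; both
are implemented. `locus_mean` (default) weights every locus equally —
robust when locus lengths vary. `pooled` divides total kept depth by
total kept bases. With `t = 0`, `m = ∞`, `pooled`, the estimator
degenerates to total depth / total bases, the natural regression baseline.

**Mitochondrial screen.** Shipping an aligner is out of scope, so the
screen is alignment-free: a read is flagged when it shares at least
`min_shared` canonical k-mers with the mitochondrial reference (default
35% of the read's windows, chosen as a rough proxy for a 70%-identity
mapping contract; the equivalence is approximate and the threshold is a
parameter). Error-free simulated mito reads share all their k-mers and a
random nuclear read effectively none, so the screen is sharp on clean
data; divergent numts and high error rates blur it.

## K-mer spectrum estimator

**Model.** For reads with negligible artifacts, the number of times a
given genomic k-mer is sequenced is approximately Poisson with mean
`λ_k = C·(L−k+1)/L` (a read of length `L` contributes `L−k+1` windows).
The spectrum `h_i` of a `G`-sized genome is then `≈ G·Poisson(i; λ_k)`
plus an error spike at low multiplicity (each sequencing error spawns up
to `k` novel k-mers, almost all singletons). Hence
`G = Σ_{i≥c0} i·h_i / λ_k`.

**Counting.** Canonical counting (lexicographic minimum of k-mer and
reverse complement) with odd `k` enforced — shotgun reads are unstranded,
and odd `k` excludes reverse-complement palindromes that would otherwise
be double-counted relative to all other k-mers. Windows containing
non-ACGT characters are skipped. Counts are exact: 2-bit packed codes in
uint64, vectorised with numpy, one `unique` pass per library. `k ≤ 31`
fits the encoding; the default `k = 21` balances specificity (4²¹ ≫ any
animal genome) against error attrition, and the sweep driver
(`--sweep 13:31:2`) exposes the k-dependence directly.

**Error cutoff.** `c0` is the first valley: the smallest `i ≥ 2` with
`h_i ≤ h_{i+1}` (absent multiplicities count as zero). A monotone
spectrum has no valley — coverage too low to separate signal from error —
and falls back to `c0 = 1` with a warning. The cutoff can be overridden.

**Peak and the quantisation problem.** The modal multiplicity
`λ = argmax_{i≥c0} h_i` (ties to the smaller bin) is reported as the
peak. Dividing by the integer mode, however, quantises the estimate: the
mode of a Poisson sits up to half a unit below its mean, and when `λ_k`
is integral the two top bins tie and the reported mode is effectively a
coin flip worth ±4% in `G` at 24×. The divisor is therefore the fitted
center `λ̂` of a truncated Poisson, maximum-likelihood fit to the bins
within `±2√λ` of the mode. The fit touches nothing outside that window,
so repeat-inflated tails do not drag it; degenerate windows with a single
occupied bin return `λ` exactly, preserving the closed-form identities
(`h = {20: 500} → G = 500`; a single read of length 100 at `k = 21` gives
`G = 80 = L−k+1`).

**Bimodal spectra.** A heterozygous diploid splits the spectrum:
haplotype-specific k-mers peak near `λ_k/2` (reads split between
haplotypes), shared k-mers near `λ_k`. The detector searches ±20% around
`2λ` and around `λ/2` for a local maximum that (a) rises above the valley
separating it from the primary peak by more than three standard deviations
of counting noise (`√(h_peak + h_valley)`) and (b) reaches at least 5% of
the primary's height. The significance form matters: at 1% per-base
heterozygosity and `k = 21` the heterozygous peak stands only ~10–15%
proud of the inter-peak valley, far below any fixed prominence ratio one
might guess, yet hundreds of standard deviations above noise. Which peak
is taller depends on the heterozygosity (the haplotype-specific fraction
is `1−(1−h)^k`); the estimator reports both and `--ploidy-peak
homozygous` selects the larger-coverage one, the correct divisor when the
half-depth peak dominates and the genome would otherwise be halved. No
mixture model is fitted; bimodality is reported, not decomposed.

**No maximum multiplicity** is imposed by default; high-copy k-mers stay
in the retained mass.

## Simulator

**What it emulates.** An idealised shotgun experiment with every
parameter known: i.i.d. background sequence at a target GC (default 0.40,
a typical insect value); repeat families as near-identical copies with
per-copy divergence; single-copy loci placed at least one read length
from any repeat copy and from the sequence ends (so locus coverage is not
confounded by genome-edge effects); an optional second haplotype with
Binomial(G, het_rate) substitutions; an optional mitochondrial sequence
contributing a fixed fraction of reads; uniform read starts, uniform
strands, i.i.d. substitution errors; and per-locus coverage projected
under a minimum-overlap contract — a read contributes to the bases it
overlaps within a locus iff its overlap is ≥ `f·L` (ties kept). With
`f = 1` the expected profile has linear ramps of width `L−1` and a flat
interior, which is precisely the artifact flank trimming corrects; with
`f = 0` the profile equals genome-wide depth restricted to the locus.

**What it does not emulate** — hence what passing recovery tests do not
show about real data: GC-dependent coverage bias, indels, paired-end
structure, PCR duplicates, quality-score structure (all written qualities
are constant), numts, contamination other than mitochondrial, and
assembly/mapping errors in the upstream locus set. Recovery on this
generator demonstrates that the estimators are unbiased under their own
model assumptions, not that those assumptions hold for any particular
library.

**Determinism.** One seed feeds a `SeedSequence` expanded into named
per-stage substreams (genome, repeats, loci, diploid, mito, reads,
errors), so identical configs are byte-identical and regenerating one
stage never perturbs another. Locus and repeat placement is rejection
sampling with an explicit infeasible-packing error after 10⁴ attempts.

**Reference conditions.** The default configuration — 1 Mb homozygous
repeat-free genome, 40 loci × 1.5 kb, 30× depth, 100 bp error-free reads,
`f = 1` — is the validation scenario used throughout the tests and the
acceptance script. At this scale one full run (simulation, read-depth
estimate, k-mer count at `k = 21`) takes ~15 s and a few hundred MB, and
both estimators recover the true size well within 3% (read depth
typically ±0.5%, spectrum ±0.1%). The scale is a deliberate design point:
large enough for the Poisson asymptotics to hold, small enough to run
everywhere.

## Degenerate inputs and numerical notes

* Coverage files: positions absent from a samtools-depth file are depth 0;
  the writers emit every position (including zeros) so round-trips are
  lossless in both dialects. Positions within a locus must be strictly
  increasing; violations are parse errors naming the line.
* An empty library, an all-too-short locus set, a spectrum with no mass
  above the cutoff, or non-positive coverage each raise an explicit
  estimation error rather than returning NaN.
* Reads shorter than `k` contribute zero windows (warning, not error);
  even `k` is rejected outright.
* The truncated-Poisson fit uses bounded scalar minimisation of the exact
  truncated log-likelihood; its result is deterministic and confined to
  the fit window.
* All percentile computations use float64; the IQR decision is a closed
  inequality (boundary values are kept).

## Known limitations

* The read-depth method inherits the single-copy assumption wholesale:
  systematic whole-genome duplication doubles every locus's coverage and
  halves the estimate undetectably (the IQR filter only catches a *few*
  discordant loci). The k-mer method inherits the complementary failure:
  collapsed repeats and heterozygosity-halving (mitigated, not solved, by
  the homozygous-peak option). Concordance between the two methods is
  therefore necessary but not sufficient evidence of accuracy.
* The spectrum estimator needs a visible peak; below roughly 10–15×
  k-mer depth the valley and peak merge and the cutoff heuristic degrades
  (it warns, but the estimate then leans on `c0 = 1`).
* The mitochondrial screen is a k-mer heuristic, not an aligner; its
  35%-shared threshold approximates, but does not reproduce, an identity
  threshold.
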