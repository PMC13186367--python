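# Methods

## Coordinate model

All intervals are 0-based, half-open on named chromosomes (BED
convention); GTF's 1-based inclusive coordinates are converted on read.
The center of an interval is `floor((start+end)/2)`; a halfwidth-0
window degenerates to the 1-bp interval `[center, center+1)` so that
overlap remains well defined. Readers validate every record against the
declared chromosome-size table and reject out-of-range coordinates
rather than clipping. Merging unifies touching intervals, so merged
collections are sorted, non-overlapping and non-adjacent.

## Callable mask and constrained shuffle

The callable mask is the genome minus the blacklist minus zero-coverage
runs strictly longer than `min_zero_run` (default 1,000 bp,
configurable): the space where a peak caller could have reported a
peak, and therefore the only space where a null peak may be placed.
Short coverage gaps stay callable.

`shuffle_peaks` relocates a peak set uniformly over all legal
placements: a placement is legal when the whole peak fits inside one
mask segment; the segment is chosen with probability proportional to
`segment_length − peak_length + 1` and the start offset uniformly among
valid positions, which together is exactly uniform over legal
placements. Peak count and the multiset of peak lengths are conserved
exactly. Shuffling is genome-wide across all mask segments — shuffled
peaks are not held to their chromosome of origin and may overlap one
another; this is the least-constrained reading consistent with
shuffling "in the genome", and per-chromosome or non-overlapping
variants would only narrow the null. Permutation *i* of an *n*-permutation
run uses seed `seed + i`, making the null fully reproducible from one
integer.

## Repeat-family enrichment

The observed statistic per family is the number of peaks whose center
±`halfwidth` (default 100 bp) window intersects ≥1 element of the
family; a peak can count toward several families, so family counts are
superadditive relative to the union. The chance expectation is the mean
count over the 40 default permutations; the significance call uses the
range rule — a family is enriched/depleted only when the observed count
falls strictly outside `[min, max]` of the null counts. Under
exchangeability this has a per-family two-sided false-call rate of
`2/(n+1)` (≈0.049 at n=40), slightly less in practice because tied
extreme counts resolve to NS. An empirical one-sided p,
`(1 + #{null ≥ obs})/(n+1)`, is reported as a conventional diagnostic
but is not the call. A null mean of 0 with a positive observed count
reports an infinite ratio rather than silently degenerating. An
alternative distance reading — center strictly less than 200 bp from an
element — is available as `--distance-mode center-to-element`;
implemented as intersecting `[center−max_dist+1, center+max_dist)`.
No multiple-testing correction is applied across families; the range
rule is reported per family as-is.

Observed peaks must lie wholly inside the callable mask; a peak outside
could never be produced by the null and is rejected with an error
rather than biasing the comparison.

## Density by expression category

Genes are ranked by expression (ties broken by gene id, so the split is
deterministic) and cut into `n_quantiles` (default 5) groups whose
sizes differ by at most one; zero-expression genes are kept and fall in
the bottom quantile(s). Each category's territory is the per-base union
of its members' full spans (TSS→TES, not exons) minus the blacklist;
"intergenic" is the genome minus all categorised gene spans minus the
blacklist. Genes lacking an expression value are dropped by default and
their spans count as intergenic, so the categories always tile the
non-blacklisted genome.

In the default midpoint mode each event is assigned to the single
category whose territory contains its center; when gene spans of two
quantiles overlap, the center goes to the higher-expression category (a
deterministic priority that preserves exact count conservation
Σk_c = N). The literal any-overlap reading, in which an event counts in
every category it touches, is retained as an option. Events whose
center falls in the blacklist are excluded from N and from all counts.
A category whose territory is erased by the blacklist reports NaN
densities, never zero. The binomial standard error on the relative
density is `sqrt(p̂(1−p̂)/N)/L_c` with `p̂ = k_c/N`.

## Distance-to-TSS/TES profile

Only genes with detectable expression (> 0) enter, split into three
equal-sized rank classes. The genome is scanned in fixed 1 kb windows
(trailing partial windows dropped); each window midpoint receives a
metagene coordinate against the profiled class's genes only: the
nearest gene by span distance, side = the nearer of TSS/TES in
transcription orientation inside the gene (ties to TSS), or the
flanked end outside, with negative offsets outside. Restricting the
nearest-gene search to the class under profile lets each class's curve
cover the full distance axis; assigning intergenic windows to the
nearest gene of any class is the main alternative reading and would
only reallocate far-field windows. Window width 1 kb, bin width 1 kb
and max distance 50 kb are defaults, all configurable; bins tile
`[−max_dist, +max_dist)`.

Bin means are map-coverage weighted: `Σ(rate×overlap_bp)/Σ(overlap_bp)`
over contributing windows, so a constant map yields bins exactly equal
to the constant, and with unbounded max distance the coverage-weighted
mean over all bins equals the map's length-weighted global mean.

## Synthetic data generator

The generator emulates the statistical structure the three stages
assume, not sequence: a 4×2.5 Mb genome; 400 non-overlapping genes with
log-normal lengths (median 8 kb) and log-normal expression with 10%
fully silent genes; four repeat families at genomic fractions 0.10
(L1), 0.04 (MaLR), 0.03 (MIR), 0.02 (Simple_repeat) with log-normal
element lengths, free to overlap genes; blacklist (2%) and
zero-coverage (3%) runs; 2,000 hotspots with log-normal widths (median
500 bp); and a piecewise-constant recombination map (background
1 cM/Mb, 5× elevation within 1 kb of each expressed TSS, 0.5×
suppression inside top-tertile gene bodies). These sizes keep every
planted effect measurable at tight sampling error while each stage
runs in seconds. Log-normal laws are simple heavy-tailed stand-ins;
the pipeline only consumes ranks and interval geometry, so the exact
law is immaterial to stage correctness.

Hotspots are placed by thinning: candidates drawn uniformly over legal
mask placements and accepted with probability `factor/max_factor`,
where the factor multiplies a per-family term (center within ±100 bp of
an element, the exact region whose centers the enrichment window test
detects) and a per-quantile term (center inside the quantile's
territory). A planted factor is therefore exactly a placement-density
ratio, which makes the recovery targets analytic: a factor-3 family
planting yields an expected enrichment ratio 3/(1+2w) for null overlap
fraction w — about 2.7 at the default MaLR geometry — and sits well
inside the 2.5–3.5 recovery band.

What the generator does **not** emulate: nucleotide sequence, PRDM9
motifs, read-level noise, peak-calling uncertainty, chromatin
covariates, or correlated placement of repeats and genes. Passing
recovery tests therefore demonstrates the correctness of the interval
statistics and the null machinery, not robustness to peak-calling
artefacts in real ChIP-seq data.

## Validation experiments and problem sizes

The validation module re-derives each stage's behaviour from scratch:
overlap counting vs a brute-force O(n·m) scan on 100 random toy
genomes; 1,000 shuffles of a 200-peak set plus 10,000 placements of a
1-bp peak for the chi-square uniformity check; 500 null simulations of
a 400-peak set for range-rule calibration (400 peaks spread the counts
enough that discrete ties are rare); 50 replicates for the
unplanted-family NS rate; 5,000 peaks for density recovery. The
gene-body-suppression recovery experiment switches the TSS elevation
off so the gene-body effect is measured in isolation; a separate test
confirms the TSS elevation appears when planted. The recovered
inside/outside ratio slightly exceeds the planted factor because 1 kb
windows straddling gene boundaries mix background into edge bins
(≈ +0.02 at the default geometry), well inside the ±0.1 recovery band.

## Numerical and degenerate-input choices

Ranking ties break lexicographically by id everywhere, so all quantile
and tertile splits are reproducible. Floats in result tables are
written at 6 significant digits; rows are sorted lexicographically so
identical results are byte-identical. The recombination-map builder
accumulates multiplicative factors in log space at breakpoints;
adjacent equal-rate segments are merged. Degenerate inputs error
loudly: empty callable mask, a peak longer than every mask segment
(named), zero peaks, a class or quantile with no genes, overlapping
recombination-map records, unstranded gene models.

## Known limitations

Nearest-gene search is an O(windows × genes) broadcast per chromosome
— fine up to mammalian-scale annotations with 1 kb windows, but not
optimised for per-base scans. The profile stage reports only bins that
received map coverage. NCO detection power varies with heterozygosity
across expression categories; observed NCO densities are reported
as-is, uncorrected. Real-data reproduction of published figures
requires the external peak/repeat/map accessions and is supported as
I/O but not bundled.
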