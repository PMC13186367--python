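# recland

Fine-scale recombination-landscape analyses for meiotic genomics:

1. **Hotspot density by meiotic expression** — the relative density of
   DSB hotspots (or CO/NCO events, or PRDM9/ZCWPW1 peaks) across five
   quantiles of gene expression plus intergenic space, normalised per bp
   of territory and per total event count, with binomial sampling error.
2. **Recombination-rate profiles around genes** — mean recombination
   rate (cM/Mb) in bins of signed distance to the nearest TSS or TES,
   stratified into three equal-sized classes of gene expression
   (detectably expressed genes only).
3. **Repeat-family enrichment of hotspots** — per-family overlap of
   hotspot centers ±100 bp with RepeatMasker elements, compared against
   a constrained-shuffle permutation null restricted to the callable
   genome (genome minus ENCODE-style blacklist minus long zero-coverage
   runs), with a range-rule significance call.

A synthetic-data generator with planted ground truth (enrichment
factors, density ratios, gene-body rate suppression) makes every stage
verifiable end-to-end without downloading any external dataset.

## The statistics

For expression category *c* with territory length *L_c* bp, event count
*k_c* out of *N* genome-wide events (blacklisted events excluded):

```
density_c           = k_c / L_c
relative_density_c  = (k_c / L_c) / N
SE(relative_c)      = sqrt(p(1-p)/N) / L_c,   p = k_c / N
```

For repeat family *F*, the observed statistic is the number of hotspots
whose center ±100 bp window shares ≥1 bp with an element of *F*. The
chance expectation is the mean of the same count over 40 shuffles of the
hotspot set within the callable mask; each shuffle preserves the peak
count and length multiset exactly and places each peak uniformly over
all legal placements (segment chosen ∝ segment_length − peak_length + 1,
then offset uniform). The call is

```
enriched  if observed > max(null)      (strictly above the whole null range)
depleted  if observed < min(null)
NS        otherwise
ratio = observed / mean(null)
```

Under exchangeability the false-call rate of this range rule is
2/(n_permutations+1) ≈ 0.049 at 40 permutations.

## Worked example

```
echo '{"planted_family_enrichment": {"MaLR": 3.0}}' > demo_cfg.json
recland simulate --config demo_cfg.json --seed 11 --outdir demo
recland enrich --peaks demo/hotspots.bed --rmsk demo/repeats_rmsk.tsv \
    --blacklist demo/blacklist.bed --zerocov demo/zero_coverage.bed \
    --chrom-sizes demo/chrom.sizes --nperm 40 --seed 42 --out demo/enrich.tsv
```

The simulated dataset is a 10 Mb, 4-chromosome genome with 400 genes,
four repeat families (L1, MaLR, MIR, Simple_repeat), 2,000 hotspots,
blacklist/zero-coverage masks, and a factor-3 hotspot enrichment
planted near MaLR elements. `demo/enrich.tsv` then reads:

```
family         observed_count  observed_pct  null_mean  null_min  null_max  ratio     call
L1             208             10.4          211.625    184       239       0.982871  NS
MIR            115             5.75          119.6      100       139       0.961538  NS
MaLR           311             15.55         114.6      100       132       2.71379   enriched
Simple_repeat  114             5.7           120.375    95        141       0.94704   NS
```

Only the planted family is called enriched: its observed count (15.6%
of peaks) lies far above the whole 40-permutation null range, while the
other families sit inside theirs. The recovered ratio 2.71 sits below
the planted factor 3 by exactly the expected dilution 3/(1+2w), where w
is the null overlap fraction (~6% here). The `density` and `profile` subcommands
produce the per-category density table (six rows: q1..q5 + intergenic)
and the per-(class, side, distance-bin) rate table the two other
analyses are built on.

The same API is available from Python (`recland.simulate_dataset`,
`recland.enrichment_test`, `recland.peak_density_by_category`,
`recland.recombination_profile`).

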