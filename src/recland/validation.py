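"""Synthetic-benchmark experiments verifying each pipeline stage.

Each function builds a toy dataset with known structure, runs the
corresponding stage and returns the measured quantities: brute-force
oracle agreement for the interval engine, conservation/containment/
uniformity of the constrained shuffle, false-call calibration of the
range-rule significance test, and recovery of planted enrichment,
density and gene-body suppression parameters. These experiments back
both the test suite and the reproduction script.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CallableMask,
    GenomeLayout,
    PeakSet,
    build_callable_mask,
    count_overlapping,
    intervals_frame,
    shuffle_peaks,
    uniform_placements,
)
from .density import INTERGENIC, assign_expression_categories, peak_density_by_category
from .enrichment import NS, enrichment_test, family_overlap_counts
from .io import RepeatAnnotation
from .profile import recombination_profile
from .synthetic import (
    LogNormalLaw,
    RecmapParams,
    SyntheticConfig,
    simulate_annotation,
    simulate_hotspots,
    simulate_recmap,
)


def brute_force_overlap(queries: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """O(n*m) pairwise scan: per query, does any target share a base?"""
    tc = targets["chrom"].to_numpy()
    ts = targets["start"].to_numpy(np.int64)
    te = targets["end"].to_numpy(np.int64)
    out = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries.itertuples(index=False)):
        out[i] = bool(np.any((tc == q.chrom) & (ts < q.end) & (te > q.start)))
    return out


def random_intervals(rng: np.random.Generator, layout: GenomeLayout, n: int,
                     max_len: int = 400) -> pd.DataFrame:
    names = layout.names
    clens = np.array([layout.length_of(c) for c in names], dtype=np.int64)
    ci = rng.integers(0, len(names), size=n)
    lengths = rng.integers(1, max_len + 1, size=n)
    lengths = np.minimum(lengths, clens[ci])
    starts = (rng.random(n) * (clens[ci] - lengths + 1)).astype(np.int64)
    return pd.DataFrame({"chrom": np.array(names, dtype=object)[ci],
                         "start": starts, "end": starts + lengths})


def overlap_oracle_experiment(n_instances: int = 100, seed: int = 0) -> dict:
    """Interval-engine counts vs brute force on random toy instances.

    Random genomes of <= 50 kb with up to 500 intervals per side; also
    checks the repeat-family counting path against the same oracle.
    Returns the number of mismatching instances (expected 0).
    """
    rng = np.random.default_rng(seed)
    mismatches = 0
    family_mismatches = 0
    for _ in range(n_instances):
        layout = GenomeLayout({f"chr{i + 1}": int(rng.integers(5_000, 25_001))
                               for i in range(int(rng.integers(1, 4)))})
        nq = int(rng.integers(1, 501))
        nt = int(rng.integers(1, 501))
        queries = random_intervals(rng, layout, nq)
        targets = random_intervals(rng, layout, nt)
        count, hit = count_overlapping(queries, targets)
        oracle = brute_force_overlap(queries, targets)
        if count != int(oracle.sum()) or not np.array_equal(hit, oracle):
            mismatches += 1
        # family path: windows +/- 100 bp of query centers vs 3 families
        fam = np.array(["L1", "MaLR", "MIR"], dtype=object)[rng.integers(0, 3, size=nt)]
        repeats = RepeatAnnotation(records=targets.assign(family=fam))
        peaks = PeakSet(label="toy", intervals=queries)
        counts = family_overlap_counts(peaks, repeats, halfwidth=100, layout=layout)
        from .core import windows_around_centers
        windows = windows_around_centers(queries, 100, layout)
        for family in repeats.families:
            want = int(brute_force_overlap(windows, repeats.family_frame(family)).sum())
            if counts[family][0] != want:
                family_mismatches += 1
    return {"instances": n_instances, "count_mismatches": mismatches,
            "family_count_mismatches": family_mismatches}


def _toy_mask(seed: int = 0, n_chrom: int = 2, clen: int = 300_000,
              n_holes: int = 12, hole_len: int = 8000) -> tuple[GenomeLayout, CallableMask]:
    rng = np.random.default_rng(seed)
    layout = GenomeLayout({f"chr{i + 1}": clen for i in range(n_chrom)})
    holes = []
    for c in layout.names:
        for _ in range(n_holes):
            s = int(rng.integers(0, clen - hole_len))
            holes.append((c, s, s + hole_len))
    blacklist = intervals_frame(holes[: len(holes) // 2])
    zero = intervals_frame(holes[len(holes) // 2:])
    return layout, build_callable_mask(layout, blacklist, zero, min_zero_run=1000)


def shuffle_validity_experiment(n_shuffles: int = 1000, n_peaks: int = 200,
                                seed: int = 42) -> dict:
    """Conservation, mask containment and placement uniformity of the shuffle.

    Over `n_shuffles` shuffles of an `n_peaks` set: peak count and the
    length multiset must be conserved exactly and no shuffled base may
    leave the callable mask. Uniformity is checked separately: 10,000
    placements of a 1-bp peak in a contiguous 1,000-bp mask, chi-square
    over 10 equal bins.
    """
    layout, mask = _toy_mask(seed)
    rng = np.random.default_rng(seed)
    lengths = rng.integers(100, 2000, size=n_peaks)
    base = PeakSet(label="obs", intervals=uniform_placements(lengths, mask, rng))
    want_lengths = np.sort(base.lengths())
    seg = {c: g for c, g in mask.segments.groupby("chrom", sort=False)}
    conserved = True
    outside_bases = 0
    for i in range(n_shuffles):
        sh = shuffle_peaks(base, mask, seed + i)
        if sh.n != base.n or not np.array_equal(np.sort(sh.lengths()), want_lengths):
            conserved = False
        for chrom, g in sh.intervals.groupby("chrom", sort=False):
            ms = seg[chrom]["start"].to_numpy(np.int64)
            me = seg[chrom]["end"].to_numpy(np.int64)
            s = g["start"].to_numpy(np.int64)
            e = g["end"].to_numpy(np.int64)
            idx = np.searchsorted(ms, s, side="right") - 1
            inside = (idx >= 0) & (e <= me[np.clip(idx, 0, me.size - 1)])
            # bases outside: whole peak length for any non-contained peak
            outside_bases += int((e - s)[~inside].sum())

    tiny_layout = GenomeLayout({"chr1": 1000})
    tiny_mask = build_callable_mask(tiny_layout, intervals_frame(), intervals_frame(), 0)
    one = PeakSet(label="p", intervals=intervals_frame([("chr1", 0, 1)]))
    counts = np.zeros(10, dtype=np.int64)
    uni_rng = np.random.default_rng(seed)
    for _ in range(10_000):
        s = int(shuffle_peaks(one, tiny_mask, uni_rng).intervals["start"].iloc[0])
        counts[s // 100] += 1
    chi2_p = float(stats.chisquare(counts).pvalue)
    return {"n_shuffles": n_shuffles, "n_peaks": n_peaks, "conserved": conserved,
            "outside_mask_bases": outside_bases, "uniformity_chi2_p": chi2_p}


def _calibration_repeats(rng: np.random.Generator, layout: GenomeLayout) -> RepeatAnnotation:
    frames = []
    for family, n, length in (("L1", 120, 900), ("MaLR", 150, 350), ("MIR", 200, 200)):
        df = random_intervals(rng, layout, n, max_len=length)
        frames.append(df.assign(family=family))
    return RepeatAnnotation(records=pd.concat(frames, ignore_index=True))


def significance_calibration_experiment(n_sims: int = 500, n_permutations: int = 40,
                                        seed: int = 0) -> dict:
    """False-call rate of the range rule with peaks drawn from the null.

    When the observed peaks are themselves a draw from the shuffle
    null, the observed count is exchangeable with the permutation
    counts, so P(observed strictly outside the null range) is
    2/(n_permutations+1) per family — 2/41 ~ 0.049 at the default 40
    permutations (slightly less in practice because tied extreme counts
    resolve to NS; the peak set is sized so counts spread enough for
    ties to be rare). Returns the fraction of non-NS calls over
    `n_sims` x families draws.
    """
    layout, mask = _toy_mask(seed=7)
    rng = np.random.default_rng(seed)
    repeats = _calibration_repeats(rng, layout)
    lengths = rng.integers(200, 1200, size=400)
    base = PeakSet(label="base", intervals=uniform_placements(lengths, mask, rng))
    calls = 0
    total = 0
    for i in range(n_sims):
        sim_seed = seed + 1_000_000 + i * (n_permutations + 1)
        observed = shuffle_peaks(base, mask, sim_seed)
        report = enrichment_test(observed, repeats, mask, n_permutations=n_permutations,
                                 halfwidth=100, seed=sim_seed + 1, layout=layout)
        calls += int((report.summary["call"] != NS).sum())
        total += len(report.summary)
    return {"n_sims": n_sims, "n_permutations": n_permutations,
            "expected_rate": 2 / (n_permutations + 1),
            "non_ns_rate": calls / total}


def planted_enrichment_experiment(factor: float = 3.0, n_hotspots: int = 2000,
                                  seed: int = 1, n_replicates: int = 50) -> dict:
    """Recovery of a planted per-family hotspot enrichment factor.

    Plants `factor`-fold hotspot placement density within +/-100 bp of
    MaLR elements, runs the enrichment test, and reports the recovered
    ratio and call for the planted family plus the NS rate of the
    unplanted families over `n_replicates` independent simulations.
    """
    config = SyntheticConfig(seed=seed, n_hotspots=n_hotspots,
                             planted_family_enrichment={"MaLR": factor})
    annotation = simulate_annotation(config)
    mask = build_callable_mask(annotation.layout, annotation.blacklist,
                               annotation.zero_coverage, config.min_zero_run)
    hotspots, _ = simulate_hotspots(config, annotation)
    report = enrichment_test(hotspots, annotation.repeats, mask, n_permutations=40,
                             halfwidth=100, seed=seed + 10_000, layout=annotation.layout)
    planted = report.summary.set_index("family").loc["MaLR"]

    unplanted = [f for f in annotation.repeats.families if f != "MaLR"]
    ns_counts = {f: 0 for f in unplanted}
    for r in range(n_replicates):
        cfg = replace(config, seed=seed + 37 * (r + 1))
        ann = simulate_annotation(cfg)
        msk = build_callable_mask(ann.layout, ann.blacklist, ann.zero_coverage, cfg.min_zero_run)
        hs, _ = simulate_hotspots(cfg, ann)
        rep = enrichment_test(hs, ann.repeats, msk, n_permutations=40, halfwidth=100,
                              seed=cfg.seed + 10_000, layout=ann.layout)
        summary = rep.summary.set_index("family")
        for f in unplanted:
            if summary.loc[f, "call"] == NS:
                ns_counts[f] += 1
    ns_fraction = {f: c / n_replicates for f, c in ns_counts.items()}
    return {"planted_factor": factor, "n_hotspots": n_hotspots,
            "recovered_ratio": float(planted["ratio"]), "call": str(planted["call"]),
            "n_replicates": n_replicates,
            "min_unplanted_ns_fraction": min(ns_fraction.values()),
            "unplanted_ns_fraction": ns_fraction}


def density_recovery_experiment(factor: float = 5.0, n_peaks: int = 5000,
                                seed: int = 0) -> dict:
    """Recovery of a planted relative-density excess in the top quantile.

    Plants a `factor`-fold hotspot placement density inside top-quantile
    gene territories, runs the density stage in midpoint mode, and
    returns the recovered top-vs-intergenic relative-density ratio, the
    count-conservation gap and the largest deviation of the reported
    binomial SE from its closed form.
    """
    config = SyntheticConfig(seed=seed, n_hotspots=n_peaks,
                             planted_expression_density={5: factor})
    annotation = simulate_annotation(config)
    hotspots, _ = simulate_hotspots(config, annotation)
    categories = assign_expression_categories(annotation.genes, annotation.expression,
                                              config.n_quantiles, layout=annotation.layout,
                                              blacklist=annotation.blacklist)
    result = peak_density_by_category(hotspots, categories, assignment_mode="midpoint")
    by_cat = result.set_index("category")
    ratio = float(by_cat.loc["q5", "relative_density"] / by_cat.loc[INTERGENIC, "relative_density"])
    conservation_gap = int(result["peak_count"].sum() - result["total_peaks"].iloc[0])
    k = result["peak_count"].to_numpy(float)
    n = result["total_peaks"].to_numpy(float)
    length = result["territory_bp"].to_numpy(float)
    p_hat = k / n
    with np.errstate(divide="ignore", invalid="ignore"):
        expected_se = np.sqrt(p_hat * (1 - p_hat) / n) / length
    se = result["se_relative"].to_numpy(float)
    ok = length > 0
    se_max_abs_err = float(np.max(np.abs(se[ok] - expected_se[ok])))
    return {"planted_factor": factor, "n_peaks": n_peaks, "recovered_ratio": ratio,
            "conservation_gap": conservation_gap, "se_max_abs_err": se_max_abs_err}


def profile_recovery_experiment(suppression: float = 0.5, seed: int = 0,
                                bin_width: int = 1000, max_dist: int = 20_000) -> dict:
    """Flat-map identity and recovery of planted gene-body suppression.

    First a constant map: every reported bin mean must equal the
    constant exactly. Then a map with the top-tertile gene bodies
    suppressed by `suppression` (TSS elevation switched off so the
    gene-body effect is measured in isolation): the recovered
    inside/outside rate ratio for the top class is returned.
    """
    flat_cfg = SyntheticConfig(
        seed=seed,
        recmap=RecmapParams(background_rate=1.7, tss_peak_factor=1.0,
                            genebody_suppression={}),
    )
    annotation = simulate_annotation(flat_cfg)
    flat_map, _ = simulate_recmap(flat_cfg, annotation)
    flat = recombination_profile(flat_map, annotation.genes, annotation.expression,
                                 n_classes=3, bin_width=bin_width, max_dist=max_dist,
                                 window=1000, layout=annotation.layout)
    flat_max_dev = float(np.max(np.abs(flat["mean_rate"].to_numpy() - 1.7)))

    cfg = SyntheticConfig(
        seed=seed,
        recmap=RecmapParams(background_rate=1.0, tss_peak_factor=1.0,
                            genebody_suppression={3: suppression}),
    )
    annotation = simulate_annotation(cfg)
    recmap, truth = simulate_recmap(cfg, annotation)
    prof = recombination_profile(recmap, annotation.genes, annotation.expression,
                                 n_classes=3, bin_width=bin_width, max_dist=max_dist,
                                 window=1000, layout=annotation.layout)
    top = prof[prof["expression_class"] == 3]
    inside = top[top["bin_lo"] >= 0]
    outside = top[top["bin_hi"] <= 0]
    w_in = inside["covered_bp"].to_numpy(float)
    w_out = outside["covered_bp"].to_numpy(float)
    inside_mean = float((inside["mean_rate"].to_numpy() * w_in).sum() / w_in.sum())
    outside_mean = float((outside["mean_rate"].to_numpy() * w_out).sum() / w_out.sum())
    return {"planted_suppression": suppression, "flat_max_abs_dev": flat_max_dev,
            "recovered_ratio": inside_mean / outside_mean,
            "inside_mean": inside_mean, "outside_mean": outside_mean}
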