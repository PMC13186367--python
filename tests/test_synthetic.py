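"""Synthetic-genome generator: determinism, realized fractions, planted maps."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from recland.core import (
    build_callable_mask,
    count_overlapping,
    covered_bp,
    merge_intervals,
    points_in_intervals,
)
from recland.io import (
    read_chrom_sizes,
    read_expression_tsv,
    read_genes_gtf,
    read_intervals,
    read_recmap_bedgraph,
    read_repeatmasker,
)
from recland.synthetic import (
    LogNormalLaw,
    RecmapParams,
    SyntheticConfig,
    simulate_annotation,
    simulate_dataset,
    simulate_hotspots,
    simulate_recmap,
    write_dataset,
)


SMALL = SyntheticConfig(n_chromosomes=2, chromosome_length=1_000_000,
                        n_genes=80, n_hotspots=300)


class TestConfig:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(blacklist_fraction=1.5).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(planted_family_enrichment={"L1": -1}).validate()

    def test_json_roundtrip(self, tmp_path):
        cfg = replace(SMALL, planted_family_enrichment={"MaLR": 3.0},
                      planted_expression_density={5: 2.0})
        p = tmp_path / "cfg.json"
        cfg.to_json(p)
        assert SyntheticConfig.from_json(p) == cfg


class TestAnnotation:
    def test_deterministic_given_seed(self, tmp_path):
        a = simulate_annotation(replace(SMALL, seed=9))
        b = simulate_annotation(replace(SMALL, seed=9))
        assert a.genes.equals(b.genes)
        assert a.expression.equals(b.expression)
        assert a.repeats.records.equals(b.repeats.records)
        c = simulate_annotation(replace(SMALL, seed=10))
        assert not a.genes.equals(c.genes)

    def test_zero_blacklist_fraction_is_empty(self):
        ann = simulate_annotation(replace(SMALL, blacklist_fraction=0.0))
        assert ann.blacklist.empty

    def test_genes_do_not_overlap(self):
        ann = simulate_annotation(SMALL)
        merged = merge_intervals(ann.genes[["chrom", "start", "end"]], ann.layout)
        assert covered_bp(merged) == int((ann.genes["end"] - ann.genes["start"]).sum())

    def test_repeat_fraction_close_to_target(self):
        cfg = SyntheticConfig(seed=2)  # default L1 fraction 0.10 on 10 Mb
        ann = simulate_annotation(cfg)
        l1 = merge_intervals(ann.repeats.family_frame("L1"), ann.layout)
        frac = covered_bp(l1) / ann.layout.total_length
        assert 0.08 <= frac <= 0.12

    def test_zero_expression_fraction_realized(self):
        ann = simulate_annotation(replace(SMALL, zero_expression_fraction=0.25))
        assert int((ann.expression == 0).sum()) == round(0.25 * len(ann.genes))


class TestHotspots:
    def test_zero_hotspots_requested_errors(self):
        with pytest.raises(ValueError):
            simulate_hotspots(replace(SMALL, n_hotspots=0), simulate_annotation(SMALL))

    def test_hotspots_inside_callable_mask(self):
        cfg = SMALL
        ann = simulate_annotation(cfg)
        hs, _ = simulate_hotspots(cfg, ann)
        assert hs.n == cfg.n_hotspots
        mask = build_callable_mask(ann.layout, ann.blacklist, ann.zero_coverage,
                                   cfg.min_zero_run)
        # no hotspot center leaves the mask, and no base hits the blacklist
        inside = mask.contains_points(hs.intervals["chrom"].to_numpy(), hs.centers())
        assert inside.all()
        if not ann.blacklist.empty:
            n_bl, _ = count_overlapping(hs.intervals, ann.blacklist)
            assert n_bl == 0

    def test_uniform_when_no_factors(self):
        cfg = replace(SMALL, seed=7, n_hotspots=2000)
        ann = simulate_annotation(cfg)
        hs, truth = simulate_hotspots(cfg, ann)
        assert truth.family_enrichment == {}
        # centers split across the two equal chromosomes close to the
        # callable-length ratio
        mask = build_callable_mask(ann.layout, ann.blacklist, ann.zero_coverage,
                                   cfg.min_zero_run)
        seg = mask.segments
        frac_mask = covered_bp(seg[seg["chrom"] == "chr1"]) / mask.total_bp
        frac_hs = float((hs.intervals["chrom"] == "chr1").mean())
        assert abs(frac_hs - frac_mask) < 0.04

    def test_planted_family_excess_near_elements(self):
        factor = 3.0
        cfg = replace(SMALL, seed=1, n_hotspots=2000,
                      planted_family_enrichment={"MaLR": factor})
        ann = simulate_annotation(cfg)
        hs, truth = simulate_hotspots(cfg, ann)
        assert truth.family_enrichment == {"MaLR": factor}
        from recland.synthetic import expand_for_center_window
        region = expand_for_center_window(ann.repeats.family_frame("MaLR"),
                                          cfg.planted_halfwidth, ann.layout)
        mask = build_callable_mask(ann.layout, ann.blacklist, ann.zero_coverage,
                                   cfg.min_zero_run)
        from recland.core import intersect_intervals
        w = covered_bp(intersect_intervals(region, mask.segments)) / mask.total_bp
        expected = factor * w / (1 + (factor - 1) * w)
        near = points_in_intervals(hs.intervals["chrom"].to_numpy(), hs.centers(), region)
        got = float(near.mean())
        assert got == pytest.approx(expected, abs=3 * math.sqrt(expected * (1 - expected) / hs.n))


class TestRecmap:
    def test_all_factors_one_gives_constant_map(self):
        cfg = replace(SMALL, recmap=RecmapParams(background_rate=1.3,
                                                 tss_peak_factor=1.0,
                                                 genebody_suppression={}))
        ann = simulate_annotation(cfg)
        recmap, _ = simulate_recmap(cfg, ann)
        assert (recmap.records["rate"] == 1.3).all()
        assert len(recmap.records) == cfg.n_chromosomes

    def test_suppression_is_exact_inside_gene_bodies(self):
        cfg = replace(SMALL, recmap=RecmapParams(background_rate=2.0,
                                                 tss_peak_factor=1.0,
                                                 genebody_suppression={3: 0.5}))
        ann = simulate_annotation(cfg)
        recmap, truth = simulate_recmap(cfg, ann)
        top = [g for g, c in truth.class_assignment.items() if c == 3]
        genes = ann.genes.set_index("gene_id").loc[top]
        # sample the map at every top-class gene-body midpoint: exactly 0.5 x bg
        for row in genes.itertuples():
            mid = (row.start + row.end) // 2
            seg = recmap.records[(recmap.records["chrom"] == row.chrom) &
                                 (recmap.records["start"] <= mid) &
                                 (recmap.records["end"] > mid)]
            assert seg["rate"].iloc[0] == pytest.approx(1.0)

    def test_tss_elevation_present(self):
        cfg = replace(SMALL, recmap=RecmapParams(background_rate=1.0,
                                                 tss_peak_factor=5.0,
                                                 tss_peak_halfwidth=500,
                                                 genebody_suppression={}))
        ann = simulate_annotation(cfg)
        recmap, truth = simulate_recmap(cfg, ann)
        expressed = ann.genes[ann.genes["gene_id"].map(ann.expression) > 0]
        tss = expressed.iloc[0]
        seg = recmap.records[(recmap.records["chrom"] == tss.chrom) &
                             (recmap.records["start"] <= tss.tss) &
                             (recmap.records["end"] > tss.tss)]
        # >= 5 x background up to float rounding; may stack with a neighbour's window
        assert seg["rate"].iloc[0] >= 5.0 - 1e-9

    def test_map_covers_genome_without_overlap(self):
        cfg = SMALL
        ann = simulate_annotation(cfg)
        recmap, _ = simulate_recmap(cfg, ann)
        assert covered_bp(recmap.records[["chrom", "start", "end"]]) == \
            ann.layout.total_length


class TestDatasetFiles:
    def test_written_files_readable_by_every_reader(self, tmp_path):
        cfg = replace(SMALL, planted_family_enrichment={"MaLR": 2.0})
        ann, hs, recmap, truth = simulate_dataset(cfg)
        paths = write_dataset(tmp_path, ann, hs, recmap, truth)
        layout = read_chrom_sizes(paths["chrom_sizes"])
        assert layout == ann.layout
        genes = read_genes_gtf(paths["genes"], layout)
        assert genes[["gene_id", "chrom", "start", "end", "strand", "tss", "tes"]] \
            .reset_index(drop=True).equals(
                ann.genes.sort_values(["chrom", "start", "gene_id"], kind="mergesort")
                .reset_index(drop=True))
        expr = read_expression_tsv(paths["expression"])
        assert np.allclose(expr.sort_index().to_numpy(),
                           ann.expression.sort_index().to_numpy())
        reps = read_repeatmasker(paths["repeats"], layout, None)
        assert len(reps.records) == len(ann.repeats.records)
        hs_back = read_intervals(paths["hotspots"], layout)
        assert hs_back.intervals[["chrom", "start", "end"]].equals(
            hs.intervals[["chrom", "start", "end"]])
        m = read_recmap_bedgraph(paths["recmap"], layout)
        assert np.allclose(m.records["rate"], recmap.records["rate"], rtol=1e-5)

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for d in ("a", "b"):
            ann, hs, recmap, truth = simulate_dataset(replace(SMALL, seed=5))
            write_dataset(tmp_path / d, ann, hs, recmap, truth)
        for name in ("chrom.sizes", "genes.gtf", "expression.tsv", "repeats_rmsk.tsv",
                     "blacklist.bed", "zero_coverage.bed", "hotspots.bed",
                     "recmap.bedgraph", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes(), name
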