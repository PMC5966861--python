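import math

import numpy as np
import pytest

from svmeta import (CallerProfile, CapacityError, LengthDist, MatchConfig,
                    SimConfig, benchmark, default_profiles, emulate_caller,
                    expected_detection, run_titration, simulate_trio,
                    simulate_truth, titration_summary, trio_adi)

CFG = MatchConfig()
SMALL = SimConfig(chrom_sizes={"1": 2_000_000}, n_del=30, n_ins=30, seed=42)


class TestSimulateTruth:
    def test_deterministic_and_counts(self):
        t1 = simulate_truth(SMALL)
        t2 = simulate_truth(SMALL)
        assert t1 == t2
        assert sum(c.svtype == "DEL" for c in t1.calls) == 30
        assert sum(c.svtype == "INS" for c in t1.calls) == 30

    def test_empty_config(self):
        t = simulate_truth(SimConfig(n_del=0, n_ins=0, seed=1))
        assert len(t) == 0

    def test_lengths_within_truncation_bounds(self):
        t = simulate_truth(SimConfig(n_del=200, n_ins=200,
                                     chrom_sizes={"1": 50_000_000}, seed=5))
        assert all(50 <= c.length <= 100_000 for c in t.calls)

    def test_deletions_respect_min_gap(self):
        cfg = SimConfig(chrom_sizes={"1": 3_000_000}, n_del=80, n_ins=80,
                        min_gap=2000, seed=9)
        t = simulate_truth(cfg)
        by_chrom = {}
        for c in t.calls:
            by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert s2 - e1 > cfg.min_gap

    def test_capacity_error_when_genome_too_small(self):
        with pytest.raises(CapacityError):
            simulate_truth(SimConfig(chrom_sizes={"1": 10_000}, n_del=500,
                                     n_ins=0, seed=1))

    def test_coordinates_within_chromosome(self):
        cfg = SimConfig(chrom_sizes={"1": 500_000}, n_del=20, n_ins=20, seed=3)
        for c in simulate_truth(cfg).calls:
            assert 1 <= c.start and c.end <= 500_000


class TestExpectedDetection:
    def test_poisson_tail_closed_form(self):
        # lambda = 5, min support 2: 1 - e^-5 - 5 e^-5 = 1 - 6 e^-5
        assert expected_detection(10, 0.5, 1.0, 2) == pytest.approx(
            1 - 6 * math.exp(-5), rel=1e-12)

    def test_zero_support_always_detected(self):
        assert expected_detection(0.001, 0.5, 0.1, 0) == 1.0

    def test_zero_rate_never_detected(self):
        assert expected_detection(10, 0.5, 0.0, 1) == 0.0

    def test_monotone_in_coverage(self):
        probs = [expected_detection(c, 0.5, 1.0, 2) for c in (2, 4, 8, 16)]
        assert probs == sorted(probs)


class TestEmulateCaller:
    def test_noise_free_limit_reproduces_truth(self):
        truth = simulate_truth(SMALL)
        profile = CallerProfile("X", min_support=0, breakpoint_sd=0.0, fp_rate=0.0)
        out = emulate_caller(truth, profile, 10, seed=1)
        assert [(c.chrom, c.start, c.end, c.svtype, c.length) for c in out.calls] == \
               [(c.chrom, c.start, c.end, c.svtype, c.length) for c in truth.calls]

    def test_asymptotic_recall_reaches_one(self):
        truth = simulate_truth(SMALL)
        profile = CallerProfile("X", min_support=2, breakpoint_sd=0.0, fp_rate=0.0)
        out = emulate_caller(truth, profile, 10_000, seed=2)
        res = benchmark(out, truth, CFG, min_len=0)
        assert res.per_type["DEL"].recall == 1.0
        assert res.per_type["INS"].recall == 1.0

    def test_deterministic_given_seed(self):
        truth = simulate_truth(SMALL)
        profile = default_profiles()[0]
        a = emulate_caller(truth, profile, 10, seed=77, chrom_sizes=SMALL.chrom_sizes)
        b = emulate_caller(truth, profile, 10, seed=77, chrom_sizes=SMALL.chrom_sizes)
        assert a == b

    def test_support_respects_min_support(self):
        truth = simulate_truth(SMALL)
        profile = CallerProfile("X", min_support=3, breakpoint_sd=0.0, fp_rate=0.0)
        out = emulate_caller(truth, profile, 4, seed=3)
        assert all(c.support >= 3 for c in out.calls)

    def test_type_bias_suppresses_detection(self):
        truth = simulate_truth(SimConfig(chrom_sizes={"1": 20_000_000},
                                         n_del=300, n_ins=300, seed=8))
        blind = CallerProfile("X", min_support=2, breakpoint_sd=0.0, fp_rate=0.0,
                              type_bias={"INS": 0.001})
        out = emulate_caller(truth, blind, 10, seed=4)
        n_ins = sum(c.svtype == "INS" for c in out.calls)
        n_del = sum(c.svtype == "DEL" for c in out.calls)
        assert n_ins <= 3 and n_del > 200

    def test_detection_frequency_matches_poisson_tail(self):
        # calibration at 10X, allele fraction 0.5, min support 2
        cfg = SimConfig(chrom_sizes={"1": 60_000_000, "2": 60_000_000},
                        n_del=1000, n_ins=1000, seed=17)
        truth = simulate_truth(cfg)
        profile = CallerProfile("X", min_support=2, breakpoint_sd=0.0, fp_rate=0.0)
        out = emulate_caller(truth, profile, 10, seed=18,
                             allele_fraction=cfg.allele_fraction)
        p = expected_detection(10, 0.5, 1.0, 2)
        n = len(truth)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(len(out) / n - p) < 3 * se


class TestTitration:
    def test_recall_increases_with_coverage(self):
        cfg = SimConfig(chrom_sizes={"1": 3_000_000}, n_del=60, n_ins=60, seed=21)
        profiles = [CallerProfile("X", min_support=2, breakpoint_sd=0.0, fp_rate=0.0),
                    CallerProfile("Y", min_support=2, breakpoint_sd=0.0, fp_rate=0.0)]
        df = run_titration(cfg, profiles, coverages=[2, 10], replicates=3, seed=5)
        m = df.groupby(["callset", "svtype", "coverage"])["recall"].mean()
        for cal in ("X", "Y"):
            for t in ("DEL", "INS"):
                assert m[(cal, t, 10)] > m[(cal, t, 2)]

    def test_noise_free_precision_is_one(self):
        cfg = SimConfig(chrom_sizes={"1": 3_000_000}, n_del=60, n_ins=60, seed=22)
        profiles = [CallerProfile(l, min_support=2, breakpoint_sd=0.0, fp_rate=0.0)
                    for l in ("A", "B", "C")]
        df = run_titration(cfg, profiles, coverages=[6], replicates=2, seed=6)
        evaluated = df[df.tp + df.fp > 0]
        assert (evaluated.precision == 1.0).all()

    def test_sensitive_recall_dominates_each_caller(self):
        cfg = SimConfig(chrom_sizes={"1": 3_000_000}, n_del=60, n_ins=60, seed=23)
        profiles = [CallerProfile(l, min_support=2, breakpoint_sd=0.0, fp_rate=0.0)
                    for l in ("A", "B", "C")]
        df = run_titration(cfg, profiles, coverages=[4, 8], replicates=3, seed=7)
        sens = df[df.callset == "meta-sensitive"].set_index(
            ["coverage", "replicate", "svtype"])["recall"]
        singles = df[df.callset.isin(["A", "B", "C"])].groupby(
            ["coverage", "replicate", "svtype"])["recall"].max()
        assert (sens >= singles - 1e-12).all()

    def test_table_shape_and_determinism(self):
        cfg = SimConfig(chrom_sizes={"1": 2_000_000}, n_del=25, n_ins=25, seed=24)
        df1 = run_titration(cfg, coverages=[4, 10], replicates=2, seed=9)
        df2 = run_titration(cfg, coverages=[4, 10], replicates=2, seed=9)
        assert df1.equals(df2)
        # coverages x replicates x (3 callers + 2 meta sets) x 2 types
        assert len(df1) == 2 * 2 * 5 * 2

    def test_summary_sd_zero_for_single_replicate(self):
        cfg = SimConfig(chrom_sizes={"1": 2_000_000}, n_del=25, n_ins=25, seed=25)
        df = run_titration(cfg, coverages=[6], replicates=1, seed=10)
        s = titration_summary(df)
        assert (s.filter(like="_std") == 0.0).all().all()


class TestSimulateTrio:
    def test_planted_private_fraction_recovered(self):
        cfg = SimConfig(chrom_sizes={"1": 10_000_000, "2": 10_000_000},
                        n_del=150, n_ins=150, seed=31)
        off, fa, mo = simulate_trio(cfg, private_fraction=0.2, seed=32)
        res = trio_adi(off, fa, mo, CFG)
        total = sum(r.offspring_calls for r in res.per_type.values())
        events = sum(r.adi_events for r in res.per_type.values())
        q = 0.2
        se = math.sqrt(q * (1 - q) / total)
        assert abs(events / total - q) < 3 * se

    def test_zero_private_fraction_gives_zero_adi(self):
        off, fa, mo = simulate_trio(SMALL, private_fraction=0.0)
        res = trio_adi(off, fa, mo, CFG)
        assert all(r.adi_events == 0 for r in res.per_type.values())

    def test_full_private_fraction_gives_unit_adi(self):
        off, fa, mo = simulate_trio(SMALL, private_fraction=1.0)
        assert len(fa) == 0 and len(mo) == 0
        res = trio_adi(off, fa, mo, CFG)
        assert all(r.adi_rate == 1.0 for r in res.per_type.values())
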