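import pandas as pd
import pytest
from scipy import stats as sps

from conftest import small_sim_config
from mapipe.repeats import find_repeats
from mapipe.simulate import (SimConfig, apply_detection_dropout,
                             generate_genome, simulate_ma_lines)


class TestGenerateGenome:
    def test_single_embedded_repeat(self):
        cfg = SimConfig(genome_length=10_000, repeat_spec=[("A", 8, 1)],
                        n_chromosomes=1)
        sequences, truth = generate_genome(cfg, seed=1)
        assert len(truth) == 1
        l = list(truth)[0]
        assert l.length_bp == 8 and l.motif_class == "A/T"
        census = {(x.chrom, x.start, x.end, x.unit)
                  for x in find_repeats(sequences)}
        assert (l.chrom, l.start, l.end, l.unit) in census

    def test_deterministic_bytes(self):
        cfg = small_sim_config()
        s1, t1 = generate_genome(cfg, seed=5)
        s2, t2 = generate_genome(cfg, seed=5)
        assert s1 == s2
        assert [(l.start, l.end) for l in t1] == [(l.start, l.end) for l in t2]

    def test_hundred_embedded_loci_recovered_exactly(self):
        spec = [("A", 5, 40), ("GT", 4, 30), ("AAT", 3, 20), ("C", 4, 10)]
        cfg = SimConfig(genome_length=60_000, repeat_spec=spec)
        sequences, truth = generate_genome(cfg, seed=9)
        assert len(truth) == 100
        census = {(x.chrom, x.start, x.end, x.unit)
                  for x in find_repeats(sequences)}
        missing = [(l.start, l.end, l.unit) for l in truth
                   if (l.chrom, l.start, l.end, l.unit) not in census]
        assert missing == []

    def test_no_unintended_repeat_touches_an_embedded_locus(self):
        cfg = small_sim_config()
        sequences, truth = generate_genome(cfg, seed=11)
        truth_keys = {(l.chrom, l.start, l.end, l.unit) for l in truth}
        by_chrom = {}
        for l in truth:
            by_chrom.setdefault(l.chrom, []).append((l.start, l.end))
        for x in find_repeats(sequences):
            if (x.chrom, x.start, x.end, x.unit) in truth_keys:
                continue
            for (s, e) in by_chrom.get(x.chrom, []):
                gap = max(s, x.start) - min(e, x.end)
                assert gap > 1, (x.chrom, x.start, x.end, x.unit, (s, e))

    def test_infeasible_packing_rejected(self):
        cfg = SimConfig(genome_length=200, repeat_spec=[("A", 8, 100)])
        with pytest.raises(ValueError, match="fit"):
            generate_genome(cfg, seed=1)

    def test_gc_content_close_to_requested(self):
        cfg = SimConfig(genome_length=200_000, repeat_spec=[],
                        gc_fraction=0.38)
        sequences, _ = generate_genome(cfg, seed=2)
        s = sequences["chr1"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert gc == pytest.approx(0.38, abs=0.01)


class TestSimulateMaLines:
    def test_zero_rates_give_no_calls(self):
        cfg = small_sim_config(snv_rate=0.0, slippage_base_rate=0.0)
        sequences, truth = generate_genome(cfg, seed=1)
        calls, events = simulate_ma_lines(sequences, truth, cfg, seed=1)
        assert calls.empty and events.empty

    def test_snv_count_matches_poisson_expectation(self):
        cfg = SimConfig(genome_length=100_000, repeat_spec=[],
                        snv_rate=2e-7, n_lineages=8, generations=100)
        sequences, truth = generate_genome(cfg, seed=4)
        calls, _ = simulate_ma_lines(sequences, truth, cfg, seed=4)
        expected = 2e-7 * 100_000 * 100 * 8   # = 16
        assert sps.poisson.ppf(0.001, expected) <= len(calls) <= \
            sps.poisson.ppf(0.999, expected)

    def test_snv_refs_match_genome(self):
        cfg = small_sim_config(slippage_base_rate=0.0, snv_rate=2e-7)
        sequences, truth = generate_genome(cfg, seed=6)
        calls, _ = simulate_ma_lines(sequences, truth, cfg, seed=6)
        for _, r in calls.iterrows():
            assert sequences[r["chrom"]][r["pos"]] == r["ref"]
            assert r["alt"] != r["ref"]

    def test_deletion_bias_reproduced(self, small_ma_run):
        cfg, sequences, truth, calls, events = small_ma_run
        at = events[events["motif_class"] == "A/T"]
        frac = (at["sign"] == "deletion").mean()
        n = len(at)
        ci = sps.binomtest(int((at["sign"] == "deletion").sum()), n) \
            .proportion_ci(0.999)
        assert ci.low <= 0.93 <= ci.high

    def test_lengths_update_between_generations(self, small_ma_run):
        """Successive events at one locus in one lineage see updated lengths."""
        cfg, sequences, truth, calls, events = small_ma_run
        multi = events.groupby(["lineage_id", "locus_id"]).filter(
            lambda g: len(g) > 1).sort_values("generation")
        assert len(multi) > 0
        for (_, _), grp in multi.groupby(["lineage_id", "locus_id"]):
            lengths = grp["length_at_event"].tolist()
            units = grp["units"].tolist()
            for i in range(1, len(grp)):
                assert lengths[i] == lengths[i - 1] + units[i - 1]

    def test_deterministic_given_seed(self):
        cfg = small_sim_config()
        sequences, truth = generate_genome(cfg, seed=8)
        c1, e1 = simulate_ma_lines(sequences, truth, cfg, seed=8)
        c2, e2 = simulate_ma_lines(sequences, truth, cfg, seed=8)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(e1, e2)

    def test_vcf_net_matches_truth_event_sums(self, small_ma_run):
        cfg, sequences, truth, calls, events = small_ma_run
        net = events.groupby(["lineage_id", "locus_id"])["units"].sum()
        indels = calls[calls["ref"].str.len() != calls["alt"].str.len()]
        for (_, r) in indels.iterrows():
            want = net[(r["lineage_id"], r["locus_id"])]
            got = len(r["alt"]) - len(r["ref"])
            k = list(truth)[int(r["locus_id"])].unit_len
            assert got == want * k
        # loci with zero net change emit no record
        zero_net = net[net == 0]
        emitted = set(zip(indels["lineage_id"], indels["locus_id"]))
        assert all((l, i) not in emitted for (l, i) in zero_net.index)


class TestDetectionDropout:
    def _long_repeat_calls(self, seed=1):
        cfg = small_sim_config(
            repeat_spec=[("A", 16, 120), ("A", 5, 100)],
            genome_length=80_000, slippage_base_rate=2e-6,
            dropout_prob=0.5, snv_rate=0.0)
        sequences, truth = generate_genome(cfg, seed=seed)
        calls, events = simulate_ma_lines(sequences, truth, cfg, seed=seed)
        return cfg, calls

    def test_prob_zero_is_identity(self):
        cfg, calls = self._long_repeat_calls()
        cfg.dropout_prob = 0.0
        kept, dropped = apply_detection_dropout(calls, cfg, seed=2)
        assert len(kept) == len(calls) and dropped.empty

    def test_prob_one_removes_all_long_repeat_indels(self):
        cfg, calls = self._long_repeat_calls()
        cfg.dropout_prob = 1.0
        kept, dropped = apply_detection_dropout(calls, cfg, seed=2)
        assert (kept["ref_len_bp"] < cfg.dropout_len).all()
        assert (dropped["ref_len_bp"] >= cfg.dropout_len).all()

    def test_half_dropout_is_binomial(self):
        cfg, calls = self._long_repeat_calls()
        at_long = (calls["ref_len_bp"] >= cfg.dropout_len).sum()
        kept, dropped = apply_detection_dropout(calls, cfg, seed=2)
        assert at_long > 50
        lo, hi = sps.binom.ppf([0.001, 0.999], at_long, 0.5)
        assert lo <= len(dropped) <= hi

    def test_survivors_get_spanning_reads(self):
        cfg, calls = self._long_repeat_calls()
        kept, _ = apply_detection_dropout(calls, cfg, seed=2)
        indel = kept["ref"].str.len() != kept["alt"].str.len()
        assert (kept.loc[indel, "span_reads_sample"] >= 3).all()
        assert (kept.loc[indel, "span_reads_ancestor"] >= 3).all()
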