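import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mapipe.classify import MutationCall, classify_all
from mapipe.rates import (SpectrumTable,
                          chromosome_size_regression, coding_fraction,
                          fit_regimes, fold_induction, per_bp_rate,
                          per_repeat_rate_by_length, poisson_ci,
                          replication_timing_test, spectrum_table)
from mapipe.repeats import RepeatCensus, RepeatLocus
from mapipe.simulate import make_coding_intervals, make_timing_bins
from oracles import ols_r2_brute


class TestPerBpRate:
    def test_msh2_null_lineage_rate(self):
        est = per_bp_rate(147, n_lineages=1, generations=170,
                          callable_genome_bp=1.216e7)
        assert est.rate == pytest.approx(7.1e-8, rel=0.03)

    def test_pooled_substitution_rate(self):
        est = per_bp_rate(158, n_lineages=16, generations=170,
                          callable_genome_bp=1.216e7)
        assert est.rate == pytest.approx(4.8e-9, rel=0.03)

    def test_zero_events(self):
        est = per_bp_rate(0, 1, 170, 1e7)
        assert est.rate == 0 and est.ci_low == 0 and est.ci_high > 0

    def test_opportunity_linearity(self):
        a = per_bp_rate(10, 2, 100, 1e6)
        b = per_bp_rate(10, 4, 100, 5e5)
        assert a.rate == pytest.approx(b.rate)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            per_bp_rate(1, 0, 170, 1e7)

    def test_poisson_ci_brackets_rate(self):
        est = per_bp_rate(13, 16, 170, 1e6)
        assert est.ci_low <= est.rate <= est.ci_high
        # Garwood bounds against the chi-square quantile closed form
        lo, hi = poisson_ci(13)
        assert lo == pytest.approx(sps.chi2.ppf(0.025, 26) / 2)
        assert hi == pytest.approx(sps.chi2.ppf(0.975, 28) / 2)


class TestFoldInduction:
    def test_published_fold(self):
        assert round(fold_induction(7.1e-8, 3.3e-10)) == 215

    def test_identity_and_doubling(self):
        assert fold_induction(5e-9, 5e-9) == 1.0
        assert fold_induction(6.6e-10, 3.3e-10) == pytest.approx(2.0)


class TestSpectrumTable:
    def test_published_fractions(self):
        t = SpectrumTable.from_counts(2011, 161, 112, 46, 86, 60)
        assert t.total == 2476
        pcts = t.subtotal_percentages.round(1)
        assert pcts["homopolymer_indels"] == 87.7
        assert pcts["microsatellite_indels"] == 5.9
        assert t.percentages.round(1)["transitions"] == 4.5
        assert t.percentages.round(1)["transversions"] == 1.9

    def test_single_transition_is_all_of_the_spectrum(self):
        t = SpectrumTable.from_counts(0, 0, 1, 0, 0, 0)
        assert t.percentages["transitions"] == 100.0

    def test_from_classified_mutations(self, small_ma_run):
        from mapipe.io import calls_from_frame

        cfg, sequences, truth, calls, events = small_ma_run
        muts = classify_all(calls_from_frame(calls), truth, sequences,
                            flag_boundary_shifts=False)
        t = spectrum_table(muts)
        assigned = [m for m in muts
                    if m.kind == "indel" and m.repeat is not None]
        snvs = [m for m in muts if m.kind == "SNV"]
        assert t.subtotals["homopolymer_indels"] + \
            t.subtotals["microsatellite_indels"] == len(assigned)
        assert t.subtotals["substitutions"] == len(snvs)
        assert t.percentages.sum() == pytest.approx(100.0)


def _uniform_census(n, length, cls="A/T", unit="A"):
    return RepeatCensus([
        RepeatLocus("c", 100 * i, 100 * i + length, unit, cls)
        for i in range(n)])


class TestLengthRateCurve:
    def test_rate_arithmetic(self):
        ev = pd.Series({("A/T", 8): 1})
        census = _uniform_census(100, 8)
        curve = per_repeat_rate_by_length(ev, census, n_lineages=16,
                                          generations=170)
        row = curve.table.iloc[0]
        assert row["rate"] == pytest.approx(1 / (100 * 16 * 170))
        assert row["rate"] == pytest.approx(3.676e-6, rel=1e-3)

    def test_zero_events_at_censused_length(self):
        curve = per_repeat_rate_by_length(pd.Series(dtype=int),
                                          _uniform_census(10, 5), 16, 170)
        assert (curve.table["rate"] == 0).all()

    def test_events_without_census_is_an_error(self):
        ev = pd.Series({("A/T", 9): 2})
        with pytest.raises(ValueError, match="census"):
            per_repeat_rate_by_length(ev, _uniform_census(10, 5), 16, 170)

    def test_long_repeats_flagged_for_dropout(self):
        ev = pd.Series(dtype=int)
        census = RepeatCensus(
            [RepeatLocus("c", 0, 14, "A", "A/T"),
             RepeatLocus("c", 100, 114, "AT", "AT/TA"),
             RepeatLocus("c", 200, 205, "A", "A/T")])
        curve = per_repeat_rate_by_length(ev, census, 16, 170)
        t = curve.table.set_index(["motif_class", "length"])
        assert t.loc[("A/T", 14), "dropout_flag"].item()
        assert t.loc[("AT/TA", 7), "dropout_flag"].item()  # 7 units = 14 bp
        assert not t.loc[("A/T", 5), "dropout_flag"].item()

    def test_true_rate_recovered_within_poisson_ci(self, rng):
        # simulation oracle: Poisson events at a known per-repeat rate
        true_rate, n_rep, n_lin, g = 1e-5, 200, 16, 170
        ev_count = rng.poisson(true_rate * n_rep * n_lin * g)
        ev = pd.Series({("A/T", 8): ev_count})
        curve = per_repeat_rate_by_length(ev, _uniform_census(n_rep, 8),
                                          n_lin, g)
        row = curve.table.iloc[0]
        assert row["ci_low"] <= true_rate <= row["ci_high"]


class TestFitRegimes:
    def _curve(self, rates_by_length, census_n=100):
        rows = []
        for L, r in rates_by_length.items():
            rows.append({"motif_class": "A/T", "length": L,
                         "events": 1, "census": census_n, "rate": r,
                         "ci_low": 0, "ci_high": 1, "dropout_flag": False})
        from mapipe.rates import LengthRateCurve
        return LengthRateCurve(pd.DataFrame(rows), 16, 170)

    def test_exact_exponential_input(self):
        curve = self._curve({L: 1e-9 * 4 ** (L - 3) for L in range(3, 9)})
        fit_regimes(curve)
        assert curve.exp_fit["fold_per_unit"] == pytest.approx(4.0, abs=1e-9)
        assert curve.exp_fit["r2"] == pytest.approx(1.0)

    def test_exact_linear_input(self):
        curve = self._curve({L: 1e-4 * (L - 9) + 1e-5 for L in range(9, 14)})
        fit_regimes(curve)
        assert curve.lin_fit["slope"] == pytest.approx(1e-4)
        assert curve.lin_fit["r2"] == pytest.approx(1.0)

    def test_noisy_curve_recovers_fold_within_ten_percent(self, rng):
        true = {L: 1e-9 * 4 ** (L - 3) for L in range(3, 9)}
        noisy = {L: r * rng.lognormal(0, 0.1) for L, r in true.items()}
        curve = self._curve(noisy)
        fit_regimes(curve)
        assert curve.exp_fit["fold_per_unit"] == pytest.approx(4.0, rel=0.10)

    def test_insufficient_points_marked_unavailable(self):
        curve = self._curve({3: 1e-9, 4: 0.0, 5: 0.0, 6: 1e-8})
        fit_regimes(curve)
        assert curve.exp_fit is None
        assert curve.lin_fit is None
        curve2 = self._curve({3: 1e-9, 4: 1e-8, 5: 0.0, 6: 4e-8})
        fit_regimes(curve2)
        assert curve2.exp_fit["zero_rate_lengths_excluded"] == [5]


class TestGenomeWideDistribution:
    def test_counts_proportional_to_length_give_r2_one(self):
        lengths = {f"chr{i}": 100000 * (i + 1) for i in range(5)}
        chroms = sum(([c] * (l // 10000) for c, l in lengths.items()), [])
        df, r2 = chromosome_size_regression(chroms, lengths)
        assert r2 == pytest.approx(1.0)

    def test_all_mutations_on_one_of_equal_chromosomes(self):
        lengths = {f"chr{i}": 100000 for i in range(10)}
        chroms = ["chr0"] * 50
        df, r2 = chromosome_size_regression(chroms, lengths)
        # constant x: size explains no count variation by convention
        assert r2 == pytest.approx(0.0, abs=1e-9)

    def test_r2_matches_closed_form_ols(self, rng):
        lengths = {f"chr{i}": 100000 * (i + 1) for i in range(6)}
        chroms = list(rng.choice(list(lengths), size=300))
        df, r2 = chromosome_size_regression(chroms, lengths)
        assert r2 == pytest.approx(
            ols_r2_brute(df["length"], df["count"]), abs=1e-12)

    def test_uniform_simulation_r2_exceeds_0_7(self, rng):
        # 2500 mutations thrown uniformly over 16 yeast-like chromosomes
        lengths = {f"chr{i + 1}": int(l) for i, l in enumerate(
            np.linspace(2.3e5, 1.5e6, 16))}
        names = list(lengths)
        p = np.array(list(lengths.values()), float)
        p /= p.sum()
        chroms = rng.choice(names, size=2500, p=p)
        _, r2 = chromosome_size_regression(list(chroms), lengths)
        assert r2 > 0.7

    def test_minimum_chromosome_count(self):
        with pytest.raises(ValueError):
            chromosome_size_regression(["c1"], {"c1": 100, "c2": 100})


class TestReplicationTiming:
    def _bins(self, sizes):
        rows = []
        pos = 0
        for i, s in enumerate(sizes):
            rows.append({"chrom": "c", "start": pos, "end": pos + s, "bin": i})
            pos += s
        return pd.DataFrame(rows)

    def test_perfectly_proportional_counts(self):
        bins = self._bins([1000, 2000, 3000])
        pos = ([500] * 10 + [1500] * 20 + [4000] * 30)
        res = replication_timing_test(
            pd.DataFrame({"chrom": "c", "pos": pos}), bins)
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_two_equal_bins_closed_form(self):
        bins = self._bins([1000, 1000])
        pos = [10] * 30 + [1500] * 10
        res = replication_timing_test(
            pd.DataFrame({"chrom": "c", "pos": pos}), bins)
        assert res["chi2"] == pytest.approx(10.0)
        assert res["p"] == pytest.approx(0.00157, rel=0.01)

    def test_sparse_bins_merged(self):
        bins = self._bins([10000, 10000, 10])  # third bin expects << 1
        pos = [100] * 5 + [15000] * 5
        res = replication_timing_test(
            pd.DataFrame({"chrom": "c", "pos": pos}), bins)
        assert res["df"] == 1

    def test_p_values_uniform_under_the_null(self):
        """Calibration: uniform mutations over bins of equal size give a
        p-value distribution indistinguishable from U(0,1)."""
        rng = np.random.default_rng(99)
        lengths = {"c": 50_000}
        bins = make_timing_bins(lengths, n_bins=5)
        ps = []
        for _ in range(200):
            pos = rng.integers(0, 50_000, size=400)
            res = replication_timing_test(
                pd.DataFrame({"chrom": "c", "pos": pos}), bins)
            ps.append(res["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestCodingFraction:
    def _muts(self, positions, chrom="c"):
        return classify_all(
            [MutationCall("L1", chrom, p, "A", "G") for p in positions],
            RepeatCensus([]), {chrom: "A" * (max(positions) + 2)},
            flag_boundary_shifts=False)

    def test_all_inside(self):
        iv = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100]})
        res = coding_fraction(self._muts([5, 50, 99]), iv)
        assert res["SNV"] == 1.0

    def test_none_inside(self):
        iv = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]})
        res = coding_fraction(self._muts([50, 60]), iv)
        assert res["SNV"] == 0.0

    def test_binomial_expectation_on_synthetic_intervals(self):
        rng = np.random.default_rng(5)
        glen = 500_000
        iv = make_coding_intervals({"c": glen}, coding_fraction=0.74, seed=5)
        iv["end"] = iv["end"].clip(upper=glen)
        frac_bp = (iv["end"] - iv["start"]).sum() / glen
        pos = rng.integers(0, glen, size=5000)
        res = coding_fraction(self._muts(list(pos)), iv)
        assert res["SNV"] == pytest.approx(frac_bp, abs=0.02)
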