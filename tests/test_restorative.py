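import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import txefficacy as tx
from txefficacy.restorative import DesirabilityReport


def _stats_frame(rows):
    """rows: (gene_id, mean_h, mean_p, abs_t)"""
    return pd.DataFrame(
        {
            "gene_id": [r[0] for r in rows],
            "mean_a": [r[1] for r in rows],
            "mean_b": [r[2] for r in rows],
            "abs_t": [r[3] for r in rows],
            "degenerate": [False] * len(rows),
        }
    )


class TestDeltaRecords:
    def test_worked_single_gene_example(self):
        """A gene overexpressed in patients (95.4289 vs healthy 63.5434) that
        the drug pulls back to 82.7131: the distance gain is 12.7158 and the
        t-statistic gain 7.6575 - 3.8293 = 3.8282."""
        before = _stats_frame([("ARID3A", 63.5434, 95.4289, 7.6575)])
        after = _stats_frame([("ARID3A", 63.5434, 82.7131, 3.8293)])
        deltas = tx.delta_t_per_gene(before, after)
        row = deltas.iloc[0]
        assert row["delta_t"] == pytest.approx(3.8282, abs=1e-10)
        assert row["delta_d"] == pytest.approx(12.7158, abs=1e-10)

    def test_side_effect_gene_goes_negative(self):
        # expression near-identical to healthy before treatment but pushed
        # away after: delta_t = 0.00516 - 4.167737
        before = _stats_frame([("TTN", 81.53304, 81.38701, 0.00516)])
        after = _stats_frame([("TTN", 81.53304, 43.38747, 4.167737)])
        row = tx.delta_t_per_gene(before, after).iloc[0]
        assert row["delta_t"] == pytest.approx(-4.16258, abs=1e-5)

    def test_gene_universe_mismatch_rejected(self):
        a = _stats_frame([("G1", 1, 2, 0.5)])
        b = _stats_frame([("G2", 1, 2, 0.5)])
        with pytest.raises(ValueError, match="different genes"):
            tx.delta_t_per_gene(a, b)

    def test_inconsistent_healthy_means_rejected(self):
        a = _stats_frame([("G1", 1.0, 2, 0.5)])
        b = _stats_frame([("G1", 1.5, 2, 0.5)])
        with pytest.raises(ValueError, match="healthy"):
            tx.delta_t_per_gene(a, b)


def _deltas(dt, degenerate=None):
    n = len(dt)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(n)],
            "delta_t": np.asarray(dt, dtype=float),
            "degenerate": degenerate if degenerate is not None else [False] * n,
        }
    )


class TestDesirabilitySummary:
    def test_forced_arithmetic(self):
        rep = tx.desirability_summary(_deltas([1.0, -1.0, 2.0]))
        assert rep.i_dd == pytest.approx(2 / 3)
        assert rep.e_index == pytest.approx(1.0)
        assert rep.t_index == pytest.approx(-1 / 3)
        assert rep.i_dd == pytest.approx(rep.e_index + rep.t_index, abs=1e-10)
        assert (rep.n_positive, rep.n_negative, rep.n_zero) == (2, 1, 0)

    def test_all_zero_deltas(self):
        rep = tx.desirability_summary(_deltas([0.0, 0.0, 0.0]))
        assert rep.i_dd == rep.e_index == rep.t_index == 0.0
        assert rep.p == 1.0 and rep.n_zero == 3

    def test_degenerate_genes_leave_both_sums_and_denominator(self):
        rep = tx.desirability_summary(_deltas([1.0, 2.0, 99.0], [False, False, True]))
        assert rep.n_genes == 2 and rep.n_degenerate == 1
        assert rep.i_dd == pytest.approx(1.5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 300))
    def test_identity_and_count_invariants(self, seed, n):
        rng = np.random.default_rng(seed)
        dt = rng.standard_cauchy(n)  # heavy tails welcome
        rep = tx.desirability_summary(_deltas(dt))
        assert rep.i_dd == pytest.approx(rep.e_index + rep.t_index, abs=1e-10)
        assert rep.e_index >= 0 >= rep.t_index
        assert rep.n_positive + rep.n_negative + rep.n_zero == rep.n_genes

    def test_ci_and_test_match_quantile_oracle(self):
        rng = np.random.default_rng(99)
        dt = rng.normal(0.3, 1.1, 500)
        rep = tx.desirability_summary(_deltas(dt), alpha=0.05)
        sem = dt.std(ddof=1) / np.sqrt(len(dt))
        tcrit = sps.t.ppf(0.975, len(dt) - 1)
        assert rep.ci_low == pytest.approx(dt.mean() - tcrit * sem, rel=1e-12)
        assert rep.ci_high == pytest.approx(dt.mean() + tcrit * sem, rel=1e-12)
        ref = sps.ttest_1samp(dt, 0.0)
        assert rep.t_stat == pytest.approx(ref.statistic, rel=1e-12)
        assert rep.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tx.desirability_summary(_deltas([]))


class TestRanking:
    def test_worst_is_ascending_best_is_descending(self):
        d = _deltas([0.5, -2.0, 3.0])
        worst = tx.rank_genes_by_delta_t(d, "worst")
        best = tx.rank_genes_by_delta_t(d, "best")
        assert list(worst["delta_t"]) == [-2.0, 0.5, 3.0]
        assert list(best["delta_t"]) == [3.0, 0.5, -2.0]

    def test_single_gene_either_direction(self):
        d = _deltas([1.0])
        assert len(tx.rank_genes_by_delta_t(d, "worst")) == 1
        assert len(tx.rank_genes_by_delta_t(d, "best")) == 1


class TestEndToEnd:
    def test_swapping_before_after_negates_every_delta(self, restorative_sim):
        m, design, _ = restorative_sim
        swapped = tx.GroupDesign(
            {s: {"Pb": "Pa", "Pa": "Pb"}.get(r, r) for s, r in design.role_of_sample.items()}
        )
        res = tx.RestorativeModel(m, design).fit()
        res_sw = tx.RestorativeModel(m, swapped).fit()
        np.testing.assert_allclose(
            res_sw.deltas["delta_t"], -res.deltas["delta_t"], rtol=1e-12
        )
        assert res_sw.i_dd == pytest.approx(-res.i_dd, rel=1e-12)
        assert res_sw.e_index == pytest.approx(-res.t_index, rel=1e-12)
        assert res_sw.t_index == pytest.approx(-res.e_index, rel=1e-12)

    def test_geneset_restriction_is_a_plain_submatrix_path(self, restorative_sim):
        m, design, _ = restorative_sim
        subset = m.gene_ids[:50]
        res = tx.RestorativeModel(m, design, geneset=subset).fit()
        assert res.report.n_genes + res.report.n_degenerate == 50

    def test_null_drug_rejection_rate_near_alpha(self):
        """With a drug that does nothing (rho = 0, patients after treatment
        drawn identically to before), the one-sample test of I_DD = 0 should
        reject at close to the nominal 5% level."""
        reps, rej = 200, 0
        for seed in range(reps):
            spec = tx.RestorativeSimSpec(n_genes=3000, restoration_fraction=0.0, seed=seed)
            m, d, _ = tx.simulate_restorative(spec)
            res = tx.RestorativeModel(m.normalize_cpm().filter_low_expression(10), d).fit()
            rej += res.report.p < 0.05
        assert rej / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_full_restoration_detected(self):
        """rho = 1 with strong disease effects: I_DD significantly positive in
        >= 95% of 200 replicates."""
        hits = 0
        for seed in range(200):
            spec = tx.RestorativeSimSpec(
                n_genes=300, affected_fraction=0.3, effect_lfc_sd=2.0,
                restoration_fraction=1.0, seed=seed,
            )
            m, d, _ = tx.simulate_restorative(spec)
            res = tx.RestorativeModel(m.normalize_cpm().filter_low_expression(10), d).fit()
            hits += (res.report.p < 0.05) and (res.i_dd > 0)
        assert hits / 200 >= 0.95


def _report(i_dd, ci_low, ci_high, n=100, e=None, t=None):
    e = i_dd if e is None else e
    t = i_dd - e if t is None else t
    return DesirabilityReport(
        n_genes=n, n_positive=n, n_negative=0, n_zero=0, n_degenerate=0,
        i_dd=i_dd, e_index=e, t_index=t, se=0.01, ci_low=ci_low, ci_high=ci_high,
        t_stat=1.0, df=n - 1, p=0.5, alpha=0.05,
    )


class TestCompareDesirability:
    def test_clearly_better_second_experiment(self):
        r1 = _report(0.6093, 0.58073, 0.63781)
        r2 = _report(0.80, 0.70, 0.90)
        verdict = tx.compare_desirability(r1, r2)
        assert verdict.verdict == "2 more desirable"
        assert verdict.delta_i_dd == pytest.approx(0.80 - 0.6093)

    def test_identical_reports_indistinguishable(self):
        r = _report(0.5, 0.4, 0.6)
        assert tx.compare_desirability(r, r).verdict == "indistinguishable"

    def test_universe_mismatch_flagged_not_blocked(self):
        r1 = _report(0.5, 0.4, 0.6, n=100)
        r2 = _report(0.5, 0.4, 0.6, n=99)
        assert tx.compare_desirability(r1, r2).universes_differ

    def test_simulated_strong_vs_weak_restoration(self):
        """A rho = 0.9 drug is declared more desirable than a rho = 0.1 drug
        in >= 95% of 200 replicate pairs at 2000 genes."""
        wins = 0
        for seed in range(200):
            reports = []
            for rho, off in ((0.1, 10_000), (0.9, 20_000)):
                spec = tx.RestorativeSimSpec(
                    n_genes=2000, affected_fraction=0.3, restoration_fraction=rho,
                    seed=off + seed,
                )
                m, d, _ = tx.simulate_restorative(spec)
                reports.append(
                    tx.RestorativeModel(m.normalize_cpm().filter_low_expression(10), d)
                    .fit().report
                )
            wins += tx.compare_desirability(*reports).verdict == "2 more desirable"
        assert wins / 200 >= 0.95
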