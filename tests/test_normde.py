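"""TMM arithmetic, dispersion recovery, exact-test oracles, EV partition, motifs."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import cfmir as m
from cfmir.io import DataError
from cfmir.normde import equalize_lib_sizes

from conftest import make_count_matrix


def tmm_oracle(df: pd.DataFrame, ref: str, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Step-by-step weighted trimmed mean of M-values, written independently."""
    lib = df.sum().astype(float)
    out = {}
    for s in df.columns:
        obs_all = df[s].to_numpy(dtype=float)
        ref_all = df[ref].to_numpy(dtype=float)
        n_o, n_r = lib[s], lib[ref]
        keep = (obs_all > 0) & (ref_all > 0)
        obs, refv = obs_all[keep], ref_all[keep]
        m_vals = np.log2((obs / n_o) / (refv / n_r))
        a_vals = 0.5 * np.log2((obs / n_o) * (refv / n_r))
        weights = 1.0 / ((n_o - obs) / (n_o * obs) + (n_r - refv) / (n_r * refv))
        if np.max(np.abs(m_vals)) < 1e-6:
            out[s] = 1.0
            continue
        n = len(m_vals)
        lo_l, lo_s = int(np.floor(n * trim_m)) + 1, int(np.floor(n * trim_a)) + 1
        hi_l, hi_s = n + 1 - lo_l, n + 1 - lo_s
        rank_m = m_vals.argsort().argsort() + 1
        rank_a = a_vals.argsort().argsort() + 1
        sel = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
        out[s] = 2.0 ** (np.sum(m_vals[sel] * weights[sel]) / np.sum(weights[sel]))
    factors = pd.Series(out)
    return factors / np.exp(np.mean(np.log(factors)))


def conditional_p_oracle(z1: int, z2: int, n1: int, n2: int, phi: float) -> float:
    """Brute-force two-sided p from the conditional NB split distribution."""
    z = z1 + z2
    r = 1.0 / phi
    logpmf = np.array([
        gammaln(k + n1 * r) - gammaln(k + 1) - gammaln(n1 * r)
        + gammaln(z - k + n2 * r) - gammaln(z - k + 1) - gammaln(n2 * r)
        for k in range(z + 1)
    ])
    probs = np.exp(logpmf - logpmf.max())
    probs /= probs.sum()
    return float(min(1.0, probs[probs <= probs[z1] * (1 + 1e-10)].sum()))


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]})
        np.testing.assert_allclose(m.tmm_factors(df), 1.0)

    def test_pure_scaling_two_samples_is_removed_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, size=40) + 1
        df = pd.DataFrame({"a": a, "b": 2 * a})
        factors = m.tmm_factors(df)
        norm = m.cpm(df, factors)
        np.testing.assert_allclose(norm["a"], norm["b"], rtol=1e-9)

    def test_matches_independent_hand_computation(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.poisson(40, size=(10, 3)) + 1,
                          index=[f"g{i}" for i in range(10)], columns=["s0", "s1", "s2"])
        df.loc["g0", "s2"] = 900  # composition outlier to engage trimming
        ours = m.tmm_factors(df, ref_sample="s0")
        oracle = tmm_oracle(df, "s0")
        np.testing.assert_allclose(ours, oracle[ours.index], atol=1e-9)

    def test_matches_edger_calcnormfactors(self, tmp_path):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.negative_binomial(10, 0.05, size=(200, 6)),
                          index=[f"g{i}" for i in range(200)],
                          columns=[f"s{j}" for j in range(6)])
        df.iloc[0, 0] = 5000
        path = tmp_path / "counts.tsv"
        df.to_csv(path, sep="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.delim("{path}", row.names=1));'
            'cat(sprintf("%.12f", calcNormFactors(x, method="TMM")), sep=",")'
        )
        run = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert run.returncode == 0, run.stderr
        edger = np.array([float(v) for v in run.stdout.strip().split(",")])
        np.testing.assert_allclose(m.tmm_factors(df).to_numpy(), edger, atol=1e-9)

    def test_zero_total_sample_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(DataError, match="b"):
            m.tmm_factors(df)


class TestDispersion:
    def test_poisson_data_gives_near_zero(self):
        cfg = m.SimConfig(n_per_group=12, fractions=("WP",), n_mirna=2000, n_other_rna={},
                          composition={"WP": {"miRNA": 1.0}}, lib_size_mean=2e5,
                          dispersion=0.0, n_reference_candidates=0, seed=0)
        tables, _, _ = m.simulate_cohort(cfg)
        cm = tables["WP"]
        phi = m.estimate_common_dispersion(cm, cm.groups(), m.tmm_factors(cm))
        assert phi < 0.01

    @pytest.mark.parametrize("seed", range(4))
    def test_nb_dispersion_recovered(self, seed):
        cfg = m.SimConfig(n_per_group=12, fractions=("WP",), n_mirna=400, n_other_rna={},
                          composition={"WP": {"miRNA": 1.0}}, lib_size_mean=1e5,
                          dispersion=0.2, n_reference_candidates=0, seed=seed)
        tables, _, _ = m.simulate_cohort(cfg)
        cm = tables["WP"]
        phi = m.estimate_common_dispersion(cm, cm.groups(), m.tmm_factors(cm))
        assert 0.15 <= phi <= 0.25

    def test_duplicated_columns_give_zero(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(30, size=50)
        df = pd.DataFrame({"a1": col, "a2": col, "b1": col * 2 // 2, "b2": col})
        groups = pd.Series(["A", "A", "B", "B"], index=df.columns)
        phi = m.estimate_common_dispersion(df, groups, pd.Series(1.0, index=df.columns))
        assert phi == 0.0

    def test_single_sample_group_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        groups = pd.Series(["A", "A", "B"], index=df.columns)
        with pytest.raises(DataError):
            m.estimate_common_dispersion(df, groups, pd.Series(1.0, index=df.columns))


class TestExactTest:
    @staticmethod
    def _two_sample_table(counts_a, counts_b, other):
        df = pd.DataFrame({"a": [counts_a, other[0]], "b": [counts_b, other[1]]},
                          index=["target", "filler"])
        groups = pd.Series(["A", "B"], index=df.columns)
        return df, groups, pd.Series(1.0, index=df.columns)

    def test_balanced_split_gives_p_one(self):
        df, groups, fac = self._two_sample_table(5, 5, (10, 10))
        res = m.nb_exact_test(df, groups, fac, dispersion=0.0)
        assert res.loc["target", "p_value"] == pytest.approx(1.0, abs=1e-12)

    def test_poisson_limit_reduces_to_binomial(self):
        # 0 vs 10 at equal sizes: two-sided binomial mass = 2 * 0.5^10
        df, groups, fac = self._two_sample_table(0, 10, (15, 5))
        res = m.nb_exact_test(df, groups, fac, dispersion=0.0)
        assert res.loc["target", "p_value"] == pytest.approx(2 * 0.5**10, abs=1e-12)

    def test_matches_enumeration_oracle_for_small_totals(self):
        rng = np.random.default_rng(2)
        cols = {f"s{j}": rng.multinomial(15, np.ones(8) / 8) for j in range(6)}
        df = pd.DataFrame(cols, index=[f"g{i}" for i in range(8)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=df.columns)
        fac = pd.Series(1.0, index=df.columns)
        res = m.nb_exact_test(df, groups, fac, dispersion=0.1)
        for feat in df.index:
            z1 = int(df.loc[feat, groups.index[groups == "B"]].sum())
            z2 = int(df.loc[feat, groups.index[groups == "A"]].sum())
            assert res.loc[feat, "p_value"] == pytest.approx(
                conditional_p_oracle(z1, z2, 3, 3, 0.1), abs=1e-10)

    def test_group_label_swap_symmetry(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.negative_binomial(5, 0.1, size=(30, 8)),
                          columns=[f"s{j}" for j in range(8)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=df.columns)
        fac = m.tmm_factors(df)
        fwd = m.nb_exact_test(df, groups, fac, 0.1, numerator="B", denominator="A")
        rev = m.nb_exact_test(df, groups, fac, 0.1, numerator="A", denominator="B")
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], atol=1e-12)
        np.testing.assert_allclose(fwd["fold_change"] * rev["fold_change"], 1.0, rtol=1e-9)

    def test_scaling_one_sample_is_nearly_invariant(self):
        # weighted TMM is only asymptotically scale-invariant: precision weights
        # shift with absolute counts, so require stability, not exact equality
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.negative_binomial(5, 0.05, size=(100, 8)),
                          columns=[f"s{j}" for j in range(8)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=df.columns)
        res1 = m.nb_exact_test(df, groups, m.tmm_factors(df), 0.1)
        df2 = df.copy()
        df2["s0"] *= 3
        res2 = m.nb_exact_test(df2, groups, m.tmm_factors(df2), 0.1)
        assert np.abs(res1["p_value"] - res2["p_value"]).max() < 0.05
        assert np.abs(res1["fold_change"] / res2["fold_change"] - 1).max() < 0.01

    def test_all_zero_feature_flagged(self):
        df = pd.DataFrame({"a": [0, 5], "b": [0, 6], "c": [0, 7], "d": [0, 8]})
        groups = pd.Series(["A", "A", "B", "B"], index=df.columns)
        res = m.nb_exact_test(df, groups, pd.Series(1.0, index=df.columns), 0.1)
        row = res.iloc[0]
        assert row["all_zero"] and row["p_value"] == 1.0 and row["fold_change"] == 1.0


class TestCallDE:
    @pytest.mark.parametrize("p,fc,expect_called,expect_dir", [
        (0.049, 1.51, True, "up"),
        (0.049, 1.49, False, "up"),
        (0.051, 3.00, False, "up"),
        (0.049, 1 / 1.51, True, "down"),
    ])
    def test_cutoff_boundaries(self, p, fc, expect_called, expect_dir):
        res = pd.DataFrame({"fold_change": [fc], "p_value": [p]}, index=["f"])
        annotated, up, down = m.call_de(res, p_cutoff=0.05, fc_cutoff=1.5)
        assert bool(annotated.loc["f", "called"]) is expect_called
        assert annotated.loc["f", "direction"] == expect_dir
        assert ("f" in (up if expect_dir == "up" else down)) is expect_called


class TestEVPartition:
    def test_identical_tables_yield_empty_sets(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(40, size=(30, 6))
        ev = make_count_matrix(counts, fraction="EV")
        evd = make_count_matrix(counts, fraction="EVD",
                                samples=[f"t{j}" for j in range(6)])
        enriched, under, _ = m.ev_partition(ev, evd)
        assert enriched == set() and under == set()

    def test_swapping_fractions_swaps_sets(self):
        rng = np.random.default_rng(6)
        a = make_count_matrix(rng.negative_binomial(5, 0.05, size=(50, 6)), fraction="EV")
        b = make_count_matrix(rng.negative_binomial(5, 0.04, size=(50, 6)), fraction="EVD",
                              samples=[f"t{j}" for j in range(6)])
        enr, under, _ = m.ev_partition(a, b)
        enr2, under2, _ = m.ev_partition(b, a)
        assert enr == under2 and under == enr2

    def test_planted_ev_excess_recovered(self):
        rng = np.random.default_rng(8)
        base = rng.lognormal(3.5, 0.8, size=200)
        phi = 0.05
        r = 1 / phi

        def draw(mean, cols):
            return np.column_stack([
                rng.negative_binomial(r, r / (r + mean)) for _ in range(cols)])

        ev_mean = base.copy()
        ev_mean[:20] *= 4.0  # planted 4-fold EV excess
        ev = make_count_matrix(draw(ev_mean, 12), fraction="EV",
                               samples=[f"e{j}" for j in range(12)])
        evd = make_count_matrix(draw(base, 12), fraction="EVD",
                                samples=[f"d{j}" for j in range(12)])
        enriched, _, _ = m.ev_partition(ev, evd)
        planted = {f"f{i}" for i in range(20)}
        assert len(enriched & planted) >= 18

    def test_disjoint_feature_sets_rejected(self):
        a = make_count_matrix([[1, 2]], features=["x"])
        b = make_count_matrix([[1, 2]], features=["y"])
        with pytest.raises(DataError):
            m.ev_partition(a, b)


class TestMotifScan:
    def test_suffix_and_window_modes(self):
        seqs = pd.Series({"hit": "UGAGGUAGGAG", "fiveprime": "GGAGUUUUUUU",
                          "dna": "TGAGGTAGGAG", "ggcu": "AAAAAAAAGGCU"})
        suffix = m.motif_scan(seqs, ["hit", "fiveprime", "dna", "ggcu"], mode="suffix")
        assert bool(suffix.per_feature.loc["hit", "has_GGAG"])
        assert not suffix.per_feature.loc["fiveprime", "hit"]
        assert bool(suffix.per_feature.loc["dna", "has_GGAG"])  # T -> U conversion
        assert bool(suffix.per_feature.loc["ggcu", "has_GGCU"])
        window = m.motif_scan(seqs, ["fiveprime"], mode="window", window_nt=6)
        assert not window.per_feature.loc["fiveprime", "hit"]

    def test_planted_fraction_recovered_exactly(self):
        seqs = m.simulate_sequences(100, 0.25, seed=3)
        report = m.motif_scan(seqs, list(seqs.index), mode="suffix")
        assert report.n_hits == 25

    def test_missing_sequence_warned_and_counted(self):
        seqs = pd.Series({"a": "AAAAGGAG"})
        with pytest.warns(UserWarning, match="without sequences"):
            report = m.motif_scan(seqs, ["a", "b"])
        assert report.n_missing == 1 and report.n_scanned == 1


def test_equalization_is_identity_at_equal_library_sizes():
    rng = np.random.default_rng(9)
    cols = {f"s{j}": rng.multinomial(200, np.ones(20) / 20) for j in range(6)}
    df = pd.DataFrame(cols)
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=df.columns)
    pseudo, common = equalize_lib_sizes(df, groups, df.sum().astype(float), 0.1)
    assert common == pytest.approx(200.0)
    np.testing.assert_allclose(pseudo.to_numpy(), df.to_numpy(), atol=1e-8)
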