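import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import f as f_dist
from scipy.stats import ttest_ind

from congenic.diffexpr import (
    ValidationError,
    contrast_fs,
    fdr_adjust,
    fit_cell_means,
    genotype_contrasts,
    permutation_pvalues,
    present_filter,
    quantile_normalize,
    select_de_genes,
    shrink_variances,
    summarize_beads,
)


def canonical_samples(n_rep=4, strain="HG2D"):
    rows = []
    for tissue in "BFL":
        for genotype in "BC":
            for r in range(1, n_rep + 1):
                rows.append(
                    {
                        "sample_id": f"{strain}.{tissue}{genotype}{r}",
                        "strain": strain,
                        "genotype": genotype,
                        "tissue": tissue,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


class TestSummarizeBeads:
    def test_constant_vector(self):
        assert summarize_beads([5, 5, 5, 5]) == (5.0, 0.0, 4)

    def test_gross_outlier_removed(self):
        mean, var, n = summarize_beads([10, 10, 10, 10, 10, 1000])
        assert (mean, n) == (10.0, 5)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_beads([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e4), min_size=2, max_size=40), st.booleans())
    def test_survivors_match_bruteforce_filter(self, values, scaled):
        med = float(np.median(values))
        mad = float(np.median([abs(v - med) for v in values]))
        if scaled:
            mad *= 1.4826
        keep = [v for v in values if abs(v - med) <= 3 * mad]
        if not keep:
            with pytest.raises(ValidationError):
                summarize_beads(values, scaled=scaled)
            return
        mean, var, n = summarize_beads(values, scaled=scaled)
        assert n == len(keep)
        assert mean == pytest.approx(np.mean(keep))
        expected_var = np.var(keep, ddof=1) if len(keep) > 1 else 0.0
        assert var == pytest.approx(expected_var)


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        m = pd.DataFrame({"a": [1.0, 3.0, 2.0], "b": [1.0, 3.0, 2.0]})
        assert np.allclose(quantile_normalize(m), m)

    def test_two_by_two_hand_computation(self):
        m = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = quantile_normalize(m)
        assert np.allclose(out["a"], [1.5, 3.5])
        assert np.allclose(out["b"], [1.5, 3.5])

    def test_all_columns_share_sorted_vector(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(50, 6)) + rng.normal(size=6))
        out = quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(30, 4)))
        out = quantile_normalize(m).to_numpy()
        for j in range(4):
            assert (np.argsort(out[:, j]) == np.argsort(m.to_numpy()[:, j])).all()

    def test_ties_get_mean_of_reference_values(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)  # [1.5, 2.5, 5.5]
        assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_single_column_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0]})
        assert quantile_normalize(m).equals(m)


class TestPresentFilter:
    def test_retained_and_dropped(self):
        samples = canonical_samples()
        det = pd.DataFrame(1.0, index=["p1", "p2"], columns=samples.index)
        liver = samples.index[samples["tissue"] == "L"][:4]
        det.loc["p1", liver] = 0.001
        det.loc["p2", liver[:3]] = 0.001  # only 3 qualifying samples
        mask = present_filter(det, samples)
        assert mask.loc["p1", "L"] and mask.loc["p1", "any"]
        assert not mask.loc["p2", "any"]

    def test_counts_match_bruteforce_tally(self):
        rng = np.random.default_rng(2)
        samples = canonical_samples()
        det = pd.DataFrame(
            rng.uniform(size=(100, len(samples))) * 0.05,
            index=[f"p{i}" for i in range(100)],
            columns=samples.index,
        )
        mask = present_filter(det, samples)
        for t in "BFL":
            cols = samples.index[samples["tissue"] == t]
            brute = (det[cols] < 0.01).sum(axis=1) >= 4
            assert (mask[t] == brute).all()

    def test_out_of_range_detection_rejected(self):
        samples = canonical_samples()
        det = pd.DataFrame(2.0, index=["p"], columns=samples.index)
        with pytest.raises(ValidationError):
            present_filter(det, samples)


class TestCellMeansFit:
    def test_canonical_design_df(self):
        samples = canonical_samples()
        rng = np.random.default_rng(3)
        m = pd.DataFrame(
            rng.normal(size=(10, 24)), columns=samples.index
        )
        groups = samples["tissue"] + "." + samples["genotype"]
        fit = fit_cell_means(m, groups)
        assert fit.df == 18
        assert sorted(fit.groups) == ["B.B", "B.C", "F.B", "F.C", "L.B", "L.C"]

    def test_identical_values_zero_residual(self):
        m = pd.DataFrame([[2.0, 2.0, 7.0, 7.0]], columns=list("abcd"))
        fit = fit_cell_means(m, ["g1", "g1", "g2", "g2"])
        assert fit.resid_var[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.group_means.loc[0, "g1"] == 2.0
        assert fit.group_means.loc[0, "g2"] == 7.0

    def test_matches_groupwise_average_oracle(self):
        rng = np.random.default_rng(4)
        samples = canonical_samples()
        m = pd.DataFrame(
            rng.normal(size=(20, 24)), columns=samples.index
        )
        groups = samples["tissue"] + "." + samples["genotype"]
        fit = fit_cell_means(m, groups)
        for g in fit.groups:
            cols = groups.index[groups == g]
            assert np.allclose(fit.group_means[g], m[cols].mean(axis=1))
        resid = m.copy()
        for g in fit.groups:
            cols = groups.index[groups == g]
            resid[cols] = m[cols].sub(m[cols].mean(axis=1), axis=0)
        assert np.allclose(fit.resid_var, (resid**2).sum(axis=1) / 18)


class TestShrinkVariances:
    def test_equal_inputs_unchanged(self):
        out = shrink_variances(np.full(10, 0.7), df=18)
        assert np.allclose(out, 0.7)

    def test_matches_james_stein_formula(self):
        rng = np.random.default_rng(5)
        s2 = rng.chisquare(18, size=200) / 18
        df = 18
        x = np.log(s2)
        from scipy.special import polygamma

        V = polygamma(1, df / 2)
        B = max(0.0, 1.0 - (len(x) - 3) * V / ((x - x.mean()) ** 2).sum())
        expected = np.exp(x.mean() + B * (x - x.mean()))
        assert np.allclose(shrink_variances(s2, df), expected)

    def test_monotone_in_input(self):
        rng = np.random.default_rng(6)
        s2 = np.sort(rng.chisquare(10, size=50) / 10)
        out = shrink_variances(s2, df=10)
        assert (np.diff(out) >= -1e-12).all()

    def test_zero_variance_floored(self):
        s2 = np.array([0.0, 0.5, 0.5, 0.5, 0.5])
        out = shrink_variances(s2, df=18)
        assert np.isfinite(out).all() and (out > 0).all()


class TestContrastFs:
    def test_zero_group_difference_gives_zero_fs(self):
        samples = canonical_samples()
        # values depend on tissue only, so every genotype contrast is null
        tissue_value = {"B": 1.0, "F": 2.0, "L": 3.0}
        vals = [tissue_value[t] for t in samples["tissue"]]
        m = pd.DataFrame([vals] * 5, columns=samples.index)
        groups = samples["tissue"] + "." + samples["genotype"]
        fit = fit_cell_means(m, groups)
        c = genotype_contrasts(fit.groups)["L.Geno"]
        fs = contrast_fs(fit, np.ones(5), c)
        assert np.allclose(fs, 0.0)

    def test_unshrunk_equals_squared_pooled_t(self):
        """On a two-group design the 1-df F equals the squared pooled-variance t."""
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(30, 8)), columns=[f"s{i}" for i in range(8)])
        groups = ["g1"] * 4 + ["g2"] * 4
        fit = fit_cell_means(m, groups)
        fs = contrast_fs(fit, fit.resid_var, np.array([1.0, -1.0]))
        x, y = m.iloc[:, :4].to_numpy(), m.iloc[:, 4:].to_numpy()
        t = ttest_ind(x, y, axis=1).statistic
        assert np.allclose(fs, t**2)

    def test_increases_with_effect_size(self):
        samples = canonical_samples()
        groups = samples["tissue"] + "." + samples["genotype"]
        rng = np.random.default_rng(8)
        base = rng.normal(size=24)
        rows = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            row = base.copy()
            row[(groups == "L.C").to_numpy()] += delta
            rows.append(row)
        m = pd.DataFrame(rows, columns=samples.index)
        fit = fit_cell_means(m, groups)
        c = genotype_contrasts(fit.groups)["L.Geno"]
        fs = contrast_fs(fit, np.full(4, 1.0), c)
        assert (np.diff(fs) > 0).all()

    def test_nonzero_sum_contrast_rejected(self):
        samples = canonical_samples()
        m = pd.DataFrame(np.zeros((2, 24)), columns=samples.index)
        fit = fit_cell_means(m, samples["tissue"] + "." + samples["genotype"])
        with pytest.raises(ValidationError):
            contrast_fs(fit, fit.resid_var, np.array([1.0, 0, 0, 0, 0, 0]))

    def test_shrinkage_disabled_recovers_classical_f(self):
        """Passing the raw residual variances gives the textbook 1-df F."""
        rng = np.random.default_rng(9)
        samples = canonical_samples()
        groups = samples["tissue"] + "." + samples["genotype"]
        m = pd.DataFrame(rng.normal(size=(40, 24)), columns=samples.index)
        fit = fit_cell_means(m, groups)
        c = genotype_contrasts(fit.groups)["B.Geno"]
        fs = contrast_fs(fit, fit.resid_var, c)
        # classical F for a 1-df contrast: (c.mu)^2 / (s2 * sum c^2/n)
        mu = fit.group_means.to_numpy()
        classical = (mu @ c) ** 2 / (fit.resid_var * (c**2 / 4).sum())
        assert np.allclose(fs, classical)
        # sanity: under the null it is F(1, 18)-distributed
        p = 1 - f_dist.cdf(fs, 1, 18)
        assert 0.3 < p.mean() < 0.7


class TestPermutationPvalues:
    def _data(self, seed=0, n_probes=60):
        rng = np.random.default_rng(seed)
        samples = canonical_samples()
        m = pd.DataFrame(
            rng.normal(size=(n_probes, 24)),
            index=[f"p{i}" for i in range(n_probes)],
            columns=samples.index,
        )
        return m, samples

    def test_identical_seed_bit_identical(self):
        m, samples = self._data()
        _, p1 = permutation_pvalues(m, samples, n_perm=30, seed=5)
        _, p2 = permutation_pvalues(m, samples, n_perm=30, seed=5)
        assert p1.equals(p2)

    def test_max_fs_attains_min_p(self):
        m, samples = self._data(seed=1)
        m.iloc[0, (samples["tissue"] == "L").to_numpy() & (samples["genotype"] == "C").to_numpy()] += 10
        fs, p = permutation_pvalues(m, samples, n_perm=40, seed=2)
        assert fs["L.Geno"].idxmax() == "p0"
        assert p.loc["p0", "L.Geno"] == p["L.Geno"].min()

    def test_warns_when_permutations_exhausted(self, caplog):
        rows = []
        for genotype in "BC":
            for r in range(2):
                rows.append(
                    {
                        "sample_id": f"x.B{genotype}{r}",
                        "strain": "x",
                        "genotype": genotype,
                        "tissue": "B",
                        "replicate": r,
                    }
                )
        samples = pd.DataFrame(rows).set_index("sample_id")
        m = pd.DataFrame(
            np.random.default_rng(0).normal(size=(10, 4)), columns=samples.index
        )
        with caplog.at_level("WARNING"):
            permutation_pvalues(m, samples, n_perm=50, seed=0)
        assert any("replacement" in r.message for r in caplog.records)


class TestFdrAdjust:
    def test_single_p(self):
        assert fdr_adjust(np.array([0.04]))[0] == pytest.approx(0.04)

    def test_hand_bh_computation(self):
        assert np.allclose(fdr_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(10)
        p = np.sort(rng.uniform(size=100))
        q = fdr_adjust(p)
        assert (np.diff(q) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            fdr_adjust(np.array([0.0, 0.5]))


class TestSelectDeGenes:
    def test_single_probe_selected_in_one_tissue(self):
        q = pd.DataFrame({"B.Geno": [0.5], "L.Geno": [0.05]}, index=["p1"])
        sel, genes = select_de_genes(q, {"p1": "g1"})
        assert sel["p1"] and genes == {"g1"}

    def test_gene_with_no_qualifying_probe(self):
        q = pd.DataFrame({"B.Geno": [0.2, 0.99]}, index=["p1", "p2"])
        _, genes = select_de_genes(q, {"p1": "g1", "p2": "g1"})
        assert genes == set()

    def test_unmapped_probe_excluded_from_gene_counts(self, caplog):
        q = pd.DataFrame({"B.Geno": [0.01]}, index=["p1"])
        with caplog.at_level("WARNING"):
            sel, genes = select_de_genes(q, {})
        assert sel["p1"] and genes == set()

    def test_counts_match_bruteforce_scan(self):
        rng = np.random.default_rng(11)
        probes = [f"p{i}" for i in range(200)]
        q = pd.DataFrame(
            rng.uniform(size=(200, 3)), index=probes, columns=["B.Geno", "F.Geno", "L.Geno"]
        )
        mapping = {p: f"g{i % 60}" for i, p in enumerate(probes)}
        sel, genes = select_de_genes(q, mapping, threshold=0.10)
        brute = {
            mapping[p]
            for p in probes
            if any(q.loc[p, c] < 0.10 for c in q.columns)
        }
        assert genes == brute
        assert sel.sum() == sum(
            any(q.loc[p, c] < 0.10 for c in q.columns) for p in probes
        )
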