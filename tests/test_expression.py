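"""Filtering, TMM normalization and the NB-GLM Wald engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import epicohort as ec
from epicohort import expression
from epicohort.enrichment import bh_adjust


def counts_frame(rows, prefix="s"):
    arr = np.atleast_2d(np.asarray(rows))
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestFilterLowCounts:
    def test_high_everywhere_kept_all_zero_removed(self):
        counts = counts_frame([[20, 30, 40, 50, 60, 70],
                               [0, 0, 0, 0, 0, 0]])
        kept = expression.filter_low_counts(counts)
        assert list(kept.index) == ["g0"]

    def test_half_of_samples_boundary(self):
        counts = counts_frame([[12, 11, 10, 0, 0, 0],
                               [12, 11, 9, 0, 0, 0]])
        kept = expression.filter_low_counts(counts)
        assert list(kept.index) == ["g0"]

    def test_odd_sample_count_uses_ceiling(self):
        # 5 samples: need >= 3 samples at >= 10
        counts = counts_frame([[10, 10, 10, 0, 0], [10, 10, 0, 0, 0]])
        kept = expression.filter_low_counts(counts)
        assert list(kept.index) == ["g0"]

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            expression.filter_low_counts(counts_frame(np.zeros((0, 4))))


class TestTMM:
    def test_identical_libraries_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, size=50)
        counts = counts_frame(np.column_stack([col] * 4))
        f = expression.tmm_factors(counts)
        assert f.tmm == pytest.approx(np.ones(4))

    def test_pure_depth_change_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        col = rng.integers(10, 500, size=80)
        counts = counts_frame(np.column_stack([col, col * 2, col * 4]))
        f = expression.tmm_factors(counts)
        assert f.tmm == pytest.approx(np.ones(3), abs=1e-8)

    def test_factor_product_is_one(self, small_bundle):
        f = expression.tmm_factors(
            expression.filter_low_counts(small_bundle.counts))
        assert np.prod(f.tmm) == pytest.approx(1.0, abs=1e-8)

    def test_gene_permutation_invariance(self, small_bundle):
        counts = expression.filter_low_counts(small_bundle.counts)
        f1 = expression.tmm_factors(counts)
        shuffled = counts.sample(frac=1.0, random_state=9)
        f2 = expression.tmm_factors(shuffled)
        assert f1.tmm == pytest.approx(f2.tmm)

    def test_composition_shift_matches_hand_oracle(self):
        """20-gene toy, half the genes doubled in sample 2: factors equal an
        independent spreadsheet-style evaluation of the weighted-mean-M
        formula."""
        rng = np.random.default_rng(42)
        base = rng.integers(50, 400, size=20)
        s2 = base.copy()
        s2[:10] = s2[:10] * 2
        counts = counts_frame(np.column_stack([base, s2]))
        got = expression.tmm_factors(counts, trim_m=0.30, trim_a=0.05)

        # --- independent hand computation -------------------------------
        y = counts.to_numpy(float)
        lib = y.sum(axis=0)
        uq = np.array([np.quantile(c[c > 0], 0.75) for c in y.T]) / lib
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        other = 1 - ref
        pk, pr = y[:, other] / lib[other], y[:, ref] / lib[ref]
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        n = len(m)
        keep_m = np.zeros(n, bool)
        order_m = np.lexsort((a, m))  # tie rule: secondary sort on A
        lo = int(np.floor(n * 0.30))
        keep_m[order_m[lo:n - lo]] = True
        keep_a = np.zeros(n, bool)
        order_a = np.lexsort((m, a))
        la = int(np.floor(n * 0.05))
        keep_a[order_a[la:n - la]] = True
        keep = keep_m & keep_a
        w = ((lib[other] - y[:, other]) / (lib[other] * y[:, other])
             + (lib[ref] - y[:, ref]) / (lib[ref] * y[:, ref]))
        f_other = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
        f = np.ones(2)
        f[other] = f_other
        f = f / np.exp(np.mean(np.log(f)))
        assert got.tmm == pytest.approx(f)

    def test_zero_library_errors(self):
        counts = counts_frame([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="zero library"):
            expression.tmm_factors(counts)


class TestNormalize:
    def test_zero_count_maps_to_zero(self):
        counts = counts_frame([[0, 0], [100, 100]])
        out = expression.normalize(counts, expression.tmm_factors(counts))
        assert out.loc["g0"].tolist() == [0.0, 0.0]

    def test_unit_case_count_equal_to_effective_size_per_million(self):
        counts = counts_frame([[5, 5], [999_995, 999_995]])
        f = expression.tmm_factors(counts)
        # effective size = 1e6, so cpm of count 1 is 1 -> log2(2) = 1
        out = expression.normalize(counts_frame([[1, 1], [0, 0]]), f)
        assert out.loc["g0"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_monotone_in_counts_within_sample(self):
        rng = np.random.default_rng(3)
        counts = counts_frame(rng.integers(0, 1000, size=(30, 4)))
        out = expression.normalize(counts, expression.tmm_factors(counts))
        for j in range(4):
            order = np.argsort(counts.iloc[:, j].to_numpy(), kind="stable")
            assert (np.diff(out.iloc[order, j].to_numpy()) >= -1e-12).all()


class TestContrastPlan:
    def test_default_design_yields_12_contrasts(self, small_bundle):
        plan = expression.plan_contrasts(small_bundle.metadata)
        assert len(plan) == 12
        assert sum(c.kind == "temporal" for c in plan) == 8
        assert sum(c.kind == "tissue" for c in plan) == 4

    def test_stratification_subset_is_8(self, small_bundle):
        plan = expression.plan_contrasts(small_bundle.metadata)
        strat = [c for c in plan if c.stratification]
        assert len(strat) == 8
        # default: 4 tissue + 4 anterior-temporal
        kinds = {(c.kind, c.tissues) for c in strat}
        assert (("temporal", ("FB", "MB")) in {(c.kind, c.tissues)
                                               for c in strat})
        assert all(c.tissues != ("HB", "SC") for c in strat
                   if c.kind == "temporal")

    def test_alternative_stratification_set(self, small_bundle):
        plan = expression.plan_contrasts(
            small_bundle.metadata, stratification_set="anterior+posterior")
        strat = [c for c in plan if c.stratification]
        assert len(strat) == 8
        assert all(c.kind == "temporal" for c in strat)

    def test_tissue_contrasts_omit_earliest_stage(self, small_bundle):
        plan = expression.plan_contrasts(small_bundle.metadata)
        for c in plan:
            if c.kind == "tissue":
                assert "E11.5" not in c.stages

    def test_missing_tissue_names_absent_cells(self, small_bundle):
        meta = small_bundle.metadata
        broken = meta[meta["tissue"] != "SC"]
        with pytest.raises(ValueError, match="SC"):
            expression.plan_contrasts(broken)


class TestNBWald:
    design_3v3 = pd.DataFrame({"intercept": 1.0,
                               "condition": [0, 0, 0, 1, 1, 1]})

    def test_constant_gene_has_near_zero_lfc(self):
        counts = counts_frame([[100] * 6, [40, 50, 60, 45, 55, 50]])
        res = expression.nb_wald_test(counts, self.design_3v3, "condition",
                                      offset=np.zeros(6))
        assert abs(res.loc["g0", "log2fc"]) < 0.01

    def test_all_zero_gene_flagged_p_one(self):
        counts = counts_frame([[0] * 6, [40, 50, 60, 45, 55, 50]])
        res = expression.nb_wald_test(counts, self.design_3v3, "condition",
                                      offset=np.zeros(6))
        assert res.loc["g0", "p"] == 1.0
        assert res.loc["g0", "log2fc"] == 0.0
        assert bool(res.loc["g0", "all_zero"])

    def test_singular_design_errors(self):
        counts = counts_frame([[10] * 6])
        bad = self.design_3v3.assign(dup=self.design_3v3["condition"])
        with pytest.raises(ValueError, match="singular"):
            expression.nb_wald_test(counts, bad, "condition",
                                    offset=np.zeros(6))

    def test_padj_at_least_p(self, small_pipeline):
        for res in small_pipeline["de"].values():
            t = res.table
            assert (t["padj"] >= t["p"] - 1e-12).all()
            assert t["padj"].between(0, 1).all()

    def test_bh_within_engine_matches_bh_adjust(self):
        rng = np.random.default_rng(8)
        counts = counts_frame(rng.integers(0, 300, size=(50, 6)))
        res = expression.nb_wald_test(counts, self.design_3v3, "condition",
                                      offset=np.zeros(6))
        assert res["padj"].to_numpy() == pytest.approx(
            bh_adjust(res["p"].to_numpy()))

    def test_recovers_planted_effect_direction(self):
        rng = np.random.default_rng(4)
        n = 1 / 0.05
        mu = np.full((30, 6), 100.0)
        mu[:, 3:] *= 2 ** 1.5
        y = rng.negative_binomial(n, n / (n + mu))
        res = expression.nb_wald_test(counts_frame(y), self.design_3v3,
                                      "condition", offset=np.zeros(6))
        assert (res["log2fc"] > 0).mean() >= 0.95
        assert res["log2fc"].mean() == pytest.approx(1.5, abs=0.3)


class TestLog2FCBias:
    def test_estimator_unbiased_at_moderate_mean(self):
        """Mean log2FC over 50 planted genes x 10 seeds within +/- 0.1 of
        the planted value at mu = 100, 3v3."""
        design = TestNBWald.design_3v3
        n = 1 / 0.1
        means = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            mu = np.full((50, 6), 100.0)
            mu[:, 3:] *= 2.0  # planted log2FC = 1
            y = rng.negative_binomial(n, n / (n + mu))
            res = expression.nb_wald_test(counts_frame(y), design,
                                          "condition", offset=np.zeros(6))
            means.append(res["log2fc"].mean())
        assert np.mean(means) == pytest.approx(1.0, abs=0.1)


class TestImportDETables:
    def make_table(self, path, **overrides):
        df = pd.DataFrame({
            "gene": ["g0", "g1"], "log2FoldChange": [1.5, -0.2],
            "pvalue": [0.001, 0.8], "padj": [0.01, 0.9]})
        for k, v in overrides.items():
            df[k] = v
        df.to_csv(path, sep="\t", index=False)
        return path

    def test_pass_through_preserves_lfc(self, tmp_path):
        p = self.make_table(tmp_path / "t.tsv")
        out = expression.import_de_tables({"tissue_FB": p})
        assert out["tissue_FB"].table["log2fc"].tolist() == [1.5, -0.2]

    def test_na_padj_not_significant(self, tmp_path):
        p = self.make_table(tmp_path / "t.tsv", padj=[np.nan, 0.9])
        out = expression.import_de_tables({"c": p})
        assert len(out["c"].significant()) == 0

    def test_missing_column_schema_error(self, tmp_path):
        df = pd.DataFrame({"gene": ["g0"], "log2FoldChange": [1.0]})
        df.to_csv(tmp_path / "bad.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="missing required columns"):
            expression.import_de_tables({"c": tmp_path / "bad.tsv"})

    def test_unmatched_contrast_names_error(self, tmp_path):
        p = self.make_table(tmp_path / "t.tsv")
        with pytest.raises(ValueError, match="unmatched"):
            expression.import_de_tables({"weird": p},
                                        contrast_names=["tissue_FB"])
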