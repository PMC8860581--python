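"""Six-category gene labelling and the ectopic-expression survey."""

import itertools

import numpy as np
import pandas as pd
import pytest

import epicohort as ec
from epicohort import stratification
from epicohort.expression import DEResult


def fake_de(genes, n_sig_map, n_large_map, n_contrasts=8):
    """Build n contrasts where gene g is significant in its first
    n_sig_map[g] contrasts and has |log2fc| > 1 in its first
    n_large_map[g]."""
    results = {}
    for i in range(n_contrasts):
        table = pd.DataFrame({
            "log2fc": [2.0 if i < n_large_map[g] else 0.1 for g in genes],
            "p": [0.001 if i < n_sig_map[g] else 0.9 for g in genes],
            "padj": [0.01 if i < n_sig_map[g] else 0.95 for g in genes],
        }, index=pd.Index(genes, name="gene_id"))
        results[f"c{i}"] = DEResult(f"c{i}", table)
    return results


def uniform_cpm(genes, value, metadata):
    return pd.DataFrame(value, index=pd.Index(genes, name="gene_id"),
                        columns=metadata["sample_id"])


@pytest.fixture(scope="module")
def meta():
    return ec.synthetic._sample_grid(2)


class TestResponseLabels:
    def test_truth_table_over_boolean_grid(self, meta):
        """Exhaustive combinations of (expressed, #significant, #large-lfc)
        match an independently evaluated truth table."""
        combos = list(itertools.product([0.1, 5.0], range(0, 9, 2),
                                        range(0, 9, 2)))
        genes = [f"g{i}" for i in range(len(combos))]
        cpm = pd.DataFrame(
            {s: [c[0] for c in combos] for s in meta["sample_id"]},
            index=pd.Index(genes, name="gene_id"))
        de = fake_de(genes, {g: c[1] for g, c in zip(genes, combos)},
                     {g: c[2] for g, c in zip(genes, combos)})
        got = stratification.label_expression_response(de, cpm, meta)
        for g, (expr_val, n_sig, n_large) in zip(genes, combos):
            expressed = expr_val > 0.5
            if expressed and n_sig >= 1 and n_large >= 3:
                want = "consistently_affected"
            elif expressed and n_sig >= 1:
                want = "partly_affected"
            else:
                want = "unaffected"
            assert got[g] == want, (g, expr_val, n_sig, n_large)

    def test_one_significant_two_large_is_partly(self, meta):
        genes = ["g"]
        de = fake_de(genes, {"g": 1}, {"g": 2})
        got = stratification.label_expression_response(
            de, uniform_cpm(genes, 5.0, meta), meta)
        assert got["g"] == "partly_affected"

    def test_three_large_is_consistent(self, meta):
        genes = ["g"]
        de = fake_de(genes, {"g": 1}, {"g": 3})
        got = stratification.label_expression_response(
            de, uniform_cpm(genes, 5.0, meta), meta)
        assert got["g"] == "consistently_affected"

    def test_expression_gate_dominates_significance(self, meta):
        genes = ["g"]
        de = fake_de(genes, {"g": 8}, {"g": 8})
        got = stratification.label_expression_response(
            de, uniform_cpm(genes, 0.1, meta), meta)
        assert got["g"] == "unaffected"

    def test_wrong_contrast_count_errors(self, meta):
        genes = ["g"]
        de = fake_de(genes, {"g": 0}, {"g": 0}, n_contrasts=7)
        with pytest.raises(ValueError, match="8"):
            stratification.label_expression_response(
                de, uniform_cpm(genes, 5.0, meta), meta)

    def test_categories_partition_genes(self, small_pipeline):
        p = small_pipeline
        strat_names = [c.name for c in p["contrasts"] if c.stratification]
        resp = stratification.label_expression_response(
            {n: p["de"][n] for n in strat_names}, p["cpm"],
            p["bundle"].metadata)
        assert set(resp.unique()) <= set(stratification.RESPONSES)
        assert len(resp) == len(p["cpm"])


class TestMarkedLabel:
    def test_peak_in_single_tissue_is_marked(self):
        sig = pd.DataFrame({"FB": [3.0, 0.0], "MB": [0.0, 0.0],
                            "HB": [0.0, 0.0]}, index=["a", "b"])
        got = stratification.label_marked(sig)
        assert got["a"] == "marked" and got["b"] == "unmarked"

    def test_missing_tissue_column_errors(self):
        sig = pd.DataFrame({"FB": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="missing"):
            stratification.label_marked(sig)

    def test_window_boundary_2600bp_unmarked(self):
        """A peak 2600 bp upstream of the TSS falls outside the symmetric
        2.5 kb window, so the gene's reference signal is zero."""
        genes = pd.DataFrame([{"gene_id": "g", "chrom": "chr1",
                               "start": 10_000, "end": 15_000,
                               "strand": "+"}])
        peaks = pd.DataFrame(
            [("chr1", 7300, 7400, "p", 0, ".", 5.0, 6.0, 5.0, -1)],
            columns=ec.io.NARROWPEAK_COLUMNS)
        col = ec.assign_peaks_to_genes(peaks, genes,
                                       window_preset="tss_symmetric")
        sig = pd.DataFrame({"FB": col["signal"], "MB": 0.0, "HB": 0.0})
        assert stratification.label_marked(sig)["g"] == "unmarked"

    def test_six_categories_exclusive_and_exhaustive(self, small_pipeline):
        p = small_pipeline
        strat_names = [c.name for c in p["contrasts"] if c.stratification]
        resp = stratification.label_expression_response(
            {n: p["de"][n] for n in strat_names}, p["cpm"],
            p["bundle"].metadata)
        rng = np.random.default_rng(0)
        marked = pd.Series(
            rng.choice(["marked", "unmarked"], size=len(resp)),
            index=resp.index)
        out = stratification.stratify(resp, marked)
        assert out["category"].notna().all()
        assert out["category"].nunique() <= 6
        assert len(out) == len(resp)


class TestEctopicSurvey:
    def test_wt_silent_ko_active_included(self, meta):
        genes = ["g"]
        cpm = uniform_cpm(genes, 0.0, meta)
        ko_fb = [s for s in cpm.columns if s.startswith("KO_FB_E11.5")]
        cpm.loc["g", ko_fb] = 1.2
        got = stratification.survey_ectopic(cpm, meta)
        assert "g" in got

    def test_any_wt_group_expression_excludes(self, meta):
        genes = ["g"]
        cpm = uniform_cpm(genes, 0.0, meta)
        wt_sc = [s for s in cpm.columns if s.startswith("WT_SC_E18.5")]
        ko = [s for s in cpm.columns if s.startswith("KO_")]
        cpm.loc["g", wt_sc] = 0.6
        cpm.loc["g", ko] = 5.0
        got = stratification.survey_ectopic(cpm, meta)
        assert "g" not in got

    def test_matches_groupby_mean_oracle(self, meta):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(60)]
        cpm = pd.DataFrame(
            rng.exponential(0.5, size=(60, len(meta))),
            index=pd.Index(genes, name="gene_id"),
            columns=meta["sample_id"])
        got = set(stratification.survey_ectopic(cpm, meta))
        expected = set()
        m = meta.set_index("sample_id")
        for g in genes:
            wt_ok, ko_ok = True, False
            for tissue in ["FB", "MB", "HB", "SC"]:
                for stage in ["E11.5", "E13.5", "E15.5", "E18.5"]:
                    wt_cols = [s for s in cpm.columns
                               if m.loc[s, "genotype"] == "WT"
                               and m.loc[s, "tissue"] == tissue
                               and m.loc[s, "stage"] == stage]
                    ko_cols = [s for s in cpm.columns
                               if m.loc[s, "genotype"] == "KO"
                               and m.loc[s, "tissue"] == tissue
                               and m.loc[s, "stage"] == stage]
                    if cpm.loc[g, wt_cols].mean() >= 0.5:
                        wt_ok = False
                    if cpm.loc[g, ko_cols].mean() >= 0.5:
                        ko_ok = True
            if wt_ok and ko_ok:
                expected.add(g)
        assert got == expected


def test_archetypes_recovered_in_expected_categories(small_pipeline):
    """Planted archetypes land in their expected response x mark category
    (diagonal-dominant confusion): marked archetypes in
    consistently_affected|marked, unmarked affected archetypes in
    consistently_affected|unmarked."""
    p = small_pipeline
    b = p["bundle"]
    strat_names = [c.name for c in p["contrasts"] if c.stratification]
    resp = stratification.label_expression_response(
        {n: p["de"][n] for n in strat_names}, p["cpm"], b.metadata)
    ref = {}
    for tissue in stratification.MARK_REFERENCE_TISSUES:
        key = ("H3K27me3", tissue, stratification.MARK_REFERENCE_STAGE)
        ref[tissue] = ec.assign_peaks_to_genes(
            b.peaks[key], b.gene_models,
            window_preset="tss_symmetric")["signal"]
    marked = stratification.label_marked(pd.DataFrame(ref)
                                         .reindex(resp.index).fillna(0.0))
    out = stratification.stratify(resp, marked)
    arch = b.truth["archetype"].reindex(out.index)
    for a, want in [("posterior", "consistently_affected|marked"),
                    ("anterior", "consistently_affected|marked"),
                    ("development", "consistently_affected|marked"),
                    ("proliferation", "consistently_affected|unmarked"),
                    ("immune", "consistently_affected|unmarked")]:
        frac = (out.loc[arch == a, "category"] == want).mean()
        assert frac >= 0.7, (a, want, frac)
    # background mostly not consistently affected
    bg = out.loc[arch == "background", "response"]
    assert (bg != "consistently_affected").mean() >= 0.9
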