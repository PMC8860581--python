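"""Stratified gene labelling: expression response x repressive-mark status.

Each gene receives one of three response labels (unaffected, partly_affected,
consistently_affected) from eight designated KO-vs-WT contrasts, and a
marked/unmarked flag from H3K27me3 peak presence near the TSS in the
reference brain tissues, giving six exclusive categories. The module also
runs the ectopic-expression survey for genes silent in every WT group but
activated in the knockout.
"""

from __future__ import annotations

import pandas as pd

from .expression import (EXPRESSED_CPM, PADJ_SIGNIFICANT, Contrast, DEResult)

RESPONSES = ("unaffected", "partly_affected", "consistently_affected")
MARK_REFERENCE_TISSUES = ("FB", "MB", "HB")
MARK_REFERENCE_STAGE = "E16.5"
CONSISTENT_LFC = 1.0
CONSISTENT_MIN_CONTRASTS = 3
N_STRATIFICATION_CONTRASTS = 8


def stratification_contrasts(contrasts: list[Contrast]) -> list[Contrast]:
    chosen = [c for c in contrasts if c.stratification]
    if len(chosen) != N_STRATIFICATION_CONTRASTS:
        raise ValueError(
            f"expected {N_STRATIFICATION_CONTRASTS} stratification "
            f"contrasts, found {len(chosen)}")
    return chosen


def label_expression_response(de_results: dict[str, DEResult],
                              cpm: pd.DataFrame, metadata: pd.DataFrame,
                              expressed_cpm: float = EXPRESSED_CPM,
                              padj_alpha: float = PADJ_SIGNIFICANT,
                              lfc_threshold: float = CONSISTENT_LFC,
                              min_contrasts: int = CONSISTENT_MIN_CONTRASTS
                              ) -> pd.Series:
    """Response label per gene from the eight stratification contrasts.

    A gene is *expressed* when its mean TMM-scaled CPM over all WT samples or
    over all KO samples exceeds ``expressed_cpm``; *partly_affected* when
    expressed and significant (padj <= alpha) in at least one contrast;
    *consistently_affected* when additionally |log2FC| > ``lfc_threshold`` in
    at least ``min_contrasts`` of the eight.
    """
    if len(de_results) != N_STRATIFICATION_CONTRASTS:
        raise ValueError(
            f"need exactly {N_STRATIFICATION_CONTRASTS} contrasts, got "
            f"{len(de_results)}: {sorted(de_results)}")
    meta = metadata.set_index("sample_id").loc[cpm.columns]
    genes = cpm.index
    wt_mean = cpm.loc[:, (meta["genotype"] == "WT").to_numpy()].mean(axis=1)
    ko_mean = cpm.loc[:, (meta["genotype"] == "KO").to_numpy()].mean(axis=1)
    expressed = (wt_mean > expressed_cpm) | (ko_mean > expressed_cpm)

    n_sig = pd.Series(0, index=genes)
    n_large = pd.Series(0, index=genes)
    for res in de_results.values():
        t = res.table.reindex(genes)
        n_sig += (t["padj"].fillna(1.0) <= padj_alpha).astype(int)
        n_large += (t["log2fc"].fillna(0.0).abs() > lfc_threshold).astype(int)

    partly = expressed & (n_sig >= 1)
    consistent = partly & (n_large >= min_contrasts)
    out = pd.Series("unaffected", index=genes, name="response")
    out[partly] = "partly_affected"
    out[consistent] = "consistently_affected"
    return out


def label_marked(mark_signals: pd.DataFrame,
                 tissues: tuple[str, ...] = MARK_REFERENCE_TISSUES
                 ) -> pd.Series:
    """Marked flag: any positive H3K27me3 signal in the reference tissues.

    ``mark_signals`` is indexed by gene with one column per reference tissue
    (signals computed with the symmetric TSS +/- 2.5 kb window preset).
    """
    missing = [t for t in tissues if t not in mark_signals.columns]
    if missing:
        raise ValueError(f"mark signal columns missing: {missing}")
    marked = (mark_signals[list(tissues)] > 0).any(axis=1)
    return marked.map({True: "marked", False: "unmarked"}).rename("marked")


def stratify(response: pd.Series, marked: pd.Series) -> pd.DataFrame:
    """Combine the two labellings into the six exclusive categories."""
    df = pd.concat([response, marked], axis=1, join="inner")
    df.columns = ["response", "marked"]
    df["category"] = df["response"] + "|" + df["marked"]
    return df


def survey_ectopic(cpm: pd.DataFrame, metadata: pd.DataFrame,
                   threshold: float = EXPRESSED_CPM) -> pd.Index:
    """Genes silent in every WT (tissue, stage) group but reaching the
    expression threshold in at least one KO group (group = per-tissue,
    per-stage mean of TMM-scaled CPM)."""
    meta = metadata.set_index("sample_id").loc[cpm.columns]
    group = meta["genotype"] + "|" + meta["tissue"] + "|" + meta["stage"]
    means = cpm.T.groupby(group.to_numpy()).mean().T
    wt_cols = [c for c in means.columns if c.startswith("WT|")]
    ko_cols = [c for c in means.columns if c.startswith("KO|")]
    silent_wt = (means[wt_cols] < threshold).all(axis=1)
    active_ko = (means[ko_cols] >= threshold).any(axis=1)
    return cpm.index[silent_wt & active_ko]
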