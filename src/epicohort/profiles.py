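"""Per-gene multi-omic profile assembly and min-max scaling.

A profile row concatenates three feature blocks for one gene:

``expression``
    the normalised transcriptome, one column per RNA-seq sample, ordered by
    (genotype WT-then-KO, tissue anterior to posterior, stage, replicate);
``mark``
    log2(H3K27me3 signal + 1), one column per ChIP (tissue, stage) cell;
``lfc``
    the KO-vs-WT log2 fold changes, one column per planned contrast.

Under the default study design this yields 64 + 21 + 12 = 97 features. All
columns are min-max scaled to [0, 1] over the gene subset being embedded;
constant columns map to 0 and scaling parameters are retained for the
inverse transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import DEResult, STAGES, TISSUES

BLOCKS = ("expression", "mark", "lfc")
GENOTYPE_ORDER = ("WT", "KO")


@dataclass
class ProfileMatrix:
    """Genes x features matrix with named feature blocks."""
    data: pd.DataFrame
    blocks: dict[str, list[str]]
    scale_params: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def is_scaled(self) -> bool:
        return self.scale_params is not None

    def block(self, name: str) -> pd.DataFrame:
        return self.data[self.blocks[name]]


def assemble_profiles(norm: pd.DataFrame, metadata: pd.DataFrame,
                      mark_signals: pd.DataFrame,
                      de_results: dict[str, DEResult],
                      gene_subset: pd.Index | list[str]) -> ProfileMatrix:
    """Build the unscaled profile matrix for ``gene_subset``.

    Parameters
    ----------
    norm
        log2(TMM CPM + 1) matrix, genes x samples.
    mark_signals
        genes x ChIP cells; columns are (tissue, stage) tuples or
        "tissue_stage" strings, raw (untransformed) peak signal.
    de_results
        contrast name -> DEResult, in contrast-plan order.
    """
    genes = pd.Index(gene_subset)
    missing = genes.difference(norm.index)
    for res in de_results.values():
        missing = missing.union(genes.difference(res.table.index))
    missing = missing.union(genes.difference(mark_signals.index))
    if len(missing):
        raise ValueError(f"genes missing from inputs: {sorted(missing)[:10]}"
                         f" ({len(missing)} total)")

    meta = (metadata.set_index("sample_id").loc[norm.columns]
            .rename_axis("sample_id").reset_index())
    order = meta.sort_values(
        by=["genotype", "tissue", "stage", "replicate"],
        key=lambda col: (col.map({g: i for i, g in enumerate(GENOTYPE_ORDER)})
                         if col.name == "genotype" else
                         col.map({t: i for i, t in enumerate(TISSUES)})
                         if col.name == "tissue" else col),
        kind="stable")["sample_id"].tolist()
    expr = norm.loc[genes, order]
    expr.columns = [f"expression|{c}" for c in expr.columns]

    def _cell_key(col):
        tissue, stage = col if isinstance(col, tuple) else str(col).rsplit(
            "_", 1)
        t = TISSUES.index(tissue) if tissue in TISSUES else len(TISSUES)
        return (t, stage)

    mark_cols = sorted(mark_signals.columns, key=_cell_key)
    mark = np.log2(mark_signals.loc[genes, mark_cols].to_numpy(float) + 1.0)
    mark_names = [c if isinstance(c, str) else f"{c[0]}_{c[1]}"
                  for c in mark_cols]
    mark = pd.DataFrame(mark, index=genes,
                        columns=[f"mark|{n}" for n in mark_names])

    lfc = pd.DataFrame(
        {f"lfc|{name}": res.table["log2fc"].reindex(genes)
         for name, res in de_results.items()}, index=genes)

    data = pd.concat([expr, mark, lfc], axis=1)
    if data.isna().any().any():
        bad = data.columns[data.isna().any()].tolist()
        raise ValueError(f"missing values in profile columns: {bad[:5]}")
    blocks = {"expression": list(expr.columns), "mark": list(mark.columns),
              "lfc": list(lfc.columns)}
    return ProfileMatrix(data.sort_index(), blocks)


def scale_features(profiles: ProfileMatrix) -> ProfileMatrix:
    """Min-max scale every column to [0, 1]; idempotent on scaled data."""
    x = profiles.data.to_numpy(dtype=float)
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    scaled = (x - lo) / safe
    scaled[:, span == 0] = 0.0
    params = pd.DataFrame({"min": lo, "max": hi},
                          index=profiles.data.columns)
    return ProfileMatrix(
        pd.DataFrame(scaled, index=profiles.data.index,
                     columns=profiles.data.columns),
        dict(profiles.blocks), params)


def inverse_transform(profiles: ProfileMatrix) -> pd.DataFrame:
    """Map a scaled matrix back to the original feature units."""
    if profiles.scale_params is None:
        raise ValueError("profile matrix carries no scaling parameters")
    lo = profiles.scale_params["min"].to_numpy()
    hi = profiles.scale_params["max"].to_numpy()
    x = profiles.data.to_numpy(dtype=float) * (hi - lo) + lo
    return pd.DataFrame(x, index=profiles.data.index,
                        columns=profiles.data.columns)


def mark_signal_wide(signal_tables: dict[tuple[str, str, str], pd.DataFrame]
                     ) -> pd.DataFrame:
    """Pivot per-(mark, tissue, stage) gene signal tables into one wide
    genes x "tissue_stage" frame (signal columns only)."""
    cols = {}
    for (mark, tissue, stage), table in sorted(signal_tables.items()):
        cols[f"{tissue}_{stage}"] = table["signal"]
    return pd.DataFrame(cols)
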