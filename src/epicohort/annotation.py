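"""Assignment of ChIP-seq peaks and chromatin-state segments to genes.

Genes are modelled on 0-based half-open coordinates with the TSS at ``start``
on the + strand and at ``end - 1`` on the - strand. A peak is assigned to a
gene when its interval intersects the gene's strand-oriented assignment
window; among several assigned peaks the one with the greatest signal is
retained (ties broken by smallest peak start), and genes with no assignment
carry signal 0 and width 0.

Window presets
--------------
``promoter_body``
    2.5 kb upstream of the TSS through 500 bp past the gene end (the default
    assignment rule for most histone marks).
``tss_symmetric``
    the symmetric +/-2.5 kb window around the TSS, used when calling a gene
    "marked" in the stratified analysis.
``gene_body``
    the gene body plus 500 bp past the gene end; the default override for
    H3K36me3, whose signal lies over transcribed regions.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: -log10 q-value threshold: peaks with adjusted P >= 0.05 are discarded.
Q_NEGLOG10_MIN = -math.log10(0.05)

WINDOW_PRESETS = ("promoter_body", "tss_symmetric", "gene_body")

#: Per-mark window override; marks not listed use ``promoter_body``.
DEFAULT_MARK_WINDOWS = {"H3K36me3": "gene_body"}

#: Label for genes whose TSS overlaps no chromatin-state segment.
NO_STATE = "NS"


def gene_tss(genes: pd.DataFrame) -> np.ndarray:
    """TSS coordinate per gene: start on +, end-1 on -."""
    return np.where(genes["strand"].to_numpy() == "+",
                    genes["start"].to_numpy(), genes["end"].to_numpy() - 1)


def assignment_windows(genes: pd.DataFrame, preset: str = "promoter_body",
                       upstream: int = 2500, downstream: int = 500
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Half-open [win_start, win_end) assignment window per gene.

    ``upstream``/``downstream`` are measured in the gene's transcriptional
    orientation; windows are clipped at zero.
    """
    if preset not in WINDOW_PRESETS:
        raise ValueError(f"unknown window preset {preset!r}; "
                         f"choose from {WINDOW_PRESETS}")
    start = genes["start"].to_numpy()
    end = genes["end"].to_numpy()
    plus = genes["strand"].to_numpy() == "+"
    tss = gene_tss(genes)
    if preset == "promoter_body":
        lo = np.where(plus, tss - upstream, start - downstream)
        hi = np.where(plus, end + downstream, tss + upstream + 1)
    elif preset == "tss_symmetric":
        lo = tss - upstream
        hi = tss + upstream
    else:  # gene_body
        lo = np.where(plus, start, start - downstream)
        hi = np.where(plus, end + downstream, end)
    return np.maximum(lo, 0), np.maximum(hi, 1)


def filter_peaks_by_q(peaks: pd.DataFrame) -> pd.DataFrame:
    """Drop peaks whose adjusted P-value is >= 0.05.

    ``qValue`` holds -log10(q); a missing value (-1 by NarrowPeak convention)
    fails the filter.
    """
    q = peaks["qValue"].to_numpy(dtype=float)
    return peaks.loc[q > Q_NEGLOG10_MIN]


def assign_peaks_to_genes(peaks: pd.DataFrame, genes: pd.DataFrame,
                          mark: str = "H3K27me3",
                          window_preset: str | None = None,
                          upstream: int = 2500, downstream: int = 500,
                          apply_q_filter: bool = True) -> pd.DataFrame:
    """Assign NarrowPeak records to genes; one (signal, width) row per gene.

    Parameters
    ----------
    peaks
        NarrowPeak frame (``io.read_narrowpeak`` schema).
    genes
        Gene models with gene_id, chrom, start, end, strand.
    mark
        Histone mark name; selects the window preset via
        ``DEFAULT_MARK_WINDOWS`` unless ``window_preset`` is given.
    window_preset
        Explicit preset overriding the per-mark table.

    Returns
    -------
    DataFrame indexed by gene_id with ``signal`` and ``width`` columns;
    unassigned genes have (0.0, 0).
    """
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_ids in gene models")
    preset = window_preset or DEFAULT_MARK_WINDOWS.get(mark, "promoter_body")
    if apply_q_filter:
        peaks = filter_peaks_by_q(peaks)

    lo, hi = assignment_windows(genes, preset, upstream, downstream)
    trees: dict[str, IntervalTree] = {}
    for i, chrom in enumerate(genes["chrom"]):
        trees.setdefault(chrom, IntervalTree()).addi(int(lo[i]), int(hi[i]), i)

    n = len(genes)
    best_signal = np.zeros(n)
    best_width = np.zeros(n, dtype=int)
    best_start = np.full(n, np.iinfo(np.int64).max)
    has_peak = np.zeros(n, dtype=bool)
    n_unassigned_chrom = 0
    for p in peaks.itertuples(index=False):
        tree = trees.get(p.chrom)
        if tree is None:
            n_unassigned_chrom += 1
            continue
        for iv in tree.overlap(p.start, p.end):
            g = iv.data
            better = (not has_peak[g]
                      or p.signalValue > best_signal[g]
                      or (p.signalValue == best_signal[g]
                          and p.start < best_start[g]))
            if better:
                has_peak[g] = True
                best_signal[g] = p.signalValue
                best_width[g] = p.end - p.start
                best_start[g] = p.start
    if n_unassigned_chrom:
        logger.info("%d peaks on chromosomes with no genes were unassigned",
                    n_unassigned_chrom)
    return pd.DataFrame({"signal": best_signal, "width": best_width},
                        index=pd.Index(genes["gene_id"], name="gene_id"))


def assign_chromatin_states(segments: pd.DataFrame, genes: pd.DataFrame,
                            flank: int = 10) -> pd.Series:
    """Assign each gene the chromatin state overlapping its TSS (+/- flank bp).

    With several overlapping segments the first in file order wins; genes
    with none are labelled ``NS``.
    """
    trees: dict[str, IntervalTree] = {}
    for seg in segments.itertuples(index=False):
        trees.setdefault(seg.chrom, IntervalTree()).addi(
            seg.start, seg.end, (seg.file_order, seg.state))
    tss = gene_tss(genes)
    out = []
    for i, g in enumerate(genes.itertuples(index=False)):
        tree = trees.get(g.chrom)
        hits = tree.overlap(tss[i] - flank, tss[i] + flank + 1) if tree else ()
        if hits:
            out.append(min(iv.data for iv in hits)[1])
        else:
            out.append(NO_STATE)
    return pd.Series(out, index=pd.Index(genes["gene_id"], name="gene_id"),
                     name="state")
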