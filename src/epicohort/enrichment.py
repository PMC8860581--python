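"""Enrichment and group-comparison statistics.

Fisher's exact test for category enrichment between a foreground and a
background gene set, hypergeometric over-representation analysis against
user-supplied gene sets (GMT semantics), Benjamini-Hochberg adjustment, and
Mann-Whitney U comparisons with Bonferroni correction and the conventional
significance star bins.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BH_ALPHA = 0.1
#: (upper p bound, label); evaluated in order.
STAR_BINS = [(0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"),
             (1.0, "NS")]


def star_bin(p: float) -> str:
    """Map a p-value to its significance annotation."""
    for bound, label in STAR_BINS:
        if p <= bound:
            return label
    return "NS"


def bh_adjust(p: np.ndarray | list[float], m: int | None = None
              ) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, clipped
    to [0, 1]. ``m`` defaults to the number of p-values; a larger ``m``
    accounts for tests not present in the vector.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def _odds_ratio(a: int, b: int, c: int, d: int,
                haldane: bool = False) -> float:
    """Sample odds ratio ad/bc; with zero cells returns inf/0/nan unless the
    Haldane 0.5 correction is requested."""
    if haldane and (0 in (a, b, c, d)):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def fisher_enrichment(foreground: set[str], background: set[str],
                      categories: pd.Series, alpha: float = BH_ALPHA,
                      alternative: str = "two-sided",
                      haldane: bool = False) -> pd.DataFrame:
    """Per-category Fisher exact enrichment of foreground vs background.

    The 2x2 table for a category compares the foreground against the rest of
    the background: [[|fg & cat|, |fg - cat|], [|rest & cat|, |rest - cat|]].
    P-values are BH-adjusted across categories; ``reject`` flags padj <=
    alpha. Categories absent from the background are omitted with a warning.
    """
    foreground = set(foreground)
    background = set(background)
    if not foreground:
        raise ValueError("empty foreground")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    rest = background - foreground
    cat_of = categories.to_dict()
    labels = sorted({v for g, v in cat_of.items() if g in background})

    rows = []
    for label in labels:
        members = {g for g in background if cat_of.get(g) == label}
        if not members:
            logger.warning("category %r absent from background; omitted",
                           label)
            continue
        a = len(foreground & members)
        b = len(foreground) - a
        c = len(rest & members)
        d = len(rest) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        rows.append({"category": label, "fg_in": a, "fg_out": b,
                     "bg_in": a + c, "bg_out": b + d,
                     "odds_ratio": _odds_ratio(a, b, c, d, haldane),
                     "p": float(p)})
    table = pd.DataFrame(rows)
    if len(table):
        table["padj"] = bh_adjust(table["p"].to_numpy())
        table["reject"] = table["padj"] <= alpha
    return table


def ora(cohort: set[str], universe: set[str],
        gene_sets: dict[str, set[str]], alpha: float = BH_ALPHA
        ) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a cohort in each set.

    Identical machinery to :func:`fisher_enrichment` with a "greater"
    alternative; one row per gene set, BH-adjusted, sorted by p.
    """
    cohort = set(cohort)
    universe = set(universe)
    if not gene_sets:
        raise ValueError("empty gene-set collection")
    if not cohort <= universe:
        raise ValueError("cohort must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        inset = members & universe
        if not inset:
            logger.warning("gene set %r has no members in universe; omitted",
                           name)
            continue
        a = len(cohort & inset)
        b = len(cohort) - a
        c = len(inset) - a
        d = len(universe) - len(cohort) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"set": name, "overlap": a, "cohort_size": len(cohort),
                     "set_size": len(inset), "universe": len(universe),
                     "odds_ratio": _odds_ratio(a, b, c, d), "p": float(p)})
    table = pd.DataFrame(rows)
    if len(table):
        table["padj"] = bh_adjust(table["p"].to_numpy())
        table["reject"] = table["padj"] <= alpha
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    return table


def mann_whitney_groups(values: pd.Series, groups: pd.Series,
                        comparisons: list[tuple[str, str]]) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per comparison with Bonferroni correction.

    The exact null distribution is used when both groups have at most 8
    observations and there are no ties; otherwise the normal approximation
    with tie correction. Star bins annotate the Bonferroni-corrected p.
    """
    if not comparisons:
        raise ValueError("no comparisons requested")
    values = pd.Series(values)
    groups = pd.Series(groups)
    rows = []
    for g1, g2 in comparisons:
        x = values[groups == g1].to_numpy(dtype=float)
        y = values[groups == g2].to_numpy(dtype=float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"empty group in comparison {g1} vs {g2}")
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (min(len(x), len(y)) <= 8 and not ties) \
            else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method=method)
        p_bonf = min(1.0, float(res.pvalue) * len(comparisons))
        rows.append({"group1": g1, "group2": g2, "n1": len(x), "n2": len(y),
                     "U": float(res.statistic), "p": float(res.pvalue),
                     "p_bonferroni": p_bonf, "stars": star_bin(p_bonf),
                     "method": method})
    return pd.DataFrame(rows)
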