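"""Gene-cohort extraction from latent-dimension tails.

A cohort is the set of genes lying beyond ``tail_sd`` standard deviations
from the mean of one latent dimension, on one side — two cohorts per
dimension, non-exclusive across dimensions. Redundant cohorts (those whose
members extensively overlap the union of the others, by Jaccard similarity)
can be pruned, and latent dimensions are characterised by Spearman
correlation against observed per-gene summary features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .vae import LatentEmbedding

DEFAULT_TAIL_SD = 1.25
DEFAULT_JACCARD = 0.5


@dataclass
class Cohort:
    dimension: str
    sign: str                    # "low" or "high"
    genes: frozenset[str]

    @property
    def id(self) -> str:
        return f"{self.dimension}_{self.sign}"

    @property
    def size(self) -> int:
        return len(self.genes)


def extract_cohorts(embedding: LatentEmbedding,
                    tail_sd: float = DEFAULT_TAIL_SD,
                    center: str = "empirical") -> list[Cohort]:
    """Two tail cohorts per latent dimension (2 * D in total).

    ``center`` selects empirical per-dimension mean/SD (default, robust for
    held-out genes) or the prior's mean 0 / SD 1 ("prior").
    """
    if center not in ("empirical", "prior"):
        raise ValueError("center must be 'empirical' or 'prior'")
    codes = embedding.codes
    out = []
    for dim in codes.columns:
        v = codes[dim]
        if center == "empirical":
            mean, sd = float(v.mean()), float(v.std(ddof=0))
        else:
            mean, sd = 0.0, 1.0
        if sd == 0:
            raise ValueError(f"latent dimension {dim} has zero SD")
        out.append(Cohort(dim, "low",
                          frozenset(codes.index[v < mean - tail_sd * sd])))
        out.append(Cohort(dim, "high",
                          frozenset(codes.index[v > mean + tail_sd * sd])))
    return out


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def overlap_matrix(cohorts: list[Cohort]) -> pd.DataFrame:
    ids = [c.id for c in cohorts]
    m = np.array([[jaccard(a.genes, b.genes) for b in cohorts]
                  for a in cohorts])
    return pd.DataFrame(m, index=ids, columns=ids)


def prune_overlapping(cohorts: list[Cohort],
                      jaccard_threshold: float = DEFAULT_JACCARD
                      ) -> tuple[list[Cohort], list[Cohort], pd.DataFrame]:
    """Iteratively drop the cohort most similar to the union of the rest.

    At each step the Jaccard similarity of every remaining cohort against the
    union of the other remaining cohorts is computed; the cohort with the
    largest similarity is dropped while that similarity exceeds the
    threshold. Returns (kept, omitted, full pairwise overlap matrix of the
    input cohorts).
    """
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    report = overlap_matrix(cohorts)
    kept = list(cohorts)
    omitted: list[Cohort] = []
    while len(kept) > 1:
        sims = []
        for i, c in enumerate(kept):
            union = frozenset().union(*(k.genes for j, k in enumerate(kept)
                                        if j != i))
            sims.append(jaccard(c.genes, union))
        worst = int(np.argmax(sims))
        if sims[worst] > jaccard_threshold:
            omitted.append(kept.pop(worst))
        else:
            break
    return kept, omitted, report


def latent_feature_correlation(embedding: LatentEmbedding,
                               features: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho (and p) between every latent dimension and every summary
    feature, over the genes shared by both tables."""
    shared = embedding.codes.index.intersection(features.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared genes; need at least 3")
    codes = embedding.codes.loc[shared]
    feats = features.loc[shared]
    rows = []
    for dim in codes.columns:
        for col in feats.columns:
            rho, p = stats.spearmanr(codes[dim], feats[col])
            rows.append({"dimension": dim, "feature": col,
                         "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows)


def latent_pairwise_correlation(embedding: LatentEmbedding) -> pd.DataFrame:
    """Pairwise Spearman |rho| between latent dimensions (diagnostic; in a
    well-behaved embedding no pair should correlate strongly)."""
    codes = embedding.codes
    rows = []
    dims = list(codes.columns)
    for i, a in enumerate(dims):
        for b in dims[i + 1:]:
            rho, p = stats.spearmanr(codes[a], codes[b])
            rows.append({"dim_a": a, "dim_b": b, "rho": float(rho),
                         "p": float(p)})
    return pd.DataFrame(rows)


def best_match_jaccard(cohorts: list[Cohort],
                       reference_sets: dict[str, set[str]]) -> pd.DataFrame:
    """For each reference gene set, the best-matching cohort by Jaccard.

    Used to score recovery of planted archetype cohorts on synthetic data.
    """
    rows = []
    for name, genes in reference_sets.items():
        scores = [(jaccard(set(genes), c.genes), c.id) for c in cohorts]
        best, cid = max(scores) if scores else (0.0, None)
        rows.append({"reference": name, "best_cohort": cid,
                     "jaccard": best})
    return pd.DataFrame(rows)
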