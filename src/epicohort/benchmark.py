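"""Silhouette benchmark of the VAE embedding against other embedders.

Labelled gene sets (genes uniquely annotated with one term) are scored in
each embedding with a one-vs-rest silhouette: for every label, genes of that
label against all other labelled genes, Euclidean distance, mean silhouette
over the label's members. Stochastic embedders are evaluated over repeated
seeded runs; deterministic ones run once.

Embedders are plain callables ``fit(x, d, seed) -> (n, d) array``. A
deterministic principal-component embedder and a seeded Gaussian
random-projection baseline ship built in; external methods (tSNE, UMAP,
PHATE, the trained VAE) plug in through the same signature.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .profiles import ProfileMatrix
from .vae import VAEConfig, encode, train_vae

Embedder = Callable[[np.ndarray, int, int], np.ndarray]


def silhouette_separation(coords: pd.DataFrame,
                          labels: pd.Series) -> pd.Series:
    """One-vs-rest mean silhouette per label.

    ``coords`` is genes x dims; ``labels`` assigns exactly one label per
    gene. Requires at least two labels and two genes per label.
    """
    shared = coords.index.intersection(labels.index)
    lab = labels.loc[shared]
    if lab.nunique() < 2:
        raise ValueError("need at least 2 distinct labels")
    counts = lab.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"singleton labels: {bad}")
    x = coords.loc[shared].to_numpy(dtype=float)
    out = {}
    for label in sorted(counts.index):
        binary = (lab == label).to_numpy()
        scores = silhouette_samples(x, binary, metric="euclidean")
        out[label] = float(scores[binary].mean())
    return pd.Series(out, name="silhouette")


def pca_embedder(x: np.ndarray, d: int, seed: int = 0) -> np.ndarray:
    """Deterministic linear baseline (full SVD; the seed is ignored)."""
    return PCA(n_components=d, svd_solver="full").fit_transform(x)


def random_projection_embedder(x: np.ndarray, d: int,
                               seed: int = 0) -> np.ndarray:
    """Seeded Gaussian random projection; a structure-free baseline."""
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((x.shape[1], d)) / np.sqrt(x.shape[1])
    return x @ w


def vae_embedder(profiles: ProfileMatrix,
                 base_config: VAEConfig | None = None) -> Embedder:
    """Wrap VAE training as a benchmark embedder over the given profiles."""
    from dataclasses import replace
    base = base_config or VAEConfig()

    def fit(x: np.ndarray, d: int, seed: int) -> np.ndarray:
        cfg = replace(base, latent_dim=d, seed=seed)
        model = train_vae(profiles, cfg)
        return encode(model, profiles).codes.to_numpy()

    return fit


DETERMINISTIC = frozenset({"pca"})


def compare_embedders(profiles: ProfileMatrix,
                      embedders: dict[str, Embedder],
                      labels: pd.Series,
                      dims: tuple[int, ...] = (3, 6),
                      runs: int = 20, seed: int = 0) -> pd.DataFrame:
    """Per-(method, run, D, label) silhouette table.

    Methods listed in ``DETERMINISTIC`` (by name) run once; others run
    ``runs`` times with seeds derived from ``seed``. Failures are recorded
    per run (status column) rather than aborting the benchmark.
    """
    x = profiles.data.to_numpy(dtype=float)
    gene_index = profiles.data.index
    rows = []
    for name, fit in embedders.items():
        n_runs = 1 if name in DETERMINISTIC else runs
        for d in dims:
            for run in range(n_runs):
                run_seed = seed * 10_000 + run
                try:
                    coords = pd.DataFrame(fit(x, d, run_seed),
                                          index=gene_index)
                    scores = silhouette_separation(coords, labels)
                except Exception as exc:  # recorded, not fatal
                    rows.append({"method": name, "D": d, "run": run,
                                 "label": None, "silhouette": np.nan,
                                 "status": f"error: {exc}"})
                    continue
                for label, s in scores.items():
                    rows.append({"method": name, "D": d, "run": run,
                                 "label": label, "silhouette": s,
                                 "status": "ok"})
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD silhouette per (method, D, label) over runs."""
    ok = results[results["status"] == "ok"]
    return (ok.groupby(["method", "D", "label"])["silhouette"]
            .agg(["mean", "std", "count"]).reset_index())
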