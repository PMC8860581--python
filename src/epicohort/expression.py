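"""Count filtering, TMM normalization and negative-binomial differential
expression.

The differential-expression engine is a self-contained approximation of the
standard NB-GLM Wald workflow: per-gene negative-binomial log-linear models
are fitted by iteratively reweighted least squares with condition and batch
covariates, gene-wise dispersions are estimated by moment matching and shrunk
halfway toward the across-gene median, and the condition coefficient is
tested with a Wald z statistic, BH-adjusted within each contrast. It performs
no posterior fold-change shrinkage and no outlier filtering; users who need
parity with a particular external DE engine can import its result tables via
:func:`import_de_tables`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TISSUES = ["FB", "MB", "HB", "SC"]
STAGES = ["E11.5", "E13.5", "E15.5", "E18.5"]
ANTERIOR = ("FB", "MB")
POSTERIOR = ("HB", "SC")
#: Stages used in the per-tissue contrasts (the earliest stage is omitted
#: because the repressive mark is largely absent before it).
DE_STAGES = ("E13.5", "E15.5", "E18.5")

LOW_COUNT_MIN = 10
EXPRESSED_CPM = 0.5
PADJ_SIGNIFICANT = 0.05


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def filter_low_counts(counts: pd.DataFrame,
                      min_count: int = LOW_COUNT_MIN) -> pd.DataFrame:
    """Keep genes with >= ``min_count`` counts in at least half the samples
    (ceiling of S/2)."""
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if counts.empty:
        raise ValueError("empty count matrix")
    s = counts.shape[1]
    need = -(-s // 2)
    keep = (counts.values >= min_count).sum(axis=1) >= need
    return counts.loc[keep]


@dataclass
class NormalizationFactors:
    """Per-sample library sizes and TMM scaling factors (product = 1)."""
    sample_ids: list[str]
    lib_size: np.ndarray
    tmm: np.ndarray

    @property
    def effective_size(self) -> np.ndarray:
        return self.lib_size * self.tmm


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose upper-quartile/library-size ratio is
    closest to the mean of that ratio. For every other sample, gene-wise
    log-ratios (M) and mean log-abundances (A) are computed over genes with
    positive counts in both libraries, doubly trimmed (30% of M each tail,
    5% of A each tail), and averaged with inverse asymptotic-variance weights;
    the factor is 2 to that weighted mean. Factors are rescaled to have
    product 1.
    """
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")

    uq = np.array([np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0
                   for col in y.T]) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    f = np.ones(len(lib))
    yr, nr = y[:, ref], lib[ref]
    for k in range(len(lib)):
        if k == ref:
            continue
        yk, nk = y[:, k], lib[k]
        ok = (yk > 0) & (yr > 0)
        if not ok.any():
            continue
        pk, pr = yk[ok] / nk, yr[ok] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = (nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        keep = _double_trim_mask(m, a, trim_m, trim_a)
        if keep.any() and w[keep].sum() > 0:
            f[k] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    # rescale to product 1 (divide by geometric mean)
    f = f / np.exp(np.mean(np.log(f)))
    return NormalizationFactors(list(counts.columns), lib, f)


def _double_trim_mask(m: np.ndarray, a: np.ndarray, trim_m: float,
                      trim_a: float) -> np.ndarray:
    """Keep entries inside the central band of both M and A, by stable
    sorted position (well-defined under tied values)."""
    n = len(m)
    lo_m = int(np.floor(n * trim_m))
    lo_a = int(np.floor(n * trim_a))
    # ties broken by the other coordinate so the kept multiset of
    # (M, A) values does not depend on gene order
    in_m = np.zeros(n, dtype=bool)
    in_m[np.lexsort((a, m))[lo_m:n - lo_m]] = True
    in_a = np.zeros(n, dtype=bool)
    in_a[np.lexsort((m, a))[lo_a:n - lo_a]] = True
    return in_m & in_a


def normalize(counts: pd.DataFrame,
              factors: NormalizationFactors) -> pd.DataFrame:
    """log2(TMM-scaled counts-per-million + 1)."""
    eff = factors.effective_size
    cpm = counts.to_numpy(dtype=float) / eff[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index,
                        columns=counts.columns)


def tmm_cpm(counts: pd.DataFrame,
            factors: NormalizationFactors) -> pd.DataFrame:
    """TMM-scaled counts-per-million on the linear scale (the "TMM counts"
    scale on which the expressed threshold is applied)."""
    eff = factors.effective_size
    return pd.DataFrame(counts.to_numpy(dtype=float) / eff[None, :] * 1e6,
                        index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Contrast planning
# ---------------------------------------------------------------------------

@dataclass
class Contrast:
    """A single KO-vs-WT comparison with its scope and batch covariate."""
    name: str
    kind: str                      # "tissue" or "temporal"
    tissues: tuple[str, ...]
    stages: tuple[str, ...]
    batch: str                     # metadata column used as batch factor
    stratification: bool = False   # member of the 8-contrast stratified set

    def sample_mask(self, metadata: pd.DataFrame) -> np.ndarray:
        return (metadata["tissue"].isin(self.tissues)
                & metadata["stage"].isin(self.stages)).to_numpy()


def plan_contrasts(metadata: pd.DataFrame,
                   stratification_set: str = "tissue+anterior"
                   ) -> list[Contrast]:
    """The full contrast plan: 4 per-tissue and 8 per-stage comparisons.

    Per-tissue contrasts compare KO vs WT within one tissue over the three
    later stages with stage as batch; temporal contrasts compare KO vs WT
    within one stage for the anterior (FB, MB) and posterior (HB, SC) tissue
    groups with tissue as batch. ``stratification_set`` selects which eight
    contrasts feed the stratified labelling: "tissue+anterior" (default) or
    "anterior+posterior".
    """
    if stratification_set not in ("tissue+anterior", "anterior+posterior"):
        raise ValueError(f"unknown stratification_set {stratification_set!r}")
    missing = []
    for g in ("WT", "KO"):
        for t in TISSUES:
            for s in STAGES:
                n = ((metadata["genotype"] == g) & (metadata["tissue"] == t)
                     & (metadata["stage"] == s)).sum()
                if n == 0:
                    missing.append(f"{g}/{t}/{s}")
    if missing:
        raise ValueError(f"design cells absent from metadata: {missing}")

    contrasts = []
    for t in TISSUES:
        contrasts.append(Contrast(
            name=f"tissue_{t}", kind="tissue", tissues=(t,),
            stages=DE_STAGES, batch="stage",
            stratification=stratification_set == "tissue+anterior"))
    for group_name, group in (("anterior", ANTERIOR), ("posterior", POSTERIOR)):
        for s in STAGES:
            strat = (group_name == "anterior"
                     if stratification_set == "tissue+anterior"
                     else True)
            contrasts.append(Contrast(
                name=f"temporal_{group_name}_{s}", kind="temporal",
                tissues=group, stages=(s,), batch="tissue",
                stratification=strat))
    return contrasts


# ---------------------------------------------------------------------------
# NB-GLM Wald engine
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-gene Wald-test results for one contrast."""
    contrast: str
    table: pd.DataFrame = field(repr=False)  # log2fc, se, stat, p, padj

    def significant(self, alpha: float = PADJ_SIGNIFICANT) -> pd.Index:
        t = self.table
        return t.index[t["padj"].fillna(1.0) <= alpha]


def _irls_nb(y: np.ndarray, x: np.ndarray, offset: np.ndarray,
             alpha: np.ndarray, n_iter: int = 50,
             tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Batched IRLS for NB2 log-linear models sharing one design matrix.

    y: (G, S) counts; x: (S, P) design; offset: (S,) log effective library
    size; alpha: (G,) dispersions (0 = Poisson). Returns (beta (G, P),
    covariance (G, P, P)).
    """
    g, s = y.shape
    p = x.shape[1]
    # init from a log-linear least-squares fit
    z0 = np.log(y + 0.5) - offset[None, :]
    beta = np.linalg.lstsq(x, z0.T, rcond=None)[0].T
    mu_min = 1e-8
    for _ in range(n_iter):
        eta = beta @ x.T + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.maximum(np.exp(eta), mu_min)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta - offset[None, :] + (y - mu) / mu
        xtwx = np.einsum("sp,gs,sq->gpq", x, w, x, optimize=True)
        xtwz = np.einsum("sp,gs,gs->gp", x, w, z, optimize=True)
        xtwx += 1e-10 * np.eye(p)[None, :, :]
        new = np.linalg.solve(xtwx, xtwz[:, :, None])[:, :, 0]
        delta = np.max(np.abs(new - beta))
        beta = new
        if delta < tol:
            break
    eta = np.clip(beta @ x.T + offset[None, :], -30.0, 30.0)
    mu = np.maximum(np.exp(eta), mu_min)
    w = mu / (1.0 + alpha[:, None] * mu)
    xtwx = np.einsum("sp,gs,sq->gpq", x, w, x, optimize=True)
    xtwx += 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(xtwx)
    return beta, cov


def _moment_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int,
                       alpha_max: float = 100.0) -> np.ndarray:
    """Per-gene NB dispersion by matching the Pearson statistic to its
    residual degrees of freedom; solved by bisection (the statistic is
    monotone decreasing in the dispersion)."""
    g, s = y.shape
    df = max(s - n_params, 1)

    def pearson(a):
        return np.sum((y - mu) ** 2 / (mu + a[:, None] * mu ** 2), axis=1)

    alpha = np.zeros(g)
    need = pearson(np.zeros(g)) > df
    if need.any():
        lo = np.zeros(need.sum())
        hi = np.full(need.sum(), alpha_max)
        ys, ms = y[need], mu[need]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            stat = np.sum((ys - ms) ** 2 / (ms + mid[:, None] * ms ** 2),
                          axis=1)
            go_up = stat > df
            lo = np.where(go_up, mid, lo)
            hi = np.where(go_up, hi, mid)
        alpha[need] = 0.5 * (lo + hi)
    return alpha


def _common_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int,
                       alpha_max: float = 100.0) -> float:
    """Common NB dispersion by matching the total Pearson statistic over all
    genes to its pooled degrees of freedom. Unlike the median of per-gene
    estimates this is not biased by zero-truncation of individual genes."""
    g, s = y.shape
    total_df = g * max(s - n_params, 1)
    if np.sum((y - mu) ** 2 / mu) <= total_df:
        return 0.0
    lo, hi = 0.0, alpha_max
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        stat = np.sum((y - mu) ** 2 / (mu + mid * mu ** 2))
        if stat > total_df:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def nb_wald_test(counts: pd.DataFrame, design: pd.DataFrame,
                 coef: str, offset: np.ndarray | None = None,
                 dispersion_shrink: float = 0.5,
                 dispersion_floor: float = 1e-8) -> pd.DataFrame:
    """Fit per-gene NB GLMs and Wald-test one coefficient.

    Parameters
    ----------
    counts
        genes x samples raw counts.
    design
        samples x covariates numeric design matrix (must include the tested
        column ``coef``; an intercept column is expected).
    offset
        log effective library size per sample (defaults to log column sums).
    dispersion_shrink
        weight pulling each gene-wise moment dispersion toward the
        across-gene median (0 = none, 1 = fully pooled).

    Returns a frame with log2fc, se, stat, p, padj (BH within this call).
    """
    y = counts.to_numpy(dtype=float)
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular design matrix")
    if offset is None:
        lib = y.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("zero library size")
        offset = np.log(lib)
    ci = list(design.columns).index(coef)

    nonzero = y.sum(axis=1) > 0
    g = y.shape[0]
    log2fc = np.zeros(g)
    se = np.full(g, np.nan)
    stat = np.zeros(g)
    p = np.ones(g)

    if nonzero.any():
        yz = y[nonzero]
        # Poisson pilot fit for the moment dispersion estimate
        beta0, _ = _irls_nb(yz, x, offset, np.zeros(yz.shape[0]))
        mu0 = np.exp(np.clip(beta0 @ x.T + offset[None, :], -30, 30))
        disp = _moment_dispersion(yz, mu0, x.shape[1])
        pooled = _common_dispersion(yz, mu0, x.shape[1])
        disp = np.maximum((1 - dispersion_shrink) * disp
                          + dispersion_shrink * pooled, dispersion_floor)
        beta, cov = _irls_nb(yz, x, offset, disp)
        ln2 = np.log(2.0)
        log2fc[nonzero] = beta[:, ci] / ln2
        se_nat = np.sqrt(np.maximum(cov[:, ci, ci], 1e-300))
        se[nonzero] = se_nat / ln2
        z = beta[:, ci] / se_nat
        stat[nonzero] = z
        p[nonzero] = 2.0 * stats.norm.sf(np.abs(z))

    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "se": se, "stat": stat, "p": p, "padj": padj,
         "all_zero": ~nonzero},
        index=counts.index)


def _design_for(metadata: pd.DataFrame, batch: str) -> pd.DataFrame:
    d = pd.DataFrame(index=metadata.index)
    d["intercept"] = 1.0
    d["condition"] = (metadata["genotype"] == "KO").astype(float)
    levels = sorted(metadata[batch].unique())
    for lv in levels[1:]:
        d[f"{batch}_{lv}"] = (metadata[batch] == lv).astype(float)
    return d


def run_contrast(counts: pd.DataFrame, metadata: pd.DataFrame,
                 contrast: Contrast,
                 factors: NormalizationFactors | None = None,
                 dispersion_shrink: float = 0.5) -> DEResult:
    """Run one planned KO-vs-WT contrast on the raw count matrix.

    The metadata rows must align with the count columns by sample_id. TMM
    factors (if given) enter as log effective-library-size offsets.
    """
    meta = (metadata.set_index("sample_id").loc[counts.columns]
            .rename_axis("sample_id").reset_index())
    mask = contrast.sample_mask(meta)
    sub_meta = meta.loc[mask].reset_index(drop=True)
    for g in ("WT", "KO"):
        if (sub_meta["genotype"] == g).sum() < 2:
            raise ValueError(
                f"contrast {contrast.name}: fewer than 2 {g} samples")
    sub = counts.loc[:, meta.loc[mask, "sample_id"]]
    if factors is not None:
        pos = [factors.sample_ids.index(s) for s in sub.columns]
        offset = np.log(factors.effective_size[pos])
    else:
        offset = None
    design = _design_for(sub_meta, contrast.batch)
    table = nb_wald_test(sub, design, "condition", offset,
                         dispersion_shrink=dispersion_shrink)
    return DEResult(contrast.name, table)


def run_all_contrasts(counts: pd.DataFrame, metadata: pd.DataFrame,
                      contrasts: list[Contrast] | None = None,
                      factors: NormalizationFactors | None = None
                      ) -> dict[str, DEResult]:
    if contrasts is None:
        contrasts = plan_contrasts(metadata)
    return {c.name: run_contrast(counts, metadata, c, factors)
            for c in contrasts}


def import_de_tables(files: dict[str, str | Path],
                     contrast_names: list[str] | None = None
                     ) -> dict[str, DEResult]:
    """Load externally computed DE tables (e.g. DESeq2 exports).

    ``files`` maps contrast name -> TSV path with columns gene,
    log2FoldChange, pvalue, padj (extra columns are kept). NA adjusted
    p-values propagate as not-significant.
    """
    if contrast_names is not None:
        unmatched = sorted(set(files) ^ set(contrast_names))
        if unmatched:
            raise ValueError(f"contrast names unmatched: {unmatched}")
    out = {}
    for name, path in files.items():
        df = pd.read_csv(path, sep="\t")
        required = {"gene", "log2FoldChange", "pvalue", "padj"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(
                f"{path}: missing required columns {sorted(missing)}")
        table = pd.DataFrame({
            "log2fc": df["log2FoldChange"].to_numpy(dtype=float),
            "se": df["lfcSE"].to_numpy(dtype=float)
                  if "lfcSE" in df else np.nan,
            "stat": df["stat"].to_numpy(dtype=float)
                    if "stat" in df else np.nan,
            "p": df["pvalue"].to_numpy(dtype=float),
            "padj": df["padj"].to_numpy(dtype=float),
        }, index=pd.Index(df["gene"], name="gene_id"))
        out[name] = DEResult(name, table)
    return out
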