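"""Ground-truth-annotated synthetic multi-omic bundles.

The generator emulates a bulk RNA-seq knockout study over the developing CNS:
2 genotypes (WT, KO) x 4 tissues along the anterior-posterior axis (FB, MB,
HB, SC) x 4 embryonic stages x replicates, with negative-binomial counts,
plus H3K27me3 NarrowPeak files on a 3-tissue x 7-stage ChIP grid, gene models
on a single synthetic chromosome, a ChromHMM-style segmentation, and the
gene -> archetype truth map.

Archetypes plant the structure the downstream analysis looks for:

========== ============= ============== ======== ==================
archetype   A-P gradient  stage slope    marked   default KO effect
========== ============= ============== ======== ==================
posterior   rising (+)    none           yes      +2.5 log2
anterior    falling (-)   none           yes      -2.0 log2
development none          rising (+)     yes      +2.5 log2
proliferation none        falling (-)    no       -2.0 log2
immune      none          none           no       +2.0 log2
background  none          none           no       0
========== ============= ============== ======== ==================

Counts for gene g in sample k are NB(mu_gk, alpha) with Var = mu + alpha*mu^2
and log2 mu_gk = per-gene baseline + gradient * (tissue index - 1.5)
+ stage slope * (stage index - 1.5) + KO effect [KO samples only]
+ log2 sample depth factor. Marked archetypes receive one retained H3K27me3
peak intersecting [TSS-2500, TSS+2500) in every ChIP (tissue, stage) cell;
unmarked archetypes receive none.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .expression import STAGES, TISSUES

ARCHETYPES = ("posterior", "anterior", "development", "proliferation",
              "immune", "background")
#: (gradient sign, stage-slope sign, carries the repressive mark)
ARCHETYPE_STRUCTURE = {
    "posterior": (+1, 0, True),
    "anterior": (-1, 0, True),
    "development": (0, +1, True),
    "proliferation": (0, -1, False),
    "immune": (0, 0, False),
    "background": (0, 0, False),
}
MARKED_ARCHETYPES = tuple(a for a, v in ARCHETYPE_STRUCTURE.items() if v[2])

#: ChIP-seq grid: anterior-brain tissues across seven stages (21 cells).
MARK = "H3K27me3"
MARK_TISSUES = ("FB", "MB", "HB")
MARK_STAGES = ("E10.5", "E11.5", "E12.5", "E13.5", "E14.5", "E15.5", "E16.5")

CHROM = "chrS"
GENE_SPACING = 20_000
GENE_LENGTH = 5_000
#: ChromHMM-style states: bivalent promoter, strong/weak enhancer.
STATE_BIVALENT = "Pr-B"
STATE_ENHANCER = "En-Sd"
STATE_WEAK = "En-W"

DEFAULT_KO_EFFECT = {
    "posterior": 2.5, "anterior": -2.0, "development": 2.5,
    "proliferation": -2.0, "immune": 2.0, "background": 0.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Data-generating parameters; defaults are the study conditions."""
    genes_per_archetype: dict[str, int] = field(
        default_factory=lambda: {**{a: 150 for a in ARCHETYPES},
                                 "background": 750})
    base_mean: float = 100.0          # expected counts at the design centre
    dispersion: float = 0.05          # NB alpha, Var = mu + alpha mu^2
    ko_effect_log2: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KO_EFFECT))
    gradient_log2: float = 1.5        # A-P slope per tissue step
    temporal_log2: float = 0.75       # slope per stage step
    libsize_range: tuple[float, float] = (0.7, 1.3)
    mark_signal_lognormal: tuple[float, float] = (3.0, 0.5)
    replicates: int = 2
    baseline_sd_log2: float = 0.5     # per-gene baseline spread
    composition_shift: bool = False   # double a gene subset in one sample
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes_per_archetype:
            raise ValueError("empty archetype map")
        unknown = set(self.genes_per_archetype) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if any(n < 1 for n in self.genes_per_archetype.values()):
            raise ValueError("archetype gene counts must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValueError("invalid libsize_range")


@dataclass
class SyntheticBundle:
    """A generated dataset with its ground truth."""
    counts: pd.DataFrame                 # genes x samples integers
    metadata: pd.DataFrame               # sample_id, genotype, tissue, stage,
                                         # replicate, depth_factor
    peaks: dict[tuple[str, str, str], pd.DataFrame]  # (mark,tissue,stage)
    gene_models: pd.DataFrame            # gene_id, chrom, start, end, strand
    chromhmm: pd.DataFrame               # chrom, start, end, state, file_order
    truth: pd.DataFrame                  # index gene_id: archetype, base_log2

    @property
    def archetype(self) -> pd.Series:
        return self.truth["archetype"]


def _sample_grid(replicates: int) -> pd.DataFrame:
    rows = []
    for genotype in ("WT", "KO"):
        for tissue in TISSUES:
            for stage in STAGES:
                for rep in range(1, replicates + 1):
                    rows.append({
                        "sample_id": f"{genotype}_{tissue}_{stage}_r{rep}",
                        "genotype": genotype, "tissue": tissue,
                        "stage": stage, "replicate": rep})
    return pd.DataFrame(rows)


def _gene_models(gene_ids: list[str]) -> pd.DataFrame:
    """Genes tiled along one synthetic chromosome, alternating strands."""
    rows = []
    for i, gid in enumerate(gene_ids):
        start = 10_000 + i * GENE_SPACING
        rows.append({"gene_id": gid, "chrom": CHROM, "start": start,
                     "end": start + GENE_LENGTH,
                     "strand": "+" if i % 2 == 0 else "-"})
    return pd.DataFrame(rows)


def expected_log2_mean(config: SyntheticConfig, truth: pd.DataFrame,
                       metadata: pd.DataFrame) -> pd.DataFrame:
    """The planted log2 mean-count matrix (genes x samples), including
    depth factors; reconstructible from an exported bundle."""
    t_idx = metadata["tissue"].map({t: i for i, t in enumerate(TISSUES)})
    s_idx = metadata["stage"].map({s: i for i, s in enumerate(STAGES)})
    is_ko = (metadata["genotype"] == "KO").to_numpy()
    out = np.zeros((len(truth), len(metadata)))
    for j in range(len(metadata)):
        grad = np.array([ARCHETYPE_STRUCTURE[a][0]
                         for a in truth["archetype"]], dtype=float)
        temp = np.array([ARCHETYPE_STRUCTURE[a][1]
                         for a in truth["archetype"]], dtype=float)
        ko = np.array([config.ko_effect_log2.get(a, 0.0)
                       for a in truth["archetype"]])
        out[:, j] = (truth["base_log2"].to_numpy()
                     + grad * config.gradient_log2 * (t_idx.iloc[j] - 1.5)
                     + temp * config.temporal_log2 * (s_idx.iloc[j] - 1.5)
                     + (ko if is_ko[j] else 0.0)
                     + np.log2(metadata["depth_factor"].iloc[j]))
    return pd.DataFrame(out, index=truth.index,
                        columns=metadata["sample_id"])


def generate_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a complete bundle; byte-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    metadata = _sample_grid(config.replicates)
    metadata["depth_factor"] = rng.uniform(*config.libsize_range,
                                           size=len(metadata))

    gene_ids, archetypes = [], []
    for a in ARCHETYPES:
        n = config.genes_per_archetype.get(a, 0)
        for i in range(n):
            gene_ids.append(f"{a}_{i:04d}")
            archetypes.append(a)
    truth = pd.DataFrame({
        "archetype": archetypes,
        "base_log2": np.log2(config.base_mean)
        + rng.normal(0.0, config.baseline_sd_log2, size=len(gene_ids)),
    }, index=pd.Index(gene_ids, name="gene_id"))

    mu = 2.0 ** expected_log2_mean(config, truth, metadata).to_numpy()
    if config.composition_shift:
        # double the first quarter of genes in the first sample only: a pure
        # composition change that TMM should absorb
        mu[: len(gene_ids) // 4, 0] *= 2.0
    n_nb = 1.0 / config.dispersion
    counts = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
    counts_df = pd.DataFrame(counts, index=truth.index,
                             columns=list(metadata["sample_id"]))

    gene_models = _gene_models(gene_ids)
    tss = np.where(gene_models["strand"] == "+", gene_models["start"],
                   gene_models["end"] - 1)

    marked = truth["archetype"].isin(MARKED_ARCHETYPES).to_numpy()
    mlog, msd = config.mark_signal_lognormal
    peaks: dict[tuple[str, str, str], pd.DataFrame] = {}
    for tissue in MARK_TISSUES:
        for stage in MARK_STAGES:
            rows = []
            for gi in np.flatnonzero(marked):
                centre = int(tss[gi] + rng.integers(-2000, 2001))
                half = int(rng.integers(200, 500))
                start = max(centre - half, 0)
                end = centre + half
                signal = float(np.exp(rng.normal(mlog, msd)))
                qv = float(rng.uniform(2.0, 10.0))  # -log10 q, passes filter
                rows.append((CHROM, start, end,
                             f"peak_{tissue}_{stage}_{gi}", 0, ".",
                             signal, qv + 1.0, qv, half))
            peaks[(MARK, tissue, stage)] = pd.DataFrame(
                rows, columns=io.NARROWPEAK_COLUMNS)

    seg_rows = []
    for gi, gid in enumerate(gene_ids):
        a = truth["archetype"].iloc[gi]
        if ARCHETYPE_STRUCTURE[a][2]:
            state = STATE_BIVALENT
        elif a == "background":
            state = STATE_WEAK if gi % 2 else None  # half stay unannotated
        else:
            state = STATE_ENHANCER
        if state is not None:
            seg_rows.append((CHROM, int(tss[gi]) - 100, int(tss[gi]) + 100,
                             state))
    chromhmm = pd.DataFrame(seg_rows,
                            columns=["chrom", "start", "end", "state"])
    chromhmm["file_order"] = range(len(chromhmm))

    return SyntheticBundle(counts_df, metadata, peaks, gene_models, chromhmm,
                           truth)


def null_config(config: SyntheticConfig | None = None) -> SyntheticConfig:
    """The same conditions with every planted knockout effect removed."""
    cfg = config or SyntheticConfig()
    return replace(cfg, ko_effect_log2={a: 0.0 for a in ARCHETYPES})


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_bundle(bundle: SyntheticBundle, directory: str | Path
                  ) -> dict[str, str]:
    """Write the bundle as plain-text files; returns the file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    bundle.counts.to_csv(directory / "counts.tsv", sep="\t")
    manifest["counts"] = "counts.tsv"
    bundle.metadata.to_csv(directory / "metadata.tsv", sep="\t", index=False)
    manifest["metadata"] = "metadata.tsv"
    bundle.truth.to_csv(directory / "truth.tsv", sep="\t")
    manifest["truth"] = "truth.tsv"
    io.write_gtf_genes(bundle.gene_models, directory / "genes.gtf")
    manifest["gene_models"] = "genes.gtf"
    io.write_bed_segments(bundle.chromhmm, directory / "chromhmm.bed")
    manifest["chromhmm"] = "chromhmm.bed"

    peak_dir = directory / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for (mark, tissue, stage), df in bundle.peaks.items():
        name = f"peaks/{mark}_{tissue}_{stage}.narrowPeak"
        io.write_narrowpeak(df, directory / name)
        manifest[f"peaks:{mark}:{tissue}:{stage}"] = name
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_bundle(directory: str | Path) -> SyntheticBundle:
    """Re-read an exported bundle (inverse of :func:`export_bundle`)."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    counts = io.read_counts(directory / manifest["counts"])
    metadata = io.read_metadata(directory / manifest["metadata"])
    truth = pd.read_csv(directory / manifest["truth"], sep="\t",
                        index_col=0)
    gene_models = io.read_gtf_genes(directory / manifest["gene_models"])
    chromhmm = io.read_bed_segments(directory / manifest["chromhmm"])
    peaks = {}
    for key, name in manifest.items():
        if key.startswith("peaks:"):
            _, mark, tissue, stage = key.split(":")
            peaks[(mark, tissue, stage)] = io.read_narrowpeak(
                directory / name)
    return SyntheticBundle(counts, metadata, peaks, gene_models, chromhmm,
                           truth)
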