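"""Synthetic six-line allopolyploid methylome cohort with planted truth.

The simulated world mirrors the study design: two progenitors (*A. arenosa*
-> A subgenome, *A. thaliana* -> T subgenome), their F1, two resynthesized
allotetraploids (Allo733, Allo738, ~F10) and the natural allotetraploid
(*A. suecica*).  Everything lives on one chromosome per subgenome ("A1",
"T1"), colinear with identical cytosine positions, so every cytosine is a
"conserved" cytosine and A-vs-T comparisons pair sites by equal offset.

Planted 100-bp windows follow trajectory classes:

==================  =============================================================
convergent          A over T by ``effect`` in parents, F1 and both resynthesized
                    lines; collapsed to the T level in the natural line
conserved           hypomethylated versus the A progenitor in F1, both
                    resynthesized lines and the natural line
persistent_hyper    A over T in every line including the natural one
hyper               methylation gained in the natural line versus the A
                    progenitor (provides hyper-DMR-linked genes)
both                convergent and conserved on one window; only attainable at
                    the saturated boundary (parent difference 1.0), so none are
                    planted by default
null                one baseline level shared by every sample
==================  =============================================================

Per-cytosine methylation probability is ``clip(mu + eps)`` with a site effect
``eps ~ N(0, site_noise_sd)`` frozen across replicates, samples and the two
homologous chromosomes (a sequence-context effect) — which also makes the
zero-effect cohort an exact null.  Read depth is negative-binomial per
cytosine and replicate; methylated counts are binomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CYTOSINE_COLUMNS,
    write_cytosine_report,
    write_expression,
    write_genes_bed,
    write_homology_map,
)

SUBGENOME_CHROM = {"A": "A1", "T": "T1"}
CHROM_SUBGENOME = {"A1": "A", "T1": "T"}
LINES = ("aar", "ath", "f1", "a733", "a738", "asu")
#: analysis samples = (line, subgenome); parents carry one subgenome each
SAMPLES = (
    "aar", "ath",
    "f1_A", "f1_T", "a733_A", "a733_T", "a738_A", "a738_T", "asu_A", "asu_T",
)
A_SAMPLES = ("aar", "f1_A", "a733_A", "a738_A", "asu_A")
T_SAMPLES = ("ath", "f1_T", "a733_T", "a738_T", "asu_T")
PLANTED_CLASSES = ("convergent", "conserved", "persistent_hyper", "hyper", "both")

TRUTH_COLUMNS = ["window_id", "chrom", "start", "end", "context", "true_class"]


@dataclass(frozen=True)
class CoverageModel:
    """Read-depth model per cytosine and replicate (negative binomial)."""

    mean_depth: float = 20.0
    dispersion: float = 5.0      # NB size parameter; Poisson as -> inf
    replicates: int = 2

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class CohortConfig:
    """Stated world of the synthetic cohort (defaults match the study's scale
    of effects and the desk-scale genome used throughout the tests)."""

    n_tiles: int = 8000                      # 100-bp tiles per subgenome
    window_size: int = 100
    contexts: tuple = ("CG", "CHG", "CHH")
    sites_per_window: dict = field(
        default_factory=lambda: {"CG": 6, "CHG": 5, "CHH": 17}
    )
    #: planted windows per trajectory class (all in ``planted_context``)
    n_planted: dict = field(
        default_factory=lambda: {
            "convergent": 50,
            "conserved": 50,
            "persistent_hyper": 25,
            "hyper": 25,
            "both": 0,
        }
    )
    #: minimum tile spacing between planted windows; 45 tiles (4.5 kb) keeps
    #: a gene and its 2-kb flanks from reaching any other planted window
    planted_spacing: int = 45
    planted_context: str = "CG"
    effect: float = 0.6                      # |Δmu| of planted windows
    baseline_low: float = 0.15               # unmethylated planted level
    #: Beta(a, b) of the shared baseline of null windows, per context
    baseline_beta: dict = field(
        default_factory=lambda: {"CG": (0.6, 1.8), "CHG": (0.5, 4.5), "CHH": (0.8, 15.0)}
    )
    site_noise_sd: float = 0.05
    coverage: CoverageModel = field(default_factory=CoverageModel)
    # homology map
    block_bp: int = 2000
    block_score: float = 2000.0
    # genes / expression
    n_background_genes: int = 200
    gene_pad: int = 0                        # gene body extends this far past its window
    expr_effect: float = 1.0                 # log2 repression at full methylation gain
    expr_replicates: int = 3
    expr_noise_sd: float = 0.25
    base_log2_mean: float = 4.0
    base_log2_sd: float = 1.5
    homolog_base_sd: float = 0.5             # baseline log2 spread within a homolog pair

    def __post_init__(self):
        if self.planted_context not in self.contexts:
            raise ValueError("planted_context must be among contexts")
        unknown = set(self.n_planted) - set(PLANTED_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes: {sorted(unknown)}")
        if not 0 < self.effect <= 1:
            raise ValueError("effect must be in (0, 1]")


@dataclass
class CohortData:
    """Everything one simulation emits (expression is generated separately)."""

    config: CohortConfig
    reports: dict          # (line, replicate index) -> cytosine DataFrame
    genes: pd.DataFrame
    blocks: pd.DataFrame
    truth: pd.DataFrame    # one row per window of the planted context
    site_probs: pd.DataFrame  # chrom,pos,strand,context + per-sample probability

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (line, rep), df in sorted(self.reports.items()):
            write_cytosine_report(df, outdir / f"{line}_rep{rep + 1}.cx.tsv")
        write_genes_bed(self.genes, outdir / "genes.bed")
        write_homology_map(self.blocks, outdir / "homology.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _class_mu(true_class: str, cfg: CohortConfig, base: float) -> dict[str, float]:
    lo, hi = cfg.baseline_low, cfg.baseline_low + cfg.effect
    if true_class == "null":
        return {s: base for s in SAMPLES}
    mu = {s: lo for s in SAMPLES}
    if true_class == "convergent":
        for s in ("aar", "f1_A", "a733_A", "a738_A"):
            mu[s] = hi
    elif true_class == "conserved":
        mu["aar"] = hi
    elif true_class == "persistent_hyper":
        for s in A_SAMPLES:
            mu[s] = hi
    elif true_class == "hyper":
        mu["asu_A"] = hi
    elif true_class == "both":
        # only realisable at the saturated boundary: parent difference 1.0
        mu.update({s: 0.0 for s in SAMPLES})
        mu["aar"] = 1.0
        for s in ("f1_A", "a733_A", "a738_A"):
            mu[s] = 0.5
    else:
        raise ValueError(f"unknown class {true_class!r}")
    return mu


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortData:
    """Generate the six-line cohort; deterministic given (config, seed)."""
    cfg = config or CohortConfig()
    n_planted_total = sum(cfg.n_planted.values())
    if n_planted_total * max(cfg.planted_spacing, 1) > cfg.n_tiles:
        raise ValueError(
            f"{n_planted_total} planted windows at spacing {cfg.planted_spacing} exceed "
            f"genome capacity ({cfg.n_tiles} tiles)"
        )
    ss = np.random.SeedSequence(seed)
    rng_place, rng_counts, _ = (np.random.default_rng(s) for s in ss.spawn(3))

    # --- cytosine placement (shared template for A1 and T1) -----------------
    w = cfg.window_size
    need = sum(cfg.sites_per_window[c] for c in cfg.contexts)
    if need > w:
        raise ValueError("more cytosines per window than base pairs")
    # distinct offsets per tile: first `need` of a random permutation of 0..w-1
    offs = np.argsort(rng_place.random((cfg.n_tiles, w)), axis=1)[:, :need]
    ctx_labels = np.concatenate(
        [np.repeat(ctx, cfg.sites_per_window[ctx]) for ctx in cfg.contexts]
    )
    template = pd.DataFrame(
        {
            "tile": np.repeat(np.arange(cfg.n_tiles), need),
            "offset": offs.ravel(),
            "context": np.tile(ctx_labels, cfg.n_tiles),
        }
    )
    template["pos"] = template["tile"] * w + template["offset"] + 1  # 1-based
    template["strand"] = np.where(
        rng_place.random(len(template)) < 0.5, "+", "-"
    )
    template = template.sort_values(["pos"], kind="mergesort").reset_index(drop=True)

    # --- window classes and mu profiles -------------------------------------
    # planted tiles sit on a sparse lattice so that no two planted windows
    # fall within one gene neighbourhood (body + 2-kb flanks)
    classes = np.array(["null"] * cfg.n_tiles, dtype=object)
    spacing = max(cfg.planted_spacing, 1)
    lattice = np.arange(0, cfg.n_tiles, spacing)
    chosen = rng_place.choice(len(lattice), size=n_planted_total, replace=False)
    planted_tiles_all = lattice[chosen]
    order = rng_place.permutation(n_planted_total)
    i = 0
    for cls in PLANTED_CLASSES:
        n = cfg.n_planted.get(cls, 0)
        classes[planted_tiles_all[order[i : i + n]]] = cls
        i += n
    base_levels = {
        ctx: rng_place.beta(*cfg.baseline_beta[ctx], size=cfg.n_tiles)
        for ctx in cfg.contexts
    }

    # per-tile mu of the planted context, per sample (vectorised by class)
    ctx0 = cfg.planted_context
    mu_tile = {
        s: base_levels[ctx0].copy() for s in SAMPLES
    }
    for cls in PLANTED_CLASSES:
        mask = classes == cls
        if not mask.any():
            continue
        profile = _class_mu(cls, cfg, 0.0)
        for s in SAMPLES:
            mu_tile[s][mask] = profile[s]

    # per-site probability matrix (sites x samples), shared across chroms/reps
    S = len(template)
    probs = np.empty((S, len(SAMPLES)))
    tile_idx = template["tile"].to_numpy()
    ctx_arr = template["context"].to_numpy()
    for j, s in enumerate(SAMPLES):
        col = np.empty(S)
        for ctx in cfg.contexts:
            sel = ctx_arr == ctx
            mu_t = mu_tile[s] if ctx == ctx0 else base_levels[ctx]
            col[sel] = mu_t[tile_idx[sel]]
        probs[:, j] = col
    eps = rng_place.normal(0.0, cfg.site_noise_sd, size=S)
    probs = np.clip(probs + eps[:, None], 0.0, 1.0)

    # --- truth table (realised window mu per sample) -------------------------
    planted_sel = ctx_arr == cfg.planted_context
    pt = pd.DataFrame(
        {"tile": tile_idx[planted_sel]}
        | {f"mu_{s}": probs[planted_sel, j] for j, s in enumerate(SAMPLES)}
    )
    mu_win = pt.groupby("tile").mean()
    truth = pd.DataFrame(
        {
            "window_id": [f"w{t:06d}" for t in range(cfg.n_tiles)],
            "chrom": SUBGENOME_CHROM["A"],
            "start": np.arange(cfg.n_tiles) * w,
            "end": np.arange(cfg.n_tiles) * w + w,
            "context": cfg.planted_context,
            "true_class": classes,
        }
    )
    for s in SAMPLES:
        truth[f"mu_{s}"] = mu_win[f"mu_{s}"].reindex(range(cfg.n_tiles)).to_numpy()

    # --- read sampling -------------------------------------------------------
    cov = cfg.coverage
    p_nb = cov.dispersion / (cov.dispersion + cov.mean_depth)
    reports: dict[tuple[str, int], pd.DataFrame] = {}
    sub_of_line = {"aar": ("A",), "ath": ("T",), "f1": ("A", "T"),
                   "a733": ("A", "T"), "a738": ("A", "T"), "asu": ("A", "T")}
    sample_col = {s: j for j, s in enumerate(SAMPLES)}
    for line in LINES:
        for rep in range(cov.replicates):
            frames = []
            for sub in sub_of_line[line]:
                samp = line if line in ("aar", "ath") else f"{line}_{sub}"
                depth = rng_counts.negative_binomial(cov.dispersion, p_nb, size=S)
                meth = rng_counts.binomial(depth, probs[:, sample_col[samp]])
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": SUBGENOME_CHROM[sub],
                            "pos": template["pos"],
                            "strand": template["strand"],
                            "n_meth": meth,
                            "n_unmeth": depth - meth,
                            "context": template["context"],
                        }
                    )
                )
            reports[(line, rep)] = pd.concat(frames, ignore_index=True)[CYTOSINE_COLUMNS]

    # --- homology map and genes ----------------------------------------------
    genome_bp = cfg.n_tiles * w
    starts = np.arange(0, genome_bp, cfg.block_bp)
    blocks = pd.DataFrame(
        {
            "chrom_a": SUBGENOME_CHROM["A"],
            "start_a": starts,
            "end_a": np.minimum(starts + cfg.block_bp, genome_bp),
            "chrom_b": SUBGENOME_CHROM["T"],
            "start_b": starts,
            "end_b": np.minimum(starts + cfg.block_bp, genome_bp),
            "score": cfg.block_score,
            "strand_rel": "+",
        }
    )
    genes = _place_genes(cfg, classes, rng_place)

    site_probs = pd.concat(
        [
            pd.DataFrame(
                {
                    "chrom": SUBGENOME_CHROM[sub],
                    "pos": template["pos"],
                    "strand": template["strand"],
                    "context": template["context"],
                }
                | {s: probs[:, j] for j, s in enumerate(SAMPLES)}
            )
            for sub in ("A", "T")
        ],
        ignore_index=True,
    )
    return CohortData(cfg, reports, genes, blocks, truth, site_probs)


def _place_genes(cfg: CohortConfig, classes: np.ndarray, rng) -> pd.DataFrame:
    """One homolog pair per planted window plus background pairs on null tiles."""
    w, pad = cfg.window_size, cfg.gene_pad
    genome_bp = cfg.n_tiles * w
    rows = []

    def add_pair(tag: str, tile: int):
        start = max(0, tile * w - pad)
        end = min(genome_bp, tile * w + w + pad)
        ga, gt = f"gA_{tag}", f"gT_{tag}"
        rows.append((ga, SUBGENOME_CHROM["A"], start, end, "+", gt))
        rows.append((gt, SUBGENOME_CHROM["T"], start, end, "+", ga))

    planted_tiles = np.flatnonzero(classes != "null")
    for t in planted_tiles:
        add_pair(f"w{t:06d}", int(t))
    null_tiles = np.flatnonzero(classes == "null")
    n_bg = min(cfg.n_background_genes, len(null_tiles))
    for t in rng.choice(null_tiles, size=n_bg, replace=False):
        add_pair(f"bg{t:06d}", int(t))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "homolog_id"]
    )
    return genes.sort_values(["chrom", "start", "gene_id"], kind="mergesort").reset_index(drop=True)


def simulate_expression(
    truth: pd.DataFrame,
    genes: pd.DataFrame,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression table (gene x line x replicate TPM) with negative coupling.

    Methylation represses: a gene anchored on a planted window is shifted by
    ``-expr_effect * (mu - baseline_low) / effect`` log2 units in every line
    (parents included) whose copy of that window is methylated above the low
    level.  A line that lost the methylation of its progenitor therefore sits
    ``expr_effect`` log2 units above it — methylation down, expression up.
    Homolog pairs share a correlated baseline (``homolog_base_sd``); genes not
    anchored on planted windows have symmetric ratios centred at zero.
    """
    cfg = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(3)[2])

    planted = truth.loc[truth["true_class"] != "null"]
    # map each gene to the planted window it overlaps most (coordinates on
    # either chromosome are homologous, so the A-side truth row serves both)
    anchor: dict[str, pd.Series] = {}
    ps, pe = planted["start"].to_numpy(), planted["end"].to_numpy()
    for g in genes.itertuples(index=False):
        ov = np.minimum(g.end, pe) - np.maximum(g.start, ps)
        if len(ov) and ov.max() > 0:
            anchor[g.gene_id] = planted.iloc[int(np.argmax(ov))]

    # baseline expression, correlated within a homolog pair
    base: dict[str, float] = {}
    for g in genes.itertuples(index=False):
        partner = g.homolog_id if isinstance(g.homolog_id, str) else None
        if partner in base:
            base[g.gene_id] = base[partner] + rng.normal(0.0, cfg.homolog_base_sd)
        else:
            base[g.gene_id] = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd)

    records = []
    for g in genes.itertuples(index=False):
        sub = CHROM_SUBGENOME[g.chrom]
        win = anchor.get(g.gene_id)
        for line in LINES:
            if line in ("aar", "ath"):
                samp = line if (line == "aar") == (sub == "A") else None
            else:
                samp = f"{line}_{sub}"
            offset = 0.0
            if win is not None and samp is not None:
                excess = (win[f"mu_{samp}"] - cfg.baseline_low) / cfg.effect
                offset = -cfg.expr_effect * float(np.clip(excess, 0.0, 1.0))
            noise = rng.normal(0.0, cfg.expr_noise_sd, size=cfg.expr_replicates)
            tpm = np.power(2.0, base[g.gene_id] + offset + noise)
            for r in range(cfg.expr_replicates):
                records.append((g.gene_id, line, r + 1, float(tpm[r])))
    return pd.DataFrame(records, columns=["gene_id", "line", "replicate", "tpm"])


def write_cohort(cohort: CohortData, outdir, expression: pd.DataFrame | None = None) -> None:
    cohort.write(outdir)
    if expression is not None:
        write_expression(expression, Path(outdir) / "expression.tsv")


def null_config(n_windows: int = 5000, depth: float = 20.0, replicates: int = 2) -> CohortConfig:
    """A zero-effect CG-only cohort: every window is a true null."""
    return CohortConfig(
        n_tiles=n_windows,
        contexts=("CG",),
        sites_per_window={"CG": 6},
        n_planted={c: 0 for c in PLANTED_CLASSES},
        coverage=CoverageModel(mean_depth=depth, replicates=replicates),
        n_background_genes=0,
    )
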