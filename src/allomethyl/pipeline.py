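"""End-to-end orchestration: reports -> shared sites -> DMRs -> trajectories
-> gene/expression association (-> LTR ages), with a summary report.

Line naming is fixed: ``aar``/``ath`` are the progenitors (A and T subgenome
respectively), ``f1`` the hybrid, ``a733``/``a738`` the resynthesized
allotetraploids, ``asu`` the natural one.  Chromosomes are assigned to
subgenomes by ``chrom_subgenome``; T-subgenome cytosines are lifted onto
A-subgenome coordinates through the homology map so that every comparison —
A-vs-T within a line as well as subgenome-vs-progenitor — runs on one shared
site matrix, and each site-count drop is logged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, dmr, io, ltr, sites, trajectory
from .simulate import CHROM_SUBGENOME, LINES

#: A-vs-T comparisons (focal A sample, reference T sample), in A coordinates
A_VS_T = {
    "parents": ("aar", "ath"),
    "f1": ("f1_A", "f1_T"),
    "a733": ("a733_A", "a733_T"),
    "a738": ("a738_A", "a738_T"),
    "asu": ("asu_A", "asu_T"),
}
#: subgenome-versus-progenitor comparisons per line
VS_PARENT = {
    "A": {ln: (f"{ln}_A", "aar") for ln in ("f1", "a733", "a738", "asu")},
    "T": {ln: (f"{ln}_T", "ath") for ln in ("f1", "a733", "a738", "asu")},
}


def percentage(numerator: int, denominator: int) -> float:
    """100 * num / den rounded half-even to one decimal (as printed in text)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    frac = Decimal(100 * numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


@dataclass
class RunConfig:
    """All thresholds of the analysis plus (for file-based runs) input paths.

    Threshold defaults are the published ones: 100-bp windows, >=4/4/16
    cytosines (CG/CHG/CHH), Fisher FDR < 0.05, minimum methylation
    differences 0.5/0.3/0.1, >=3 reads per merged site, 2-kb gene flanks,
    homology blocks >=1 kb with score >=1,000, substitution rate 7e-9.
    """

    reports: dict = field(default_factory=dict)   # line -> [replicate paths]
    genes: str | None = None
    homology: str | None = None
    expression: str | None = None
    ltr_table: str | None = None
    outdir: str | None = None
    chrom_subgenome: dict = field(default_factory=lambda: dict(CHROM_SUBGENOME))
    contexts: tuple = ("CG", "CHG", "CHH")
    window_size: int = 100
    step: int = 100
    fdr: float = 0.05
    min_reads: int = 3
    flank: int = 2000
    min_block_len: int = 1000
    min_block_score: float = 1000.0
    pseudocount: float = 1.0
    rate: float = ltr.DEFAULT_RATE
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        for name in ("window_size", "step", "min_reads", "min_block_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.flank < 0 or self.pseudocount < 0:
            raise ValueError("flank and pseudocount must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "contexts" in raw:
            raw["contexts"] = tuple(raw["contexts"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def build_site_matrix(
    reports: dict, blocks: pd.DataFrame, config: RunConfig, log: dict | None = None
) -> sites.SiteMatrix:
    """Merge replicates, filter coverage, lift T onto A coordinates and
    intersect sites across all ten (line, subgenome) samples."""
    log = log if log is not None else {}
    per_sample: dict[str, pd.DataFrame] = {}
    sub_chroms = {
        sub: [c for c, s in config.chrom_subgenome.items() if s == sub] for sub in ("A", "T")
    }
    for line in LINES:
        reps = [reports[k] for k in sorted(reports) if k[0] == line]
        if not reps:
            raise ValueError(f"no replicates for line {line!r}")
        merged = sites.merge_replicates(*reps)
        covered = sites.filter_coverage(merged, config.min_reads)
        log[f"sites_{line}_merged"] = len(merged)
        log[f"sites_{line}_covered"] = len(covered)
        for sub in ("A", "T"):
            part = covered.loc[covered["chrom"].isin(sub_chroms[sub])]
            if part.empty:
                continue
            if sub == "T":
                part = sites.liftover_sites(part, blocks, direction="b_to_a")
            samp = line if line in ("aar", "ath") else f"{line}_{sub}"
            per_sample[samp] = part.reset_index(drop=True)
    matrix = sites.harmonize(per_sample)
    log["sites_shared"] = matrix.n_sites
    matrix = sites.filter_conserved_regions(
        matrix, blocks, config.min_block_len, config.min_block_score, side="a"
    )
    log["sites_conserved"] = matrix.n_sites
    return matrix


def call_all_dmrs(matrix: sites.SiteMatrix, config: RunConfig) -> dict:
    """Window tables for every comparison x context.

    Returns {"a_vs_t": {ctx: {name: table}}, "vs_parent": {sub: {ctx: {...}}}}.
    """
    windows = dmr.make_windows(matrix, config.window_size, config.step)
    out = {"a_vs_t": {}, "vs_parent": {"A": {}, "T": {}}}
    for ctx in config.contexts:
        out["a_vs_t"][ctx] = {
            name: dmr.test_windows(windows, focal, ref, ctx, fdr=config.fdr)
            for name, (focal, ref) in A_VS_T.items()
        }
        for sub in ("A", "T"):
            out["vs_parent"][sub][ctx] = {
                name: dmr.test_windows(windows, focal, ref, ctx, fdr=config.fdr)
                for name, (focal, ref) in VS_PARENT[sub].items()
            }
    return out


def _dmr_counts(tables: dict) -> dict:
    out = {}
    for name, t in tables.items():
        sig = t.loc[t["significant"]]
        out[name] = {
            "tested": int(len(t)),
            "hyper": int((sig["direction"] == "hyper").sum()),
            "hypo": int((sig["direction"] == "hypo").sum()),
        }
    return out


def _fraction_entry(num: int, den: int) -> dict:
    entry = {"numerator": int(num), "denominator": int(den)}
    entry["percentage"] = percentage(num, den) if den else None
    return entry


def analyze(
    reports: dict,
    blocks: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    ltr_table: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Run the full analysis on in-memory inputs; returns the summary report.

    Intermediate artifacts (window tables, trajectory calls, links) are under
    the ``"artifacts"`` key; everything else is JSON-serialisable.
    """
    config = config or RunConfig()
    log: dict = {}
    matrix = build_site_matrix(reports, blocks, config, log)
    calls = call_all_dmrs(matrix, config)

    report = {"log": log, "dmr_counts": {}, "trajectory": {}, "association": {}}
    artifacts = {"matrix": matrix, "calls": calls}

    for ctx in config.contexts:
        report["dmr_counts"][ctx] = {
            "a_vs_t": _dmr_counts(calls["a_vs_t"][ctx]),
            "vs_parent_A": _dmr_counts(calls["vs_parent"]["A"][ctx]),
            "vs_parent_T": _dmr_counts(calls["vs_parent"]["T"][ctx]),
        }
        clf = trajectory.classify_trajectories(
            calls["a_vs_t"][ctx], calls["vs_parent"]["A"][ctx]
        )
        artifacts[f"trajectory_{ctx}"] = clf
        counts = clf.summary()
        parents_hyper = int(clf.calls_["hyper_parents"].sum())
        n_conv = counts["convergent"] + counts["both"]
        traj = {
            "labels": counts,
            "parents_hyper": parents_hyper,
            "convergent_of_parents_hyper": _fraction_entry(n_conv, parents_hyper)
            if parents_hyper
            else None,
            "conserved_fractions": [
                {
                    "line": r.line,
                    **_fraction_entry(r.overlap, r.total),
                }
                for r in clf.fractions_.itertuples(index=False)
                if r.total
            ],
        }
        report["trajectory"][ctx] = traj

    if genes is not None and expression is not None:
        report["association"] = _associate(
            matrix, calls, genes, expression, config, artifacts
        )

    if ltr_table is not None:
        aged = ltr.ltr_ages(ltr_table, config.rate)
        artifacts["ltr"] = aged
        report["ltr"] = {
            "n_elements": int(len(aged)),
            "mean_age_years": float(aged["t"].mean()) if len(aged) else None,
        }

    report["artifacts"] = artifacts
    return report


def _associate(matrix, calls, genes, expression, config: RunConfig, artifacts) -> dict:
    ctx = "CG" if "CG" in config.contexts else config.contexts[0]
    asu_vs_parent = calls["vs_parent"]["A"][ctx]["asu"]
    sig = asu_vs_parent.loc[asu_vs_parent["significant"]]
    links = assoc.genes_near_dmrs(sig, genes, config.flank)
    artifacts["links"] = links
    direction = sig.set_index(["chrom", "start"])["direction"]
    out: dict = {"n_links": int(len(links))}
    if links.empty:
        return out
    links = links.assign(
        direction=direction.loc[list(zip(links["chrom"], links["start"]))].to_numpy()
    )
    hypo_genes = sorted(set(links.loc[links["direction"] == "hypo", "gene_id"]))
    hyper_genes = sorted(set(links.loc[links["direction"] == "hyper", "gene_id"]))

    ratios = assoc.expression_ratios(expression, "asu", "aar", config.pseudocount)
    r_hypo = ratios.reindex(hypo_genes).dropna()
    r_hyper = ratios.reindex(hyper_genes).dropna()
    out["hypo_linked"] = {"n": int(len(r_hypo)), "mean_log2_ratio": float(r_hypo.mean())}
    out["hyper_linked"] = {"n": int(len(r_hyper)), "mean_log2_ratio": float(r_hyper.mean())}
    if len(r_hypo) and len(r_hyper):
        u, p = assoc.compare_groups(r_hypo.to_numpy(), r_hyper.to_numpy())
        out["hypo_vs_hyper_mannwhitney"] = {"U": u, "p": p}

    # per-gene methylation-expression correlation across the five A-side lines
    lines5 = [("aar", "aar"), ("f1_A", "f1"), ("a733_A", "a733"), ("a738_A", "a738"), ("asu_A", "asu")]
    mean_tpm = expression.groupby(["gene_id", "line"])["tpm"].mean()
    corr = []
    linked = genes.loc[genes["gene_id"].isin(set(links["gene_id"]))]
    for g in linked.itertuples(index=False):
        m = assoc.gene_methylation(matrix, g, context=ctx)
        levels = [m.get(s, float("nan")) for s, _ in lines5]
        try:
            expr5 = [np.log2(mean_tpm.loc[(g.gene_id, line)] + config.pseudocount) for _, line in lines5]
        except KeyError:
            continue
        r = assoc.methylation_expression_correlation(levels, expr5)
        if np.isfinite(r):
            corr.append(r)
    out["meth_expr_correlation"] = {
        "n_genes": len(corr),
        "mean_r": float(np.mean(corr)) if corr else None,
        "frac_negative": float(np.mean(np.array(corr) < 0)) if corr else None,
    }

    pairs = _homolog_pair_table(matrix, genes, expression, config, ctx)
    artifacts["pairs"] = pairs
    if len(pairs):
        conv = assoc.homolog_convergence(pairs)
        out["homolog_convergence"] = _fraction_entry(conv["n_decreased"], conv["n_candidates"]) if conv[
            "n_candidates"
        ] else None
        gene_pairs = pairs.rename(columns={"gene_a": "gene_a", "gene_t": "gene_t"})[
            ["gene_a", "gene_t"]
        ]
        upreg = assoc.upregulation_breakdown(gene_pairs, expression, pseudocount=config.pseudocount)
        out["upregulation"] = {
            "counts": upreg["counts"],
            "fraction_upregulated": upreg["fraction_upregulated"],
        }
    return out


def _homolog_pair_table(matrix, genes, expression, config: RunConfig, ctx: str) -> pd.DataFrame:
    a_genes = genes.dropna(subset=["homolog_id"])
    a_genes = a_genes.loc[
        a_genes["chrom"].map(config.chrom_subgenome).eq("A")
    ]
    mean_tpm = expression.groupby(["gene_id", "line"])["tpm"].mean()
    pc = config.pseudocount
    rows = []
    gene_by_id = genes.set_index("gene_id")
    for g in a_genes.itertuples(index=False):
        if g.homolog_id not in gene_by_id.index:
            continue
        # homologous coordinates: the T homolog's sites live at the same lifted
        # positions, so one interval lookup serves both subgenomes' samples
        m = assoc.gene_methylation(matrix, g, context=ctx)
        try:
            e = {
                key: float(mean_tpm.loc[key])
                for key in [
                    (g.gene_id, "aar"), (g.homolog_id, "ath"),
                    (g.gene_id, "asu"), (g.homolog_id, "asu"),
                ]
            }
        except KeyError:
            continue
        rows.append(
            {
                "gene_a": g.gene_id,
                "gene_t": g.homolog_id,
                "m_parent_a": m.get("aar"),
                "m_parent_t": m.get("ath"),
                "m_asu_a": m.get("asu_A"),
                "m_asu_t": m.get("asu_T"),
                "log2_parents": float(
                    np.log2((e[(g.gene_id, "aar")] + pc) / (e[(g.homolog_id, "ath")] + pc))
                ),
                "log2_asu": float(
                    np.log2((e[(g.gene_id, "asu")] + pc) / (e[(g.homolog_id, "asu")] + pc))
                ),
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """File-based entry point: read inputs, analyse, write artifacts."""
    if not config.reports or config.homology is None:
        raise ValueError("config must provide cytosine reports and a homology map")
    reports = {}
    for line, paths in config.reports.items():
        for i, p in enumerate(paths):
            reports[(line, i)] = io.read_cytosine_report(p)
    blocks = io.read_homology_map(config.homology)
    genes = io.read_genes(config.genes) if config.genes else None
    expression = io.read_expression(config.expression) if config.expression else None
    ltr_table = ltr.read_ltr_table(config.ltr_table) if config.ltr_table else None
    report = analyze(reports, blocks, genes, expression, ltr_table, config)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        artifacts = report["artifacts"]
        for ctx in config.contexts:
            for name, t in artifacts["calls"]["a_vs_t"][ctx].items():
                io.write_dmr_bed(
                    t.loc[t["significant"]], outdir / f"dmr_{ctx}_avt_{name}.bed"
                )
            clf = artifacts[f"trajectory_{ctx}"]
            clf.calls_.to_csv(outdir / f"trajectory_{ctx}.tsv", sep="\t", index=False)
        if "links" in artifacts:
            artifacts["links"].to_csv(outdir / "links.tsv", sep="\t", index=False)
        if "pairs" in artifacts and len(artifacts["pairs"]):
            artifacts["pairs"].to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        if "ltr" in artifacts:
            artifacts["ltr"].to_csv(outdir / "ltr_ages.tsv", sep="\t", index=False)
        config.to_yaml(outdir / "resolved_config.yaml")
        serialisable = {k: v for k, v in report.items() if k != "artifacts"}
        with open(outdir / "summary.json", "w") as fh:
            json.dump(serialisable, fh, indent=2, sort_keys=True)
    return report
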