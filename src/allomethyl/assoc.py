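"""DMR-gene links, expression ratios and homolog convergence statistics.

A gene is linked to a DMR when the DMR overlaps the gene body or its 2-kb
flanks.  Expression effects are quantified as log2 ratios of replicate-mean
TPM (with a pseudo-count), compared between gene groups by Mann-Whitney U,
and related to methylation by per-gene correlation across lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .sites import SiteMatrix


def genes_near_dmrs(dmrs: pd.DataFrame, genes: pd.DataFrame, flank: int = 2000) -> pd.DataFrame:
    """Link each DMR to every gene whose flank-extended interval it overlaps.

    A link exists iff the DMR interval intersects ``[start - flank, end + flank)``
    (half-open arithmetic).  ``relation`` is "body" when the DMR touches the
    gene body itself, otherwise "flank5"/"flank3" by gene strand; ``distance``
    is the bp gap from the nearest gene edge (0 for body).
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    links = []
    for chrom, gsub in genes.groupby("chrom"):
        dsub = dmrs.loc[dmrs["chrom"] == chrom]
        if dsub.empty:
            continue
        ds = dsub["start"].to_numpy()
        de = dsub["end"].to_numpy()
        for g in gsub.itertuples(index=False):
            lo, hi = g.start - flank, g.end + flank
            hit = (ds < hi) & (de > lo)
            for i in np.flatnonzero(hit):
                if ds[i] < g.end and de[i] > g.start:
                    relation, dist = "body", 0
                elif de[i] <= g.start:
                    dist = int(g.start - de[i])
                    relation = "flank5" if g.strand == "+" else "flank3"
                else:
                    dist = int(ds[i] - g.end)
                    relation = "flank3" if g.strand == "+" else "flank5"
                links.append(
                    {
                        "gene_id": g.gene_id,
                        "chrom": chrom,
                        "start": int(ds[i]),
                        "end": int(de[i]),
                        "relation": relation,
                        "distance": dist,
                    }
                )
    return pd.DataFrame(links, columns=["gene_id", "chrom", "start", "end", "relation", "distance"])


def gene_methylation(
    matrix: SiteMatrix,
    gene,
    region: str = "body",
    flank: int = 2000,
    context: str | None = "CG",
) -> dict[str, float]:
    """Weighted methylation pooled over a gene's cytosines, per sample.

    ``region`` is "body" (default), "flank5", "flank3" or "body+flank".
    Samples with no covered cytosine in the region map to NaN.
    """
    if region == "body":
        lo, hi = gene.start, gene.end
    elif region == "body+flank":
        lo, hi = gene.start - flank, gene.end + flank
    elif region == "flank5":
        lo, hi = (gene.start - flank, gene.start) if gene.strand == "+" else (gene.end, gene.end + flank)
    elif region == "flank3":
        lo, hi = (gene.end, gene.end + flank) if gene.strand == "+" else (gene.start - flank, gene.start)
    else:
        raise ValueError(f"unknown region {region!r}")
    df = matrix.data
    pos0 = df["pos"] - 1
    sel = (df["chrom"] == gene.chrom) & (pos0 >= lo) & (pos0 < hi)
    if context is not None:
        sel &= df["context"] == context
    sub = df.loc[sel]
    out = {}
    for s in matrix.samples:
        total = sub[f"{s}.total"].sum()
        out[s] = float(sub[f"{s}.meth"].sum() / total) if total > 0 else float("nan")
    return out


def _mean_tpm(expr: pd.DataFrame, gene: str, line: str) -> float:
    sel = expr.loc[(expr["gene_id"] == gene) & (expr["line"] == line), "tpm"]
    if sel.empty:
        raise KeyError(f"no expression for gene {gene!r} in line {line!r}")
    return float(sel.mean())


def expression_ratio(
    expr: pd.DataFrame, gene: str, line_num: str, line_den: str, pseudocount: float = 1.0
) -> float:
    """log2((mean TPM numerator + pc) / (mean TPM denominator + pc))."""
    num = _mean_tpm(expr, gene, line_num)
    den = _mean_tpm(expr, gene, line_den)
    return float(np.log2((num + pseudocount) / (den + pseudocount)))


def expression_ratios(
    expr: pd.DataFrame, line_num: str, line_den: str, pseudocount: float = 1.0
) -> pd.Series:
    """Vectorised log2 ratio for every gene (index: gene_id)."""
    means = expr.groupby(["gene_id", "line"])["tpm"].mean().unstack("line")
    return np.log2((means[line_num] + pseudocount) / (means[line_den] + pseudocount))


def compare_groups(ratios_group1, ratios_group2) -> tuple[float, float]:
    """Mann-Whitney U (group1 vs group2) with a two-sided p.

    Exact enumeration when the combined sample is small (n <= 20) and
    tie-free; normal approximation with tie correction otherwise.
    """
    x = np.asarray(ratios_group1, dtype=float)
    y = np.asarray(ratios_group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def methylation_expression_correlation(
    levels, expression, method: str = "pearson"
) -> float:
    """Correlation of one gene's methylation and expression across lines.

    NaN when fewer than three complete pairs remain or either vector is
    constant (correlation undefined).
    """
    m = np.asarray(levels, dtype=float)
    e = np.asarray(expression, dtype=float)
    ok = np.isfinite(m) & np.isfinite(e)
    m, e = m[ok], e[ok]
    if m.size < 3:
        return float("nan")
    if np.ptp(m) == 0 or np.ptp(e) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(m, e).statistic)
    if method == "spearman":
        return float(stats.spearmanr(m, e).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def homolog_convergence(pairs: pd.DataFrame, meth_threshold: float = 0.5) -> dict:
    """Concerted-expression summary over homolog pairs.

    ``pairs`` needs columns m_parent_a, m_parent_t (gene-level CG methylation
    of the two progenitor homologs), m_asu_a, m_asu_t (same in the natural
    allotetraploid), log2_parents and log2_asu (between-homolog expression
    log-ratios).  A pair is a *candidate* when the progenitor homologs differ
    in methylation by at least the threshold while the natural-line homologs
    do not; it has *decreased* expression difference when |log2_asu| <
    |log2_parents|.
    """
    dm_parents = (pairs["m_parent_a"] - pairs["m_parent_t"]).abs() >= meth_threshold
    sim_asu = (pairs["m_asu_a"] - pairs["m_asu_t"]).abs() < meth_threshold
    candidate = dm_parents & sim_asu
    decreased = candidate & (pairs["log2_asu"].abs() < pairs["log2_parents"].abs())
    n_cand, n_dec = int(candidate.sum()), int(decreased.sum())
    return {
        "n_candidates": n_cand,
        "n_decreased": n_dec,
        "fraction": n_dec / n_cand if n_cand else float("nan"),
        "candidate": candidate,
        "decreased": decreased,
    }


def upregulation_breakdown(
    gene_pairs: pd.DataFrame,
    expr: pd.DataFrame,
    focal_line: str = "asu",
    parent_a: str = "aar",
    parent_t: str = "ath",
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> dict:
    """Classify homolog pairs by which copy is upregulated in the focal line.

    ``gene_pairs`` has columns gene_a, gene_t (homolog ids).  A homolog is
    upregulated when its focal/parent log2 ratio is positive and a two-sided
    two-sample test on log-TPM across replicates gives p < ``alpha``
    (a two-group ANOVA, equivalently Student's t).  Pairs with a missing
    homolog are skipped and counted.
    """
    by = expr.set_index(["gene_id", "line"]).sort_index()

    def _tpms(gene, line):
        try:
            v = by.loc[(gene, line), "tpm"]
        except KeyError:
            return None
        return np.atleast_1d(np.asarray(v, dtype=float))

    def _up(gene, line_num, line_den):
        a, b = _tpms(gene, line_num), _tpms(gene, line_den)
        if a is None or b is None:
            return None
        ratio = np.log2((a.mean() + pseudocount) / (b.mean() + pseudocount))
        la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
        if min(la.size, lb.size) < 2 or (np.ptp(la) == 0 and np.ptp(lb) == 0):
            p = 1.0
        else:
            p = float(stats.ttest_ind(la, lb).pvalue)
        return bool(ratio > 0 and p < alpha)

    counts = {"A_only": 0, "T_only": 0, "both": 0, "none": 0, "skipped": 0}
    labels = []
    for pair in gene_pairs.itertuples(index=False):
        up_a = _up(pair.gene_a, focal_line, parent_a)
        up_t = _up(pair.gene_t, focal_line, parent_t)
        if up_a is None or up_t is None:
            counts["skipped"] += 1
            labels.append("skipped")
            continue
        lab = {
            (True, True): "both",
            (True, False): "A_only",
            (False, True): "T_only",
            (False, False): "none",
        }[(up_a, up_t)]
        counts[lab] += 1
        labels.append(lab)
    total = counts["A_only"] + counts["T_only"] + counts["both"] + counts["none"]
    upregulated = counts["A_only"] + counts["T_only"] + counts["both"]
    return {
        "counts": counts,
        "n_total": total,
        "n_upregulated": upregulated,
        "fraction_upregulated": upregulated / total if total else float("nan"),
        "labels": labels,
    }
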