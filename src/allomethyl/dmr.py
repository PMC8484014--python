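"""Window-level differential methylation calling.

The genome is tiled into fixed 100-bp windows; within each window and context
the read counts of all cytosines are pooled and the two samples are compared
by a two-sided Fisher's exact test on the pooled 2x2 table.  P-values are
Benjamini-Hochberg adjusted within each (comparison, context) family and a
window is a DMR when q < ``fdr`` AND the weighted-methylation difference
exceeds the context-specific minimum effect (0.5 CG / 0.3 CHG / 0.1 CHH).
Windows with fewer cytosines than the context minimum (4 CG / 4 CHG / 16 CHH)
are never tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .sites import SiteMatrix

#: minimum number of cytosines for a window to be testable, per context
MIN_SITES = {"CG": 4, "CHG": 4, "CHH": 16}
#: minimum |difference in weighted methylation| for a DMR, per context
MIN_DELTA = {"CG": 0.5, "CHG": 0.3, "CHH": 0.1}

_REL_TOL = 1.0 + 1e-7  # relative slack when comparing point probabilities


def weighted_methylation(pooled_meth, pooled_total):
    """Pooled methylated reads / pooled total reads; NaN where total is 0."""
    meth = np.asarray(pooled_meth, dtype=float)
    total = np.asarray(pooled_total, dtype=float)
    if np.any(meth < 0) or np.any(total < meth):
        raise ValueError("need 0 <= pooled_meth <= pooled_total")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    p is the sum of hypergeometric point probabilities no larger than that of
    the observed table, with row and column margins fixed.  A table with any
    zero margin carries no information and returns p = 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    return float(
        fisher_exact_many(np.array([a]), np.array([b]), np.array([c]), np.array([d]))[0]
    )


def fisher_exact_many(a, b, c, d) -> np.ndarray:
    """Vectorised two-sided Fisher exact test over many 2x2 tables.

    Point probabilities are evaluated from a shared log-factorial lookup
    table, so the cost is O(sum of support sizes) rather than one scipy call
    per window.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    r1, r2 = a + b, c + d
    k = a + c
    n = r1 + r2
    lg = gammaln(np.arange(int(n.max()) + 2))  # lg[x] = ln((x-1)!)

    def logcomb(nn, kk):
        return lg[nn + 1] - lg[kk + 1] - lg[nn - kk + 1]

    lo = np.maximum(0, k - r2)
    hi = np.minimum(k, r1)
    width = int((hi - lo).max()) + 1
    x = lo[:, None] + np.arange(width)[None, :]
    valid = x <= hi[:, None]
    xc = np.where(valid, x, 0)
    # log P(X = x) for X ~ Hypergeom(n, r1, k)
    logdenom = logcomb(n, k)
    logpmf = (
        logcomb(r1[:, None], xc)
        + logcomb(r2[:, None], k[:, None] - xc)
        - logdenom[:, None]
    )
    logpmf = np.where(valid, logpmf, -np.inf)
    log_obs = logpmf[np.arange(len(a)), (a - lo)]
    pmf = np.exp(logpmf)
    p = np.where(pmf <= np.exp(log_obs)[:, None] * _REL_TOL, pmf, 0.0).sum(axis=1)
    p = np.minimum(p, 1.0)
    # zero-margin tables are uninformative
    p[(r1 == 0) | (r2 == 0) | (k == 0) | (k == n)] = 1.0
    return p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def make_windows(
    matrix: SiteMatrix, window_size: int = 100, step: int = 100
) -> pd.DataFrame:
    """Pool site counts on fixed genomic tiles [k*step, k*step + window_size).

    Returns one row per (tile, context) containing at least one site, with
    columns chrom, start, end, context, n_sites and per-sample pooled
    ``{s}.meth`` / ``{s}.total``.  With ``step < window_size`` tiles overlap
    and a site contributes to every tile containing it.
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    df = matrix.data
    if df.empty:
        cols = ["chrom", "start", "end", "context", "n_sites"]
        cols += [f"{s}.{f}" for s in matrix.samples for f in ("meth", "total")]
        return pd.DataFrame(columns=cols)
    pos0 = df["pos"].to_numpy() - 1
    # tile indices k with k*step <= pos0 < k*step + window_size
    k_hi = pos0 // step
    k_lo = np.maximum(0, (pos0 - window_size) // step + 1)
    n_tiles = (k_hi - k_lo + 1).astype(int)
    rep_idx = np.repeat(np.arange(len(df)), n_tiles)
    offsets = np.concatenate([np.arange(n) for n in n_tiles]) if len(df) else np.array([], int)
    tile = np.repeat(k_lo, n_tiles) + offsets
    expanded = df.iloc[rep_idx].copy()
    expanded["start"] = tile * step
    count_cols = [f"{s}.{f}" for s in matrix.samples for f in ("meth", "total")]
    grouped = expanded.groupby(["chrom", "start", "context"], sort=True)
    pooled = grouped[count_cols].sum()
    pooled["n_sites"] = grouped.size()
    pooled = pooled.reset_index()
    pooled["end"] = pooled["start"] + window_size
    return pooled[["chrom", "start", "end", "context", "n_sites"] + count_cols]


class DMRCaller(BaseEstimator):
    """Call DMRs between a focal and a reference sample of a site matrix.

    Parameters
    ----------
    focal, reference : sample names in the matrix; delta = m_focal - m_ref,
        so direction ``hyper`` means focal above reference.
    context : "CG", "CHG" or "CHH"; fixes the default effect-size cutoff and
        site-count minimum.
    window_size, step : tiling in bp (default non-overlapping 100-bp tiles).
    fdr : BH q-value threshold (default 0.05), applied within this
        comparison and context.
    min_delta, min_sites : override the context defaults.

    Attributes
    ----------
    windows_ : all testable windows with m_focal, m_ref, delta, p, q,
        significant, direction.
    dmrs_ : the significant subset.
    """

    def __init__(
        self,
        focal: str,
        reference: str,
        context: str = "CG",
        window_size: int = 100,
        step: int = 100,
        fdr: float = 0.05,
        min_delta: float | None = None,
        min_sites: int | None = None,
    ):
        self.focal = focal
        self.reference = reference
        self.context = context
        self.window_size = window_size
        self.step = step
        self.fdr = fdr
        self.min_delta = min_delta
        self.min_sites = min_sites

    def fit(self, X: SiteMatrix | pd.DataFrame, y=None):
        """X is a SiteMatrix, or a window table from :func:`make_windows`."""
        if self.context not in MIN_SITES:
            raise ValueError(f"unknown context {self.context!r}")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        windows = X if isinstance(X, pd.DataFrame) else make_windows(X, self.window_size, self.step)
        self.windows_ = test_windows(
            windows,
            self.focal,
            self.reference,
            self.context,
            fdr=self.fdr,
            min_delta=self.min_delta,
            min_sites=self.min_sites,
        )
        self.dmrs_ = self.windows_.loc[self.windows_["significant"]].reset_index(drop=True)
        return self


def test_windows(
    windows: pd.DataFrame,
    focal: str,
    reference: str,
    context: str,
    fdr: float = 0.05,
    min_delta: float | None = None,
    min_sites: int | None = None,
) -> pd.DataFrame:
    """Fisher-test every eligible window of one context; annotate DMR status."""
    if context not in MIN_SITES:
        raise ValueError(f"unknown context {context!r}")
    min_sites = MIN_SITES[context] if min_sites is None else min_sites
    min_delta = MIN_DELTA[context] if min_delta is None else min_delta
    fm, ft = windows.get(f"{focal}.meth"), windows.get(f"{focal}.total")
    if fm is None or f"{reference}.meth" not in windows.columns:
        raise ValueError(f"window table lacks counts for {focal!r} or {reference!r}")
    eligible = (
        (windows["context"] == context)
        & (windows["n_sites"] >= min_sites)
        & (windows[f"{focal}.total"] > 0)
        & (windows[f"{reference}.total"] > 0)
    )
    w = windows.loc[eligible, ["chrom", "start", "end", "context", "n_sites"]].copy()
    a = windows.loc[eligible, f"{focal}.meth"].to_numpy(dtype=np.int64)
    at = windows.loc[eligible, f"{focal}.total"].to_numpy(dtype=np.int64)
    c = windows.loc[eligible, f"{reference}.meth"].to_numpy(dtype=np.int64)
    ct = windows.loc[eligible, f"{reference}.total"].to_numpy(dtype=np.int64)
    w["m_focal"] = weighted_methylation(a, at)
    w["m_ref"] = weighted_methylation(c, ct)
    w["delta"] = w["m_focal"] - w["m_ref"]
    if len(w):
        w["p"] = fisher_exact_many(a, at - a, c, ct - c)
        w["q"] = bh_fdr(w["p"].to_numpy())
    else:
        w["p"] = np.array([], dtype=float)
        w["q"] = np.array([], dtype=float)
    w["significant"] = (w["q"] < fdr) & (w["delta"].abs() >= min_delta)
    w["direction"] = np.where(w["delta"] >= 0, "hyper", "hypo")
    w.loc[~w["significant"], "direction"] = "none"
    return w.reset_index(drop=True)


def call_dmrs(
    windows: pd.DataFrame,
    focal: str,
    reference: str,
    context: str,
    fdr: float = 0.05,
    min_delta: float | None = None,
    min_sites: int | None = None,
) -> pd.DataFrame:
    """Significant DMRs only; thin wrapper over :class:`DMRCaller`."""
    caller = DMRCaller(
        focal, reference, context, fdr=fdr, min_delta=min_delta, min_sites=min_sites
    )
    caller.fit(windows)
    return caller.dmrs_
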