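"""Harmonize cytosines across lines into one shared-site matrix.

The analysis compares methylation of the same cytosine across samples, so
before any window statistics the per-line reports are (1) replicate-merged,
(2) coverage-filtered (>= 3 reads by default), (3) intersected to the sites
shared by every sample, and (4) restricted to long, high-scoring homology
blocks so that only conserved positions are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CYTOSINE_COLUMNS

SITE_KEY = ["chrom", "pos", "strand", "context"]


@dataclass
class SiteMatrix:
    """Shared cytosines (rows) x samples (count pairs).

    ``data`` holds the site key columns (chrom, pos, strand, context; pos is
    1-based as in cytosine reports) plus, for every sample ``s``, columns
    ``f"{s}.meth"`` and ``f"{s}.total"``.
    """

    data: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        for s in self.samples:
            if f"{s}.meth" not in self.data.columns or f"{s}.total" not in self.data.columns:
                raise ValueError(f"sample {s!r} missing count columns")

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def counts(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        """(n_meth, n_total) arrays for one sample."""
        return (
            self.data[f"{sample}.meth"].to_numpy(),
            self.data[f"{sample}.total"].to_numpy(),
        )

    def subset(self, mask) -> "SiteMatrix":
        return SiteMatrix(self.data.loc[mask].reset_index(drop=True), list(self.samples))


def merge_replicates(*replicates: pd.DataFrame) -> pd.DataFrame:
    """Sum methylated/unmethylated counts over replicates of the same line.

    A site present in any replicate is present in the merge.  The same
    (chrom, pos, strand) key must not carry two different contexts.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    cat = pd.concat(replicates, ignore_index=True)
    ctx_per_key = cat.groupby(["chrom", "pos", "strand"], sort=False)["context"].nunique()
    if (ctx_per_key > 1).any():
        key = ctx_per_key[ctx_per_key > 1].index[0]
        raise ValueError(f"conflicting context at site {key}")
    merged = (
        cat.groupby(SITE_KEY, sort=False, as_index=False)[["n_meth", "n_unmeth"]].sum()
    )
    merged = merged.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    return merged[CYTOSINE_COLUMNS]


def filter_coverage(records: pd.DataFrame, min_reads: int = 3) -> pd.DataFrame:
    """Keep sites with n_meth + n_unmeth >= min_reads (boundary inclusive)."""
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    total = records["n_meth"] + records["n_unmeth"]
    return records.loc[total >= min_reads].reset_index(drop=True)


def harmonize(records_per_sample: dict[str, pd.DataFrame]) -> SiteMatrix:
    """Intersect site sets over all samples; keep per-sample counts.

    Each input must already be replicate-merged and coverage-filtered.
    """
    if len(records_per_sample) < 2:
        raise ValueError("harmonize needs at least two samples")
    samples = list(records_per_sample)
    merged = None
    for s in samples:
        df = records_per_sample[s].copy()
        df[f"{s}.total"] = df["n_meth"] + df["n_unmeth"]
        df = df.rename(columns={"n_meth": f"{s}.meth"})[SITE_KEY + [f"{s}.meth", f"{s}.total"]]
        merged = df if merged is None else merged.merge(df, on=SITE_KEY, how="inner")
    if merged.empty:
        counts = {s: len(records_per_sample[s]) for s in samples}
        raise ValueError(f"no sites shared by all samples; per-sample site counts: {counts}")
    merged = merged.sort_values(["chrom", "pos", "strand", "context"], kind="mergesort")
    return SiteMatrix(merged.reset_index(drop=True), samples)


def _covered_mask(chrom: pd.Series, pos0: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """True where a 0-based point falls in any [start, end) of its chromosome."""
    keep = np.zeros(len(pos0), dtype=bool)
    for c, sub in intervals.groupby("chrom"):
        sel = (chrom == c).to_numpy()
        if not sel.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        p = pos0[sel]
        # blocks assumed non-overlapping per chromosome: point covered iff
        # more intervals have started than have ended at p
        n_started = np.searchsorted(starts, p, side="right")
        n_ended = np.searchsorted(ends, p, side="right")
        keep[sel] = n_started > n_ended
    return keep


def filter_conserved_regions(
    matrix: SiteMatrix,
    blocks: pd.DataFrame,
    min_len: int = 1000,
    min_score: int = 1000,
    side: str = "a",
) -> SiteMatrix:
    """Restrict the matrix to sites inside qualifying homology blocks.

    A block qualifies when its length is >= ``min_len`` AND its alignment
    score is >= ``min_score`` (short or low-scoring alignments are dropped).
    ``side`` selects which block coordinates the matrix lives on.
    """
    good = blocks.loc[
        ((blocks["end_a"] - blocks["start_a"]) >= min_len) & (blocks["score"] >= min_score)
    ]
    iv = good[[f"chrom_{side}", f"start_{side}", f"end_{side}"]].rename(
        columns={f"chrom_{side}": "chrom", f"start_{side}": "start", f"end_{side}": "end"}
    )
    pos0 = matrix.data["pos"].to_numpy() - 1
    keep = _covered_mask(matrix.data["chrom"], pos0, iv)
    if not keep.any():
        import warnings

        warnings.warn("no sites fall inside qualifying conserved regions", stacklevel=2)
    return matrix.subset(keep)


def liftover_sites(records: pd.DataFrame, blocks: pd.DataFrame, direction: str = "b_to_a") -> pd.DataFrame:
    """Map cytosine records between the two sides of gapless homology blocks.

    Sites outside any block are dropped.  Only ``strand_rel == '+'`` blocks are
    supported (the synthetic homology maps are colinear).
    """
    if direction not in ("b_to_a", "a_to_b"):
        raise ValueError(f"unknown direction {direction!r}")
    src, dst = ("b", "a") if direction == "b_to_a" else ("a", "b")
    if (blocks["strand_rel"] != "+").any():
        raise ValueError("liftover only supports '+' relative orientation")
    out = []
    for c_src, blk in blocks.groupby(f"chrom_{src}"):
        blk = blk.sort_values(f"start_{src}")
        starts = blk[f"start_{src}"].to_numpy()
        ends = blk[f"end_{src}"].to_numpy()
        dst_starts = blk[f"start_{dst}"].to_numpy()
        dst_chroms = blk[f"chrom_{dst}"].to_numpy()
        sub = records.loc[records["chrom"] == c_src]
        if sub.empty:
            continue
        pos0 = sub["pos"].to_numpy() - 1
        i = np.searchsorted(starts, pos0, side="right") - 1
        inside = (i >= 0) & (pos0 < ends[np.maximum(i, 0)])
        sub = sub.loc[inside].copy()
        i = i[inside]
        sub["chrom"] = dst_chroms[i]
        sub["pos"] = sub["pos"].to_numpy() - starts[i] + dst_starts[i]
        out.append(sub)
    if not out:
        return records.iloc[0:0].copy()
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
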