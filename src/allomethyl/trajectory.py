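"""Classify DMR trajectories across generations of allopolyploidy.

Two families of comparisons feed the classifier:

* **A-vs-T** calls — A subgenome versus T subgenome within each line (for the
  parents: *A. arenosa* versus *A. thaliana* on homologous coordinates).
  ``hyper`` means A above T.
* **vs-parent** calls — a line's subgenome versus the corresponding progenitor
  (A subgenome vs Aar; T subgenome vs Ath).

A window is **convergent** when it is an A-over-T hyper-DMR in the parents,
the F1 and both resynthesized lines, but in the natural allotetraploid is no
longer a DMR and its |A - T| difference falls below the context cutoff ("back
to the T level").  It is **conserved** (per line) when it is a hypo-DMR
versus the parent in the natural line and in that earlier line; an all-three
flag marks windows hypo in F1 and both resynthesized lines as well.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .dmr import MIN_DELTA

WINDOW_KEY = ["chrom", "start", "end", "context"]
AVT_LINES = ["parents", "f1", "a733", "a738", "asu"]
CONSERVED_LINES = ["f1", "a733", "a738"]


def _window_index(calls: pd.DataFrame) -> pd.DataFrame:
    return calls.set_index(WINDOW_KEY, verify_integrity=True)


def _aligned(calls_per_line: dict[str, pd.DataFrame], lines) -> dict[str, pd.DataFrame]:
    missing = [ln for ln in lines if ln not in calls_per_line]
    if missing:
        raise ValueError(f"missing DMR calls for line(s): {missing}")
    idx = {ln: _window_index(calls_per_line[ln]) for ln in lines}
    universe = idx[lines[0]].index
    for ln in lines[1:]:
        if not universe.equals(idx[ln].index):
            raise ValueError(f"window universe of {ln!r} differs from {lines[0]!r}")
    return idx


def classify_convergent(
    calls_per_line: dict[str, pd.DataFrame], delta_cutoff: float | None = None
) -> pd.DataFrame:
    """Flag convergent and persistently-hyper windows from A-vs-T calls.

    ``calls_per_line`` maps {parents, f1, a733, a738, asu} to window tables
    from :func:`allomethyl.dmr.test_windows` on a common window universe.
    Returns the window key plus boolean ``hyper_<line>`` flags, ``convergent``
    and ``persistent_hyper``.
    """
    idx = _aligned(calls_per_line, AVT_LINES)
    out = idx["parents"].reset_index()[WINDOW_KEY].copy()
    cutoff = {
        ctx: MIN_DELTA[ctx] if delta_cutoff is None else delta_cutoff
        for ctx in out["context"].unique()
    }
    hyper = {}
    for ln in AVT_LINES:
        t = idx[ln]
        hyper[ln] = (t["significant"] & (t["direction"] == "hyper")).to_numpy()
        if delta_cutoff is not None:
            # re-applying the effect cutoff keeps the classifier consistent
            # when scanned at a cutoff other than the one used for calling
            hyper[ln] &= t["delta"].to_numpy() >= delta_cutoff
        out[f"hyper_{ln}"] = hyper[ln]
        out[f"delta_{ln}"] = t["delta"].to_numpy()
    hyper_through_neo = hyper["parents"] & hyper["f1"] & hyper["a733"] & hyper["a738"]
    asu = idx["asu"]
    cut = out["context"].map(cutoff).to_numpy(dtype=float)
    asu_levelled = (~asu["significant"].to_numpy()) & (
        np.abs(asu["delta"].to_numpy()) < cut
    )
    out["convergent"] = hyper_through_neo & asu_levelled
    out["persistent_hyper"] = hyper_through_neo & hyper["asu"]
    return out


def classify_conserved(
    calls_vs_parent: dict[str, pd.DataFrame]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag conserved hypo-DMRs from vs-parent calls on one subgenome.

    ``calls_vs_parent`` maps {f1, a733, a738, asu} to window tables versus the
    progenitor.  A window is conserved for earlier line L when it is a
    hypo-DMR in the natural line AND in L; ``conserved_all`` requires all
    three earlier lines, ``conserved_any`` at least one.

    Returns ``(flags, fractions)`` where ``fractions`` has one row per line
    (and "all"/"any") with overlap, total (hypo-DMRs in the natural line) and
    the overlap fraction.
    """
    lines = CONSERVED_LINES + ["asu"]
    idx = _aligned(calls_vs_parent, lines)
    out = idx["asu"].reset_index()[WINDOW_KEY].copy()
    hypo = {
        ln: (idx[ln]["significant"] & (idx[ln]["direction"] == "hypo")).to_numpy()
        for ln in lines
    }
    out["hypo_asu"] = hypo["asu"]
    for ln in CONSERVED_LINES:
        out[f"conserved_{ln}"] = hypo["asu"] & hypo[ln]
    out["conserved_all"] = (
        hypo["asu"] & hypo["f1"] & hypo["a733"] & hypo["a738"]
    )
    out["conserved_any"] = out[[f"conserved_{ln}" for ln in CONSERVED_LINES]].any(axis=1)
    total = int(hypo["asu"].sum())
    rows = []
    for name in CONSERVED_LINES + ["all", "any"]:
        col = f"conserved_{name}" if name in CONSERVED_LINES else f"conserved_{name}"
        overlap = int(out[col].sum())
        rows.append(
            {
                "line": name,
                "overlap": overlap,
                "total": total,
                "fraction": overlap / total if total else np.nan,
            }
        )
    return out, pd.DataFrame(rows)


def inheritance_fraction(child_dmrs: set, ancestor_dmrs: set) -> tuple[int, int, float]:
    """(overlap, |child|, |child ∩ ancestor| / |child|); NaN fraction if empty."""
    child = set(child_dmrs)
    overlap = len(child & set(ancestor_dmrs))
    total = len(child)
    return overlap, total, (overlap / total if total else float("nan"))


def overlap_enrichment(set_a, set_b, universe_size: int):
    """Fisher enrichment of the overlap of two window/gene sets.

    Returns (overlap, expected, p, odds_ratio) from the 2x2 table
    [[|a∩b|, |a\\b|], [|b\\a|, rest]].
    """
    a, b = set(set_a), set(set_b)
    if universe_size < len(a | b):
        raise ValueError("universe smaller than the union of the two sets")
    k = len(a & b)
    table = [
        [k, len(a) - k],
        [len(b) - k, universe_size - len(a) - len(b) + k],
    ]
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    expected = len(a) * len(b) / universe_size if universe_size else float("nan")
    return k, expected, float(p), float(odds_ratio)


LABELS = ("both", "convergent", "conserved", "persistent_hyper", "other")


class TrajectoryClassifier(BaseEstimator):
    """Assign one trajectory label per window from the two call families.

    Parameters
    ----------
    delta_cutoff : override of the context-specific "back to the same level"
        cutoff used for the convergence test (defaults to the DMR effect-size
        cutoff of each window's context).

    Attributes
    ----------
    calls_ : per-window flag table (convergence and conservation flags).
    labels_ : per-window label among {both, convergent, conserved,
        persistent_hyper, other}; precedence in that order.
    fractions_ : conserved-fraction summary per earlier line.
    """

    def __init__(self, delta_cutoff: float | None = None):
        self.delta_cutoff = delta_cutoff

    def fit(self, X: dict, y=None):
        """X = {"a_vs_t": {line: window table}, "vs_parent": {line: window table}}."""
        conv = classify_convergent(X["a_vs_t"], self.delta_cutoff)
        cons, fractions = classify_conserved(X["vs_parent"])
        merged = conv.merge(cons, on=WINDOW_KEY, how="inner", validate="one_to_one")
        if len(merged) != len(conv) or len(merged) != len(cons):
            raise ValueError("A-vs-T and vs-parent window universes differ")
        label = np.full(len(merged), "other", dtype=object)
        label[merged["persistent_hyper"].to_numpy()] = "persistent_hyper"
        label[merged["conserved_any"].to_numpy()] = "conserved"
        label[merged["convergent"].to_numpy()] = "convergent"
        label[(merged["convergent"] & merged["conserved_any"]).to_numpy()] = "both"
        merged["label"] = label
        self.calls_ = merged
        self.labels_ = merged.set_index(WINDOW_KEY)["label"]
        self.fractions_ = fractions
        return self

    def summary(self) -> dict:
        counts = self.calls_["label"].value_counts().to_dict()
        return {lab: int(counts.get(lab, 0)) for lab in LABELS}


def classify_trajectories(
    a_vs_t: dict[str, pd.DataFrame],
    vs_parent: dict[str, pd.DataFrame],
    delta_cutoff: float | None = None,
) -> TrajectoryClassifier:
    """Thin functional wrapper over :class:`TrajectoryClassifier`."""
    return TrajectoryClassifier(delta_cutoff).fit({"a_vs_t": a_vs_t, "vs_parent": vs_parent})
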