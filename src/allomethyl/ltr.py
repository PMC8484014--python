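"""Date LTR retrotransposon insertions from 5'/3' LTR divergence.

At insertion the two long terminal repeats of an element are identical; they
then diverge neutrally, so the substitution-corrected distance K between
them, divided by twice the substitution rate r, gives the insertion age
t = K / (2r).  K comes from the Jukes-Cantor one-parameter model,
K = -(3/4) ln(1 - (4/3) d), with d the proportion of mismatched sites.  The
default rate is 7e-9 substitutions per site per generation, with one
generation taken as one year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_RATE = 7e-9


def jc_distance(d):
    """Jukes-Cantor distance K = -(3/4) ln(1 - (4/3) d); requires 0 <= d < 0.75."""
    d_arr = np.asarray(d, dtype=float)
    if np.any((d_arr < 0) | (d_arr >= 0.75)):
        raise ValueError("observed divergence d must satisfy 0 <= d < 0.75 (saturation)")
    k = -0.75 * np.log1p(-(4.0 / 3.0) * d_arr)
    return float(k) if np.isscalar(d) or d_arr.ndim == 0 else k


def insertion_time(k, rate: float = DEFAULT_RATE):
    """Insertion age in years: t = K / (2 r)."""
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 0):
        raise ValueError("K must be non-negative")
    t = k_arr / (2.0 * rate)
    return float(t) if np.isscalar(k) or k_arr.ndim == 0 else t


def pairwise_divergence(seq_a: str, seq_b: str) -> float:
    """Mismatch proportion of two aligned LTR sequences, ignoring gap columns."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    mismatches = compared = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x in "-." or y in "-.":
            continue
        compared += 1
        mismatches += x != y
    if compared == 0:
        raise ValueError("no comparable (non-gap) columns")
    return mismatches / compared


@dataclass(frozen=True)
class LTRPair:
    """One element's LTR divergence and its dating."""

    element_id: str
    d: float
    rate: float = DEFAULT_RATE

    @property
    def k(self) -> float:
        return jc_distance(self.d)

    @property
    def t(self) -> float:
        return insertion_time(self.k, self.rate)


def ltr_ages(table: pd.DataFrame, rate: float = DEFAULT_RATE) -> pd.DataFrame:
    """Add K and t columns to a table with element_id and d."""
    out = table.copy()
    out["K"] = jc_distance(out["d"].to_numpy())
    out["t"] = insertion_time(out["K"].to_numpy(), rate)
    return out


def read_ltr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"element_id", "d"} <= set(df.columns):
        raise ValueError(f"{path}: need columns element_id, d")
    return df
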