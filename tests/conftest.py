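import math
from fractions import Fraction

import pandas as pd
import pytest

from allomethyl.simulate import CohortConfig, simulate_cohort, simulate_expression
from allomethyl.sites import SiteMatrix


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Exact integer arithmetic; a point probability counts toward p when it is
    <= the observed one up to the same 1e-7 relative slack float
    implementations use for ties (exact ties are integer-equal anyway).
    """
    r1, r2, k = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or k == 0 or k == r1 + r2:
        return Fraction(1)
    obs = math.comb(r1, a) * math.comb(r2, k - a)
    total = math.comb(r1 + r2, k)
    acc = 0
    for x in range(max(0, k - r2), min(k, r1) + 1):
        w = math.comb(r1, x) * math.comb(r2, k - x)
        if w * 10**7 <= obs * (10**7 + 1):
            acc += w
    return Fraction(acc, total)


def make_records(rows):
    """Cytosine DataFrame from (chrom, pos, strand, n_meth, n_unmeth, context) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]
    )


def make_matrix(site_rows, counts):
    """SiteMatrix from site tuples and {sample: [(meth, total), ...]}."""
    data = pd.DataFrame(site_rows, columns=["chrom", "pos", "strand", "context"])
    for s, pairs in counts.items():
        data[f"{s}.meth"] = [m for m, _ in pairs]
        data[f"{s}.total"] = [t for _, t in pairs]
    return SiteMatrix(data, list(counts))


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully planted cohort used by several integration tests."""
    return CohortConfig(
        n_tiles=2500,
        contexts=("CG",),
        sites_per_window={"CG": 6},
        n_planted={
            "convergent": 20,
            "conserved": 20,
            "persistent_hyper": 10,
            "hyper": 10,
            "both": 0,
        },
        planted_spacing=40,
        n_background_genes=30,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def small_expression(small_config, small_cohort):
    return simulate_expression(small_cohort.truth, small_cohort.genes, small_config, seed=11)
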