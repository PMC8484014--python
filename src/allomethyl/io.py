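"""Readers and writers for the formats the pipeline consumes and emits.

Coordinate conventions
----------------------
Cytosine positions follow the per-cytosine report convention: ``pos`` is the
1-based position of the cytosine on its strand, exactly as printed in
Bismark-style cytosine/CX reports.  Every *interval* (genes, homology blocks,
windows, DMRs) is 0-based half-open internally; BED input is taken as-is and
GFF3 ``(start, end)`` is converted to ``(start - 1, end)`` on read and back on
write.  A 1-based cytosine at ``pos`` falls in interval ``[s, e)`` iff
``s <= pos - 1 < e``.

Tables are pandas DataFrames throughout; the dataclasses below document the
per-row semantics and are what single-record helpers return.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
#: column order of a cytosine-report DataFrame
CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "homolog_id"]
BLOCK_COLUMNS = [
    "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "score", "strand_rel",
]
EXPRESSION_COLUMNS = ["gene_id", "line", "replicate", "tpm"]

# tokens seen in cytosine reports, normalised to the three canonical contexts
_CONTEXT_ALIASES = {
    "CG": "CG", "CPG": "CG", "CGN": "CG",
    "CHG": "CHG", "CHH": "CHH",
}


@dataclass(frozen=True)
class CytosineRecord:
    """One strand-specific cytosine with its methylated/unmethylated counts."""

    chrom: str
    pos: int          # 1-based, as in the input report
    strand: str       # '+' or '-'
    context: str      # CG / CHG / CHH
    n_meth: int
    n_unmeth: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("read counts must be non-negative")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (0-based half-open) with optional cross-subgenome homolog."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    homolog_id: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty gene interval for {self.gene_id}: [{self.start}, {self.end})")


@dataclass(frozen=True)
class HomologyBlock:
    """A gapless aligned block between two chromosomes (0-based half-open)."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    score: float
    strand_rel: str = "+"

    def __post_init__(self):
        if self.end_a - self.start_a != self.end_b - self.start_b:
            raise ValueError(
                f"homology block sides differ in length: {self.end_a - self.start_a} vs "
                f"{self.end_b - self.start_b}"
            )
        if self.score < 0:
            raise ValueError("alignment score must be non-negative")

    @property
    def length(self) -> int:
        return self.end_a - self.start_a


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_cytosine_report(path, context_filter: str | None = None) -> pd.DataFrame:
    """Read a Bismark-style cytosine report into a cytosine DataFrame.

    Expected columns (tab-separated, no header): chrom, pos (1-based), strand,
    count_methylated, count_unmethylated, context[, trinucleotide].  Rows with
    zero total coverage are retained; filtering happens downstream.

    Parameters
    ----------
    context_filter : optional
        Keep only this context (``"CG"``, ``"CHG"`` or ``"CHH"``).
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >= 6 columns, got {len(fields)}")
            chrom, pos_s, strand, meth_s, unmeth_s, ctx = fields[:6]
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field ({exc})") from None
            if pos < 1:
                raise ValueError(f"{path}: line {lineno}: position must be 1-based (got {pos})")
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}: line {lineno}: negative read count")
            context = _CONTEXT_ALIASES.get(ctx.upper())
            if context is None:
                raise ValueError(f"{path}: line {lineno}: unknown context token {ctx!r}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: strand must be + or -, got {strand!r}")
            rows.append((chrom, pos, strand, n_meth, n_unmeth, context))
    df = pd.DataFrame(rows, columns=CYTOSINE_COLUMNS)
    if context_filter is not None:
        if context_filter not in CONTEXTS:
            raise ValueError(f"unknown context {context_filter!r}")
        df = df[df["context"] == context_filter].reset_index(drop=True)
    return df


def write_cytosine_report(records: pd.DataFrame, path) -> None:
    """Write a cytosine DataFrame back to the 6-column tab-separated report."""
    records = records[CYTOSINE_COLUMNS]
    with _open_text(path, "wt") as fh:
        for row in records.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.strand}\t{row.n_meth}\t{row.n_unmeth}\t{row.context}\n")


def read_genes(path, fmt: str | None = None) -> pd.DataFrame:
    """Read genes from BED6(+) or GFF3 into a gene DataFrame (0-based half-open).

    Format is taken from the extension (``.bed`` / ``.gff``, ``.gff3``) unless
    ``fmt`` is given.  GFF3 coordinates ``(s, e)`` (1-based inclusive) become
    ``(s - 1, e)``; an optional 7th BED column or a ``homolog=`` GFF attribute
    carries the homolog pairing.
    """
    path = Path(path)
    if fmt is None:
        suffixes = [s.lower() for s in path.suffixes]
        if any(s in (".gff", ".gff3") for s in suffixes):
            fmt = "gff3"
        elif ".bed" in suffixes:
            fmt = "bed"
        else:
            raise ValueError(f"cannot infer gene format from {path.name!r}; pass fmt=")
    if fmt == "bed":
        df = _read_genes_bed(path)
    elif fmt == "gff3":
        df = _read_genes_gff3(path)
    else:
        raise ValueError(f"unknown gene format {fmt!r}")
    bad = df["start"] >= df["end"]
    if bad.any():
        first = df.loc[bad].iloc[0]
        raise ValueError(f"empty gene interval for {first.gene_id}: [{first.start}, {first.end})")
    _check_homolog_symmetry(df)
    return df.reset_index(drop=True)


def _read_genes_bed(path) -> pd.DataFrame:
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"{path}: line {lineno}: BED needs >= 4 columns")
            strand = f[5] if len(f) > 5 else "+"
            homolog = f[6] if len(f) > 6 and f[6] != "." else None
            rows.append((f[3], f[0], int(f[1]), int(f[2]), strand, homolog))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def _read_genes_gff3(path) -> pd.DataFrame:
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: line {lineno}: GFF3 needs 9 columns")
            if f[2].lower() != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise ValueError(f"{path}: line {lineno}: gene without ID attribute")
            rows.append(
                (gene_id, f[0], int(f[3]) - 1, int(f[4]), f[6], attrs.get("homolog"))
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def _check_homolog_symmetry(genes: pd.DataFrame) -> None:
    paired = genes.dropna(subset=["homolog_id"])
    partner = dict(zip(paired["gene_id"], paired["homolog_id"]))
    for g, h in partner.items():
        if partner.get(h) not in (None, g):
            raise ValueError(f"homolog pairing not symmetric: {g} -> {h} -> {partner.get(h)}")


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        for r in genes.itertuples(index=False):
            homolog = r.homolog_id if isinstance(r.homolog_id, str) else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t.\t{r.strand}\t{homolog}\n")


def write_genes_gff3(genes: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples(index=False):
            attrs = f"ID={r.gene_id}"
            if isinstance(r.homolog_id, str):
                attrs += f";homolog={r.homolog_id}"
            fh.write(f"{r.chrom}\t.\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n")


def read_homology_map(path) -> pd.DataFrame:
    """Read gapless homology blocks (8-column TSV), sorted by (chrom_a, start_a)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=BLOCK_COLUMNS,
        dtype={"chrom_a": str, "chrom_b": str, "strand_rel": str},
    )
    bad = (df["end_a"] - df["start_a"]) != (df["end_b"] - df["start_b"])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: block {i}: side lengths differ")
    if (df["score"] < 0).any():
        raise ValueError(f"{path}: negative alignment score")
    return df.sort_values(["chrom_a", "start_a"], kind="mergesort").reset_index(drop=True)


def write_homology_map(blocks: pd.DataFrame, path) -> None:
    blocks[BLOCK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_expression(path) -> pd.DataFrame:
    """Read an expression table (TSV: gene_id, line, replicate, tpm)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "line": str})
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: expression table missing columns {sorted(missing)}")
    if (df["tpm"] < 0).any():
        raise ValueError(f"{path}: negative TPM")
    per_line = df.groupby("line")["gene_id"].apply(lambda s: frozenset(s))
    if per_line.nunique() != 1:
        raise ValueError(f"{path}: lines do not share the same gene universe")
    return df[EXPRESSION_COLUMNS]


def write_expression(expr: pd.DataFrame, path) -> None:
    expr[EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


DMR_BED_COLUMNS = [
    "chrom", "start", "end", "context", "m_focal", "m_ref", "delta", "p", "q", "direction",
]


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """Write DMRs as BED3 + (context, m_focal, m_ref, delta, p, q, direction).

    Rows are ordered by (chrom, start, context); a header line (``#``-prefixed)
    is always written so an empty call set still yields a valid file.
    """
    out = dmrs[DMR_BED_COLUMNS].sort_values(
        ["chrom", "start", "context"], kind="mergesort"
    )
    with _open_text(path, "wt") as fh:
        fh.write("#" + "\t".join(DMR_BED_COLUMNS) + "\n")
        for r in out.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.context}\t{r.m_focal:.6g}\t{r.m_ref:.6g}"
                f"\t{r.delta:.6g}\t{r.p:.6g}\t{r.q:.6g}\t{r.direction}\n"
            )


def read_dmr_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df.columns = [c.lstrip("#") for c in df.columns]
    return df[DMR_BED_COLUMNS]
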