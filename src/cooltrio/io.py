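"""File formats: BED3/BED6 intervals, per-cell site-call tables, gene models,
and TSV matrices with explicit NA.

Site-call files are tab-separated with a header
``chrom  pos  context  meth_fraction  depth`` where ``pos`` is 1-based on disk
and converted to the package-wide 0-based convention on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, MergedInterval

CONTEXTS = ("WCG", "GCH")
SITE_COLUMNS = ["chrom", "pos", "context", "meth_fraction", "depth"]


@dataclass
class SiteCallTable:
    """Per-cell cytosine calls (one row per covered site).

    ``data`` columns: ``chrom`` (str), ``pos`` (0-based int), ``context``
    (WCG endogenous methylation / GCH exogenous accessibility),
    ``meth_fraction`` in [0, 1], ``depth`` >= 1 and, after
    :func:`cooltrio.methylome.usable_sites`, a binary ``call`` column.
    """

    cell_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ("chrom", "pos", "context", "meth_fraction", "depth")
                   if c not in df.columns]
        if missing:
            raise ValueError(f"site table missing columns: {missing}")
        bad_ctx = set(df["context"].unique()) - set(CONTEXTS)
        if bad_ctx:
            raise ValueError(f"unknown context value(s): {sorted(bad_ctx)}")
        frac = df["meth_fraction"].to_numpy()
        if len(frac) and (np.nanmin(frac) < 0 or np.nanmax(frac) > 1):
            raise ValueError("meth_fraction outside [0, 1]")
        if len(df) and int(df["depth"].min()) < 1:
            raise ValueError("depth must be >= 1")
        if df.duplicated(subset=["chrom", "pos", "context"]).any():
            dup = df[df.duplicated(subset=["chrom", "pos", "context"], keep=False)]
            rec = dup.iloc[0]
            raise ValueError(
                f"duplicate site for cell {self.cell_id}: "
                f"{rec['chrom']}:{rec['pos']} ({rec['context']})"
            )
        self.data = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, context: str) -> "SiteCallTable":
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        sub = self.data[self.data["context"] == context].reset_index(drop=True)
        return SiteCallTable(self.cell_id, sub)

    @property
    def contexts(self) -> set[str]:
        return set(self.data["context"].unique())


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; skips ``#``, ``track`` and ``browser`` lines."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track") \
                    or line.startswith("browser"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 else ""
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return intervals


def write_bed(
    intervals: Sequence[GenomicInterval | MergedInterval],
    path: str | Path,
    header: str | None = None,
) -> None:
    """Write BED6 (name/score/strand default to ``.``/0/``.``)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for iv in intervals:
            if isinstance(iv, MergedInterval):
                name, score, strand = ",".join(sorted(iv.sources)), iv.support, "."
            else:
                name = iv.name if iv.name else "."
                score, strand = iv.score, iv.strand
            score = int(score) if float(score).is_integer() else score
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n")


def read_site_calls(path: str | Path, cell_id: str | None = None) -> SiteCallTable:
    """Read a per-cell site-call TSV (1-based positions on disk)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.rename(columns={"pos": "pos"})
    df["pos"] = df["pos"].astype(np.int64) - 1  # 1-based on disk -> 0-based
    if (df["pos"] < 0).any():
        raise ValueError(f"{path}: positions must be >= 1 (1-based)")
    if cell_id is None:
        cell_id = Path(path).stem
    return SiteCallTable(cell_id, df[SITE_COLUMNS])


def write_site_calls(table: SiteCallTable, path: str | Path) -> None:
    out = table.data[SITE_COLUMNS].copy()
    out["pos"] = out["pos"] + 1  # back to 1-based on disk
    out.to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Gene models as a 5-column TSV (gene_id, chrom, strand, tss, tes) or BED6."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("gene_id"):
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return [GeneModel(r.gene_id, r.chrom, r.strand, int(r.tss), int(r.tes))
                for r in df.itertuples()]
    genes = []
    for iv in read_bed(path):
        if iv.strand == "+":
            genes.append(GeneModel(iv.name, iv.chrom, "+", iv.start, iv.end))
        elif iv.strand == "-":
            genes.append(GeneModel(iv.name, iv.chrom, "-", iv.end, iv.start))
        else:
            raise ValueError(f"gene {iv.name}: BED gene models need a +/- strand")
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [{"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
             "tss": g.tss, "tes": g.tes} for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Features x cells TSV with 'NA' for missing values."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")
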