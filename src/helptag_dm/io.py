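"""Readers and writers for the plain-text formats used across the pipeline.

Coordinate conventions: BED output is 0-based half-open; GTF output is
1-based inclusive and converted back on read. All tables are tab-delimited
unless the format dictates otherwise.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def write_bed4(loci: pd.DataFrame, path: str | Path) -> None:
    """Write a locus track (chrom, start, end, locus_id) as BED4."""
    loci[["chrom", "start", "end", "locus_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed4(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "locus_id"]
    )
    return df[["locus_id", "chrom", "start", "end"]]


def write_gtf(genes: pd.DataFrame, path: str | Path, source: str = "helptag_dm") -> None:
    """Write gene models as GTF ``gene`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}";'
            fh.write(
                "\t".join(
                    [
                        str(row.chrom),
                        source,
                        "gene",
                        str(int(row.start) + 1),
                        str(int(row.end)),
                        ".",
                        row.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read ``gene`` features from a GTF into the internal 0-based table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            gene_id = None
            for field in f[8].split(";"):
                field = field.strip()
                if field.startswith("gene_id"):
                    gene_id = field.split(None, 1)[1].strip('"')
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                }
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_bed12(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as single-exon BED12 records."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            start, end = int(row.start), int(row.end)
            fh.write(
                "\t".join(
                    [
                        str(row.chrom),
                        str(start),
                        str(end),
                        row.gene_id,
                        "0",
                        row.strand,
                        str(start),
                        str(end),
                        "0",
                        "1",
                        str(end - start) + ",",
                        "0,",
                    ]
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=range(6),
                     names=["chrom", "start", "end", "gene_id", "score", "strand"])
    return df[GENE_COLUMNS]


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                sets[f[0]] = [g for g in f[2:] if g]
    return sets


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
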