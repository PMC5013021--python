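"""Mapping candidate loci and DMRs to gene models via promoter-to-tail windows.

A gene's mapping window runs from 10 kb upstream of its transcription
start site to 10 kb downstream of the transcription end site (strand
aware, clipped at the chromosome start). A locus maps to every gene whose
window overlaps it under half-open interval semantics; a DMR maps when
any member locus does. An alternative mode stops the window at the TES
(no downstream extension).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

WINDOW_COLUMNS = ["gene_id", "chrom", "window_start", "window_end",
                  "start", "end", "strand", "tss", "tes"]


def build_windows(
    genes: pd.DataFrame,
    upstream: int = 10_000,
    downstream: int = 10_000,
    mode: str = "results",
) -> pd.DataFrame:
    """Attach strand-aware mapping windows to a gene table.

    ``genes`` needs gene_id, chrom, start, end (0-based half-open,
    start < end) and strand. For a + strand gene the window is
    [tss - upstream, tes + downstream); for a - strand gene it is
    mirrored. ``mode='methods'`` sets the downstream extension to 0 so the
    window ends at the gene body.
    """
    if mode == "methods":
        downstream = 0
    elif mode != "results":
        raise ValueError("mode must be 'results' or 'methods'")
    g = genes.copy()
    if (g["start"] >= g["end"]).any():
        raise ValueError("gene start must be < end (0-based half-open)")
    bad = ~g["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"invalid strand values: {g.loc[bad, 'strand'].unique()}")
    plus = (g["strand"] == "+").values
    g["tss"] = np.where(plus, g["start"], g["end"] - 1)
    g["tes"] = np.where(plus, g["end"] - 1, g["start"])
    ws = np.where(plus, g["start"] - upstream, g["start"] - downstream)
    we = np.where(plus, g["end"] + downstream, g["end"] + upstream)
    g["window_start"] = np.maximum(0, ws)
    g["window_end"] = we
    return g


def _overlap_pairs(
    q_start: np.ndarray, q_end: np.ndarray,
    w_start: np.ndarray, w_end: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(query, window) index pairs with half-open overlap.

    Queries must be sorted by start. For each window, the candidate query
    range is located by binary search using the largest query length as a
    reach bound, then filtered exactly.
    """
    if len(q_start) == 0 or len(w_start) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    reach = int((q_end - q_start).max())
    lo = np.searchsorted(q_start, w_start - reach + 1, side="left")
    hi = np.searchsorted(q_start, w_end, side="left")
    counts = np.maximum(0, hi - lo)
    w_idx = np.repeat(np.arange(len(w_start)), counts)
    q_idx = (np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
             if counts.sum() else np.empty(0, dtype=np.int64))
    exact = (q_end[q_idx] > w_start[w_idx]) & (q_start[q_idx] < w_end[w_idx])
    return q_idx[exact], w_idx[exact]


def map_loci(
    loci: pd.DataFrame,
    windowed_genes: pd.DataFrame,
    require_shared_chroms: bool = False,
) -> pd.DataFrame:
    """Many-to-many locus-to-gene association table.

    A locus [start, end) maps to every gene whose window overlaps it on
    the same chromosome. The ``relation`` column situates the locus
    relative to the gene body: upstream / body / downstream in
    transcription orientation (promoter side first).
    """
    for col in ("window_start", "window_end"):
        if col not in windowed_genes.columns:
            raise ValueError("run build_windows on the gene table first")
    locus_chroms = set(loci["chrom"].unique())
    gene_chroms = set(windowed_genes["chrom"].unique())
    if require_shared_chroms:
        missing = sorted(locus_chroms - gene_chroms)
        if missing:
            raise ValueError(
                f"chromosomes absent from the gene track: {missing}")
    frames = []
    genes_by_chrom = dict(tuple(windowed_genes.groupby("chrom", sort=False)))
    for chrom, lsub in loci.groupby("chrom", sort=False):
        gsub = genes_by_chrom.get(chrom)
        if gsub is None:
            continue
        ls = lsub["start"].values.astype(np.int64)
        le = lsub["end"].values.astype(np.int64)
        order = np.argsort(gsub["window_start"].values, kind="stable")
        gsub = gsub.iloc[order]
        qi, wi = _overlap_pairs(
            ls, le,
            gsub["window_start"].values.astype(np.int64),
            gsub["window_end"].values.astype(np.int64),
        )
        if qi.size == 0:
            continue
        gs = gsub["start"].values.astype(np.int64)[wi]
        ge = gsub["end"].values.astype(np.int64)[wi]
        plus = (gsub["strand"].values == "+")[wi]
        in_body = (le[qi] > gs) & (ls[qi] < ge)
        before = le[qi] <= gs
        relation = np.where(
            in_body, "body",
            np.where(before == plus, "upstream", "downstream"))
        frames.append(pd.DataFrame({
            "locus_id": lsub["locus_id"].values[qi],
            "gene_id": gsub["gene_id"].values[wi],
            "relation": relation,
        }))
    if not frames:
        return pd.DataFrame(columns=["locus_id", "gene_id", "relation"])
    return pd.concat(frames, ignore_index=True)


def map_dmrs(
    dmr_frame: pd.DataFrame,
    loci: pd.DataFrame,
    windowed_genes: pd.DataFrame,
) -> pd.DataFrame:
    """Associate DMRs with genes through their member loci."""
    assoc = map_loci(loci, windowed_genes)
    by_locus = assoc.groupby("locus_id")["gene_id"].apply(set)
    rows = []
    for i, row in dmr_frame.iterrows():
        members = row["locus_ids"].split(",") if isinstance(
            row["locus_ids"], str) else list(row["locus_ids"])
        hit: set = set()
        for m in members:
            hit |= by_locus.get(m, set())
        for gid in sorted(hit):
            rows.append({"dmr_index": i, "gene_id": gid})
    return pd.DataFrame(rows, columns=["dmr_index", "gene_id"])


def gene_summary(
    assoc: pd.DataFrame,
    candidate_locus_ids,
    windowed_genes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene summary: mapped loci, mapped candidates, DM flag."""
    cand = set(candidate_locus_ids)
    n_loci = assoc.groupby("gene_id").size()
    n_cand = assoc[assoc["locus_id"].isin(cand)].groupby("gene_id").size()
    out = windowed_genes[["gene_id", "chrom", "start", "end", "strand"]].copy()
    out["n_mapped_loci"] = out["gene_id"].map(n_loci).fillna(0).astype(int)
    out["n_candidate_loci"] = out["gene_id"].map(n_cand).fillna(0).astype(int)
    out["differentially_methylated"] = out["n_candidate_loci"] > 0
    return out
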