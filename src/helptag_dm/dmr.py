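"""Run-based detection of differentially methylated regions (DMRs).

A DMR is a run of >= 4 candidate loci that are consecutive in the
ordering of all testable loci (an intervening tested-but-non-candidate
locus breaks the run), with adjacent loci at most 10 kb apart and — by
default — a uniform direction of change. Region coordinates span the
first member's start to the last member's end (0-based half-open).

``find_dmrs`` is the linear-scan implementation; ``dmr_oracle`` is an
independent exhaustive enumerator used for cross-validation in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DMRecord:
    chrom: str
    start: int
    end: int
    n_loci: int
    locus_ids: list[str] = field(repr=False)
    direction: str = ""
    mean_delta: float = 0.0
    min_p: float = 1.0

    def as_row(self) -> dict:
        d = self.__dict__.copy()
        d["locus_ids"] = ",".join(self.locus_ids)
        return d


def _check_sorted(results: pd.DataFrame) -> None:
    for chrom, sub in results.groupby("chrom", sort=False):
        if not sub["start"].is_monotonic_increasing:
            raise ValueError(
                f"results must be pre-sorted by (chrom, start); {chrom} is not "
                "(refusing to re-sort silently)")


def _make_record(rows: pd.DataFrame) -> DMRecord:
    deltas = rows["delta"].values
    return DMRecord(
        chrom=str(rows["chrom"].iloc[0]),
        start=int(rows["start"].iloc[0]),
        end=int(rows["end"].iloc[-1]),
        n_loci=len(rows),
        locus_ids=list(rows["locus_id"]),
        direction="hyper" if deltas.mean() < 0 else "hypo",
        mean_delta=float(deltas.mean()),
        min_p=float(rows["p_value"].min()),
    )


def find_dmrs(
    results: pd.DataFrame,
    min_loci: int = 4,
    max_gap: int = 10_000,
    require_uniform_direction: bool = True,
    break_on_noncandidate: bool = True,
) -> list[DMRecord]:
    """Call maximal candidate runs from a sorted per-locus result table.

    ``results`` must carry locus coordinates, ``candidate``/``testable``
    flags and ``delta``/``p_value`` columns, sorted by (chrom, start).
    Adjacent spacing is measured between consecutive locus starts. With
    ``break_on_noncandidate`` (the default, the literal reading of
    "consecutive"), a testable non-candidate between two candidates breaks
    the run; switching it off gives a gap-only mode.
    """
    _check_sorted(results)
    r = results[results["testable"]].reset_index(drop=True)
    cand_idx = np.flatnonzero(r["candidate"].values)
    if cand_idx.size == 0:
        return []
    chrom = r["chrom"].values
    start = r["start"].values
    sign = np.sign(r["delta"].values)

    out: list[DMRecord] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= min_loci:
            out.append(_make_record(r.iloc[run]))
        run.clear()

    for i in cand_idx:
        if run:
            prev = run[-1]
            breaks = (
                chrom[i] != chrom[prev]
                or start[i] - start[prev] > max_gap
                or (break_on_noncandidate and i != prev + 1)
                or (require_uniform_direction and sign[i] != sign[prev])
            )
            if breaks:
                flush()
        run.append(int(i))
    flush()
    return out


def dmr_oracle(
    results: pd.DataFrame,
    min_loci: int = 4,
    max_gap: int = 10_000,
    require_uniform_direction: bool = True,
    break_on_noncandidate: bool = True,
) -> list[DMRecord]:
    """Exhaustive O(n^2) DMR enumerator for small inputs (tests only).

    Checks every contiguous index window of the testable-locus ordering
    for validity and emits windows that are valid, long enough, and not
    extendable on either side.
    """
    _check_sorted(results)
    r = results[results["testable"]].reset_index(drop=True)
    n = len(r)
    if n > 5000:
        raise ValueError("oracle is for small inputs only")
    chrom = r["chrom"].values
    start = r["start"].values
    cand = r["candidate"].values
    sign = np.sign(r["delta"].values)

    def valid(seq: list[int]) -> bool:
        if not all(cand[i] for i in seq):
            return False
        for a, b in zip(seq, seq[1:]):
            if chrom[a] != chrom[b] or start[b] - start[a] > max_gap:
                return False
            if break_on_noncandidate and b != a + 1:
                return False
            if require_uniform_direction and sign[a] != sign[b]:
                return False
        return True

    # candidate ordering to extend over: all testable indices in gap-only
    # mode collapse to the candidate subsequence
    order = list(range(n)) if break_on_noncandidate else list(np.flatnonzero(cand))
    pos = {idx: k for k, idx in enumerate(order)}

    out = []
    for ai in range(len(order)):
        for bi in range(ai, len(order)):
            seq = order[ai:bi + 1]
            if not valid(seq):
                break  # extending an invalid window cannot make it valid
            left_ext = ai > 0 and valid(order[ai - 1:bi + 1])
            right_ext = bi < len(order) - 1 and valid(order[ai:bi + 2])
            if left_ext or right_ext:
                continue
            if len(seq) >= min_loci:
                out.append(_make_record(r.iloc[seq]))
    out.sort(key=lambda d: (d.chrom, d.start))
    return out


def dmrs_to_frame(dmrs: list[DMRecord]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "n_loci", "locus_ids",
            "direction", "mean_delta", "min_p"]
    return pd.DataFrame([d.as_row() for d in dmrs], columns=cols)


def write_bed(dmrs: list[DMRecord], path) -> None:
    """BED6+3: name, -log10 min p (capped at 99) as score, '.', then
    n_loci, mean_delta, direction."""
    with open(path, "w") as fh:
        for k, d in enumerate(dmrs):
            score = 99.0 if d.min_p <= 0 else min(99.0, -np.log10(d.min_p))
            fh.write("\t".join([
                d.chrom, str(d.start), str(d.end), f"DMR{k + 1:04d}",
                f"{score:.2f}", ".", str(d.n_loci),
                f"{d.mean_delta:.3f}", d.direction]) + "\n")
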