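"""Core in-memory containers shared across pipeline stages.

Two-enzyme tag-count data and derived methylation scores are kept as
pandas DataFrames indexed by locus id, with sample-level metadata (group
labels, library totals) carried alongside so that a table round-trips
through TSV without a sidecar file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LOCUS_COLUMNS = ["locus_id", "chrom", "start", "end"]


def _check_loci(loci: pd.DataFrame) -> pd.DataFrame:
    loci = loci.reset_index(drop=True)
    missing = [c for c in LOCUS_COLUMNS if c not in loci.columns]
    if missing:
        raise ValueError(f"locus table missing columns: {missing}")
    for chrom, sub in loci.groupby("chrom", sort=False):
        if not sub["start"].is_monotonic_increasing:
            raise ValueError(f"loci not coordinate-sorted on {chrom}")
    return loci


@dataclass
class LocusCountTable:
    """Per-locus, per-sample HpaII and MspI tag counts with coordinates.

    ``hpaii`` / ``mspi`` are (locus x sample) integer frames sharing the
    locus_id index; ``groups`` maps sample -> group label; the two
    ``*_totals`` series are per-sample sequencing library totals (tags in
    the whole library, of which the tabulated loci are a subset).
    """

    loci: pd.DataFrame
    hpaii: pd.DataFrame
    mspi: pd.DataFrame
    groups: pd.Series
    hpaii_totals: pd.Series
    mspi_totals: pd.Series

    def __post_init__(self) -> None:
        self.loci = _check_loci(self.loci)
        if (self.hpaii.values < 0).any() or (self.mspi.values < 0).any():
            raise ValueError("tag counts must be non-negative")
        if list(self.hpaii.columns) != list(self.mspi.columns):
            raise ValueError("hpaii and mspi tables must cover the same samples")
        if set(self.groups.index) != set(self.hpaii.columns):
            raise ValueError("group labels must cover every sample")

    @property
    def samples(self) -> list[str]:
        return list(self.hpaii.columns)

    def drop_samples(self, samples: list[str]) -> "LocusCountTable":
        keep = [s for s in self.samples if s not in set(samples)]
        return LocusCountTable(
            self.loci,
            self.hpaii[keep],
            self.mspi[keep],
            self.groups[keep],
            self.hpaii_totals[keep],
            self.mspi_totals[keep],
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.samples:
                fh.write(f"#sample\t{s}\t{self.groups[s]}\t"
                         f"{int(self.hpaii_totals[s])}\t{int(self.mspi_totals[s])}\n")
            wide = self.loci.set_index("locus_id")
            for s in self.samples:
                wide[f"{s}.hpaii"] = self.hpaii[s]
                wide[f"{s}.mspi"] = self.mspi[s]
            wide.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LocusCountTable":
        groups, htot, mtot = {}, {}, {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#sample"):
                    break
                _, s, g, ht, mt = line.rstrip("\n").split("\t")
                groups[s], htot[s], mtot[s] = g, int(ht), int(mt)
        df = pd.read_csv(path, sep="\t", skiprows=len(groups))
        loci = df[LOCUS_COLUMNS].copy()
        idx = df["locus_id"]
        samples = list(groups)
        hpaii = pd.DataFrame(
            {s: df[f"{s}.hpaii"].values for s in samples}, index=idx)
        mspi = pd.DataFrame(
            {s: df[f"{s}.mspi"].values for s in samples}, index=idx)
        return cls(loci, hpaii, mspi, pd.Series(groups),
                   pd.Series(htot, dtype=float), pd.Series(mtot, dtype=float))


@dataclass
class MethylationMatrix:
    """Filtered per-locus methylation scores on the 0-100 scale.

    Score 0 = fully methylated (no HpaII cutting), 100 = unmethylated
    (HpaII tag density matches the MspI reference). NaN marks a locus
    unscorable or filtered for a sample.
    """

    loci: pd.DataFrame
    scores: pd.DataFrame
    groups: pd.Series
    confidence: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.loci = _check_loci(self.loci)
        vals = self.scores.values
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("methylation scores must lie in [0, 100]")

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)

    def group_samples(self, group: str) -> list[str]:
        names = [s for s in self.samples if self.groups[s] == group]
        if not names:
            raise KeyError(f"unknown or empty group label: {group!r}")
        return names

    def subset_loci(self, locus_ids) -> "MethylationMatrix":
        mask = self.loci["locus_id"].isin(set(locus_ids)).values
        conf = self.confidence.loc[mask] if self.confidence is not None else None
        return MethylationMatrix(
            self.loci.loc[mask], self.scores.loc[mask], self.groups, conf)

    def drop_samples(self, samples: list[str]) -> "MethylationMatrix":
        keep = [s for s in self.samples if s not in set(samples)]
        conf = self.confidence[keep] if self.confidence is not None else None
        return MethylationMatrix(self.loci, self.scores[keep],
                                 self.groups[keep], conf)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.samples:
                fh.write(f"#sample\t{s}\t{self.groups[s]}\n")
            wide = self.loci.set_index("locus_id").join(self.scores)
            wide.to_csv(fh, sep="\t", float_format="%.4f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MethylationMatrix":
        groups = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#sample"):
                    break
                _, s, g = line.rstrip("\n").split("\t")
                groups[s] = g
        df = pd.read_csv(path, sep="\t", skiprows=len(groups))
        loci = df[LOCUS_COLUMNS].copy()
        scores = df.set_index("locus_id")[list(groups)]
        return cls(loci, scores, pd.Series(groups))
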