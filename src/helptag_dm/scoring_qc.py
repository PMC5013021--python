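"""Methylation scoring and quality control for two-enzyme count tables.

The methylation score of a locus in a sample compares the sample's
depth-normalized HpaII tag density with a locus-matched MspI reference
density (here pooled across all samples, mirroring a pre-built
methylation-insensitive reference):

    score = 100 * min(1, (hpaii / hpaii_library_total)
                         / (mspi_ref / mspi_ref_total))

so 0 means fully methylated (HpaII cannot cut) and 100 unmethylated.
Loci with no MspI reference coverage are unscorable.

Confidence scores weigh both enzymes' read depth; loci whose confidence in
any sample falls well below the locus's expected (across-sample mean)
confidence are excluded from between-group comparisons, and samples with
an overrepresentation of zero scores are flagged and removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .containers import LocusCountTable, MethylationMatrix


class EmptyResultError(ValueError):
    """Raised when confidence filtering removes every locus."""


def mspi_reference(counts: LocusCountTable) -> tuple[pd.Series, float]:
    """Pooled MspI reference: per-locus tag totals and the library total."""
    ref = counts.mspi.sum(axis=1).astype(float)
    total = float(counts.mspi_totals.sum())
    if total <= 0:
        raise ValueError("all-zero MspI library")
    return ref, total


def compute_scores(counts: LocusCountTable) -> MethylationMatrix:
    """Convert paired counts into 0-100 methylation scores.

    HpaII density can stochastically exceed the MspI reference density, so
    the ratio is clipped at 1 to keep the bounded scale.
    """
    if (counts.hpaii_totals <= 0).any():
        raise ValueError("every sample needs a positive HpaII library total")
    ref, ref_total = mspi_reference(counts)
    ref_density = ref.values / ref_total  # per-locus reference density
    scorable = ref_density > 0

    scores = np.full(counts.hpaii.shape, np.nan)
    for j, s in enumerate(counts.samples):
        dens = counts.hpaii[s].values / float(counts.hpaii_totals[s])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = dens / ref_density
        scores[scorable, j] = 100.0 * np.minimum(1.0, ratio[scorable])
    mat = pd.DataFrame(scores, index=counts.hpaii.index,
                       columns=counts.samples)
    conf = compute_confidence(counts)
    return MethylationMatrix(counts.loci, mat, counts.groups, conf)


def compute_confidence(counts: LocusCountTable) -> pd.DataFrame:
    """Per-locus, per-sample confidence from both enzymes' read depth.

    confidence = (mspi_ref / mspi_ref_total) * mean_depth
                 * (1 - exp(-(hpaii + mspi_ref)))

    Monotone non-decreasing in both the HpaII count and the MspI reference
    count; zero when the locus has no reference coverage.
    """
    ref, ref_total = mspi_reference(counts)
    mean_depth = float(
        np.mean(np.concatenate([counts.hpaii_totals.values,
                                counts.mspi_totals.values])))
    base = (ref.values / ref_total) * mean_depth
    damp = 1.0 - np.exp(-(counts.hpaii.values + ref.values[:, None]))
    return pd.DataFrame(base[:, None] * damp,
                        index=counts.hpaii.index, columns=counts.samples)


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    n_unscorable: int
    n_low_confidence: int
    threshold_factor: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def filter_loci(
    matrix: MethylationMatrix,
    confidence: pd.DataFrame | None = None,
    threshold_factor: float = 0.5,
    per_locus: bool = True,
) -> tuple[MethylationMatrix, FilterReport]:
    """Drop loci whose confidence falls below the expected mean by locus.

    A locus is removed when any sample's confidence is below
    ``threshold_factor`` times the expected confidence — the across-sample
    mean at that locus (``per_locus=True``, default) or the global mean
    confidence (``per_locus=False``). Loci unscorable in any sample are
    removed as well, so retained loci are complete across samples.
    """
    conf = matrix.confidence if confidence is None else confidence
    if conf is None:
        raise ValueError("confidence scores required; run compute_scores first")
    conf = conf[matrix.samples]
    scorable = ~matrix.scores.isna().any(axis=1).values
    if per_locus:
        expected = conf.mean(axis=1).values[:, None]
    else:
        expected = float(conf.values.mean())
    ok = (conf.values >= threshold_factor * expected).all(axis=1)
    keep = scorable & ok
    report = FilterReport(
        n_input=len(matrix.loci),
        n_retained=int(keep.sum()),
        n_unscorable=int((~scorable).sum()),
        n_low_confidence=int((scorable & ~ok).sum()),
        threshold_factor=threshold_factor,
    )
    if not keep.any():
        raise EmptyResultError("confidence filtering removed every locus")
    filtered = MethylationMatrix(
        matrix.loci.loc[keep], matrix.scores.loc[keep],
        matrix.groups, conf.loc[keep])
    return filtered, report


def sample_qc(
    matrix: MethylationMatrix,
    mad_multiplier: float = 3.0,
    zero_tol: float = 1e-9,
) -> list[str]:
    """Flag samples with an overrepresentation of zero scores.

    A sample is flagged when its fraction of zero-score loci exceeds the
    across-sample median by more than ``mad_multiplier`` robust MADs.
    Flagged samples should be dropped before group comparisons.
    """
    if len(matrix.samples) < 3:
        warnings.warn("fewer than 3 samples: zero-inflation QC skipped")
        return []
    zero_frac = (matrix.scores <= zero_tol).mean(axis=0)
    med = float(zero_frac.median())
    mad = float(median_abs_deviation(zero_frac.values, scale="normal"))
    cut = med + mad_multiplier * max(mad, 1e-12)
    return [s for s in matrix.samples if zero_frac[s] > cut]
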