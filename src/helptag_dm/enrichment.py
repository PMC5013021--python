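"""Gene-set enrichment with correction for per-gene assayed-site bias.

Genes with more assayed HpaII sites have more chances to contain a
candidate locus, so naive set enrichment is biased toward long,
site-rich genes. The correction estimates the probability of being
called differentially methylated as a function of site count (by
quantile bins) and uses those probabilities as sampling weights: null
draws of |DM| genes are taken from the universe without replacement with
probability proportional to the weights, and over/under-representation
p-values are the add-one-corrected tail fractions of the sampled overlap
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EnrichmentResult:
    set_name: str
    n_set: int
    n_dm_in_set: int
    p_over: float
    p_under: float
    n_samples: int
    seed: int


def compute_bias_weights(
    site_counts: pd.Series,
    dm_flags: pd.Series,
    n_bins: int = 10,
    floor: float | None = None,
) -> pd.Series:
    """Per-gene sampling weights from the DM rate of site-count bins.

    Genes are binned by quantiles of their HpaII-site counts; a gene's
    raw weight is the empirical P(DM | bin), floored at a pseudo-count
    rate (default 0.5 / universe size) so no gene is unsampleable.
    Weights are normalized to sum to one over the universe.
    """
    if (site_counts < 0).any():
        raise ValueError("site counts must be non-negative")
    dm_flags = dm_flags.reindex(site_counts.index).fillna(False).astype(bool)
    if dm_flags.sum() == 0:
        raise ValueError("need at least one differentially methylated gene")
    if floor is None:
        floor = 0.5 / len(site_counts)
    try:
        bins = pd.qcut(site_counts.rank(method="first"), q=n_bins,
                       labels=False, duplicates="drop")
    except ValueError:
        bins = pd.Series(0, index=site_counts.index)
    if site_counts.nunique() == 1 or bins.nunique() == 1:
        warnings.warn("no site-count variation: uniform weights")
        w = pd.Series(1.0, index=site_counts.index)
        return w / w.sum()
    rate = dm_flags.groupby(bins).mean()
    w = bins.map(rate).astype(float).clip(lower=floor)
    return w / w.sum()


def _weighted_draw_overlaps(
    weights: np.ndarray,
    set_mask: np.ndarray,
    k: int,
    n_samples: int,
    rng: np.random.Generator,
    chunk: int = 500,
) -> np.ndarray:
    """Overlap sizes between a gene set and weighted size-k null draws.

    Sampling without replacement with probability proportional to weights
    uses the Gumbel top-k trick: perturb log-weights with Gumbel noise
    and take the k largest keys (equivalent to sequential weighted
    sampling without replacement).
    """
    if k == 0:
        return np.zeros(n_samples, dtype=np.int64)
    logw = np.log(weights)
    out = np.empty(n_samples, dtype=np.int64)
    done = 0
    while done < n_samples:
        c = min(chunk, n_samples - done)
        keys = logw[None, :] + rng.gumbel(size=(c, len(weights)))
        top = np.argpartition(-keys, k - 1, axis=1)[:, :k]
        out[done:done + c] = set_mask[top].sum(axis=1)
        done += c
    return out


def weighted_enrichment(
    gene_set,
    dm_genes,
    weights: pd.Series,
    n_samples: int = 10_000,
    seed: int = 0,
    set_name: str = "",
    _overlaps: np.ndarray | None = None,
) -> EnrichmentResult:
    """Over/under-representation of DM genes in one set by weighted sampling.

    p_over = (1 + #{draws with overlap >= observed}) / (n_samples + 1),
    p_under analogously with <=. Weights only need to be proportional;
    they are renormalized internally.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    universe = list(weights.index)
    uset = set(universe)
    if len(set(dm_genes)) > len(universe):
        raise ValueError("more DM genes than universe genes")
    members = [g for g in gene_set if g in uset]
    dm = [g for g in dm_genes if g in uset]
    observed = len(set(members) & set(dm))
    w = weights.values.astype(float)
    w = w / w.sum()
    if _overlaps is None:
        rng = np.random.default_rng(seed)
        pos = {g: i for i, g in enumerate(universe)}
        mask = np.zeros(len(universe), dtype=bool)
        mask[[pos[g] for g in members]] = True
        _overlaps = _weighted_draw_overlaps(w, mask, len(dm), n_samples, rng)
    p_over = (1 + int((_overlaps >= observed).sum())) / (n_samples + 1)
    p_under = (1 + int((_overlaps <= observed).sum())) / (n_samples + 1)
    return EnrichmentResult(set_name, len(members), observed,
                            p_over, p_under, n_samples, seed)


def enrich_all(
    collection: dict[str, list[str]],
    dm_genes,
    weights: pd.Series,
    n_samples: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Weighted-sampling enrichment for every set in a GMT-shaped dict.

    The null draws are shared across sets (one sampling pass), which
    leaves each set's p-values within Monte-Carlo tolerance of
    independent runs. Empty sets (after universe intersection) are
    dropped with a warning. Results are sorted by p_over.
    """
    universe = list(weights.index)
    uset = set(universe)
    dm = [g for g in dm_genes if g in uset]
    w = weights.values.astype(float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    pos = {g: i for i, g in enumerate(universe)}

    logw = np.log(w)
    k = len(dm)
    masks, names = [], []
    for name, members in collection.items():
        inter = [g for g in members if g in uset]
        if not inter:
            warnings.warn(f"gene set {name!r} empty after universe intersection")
            continue
        m = np.zeros(len(universe), dtype=bool)
        m[[pos[g] for g in inter]] = True
        masks.append(m)
        names.append(name)
    if not names:
        return pd.DataFrame(columns=[
            "set_name", "n_set", "n_dm_in_set", "p_over", "p_under",
            "n_samples", "seed"])
    mask_mat = np.stack(masks)  # (n_sets, n_universe)
    counts = np.zeros((len(names), n_samples), dtype=np.int64)
    done, chunk = 0, 500
    while done < n_samples and k > 0:
        c = min(chunk, n_samples - done)
        keys = logw[None, :] + rng.gumbel(size=(c, len(universe)))
        top = np.argpartition(-keys, k - 1, axis=1)[:, :k]
        sel = np.zeros((c, len(universe)), dtype=bool)
        sel[np.repeat(np.arange(c), k), top.ravel()] = True
        counts[:, done:done + c] = mask_mat @ sel.T.astype(np.int64)
        done += c
    dm_set = set(dm)
    rows = []
    for i, name in enumerate(names):
        inter = [g for g in collection[name] if g in uset]
        observed = len(set(inter) & dm_set)
        over = (1 + int((counts[i] >= observed).sum())) / (n_samples + 1)
        under = (1 + int((counts[i] <= observed).sum())) / (n_samples + 1)
        rows.append({"set_name": name, "n_set": len(inter),
                     "n_dm_in_set": observed, "p_over": over,
                     "p_under": under, "n_samples": n_samples, "seed": seed})
    return (pd.DataFrame(rows)
            .sort_values("p_over", kind="stable")
            .reset_index(drop=True))
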