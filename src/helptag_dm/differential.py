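"""Per-locus differential methylation testing and calibration.

Candidate loci ("loci of interest") are called from a pooled-variance
two-sided t-test per locus, with an absolute mean-score difference above
30 units AND p below 0.005 (both strict). Direction follows the bounded
score scale: delta = exposed mean - control mean, so delta < 0 is
hypermethylation (toward methylated) and delta > 0 hypomethylation.

Multiple-testing behaviour is controlled by a label-permutation null:
permuted per-locus p-values are pooled into a single distribution and a
candidate survives correction when its observed p is more extreme than
97.5% of that pooled distribution. A simulation-based power calculation
(with a closed-form noncentral-t counterpart) calibrates the thresholds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .containers import MethylationMatrix

RESULT_COLUMNS = ["locus_id", "chrom", "start", "end", "n_a", "n_b",
                  "delta", "t_stat", "p_value", "testable", "direction"]


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized equal-variance two-sample t-test along axis 1.

    Returns (delta, t, p, df, testable) where delta = mean(b) - mean(a).
    NaNs are treated as missing values.
    """
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        var_a = np.nanvar(a, axis=1, ddof=1)
        var_b = np.nanvar(b, axis=1, ddof=1)
    delta = mean_b - mean_a
    df = n_a + n_b - 2
    enough = (n_a >= 2) & (n_b >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / np.where(df > 0, df, 1)
        se = np.sqrt(sp2 * (1.0 / np.where(n_a > 0, n_a, 1)
                            + 1.0 / np.where(n_b > 0, n_b, 1)))
        t = delta / se
    degenerate = enough & (se == 0) & (delta == 0)
    testable = enough & ~degenerate
    p = np.full(a.shape[0], np.nan)
    finite_t = testable & np.isfinite(t)
    p[finite_t] = 2.0 * stats.t.sf(np.abs(t[finite_t]), df[finite_t])
    p[testable & np.isinf(t)] = 0.0  # zero variance, nonzero difference
    return delta, t, p, df, testable


def loci_t_test(
    matrix: MethylationMatrix,
    group_a: str,
    group_b: str,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sided per-locus t-test of group_b (exposed) against group_a (control).

    delta is the exposed-minus-control mean score difference. Loci with
    fewer than two non-missing values in either group, or with no
    within-group variance and equal means, are reported with
    ``testable=False`` rather than dropped.
    """
    a = matrix.scores[matrix.group_samples(group_a)].values
    b = matrix.scores[matrix.group_samples(group_b)].values
    if welch:
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False,
                               nan_policy="omit")
        n_a = np.sum(~np.isnan(a), axis=1)
        n_b = np.sum(~np.isnan(b), axis=1)
        delta = np.nanmean(b, axis=1) - np.nanmean(a, axis=1)
        testable = (n_a >= 2) & (n_b >= 2) & np.isfinite(p)
    else:
        delta, t, p, _, testable = _pooled_t(a, b)
        n_a = np.sum(~np.isnan(a), axis=1)
        n_b = np.sum(~np.isnan(b), axis=1)
    direction = np.where(delta < 0, "hyper", np.where(delta > 0, "hypo", ""))
    out = matrix.loci[["locus_id", "chrom", "start", "end"]].copy()
    out["n_a"], out["n_b"] = n_a, n_b
    out["delta"], out["t_stat"], out["p_value"] = delta, t, p
    out["testable"] = testable
    out["direction"] = direction
    return out


def select_candidates(
    results: pd.DataFrame,
    min_abs_delta: float = 30.0,
    max_p: float = 0.005,
) -> pd.DataFrame:
    """Apply the strict candidate gates |delta| > 30 and p < 0.005.

    Returns the candidate rows sorted by p-value then descending |delta|.
    The input frame gains a boolean ``candidate`` column in place.
    """
    cand = (
        results["testable"].values
        & (np.abs(results["delta"].values) > min_abs_delta)
        & (results["p_value"].values < max_p)
    )
    results["candidate"] = cand
    out = results.loc[cand].copy()
    out["abs_delta"] = out["delta"].abs()
    out = out.sort_values(["p_value", "abs_delta"],
                          ascending=[True, False]).drop(columns="abs_delta")
    return out.reset_index(drop=True)


def direction_enrichment(results: pd.DataFrame) -> tuple[float, float]:
    """Fisher's exact test for hyper/hypo imbalance among candidates.

    2x2 table: {candidate, non-candidate} x {hyper (delta<0), hypo
    (delta>0)}; zero-delta loci are excluded. Returns (odds_ratio, p).
    An empty stratum yields (nan or inf, 1.0) with a warning.
    """
    if "candidate" not in results.columns:
        raise ValueError("run select_candidates first")
    r = results[results["testable"] & (results["delta"] != 0)]
    cand = r["candidate"].values
    hyper = (r["delta"] < 0).values
    table = np.array([
        [int((cand & hyper).sum()), int((cand & ~hyper).sum())],
        [int((~cand & hyper).sum()), int((~cand & ~hyper).sum())],
    ])
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        warnings.warn("empty stratum in direction table; p set to 1")
        odds = np.nan
        if table[0, 1] == 0 and table[0, 0] > 0:
            odds = math.inf
        return odds, 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    if table[0, 1] == 0 or table[1, 0] == 0:
        odds = math.inf  # documented convention for a zero cell
    return float(odds), float(p)


@dataclass
class PermutationCorrection:
    threshold_p: float
    n_perm: int
    n_distinct_available: int
    seed: int
    corrected: pd.Series  # locus_id -> bool (candidates only)


def permutation_correction(
    matrix: MethylationMatrix,
    group_a: str,
    group_b: str,
    results: pd.DataFrame,
    n_perm: int = 400,
    seed: int = 0,
    quantile: float = 0.025,
) -> PermutationCorrection:
    """Label-permutation correction of the candidate list.

    Group labels are shuffled across the pooled samples ``n_perm`` times
    (the identity assignment included once as the first draw); each
    permutation's per-locus p-values are pooled into one permuted-p
    distribution. A candidate is corrected-significant iff its observed p
    is at or below the ``quantile`` (default 2.5%) point of that pooled
    distribution — i.e. more extreme than 97.5% of permuted values,
    a two-tailed 5% criterion.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if "candidate" not in results.columns:
        raise ValueError("run select_candidates first")
    rng = np.random.default_rng(seed)
    samples_a = matrix.group_samples(group_a)
    samples_b = matrix.group_samples(group_b)
    pooled = matrix.scores[samples_a + samples_b].values
    n_a = len(samples_a)
    n_tot = pooled.shape[1]
    n_distinct = math.comb(n_tot, n_a)
    if n_distinct < 2:
        raise ValueError("not enough samples to permute")
    if n_distinct < n_perm:
        warnings.warn(
            f"only {n_distinct} distinct label assignments for {n_perm} "
            "permutations; sampling with replacement from the distinct set")
    perm_ps = []
    for k in range(n_perm):
        if k == 0:
            order = np.arange(n_tot)  # identity: reproduces observed p's
        else:
            order = rng.permutation(n_tot)
        a = pooled[:, order[:n_a]]
        b = pooled[:, order[n_a:]]
        _, _, p, _, testable = _pooled_t(a, b)
        perm_ps.append(p[testable])
    pooled_ps = np.concatenate(perm_ps)
    threshold = float(np.quantile(pooled_ps, quantile))
    cand = results[results["candidate"]]
    corrected = pd.Series(
        (cand["p_value"].values <= threshold),
        index=cand["locus_id"].values, name="corrected_significant")
    return PermutationCorrection(
        threshold_p=threshold, n_perm=n_perm,
        n_distinct_available=n_distinct, seed=seed, corrected=corrected)


@dataclass
class PowerEstimate:
    n_per_group: int
    n_per_group_b: int
    sd: float
    delta: float
    alpha: float
    n_sim: int
    power: float
    mc_se: float
    seed: int

    @property
    def analytic_power(self) -> float:
        """Closed-form noncentral-t power for the same configuration."""
        return analytic_power(self.n_per_group, self.sd, self.delta,
                              self.alpha, self.n_per_group_b)


def analytic_power(n_per_group: int, sd: float, delta: float,
                   alpha: float, n_per_group_b: int | None = None) -> float:
    """Exact power of the pooled two-sided t-test via the noncentral t."""
    n_a = n_per_group
    n_b = n_per_group if n_per_group_b is None else n_per_group_b
    df = n_a + n_b - 2
    ncp = delta / (sd * math.sqrt(1.0 / n_a + 1.0 / n_b))
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp))


def power_simulation(
    n_per_group: int = 5,
    sd: float = 10.0,
    delta: float = 30.0,
    alpha: float = 0.005,
    n_sim: int = 1000,
    seed: int = 0,
    n_per_group_b: int | None = None,
) -> PowerEstimate:
    """Monte-Carlo power of the per-locus t-test at the candidate p-gate.

    Simulates ``n_sim`` two-group normal datasets whose means differ by
    ``delta`` with common SD ``sd`` and counts the fraction rejected by a
    pooled two-sided t-test at level ``alpha``.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    n_b = n_per_group if n_per_group_b is None else n_per_group_b
    a = rng.normal(0.0, sd, size=(n_sim, n_per_group))
    b = rng.normal(delta, sd, size=(n_sim, n_b))
    _, _, p, _, testable = _pooled_t(a, b)
    power = float(np.mean(p[testable] < alpha))
    mc_se = math.sqrt(power * (1.0 - power) / n_sim)
    return PowerEstimate(n_per_group, n_b, sd, delta, alpha, n_sim,
                         power, mc_se, seed)


def cluster_loci(
    matrix: MethylationMatrix,
    locus_ids,
    by: str = "samples",
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering (Euclidean, average linkage) of a locus subset.

    ``by='samples'`` clusters the sample profiles over the selected loci
    (the heatmap column tree); ``by='loci'`` clusters the loci themselves.
    Returns (linkage matrix, leaf labels in dendrogram order); a single
    observation yields an empty linkage and the trivial order.
    """
    sub = matrix.subset_loci(locus_ids)
    data = sub.scores.values
    if by == "samples":
        obs = np.nan_to_num(data.T, nan=float(np.nanmean(data)))
        labels = sub.samples
    elif by == "loci":
        obs = np.nan_to_num(data, nan=float(np.nanmean(data)))
        labels = list(sub.scores.index)
    else:
        raise ValueError("by must be 'samples' or 'loci'")
    if len(labels) == 0:
        raise ValueError("empty locus subset")
    if len(labels) == 1:
        return np.empty((0, 4)), labels
    z = linkage(pdist(obs, metric="euclidean"), method="average")
    order = leaves_list(z)
    return z, [labels[i] for i in order]
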