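"""Relative qPCR expression analysis by the 2^-ddCt method.

Per animal, replicate Ct values are averaged per gene, the reference
gene's Ct is subtracted (dCt), and the calibrator group's mean dCt is
subtracted again (ddCt); fold change is 2^-ddCt. Group-level fold
changes are reported as 2^-mean(ddCt) — the geometric-mean fold — so the
calibrator group sits at exactly 1, with the SEM taken over per-animal
folds. Group differences are tested by one-way ANOVA on the ddCt scale
followed by Tukey's HSD for all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

REQUIRED = ["animal_id", "group", "gene", "replicate", "ct"]


@dataclass
class ExpressionResult:
    gene: str
    calibrator_group: str
    per_animal: pd.DataFrame = field(repr=False)  # animal, group, dct, ddct, fold
    group_stats: pd.DataFrame = field(repr=False)  # group, mean_fold, sem_fold, n
    anova_f: float | None = None
    anova_p: float | None = None
    tukey: pd.DataFrame | None = field(default=None, repr=False)


def _mean_ct(ct_table: pd.DataFrame, gene: str,
             spread_warn: float | None = None) -> pd.Series:
    sub = ct_table[ct_table["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from the Ct table")
    if spread_warn is not None:
        spread = sub.groupby("animal_id")["ct"].agg(lambda x: x.max() - x.min())
        wide = spread[spread > spread_warn]
        if len(wide):
            import warnings
            warnings.warn(
                f"{gene}: replicate Ct spread > {spread_warn} cycles for "
                f"animals {list(wide.index)}")
    return sub.groupby("animal_id")["ct"].mean()


def ddct_fold_change(
    ct_table: pd.DataFrame,
    target_gene: str,
    ref_gene: str = "Rps3",
    calibrator_group: str | None = None,
    replicate_spread_warn: float | None = None,
) -> ExpressionResult:
    """Fold change of a target gene relative to a reference gene.

    dCt = mean target Ct - mean reference Ct per animal;
    ddCt = dCt - mean(dCt over calibrator-group animals); fold = 2^-ddCt.
    """
    missing = [c for c in REQUIRED if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    target = _mean_ct(ct_table, target_gene, replicate_spread_warn)
    ref = _mean_ct(ct_table, ref_gene, replicate_spread_warn)
    if not target.index.equals(ref.index):
        both = target.index.intersection(ref.index)
        if len(both) < len(target.index):
            raise ValueError(
                f"reference gene {ref_gene!r} missing for some animals")
        ref = ref[target.index]
    groups = (ct_table[["animal_id", "group"]]
              .drop_duplicates().set_index("animal_id")["group"])
    if calibrator_group is None:
        calibrator_group = groups.iloc[0]
    cal_animals = groups[groups == calibrator_group].index
    if len(cal_animals) == 0:
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")
    dct = target - ref
    ddct = dct - dct[cal_animals].mean()
    fold = np.power(2.0, -ddct)
    per_animal = pd.DataFrame({
        "animal_id": dct.index,
        "group": groups[dct.index].values,
        "dct": dct.values,
        "ddct": ddct.values,
        "fold": fold.values,
    })
    rows = []
    for g, sub in per_animal.groupby("group", sort=False):
        n = len(sub)
        rows.append({
            "group": g,
            "mean_fold": float(2.0 ** (-sub["ddct"].mean())),
            "sem_fold": float(sub["fold"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "n": n,
        })
    return ExpressionResult(target_gene, calibrator_group,
                            per_animal, pd.DataFrame(rows))


def anova_tukey(
    values_by_group: dict[str, np.ndarray] | pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[float, float, pd.DataFrame]:
    """One-way fixed-effects ANOVA plus Tukey HSD over all group pairs.

    Accepts either {group: values} or a DataFrame with ``group`` and a
    single value column. Returns (F, p, tukey table with columns
    group1/group2/meandiff/p_adj/reject).
    """
    if isinstance(values_by_group, pd.DataFrame):
        value_col = [c for c in values_by_group.columns if c != "group"][0]
        values_by_group = {
            g: sub[value_col].values
            for g, sub in values_by_group.groupby("group", sort=False)}
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    if all(np.allclose(a.var(), 0.0) for a in arrays):
        raise ValueError("zero within-group variance everywhere: "
                         "ANOVA is degenerate")
    f_stat, p = stats.f_oneway(*arrays)
    flat = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
    hsd = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    tukey = pd.DataFrame(
        hsd.summary().data[1:],
        columns=[str(c) for c in hsd.summary().data[0]],
    ).rename(columns={"p-adj": "p_adj"})
    return float(f_stat), float(p), tukey


def analyze_expression(
    ct_table: pd.DataFrame,
    target_gene: str,
    ref_gene: str = "Rps3",
    calibrator_group: str | None = None,
) -> ExpressionResult:
    """Fold changes plus ANOVA/Tukey on the ddCt scale for one target gene."""
    res = ddct_fold_change(ct_table, target_gene, ref_gene, calibrator_group)
    by_group = {g: sub["ddct"].values
                for g, sub in res.per_animal.groupby("group", sort=False)}
    if len(by_group) >= 2 and all(len(v) >= 2 for v in by_group.values()):
        res.anova_f, res.anova_p, res.tukey = anova_tukey(by_group)
    return res
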