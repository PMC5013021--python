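"""Synthetic two-enzyme methylation data with known ground truth.

Emulates a HELP-tagging style experiment: CCGG loci spaced ~2 kb apart on
average, four animal groups (young control, maternal undernutrition,
maternal overnutrition, aged), per-locus tag counts for a
methylation-sensitive enzyme (HpaII) and a methylation-insensitive
reference (MspI), gene models with widely varying numbers of assayed
sites, gene sets, and qPCR Ct tables.

Direction convention (fixed repo-wide): score 100 = unmethylated, so
"hypermethylation" is a score DECREASE and "hypomethylation" a score
increase relative to control. The undernutrition group defaults to
hypermethylation spikes, the aged group to hypomethylation, and the
overnutrition group to mixed-direction spikes with no net shift.

Every generator is deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import LocusCountTable

HYPER = "hyper"  # score decrease: toward methylated
HYPO = "hypo"    # score increase: toward unmethylated
MIXED = "mixed"

TRUTH_COLUMNS = ["locus_id", "group", "true_delta", "dmr_block"]


class ConfigError(ValueError):
    pass


class SizingError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults follow the study design this generator emulates: groups
    Con/UN/ON/Old with 5/6/5/6 animals, loci every ~2000 bp, within-group
    score SD of 10 units, and spiked absolute effects of 30 score units.
    """

    n_chromosomes: int = 10
    chromosome_length: int = 25_000_000
    n_loci: int = 100_000
    mean_locus_spacing: float = 2000.0
    groups: tuple = (("Con", 5), ("UN", 6), ("ON", 5), ("Old", 6))
    control_group: str = "Con"
    # two-component baseline on [0,100]: (weight, mean) pairs, CpG-like bimodality
    baseline_mixture: tuple = ((0.5, 15.0), (0.5, 85.0))
    baseline_jitter_sd: float = 5.0
    score_sd: float = 10.0
    frac_differential: float = 0.005
    effect_size: float = 30.0
    direction_by_group: dict = field(
        default_factory=lambda: {"UN": HYPER, "ON": MIXED, "Old": HYPO})
    n_shared_spikes: int = 0
    n_dmr_blocks: int = 5
    dmr_block_span: int = 6
    dmr_max_gap: int = 10_000
    mean_locus_depth: float = 800.0
    depth_dispersion: float = 5.0
    library_size_range: tuple = (900_000, 1_100_000)
    zero_inflation_sample: str | None = None
    zero_inflation_rate: float = 0.35
    # gene annotation
    n_genes: int = 2000
    gene_length_range: tuple = (2_000, 100_000)
    # gene sets
    n_gene_sets: int = 20
    gene_set_size_range: tuple = (20, 200)
    # qPCR stage: per-target-gene fold change by group (reference gene fold = 1)
    ct_target_folds: dict = field(
        default_factory=lambda: {"Ncor2": {"UN": 10.0, "ON": 4.0, "Old": 6.0}})
    ct_reference_gene: str = "Rps3"
    ct_animals_per_group: int = 6
    ct_baseline: float = 26.0
    ct_reference_baseline: float = 18.0
    ct_animal_sd: float = 0.15
    ct_replicate_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        # normalize sequence fields so YAML round-trips compare equal
        self.groups = tuple((str(g), int(n)) for g, n in self.groups)
        self.baseline_mixture = tuple(
            (float(w), float(m)) for w, m in self.baseline_mixture)
        self.library_size_range = tuple(self.library_size_range)
        self.gene_length_range = tuple(self.gene_length_range)
        self.gene_set_size_range = tuple(self.gene_set_size_range)
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ConfigError(
                f"frac_differential must lie in [0,1], got {self.frac_differential}")
        if self.mean_locus_spacing <= 0 or self.chromosome_length <= 0:
            raise ConfigError("spacing and chromosome length must be positive")
        if self.dmr_block_span < 4:
            raise ConfigError("dmr_block_span must be >= 4 to form a region")
        if any(n < 2 for _, n in self.groups):
            raise ConfigError("every group needs at least 2 samples")
        w = sum(w for w, _ in self.baseline_mixture)
        if not math.isclose(w, 1.0, abs_tol=1e-6):
            raise ConfigError("baseline mixture weights must sum to 1")

    @property
    def exposed_groups(self) -> list[str]:
        return [g for g, _ in self.groups if g != self.control_group]

    @property
    def sample_names(self) -> list[str]:
        return [f"{g}{i + 1}" for g, n in self.groups for i in range(n)]

    @property
    def sample_groups(self) -> pd.Series:
        return pd.Series({f"{g}{i + 1}": g for g, n in self.groups
                          for i in range(n)})

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["groups"] = [list(g) for g in self.groups]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "groups" in d:
            d["groups"] = tuple(tuple(g) for g in d["groups"])
        return cls(**d)


def generate_loci(config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Place CCGG-style loci along chromosomes.

    Inter-locus gaps are exponential with the configured mean spacing, so
    adjacent-locus distances are positive with occasional long gaps, as in
    a real restriction-site landscape. Returns a sorted strandless track
    (locus_id, chrom, start, end); each locus spans 4 bp.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    per_chrom = _split_counts(config.n_loci, config.n_chromosomes)
    needed = (max(per_chrom) + 1) * config.mean_locus_spacing
    if needed > config.chromosome_length:
        raise SizingError(
            f"chromosome_length {config.chromosome_length} too short for "
            f"{max(per_chrom)} loci at mean spacing {config.mean_locus_spacing}")
    frames = []
    for ci, n in enumerate(per_chrom):
        if n == 0:
            continue
        chrom = f"chr{ci + 1}"
        gaps = np.maximum(
            1, rng.exponential(config.mean_locus_spacing, size=n).round()
        ).astype(np.int64)
        starts = np.cumsum(gaps)
        if starts[-1] + 4 > config.chromosome_length:
            raise SizingError(
                f"{chrom}: loci overran chromosome end at {starts[-1]}")
        frames.append(pd.DataFrame({
            "locus_id": [f"{chrom}:{s}" for s in starts],
            "chrom": chrom,
            "start": starts,
            "end": starts + 4,
        }))
    return pd.concat(frames, ignore_index=True)


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _draw_baseline(config: SimulationConfig, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    weights = np.array([w for w, _ in config.baseline_mixture])
    means = np.array([m for _, m in config.baseline_mixture])
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    base = means[comp] + rng.normal(0.0, config.baseline_jitter_sd, size=n)
    return np.clip(base, 1.0, 99.0)


def _pick_dmr_blocks(loci: pd.DataFrame, config: SimulationConfig,
                     n_blocks: int, rng: np.random.Generator,
                     taken: np.ndarray) -> list[np.ndarray]:
    """Pick disjoint runs of consecutive loci with adjacent gaps <= dmr_max_gap."""
    span = config.dmr_block_span
    starts = loci["start"].values
    same_chrom = loci["chrom"].values[1:] == loci["chrom"].values[:-1]
    ok_gap = np.concatenate(
        [(np.diff(starts) <= config.dmr_max_gap) & same_chrom, [False]])
    blocks: list[np.ndarray] = []
    candidates = rng.permutation(len(loci) - span)
    for i in candidates:
        idx = np.arange(i, i + span)
        if taken[idx].any() or not ok_gap[i:i + span - 1].all():
            continue
        taken[idx] = True
        blocks.append(idx)
        if len(blocks) == n_blocks:
            break
    if len(blocks) < n_blocks:
        raise SizingError(
            f"could only place {len(blocks)}/{n_blocks} DMR blocks; "
            "increase n_loci or relax spacing")
    return blocks


def generate_counts(
    config: SimulationConfig,
    loci: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[LocusCountTable, pd.DataFrame]:
    """Draw two-enzyme tag counts and return them with the ground truth.

    Model: each locus has a negative-binomial reference depth d_l; MspI
    counts are Poisson(d_l * f_s) where f_s scales with the sample's
    library size, and HpaII counts are Poisson(d_l * f_s * s/100) with s
    the sample's realized methylation score (group mean + normal noise of
    SD ``score_sd``, clipped to [0,100]).

    The truth table has one row per spiked (locus, group) with the signed
    true score shift (negative = hypermethylation) and, where the spike
    belongs to a contiguous DMR block, the block id.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = len(loci)
    n_each = {g: cnt for g, cnt in config.groups}
    baseline = _draw_baseline(config, n, rng)
    eff = config.effect_size

    # signed true deltas per exposed group, plus DMR block membership
    delta = {g: np.zeros(n) for g in config.exposed_groups}
    block_of = {g: np.full(n, -1, dtype=np.int64) for g in config.exposed_groups}
    taken = np.zeros(n, dtype=bool)

    # Spiked-locus baselines are redrawn inside bands that keep both the
    # baseline and the shifted mean at least ~1.5 noise SDs away from the
    # scale boundaries, so the realized effect is the configured size and
    # the realized SD stays near score_sd (clipping would otherwise
    # attenuate both). hyper: baseline high enough to drop by eff;
    # hypo: low enough to rise by eff.
    margin = min(15.0, max(2.0, 1.5 * config.score_sd))
    hyper_band = (min(eff + margin, 100.0 - margin), 100.0 - margin)
    hypo_band = (margin, max(margin, 100.0 - margin - eff))
    shared_band = (hyper_band[0], hypo_band[1])
    if shared_band[0] >= shared_band[1]:  # very large effects: fall back to midpoint
        mid = 50.0
        shared_band = (mid - 1.0, mid + 1.0)

    def _spike(idx: np.ndarray, g: str, signs: np.ndarray) -> None:
        band = np.where(signs < 0, 1, 0)  # hyper -> hyper_band
        lo = np.where(band == 1, hyper_band[0], hypo_band[0])
        hi = np.where(band == 1, hyper_band[1], hypo_band[1])
        baseline[idx] = rng.uniform(lo, hi)
        delta[g][idx] = signs * eff

    block_counter = 0
    for g in config.exposed_groups:
        direction = config.direction_by_group.get(g, MIXED)
        if config.n_dmr_blocks > 0 and n > config.dmr_block_span:
            blocks = _pick_dmr_blocks(loci, config, config.n_dmr_blocks, rng, taken)
            for bi, idx in enumerate(blocks):
                d = direction if direction != MIXED else (HYPER, HYPO)[bi % 2]
                _spike(idx, g, np.full(len(idx), -1.0 if d == HYPER else 1.0))
                block_of[g][idx] = block_counter
                block_counter += 1

    # shared single-locus spikes: differential in every exposed group
    n_shared = min(config.n_shared_spikes, int((~taken).sum()))
    if n_shared:
        free = np.flatnonzero(~taken)
        shared = rng.choice(free, size=n_shared, replace=False)
        taken[shared] = True
        baseline[shared] = rng.uniform(*shared_band, size=n_shared)
        for g in config.exposed_groups:
            direction = config.direction_by_group.get(g, MIXED)
            if direction == MIXED:
                signs = rng.choice([-1.0, 1.0], size=n_shared)
            else:
                signs = np.full(n_shared, -1.0 if direction == HYPER else 1.0)
            delta[g][shared] = signs * eff

    # independent single-locus spikes per exposed group
    n_spike = int(round(config.frac_differential * n))
    for g in config.exposed_groups:
        extra = n_spike - int((delta[g] != 0).sum())
        if extra <= 0:
            continue
        direction = config.direction_by_group.get(g, MIXED)
        free = np.flatnonzero((delta[g] == 0) & ~taken)
        chosen = rng.choice(free, size=min(extra, len(free)), replace=False)
        taken[chosen] = True
        if direction == HYPER:
            signs = np.full(len(chosen), -1.0)
        elif direction == HYPO:
            signs = np.full(len(chosen), 1.0)
        else:
            signs = rng.choice([-1.0, 1.0], size=len(chosen))
        _spike(chosen, g, signs)

    # per-sample scores and counts
    samples = config.sample_names
    sgroups = config.sample_groups
    depth_k = config.depth_dispersion
    p_nb = depth_k / (depth_k + config.mean_locus_depth)
    locus_depth = rng.negative_binomial(depth_k, p_nb, size=n).astype(float)
    locus_depth = np.maximum(locus_depth, 1.0)

    lib = rng.uniform(*config.library_size_range, size=(2, len(samples)))
    hpaii_totals = pd.Series(lib[0].round(), index=samples)
    mspi_totals = pd.Series(lib[1].round(), index=samples)
    f_h = hpaii_totals.values / hpaii_totals.values.mean()
    f_m = mspi_totals.values / mspi_totals.values.mean()

    hpaii = np.empty((n, len(samples)), dtype=np.int64)
    mspi = np.empty((n, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        g = sgroups[s]
        mean_score = baseline + (delta[g] if g in delta else 0.0)
        realized = np.clip(
            mean_score + rng.normal(0.0, config.score_sd, size=n), 0.0, 100.0)
        hpaii[:, j] = rng.poisson(locus_depth * f_h[j] * realized / 100.0)
        mspi[:, j] = rng.poisson(locus_depth * f_m[j])
    if config.zero_inflation_sample is not None:
        j = samples.index(config.zero_inflation_sample)
        kill = rng.random(n) < config.zero_inflation_rate
        hpaii[kill, j] = 0

    idx = pd.Index(loci["locus_id"], name="locus_id")
    table = LocusCountTable(
        loci=loci,
        hpaii=pd.DataFrame(hpaii, index=idx, columns=samples),
        mspi=pd.DataFrame(mspi, index=idx, columns=samples),
        groups=sgroups,
        hpaii_totals=hpaii_totals,
        mspi_totals=mspi_totals,
    )

    rows = []
    ids = loci["locus_id"].values
    for g in config.exposed_groups:
        hit = np.flatnonzero(delta[g] != 0)
        for i in hit:
            b = block_of[g][i]
            rows.append((ids[i], g, delta[g][i], b if b >= 0 else None))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return table, truth


def generate_annotation(
    config: SimulationConfig,
    loci: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Lay down non-overlapping gene models and count assayed sites per gene.

    Gene lengths are log-uniform over ``gene_length_range`` so per-gene
    HpaII-site counts span at least an order of magnitude — the bias the
    enrichment stage corrects for. The ``n_hpaii_sites`` column counts loci
    overlapping the default mapping window (10 kb upstream of the TSS to
    10 kb past the TES).
    """
    from .gene_mapping import build_windows, map_loci  # local to avoid cycle

    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    per_chrom = _split_counts(config.n_genes, config.n_chromosomes)
    lo, hi = config.gene_length_range
    rows = []
    gid = 0
    for ci, n_g in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = 0
        for _ in range(n_g):
            gap = int(rng.exponential(
                max(1.0, config.chromosome_length / max(n_g, 1) * 0.3)))
            length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            start = pos + gap
            end = start + length
            if end >= config.chromosome_length:
                break
            gid += 1
            rows.append({
                "gene_id": f"Gene{gid:05d}", "chrom": chrom,
                "start": start, "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
            })
            pos = end
    genes = pd.DataFrame(rows)
    windows = build_windows(genes)
    assoc = map_loci(loci, windows)
    counts = assoc.groupby("gene_id").size()
    genes["n_hpaii_sites"] = (
        genes["gene_id"].map(counts).fillna(0).astype(np.int64))
    return genes


def generate_gene_sets(
    config: SimulationConfig,
    genes: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> dict[str, list[str]]:
    """Random gene sets over the annotated universe (GMT-shaped dict)."""
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    ids = genes["gene_id"].values
    lo, hi = config.gene_set_size_range
    sets = {}
    for k in range(config.n_gene_sets):
        size = int(rng.integers(lo, min(hi, len(ids)) + 1))
        members = rng.choice(ids, size=size, replace=False)
        sets[f"SET{k + 1:03d}"] = sorted(members)
    return sets


def generate_ct_table(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table (target and reference gene, triplicates).

    Target Ct per animal = baseline - log2(fold of its group) + animal
    noise; the reference gene has fold 1 everywhere. Returns records of
    (animal_id, group, gene, replicate, ct).
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    group_names = [g for g, _ in config.groups]
    if len(group_names) < 2:
        raise ConfigError("qPCR simulation needs at least 2 groups")
    genes = list(config.ct_target_folds) + [config.ct_reference_gene]
    rows = []
    for g in group_names:
        for a in range(config.ct_animals_per_group):
            animal = f"{g}_a{a + 1}"
            animal_shift = rng.normal(0.0, config.ct_animal_sd)
            for gene in genes:
                if gene == config.ct_reference_gene:
                    mu = config.ct_reference_baseline
                else:
                    fold = config.ct_target_folds[gene].get(g, 1.0)
                    mu = config.ct_baseline - math.log2(fold)
                for r in range(3):
                    ct = mu + animal_shift + rng.normal(0.0, config.ct_replicate_sd)
                    rows.append((animal, g, gene, r + 1, round(ct, 4)))
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "gene", "replicate", "ct"])
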