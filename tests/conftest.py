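import numpy as np
import pandas as pd
import pytest

from helptag_dm.containers import LocusCountTable
from helptag_dm.scoring_qc import compute_scores
from helptag_dm.synthetic_data import (SimulationConfig, generate_counts,
                                       generate_loci)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_loci=6000, n_chromosomes=3, chromosome_length=6_000_000,
        n_genes=150, n_dmr_blocks=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    rng = np.random.default_rng(small_config.seed)
    loci = generate_loci(small_config, rng)
    counts, truth = generate_counts(small_config, loci, rng)
    return loci, counts, truth


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    _, counts, _ = small_dataset
    return compute_scores(counts)


@pytest.fixture(scope="session")
def default_dataset():
    """Mid-size simulation at the default study conditions (Δ=30, sd=10)."""
    cfg = SimulationConfig(
        n_loci=50_000, n_chromosomes=5, chromosome_length=25_000_000, seed=7)
    rng = np.random.default_rng(cfg.seed)
    loci = generate_loci(cfg, rng)
    counts, truth = generate_counts(cfg, loci, rng)
    return cfg, loci, counts, truth


def make_count_table(hpaii: dict, mspi: dict, loci: pd.DataFrame | None = None,
                     groups: dict | None = None,
                     hpaii_totals: dict | None = None,
                     mspi_totals: dict | None = None) -> LocusCountTable:
    """Hand-built count table for toy fixtures."""
    hp = pd.DataFrame(hpaii)
    ms = pd.DataFrame(mspi)
    n = len(hp)
    if loci is None:
        loci = pd.DataFrame({
            "locus_id": [f"L{i}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 1000 + 100,
            "end": np.arange(n) * 1000 + 104,
        })
    hp.index = pd.Index(loci["locus_id"], name="locus_id")
    ms.index = hp.index
    samples = list(hp.columns)
    if groups is None:
        groups = {s: "G1" for s in samples}
    if hpaii_totals is None:
        hpaii_totals = {s: 1_000_000 for s in samples}
    if mspi_totals is None:
        mspi_totals = {s: 1_000_000 for s in samples}
    return LocusCountTable(loci, hp, ms, pd.Series(groups),
                           pd.Series(hpaii_totals, dtype=float),
                           pd.Series(mspi_totals, dtype=float))


def make_results_frame(starts, candidate, delta=None, chrom="chr1",
                       p_value=None, testable=None) -> pd.DataFrame:
    """Hand-built per-locus result table for DMR tests."""
    n = len(starts)
    starts = np.asarray(starts)
    if delta is None:
        delta = np.where(np.asarray(candidate), 40.0, 1.0)
    if p_value is None:
        p_value = np.where(np.asarray(candidate), 1e-4, 0.5)
    if testable is None:
        testable = np.ones(n, dtype=bool)
    chroms = [chrom] * n if isinstance(chrom, str) else list(chrom)
    return pd.DataFrame({
        "locus_id": [f"{c}:{s}" for c, s in zip(chroms, starts)],
        "chrom": chroms,
        "start": starts,
        "end": starts + 1,
        "delta": np.asarray(delta, dtype=float),
        "p_value": np.asarray(p_value, dtype=float),
        "testable": np.asarray(testable, dtype=bool),
        "candidate": np.asarray(candidate, dtype=bool),
    })
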