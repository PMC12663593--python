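"""End-to-end benchmark workflows on fully synthetic data.

These functions wire the simulator, database builder, profiler and
metrics into the standard evaluation designs: an evenly mixed mock
community diluted with host reads (profiled and scored against its
ground truth), a rarefaction ladder on a complex community, and
abundance-recovery runs on log-uniform communities.  They are used both
by the test suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from twobrad.enzyme import BCGI
from twobrad.metrics import (
    aupr,
    l2_similarity,
    pearson_union,
    precision_recall_curve,
    rarefaction_similarity,
    saturating_depth,
)
from twobrad.profiler import ProfileConfig, ReadSet, profile_sample
from twobrad.simulate import (
    CommunitySpec,
    SimGenomeSpec,
    log_uniform_abundances,
    mock_scenario,
    simulate_reads,
    synth_genome,
)
from twobrad.tagdb import build_tag_db_from_sequences

__all__ = [
    "MockBenchmarkResult",
    "run_mock_benchmark",
    "RarefactionBenchmarkResult",
    "run_rarefaction_benchmark",
    "run_parameter_recovery",
]

RAREFACTION_DEPTHS = (1_000, 5_000, 10_000, 25_000, 50_000, 100_000, 150_000)


@dataclass
class MockBenchmarkResult:
    aupr: float
    l2: float
    n_retained: int
    n_truth: int
    false_positives: int
    host_reads: int
    total_reads: int


def run_mock_benchmark(host_pct: float = 0.90, n_reads: int = 100_000,
                       seed: int = 7, error_rate: float = 0.005,
                       n_species: int = 20) -> MockBenchmarkResult:
    """Even mock community with host spike: simulate, build the marker
    database from the same synthetic genomes, profile with default
    settings (two-pass, G >= 5, host-tag exclusion), and score against
    the even ground truth."""
    scenario = mock_scenario(n_species=n_species, host_pct=host_pct,
                             n_reads=n_reads, seed=seed,
                             error_rate=error_rate)
    db = build_tag_db_from_sequences(scenario.genomes, BCGI)
    profile = profile_sample(scenario.readset, db, scenario.host_tags)
    pred = profile.abundances()
    points = precision_recall_curve(pred, set(scenario.truth))
    return MockBenchmarkResult(
        aupr=aupr(points),
        l2=l2_similarity(pred, scenario.truth),
        n_retained=len(profile.hits),
        n_truth=len(scenario.truth),
        false_positives=len(set(pred) - set(scenario.truth)),
        host_reads=profile.host_reads,
        total_reads=profile.total_reads,
    )


@dataclass
class RarefactionBenchmarkResult:
    table: pd.DataFrame
    saturating_depth: int
    shannon_at_saturation: float
    bray_curtis_at_saturation: float
    max_gain_beyond_saturation: float


def run_rarefaction_benchmark(seed: int = 5, n_species: int = 50,
                              n_reads: int = 200_000,
                              depths: Sequence[int] = RAREFACTION_DEPTHS,
                              reps: int = 3,
                              genome_length: int = 60_000,
                              ) -> RarefactionBenchmarkResult:
    """Diversity saturation on a log-uniform community.

    Reads are subsampled at the depth ladder (``reps`` replicates each),
    each subsample is profiled, and its Shannon index and Bray-Curtis
    profile are compared with the full-depth profile.  The saturating
    depth is where both similarities come within 1 point of full depth;
    the result also reports the largest per-tier improvement beyond it.
    """
    rng = np.random.default_rng(seed)
    species = [f"sp{i:03d}" for i in range(n_species)]
    genomes = {}
    for sp in species:
        _, seq = synth_genome(
            SimGenomeSpec(sp, length=genome_length,
                          seed=int(rng.integers(2**31 - 1))), BCGI)
        genomes[sp] = seq
    truth = log_uniform_abundances(species, seed=int(rng.integers(2**31 - 1)))
    community = CommunitySpec(truth, n_reads=n_reads,
                              seed=int(rng.integers(2**31 - 1)))
    readset, _ = simulate_reads(community, genomes, BCGI)
    db = build_tag_db_from_sequences(genomes, BCGI)
    config = ProfileConfig(decontam_mode="off")

    def profile_fn(reads):
        result = profile_sample(ReadSet("rarefied", list(reads)), db,
                                None, None, config)
        return result.abundances()

    table = rarefaction_similarity(profile_fn, readset.reads, list(depths),
                                   reps=reps,
                                   seed=int(rng.integers(2**31 - 1)))
    depth = saturating_depth(table)
    at = table[table["depth"] == depth].iloc[0]
    beyond = table[table["depth"] >= depth].reset_index(drop=True)
    max_gain = 0.0
    for col in ("shannon_similarity", "bray_curtis_similarity"):
        diffs = beyond[col].diff().dropna()
        if len(diffs):
            max_gain = max(max_gain, float(diffs.max()))
    return RarefactionBenchmarkResult(
        table=table,
        saturating_depth=depth,
        shannon_at_saturation=float(at["shannon_similarity"]),
        bray_curtis_at_saturation=float(at["bray_curtis_similarity"]),
        max_gain_beyond_saturation=max_gain,
    )


def run_parameter_recovery(seeds: Sequence[int], n_species: int = 10,
                           n_reads: int = 10_000,
                           genome_length: int = 40_000,
                           ) -> List[Dict[str, float]]:
    """Noiseless, host-free abundance recovery on log-uniform communities.

    For each seed, a fresh genome set and community are drawn and the
    profiled abundances are compared with the ground truth (zero-filled
    Pearson r and L2 similarity)."""
    out = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        species = [f"sp{i:02d}" for i in range(n_species)]
        genomes = {}
        for sp in species:
            _, seq = synth_genome(
                SimGenomeSpec(sp, length=genome_length,
                              seed=int(rng.integers(2**31 - 1))), BCGI)
            genomes[sp] = seq
        truth = log_uniform_abundances(species,
                                       seed=int(rng.integers(2**31 - 1)))
        community = CommunitySpec(truth, n_reads=n_reads,
                                  seed=int(rng.integers(2**31 - 1)))
        readset, _ = simulate_reads(community, genomes, BCGI)
        db = build_tag_db_from_sequences(genomes, BCGI)
        profile = profile_sample(readset, db)
        pred = profile.abundances()
        out.append({
            "pearson": pearson_union(pred, truth),
            "l2": l2_similarity(pred, truth),
        })
    return out
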