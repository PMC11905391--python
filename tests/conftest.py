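"""Shared fixtures: a small synthetic study run end to end once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from srnakit.io_formats import reverse_complement
from srnakit.pipeline import (
    config_for_simulation,
    run_pipeline,
    simulate_inputs,
)
from srnakit.synthetic_data import SimConfig


def make_hairpin(rng: np.random.Generator, mature: str, loop_len: int = 12,
                 n_mismatches: int = 0, lower: int = 8, upper: int = 4,
                 gc: float = 0.6) -> tuple[str, int]:
    """Construct a stem-loop: [lower][mature][upper] + loop + rc(arm).

    Returns the precursor sequence and the 0-based mature offset. Mismatches
    are planted into the 3' copy opposite the mature, so they show up as
    duplex mismatches.
    """
    def rand(n: int) -> str:
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(rng.choice(list("ACGT"), size=n, p=probs))

    arm = rand(lower) + mature + rand(upper)
    right = list(reverse_complement(arm))
    # positions in the right arm opposite the mature
    arm_len = len(arm)
    opposite = [arm_len - 1 - (lower + k) for k in range(len(mature))]
    picks = rng.choice(opposite, size=n_mismatches, replace=False)
    for pos in picks:
        right[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[right[pos]]
    precursor = arm + rand(loop_len) + "".join(right)
    return precursor, lower


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    return SimConfig(seed=42, n_hairpin_loci=10, read_count_per_library=3000,
                     genome_length=150_000, n_genes=12)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory, small_sim_config):
    """Simulated inputs plus a completed pipeline run at small scale."""
    root = tmp_path_factory.mktemp("study")
    paths = simulate_inputs(small_sim_config, root / "in")
    config = config_for_simulation(small_sim_config, root / "in", root / "out")
    result = run_pipeline(config)
    truth = pd.read_csv(paths["truth"], sep="\t")
    return {
        "sim": small_sim_config,
        "paths": paths,
        "config": config,
        "result": result,
        "truth": truth,
        "root": root,
    }
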