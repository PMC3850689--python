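"""Shared fixtures: session-scoped simulated datasets and helpers.

Three full simulation runs (zero-noise, default-noise, attenuated-pool)
feed both the unit tests and the acceptance suite; each is generated once
per session into a temporary directory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pytest

from poolmapper.deconvolve import DeconvolutionResult
from poolmapper.pipeline import run_pipeline
from poolmapper.preprocess import FilterStats
from poolmapper.simpool import GroundTruth, SimConfig, simulate
from poolmapper.store import COVERAGE_COLUMNS


def make_coverage(counts: dict[str, int]) -> pd.DataFrame:
    """Build a coverage table directly from index -> raw count (the same
    ranking contract the store implements: descending count, then index)."""
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [
            {
                "index_seq": idx,
                "raw_count": c,
                "norm_cov": c / total,
                "rank": i + 1,
                "representative_read": idx + "ACGT",
            }
            for i, (idx, c) in enumerate(rows)
        ],
        columns=COVERAGE_COLUMNS,
    )


@dataclass
class SimRun:
    cfg: SimConfig
    truth: GroundTruth
    out_dir: Path
    result: DeconvolutionResult  # three_prime deconvolution
    stats: dict[str, FilterStats]

    def truth_index(self, end: str = "three_prime") -> dict[tuple, str]:
        """well -> expected index for single-well elements."""
        return {
            w: (e.index_three if end == "three_prime" else e.index_five)
            for e in self.truth.insertions
            for w in e.wells
        }


def _run(cfg: SimConfig, out_dir: Path) -> SimRun:
    truth, _ledger = simulate(cfg, out_dir)
    spec = cfg.filter_specs()["three_prime"]
    result, stats = run_pipeline(cfg.design, out_dir / "reads", spec)
    return SimRun(cfg, truth, out_dir, result, stats)


@pytest.fixture(scope="session")
def zero_noise_run(tmp_path_factory) -> SimRun:
    cfg = SimConfig(
        seed=1, noise_fraction=0.0, substitution_error_rate=0.0, n_endogenous=0
    )
    return _run(cfg, tmp_path_factory.mktemp("sim_zero"))


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory) -> SimRun:
    cfg = SimConfig(seed=2)  # default noise/error/endogenous conditions
    return _run(cfg, tmp_path_factory.mktemp("sim_noisy"))


@pytest.fixture(scope="session")
def attenuated_run(tmp_path_factory) -> SimRun:
    cfg = SimConfig(seed=3, attenuated_pools={("plate", "01"): 20.0})
    return _run(cfg, tmp_path_factory.mktemp("sim_attenuated"))
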