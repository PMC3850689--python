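"""End-to-end driver: pooled FASTQ files -> well assignments.

Chains the pipeline stages for one element end: filter/trim each pooled
library, load the retained reads into the embedded store, compute per-pool
coverage and deconvolve. Each library is processed independently (the
stages are order-invariant), so the steps can equally be run one pool at a
time from the command line.
"""

from __future__ import annotations

from pathlib import Path

from .deconvolve import DeconvolutionConfig, DeconvolutionResult, deconvolve_store
from .design import PoolDesign
from .preprocess import FilterSpec, FilterStats, filter_reads, read_sequences
from .store import ReadStore


def run_pipeline(
    design: PoolDesign,
    reads_dir: str | Path,
    spec: FilterSpec,
    cfg: DeconvolutionConfig | None = None,
    db_path: str | Path = ":memory:",
) -> tuple[DeconvolutionResult, dict[str, FilterStats]]:
    """Process every pool library named ``<library_id>.fastq`` (or
    ``.fasta``) under `reads_dir` and deconvolve the cube.

    Returns the deconvolution result and per-library filter statistics.
    """
    reads_dir = Path(reads_dir)
    stats_by_lib: dict[str, FilterStats] = {}
    with ReadStore(db_path) as store:
        for pool in design.pools():
            path = reads_dir / f"{pool.library_id}.fastq"
            if not path.exists():
                path = reads_dir / f"{pool.library_id}.fasta"
            if not path.exists():
                raise FileNotFoundError(
                    f"no reads file for library {pool.library_id} in {reads_dir}"
                )
            stats = FilterStats()
            stream = filter_reads(
                read_sequences(path), spec, pool.library_id, stats
            )
            store.load_library(stream, spec.end_label, pool.library_id, overwrite=True)
            stats_by_lib[pool.library_id] = stats
        result = deconvolve_store(store, design, spec.end_label, cfg)
    return result, stats_by_lib
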