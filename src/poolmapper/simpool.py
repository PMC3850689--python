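"""Synthetic target-enriched pooled reads with known ground truth.

The generator emulates the real experiment at desk scale: a toy reference
genome, one transposon insertion per well of a plate x row x column cube,
one pooled amplicon library per plate/row/column, and reads of the form
``barcode + primer + identifier + TSD + genomic flank`` for both element
ends (the TSD — target site duplication — is the short host motif
duplicated at the insertion junction and serves as the read's index).

Realism knobs, each config-exposed:

* per-amplicon abundance ~ lognormal(0, sigma), the multiplicative PCR
  amplification bias that makes coverage ranks noisy;
* a noise fraction split evenly between misprimed reads (correct technical
  prefix, drawn from off-target genomic loci with their own lognormal
  abundances — mispriming amplifies specific loci, not uniform junk) and
  junk reads (random sequence failing the prefix filter);
* i.i.d. substitution sequencing errors;
* endogenous elements present in every pool at a copy multiplier;
* duplicate-well insertions (premeiotic-transposition mimic);
* per-pool attenuation of the on-target amplification relative to noise
  (a failed enrichment in one library, the scenario Grade-2 rescues).

Everything is deterministic under the seed; each pool draws from an RNG
stream keyed by (seed, pool position) so per-pool output is independent of
generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import DIMENSIONS, PoolDesign
from .elementmap import Gene
from .preprocess import FilterSpec

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: fixed enrichment primers / element-terminus identifiers per end
DEFAULT_PRIMERS: dict[str, tuple[str, str]] = {
    "five_prime": ("GTCGGAGCCGTTTTACAACC", "TACCTCGG"),
    "three_prime": ("CGGTCGGTACGGGATTTTCC", "TTACCTCG"),
}

_CONTEXT_CYCLE = (
    "exon",
    "intron",
    "within_1kb_upstream",
    "within_1kb_downstream",
    "intergenic",
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Study conditions for one simulated run (defaults = the conditions the
    desk-scale validation uses: a 96-well 4x4x6 cube, 10,000 reads per
    pool, sigma 0.5 amplification spread, 10% noise, 0.5% substitution
    errors)."""

    seed: int = 0
    design: PoolDesign = field(default_factory=lambda: PoolDesign.grid(4, 4, 6))
    n_chroms: int = 3
    chrom_length: int = 250_000
    reads_per_pool: int = 10_000
    coverage_lognormal_sigma: float = 0.5
    noise_fraction: float = 0.1
    substitution_error_rate: float = 0.005
    n_endogenous: int = 2
    endogenous_copy_multiplier: float = 5.0
    duplicate_wells: tuple[tuple[tuple[str, str, str], tuple[str, str, str]], ...] = ()
    attenuated_pools: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise_loci_per_pool: int = 25
    index_length: int = 8
    read_length: int = 100
    primers: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_PRIMERS)
    )
    barcodes: Mapping[str, str] = field(default_factory=dict)
    min_insertion_spacing: int = 3_000

    def __post_init__(self) -> None:
        if self.reads_per_pool <= 0:
            raise ValueError("reads_per_pool must be positive")
        if not (0 <= self.noise_fraction < 1):
            raise ValueError("noise_fraction must lie in [0, 1)")
        if not (0 <= self.substitution_error_rate < 1):
            raise ValueError("substitution_error_rate must lie in [0, 1)")
        if self.index_length < 1:
            raise ValueError("index_length must be >= 1")
        for end in ("five_prime", "three_prime"):
            if end not in self.primers:
                raise ValueError(f"primers must cover {end}")
        if self.read_length <= self.max_prefix_length + self.index_length:
            raise ValueError("read_length leaves no room for index + flank")
        for factor in self.attenuated_pools.values():
            if factor < 1:
                raise ValueError("attenuation factors must be >= 1")

    def prefix(self, end: str, library_id: str | None = None) -> str:
        primer, identifier = self.primers[end]
        barcode = self.barcodes.get(library_id, "") if library_id else ""
        return barcode + primer + identifier

    @property
    def max_prefix_length(self) -> int:
        bc = max((len(b) for b in self.barcodes.values()), default=0)
        return bc + max(len(p) + len(i) for p, i in self.primers.values())

    def content_length(self, end: str, library_id: str | None = None) -> int:
        """Post-prefix payload length of a read (TSD + flank)."""
        return self.read_length - len(self.prefix(end, library_id))

    def filter_specs(self, library_id: str | None = None) -> dict[str, FilterSpec]:
        """Matching preprocess filter specs for both element ends."""
        specs = {}
        for end, (primer, identifier) in self.primers.items():
            specs[end] = FilterSpec(
                primer=primer,
                identifier=identifier,
                barcode=self.barcodes.get(library_id, "") if library_id else "",
                max_mismatches_primer=1,
                max_mismatches_identifier=1,
                index_length=self.index_length,
                end_label=end,
            )
        return specs


@dataclass(frozen=True)
class InsertionTruth:
    """One simulated element; usually one well, several for duplicates."""

    name: str
    wells: tuple[tuple[str, str, str], ...]
    chrom: str
    position: int  # 1-based start of the TSD on the reference
    tsd: str
    index_three: str  # TSD as read from the 3' flank
    index_five: str  # reverse complement, as read from the 5' flank
    flank_three: str
    flank_five: str
    gene_context: str
    gene_id: str | None
    exon_index: int | None
    exon_count: int | None


@dataclass
class GroundTruth:
    config: SimConfig
    chromosomes: dict[str, str]
    insertions: list[InsertionTruth]
    endogenous: list[InsertionTruth]
    genes: list[Gene]

    @property
    def genuine_indices(self) -> set[str]:
        out = set()
        for e in self.insertions + self.endogenous:
            out.update((e.index_three, e.index_five))
        return out

    def endogenous_indices(self) -> set[str]:
        out = set()
        for e in self.endogenous:
            out.update((e.index_three, e.index_five))
        return out


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


def _random_genome(rng: np.random.Generator, cfg: SimConfig) -> dict[str, str]:
    return {
        f"chr{i + 1}": _BASES[rng.integers(0, 4, size=cfg.chrom_length)].tobytes().decode()
        for i in range(cfg.n_chroms)
    }


def _draw_position(
    rng: np.random.Generator,
    cfg: SimConfig,
    chromosomes: dict[str, str],
    taken: dict[str, list[int]],
    used_indices: set[str],
) -> tuple[str, int, str]:
    """A fresh (chrom, 1-based position, tsd) respecting spacing and TSD
    uniqueness across both read orientations."""
    names = sorted(chromosomes)
    margin = 2_000 + cfg.read_length
    for _ in range(10_000):
        chrom = names[rng.integers(0, len(names))]
        pos = int(rng.integers(margin, cfg.chrom_length - margin))
        if any(abs(pos - p) < cfg.min_insertion_spacing for p in taken[chrom]):
            continue
        tsd = chromosomes[chrom][pos - 1 : pos - 1 + cfg.index_length]
        if tsd in used_indices or revcomp(tsd) in used_indices:
            continue
        taken[chrom].append(pos)
        used_indices.update((tsd, revcomp(tsd)))
        return chrom, pos, tsd
    raise ValueError(
        "genome too small for the requested number of well-separated insertions"
    )


def _flanks(cfg: SimConfig, chrom_seq: str, pos: int) -> tuple[str, str]:
    """(flank_three, flank_five) payloads; both begin with the TSD in their
    own read orientation."""
    n3 = cfg.content_length("three_prime")
    n5 = cfg.content_length("five_prime")
    flank_three = chrom_seq[pos - 1 : pos - 1 + n3]
    hi = pos - 1 + cfg.index_length
    flank_five = revcomp(chrom_seq[hi - n5 : hi])
    return flank_three, flank_five


def _gene_for_context(
    context: str, chrom: str, pos: int, strand: str, gene_id: str
) -> tuple[Gene | None, int | None, int | None]:
    """A toy gene realizing `context` at reference point `pos` (both element
    ends, pos .. pos+TSD-1, fall in the same class). Returns
    (gene, expected exon_index, exon_count)."""
    if context == "exon":
        exons = ((pos - 200, pos + 50), (pos + 150, pos + 400))
        gene = Gene(gene_id, chrom, pos - 200, pos + 400, strand, exons)
        k = 1 if strand == "+" else 2
        return gene, k, 2
    if context == "intron":
        exons = ((pos - 300, pos - 100), (pos + 100, pos + 300))
        return Gene(gene_id, chrom, pos - 300, pos + 300, strand, exons), None, None
    if context == "within_1kb_upstream":
        span = (pos + 200, pos + 800)
        return Gene(gene_id, chrom, *span, "+", (span,)), None, None
    if context == "within_1kb_downstream":
        span = (pos - 800, pos - 200)
        return Gene(gene_id, chrom, *span, "+", (span,)), None, None
    return None, None, None  # intergenic


def generate_truth(cfg: SimConfig) -> GroundTruth:
    """Toy reference, per-well insertions, endogenous elements, gene models.

    Deterministic under ``cfg.seed``. Insertion sites are drawn uniformly,
    kept well separated, and their TSDs kept unique across both read
    orientations so that index identity is unambiguous. Gene contexts cycle
    through exon / intron / upstream / downstream / intergenic across the
    insertions, alternating gene strand, so the annotation stage sees every
    class with a known expectation.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    chromosomes = _random_genome(rng, cfg)
    taken: dict[str, list[int]] = {name: [] for name in chromosomes}
    used_indices: set[str] = set()

    secondary = {pair[1] for pair in cfg.duplicate_wells}
    primary_extra: dict[tuple[str, str, str], list[tuple[str, str, str]]] = {}
    for w1, w2 in cfg.duplicate_wells:
        if w1 in secondary:
            raise ValueError("duplicate_wells must not chain wells")
        primary_extra.setdefault(w1, []).append(w2)

    insertions: list[InsertionTruth] = []
    genes: list[Gene] = []
    i = 0
    for well in cfg.design.iter_wells():
        if well in secondary:
            continue
        cfg.design.well_label(*well)  # bounds check
        chrom, pos, tsd = _draw_position(rng, cfg, chromosomes, taken, used_indices)
        flank3, flank5 = _flanks(cfg, chromosomes[chrom], pos)
        context = _CONTEXT_CYCLE[i % len(_CONTEXT_CYCLE)]
        strand = "+" if (i // len(_CONTEXT_CYCLE)) % 2 == 0 else "-"
        gene, k, n = _gene_for_context(context, chrom, pos, strand, f"gene_{i:04d}")
        if gene is not None:
            genes.append(gene)
        wells = (well, *primary_extra.get(well, ()))
        insertions.append(
            InsertionTruth(
                name=cfg.design.well_label(*well),
                wells=tuple(wells),
                chrom=chrom,
                position=pos,
                tsd=tsd,
                index_three=tsd,
                index_five=revcomp(tsd),
                flank_three=flank3,
                flank_five=flank5,
                gene_context=context,
                gene_id=gene.gene_id if gene else None,
                exon_index=k,
                exon_count=n,
            )
        )
        i += 1

    endogenous: list[InsertionTruth] = []
    for j in range(cfg.n_endogenous):
        chrom, pos, tsd = _draw_position(rng, cfg, chromosomes, taken, used_indices)
        flank3, flank5 = _flanks(cfg, chromosomes[chrom], pos)
        endogenous.append(
            InsertionTruth(
                name=f"endogenous_{j}",
                wells=(),
                chrom=chrom,
                position=pos,
                tsd=tsd,
                index_three=tsd,
                index_five=revcomp(tsd),
                flank_three=flank3,
                flank_five=flank5,
                gene_context="intergenic",
                gene_id=None,
                exon_index=None,
                exon_count=None,
            )
        )
    return GroundTruth(cfg, chromosomes, insertions, endogenous, genes)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _encode(seqs: Sequence[str]) -> np.ndarray:
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).copy()
    return mat.reshape(len(seqs), -1)


_CODE = np.zeros(256, dtype=np.uint8)
_CODE[ord("A")], _CODE[ord("C")], _CODE[ord("G")], _CODE[ord("T")] = 0, 1, 2, 3


def _apply_errors(
    mat: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. substitutions at `rate` per base; the new base is always
    different from the old one."""
    if rate <= 0:
        return mat
    mask = rng.random(mat.shape) < rate
    n = int(mask.sum())
    if n == 0:
        return mat
    codes = _CODE[mat[mask]]
    new = (codes + rng.integers(1, 4, size=n)) % 4
    mat[mask] = _BASES[new]
    return mat


def _pool_elements(
    truth: GroundTruth, dimension: str, label: str
) -> list[InsertionTruth]:
    axis = DIMENSIONS.index(dimension)
    return [
        e for e in truth.insertions if any(w[axis] == label for w in e.wells)
    ]


def simulate_reads(
    truth: GroundTruth, out_dir: str | Path
) -> pd.DataFrame:
    """Write one FASTQ per pooled library; return the per-category ledger.

    Per pool, the read budget is split multinomially between on-target
    amplicons (one per element x end, lognormal weights; endogenous
    elements carry the copy multiplier in *every* pool), misprimed
    off-target loci and junk. Attenuated pools have their on-target weight
    divided by the attenuation factor, noise left untouched. Substitution
    errors are applied after composition, so ledger counts are exact.
    """
    cfg = truth.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ledger_rows: list[dict] = []
    chrom_names = sorted(truth.chromosomes)
    genuine_idx = truth.genuine_indices

    for pool_i, pool in enumerate(cfg.design.pools()):
        rng = np.random.default_rng([cfg.seed, 1 + pool_i])
        lib = pool.library_id

        # amplicons: (name, end, payload, weight)
        amplicons: list[tuple[str, str, str, float]] = []
        for e in _pool_elements(truth, pool.dimension, pool.label):
            for end, payload in (("three_prime", e.flank_three), ("five_prime", e.flank_five)):
                w = float(rng.lognormal(0.0, cfg.coverage_lognormal_sigma))
                amplicons.append((e.name, end, payload, w))
        for e in truth.endogenous:
            for end, payload in (("three_prime", e.flank_three), ("five_prime", e.flank_five)):
                w = cfg.endogenous_copy_multiplier * float(
                    rng.lognormal(0.0, cfg.coverage_lognormal_sigma)
                )
                amplicons.append((e.name, end, payload, w))

        # misprimed off-target loci, indices disjoint from genuine ones
        loci: list[tuple[str, str, str, float]] = []
        if cfg.noise_fraction > 0:
            while len(loci) < cfg.noise_loci_per_pool:
                chrom = chrom_names[rng.integers(0, len(chrom_names))]
                end = ("three_prime", "five_prime")[rng.integers(0, 2)]
                n = cfg.content_length(end, lib)
                pos = int(rng.integers(0, cfg.chrom_length - n))
                payload = truth.chromosomes[chrom][pos : pos + n]
                if payload[: cfg.index_length] in genuine_idx:
                    continue
                w = float(rng.lognormal(0.0, cfg.coverage_lognormal_sigma))
                loci.append((f"offtarget_{len(loci)}", end, payload, w))

        atten = float(cfg.attenuated_pools.get(pool.key, 1.0))
        w_on = (1.0 - cfg.noise_fraction) / atten
        w_mis = w_jnk = cfg.noise_fraction / 2.0
        shares = np.array([w_on, w_mis, w_jnk], dtype=float)
        n_on, n_mis, n_jnk = rng.multinomial(cfg.reads_per_pool, shares / shares.sum())

        seqs: list[str] = []
        meta: list[tuple[str, str]] = []  # (category, name)
        if amplicons and n_on:
            w = np.array([a[3] for a in amplicons])
            counts = rng.multinomial(n_on, w / w.sum())
            for (name, end, payload, _w), c in zip(amplicons, counts):
                if not c:
                    continue
                read = (cfg.prefix(end, lib) + payload)[: cfg.read_length]
                seqs.extend([read] * int(c))
                meta.extend([("on_target", name)] * int(c))
        if loci and n_mis:
            w = np.array([a[3] for a in loci])
            counts = rng.multinomial(n_mis, w / w.sum())
            for (name, end, payload, _w), c in zip(loci, counts):
                if not c:
                    continue
                read = (cfg.prefix(end, lib) + payload)[: cfg.read_length]
                seqs.extend([read] * int(c))
                meta.extend([("misprimed", name)] * int(c))
        for _ in range(int(n_jnk)):
            seqs.append(_BASES[rng.integers(0, 4, cfg.read_length)].tobytes().decode())
            meta.append(("junk", "junk"))

        if seqs:
            mat = _apply_errors(_encode(seqs), cfg.substitution_error_rate, rng)
            order = rng.permutation(len(seqs))
            qual = "I" * cfg.read_length
            with open(out_dir / f"{lib}.fastq", "wt") as fq:
                for out_i, src in enumerate(order):
                    read = mat[src].tobytes().decode()
                    fq.write(f"@{lib}_r{out_i:06d}\n{read}\n+\n{qual}\n")
        else:
            (out_dir / f"{lib}.fastq").write_text("")

        counts_by: dict[tuple[str, str], int] = {}
        for cat_name in meta:
            counts_by[cat_name] = counts_by.get(cat_name, 0) + 1
        for (category, name), c in sorted(counts_by.items()):
            ledger_rows.append(
                {
                    "dimension": pool.dimension,
                    "pool": pool.label,
                    "library_id": lib,
                    "category": category,
                    "source": name,
                    "count": c,
                }
            )
    return pd.DataFrame(
        ledger_rows,
        columns=["dimension", "pool", "library_id", "category", "source", "count"],
    )


# ---------------------------------------------------------------------------
# File outputs
# ---------------------------------------------------------------------------


def write_reference_fasta(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "wt") as out:
        for name in sorted(truth.chromosomes):
            seq = truth.chromosomes[name]
            out.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")


def write_gff3(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "wt") as out:
        out.write("##gff-version 3\n")
        for g in sorted(truth.genes, key=lambda g: (g.chrom, g.start)):
            out.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for j, (es, ee) in enumerate(g.exons, 1):
                out.write(
                    f"{g.chrom}\tsim\texon\t{es}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{j};Parent={g.gene_id}\n"
                )


def write_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for e in truth.insertions + truth.endogenous:
        rows.append(
            {
                "name": e.name,
                "wells": ";".join("".join(w) for w in e.wells),
                "chrom": e.chrom,
                "position": e.position,
                "tsd": e.tsd,
                "index_three": e.index_three,
                "index_five": e.index_five,
                "gene_context": e.gene_context,
                "gene_id": e.gene_id or "",
                "exon_index": e.exon_index if e.exon_index is not None else "",
                "exon_count": e.exon_count if e.exon_count is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth_alignments(
    truth: GroundTruth, path: str | Path, end: str = "three_prime", grade: int = 1
) -> int:
    """Perfect BLAST-tabular hits for every (element, well) flank — the
    alignment fixture an external aligner would produce on error-free
    data. Query IDs follow the assignment-FASTA convention
    ``<well>|grade<g>``."""
    cfg = truth.config
    n = 0
    with open(path, "wt") as out:
        for e in truth.insertions:
            flank = e.flank_three if end == "three_prime" else e.flank_five
            length = len(flank)
            if end == "three_prime":
                sstart, send = e.position, e.position + length - 1
            else:
                hi = e.position + cfg.index_length - 1
                sstart, send = hi, hi - length + 1
            for well in e.wells:
                qid = f"{''.join(well)}|grade{grade}"
                out.write(
                    f"{qid}\t{e.chrom}\t100.00\t{length}\t0\t0\t1\t{length}\t"
                    f"{sstart}\t{send}\t1e-50\t{2 * length:.1f}\n"
                )
                n += 1
    return n


def write_filter_config(cfg: SimConfig, path: str | Path) -> None:
    data = {
        "index_length": cfg.index_length,
        "ends": {
            end: {
                "primer": primer,
                "identifier": identifier,
                "max_mismatches_primer": 1,
                "max_mismatches_identifier": 1,
            }
            for end, (primer, identifier) in cfg.primers.items()
        },
        "barcodes": dict(cfg.barcodes),
        "known_endogenous": [],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def simulate(cfg: SimConfig, out_dir: str | Path) -> tuple[GroundTruth, pd.DataFrame]:
    """Full simulation run: truth + reads + every companion file.

    Writes per-pool FASTQ files, ``reference.fasta``, ``annotation.gff3``,
    ``truth.tsv``, ``ledger.tsv``, ``design.yaml`` and ``filter.yaml``
    under `out_dir`; returns (truth, ledger).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(cfg)
    ledger = simulate_reads(truth, out_dir / "reads")
    write_reference_fasta(truth, out_dir / "reference.fasta")
    write_gff3(truth, out_dir / "annotation.gff3")
    write_truth_tsv(truth, out_dir / "truth.tsv")
    ledger.to_csv(out_dir / "ledger.tsv", sep="\t", index=False)
    cfg.design.to_yaml(out_dir / "design.yaml")
    write_filter_config(cfg, out_dir / "filter.yaml")
    return truth, ledger
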