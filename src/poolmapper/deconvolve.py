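"""3-D pool deconvolution: assign each element to its well of origin.

A genuine element was placed in exactly one well, so its reads occur at
high coverage in exactly three pooled libraries — its plate pool, its row
pool and its column pool. Conversely an index sequence that ranks highly in
exactly one pool of each dimension identifies the well at their
intersection.

Two grades of assignment are made. Grade-1: a pool of a given dimension
contains `expected` genuine elements (R*C for a plate pool, etc.), so the
top ``floor(TH_G1 * expected)`` ranking indices of each pool are its
candidates (TH_G1 defaults to 1.5, leaving headroom for noise); an index
that is a candidate in exactly one pool per dimension is assigned Grade-1.
Grade-2 rescues elements that under-amplified in a single library: two
dimensions as strict as Grade-1, and in the remaining dimension a unique
pool within the relaxed bound ``floor(TH_G2 * expected)`` (TH_G2 default 3)
but beyond the Grade-1 bound.

Endogenous elements — copies native to the host genome rather than a
single well — are amplified from every sample and therefore rank highly in
more than half of all pools, against exactly 3 for a genuine element; they
are inferred first and excluded from candidacy. An index landing in several
candidate pools of one dimension implies multiple wells (e.g. a premeiotic
transposition inherited by several progeny) and is reported for
investigation rather than assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import pandas as pd

from .design import DIMENSIONS, PoolDesign
from .store import ReadStore

#: pool key: (dimension, label)
PoolKey = tuple[str, str]
CoverageMap = Mapping[PoolKey, pd.DataFrame]


@dataclass(frozen=True)
class DeconvolutionConfig:
    """Thresholds driving candidate selection and endogenous inference.

    th_g1:
        Grade-1 candidate multiplier on the expected per-pool element count
        (default 1.5; raise for noisier reads).
    th_g2:
        Relaxed multiplier for the single weak dimension of a Grade-2
        assignment (default 3); must be >= th_g1.
    endogenous_pool_fraction:
        An index prominent in strictly more than this fraction of all pools
        is inferred endogenous (default 0.5).
    endogenous_min_rank_fraction:
        Prominence bound for endogenous inference as a multiplier on the
        expected per-pool count; ``None`` reuses th_g1, keeping a single
        coherent notion of "high coverage".
    max_multi_wells:
        An index implying more than this many wells is reclassified as
        suspected endogenous instead of multi-well.
    """

    th_g1: float = 1.5
    th_g2: float = 3.0
    endogenous_pool_fraction: float = 0.5
    endogenous_min_rank_fraction: float | None = None
    max_multi_wells: int = 8

    def __post_init__(self) -> None:
        if self.th_g1 <= 0 or self.th_g2 <= 0:
            raise ValueError("thresholds must be positive")
        if self.th_g2 < self.th_g1:
            raise ValueError("th_g2 must be >= th_g1 (Grade-2 is a relaxation)")
        if not (0 < self.endogenous_pool_fraction <= 1):
            raise ValueError("endogenous_pool_fraction must be in (0, 1]")

    @property
    def prominence_fraction(self) -> float:
        return (
            self.th_g1
            if self.endogenous_min_rank_fraction is None
            else self.endogenous_min_rank_fraction
        )


@dataclass(frozen=True)
class WellAssignment:
    """A deconvoluted element assigned to one well."""

    index_seq: str
    representative_read: str
    plate: str
    row: str
    column: str
    grade: int
    ranks: dict[str, int] = field(compare=False, default_factory=dict)
    norm_cov: dict[str, float] = field(compare=False, default_factory=dict)
    ambiguous: bool = False  # another index was assigned to the same well
    weak_dimension: str | None = None  # Grade-2 only

    @property
    def well(self) -> tuple[str, str, str]:
        return (self.plate, self.row, self.column)

    def well_label(self) -> str:
        return f"{self.plate}{self.row}{self.column}"


@dataclass(frozen=True)
class MultiWellElement:
    """An index that is a candidate in >1 pool of some dimension, hence
    assignable to several wells (premeiotic-transposition signature)."""

    index_seq: str
    representative_read: str
    plates: tuple[str, ...]
    rows: tuple[str, ...]
    columns: tuple[str, ...]

    @property
    def implied_wells(self) -> tuple[tuple[str, str, str], ...]:
        return tuple(product(self.plates, self.rows, self.columns))


@dataclass
class DeconvolutionResult:
    design: PoolDesign
    config: DeconvolutionConfig
    assignments: list[WellAssignment]
    multi_well: list[MultiWellElement]
    endogenous: pd.DataFrame  # columns: index_seq, n_pools, pools
    suspected_endogenous: list[str]
    ambiguous_grade2: list[str]
    unresolved_wells: list[tuple[str, str, str]]

    @property
    def grade1(self) -> list[WellAssignment]:
        return [a for a in self.assignments if a.grade == 1]

    @property
    def grade2(self) -> list[WellAssignment]:
        return [a for a in self.assignments if a.grade == 2]


# ---------------------------------------------------------------------------
# Coverage access
# ---------------------------------------------------------------------------


def load_coverages(
    store: ReadStore, design: PoolDesign, element_type: str
) -> dict[PoolKey, pd.DataFrame]:
    """Compute a coverage table for every pool of the design."""
    return {
        pool.key: store.compute_coverage(element_type, pool.library_id)
        for pool in design.pools()
    }


def _check_coverages(design: PoolDesign, coverages: CoverageMap) -> None:
    for pool in design.pools():
        if pool.key not in coverages:
            raise KeyError(
                f"no coverage table for pool {pool.dimension} {pool.label!r} "
                f"(library {pool.library_id})"
            )


def _ranked_slice(
    cov: pd.DataFrame, max_rank: int, min_rank: int = 1
) -> dict[str, tuple[int, float, str]]:
    """index_seq -> (rank, norm_cov, representative_read) for ranks in
    [min_rank, max_rank]."""
    if cov.empty:
        return {}
    sel = cov[(cov["rank"] >= min_rank) & (cov["rank"] <= max_rank)]
    return {
        r.index_seq: (int(r.rank), float(r.norm_cov), r.representative_read)
        for r in sel.itertuples()
    }


# ---------------------------------------------------------------------------
# Candidate selection and endogenous inference
# ---------------------------------------------------------------------------


def candidate_sets(
    design: PoolDesign,
    cfg: DeconvolutionConfig,
    coverages: CoverageMap,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> dict[PoolKey, dict[str, tuple[int, float, str]]]:
    """Grade-1 candidate indices per pool: rank within
    ``floor(th_g1 * expected_per_pool)``, minus excluded (endogenous)
    indices. Pools with fewer distinct indices than the bound return all."""
    _check_coverages(design, coverages)
    out: dict[PoolKey, dict[str, tuple[int, float, str]]] = {}
    for pool in design.pools():
        bound = design.candidate_bound(pool.dimension, cfg.th_g1)
        members = _ranked_slice(coverages[pool.key], bound)
        out[pool.key] = {k: v for k, v in members.items() if k not in exclude}
    return out


def relaxed_sets(
    design: PoolDesign,
    cfg: DeconvolutionConfig,
    coverages: CoverageMap,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> dict[PoolKey, dict[str, tuple[int, float, str]]]:
    """Grade-2 relaxed indices per pool: beyond the Grade-1 bound but within
    ``floor(th_g2 * expected_per_pool)``."""
    _check_coverages(design, coverages)
    out: dict[PoolKey, dict[str, tuple[int, float, str]]] = {}
    for pool in design.pools():
        g1 = design.candidate_bound(pool.dimension, cfg.th_g1)
        g2 = design.candidate_bound(pool.dimension, cfg.th_g2)
        members = _ranked_slice(coverages[pool.key], g2, min_rank=g1 + 1)
        out[pool.key] = {k: v for k, v in members.items() if k not in exclude}
    return out


def infer_endogenous(
    design: PoolDesign, cfg: DeconvolutionConfig, coverages: CoverageMap
) -> tuple[set[str], pd.DataFrame]:
    """Infer endogenous indices: prominent (within the pool's candidate
    bound) in strictly more than ``endogenous_pool_fraction`` of all pools.

    Returns the index set and an evidence frame listing, per index, the
    pools where it is prominent and its rank in each.
    """
    _check_coverages(design, coverages)
    prominence: dict[str, list[tuple[str, str, int]]] = {}
    for pool in design.pools():
        bound = design.candidate_bound(pool.dimension, cfg.prominence_fraction)
        for idx, (rank, _cov, _rep) in _ranked_slice(coverages[pool.key], bound).items():
            prominence.setdefault(idx, []).append((pool.dimension, pool.label, rank))
    cutoff = cfg.endogenous_pool_fraction * design.n_pools
    rows = []
    endo: set[str] = set()
    for idx in sorted(prominence):
        pools = prominence[idx]
        if len(pools) > cutoff:
            endo.add(idx)
            rows.append(
                {
                    "index_seq": idx,
                    "n_pools": len(pools),
                    "pools": ";".join(f"{d}:{l}(rank {r})" for d, l, r in pools),
                }
            )
    evidence = pd.DataFrame(rows, columns=["index_seq", "n_pools", "pools"])
    return endo, evidence


# ---------------------------------------------------------------------------
# Grade-1 / Grade-2 assignment
# ---------------------------------------------------------------------------


def _membership_by_dimension(
    candidates: Mapping[PoolKey, Mapping[str, tuple[int, float, str]]],
) -> dict[str, dict[str, list[str]]]:
    """index -> dimension -> sorted pool labels whose candidate set holds it."""
    members: dict[str, dict[str, list[str]]] = {}
    for (dim, label), idx_map in candidates.items():
        for idx in idx_map:
            members.setdefault(idx, {d: [] for d in DIMENSIONS})[dim].append(label)
    for dim_map in members.values():
        for labels in dim_map.values():
            labels.sort()
    return members


def _evidence(
    candidates: Mapping[PoolKey, Mapping[str, tuple[int, float, str]]],
    idx: str,
    wells: tuple[str, str, str],
) -> tuple[dict[str, int], dict[str, float], str]:
    """Per-dimension rank/coverage for an index at a well; representative
    read taken from the plate pool (falling back along dimensions)."""
    ranks: dict[str, int] = {}
    covs: dict[str, float] = {}
    rep = ""
    for dim, label in zip(DIMENSIONS, wells):
        rank, cov, dim_rep = candidates[(dim, label)][idx]
        ranks[dim] = rank
        covs[dim] = cov
        if not rep:
            rep = dim_rep
    return ranks, covs, rep


def assign_grade1(
    design: PoolDesign,
    cfg: DeconvolutionConfig,
    candidates: Mapping[PoolKey, Mapping[str, tuple[int, float, str]]],
) -> tuple[list[WellAssignment], list[MultiWellElement], list[str]]:
    """Grade-1 pass over the candidate sets.

    Returns (assignments, multi-well elements, suspected-endogenous
    indices). An index present in exactly one candidate pool per dimension
    is assigned to that intersection; one present in several pools of some
    dimension (every dimension still covered) implies the cartesian product
    of wells and is reported as multi-well, unless the product exceeds
    ``cfg.max_multi_wells`` in which case it is suspected endogenous.
    """
    members = _membership_by_dimension(candidates)
    assignments: list[WellAssignment] = []
    multi: list[MultiWellElement] = []
    suspected: list[str] = []
    for idx in sorted(members):
        dims = members[idx]
        counts = tuple(len(dims[d]) for d in DIMENSIONS)
        if 0 in counts:
            continue  # not resolvable at Grade-1; Grade-2 may rescue
        if counts == (1, 1, 1):
            well = (dims["plate"][0], dims["row"][0], dims["column"][0])
            ranks, covs, rep = _evidence(candidates, idx, well)
            assignments.append(
                WellAssignment(idx, rep, *well, grade=1, ranks=ranks, norm_cov=covs)
            )
        else:
            n_wells = counts[0] * counts[1] * counts[2]
            if n_wells > cfg.max_multi_wells:
                suspected.append(idx)
                continue
            first = (dims["plate"][0], dims["row"][0], dims["column"][0])
            _, _, rep = _evidence(candidates, idx, first)
            multi.append(
                MultiWellElement(
                    idx,
                    rep,
                    tuple(dims["plate"]),
                    tuple(dims["row"]),
                    tuple(dims["column"]),
                )
            )
    return assignments, multi, suspected


def assign_grade2(
    design: PoolDesign,
    cfg: DeconvolutionConfig,
    candidates: Mapping[PoolKey, Mapping[str, tuple[int, float, str]]],
    relaxed: Mapping[PoolKey, Mapping[str, tuple[int, float, str]]],
    already_assigned: set[str],
) -> tuple[list[WellAssignment], list[str]]:
    """Grade-2 pass: rescue indices with two strict dimensions and one weak.

    An index unassigned at Grade-1, a candidate in exactly one pool of each
    of two dimensions and absent from the third, is assigned Grade-2 when
    the missing dimension holds it in exactly one pool within the relaxed
    (th_g2) bound. Several relaxed pools in the weak dimension → ambiguous,
    reported but not assigned.
    """
    strict = _membership_by_dimension(candidates)
    weak = _membership_by_dimension(relaxed)
    assignments: list[WellAssignment] = []
    ambiguous: list[str] = []
    for idx in sorted(strict):
        if idx in already_assigned:
            continue
        dims = strict[idx]
        counts = {d: len(dims[d]) for d in DIMENSIONS}
        missing = [d for d in DIMENSIONS if counts[d] == 0]
        if len(missing) != 1:
            continue
        weak_dim = missing[0]
        if any(counts[d] != 1 for d in DIMENSIONS if d != weak_dim):
            continue
        weak_pools = weak.get(idx, {}).get(weak_dim, [])
        if len(weak_pools) == 0:
            continue
        if len(weak_pools) > 1:
            ambiguous.append(idx)
            continue
        coords: dict[str, str] = {
            d: dims[d][0] for d in DIMENSIONS if d != weak_dim
        }
        coords[weak_dim] = weak_pools[0]
        well = (coords["plate"], coords["row"], coords["column"])
        ranks: dict[str, int] = {}
        covs: dict[str, float] = {}
        rep = ""
        for dim, label in zip(DIMENSIONS, well):
            source = relaxed if dim == weak_dim else candidates
            rank, cov, dim_rep = source[(dim, label)][idx]
            ranks[dim] = rank
            covs[dim] = cov
            if not rep:
                rep = dim_rep
        assignments.append(
            WellAssignment(
                idx, rep, *well, grade=2, ranks=ranks, norm_cov=covs,
                weak_dimension=weak_dim,
            )
        )
    return assignments, ambiguous


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def deconvolve(
    design: PoolDesign,
    coverages: CoverageMap,
    cfg: DeconvolutionConfig | None = None,
) -> DeconvolutionResult:
    """Full deconvolution: endogenous inference, Grade-1, Grade-2, flags.

    Output ordering is deterministic: assignments sorted by (plate, row,
    column, index_seq). Wells receiving two different indices are kept and
    both flagged ambiguous (a collision worth investigating); wells covered
    by neither an assignment nor a multi-well element are unresolved.
    """
    cfg = cfg or DeconvolutionConfig()
    endo_set, endo_evidence = infer_endogenous(design, cfg, coverages)
    candidates = candidate_sets(design, cfg, coverages, exclude=endo_set)
    relaxed = relaxed_sets(design, cfg, coverages, exclude=endo_set)
    g1, multi, suspected = assign_grade1(design, cfg, candidates)
    assigned = {a.index_seq for a in g1} | {m.index_seq for m in multi} | set(suspected)
    g2, ambiguous = assign_grade2(design, cfg, candidates, relaxed, assigned)

    assignments = g1 + g2
    by_well: dict[tuple[str, str, str], list[int]] = {}
    for i, a in enumerate(assignments):
        by_well.setdefault(a.well, []).append(i)
    for well, idxs in by_well.items():
        if len(idxs) > 1:
            for i in idxs:
                a = assignments[i]
                assignments[i] = WellAssignment(
                    a.index_seq, a.representative_read, *a.well, grade=a.grade,
                    ranks=a.ranks, norm_cov=a.norm_cov, ambiguous=True,
                    weak_dimension=a.weak_dimension,
                )
    assignments.sort(key=lambda a: (a.plate, a.row, a.column, a.index_seq))

    covered = {a.well for a in assignments}
    for m in multi:
        covered.update(m.implied_wells)
    unresolved = [w for w in design.iter_wells() if w not in covered]
    return DeconvolutionResult(
        design=design,
        config=cfg,
        assignments=assignments,
        multi_well=sorted(multi, key=lambda m: m.index_seq),
        endogenous=endo_evidence,
        suspected_endogenous=sorted(suspected),
        ambiguous_grade2=sorted(ambiguous),
        unresolved_wells=unresolved,
    )


def deconvolve_store(
    store: ReadStore,
    design: PoolDesign,
    element_type: str,
    cfg: DeconvolutionConfig | None = None,
) -> DeconvolutionResult:
    """Convenience: compute coverages from a read store, then deconvolve."""
    return deconvolve(design, load_coverages(store, design, element_type), cfg)
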