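"""Deconvolution: candidate bounds, grading, endogenous inference, reports.

The grading algorithms are checked against an exhaustive brute-force
enumerator over all (index, well) consistency combinations on random small
cubes, per the oracle-equivalence requirement.
"""

import math

import numpy as np
import pytest

from conftest import make_coverage
from poolmapper.deconvolve import (
    DeconvolutionConfig,
    assign_grade1,
    assign_grade2,
    candidate_sets,
    deconvolve,
    infer_endogenous,
    relaxed_sets,
)
from poolmapper.design import DIMENSIONS, PoolDesign
from poolmapper.report import emit_report, write_fasta
from poolmapper.simpool import SimConfig, simulate
from poolmapper.pipeline import run_pipeline


def _coverages(design, counts_by_pool):
    """pool key -> coverage table, empty tables for unlisted pools."""
    return {
        pool.key: make_coverage(counts_by_pool.get(pool.key, {"ZZ": 1}))
        for pool in design.pools()
    }


def _well_counts(design, truth_wells, base=100):
    """Counts placing one distinct index per well into its three pools."""
    counts = {pool.key: {} for pool in design.pools()}
    for i, well in enumerate(truth_wells):
        idx = f"IDX{i:03d}"
        for dim, label in zip(DIMENSIONS, well):
            counts[(dim, label)][idx] = base
    return counts


# ---------------------------------------------------------------------------
# Candidate sets
# ---------------------------------------------------------------------------


def test_candidate_sets_respect_per_dimension_bounds():
    design = PoolDesign.grid(3, 3, 3)
    cfg = DeconvolutionConfig()
    # 20 indices in one plate pool; bound floor(1.5*9)=13
    counts = {("plate", "01"): {f"I{i:02d}": 100 - i for i in range(20)}}
    cands = candidate_sets(design, cfg, _coverages(design, counts))
    assert len(cands[("plate", "01")]) == 13
    assert set(cands[("plate", "01")]) == {f"I{i:02d}" for i in range(13)}


def test_candidate_sets_return_all_when_pool_is_small():
    design = PoolDesign.grid(3, 3, 3)
    counts = {("row", "A"): {f"I{i}": 5 for i in range(4)}}
    cands = candidate_sets(design, DeconvolutionConfig(), _coverages(design, counts))
    assert len(cands[("row", "A")]) == 4


def test_missing_pool_coverage_is_a_hard_error_naming_the_pool():
    design = PoolDesign.grid(2, 2, 2)
    covs = {p.key: make_coverage({"AA": 1}) for p in design.pools()}
    del covs[("column", "02")]
    with pytest.raises(KeyError, match="column '02'"):
        candidate_sets(design, DeconvolutionConfig(), covs)


def test_relaxed_sets_cover_ranks_between_the_two_bounds():
    design = PoolDesign.grid(3, 3, 3)
    counts = {("plate", "01"): {f"I{i:02d}": 100 - i for i in range(40)}}
    relaxed = relaxed_sets(design, DeconvolutionConfig(), _coverages(design, counts))
    # g1 bound 13, g2 bound 27: relaxed holds ranks 14..27
    assert set(relaxed[("plate", "01")]) == {f"I{i:02d}" for i in range(13, 27)}


# ---------------------------------------------------------------------------
# Grading on constructed cubes
# ---------------------------------------------------------------------------


def test_unique_triple_intersection_is_grade1():
    design = PoolDesign.grid(3, 3, 3)
    counts = _well_counts(design, [("02", "B", "03")])
    result = deconvolve(design, _coverages(design, counts))
    (a,) = result.assignments
    assert a.well == ("02", "B", "03") and a.grade == 1 and not a.ambiguous
    assert a.well_label() == "02B03"


def test_index_in_two_plate_pools_is_multi_well_with_two_implied_wells():
    design = PoolDesign.grid(3, 3, 3)
    counts = {pool.key: {} for pool in design.pools()}
    for key in [("plate", "01"), ("plate", "02"), ("row", "A"), ("column", "01")]:
        counts[key]["DUP"] = 50
    result = deconvolve(design, _coverages(design, counts))
    assert not result.assignments
    (m,) = result.multi_well
    assert set(m.implied_wells) == {("01", "A", "01"), ("02", "A", "01")}


def test_noise_free_cube_fully_resolves_grade1():
    design = PoolDesign.grid(3, 3, 3)
    counts = _well_counts(design, list(design.iter_wells()))
    result = deconvolve(design, _coverages(design, counts))
    assert len(result.grade1) == 27
    assert not result.unresolved_wells
    assert {a.well for a in result.grade1} == set(design.iter_wells())


def test_well_collision_keeps_both_flagged_ambiguous():
    design = PoolDesign.grid(2, 2, 2)
    counts = {pool.key: {} for pool in design.pools()}
    for idx in ("AAAA", "CCCC"):
        for key in [("plate", "01"), ("row", "A"), ("column", "01")]:
            counts[key][idx] = 40
    result = deconvolve(design, _coverages(design, counts))
    assert len(result.assignments) == 2
    assert all(a.ambiguous and a.well == ("01", "A", "01") for a in result.assignments)


def test_grade2_rescues_single_weak_dimension():
    design = PoolDesign.grid(3, 3, 3)  # g1 bound 13, g2 bound 27
    counts = {pool.key: {} for pool in design.pools()}
    counts[("row", "B")]["WEAK"] = 90
    counts[("column", "02")]["WEAK"] = 90
    # rank 20 in its plate pool: beyond Grade-1, within Grade-2
    counts[("plate", "02")] = {f"F{i:02d}": 100 - i for i in range(19)}
    counts[("plate", "02")]["WEAK"] = 50
    result = deconvolve(design, _coverages(design, counts))
    (a,) = result.assignments
    assert a.grade == 2 and a.well == ("02", "B", "02")
    assert a.weak_dimension == "plate"
    assert a.ranks["plate"] == 20


def test_beyond_grade2_bound_is_not_assigned():
    design = PoolDesign.grid(3, 3, 3)
    counts = {pool.key: {} for pool in design.pools()}
    counts[("row", "B")]["WEAK"] = 90
    counts[("column", "02")]["WEAK"] = 90
    counts[("plate", "02")] = {f"F{i:02d}": 100 - i for i in range(30)}
    counts[("plate", "02")]["WEAK"] = 1  # rank 31 > floor(3*9)=27
    result = deconvolve(design, _coverages(design, counts))
    assert not result.assignments


def test_weak_dimension_ambiguous_between_two_pools_is_reported_not_assigned():
    design = PoolDesign.grid(3, 3, 3)
    counts = {pool.key: {} for pool in design.pools()}
    counts[("row", "B")]["AMB"] = 90
    counts[("column", "02")]["AMB"] = 90
    for plate in ("01", "03"):
        counts[("plate", plate)] = {f"F{plate}{i:02d}": 100 - i for i in range(19)}
        counts[("plate", plate)]["AMB"] = 50  # rank 20 in both plate pools
    result = deconvolve(design, _coverages(design, counts))
    assert not result.assignments
    assert result.ambiguous_grade2 == ["AMB"]


# ---------------------------------------------------------------------------
# Endogenous inference
# ---------------------------------------------------------------------------


def test_endogenous_boundary_is_strictly_more_than_half_of_30_pools():
    design = PoolDesign.grid(10, 8, 12)  # 30 pools
    cfg = DeconvolutionConfig()
    for n_pools, expected in [(16, True), (15, False)]:
        counts = {}
        pools = design.pools()
        for pool in pools[:n_pools]:
            counts[pool.key] = {"ENDO": 100, "OTHER": 10}
        endo, evidence = infer_endogenous(design, cfg, _coverages(design, counts))
        assert ("ENDO" in endo) is expected
        if expected:
            assert evidence.iloc[0].n_pools == 16


def test_genuine_element_in_three_pools_is_not_endogenous():
    design = PoolDesign.grid(2, 2, 2)  # 6 pools, cutoff 3
    counts = _well_counts(design, [("01", "A", "01")])
    endo, _ = infer_endogenous(design, DeconvolutionConfig(), _coverages(design, counts))
    assert not endo


def test_endogenous_indices_are_excluded_from_assignment():
    design = PoolDesign.grid(2, 2, 2)
    counts = {pool.key: {"EVERY": 100} for pool in design.pools()}
    # plus one genuine element
    for dim, label in zip(DIMENSIONS, ("01", "A", "01")):
        counts[(dim, label)]["GENUINE"] = 50
    result = deconvolve(design, _coverages(design, counts))
    assert "EVERY" in set(result.endogenous.index_seq)
    assert [a.index_seq for a in result.assignments] == ["GENUINE"]


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence
# ---------------------------------------------------------------------------


def _naive_members(design, counts_by_pool, threshold):
    """Independent ranking + thresholding: sort counts, take the top
    floor(threshold * expected) indices of each pool."""
    members = {}
    for pool in design.pools():
        bound = math.floor(threshold * design.expected_per_pool(pool.dimension))
        counts = counts_by_pool.get(pool.key, {})
        order = sorted(counts, key=lambda i: (-counts[i], i))
        members[pool.key] = set(order[:bound])
    return members


def _brute_force(design, counts_by_pool, th_g1=1.5, th_g2=3.0, max_multi=8):
    """Enumerate every (index, well) combination and test consistency
    directly against the per-pool member sets."""
    strict = _naive_members(design, counts_by_pool, th_g1)
    relaxed_full = _naive_members(design, counts_by_pool, th_g2)
    relaxed = {k: relaxed_full[k] - strict[k] for k in relaxed_full}
    universe = set().union(*strict.values(), *relaxed.values())

    g1, multi, suspected, g2, ambiguous = {}, {}, set(), {}, set()
    for idx in universe:
        consistent = [
            well
            for well in design.iter_wells()
            if all(
                idx in strict[(dim, label)]
                for dim, label in zip(DIMENSIONS, well)
            )
        ]
        if len(consistent) == 1:
            g1[idx] = consistent[0]
            continue
        if len(consistent) > 1:
            if len(consistent) > max_multi:
                suspected.add(idx)
            else:
                multi[idx] = frozenset(consistent)
            continue
        # Grade-2: two dimensions exactly as strict as Grade-1, the third
        # absent from every strict set but present in exactly one relaxed pool
        rescue = []
        for well in design.iter_wells():
            ok = 0
            weak = []
            for axis, dim in enumerate(DIMENSIONS):
                in_pools = [
                    lab for lab in design.labels(dim) if idx in strict[(dim, lab)]
                ]
                if in_pools == [well[axis]]:
                    ok += 1
                elif not in_pools:
                    weak.append((dim, well[axis]))
            if ok == 2 and len(weak) == 1 and idx in relaxed[weak[0]]:
                rescue.append(well)
        if len(rescue) == 1:
            g2[idx] = rescue[0]
        elif len(rescue) > 1:
            ambiguous.add(idx)
    return g1, multi, suspected, g2, ambiguous


def _random_instance(rng, design, n_indices=40):
    counts = {}
    names = [f"I{i:02d}" for i in range(n_indices)]
    for pool in design.pools():
        present = [n for n in names if rng.random() < 0.5]
        counts[pool.key] = {n: int(rng.integers(1, 20)) for n in present}
    return counts


@pytest.mark.parametrize("seed", range(100))
def test_grading_matches_brute_force_enumerator(seed):
    design = PoolDesign.grid(3, 3, 3)
    cfg = DeconvolutionConfig()
    counts = _random_instance(np.random.default_rng(seed), design)
    covs = _coverages(design, counts)

    cands = candidate_sets(design, cfg, covs)
    relaxed = relaxed_sets(design, cfg, covs)
    g1, multi, suspected = assign_grade1(design, cfg, cands)
    assigned = {a.index_seq for a in g1} | {m.index_seq for m in multi} | set(suspected)
    g2, ambiguous = assign_grade2(design, cfg, cands, relaxed, assigned)

    eg1, emulti, esusp, eg2, eamb = _brute_force(design, counts)
    assert {a.index_seq: a.well for a in g1} == eg1
    assert {m.index_seq: frozenset(m.implied_wells) for m in multi} == emulti
    assert set(suspected) == esusp
    assert {a.index_seq: a.well for a in g2} == eg2
    assert set(ambiguous) == eamb


def _run_grading(design, cfg, covs):
    cands = candidate_sets(design, cfg, covs)
    g1, multi, suspected = assign_grade1(design, cfg, cands)
    return g1, multi, suspected


@pytest.mark.parametrize("seed", range(20))
def test_raising_th_g1_never_silently_reassigns(seed):
    """An unambiguous Grade-1 assignment under th_g1=a is, under th_g1>a,
    either reproduced or flagged (multi-well/suspected) — never moved to a
    different well. Candidate sets only grow, so uniqueness can be lost but
    the original well stays among the implied ones."""
    design = PoolDesign.grid(3, 3, 3)
    counts = _random_instance(np.random.default_rng(1000 + seed), design)
    covs = _coverages(design, counts)
    g1_low, _, _ = _run_grading(design, DeconvolutionConfig(th_g1=1.5), covs)
    cfg_high = DeconvolutionConfig(th_g1=2.5, th_g2=3.0)
    g1_high, multi_high, susp_high = _run_grading(design, cfg_high, covs)
    high_wells = {a.index_seq: a.well for a in g1_high}
    high_multi = {m.index_seq: set(m.implied_wells) for m in multi_high}
    for a in g1_low:
        if a.index_seq in high_wells:
            assert high_wells[a.index_seq] == a.well
        elif a.index_seq in high_multi:
            assert a.well in high_multi[a.index_seq]
        else:
            assert a.index_seq in susp_high


# ---------------------------------------------------------------------------
# End-to-end behaviours on simulated data
# ---------------------------------------------------------------------------


def test_small_noise_free_simulation_candidate_sets_contain_all_genuine(tmp_path):
    cfg = SimConfig(
        seed=5,
        design=PoolDesign.grid(3, 3, 3),
        reads_per_pool=2_000,
        noise_fraction=0.0,
        substitution_error_rate=0.0,
        n_endogenous=0,
    )
    truth, _ = simulate(cfg, tmp_path)
    spec = cfg.filter_specs()["three_prime"]
    result, _ = run_pipeline(cfg.design, tmp_path / "reads", spec)
    assert len(result.grade1) == 27 and not result.unresolved_wells
    truth_map = {e.wells[0]: e.index_three for e in truth.insertions}
    assert all(truth_map[a.well] == a.index_seq for a in result.grade1)


def test_duplicate_well_insertion_reported_as_multi_well(tmp_path):
    # 4x4x4: 12 pools, so the duplicate's 6-pool footprint stays below the
    # endogenous-inference cutoff (a genuinely premeiotic-like signature)
    dup = ((("01", "A", "01"), ("02", "B", "03")),)
    cfg = SimConfig(
        seed=6,
        design=PoolDesign.grid(4, 4, 4),
        reads_per_pool=2_000,
        noise_fraction=0.0,
        substitution_error_rate=0.0,
        n_endogenous=0,
        duplicate_wells=dup,
    )
    truth, _ = simulate(cfg, tmp_path)
    spec = cfg.filter_specs()["three_prime"]
    result, _ = run_pipeline(cfg.design, tmp_path / "reads", spec)
    shared = next(e for e in truth.insertions if len(e.wells) == 2)
    (m,) = [m for m in result.multi_well if m.index_seq == shared.index_three]
    assert set(shared.wells) <= set(m.implied_wells)
    assert not any(a.index_seq == shared.index_three for a in result.assignments)


def test_spiked_endogenous_elements_are_inferred_and_never_assigned(noisy_run):
    endo_truth = noisy_run.truth.endogenous_indices()
    inferred = set(noisy_run.result.endogenous.index_seq)
    three_prime_endo = {e.index_three for e in noisy_run.truth.endogenous}
    assert three_prime_endo <= inferred
    assert not endo_truth & {a.index_seq for a in noisy_run.result.assignments}


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def test_empty_result_yields_valid_grid_and_empty_fasta(tmp_path):
    design = PoolDesign.grid(2, 2, 2)
    result = deconvolve(design, {p.key: make_coverage({"ZZ": 1}) for p in design.pools()})
    paths = emit_report(result, tmp_path)
    html = paths["index_html"].read_text()
    assert "unresolved" in html and html.count("<table") == len(design.plates)
    assert paths["assignments_fasta"].read_text() == ""


def test_fasta_header_carries_well_coordinates(tmp_path):
    design = PoolDesign(["21", "22"], ["D", "E"], ["03", "04"])
    counts = _well_counts(design, [("22", "E", "04")])
    result = deconvolve(design, _coverages(design, counts))
    out = tmp_path / "a.fasta"
    write_fasta(result, out)
    assert out.read_text().startswith(">22E04|grade1\n")


def test_fasta_record_count_equals_assignment_count(zero_noise_run, tmp_path):
    paths = emit_report(zero_noise_run.result, tmp_path)
    n_records = paths["assignments_fasta"].read_text().count(">")
    assert n_records == len(zero_noise_run.result.assignments) == 96
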