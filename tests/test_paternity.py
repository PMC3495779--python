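"""Paternity LOD machinery: hand-checked transition probabilities, an
enumeration oracle for the LOD denominator, threshold calibration behavior,
categorization and network bookkeeping."""

import numpy as np
import pytest

from pollenflow import paternity
from pollenflow.core_io import Locus
from pollenflow.paternity import (CATEGORY_ASSIGNED, CATEGORY_BELOW,
                                  CATEGORY_NONE, assign, calibrate_threshold,
                                  immigration_bounds,
                                  immigration_bounds_from_counts, lod_matrix,
                                  lod_score, mating_network,
                                  transition_probability)
from pollenflow.popgen import AlleleFrequencies, allele_freqs
from pollenflow.simgen import SimulationScenario, simulate_dataset

from conftest import make_progeny, make_table


@pytest.mark.parametrize("off,mom,dad,expected", [
    ((0, 1), (0, 1), (0, 1), 0.5),    # het x het -> het offspring
    ((0, 1), (0, 0), (1, 1), 1.0),    # fully determined cross
    ((0, 0), (0, 0), (0, 1), 0.5),    # father transmits 0 half the time
    ((0, 0), (0, 0), (1, 1), 0.0),    # father cannot transmit 0
    ((2, 3), (0, 1), (2, 3), 0.0),    # seed incompatible with the mother
    ((0, 1), (0, 1), (1, 1), 0.5),    # paternal 1 w=0.5 x 1, paternal 0 w=0
])
def test_transition_probability_hand_cases(off, mom, dad, expected):
    got = transition_probability(np.array(off), np.array(mom), np.array(dad))
    assert got == pytest.approx(expected)


def _genotype_probs(p, F):
    """All genotypes (i <= j) with Hardy-Weinberg-with-inbreeding probs."""
    k = len(p)
    out = []
    for i in range(k):
        out.append(((i, i), F * p[i] + (1 - F) * p[i] ** 2))
        for j in range(i + 1, k):
            out.append(((i, j), (1 - F) * 2 * p[i] * p[j]))
    return out


@pytest.mark.parametrize("F", [0.0, 0.3])
def test_lod_matches_enumerated_denominator(F):
    """The LOD denominator equals the transition probability marginalized
    over a random father enumerated genotype-by-genotype; inbreeding F of
    the random father provably cancels from the gamete marginal."""
    rng = np.random.default_rng(14)
    freqs_per_locus = [np.array([0.5, 0.3, 0.2]), np.array([0.6, 0.4])]
    loci = [Locus(f"L{l}", [str(a) for a in range(len(p))])
            for l, p in enumerate(freqs_per_locus)]
    ref = AlleleFrequencies(loci, freqs_per_locus)
    for _ in range(30):
        mom, dad, off = [], [], []
        for p in freqs_per_locus:
            k = len(p)
            m = tuple(rng.integers(k, size=2))
            d = tuple(rng.integers(k, size=2))
            off.append((m[rng.integers(2)], d[rng.integers(2)]))
            mom.append(m)
            dad.append(d)
        mg, dg, og = (np.array(x, dtype=np.int32) for x in (mom, dad, off))
        expected = 0.0
        for l, p in enumerate(freqs_per_locus):
            num = transition_probability(og[l], mg[l], dg[l])
            den = sum(pr * transition_probability(og[l], mg[l], np.array(g))
                      for g, pr in _genotype_probs(p, F))
            expected += np.log(num / den)
        got = lod_score(og, mg, dg, ref, inbreeding_f=F)
        assert got == pytest.approx(expected, rel=1e-10)


def test_monomorphic_locus_contributes_zero():
    loci = [Locus("L", ["a"])]
    ref = AlleleFrequencies(loci, [np.array([1.0])])
    z = np.array([[(0, 0)]], dtype=np.int32)[0]
    assert lod_score(z, z, z, ref) == 0.0


def test_lod_matrix_agrees_with_scalar_scores():
    """The vectorized matrix equals per-seed scalar LODs, including with
    missing data (untyped male loci contribute zero in both paths)."""
    scn = SimulationScenario(n_males=25, n_females=6, n_sampled_mothers=6,
                             allele_counts=(6, 6, 6, 6), seeds_per_mother=8,
                             missing_rate=0.1)
    adults, progeny, _ = simulate_dataset(scn, 77)
    ref = allele_freqs(adults)
    male_idx = np.flatnonzero(adults.males_mask())
    mother_row = np.array([adults.index_of(m) for m in progeny.mother_ids])
    M = lod_matrix(progeny.genotypes, np.arange(len(progeny)),
                   adults.genotypes[mother_row], adults, male_idx, ref)
    rng = np.random.default_rng(0)
    for s in rng.integers(len(progeny), size=12):
        for j in rng.integers(len(male_idx), size=6):
            scalar = lod_score(progeny.genotypes[s],
                               adults.genotypes[mother_row[s]],
                               adults.genotypes[male_idx[j]], ref)
            assert M[s, j] == pytest.approx(scalar, abs=1e-9) or \
                (np.isneginf(M[s, j]) and np.isneginf(scalar))


def test_true_father_scores_high():
    """Across simulated seeds the true father's LOD exceeds the median
    candidate LOD in the vast majority of cases."""
    scn = SimulationScenario(n_males=40, n_females=8, n_sampled_mothers=8,
                             allele_counts=(10, 10, 10, 10, 10),
                             seeds_per_mother=10, immigration=0.0)
    adults, progeny, ledger = simulate_dataset(scn, 21)
    ref = allele_freqs(adults)
    male_idx = np.flatnonzero(adults.males_mask())
    ids = list(adults.ids[male_idx])
    mother_row = np.array([adults.index_of(m) for m in progeny.mother_ids])
    M = lod_matrix(progeny.genotypes, np.arange(len(progeny)),
                   adults.genotypes[mother_row], adults, male_idx, ref)
    wins = 0
    for s, father in enumerate(ledger.father_ids):
        j = ids.index(father)
        finite = M[s][np.isfinite(M[s])]
        wins += M[s, j] >= np.median(finite)
    assert wins / len(progeny) > 0.95


def test_calibration_separates_good_markers():
    scn = SimulationScenario(n_males=60, n_females=12, n_sampled_mothers=12,
                             allele_counts=(12, 12, 12, 12, 12, 12, 12))
    adults, _, _ = simulate_dataset(scn, 33)
    ref = allele_freqs(adults)
    cal = calibrate_threshold(adults, ref, n_sim=2000, seed=6)
    assert cal.separated
    assert cal.outside_lods.mean() < cal.tf < cal.inside_lods.mean()
    # informative markers: most inside-sired seeds fall above TF
    assert (cal.inside_lods > cal.tf).mean() > 0.8


def test_calibration_degenerate_markers_warn():
    """All-monomorphic loci make the two LOD distributions identical: the
    calibration must flag the failure rather than return a sharp TF."""
    t = make_table([[(0, 0)]] * 10, sex=["male"] * 8 + ["female"] * 2)
    ref = allele_freqs(t)
    with pytest.warns(UserWarning, match="indistinguishable"):
        cal = calibrate_threshold(t, ref, n_sim=1000, seed=3)
    assert not cal.separated


def test_calibration_rejects_tiny_simulations():
    t = make_table([[(0, 1)]] * 4, sex=["male", "male", "female", "female"])
    with pytest.raises(ValueError, match="n_sim"):
        calibrate_threshold(t, allele_freqs(t), n_sim=10)


def test_assignment_tie_breaks_to_closest_male():
    """Two males above TF with identical genotypes: the 10 m male wins over
    the 500 m male, and the bearing is father-to-mother."""
    adults = make_table([[(1, 1)], [(1, 1)], [(0, 0)], [(0, 0)]],
                        sex=["male", "male", "female", "male"],
                        xy=[(0.0, 10.0), (0.0, 500.0), (0.0, 0.0),
                            (300.0, 300.0)],
                        n_alleles=[2])
    # allele 1 rare in the reference: positive LOD for carriers
    ref = AlleleFrequencies(adults.loci, [np.array([0.95, 0.05])])
    prog = make_progeny(adults, [("I003", [(0, 1)])])
    res = assign(prog, adults, tf=0.0, ref_freqs=ref, min_typed_loci=1)
    row = res.table.iloc[0]
    assert row.category == CATEGORY_ASSIGNED
    assert row.father_id == "I001"
    assert row.distance_m == pytest.approx(10.0)
    assert row.bearing_deg == pytest.approx(180.0)   # father north of mother


def test_categories_partition_and_bounds():
    """Every kept seed lands in exactly one category; immigration bounds
    follow the two category counts."""
    scn = SimulationScenario(n_males=50, n_females=10, n_sampled_mothers=10,
                             allele_counts=(8, 8, 8, 8, 8, 8),
                             seeds_per_mother=12, immigration=0.4,
                             missing_rate=0.05)
    adults, progeny, _ = simulate_dataset(scn, 55)
    ref = allele_freqs(adults)
    cal = calibrate_threshold(adults, ref, n_sim=2000, seed=8)
    res = assign(progeny, adults, cal.tf, ref)
    c = res.counts()
    kept = res.table[res.table.category != "excluded"]
    assert sum(c.values()) == len(kept)
    lo, hi = immigration_bounds(res)
    n = sum(c.values())
    assert lo == pytest.approx(c[CATEGORY_NONE] / n)
    assert hi == pytest.approx((c[CATEGORY_NONE] + c[CATEGORY_BELOW]) / n)
    assert 0 <= lo <= hi <= 1
    assert immigration_bounds_from_counts(9, 0, 155) == \
        pytest.approx((9 / 164, 9 / 164))


def test_assignments_shrink_as_tf_rises():
    """Raising TF moves seeds from 'assigned' to 'below', never the
    reverse, and leaves the no-compatible-father count unchanged."""
    scn = SimulationScenario(n_males=30, n_females=6, n_sampled_mothers=6,
                             allele_counts=(8, 8, 8, 8, 8),
                             seeds_per_mother=10, immigration=0.2)
    adults, progeny, _ = simulate_dataset(scn, 91)
    ref = allele_freqs(adults)
    prev_assigned = None
    none_counts = set()
    for tf in (-5.0, 0.0, 2.0, 5.0):
        res = assign(progeny, adults, tf, ref)
        c = res.counts()
        none_counts.add(c[CATEGORY_NONE])
        if prev_assigned is not None:
            assert c[CATEGORY_ASSIGNED] <= prev_assigned
        prev_assigned = c[CATEGORY_ASSIGNED]
    assert len(none_counts) == 1


def test_short_profiles_are_excluded():
    adults = make_table([[(0, 1)] * 7], sex=["female"])
    genos = [(0, 0)] * 3 + [None] * 4          # typed at 3 < 5 loci
    prog = make_progeny(adults, [("I001", genos)])
    ref = allele_freqs(adults)
    res = assign(prog, adults, tf=0.0, ref_freqs=ref)
    assert res.table.iloc[0].category == "excluded"
    with pytest.raises(ValueError):
        immigration_bounds(res)


def test_mating_network_conservation(recovery_dataset):
    """Edge seed counts and per-male sired counts both sum to the number of
    assigned seeds; males without offspring are still reported."""
    _, adults, progeny, _ = recovery_dataset
    ref = allele_freqs(adults)
    cal = calibrate_threshold(adults, ref, n_sim=2000, seed=2)
    res = assign(progeny, adults, cal.tf, ref)
    edges, summary = mating_network(res, adults)
    assert int(edges.n_seeds.sum()) == summary["n_assigned"]
    assert int(summary["sired_counts"].sum()) == summary["n_assigned"]
    assert len(summary["sired_counts"]) == int(adults.males_mask().sum())
    assert 0 <= summary["prop_males_without_offspring"] <= 1
    if summary["n_assigned"]:
        assert summary["min_distance_m"] <= summary["mean_distance_m"] \
            <= summary["max_distance_m"]
        assert 1 <= summary["n_males_for_half_of_assignments"] \
            <= len(summary["sired_counts"])
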