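"""Dispersal kernels and tests: closed-form means vs quadrature, an
analytic overlap oracle, correlated-paternity limits, fit recovery and the
distance/direction hypothesis tests."""

import numpy as np
import pandas as pd
import pytest

from pollenflow.core_io import Locus
from pollenflow.dispersal import (CorrelatedPaternityCurve, DispersalKernel,
                                  anisotropy_test,
                                  between_mother_correlated_paternity,
                                  decay_precheck, distance_distribution_test,
                                  fit_kernel_kindist, mean_distance,
                                  mean_distance_quadrature, overlap_ratio,
                                  potential_mating_distances, rose_histogram,
                                  scale_for_delta, watson_u2)
from pollenflow.popgen import AlleleFrequencies
from pollenflow.simgen import SimulationScenario, simulate_dataset

from conftest import make_progeny, make_table


@pytest.mark.parametrize("family,a,b,expected,rmax", [
    ("exponential", 100.0, 1.0, 200.0, 60.0),     # delta = 2a
    ("normal", 100.0, 2.0, 100.0 * np.sqrt(np.pi) / 2, 60.0),
    ("geometric", 100.0, 5.0, 100.0, 1000.0),     # 2a/(b-3); heavy tail
    ("power_exponential", 50.0, 0.5, 50.0 * 120.0 / 6.0, 60.0),  # G(6)/G(4)
])
def test_mean_distance_closed_forms(family, a, b, expected, rmax):
    k = DispersalKernel(family, a, b)
    assert mean_distance(k) == pytest.approx(expected, rel=1e-12)
    assert mean_distance_quadrature(k, r_max_deltas=rmax) == \
        pytest.approx(expected, rel=1e-4)


@pytest.mark.parametrize("family,a,b", [
    ("power_exponential", 80.0, 0.3), ("power_exponential", 80.0, 1.7),
    ("geometric", 120.0, 3.5), ("exponential", 200.0, 1.0),
])
def test_pdf_normalizes_and_delta_roundtrip(family, a, b):
    k = DispersalKernel(family, a, b)
    delta = mean_distance(k)
    x, w = np.polynomial.legendre.leggauss(4096)
    R = 400.0 * delta if family == "geometric" else 60.0 * delta
    r = 0.5 * R * (x + 1.0)
    mass = float(np.sum(0.5 * R * w * 2 * np.pi * r * k.pdf(r)))
    assert mass == pytest.approx(1.0, abs=2e-3)
    a_back = scale_for_delta(family, delta, b)
    assert a_back == pytest.approx(a, rel=1e-12)


def test_kernel_validation():
    with pytest.raises(ValueError):
        DispersalKernel("geometric", 100.0, 2.0)     # improper
    with pytest.raises(ValueError):
        DispersalKernel("power_exponential", -1.0, 1.0)
    with pytest.raises(ValueError):
        DispersalKernel("cauchy", 100.0, 1.0)
    with pytest.raises(ValueError, match="diverges"):
        mean_distance(DispersalKernel("geometric", 100.0, 2.5))


def test_overlap_ratio_gaussian_oracle():
    """For the normal kernel the self-overlap has the closed form
    O(z)/O(0) = exp(-z^2 / (2 a^2)) (Gaussian autocorrelation)."""
    a = 120.0
    z = np.array([0.0, 50.0, 150.0, 300.0, 500.0])
    got = overlap_ratio(z, "normal", a, 2.0)
    expected = np.exp(-(z ** 2) / (2 * a ** 2))
    assert np.allclose(got, expected, atol=2e-4)


def test_overlap_ratio_shape_properties():
    z = np.linspace(0.0, 800.0, 9)
    for family, a, b in (("exponential", 150.0, 1.0),
                         ("power_exponential", 60.0, 0.5),
                         ("geometric", 100.0, 4.0)):
        r = overlap_ratio(z, family, a, b)
        assert r[0] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(r) < 0)
        assert np.all((r > 0) & (r <= 1.0 + 1e-9))
    # a larger scale decays more slowly at any positive lag
    r_small = overlap_ratio([300.0], "exponential", 50.0, 1.0)
    r_big = overlap_ratio([300.0], "exponential", 200.0, 1.0)
    assert r_big > r_small


def _sibship_curve(shared_father: bool, seed: int, k: int = 20,
                   n_loci: int = 10, n_seeds: int = 40):
    """Two mothers; seeds either all full sibs (one heterozygous father) or
    sired by independent random fathers from a uniform reference pool."""
    rng = np.random.default_rng(seed)
    mA = [(k - 2, k - 2)] * n_loci          # homozygous: unambiguous
    mB = [(k - 1, k - 1)] * n_loci          # subtraction
    adults = make_table([mA, mB], sex=["female", "female"],
                        xy=[(0.0, 0.0), (100.0, 0.0)], n_alleles=[k] * n_loci)
    rows = []
    for m, mat in (("I001", k - 2), ("I002", k - 1)):
        for _ in range(n_seeds):
            geno = []
            for l in range(n_loci):
                if shared_father:
                    pat = int(rng.integers(2))          # father (0, 1)
                else:
                    pat = int(rng.integers(k))
                geno.append(tuple(sorted((mat, pat))))
            rows.append((m, geno))
    progeny = make_progeny(adults, rows)
    freqs = AlleleFrequencies(adults.loci,
                              [np.full(k, 1.0 / k)] * n_loci)
    return between_mother_correlated_paternity(progeny, adults, freqs=freqs)


def test_correlated_paternity_full_sib_limit():
    """All seeds share one heterozygous father: Psi tends to (k-2)/(k-1)
    (twice the expected kinship of two gametes of the same father)."""
    k = 20
    curve = _sibship_curve(shared_father=True, seed=101, k=k)
    expected = (k - 2) / (k - 1)
    assert curve.psi_within == pytest.approx(expected, abs=0.08)
    assert curve.pairs.psi.iloc[0] == pytest.approx(expected, abs=0.08)


def test_correlated_paternity_unrelated_limit():
    curve = _sibship_curve(shared_father=False, seed=102)
    assert curve.psi_within == pytest.approx(0.0, abs=0.05)
    assert curve.pairs.psi.iloc[0] == pytest.approx(0.0, abs=0.05)


def test_decay_precheck_cases():
    pairs = pd.DataFrame({"mother_a": list("aabbcc"), "mother_b": list("defdef"),
                          "distance": [50, 100, 200, 400, 800, 1600],
                          "psi": [0.5, 0.4, 0.3, 0.2, 0.1, 0.0],
                          "n_seed_pairs": [10] * 6})
    # psi here is exactly linear in ln(distance): r = -1
    pairs["psi"] = 0.6 - 0.1 * np.log2(pairs.distance / 25.0)
    r, p = decay_precheck(CorrelatedPaternityCurve(pairs, 0.7))
    assert r == pytest.approx(-1.0, abs=1e-12)
    assert p < 1e-6
    flat = pairs.copy()
    flat["psi"] = 0.3
    with pytest.raises(ValueError, match="zero-variance"):
        decay_precheck(CorrelatedPaternityCurve(flat, 0.7))


def _model_curve(family, a, b, distances, baseline=0.05, denom=0.4):
    """Noise-free decay curve generated directly from the overlap model."""
    ratio = overlap_ratio(np.asarray(distances, float), family, a, b)
    pairs = pd.DataFrame({
        "mother_a": [f"m{i}" for i in range(len(distances))],
        "mother_b": [f"n{i}" for i in range(len(distances))],
        "distance": distances,
        "psi": baseline + denom * ratio,
        "n_seed_pairs": [50] * len(distances)})
    return CorrelatedPaternityCurve(pairs, psi_within=baseline + denom)


# lags reaching far enough that pairs past the unrelatedness threshold
# really carry no kernel overlap (otherwise the far-pair baseline is biased)
DISTS = [30, 60, 90, 120, 160, 200, 250, 320, 400, 500, 650, 800, 1000,
         1300, 1700, 2200, 2800]
FAR = 1500.0


def test_kindist_fit_recovers_exponential():
    a = 140.0
    fit = fit_kernel_kindist(_model_curve("exponential", a, 1.0, DISTS),
                             family="exponential", threshold=FAR)
    assert fit.kernel.a == pytest.approx(a, rel=0.05)
    assert fit.delta == pytest.approx(2 * a, rel=0.05)
    assert fit.rss < 1e-3


def test_kindist_fit_recovers_power_exponential():
    a, b = 20.0, 0.5                      # delta = a G(6)/G(4) = 400 m
    fit = fit_kernel_kindist(_model_curve("power_exponential", a, b, DISTS),
                             family="power_exponential", threshold=FAR)
    assert fit.kernel.b == pytest.approx(b, rel=0.15)
    assert fit.delta == pytest.approx(400.0, rel=0.15)


def test_kindist_fit_scale_equivariance():
    """Multiplying every distance by c multiplies the fitted delta by c."""
    base = fit_kernel_kindist(_model_curve("exponential", 100.0, 1.0, DISTS),
                              family="exponential", threshold=FAR)
    scaled_d = [3 * d for d in DISTS]
    scaled = fit_kernel_kindist(
        _model_curve("exponential", 300.0, 1.0, scaled_d),
        family="exponential", threshold=3 * FAR)
    assert scaled.delta == pytest.approx(3 * base.delta, rel=0.05)


def test_kindist_model_selection_sanity():
    """Data generated from the exponential kernel: the exponential fit beats
    normal and geometric, and the nesting power-exponential matches it."""
    rng = np.random.default_rng(9)
    curve = _model_curve("exponential", 140.0, 1.0, DISTS)
    curve.pairs["psi"] += rng.normal(0.0, 0.004, size=len(curve.pairs))
    fits = {fam: fit_kernel_kindist(curve, family=fam, threshold=FAR)
            for fam in ("exponential", "normal", "geometric",
                        "power_exponential")}
    assert fits["exponential"].rss < fits["normal"].rss
    assert fits["exponential"].rss < fits["geometric"].rss
    assert fits["power_exponential"].rss <= fits["exponential"].rss * 1.05


def test_kindist_fit_input_validation():
    curve = _model_curve("exponential", 100.0, 1.0, [50, 100, 150])
    with pytest.raises(ValueError, match="threshold"):
        fit_kernel_kindist(curve, threshold=300.0)   # no far pairs
    flat = _model_curve("exponential", 100.0, 1.0, DISTS, denom=0.4)
    flat.pairs["psi"] = 0.5
    bad = CorrelatedPaternityCurve(flat.pairs, psi_within=0.4)
    with pytest.raises(ValueError, match="decay signal"):
        fit_kernel_kindist(bad, threshold=300.0)


def test_distance_test_against_potential_pairs():
    scn = SimulationScenario()            # 164 males x 29 mothers
    adults, _, ledger = simulate_dataset(scn, 12)
    pot = potential_mating_distances(adults)
    assert pot.size == 164 * 29
    rng = np.random.default_rng(4)
    # a potential-distribution sample should not be rejected...
    res_null = distance_distribution_test(rng.choice(pot, 150, replace=False),
                                          adults)
    assert res_null["p"] > 0.01
    assert res_null["n_potential"] == 4756
    # ...while strictly-nearest-neighbour mating must be
    obs = np.sort(pot)[:150]
    res_alt = distance_distribution_test(obs, adults, n_perm=200, seed=7)
    assert res_alt["p"] < 1e-6
    assert res_alt["p_perm"] < 0.01
    with pytest.raises(ValueError):
        distance_distribution_test([], adults)


def _u2_reference(a, b):
    """Independent O(N^2) Watson U^2 from the definition: variance of the
    CDF difference over the pooled sample (tie multiplicities as weights)."""
    a, b = np.asarray(a, float) % 360.0, np.asarray(b, float) % 360.0
    pooled = np.concatenate([a, b])
    vals, t = np.unique(pooled, return_counts=True)
    d = np.array([np.mean(a <= v) - np.mean(b <= v) for v in vals])
    dbar = np.sum(t * d) / len(pooled)
    return len(a) * len(b) / len(pooled) ** 2 * np.sum(t * (d - dbar) ** 2)


def test_watson_u2_matches_reference_and_zero_case():
    rng = np.random.default_rng(11)
    a = rng.uniform(0, 360, 23)
    b = rng.uniform(0, 360, 31)
    assert watson_u2(a, b) == pytest.approx(_u2_reference(a, b), rel=1e-12)
    tied_a = rng.integers(0, 12, 40) * 30.0
    tied_b = rng.integers(0, 12, 25) * 30.0
    assert watson_u2(tied_a, tied_b) == \
        pytest.approx(_u2_reference(tied_a, tied_b), rel=1e-12)
    same = rng.uniform(0, 360, 17)
    assert watson_u2(same, same) == pytest.approx(0.0, abs=1e-15)


def test_anisotropy_test_power_and_validation():
    rng = np.random.default_rng(23)
    north = rng.normal(0.0, 20.0, 60) % 360.0
    south = rng.normal(180.0, 20.0, 60) % 360.0
    res = anisotropy_test(north, south, n_perm=400, seed=3)
    assert res["p"] < 1e-4 and res["p_perm"] < 0.01
    null = anisotropy_test(rng.uniform(0, 360, 60), rng.uniform(0, 360, 60))
    assert null["p"] > 0.01
    with pytest.raises(ValueError, match="8 bearings"):
        anisotropy_test([0.0] * 5, [10.0] * 20)
    with pytest.raises(ValueError, match="identical"):
        anisotropy_test([90.0] * 10, [90.0] * 10)


def test_rose_histogram_sectors():
    df = rose_histogram([0.0, 10.0, 350.0, 90.0, 182.0])
    assert len(df) == 16 and df["count"].sum() == 5
    # the first sector straddles north: 0, 10 and 350 all fall in it
    assert df.loc[0, "count"] == 3
    assert df.loc[4, "count"] == 1        # 90 deg = east sector
    assert df.pct.sum() == pytest.approx(100.0)
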