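"""Synthetic populations and progeny arrays with a known mating truth.

The generator emulates a fragmented, dioecious, wind-pollinated shrub
population: ~164 males and 29 sampled mothers on a 1000 x 700 m plot,
seven microsatellite loci with 3-18 alleles, maternal arrays of ~24 seeds,
mating governed by a fat-tailed power-exponential kernel with strongly
skewed male fecundities, and a high rate of pollen immigration from an
outside pool.  Every simulated seed carries its true father in a
:class:`TruthLedger` so each downstream estimator can be validated against
a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .core_io import MISSING, Locus, ProgenyArray, SpatialGenotypeTable
from .popgen import AlleleFrequencies

HABITATS = ("canopy", "shrubland", "hedge")


@dataclass
class SimulationScenario:
    """All knobs of the generative model; defaults emulate the study system."""

    n_males: int = 164
    n_females: int = 29
    n_sampled_mothers: int = 29
    plot_size: tuple = (1000.0, 700.0)
    spatial: str = "uniform"            # or "clustered"
    n_clusters: int = 12
    cluster_sd: float = 30.0
    founder_mixture: float = 0.5        # clustered mode: P(allele from cluster founders)
    allele_counts: tuple = (14, 6, 18, 10, 15, 3, 3)
    freq_alpha: float = 0.6             # Dirichlet concentration per allele
    adult_f: float = 0.15
    kernel_family: str = "power_exponential"
    delta: float = 270.0                # mean pollination distance, m
    shape_b: float = 0.2
    immigration: float = 0.85
    outside_concentration: float = 100.0
    fecundity_family: str = "gamma"     # or "log_normal"
    fecundity_cv: float = 1.5
    habitat_effects: dict | None = None  # habitat -> fecundity multiplier
    habitat_probs: tuple = (0.3, 0.5, 0.2)
    seeds_per_mother: int = 24
    missing_rate: float = 0.0
    mistyping_rate: float = 0.0
    uniform_mating: bool = False        # flat-kernel mode: fathers uniform

    def __post_init__(self) -> None:
        if not 0.0 <= self.immigration <= 1.0:
            raise ValueError("immigration rate must be in [0, 1]")
        if self.shape_b <= 0 or self.delta <= 0:
            raise ValueError("kernel parameters must be positive")
        if self.fecundity_cv <= 0:
            raise ValueError("fecundity dispersion must be positive")
        if self.n_sampled_mothers > self.n_females:
            raise ValueError("cannot sample more mothers than females")
        if self.spatial not in ("uniform", "clustered"):
            raise ValueError(f"unknown spatial pattern {self.spatial!r}")


@dataclass
class TruthLedger:
    """Ground truth of one mating simulation.

    ``father_ids[s]`` is the true father's id or ``"immigrant"``;
    ``sired_counts`` maps every male to its realized number of local seeds;
    ``distances`` are the realized pollination distances of local matings.
    """

    father_ids: list
    sired_counts: dict
    distances: np.ndarray
    mother_ids: list = field(default_factory=list)
    fecundities: dict = field(default_factory=dict)
    outside_freqs: AlleleFrequencies | None = None

    def __post_init__(self) -> None:
        n_local = sum(1 for f in self.father_ids if f != "immigrant")
        if sum(self.sired_counts.values()) != n_local:
            raise ValueError("sired counts do not sum to local seed count")

    @property
    def immigrant_fraction(self) -> float:
        return float(np.mean([f == "immigrant" for f in self.father_ids]))

    def to_json(self, path) -> None:
        payload = {
            "father_ids": list(self.father_ids),
            "sired_counts": {k: int(v) for k, v in self.sired_counts.items()},
            "distances": [float(d) for d in self.distances],
            "mother_ids": list(self.mother_ids),
            "fecundities": {k: float(v) for k, v in self.fecundities.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def draw_locus_frequencies(scenario: SimulationScenario, seed) -> list:
    """Dirichlet draw of the per-locus allele frequency vectors."""
    rng = _as_rng(seed)
    return [rng.dirichlet(np.full(k, scenario.freq_alpha))
            for k in scenario.allele_counts]


def power_exponential_scale(delta: float, b: float) -> float:
    """Scale a of exp(-(r/a)^b) with mean pollination distance delta:
    delta = a * Gamma(3/b) / Gamma(2/b)."""
    return delta * np.exp(gammaln(2.0 / b) - gammaln(3.0 / b))


def simulate_adults(scenario: SimulationScenario, seed,
                    freqs: list | None = None) -> SpatialGenotypeTable:
    """Simulate adult positions, sexes, habitats and multilocus genotypes.

    Genotypes follow inbred genotype proportions p^2 + F p(1-p) /
    2pq(1-F); in clustered mode each cluster carries a small founder allele
    pool so kinship decays with distance instead.
    """
    rng = _as_rng(seed)
    if freqs is None:
        freqs = draw_locus_frequencies(scenario, rng)
    n = scenario.n_males + scenario.n_females
    w, h = scenario.plot_size
    if scenario.spatial == "uniform":
        xy = rng.uniform((0, 0), (w, h), size=(n, 2))
        cluster_of = None
    else:
        centres = rng.uniform((0, 0), (w, h), size=(scenario.n_clusters, 2))
        cluster_of = rng.integers(scenario.n_clusters, size=n)
        xy = centres[cluster_of] + rng.normal(0, scenario.cluster_sd, size=(n, 2))
        xy = np.clip(xy, (0, 0), (w, h))
    sex = np.array(["male"] * scenario.n_males + ["female"] * scenario.n_females,
                   dtype=object)
    ids = np.array([f"M{i + 1:03d}" for i in range(scenario.n_males)]
                   + [f"F{i + 1:03d}" for i in range(scenario.n_females)],
                   dtype=object)
    habitat = rng.choice(HABITATS, size=n, p=scenario.habitat_probs)
    loci = [Locus(f"loc{l + 1}", [str(a + 101) for a in range(len(p))])
            for l, p in enumerate(freqs)]
    geno = np.empty((n, len(loci), 2), dtype=np.int32)
    for l, p in enumerate(freqs):
        k = len(p)
        if cluster_of is None:
            first = rng.choice(k, size=n, p=p)
            ibd = rng.random(n) < scenario.adult_f
            second = np.where(ibd, first, rng.choice(k, size=n, p=p))
            geno[:, l, 0], geno[:, l, 1] = first, second
        else:
            pools = rng.choice(k, size=(scenario.n_clusters, 4), p=p)
            for copy in range(2):
                from_pool = rng.random(n) < scenario.founder_mixture
                pool_pick = pools[cluster_of, rng.integers(4, size=n)]
                pop_pick = rng.choice(k, size=n, p=p)
                geno[:, l, copy] = np.where(from_pool, pool_pick, pop_pick)
    return SpatialGenotypeTable(ids, sex, xy, geno, loci, habitat)


def _draw_fecundities(scenario: SimulationScenario, adults, male_idx,
                      rng) -> np.ndarray:
    cv = scenario.fecundity_cv
    if scenario.fecundity_family == "gamma":
        shape = 1.0 / cv ** 2
        f = rng.gamma(shape, cv ** 2, size=len(male_idx))
    elif scenario.fecundity_family == "log_normal":
        s2 = np.log1p(cv ** 2)
        f = rng.lognormal(-s2 / 2.0, np.sqrt(s2), size=len(male_idx))
    else:
        raise ValueError(f"unknown fecundity family {scenario.fecundity_family!r}")
    if scenario.habitat_effects:
        mult = np.array([scenario.habitat_effects.get(h, 1.0)
                         for h in adults.habitat[male_idx]])
        f = f * mult
    if np.all(f == 0):
        raise ValueError("all male fecundities are zero")
    return f


def simulate_mating(adults: SpatialGenotypeTable, scenario: SimulationScenario,
                    seed, outside_freqs: AlleleFrequencies | None = None):
    """Simulate maternal progeny arrays under the spatial mating model.

    Each seed of each sampled mother is an immigrant with probability ``m``
    (paternal gamete drawn from the outside-pool frequencies); otherwise
    father j is chosen with probability proportional to ``f_j * k(d_mj)``
    over the male roster.  Returns ``(progeny, ledger)``.
    """
    rng = _as_rng(seed)
    male_idx = np.flatnonzero(adults.males_mask())
    female_idx = np.flatnonzero(adults.females_mask())
    if male_idx.size == 0:
        raise ValueError("no males in the adult table")
    mother_idx = rng.choice(female_idx, size=scenario.n_sampled_mothers,
                            replace=False)
    fec = _draw_fecundities(scenario, adults, male_idx, rng)
    if outside_freqs is None:
        from .popgen import allele_freqs
        base = allele_freqs(adults)
        K = scenario.outside_concentration
        outside_freqs = AlleleFrequencies(
            adults.loci,
            [rng.dirichlet(K * (p + 1e-3)) for p in base.freqs])
    a = power_exponential_scale(scenario.delta, scenario.shape_b)
    L = adults.n_loci
    seed_rows, mothers_of, fathers = [], [], []
    distances = []
    sired = {adults.ids[j]: 0 for j in male_idx}
    for mi in mother_idx:
        d = np.hypot(*(adults.xy[male_idx] - adults.xy[mi]).T)
        if scenario.uniform_mating:
            wgt = np.ones(male_idx.size)
        else:
            wgt = fec * np.exp(-(d / a) ** scenario.shape_b)
        if wgt.sum() == 0:
            raise ValueError("degenerate mating weights for a mother")
        wgt = wgt / wgt.sum()
        mg = adults.genotypes[mi]
        for _ in range(scenario.seeds_per_mother):
            g = np.empty((L, 2), dtype=np.int32)
            mat_pick = rng.integers(2, size=L)
            g[:, 0] = mg[np.arange(L), mat_pick]
            if rng.random() < scenario.immigration:
                fathers.append("immigrant")
                for l in range(L):
                    g[l, 1] = rng.choice(len(outside_freqs.p(l)),
                                         p=outside_freqs.p(l))
            else:
                j = rng.choice(male_idx.size, p=wgt)
                fathers.append(adults.ids[male_idx[j]])
                sired[adults.ids[male_idx[j]]] += 1
                distances.append(d[j])
                fg = adults.genotypes[male_idx[j]]
                pat_pick = rng.integers(2, size=L)
                g[:, 1] = fg[np.arange(L), pat_pick]
            if scenario.mistyping_rate > 0:
                for l in range(L):
                    for c in range(2):
                        if rng.random() < scenario.mistyping_rate:
                            g[l, c] = rng.integers(adults.loci[l].n_alleles)
            if scenario.missing_rate > 0:
                drop = rng.random(L) < scenario.missing_rate
                g[drop] = MISSING
            seed_rows.append(g)
            mothers_of.append(adults.ids[mi])
    geno = np.stack(seed_rows)
    seed_ids = [f"S{i + 1:04d}" for i in range(len(seed_rows))]
    progeny = ProgenyArray(seed_ids, mothers_of, geno, adults.loci)
    ledger = TruthLedger(
        father_ids=fathers, sired_counts=sired,
        distances=np.asarray(distances, dtype=float),
        mother_ids=[adults.ids[i] for i in mother_idx],
        fecundities={adults.ids[j]: float(f) for j, f in zip(male_idx, fec)},
        outside_freqs=outside_freqs)
    return progeny, ledger


def simulate_dataset(scenario: SimulationScenario, seed):
    """Adults + progeny + truth in one call (seed split deterministically)."""
    rng = _as_rng(seed)
    adults = simulate_adults(scenario, rng)
    progeny, ledger = simulate_mating(adults, scenario, rng)
    return adults, progeny, ledger
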