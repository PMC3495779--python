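"""Likelihood-based paternity assignment with a simulation-calibrated threshold.

For every seed and candidate male a LOD score is computed: the log
likelihood-ratio of the candidate being the father versus a random father
drawn from reference allele frequencies.  The assignment threshold ``TF``
is calibrated by simulation, comparing the most-likely-father LOD
distributions of inside-sired versus randomly-sired synthetic seeds and
taking the abscissa where the two kernel-smoothed densities cross.  Seeds
are then placed in three categories: no compatible father on site, a
compatible father below ``TF``, or a confident assignment — ties above the
threshold resolved to the spatially closest male.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .core_io import (MISSING, ProgenyArray, SpatialGenotypeTable, bearing_deg)
from .popgen import AlleleFrequencies, paternal_allele_weights

logger = logging.getLogger("pollenflow")

_FREQ_FLOOR = 1e-9   # guards the null likelihood when a paternal allele is
                     # absent from the reference sample


def transition_probability(offspring_pair, mother_pair, father_pair) -> float:
    """P(offspring genotype | mother, father) under Mendelian segregation.

    All three genotypes are at one locus; zero genotyping error.  Sums, over
    the candidate paternal alleles, the probability that the mother
    transmitted the complement times the father's transmission probability.
    """
    res = paternal_allele_weights(offspring_pair, mother_pair)
    if res is None:
        return 0.0
    alleles, raw, _ = res
    f = (int(father_pair[0]), int(father_pair[1]))
    return float(sum(w * 0.5 * ((f[0] == a) + (f[1] == a))
                     for a, w in zip(alleles, raw)))


def _seed_locus_weights(seed_pair, mother_pair):
    """(a1, a2, w1, w2) raw-weight encoding of one seed locus; a2 = -1 when
    the paternal allele is unambiguous; returns None when incompatible."""
    res = paternal_allele_weights(seed_pair, mother_pair)
    if res is None:
        return None
    alleles, raw, _ = res
    if len(alleles) == 1:
        return alleles[0], -1, float(raw[0]), 0.0
    return alleles[0], alleles[1], float(raw[0]), float(raw[1])


def transmission_matrices(adults: SpatialGenotypeTable, male_idx) -> list:
    """Per locus, matrix (n_males, n_alleles) of allele-transmission
    probabilities; untyped males get NaN rows (treated as incompatible)."""
    out = []
    for l, loc in enumerate(adults.loci):
        g = adults.genotypes[male_idx, l, :]
        M = np.zeros((len(male_idx), loc.n_alleles))
        for slot in range(2):
            ok = g[:, slot] != MISSING
            M[np.flatnonzero(ok), g[ok, slot]] += 0.5
        M[~(g[:, 0] != MISSING)] = np.nan
        out.append(M)
    return out


def lod_score(seed_geno, mother_geno, candidate_geno,
              ref_freqs: AlleleFrequencies, inbreeding_f: float = 0.0) -> float:
    """Multilocus LOD of one candidate father.

    Sum over typed loci of ``ln[T(o|m,c) / T(o|m, random father)]`` where the
    random father's transmitted allele follows the reference frequencies.
    (The marginal allele of a gamete from an individual with inbreeding
    coefficient F is F-free, so F — kept for interface fidelity — affects
    simulated genotypes, not this ratio.)  Mendelian-incompatible candidates
    get ``-inf``; loci missing in any of the three genotypes are skipped.
    """
    total = 0.0
    for l in range(len(ref_freqs.loci)):
        if (seed_geno[l, 0] == MISSING or mother_geno[l, 0] == MISSING
                or candidate_geno[l, 0] == MISSING):
            continue
        res = paternal_allele_weights(seed_geno[l], mother_geno[l])
        if res is None:
            return -np.inf
        alleles, raw, _ = res
        c = (int(candidate_geno[l, 0]), int(candidate_geno[l, 1]))
        num = sum(w * 0.5 * ((c[0] == a) + (c[1] == a))
                  for a, w in zip(alleles, raw))
        if num == 0.0:
            return -np.inf
        p = ref_freqs.p(l)
        den = max(sum(w * p[a] for a, w in zip(alleles, raw)), _FREQ_FLOOR)
        total += np.log(num / den)
    return float(total)


def _lod_block(a1, a2, w1, w2, typed, trans, freqs_vec):
    """Vectorized per-locus LOD contributions for a block of seeds.

    a1/a2/w1/w2: (n_seeds,) encoded paternal-allele weights; trans:
    (n_males, n_alleles) transmission matrix; returns (n_seeds, n_males)
    log-ratio with -inf for incompatible, 0 for untyped seeds.
    """
    n_seeds, n_males = len(a1), trans.shape[0]
    out = np.zeros((n_seeds, n_males))
    use = typed & (a1 >= 0)
    if not use.any():
        return out
    idx = np.flatnonzero(use)
    num = w1[idx, None] * trans[:, a1[idx]].T
    den = w1[idx] * freqs_vec[a1[idx]]
    two = a2[idx] >= 0
    if two.any():
        j = idx[two]
        num[two] += w2[j, None] * trans[:, a2[j]].T
        den[two] += w2[j] * freqs_vec[a2[j]]
    den = np.maximum(den, _FREQ_FLOOR)
    with np.errstate(divide="ignore"):
        out[idx] = np.log(num / den[:, None])
    # males untyped at this locus contribute nothing (NaN transmission rows)
    out[np.isnan(out)] = 0.0
    return out


def lod_matrix(seed_geno: np.ndarray, mother_of: np.ndarray,
               mother_geno: np.ndarray, adults: SpatialGenotypeTable,
               male_idx: np.ndarray, ref_freqs: AlleleFrequencies,
               trans: list | None = None) -> np.ndarray:
    """LOD scores (n_seeds, n_males); -inf marks Mendelian incompatibility."""
    if trans is None:
        trans = transmission_matrices(adults, male_idx)
    n, L = seed_geno.shape[0], seed_geno.shape[1]
    a1 = np.full((n, L), -1, dtype=np.int64)
    a2 = np.full((n, L), -1, dtype=np.int64)
    w1 = np.zeros((n, L))
    w2 = np.zeros((n, L))
    typed = np.zeros((n, L), dtype=bool)
    incompatible = np.zeros(n, dtype=bool)
    for s in range(n):
        mg = mother_geno[mother_of[s]]
        for l in range(L):
            if seed_geno[s, l, 0] == MISSING or mg[l, 0] == MISSING:
                continue
            enc = _seed_locus_weights(seed_geno[s, l], mg[l])
            if enc is None:
                incompatible[s] = True
                continue
            a1[s, l], a2[s, l], w1[s, l], w2[s, l] = enc
            typed[s, l] = True
    lod = np.zeros((n, len(male_idx)))
    for l in range(L):
        lod += _lod_block(a1[:, l], a2[:, l], w1[:, l], w2[:, l],
                          typed[:, l], trans[l], ref_freqs.p(l))
    return lod


@dataclass
class ThresholdCalibration:
    """Result of the LOD-threshold simulation: TF plus the two samples."""

    tf: float
    inside_lods: np.ndarray
    outside_lods: np.ndarray
    separated: bool = True

    def __float__(self) -> float:
        return self.tf


def calibrate_threshold(adults: SpatialGenotypeTable,
                        ref_freqs: AlleleFrequencies,
                        inbreeding_f: float = 0.0, n_sim: int = 50000,
                        seed=None, mothers_mask=None) -> ThresholdCalibration:
    """Simulation calibration of the assignment threshold ``TF``.

    Two sets of ``n_sim`` synthetic seeds are generated from mothers drawn
    among the sampled females: one sired by fathers drawn uniformly from the
    on-site males, one with a randomly generated paternal genotype
    (reference frequencies, inbreeding ``inbreeding_f``).  ``TF`` is the
    crossing point of Gaussian-KDE densities of the two most-likely-father
    LOD distributions, searched between the two distribution means.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000 for a stable calibration")
    rng = np.random.default_rng(seed)
    male_idx = np.flatnonzero(adults.males_mask())
    mom_idx = np.flatnonzero(adults.females_mask() if mothers_mask is None
                             else mothers_mask)
    trans = transmission_matrices(adults, male_idx)
    L = adults.n_loci

    def best_lods(inside: bool) -> np.ndarray:
        moms = rng.choice(mom_idx, size=n_sim)
        seed_geno = np.full((n_sim, L, 2), MISSING, dtype=np.int32)
        mg = adults.genotypes[moms]
        pick = rng.integers(2, size=(n_sim, L))
        mat = np.take_along_axis(mg, pick[:, :, None], axis=2)[:, :, 0]
        if inside:
            dads = adults.genotypes[rng.choice(male_idx, size=n_sim)]
            pickp = rng.integers(2, size=(n_sim, L))
            pat = np.take_along_axis(dads, pickp[:, :, None], axis=2)[:, :, 0]
        else:
            # father genotype from reference freqs with inbreeding F, then
            # one allele transmitted: marginally an allele-frequency draw
            pat = np.stack([rng.choice(len(ref_freqs.p(l)), size=n_sim,
                                       p=ref_freqs.p(l)) for l in range(L)],
                           axis=1).astype(np.int32)
        ok = (mat != MISSING) & (pat != MISSING)
        seed_geno[:, :, 0] = np.where(ok, mat, MISSING)
        seed_geno[:, :, 1] = np.where(ok, pat, MISSING)
        lods = lod_matrix(seed_geno, np.arange(n_sim), adults.genotypes[moms],
                          adults, male_idx, ref_freqs, trans)
        best = lods.max(axis=1)
        return best[np.isfinite(best)]

    inside = best_lods(True)
    outside = best_lods(False)
    lo = min(inside.mean(), outside.mean())
    hi = max(inside.mean(), outside.mean())
    if hi - lo < 1e-9:
        warnings.warn("LOD distributions indistinguishable; TF at common mean")
        return ThresholdCalibration(float(lo), inside, outside, separated=False)
    grid = np.linspace(lo, hi, 512)
    diff = gaussian_kde(inside)(grid) - gaussian_kde(outside)(grid)
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if sign_change.size == 0:
        tf = 0.5 * (inside.min() + outside.max()) \
            if outside.mean() < inside.mean() else 0.5 * (lo + hi)
        warnings.warn("LOD densities do not cross between the means "
                      "(poor marker separation); TF set between supports")
        return ThresholdCalibration(float(tf), inside, outside, separated=False)
    mid = 0.5 * (lo + hi)
    k = sign_change[np.argmin(np.abs(grid[sign_change] - mid))]
    tf = float(0.5 * (grid[k] + grid[k + 1]))
    return ThresholdCalibration(tf, inside, outside)


CATEGORY_NONE = "no_compatible_father"
CATEGORY_BELOW = "compatible_below_tf"
CATEGORY_ASSIGNED = "assigned"
CATEGORY_EXCLUDED = "excluded"


@dataclass
class PaternityResult:
    """Per-seed categories and assignments plus the settings used."""

    table: pd.DataFrame
    tf: float
    inbreeding_f: float
    lods: np.ndarray | None = field(default=None, repr=False)
    male_ids: np.ndarray | None = field(default=None, repr=False)

    def counts(self) -> dict:
        t = self.table[self.table.category != CATEGORY_EXCLUDED]
        return {c: int((t.category == c).sum())
                for c in (CATEGORY_NONE, CATEGORY_BELOW, CATEGORY_ASSIGNED)}


def assign(progeny: ProgenyArray, adults: SpatialGenotypeTable, tf: float,
           ref_freqs: AlleleFrequencies, inbreeding_f: float = 0.0,
           min_typed_loci: int = 5) -> PaternityResult:
    """Categorize every seed and assign confident paternities.

    Category (i): no Mendelian-compatible male on site; (ii): best LOD below
    ``tf``; (iii): assigned — the spatially closest male among those with
    LOD above ``tf``.  Seeds typed at fewer than ``min_typed_loci`` loci are
    excluded with a notice.
    """
    if not np.isfinite(tf):
        raise ValueError("TF must be finite")
    male_idx = np.flatnonzero(adults.males_mask())
    mother_row = np.array([adults.index_of(m) for m in progeny.mother_ids])
    lods = lod_matrix(progeny.genotypes, np.arange(len(progeny)),
                      adults.genotypes[mother_row], adults, male_idx, ref_freqs)
    n_typed = progeny.n_typed_loci()
    rows = []
    for s in range(len(progeny)):
        rec = {"seed_id": progeny.seed_ids[s],
               "mother_id": progeny.mother_ids[s],
               "n_typed": int(n_typed[s]), "category": CATEGORY_EXCLUDED,
               "father_id": None, "best_lod": np.nan,
               "distance_m": np.nan, "bearing_deg": np.nan}
        if n_typed[s] >= min_typed_loci:
            lv = lods[s]
            finite = np.isfinite(lv)
            if not finite.any():
                rec["category"] = CATEGORY_NONE
            else:
                best = float(lv[finite].max())
                rec["best_lod"] = best
                if best < tf:
                    rec["category"] = CATEGORY_BELOW
                else:
                    above = np.flatnonzero(finite & (lv >= tf))
                    mom_xy = adults.xy[mother_row[s]]
                    dists = np.hypot(*(adults.xy[male_idx[above]] - mom_xy).T)
                    j = above[np.argmin(dists)]
                    rec.update(category=CATEGORY_ASSIGNED,
                               father_id=adults.ids[male_idx[j]],
                               distance_m=float(dists.min()),
                               bearing_deg=bearing_deg(
                                   adults.xy[male_idx[j]], mom_xy))
            rows.append(rec)
        else:
            rows.append(rec)
    n_excluded = sum(r["category"] == CATEGORY_EXCLUDED for r in rows)
    if n_excluded:
        logger.info("%d seeds excluded (typed at < %d loci)",
                    n_excluded, min_typed_loci)
    return PaternityResult(pd.DataFrame(rows), tf, inbreeding_f,
                           lods=lods, male_ids=adults.ids[male_idx])


def immigration_bounds(result: PaternityResult) -> tuple:
    """(min, max) pollen-immigration rate from the category counts.

    The minimum counts only seeds with no compatible on-site father; the
    maximum adds the below-threshold seeds, whose fathers may or may not be
    local.
    """
    c = result.counts()
    n = sum(c.values())
    if n == 0:
        raise ValueError("empty paternity result")
    return immigration_bounds_from_counts(c[CATEGORY_NONE], c[CATEGORY_BELOW],
                                          c[CATEGORY_ASSIGNED])


def immigration_bounds_from_counts(n_none: int, n_below: int,
                                   n_assigned: int) -> tuple:
    n = n_none + n_below + n_assigned
    return n_none / n, (n_none + n_below) / n


def mating_network(result: PaternityResult, adults: SpatialGenotypeTable):
    """Edge list of detected pollination events plus summary statistics.

    Returns ``(edges, summary)``: edges have father, mother, seed count,
    distance and father-to-mother bearing; the summary reports the
    distance distribution over assigned seeds and the per-male sired counts
    (zeros included) for male reproductive-variance reporting.
    """
    t = result.table
    assigned = t[t.category == CATEGORY_ASSIGNED]
    male_ids = adults.ids[adults.males_mask()]
    sired = pd.Series(0, index=male_ids, dtype=int)
    for f, k in assigned.father_id.value_counts().items():
        sired[f] = int(k)
    edges = (assigned.groupby(["father_id", "mother_id"], sort=False)
             .agg(n_seeds=("seed_id", "size"), distance_m=("distance_m", "first"),
                  bearing_deg=("bearing_deg", "first")).reset_index())
    d = assigned.distance_m.to_numpy(dtype=float)
    counts_sorted = np.sort(sired.to_numpy())[::-1]
    cum = np.cumsum(counts_sorted)
    n_half = (int(np.searchsorted(cum, 0.5 * len(assigned)) + 1)
              if len(assigned) else 0)
    summary = {
        "n_assigned": int(len(assigned)),
        "n_edges": int(len(edges)),
        "mean_distance_m": float(d.mean()) if d.size else np.nan,
        "sd_distance_m": float(d.std(ddof=1)) if d.size > 1 else np.nan,
        "min_distance_m": float(d.min()) if d.size else np.nan,
        "max_distance_m": float(d.max()) if d.size else np.nan,
        "prop_males_without_offspring": float((sired == 0).mean()),
        "n_males_for_half_of_assignments": n_half,
        "sired_counts": sired,
    }
    return edges, summary
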