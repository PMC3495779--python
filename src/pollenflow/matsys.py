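"""Mating-system estimation: outcrossing rates, correlated paternity, Nep.

The multilocus (tm) and single-locus (ts) outcrossing rates come from the
classical mixed-mating model — each seed is an outcross with probability t
(paternal gamete from a shared pollen pool) or a self with probability
1 - t — maximized jointly in t and the pollen-pool allele frequencies.
For a dioecious species literal selfing is impossible, so 1 - tm and the
difference tm - ts are read as *apparent* selfing and biparental
inbreeding (matings between relatives mimic selfing locus by locus).

Within-mother correlated paternity rp is twice the mean pairwise Loiselle
kinship between the paternal gametes of seed pairs of the same mother; the
effective number of pollen donors is Nep = 1/rp.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, ProgenyArray, SpatialGenotypeTable
from .paternity import transition_probability
from .popgen import (AlleleFrequencies, PaternalGametes,
                     infer_paternal_gametes, paternal_allele_weights,
                     paternal_pool_freqs)
from .sgs import loiselle_kinship_gametes

logger = logging.getLogger("pollenflow")


@dataclass
class MatingSystemEstimate:
    """Outcrossing rates with family-bootstrap inference.

    ``tm`` is the multilocus estimate, ``ts`` the arithmetic mean of the
    per-locus estimates; ``tm - ts`` measures biparental inbreeding.  The
    paired t statistic compares the bootstrap series of tm and ts.
    """

    tm: float
    ts: float
    per_locus_t: np.ndarray
    boot_tm: np.ndarray = field(repr=False)
    boot_ts: np.ndarray = field(repr=False)
    t_statistic: float = np.nan
    p_value: float = np.nan

    @property
    def tm_minus_ts(self) -> float:
        return self.tm - self.ts

    def bootstrap_ci(self, level: float = 0.95) -> dict:
        q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
        return {"tm": tuple(np.percentile(self.boot_tm, q)),
                "ts": tuple(np.percentile(self.boot_ts, q)),
                "tm_minus_ts": tuple(np.percentile(self.boot_tm - self.boot_ts,
                                                   q))}


def _mixed_model_arrays(progeny: ProgenyArray, adults: SpatialGenotypeTable):
    """Per seed-locus pieces of the mixed-mating likelihood.

    Returns (a1, a2, w1, w2, p_self, typed): encoded outcross paternal-
    allele weights (P_outcross = w1*q[a1] + w2*q[a2]) and the selfing
    transition probability P(o | mother x mother).
    """
    n, L = len(progeny), len(progeny.loci)
    mother_row = np.array([adults.index_of(m) for m in progeny.mother_ids])
    a1 = np.full((n, L), 0, dtype=np.int64)
    a2 = np.full((n, L), -1, dtype=np.int64)
    w1 = np.zeros((n, L)); w2 = np.zeros((n, L))
    p_self = np.zeros((n, L))
    typed = np.zeros((n, L), dtype=bool)
    for s in range(n):
        mg = adults.genotypes[mother_row[s]]
        sg = progeny.genotypes[s]
        for l in range(L):
            if sg[l, 0] == MISSING or mg[l, 0] == MISSING:
                continue
            res = paternal_allele_weights(sg[l], mg[l])
            if res is None:
                continue
            alleles, raw, _ = res
            a1[s, l] = alleles[0]
            w1[s, l] = raw[0]
            if len(alleles) > 1:
                a2[s, l] = alleles[1]
                w2[s, l] = raw[1]
            p_self[s, l] = transition_probability(sg[l], mg[l], mg[l])
            typed[s, l] = True
    return a1, a2, w1, w2, p_self, typed


def _fit_t(p_out_prod, p_self_prod, t0=0.9, max_iter=200, tol=1e-10):
    """1-D Newton-Raphson for t in sum(log(t*A + (1-t)*B)), clipped to [0,1]."""
    A, B = p_out_prod, p_self_prod
    t = t0
    pinned = False
    for _ in range(max_iter):
        den = t * A + (1 - t) * B
        den = np.maximum(den, 1e-300)
        g = np.sum((A - B) / den)
        h = -np.sum(((A - B) / den) ** 2)
        if h == 0:
            break
        step = g / h
        t_new = min(max(t - step, 0.0), 1.0)
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    else:
        raise RuntimeError(f"outcrossing Newton-Raphson did not converge "
                           f"(last t={t:.6f})")
    if t in (0.0, 1.0):
        pinned = True
    return t, pinned


def _estimate_once(a1, a2, w1, w2, p_self, typed, q_init, t0=0.9,
                   max_outer=100, tol=1e-8):
    """Block ascent: Newton updates of t alternate with EM updates of the
    pollen-pool frequencies; then per-locus t estimates at the joint q."""
    L = typed.shape[1]
    q = [np.array(f, dtype=float) for f in q_init]
    t = t0
    pinned = False
    for _ in range(max_outer):
        p_out = np.ones_like(p_self)
        per_locus_out = np.empty_like(p_self)
        for l in range(L):
            pol = q[l]
            v = w1[:, l] * pol[a1[:, l]]
            sec = a2[:, l] >= 0
            v[sec] += w2[sec, l] * pol[a2[sec, l]]
            per_locus_out[:, l] = np.where(typed[:, l], v, 1.0)
        p_out = np.where(typed, per_locus_out, 1.0).prod(axis=1)
        p_slf = np.where(typed, p_self, 1.0).prod(axis=1)
        t_new, pinned = _fit_t(p_out, p_slf, t0=t)
        # E step: posterior outcross weight per seed, then expected paternal
        # allele counts refresh the pollen-pool frequencies
        den = t_new * p_out + (1 - t_new) * p_slf
        w_s = np.where(den > 0, t_new * p_out / np.maximum(den, 1e-300), 0.0)
        dq = 0.0
        for l in range(L):
            pol = q[l]
            counts = np.zeros_like(pol)
            v1 = w1[:, l] * pol[a1[:, l]]
            v2 = np.where(a2[:, l] >= 0, w2[:, l] * pol[np.maximum(a2[:, l], 0)],
                          0.0)
            tot = np.maximum(v1 + v2, 1e-300)
            share1 = np.where(typed[:, l], w_s * v1 / tot, 0.0)
            share2 = np.where(typed[:, l], w_s * v2 / tot, 0.0)
            np.add.at(counts, a1[:, l], share1)
            np.add.at(counts, np.maximum(a2[:, l], 0), share2)
            if counts.sum() > 0:
                newq = counts / counts.sum()
                dq = max(dq, float(np.abs(newq - pol).max()))
                q[l] = newq
        if abs(t_new - t) < tol and dq < tol:
            t = t_new
            break
        t = t_new
    if pinned:
        warnings.warn("multilocus outcrossing estimate pinned at a bound")
    per_locus_t = np.empty(L)
    for l in range(L):
        pol = q[l]
        v = w1[:, l] * pol[a1[:, l]]
        sec = a2[:, l] >= 0
        v[sec] += w2[sec, l] * pol[a2[sec, l]]
        mask = typed[:, l]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_locus_t[l], _ = _fit_t(v[mask], p_self[mask, l], t0=t or 0.9)
    return t, per_locus_t, q


def estimate_outcrossing(progeny: ProgenyArray, adults: SpatialGenotypeTable,
                         n_boot: int = 1000, seed=None) -> MatingSystemEstimate:
    """Fit the mixed-mating model and bootstrap over families.

    Starting values: t = 0.9 and pollen-pool frequencies equal to the
    paternal-pool frequencies from maternal subtraction.  Significance of
    tm - ts comes from a paired Student t-test over the bootstrap series
    (families resampled with replacement).
    """
    groups = progeny.groups()
    if len(groups) < 2:
        raise ValueError("need at least two families")
    arrays = _mixed_model_arrays(progeny, adults)
    q0 = [f.copy() for f in paternal_pool_freqs(progeny, adults).freqs]
    q0 = [np.maximum(f, 1e-6) / np.maximum(f, 1e-6).sum() for f in q0]
    tm, per_locus_t, _ = _estimate_once(*arrays, q0)
    ts = float(np.mean(per_locus_t))
    rng = np.random.default_rng(seed)
    fam_idx = list(groups.values())
    boot_tm = np.empty(n_boot)
    boot_ts = np.empty(n_boot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_boot):
            pick = rng.integers(len(fam_idx), size=len(fam_idx))
            rows = np.concatenate([fam_idx[i] for i in pick])
            sub = tuple(a[rows] for a in arrays)
            t_k, pl_k, _ = _estimate_once(*sub, q0, max_outer=40)
            boot_tm[k] = t_k
            boot_ts[k] = float(np.mean(pl_k))
    if n_boot > 1 and np.var(boot_tm - boot_ts) > 0:
        t_stat, p = stats.ttest_rel(boot_tm, boot_ts)
    else:
        t_stat, p = np.nan, np.nan
    return MatingSystemEstimate(float(tm), ts, per_locus_t, boot_tm, boot_ts,
                                float(t_stat), float(p))


# ---------------------------------------------------------------------------
# correlated paternity

def correlated_paternity(progeny: ProgenyArray, adults: SpatialGenotypeTable,
                         freqs: AlleleFrequencies | None = None,
                         gametes: PaternalGametes | None = None):
    """Within-mother correlated paternity rp = 2 x mean paternal-gamete
    kinship over within-mother seed pairs; also per-mother values.

    Ambiguous paternal gametes enter with fractional Mendelian weights, so
    the kinship of two gametes is the weight-averaged allele kinship.
    Mothers with a single seed are skipped with a notice.
    """
    if gametes is None:
        gametes = infer_paternal_gametes(progeny, adults)
    if freqs is None:
        freqs = paternal_pool_freqs(progeny, adults, gametes)
    kin = loiselle_kinship_gametes(gametes, freqs)
    groups = progeny.groups()
    per_mother = {}
    all_vals = []
    n_single = 0
    for mother, idx in groups.items():
        if len(idx) < 2:
            n_single += 1
            continue
        block = kin.F[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        vals = block[iu]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            per_mother[mother] = 2.0 * float(vals.mean())
            all_vals.append(vals)
    if n_single:
        logger.info("%d mothers with a single seed skipped for rp", n_single)
    if not all_vals:
        raise ValueError("no mother with >= 2 seeds")
    rp = 2.0 * float(np.concatenate(all_vals).mean())
    return rp, pd.Series(per_mother, name="rp")


def effective_fathers(rp: float) -> float:
    """Effective number of pollen donors Nep = 1/rp; NaN when rp <= 0."""
    if rp <= 0:
        warnings.warn("rp <= 0: effective number of fathers not estimable")
        return float("nan")
    return 1.0 / rp


def rp_vs_nearest_males(per_mother_rp: pd.Series, adults: SpatialGenotypeTable,
                        k_list=(1, 3, 5)) -> dict:
    """Pearson correlation of per-mother rp with the log mean distance to
    the k nearest males, for each k."""
    male_xy = adults.xy[adults.males_mask()]
    out = {}
    rp = per_mother_rp.to_numpy(dtype=float)
    if np.var(rp) == 0:
        warnings.warn("rp constant across mothers; correlation undefined")
        return {k: (float("nan"), float("nan")) for k in k_list}
    for k in k_list:
        if k > male_xy.shape[0]:
            raise ValueError(f"fewer than {k} males available")
        dists = []
        for mother in per_mother_rp.index:
            xy = adults.xy[adults.index_of(mother)]
            d = np.sort(np.hypot(*(male_xy - xy).T))[:k]
            dists.append(d.mean())
        r, p = stats.pearsonr(rp, np.log(np.asarray(dists)))
        out[k] = (float(r), float(p))
    return out
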