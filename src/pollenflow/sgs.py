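"""Fine-scale spatial genetic structure: Loiselle kinship, correlograms, Sp.

The Loiselle et al. (1995) kinship coefficient F_ij is the correlation of
allele-frequency indicators of two individuals relative to a reference
sample, with a finite-sample correction.  Spatial genetic structure is
quantified by regressing pairwise F_ij on the logarithm of distance
(slope *b-log*, tested by permuting individual locations), by a
distance-class correlogram with a permutation envelope and
jackknife-over-loci errors, and by the dimensionless statistic
``Sp = b_log / (F(1) - 1)`` where F(1) is the mean kinship of the first
distance class.

The estimator runs in diploid mode (individuals; allele indicators in
{0, 0.5, 1}) or haploid mode (gametes; indicators in [0, 1], fractional
for ambiguous paternal gametes) — the latter serves the correlated-
paternity machinery of the mating-system and dispersal modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import MISSING, SpatialGenotypeTable, pairwise_distances
from .popgen import AlleleFrequencies, PaternalGametes

DEFAULT_MAX_DISTANCE = 460.0
DEFAULT_N_CLASSES = 10


@dataclass
class KinshipMatrix:
    """Pairwise Loiselle kinship with per-locus components for jackknifing.

    ``numerators[l]`` and ``denominators[l]`` are the per-locus terms of the
    ratio-of-sums multilocus estimator; ``valid[l]`` marks pairs typed at
    locus l.  ``F`` is the multilocus matrix (NaN for pairs with no shared
    typed locus).
    """

    F: np.ndarray
    numerators: np.ndarray
    denominators: np.ndarray
    valid: np.ndarray

    @property
    def n(self) -> int:
        return self.F.shape[0]

    def multilocus(self, drop_locus: int | None = None) -> np.ndarray:
        keep = np.ones(len(self.denominators), dtype=bool)
        if drop_locus is not None:
            keep[drop_locus] = False
        num = np.where(self.valid[keep], self.numerators[keep], 0.0).sum(axis=0)
        den = (self.valid[keep] * self.denominators[keep, None, None]).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)


def _indicator_matrices(table: SpatialGenotypeTable):
    """Diploid allele-indicator matrices: X[l] is (n, k_l) with half-counts."""
    mats, typed = [], []
    for l, loc in enumerate(table.loci):
        g = table.genotypes[:, l, :]
        ok = g[:, 0] != MISSING
        X = np.zeros((len(table), loc.n_alleles))
        for slot in range(2):
            X[np.flatnonzero(ok), g[ok, slot]] += 0.5
        mats.append(X)
        typed.append(ok)
    return mats, typed


def _gamete_indicator_matrices(gametes: PaternalGametes):
    mats = [gametes.gamete_matrix(l) for l in range(len(gametes.loci))]
    typed = [gametes.valid[:, l] for l in range(len(gametes.loci))]
    return mats, typed


def kinship_from_indicators(mats, typed, freqs: AlleleFrequencies) -> KinshipMatrix:
    """Loiselle estimator from allele-indicator matrices.

    Per locus: ``num_ij = sum_a (x_ia - p_a)(x_ja - p_a) + sum_a p_a(1-p_a)
    / (N_l - 1)`` (the correction uses the reference gene count ``N_l``;
    zero when the reference is external), ``den = sum_a p_a(1-p_a)``.
    Monomorphic loci contribute nothing.
    """
    L, n = len(mats), mats[0].shape[0]
    nums = np.zeros((L, n, n))
    dens = np.zeros(L)
    valid = np.zeros((L, n, n), dtype=bool)
    for l in range(L):
        p = freqs.p(l)
        den = float(np.sum(p * (1.0 - p)))
        if den <= 0:
            continue
        Xc = mats[l] - p[None, :]
        Xc[~typed[l]] = 0.0
        N = freqs.gene_counts[l]
        corr = den / (N - 1) if N > 1 else 0.0
        nums[l] = Xc @ Xc.T + corr
        dens[l] = den
        valid[l] = np.outer(typed[l], typed[l])
    km = KinshipMatrix(np.empty((n, n)), nums, dens, valid)
    km.F = km.multilocus()
    return km


def loiselle_kinship(table: SpatialGenotypeTable,
                     freqs: AlleleFrequencies | None = None) -> KinshipMatrix:
    """Diploid-mode pairwise kinship; reference frequencies default to the
    analysed sample itself."""
    from .popgen import allele_freqs
    if freqs is None:
        freqs = allele_freqs(table)
    mats, typed = _indicator_matrices(table)
    return kinship_from_indicators(mats, typed, freqs)


def loiselle_kinship_gametes(gametes: PaternalGametes,
                             freqs: AlleleFrequencies) -> KinshipMatrix:
    """Haploid-mode kinship between inferred paternal gametes."""
    mats, typed = _gamete_indicator_matrices(gametes)
    return kinship_from_indicators(mats, typed, freqs)


def _pair_arrays(kin: KinshipMatrix, xy, max_distance=None):
    d = pairwise_distances(xy)
    iu = np.triu_indices(kin.n, k=1)
    dv, fv = d[iu], kin.F[iu]
    keep = np.isfinite(fv) & (dv > 0)
    n_coincident = int(np.sum(dv == 0))
    if max_distance is not None:
        keep &= dv <= max_distance
    return dv[keep], fv[keep], iu, keep, n_coincident


def sgs_regression(kin: KinshipMatrix, xy, n_perm: int = 1000, seed=None,
                   max_distance: float | None = None,
                   two_sided: bool = False) -> dict:
    """Slope of pairwise kinship on ln(distance) with a location-permutation
    test (one-sided for structure, i.e. negative slope, by default).

    Coincident pairs (d = 0) are excluded and counted.  With ``n_perm=0``
    only the slope is returned.
    """
    if kin.n < 10:
        raise ValueError("need at least 10 individuals for the SGS regression")
    dv, fv, iu, keep, n_co = _pair_arrays(kin, xy, max_distance)
    x = np.log(dv)
    if len(x) < 3 or np.var(x) == 0:
        raise ValueError("degenerate distance structure")

    def slope(f):
        return float(np.cov(f, x)[0, 1] / np.var(x, ddof=1))

    b_obs = slope(fv)
    out = {"b_log": b_obs, "n_pairs": int(len(x)),
           "n_coincident_excluded": n_co, "p": None}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        perms = np.empty(n_perm)
        for k in range(n_perm):
            perm = rng.permutation(kin.n)
            fp = kin.F[perm[iu[0]], perm[iu[1]]][keep]
            perms[k] = slope(fp)
        if two_sided:
            hits = int(np.sum(np.abs(perms) >= abs(b_obs)))
        else:
            hits = int(np.sum(perms <= b_obs))
        out["p"] = (hits + 1) / (n_perm + 1)
        out["perm_slopes"] = perms
    return out


@dataclass
class SGSCorrelogram:
    """Distance-class kinship profile with permutation envelope and
    jackknife-over-loci standard errors."""

    class_edges: np.ndarray
    n_pairs: np.ndarray
    mean_fij: np.ndarray
    jackknife_se: np.ndarray
    envelope_lo: np.ndarray
    envelope_hi: np.ndarray
    outside_envelope: np.ndarray
    b_log: float
    b_log_p: float | None
    F1: float
    Sp: float


def default_class_edges(max_distance: float = DEFAULT_MAX_DISTANCE,
                        n_classes: int = DEFAULT_N_CLASSES) -> np.ndarray:
    """Equal-width classes on (0, max_distance]."""
    return np.linspace(0.0, max_distance, n_classes + 1)[1:]


def correlogram(kin: KinshipMatrix, xy, class_edges=None, n_perm: int = 1000,
                seed=None) -> SGSCorrelogram:
    """Mean F_ij per distance class, ±2·SE jackknife intervals, permutation
    envelope, the ln-distance regression slope over the same pairs, F(1)
    and Sp."""
    edges = default_class_edges() if class_edges is None \
        else np.asarray(class_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("class edges must be strictly increasing")
    max_d = float(edges[-1])
    dv, fv, iu, keep, _ = _pair_arrays(kin, xy, max_d)
    cls = np.searchsorted(edges, dv, side="left")
    n_classes = len(edges)
    n_pairs = np.bincount(cls, minlength=n_classes)

    def class_means(f):
        sums = np.bincount(cls, weights=f, minlength=n_classes)
        with np.errstate(invalid="ignore"):
            return np.where(n_pairs > 0, sums / np.maximum(n_pairs, 1), np.nan)

    mean_fij = class_means(fv)
    # jackknife over loci
    L = len(kin.denominators)
    usable = [l for l in range(L) if kin.denominators[l] > 0]
    theta = []
    for l in usable:
        Fl = kin.multilocus(drop_locus=l)
        fl = Fl[iu][keep]
        theta.append(class_means(fl))
    theta = np.array(theta)
    if len(usable) > 1:
        # empty distance classes are all-NaN across jackknife replicates
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(theta, axis=0)
        jk_se = np.sqrt((len(usable) - 1) / len(usable)
                        * np.nansum((theta - m) ** 2, axis=0))
    else:
        jk_se = np.full(n_classes, np.nan)
    # permutation envelope
    rng = np.random.default_rng(seed)
    if n_perm > 0:
        perm_means = np.empty((n_perm, n_classes))
        perm_slopes = np.empty(n_perm)
        x = np.log(dv)
        vx = np.var(x, ddof=1)
        for k in range(n_perm):
            perm = rng.permutation(kin.n)
            fp = kin.F[perm[iu[0]], perm[iu[1]]][keep]
            perm_means[k] = class_means(fp)
            perm_slopes[k] = np.cov(fp, x)[0, 1] / vx
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanpercentile(perm_means, 2.5, axis=0)
            hi = np.nanpercentile(perm_means, 97.5, axis=0)
    else:
        lo = np.full(n_classes, np.nan)
        hi = np.full(n_classes, np.nan)
    b_obs = float(np.cov(fv, np.log(dv))[0, 1] / np.var(np.log(dv), ddof=1))
    b_p = None
    if n_perm > 0:
        b_p = (int(np.sum(perm_slopes <= b_obs)) + 1) / (n_perm + 1)
    F1 = float(mean_fij[0])
    outside = (mean_fij < lo) | (mean_fij > hi)
    return SGSCorrelogram(edges, n_pairs, mean_fij, jk_se, lo, hi, outside,
                          b_obs, b_p, F1, sp_statistic(b_obs, F1))


def sp_statistic(b_log: float, F1: float) -> float:
    """Sp = b_log / (F(1) - 1); undefined for F(1) >= 1."""
    if F1 >= 1.0:
        raise ValueError("Sp undefined for F(1) >= 1")
    return float(b_log / (F1 - 1.0))
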