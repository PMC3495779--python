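"""Pollen dispersal kernels: indirect estimation, distance and direction tests.

The indirect route to the dispersal kernel uses the decay of correlated
paternity between pairs of mothers with inter-mother distance: two nearby
mothers sample overlapping pollen clouds, so their seeds share fathers
more often than seeds of distant mothers.  Under a homogeneous effective
father density the expected between-mother correlated paternity at lag z
is proportional to the kernel's self-overlap integral
``O(z) = ∫ k(u) k(u - z) du``, so the observed curve — normalized by the
within-mother value and baselined on pairs beyond an unrelatedness
threshold — is fit by least squares to ``O(z)/O(0)``.

Also here: the observed-versus-potential mating-distance Kolmogorov-
Smirnov comparison and Watson's two-sample U² test for pollination
anisotropy on circular bearings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .core_io import ProgenyArray, SpatialGenotypeTable, pairwise_distances
from .popgen import (AlleleFrequencies, PaternalGametes,
                     infer_paternal_gametes, paternal_pool_freqs)
from .sgs import loiselle_kinship_gametes

logger = logging.getLogger("pollenflow")

KERNEL_FAMILIES = ("normal", "exponential", "geometric", "power_exponential")


@dataclass
class DispersalKernel:
    """A radially symmetric 2-D pollen dispersal density.

    ``power_exponential``: k(r) ∝ exp(-(r/a)^b); b < 1 is fat-tailed.
    ``exponential`` and ``normal`` are the b = 1 and b = 2 special cases;
    ``geometric``: k(r) ∝ (1 + r/a)^(-b), b > 2.
    """

    family: str
    a: float
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.a <= 0:
            raise ValueError("scale a must be positive")
        if self.family == "power_exponential" and self.b <= 0:
            raise ValueError("power-exponential shape b must be positive")
        if self.family == "geometric" and self.b <= 2:
            raise ValueError("geometric shape b must exceed 2 for a proper "
                             "2-D kernel")
        if self.family == "exponential":
            self.b = 1.0
        elif self.family == "normal":
            self.b = 2.0

    def unnormalized(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if self.family == "geometric":
            return (1.0 + r / self.a) ** (-self.b)
        with np.errstate(over="ignore"):
            return np.exp(-((r / self.a) ** self.b))

    def pdf(self, r) -> np.ndarray:
        """Normalized 2-D density at radius r (per m^2)."""
        if self.family == "geometric":
            c = (self.b - 1) * (self.b - 2) / (2 * np.pi * self.a ** 2)
        else:
            c = self.b / (2 * np.pi * self.a ** 2
                          * np.exp(gammaln(2.0 / self.b)))
        return c * self.unnormalized(r)

    @property
    def delta(self) -> float:
        return mean_distance(self)


def mean_distance(kernel: DispersalKernel) -> float:
    """Mean pollination distance δ = ∫ r k(r) dA, in closed form.

    Power-exponential family: δ = a Γ(3/b) / Γ(2/b); geometric:
    δ = 2a / (b - 3) (divergent — an error — for b <= 3).
    """
    if kernel.family == "geometric":
        if kernel.b <= 3:
            raise ValueError("geometric kernel mean diverges for b <= 3")
        return 2.0 * kernel.a / (kernel.b - 3.0)
    b = kernel.b
    return float(kernel.a * np.exp(gammaln(3.0 / b) - gammaln(2.0 / b)))


def mean_distance_quadrature(kernel: DispersalKernel, n_nodes: int = 4096,
                             r_max_deltas: float = 60.0) -> float:
    """Numerical cross-check of the closed-form mean distance."""
    # integrate rho(r) = 2 pi r k(r) against r on [0, R]
    try:
        R = r_max_deltas * mean_distance(kernel)
    except ValueError:
        raise
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    r = 0.5 * R * (x + 1.0)
    wr = 0.5 * R * w
    dens = kernel.pdf(r) * 2 * np.pi * r
    return float(np.sum(wr * dens * r) / np.sum(wr * dens))


def scale_for_delta(family: str, delta: float, b: float = 1.0) -> float:
    """Scale parameter a giving mean distance ``delta`` at shape ``b``."""
    probe = DispersalKernel(family, 1.0, b)
    return delta / mean_distance(probe)


# ---------------------------------------------------------------------------
# correlated-paternity decay (KinDist-style indirect estimation)

@dataclass
class CorrelatedPaternityCurve:
    """Between-mother correlated paternity against inter-mother distance.

    ``pairs`` holds one row per mother pair (distance, psi, n seed pairs);
    ``psi_within`` is the within-mother value anchoring the normalization
    at lag zero.
    """

    pairs: pd.DataFrame
    psi_within: float
    mother_ids: list = field(default_factory=list)


def between_mother_correlated_paternity(
        progeny: ProgenyArray, adults: SpatialGenotypeTable,
        freqs: AlleleFrequencies | None = None,
        gametes: PaternalGametes | None = None) -> CorrelatedPaternityCurve:
    """Ψ for every mother pair: twice the mean pairwise Loiselle kinship
    between paternal gametes of seeds of the two mothers."""
    if gametes is None:
        gametes = infer_paternal_gametes(progeny, adults)
    if freqs is None:
        freqs = paternal_pool_freqs(progeny, adults, gametes)
    kin = loiselle_kinship_gametes(gametes, freqs)
    groups = progeny.groups()
    mothers = list(groups)
    if len(mothers) < 2:
        raise ValueError("need at least two mothers")
    xy = {m: adults.xy[adults.index_of(m)] for m in mothers}
    rows = []
    for i in range(len(mothers)):
        for j in range(i + 1, len(mothers)):
            a, b = mothers[i], mothers[j]
            block = kin.F[np.ix_(groups[a], groups[b])].ravel()
            block = block[np.isfinite(block)]
            if block.size == 0:
                continue
            d = float(np.hypot(*(xy[a] - xy[b])))
            rows.append({"mother_a": a, "mother_b": b, "distance": d,
                         "psi": 2.0 * float(block.mean()),
                         "n_seed_pairs": int(block.size)})
    # within-mother anchor (the z = 0 limit of the decay curve)
    within = []
    for m, idx in groups.items():
        if len(idx) < 2:
            continue
        block = kin.F[np.ix_(idx, idx)]
        vals = block[np.triu_indices(len(idx), k=1)]
        within.append(vals[np.isfinite(vals)])
    psi_within = 2.0 * float(np.concatenate(within).mean()) if within else np.nan
    return CorrelatedPaternityCurve(pd.DataFrame(rows), psi_within, mothers)


def decay_precheck(curve: CorrelatedPaternityCurve) -> tuple:
    """Pearson correlation of Ψ with ln(distance), two-sided p (t approx)."""
    if len(curve.pairs) < 3:
        raise ValueError("need at least 3 mother pairs")
    psi = curve.pairs.psi.to_numpy(dtype=float)
    d = curve.pairs.distance.to_numpy(dtype=float)
    if np.var(psi) == 0 or np.var(np.log(d)) == 0:
        raise ValueError("zero-variance input to the decay precheck")
    r, p = stats.pearsonr(psi, np.log(d))
    return float(r), float(p)


def overlap_ratio(z, family: str, a: float, b: float,
                  n_theta: int = 48, n_r: int = 128) -> np.ndarray:
    """Kernel self-overlap O(z)/O(0) by polar quadrature.

    ``O(z) = ∫ k(u) k(u - z) du`` over the plane; the uniform effective
    father density of the model makes the expected co-paternity of two
    pollen clouds at lag z proportional to this integral.  The radial grid
    is truncated where the integrand is negligible (5 kernel mean distances
    past the lag).
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    kern = DispersalKernel(family, a, b)
    try:
        delta = mean_distance(kern)
    except ValueError:
        delta = a  # divergent-mean corner of the geometric family
    theta = (np.arange(n_theta) + 0.5) * (2 * np.pi / n_theta)
    x_leg, w_leg = np.polynomial.legendre.leggauss(n_r)
    out = np.empty(z.shape)
    R0 = 5.0 * delta
    r0 = 0.5 * R0 * (x_leg + 1.0)
    k0 = kern.unnormalized(r0)
    o_zero = float(np.sum(0.5 * R0 * w_leg * r0 * k0 * k0) * 2 * np.pi)
    for i, zi in enumerate(z):
        R = 5.0 * delta + zi
        r = 0.5 * R * (x_leg + 1.0)
        wr = 0.5 * R * w_leg
        kr = kern.unnormalized(r)
        # |u - z| on the polar grid
        d = np.sqrt(r[:, None] ** 2 + zi ** 2
                    - 2 * r[:, None] * zi * np.cos(theta)[None, :])
        integrand = kr[:, None] * kern.unnormalized(d)
        out[i] = float(np.sum(wr * r * integrand.sum(axis=1))
                       * (2 * np.pi / n_theta))
    return out / o_zero


@dataclass
class KinDistFit:
    kernel: DispersalKernel
    delta: float
    rss: float
    baseline: float
    normalization: float
    residuals: np.ndarray = field(repr=False)
    normalized_psi: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)


def fit_kernel_kindist(curve: CorrelatedPaternityCurve,
                       family: str = "power_exponential",
                       threshold: float = 300.0, n_theta: int = 48,
                       n_r: int = 128, n_starts: int = 9,
                       n_z_grid: int = 40) -> KinDistFit:
    """Least-squares fit of a dispersal kernel to the normalized decay curve.

    The baseline — the mean Ψ of mother pairs beyond the unrelatedness
    ``threshold`` — is subtracted and the curve rescaled by the within-
    mother value so the observation at lag z targets ``O(z)/O(0)``, which
    tends to 0 at large z.  Minimization is multi-start Nelder-Mead over
    (ln a, ln b) to cope with the flat ridge of fat-tailed kernels.
    """
    df = curve.pairs
    if not ((df.distance > threshold).any() and (df.distance <= threshold).any()):
        raise ValueError("need mother pairs on both sides of the threshold")
    baseline = float(df.psi[df.distance > threshold].mean())
    denom = curve.psi_within - baseline
    if not np.isfinite(denom) or denom <= 0:
        raise ValueError("within-mother correlated paternity does not exceed "
                         "the far-pair baseline; no decay signal to fit")
    z = df.distance.to_numpy(dtype=float)
    y = (df.psi.to_numpy(dtype=float) - baseline) / denom
    z_grid = np.linspace(0.0, z.max(), n_z_grid)

    two_param = family in ("power_exponential", "geometric")

    def unpack(theta):
        if family == "geometric":
            return np.exp(theta[0]), 2.0 + np.exp(theta[1])
        if two_param:
            return np.exp(theta[0]), np.exp(theta[1])
        return np.exp(theta[0]), {"exponential": 1.0, "normal": 2.0}[family]

    def objective(theta):
        a, b = unpack(theta)
        if not (1e-3 < a < 1e7) or not (1e-3 < b < 1e3):
            return 1e10
        try:
            ratio = overlap_ratio(z_grid, family, a, b, n_theta, n_r)
        except (ValueError, FloatingPointError):
            return 1e10
        pred = np.interp(z, z_grid, ratio)
        return float(np.sum((y - pred) ** 2))

    scale0 = max(np.median(z) / 2.0, 1.0)
    a_starts = scale0 * np.array([0.1, 1.0, 10.0])
    b_starts = np.array([0.3, 1.0, 3.0])
    starts = [(np.log(a0), np.log(b0)) for a0 in a_starts for b0 in b_starts]
    if not two_param:
        starts = [(np.log(a0),) for a0 in
                  scale0 * np.exp(np.linspace(np.log(0.05), np.log(20.0),
                                              n_starts))]
    best = None
    for theta0 in starts[:n_starts]:
        res = optimize.minimize(objective, np.asarray(theta0),
                                method="Nelder-Mead",
                                options={"maxiter": 300, "xatol": 1e-4,
                                         "fatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise RuntimeError("KinDist fit failed to converge; check the decay "
                           "curve and threshold")
    a_hat, b_hat = unpack(best.x)
    if two_param and not (1e-2 < b_hat < 1e2):
        warnings.warn(f"shape parameter pinned near a bound (b = {b_hat:.3g})")
    kernel = DispersalKernel(family, a_hat, b_hat)
    ratio = overlap_ratio(z_grid, family, a_hat, b_hat, n_theta, n_r)
    pred = np.interp(z, z_grid, ratio)
    try:
        delta = mean_distance(kernel)
    except ValueError:
        delta = np.nan
    return KinDistFit(kernel, delta, float(best.fun), baseline, denom,
                      y - pred, y, pred)


# ---------------------------------------------------------------------------
# distance and direction tests

def potential_mating_distances(adults: SpatialGenotypeTable) -> np.ndarray:
    """Distances of all male x female pairs (the potential mating set)."""
    d = pairwise_distances(adults.xy[adults.males_mask()],
                           adults.xy[adults.females_mask()])
    return d.ravel()


def distance_distribution_test(observed_distances, adults,
                               n_perm: int = 0, seed=None) -> dict:
    """Two-sample KS test of observed mating distances against the potential
    distribution over all male x female pairs."""
    obs = np.asarray(observed_distances, dtype=float)
    if obs.size == 0:
        raise ValueError("no observed mating events")
    pot = potential_mating_distances(adults)
    d, p = stats.ks_2samp(obs, pot)
    out = {"d": float(d), "p": float(p), "n_observed": int(obs.size),
           "n_potential": int(pot.size)}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        stats_perm = np.empty(n_perm)
        for k in range(n_perm):
            fake = rng.choice(pot, size=obs.size, replace=False)
            stats_perm[k] = stats.ks_2samp(fake, pot).statistic
        out["p_perm"] = (int(np.sum(stats_perm >= d)) + 1) / (n_perm + 1)
    return out


def watson_u2(sample_a, sample_b) -> float:
    """Watson's two-sample U² statistic on circular data (degrees)."""
    a = np.sort(np.asarray(sample_a, dtype=float) % 360.0)
    b = np.sort(np.asarray(sample_b, dtype=float) % 360.0)
    n1, n2 = len(a), len(b)
    N = n1 + n2
    values = np.unique(np.concatenate([a, b]))
    c1 = np.searchsorted(a, values, side="right") / n1
    c2 = np.searchsorted(b, values, side="right") / n2
    # multiplicity of each combined value weights the sums
    t = (np.searchsorted(a, values, side="right")
         - np.searchsorted(a, values, side="left")
         + np.searchsorted(b, values, side="right")
         - np.searchsorted(b, values, side="left"))
    d = c1 - c2
    dbar = np.sum(t * d) / N
    u2 = (n1 * n2) / N ** 2 * np.sum(t * (d - dbar) ** 2)
    return float(u2)


def _watson_asymptotic_p(u2: float, terms: int = 30) -> float:
    m = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (m - 1) * np.exp(-2.0 * m ** 2 * np.pi ** 2 * u2))
    return float(min(max(p, 0.0), 1.0))


def anisotropy_test(bearings_a, bearings_b, n_perm: int = 0,
                    seed=None) -> dict:
    """Watson's two-sample U² test for a difference between two circular
    (bearing) distributions; asymptotic p with a permutation fallback."""
    a = np.asarray(bearings_a, dtype=float)
    b = np.asarray(bearings_b, dtype=float)
    if len(a) < 8 or len(b) < 8:
        raise ValueError("need at least 8 bearings per sample")
    if np.ptp(np.concatenate([a, b]) % 360.0) == 0:
        raise ValueError("all bearings identical; circular test undefined")
    u2 = watson_u2(a, b)
    out = {"u2": u2, "p": _watson_asymptotic_p(u2), "method": "asymptotic"}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        pool = np.concatenate([a, b])
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            if watson_u2(perm[:len(a)], perm[len(a):]) >= u2:
                hits += 1
        out["p_perm"] = (hits + 1) / (n_perm + 1)
        out["method"] = "permutation"
    return out


def rose_histogram(bearings, n_sectors: int = 16) -> pd.DataFrame:
    """Sector counts and percentages of a bearing sample (wind-rose style),
    first sector centred on north."""
    az = np.asarray(bearings, dtype=float) % 360.0
    width = 360.0 / n_sectors
    sector = np.floor(((az + width / 2) % 360.0) / width).astype(int)
    counts = np.bincount(sector, minlength=n_sectors)
    start = (np.arange(n_sectors) * width - width / 2) % 360.0
    return pd.DataFrame({"sector_start_deg": start,
                         "sector_end_deg": (start + width) % 360.0,
                         "count": counts,
                         "pct": 100.0 * counts / max(len(az), 1)})
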