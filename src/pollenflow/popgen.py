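"""Allele frequencies, diversity statistics, HWE testing and exclusion power.

Everything downstream of the raw genotype tables starts here: gene-count
allele frequencies, the paternal-gamete pool obtained by subtracting the
maternal contribution from each seed, Nei's unbiased expected
heterozygosity, the Weir & Cockerham (1984) inbreeding coefficient, a
Markov-chain exact test of Hardy-Weinberg proportions, an EM estimate of
null-allele frequency, and the known-mother paternity-exclusion
probability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, ProgenyArray, SpatialGenotypeTable

logger = logging.getLogger("pollenflow")


class AlleleFrequencies:
    """Per-locus allele frequencies aligned to the shared allele catalogue.

    ``freqs[l]`` is a vector over ``loci[l].alleles`` summing to one;
    ``gene_counts[l]`` is the number of gene copies it was computed from
    (0 for externally supplied frequency sets).
    """

    def __init__(self, loci, freqs, gene_counts=None):
        self.loci = list(loci)
        self.freqs = [np.asarray(f, dtype=float) for f in freqs]
        if gene_counts is None:
            gene_counts = [0] * len(self.loci)
        self.gene_counts = list(gene_counts)
        for loc, f in zip(self.loci, self.freqs):
            if len(f) != loc.n_alleles:
                raise ValueError(f"locus {loc.name}: frequency vector length "
                                 f"{len(f)} != catalogue size {loc.n_alleles}")
            if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError(f"locus {loc.name}: frequencies must be "
                                 "non-negative and sum to 1")

    def p(self, l: int) -> np.ndarray:
        return self.freqs[l]

    def as_dict(self) -> dict:
        return {loc.name: {a: float(f) for a, f in zip(loc.alleles, fv)}
                for loc, fv in zip(self.loci, self.freqs)}

    def padded(self) -> "AlleleFrequencies":
        """Re-pad vectors after the shared catalogue has grown (new alleles
        get frequency zero)."""
        new = []
        for loc, f in zip(self.loci, self.freqs):
            if len(f) < loc.n_alleles:
                f = np.append(f, np.zeros(loc.n_alleles - len(f)))
            new.append(f)
        return AlleleFrequencies(self.loci, new, self.gene_counts)


def allele_freqs(table: SpatialGenotypeTable | ProgenyArray,
                 subset=None) -> AlleleFrequencies:
    """Gene-count allele frequencies, missing genotypes excluded locus-wise."""
    geno = table.genotypes if subset is None else table.genotypes[subset]
    freqs, counts = [], []
    for l, loc in enumerate(table.loci):
        pair = geno[:, l, :]
        alleles = pair[pair[:, 0] != MISSING].ravel()
        if alleles.size == 0:
            raise ValueError(f"locus {loc.name}: no genotyped individuals")
        c = np.bincount(alleles, minlength=loc.n_alleles).astype(float)
        freqs.append(c / c.sum())
        counts.append(int(alleles.size))
    return AlleleFrequencies(table.loci, freqs, counts)


# ---------------------------------------------------------------------------
# paternal gametes by maternal subtraction

def paternal_allele_weights(seed_pair, mother_pair):
    """Mendelian weights of the candidate paternal alleles of one seed locus.

    Returns ``(alleles, unnormalized, normalized)`` where ``unnormalized[i]``
    is the probability that the mother transmitted the complementary allele
    (the transition probability to a father carrying ``alleles[i]`` is
    ``sum(unnormalized * father_transmission)``), and ``normalized`` sums to
    one.  Returns ``None`` for a mother/seed Mendelian incompatibility.
    """
    s1, s2 = int(seed_pair[0]), int(seed_pair[1])
    m = (int(mother_pair[0]), int(mother_pair[1]))
    if s1 == s2:
        w = 0.5 * ((m[0] == s1) + (m[1] == s1))
        if w == 0.0:
            return None
        return [s1], np.array([w]), np.array([1.0])
    w_s2 = 0.5 * ((m[0] == s1) + (m[1] == s1))   # mother gave s1 -> father gave s2
    w_s1 = 0.5 * ((m[0] == s2) + (m[1] == s2))
    tot = w_s1 + w_s2
    if tot == 0.0:
        return None
    if w_s1 == 0.0:
        return [s2], np.array([w_s2]), np.array([1.0])
    if w_s2 == 0.0:
        return [s1], np.array([w_s1]), np.array([1.0])
    raw = np.array([w_s1, w_s2])
    return [s1, s2], raw, raw / tot


@dataclass
class PaternalGametes:
    """Per-seed inferred paternal gametes with fractional Mendelian weights.

    ``alleles[s, l, :]`` holds up to two candidate paternal allele indices
    (``-1`` padding) and ``weights`` the matching normalized weights.
    ``valid[s, l]`` is False where the locus is untyped in seed or mother or
    Mendelian-incompatible (incompatibilities are counted, not fatal).
    """

    alleles: np.ndarray
    weights: np.ndarray
    raw_weights: np.ndarray
    valid: np.ndarray
    n_incompatible: int
    loci: list

    def gamete_matrix(self, l: int) -> np.ndarray:
        """Fractional allele-indicator matrix (n_seeds, n_alleles) at locus l;
        rows of invalid seed-loci are all zero."""
        n = self.alleles.shape[0]
        out = np.zeros((n, self.loci[l].n_alleles))
        for slot in range(2):
            a = self.alleles[:, l, slot]
            ok = a >= 0
            out[np.flatnonzero(ok), a[ok]] += self.weights[ok, l, slot]
        return out


def infer_paternal_gametes(progeny: ProgenyArray,
                           adults: SpatialGenotypeTable) -> PaternalGametes:
    """Subtract the maternal contribution from every seed genotype."""
    n, L = len(progeny), len(progeny.loci)
    alleles = np.full((n, L, 2), MISSING, dtype=np.int32)
    weights = np.zeros((n, L, 2))
    raw = np.zeros((n, L, 2))
    valid = np.zeros((n, L), dtype=bool)
    mother_idx = np.array([adults.index_of(m) for m in progeny.mother_ids])
    n_bad = 0
    for s in range(n):
        mg = adults.genotypes[mother_idx[s]]
        sg = progeny.genotypes[s]
        for l in range(L):
            if sg[l, 0] == MISSING or mg[l, 0] == MISSING:
                continue
            res = paternal_allele_weights(sg[l], mg[l])
            if res is None:
                n_bad += 1
                continue
            als, un, norm = res
            for k, a in enumerate(als):
                alleles[s, l, k] = a
                weights[s, l, k] = norm[k]
                raw[s, l, k] = un[k]
            valid[s, l] = True
    if n_bad:
        logger.warning("%d seed-locus mother/seed incompatibilities skipped",
                       n_bad)
    return PaternalGametes(alleles, weights, raw, valid, n_bad, progeny.loci)


def paternal_pool_freqs(progeny: ProgenyArray, adults: SpatialGenotypeTable,
                        gametes: PaternalGametes | None = None,
                        subset=None) -> AlleleFrequencies:
    """Allele frequencies of the paternal gamete pool of a progeny array.

    Each seed contributes its inferred paternal gamete per locus: weight one
    for an unambiguous non-maternal allele, fractional Mendelian weights
    when both seed alleles occur in the mother.
    """
    if gametes is None:
        gametes = infer_paternal_gametes(progeny, adults)
    freqs, counts = [], []
    for l, loc in enumerate(progeny.loci):
        mat = gametes.gamete_matrix(l)
        if subset is not None:
            mat = mat[subset]
        tot = mat.sum()
        if tot == 0:
            raise ValueError(f"locus {loc.name}: no paternal gametes inferred")
        freqs.append(mat.sum(axis=0) / tot)
        counts.append(int(round(tot)))
    return AlleleFrequencies(progeny.loci, freqs, counts)


# ---------------------------------------------------------------------------
# diversity statistics

def _wc_components(pair: np.ndarray, n_alleles: int):
    """Weir & Cockerham (1984) single-population variance components
    (b = between-individual, c = within-individual) summed over alleles."""
    typed = pair[pair[:, 0] != MISSING]
    n = len(typed)
    if n < 2:
        return 0.0, 0.0
    c_all = np.bincount(typed.ravel(), minlength=n_alleles).astype(float)
    p = c_all / (2 * n)
    het = typed[:, 0] != typed[:, 1]
    b_sum = c_sum = 0.0
    for a in range(n_alleles):
        if c_all[a] == 0:
            continue
        hbar = np.mean(het & ((typed[:, 0] == a) | (typed[:, 1] == a)))
        b_sum += (n / (n - 1)) * (p[a] * (1 - p[a]) - (2 * n - 1) / (4 * n) * hbar)
        c_sum += hbar / 2.0
    return b_sum, c_sum


def diversity(table: SpatialGenotypeTable | ProgenyArray) -> pd.DataFrame:
    """Per-locus and overall A, unbiased He (Nei 1978) and Weir-Cockerham f.

    The overall row sums allele counts, averages He unweighted, and combines
    the Weir-Cockerham variance components over loci (ratio of summed
    components, not the mean of per-locus f).
    """
    rows = []
    b_tot = c_tot = 0.0
    for l, loc in enumerate(table.loci):
        pair = table.genotypes[:, l, :]
        typed = pair[pair[:, 0] != MISSING]
        n = len(typed)
        counts = np.bincount(typed.ravel(), minlength=loc.n_alleles).astype(float)
        p = counts / counts.sum()
        A = int((counts > 0).sum())
        he = (2 * n / (2 * n - 1)) * (1.0 - np.sum(p ** 2)) if n > 1 else np.nan
        b, c = _wc_components(pair, loc.n_alleles)
        f = 1.0 - c / (b + c) if (b + c) != 0 else np.nan
        b_tot += b
        c_tot += c
        rows.append({"locus": loc.name, "n": n, "A": A, "He": he, "f": f})
    overall_f = 1.0 - c_tot / (b_tot + c_tot) if (b_tot + c_tot) != 0 else np.nan
    rows.append({"locus": "overall", "n": int(np.mean([r["n"] for r in rows])),
                 "A": int(sum(r["A"] for r in rows)),
                 "He": float(np.mean([r["He"] for r in rows])),
                 "f": overall_f})
    return pd.DataFrame(rows).set_index("locus")


def combine_diversity(per_locus_A, per_locus_He) -> tuple:
    """Overall (A, He) from per-locus values: summed allele counts and the
    unweighted mean expected heterozygosity."""
    return int(np.sum(per_locus_A)), float(np.mean(per_locus_He))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Markov chain, Guo & Thompson switch chain)

def _log_table_prob(counts: dict, het: int) -> float:
    return het * math.log(2.0) - sum(math.lgamma(v + 1) for v in counts.values())


def hwe_exact_test(table, locus, dememorization: int = 10000,
                   batches: int = 20, iterations_per_batch: int = 5000,
                   seed: int | None = None) -> dict:
    """Markov-chain estimate of the exact HWE probability-test p-value.

    The switch chain of Guo & Thompson resamples genotype tables conditional
    on the allele counts; the p-value is the visited-state probability mass
    with conditional probability not exceeding the observed table's.
    Defaults match common practice (10000 dememorization steps, 20 batches
    of 5000 iterations); the standard error is estimated over batches.
    Returns ``{'p': ..., 'se': ...}``; a monomorphic locus has p = 1.
    """
    l = table.locus_names.index(locus) if isinstance(locus, str) else locus
    pair = table.genotypes[:, l, :]
    typed = pair[pair[:, 0] != MISSING]
    genos = [tuple(sorted(map(int, g))) for g in typed]
    if len({a for g in genos for a in g}) < 2:
        return {"p": 1.0, "se": 0.0}
    rng = np.random.default_rng(seed)
    counts: dict = {}
    for g in genos:
        counts[g] = counts.get(g, 0) + 1
    het = sum(1 for g in genos if g[0] != g[1])
    logp = _log_table_prob(counts, het)
    logp_obs = logp
    n = len(genos)

    def step():
        nonlocal het, logp
        i1 = rng.integers(n)
        i2 = rng.integers(n - 1)
        if i2 >= i1:
            i2 += 1
        g1, g2 = genos[i1], genos[i2]
        s1, s2 = rng.integers(2), rng.integers(2)
        u, v = g1[s1], g2[s2]
        if u == v:
            return
        n1 = tuple(sorted((g1[1 - s1], v)))
        n2 = tuple(sorted((g2[1 - s2], u)))
        dh = ((n1[0] != n1[1]) + (n2[0] != n2[1])
              - (g1[0] != g1[1]) - (g2[0] != g2[1]))
        # Metropolis-Hastings on labelled individuals with target 2**H: the
        # slot-swap proposal needs a multiplicity correction m_y / m_x
        # (number of slot pairs realizing the move and its reverse).
        m_x = ((g1[0] == u) + (g1[1] == u)) * ((g2[0] == v) + (g2[1] == v))
        m_y = ((n1[0] == v) + (n1[1] == v)) * ((n2[0] == u) + (n2[1] == u))
        ratio = (2.0 ** dh) * m_y / m_x
        if ratio >= 1.0 or rng.random() < ratio:
            dlog = dh * math.log(2.0)
            for g in (g1, g2):
                dlog += math.log(counts[g])
                counts[g] -= 1
                if counts[g] == 0:
                    del counts[g]
            for g in (n1, n2):
                counts[g] = counts.get(g, 0) + 1
                dlog -= math.log(counts[g])
            genos[i1], genos[i2] = n1, n2
            het += dh
            logp += dlog

    for _ in range(dememorization):
        step()
    tol = 1e-9
    batch_means = []
    for _ in range(batches):
        hits = 0
        for _ in range(iterations_per_batch):
            step()
            if logp <= logp_obs + tol:
                hits += 1
        batch_means.append(hits / iterations_per_batch)
    p = float(np.mean(batch_means))
    se = float(np.std(batch_means, ddof=1) / math.sqrt(batches))
    return {"p": p, "se": se}


# ---------------------------------------------------------------------------
# null alleles (Dempster EM)

def null_allele_freq(table, locus, max_iter: int = 2000,
                     tol: float = 1e-9) -> float:
    """EM estimate of a single null-allele frequency from homozygote excess.

    Observed homozygotes are modelled as a mixture of true homozygotes and
    visible/null heterozygotes under random mating; blank (null/null)
    individuals are unobservable and handled by conditioning.  Returns 0
    when there is no homozygote excess.
    """
    l = table.locus_names.index(locus) if isinstance(locus, str) else locus
    pair = table.genotypes[:, l, :]
    typed = pair[pair[:, 0] != MISSING]
    if len(typed) == 0:
        raise ValueError("no typed individuals at locus")
    k = int(typed.max()) + 1
    hom_counts = np.zeros(k)
    het_allele_counts = np.zeros(k)
    for a, b in typed:
        if a == b:
            hom_counts[a] += 1
        else:
            het_allele_counts[a] += 1
            het_allele_counts[b] += 1
    n_obs = len(typed)
    p = np.bincount(typed.ravel(), minlength=k).astype(float)
    p /= p.sum()
    r = 0.05
    for _ in range(max_iter):
        p_safe = np.maximum(p, 1e-12)
        w_null = 2 * r / (p_safe + 2 * r)          # share of obs homozygotes that are A/null
        null_from_homs = float(np.sum(hom_counts * w_null))
        n_blank = n_obs * r ** 2 / max(1.0 - r ** 2, 1e-12)
        allele_counts = het_allele_counts + hom_counts * (2 - w_null)
        total = 2 * (n_obs + n_blank)
        new_r = (null_from_homs + 2 * n_blank) / total
        new_p = allele_counts / total
        scale = new_p.sum() + new_r
        new_p, new_r = new_p / scale, new_r / scale
        if abs(new_r - r) + np.abs(new_p - p).sum() < tol:
            p, r = new_p, new_r
            break
        p, r = new_p, new_r
    return float(max(r, 0.0))


# ---------------------------------------------------------------------------
# paternity exclusion

def exclusion_probability(freqs: AlleleFrequencies, locus=None):
    """Known-mother paternity-exclusion probability.

    Per locus, the probability that a random non-father is Mendelian-
    incompatible with a random mother-offspring pair, from the classical
    allele-frequency formula (Jamieson & Taylor); a Monte-Carlo oracle
    validates the expression in the test-suite.  With ``locus=None`` a
    vector of per-locus values is returned.
    """
    def one(l):
        p = freqs.p(l)
        a2, a3 = np.sum(p ** 2), np.sum(p ** 3)
        a4, a5 = np.sum(p ** 4), np.sum(p ** 5)
        return float(1 - 2 * a2 + a3 + 2 * a4 - 3 * a5 - 2 * a2 ** 2
                     + 3 * a2 * a3)
    if locus is None:
        return np.array([one(l) for l in range(len(freqs.loci))])
    l = ([loc.name for loc in freqs.loci].index(locus)
         if isinstance(locus, str) else locus)
    return one(l)


def combined_exclusion(per_locus) -> float:
    """Multi-locus exclusion: 1 - prod(1 - Excl_l); monotone in locus count."""
    per_locus = np.asarray(per_locus, dtype=float)
    return float(1.0 - np.prod(1.0 - per_locus))


def summary_table(table: SpatialGenotypeTable, hwe_params: dict | None = None,
                  seed: int | None = None) -> pd.DataFrame:
    """Locus-by-locus diversity report: A, He, f, HWE p, null freq, Excl."""
    div = diversity(table)
    freqs = allele_freqs(table)
    excl = exclusion_probability(freqs)
    hwe_params = hwe_params or {}
    rows = []
    for l, loc in enumerate(table.loci):
        res = hwe_exact_test(table, l, seed=None if seed is None else seed + l,
                             **hwe_params)
        rows.append({"locus": loc.name, "hwe_p": res["p"],
                     "null": null_allele_freq(table, l), "excl": excl[l]})
    extra = pd.DataFrame(rows).set_index("locus")
    extra.loc["overall"] = {"hwe_p": np.nan, "null": np.nan,
                            "excl": combined_exclusion(excl)}
    return div.join(extra)
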