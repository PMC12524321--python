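"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — enumeration, Monte-Carlo gene
dropping, literal window scans — and shares no code with the package.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


# --------------------------------------------------------------------------
# Monte-Carlo gene dropping for the additive relationship matrix

def mc_relationship(parents: list[tuple[int, int]], n_rep: int,
                    rng: np.random.Generator):
    """Estimate the additive relationship matrix by dropping allele labels.

    ``parents[i] = (sire_index, dam_index)`` with -1 for unknown; indices
    must precede their offspring.  Returns ``(A_hat, se)`` with the
    Monte-Carlo standard error per entry.
    """
    n = len(parents)
    pat = [None] * n
    mat = [None] * n
    label = 0
    for i, (s, d) in enumerate(parents):
        if s < 0:
            pat[i] = np.full(n_rep, label)
            label += 1
        else:
            pick = rng.integers(2, size=n_rep).astype(bool)
            pat[i] = np.where(pick, pat[s], mat[s])
        if d < 0:
            mat[i] = np.full(n_rep, label)
            label += 1
        else:
            pick = rng.integers(2, size=n_rep).astype(bool)
            mat[i] = np.where(pick, pat[d], mat[d])
    A = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        x = 1.0 + (pat[i] == mat[i])
        A[i, i] = x.mean()
        se[i, i] = x.std(ddof=1) / np.sqrt(n_rep)
        for j in range(i):
            x = 0.5 * ((pat[i] == pat[j]).astype(float) + (pat[i] == mat[j])
                       + (mat[i] == pat[j]) + (mat[i] == mat[j]))
            A[i, j] = A[j, i] = x.mean()
            se[i, j] = se[j, i] = x.std(ddof=1) / np.sqrt(n_rep)
    return A, se


def random_pedigree_parents(n: int, rng: np.random.Generator,
                            p_parents: float = 0.6):
    """Random topologically ordered pedigree as parent index pairs."""
    parents = []
    for i in range(n):
        if i >= 2 and rng.random() < p_parents:
            s = int(rng.integers(i))
            d = int(rng.integers(i))
            if s == d:
                d = -1
            parents.append((s, d))
        else:
            parents.append((-1, -1))
    return parents


# --------------------------------------------------------------------------
# exact HWE test by full enumeration with rational arithmetic

def hwe_enumeration(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE p-value via exhaustive enumeration of all
    heterozygote counts compatible with the observed allele counts."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n - n_a
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    weights = {}
    for het in range(rare % 2, rare + 1, 2):
        ref = (n_a - het) // 2
        alt = (n_b - het) // 2
        # multinomial count of genotype configurations x 2^het phase choices
        w = Fraction(
            comb(n, het) * comb(n - het, ref) * (2 ** het))
        weights[het] = w
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


# --------------------------------------------------------------------------
# literal ROH window scan

def roh_scan(genotypes, positions, *, window_snps, window_max_het,
             window_max_missing, hit_threshold, min_length_bp, min_snps,
             max_gap_bp, max_density_bp_per_snp):
    """Enumerate every window and candidate run explicitly.

    Returns (flags, segments) with segments as (start_idx, end_idx) marker
    index pairs.
    """
    g = list(genotypes)
    n = len(g)
    windows = []
    for start in range(0, n - window_snps + 1):
        chunk = g[start:start + window_snps]
        het = sum(1 for x in chunk if x == 1)
        mis = sum(1 for x in chunk if x == -1)
        windows.append((start, het <= window_max_het and mis <= window_max_missing))
    flags = []
    for i in range(n):
        covering = [hom for start, hom in windows
                    if start <= i < start + window_snps]
        if not covering:
            flags.append(False)
        else:
            flags.append(sum(covering) / len(covering) >= hit_threshold)
    segments = []
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and flags[j + 1]
               and positions[j + 1] - positions[j] <= max_gap_bp):
            j += 1
        length = positions[j] - positions[i] + 1
        n_snps = j - i + 1
        if (length >= min_length_bp and n_snps >= min_snps
                and length / n_snps <= max_density_bp_per_snp):
            segments.append((i, j))
        i = j + 1
    return flags, segments


# --------------------------------------------------------------------------
# exhaustive HMM path enumeration

def hmm_emission(genotype, p, hbd, eps):
    if genotype == -1:
        return 1.0
    q = 1.0 - p
    if hbd:
        return {0: q * (1 - eps) + q * q * eps,
                1: 2 * p * q * eps,
                2: p * (1 - eps) + p * p * eps}[genotype]
    return {0: q * q, 1: 2 * p * q, 2: p * p}[genotype]


def hmm_enumerate(genotypes, freqs, dists, rates, mixing, eps):
    """Likelihood, posteriors and best path by summing over all K^L paths.

    The last class is non-HBD; transition over distance d from class k:
    stay with exp(-rates[k] * d), otherwise re-draw from ``mixing``.
    """
    K = len(rates)
    L = len(genotypes)
    emis = np.array([[hmm_emission(genotypes[t], freqs[t], k < K - 1, eps)
                      for k in range(K)] for t in range(L)])
    stay = np.exp(-np.outer(dists, rates))
    lik = 0.0
    post = np.zeros((L, K))
    best_logp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=L):
        p = mixing[path[0]] * emis[0, path[0]]
        for t in range(L - 1):
            k, l = path[t], path[t + 1]
            trans = (1.0 - stay[t, k]) * mixing[l]
            if k == l:
                trans += stay[t, k]
            p *= trans * emis[t + 1, l]
        lik += p
        for t, k in enumerate(path):
            post[t, k] += p
        if p > 0 and np.log(p) > best_logp:
            best_logp, best_path = np.log(p), np.array(path)
    return np.log(lik), post / lik, best_logp, best_path
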