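"""Independent, deliberately naive reference implementations used as
oracles: scalar transcriptions and brute-force enumerations, kept free of
any code path from the package itself."""

from __future__ import annotations

import itertools

import numpy as np


def wc_fst_components(geno1, geno2):
    """Weir & Cockerham (1984) a, b, c for one biallelic site, two groups.

    ``geno1``/``geno2`` are lists of diploid dosages (0/1/2), missing calls
    already removed. Pure-scalar transcription of the published formulas
    for r = 2 sampled populations, with the within-individual
    (heterozygosity) components.
    """
    r = 2
    pops = [list(geno1), list(geno2)]
    n = [len(g) for g in pops]
    if min(n) == 0:
        return float("nan"), float("nan"), float("nan")
    p = [sum(g) / (2.0 * len(g)) for g in pops]
    h = [sum(1 for x in g if x == 1) / len(g) for g in pops]
    n_tot = sum(n)
    nbar = n_tot / r
    nc = (n_tot - sum(ni * ni for ni in n) / n_tot) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / n_tot
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / n_tot
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_fst(geno1, geno2):
    a, b, c = wc_fst_components(geno1, geno2)
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


def pi_pairwise(dosages):
    """Nucleotide diversity at one site by enumerating chromosome pairs.

    Expands diploid dosages into alleles and averages the Hamming distance
    over all allele pairs.
    """
    alleles = []
    for d in dosages:
        if np.isnan(d):
            continue
        d = int(d)
        alleles += [1] * d + [0] * (2 - d)
    if len(alleles) < 2:
        return float("nan")
    pairs = list(itertools.combinations(alleles, 2))
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def gls_fit(y, x_fixed, v_matrix, s=None, z=None, k=None, sigma_c2=0.0, sigma_g2=0.0):
    """Generalized least squares by direct inversion of V, with BLUPs.

    beta = (X'V^-1X)^-1 X'V^-1 y; random-effect predictions follow from
    c_hat = sigma_c^2 S'V^-1 (y - X beta), g_hat = sigma_g^2 K Z'V^-1 (y - X beta).
    """
    vi = np.linalg.inv(v_matrix)
    xtvi = x_fixed.T @ vi
    beta = np.linalg.solve(xtvi @ x_fixed, xtvi @ y)
    resid = y - x_fixed @ beta
    c_hat = sigma_c2 * (s.T @ (vi @ resid)) if s is not None else None
    g_hat = sigma_g2 * (k @ (z.T @ (vi @ resid))) if z is not None else None
    return beta, c_hat, g_hat
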