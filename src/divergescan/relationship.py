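"""Realized genomic relationship matrix (VanRaden) and genotype PCA.

The polygenic covariance kernel of the mixed model is the realized
relationship matrix

    K = W W' / (2 * sum_j p_j (1 - p_j)),

where W is the dosage matrix with column j centered by 2*p_j and p_j is the
observed alt-allele frequency (VanRaden's first method). Missing dosages are
mean-imputed per marker before centering; monomorphic markers contribute
nothing and are excluded. Allele frequencies are estimated from the full
(pooled) sample, since a single K enters one fitted model across both lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = ["Grm", "PcaResult", "vanraden_grm", "pca"]

_PSD_TOL = 1e-8


@dataclass
class Grm:
    """Genomic relationship matrix over samples."""

    matrix: np.ndarray = field(repr=False)
    samples: list[str]
    n_markers: int
    freqs: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.samples, columns=self.samples)


@dataclass
class PcaResult:
    """Leading principal components of standardized genotypes."""

    scores: np.ndarray = field(repr=False)  # (n_samples, k)
    eigenvalues: np.ndarray
    proportion_variance: np.ndarray
    samples: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.samples, columns=cols)


def _imputed_dosages(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing calls per marker; returns (matrix, allele freqs)."""
    m = g.dosages.copy()
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(m, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)  # all-missing marker
    nan_r, nan_c = np.nonzero(np.isnan(m))
    m[nan_r, nan_c] = col_mean[nan_c]
    return m, col_mean / 2.0


def vanraden_grm(g: GenotypeMatrix, psd_tol: float = _PSD_TOL) -> Grm:
    """Compute K = WW' / (2 Σ p(1-p)) from observed dosages.

    Raises ``ValueError`` if every marker is monomorphic (zero denominator).
    Eigenvalues below ``-psd_tol`` raise; tiny negatives are tolerated
    (clipped implicitly by downstream ridge handling).
    """
    m, p = _imputed_dosages(g)
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all markers monomorphic: zero denominator for K")
    m = m[:, poly]
    p = p[poly]
    w = m - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    k = (w @ w.T) / denom
    k = (k + k.T) / 2.0
    eigmin = np.linalg.eigvalsh(k)[0]
    if eigmin < -psd_tol:
        raise ValueError(f"K has eigenvalue {eigmin:.3e} below -{psd_tol:.0e}")
    return Grm(matrix=k, samples=list(g.samples), n_markers=int(poly.sum()), freqs=p)


def pca(g: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of column-standardized dosages (unit-variance VanRaden scaling).

    Scores are centered per component. Monomorphic markers are dropped.
    ``n_components`` is truncated to n_samples - 1 with a warning.
    """
    n = g.n_samples
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > n - 1:
        warnings.warn(
            f"n_components={n_components} truncated to {n - 1}", stacklevel=2
        )
        n_components = n - 1
    m, p = _imputed_dosages(g)
    poly = (p > 0.0) & (p < 1.0)
    m = m[:, poly]
    p = p[poly]
    z = (m - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    if z.shape[1] == 0:
        k = min(n_components, max(n - 1, 1))
        return PcaResult(
            scores=np.zeros((n, k)),
            eigenvalues=np.zeros(k),
            proportion_variance=np.zeros(k),
            samples=list(g.samples),
        )
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    k = min(n_components, len(s))
    eig = s**2 / (n - 1)
    total = eig.sum()
    prop = eig[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(
        scores=u[:, :k] * s[:k],
        eigenvalues=eig[:k],
        proportion_variance=prop,
        samples=list(g.samples),
    )
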