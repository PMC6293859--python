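"""Per-SNP Weir–Cockerham Fst, nucleotide diversity, window scan and
selection-signature calling.

Fst between the selection and control lines uses the Weir & Cockerham (1984)
estimator with the individual-level variance components: for each biallelic
site, a (among populations), b (among individuals within populations) and
c (within individuals, driven by observed heterozygosity) are computed from
genotype counts, and Fst = a / (a + b + c). Sites with a zero denominator
(e.g. both groups monomorphic for the same allele) are reported as undefined
(NaN), distinct from Fst = 0. Negative estimates are retained, matching the
per-site output of the standard VCF toolchain.

Per-site nucleotide diversity is the unbiased pairwise-difference
proportion pi = 2 * nA * na / (n * (n - 1)) over observed alleles; window
pi is the sum of per-site pi divided by the window span in bp, which is the
natural per-bp scale for sparse reduced-representation markers.

Windows are non-overlapping, tiled from position 1 per chromosome, half-open
[start, start + size). A window is flagged as a candidate selection
signature when its mean per-SNP Fst exceeds 0.05 or its 95% quantile
exceeds 0.25 (both configurable); genome-wide outlier SNPs are called at
the top 1% of defined Fst values by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = [
    "FstThresholds",
    "wc_fst_site",
    "pi_site",
    "window_stats",
    "top_quantile_loci",
]


@dataclass(frozen=True)
class FstThresholds:
    """Window-flagging thresholds: mean Fst and 95% quantile Fst."""

    mean: float = 0.05
    q95: float = 0.25


def _group_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n genotyped, alt freq, het proportion) for one group."""
    obs = ~np.isnan(dosages)
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dosages, axis=0) / (2.0 * n)
        h = np.nansum(dosages == 1.0, axis=0) / n
    return n, p, h


def wc_fst_site(g: GenotypeMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Weir–Cockerham (1984) per-site Fst between the two lines.

    Parameters
    ----------
    g : GenotypeMatrix
    samples : DataFrame with ``sample_id`` and ``line`` columns; exactly two
        distinct lines must be present among g's samples.

    Returns
    -------
    DataFrame indexed like ``g.markers`` with columns ``chrom, pos, a, d,
    fst, p_sel, p_con, pi_sel, pi_con`` where ``d = a + b + c`` and
    undefined Fst is NaN.
    """
    lines = samples.set_index("sample_id").loc[g.samples, "line"].to_numpy()
    groups = pd.unique(lines)
    if len(groups) != 2:
        raise ValueError(f"expected exactly two lines, found {list(groups)}")
    # canonical order: selection first when present
    if "selection" in groups:
        groups = ["selection", "control"] if "control" in groups else list(groups)
    r = 2
    n_i, p_i, h_i = [], [], []
    for grp in groups:
        idx = np.flatnonzero(lines == grp)
        n, p, h = _group_counts(g.dosages[idx, :])
        if np.all(n == 0):
            raise ValueError(f"group {grp!r} has zero genotyped samples at every site")
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)  # (2, m)
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_tot = n_i.sum(axis=0)
        nbar = n_tot / r
        nc = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_tot

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        fst = np.where(denom != 0, a / denom, np.nan)
    # sites unusable (a group ungenotyped, or single individual overall)
    bad = (n_i == 0).any(axis=0) | (nbar <= 1) | ~np.isfinite(denom)
    fst = np.where(bad, np.nan, fst)
    a = np.where(bad, np.nan, a)
    denom = np.where(bad, np.nan, denom)

    sel_idx = np.flatnonzero(lines == groups[0])
    con_idx = np.flatnonzero(lines == groups[1])
    out = g.markers[["chrom", "pos"]].copy()
    out["a"] = a
    out["d"] = denom
    out["fst"] = fst
    out["p_sel"] = p_i[0]
    out["p_con"] = p_i[1]
    out["pi_sel"] = pi_site(g, [g.samples[i] for i in sel_idx])
    out["pi_con"] = pi_site(g, [g.samples[i] for i in con_idx])
    return out


def pi_site(g: GenotypeMatrix, samples: list[str] | None = None) -> np.ndarray:
    """Per-site nucleotide diversity pi = 2*nA*na / (n*(n-1)).

    nA, na are observed alt/ref allele counts, n their sum (chromosomes).
    Monomorphic sites give 0; sites with fewer than 2 observed alleles NaN.
    """
    if samples is None:
        dos = g.dosages
    else:
        pos = {s: i for i, s in enumerate(g.samples)}
        dos = g.dosages[[pos[s] for s in samples], :]
    obs = ~np.isnan(dos)
    n = 2.0 * obs.sum(axis=0)
    n_alt = np.nansum(dos, axis=0)
    n_ref = n - n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * n_alt * n_ref / (n * (n - 1.0))
    return np.where(n < 2, np.nan, pi)


def window_stats(
    sites: pd.DataFrame,
    window_size_bp: int,
    thresholds: FstThresholds = FstThresholds(),
) -> pd.DataFrame:
    """Aggregate per-site statistics into non-overlapping windows.

    Windows tile each chromosome from position 1, half-open
    ``[start, start+size)``; tiling extends to the last window containing a
    site, and intermediate empty windows are emitted with ``n_snps = 0`` and
    NaN statistics.

    mean Fst is the unweighted mean of defined per-SNP values; weighted Fst
    is the ratio-of-sums Σa / Σ(a+b+c); the 95% quantile uses linear
    interpolation between order statistics. Window pi (per line) is the sum
    of per-site pi divided by the window size in bp.
    """
    if window_size_bp <= 0:
        raise ValueError("window_size_bp must be positive")
    records = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        widx = (grp["pos"].to_numpy() - 1) // window_size_bp
        for w in range(int(widx.max()) + 1 if len(grp) else 0):
            sub = grp.iloc[np.flatnonzero(widx == w)]
            start = 1 + w * window_size_bp
            end = start + window_size_bp
            fst = sub["fst"].dropna().to_numpy()
            a_sum = sub["a"].sum(skipna=True)
            d_sum = sub["d"].sum(skipna=True)
            mean_fst = fst.mean() if len(fst) else np.nan
            q95 = (
                float(np.quantile(fst, 0.95, method="linear"))
                if len(fst)
                else np.nan
            )
            weighted = a_sum / d_sum if d_sum and np.isfinite(d_sum) and d_sum != 0 else np.nan
            records.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": len(sub),
                    "mean_fst": mean_fst,
                    "weighted_fst": weighted,
                    "q95_fst": q95,
                    "pi_sel": np.nansum(sub["pi_sel"].to_numpy()) / window_size_bp
                    if len(sub)
                    else np.nan,
                    "pi_con": np.nansum(sub["pi_con"].to_numpy()) / window_size_bp
                    if len(sub)
                    else np.nan,
                    "elevated_mean": bool(mean_fst > thresholds.mean)
                    if np.isfinite(mean_fst)
                    else False,
                    "elevated_q95": bool(q95 > thresholds.q95)
                    if np.isfinite(q95)
                    else False,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "chrom", "start", "end", "n_snps", "mean_fst", "weighted_fst",
            "q95_fst", "pi_sel", "pi_con", "elevated_mean", "elevated_q95",
        ],
    )


def top_quantile_loci(sites: pd.DataFrame, quantile: float = 0.01) -> pd.DataFrame:
    """Call the top-``quantile`` fraction of defined per-SNP Fst values.

    The threshold is the (1-quantile) quantile (linear interpolation) of the
    defined Fst values; all loci with Fst >= threshold are returned, ranked
    descending, with ties at the threshold included.
    """
    defined = sites.dropna(subset=["fst"])
    if defined.empty:
        raise ValueError("no defined Fst values")
    threshold = float(
        np.quantile(defined["fst"].to_numpy(), 1.0 - quantile, method="linear")
    )
    hits = defined[defined["fst"] >= threshold].copy()
    hits = hits.sort_values(
        ["fst", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    )
    hits["rank"] = np.arange(1, len(hits) + 1)
    hits["threshold"] = threshold
    return hits[["chrom", "pos", "fst", "rank", "threshold"]]
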