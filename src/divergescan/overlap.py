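"""Intersect QTL hits with elevated-Fst windows; flanking allele profiles.

A QTL corroborates a selection signature when its position falls inside a
window flagged by the chosen criterion (default: the 95%-quantile rule,
window q95 Fst > 0.25; alternatives: the mean-Fst rule, or windows
containing a genome-wide top-quantile SNP). For candidate intervals, the
per-line allele-frequency profile of every SNP within a +/- 5 kb flank is
reported, with loci fixed in one line flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .qtl import QtlHit

__all__ = [
    "OverlapHit",
    "overlap_qtl_windows",
    "flank_allele_frequencies",
    "read_feature_intervals",
    "label_hits_with_features",
]

FLAG_CRITERIA = ("elevated_q95", "elevated_mean", "top_quantile")


@dataclass
class OverlapHit:
    """A QTL located inside a flagged differentiation window."""

    trait: str
    marker_id: str
    chrom: str
    pos: int
    window_start: int
    window_end: int
    window_mean_fst: float
    window_q95_fst: float
    criterion: str


def overlap_qtl_windows(
    qtl: list[QtlHit],
    windows: pd.DataFrame,
    criterion: str = "elevated_q95",
    top_loci: pd.DataFrame | None = None,
) -> list[OverlapHit]:
    """Emit a hit for each QTL inside a window flagged by ``criterion``.

    Windows are half-open [start, end): a QTL exactly at a window's end
    coordinate belongs to the next window. Output is ordered by
    (chrom, pos, trait). With ``criterion="top_quantile"`` a window is
    flagged when it contains a genome-wide top-quantile SNP (pass the
    ``top_loci`` frame from the scan module).
    """
    if criterion not in FLAG_CRITERIA:
        raise ValueError(f"criterion must be one of {FLAG_CRITERIA}")
    if criterion == "top_quantile":
        if top_loci is None:
            raise ValueError("criterion 'top_quantile' requires top_loci")
        flag = np.zeros(len(windows), dtype=bool)
        for i, (_, w) in enumerate(windows.iterrows()):
            flag[i] = bool(
                (
                    (top_loci["chrom"] == w["chrom"])
                    & (top_loci["pos"] >= w["start"])
                    & (top_loci["pos"] < w["end"])
                ).any()
            )
        flagged = windows[flag]
    else:
        flagged = windows[windows[criterion]]
    hits: list[OverlapHit] = []
    for q in qtl:
        w = flagged[
            (flagged["chrom"] == q.chrom)
            & (flagged["start"] <= q.pos)
            & (q.pos < flagged["end"])
        ]
        for _, row in w.iterrows():
            hits.append(
                OverlapHit(
                    trait=q.trait,
                    marker_id=q.marker_id,
                    chrom=q.chrom,
                    pos=q.pos,
                    window_start=int(row["start"]),
                    window_end=int(row["end"]),
                    window_mean_fst=float(row["mean_fst"]),
                    window_q95_fst=float(row["q95_fst"]),
                    criterion=criterion,
                )
            )
    hits.sort(key=lambda h: (h.chrom, h.pos, h.trait))
    return hits


def flank_allele_frequencies(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    interval: tuple[str, int, int],
    flank_bp: int = 5000,
) -> pd.DataFrame:
    """Per-line allele frequencies for SNPs in interval +/- flank.

    Returns a frame with ``pos, freq_sel, freq_con, abs_diff, fixed_sel,
    fixed_con``; a locus is "fixed" in a line when its observed frequency
    there is exactly 0 or 1. An empty region yields an empty frame.
    """
    chrom, start, end = interval
    mk = g.markers
    in_region = (
        (mk["chrom"] == chrom)
        & (mk["pos"] >= start - flank_bp)
        & (mk["pos"] <= end + flank_bp)
    ).to_numpy()
    idx = np.flatnonzero(in_region)
    lines = samples.set_index("sample_id").loc[g.samples, "line"].to_numpy()
    rows = []
    for j in idx:
        rec = {"marker_id": mk.index[j], "pos": int(mk["pos"].iloc[j])}
        for key, grp in (("sel", "selection"), ("con", "control")):
            dos = g.dosages[lines == grp, j]
            obs = dos[~np.isnan(dos)]
            freq = obs.sum() / (2 * len(obs)) if len(obs) else np.nan
            rec[f"freq_{key}"] = freq
            rec[f"fixed_{key}"] = bool(freq in (0.0, 1.0)) if len(obs) else False
        rec["abs_diff"] = abs(rec["freq_sel"] - rec["freq_con"])
        rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=["marker_id", "pos", "freq_sel", "freq_con", "abs_diff",
                 "fixed_sel", "fixed_con"],
    )


def read_feature_intervals(path) -> pd.DataFrame:
    """Read named intervals from BED (0-based half-open) or GFF3 (1-based).

    Returns 1-based inclusive ``chrom, start, end, name`` rows, for labeling
    candidate hits with overlapping feature (gene) names.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "type", "start", "end", "score",
                   "strand", "phase", "attributes"],
        )
        name = df["attributes"].str.extract(r"Name=([^;]+)")[0]
        name = name.fillna(df["attributes"].str.extract(r"ID=([^;]+)")[0])
        return pd.DataFrame(
            {"chrom": df["chrom"].astype(str), "start": df["start"],
             "end": df["end"], "name": name.fillna("feature")}
        )
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    out = pd.DataFrame(
        {"chrom": df[0].astype(str), "start": df[1] + 1, "end": df[2]}
    )
    out["name"] = df[3] if df.shape[1] > 3 else "feature"
    return out


def label_hits_with_features(
    hits: list[OverlapHit], features: pd.DataFrame
) -> pd.DataFrame:
    """Tabulate hits with a comma-joined list of overlapping feature names."""
    columns = [
        "trait", "marker_id", "chrom", "pos", "window_start", "window_end",
        "window_mean_fst", "window_q95_fst", "criterion", "features",
    ]
    rows = []
    for h in hits:
        ov = features[
            (features["chrom"] == h.chrom)
            & (features["start"] <= h.pos)
            & (h.pos <= features["end"])
        ]
        rows.append(
            {
                "trait": h.trait, "marker_id": h.marker_id, "chrom": h.chrom,
                "pos": h.pos, "window_start": h.window_start,
                "window_end": h.window_end,
                "window_mean_fst": h.window_mean_fst,
                "window_q95_fst": h.window_q95_fst,
                "criterion": h.criterion,
                "features": ",".join(ov["name"]) if len(ov) else "",
            }
        )
    return pd.DataFrame(rows, columns=columns)
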