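"""Genotype and sample-table containers, VCF/TSV round-trip and marker QC.

The central container is :class:`GenotypeMatrix`: an (n_samples, n_markers)
dosage matrix (0/1/2 counted alt alleles, NaN for missing calls) together
with an ordered marker map (chromosome, 1-based bp position, ref/alt).
Sample metadata and trait observations travel in a plain pandas DataFrame
(see :data:`SAMPLE_COLUMNS` and :data:`TRAITS`).

Coordinates follow the VCF convention: 1-based, inclusive. Window logic in
other modules converts to half-open intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "TRAITS",
    "SAMPLE_COLUMNS",
    "GenotypeMatrix",
    "VcfFormatError",
    "read_vcf",
    "write_vcf",
    "read_sample_table",
    "write_sample_table",
    "qc_filter",
    "QcReport",
]

logger = logging.getLogger(__name__)

#: The six growth traits, in the order they are reported:
#: body weight / length at tagging (~3 months), then weight, length,
#: depth and width at 8 months of age.
TRAITS = ("iBwt", "iBlen", "Bwt8m", "Blen8m", "Bdp8m", "Bwd8m")

SAMPLE_COLUMNS = ("sample_id", "family_id", "line", "cage_id", "role")

LINES = ("selection", "control")


class VcfFormatError(ValueError):
    """Raised for malformed VCF input; message names the offending line."""


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with a marker map.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows).
    markers : pandas.DataFrame
        Ordered marker map indexed by marker id, with columns
        ``chrom`` (str), ``pos`` (1-based int), ``ref``, ``alt``.
    dosages : ndarray, shape (n_samples, n_markers)
        Counted alt alleles in {0, 1, 2}; ``nan`` marks a missing call.
    """

    samples: list[str]
    markers: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freq(self) -> np.ndarray:
        """Observed alt-allele frequency per marker (missing calls excluded).

        All-missing markers give NaN.
        """
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def take_markers(self, index) -> "GenotypeMatrix":
        """Subset/reorder markers by positional index."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=self.markers.iloc[index].copy(),
            dosages=self.dosages[:, index],
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            markers=self.markers.copy(),
            dosages=self.dosages[index, :],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.markers.index.tolist() == other.markers.index.tolist()
            and self.markers.reset_index(drop=True).equals(
                other.markers.reset_index(drop=True)
            )
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (possibly gzipped) VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are dropped (count logged). Phased and
    unphased separators are both accepted; half-missing genotypes (``./1``)
    are treated as missing.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise VcfFormatError(f"{path}: malformed VCF header ({exc})") from exc
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    records: list[tuple] = []
    n_dropped = 0
    for i, v in enumerate(vcf):
        if v.POS <= 0:
            raise VcfFormatError(
                f"{path}: data line {i + 1}: non-positive position {v.POS}"
            )
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        gts = np.array(v.genotypes, dtype=int)[:, :2]
        dos = gts.sum(axis=1).astype(float)
        dos[(gts < 0).any(axis=1)] = np.nan  # half-missing -> missing
        rows.append(dos)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        records.append((vid, v.CHROM, v.POS, v.REF, v.ALT[0]))
    if n_dropped:
        logger.info("read_vcf: dropped %d multi-allelic/non-SNP records", n_dropped)
    markers = pd.DataFrame(
        records, columns=["marker_id", "chrom", "pos", "ref", "alt"]
    ).set_index("marker_id")
    dosages = (
        np.array(rows).T if rows else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples=samples, markers=markers, dosages=dosages)


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a VCF v4.2 file with GT-only genotypes and contig header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=divergescan\n")
        for chrom, grp in g.markers.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, (mid, row) in enumerate(g.markers.iterrows()):
            gts = "\t".join(
                _GT_CODE.get(d, "./.") for d in g.dosages[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{mid}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a sample/phenotype TSV (header row required; gzip tolerated)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str, "cage_id": str})
    missing = [c for c in ("sample_id", "line") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


class QcReport(NamedTuple):
    n_input: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_kept: int


def qc_filter(
    g: GenotypeMatrix, min_call_rate: float = 0.0, min_maf: float = 0.0
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers failing a call-rate or minor-allele-frequency floor.

    MAF is computed on observed (non-missing) alleles. Returns the filtered
    matrix and a report with removal counts. Idempotent.
    """
    if not 0.0 <= min_call_rate <= 1.0:
        raise ValueError("min_call_rate must be in [0, 1]")
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    cr = g.call_rate()
    p = g.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    fail_cr = cr < min_call_rate
    # all-missing markers have undefined MAF; they fail any call-rate floor > 0
    # and are kept (MAF test vacuous) otherwise
    fail_maf = np.where(np.isnan(maf), False, maf < min_maf) & ~fail_cr
    keep = ~(fail_cr | fail_maf)
    report = QcReport(
        n_input=g.n_markers,
        n_removed_call_rate=int(fail_cr.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_kept=int(keep.sum()),
    )
    logger.info(
        "qc_filter: %d in, %d removed (call rate), %d removed (MAF), %d kept",
        *report[:4],
    )
    return g.take_markers(np.flatnonzero(keep)), report
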