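"""Synthetic full-sib-family cohort generator.

Emulates the structure of a two-line carp breeding cohort: 25 full-sib
families of 2 parents + 8 offspring each (250 fish), 19 families from a
growth-selected line and 6 from an unselected control line, each family
housed in its own cage (hapa), genotyped at biallelic SNPs spread over
multiple chromosomes.

Line divergence is induced at a configurable fraction of markers by
drawing the two lines' founder allele frequencies independently from a
Balding-Nichols beta distribution around a shared ancestral frequency,
with the differentiation parameter playing the role of the target Fst.
Remaining markers share a single ancestral frequency. Parent genotypes are
binomial draws from the line frequency; offspring receive one allele per
parent by Mendelian transmission. Markers segregate independently (no
recombination map is simulated).

Phenotypes follow the analysis model exactly:

    y = X b + S c + Z g + W q + e

with a fixed line effect, a N(0, sigma_c^2) cage effect shared within each
family, a polygenic effect drawn multivariate-normal with covariance
K sigma_g^2 where K is the VanRaden relationship matrix computed from the
simulated genotypes themselves, fixed planted-QTL effects applied to
centered dosages (so planting a QTL does not shift the trait mean), and
i.i.d. N(0, sigma_e^2) residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TRAITS, GenotypeMatrix
from .qtl import VarianceComponents
from .relationship import vanraden_grm

__all__ = [
    "CohortSpec",
    "FounderFrequencies",
    "simulate_pedigree",
    "simulate_founder_frequencies",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Simulation truth for one synthetic cohort.

    Defaults are desk-scale but structurally faithful: 25 families
    (19 selection + 6 control) of 2 parents + 8 offspring, 5,000 markers on
    10 chromosomes of 2 Mb each, 1% of markers line-divergent at a target
    differentiation of 0.4, and variance components giving h^2 = 0.5
    (sigma_g^2 = 1.0 against sigma_c^2 = 0.1 and sigma_e^2 = 0.9).

    ``qtl_list`` holds planted major QTL as (trait, marker index, allele
    substitution effect); ``line_effect`` is the fixed phenotype shift of
    the selection line, applied to every trait.
    """

    n_families: int = 25
    offspring_per_family: int = 8
    n_selection_families: int = 19
    n_markers: int = 5000
    n_chromosomes: int = 10
    chromosome_length: int = 2_000_000
    divergent_fraction: float = 0.01
    divergence_fst: float = 0.4
    qtl_list: tuple[tuple[str, int, float], ...] = ()
    divergent_centers: tuple[int, ...] = ()
    varcomp_true: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(
            cage=0.1, polygenic=1.0, residual=0.9
        )
    )
    line_effect: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_selection_families > self.n_families:
            raise ValueError("n_selection_families must be <= n_families")
        if not 0.0 <= self.divergent_fraction <= 1.0:
            raise ValueError("divergent_fraction must be in [0, 1]")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        if not 0.0 <= self.divergence_fst < 1.0:
            raise ValueError("divergence_fst must be in [0, 1)")
        for trait, idx, _ in self.qtl_list:
            if trait not in TRAITS:
                raise ValueError(f"unknown trait {trait!r}")
            if not 0 <= idx < self.n_markers:
                raise ValueError(f"QTL marker index {idx} out of range")
        for idx in self.divergent_centers:
            if not 0 <= idx < self.n_markers:
                raise ValueError(f"divergent center index {idx} out of range")


@dataclass
class FounderFrequencies:
    """Per-marker founder allele frequencies for the two lines."""

    p_selection: np.ndarray
    p_control: np.ndarray
    divergent: np.ndarray  # bool flags

    def __post_init__(self):
        for arr in (self.p_selection, self.p_control):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("allele frequencies must lie in [0, 1]")


def _rng(spec: CohortSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def simulate_pedigree(spec: CohortSpec) -> pd.DataFrame:
    """Family/line/cage/role table: one cage per family, 2 parents + offspring."""
    rows = []
    for f in range(spec.n_families):
        line = "selection" if f < spec.n_selection_families else "control"
        fam = f"F{f + 1:03d}"
        cage = f"C{f + 1:03d}"
        for p in (1, 2):
            rows.append((f"{fam}_P{p}", fam, line, cage, "parent"))
        for o in range(spec.offspring_per_family):
            rows.append((f"{fam}_O{o + 1}", fam, line, cage, "offspring"))
    return pd.DataFrame(
        rows, columns=["sample_id", "family_id", "line", "cage_id", "role"]
    )


def simulate_founder_frequencies(spec: CohortSpec) -> FounderFrequencies:
    """Ancestral frequencies ~ U[0.05, 0.95]; divergent markers get
    independent Balding-Nichols draws per line.

    Under Balding-Nichols with differentiation F, a line frequency is
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral p, so the expected
    between-line Fst of divergent markers matches ``divergence_fst``.
    """
    rng = _rng(spec, 1)
    m = spec.n_markers
    p0 = rng.uniform(0.05, 0.95, size=m)
    n_div = int(round(spec.divergent_fraction * m))
    divergent = np.zeros(m, dtype=bool)
    if spec.divergent_centers and n_div > 0:
        # hitchhiking emulation: markers segregate independently, so the
        # local footprint of a selected site is planted as a block of
        # divergent markers centered on each requested locus, kept within
        # that locus's chromosome
        chrom_of = np.repeat(
            np.arange(spec.n_chromosomes), _markers_per_chromosome(spec)
        )
        per = max(1, n_div // len(spec.divergent_centers))
        for c in spec.divergent_centers:
            lo = max(0, c - per // 2)
            block = np.arange(lo, min(m, lo + per))
            divergent[block[chrom_of[block] == chrom_of[c]]] = True
            divergent[c] = True
    else:
        divergent[rng.choice(m, size=n_div, replace=False)] = True

    p_sel = p0.copy()
    p_con = p0.copy()
    f = spec.divergence_fst
    if f > 0 and n_div > 0:
        shape = (1.0 - f) / f
        a = p0[divergent] * shape
        b = (1.0 - p0[divergent]) * shape
        p_sel[divergent] = rng.beta(a, b)
        p_con[divergent] = rng.beta(a, b)
    return FounderFrequencies(p_selection=p_sel, p_control=p_con, divergent=divergent)


def _markers_per_chromosome(spec: CohortSpec) -> np.ndarray:
    per_chrom = np.full(spec.n_chromosomes, spec.n_markers // spec.n_chromosomes)
    per_chrom[: spec.n_markers % spec.n_chromosomes] += 1
    return per_chrom


def _marker_map(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Markers spread evenly over chromosomes, sorted unique positions."""
    per_chrom = _markers_per_chromosome(spec)
    records = []
    for c, n_c in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        pos = np.sort(
            rng.choice(np.arange(1, spec.chromosome_length + 1), size=n_c, replace=False)
        )
        for p in pos:
            records.append((f"{chrom}_{p}", chrom, int(p), "A", "G"))
    return pd.DataFrame(
        records, columns=["marker_id", "chrom", "pos", "ref", "alt"]
    ).set_index("marker_id")


def simulate_genotypes(
    pedigree: pd.DataFrame, freqs: FounderFrequencies, spec: CohortSpec
) -> GenotypeMatrix:
    """Parents ~ Binomial(2, p_line); offspring by Mendelian transmission."""
    rng = _rng(spec, 2)
    markers = _marker_map(spec, rng)
    m = len(markers)
    n = len(pedigree)
    dosages = np.zeros((n, m))
    sample_pos = {s: i for i, s in enumerate(pedigree["sample_id"])}
    for fam, grp in pedigree.groupby("family_id", sort=False):
        line = grp["line"].iloc[0]
        p_line = freqs.p_selection if line == "selection" else freqs.p_control
        parents = grp[grp["role"] == "parent"]["sample_id"].tolist()
        offspring = grp[grp["role"] == "offspring"]["sample_id"].tolist()
        par_dos = rng.binomial(2, p_line, size=(len(parents), m)).astype(float)
        for s, d in zip(parents, par_dos):
            dosages[sample_pos[s]] = d
        if offspring:
            # one allele from each parent: Bernoulli(dosage/2) per marker
            for s in offspring:
                a1 = rng.random(m) < par_dos[0] / 2.0
                a2 = rng.random(m) < par_dos[1] / 2.0
                dosages[sample_pos[s]] = a1.astype(float) + a2.astype(float)
    if spec.missing_rate > 0:
        mask = rng.random(dosages.shape) < spec.missing_rate
        dosages[mask] = np.nan
    return GenotypeMatrix(
        samples=pedigree["sample_id"].tolist(), markers=markers, dosages=dosages
    )


def simulate_phenotypes(
    genotypes: GenotypeMatrix, pedigree: pd.DataFrame, spec: CohortSpec
) -> pd.DataFrame:
    """Fill the six trait columns from y = Xb + Sc + Zg + Wq + e.

    The polygenic vector is drawn from N(0, K sigma_g^2) with K computed
    from the simulated genotypes, so the simulation truth matches the
    fitted model exactly. Cage effects are shared within family (one cage
    per family); QTL dosages are centered before the fixed effect is added.
    """
    rng = _rng(spec, 3)
    n = len(pedigree)
    v = spec.varcomp_true
    table = pedigree.copy()

    sel = (table["line"] == "selection").to_numpy().astype(float)
    cages = pd.unique(table["cage_id"])
    cage_idx = pd.Categorical(table["cage_id"], categories=cages).codes

    if v.polygenic > 0:
        k = vanraden_grm(genotypes).matrix
        eigval, eigvec = np.linalg.eigh(k)
        eigval = np.clip(eigval, 0.0, None)
        root = eigvec * np.sqrt(eigval)
    else:
        root = None

    qtl_by_trait: dict[str, list[tuple[int, float]]] = {t: [] for t in TRAITS}
    for trait, idx, effect in spec.qtl_list:
        if not 0 <= idx < genotypes.n_markers:
            raise ValueError(f"QTL marker index {idx} out of range")
        qtl_by_trait[trait].append((idx, effect))

    for trait in TRAITS:
        y = spec.line_effect * sel
        if v.cage > 0:
            c = rng.normal(0.0, np.sqrt(v.cage), size=len(cages))
            y = y + c[cage_idx]
        if root is not None:
            g_eff = root @ rng.standard_normal(n) * np.sqrt(v.polygenic)
            y = y + g_eff
        for idx, effect in qtl_by_trait[trait]:
            w = genotypes.dosages[:, idx].copy()
            mean = np.nanmean(w)
            w[np.isnan(w)] = mean
            y = y + effect * (w - mean)
        if v.residual > 0:
            y = y + rng.normal(0.0, np.sqrt(v.residual), size=n)
        table[trait] = y
    return table


def simulate_cohort(spec: CohortSpec) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Full generator: pedigree -> founder freqs -> genotypes -> phenotypes."""
    pedigree = simulate_pedigree(spec)
    freqs = simulate_founder_frequencies(spec)
    genotypes = simulate_genotypes(pedigree, freqs, spec)
    samples = simulate_phenotypes(genotypes, pedigree, spec)
    return genotypes, samples
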