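import numpy as np
import pandas as pd
import pytest

from divergescan import CohortSpec, GenotypeMatrix, simulate_cohort


def make_genotypes(dosages, chrom="chr1", start=100, step=100, samples=None):
    """Hand-built GenotypeMatrix from a (samples x markers) array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    samples = samples or [f"s{i}" for i in range(n)]
    markers = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": [start + step * j for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        },
        index=pd.Index([f"m{j}" for j in range(m)], name="marker_id"),
    )
    return GenotypeMatrix(samples=samples, markers=markers, dosages=dosages)


def make_samples(genotypes, lines=None, traits=None):
    """Minimal sample table for a hand-built genotype matrix."""
    n = genotypes.n_samples
    lines = lines or ["selection"] * (n // 2) + ["control"] * (n - n // 2)
    df = pd.DataFrame(
        {
            "sample_id": genotypes.samples,
            "family_id": [f"F{i}" for i in range(n)],
            "line": lines,
            "cage_id": [f"C{i}" for i in range(n)],
            "role": ["offspring"] * n,
        }
    )
    if traits:
        for name, values in traits.items():
            df[name] = values
    return df


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-family, 400-marker cohort shared by read-only tests."""
    spec = CohortSpec(
        n_families=6, n_selection_families=4, offspring_per_family=6,
        n_markers=400, n_chromosomes=4, seed=1234,
    )
    genotypes, samples = simulate_cohort(spec)
    return spec, genotypes, samples


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the generator's default scale (25 families, 5k markers)."""
    spec = CohortSpec(seed=77)
    genotypes, samples = simulate_cohort(spec)
    return spec, genotypes, samples
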