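"""Shared builders for genotype fixtures.

All fixtures are generated programmatically; genotype rows use the panel
encoding 0/1/2 with -1 for missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohislands.panel import MISSING, GenotypePanel


def make_map(
    positions: np.ndarray | list[int], chrom: str = "1"
) -> pd.DataFrame:
    positions = np.asarray(positions)
    return pd.DataFrame(
        {
            "snp_id": [f"{chrom}_snp{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos_bp": positions,
            "a1": "A",
            "a2": "B",
        }
    )


def make_panel(
    genotypes: np.ndarray,
    positions: np.ndarray | list[int] | None = None,
    chroms: list[str] | None = None,
    breeds: list[str] | None = None,
    spacing: int = 5_000,
) -> GenotypePanel:
    """Panel from a raw genotype matrix; evenly spaced single-chromosome map by default."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if positions is None:
        positions = np.arange(1, m + 1) * spacing
    positions = np.asarray(positions)
    if chroms is None:
        chroms = ["1"] * m
    samples = [f"s{i:03d}" for i in range(n)]
    if breeds is None:
        breeds = ["X"] * n
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(m)],
            "chrom": chroms,
            "pos_bp": positions,
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypePanel(
        snps=snps,
        samples=samples,
        breed_of=dict(zip(samples, breeds)),
        genotypes=genotypes,
    )


def random_panel(
    rng: np.random.Generator,
    n_samples: int = 5,
    n_snps: int = 20,
    missing_rate: float = 0.1,
    n_chroms: int = 2,
) -> GenotypePanel:
    geno = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    geno[rng.random((n_samples, n_snps)) < missing_rate] = MISSING
    per = n_snps // n_chroms
    chroms = []
    positions = []
    for c in range(n_chroms):
        k = per if c < n_chroms - 1 else n_snps - per * (n_chroms - 1)
        chroms.extend([str(c + 1)] * k)
        positions.extend(np.sort(rng.choice(np.arange(1, 10**7), size=k, replace=False)))
    breeds = [f"b{int(i)}" for i in rng.integers(0, 3, size=n_samples)]
    return make_panel(geno, positions=positions, chroms=chroms, breeds=breeds)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
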