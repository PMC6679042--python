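"""Population stratification: pairwise identity-by-state and similarity PCA.

The genomic relationship used here is the mean identity by state (IBS): for
each pair of individuals, (number of shared alleles) / 2 averaged over the
SNPs genotyped in both. Principal components are extracted from the IBS
similarity matrix by the classical multidimensional-scaling construction:
double-centre G, eigendecompose, scale eigenvectors by the square roots of
the non-negative eigenvalues. Negative eigenvalues (possible after centring
a similarity matrix) are excluded from the variance normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .panel import MISSING, GenotypePanel


@dataclass
class IBSMatrix:
    samples: list[str]
    matrix: np.ndarray  # symmetric, entries in [0, 1]


@dataclass
class PCAResult:
    samples: list[str]
    coordinates: np.ndarray  # samples x k
    variance_fraction: np.ndarray  # length k, non-increasing


def ibs_matrix(panel: GenotypePanel) -> IBSMatrix:
    """Mean pairwise IBS over SNPs non-missing in both individuals.

    Per-SNP IBS between dosages a and b is 1 - |a - b| / 2 (1 for identical
    genotypes, 0.5 for one shared allele, 0 for opposite homozygotes). A
    pair with no jointly typed SNP is an error naming the pair.
    """
    if panel.n_samples < 2:
        raise ValidationError("IBS matrix needs at least 2 samples")
    g = panel.genotypes
    typed = g != MISSING
    # decompose |a-b| via dosage indicator matrices: N_ab = A_a @ A_b.T
    ind = [np.asarray(g == d, dtype=np.float64) for d in (0, 1, 2)]
    n_shared = typed.astype(np.float64) @ typed.astype(np.float64).T
    zero_pairs = np.argwhere(np.triu(n_shared == 0, k=1))
    if zero_pairs.size:
        i, j = zero_pairs[0]
        raise ValidationError(
            f"samples {panel.samples[int(i)]!r} and {panel.samples[int(j)]!r} "
            "share no non-missing SNP; IBS undefined"
        )
    abs_diff = np.zeros_like(n_shared)
    for a in range(3):
        for b in range(3):
            if a != b:
                abs_diff += abs(a - b) * (ind[a] @ ind[b].T)
    matrix = 1.0 - abs_diff / (2.0 * n_shared)
    matrix = (matrix + matrix.T) / 2.0
    return IBSMatrix(samples=list(panel.samples), matrix=matrix)


def pca_from_similarity(
    ibs: IBSMatrix | np.ndarray, k: int = 3, samples: list[str] | None = None
) -> PCAResult:
    """Principal components of a similarity matrix via double-centring.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); requesting more
    components than there are positive eigenvalues pads with zero-variance
    components. The sign of each component is fixed so its largest-magnitude
    loading is positive.
    """
    if isinstance(ibs, IBSMatrix):
        G = ibs.matrix
        samples = ibs.samples
    else:
        G = np.asarray(ibs, dtype=float)
        samples = samples or [f"s{i}" for i in range(G.shape[0])]
    if G.shape[0] != G.shape[1] or not np.allclose(G, G.T, atol=1e-10):
        raise ValidationError("similarity matrix must be symmetric")
    n = G.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = J @ G @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = np.clip(eigval, 0.0, None)
    total = positive.sum()
    coords = np.zeros((n, k))
    varfrac = np.zeros(k)
    for c in range(min(k, n)):
        if eigval[c] <= 1e-12 * max(total, 1.0):
            break  # remaining components are numerically zero
        v = eigvec[:, c]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, c] = v * np.sqrt(eigval[c])
        varfrac[c] = eigval[c] / total if total > 0 else 0.0
    return PCAResult(
        samples=list(samples), coordinates=coords, variance_fraction=varfrac
    )
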