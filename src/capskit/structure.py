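"""Sample identification: genotype dosage encoding, PCA, clustering.

Before marker discovery the samples themselves are verified: the genotype
matrix is encoded numerically (per site, the count of non-reference alleles
in each call, 0/1/2, with missing calls imputed by the site mean), reduced
by PCA, and the PC scores hierarchically clustered.  On two-species data
the first principal component separates the species.

PCA is computed as an SVD of the column-centered dosage matrix; columns are
not scaled to unit variance.  Component signs are fixed so each loading
vector's largest-magnitude entry is positive, making scores reproducible
across runs and sample orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .exceptions import ParameterError
from .matrix import MISSING, GenotypeMatrix


def encode_genotypes(matrix: GenotypeMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Samples x sites dosage matrix (count of non-reference alleles).

    "NN" is imputed with the site mean dosage; sites where every call is
    missing are dropped and their keys returned as the second element.
    """
    n_sites, n_samples = matrix.n_sites, matrix.n_samples
    dosage = np.empty((n_sites, n_samples), dtype=float)
    calls = matrix.calls.to_numpy()
    for i, site in enumerate(matrix.sites):
        ref = site.ref_allele
        for j in range(n_samples):
            g = calls[i, j]
            if g == MISSING:
                dosage[i, j] = np.nan
            else:
                dosage[i, j] = (g[0] != ref) + (g[1] != ref)

    dropped: list[str] = []
    keep_rows = []
    for i, site in enumerate(matrix.sites):
        row = dosage[i]
        mask = np.isnan(row)
        if mask.all():
            dropped.append(site.key)
            continue
        if mask.any():
            row[mask] = row[~mask].mean()
        keep_rows.append(i)

    encoded = pd.DataFrame(
        dosage[keep_rows].T,
        index=matrix.samples,
        columns=[matrix.sites[i].key for i in keep_rows],
    )
    return encoded, dropped


@dataclass
class PcaResult:
    """PC scores and explained-variance ratios for the samples."""

    scores: pd.DataFrame            # samples x components
    explained_variance_ratio: np.ndarray
    components: np.ndarray          # components x sites (loadings)
    n_components: int


def run_pca(encoded: pd.DataFrame, n_components: int = 7) -> PcaResult:
    """PCA of the dosage matrix via SVD of the centered data."""
    x = encoded.to_numpy(dtype=float)
    n, p = x.shape
    if not 1 <= n_components <= min(n, p):
        raise ParameterError(
            f"n_components must be in 1..{min(n, p)}, got {n_components}"
        )
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)

    # deterministic signs: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1

    total = float((s ** 2).sum())
    if total == 0.0:
        raise ParameterError("matrix has zero variance; PCA undefined")
    evr = (s[:n_components] ** 2) / total
    scores = u[:, :n_components] * s[:n_components]
    frame = pd.DataFrame(
        scores,
        index=encoded.index,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return PcaResult(
        scores=frame,
        explained_variance_ratio=evr,
        components=vt[:n_components],
        n_components=n_components,
    )


def cluster_samples(
    pca: PcaResult,
    labels: Mapping[str, str],
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[list[str], pd.DataFrame, np.ndarray]:
    """Agglomerative clustering of samples on their PC scores.

    Returns (leaf order, heatmap table, linkage matrix).  The heatmap table
    carries the species label and the PC scores, rows in dendrogram leaf
    order — everything needed to render the clustered-heatmap figure.
    """
    if pca.scores.shape[0] < 2:
        raise ParameterError("need at least two samples to cluster")
    z = hierarchy.linkage(pca.scores.to_numpy(), method=method, metric=metric)
    order = hierarchy.leaves_list(z)
    samples = list(pca.scores.index)
    leaf_order = [samples[i] for i in order]
    table = pca.scores.loc[leaf_order].copy()
    table.insert(0, "species", [labels[s] for s in leaf_order])
    return leaf_order, table, z
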