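"""Population-substructure screen: microsatellite recoding + PCA.

Multi-allelic microsatellites are recoded to n-1 biallelic indicator loci
(one count column per allele, omitting the most frequent), markers with
more than 20% missingness among the unrelated individuals are dropped, and
the indicator matrix is mean-imputed, centered, variance-scaled and fed to
principal component analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .pedio import MISSING, GenotypeMatrix, Pedigree, unrelated_individuals

MAX_MISSING = 0.2


def recode_microsatellites(gm: GenotypeMatrix, pedigrees: list[Pedigree],
                           unrelated: list[tuple[str, str]] | None = None,
                           max_missing: float = MAX_MISSING) -> pd.DataFrame:
    """Indicator matrix over unrelated individuals.

    Each marker with n observed alleles contributes n-1 columns named
    ``marker:allele`` holding the 0/1/2 count of that allele in the
    genotype (the most frequent allele is omitted); missing genotypes give
    NaN.  Markers whose missingness exceeds ``max_missing`` are excluded.
    """
    if unrelated is None:
        unrelated = unrelated_individuals(pedigrees)
    rows = [key for key in unrelated if key in gm._row]
    ridx = [gm._row[k] for k in rows]
    cols: dict[str, np.ndarray] = {}
    for marker in gm.markers:
        g = gm.data[ridx, gm._col[marker], :]
        typed = g[:, 0] != MISSING
        if len(rows) == 0 or (1.0 - typed.mean()) > max_missing:
            continue
        alleles, counts = np.unique(g[typed].reshape(-1), return_counts=True)
        if len(alleles) < 2:
            continue                      # monomorphic: 0 columns
        allele_cols = {
            int(a): np.where(typed,
                             (g[:, 0] == a).astype(float) + (g[:, 1] == a),
                             np.nan)
            for a in alleles}
        # omit the most frequent allele; count ties break on column content
        # (label-free, so recoding is invariant under allele relabeling)
        tied = alleles[counts == counts.max()]
        omit = max((tuple(np.nan_to_num(allele_cols[int(a)], nan=-1.0)),
                    int(a)) for a in tied)[1]
        for a in alleles:
            if int(a) != omit:
                cols[f"{marker}:{int(a)}"] = allele_cols[int(a)]
    return pd.DataFrame(cols, index=pd.MultiIndex.from_tuples(
        rows, names=["family_id", "person_id"]))


def pca(indicators: pd.DataFrame, k: int):
    """Top-k principal components of the processed indicator matrix.

    Columns are mean-imputed, centered and scaled to unit variance
    (zero-variance columns dropped).  Returns ``(scores, eigenvalues)``
    with scores indexed like the input and eigenvalues non-increasing;
    raises if ``k`` exceeds the matrix rank.
    """
    X = indicators.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu[None, :], X)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    X = X[:, sd > 0] / sd[sd > 0]
    rank = np.linalg.matrix_rank(X)
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    scores = pd.DataFrame(scores, index=indicators.index,
                          columns=[f"PC{i + 1}" for i in range(k)])
    return scores, model.explained_variance_


def total_variance(indicators: pd.DataFrame) -> float:
    """Total variance of the processed (imputed/scaled) matrix; equals the
    full eigenvalue sum."""
    X = indicators.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu[None, :], X)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    X = X[:, sd > 0] / sd[sd > 0]
    return float(X.var(axis=0, ddof=1).sum())
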