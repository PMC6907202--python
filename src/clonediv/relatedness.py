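"""Pairwise relatedness: KING-robust kinship, genotype PCA, dendrogram.

The KING-robust within-pair estimator of the kinship coefficient PHI uses
only heterozygote and opposite-homozygote counts,

    PHI(i, j) = (N_AaAa - 2 * N_AA,aa) / (N_Aa(i) + N_Aa(j)),

over the sites where both samples are genotyped.  It is 0.5 for a sample
against itself, ~0.25 for parent-offspring, and ~0 for unrelated pairs, and
it requires no allele-frequency estimates — which is what makes it usable
on a panel of near-identical clones, where a mother-clone pair differing
only by a handful of private somatic heterozygotes sits just below 0.5.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .variants import VariantTable, classify_variant_type

logger = logging.getLogger(__name__)

MISSING = -1


class KinshipUndefinedError(ValueError):
    """Neither sample of a pair has a heterozygous site over shared sites."""


def genotype_matrix(
    table: VariantTable,
    samples: Sequence[str] | None = None,
    *,
    passing_only: bool = True,
    complete_only: bool = True,
) -> pd.DataFrame:
    """Samples x sites dosage matrix from biallelic SNVs.

    Entries count non-reference alleles (0/1/2, -1 for missing); 1 means
    heterozygous.  Multi-allelic sites are excluded (dosage ill-defined;
    logged).  Returns a DataFrame with sample index and site-key columns.
    """
    samples = list(samples) if samples is not None else list(table.samples)
    cols: list[str] = []
    data: list[list[int]] = []
    n_multi = 0
    for rec in table.records:
        if passing_only and rec.filters is not None and not rec.is_pass:
            continue
        if len(rec.alts) != 1:
            n_multi += 1
            continue
        if classify_variant_type(rec.ref, rec.alts[0]) != "SNV":
            continue
        gts = [rec.genotypes.get(s) for s in samples]
        if complete_only and any(g is None for g in gts):
            continue
        col = [MISSING if g is None else int(g[0] > 0) + int(g[1] > 0)
               for g in gts]
        cols.append(f"{rec.contig}:{rec.pos}")
        data.append(col)
    if n_multi:
        logger.info("genotype_matrix: excluded %d multi-allelic sites", n_multi)
    arr = (np.array(data, dtype=np.int8).T if data
           else np.empty((len(samples), 0), dtype=np.int8))
    return pd.DataFrame(arr, index=samples, columns=cols)


def king_phi(gi: np.ndarray, gj: np.ndarray) -> float:
    """KING-robust kinship from two dosage vectors (0/1/2, -1 missing)."""
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    ok = (gi != MISSING) & (gj != MISSING)
    a, b = gi[ok], gj[ok]
    n_hethet = int(np.sum((a == 1) & (b == 1)))
    n_opp = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    n_het_i = int(np.sum(a == 1))
    n_het_j = int(np.sum(b == 1))
    denom = n_het_i + n_het_j
    if denom == 0:
        raise KinshipUndefinedError(
            "no heterozygous sites in either sample over shared sites")
    return (n_hethet - 2 * n_opp) / denom


def kinship_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric PHI matrix over all sample pairs (diagonal = self = 0.5).

    Pairs with an undefined estimate are reported NaN with a warning.
    """
    samples = list(matrix.index)
    if len(samples) < 2:
        raise ValueError("kinship matrix needs at least 2 samples")
    g = matrix.to_numpy()
    out = np.full((len(samples), len(samples)), np.nan)
    for i in range(len(samples)):
        for j in range(i, len(samples)):
            try:
                phi = king_phi(g[i], g[j])
            except KinshipUndefinedError:
                logger.warning("kinship undefined for pair (%s, %s)",
                               samples[i], samples[j])
                phi = np.nan
            out[i, j] = out[j, i] = phi
    return pd.DataFrame(out, index=samples, columns=samples)


def genotype_pca(
    matrix: pd.DataFrame,
    n_components: int = 2,
    exclude: Sequence[str] = (),
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of mean-centered (unscaled) dosages.

    Returns (coordinates indexed by sample, explained-variance fractions).
    ``exclude`` drops samples (e.g. the reference-derived sample) before
    the decomposition.
    """
    sub = matrix.drop(index=[s for s in exclude if s in matrix.index])
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 sites")
    x = sub.to_numpy(dtype=float)
    x[x == MISSING] = np.nan
    col_means = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_means, inds[1])
    if np.allclose(x.std(axis=0), 0):
        raise ValueError("degenerate decomposition: constant genotype matrix")
    n_components = min(n_components, sub.shape[0] - 1, sub.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x - x.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (pd.DataFrame(coords, index=sub.index, columns=cols),
            pca.explained_variance_ratio_)


def kinship_dendrogram(kin: pd.DataFrame) -> tuple[np.ndarray, str]:
    """Average-linkage clustering on d = 0.5 - PHI; Newick serialization.

    Negative distances (PHI > 0.5 by noise) clip to 0 with a warning.
    Returns (scipy linkage matrix, newick string with branch lengths equal
    to merge-height differences).
    """
    if kin.isna().any().any():
        raise ValueError("kinship matrix contains undefined pairs")
    d = 0.5 - kin.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    if (d < 0).any():
        logger.warning("clipping %d negative kinship distances to 0",
                       int((d < 0).sum()))
        d = np.clip(d, 0.0, None)
    d = (d + d.T) / 2
    z = linkage(squareform(d, checks=False), method="average")
    root = to_tree(z)
    labels = list(kin.index)

    def newick(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = newick(node.left)
        right = newick(node.right)
        bl_l = node.dist - node.left.dist
        bl_r = node.dist - node.right.dist
        return f"({left}:{bl_l:.6f},{right}:{bl_r:.6f})"

    return z, newick(root) + ";"


def simulate_hardy_weinberg_pair(
    n_sites: int, seed: int, maf_low: float = 0.05, maf_high: float = 0.5,
) -> pd.DataFrame:
    """Two independent diploid individuals drawn from shared allele
    frequencies — the unrelated-pair null for the kinship estimator."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=n_sites)
    g = rng.binomial(2, p, size=(2, n_sites)).astype(np.int8)
    return pd.DataFrame(g, index=["ind1", "ind2"],
                        columns=[f"s{i}" for i in range(n_sites)])
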