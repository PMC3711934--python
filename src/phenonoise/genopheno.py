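"""Genotype-phenotype structure: distances, similarities, and the gPC x pPC screen.

Genetic distance between two strains is the fraction of segregating sites
at which their boolean SNP profiles differ.  Phenotypic similarity is the
Pearson correlation of the two strains' coordinates along the first k
phenotypic principal components (k chosen to cover ~97% of variance,
default 28).  The headline statistic is the Spearman rank correlation
between the two quantities over all strain pairs (optionally restricted
to the clean-lineage subset, controlling for genome mosaicism).

The structure-level screen correlates every genotypic principal component
with every phenotypic one (Spearman, over strains) and calibrates the
significance of the largest observed |rho| with a permutation scheme that
shuffles strain identity in the phenotype matrix and recomputes the
phenotypic PCA each time (pPC orientation is data-dependent, so the
components must be re-derived under the null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io import GenotypeMatrix
from .morphospace import PcaResult, RankSumMatrix, _pca

__all__ = [
    "PairwiseDistanceSet",
    "GpcPpcScreen",
    "genetic_distance",
    "genotype_pca",
    "phenotype_similarity",
    "pairwise_set",
    "distance_similarity_correlation",
    "gpc_ppc_screen",
    "mantel_pvalue",
]


def genetic_distance(G: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise fraction of segregating sites differentiating each strain pair."""
    if len(G.strains) < 2:
        raise ValueError("need at least 2 strains")
    if G.n_sites == 0:
        raise ValueError("genotype matrix has no sites")
    D = squareform(pdist(G.sites.astype(float), metric="hamming"))
    return pd.DataFrame(D, index=G.strains, columns=G.strains)


def genotype_pca(G: GenotypeMatrix) -> PcaResult:
    """Centered, unscaled PCA of the boolean SNP matrix (gPCs)."""
    X = G.sites.astype(float)
    scores, loadings, sdev = _pca(X)
    var = sdev**2
    total = var.sum()
    if total <= 0:
        raise ValueError("constant genotype matrix")
    prop = var / total
    comp = [f"gPC{i + 1}" for i in range(len(sdev))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=pd.Index(G.strains, name="strain"), columns=comp),
        loadings=pd.DataFrame(loadings, columns=comp),
        sdev=sdev,
        proportions=prop,
        cumulative=np.cumsum(prop),
    )


def phenotype_similarity(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of strains' component-score vectors."""
    X = scores.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 components for a meaningful correlation")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = scores.index[np.nonzero(sd == 0)[0][0]]
        raise ValueError(f"constant score vector for strain {bad!r}")
    S = np.corrcoef(X)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=scores.index, columns=scores.index)


@dataclass
class PairwiseDistanceSet:
    """All C(n,2) strain pairs with genetic distance and phenotypic similarity."""

    pairs: pd.DataFrame  # columns strain_a, strain_b, genetic_distance, similarity

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def subset(self, strains) -> "PairwiseDistanceSet":
        keep = set(strains)
        mask = self.pairs["strain_a"].isin(keep) & self.pairs["strain_b"].isin(keep)
        return PairwiseDistanceSet(self.pairs[mask].reset_index(drop=True))


def pairwise_set(
    G: GenotypeMatrix, ppc_scores: pd.DataFrame, k: int = 28
) -> PairwiseDistanceSet:
    """Build the strain-pair table of genetic distance vs phenotypic similarity.

    ``ppc_scores`` are phenotypic PC scores indexed by strain; the first
    ``k`` components (at most) are used for the similarity.
    """
    if list(ppc_scores.index) != list(G.strains):
        ppc_scores = ppc_scores.loc[G.strains]
    use = ppc_scores.iloc[:, : min(k, ppc_scores.shape[1])]
    D = genetic_distance(G)
    S = phenotype_similarity(use)
    rows = []
    strains = G.strains
    for i in range(len(strains)):
        for j in range(i + 1, len(strains)):
            rows.append((strains[i], strains[j], D.iloc[i, j], S.iloc[i, j]))
    return PairwiseDistanceSet(
        pd.DataFrame(rows, columns=["strain_a", "strain_b", "genetic_distance", "similarity"])
    )


def distance_similarity_correlation(
    pairs: PairwiseDistanceSet, subset=None
) -> float:
    """Spearman rank correlation of phenotypic similarity vs genetic distance.

    ``subset`` restricts the pairs to those within the given strain set
    (e.g. the clean-lineage strains); at least 3 strains required.
    """
    ps = pairs if subset is None else pairs.subset(subset)
    strains = set(ps.pairs["strain_a"]) | set(ps.pairs["strain_b"])
    if len(strains) < 3:
        raise ValueError("need at least 3 strains for a pair-level correlation")
    rho = stats.spearmanr(ps.pairs["genetic_distance"], ps.pairs["similarity"]).statistic
    return float(rho)


def mantel_pvalue(
    pairs: PairwiseDistanceSet, B: int = 999, seed: int | None = None
) -> float:
    """Optional Mantel-style permutation p-value for the pair correlation.

    Strain labels of the similarity side are permuted jointly (rows and
    columns), respecting the non-independence of pairs.  Two-sided.
    """
    df = pairs.pairs
    strains = sorted(set(df["strain_a"]) | set(df["strain_b"]))
    idx = {s: i for i, s in enumerate(strains)}
    n = len(strains)
    D = np.zeros((n, n))
    S = np.zeros((n, n))
    for a, b, d, s in df[["strain_a", "strain_b", "genetic_distance", "similarity"]].itertuples(index=False):
        i, j = idx[a], idx[b]
        D[i, j] = D[j, i] = d
        S[i, j] = S[j, i] = s
    iu = np.triu_indices(n, 1)
    obs = stats.spearmanr(D[iu], S[iu]).statistic
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        perm = rng.permutation(n)
        Sp = S[np.ix_(perm, perm)]
        r = stats.spearmanr(D[iu], Sp[iu]).statistic
        if abs(r) >= abs(obs):
            hits += 1
    return (hits + 1) / (B + 1)


@dataclass
class GpcPpcScreen:
    """Spearman correlations between genotypic and phenotypic PCs."""

    correlations: pd.DataFrame  # gPCs x pPCs
    threshold: float | None  # smallest |rho| significant at target FDR
    target_fdr: float
    B: int
    min_rho: float
    max_rho: float
    significant: pd.DataFrame  # boolean gPCs x pPCs

    @property
    def any_significant(self) -> bool:
        return bool(self.significant.to_numpy().any())


def _spearman_cross(A: np.ndarray, Bm: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix between the columns of A and of B."""
    ra = stats.rankdata(A, axis=0)
    rb = stats.rankdata(Bm, axis=0)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    na = np.linalg.norm(ra, axis=0)
    nb = np.linalg.norm(rb, axis=0)
    na[na == 0] = np.nan
    nb[nb == 0] = np.nan
    return (ra.T @ rb) / np.outer(na, nb)


def gpc_ppc_screen(
    G: GenotypeMatrix,
    rs: RankSumMatrix,
    B: int = 1000,
    target_fdr: float = 0.05,
    seed: int | None = None,
) -> GpcPpcScreen:
    """Screen all gPC x pPC Spearman correlations at a permutation FDR.

    The null distribution permutes the strain rows of the rank-sum matrix
    relative to the genotypes and recomputes the phenotypic PCA per
    permutation.  Empirical FDR(t) = mean permuted count of |rho| >= t
    divided by the observed count; the threshold is the smallest observed
    |rho| with monotonised FDR <= target.
    """
    if list(rs.strains) != list(G.strains):
        if set(rs.strains) != set(G.strains):
            raise ValueError("strain sets of genotypes and rank-sum matrix differ")
        rs = RankSumMatrix(rs.values.loc[G.strains], rs.n_samples)
    gpc = genotype_pca(G).scores.to_numpy()
    values = rs.values.to_numpy(dtype=float)
    ppc, _, _ = _pca(values)
    obs = _spearman_cross(gpc, ppc)
    obs_abs = np.abs(obs[~np.isnan(obs)])

    rng = np.random.default_rng(seed)
    grid = np.sort(obs_abs)
    perm_exceed = np.zeros(grid.size)
    for _ in range(B):
        perm = rng.permutation(values.shape[0])
        ppc_b, _, _ = _pca(values[perm])
        rho = np.abs(_spearman_cross(gpc, ppc_b))
        rho = np.sort(rho[~np.isnan(rho)])
        perm_exceed += rho.size - np.searchsorted(rho, grid, side="left")
    perm_mean = perm_exceed / B
    obs_count = grid.size - np.searchsorted(grid, grid, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.minimum(np.nan_to_num(perm_mean / obs_count, nan=1.0), 1.0)
    fdr = np.minimum.accumulate(fdr)
    passing = np.nonzero(fdr <= target_fdr)[0]
    threshold = float(grid[passing[0]]) if passing.size else None

    gpc_names = [f"gPC{i + 1}" for i in range(obs.shape[0])]
    ppc_names = [f"pPC{i + 1}" for i in range(obs.shape[1])]
    corr = pd.DataFrame(obs, index=gpc_names, columns=ppc_names)
    sig = corr.abs() >= threshold if threshold is not None else corr.abs() > np.inf
    finite = corr.to_numpy()[np.isfinite(corr.to_numpy())]
    return GpcPpcScreen(
        correlations=corr,
        threshold=threshold,
        target_fdr=target_fdr,
        B=B,
        min_rho=float(finite.min()),
        max_rho=float(finite.max()),
        significant=sig.fillna(False) if hasattr(sig, "fillna") else sig,
        )
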