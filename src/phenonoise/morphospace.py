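"""Morphospace structure: rank-sum PCA, AU clustering, and LDA class profiles.

The 185 x 501 trait table is first made scale-free by the rank-sum
transform: per trait, all samples are ranked (midranks) and each strain is
assigned the sum of its replicate ranks, giving a strains x traits matrix
on which all multivariate analyses operate.

* :func:`pca_ranksum` - column-centered, unscaled PCA (R ``prcomp``
  convention); :func:`pc_chance_threshold` estimates, by independent
  column permutation, the largest variance share any component is
  expected to capture by chance, the retention rule for "real" components.
* :func:`angle_dissimilarity` - morphological dissimilarity between
  strains as the angle between their component-score vectors.
* :func:`au_cluster` - average-linkage hierarchical clustering with
  multiscale-bootstrap approximately-unbiased (AU) cluster support:
  parameter columns are resampled with replacement at several sizes
  round(p * r), the full transform (PCA -> scores -> angles -> tree) is
  recomputed per replicate, bootstrap proportions BP_r are converted to
  z-scores and extrapolated through z(sigma) = v * sigma + c / sigma with
  sigma = 1 / sqrt(r); AU = 1 - Phi(v - c).  Clusters with AU > 0.95 are
  flagged as supported.
* :func:`lda_classes` - characterises AU-supported strain classes by
  linear discriminant analysis in the p >> n regime (pseudo-inverse
  within-class scatter), selecting the parameters whose coefficient
  vectors fall inside each class's cone of strain projections
  (contribution angle below the class's largest strain angle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import TraitTable

__all__ = [
    "RankSumMatrix",
    "PcaResult",
    "ChancePca",
    "ClusterSupport",
    "AuDendrogram",
    "LdaClassModel",
    "ranksum_transform",
    "pca_ranksum",
    "pc_chance_threshold",
    "null_ranksum_matrix",
    "angle_dissimilarity",
    "au_cluster",
    "lda_classes",
]


@dataclass
class RankSumMatrix:
    """Strains x parameters matrix of summed within-trait replicate ranks."""

    values: pd.DataFrame  # index strains, columns param ids
    n_samples: int  # number of samples ranked (strains * replicates)

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_sum(self) -> int:
        """Every column sums to N(N+1)/2 (17,205 for N = 185)."""
        return self.n_samples * (self.n_samples + 1) // 2


def ranksum_transform(table: TraitTable) -> RankSumMatrix:
    """Per trait, midrank all samples and sum the ranks within each strain."""
    values = table.values.to_numpy(dtype=float)
    ranks = stats.rankdata(values, axis=0)
    codes = table.strain_codes()
    k = codes.max() + 1
    G = np.zeros((k, len(codes)))
    G[codes, np.arange(len(codes))] = 1.0
    rs = G @ ranks
    return RankSumMatrix(
        pd.DataFrame(rs, index=pd.Index(table.strain_order, name="strain"),
                     columns=table.values.columns),
        n_samples=values.shape[0],
    )


@dataclass
class PcaResult:
    """Column-centered, unscaled PCA (prcomp convention)."""

    scores: pd.DataFrame  # strains x components
    loadings: pd.DataFrame  # params x components (unit right singular vectors)
    sdev: np.ndarray
    proportions: np.ndarray  # variance shares, sum to 1
    cumulative: np.ndarray
    chance_threshold: float | None = None  # max chance per-component proportion

    @property
    def n_components(self) -> int:
        return len(self.sdev)

    def n_components_for(self, cumulative_variance: float, cap: int | None = None) -> int:
        """Smallest component count covering the given cumulative variance."""
        k = int(np.searchsorted(self.cumulative, cumulative_variance) + 1)
        k = min(k, self.n_components)
        return min(k, cap) if cap else k

    def n_above_chance(self) -> int:
        """Components whose variance share exceeds the chance threshold."""
        if self.chance_threshold is None:
            raise ValueError("no chance threshold attached; run pc_chance_threshold")
        return int((self.proportions > self.chance_threshold).sum())


def _pca(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered SVD; returns (scores, loadings, sdev)."""
    X = values - values.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(len(s)):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    n = X.shape[0]
    return U * s, Vt.T, s / np.sqrt(max(n - 1, 1))


def pca_ranksum(rs: RankSumMatrix) -> PcaResult:
    """PCA of the column-centered rank-sum matrix (scores, loadings, shares)."""
    values = rs.values.to_numpy(dtype=float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 strains and 2 parameters")
    scores, loadings, sdev = _pca(values)
    var = sdev**2
    total = var.sum()
    if total <= 0:
        raise ValueError("constant rank-sum matrix: variance proportions undefined")
    prop = var / total
    comp = [f"pPC{i + 1}" for i in range(len(sdev))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=rs.values.index, columns=comp),
        loadings=pd.DataFrame(loadings, index=rs.values.columns, columns=comp),
        sdev=sdev,
        proportions=prop,
        cumulative=np.cumsum(prop),
    )


def null_ranksum_matrix(
    n_strains: int, n_reps: int, n_params: int, rng: np.random.Generator
) -> np.ndarray:
    """Rank-sum matrix under the global null: per column, a random partition
    of the ranks 1..N (N = strains * reps) into strains groups of reps."""
    N = n_strains * n_reps
    ranks = np.arange(1.0, N + 1)
    out = np.empty((n_strains, n_params))
    for j in range(n_params):
        out[:, j] = rng.permutation(ranks).reshape(n_strains, n_reps).sum(axis=1)
    return out


@dataclass
class ChancePca:
    """Chance levels of per-component variance shares under column permutation."""

    expected_max: float  # mean over replicates of the largest share
    q95_max: float
    max_samples: np.ndarray
    B: int


def pc_chance_threshold(
    rs: RankSumMatrix | np.ndarray, B: int = 1000, seed: int | None = None
) -> ChancePca:
    """Permutation chance threshold for per-component variance proportions.

    Each replicate independently permutes every column of the rank-sum
    matrix across strains (destroying all inter-trait correlation), runs
    the centered PCA, and records the largest per-component variance
    share.  Reports the expected and 95th-percentile maximum share.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    values = rs.values.to_numpy(dtype=float) if isinstance(rs, RankSumMatrix) else np.asarray(rs, float)
    n, p = values.shape
    rng = np.random.default_rng(seed)
    maxes = np.empty(B)
    for b in range(B):
        perm = np.argsort(rng.random((n, p)), axis=0)
        X = np.take_along_axis(values, perm, axis=0)
        X = X - X.mean(axis=0)
        # variance shares from the eigenvalues of the small gram matrix
        eig = np.linalg.eigvalsh(X @ X.T)
        eig = np.clip(eig, 0.0, None)
        maxes[b] = eig[-1] / eig.sum() if p > 1 else 1.0
    return ChancePca(
        expected_max=float(maxes.mean()),
        q95_max=float(np.quantile(maxes, 0.95)),
        max_samples=maxes,
        B=B,
    )


def angle_dissimilarity(scores, centered: bool = False) -> pd.DataFrame:
    """Pairwise dissimilarity between strains as angles (radians).

    d(i, j) = arccos of the cosine similarity of the two strains'
    component-score vectors (uncentered by default; ``centered=True``
    subtracts each vector's own mean first, i.e. 1-to-1 with Pearson).
    """
    if isinstance(scores, pd.DataFrame):
        index, X = scores.index, scores.to_numpy(dtype=float)
    else:
        X = np.asarray(scores, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("scores must be a strains x k matrix with k >= 1")
    if centered:
        X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = index[np.nonzero(norms == 0)[0][0]]
        raise ValueError(f"zero-norm score vector for strain {bad!r}")
    C = (X @ X.T) / np.outer(norms, norms)
    D = np.arccos(np.clip(C, -1.0, 1.0))
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2  # enforce exact symmetry against rounding
    return pd.DataFrame(D, index=index, columns=index)


# ---------------------------------------------------------------------------
# multiscale bootstrap AU support


def _tree_clusters(Z: np.ndarray, n: int) -> list[frozenset[int]]:
    """Leaf-index sets of every internal node of a linkage matrix."""
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out: list[frozenset[int]] = []
    for i, (a, b, *_ ) in enumerate(Z):
        m = members[int(a)] | members[int(b)]
        members[n + i] = m
        out.append(m)
    return out


def _avg_linkage_clusters(D: np.ndarray) -> tuple[np.ndarray, list[frozenset[int]]]:
    Z = linkage(squareform(D, checks=False), method="average")
    return Z, _tree_clusters(Z, D.shape[0])


def fit_au(
    bp: np.ndarray, r_values: np.ndarray, B: int
) -> tuple[float, float, float, bool]:
    """Fit the multiscale model to bootstrap proportions at several scales.

    z_r = Phi^-1(1 - BP_r) is regressed on sigma = sqrt(r) through
    z(sigma) = v * sigma + c / sigma by weighted least squares with
    binomial (delta-method) weights B * phi(z)^2 / (BP (1 - BP)); scales
    with BP in {0, 1} are dropped.  Returns (v, c, AU, degenerate): AU =
    1 - Phi(v - c) (v is the signed distance, negative for supported
    clusters; c the boundary curvature), clamped to the boundary with a
    degenerate flag when fewer than two scales are usable.
    """
    bp = np.asarray(bp, dtype=float)
    r_values = np.asarray(r_values, dtype=float)
    ok = (bp > 0.0) & (bp < 1.0)
    if ok.sum() < 2:
        au = 1.0 if bp.mean() >= 0.5 else 0.0
        return np.nan, np.nan, au, True
    bpj, r = bp[ok], r_values[ok]
    z = stats.norm.ppf(1.0 - bpj)
    sigma = np.sqrt(r)
    X = np.column_stack([sigma, 1.0 / sigma])
    w = B * stats.norm.pdf(z) ** 2 / (bpj * (1.0 - bpj))
    Xw = X * w[:, None]
    beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ z, rcond=None)
    v, c = float(beta[0]), float(beta[1])
    au = float(1.0 - stats.norm.cdf(v - c))
    return v, c, au, False


@dataclass
class ClusterSupport:
    members: tuple[str, ...]
    bp: dict[float, float]  # scale r -> bootstrap proportion
    v: float
    c: float
    au: float
    degenerate: bool

    @property
    def significant(self) -> bool:
        return self.au > 0.95


@dataclass
class AuDendrogram:
    """Average-linkage tree with AU support per internal node."""

    linkage: np.ndarray
    strains: list[str]
    clusters: list[ClusterSupport]
    scales: np.ndarray
    B: int
    n_pcs: int

    def significant_clusters(self, threshold: float = 0.95) -> list[ClusterSupport]:
        return [c for c in self.clusters if c.au > threshold]

    def to_newick(self) -> str:
        """Newick string with AU values (3 decimals) as internal node labels."""
        n = len(self.strains)
        au = {frozenset(np.nonzero([s in c.members for s in self.strains])[0]): c.au
              for c in self.clusters}
        members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        labels: dict[int, str] = {i: self.strains[i] for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            node = n + i
            members[node] = members[a] | members[b]
            la = max(self.linkage[i, 2] - heights[a], 0.0)
            lb = max(self.linkage[i, 2] - heights[b], 0.0)
            sup = au.get(members[node], np.nan)
            tag = f"{sup:.3f}" if np.isfinite(sup) else ""
            labels[node] = f"({labels[a]}:{la:.6g},{labels[b]}:{lb:.6g}){tag}"
            heights[node] = h
        return labels[2 * n - 2] + ";"


def _score_transform(
    columns: np.ndarray, n_pcs: int, cheap: bool
) -> np.ndarray:
    """Columns -> strain score vectors used for angle distances."""
    if cheap:
        return columns
    X = columns - columns.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_pcs, len(s))
    return U[:, :k] * s[:k]


def au_cluster(
    rs: RankSumMatrix,
    scales: Sequence[float] | None = None,
    B: int = 1000,
    n_pcs: int | None = None,
    seed: int | None = None,
    *,
    cumulative_variance: float = 0.97,
    pc_cap: int = 28,
    cheap: bool = False,
) -> AuDendrogram:
    """Hierarchical clustering of strains with multiscale-bootstrap AU support.

    The reference tree is average linkage on the angle dissimilarity of
    the top ``n_pcs`` PCA scores (default: smallest count covering
    ``cumulative_variance``, capped at ``pc_cap``).  For each scale r, B
    resamples of round(p * r) parameter columns (with replacement) rerun
    the full transform; per reference cluster the bootstrap proportions
    across scales are extrapolated to the AU p-value.  ``cheap=True``
    skips the per-replicate PCA and measures angles on the raw resampled
    columns (fast mode for testing).
    """
    if scales is None:
        scales = np.round(np.arange(0.5, 1.401, 0.1), 10)
    scales = np.asarray(sorted(scales), dtype=float)
    if (scales <= 0).any() or (scales > 2).any():
        raise ValueError("scales must lie in (0, 2]")
    values = rs.values.to_numpy(dtype=float)
    n, p = values.shape
    if n_pcs is None:
        ref_pca = pca_ranksum(rs)
        n_pcs = ref_pca.n_components_for(cumulative_variance, cap=pc_cap)

    ref_scores = _score_transform(values, n_pcs, cheap)
    D = angle_dissimilarity(ref_scores).to_numpy()
    Z, ref_clusters = _avg_linkage_clusters(D)
    # root and singletons excluded from support assessment? keep all internal nodes
    counts = np.zeros((len(scales), len(ref_clusters)))
    ref_index = {c: i for i, c in enumerate(ref_clusters)}

    rng = np.random.default_rng(seed)
    for si, r in enumerate(scales):
        size = max(int(round(p * r)), 2)
        for _ in range(B):
            cols = rng.integers(0, p, size=size)
            scores = _score_transform(values[:, cols], n_pcs, cheap)
            norms = np.linalg.norm(scores, axis=1)
            if (norms == 0).any():
                continue  # degenerate resample; contributes absence
            Db = angle_dissimilarity(scores).to_numpy()
            _, clusters = _avg_linkage_clusters(Db)
            for c in clusters:
                i = ref_index.get(c)
                if i is not None:
                    counts[si, i] += 1
    bp = counts / B

    supports: list[ClusterSupport] = []
    strains = rs.strains
    for i, c in enumerate(ref_clusters):
        v, cc, au, degen = fit_au(bp[:, i], scales, B)
        supports.append(
            ClusterSupport(
                members=tuple(strains[j] for j in sorted(c)),
                bp={float(r): float(bp[si, i]) for si, r in enumerate(scales)},
                v=v,
                c=cc,
                au=au,
                degenerate=degen,
            )
        )
    return AuDendrogram(Z, strains, supports, scales, B, n_pcs)


# ---------------------------------------------------------------------------
# linear discriminant class characterisation


@dataclass
class LdaClassModel:
    """LDA characterisation of AU-supported strain classes."""

    classes: list[str]  # named classes (excluding "other")
    labels: pd.Series  # strain -> class label (incl. "other")
    selected_params: list[str]
    axes: pd.DataFrame  # params x LD axes (coefficients)
    projections: pd.DataFrame  # strains x LD axes
    centers: pd.DataFrame  # named classes x LD axes
    max_angles: pd.Series  # per named class, degrees
    contribution_angles: pd.DataFrame  # params x named classes, degrees
    discriminating: dict[str, list[str]]  # class -> params below max angle
    representative_scores: pd.DataFrame  # strains x named classes
    representative_correlations: pd.DataFrame  # params x named classes
    predicted: pd.Series  # resubstitution class of every strain

    @property
    def self_consistent(self) -> bool:
        """Resubstitution check: every class-labelled strain is predicted back
        into its own class (unclassified strains carry no label to match)."""
        named = self.labels[self.labels != "other"].index
        return bool((self.predicted[named] == self.labels[named]).all())


def _angles_deg(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angles (degrees) between the rows of A and the vector b."""
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(b)
    cos = (A @ b) / np.where(na * nb > 0, na * nb, np.nan)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def lda_classes(
    rs: RankSumMatrix,
    class_labels: Mapping[str, str],
    kw_pvalues: pd.Series | None = None,
    *,
    preselected: Sequence[str] | None = None,
    alpha: float = 0.01,
    n_axes: int = 3,
    svd_tol: float = 1e-8,
) -> LdaClassModel:
    """Characterise strain classes by high-dimensional LDA.

    Parameters are preselected by the Kruskal-Wallis strain-effect test at
    ``alpha`` after Bonferroni correction over all parameters (or passed
    explicitly).  Discriminant axes come from the pseudo-inverse (truncated
    SVD) of the within-class scatter, required in the p >> n regime.  Per
    class: the center vector is the mean member projection; a parameter
    discriminates the class when the contribution angle between its LD-space
    vector and the center is below the largest member-to-center angle; the
    representative score of each strain is its projection onto the center
    direction.  The parameter's LD-space vector is its structure vector
    (covariance with the LD coordinates across strains), the stable choice
    when parameters far outnumber strains.
    """
    labels = pd.Series({s: class_labels.get(s, "other") for s in rs.strains})
    named = sorted(set(labels) - {"other"})
    if len(named) < n_axes:
        raise ValueError(f"need >= {n_axes} named classes (plus 'other') for {n_axes} axes")
    for cls_name, size in labels.value_counts().items():
        if size < 2:
            raise ValueError(f"class {cls_name!r} has a single strain: max angle undefined")

    if preselected is None:
        if kw_pvalues is None:
            raise ValueError("provide kw_pvalues or an explicit preselected list")
        m = len(kw_pvalues)
        preselected = [p for p in rs.values.columns
                       if p in kw_pvalues.index and kw_pvalues[p] < alpha / m]
    preselected = list(preselected)
    if len(preselected) < n_axes:
        raise ValueError("fewer preselected parameters than discriminant axes")

    X = rs.values.loc[:, preselected].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    codes, uniq = pd.factorize(labels.loc[rs.strains])
    k = len(uniq)

    # within/between scatter
    Sw = np.zeros((X.shape[1], X.shape[1]))
    Sb = np.zeros_like(Sw)
    for g in range(k):
        Xg = X[codes == g]
        mg = Xg.mean(axis=0)
        Xc = Xg - mg
        Sw += Xc.T @ Xc
        Sb += len(Xg) * np.outer(mg, mg)

    # whiten within-class scatter by truncated SVD pseudo-inverse
    U, s, _ = np.linalg.svd(Sw, hermitian=True)
    keep = s > svd_tol * s[0]
    W = U[:, keep] / np.sqrt(s[keep])
    M = W.T @ Sb @ W
    eigval, eigvec = np.linalg.eigh(M)
    order = np.argsort(eigval)[::-1]
    rank = int((eigval[order] > svd_tol * max(eigval[order][0], 1.0)).sum())
    if rank < n_axes:
        raise ValueError(f"discriminant space has rank {rank} < {n_axes}")
    A = W @ eigvec[:, order[:n_axes]]  # params x n_axes coefficient matrix
    # deterministic sign per axis
    for j in range(n_axes):
        i = np.argmax(np.abs(A[:, j]))
        if A[i, j] < 0:
            A[:, j] *= -1

    proj = X @ A  # strains x n_axes
    axis_names = [f"LD{i + 1}" for i in range(n_axes)]
    projections = pd.DataFrame(proj, index=rs.values.index, columns=axis_names)

    centers = pd.DataFrame(
        [proj[labels.loc[rs.strains].to_numpy() == c].mean(axis=0) for c in named],
        index=named, columns=axis_names,
    )
    max_angles = pd.Series(
        {
            c: float(np.nanmax(_angles_deg(
                proj[labels.loc[rs.strains].to_numpy() == c], centers.loc[c].to_numpy()
            )))
            for c in named
        },
        name="max_angle_deg",
    )
    # parameter vectors in LD space: structure vectors (covariance of each
    # centered parameter with the LD coordinates).  These are the stable
    # representation of a parameter's direction when p >> n; raw weight rows
    # of A are noise-amplified by the pseudo-inverse whitening.
    struct = X.T @ (proj - proj.mean(axis=0))
    contrib = pd.DataFrame(
        {c: _angles_deg(struct, centers.loc[c].to_numpy()) for c in named},
        index=pd.Index(preselected, name="param_id"),
    )
    discriminating = {
        c: [p for p in preselected if contrib.loc[p, c] < max_angles[c]] for c in named
    }

    rep_scores = pd.DataFrame(index=rs.values.index, columns=named, dtype=float)
    rep_corr = pd.DataFrame(index=pd.Index(preselected, name="param_id"),
                            columns=named, dtype=float)
    for c in named:
        u = centers.loc[c].to_numpy()
        u = u / np.linalg.norm(u)
        scores_c = proj @ u
        rep_scores[c] = scores_c
        Xs = rs.values.loc[:, preselected].to_numpy(dtype=float)
        xc = Xs - Xs.mean(axis=0)
        sc = scores_c - scores_c.mean()
        denom = np.linalg.norm(xc, axis=0) * np.linalg.norm(sc)
        with np.errstate(invalid="ignore", divide="ignore"):
            rep_corr[c] = (xc.T @ sc) / np.where(denom > 0, denom, np.nan)

    # resubstitution prediction: nearest class mean (incl. "other") in LD space
    all_centers = np.stack([proj[codes == g].mean(axis=0) for g in range(k)])
    d2 = ((proj[:, None, :] - all_centers[None, :, :]) ** 2).sum(axis=2)
    predicted = pd.Series([uniq[j] for j in d2.argmin(axis=1)], index=rs.values.index)

    return LdaClassModel(
        classes=named,
        labels=labels.loc[rs.strains],
        selected_params=preselected,
        axes=pd.DataFrame(A, index=pd.Index(preselected, name="param_id"), columns=axis_names),
        projections=projections,
        centers=centers,
        max_angles=max_angles,
        contribution_angles=contrib,
        discriminating=discriminating,
        representative_scores=rep_scores,
        representative_correlations=rep_corr,
        predicted=predicted,
    )
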