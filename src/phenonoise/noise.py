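"""Mean-decoupled phenotypic-noise analysis.

Coefficients of variation estimate cell-to-cell variability but co-vary,
often nonlinearly, with the trait mean.  'Noise traits' remove this
dependency: for each mean/CV parameter pair, the CV is regressed on the
mean across all samples by LOWESS (locally weighted, tricube kernel,
smoother span 0.4, robustness iterations) and the noise value of a sample
is the residual (observed minus predicted CV).

Downstream: a Kruskal-Wallis strain-effect test per noise trait with
Bonferroni verdicts; the phenotypic potential (a sample's global-noise
summary: the mean of its top half of noise values over a non-redundant
medoid trait set); PAM medoid selection for that set; and a rank-sum PCA
of the significant noise traits with per-loading significance tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import ParameterCatalogue, TraitTable
from .morphospace import pc_chance_threshold, pca_ranksum, ranksum_transform
from .screen import kw_statistics

__all__ = [
    "NoiseTable",
    "PotentialResult",
    "NoiseLoadingTest",
    "lowess_decouple",
    "build_noise_table",
    "noise_strain_test",
    "select_medoids",
    "phenotypic_potential",
    "noise_pca_loadings",
]


def lowess_decouple(
    means: np.ndarray, cvs: np.ndarray, span: float = 0.4, iters: int = 3
) -> np.ndarray:
    """Residuals of a LOWESS regression of CV on mean (noise values).

    Locally weighted linear regression with tricube weights at smoother
    span ``span`` and ``iters`` robustness iterations; the residual is
    observed minus fitted CV at each sample's mean.
    """
    means = np.asarray(means, dtype=float)
    cvs = np.asarray(cvs, dtype=float)
    if means.shape != cvs.shape or means.ndim != 1:
        raise ValueError("means and cvs must be equal-length 1-d vectors")
    if means.size < 10:
        raise ValueError("need at least 10 samples for a LOWESS fit")
    if np.ptp(means) == 0:
        raise ValueError("degenerate mean vector (all equal): conditioning impossible")
    fitted = lowess(
        cvs, means, frac=span, it=iters, delta=0.0, return_sorted=False
    )
    return cvs - fitted


@dataclass
class NoiseTable:
    """Samples x noise-traits matrix of mean-decoupled CV residuals."""

    values: pd.DataFrame  # index sample ids, columns = CV parameter ids
    span: float
    iters: int
    mean_param: dict[str, str] = field(default_factory=dict)  # noise trait -> mean param

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def as_trait_table(self) -> TraitTable:
        from .io import TraitTable as TT

        return TT(self.values.copy(), {"noise_span": self.span})


def build_noise_table(
    table: TraitTable, meta: ParameterCatalogue, span: float = 0.4, iters: int = 3
) -> NoiseTable:
    """One noise trait per mean/CV pair: LOWESS residual of CV given mean."""
    cols: dict[str, np.ndarray] = {}
    pairing: dict[str, str] = {}
    for mean_id, cv_id in meta.pairs():
        if mean_id not in table.values.columns or cv_id not in table.values.columns:
            continue
        m = table.values[mean_id].to_numpy(dtype=float)
        v = table.values[cv_id].to_numpy(dtype=float)
        cols[cv_id] = lowess_decouple(m, v, span=span, iters=iters)
        pairing[cv_id] = mean_id
    if not cols:
        raise ValueError("no mean/CV pairs of the catalogue present in the table")
    return NoiseTable(
        pd.DataFrame(cols, index=table.values.index), span, iters, pairing
    )


def noise_strain_test(
    noise: NoiseTable, groups: Sequence | None = None, alphas: tuple[float, ...] = (0.05, 0.01)
) -> pd.DataFrame:
    """Kruskal-Wallis strain-effect test per noise trait with Bonferroni verdicts.

    ``groups`` defaults to the strain encoded in each sample id.  The
    Bonferroni family size is the number of noise traits (per-test
    threshold alpha/m, e.g. 0.05/220 = 2.27e-4).
    """
    if groups is None:
        groups = [s.rpartition(".")[0] for s in noise.sample_ids]
    codes, uniques = pd.factorize(np.asarray(groups))
    sizes = np.bincount(codes)
    if sizes.min() != sizes.max():
        raise ValueError("strain groups must be of equal size")
    K, p = kw_statistics(noise.values.to_numpy(dtype=float), codes)
    out = pd.DataFrame({"param_id": noise.values.columns, "K": K, "p": p})
    m = len(out)
    for a in alphas:
        out[f"significant_{a}"] = out["p"] < a / m
    return out


def _pam(D: np.ndarray, k: int, max_iter: int = 100) -> list[int]:
    """Deterministic PAM (build + swap) on a dissimilarity matrix."""
    n = D.shape[0]
    # BUILD: greedy total-dissimilarity minimisation, ties to lowest index
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dist_to_near = D[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, None
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(dist_to_near - D[:, j], 0.0).sum()
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    medoids = sorted(medoids)
    # SWAP: best-improvement until no swap lowers the total cost
    def cost(ms: list[int]) -> float:
        return D[:, ms].min(axis=1).sum()

    current = cost(medoids)
    for _ in range(max_iter):
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1:]
                delta = cost(trial) - current
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)
        current = cost(medoids)
    return medoids


def select_medoids(noise: NoiseTable, k: int = 70) -> list[str]:
    """Select a non-redundant medoid trait set by PAM clustering.

    Dissimilarity between two noise traits is 1 - |Spearman correlation|
    across samples; the k medoids summarise the trait space without
    redundant (highly correlated) members.  An externally supplied list
    can be used instead of this selection wherever a medoid list is
    accepted.
    """
    traits = list(noise.values.columns)
    if not 1 <= k <= len(traits):
        raise ValueError(f"k must be in 1..{len(traits)}")
    if k == len(traits):
        return traits
    R = stats.spearmanr(noise.values.to_numpy(dtype=float)).statistic
    R = np.atleast_2d(R)
    D = 1.0 - np.abs(R)
    np.fill_diagonal(D, 0.0)
    idx = _pam(D, k)
    return [traits[i] for i in idx]


@dataclass
class PotentialResult:
    """Per-sample phenotypic potential and its strain-effect test."""

    per_sample: pd.Series  # indexed by sample id
    per_strain: pd.DataFrame  # strain x replicate potentials
    medoids: list[str]
    top_count: int
    kw_K: float
    kw_p: float
    standardized: bool


def phenotypic_potential(
    noise: NoiseTable,
    medoids: Sequence[str],
    top_fraction: float = 0.5,
    standardized: bool = False,
) -> PotentialResult:
    """Global-noise summary per sample: mean of its highest noise values.

    The noise matrix is reduced to the medoid traits (e.g. 185 x 220 ->
    185 x 70) and each sample's potential is the mean of its top
    round(top_fraction * k) noise values (default: top 35 of 70).  Ties
    are broken by trait id for determinism.  ``standardized=True``
    z-scores each noise trait across samples before pooling (logged in
    the result).  A Kruskal-Wallis test assesses the strain effect on the
    five replicate potentials per strain.
    """
    medoids = list(medoids)
    if len(medoids) < 2:
        raise ValueError("need at least 2 medoid traits")
    missing = [m for m in medoids if m not in noise.values.columns]
    if missing:
        raise ValueError(f"medoid traits absent from noise table: {missing[:5]}")
    top = int(round(top_fraction * len(medoids)))
    if top < 1:
        raise ValueError("top count must be >= 1")
    # stable tie-break: order columns by trait id, then stable-sort values
    ordered = sorted(medoids)
    M = noise.values.loc[:, ordered].to_numpy(dtype=float)
    if standardized:
        M = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    part = np.sort(M, axis=1, kind="stable")[:, -top:]
    pot = part.mean(axis=1)
    per_sample = pd.Series(pot, index=noise.values.index, name="phenotypic_potential")

    strains = [s.rpartition(".")[0] for s in noise.sample_ids]
    reps = [s.rpartition(".")[2] for s in noise.sample_ids]
    per_strain = pd.DataFrame({"strain": strains, "replicate": reps, "potential": pot})
    per_strain = per_strain.pivot(index="strain", columns="replicate", values="potential")

    codes, _ = pd.factorize(np.asarray(strains))
    K, p = kw_statistics(pot[:, None], codes)
    return PotentialResult(
        per_sample=per_sample,
        per_strain=per_strain,
        medoids=ordered,
        top_count=top,
        kw_K=float(K[0]),
        kw_p=float(p[0]),
        standardized=standardized,
    )


@dataclass
class NoiseLoadingTest:
    """Noise-trait PCA with per-loading significance tests."""

    pca: object  # PcaResult of the noise rank-sum matrix
    n_retained: int
    loading_R: pd.DataFrame  # traits x retained nPCs, correlation scale
    T: pd.DataFrame
    pvalues: pd.DataFrame
    family_size: int  # retained nPCs x noise traits
    significant: pd.DataFrame
    alpha: float


def noise_pca_loadings(
    noise: NoiseTable,
    significant_traits: Sequence[str],
    alpha: float = 0.05,
    B: int = 1000,
    seed: int | None = None,
    n_retained: int | None = None,
) -> NoiseLoadingTest:
    """Rank-sum PCA of the significant noise traits with loading tests.

    The samples x significant-noise-traits matrix is rank-sum transformed
    (as for the trait morphospace) and decomposed by centered PCA.  nPCs
    are retained while their variance share exceeds the permutation
    chance threshold (or pass ``n_retained`` explicitly).  For each
    (retained nPC, trait) the loading is expressed as the correlation R
    between nPC scores and the trait's rank-sum column, tested with
    T = R * sqrt((n - 2) / (1 - R^2)) against the t distribution with
    n - 2 degrees of freedom, Bonferroni-corrected over the family of
    (retained nPCs x traits) combinations.
    """
    significant_traits = list(significant_traits)
    if not significant_traits:
        raise ValueError("significant_traits must be nonempty")
    sub = noise.as_trait_table().subset_params(significant_traits)
    rs = ranksum_transform(sub)
    pca = pca_ranksum(rs)
    if n_retained is None:
        chance = pc_chance_threshold(rs, B=B, seed=seed)
        pca.chance_threshold = chance.expected_max
        n_retained = max(pca.n_above_chance(), 1)
    n = rs.values.shape[0]

    scores = pca.scores.iloc[:, :n_retained].to_numpy()
    X = rs.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    denom = np.outer(np.linalg.norm(Xc, axis=0), np.linalg.norm(Sc, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc.T @ Sc) / np.where(denom > 0, denom, np.nan)
    R = np.clip(R, -1.0, 1.0)
    npc_names = list(pca.scores.columns[:n_retained])
    Rdf = pd.DataFrame(R, index=significant_traits, columns=npc_names)

    with np.errstate(divide="ignore", invalid="ignore"):
        T = R * np.sqrt((n - 2) / (1.0 - R**2))
    boundary = np.isclose(np.abs(R), 1.0)
    T = np.where(boundary, np.inf * np.sign(R), T)
    p = 2.0 * stats.t.sf(np.abs(T), df=n - 2)
    p = np.where(boundary, 0.0, p)

    family = n_retained * len(significant_traits)
    sig = p < alpha / family
    return NoiseLoadingTest(
        pca=pca,
        n_retained=n_retained,
        loading_R=Rdf,
        T=pd.DataFrame(T, index=significant_traits, columns=npc_names),
        pvalues=pd.DataFrame(p, index=significant_traits, columns=npc_names),
        family_size=family,
        significant=pd.DataFrame(sig, index=significant_traits, columns=npc_names),
        alpha=alpha,
    )
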