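"""Kruskal-Wallis strain-effect screening with a permutation-calibrated FDR.

Every trait is tested against the null hypothesis of no strain effect with
a (tie-corrected) Kruskal-Wallis rank-sum test.  Because hundreds of
traits are screened at once, significance is calibrated empirically: the
whole screen is re-run on B permuted datasets (each trait's values
re-attributed to strains at random), and for any statistic threshold t the
empirical false discovery rate is

    FDR(t) = mean permuted count of traits with K >= t  /  observed count.

The selected threshold K* is the smallest observed statistic whose
(monotonised) FDR is at or below the target.

The module also provides the ecological/geographical origin-association
test: replicate values are averaged per strain and a Kruskal-Wallis test
across origin classes is applied per trait, with a Bonferroni verdict over
the full parameter family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import StrainAnnotation, TraitTable

__all__ = [
    "KWResult",
    "FdrCalibration",
    "OriginAssociation",
    "kruskal_wallis",
    "kw_statistics",
    "permutation_fdr",
    "origin_association",
]


@dataclass(frozen=True)
class KWResult:
    param_id: str
    K: float
    df: int
    p: float


def _group_onehot(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-hot (k, N) indicator and group sizes from integer labels."""
    k = int(codes.max()) + 1
    G = np.zeros((k, codes.size))
    G[codes, np.arange(codes.size)] = 1.0
    return G, G.sum(axis=1)


def _tie_correction(values: np.ndarray) -> np.ndarray:
    """Per-column tie correction factor 1 - sum(t^3 - t) / (N^3 - N)."""
    v = np.sort(values, axis=0)
    N = v.shape[0]
    corr = np.ones(v.shape[1])
    for j in range(v.shape[1]):
        _, counts = np.unique(v[:, j], return_counts=True)
        t = counts[counts > 1]
        if t.size:
            corr[j] = 1.0 - (t**3 - t).sum() / (N**3 - N)
    return corr


def kw_statistics(
    values: np.ndarray, codes: np.ndarray, *, ranks: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Kruskal-Wallis over the columns of ``values``.

    ``codes`` are integer group labels per row.  Uses midranks and the
    standard tie correction.  Returns (K, p) vectors; a column with all
    values tied gets K = 0, p = 1.  Precomputed ``ranks`` may be supplied
    (they must be midranks of ``values`` along axis 0).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    N = values.shape[0]
    G, sizes = _group_onehot(codes)
    if (sizes == 0).any():
        raise ValueError("every group must have at least one observation")
    if ranks is None:
        ranks = stats.rankdata(values, axis=0)
    R = G @ ranks  # (k, P) group rank sums
    H = 12.0 / (N * (N + 1)) * ((R**2) / sizes[:, None]).sum(axis=0) - 3.0 * (N + 1)
    corr = _tie_correction(values)
    K = np.where(corr > 0, H / np.where(corr > 0, corr, 1.0), 0.0)
    K = np.maximum(K, 0.0)  # guard tiny negative rounding
    df = G.shape[0] - 1
    p = stats.chi2.sf(K, df)
    p = np.where(corr > 0, p, 1.0)
    return K, p


def kruskal_wallis(values, groups, param_id: str = "") -> KWResult:
    """Tie-corrected Kruskal-Wallis test of ``values`` across ``groups``.

    ``groups`` may be any label sequence; with all values tied the
    convention K = 0, p = 1 applies.
    """
    values = np.asarray(values, dtype=float)
    codes, uniques = pd.factorize(np.asarray(groups))
    if len(uniques) < 2:
        raise ValueError("need at least 2 groups")
    if values.size < len(uniques):
        raise ValueError("need at least as many observations as groups")
    K, p = kw_statistics(values[:, None], codes)
    return KWResult(param_id, float(K[0]), len(uniques) - 1, float(p[0]))


@dataclass
class FdrCalibration:
    """Empirical-FDR calibration curve of a permutation screen."""

    thresholds: np.ndarray  # ascending grid (the sorted observed K values)
    observed_count: np.ndarray  # of traits with K >= t
    mean_permuted_count: np.ndarray
    fdr_raw: np.ndarray
    fdr: np.ndarray  # monotone (nonincreasing in t) adjustment
    B: int
    target_fdr: float
    k_star: float | None
    results: pd.DataFrame = field(repr=False)  # param_id, K, p, significant
    status: str = "ok"

    @property
    def n_significant(self) -> int:
        return int(self.results["significant"].sum())


def permutation_fdr(
    table: TraitTable,
    B: int = 1000,
    target_fdr: float = 0.01,
    seed: int | None = None,
) -> FdrCalibration:
    """Strain-effect screen with permutation-calibrated empirical FDR.

    Runs the Kruskal-Wallis screen on the observed table and on *B*
    permuted datasets (per trait, values re-attributed to strains at
    random).  The threshold grid is the set of observed K values; K* is
    the smallest threshold with monotonised FDR <= ``target_fdr``.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a usable calibration")
    codes = table.strain_codes()
    values = table.values.to_numpy(dtype=float)
    N, P = values.shape
    K_obs, p_obs = kw_statistics(values, codes)

    # permuting a column permutes its ranks; rank once, shuffle rank rows
    ranks = stats.rankdata(values, axis=0)
    corr = _tie_correction(values)
    G, sizes = _group_onehot(codes)
    rng = np.random.default_rng(seed)
    perm_K = np.empty((B, P))
    scale = 12.0 / (N * (N + 1))
    for b in range(B):
        perm = np.argsort(rng.random((N, P)), axis=0)
        pr = np.take_along_axis(ranks, perm, axis=0)
        R = G @ pr
        H = scale * ((R**2) / sizes[:, None]).sum(axis=0) - 3.0 * (N + 1)
        perm_K[b] = np.where(corr > 0, H / np.where(corr > 0, corr, 1.0), 0.0)

    grid = np.sort(K_obs)
    obs_count = P - np.searchsorted(grid, grid, side="left")  # #{K_obs >= t}
    flat = np.sort(perm_K.ravel())
    perm_count = (flat.size - np.searchsorted(flat, grid, side="left")) / B
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_raw = np.where(obs_count > 0, perm_count / obs_count, np.nan)
    fdr_raw = np.minimum(np.nan_to_num(fdr_raw, nan=1.0), 1.0)
    fdr = np.minimum.accumulate(fdr_raw)  # nonincreasing in t

    passing = np.nonzero(fdr <= target_fdr)[0]
    status = "ok"
    if passing.size and obs_count[passing[0]] > 0:
        k_star = float(grid[passing[0]])
        significant = K_obs >= k_star
    else:
        k_star, significant = None, np.zeros(P, dtype=bool)
        status = "no-threshold-achieves-target-fdr"

    results = pd.DataFrame(
        {"param_id": table.param_ids, "K": K_obs, "p": p_obs, "significant": significant}
    )
    return FdrCalibration(
        thresholds=grid,
        observed_count=obs_count,
        mean_permuted_count=perm_count,
        fdr_raw=fdr_raw,
        fdr=fdr,
        B=B,
        target_fdr=target_fdr,
        k_star=k_star,
        results=results,
        status=status,
    )


def expected_null_exceedances(
    threshold: float = 56.0,
    n_strains: int = 37,
    n_reps: int = 5,
    n_traits: int = 501,
    n_draws: int = 200_000,
    seed: int | None = None,
    chunk: int = 20_000,
) -> float:
    """Expected count of traits exceeding a K threshold under the global null.

    Monte-Carlo over random re-attributions of a continuous trait's values
    to strains: the ranks 1..N (N = strains * reps) are partitioned at
    random into equal groups and the exact tie-free Kruskal-Wallis
    statistic computed per draw.  Returns n_traits * P(K > threshold), the
    mean number of null traits per permuted screen that clear the
    threshold (strict inequality).
    """
    N = n_strains * n_reps
    scale = 12.0 / (N * (N + 1))
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        ranks = np.argsort(rng.random((b, N)), axis=1) + 1.0
        R = ranks.reshape(b, n_strains, n_reps).sum(axis=2)
        K = scale * (R**2 / n_reps).sum(axis=1) - 3.0 * (N + 1)
        hits += int((K > threshold).sum())
        done += b
    return n_traits * hits / n_draws


@dataclass
class OriginAssociation:
    factor: str
    pvalues: pd.Series  # per trait
    min_p: float
    bonferroni_alpha: float
    significant: bool  # min_p < alpha / n_traits


def origin_association(
    table: TraitTable,
    annot: StrainAnnotation,
    factor: str,
    alpha: float = 0.05,
) -> OriginAssociation:
    """Test each trait for association with ecological/geographical origin.

    Replicates are averaged per strain (one value per strain per trait),
    then a Kruskal-Wallis test across the factor's classes is applied.
    The verdict is Bonferroni-corrected over the number of traits.
    """
    annot.check_covers(table.strain_order)
    means = table.values.groupby(pd.Index(table.strains, name="strain"), sort=False).mean()
    labels = annot.factor(factor).reindex(means.index)
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    level_sizes = np.bincount(codes)
    if (level_sizes < 2).any():
        small = [uniques[i] for i in np.nonzero(level_sizes < 2)[0]]
        raise ValueError(f"factor levels with fewer than 2 strains: {small}")
    _, p = kw_statistics(means.to_numpy(dtype=float), codes)
    pvalues = pd.Series(p, index=means.columns, name=f"p_{factor}")
    min_p = float(pvalues.min())
    return OriginAssociation(
        factor=factor,
        pvalues=pvalues,
        min_p=min_p,
        bonferroni_alpha=alpha,
        significant=min_p < alpha / len(pvalues),
    )
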