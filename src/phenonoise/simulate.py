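"""Synthetic single-cell phenome generator with planted, recorded ground truth.

Emulates the study design of a wild-yeast morphological survey: 37 strains
x 5 replicate cultures x >=200 cells, summarised into 501 CalMorph-style
parameters (220 trait means + 220 paired CVs + 61 sample-level
proportions).  Cell-level trait values are lognormal, which makes the
coefficient of variation controllable independently of the mean: for a
target mean m and CV v the log-scale parameters are
``sigma^2 = log(1 + v^2)`` and ``mu = log(m) - sigma^2/2``.

Planted effects, all recorded in :class:`GroundTruth`:

* strain-specific trait means (a fraction of traits receive per-strain
  log-mean offsets),
* trait-specific noise effects (for a fraction of traits, a few strains
  get their baseline CV multiplied by a fold >= 1),
* global noise multipliers (a few strains get every trait's CV inflated),
* a subpopulation-structured boolean SNP matrix (Balding-Nichols style
  divergence, with a configurable fraction of mosaic strains),
* ecology/geography labels drawn independently of phenotype, so the
  origin-association test has a true null by default.

The baseline noise-mean dependency ``cv0(m) = a + b * m**g`` reproduces
both decreasing (g = -1) and increasing (g = +1) CV-vs-mean trends.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd

from .io import (
    STAGES,
    CellTable,
    GenotypeMatrix,
    Parameter,
    ParameterCatalogue,
    StrainAnnotation,
    TraitTable,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedDataset",
    "build_catalogue",
    "generate",
    "null_permutation_dataset",
]

_STAGE_SUFFIX = {"G1": "_A", "S/G2": "_A1B", "M": "_C"}

ECOLOGY_CLASSES = ("wine", "fruit", "oak", "clinical", "fermentation", "soil", "lab")
GEOGRAPHY_CLASSES = ("Europe", "N_America", "Asia", "Africa", "S_America")


@dataclass(frozen=True)
class SimConfig:
    """Study-design and effect-size parameters for :func:`generate`."""

    n_strains: int = 37
    n_reps: int = 5
    n_cells: int = 200
    n_base_traits: int = 220  # mean/CV pairs; catalogue size = 2*base + n_other
    n_other: int = 61
    stage_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)  # G1, S/G2, M

    # strain effects on trait means
    frac_strain_effect_traits: float = 0.5
    strain_mean_sd: float = 0.5  # log-scale offset sd, in units of cell-level log-sd

    # baseline noise-mean dependency cv0(m) = a + b * m**g
    cv0_a: float = 0.1
    cv0_b: float = 2.0
    cv0_g: float = -1.0

    # trait-specific strain noise effects
    frac_noise_traits: float = 0.3
    n_noise_strains_per_trait: int = 3
    noise_effect_fold: float = 2.0

    # strain-level global noise
    n_global_noisy_strains: int = 3
    global_noise_fold: float = 1.5

    # correlated trait blocks (shared latent factor per block, per cell)
    block_size: int = 10
    block_rho: float = 0.5

    # trait mean range (log-uniform draw)
    mean_low: float = 5.0
    mean_high: float = 100.0

    # genotypes
    n_sites: int = 101_343
    n_subpopulations: int = 5
    divergence_f: float = 0.2  # F-like Balding-Nichols divergence
    mosaic_fraction: float = 0.57

    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_strain_effect_traits", "frac_noise_traits", "mosaic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for name in ("noise_effect_fold", "global_noise_fold"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9 or min(self.stage_probs) <= 0:
            raise ValueError("stage_probs must be positive and sum to 1")
        m = np.geomspace(self.mean_low, self.mean_high, 64)
        if (self.cv0(m) <= 0).any():
            raise ValueError("cv0(m) must be positive on the simulated mean range")

    def cv0(self, m: np.ndarray | float) -> np.ndarray:
        """Baseline CV as a function of the trait mean."""
        return self.cv0_a + self.cv0_b * np.asarray(m, dtype=float) ** self.cv0_g

    @classmethod
    def null(cls, **overrides) -> "SimConfig":
        """A configuration with no planted effects of any kind."""
        base = dict(
            frac_strain_effect_traits=0.0,
            strain_mean_sd=0.0,
            frac_noise_traits=0.0,
            noise_effect_fold=1.0,
            n_global_noisy_strains=0,
            global_noise_fold=1.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Planted effects of one simulated dataset, for recovery testing."""

    strain_effect_traits: list[str]  # mean param ids with planted strain effects
    mean_offsets: dict[str, dict[str, float]]  # trait -> strain -> log-mean offset
    noise_traits: dict[str, dict[str, float]]  # cv param id -> strain -> CV fold
    global_noisy_strains: list[str]
    subpopulation: dict[str, int]
    mosaic: dict[str, bool]
    ecology: dict[str, str]
    geography: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))

    @property
    def noise_trait_ids(self) -> list[str]:
        return list(self.noise_traits)


@dataclass
class SimulatedDataset:
    cells: CellTable
    genotypes: GenotypeMatrix
    annotations: StrainAnnotation
    truth: GroundTruth
    catalogue: ParameterCatalogue

    def __iter__(self):  # allow 4-tuple unpacking (cells, genotypes, annotations, truth)
        return iter((self.cells, self.genotypes, self.annotations, self.truth))


def build_catalogue(config: SimConfig | None = None) -> ParameterCatalogue:
    """Parameter catalogue matching the generator's naming scheme.

    Mean parameters ``C{i}{suffix}`` pair with CV parameters
    ``CCV{i}{suffix}``; 'other' parameters are the three stage fractions
    ``FRAC_*`` plus boolean-feature proportions ``B{i}{suffix}``.
    Defaults yield the full 220 + 220 + 61 = 501 catalogue.
    """
    cfg = config or SimConfig()
    params: list[Parameter] = []
    for i in range(cfg.n_base_traits):
        stage = STAGES[i % 3]
        suf = _STAGE_SUFFIX[stage]
        mean_id, cv_id = f"C{i + 101}{suf}", f"CCV{i + 101}{suf}"
        params.append(Parameter(mean_id, "mean", cv_id, stage, f"trait {i} mean"))
        params.append(Parameter(cv_id, "cv", mean_id, stage, f"trait {i} CV"))
    n_other = cfg.n_other
    for stage in STAGES[: min(3, n_other)]:
        params.append(
            Parameter(f"FRAC{_STAGE_SUFFIX[stage]}", "other", "", stage, f"fraction of cells at {stage}")
        )
    for i in range(max(0, n_other - 3)):
        stage = STAGES[i % 3]
        params.append(
            Parameter(f"B{i + 1}{_STAGE_SUFFIX[stage]}", "other", "", stage, f"feature {i} proportion")
        )
    return ParameterCatalogue(params)


def _simulate_genotypes(
    cfg: SimConfig, strains: list[str], rng: np.random.Generator
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Balding-Nichols style subpopulation structure with mosaic strains."""
    n, S, K = cfg.n_strains, cfg.n_sites, cfg.n_subpopulations
    subpop = rng.permutation(np.arange(n) % K)
    mosaic = np.zeros(n, dtype=bool)
    n_mosaic = int(round(cfg.mosaic_fraction * n))
    mosaic[rng.choice(n, size=n_mosaic, replace=False)] = True

    p_anc = rng.uniform(0.05, 0.95, size=S)
    F = cfg.divergence_f
    if F > 0:
        a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
        p_sub = rng.beta(a, b, size=(K, S))
    else:
        p_sub = np.broadcast_to(p_anc, (K, S)).copy()

    geno = np.empty((n, S), dtype=np.uint8)
    for i in range(n):
        if mosaic[i]:
            donors = rng.integers(0, K, size=S)  # per-site ancestry mixing
            freqs = p_sub[donors, np.arange(S)]
        else:
            freqs = p_sub[subpop[i]]
        geno[i] = rng.random(S) < freqs
    return GenotypeMatrix(strains, geno), subpop, mosaic


def generate(config: SimConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """Simulate a full per-cell phenome dataset with planted ground truth.

    Deterministic given the configuration: the same config (and *seed*,
    which overrides ``config.seed`` when given) yields byte-identical
    outputs.  Per-strain RNG sub-streams are derived from the dataset
    seed, so single strains can be regenerated in isolation.
    """
    cfg = config or SimConfig()
    cfg.validate()
    use_seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(use_seed)
    rng = np.random.default_rng(ss)

    n, T = cfg.n_strains, cfg.n_base_traits
    strains = [f"W{i + 1:02d}" for i in range(n)]
    cat = build_catalogue(cfg)
    mean_ids = [p.param_id for p in cat.of_kind("mean")]
    cv_ids = [cat[m].partner_id for m in mean_ids]
    trait_stage = np.array([STAGES.index(cat[m].stage) for m in mean_ids])

    # baseline trait means and log-scale sds
    base_mean = np.exp(rng.uniform(np.log(cfg.mean_low), np.log(cfg.mean_high), size=T))
    base_logsd = np.sqrt(np.log1p(cfg.cv0(base_mean) ** 2))

    # planted strain effects on means
    n_eff = int(round(cfg.frac_strain_effect_traits * T))
    eff_idx = np.sort(rng.choice(T, size=n_eff, replace=False))
    offsets = np.zeros((n, T))
    if n_eff and cfg.strain_mean_sd > 0:
        offsets[:, eff_idx] = rng.normal(
            0.0, cfg.strain_mean_sd * base_logsd[eff_idx], size=(n, n_eff)
        )

    # planted noise effects
    n_noise = int(round(cfg.frac_noise_traits * T))
    noise_idx = np.sort(rng.choice(T, size=n_noise, replace=False))
    cv_fold = np.ones((n, T))
    noise_truth: dict[str, dict[str, float]] = {}
    for j in noise_idx:
        hit = rng.choice(n, size=min(cfg.n_noise_strains_per_trait, n), replace=False)
        cv_fold[hit, j] *= cfg.noise_effect_fold
        noise_truth[cv_ids[j]] = {strains[s]: cfg.noise_effect_fold for s in hit}

    global_idx = rng.choice(n, size=min(cfg.n_global_noisy_strains, n), replace=False)
    global_fold = np.ones(n)
    global_fold[global_idx] = cfg.global_noise_fold

    # per-(strain, trait) realised mean and CV
    m_st = base_mean[None, :] * np.exp(offsets)  # (n, T)
    cv_st = cfg.cv0(m_st) * cv_fold * global_fold[:, None]
    sigma_st = np.sqrt(np.log1p(cv_st**2))
    mu_st = np.log(m_st) - sigma_st**2 / 2

    # correlated blocks: traits share a per-cell latent factor within a block
    n_blocks = int(np.ceil(T / cfg.block_size))
    block_of = np.arange(T) // cfg.block_size
    rho = cfg.block_rho

    # boolean cell features feeding the 'other' parameters
    # feature probabilities are strain-independent (no planted signal there)
    feat_params = [p for p in cat.of_kind("other") if not p.param_id.startswith("FRAC")]
    feat_base = rng.uniform(0.1, 0.5, size=len(feat_params))
    feat_p = np.broadcast_to(feat_base, (n, len(feat_params)))

    strain_streams = ss.spawn(n)
    frames: list[pd.DataFrame] = []
    for i, strain in enumerate(strains):
        srng = np.random.default_rng(strain_streams[i])
        for rep in range(1, cfg.n_reps + 1):
            nc = cfg.n_cells
            stages = srng.choice(3, size=nc, p=cfg.stage_probs)
            z_block = srng.standard_normal((nc, n_blocks))
            eps = srng.standard_normal((nc, T))
            mix = np.sqrt(rho) * z_block[:, block_of] + np.sqrt(1 - rho) * eps
            logx = mu_st[i][None, :] + sigma_st[i][None, :] * mix
            values = np.exp(logx)
            feats = (srng.random((nc, len(feat_params))) < feat_p[i][None, :]).astype(np.int8)
            frame = pd.DataFrame(values, columns=mean_ids)
            frame.insert(0, "strain", strain)
            frame.insert(1, "replicate", rep)
            frame.insert(2, "stage", [STAGES[s] for s in stages])
            for k, p in enumerate(feat_params):
                frame[p.param_id] = feats[:, k]
            frames.append(frame)
    cells = CellTable(pd.concat(frames, ignore_index=True))

    genotypes, subpop, mosaic = _simulate_genotypes(cfg, strains, rng)

    # labels independent of phenotype; every used class gets >= 2 strains so
    # the origin-association test's preconditions hold by construction
    def _labels(classes: tuple[str, ...]) -> dict[str, str]:
        k = min(len(classes), max(2, n // 3))
        pool = [classes[i % k] for i in range(n)]
        rng.shuffle(pool)
        return dict(zip(strains, pool))

    ecology = _labels(ECOLOGY_CLASSES)
    geography = _labels(GEOGRAPHY_CLASSES)
    annot = StrainAnnotation(
        pd.DataFrame(
            {
                "ecology_class": [ecology[s] for s in strains],
                "geography_class": [geography[s] for s in strains],
                "clean_lineage": [not m for m in mosaic],
            },
            index=pd.Index(strains, name="strain_id"),
        )
    )

    truth = GroundTruth(
        strain_effect_traits=[mean_ids[j] for j in eff_idx],
        mean_offsets={
            mean_ids[j]: {strains[i]: float(offsets[i, j]) for i in range(n)}
            for j in eff_idx
        },
        noise_traits=noise_truth,
        global_noisy_strains=[strains[i] for i in sorted(global_idx)],
        subpopulation={strains[i]: int(subpop[i]) for i in range(n)},
        mosaic={strains[i]: bool(mosaic[i]) for i in range(n)},
        ecology=ecology,
        geography=geography,
    )
    return SimulatedDataset(cells, genotypes, annot, truth, cat)


def null_permutation_dataset(table: TraitTable, seed: int | None = None) -> TraitTable:
    """Destroy strain structure: permute each parameter's values across samples.

    Per parameter, the sample values are independently re-attributed to
    samples (marginals preserved exactly); the paper-style permutation
    null for the strain-effect screen.
    """
    rng = np.random.default_rng(seed)
    v = table.values.to_numpy().copy()
    n, p = v.shape
    perm = np.argsort(rng.random((n, p)), axis=0)
    out = np.take_along_axis(v, perm, axis=0)
    return TraitTable(
        pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        {**table.provenance, "permuted": True},
    )
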