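"""Data model and plain-TSV readers/writers for CalMorph-style phenome data.

The pipeline's main currency is the :class:`TraitTable`: a samples x
parameters matrix of per-culture summary values (trait means, coefficients
of variation, and sample-level proportions), with samples identified as
``STRAIN.replicate``.  A :class:`ParameterCatalogue` describes each
parameter: its kind (mean / cv / other), the mean<->CV pairing, and the
cell-cycle stage encoded in the parameter-name suffix (``_A`` = G1,
``_A1B`` = S/G2, ``_C`` = M).

All files are tab-separated text with '.' decimal separator; no locale
dependence anywhere.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STAGE_SUFFIXES",
    "STAGES",
    "Parameter",
    "ParameterCatalogue",
    "TraitTable",
    "CellTable",
    "StrainAnnotation",
    "GenotypeMatrix",
    "SchemaError",
    "ValidationError",
    "stage_from_suffix",
    "read_trait_table",
    "write_trait_table",
    "summarize_cells",
]

#: Suffix convention mapping parameter-name endings to cell-cycle stages.
STAGE_SUFFIXES: dict[str, str] = {"_A1B": "S/G2", "_A": "G1", "_C": "M"}
STAGES: tuple[str, ...] = ("G1", "S/G2", "M")

KINDS = ("mean", "cv", "other")


class SchemaError(ValueError):
    """A file or catalogue violates the declared schema."""


class ValidationError(ValueError):
    """Data content violates an invariant (missing value, imbalance, ...)."""


def stage_from_suffix(param_id: str, convention: Mapping[str, str] | None = None) -> str:
    """Derive the cell-cycle stage of a parameter from its name suffix.

    ``_A`` -> G1, ``_A1B`` -> S/G2, ``_C`` -> M (overridable via
    *convention*, mapping suffixes to stage names; longest suffix wins).
    """
    conv = STAGE_SUFFIXES if convention is None else convention
    for suffix in sorted(conv, key=len, reverse=True):
        if param_id.endswith(suffix):
            return conv[suffix]
    raise SchemaError(f"parameter {param_id!r} has no recognised stage suffix")


@dataclass(frozen=True)
class Parameter:
    """One catalogue entry: a named morphology parameter."""

    param_id: str
    kind: str  # "mean" | "cv" | "other"
    partner_id: str = ""  # paired CV (for mean) or paired mean (for cv)
    stage: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"{self.param_id}: unknown kind {self.kind!r}")
        if self.stage and self.stage not in STAGES:
            raise SchemaError(f"{self.param_id}: unknown stage {self.stage!r}")


class ParameterCatalogue:
    """Ordered collection of :class:`Parameter` records with pairing checks.

    Invariant: the ``partner_id`` links form a bijection between cv and
    mean parameters (every CV parameter points at an existing mean
    parameter and vice versa).
    """

    def __init__(self, params: Iterable[Parameter]):
        self._params: dict[str, Parameter] = {}
        for p in params:
            if p.param_id in self._params:
                raise SchemaError(f"duplicate parameter id {p.param_id!r}")
            self._params[p.param_id] = p
        self._check_pairing()

    def _check_pairing(self) -> None:
        means = {p.param_id for p in self if p.kind == "mean"}
        cvs = {p.param_id for p in self if p.kind == "cv"}
        seen_partners: set[str] = set()
        for p in self:
            if p.kind == "cv":
                if p.partner_id not in means:
                    raise SchemaError(
                        f"cv parameter {p.param_id!r} has no mean partner "
                        f"{p.partner_id!r} in the catalogue"
                    )
                if p.partner_id in seen_partners:
                    raise SchemaError(
                        f"mean parameter {p.partner_id!r} paired with more than one CV"
                    )
                seen_partners.add(p.partner_id)
        if len(cvs) != len(means):
            raise SchemaError(
                f"mean/CV pairing is not a bijection: {len(means)} mean vs {len(cvs)} cv"
            )

    # -- container protocol -------------------------------------------------
    def __iter__(self):
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    def __contains__(self, param_id: str) -> bool:
        return param_id in self._params

    def __getitem__(self, param_id: str) -> Parameter:
        return self._params[param_id]

    @property
    def param_ids(self) -> list[str]:
        return list(self._params)

    def of_kind(self, kind: str) -> list[Parameter]:
        return [p for p in self if p.kind == kind]

    def counts(self) -> dict[str, int]:
        """Number of parameters per kind, e.g. {'mean': 220, 'cv': 220, 'other': 61}."""
        out = {k: 0 for k in KINDS}
        for p in self:
            out[p.kind] += 1
        return out

    def pairs(self) -> list[tuple[str, str]]:
        """(mean_id, cv_id) pairs, in catalogue order of the CV parameter."""
        return [(p.partner_id, p.param_id) for p in self if p.kind == "cv"]

    # -- TSV round trip -----------------------------------------------------
    COLUMNS = ("param_id", "kind", "partner_id", "stage", "description")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ParameterCatalogue":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"metadata file lacks columns {sorted(missing)}")
        return cls(
            Parameter(r.param_id, r.kind, r.partner_id, r.stage, r.description)
            for r in df.itertuples()
        )

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(p.param_id, p.kind, p.partner_id, p.stage, p.description) for p in self],
            columns=list(self.COLUMNS),
        ).to_csv(path, sep="\t", index=False)


def _split_sample_id(sample_id: str) -> tuple[str, int]:
    """Parse a 'STRAIN.rep' sample id into (strain, replicate)."""
    strain, _, rep = sample_id.rpartition(".")
    if not strain or not rep.isdigit():
        raise ValidationError(f"sample id {sample_id!r} is not of the form STRAIN.rep")
    return strain, int(rep)


@dataclass
class TraitTable:
    """Samples x parameters matrix of CalMorph-style summary values.

    ``values`` is a DataFrame whose index holds 'STRAIN.rep' sample ids
    (order preserved) and whose columns are parameter ids.  Every strain
    must carry the same number of replicates and no cell may be missing.
    """

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.isna().any().any():
            r, c = next(zip(*np.nonzero(v.isna().to_numpy())))
            raise ValidationError(
                f"missing value at sample {v.index[r]!r}, parameter {v.columns[c]!r}"
            )
        counts = pd.Series(self.strains).value_counts()
        if counts.nunique() > 1:
            raise ValidationError(
                "replicate imbalance: strains have replicate counts "
                f"{sorted(set(counts))}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def strains(self) -> list[str]:
        return [_split_sample_id(s)[0] for s in self.sample_ids]

    @property
    def strain_order(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.strains:
            seen.setdefault(s)
        return list(seen)

    @property
    def replicates(self) -> list[int]:
        return [_split_sample_id(s)[1] for s in self.sample_ids]

    @property
    def n_replicates(self) -> int:
        return len(self.sample_ids) // len(self.strain_order)

    @property
    def param_ids(self) -> list[str]:
        return list(self.values.columns)

    def strain_codes(self) -> np.ndarray:
        """Integer strain label per sample, coded in order of first appearance."""
        order = {s: i for i, s in enumerate(self.strain_order)}
        return np.array([order[s] for s in self.strains])

    def subset_params(self, param_ids: Sequence[str]) -> "TraitTable":
        return TraitTable(self.values.loc[:, list(param_ids)], dict(self.provenance))


def read_trait_table(path: str | Path, meta: ParameterCatalogue | None = None) -> TraitTable:
    """Read a tab-separated trait table, validating against *meta* if given.

    First column: sample ids encoded ``STRAIN.rep``; header row of
    parameter ids.  Unknown parameter ids raise :class:`SchemaError`;
    missing cells raise :class:`ValidationError` naming (row, column).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    if meta is not None:
        unknown = [c for c in df.columns if c not in meta]
        if unknown:
            raise SchemaError(f"unknown parameter ids in {path}: {unknown[:5]}")
    for s in df.index:
        _split_sample_id(s)
    return TraitTable(df)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """Write a trait table as TSV at full float precision (repr round-trip)."""
    v = table.values
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(map(str, v.columns)) + "\n")
        arr = v.to_numpy()
        for i, sid in enumerate(v.index):
            fh.write(sid + "\t" + "\t".join(repr(float(x)) for x in arr[i]) + "\n")


@dataclass
class CellTable:
    """Per-cell measurements: one row per cell.

    Required columns: ``strain``, ``replicate``, ``stage`` (G1 / S/G2 / M);
    remaining columns hold single-cell trait values (named after the mean
    parameter they feed) or 0/1 feature flags feeding 'other' parameters.
    """

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"strain", "replicate", "stage"} - set(self.cells.columns)
        if missing:
            raise SchemaError(f"cell table lacks columns {sorted(missing)}")
        bad = set(self.cells["stage"].unique()) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stages {sorted(bad)}")

    @property
    def trait_columns(self) -> list[str]:
        return [c for c in self.cells.columns if c not in ("strain", "replicate", "stage")]

    def write_tsv(self, path: str | Path) -> None:
        self.cells.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CellTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class StrainAnnotation:
    """Per-strain annotations: ecology class, geography class, clean-lineage flag."""

    table: pd.DataFrame  # index strain_id; columns ecology_class, geography_class, clean_lineage

    def __post_init__(self) -> None:
        need = {"ecology_class", "geography_class", "clean_lineage"}
        missing = need - set(self.table.columns)
        if missing:
            raise SchemaError(f"annotation table lacks columns {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate strain ids in annotation table")

    def check_covers(self, strains: Iterable[str]) -> None:
        missing = set(strains) - set(self.table.index)
        if missing:
            raise ValidationError(f"strains without annotation: {sorted(missing)[:5]}")

    def factor(self, name: str) -> pd.Series:
        if name not in ("ecology", "geography"):
            raise ValueError(f"unknown factor {name!r}")
        return self.table[f"{name}_class"]

    @property
    def clean_lineage_strains(self) -> list[str]:
        return list(self.table.index[self.table["clean_lineage"].astype(bool)])

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="strain_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "StrainAnnotation":
        return cls(pd.read_csv(path, sep="\t", index_col="strain_id"))


@dataclass
class GenotypeMatrix:
    """Strains x segregating-sites boolean SNP matrix."""

    strains: list[str]
    sites: np.ndarray  # (n_strains, n_sites) uint8/bool in {0, 1}

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites)
        if self.sites.ndim != 2 or self.sites.shape[0] != len(self.strains):
            raise ValidationError("genotype matrix shape does not match strain list")
        vals = np.unique(self.sites)
        if not np.isin(vals, [0, 1]).all():
            raise ValidationError("genotype entries must be 0/1")
        self.sites = self.sites.astype(np.uint8)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("strain_id\t" + "\t".join(f"s{i}" for i in range(self.n_sites)) + "\n")
            for name, row in zip(self.strains, self.sites):
                fh.write(name + "\t" + "\t".join(map(str, row.tolist())) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.isna().any().any():
            raise ValidationError("missing genotype calls are rejected")
        return cls(list(df.index.astype(str)), df.to_numpy())


# ---------------------------------------------------------------------------
# cells -> sample summaries


def summarize_cells(
    cells: CellTable, meta: ParameterCatalogue, ddof: int = 1
) -> TraitTable:
    """Collapse per-cell values into the samples x parameters trait table.

    For each (strain, replicate) sample and each mean/CV parameter pair,
    the mean parameter is the arithmetic mean over the sample's cells of
    the parameter's stage, and the CV parameter is sd/mean over the same
    cells (sample sd, ``ddof=1``, by default; set ``ddof=0`` for the
    population convention).  'Other' parameters are cell-count
    proportions: stage fractions for ``FRAC_*`` parameters, otherwise the
    mean of the named 0/1 feature column within the parameter's stage.
    """
    df = cells.cells
    sample_keys = df[["strain", "replicate"]].drop_duplicates()
    sample_ids = [f"{s}.{r}" for s, r in sample_keys.itertuples(index=False)]

    mean_params = meta.of_kind("mean")
    grouped = df.groupby(["strain", "replicate", "stage"], sort=False)
    sizes = grouped.size()

    cols: dict[str, pd.Series] = {}
    key_index = pd.MultiIndex.from_frame(sample_keys)

    # stage-conditional means and sds of every base trait column, computed once
    base_cols = [p.param_id for p in mean_params if p.param_id in df.columns]
    missing = [p.param_id for p in mean_params if p.param_id not in df.columns]
    if missing:
        raise SchemaError(f"cell table lacks base trait columns {missing[:5]}")
    agg_mean = grouped[base_cols].mean()
    agg_sd = grouped[base_cols].std(ddof=ddof)

    for p in mean_params:
        stage = p.stage or stage_from_suffix(p.param_id)
        n = sizes.xs(stage, level="stage").reindex(key_index)
        if n.isna().any() or (n < 2).any():
            bad = key_index[(n.isna() | (n < 2)).to_numpy()][0]
            raise ValidationError(
                f"sample {bad[0]}.{bad[1]} has fewer than 2 cells in stage {stage}"
            )
        m = agg_mean[p.param_id].xs(stage, level="stage").reindex(key_index)
        sd = agg_sd[p.param_id].xs(stage, level="stage").reindex(key_index)
        if (m == 0).any():
            bad = key_index[(m == 0).to_numpy()][0]
            raise ValidationError(
                f"sample {bad[0]}.{bad[1]}: mean of {p.param_id} is 0, CV undefined"
            )
        cols[p.param_id] = m
        if p.partner_id:
            cols[p.partner_id] = sd / m

    total = sizes.groupby(level=["strain", "replicate"]).sum().reindex(key_index)
    for p in meta.of_kind("other"):
        stage = p.stage or stage_from_suffix(p.param_id)
        n_stage = sizes.xs(stage, level="stage").reindex(key_index).fillna(0)
        if p.param_id.startswith("FRAC"):
            cols[p.param_id] = n_stage / total
        else:
            if p.param_id not in df.columns:
                raise SchemaError(f"cell table lacks feature column {p.param_id!r}")
            frac = grouped[p.param_id].mean().xs(stage, level="stage").reindex(key_index)
            cols[p.param_id] = frac.fillna(0.0)

    out = pd.DataFrame({pid: cols[pid].to_numpy() for pid in meta.param_ids if pid in cols})
    out.index = pd.Index(sample_ids, name="sample")
    prov = {"cv_ddof": ddof}
    return TraitTable(out, prov)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
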