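"""Core data containers for the cross-integration pipeline.

The pipeline operates on three kinds of objects: a segregant genotype matrix
with its marker map, phenotype matrices (gene expression and growth in
environmental conditions) with optional per-segregant covariates, and QTL
tables (eQTLs, growth QTLs, and trans-eQTL hotspots) holding peak markers,
confidence intervals, LOD scores, and signed allele effects.

Conventions
-----------
* Genotypes are coded -1 (BY allele) / +1 (RM allele), never missing, so a
  marker-trait Pearson correlation is sign-symmetric in the parent labels.
* Genomic coordinates are 1-based inclusive base pairs; BED exports convert
  to 0-based half-open.
* Growth phenotypes may contain NaN (missing colony measurements);
  expression may not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MARKER_COLUMNS = ["id", "chrom", "pos_bp", "pos_cM"]
QTL_COLUMNS = [
    "trait_id",
    "peak_marker_id",
    "chrom",
    "peak_pos_bp",
    "ci_start_bp",
    "ci_end_bp",
    "lod",
    "effect_r",
    "qtl_class",
]
QTL_CLASSES = {"local-eQTL", "trans-eQTL", "gQTL", "hotspot"}


class ValidationError(ValueError):
    """A data object violates one of its structural invariants."""


class ParseError(ValidationError):
    """A delimited input file does not conform to its documented schema."""


@dataclass
class GenotypeMatrix:
    """Segregants x markers matrix of biallelic parental genotypes.

    Parameters
    ----------
    values
        ``(n_segregants, n_markers)`` array with entries in ``{-1, +1}``.
    markers
        Marker map with columns ``id, chrom, pos_bp, pos_cM``, sorted by
        ``(chrom, pos_bp)``.
    segregant_ids
        Row labels, one per segregant.
    """

    values: np.ndarray
    markers: pd.DataFrame
    segregant_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.segregant_ids = list(self.segregant_ids)
        self.markers = self.markers.reset_index(drop=True)

    # -- invariants ------------------------------------------------------
    def validate(self, allow_constant: bool = False) -> "GenotypeMatrix":
        v = self.values
        if v.ndim != 2:
            raise ValidationError("genotype values must be 2-D")
        if v.shape[0] != len(self.segregant_ids):
            raise ValidationError("segregant_ids length does not match rows")
        if v.shape[1] != len(self.markers):
            raise ValidationError("marker table length does not match columns")
        bad = ~np.isin(v, (-1, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"genotype entry {v[i, j]!r} at segregant "
                f"{self.segregant_ids[i]!r}, marker "
                f"{self.markers['id'].iloc[j]!r} is not in {{-1, +1}}"
            )
        if list(self.markers.columns[:4]) != MARKER_COLUMNS:
            raise ValidationError(f"marker table must have columns {MARKER_COLUMNS}")
        m = self.markers
        if not ((m["chrom"] >= 1).all()):
            raise ValidationError("chromosomes must be numbered from 1")
        key = m[["chrom", "pos_bp"]].to_numpy()
        if not (np.lexsort((key[:, 1], key[:, 0])) == np.arange(len(m))).all():
            raise ValidationError("markers must be sorted by (chrom, pos_bp)")
        for _, grp in m.groupby("chrom"):
            if (np.diff(grp["pos_cM"].to_numpy()) < 0).any():
                raise ValidationError("pos_cM must be non-decreasing within chrom")
        if (m["pos_cM"] < 0).any():
            raise ValidationError("pos_cM must be >= 0")
        if not allow_constant:
            const = np.nonzero(v.min(axis=0) == v.max(axis=0))[0]
            if const.size:
                raise ValidationError(
                    f"marker {m['id'].iloc[const[0]]!r} is constant "
                    "(both alleles must be present)"
                )
        return self

    # -- helpers ---------------------------------------------------------
    @property
    def n_segregants(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers["id"])

    def marker_indices(self, marker_ids) -> np.ndarray:
        lut = {mid: i for i, mid in enumerate(self.markers["id"])}
        try:
            return np.array([lut[m] for m in marker_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown marker id {exc.args[0]!r}") from exc

    def subset_segregants(self, ids) -> "GenotypeMatrix":
        lut = {sid: i for i, sid in enumerate(self.segregant_ids)}
        rows = [lut[s] for s in ids]
        return GenotypeMatrix(self.values[rows], self.markers.copy(), list(ids))


@dataclass
class PhenotypeMatrix:
    """Segregants x traits matrix (expression or growth) with covariates.

    ``covariates``, when present, is a DataFrame indexed like
    ``segregant_ids`` with a categorical ``batch`` column and/or a numeric
    ``od600`` column.
    """

    values: np.ndarray
    trait_ids: list[str]
    segregant_ids: list[str]
    covariates: pd.DataFrame | None = None
    kind: str = "expression"  # or "growth"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.trait_ids = list(self.trait_ids)
        self.segregant_ids = list(self.segregant_ids)

    def validate(self) -> "PhenotypeMatrix":
        if self.values.shape != (len(self.segregant_ids), len(self.trait_ids)):
            raise ValidationError("phenotype shape does not match labels")
        if self.kind == "expression" and np.isnan(self.values).any():
            raise ValidationError("expression matrix must not contain missing values")
        if self.covariates is not None:
            if len(self.covariates) != len(self.segregant_ids):
                raise ValidationError("covariate rows do not match segregants")
        return self

    @property
    def n_segregants(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def subset_segregants(self, ids) -> "PhenotypeMatrix":
        lut = {sid: i for i, sid in enumerate(self.segregant_ids)}
        rows = [lut[s] for s in ids]
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[rows].reset_index(drop=True)
        return PhenotypeMatrix(
            self.values[rows], list(self.trait_ids), list(ids), cov, self.kind
        )

    def column(self, trait_id: str) -> np.ndarray:
        return self.values[:, self.trait_ids.index(trait_id)]


def validate_qtl_table(df: pd.DataFrame, markers: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check structural invariants of an eQTL / gQTL / hotspot table."""
    missing = [c for c in QTL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"QTL table is missing columns {missing}")
    if (df["lod"] < 0).any():
        raise ValidationError("LOD scores must be >= 0")
    if (df["effect_r"].abs() > 1 + 1e-12).any():
        raise ValidationError("|effect_r| must be <= 1")
    bad_class = set(df["qtl_class"]) - QTL_CLASSES
    if bad_class:
        raise ValidationError(f"unknown qtl_class values {sorted(bad_class)}")
    inside = (df["ci_start_bp"] <= df["peak_pos_bp"]) & (df["peak_pos_bp"] <= df["ci_end_bp"])
    if not inside.all():
        row = df.loc[~inside].iloc[0]
        raise ValidationError(
            f"peak position outside confidence interval for trait {row['trait_id']!r}"
        )
    return df


def validate_hotspot_table(df: pd.DataFrame) -> pd.DataFrame:
    """Hotspot table: QTL invariants plus unique peaks and target counts."""
    validate_qtl_table(df)
    if "n_target_genes" not in df.columns:
        raise ValidationError("hotspot table requires an n_target_genes column")
    if df["peak_marker_id"].duplicated().any():
        raise ValidationError("hotspot peak markers must be unique")
    if (df["n_target_genes"] < 1).any():
        raise ValidationError("n_target_genes must be >= 1")
    if not (df["qtl_class"] == "hotspot").all():
        raise ValidationError("hotspot table rows must have qtl_class == 'hotspot'")
    return df


@dataclass
class Dataset:
    """A matched bundle of genotypes, phenotypes, and QTL tables."""

    genotypes: GenotypeMatrix
    expression: PhenotypeMatrix
    growth: PhenotypeMatrix
    eqtls: pd.DataFrame | None = None
    gqtls: pd.DataFrame | None = None
    hotspots: pd.DataFrame | None = None
    gene_sets: dict[str, set[str]] = field(default_factory=dict)


def intersect_segregants(
    genotypes: GenotypeMatrix,
    expression: PhenotypeMatrix,
    growth: PhenotypeMatrix,
) -> tuple[GenotypeMatrix, PhenotypeMatrix, PhenotypeMatrix, list[str]]:
    """Restrict all three matrices to segregants present in each of them.

    Growth contributes a segregant as long as it has a measurement in at
    least one condition (missing values are allowed).
    """
    shared = [
        s
        for s in genotypes.segregant_ids
        if s in set(expression.segregant_ids) and s in set(growth.segregant_ids)
    ]
    if not shared:
        raise ValidationError("no segregants shared between genotype, expression, and growth")
    return (
        genotypes.subset_segregants(shared),
        expression.subset_segregants(shared),
        growth.subset_segregants(shared),
        shared,
    )
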