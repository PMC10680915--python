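"""Tab-separated readers and writers for every pipeline object.

Formats (all TSV with header rows; floats serialized with 17 significant
digits so write -> read round-trips are bit-identical):

* genotypes: rows = segregants (first column ``segregant``), columns =
  marker ids, entries -1/+1; the marker map travels in a companion file
  with columns ``id, chrom, pos_bp, pos_cM``.
* phenotypes: rows = segregants, columns = trait ids, ``NA`` for missing;
  optional covariates file with ``segregant, batch, od600``.
* QTL / hotspot tables: the documented QTL columns.
* gene sets: GMT (term, description, members...).
* intervals: BED export (0-based half-open).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeMatrix,
    ParseError,
    PhenotypeMatrix,
    intersect_segregants,
    validate_hotspot_table,
    validate_qtl_table,
)

FLOAT_FMT = "%.17g"


# -- genotypes -------------------------------------------------------------

def write_genotypes(gm: GenotypeMatrix, geno_path, map_path) -> None:
    df = pd.DataFrame(gm.values, columns=gm.marker_ids)
    df.insert(0, "segregant", gm.segregant_ids)
    df.to_csv(geno_path, sep="\t", index=False)
    gm.markers.to_csv(map_path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_genotypes(geno_path, map_path) -> GenotypeMatrix:
    df = pd.read_csv(geno_path, sep="\t")
    if df.columns[0] != "segregant":
        raise ParseError(f"{geno_path}: first column must be 'segregant'")
    markers = pd.read_csv(map_path, sep="\t", float_precision="round_trip")
    seg = df["segregant"].astype(str).tolist()
    vals = df.drop(columns="segregant")
    arr = vals.to_numpy()
    bad = ~np.isin(arr, (-1, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{geno_path}: entry {arr[i, j]!r} at segregant {seg[i]!r}, "
            f"marker {vals.columns[j]!r} is not in {{-1, +1}}"
        )
    if list(vals.columns) != list(markers["id"].astype(str)):
        raise ParseError(f"{geno_path}: marker columns do not match the map file {map_path}")
    return GenotypeMatrix(arr.astype(np.int8), markers, seg).validate(allow_constant=True)


# -- phenotypes ------------------------------------------------------------

def write_phenotypes(pm: PhenotypeMatrix, path, covariates_path=None) -> None:
    df = pd.DataFrame(pm.values, columns=pm.trait_ids)
    df.insert(0, "segregant", pm.segregant_ids)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep="NA")
    if covariates_path is not None and pm.covariates is not None:
        cov = pm.covariates.copy()
        cov.insert(0, "segregant", pm.segregant_ids)
        cov.to_csv(covariates_path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_phenotypes(path, covariates_path=None, kind="expression") -> PhenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")
    if df.columns[0] != "segregant":
        raise ParseError(f"{path}: first column must be 'segregant'")
    seg = df["segregant"].astype(str).tolist()
    vals = df.drop(columns="segregant")
    cov = None
    if covariates_path is not None and Path(covariates_path).exists():
        cov = pd.read_csv(covariates_path, sep="\t", float_precision="round_trip")
        if "segregant" not in cov.columns:
            raise ParseError(f"{covariates_path}: missing 'segregant' column")
        cov = cov.set_index("segregant").loc[seg].reset_index(drop=True)
    return PhenotypeMatrix(
        vals.to_numpy(float), list(vals.columns), seg, cov, kind
    ).validate()


# -- QTL tables ------------------------------------------------------------

def write_qtl_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_qtl_table(path, hotspot: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    try:
        return validate_hotspot_table(df) if hotspot else validate_qtl_table(df)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


# -- gene sets (GMT) -------------------------------------------------------

def write_gmt(gene_sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(gene_sets):
            members = sorted(gene_sets[term])
            fh.write("\t".join([term, "synthetic"] + members) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{line_no}: GMT lines need term and description")
            sets[parts[0]] = set(parts[2:])
    return sets


# -- BED -------------------------------------------------------------------

def write_bed(interval_set, path) -> None:
    interval_set.to_bed().to_csv(path, sep="\t", index=False, header=False)


# -- bundles ---------------------------------------------------------------

def read_tables(paths: dict, log=None):
    """Read and cross-validate a full input bundle.

    ``paths`` keys: genotypes, marker_map, expression, expression_covariates
    (optional), growth, eqtls, gqtls, hotspots, gene_sets (the last four
    optional). Segregants are intersected across genotype/expression/growth
    (growth counts if measured in at least one condition) and the
    intersection size is logged.
    """
    gm = read_genotypes(paths["genotypes"], paths["marker_map"])
    expr = read_phenotypes(
        paths["expression"], paths.get("expression_covariates"), kind="expression"
    )
    growth = read_phenotypes(paths["growth"], kind="growth")
    gm, expr, growth, shared = intersect_segregants(gm, expr, growth)
    if log is not None:
        log.info("shared segregants across genotype/expression/growth: %d", len(shared))
    out = {"genotypes": gm, "expression": expr, "growth": growth}
    if "eqtls" in paths:
        out["eqtls"] = read_qtl_table(paths["eqtls"])
    if "gqtls" in paths:
        out["gqtls"] = read_qtl_table(paths["gqtls"])
    if "hotspots" in paths:
        out["hotspots"] = read_qtl_table(paths["hotspots"], hotspot=True)
    if "gene_sets" in paths:
        out["gene_sets"] = read_gmt(paths["gene_sets"])
    return out
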