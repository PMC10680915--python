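"""Pipeline orchestration: stages, provenance, deterministic outputs.

Each stage reads what it needs (from memory when chained by ``run_pipeline``
or from the working directory when run in isolation), writes its result
tables as TSV, and records a JSON provenance entry (global seed, stage
seed, config hash, input/output file hashes). Two runs with the same
config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import enrich as enrich_mod
from . import gencor as gencor_mod
from . import hotspots as hotspots_mod
from . import intervals as intervals_mod
from . import io as io_mod
from . import mediate as mediate_mod
from . import qtlfx as qtlfx_mod
from . import removal as removal_mod
from . import simulate as simulate_mod
from . import varcomp as varcomp_mod
from .config import RunConfig, stage_rng, stage_seed
from .datatypes import intersect_segregants
from .preprocess import correct_expression, standardize

log = logging.getLogger("eqtlgrowth")

STAGES = [
    "simulate",
    "preprocess",
    "gencor",
    "qtlfx",
    "hotspot",
    "varcomp",
    "overlap",
    "coloc",
    "removal",
    "enrich",
    "mediate",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_provenance(outdir: Path, stage: str, cfg: RunConfig,
                      inputs: list[str], outputs: list[str]) -> None:
    rec = {
        "stage": stage,
        "seed": cfg.seed,
        "stage_seed": stage_seed(cfg.seed, stage),
        "config_hash": cfg.config_hash(),
        "inputs": {f: _sha(outdir / f) for f in inputs if (outdir / f).exists()},
        "outputs": {f: _sha(outdir / f) for f in outputs if (outdir / f).exists()},
    }
    (outdir / f"provenance_{stage}.json").write_text(json.dumps(rec, indent=1, sort_keys=True))


def _tsv(df: pd.DataFrame, outdir: Path, name: str) -> str:
    df.to_csv(outdir / name, sep="\t", index=False, float_format=io_mod.FLOAT_FMT, na_rep="NA")
    return name


# -- lazy state loading ----------------------------------------------------

def _need(state: dict, outdir: Path, *keys) -> None:
    loaders = {
        "genotypes": lambda: io_mod.read_genotypes(outdir / "genotypes.tsv", outdir / "marker_map.tsv"),
        "expression": lambda: io_mod.read_phenotypes(
            outdir / "expression.tsv", outdir / "expression_covariates.tsv", "expression"),
        "growth": lambda: io_mod.read_phenotypes(outdir / "growth.tsv", kind="growth"),
        "expr_std": lambda: io_mod.read_phenotypes(outdir / "expression_corrected.tsv", kind="expression"),
        "growth_std": lambda: io_mod.read_phenotypes(outdir / "growth_std.tsv", kind="growth"),
        "eqtls": lambda: io_mod.read_qtl_table(outdir / "eqtls.tsv"),
        "gqtls": lambda: io_mod.read_qtl_table(outdir / "gqtls.tsv"),
        "hotspots": lambda: io_mod.read_qtl_table(outdir / "hotspots.tsv", hotspot=True),
        "gene_sets": lambda: io_mod.read_gmt(outdir / "gene_sets.gmt"),
        "gencor": lambda: pd.read_csv(outdir / "gencor.tsv", sep="\t", na_values=["NA"]),
        "hotspot_cor": lambda: pd.read_csv(outdir / "hotspot_correlations.tsv", sep="\t", na_values=["NA"]),
        "gene_eff": lambda: pd.read_csv(outdir / "hotspot_effects_genes.tsv", sep="\t", index_col=0),
        "cond_eff": lambda: pd.read_csv(outdir / "hotspot_effects_conditions.tsv", sep="\t", index_col=0),
    }
    for key in keys:
        if key not in state:
            state[key] = loaders[key]()


def _hotspot_indices(state: dict) -> np.ndarray:
    return state["genotypes"].marker_indices(state["hotspots"]["peak_marker_id"])


# -- stages ----------------------------------------------------------------

def stage_simulate(state: dict, cfg: RunConfig, outdir: Path) -> None:
    rng = stage_rng(cfg.seed, "simulate")
    genome = simulate_mod.GenomeModel()
    spacing = max(1, genome.total_bp // cfg.n_markers)
    gm = simulate_mod.simulate_cross(genome, cfg.n_segregants, spacing, rng)
    arch_cfg = simulate_mod.ArchitectureConfig(n_hotspots=cfg.n_hotspots)
    arch = simulate_mod.build_architecture(gm, cfg.n_genes, cfg.n_conditions, arch_cfg, rng)
    expr, growth = simulate_mod.generate_phenotypes(gm, arch, rng)
    eqtl, gqtl, hotspot = simulate_mod.truth_qtl_tables(gm, expr, growth, arch)
    sets = simulate_mod.gene_set_fixtures(arch)
    io_mod.write_genotypes(gm, outdir / "genotypes.tsv", outdir / "marker_map.tsv")
    io_mod.write_phenotypes(expr, outdir / "expression.tsv", outdir / "expression_covariates.tsv")
    io_mod.write_phenotypes(growth, outdir / "growth.tsv")
    io_mod.write_qtl_table(eqtl, outdir / "eqtls.tsv")
    io_mod.write_qtl_table(gqtl, outdir / "gqtls.tsv")
    io_mod.write_qtl_table(hotspot, outdir / "hotspots.tsv")
    io_mod.write_gmt(sets, outdir / "gene_sets.gmt")
    _tsv(arch.to_frame(), outdir, "truth.tsv")
    state.update(genotypes=gm, expression=expr, growth=growth, eqtls=eqtl,
                 gqtls=gqtl, hotspots=hotspot, gene_sets=sets, arch=arch, genome=genome)
    _write_provenance(outdir, "simulate", cfg, [],
                      ["genotypes.tsv", "expression.tsv", "growth.tsv", "eqtls.tsv",
                       "gqtls.tsv", "hotspots.tsv", "gene_sets.gmt", "truth.tsv"])


def stage_preprocess(state: dict, cfg: RunConfig, outdir: Path) -> None:
    _need(state, outdir, "genotypes", "expression", "growth")
    gm, expr, growth, shared = intersect_segregants(
        state["genotypes"], state["expression"], state["growth"]
    )
    log.info("preprocess: %d shared segregants", len(shared))
    corrected, _ = correct_expression(expr)
    expr_std = standardize(corrected)
    growth_std = standardize(growth)
    state.update(genotypes=gm, expression=expr, growth=growth,
                 expr_std=expr_std, growth_std=growth_std)
    io_mod.write_phenotypes(expr_std, outdir / "expression_corrected.tsv")
    io_mod.write_phenotypes(growth_std, outdir / "growth_std.tsv")
    _write_provenance(outdir, "preprocess", cfg,
                      ["expression.tsv", "growth.tsv"],
                      ["expression_corrected.tsv", "growth_std.tsv"])


def stage_gencor(state: dict, cfg: RunConfig, outdir: Path) -> None:
    _need(state, outdir, "expr_std", "growth_std", "eqtls")
    expr, growth = state["expr_std"], state["growth_std"]
    with_eqtl = sorted(set(state["eqtls"]["trait_id"]) & set(expr.trait_ids))
    keep = [expr.trait_ids.index(g) for g in with_eqtl]
    expr_sub = type(expr)(expr.values[:, keep], with_eqtl, expr.segregant_ids, None, "expression")
    table = gencor_mod.genetic_correlations(expr_sub, growth, fdr=cfg.fdr_genetic)
    summary = gencor_mod.significant_summary(table, cfg.fdr_genetic)
    outs = [_tsv(table, outdir, "gencor.tsv"), _tsv(summary, outdir, "gencor_summary.tsv")]
    sizes = tuple(s for s in cfg.downsample_sizes if s <= expr.n_segregants)
    if sizes:
        ds = gencor_mod.downsample_analysis(
            expr_sub, growth, sizes, cfg.downsample_reps,
            stage_seed(cfg.seed, "gencor"), cfg.fdr_genetic,
        )
        outs.append(_tsv(ds, outdir, "downsample.tsv"))
    state["gencor"] = table
    _write_provenance(outdir, "gencor", cfg,
                      ["expression_corrected.tsv", "growth_std.tsv"], outs)


def stage_qtlfx(state: dict, cfg: RunConfig, outdir: Path) -> None:
    _need(state, outdir, "genotypes", "expr_std", "growth_std", "eqtls")
    table = qtlfx_mod.qtl_effect_correlations(
        state["expr_std"], state["growth_std"], state["genotypes"], state["eqtls"],
        min_eqtls=3, fdr=cfg.fdr_qtlfx,
    )
    state["qtlfx"] = table
    _tsv(table, outdir, "qtlfx.tsv")
    _write_provenance(outdir, "qtlfx", cfg, ["eqtls.tsv"], ["qtlfx.tsv"])


def _row_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """corr(A[i], B[j]) for all row pairs -> (rows_A, rows_B)."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((Ac**2).sum(axis=1))
    nb = np.sqrt((Bc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (Ac @ Bc.T) / (na[:, None] * nb[None, :])


def stage_hotspot(state: dict, cfg: RunConfig, outdir: Path) -> None:
    _need(state, outdir, "genotypes", "expr_std", "growth_std", "hotspots", "gencor")
    gm = state["genotypes"]
    expr, growth = state["expr_std"], state["growth_std"]
    hot_idx = _hotspot_indices(state)
    H = gm.values[:, hot_idx].astype(float)
    gene_eff, cond_eff = hotspots_mod.hotspot_effect_tables(
        expr.values, growth.values, H, expr.trait_ids, growth.trait_ids, cfg.stepwise_p
    )
    cor = hotspots_mod.hotspot_correlation_table(
        gene_eff, cond_eff, expr.trait_ids, growth.trait_ids, cfg.fdr_genetic
    )
    state.update(gene_eff=gene_eff, cond_eff=cond_eff, hotspot_cor=cor)
    hot_ids = list(state["hotspots"]["peak_marker_id"])
    _tsv(pd.DataFrame(gene_eff, index=expr.trait_ids, columns=hot_ids).reset_index(names="gene_id"),
         outdir, "hotspot_effects_genes.tsv")
    _tsv(pd.DataFrame(cond_eff, index=growth.trait_ids, columns=hot_ids).reset_index(names="condition_id"),
         outdir, "hotspot_effects_conditions.tsv")
    _tsv(cor, outdir, "hotspot_correlations.tsv")

    # per-condition agreement between hotspot correlations and genetic
    # correlations, with a random-marker-set null
    gc = state["gencor"].pivot(index="gene_id", columns="condition_id", values="r")
    gc = gc.reindex(index=expr.trait_ids, columns=growth.trait_ids)

    def agreement(gene_e: np.ndarray, cond_e: np.ndarray) -> np.ndarray:
        hc = _row_corr(gene_e, cond_e)  # genes x conditions
        out = np.full(len(growth.trait_ids), np.nan)
        for c in range(len(growth.trait_ids)):
            x = hc[:, c]
            y = gc.iloc[:, c].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 3 and x[ok].std() > 0 and y[ok].std() > 0:
                out[c] = np.corrcoef(x[ok], y[ok])[0, 1]
        return out

    obs = agreement(gene_eff, cond_eff)

    def null_stat(marker_idx: np.ndarray) -> np.ndarray:
        Hr = gm.values[:, marker_idx].astype(float)
        ge, ce = hotspots_mod.hotspot_effect_tables(
            expr.values, growth.values, Hr, expr.trait_ids, growth.trait_ids, cfg.stepwise_p
        )
        return agreement(ge, ce)

    null = hotspots_mod.random_markerset_null(
        null_stat, gm.n_markers, len(hot_idx), cfg.n_null_sets,
        stage_seed(cfg.seed, "hotspot"),
    )
    rows = []
    for c, cond in enumerate(growth.trait_ids):
        nd = null[:, c]
        nd = nd[np.isfinite(nd)]
        rows.append(
            {
                "condition_id": cond,
                "agreement_r": obs[c],
                "null_q95": float(np.quantile(nd, 0.95)) if nd.size else np.nan,
                "p_emp": hotspots_mod.empirical_p(obs[c], nd) if nd.size and np.isfinite(obs[c]) else np.nan,
            }
        )
    _tsv(pd.DataFrame(rows), outdir, "hotspot_agreement.tsv")
    _write_provenance(outdir, "hotspot", cfg, ["hotspots.tsv", "gencor.tsv"],
                      ["hotspot_effects_genes.tsv", "hotspot_effects_conditions.tsv",
                       "hotspot_correlations.tsv", "hotspot_agreement.tsv"])


def stage_varcomp(state: dict, cfg: RunConfig, outdir: Path) -> None:
    _need(state, outdir, "genotypes", "growth_std", "hotspots", "gqtls")
    gm = state["genotypes"]
    growth = state["growth_std"]
    hot_idx = _hotspot_indices(state)
    conds = growth.trait_ids
    parts = [
        varcomp_mod.marker_set_h2(growth.values, conds, gm, np.arange(gm.n_markers), "all_markers"),
        varcomp_mod.marker_set_h2(growth.values, conds, gm, hot_idx, "hotspots"),
    ]
    for cond, grp in state["gqtls"].groupby("trait_id"):
        if cond not in conds:
            continue
        idx = gm.marker_indices(grp["peak_marker_id"])
        part = varcomp_mod.marker_set_h2(growth.values, [cond], gm, idx, "own_gqtls")
        parts.append(part)
    vc = pd.concat(parts, ignore_index=True)
    outs = [_tsv(vc, outdir, "varcomp.tsv")]

    ranked = hot_idx  # hotspot table is sorted by n_target_genes desc
    curve = varcomp_mod.hotspot_variance_curve(growth.values, conds, gm, ranked)
    outs.append(_tsv(curve, outdir, "varcomp_curve.tsv"))
    outs.append(_tsv(curve.attrs["summary"], outdir, "varcomp_curve_summary.tsv"))

    obs = (
        vc[vc["set_name"] == "hotspots"].set_index("condition_id")["fraction"]
        .reindex(conds).to_numpy()
    )
    null = varcomp_mod.random_set_h2(
        growth.values, conds, gm, len(hot_idx), cfg.n_null_sets,
        stage_seed(cfg.seed, "varcomp"), observed_fractions=obs,
    )
    outs.append(_tsv(null.attrs["summary"], outdir, "varcomp_null_summary.tsv"))
    state["varcomp"] = vc
    state["varcomp_null_summary"] = null.attrs["summary"]
    _write_provenance(outdir, "varcomp", cfg, ["growth_std.tsv", "hotspots.tsv"], outs)


def stage_overlap(state: dict, cfg: RunConfig, outdir: Path) -> None:
    _need(state, outdir, "genotypes", "eqtls", "gqtls", "hotspots")
    genome = state.get("genome", simulate_mod.GenomeModel()).as_dict()
    hs_set = intervals_mod.qtl_intervals(state["hotspots"], genome)
    rng = stage_rng(cfg.seed, "overlap")
    rows = []
    for cond, grp in state["gqtls"].groupby("trait_id"):
        gq_set = intervals_mod.qtl_intervals(grp, genome)
        _, n_obs = intervals_mod.count_overlaps(gq_set, hs_set, cfg.pad_bp)
        sizes = (grp["ci_end_bp"] - grp["ci_start_bp"] + 1).tolist()
        null = []
        rand_sets = intervals_mod.random_interval_placement(
            sizes, genome, cfg.n_null_sets, rng
        )
        for rs in rand_sets:
            _, k = intervals_mod.count_overlaps(rs, hs_set, cfg.pad_bp)
            null.append(k)
        rows.append(
            {
                "condition_id": cond,
                "n_gqtls": len(grp),
                "n_overlapping": n_obs,
                "null_mean": float(np.mean(null)),
                "p_emp": intervals_mod.overlap_pvalue(n_obs, np.array(null)),
            }
        )
    outs = [_tsv(pd.DataFrame(rows), outdir, "overlap.tsv")]
    bin_rows = []
    for bs in cfg.bin_sizes:
        rho, p, _ = intervals_mod.bin_cooccurrence(state["eqtls"], state["gqtls"], bs, genome)
        bin_rows.append({"bin_size": bs, "rho": rho, "p": p})
    outs.append(_tsv(pd.DataFrame(bin_rows), outdir, "bins.tsv"))
    state["overlap"] = pd.DataFrame(rows)
    _write_provenance(outdir, "overlap", cfg, ["gqtls.tsv", "hotspots.tsv"], outs)


def stage_coloc(state: dict, cfg: RunConfig, outdir: Path) -> None:
    _need(state, outdir, "genotypes", "expr_std", "growth_std", "eqtls", "gqtls")
    gm = state["genotypes"]
    expr, growth = state["expr_std"], state["growth_std"]
    local = state["eqtls"][(state["eqtls"]["qtl_class"] == "local-eQTL")
                           & (state["eqtls"]["lod"] >= cfg.coloc_min_lod)]
    gq = state["gqtls"][state["gqtls"]["lod"] >= cfg.coloc_min_lod]
    mk = gm.markers
    rng = stage_rng(cfg.seed, "coloc")
    rows = []
    tested = 0
    for _, lrow in local.iterrows():
        if tested >= cfg.coloc_max_pairs:
            break
        hits = gq[(gq["chrom"] == lrow["chrom"])
                  & (gq["ci_start_bp"] - cfg.pad_bp <= lrow["ci_end_bp"])
                  & (lrow["ci_start_bp"] - cfg.pad_bp <= gq["ci_end_bp"])]
        for _, grow in hits.iterrows():
            if tested >= cfg.coloc_max_pairs:
                break
            lo = min(lrow["ci_start_bp"], grow["ci_start_bp"]) - cfg.pad_bp
            hi = max(lrow["ci_end_bp"], grow["ci_end_bp"]) + cfg.pad_bp
            on = np.nonzero(((mk["chrom"] == lrow["chrom"])
                             & (mk["pos_bp"] >= lo) & (mk["pos_bp"] <= hi)).to_numpy())[0]
            G = gm.values[:, on].astype(float)
            keep = coloc_mod.prune_markers(G, cfg.prune_r)
            G = G[:, keep]
            ids = [mk["id"].iloc[on[k]] for k in keep]
            scan = coloc_mod.two_qtl_scan(
                expr.column(lrow["trait_id"]), growth.column(grow["trait_id"]),
                G, ids, cfg.coloc_min_markers,
            )
            p_boot = np.nan
            if scan.verdict != "not-tested":
                p_boot = coloc_mod.parametric_bootstrap_p(scan, cfg.n_boot, rng)
                tested += 1
            rows.append(
                {
                    "gene_id": lrow["trait_id"],
                    "condition_id": grow["trait_id"],
                    "chrom": int(lrow["chrom"]),
                    "n_markers": G.shape[1],
                    "lrt": scan.lrt,
                    "p_boot": p_boot,
                    "verdict": scan.verdict,
                    "max_profile_lod_expr": float(scan.profile_lod_1.max()) if G.shape[1] else np.nan,
                    "max_profile_lod_growth": float(scan.profile_lod_2.max()) if G.shape[1] else np.nan,
                }
            )
    table = pd.DataFrame(rows, columns=["gene_id", "condition_id", "chrom", "n_markers",
                                        "lrt", "p_boot", "verdict",
                                        "max_profile_lod_expr", "max_profile_lod_growth"])
    state["coloc"] = table
    _tsv(table, outdir, "coloc.tsv")
    _write_provenance(outdir, "coloc", cfg, ["eqtls.tsv", "gqtls.tsv"], ["coloc.tsv"])


def stage_removal(state: dict, cfg: RunConfig, outdir: Path) -> None:
    _need(state, outdir, "genotypes", "expr_std", "growth_std", "eqtls", "hotspots", "gencor")
    table = removal_mod.removal_comparison(
        state["expr_std"], state["growth_std"], state["genotypes"],
        state["eqtls"], state["hotspots"], state["gencor"],
        fdr=cfg.fdr_genetic, n_random_sets=min(cfg.n_null_sets, 20),
        seed=stage_seed(cfg.seed, "removal"),
    )
    state["removal"] = table
    outs = [_tsv(table, outdir, "removal.tsv")]
    if "tests" in table.attrs:
        outs.append(_tsv(table.attrs["tests"], outdir, "removal_tests.tsv"))
    if "random_expectation" in table.attrs:
        outs.append(_tsv(table.attrs["random_expectation"], outdir, "removal_random.tsv"))
    _write_provenance(outdir, "removal", cfg, ["gencor.tsv"], outs)


def stage_enrich(state: dict, cfg: RunConfig, outdir: Path) -> None:
    _need(state, outdir, "gencor", "gene_sets", "expr_std", "growth_std")
    universe = state["expr_std"].trait_ids
    records = enrich_mod.sign_split_enrichment(
        state["gencor"], state["gene_sets"], universe,
        cfg.fdr_genetic, cfg.go_p_display, cfg.go_p_strict,
    )
    outs = [_tsv(records, outdir, "enrichment.tsv")]
    fm = enrich_mod.fold_matrix(records, state["growth_std"].trait_ids)
    outs.append(_tsv(fm.reset_index(names="condition_id"), outdir, "fold_matrix.tsv"))
    if len(fm.columns) and len(fm) >= cfg.k_clusters:
        labels, inertia = enrich_mod.cluster_traits(
            fm, cfg.k_clusters, stage_seed(cfg.seed, "enrich")
        )
        cl = labels.reset_index()
        cl.columns = ["condition_id", "cluster"]
        outs.append(_tsv(cl, outdir, "clusters.tsv"))
        state["clusters"] = labels
    sig_groups = {t: s for t, s in state["gene_sets"].items() if t.startswith("signature")}
    if sig_groups:
        means = enrich_mod.signature_average(state["gencor"], sig_groups)
        outs.append(_tsv(means, outdir, "signature_means.tsv"))
    state["enrichment"] = records
    _write_provenance(outdir, "enrich", cfg, ["gencor.tsv", "gene_sets.gmt"], outs)


def stage_mediate(state: dict, cfg: RunConfig, outdir: Path) -> None:
    _need(state, outdir, "genotypes", "expr_std", "growth_std", "hotspots", "gqtls", "gene_sets")
    gm = state["genotypes"]
    expr, growth = state["expr_std"], state["growth_std"]
    hs = state["hotspots"].iloc[0]  # largest hotspot (table sorted by targets)
    marker = hs["peak_marker_id"]
    targets = sorted(state["gene_sets"].get(f"targets_{marker}", set()) & set(expr.trait_ids))
    if not targets:
        targets = expr.trait_ids[:50]
    # condition with a gQTL at this hotspot marker, else strongest marginal effect
    at_marker = state["gqtls"][state["gqtls"]["peak_marker_id"] == marker]
    if len(at_marker):
        cond = at_marker.sort_values("lod", ascending=False)["trait_id"].iloc[0]
    else:
        j = gm.marker_indices([marker])[0]
        g = gm.values[:, j].astype(float)
        best, cond = 0.0, growth.trait_ids[0]
        for c in growth.trait_ids:
            y = growth.column(c)
            ok = ~np.isnan(y)
            r = abs(np.corrcoef(g[ok], y[ok])[0, 1])
            if r > best:
                best, cond = r, c
    j = gm.marker_indices([marker])[0]
    keep = [expr.trait_ids.index(g) for g in targets]
    table = mediate_mod.mediation_scan(
        gm.values[:, j].astype(float), expr.values[:, keep], targets,
        growth.column(cond), cond, marker, cfg.n_boot,
        stage_seed(cfg.seed, "mediate"), cfg.fdr_genetic,
    )
    state["mediation"] = table
    _tsv(table, outdir, "mediation.tsv")
    _write_provenance(outdir, "mediate", cfg, ["hotspots.tsv", "gqtls.tsv"], ["mediation.tsv"])


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "gencor": stage_gencor,
    "qtlfx": stage_qtlfx,
    "hotspot": stage_hotspot,
    "varcomp": stage_varcomp,
    "overlap": stage_overlap,
    "coloc": stage_coloc,
    "removal": stage_removal,
    "enrich": stage_enrich,
    "mediate": stage_mediate,
}


def run_stage(name: str, cfg: RunConfig, outdir, state: dict | None = None) -> dict:
    """Run a single stage; inputs are loaded from ``outdir`` when missing."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = {} if state is None else state
    try:
        STAGE_FUNCS[name](state, cfg, outdir)
    except Exception as exc:
        raise PipelineError(name, exc) from exc
    return state


def run_pipeline(cfg: RunConfig, outdir, stages: list[str] | None = None) -> dict:
    """Run all stages in dependency order.

    When input paths are configured the simulate stage is replaced by
    reading the given files; otherwise a synthetic cross is generated.
    A stage failure raises :class:`PipelineError` naming the stage; output
    tables of completed stages remain on disk.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    state: dict = {}
    todo = stages or STAGES
    if cfg.paths:
        bundle = io_mod.read_tables(cfg.paths, log)
        state.update(bundle)
        todo = [s for s in todo if s != "simulate"]
    for name in todo:
        log.info("running stage %s", name)
        run_stage(name, cfg, outdir, state)
    return state
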