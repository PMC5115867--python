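"""End-to-end synthetic pipeline runs and the retention report.

``run_pipeline`` simulates every input, executes normalization, DE,
network construction, module detection, preservation, reconciliation,
Ka/Ks and the retention-enrichment statistics, and returns one
machine-readable report (plus files when an output directory is given).

``worked_example_report`` recomputes the retention-enrichment table from
the published worked-example counts (the counts themselves are the only
input; every statistic is recomputed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import coexpression as cx
from . import enrichment as en
from . import expression as ex
from . import kaks as kk
from . import phylogenomics as pg
from . import simulate as sim
from .io import PipelineConfig

log = logging.getLogger("edsnet")

__all__ = ["run_pipeline", "worked_example_report", "WORKED_EXAMPLE_COUNTS"]

#: Published worked-example retention counts: per gene set, the number of
#: focal-species leaf-expressed genes whose most recent duplication puts
#: them in each category, and the filtered totals.
WORKED_EXAMPLE_COUNTS: Dict[str, Dict[str, int]] = {
    "genome_wide": {"multi_copy": 9691, "wgt": 6181, "nld": 1249,
                    "total": 14642},
    "complete_eds": {"multi_copy": 906, "wgt": 587, "nld": 87,
                     "total": 1140},
    "conserved_eds": {"multi_copy": 561, "wgt": 355, "nld": 65,
                      "total": 692},
}

#: Published worked-example pair bookkeeping: WGT-derived duplicate pairs
#: expressed in leaves, module members among their genes, and pairs with
#: both members in the module.
WORKED_EXAMPLE_PAIRS = {"n_pairs": 4292, "m_in_module": 428,
                        "observed_both": 120}


def worked_example_report() -> pd.DataFrame:
    """Recompute the retention-enrichment table from the published counts.

    Rows: (gene set, category); columns: counts, percentages, the odds
    ratio (full precision and truncated to the table's two decimals) and
    the exact upper-tail binomial p.
    """
    genome = WORKED_EXAMPLE_COUNTS["genome_wide"]
    rows = []
    for set_name in ("complete_eds", "conserved_eds"):
        counts = WORKED_EXAMPLE_COUNTS[set_name]
        for cat in ("multi_copy", "wgt", "nld"):
            res = en.category_odds_ratio(
                counts[cat], counts["total"], genome[cat], genome["total"])
            rows.append({
                "gene_set": set_name, "category": cat,
                "k_in_set": res.k_cat_in_set, "n_set": res.n_set,
                "k_genome": res.k_cat_genome, "n_genome": res.n_genome,
                "pct_in_set": round(100.0 * res.p1, 1),
                "pct_genome": round(100.0 * res.p2, 1),
                "odds": res.odds,
                "odds_2dp": en.truncate2(res.odds),
                "p_value": res.p_value,
                "p_printed": en.format_p(res.p_value),
            })
    return pd.DataFrame(rows)


def worked_example_pair_test() -> en.PairRetentionResult:
    """Recompute the preferential pair-retention chi-square from the
    published pair bookkeeping."""
    return en.pair_retention_chi2(**WORKED_EXAMPLE_PAIRS)


# ---------------------------------------------------------------------------
# the synthetic end-to-end run
# ---------------------------------------------------------------------------

def run_pipeline(config: Optional[PipelineConfig] = None,
                 outdir: Optional[str] = None) -> Dict:
    """Simulate all inputs and execute every stage; returns the report.

    Deterministic for a fixed config seed.  When ``outdir`` is given the
    main tables and the report JSON are written there.
    """
    cfg = config or PipelineConfig()
    rng_seed = int(cfg.seed)
    log.info("edsnet %s pipeline run, config: %s", __version__,
             dataclasses.asdict(cfg))

    report: Dict = {"version": __version__, "seed": rng_seed,
                    "config": dataclasses.asdict(cfg)}

    tree = sim.make_species_tree("nicotiana6")

    # ---- expression arm -------------------------------------------------
    counts, lengths, meta, truth = sim.simulate_expression(
        tree, n_genes=cfg.n_genes, module_size=cfg.module_size,
        effect_log2=cfg.effect_log2, batch_sd=cfg.batch_sd,
        dispersion=cfg.dispersion, seed=rng_seed,
    )
    factors = ex.tmm_factors(counts)
    fpkm = ex.fpkm_matrix(counts, lengths, factors)
    expressed = ex.filter_expressed(fpkm, cfg.fpkm_min, cfg.fpkm_min_samples)
    logfpkm = np.log2(fpkm.loc[expressed] + 1.0)
    adjusted = ex.batch_adjust(logfpkm, meta["species"], meta["treatment"])

    de_by_species = {}
    for sp in tree.leaf_names():
        cols = meta.index[meta["species"] == sp]
        de = ex.nb_exact_de(counts.loc[expressed, cols],
                            meta.loc[cols, "treatment"],
                            fc_threshold=cfg.fc_threshold, alpha=cfg.alpha)
        # orient fold changes as elicited vs control
        de_by_species[sp] = de
    report["n_expressed"] = int(len(expressed))
    report["de_counts"] = {sp: int(de.table["de"].sum())
                           for sp, de in de_by_species.items()}
    focal_de = de_by_species[cfg.focal_species]
    planted_kept = [g for g in truth.module_genes
                    if g in focal_de.table.index]
    report["de_counts_planted_recovery"] = (
        len(set(planted_kept) & set(focal_de.de_genes))
        / len(planted_kept) if planted_kept else float("nan"))

    top = cx.select_top_connected(adjusted, k=min(cfg.top_k, len(adjusted)),
                                  power=float(cfg.power or 6))
    if cfg.power is None:
        power, _sft = cx.pick_soft_power(adjusted.loc[top],
                                         r2_target=cfg.r2_target)
    else:
        power = int(cfg.power)
    net = cx.build_network(adjusted.loc[top], power)
    modules = cx.detect_modules(net, cfg.min_module_size, cfg.cut_height)
    elicited_cols = meta.index[meta["treatment"] == "FAC"]
    modules = cx.module_statistics(adjusted.loc[top], net, modules,
                                   cfg.kme_core, cfg.hub_fraction,
                                   hub_samples=elicited_cols)
    trait_table, trait_cors = cx.module_trait_correlation(
        adjusted.loc[top], modules, meta["trait"])

    planted = set(truth.module_genes)
    jaccard, best_label = 0.0, None
    for lab in modules.module_labels:
        got = set(modules.module_genes(lab))
        j = len(got & planted) / len(got | planted) if got | planted else 0.0
        if j > jaccard:
            jaccard, best_label = j, lab
    core_jaccard = 0.0
    if best_label is not None:
        core = set(modules.core) & set(modules.module_genes(best_label))
        if core | planted:
            core_jaccard = len(core & planted) / len(core | planted)
    report["network"] = {
        "power": int(power),
        "n_modules": len(modules.module_labels),
        "planted_jaccard": float(jaccard),
        "planted_core_jaccard": float(core_jaccard),
        "planted_module_label": best_label,
        "trait_top_module": (int(trait_table["mean_cor"].idxmax())
                             if len(trait_table) else None),
        "trait_rank_p": float(trait_table.attrs.get("focal_p", np.nan)),
    }

    edges = cx.export_edges(net, cfg.edge_cutoff)
    report["network"]["n_edges"] = int(len(edges))

    # preservation against an independent replicate of the same design
    counts2, lengths2, meta2, _ = sim.simulate_expression(
        tree, n_genes=cfg.n_genes, module_size=cfg.module_size,
        effect_log2=cfg.effect_log2, batch_sd=cfg.batch_sd,
        dispersion=cfg.dispersion, seed=rng_seed + 1000,
    )
    fpkm2 = ex.fpkm_matrix(counts2, lengths2, ex.tmm_factors(counts2))
    logfpkm2 = np.log2(fpkm2 + 1.0)
    adjusted2 = ex.batch_adjust(logfpkm2, meta2["species"],
                                meta2["treatment"])
    pres = cx.module_preservation(
        adjusted.loc[top], adjusted2.reindex(top).dropna(), modules,
        power=power, n_perm=cfg.n_perm, seed=rng_seed,
    )
    report["preservation"] = {
        str(lab): {"z_summary": r.z_summary, "p": r.p_value,
                   "p_is_floor": r.p_is_floor}
        for lab, r in pres.items()
    }

    # ---- phylogenomic arm ----------------------------------------------
    gene_trees, families, fam_truth = sim.simulate_gene_families(
        tree, n_families=cfg.n_families, dup_rate_per_branch=cfg.dup_rate,
        wgt_retention_prob=cfg.wgt_retention_prob, loss_prob=cfg.loss_prob,
        support_model=None, seed=rng_seed,
    )
    calls = []
    for gt in gene_trees:
        rec = pg.reconcile_lca(gt, tree)
        calls.extend(pg.call_all(rec, cfg.support_min))
    call_of = {c.gene: c for c in calls}
    truth_map = fam_truth.mrd_branch
    scored = [g for g in truth_map if g in call_of]
    agree = sum(1 for g in scored if call_of[g].branch == truth_map[g])
    single = [g for g in truth_map if g not in call_of]
    # genes in single-gene families have no tree: truth is no-duplication
    agree += sum(1 for g in single if truth_map[g] is None)
    total_genes = len(truth_map)
    report["reconciliation"] = {
        "n_genes": total_genes,
        "n_gene_trees": len(gene_trees),
        "branch_recovery": agree / total_genes if total_genes else np.nan,
    }

    focal = cfg.focal_species
    focal_genes = {g for fam_id, members in families for g in members
                   if members[g] == focal}
    retention, wgt_pairs = pg.classify_retention(
        calls, expressed=focal_genes, wgt_branch=cfg.wgt_branch,
        lineage_branches=tree.focal_labels - set(tree.leaf_names()),
        focal_species=focal, families=families, gene_trees=gene_trees,
    )
    paired_genes = {g for p in wgt_pairs for g in p}
    report["retention"] = {
        "n_focal_genes": len(focal_genes),
        "n_classified": int(len(retention)),
        "n_multi_copy": int(retention["multi_copy"].sum()),
        "n_wgt": int(retention["wgt_retained"].sum()),
        "n_nld": int(retention["nld_retained"].sum()),
        "n_wgt_pairs": len(wgt_pairs),
        "n_paired_genes": len(paired_genes),
        "pairs_times_two_equals_genes":
            2 * len(wgt_pairs) == len(paired_genes),
    }

    # Table-2-style layout on the synthetic run: map detected-module
    # expression genes onto focal family genes positionally
    focal_sorted = sorted(retention.index)
    module_set = set()
    if best_label is not None:
        det = sorted(modules.module_genes(best_label))
        gene_order = {g: i for i, g in enumerate(sorted(counts.index))}
        for g in det:
            i = gene_order[g]
            if i < len(focal_sorted):
                module_set.add(focal_sorted[i])
    synth_table = None
    if len(module_set) >= 5:
        rows = []
        n_set = len(module_set)
        n_genome = len(focal_sorted)
        for cat, col in (("multi_copy", "multi_copy"),
                         ("wgt", "wgt_retained"), ("nld", "nld_retained")):
            k_genome = int(retention[col].sum())
            k_set = int(retention.loc[sorted(module_set), col].sum())
            if 0 < k_set < n_set and 0 < k_genome < n_genome:
                res = en.category_odds_ratio(k_set, n_set, k_genome,
                                             n_genome)
                rows.append({"category": cat, "odds": res.odds,
                             "p_value": res.p_value,
                             "k_set": k_set, "n_set": n_set,
                             "k_genome": k_genome, "n_genome": n_genome})
        synth_table = rows
    report["retention"]["table2_style"] = synth_table

    obs_both = sum(1 for a, b in wgt_pairs
                   if a in module_set and b in module_set)
    m_in_module = sum(1 for g in paired_genes if g in module_set)
    if wgt_pairs and m_in_module:
        pr = en.pair_retention_chi2(len(wgt_pairs), m_in_module, obs_both)
        report["retention"]["pair_chi2_p"] = pr.p_value
    else:
        report["retention"]["pair_chi2_p"] = None

    # ---- sequence-evolution arm -----------------------------------------
    pairs, true_omega, true_ks = sim.simulate_codon_pairs(
        cfg.sim_omega, cfg.sim_ks, n_codons=cfg.n_codons,
        n_pairs=cfg.n_codon_pairs, seed=rng_seed,
    )
    results = [kk.ng86_kaks(a, b, f"pair{i}")
               for i, (a, b) in enumerate(pairs)]
    omegas = [r.omega for r in results if r.usable and r.omega is not None]
    sig = [r for r in results if r.usable and kk.omega_test(r) < 0.05]
    report["kaks"] = {
        "true_omega": true_omega, "true_ks": true_ks,
        "n_pairs": len(results),
        "n_usable": len(omegas),
        "median_omega": float(np.median(omegas)) if omegas else None,
        "median_ks": float(np.median([r.ks for r in results if r.usable])),
        "frac_omega_lt1_significant":
            len(sig) / len(omegas) if omegas else None,
    }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_counts

        write_counts(out / "counts.tsv", counts, lengths)
        meta.to_csv(out / "metadata.tsv", sep="\t")
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        module_table = pd.DataFrame({
            "module": modules.labels, "kme": modules.kme,
            "kim": modules.kim,
            "core": modules.labels.index.isin(modules.core),
            "hub": modules.labels.index.isin(modules.hubs),
        })
        module_table.index.name = "gene"
        module_table.to_csv(out / "modules.tsv", sep="\t")
        retention.to_csv(out / "retention.tsv", sep="\t")
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str))
    return report
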