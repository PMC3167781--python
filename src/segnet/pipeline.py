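"""End-to-end orchestration: simulate -> networks -> communities ->
linkage -> mediation -> report, driven by one YAML-serialisable config.

Stage outputs are plain TSVs plus a single JSON report whose headline
numbers (pair counts, edges, expected-by-chance, community sizes, linkage
counts per tier, mediation label counts) are all recomputable from the
stage tables.  Runs are deterministic for a fixed config: every stochastic
stage has its own seed and the report carries the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import segnet
from segnet import io, linkage, mediation, network, simulate
from segnet.communities import cpm_communities, merge_communities, scan_k

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seeds": {
        "architecture": 11,
        "genotypes": 12,
        "expression": 13,
        "network_protein": 14,
        "network_transcript": 15,
        "gene_correlation": 16,
        "linkage_protein": 17,
        "linkage_transcript": 18,
        "avoidance": 19,
    },
    "simulation": {
        "n_segregants": simulate.DEFAULT_N_SEGREGANTS,
        "n_markers": simulate.DEFAULT_N_MARKERS,
        "n_genes": simulate.DEFAULT_N_GENES,
        "recomb_prob": simulate.DEFAULT_RECOMB_PROB,
        "biological_sd": simulate.DEFAULT_BIO_SD,
        "technical_sd": simulate.DEFAULT_TECH_SD,
        "null_architecture": False,
    },
    "network": {"n_perm": 1000, "fpr": 0.01, "scheme": "random"},
    "communities": {"k_min": 3, "k_max": 40, "merge_jaccard": 0.8},
    "linkage": {"n_perm": 100, "fdr_levels": [0.05, 0.01], "min_gap": 100000},
    "cis": {"alpha": 0.01},
    "mediation": {"alpha": 0.05},
    "avoidance": {"n_perm": 10000, "bin_size": 20000},
    "bin_size": 20000,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        cfg = _merge(cfg, io.read_config(path))
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]


def expected_by_chance(n_items: int, rate: float) -> dict:
    """Expected false-positive count n_items * rate, raw and rounded."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    raw = n_items * rate
    return {"raw": raw, "rounded": int(round(raw))}


def fraction_genuine(edges: int, expected: float) -> float:
    """(edges - expected) / edges: the share of connections beyond chance."""
    if edges <= 0:
        raise ValueError("need at least one edge")
    return (edges - expected) / edges


def format_percent(x: float) -> str:
    """Whole percent at >= 10%, one decimal below (report presentation)."""
    pct = 100.0 * x
    return f"{pct:.0f}%" if pct >= 10 else f"{pct:.1f}%"


def intercommunity_stats(graph, community_a: set, community_b: set) -> dict:
    """Cross-community connection count vs the density expectation."""
    if community_a & community_b:
        raise ValueError(f"communities overlap: {sorted(community_a & community_b)[:5]}")
    nodes = set(graph.nodes)
    if not (community_a <= nodes and community_b <= nodes):
        raise ValueError("communities must be subsets of the graph's nodes")
    possible = len(community_a) * len(community_b)
    connected = sum(
        1 for a, b in graph.edges if (a in community_a) != (b in community_a)
        and {a, b} <= (community_a | community_b)
    )
    n = graph.number_of_nodes()
    total_pairs = n * (n - 1) // 2
    density = graph.number_of_edges() / total_pairs if total_pairs else 0.0
    return {
        "possible_pairs": possible,
        "connected_pairs": connected,
        "percent_connected": 100.0 * connected / possible if possible else 0.0,
        "expected_by_density": density * possible,
    }


def cis_excess_ratio(n_cis_a: int, n_cis_b: int, expected_fp: float) -> float:
    """Ratio of chance-corrected cis counts between two layers."""
    denom = n_cis_b - expected_fp
    if denom <= 0:
        raise ValueError("layer-b cis count does not exceed its chance expectation")
    return (n_cis_a - expected_fp) / denom


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Execute every stage on simulated data and write tables + report.

    Returns the report dict (also written to ``report.json``).  Outputs are
    byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = cfg["seeds"]
    sim = cfg["simulation"]
    report: dict = {
        "config_hash": config_hash(cfg),
        "segnet_version": segnet.__version__,
        "stages": {},
    }

    def stage(name):
        t0 = time.time()
        logger.info("stage %s started", name)
        return t0

    # --- simulate ---------------------------------------------------------
    t0 = stage("simulate")
    mm = simulate.default_marker_map(sim["n_markers"])
    geno = simulate.simulate_genotypes(
        sim["n_segregants"], mm, sim["recomb_prob"], seed=seeds["genotypes"]
    )
    if sim.get("null_architecture"):
        arch = simulate.null_architecture(sim["n_genes"], seed=seeds["architecture"])
    else:
        arch = simulate.default_study_architecture(seed=seeds["architecture"], n_genes=sim["n_genes"])
    transcripts, proteins = simulate.simulate_expression(
        geno, arch, sim["biological_sd"], sim["technical_sd"], seed=seeds["expression"]
    )
    io.write_genotypes(geno, outdir / "genotypes.tsv")
    io.write_expression(transcripts, outdir / "transcripts.tsv")
    io.write_expression(proteins, outdir / "proteins.tsv")
    io.write_architecture(arch, outdir / "architecture.json")
    prot_traits = proteins.to_traits()
    trans_traits = transcripts.to_traits()
    report["stages"]["simulate"] = {
        "n_segregants": geno.n_segregants,
        "n_markers": geno.n_markers,
        "n_genes": len(arch.gene_ids),
        "seconds": None,
    }
    logger.info("stage simulate done in %.1fs", time.time() - t0)

    # --- networks ---------------------------------------------------------
    t0 = stage("network")
    net_cfg = cfg["network"]
    nets = {}
    for layer, traits, seed in (
        ("protein", prot_traits, seeds["network_protein"]),
        ("transcript", trans_traits, seeds["network_transcript"]),
    ):
        res = network.build_connectivity(
            traits, n_perm=net_cfg["n_perm"], fpr=net_cfg["fpr"], seed=seed,
            scheme=net_cfg["scheme"],
        )
        res.pairs.to_csv(outdir / f"edges_{layer}.tsv", sep="\t", index=False, float_format="%.6g")
        nets[layer] = res
        deg = network.degree_summary(res.graph)
        expected = expected_by_chance(res.n_pairs, net_cfg["fpr"])
        report["stages"][f"network_{layer}"] = {
            "pairs_tested": res.n_pairs,
            "edges": res.n_edges,
            "expected_by_chance": expected["raw"],
            "expected_by_chance_rounded": expected["rounded"],
            "fraction_genuine": fraction_genuine(res.n_edges, expected["raw"])
            if res.n_edges
            else None,
            "degree": deg,
        }
    corr_table, corr_avg = network.gene_correlation_significance(
        prot_traits, trans_traits, n_perm=net_cfg["n_perm"], seed=seeds["gene_correlation"],
        scheme=net_cfg["scheme"],
    )
    corr_table.to_csv(outdir / "gene_correlation.tsv", sep="\t", index=False, float_format="%.6g")
    report["stages"]["gene_correlation"] = {
        "n_genes": len(corr_table),
        "n_sig05": int(corr_table["sig05"].sum()),
        "n_sig01": int(corr_table["sig01"].sum()),
        "percent_sig05": 100.0 * corr_table["sig05"].mean(),
        **corr_avg,
    }
    logger.info("stage network done in %.1fs", time.time() - t0)

    # --- communities ------------------------------------------------------
    t0 = stage("communities")
    comm_cfg = cfg["communities"]
    comm_rows = []
    comm_summary = {}
    for layer in ("protein", "transcript"):
        by_k, overview = scan_k(nets[layer].graph, comm_cfg["k_min"], comm_cfg["k_max"])
        overview.to_csv(outdir / f"communities_scan_{layer}.tsv", sep="\t", index=False)
        best_k = max((k for k, cs in by_k.items() if cs), default=None)
        merged = None
        if best_k is not None:
            merged = merge_communities(by_k[best_k], comm_cfg["merge_jaccard"])
        for k, comms in by_k.items():
            for c in comms:
                for g in sorted(c.members):
                    comm_rows.append(
                        {"layer": layer, "k": k, "community_id": c.community_id, "gene_id": g}
                    )
        comm_summary[layer] = {
            "max_k_with_community": best_k,
            "communities_at_max_k": len(by_k[best_k]) if best_k else 0,
            "merged_sizes_at_max_k": sorted((len(c.members) for c in merged), reverse=True)
            if merged
            else [],
        }
    pd.DataFrame(comm_rows).to_csv(outdir / "communities.tsv", sep="\t", index=False)
    report["stages"]["communities"] = comm_summary
    logger.info("stage communities done in %.1fs", time.time() - t0)

    # --- linkage ----------------------------------------------------------
    t0 = stage("linkage")
    lk = cfg["linkage"]
    deduped, groups = linkage.dedupe_markers(geno)
    report["stages"]["markers"] = {
        "total": geno.n_markers,
        "unique_patterns": deduped.n_markers,
    }
    linkages = {}
    for layer, traits, seed in (
        ("protein", prot_traits, seeds["linkage_protein"]),
        ("transcript", trans_traits, seeds["linkage_transcript"]),
    ):
        rec = linkage.permutation_fdr(
            traits, deduped, layer=layer, n_perm=lk["n_perm"],
            fdr_levels=tuple(lk["fdr_levels"]), seed=seed, min_gap=lk["min_gap"],
        )
        rec.to_csv(outdir / f"linkage_{layer}.tsv", sep="\t", index=False, float_format="%.6g")
        linkages[layer] = rec
        peaks = rec[(rec["fdr_tier"] != "none") & rec["is_peak"]]
        tiers = sorted(lk["fdr_levels"], reverse=True)
        tier_counts = {}
        for level in tiers:
            sub = peaks[[float(t) <= level for t in peaks["fdr_tier"]]]
            tier_counts[str(level)] = {
                "linkages": int(len(sub)),
                "traits_with_linkage": int(sub["trait"].nunique()),
            }
        hist = linkage.hotspot_histogram(rec, mm, bin_size=cfg["bin_size"])
        hist.to_csv(outdir / f"hotspots_{layer}.tsv", sep="\t", index=False)
        report["stages"][f"linkage_{layer}"] = {
            "tier_counts": tier_counts,
            "max_bin_count": int(hist["count"].max()),
        }
    # heritability over all genes, both layers
    her_rows = []
    for layer, expr in (("protein", proteins), ("transcript", transcripts)):
        for gene in expr.gene_ids:
            h = linkage.heritability(expr, gene)
            her_rows.append({"layer": layer, **h})
    her = pd.DataFrame(her_rows)
    her.to_csv(outdir / "heritability.tsv", sep="\t", index=False, float_format="%.6g")
    report["stages"]["heritability"] = {
        layer: {
            "mean": float(her.loc[her["layer"] == layer, "H"].mean()),
            "median": float(her.loc[her["layer"] == layer, "H"].median()),
        }
        for layer in ("protein", "transcript")
    }
    # cis scan
    gene_pos = arch.genes.rename(columns={})[["gene_id", "chromosome", "position"]]
    cis_counts = {}
    for layer, traits in (("protein", prot_traits), ("transcript", trans_traits)):
        cis_tab, exp_fp = linkage.cis_scan(traits, deduped, gene_pos, alpha=cfg["cis"]["alpha"])
        cis_tab.to_csv(outdir / f"cis_{layer}.tsv", sep="\t", index=False, float_format="%.6g")
        cis_counts[layer] = int(cis_tab["cis"].sum())
    report["stages"]["cis"] = {
        "alpha": cfg["cis"]["alpha"],
        "expected_false_positives": len(prot_traits.gene_ids) * cfg["cis"]["alpha"],
        "n_cis_protein": cis_counts["protein"],
        "n_cis_transcript": cis_counts["transcript"],
    }
    # avoidance test on the ribosomal community genes
    rib = set(arch.community_members("ribosomal"))
    try:
        avoid = linkage.shared_locus_avoidance(
            linkages["protein"], linkages["transcript"], rib,
            n_perm=cfg["avoidance"]["n_perm"], bin_size=cfg["avoidance"]["bin_size"],
            seed=seeds["avoidance"],
        )
    except ValueError as err:
        avoid = {"skipped": str(err)}
    report["stages"]["avoidance"] = avoid
    logger.info("stage linkage done in %.1fs", time.time() - t0)

    # --- mediation --------------------------------------------------------
    t0 = stage("mediation")
    med = mediation.mediation_table(
        prot_traits, trans_traits, deduped, linkages["protein"], alpha=cfg["mediation"]["alpha"]
    )
    med.to_csv(outdir / "mediation.tsv", sep="\t", index=False, float_format="%.6g")
    report["stages"]["mediation"] = {
        "n_tested": int(len(med)),
        "n_transcript_mediated": int((med["label"] == mediation.TRANSCRIPT_MEDIATED).sum()),
        "n_not_transcript_mediated": int(
            (med["label"] == mediation.NOT_TRANSCRIPT_MEDIATED).sum()
        ),
    }
    logger.info("stage mediation done in %.1fs", time.time() - t0)

    for st in report["stages"].values():
        if isinstance(st, dict):
            st.pop("seconds", None)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
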