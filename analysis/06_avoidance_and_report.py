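#!/usr/bin/env python
"""Shared-locus avoidance test and the machine-readable study report.

Asks whether the loci regulating ribosomal *proteins* and ribosomal
*transcripts* share 20-kb bins more or less often than chance (10,000
permutations), then assembles the headline numbers of every stage into
results/study/report.json.
"""

import json
from pathlib import Path

import pandas as pd

from segnet import io, linkage, pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def read_linkage(layer: str) -> pd.DataFrame:
    return pd.read_csv(OUT / f"linkage_{layer}.tsv", sep="\t", keep_default_na=False,
                       na_values=[""], dtype={"marker": str, "fdr_tier": str})


def main() -> None:
    cfg = pipeline.load_config()
    arch = io.read_architecture(OUT / "architecture.json")
    rec = {layer: read_linkage(layer) for layer in ("protein", "transcript")}

    rib = set(arch.community_members("ribosomal"))
    avoid = linkage.shared_locus_avoidance(
        rec["protein"], rec["transcript"], rib,
        n_perm=cfg["avoidance"]["n_perm"], bin_size=cfg["avoidance"]["bin_size"],
        seed=cfg["seeds"]["avoidance"],
    )
    print("ribosomal community, protein vs transcript regulatory loci:")
    print(f"  {avoid['observed_shared_bins']} shared 20-kb bins observed, "
          f"{avoid['null_mean']:.1f} expected under the null")
    print(f"  avoidance p = {avoid['p_low']:.4g} "
          f"({avoid['n_perm']} permutations; floor 1/{avoid['n_perm']})")

    summary: dict = {"config_hash": pipeline.config_hash(cfg), "avoidance": avoid}
    for layer in ("protein", "transcript"):
        edges = pd.read_csv(OUT / f"edges_{layer}.tsv", sep="\t")
        n_pairs = len(edges)
        n_edges = int(edges["connected"].sum())
        expected = pipeline.expected_by_chance(n_pairs, cfg["network"]["fpr"])
        peaks = rec[layer][(rec[layer]["fdr_tier"] != "none") & rec[layer]["is_peak"]]
        summary[layer] = {
            "pairs_tested": n_pairs,
            "edges": n_edges,
            "expected_by_chance": expected["raw"],
            "fraction_genuine": pipeline.fraction_genuine(n_edges, expected["raw"]),
            "linkages_fdr05": int(len(peaks)),
            "traits_with_linkage_fdr05": int(peaks["trait"].nunique()),
        }
    corr = pd.read_csv(OUT / "gene_correlation.tsv", sep="\t")
    summary["gene_correlation"] = {
        "n_sig05": int(corr["sig05"].sum()),
        "n_genes": len(corr),
        "percent_sig05": 100.0 * float(corr["sig05"].mean()),
    }
    (OUT / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    print(f"report written to {OUT / 'report.json'}")


if __name__ == "__main__":
    main()
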