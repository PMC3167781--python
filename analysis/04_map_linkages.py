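#!/usr/bin/env python
"""Map loci controlling protein and transcript levels.

Marker t tests against 1,969-odd unique segregation patterns, per-trait FDR
from 100 permutations (5% and 1% tiers), 20-kb hotspot histograms,
per-gene heritability, and the nearest-marker cis scan.
"""

from pathlib import Path

import pandas as pd

from segnet import io, linkage, pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    cfg = pipeline.load_config()
    lk, seeds = cfg["linkage"], cfg["seeds"]
    geno = io.read_genotypes(OUT / "genotypes.tsv")
    arch = io.read_architecture(OUT / "architecture.json")
    deduped, _ = linkage.dedupe_markers(geno)
    print(f"{geno.n_markers} markers, {deduped.n_markers} unique segregation patterns")

    for layer in ("protein", "transcript"):
        expr = io.read_expression(OUT / f"{layer}s.tsv")
        traits = expr.to_traits()
        rec = linkage.permutation_fdr(
            traits, deduped, layer=layer, n_perm=lk["n_perm"],
            fdr_levels=tuple(lk["fdr_levels"]), seed=seeds[f"linkage_{layer}"],
            min_gap=lk["min_gap"],
        )
        rec.to_csv(OUT / f"linkage_{layer}.tsv", sep="\t", index=False, float_format="%.6g")
        peaks = rec[(rec["fdr_tier"] != "none") & rec["is_peak"]]
        strict = peaks[peaks["fdr_tier"] == "0.01"]
        print(f"{layer}: {len(peaks)} linkages for {peaks['trait'].nunique()} traits at 5% FDR "
              f"({len(strict)} linkages / {strict['trait'].nunique()} traits at 1%)")
        hist = linkage.hotspot_histogram(rec, geno.markers, bin_size=cfg["bin_size"])
        hist.to_csv(OUT / f"hotspots_{layer}.tsv", sep="\t", index=False)
        top = hist.sort_values("count", ascending=False).head(3)
        bins = ", ".join(f"chr{r.chrom}:{r.start // 1000}-{r.end // 1000}kb ({r.count})"
                         for r in top.itertuples())
        print(f"  busiest 20-kb bins: {bins}")

        her = pd.DataFrame([linkage.heritability(expr, g) for g in expr.gene_ids])
        her.insert(0, "layer", layer)
        her.to_csv(OUT / f"heritability_{layer}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        print(f"  heritability mean {her['H'].mean():.2f}, median {her['H'].median():.2f}")

        cis_tab, exp_fp = linkage.cis_scan(
            traits, deduped, arch.genes[["gene_id", "chromosome", "position"]],
            alpha=cfg["cis"]["alpha"],
        )
        cis_tab.to_csv(OUT / f"cis_{layer}.tsv", sep="\t", index=False, float_format="%.6g")
        print(f"  cis (nearest-marker, alpha={cfg['cis']['alpha']}): "
              f"{int(cis_tab['cis'].sum())} genes ({exp_fp:.2f} false positives expected)")


if __name__ == "__main__":
    main()
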