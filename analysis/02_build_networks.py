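#!/usr/bin/env python
"""Build permutation-thresholded co-expression networks for both layers.

Every gene pair gets its own 1% FPR cutoff from 1,000 permutations; edges
require r above the pair's cutoff.  Also computes per-gene protein-
transcript correlation significance and the connectivity between the two
planted communities.
"""

from pathlib import Path

from segnet import io, network, pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    cfg = pipeline.load_config()
    net, seeds = cfg["network"], cfg["seeds"]
    arch = io.read_architecture(OUT / "architecture.json")
    traits = {
        layer: io.read_expression(OUT / f"{layer}s.tsv").to_traits()
        for layer in ("protein", "transcript")
    }

    graphs = {}
    for layer in ("protein", "transcript"):
        res = network.build_connectivity(
            traits[layer], n_perm=net["n_perm"], fpr=net["fpr"],
            seed=seeds[f"network_{layer}"], scheme=net["scheme"],
        )
        res.pairs.to_csv(OUT / f"edges_{layer}.tsv", sep="\t", index=False, float_format="%.6g")
        graphs[layer] = res
        deg = network.degree_summary(res.graph)
        expected = pipeline.expected_by_chance(res.n_pairs, net["fpr"])
        genuine = pipeline.fraction_genuine(res.n_edges, expected["raw"])
        print(f"{layer}: {res.n_edges} of {res.n_pairs} pairs connected "
              f"({expected['rounded']} expected by chance; "
              f"{pipeline.format_percent(genuine)} genuine)")
        print(f"  degree min {deg['min']:.0f} max {deg['max']:.0f} "
              f"mean {deg['mean']:.1f} median {deg['median']:.0f}")

    corr, avg = network.gene_correlation_significance(
        traits["protein"], traits["transcript"],
        n_perm=net["n_perm"], seed=seeds["gene_correlation"], scheme=net["scheme"],
    )
    corr.to_csv(OUT / "gene_correlation.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"protein-transcript correlation significant for "
          f"{int(corr['sig05'].sum())}/{len(corr)} genes at p<0.05 "
          f"({pipeline.format_percent(corr['sig05'].mean())}); "
          f"average cutoffs {avg['avg_cutoff05']:.2f} (0.05) / {avg['avg_cutoff01']:.2f} (0.01)")

    aa = set(arch.community_members("amino_acid"))
    rib = set(arch.community_members("ribosomal"))
    stats = pipeline.intercommunity_stats(graphs["protein"].graph, aa, rib)
    print(f"intercommunity (amino_acid x ribosomal, protein layer): "
          f"{stats['connected_pairs']} of {stats['possible_pairs']} pairs connected "
          f"({pipeline.format_percent(stats['percent_connected'] / 100)}; "
          f"{stats['expected_by_density']:.0f} expected from overall density)")


if __name__ == "__main__":
    main()
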