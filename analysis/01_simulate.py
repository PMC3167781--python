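#!/usr/bin/env python
"""Generate the default study: 95 segregants, 2,955 markers, 354 genes.

Writes genotypes, the regulatory architecture, and replicated transcript /
protein expression (2 biological x 2 technical) to results/study/.
"""

from pathlib import Path

import numpy as np

from segnet import io, linkage, pipeline, simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    cfg = pipeline.load_config()
    sim, seeds = cfg["simulation"], cfg["seeds"]
    OUT.mkdir(parents=True, exist_ok=True)

    mm = simulate.default_marker_map(sim["n_markers"])
    geno = simulate.simulate_genotypes(
        sim["n_segregants"], mm, sim["recomb_prob"], seed=seeds["genotypes"]
    )
    arch = simulate.default_study_architecture(seed=seeds["architecture"], n_genes=sim["n_genes"])
    transcripts, proteins = simulate.simulate_expression(
        geno, arch, sim["biological_sd"], sim["technical_sd"], seed=seeds["expression"]
    )

    io.write_genotypes(geno, OUT / "genotypes.tsv")
    io.write_architecture(arch, OUT / "architecture.json")
    io.write_expression(transcripts, OUT / "transcripts.tsv")
    io.write_expression(proteins, OUT / "proteins.tsv")
    io.write_config(cfg, OUT / "config.yaml")

    unique = linkage.dedupe_markers(geno)[0].n_markers
    tt = transcripts.to_traits().values
    fold = float(np.median(np.exp(tt.max(axis=1) - tt.min(axis=1))))
    print(f"simulated {geno.n_markers} markers x {geno.n_segregants} segregants "
          f"({unique} unique segregation patterns)")
    print(f"{len(arch.gene_ids)} genes: 36 ribosomal, 93 amino_acid, "
          f"{len(arch.gene_ids) - 129} background")
    print(f"median max/min transcript fold change across genes: {fold:.2f}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
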