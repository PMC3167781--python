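#!/usr/bin/env python
"""Does a locus control a protein through its transcript?

For every significant protein linkage peak, regress the protein on its own
transcript and re-test linkage on the residuals; linkages whose residual p
rises above 0.05 are transcript-mediated.
"""

from pathlib import Path

import pandas as pd

from segnet import io, linkage, mediation, pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    cfg = pipeline.load_config()
    geno = io.read_genotypes(OUT / "genotypes.tsv")
    arch = io.read_architecture(OUT / "architecture.json")
    deduped, _ = linkage.dedupe_markers(geno)
    prot = io.read_expression(OUT / "proteins.tsv").to_traits()
    trans = io.read_expression(OUT / "transcripts.tsv").to_traits()
    records = pd.read_csv(OUT / "linkage_protein.tsv", sep="\t", keep_default_na=False,
                          na_values=[""], dtype={"marker": str, "fdr_tier": str})

    med = mediation.mediation_table(prot, trans, deduped, records,
                                    alpha=cfg["mediation"]["alpha"])
    genes = arch.genes.set_index("gene_id")
    med["community"] = [genes.loc[g, "community"] for g in med["gene"]]
    med["transmission"] = [round(float(genes.loc[g, "transmission"]), 3) for g in med["gene"]]
    med.to_csv(OUT / "mediation.tsv", sep="\t", index=False, float_format="%.6g")

    n_med = int((med["label"] == mediation.TRANSCRIPT_MEDIATED).sum())
    print(f"{len(med)} protein linkages tested; {n_med} transcript-mediated, "
          f"{len(med) - n_med} not")
    by = med.groupby("community")["label"].value_counts()
    for (comm, label), n in by.items():
        print(f"  {comm:>10}: {n:3d} {label}")
    hi = med[med["transmission"] >= 0.8]
    if len(hi):
        frac = (hi["label"] == mediation.TRANSCRIPT_MEDIATED).mean()
        print(f"linkages of genes with transmission >= 0.8: "
              f"{pipeline.format_percent(frac)} transcript-mediated")


if __name__ == "__main__":
    main()
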