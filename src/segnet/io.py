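"""Readers and writers for the pipeline's plain-text formats.

* genotypes: TSV, rows = markers (marker_id, chrom, pos, then one column
  per segregant holding "BY"/"RM");
* expression: TSV, rows = genes (gene_id then <segregant>_b<1|2>_t<1|2>
  columns); empty cells mark missing replicates;
* architecture: JSON;
* annotations: GMT (term <tab> description <tab> gene ...);
* run config: YAML.

All readers validate and report the offending line/id on failure;
write -> read round-trips are lossless on canonical files.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from segnet.types import (
    ALLELE_CODES,
    ALLELE_NAMES,
    ExpressionSet,
    GenotypeMatrix,
    Hotspot,
    MarkerMap,
    RegulatoryArchitecture,
)

_REP_COL = re.compile(r"^(?P<seg>.+)_b(?P<bio>\d+)_t(?P<tech>\d+)$")


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    df = geno.markers.to_frame()
    df["length"] = [geno.markers.chrom_lengths[int(c)] for c in geno.markers.chromosome]
    alleles = pd.DataFrame(
        np.vectorize(ALLELE_NAMES.get)(geno.calls), columns=geno.segregant_ids
    )
    pd.concat([df, alleles], axis=1).to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str})
    fixed = ["marker", "chrom", "pos", "length"]
    for col in fixed:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        line = int(df.index[df["marker"] == dup][1]) + 2
        raise ValueError(f"{path}: duplicate marker id {dup!r} at line {line}")
    seg_cols = [c for c in df.columns if c not in fixed]
    calls = np.empty((len(df), len(seg_cols)), dtype=np.uint8)
    for j, col in enumerate(seg_cols):
        vals = df[col].astype(str)
        bad = ~vals.isin(ALLELE_CODES)
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValueError(
                f"{path}: bad allele {vals[bad].iloc[0]!r} in column {col} at line {line}"
            )
        calls[:, j] = vals.map(ALLELE_CODES).to_numpy()
    lengths = {
        int(c): int(df.loc[df["chrom"] == c, "length"].iloc[0]) for c in df["chrom"].unique()
    }
    mm = MarkerMap(
        df["marker"].to_numpy(dtype=object),
        df["chrom"].to_numpy(dtype=np.int64),
        df["pos"].to_numpy(dtype=np.int64),
        lengths,
    )
    return GenotypeMatrix(mm, seg_cols, calls)


def write_expression(expr: ExpressionSet, path: str | Path) -> None:
    cols = {}
    for si, seg in enumerate(expr.segregant_ids):
        for b in range(expr.n_bio):
            for t in range(expr.n_tech):
                cols[f"{seg}_b{b + 1}_t{t + 1}"] = expr.values[:, si, b, t]
    out = pd.DataFrame({"gene_id": expr.gene_ids, **cols})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_expression(path: str | Path) -> ExpressionSet:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        line = int(df.index[df["gene_id"] == dup][1]) + 2
        raise ValueError(f"{path}: duplicate gene id {dup!r} at line {line}")
    layout: dict[str, dict[tuple[int, int], str]] = {}
    max_b = max_t = 0
    for col in df.columns[1:]:
        m = _REP_COL.match(col)
        if not m:
            raise ValueError(f"{path}: malformed replicate column {col!r}")
        b, t = int(m["bio"]), int(m["tech"])
        layout.setdefault(m["seg"], {})[(b, t)] = col
        max_b, max_t = max(max_b, b), max(max_t, t)
    for col in df.columns[1:]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValueError(f"{path}: non-numeric cell in column {col} at line {line}")
    segs = list(layout)
    values = np.full((len(df), len(segs), max_b, max_t), np.nan)
    for si, seg in enumerate(segs):
        for (b, t), col in layout[seg].items():
            values[:, si, b - 1, t - 1] = pd.to_numeric(df[col]).to_numpy()
    return ExpressionSet(list(df["gene_id"]), segs, values)


def write_architecture(arch: RegulatoryArchitecture, path: str | Path) -> None:
    payload = {
        "genes": arch.genes.to_dict(orient="records"),
        "hotspots": [
            {
                "chromosome": h.chromosome,
                "position": h.position,
                "transcript_effects": h.transcript_effects,
                "protein_effects": h.protein_effects,
            }
            for h in arch.hotspots
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_architecture(path: str | Path) -> RegulatoryArchitecture:
    payload = json.loads(Path(path).read_text())
    genes = pd.DataFrame(payload["genes"])
    hotspots = [
        Hotspot(
            chromosome=h["chromosome"],
            position=h["position"],
            transcript_effects=dict(h.get("transcript_effects", {})),
            protein_effects=dict(h.get("protein_effects", {})),
        )
        for h in payload["hotspots"]
    ]
    return RegulatoryArchitecture(genes=genes, hotspots=hotspots)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT annotation sets: term -> gene set (descriptions dropped)."""
    terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: line {lineno}: GMT line needs term, description, >=1 gene")
        term = parts[0]
        if term in terms:
            raise ValueError(f"{path}: line {lineno}: duplicate term {term!r}")
        terms[term] = set(g for g in parts[2:] if g)
        if not terms[term]:
            raise ValueError(f"{path}: line {lineno}: term {term!r} has no genes")
    return terms


def write_gmt(terms: dict[str, set[str]], path: str | Path) -> None:
    lines = [
        "\t".join([term, term] + sorted(genes)) for term, genes in sorted(terms.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
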