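"""Synthetic segregant-cross generator.

Emulates the study design the downstream analysis assumes: 95 haploid
segregants from a BY x RM cross genotyped at ~2,955 biallelic markers on 16
chromosomes, with two technical replicates of two biological replicates of
log-scale protein and transcript measurements for 354 genes.  The default
regulatory architecture places two trans-acting hotspots (chromosomes 3 and
13) with opposite-sign effects on an "amino_acid" community of 93 genes
(transcript level, propagated to protein through per-gene transmission) and
a "ribosomal" community of 36 genes (direct protein level, transcripts
untouched).

Scale conventions
-----------------
Expression is simulated on the natural-log scale, so locus effects are
additive and a gene's fold variation across segregants is
``exp(max - min)`` of its segregant means.  Hotspot and cis effect sizes
are expressed in units of the within-gene SD of a *null* gene's
segregant-mean trait under the replicate layout,
``sd_ref = sqrt(bio_sd^2 / n_bio + tech_sd^2 / (n_bio * n_tech))``,
so "a 1.5 SD effect" detaches effect calibration from the noise settings.
With the default noise (bio_sd=0.24, tech_sd=0.15, 2x2 replicates)
sd_ref ~ 0.186 log-units, which puts the median max/min fold change of
segregant means across genes near the 2.7-fold transcript variation
typical of this cross.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from segnet.types import (
    ExpressionSet,
    GenotypeMatrix,
    Hotspot,
    MarkerMap,
    MonomorphicMarkerError,
    RegulatoryArchitecture,
)

# Approximate S. cerevisiae chromosome lengths (bp), ~12.1 Mb genome.
YEAST_CHROM_LENGTHS: dict[int, int] = {
    1: 230_218,
    2: 813_184,
    3: 316_620,
    4: 1_531_933,
    5: 576_874,
    6: 270_161,
    7: 1_090_940,
    8: 562_643,
    9: 439_888,
    10: 745_751,
    11: 666_816,
    12: 1_078_177,
    13: 924_431,
    14: 784_333,
    15: 1_091_291,
    16: 948_066,
}

DEFAULT_N_SEGREGANTS = 95
DEFAULT_N_MARKERS = 2_955
DEFAULT_N_GENES = 354
DEFAULT_RECOMB_PROB = 0.0115
DEFAULT_BIO_SD = 0.24
DEFAULT_TECH_SD = 0.15
N_BIO = 2
N_TECH = 2


def default_marker_map(
    n_markers: int = DEFAULT_N_MARKERS,
    chrom_lengths: dict[int, int] | None = None,
) -> MarkerMap:
    """Uniformly spaced markers allocated to chromosomes by length.

    Marker counts per chromosome are proportional to chromosome length
    (largest-remainder rounding so the total is exactly *n_markers*); within
    a chromosome markers sit at evenly spaced positions.
    """
    lengths = dict(chrom_lengths or YEAST_CHROM_LENGTHS)
    chroms = sorted(lengths)
    total = sum(lengths.values())
    raw = np.array([n_markers * lengths[c] / total for c in chroms])
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    remainder = raw - np.floor(raw)
    short = n_markers - counts.sum()
    if short > 0:
        for i in np.argsort(-remainder)[:short]:
            counts[i] += 1
    elif short < 0:
        for i in np.argsort(remainder):
            if counts[i] > 1 and short < 0:
                counts[i] -= 1
                short += 1
    ids, cc, pp = [], [], []
    for c, m in zip(chroms, counts):
        # evenly spaced, away from the telomeres
        pos = np.linspace(1, lengths[c], m + 2)[1:-1].astype(np.int64)
        pos = np.maximum.accumulate(np.maximum(pos, 1))
        pos += np.arange(m)  # guard strict monotonicity after int rounding
        for p in pos:
            ids.append(f"{c}_{int(p)}")
        cc.extend([c] * m)
        pp.extend(pos.tolist())
    return MarkerMap(
        np.array(ids, dtype=object),
        np.array(cc, dtype=np.int64),
        np.array(pp, dtype=np.int64),
        lengths,
    )


def simulate_genotypes(
    n_segregants: int,
    marker_map: MarkerMap,
    recomb_prob: float = DEFAULT_RECOMB_PROB,
    seed: int = 0,
    max_retries: int = 10,
) -> GenotypeMatrix:
    """Simulate haploid segregant genotypes as Markov chains along chromosomes.

    Each segregant's first allele on a chromosome is Bernoulli(0.5); the
    allele switches between adjacent markers with probability *recomb_prob*
    (per-interval Bernoulli recombination, no interference); chromosomes are
    independent.  A marker that comes out monomorphic is re-drawn iid
    Bernoulli(0.5) up to *max_retries* times (this breaks that single
    marker's linkage to its neighbours, and essentially never triggers at
    realistic panel sizes).
    """
    if not 0.0 <= recomb_prob <= 0.5:
        raise ValueError(f"recomb_prob must be in [0, 0.5], got {recomb_prob}")
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")
    if n_segregants < 2:
        raise ValueError("need at least 2 segregants")
    rng = np.random.default_rng(seed)
    calls = np.empty((len(marker_map), n_segregants), dtype=np.uint8)
    for c in np.unique(marker_map.chromosome):
        rows = np.nonzero(marker_map.chromosome == c)[0]
        m = len(rows)
        start = rng.random(n_segregants) < 0.5
        switches = rng.random((m - 1, n_segregants)) < recomb_prob
        states = np.empty((m, n_segregants), dtype=bool)
        states[0] = start
        if m > 1:
            # cumulative XOR of switch events gives the Markov chain
            flips = np.cumsum(switches, axis=0) % 2
            states[1:] = start[None, :] ^ flips.astype(bool)
        calls[rows] = states.astype(np.uint8)
    geno = GenotypeMatrix(marker_map, [f"seg{i + 1:03d}" for i in range(n_segregants)], calls)
    mono = geno.monomorphic()
    tries = 0
    while mono.any():
        tries += 1
        if tries > max_retries:
            bad = marker_map.marker_id[np.nonzero(mono)[0][0]]
            raise MonomorphicMarkerError(
                f"marker {bad} stayed monomorphic after {max_retries} resamples "
                f"(n_segregants={n_segregants} may be too small)"
            )
        redraw = (rng.random((int(mono.sum()), n_segregants)) < 0.5).astype(np.uint8)
        calls = geno.calls.copy()
        calls[mono] = redraw
        geno = GenotypeMatrix(marker_map, geno.segregant_ids, calls)
        mono = geno.monomorphic()
    return geno


def reference_sd(bio_sd: float, tech_sd: float, n_bio: int = N_BIO, n_tech: int = N_TECH) -> float:
    """SD of a null gene's segregant-mean trait; unit for effect sizes.

    Falls back to 1.0 (absolute log-units) in the noiseless limit.
    """
    s = float(np.sqrt(bio_sd**2 / n_bio + tech_sd**2 / (n_bio * n_tech)))
    return s if s > 0 else 1.0


def _locus_indicator(geno: GenotypeMatrix, chromosome: int, position: int) -> np.ndarray:
    lo = geno.markers.position[geno.markers.chromosome == chromosome]
    if len(lo) == 0 or not (lo.min() <= position <= lo.max()):
        raise ValueError(
            f"locus chr{chromosome}:{position} outside the marker map coordinate range"
        )
    return geno.calls[geno.markers.nearest_marker(chromosome, position)].astype(float)


def simulate_expression(
    genotypes: GenotypeMatrix,
    architecture: RegulatoryArchitecture,
    biological_sd: float = DEFAULT_BIO_SD,
    technical_sd: float = DEFAULT_TECH_SD,
    seed: int = 0,
    n_bio: int = N_BIO,
    n_tech: int = N_TECH,
) -> tuple[ExpressionSet, ExpressionSet]:
    """Generate paired (transcript, protein) replicated expression.

    Per gene g and segregant s, the genetic transcript signal is the sum of
    hotspot transcript effects times the RM-allele indicator at the nearest
    marker, plus any transcript-layer cis effect at the marker nearest the
    gene.  The per-biological-replicate true transcript adds biological
    noise; the true protein is ``transmission(g)`` times the true transcript
    (so transcript-level biological variation propagates) plus direct
    protein effects and an independent biological noise draw.  Observed
    values add technical noise per measurement.  Both layers share segregant
    ordering and replicate layout.
    """
    if biological_sd < 0 or technical_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    genes = architecture.genes
    if len(genes) == 0:
        raise ValueError("architecture has no genes")
    rng = np.random.default_rng(seed)
    n_genes = len(genes)
    n_seg = genotypes.n_segregants
    sd_ref = reference_sd(biological_sd, technical_sd, n_bio, n_tech)

    community = genes["community"].to_numpy()
    transmission = genes["transmission"].to_numpy(dtype=float)

    a_transcript = np.zeros((n_genes, n_seg))
    a_protein = np.zeros((n_genes, n_seg))
    for h in architecture.hotspots:
        x = _locus_indicator(genotypes, h.chromosome, h.position)
        for label, eff in h.transcript_effects.items():
            a_transcript[community == label] += eff * sd_ref * x
        for label, eff in h.protein_effects.items():
            a_protein[community == label] += eff * sd_ref * x
    for i, row in genes.iterrows():
        if row["cis_layer"] and row["cis_effect"]:
            # cis effect acts at the marker nearest the gene, wherever that is
            midx = genotypes.markers.nearest_marker(int(row["chromosome"]), int(row["position"]))
            x = genotypes.calls[midx].astype(float)
            if row["cis_layer"] == "transcript":
                a_transcript[i] += float(row["cis_effect"]) * sd_ref * x
            elif row["cis_layer"] == "protein":
                a_protein[i] += float(row["cis_effect"]) * sd_ref * x
            else:
                raise ValueError(f"unknown cis layer {row['cis_layer']!r}")

    shape_bio = (n_genes, n_seg, n_bio)
    e_bio_t = rng.normal(0.0, biological_sd, shape_bio)
    e_bio_p = rng.normal(0.0, biological_sd, shape_bio)
    true_t = a_transcript[:, :, None] + e_bio_t
    true_p = transmission[:, None, None] * true_t + a_protein[:, :, None] + e_bio_p

    shape_obs = (n_genes, n_seg, n_bio, n_tech)
    obs_t = true_t[..., None] + rng.normal(0.0, technical_sd, shape_obs)
    obs_p = true_p[..., None] + rng.normal(0.0, technical_sd, shape_obs)

    gene_ids = list(genes["gene_id"])
    seg_ids = list(genotypes.segregant_ids)
    return (
        ExpressionSet(gene_ids, seg_ids, obs_t),
        ExpressionSet(gene_ids, seg_ids, obs_p),
    )


def default_study_architecture(
    seed: int = 0,
    n_genes: int = DEFAULT_N_GENES,
    n_ribosomal: int | None = None,
    n_amino_acid: int | None = None,
    hotspot_transcript_effect: float = 1.5,
    hotspot_protein_effect: float = -1.5,
    minor_locus_chromosomes: tuple[int, ...] = (2, 5, 7, 15),
    minor_locus_effect: float = 0.8,
    frac_high_transmission: float = 0.25,
    n_cis_transcript: int | None = None,
    n_cis_protein: int | None = None,
    cis_effect: float = 1.5,
    chrom_lengths: dict[int, int] | None = None,
) -> RegulatoryArchitecture:
    """The default two-community hotspot architecture.

    Two hotspots (mid chromosome 3 and mid chromosome 13) raise every
    amino_acid transcript on the RM allele and directly lower every
    ribosomal protein — the diametrically opposed regulation the analysis
    is designed to expose.  Ribosomal *transcripts* are instead shaped by
    several minor loci of smaller effect on other chromosomes (their
    genetic regulation is many-loci/small-effect, disjoint from the loci
    that move the proteins — the configuration the shared-locus avoidance
    test is built to detect).  Transmission is near zero for ribosomal genes,
    high (uniform on [0.8, 1]) for a *frac_high_transmission* minority of
    amino_acid genes and moderate-to-low elsewhere, so transcript-mediated
    and non-transcript-mediated protein linkages coexist.  A subset of
    background genes carries cis effects (more transcript-layer than
    protein-layer, mirroring the relative rarity of protein cis linkage).
    Gene positions are drawn uniformly over the genome.

    Community and cis-gene counts default to the study proportions
    (36 ribosomal, 93 amino_acid, 47 transcript-cis, 9 protein-cis out of
    354) and scale with *n_genes* when left unset.
    """
    scale = n_genes / DEFAULT_N_GENES
    if n_ribosomal is None:
        n_ribosomal = max(2, round(36 * scale))
    if n_amino_acid is None:
        n_amino_acid = max(2, round(93 * scale))
    if n_cis_transcript is None:
        n_cis_transcript = round(47 * scale)
    if n_cis_protein is None:
        n_cis_protein = round(9 * scale)
    if n_ribosomal + n_amino_acid > n_genes:
        raise ValueError("community sizes exceed total gene count")
    lengths = dict(chrom_lengths or YEAST_CHROM_LENGTHS)
    rng = np.random.default_rng(seed)
    chroms = sorted(lengths)
    total = sum(lengths.values())

    n_bg = n_genes - n_ribosomal - n_amino_acid
    gene_ids = (
        [f"RIB{i + 1:03d}" for i in range(n_ribosomal)]
        + [f"AA{i + 1:03d}" for i in range(n_amino_acid)]
        + [f"BG{i + 1:03d}" for i in range(n_bg)]
    )
    communities = ["ribosomal"] * n_ribosomal + ["amino_acid"] * n_amino_acid + ["none"] * n_bg

    # uniform gene positions over the genome (margin keeps cis markers in range)
    offsets = rng.integers(0, total, size=n_genes)
    bounds = np.cumsum([lengths[c] for c in chroms])
    gchrom, gpos = [], []
    for off in offsets:
        ci = int(np.searchsorted(bounds, off, side="right"))
        start = bounds[ci - 1] if ci else 0
        within = int(off - start)
        within = min(max(within, 1_000), lengths[chroms[ci]] - 1_000)
        gchrom.append(chroms[ci])
        gpos.append(within)

    transmission = np.empty(n_genes)
    transmission[:n_ribosomal] = rng.uniform(0.0, 0.05, n_ribosomal)
    aa = slice(n_ribosomal, n_ribosomal + n_amino_acid)
    n_high = int(round(frac_high_transmission * n_amino_acid))
    t_aa = np.concatenate(
        [rng.uniform(0.8, 1.0, n_high), rng.uniform(0.0, 0.5, n_amino_acid - n_high)]
    )
    transmission[aa] = rng.permutation(t_aa)
    transmission[n_ribosomal + n_amino_acid :] = rng.uniform(0.0, 0.6, n_bg)

    cis_layer = [""] * n_genes
    cis_eff = np.zeros(n_genes)
    bg_idx = rng.permutation(np.arange(n_ribosomal + n_amino_acid, n_genes))
    if n_cis_transcript + n_cis_protein > n_bg:
        raise ValueError("not enough background genes for the requested cis effects")
    for i in bg_idx[:n_cis_transcript]:
        cis_layer[i] = "transcript"
        cis_eff[i] = cis_effect
    for i in bg_idx[n_cis_transcript : n_cis_transcript + n_cis_protein]:
        cis_layer[i] = "protein"
        cis_eff[i] = cis_effect

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "community": communities,
            "chromosome": gchrom,
            "position": gpos,
            "transmission": transmission,
            "cis_layer": cis_layer,
            "cis_effect": cis_eff,
        }
    )
    hotspots = [
        Hotspot(
            chromosome=3,
            position=lengths[3] // 2,
            transcript_effects={"amino_acid": hotspot_transcript_effect},
            protein_effects={"ribosomal": hotspot_protein_effect},
        ),
        Hotspot(
            chromosome=13,
            position=lengths[13] // 2,
            transcript_effects={"amino_acid": hotspot_transcript_effect},
            protein_effects={"ribosomal": hotspot_protein_effect},
        ),
    ]
    hotspots += [
        Hotspot(
            chromosome=c,
            position=lengths[c] // 2,
            transcript_effects={"ribosomal": minor_locus_effect},
        )
        for c in minor_locus_chromosomes
    ]
    return RegulatoryArchitecture(genes=genes, hotspots=hotspots)


def null_architecture(n_genes: int = DEFAULT_N_GENES, seed: int = 0) -> RegulatoryArchitecture:
    """Pure-noise variant: no hotspots, no cis effects, zero transmission."""
    arch = default_study_architecture(seed=seed, n_genes=n_genes, n_cis_transcript=0, n_cis_protein=0)
    genes = arch.genes.copy()
    genes["transmission"] = 0.0
    genes["cis_layer"] = ""
    genes["cis_effect"] = 0.0
    return RegulatoryArchitecture(genes=genes, hotspots=[])
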