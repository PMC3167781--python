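"""Marker-trait linkage mapping with permutation FDR, plus the
heritability / variance-explained estimators, hotspot histograms, the
nearest-marker cis scan, and the shared-locus avoidance permutation test.

Linkage uses two-sample t tests (Welch by default) of trait values split by
marker allele.  Per-trait FDR control follows the empirical-null count
ratio: with observed p-values over all unique markers and ``n_perm``
permuted rescans, FDR(theta) = mean permuted count of p <= theta divided by
the observed count; each trait's cutoff is the largest observed p with
FDR <= level.  Markers with identical (or fully complementary — the t test
is sign-symmetric) segregation patterns are collapsed to one representative
before scanning.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from segnet.types import ConstantTraitError, GenotypeMatrix, ExpressionSet, MarkerMap, TraitMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# marker deduplication

def dedupe_markers(genotypes: GenotypeMatrix) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Collapse markers sharing a segregation pattern (up to allele flip).

    Returns the reduced genotype matrix (left-most marker of each group by
    genomic order kept as representative) and the representative -> group
    members map.
    """
    calls = genotypes.calls
    # canonical form: flip so that the first segregant carries BY
    flip = calls[:, :1] == 1
    canon = np.where(flip, 1 - calls, calls)
    # np.unique's return_index points at the first occurrence, which is the
    # left-most marker in genomic order since markers are (chrom, pos)-sorted
    _, rep_idx, inverse = np.unique(canon, axis=0, return_index=True, return_inverse=True)
    ids = genotypes.markers.marker_id
    groups: dict[str, list[str]] = {str(ids[i]): [] for i in rep_idx}
    for i, g in enumerate(inverse):
        groups[str(ids[rep_idx[g]])].append(str(ids[i]))
    order = np.sort(rep_idx)
    reduced = GenotypeMatrix(
        genotypes.markers.subset(order), list(genotypes.segregant_ids), calls[order]
    )
    return reduced, groups


# ---------------------------------------------------------------------------
# t tests

def marker_t_test(
    trait: np.ndarray, marker: np.ndarray, equal_var: bool = False, marker_id: str = "?"
) -> tuple[float, float]:
    """Two-sample t test of trait values split by allele (BY=0 vs RM=1).

    Welch by default; two-sided p.  The sign convention is RM minus BY.
    """
    trait = np.asarray(trait, dtype=float)
    marker = np.asarray(marker)
    rm = trait[marker == 1]
    by = trait[marker == 0]
    if len(rm) < 2 or len(by) < 2:
        raise ValueError(
            f"marker {marker_id}: both allele groups need >= 2 segregants "
            f"(got RM={len(rm)}, BY={len(by)})"
        )
    res = stats.ttest_ind(rm, by, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def t_scan(Y: np.ndarray, G: np.ndarray, equal_var: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised t tests of every row of Y against every row of G.

    Y: (n_traits, n_segregants) trait values; G: (n_markers, n_segregants)
    0/1 allele calls.  Returns (t, p) arrays of shape (n_traits, n_markers);
    t is RM mean minus BY mean.
    """
    Y = np.asarray(Y, dtype=float)
    Gf = np.asarray(G, dtype=float)
    n1 = Gf.sum(axis=1)
    n0 = Gf.shape[1] - n1
    if np.any(n1 < 2) or np.any(n0 < 2):
        bad = np.nonzero((n1 < 2) | (n0 < 2))[0]
        raise ValueError(f"marker row(s) {bad.tolist()} have an allele group smaller than 2")
    s1 = Y @ Gf.T                      # (T, M) RM-group sums
    s0 = Y.sum(axis=1, keepdims=True) - s1
    q1 = (Y**2) @ Gf.T
    q0 = (Y**2).sum(axis=1, keepdims=True) - q1
    m1, m0 = s1 / n1, s0 / n0
    v1 = np.maximum(q1 - n1 * m1**2, 0.0) / (n1 - 1)
    v0 = np.maximum(q0 - n0 * m0**2, 0.0) / (n0 - 1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        se2 = sp2 * (1 / n1 + 1 / n0)
        df = np.broadcast_to(n1 + n0 - 2, se2.shape)
    else:
        a, b = v1 / n1, v0 / n0
        se2 = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (a**2 / (n1 - 1) + b**2 / (n0 - 1))
        df = np.where(np.isfinite(df), df, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(se2)
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * special.stdtr(df, -np.abs(t))
    return t, p


# ---------------------------------------------------------------------------
# variance explained & heritability

def variance_explained(trait: np.ndarray, marker: np.ndarray) -> float:
    """Between-allele-group sum of squares over total sum of squares.

    [i*(mean_RM - GM)^2 + j*(mean_BY - GM)^2] / sum_k (m_k - GM)^2, where i
    and j are the RM and BY group sizes among the k segregants.  Equals the
    squared point-biserial correlation between trait and allele.
    """
    trait = np.asarray(trait, dtype=float)
    marker = np.asarray(marker)
    rm, by = trait[marker == 1], trait[marker == 0]
    if len(rm) == 0 or len(by) == 0:
        raise ValueError("both allele groups must be nonempty")
    gm = trait.mean()
    total = float(((trait - gm) ** 2).sum())
    if total == 0:
        raise ConstantTraitError("zero total sum of squares; variance explained undefined")
    between = len(rm) * (rm.mean() - gm) ** 2 + len(by) * (by.mean() - gm) ** 2
    return float(between / total)


def heritability(measurements: ExpressionSet, gene_id: str) -> dict:
    """Strain-to-strain fraction of total measurement variance for one gene.

    H = sum_i n_i (x_i - GM)^2 / sum_j (m_j - GM)^2 with x_i the mean of
    strain i over its n_i available measurements, m_j the individual
    measurements (N in total) and GM the grand mean of all measurements.
    """
    vals, strain = measurements.measurements(gene_id)
    if len(vals) == 0:
        raise ValueError(f"no measurements for gene {gene_id}")
    n_i = np.bincount(strain, minlength=len(measurements.segregant_ids))
    used = n_i > 0
    if used.sum() < 2:
        raise ValueError(f"gene {gene_id}: need measurements from >= 2 strains")
    gm = vals.mean()
    total = float(((vals - gm) ** 2).sum())
    if total == 0:
        raise ConstantTraitError(f"gene {gene_id}: zero total sum of squares")
    sums = np.bincount(strain, weights=vals, minlength=len(n_i))
    x_i = np.divide(sums, n_i, out=np.zeros_like(sums), where=used)
    between = float((n_i[used] * (x_i[used] - gm) ** 2).sum())
    return {
        "gene_id": gene_id,
        "H": between / total,
        "N": int(len(vals)),
        "grand_mean": float(gm),
        "n_strains": int(used.sum()),
    }


# ---------------------------------------------------------------------------
# permutation FDR linkage scan

def _fdr_threshold(
    p_obs: np.ndarray, p_perm: np.ndarray, level: float, method: str = "count_ratio"
) -> float:
    """Largest observed p usable as cutoff with estimated FDR <= level.

    ``count_ratio`` (default): FDR(theta) = mean permuted count of p <=
    theta over the observed count, maximised over the observed p grid.
    ``max_stat``: genome-wide threshold at the *level*-quantile of the
    per-permutation minimum p (family-wise control; stricter).  Returns
    NaN when no threshold qualifies.
    """
    if method == "max_stat":
        cut = float(np.quantile(p_perm.min(axis=1), level))
        below = p_obs[p_obs <= cut]
        return float(below.max()) if len(below) else float("nan")
    if method != "count_ratio":
        raise ValueError(f"unknown FDR method {method!r}")
    thr = np.sort(p_obs)
    obs_counts = np.arange(1, len(thr) + 1)
    perm_sorted = np.sort(p_perm.ravel())
    perm_counts = np.searchsorted(perm_sorted, thr, side="right") / p_perm.shape[0]
    fdr = perm_counts / obs_counts
    ok = np.nonzero(fdr <= level)[0]
    return float(thr[ok[-1]]) if len(ok) else float("nan")


def permutation_fdr(
    traits: TraitMatrix,
    genotypes: GenotypeMatrix,
    layer: str = "protein",
    n_perm: int = 100,
    fdr_levels: tuple[float, float] = (0.05, 0.01),
    seed: int = 0,
    equal_var: bool = False,
    min_gap: int = 100_000,
    trait_chunk: int = 32,
    fdr_method: str = "count_ratio",
) -> pd.DataFrame:
    """Scan all unique markers for every trait and tier hits by permutation FDR.

    Returns one row per significant (trait, marker) pair at the loosest FDR
    level — columns trait, layer, marker, chrom, pos, t, p, var_explained,
    fdr_tier, locus_id — plus one ``fdr_tier='none'`` row per trait with no
    linkage, so every trait appears.  Contiguous significant markers within
    *min_gap* bp on one chromosome share a locus_id (peak = minimum p,
    left-most on ties).
    """
    if traits.segregant_ids != genotypes.segregant_ids:
        raise ValueError("trait and genotype segregant sets/order differ")
    if n_perm < 20:
        warnings.warn(
            f"n_perm={n_perm} gives coarse FDR resolution; >= 20 recommended", stacklevel=2
        )
    lo, hi = max(fdr_levels), min(fdr_levels)
    rng = np.random.default_rng(seed)
    G = genotypes.calls
    mm = genotypes.markers
    n_seg = len(traits.segregant_ids)
    rows: list[dict] = []
    for start in range(0, traits.n_genes, trait_chunk):
        block = traits.values[start : start + trait_chunk]
        nb = block.shape[0]
        # stack observed + permuted copies of each trait in the block
        perms = np.array([rng.permutation(n_seg) for _ in range(n_perm * nb)])
        permuted = np.take_along_axis(block.repeat(n_perm, axis=0), perms, axis=1)
        Y = np.concatenate([block, permuted], axis=0)
        t_all, p_all = t_scan(Y, G, equal_var=equal_var)
        t_obs, p_obs = t_all[:nb], p_all[:nb]
        p_perm = p_all[nb:].reshape(nb, n_perm, -1)
        for bi in range(nb):
            gene = traits.gene_ids[start + bi]
            cut_lo = _fdr_threshold(p_obs[bi], p_perm[bi], lo, fdr_method)
            cut_hi = _fdr_threshold(p_obs[bi], p_perm[bi], hi, fdr_method)
            sig = np.nonzero(p_obs[bi] <= cut_lo)[0] if np.isfinite(cut_lo) else np.array([], int)
            if len(sig) == 0:
                rows.append(
                    {
                        "trait": gene, "layer": layer, "marker": "", "chrom": 0, "pos": 0,
                        "t": np.nan, "p": np.nan, "var_explained": np.nan,
                        "fdr_tier": "none", "locus_id": "",
                    }
                )
                continue
            for mi in sig:
                tier = hi if (np.isfinite(cut_hi) and p_obs[bi, mi] <= cut_hi) else lo
                rows.append(
                    {
                        "trait": gene,
                        "layer": layer,
                        "marker": str(mm.marker_id[mi]),
                        "chrom": int(mm.chromosome[mi]),
                        "pos": int(mm.position[mi]),
                        "t": float(t_obs[bi, mi]),
                        "p": float(p_obs[bi, mi]),
                        "var_explained": variance_explained(block[bi], G[mi]),
                        "fdr_tier": str(tier),
                        "locus_id": "",
                    }
                )
    records = pd.DataFrame(
        rows,
        columns=[
            "trait", "layer", "marker", "chrom", "pos", "t", "p",
            "var_explained", "fdr_tier", "locus_id",
        ],
    )
    return collapse_to_loci(records, min_gap=min_gap)


def collapse_to_loci(records: pd.DataFrame, min_gap: int = 100_000) -> pd.DataFrame:
    """Assign locus ids: per trait, significant markers on one chromosome
    separated by < *min_gap* bp merge into one locus, represented by its
    minimum-p marker (left-most on ties).  ``is_peak`` marks representatives.
    """
    records = records.copy()
    records["is_peak"] = False
    for trait, idx in records.groupby("trait", sort=False).groups.items():
        sub = records.loc[idx]
        sig = sub[sub["fdr_tier"] != "none"].sort_values(["chrom", "pos"])
        locus_n = 0
        prev_chrom, prev_pos = None, None
        current: list = []

        def _close(group: list, n: int) -> None:
            block = records.loc[group]
            peak = block.sort_values(["p", "pos"]).index[0]
            lid = f"{trait}:L{n}"
            records.loc[group, "locus_id"] = lid
            records.loc[peak, "is_peak"] = True

        for ridx, row in sig.iterrows():
            if current and (row["chrom"] != prev_chrom or row["pos"] - prev_pos >= min_gap):
                locus_n += 1
                _close(current, locus_n)
                current = []
            current.append(ridx)
            prev_chrom, prev_pos = row["chrom"], row["pos"]
        if current:
            locus_n += 1
            _close(current, locus_n)
    return records


# ---------------------------------------------------------------------------
# hotspot histogram

def hotspot_histogram(
    records: pd.DataFrame, marker_map: MarkerMap, bin_size: int = 20_000, peaks_only: bool = True
) -> pd.DataFrame:
    """Count linkages per half-open genomic bin of *bin_size* bp.

    Bins tile each declared chromosome as [0, bin_size), [bin_size,
    2*bin_size), ... ordered chromosome 1 through 16; a linkage lands in the
    bin containing its (peak) marker position.  The counts sum to the
    number of linkages binned.
    """
    sig = records[records["fdr_tier"] != "none"]
    if peaks_only and "is_peak" in sig.columns:
        sig = sig[sig["is_peak"]]
    rows = []
    for c in sorted(marker_map.chrom_lengths):
        length = marker_map.chrom_lengths[c]
        for start in range(0, length, bin_size):
            rows.append({"chrom": c, "start": start, "end": min(start + bin_size, length)})
    bins = pd.DataFrame(rows)
    bins["count"] = 0
    index = {(r.chrom, r.start): i for i, r in bins.iterrows()}
    for _, rec in sig.iterrows():
        c, p = int(rec["chrom"]), int(rec["pos"])
        if c not in marker_map.chrom_lengths or p > marker_map.chrom_lengths[c]:
            raise ValueError(f"linkage position chr{c}:{p} beyond declared chromosome length")
        key = (c, (p // bin_size) * bin_size)
        bins.loc[index[key], "count"] += 1
    return bins


# ---------------------------------------------------------------------------
# cis scan

def cis_scan(
    traits: TraitMatrix,
    genotypes: GenotypeMatrix,
    gene_positions: pd.DataFrame,
    alpha: float = 0.01,
    equal_var: bool = False,
) -> tuple[pd.DataFrame, float]:
    """One t test per gene against the marker nearest the gene.

    *gene_positions* needs columns gene_id, chromosome, position.  Returns
    the per-gene table (gene, marker, t, p, cis) and the expected number of
    false positives n_genes * alpha.
    """
    pos = gene_positions.set_index("gene_id")
    rows = []
    for gi, gene in enumerate(traits.gene_ids):
        if gene not in pos.index:
            raise ValueError(f"no genomic position for gene {gene}")
        c = int(pos.loc[gene, "chromosome"])
        midx = genotypes.markers.nearest_marker(c, int(pos.loc[gene, "position"]))
        t, p = marker_t_test(
            traits.values[gi], genotypes.calls[midx], equal_var=equal_var,
            marker_id=str(genotypes.markers.marker_id[midx]),
        )
        rows.append(
            {
                "gene": gene,
                "marker": str(genotypes.markers.marker_id[midx]),
                "chrom": c,
                "t": t,
                "p": p,
                "cis": p < alpha,
            }
        )
    expected_fp = len(traits.gene_ids) * alpha
    return pd.DataFrame(rows), expected_fp


# ---------------------------------------------------------------------------
# shared-locus avoidance test

def _occupied_bins(records: pd.DataFrame, bin_size: int) -> list[tuple[int, int]]:
    sig = records[records["fdr_tier"] != "none"]
    if "is_peak" in sig.columns:
        sig = sig[sig["is_peak"]]
    return [
        (int(c), int(p) // bin_size) for c, p in zip(sig["chrom"], sig["pos"])
    ]


def shared_locus_avoidance(
    protein_records: pd.DataFrame,
    transcript_records: pd.DataFrame,
    gene_subset: set[str],
    n_perm: int = 10_000,
    bin_size: int = 20_000,
    seed: int = 0,
) -> dict:
    """Permutation test for regulatory-locus avoidance between layers.

    Observed statistic: the number of genomic bins holding at least one
    protein linkage AND at least one transcript linkage for the genes in
    *gene_subset*.  Null: each layer's subset linkages are re-assigned bins
    drawn (without replacement) from that layer's full genome-wide linkage
    bin distribution, n_perm times.  p_low is the fraction of permutations
    with shared count <= observed (avoidance); p_high the fraction >=
    observed (coincidence); ties count toward both, and the resolution
    floor is 1/n_perm.
    """
    pool_p = _occupied_bins(protein_records, bin_size)
    pool_t = _occupied_bins(transcript_records, bin_size)
    sub_p = _occupied_bins(protein_records[protein_records["trait"].isin(gene_subset)], bin_size)
    sub_t = _occupied_bins(
        transcript_records[transcript_records["trait"].isin(gene_subset)], bin_size
    )
    if not sub_p or not sub_t:
        raise ValueError("empty linkage record set for the gene subset in one layer")
    observed = len(set(sub_p) & set(sub_t))
    rng = np.random.default_rng(seed)
    # map bins to integer codes for fast occupancy intersection
    all_bins = {b: i for i, b in enumerate(sorted(set(pool_p) | set(pool_t)))}
    n_codes = len(all_bins)
    code_p = np.array([all_bins[b] for b in pool_p])
    code_t = np.array([all_bins[b] for b in pool_t])

    def _occupancy(codes: np.ndarray, n_draw: int, rounds: int) -> np.ndarray:
        """rounds x n_codes occupancy of *n_draw* records sampled w/o replacement."""
        occ = np.zeros((rounds, n_codes), dtype=bool)
        if n_draw >= len(codes):
            occ[:, np.unique(codes)] = True
            return occ
        keys = rng.random((rounds, len(codes)))
        picks = np.argpartition(keys, n_draw, axis=1)[:, :n_draw]
        rows = np.repeat(np.arange(rounds), n_draw)
        occ[rows, codes[picks].ravel()] = True
        return occ

    shared = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, min(n_perm, 64_000_000 // max(n_codes, 1)))
    done = 0
    while done < n_perm:
        rounds = min(chunk, n_perm - done)
        occ_p = _occupancy(code_p, len(sub_p), rounds)
        occ_t = _occupancy(code_t, len(sub_t), rounds)
        shared[done : done + rounds] = (occ_p & occ_t).sum(axis=1)
        done += rounds
    # resolution floor: the smallest reportable p is 1/n_perm
    p_low = max(float((shared <= observed).mean()), 1.0 / n_perm)
    p_high = max(float((shared >= observed).mean()), 1.0 / n_perm)
    return {
        "observed_shared_bins": observed,
        "p_low": p_low,
        "p_high": p_high,
        "n_perm": n_perm,
        "null_mean": float(shared.mean()),
    }
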