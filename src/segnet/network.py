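"""Permutation-thresholded Pearson co-expression networks.

Every unordered gene pair receives its own false-positive-rate cutoff from
a permutation null: one gene's segregant assignment is shuffled ``n_perm``
times and the cutoff is the ceil(n_perm * fpr)-th highest permuted
correlation (the "10th highest of 1,000" rule at 1% FPR); a pair is
connected iff its observed r is strictly above its own cutoff.  Network
edges are one-tailed (upper tail); per-gene protein-transcript correlation
significance is two-sided on |r| because genuinely negative correlations
occur.

The default permutation scheme draws uniform random permutations.  A
cyclic-shift scheme (segregant identities rotated by 1, 2, ...) is
available via ``scheme="cyclic"``; note only n-1 distinct non-trivial
rotations exist, so shifts repeat when n_perm > n-1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from segnet.types import ConstantTraitError, TraitMatrix

logger = logging.getLogger(__name__)

_CHUNK = 200  # permutation rounds held in memory at once during top-k reduction


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with explicit degenerate-input errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantTraitError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def _cutoff_rank(n_perm: int, fpr: float) -> int:
    """1-based rank from the top of the permuted distribution."""
    k = math.ceil(n_perm * fpr)
    if k < 1:
        raise ValueError(f"n_perm * fpr must be >= 1 (got {n_perm} * {fpr})")
    return k


def _permutations(n: int, n_perm: int, scheme: str, rng: np.random.Generator) -> np.ndarray:
    if scheme == "random":
        return np.array([rng.permutation(n) for _ in range(n_perm)])
    if scheme == "cyclic":
        shifts = (np.arange(n_perm) % (n - 1)) + 1
        return np.array([np.roll(np.arange(n), -s) for s in shifts])
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def pair_permutation_cutoff(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    fpr: float = 0.01,
    seed: int = 0,
    scheme: str = "random",
) -> float:
    """Upper-tail FPR cutoff for one gene pair.

    Shuffles *y*'s segregant assignment n_perm times; returns the
    ceil(n_perm*fpr)-th highest permuted r.  The observed pair is connected
    when r is strictly greater than this cutoff.
    """
    pearson(x, y)  # validates lengths and non-constancy
    k = _cutoff_rank(n_perm, fpr)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    perms = _permutations(len(y), n_perm, scheme, rng)
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    r = yc[perms] @ xc / len(x)
    return float(np.sort(r)[-k])


@dataclass(frozen=True)
class ConnectivityResult:
    """Graph plus the full per-pair record table."""

    graph: nx.Graph
    pairs: pd.DataFrame  # gene_a, gene_b, r, cutoff, connected

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _standardized(traits: TraitMatrix) -> np.ndarray:
    const = traits.constant_genes()
    if const:
        raise ConstantTraitError(
            f"constant trait vector for gene(s): {', '.join(const[:10])}"
        )
    v = traits.values
    z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)
    return z / np.sqrt(v.shape[1])  # rows unit-norm: R = Z @ Z.T


def build_connectivity(
    traits: TraitMatrix,
    n_perm: int = 1000,
    fpr: float = 0.01,
    seed: int = 0,
    scheme: str = "random",
) -> ConnectivityResult:
    """Evaluate all unordered gene pairs and keep edges above per-pair cutoffs.

    The permutation null is vectorised: each round independently shuffles
    every gene's segregant assignment and correlates the shuffled copy of
    gene a against the original gene b, giving each pair one null draw per
    round (exactly the single-pair null marginally).  Only the top
    ceil(n_perm*fpr) null values per pair are retained, in chunks, to bound
    memory.
    """
    g = traits.n_genes
    if g < 2:
        raise ValueError("need at least 2 genes to build a network")
    k = _cutoff_rank(n_perm, fpr)
    z = _standardized(traits)
    iu = np.triu_indices(g, 1)
    r_obs = (z @ z.T)[iu]

    rng = np.random.default_rng(seed)
    top: np.ndarray | None = None  # (n_pairs, <=k) best null values so far
    done = 0
    while done < n_perm:
        rounds = min(_CHUNK, n_perm - done)
        buf = np.empty((len(iu[0]), rounds))
        for j in range(rounds):
            if scheme == "random":
                zp = rng.permuted(z, axis=1)
            else:
                perm = _permutations(z.shape[1], done + j + 1, scheme, rng)[-1]
                zp = z[:, perm]
            buf[:, j] = (zp @ z.T)[iu]
        pool = buf if top is None else np.concatenate([top, buf], axis=1)
        if pool.shape[1] > k:
            pool = np.partition(pool, pool.shape[1] - k, axis=1)[:, -k:]
        top = pool
        done += rounds
    assert top is not None
    cutoffs = np.sort(top, axis=1)[:, 0] if top.shape[1] == k else np.sort(top, axis=1)[:, -k]

    connected = r_obs > cutoffs
    gene_ids = traits.gene_ids
    pairs = pd.DataFrame(
        {
            "gene_a": [gene_ids[i] for i in iu[0]],
            "gene_b": [gene_ids[j] for j in iu[1]],
            "r": r_obs,
            "cutoff": cutoffs,
            "connected": connected,
        }
    )
    graph = nx.Graph()
    graph.add_nodes_from(gene_ids)
    graph.add_edges_from(
        (gene_ids[i], gene_ids[j])
        for i, j, c in zip(iu[0], iu[1], connected)
        if c
    )
    logger.info(
        "connectivity: %d/%d pairs connected at FPR %.3g (%d permutations)",
        int(connected.sum()), len(r_obs), fpr, n_perm,
    )
    return ConnectivityResult(graph=graph, pairs=pairs)


def degree_summary(graph: nx.Graph) -> dict[str, float]:
    """Degree range/mean/median over all nodes (degree-0 included) + edges."""
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    if len(degrees) == 0:
        return {"min": 0.0, "max": 0.0, "mean": 0.0, "median": 0.0, "edges": 0}
    return {
        "min": float(degrees.min()),
        "max": float(degrees.max()),
        "mean": float(degrees.mean()),
        "median": float(np.median(degrees)),
        "edges": graph.number_of_edges(),
    }


def gene_correlation_significance(
    proteins: TraitMatrix,
    transcripts: TraitMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "random",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-gene protein-transcript correlation with permutation significance.

    For each gene the transcript vector is shuffled n_perm times; two-sided
    cutoffs at 0.05 and 0.01 are the ceil(n_perm*alpha)-th highest |permuted
    r|.  Returns the per-gene table (gene, r, cutoff05, cutoff01, sig05,
    sig01) and the across-gene average cutoffs.
    """
    pg, tg = set(proteins.gene_ids), set(transcripts.gene_ids)
    if pg != tg:
        raise ValueError(f"gene sets differ; symmetric difference: {sorted(pg ^ tg)}")
    if proteins.segregant_ids != transcripts.segregant_ids:
        raise ValueError("segregant sets/order differ between layers")
    order = [transcripts.gene_ids.index(g) for g in proteins.gene_ids]
    zp = _standardized(proteins)
    zt = _standardized(transcripts)[order]
    n = len(proteins.segregant_ids)
    r_obs = np.einsum("ij,ij->i", zp, zt) * 1.0  # rows are unit-norm

    k05 = _cutoff_rank(n_perm, 0.05)
    k01 = _cutoff_rank(n_perm, 0.01)
    rng = np.random.default_rng(seed)
    g = proteins.n_genes
    absr = np.empty((g, n_perm))
    for j in range(n_perm):
        if scheme == "random":
            ztp = rng.permuted(zt, axis=1)
        else:
            perm = _permutations(n, j + 1, scheme, rng)[-1]
            ztp = zt[:, perm]
        absr[:, j] = np.abs(np.einsum("ij,ij->i", zp, ztp))
    srt = np.sort(absr, axis=1)
    cut05 = srt[:, -k05]
    cut01 = srt[:, -k01]
    table = pd.DataFrame(
        {
            "gene": proteins.gene_ids,
            "r": r_obs,
            "cutoff05": cut05,
            "cutoff01": cut01,
            "sig05": np.abs(r_obs) > cut05,
            "sig01": np.abs(r_obs) > cut01,
        }
    )
    averages = {"avg_cutoff05": float(cut05.mean()), "avg_cutoff01": float(cut01.mean())}
    return table, averages


def sliding_window_correlation(
    transcript_abundance: np.ndarray,
    protein_abundance: np.ndarray,
    max_fold: float = 3.5,
    log_values: bool = True,
) -> tuple[list[dict], float, float]:
    """Across-gene correlation inside abundance-limited bins.

    Sorts genes by transcript abundance and greedily extends each bin while
    the max/min transcript ratio stays below *max_fold*; Pearson r is
    computed per bin (on log abundances by default) and averaged unweighted.
    Returns (per-bin records, mean binned r, global r).  Bins with fewer
    than 3 genes are skipped (and logged), since r is undefined there.
    """
    t = np.asarray(transcript_abundance, dtype=float)
    p = np.asarray(protein_abundance, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("abundance vectors must be 1-d and equal length")
    if np.any(t <= 0) or np.any(p <= 0):
        raise ValueError("abundances must be positive")
    order = np.argsort(t)
    ts, ps = t[order], p[order]
    xt = np.log(ts) if log_values else ts
    xp = np.log(ps) if log_values else ps

    bins: list[dict] = []
    rs: list[float] = []
    start = 0
    n = len(ts)
    while start < n:
        end = start
        while end < n and ts[end] / ts[start] < max_fold:
            end += 1
        size = end - start
        if size >= 3 and np.ptp(xt[start:end]) > 0 and np.ptp(xp[start:end]) > 0:
            r = pearson(xt[start:end], xp[start:end])
            bins.append(
                {"start_rank": start, "n_genes": size, "fold_span": ts[end - 1] / ts[start], "r": r}
            )
            rs.append(r)
        else:
            logger.info("skipping bin of %d gene(s) starting at rank %d", size, start)
        start = end
    mean_r = float(np.mean(rs)) if rs else float("nan")
    global_r = pearson(xt, xp)
    return bins, mean_r, global_r
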