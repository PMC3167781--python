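"""Core containers for the segregant-cross analysis.

All containers are thin, validated wrappers around numpy arrays / pandas
frames.  Alleles are stored as uint8 (0 = BY, the laboratory parent;
1 = RM, the vineyard parent); expression is stored on the natural-log scale
throughout, so additive locus effects correspond to fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BY = 0
RM = 1
ALLELE_NAMES = {BY: "BY", RM: "RM"}
ALLELE_CODES = {"BY": BY, "RM": RM}


class SegnetError(Exception):
    """Base class for segnet-specific errors."""


class ConstantTraitError(SegnetError):
    """A correlation or t-test was requested on a constant vector."""


class MonomorphicMarkerError(SegnetError):
    """A marker carries only one allele across segregants."""


@dataclass(frozen=True)
class MarkerMap:
    """Genomic marker coordinates on the 16 yeast chromosomes.

    Positions are 1-based base pairs and must be strictly increasing within
    a chromosome; marker ids must be unique.  ``chrom_lengths`` declares the
    chromosome ends used by genome-bin histograms; when omitted it defaults
    to the last marker position per chromosome.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    chrom_lengths: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mid = np.asarray(self.marker_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        pos = np.asarray(self.position, dtype=np.int64)
        if not (len(mid) == len(chrom) == len(pos)):
            raise ValueError("marker_id, chromosome and position must have equal length")
        if len(set(mid)) != len(mid):
            raise ValueError("marker ids are not unique")
        if len(pos) and pos.min() < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        order = np.lexsort((pos, chrom))
        if not np.array_equal(order, np.arange(len(pos))):
            raise ValueError("markers must be sorted by (chromosome, position)")
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)
        lengths = dict(self.chrom_lengths)
        for c in np.unique(chrom):
            last = int(pos[chrom == c].max())
            if c not in lengths:
                lengths[int(c)] = last
            elif lengths[int(c)] < last:
                raise ValueError(f"declared length of chromosome {c} shorter than its last marker")
        object.__setattr__(self, "chrom_lengths", lengths)

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def n_chromosomes(self) -> int:
        return len(np.unique(self.chromosome))

    def index_of(self, marker_id: str) -> int:
        hits = np.nonzero(self.marker_id == marker_id)[0]
        if len(hits) == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return int(hits[0])

    def nearest_marker(self, chromosome: int, position: int) -> int:
        """Row index of the marker nearest *position* on *chromosome*."""
        on_chrom = np.nonzero(self.chromosome == chromosome)[0]
        if len(on_chrom) == 0:
            raise ValueError(f"no markers on chromosome {chromosome}")
        dist = np.abs(self.position[on_chrom] - position)
        return int(on_chrom[np.argmin(dist)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker_id, "chrom": self.chromosome, "pos": self.position}
        )

    def subset(self, rows: np.ndarray) -> "MarkerMap":
        rows = np.asarray(rows)
        return MarkerMap(
            self.marker_id[rows],
            self.chromosome[rows],
            self.position[rows],
            dict(self.chrom_lengths),
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """Biallelic calls (marker x segregant) from the two-parent cross.

    ``calls[i, j]`` is 0 (BY) or 1 (RM) for marker i in segregant j.  The
    simulator guarantees no missing calls and both alleles present at every
    marker; analysis operations reject monomorphic markers explicitly.
    """

    markers: MarkerMap
    segregant_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.uint8)
        if calls.shape != (len(self.markers), len(self.segregant_ids)):
            raise ValueError(
                f"calls shape {calls.shape} != (n_markers={len(self.markers)}, "
                f"n_segregants={len(self.segregant_ids)})"
            )
        if calls.size and not np.isin(calls, [BY, RM]).all():
            raise ValueError("calls must be 0 (BY) or 1 (RM)")
        if len(set(self.segregant_ids)) != len(self.segregant_ids):
            raise ValueError("segregant ids are not unique")
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "segregant_ids", list(self.segregant_ids))

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_segregants(self) -> int:
        return self.calls.shape[1]

    def monomorphic(self) -> np.ndarray:
        """Boolean mask of markers with only one allele across segregants."""
        s = self.calls.sum(axis=1)
        return (s == 0) | (s == self.calls.shape[1])

    def marker_calls(self, marker_id: str) -> np.ndarray:
        return self.calls[self.markers.index_of(marker_id)]

    def reorder_segregants(self, new_order: list[str]) -> "GenotypeMatrix":
        idx = [self.segregant_ids.index(s) for s in new_order]
        return GenotypeMatrix(self.markers, list(new_order), self.calls[:, idx])


@dataclass(frozen=True)
class Hotspot:
    """A trans-acting locus with community-specific effects on both layers.

    Effect sizes are in units of the within-gene SD of a null gene's
    segregant-mean trait (see :func:`segnet.simulate.simulate_expression`).
    ``transcript_effects`` and ``protein_effects`` map community labels to
    the additive shift carried by the RM allele; the protein effects act
    directly, bypassing the transcript.
    """

    chromosome: int
    position: int
    transcript_effects: dict[str, float] = field(default_factory=dict)
    protein_effects: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class RegulatoryArchitecture:
    """Ground-truth regulatory structure for simulated expression.

    ``genes`` is a frame with columns gene_id, community (one of
    'ribosomal', 'amino_acid', 'none'), chromosome, position, transmission
    (in [0, 1]: the fraction of transcript variation that propagates into
    the protein), cis_layer ('' | 'transcript' | 'protein') and cis_effect
    (SD units, applied at the marker nearest the gene).
    """

    genes: pd.DataFrame
    hotspots: list[Hotspot]

    def __post_init__(self) -> None:
        required = {
            "gene_id",
            "community",
            "chromosome",
            "position",
            "transmission",
            "cis_layer",
            "cis_effect",
        }
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"architecture gene table missing columns: {sorted(missing)}")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in architecture")
        t = self.genes["transmission"].to_numpy(dtype=float)
        if len(t) and (np.any(t < 0) or np.any(t > 1)):
            raise ValueError("transmission must lie in [0, 1]")
        object.__setattr__(self, "genes", self.genes.reset_index(drop=True))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    def community_members(self, label: str) -> list[str]:
        return list(self.genes.loc[self.genes["community"] == label, "gene_id"])


@dataclass(frozen=True)
class ExpressionSet:
    """Replicated log-abundance values for one molecular layer.

    ``values`` has shape (gene, segregant, biological replicate, technical
    replicate); NaN marks a missing measurement (the simulator never
    produces one, but readers and the replicate-collapse tolerate them).
    """

    gene_ids: list[str]
    segregant_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4:
            raise ValueError("values must be 4-dimensional (gene, segregant, bio, tech)")
        if v.shape[0] != len(self.gene_ids) or v.shape[1] != len(self.segregant_ids):
            raise ValueError("values shape inconsistent with gene/segregant ids")
        if np.isinf(v).any():
            raise ValueError("expression values must be finite or NaN")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if len(set(self.segregant_ids)) != len(self.segregant_ids):
            raise ValueError("segregant ids are not unique")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_ids", list(self.gene_ids))
        object.__setattr__(self, "segregant_ids", list(self.segregant_ids))

    @property
    def n_bio(self) -> int:
        return self.values.shape[2]

    @property
    def n_tech(self) -> int:
        return self.values.shape[3]

    def to_traits(self) -> "TraitMatrix":
        """Collapse replicates to one segregant-level trait per gene.

        Technical replicates are averaged within each biological replicate
        first, then biological replicates are averaged, ignoring missing
        values at both steps — so the two biological replicates carry equal
        weight even under partial missingness.
        """
        with np.errstate(invalid="ignore"):
            bio_means = np.nanmean(self.values, axis=3)
            traits = np.nanmean(bio_means, axis=2)
        return TraitMatrix(self.gene_ids, self.segregant_ids, traits)

    def measurements(self, gene_id: str) -> tuple[np.ndarray, np.ndarray]:
        """All non-missing measurements for a gene with their strain indices."""
        g = self.gene_ids.index(gene_id)
        vals = self.values[g].reshape(len(self.segregant_ids), -1)
        strain = np.repeat(np.arange(vals.shape[0]), vals.shape[1])
        flat = vals.ravel()
        keep = ~np.isnan(flat)
        return flat[keep], strain[keep]

    def reorder_segregants(self, new_order: list[str]) -> "ExpressionSet":
        idx = [self.segregant_ids.index(s) for s in new_order]
        return ExpressionSet(self.gene_ids, list(new_order), self.values[:, idx])


@dataclass(frozen=True)
class TraitMatrix:
    """Segregant-level traits (gene x segregant), log scale."""

    gene_ids: list[str]
    segregant_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids), len(self.segregant_ids)):
            raise ValueError("trait matrix shape inconsistent with ids")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_ids", list(self.gene_ids))
        object.__setattr__(self, "segregant_ids", list(self.segregant_ids))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def constant_genes(self) -> list[str]:
        ptp = self.values.max(axis=1) - self.values.min(axis=1)
        return [g for g, c in zip(self.gene_ids, ptp == 0) if c]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.segregant_ids)
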