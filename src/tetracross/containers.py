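"""Core data containers: genetic maps and phased tetraploid haplotype sets.

A :class:`HaplotypeSet` stores the four phased haplotypes of every clone over
a shared biallelic marker panel, together with the :class:`GeneticMap` that
places each marker on a chromosome at a physical (bp) and genetic (Morgan)
position.  All downstream machinery (meiosis, trait values, cross scoring)
operates on these two containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Constant ploidy of all simulated material.
PLOIDY = 4

#: Maximum expected heterozygosity of a biallelic tetraploid locus,
#: attained at allele frequency 1/2: 1 - 2 * (1/2)**4.
HE_MAX_BIALLELIC = 0.875


def expected_heterozygosity(freq: np.ndarray) -> float:
    """Gene diversity of a biallelic tetraploid panel.

    Computes ``mean_j(1 - p_j**4 - (1 - p_j)**4)`` over markers, the
    tetraploid expected heterozygosity.  ``freq`` holds the frequency of
    the coded (allele-1) allele per marker.

    Parameters
    ----------
    freq
        Allele frequencies in ``[0, 1]``, one per marker.

    Returns
    -------
    float
        Mean per-marker gene diversity, in ``[0, 0.875]``.
    """
    p = np.asarray(freq, dtype=np.float64)
    if p.size == 0:
        raise ValueError("expected_heterozygosity requires at least one marker")
    return float(np.mean(1.0 - p**PLOIDY - (1.0 - p) ** PLOIDY))


@dataclass(frozen=True)
class GeneticMap:
    """Marker map: chromosome index, physical and genetic positions.

    Markers are stored in panel order: grouped by chromosome (ascending
    1-based chromosome index), physical position strictly increasing and
    genetic position non-decreasing within each chromosome.
    """

    chrom: np.ndarray  # int32 (m,), 1-based chromosome index
    pos_bp: np.ndarray  # int64 (m,), 1-based physical position
    pos_m: np.ndarray  # float64 (m,), genetic position in Morgans

    def __post_init__(self) -> None:
        chrom = np.ascontiguousarray(np.asarray(self.chrom, dtype=np.int32))
        pos_bp = np.ascontiguousarray(np.asarray(self.pos_bp, dtype=np.int64))
        pos_m = np.ascontiguousarray(np.asarray(self.pos_m, dtype=np.float64))
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos_bp", pos_bp)
        object.__setattr__(self, "pos_m", pos_m)
        if not (chrom.shape == pos_bp.shape == pos_m.shape) or chrom.ndim != 1:
            raise ValueError("chrom, pos_bp and pos_m must be 1-D arrays of equal length")
        if chrom.size == 0:
            raise ValueError("a GeneticMap must contain at least one marker")
        if np.any(np.diff(chrom) < 0):
            raise ValueError("markers must be grouped by ascending chromosome index")
        for sl in chrom_slices(chrom).values():
            if np.any(np.diff(pos_bp[sl]) <= 0):
                raise ValueError("physical positions must be strictly increasing within a chromosome")
            if np.any(np.diff(pos_m[sl]) < 0):
                raise ValueError("genetic positions must be non-decreasing within a chromosome")

    @property
    def n_markers(self) -> int:
        return int(self.chrom.size)

    @property
    def chromosomes(self) -> np.ndarray:
        """Distinct chromosome indices, ascending."""
        return np.unique(self.chrom)

    def chrom_slices(self) -> dict[int, slice]:
        """Mapping chromosome index -> slice of the marker panel."""
        return chrom_slices(self.chrom)

    def length_morgan(self, chromosome: int) -> float:
        sl = self.chrom_slices()[int(chromosome)]
        g = self.pos_m[sl]
        return float(g[-1] - g[0])

    def subset(self, idx: np.ndarray) -> "GeneticMap":
        """Map restricted to markers ``idx`` (kept in panel order)."""
        idx = _as_sorted_index(idx, self.n_markers)
        return GeneticMap(self.chrom[idx], self.pos_bp[idx], self.pos_m[idx])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"chrom": self.chrom, "pos_bp": self.pos_bp, "pos_morgan": self.pos_m}
        )

    @classmethod
    def from_frame(cls, frame) -> "GeneticMap":
        return cls(
            np.asarray(frame["chrom"]),
            np.asarray(frame["pos_bp"]),
            np.asarray(frame["pos_morgan"]),
        )


def chrom_slices(chrom: np.ndarray) -> dict[int, slice]:
    """Slices of a chromosome-grouped marker vector, keyed by chromosome."""
    out: dict[int, slice] = {}
    values, starts = np.unique(chrom, return_index=True)
    order = np.argsort(starts)
    starts = starts[order]
    values = values[order]
    bounds = np.append(starts, chrom.size)
    for v, a, b in zip(values, bounds[:-1], bounds[1:]):
        out[int(v)] = slice(int(a), int(b))
    return out


def _as_sorted_index(idx, m: int) -> np.ndarray:
    idx = np.asarray(idx)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    idx = idx.astype(np.intp)
    if idx.size and (idx.min() < 0 or idx.max() >= m):
        raise IndexError("marker index out of range")
    if np.any(np.diff(idx) < 0):
        idx = np.sort(idx)
    return idx


@dataclass
class HaplotypeSet:
    """Phased tetraploid genotypes of a set of clones on a shared panel.

    ``haplotypes`` has shape ``(n_clones, 4, m)`` with alleles coded 0/1;
    the four rows per clone are the phased homologs across the whole
    concatenated marker panel described by ``gmap``.
    """

    haplotypes: np.ndarray  # uint8 (n, 4, m)
    ids: np.ndarray  # (n,) clone identifiers (str)
    gmap: GeneticMap

    def __post_init__(self) -> None:
        hap = np.asarray(self.haplotypes, dtype=np.uint8)
        ids = np.asarray(self.ids, dtype=object)
        if hap.ndim != 3 or hap.shape[1] != PLOIDY:
            raise ValueError("haplotypes must have shape (n_clones, 4, n_markers)")
        if hap.shape[2] != self.gmap.n_markers:
            raise ValueError("haplotype panel width does not match the genetic map")
        if ids.shape != (hap.shape[0],):
            raise ValueError("ids must have one entry per clone")
        if hap.size and hap.max() > 1:
            raise ValueError("alleles must be coded 0/1")
        self.haplotypes = hap
        self.ids = ids

    @property
    def n_clones(self) -> int:
        return int(self.haplotypes.shape[0])

    @property
    def n_markers(self) -> int:
        return int(self.haplotypes.shape[2])

    def dosage(self, markers: np.ndarray | None = None) -> np.ndarray:
        """Allele-1 dosage per clone per marker, values in 0..4."""
        hap = self.haplotypes
        if markers is not None:
            hap = hap[:, :, np.asarray(markers, dtype=np.intp)]
        return hap.sum(axis=1, dtype=np.int16)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the coded allele per marker over all 4n haplotypes."""
        if self.n_clones == 0:
            raise ValueError("allele_freq of an empty clone set is undefined")
        return self.haplotypes.mean(axis=(0, 1), dtype=np.float64)

    def expected_heterozygosity(self) -> float:
        """Population gene diversity over the whole panel."""
        return expected_heterozygosity(self.allele_freq())

    def subset_clones(self, idx) -> "HaplotypeSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypeSet(self.haplotypes[idx], self.ids[idx], self.gmap)

    def subset_markers(self, idx) -> "HaplotypeSet":
        idx = _as_sorted_index(idx, self.n_markers)
        return HaplotypeSet(self.haplotypes[:, :, idx], self.ids, self.gmap.subset(idx))

    def index_of(self, clone_ids) -> np.ndarray:
        """Row indices of the given clone identifiers."""
        lookup = {cid: i for i, cid in enumerate(self.ids)}
        try:
            return np.array([lookup[c] for c in clone_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown clone id {exc.args[0]!r}") from exc

    @staticmethod
    def concatenate(sets: list["HaplotypeSet"]) -> "HaplotypeSet":
        """Stack clone sets sharing one marker panel."""
        if not sets:
            raise ValueError("need at least one HaplotypeSet")
        first = sets[0]
        for s in sets[1:]:
            if s.n_markers != first.n_markers:
                raise ValueError("marker panels differ")
        hap = np.concatenate([s.haplotypes for s in sets], axis=0)
        ids = np.concatenate([s.ids for s in sets])
        return HaplotypeSet(hap, ids, first.gmap)
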