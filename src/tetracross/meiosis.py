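"""Autotetraploid meiosis: bivalent pairing, Haldane crossovers, crosses.

Gamete formation follows the random-bivalent model: per chromosome the four
homologs are partitioned uniformly at random into two bivalents (three
possible pairings); each bivalent contributes one recombinant chromatid to
the gamete.  Crossovers on a chromatid form a Poisson process on the
genetic map (Haldane, no interference): the crossover count is Poisson in
the chromosome's map span and breakpoint positions are uniform on the map,
so the recombination fraction between two markers at distance ``d`` Morgans
is ``(1 - exp(-2 d)) / 2``.  Double reduction and preferential pairing are
absent, so single-locus gamete dosages follow the classical tetrasomic
segregation law (e.g. a duplex parent transmits dosage 0/1/2 with
probabilities 1/6, 2/3, 1/6 at an unlinked locus).

All randomness is drawn from a numpy ``Generator`` in a fixed order; the
compiled assembly kernel is deterministic given those draws, so gametes are
bit-reproducible for a fixed generator state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .containers import PLOIDY, GeneticMap, HaplotypeSet, chrom_slices

# The three ways to partition homologs {0,1,2,3} into two bivalents:
# code 0 -> (01)(23), 1 -> (02)(13), 2 -> (03)(12).


@njit(cache=True)
def _assemble_chrom(haps, par, pairing, starts, counts, bps, gpos, abs_cols, out):
    """Fill ``out[:, :, :]`` (G, 2, mc) with chromatid alleles for one chromosome.

    ``bps`` holds the flat breakpoint positions in (gamete, bivalent) order;
    each chromatid's slice is sorted in place and walked alongside the
    marker positions ``gpos``.
    """
    n_gam = par.shape[0]
    mc = gpos.shape[0]
    ptr = 0
    for i in range(n_gam):
        pr = par[i]
        code = pairing[i]
        if code == 0:
            hA0, hB0, hA1, hB1 = 0, 1, 2, 3
        elif code == 1:
            hA0, hB0, hA1, hB1 = 0, 2, 1, 3
        else:
            hA0, hB0, hA1, hB1 = 0, 3, 1, 2
        for b in range(2):
            k = counts[i, b]
            end = ptr + k
            for a in range(ptr + 1, end):  # insertion sort of the tiny slice
                key = bps[a]
                j = a - 1
                while j >= ptr and bps[j] > key:
                    bps[j + 1] = bps[j]
                    j -= 1
                bps[j + 1] = key
            if b == 0:
                hA, hB = hA0, hB0
            else:
                hA, hB = hA1, hB1
            s = starts[i, b]
            p = ptr
            for j in range(mc):
                g = gpos[j]
                while p < end and bps[p] < g:
                    s ^= 1
                    p += 1
                hom = hA if s == 0 else hB
                out[i, b, j] = haps[pr, hom, abs_cols[j]]
            ptr = end
    return out


def simulate_gametes_batch(
    haplotypes: np.ndarray,
    parent_of: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
    marker_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate one gamete per entry of ``parent_of``, vectorised.

    Parameters
    ----------
    haplotypes
        ``(n_parents, 4, m_full)`` phased parental haplotypes.
    parent_of
        ``(G,)`` parent row index for each gamete to produce.
    gmap
        Map of the full panel.
    rng
        Source of randomness; consumed in a fixed order, so results are
        reproducible for a fixed generator state.
    marker_idx
        Optional sorted subset of panel columns; gametes are generated only
        at those markers.  Restricting the panel is exact: the strand at a
        marker depends only on crossovers before it, so dropping
        intermediate markers does not change the marginal law at the kept
        ones.

    Returns
    -------
    ndarray
        ``(G, 2, m_sub)`` uint8 gamete haplotypes.
    """
    parent_of = np.ascontiguousarray(parent_of, dtype=np.int64)
    n_gam = parent_of.size
    haplotypes = np.ascontiguousarray(haplotypes, dtype=np.uint8)
    if marker_idx is None:
        cols = np.arange(gmap.n_markers, dtype=np.int64)
    else:
        cols = np.ascontiguousarray(marker_idx, dtype=np.int64)
    sub_chrom = gmap.chrom[cols]
    sub_pos = gmap.pos_m[cols]
    out = np.empty((n_gam, 2, cols.size), dtype=np.uint8)
    for sl in chrom_slices(sub_chrom).values():
        mc = sl.stop - sl.start
        if mc == 0:
            raise ValueError("empty chromosome in marker subset")
        gpos = np.ascontiguousarray(sub_pos[sl])
        span = float(gpos[-1] - gpos[0])
        pairing = rng.integers(0, 3, size=n_gam).astype(np.int8)
        starts = rng.integers(0, 2, size=(n_gam, 2)).astype(np.int8)
        if span > 0:
            counts = rng.poisson(span, size=(n_gam, 2)).astype(np.int64)
            bps = rng.uniform(gpos[0], gpos[-1], size=int(counts.sum()))
        else:
            counts = np.zeros((n_gam, 2), dtype=np.int64)
            bps = np.empty(0, dtype=np.float64)
        _assemble_chrom(
            haplotypes,
            parent_of,
            pairing,
            starts,
            counts,
            bps,
            gpos,
            np.ascontiguousarray(cols[sl]),
            out[:, :, sl],
        )
    return out


def simulate_gamete(
    parent: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One gamete (``(2, m)`` haplotypes) from a single ``(4, m)`` parent."""
    parent = np.asarray(parent, dtype=np.uint8)
    if parent.ndim != 2 or parent.shape[0] != PLOIDY:
        raise ValueError("parent must be a (4, m) haplotype array")
    return simulate_gametes_batch(parent[None], np.zeros(1, dtype=np.intp), gmap, rng)[0]


def make_cross(
    p1: np.ndarray,
    p2: np.ndarray,
    n_progeny: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    ids: list[str] | None = None,
) -> HaplotypeSet:
    """Progeny of a biparental cross: one gamete from each parent per clone.

    Parameters are the two parents' ``(4, m)`` haplotype arrays; ``n_progeny``
    clones are returned, each holding the two maternal plus two paternal
    chromatids.
    """
    if n_progeny <= 0:
        raise ValueError("n_progeny must be positive")
    p1 = np.asarray(p1, dtype=np.uint8)
    p2 = np.asarray(p2, dtype=np.uint8)
    if np.array_equal(p1, p2):
        raise ValueError("self-crosses are not permitted")
    parents = np.stack([p1, p2])
    zeros = np.zeros(n_progeny, dtype=np.intp)
    g1 = simulate_gametes_batch(parents, zeros, gmap, rng)
    g2 = simulate_gametes_batch(parents, zeros + 1, gmap, rng)
    hap = np.concatenate([g1, g2], axis=1)
    if ids is None:
        ids = [f"prog{i:05d}" for i in range(n_progeny)]
    return HaplotypeSet(hap, np.asarray(ids, dtype=object), gmap)


def progeny_for_crosses(
    hs: HaplotypeSet,
    pairs: np.ndarray,
    n_per_cross: int,
    rng: np.random.Generator,
    marker_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate ``n_per_cross`` progeny for many crosses in one batch.

    ``pairs`` is ``(n_cross, 2)`` clone row indices into ``hs``.  Returns a
    ``(n_cross * n_per_cross, 4, m_sub)`` uint8 array grouped by cross; the
    two gametes of a progeny come from pairs[:, 0] and pairs[:, 1]
    respectively.
    """
    pairs = np.asarray(pairs, dtype=np.intp)
    if n_per_cross <= 0:
        raise ValueError("n_per_cross must be positive")
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be (n_cross, 2)")
    if np.any(pairs[:, 0] == pairs[:, 1]):
        raise ValueError("self-crosses are not permitted")
    par1 = np.repeat(pairs[:, 0], n_per_cross)
    par2 = np.repeat(pairs[:, 1], n_per_cross)
    g1 = simulate_gametes_batch(hs.haplotypes, par1, hs.gmap, rng, marker_idx)
    g2 = simulate_gametes_batch(hs.haplotypes, par2, hs.gmap, rng, marker_idx)
    return np.concatenate([g1, g2], axis=1)
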