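"""Founder panels: synthetic generation, VCF ingest and marker thinning.

The synthetic generator emulates the kind of starting material a tetraploid
clonal breeding program works from: a modest number of phased tetraploid
clones genotyped on a multi-chromosome biallelic panel with a genetic map
and all minor allele frequencies above a floor.  Linkage disequilibrium is
induced by several generations of random mating run through the meiosis
module, so nearby markers end up correlated in a map-consistent way.

Real material enters through :func:`read_phased_vcf`, which accepts a
phased multi-sample VCF with ploidy-4 genotypes plus a per-marker genetic
map table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PLOIDY, GeneticMap, HaplotypeSet
from .meiosis import simulate_gametes_batch

logger = logging.getLogger(__name__)

#: Default physical chromosome length used to place synthetic markers (bp).
DEFAULT_CHROM_BP = 70_000_000


def generate_founders(
    n_founders: int = 80,
    n_chrom: int = 12,
    markers_per_chrom: int = 200,
    map_length_per_chrom: float = 1.0,
    maf_min: float = 0.05,
    burnin_generations: int = 10,
    seed: int = 0,
    chrom_length_bp: int = DEFAULT_CHROM_BP,
    surplus: float = 2.0,
) -> HaplotypeSet:
    """Generate a phased tetraploid founder panel with a linear genetic map.

    Per-marker allele frequencies are drawn uniformly on
    ``[maf_min, 1 - maf_min]``, haplotypes sampled independently per
    haplotype copy, and the panel is then passed through
    ``burnin_generations`` of random mating (via tetraploid meiosis) to
    build up linkage disequilibrium.  Markers whose realised minor allele
    frequency drops below ``maf_min`` during the burn-in are discarded; a
    surplus of candidate markers is simulated so that exactly
    ``markers_per_chrom`` survivors per chromosome can be retained.

    The genetic map is linear: ``map_length_per_chrom`` Morgans spread
    proportionally to physical position along each chromosome.

    Returns a :class:`HaplotypeSet` whose ``gmap`` attribute carries the map.
    """
    if n_founders < 2:
        raise ValueError("n_founders must be at least 2")
    if n_chrom < 1 or markers_per_chrom < 1:
        raise ValueError("n_chrom and markers_per_chrom must be positive")
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    if map_length_per_chrom < 0:
        raise ValueError("map length must be non-negative")
    rng = np.random.default_rng(seed)

    m_cand = max(markers_per_chrom + 4, int(np.ceil(markers_per_chrom * surplus)))
    chrom = np.repeat(np.arange(1, n_chrom + 1, dtype=np.int32), m_cand)
    pos_bp = np.concatenate(
        [_sample_positions(m_cand, chrom_length_bp, rng) for _ in range(n_chrom)]
    )
    pos_m = np.concatenate(
        [
            pos_bp[chrom == c] / chrom_length_bp * map_length_per_chrom
            for c in range(1, n_chrom + 1)
        ]
    )
    gmap = GeneticMap(chrom, pos_bp, pos_m)

    freq = rng.uniform(maf_min, 1.0 - maf_min, size=gmap.n_markers)
    hap = (rng.random((n_founders, PLOIDY, gmap.n_markers)) < freq).astype(np.uint8)
    hap = _random_mating(hap, gmap, burnin_generations, rng)

    p = hap.mean(axis=(0, 1))
    keep_mask = np.minimum(p, 1.0 - p) >= maf_min if maf_min > 0 else (p > 0) & (p < 1)
    keep: list[np.ndarray] = []
    for c, sl in gmap.chrom_slices().items():
        ok = np.flatnonzero(keep_mask[sl]) + sl.start
        failed = np.flatnonzero(~keep_mask[sl]) + sl.start
        if ok.size >= markers_per_chrom:
            # deterministic evenly spaced thinning of the survivors keeps coverage
            pick = np.linspace(0, ok.size - 1, markers_per_chrom).round().astype(np.intp)
            keep.append(ok[np.unique(pick)])
            continue
        # low-MAF columns are resampled in place (fresh frequency and fresh
        # haplotype draws; such columns carry no burn-in LD)
        deficit = markers_per_chrom - ok.size
        if deficit > failed.size:
            raise ValueError(
                f"chromosome {c}: cannot reach {markers_per_chrom} markers"
            )
        refill = failed[:deficit]
        for col in refill:
            hap[:, :, col] = _resample_column(n_founders, maf_min, rng)
        keep.append(np.sort(np.concatenate([ok, refill])))
    idx = np.concatenate(keep)
    ids = np.array([f"F{i:03d}" for i in range(n_founders)], dtype=object)
    return HaplotypeSet(hap, ids, gmap).subset_markers(idx)


def _resample_column(
    n_founders: int, maf_min: float, rng: np.random.Generator, max_tries: int = 5000
) -> np.ndarray:
    """One marker column meeting the realised MAF floor (polymorphic)."""
    copies = 4 * n_founders
    for _ in range(max_tries):
        u = rng.uniform(maf_min, 1.0 - maf_min) if maf_min > 0 else rng.uniform(0.05, 0.95)
        col = (rng.random((n_founders, PLOIDY)) < u).astype(np.uint8)
        realized = col.sum() / copies
        minor = min(realized, 1.0 - realized)
        if (maf_min > 0 and minor >= maf_min) or (maf_min == 0 and 0 < realized < 1):
            return col
    raise RuntimeError(
        f"could not resample a marker with minor allele frequency >= {maf_min} "
        f"in {max_tries} tries"
    )


def _sample_positions(m: int, length_bp: int, rng: np.random.Generator) -> np.ndarray:
    """``m`` distinct sorted 1-based positions on a chromosome."""
    if m > length_bp:
        raise ValueError("more markers than base pairs")
    pos: np.ndarray = np.unique(rng.integers(1, length_bp + 1, size=2 * m))
    while pos.size < m:  # vanishingly rare for m << length_bp
        extra = rng.integers(1, length_bp + 1, size=m)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=m, replace=False))


def _random_mating(
    hap: np.ndarray, gmap: GeneticMap, generations: int, rng: np.random.Generator
) -> np.ndarray:
    """Random non-self mating keeping a constant census."""
    n = hap.shape[0]
    for _ in range(generations):
        p1 = rng.integers(0, n, size=n)
        p2 = rng.integers(0, n - 1, size=n)
        p2[p2 >= p1] += 1  # exclude selfing
        g1 = simulate_gametes_batch(hap, p1, gmap, rng)
        g2 = simulate_gametes_batch(hap, p2, gmap, rng)
        hap = np.concatenate([g1, g2], axis=1)
    return hap


def thin_markers(hs: HaplotypeSet, window_bp: int, seed: int) -> HaplotypeSet:
    """Keep one random marker per non-overlapping physical window.

    Windows are half-open, 1-based: ``[1 + k*window_bp, 1 + (k+1)*window_bp)``
    per chromosome; within each occupied window one marker is retained
    uniformly at random.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rng = np.random.default_rng(seed)
    gmap = hs.gmap
    win = (gmap.pos_bp - 1) // window_bp
    keep = []
    for c, sl in gmap.chrom_slices().items():
        w = win[sl]
        for value in np.unique(w):
            members = np.flatnonzero(w == value) + sl.start
            keep.append(members[rng.integers(0, members.size)])
    return hs.subset_markers(np.sort(np.array(keep, dtype=np.intp)))


@dataclass
class IngestReport:
    """Per-record rejections produced while reading a VCF."""

    n_read: int = 0
    n_kept: int = 0
    rejected: list[tuple[str, int, str]] = field(default_factory=list)  # (chrom, pos, reason)

    def reject(self, chrom: str, pos: int, reason: str) -> None:
        self.rejected.append((chrom, pos, reason))
        logger.warning("rejected %s:%d (%s)", chrom, pos, reason)


def read_map_table(path) -> pd.DataFrame:
    """Read a tab-separated map table with columns chrom, pos_bp, pos_morgan."""
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos_bp", "pos_morgan"} - set(tab.columns)
    if missing:
        raise ValueError(f"map table lacks columns: {sorted(missing)}")
    return tab


def read_phased_vcf(path, map_table) -> tuple[HaplotypeSet, IngestReport]:
    """Read phased ploidy-4 genotypes from a VCF plus a genetic-map table.

    Records that are not biallelic, carry an unphased or non-tetraploid or
    missing genotype in any sample, or are absent from the map table are
    rejected individually and listed in the returned :class:`IngestReport`.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped) with ``GT`` fields like ``0|1|0|0``.
    map_table
        Path to a tab-separated table (chrom, pos_bp, pos_morgan) or an
        equivalent :class:`pandas.DataFrame`; chromosome labels must match
        the VCF CHROM column and are numbered 1..C in table order.

    Returns
    -------
    (HaplotypeSet, IngestReport)
    """
    import pysam

    if not isinstance(map_table, pd.DataFrame):
        map_table = read_map_table(map_table)
    chrom_order = list(dict.fromkeys(map_table["chrom"].astype(str)))
    chrom_index = {c: i + 1 for i, c in enumerate(chrom_order)}
    map_lookup = {
        (str(row.chrom), int(row.pos_bp)): float(row.pos_morgan)
        for row in map_table.itertuples()
    }

    report = IngestReport()
    columns: list[np.ndarray] = []
    meta: list[tuple[int, int, float]] = []  # (chrom_idx, pos_bp, pos_m)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError("VCF contains no samples")
        for rec in vcf:
            report.n_read += 1
            if rec.alts is None or len(rec.alts) != 1:
                report.reject(rec.chrom, rec.pos, "not biallelic")
                continue
            key = (str(rec.chrom), int(rec.pos))
            if key not in map_lookup:
                report.reject(rec.chrom, rec.pos, "missing from map table")
                continue
            col = np.empty((len(samples), PLOIDY), dtype=np.uint8)
            ok = True
            for i, s in enumerate(samples):
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or len(gt) != PLOIDY or any(a is None for a in gt):
                    report.reject(rec.chrom, rec.pos, f"sample {s}: not tetraploid")
                    ok = False
                    break
                if not call.phased:
                    report.reject(rec.chrom, rec.pos, f"sample {s}: unphased")
                    ok = False
                    break
                col[i] = gt
            if not ok:
                continue
            columns.append(col)
            meta.append((chrom_index[key[0]], key[1], map_lookup[key]))
    if not columns:
        raise ValueError("all VCF records were rejected")
    report.n_kept = len(columns)

    order = np.lexsort((
        np.array([m[1] for m in meta]),
        np.array([m[0] for m in meta]),
    ))
    hap = np.stack(columns, axis=-1)[:, :, order]
    gmap = GeneticMap(
        np.array([meta[i][0] for i in order], dtype=np.int32),
        np.array([meta[i][1] for i in order], dtype=np.int64),
        np.array([meta[i][2] for i in order], dtype=np.float64),
    )
    return HaplotypeSet(hap, np.asarray(samples, dtype=object), gmap), report


def write_phased_vcf(hs: HaplotypeSet, path) -> None:
    """Write a HaplotypeSet as a plain phased VCF (chromosomes named 1..C)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    gmap = hs.gmap
    for c in gmap.chromosomes:
        end = int(gmap.pos_bp[gmap.chrom == c].max()) + 1
        header.contigs.add(str(int(c)), length=end)
    for cid in hs.ids:
        header.add_sample(str(cid))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(hs.n_markers):
            rec = out.new_record(
                contig=str(int(gmap.chrom[j])),
                start=int(gmap.pos_bp[j]) - 1,
                stop=int(gmap.pos_bp[j]),
                alleles=("A", "T"),
            )
            for i, cid in enumerate(hs.ids):
                rec.samples[str(cid)]["GT"] = tuple(int(a) for a in hs.haplotypes[i, :, j])
                rec.samples[str(cid)].phased = True
            out.write(rec)


def write_map_table(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)
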