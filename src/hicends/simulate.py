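"""Synthetic genomes, contigs and HiC-Pro style contact matrices.

The generator emulates the statistical structure that end-based scaffolding
relies on: within a chromosome the expected Hi-C contact between two bins at
distance ``d`` bins decays as a power law ``C * d**-alpha`` (alpha = 1, the
canonical intra-chromosomal decay), while bins on different chromosomes share
a uniform background rate ``lambda_t`` three orders of magnitude below the
near-diagonal cis rate.  Counts are Poisson.  Chromosomes are fragmented into
1-6 contigs of at least 1 Mb at random bin boundaries, and the bin table
lists contigs in shuffled order so that bin numbering carries no adjacency
hint.  Optional features: contigs with one injected mis-join (two non-
adjacent fragments concatenated), and junction-local contact suppression that
mimics repeat-dead contig ends.

What it does not emulate: read-level noise, restriction-site spacing,
ICE's full balancing model (the "normalized" flavor is plain symmetric
row-balancing), diploid artefacts, or inversions in the contig truth.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io import (
    BinTable,
    ContactMatrix,
    write_bin_table,
    write_contact_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimSpec",
    "GenomeLayout",
    "SimContig",
    "SimData",
    "simulate_genome_layout",
    "fragment_chromosomes",
    "simulate_contact_matrix",
    "inject_misjoins",
    "simulate_dataset",
    "write_hicpro_fixture",
]


@dataclass(frozen=True)
class SimSpec:
    """Simulation parameters; defaults give a large-contig 5-chromosome
    genome with ~100:1 cis/trans contrast at unit distance."""

    n_chrom: int = 5
    chrom_sizes: Optional[Tuple[int, ...]] = None  # default 40 Mb each
    bin_size: int = 100_000
    contigs_per_chrom: Tuple[int, int] = (1, 6)
    min_contig: int = 1_000_000
    decay_exponent: float = 1.0
    cis_scale: float = 100.0
    trans_rate: Optional[float] = None  # default cis_scale / 1000
    seed: int = 0

    def sizes(self) -> Tuple[int, ...]:
        if self.chrom_sizes is not None:
            return self.chrom_sizes
        return tuple(40_000_000 for _ in range(self.n_chrom))

    @property
    def lambda_trans(self) -> float:
        return self.trans_rate if self.trans_rate is not None else self.cis_scale / 1000


@dataclass
class GenomeLayout:
    chroms: List[Tuple[str, int]]  # (name, size in bp, a bin multiple)
    bin_size: int


@dataclass
class SimContig:
    """A contig as one or two genomic fragments (two = injected mis-join)."""

    name: str
    parts: List[Tuple[str, int, int]]  # (chrom, gstart, gend), bin-aligned

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e in self.parts)


@dataclass
class SimData:
    spec: SimSpec
    layout: GenomeLayout
    contigs: List[SimContig]
    bins: BinTable
    raw: ContactMatrix
    normalized: ContactMatrix
    order: Dict[str, List[str]]  # chrom -> contig names in genomic order
    breakpoints: Dict[str, int]  # misjoined contig -> junction bp offset

    def adjacency(self) -> Set[FrozenSet]:
        from .ends import adjacency_end_pairs

        return adjacency_end_pairs(self.order)

    def true_clusters(self) -> List[Tuple[Tuple[str, str], ...]]:
        """Canonical per-chromosome contig clusters (all forward)."""
        from .graph import Cluster, canonicalize_cluster

        out = []
        for chrom in sorted(self.order):
            cluster = Cluster(members=[(c, "+") for c in self.order[chrom]])
            out.append(canonicalize_cluster(cluster).tokens())
        return out


def simulate_genome_layout(spec: SimSpec) -> GenomeLayout:
    """Chromosome names and sizes, rounded up to whole bins."""
    chroms: List[Tuple[str, int]] = []
    for k, size in enumerate(spec.sizes(), 1):
        rounded = int(math.ceil(size / spec.bin_size)) * spec.bin_size
        if rounded != size:
            logger.warning(
                "chromosome %d size %d rounded up to %d (bin multiple)",
                k, size, rounded,
            )
        chroms.append((f"chr{k}", rounded))
    return GenomeLayout(chroms=chroms, bin_size=spec.bin_size)


def _draw_cuts(
    n_bins: int, k: int, min_bins: int, rng: np.random.Generator
) -> List[int]:
    """k-1 cut points (in bins) leaving every fragment >= min_bins."""
    if k == 1:
        return []
    for _ in range(10_000):
        cuts = sorted(rng.choice(np.arange(1, n_bins), size=k - 1, replace=False))
        sizes = np.diff([0] + list(cuts) + [n_bins])
        if (sizes >= min_bins).all():
            return [int(c) for c in cuts]
    raise RuntimeError("could not place cuts respecting the minimum contig size")


def fragment_chromosomes(
    layout: GenomeLayout, spec: SimSpec, rng: Optional[np.random.Generator] = None
) -> Tuple[List[SimContig], Dict[str, List[str]]]:
    """Split each chromosome into 1-6 contigs of at least ``min_contig`` bp.

    Cut points fall on bin boundaries; infeasible draws of the contig count
    are redrawn (capped by what the chromosome can hold).  Contigs are
    returned in shuffled order with order-free names; the returned truth maps
    each chromosome to its contig names in genomic order.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    min_bins = max(1, int(math.ceil(spec.min_contig / spec.bin_size)))
    lo, hi = spec.contigs_per_chrom
    contigs: List[SimContig] = []
    order: Dict[str, List[str]] = {}
    per_chrom: List[List[SimContig]] = []
    for chrom, size in layout.chroms:
        n_bins = size // spec.bin_size
        k_hi = min(hi, max(1, n_bins // min_bins))  # cap at what fits
        k_lo = min(max(lo, 1), k_hi)
        k = int(rng.integers(k_lo, k_hi + 1))
        cuts = _draw_cuts(n_bins, k, min_bins, rng)
        edges = [0] + cuts + [n_bins]
        pieces = [
            SimContig(name="", parts=[(chrom, a * spec.bin_size, b * spec.bin_size)])
            for a, b in zip(edges, edges[1:])
        ]
        per_chrom.append(pieces)
        contigs.extend(pieces)
    perm = rng.permutation(len(contigs))
    for rank, idx in enumerate(perm):
        contigs[idx].name = f"contig_{rank:03d}"
    shuffled = [contigs[idx] for idx in perm]
    for (chrom, _), pieces in zip(layout.chroms, per_chrom):
        order[chrom] = [p.name for p in pieces]
    return shuffled, order


def _bin_coordinates(
    contigs: Sequence[SimContig], bin_size: int
) -> Tuple[BinTable, np.ndarray, np.ndarray]:
    """BinTable over contigs plus per-bin genomic (chrom index, bin index)."""
    chrom_names: Dict[str, int] = {}
    rows: List[Tuple[str, int, int, int]] = []
    chrom_idx: List[int] = []
    gbin: List[int] = []
    bin_id = 1
    for contig in contigs:
        pos = 0
        for chrom, gstart, gend in contig.parts:
            cidx = chrom_names.setdefault(chrom, len(chrom_names))
            for g in range(gstart // bin_size, gend // bin_size):
                rows.append((contig.name, pos, pos + bin_size, bin_id))
                chrom_idx.append(cidx)
                gbin.append(g)
                pos += bin_size
                bin_id += 1
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "bin_id"])
    return (
        BinTable(df, bin_size=bin_size),
        np.asarray(chrom_idx, dtype=np.int64),
        np.asarray(gbin, dtype=np.int64),
    )


def _row_balance(dense: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """Symmetric row-balancing toward equal row sums (an ICE stand-in)."""
    mat = dense.astype(float).copy()
    for _ in range(n_iter):
        sums = mat.sum(axis=1)
        target = sums[sums > 0].mean() if (sums > 0).any() else 0.0
        if target == 0:
            break
        scale = np.ones_like(sums)
        nz = sums > 0
        scale[nz] = np.sqrt(target / sums[nz])
        mat = mat * scale[:, None] * scale[None, :]
    return mat


def simulate_contact_matrix(
    contigs: Sequence[SimContig],
    spec: SimSpec,
    rng: Optional[np.random.Generator] = None,
    suppressed_junctions: Sequence[Tuple[str, int, int]] = (),
) -> Tuple[BinTable, ContactMatrix, ContactMatrix]:
    """Poisson contact counts from the true genomic bin positions.

    Cis pairs at distance ``d`` bins draw from Poisson(C * d**-alpha); the
    diagonal uses d = 1; trans pairs draw from Poisson(lambda_t).  Entries in
    ``suppressed_junctions`` — (chrom, junction bp, radius in bins) — zero
    the expected contact of cis pairs that straddle the junction with both
    bins inside the radius, emulating repeat-dead ends.  Returns the bin
    table, the raw counts and a row-balanced "normalized" flavor.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    bins, chrom_idx, gbin = _bin_coordinates(contigs, spec.bin_size)
    n = bins.n_bins
    same = chrom_idx[:, None] == chrom_idx[None, :]
    dist = np.abs(gbin[:, None] - gbin[None, :]).astype(float)
    dist[dist == 0] = 1.0
    lam = np.where(
        same,
        spec.cis_scale * dist ** (-spec.decay_exponent),
        spec.lambda_trans,
    )
    chrom_name_to_idx: Dict[str, int] = {}
    for contig in contigs:
        for chrom, _, _ in contig.parts:
            chrom_name_to_idx.setdefault(chrom, len(chrom_name_to_idx))
    for chrom, junction_bp, radius in suppressed_junctions:
        cidx = chrom_name_to_idx.get(chrom)
        if cidx is None:
            continue
        jbin = junction_bp // spec.bin_size  # first bin right of the junction
        on_chrom = chrom_idx == cidx
        left = on_chrom & (gbin < jbin) & (gbin >= jbin - radius)
        right = on_chrom & (gbin >= jbin) & (gbin < jbin + radius)
        lam[np.ix_(left, right)] = 0.0
        lam[np.ix_(right, left)] = 0.0
    upper = np.triu(np.ones((n, n), dtype=bool))
    counts = np.zeros((n, n))
    counts[upper] = rng.poisson(lam[upper])
    counts = counts + np.triu(counts, 1).T  # symmetric dense, diagonal once
    ii, jj = np.nonzero(np.triu(counts))
    vv = counts[ii, jj]
    ids = bins.bin_ids
    raw = ContactMatrix(ids[ii], ids[jj], vv, flavor="raw")
    balanced = _row_balance(counts)
    bi, bj = np.nonzero(np.triu(balanced))
    normalized = ContactMatrix(
        ids[bi], ids[bj], balanced[bi, bj], flavor="normalized"
    )
    return bins, raw, normalized


def inject_misjoins(
    contigs: Sequence[SimContig],
    order: Dict[str, List[str]],
    n_errors: int,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> Tuple[List[SimContig], Dict[str, List[str]], Dict[str, int]]:
    """Concatenate pairs of non-adjacent contigs into mis-joined contigs.

    Each error consumes two contigs that are not genomic neighbours and
    replaces them with one contig whose recorded junction (a bin boundary)
    is the truth breakpoint.  The genomic order truth drops the consumed
    contigs.  Remaining contigs are untouched.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    by_name = {c.name: c for c in contigs}
    neighbors: Set[FrozenSet] = set()
    for names in order.values():
        for a, b in zip(names, names[1:]):
            neighbors.add(frozenset({a, b}))
    available = [c.name for c in contigs]
    pairs: List[Tuple[str, str]] = []
    guard = 0
    while len(pairs) < n_errors:
        guard += 1
        if guard > 100_000 or len(available) < 2:
            raise ValueError("not enough non-adjacent contig pairs for the "
                             "requested number of errors")
        a, b = rng.choice(len(available), size=2, replace=False)
        na, nb = available[a], available[b]
        if frozenset({na, nb}) in neighbors:
            continue
        pairs.append((na, nb))
        for idx in sorted((int(a), int(b)), reverse=True):
            available.pop(idx)
    consumed = {n for pair in pairs for n in pair}
    out: List[SimContig] = [c for c in contigs if c.name not in consumed]
    breakpoints: Dict[str, int] = {}
    for k, (na, nb) in enumerate(pairs, 1):
        left, right = by_name[na], by_name[nb]
        name = f"err_{k:03d}"
        out.append(SimContig(name=name, parts=left.parts + right.parts))
        breakpoints[name] = left.length
    new_order = {
        chrom: [n for n in names if n not in consumed]
        for chrom, names in order.items()
    }
    return out, new_order, breakpoints


def simulate_dataset(
    spec: SimSpec,
    n_errors: int = 0,
    suppressed_junctions: Sequence[Tuple[str, int, int]] = (),
) -> SimData:
    """End-to-end fixture: layout, fragmentation, optional errors, matrices."""
    rng = np.random.default_rng(spec.seed)
    layout = simulate_genome_layout(spec)
    contigs, order = fragment_chromosomes(layout, spec, rng)
    breakpoints: Dict[str, int] = {}
    if n_errors:
        contigs, order, breakpoints = inject_misjoins(
            contigs, order, n_errors, rng
        )
    bins, raw, normalized = simulate_contact_matrix(
        contigs, spec, rng, suppressed_junctions=suppressed_junctions
    )
    return SimData(
        spec=spec,
        layout=layout,
        contigs=list(contigs),
        bins=bins,
        raw=raw,
        normalized=normalized,
        order=order,
        breakpoints=breakpoints,
    )


def write_hicpro_fixture(
    bins: BinTable, raw: ContactMatrix, normalized: ContactMatrix, out_dir
) -> Dict[str, str]:
    """Write abs-bed and matrix files byte-compatible with the readers."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "bed": os.path.join(out_dir, "abs.bed"),
        "raw": os.path.join(out_dir, "raw.matrix"),
        "normalized": os.path.join(out_dir, "iced.matrix"),
    }
    write_bin_table(bins, paths["bed"])
    write_contact_matrix(raw, paths["raw"])
    write_contact_matrix(normalized, paths["normalized"])
    return paths
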