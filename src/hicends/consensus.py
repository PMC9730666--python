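"""Parameter-grid scaffolding and consensus merging.

A single scaffolding run depends on three choices: the end-window size, the
contact-cutoff multiplier applied to the automatically detected turning
point, and the matrix flavor (raw counts or ICE-normalized).  Rather than
trusting one combination, the whole grid is run — by default five end sizes
(0.5–2.5 Mb in 0.5-Mb steps), nine multipliers (1.0–5.0 in 0.5 steps) and
both flavors, 90 cells — and the resulting cluster units are merged by
frequency.  A unit's frequency across cells is its robustness score; units
are emitted greedily from the most frequent down, skipping any unit that
reuses an already-placed contig.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .ends import compute_end_contacts, make_end_windows
from .graph import (
    Cluster,
    break_cycles,
    build_link_graph,
    canonicalize_cluster,
    extract_clusters,
    reciprocal_best_filter,
)
from .io import BinTable, ContactMatrix
from .turning import TurningPointError, find_turning_point

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "GridCellResult",
    "ConsensusResult",
    "run_single_cell",
    "run_parameter_grid",
    "merge_cluster_results",
    "scaffold_once",
]

DEFAULT_END_SIZES = tuple(range(500_000, 2_500_001, 500_000))
DEFAULT_MULTIPLIERS = tuple(1.0 + 0.5 * k for k in range(9))  # 1.0 .. 5.0


@dataclass(frozen=True)
class GridSpec:
    end_sizes_bp: Tuple[int, ...] = DEFAULT_END_SIZES
    multipliers: Tuple[float, ...] = DEFAULT_MULTIPLIERS
    flavors: Tuple[str, ...] = ("raw", "normalized")

    def __post_init__(self) -> None:
        if not all(s > 0 for s in self.end_sizes_bp):
            raise ValueError("end sizes must be positive")
        if not all(m > 0 for m in self.multipliers):
            raise ValueError("multipliers must be positive")

    @property
    def cardinality(self) -> int:
        return len(self.end_sizes_bp) * len(self.multipliers) * len(self.flavors)

    def floor_window(self, bin_size: int) -> int:
        """Window floor (bins) from the smallest end size in the grid.

        Contigs with at least twice this many bins are kept in every cell,
        with windows capped at half their bins, so all cells scaffold the
        same contig set.
        """
        return max(1, min(self.end_sizes_bp) // bin_size)


@dataclass
class GridCellResult:
    end_size_bp: int
    flavor: str
    multiplier: float
    turning_point: Optional[float]
    cutoff: Optional[float]
    clusters: List[Cluster] = field(default_factory=list)
    small_contigs: List[str] = field(default_factory=list)
    degenerate: bool = False


@dataclass
class ConsensusResult:
    clusters: List[Cluster]
    max_robustness: int
    cells: List[GridCellResult] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def run_single_cell(
    bins: BinTable,
    matrix: ContactMatrix,
    end_size_bp: int,
    multiplier: float,
    cutoff: Optional[float] = None,
    floor_bins: Optional[int] = None,
) -> GridCellResult:
    """One scaffolding run: windows -> end contacts -> cutoff -> clean graph.

    When ``cutoff`` is not given it is ``multiplier`` times the detected
    turning point of the nonzero end-pair values.  ``floor_bins`` keeps
    contigs shorter than ``2w`` bins in play with capped windows (see
    :func:`hicends.ends.make_end_windows`).
    """
    w = max(1, end_size_bp // bins.bin_size)
    ends, small = make_end_windows(bins, w, floor_bins=floor_bins)
    result = GridCellResult(
        end_size_bp=end_size_bp,
        flavor=matrix.flavor,
        multiplier=multiplier,
        turning_point=None,
        cutoff=cutoff,
        small_contigs=small,
    )
    if not ends:
        result.degenerate = True
        return result
    table = compute_end_contacts(matrix, ends, bins)
    if cutoff is None:
        try:
            tp = find_turning_point(table.nonzero_values())
        except TurningPointError as exc:
            logger.warning(
                "degenerate cell (end=%d, flavor=%s, m=%.1f): %s",
                end_size_bp, matrix.flavor, multiplier, exc,
            )
            result.degenerate = True
            return result
        result.turning_point = tp.value
        cutoff = multiplier * tp.value
        result.cutoff = cutoff
    graph = build_link_graph(table, cutoff)
    graph = reciprocal_best_filter(graph)
    graph = break_cycles(graph)
    lengths = bins.contig_lengths()
    result.clusters = extract_clusters(graph, lengths)
    return result


def run_parameter_grid(
    bins: BinTable,
    raw: ContactMatrix,
    normalized: Optional[ContactMatrix],
    grid: GridSpec = GridSpec(),
) -> List[GridCellResult]:
    """Run every grid cell; degenerate cells yield empty cluster lists.

    The turning point is detected once per (end size, flavor) and shared by
    that pair's multiplier column.
    """
    matrices = {"raw": raw, "normalized": normalized}
    floor = grid.floor_window(bins.bin_size)
    cells: List[GridCellResult] = []
    for flavor in grid.flavors:
        matrix = matrices.get(flavor)
        if matrix is None:
            raise ValueError(f"no matrix supplied for flavor {flavor!r}")
        for end_size in grid.end_sizes_bp:
            w = max(1, end_size // bins.bin_size)
            ends, small = make_end_windows(bins, w, floor_bins=floor)
            table = compute_end_contacts(matrix, ends, bins) if ends else None
            tp_value: Optional[float] = None
            if table is not None:
                try:
                    tp_value = find_turning_point(table.nonzero_values()).value
                except TurningPointError as exc:
                    logger.warning(
                        "degenerate turning point (end=%d, flavor=%s): %s",
                        end_size, flavor, exc,
                    )
            for m in grid.multipliers:
                cell = GridCellResult(
                    end_size_bp=end_size,
                    flavor=flavor,
                    multiplier=m,
                    turning_point=tp_value,
                    cutoff=None if tp_value is None else m * tp_value,
                    small_contigs=small,
                    degenerate=tp_value is None,
                )
                if tp_value is not None and table is not None:
                    graph = build_link_graph(table, m * tp_value)
                    graph = reciprocal_best_filter(graph)
                    graph = break_cycles(graph)
                    cell.clusters = extract_clusters(graph, bins.contig_lengths())
                cells.append(cell)
    return cells


def merge_cluster_results(
    cells: Sequence[GridCellResult],
    lengths: Optional[Dict[str, int]] = None,
) -> ConsensusResult:
    """Merge grid-cell clusters into a non-redundant consensus by frequency.

    Canonical cluster units are counted across cells and emitted from the
    most frequent down (ties: longer first, then lexicographic); a unit is
    skipped when any of its contigs was already placed.  Contigs left over
    become singletons carrying their own singleton frequency.
    """
    if not cells:
        raise ValueError("no grid results to merge")
    counts: Dict[Tuple[Tuple[str, str], ...], int] = {}
    unit_length: Dict[Tuple[Tuple[str, str], ...], int] = {}
    eligible: Dict[str, None] = {}
    for cell in cells:
        for cluster in cell.clusters:
            canon = canonicalize_cluster(cluster)
            key = canon.tokens()
            counts[key] = counts.get(key, 0) + 1
            unit_length[key] = canon.total_length
            for contig in canon.contigs():
                eligible.setdefault(contig, None)
    ordered = sorted(
        counts.items(), key=lambda kv: (-kv[1], -unit_length[kv[0]], kv[0])
    )
    used: set = set()
    emitted: List[Cluster] = []
    for key, freq in ordered:
        contigs = [c for c, _ in key]
        if any(c in used for c in contigs):
            continue
        used.update(contigs)
        emitted.append(
            Cluster(members=list(key), total_length=unit_length[key], robustness=freq)
        )
    for contig in eligible:
        if contig in used:
            continue
        singleton_key = ((contig, "+"),)
        freq = counts.get(singleton_key, 0)
        length = (
            lengths.get(contig, unit_length.get(singleton_key, 0))
            if lengths
            else unit_length.get(singleton_key, 0)
        )
        emitted.append(
            Cluster(members=[(contig, "+")], total_length=length, robustness=freq)
        )
        used.add(contig)
    emitted.sort(key=lambda c: (-c.total_length, c.members[0][0]))
    return ConsensusResult(
        clusters=emitted, max_robustness=len(cells), cells=list(cells)
    )


def write_grid_summary(cells: Sequence[GridCellResult], path) -> None:
    """Per-cell audit table: parameters, turning point, cluster count."""
    with open(path, "w") as fh:
        fh.write(
            "#end_size_bp\tflavor\tmultiplier\tturning_point\tcutoff\t"
            "n_clusters\tn_small_contigs\n"
        )
        for c in cells:
            tp = "NA" if c.turning_point is None else f"{c.turning_point:.6g}"
            co = "NA" if c.cutoff is None else f"{c.cutoff:.6g}"
            fh.write(
                f"{c.end_size_bp}\t{c.flavor}\t{c.multiplier}\t{tp}\t{co}\t"
                f"{len(c.clusters)}\t{len(c.small_contigs)}\n"
            )


def scaffold_once(
    bins: BinTable,
    raw: ContactMatrix,
    normalized: Optional[ContactMatrix] = None,
    grid: GridSpec = GridSpec(),
    out_prefix: Optional[str] = None,
    contig_seqs=None,
    gap_len: int = 100,
) -> ConsensusResult:
    """One full scaffolding round: parameter grid plus consensus merge.

    With ``out_prefix`` set, writes the cluster table, a grid summary, a
    representative cleaned GFA (mid-grid cell), AGP and, when sequences are
    supplied, the scaffold FASTA.
    """
    from . import io as hio

    if normalized is None:
        grid = GridSpec(grid.end_sizes_bp, grid.multipliers, ("raw",))
    cells = run_parameter_grid(bins, raw, normalized, grid)
    consensus = merge_cluster_results(cells, lengths=bins.contig_lengths())
    if out_prefix is not None:
        hio.write_cluster_table(consensus.clusters, f"{out_prefix}.cluster.tsv")
        write_grid_summary(cells, f"{out_prefix}.grid_summary.tsv")
        lengths = bins.contig_lengths()
        # representative cell: median end size, multiplier 1.5, raw flavor
        rep = _representative_cell(bins, raw, grid)
        if rep is not None:
            hio.write_gfa(rep, lengths, f"{out_prefix}.gfa")
        records = hio.write_agp(
            consensus.clusters, lengths, f"{out_prefix}.agp", gap_len=gap_len
        )
        if contig_seqs is not None:
            hio.emit_scaffold_fasta(records, contig_seqs, f"{out_prefix}.fasta")
    return consensus


def _representative_cell(bins: BinTable, raw: ContactMatrix, grid: GridSpec):
    """Cleaned graph of the mid-grid raw cell, for GFA export."""
    sizes = sorted(grid.end_sizes_bp)
    end_size = sizes[len(sizes) // 2]
    mult = sorted(grid.multipliers)[0]
    w = max(1, end_size // bins.bin_size)
    ends, _ = make_end_windows(bins, w, floor_bins=grid.floor_window(bins.bin_size))
    if not ends:
        return None
    table = compute_end_contacts(raw, ends, bins)
    try:
        tp = find_turning_point(table.nonzero_values())
    except TurningPointError:
        return None
    graph = build_link_graph(table, mult * tp.value)
    graph = reciprocal_best_filter(graph)
    return break_cycles(graph)
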