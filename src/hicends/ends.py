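"""Contig-end windows and end-pair contact values.

Hi-C links between two adjacent contigs concentrate at their facing ends, so
the scaffolder sums contact values only over the first (head) and last (tail)
``w`` bins of each contig.  Small end windows keep the adjacent-pair signal
well separated from the non-adjacent background; the signal-to-noise ratio
diagnostic quantifies that separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse

from .io import BinTable, ContactMatrix

__all__ = [
    "ContigEnd",
    "EndContactTable",
    "make_end_windows",
    "compute_end_contacts",
    "compute_snr",
]

EndKey = Tuple[str, str]  # (contig_id, "head" | "tail")


@dataclass(frozen=True)
class ContigEnd:
    contig_id: str
    side: str  # "head" | "tail"
    window_bins: int
    bin_ids: Tuple[int, ...]

    @property
    def key(self) -> EndKey:
        return (self.contig_id, self.side)


def make_end_windows(
    bins: BinTable, w: int, strict: bool = False, floor_bins: Optional[int] = None
) -> Tuple[List[ContigEnd], List[str]]:
    """Head/tail windows of ``w`` bins for every sufficiently long contig.

    Contigs need at least ``2w`` bins so that the two windows do not overlap;
    shorter contigs are returned separately as small contigs.  With
    ``strict=True`` a contig of exactly ``2w`` bins (touching windows) is
    also excluded.  The final short bin of a contig counts as a full bin.

    ``floor_bins`` relaxes the exclusion for parameter sweeps: a contig with
    fewer than ``2w`` but at least ``2 * floor_bins`` bins gets capped
    windows of half its bins instead of being dropped, so the set of
    scaffolded contigs stays constant across a grid of window sizes.
    """
    if w < 1:
        raise ValueError("end window must span at least one bin")
    if floor_bins is not None and not 1 <= floor_bins <= w:
        raise ValueError("floor_bins must lie in [1, w]")
    ends: List[ContigEnd] = []
    small: List[str] = []
    minimum = 2 * w + 1 if strict else 2 * w
    for contig in bins.contigs:
        ids = bins.bins_of(contig)
        w_eff = w
        if len(ids) < minimum:
            if floor_bins is None or len(ids) < 2 * floor_bins:
                small.append(contig)
                continue
            w_eff = len(ids) // 2
        ends.append(
            ContigEnd(contig, "head", w_eff, tuple(int(b) for b in ids[:w_eff]))
        )
        ends.append(
            ContigEnd(contig, "tail", w_eff, tuple(int(b) for b in ids[-w_eff:]))
        )
    return ends, small


class EndContactTable:
    """Contact value per unordered pair of contig ends from different contigs.

    Values are dense internally (the number of ends is small); same-contig
    pairs are never reported.
    """

    def __init__(self, ends: Sequence[ContigEnd], values: np.ndarray, flavor: str):
        self.ends = list(ends)
        self._values = values
        self.flavor = flavor
        self._index: Dict[EndKey, int] = {e.key: k for k, e in enumerate(self.ends)}
        self.window_bins = ends[0].window_bins if ends else 0

    @property
    def contigs(self) -> List[str]:
        seen: Dict[str, None] = {}
        for e in self.ends:
            seen.setdefault(e.contig_id, None)
        return list(seen)

    def value(self, end1: EndKey, end2: EndKey) -> float:
        if end1[0] == end2[0]:
            raise KeyError("same-contig end pairs are not defined")
        return float(self._values[self._index[end1], self._index[end2]])

    def pairs(self) -> Iterator[Tuple[EndKey, EndKey, float]]:
        """All cross-contig end pairs (including zero values), each once."""
        n = len(self.ends)
        for a in range(n):
            for b in range(a + 1, n):
                if self.ends[a].contig_id == self.ends[b].contig_id:
                    continue
                yield self.ends[a].key, self.ends[b].key, float(self._values[a, b])

    def nonzero_values(self) -> np.ndarray:
        vals = np.array([v for _, _, v in self.pairs()])
        return vals[vals > 0]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#end1_contig\tend1_side\tend2_contig\tend2_side\tvalue\n")
            for e1, e2, v in self.pairs():
                if v == 0:
                    continue
                vtxt = f"{int(v)}" if float(v).is_integer() else f"{v:.6f}"
                fh.write(f"{e1[0]}\t{e1[1]}\t{e2[0]}\t{e2[1]}\t{vtxt}\n")


def compute_end_contacts(
    matrix: ContactMatrix, ends: Sequence[ContigEnd], bins: BinTable
) -> EndContactTable:
    """Sum matrix entries over every cross-contig pair of end windows.

    Computed as ``E S E^T`` where ``E`` is the ends-by-bins indicator matrix
    and ``S`` the full symmetric contact matrix.
    """
    if not ends:
        return EndContactTable([], np.zeros((0, 0)), matrix.flavor)
    sym, index = matrix.to_symmetric_csr(bins.bin_ids)
    n_ends = len(ends)
    rows: List[int] = []
    cols: List[int] = []
    for k, end in enumerate(ends):
        for b in end.bin_ids:
            rows.append(k)
            cols.append(index[b])
    indicator = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_ends, sym.shape[0])
    )
    table = np.asarray((indicator @ sym @ indicator.T).todense())
    return EndContactTable(ends, table, matrix.flavor)


def adjacency_end_pairs(order: Dict[str, List[str]]) -> Set[frozenset]:
    """Truth adjacency as unordered end-key pairs from per-chromosome orders.

    Assumes forward-oriented contigs: neighbour ``i``'s tail faces neighbour
    ``i+1``'s head.
    """
    pairs: Set[frozenset] = set()
    for contigs in order.values():
        for a, b in zip(contigs, contigs[1:]):
            pairs.add(frozenset({(a, "tail"), (b, "head")}))
    return pairs


def compute_snr(table: EndContactTable, truth_adjacent: Set[frozenset]) -> float:
    """Median signal over median noise contact value.

    Signal pairs are the true adjacent end pairs; every other cross-contig
    end pair is noise.  Returns ``inf`` when the noise median is zero.
    """
    signal: List[float] = []
    noise: List[float] = []
    for e1, e2, v in table.pairs():
        if frozenset({e1, e2}) in truth_adjacent:
            signal.append(v)
        else:
            noise.append(v)
    if not signal or not noise:
        raise ValueError("need at least one signal and one noise end pair")
    med_noise = float(np.median(noise))
    med_signal = float(np.median(signal))
    if med_noise == 0:
        return math.inf
    return med_signal / med_noise
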