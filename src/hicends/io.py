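"""Readers and writers for HiC-Pro style inputs and scaffold outputs.

The scaffolder consumes the two text files produced by the HiC-Pro mapping
pipeline at a fixed bin size (100 kb recommended): the ``.bed`` file that maps
genome bins onto contigs, and sparse ``.matrix`` files holding raw or
ICE-normalized contact counts as ``bin_i bin_j value`` triplets.  On the
output side it emits cluster tables, GFA1 graphs, AGP v2.1 scaffold layouts
and scaffold FASTA sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "BinTable",
    "ContactMatrix",
    "UnitigMap",
    "AgpRecord",
    "read_bin_table",
    "read_contact_matrix",
    "parse_unitig_map",
    "read_unitig_map_tsv",
    "write_cluster_table",
    "read_cluster_table",
    "write_gfa",
    "write_agp",
    "emit_scaffold_fasta",
    "reverse_complement",
]

DEFAULT_BIN_SIZE = 100_000


class BinTableError(ValueError):
    """Raised when a bin definition file violates the tiling contract."""


@dataclass
class BinTable:
    """Mapping of fixed-width genome bins onto contigs.

    Each row is ``(contig, start, end, bin_id)`` with BED-style 0-based
    half-open coordinates, in file order.  Within a contig, bins tile the
    sequence contiguously; every bin except possibly the last has length
    ``bin_size``.
    """

    df: pd.DataFrame
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self._bins_by_contig: Dict[str, np.ndarray] = {
            str(c): g["bin_id"].to_numpy()
            for c, g in self.df.groupby("contig", sort=False)
        }

    # -- accessors ---------------------------------------------------------

    @property
    def contigs(self) -> List[str]:
        return list(self._bins_by_contig)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def bin_ids(self) -> np.ndarray:
        return self.df["bin_id"].to_numpy()

    def bins_of(self, contig: str) -> np.ndarray:
        """Bin ids of one contig, in head-to-tail order."""
        return self._bins_by_contig[contig]

    def n_bins_of(self, contig: str) -> int:
        return len(self._bins_by_contig[contig])

    def contig_length(self, contig: str) -> int:
        sub = self.df[self.df["contig"] == contig]
        return int(sub["end"].max())

    def contig_lengths(self) -> Dict[str, int]:
        return {c: self.contig_length(c) for c in self.contigs}

    def bin_lengths_of(self, contig: str) -> np.ndarray:
        sub = self.df[self.df["contig"] == contig]
        return (sub["end"] - sub["start"]).to_numpy()

    def contig_of_bin(self) -> Dict[int, str]:
        return dict(zip(self.df["bin_id"], self.df["contig"]))

    def validate(self, require_increasing_ids: bool = True) -> None:
        df = self.df
        if df.empty:
            return
        if df["bin_id"].duplicated().any():
            raise BinTableError("duplicate bin ids")
        if require_increasing_ids and not df["bin_id"].is_monotonic_increasing:
            raise BinTableError("bin ids are not strictly increasing")
        if (df["start"] >= df["end"]).any():
            raise BinTableError("bin with start >= end")
        for contig, g in df.groupby("contig", sort=False):
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            if starts[0] != 0:
                raise BinTableError(f"contig {contig}: first bin does not start at 0")
            if not np.array_equal(starts[1:], ends[:-1]):
                raise BinTableError(f"contig {contig}: bins do not tile contiguously")
            widths = ends - starts
            if len(widths) > 1 and not (widths[:-1] == self.bin_size).all():
                raise BinTableError(
                    f"contig {contig}: interior bin with length != bin_size"
                )
            if widths[-1] > self.bin_size:
                raise BinTableError(f"contig {contig}: last bin longer than bin_size")


def read_bin_table(path, bin_size: int = DEFAULT_BIN_SIZE) -> BinTable:
    """Read a HiC-Pro abs-bed file (contig, start, end, bin_id)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 4:
                raise BinTableError(f"{path}:{lineno}: expected >= 4 columns")
            try:
                rows.append(
                    (fields[0], int(fields[1]), int(fields[2]), int(fields[3]))
                )
            except ValueError as exc:
                raise BinTableError(f"{path}:{lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "bin_id"])
    table = BinTable(df, bin_size=bin_size)
    table.validate()
    return table


class ContactMatrixError(ValueError):
    """Raised for malformed sparse matrix files."""


class ContactMatrix:
    """Sparse symmetric contact matrix over genome bins.

    Entries are canonicalized so that ``i <= j``; mirrored duplicates are
    collapsed by summation.  ``value(i, j)`` honours the symmetric access
    contract and returns 0 for absent pairs.
    """

    def __init__(
        self,
        i: Sequence[int],
        j: Sequence[int],
        v: Sequence[float],
        flavor: str = "raw",
    ) -> None:
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        v = np.asarray(v, dtype=np.float64)
        if np.any(v < 0):
            raise ContactMatrixError("negative contact value")
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        if len(lo):
            order = np.lexsort((hi, lo))
            lo, hi, v = lo[order], hi[order], v[order]
            # collapse duplicate keys by summation
            key_change = np.empty(len(lo), dtype=bool)
            key_change[0] = True
            key_change[1:] = (lo[1:] != lo[:-1]) | (hi[1:] != hi[:-1])
            group = np.cumsum(key_change) - 1
            n_groups = group[-1] + 1
            self.i = lo[key_change]
            self.j = hi[key_change]
            self.v = np.bincount(group, weights=v, minlength=n_groups)
        else:
            self.i, self.j, self.v = lo, hi, v
        self.flavor = flavor
        self._lookup: Optional[Dict[Tuple[int, int], float]] = None

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.i)

    def triplets(self) -> Iterator[Tuple[int, int, float]]:
        yield from zip(self.i.tolist(), self.j.tolist(), self.v.tolist())

    def value(self, a: int, b: int) -> float:
        if self._lookup is None:
            self._lookup = {
                (int(x), int(y)): float(w)
                for x, y, w in zip(self.i, self.j, self.v)
            }
        key = (a, b) if a <= b else (b, a)
        return self._lookup.get(key, 0.0)

    def check_bins(self, bins: BinTable) -> None:
        known = set(int(b) for b in bins.bin_ids)
        for arr in (self.i, self.j):
            unknown = set(arr.tolist()) - known
            if unknown:
                raise ContactMatrixError(
                    f"matrix references bin ids absent from the bin table: "
                    f"{sorted(unknown)[:5]}"
                )

    def to_symmetric_csr(
        self, bin_ids: Sequence[int]
    ) -> Tuple[sparse.csr_matrix, Dict[int, int]]:
        """Full symmetric CSR over the given bin-id universe.

        Returns the matrix and the bin-id -> row-index map.  Off-diagonal
        entries appear in both triangles; the diagonal appears once.
        """
        index = {int(b): k for k, b in enumerate(bin_ids)}
        n = len(index)
        ri = np.fromiter((index[int(x)] for x in self.i), dtype=np.int64, count=len(self))
        rj = np.fromiter((index[int(x)] for x in self.j), dtype=np.int64, count=len(self))
        off = ri != rj
        rows = np.concatenate([ri, rj[off]])
        cols = np.concatenate([rj, ri[off]])
        vals = np.concatenate([self.v, self.v[off]])
        mat = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        return mat, index

    def scaled(self, factor: float) -> "ContactMatrix":
        return ContactMatrix(self.i, self.j, self.v * factor, flavor=self.flavor)


def read_contact_matrix(
    path, bins: Optional[BinTable] = None, flavor: str = "raw"
) -> ContactMatrix:
    """Read a HiC-Pro sparse matrix file of ``bin_i bin_j value`` triplets."""
    ii: List[int] = []
    jj: List[int] = []
    vv: List[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ContactMatrixError(f"{path}:{lineno}: expected 3 columns")
            try:
                ii.append(int(fields[0]))
                jj.append(int(fields[1]))
                vv.append(float(fields[2]))
            except ValueError as exc:
                raise ContactMatrixError(f"{path}:{lineno}: {exc}") from exc
            if vv[-1] < 0:
                raise ContactMatrixError(f"{path}:{lineno}: negative value")
    matrix = ContactMatrix(ii, jj, vv, flavor=flavor)
    if bins is not None:
        matrix.check_bins(bins)
    return matrix


def write_contact_matrix(matrix: ContactMatrix, path) -> None:
    """Write triplets sorted by (i, j), integers without trailing zeros."""
    with open(path, "w") as fh:
        for a, b, w in matrix.triplets():
            wtxt = f"{int(w)}" if float(w).is_integer() else f"{w:.6f}"
            fh.write(f"{a}\t{b}\t{wtxt}\n")


def write_bin_table(bins: BinTable, path) -> None:
    with open(path, "w") as fh:
        for row in bins.df.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.start}\t{row.end}\t{row.bin_id}\n")


# ---------------------------------------------------------------------------
# unitig-to-contig mapping


@dataclass
class UnitigMap:
    """Ordered unitig intervals per contig (bp coordinates, half-open)."""

    intervals: Dict[str, List[Tuple[str, int, int]]] = field(default_factory=dict)

    def boundaries(self, contig: str) -> List[int]:
        """Internal unitig boundaries of a contig (excludes 0 and the end)."""
        ivs = self.intervals.get(contig, [])
        if len(ivs) < 2:
            return []
        return [iv[2] for iv in ivs[:-1]]

    def validate(self) -> None:
        for contig, ivs in self.intervals.items():
            prev_end = 0
            for name, start, end in ivs:
                if start < prev_end or start >= end:
                    raise ValueError(
                        f"unitig {name} on {contig}: bad interval ({start}, {end})"
                    )
                prev_end = end


class GfaDialectError(ValueError):
    """Raised when GFA files lack the read-placement lines we rely on."""


def _read_placements(gfa_path) -> Dict[str, List[Tuple[str, int, int]]]:
    """Read A-lines (hifiasm read placements): seq -> [(read, start, end)]."""
    placements: Dict[str, List[Tuple[str, int, int]]] = {}
    with open(gfa_path) as fh:
        for line in fh:
            if not line.startswith("A\t"):
                continue
            f = line.rstrip("\n").split("\t")
            # A <seq> <pos> <strand> <read> <read_start> <read_end> ...
            seq, pos, read = f[1], int(f[2]), f[4]
            rlen = int(f[6]) - int(f[5])
            placements.setdefault(seq, []).append((read, pos, pos + rlen))
    return placements


def parse_unitig_map(utg_gfa, ctg_gfa) -> UnitigMap:
    """Derive unitig-to-contig intervals from two assembler GFA files.

    Both files must carry read-placement (``A``) lines naming the reads that
    compose each unitig/contig.  A unitig is projected onto every contig
    sharing reads with it, over the span of those shared reads in contig
    coordinates.
    """
    utg = _read_placements(utg_gfa)
    ctg = _read_placements(ctg_gfa)
    if not utg or not ctg:
        raise GfaDialectError(
            "no read-placement (A) lines found; supply a 4-column TSV "
            "unitig map instead"
        )
    read_to_unitigs: Dict[str, List[str]] = {}
    for unitig, reads in utg.items():
        for read, _, _ in reads:
            read_to_unitigs.setdefault(read, []).append(unitig)
    result: Dict[str, List[Tuple[str, int, int]]] = {}
    for contig, reads in ctg.items():
        spans: Dict[str, Tuple[int, int]] = {}
        for read, start, end in reads:
            for unitig in read_to_unitigs.get(read, ()):
                if unitig in spans:
                    s, e = spans[unitig]
                    spans[unitig] = (min(s, start), max(e, end))
                else:
                    spans[unitig] = (start, end)
        ivs = sorted(
            ((u, s, e) for u, (s, e) in spans.items()), key=lambda t: (t[1], t[2])
        )
        result[contig] = ivs
    umap = UnitigMap(result)
    umap.validate()
    return umap


def read_unitig_map_tsv(path) -> UnitigMap:
    """Read the canonical 4-column TSV form: contig, unitig, start, end."""
    intervals: Dict[str, List[Tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            intervals.setdefault(f[0], []).append((f[1], int(f[2]), int(f[3])))
    for contig in intervals:
        intervals[contig].sort(key=lambda t: (t[1], t[2]))
    umap = UnitigMap(intervals)
    umap.validate()
    return umap


# ---------------------------------------------------------------------------
# cluster table

CLUSTER_HEADER = [
    "cluster_id",
    "contig_count",
    "cluster_length",
    "robustness",
    "contigs_with_order_and_orientation",
]


def write_cluster_table(clusters, path) -> None:
    """Write one row per cluster: id, count, length, robustness, tokens.

    Tokens are semicolon-joined ``contig+`` / ``contig-`` strings in scaffold
    order.
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CLUSTER_HEADER) + "\n")
        for k, cluster in enumerate(clusters, 1):
            tokens = ";".join(f"{c}{o}" for c, o in cluster.members)
            fh.write(
                f"Cluster_{k:02d}\t{len(cluster.members)}\t"
                f"{cluster.total_length}\t{cluster.robustness}\t{tokens}\n"
            )


def read_cluster_table(path):
    """Re-parse a cluster table written by :func:`write_cluster_table`."""
    from .graph import Cluster  # local import to avoid a cycle

    clusters = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            _, count, length, robustness, tokens = line.rstrip("\n").split("\t")
            members = [(t[:-1], t[-1]) for t in tokens.split(";")]
            assert len(members) == int(count)
            clusters.append(
                Cluster(
                    members=members,
                    total_length=int(length),
                    robustness=int(robustness),
                )
            )
    return clusters


# ---------------------------------------------------------------------------
# GFA

def _link_strands(side1: str, side2: str) -> Tuple[str, str]:
    """GFA strand marks for a link joining two contig ends.

    A link leaving the first contig's tail marks it ``+``, leaving its head
    marks it ``-``; the second contig is marked ``+`` when entered at its
    head and ``-`` when entered at its tail.
    """
    s1 = "+" if side1 == "tail" else "-"
    s2 = "+" if side2 == "head" else "-"
    return s1, s2


def write_gfa(graph, contig_lengths: Mapping[str, int], path) -> None:
    """Write a sequence-less GFA1 view of a scaffolding graph."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for contig in graph.contigs:
            length = contig_lengths[contig]
            fh.write(f"S\t{contig}\t*\tLN:i:{length}\n")
        for (end1, end2), weight in sorted(graph.link_edges.items()):
            s1, s2 = _link_strands(end1[1], end2[1])
            fh.write(
                f"L\t{end1[0]}\t{s1}\t{end2[0]}\t{s2}\t0M\tFC:i:{int(round(weight))}\n"
            )


# ---------------------------------------------------------------------------
# AGP v2.1


@dataclass
class AgpRecord:
    scaffold_id: str
    scaffold_start: int  # 1-based inclusive
    scaffold_end: int
    part_number: int
    component_type: str  # W or U
    # W fields
    component_id: Optional[str] = None
    component_beg: Optional[int] = None
    component_end: Optional[int] = None
    orientation: Optional[str] = None
    # U fields
    gap_length: Optional[int] = None
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "proximity_ligation"

    def to_line(self) -> str:
        if self.component_type == "W":
            tail = (
                f"{self.component_id}\t{self.component_beg}\t"
                f"{self.component_end}\t{self.orientation}"
            )
        else:
            tail = f"{self.gap_length}\t{self.gap_type}\t{self.linkage}\t{self.evidence}"
        return (
            f"{self.scaffold_id}\t{self.scaffold_start}\t{self.scaffold_end}\t"
            f"{self.part_number}\t{self.component_type}\t{tail}"
        )


def agp_records(
    clusters, contig_lengths: Mapping[str, int], gap_len: int = 100
) -> List[AgpRecord]:
    """Lay out clusters as AGP v2.1 records with U gaps between contigs."""
    records: List[AgpRecord] = []
    for k, cluster in enumerate(clusters, 1):
        scaffold = f"scaffold_{k:02d}"
        pos = 0
        part = 0
        for idx, (contig, orient) in enumerate(cluster.members):
            if contig not in contig_lengths:
                raise ValueError(f"unknown length for contig {contig}")
            if idx > 0:
                part += 1
                records.append(
                    AgpRecord(
                        scaffold, pos + 1, pos + gap_len, part, "U",
                        gap_length=gap_len,
                    )
                )
                pos += gap_len
            length = contig_lengths[contig]
            part += 1
            records.append(
                AgpRecord(
                    scaffold, pos + 1, pos + length, part, "W",
                    component_id=contig, component_beg=1,
                    component_end=length, orientation=orient,
                )
            )
            pos += length
    return records


def write_agp(
    clusters, contig_lengths: Mapping[str, int], path, gap_len: int = 100
) -> List[AgpRecord]:
    records = agp_records(clusters, contig_lengths, gap_len=gap_len)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")
    return records


# ---------------------------------------------------------------------------
# FASTA

def reverse_complement(seq: str) -> str:
    from Bio.Seq import reverse_complement as _rc

    return str(_rc(seq))


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as _write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    _write(records, str(path), "fasta")


def emit_scaffold_fasta(
    records: Iterable[AgpRecord], contig_seqs: Mapping[str, str], path
) -> Dict[str, str]:
    """Assemble scaffold sequences from AGP records and contig sequences."""
    scaffolds: Dict[str, List[str]] = {}
    ends: Dict[str, int] = {}
    for rec in records:
        parts = scaffolds.setdefault(rec.scaffold_id, [])
        if rec.component_type == "U":
            parts.append("N" * rec.gap_length)
        else:
            if rec.component_id not in contig_seqs:
                raise KeyError(f"no sequence for contig {rec.component_id}")
            seq = contig_seqs[rec.component_id][
                rec.component_beg - 1 : rec.component_end
            ]
            if rec.orientation == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
        ends[rec.scaffold_id] = rec.scaffold_end
    out = {name: "".join(parts) for name, parts in scaffolds.items()}
    for name, seq in out.items():
        if len(seq) != ends[name]:
            raise AssertionError(
                f"{name}: assembled length {len(seq)} != AGP end {ends[name]}"
            )
    write_fasta(out, path)
    return out
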