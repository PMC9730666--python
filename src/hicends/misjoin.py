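"""Contig mis-join detection and correction from intra-contig Hi-C contacts.

A mis-join concatenates two genomic segments that are not neighbours, so Hi-C
links barely cross the junction: the contact value between two bins a fixed
distance apart (five 100-kb bins, i.e. 500 kb, by default) collapses at the
junction.  A candidate breakpoint is a run of such bin pairs whose contact
falls below a fraction (default 0.1) of the genome-wide median at that
distance.  Because correctly assembled regions can also be link-poor, a
candidate is optionally required to coincide with a unitig boundary — contigs
are concatenations of unitigs, so true mis-joins fall between unitigs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .io import BinTable, ContactMatrix, UnitigMap

__all__ = [
    "ContactProfile",
    "Breakpoint",
    "adjacent_contact_profile",
    "genome_median_gap_contact",
    "detect_misjoins",
    "apply_breaks",
]

DEFAULT_GAP_BINS = 5
DEFAULT_FRACTION = 0.1


@dataclass(frozen=True)
class ProfilePoint:
    left_bin: int
    right_bin: int
    midpoint: int  # bp, contig-local
    value: float


@dataclass
class ContactProfile:
    contig_id: str
    points: List[ProfilePoint]
    gap_bins: int = DEFAULT_GAP_BINS

    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.points])


@dataclass(frozen=True)
class Breakpoint:
    contig_id: str
    position: int  # bp, on a bin boundary
    min_value: float
    unitig_confirmed: bool = False


def adjacent_contact_profile(
    contig: str,
    bins: BinTable,
    matrix: ContactMatrix,
    gap_bins: int = DEFAULT_GAP_BINS,
) -> ContactProfile:
    """Contact between in-contig bin pairs ``(i, i + gap_bins)`` along a contig.

    Contigs with at most ``gap_bins`` bins yield an empty profile.  Absent
    matrix entries count as zero contact.
    """
    sub = bins.df[bins.df["contig"] == contig]
    ids = sub["bin_id"].to_numpy()
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    points: List[ProfilePoint] = []
    for k in range(len(ids) - gap_bins):
        left, right = int(ids[k]), int(ids[k + gap_bins])
        midpoint = int((starts[k] + ends[k + gap_bins]) // 2)
        points.append(
            ProfilePoint(left, right, midpoint, matrix.value(left, right))
        )
    return ContactProfile(contig, points, gap_bins)


def genome_median_gap_contact(
    bins: BinTable, matrix: ContactMatrix, gap_bins: int = DEFAULT_GAP_BINS
) -> float:
    """Median contact over all in-contig bin pairs ``gap_bins`` apart."""
    values: List[float] = []
    for contig in bins.contigs:
        profile = adjacent_contact_profile(contig, bins, matrix, gap_bins)
        values.extend(p.value for p in profile.points)
    if not values:
        raise ValueError("no in-contig bin pair at the requested gap distance")
    return float(np.median(values))


def _nearest_boundary(midpoint: int, contig_length: int, bin_size: int) -> int:
    """Bin boundary nearest to a bp position, clamped inside the contig."""
    boundary = int(round(midpoint / bin_size)) * bin_size
    boundary = max(bin_size, min(boundary, ((contig_length - 1) // bin_size) * bin_size))
    return boundary


def detect_misjoins(
    profile: ContactProfile,
    median: float,
    bins: BinTable,
    unitigs: Optional[UnitigMap] = None,
    frac: float = DEFAULT_FRACTION,
) -> List[Breakpoint]:
    """Collapse sub-threshold runs of the profile into breakpoints.

    Maximal runs of consecutive points with value below ``frac * median``
    become one breakpoint each, placed at the bin boundary nearest the
    minimum-value midpoint of the run.  With a unitig map, only breakpoints
    within one bin of an internal unitig boundary are kept (and flagged
    confirmed); without one, all Hi-C-only candidates are returned.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must lie in (0, 1)")
    threshold = frac * median
    contig_length = bins.contig_length(profile.contig_id)
    bin_size = bins.bin_size
    breakpoints: List[Breakpoint] = []
    run: List[ProfilePoint] = []

    def flush(run: List[ProfilePoint]) -> None:
        if not run:
            return
        # value ties (e.g. an all-zero trough) resolve toward the run center,
        # which for a genuine mis-join straddles the junction
        center = sum(p.midpoint for p in run) / len(run)
        trough = min(run, key=lambda p: (p.value, abs(p.midpoint - center)))
        position = _nearest_boundary(trough.midpoint, contig_length, bin_size)
        breakpoints.append(
            Breakpoint(profile.contig_id, position, trough.value)
        )

    for point in profile.points:
        if point.value < threshold:
            run.append(point)
        else:
            flush(run)
            run = []
    flush(run)

    if unitigs is None:
        return breakpoints
    boundaries = unitigs.boundaries(profile.contig_id)
    confirmed: List[Breakpoint] = []
    for bp in breakpoints:
        if any(abs(b - bp.position) <= bin_size for b in boundaries):
            confirmed.append(replace(bp, unitig_confirmed=True))
    return confirmed


def apply_breaks(
    assembly: Optional[Mapping[str, str]],
    bins: BinTable,
    matrix: ContactMatrix,
    breaks: List[Breakpoint],
) -> Tuple[Optional[Dict[str, str]], BinTable, ContactMatrix]:
    """Split contigs at breakpoints, keeping bin ids (and the matrix) stable.

    Each broken contig is replaced by children named ``<id>_1``, ``<id>_2``,
    ... in left-to-right order; existing bins are reassigned to the children
    with recomputed local coordinates.  Sequences, when provided, are split
    exactly at the breakpoints.
    """
    by_contig: Dict[str, List[int]] = {}
    for bp in breaks:
        length = bins.contig_length(bp.contig_id)
        if not 0 < bp.position < length:
            raise ValueError(
                f"breakpoint {bp.position} outside contig {bp.contig_id}"
            )
        if bp.position % bins.bin_size != 0:
            raise ValueError(
                f"breakpoint {bp.position} of {bp.contig_id} is not on a bin boundary"
            )
        by_contig.setdefault(bp.contig_id, []).append(bp.position)
    if not by_contig:
        new_assembly = dict(assembly) if assembly is not None else None
        return new_assembly, bins, matrix

    rows: List[Tuple[str, int, int, int]] = []
    new_assembly: Optional[Dict[str, str]] = {} if assembly is not None else None
    for contig, g in bins.df.groupby("contig", sort=False):
        if contig not in by_contig:
            rows.extend(
                (contig, int(r.start), int(r.end), int(r.bin_id))
                for r in g.itertuples(index=False)
            )
            if new_assembly is not None:
                new_assembly[contig] = assembly[contig]
            continue
        cuts = sorted(set(by_contig[contig]))
        length = int(g["end"].max())
        edges = [0] + cuts + [length]
        for part, (lo, hi) in enumerate(zip(edges, edges[1:]), 1):
            child = f"{contig}_{part}"
            seg = g[(g["start"] >= lo) & (g["end"] <= hi)]
            rows.extend(
                (child, int(r.start) - lo, int(r.end) - lo, int(r.bin_id))
                for r in seg.itertuples(index=False)
            )
            if new_assembly is not None:
                new_assembly[child] = assembly[contig][lo:hi]
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "bin_id"])
    new_bins = BinTable(df, bin_size=bins.bin_size)
    new_bins.validate(require_increasing_ids=False)
    return new_assembly, new_bins, matrix
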