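# Methods

## Model and assumptions

The scaffolder assumes standard Hi-C contact statistics: within a
chromosome, the expected contact between two loci decays with their genomic
distance (approximately a power law), and contacts between different
chromosomes form a roughly uniform background orders of magnitude below the
near-diagonal cis level. Two contigs adjacent on a chromosome therefore
share strong links between their *facing ends*, while all other end pairs —
non-facing ends of neighbours, non-adjacent pairs in cis, and trans pairs —
sit near background. Everything downstream (turning point, reciprocal best,
robustness) exploits this bimodality. The method is designed for assemblies
whose contigs are large relative to the end windows (N50 near or above
10 Mb, N90 near or above 1 Mb); for fragmented assemblies, whole-contig
scaffolders are the better tool.

All computations run on the HiC-Pro bin representation: a bin table mapping
fixed-width bins (default 100 kb) onto contigs, and sparse symmetric
matrices of raw counts and ICE-normalized intensities. Bin coordinates are
treated as BED-style 0-based half-open intervals, and bin ids are taken
verbatim from the file. ICE normalization itself is consumed, never
computed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| bin size | 100 kb | width of the HiC-Pro matrix bins; all windows and breakpoints are bin-aligned |
| end sizes | 0.5–2.5 Mb, step 0.5 Mb | end-window sizes of the round-1 grid (5, 10, …, 25 bins) |
| cutoff multipliers | 1.0–5.0, step 0.5 | contact cutoffs as multiples of the detected turning point |
| matrix flavors | raw, normalized | both are scaffolded; the grid is the product of all three axes (90 cells) |
| round schedule | 3–5, 5.5–7.5, 8–10 Mb | end sizes of iterative rounds 2–4; ≤ 3 rounds recommended, since accuracy falls as windows grow |
| mis-join gap | 5 bins (500 kb) | distance of the intra-contig bin pairs profiled for mis-join detection |
| mis-join fraction | 0.1 | profile values below this fraction of the genome-wide median are breakpoint candidates |
| unitig window | ±1 bin | maximal distance between a candidate breakpoint and a corroborating unitig boundary |
| AGP gap | 100 bp | length of the `U` gap records between scaffold components |

End windows count a contig's final short bin as a full bin; for the
recommended window sizes (≥ 5 bins) the head/tail asymmetry this introduces
is negligible.

## Numerical and design choices

**Turning point.** The descending value curve is min-max normalized on both
axes and rotated 45° anticlockwise; the minimum rotated ordinate is exactly
`argmin(x + y)`, which is how it is computed. Ties resolve to the smaller
rank (larger contact value), the conservative direction — it raises every
derived cutoff. Zero-valued pairs are excluded before ranking, since only
materialized contacts carry information. Fewer than three values, or an
all-equal vector, is a hard error asking for a manual cutoff. The detector
is invariant to uniform positive scaling of the values.

**Window floor in parameter sweeps.** A contig needs `2w` bins for
non-overlapping windows, and in a single run shorter contigs are excluded
(reported as small contigs). Inside a parameter grid this rule would make
the *contig set itself* vary across cells: a 3-Mb contig participates at
w = 5–15 bins but vanishes at w = 20–25, so the cells that exclude it vote
for a partial chromosome unit, and with 9 multipliers × 2 flavors per end
size those partial units can out-vote the complete one. The grid therefore
applies a window floor: any contig with at least twice the *smallest* grid
end size in bins stays in every cell, with its window capped at half its
bins. Eligibility is then decided once (contigs ≥ 1 Mb under the default
grid), the consensus votes on a fixed contig universe, and capped windows
simply revert to the contig's widest valid window. Single runs outside a
grid keep the plain `2w` rule.

**Graph cleaning.** The cutoff comparison is strict (`>`). A tie at an
endpoint's maximum drops all tied edges — joining on an ambiguous best hit
risks chimeras, and a dropped true join can be recovered by a later round.
After reciprocal-best filtering every node has link degree ≤ 1, so
components are alternating sister/link paths or cycles; each cycle loses its
minimum-weight link (ties: lexicographically smallest end pair). Path
traversal assigns orientation by the side a link leaves (tail → `+`,
head → `-`) and enters (head → `+`, tail → `-`); the two rules agree on
interior contigs, isolated contigs become forward singletons, and a
traversal from the other terminal yields the same canonical cluster.

**Consensus.** The turning point is detected once per (end size, flavor)
pair and shared across that pair's multipliers — ten detections feeding
ninety cutoffs. Cluster units are canonicalized (the lexicographically
smaller of a unit and its reversal-with-flipped-strands) before counting.
Units are emitted by frequency; ties order by total length descending
(favoring chromosome-scale units), then lexicographically, making the
output byte-deterministic. Contigs left unplaced are emitted as singletons
carrying their own singleton frequency, possibly zero. Degenerate grid
cells (no detectable turning point) contribute empty results and lower the
achievable robustness rather than aborting the run.

**Iterative rounds.** Consensus clusters become super-contigs whose member
bins are concatenated in path order (reversed within `-` members); bin ids
are untouched, so the contact matrix is reused without recounting — link
counts are position-independent, making the permutation exact. No gap bins
are inserted: a super-contig's end window deliberately spans member
junctions, which is precisely the mechanism that bridges repeat-dead ends.
Later rounds reuse the same multiplier grid and flavors. Iteration stops
when the cluster count stops decreasing or reaches the known chromosome
number; contigs too short for a round's windows are carried along as
singleton clusters so nothing is dropped between rounds.

**Mis-join detection.** Profiles use the raw matrix (counts, not balanced
intensities; configurable). The genome-wide median at the gap distance uses
the conventional mean-of-central-pair for even counts. Maximal sub-threshold
runs collapse to one breakpoint at the bin boundary nearest the run's
minimum; value ties (an all-zero trough) resolve toward the run's center,
which straddles a genuine junction. With a unitig map, only candidates
within one bin of an internal unitig boundary survive — bin resolution is
the natural corroboration window. Breaking a contig renames it
`<id>_1, <id>_2, …`, reassigns its bins with recomputed local coordinates,
and leaves the matrix untouched.

**Small contigs.** Contigs below the eligibility floor are excluded from
scaffolding and can afterwards be assigned to the cluster with the maximal
total link count over all their bins; ties or an all-zero row leave them
unassigned, and no order or orientation is attempted for them.

## The synthetic data generator

The generator emulates exactly the structure the method assumes: cis
contacts Poisson-distributed with mean `C · d^(-α)` at distance `d` bins
(defaults `C = 100`, `α = 1`, diagonal treated as `d = 1`), trans contacts
Poisson with mean `λ_t = C / 1000 = 0.1`; chromosomes (default five of
40 Mb, the large-contig regime the tool targets) split at random bin
boundaries into 1–6 contigs of ≥ 1 Mb; the bin table lists contigs in
shuffled order so bin numbering leaks no adjacency; the "normalized" flavor
is symmetric row-balancing toward a common row sum — a stand-in with the
same interface as ICE output, sufficient because the pipeline consumes
matrix values generically. Optional features: mis-joined contigs built by
concatenating two non-adjacent fragments at a recorded bin boundary (the
matrix is generated from true genomic positions, so the junction shows a
contact trough at the trans level), and junction-local contact suppression
(all cis pairs straddling a junction with both bins inside a radius) that
mimics repeat-dead contig ends.

It does **not** emulate read-level noise, restriction-site geometry, ICE's
actual balancing model, diploid artefacts, structural heterozygosity, or
reverse-oriented contigs in the truth (orientation recovery is still
exercised, because the extractor must infer strand from end-pair geometry
alone). Passing tests on these fixtures therefore demonstrate the
correctness of the algorithmics under the method's own statistical
assumptions — not performance on real libraries, where repeat structure,
coverage waves and normalization artefacts matter.

Fixture scales were chosen to keep the full suite and the acceptance script
within a few minutes on one CPU: recovery runs use five 40-Mb chromosomes
(20 simulated genomes), mis-join accuracy uses five six-chromosome genomes
of 30 Mb with ten injected errors each (≥ 50 erroneous and ≥ 50 clean
contigs), and the iterative scenario uses three 100-Mb chromosomes of two
contigs each with a 25-bin suppression radius — chromosomes must be long
enough that links between the *far* ends of two same-chromosome contigs sit
at the trans background, as they do in real genomes, otherwise round 1
would bridge chromosomes through their distal ends.

## Known limitations

- Eligibility is all-or-nothing per contig; a contig barely above the floor
  contributes noisy, narrow windows.
- The consensus has no notion of partial credit: a unit either recurs
  verbatim (after canonicalization) or not, so near-identical units split
  their frequency.
- Cycle breaking assumes at most one circular path per component
  (guaranteed after reciprocal-best filtering, where link degree ≤ 1).
- Robustness compares against the full grid cardinality even when some
  cells are degenerate; on sparse inputs the printed maximum may be
  unreachable.
- The mis-join detector needs the junction's flanks to span the gap
  distance; errors within 500 kb of a contig end are invisible at the
  default gap.
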