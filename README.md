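# hicends

Chromosome-level scaffolding of **large contigs** from Hi-C links restricted
to contig ends.

Modern HiFi/ONT assemblies routinely reach contig N50 sizes of tens of
megabases, with a handful of contigs per chromosome. Classical Hi-C
scaffolders aggregate links over whole contigs, which works for fragmented
assemblies but backfires for large contigs: the Hi-C links that tie two
*adjacent* contigs together concentrate in a narrow region around their
facing ends (usually < 3 Mb), while whole-contig sums are dominated by
background links that every pair of contigs shares. As contigs grow, the
adjacent (signal) and non-adjacent (noise) linkage counts converge and
mis-joins become likely.

`hicends` scaffolds large contigs (N50 near or above 10 Mb, N90 near or
above 1 Mb) by using only the most informative part of the data:

1. **End windows.** For every contig with at least `2w` bins, sum contacts
   over its first (head) and last (tail) `w` 100-kb bins; the end-pair
   contact is `T(e1, e2) = Σ_{i∈e1, j∈e2} M(i, j)` over the HiC-Pro bin
   matrix `M` (raw or ICE-normalized).
2. **Turning point.** Sorted in descending order, end-pair values drop
   steeply through the adjacent-pair regime and flatten into background.
   After min-max normalizing both axes, the curve runs from (0, 1) to
   (1, 0); rotating it 45° anticlockwise makes the endpoint chord
   horizontal, and the lowest rotated point — `argmin(x + y)` — is the
   basic cutoff `T`.
3. **Graph cleaning.** Build a graph whose nodes are contig ends (the two
   ends of a contig tied by an unbreakable sister edge) and whose link
   edges are end pairs with contact above `m × T`. Keep a link only if it
   is the strict maximum for *both* of its endpoints (reciprocal best),
   then break any remaining circular path at its weakest link. The result
   is a union of simple paths, each an ordered, oriented scaffold.
4. **Consensus and robustness.** Repeat over a grid of end sizes
   (0.5–2.5 Mb in 0.5-Mb steps), cutoff multipliers (1.0–5.0 in 0.5
   steps) and both matrix flavors — 90 runs — then merge the canonical
   cluster units by frequency, greedily emitting non-overlapping units.
   A unit's frequency (max 90) is its *robustness* score.
5. **Iterative mode.** If round 1 leaves a chromosome in pieces (e.g.
   repeat-dead contig ends), consensus clusters become super-contigs and
   are re-scaffolded with larger end windows (3–5 Mb, then 5.5–7.5 Mb, …).
6. **Mis-join correction (optional).** Inside a contig, the contact
   between bins 500 kb apart collapses at an assembly mis-join. Positions
   where this profile falls below 10% of the genome-wide median — and,
   when a unitig map is available, that coincide with a unitig boundary —
   are breakpoints at which contigs are split before scaffolding.

Inputs are the HiC-Pro `.bed` bin table and sparse `.matrix` files at
100-kb bin size, plus optionally contig FASTA and a unitig-to-contig map
(4-column TSV, or derived from assembler GFA read placements). Outputs are
a cluster table, GFA1 (viewable in Bandage), AGP v2.1 and scaffold FASTA.

## Worked example

Simulate a two-chromosome genome (30 Mb each, power-law cis contact decay,
uniform trans background), then scaffold it:

```bash
hicends simulate --chroms 2 --sizes 30000000,30000000 --seed 3 --out-dir demo
hicends scaffold --bed demo/abs.bed --raw-matrix demo/raw.matrix \
    --iced-matrix demo/iced.matrix --out-prefix demo/run
```

which prints

```
2 clusters (max robustness 90) -> demo/run.cluster.tsv
```

and writes the cluster table

```
#cluster_id  contig_count  cluster_length  robustness  contigs_with_order_and_orientation
Cluster_01   1             30000000        90          contig_000+
Cluster_02   5             30000000        55          contig_001-;contig_003-;contig_005-;contig_004-;contig_002-
```

Chromosome 2 was simulated as a single contig (`contig_000`): it appears as
a singleton cluster found in all 90 grid cells (robustness 90). Chromosome 1
was split into five contigs; the simulator's truth table
(`demo/truth_order.tsv`) lists them in genomic order
`contig_002;contig_004;contig_005;contig_003;contig_001`, and `Cluster_02`
is exactly that path read in reverse with all orientations flipped — the
same scaffold. Its robustness of 55/90 reflects that very aggressive
cutoffs (high multipliers) split off weakly linked ends in some cells.
`demo/run.grid_summary.tsv` records, per grid cell, the detected turning
point, the cutoff and the resulting cluster count, e.g.

```
#end_size_bp  flavor  multiplier  turning_point  cutoff  n_clusters  n_small_contigs
500000        raw     1.0         39             39      2           0
500000        raw     1.5         39             58.5    2           0
```

`demo/run.agp` lays the scaffolds out with 100-bp proximity-ligation gaps,
and with `--fasta` the scaffold sequences are emitted as well.

Other subcommands: `hicends correct` (mis-join detection/breaking),
`hicends iterate` (multi-round scaffolding), `hicends assign-small`
(attach sub-1-Mb contigs to finished clusters by maximum total links).

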