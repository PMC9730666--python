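import numpy as np
import pytest

from hicends.io import read_bin_table, read_contact_matrix
from hicends.simulate import (
    SimSpec,
    fragment_chromosomes,
    inject_misjoins,
    simulate_contact_matrix,
    simulate_dataset,
    simulate_genome_layout,
    write_hicpro_fixture,
)


def test_layout_sizes_and_determinism():
    spec = SimSpec(n_chrom=2, chrom_sizes=(10_000_000, 10_000_000), seed=4)
    layout = simulate_genome_layout(spec)
    assert [s // spec.bin_size for _, s in layout.chroms] == [100, 100]
    assert simulate_genome_layout(spec).chroms == layout.chroms


def test_layout_rounds_up_to_bin_multiple():
    spec = SimSpec(n_chrom=1, chrom_sizes=(10_050_000,))
    layout = simulate_genome_layout(spec)
    assert layout.chroms[0][1] == 10_100_000


def test_fragmentation_respects_bounds_over_seeds():
    adjacency_total = 0
    for seed in range(12):
        spec = SimSpec(n_chrom=3, chrom_sizes=(10_000_000,) * 3,
                       contigs_per_chrom=(1, 6), seed=seed)
        layout = simulate_genome_layout(spec)
        contigs, order = fragment_chromosomes(layout, spec)
        ks = []
        for chrom, size in layout.chroms:
            names = order[chrom]
            ks.append(len(names))
            assert 1 <= len(names) <= 6
            by = {c.name: c for c in contigs}
            total = sum(by[n].length for n in names)
            assert total == size
            assert all(by[n].length >= spec.min_contig for n in names)
            # contiguous, ordered fragments
            pos = 0
            for n in names:
                chrom_name, start, end = by[n].parts[0]
                assert (chrom_name, start) == (chrom, pos)
                pos = end
        adjacency_total += sum(k - 1 for k in ks)
    assert adjacency_total > 0


def test_single_contig_chromosome():
    spec = SimSpec(n_chrom=1, chrom_sizes=(5_000_000,), contigs_per_chrom=(1, 1))
    layout = simulate_genome_layout(spec)
    contigs, order = fragment_chromosomes(layout, spec)
    assert len(contigs) == 1
    assert contigs[0].length == 5_000_000


def test_contact_rates_match_the_decay_model():
    """Empirical means approach C/d in cis and lambda_t in trans."""
    spec = SimSpec(n_chrom=2, chrom_sizes=(20_000_000,) * 2,
                   contigs_per_chrom=(1, 1), cis_scale=100.0, seed=9)
    layout = simulate_genome_layout(spec)
    contigs, _ = fragment_chromosomes(layout, spec)
    bins, raw, _ = simulate_contact_matrix(contigs, spec)
    ids = {c.name: bins.bins_of(c.name) for c in contigs}
    (a, b) = [c.name for c in contigs]
    d1 = [raw.value(int(i), int(i) + 1) for i in ids[a][:-1]]
    assert np.mean(d1) == pytest.approx(spec.cis_scale, rel=0.15)
    d10 = [raw.value(int(i), int(i) + 10) for i in ids[a][:-10]]
    assert np.mean(d10) == pytest.approx(spec.cis_scale / 10, rel=0.3)
    rng = np.random.default_rng(0)
    trans = [
        raw.value(int(rng.choice(ids[a])), int(rng.choice(ids[b])))
        for _ in range(4000)
    ]
    assert np.mean(trans) == pytest.approx(spec.lambda_trans, abs=0.05)


def test_same_seed_reproduces_triplets(tmp_path):
    spec = SimSpec(n_chrom=2, chrom_sizes=(5_000_000,) * 2, seed=11)
    d1 = simulate_dataset(spec)
    d2 = simulate_dataset(spec)
    assert list(d1.raw.triplets()) == list(d2.raw.triplets())
    assert d1.order == d2.order


def test_misjoin_injection_bookkeeping():
    spec = SimSpec(n_chrom=3, chrom_sizes=(12_000_000,) * 3,
                   contigs_per_chrom=(3, 4), seed=13)
    layout = simulate_genome_layout(spec)
    contigs, order = fragment_chromosomes(layout, spec)
    out, new_order, breakpoints = inject_misjoins(contigs, order, 2, seed=13)
    assert len(breakpoints) == 2
    assert len(out) == len(contigs) - 2
    by = {c.name: c for c in out}
    for name, pos in breakpoints.items():
        assert pos % spec.bin_size == 0
        assert len(by[name].parts) == 2
        assert by[name].parts[0][2] - by[name].parts[0][1] == pos
        # the two fragments are not genomic neighbours
        (c1, s1, e1), (c2, s2, e2) = by[name].parts
        assert not (c1 == c2 and (e1 == s2 or e2 == s1))


def test_misjoin_identity_and_infeasible():
    spec = SimSpec(n_chrom=1, chrom_sizes=(5_000_000,), contigs_per_chrom=(2, 2))
    layout = simulate_genome_layout(spec)
    contigs, order = fragment_chromosomes(layout, spec)
    same, same_order, bps = inject_misjoins(contigs, order, 0)
    assert same == contigs and bps == {}
    with pytest.raises(ValueError):
        # the only two contigs are neighbours: no non-adjacent pair exists
        inject_misjoins(contigs, order, 1)


def test_junction_contact_is_trough_level():
    """At an injected junction the crossing contact sits at the trans rate,
    far below a tenth of the genome median at the profile gap distance."""
    from hicends.misjoin import (
        adjacent_contact_profile,
        genome_median_gap_contact,
    )

    spec = SimSpec(n_chrom=3, chrom_sizes=(20_000_000,) * 3,
                   contigs_per_chrom=(3, 4), seed=17)
    data = simulate_dataset(spec, n_errors=2)
    median = genome_median_gap_contact(data.bins, data.raw)
    for contig, pos in data.breakpoints.items():
        prof = adjacent_contact_profile(contig, data.bins, data.raw)
        crossing = [
            p.value for p in prof.points
            if abs(p.midpoint - pos) <= data.bins.bin_size
        ]
        assert crossing and min(crossing) < 0.1 * median


def test_fixture_write_read_round_trip(tmp_path):
    spec = SimSpec(n_chrom=2, chrom_sizes=(6_000_000,) * 2, seed=19)
    data = simulate_dataset(spec)
    paths = write_hicpro_fixture(data.bins, data.raw, data.normalized, tmp_path)
    bins = read_bin_table(paths["bed"])
    raw = read_contact_matrix(paths["raw"], bins, flavor="raw")
    norm = read_contact_matrix(paths["normalized"], bins, flavor="normalized")
    assert bins.df.equals(data.bins.df)
    assert list(raw.triplets()) == list(data.raw.triplets())
    for (i1, j1, v1), (i2, j2, v2) in zip(norm.triplets(), data.normalized.triplets()):
        assert (i1, j1) == (i2, j2)
        assert v1 == pytest.approx(v2, abs=5e-6)
    # triplet files are sorted by (i, j)
    rows = [tuple(map(float, l.split())) for l in open(paths["raw"])]
    assert rows == sorted(rows)


def test_empty_matrix_file_round_trip(tmp_path):
    from hicends.io import ContactMatrix, write_contact_matrix

    p = tmp_path / "empty.matrix"
    write_contact_matrix(ContactMatrix([], [], []), p)
    assert len(read_contact_matrix(p)) == 0


def test_normalized_rows_approach_common_sum():
    spec = SimSpec(n_chrom=2, chrom_sizes=(8_000_000,) * 2,
                   contigs_per_chrom=(1, 1), seed=23)
    data = simulate_dataset(spec)
    sym, _ = data.normalized.to_symmetric_csr(data.bins.bin_ids)
    sums = np.asarray(sym.sum(axis=1)).ravel()
    assert sums.std() / sums.mean() < 0.05
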