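"""Feature-block construction checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epifusion.ingest import (
    BIN_SIZE,
    HISTONE_MARKS,
    N_BINS,
    N_TFS,
    WINDOW_HALF,
    GeneRecord,
    MultiOmicsDataset,
    TFMatrix,
    bin_histone_signal,
    build_tf_matrix,
    extract_methylation,
    label_genes,
    tf_catalog,
)


def gene(tss=100000, strand="+", expression=1.0):
    return GeneRecord("g1", "chr1", tss, strand, expression)


def brute_force_bins(positions, g):
    """Independent per-read assignment: window bins in transcriptional order."""
    counts = np.zeros(N_BINS)
    for p in positions:
        off = p - (g.tss - WINDOW_HALF)
        if 0 <= off < 2 * WINDOW_HALF:
            b = off // BIN_SIZE
            if g.strand == "-":
                b = N_BINS - 1 - b
            counts[b] += 1
    return counts


class TestHistoneBinning:
    def test_matrix_has_40_bins_of_100bp(self):
        hm = bin_histone_signal({}, gene())
        assert hm.values.shape == (7, 40)
        assert 2 * WINDOW_HALF // BIN_SIZE == 40

    def test_zero_coverage_gives_all_zero_matrix(self):
        hm = bin_histone_signal({m: np.array([]) for m in HISTONE_MARKS}, gene())
        assert np.all(hm.values == 0.0)

    def test_five_reads_in_tss_bin(self):
        """5 H3K4me3 reads at the TSS -> a single ln(6) entry at the TSS bin."""
        g = gene(tss=100000)
        reads = {"H3K4me3": np.full(5, g.tss)}
        hm = bin_histone_signal(reads, g)
        expected_bin = WINDOW_HALF // BIN_SIZE  # bin containing the TSS
        assert hm.values[HISTONE_MARKS.index("H3K4me3"), expected_bin] == pytest.approx(
            np.log(6)
        )
        assert np.count_nonzero(hm.values) == 1
        oracle = brute_force_bins(reads["H3K4me3"], g)
        np.testing.assert_array_equal(
            hm.values[HISTONE_MARKS.index("H3K4me3")], np.log1p(oracle)
        )

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_per_read_oracle(self, strand):
        rng = np.random.default_rng(11)
        g = gene(tss=50000, strand=strand)
        reads = {
            m: rng.integers(g.tss - 3000, g.tss + 3000, size=200) for m in HISTONE_MARKS
        }
        hm = bin_histone_signal(reads, g)
        for mi, m in enumerate(HISTONE_MARKS):
            np.testing.assert_allclose(
                hm.values[mi], np.log1p(brute_force_bins(reads[m], g))
            )

    def test_strand_convention_round_trip(self):
        """Mirroring a minus-strand gene's reads onto a plus-strand gene is identity."""
        rng = np.random.default_rng(3)
        tss = 80000
        pos = rng.integers(tss - WINDOW_HALF, tss + WINDOW_HALF, size=300)
        minus = bin_histone_signal({"H3K27ac": pos}, gene(tss=tss, strand="-"))
        mirrored = 2 * tss - 1 - pos  # reverses the window around the TSS
        plus = bin_histone_signal({"H3K27ac": mirrored}, gene(tss=tss, strand="+"))
        np.testing.assert_array_equal(minus.values, plus.values)

    def test_window_past_chromosome_start_pads_and_warns(self):
        g = gene(tss=500)
        with pytest.warns(UserWarning, match="past chromosome start"):
            hm = bin_histone_signal({"H3K9ac": np.array([100, 600])}, g)
        assert hm.values.shape == (7, 40)

    def test_interval_coverage_equivalent_to_reads(self):
        """Aligned coverage tiles reproduce per-read counts exactly."""
        g = gene(tss=10000)
        reads = np.repeat([10000, 10150], [4, 3])
        via_reads = bin_histone_signal({"H3K4me3": reads}, g)
        tiles = [(10000, 10100, 4), (10100, 10200, 3)]
        via_tiles = bin_histone_signal({"H3K4me3": np.array(tiles)}, g)
        np.testing.assert_allclose(via_reads.values, via_tiles.values)


class TestMethylationExtraction:
    def test_window_filter_matches_brute_force(self):
        g = gene(tss=10000)
        calls = [(8500, 0.2), (10010, 0.5), (12500, 0.9)]
        track = extract_methylation(calls, g)
        assert len(track) == 2
        np.testing.assert_array_equal(track.offsets, [-1500, 10])
        # brute force over random calls
        rng = np.random.default_rng(5)
        pos = rng.choice(np.arange(5000, 15000), size=500, replace=False)
        betas = rng.random(500)
        track = extract_methylation(list(zip(pos, betas)), g)
        keep = np.abs(pos - g.tss) <= 2000
        assert len(track) == keep.sum()

    def test_boundary_cpgs_are_retained(self):
        g = gene(tss=10000)
        track = extract_methylation([(8000, 0.1), (12000, 0.9)], g)
        assert len(track) == 2  # closed interval: both boundaries kept

    def test_empty_window(self):
        assert len(extract_methylation([], gene())) == 0

    def test_minus_strand_offsets_increase_in_transcription_direction(self):
        g = gene(tss=10000, strand="-")
        track = extract_methylation([(9000, 0.1), (11500, 0.6)], g)
        np.testing.assert_array_equal(track.offsets, [-1500, 1000])
        np.testing.assert_array_equal(track.betas, [0.6, 0.1])

    def test_invalid_beta_rejected_with_location(self):
        with pytest.raises(ValueError, match="record 1"):
            extract_methylation([(10000, 0.5), (10010, 1.5)], gene())


class TestTFMatrix:
    def test_empty_candidate_set(self):
        tf = build_tf_matrix([], gene())
        assert tf.values.shape == (3, N_TFS)
        assert not tf.mask.any()
        assert np.all(tf.values == 0)

    def test_two_candidates_two_nonzero_columns(self):
        catalog = tf_catalog()
        table = [(catalog[3], 5.0, 2, 7.5), (catalog[100], 1.0, 1, 3.0)]
        tf = build_tf_matrix(table, gene())
        nonzero_cols = int((np.abs(tf.values).sum(axis=0) > 0).sum())  # independent scan
        assert nonzero_cols == 2
        assert tf.mask.sum() == 2
        assert tf.values[:, 3] == pytest.approx([5.0, 2.0, 7.5])

    def test_unknown_tf_name_names_offender(self):
        with pytest.raises(KeyError, match="NOSUCHTF"):
            build_tf_matrix([("NOSUCHTF", 1.0, 1, 1.0)], gene())

    def test_mask_false_columns_must_be_zero(self):
        values = np.zeros((3, N_TFS))
        values[0, 5] = 1.0
        with pytest.raises(ValueError, match="masked|zero"):
            TFMatrix(values, np.zeros(N_TFS, dtype=bool))


class TestLabels:
    def test_median_split_of_sorted_quartet(self):
        labels = label_genes(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        np.testing.assert_array_equal(labels.values, [-1, -1, 1, 1])

    def test_labels_are_plus_minus_one(self):
        rng = np.random.default_rng(0)
        labels = label_genes(pd.Series(rng.random(31)))
        assert set(labels.unique()) <= {1, -1}

    @given(
        st.lists(st.floats(min_value=0, max_value=100, allow_nan=False), min_size=2,
                 max_size=40)
    )
    @settings(max_examples=60, deadline=None)
    def test_tie_rule_matches_brute_force_and_caps_heg(self, values):
        labels = label_genes(pd.Series(values))
        med = float(np.median(values))
        brute = np.where(np.asarray(values) > med, 1, -1)  # ties -> LEG
        np.testing.assert_array_equal(labels.values, brute)
        assert (labels == 1).sum() <= int(np.ceil(len(values) / 2))

    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError):
            label_genes(pd.Series([1.0]))


def test_dataset_npz_round_trip(tmp_path):
    from epifusion.synthetic_data import SimConfig, simulate_dataset

    ds, _ = simulate_dataset(SimConfig(seed=2, n_genes=20))
    path = tmp_path / "ds.npz"
    ds.to_npz(path)
    back = MultiOmicsDataset.from_npz(path)
    assert back.gene_ids == ds.gene_ids
    np.testing.assert_array_equal(back.hm, ds.hm)
    np.testing.assert_array_equal(back.labels, ds.labels)
    for a, b in zip(back.me_betas, ds.me_betas):
        np.testing.assert_array_equal(a, b)
    for a, b in zip(back.tf_vals, ds.tf_vals):
        np.testing.assert_array_equal(a, b)


def test_prebinned_histone_tsv_round_trip(tmp_path):
    """(gene_id, mark, 40 comma-separated counts) TSV reproduces the matrix."""
    from epifusion.ingest import histone_matrix_from_binned, read_binned_histone_tsv

    rng = np.random.default_rng(8)
    counts = {m: rng.poisson(3.0, N_BINS) for m in HISTONE_MARKS[:2]}
    lines = [
        f"g1\t{m}\t" + ",".join(str(int(c)) for c in v) for m, v in counts.items()
    ]
    path = tmp_path / "binned.tsv"
    path.write_text("\n".join(lines) + "\n")
    binned = read_binned_histone_tsv(path)
    hm = histone_matrix_from_binned(binned["g1"])
    for m, v in counts.items():
        np.testing.assert_allclose(
            hm.values[HISTONE_MARKS.index(m)], np.log1p(v)
        )
    assert np.all(hm.values[2:] == 0)

    bad = tmp_path / "bad.tsv"
    bad.write_text("g1\tH3K4me3\t1,2,3\n")
    with pytest.raises(ValueError, match="expected 40"):
        read_binned_histone_tsv(bad)
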