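import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taucleave import (
    KineticsConfig,
    PeptideObservation,
    SubstrateSequence,
    TimeSeriesDesign,
    average_intensities,
    benjamini_hochberg,
    compute_cut_frequency,
    cut_frequency,
    filter_by_score,
    intensity_ratios,
    significance_gate,
    site_counts,
)

from .conftest import make_observation
from .oracles import straight_line_frequencies


class TestDesign:
    def test_time_points_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            TimeSeriesDesign.create([60.0, 60.0, 10.0], 2, 1)

    def test_requires_a_control(self):
        with pytest.raises(ValueError, match="control"):
            TimeSeriesDesign.create([10.0], 2, 0)

    def test_manifest_roundtrip(self, small_design, tmp_path):
        path = tmp_path / "manifest.tsv"
        small_design.to_manifest(path)
        back = TimeSeriesDesign.from_manifest(path)
        assert back.time_points == small_design.time_points
        assert back.samples == dict(small_design.samples)


class TestScoreFilter:
    def test_boundary_inclusive_at_threshold(self):
        peptides = [
            PeptideObservation("AAAAAAA", s, {"x": 1.0}) for s in (49.0, 50.0, 51.0)
        ]
        kept = filter_by_score(peptides, 50.0)
        assert [p.score for p in kept] == [50.0, 51.0]

    def test_zero_threshold_is_identity(self):
        peptides = [PeptideObservation("AAAAAAA", 1.0, {"x": 1.0})]
        assert filter_by_score(peptides, 0.0) == peptides

    def test_empty_input(self):
        assert filter_by_score([], 50.0) == []


class TestSignificanceGate:
    def test_product_absent_from_controls_is_significant(self):
        assert significance_gate([100.0, 110.0, 90.0], [0.0, 0.0, 0.0])

    def test_single_replicate_detection_not_sufficient(self):
        assert not significance_gate([100.0, 0.0, 0.0], [0.0, 0.0, 0.0])

    def test_identical_to_controls_not_significant(self):
        assert not significance_gate([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])

    def test_strong_separation_significant(self):
        """On the log2 scale (10.0, 10.1, 9.9) vs (2.0, 2.1, 1.9): Welch t is
        ~98 with ~4 df, far beyond the 0.05 critical value."""
        assert significance_gate(
            [10.0, 10.1, 9.9], [2.0, 2.1, 1.9], alpha=0.05, log2_transform=False
        )

    def test_undetected_never_significant(self):
        assert not significance_gate([0.0, 0.0], [0.0, 0.0])

    def test_requires_replicates(self):
        with pytest.raises(ValueError):
            significance_gate([], [0.0])

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            significance_gate([1.0], [0.0], alpha=1.5)


class TestAveraging:
    def test_mean_over_replicates(self, small_design):
        p = make_observation(
            "AAAAAAA",
            100.0,
            {10.0: [100.0, 200.0], 60.0: [300.0, 300.0], 300.0: [0.0, 0.0]},
            small_design,
        )
        row = average_intensities(p, small_design)
        assert row.tolist() == [150.0, 300.0, 0.0]

    def test_gated_out_time_point_is_zero(self, small_design):
        """Present in one replicate only (and absent from controls): below
        the detection rule, so the average is forced to zero."""
        p = make_observation("AAAAAAA", 100.0, {10.0: [500.0, 0.0]}, small_design)
        row = average_intensities(p, small_design)
        assert row.tolist() == [0.0, 0.0, 0.0]

    def test_all_zero_row(self, small_design):
        p = make_observation("AAAAAAA", 100.0, {}, small_design)
        assert average_intensities(p, small_design).tolist() == [0.0, 0.0, 0.0]


class TestIntensityRatios:
    @pytest.mark.parametrize(
        "averages,expected",
        [
            ([0.0, 100.0, 200.0], [0.0, 1.0, 2.0]),
            ([50.0, 0.0, 100.0], [1.0, 0.0, 2.0]),
            ([5.0], [1.0]),
        ],
    )
    def test_reference_is_first_positive_average(self, averages, expected):
        assert intensity_ratios(averages).tolist() == expected

    def test_all_zero_row_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            intensity_ratios([0.0, 0.0])

    @settings(max_examples=100, deadline=None)
    @given(
        averages=st.lists(
            st.one_of(st.just(0.0), st.floats(1e-6, 1e6, allow_nan=False)),
            min_size=1,
            max_size=8,
        ).filter(lambda a: any(v > 0 for v in a)),
        factor=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, averages, factor):
        """Multiplying all of a peptide's intensities by a constant leaves
        its ratios unchanged."""
        scaled = [v * factor for v in averages]
        np.testing.assert_allclose(
            intensity_ratios(scaled), intensity_ratios(averages), rtol=1e-9
        )


class TestCutFrequencyAssembly:
    def test_single_peptide_single_site(self):
        matrix = cut_frequency(
            {266: [(0, 1.0)]}, {0: np.array([0.0, 1.0, 2.0])}, [10.0, 60.0, 300.0]
        )
        assert matrix.frequencies.loc[266].tolist() == [0.0, 1.0, 2.0]
        assert matrix.provenance[266] == [0]

    def test_shared_site_sums_ratios(self):
        matrix = cut_frequency(
            {266: [(0, 1.0), (1, 1.0)]},
            {0: np.array([1.0, 2.0]), 1: np.array([1.0, 3.0])},
            [10.0, 60.0],
        )
        assert matrix.frequencies.loc[266].tolist() == [2.0, 5.0]

    def test_fractional_weights(self):
        matrix = cut_frequency(
            {266: [(0, 0.5)]}, {0: np.array([1.0, 4.0])}, [10.0, 60.0]
        )
        assert matrix.frequencies.loc[266].tolist() == [0.5, 2.0]

    def test_site_counts_per_time_and_cumulative(self):
        matrix = cut_frequency(
            {266: [(0, 1.0)], 344: [(1, 1.0)]},
            {0: np.array([0.0, 1.0]), 1: np.array([1.0, 1.0])},
            [10.0, 60.0],
        )
        assert site_counts(matrix).tolist() == [1, 2]
        matrix2 = cut_frequency(
            {266: [(0, 1.0)]}, {0: np.array([1.0, 0.0])}, [10.0, 60.0]
        )
        assert site_counts(matrix2).tolist() == [1, 0]
        assert site_counts(matrix2, cumulative=True).tolist() == [1, 1]

    def test_empty_matrix_counts_zero(self):
        matrix = cut_frequency({}, {}, [10.0, 60.0])
        assert site_counts(matrix).tolist() == [0, 0]


def random_instance(rng, n_time=3, n_rep=2, n_ctrl=2):
    """A random small digest table on a random substrate."""
    L = int(rng.integers(12, 40))
    residues = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
    seq = SubstrateSequence(id="rand", residues=residues)
    times = sorted(rng.choice([5.0, 15.0, 60.0, 120.0, 300.0], n_time, replace=False))
    design = TimeSeriesDesign.create(times, n_rep, n_ctrl)
    peptides = []
    for _ in range(int(rng.integers(1, 11))):
        s = int(rng.integers(1, L))
        e = int(rng.integers(s, min(L, s + 12)))
        per_time = {}
        for t in times:
            if rng.random() < 0.25:
                per_time[t] = [0.0] * n_rep
            else:
                per_time[t] = list(np.round(rng.uniform(0, 500, n_rep), 3))
        controls = (
            list(np.round(rng.uniform(0, 50, n_ctrl), 3))
            if rng.random() < 0.3
            else [0.0] * n_ctrl
        )
        peptides.append(
            make_observation(
                seq.subsequence(s, e),
                float(np.round(rng.uniform(20, 200), 1)),
                per_time,
                design,
                controls,
            )
        )
    return peptides, seq, design


class TestPipelineAgainstOracle:
    def test_matches_straight_line_implementation(self):
        """The pipeline's frequency matrix equals a naive line-by-line
        rendering of the two-step procedure, cell for cell, on random
        small instances."""
        rng = np.random.default_rng(202)
        for _ in range(30):
            peptides, seq, design = random_instance(rng)
            result = compute_cut_frequency(peptides, seq, design)
            expected = straight_line_frequencies(peptides, seq, design)
            got = {
                int(p1): result.matrix.frequencies.loc[p1].tolist()
                for p1 in result.matrix.sites
            }
            assert set(got) == set(expected)
            for p1 in expected:
                np.testing.assert_allclose(got[p1], expected[p1], rtol=1e-9, atol=1e-12)

    def test_monotone_under_added_evidence(self, small_design):
        """Adding a peptide with positive ratios to a site never decreases
        any cell."""
        seq = SubstrateSequence(id="s", residues="MKLVAEGHIKW")
        base = [
            make_observation(
                "KLVA", 90.0, {10.0: [50.0, 60.0], 60.0: [100.0, 120.0]}, small_design
            )
        ]
        extra = make_observation(
            "VAEG", 90.0, {10.0: [10.0, 12.0], 60.0: [30.0, 33.0]}, small_design
        )
        before = compute_cut_frequency(base, seq, small_design).matrix
        after = compute_cut_frequency(base + [extra], seq, small_design).matrix
        for p1 in before.sites:
            assert (
                after.frequencies.loc[p1].to_numpy()
                >= before.frequencies.loc[p1].to_numpy() - 1e-12
            ).all()

    def test_ambiguous_peptides_counted_in_qc_not_matrix(self, small_design):
        seq = SubstrateSequence(id="rep", residues="MKLVKLVAEGH")
        ambiguous = make_observation(
            "KLV", 90.0, {10.0: [50.0, 60.0]}, small_design
        )
        result = compute_cut_frequency([ambiguous], seq, small_design)
        assert result.qc.n_ambiguous == 1
        assert result.matrix.frequencies.empty

    def test_fractional_policy_splits_weight(self, small_design):
        seq = SubstrateSequence(id="rep", residues="MKLVKLVAEGH")
        ambiguous = make_observation(
            "KLV", 90.0, {10.0: [50.0, 60.0], 60.0: [100.0, 120.0]}, small_design
        )
        cfg = KineticsConfig(ambiguity="fractional")
        result = compute_cut_frequency([ambiguous], seq, small_design, cfg)
        # loci (2-4) and (5-7): p1=1 is evidenced only by the N-terminus of
        # the first locus, so it carries half weight; p1=4 collects half
        # weight from each locus (C of 2-4, N of 5-7) for a full ratio.
        assert result.matrix.frequencies.loc[1].tolist() == [0.5, 1.0, 0.0]
        assert result.matrix.frequencies.loc[4].tolist() == [1.0, 2.0, 0.0]

    def test_all_frequencies_nonnegative(self, default_sim):
        result = default_sim.analyze()
        assert (result.matrix.frequencies.to_numpy() >= 0).all()

    def test_bh_correction_is_no_less_strict(self, small_design):
        """BH-adjusted p-values are >= raw p-values, so the corrected run
        never admits a peptide the uncorrected run rejects."""
        seq = SubstrateSequence(id="s", residues="MKLVAEGHIKW")
        rng = np.random.default_rng(7)
        peptides = []
        for s, e in [(2, 5), (3, 7), (5, 9)]:
            per_time = {
                t: list(rng.uniform(50, 200, 2)) for t in small_design.time_points
            }
            peptides.append(
                make_observation(
                    seq.subsequence(s, e), 90.0, per_time, small_design,
                    controls=list(rng.uniform(30, 120, 2)),
                )
            )
        raw = compute_cut_frequency(peptides, seq, small_design).matrix
        bh = compute_cut_frequency(
            peptides, seq, small_design, KineticsConfig(bh_correction=True)
        ).matrix
        raw_positive = (raw.frequencies.to_numpy() > 0).sum()
        bh_positive = (bh.frequencies.to_numpy() > 0).sum() if not bh.frequencies.empty else 0
        assert bh_positive <= raw_positive


def test_benjamini_hochberg_known_values():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(benjamini_hochberg(p), [0.04, 0.04, 0.04, 0.04])
    p = np.array([0.005, 0.5, np.nan])
    adj = benjamini_hochberg(p)
    np.testing.assert_allclose(adj[:2], [0.01, 0.5])
    assert np.isnan(adj[2])


def test_frequency_matrix_tsv_export(tmp_path, tau, default_sim):
    result = default_sim.analyze()
    path = tmp_path / "freq.tsv"
    result.matrix.to_tsv(path, substrate=tau)
    header = path.read_text().splitlines()[0].split("\t")
    assert header[:2] == ["p1", "residue"]
    assert len(header) == 2 + len(default_sim.design.time_points)
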