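import numpy as np
import pytest

import crosstalkqc as cq
from crosstalkqc.demux import DemuxPolicy
from crosstalkqc.simulate import ContaminationEvent, FamilySizeSpec, SimConfig
from crosstalkqc.stats import (
    CrosstalkMatrix,
    expected_misassignment,
    hop_rate_estimate,
    misassignment_report,
    mismatched_pair_rate,
    plate_grid,
    row_column_decomposition,
    symmetry_diagnostic,
)


def _dual_matrix(counts, plate, used):
    labels = [plate.i7_of(w) for w in plate.sorted_wells()]
    n = len(labels)
    return CrosstalkMatrix(np.asarray(counts)[:n, :n], labels[: len(counts)],
                           labels[: len(counts)], {w.label for w in used})


class TestMisassignmentReport:
    def test_zero_error_simulation_has_no_misassignment(self, dual_plate, dual_sheet):
        cfg = SimConfig(n_fragments=2000, seed=2,
                        duplicate_family_size=FamilySizeSpec("degenerate", 1))
        reads, _ = cq.simulate_experiment(dual_plate, dual_sheet, cfg)
        m = cq.build_crosstalk_matrix(reads, DemuxPolicy.for_plate(dual_plate),
                                      used_wells=dual_sheet.wells)
        rep = misassignment_report(m, dual_sheet.wells, dual_plate)
        assert rep.misassigned_reads == 0 and rep.overall_rate == 0.0

    def test_hand_built_three_by_three(self):
        """Diagonal (100,100,0) + one off-diagonal read, two used wells."""
        plate = cq.default_unique_dual_plate(n=3, seed=1)
        wells = plate.sorted_wells()
        counts = np.zeros((3, 3), int)
        counts[0, 0], counts[1, 1] = 100, 100
        counts[0, 1] = 1
        labels = [plate.i7_of(w) for w in wells]
        m = CrosstalkMatrix(counts, labels, labels)
        rep = misassignment_report(m, wells[:2], plate)
        assert rep.total_reads == 201
        assert rep.misassigned_reads == 1
        assert rep.overall_rate == pytest.approx(1 / 201)
        assert rep.not_a_well_reads == 1  # off-diagonal pair is not a well

    def test_unused_diagonal_well_counts_as_misassigned(self):
        plate = cq.default_unique_dual_plate(n=3, seed=1)
        wells = plate.sorted_wells()
        labels = [plate.i7_of(w) for w in wells]
        counts = np.diag([50, 50, 7])
        m = CrosstalkMatrix(counts, labels, labels)
        rep = misassignment_report(m, wells[:2], plate)
        assert rep.misassigned_reads == 7
        assert rep.per_unused_index == {wells[2].label: 7}

    def test_category_conservation(self, dual_plate, dual_sheet):
        cfg = SimConfig(n_fragments=4000, seed=3, index_error_rate=0.01, hop_rate=0.01,
                        duplicate_family_size=FamilySizeSpec("degenerate", 1))
        reads, _ = cq.simulate_experiment(dual_plate, dual_sheet, cfg)
        m = cq.build_crosstalk_matrix(reads, DemuxPolicy.for_plate(dual_plate),
                                      used_wells=dual_sheet.wells)
        rep = misassignment_report(m, dual_sheet.wells, dual_plate)
        assert sum(rep.per_unused_index.values()) + rep.not_a_well_reads == rep.misassigned_reads


class TestRowColumnDecomposition:
    def test_geometry_cases(self, combinatorial_plate):
        from crosstalkqc.plates import Well
        from crosstalkqc.stats import CrosstalkReport

        rep = CrosstalkReport(
            total_reads=100, misassigned_reads=12, overall_rate=0.12,
            per_unused_index={"A5": 5, "C7": 3, "C1": 4},
        )
        part = row_column_decomposition(rep, combinatorial_plate, [Well("A", 1)])
        assert part.same_row_only == 5  # A5 shares row A
        assert part.same_column_only == 4  # C1 shares column 1
        assert part.neither == 3  # C7 shares nothing
        assert part.total == 12

    def test_not_applicable_to_unique_dual(self, dual_plate):
        from crosstalkqc.stats import CrosstalkReport

        rep = CrosstalkReport(1, 0, 0.0, {})
        with pytest.raises(ValueError, match="combinatorial"):
            row_column_decomposition(rep, dual_plate, [])

    def test_oligo_contamination_lands_in_contaminant_column(self, combinatorial_plate):
        """i7-arm leaks misassign into the leaking well's column, never elsewhere."""
        from crosstalkqc.plates import Well

        used = [Well("A", 1), Well("B", 1), Well("C", 1)]
        sheet = cq.SampleSheet([cq.SampleEntry(f"s{i}", w) for i, w in enumerate(used)])
        events = tuple(ContaminationEvent(w, Well(w.row, 2), 0.01, arm="i7") for w in used)
        cfg = SimConfig(n_fragments=50_000, seed=5, contamination=events,
                        contamination_stage="oligo",
                        duplicate_family_size=FamilySizeSpec("degenerate", 1))
        reads, _ = cq.simulate_experiment(combinatorial_plate, sheet, cfg)
        m = cq.build_crosstalk_matrix(reads, DemuxPolicy.for_plate(combinatorial_plate),
                                      used_wells=used)
        rep = misassignment_report(m, used, combinatorial_plate)
        assert rep.misassigned_reads > 0
        assert all(Well.from_label(w).column == 2 for w in rep.per_unused_index)
        assert rep.row_column_partition.neither == 0


class TestMismatchedPairsAndHopEstimates:
    def test_diagonal_only_matrix_rate_zero(self, dual_plate):
        m = _dual_matrix(np.diag([10, 20, 30]), dual_plate, dual_plate.sorted_wells()[:3])
        assert mismatched_pair_rate(m) == 0.0

    def test_two_by_two_hand_count(self, dual_plate):
        m = _dual_matrix([[99, 1], [1, 99]], dual_plate, dual_plate.sorted_wells()[:2])
        assert mismatched_pair_rate(m) == pytest.approx(0.01)

    def test_published_arithmetic_baseline_correction(self, dual_plate):
        """pool 0.48% - baseline 0.09% -> corrected 0.39%."""
        base = _dual_matrix([[4991, 4], [5, 5000]], dual_plate, dual_plate.sorted_wells()[:2])
        pool = _dual_matrix([[4952, 24], [24, 5000]], dual_plate, dual_plate.sorted_wells()[:2])
        assert mismatched_pair_rate(base) == pytest.approx(0.0009)
        assert mismatched_pair_rate(pool) == pytest.approx(0.0048)
        (est,) = hop_rate_estimate({2: pool}, base)
        assert est.corrected_hop_rate == pytest.approx(0.0039)
        assert est.corrected_hop_rate <= est.mismatched_pair_rate

    def test_pool_rate_at_baseline_corrects_to_zero(self, dual_plate):
        m = _dual_matrix([[999, 1], [1, 999]], dual_plate, dual_plate.sorted_wells()[:2])
        (est,) = hop_rate_estimate({4: m}, m)
        assert est.corrected_hop_rate == 0.0

    def test_missing_baseline_flags_uncorrected(self, dual_plate):
        m = _dual_matrix([[999, 1], [1, 999]], dual_plate, dual_plate.sorted_wells()[:2])
        (est,) = hop_rate_estimate({4: m}, None)
        assert not est.corrected
        assert est.corrected_hop_rate == est.mismatched_pair_rate


class TestSymmetryDiagnostic:
    def _mat(self, counts, dual_plate):
        return _dual_matrix(counts, dual_plate, dual_plate.sorted_wells()[:3])

    def test_symmetric_counts_score_zero(self, dual_plate):
        m = self._mat([[1000, 40, 30], [40, 1000, 20], [30, 20, 1000]], dual_plate)
        diag = symmetry_diagnostic(m)
        assert diag.asymmetry_score == 0.0 and diag.verdict == "symmetric"

    def test_fully_one_sided_scores_one(self, dual_plate):
        m = self._mat([[1000, 100, 0], [0, 1000, 0], [0, 0, 1000]], dual_plate)
        diag = symmetry_diagnostic(m)
        assert diag.asymmetry_score == 1.0 and diag.verdict == "skewed"

    def test_empty_off_diagonal_is_indeterminate(self, dual_plate):
        diag = symmetry_diagnostic(self._mat(np.diag([5, 5, 5]), dual_plate))
        assert diag.verdict == "indeterminate"

    def test_sparse_counts_are_indeterminate(self, dual_plate):
        m = self._mat([[1000, 3, 0], [0, 1000, 0], [0, 0, 1000]], dual_plate)
        assert symmetry_diagnostic(m).verdict == "indeterminate"


class TestExpectedMisassignment:
    @pytest.mark.parametrize(
        "c,mode,expected",
        [
            (0.01, "single_index", (0.01, 0.0)),
            (0.01, "dual_matched", (0.0001, 2 * 0.01 * 0.99)),
            (0.0, "single_index", (0.0, 0.0)),
            (0.0, "dual_matched", (0.0, 0.0)),
            (1.0, "single_index", (1.0, 0.0)),
            (1.0, "dual_matched", (1.0, 0.0)),
        ],
    )
    def test_model_values(self, c, mode, expected):
        mis, filt = expected_misassignment(c, mode)
        assert mis == pytest.approx(expected[0])
        assert filt == pytest.approx(expected[1])

    def test_simulation_agrees_with_analytic_model(self, dual_plate, single_sample_sheet):
        """Duplex contamination Monte Carlo vs c^2 / 2c(1-c), 3 binomial sigma."""
        wells = dual_plate.sorted_wells()
        for c in (0.01, 0.05):
            n = 400_000
            cfg = SimConfig(n_fragments=n, seed=int(c * 1000), umi_length=0,
                            contamination=(ContaminationEvent(wells[0], wells[1], c),),
                            duplicate_family_size=FamilySizeSpec("degenerate", 1))
            reads, _ = cq.simulate_experiment(dual_plate, single_sample_sheet, cfg)
            m = cq.build_crosstalk_matrix(reads, DemuxPolicy.for_plate(dual_plate),
                                          used_wells=[wells[0]])
            mis_expected, filt_expected = expected_misassignment(c, "dual_matched")
            k = dual_plate.i7_sequences().index(dual_plate.i7_of(wells[1]))
            mis = m.counts[k, k] / n
            filt = mismatched_pair_rate(m)
            assert abs(mis - mis_expected) <= 3 * np.sqrt(mis_expected / n)
            assert abs(filt - filt_expected) <= 3 * np.sqrt(filt_expected / n)


def test_plate_grid_places_counts_on_wells(dual_plate, dual_sheet):
    cfg = SimConfig(n_fragments=500, seed=4,
                    duplicate_family_size=FamilySizeSpec("degenerate", 1))
    reads, _ = cq.simulate_experiment(dual_plate, dual_sheet, cfg)
    m = cq.build_crosstalk_matrix(reads, DemuxPolicy.for_plate(dual_plate),
                                  used_wells=dual_sheet.wells)
    grid = plate_grid(m, dual_plate)
    assert grid.to_numpy().sum() == m.total
    for e in dual_sheet.entries:
        assert grid.loc[e.well.row, e.well.column] == 500
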