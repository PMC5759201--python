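import numpy as np
import pytest

import crosstalkqc as cq
from crosstalkqc import simulate as sim
from crosstalkqc.simulate import (
    CONTAM_I5,
    CONTAM_I7,
    ERR_I7,
    HOP_I5,
    HOP_I7,
    ConfigError,
    ContaminationEvent,
    FamilySizeSpec,
    Molecule,
    SimConfig,
    Variant,
)


def _zero_noise_config(n=1000, seed=0, **kw):
    kw.setdefault("duplicate_family_size", FamilySizeSpec("degenerate", 1))
    return SimConfig(n_fragments=n, seed=seed, **kw)


def _three_sigma(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


class TestAdapterArmDraws:
    def test_no_contamination_always_own_well(self, dual_plate, rng):
        well = dual_plate.sorted_wells()[0]
        for _ in range(20):
            i7w, i5w = cq.draw_adapter_arms(well, dual_plate, (), "duplex", rng)
            assert i7w == well and i5w == well

    def test_duplex_independence_product(self, dual_plate, single_sample_sheet):
        """Both-arm contamination ~ c^2, one-arm ~ 2c(1-c): independent draws."""
        wells = dual_plate.sorted_wells()
        c = 0.01
        n = 10**6
        cfg = _zero_noise_config(
            n, seed=42, contamination=(ContaminationEvent(wells[0], wells[1], c),),
            umi_length=0,
        )
        reads, _ = cq.simulate_experiment(dual_plate, single_sample_sheet, cfg)
        both = ((reads.event_tags & CONTAM_I7) > 0) & ((reads.event_tags & CONTAM_I5) > 0)
        one = (((reads.event_tags & CONTAM_I7) > 0) ^ ((reads.event_tags & CONTAM_I5) > 0))
        assert abs(both.mean() - c**2) <= _three_sigma(c**2, n)
        assert abs(one.mean() - 2 * c * (1 - c)) <= _three_sigma(2 * c * (1 - c), n)

    def test_oligo_stage_is_directional(self, dual_plate, single_sample_sheet):
        """An i7-arm oligo leak never contaminates the i5 arm (exact)."""
        wells = dual_plate.sorted_wells()
        c = 0.01
        cfg = _zero_noise_config(
            200_000, seed=7,
            contamination=(ContaminationEvent(wells[0], wells[1], c, arm="i7"),),
            contamination_stage="oligo", umi_length=0,
        )
        reads, _ = cq.simulate_experiment(dual_plate, single_sample_sheet, cfg)
        contaminated_i5 = (reads.event_tags & CONTAM_I5) > 0
        contaminated_i7 = (reads.event_tags & CONTAM_I7) > 0
        assert contaminated_i5.sum() == 0
        assert (reads.i5_code != reads.true_i5_code).sum() == 0
        assert abs(contaminated_i7.mean() - c) <= _three_sigma(c, len(reads))

    def test_rates_over_one_rejected(self, dual_plate):
        wells = dual_plate.sorted_wells()
        cfg = SimConfig(contamination=(
            ContaminationEvent(wells[0], wells[1], 0.7),
            ContaminationEvent(wells[0], wells[2], 0.7),
        ))
        with pytest.raises(ConfigError, match="sum"):
            cfg.validate(dual_plate)

    def test_oligo_stage_requires_arm(self, dual_plate):
        wells = dual_plate.sorted_wells()
        cfg = SimConfig(contamination=(ContaminationEvent(wells[0], wells[1], 0.1),),
                        contamination_stage="oligo")
        with pytest.raises(ConfigError, match="arm"):
            cfg.validate(dual_plate)


class TestIndexHopping:
    def _pool_sim(self, plate, n_samples, h, n_per_sample, seed):
        sheet = cq.sheet_for_samples(plate, [f"s{i}" for i in range(n_samples)])
        cfg = _zero_noise_config(n_per_sample, seed=seed, hop_rate=h, umi_length=0)
        return cq.simulate_experiment(plate, sheet, cfg)

    def test_zero_rate_is_identity(self, dual_plate):
        reads, _ = self._pool_sim(dual_plate, 4, 0.0, 5000, seed=3)
        assert (reads.i7_code == reads.true_i7_code).all()
        assert (reads.i5_code == reads.true_i5_code).all()

    def test_hopped_fraction_matches_binomial_complement(self):
        plate = cq.default_unique_dual_plate(n=16, seed=8)
        h, per = 0.004, 62_500
        reads, _ = self._pool_sim(plate, 16, h, per, seed=9)
        n = len(reads)
        hopped = (reads.event_tags & (HOP_I7 | HOP_I5)) > 0
        expected = 1 - (1 - h) ** 2
        assert abs(hopped.mean() - expected) <= _three_sigma(expected, n)
        # hops always land on another pool member's index
        mask7 = (reads.event_tags & HOP_I7) > 0
        assert (reads.i7_code[mask7] != reads.true_i7_code[mask7]).all()

    def test_single_plex_pool_never_hops(self, dual_plate, single_sample_sheet):
        cfg = _zero_noise_config(5000, seed=5, hop_rate=0.5, umi_length=0)
        with pytest.warns(UserWarning, match="single"):
            reads, _ = cq.simulate_experiment(dual_plate, single_sample_sheet, cfg)
        assert ((reads.event_tags & (HOP_I7 | HOP_I5)) > 0).sum() == 0


class TestIndexSequencingError:
    def test_zero_rate_is_identity(self, dual_plate, dual_sheet):
        cfg = _zero_noise_config(2000, seed=1)
        reads, _ = cq.simulate_experiment(dual_plate, dual_sheet, cfg)
        assert (reads.i7_code == reads.true_i7_code).all()

    def test_error_fraction_matches_closed_form(self, dual_plate, single_sample_sheet):
        e, n = 0.001, 10**6
        cfg = _zero_noise_config(n, seed=21, index_error_rate=e, umi_length=0)
        reads, _ = cq.simulate_experiment(dual_plate, single_sample_sheet, cfg)
        frac = ((reads.event_tags & ERR_I7) > 0).mean()
        expected = 1 - (1 - e) ** 8
        assert abs(frac - expected) <= _three_sigma(expected, n)

    def test_errored_index_differs_from_truth(self, dual_plate, single_sample_sheet):
        cfg = _zero_noise_config(5000, seed=22, index_error_rate=0.05, umi_length=0)
        reads, _ = cq.simulate_experiment(dual_plate, single_sample_sheet, cfg)
        erred = (reads.event_tags & ERR_I7) > 0
        assert erred.any()
        assert (reads.i7_code[erred] != reads.true_i7_code[erred]).all()
        # single-error reads differ from the true index at exactly the error count
        pool = reads.index_pool
        for i in np.nonzero(erred)[0][:50]:
            obs = pool[reads.i7_code[i]]
            true = pool[reads.true_i7_code[i]]
            assert 1 <= sum(a != b for a, b in zip(obs, true)) <= 8


class TestAmplification:
    def _molecules(self, plate, n, umi="AAAAAA", damage=None):
        well = plate.sorted_wells()[0]
        return [
            Molecule(i, "S1", 0, 20, "+", umi, well, well,
                     oxo_damaged_positions=frozenset(damage or ()))
            for i in range(n)
        ]

    def test_degenerate_family_is_one_read_per_molecule(self, dual_plate, rng):
        ref = "ACGT" * 5
        mols = self._molecules(dual_plate, 100)
        reads = cq.amplify_with_umi(mols, FamilySizeSpec("degenerate", 1), 0.0,
                                    dual_plate, ref, rng)
        assert len(reads) == 100
        assert len(set(reads.molecule_id.tolist())) == 100

    def test_conservation_of_reads(self, dual_plate, dual_sheet):
        cfg = SimConfig(n_fragments=2000, seed=4,
                        duplicate_family_size=FamilySizeSpec("poisson_plus_one", 2.0))
        reads, truth = cq.simulate_experiment(dual_plate, dual_sheet, cfg)
        fam_sizes = np.bincount(reads.molecule_id)
        n_mols = 3 * 2000
        assert len(fam_sizes) == n_mols
        assert (fam_sizes >= 1).all()
        assert fam_sizes.sum() == len(reads)

    def test_certain_misread_marks_every_copy(self, dual_plate, rng):
        ref = "GGGG" + "ACGT" * 4
        mols = self._molecules(dual_plate, 50, damage=[0])
        reads = cq.amplify_with_umi(mols, FamilySizeSpec("degenerate", 4), 1.0,
                                    dual_plate, ref, rng)
        assert all(reads.insert_bases(i)[0] == "T" for i in range(len(reads)))

    def test_misread_mean_matches_binomial(self, dual_plate, rng):
        ref = "GGGG" + "ACGT" * 4
        mols = self._molecules(dual_plate, 10_000, damage=[0])
        reads = cq.amplify_with_umi(mols, FamilySizeSpec("degenerate", 6), 0.5,
                                    dual_plate, ref, rng)
        artifact = np.array([reads.insert_bases(i)[0] == "T" for i in range(len(reads))])
        per_family = artifact.reshape(10_000, 6).sum(axis=1)
        assert abs(per_family.mean() - 3.0) <= 3 * per_family.std() / np.sqrt(10_000)


class TestExperimentComposition:
    def test_zero_noise_observed_equals_plate_indices(self, dual_plate, dual_sheet):
        cfg = _zero_noise_config(3000, seed=6)
        reads, _ = cq.simulate_experiment(dual_plate, dual_sheet, cfg)
        for i in range(0, len(reads), 97):
            rec = reads.record(i)
            well = dual_sheet.well_of(rec.true_sample)
            assert rec.i7_obs == dual_plate.i7_of(well)
            assert rec.i5_obs == dual_plate.i5_of(well)

    def test_variant_fraction_matches_binomial(self, dual_plate, single_sample_sheet):
        af, n = 0.01, 100_000
        cfg = _zero_noise_config(
            n, seed=30, reference_length=100, read_length=100,
            variants=(Variant(50, "A", "T", af),),
        )
        reads, _ = cq.simulate_experiment(dual_plate, single_sample_sheet, cfg)
        alt = sum(1 for i in reads.subs if any(p == 50 for p, _ in reads.subs[i]))
        assert abs(alt / n - af) <= _three_sigma(af, n)

    def test_truth_tags_explain_every_index_discrepancy(self, dual_plate):
        sheet = cq.sheet_for_samples(dual_plate, ["a", "b", "c", "d"])
        wells = dual_plate.sorted_wells()
        cfg = SimConfig(
            n_fragments=20_000, seed=31, hop_rate=0.01, index_error_rate=0.005,
            contamination=(ContaminationEvent(wells[0], wells[1], 0.01),),
            duplicate_family_size=FamilySizeSpec("degenerate", 1),
        )
        reads, _ = cq.simulate_experiment(dual_plate, sheet, cfg)
        i7_bits = CONTAM_I7 | HOP_I7 | ERR_I7
        i5_bits = CONTAM_I5 | HOP_I5 | sim.ERR_I5
        i7_mismatch = reads.i7_code != reads.true_i7_code
        i5_mismatch = reads.i5_code != reads.true_i5_code
        # every discrepancy is tagged ...
        assert ((reads.event_tags[i7_mismatch] & i7_bits) > 0).all()
        assert ((reads.event_tags[i5_mismatch] & i5_bits) > 0).all()
        # ... and untagged reads match exactly
        clean7 = (reads.event_tags & i7_bits) == 0
        clean5 = (reads.event_tags & i5_bits) == 0
        assert (~i7_mismatch[clean7]).all()
        assert (~i5_mismatch[clean5]).all()

    def test_determinism_byte_identical_fastq(self, dual_plate, dual_sheet, tmp_path):
        cfg = SimConfig(n_fragments=300, seed=77, hop_rate=0.01, index_error_rate=0.01)
        outs = []
        for run in ("one", "two"):
            reads, _ = cq.simulate_experiment(dual_plate, dual_sheet, cfg)
            paths = cq.write_fastq(reads, str(tmp_path / run))
            outs.append(b"".join(open(p, "rb").read() for p in paths))
        assert outs[0] == outs[1]


class TestFastqLayout:
    def test_unique_dual_i1_carries_umi(self, dual_plate, dual_sheet, tmp_path):
        cfg = _zero_noise_config(50, seed=8)
        reads, _ = cq.simulate_experiment(dual_plate, dual_sheet, cfg)
        paths = cq.write_fastq(reads, str(tmp_path / "x"))
        i1_seqs = open(paths[2]).read().splitlines()[1::4]
        assert all(len(s) == 8 + 6 for s in i1_seqs)
        i2_seqs = open(paths[3]).read().splitlines()[1::4]
        assert all(len(s) == 8 for s in i2_seqs)

    def test_combinatorial_i1_is_bare_index(self, combinatorial_plate, tmp_path):
        sheet = cq.sheet_for_samples(combinatorial_plate, ["s"])
        cfg = _zero_noise_config(50, seed=8)
        reads, _ = cq.simulate_experiment(combinatorial_plate, sheet, cfg)
        paths = cq.write_fastq(reads, str(tmp_path / "y"))
        i1_seqs = open(paths[2]).read().splitlines()[1::4]
        assert all(len(s) == 8 for s in i1_seqs)

    def test_read_count_identical_across_files(self, dual_plate, dual_sheet, tmp_path):
        cfg = SimConfig(n_fragments=40, seed=9)
        reads, _ = cq.simulate_experiment(dual_plate, dual_sheet, cfg)
        paths = cq.write_fastq(reads, str(tmp_path / "z"))
        counts = {p: sum(1 for _ in open(p)) // 4 for p in paths}
        assert len(set(counts.values())) == 1
        assert next(iter(counts.values())) == len(reads)

    def test_fastq_round_trip_restores_observed_fields(self, dual_plate, dual_sheet, tmp_path):
        cfg = SimConfig(n_fragments=30, seed=10, index_error_rate=0.02)
        reads, _ = cq.simulate_experiment(dual_plate, dual_sheet, cfg)
        paths = cq.write_fastq(reads, str(tmp_path / "rt"))
        back = cq.read_fastq_set(str(tmp_path / "rt"), index_length=8, umi_length=6)
        assert len(back) == len(reads)
        for i in range(len(reads)):
            assert back.i7_obs(i) == reads.i7_obs(i)
            assert back.i5_obs(i) == reads.i5_obs(i)
            assert back.umi_obs(i) == reads.umi_obs(i)
            assert back.insert_bases(i) == reads.insert_bases(i)


def test_truth_table_shape_and_fragment_counts(dual_plate, dual_sheet):
    cfg = SimConfig(n_fragments={"S1": 100, "S2": 50, "S3": 25}, seed=12,
                    duplicate_family_size=FamilySizeSpec("degenerate", 2))
    reads, truth = cq.simulate_experiment(dual_plate, dual_sheet, cfg)
    assert truth.per_sample_fragments == {"S1": 100, "S2": 50, "S3": 25}
    df = truth.to_dataframe()
    assert len(df) == len(reads) == 2 * 175
    assert set(df["true_sample"]) == {"S1", "S2", "S3"}
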