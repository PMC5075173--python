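import numpy as np
import pytest

from ipcalc import charge, datasets, pka, simulate
from ipcalc.errors import DatasetError, EmptyPanelError, MalformedFastaError

EMBOSS = pka.get_pka_set("EMBOSS")


def make_record(record_id, sequence, pis, consensus=None):
    rec = datasets.SequenceRecord(
        record_id=record_id, sequence=sequence, experimental_pis=list(pis)
    )
    rec.consensus_pi = consensus
    return rec


class TestPiFasta:
    def test_legacy_quoted_tokens(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(
            ">P04807-1|['5.17/55102', '5.27/54793']\nMVHLGPKKPQARKGSMADVPKELMQQIENFEKIFT\n"
        )
        (rec,) = datasets.read_pi_fasta(path)
        assert rec.record_id == "P04807-1"
        assert rec.experimental_pis == [5.17, 5.27]

    def test_prime_quoted_tokens(self, tmp_path):
        # some published files quote with the prime character
        path = tmp_path / "a.fasta"
        path.write_text(">X|[′5.17/55102′, ′5.27/54793′]\nGGGG\n")
        (rec,) = datasets.read_pi_fasta(path)
        assert rec.experimental_pis == [5.17, 5.27]

    def test_canonical_bare_numbers(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">X|[5.17, 5.27]\nGGGG\n")
        (rec,) = datasets.read_pi_fasta(path)
        assert rec.experimental_pis == [5.17, 5.27]

    def test_plain_header_gives_empty_measurements(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">toy\nGGGG\n")
        (rec,) = datasets.read_pi_fasta(path)
        assert rec.record_id == "toy"
        assert rec.experimental_pis == []

    def test_unparseable_annotation_warns(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">weird|5.17\nGGGG\n")
        with pytest.warns(UserWarning, match="bracket"):
            (rec,) = datasets.read_pi_fasta(path)
        assert rec.experimental_pis == []

    def test_order_preserved(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">a|[5.0]\nGGGG\n>b|[6.0]\nDECK\n>c|[7.0]\nKKKK\n")
        records = datasets.read_pi_fasta(path)
        assert [r.record_id for r in records] == ["a", "b", "c"]

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            datasets.read_pi_fasta(tmp_path / "absent.fasta")

    def test_sequence_before_header_is_malformed(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text("GGGG\n>late\nDECK\n")
        with pytest.raises(MalformedFastaError):
            datasets.read_pi_fasta(path)

    def test_write_read_round_trip(self, tmp_path):
        records = [
            make_record("a", "GGGGDECK", [5.17, 5.27]),
            make_record("b", "KKKK", []),
        ]
        path = tmp_path / "out.fasta"
        datasets.write_pi_fasta(records, path)
        loaded = datasets.read_pi_fasta(path)
        assert [r.record_id for r in loaded] == ["a", "b"]
        assert loaded[0].experimental_pis == [5.17, 5.27]
        assert loaded[0].sequence == "GGGGDECK"
        assert loaded[1].experimental_pis == []

    def test_out_of_range_pi_rejected(self):
        with pytest.raises(DatasetError):
            make_record("a", "GGGG", [15.0])


class TestMergeAndAverage:
    def test_duplicate_pair_averaged(self):
        records = [
            make_record("a", "GGGGDECK", [5.17]),
            make_record("a2", "GGGGDECK", [5.27]),
        ]
        merged, report = datasets.merge_and_average(records)
        assert len(merged) == 1
        assert merged[0].consensus_pi == pytest.approx(5.22)
        assert len(report.merged_away) == 1

    def test_single_measurement(self):
        merged, _ = datasets.merge_and_average([make_record("a", "GGGG", [7.0])])
        assert merged[0].consensus_pi == 7.0

    def test_three_duplicates(self):
        records = [
            make_record(f"r{i}", "DECK", [float(v)]) for i, v in enumerate((4, 5, 6))
        ]
        merged, _ = datasets.merge_and_average(records)
        assert len(merged) == 1
        assert merged[0].consensus_pi == pytest.approx(5.0)

    def test_records_without_pi_dropped_and_counted(self):
        records = [make_record("a", "GGGG", []), make_record("b", "DECK", [6.0])]
        merged, report = datasets.merge_and_average(records)
        assert [r.record_id for r in merged] == ["b"]
        assert [r.record_id for r in report.dropped_no_pi] == ["a"]

    def test_idempotent(self):
        records = [
            make_record("a", "GGGGDECK", [5.17]),
            make_record("a2", "GGGGDECK", [5.27]),
            make_record("b", "KKKKDDDD", [7.0]),
        ]
        once, _ = datasets.merge_and_average(records)
        twice, report = datasets.merge_and_average(once)
        assert [(r.sequence, r.consensus_pi) for r in twice] == [
            (r.sequence, r.consensus_pi) for r in once
        ]
        assert not report.merged_away and not report.dropped_no_pi


class TestRemoveOutliers:
    def _with_delta(self, sequence, delta, panel):
        baseline = np.mean(
            [charge.isoelectric_point(sequence, s).pi for s in panel]
        )
        return make_record("x", sequence, [baseline + delta], consensus=baseline + delta)

    def test_large_delta_removed(self):
        panel = [EMBOSS]
        rec = self._with_delta("GGDECKRH", 2.0, panel)
        kept, removed = datasets.remove_outliers([rec], panel=panel, mse_threshold=3.0)
        assert not kept and len(removed) == 1
        assert removed[0][1] == pytest.approx(2.0, abs=1e-6)

    def test_boundary_value_kept(self):
        # squared error exactly at the threshold survives the strict '>'
        panel = [EMBOSS]
        rec = self._with_delta("GGDECKRH", np.sqrt(3.0), panel)
        kept, removed = datasets.remove_outliers([rec], panel=panel, mse_threshold=3.0)
        assert len(kept) == 1 and not removed

    def test_one_point_seven_kept_under_protein_threshold(self):
        panel = [EMBOSS]
        rec = self._with_delta("GGDECKRH", 1.7, panel)
        kept, _ = datasets.remove_outliers([rec], panel=panel, mse_threshold=3.0)
        assert kept

    def test_peptide_threshold_boundary(self):
        panel = [EMBOSS]
        kept, _ = datasets.remove_outliers(
            [self._with_delta("GGDECKRH", 0.5, panel)], panel=panel, mse_threshold=0.25
        )
        assert kept
        _, removed = datasets.remove_outliers(
            [self._with_delta("GGDECKRH", 0.51, panel)], panel=panel, mse_threshold=0.25
        )
        assert removed

    def test_default_panel_is_the_fourteen_literature_sets(self):
        rec = make_record("a", "GGGG", [6.0], consensus=6.0)
        kept, _ = datasets.remove_outliers([rec])
        assert kept  # GGGG consensus midpoints all sit near 5.5-6.1

    def test_empty_panel_rejected(self):
        rec = make_record("a", "GGGG", [6.0], consensus=6.0)
        with pytest.raises(EmptyPanelError):
            datasets.remove_outliers([rec], panel=[])

    def test_missing_consensus_rejected(self):
        rec = make_record("a", "GGGG", [6.0])
        with pytest.raises(DatasetError, match="consensus"):
            datasets.remove_outliers([rec], panel=[EMBOSS])


class TestClusterRedundant:
    def test_byte_identical_collapse(self):
        records = [
            make_record("a", "GGGGDECK", [5.0], 5.0),
            make_record("b", "GGGGDECK", [5.1], 5.1),
        ]
        reps, removed = datasets.cluster_redundant(records)
        assert len(reps) == 1 and len(removed) == 1

    def test_single_substitution_at_099_clustered(self, rng):
        base = "".join("ACDEFGHIKL"[i % 10] for i in range(100))
        mutant = "W" + base[1:]
        records = [make_record("a", base, [5.0], 5.0), make_record("b", mutant, [5.0], 5.0)]
        reps, removed = datasets.cluster_redundant(records, 0.99)
        assert len(reps) == 1
        assert removed[0][0].record_id == "b"

    def test_two_substitutions_kept_separate(self):
        base = "".join("ACDEFGHIKL"[i % 10] for i in range(100))
        mutant = "WW" + base[2:]
        records = [make_record("a", base, [5.0], 5.0), make_record("b", mutant, [5.0], 5.0)]
        reps, _ = datasets.cluster_redundant(records, 0.99)
        assert len(reps) == 2

    def test_longest_member_is_representative(self):
        base = "".join("ACDEFGHIKL"[i % 10] for i in range(200))
        records = [
            make_record("short", base[:-1], [5.0], 5.0),
            make_record("long", base, [5.0], 5.0),
        ]
        reps, removed = datasets.cluster_redundant(records, 0.99)
        assert [r.record_id for r in reps] == ["long"]
        assert removed[0][1] == "long"

    def test_threshold_one_removes_only_byte_identical(self, rng):
        base = "".join("ACDEFGHIKL"[i % 10] for i in range(50))
        records = [
            make_record("a", base, [5.0], 5.0),
            make_record("prefix", base[:-1], [5.0], 5.0),
            make_record("same", base, [5.0], 5.0),
        ]
        reps, removed = datasets.cluster_redundant(records, 1.0)
        assert {r.record_id for r in reps} == {"a", "prefix"}
        assert removed[0][0].record_id == "same"


class TestSplit:
    def _records(self, n):
        return [make_record(f"r{i}", "G" * (i + 1), [7.0], 7.0) for i in range(n)]

    def test_100_records(self):
        train, test = datasets.split_train_test(self._records(100), 0.75, seed=0)
        assert len(train) == 75 and len(test) == 25

    def test_reproducible(self):
        records = self._records(40)
        first = datasets.split_train_test(records, 0.75, seed=11)
        second = datasets.split_train_test(records, 0.75, seed=11)
        assert [r.record_id for r in first[0]] == [r.record_id for r in second[0]]

    def test_paper_sized_protein_split(self):
        train, test = datasets.split_train_test(self._records(2324), 0.75, seed=3)
        assert len(train) == 1743 and len(test) == 581

    def test_too_few_records(self):
        with pytest.raises(DatasetError):
            datasets.split_train_test(self._records(1))


class TestCuratePipeline:
    def test_conservation_on_synthetic_fixture(self):
        spec = simulate.FixtureSpec(
            n_records=120,
            rng_seed=5,
            outlier_fraction=0.1,
            duplicate_fraction=0.05,
            label_pka_set=EMBOSS,
        )
        records = simulate.generate(spec)
        curated = datasets.curate(records, panel=[EMBOSS], mse_threshold=3.0)
        report = curated.report
        assert report.n_input == 120
        total = (
            len(curated.records)
            + len(report.dropped_no_pi)
            + len(report.merged_away)
            + len(report.removed_outliers)
            + len(report.removed_redundant)
        )
        assert total == report.n_input
        removed_ids = {rec.record_id for rec, _ in report.removed_outliers}
        planted = {r.record_id for r in records if r.source_tag == "outlier"}
        assert removed_ids == planted

    def test_split_labels_cover_all_records(self):
        records = simulate.generate(
            simulate.FixtureSpec(n_records=40, rng_seed=9, label_pka_set=EMBOSS)
        )
        curated = datasets.curate(
            records, panel=[EMBOSS], train_fraction=0.75, split_seed=1
        )
        assert set(curated.split_labels) == {r.record_id for r in curated.records}
        n_train = sum(1 for v in curated.split_labels.values() if v == "train")
        assert n_train == round(0.75 * len(curated.records))
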