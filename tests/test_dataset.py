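"""Quality filtering, non-redundantization, splitting, temporal holdout."""

import pytest
from hypothesis import given, settings, strategies as st

from abypap.dataset import (
    AngleRecord,
    build_records,
    deduplicate,
    prepare_dataset,
    quality_filter,
    read_dataset,
    split,
    temporal_holdout,
    write_dataset,
)
from abypap.models import records_to_xy
from abypap.synthetic import make_duplicate_pack


def rec(id="r", residues="QQLVMQAWRHGEN", angle=-46.0, lengths=(11, 9, 8)):
    return AngleRecord(id=id, feature_residues=residues, angle_deg=angle,
                       loop_lengths=lengths, resolution=1.8)


class TestQualityFilter:
    def test_good_xray_structure_kept(self, fv_factory):
        kept, rejected = quality_filter([fv_factory()])
        assert len(kept) == 1 and not rejected

    def test_resolution_worse_than_3A_rejected(self, fv_factory):
        fv = fv_factory(resolution=3.2)
        assert quality_filter([fv])[1] == [(fv.id, "resolution")]

    def test_non_crystallographic_rejected(self, fv_factory):
        fv = fv_factory(method="SOLUTION NMR")
        assert quality_filter([fv])[1] == [(fv.id, "method")]

    def test_missing_conserved_residue_rejected(self, fv_factory):
        fv = fv_factory(drop_positions=["L87"])
        assert quality_filter([fv])[1] == [(fv.id, "missing")]

    def test_internal_numbering_gap_rejected(self, fv_factory):
        fv = fv_factory(drop_positions=["H60"])
        assert quality_filter([fv])[1] == [(fv.id, "missing")]

    def test_partition(self, fv_factory):
        fvs = [fv_factory(name=f"s{i}") for i in range(3)]
        fvs.append(fv_factory(name="bad", resolution=3.5))
        kept, rejected = quality_filter(fvs)
        assert len(kept) + len(rejected) == len(fvs)


class TestDeduplicate:
    def test_hand_rounded_pair_collapses(self):
        # both round to -45.12 at two decimals
        records = [rec(id="a", angle=-45.123), rec(id="b", angle=-45.1249)]
        assert [r.id for r in deduplicate(records)] == ["a"]

    def test_flexible_angles_both_survive(self):
        records = [rec(id="a", angle=-44.0), rec(id="b", angle=-46.0)]
        assert len(deduplicate(records)) == 2

    def test_duplicate_pack_survivors(self):
        pack = make_duplicate_pack(rec(angle=-46.0), 3, [0.0, 0.004, 1.0])
        assert len(deduplicate(pack)) == 2  # -46.0 and -46.004 round equal

    def test_all_identical_keeps_first(self):
        pack = make_duplicate_pack(rec(), 4, [0.0] * 4)
        survivors = deduplicate(pack)
        assert [r.id for r in survivors] == [pack[0].id]

    def test_loop_lengths_not_in_key(self):
        a = rec(id="a", lengths=(11, 9, 8))
        b = rec(id="b", lengths=(12, 9, 9))
        assert len(deduplicate([a, b])) == 1

    def test_empty(self):
        assert deduplicate([]) == []

    @given(st.lists(st.tuples(st.sampled_from("AC"), st.floats(-60, -30)), max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_order_stable(self, raw):
        records = [rec(id=str(i), residues=aa * 13, angle=a) for i, (aa, a) in enumerate(raw)]
        once = deduplicate(records)
        assert deduplicate(once) == once
        ids = [r.id for r in records]
        assert [r.id for r in once] == sorted((r.id for r in once), key=ids.index)

    def test_key_equals_feature_vector_equality(self):
        # two records share a dedup key iff their encoded features and
        # rounded angles coincide (loop lengths excluded from the key)
        a, b = rec(id="a"), rec(id="b", lengths=(12, 9, 8))
        Xa, _ = records_to_xy([a], "gbr1")
        Xb, _ = records_to_xy([b], "gbr1")
        assert (Xa == Xb).all() and a.dedup_key() == b.dedup_key()
        c = rec(id="c", residues="AQLVMQAWRHGEN")
        Xc, _ = records_to_xy([c], "gbr1")
        assert not (Xa == Xc).all() and a.dedup_key() != c.dedup_key()


class TestSplit:
    def test_ten_percent(self):
        records = [rec(id=str(i), angle=-46 + i * 0.01) for i in range(100)]
        part = split(records, 0.1, seed=1)
        assert len(part.test) == 10 and len(part.train) == 90

    def test_deterministic(self):
        records = [rec(id=str(i), angle=-46 + i * 0.01) for i in range(50)]
        a, b = split(records, 0.1, seed=7), split(records, 0.1, seed=7)
        assert [r.id for r in a.test] == [r.id for r in b.test]

    def test_half_split_of_four(self):
        records = [rec(id=str(i), angle=-46 + i) for i in range(4)]
        part = split(records, 0.5, seed=0)
        assert len(part.train) == len(part.test) == 2

    def test_partition_disjoint_and_complete(self):
        records = [rec(id=str(i), angle=-46 + i * 0.1) for i in range(23)]
        part = split(records, 0.25, seed=3)
        train_ids = {r.id for r in part.train}
        test_ids = {r.id for r in part.test}
        assert not train_ids & test_ids
        assert train_ids | test_ids == {r.id for r in records}

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split([rec()], 0.1, seed=0)


class TestTemporalHoldout:
    def test_identical_sets_empty(self):
        records = [rec(id=str(i), angle=-46 + i) for i in range(5)]
        assert temporal_holdout(records, records) == []

    def test_new_keys_extracted(self):
        old = [rec(id=str(i), angle=-46 + i) for i in range(5)]
        new = old + [rec(id=f"n{i}", angle=-30 - i) for i in range(3)]
        held = temporal_holdout(old, new)
        assert [r.id for r in held] == ["n0", "n1", "n2"]

    def test_empty_old(self):
        new = [rec(id=str(i), angle=-46 + i) for i in range(4)]
        assert temporal_holdout([], new) == new


class TestRoundTripAndPrepare:
    def test_tsv_round_trip(self, tmp_path):
        records = [rec(id=str(i), angle=-46.123456 + i) for i in range(5)]
        write_dataset(records, tmp_path / "d.tsv")
        loaded = read_dataset(tmp_path / "d.tsv")
        assert [r.id for r in loaded] == [r.id for r in records]
        assert loaded[0].angle_deg == pytest.approx(records[0].angle_deg)
        assert loaded[0].loop_lengths == records[0].loop_lengths

    def test_prepare_dataset_end_to_end(self, fv_factory, tmp_path):
        for i, theta in enumerate((-44.0, -46.0, -48.0)):
            fv_factory(theta=theta, name=f"p{i}", write=True)
        fv_factory(theta=-46.0, name="nmr", write=True, method="SOLUTION NMR")
        records, rejected = prepare_dataset(tmp_path, schema="gbr4")
        assert len(records) == 3
        assert ("nmr", "method") in rejected

    def test_build_records_carries_angle_and_resolution(self, fv_factory):
        fv = fv_factory(theta=-43.21)
        record = build_records([fv], "gbr4")[0]
        assert record.angle_deg == pytest.approx(-43.21, abs=1e-6)
        assert record.resolution == pytest.approx(1.8)
        assert len(record.feature_residues) == 37
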