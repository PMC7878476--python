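"""Cross-link table handling: I/O round trips, dedup/classification/
condition-comparison against brute-force set-operation oracles."""

import numpy as np
import pandas as pd
import pytest

from xlintegrate import xl_tables as xt
from xlintegrate.synthetic_data import gen_random_xl_table, stage_rng
from xlintegrate.xl_tables import (
    CrosslinkRecord, MonolinkRecord, classify_pair, compare_conditions,
    contact_map, covariation_overlap, deduplicate, dnajb8_domain_map,
    monolink_frequency, read_xl_table, unique_pairs, write_xl_table,
)


def make_record(a, b, cond="c1", chem="DMTMM", ta="K", tb="E"):
    return CrosslinkRecord("P", a, ta, "P", b, tb, chem, cond)


class TestRecords:
    def test_position_invariant(self):
        with pytest.raises(ValueError):
            make_record(0, 5)

    def test_unordered_pair_identity(self):
        r1 = make_record(34, 208)
        r2 = CrosslinkRecord("P", 208, "E", "P", 34, "K", "DMTMM", "c1")
        assert r1.pair == r2.pair

    def test_chemistry_validity_flag(self):
        from xlintegrate.linker_chemistry import REGISTRY
        assert make_record(1, 2, ta="K", tb="E").is_valid(REGISTRY["DMTMM"])
        assert not make_record(1, 2, ta="K", tb="K").is_valid(REGISTRY["DMTMM"])


class TestTableIO:
    def test_round_trip(self, tmp_path):
        records = gen_random_xl_table(30, 232, seed=9)
        path = tmp_path / "links.tsv"
        write_xl_table(records, str(path))
        back = read_xl_table(str(path))
        assert back == records

    def test_empty_table(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_xl_table([], str(path))
        assert read_xl_table(str(path)) == []

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("protein_a\tresidue_a\n X\t1\n")
        with pytest.raises(ValueError, match="restype_a"):
            read_xl_table(str(path))

    def test_malformed_row_reports_line(self, tmp_path):
        records = [make_record(3, 9)]
        path = tmp_path / "links.tsv"
        write_xl_table(records, str(path))
        text = path.read_text().replace("\t3\t", "\t0\t")
        path.write_text(text)
        with pytest.raises(ValueError, match="line 2"):
            read_xl_table(str(path))

    def test_unknown_columns_preserved(self, tmp_path):
        rec = CrosslinkRecord("P", 1, "K", "P", 9, "E", "DMTMM", "c1",
                              extra=(("spectrum", "scan_41"),))
        path = tmp_path / "links.tsv"
        write_xl_table([rec], str(path))
        assert read_xl_table(str(path))[0].extra == (("spectrum", "scan_41"),)


class TestDomainMap:
    def test_default_dnajb8_intervals(self):
        dm = dnajb8_domain_map()
        assert dm.domain_of(1) == "JD"
        assert dm.domain_of(82) == "JD"
        assert dm.domain_of(83) == "G/F"
        assert dm.domain_of(170) == "CTD"
        assert dm.domain_of(232) == "CTD"
        assert dm.domain_of(233) is None

    def test_overlapping_domains_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            xt.DomainMap(domains=(("A", 1, 10), ("B", 5, 20)))

    def test_h5_subfeature_annotation(self):
        dm = dnajb8_domain_map(h5=(90, 110))
        label, notes = classify_pair((95, 200), dm)
        assert label == "CTD–G/F"
        assert notes == ["H5"]


class TestClassification:
    @pytest.mark.parametrize("pair, expected", [
        ((34, 208), "CTD–JD"),
        ((50, 60), "JD–JD"),
        ((90, 100), "G/F–G/F"),
        ((1, 300), "JD–unassigned"),
    ])
    def test_labels(self, pair, expected):
        assert classify_pair(pair, dnajb8_domain_map())[0] == expected

    def test_symmetry(self):
        dm = dnajb8_domain_map()
        rng = stage_rng(7, "classify_symm")
        for _ in range(50):
            a, b = rng.integers(1, 233, size=2)
            assert classify_pair((a, b), dm)[0] == classify_pair((b, a), dm)[0]


class TestDeduplication:
    def test_swapped_and_repeated_records_collapse(self):
        records = [make_record(34, 208),
                   CrosslinkRecord("P", 208, "E", "P", 34, "K", "DMTMM", "c1"),
                   make_record(34, 208)]
        assert len(deduplicate(records)) == 1

    def test_disjoint_pairs_kept(self):
        assert len(deduplicate([make_record(1, 5), make_record(2, 6)])) == 2

    def test_planted_pairs_recovered(self):
        rng = stage_rng(3, "dedup_plant")
        planted = [(4, 40), (7, 90), (12, 200), (60, 61)]
        records = []
        for _ in range(10):
            a, b = planted[rng.integers(len(planted))]
            if rng.random() < 0.5:
                a, b = b, a
            records.append(make_record(a, b))
        # ensure all planted pairs appear at least once
        records += [make_record(a, b) for a, b in planted]
        assert unique_pairs(records) == {
            (("P", a), ("P", b)) for a, b in planted}


class TestOracles:
    """Randomized tables against brute-force set-operation oracles."""

    N_TRIALS = 1000

    def test_dedup_and_condition_comparison_match_brute_force(self):
        for trial in range(self.N_TRIALS):
            records = gen_random_xl_table(
                n_records=20, n_residues=50, seed=trial)
            # brute-force oracle: plain python sets over sorted tuples
            def pairs_of(cond):
                return {
                    tuple(sorted([(r.protein_a, r.residue_a),
                                  (r.protein_b, r.residue_b)]))
                    for r in records if r.condition == cond}
            pa, pb = pairs_of("PBS_150mM"), pairs_of("PBS_285mM")
            conds = {r.condition for r in records}
            if {"PBS_150mM", "PBS_285mM"} <= conds:
                result = compare_conditions(records, "PBS_150mM", "PBS_285mM")
                assert result["shared"] == {tuple(p) for p in pa & pb}
                assert result["a_only"] == {tuple(p) for p in pa - pb}
                assert result["b_only"] == {tuple(p) for p in pb - pa}
                # disjoint and exhaustive
                assert not (result["shared"] & result["a_only"])
                assert not (result["shared"] & result["b_only"])
                assert not (result["a_only"] & result["b_only"])
                assert (result["shared"] | result["a_only"]
                        | result["b_only"]) == pa | pb
            assert unique_pairs(records) == pa | pb

    def test_class_counts_match_brute_force_and_shuffling(self):
        dm = dnajb8_domain_map()
        rng = stage_rng(5, "class_oracle")
        for trial in range(100):
            records = gen_random_xl_table(
                n_records=50, n_residues=232, seed=10_000 + trial)
            cmap = contact_map(records, dm)
            # brute force: interval lookup per unique off-diagonal pair
            expected = {}
            for pair in {r.pair for r in records}:
                (_, a), (_, b) = pair
                if a == b:
                    continue
                da = dm.domain_of(a) or "unassigned"
                db = dm.domain_of(b) or "unassigned"
                label = "–".join(sorted([da, db]))
                expected[label] = expected.get(label, 0) + 1
            assert dict(cmap.class_counts) == expected
            assert sum(cmap.class_counts.values()) == len(cmap.counts)
            # invariance under shuffling
            shuffled = list(records)
            rng.shuffle(shuffled)
            assert dict(contact_map(shuffled, dm).class_counts) == expected

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="no_such"):
            compare_conditions([make_record(1, 5)], "c1", "no_such")


class TestMonolinks:
    def test_empty(self):
        assert monolink_frequency([]) == {}

    def test_counts_per_residue(self):
        monos = [MonolinkRecord("P", 208, "E", "ADH", "c1")] * 3
        assert monolink_frequency(monos) == {(208, "ADH"): 3}

    def test_identical_conditions_give_zero_differences(self):
        monos = [MonolinkRecord("P", r, "E", "ADH", c)
                 for c in ("c1", "c2") for r in (10, 10, 55)]
        report = xt.compare_monolink_conditions(monos, "c1", "c2")
        assert (report["difference"] == 0).all()


class TestCovariationOverlap:
    def covar(self, rows):
        return pd.DataFrame(rows, columns=["i", "j", "probability"])

    def test_exact_match(self):
        result = covariation_overlap(
            [(40, 210)], self.covar([(40, 210, 0.9)]), 0.7, window=0)
        assert result["count"] == 1

    def test_probability_threshold(self):
        result = covariation_overlap(
            [(40, 210)], self.covar([(40, 210, 0.5)]), 0.7, window=0)
        assert result["count"] == 0

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            covariation_overlap([], self.covar([]), 0.7, window=-1)

    def test_matches_brute_force_double_loop(self):
        rng = stage_rng(11, "covar_oracle")
        for _ in range(50):
            n_xl, n_cv = rng.integers(1, 15), rng.integers(1, 30)
            pairs = [tuple(sorted(rng.integers(1, 120, size=2)))
                     for _ in range(n_xl)]
            table = self.covar([
                (int(rng.integers(1, 120)), int(rng.integers(1, 120)),
                 float(rng.random())) for _ in range(n_cv)])
            window = int(rng.integers(0, 4))
            result = covariation_overlap(pairs, table, 0.7, window)
            expected = 0
            for a, b in pairs:
                hit = False
                for _, row in table.iterrows():
                    if row["probability"] < 0.7:
                        continue
                    i, j = row["i"], row["j"]
                    if (abs(i - a) <= window and abs(j - b) <= window) or \
                       (abs(i - b) <= window and abs(j - a) <= window):
                        hit = True
                        break
                expected += hit
            assert result["count"] == expected
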