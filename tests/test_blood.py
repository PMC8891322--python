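"""Blood JSON/TSV pairs: parsing, cross-checks, exact round trip, merging."""

import json
import math
import random

import numpy as np
import pandas as pd
import pytest

from petbids.blood import (
    CANONICAL_COLUMNS,
    BloodMetadata,
    BloodTable,
    default_column_descriptors,
    merge_recordings,
    read_blood_record,
    write_blood_record,
)


def make_meta(columns, recording="manual"):
    return BloodMetadata(
        recording=recording,
        plasma_avail="plasma_radioactivity" in columns,
        whole_blood_avail="whole_blood_radioactivity" in columns,
        metabolite_avail="metabolite_parent_fraction" in columns,
        columns=default_column_descriptors(columns),
    )


def make_table(**cols):
    return BloodTable(pd.DataFrame(cols, dtype=float))


def full_manual_record():
    """A manual recording with all five canonical columns."""
    table = make_table(
        time=[60.0, 120.0, 300.0],
        plasma_radioactivity=[1000.0, 2500.5, 1800.25],
        whole_blood_radioactivity=[900.0, 2200.0, 1500.0],
        metabolite_parent_fraction=[1.0, 0.8, 0.55],
        metabolite_polar_fraction=[0.0, 0.1, 0.3],
    )
    return make_meta(list(table.frame.columns)), table


def codes(findings):
    return [f.code for f in findings]


class TestReadBloodRecord:
    def test_five_column_manual_record_is_clean(self):
        meta, table = full_manual_record()
        json_doc, tsv_doc = write_blood_record(meta, table)
        meta2, table2, findings = read_blood_record(json_doc, tsv_doc)
        assert findings == []
        assert list(table2.frame.columns) == list(CANONICAL_COLUMNS)

    def test_declared_not_present(self):
        meta = make_meta(["time", "plasma_radioactivity"])
        _, _, findings = read_blood_record(
            json.dumps({"Recording": "manual", "PlasmaAvail": True}),
            "time\n60\n120\n",
        )
        assert "PET304" in codes(findings)

    def test_present_not_declared(self):
        _, _, findings = read_blood_record(
            json.dumps({"Recording": "manual"}),
            "time\tplasma_radioactivity\n60\t100\n",
        )
        assert "PET305" in codes(findings)

    def test_non_monotonic_time(self):
        meta, _ = full_manual_record()
        _, _, findings = read_blood_record(
            json.dumps({"Recording": "manual"}), "time\n60\n30\n"
        )
        assert "PET302" in codes(findings)

    def test_missing_time_column(self):
        _, _, findings = read_blood_record(
            json.dumps({"Recording": "manual"}),
            "plasma_radioactivity\n100\n",
        )
        assert "PET301" in codes(findings)

    def test_non_numeric_cell_reports_coordinates(self):
        _, _, findings = read_blood_record(
            json.dumps({"Recording": "manual"}),
            "time\n60\noops\n",
        )
        bad = [f for f in findings if f.code == "PET303"]
        assert len(bad) == 1
        assert "row 1" in bad[0].message and "time" in bad[0].message

    def test_fraction_out_of_range(self):
        meta, table = full_manual_record()
        table.frame.loc[0, "metabolite_parent_fraction"] = 1.5
        json_doc = json.dumps({
            "Recording": "manual",
            **{c: d for c, d in meta.columns.items()},
        })
        tsv = "time\tmetabolite_parent_fraction\n60\t1.5\n"
        _, _, findings = read_blood_record(json_doc, tsv)
        assert "PET306" in codes(findings)

    def test_na_cells_become_nan(self):
        _, table, findings = read_blood_record(
            json.dumps({
                "Recording": "manual",
                "metabolite_parent_fraction": {"Units": "arbitrary"},
            }),
            "time\tmetabolite_parent_fraction\n60\tn/a\n",
        )
        assert findings == []
        assert math.isnan(table.frame.loc[0, "metabolite_parent_fraction"])


class TestWriteBloodRecord:
    def test_header_only_table(self):
        meta = make_meta(["time"])
        _, tsv = write_blood_record(meta, make_table(time=[]))
        assert tsv == "time\n"

    def test_na_sentinel_written_literally(self):
        meta, table = full_manual_record()
        table.frame.loc[1, "metabolite_parent_fraction"] = math.nan
        _, tsv = write_blood_record(meta, table)
        row = tsv.splitlines()[2].split("\t")
        assert row[3] == "n/a"

    def test_random_tables_round_trip_exactly(self):
        rng = random.Random(42)
        for _ in range(25):
            n = rng.randint(1, 12)
            t = sorted(rng.sample(range(0, 10000), n))
            cols = {"time": [float(x) for x in t]}
            for name in CANONICAL_COLUMNS[1:]:
                if rng.random() < 0.7:
                    hi = 1.0 if "fraction" in name else 5e4
                    cols[name] = [
                        math.nan if rng.random() < 0.15 else rng.uniform(0, hi)
                        for _ in range(n)
                    ]
            table = BloodTable(pd.DataFrame(cols, dtype=float))
            meta = make_meta(list(cols))
            json_doc, tsv_doc = write_blood_record(meta, table)
            meta2, table2, findings = read_blood_record(json_doc, tsv_doc)
            assert findings == []
            assert table2 == table  # bit-exact value round trip
            assert meta2 == meta

    def test_invariant_violation_raises(self):
        meta = make_meta(["time"])
        with pytest.raises(ValueError):
            write_blood_record(meta, make_table(time=[60.0, 30.0]))
        with pytest.raises(ValueError):
            write_blood_record(
                make_meta(["time"]),  # no descriptor for plasma
                make_table(time=[60.0], plasma_radioactivity=[10.0]),
            )


class TestMergeRecordings:
    def test_union_count_matches_set_oracle(self):
        # manual at {300, 600}; autosampler at 0..600 step 10 (61 points);
        # two shared times -> 61 + 2 - 2 = 61 distinct times... the set
        # union is the oracle, computed independently below.
        man_t = [300.0, 600.0]
        auto_t = [float(x) for x in range(0, 601, 10)]
        manual = make_table(
            time=man_t, plasma_radioactivity=[5.0, 6.0],
            whole_blood_radioactivity=[4.0, 5.0],
        )
        auto = make_table(
            time=auto_t,
            whole_blood_radioactivity=[1.0 * i for i in range(len(auto_t))],
        )
        merged = merge_recordings(manual, auto)
        assert len(merged.frame) == len(set(man_t) | set(auto_t))
        # continuous device wins at the shared time points
        at300 = merged.frame.set_index("time").loc[300.0]
        assert at300["whole_blood_radioactivity"] == 30.0
        assert at300["plasma_radioactivity"] == 5.0

    def test_merge_with_empty_autosampler_is_identity(self):
        _, manual = full_manual_record()
        merged = merge_recordings(manual, make_table(time=[]))
        assert merged == manual

    def test_merge_preserves_monotone_time(self):
        _, manual = full_manual_record()
        auto = make_table(time=[10.0, 90.0, 150.0], whole_blood_radioactivity=[1, 2, 3])
        merged = merge_recordings(manual, auto)
        assert (np.diff(merged.times) > 0).all()

    def test_disagreeing_manual_values_raise(self):
        manual = make_table(time=[300.0], plasma_radioactivity=[5.0])
        auto = make_table(time=[300.0], plasma_radioactivity=[7.0])
        with pytest.raises(ValueError):
            merge_recordings(manual, auto)

    def test_equal_shared_whole_blood_gives_single_row(self):
        manual = make_table(time=[300.0], whole_blood_radioactivity=[4.0])
        auto = make_table(time=[300.0], whole_blood_radioactivity=[4.0])
        merged = merge_recordings(manual, auto)
        assert len(merged.frame) == 1
        assert merged.frame.loc[0, "whole_blood_radioactivity"] == 4.0
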