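"""Barcode decoding, consensus calling, filters and activity joining."""

import numpy as np
import pandas as pd
import pytest

from armlearn.ngs_demux import (
    BarcodeScheme,
    ReadLayout,
    barcode_arithmetic,
    default_scheme,
    demultiplex,
    join_with_activity,
    parse_read_pair,
)
from armlearn.synthetic_data import generate_fastq_fixture


@pytest.fixture(scope="module")
def scheme():
    return default_scheme()


def _plate_map(n_wells, seed=0, plate=1):
    rng = np.random.default_rng(seed)
    out = {}
    for w in range(n_wells):
        well = f"{'ABCDEFGH'[w // 12]}{w % 12 + 1:02d}"
        out[(plate, well)] = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(20, size=5))
    return out


def test_error_free_round_trip_recovers_every_well(scheme, tmp_path):
    plate_map = _plate_map(96, seed=1)
    paths = generate_fastq_fixture(plate_map, scheme, tmp_path, reads_per_well=20, seed=2)
    calls, qc = demultiplex(paths["r1"], paths["r2"], scheme)
    assert qc["reads_total"] == 96 * 20
    assert qc["reads_assigned"] == qc["reads_total"]
    assert len(calls) == 96
    assert (calls["status"] == "ok").all()
    assert (calls["purity"] == 1.0).all()
    manifest = pd.read_csv(paths["manifest"])
    merged = calls.merge(manifest, on=["plate_id", "well_id"])
    assert len(merged) == 96
    assert (merged["variant_code"] == merged["true_variants"]).all()


def test_read_counts_are_conserved(scheme, tmp_path):
    plate_map = _plate_map(12, seed=3)
    paths = generate_fastq_fixture(
        plate_map, scheme, tmp_path, reads_per_well=40, error_rate=0.05, seed=4
    )
    _, qc = demultiplex(paths["r1"], paths["r2"], scheme)
    assert qc["reads_assigned"] + sum(qc["rejected"].values()) == qc["reads_total"]
    assert qc["rejected"]  # 5% per-base errors must reject some barcodes


def test_demux_is_order_invariant(scheme, tmp_path):
    plate_map = _plate_map(8, seed=5)
    paths = generate_fastq_fixture(plate_map, scheme, tmp_path / "a", reads_per_well=15, seed=6)
    calls, _ = demultiplex(paths["r1"], paths["r2"], scheme)

    def records(path):
        lines = path.read_text().splitlines()
        return ["\n".join(lines[i : i + 4]) for i in range(0, len(lines), 4)]

    r1, r2 = records(paths["r1"]), records(paths["r2"])
    perm = np.random.default_rng(7).permutation(len(r1))
    (tmp_path / "b").mkdir()
    (tmp_path / "b" / "r1.fastq").write_text("\n".join(r1[i] for i in perm) + "\n")
    (tmp_path / "b" / "r2.fastq").write_text("\n".join(r2[i] for i in perm) + "\n")
    calls_shuf, _ = demultiplex(tmp_path / "b" / "r1.fastq", tmp_path / "b" / "r2.fastq", scheme)
    pd.testing.assert_frame_equal(calls, calls_shuf)


def test_gzip_fixture_round_trip(scheme, tmp_path):
    plate_map = _plate_map(4, seed=8)
    paths = generate_fastq_fixture(
        plate_map, scheme, tmp_path, reads_per_well=12, seed=9, gzip_output=True
    )
    assert paths["r1"].suffix == ".gz"
    calls, _ = demultiplex(paths["r1"], paths["r2"], scheme)
    assert (calls["status"] == "ok").all()


def test_single_mismatch_decoding_threshold(scheme, tmp_path):
    plate_map = {(1, "B07"): "CTNLV"}
    paths = generate_fastq_fixture(plate_map, scheme, tmp_path, reads_per_well=1, seed=10)
    r1 = paths["r1"].read_text().splitlines()[1]
    r2 = paths["r2"].read_text().splitlines()[1]
    # Corrupt one base of the row barcode (read 1, offset 6..12).
    pos = 8
    corrupted = r1[:pos] + ("A" if r1[pos] != "A" else "C") + r1[pos + 1 :]
    parsed, reason = parse_read_pair(corrupted, r2, scheme)
    assert reason == "ok"
    assert (parsed.plate, parsed.well) == (1, "B07")
    strict = default_scheme(max_mismatches=0)
    parsed0, reason0 = parse_read_pair(corrupted, r2, strict)
    assert parsed0 is None and reason0 == "well_barcode_unmatched"
    # Uncorrupted read decodes under both.
    assert parse_read_pair(r1, r2, strict)[1] == "ok"


def test_truncated_read_rejected(scheme):
    parsed, reason = parse_read_pair("ACGT", "ACGT", scheme)
    assert parsed is None and reason == "truncated"


def test_mixed_well_flagged(scheme, tmp_path):
    plate_map = {(1, "A01"): ["CTNLV", "TFNAQ"]}
    paths = generate_fastq_fixture(plate_map, scheme, tmp_path, reads_per_well=40, seed=11)
    calls, _ = demultiplex(paths["r1"], paths["r2"], scheme, purity_threshold=0.8)
    assert calls.loc[0, "status"] == "mixed"


def test_nonsense_well_flagged(scheme, tmp_path):
    plate_map = {(1, "A01"): "TF*AQ"}  # amber stop at the third site
    paths = generate_fastq_fixture(plate_map, scheme, tmp_path, reads_per_well=20, seed=12)
    calls, _ = demultiplex(paths["r1"], paths["r2"], scheme)
    assert calls.loc[0, "status"] == "nonsense"


def test_low_coverage_well_flagged(scheme, tmp_path):
    plate_map = {(1, "A01"): "CTNLV"}
    paths = generate_fastq_fixture(plate_map, scheme, tmp_path, reads_per_well=4, seed=13)
    calls, _ = demultiplex(paths["r1"], paths["r2"], scheme, min_reads=10)
    assert calls.loc[0, "status"] == "low_coverage"


def test_chimeras_of_identical_parents_are_harmless(scheme, tmp_path):
    plate_map = {(1, "A01"): "CTNLV"}
    paths = generate_fastq_fixture(
        plate_map, scheme, tmp_path, reads_per_well=30, chimera_rate=0.5, seed=14
    )
    calls, _ = demultiplex(paths["r1"], paths["r2"], scheme)
    assert calls.loc[0, "status"] == "ok"
    assert calls.loc[0, "purity"] == 1.0


def test_two_variant_well_with_chimeras_is_mixed(scheme, tmp_path):
    plate_map = {(1, "A01"): ["CTNLV", "AFNAQ"]}
    paths = generate_fastq_fixture(
        plate_map, scheme, tmp_path, reads_per_well=60, chimera_rate=0.3, seed=15
    )
    calls, _ = demultiplex(paths["r1"], paths["r2"], scheme, purity_threshold=0.8)
    assert calls.loc[0, "status"] == "mixed"


def test_join_with_activity():
    calls = pd.DataFrame(
        {
            "plate_id": [1, 1, 1],
            "well_id": ["A01", "A02", "A03"],
            "variant_code": ["CTNLV", "CTNLV", "TFNAQ"],
            "status": ["ok", "ok", "mixed"],
        }
    )
    meas = pd.DataFrame(
        {
            "plate_id": [1, 1, 1],
            "well_id": ["A01", "A02", "A03"],
            "relative_activity": [1.2, 1.1, 0.4],
        }
    )
    joined, report = join_with_activity(calls, meas)
    assert len(joined) == 2  # replicate wells of the same variant kept separate
    assert set(joined["variant_code"]) == {"CTNLV"}
    assert list(report["reason"]) == ["mixed"]
    with pytest.raises(ValueError, match="duplicate"):
        join_with_activity(pd.concat([calls, calls.iloc[[0]]]), meas)


def test_barcode_arithmetic():
    assert barcode_arithmetic(rows=8, cols=12) == {"wells": 96, "primers": 20}
    assert barcode_arithmetic(n_primers=12)["plates"] == 36
    assert barcode_arithmetic(rows=1, cols=1) == {"wells": 1, "primers": 2}
    with pytest.raises(ValueError):
        barcode_arithmetic(rows=0, cols=5)
    with pytest.raises(ValueError):
        barcode_arithmetic()


def test_ambiguous_barcode_sets_rejected():
    layout = ReadLayout(read1=(("row", 4),), read2=(("col", 4),))
    with pytest.raises(ValueError, match="ambiguous"):
        BarcodeScheme(
            row_barcodes=("AAAA", "AAAT"),
            col_barcodes=("CCCC",),
            plate_fwd_barcodes=("GGGG",),
            plate_rev_barcodes=("TTTT",),
            layout=layout,
            max_mismatches=1,
        )
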