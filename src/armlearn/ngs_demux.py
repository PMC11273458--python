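"""Plate-barcode NGS demultiplexing and sequence-activity joining.

Screening wells are sequenced in bulk: a first PCR appends row- and
column-specific barcodes (8 + 12 primers address all 96 wells of a plate),
a second PCR appends two plate-specific barcodes, and paired-end reads then
carry every barcode plus the five mutated codons.  Demultiplexing decodes
the barcodes (within a mismatch budget), groups reads per well, calls a
consensus over the full five-codon haplotype (so chimera-like mixtures show
up as "mixed" wells rather than being recombined silently), applies the
coverage/purity/nonsense filters, and joins the surviving calls to the
plate activity table.

The exact primer sequences of any given lab are configurable; the default
``BarcodeScheme`` ships deterministic synthetic barcodes (pairwise Hamming
distance >= 3) and a documented read layout, which the fixture generator in
:mod:`armlearn.synthetic_data` shares.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_space import GENETIC_CODE, hamming_distance

__all__ = [
    "BarcodeScheme",
    "ReadLayout",
    "ParsedRead",
    "default_scheme",
    "parse_read_pair",
    "demultiplex",
    "join_with_activity",
    "barcode_arithmetic",
]

ROW_NAMES = "ABCDEFGH"


def _make_barcodes(n: int, length: int = 6, min_dist: int = 3, seed: int = 20240522) -> list[str]:
    """Deterministic synthetic barcode set with pairwise Hamming >= min_dist."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out: list[str] = []
    while len(out) < n:
        cand = "".join(rng.choice(bases, size=length))
        if all(hamming_distance(cand, b) >= min_dist for b in out):
            out.append(cand)
    return out


@dataclass(frozen=True)
class ReadLayout:
    """Which read carries which barcode/codon, as (field, length) segments.

    Fields: ``plate_fwd``, ``plate_rev``, ``row``, ``col``, ``const``
    (ignored spacer) and ``codon<i>`` for the i-th mutated codon.
    """

    read1: tuple[tuple[str, int], ...]
    read2: tuple[tuple[str, int], ...]

    def min_lengths(self) -> tuple[int, int]:
        return (
            sum(n for _, n in self.read1),
            sum(n for _, n in self.read2),
        )

    def offsets(self, read: int) -> dict[str, tuple[int, int]]:
        segs = self.read1 if read == 1 else self.read2
        out: dict[str, tuple[int, int]] = {}
        pos = 0
        for name, n in segs:
            if name != "const":
                out[name] = (pos, pos + n)
            pos += n
        return out


@dataclass(frozen=True)
class BarcodeScheme:
    """Barcode sets, read layout and decoding tolerance."""

    row_barcodes: tuple[str, ...]
    col_barcodes: tuple[str, ...]
    plate_fwd_barcodes: tuple[str, ...]
    plate_rev_barcodes: tuple[str, ...]
    layout: ReadLayout
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        for name in ("row_barcodes", "col_barcodes", "plate_fwd_barcodes", "plate_rev_barcodes"):
            bcs = getattr(self, name)
            for a, b in itertools.combinations(bcs, 2):
                if hamming_distance(a, b) <= 2 * self.max_mismatches:
                    raise ValueError(
                        f"{name}: barcodes {a}/{b} are within 2*max_mismatches "
                        f"({self.max_mismatches}) — decoding would be ambiguous"
                    )

    @property
    def n_plates(self) -> int:
        return len(self.plate_fwd_barcodes) * len(self.plate_rev_barcodes)

    def plate_id(self, fwd_idx: int, rev_idx: int) -> int:
        """1-based plate number from the (forward, reverse) barcode pair."""
        return fwd_idx * len(self.plate_rev_barcodes) + rev_idx + 1

    def plate_indices(self, plate_id: int) -> tuple[int, int]:
        n_rev = len(self.plate_rev_barcodes)
        if not 1 <= plate_id <= self.n_plates:
            raise ValueError(f"plate_id {plate_id} outside 1..{self.n_plates}")
        return (plate_id - 1) // n_rev, (plate_id - 1) % n_rev


def default_scheme(n_sites: int = 5, max_mismatches: int = 1) -> BarcodeScheme:
    """8 row + 12 column + 6x6 plate barcodes with a 40/110 bp read layout.

    Read 1 (40 bp): forward plate barcode, row barcode, constant spacer.
    Read 2 (110 bp): reverse plate barcode, column barcode, then the mutated
    codons separated by constant gene segments (two adjacent codon pairs and
    one isolated codon for the default five sites).
    """
    bcs = _make_barcodes(8 + 12 + 6 + 6)
    rows, cols = bcs[:8], bcs[8:20]
    pf, pr = bcs[20:26], bcs[26:32]
    read1 = (("plate_fwd", 6), ("row", 6), ("const", 28))
    codon_segs: list[tuple[str, int]] = []
    # Mimics sites 111,112 | 118,119 | 121: gaps of 5 and 1 codons.
    gaps_after = {1: 15, 3: 3}
    for i in range(n_sites):
        codon_segs.append((f"codon{i}", 3))
        if i in gaps_after:
            codon_segs.append(("const", gaps_after[i]))
    used = 12 + sum(n for _, n in codon_segs)
    read2 = (("plate_rev", 6), ("col", 6), ("const", 8), *codon_segs, ("const", max(110 - 8 - used, 0)))
    return BarcodeScheme(
        row_barcodes=tuple(rows),
        col_barcodes=tuple(cols),
        plate_fwd_barcodes=tuple(pf),
        plate_rev_barcodes=tuple(pr),
        layout=ReadLayout(read1=tuple(read1), read2=tuple(read2)),
        max_mismatches=max_mismatches,
    )


def _match_barcode(seq: str, barcodes: tuple[str, ...], max_mm: int) -> int | None:
    best_i, best_d = None, max_mm + 1
    for i, bc in enumerate(barcodes):
        d = sum(a != b for a, b in zip(seq, bc))
        if d < best_d:
            best_i, best_d = i, d
    return best_i


@dataclass(frozen=True)
class ParsedRead:
    plate: int
    well: str
    codons: tuple[str, ...]


def parse_read_pair(
    r1: str, r2: str, scheme: BarcodeScheme
) -> tuple[ParsedRead | None, str]:
    """Decode one read pair; returns (parsed, "ok") or (None, reason)."""
    r1, r2 = r1.upper(), r2.upper()
    min1, min2 = scheme.layout.min_lengths()
    if len(r1) < min1 or len(r2) < min2:
        return None, "truncated"
    off1 = scheme.layout.offsets(1)
    off2 = scheme.layout.offsets(2)
    mm = scheme.max_mismatches

    pf = _match_barcode(r1[slice(*off1["plate_fwd"])], scheme.plate_fwd_barcodes, mm)
    row = _match_barcode(r1[slice(*off1["row"])], scheme.row_barcodes, mm)
    pr = _match_barcode(r2[slice(*off2["plate_rev"])], scheme.plate_rev_barcodes, mm)
    col = _match_barcode(r2[slice(*off2["col"])], scheme.col_barcodes, mm)
    if pf is None or pr is None:
        return None, "plate_barcode_unmatched"
    if row is None or col is None:
        return None, "well_barcode_unmatched"
    codons = []
    i = 0
    while f"codon{i}" in off2:
        codons.append(r2[slice(*off2[f"codon{i}"])])
        i += 1
    well = f"{ROW_NAMES[row]}{col + 1:02d}"
    return ParsedRead(plate=scheme.plate_id(pf, pr), well=well, codons=tuple(codons)), "ok"


def _translate(codons: tuple[str, ...]) -> str:
    return "".join(GENETIC_CODE.get(c, "*" if c in ("TAA", "TAG", "TGA") else "X") for c in codons)


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq_pairs(fastq1: str | Path, fastq2: str | Path):
    with _open_maybe_gz(fastq1) as f1, _open_maybe_gz(fastq2) as f2:
        while True:
            block1 = [f1.readline() for _ in range(4)]
            block2 = [f2.readline() for _ in range(4)]
            if not block1[0] or not block2[0]:
                return
            yield block1[1].strip(), block2[1].strip()


def demultiplex(
    fastq1: str | Path,
    fastq2: str | Path,
    scheme: BarcodeScheme,
    min_reads: int = 10,
    purity_threshold: float = 0.8,
) -> tuple[pd.DataFrame, dict]:
    """Demultiplex a paired FASTQ into per-well consensus variant calls.

    The consensus of a well is the most frequent full five-codon haplotype;
    purity is the fraction of reads supporting it.  Status per well:
    ``ok`` (enough reads, pure, no stop), ``low_coverage``, ``mixed``
    (more than one variant above the purity threshold), or ``nonsense``
    (consensus contains a stop codon).  Returns the WellCall table and a QC
    summary with read counts conserved across rejection categories.
    """
    groups: dict[tuple[int, str], dict[tuple[str, ...], int]] = {}
    qc = {
        "reads_total": 0,
        "reads_assigned": 0,
        "rejected": {},
    }
    for s1, s2 in _iter_fastq_pairs(fastq1, fastq2):
        qc["reads_total"] += 1
        parsed, reason = parse_read_pair(s1, s2, scheme)
        if parsed is None:
            qc["rejected"][reason] = qc["rejected"].get(reason, 0) + 1
            continue
        qc["reads_assigned"] += 1
        key = (parsed.plate, parsed.well)
        groups.setdefault(key, {})
        groups[key][parsed.codons] = groups[key].get(parsed.codons, 0) + 1
    if qc["reads_total"] == 0:
        raise ValueError("empty FASTQ input")

    rows = []
    for (plate, well), haplotypes in sorted(groups.items()):
        n_reads = sum(haplotypes.values())
        consensus, count = max(haplotypes.items(), key=lambda kv: (kv[1], kv[0]))
        purity = count / n_reads
        variant = _translate(consensus)
        if n_reads < min_reads:
            status = "low_coverage"
        elif purity < purity_threshold:
            status = "mixed"
        elif "*" in variant:
            status = "nonsense"
        elif "X" in variant:
            status = "undecodable"
        else:
            status = "ok"
        rows.append(
            {
                "plate_id": plate,
                "well_id": well,
                "consensus_codons": "-".join(consensus),
                "variant_code": variant,
                "n_reads": n_reads,
                "purity": purity,
                "status": status,
            }
        )
    calls = pd.DataFrame(rows)
    qc["wells_called"] = len(calls)
    qc["wells_ok"] = int((calls["status"] == "ok").sum()) if len(calls) else 0
    return calls, qc


def join_with_activity(
    wellcalls: pd.DataFrame, measurements: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join status-ok well calls to plate activities on (plate, well).

    Replicate wells of the same variant stay as separate rows (they feed the
    noise estimate).  Returns (joined table, drop report of excluded or
    unmatched wells with reasons).
    """
    for name, df in (("wellcalls", wellcalls), ("measurements", measurements)):
        dup = df.duplicated(subset=["plate_id", "well_id"])
        if dup.any():
            raise ValueError(f"duplicate (plate_id, well_id) rows in {name}")
    ok = wellcalls[wellcalls["status"] == "ok"]
    joined = ok.merge(measurements, on=["plate_id", "well_id"], how="inner")
    dropped_calls = wellcalls[wellcalls["status"] != "ok"][
        ["plate_id", "well_id", "status"]
    ].rename(columns={"status": "reason"})
    matched = set(map(tuple, joined[["plate_id", "well_id"]].to_numpy()))
    unmatched = ok[
        [tuple(r) not in matched for r in ok[["plate_id", "well_id"]].to_numpy()]
    ][["plate_id", "well_id"]].assign(reason="no_activity_measurement")
    report = pd.concat([dropped_calls, unmatched], ignore_index=True)
    return joined.reset_index(drop=True), report


def barcode_arithmetic(
    rows: int | None = None, cols: int | None = None, n_primers: int | None = None
) -> dict[str, int]:
    """Counting facts of the combinatorial barcoding scheme.

    With ``rows`` and ``cols``: wells addressable (rows x cols) and primers
    needed (rows + cols) — 8 rows and 12 columns give 96 wells from 20
    primers.  With ``n_primers``: the number of plates distinguishable by a
    two-barcode combination, max over the forward/reverse split f*(n-f) —
    12 primers distinguish 36 plates.
    """
    out: dict[str, int] = {}
    if rows is not None and cols is not None:
        if rows < 1 or cols < 1:
            raise ValueError("rows and cols must be positive")
        out["wells"] = rows * cols
        out["primers"] = rows + cols
    if n_primers is not None:
        if n_primers < 2:
            raise ValueError("need at least 2 primers for a two-barcode combination")
        out["plates"] = (n_primers // 2) * (n_primers - n_primers // 2)
    if not out:
        raise ValueError("supply rows+cols and/or n_primers")
    return out
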