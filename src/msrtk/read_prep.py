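"""Demultiplexing, UMI extraction, and adapter/length trimming.

Native re-implementation of the inline-barcode splitting and trimming step
of a multiplexed small-RNA library: pooled paired-end reads carry a sample
barcode (3-6 nt) at the start of one read and a 6-nt unique molecular
identifier (UMI) at the start of the other. Demultiplexing routes each pair
to its sample, strips barcode and UMI from the sequences, and appends the
UMI to the read id as ``:UMI:<seq>`` so downstream deduplication remains
possible. The module is fully deterministic.

Reads are handled as ``(read_id, sequence, quality)`` tuples; FASTQ I/O is
gzip-transparent.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

Read = tuple[str, str, str]
ReadPair = tuple[Read, Read]


class DemuxError(ValueError):
    """Raised for invalid barcode specs or desynchronized mate streams."""


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeSpec:
    """Sample barcode layout for a pooled run.

    ``barcodes`` maps sample_id -> barcode sequence (3-6 nt, lengths may
    differ between samples). ``barcode_read``/``umi_read`` select which mate
    carries each element. With ``max_mismatch`` = 0 assignment is exact; any
    tolerance requires barcodes to stay mutually distinguishable
    (pairwise Hamming distance > 2 * max_mismatch on equal-length pairs).
    """

    barcodes: dict[str, str]
    barcode_read: str = "read2"  # {"read1", "read2"}
    umi_length: int = 6
    umi_read: str = "read1"
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise DemuxError("barcode spec has no samples")
        for sid, bc in self.barcodes.items():
            if not 3 <= len(bc) <= 6:
                raise DemuxError(f"{sid}: barcode length {len(bc)} outside 3-6")
            if set(bc) - set("ACGT"):
                raise DemuxError(f"{sid}: barcode {bc} has non-ACGT characters")
        if self.barcode_read not in ("read1", "read2", "both"):
            raise DemuxError(f"bad barcode_read: {self.barcode_read}")
        if self.umi_read not in ("read1", "read2"):
            raise DemuxError(f"bad umi_read: {self.umi_read}")
        items = list(self.barcodes.items())
        for i, (sa, ba) in enumerate(items):
            for sb, bb in items[i + 1:]:
                if ba == bb:
                    raise DemuxError(f"samples {sa} and {sb} share barcode {ba}")
                if len(ba) == len(bb) and _hamming(ba, bb) <= 2 * self.max_mismatch:
                    raise DemuxError(
                        f"barcodes {ba}/{sa} and {bb}/{sb} not distinguishable "
                        f"at max_mismatch={self.max_mismatch}"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "BarcodeSpec":
        """Read a spec from a TSV with columns sample_id, barcode[, umi_len]."""
        barcodes = {}
        umi_len = None
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            col = {name: i for i, name in enumerate(header)}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if not parts or not parts[0]:
                    continue
                barcodes[parts[col["sample_id"]]] = parts[col["barcode"]].upper()
                if "umi_len" in col:
                    umi_len = int(parts[col["umi_len"]])
        if umi_len is not None:
            kwargs.setdefault("umi_length", umi_len)
        return cls(barcodes=barcodes, **kwargs)

    def match(self, seq: str) -> str | None:
        """Sample id whose barcode matches the start of ``seq``, or None."""
        best: str | None = None
        for sid, bc in self.barcodes.items():
            if len(seq) < len(bc):
                continue
            if _hamming(seq[: len(bc)], bc) <= self.max_mismatch:
                if best is not None:
                    return None  # ambiguous under tolerance
                best = sid
                if self.max_mismatch == 0:
                    return best
        return best


@dataclass
class DemuxResult:
    """Per-sample processed read pairs plus accounting."""

    by_sample: dict[str, list[ReadPair]] = field(default_factory=dict)
    unassigned: list[ReadPair] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + len(self.unassigned)


def demultiplex(
    pairs: Iterable[ReadPair],
    spec: BarcodeSpec,
) -> DemuxResult:
    """Split read pairs by inline barcode and extract UMIs.

    Every input pair lands in exactly one output stream (a sample or
    ``unassigned``); counts are conserved. For assigned pairs the barcode
    and UMI prefixes are removed and ``:UMI:<seq>`` is appended to both
    mate ids. Pairs too short for barcode + UMI go to ``unassigned``.
    """
    res = DemuxResult(by_sample={sid: [] for sid in spec.barcodes})
    res.counts = {sid: 0 for sid in spec.barcodes}
    for r1, r2 in pairs:
        if r1[0].split()[0].split("/")[0] != r2[0].split()[0].split("/")[0]:
            raise DemuxError(f"desynchronized mates: {r1[0]!r} vs {r2[0]!r}")
        bc_read = r2 if spec.barcode_read in ("read2", "both") else r1
        sid = spec.match(bc_read[1])
        umi_src = r1 if spec.umi_read == "read1" else r2
        if sid is None or len(umi_src[1]) < spec.umi_length:
            res.unassigned.append((r1, r2))
            continue
        bclen = len(spec.barcodes[sid])
        if len(bc_read[1]) < bclen:
            res.unassigned.append((r1, r2))
            continue
        umi = umi_src[1][: spec.umi_length]

        def strip(read: Read, n: int) -> Read:
            return (read[0], read[1][n:], read[2][n:])

        new1, new2 = r1, r2
        if spec.barcode_read in ("read2", "both"):
            new2 = strip(new2, bclen)
        if spec.barcode_read in ("read1", "both"):
            new1 = strip(new1, bclen)
        if spec.umi_read == "read1":
            new1 = strip(new1, spec.umi_length)
        else:
            new2 = strip(new2, spec.umi_length)
        tag = f":UMI:{umi}"
        new1 = (new1[0] + tag, new1[1], new1[2])
        new2 = (new2[0] + tag, new2[1], new2[2])
        res.by_sample[sid].append((new1, new2))
        res.counts[sid] += 1
    return res


def trim_adapter(seq: str, adapter: str, min_overlap: int = 5) -> str:
    """Remove a 3' adapter occurrence, allowing trailing partial matches.

    A full adapter match anywhere trims from its start; otherwise the
    longest adapter prefix (>= ``min_overlap`` nt) matching the read's
    3' terminus is trimmed.
    """
    idx = seq.find(adapter)
    if idx >= 0:
        return seq[:idx]
    max_partial = min(len(adapter) - 1, len(seq))
    for k in range(max_partial, min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[: len(seq) - k]
    return seq


@dataclass
class TrimStats:
    kept: int = 0
    dropped: int = 0
    trimmed: int = 0


def trim_and_filter(
    reads: Iterable[Read],
    adapter: str,
    min_length: int = 15,
) -> tuple[list[Read], TrimStats]:
    """Adapter-trim single reads and drop those shorter than ``min_length``.

    Quality strings are clipped alongside sequences. Quality-based trimming
    is deliberately not performed: base changes carry the modification
    signal downstream and must survive intact.
    """
    if not adapter:
        raise DemuxError("adapter sequence must be non-empty")
    if min_length < 1:
        raise DemuxError("min_length must be >= 1")
    out: list[Read] = []
    stats = TrimStats()
    for rid, seq, qual in reads:
        trimmed = trim_adapter(seq, adapter)
        if len(trimmed) != len(seq):
            stats.trimmed += 1
        if len(trimmed) < min_length:
            stats.dropped += 1
            continue
        out.append((rid, trimmed, qual[: len(trimmed)]))
        stats.kept += 1
    return out, stats


def dedup_umi(
    records: Iterable[tuple[str, str, int, int]],
) -> list[tuple[str, str, int, int]]:
    """Optional UMI deduplication: collapse (gene, start, end, UMI) groups.

    Input records are (umi, gene_id, ref_start, ref_end); one representative
    per identical key is kept. Off by default in the pipeline — the standard
    analysis trims UMIs without deduplicating.
    """
    seen: set[tuple[str, str, int, int]] = set()
    out = []
    for umi, gene, start, end in records:
        key = (umi, gene, start, end)
        if key in seen:
            continue
        seen.add(key)
        out.append(key)
    return out


# ---------------------------------------------------------------------------
# FASTQ I/O helpers (gzip-transparent)

def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, mode)
    return open(p, mode)


def read_fastq(path: str | Path) -> Iterator[Read]:
    with _open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    it1, it2 = read_fastq(r1_path), read_fastq(r2_path)
    for r1 in it1:
        r2 = next(it2, None)
        if r2 is None:
            raise DemuxError("read1 file has more records than read2")
        yield r1, r2
    if next(it2, None) is not None:
        raise DemuxError("read2 file has more records than read1")


def write_fastq(path: str | Path, reads: Iterable[Read]) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n
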