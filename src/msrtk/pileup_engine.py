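"""Per-gene, per-position pileup matrices and positional signals.

Alignments against the tRNA (or rRNA) reference are reduced to count
matrices — base calls, deletions, insertion starts, read starts and read
ends per position — from which the two positional signals of
reverse-transcription-based modification detection are derived:

* **mutation fraction**: (non-reference base calls + deletions) / (all base
  calls + deletions). Elevated at Watson-Crick-face methylations (m1A, m3C,
  m1G, m2,2G) that the RT reads through with misincorporation.
* **stop fraction**: the RT synthesizes cDNA toward the RNA 5' end, so a
  cDNA blocked by a modification at position i begins (reference-leftmost)
  at i+1. stop_fraction(i) = start(i+1) / (start(i+1) + coverage(i)).

Only primary, mapped alignments are counted; MAPQ is ignored because the
aligner reports one best placement among near-identical isodecoders and a
MAPQ filter would silently delete whole multi-mapped tRNA families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .reference_model import ReferenceSet

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
#: row index of the deletion channel in the call matrix
DEL = 4

#: maximum soft-clipped bases tolerated at the 3' end before an alignment is
#: excluded from end profiles (local alignment could otherwise fake a CC end)
MAX_END_SOFTCLIP = 2


class PileupError(ValueError):
    pass


@dataclass
class GenePileup:
    """Count arrays for one reference gene.

    ``calls`` is (5, L): A/C/G/T call counts plus deletions. ``read_end``
    counts every alignment's rightmost reference base; ``read_end_clean``
    additionally requires <= MAX_END_SOFTCLIP soft-clipped bases 3' of the
    alignment and is what end profiles, charging and fragment binning use.
    """

    gene_id: str
    sequence: str
    calls: np.ndarray  # (5, L) int64
    ins_start: np.ndarray  # (L,)
    read_start: np.ndarray  # (L,)
    read_end: np.ndarray  # (L,)
    read_end_clean: np.ndarray  # (L,)
    n_reads: int = 0

    @classmethod
    def empty(cls, gene_id: str, sequence: str) -> "GenePileup":
        L = len(sequence)
        gp = cls(
            gene_id=gene_id,
            sequence=sequence,
            calls=np.zeros((5, L), dtype=np.int64),
            ins_start=np.zeros(L, dtype=np.int64),
            read_start=np.zeros(L, dtype=np.int64),
            read_end=np.zeros(L, dtype=np.int64),
            read_end_clean=np.zeros(L, dtype=np.int64),
        )
        gp._init_scratch()
        return gp

    def _init_scratch(self) -> None:
        """Scratch arrays for the vectorized match-run accumulation."""
        L = len(self.sequence)
        self._refbytes = np.frombuffer(self.sequence.encode(), dtype=np.uint8).copy()
        self._ref_idx = np.array(
            [_BASE_IDX.get(b, -1) for b in self.sequence], dtype=np.int64
        )
        self._mcov = np.zeros(L, dtype=np.int64)  # aligned-base coverage
        self._nonref = np.zeros(L, dtype=np.int64)  # mismatches + N calls
        self._finalized = True  # an empty pileup is trivially consistent

    def _finalize(self) -> None:
        """Fold match-run coverage into per-base call counts.

        Match runs are accumulated as a coverage counter plus explicit
        mismatch entries; reference-base calls are the difference. Safe to
        call repeatedly.
        """
        if self._finalized:
            return
        ok = self._ref_idx >= 0
        idx = np.where(ok, self._ref_idx, 0)
        ref_calls = self._mcov - self._nonref
        pos = np.arange(len(self.sequence))
        np.add.at(self.calls, (idx[ok], pos[ok]), ref_calls[ok])
        self._mcov[:] = 0
        self._nonref[:] = 0
        self._finalized = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    def coverage(self) -> np.ndarray:
        """Reads spanning each position: base calls + deletions."""
        self._finalize()
        return self.calls.sum(axis=0)


@dataclass
class PileupMatrix:
    """Pileups for a whole reference set, keyed by gene id."""

    genes: dict[str, GenePileup] = field(default_factory=dict)
    skipped_refs: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, gene_id: str) -> GenePileup:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __iter__(self):
        return iter(self.genes.values())

    @property
    def total_reads(self) -> int:
        return sum(g.n_reads for g in self)

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-position table (1-based positions)."""
        frames = []
        for g in self:
            L = g.length
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": g.gene_id,
                        "pos": np.arange(1, L + 1),
                        "ref": list(g.sequence),
                        "A": g.calls[0],
                        "C": g.calls[1],
                        "G": g.calls[2],
                        "T": g.calls[3],
                        "del": g.calls[DEL],
                        "ins": g.ins_start,
                        "start": g.read_start,
                        "end": g.read_end,
                        "end_clean": g.read_end_clean,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PileupMatrix":
        df = pd.read_csv(path, sep="\t")
        mat = cls()
        for gid, sub in df.groupby("gene_id", sort=False):
            sub = sub.sort_values("pos")
            seq = "".join(sub["ref"])
            gp = GenePileup.empty(str(gid), seq)
            for i, base in enumerate(_BASES):
                gp.calls[i] = sub[base].to_numpy()
            gp.calls[DEL] = sub["del"].to_numpy()
            gp.ins_start = sub["ins"].to_numpy()
            gp.read_start = sub["start"].to_numpy()
            gp.read_end = sub["end"].to_numpy()
            gp.read_end_clean = sub["end_clean"].to_numpy()
            gp.n_reads = int(gp.read_start.sum())
            mat.genes[str(gid)] = gp
        return mat


def _apply_alignment(
    gp: GenePileup,
    ref_start: int,
    cigartuples: list[tuple[int, int]],
    query: str,
) -> None:
    """Walk one CIGAR, incrementing the gene's count arrays.

    M/=/X add base calls, D adds deletions at deleted reference positions,
    I adds one insertion-start at the preceding reference position, S/H
    contribute nothing to coverage.
    """
    rpos = ref_start
    qpos = 0
    end_clip = 0
    if cigartuples and cigartuples[-1][0] == 4:  # soft clip at 3' end
        end_clip = cigartuples[-1][1]
    gp._finalized = False
    for op, ln in cigartuples:
        if op in (0, 7, 8):  # M, =, X
            if rpos < 0 or rpos + ln > gp.length:
                raise PileupError(
                    f"alignment run [{rpos},{rpos + ln}) out of bounds for {gp.gene_id}"
                )
            q = np.frombuffer(
                query[qpos : qpos + ln].encode(), dtype=np.uint8
            )
            gp._mcov[rpos : rpos + ln] += 1
            diff = np.nonzero(q != gp._refbytes[rpos : rpos + ln])[0]
            for d in diff:
                gp._nonref[rpos + d] += 1
                bi = _BASE_IDX.get(chr(q[d]))
                if bi is not None:
                    gp.calls[bi, rpos + d] += 1
                # non-ACGT query bases (N) are not calls at all
            rpos += ln
            qpos += ln
        elif op == 2:  # D
            gp.calls[DEL, rpos : min(rpos + ln, gp.length)] += 1
            rpos += ln
        elif op == 1:  # I — one insertion event at the preceding ref position
            if rpos - 1 >= 0:
                gp.ins_start[rpos - 1] += 1
            qpos += ln
        elif op == 4:  # S
            qpos += ln
        elif op == 3:  # N
            rpos += ln
        elif op == 5:  # H
            pass
        elif op == 6:  # P
            pass
        else:
            raise PileupError(f"unsupported CIGAR op {op} in {gp.gene_id}")
    leftmost = ref_start
    rightmost = rpos - 1
    if not 0 <= leftmost < gp.length or not 0 <= rightmost < gp.length:
        raise PileupError(
            f"alignment [{leftmost},{rightmost}] out of bounds for {gp.gene_id}"
        )
    gp.read_start[leftmost] += 1
    gp.read_end[rightmost] += 1
    if end_clip <= MAX_END_SOFTCLIP:
        gp.read_end_clean[rightmost] += 1
    gp.n_reads += 1


def build_pileup(
    alignments: str | Path | pysam.AlignmentFile | Iterable,
    ref: ReferenceSet,
    read_filter: Callable[[pysam.AlignedSegment], bool] | None = None,
) -> PileupMatrix:
    """Build per-gene pileups from a SAM/BAM stream.

    Secondary, supplementary and unmapped records are skipped. Alignments to
    reference names absent from ``ref`` are skipped and counted in
    ``skipped_refs``. ``read_filter`` (when given) further restricts which
    reads are counted — used for per-fragment-bin pileups.
    """
    mat = PileupMatrix()
    for g in ref:
        mat.genes[g.gene_id] = GenePileup.empty(g.gene_id, g.sequence)

    own = False
    if isinstance(alignments, (str, Path)):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    try:
        for aln in alignments:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            rname = aln.reference_name
            if rname not in mat.genes:
                mat.skipped_refs[rname] = mat.skipped_refs.get(rname, 0) + 1
                continue
            if read_filter is not None and not read_filter(aln):
                continue
            if aln.cigartuples is None:
                raise PileupError(f"missing CIGAR for record {aln.query_name}")
            _apply_alignment(
                mat.genes[rname],
                aln.reference_start,
                aln.cigartuples,
                aln.query_sequence or "",
            )
    finally:
        if own:
            alignments.close()
    for gp in mat:
        gp._finalize()
    return mat


def mutation_fraction(
    pileup: PileupMatrix,
    gene: str,
    position: int,
    min_coverage: int = 20,
) -> float:
    """Mutation fraction at a 0-based position, or NaN below ``min_coverage``.

    Numerator: non-reference base calls plus deletions. Denominator: all
    base calls plus deletions. Insertions count in neither.
    """
    if gene not in pileup:
        raise PileupError(f"unknown gene {gene}")
    gp = pileup[gene]
    if not 0 <= position < gp.length:
        raise PileupError(f"position {position} out of bounds for {gene}")
    gp._finalize()
    col = gp.calls[:, position]
    denom = int(col.sum())
    if denom < min_coverage:
        return float("nan")
    ref_base = gp.sequence[position]
    ref_calls = int(col[_BASE_IDX[ref_base]]) if ref_base in _BASE_IDX else 0
    return (denom - ref_calls) / denom


def mutation_fraction_profile(
    pileup: PileupMatrix, gene: str, min_coverage: int = 20
) -> np.ndarray:
    """Vectorized mutation fraction over all positions of a gene."""
    gp = pileup[gene]
    gp._finalize()
    denom = gp.calls.sum(axis=0).astype(float)
    ref_idx = np.array([_BASE_IDX.get(b, -1) for b in gp.sequence])
    ref_calls = np.where(
        ref_idx >= 0,
        gp.calls[np.clip(ref_idx, 0, 3), np.arange(gp.length)],
        0,
    ).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (denom - ref_calls) / denom
    frac[denom < min_coverage] = np.nan
    return frac


def stop_fraction(
    pileup: PileupMatrix,
    gene: str,
    position: int,
    min_denominator: int = 20,
) -> float:
    """RT-stop fraction at a 0-based position, or NaN when undefined.

    stop(i) = start(i+1) / (start(i+1) + coverage(i)): a cDNA blocked by the
    modification at i has its reference-leftmost base at i+1, while reads
    covering i read through. Undefined at the last position (no i+1) and
    below ``min_denominator``.
    """
    if gene not in pileup:
        raise PileupError(f"unknown gene {gene}")
    gp = pileup[gene]
    if not 0 <= position < gp.length:
        raise PileupError(f"position {position} out of bounds for {gene}")
    if position == gp.length - 1:
        return float("nan")
    gp._finalize()
    stops = int(gp.read_start[position + 1])
    through = int(gp.calls[:, position].sum())
    denom = stops + through
    if denom < min_denominator:
        return float("nan")
    return stops / denom


def stop_fraction_profile(
    pileup: PileupMatrix, gene: str, min_denominator: int = 20
) -> np.ndarray:
    """Vectorized stop fraction over all positions (NaN where undefined)."""
    gp = pileup[gene]
    gp._finalize()
    out = np.full(gp.length, np.nan)
    cov = gp.calls.sum(axis=0).astype(float)
    stops = gp.read_start[1:].astype(float)
    denom = stops + cov[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = stops / denom
    frac[denom < min_denominator] = np.nan
    out[:-1] = frac
    return out


def end_profile(pileup: PileupMatrix, gene: str) -> dict[int, int]:
    """Histogram of clean 3'-end positions (0-based) for a gene."""
    if gene not in pileup:
        raise PileupError(f"unknown gene {gene}")
    gp = pileup[gene]
    nz = np.nonzero(gp.read_end_clean)[0]
    return {int(i): int(gp.read_end_clean[i]) for i in nz}


def signal_frame(
    pileup: PileupMatrix,
    min_coverage: int = 20,
) -> pd.DataFrame:
    """Per-gene, per-position mutation and stop fractions (1-based positions)."""
    frames = []
    for gp in pileup:
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gp.gene_id,
                    "pos": np.arange(1, gp.length + 1),
                    "coverage": gp.coverage(),
                    "mutation_fraction": mutation_fraction_profile(
                        pileup, gp.gene_id, min_coverage
                    ),
                    "stop_fraction": stop_fraction_profile(
                        pileup, gp.gene_id, min_coverage
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
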