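"""Curated tRNA reference handling.

Loads a tRNA gene set from FASTA, guarantees the 3' CCA tail used for
aminoacylation (charging) readout, collapses duplicate sequences into a
non-redundant set, and attaches the naming/coordinate conventions every
downstream stage relies on (isoacceptor grouping by anticodon, wobble base
at anticodon position 34, optional canonical-position labels such as "47d").

Coordinates are 0-based half-open internally; user-facing tables and the
canonical map are 1-based inclusive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: amino-acid tokens accepted in gene names (3-letter codes plus specials)
_AA_TOKENS = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    "iMet", "fMet", "SeC", "Sec", "Sup", "Und",
}

_NAME_RE = re.compile(
    r"(?P<mt>mt-|MT-)?tRNA-(?P<aa>[A-Za-z]{3,4})-(?P<ac>[ACGTacgt]{3})(?:-(?P<locus>\S+))?"
)


class ReferenceError(ValueError):
    """Raised for unusable reference input (empty file, bad canonical table)."""


@dataclass
class TRNAGene:
    """A single tRNA gene with CCA appended.

    The anticodon is stored in gene (DNA) sense; its first base is the
    wobble position 34. ``canonical_map`` maps 1-based linear positions to
    canonical tRNA-position labels (e.g. 50 -> "47d" for long variable arms).
    """

    gene_id: str
    amino_acid: str
    anticodon: str
    sequence: str
    origin: str = "nuclear"  # or "mitochondrial"
    anticodon_offset: int | None = None  # 0-based start of anticodon in sequence
    canonical_map: dict[int, str] | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def wobble(self) -> str:
        return self.anticodon[0]

    @property
    def isoacceptor(self) -> tuple[str, str]:
        return (self.amino_acid, self.anticodon)

    def position_label(self, pos1: int) -> str:
        """Label for a 1-based position: canonical if annotated, else str(pos1)."""
        if self.canonical_map and pos1 in self.canonical_map:
            return self.canonical_map[pos1]
        return str(pos1)

    def validate(self) -> None:
        if not self.sequence.endswith("CCA"):
            raise ReferenceError(f"{self.gene_id}: sequence does not end in CCA")
        if self.anticodon_offset is not None:
            off = self.anticodon_offset
            if self.sequence[off:off + 3] != self.anticodon:
                raise ReferenceError(
                    f"{self.gene_id}: anticodon {self.anticodon} not at offset {off}"
                )


@dataclass
class ReferenceSet:
    """A curated, optionally non-redundant collection of tRNA genes."""

    genes: dict[str, TRNAGene] = field(default_factory=dict)
    nonredundant: bool = False
    merged: dict[str, str] = field(default_factory=dict)  # dropped id -> kept id

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> TRNAGene:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    @property
    def isoacceptor_index(self) -> dict[tuple[str, str], list[str]]:
        idx: dict[tuple[str, str], list[str]] = {}
        for g in self:
            idx.setdefault(g.isoacceptor, []).append(g.gene_id)
        return idx

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in self:
                fh.write(f">{g.gene_id}\n{g.sequence}\n")

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g.gene_id,
                "amino_acid": g.amino_acid,
                "anticodon": g.anticodon,
                "wobble": g.wobble,
                "origin": g.origin,
                "length": g.length,
            }
            for g in self
        ]
        return pd.DataFrame(rows)


def parse_gene_name(name: str) -> tuple[str, str, str] | None:
    """Parse amino acid, anticodon and origin from a tRNA record name.

    Accepts gtRNAdb-style ids ("tRNA-Ser-GCT-1-1", "tRNA-Lys-TTT-1"),
    locus-suffixed ids ("tRNA-Ser-GCT-c17.t35") and mitochondrial prefixes
    ("mt-tRNA-..."). Returns (amino_acid, anticodon, origin) or None when
    the name is not parseable.
    """
    m = _NAME_RE.search(name)
    if m is None:
        return None
    aa = m.group("aa")
    if aa not in _AA_TOKENS:
        # Case-normalise 3-letter codes like "SER"
        aa_t = aa[0].upper() + aa[1:].lower()
        if aa_t not in _AA_TOKENS:
            return None
        aa = aa_t
    origin = "mitochondrial" if m.group("mt") else "nuclear"
    return aa, m.group("ac").upper(), origin


def load_reference(
    fasta_path: str | Path,
    metadata: pd.DataFrame | None = None,
) -> ReferenceSet:
    """Load a tRNA reference FASTA into a non-redundant :class:`ReferenceSet`.

    Every stored sequence is guaranteed to end in CCA (appended when absent,
    as the mature-tRNA reference requires). Records whose names cannot be
    parsed into amino acid + anticodon are rejected with a warning. Records
    with identical sequences are collapsed onto the lexicographically first
    id, with the merge recorded in ``ReferenceSet.merged``.

    Parameters
    ----------
    fasta_path
        Reference FASTA of tRNA genes.
    metadata
        Optional table with columns ``gene_id`` and any of ``origin``,
        ``anticodon_offset``; overrides name-derived values.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ReferenceError(f"empty or unparseable FASTA: {fasta_path}")

    meta: dict[str, dict] = {}
    if metadata is not None:
        for _, row in metadata.iterrows():
            meta[str(row["gene_id"])] = row.to_dict()

    genes: list[TRNAGene] = []
    for rec in records:
        parsed = parse_gene_name(rec.id)
        if parsed is None:
            logger.warning("rejecting unparseable record name: %s", rec.id)
            continue
        aa, anticodon, origin = parsed
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq.endswith("CCA"):
            seq += "CCA"
        m = meta.get(rec.id, {})
        if "origin" in m and pd.notna(m["origin"]):
            origin = str(m["origin"])
        offset = None
        if "anticodon_offset" in m and pd.notna(m["anticodon_offset"]):
            offset = int(m["anticodon_offset"])
        else:
            # default annotation: first occurrence near the anticodon loop
            found = seq.find(anticodon)
            offset = found if found >= 0 else None
        g = TRNAGene(
            gene_id=rec.id,
            amino_acid=aa,
            anticodon=anticodon,
            sequence=seq,
            origin=origin,
            anticodon_offset=offset,
        )
        g.validate()
        genes.append(g)

    # collapse identical sequences onto the lexicographically first id
    by_seq: dict[str, list[TRNAGene]] = {}
    for g in sorted(genes, key=lambda g: g.gene_id):
        by_seq.setdefault(g.sequence, []).append(g)
    ref = ReferenceSet(nonredundant=True)
    for seq, group in by_seq.items():
        keep = group[0]
        ref.genes[keep.gene_id] = keep
        for dup in group[1:]:
            ref.merged[dup.gene_id] = keep.gene_id
            logger.info("merged duplicate sequence %s -> %s", dup.gene_id, keep.gene_id)
    # restore input order among kept genes
    kept_order = [g.gene_id for g in genes if g.gene_id in ref.genes]
    ref.genes = {gid: ref.genes[gid] for gid in dict.fromkeys(kept_order)}
    return ref


def annotate_gene(
    gene: TRNAGene,
    canonical_table: pd.DataFrame | Iterable[tuple] | None = None,
) -> TRNAGene:
    """Attach a canonical (Sprinzl-style) position map to a gene.

    ``canonical_table`` rows are (gene_id, linear_position, label) with
    1-based linear positions; rows for other genes are ignored. Positions
    without an entry fall back to their 1-based linear index as text. The
    labels are supplied, never computed.
    """
    cmap: dict[int, str] = {i: str(i) for i in range(1, gene.length + 1)}
    if canonical_table is not None:
        if isinstance(canonical_table, pd.DataFrame):
            rows = canonical_table.itertuples(index=False)
        else:
            rows = canonical_table
        for row in rows:
            gid, pos, label = row[0], int(row[1]), str(row[2])
            if gid != gene.gene_id:
                continue
            if not 1 <= pos <= gene.length:
                raise ReferenceError(
                    f"canonical table position {pos} out of bounds for "
                    f"{gene.gene_id} (length {gene.length})"
                )
            cmap[pos] = label
    gene.canonical_map = cmap
    return gene
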