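"""Synthetic data with known truth for every pipeline stage.

The generator emulates the statistical structure a multiplexed tRNA-seq
experiment produces, so each analysis stage can be tested for recovery of
planted parameters without any external data:

* a tRNA reference with isodecoder families (including a Ser-GCT family
  carrying both C and T at the variable-arm position annotated 47d, and
  T34/C34 wobble isoacceptor pairs for several amino acids);
* 3'-anchored tRNA reads: gene drawn from planted abundances, 3' end CCA
  (charged) or CC (uncharged) by a planted charging fraction, or a
  fragment 3' end from a planted bin distribution; the reverse
  transcriptase then walks toward the RNA 5' end and, at each planted
  modification, stops, misincorporates, or deletes with planted
  probabilities; uniform sequencing errors on top;
* matched +/-CMC libraries over an rRNA-scale reference with planted
  pseudouridine sites differing only in stop (and mutation) penetrance;
* mRNA input/polysome count tables under a log-linear codon-usage model of
  translational efficiency, log10(TE) = alpha + beta * z(freq(target
  codon)) + noise, with negative-binomial counting noise.

Reads are emitted both as barcoded, UMI-tagged FASTQ (exercising the
demultiplexer) and as truth-aligned SAM, so no external aligner is needed.
All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical seed and config give identical
output bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .reference_model import ReferenceSet, TRNAGene
from .translation_codon import SENSE_CODONS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ModSite:
    """Planted modification at one position (probabilities conditional on
    the RT reaching the position; mis/del conditional on reading through)."""

    p_stop: float = 0.0
    p_mis: float = 0.0
    p_del: float = 0.0


@dataclass
class SimConfig:
    """Generator parameters; defaults are the standard study conditions."""

    n_genes: int = 17
    read_length: int = 100
    depth_per_gene: int = 10_000
    charging_fraction: float = 0.80
    fragment_rate: float = 0.01
    fragment_bin_probs: tuple[float, ...] = (0.15, 0.35, 0.30, 0.20)  # <30,30-39,40-49,50-59
    seq_error_rate: float = 0.001
    umi_length: int = 6
    barcodes: tuple[str, ...] = ("CTGA", "ACTG", "GACT", "TGAC")
    # +/-CMC model (rRNA-scale single reference)
    rrna_length: int = 1800
    n_psi: int = 36
    psi_stop_range: tuple[float, float] = (0.15, 0.80)
    psi_mut_range: tuple[float, float] = (0.0, 0.30)
    p_stop_minus: float = 0.01
    sub_threshold_delta: float = 0.08
    background_stop: float = 0.002
    cmc_depth: int = 10_000  # mean per-position coverage
    # mRNA / TE model
    n_mrna_genes: int = 600
    n_noncoding: int = 20
    cds_codon_range: tuple[int, int] = (100, 500)
    codon_dirichlet_alpha: float = 2.0
    target_codon: str = "AAA"
    te_alpha: float = 0.0
    te_sigma: float = 0.30
    te_beta: float = -0.5  # in units of te_sigma per SD of target-codon frequency
    nb_dispersion: float = 0.1
    mean_count: float = 500.0
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("control", "stress")


#: default gene table: (amino_acid, anticodon, copy, length, variant_base_at_50, origin)
_DEFAULT_GENES = [
    ("Ser", "GCT", 1, 88, "C", "nuclear"),
    ("Ser", "GCT", 2, 88, "C", "nuclear"),
    ("Ser", "GCT", 3, 88, "T", "nuclear"),
    ("Ser", "GCT", 4, 88, "T", "nuclear"),
    ("Lys", "TTT", 1, 76, None, "nuclear"),
    ("Lys", "TTT", 2, 76, None, "nuclear"),
    ("Lys", "CTT", 1, 76, None, "nuclear"),
    ("Glu", "TTC", 1, 75, None, "nuclear"),
    ("Glu", "CTC", 1, 75, None, "nuclear"),
    ("Gln", "TTG", 1, 74, None, "nuclear"),
    ("Gln", "CTG", 1, 74, None, "nuclear"),
    ("Arg", "TCT", 1, 77, None, "nuclear"),
    ("Arg", "CCT", 1, 77, None, "nuclear"),
    ("Gly", "GCC", 1, 74, None, "nuclear"),
    ("Ala", "AGC", 1, 76, None, "nuclear"),
    ("iMet", "CAT", 1, 75, None, "nuclear"),
    ("Leu", "TAG", 1, 85, None, "mitochondrial"),
]

_EXTRA_POOL = [
    ("Val", "AAC"), ("Thr", "AGT"), ("Pro", "AGG"), ("Asp", "GTC"),
    ("Asn", "GTT"), ("His", "GTG"), ("Phe", "GAA"), ("Cys", "GCA"),
    ("Trp", "CCA"), ("Tyr", "GTA"), ("Ile", "AAT"), ("Met", "CAT"),
]


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def make_reference(cfg: SimConfig, seed: int) -> ReferenceSet:
    """Deterministic synthetic tRNA reference.

    Genes are 60-95 nt including the 3' CCA, carry their anticodon at
    linear positions 34-36 (0-based offset 33), and include by default a
    four-member Ser-GCT family with C or T at linear position 50 (the
    variable-arm position conventionally labelled 47d in long-arm tRNAs)
    plus T34/C34 wobble pairs for four amino acids.
    """
    rng = np.random.default_rng(seed)
    spec = list(_DEFAULT_GENES)
    seen_ids = {f"tRNA-{aa}-{ac}-{copy}" for aa, ac, copy, *_ in spec}
    pool_i = 0
    while len(spec) < cfg.n_genes:
        aa, ac = _EXTRA_POOL[pool_i % len(_EXTRA_POOL)]
        copy = pool_i // len(_EXTRA_POOL) + 1
        gid = f"tRNA-{aa}-{ac}-{copy}"
        if gid in seen_ids:
            raise ValueError(f"duplicate synthetic gene id {gid}")
        seen_ids.add(gid)
        L = int(rng.integers(72, 90))
        spec.append((aa, ac, copy, L, None, "nuclear"))
        pool_i += 1
    spec = spec[: cfg.n_genes]

    ref = ReferenceSet(nonredundant=True)
    for aa, ac, copy, L, var50, origin in spec:
        if not 60 <= L <= 95:
            raise ValueError(f"gene length {L} outside 60-95")
        arr = _random_seq(rng, L)
        arr[33:36] = np.frombuffer(ac.encode(), dtype=np.uint8)
        if var50 is not None:
            arr[49] = ord(var50)
        arr[-3:] = np.frombuffer(b"CCA", dtype=np.uint8)
        prefix = "mt-" if origin == "mitochondrial" else ""
        gid = f"{prefix}tRNA-{aa}-{ac}-{copy}"
        g = TRNAGene(
            gene_id=gid,
            amino_acid=aa,
            anticodon=ac,
            sequence=arr.tobytes().decode(),
            origin=origin,
            anticodon_offset=33,
        )
        g.validate()
        ref.genes[gid] = g
    seqs = [g.sequence for g in ref]
    if len(set(seqs)) != len(seqs):  # astronomically unlikely; regenerate upstream
        raise ValueError("duplicate sequences in synthetic reference")
    return ref


def default_modifications(ref: ReferenceSet) -> dict[str, dict[int, ModSite]]:
    """Default planted modification profile.

    Every sufficiently long gene carries an m1A58-like site (stop + mutation)
    at 0-based position 57; Ser genes additionally carry m3C-like
    mutation-only sites at positions 31 (anticodon loop, 32 in canonical
    numbering) and 49 (variable arm, 47d).
    """
    mods: dict[str, dict[int, ModSite]] = {}
    for g in ref:
        site: dict[int, ModSite] = {}
        if g.length >= 64:
            site[57] = ModSite(p_stop=0.25, p_mis=0.25)
        if g.amino_acid == "Ser":
            site[31] = ModSite(p_mis=0.30)
            site[49] = ModSite(p_mis=0.35)
        mods[g.gene_id] = site
    return mods


# ---------------------------------------------------------------------------
# tRNA library simulation


@dataclass
class SimTruth:
    """Planted parameters keyed the way the pipeline outputs are keyed."""

    abundance: pd.DataFrame = field(default_factory=pd.DataFrame)
    charging: pd.DataFrame = field(default_factory=pd.DataFrame)
    modifications: pd.DataFrame = field(default_factory=pd.DataFrame)
    fragments: pd.DataFrame = field(default_factory=pd.DataFrame)
    psi_sites: pd.DataFrame = field(default_factory=pd.DataFrame)
    te: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("abundance", "charging", "modifications", "fragments",
                     "psi_sites", "te"):
            df = getattr(self, name)
            if len(df):
                df.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)


_FRAG_BOUNDS = ((1, 29), (30, 39), (40, 49), (50, 59))  # 1-based 3'-end windows
_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(s: str) -> str:
    return s.encode().translate(_COMP)[::-1].decode()


def _sam_header(ref: ReferenceSet) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": g.gene_id, "LN": g.length} for g in ref],
        }
    )


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    others = [b for b in _BASE_STR if b != base]
    return others[int(rng.integers(0, 3))]


def simulate_trna_sample(
    ref: ReferenceSet,
    cfg: SimConfig,
    rng: np.random.Generator,
    sample_id: str,
    abundance: Mapping[str, float] | None = None,
    charging: Mapping[str, float] | None = None,
    modifications: Mapping[str, Mapping[int, ModSite]] | None = None,
    n_reads: int | None = None,
) -> tuple[list[dict], pd.DataFrame]:
    """Draw one sample's reads; returns (read records, per-gene truth).

    Each record holds the aligned coordinates, CIGAR and sequence needed to
    emit both SAM and FASTQ. ``abundance`` defaults to a flat-Dirichlet
    draw; ``charging`` to the config's global fraction; ``modifications``
    to :func:`default_modifications`.
    """
    gene_ids = [g.gene_id for g in ref]
    if abundance is None:
        probs = rng.dirichlet(np.full(len(gene_ids), 3.0))
        abundance = dict(zip(gene_ids, probs))
    p = np.array([abundance[g] for g in gene_ids], dtype=float)
    p = p / p.sum()
    if charging is None:
        charging = {g: cfg.charging_fraction for g in gene_ids}
    if modifications is None:
        modifications = default_modifications(ref)
    total = n_reads if n_reads is not None else cfg.depth_per_gene * len(gene_ids)

    gene_draw = rng.choice(len(gene_ids), size=total, p=p)
    records: list[dict] = []
    bin_probs = np.asarray(cfg.fragment_bin_probs, dtype=float)
    bin_probs = bin_probs / bin_probs.sum()
    for ridx in range(total):
        gid = gene_ids[int(gene_draw[ridx])]
        gene = ref[gid]
        L = gene.length
        seq = gene.sequence
        mods = modifications.get(gid, {})
        is_fragment = rng.random() < cfg.fragment_rate
        charged = None
        if is_fragment:
            b = int(rng.choice(4, p=bin_probs))
            lo, hi = _FRAG_BOUNDS[b]
            hi = min(hi, L - 3)
            end0 = int(rng.integers(lo, hi + 1)) - 1
        else:
            charged = rng.random() < charging[gid]
            end0 = L - 1 if charged else L - 2
        limit = max(0, end0 - cfg.read_length + 1)
        start0 = limit
        muts: dict[int, str] = {}
        dels: set[int] = set()
        # first base (the 3' end) is always incorporated; then walk 5'-ward
        for pos in range(end0, limit - 1, -1):
            site = mods.get(pos)
            if site is None:
                continue
            if pos < end0 and rng.random() < site.p_stop:
                start0 = pos + 1
                break
            r = rng.random()
            if r < site.p_mis:
                muts[pos] = _mutate_base(rng, seq[pos])
            elif r < site.p_mis + site.p_del and start0 < pos < end0:
                dels.add(pos)
        # a later 5'-ward stop can land the read start on a recorded
        # deletion; deletions must stay strictly internal to the alignment
        dels = {d for d in dels if start0 < d < end0}
        read_chars = []
        for pos in range(start0, end0 + 1):
            if pos in dels:
                continue
            read_chars.append(muts.get(pos, seq[pos]))
        # uniform sequencing errors
        n_err = rng.binomial(len(read_chars), cfg.seq_error_rate)
        for _ in range(n_err):
            i = int(rng.integers(0, len(read_chars)))
            read_chars[i] = _mutate_base(rng, read_chars[i])
        read_seq = "".join(read_chars)
        cigar = _cigar_from_dels(start0, end0, dels)
        records.append(
            {
                "gene_id": gid,
                "start": start0,
                "end": end0,
                "cigar": cigar,
                "seq": read_seq,
                "charged": charged,
                "fragment": is_fragment,
            }
        )
    truth_rows = []
    for i, gid in enumerate(gene_ids):
        truth_rows.append(
            {
                "sample_id": sample_id,
                "gene_id": gid,
                "abundance": p[i],
                "charging_fraction": charging[gid],
                "n_reads": int((gene_draw == i).sum()),
            }
        )
    return records, pd.DataFrame(truth_rows)


def _cigar_from_dels(start0: int, end0: int, dels: set[int]) -> str:
    if not dels:
        return f"{end0 - start0 + 1}M"
    ops = []
    run_m = 0
    pos = start0
    while pos <= end0:
        if pos in dels:
            if run_m:
                ops.append(f"{run_m}M")
                run_m = 0
            run_d = 0
            while pos <= end0 and pos in dels:
                run_d += 1
                pos += 1
            ops.append(f"{run_d}D")
        else:
            run_m += 1
            pos += 1
    if run_m:
        ops.append(f"{run_m}M")
    return "".join(ops)


def write_sam(
    records: Sequence[dict],
    ref: ReferenceSet,
    path: str | Path,
    prefix: str = "sim",
) -> None:
    """Write simulated records as a truth-aligned SAM file."""
    header = _sam_header(ref)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, rec in enumerate(records):
            a = pysam.AlignedSegment(header)
            a.query_name = f"{prefix}:{i}"
            a.flag = 0
            a.reference_id = header.get_tid(rec["gene_id"])
            a.reference_start = rec["start"]
            a.mapping_quality = 42
            a.cigarstring = rec["cigar"]
            a.query_sequence = rec["seq"]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(rec["seq"]))
            out.write(a)


def write_fastq_pair(
    records_by_sample: Mapping[str, Sequence[dict]],
    cfg: SimConfig,
    rng: np.random.Generator,
    r1_path: str | Path,
    r2_path: str | Path,
    barcode_by_sample: Mapping[str, str] | None = None,
) -> None:
    """Emit pooled, barcoded, UMI-tagged FASTQ for the demultiplexer.

    Read 2 carries the sample barcode followed by the RNA-sense insert;
    read 1 carries a random 6-nt UMI followed by the reverse complement.
    """
    if barcode_by_sample is None:
        barcode_by_sample = dict(zip(records_by_sample, cfg.barcodes))
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        i = 0
        for sample_id, records in records_by_sample.items():
            bc = barcode_by_sample[sample_id]
            for rec in records:
                umi = "".join(
                    _BASE_STR[j] for j in rng.integers(0, 4, size=cfg.umi_length)
                )
                rid = f"sim:{i}"
                s2 = bc + rec["seq"]
                s1 = umi + _revcomp(rec["seq"])
                f1.write(f"@{rid}\n{s1}\n+\n{'I' * len(s1)}\n")
                f2.write(f"@{rid}\n{s2}\n+\n{'I' * len(s2)}\n")
                i += 1


def simulate_trna_library(
    ref: ReferenceSet,
    cfg: SimConfig,
    out_dir: str | Path,
    seed: int,
    samples: Mapping[str, dict] | None = None,
) -> SimTruth:
    """Generate a multi-sample tRNA library: per-sample SAM, pooled FASTQ,
    and planted-truth tables.

    ``samples`` maps sample_id -> overrides for
    :func:`simulate_trna_sample` (``abundance``, ``charging``,
    ``modifications``, ``n_reads``); by default one sample per configured
    barcode with shared defaults.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = {f"S{i + 1}": {} for i in range(len(cfg.barcodes))}
    truth = SimTruth()
    records_by_sample: dict[str, list[dict]] = {}
    truth_frames = []
    for sample_id, overrides in samples.items():
        records, tr = simulate_trna_sample(ref, cfg, rng, sample_id, **overrides)
        records_by_sample[sample_id] = records
        truth_frames.append(tr)
        write_sam(records, ref, out / f"{sample_id}.sam", prefix=f"sim:{sample_id}")
    truth.abundance = pd.concat(truth_frames, ignore_index=True)
    truth.charging = truth.abundance[
        ["sample_id", "gene_id", "charging_fraction"]
    ].copy()
    mods = default_modifications(ref)
    mod_rows = [
        {
            "gene_id": gid,
            "pos": pos + 1,
            "p_stop": site.p_stop,
            "p_mis": site.p_mis,
            "p_del": site.p_del,
        }
        for gid, sites in mods.items()
        for pos, site in sites.items()
    ]
    truth.modifications = pd.DataFrame(mod_rows)
    write_fastq_pair(
        records_by_sample, cfg, rng, out / "pooled_R1.fastq", out / "pooled_R2.fastq"
    )
    ref.to_fasta(out / "reference.fasta")
    truth.write(out / "truth")
    return truth


# ---------------------------------------------------------------------------
# +/-CMC simulation


def make_rrna_reference(cfg: SimConfig, rng: np.random.Generator) -> ReferenceSet:
    """Single rRNA-scale synthetic reference gene for +/-CMC simulation.

    The sequence is generated ending in CCA purely so it satisfies the
    shared reference-container invariant; nothing in the CMC analysis uses
    the tail.
    """
    arr = _random_seq(rng, cfg.rrna_length)
    arr[-3:] = np.frombuffer(b"CCA", dtype=np.uint8)
    seq = arr.tobytes().decode()
    g = TRNAGene(
        gene_id="rRNA-18S-synthetic",
        amino_acid="Und",
        anticodon=seq[33:36],
        sequence=seq,
        origin="nuclear",
        anticodon_offset=33,
    )
    ref = ReferenceSet(nonredundant=True)
    ref.genes[g.gene_id] = g
    return ref


def plant_psi_sites(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Plant n_psi pseudouridine sites with drawn penetrances.

    Stop penetrance in the +CMC condition is drawn from ``psi_stop_range``;
    the last site is planted sub-threshold (delta_stop =
    ``sub_threshold_delta``, below the default calling threshold) and given
    no mutation signal, mirroring a site that genuinely evades detection.
    """
    lo = 40
    hi = cfg.rrna_length - 40
    positions = np.sort(
        rng.choice(np.arange(lo, hi), size=cfg.n_psi, replace=False)
    )
    # enforce >= 5 nt separation so calls are unambiguous at +/-1 nt slack
    for _ in range(100):
        gaps = np.diff(positions)
        if (gaps >= 5).all():
            break
        positions = np.sort(
            rng.choice(np.arange(lo, hi), size=cfg.n_psi, replace=False)
        )
    p_stop_plus = rng.uniform(*cfg.psi_stop_range, size=cfg.n_psi)
    p_mut_plus = rng.uniform(*cfg.psi_mut_range, size=cfg.n_psi)
    p_stop_minus = np.full(cfg.n_psi, cfg.p_stop_minus)
    sub = cfg.n_psi - 1
    p_stop_plus[sub] = cfg.p_stop_minus + cfg.sub_threshold_delta
    p_mut_plus[sub] = 0.0
    return pd.DataFrame(
        {
            "position": positions,  # 0-based
            "p_stop_plus": p_stop_plus,
            "p_stop_minus": p_stop_minus,
            "p_mut_plus": p_mut_plus,
            "p_mut_minus": 0.0,
            "sub_threshold": [i == sub for i in range(cfg.n_psi)],
        }
    )


def _simulate_cmc_reads(
    seq: str,
    sites: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator,
    plus: bool,
) -> list[dict]:
    """Vectorized fragmented-RNA read draw with site-dependent RT stops."""
    L = len(seq)
    rl = cfg.read_length
    n_reads = int(round(cfg.cmc_depth * L / rl))
    end0 = rng.integers(30, L, size=n_reads)
    limit = np.maximum(0, end0 - rl + 1)
    start0 = limit.copy()
    stopped = np.zeros(n_reads, dtype=bool)
    pos_arr = sites["position"].to_numpy()
    p_stop = (sites["p_stop_plus"] if plus else sites["p_stop_minus"]).to_numpy()
    p_mut = (sites["p_mut_plus"] if plus else sites["p_mut_minus"]).to_numpy()
    order = np.argsort(pos_arr)[::-1]  # RT meets high positions first
    mut_at: dict[int, np.ndarray] = {}
    for k in order:
        s = int(pos_arr[k])
        reach = (~stopped) & (limit <= s) & (s < end0)
        if not reach.any():
            continue
        draw = rng.random(n_reads) < p_stop[k]
        stop_here = reach & draw
        start0[stop_here] = s + 1
        stopped |= stop_here
        covers = (~stop_here) & (limit <= s) & (s <= end0) & (start0 <= s)
        mdraw = rng.random(n_reads) < p_mut[k]
        mut_at[s] = covers & mdraw
    # background stops: each read may independently stop at a uniform
    # position (thin background for realistic noise floor)
    bg = rng.random(n_reads) < cfg.background_stop * rl
    bg_pos = rng.integers(0, rl, size=n_reads)
    cand = np.minimum(end0 - bg_pos, end0)
    apply_bg = bg & ~stopped & (cand > start0)
    start0[apply_bg] = cand[apply_bg]

    err = cfg.seq_error_rate
    records = []
    site_muts_by_read: dict[int, list[int]] = {}
    for s, mask in mut_at.items():
        for ridx in np.nonzero(mask)[0]:
            site_muts_by_read.setdefault(int(ridx), []).append(s)
    n_err_all = rng.binomial(np.maximum(end0 - start0 + 1, 1), err)
    for ridx in range(n_reads):
        s0, e0 = int(start0[ridx]), int(end0[ridx])
        chars = list(seq[s0 : e0 + 1])
        for s in site_muts_by_read.get(ridx, ()):
            if s0 <= s <= e0:
                chars[s - s0] = _mutate_base(rng, chars[s - s0])
        for _ in range(int(n_err_all[ridx])):
            i = int(rng.integers(0, len(chars)))
            chars[i] = _mutate_base(rng, chars[i])
        records.append(
            {
                "gene_id": "rRNA-18S-synthetic",
                "start": s0,
                "end": e0,
                "cigar": f"{e0 - s0 + 1}M",
                "seq": "".join(chars),
            }
        )
    return records


def simulate_cmc_pair(
    cfg: SimConfig,
    out_dir: str | Path,
    seed: int,
) -> tuple[ReferenceSet, SimTruth]:
    """Matched +CMC / -CMC libraries over a synthetic rRNA-scale gene.

    Writes ``plus.sam`` and ``minus.sam`` plus the planted-site truth
    table; the two conditions share every parameter except stop/mutation
    penetrance at the planted pseudouridine sites.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ref = make_rrna_reference(cfg, rng)
    sites = plant_psi_sites(cfg, rng)
    seq = ref["rRNA-18S-synthetic"].sequence
    plus_recs = _simulate_cmc_reads(seq, sites, cfg, rng, plus=True)
    minus_recs = _simulate_cmc_reads(seq, sites, cfg, rng, plus=False)
    write_sam(plus_recs, ref, out / "plus.sam", prefix="cmc+")
    write_sam(minus_recs, ref, out / "minus.sam", prefix="cmc-")
    truth = SimTruth()
    sites = sites.copy()
    sites.insert(0, "gene_id", "rRNA-18S-synthetic")
    truth.psi_sites = sites
    truth.write(out / "truth")
    ref.to_fasta(out / "reference.fasta")
    return ref, truth


# ---------------------------------------------------------------------------
# mRNA / TE simulation


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_mrna_te(
    cfg: SimConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]], SimTruth]:
    """Input/polysome count tables under a codon-driven TE model.

    Returns (transcript count table, transcript-to-gene map, CDS sequences
    by gene, truth). Genes' codon usage is drawn from a Dirichlet; in each
    condition log10(TE) = alpha + beta_cond * sigma * z(freq(target)) +
    N(0, sigma), with beta 0 in the control condition and ``cfg.te_beta``
    (in sigma units per SD of target-codon frequency) under stress. Counts
    are negative binomial around expression (input) and expression * TE
    (polysome). A handful of non-coding genes is included to exercise the
    protein-coding-only normalization rule.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_mrna_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    codon_p = rng.dirichlet(
        np.full(len(SENSE_CODONS), cfg.codon_dirichlet_alpha), size=n
    )
    n_codons = rng.integers(*cfg.cds_codon_range, size=n)
    cds_by_gene: dict[str, list[str]] = {}
    freq_target = np.empty(n)
    t_idx = SENSE_CODONS.index(cfg.target_codon)
    for i, gid in enumerate(gene_ids):
        draws = rng.choice(len(SENSE_CODONS), size=int(n_codons[i]), p=codon_p[i])
        codons = [SENSE_CODONS[j] for j in draws]
        cds_by_gene[gid] = ["".join(codons) + "TAA"]
        freq_target[i] = (draws == t_idx).sum() / len(draws)
    z_freq = (freq_target - freq_target.mean()) / freq_target.std(ddof=0)

    expression = rng.lognormal(mean=np.log(cfg.mean_count), sigma=0.5, size=n)
    conditions = {
        c: (0.0 if c == "control" else cfg.te_beta) for c in cfg.conditions
    }

    count_cols: dict[str, np.ndarray] = {}
    design_rows = []
    te_truth_rows = []
    for cond, beta in conditions.items():
        for rep in range(1, cfg.n_replicates + 1):
            log_te = (
                cfg.te_alpha
                + beta * cfg.te_sigma * z_freq
                + rng.normal(0.0, cfg.te_sigma, size=n)
            )
            te = 10.0 ** log_te
            sid_in = f"{cond}_r{rep}_input"
            sid_pol = f"{cond}_r{rep}_polysome"
            count_cols[sid_in] = _nb_draw(rng, expression, cfg.nb_dispersion)
            pol_mean = expression * te
            pol_mean *= expression.sum() / pol_mean.sum()  # library re-scaling
            count_cols[sid_pol] = _nb_draw(rng, pol_mean, cfg.nb_dispersion)
            design_rows += [
                {"sample_id": sid_in, "condition": cond, "fraction": "total",
                 "replicate": rep},
                {"sample_id": sid_pol, "condition": cond, "fraction": "polysome",
                 "replicate": rep},
            ]
            te_truth_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": gene_ids,
                        "condition": cond,
                        "replicate": rep,
                        "true_TE": te,
                        "beta": beta,
                        "freq_target": freq_target,
                    }
                )
            )

    tx_rows = {"transcript_id": [f"{g}.t1" for g in gene_ids]}
    tx_rows.update({k: v for k, v in count_cols.items()})
    counts = pd.DataFrame(tx_rows)
    tx2gene = pd.DataFrame(
        {
            "transcript_id": [f"{g}.t1" for g in gene_ids],
            "gene_id": gene_ids,
            "biotype": "protein_coding",
        }
    )
    # non-coding passengers: counted but excluded from normalization
    if cfg.n_noncoding > 0:
        nc_ids = [f"NC{i:04d}" for i in range(cfg.n_noncoding)]
        nc_expr = rng.lognormal(np.log(cfg.mean_count), 0.5, size=cfg.n_noncoding)
        nc_cols = {"transcript_id": [f"{g}.t1" for g in nc_ids]}
        for sid in count_cols:
            nc_cols[sid] = _nb_draw(rng, nc_expr, cfg.nb_dispersion)
        counts = pd.concat([counts, pd.DataFrame(nc_cols)], ignore_index=True)
        tx2gene = pd.concat(
            [
                tx2gene,
                pd.DataFrame(
                    {
                        "transcript_id": [f"{g}.t1" for g in nc_ids],
                        "gene_id": nc_ids,
                        "biotype": "lncRNA",
                    }
                ),
            ],
            ignore_index=True,
        )

    truth = SimTruth()
    truth.te = pd.concat(te_truth_rows, ignore_index=True)
    design = pd.DataFrame(design_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        counts.to_csv(out / "transcript_counts.tsv", sep="\t", index=False)
        tx2gene.to_csv(out / "tx2gene.tsv", sep="\t", index=False)
        design.to_csv(out / "design.tsv", sep="\t", index=False)
        with open(out / "cds.fasta", "w") as fh:
            for gid, seqs in cds_by_gene.items():
                for j, s in enumerate(seqs, 1):
                    fh.write(f">{gid}.t{j} gene={gid}\n{s}\n")
        truth.write(out / "truth")
    truth.te.attrs["design"] = design
    return counts, tx2gene, cds_by_gene, truth


def mrna_design(cfg: SimConfig) -> list:
    """SampleDesign list matching :func:`simulate_mrna_te`'s sample ids."""
    from .trna_metrics import SampleDesign

    out = []
    for cond in cfg.conditions:
        for rep in range(1, cfg.n_replicates + 1):
            out.append(SampleDesign(f"{cond}_r{rep}_input", cond, "total", rep))
            out.append(SampleDesign(f"{cond}_r{rep}_polysome", cond, "polysome", rep))
    return out
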