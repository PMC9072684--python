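"""tRNA-level derived statistics.

From per-sample pileups this module computes the quantities a multiplexed
tRNA-seq experiment reports:

* normalized abundance per isodecoder and isoacceptor (reads per million
  tRNA-mapped reads, so per-sample rows sum to 1e6);
* aminoacylation (charging) readout from 3'-end identity — reads ending on
  the terminal A of the genomically encoded CCA are charged, reads ending
  on ...CC lost the terminal A to periodate oxidation / beta-elimination
  and are uncharged;
* stress-response changes versus control replicates (ratio statistics as
  fold changes against the mean of controls; mutation fractions as plain
  differences);
* tRNA-fragment (tRF) binning by mapped 3'-end window, and per-bin
  modification fractions for fragment-vs-full-length comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .pileup_engine import (
    PileupMatrix,
    build_pileup,
    end_profile,
    mutation_fraction,
)
from .reference_model import ReferenceSet

#: 3'-end windows (1-based positions). Ends at 60+ are full-length tRNA;
#: 30-39 ~ anticodon loop, 40-49 ~ variable loop, 50-59 ~ T loop. Ends
#: below 30 keep their own bin so the bins always partition the reads.
FRAGMENT_BINS = ("<30", "30-39", "40-49", "50-59", "60+")


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing library in the experimental design."""

    sample_id: str
    condition: str  # e.g. control, heat, H2O2, AsO2
    fraction: str = "total"  # {"total", "polysome"}
    replicate: int = 1


def load_design(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t")
    out = [
        SampleDesign(
            sample_id=str(r.sample_id),
            condition=str(r.condition),
            fraction=str(getattr(r, "fraction", "total")),
            replicate=int(r.replicate),
        )
        for r in df.itertuples(index=False)
    ]
    keys = [(d.condition, d.fraction, d.replicate) for d in out]
    if len(set(keys)) != len(keys):
        raise MetricsError("duplicate (condition, fraction, replicate) in design")
    return out


def compute_abundance(
    pileups: Mapping[str, PileupMatrix],
    ref: ReferenceSet,
) -> pd.DataFrame:
    """Normalized abundance table at isodecoder and isoacceptor level.

    Isodecoder raw counts are the pileup's assigned reads; normalization is
    reads-per-million over all tRNA-mapped reads in the sample, so the
    isodecoder rows of one sample sum to 1e6 and an isoacceptor row is the
    exact sum of its member isodecoders (the summed normalized coverage of
    an anticodon family).
    """
    rows = []
    for sample_id, mat in pileups.items():
        total = mat.total_reads
        if total == 0:
            raise MetricsError(f"sample {sample_id} has zero tRNA-mapped reads")
        iso_rpm: dict[tuple[str, str], float] = {}
        iso_raw: dict[tuple[str, str], int] = {}
        for g in ref:
            raw = mat[g.gene_id].n_reads if g.gene_id in mat else 0
            rpm = 1e6 * raw / total
            rows.append(
                {
                    "sample_id": sample_id,
                    "level": "isodecoder",
                    "entity_id": g.gene_id,
                    "raw_reads": raw,
                    "normalized_abundance": rpm,
                }
            )
            key = g.isoacceptor
            iso_rpm[key] = iso_rpm.get(key, 0.0) + rpm
            iso_raw[key] = iso_raw.get(key, 0) + raw
        for (aa, ac), rpm in iso_rpm.items():
            rows.append(
                {
                    "sample_id": sample_id,
                    "level": "isoacceptor",
                    "entity_id": f"{aa}-{ac}",
                    "raw_reads": iso_raw[(aa, ac)],
                    "normalized_abundance": rpm,
                }
            )
    return pd.DataFrame(rows)


def compute_charging(
    pileups: Mapping[str, PileupMatrix],
    ref: ReferenceSet,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Charging table from 3'-end identity.

    Reads whose (clean) alignment ends on the gene's last position are
    CCA-ending (charged); ends on last-1 are CC-ending (uncharged); all
    other ends are excluded from the charging readout. Isoacceptor rows sum
    member counts before forming the ratio. charging_ratio = CCA/CC is the
    conventional report; charging_fraction = CCA/(CCA+CC) stays estimable
    when CC -> 0 and is what recovery tests use. Entities with
    CCA+CC < ``min_reads`` are masked (NaN) but kept in the table.
    """
    rows = []
    for sample_id, mat in pileups.items():
        iso: dict[tuple[str, str], list[int]] = {}
        for g in ref:
            gp = mat[g.gene_id]
            L = g.length
            n_cca = int(gp.read_end_clean[L - 1])
            n_cc = int(gp.read_end_clean[L - 2]) if L >= 2 else 0
            rows.append(_charging_row(sample_id, "isodecoder", g.gene_id, n_cca, n_cc, min_reads))
            acc = iso.setdefault(g.isoacceptor, [0, 0])
            acc[0] += n_cca
            acc[1] += n_cc
        for (aa, ac), (n_cca, n_cc) in iso.items():
            rows.append(
                _charging_row(sample_id, "isoacceptor", f"{aa}-{ac}", n_cca, n_cc, min_reads)
            )
    return pd.DataFrame(rows)


def _charging_row(sample_id, level, entity_id, n_cca, n_cc, min_reads):
    masked = (n_cca + n_cc) < min_reads
    ratio = np.nan if (masked or n_cc == 0) else n_cca / n_cc
    frac = np.nan if masked else n_cca / (n_cca + n_cc)
    return {
        "sample_id": sample_id,
        "level": level,
        "entity_id": entity_id,
        "n_CCA": n_cca,
        "n_CC": n_cc,
        "charging_ratio": ratio,
        "charging_fraction": frac,
        "masked": masked,
    }


def compute_change(
    table: pd.DataFrame,
    design: Iterable[SampleDesign],
    statistic: str,
    value_col: str | None = None,
    control_condition: str = "control",
    ratio_of_means: bool = False,
) -> pd.DataFrame:
    """Per-entity change of a statistic in stress versus control replicates.

    For ratio statistics (``abundance``, ``charging_ratio``) each stress
    replicate's value is divided by the mean of the control replicates and
    the per-replicate fold changes are averaged; reported as raw fold and
    log2. For ``mutation_fraction`` the change is the plain difference
    value - mean(control replicates), never a ratio. ``ratio_of_means``
    switches to mean(stress)/mean(control) for ratio statistics.

    ``table`` must carry ``sample_id``, ``entity_id`` and the value column
    (default: statistic name mapped to its conventional column).
    """
    default_cols = {
        "abundance": "normalized_abundance",
        "charging_ratio": "charging_ratio",
        "charging_fraction": "charging_fraction",
        "mutation_fraction": "mutation_fraction",
    }
    if statistic not in default_cols:
        raise MetricsError(f"unknown statistic {statistic!r}")
    col = value_col or default_cols[statistic]
    is_difference = statistic == "mutation_fraction"

    by_sample = {d.sample_id: d for d in design}
    df = table[table["sample_id"].isin(by_sample)].copy()
    df["condition"] = df["sample_id"].map(lambda s: by_sample[s].condition)
    df["fraction"] = df["sample_id"].map(lambda s: by_sample[s].fraction)

    rows = []
    for (fraction, entity), sub in df.groupby(["fraction", "entity_id"], sort=False):
        ctrl = sub.loc[sub["condition"] == control_condition, col].dropna()
        if ctrl.empty:
            continue
        ctrl_mean = ctrl.mean()
        for condition, csub in sub.groupby("condition", sort=False):
            if condition == control_condition:
                continue
            vals = csub[col].dropna()
            if vals.empty:
                continue
            if is_difference:
                change = float((vals - ctrl_mean).mean())
                rows.append(
                    {
                        "fraction": fraction,
                        "entity_id": entity,
                        "condition": condition,
                        "statistic": statistic,
                        "change": change,
                        "n_stress": len(vals),
                        "n_control": len(ctrl),
                        "masked": False,
                        "reason": "",
                    }
                )
            else:
                if ctrl_mean == 0:
                    rows.append(
                        {
                            "fraction": fraction,
                            "entity_id": entity,
                            "condition": condition,
                            "statistic": statistic,
                            "change": np.nan,
                            "n_stress": len(vals),
                            "n_control": len(ctrl),
                            "masked": True,
                            "reason": "control mean is zero",
                        }
                    )
                    continue
                if ratio_of_means:
                    fold = float(vals.mean() / ctrl_mean)
                else:
                    fold = float((vals / ctrl_mean).mean())
                rows.append(
                    {
                        "fraction": fraction,
                        "entity_id": entity,
                        "condition": condition,
                        "statistic": statistic,
                        "change": fold,
                        "log2_change": float(np.log2(fold)) if fold > 0 else np.nan,
                        "n_stress": len(vals),
                        "n_control": len(ctrl),
                        "masked": False,
                        "reason": "",
                    }
                )
    return pd.DataFrame(rows)


def assign_bin(end_pos1: int) -> str:
    """Fragment bin for a 1-based 3'-end position."""
    if end_pos1 < 30:
        return "<30"
    if end_pos1 < 40:
        return "30-39"
    if end_pos1 < 50:
        return "40-49"
    if end_pos1 < 60:
        return "50-59"
    return "60+"


def bin_fragments(
    end_profiles: Mapping[str, Mapping[str, Mapping[int, int]]],
    ref: ReferenceSet,
) -> pd.DataFrame:
    """Bin reads by 3'-end window into the tRF classification.

    ``end_profiles`` maps sample_id -> gene_id -> {0-based end: count}.
    Each read falls in exactly one bin; the per-sample tRF ratio is
    sum(bins below 60) / sum(60+ bin).
    """
    rows = []
    for sample_id, genes in end_profiles.items():
        for gene_id, prof in genes.items():
            counts = {b: 0 for b in FRAGMENT_BINS}
            for end0, n in prof.items():
                counts[assign_bin(end0 + 1)] += n
            for b in FRAGMENT_BINS:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "gene_id": gene_id,
                        "bin": b,
                        "read_count": counts[b],
                    }
                )
    return pd.DataFrame(rows)


def trf_ratio(bin_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample ratio of fragment reads (<60 bins) to full-length (60+)."""
    rows = []
    for sample_id, sub in bin_table.groupby("sample_id", sort=False):
        frag = int(sub.loc[sub["bin"] != "60+", "read_count"].sum())
        full = int(sub.loc[sub["bin"] == "60+", "read_count"].sum())
        rows.append(
            {
                "sample_id": sample_id,
                "fragment_reads": frag,
                "full_length_reads": full,
                "tRF_ratio": frag / full if full > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def end_profiles_from_pileups(
    pileups: Mapping[str, PileupMatrix],
) -> dict[str, dict[str, dict[int, int]]]:
    """Collect per-sample, per-gene clean 3'-end histograms."""
    return {
        sample_id: {g.gene_id: end_profile(mat, g.gene_id) for g in mat}
        for sample_id, mat in pileups.items()
    }


def binned_pileups(
    alignments,
    ref: ReferenceSet,
) -> dict[str, PileupMatrix]:
    """Build one pileup per fragment bin from a SAM/BAM path or handle.

    Each alignment is routed by its 1-based 3'-end position into the
    fragment bins, yielding per-bin pileups for fragment-vs-full-length
    modification comparison. Requires a path (the stream is read once per
    bin).
    """
    from .pileup_engine import MAX_END_SOFTCLIP

    def clean_end(aln) -> bool:
        ct = aln.cigartuples
        return not (ct and ct[-1][0] == 4 and ct[-1][1] > MAX_END_SOFTCLIP)

    out = {}
    for b in FRAGMENT_BINS:
        out[b] = build_pileup(
            alignments,
            ref,
            read_filter=lambda aln, b=b: clean_end(aln)
            and assign_bin(aln.reference_end) == b,
        )
    return out


def fragment_mod_compare(
    bin_pileups: Mapping[str, PileupMatrix],
    gene: str,
    position: int,
    min_coverage: int = 20,
) -> pd.DataFrame:
    """Mutation fraction at one position, separately per fragment bin.

    Returns a row per bin with the bin's mutation fraction (NaN when the
    bin's reads do not reach ``min_coverage`` at the position) and the
    full-length ("60+") value repeated for pairing.
    """
    vals = {
        b: mutation_fraction(mat, gene, position, min_coverage)
        for b, mat in bin_pileups.items()
    }
    full = vals.get("60+", np.nan)
    rows = [
        {
            "gene_id": gene,
            "position": position + 1,
            "bin": b,
            "mutation_fraction": v,
            "full_length_mutation_fraction": full,
            "masked": bool(np.isnan(v)),
        }
        for b, v in vals.items()
    ]
    return pd.DataFrame(rows)
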