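"""Translational efficiency and codon-usage association analysis.

Translational efficiency (TE) of a gene is its normalized polysome-fraction
count divided by its normalized input (total) count; log10 TE is roughly
normal, so each library is summarized by within-sample Z-scores and
stress responses by deltaZ = Z - mean(control-replicate Z). Codon-usage
coupling to translation is tested non-parametrically: genes are split into
tertiles of the grouping variable (TE level or deltaZ) at the 33rd/66th
percentiles and, per codon, the codon-frequency distributions of the top
and bottom tertiles are compared by a two-sided rank-sum test. Percentile
ranks of frequency are a monotone transform of frequency itself, so the
rank-sum statistic computed on raw frequencies is identical.

The wobble analysis groups tRNA isodecoder abundance changes by the
gene-encoded anticodon position-34 base (T34 tRNAs read A-ending codons,
C34 only G-ending ones) and compares groups with the same rank-sum test.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference_model import ReferenceSet
from .trna_metrics import SampleDesign

logger = logging.getLogger(__name__)

_STOP_CODONS = {"TAA", "TAG", "TGA"}
#: the 61 sense codons of the standard genetic code
SENSE_CODONS = tuple(
    c
    for c in ("".join(t) for t in itertools.product("TCAG", repeat=3))
    if c not in _STOP_CODONS
)


class TranslationError(ValueError):
    pass


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration (via the Mann-Whitney exact distribution) when both
    groups have <= 8 observations and no ties; otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise TranslationError("empty group in rank-sum test")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


# ---------------------------------------------------------------------------
# counts -> TE

def aggregate_and_normalize(
    counts: pd.DataFrame,
    tx2gene: pd.DataFrame,
) -> pd.DataFrame:
    """Sum transcript counts per gene and normalize to RPM over coding genes.

    ``counts`` columns: transcript_id + one column per sample (raw counts).
    ``tx2gene`` columns: transcript_id, gene_id, biotype. Counts of all
    transcript variants of a gene are summed; normalization is reads per
    million over protein-coding genes only, so non-coding genes are carried
    through but never inflate the denominator. Returns a long table
    (gene_id, biotype, sample_id, raw, rpm).
    """
    tmap = tx2gene.set_index("transcript_id")
    merged = counts.join(tmap, on="transcript_id", how="inner")
    sample_cols = [c for c in counts.columns if c != "transcript_id"]
    gene = merged.groupby(["gene_id", "biotype"], sort=False)[sample_cols].sum()
    long = (
        gene.reset_index()
        .melt(id_vars=["gene_id", "biotype"], var_name="sample_id", value_name="raw")
    )
    coding = long[long["biotype"] == "protein_coding"]
    denom = coding.groupby("sample_id")["raw"].sum()
    if (denom == 0).any():
        bad = denom.index[denom == 0].tolist()
        raise TranslationError(f"zero protein-coding counts in samples: {bad}")
    long["rpm"] = 1e6 * long["raw"] / long["sample_id"].map(denom)
    return long


def compute_te(
    gene_counts: pd.DataFrame,
    design: Iterable[SampleDesign],
    min_norm_count: float = 100.0,
    control_condition: str = "control",
) -> tuple[pd.DataFrame, set[str]]:
    """TE, Z(log10 TE) and deltaZ per gene and (condition, replicate).

    Only protein-coding genes whose RPM strictly exceeds ``min_norm_count``
    in both the input and polysome library of a (condition, replicate) get
    a TE there. Z-scores are computed within each sample over its defined
    TE values; deltaZ is Z minus the gene's mean Z across control
    replicates. The second return value is the well-detected gene set:
    genes with TE defined in every condition for at least one replicate.
    """
    designs = list(design)
    by_key: dict[tuple[str, int], dict[str, str]] = {}
    for d in designs:
        by_key.setdefault((d.condition, d.replicate), {})[d.fraction] = d.sample_id
    conditions = sorted({d.condition for d in designs})

    coding = gene_counts[gene_counts["biotype"] == "protein_coding"]
    rpm = coding.pivot_table(index="gene_id", columns="sample_id", values="rpm")

    rows = []
    for (condition, replicate), fr in sorted(by_key.items()):
        if "total" not in fr or "polysome" not in fr:
            raise TranslationError(
                f"missing matched fraction for ({condition}, replicate {replicate})"
            )
        inp, pol = rpm[fr["total"]], rpm[fr["polysome"]]
        ok = (inp > min_norm_count) & (pol > min_norm_count)
        te = pol[ok] / inp[ok]
        log_te = np.log10(te)
        sd = log_te.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise TranslationError(
                f"degenerate TE distribution (zero variance) in "
                f"({condition}, replicate {replicate})"
            )
        z = (log_te - log_te.mean()) / sd
        sub = pd.DataFrame(
            {
                "gene_id": te.index,
                "condition": condition,
                "replicate": replicate,
                "TE": te.to_numpy(),
                "log10_TE": log_te.to_numpy(),
                "Z": z.to_numpy(),
            }
        )
        rows.append(sub)
    te_table = pd.concat(rows, ignore_index=True)

    ctrl = te_table[te_table["condition"] == control_condition]
    ctrl_mean = ctrl.groupby("gene_id")["Z"].mean()
    te_table["deltaZ"] = te_table["Z"] - te_table["gene_id"].map(ctrl_mean)

    per_rep = te_table.groupby(["gene_id", "replicate"])["condition"].nunique()
    well = set(per_rep[per_rep == len(conditions)].reset_index()["gene_id"])
    return te_table, well


# ---------------------------------------------------------------------------
# codon profiles

def codon_frequency(
    cds_by_gene: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-gene codon frequencies: occurrences / protein length.

    Each transcript CDS is tallied over its sense codons after removing a
    terminal stop; protein length is that sense-codon count. Genes with
    several transcripts get the per-codon median across transcripts.
    Transcripts with an internal stop or length not divisible by 3 are
    excluded with a warning; a gene with no clean transcript is dropped.
    Returns a DataFrame indexed by gene_id with the 61 sense-codon columns
    plus ``protein_length`` (median over transcripts).
    """
    records = {}
    lengths = {}
    for gene_id, transcripts in cds_by_gene.items():
        per_tx = []
        tx_len = []
        for seq in transcripts:
            seq = seq.upper().replace("U", "T")
            if len(seq) % 3 != 0:
                warnings.warn(f"{gene_id}: CDS length not divisible by 3; excluded")
                continue
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            if codons and codons[-1] in _STOP_CODONS:
                codons = codons[:-1]
            if any(c in _STOP_CODONS for c in codons):
                warnings.warn(f"{gene_id}: internal stop codon; transcript excluded")
                continue
            if not codons:
                continue
            n = len(codons)
            counts = pd.Series(codons).value_counts()
            freq = np.array([counts.get(c, 0) / n for c in SENSE_CODONS])
            per_tx.append(freq)
            tx_len.append(n)
        if per_tx:
            records[gene_id] = np.median(np.vstack(per_tx), axis=0)
            lengths[gene_id] = float(np.median(tx_len))
    if not records:
        raise TranslationError("no gene with a clean CDS")
    df = pd.DataFrame.from_dict(records, orient="index", columns=list(SENSE_CODONS))
    df.index.name = "gene_id"
    df["protein_length"] = pd.Series(lengths)
    return df


# ---------------------------------------------------------------------------
# association tests

def tertile_split(values: pd.Series) -> tuple[pd.Index, pd.Index, pd.Index]:
    """Bottom / middle / top gene sets by percentile rank.

    The split is by rank with equal tail sizes (n // 3 genes in the bottom
    and top groups), i.e. the 33rd/66th percentile-rank cut applied
    symmetrically, which makes the grouping exactly antisymmetric under
    negation of the variable.
    """
    v = values.dropna()
    order = v.sort_values(kind="mergesort").index
    k = len(v) // 3
    bottom = order[:k]
    top = order[len(v) - k:]
    middle = order[k : len(v) - k]
    return bottom, middle, top


def codon_te_association(
    grouping_values: pd.Series,
    codon_profile: pd.DataFrame,
    alpha: float = 0.05,
    condition: str = "",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-codon rank-sum comparison of top vs bottom grouping tertiles.

    ``grouping_values`` is a per-gene Series of the grouping variable (a
    sample's log10 TE, Z, or deltaZ). For every sense codon, genes in the
    top and bottom tertiles are compared on codon frequency by a two-sided
    rank-sum test; direction is the sign of the median difference
    (top minus bottom), "ns" when p >= alpha. ``bh_correct`` applies
    Benjamini-Hochberg across the 61 codons (off by default; the
    conventional report uses raw p < 0.05).
    """
    common = grouping_values.dropna().index.intersection(codon_profile.index)
    if len(common) < 30:
        raise TranslationError(f"only {len(common)} genes with TE and codon data")
    vals = grouping_values.loc[common]
    bottom, _, top = tertile_split(vals)
    if min(len(bottom), len(top)) < 5:
        raise TranslationError("fewer than 5 genes in a tertile")
    top_mat = codon_profile.loc[top, list(SENSE_CODONS)].to_numpy()
    bot_mat = codon_profile.loc[bottom, list(SENSE_CODONS)].to_numpy()
    rows = []
    for j, codon in enumerate(SENSE_CODONS):
        f_top, f_bot = top_mat[:, j], bot_mat[:, j]
        p = rank_sum_test(f_top, f_bot)
        med_diff = float(np.median(f_top) - np.median(f_bot))
        rows.append(
            {"codon": codon, "condition": condition, "p": p, "median_diff": med_diff}
        )
    out = pd.DataFrame(rows)
    pcol = out["p"].to_numpy()
    if bh_correct:
        order = np.argsort(pcol)
        m = len(pcol)
        adj = np.empty(m)
        prev = 1.0
        for rank_i in range(m - 1, -1, -1):
            i = order[rank_i]
            prev = min(prev, pcol[i] * m / (rank_i + 1))
            adj[i] = prev
        out["p_adj"] = adj
        sig = out["p_adj"] < alpha
    else:
        sig = out["p"] < alpha
    out["direction"] = np.where(
        ~sig, "ns", np.where(out["median_diff"] > 0, "up", "down")
    )
    return out


def association_by_condition(
    te_table: pd.DataFrame,
    codon_profile: pd.DataFrame,
    grouping: str = "deltaZ",
    alpha: float = 0.05,
    control_condition: str = "control",
    genes: Iterable[str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Association matrix across stress conditions.

    For each non-control condition the grouping variable is the per-gene
    mean of ``grouping`` ("deltaZ" for stress response, "log10_TE" or "Z"
    for absolute TE level) across that condition's replicates.
    """
    if grouping not in ("deltaZ", "Z", "log10_TE", "TE"):
        raise TranslationError(f"unknown grouping {grouping!r}")
    frames = []
    sub = te_table
    if genes is not None:
        genes = set(genes)
        sub = te_table[te_table["gene_id"].isin(genes)]
    for condition, csub in sub.groupby("condition", sort=False):
        if grouping == "deltaZ" and condition == control_condition:
            continue
        vals = csub.groupby("gene_id")[grouping].mean()
        frames.append(
            codon_te_association(
                vals, codon_profile, alpha=alpha, condition=str(condition),
                bh_correct=bh_correct,
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# wobble analysis

def wobble_analysis(
    change_table: pd.DataFrame,
    ref: ReferenceSet,
    value_col: str = "log2_change",
) -> dict:
    """Wobble-base grouping of per-isodecoder abundance changes.

    Isodecoders are grouped by the gene-encoded base at anticodon position
    34 (the change table's ``entity_id`` must be gene ids); each pair of
    wobble groups is compared by a two-sided rank-sum test. Additionally,
    for every amino acid with both T34 and C34 isoacceptors, the ratio of
    mean T34 fold change to mean C34 fold change is reported.
    """
    wob = {g.gene_id: g.wobble for g in ref}
    aa = {g.gene_id: g.amino_acid for g in ref}
    df = change_table[change_table["entity_id"].isin(wob)].copy()
    if df.empty:
        raise TranslationError("no isodecoder rows matching the reference")
    df["wobble"] = df["entity_id"].map(wob)
    df["amino_acid"] = df["entity_id"].map(aa)
    df = df.dropna(subset=[value_col])

    groups = {w: s[value_col].to_numpy() for w, s in df.groupby("wobble")}
    pair_rows = []
    for (w1, v1), (w2, v2) in itertools.combinations(sorted(groups.items()), 2):
        if len(v1) == 0 or len(v2) == 0:
            continue
        p = rank_sum_test(v1, v2)
        pair_rows.append(
            {
                "group1": w1,
                "group2": w2,
                "n1": len(v1),
                "n2": len(v2),
                "p": p,
                "median_diff": float(np.median(v1) - np.median(v2)),
            }
        )

    # per-amino-acid T34/C34 fold-ratio panel (fold changes, not log2)
    fold_col = "change" if "change" in df.columns else value_col
    ratio_rows = []
    for amino, s in df.groupby("amino_acid"):
        t34 = s.loc[s["wobble"] == "T", fold_col]
        c34 = s.loc[s["wobble"] == "C", fold_col]
        if t34.empty or c34.empty:
            continue  # amino acid lacks one wobble class
        ratio_rows.append(
            {
                "amino_acid": amino,
                "t34_mean_fold": float(t34.mean()),
                "c34_mean_fold": float(c34.mean()),
                "ratio_change": float(t34.mean() / c34.mean()),
            }
        )
    return {
        "pairwise": pd.DataFrame(pair_rows),
        "t34_vs_c34": pd.DataFrame(ratio_rows),
        "group_sizes": {w: len(v) for w, v in groups.items()},
    }
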