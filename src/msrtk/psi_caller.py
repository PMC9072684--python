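"""Paired +/-CMC pseudouridine (Psi) mapping.

CMC (N-cyclohexyl-N'-(2-morpholinoethyl)carbodiimide) forms an adduct at
pseudouridine that blocks reverse transcription, so a Psi site shows a
stop-fraction (and often a mutation-fraction) excess in the CMC-treated
sample over the mock-treated one. This module computes the per-position
deltas between matched +CMC and -CMC pileups, calls sites where a delta
crosses its threshold, and scores calls against a known-site list.

Thresholds default to 0.10 on both deltas with a minimum coverage of 50 on
both sides; the CMC adduct can stall the RT one nucleotide off the exact
Psi register depending on the enzyme, so calling and evaluation allow a
+/-1 nt window by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pileup_engine import (
    PileupMatrix,
    mutation_fraction_profile,
    stop_fraction_profile,
)


class PsiError(ValueError):
    pass


@dataclass
class CmcPair:
    """Matched +CMC / -CMC pileups with per-position deltas.

    ``delta_stop``/``delta_mut`` map gene_id to arrays (NaN where either
    side fails min_coverage). Deltas are (+CMC) minus (-CMC), in [-1, 1].
    """

    plus: PileupMatrix
    minus: PileupMatrix
    min_coverage: int = 50
    delta_stop: dict[str, np.ndarray] = field(default_factory=dict)
    delta_mut: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class PsiCall:
    gene_id: str
    position: int  # 0-based
    delta_stop: float
    delta_mut: float
    evidence: str  # {"stop", "mutation", "both"}


def cmc_delta(
    plus: PileupMatrix,
    minus: PileupMatrix,
    min_coverage: int = 50,
) -> CmcPair:
    """Per-position stop/mutation deltas between +CMC and -CMC pileups.

    Both pileups must cover the same reference genes and sequences. Deltas
    are defined only where both conditions reach ``min_coverage`` (coverage
    for the mutation delta; the stop denominator for the stop delta).
    """
    plus_ids = set(plus.genes)
    if plus_ids != set(minus.genes):
        raise PsiError("mismatched references between +CMC and -CMC pileups")
    pair = CmcPair(plus=plus, minus=minus, min_coverage=min_coverage)
    for gid in plus.genes:
        if plus[gid].sequence != minus[gid].sequence:
            raise PsiError(f"reference sequence mismatch for {gid}")
        sp = stop_fraction_profile(plus, gid, min_coverage)
        sm = stop_fraction_profile(minus, gid, min_coverage)
        mp = mutation_fraction_profile(plus, gid, min_coverage)
        mm = mutation_fraction_profile(minus, gid, min_coverage)
        pair.delta_stop[gid] = sp - sm
        pair.delta_mut[gid] = mp - mm
    return pair


def _threshold_peaks(delta: np.ndarray, tau: float, window: int) -> list[int]:
    """Positions crossing tau, reduced to local maxima within ``window``.

    One modified site produces threshold crossings at its own register and
    possibly the adjacent one; non-maximum suppression keeps a single call
    per contiguous signal so each site is reported once.
    """
    vals = np.where(np.isnan(delta), -np.inf, delta)
    above = np.nonzero(vals >= tau)[0]
    peaks = []
    for i in above:
        lo, hi = max(0, i - window), min(len(vals), i + window + 1)
        neighborhood = vals[lo:hi]
        if vals[i] == neighborhood.max():
            # tie-break toward the leftmost position of a flat maximum
            if i == lo + int(np.argmax(neighborhood)):
                peaks.append(int(i))
    return peaks


def call_sites(
    pair: CmcPair,
    tau_stop: float = 0.10,
    tau_mut: float = 0.10,
    offset_window: int = 1,
) -> list[PsiCall]:
    """Threshold the deltas into Psi site calls.

    A site is called where delta_stop crosses ``tau_stop`` (within
    ``offset_window`` nt of the expected stop register) or delta_mut
    crosses ``tau_mut``; each site is reported once with its maximal
    evidence ("both" when stop and mutation calls coincide within the
    window). Raising either threshold can only remove calls.
    """
    if not 0 < tau_stop <= 1 or not 0 < tau_mut <= 1:
        raise PsiError("thresholds must lie in (0, 1]")
    calls: list[PsiCall] = []
    for gid in pair.plus.genes:
        ds, dm = pair.delta_stop[gid], pair.delta_mut[gid]
        stop_peaks = set(_threshold_peaks(ds, tau_stop, offset_window))
        mut_peaks = set(_threshold_peaks(dm, tau_mut, offset_window))
        merged: dict[int, str] = {}
        for p in stop_peaks:
            near_mut = any(abs(p - q) <= offset_window for q in mut_peaks)
            merged[p] = "both" if near_mut else "stop"
        for q in mut_peaks:
            if any(abs(p - q) <= offset_window for p in stop_peaks):
                continue  # already represented by the stop call
            merged[q] = "mutation"
        for pos in sorted(merged):
            calls.append(
                PsiCall(
                    gene_id=gid,
                    position=pos,
                    delta_stop=float(ds[pos]) if not np.isnan(ds[pos]) else np.nan,
                    delta_mut=float(dm[pos]) if not np.isnan(dm[pos]) else np.nan,
                    evidence=merged[pos],
                )
            )
    return calls


def evaluate_calls(
    calls: Sequence[PsiCall],
    known_sites: Iterable[tuple[str, int]] | Iterable[int],
    tolerance: int = 1,
    gene_id: str | None = None,
    exclude: Iterable[tuple[str, int]] | None = None,
) -> dict:
    """Score calls against known Psi positions.

    ``known_sites`` holds (gene_id, 0-based position) pairs, or bare
    positions when ``gene_id`` is given. A known site counts as detected
    when a call lies within ``tolerance`` nt of it; sensitivity is
    detected/known and precision is matched calls/total calls. Sites in
    ``exclude`` (e.g. CMC-independent signals such as m1acp3-Psi or
    m6,2A) are removed from the call list before scoring.
    """
    known = []
    for s in known_sites:
        if isinstance(s, tuple):
            known.append((s[0], int(s[1])))
        else:
            if gene_id is None:
                raise PsiError("bare positions require gene_id")
            known.append((gene_id, int(s)))
    if not known:
        raise PsiError("empty known-site list")
    excl = {(g, int(p)) for g, p in (exclude or [])}
    scored_calls = [
        c
        for c in calls
        if not any(
            c.gene_id == g and abs(c.position - p) <= tolerance for g, p in excl
        )
    ]
    hit_rows = []
    detected = 0
    matched_calls: set[tuple[str, int]] = set()
    for g, p in known:
        hits = [
            c
            for c in scored_calls
            if c.gene_id == g and abs(c.position - p) <= tolerance
        ]
        if hits:
            detected += 1
            for c in hits:
                matched_calls.add((c.gene_id, c.position))
        hit_rows.append(
            {
                "gene_id": g,
                "position": p + 1,
                "detected": bool(hits),
                "n_calls": len(hits),
                "best_delta_stop": max((c.delta_stop for c in hits), default=np.nan),
            }
        )
    n_calls = len(scored_calls)
    precision = (
        len([c for c in scored_calls if (c.gene_id, c.position) in matched_calls])
        / n_calls
        if n_calls
        else np.nan
    )
    return {
        "sensitivity": detected / len(known),
        "precision": precision,
        "n_known": len(known),
        "n_detected": detected,
        "n_calls": n_calls,
        "hits": pd.DataFrame(hit_rows),
    }


def calls_to_frame(calls: Sequence[PsiCall]) -> pd.DataFrame:
    """Calls as a table with 1-based positions for reporting."""
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "position": c.position + 1,
                "delta_stop": c.delta_stop,
                "delta_mut": c.delta_mut,
                "evidence": c.evidence,
            }
            for c in calls
        ]
    )
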