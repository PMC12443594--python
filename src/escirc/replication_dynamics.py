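"""Replication/persistence inference for excised circles.

Implements the doubling and exponential-dilution arithmetic, the recent-event
filter, observed/predicted ratios, clonotype extraction from merged amplicon
reads, and major-event (knee) detection on sorted read distributions.

Divisions may be fractional; no rounding is applied anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Doubling / dilution arithmetic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DivisionEstimate:
    """N2 = N1 * 2**n solved for n."""

    N2: float
    N1: float = 1.0
    n: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.N1 <= 0 or self.N2 <= 0:
            raise ValueError("cell counts must be positive")
        object.__setattr__(self, "n", math.log2(self.N2 / self.N1))


def estimate_divisions(N2: float, N1: float = 1.0) -> DivisionEstimate:
    """Cell population doublings n = log2(N2 / N1)."""
    return DivisionEstimate(N2=N2, N1=N1)


@dataclass(frozen=True)
class DilutionPrediction:
    """x_t = x0 / 2**t: SJ level remaining after t divisions without replication."""

    x0: float
    t: float
    xt: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("t must be non-negative")
        object.__setattr__(self, "xt", self.x0 / 2.0**self.t)


def predicted_sj(x0: float, t: float) -> DilutionPrediction:
    """Predicted SJ level under pure twofold dilution per division."""
    return DilutionPrediction(x0=x0, t=t)


def conservative_predicted_sum(
    clonotype_divisions: Sequence[float], x0: float = 1.0
) -> float:
    """Sum of predicted SJ values over all distinguishable clonotypes.

    The measured SJ could correspond to any of the clonotypes, so the
    conservative denominator adds every clonotype's predicted level.
    """
    return sum(predicted_sj(x0, t).xt for t in clonotype_divisions)


def observed_over_predicted(observed_sj: float, predicted: float) -> float:
    """Ratio ~1 under pure dilution; >1 indicates replication/persistence."""
    if predicted <= 0:
        raise ValueError("predicted SJ level must be positive")
    return observed_sj / predicted


# ---------------------------------------------------------------------------
# Recent-event filter and ratio tables
# ---------------------------------------------------------------------------


def select_recent_events(rec_table: pd.DataFrame, cutoff: float = 0.2) -> pd.DataFrame:
    """Junctions at <= ``cutoff`` normalized recombination reads (inclusive)."""
    return rec_table[rec_table["normalized_reads"] <= cutoff].copy()


def replication_ratio_table(
    summary: pd.DataFrame,
    max_divisions: Optional[float] = None,
) -> pd.DataFrame:
    """Observed/predicted SJ ratios per junction from copy-number truth.

    ``summary`` needs ``rec_copies`` and ``sj_copies`` columns (one row per
    junction; one recombination copy equates to one carrier cell).  Divisions
    since each event are estimated from the recombination copy number
    (N1 = 1); the predicted total SJ level in the sample is then
    ``rec_copies * x0 / 2**t``.  With ``max_divisions`` set, junctions whose
    estimate exceeds it are dropped (the <=6-relative-divisions rule).
    """
    df = summary[summary["rec_copies"] > 0].copy()
    df["t_est"] = np.log2(df["rec_copies"].astype(float))
    if max_divisions is not None:
        df = df[df["t_est"] <= max_divisions].copy()
    predicted = df["rec_copies"].astype(float) * (1.0 / 2.0 ** df["t_est"])
    df["predicted_sj"] = predicted
    df["observed_sj"] = df["sj_copies"].astype(float)
    df["ratio"] = df["observed_sj"] / df["predicted_sj"]
    return df


# ---------------------------------------------------------------------------
# Major-event (knee) detection
# ---------------------------------------------------------------------------


@dataclass
class MajorEventPartition:
    junction_ids: list[str]  # sorted by descending normalized reads
    values: list[float]
    knee_index: int
    labels: list[str]  # "major" | "other", aligned with junction_ids

    def majors(self) -> list[str]:
        return [j for j, l in zip(self.junction_ids, self.labels) if l == "major"]


def detect_major_events(
    rec_table: pd.DataFrame, log_scale: bool = False
) -> MajorEventPartition:
    """Split junctions at the maximal change in gradient of sorted reads.

    Junctions are ordered by descending normalized reads; the knee is the
    0-based index i maximizing the discrete gradient y_i - y_{i+1} (ties go
    to the smallest index); ranks <= knee are "major".  A single junction is
    major by definition; strictly uniform distributions yield one major.
    """
    if len(rec_table) == 0:
        raise ValueError("empty recombination table")
    df = rec_table.sort_values(
        "normalized_reads", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    ids = df["junction_id"].tolist()
    y = df["normalized_reads"].to_numpy(dtype=float)
    if log_scale:
        y = np.log10(np.maximum(y, 1e-12))
    if len(y) == 1:
        return MajorEventPartition(ids, y.tolist(), 0, ["major"])
    grad = y[:-1] - y[1:]
    knee = int(np.argmax(grad))  # argmax takes the smallest index on ties
    labels = ["major" if i <= knee else "other" for i in range(len(y))]
    return MajorEventPartition(ids, y.tolist(), knee, labels)


# ---------------------------------------------------------------------------
# Clonotypes
# ---------------------------------------------------------------------------

#: Anchor geometry: 5 bp of reference taken after omitting 20 bp to the boundary.
ANCHOR_LEN = 5
ANCHOR_OFFSET = 20


@dataclass
class ClonotypeTable:
    clonotypes: pd.DataFrame  # columns: insert, read_count, fraction
    n_reads: int
    n_no_anchor: int
    n_ambiguous: int


def extract_clonotypes(
    merged_reads: Sequence[str],
    v_ref: str,
    j_ref: str,
    anchor_len: int = ANCHOR_LEN,
    anchor_offset: int = ANCHOR_OFFSET,
    collapse_one_mismatch: bool = False,
) -> ClonotypeTable:
    """Aggregate junction inserts between fixed V- and J-side anchor motifs.

    ``v_ref`` is the reference 5' of the junction in read orientation (its
    last base abuts the unprocessed boundary); ``j_ref`` starts at the
    boundary.  The anchors are the 5 bp lying 25-20 bp from the boundary on
    each side.  Reads lacking either anchor are discarded and counted; reads
    where an anchor occurs more than once are discarded separately.  Identity
    is exact string match unless ``collapse_one_mismatch`` is set.
    """
    need = anchor_offset + anchor_len
    if len(v_ref) < need or len(j_ref) < need:
        raise ValueError(f"references must provide >= {need} bp around the boundary")
    v_anchor = v_ref[-need : -anchor_offset]
    j_anchor = j_ref[anchor_offset:need]

    counts: dict[str, int] = {}
    n_no_anchor = 0
    n_ambiguous = 0
    for read in merged_reads:
        vi = read.find(v_anchor)
        if vi == -1 or read.find(v_anchor, vi + 1) != -1:
            if vi == -1:
                n_no_anchor += 1
            else:
                n_ambiguous += 1
            continue
        ji = read.find(j_anchor, vi + anchor_len)
        if ji == -1:
            n_no_anchor += 1
            continue
        if read.find(j_anchor, ji + 1) != -1 or j_anchor in read[:vi]:
            n_ambiguous += 1
            continue
        insert = read[vi + anchor_len : ji]
        counts[insert] = counts.get(insert, 0) + 1

    if collapse_one_mismatch:
        counts = _collapse_near_identical(counts)

    total = sum(counts.values())
    rows = [
        {"insert": ins, "read_count": c, "fraction": c / total if total else 0.0}
        for ins, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return ClonotypeTable(
        clonotypes=pd.DataFrame(rows, columns=["insert", "read_count", "fraction"]),
        n_reads=len(merged_reads),
        n_no_anchor=n_no_anchor,
        n_ambiguous=n_ambiguous,
    )


def _collapse_near_identical(counts: dict[str, int]) -> dict[str, int]:
    """Optional 1-mismatch collapse into the more abundant clonotype."""
    ordered = sorted(counts, key=lambda k: (-counts[k], k))
    merged: dict[str, int] = {}
    for ins in ordered:
        target = None
        for rep in merged:
            if len(rep) == len(ins) and sum(a != b for a, b in zip(rep, ins)) <= 1:
                target = rep
                break
        merged[target or ins] = merged.get(target or ins, 0) + counts[ins]
    return merged


def clonotype_division_profile(
    clonotypes: pd.DataFrame, absolute_event_copies: float
) -> pd.DataFrame:
    """Per-clonotype copies and division estimates from an absolute copy count.

    Copies = absolute copies x clonotype fraction; one copy equates to one
    carrier cell, so divisions follow from :func:`estimate_divisions`.
    """
    if absolute_event_copies <= 0:
        raise ValueError("absolute copy number must be positive")
    fr = clonotypes["fraction"].to_numpy(dtype=float)
    if ((fr < 0) | (fr > 1)).any():
        raise ValueError("clonotype fractions must lie in [0, 1]")
    out = clonotypes.copy()
    out["copies"] = fr * absolute_event_copies
    out["divisions"] = [
        estimate_divisions(c).n if c > 0 else float("nan") for c in out["copies"]
    ]
    return out
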