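"""LAM-ESC / LAM-recombination junction calling.

Stages: demultiplex read pairs by their J-side nested primer, merge mates by
3' overlap, assign merged reads to junction-database entries with a seeded,
banded local aligner, quantify per junction and threshold against controls.

The aligner is bespoke (match +1 / mismatch -1 / gap -2, k-mer seeded with a
diagonal band) so the pipeline stays self-contained and oracle-testable
against exhaustive dynamic programming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .io import FastqRead
from .locus_model import JunctionDatabase, JunctionEntry

# ---------------------------------------------------------------------------
# Primers and demultiplexing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Primer:
    primer_id: str
    target: str  # J segment or J RSS name
    sequence: str
    assay: str  # "coding" | "signal"


@dataclass
class PrimerSet:
    primers: list[Primer]

    def __post_init__(self) -> None:
        ids = [p.primer_id for p in self.primers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate primer ids")
        seqs = [p.sequence for p in self.primers]
        if len(set(seqs)) != len(seqs):
            raise ValueError("primer sequences must be unique")

    def __iter__(self):
        return iter(self.primers)


def design_primers(db: JunctionDatabase, assay: str, primer_len: int = 20) -> PrimerSet:
    """Derive one nested J-side primer per J target from the reference flanks.

    Every database entry for a given J target shares its J-side flank, so the
    primer is simply the first ``primer_len`` bases of the reference.
    """
    kind = "signal" if assay in ("signal", "esc") else "coding"
    entries = [e for e in db if e.kind == kind]
    by_target: dict[str, list[JunctionEntry]] = {}
    for e in entries:
        by_target.setdefault(e.partner_a, []).append(e)
    primers = []
    for target in sorted(by_target):
        prefixes = {e.sequence[:primer_len] for e in by_target[target]}
        if len(prefixes) != 1:
            raise ValueError(f"inconsistent J-side flanks for target {target!r}")
        primers.append(Primer(f"{target}|{kind}", target, prefixes.pop(), kind))
    return PrimerSet(primers)


def demultiplex(
    pairs: Sequence[tuple[FastqRead, FastqRead]],
    primers: PrimerSet,
    max_mismatch: int = 1,
) -> tuple[dict[str, list[tuple[FastqRead, FastqRead]]], list[tuple[FastqRead, FastqRead]]]:
    """Assign each pair to the unique primer matching read 1's 5' end.

    Multiple equal-best primers leave the pair unassigned.  Bin sizes plus
    unassigned always sum to the input count.
    """
    bins: dict[str, list] = {p.primer_id: [] for p in primers}
    unassigned: list = []
    for pair in pairs:
        seq = pair[0].sequence
        best: list[str] = []
        best_d = max_mismatch + 1
        for p in primers:
            prefix = seq[: len(p.sequence)]
            if len(prefix) < len(p.sequence):
                continue
            d = sum(a != b for a, b in zip(prefix, p.sequence))
            if d < best_d:
                best, best_d = [p.primer_id], d
            elif d == best_d:
                best.append(p.primer_id)
        if len(best) == 1:
            bins[best[0]].append(pair)
        else:
            unassigned.append(pair)
    return bins, unassigned


# ---------------------------------------------------------------------------
# Pair merging by 3' overlap
# ---------------------------------------------------------------------------


@dataclass
class MergedRead:
    read_id: str
    sequence: str
    quality: str
    merged: bool  # False -> read 1 fallback
    overlap: int = 0


def merge_pair(
    r1: FastqRead,
    r2: FastqRead,
    min_overlap: int = 20,
    max_mismatch_rate: float = 0.1,
) -> MergedRead:
    """Merge mates on the best-scoring ungapped 3' overlap.

    Candidate overlaps of length o align r1's 3' tail with revcomp(r2)'s 5'
    head; score = matches - mismatches, requiring mismatch rate <=
    ``max_mismatch_rate``; ties go to the longer overlap.  Disagreements take
    the higher-quality base (tie -> r1).  With no acceptable overlap, read 1
    is returned with the fallback flag.
    """
    rc2 = revcomp(r2.sequence)
    q2 = r2.quality[::-1]
    a1 = np.frombuffer(r1.sequence.encode("ascii"), dtype=np.uint8)
    a2 = np.frombuffer(rc2.encode("ascii"), dtype=np.uint8)
    best_o, best_score = 0, None
    for o in range(min_overlap, min(len(a1), len(a2)) + 1):
        mism = int(np.count_nonzero(a1[-o:] != a2[:o]))
        if mism > max_mismatch_rate * o:
            continue
        score = o - 2 * mism
        if best_score is None or score > best_score or (score == best_score and o > best_o):
            best_o, best_score = o, score
    if best_score is None:
        return MergedRead(r1.read_id, r1.sequence, r1.quality, merged=False)

    o = best_o
    n1 = len(r1.sequence)
    seq = list(r1.sequence + rc2[o:])
    qual = list(r1.quality + q2[o:])
    for i in range(o):
        a, qa = r1.sequence[n1 - o + i], r1.quality[n1 - o + i]
        b, qb = rc2[i], q2[i]
        if a != b and qb > qa:
            seq[n1 - o + i] = b
        qual[n1 - o + i] = max(qa, qb)
    return MergedRead(r1.read_id, "".join(seq), "".join(qual), merged=True, overlap=o)


# ---------------------------------------------------------------------------
# Seeded banded local alignment
# ---------------------------------------------------------------------------

MATCH, MISMATCH, GAP = 1, -1, -2


@dataclass
class AlignmentResult:
    score: int
    identity: float
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    matches: int
    columns: int


_NEG = -1e9


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def banded_local_align(
    read: str, ref: str, diag_lo: int, diag_hi: int
) -> Optional[AlignmentResult]:
    """Smith-Waterman (linear gap) restricted to diagonals d = i_read - i_ref
    in [diag_lo, diag_hi]; returns the best local alignment or None.

    The band is processed row-wise with vectorized within-row gap chains
    (suffix running max), so the result is exact for the banded search space.
    """
    m, n = len(read), len(ref)
    if m == 0 or n == 0:
        return None
    w = diag_hi - diag_lo + 1
    ds = np.arange(diag_lo, diag_hi + 1)
    rd = _encode(read)
    rf = _encode(ref)
    H = np.full((m + 1, w), _NEG)
    # row 0: empty-read prefix, valid wherever j = -d is a legal ref offset
    H[0][(ds <= 0) & (-ds <= n)] = 0.0
    gap_k = GAP * np.arange(w)
    # precompute per-row validity and substitution scores for the whole band
    js_all = np.arange(1, m + 1)[:, None] - ds[None, :]
    valid_all = (js_all >= 1) & (js_all <= n)
    sub_all = np.where(
        rd[:, None] == rf[np.clip(js_all - 1, 0, n - 1)], float(MATCH), float(MISMATCH)
    )
    up_pad = np.full(1, _NEG)
    for i in range(1, m + 1):
        valid = valid_all[i - 1]
        prev = H[i - 1]
        diag = np.where(prev > _NEG / 2, prev, 0.0) + sub_all[i - 1]
        up = np.concatenate((up_pad, prev[:-1])) + GAP
        cand = np.maximum(np.maximum(diag, up), 0.0)
        cand[~valid] = _NEG
        # left-gap chains: H[k] = max_{k' >= k} cand[k'] + GAP*(k'-k)
        shifted = cand + gap_k
        suffix = np.maximum.accumulate(shifted[::-1])[::-1]
        row = np.maximum(cand, suffix - gap_k)
        row[~valid] = _NEG
        H[i] = row
    best = float(H[1:].max(initial=0.0))
    if best <= 0:
        return None
    bi, bk = divmod(int(np.argmax(H[1:])), w)
    i = bi + 1
    k = bk
    read_end, ref_end = i, i - int(ds[bk])
    matches = columns = 0
    # traceback by predecessor recomputation (scores are exact integers)
    while i > 0 and H[i, k] > 0:
        j = i - int(ds[k])
        sub = MATCH if read[i - 1] == ref[j - 1] else MISMATCH
        prev_diag = H[i - 1, k] if H[i - 1, k] > _NEG / 2 else 0.0
        if H[i, k] == max(prev_diag, 0.0) + sub:
            columns += 1
            matches += sub == MATCH
            if H[i - 1, k] <= 0:
                i -= 1
                break
            i -= 1
        elif k > 0 and H[i, k] == H[i - 1, k - 1] + GAP:
            columns += 1
            i -= 1
            k -= 1
        elif k + 1 < w and H[i, k] == H[i, k + 1] + GAP:
            columns += 1
            k += 1
        else:  # alignment start
            break
    ref_start = i - int(ds[k])
    return AlignmentResult(
        score=int(best),
        identity=matches / columns if columns else 0.0,
        ref_start=ref_start,
        ref_end=ref_end,
        read_start=i,
        read_end=read_end,
        matches=matches,
        columns=columns,
    )


class JunctionIndex:
    """k-mer seed index over the reference entries of one assay kind."""

    def __init__(self, db: JunctionDatabase, kind: Optional[str] = None, k: int = 12):
        self.k = k
        self.entries = [e for e in db if kind is None or e.kind == kind]
        if not self.entries:
            raise ValueError("empty junction database")
        self.index: dict[str, list[tuple[int, int]]] = {}
        for idx, e in enumerate(self.entries):
            seq = e.sequence
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((idx, i))

    def seed_diagonals(self, read: str) -> dict[int, list[tuple[int, int]]]:
        """entry index -> list of (read_pos - ref_pos diagonal, ref_pos) seeds."""
        out: dict[int, list[tuple[int, int]]] = {}
        k = self.k
        for i in range(0, len(read) - k + 1):
            for idx, rpos in self.index.get(read[i : i + k], ()):
                out.setdefault(idx, []).append((i - rpos, rpos))
        return out


@dataclass
class Assignment:
    read_id: str
    junction_id: Optional[str]
    status: str  # assigned | unassigned | ambiguous
    identity: float = 0.0
    ref_span: tuple[int, int] = (0, 0)
    score: int = 0


def assign_junction(
    read,
    index: JunctionIndex,
    min_identity: float = 0.9,
    min_span: int = 50,
    band_pad: int = 8,
) -> Assignment:
    """Best junction entry for a (merged) read, by seeded banded alignment.

    Requires identity >= ``min_identity`` over a reference span >=
    ``min_span`` that crosses the entry's junction point; equal top scores on
    different entries yield status ``ambiguous``.
    """
    if isinstance(read, (FastqRead, MergedRead)):
        read_id, seq = read.read_id, read.sequence
    else:
        read_id, seq = "", str(read)
    candidates = index.seed_diagonals(seq)
    # entries sharing only one flank with the read (e.g. the common J side)
    # cannot yield a junction-crossing alignment; require seeds on both sides
    # of the junction point when any candidate has them.
    def both_sides(idx: int) -> bool:
        joff = index.entries[idx].junction_offset
        seeds = candidates[idx]
        return any(r + index.k <= joff for _, r in seeds) and any(
            r >= joff for _, r in seeds
        )

    crossing = [idx for idx in candidates if both_sides(idx)]
    pool = crossing if crossing else list(candidates)
    best: Optional[tuple[int, JunctionEntry, AlignmentResult]] = None
    tied = False
    for idx in pool:
        diags = [d for d, _ in candidates[idx]]
        entry = index.entries[idx]
        aln = banded_local_align(
            seq, entry.sequence, min(diags) - band_pad, max(diags) + band_pad
        )
        if aln is None:
            continue
        if best is None or aln.score > best[0]:
            best, tied = (aln.score, entry, aln), False
        elif aln.score == best[0] and entry.junction_id != best[1].junction_id:
            tied = True
    if best is None:
        return Assignment(read_id, None, "unassigned")
    score, entry, aln = best
    if tied:
        return Assignment(read_id, None, "ambiguous", aln.identity, (aln.ref_start, aln.ref_end), score)
    crosses = aln.ref_start < entry.junction_offset < aln.ref_end
    span = aln.ref_end - aln.ref_start
    if aln.identity >= min_identity and span >= min_span and crosses:
        return Assignment(
            read_id, entry.junction_id, "assigned", aln.identity,
            (aln.ref_start, aln.ref_end), score,
        )
    return Assignment(read_id, None, "unassigned", aln.identity, (aln.ref_start, aln.ref_end), score)


# ---------------------------------------------------------------------------
# Quantification and thresholding
# ---------------------------------------------------------------------------


@dataclass
class ThresholdModel:
    """Threshold = highest normalized junction level across control samples."""

    threshold: float
    source_controls: list[str] = field(default_factory=list)


def quantify(
    assignments: Sequence[Assignment],
    experiment_id: str,
    assay: str,
    total_reads: Optional[int] = None,
    assigned_only: bool = False,
) -> pd.DataFrame:
    """Per-junction raw and normalized read counts.

    The normalization denominator is all reads of the experiment/assay
    (assigned + unassigned) unless ``assigned_only`` is set.
    """
    if len(assignments) == 0:
        raise ValueError("zero reads: nothing to quantify")
    counts: dict[str, int] = {}
    n_assigned = 0
    for a in assignments:
        if a.status == "assigned" and a.junction_id:
            counts[a.junction_id] = counts.get(a.junction_id, 0) + 1
            n_assigned += 1
    total = n_assigned if assigned_only else (total_reads if total_reads is not None else len(assignments))
    if total <= 0:
        raise ValueError("zero total reads in experiment")
    rows = [
        {
            "junction_id": jid,
            "raw_reads": c,
            "normalized_reads": c / total,
            "above_threshold": pd.NA,
            "experiment_id": experiment_id,
            "assay": assay,
        }
        for jid, c in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "junction_id", "raw_reads", "normalized_reads",
            "above_threshold", "experiment_id", "assay",
        ],
    )


def fit_threshold(control_tables: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame]) -> ThresholdModel:
    """Threshold at the highest normalized junction level in the controls."""
    if isinstance(control_tables, Mapping):
        items = list(control_tables.items())
    else:
        items = [(str(t["experiment_id"].iloc[0]) if len(t) else str(i), t) for i, t in enumerate(control_tables)]
    if not items:
        raise ValueError("at least one control table required")
    best = 0.0
    for _, table in items:
        if len(table):
            best = max(best, float(table["normalized_reads"].max()))
    return ThresholdModel(threshold=best, source_controls=[k for k, _ in items])


def apply_threshold(table: pd.DataFrame, model: ThresholdModel) -> pd.DataFrame:
    """Strict inequality: controls define zero positives by construction."""
    out = table.copy()
    out["above_threshold"] = out["normalized_reads"] > model.threshold
    return out


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def run_lam_pipeline(
    pairs: Sequence[tuple[FastqRead, FastqRead]],
    primers: PrimerSet,
    db: JunctionDatabase,
    experiment_id: str,
    assay: str,
    max_mismatch: int = 1,
    min_overlap: int = 20,
    min_identity: float = 0.9,
    min_span: int = 50,
    assigned_only: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """demultiplex -> merge -> assign -> quantify, with a run report."""
    kind = "signal" if assay in ("signal", "esc") else "coding"
    bins, unassigned_pairs = demultiplex(pairs, primers, max_mismatch=max_mismatch)
    index = JunctionIndex(db, kind=kind)
    assignments: list[Assignment] = []
    n_merged = 0
    for primer_id, bin_pairs in bins.items():
        for r1, r2 in bin_pairs:
            merged = merge_pair(r1, r2, min_overlap=min_overlap)
            n_merged += merged.merged
            assignments.append(
                assign_junction(merged, index, min_identity=min_identity, min_span=min_span)
            )
    table = quantify(
        assignments, experiment_id, assay,
        total_reads=len(pairs), assigned_only=assigned_only,
    ) if assignments else pd.DataFrame()
    report = {
        "experiment_id": experiment_id,
        "assay": assay,
        "n_pairs": len(pairs),
        "n_demux_unassigned": len(unassigned_pairs),
        "bin_sizes": {k: len(v) for k, v in bins.items()},
        "n_merged": n_merged,
        "n_assigned": sum(a.status == "assigned" for a in assignments),
        "n_align_unassigned": sum(a.status == "unassigned" for a in assignments),
        "n_ambiguous": sum(a.status == "ambiguous" for a in assignments),
        "params": {
            "max_mismatch": max_mismatch, "min_overlap": min_overlap,
            "min_identity": min_identity, "min_span": min_span,
        },
    }
    return table, report
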