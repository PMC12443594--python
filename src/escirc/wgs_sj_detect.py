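"""SJ-bearing circle detection from paired-end alignments.

Divergent (outward-facing) read pairs restricted to antigen-receptor loci
are the circle-junction signature; clusters of such pairs become SJ
candidates, refined to exact breakpoints by split reads positioned across
the junction.

The module consumes alignments; it does not align.  A naive exact-match
aligner is provided only for building test fixtures from simulated reads.
Detection is presence/absence, not quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._seq import revcomp
from .io import BedInterval, FastqRead
from .locus_model import JunctionDatabase

PAIR_CLASSES = ("concordant", "divergent", "convergent_distal", "same_strand", "interchrom")


@dataclass(frozen=True)
class MateAlignment:
    chrom: str
    start: int  # 0-based
    end: int
    strand: str


@dataclass(frozen=True)
class AlignedPair:
    read_id: str
    mate1: MateAlignment
    mate2: MateAlignment

    @property
    def insert(self) -> Optional[int]:
        if self.mate1.chrom != self.mate2.chrom:
            return None
        return max(self.mate1.end, self.mate2.end) - min(self.mate1.start, self.mate2.start)


@dataclass(frozen=True)
class SplitRead:
    read_id: str
    parts: tuple[MateAlignment, MateAlignment]


@dataclass
class SJCandidate:
    chrom_a: str  # J-side breakpoint (circle end)
    pos_a: int
    strand_a: str
    chrom_b: str  # V-side breakpoint (circle start)
    pos_b: int
    strand_b: str
    support_divergent_pairs: int
    support_split_reads: int = 0
    breakpoint_resolution: str = "interval"  # "exact" requires >=1 split read
    matched_db_entry: Optional[str] = None


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------


def classify_pair(
    pair: AlignedPair, insert_mean: float, insert_sd: float, k: float = 4.0
) -> str:
    """Geometry class of a mapped pair.

    concordant: inward-facing with insert within mean +- k*sd; divergent:
    outward-facing (each read pointing away from the other) -- the
    circle-junction signature; convergent_distal: inward but too far;
    same_strand / interchrom otherwise.
    """
    m1, m2 = pair.mate1, pair.mate2
    if m1.chrom != m2.chrom:
        return "interchrom"
    if m1.strand == m2.strand:
        return "same_strand"
    left, right = sorted((m1, m2), key=lambda m: (m.start, m.end))
    if left.strand == "+" and right.strand == "-":
        insert = right.end - left.start
        if abs(insert - insert_mean) <= k * insert_sd:
            return "concordant"
        return "convergent_distal"
    return "divergent"


def count_pair_classes(
    pairs: Iterable[AlignedPair], insert_mean: float, insert_sd: float, k: float = 4.0
) -> dict[str, int]:
    """Audit of pair geometry classes (both orientation conventions countable)."""
    counts = {c: 0 for c in PAIR_CLASSES}
    for p in pairs:
        counts[classify_pair(p, insert_mean, insert_sd, k)] += 1
    return counts


# ---------------------------------------------------------------------------
# Candidate detection
# ---------------------------------------------------------------------------


def _in_regions(chrom: str, start: int, end: int, regions: Sequence[BedInterval]) -> bool:
    return any(r.chrom == chrom and start < r.end and end > r.start for r in regions)


def detect_sj_candidates(
    pairs: Sequence[AlignedPair],
    loci_regions: Sequence[BedInterval],
    db: Optional[JunctionDatabase] = None,
    insert_mean: float = 500.0,
    insert_sd: float = 60.0,
    k: float = 4.0,
    min_support: int = 2,
    merge_distance: int = 1000,
    match_tolerance: int = 10,
    interval_match_tolerance: int = 100,
) -> list[SJCandidate]:
    """Cluster divergent pairs inside the antigen-receptor loci.

    Each divergent pair bounds the junction: the ``-`` mate lies at or right
    of the V-side breakpoint and the ``+`` mate ends at or left of the J-side
    breakpoint.  Clusters within ``merge_distance`` collapse; clusters below
    ``min_support`` divergent pairs are dropped.  Candidates are matched to
    signal entries of ``db`` by breakpoint proximity (``match_tolerance``).
    """
    if not loci_regions:
        raise ValueError("empty loci region list")
    divergent = []
    for p in pairs:
        if p.mate1.chrom is None or p.mate2.chrom is None:
            continue
        if classify_pair(p, insert_mean, insert_sd, k) != "divergent":
            continue
        if not (
            _in_regions(p.mate1.chrom, p.mate1.start, p.mate1.end, loci_regions)
            and _in_regions(p.mate2.chrom, p.mate2.start, p.mate2.end, loci_regions)
        ):
            continue
        minus = p.mate1 if p.mate1.strand == "-" else p.mate2
        plus = p.mate1 if p.mate1.strand == "+" else p.mate2
        divergent.append((p, minus, plus))

    # greedy clustering on (V-side start, J-side end)
    divergent.sort(key=lambda t: (t[1].chrom, t[1].start, t[2].end))
    clusters: list[dict] = []
    for p, minus, plus in divergent:
        placed = False
        for cl in clusters:
            if (
                cl["chrom_b"] == minus.chrom
                and cl["chrom_a"] == plus.chrom
                and abs(minus.start - cl["pos_b"]) <= merge_distance
                and abs(plus.end - cl["pos_a"]) <= merge_distance
            ):
                cl["pos_b"] = min(cl["pos_b"], minus.start)
                cl["pos_a"] = max(cl["pos_a"], plus.end)
                cl["support"] += 1
                placed = True
                break
        if not placed:
            clusters.append(
                {
                    "chrom_b": minus.chrom,
                    "pos_b": minus.start,
                    "chrom_a": plus.chrom,
                    "pos_a": plus.end,
                    "support": 1,
                }
            )

    candidates = []
    for cl in clusters:
        if cl["support"] < min_support:
            continue
        cand = SJCandidate(
            chrom_a=cl["chrom_a"],
            pos_a=cl["pos_a"],
            strand_a="+",
            chrom_b=cl["chrom_b"],
            pos_b=cl["pos_b"],
            strand_b="-",
            support_divergent_pairs=cl["support"],
        )
        if db is not None:
            cand.matched_db_entry = _match_db(cand, db, interval_match_tolerance)
        candidates.append(cand)
    return candidates


def _match_db(cand: SJCandidate, db: JunctionDatabase, tol: int) -> Optional[str]:
    best = None
    best_d = tol + 1
    for e in db.signal_entries():
        d = max(abs(e.break_a - cand.pos_a), abs(e.break_b - cand.pos_b))
        if d < best_d:
            best, best_d = e.junction_id, d
    return best


def refine_with_split_reads(
    candidate: SJCandidate,
    split_alignments: Sequence[SplitRead],
    tolerance: int = 500,
    db: Optional[JunctionDatabase] = None,
    match_tolerance: int = 10,
    interval_match_tolerance: int = 100,
) -> SJCandidate:
    """Set exact breakpoints by majority vote of split reads across the SJ.

    A split read supports the candidate when one part ends near the J-side
    breakpoint and the other starts near the V-side breakpoint (within
    ``tolerance``).  Majority vote across split reads; ties take the lower
    coordinate pair.  Without split reads the resolution stays ``interval``.
    """
    votes: dict[tuple[int, int], int] = {}
    for sr in split_alignments:
        p, q = sr.parts
        for a_part, b_part in ((p, q), (q, p)):
            if (
                a_part.chrom == candidate.chrom_a
                and b_part.chrom == candidate.chrom_b
                and abs(a_part.end - candidate.pos_a) <= tolerance
                and abs(b_part.start - candidate.pos_b) <= tolerance
            ):
                key = (a_part.end, b_part.start)
                votes[key] = votes.get(key, 0) + 1
                break
    if not votes:
        if db is not None and candidate.matched_db_entry is None:
            candidate.matched_db_entry = _match_db(candidate, db, interval_match_tolerance)
        return candidate
    (pos_a, pos_b), n = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    refined = replace(
        candidate,
        pos_a=pos_a,
        pos_b=pos_b,
        support_split_reads=sum(votes.values()),
        breakpoint_resolution="exact",
    )
    if db is not None:
        refined.matched_db_entry = _match_db(refined, db, match_tolerance)
    return refined


def candidates_to_frame(candidates: Sequence[SJCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom_a": c.chrom_a, "pos_a": c.pos_a, "strand_a": c.strand_a,
                "chrom_b": c.chrom_b, "pos_b": c.pos_b, "strand_b": c.strand_b,
                "support_divergent_pairs": c.support_divergent_pairs,
                "support_split_reads": c.support_split_reads,
                "breakpoint_resolution": c.breakpoint_resolution,
                "matched_db_entry": c.matched_db_entry,
            }
            for c in candidates
        ]
    )


# ---------------------------------------------------------------------------
# Naive exact-match fixture aligner
# ---------------------------------------------------------------------------


def _find_exact(seq: str, reference: dict[str, str]) -> Optional[tuple[str, int]]:
    for chrom, ref in reference.items():
        i = ref.find(seq)
        if i != -1:
            return chrom, i
    return None


def align_read_naive(
    seq: str, reference: dict[str, str], min_part: int = 15
) -> tuple[Optional[MateAlignment], Optional[SplitRead]]:
    """Exact-match alignment of one read; split if no contiguous placement.

    Returns (full_alignment, split) -- exactly one is non-None on success.
    Fixture-only: no mismatches, first exact occurrence wins.
    """
    for strand, probe in (("+", seq), ("-", revcomp(seq))):
        hit = _find_exact(probe, reference)
        if hit:
            chrom, i = hit
            return MateAlignment(chrom, i, i + len(probe), strand), None
    for strand, probe in (("+", seq), ("-", revcomp(seq))):
        n = len(probe)
        for split_at in range(n - min_part, min_part - 1, -1):
            h1 = _find_exact(probe[:split_at], reference)
            h2 = _find_exact(probe[split_at:], reference)
            if h1 and h2:
                c1, i1 = h1
                c2, i2 = h2
                return None, SplitRead(
                    "",
                    (
                        MateAlignment(c1, i1, i1 + split_at, strand),
                        MateAlignment(c2, i2, i2 + n - split_at, strand),
                    ),
                )
    return None, None


def align_pairs_naive(
    pairs: Sequence[tuple[FastqRead, FastqRead]],
    reference: dict[str, str],
    min_part: int = 15,
) -> tuple[list[AlignedPair], list[SplitRead], int]:
    """Align simulated read pairs exactly; returns (pairs, splits, n_unmapped).

    A pair is reported when both mates place contiguously; mates that only
    place as split reads contribute to the split list (the junction-crossing
    signature), with the partner's contiguous placement ignored for pairing.
    """
    aligned: list[AlignedPair] = []
    splits: list[SplitRead] = []
    unmapped = 0
    for r1, r2 in pairs:
        a1, s1 = align_read_naive(r1.sequence, reference, min_part)
        a2, s2 = align_read_naive(r2.sequence, reference, min_part)
        if s1 is not None:
            splits.append(SplitRead(r1.read_id, s1.parts))
        if s2 is not None:
            splits.append(SplitRead(r2.read_id, s2.parts))
        if a1 is not None and a2 is not None:
            aligned.append(AlignedPair(r1.read_id, a1, a2))
        elif a1 is None and s1 is None or a2 is None and s2 is None:
            unmapped += 1
    return aligned, splits, unmapped


# ---------------------------------------------------------------------------
# SAM round trip (pysam-backed)
# ---------------------------------------------------------------------------


def write_sam(
    path,
    reference_lengths: dict[str, int],
    pairs: Sequence[AlignedPair],
    splits: Sequence[SplitRead] = (),
) -> None:
    """Serialize aligned pairs and split reads as coordinate-sorted SAM."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in reference_lengths.items()],
    }
    records = []
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {c: i for i, c in enumerate(reference_lengths)}
        for p in pairs:
            for mate_idx, (mate, other) in enumerate(
                [(p.mate1, p.mate2), (p.mate2, p.mate1)]
            ):
                a = pysam.AlignedSegment(out.header)
                a.query_name = p.read_id
                a.flag = (
                    0x1
                    | 0x2 * 0
                    | (0x40 if mate_idx == 0 else 0x80)
                    | (0x10 if mate.strand == "-" else 0)
                    | (0x20 if other.strand == "-" else 0)
                )
                a.reference_id = tid[mate.chrom]
                a.reference_start = mate.start
                length = mate.end - mate.start
                a.cigarstring = f"{length}M"
                a.query_sequence = "N" * length
                a.next_reference_id = tid[other.chrom]
                a.next_reference_start = other.start
                records.append(a)
        for s in splits:
            for part_idx, part in enumerate(s.parts):
                a = pysam.AlignedSegment(out.header)
                a.query_name = s.read_id
                a.flag = (0x10 if part.strand == "-" else 0) | (0x800 if part_idx else 0)
                a.reference_id = tid[part.chrom]
                a.reference_start = part.start
                length = part.end - part.start
                a.cigarstring = f"{length}M"
                a.query_sequence = "N" * length
                records.append(a)
        for a in sorted(records, key=lambda r: (r.reference_id, r.reference_start)):
            out.write(a)


def read_sam(path) -> tuple[list[AlignedPair], list[SplitRead]]:
    """Parse SAM back into aligned pairs and split reads."""
    import pysam

    mates: dict[str, list] = {}
    split_parts: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            mate = MateAlignment(
                rec.reference_name,
                rec.reference_start,
                rec.reference_end,
                "-" if rec.is_reverse else "+",
            )
            if rec.is_paired:
                mates.setdefault(rec.query_name, [None, None])[
                    1 if rec.is_read2 else 0
                ] = mate
            else:
                split_parts.setdefault(rec.query_name, []).append(
                    (rec.is_supplementary, mate)
                )
    pairs = [
        AlignedPair(name, m[0], m[1])
        for name, m in mates.items()
        if m[0] is not None and m[1] is not None
    ]
    splits = []
    for name, parts in split_parts.items():
        if len(parts) == 2:
            parts.sort(key=lambda t: t[0])  # primary first
            splits.append(SplitRead(name, (parts[0][1], parts[1][1])))
    return pairs, splits
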