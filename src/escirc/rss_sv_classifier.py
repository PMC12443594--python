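"""Cryptic-RSS scanning and SV breakpoint mechanism classification.

The scanner is a position-weight-matrix log-odds scan seeded from the
canonical heptamer/nonamer consensus (pluggable: externally derived matrices
can be supplied via :class:`PWMConfig`).  Both spacer classes are scanned at
their three tolerated spacer lengths (12+-1, 23+-1), on both strands.

Position convention matches the locus model: ``position`` is the 0-based
forward-strand start of the 7-mer that reads as the heptamer on ``strand``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import HEPTAMER_CONSENSUS, NONAMER_CONSENSUS, revcomp
from .io import BedInterval
from .stats_report import hypergeometric_upper

#: Default log2-odds threshold: ~13/16 consensus matches at match_prob=0.85.
DEFAULT_THRESHOLD = 16.0

_MIN_SPAN = 7 + 11 + 9  # heptamer + shortest spacer + nonamer

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class PWMConfig:
    """Scoring model for the RSS scan.

    If explicit matrices are not given, they are derived from the consensus:
    ``match_prob`` at the consensus base, the remainder split evenly, scored
    as log2 odds against a uniform background.  ``N`` scores as background
    (log-odds 0).
    """

    heptamer: str = HEPTAMER_CONSENSUS
    nonamer: str = NONAMER_CONSENSUS
    match_prob: float = 0.85
    heptamer_matrix: Optional[np.ndarray] = None  # shape (7, 4) log2-odds
    nonamer_matrix: Optional[np.ndarray] = None  # shape (9, 4)

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        def consensus_matrix(motif: str) -> np.ndarray:
            p_other = (1.0 - self.match_prob) / 3.0
            m = np.full((len(motif), 5), math.log2(p_other / 0.25))
            for i, base in enumerate(motif):
                m[i, _BASE_INDEX[base]] = math.log2(self.match_prob / 0.25)
            m[:, 4] = 0.0  # N scores as background
            return m

        def pad(matrix: np.ndarray) -> np.ndarray:
            m = np.zeros((matrix.shape[0], 5))
            m[:, :4] = matrix
            return m

        h = pad(self.heptamer_matrix) if self.heptamer_matrix is not None else consensus_matrix(self.heptamer)
        n = pad(self.nonamer_matrix) if self.nonamer_matrix is not None else consensus_matrix(self.nonamer)
        return h, n


@dataclass(frozen=True)
class RSSHit:
    position: int  # 0-based forward-strand heptamer start
    strand: str
    spacer_class: int
    spacer_len: int
    score: float
    chrom: str = ""


def _motif_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Score of the motif starting at every valid position."""
    width = matrix.shape[0]
    n = len(codes) - width + 1
    if n <= 0:
        return np.empty(0)
    acc = np.zeros(n)
    for j in range(width):
        acc += matrix[j, codes[j : j + n]]
    return acc


def _scan_strand(seq: str, pwm: PWMConfig, threshold: float) -> list[tuple[int, int, int, float]]:
    """Hits on the forward reading of ``seq``: (start, class, spacer, score)."""
    codes = np.array([_BASE_INDEX.get(c, 4) for c in seq.upper()], dtype=np.intp)
    hmat, nmat = pwm.matrices()
    hs = _motif_scores(codes, hmat)
    ns = _motif_scores(codes, nmat)
    out = []
    for spacer_class in (12, 23):
        for spacer in (spacer_class - 1, spacer_class, spacer_class + 1):
            offset = 7 + spacer
            m = min(len(hs), len(ns) - offset)
            if m <= 0:
                continue
            total = hs[:m] + ns[offset : offset + m]
            for i in np.flatnonzero(total >= threshold):
                out.append((int(i), spacer_class, spacer, float(total[i])))
    # keep the best spacer per (start, class); ties -> shorter spacer
    best: dict[tuple[int, int], tuple[int, float]] = {}
    for start, cls, spacer, score in sorted(out, key=lambda t: (t[0], t[1], t[2])):
        key = (start, cls)
        if key not in best or score > best[key][1]:
            best[key] = (spacer, score)
    return [(s, c, sp, sc) for (s, c), (sp, sc) in best.items()]


def scan_rss(
    sequence: str,
    pwm_config: Optional[PWMConfig] = None,
    threshold: Optional[float] = None,
    chrom: str = "",
) -> list[RSSHit]:
    """Scan both strands for RSS-like motifs scoring at or above threshold.

    One hit is reported per (heptamer position, strand, spacer class), taking
    the best of the three tolerated spacer lengths.
    """
    if len(sequence) < _MIN_SPAN:
        raise ValueError(f"sequence shorter than minimal motif span ({_MIN_SPAN})")
    pwm = pwm_config or PWMConfig()
    thr = DEFAULT_THRESHOLD if threshold is None else threshold
    hits: list[RSSHit] = []
    n = len(sequence)
    for start, cls, spacer, score in _scan_strand(sequence, pwm, thr):
        hits.append(RSSHit(start, "+", cls, spacer, score, chrom))
    for start, cls, spacer, score in _scan_strand(revcomp(sequence), pwm, thr):
        hits.append(RSSHit(n - start - 7, "-", cls, spacer, score, chrom))
    hits.sort(key=lambda h: (h.position, h.strand, h.spacer_class))
    return hits


# ---------------------------------------------------------------------------
# SV typing and breakpoint annotation
# ---------------------------------------------------------------------------

SV_TYPES = ("deletion", "insertion", "translocation", "complex_insertion")
MECHANISMS = (
    "cut_and_run_candidate",
    "reintegration",
    "rag_insertion",
    "two_cRSS_offtarget",
    "other",
)


@dataclass
class BreakpointAnnotation:
    sv_id: str
    sv_type: str
    sideA_cRSS: bool
    sideB_cRSS: bool
    category: str  # none | single | double
    mechanism: str = ""
    in_antigen_receptor_locus: bool = False


def _get(record, key):
    if isinstance(record, dict):
        return record[key]
    return getattr(record, key)


def locate_insert(
    insert: str, genome: dict[str, str], exclude: Sequence[tuple[str, int]] = (), margin: int = 1000
):
    """Find an exact (or reverse-complement) placement of ``insert`` in the
    genome away from the excluded breakpoints; None if absent."""
    if not insert:
        return None
    for chrom, seq in genome.items():
        for strand, probe in (("+", insert), ("-", revcomp(insert))):
            start = seq.find(probe)
            while start != -1:
                near = any(
                    c == chrom and abs(start - p) < margin for c, p in exclude
                )
                if not near:
                    return (chrom, start, strand)
                start = seq.find(probe, start + 1)
    return None


def classify_sv_type(sv_record, genome: Optional[dict[str, str]] = None) -> str:
    """Derive the SV type from the record's ends and inserted sequence."""
    chrom = _get(sv_record, "chrom")
    mate_chrom = _get(sv_record, "mate_chrom")
    pos = int(_get(sv_record, "pos"))
    mate_pos = int(_get(sv_record, "mate_pos"))
    insert = _get(sv_record, "insert_seq")
    insert = "" if insert is None or (isinstance(insert, float) and math.isnan(insert)) else str(insert)
    if insert:
        if genome is not None:
            hit = locate_insert(
                insert, genome, exclude=[(chrom, pos), (mate_chrom, mate_pos)]
            )
            if hit is not None:
                return "complex_insertion"
        return "insertion"
    if chrom != mate_chrom:
        return "translocation"
    if pos == mate_pos:
        raise ValueError(f"malformed SV record: identical ends with no insert")
    return "deletion"


def _window_has_hit(
    genome: dict[str, str],
    chrom: str,
    pos: int,
    window: int,
    pwm: Optional[PWMConfig],
    threshold: Optional[float],
) -> bool:
    seq = genome.get(chrom)
    if seq is None or not 0 <= pos < len(seq):
        raise ValueError(f"breakpoint {chrom}:{pos} outside genome")
    margin = 7 + 24 + 9  # widest motif
    lo = max(pos - window - margin, 0)
    hi = min(pos + window + margin + 1, len(seq))
    if hi - lo < _MIN_SPAN:
        return False
    for h in scan_rss(seq[lo:hi], pwm, threshold):
        start = lo + h.position
        # closed +-window: heptamer overlaps [pos-window, pos+window] by >=1 base
        if start + 6 >= pos - window and start <= pos + window:
            return True
    return False


def _in_regions(chrom: str, pos: int, regions: Iterable[BedInterval]) -> bool:
    return any(r.chrom == chrom and r.start <= pos < r.end for r in regions)


def annotate_breakpoint(
    sv_record,
    genome: dict[str, str],
    window: int = 50,
    pwm_config: Optional[PWMConfig] = None,
    threshold: Optional[float] = None,
    loci_regions: Sequence[BedInterval] = (),
) -> BreakpointAnnotation:
    """Annotate one SV with cRSS sidedness, category and locus membership.

    For insertion-like records whose two breakpoints coincide (same chrom,
    |posA - posB| <= 1) the insertion site is counted once: side B is False
    by definition, so a cRSS at the site yields category ``single``.
    """
    chrom = _get(sv_record, "chrom")
    mate_chrom = _get(sv_record, "mate_chrom")
    pos = int(_get(sv_record, "pos"))
    mate_pos = int(_get(sv_record, "mate_pos"))

    side_a = _window_has_hit(genome, chrom, pos, window, pwm_config, threshold)
    if chrom == mate_chrom and abs(pos - mate_pos) <= 1:
        side_b = False
    else:
        side_b = _window_has_hit(genome, mate_chrom, mate_pos, window, pwm_config, threshold)
    n_sides = int(side_a) + int(side_b)
    category = ("none", "single", "double")[n_sides]
    in_locus = _in_regions(chrom, pos, loci_regions) or _in_regions(
        mate_chrom, mate_pos, loci_regions
    )
    return BreakpointAnnotation(
        sv_id=str(_get(sv_record, "sv_id")),
        sv_type=classify_sv_type(sv_record, genome),
        sideA_cRSS=side_a,
        sideB_cRSS=side_b,
        category=category,
        in_antigen_receptor_locus=in_locus,
    )


def attribute_mechanism(
    annotation: BreakpointAnnotation,
    insert_alignment,
    loci_regions: Sequence[BedInterval],
) -> str:
    """Mechanism call from sidedness, SV type and insert origin."""
    is_insertion = annotation.sv_type in ("insertion", "complex_insertion")
    if is_insertion and insert_alignment is not None:
        chrom, start, _strand = insert_alignment
        if _in_regions(chrom, start, loci_regions):
            return "reintegration"
    if is_insertion and annotation.category == "single":
        return "rag_insertion"
    if annotation.category == "single":
        return "cut_and_run_candidate"
    if annotation.category == "double":
        return "two_cRSS_offtarget"
    return "other"


def annotate_sv_table(
    sv_table: pd.DataFrame,
    genome: dict[str, str],
    loci_regions: Sequence[BedInterval] = (),
    window: int = 50,
    pwm_config: Optional[PWMConfig] = None,
    threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Annotate every SV record; convenience wrapper used by the CLI."""
    rows = []
    for rec in sv_table.to_dict("records"):
        ann = annotate_breakpoint(
            rec, genome, window=window, pwm_config=pwm_config,
            threshold=threshold, loci_regions=loci_regions,
        )
        insert = rec.get("insert_seq") or ""
        if isinstance(insert, float):
            insert = ""
        alignment = locate_insert(
            insert, genome,
            exclude=[(rec["chrom"], int(rec["pos"])), (rec["mate_chrom"], int(rec["mate_pos"]))],
        )
        ann.mechanism = attribute_mechanism(ann, alignment, loci_regions)
        rows.append(
            {
                "sv_id": ann.sv_id,
                "sv_type": ann.sv_type,
                "sideA_cRSS": ann.sideA_cRSS,
                "sideB_cRSS": ann.sideB_cRSS,
                "category": ann.category,
                "mechanism": ann.mechanism,
                "in_antigen_receptor_locus": ann.in_antigen_receptor_locus,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene-set enrichment
# ---------------------------------------------------------------------------


def gene_set_enrichment(
    annotations: pd.DataFrame,
    sv_table: pd.DataFrame,
    gene_intervals: Sequence[BedInterval],
    relapse_gene_set: set[str],
    universe: set[str],
) -> tuple[int, float]:
    """One-sided hypergeometric enrichment of single-cRSS SVs in a gene set.

    Genes are assigned by breakpoint/interval overlap; cohort tallies exclude
    SVs inside antigen-receptor loci.  Returns (overlap count k, upper-tail p).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not relapse_gene_set <= universe:
        raise ValueError("relapse gene set must be a subset of the universe")
    merged = annotations.merge(sv_table, on="sv_id")
    single = merged[
        (merged["category"] == "single") & (~merged["in_antigen_receptor_locus"])
    ]
    hit_genes: set[str] = set()
    for rec in single.itertuples():
        for g in gene_intervals:
            if g.name not in universe:
                continue
            if (g.chrom == rec.chrom and g.start <= rec.pos < g.end) or (
                g.chrom == rec.mate_chrom and g.start <= rec.mate_pos < g.end
            ):
                hit_genes.add(g.name)
    n = len(hit_genes)
    k = len(hit_genes & relapse_gene_set)
    p = hypergeometric_upper(k, len(relapse_gene_set), n, len(universe))
    return k, p
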