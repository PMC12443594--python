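"""Toy antigen-receptor locus model and junction reference databases.

The locus is a single contiguous nucleotide sequence carrying ordered gene
segments (V, J, KDE, intron-RSS, constant).  Each recombining segment has one
recombination signal sequence (RSS): a heptamer, a 12+-1 or 23+-1 bp spacer and
a nonamer.  All coordinates are 0-based, half-open, BED-compatible.

Conventions
-----------
* An RSS on the ``+`` strand lies *downstream* of its segment and its heptamer
  reads forward starting at ``position``; the excision boundary is
  ``position`` (the heptamer leaves on the circle).
* An RSS on the ``-`` strand lies *upstream* of its segment; the forward-strand
  7-mer at ``[position, position + 7)`` is the reverse complement of the
  heptamer and the excision boundary is ``position + 7``.
* A pair of RSSs is *convergent* (deletional) when the left one is ``+`` and
  the right one is ``-`` -- the heptamers face each other, so joining them
  excises the intervening DNA as a circle carrying the signal joint (SJ).
* SJ reference sequences are written with the J-side flank 5'->3' first, then
  the V-side signal end, matching amplification primed from J regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from ._seq import HEPTAMER_CONSENSUS, NONAMER_CONSENSUS, random_dna, revcomp

SEGMENT_KINDS = ("V", "J", "KDE", "intronRSS", "constant")

#: Segment kinds that sit on the J-like (downstream, ``-`` RSS) side of a join.
_J_SIDE_KINDS = ("J", "KDE")


@dataclass(frozen=True)
class RSSMotif:
    """One recombination signal sequence anchored by its heptamer."""

    heptamer: str
    spacer_len: int
    nonamer: str
    spacer_class: int
    strand: str
    position: int  # 0-based genomic offset of the forward-strand heptamer 7-mer

    def __post_init__(self) -> None:
        if self.spacer_class not in (12, 23):
            raise ValueError(f"spacer_class must be 12 or 23, got {self.spacer_class}")
        if abs(self.spacer_len - self.spacer_class) > 1:
            raise ValueError(
                f"spacer_len {self.spacer_len} outside {self.spacer_class} +- 1"
            )
        if len(self.heptamer) != 7 or set(self.heptamer) - set("ACGT"):
            raise ValueError(f"invalid heptamer {self.heptamer!r}")
        if len(self.nonamer) != 9 or set(self.nonamer) - set("ACGT"):
            raise ValueError(f"invalid nonamer {self.nonamer!r}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def boundary(self) -> int:
        """Genomic coordinate of the segment/heptamer excision boundary."""
        return self.position if self.strand == "+" else self.position + 7

    @property
    def span(self) -> tuple[int, int]:
        """Forward-strand half-open interval covered by heptamer+spacer+nonamer."""
        if self.strand == "+":
            return (self.position, self.position + 7 + self.spacer_len + 9)
        return (self.position - self.spacer_len - 9, self.position + 7)


@dataclass(frozen=True)
class GeneSegment:
    """A named locus element; V/J/KDE/intronRSS carry exactly one RSS."""

    name: str
    kind: str
    interval: tuple[int, int]
    strand: str
    rss: Optional[RSSMotif] = None

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind in ("V", "J") and self.rss is None:
            raise ValueError(f"{self.kind} segment {self.name!r} must carry an RSS")
        if self.kind == "constant" and self.rss is not None:
            raise ValueError("constant segments carry no RSS")
        start, end = self.interval
        if not 0 <= start < end:
            raise ValueError(f"bad interval {self.interval} for {self.name!r}")


@dataclass
class IgLocus:
    """A toy immunoglobulin-like locus: sequence + ordered segments."""

    name: str
    sequence: str
    segments: list[GeneSegment]
    alleles: int = 2

    def __post_init__(self) -> None:
        n = len(self.sequence)
        prev_end = -1
        for seg in self.segments:
            lo = min(seg.interval[0], seg.rss.span[0] if seg.rss else n)
            hi = max(seg.interval[1], seg.rss.span[1] if seg.rss else 0)
            if lo < 0 or hi > n:
                raise ValueError(f"segment {seg.name!r} outside locus sequence")
            if lo <= prev_end:
                raise ValueError(f"segment {seg.name!r} overlaps its predecessor")
            prev_end = hi - 1
        kde = [s for s in self.segments if s.kind == "KDE"]
        if len(kde) > 1:
            raise ValueError("at most one KDE element per allele")

    def segment(self, name: str) -> GeneSegment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def by_kind(self, kind: str) -> list[GeneSegment]:
        return [s for s in self.segments if s.kind == kind]

    def rss_sequence(self, rss: RSSMotif) -> str:
        """Heptamer as read on its own strand (string-extraction oracle)."""
        s = self.sequence[rss.position : rss.position + 7]
        return s if rss.strand == "+" else revcomp(s)


@dataclass(frozen=True)
class JunctionEntry:
    """One reference entry of the junction database."""

    junction_id: str
    kind: str  # "coding" | "signal"
    partner_a: str  # J-side segment name
    partner_b: str  # V-side segment name
    topology: str  # "deletional" | "inversional"
    sequence: str
    junction_offset: int  # index in `sequence` where the V-side part begins
    break_a: int  # genomic boundary on the J side
    break_b: int  # genomic boundary on the V side
    truncated: bool = False


@dataclass
class JunctionDatabase:
    """Enumerated coding-junction and signal-joint reference sequences."""

    entries: list[JunctionEntry] = field(default_factory=list)
    flank_len: int = 60
    locus_name: str = ""

    def __iter__(self) -> Iterator[JunctionEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, junction_id: str) -> JunctionEntry:
        for e in self.entries:
            if e.junction_id == junction_id:
                return e
        raise KeyError(junction_id)

    def signal_entries(self) -> list[JunctionEntry]:
        return [e for e in self.entries if e.kind == "signal"]

    def coding_entries(self) -> list[JunctionEntry]:
        return [e for e in self.entries if e.kind == "coding"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "junction_id": e.junction_id,
                    "kind": e.kind,
                    "partner_a": e.partner_a,
                    "partner_b": e.partner_b,
                    "topology": e.topology,
                    "sequence": e.sequence,
                    "junction_offset": e.junction_offset,
                    "break_a": e.break_a,
                    "break_b": e.break_b,
                    "truncated": e.truncated,
                }
                for e in self.entries
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "JunctionDatabase":
        df = pd.read_csv(path, sep="\t")
        entries = [
            JunctionEntry(
                junction_id=r.junction_id,
                kind=r.kind,
                partner_a=r.partner_a,
                partner_b=r.partner_b,
                topology=r.topology,
                sequence=r.sequence,
                junction_offset=int(r.junction_offset),
                break_a=int(r.break_a),
                break_b=int(r.break_b),
                truncated=bool(r.truncated),
            )
            for r in df.itertuples()
        ]
        return cls(entries=entries)


# ---------------------------------------------------------------------------
# Locus construction
# ---------------------------------------------------------------------------

_DEFAULT_SEGMENT_LEN = 120
_DEFAULT_GAP = 300


def build_locus(config: dict) -> IgLocus:
    """Construct a toy locus from a config mapping.

    Config keys: ``name``, ``seed`` (mandatory), ``segments`` -- a list of
    mappings with ``name``, ``kind``, and for recombining segments
    ``spacer_class``; optional per-segment ``length``, ``gap_after``,
    ``orientation`` (RSS strand, default ``+`` for V/intronRSS and ``-`` for
    J/KDE) -- plus optional ``heptamer``/``nonamer`` consensus overrides.

    Deterministic for a fixed seed; the returned sequence embeds each segment
    and RSS at its recorded coordinates.
    """
    if "seed" not in config:
        raise ValueError("locus config requires a seed")
    rng = np.random.default_rng(int(config["seed"]))
    heptamer = config.get("heptamer", HEPTAMER_CONSENSUS)
    nonamer = config.get("nonamer", NONAMER_CONSENSUS)

    parts: list[str] = []
    segments: list[GeneSegment] = []
    cursor = 0

    def emit(chunk: str) -> None:
        nonlocal cursor
        parts.append(chunk)
        cursor += len(chunk)

    emit(random_dna(rng, int(config.get("left_pad", _DEFAULT_GAP))))

    for spec in config["segments"]:
        name = spec["name"]
        kind = spec["kind"]
        if kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {kind!r} for {name!r}")
        length = int(spec.get("length", _DEFAULT_SEGMENT_LEN))
        gap = int(spec.get("gap_after", config.get("gap_after", _DEFAULT_GAP)))

        if kind == "constant":
            seg = GeneSegment(name, kind, (cursor, cursor + length), "+", None)
            emit(random_dna(rng, length))
        else:
            if "spacer_class" not in spec:
                raise ValueError(f"{kind} segment {name!r} needs a spacer_class")
            spacer_class = int(spec["spacer_class"])
            spacer_len = int(spec.get("spacer_len", spacer_class))
            default_orient = "+" if kind in ("V", "intronRSS") else "-"
            orient = spec.get("orientation", default_orient)
            spacer = random_dna(rng, spacer_len)
            if orient == "+":
                # segment, then heptamer/spacer/nonamer reading forward
                seg_start = cursor
                emit(random_dna(rng, length))
                rss = RSSMotif(heptamer, spacer_len, nonamer, spacer_class, "+", cursor)
                emit(heptamer + spacer + nonamer)
                seg = GeneSegment(name, kind, (seg_start, seg_start + length), "+", rss)
            else:
                # rc(nonamer)/rc(spacer)/rc(heptamer), then segment
                emit(revcomp(nonamer) + revcomp(spacer))
                rss = RSSMotif(heptamer, spacer_len, nonamer, spacer_class, "-", cursor)
                emit(revcomp(heptamer))
                seg_start = cursor
                emit(random_dna(rng, length))
                seg = GeneSegment(name, kind, (seg_start, seg_start + length), "+", rss)
        segments.append(seg)
        emit(random_dna(rng, gap))

    locus = IgLocus(
        name=config.get("name", "toy_locus"),
        sequence="".join(parts),
        segments=segments,
        alleles=int(config.get("alleles", 2)),
    )
    return locus


# ---------------------------------------------------------------------------
# Topology and junction enumeration
# ---------------------------------------------------------------------------


def classify_topology(v: GeneSegment, j: GeneSegment) -> str:
    """``deletional`` iff the two RSS heptamers face each other (convergent).

    Raises ``ValueError`` for same-spacer-class pairs (12/23 rule).
    """
    if v.rss is None or j.rss is None:
        raise ValueError("both segments must carry an RSS")
    if v.rss.spacer_class == j.rss.spacer_class:
        raise ValueError(
            f"12/23 rule violation: {v.name} and {j.name} both carry "
            f"{v.rss.spacer_class}-RSSs"
        )
    left, right = sorted((v.rss, j.rss), key=lambda r: r.position)
    if left.strand == "+" and right.strand == "-":
        return "deletional"
    return "inversional"


def _coding_flank_v(locus: IgLocus, rss: RSSMotif, flank_len: int) -> tuple[str, bool]:
    """V-side coding flank reading 5'->3' toward the junction."""
    seq = locus.sequence
    if rss.strand == "+":
        lo = rss.boundary - flank_len
        trunc = lo < 0
        return seq[max(lo, 0) : rss.boundary], trunc
    hi = rss.boundary + flank_len
    trunc = hi > len(seq)
    return revcomp(seq[rss.boundary : min(hi, len(seq))]), trunc


def excised_circle(locus: IgLocus, v: GeneSegment, j: GeneSegment) -> str:
    """Sequence of the circle excised by a deletional V-J joining.

    The string starts at the V-side boundary; circular coordinate 0 is the SJ
    (the last base joins back to the first).
    """
    if classify_topology(v, j) != "deletional":
        raise ValueError("only deletional pairs excise a circle")
    left, right = sorted((v.rss, j.rss), key=lambda r: r.position)
    return locus.sequence[left.boundary : right.boundary]


def enumerate_junctions(locus: IgLocus, flank_len: int = 60) -> JunctionDatabase:
    """Enumerate coding and signal reference entries for the locus.

    Coding entries exist for every valid (unlike spacer class) V-J, V-KDE and
    intronRSS-KDE pair regardless of topology; signal entries only for
    deletional pairs.  Intra-KV (V-V) joins are never enumerated.  Flanks
    exceeding the available sequence are truncated and flagged.
    """
    if flank_len < 20:
        raise ValueError("flank_len must be >= 20")
    seq = locus.sequence
    n = len(seq)

    pairs: list[tuple[GeneSegment, GeneSegment]] = []
    js = locus.by_kind("J")
    vs = locus.by_kind("V")
    kdes = locus.by_kind("KDE")
    introns = locus.by_kind("intronRSS")
    for j in js:
        for v in vs:
            pairs.append((v, j))
    for kde in kdes:
        for v in vs:
            pairs.append((v, kde))
        for intron in introns:
            pairs.append((intron, kde))

    entries: list[JunctionEntry] = []
    for v, jlike in pairs:
        if v.rss.spacer_class == jlike.rss.spacer_class:
            continue  # 12/23 rule
        topology = classify_topology(v, jlike)

        # coding entry (any topology); like the SJ references, the sequence is
        # written in sequencing orientation: J-side flank 5'->3' first (the
        # amplicon is primed from within the J segment), then the V side.
        v_flank, v_trunc = _coding_flank_v(locus, v.rss, flank_len)
        j_bound = jlike.rss.boundary
        j_hi = min(j_bound + flank_len, n)
        coding_seq = revcomp(v_flank + seq[j_bound:j_hi])
        entries.append(
            JunctionEntry(
                junction_id=f"{jlike.name}-{v.name}|coding",
                kind="coding",
                partner_a=jlike.name,
                partner_b=v.name,
                topology=topology,
                sequence=coding_seq,
                junction_offset=j_hi - j_bound,
                break_a=j_bound,
                break_b=v.rss.boundary,
                truncated=v_trunc or (j_bound + flank_len > n),
            )
        )

        # signal entry: deletional only -- two heptamers fused head-to-head
        if topology == "deletional":
            left, right = sorted((v.rss, jlike.rss), key=lambda r: r.position)
            lo = max(right.boundary - flank_len, left.boundary)
            hi = min(left.boundary + flank_len, right.boundary)
            sj_seq = seq[lo : right.boundary] + seq[left.boundary : hi]
            entries.append(
                JunctionEntry(
                    junction_id=f"{jlike.name}-{v.name}|signal",
                    kind="signal",
                    partner_a=jlike.name,
                    partner_b=v.name,
                    topology="deletional",
                    sequence=sj_seq,
                    junction_offset=right.boundary - lo,
                    break_a=right.boundary,
                    break_b=left.boundary,
                    truncated=(right.boundary - flank_len < left.boundary)
                    or (left.boundary + flank_len > right.boundary),
                )
            )

    return JunctionDatabase(entries=entries, flank_len=flank_len, locus_name=locus.name)


# ---------------------------------------------------------------------------
# Serialization (FASTA / BED round trip)
# ---------------------------------------------------------------------------


def locus_to_fasta_bed(locus: IgLocus, fasta_path, bed_path) -> None:
    """Write the locus sequence as FASTA and its segments/RSSs as BED6."""
    from .io import write_fasta

    write_fasta(fasta_path, [(locus.name, locus.sequence)])
    with open(bed_path, "w") as fh:
        for seg in locus.segments:
            fh.write(
                f"{locus.name}\t{seg.interval[0]}\t{seg.interval[1]}\t"
                f"{seg.name}|{seg.kind}\t0\t{seg.strand}\n"
            )
            if seg.rss is not None:
                r = seg.rss
                fh.write(
                    f"{locus.name}\t{r.span[0]}\t{r.span[1]}\t"
                    f"{seg.name}|rss|{r.spacer_class}|{r.spacer_len}|{r.position}\t"
                    f"0\t{r.strand}\n"
                )


def locus_from_fasta_bed(fasta_path, bed_path) -> IgLocus:
    """Inverse of :func:`locus_to_fasta_bed` (identity round trip)."""
    from .io import read_fasta

    records = read_fasta(fasta_path)
    name, sequence = records[0]
    seg_rows: dict[str, dict] = {}
    order: list[str] = []
    with open(bed_path) as fh:
        for line in fh:
            chrom, start, end, label, _score, strand = line.rstrip("\n").split("\t")
            fields = label.split("|")
            seg_name = fields[0]
            if len(fields) == 2:
                seg_rows.setdefault(seg_name, {})["segment"] = (
                    int(start),
                    int(end),
                    fields[1],
                    strand,
                )
                order.append(seg_name)
            else:
                seg_rows.setdefault(seg_name, {})["rss"] = (
                    int(fields[2]),
                    int(fields[3]),
                    int(fields[4]),
                    strand,
                )
    segments = []
    for seg_name in order:
        row = seg_rows[seg_name]
        start, end, kind, strand = row["segment"]
        rss = None
        if "rss" in row:
            spacer_class, spacer_len, position, rstrand = row["rss"]
            hepta = sequence[position : position + 7]
            if rstrand == "-":
                hepta = revcomp(hepta)
            if rstrand == "+":
                nona_start = position + 7 + spacer_len
                nona = sequence[nona_start : nona_start + 9]
            else:
                nona_start = position - spacer_len - 9
                nona = revcomp(sequence[nona_start : nona_start + 9])
            rss = RSSMotif(hepta, spacer_len, nona, spacer_class, rstrand, position)
        segments.append(GeneSegment(seg_name, kind, (start, end), strand, rss))
    return IgLocus(name=name, sequence=sequence, segments=segments)
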