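"""Synthetic clonal populations, sequencing reads and SV sets.

Everything here is deterministic given ``(config, seed)``.  Per-stage random
generators are derived from the config seed by stage name so that, for
example, regenerating WGS reads does not perturb the population draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import mutate, random_dna, revcomp
from .io import FastqRead, stage_seed
from .locus_model import IgLocus, JunctionDatabase, excised_circle

_QUAL_CHAR = "?"  # constant Phred 30


@dataclass
class SimulationConfig:
    """Parameters for population, WGS and LAM simulations."""

    seed: int
    n_founders: int = 1
    divisions: int = 6
    esc_replication_prob: float = 0.0  # r: per circle per division
    segregation: str = "binomial"  # or "even"
    secondary_event_prob: float = 0.0
    kde_event_prob: float = 0.0
    junction_assignment: str = "random"  # or "distinct"
    insert_len_max: int = 6
    fitness_multiplier: float = 1.0  # optional selection on ESC-high clones; off
    # WGS
    wgs_fragment_mean: float = 500.0
    wgs_fragment_sd: float = 60.0
    wgs_read_len: int = 50
    wgs_n_fragments: int = 2000
    wgs_circle_fraction: Optional[float] = None  # None -> DNA-mass proportional
    # LAM
    lam_read_len: int = 250
    lam_n_reads: int = 5000
    amplification_sigma: float = 0.2
    # shared
    seq_error_rate: float = 0.0
    max_cells: int = 1 << 17

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.esc_replication_prob <= 1.0:
            raise ValueError("esc_replication_prob must be in [0, 1]")
        if self.segregation not in ("binomial", "even"):
            raise ValueError(f"unknown segregation mode {self.segregation!r}")
        if not 35 <= self.wgs_read_len <= 50:
            raise ValueError("wgs_read_len must be within [35, 50]")
        if self.lam_read_len <= 0 or self.wgs_read_len <= 0:
            raise ValueError("read lengths must be positive")
        if self.n_founders << self.divisions > self.max_cells:
            raise ValueError(
                f"{self.n_founders} founders x 2^{self.divisions} divisions exceeds "
                f"max_cells={self.max_cells}"
            )


@dataclass(frozen=True)
class RecombinationEvent:
    signal_id: str  # '' for events with no deletional SJ (inversional topology)
    coding_id: str
    v_name: str
    j_name: str
    insert: str
    allele: int
    generation: int
    is_kde: bool = False


@dataclass
class Cell:
    cell_id: int
    clone_id: int
    events: list[RecombinationEvent] = field(default_factory=list)
    esc_copies: dict[str, int] = field(default_factory=dict)


@dataclass
class PopulationTruth:
    """Simulated cells plus per-junction bookkeeping."""

    cells: list[Cell]
    divisions: int
    config: SimulationConfig

    def junction_summary(self) -> pd.DataFrame:
        """Per-junction totals: carrier cells (rec copies), SJ copies, t."""
        rows: dict[str, dict] = {}
        for cell in self.cells:
            for ev in cell.events:
                row = rows.setdefault(
                    ev.coding_id,
                    {
                        "coding_id": ev.coding_id,
                        "signal_id": ev.signal_id,
                        "v_name": ev.v_name,
                        "j_name": ev.j_name,
                        "is_kde": ev.is_kde,
                        "generation": ev.generation,
                        "rec_copies": 0,
                        "sj_copies": 0,
                    },
                )
                row["rec_copies"] += 1
            for sid, copies in cell.esc_copies.items():
                for ev in cell.events:
                    if ev.signal_id == sid:
                        rows[ev.coding_id]["sj_copies"] += copies
                        break
        df = pd.DataFrame(rows.values())
        if len(df):
            df["t"] = self.divisions - df["generation"]
        return df

    def total_sj_copies(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for cell in self.cells:
            for sid, c in cell.esc_copies.items():
                totals[sid] = totals.get(sid, 0) + c
        return totals


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------


def _duplicate_and_segregate(
    copies: int, r: float, mode: str, rng: np.random.Generator
) -> tuple[int, int]:
    """One mitosis for one circle species: duplicate w.p. r, then segregate.

    Returns (daughter1, daughter2); their sum always equals the post-
    duplication total (no copies created or lost by segregation).
    """
    dup = copies + (int(rng.binomial(copies, r)) if r > 0 else 0)
    if mode == "binomial":
        d1 = int(rng.binomial(dup, 0.5))
    else:  # even: split exactly, odd copy to a random daughter
        d1 = dup // 2 + (int(rng.integers(2)) if dup % 2 else 0)
    return d1, dup - d1


def simulate_population(
    cfg: SimulationConfig,
    db: JunctionDatabase,
    locus: Optional[IgLocus] = None,
) -> PopulationTruth:
    """Grow ``n_founders`` lineages for ``divisions`` generations.

    Each founder acquires one primary deletional recombination event on allele
    0 (one ESC copy).  At every division each ESC copy duplicates with
    probability ``esc_replication_prob`` and copies segregate to the two
    daughters per the configured mode.  Optional secondary V-J and KDE events
    occur per daughter per division; a KDE join consumes its allele's capacity
    for further KDE joins, so with r=0 a cell can never hold more than
    ``alleles`` distinct KDE-derived ESCs.
    """
    rng = np.random.default_rng(stage_seed(cfg.seed, "population"))
    signal = db.signal_entries()
    if not signal:
        raise ValueError("junction database has no deletional signal entries")

    kde_names = set()
    if locus is not None:
        kde_names = {s.name for s in locus.by_kind("KDE")}
    else:
        kde_names = {e.partner_a for e in signal if "KDE" in e.partner_a.upper()}
    vj_entries = [e for e in signal if e.partner_a not in kde_names]
    kde_entries = [e for e in signal if e.partner_a in kde_names]

    def make_event(entry, allele: int, generation: int, is_kde: bool) -> RecombinationEvent:
        insert = random_dna(rng, int(rng.integers(cfg.insert_len_max + 1)))
        coding_id = entry.junction_id.replace("|signal", "|coding")
        return RecombinationEvent(
            signal_id=entry.junction_id,
            coding_id=coding_id,
            v_name=entry.partner_b,
            j_name=entry.partner_a,
            insert=insert,
            allele=allele,
            generation=generation,
            is_kde=is_kde,
        )

    cells: list[Cell] = []
    for i in range(cfg.n_founders):
        if cfg.junction_assignment == "distinct":
            if i >= len(vj_entries):
                raise ValueError(
                    "distinct junction assignment needs >= n_founders signal entries"
                )
            entry = vj_entries[i]
        else:
            entry = vj_entries[int(rng.integers(len(vj_entries)))]
        ev = make_event(entry, allele=0, generation=0, is_kde=False)
        cells.append(Cell(cell_id=i, clone_id=i, events=[ev], esc_copies={ev.signal_id: 1}))

    next_id = len(cells)
    for gen in range(1, cfg.divisions + 1):
        new_cells: list[Cell] = []
        for cell in cells:
            d1 = Cell(next_id, cell.clone_id, list(cell.events), {})
            d2 = Cell(next_id + 1, cell.clone_id, list(cell.events), {})
            next_id += 2
            for sid, copies in cell.esc_copies.items():
                c1, c2 = _duplicate_and_segregate(
                    copies, cfg.esc_replication_prob, cfg.segregation, rng
                )
                if c1:
                    d1.esc_copies[sid] = c1
                if c2:
                    d2.esc_copies[sid] = c2
            for daughter in (d1, d2):
                if cfg.secondary_event_prob > 0 and rng.random() < cfg.secondary_event_prob:
                    used = {ev.allele for ev in daughter.events if not ev.is_kde}
                    free = [a for a in range(2) if a not in used]
                    if free and vj_entries:
                        e = vj_entries[int(rng.integers(len(vj_entries)))]
                        ev = make_event(e, allele=free[0], generation=gen, is_kde=False)
                        daughter.events.append(ev)
                        daughter.esc_copies[ev.signal_id] = (
                            daughter.esc_copies.get(ev.signal_id, 0) + 1
                        )
                if cfg.kde_event_prob > 0 and kde_entries and rng.random() < cfg.kde_event_prob:
                    kde_used = {ev.allele for ev in daughter.events if ev.is_kde}
                    free = [a for a in range(2) if a not in kde_used]
                    if free:
                        e = kde_entries[int(rng.integers(len(kde_entries)))]
                        ev = make_event(e, allele=free[0], generation=gen, is_kde=True)
                        daughter.events.append(ev)
                        daughter.esc_copies[ev.signal_id] = (
                            daughter.esc_copies.get(ev.signal_id, 0) + 1
                        )
                new_cells.append(daughter)
        cells = new_cells

    return PopulationTruth(cells=cells, divisions=cfg.divisions, config=cfg)


def simulate_copy_totals(
    n_lineages: int, divisions: int, r: float, seed: int
) -> np.ndarray:
    """Vectorized total-copy branching process (one circle per lineage).

    Segregation never changes totals, so the per-lineage total after t
    divisions has expectation ``(1 + r)**t``; mean per-cell copies are
    ``(1 + r)**t / 2**t``.
    """
    rng = np.random.default_rng(seed)
    totals = np.ones(n_lineages, dtype=np.int64)
    for _ in range(divisions):
        if r > 0:
            totals = totals + rng.binomial(totals, r)
    return totals


# ---------------------------------------------------------------------------
# WGS read simulation
# ---------------------------------------------------------------------------


def simulate_wgs_reads(
    truth: PopulationTruth,
    locus: IgLocus,
    cfg: SimulationConfig,
) -> tuple[list[tuple[FastqRead, FastqRead]], pd.DataFrame]:
    """Paired-end WGS-style fragments from genomic alleles and ESC circles.

    Fragment origins are sampled proportionally to DNA mass (allele copies x
    length vs circle copies x length) unless ``wgs_circle_fraction`` pins the
    circle share.  Circle fragments may wrap the SJ; those are labelled
    ``spans_SJ`` in the truth table.
    """
    if not truth.cells:
        raise ValueError("population has no cells")
    if cfg.wgs_fragment_mean < 2 * cfg.wgs_read_len:
        raise ValueError("fragment mean must be >= 2x read length")
    rng = np.random.default_rng(stage_seed(cfg.seed, "wgs"))

    circles: list[tuple[str, str, int]] = []  # (signal_id, circle_seq, copies)
    sj_totals = truth.total_sj_copies()
    seen_events = {}
    for cell in truth.cells:
        for ev in cell.events:
            if ev.signal_id and ev.signal_id not in seen_events:
                seen_events[ev.signal_id] = ev
    for sid, copies in sorted(sj_totals.items()):
        ev = seen_events[sid]
        circ = excised_circle(locus, locus.segment(ev.v_name), locus.segment(ev.j_name))
        circles.append((sid, circ, copies))

    genome_mass = len(truth.cells) * locus.alleles * len(locus.sequence)
    circle_mass = sum(len(c) * n for _, c, n in circles)
    if cfg.wgs_circle_fraction is not None:
        p_circle = cfg.wgs_circle_fraction if circles else 0.0
    else:
        p_circle = circle_mass / (genome_mass + circle_mass) if circle_mass else 0.0
    circle_weights = np.array([len(c) * n for _, c, n in circles], dtype=float)
    if circle_weights.sum() > 0:
        circle_weights /= circle_weights.sum()

    pairs: list[tuple[FastqRead, FastqRead]] = []
    rows = []
    rl = cfg.wgs_read_len
    for i in range(cfg.wgs_n_fragments):
        flen = int(round(rng.normal(cfg.wgs_fragment_mean, cfg.wgs_fragment_sd)))
        flen = max(flen, 2 * rl)
        if circles and rng.random() < p_circle:
            ci = int(rng.choice(len(circles), p=circle_weights))
            sid, circ, _ = circles[ci]
            L = len(circ)
            flen = min(flen, L)
            start = int(rng.integers(L))
            frag = (circ + circ)[start : start + flen]
            origin, spans = sid, start + flen > L
        else:
            start = int(rng.integers(len(locus.sequence) - flen + 1))
            frag = locus.sequence[start : start + flen]
            origin, spans = "genome", False
        r1 = mutate(frag[:rl], rng, cfg.seq_error_rate)
        r2 = mutate(revcomp(frag[-rl:]), rng, cfg.seq_error_rate)
        rid = f"wgs{i:06d}"
        pairs.append(
            (FastqRead(rid, r1, _QUAL_CHAR * rl), FastqRead(rid, r2, _QUAL_CHAR * rl))
        )
        rows.append(
            {
                "read_id": rid,
                "origin": origin,
                "spans_SJ": spans,
                "frag_start": start,
                "frag_len": flen,
            }
        )
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LAM amplicon simulation
# ---------------------------------------------------------------------------


def simulate_lam_reads(
    truth: PopulationTruth,
    junction_db: JunctionDatabase,
    primers,
    cfg: SimulationConfig,
    assay: str = "signal",
) -> tuple[list[tuple[FastqRead, FastqRead]], pd.DataFrame]:
    """Overlapping 2 x ``lam_read_len`` amplicon pairs primed from the J side.

    Read counts per junction are multinomial with weights proportional to
    truth copy numbers times a per-junction lognormal amplification factor
    (sigma = ``amplification_sigma``).  Substitution errors only.
    """
    if assay not in ("signal", "coding"):
        raise ValueError("assay must be 'signal' or 'coding'")
    rng = np.random.default_rng(stage_seed(cfg.seed, f"lam-{assay}"))
    summary = truth.junction_summary()
    if not len(summary):
        raise ValueError("population has no recombination events")

    # species: (junction_id, amplicon_sequence, copies)
    species: list[tuple[str, str, int]] = []
    if assay == "signal":
        for row in summary.itertuples():
            if not row.signal_id or row.sj_copies <= 0:
                continue
            entry = junction_db.get(row.signal_id)  # KeyError if absent
            species.append((row.signal_id, entry.sequence, int(row.sj_copies)))
    else:
        # one species per (coding junction, insert) -- i.e. per clonotype
        counts: dict[tuple[str, str], int] = {}
        for cell in truth.cells:
            for ev in cell.events:
                counts[(ev.coding_id, ev.insert)] = (
                    counts.get((ev.coding_id, ev.insert), 0) + 1
                )
        for (cid, insert), copies in sorted(counts.items()):
            entry = junction_db.get(cid)
            amp = (
                entry.sequence[: entry.junction_offset]
                + insert
                + entry.sequence[entry.junction_offset :]
            )
            species.append((cid, amp, copies))
    if not species:
        raise ValueError("no amplifiable junctions for this assay")

    primer_seqs = [p.sequence for p in getattr(primers, "primers", primers)]
    for jid, amp, _ in species:
        if not any(amp.startswith(p) for p in primer_seqs):
            raise ValueError(f"no primer matches the amplicon of {jid}")

    weights = np.array(
        [c * rng.lognormal(0.0, cfg.amplification_sigma) for _, _, c in species]
    )
    counts = rng.multinomial(cfg.lam_n_reads, weights / weights.sum())

    pairs: list[tuple[FastqRead, FastqRead]] = []
    rows = []
    rl = cfg.lam_read_len
    idx = 0
    for (jid, amp, _), n_reads in zip(species, counts):
        for _ in range(n_reads):
            r1 = mutate(amp[:rl], rng, cfg.seq_error_rate)
            r2 = mutate(revcomp(amp)[:rl], rng, cfg.seq_error_rate)
            rid = f"lam{idx:06d}"
            idx += 1
            pairs.append(
                (
                    FastqRead(rid, r1, _QUAL_CHAR * len(r1)),
                    FastqRead(rid, r2, _QUAL_CHAR * len(r2)),
                )
            )
            rows.append({"read_id": rid, "junction_id": jid, "amplicon_len": len(amp)})
    # deterministic interleave not required; order is per-species, stable
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SV set simulation
# ---------------------------------------------------------------------------


@dataclass
class SVSimConfig:
    seed: int
    n_sv: int = 100
    proportions: dict = field(
        default_factory=lambda: {"none": 0.4, "single": 0.4, "double": 0.2}
    )
    slot: int = 800  # spacing between consecutive breakpoints
    insert_len: int = 40
    scan_threshold: Optional[float] = None  # default scanner threshold
    n_in_locus: int = 0  # SVs planted inside the antigen-receptor locus

    def __post_init__(self) -> None:
        total = sum(self.proportions.get(k, 0.0) for k in ("none", "single", "double"))
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")


def _largest_remainder(n: int, props: dict) -> dict:
    keys = ["none", "single", "double"]
    raw = {k: n * props.get(k, 0.0) for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    rem = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:rem]:
        counts[k] += 1
    return counts


def simulate_sv_set(
    cfg: SVSimConfig, locus: IgLocus
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """SV records with cRSSs planted on zero, one or both breakpoint sides.

    Returns ``(sv_table, genome, truth_table)``.  The genome dict includes the
    antigen-receptor locus as its own contig; reintegration-class insertions
    carry inserted sequence copied from it.  Class counts follow the
    configured proportions exactly (largest-remainder apportionment);
    mechanisms cycle deterministically within each class.
    """
    from .rss_sv_classifier import DEFAULT_THRESHOLD, scan_rss

    threshold = cfg.scan_threshold if cfg.scan_threshold is not None else DEFAULT_THRESHOLD
    rng = np.random.default_rng(stage_seed(cfg.seed, "sv"))
    counts = _largest_remainder(cfg.n_sv, cfg.proportions)
    classes = (
        ["none"] * counts["none"]
        + ["single"] * counts["single"]
        + ["double"] * counts["double"]
    )

    chrom_len = cfg.slot * (cfg.n_sv + 2)
    genome = {
        "chr1": bytearray(random_dna(rng, chrom_len), "ascii"),
        "chr2": bytearray(random_dna(rng, chrom_len), "ascii"),
    }

    def plant_crss(chrom: str, pos: int) -> None:
        from ._seq import HEPTAMER_CONSENSUS, NONAMER_CONSENSUS

        offset = int(rng.integers(-40, 35))  # heptamer start within +-50 window
        start = pos + offset
        motif = HEPTAMER_CONSENSUS + random_dna(rng, 12) + NONAMER_CONSENSUS
        genome[chrom][start : start + len(motif)] = motif.encode()

    def scrub(chrom: str, pos: int) -> None:
        """Rewrite around pos until no motif scores above threshold in +-50."""
        lo, hi = pos - 90, pos + 90
        for _ in range(50):
            region = genome[chrom][lo:hi].decode()
            hits = scan_rss(region, threshold=threshold)
            window_hits = [
                h for h in hits if h.position + 7 > 40 and h.position <= 140
            ]
            if not window_hits:
                return
            genome[chrom][lo:hi] = random_dna(rng, hi - lo).encode()
        raise RuntimeError("could not scrub cRSS-free region")

    single_cycle = ["cut_and_run_candidate", "reintegration", "rag_insertion"]
    double_cycle = ["two_cRSS_offtarget"]

    sv_rows, truth_rows = [], []
    cycle_idx = {"single": 0, "double": 0}
    for i, category in enumerate(classes):
        pos_a = cfg.slot * (i + 1)
        if category == "single":
            mechanism = single_cycle[cycle_idx["single"] % len(single_cycle)]
            cycle_idx["single"] += 1
        elif category == "double":
            mechanism = double_cycle[cycle_idx["double"] % len(double_cycle)]
            cycle_idx["double"] += 1
        else:
            mechanism = "other"

        insert = ""
        if mechanism == "reintegration":
            # insert copied from the antigen-receptor locus
            src = int(rng.integers(100, len(locus.sequence) - 100 - cfg.insert_len))
            insert = locus.sequence[src : src + cfg.insert_len]
            chrom_a, chrom_b, pos_b = "chr1", "chr1", pos_a + 1
            svtype = "complex_insertion"
        elif mechanism == "rag_insertion":
            insert = random_dna(rng, cfg.insert_len)
            chrom_a, chrom_b, pos_b = "chr1", "chr1", pos_a + 1
            svtype = "insertion"
        else:
            # alternate deletions and translocations deterministically
            if i % 2 == 0:
                chrom_a, chrom_b, pos_b = "chr1", "chr1", pos_a + cfg.slot // 2
                svtype = "deletion"
            else:
                chrom_a, chrom_b, pos_b = "chr1", "chr2", cfg.slot * (i + 1)
                svtype = "translocation"

        side_a = category in ("single", "double")
        side_b = category == "double"
        if side_a:
            plant_crss(chrom_a, pos_a)
        if side_b:
            plant_crss(chrom_b, pos_b)

        sv_rows.append(
            {
                "sv_id": f"sv{i:04d}",
                "chrom": chrom_a,
                "pos": pos_a,
                "mate_chrom": chrom_b,
                "mate_pos": pos_b,
                "svtype": svtype,
                "insert_seq": insert,
            }
        )
        truth_rows.append(
            {
                "sv_id": f"sv{i:04d}",
                "true_category": category,
                "true_mechanism": mechanism,
                "side_a_crss": side_a,
                "side_b_crss": side_b,
            }
        )

    # scrub every side that must be cRSS-free
    for sv, tr in zip(sv_rows, truth_rows):
        if not tr["side_a_crss"]:
            scrub(sv["chrom"], sv["pos"])
        if not tr["side_b_crss"] and (sv["mate_chrom"], sv["mate_pos"]) != (
            sv["chrom"],
            sv["pos"] + 1,
        ):
            scrub(sv["mate_chrom"], sv["mate_pos"])

    # optional SVs inside the antigen-receptor locus (to exercise exclusion)
    n0 = len(sv_rows)
    for k in range(cfg.n_in_locus):
        pos = 200 + k * 400
        sv_rows.append(
            {
                "sv_id": f"sv{n0 + k:04d}",
                "chrom": locus.name,
                "pos": pos,
                "mate_chrom": locus.name,
                "mate_pos": pos + 200,
                "svtype": "deletion",
                "insert_seq": "",
            }
        )
        truth_rows.append(
            {
                "sv_id": f"sv{n0 + k:04d}",
                "true_category": "in_locus",
                "true_mechanism": "in_locus",
                "side_a_crss": False,
                "side_b_crss": False,
            }
        )

    genome_str = {k: v.decode() for k, v in genome.items()}
    genome_str[locus.name] = locus.sequence
    return pd.DataFrame(sv_rows), genome_str, pd.DataFrame(truth_rows)
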