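"""Shared readers/writers and run configuration.

All repo-produced files round-trip losslessly.  Malformed records raise
``FormatError`` carrying the offending line number or read id.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import yaml


class FormatError(ValueError):
    """A file did not conform to its declared format."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                if name is None:
                    raise FormatError(f"{path}:{lineno}: sequence before header")
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (paired)
# ---------------------------------------------------------------------------


@dataclass
class FastqRead:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FormatError(f"read {self.read_id!r}: sequence/quality length mismatch")


def read_fastq(path) -> list[FastqRead]:
    reads: list[FastqRead] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4:
        raise FormatError(f"{path}: truncated FASTQ record at line {len(lines)}")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"{path}:{i + 1}: malformed FASTQ record")
        reads.append(FastqRead(header[1:].split()[0], seq, qual))
    return reads


def write_fastq(path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq_pairs(path1, path2) -> list[tuple[FastqRead, FastqRead]]:
    """Read a mate pair of FASTQ files, enforcing matching read ids."""
    r1 = read_fastq(path1)
    r2 = read_fastq(path2)
    if len(r1) != len(r2):
        raise FormatError(f"paired FASTQ length mismatch: {len(r1)} vs {len(r2)}")
    for a, b in zip(r1, r2):
        ida = a.read_id.removesuffix("/1")
        idb = b.read_id.removesuffix("/2")
        if ida != idb:
            raise FormatError(f"read id mismatch: {a.read_id!r} vs {b.read_id!r}")
    return list(zip(r1, r2))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "0"
    strand: str = "."


def read_bed(path) -> list[BedInterval]:
    intervals: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line with <3 fields")
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: degenerate BED interval {start}>={end}"
                )
            extra = fields[3:6] + ["."] * (3 - len(fields[3:6]))
            intervals.append(BedInterval(fields[0], start, end, *extra))
    return intervals


def write_bed(path, intervals: Iterable[BedInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Config / seeds
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed by stage name."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0])


@dataclass
class RunConfig:
    """Umbrella run configuration: global seed plus per-stage blocks."""

    seed: int
    stages: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = load_config(path)
        if "seed" not in raw:
            raise ValueError("run config requires a global seed")
        return cls(
            seed=int(raw["seed"]),
            stages={k: v for k, v in raw.items() if k not in ("seed", "log_level")},
            log_level=raw.get("log_level", "INFO"),
        )

    def seed_for(self, stage: str) -> int:
        block = self.stages.get(stage, {}) or {}
        if isinstance(block, dict) and "seed" in block:
            return int(block["seed"])
        return stage_seed(self.seed, stage)
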