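"""FASTQ adapter trimming and length filtering for small-RNA reads.

Small-RNA libraries ligate adapters on both sides of the insert; a 50-cycle
read therefore runs through the insert into the 3' adapter. Trimming locates
the earliest occurrence of the 3' adapter's 8-nt seed prefix (allowing a
configurable number of substitutions) and cuts there; a 5' adapter, when
present, is removed by the suffix-anchored analogue. Reads are then kept
only if their length lies in (min_len, max_len] — the lower bound is
exclusive, so a 15-nt insert is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

SEED_LEN = 8


class FastqError(ValueError):
    """Raised for malformed FASTQ records."""


@dataclass
class ReadPrepConfig:
    adapter3: str = ""
    adapter5: str = ""
    min_len: int = 15          # exclusive: survivors are strictly longer
    max_len: int = 50
    max_adapter_mismatch: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.min_len < self.max_len):
            raise ValueError("require 0 < min_len < max_len")
        if self.max_adapter_mismatch < 0:
            raise ValueError("max_adapter_mismatch must be >= 0")
        self.adapter3 = self.adapter3.upper()
        self.adapter5 = self.adapter5.upper()


@dataclass
class ReadPrepSummary:
    """Stage counts; input = passed + discarded always holds."""

    n_input: int = 0
    n_trimmed3: int = 0
    n_trimmed5: int = 0
    n_untrimmed: int = 0   # no 3' adapter found; kept, flagged
    n_passed: int = 0
    n_discarded_short: int = 0
    n_discarded_long: int = 0

    @property
    def n_discarded(self) -> int:
        return self.n_discarded_short + self.n_discarded_long

    def to_rows(self) -> list[tuple[str, int]]:
        return [
            ("input", self.n_input),
            ("trimmed3", self.n_trimmed3),
            ("trimmed5", self.n_trimmed5),
            ("untrimmed", self.n_untrimmed),
            ("passed", self.n_passed),
            ("discarded_short", self.n_discarded_short),
            ("discarded_long", self.n_discarded_long),
        ]


@dataclass
class FastqRead:
    id: str
    seq: str
    qual: str


def read_fastq(handle: TextIO | str | Path) -> Iterator[FastqRead]:
    """Yield 4-line FASTQ records, validating structure per record."""
    if isinstance(handle, (str, Path)):
        with open(handle) as fh:
            yield from read_fastq(fh)
        return
    idx = 0
    while True:
        lines = [handle.readline() for _ in range(4)]
        if not lines[0]:
            return
        if any(not ln for ln in lines[1:]):
            raise FastqError(f"truncated FASTQ record at index {idx}")
        head, seq, plus, qual = (ln.rstrip("\n") for ln in lines)
        if not head.startswith("@") or not plus.startswith("+"):
            raise FastqError(f"malformed FASTQ record at index {idx}")
        if len(seq) != len(qual):
            raise FastqError(
                f"sequence/quality length mismatch at record index {idx}")
        yield FastqRead(id=head[1:].split()[0], seq=seq.upper(), qual=qual)
        idx += 1


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_adapter3(seq: str, adapter: str, max_mismatch: int) -> int | None:
    """Leftmost start of the 3' adapter, or None.

    Scans 5'→3' for the earliest window matching the first ``SEED_LEN`` nt
    of the adapter with at most ``max_mismatch`` substitutions, then
    confirms the hit over up to ``2×SEED_LEN`` adapter bases with a
    proportional allowance (``max_mismatch`` per seed length). The
    confirmation step keeps chance seed look-alikes inside the insert from
    triggering a premature trim while still tolerating sequencing errors.
    When fewer than ``SEED_LEN`` adapter bases fit at the read's 3' end,
    the remaining suffix windows are compared over the available overlap
    so partial adapter run-in is still trimmed.
    """
    seed = adapter[:SEED_LEN]
    n, m = len(seq), len(seed)

    def confirmed(start: int) -> bool:
        ext = min(len(adapter), n - start, 2 * SEED_LEN)
        allowed = max_mismatch * -(-ext // SEED_LEN)     # ceil(ext/SEED_LEN)
        return _mismatches(seq[start:start + ext], adapter[:ext]) <= allowed

    for start in range(0, n):
        window = seq[start:start + m]
        if len(window) == m:
            if _mismatches(window, seed) <= max_mismatch and confirmed(start):
                return start
        else:
            # partial overlap at the 3' end; require proportionally clean match
            if window and _mismatches(window, seed[:len(window)]) <= max_mismatch \
                    and len(window) >= 3:
                return start
    return None


def find_adapter5(seq: str, adapter: str, max_mismatch: int) -> int | None:
    """End (exclusive, 0-based) of a 5' adapter suffix at the read start.

    Suffix-anchored analogue of :func:`find_adapter3`: the rightmost
    ``SEED_LEN`` nt of the adapter are searched as a prefix-aligned block
    ending latest in the read's 5' region.
    """
    seed = adapter[-SEED_LEN:]
    m = len(seed)
    # longest placement first: adapter suffix ends at position `end`
    for end in range(min(len(seq), len(adapter)), 0, -1):
        start = max(0, end - m)
        window = seq[start:end]
        ref = seed[-len(window):]
        if len(window) >= 3 and _mismatches(window, ref) <= max_mismatch:
            return end
    return None


def _trim_coords(seq: str, cfg: ReadPrepConfig) -> tuple[int, int, bool, bool]:
    """(start, end, trimmed3, trimmed5) slice coordinates for one sequence."""
    start, end = 0, len(seq)
    trimmed3 = trimmed5 = False
    if cfg.adapter5:
        cut = find_adapter5(seq, cfg.adapter5, cfg.max_adapter_mismatch)
        if cut is not None:
            start, trimmed5 = cut, True
    if cfg.adapter3:
        cut = find_adapter3(seq[start:], cfg.adapter3, cfg.max_adapter_mismatch)
        if cut is not None:
            end, trimmed3 = start + cut, True
    return start, end, trimmed3, trimmed5


def trim_read(read: FastqRead, cfg: ReadPrepConfig) -> tuple[FastqRead, bool, bool]:
    """Trim one read; returns (read, trimmed3, trimmed5)."""
    start, end, t3, t5 = _trim_coords(read.seq, cfg)
    return FastqRead(read.id, read.seq[start:end], read.qual[start:end]), t3, t5


def trim_and_filter(
    reads: Iterable[FastqRead], cfg: ReadPrepConfig
) -> tuple[list[FastqRead], ReadPrepSummary]:
    """Trim adapters and keep reads with min_len < length ≤ max_len.

    Reads with no 3'-adapter occurrence are kept untrimmed (counted as
    ``untrimmed``); they are still subject to the length gate, which in
    practice discards full-length no-insert reads via ``max_len``.
    """
    summary = ReadPrepSummary()
    passed: list[FastqRead] = []
    cache: dict[str, tuple[int, int, bool, bool]] = {}
    for read in reads:
        summary.n_input += 1
        coords = cache.get(read.seq)
        if coords is None:
            coords = _trim_coords(read.seq, cfg)
            cache[read.seq] = coords
        start, end, t3, t5 = coords
        out = FastqRead(read.id, read.seq[start:end], read.qual[start:end])
        if t3:
            summary.n_trimmed3 += 1
        elif cfg.adapter3:
            summary.n_untrimmed += 1
        if t5:
            summary.n_trimmed5 += 1
        n = len(out.seq)
        if n <= cfg.min_len:
            summary.n_discarded_short += 1
        elif n > cfg.max_len:
            summary.n_discarded_long += 1
        else:
            summary.n_passed += 1
            passed.append(out)
    assert summary.n_input == summary.n_passed + summary.n_discarded
    return passed, summary


def write_summary(summary: ReadPrepSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tcount\n")
        for stage, count in summary.to_rows():
            fh.write(f"{stage}\t{count}\n")
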