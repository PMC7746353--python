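"""Structure-annotated tRNA reference model.

Mature tRNAs fold into a cloverleaf with three hairpin loops — the D-loop,
the anticodon loop and the T-loop, in 5'→3' order. tsRNA classification is
entirely driven by where a fragment's endpoints fall relative to these
loops, so the reference parser locates them from a dot-bracket secondary
structure supplied alongside each sequence.

The reference dialect is a FASTA-like 3-line record::

    >id amino_acid anticodon [precursor_trailer=SEQ]
    <mature sequence, 5'→3', CCA-appended>
    <dot-bracket structure of the same length>

Coordinates throughout are 1-based closed intervals on the mature sequence
(trailer spans are on the precursor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional


class ReferenceError(ValueError):
    """Raised for malformed reference records or structures."""


@dataclass(frozen=True)
class Interval:
    """1-based closed interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ReferenceError(f"invalid interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class LoopSpans:
    """The three cloverleaf hairpin loops, 5'→3'.

    The anticodon triplet sits at the centre of the anticodon loop.
    """

    d_loop: Interval
    anticodon_loop: Interval
    t_loop: Interval

    def __post_init__(self) -> None:
        if not (self.d_loop.end < self.anticodon_loop.start
                and self.anticodon_loop.end < self.t_loop.start):
            raise ReferenceError(
                "loops must be disjoint and ordered D < anticodon < T: "
                f"{self.d_loop}, {self.anticodon_loop}, {self.t_loop}")

    @property
    def anticodon_center(self) -> int:
        return (self.anticodon_loop.start + self.anticodon_loop.end) // 2


@dataclass(frozen=True)
class PrecursorRecord:
    """Precursor context for a mature tRNA: the 3' trailer.

    tRF-1 species derive from the U-rich trailer immediately 3' of the
    mature sequence on the precursor transcript.
    """

    precursor_seq: str
    mature_span: Interval
    trailer_span: Interval

    def __post_init__(self) -> None:
        if self.trailer_span.start != self.mature_span.end + 1:
            raise ReferenceError("trailer must start immediately 3' of the mature span")
        if self.trailer_span.end > len(self.precursor_seq):
            raise ReferenceError("trailer span exceeds precursor length")

    @property
    def trailer_seq(self) -> str:
        return self.precursor_seq[self.trailer_span.start - 1:self.trailer_span.end]


@dataclass(frozen=True)
class TRNARecord:
    """A mature tRNA with located loops and optional precursor trailer."""

    id: str
    amino_acid: str
    anticodon: str
    mature_seq: str
    structure: str
    loops: LoopSpans
    cca_appended: bool = True
    precursor: Optional[PrecursorRecord] = None

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.mature_seq):
            raise ReferenceError(
                f"{self.id}: structure length {len(self.structure)} != "
                f"sequence length {len(self.mature_seq)}")
        if self.loops.t_loop.end > len(self.mature_seq):
            raise ReferenceError(f"{self.id}: loops exceed sequence bounds")

    def __len__(self) -> int:
        return len(self.mature_seq)


_ALIAS = str.maketrans("><", "()")


def _normalize_structure(structure: str) -> str:
    s = structure.translate(_ALIAS)
    bad = set(s) - set(".()")
    if bad:
        raise ReferenceError(f"illegal structure characters: {sorted(bad)}")
    return s


def pair_table(structure: str) -> dict[int, int]:
    """Map each paired position to its partner (1-based), via a bracket stack.

    Raises on unbalanced brackets.
    """
    s = _normalize_structure(structure)
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(s, start=1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ReferenceError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
    if stack:
        raise ReferenceError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def hairpin_loops(structure: str) -> list[Interval]:
    """All hairpin loops of a dot-bracket string, 5'→3'.

    A hairpin loop is a maximal unpaired run directly enclosed by a stem:
    the positions flanking the run are paired with each other.
    """
    s = _normalize_structure(structure)
    pairs = pair_table(s)
    loops: list[Interval] = []
    n = len(s)
    i = 1
    while i <= n:
        if s[i - 1] == ".":
            j = i
            while j < n and s[j] == ".":
                j += 1
            # run is [i, j]; enclosed iff flanks pair with each other
            if i > 1 and j < n and s[i - 2] == "(" and s[j] == ")" \
                    and pairs.get(i - 1) == j + 1:
                loops.append(Interval(i, j))
            i = j + 1
        else:
            i += 1
    return loops


def locate_loops(structure: str) -> LoopSpans:
    """Assign D-, anticodon- and T-loops from a cloverleaf dot-bracket.

    The 1st hairpin loop is the D-loop and the 2nd the anticodon loop.
    tRNAs with a long variable arm (Ser, Leu) present a 4th hairpin between
    the anticodon and T arms; the LAST loop is always the T-loop.
    """
    loops = hairpin_loops(structure)
    if len(loops) < 3:
        raise ReferenceError(
            f"expected ≥3 hairpin loops in a cloverleaf, found {len(loops)}")
    return LoopSpans(d_loop=loops[0], anticodon_loop=loops[1], t_loop=loops[-1])


def _parse_header(line: str) -> tuple[str, str, str, Optional[str]]:
    if not line.startswith(">"):
        raise ReferenceError(f"expected '>' header, got {line[:30]!r}")
    fields = line[1:].split()
    if len(fields) < 3:
        raise ReferenceError(f"header needs id, amino_acid, anticodon: {line!r}")
    rid, aa, anticodon = fields[:3]
    trailer = None
    for extra in fields[3:]:
        if extra.startswith("precursor_trailer="):
            trailer = extra.split("=", 1)[1]
    return rid, aa, anticodon, trailer


def _build_record(header: str, seq: str, structure: str) -> TRNARecord:
    rid, aa, anticodon, trailer = _parse_header(header)
    seq = seq.strip().upper().replace("T", "U")
    structure = structure.strip()
    if len(structure) != len(seq):
        raise ReferenceError(
            f"{rid}: structure line length {len(structure)} != sequence "
            f"length {len(seq)}")
    loops = locate_loops(structure)
    precursor = None
    if trailer:
        trailer = trailer.upper().replace("T", "U")
        pre_seq = seq + trailer
        precursor = PrecursorRecord(
            precursor_seq=pre_seq,
            mature_span=Interval(1, len(seq)),
            trailer_span=Interval(len(seq) + 1, len(pre_seq)),
        )
    return TRNARecord(
        id=rid,
        amino_acid=aa,
        anticodon=anticodon.upper().replace("T", "U"),
        mature_seq=seq,
        structure=_normalize_structure(structure),
        loops=loops,
        cca_appended=seq.endswith("CCA"),
        precursor=precursor,
    )


def parse_reference(path: str | Path) -> list[TRNARecord]:
    """Parse a 3-line-record reference file into TRNARecords.

    Records whose structure cannot be parsed are collected and reported in
    a single error naming each offending record; an empty file is an error.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    if not lines:
        raise ReferenceError(f"{path}: no records found")
    if len(lines) % 3 != 0:
        raise ReferenceError(
            f"{path}: expected 3-line records, got {len(lines)} lines")
    records: list[TRNARecord] = []
    errors: list[str] = []
    for k in range(0, len(lines), 3):
        header, seq, structure = lines[k], lines[k + 1], lines[k + 2]
        try:
            records.append(_build_record(header, seq, structure))
        except ReferenceError as exc:
            errors.append(str(exc))
    if errors:
        raise ReferenceError(
            f"{path}: {len(errors)} record(s) rejected:\n  " + "\n  ".join(errors))
    return records


def write_reference(records: Iterable[TRNARecord], path: str | Path) -> None:
    """Write records in the same 3-line dialect, bit-exactly re-parseable."""
    out: list[str] = []
    for rec in records:
        header = f">{rec.id} {rec.amino_acid} {rec.anticodon}"
        if rec.precursor is not None:
            header += f" precursor_trailer={rec.precursor.trailer_seq}"
        out.append(header)
        out.append(rec.mature_seq)
        out.append(rec.structure)
    Path(path).write_text("\n".join(out) + "\n")
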