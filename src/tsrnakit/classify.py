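"""tsRNA classification and systematic nomenclature.

Six fragment types are distinguished by where a fragment's endpoints fall
on its source tRNA:

* **tRF-1** — from the U-rich 3' trailer of the precursor transcript;
* **tRF-5** — 5'-anchored on the mature tRNA, ending before the anticodon
  loop (within the D-arm region);
* **tiRNA-5** — 5'-anchored, ending in or beyond the anticodon loop
  (a stress-induced 5' half);
* **tRF-3** — 3'-anchored (CCA terminus), starting after the anticodon loop
  (within the T-arm region);
* **tiRNA-3** — 3'-anchored, starting in or before the anticodon loop
  (a 3' half);
* **i-tRF** — anchored at neither mature end.

Each distinct fragment sequence receives a systematic name of the form
``<organism>-<type code>-<amino acid>-<length><variant>``, e.g.
``rno-tRFi-Ser-25a``: a rat internal tRF of a serine tRNA family, 25 nt,
the most abundant ('a') variant of that (type, family, length) group.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .reference import TRNARecord


class TsRNAType(str, Enum):
    TRF1 = "tRF-1"
    TRF3 = "tRF-3"
    TRF5 = "tRF-5"
    ITRF = "i-tRF"
    TIRNA3 = "tiRNA-3"
    TIRNA5 = "tiRNA-5"


TYPE_CODES: dict[TsRNAType, str] = {
    TsRNAType.TIRNA5: "tiR5",
    TsRNAType.TIRNA3: "tiR3",
    TsRNAType.TRF5: "tRF5",
    TsRNAType.TRF3: "tRF3",
    TsRNAType.ITRF: "tRFi",
    TsRNAType.TRF1: "tRF1",
}
CODE_TYPES = {code: t for t, code in TYPE_CODES.items()}

# maximum trailer-coordinate start (1-based) for a trailer hit to count as
# tRF-1: within 2 nt of the mature 3' boundary
TRF1_MAX_TRAILER_START = 3


@dataclass(frozen=True)
class FragmentAlignment:
    """One forward-strand substitution-only hit of a read in tRNA space."""

    read_seq: str
    trna_id: str
    region: str               # "mature" | "trailer"
    start: int                # 1-based closed, on the region's coordinates
    end: int
    mismatches: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end}]")
        if self.end - self.start + 1 != len(self.read_seq):
            raise ValueError("interval length != read length")
        if self.region not in ("mature", "trailer"):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class TsRNAName:
    organism: str
    type_code: str
    amino_acid: str
    length: int
    variant: str

    def render(self) -> str:
        return f"{self.organism}-{self.type_code}-{self.amino_acid}-{self.length}{self.variant}"


@dataclass
class TsRNAFragment:
    sequence: str
    type: TsRNAType
    amino_acid: str
    variant: str
    name: str
    source_trna_ids: frozenset[str]

    @property
    def length(self) -> int:
        return len(self.sequence)


class AlignmentStats:
    """Tallies kept per mapping run."""

    def __init__(self) -> None:
        self.n_reads = 0
        self.n_aligned = 0
        self.n_unaligned = 0


def _hits(read: str, ref: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(0-based offset, mismatches) for every placement of read in ref."""
    out = []
    n, m = len(ref), len(read)
    if max_mismatch == 0:
        pos = ref.find(read)
        while pos != -1:
            out.append((pos, 0))
            pos = ref.find(read, pos + 1)
        return out
    for off in range(n - m + 1):
        mm = 0
        for a, b in zip(read, ref[off:off + m]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            out.append((off, mm))
    return out


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def map_reads(
    reads: Iterable[str],
    references: Sequence[TRNARecord],
    max_mismatch: int = 0,
    stats: Optional[AlignmentStats] = None,
) -> list[FragmentAlignment]:
    """Exhaustively align read sequences to mature tRNAs and 3' trailers.

    Forward strand only, substitutions only; every occurrence in every
    reference is reported. Reads with zero hits anywhere increment the
    unaligned counter.
    """
    if not references:
        raise ValueError("empty reference set")
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    alignments: list[FragmentAlignment] = []
    for raw in reads:
        read = _rna(raw)
        if stats is not None:
            stats.n_reads += 1
        found = False
        for rec in references:
            for off, mm in _hits(read, rec.mature_seq, max_mismatch):
                alignments.append(FragmentAlignment(
                    read_seq=read, trna_id=rec.id, region="mature",
                    start=off + 1, end=off + len(read), mismatches=mm))
                found = True
            if rec.precursor is not None:
                trailer = rec.precursor.trailer_seq
                for off, mm in _hits(read, trailer, max_mismatch):
                    alignments.append(FragmentAlignment(
                        read_seq=read, trna_id=rec.id, region="trailer",
                        start=off + 1, end=off + len(read), mismatches=mm))
                    found = True
        if stats is not None:
            if found:
                stats.n_aligned += 1
            else:
                stats.n_unaligned += 1
    return alignments


def classify(
    aln: FragmentAlignment,
    rec: TRNARecord,
    tol5: int = 1,
    tol3: int = 3,
) -> Optional[TsRNAType]:
    """Classify one alignment into a tsRNA type, or None if excluded.

    ``tol5`` is the slack on the 5' anchor (default 1: must start at
    position 1); ``tol3`` allows 3'-anchored fragments to stop short of the
    CCA terminus by up to 3 nt. Full-length molecules (both ends anchored)
    are not tsRNAs and return None, as do trailer hits that start more than
    2 nt into the trailer (spurious precursor hits rather than tRF-1).
    """
    if aln.region == "trailer":
        if rec.precursor is None:
            raise ValueError(f"{rec.id}: trailer alignment but no precursor")
        if aln.end > len(rec.precursor.trailer_seq):
            raise ValueError(f"{rec.id}: trailer alignment out of bounds")
        return TsRNAType.TRF1 if aln.start <= TRF1_MAX_TRAILER_START else None
    L = len(rec.mature_seq)
    if aln.end > L:
        raise ValueError(f"{rec.id}: alignment [{aln.start},{aln.end}] outside 1..{L}")
    ac = rec.loops.anticodon_loop
    anchored5 = aln.start <= tol5
    anchored3 = aln.end >= L - tol3
    if anchored5 and anchored3:
        return None                      # full-length tRNA, not a fragment
    if anchored5:
        return TsRNAType.TRF5 if aln.end < ac.start else TsRNAType.TIRNA5
    if anchored3:
        return TsRNAType.TRF3 if aln.start > ac.end else TsRNAType.TIRNA3
    return TsRNAType.ITRF


_TYPE_ORDER = [TsRNAType.TIRNA5, TsRNAType.TIRNA3, TsRNAType.TRF5,
               TsRNAType.TRF3, TsRNAType.ITRF, TsRNAType.TRF1]


def _majority(values: list[str] | list[TsRNAType], order_key) -> str | TsRNAType:
    counts = Counter(values)
    # deterministic: highest count, ties broken by order_key ascending
    top = max(counts.values())
    tied = sorted((v for v, c in counts.items() if c == top), key=order_key)
    return tied[0]


def collapse_and_name(
    classified: Sequence[tuple[FragmentAlignment, TRNARecord, TsRNAType]],
    organism: str,
    abundance: Mapping[str, float],
) -> list[TsRNAFragment]:
    """Collapse alignments to distinct fragment sequences and name them.

    A fragment is a distinct read sequence, counted once however many tRNA
    genes it hits. Its amino-acid family is decided by majority vote over
    its hits (alphabetical tie-break) and its type likewise (fixed
    type-order tie-break). Within each (type, family, length) group,
    variant letters a, b, c… go to fragments in order of descending total
    abundance, ties broken by lexicographic sequence.
    """
    by_seq: dict[str, list[tuple[FragmentAlignment, TRNARecord, TsRNAType]]] = \
        defaultdict(list)
    for aln, rec, ftype in classified:
        by_seq[aln.read_seq].append((aln, rec, ftype))

    provisional: list[tuple[str, TsRNAType, str, frozenset[str]]] = []
    for seq, entries in by_seq.items():
        if seq not in abundance:
            raise ValueError(f"no abundance for sequence {seq[:20]}…")
        aa = _majority([rec.amino_acid for _, rec, _ in entries], str)
        ftype = _majority([t for _, _, t in entries], _TYPE_ORDER.index)
        sources = frozenset(rec.id for _, rec, _ in entries)
        provisional.append((seq, ftype, aa, sources))

    groups: dict[tuple[TsRNAType, str, int], list[tuple[str, frozenset[str]]]] = \
        defaultdict(list)
    for seq, ftype, aa, sources in provisional:
        groups[(ftype, aa, len(seq))].append((seq, sources))

    fragments: list[TsRNAFragment] = []
    for (ftype, aa, length), members in groups.items():
        members.sort(key=lambda m: (-abundance[m[0]], m[0]))
        if len(members) > 26:
            raise ValueError(
                f"{len(members)} variants in group ({ftype.value}, {aa}, "
                f"{length}); names limited to 26")
        for i, (seq, sources) in enumerate(members):
            variant = chr(ord("a") + i)
            name = TsRNAName(organism, TYPE_CODES[ftype], aa, length,
                             variant).render()
            fragments.append(TsRNAFragment(
                sequence=seq, type=ftype, amino_acid=aa, variant=variant,
                name=name, source_trna_ids=sources))
    fragments.sort(key=lambda f: f.name)
    return fragments


_NAME_RE = re.compile(
    r"^(?P<org>[A-Za-z]+)-(?P<code>tiR5|tiR3|tRF5|tRF3|tRFi|tRF1)-"
    r"(?P<aa>[A-Z][a-z]{2})-(?P<len>\d+)(?P<var>[a-z])$")


def parse_name(name: str) -> TsRNAName:
    """Parse a systematic tsRNA name; render(parse(x)) == x."""
    m = _NAME_RE.match(name)
    if m is None:
        for code in ("tiR5", "tiR3", "tRF5", "tRF3", "tRFi", "tRF1"):
            if f"-{code}-" in name:
                raise ValueError(f"malformed tsRNA name {name!r}")
        raise ValueError(f"unknown type code in tsRNA name {name!r}")
    return TsRNAName(
        organism=m.group("org"),
        type_code=m.group("code"),
        amino_acid=m.group("aa"),
        length=int(m.group("len")),
        variant=m.group("var"),
    )
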