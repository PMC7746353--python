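"""Consensus tsRNA → mRNA target prediction.

tsRNAs can act like miRNAs: their 5' nucleotides pair antisense with sites
in mRNA 3'UTRs. Three independent rule engines mirror the three classes of
miRNA target predictors, and a gene is a consensus target only when a site
passes all three simultaneously:

1. **Seed matching** — 7-nt windows are slid one nt at a time along the
   tsRNA; a site is an exact 3'UTR match of a window's reverse complement
   (7mer), or of positions 2–7's reverse complement followed by an A
   opposite position 1 (7mer-1a).
2. **Pairing filter** — perfect Watson–Crick pairing at tsRNA positions
   2–11 against the site, and at most 4 mismatches at positions 12–21
   (G:U wobble counts as a mismatch here).
3. **Duplex stability** — a nearest-neighbour stacking model scores the
   best ungapped antiparallel registration of the tsRNA against the site;
   the duplex must reach a minimum free energy below −20 kcal/mol.

Positions on the tsRNA are numbered 5'→3' from 1, miRNA-style; the UTR
site opposes them antiparallel, so tsRNA position 1 faces the site's
3'-most base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}

# Watson-Crick nearest-neighbour stack free energies, kcal/mol at 37 °C
# (Xia et al. 1998 RNA parameters). Key: 5'-XY-3' paired with 3'-WZ-5',
# stored as (XY, WZ); the table is closed under strand swap.
_WC_STACKS = {
    ("AA", "UU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08,
    ("CA", "GU"): -2.11,
    ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
}
# weakly stabilising flat value for any stack involving a G:U wobble pair
GU_STACK_ENERGY = -0.5


def _rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)} in sequence")
    return s


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(_rna(seq)))


def _is_wc(a: str, b: str) -> bool:
    return _COMPLEMENT[a] == b


def _pairs(a: str, b: str, wobble: bool) -> bool:
    return _is_wc(a, b) or (wobble and (a, b) in _WOBBLE)


def _stack_energy(x1: str, y1: str, x2: str, y2: str) -> float:
    """Energy of stacking pair (x2:y2) on pair (x1:y1), strand-swap symmetric."""
    key = (x1 + x2, y1 + y2)
    if key in _WC_STACKS:
        return _WC_STACKS[key]
    swapped = (y2 + y1, x2 + x1)    # same stack read from the other strand
    if swapped in _WC_STACKS:
        return _WC_STACKS[swapped]
    return GU_STACK_ENERGY          # stack involving ≥1 wobble pair


@dataclass
class DuplexModel:
    """Nearest-neighbour duplex free-energy model (ungapped, antiparallel)."""

    init_penalty: float = 4.09       # duplex initiation, kcal/mol
    mismatch_penalty: float = 1.0    # per unpaired opposing position
    allow_gu_wobble: bool = True

    def pair_ok(self, a: str, b: str) -> bool:
        return _pairs(a, b, self.allow_gu_wobble)


@dataclass
class TargetConfig:
    seed_window: int = 7
    seed_start: int = 2              # seed region = positions 2..7
    seed_end: int = 7
    perfect_span: tuple[int, int] = (2, 11)
    mismatch_span: tuple[int, int] = (12, 21)
    max_mismatches: int = 4
    mfe_threshold: float = -20.0     # kcal/mol


@dataclass
class SeedSite:
    """One seed-anchored candidate site on a UTR."""

    window_offset: int        # 0-based offset of the 7-nt window on the tsRNA
    utr_position: int         # 1-based start of the matched site on the UTR
    seed_evidence: str        # "7mer" | "7mer-1a"


@dataclass
class TargetCall:
    tsrna_name: str
    gene_id: str
    utr_position: int
    seed_evidence: str
    pairing_pass: bool
    pairing_mismatches: int
    mfe: float
    consensus: bool


def enumerate_seed_windows(tsrna_seq: str, window: int = 7) -> list[tuple[int, str]]:
    """All (0-based offset, window) 7-mers of the tsRNA, 5'→3'."""
    seq = _rna(tsrna_seq)
    if len(seq) < window:
        raise ValueError(
            f"tsRNA of {len(seq)} nt is shorter than the {window}-nt window")
    return [(i, seq[i:i + window]) for i in range(len(seq) - window + 1)]


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    pos = haystack.find(needle)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)


def seed_match_sites(tsrna_seq: str, utr_seq: str,
                     cfg: TargetConfig | None = None) -> list[SeedSite]:
    """Seed-anchored sites of a tsRNA on one UTR.

    For each 7-nt window, a 7mer site is an exact UTR match of the window's
    reverse complement; a 7mer-1a site matches the reverse complement of
    window positions 2–7 with an A on the UTR opposite window position 1.
    Sites are deduplicated by (window offset, UTR position); a position
    matching both patterns reports the stronger 7mer evidence.
    """
    cfg = cfg or TargetConfig()
    tsrna = _rna(tsrna_seq)
    utr = _rna(utr_seq)
    seen: dict[tuple[int, int], str] = {}
    for off, window in enumerate_seed_windows(tsrna, cfg.seed_window):
        full = revcomp(window)
        for pos in _find_all(utr, full):
            seen[(off, pos + 1)] = "7mer"
        # 7mer-1a: revcomp of window[2..7] then an A opposite position 1
        pattern = revcomp(window[1:]) + "A"
        for pos in _find_all(utr, pattern):
            seen.setdefault((off, pos + 1), "7mer-1a")
    return [SeedSite(window_offset=o, utr_position=p, seed_evidence=ev)
            for (o, p), ev in sorted(seen.items())]


def pairing_filter(tsrna_seq: str, utr_site_seq: str,
                   cfg: TargetConfig | None = None) -> tuple[bool, int]:
    """Apply the perfect-2–11 / ≤4-mismatches-12–21 duplex rule.

    ``utr_site_seq`` is the antiparallel opposing window, 5'→3', so tsRNA
    position 1 faces its last base. G:U wobble counts as a mismatch. For
    tsRNAs (or sites) covering fewer than 21 positions the mismatch span is
    truncated and its allowance prorated as floor(4 × span/10); positions
    with no opposing base at all are outside the evaluated span.
    Returns (pass, mismatches in the 12–21 span).
    """
    cfg = cfg or TargetConfig()
    tsrna = _rna(tsrna_seq)
    site = _rna(utr_site_seq)
    span = min(len(tsrna), len(site), cfg.mismatch_span[1])

    def opposing(i: int) -> str:
        return site[len(site) - i]      # tsRNA position i ↔ site index -i

    p_lo, p_hi = cfg.perfect_span
    for i in range(p_lo, min(p_hi, span) + 1):
        if not _is_wc(tsrna[i - 1], opposing(i)):
            return False, -1
    if span < p_hi:
        return False, -1                # cannot establish perfect pairing
    m_lo, m_hi = cfg.mismatch_span
    hi = min(m_hi, span)
    mism = sum(1 for i in range(m_lo, hi + 1)
               if not _is_wc(tsrna[i - 1], opposing(i)))
    window = max(hi - m_lo + 1, 0)
    allowed = (cfg.max_mismatches * window) // (m_hi - m_lo + 1)
    return mism <= allowed, mism


def duplex_mfe(tsrna_seq: str, utr_site_seq: str,
               model: DuplexModel | None = None) -> float:
    """Minimum free energy of the best ungapped antiparallel duplex.

    All registrations of the tsRNA against the reversed site are scored:
    initiation penalty, plus nearest-neighbour stack energies over runs of
    adjacent pairs, plus a penalty per opposed-but-unpaired position. The
    most negative total wins; more negative = more stable.
    """
    model = model or DuplexModel()
    a = _rna(tsrna_seq)
    b = _rna(utr_site_seq)[::-1]     # antiparallel: walk the site 3'→5'
    if len(a) < 7 or len(b) < 7:
        raise ValueError("both sequences must be ≥ 7 nt")
    best = model.init_penalty        # zero-pair registration
    for shift in range(-(len(b) - 1), len(a)):
        lo = max(0, shift)
        hi = min(len(a), len(b) + shift)
        if hi - lo < 2:
            continue
        energy = model.init_penalty
        prev_paired = False
        for i in range(lo, hi):
            x, y = a[i], b[i - shift]
            if model.pair_ok(x, y):
                if prev_paired:
                    energy += _stack_energy(a[i - 1], b[i - 1 - shift], x, y)
                prev_paired = True
            else:
                energy += model.mismatch_penalty
                prev_paired = False
        best = min(best, energy)
    return best


def site_region(utr_seq: str, site: SeedSite, tsrna_len: int,
                up_to: int = 21) -> str:
    """UTR subsequence opposing tsRNA positions 1..min(up_to, tsrna_len).

    The seed match fixes the register: with the window at tsRNA offset
    ``o`` matched at UTR position ``p`` (1-based), tsRNA position i opposes
    UTR position p + o + 6 − (i − 1). The returned slice is clipped to the
    UTR bounds and is 5'→3' (so position 1 opposes its last base).
    """
    utr = _rna(utr_seq)
    o, p = site.window_offset, site.utr_position
    hi = p + o + 6                      # opposes tsRNA position 1
    lo = hi - min(up_to, tsrna_len) + 1
    lo = max(lo, 1)
    hi = min(hi, len(utr))
    return utr[lo - 1:hi]


def consensus_targets(
    tsrnas: Mapping[str, str],
    utrs: Mapping[str, str],
    cfg: TargetConfig | None = None,
    model: DuplexModel | None = None,
) -> list[TargetCall]:
    """Run all three engines over every (tsRNA, UTR) pair.

    Each seed-anchored site is annotated with the pairing filter verdict
    and duplex MFE; the consensus flag requires all three. The consensus
    gene set for a tsRNA is the genes carrying ≥1 consensus site.
    """
    if not utrs:
        raise ValueError("empty UTR collection")
    cfg = cfg or TargetConfig()
    model = model or DuplexModel()
    calls: list[TargetCall] = []
    for ts_name, ts_seq in tsrnas.items():
        ts_seq = _rna(ts_seq)
        for gene, utr in utrs.items():
            for site in seed_match_sites(ts_seq, utr, cfg):
                region = site_region(utr, site, len(ts_seq))
                # a window matched so close to the UTR 3' end that the tsRNA
                # 5' positions have nothing to oppose cannot satisfy rule (i)
                clipped5 = site.utr_position + site.window_offset + 6 > len(utr)
                if clipped5 or len(region) < cfg.perfect_span[1]:
                    ok, mism = False, -1
                else:
                    ok, mism = pairing_filter(ts_seq, region, cfg)
                mfe = duplex_mfe(ts_seq, region, model) if len(region) >= 7 \
                    else 0.0
                calls.append(TargetCall(
                    tsrna_name=ts_name, gene_id=gene,
                    utr_position=site.utr_position,
                    seed_evidence=site.seed_evidence,
                    pairing_pass=ok, pairing_mismatches=mism, mfe=mfe,
                    consensus=ok and mfe < cfg.mfe_threshold))
    return calls


def consensus_gene_sets(calls: Sequence[TargetCall]) -> dict[str, set[str]]:
    """Per-tsRNA consensus target gene sets."""
    out: dict[str, set[str]] = {}
    for call in calls:
        out.setdefault(call.tsrna_name, set())
        if call.consensus:
            out[call.tsrna_name].add(call.gene_id)
    return out
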