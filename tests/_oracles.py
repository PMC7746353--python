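"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from the rule definitions, not by
calling the package code paths it checks.
"""

from __future__ import annotations

from math import comb

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# --- dot-bracket hairpins ---------------------------------------------------

def hairpins_by_stack(structure: str) -> list[tuple[int, int]]:
    """Hairpin loops via an explicit pairing stack (1-based closed spans)."""
    s = structure.replace(">", "(").replace("<", ")")
    stack, partner = [], {}
    for i, c in enumerate(s, 1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            partner[j], partner[i] = i, j
    loops = []
    for i in sorted(partner):
        j = partner[i]
        if j > i and all(s[k - 1] == "." for k in range(i + 1, j)) and j > i + 1:
            loops.append((i + 1, j - 1))
    return loops


# --- six-way fragment classification ----------------------------------------

def classify_case(start: int, end: int, length: int,
                  ac_start: int, ac_end: int,
                  tol5: int = 1, tol3: int = 3) -> str | None:
    """Exhaustive case enumeration of the mature-fragment type rules."""
    a5 = start <= tol5
    a3 = end >= length - tol3
    if a5 and a3:
        return None
    if a5:
        return "tRF-5" if end < ac_start else "tiRNA-5"
    if a3:
        return "tRF-3" if start > ac_end else "tiRNA-3"
    return "i-tRF"


# --- seed matching ----------------------------------------------------------

def seed_sites_bruteforce(tsrna: str, utr: str) -> dict[tuple[int, int], str]:
    """All (window offset, 1-based UTR pos) → evidence, by full scanning."""
    found: dict[tuple[int, int], str] = {}
    for off in range(len(tsrna) - 6):
        window = tsrna[off:off + 7]
        for pos in range(len(utr) - 6):
            if utr[pos:pos + 7] == rc(window):
                found[(off, pos + 1)] = "7mer"
    for off in range(len(tsrna) - 6):
        window = tsrna[off:off + 7]
        pat = rc(window[1:]) + "A"
        for pos in range(len(utr) - 6):
            if utr[pos:pos + 7] == pat:
                found.setdefault((off, pos + 1), "7mer-1a")
    return found


# --- nearest-neighbour duplex energy ----------------------------------------

_XIA = {
    ("AA", "UU"): -0.93, ("AU", "UA"): -1.10, ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08, ("CA", "GU"): -2.11, ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35, ("CG", "GC"): -2.36, ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
}


def stack_lookup(x1: str, y1: str, x2: str, y2: str, gu: float = -0.5) -> float:
    key = (x1 + x2, y1 + y2)
    if key in _XIA:
        return _XIA[key]
    alt = (y2 + y1, x2 + x1)
    if alt in _XIA:
        return _XIA[alt]
    return gu


def mfe_summation(a: str, b: str, init: float = 4.09, mm: float = 1.0,
                  wobble: bool = True) -> float:
    """Plain enumeration of ungapped antiparallel registrations."""
    def paired(x: str, y: str) -> bool:
        if _COMP[x] == y:
            return True
        return wobble and {x, y} == {"G", "U"}

    brev = b[::-1]
    best = init
    for shift in range(-(len(brev) - 1), len(a)):
        lo, hi = max(0, shift), min(len(a), len(brev) + shift)
        if hi - lo < 2:
            continue
        e = init
        run = False
        for i in range(lo, hi):
            x, y = a[i], brev[i - shift]
            if paired(x, y):
                if run:
                    e += stack_lookup(a[i - 1], brev[i - 1 - shift], x, y)
                run = True
            else:
                e += mm
                run = False
        best = min(best, e)
    return best


# --- statistics -------------------------------------------------------------

def pooled_t_textbook(x, y):
    """Two-sample pooled-variance t statistic and two-sided P, by formula."""
    from scipy.stats import t as tdist

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    ssx = sum((v - mx) ** 2 for v in x)
    ssy = sum((v - my) ** 2 for v in y)
    df = nx + ny - 2
    sp2 = (ssx + ssy) / df
    se = (sp2 * (1 / nx + 1 / ny)) ** 0.5
    if se == 0:
        return (0.0, 1.0) if mx == my else (float("inf"), 0.0)
    t = (mx - my) / se
    return t, 2 * tdist.sf(abs(t), df)


def hypergeom_tail_enumeration(k: int, n_universe: int, n_term: int,
                               n_list: int) -> float:
    """Upper tail P(X ≥ k) by exact combinatorial summation."""
    denom = comb(n_universe, n_list)
    total = 0
    for i in range(k, min(n_term, n_list) + 1):
        total += comb(n_term, i) * comb(n_universe - n_term, n_list - i)
    return total / denom
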