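"""Synthetic study generator: references, reads, UTRs, DE table, pathways.

Everything the pipeline consumes can be generated here with known ground
truth, emulating a two-group (sham vs ICH) rat brain small-RNA study:

* cloverleaf tRNA references (76 nt, CCA-appended, U-rich 3' trailer) for
  a panel of amino-acid families, in the structure-annotated dialect;
* adapter-ligated FASTQ reads whose fragment endpoints are drawn
  conditional on tsRNA type, with the type mixture calibrated to reported
  brain-tissue composition (tiRNA-5 38.36%, tRF-3 21.29%, tRF-1 0.12%,
  the remainder split over tRF-5 / i-tRF / tiRNA-3) and lengths in the
  16–23 / 29–36 / 49 nt bands;
* negative-binomial replicate counts with planted fold changes between
  groups;
* 3'UTRs with planted consensus target sites (and seed-only decoys), a
  DE-mRNA table with a planted overlap, and a gene→pathway annotation with
  one planted enriched term.

One RNG stream per artifact (references / reads / targets) is derived from
the master seed so perturbing one stage never reshuffles the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import TsRNAType
from .readprep import FastqRead, write_fastq
from .reference import TRNARecord
from .targets import DuplexModel, TargetConfig, duplex_mfe, revcomp

# 76-nt canonical cloverleaf: acceptor stem, D-arm, anticodon arm,
# variable region, T-arm, discriminator + CCA
CLOVERLEAF = ("(((((((..((((........))))."
              "(((((.......)))))"
              "....."
              "(((((.......)))))"
              ")))))))"
              "....")
assert len(CLOVERLEAF) == 76

ANTICODONS = {
    "Ala": "AGC", "Arg": "ACG", "Cys": "GCA", "Gln": "CUG", "Glu": "CUC",
    "Gly": "GCC", "Leu": "CAA", "Lys": "CUU", "Met": "CAU", "Ser": "AGA",
}
_ANTICODON_SPAN = (34, 36)          # centre of the anticodon loop [32, 38]
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = np.array(list("ACGU"))

DEFAULT_TYPE_MIXTURE: dict[TsRNAType, float] = {
    TsRNAType.TIRNA5: 0.3836,
    TsRNAType.TRF3: 0.2129,
    TsRNAType.TRF1: 0.0012,
    # remaining mass split evenly over the types with no reported share
    TsRNAType.TRF5: 0.4023 / 3,
    TsRNAType.ITRF: 0.4023 / 3,
    TsRNAType.TIRNA3: 0.4023 / 3,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator."""

    rng_seed: int = 0
    organism: str = "rno"
    families: tuple[str, ...] = tuple(sorted(ANTICODONS))
    n_trnas_per_family: int = 2
    type_mixture: dict[TsRNAType, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIXTURE))
    fragments_per_type: int = 6
    n_replicates: int = 3
    depth: int = 50_000              # reads per sample
    n_de: int = 8                    # fragments with planted fold change
    de_log2fc: float = 2.0
    de_min_abundance: float = 0.002  # detectability floor for planted DE
    noise_cv: float = 0.1
    seq_error_rate: float = 0.0
    adapter3: str = "AGATCGGAAGAGCACACGTCT"
    adapter5: str = ""
    # target-side inputs
    n_genes: int = 60
    utr_len_range: tuple[int, int] = (200, 2000)
    n_planted_sites: int = 10
    n_decoy_sites: int = 5
    n_de_genes: int = 20
    n_overlap: int = 6               # planted target genes also DE
    pathway_sizes: tuple[int, ...] = (15, 12, 10, 8, 5)

    def __post_init__(self) -> None:
        total = sum(self.type_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type mixture sums to {total}, expected 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_overlap > min(self.n_planted_sites, self.n_de_genes):
            raise ValueError("n_overlap exceeds planted targets or DE genes")

    def stream(self, artifact: str) -> np.random.Generator:
        idx = {"references": 0, "reads": 1, "targets": 2}[artifact]
        return np.random.default_rng([self.rng_seed, idx])


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic data."""

    fragments: pd.DataFrame          # seq, type, source, means, log2fc
    sites: pd.DataFrame              # gene, tsrna, position, consensus flag
    de_genes: set[str]
    target_genes: set[str]
    enriched_term: str


def _fill_structure(rng: np.random.Generator, structure: str,
                    anticodon: str) -> str:
    """Random bases consistent with the scaffold pairing; CCA 3' end."""
    from .reference import pair_table

    pairs = pair_table(structure)
    n = len(structure)
    seq = [""] * n
    for i in range(1, n + 1):
        if seq[i - 1]:
            continue
        base = str(rng.choice(_BASES))
        seq[i - 1] = base
        if i in pairs:
            seq[pairs[i] - 1] = _COMP[base]
    lo, hi = _ANTICODON_SPAN
    seq[lo - 1:hi] = list(anticodon)
    seq[-3:] = list("CCA")
    return "".join(seq)


def _u_rich_trailer(rng: np.random.Generator, lo: int = 16, hi: int = 20) -> str:
    """Random trailer with U fraction ≥ 0.5 by construction."""
    n = int(rng.integers(lo, hi + 1))
    bases = [str(b) for b in rng.choice(_BASES, size=n, p=[0.1, 0.15, 0.05, 0.7])]
    need = (n + 1) // 2 - bases.count("U")
    if need > 0:
        non_u = [i for i, b in enumerate(bases) if b != "U"]
        for i in rng.choice(non_u, size=need, replace=False):
            bases[i] = "U"
    return "".join(bases)


def simulate_references(cfg: SimConfig) -> list[TRNARecord]:
    """Generate the cloverleaf tRNA reference panel (deterministic by seed)."""
    rng = cfg.stream("references")
    records = []
    for family in cfg.families:
        for k in range(1, cfg.n_trnas_per_family + 1):
            seq = _fill_structure(rng, CLOVERLEAF, ANTICODONS[family])
            trailer = _u_rich_trailer(rng)
            header = f">{cfg.organism}-tRNA-{family}-{k} {family} " \
                     f"{ANTICODONS[family]} precursor_trailer={trailer}"
            # route through the parser so loops are located and validated
            from .reference import _build_record
            records.append(_build_record(header, seq, CLOVERLEAF))
    return records


_ENDPOINT_RULES = {
    # type → (draw start, draw end) given record geometry; 1-based closed
    TsRNAType.TRF5: lambda rng, rec: (1, int(rng.integers(16, 24))),
    TsRNAType.TIRNA5: lambda rng, rec: (1, int(rng.integers(
        rec.loops.anticodon_loop.start, min(rec.loops.anticodon_loop.end, 36) + 1))),
    TsRNAType.TRF3: lambda rng, rec: (int(rng.integers(
        len(rec) - 22, len(rec) - 15)), len(rec)),
    TsRNAType.TIRNA3: lambda rng, rec: (int(rng.integers(
        28, rec.loops.anticodon_loop.end + 1)), len(rec)),
    TsRNAType.ITRF: lambda rng, rec: (lambda s, l: (s, s + l - 1))(
        int(rng.integers(5, 41)), int(rng.integers(16, 24))),
}


def _draw_fragment(rng: np.random.Generator, ftype: TsRNAType,
                   rec: TRNARecord) -> tuple[str, int, int]:
    if ftype is TsRNAType.TRF1:
        trailer = rec.precursor.trailer_seq
        return trailer, 1, len(trailer)
    start, end = _ENDPOINT_RULES[ftype](rng, rec)
    return rec.mature_seq[start - 1:end], start, end


def build_fragment_catalog(
    cfg: SimConfig,
    references: Sequence[TRNARecord],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Distinct fragments with true type, source and relative abundance."""
    rng = rng if rng is not None else cfg.stream("reads")
    rows = []
    seen: set[str] = set()
    for ftype, weight in cfg.type_mixture.items():
        if weight <= 0:
            continue
        n_frag = cfg.fragments_per_type if ftype is not TsRNAType.TRF1 else 1
        drawn = 0
        attempts = 0
        while drawn < n_frag:
            attempts += 1
            if attempts > 100 * n_frag:
                raise RuntimeError(f"cannot draw distinct {ftype.value} fragments")
            rec = references[int(rng.integers(len(references)))]
            seq, start, end = _draw_fragment(rng, ftype, rec)
            if seq in seen:
                continue
            seen.add(seq)
            rows.append({"sequence": seq, "type": ftype.value,
                         "source_trna": rec.id, "start": start, "end": end,
                         "type_weight": weight,
                         "within_weight": float(rng.gamma(5.0))})
            drawn += 1
    cat = pd.DataFrame(rows)
    cat["within_weight"] /= cat.groupby("type")["within_weight"].transform("sum")
    cat["abundance"] = cat["type_weight"] * cat["within_weight"]
    return cat


def plant_fold_changes(cfg: SimConfig, catalog: pd.DataFrame) -> pd.DataFrame:
    """Assign planted log2 fold changes to low-mass detectable fragments.

    Effects go to the smallest mature fragments above the detectability
    floor so the planted set carries little library mass: TPM is
    compositional, and concentrating fold changes on dominant fragments
    would shift every null fragment's TPM by the group mass ratio.
    Up/down assignments alternate.
    """
    cat = catalog.copy()
    cat["log2fc"] = 0.0
    eligible = cat.index[(cat["type"] != TsRNAType.TRF1.value)
                         & (cat["abundance"] >= cfg.de_min_abundance)]
    ranked = cat.loc[eligible].sort_values(
        "abundance", ascending=True).index[:cfg.n_de]
    signs = np.where(np.arange(len(ranked)) % 2 == 0, 1.0, -1.0)
    cat.loc[ranked, "log2fc"] = signs * cfg.de_log2fc
    cat["mean_sham"] = cat["abundance"] * cfg.depth
    cat["mean_ich"] = cat["mean_sham"] * 2.0 ** cat["log2fc"]
    return cat


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Negative-binomial draws parameterised by mean and CV (r = 1/cv²)."""
    mean = np.asarray(mean, dtype=float)
    if cv <= 0:
        return np.round(mean).astype(np.int64)
    r = 1.0 / cv ** 2
    p = r / (r + mean)
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def simulate_counts(
    cfg: SimConfig,
    catalog: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Replicate count matrix (fragments × samples) from the truth means."""
    rng = rng if rng is not None else cfg.stream("reads")
    cols = {}
    for grp, mean_col in (("sham", "mean_sham"), ("ICH", "mean_ich")):
        for rep in range(1, cfg.n_replicates + 1):
            cols[f"{grp}_{rep}"] = _nb_counts(
                rng, catalog[mean_col].to_numpy(), cfg.noise_cv)
    return pd.DataFrame(cols, index=catalog["sequence"])


def _with_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGU" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_reads(
    cfg: SimConfig,
    references: Sequence[TRNARecord],
    outdir: str | Path | None = None,
) -> tuple[dict[str, list[FastqRead]], pd.DataFrame, pd.DataFrame]:
    """Adapter-ligated FASTQ reads per sample plus the fragment truth table.

    Returns (sample → reads, truth catalog, true count matrix); when
    ``outdir`` is given, one ``<sample>.fastq`` per sample is also written.
    Reads are the fragment sequence (with optional substitution errors)
    followed by the full 3' adapter, shuffled deterministically.
    """
    rng = cfg.stream("reads")
    catalog = plant_fold_changes(cfg, build_fragment_catalog(cfg, references, rng))
    counts = simulate_counts(cfg, catalog, rng)
    samples: dict[str, list[FastqRead]] = {}
    for sample in counts.columns:
        reads: list[FastqRead] = []
        for seq, n in counts[sample].items():
            for j in range(int(n)):
                insert = _with_errors(rng, seq, cfg.seq_error_rate)
                full = (cfg.adapter5 + insert + cfg.adapter3).replace("U", "T")
                reads.append(FastqRead(
                    id=f"{sample}:{len(reads)}", seq=full, qual="I" * len(full)))
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]
        for k, r in enumerate(reads):
            r.id = f"{sample}:read{k}"
        samples[sample] = reads
        if outdir is not None:
            write_fastq(reads, Path(outdir) / f"{sample}.fastq")
    return samples, catalog, counts


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def simulate_targets(
    cfg: SimConfig,
    tsrna_seqs: Mapping[str, str],
    target_cfg: TargetConfig | None = None,
    model: DuplexModel | None = None,
) -> tuple[dict[str, str], pd.DataFrame, dict[str, set[str]], SimTruth]:
    """UTRs with planted sites, DE-mRNA table and pathway annotation.

    Planted consensus sites are exact antiparallel complements of a
    tsRNA's first 21 nt (perfect 2–11 pairing, 0 mismatches 12–21) whose
    duplex energy clears the MFE threshold; an AU-rich tsRNA that cannot
    clear it is skipped in favour of another, with a bounded retry budget.
    Decoy sites satisfy only a mid-sequence seed match. The DE table marks
    ``n_de_genes`` genes significant, ``n_overlap`` of which are planted
    target genes, and the annotation groups genes into terms of
    ``pathway_sizes`` with the first term enriched for validated genes.
    """
    target_cfg = target_cfg or TargetConfig()
    model = model or DuplexModel()
    rng = cfg.stream("targets")
    names = list(tsrna_seqs)
    usable = [n for n in names
              if len(tsrna_seqs[n]) >= target_cfg.perfect_span[1]]
    if not usable:
        raise ValueError("no tsRNA long enough to plant sites for")

    genes = [f"gene{k:04d}" for k in range(1, cfg.n_genes + 1)]
    utrs = {g: _random_seq(rng, int(rng.integers(*cfg.utr_len_range)))
            for g in genes}

    site_rows = []
    planted_genes = [str(g) for g in
                     rng.choice(genes, size=cfg.n_planted_sites, replace=False)]
    for i, gene in enumerate(planted_genes):
        site = None
        for attempt in range(20):
            ts_name = usable[(i + attempt) % len(usable)]
            ts = tsrna_seqs[ts_name].upper().replace("T", "U")
            span = min(21, len(ts))
            candidate = revcomp(ts[:span])
            if duplex_mfe(ts, candidate, model) < target_cfg.mfe_threshold:
                site = (ts_name, candidate)
                break
        if site is None:
            raise RuntimeError(
                f"no tsRNA yields a site below {target_cfg.mfe_threshold} "
                f"kcal/mol for {gene}")
        ts_name, candidate = site
        utr = utrs[gene]
        pos = int(rng.integers(30, len(utr) - len(candidate) - 30))
        utrs[gene] = utr[:pos] + candidate + utr[pos + len(candidate):]
        site_rows.append({"gene": gene, "tsrna": ts_name,
                          "position": pos + 1, "consensus": True})

    decoy_pool = [g for g in genes if g not in planted_genes]
    decoys = [str(g) for g in
              rng.choice(decoy_pool, size=cfg.n_decoy_sites, replace=False)]
    for i, gene in enumerate(decoys):
        ts_name = usable[i % len(usable)]
        ts = tsrna_seqs[ts_name].upper().replace("T", "U")
        off = min(10, len(ts) - 7)
        seed_only = revcomp(ts[off:off + 7])   # seed hit, random flanks
        utr = utrs[gene]
        pos = int(rng.integers(30, len(utr) - 7 - 30))
        utrs[gene] = utr[:pos] + seed_only + utr[pos + 7:]
        site_rows.append({"gene": gene, "tsrna": ts_name,
                          "position": pos + 1, "consensus": False})

    target_genes = set(planted_genes)
    overlap = [str(g) for g in
               rng.choice(planted_genes, size=cfg.n_overlap, replace=False)]
    non_target = [g for g in genes if g not in target_genes]
    extra_de = [str(g) for g in rng.choice(
        non_target, size=cfg.n_de_genes - cfg.n_overlap, replace=False)]
    de_genes = set(overlap) | set(extra_de)
    de_rows = []
    for g in genes:
        if g in de_genes:
            lfc = float(rng.uniform(1.0, 3.0)) * (1 if rng.random() < 0.5 else -1)
            p = float(rng.uniform(1e-6, 1e-3))
        else:
            lfc = float(rng.normal(0, 0.2))
            p = float(rng.uniform(0.1, 1.0))
        de_rows.append({"gene": g, "log2fc": lfc, "p": p})
    de_table = pd.DataFrame(de_rows)

    validated = sorted(set(overlap))
    annotation: dict[str, set[str]] = {}
    pool = [g for g in genes if g not in validated]
    rng.shuffle(pool)
    cursor = 0
    for t, size in enumerate(cfg.pathway_sizes, start=1):
        term = f"TERM{t:03d}"
        if t == 1:
            members = set(validated) | set(pool[cursor:cursor + size - len(validated)])
            cursor += max(size - len(validated), 0)
        else:
            members = set(pool[cursor:cursor + size])
            cursor += size
        annotation[term] = members

    truth = SimTruth(
        fragments=pd.DataFrame(),
        sites=pd.DataFrame(site_rows),
        de_genes=de_genes,
        target_genes=target_genes,
        enriched_term="TERM001",
    )
    return utrs, de_table, annotation, truth


def write_utrs(utrs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, seq in utrs.items():
            fh.write(f">{gene}\n{seq}\n")


def write_de_table(de_table: pd.DataFrame, path: str | Path) -> None:
    de_table.to_csv(path, sep="\t", index=False)


def write_annotation(annotation: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm_id\tterm_name\n")
        for term in sorted(annotation):
            for gene in sorted(annotation[term]):
                fh.write(f"{gene}\t{term}\t{term}\n")
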