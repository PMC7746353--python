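"""End-to-end orchestration of the tsRNA analysis workflow.

Stages mirror the study design: simulate (or load) inputs → adapter trim
and length-filter → align to tRNA space and classify/name fragments →
TPM quantification, composition and Venn → differential calling → target
prediction for the responsive tsRNAs → intersection with DE mRNAs →
pathway enrichment → network export. All outputs are plain TSV/JSON and
every write is atomic (temp file + rename); a run manifest records the
configuration hash and output hashes so reruns can be compared.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd

from . import quant
from . import simulate as sim
from . import targets as tgt
from .classify import TsRNAFragment, classify as classify_fragment, \
    collapse_and_name, map_reads
from .enrich import (build_network, degree_table, enrich as run_enrichment,
                     intersect_targets, significant_genes, write_edge_list)
from .readprep import FastqRead, ReadPrepConfig, trim_and_filter, write_summary
from .reference import TRNARecord, write_reference


def atomic_write(path: str | Path, writer: Callable[[Path], None]) -> None:
    """Write via a temp file in the destination directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    """In-memory artefacts of a full pipeline run."""

    references: list[TRNARecord]
    fragment_catalog: pd.DataFrame          # generator truth
    prep_summaries: dict[str, "object"]
    fragments: list[TsRNAFragment]
    matrix: quant.ExpressionMatrix
    composition: dict[str, pd.DataFrame]
    venn: tuple[int, int, int, int]
    diff: pd.DataFrame
    target_calls: list[tgt.TargetCall]
    consensus_genes: dict[str, set[str]]
    validated: dict[str, set[str]]
    validated_pooled: set[str]
    enrichment: pd.DataFrame
    network: "object"
    sim_truth: sim.SimTruth


def quantify_from_reads(
    samples: Mapping[str, list[FastqRead]],
    references: list[TRNARecord],
    organism: str,
    prep_cfg: ReadPrepConfig,
    max_mismatch: int = 0,
) -> tuple[list[TsRNAFragment], quant.ExpressionMatrix, dict]:
    """Trim, align, classify, collapse and quantify a set of samples.

    The TPM denominator for each sample is its total aligned tRNA reads
    (reads with ≥1 hit in mature or trailer space, whether or not the hit
    yields a tsRNA type).
    """
    prep_summaries = {}
    sample_seq_counts: dict[str, dict[str, int]] = {}
    for sample, reads in samples.items():
        passed, summary = trim_and_filter(reads, prep_cfg)
        prep_summaries[sample] = summary
        counts: dict[str, int] = defaultdict(int)
        for r in passed:
            counts[r.seq.upper().replace("T", "U")] += 1
        sample_seq_counts[sample] = dict(counts)

    distinct = sorted(set().union(*[set(c) for c in sample_seq_counts.values()]))
    alignments = map_reads(distinct, references, max_mismatch=max_mismatch)
    by_ref = {rec.id: rec for rec in references}
    classified = []
    aligned_seqs: set[str] = set()
    for aln in alignments:
        aligned_seqs.add(aln.read_seq)
        ftype = classify_fragment(aln, by_ref[aln.trna_id])
        if ftype is not None:
            classified.append((aln, by_ref[aln.trna_id], ftype))

    classified_seqs = {aln.read_seq for aln, _, _ in classified}
    abundance = {seq: sum(c.get(seq, 0) for c in sample_seq_counts.values())
                 for seq in classified_seqs}
    fragments = collapse_and_name(classified, organism, abundance)

    name_by_seq = {f.sequence: f.name for f in fragments}
    sample_names = list(samples)
    count_rows = {
        name_by_seq[seq]: [sample_seq_counts[s].get(seq, 0)
                           for s in sample_names]
        for seq in sorted(classified_seqs)}
    counts_df = pd.DataFrame.from_dict(
        count_rows, orient="index", columns=sample_names).sort_index()
    aligned_totals = {
        s: sum(c for seq, c in sample_seq_counts[s].items()
               if seq in aligned_seqs)
        for s in sample_names}
    groups = {s: s.rsplit("_", 1)[0] for s in sample_names}
    matrix = quant.compute_tpm(counts_df, aligned_totals, groups)
    return fragments, matrix, prep_summaries


def run_pipeline(
    cfg: sim.SimConfig,
    outdir: str | Path | None = None,
    write_fastq_files: bool = False,
) -> PipelineResult:
    """Run the full synthetic study end-to-end; optionally write artefacts."""
    out = Path(outdir) if outdir is not None else None

    references = sim.simulate_references(cfg)
    samples, catalog, _ = sim.simulate_reads(
        cfg, references,
        outdir=out if (out is not None and write_fastq_files) else None)

    prep_cfg = ReadPrepConfig(adapter3=cfg.adapter3, adapter5=cfg.adapter5)
    fragments, matrix, prep_summaries = quantify_from_reads(
        samples, references, cfg.organism, prep_cfg)

    ann = pd.DataFrame(
        {"type": [f.type.value for f in fragments],
         "amino_acid": [f.amino_acid for f in fragments],
         "length": [f.length for f in fragments]},
        index=[f.name for f in fragments])
    comp = quant.composition(matrix, ann)
    detected = quant.detected_sets(matrix)
    groups = list(detected)
    venn = quant.venn_counts(detected[groups[0]], detected[groups[1]]) \
        if len(groups) >= 2 else (0, 0, 0, 0)
    diff = quant.diff_test(matrix)

    sig_names = list(diff.loc[diff["significant"], "name"])
    seq_by_name = {f.name: f.sequence for f in fragments}
    responsive = {n: seq_by_name[n] for n in sig_names
                  if len(seq_by_name[n]) >= 11}
    if not responsive:        # degenerate run: fall back to top fragments
        top = diff["name"].head(5)
        responsive = {n: seq_by_name[n] for n in top
                      if len(seq_by_name[n]) >= 11}

    utrs, de_table, annotation, truth = sim.simulate_targets(cfg, responsive)
    calls = tgt.consensus_targets(responsive, utrs)
    consensus = tgt.consensus_gene_sets(calls)
    de_genes = significant_genes(enr_flag(de_table))
    validated, pooled = intersect_targets(consensus, de_genes)

    universe = set().union(*annotation.values())
    gene_list = pooled & universe
    enrichment = run_enrichment(gene_list, annotation, universe)
    passing = set(enrichment.loc[enrichment["pass"], "term_id"]) \
        if len(enrichment) else set()
    term_members = {t: annotation[t] for t in (passing or annotation)}
    network = build_network(validated, term_members)

    result = PipelineResult(
        references=references, fragment_catalog=catalog,
        prep_summaries=prep_summaries, fragments=fragments, matrix=matrix,
        composition=comp, venn=venn, diff=diff, target_calls=calls,
        consensus_genes=consensus, validated=validated,
        validated_pooled=pooled, enrichment=enrichment, network=network,
        sim_truth=truth)
    if out is not None:
        write_outputs(result, cfg, out)
    return result


def enr_flag(de_table: pd.DataFrame) -> pd.DataFrame:
    """Attach the significance flag to a raw DE table (gene, log2fc, p)."""
    import math
    df = de_table.copy()
    df["significant"] = (df["log2fc"].abs() > math.log2(1.5)) & (df["p"] < 0.05)
    return df


def write_outputs(result: PipelineResult, cfg: sim.SimConfig,
                  outdir: str | Path) -> dict[str, str]:
    """Write all result tables; returns output-file hash map (manifest)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    atomic_write(out / "reference.txt",
                 lambda p: write_reference(result.references, p))

    frag_df = pd.DataFrame(
        [{"name": f.name, "sequence": f.sequence, "type": f.type.value,
          "amino_acid": f.amino_acid, "length": f.length,
          "variant": f.variant,
          "source_trna_ids": ",".join(sorted(f.source_trna_ids))}
         for f in result.fragments])
    atomic_write(out / "fragments.tsv",
                 lambda p: frag_df.to_csv(p, sep="\t", index=False))

    atomic_write(out / "counts.tsv",
                 lambda p: quant.write_matrix(result.matrix, p, kind="counts"))
    atomic_write(out / "tpm.tsv",
                 lambda p: quant.write_matrix(result.matrix, p, kind="tpm"))
    for key, df in result.composition.items():
        atomic_write(out / f"composition_{key}.tsv",
                     lambda p, d=df: d.to_csv(p, sep="\t"))
    atomic_write(out / "diff.tsv",
                 lambda p: result.diff.to_csv(p, sep="\t", index=False))

    calls_df = pd.DataFrame(
        [{"tsrna": c.tsrna_name, "gene": c.gene_id,
          "utr_pos": c.utr_position, "seed_evidence": c.seed_evidence,
          "pairing_mismatches": c.pairing_mismatches,
          "mfe": round(c.mfe, 4), "consensus": c.consensus}
         for c in result.target_calls])
    atomic_write(out / "targets.tsv",
                 lambda p: calls_df.to_csv(p, sep="\t", index=False))

    val_df = pd.DataFrame(
        [{"tsrna": ts, "gene": g}
         for ts, genes in sorted(result.validated.items())
         for g in sorted(genes)])
    atomic_write(out / "validated_targets.tsv",
                 lambda p: val_df.to_csv(p, sep="\t", index=False))
    atomic_write(out / "enrichment.tsv",
                 lambda p: result.enrichment.to_csv(p, sep="\t", index=False))
    atomic_write(out / "network_edges.tsv",
                 lambda p: write_edge_list(result.network, p))
    atomic_write(out / "degrees.tsv",
                 lambda p: degree_table(result.network).to_csv(
                     p, sep="\t", index=False))
    for sample, summary in result.prep_summaries.items():
        atomic_write(out / f"prep_{sample}.tsv",
                     lambda p, s=summary: write_summary(s, p))

    n_a, n_b, n_union, n_int = result.venn
    summary = {
        "n_fragments": len(result.fragments),
        "venn": {"sham": n_a, "ICH": n_b, "union": n_union,
                 "intersection": n_int},
        "n_significant": int(result.diff["significant"].sum()),
        "n_consensus_genes": len(set().union(*result.consensus_genes.values()))
        if result.consensus_genes else 0,
        "n_validated": len(result.validated_pooled),
        "n_terms_pass": int(result.enrichment["pass"].sum())
        if len(result.enrichment) else 0,
    }
    atomic_write(out / "summary.json",
                 lambda p: p.write_text(json.dumps(summary, indent=2) + "\n"))

    hashes = {f.name: file_sha256(f)
              for f in sorted(out.iterdir())
              if f.is_file() and f.name != "manifest.json"}
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["type_mixture"] = {k.value: v
                                for k, v in cfg.type_mixture.items()}
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": hashes,
    }
    atomic_write(out / "manifest.json",
                 lambda p: p.write_text(json.dumps(manifest, indent=2,
                                                   default=str) + "\n"))
    return hashes
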