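"""Target validation, hypergeometric enrichment and network construction.

Predicted consensus targets are validated by intersection with an
independently measured differentially-expressed mRNA table. The validated
gene list is then tested for pathway enrichment with the accumulative
(upper-tail) hypergeometric distribution: for a term annotating K of N
universe genes, observing k of an n-gene list has

    P = Σ_{i≥k} C(K,i) C(N−K, n−i) / C(N,n)

and an enrichment factor EF = k / (n·K/N), the observed count over the
count expected by chance. A term passes at P < 0.01, k ≥ 3 and EF > 1.5,
with no multiple-testing correction (a Benjamini–Hochberg column is
emitted for information only). Validated tsRNA→mRNA pairs and mRNA→term
memberships are exported as a bipartite-by-kind edge list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentThresholds:
    p_max: float = 0.01
    min_count: int = 3
    ef_min: float = 1.5


def read_de_table(path) -> pd.DataFrame:
    """Read a DE-mRNA TSV (gene, log2fc, p) and flag significance.

    Significant ⇔ |log2 FC| > log2(1.5) and P < 0.05, matching the
    fragment-level differential rule.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    required = {"gene", "log2fc", "p"}
    if not required <= set(df.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    df["significant"] = (df["log2fc"].abs() > math.log2(1.5)) & (df["p"] < 0.05)
    return df


def significant_genes(de_table: pd.DataFrame) -> set[str]:
    return set(de_table.loc[de_table["significant"], "gene"])


def intersect_targets(
    consensus_genes: Mapping[str, set[str]],
    de_genes: set[str],
) -> tuple[dict[str, set[str]], set[str]]:
    """Validated targets: consensus predictions ∩ significant DE genes.

    Returns (per-tsRNA validated sets, pooled validated set).
    """
    if not de_genes:
        raise ValueError("empty DE gene set")
    per_tsrna = {name: genes & de_genes
                 for name, genes in consensus_genes.items()}
    pooled = set().union(*per_tsrna.values()) if per_tsrna else set()
    return per_tsrna, pooled


def hypergeom_tail(k: int, n_universe: int, n_term: int, n_list: int) -> float:
    """Upper-tail (accumulative) hypergeometric P(X ≥ k)."""
    return float(stats.hypergeom.sf(k - 1, n_universe, n_term, n_list))


def enrich(
    gene_list: set[str],
    annotation: Mapping[str, set[str]],
    universe: set[str],
    term_names: Mapping[str, str] | None = None,
    thresholds: EnrichmentThresholds | None = None,
) -> pd.DataFrame:
    """Accumulative-hypergeometric enrichment of a gene list, per term.

    ``annotation`` maps term_id → member genes; every annotated gene must
    be in the universe and the list must be a subset of the universe. All
    terms with at least one observed gene are reported with their pass
    flag; ``p_bh`` is a Benjamini–Hochberg-adjusted column for information.
    """
    thresholds = thresholds or EnrichmentThresholds()
    if not gene_list <= universe:
        raise ValueError("gene list is not a subset of the universe")
    if len(universe) < len(gene_list):
        raise ValueError("universe smaller than the gene list")
    n_uni, n_list = len(universe), len(gene_list)
    rows = []
    for term_id, members in sorted(annotation.items()):
        if not members <= universe:
            raise ValueError(f"term {term_id}: members outside the universe")
        k = len(gene_list & members)
        if k == 0:
            continue
        n_term = len(members)
        expected = n_list * n_term / n_uni
        ef = k / expected if expected > 0 else math.inf
        p = hypergeom_tail(k, n_uni, n_term, n_list)
        rows.append({
            "term_id": term_id,
            "term_name": (term_names or {}).get(term_id, term_id),
            "observed": k,
            "list_size": n_list,
            "term_size": n_term,
            "universe_size": n_uni,
            "expected": expected,
            "enrichment_factor": ef,
            "p_value": p,
            "pass": (p < thresholds.p_max and k >= thresholds.min_count
                     and ef > thresholds.ef_min),
        })
    df = pd.DataFrame(rows, columns=[
        "term_id", "term_name", "observed", "list_size", "term_size",
        "universe_size", "expected", "enrichment_factor", "p_value", "pass"])
    if len(df):
        df["p_bh"] = stats.false_discovery_control(df["p_value"], method="bh")
        df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        df["p_bh"] = pd.Series(dtype=float)
    return df


def read_annotation(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read gene→pathway TSV (gene, term_id, term_name) or GMT.

    Returns (term_id → member genes, term_id → display name).
    """
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if "\t" in first and len(first.split("\t")) > 3 and \
                not first.lower().startswith("gene"):
            # GMT: term, description, gene, gene, ...
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                terms[parts[0]] = set(parts[2:])
                names[parts[0]] = parts[1] or parts[0]
        else:
            df = pd.read_csv(fh, sep="\t")
            df.columns = [c.lower() for c in df.columns]
            for _, row in df.iterrows():
                terms.setdefault(row["term_id"], set()).add(row["gene"])
                names[row["term_id"]] = row.get("term_name", row["term_id"])
    return terms, names


def build_network(
    validated: Mapping[str, set[str]],
    term_members: Mapping[str, set[str]],
) -> nx.DiGraph:
    """tsRNA → mRNA → pathway network as a directed graph.

    Edge kinds: ``targets`` (tsRNA → mRNA) and ``member_of`` (mRNA → term);
    only mRNAs present in the validated sets are wired to terms. Nodes
    carry a ``kind`` attribute in {tsrna, mrna, term}.
    """
    g = nx.DiGraph()
    mrnas: set[str] = set()
    for tsrna, genes in validated.items():
        if genes:
            g.add_node(tsrna, kind="tsrna")
        for gene in genes:
            g.add_node(gene, kind="mrna")
            g.add_edge(tsrna, gene, kind="targets")
            mrnas.add(gene)
    for term, members in term_members.items():
        hits = members & mrnas
        if not hits:
            continue
        g.add_node(term, kind="term")
        for gene in hits:
            g.add_edge(gene, term, kind="member_of")
    return g


def degree_table(g: nx.DiGraph) -> pd.DataFrame:
    rows = [{"node": n, "kind": g.nodes[n]["kind"],
             "degree": g.degree(n), "in_degree": g.in_degree(n),
             "out_degree": g.out_degree(n)}
            for n in sorted(g.nodes)]
    return pd.DataFrame(rows, columns=["node", "kind", "degree",
                                       "in_degree", "out_degree"])


def write_edge_list(g: nx.DiGraph, path) -> None:
    """Edge-list TSV (source, target, kind) for graph viewers."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tkind\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['kind']}\n")
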