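"""Fragment quantification (TPM), composition summaries and differential calls.

Expression is normalised as tag counts per million of total aligned tRNA
reads (TPM) — a within-tRNA-space library-size normalisation, so each
sample's TPM column sums to 1e6. Group comparison uses a two-sided
pooled-variance Student's t test on TPM, with a fold-change gate: a
fragment is called significant when |log2 FC| > log2(1.5) and P < 0.05,
with no multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FC_PSEUDOCOUNT = 0.01   # TPM floor used for fold change only, never for testing


@dataclass
class ExpressionMatrix:
    """Fragment × sample counts and TPM with group labels per sample."""

    counts: pd.DataFrame          # fragments × samples, nonnegative ints
    tpm: pd.DataFrame             # same shape
    groups: pd.Series             # sample → group label

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


def compute_tpm(
    counts: pd.DataFrame,
    aligned_totals: Mapping[str, int] | pd.Series | None = None,
    groups: Mapping[str, str] | pd.Series | None = None,
) -> ExpressionMatrix:
    """Normalise counts to tag counts per million of aligned tRNA reads.

    ``aligned_totals`` defaults to the per-sample column sums (every counted
    tag aligned to tRNA space). A sample with zero aligned reads is an
    error. Zero counts stay exactly zero.
    """
    counts = counts.astype(np.int64)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if aligned_totals is None:
        totals = counts.sum(axis=0)
    else:
        totals = pd.Series(aligned_totals).reindex(counts.columns)
        if totals.isna().any():
            missing = list(totals[totals.isna()].index)
            raise ValueError(f"missing aligned totals for samples {missing}")
        if (counts.sum(axis=0) > totals).any():
            raise ValueError("counts exceed aligned totals")
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero aligned total for sample(s) {list(zero.index)}")
    tpm = counts.div(totals, axis=1) * 1e6
    if groups is None:
        grp = pd.Series("all", index=counts.columns)
    else:
        grp = pd.Series(groups).reindex(counts.columns)
    return ExpressionMatrix(counts=counts, tpm=tpm, groups=grp)


def composition(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """TPM-weighted composition per group, by type, amino acid and length.

    ``annotation`` indexes fragments with columns ``type``, ``amino_acid``,
    ``length``. Each breakdown sums to 1 within each group (empty groups
    are all-zero).
    """
    out: dict[str, pd.DataFrame] = {}
    ann = annotation.reindex(matrix.tpm.index)
    for key in ("type", "amino_acid", "length"):
        per_group = {}
        for group in matrix.groups.unique():
            cols = matrix.samples_in(group)
            weight = matrix.tpm[cols].sum(axis=1)
            total = weight.sum()
            frac = weight.groupby(ann[key]).sum()
            per_group[group] = frac / total if total > 0 else frac
        out[key] = pd.DataFrame(per_group).fillna(0.0)
    return out


def detected_sets(matrix: ExpressionMatrix) -> dict[str, set[str]]:
    """Fragments detected per group: nonzero raw count in ≥1 replicate."""
    out = {}
    for group in matrix.groups.unique():
        cols = matrix.samples_in(group)
        mask = (matrix.counts[cols] > 0).any(axis=1)
        out[group] = set(matrix.counts.index[mask])
    return out


def venn_counts(set_a: set, set_b: set) -> tuple[int, int, int, int]:
    """(n_A, n_B, n_union, n_intersection); union = A + B − intersection."""
    return (len(set_a), len(set_b), len(set_a | set_b), len(set_a & set_b))


def intersection_from_union(n_a: int, n_b: int, n_union: int) -> int:
    """Recover the overlap of two sets from their sizes and union size."""
    n_int = n_a + n_b - n_union
    if not (0 <= n_int <= min(n_a, n_b)):
        raise ValueError(f"inconsistent Venn counts ({n_a}, {n_b}, {n_union})")
    return n_int


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided unpaired pooled-variance t on two samples."""
    t, p = stats.ttest_ind(x, y, equal_var=True)
    if math.isnan(p):
        # both groups constant; identical means → p = 1 by convention,
        # different constant means → p = 0 (infinite t)
        return (0.0, 1.0) if np.isclose(x.mean(), y.mean()) else (math.inf, 0.0)
    return float(t), float(p)


def diff_test(
    matrix: ExpressionMatrix,
    group_ref: str = "sham",
    group_alt: str = "ICH",
    fc_thresh: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential call per fragment: FC on group-mean TPM plus Student's t.

    Fold change is (mean_alt + ε)/(mean_ref + ε) with ε = 0.01 TPM; the t
    test runs on raw TPM with no pseudocount. Output is sorted by P.
    """
    cols_ref = matrix.samples_in(group_ref)
    cols_alt = matrix.samples_in(group_alt)
    for name, cols in ((group_ref, cols_ref), (group_alt, cols_alt)):
        if len(cols) < 2:
            raise ValueError(f"group {name!r} needs ≥2 replicates, has {len(cols)}")
    rows = []
    log2_gate = math.log2(fc_thresh)
    for frag in matrix.tpm.index:
        x = matrix.tpm.loc[frag, cols_ref].to_numpy(dtype=float)
        y = matrix.tpm.loc[frag, cols_alt].to_numpy(dtype=float)
        t, p = _pooled_t(y, x)
        num, den = y.mean() + FC_PSEUDOCOUNT, x.mean() + FC_PSEUDOCOUNT
        fc = num / den
        # difference of logs so that swapping groups negates log2fc exactly
        log2fc = math.log2(num) - math.log2(den)
        rows.append({
            "name": frag,
            f"mean_tpm_{group_ref.lower()}": x.mean(),
            f"mean_tpm_{group_alt.lower()}": y.mean(),
            "fold_change": fc,
            "log2fc": log2fc,
            "p_value": p,
            "significant": abs(log2fc) > log2_gate and p < alpha,
        })
    return pd.DataFrame(rows).sort_values(
        "p_value", kind="mergesort").reset_index(drop=True)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, kind: str = "tpm") -> None:
    """Write counts or TPM as TSV with a group header row."""
    df = matrix.tpm if kind == "tpm" else matrix.counts
    with open(path, "w") as fh:
        fh.write("group\t" + "\t".join(matrix.groups[c] for c in df.columns) + "\n")
        df.to_csv(fh, sep="\t", index_label="fragment")
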