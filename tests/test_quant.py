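from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tsrnakit.quant import (compute_tpm, composition, detected_sets,
                            diff_test, intersection_from_union, venn_counts)

from ._oracles import pooled_t_textbook


def _matrix(counts: dict, groups=None):
    df = pd.DataFrame(counts)
    return compute_tpm(df, groups=groups)


class TestTpm:
    def test_single_fragment_gets_full_million(self):
        m = _matrix({"s1": [7]})
        assert m.tpm.iloc[0, 0] == pytest.approx(1_000_000)

    def test_proportional_split(self):
        m = compute_tpm(pd.DataFrame({"s1": [2, 8]}, index=["a", "b"]),
                        aligned_totals={"s1": 10})
        assert list(m.tpm["s1"]) == [200_000.0, 800_000.0]

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError, match="zero aligned total"):
            compute_tpm(pd.DataFrame({"s1": [0, 0]}))

    def test_counts_above_totals_rejected(self):
        with pytest.raises(ValueError):
            compute_tpm(pd.DataFrame({"s1": [5, 6]}),
                        aligned_totals={"s1": 10})

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(40, 6)),
                              columns=[f"s{i}" for i in range(6)])
        counts.iloc[0] += 1          # ensure nonzero totals
        m = compute_tpm(counts)
        np.testing.assert_allclose(m.tpm.sum(axis=0), 1e6, rtol=1e-9)


class TestComposition:
    def test_single_type_is_everything(self):
        m = _matrix({"s1": [5, 5]}, groups={"s1": "g"})
        ann = pd.DataFrame({"type": ["i-tRF", "i-tRF"],
                            "amino_acid": ["Gly", "Ser"],
                            "length": [20, 21]}, index=m.tpm.index)
        comp = composition(m, ann)
        assert comp["type"].loc["i-tRF", "g"] == pytest.approx(1.0)
        assert comp["amino_acid"]["g"].sum() == pytest.approx(1.0)

    def test_breakdowns_sum_to_one_in_both_groups(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, size=(12, 4)),
                              columns=["sham_1", "sham_2", "ICH_1", "ICH_2"])
        groups = {c: c.split("_")[0] for c in counts.columns}
        m = compute_tpm(counts, groups=groups)
        ann = pd.DataFrame(
            {"type": ["tRF-5", "tRF-3", "i-tRF"] * 4,
             "amino_acid": ["Gly", "Ser", "Lys", "Ala"] * 3,
             "length": list(range(16, 28))}, index=m.tpm.index)
        comp = composition(m, ann)
        for key in ("type", "amino_acid", "length"):
            for g in ("sham", "ICH"):
                assert comp[key][g].sum() == pytest.approx(1.0, abs=1e-9)


class TestVenn:
    def test_reported_group_sizes_imply_overlap(self):
        # 308 sham + 309 ICH with a 331-species union → 286 shared
        assert intersection_from_union(308, 309, 331) == 286

    def test_identical_sets(self):
        a = {"x", "y", "z"}
        assert venn_counts(a, set(a)) == (3, 3, 3, 3)

    def test_disjoint_sets(self):
        assert venn_counts({"a"}, {"b", "c"}) == (1, 2, 3, 0)

    def test_inclusion_exclusion_consistency(self, rng):
        pool = [f"f{i}" for i in range(50)]
        for _ in range(20):
            a = set(rng.choice(pool, size=20))
            b = set(rng.choice(pool, size=25))
            n_a, n_b, n_u, n_i = venn_counts(a, b)
            assert n_u == n_a + n_b - n_i

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            intersection_from_union(10, 10, 25)

    def test_detection_rule_nonzero_in_any_replicate(self):
        counts = pd.DataFrame({"sham_1": [0, 3], "sham_2": [0, 1],
                               "ICH_1": [1, 0], "ICH_2": [0, 2]},
                              index=["a", "b"])
        m = compute_tpm(counts, groups={c: c.split("_")[0]
                                        for c in counts.columns})
        sets = detected_sets(m)
        assert sets["sham"] == {"b"} and sets["ICH"] == {"a", "b"}


class TestDiff:
    def _m(self, sham, ich):
        counts = pd.DataFrame(
            np.column_stack([*sham.T, *ich.T]).astype(int),
            columns=[f"sham_{i}" for i in range(1, sham.shape[1] + 1)]
            + [f"ICH_{i}" for i in range(1, ich.shape[1] + 1)])
        groups = {c: c.split("_")[0] for c in counts.columns}
        return compute_tpm(counts, groups=groups)

    def test_identical_groups_not_significant(self):
        counts = pd.DataFrame({"sham_1": [10, 5], "sham_2": [11, 5],
                               "ICH_1": [10, 5], "ICH_2": [11, 5]})
        m = compute_tpm(counts, groups={c: c.split("_")[0]
                                        for c in counts.columns})
        out = diff_test(m)
        assert (out["log2fc"] == 0).all()
        assert not out["significant"].any()

    def test_textbook_example(self):
        """(10, 11, 12) vs (20, 21, 22): t and P match the pooled-variance
        formula computed by hand."""
        x, y = [10.0, 11.0, 12.0], [20.0, 21.0, 22.0]
        t_ref, p_ref = pooled_t_textbook(y, x)
        counts = pd.DataFrame({"sham_1": [10, 90], "sham_2": [11, 89],
                               "sham_3": [12, 88], "ICH_1": [20, 80],
                               "ICH_2": [21, 79], "ICH_3": [22, 78]},
                              index=["f", "other"])
        m = compute_tpm(counts,
                        aligned_totals={c: 100 for c in counts.columns},
                        groups={c: c.split("_")[0] for c in counts.columns})
        row = diff_test(m).set_index("name").loc["f"]
        # TPM scales counts by 1e4 here; t and P are scale-invariant
        assert row["p_value"] == pytest.approx(p_ref, abs=1e-12)

    def test_pvalues_match_t_distribution_oracle(self, rng):
        """100 random matrices agree with the textbook formula to 1e-9."""
        for _ in range(100):
            tpm = rng.uniform(1, 1000, size=6)
            counts = pd.DataFrame(
                {f"sham_{i}": [int(tpm[i])] for i in range(3)} |
                {f"ICH_{i}": [int(tpm[i + 3])] for i in range(3)})
            counts.loc[1] = 1000          # second row to keep totals sane
            m = compute_tpm(counts, groups={c: c.split("_")[0]
                                            for c in counts.columns})
            out = diff_test(m).set_index("name")
            for frag in out.index:
                x = m.tpm.loc[frag, m.samples_in("sham")].tolist()
                y = m.tpm.loc[frag, m.samples_in("ICH")].tolist()
                _, p_ref = pooled_t_textbook(y, x)
                assert out.loc[frag, "p_value"] == pytest.approx(
                    p_ref, abs=1e-9)

    def test_fold_change_antisymmetry(self):
        counts = pd.DataFrame({"sham_1": [10, 50], "sham_2": [12, 48],
                               "ICH_1": [40, 20], "ICH_2": [44, 16]})
        groups = {c: c.split("_")[0] for c in counts.columns}
        m = compute_tpm(counts, groups=groups)
        fwd = diff_test(m).set_index("name")["log2fc"]
        swapped = {c: ("ICH" if g == "sham" else "sham")
                   for c, g in groups.items()}
        m2 = compute_tpm(counts, groups=swapped)
        rev = diff_test(m2).set_index("name")["log2fc"]
        assert all(fwd[n] == -rev[n] for n in fwd.index)

    def test_single_replicate_group_is_error(self):
        counts = pd.DataFrame({"sham_1": [1], "ICH_1": [1], "ICH_2": [2]})
        m = compute_tpm(counts, groups={"sham_1": "sham", "ICH_1": "ICH",
                                        "ICH_2": "ICH"})
        with pytest.raises(ValueError, match="replicates"):
            diff_test(m)

    def test_planted_fourfold_change_is_flagged(self, rng):
        """A 4-fold planted change at 10% CV and n=3 is called significant."""
        base, high = 500.0, 2000.0
        sham = rng.normal(base, 0.1 * base, size=3).round()
        ich = rng.normal(high, 0.1 * high, size=3).round()
        counts = pd.DataFrame(
            {f"sham_{i+1}": [int(sham[i]), 5000] for i in range(3)} |
            {f"ICH_{i+1}": [int(ich[i]), 5000] for i in range(3)})
        m = compute_tpm(counts, groups={c: c.split("_")[0]
                                        for c in counts.columns})
        out = diff_test(m).set_index("name")
        assert bool(out.loc[0, "significant"])
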