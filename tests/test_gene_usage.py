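"""Gene-segment usage frequencies, differential testing, PCA."""

import numpy as np
import pytest

from ighrep import (
    Cohort,
    active_disease_grouping,
    differential_usage,
    usage_frequencies,
    usage_pca,
)
from ighrep.gene_usage import UsageTable, strip_allele
from conftest import make_sample


def test_counting_and_row_normalization():
    s = make_sample("S1", "nontreated", "IGHG",
                    [("CAAW", "IGHV3-30", "IGHJ4", 1),
                     ("CACW", "IGHV3-30", "IGHJ4", 1),
                     ("CADW", "IGHV3-23", "IGHJ4", 1)])
    cohort = Cohort([s], {"S1": "nontreated"})
    table = usage_frequencies(cohort, "V", "IGHG")
    assert table.frequencies.loc["S1", "IGHV3-30"] == pytest.approx(2 / 3)
    assert table.frequencies.loc["S1", "IGHV3-23"] == pytest.approx(1 / 3)
    assert table.frequencies.sum(axis=1).iloc[0] == pytest.approx(1.0)


def test_allele_suffix_stripped():
    assert strip_allele("IGHV3-30*03") == "IGHV3-30"
    assert strip_allele("IGHV3-30*01,IGHV3-30-3*02") == "IGHV3-30"
    s = make_sample("S1", "treated", "IGHG", [("CAAW", "IGHV3-30*03", "IGHJ4*01", 2)])
    table = usage_frequencies(Cohort([s], {"S1": "treated"}), "V", "IGHG")
    assert list(table.frequencies.columns) == ["IGHV3-30"]


def test_usage_rows_sum_to_one(small_synthetic):
    for family in ("V", "J"):
        table = usage_frequencies(small_synthetic, family, "IGHM")
        assert np.allclose(table.frequencies.sum(axis=1), 1.0, atol=1e-9)


class TestDifferentialUsage:
    def _table(self, values_by_status):
        rows = {}
        groups = {}
        for status, vals in values_by_status.items():
            group = "nontreated" if status == "a" else "endemic_control"
            for i, v in enumerate(vals):
                sid = f"{status}{i}"
                rows[sid] = {"SEG1": v, "OTHER": 1 - v}
                groups[sid] = group
        import pandas as pd

        return UsageTable(pd.DataFrame.from_dict(rows, orient="index"),
                          pd.Series(groups), "V", "IGHG")

    def test_identical_groups_p_one(self):
        table = self._table({"a": [0.1, 0.2], "b": [0.1, 0.2]})
        out = differential_usage(table, {"a0": "x", "a1": "x", "b0": "y", "b1": "y"})
        assert (out["p_value"] == 1.0).all()

    def test_exact_enumeration_p(self):
        table = self._table({"a": [0.01, 0.02], "b": [0.03, 0.04]})
        out = differential_usage(table, {"a0": "x", "a1": "x", "b0": "y", "b1": "y"})
        seg = out[out.segment == "SEG1"].iloc[0]
        assert seg["p_value"] == pytest.approx(2 / 6, abs=1e-12)

    def test_symmetric_under_status_swap(self):
        table = self._table({"a": [0.01, 0.05, 0.02], "b": [0.03, 0.04, 0.06]})
        g1 = {"a0": "x", "a1": "x", "a2": "x", "b0": "y", "b1": "y", "b2": "y"}
        g2 = {k: ("y" if v == "x" else "x") for k, v in g1.items()}
        out1 = differential_usage(table, g1).set_index("segment")
        out2 = differential_usage(table, g2).set_index("segment")
        assert np.allclose(out1["p_value"], out2["p_value"])

    def test_adjusted_column_present_and_monotone(self):
        table = self._table({"a": [0.01, 0.02, 0.03], "b": [0.05, 0.06, 0.04]})
        out = differential_usage(table, {"a0": "x", "a1": "x", "a2": "x",
                                         "b0": "y", "b1": "y", "b2": "y"})
        assert (out["p_adj"] >= out["p_value"] - 1e-12).all()


def test_active_disease_grouping_preset(small_synthetic):
    grouping = active_disease_grouping(small_synthetic)
    actives = {s for s, v in grouping.items() if v == "active"}
    without = {s for s, v in grouping.items() if v == "without_disease"}
    assert all(s.startswith(("NT", "TR")) for s in actives)
    assert all(s.startswith(("RE", "EC")) for s in without)
    assert not any(s.startswith("NE") for s in grouping)


class TestUsagePca:
    def test_correlated_columns_single_component(self):
        import pandas as pd

        freqs = pd.DataFrame(
            {"A": [0.1, 0.2, 0.3, 0.4], "B": [0.2, 0.4, 0.6, 0.8]},
            index=[f"s{i}" for i in range(4)],
        )
        table = UsageTable(freqs, pd.Series("nontreated", index=freqs.index), "V", "IGHG")
        res = usage_pca(table, ["A", "B"], n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_zero_eigenvalues(self):
        import pandas as pd

        freqs = pd.DataFrame({"A": [0.5] * 3, "B": [0.5] * 3},
                             index=[f"s{i}" for i in range(3)])
        table = UsageTable(freqs, pd.Series("treated", index=freqs.index), "V", "IGHG")
        res = usage_pca(table, ["A", "B"])
        assert np.allclose(res.scores, 0, atol=1e-12)

    def test_reconstruction_round_trip(self):
        import pandas as pd

        rng = np.random.default_rng(2)
        X = rng.random((6, 4))
        freqs = pd.DataFrame(X, index=[f"s{i}" for i in range(6)],
                             columns=list("ABCD"))
        table = UsageTable(freqs, pd.Series("remission", index=freqs.index), "V", "IGHG")
        res = usage_pca(table, list("ABCD"), n_components=4)
        Xc = X - X.mean(axis=0)
        assert np.allclose(res.scores @ res.loadings.T, Xc, atol=1e-9)

    def test_deterministic_sign_convention(self):
        import pandas as pd

        rng = np.random.default_rng(6)
        X = rng.random((5, 3))
        freqs = pd.DataFrame(X, index=[f"s{i}" for i in range(5)], columns=list("ABC"))
        table = UsageTable(freqs, pd.Series("treated", index=freqs.index), "V", "IGHG")
        res = usage_pca(table, list("ABC"))
        for comp in range(res.loadings.shape[1]):
            col = res.loadings[:, comp]
            assert col[np.argmax(np.abs(col))] > 0
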