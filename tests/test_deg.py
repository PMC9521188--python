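"""TMM normalization, BH adjustment, the NB contrast test and DEG filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ptiseq.deg import (
    CountMatrix,
    DifferentialExpression,
    adjust_bh,
    filter_degs,
    normalize_tmm,
    test_contrast as nb_contrast,
)

from conftest import two_group_counts


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def brute_force_tmm_log2(obs, ref, lib_obs, lib_ref):
    """Independently coded doubly trimmed weighted mean of M-values
    (30% trim on M, 5% on A, inverse-variance weights)."""
    M, A, W = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            po, pr = o / lib_obs, r / lib_ref
            M.append(np.log2(po / pr))
            A.append(0.5 * np.log2(po * pr))
            W.append(1.0 / ((lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)))
    n = len(M)
    order_m = sorted(range(n), key=lambda i: M[i])
    order_a = sorted(range(n), key=lambda i: A[i])
    cut_m, cut_a = int(np.floor(n * 0.3)), int(np.floor(n * 0.05))
    keep_m = set(order_m[cut_m : n - cut_m])
    keep_a = set(order_a[cut_a : n - cut_a])
    keep = keep_m & keep_a
    num = sum(M[i] * W[i] for i in keep)
    den = sum(W[i] for i in keep)
    return num / den


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame(np.tile([[10], [40], [7], [100]], (1, 4)),
                          columns=list("abcd"))
        f = normalize_tmm(df)
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, size=100) + 1
        df = pd.DataFrame({"A": a, "B": 2 * a})
        f = normalize_tmm(df)
        # M-values vanish after library-size division; factors stay 1 and
        # normalized expression count/(lib*factor) is equal across samples
        assert np.allclose(f, 1.0, atol=1e-12)
        norm = df / (df.sum(axis=0) * f)
        assert np.allclose(norm["A"], norm["B"])

    def test_matches_brute_force_oracle_on_fixture(self):
        rng = np.random.default_rng(5)
        obs = rng.integers(1, 500, size=20)
        ref = rng.integers(1, 500, size=20)
        df = pd.DataFrame({"ref": ref, "obs": obs})
        f = normalize_tmm(df)
        lib = df.sum(axis=0).astype(float)
        expected_log2 = brute_force_tmm_log2(obs, ref, lib["obs"], lib["ref"])
        # factors are geometric-mean centered, so compare the ratio
        got_log2 = np.log2(f["obs"] / f["ref"])
        assert got_log2 == pytest.approx(expected_log2, abs=1e-10)

    def test_factors_multiply_to_one(self, counts_small):
        cm, _ = counts_small
        f = normalize_tmm(cm)
        assert np.prod(f) == pytest.approx(1.0, abs=1e-12)
        assert (f > 0).all()

    def test_all_zero_sample_rejected_by_name(self):
        df = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            normalize_tmm(df)


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Definitional step-up oracle: for each i, the minimum over all j with
    p_j >= p_i of min(1, p_j * m / rank_j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    out = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, p[j] * m / ranks[j]) for j in range(m) if p[j] >= p[i]
        ]
        out[i] = min(candidates)
    return out


class TestBH:
    def test_worked_example(self):
        got = adjust_bh([0.005, 0.011, 0.02, 0.8])
        assert np.allclose(got, [0.02, 0.022, 0.02 * 4 / 3, 0.8], atol=1e-12)

    def test_single_p_unchanged(self):
        assert adjust_bh([0.37])[0] == pytest.approx(0.37)

    def test_ties_propagate(self):
        assert np.allclose(adjust_bh([0.03] * 5), 0.03, atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.1, 1.2])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_definitional_oracle_and_statsmodels(self, p):
        got = adjust_bh(p)
        assert np.allclose(got, bh_oracle(p), atol=1e-12)
        from statsmodels.stats.multitest import multipletests

        sm = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(got, sm, atol=1e-12)
        assert (got >= np.asarray(p) - 1e-15).all()


# ---------------------------------------------------------------------------
# contrast test
# ---------------------------------------------------------------------------

class TestContrast:
    def test_identical_groups_null_identity(self):
        y = np.tile([[20, 20, 20, 20, 20, 20]], (5, 1))
        sheet = pd.DataFrame(
            {"timepoint_h": [0, 0, 0, 3, 3, 3], "replicate": [1, 2, 3, 1, 2, 3]},
            index=[f"s{i}" for i in range(6)],
        )
        cm = CountMatrix(pd.DataFrame(y, index=[f"g{i}" for i in range(5)],
                                      columns=sheet.index), sheet)
        tab = nb_contrast(cm, normalize_tmm(cm), 3)
        assert np.allclose(tab["log2FC"], 0, atol=1e-8)
        assert np.allclose(tab["p"], 1, atol=1e-8)

    def test_minimum_count_filter_marks_untested(self):
        cm = two_group_counts(50, 100, 0.1, seed=1)
        cm.counts.iloc[0] = 1  # total 6 < 10
        tab = nb_contrast(cm, normalize_tmm(cm), 3)
        assert np.isnan(tab.iloc[0]["p"])
        assert tab.iloc[1:]["p"].notna().all()

    def test_single_replicate_group_rejected(self):
        y = np.ones((3, 4), int) * 10
        sheet = pd.DataFrame(
            {"timepoint_h": [0, 0, 0, 3], "replicate": [1, 2, 3, 1]},
            index=list("abcd"),
        )
        cm = CountMatrix(pd.DataFrame(y, index=list("xyz"), columns=sheet.index), sheet)
        with pytest.raises(ValueError, match="replicates"):
            nb_contrast(cm, normalize_tmm(cm), 3)

    def test_null_type_one_error_rate(self):
        cm = two_group_counts(2000, 100, 0.1, seed=3)
        tab = nb_contrast(cm, normalize_tmm(cm), 3)
        rate = (tab["p"].dropna() < 0.05).mean()
        assert 0.02 < rate < 0.09

    def test_planted_fold_change_recovered(self):
        cm = two_group_counts(2000, 100, 0.1, seed=4, mu_alt=400, n_signal=200)
        tab = nb_contrast(cm, normalize_tmm(cm), 3)
        planted = tab.iloc[:200]
        assert planted["log2FC"].median() == pytest.approx(2.0, abs=0.15)
        assert (planted["FDR"] < 0.01).mean() > 0.8


# ---------------------------------------------------------------------------
# DEG filter
# ---------------------------------------------------------------------------

def _row(gene, t, lfc, p, fdr):
    return {"gene_id": gene, "timepoint_h": t, "log2FC": lfc, "p": p, "FDR": fdr}


class TestFilter:
    def test_rule_application(self):
        tab = pd.DataFrame(
            [
                _row("up_ok", 1, 1.2, 0.001, 0.005),
                _row("p_too_big", 1, 2.0, 0.02, 0.005),
                _row("boundary_2fold", 1, 1.0, 0.001, 0.001),
                _row("down_ok", 1, -1.5, 0.002, 0.003),
                _row("fdr_too_big", 1, 3.0, 0.001, 0.02),
            ]
        )
        d = filter_degs(tab)
        assert d.up[1.0] == ["up_ok"]
        assert d.down[1.0] == ["down_ok"]
        assert set(d.union) == {"up_ok", "down_ok"}

    def test_union_deduplicates_across_timepoints(self):
        tab = pd.DataFrame(
            [_row("g", 0.5, 2.0, 1e-5, 1e-4), _row("g", 1.0, 2.2, 1e-5, 1e-4)]
        )
        d = filter_degs(tab)
        assert len(d.union) == 1
        c = d.counts()
        assert c.loc["total", 0.5] == 1 and c.loc["total", 1.0] == 1
        assert c.loc["total", "union"] == 1

    def test_counts_identity_up_plus_down(self, counts_small):
        cm, _ = counts_small
        res = DifferentialExpression(cm).fit()
        d = res.filter_degs()
        c = d.counts()
        for t in d.timepoints:
            assert c.loc["total", t] == c.loc["up", t] + c.loc["down", t]
        assert c.loc["total", "union"] <= sum(c.loc["total", t] for t in d.timepoints)

    def test_empty_set_counts_all_zero(self):
        from ptiseq.deg import DEGSet

        c = DEGSet().counts()
        assert c.loc["total", "union"] == 0

    def test_missing_fdr_column_rejected(self):
        tab = pd.DataFrame([_row("g", 1, 2.0, 0.001, 0.001)]).drop(columns="FDR")
        with pytest.raises(ValueError, match="FDR"):
            filter_degs(tab)


class TestModelFacade:
    def test_fit_covers_all_nonzero_timepoints(self, counts_small):
        cm, _ = counts_small
        res = DifferentialExpression(cm).fit()
        assert set(res.contrasts["timepoint_h"]) == {0.5, 1.0, 3.0, 6.0, 12.0}
        # FDR >= p within each contrast
        ok = res.contrasts.dropna(subset=["p"])
        assert (ok["FDR"] >= ok["p"] - 1e-12).all()

    def test_omnibus_detects_planted_signal(self, counts_small):
        cm, manifest = counts_small
        model = DifferentialExpression(cm)
        p = model.fit_omnibus().dropna()
        arch = pd.Series(manifest["gene_archetype"]).loc[p.index]
        assert (p[arch > 0] < 0.01).mean() > 0.7
        assert (p[arch == 0] < 0.01).mean() < 0.1 if (arch == 0).any() else True
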