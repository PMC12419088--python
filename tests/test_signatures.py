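"""Moderated differential abundance, unique signatures and layer mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cortexlayers as cl
from cortexlayers.signatures import squeeze_variances


def _de_manifest(n1, n2):
    n = n1 + n2
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "model": ["CTRL"] * n, "timepoint": ["E14.5"] * n,
        "hemisphere_id": [f"h{i}" for i in range(n)],
        "layer_index": [1] * n1 + [2] * n2,
        "la_batch": ["LA1"] * n, "m_batch": ["M1"] * n,
        "excluded": [False] * n, "exclusion_reason": [""] * n})


def _ebayes_oracle(matrix, in_layer):
    """Step-by-step moderated t on a tiny matrix (independent of the library path)."""
    rows = []
    for protein, values in matrix.iterrows():
        y = values.to_numpy(dtype=float)
        g1, g2 = y[in_layer], y[~in_layer]
        n1, n2 = len(g1), len(g2)
        v1 = sum((x - g1.mean()) ** 2 for x in g1) / (n1 - 1)
        v2 = sum((x - g2.mean()) ** 2 for x in g2) / (n2 - 1)
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        rows.append((protein, g1.mean() - g2.mean(), s2, n1 + n2 - 2, n1, n2))
    tab = pd.DataFrame(rows, columns=["protein", "logFC", "s2", "df", "n1", "n2"])
    d = tab["df"].mean()
    m = tab["s2"].mean()
    v = tab["s2"].var(ddof=1)
    c = v / m ** 2
    if c * d <= 2.0:
        d0, s02 = np.inf, m
    else:
        d0 = (2 * d - 4 + 4 * c * d) / (c * d - 2)
        if d0 <= 4.0:
            d0 = 4.01
        s02 = m * (d0 - 2) / d0
    out = {}
    for _, r in tab.iterrows():
        if np.isinf(d0):
            s2p, dft = s02, 1e9
        else:
            s2p = (d0 * s02 + r["df"] * r["s2"]) / (d0 + r["df"])
            dft = r["df"] + d0
        t = r["logFC"] / np.sqrt(s2p * (1 / r["n1"] + 1 / r["n2"]))
        out[r["protein"]] = (t, 2 * stats.t.sf(abs(t), dft))
    return out


class TestModeratedT:
    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.normal(size=(30, 10)),
                              index=[f"p{i}" for i in range(30)],
                              columns=[f"s{i}" for i in range(10)])
        manifest = _de_manifest(5, 5)
        res = cl.moderated_layer_de(matrix, manifest, 1, "E14.5", "CTRL",
                                    prior_df=0)
        for protein in matrix.index:
            t, p = stats.ttest_ind(matrix.loc[protein, :"s4"],
                                   matrix.loc[protein, "s5":], equal_var=True)
            assert res.loc[protein, "t"] == pytest.approx(t, abs=1e-9)
            assert res.loc[protein, "p_value"] == pytest.approx(p, abs=1e-9)

    def test_equal_group_means_give_zero(self):
        values = np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], (4, 1))
        matrix = pd.DataFrame(values, index=[f"p{i}" for i in range(4)],
                              columns=[f"s{i}" for i in range(6)])
        res = cl.moderated_layer_de(matrix, _de_manifest(3, 3), 1,
                                    "E14.5", "CTRL")
        assert np.allclose(res["logFC"], 0.0)
        assert np.allclose(res["t"], 0.0)

    def test_planted_effect_ranks_first_and_matches_oracle(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(rng.normal(0, 0.3, size=(20, 12)),
                              index=[f"p{i:02d}" for i in range(20)],
                              columns=[f"s{i}" for i in range(12)])
        matrix.iloc[7, :6] += 2.0  # 2-log2 planted effect in layer 1
        manifest = _de_manifest(6, 6)
        res = cl.moderated_layer_de(matrix, manifest, 1, "E14.5", "CTRL")
        assert res["t"].abs().idxmax() == "p07"
        oracle = _ebayes_oracle(matrix, np.array([True] * 6 + [False] * 6))
        for protein, (t, p) in oracle.items():
            assert res.loc[protein, "t"] == pytest.approx(t, abs=1e-9)
            assert res.loc[protein, "p_value"] == pytest.approx(p, abs=1e-9)

    def test_posterior_variance_is_convex_combination(self, corrected, manifest):
        out, _ = corrected
        res = cl.moderated_layer_de(out, manifest, 5, "E14.5", "CTRL")
        d0 = res["df_prior"].iloc[0]
        if np.isinf(d0):
            return
        s02 = (res["s2_post"] * (d0 + res["df"]) - res["df"] * res["s2"]) / d0
        lo = np.minimum(res["s2"], s02)
        hi = np.maximum(res["s2"], s02)
        assert ((res["s2_post"] >= lo - 1e-12) & (res["s2_post"] <= hi + 1e-12)).all()

    def test_small_layer_raises(self):
        matrix = pd.DataFrame(np.ones((3, 4)), index=list("abc"),
                              columns=[f"s{i}" for i in range(4)])
        manifest = _de_manifest(1, 3)
        with pytest.raises(ValueError, match="fewer than 2"):
            cl.moderated_layer_de(matrix, manifest, 1, "E14.5", "CTRL")

    def test_squeeze_underdispersed_gives_infinite_prior(self):
        s2 = np.full(50, 0.25)
        d0, s02 = squeeze_variances(s2, np.full(50, 10.0))
        assert np.isinf(d0)
        assert s02 == pytest.approx(0.25)


class TestBenjaminiHochberg:
    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=20),
           st.integers(0, 10**6))
    def test_matches_bruteforce_stepup(self, pvals, _seed):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(pvals, method="fdr_bh")[1]
        n = len(pvals)
        order = np.argsort(pvals, kind="mergesort")
        brute = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, pvals[i] * n / rank)
            brute[i] = running
        assert np.allclose(adj, brute, atol=1e-9)


class TestUniqueSignatures:
    @staticmethod
    def _table(proteins, logfcs, p=0.001):
        return pd.DataFrame({"logFC": logfcs, "p_value": p, "adj_p": p},
                            index=pd.Index(proteins, name="protein_id"))

    def test_disjoint_inputs_pass_through(self):
        tables = {1: self._table([f"A{i}" for i in range(10)], np.arange(10, 0, -1)),
                  2: self._table([f"B{i}" for i in range(10)], np.arange(10, 0, -1))}
        sigs = cl.unique_top_signatures(tables)
        assert list(sigs[1].index) == [f"A{i}" for i in range(10)]
        assert list(sigs[2].index) == [f"B{i}" for i in range(10)]

    def test_first_come_first_serve_claim(self):
        layer1 = self._table([f"P{i}" for i in range(1, 11)],
                             np.arange(20, 10, -1))
        layer2 = self._table(["P1"] + [f"P{i}" for i in range(11, 21)],
                             np.arange(21, 10, -1))
        sigs = cl.unique_top_signatures({1: layer1, 2: layer2})
        assert list(sigs[1].index) == [f"P{i}" for i in range(1, 11)]
        assert list(sigs[2].index) == [f"P{i}" for i in range(11, 21)]

    def test_short_signature_when_few_candidates(self):
        tables = {1: self._table(["X1", "X2", "X3", "X4"], [4.0, 3.0, 2.0, 1.0])}
        assert len(cl.unique_top_signatures(tables)[1]) == 4

    def test_insignificant_and_low_proteins_excluded(self):
        tab = self._table(["up", "down", "weak"], [2.0, -2.0, 1.0])
        tab.loc["weak", "p_value"] = 0.5
        sigs = cl.unique_top_signatures({1: tab})
        assert list(sigs[1].index) == ["up"]

    def test_claim_order_depends_on_layer_order(self, corrected, manifest):
        out, _ = corrected
        tables = cl.all_layer_de(out, manifest, "E14.5", "CTRL")
        forward = cl.unique_top_signatures(tables)
        reverse_tables = {-l: t for l, t in tables.items()}
        backward = {-l: s for l, s in
                    cl.unique_top_signatures(reverse_tables).items()}
        assert any(list(forward[l].index) != list(backward[l].index)
                   for l in forward)

    def test_signatures_disjoint_on_real_tables(self, corrected, manifest):
        out, _ = corrected
        sigs = cl.unique_top_signatures(cl.all_layer_de(out, manifest,
                                                        "E14.5", "CTRL"))
        all_proteins = [p for s in sigs.values() for p in s.index]
        assert len(all_proteins) == len(set(all_proteins))


class TestCorrelationMap:
    def test_self_map_is_identity_noise_free(self, clean_dataset, manifest):
        matrix, _ = clean_dataset
        tables = cl.all_layer_de(matrix, manifest, "E14.5", "CTRL")
        sigs = cl.unique_top_signatures(tables)
        means = cl.layer_mean_matrix(matrix, manifest, "E14.5", "CTRL")
        _, assign = cl.signature_correlation_map(sigs, means, means)
        assert list(assign["best_ctrl_layer"]) == list(range(1, 10))
        assert np.allclose(assign["best_r"], 1.0)

    def test_tied_query_layers_get_same_lowest_assignment(self):
        sigs = {1: pd.DataFrame(index=pd.Index(["a", "b", "c", "d"],
                                               name="protein_id"))}
        ctrl = pd.DataFrame({1: [1.0, 2.0, 3.0, 4.0], 2: [1.0, 2.0, 3.0, 4.0],
                             3: [4.0, 3.0, 2.0, 1.0]}, index=["a", "b", "c", "d"])
        query = pd.DataFrame({1: [2.0, 4.0, 6.0, 8.0], 2: [2.0, 4.0, 6.0, 8.0]},
                             index=["a", "b", "c", "d"])
        _, assign = cl.signature_correlation_map(sigs, ctrl, query)
        assert list(assign["best_ctrl_layer"]) == [1, 1]

    def test_zero_variance_vector_yields_missing(self):
        sigs = {1: pd.DataFrame(index=pd.Index(["a", "b", "c"],
                                               name="protein_id"))}
        ctrl = pd.DataFrame({1: [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        query = pd.DataFrame({1: [5.0, 5.0, 5.0]}, index=["a", "b", "c"])
        _, assign = cl.signature_correlation_map(sigs, ctrl, query)
        assert assign["best_ctrl_layer"].isna().all()

    def test_planted_identity_shift_maps_superficial_to_deep(self, corrected, manifest):
        out, _ = corrected
        tables = cl.all_layer_de(out, manifest, "E18.5", "CTRL")
        sigs = cl.unique_top_signatures(tables)
        ctrl = cl.layer_mean_matrix(out, manifest, "E18.5", "CTRL")
        gbl = cl.layer_mean_matrix(out, manifest, "E18.5", "GBL")
        _, assign = cl.signature_correlation_map(sigs, ctrl, gbl)
        shifted = assign.loc[[1, 2, 3, 4], "best_ctrl_layer"]
        assert (shifted >= 10).all()


class TestOverlap:
    def test_identical_and_disjoint(self):
        sig_a = {1: pd.DataFrame(index=pd.Index([f"p{i}" for i in range(10)]))}
        sig_b = {1: pd.DataFrame(index=pd.Index([f"q{i}" for i in range(10)]))}
        same = cl.signature_overlap({"CTRL": sig_a, "GL": sig_a})
        assert same.loc[1, "CTRL&GL"] == 10
        diff = cl.signature_overlap({"CTRL": sig_a, "GL": sig_b})
        assert diff.loc[1, "CTRL&GL"] == 0

    def test_superficial_overlap_exceeds_deep(self, corrected, manifest):
        out, _ = corrected
        sigs = {m: cl.unique_top_signatures(
                    cl.all_layer_de(out, manifest, "E14.5", m))
                for m in cl.MODELS}
        overlap = cl.signature_overlap(sigs)
        pair_cols = [c for c in overlap.columns if "&" in c]
        assert overlap.loc[1, pair_cols].mean() > overlap.loc[9, pair_cols].mean()
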