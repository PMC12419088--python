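"""Per-layer moderated differential abundance and unique layer signatures.

Each layer L_n of one genotype/timepoint is contrasted against all other
layers (L_all-n) with an empirical-Bayes moderated t-test: per-protein
residual variances are shrunk toward a common prior estimated by
inverse-gamma moment matching across proteins, and the t statistic gains the
prior degrees of freedom.  Per-layer signatures are the top 10 significantly
high-abundant proteins after earlier (more superficial) layers have claimed
overlapping proteins — the first-come-first-serve rule.  Signatures are then
used to map every genotype's layers onto the control layers by Pearson
correlation of per-layer mean abundance vectors.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import filter_by_validity

logger = logging.getLogger(__name__)

_BIG_DF = 1e9  # stands in for an infinite prior df in t quantiles


def squeeze_variances(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate prior df and prior variance by moment matching.

    Under the hierarchical model s2 ~ s0^2 * F(df, d0), the squared
    coefficient of variation of s2 is c = 2 (df + d0 - 2) / (df (d0 - 4)).
    Solving for d0 from the observed mean/variance of the sample variances
    gives the prior df; the prior variance follows from the marginal mean
    m = s0^2 d0 / (d0 - 2).  Under-dispersed variances give an infinite
    prior df (complete shrinkage to the common value).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    d = float(np.mean(df))
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1))
    c = v / m ** 2
    if c * d <= 2.0:
        return np.inf, m
    d0 = (2.0 * d - 4.0 + 4.0 * c * d) / (c * d - 2.0)
    if d0 <= 4.0 or not np.isfinite(d0):
        d0 = 4.01  # boundary of moment existence; minimal shrinkage stability
    s02 = m * (d0 - 2.0) / d0
    return float(d0), float(s02)


def moderated_layer_de(matrix: pd.DataFrame, manifest: pd.DataFrame,
                       layer: int, timepoint: str, model: str,
                       min_valid_fraction: float = 0.7,
                       prior_df: float | None = None) -> pd.DataFrame:
    """Moderated t-test of one layer against all other layers.

    Proteins must pass the validity filter over the genotype/timepoint
    samples and have >= 2 observed values in both groups; others are
    skipped.  ``prior_df`` overrides the estimated prior degrees of freedom
    (0 recovers the ordinary pooled two-sample t-test).  Returns one row per
    tested protein: logFC (layer minus rest), moderated t, p, BH-adjusted p,
    residual df, and the sample/posterior variances.
    """
    meta = manifest[(~manifest["excluded"])
                    & (manifest["timepoint"] == timepoint)
                    & (manifest["model"] == model)]
    samples = [s for s in meta["sample_id"] if s in matrix.columns]
    layers = meta.set_index("sample_id").loc[samples, "layer_index"]
    in_layer = (layers == layer).to_numpy()
    if in_layer.sum() < 2:
        raise ValueError(f"layer {layer} has fewer than 2 samples")

    sub = filter_by_validity(matrix[samples], min_valid_fraction)
    X = sub.to_numpy(dtype=float)
    g1, g2 = X[:, in_layer], X[:, ~in_layer]
    n1 = np.sum(~np.isnan(g1), axis=1)
    n2 = np.sum(~np.isnan(g2), axis=1)
    tested = (n1 >= 2) & (n2 >= 2)

    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(g1, axis=1)
        m2 = np.nanmean(g2, axis=1)
        v1 = np.nanvar(g1, axis=1, ddof=1)
        v2 = np.nanvar(g2, axis=1, ddof=1)
    df = n1 + n2 - 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df

    idx = sub.index[tested]
    logfc = (m1 - m2)[tested]
    s2_t, df_t = s2[tested], df[tested]
    n1_t, n2_t = n1[tested], n2[tested]

    if prior_df is None:
        d0, s02 = squeeze_variances(s2_t, df_t)
    elif prior_df == 0:
        d0, s02 = 0.0, float(np.nanmean(s2_t))
    else:
        d0 = float(prior_df)
        s02 = float(np.nanmean(s2_t))
    if np.isinf(d0):
        s2_post = np.full_like(s2_t, s02)
        df_total = np.full_like(df_t, _BIG_DF)
    else:
        s2_post = (d0 * s02 + df_t * s2_t) / (d0 + df_t)
        df_total = df_t + d0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = logfc / np.sqrt(s2_post * (1.0 / n1_t + 1.0 / n2_t))
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj = multipletests(p, method="fdr_bh")[1] if p.size else p

    return pd.DataFrame({"layer": layer, "logFC": logfc, "t": t,
                         "p_value": p, "adj_p": adj, "df": df_t,
                         "df_prior": d0, "s2": s2_t, "s2_post": s2_post},
                        index=pd.Index(idx, name="protein_id"))


def all_layer_de(matrix: pd.DataFrame, manifest: pd.DataFrame,
                 timepoint: str, model: str,
                 min_valid_fraction: float = 0.7) -> dict[int, pd.DataFrame]:
    """Moderated DE tables for every layer of a genotype/timepoint."""
    meta = manifest[(~manifest["excluded"])
                    & (manifest["timepoint"] == timepoint)
                    & (manifest["model"] == model)]
    return {int(l): moderated_layer_de(matrix, manifest, int(l), timepoint,
                                       model, min_valid_fraction)
            for l in sorted(meta["layer_index"].unique())}


def unique_top_signatures(tables: Mapping[int, pd.DataFrame], k: int = 10,
                          p_threshold: float = 0.05) -> dict[int, pd.DataFrame]:
    """Top-k unique high-abundant proteins per layer, first come first serve.

    Layers are processed in ascending (superficial to deep) order.  The
    candidate list of a layer contains its significantly high-abundant
    proteins (raw p below threshold, positive logFC) ordered by descending
    logFC, ties broken by smaller p then protein id; the first k candidates
    not claimed by an earlier layer form the signature.  Layers may end with
    fewer than k proteins.
    """
    claimed: set[str] = set()
    out: dict[int, pd.DataFrame] = {}
    for layer in sorted(tables):
        tab = tables[layer]
        cand = tab[(tab["p_value"] < p_threshold) & (tab["logFC"] > 0)].copy()
        # stable sort after ordering by protein id implements the tie-break
        cand = cand.loc[sorted(cand.index)].sort_values(
            ["logFC", "p_value"], ascending=[False, True], kind="mergesort")
        picked = [p for p in cand.index if p not in claimed][:k]
        claimed.update(picked)
        sig = cand.loc[picked, ["logFC", "p_value", "adj_p"]].copy()
        sig.insert(0, "rank", np.arange(1, len(picked) + 1))
        out[int(layer)] = sig
    return out


def layer_mean_matrix(matrix: pd.DataFrame, manifest: pd.DataFrame,
                      timepoint: str, model: str) -> pd.DataFrame:
    """Per-layer replicate-mean abundances (proteins x layers)."""
    meta = manifest[(~manifest["excluded"])
                    & (manifest["timepoint"] == timepoint)
                    & (manifest["model"] == model)]
    samples = [s for s in meta["sample_id"] if s in matrix.columns]
    layers = meta.set_index("sample_id").loc[samples, "layer_index"]
    means = matrix[samples].T.groupby(layers).mean().T
    means.columns = means.columns.astype(int)
    return means.sort_index(axis=1)


def _pairwise_pearson(a: np.ndarray, b: np.ndarray, min_pairs: int) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_pairs:
        return np.nan
    x, y = a[ok], b[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero-variance vector in correlation; assignment undefined")
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def signature_correlation_map(signatures: Mapping[int, pd.DataFrame],
                              ctrl_layer_means: pd.DataFrame,
                              query_layer_means: pd.DataFrame,
                              min_pairs: int = 3
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map each query layer to its best-correlated control layer.

    The correlation uses the concatenated signature-protein vector (all
    layers' signatures, in layer order).  Returns the full query x control
    correlation matrix and a per-query-layer table with the argmax control
    layer and correlation; ties resolve to the lowest control layer index.
    """
    proteins: list[str] = []
    for layer in sorted(signatures):
        proteins.extend(p for p in signatures[layer].index if p not in proteins)
    ctrl = ctrl_layer_means.reindex(proteins)
    query = query_layer_means.reindex(proteins)

    corr = pd.DataFrame(np.nan, index=query.columns, columns=ctrl.columns)
    for ql in query.columns:
        qv = query[ql].to_numpy(dtype=float)
        for cl in ctrl.columns:
            corr.loc[ql, cl] = _pairwise_pearson(qv, ctrl[cl].to_numpy(dtype=float),
                                                 min_pairs)
    rows = []
    for ql in corr.index:
        vec = corr.loc[ql]
        if vec.isna().all():
            rows.append((ql, pd.NA, np.nan))
            continue
        best = vec.idxmax()  # first occurrence wins -> lowest control layer
        rows.append((ql, int(best), float(vec[best])))
    assign = pd.DataFrame(rows, columns=["query_layer", "best_ctrl_layer",
                                         "best_r"]).set_index("query_layer")
    corr.index.name, corr.columns.name = "query_layer", "ctrl_layer"
    return corr, assign


def signature_overlap(signatures_by_model: Mapping[str, Mapping[int, pd.DataFrame]]
                      ) -> pd.DataFrame:
    """Pairwise and joint signature intersections per layer across genotypes."""
    models = list(signatures_by_model)
    layers = sorted({l for sigs in signatures_by_model.values() for l in sigs})
    rows = []
    for layer in layers:
        sets = {m: set(signatures_by_model[m].get(layer, pd.DataFrame()).index)
                for m in models}
        row: dict[str, object] = {"layer": layer}
        for i, a in enumerate(models):
            for b in models[i + 1:]:
                row[f"{a}&{b}"] = len(sets[a] & sets[b])
        row["all_models"] = len(set.intersection(*sets.values())) if models else 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("layer")
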