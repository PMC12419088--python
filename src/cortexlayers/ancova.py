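"""Per-cluster analysis of covariance: control versus one genotype.

For every protein within one layer cluster, abundance is regressed on the
layer index with genotype as group.  The slope difference (rate of change
along depth) is tested by the interaction term of the full model
``abundance ~ layer * group``; the abundance (intercept) difference by the
group term of the additive model ``abundance ~ layer + group``.  A protein
is significant when either test passes p < 0.05 and the full-model R^2
exceeds 0.1.  Proteins significant against exactly one genotype form the
model-specific sets (three-way Venn partition).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import filter_by_validity


def _ols_t(y: np.ndarray, X: np.ndarray, col: int) -> tuple[float, float, float]:
    """Coefficient, two-sided p of one column, and R^2 of a small OLS fit."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    dof = n - p
    if dof <= 0:
        return float(beta[col]), np.nan, np.nan
    sigma2 = rss / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(max(sigma2 * XtX_inv[col, col], 0.0))
    if se == 0:
        t = np.inf if beta[col] != 0 else 0.0
    else:
        t = beta[col] / se
    pval = 2.0 * stats.t.sf(abs(t), dof)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return float(beta[col]), float(pval), float(r2)


def ancova_fit(matrix: pd.DataFrame, manifest: pd.DataFrame,
               cluster_layers: Iterable[int], contrast_model: str,
               timepoint: str, min_valid_fraction: float = 0.7,
               p_threshold: float = 0.05,
               r2_threshold: float = 0.1) -> pd.DataFrame:
    """ANCOVA of every valid protein over one cluster's samples.

    Samples are the control plus ``contrast_model`` samples of the cluster's
    layers; proteins must pass the validity fraction over those samples and
    retain at least one sample per group and three distinct layers after
    casewise deletion.  Returns per protein: slope_diff, intercept_diff,
    p_slope, p_intercept, full-model r2, n and the significance flag; the
    number of proteins skipped by the validity filter is in
    ``attrs['n_skipped']``.
    """
    cluster_layers = sorted(set(int(l) for l in cluster_layers))
    if len(cluster_layers) < 3:
        raise ValueError("cluster must span at least 3 layers")
    meta = manifest[(~manifest["excluded"])
                    & (manifest["timepoint"] == timepoint)
                    & (manifest["model"].isin(["CTRL", contrast_model]))
                    & (manifest["layer_index"].isin(cluster_layers))]
    if set(meta["model"]) != {"CTRL", contrast_model}:
        raise ValueError("both groups must be present in the cluster")
    samples = [s for s in meta["sample_id"] if s in matrix.columns]
    info = meta.set_index("sample_id").loc[samples]
    layer = info["layer_index"].to_numpy(dtype=float)
    group = (info["model"] == contrast_model).to_numpy(dtype=float)

    sub = filter_by_validity(matrix[samples], min_valid_fraction)
    n_skipped = len(matrix.index) - len(sub.index)
    X_full = np.column_stack([np.ones_like(layer), layer, group, layer * group])
    X_add = X_full[:, :3]

    rows = []
    for protein, values in sub.iterrows():
        y = values.to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 6 or len(set(group[ok])) < 2 or len(set(layer[ok])) < 3:
            continue
        slope_diff, p_slope, r2 = _ols_t(y[ok], X_full[ok], 3)
        intercept_diff, p_intercept, _ = _ols_t(y[ok], X_add[ok], 2)
        significant = (min(p_slope, p_intercept) < p_threshold) and (r2 > r2_threshold)
        rows.append((protein, slope_diff, intercept_diff, p_slope, p_intercept,
                     r2, int(ok.sum()), bool(significant)))
    out = pd.DataFrame(rows, columns=["protein_id", "slope_diff", "intercept_diff",
                                      "p_slope", "p_intercept", "r2", "n",
                                      "significant"]).set_index("protein_id")
    out.attrs["n_skipped"] = n_skipped
    out.attrs["contrast"] = f"CTRL vs {contrast_model}"
    return out


def ancova_all_clusters(matrix: pd.DataFrame, manifest: pd.DataFrame,
                        clusters: Mapping[str, Sequence[int]],
                        contrast_model: str, timepoint: str,
                        **kwargs) -> pd.DataFrame:
    """Concatenate :func:`ancova_fit` over named clusters of one timepoint."""
    parts = []
    for name, layers in clusters.items():
        res = ancova_fit(matrix, manifest, layers, contrast_model, timepoint,
                         **kwargs)
        res = res.reset_index()
        res.insert(1, "cluster", name)
        parts.append(res)
    return pd.concat(parts, ignore_index=True)


def venn_partition(sets: Mapping[str, set]) -> dict[frozenset, set]:
    """Exhaustive Venn partition of named sets: region -> members."""
    names = list(sets)
    universe = set().union(*sets.values()) if sets else set()
    partition: dict[frozenset, set] = {}
    for item in universe:
        region = frozenset(n for n in names if item in sets[n])
        partition.setdefault(region, set()).add(item)
    return partition


@dataclass
class ModelSpecificSets:
    """Venn partition of significant proteins across the three contrasts."""

    specific: dict[str, set]            # exactly-one-contrast proteins
    partition: dict[frozenset, set]     # full Venn regions

    def shared_by_all(self) -> set:
        return set(self.partition.get(frozenset(self.specific), set()))


def model_specific_sets(results: Mapping[str, pd.DataFrame | set]
                        ) -> ModelSpecificSets:
    """Partition significant proteins into model-specific and shared sets.

    ``results`` maps genotype -> ANCOVA result table (the significant rows
    are used, pooled over clusters) or directly to a set of proteins.
    Specific proteins are significant in exactly one contrast.
    """
    sets = {}
    for model, res in results.items():
        if isinstance(res, pd.DataFrame):
            if "protein_id" in res.columns:
                sig = set(res.loc[res["significant"], "protein_id"])
            else:
                sig = set(res.index[res["significant"]])
        else:
            sig = set(res)
        sets[model] = sig
    partition = venn_partition(sets)
    specific = {m: set(partition.get(frozenset([m]), set())) for m in sets}
    return ModelSpecificSets(specific=specific, partition=partition)


def annotate_candidates(specific: Mapping[str, set],
                        interaction_table: Mapping[str, str] | None = None,
                        litminer_table: Mapping[str, int] | None = None,
                        flag_threshold_pct: float = 40.0
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach interaction-partner and literature categories to specific sets.

    ``interaction_table`` maps protein -> partner type (e.g. ``protein`` or
    ``mRNA``); ``litminer_table`` maps protein -> category 1/2/3.  Missing
    annotations become ``unknown``.  Returns the annotated long table and a
    per-genotype summary with the percentage of potential partners, flagged
    when it exceeds ``flag_threshold_pct``.
    """
    interaction_table = dict(interaction_table or {})
    litminer_table = dict(litminer_table or {})
    rows, summary = [], []
    for model, proteins in specific.items():
        n_partner = 0
        for protein in sorted(proteins):
            partner = interaction_table.get(protein, "unknown")
            category = litminer_table.get(protein, "unknown")
            n_partner += partner != "unknown"
            rows.append((model, protein, partner, category))
        n = len(proteins)
        pct = 100.0 * n_partner / n if n else 0.0
        summary.append((model, n, n_partner, pct, pct > flag_threshold_pct))
    annotated = pd.DataFrame(rows, columns=["model", "protein_id",
                                            "partner_type", "litminer_category"])
    summary_df = pd.DataFrame(summary, columns=["model", "n_proteins",
                                                "n_partners", "pct_partners",
                                                "flagged"]).set_index("model")
    return annotated, summary_df


def export_for_enrichment(de_table: pd.DataFrame, max_proteins: int = 50,
                          p_threshold: float = 0.05) -> list[str]:
    """Significantly high-abundant proteins ordered by logFC, capped at 50.

    The export rule for downstream gene-ontology queries (performed outside
    this package against live databases).
    """
    sig = de_table[(de_table["p_value"] < p_threshold) & (de_table["logFC"] > 0)]
    sig = sig.loc[sorted(sig.index)].sort_values(
        ["logFC", "p_value"], ascending=[False, True], kind="mergesort")
    return list(sig.index[:max_proteins])
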