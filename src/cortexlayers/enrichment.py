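"""Gene-set depth scoring and the Best-Match / DiffScore deconvolution.

Single-sample gene-set scores along depth use the combined-z method: per
gene, abundances (layer means of fully quantified proteins) are z-scored
across the layers of one genotype/timepoint; a set of m quantified members
scores sum(z_i)/sqrt(m) per layer.  Scores are then screened for linear
depth trends over the cortex-related layers (ordinary least squares, kept at
p < 0.05 and R^2 > 0.1).

The term deconvolution operates on a precomputed parent-term representation
table (term, model, layer, adjusted p).  Best Match is the (model, layer)
with the highest -log10 mean adjusted p; the DiffScore of a term is the
range, across the four genotypes, of the per-genotype sums of represented
layer indices, an absent genotype receiving the placeholder
S_n = -n(n+1)/2 (S_9 = -45, S_18 = -171).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MODEL_ORDER = ("CTRL", "GL", "GB", "GBL")


def gene_zscores(layer_means: pd.DataFrame) -> pd.DataFrame:
    """Z-score each protein's layer-mean profile across layers.

    Zero-variance profiles become all-zero rows (logged) so they contribute
    nothing to set scores.
    """
    mu = layer_means.mean(axis=1)
    sd = layer_means.std(axis=1, ddof=1)
    flat = sd[(sd == 0) | sd.isna()].index
    if len(flat):
        logger.info("%d zero-variance genes contribute 0", len(flat))
    return layer_means.sub(mu, axis=0).div(sd.where(sd > 0), axis=0).fillna(0.0)


def ssgsea_zscore(layer_means: pd.DataFrame,
                  gene_sets: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Combined-z enrichment of each gene set per layer.

    Score(set, layer) = sum over quantified members of z(gene, layer),
    divided by sqrt(m) where m is the number of quantified members.  Sets
    with no quantified member are skipped.  Returns terms x layers with the
    set size in ``attrs['set_sizes']``.
    """
    z = gene_zscores(layer_means)
    rows, sizes = {}, {}
    for term, members in gene_sets.items():
        present = [g for g in members if g in z.index]
        if not present:
            logger.warning("gene set %s has no quantified member; skipped", term)
            continue
        rows[term] = z.loc[present].sum(axis=0) / np.sqrt(len(present))
        sizes[term] = len(present)
    scores = pd.DataFrame(rows).T
    scores.index.name = "term"
    scores.attrs["set_sizes"] = sizes
    return scores


def gradient_filter(scores: pd.DataFrame,
                    cortex_layers: Sequence[int],
                    p_threshold: float = 0.05,
                    r2_threshold: float = 0.1) -> pd.DataFrame:
    """Linear depth-trend screen over the cortex-related layers.

    Ordinary least squares of each term's score on the layer index; a term
    is kept iff the slope is significant (p below threshold) and R^2 exceeds
    the threshold.  Constant scores yield slope 0 / R^2 0 and are dropped.
    """
    cortex_layers = sorted(int(l) for l in cortex_layers)
    if len(cortex_layers) < 3:
        raise ValueError("need at least 3 layers for a gradient fit")
    x = np.array(cortex_layers, dtype=float)
    rows = []
    for term, row in scores[cortex_layers].iterrows():
        y = row.to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 3 or np.std(y[ok]) == 0:
            rows.append((term, 0.0, float(np.nanmean(y)) if ok.any() else np.nan,
                         1.0, 0.0, "none", False))
            continue
        fit = stats.linregress(x[ok], y[ok])
        r2 = fit.rvalue ** 2
        kept = (fit.pvalue < p_threshold) and (r2 > r2_threshold)
        direction = "positive" if fit.slope > 0 else "negative"
        rows.append((term, float(fit.slope), float(fit.intercept),
                     float(fit.pvalue), float(r2), direction, bool(kept)))
    return pd.DataFrame(rows, columns=["term", "slope", "intercept", "p_slope",
                                       "r2", "direction", "kept"]
                        ).set_index("term")


def cross_timepoint_direction(fits_early: pd.DataFrame,
                              fits_late: pd.DataFrame) -> pd.Series:
    """Classify terms kept at both timepoints by slope-sign agreement.

    Returns per term: ``same-direction``, ``opposite`` or ``absent`` (kept
    at one timepoint at most).
    """
    terms = fits_early.index.union(fits_late.index)
    out = {}
    for term in terms:
        e = term in fits_early.index and bool(fits_early.loc[term, "kept"])
        l = term in fits_late.index and bool(fits_late.loc[term, "kept"])
        if not (e and l):
            out[term] = "absent"
        else:
            same = (fits_early.loc[term, "slope"] > 0) == (fits_late.loc[term, "slope"] > 0)
            out[term] = "same-direction" if same else "opposite"
    return pd.Series(out, name="direction_class")


def _validate_rep(rep: pd.DataFrame) -> pd.DataFrame:
    required = {"term", "model", "layer", "adj_p"}
    if not required.issubset(rep.columns):
        raise ValueError(f"representation table needs columns {sorted(required)}")
    if (rep["adj_p"] <= 0).any() or (rep["adj_p"] > 1).any():
        raise ValueError("adjusted p-values must lie in (0, 1]")
    return rep


def best_match(rep: pd.DataFrame) -> pd.DataFrame:
    """Best-representing (model, layer) per term.

    Score(model, layer) = -log10(mean adjusted p at that site); the best
    match is the argmax with deterministic tie-breaks (model order
    CTRL < GL < GB < GBL, then lower layer).
    """
    rep = _validate_rep(rep)
    grouped = (rep.groupby(["term", "model", "layer"])["adj_p"].mean()
               .reset_index())
    grouped["score"] = -np.log10(grouped["adj_p"])
    grouped["model_rank"] = grouped["model"].map(
        {m: i for i, m in enumerate(MODEL_ORDER)})
    rows = []
    for term, sub in grouped.groupby("term"):
        sub = sub.sort_values(["score", "model_rank", "layer"],
                              ascending=[False, True, True], kind="mergesort")
        top = sub.iloc[0]
        rows.append((term, top["model"], int(top["layer"]), float(top["score"])))
    return pd.DataFrame(rows, columns=["term", "best_model", "best_layer",
                                       "best_match"]).set_index("term")


def absent_model_sum(n_layers: int) -> int:
    """Placeholder layer-index sum for a genotype not representing a term.

    S_n = -(1 + n)/2 * n, i.e. minus the sum of all layer indices:
    S_9 = -45 at E14.5 and S_18 = -171 at E18.5.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be positive")
    return -(n_layers * (n_layers + 1)) // 2


def model_layer_sum(layers: Sequence[int], n_layers: int) -> int:
    """Sum of represented layer indices for one genotype (e.g. 4+5+7 = 16)."""
    layers = sorted(set(int(l) for l in layers))
    if any(l < 1 or l > n_layers for l in layers):
        raise ValueError(f"layer index outside [1, {n_layers}]")
    return int(sum(layers))


def diff_score(rep: pd.DataFrame, n_layers: int,
               models: Sequence[str] = MODEL_ORDER) -> pd.DataFrame:
    """Range of per-genotype layer-index sums per term.

    Per genotype the represented layer indices are summed; an absent
    genotype receives the placeholder ``absent_model_sum(n_layers)``.  The
    DiffScore is highest minus smallest sum: 0 means identical
    representation, larger values mean displaced or missing representation.
    """
    rep = _validate_rep(rep)
    placeholder = absent_model_sum(n_layers)
    rows = []
    for term, sub in rep.groupby("term"):
        sums = {}
        for model in models:
            layers = sub.loc[sub["model"] == model, "layer"]
            sums[model] = (model_layer_sum(layers, n_layers) if len(layers)
                           else placeholder)
        values = list(sums.values())
        rows.append((term, *[sums[m] for m in models],
                     int(max(values) - min(values))))
    cols = ["term", *[f"sum_{m}" for m in models], "diff_score"]
    return pd.DataFrame(rows, columns=cols).set_index("term")
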