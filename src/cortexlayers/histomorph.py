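"""Histomorphometry statistics on tabular cell measurements.

Migration distances of labelled cells are binned into ten 50-um bins from
the ventricular margin (0-500 um; the last bin is closed at 500 um and
distances beyond 500 um are reported as a separate overflow category).
Replicate (ROI) means of distance and cortex thickness are compared across
genotypes with one-way ANOVA plus Tukey's HSD; per-bin counts with a
two-factor (genotype x bin) ANOVA.  Proliferation is expressed as positive
cells per 100 um of ventricular margin, and cell-cycle re-entry fractions
(BrdU+Ki67+ among BrdU+) are compared with a Yates-corrected chi-square on
replicate-summed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

DEFAULT_BIN_WIDTH = 50.0
DEFAULT_N_BINS = 10


@dataclass
class BinCounts:
    counts: np.ndarray       # length n_bins
    overflow: int
    edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum() + self.overflow)


def bin_distances(distances: Sequence[float], bin_width: float = DEFAULT_BIN_WIDTH,
                  n_bins: int = DEFAULT_N_BINS) -> BinCounts:
    """Assign distances to half-open 50-um bins [0,50), ..., [450,500].

    The last bin is closed at the upper edge; larger distances count as
    overflow.  Negative distances are invalid.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size and (np.any(d < 0) or not np.all(np.isfinite(d))):
        raise ValueError("distances must be finite and non-negative")
    edges = np.arange(0.0, bin_width * (n_bins + 1), bin_width)
    counts, _ = np.histogram(d[d <= edges[-1]], bins=edges)
    overflow = int(np.sum(d > edges[-1]))
    return BinCounts(counts=counts, overflow=overflow, edges=edges)


def bin_count_table(cells: pd.DataFrame, marker: str | None = None,
                    bin_width: float = DEFAULT_BIN_WIDTH,
                    n_bins: int = DEFAULT_N_BINS) -> pd.DataFrame:
    """Per (model, ROI) bin counts; rows are replicates, columns bins."""
    sub = cells if marker is None else cells[cells[marker]]
    rows = []
    for (model, roi), grp in sub.groupby(["model", "roi_id"], sort=True):
        bc = bin_distances(grp["distance_um"], bin_width, n_bins)
        rows.append((model, roi, *bc.counts, bc.overflow))
    cols = ["model", "roi_id"] + [f"bin{i + 1}" for i in range(n_bins)] + ["overflow"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class GroupComparison:
    means: pd.Series
    f_statistic: float | None
    p_value: float | None
    tukey: pd.DataFrame | None   # group1, group2, meandiff, p_adj, reject

    def pairwise_p(self, a: str, b: str) -> float:
        tk = self.tukey
        row = tk[((tk["group1"] == a) & (tk["group2"] == b))
                 | ((tk["group1"] == b) & (tk["group2"] == a))]
        return float(row["p_adj"].iloc[0])


def group_comparison(values_by_group: Mapping[str, Sequence[float]]
                     ) -> GroupComparison:
    """One-way ANOVA with Tukey HSD across groups of replicate values.

    With fewer than two replicates in any group only descriptive means are
    returned (no test).
    """
    means = pd.Series({g: float(np.mean(v)) for g, v in values_by_group.items()})
    if any(len(v) < 2 for v in values_by_group.values()) or len(values_by_group) < 2:
        return GroupComparison(means=means, f_statistic=None, p_value=None,
                               tukey=None)
    f, p = stats.f_oneway(*values_by_group.values())
    data = np.concatenate([np.asarray(v, dtype=float)
                           for v in values_by_group.values()])
    labels = np.concatenate([[g] * len(v) for g, v in values_by_group.items()])
    with np.errstate(invalid="ignore", divide="ignore"):
        res = pairwise_tukeyhsd(data, labels)
    tk = pd.DataFrame(res.summary().data[1:],
                      columns=[c.strip() for c in res.summary().data[0]])
    tk = tk.rename(columns={"p-adj": "p_adj"})[
        ["group1", "group2", "meandiff", "p_adj", "reject"]]
    tk["p_adj"] = res.pvalues
    return GroupComparison(means=means, f_statistic=float(f), p_value=float(p),
                           tukey=tk)


@dataclass
class MigrationSummary:
    distance_means: pd.Series
    thickness_means: pd.Series
    distance_comparison: GroupComparison
    thickness_comparison: GroupComparison
    bin_anova: pd.DataFrame | None
    bin_tukey: dict[str, pd.DataFrame] = field(default_factory=dict)


def migration_summary(cells: pd.DataFrame, rois: pd.DataFrame,
                      marker: str = "BrdU") -> MigrationSummary:
    """Genotype comparison of migration distances and cortex thickness.

    ROI means of per-cell distance (marker-positive cells) feed a one-way
    ANOVA with Tukey HSD; the three thickness measurements per ROI are
    averaged and compared the same way; per-bin counts feed a two-factor
    genotype x bin ANOVA with per-bin Tukey tests across genotypes.
    """
    sub = cells[cells[marker]] if marker in cells.columns else cells
    roi_means = sub.groupby(["model", "roi_id"])["distance_um"].mean()
    dist_groups = {m: g.to_numpy() for m, g in roi_means.groupby(level="model")}

    thick = rois.set_index(["model", "roi_id"])[
        ["thickness_um_1", "thickness_um_2", "thickness_um_3"]].mean(axis=1)
    thick_groups = {m: g.to_numpy() for m, g in thick.groupby(level="model")}

    dist_cmp = group_comparison(dist_groups)
    thick_cmp = group_comparison(thick_groups)

    bins = bin_count_table(sub)
    bin_cols = [c for c in bins.columns if c.startswith("bin")]
    long = bins.melt(id_vars=["model", "roi_id"], value_vars=bin_cols,
                     var_name="bin", value_name="count")
    anova = None
    tukeys: dict[str, pd.DataFrame] = {}
    if bins.groupby("model")["roi_id"].count().min() >= 2:
        fit = ols("count ~ C(model) * C(bin)", data=long).fit()
        anova = anova_lm(fit, typ=2)
        for b, grp in long.groupby("bin"):
            per_model = {m: g["count"].to_numpy() for m, g in grp.groupby("model")}
            cmp = group_comparison(per_model)
            if cmp.tukey is not None:
                tukeys[b] = cmp.tukey
    return MigrationSummary(
        distance_means=pd.Series(dist_groups).map(np.mean),
        thickness_means=pd.Series(thick_groups).map(np.mean),
        distance_comparison=dist_cmp, thickness_comparison=thick_cmp,
        bin_anova=anova, bin_tukey=tukeys)


def proliferation_rate(positive_count: int, margin_length_um: float) -> float:
    """Positive cells per 100 um of ventricular margin."""
    if margin_length_um <= 0:
        raise ValueError("margin length must be positive")
    if positive_count < 0:
        raise ValueError("cell count must be non-negative")
    return positive_count / margin_length_um * 100.0


def proliferation_summary(cells: pd.DataFrame, rois: pd.DataFrame,
                          marker: str = "pHH3") -> tuple[pd.DataFrame, GroupComparison]:
    """Per-ROI proliferation rates for one marker plus the group comparison."""
    counts = cells[cells[marker]].groupby("roi_id")["cell_id"].count()
    table = rois[["roi_id", "model", "margin_length_um"]].copy()
    table["positive"] = table["roi_id"].map(counts).fillna(0).astype(int)
    table["rate_per_100um"] = [proliferation_rate(c, m) for c, m in
                               zip(table["positive"], table["margin_length_um"])]
    groups = {m: g["rate_per_100um"].to_numpy()
              for m, g in table.groupby("model")}
    return table, group_comparison(groups)


@dataclass
class ReentryResult:
    table: pd.DataFrame       # 2x2 counts
    chi2: float
    p_value: float
    fraction_ctrl: float
    fraction_model: float


def reentry_counts(cells: pd.DataFrame, model: str) -> tuple[int, int]:
    """(BrdU+Ki67+, BrdU+Ki67-) counts summed over all replicates."""
    sub = cells[(cells["model"] == model) & cells["BrdU"]]
    double = int(sub["Ki67"].sum())
    return double, int(len(sub) - double)


def reentry_test(ctrl_counts: tuple[int, int], model_counts: tuple[int, int],
                 continuity_correction: bool = True) -> ReentryResult:
    """Chi-square test of the cell-cycle re-entry fraction, CTRL vs model.

    Rows are (double-positive, single-positive), columns the two genotypes;
    Yates' continuity correction is applied by default.
    """
    table = np.array([[ctrl_counts[0], model_counts[0]],
                      [ctrl_counts[1], model_counts[1]]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined for a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    frame = pd.DataFrame(table.astype(int), index=["double_pos", "single_pos"],
                         columns=["CTRL", "model"])
    return ReentryResult(table=frame, chi2=float(chi2), p_value=float(p),
                         fraction_ctrl=ctrl_counts[0] / sum(ctrl_counts),
                         fraction_model=model_counts[0] / sum(model_counts))


def bin_positive_cells(cells: pd.DataFrame, marker: str,
                       bin_width: float = DEFAULT_BIN_WIDTH,
                       n_bins: int = DEFAULT_N_BINS) -> pd.DataFrame:
    """Per-genotype mean bin counts of marker-positive cells (heat-map table)."""
    table = bin_count_table(cells, marker=marker, bin_width=bin_width,
                            n_bins=n_bins)
    bin_cols = [c for c in table.columns if c.startswith("bin")]
    if table.empty:
        models = sorted(cells["model"].unique())
        return pd.DataFrame(0.0, index=models, columns=bin_cols)
    means = table.groupby("model")[bin_cols].mean()
    all_models = sorted(cells["model"].unique())
    return means.reindex(all_models).fillna(0.0)
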