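"""Synthetic study generator for depth-resolved cortical proteomics.

Emulates a four-genotype (CTRL, GL, GB, GBL), two-timepoint serial-ablation
design: nine ~40 um layers ablated from the skin surface into the cerebral
cortex at E14.5 and eighteen at E18.5, with hemisphere replicates, two
technical batch factors (laser-ablation batch and mass-spectrometry
measurement batch), anatomical compartment profiles, linear depth gradients,
intensity-dependent (left-censoring) missingness and genotype-specific
perturbations.  Every planted parameter is recorded in a :class:`GroundTruth`
object so downstream stages can be tested against known answers.

The generator also fabricates the auxiliary inputs consumed by later stages:
gene-set collections (GMT), per-term representation tables for the
Best-Match/DiffScore deconvolution, and per-cell distance tables for the
histomorphometry statistics.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MODELS = ("CTRL", "GL", "GB", "GBL")
TIMEPOINTS = ("E14.5", "E18.5")
LAYER_COUNTS = {"E14.5": 9, "E18.5": 18}

#: Anatomical compartment of each ablated layer, per timepoint.  At E14.5 the
#: skin/bone/meningeal layers are not yet separable and form one non-neural
#: block; at E18.5 the outer (skin/bone), meningeal and cortical blocks are
#: distinct.  These blocks are what consensus clustering should recover.
DEFAULT_COMPARTMENT_LAYOUT: dict[str, dict[int, str]] = {
    "E14.5": {**{l: "non_neural" for l in range(1, 5)},
              **{l: "cortex" for l in range(5, 10)}},
    "E18.5": {**{l: "outer" for l in range(1, 3)},
              **{l: "meningeal" for l in range(3, 10)},
              **{l: "cortex" for l in range(10, 19)}},
}

#: Which compartments a protein tissue class is elevated in.
CLASS_AFFINITY: dict[str, frozenset[str]] = {
    "surface": frozenset({"non_neural", "outer"}),
    "meninges": frozenset({"non_neural", "meningeal"}),
    "cortex": frozenset({"cortex"}),
}

#: Marker panels used to annotate anatomical identity of layer clusters.
DEFAULT_MARKER_PANELS: dict[str, tuple[str, ...]] = {
    "skin": ("FLG", "KRT14", "LOR"),
    "bone": ("COL1A1", "COL1A2", "SERPINF1"),
    "meninges": ("CDH11", "CRABP2", "TAGLN"),
    "cortex": ("TBR1", "MAP2", "BCL11B"),
}

_MARKER_CLASS = {
    **{p: "surface" for p in DEFAULT_MARKER_PANELS["skin"] + DEFAULT_MARKER_PANELS["bone"]},
    **{p: "meninges" for p in DEFAULT_MARKER_PANELS["meninges"]},
    **{p: "cortex" for p in DEFAULT_MARKER_PANELS["cortex"]},
}

# Proteins carrying the planted genotype-specific effects.  GL/GB/GBL receive
# disjoint intercept-shift sets (Venn-partition ground truth); the ECM
# receptors RPSA/ITGB1 plus P0061..P0078 carry the GBL slope inversion.
GL_SHIFT_SET = tuple(f"P{i:04d}" for i in range(1, 21))
GB_SHIFT_SET = tuple(f"P{i:04d}" for i in range(21, 41))
GBL_SHIFT_SET = tuple(f"P{i:04d}" for i in range(41, 61))
SLOPE_INVERSION_SET = ("RPSA", "ITGB1") + tuple(f"P{i:04d}" for i in range(61, 79))
ECM_PROTEIN = "LAMB1"

CORTEX_LAYERS = {"E14.5": tuple(range(5, 10)), "E18.5": tuple(range(10, 19))}
MENINGEAL_LAYERS = {"E14.5": tuple(range(1, 5)), "E18.5": tuple(range(3, 10))}


# ---------------------------------------------------------------------------
# Study design and manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Hemisphere counts per genotype and layer counts per timepoint."""

    hemispheres: Mapping[str, int] = field(
        default_factory=lambda: {"CTRL": 5, "GL": 3, "GB": 3, "GBL": 3})
    layers: Mapping[str, int] = field(
        default_factory=lambda: dict(LAYER_COUNTS))

    def __post_init__(self) -> None:
        for model, n in self.hemispheres.items():
            if model not in MODELS:
                raise ValueError(f"unknown model {model!r}")
            if n < 1:
                raise ValueError(f"hemisphere count for {model} must be >= 1")
        for tp, n in self.layers.items():
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r}")
            if n not in (9, 18):
                raise ValueError("layer counts must be 9 or 18")


@dataclass(frozen=True)
class Exclusion:
    """Selector flagging samples as excluded, with a reason.

    ``hemisphere`` is the 1-based hemisphere index within the model;
    ``layers=None`` matches all layers of the hemisphere.
    """

    reason: str
    model: str
    timepoint: str
    hemisphere: int
    layers: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r} in exclusion selector")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r} in exclusion selector")


#: The published exclusions: one E14.5 GBL sample (ROI shift), one E14.5 CTRL
#: sample (human keratin contamination) and nine deep E18.5 CTRL samples
#: (ROI shift).
DEFAULT_EXCLUSIONS: tuple[Exclusion, ...] = (
    Exclusion("ROI shift during sampling", "GBL", "E14.5", 1, (9,)),
    Exclusion("human keratin contamination", "CTRL", "E14.5", 4, (4,)),
    Exclusion("ROI shift during sampling", "CTRL", "E18.5", 5, tuple(range(10, 19))),
)

MANIFEST_COLUMNS = ["sample_id", "model", "timepoint", "hemisphere_id",
                    "layer_index", "la_batch", "m_batch", "excluded",
                    "exclusion_reason"]


def build_manifest(design: StudyDesign | None = None,
                   exclusions: Sequence[Exclusion] | None = None) -> pd.DataFrame:
    """Enumerate one sample per (model, timepoint, hemisphere, layer).

    Laser-ablation batches follow the study layout: hemispheres 1-3 of every
    genotype fall in batches LA1-LA3 and the additional CTRL hemispheres in
    the separate batch LA4; measurement batches are the eight
    (timepoint x ablation-batch) combinations.
    """
    design = StudyDesign() if design is None else design
    exclusions = DEFAULT_EXCLUSIONS if exclusions is None else tuple(exclusions)
    for ex in exclusions:  # re-validate plain tuples passed by callers
        if ex.model not in MODELS or ex.timepoint not in TIMEPOINTS:
            raise ValueError("invalid exclusion selector")

    m_batch_index = {(tp, la): i + 1 + 4 * t
                     for t, tp in enumerate(TIMEPOINTS)
                     for i, la in enumerate(("LA1", "LA2", "LA3", "LA4"))}
    rows = []
    for tp in TIMEPOINTS:
        n_layers = design.layers[tp]
        for model in MODELS:
            if model not in design.hemispheres:
                continue
            for h in range(1, design.hemispheres[model] + 1):
                hemi = f"{model}-{tp}-H{h}"
                la = f"LA{min(h, 3) if model != 'CTRL' else (h if h <= 3 else 4)}"
                mb = f"M{m_batch_index[(tp, la)]}"
                for layer in range(1, n_layers + 1):
                    excluded, reason = False, ""
                    for ex in exclusions:
                        if (ex.model == model and ex.timepoint == tp
                                and ex.hemisphere == h
                                and (ex.layers is None or layer in ex.layers)):
                            excluded, reason = True, ex.reason
                            break
                    rows.append((f"{hemi}-L{layer:02d}", model, tp, hemi,
                                 layer, la, mb, excluded, reason))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if manifest["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in manifest")
    return manifest


def manifest_counts(manifest: pd.DataFrame) -> dict:
    """Non-excluded sample accounting, overall and per timepoint/model."""
    keep = manifest[~manifest["excluded"]]
    by_tp = keep.groupby("timepoint")["sample_id"].count().to_dict()
    by_tp_model = {f"{tp} {model}": int(n) for (tp, model), n in
                   keep.groupby(["timepoint", "model"])["sample_id"].count().items()}
    return {"total": int(len(keep)),
            "per_timepoint": {k: int(v) for k, v in by_tp.items()},
            "per_timepoint_model": by_tp_model,
            "n_excluded": int(manifest["excluded"].sum())}


# ---------------------------------------------------------------------------
# Abundance matrix generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Perturbation:
    """A planted genotype-specific effect.

    kind:
      ``shift``        additive log2 shift on ``proteins`` in ``layers``
      ``slope``        additional per-layer slope on ``proteins`` in
                       ``layers`` (anchored at the shallowest listed layer)
      ``copy_layers``  layer-identity shift: the structural (noise-free,
                       batch-free) profile of each target layer is replaced
                       by the profile of its source layer for all proteins
    """

    kind: str
    model: str
    proteins: tuple[str, ...] | None = None
    layers: Mapping[str, tuple[int, ...]] | None = None
    size: float = 0.0
    layer_map: Mapping[str, Mapping[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("shift", "slope", "copy_layers"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not math.isfinite(self.size):
            raise ValueError("perturbation size must be finite")


def default_perturbations() -> tuple[Perturbation, ...]:
    """The study-condition perturbation set.

    * GBL layer-identity shift at E18.5: the four most superficial layers
      carry the profiles of the four deepest cortical layers (overmigration
      phenotype).
    * GBL meningeal drop of the ECM protein LAMB1.
    * Disjoint +1 log2 intercept shifts on cortical layers for GL, GB, GBL
      (model-specific ANCOVA ground truth).
    * GBL slope inversion of the ECM receptor module (RPSA/ITGB1 + partners):
      baseline depth slope -0.2 becomes +0.2 within the cortex.
    """
    return (
        Perturbation("copy_layers", "GBL",
                     layer_map={"E18.5": {1: 15, 2: 16, 3: 17, 4: 18}}),
        Perturbation("shift", "GBL", proteins=(ECM_PROTEIN,),
                     layers=MENINGEAL_LAYERS, size=-2.5),
        Perturbation("shift", "GL", proteins=GL_SHIFT_SET,
                     layers=CORTEX_LAYERS, size=1.0),
        Perturbation("shift", "GB", proteins=GB_SHIFT_SET,
                     layers=CORTEX_LAYERS, size=1.0),
        Perturbation("shift", "GBL", proteins=GBL_SHIFT_SET,
                     layers=CORTEX_LAYERS, size=1.0),
        Perturbation("slope", "GBL", proteins=SLOPE_INVERSION_SET,
                     layers=CORTEX_LAYERS, size=0.4),
    )


@dataclass(frozen=True)
class BatchEffectConfig:
    enabled: bool = True
    la_sd: float = 0.5       # SD of ablation-batch level shifts
    m_sd: float = 0.3        # SD of measurement-batch level shifts
    protein_sd: float = 0.15  # per-(protein,batch) jitter around the level
    scale_sd: float = 0.0    # multiplicative component, off by default


@dataclass(frozen=True)
class MissingnessConfig:
    """Left-censoring MNAR: P(missing) = logistic((midpoint - x)/scale)."""

    enabled: bool = True
    midpoint: float = 18.5
    scale: float = 1.0

    def probability(self, x: np.ndarray) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp((x - self.midpoint) / self.scale))
        if np.any((p < 0) | (p > 1)):
            raise ValueError("missingness probabilities outside [0,1]")
        return p


@dataclass(frozen=True)
class GeneratorConfig:
    n_proteins: int = 1000
    compartment_layout: Mapping[str, Mapping[int, str]] = field(
        default_factory=lambda: {tp: dict(m) for tp, m in DEFAULT_COMPARTMENT_LAYOUT.items()})
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"surface": 0.08, "meninges": 0.08, "cortex": 0.15})
    compartment_effect: Mapping[str, float] = field(
        default_factory=lambda: {"surface": 7.0, "meninges": 2.5, "cortex": 2.5})
    effect_jitter_sd: float = 0.4
    gradient_fraction: float = 0.30
    slope_range: tuple[float, float] = (0.05, 0.2)
    marker_slope: float = 0.12   # cortex markers rise with depth
    inversion_base_slope: float = -0.2
    base_mean: float = 21.0
    base_sd: float = 1.5
    noise_sd: float = 0.25
    batch_effects: BatchEffectConfig = field(default_factory=BatchEffectConfig)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    perturbations: tuple[Perturbation, ...] = field(default_factory=default_perturbations)
    seed: int = 0

    def protein_ids(self) -> list[str]:
        named = [p for panel in DEFAULT_MARKER_PANELS.values() for p in panel]
        named += [ECM_PROTEIN, "RPSA", "ITGB1"]
        n_generic = self.n_proteins - len(named)
        if n_generic < 100:
            raise ValueError("n_proteins too small for the default design")
        return named + [f"P{i:04d}" for i in range(1, n_generic + 1)]

    def validate_against_layout(self) -> None:
        for pert in self.perturbations:
            for tp, layers in (pert.layers or {}).items():
                known = self.compartment_layout.get(tp, {})
                bad = [l for l in layers if l not in known]
                if bad:
                    raise ValueError(f"perturbation references unknown layers {bad} at {tp}")
            for tp, mapping in (pert.layer_map or {}).items():
                known = self.compartment_layout.get(tp, {})
                bad = [l for pair in mapping.items() for l in pair if l not in known]
                if bad:
                    raise ValueError(f"perturbation references unknown layers {bad} at {tp}")


@dataclass
class GroundTruth:
    """Complete record of the planted parameters of one simulation."""

    proteins: pd.DataFrame          # index protein_id: tissue_class, base, delta, slope
    batch_offsets: pd.DataFrame     # index batch id, columns protein ids
    perturbations: tuple[Perturbation, ...]
    compartment_layout: Mapping[str, Mapping[int, str]]
    noise_sd: float
    missingness: MissingnessConfig
    seed: int

    def structural_value(self, protein: str, model: str, timepoint: str,
                         layer: int) -> float:
        """Noise-free, batch-free planted abundance."""
        row = self.proteins.loc[protein]
        eff_layer = layer
        for pert in self.perturbations:
            if pert.kind == "copy_layers" and pert.model == model:
                mapping = (pert.layer_map or {}).get(timepoint, {})
                eff_layer = mapping.get(layer, eff_layer)
        comp = self.compartment_layout[timepoint][eff_layer]
        value = row["base"] + row["slope"] * eff_layer
        if comp in CLASS_AFFINITY.get(row["tissue_class"], ()):
            value += row["delta"]
        for pert in self.perturbations:
            if pert.model != model or pert.proteins is None:
                continue
            if protein not in pert.proteins:
                continue
            layers = (pert.layers or {}).get(timepoint, ())
            if layer not in layers:
                continue
            if pert.kind == "shift":
                value += pert.size
            elif pert.kind == "slope":
                value += pert.size * (layer - min(layers))
        return float(value)

    def to_json(self, path) -> None:
        payload = {
            "proteins": self.proteins.reset_index().to_dict(orient="list"),
            "batch_offsets": {"index": list(self.batch_offsets.index),
                              "columns": list(self.batch_offsets.columns),
                              "values": self.batch_offsets.values.tolist()},
            "perturbations": [dataclasses.asdict(p) for p in self.perturbations],
            "compartment_layout": {tp: {str(k): v for k, v in m.items()}
                                   for tp, m in self.compartment_layout.items()},
            "noise_sd": self.noise_sd,
            "missingness": dataclasses.asdict(self.missingness),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _assign_protein_params(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = config.protein_ids()
    n = len(ids)
    tissue = np.array(["none"] * n, dtype=object)
    base = rng.normal(config.base_mean, config.base_sd, size=n)
    delta = np.zeros(n)
    slope = np.zeros(n)

    idx = {p: i for i, p in enumerate(ids)}
    reserved = set()

    def set_class(protein: str, cls: str) -> None:
        i = idx[protein]
        tissue[i] = cls
        delta[i] = max(0.5, rng.normal(config.compartment_effect[cls],
                                       config.effect_jitter_sd))
        reserved.add(protein)

    for protein, cls in _MARKER_CLASS.items():
        set_class(protein, cls)
        if cls == "cortex":
            slope[idx[protein]] = config.marker_slope
    set_class(ECM_PROTEIN, "meninges")
    # perturbation targets sit in the well-quantified abundance range so that
    # recovery tests measure the planted effect, not censoring
    for protein in SLOPE_INVERSION_SET:
        slope[idx[protein]] = config.inversion_base_slope
        base[idx[protein]] = rng.normal(config.base_mean + 1.5, 0.5)
        reserved.add(protein)
    for protein in GL_SHIFT_SET + GB_SHIFT_SET + GBL_SHIFT_SET:
        base[idx[protein]] = rng.normal(config.base_mean + 1.5, 0.5)
        reserved.add(protein)  # background class, shift carried by perturbation

    free = [p for p in ids if p not in reserved]
    rng.shuffle(free)
    pos = 0
    for cls, frac in config.class_fractions.items():
        n_cls = int(round(frac * n))
        for protein in free[pos:pos + n_cls]:
            set_class(protein, cls)
        pos += n_cls

    # depth gradients on a random subset of the unreserved proteins
    gradient_pool = [p for p in ids
                     if p not in SLOPE_INVERSION_SET and p not in _MARKER_CLASS]
    n_grad = int(round(config.gradient_fraction * len(gradient_pool)))
    chosen = rng.choice(len(gradient_pool), size=n_grad, replace=False)
    lo, hi = config.slope_range
    for j in chosen:
        i = idx[gradient_pool[j]]
        slope[i] = rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi)

    return pd.DataFrame({"tissue_class": tissue, "base": base,
                         "delta": delta, "slope": slope},
                        index=pd.Index(ids, name="protein_id"))


def simulate_abundance(config: GeneratorConfig,
                       manifest: pd.DataFrame,
                       seed: int | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a log2 abundance matrix for all non-excluded samples.

    Per protein and sample: compartment baseline + depth gradient +
    genotype perturbations + batch offsets + Gaussian noise, then masked by
    the left-censoring missingness mechanism.  Returns the matrix
    (proteins x samples) and the full :class:`GroundTruth`.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    config.validate_against_layout()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    proteins = _assign_protein_params(config, rng)
    ids = list(proteins.index)
    n_prot = len(ids)

    keep = manifest[~manifest["excluded"]].reset_index(drop=True)
    samples = list(keep["sample_id"])

    batches = sorted(set(keep["la_batch"])) + sorted(set(keep["m_batch"]))
    bcfg = config.batch_effects
    offsets = pd.DataFrame(0.0, index=pd.Index(batches, name="batch"), columns=ids)
    if bcfg.enabled:
        for b in batches:
            level_sd = bcfg.la_sd if b.startswith("LA") else bcfg.m_sd
            level = rng.normal(0.0, level_sd)
            offsets.loc[b] = level + rng.normal(0.0, bcfg.protein_sd, size=n_prot)

    truth = GroundTruth(proteins=proteins, batch_offsets=offsets,
                        perturbations=config.perturbations,
                        compartment_layout=config.compartment_layout,
                        noise_sd=config.noise_sd,
                        missingness=config.missingness, seed=seed)

    # structural values per unique condition, then broadcast to samples
    conds = keep[["model", "timepoint", "layer_index"]].drop_duplicates()
    structural = {}
    for model, tp, layer in conds.itertuples(index=False):
        structural[(model, tp, layer)] = np.array(
            [_structural_column(proteins, config, model, tp, int(layer))]
        ).ravel()

    X = np.empty((n_prot, len(samples)))
    for j, row in enumerate(keep.itertuples(index=False)):
        X[:, j] = structural[(row.model, row.timepoint, row.layer_index)]
        X[:, j] += offsets.loc[row.la_batch].to_numpy()
        X[:, j] += offsets.loc[row.m_batch].to_numpy()
    if config.noise_sd > 0:
        X += rng.normal(0.0, config.noise_sd, size=X.shape)

    if config.missingness.enabled:
        p_miss = config.missingness.probability(X)
        X = np.where(rng.random(X.shape) < p_miss, np.nan, X)

    matrix = pd.DataFrame(X, index=proteins.index, columns=samples)
    return matrix, truth


def _structural_column(proteins: pd.DataFrame, config: GeneratorConfig,
                       model: str, tp: str, layer: int) -> np.ndarray:
    layout = config.compartment_layout[tp]
    eff_layer = layer
    for pert in config.perturbations:
        if pert.kind == "copy_layers" and pert.model == model:
            eff_layer = (pert.layer_map or {}).get(tp, {}).get(layer, eff_layer)
    comp = layout[eff_layer]
    base = proteins["base"].to_numpy()
    delta = proteins["delta"].to_numpy()
    slope = proteins["slope"].to_numpy()
    affinity = proteins["tissue_class"].map(
        lambda c: comp in CLASS_AFFINITY.get(c, ())).to_numpy()
    values = base + slope * eff_layer + np.where(affinity, delta, 0.0)

    pidx = {p: i for i, p in enumerate(proteins.index)}
    for pert in config.perturbations:
        if pert.model != model or pert.proteins is None:
            continue
        layers = (pert.layers or {}).get(tp, ())
        if layer not in layers:
            continue
        rows = [pidx[p] for p in pert.proteins if p in pidx]
        if pert.kind == "shift":
            values[rows] += pert.size
        elif pert.kind == "slope":
            values[rows] += pert.size * (layer - min(layers))
    return values


# ---------------------------------------------------------------------------
# Gene sets and term-representation tables
# ---------------------------------------------------------------------------

def simulate_gene_sets(truth: GroundTruth, n_random: int = 30,
                       n_coherent: int = 20, size_range: tuple[int, int] = (5, 25),
                       seed: int = 0) -> dict[str, list[str]]:
    """Fabricate a gene-set collection over the simulated proteome.

    Coherent sets draw members from gradient proteins of a common slope sign
    (these produce linear depth trends in the combined-z scores); the special
    set ``cell_surface_receptor_signaling`` is the planted slope-inversion
    module (declining with depth in CTRL, inverted in GBL).  Random sets act
    as null controls.
    """
    rng = np.random.default_rng(seed)
    proteins = truth.proteins
    up = list(proteins.index[proteins["slope"] > 0.04])
    down = [p for p in proteins.index[proteins["slope"] < -0.04]
            if p not in SLOPE_INVERSION_SET]
    everything = list(proteins.index)
    lo, hi = size_range

    sets: dict[str, list[str]] = {
        "cell_surface_receptor_signaling": list(SLOPE_INVERSION_SET)}
    for i in range(n_coherent):
        pool = up if i % 2 == 0 else down
        m = int(rng.integers(lo, min(hi, len(pool)) + 1))
        members = rng.choice(pool, size=m, replace=False)
        sets[f"coherent_{'up' if i % 2 == 0 else 'down'}_{i:02d}"] = sorted(members)
    for i in range(n_random):
        m = int(rng.integers(lo, hi + 1))
        sets[f"random_{i:02d}"] = sorted(rng.choice(everything, size=m, replace=False))
    return sets


def simulate_term_table(n_terms: int = 30, n_layers: int = 9,
                        models: Sequence[str] = MODELS,
                        absent_rate: float = 0.25,
                        seed: int = 0) -> pd.DataFrame:
    """Fabricate a parent-term representation table (term, model, layer, adj_p).

    Stands in for the externally computed GO:BP enrichment/condensation step
    whose output feeds the Best-Match/DiffScore deconvolution.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_terms):
        term = f"term_{t:03d}"
        for model in models:
            if rng.random() < absent_rate:
                continue
            n_rep = int(rng.integers(1, 5))
            layers = rng.choice(np.arange(1, n_layers + 1), size=n_rep, replace=False)
            for layer in sorted(layers):
                rows.append((term, model, int(layer),
                             float(10 ** rng.uniform(-4, np.log10(0.05)))))
    return pd.DataFrame(rows, columns=["term", "model", "layer", "adj_p"])


# ---------------------------------------------------------------------------
# Cell tables for histomorphometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSimConfig:
    """Per-genotype distance distributions and marker positivity rates.

    Defaults plant the study's printed means: migration distance (um)
    CTRL 171.94 / GL 182.90 / GB 107.15 / GBL 112.85, cortex thickness
    CTRL 456.83 / GL 447.38 / GB 240.92 / GBL 225.12 and BrdU+ totals
    around 607/545/380/371 per region of interest.
    """

    mean_distance: Mapping[str, float] = field(default_factory=lambda: {
        "CTRL": 171.94, "GL": 182.90, "GB": 107.15, "GBL": 112.85})
    sd_distance: Mapping[str, float] = field(default_factory=lambda: {
        "CTRL": 70.0, "GL": 70.0, "GB": 60.0, "GBL": 60.0})
    thickness_mean: Mapping[str, float] = field(default_factory=lambda: {
        "CTRL": 456.83, "GL": 447.38, "GB": 240.92, "GBL": 225.12})
    thickness_sd: float = 15.0
    roi_mean_sd: float = 15.0     # replicate-level (ROI) shift of the mean
    cells_per_roi: Mapping[str, int] = field(default_factory=lambda: {
        "CTRL": 607, "GL": 545, "GB": 380, "GBL": 371})
    n_rois: int = 3
    margin_mean: float = 800.0
    margin_sd: float = 60.0
    rates: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: {
        "BrdU": {"CTRL": 1.0, "GL": 1.0, "GB": 1.0, "GBL": 1.0},
        "Ki67": {"CTRL": 0.30, "GL": 0.30, "GB": 0.45, "GBL": 0.45},
        "pHH3": {"CTRL": 0.05, "GL": 0.08, "GB": 0.03, "GBL": 0.03},
        "Reelin": {"CTRL": 0.02, "GL": 0.02, "GB": 0.01, "GBL": 0.02}})
    timepoint: str = "E16.5"

    def __post_init__(self) -> None:
        for model, mu in self.mean_distance.items():
            if mu < 0:
                raise ValueError(f"negative mean distance for {model}")
        for model, n in self.cells_per_roi.items():
            if n < 0:
                raise ValueError(f"negative cell count for {model}")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        for marker, per_model in self.rates.items():
            for model, r in per_model.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"rate for {marker}/{model} outside [0,1]")


def simulate_cells(config: CellSimConfig | None = None,
                   seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-cell distances and marker labels plus per-ROI measurements.

    Distances are normal, truncated to [0, ROI cortex thickness]; each ROI
    (biological replicate) receives a random shift of the mean to emulate
    between-animal variability.  Returns (cells, rois): cells has one row per
    cell with boolean marker columns; rois carries margin length and three
    thickness measurements per ROI.
    """
    config = CellSimConfig() if config is None else config
    rng = np.random.default_rng(seed)
    markers = list(config.rates)
    cell_rows = []
    roi_rows = []
    for model in config.mean_distance:
        for r in range(1, config.n_rois + 1):
            roi = f"{model}-ROI{r}"
            thickness = np.maximum(
                50.0, rng.normal(config.thickness_mean[model], config.thickness_sd, 3))
            margin = max(100.0, rng.normal(config.margin_mean, config.margin_sd))
            roi_rows.append((roi, model, config.timepoint, margin,
                             *np.round(thickness, 2)))
            upper = float(np.mean(thickness))
            mu = config.mean_distance[model] + rng.normal(0.0, config.roi_mean_sd)
            sd = config.sd_distance[model]
            a, b = (0.0 - mu) / sd, (upper - mu) / sd
            n_cells = int(rng.poisson(config.cells_per_roi[model]))
            dist = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n_cells,
                                       random_state=rng)
            flags = {m: rng.random(n_cells) < config.rates[m].get(model, 0.0)
                     for m in markers}
            for i in range(n_cells):
                cell_rows.append((f"{roi}-c{i:04d}", model, config.timepoint,
                                  roi, float(dist[i]),
                                  *[bool(flags[m][i]) for m in markers]))
    cells = pd.DataFrame(cell_rows, columns=["cell_id", "model", "timepoint",
                                             "roi_id", "distance_um", *markers])
    rois = pd.DataFrame(roi_rows, columns=["roi_id", "model", "timepoint",
                                           "margin_length_um", "thickness_um_1",
                                           "thickness_um_2", "thickness_um_3"])
    return cells, rois
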