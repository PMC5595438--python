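"""Synthetic lifespan-expression cohorts with known ground truth.

The generator emulates the statistical structure the analysis stages
consume: smooth per-gene trajectories with at most one planted turning
age, a cosine-eased rise (or fall) of magnitude |dE| to the turn
followed by a near-flat plateau or an opposite-direction reversal,
Gaussian noise, a female turning-age delay, gene sets whose turning ages
concentrate in a planted window, and cell-type marker blocks for the
specificity matrix.  Sampling is denser in early life, mirroring typical
lifespan cohorts.  Every generator is a pure function of (spec, seed).

A smooth ramp is used rather than a hard kink so the spline-plus-
finite-difference detector has measurable (nonzero) bias; "plateau"
genes decline by a small fixed fraction of |dE| after the turn so the
turning point is geometrically defined while the post-turn slope stays
statistically undetectable at the default noise level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .datamodel import ExpressionDataset, GeneAssociationTable, GeneSetCollection, SpecificityMatrix
from .trajectories import LifespanTrajectory

logger = logging.getLogger(__name__)

DEFAULT_CELL_TYPES = ("pyramidal", "interneuron", "astrocyte", "microglia",
                      "oligodendrocyte", "endothelial")


@dataclass
class PlantedSet:
    """A gene set whose members turn at ages ~ Normal(mean, sd)."""

    size: int
    turn_age_mean: float
    turn_age_sd: float


@dataclass
class CelltypeBlock:
    """A block of genes with elevated specificity in one cell type;
    optionally with its own planted turning-age distribution."""

    size: int
    turn_age_mean: float | None = None
    turn_age_sd: float | None = None


@dataclass
class SimulationSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror a human lifespan design: ages from the 14th
    gestational week (-0.5 y) to 78 y sampled more densely in early
    life, turning ages ~ Normal(26, 8) truncated to the lifespan, the
    female turn delayed by 1.5 y, mostly post-turn plateaus, and noise
    proportional to each gene's amplitude.
    """

    seed: int
    n_samples: int = 200
    n_genes: int = 500
    age_min: float = -0.5
    age_max: float = 78.0
    early_age: float = 20.0        # half the samples land below this age
    early_fraction: float = 0.5
    fraction_simple: float = 0.5
    turn_age_mean: float = 26.0
    turn_age_sd: float = 8.0
    amplitude_low: float = 0.5
    amplitude_high: float = 2.0
    fraction_up: float = 0.5
    plateau_fraction: float = 0.7
    plateau_drift: float = 0.05    # post-turn decline, fraction of |dE|
    reversal_depth: float = 0.8    # post-turn reversal, fraction of |dE|
    noise_sd: float = 0.25
    noise_relative: bool = True    # sd = noise_sd * |dE| when True
    sex_delay: float = 1.5         # added to female turning ages
    sex_effect: float = 0.0        # additive female expression offset
    baseline_low: float = 5.0
    baseline_high: float = 10.0
    planted_sets: dict[str, PlantedSet] = field(default_factory=dict)
    celltype_blocks: dict[str, CelltypeBlock] = field(default_factory=dict)
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    specificity_boost: float = 5.0
    species: str = "human"
    age_unit: str = "year"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name, frac in (("fraction_simple", self.fraction_simple),
                           ("fraction_up", self.fraction_up),
                           ("plateau_fraction", self.plateau_fraction),
                           ("early_fraction", self.early_fraction)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.age_min < self.turn_age_mean < self.age_max:
            raise ValueError("planted turning-age mean outside the lifespan")
        for name, ps in self.planted_sets.items():
            if not self.age_min < ps.turn_age_mean < self.age_max:
                raise ValueError(f"planted set {name!r}: turning age outside the lifespan")
        reserved = sum(ps.size for ps in self.planted_sets.values()) + \
            sum(b.size for b in self.celltype_blocks.values())
        if reserved > self.n_genes:
            raise ValueError("planted sets and cell-type blocks exceed n_genes")
        unknown = set(self.celltype_blocks) - set(self.cell_types)
        if unknown:
            raise ValueError(f"cell-type blocks for unknown types: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Per-gene and per-sample truth consistent with the generated matrix."""

    genes: pd.DataFrame        # turn_age, delta_e, direction, post_class, set, celltype
    samples: pd.DataFrame      # age, sex
    spec: SimulationSpec

    def turning_genes(self) -> pd.Index:
        return self.genes.index[self.genes["turn_age"].notna()]

    def gene_sets(self) -> GeneSetCollection:
        sets = {}
        for name in self.spec.planted_sets:
            sets[name] = list(self.genes.index[self.genes["set"] == name])
        return GeneSetCollection(sets, {n: "planted" for n in sets})

    def to_table(self, sex: str | None = None):
        """The planted turning points as a turning-point table, bypassing
        trajectory estimation (for exercising scoring and enrichment
        against exact ground truth).  ``sex="female"`` applies the
        planted female delay."""
        from .turning_points import TABLE_COLUMNS, TTTPTable
        g = self.genes
        age = g["turn_age"].to_numpy(dtype=float).copy()
        if sex == "female":
            age = np.minimum(age + self.spec.sex_delay, self.spec.age_max - 1.0)
        table = pd.DataFrame({
            "feature_id": g.index,
            "age": age,
            "age_rounded": np.round(age),
            "delta_e": np.where(np.isnan(age), np.nan, g["delta_e"]),
            "pre_direction": np.where(np.isnan(age), "", g["direction"]),
            "post_class": g["post_class"],
            "p_pre": np.nan, "p_post": np.nan, "q_pre": np.nan, "q_post": np.nan,
        }, columns=TABLE_COLUMNS)
        return TTTPTable(table.reset_index(drop=True), species=self.spec.species,
                         age_unit=self.spec.age_unit)

    def true_trajectory(self, feature_id: str, grid: np.ndarray,
                        sex: str = "male") -> LifespanTrajectory:
        """Noiseless trajectory of one gene on an age grid."""
        row = self.genes.loc[feature_id]
        turn = row["turn_age"]
        if sex == "female" and not np.isnan(turn):
            turn = min(turn + self.spec.sex_delay, self.spec.age_max - 1e-6)
        values = _gene_curve(np.asarray(grid, float), self.spec, turn,
                             row["delta_e"], row["post_class"], row["baseline"])
        step = float(np.min(np.diff(grid))) if len(grid) > 1 else 1.0
        return LifespanTrajectory(feature_id, grid, values, step)

    def true_trajectories(self, grid_step: float = 0.1,
                          sex: str = "male") -> dict[str, LifespanTrajectory]:
        lo, hi = self.spec.age_min, self.spec.age_max
        n = int(np.floor((hi - lo) / grid_step + 1e-9)) + 1
        grid = lo + grid_step * np.arange(n)
        return {fid: self.true_trajectory(fid, grid, sex=sex)
                for fid in self.genes.index}


# ---------------------------------------------------------------------------
# trajectory primitive
# ---------------------------------------------------------------------------

def _ramp(u: np.ndarray) -> np.ndarray:
    """Cosine-eased 0 -> 1 ramp with zero slope at both ends."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def _gene_curve(ages: np.ndarray, spec: SimulationSpec, turn_age: float,
                delta_e: float, post_class: str, baseline: float) -> np.ndarray:
    lo, hi = spec.age_min, spec.age_max
    if post_class == "simple" or np.isnan(turn_age):
        return baseline + delta_e * (ages - lo) / (hi - lo)
    pre = _ramp((ages - lo) / (turn_age - lo))
    post_u = (ages - turn_age) / max(hi - turn_age, 1e-9)
    depth = spec.plateau_drift if post_class == "plateau" else spec.reversal_depth
    post = 1.0 - depth * _ramp(post_u)
    return baseline + delta_e * np.where(ages <= turn_age, pre, post)


# ---------------------------------------------------------------------------
# dataset generator
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_dataset(spec: SimulationSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate an expression matrix plus its ground truth."""
    rng = np.random.default_rng(spec.seed)

    # samples: a denser early-life stratum plus the rest of the lifespan
    n_early = int(round(spec.early_fraction * spec.n_samples))
    early_hi = min(spec.early_age, spec.age_max)
    ages = np.sort(np.r_[rng.uniform(spec.age_min, early_hi, n_early),
                         rng.uniform(early_hi, spec.age_max,
                                     spec.n_samples - n_early)])
    sex = np.where(rng.random(spec.n_samples) < 0.5, "female", "male")
    sample_ids = [f"s{i + 1:04d}" for i in range(spec.n_samples)]
    samples = pd.DataFrame({"age": ages, "sex": sex}, index=pd.Index(sample_ids, name="sample_id"))

    # gene layout: planted sets, then cell-type blocks, then the rest
    gene_ids = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    set_label = np.array([""] * spec.n_genes, dtype=object)
    block_label = np.array([""] * spec.n_genes, dtype=object)
    cursor = 0
    planted_turn: dict[int, tuple[float, float]] = {}
    for name, ps in spec.planted_sets.items():
        for i in range(cursor, cursor + ps.size):
            set_label[i] = name
            planted_turn[i] = (ps.turn_age_mean, ps.turn_age_sd)
        cursor += ps.size
    for name, block in spec.celltype_blocks.items():
        for i in range(cursor, cursor + block.size):
            block_label[i] = name
            if block.turn_age_mean is not None:
                planted_turn[i] = (block.turn_age_mean, block.turn_age_sd or 1.0)
        cursor += block.size

    n_free = spec.n_genes - cursor
    n_simple = min(n_free, int(round(spec.fraction_simple * spec.n_genes)))
    is_simple = np.zeros(spec.n_genes, dtype=bool)
    if n_simple:
        simple_idx = cursor + rng.permutation(n_free)[:n_simple]
        is_simple[simple_idx] = True

    lo_t = max(spec.age_min + 1.0, spec.age_min)
    hi_t = spec.age_max - 1.0
    turn_age = np.full(spec.n_genes, np.nan)
    complex_mask = ~is_simple
    base_draws = _truncated_normal(rng, spec.turn_age_mean, spec.turn_age_sd,
                                   lo_t, hi_t, int(complex_mask.sum()))
    turn_age[complex_mask] = base_draws
    for i, (mu, sd) in planted_turn.items():
        turn_age[i] = _truncated_normal(rng, mu, sd, lo_t, hi_t, 1)[0]

    amplitude = rng.uniform(spec.amplitude_low, spec.amplitude_high, spec.n_genes)
    sign = np.where(rng.random(spec.n_genes) < spec.fraction_up, 1.0, -1.0)
    delta_e = sign * amplitude
    post_class = np.where(is_simple, "simple",
                          np.where(rng.random(spec.n_genes) < spec.plateau_fraction,
                                   "plateau", "reversal"))
    baseline = rng.uniform(spec.baseline_low, spec.baseline_high, spec.n_genes)

    female = sex == "female"
    values = np.empty((spec.n_genes, spec.n_samples))
    for g in range(spec.n_genes):
        turn_m = turn_age[g]
        curve = _gene_curve(ages, spec, turn_m, delta_e[g], post_class[g], baseline[g])
        if not np.isnan(turn_m) and spec.sex_delay and female.any():
            turn_f = min(turn_m + spec.sex_delay, hi_t)
            curve_f = _gene_curve(ages, spec, turn_f, delta_e[g], post_class[g], baseline[g])
            curve = np.where(female, curve_f, curve)
        sd = spec.noise_sd * (amplitude[g] if spec.noise_relative else 1.0)
        values[g] = curve + spec.sex_effect * female + rng.normal(0.0, sd, spec.n_samples) \
            if sd > 0 else curve + spec.sex_effect * female

    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="feature_id"),
                          columns=sample_ids)
    ds = ExpressionDataset(matrix, samples, species=spec.species, age_unit=spec.age_unit)
    genes = pd.DataFrame({"turn_age": turn_age, "delta_e": delta_e,
                          "direction": np.where(sign > 0, "upward", "downward"),
                          "post_class": post_class, "baseline": baseline,
                          "set": set_label, "celltype": block_label},
                         index=pd.Index(gene_ids, name="feature_id"))
    return ds, GroundTruth(genes, samples, spec)


# ---------------------------------------------------------------------------
# specificity and association generators
# ---------------------------------------------------------------------------

def simulate_specificity(spec: SimulationSpec,
                         truth: GroundTruth | None = None) -> SpecificityMatrix:
    """Block-structured gene x cell-type specificity: marker-block genes
    get boosted mean expression in their type, rows are then normalized."""
    rng = np.random.default_rng(spec.seed + 1)
    gene_ids = (truth.genes.index if truth is not None
                else pd.Index([f"g{i + 1:05d}" for i in range(spec.n_genes)]))
    n = len(gene_ids)
    mean_expr = rng.gamma(2.0, 1.0, size=(n, len(spec.cell_types)))
    if truth is not None:
        blocks = truth.genes["celltype"].to_numpy()
    else:
        blocks = np.array([""] * n, dtype=object)
        cursor = sum(ps.size for ps in spec.planted_sets.values())
        for name, block in spec.celltype_blocks.items():
            blocks[cursor:cursor + block.size] = name
            cursor += block.size
    for j, ct in enumerate(spec.cell_types):
        mask = blocks == ct
        mean_expr[mask, j] *= spec.specificity_boost
    frame = pd.DataFrame(mean_expr, index=gene_ids, columns=list(spec.cell_types))
    from .celltype import compute_specificity
    return compute_specificity(frame)


def simulate_associations(spec: SimulationSpec, scores: pd.Series | None = None,
                          coupling: str = "null", slope: float = 1.0,
                          noise: float = 1.0,
                          mhc_genes=() ) -> GeneAssociationTable:
    """Gene-level z-scores: standard normal under the null, or
    score-coupled (z = slope * score + noise * N(0,1)) for power studies.
    ``mhc_genes`` get chromosome-6 coordinates inside the extended MHC so
    region exclusion is exercised; other genes get dummy coordinates."""
    rng = np.random.default_rng(spec.seed + 2)
    if coupling not in ("null", "linear"):
        raise ValueError(f"unknown coupling {coupling!r}")
    gene_ids = (scores.index if scores is not None
                else pd.Index([f"g{i + 1:05d}" for i in range(spec.n_genes)]))
    z = rng.standard_normal(len(gene_ids))
    if coupling == "linear":
        if scores is None:
            raise ValueError("linear coupling needs a score vector")
        z = slope * scores.to_numpy(dtype=float) + noise * z
    table = pd.DataFrame({"zscore": z}, index=pd.Index(gene_ids, name="gene_id"))
    if len(mhc_genes):
        chrom = np.where(table.index.isin(mhc_genes), "6", "1")
        start = np.where(table.index.isin(mhc_genes), 26_000_000,
                         1_000_000 + 10_000 * np.arange(len(table)))
        table["chrom"] = chrom
        table["start"] = start
        table["stop"] = start + 5_000
    return GeneAssociationTable(table)
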