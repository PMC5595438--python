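"""Turning-point scores: age-linked (ALiGeT), decile (DeGeT) and peak
(PeGeT) gene-turning scores.

The age-linked score of gene g at target age T is

    S(g, T) = base^(-|A_g - T| / scale) * |dE|

with base 1.5 and scale 1 for human ages in years; mouse day distances
are divided by 650/78 so that a day of distance counts as the same
fraction of lifespan as a year does in humans (old age: 650 d vs 78 y).
At distance 6 human years the score is 1.5^-6 ~ 8.8% of the
zero-distance score.  The decile score assigns |dE| to the one
turning-count-decile age set containing A_g; the peak score is the
age-linked score at the modal turning year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MOUSE_LIFESPAN_SCALE
from .turning_points import TTTPTable

logger = logging.getLogger(__name__)


@dataclass
class ScoreParams:
    """Decay base, species distance scale and target-age grid."""

    base: float = 1.5
    species_scale: float = 1.0
    t_grid: np.ndarray = field(default_factory=lambda: np.arange(1, 79, dtype=float))

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.base <= 1:
            raise ValueError("decay base must exceed 1")
        if self.species_scale <= 0:
            raise ValueError("species scale must be positive")
        if self.t_grid.size == 0:
            raise ValueError("empty target-age grid")

    @classmethod
    def for_species(cls, species: str, base: float = 1.5) -> "ScoreParams":
        if species == "human":
            return cls(base=base, species_scale=1.0, t_grid=np.arange(1, 79, dtype=float))
        if species == "mouse":
            return cls(base=base, species_scale=MOUSE_LIFESPAN_SCALE,
                       t_grid=np.arange(1, 651, dtype=float))
        raise ValueError(f"unknown species {species!r}")


@dataclass
class AligetScores:
    """Gene x target-age score matrix."""

    matrix: pd.DataFrame
    params: ScoreParams

    @property
    def t_grid(self) -> np.ndarray:
        return self.matrix.columns.to_numpy(dtype=float)

    def column(self, t: float) -> pd.Series:
        return self.matrix[float(t)]


@dataclass
class AgeSets:
    """Ten age intervals with boundaries at turning-age deciles.

    ``edges`` are the n_sets-1 interior boundaries; a turning age equal
    to a boundary belongs to the lower set.  ``assignment`` maps turning
    feature -> set index.
    """

    edges: np.ndarray
    assignment: pd.Series
    n_sets: int

    def set_of_age(self, age: float) -> int:
        return int(np.searchsorted(self.edges, age, side="left"))

    def labels(self) -> list[str]:
        lo = [-np.inf, *self.edges]
        hi = [*self.edges, np.inf]
        return [f"set{k}({a:.3g},{b:.3g}]" for k, (a, b) in enumerate(zip(lo, hi))]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment.to_numpy(), minlength=self.n_sets)


# ---------------------------------------------------------------------------
# age-linked scores
# ---------------------------------------------------------------------------

def aliget_score(age: float, delta_e: float, t: float,
                 params: ScoreParams | None = None) -> float:
    """Score of a single turning gene at target age ``t``; genes with no
    turning point (NaN age) score zero."""
    params = params or ScoreParams()
    if age is None or np.isnan(age):
        return 0.0
    d = abs(float(age) - float(t)) / params.species_scale
    return params.base ** (-d) * abs(float(delta_e))


def aliget_matrix(table: TTTPTable, params: ScoreParams | None = None) -> AligetScores:
    """Dense gene x target-age score matrix over the params grid."""
    if params is None:
        params = ScoreParams.for_species(table.species)
    if table.species == "mouse" and params.species_scale == 1.0:
        raise ValueError("mouse table scored with human (unscaled) params")
    if table.species == "human" and params.species_scale != 1.0:
        raise ValueError("human table scored with non-unit species scale")
    tab = table.table
    ages = tab["age"].to_numpy(dtype=float)
    amp = np.abs(tab["delta_e"].to_numpy(dtype=float))
    t = params.t_grid
    with np.errstate(invalid="ignore"):
        dist = np.abs(ages[:, None] - t[None, :]) / params.species_scale
        scores = params.base ** (-dist) * amp[:, None]
    scores = np.nan_to_num(scores, nan=0.0)
    matrix = pd.DataFrame(scores, index=tab["feature_id"].to_numpy(), columns=t)
    return AligetScores(matrix, params)


# ---------------------------------------------------------------------------
# decile age sets and scores
# ---------------------------------------------------------------------------

def make_age_sets(table: TTTPTable, n_sets: int = 10) -> AgeSets:
    """Split turning features into ``n_sets`` age groups of approximately
    equal size (boundaries at turning-age quantiles, ties to the lower set)."""
    ages = table.turning_ages()
    if len(ages) < n_sets:
        raise ValueError(f"need at least {n_sets} turning features, got {len(ages)}")
    a = ages.to_numpy(dtype=float)
    edges = np.quantile(a, np.arange(1, n_sets) / n_sets)
    assignment = pd.Series(np.searchsorted(edges, a, side="left"), index=ages.index)
    sets = AgeSets(edges=edges, assignment=assignment, n_sets=n_sets)
    sizes = sets.sizes()
    if sizes.max() - sizes.min() > max(1, int((a[:, None] == edges[None, :]).sum())):
        logger.info("age-set sizes uneven due to tied ages: %s", sizes.tolist())
    return sets


@dataclass
class DegetScores:
    """Gene x age-set scores: |dE| in the set containing the turning age,
    zero elsewhere; non-turning genes all-zero."""

    matrix: pd.DataFrame
    age_sets: AgeSets


def deget_scores(table: TTTPTable, age_sets: AgeSets) -> DegetScores:
    tab = table.table
    universe = tab["feature_id"].to_numpy()
    turning = table.turning
    missing = set(turning["feature_id"]) - set(age_sets.assignment.index)
    if missing:
        raise ValueError(f"turning genes missing from the age sets: {sorted(missing)[:5]}")
    matrix = pd.DataFrame(0.0, index=universe, columns=age_sets.labels())
    cols = matrix.columns.to_numpy()
    for fid, amp in zip(turning["feature_id"], np.abs(turning["delta_e"])):
        matrix.at[fid, cols[age_sets.assignment[fid]]] = amp
    return DegetScores(matrix, age_sets)


# ---------------------------------------------------------------------------
# peak scores
# ---------------------------------------------------------------------------

def modal_turning_age(table: TTTPTable) -> float:
    """The whole year/day with the most turning points; ties break to
    the earliest age (logged)."""
    rounded = table.turning["age_rounded"].to_numpy(dtype=float)
    if rounded.size == 0:
        raise ValueError("no turning points")
    values, counts = np.unique(rounded, return_counts=True)
    winners = values[counts == counts.max()]
    if len(winners) > 1:
        logger.warning("tie for the modal turning age %s; using the earliest",
                       winners.tolist())
    return float(winners.min())


def peget_scores(aliget: AligetScores, table: TTTPTable) -> pd.Series:
    """Per-gene age-linked score at the modal turning year."""
    mode = modal_turning_age(table)
    grid = aliget.t_grid
    if mode not in grid:
        nearest = float(grid[np.argmin(np.abs(grid - mode))])
        logger.warning("modal age %g not on the target grid; using %g", mode, nearest)
        mode = nearest
    out = aliget.matrix[mode].copy()
    out.name = f"peget@{mode:g}"
    return out
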