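"""Detection, classification and summaries of trajectory turning points.

A turning point (TTTP) is the first age at which the derivative of a
gene's interpolated lifespan trajectory equals zero and changes sign —
the peak (or trough) after which expression plateaus or reverses.  The
derivative is approximated by central finite differences on the grid;
"equals zero" is operationalized as a sign change between adjacent grid
derivatives, with an exact-zero flat stretch dated to its first age.
Only the first turning point of a trajectory is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionDataset
from .trajectories import LifespanTrajectory

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["feature_id", "age", "age_rounded", "delta_e", "pre_direction",
                 "post_class", "p_pre", "p_post", "q_pre", "q_post"]


@dataclass
class TurningPoint:
    """First turning point of one feature's trajectory.

    ``age`` is the grid age of the derivative sign change; ``delta_e``
    is the signed expression change from the trajectory start to the
    turning age (its sign defines ``pre_direction``).
    """

    feature_id: str
    age: float
    delta_e: float
    pre_direction: str            # upward | downward
    post_class: str = "unclassified"   # plateau | reversal | continuation | unclassified
    p_pre: float = np.nan
    p_post: float = np.nan
    q_pre: float = np.nan
    q_post: float = np.nan


@dataclass
class TTTPTable:
    """Per-feature turning points plus the simple (monotone) features.

    ``table`` has one row per feature; simple features carry NaN ages.
    ``age_rounded`` is the turning age rounded to the nearest whole age
    unit (year/day), the resolution at which results are reported.
    """

    table: pd.DataFrame
    species: str = "human"
    age_unit: str = "year"

    def __post_init__(self) -> None:
        if self.table["feature_id"].duplicated().any():
            raise ValueError("at most one turning point per feature")

    @property
    def turning(self) -> pd.DataFrame:
        return self.table[self.table["age"].notna()]

    @property
    def n_turning(self) -> int:
        return int(self.table["age"].notna().sum())

    def turning_ages(self) -> pd.Series:
        t = self.turning
        return pd.Series(t["age"].to_numpy(dtype=float),
                         index=t["feature_id"].to_numpy())

    def feature_universe(self) -> list[str]:
        return list(self.table["feature_id"])


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_turning_point(traj: LifespanTrajectory) -> TurningPoint | None:
    """First derivative sign change of a trajectory, or None if monotone.

    Differences between adjacent grid values give the central-difference
    derivative estimate at the midpoints of the grid intervals.  A sign
    change between adjacent nonzero midpoint derivatives dates the
    turning point at the grid age between them (the midpoint of the
    bracketing pair); a transition into an exact-zero stretch dates it
    at the stretch's first age (unless the derivative later resumes the
    same sign, a saddle, which is skipped).
    """
    v = traj.values
    if len(v) < 3:
        raise ValueError("trajectory needs at least 3 grid points")
    # derivative at interval midpoints; the age between intervals j-1
    # and j is the grid age traj.age_grid[j]
    ages = 0.5 * (traj.age_grid[1:] + traj.age_grid[:-1])
    d = np.diff(v) / np.diff(traj.age_grid)
    s = np.sign(d)

    age_turn = None
    i = 0
    m = len(s)
    while i < m:
        if s[i] == 0:
            i += 1
            continue
        # find the next index whose sign differs
        j = i + 1
        while j < m and s[j] == s[i]:
            j += 1
        if j >= m:
            break  # monotone to the end
        if s[j] == -s[i]:
            age_turn = 0.5 * (ages[j - 1] + ages[j])
            break
        # s[j] == 0: exact-zero stretch; see what follows it
        k = j
        while k < m and s[k] == 0:
            k += 1
        if k >= m or s[k] == -s[i]:
            # first age of the exact-zero stretch (a grid age)
            age_turn = traj.age_grid[j]
            break
        i = k  # same sign resumes: saddle, keep scanning

    if age_turn is None:
        return None
    idx = int(np.argmin(np.abs(traj.age_grid - age_turn)))
    delta_e = float(traj.values[idx] - traj.values[0])
    direction = "upward" if delta_e >= 0 else "downward"
    return TurningPoint(traj.feature_id, float(age_turn), delta_e, direction)


def detect_all(trajectories, species: str = "human",
               age_unit: str = "year") -> TTTPTable:
    """Build a turning-point table over a collection of trajectories
    (mapping or iterable); non-turning features are kept, flagged simple."""
    if isinstance(trajectories, dict):
        trajectories = trajectories.values()
    rows = []
    for traj in trajectories:
        tp = detect_turning_point(traj)
        if tp is None:
            rows.append({"feature_id": traj.feature_id, "age": np.nan,
                         "age_rounded": np.nan, "delta_e": np.nan,
                         "pre_direction": "", "post_class": "simple",
                         "p_pre": np.nan, "p_post": np.nan,
                         "q_pre": np.nan, "q_post": np.nan})
        else:
            rows.append({"feature_id": tp.feature_id, "age": tp.age,
                         "age_rounded": float(np.round(tp.age)),
                         "delta_e": tp.delta_e, "pre_direction": tp.pre_direction,
                         "post_class": tp.post_class, "p_pre": tp.p_pre,
                         "p_post": tp.p_post, "q_pre": tp.q_pre, "q_post": tp.q_post})
    return TTTPTable(pd.DataFrame(rows, columns=TABLE_COLUMNS),
                     species=species, age_unit=age_unit)


# ---------------------------------------------------------------------------
# classification (plateau / reversal / continuation)
# ---------------------------------------------------------------------------

def _segment_slope(ages: np.ndarray, y: np.ndarray):
    if len(ages) < 3 or len(np.unique(ages)) < 2:
        return np.nan, np.nan
    res = stats.linregress(ages, y)
    slope = float(res.slope)
    p = float(res.pvalue)
    if np.isnan(p):  # zero-variance response: slope 0, no evidence of change
        p = 1.0
    return slope, p


def classify_turning_points(ds: ExpressionDataset, table: TTTPTable,
                            fdr: float = 0.05) -> TTTPTable:
    """Fill post-turn classes from sample-level linear fits.

    Simple linear regressions of expression on age are fitted separately
    to samples at ages <= and >= each feature's turning age; slope
    p-values are pooled across features and BH-adjusted at the given
    FDR.  Features without a significant pre-turn slope stay
    unclassified (and are excluded from trajectory-characteristics
    summaries); otherwise the post-turn slope decides: not significant
    -> plateau, significant opposite sign -> reversal, significant same
    sign -> continuation.
    """
    ages = ds.sample_age
    tab = table.table.copy()
    turning = tab["age"].notna()
    slopes_pre, slopes_post, p_pre, p_post, idx = [], [], [], [], []
    for i in tab.index[turning]:
        fid, a_g = tab.at[i, "feature_id"], tab.at[i, "age"]
        y = ds.values.loc[fid].to_numpy(dtype=float)
        pre, post = ages <= a_g, ages >= a_g
        if pre.sum() < 3 or post.sum() < 3:
            logger.info("feature %s: <3 samples on one side of the turn", fid)
            tab.at[i, "post_class"] = "unclassified"
            continue
        s1, pv1 = _segment_slope(ages[pre], y[pre])
        s2, pv2 = _segment_slope(ages[post], y[post])
        slopes_pre.append(s1); slopes_post.append(s2)
        p_pre.append(pv1); p_post.append(pv2); idx.append(i)

    if idx:
        q_pre = multipletests(p_pre, alpha=fdr, method="fdr_bh")[1]
        q_post = multipletests(p_post, alpha=fdr, method="fdr_bh")[1]
        for k, i in enumerate(idx):
            tab.at[i, "p_pre"], tab.at[i, "p_post"] = p_pre[k], p_post[k]
            tab.at[i, "q_pre"], tab.at[i, "q_post"] = q_pre[k], q_post[k]
            if not (q_pre[k] <= fdr):
                tab.at[i, "post_class"] = "unclassified"
            elif not (q_post[k] <= fdr):
                tab.at[i, "post_class"] = "plateau"
            elif np.sign(slopes_post[k]) == -np.sign(slopes_pre[k]):
                tab.at[i, "post_class"] = "reversal"
            else:
                tab.at[i, "post_class"] = "continuation"
    return TTTPTable(tab, species=table.species, age_unit=table.age_unit)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def tttp_summary(table: TTTPTable, bin_width: float = 1.0) -> dict:
    """Histogram (percent of TTTPs per age bin), cumulative fraction by
    age, and the mean turning age."""
    ages = table.turning["age"].to_numpy(dtype=float)
    if ages.size == 0:
        raise ValueError("no turning points to summarize")
    lo = np.floor(ages.min() / bin_width) * bin_width
    hi = np.ceil(ages.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(ages, bins=edges)
    hist = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "percent": 100.0 * counts / ages.size})
    order = np.sort(ages)
    cumulative = pd.DataFrame({"age": order,
                               "cumulative_fraction": np.arange(1, ages.size + 1) / ages.size})
    return {"histogram": hist, "cumulative": cumulative,
            "mean_age": float(ages.mean()), "n_turning": int(ages.size)}


def decile_age_groups(table: TTTPTable, n_groups: int = 10) -> pd.Series:
    """Group turning features by deciles of turning age (ties to the
    lower group); used for age-binned trajectory summaries."""
    from .scoring import make_age_sets
    return make_age_sets(table, n_sets=n_groups).assignment


def compare_sex_tttp_ages(male_table: TTTPTable, female_table: TTTPTable,
                          paired: bool = True,
                          exclude_features: set | None = None) -> dict:
    """Test for a female-male difference in turning ages.

    Features turning in both sexes are paired by feature id and the
    Wilcoxon signed-rank test applied to (female age - male age); the
    unpaired rank-sum variant is available.  ``exclude_features`` allows
    e.g. dropping X-chromosome genes.
    """
    m = male_table.turning_ages()
    f = female_table.turning_ages()
    if exclude_features:
        m = m[~m.index.isin(exclude_features)]
        f = f[~f.index.isin(exclude_features)]
    shared = m.index.intersection(f.index)
    if paired:
        if len(shared) < 10:
            raise ValueError(f"only {len(shared)} features turn in both sexes")
        diff = (f[shared] - m[shared]).to_numpy(dtype=float)
        if np.allclose(diff, 0.0):
            return {"statistic": 0.0, "p_value": 1.0, "n": len(shared),
                    "median_shift": 0.0, "test": "wilcoxon_signed_rank"}
        res = stats.wilcoxon(diff, zero_method="zsplit")
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
                "n": len(shared), "median_shift": float(np.median(diff)),
                "test": "wilcoxon_signed_rank"}
    res = stats.mannwhitneyu(f.to_numpy(float), m.to_numpy(float),
                             alternative="two-sided")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n": int(len(m) + len(f)),
            "median_shift": float(np.median(f) - np.median(m)),
            "test": "mann_whitney_u"}
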