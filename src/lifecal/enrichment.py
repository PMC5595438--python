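"""Bootstrap, covariate-matched and shuffle tests for elevated
turning-point scores of gene sets and genome-wide association statistics.

The plain test compares the mean score of a target list against the
means of random same-length lists drawn from the expressed background;
the one-sided enrichment p-value uses the add-one rule
p = (1 + #{null >= observed}) / (1 + n_boot).  The matched variant draws
the i-th gene of each random list from the same transcript-length x GC
decile grid cell as the i-th target gene, removing mutation-rate
confounds.  The shuffle test couples per-gene association z-scores with
turning scores via the statistic sum_g z_g * s_g under permutation of z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import FeatureAnnotation, GeneAssociationTable
from .scoring import AligetScores, DegetScores
from .turning_points import TTTPTable

logger = logging.getLogger(__name__)

#: extended MHC (GRCh37) default for association-score exclusion
EXTENDED_MHC = ("6", 25_000_000, 34_000_000)


@dataclass
class BootstrapResult:
    observed_mean: float
    null_mean: float
    null_sd: float
    n_boot: int
    p_raw: float
    p_adjusted: float = np.nan
    correction: str = "none"
    seed: int | None = None
    note: str = ""


@dataclass
class EnrichmentWindow:
    """A contiguous run of target ages significant after correction."""

    start: float
    end: float
    ages: np.ndarray

    def __contains__(self, age: float) -> bool:
        return self.start <= age <= self.end

    @property
    def span(self) -> float:
        return self.end - self.start

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


def bonferroni(p: float | np.ndarray, n_tests: int):
    return np.minimum(1.0, np.asarray(p, dtype=float) * n_tests)


# ---------------------------------------------------------------------------
# shared resampling machinery
# ---------------------------------------------------------------------------

def _clean_target(target, background) -> list:
    bg = set(background)
    seen = dict.fromkeys(target)
    kept = [g for g in seen if g in bg]
    dropped = len(seen) - len(kept)
    if dropped:
        logger.info("dropped %d target genes absent from the background", dropped)
    if not kept:
        raise ValueError("target list empty after restricting to the background")
    return kept


def sample_index_matrix(rng: np.random.Generator, n: int, size: int,
                        n_boot: int) -> np.ndarray:
    """(n_boot, size) indices, each row a without-replacement draw from
    range(n)."""
    if size > n:
        raise ValueError("list size exceeds background size")
    out = np.empty((n_boot, size), dtype=np.int64)
    for b in range(n_boot):
        out[b] = rng.choice(n, size=size, replace=False)
    return out


def _null_means(values: np.ndarray, idx: np.ndarray,
                chunk: int = 256) -> np.ndarray:
    """Row means of values[idx]; values may be (n,) or (n, k) giving
    null means of shape (n_boot,) or (n_boot, k)."""
    n_boot = idx.shape[0]
    if values.ndim == 1:
        return values[idx].mean(axis=1)
    out = np.empty((n_boot, values.shape[1]))
    for s in range(0, n_boot, chunk):
        out[s:s + chunk] = values[idx[s:s + chunk]].mean(axis=1)
    return out


def _p_one_sided(null: np.ndarray, observed: float | np.ndarray):
    n = null.shape[0]
    return (1.0 + (null >= observed).sum(axis=0)) / (1.0 + n)


# ---------------------------------------------------------------------------
# plain bootstrap set test
# ---------------------------------------------------------------------------

def bootstrap_set_test(scores: pd.Series, target, background=None,
                       n_boot: int = 10_000, seed: int | None = 0,
                       rng: np.random.Generator | None = None) -> BootstrapResult:
    """One-sided enrichment of a gene list's mean score over random
    same-length lists from the background."""
    background = list(background) if background is not None else list(scores.index)
    target = _clean_target(target, background)
    values = scores.loc[background].to_numpy(dtype=float)
    observed = float(scores.loc[target].mean())
    if len(target) == len(background):
        logger.warning("target equals the background; enrichment is degenerate")
        return BootstrapResult(observed, observed, 0.0, n_boot, 1.0, seed=seed,
                               note="degenerate: target equals background")
    rng = rng if rng is not None else np.random.default_rng(seed)
    idx = sample_index_matrix(rng, len(background), len(target), n_boot)
    null = _null_means(values, idx)
    return BootstrapResult(observed, float(null.mean()), float(null.std(ddof=1)),
                           n_boot, float(_p_one_sided(null, observed)), seed=seed)


# ---------------------------------------------------------------------------
# per-age windows / per-set tests
# ---------------------------------------------------------------------------

def _multi_column_bootstrap(matrix: pd.DataFrame, target, background,
                            n_boot: int, seed: int | None):
    """Shared-draw bootstrap over every column of a gene x condition
    score matrix; returns (columns, observed, null_mean, null_sd, p_raw)."""
    background = list(background) if background is not None else list(matrix.index)
    target = _clean_target(target, background)
    S = matrix.loc[background].to_numpy(dtype=float)
    t_pos = pd.Index(background).get_indexer(target)
    observed = S[t_pos].mean(axis=0)
    rng = np.random.default_rng(seed)
    idx = sample_index_matrix(rng, len(background), len(target), n_boot)
    null = _null_means(S, idx)
    p_raw = _p_one_sided(null, observed)
    return observed, null.mean(axis=0), null.std(axis=0, ddof=1), p_raw


def _contiguous_windows(ages: np.ndarray, significant: np.ndarray) -> list[EnrichmentWindow]:
    windows = []
    run: list[float] = []
    step = np.min(np.diff(ages)) if len(ages) > 1 else 1.0
    for a, sig in zip(ages, significant):
        if sig and (not run or a - run[-1] <= step * 1.5):
            run.append(a)
        else:
            if run:
                windows.append(EnrichmentWindow(run[0], run[-1], np.array(run)))
            run = [a] if sig else []
    if run:
        windows.append(EnrichmentWindow(run[0], run[-1], np.array(run)))
    return windows


def enrichment_windows(aliget: AligetScores, target, background=None,
                       n_boot: int = 10_000, alpha: float = 0.05,
                       n_tests_extra: int = 1, seed: int | None = 0):
    """Per-target-age bootstrap tests with Bonferroni correction over all
    ages (times ``n_tests_extra`` when several lists are screened),
    merged into contiguous significant windows.

    Returns (windows, per_age table).
    """
    ages = aliget.t_grid
    observed, null_mean, null_sd, p_raw = _multi_column_bootstrap(
        aliget.matrix, target, background, n_boot, seed)
    n_tests = len(ages) * n_tests_extra
    p_adj = bonferroni(p_raw, n_tests)
    per_age = pd.DataFrame({"age": ages, "observed_mean": observed,
                            "null_mean": null_mean, "null_sd": null_sd,
                            "p_raw": p_raw, "p_adjusted": p_adj})
    windows = _contiguous_windows(ages, p_adj < alpha)
    return windows, per_age


def deget_set_test(deget: DegetScores, target, background=None,
                   n_boot: int = 10_000, alpha: float = 0.05,
                   seed: int | None = 0) -> pd.DataFrame:
    """Bootstrap enrichment per decile age set, Bonferroni over the sets."""
    observed, null_mean, null_sd, p_raw = _multi_column_bootstrap(
        deget.matrix, target, background, n_boot, seed)
    p_adj = bonferroni(p_raw, deget.matrix.shape[1])
    return pd.DataFrame({"age_set": deget.matrix.columns,
                         "observed_mean": observed, "null_mean": null_mean,
                         "null_sd": null_sd, "p_raw": p_raw,
                         "p_adjusted": p_adj,
                         "significant": p_adj < alpha})


# ---------------------------------------------------------------------------
# transcript-length x GC matched bootstrap
# ---------------------------------------------------------------------------

@dataclass
class SamplingGrid:
    """10 x 10 deciles of transcript length x GC content over the
    expressed genes; every annotated expressed gene sits in one cell."""

    cell_of: pd.Series                       # gene -> cell id
    members: dict = field(default_factory=dict)  # cell id -> np.ndarray of genes

    @classmethod
    def from_annotation(cls, ann: FeatureAnnotation, expressed_genes,
                        n_bins: int = 10) -> "SamplingGrid":
        table = ann.table.loc[ann.table.index.intersection(expressed_genes)]
        missing = {"transcript_length", "gc_content"} - set(table.columns)
        if missing:
            raise ValueError(f"annotation lacks columns: {sorted(missing)}")
        lb = pd.qcut(table["transcript_length"].astype(float), n_bins,
                     labels=False, duplicates="drop")
        gb = pd.qcut(table["gc_content"].astype(float), n_bins,
                     labels=False, duplicates="drop")
        cell_of = pd.Series(list(zip(lb, gb)), index=table.index)
        members = {cell: sub.index.to_numpy()
                   for cell, sub in table.groupby(cell_of)}
        return cls(cell_of=cell_of, members=members)


def matched_bootstrap_test(scores: pd.Series, target, grid: SamplingGrid,
                           background=None, n_boot: int = 10_000,
                           seed: int | None = 0) -> BootstrapResult:
    """As the plain bootstrap, but the i-th null gene is drawn from the
    grid cell of the i-th target gene (positional matching)."""
    background = list(background) if background is not None else list(scores.index)
    target = _clean_target(target, background)
    observed = float(scores.loc[target].mean())
    rng = np.random.default_rng(seed)
    bg = set(background)
    total = np.zeros(n_boot)
    for g in target:
        if g not in grid.cell_of.index:
            raise ValueError(f"target gene {g!r} has no grid cell (missing annotation)")
        members = grid.members[grid.cell_of[g]]
        members = members[np.isin(members, list(bg))] if len(bg) < len(grid.cell_of) else members
        if len(members) == 0:
            raise ValueError(f"empty grid cell for target gene {g!r}")
        vals = scores.loc[members].to_numpy(dtype=float)
        total += vals[rng.integers(0, len(vals), size=n_boot)]
    null = total / len(target)
    return BootstrapResult(observed, float(null.mean()), float(null.std(ddof=1)),
                           n_boot, float(_p_one_sided(null, observed)), seed=seed,
                           note="length/GC matched")


# ---------------------------------------------------------------------------
# association-score shuffle test
# ---------------------------------------------------------------------------

def association_shuffle_test(scores: pd.Series, assoc: GeneAssociationTable,
                             n_shuffle: int = 20_000,
                             mhc_exclude: tuple | None = EXTENDED_MHC,
                             seed: int | None = 0,
                             n_tests: int = 1) -> BootstrapResult:
    """Couple per-gene association z-scores with turning scores.

    Statistic = sum_g z_g * score_g; the null permutes z across genes
    (the extended MHC is excluded first when coordinates are available,
    since LD there makes gene-level scores unassignable).
    """
    if mhc_exclude is not None and assoc.has_coordinates():
        assoc = assoc.exclude_region(*mhc_exclude)
    genes = scores.index.intersection(assoc.gene_ids)
    if len(genes) < 100:
        raise ValueError(f"only {len(genes)} genes matched between scores and associations")
    z = assoc.zscores().loc[genes].to_numpy(dtype=float)
    s = scores.loc[genes].to_numpy(dtype=float)
    # same matmul pathway as the null so permutation-invariant statistics
    # (e.g. constant z) tie exactly up to round-off
    observed = float((z[None, :] @ s)[0])
    tol = 1e-9 * max(1.0, abs(observed))

    rng = np.random.default_rng(seed)
    exceed = 0
    null_sum = 0.0
    null_sq = 0.0
    chunk = max(1, min(n_shuffle, int(5e7 // max(1, len(genes)))))
    done = 0
    while done < n_shuffle:
        c = min(chunk, n_shuffle - done)
        perm = rng.permuted(np.broadcast_to(z, (c, len(z))).copy(), axis=1)
        null = perm @ s
        exceed += int((null >= observed - tol).sum())
        null_sum += null.sum()
        null_sq += (null ** 2).sum()
        done += c
    p_raw = (1.0 + exceed) / (1.0 + n_shuffle)
    null_mean = null_sum / n_shuffle
    var = max(0.0, (null_sq - n_shuffle * null_mean ** 2) / max(1, n_shuffle - 1))
    return BootstrapResult(observed, null_mean, float(np.sqrt(var)), n_shuffle,
                           p_raw, p_adjusted=float(bonferroni(p_raw, n_tests)),
                           correction="bonferroni" if n_tests > 1 else "none",
                           seed=seed, note=f"{len(genes)} genes")


# ---------------------------------------------------------------------------
# hypergeometric overlap and quantile-comparison data
# ---------------------------------------------------------------------------

def hypergeometric_test(target, category, background) -> dict:
    """One-sided over-representation of ``category`` within ``target``."""
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    t = set(target) & bg
    c = set(category) & bg
    k = len(t & c)
    expected = len(t) * len(c) / len(bg)
    p = float(stats.hypergeom.sf(k - 1, len(bg), len(c), len(t)))
    return {"observed": k, "expected": expected, "p_value": p,
            "n_background": len(bg), "n_target": len(t), "n_category": len(c)}


def qq_comparison_data(scores: pd.Series, target, background=None,
                       n_lists: int = 100, seed: int | None = 0) -> pd.DataFrame:
    """Sorted target scores paired with sorted scores of random
    same-length lists (the i-th largest against the i-th largest), for
    quantile-comparison plots against the identity line."""
    background = list(background) if background is not None else list(scores.index)
    target = _clean_target(target, background)
    t_sorted = np.sort(scores.loc[target].to_numpy(dtype=float))[::-1]
    values = scores.loc[background].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    idx = sample_index_matrix(rng, len(background), len(target), n_lists)
    null_sorted = -np.sort(-values[idx], axis=1)
    frames = []
    for j in range(n_lists):
        frames.append(pd.DataFrame({"list_id": j,
                                    "rank": np.arange(1, len(target) + 1),
                                    "target_score": t_sorted,
                                    "random_score": null_sorted[j]}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# background filters (directional / subset restriction)
# ---------------------------------------------------------------------------

def features_by_direction(table: TTTPTable, direction: str) -> list[str]:
    """Turning features whose pre-turn trajectory runs in ``direction``
    ("upward"/"downward"); used as a background/target filter so that
    direction-restricted tests reuse the same statistics."""
    if direction not in ("upward", "downward"):
        raise ValueError("direction must be 'upward' or 'downward'")
    t = table.turning
    return list(t.loc[t["pre_direction"] == direction, "feature_id"])
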