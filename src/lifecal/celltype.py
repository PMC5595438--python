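"""Expression-weighted cell-type enrichment of age-windowed,
direction-stratified turning-gene lists.

For each turning-count-decile age window and each trajectory direction,
the 10% of window-turning genes with the largest expression change form
a target list.  The test asks whether the list's mean cell-type
specificity exceeds that of random same-length lists from the expressed
background; the enrichment is reported as d = (observed - mu) / sigma in
null standard deviations, Bonferroni-corrected across cell types,
windows and directions, and normalized per (direction, cell type) so the
maximal |d| across windows is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SpecificityMatrix
from .enrichment import _clean_target, _null_means, sample_index_matrix
from .scoring import AgeSets
from .turning_points import TTTPTable

logger = logging.getLogger(__name__)

DIRECTIONS = ("upward", "downward")


def compute_specificity(mean_expr: pd.DataFrame) -> SpecificityMatrix:
    """Row-normalize a gene x cell-type mean-expression matrix:
    specificity(g, c) = mean_expr(g, c) / sum_c mean_expr(g, c); all-zero
    rows stay zero."""
    values = mean_expr.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("mean expression must be nonnegative")
    rs = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = np.where(rs > 0, values / rs, 0.0)
    return SpecificityMatrix(pd.DataFrame(spec, index=mean_expr.index,
                                          columns=mean_expr.columns),
                             kind="specificity")


# ---------------------------------------------------------------------------
# target lists
# ---------------------------------------------------------------------------

@dataclass
class DirectionalGeneLists:
    """(window index, direction) -> gene list; ``window_labels`` carry
    the age spans for display."""

    lists: dict[tuple[int, str], list[str]]
    window_labels: list[str]

    def __getitem__(self, key):
        return self.lists[key]

    def items(self):
        return self.lists.items()


def build_directional_lists(table: TTTPTable, age_sets: AgeSets,
                            spec: SpecificityMatrix, top_frac: float = 0.1,
                            ortholog_map: pd.Series | None = None,
                            ) -> DirectionalGeneLists:
    """Per window and direction, the top fraction (of the window's
    turning-gene count) ranked by signed expression change; genes absent
    from the specificity data are dropped after ranking (no re-top-up).

    ``ortholog_map`` optionally maps feature ids to the specificity
    matrix's gene universe (e.g. human symbols -> mouse symbols).
    """
    turning = table.turning.set_index("feature_id")
    spec_genes = set(spec.genes)
    lists: dict[tuple[int, str], list[str]] = {}
    for w in range(age_sets.n_sets):
        members = age_sets.assignment.index[age_sets.assignment == w]
        window = turning.loc[turning.index.intersection(members)]
        n_top = int(round(top_frac * len(window)))
        for direction, sign in (("upward", 1.0), ("downward", -1.0)):
            sub = window[window["pre_direction"] == direction]
            ranked = sub["delta_e"].mul(sign).sort_values(ascending=False)
            chosen = list(ranked.index[:n_top])
            if ortholog_map is not None:
                chosen = [ortholog_map[g] for g in chosen if g in ortholog_map.index]
            kept = [g for g in chosen if g in spec_genes]
            if len(kept) < len(chosen):
                logger.info("window %d %s: dropped %d genes absent from the "
                            "specificity data", w, direction, len(chosen) - len(kept))
            if not kept:
                logger.info("window %d %s: empty target list", w, direction)
            lists[(w, direction)] = kept
    return DirectionalGeneLists(lists, age_sets.labels())


# ---------------------------------------------------------------------------
# the bootstrap enrichment test
# ---------------------------------------------------------------------------

@dataclass
class CellTypeEnrichment:
    """Result of one window/direction test: per-cell-type standardized
    deviations d, raw and Bonferroni p-values; the normalized column is
    filled across windows by :func:`normalize_enrichments`."""

    window: int
    direction: str
    table: pd.DataFrame      # index cell type: d, p_raw, p_bonferroni, normalized
    n_boot: int
    degenerate_null: list[str] = field(default_factory=list)


def ewce_test(target, background, spec: SpecificityMatrix,
              n_boot: int = 100_000, seed: int | None = 0,
              n_tests: int | None = None, window: int = 0,
              direction: str = "upward") -> CellTypeEnrichment:
    """Expression-weighted enrichment of a gene list in each cell type.

    Null lists are uniform same-length draws from the background;
    d = (observed mean specificity - null mean) / null sd, with a
    degenerate (sd = 0) null flagged and d set to 0.  ``n_tests``
    defaults to the number of cell types (the caller multiplies in
    windows x directions when screening them jointly).
    """
    background = [g for g in background if g in set(spec.genes)]
    target = _clean_target(target, background)
    if len(target) < 4:
        raise ValueError(f"target list too small for enrichment ({len(target)} genes)")
    S = spec.values.loc[background].to_numpy(dtype=float)
    t_pos = pd.Index(background).get_indexer(target)
    observed = S[t_pos].mean(axis=0)

    rng = np.random.default_rng(seed)
    idx = sample_index_matrix(rng, len(background), len(target), n_boot)
    null = _null_means(S, idx)
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    # a null that varies only at round-off level is degenerate
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(degenerate, 0.0, (observed - mu) / np.where(degenerate, 1.0, sd))
    p_raw = (1.0 + (null >= observed).sum(axis=0)) / (1.0 + n_boot)
    n_tests = n_tests if n_tests is not None else len(spec.cell_types)
    table = pd.DataFrame({"d": d, "p_raw": p_raw,
                          "p_bonferroni": np.minimum(1.0, p_raw * n_tests),
                          "normalized": np.nan},
                         index=spec.cell_types)
    flagged = [c for c, bad in zip(spec.cell_types, degenerate) if bad]
    if flagged:
        logger.warning("degenerate null (sd=0) for cell types: %s", flagged)
    return CellTypeEnrichment(window, direction, table, n_boot, flagged)


def ewce_across_windows(lists: DirectionalGeneLists, background,
                        spec: SpecificityMatrix, n_boot: int = 100_000,
                        seed: int | None = 0) -> list[CellTypeEnrichment]:
    """Run the test for every non-empty (window, direction) list with
    Bonferroni correction across cell types x windows x directions, then
    normalize."""
    todo = [(key, lst) for key, lst in lists.items() if len(lst) >= 4]
    n_tests = len(spec.cell_types) * len(todo)
    results = []
    for k, ((w, direction), lst) in enumerate(todo):
        results.append(ewce_test(lst, background, spec, n_boot=n_boot,
                                 seed=None if seed is None else seed + k,
                                 n_tests=n_tests, window=w, direction=direction))
    return normalize_enrichments(results)


def normalize_enrichments(results: list[CellTypeEnrichment]) -> list[CellTypeEnrichment]:
    """Scale d per (direction, cell type) by the maximal |d| across age
    windows, so the extreme enrichment is exactly +-1 (all-zero d stays 0)."""
    for direction in {r.direction for r in results}:
        group = [r for r in results if r.direction == direction]
        cell_types = group[0].table.index
        for c in cell_types:
            dmax = max(abs(r.table.at[c, "d"]) for r in group)
            for r in group:
                r.table.at[c, "normalized"] = (
                    0.0 if dmax == 0 else r.table.at[c, "d"] / dmax)
    return results


def enrichment_frame(results: list[CellTypeEnrichment]) -> pd.DataFrame:
    """Long-format window x direction x cell-type table."""
    rows = []
    for r in results:
        for c, row in r.table.iterrows():
            rows.append({"window": r.window, "direction": r.direction,
                         "cell_type": c, "d": row["d"],
                         "d_normalized": row["normalized"],
                         "p_raw": row["p_raw"],
                         "p_bonferroni": row["p_bonferroni"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# neuron/glia restriction
# ---------------------------------------------------------------------------

def neuron_glia_ratio(mean_expr: pd.DataFrame, neuron_types, glia_types) -> pd.Series:
    """Per-gene ratio of summed neuronal to summed glial mean expression;
    a zero glial sum yields +inf (ranked first, logged)."""
    missing = (set(neuron_types) | set(glia_types)) - set(mean_expr.columns)
    if missing:
        raise ValueError(f"unknown cell types: {sorted(missing)}")
    neuron = mean_expr[list(neuron_types)].sum(axis=1).to_numpy(dtype=float)
    glia = mean_expr[list(glia_types)].sum(axis=1).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(glia > 0, neuron / np.where(glia > 0, glia, 1.0), np.inf)
    ratio = np.where((glia == 0) & (neuron == 0), 0.0, ratio)
    n_inf = int(np.isinf(ratio).sum())
    if n_inf:
        logger.info("%d genes with zero glial expression ranked first", n_inf)
    return pd.Series(ratio, index=mean_expr.index, name="neuron_glia_ratio")


def top_neuron_specific(ratio: pd.Series, n: int = 5000) -> list[str]:
    """The n genes with the largest neuron/glia ratio (stable order)."""
    return list(ratio.sort_values(ascending=False, kind="mergesort").index[:n])
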