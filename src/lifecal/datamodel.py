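"""Core containers shared by every analysis stage.

All containers are thin wrappers around pandas objects so that every
external format round-trips through plain TSV.  Ages are in years for
human data (fetal ages negative, e.g. the 14th gestational week is about
-0.50 y) and in days for mouse data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES_AGE_UNIT = {"human": "year", "mouse": "day"}

#: divisor applied to |A_g - T| so a mouse-day distance counts as the
#: equivalent fraction of lifespan as a human-year distance (old age:
#: 650 d mouse vs 78 y human)
MOUSE_LIFESPAN_SCALE = 650.0 / 78.0


@dataclass
class ExpressionDataset:
    """An expression matrix (features x samples) plus per-sample metadata.

    Parameters
    ----------
    values
        Log-scale expression, rows indexed by unique probe/gene
        identifiers, columns by sample identifiers.
    samples
        Per-sample metadata indexed by sample identifier, aligned with
        the columns of ``values``.  Must contain an ``age`` column
        (numeric) and a ``sex`` column with values in
        {male, female, unknown}; further columns are treated as
        covariates (e.g. strain).
    species
        "human" or "mouse".
    age_unit
        "year" or "day"; must be consistent with the species scaling
        used downstream.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    species: str = "human"
    age_unit: str = "year"

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"feature identifiers not unique: {list(dupes)[:5]}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata is not aligned with matrix columns")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if "age" not in self.samples.columns:
            raise ValueError("sample metadata needs an 'age' column")
        age = pd.to_numeric(self.samples["age"], errors="coerce")
        if not np.isfinite(age.to_numpy(dtype=float)).all():
            bad = self.samples.index[~np.isfinite(age.to_numpy(dtype=float))]
            raise ValueError(f"non-finite age for samples: {list(bad)[:5]}")
        self.samples = self.samples.copy()
        self.samples["age"] = age.astype(float)
        if "sex" not in self.samples.columns:
            self.samples["sex"] = "unknown"
        if self.species not in SPECIES_AGE_UNIT:
            raise ValueError(f"unknown species {self.species!r}")
        if self.age_unit not in ("year", "day"):
            raise ValueError(f"unknown age unit {self.age_unit!r}")

    # -- convenience accessors -----------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_age(self) -> np.ndarray:
        return self.samples["age"].to_numpy(dtype=float)

    @property
    def sample_sex(self) -> pd.Series:
        return self.samples["sex"]

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.samples.columns if c not in ("age", "sex")]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_features(self, ids) -> "ExpressionDataset":
        return ExpressionDataset(self.values.loc[ids], self.samples,
                                 self.species, self.age_unit)

    def select_samples(self, mask) -> "ExpressionDataset":
        sub = self.samples.loc[mask]
        return ExpressionDataset(self.values[sub.index], sub,
                                 self.species, self.age_unit)

    def subset_sex(self, sex: str) -> "ExpressionDataset":
        """Samples of one sex, with the sex column dropped (for
        sex-stratified refits without a sex covariate)."""
        keep = self.samples.index[self.samples["sex"] == sex]
        if len(keep) == 0:
            raise ValueError(f"no samples with sex={sex!r}")
        sub = self.samples.loc[keep].drop(columns=["sex"])
        sub["sex"] = "unknown"
        return ExpressionDataset(self.values[keep], sub, self.species, self.age_unit)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): name -> deduplicated member list."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class SpecificityMatrix:
    """Gene x cell-type specificity (rows sum to one) or mean expression."""

    values: pd.DataFrame
    kind: str = "specificity"

    def __post_init__(self) -> None:
        if self.kind not in ("specificity", "mean_expression"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("specificity/mean-expression entries must be nonnegative")
        if self.kind == "specificity":
            rs = self.values.sum(axis=1).to_numpy()
            ok = np.isclose(rs, 1.0, atol=1e-9) | (rs == 0.0)
            if not ok.all():
                bad = self.values.index[~ok]
                raise ValueError(
                    f"specificity rows must sum to 1 (or be all-zero); bad rows: {list(bad)[:5]}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index


@dataclass
class GeneAssociationTable:
    """Gene-level association z-scores (the MAGMA .genes.out dialect).

    ``table`` is indexed by gene id with a ``zscore`` column and optional
    ``chrom``/``start``/``stop`` coordinates used for region exclusion.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValueError("one row per gene required in the association table")
        if "zscore" not in self.table.columns:
            raise ValueError("association table needs a 'zscore' column")
        z = self.table["zscore"].to_numpy(dtype=float)
        if not np.isfinite(z).all():
            raise ValueError("non-finite z-scores in association table")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def zscores(self) -> pd.Series:
        return self.table["zscore"].astype(float)

    def has_coordinates(self) -> bool:
        return {"chrom", "start", "stop"}.issubset(self.table.columns)

    def exclude_region(self, chrom: str, start: float, stop: float) -> "GeneAssociationTable":
        """Drop genes overlapping [start, stop] on ``chrom`` (e.g. the
        extended MHC, where LD makes gene-level scores unassignable)."""
        if not self.has_coordinates():
            raise ValueError("association table has no coordinates; cannot exclude region")
        t = self.table
        c = t["chrom"].astype(str).str.removeprefix("chr")
        inside = (c == str(chrom).removeprefix("chr")) & \
            (t["stop"].astype(float) >= float(start)) & \
            (t["start"].astype(float) <= float(stop))
        n = int(inside.sum())
        if n:
            logger.info("excluded %d genes in %s:%g-%g", n, chrom, start, stop)
        return GeneAssociationTable(t.loc[~inside])


@dataclass
class FeatureAnnotation:
    """Probe/gene annotation: gene symbol, transcript length, GC content.

    ``table`` is indexed by feature id with columns ``gene_symbol``,
    ``transcript_length`` (bases, max over transcripts) and
    ``gc_content`` (fraction).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "gene_symbol" not in self.table.columns:
            raise ValueError("annotation needs a 'gene_symbol' column")
        if "gc_content" in self.table.columns:
            gc = self.table["gc_content"].dropna().to_numpy(dtype=float)
            if ((gc < 0) | (gc > 1)).any():
                raise ValueError("gc_content must lie in [0, 1]")
        if "transcript_length" in self.table.columns:
            ln = self.table["transcript_length"].dropna().to_numpy(dtype=float)
            if (ln <= 0).any():
                raise ValueError("transcript_length must be positive")

    def symbol_of(self, feature_id: str):
        if feature_id in self.table.index:
            return self.table.at[feature_id, "gene_symbol"]
        return None
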