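"""Expression tables, sample metadata and the merged two-cycle time axis.

A probe-by-sample expression matrix and its per-sample metadata (cycle label
and collection day) are the raw inputs of every downstream stage.  Samples
come from two experimental conditions -- a naturally synchronized hair-growth
cycle and a depilation-induced one -- that are merged onto a single postnatal
time axis by mapping induced collection days onto morphologically equivalent
natural days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

NATURAL = "natural"
INDUCED = "induced"

#: Induced-cycle collection day -> morphologically equivalent natural-cycle
#: postnatal day used by the study this analysis reimplements.
STUDY_TIME_MAP: dict[float, float] = {3: 24, 5: 25, 8: 27, 12: 29, 17: 37}


class SchemaError(ValueError):
    """Input tables disagree with the expected layout."""


class ValidationError(ValueError):
    """Values violate a dataset invariant."""


class MappingError(KeyError):
    """An induced sample day has no natural-cycle equivalent."""


class DegenerateInputError(ValueError):
    """An operation was asked to normalize a degenerate vector."""


@dataclass(frozen=True)
class TimeMap:
    """Mapping from induced-cycle days to natural-equivalent postnatal days.

    Keys must be unique and the mapped days must increase strictly with the
    keys (later induced samples cannot map to earlier natural days).
    """

    pairs: Mapping[float, float] = field(default_factory=lambda: dict(STUDY_TIME_MAP))

    def __post_init__(self) -> None:
        keys = sorted(self.pairs)
        vals = [self.pairs[k] for k in keys]
        if len(keys) != len(set(keys)):
            raise ValidationError("time map keys must be unique")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValidationError("mapped days must increase strictly with induced days")

    def __getitem__(self, day: float) -> float:
        try:
            return self.pairs[day]
        except KeyError:
            raise MappingError(f"induced day {day!r} has no natural equivalent") from None


@dataclass
class ExpressionDataset:
    """Probe x sample expression values plus per-sample time/cycle metadata.

    ``values`` is a (n_probes, n_samples) array, nonnegative on linear scale
    and real-valued on log2 scale.  ``merged_day`` is the unified postnatal
    axis and is ``None`` until :func:`merge_cycles` runs; natural samples keep
    ``merged_day == sample_day``.
    """

    values: np.ndarray
    scale: str  # {"linear", "log2"}
    probe_ids: np.ndarray
    sample_ids: np.ndarray
    sample_day: np.ndarray
    sample_cycle: np.ndarray
    merged_day: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.sample_day = np.asarray(self.sample_day, dtype=float)
        self.sample_cycle = np.asarray(self.sample_cycle, dtype=object)
        if self.merged_day is not None:
            self.merged_day = np.asarray(self.merged_day, dtype=float)
        self._validate()

    def _validate(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        n_probes, n_samples = self.values.shape
        if len(self.probe_ids) != n_probes:
            raise SchemaError("probe_ids length does not match value rows")
        for name, arr in (
            ("sample_ids", self.sample_ids),
            ("sample_day", self.sample_day),
            ("sample_cycle", self.sample_cycle),
        ):
            if len(arr) != n_samples:
                raise SchemaError(f"{name} length does not match value columns")
        if len(set(self.probe_ids)) != n_probes:
            raise ValidationError("duplicate probe ids")
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("duplicate sample ids")
        if self.scale == "linear" and np.any(self.values < 0):
            raise ValidationError("linear-scale expression must be nonnegative")
        bad = set(self.sample_cycle) - {NATURAL, INDUCED}
        if bad:
            raise ValidationError(f"unknown cycle labels: {sorted(bad)}")

    # -- convenience -------------------------------------------------------

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionDataset":
        return replace(
            self,
            values=self.values.copy(),
            merged_day=None if self.merged_day is None else self.merged_day.copy(),
        )

    def to_log2(self, pseudocount: float = 0.0) -> "ExpressionDataset":
        """Explicit linear -> log2 conversion."""
        if self.scale == "log2":
            raise ValidationError("dataset is already on log2 scale")
        out = self.copy()
        out.values = np.log2(self.values + pseudocount)
        out.scale = "log2"
        return out

    def to_linear(self) -> "ExpressionDataset":
        """Explicit log2 -> linear conversion."""
        if self.scale == "linear":
            raise ValidationError("dataset is already on linear scale")
        out = self.copy()
        out.values = np.power(2.0, self.values)
        out.scale = "linear"
        return out


def read_expression(matrix_path: str | Path, metadata_path: str | Path, scale: str) -> ExpressionDataset:
    """Read an expression matrix TSV and its sample-metadata TSV.

    The matrix is tab-separated with a ``probe_id`` first column and one
    column per sample; the metadata table has columns ``sample_id``, ``cycle``
    and ``day`` with one row per matrix column.  Metadata rows are aligned to
    the matrix column order.
    """
    mat = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    if mat.columns[0] != "probe_id":
        raise SchemaError("first matrix column must be 'probe_id'")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "cycle", "day"}
    if not required.issubset(meta.columns):
        raise SchemaError(f"metadata must have columns {sorted(required)}")
    sample_ids = list(mat.columns[1:])
    meta_ids = list(meta["sample_id"])
    if sorted(sample_ids) != sorted(meta_ids):
        raise SchemaError("metadata sample ids do not match matrix columns")
    meta = meta.set_index("sample_id").loc[sample_ids]
    return ExpressionDataset(
        values=mat.iloc[:, 1:].to_numpy(dtype=float),
        scale=scale,
        probe_ids=mat["probe_id"].to_numpy(dtype=object),
        sample_ids=np.asarray(sample_ids, dtype=object),
        sample_day=meta["day"].to_numpy(dtype=float),
        sample_cycle=meta["cycle"].to_numpy(dtype=object),
    )


def write_expression(ds: ExpressionDataset, matrix_path: str | Path, metadata_path: str | Path) -> None:
    """Write the matrix and metadata TSVs read back by :func:`read_expression`."""
    mat = pd.DataFrame(ds.values, columns=list(ds.sample_ids))
    mat.insert(0, "probe_id", list(ds.probe_ids))
    # 12 significant digits keeps the read/write round trip value-stable
    mat.to_csv(matrix_path, sep="\t", index=False, float_format="%.12g")
    meta = pd.DataFrame(
        {"sample_id": list(ds.sample_ids), "cycle": list(ds.sample_cycle), "day": ds.sample_day}
    )
    meta.to_csv(metadata_path, sep="\t", index=False, float_format="%.12g")


def merge_cycles(ds: ExpressionDataset, time_map: TimeMap | None = None) -> ExpressionDataset:
    """Place both cycles on the unified postnatal time axis.

    Natural samples keep their collection day; induced samples get the mapped
    natural-equivalent day.  Samples are sorted by merged day with a stable
    tie order (natural before induced) so downstream regression design
    matrices are deterministic.  Idempotent: merging twice is a no-op.
    """
    time_map = time_map or TimeMap()
    merged = np.empty(ds.n_samples)
    for i, (cyc, day) in enumerate(zip(ds.sample_cycle, ds.sample_day)):
        merged[i] = day if cyc == NATURAL else time_map[day]
    tie_rank = np.where(ds.sample_cycle == NATURAL, 0, 1)
    order = np.lexsort((tie_rank, merged))
    return ExpressionDataset(
        values=ds.values[:, order],
        scale=ds.scale,
        probe_ids=ds.probe_ids.copy(),
        sample_ids=ds.sample_ids[order],
        sample_day=ds.sample_day[order],
        sample_cycle=ds.sample_cycle[order],
        merged_day=merged[order],
    )


def normalize_for_viz(values: np.ndarray, scheme: str) -> np.ndarray:
    """Display-only normalizations; never used in statistics.

    ``zero_one`` rescales to [0, 1] via (x - min) / (max - min); ``frac_max``
    divides by the maximum, preserving relative fold change.
    """
    x = np.asarray(values, dtype=float)
    if scheme == "zero_one":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise DegenerateInputError("constant vector has no 0-1 normalization")
        return (x - lo) / (hi - lo)
    if scheme == "frac_max":
        hi = x.max()
        if hi <= 0:
            raise DegenerateInputError("fraction-of-max requires a positive maximum")
        return x / hi
    raise ValueError(f"unknown scheme {scheme!r}")
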