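"""Heterogeneous-cohort data model, CSV I/O and stratified splitting.

Two tabular COPD cohorts ("source" and "target") share a core of clinical
columns (demographics and spirometry) while each also carries cohort-private
measurements (symptom scores / exacerbations in the source, walk tests in the
target).  Every patient row has an integer GOLD severity stage 1-4.  Missing
cells are first-class citizens: they are stored as NaN, never imputed, and a
measured 0.0 is distinct from a missing value throughout the pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ROLES = ("shared", "source_private", "target_private")
DOMAINS = ("source", "target")
STAGES = (1, 2, 3, 4)

#: cell contents parsed as missing (case-insensitive), besides the empty cell
MISSING_TOKENS = frozenset({"", "na", "nan"})

DEFAULT_LABEL_COLUMN = "GOLD"


class SchemaError(ValueError):
    """A cohort file or feature specification violates the data contract."""


@dataclass(frozen=True)
class FeatureSpec:
    """One clinical variable: its cohort role and fixed normalization range.

    Parameters
    ----------
    name
        Column name in the cohort CSV.
    role
        ``"shared"`` (present in both cohorts), ``"source_private"`` or
        ``"target_private"``.
    lo, hi
        Fixed clinical normalization bounds (clinical units).  Only consulted
        when ``normalize`` is true; private features pass through unscaled.
    normalize
        Whether the feature receives fixed-range min-max normalization.
    """

    name: str
    role: str
    lo: float = 0.0
    hi: float = 1.0
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"unknown feature role {self.role!r} for {self.name!r}")
        if self.normalize and not self.hi > self.lo:
            raise SchemaError(
                f"feature {self.name!r}: hi ({self.hi}) must exceed lo ({self.lo})"
            )


def default_feature_specs() -> list[FeatureSpec]:
    """The default COPD schema: 7 shared + 2 source-private + 2 target-private.

    Normalization ranges are fixed clinical ranges, not data-driven: age
    40-100 years, pack-years 0-110, FEV1 0.4-4.0 L, with binary sex and a
    0/1/2 smoking-status coding.  FVC (0.5-6.0 L) and FEV1/FVC (0-1) use
    physiologically generous defaults.  Private features are never scaled.
    """
    return [
        FeatureSpec("age", "shared", 40.0, 100.0, True),
        FeatureSpec("sex", "shared", 0.0, 1.0, True),
        FeatureSpec("smoking_status", "shared", 0.0, 2.0, True),
        FeatureSpec("pack_years", "shared", 0.0, 110.0, True),
        FeatureSpec("fev1", "shared", 0.4, 4.0, True),
        FeatureSpec("fvc", "shared", 0.5, 6.0, True),
        FeatureSpec("fev1_fvc", "shared", 0.0, 1.0, True),
        FeatureSpec("cat_score", "source_private"),
        FeatureSpec("exacerbations", "source_private"),
        FeatureSpec("mwt1", "target_private"),
        FeatureSpec("mwt2", "target_private"),
    ]


def load_feature_specs(path) -> list[FeatureSpec]:
    """Read FeatureSpec entries from a YAML file (list of mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise SchemaError(f"{path}: expected a YAML list of feature entries")
    specs = [FeatureSpec(**entry) for entry in raw]
    _check_role_partition(specs)
    return specs


def dump_feature_specs(specs: list[FeatureSpec], path) -> None:
    entries = [
        {"name": s.name, "role": s.role, "lo": s.lo, "hi": s.hi, "normalize": s.normalize}
        for s in specs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def _check_role_partition(specs: list[FeatureSpec]) -> None:
    seen: dict[str, str] = {}
    for s in specs:
        if s.name in seen:
            raise SchemaError(
                f"feature {s.name!r} declared under two roles "
                f"({seen[s.name]!r} and {s.role!r})"
            )
        seen[s.name] = s.role


@dataclass
class CohortTable:
    """One cohort: a float feature table (NaN = missing) plus GOLD labels.

    ``data`` holds one float64 column per declared feature, in declaration
    order; ``labels`` holds the integer GOLD stage (1-4) per row.
    """

    domain: str
    data: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise SchemaError(f"unknown domain {self.domain!r}")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.data):
            raise SchemaError(
                f"{len(self.labels)} labels for {len(self.data)} records"
            )
        bad = np.flatnonzero(~np.isin(self.labels, STAGES))
        if bad.size:
            raise SchemaError(
                f"GOLD label outside 1-4 at row {int(bad[0])}: "
                f"{int(self.labels[bad[0]])}"
            )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, indices) -> "CohortTable":
        """Row subset (by positional indices) preserving order of `indices`."""
        idx = np.asarray(indices, dtype=np.int64)
        return CohortTable(
            domain=self.domain,
            data=self.data.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
        )


def read_cohort_csv(
    path,
    specs: list[FeatureSpec],
    domain: str,
    label_column: str = DEFAULT_LABEL_COLUMN,
) -> CohortTable:
    """Read one cohort CSV into a :class:`CohortTable`.

    Empty cells and the tokens "NA"/"NaN" (case-insensitive) are recorded as
    missing, never as 0.  Columns containing "predicted" in their name are
    dropped (noisy derived lung-capacity metrics); any other undeclared column
    is ignored with a logged warning.
    """
    _check_role_partition(specs)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read cohort CSV {path}: {exc}") from exc
    if label_column not in raw.columns:
        raise SchemaError(f"{path}: no GOLD label column {label_column!r}")

    wanted = {s.name for s in specs if s.role in ("shared", f"{domain}_private")}
    data = {}
    for col in raw.columns:
        if col == label_column:
            continue
        if "predicted" in col.lower():
            logger.warning("%s: dropping predicted lung-capacity column %r", path, col)
            continue
        if col not in wanted:
            logger.warning("%s: ignoring undeclared column %r", path, col)
            continue
        cells = raw[col].str.strip()
        missing = cells.str.lower().isin(MISSING_TOKENS)
        values = pd.to_numeric(cells.mask(missing), errors="raise")
        data[col] = values.astype(np.float64)

    labels_raw = raw[label_column].str.strip()
    try:
        labels = labels_raw.astype(np.int64).to_numpy()
    except ValueError as exc:
        raise SchemaError(f"{path}: non-integer GOLD label ({exc})") from exc
    # column order follows the spec declaration, restricted to columns present
    ordered = [s.name for s in specs if s.name in data]
    frame = pd.DataFrame(data, columns=ordered) if ordered else pd.DataFrame(index=raw.index)
    return CohortTable(domain=domain, data=frame, labels=labels)


def write_cohort_csv(
    table: CohortTable, path, label_column: str = DEFAULT_LABEL_COLUMN
) -> None:
    """Write a cohort back to CSV; missing values become empty cells."""
    out = table.data.copy()
    out[label_column] = table.labels
    out.to_csv(path, index=False, na_rep="")


@dataclass
class SplitIndices:
    """A stratified train/validation partition of the target cohort rows."""

    train: np.ndarray
    validation: np.ndarray
    seed: int
    fraction: float

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=np.int64)
        self.validation = np.asarray(self.validation, dtype=np.int64)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stratified_split(labels, fraction: float, seed: int) -> SplitIndices:
    """Stratified train/validation split preserving GOLD stage proportions.

    The global validation size is round(fraction * N) (ties away from zero).
    Per-class validation counts come from largest-remainder rounding of
    fraction * class_count, so every class is within +/-1 of its exact quota.
    Shuffling within each stratum is driven by ``seed``; the returned index
    lists are sorted and deterministic.
    """
    labels = np.asarray(labels, dtype=np.int64)
    n = labels.size
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 1).any() or classes.size < 1:
        raise ValueError("every class must have at least one member")

    total = _round_half_away(fraction * n)
    if total < 1:
        raise ValueError(
            f"fraction {fraction} yields an empty validation set for N={n}"
        )
    quotas = fraction * counts
    alloc = np.floor(quotas).astype(np.int64)
    remainders = quotas - alloc
    need = total - int(alloc.sum())
    # distribute leftovers by largest remainder; ties broken toward the
    # larger class, then by class order — deterministic
    order = sorted(
        range(classes.size), key=lambda i: (-remainders[i], -counts[i], classes[i])
    )
    for i in order[:max(need, 0)]:
        alloc[i] += 1
    while alloc.sum() > total:  # defensive; cannot trigger with need >= 0
        alloc[int(np.argmax(counts))] -= 1

    rng = np.random.default_rng(seed)
    val_parts, train_parts = [], []
    for cls, take in zip(classes, alloc):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        val_parts.append(idx[:take])
        train_parts.append(idx[take:])
    validation = np.sort(np.concatenate(val_parts))
    train = np.sort(np.concatenate(train_parts))
    return SplitIndices(train=train, validation=validation, seed=seed, fraction=fraction)
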