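"""Fixed-range normalization and value-mask encoding of missing data.

Shared clinical features are min-max normalized with *fixed* clinical ranges
(never data-driven statistics) and clamped to [0, 1]; private features pass
through in raw clinical units.  Every feature is then paired with a binary
availability mask (1.0 = measured, 0.0 = missing), and masked-out value
entries are zeroed, doubling the width of each design block.  This lets the
encoders distinguish a true measured zero from an absent measurement without
any imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import CohortTable, FeatureSpec, SchemaError, _check_role_partition


@dataclass
class DesignBlocks:
    """Value-mask design matrices for one cohort.

    Each block is laid out ``[values | masks]``: the first half holds the
    (possibly normalized) feature values with missing entries zero-filled,
    the second half the binary availability masks, in matching column order.
    """

    shared: np.ndarray
    private: np.ndarray
    shared_features: list[str]
    private_features: list[str]

    @property
    def d_shared(self) -> int:
        return len(self.shared_features)

    @property
    def d_private(self) -> int:
        return len(self.private_features)

    @property
    def n(self) -> int:
        return self.shared.shape[0]

    def subset(self, indices) -> "DesignBlocks":
        idx = np.asarray(indices, dtype=np.int64)
        return DesignBlocks(
            shared=self.shared[idx],
            private=self.private[idx],
            shared_features=self.shared_features,
            private_features=self.private_features,
        )


def minmax_normalize(v, lo: float, hi: float):
    """(v - lo) / (hi - lo), clamped to [0, 1].  Scalar or array."""
    if not hi > lo:
        raise ValueError(f"normalization range requires hi > lo, got [{lo}, {hi}]")
    return np.clip((np.asarray(v, dtype=np.float64) - lo) / (hi - lo), 0.0, 1.0)


def value_mask_encode(row, order):
    """Encode one record as parallel (values, masks) vectors over ``order``.

    Missing (absent key, None, or NaN) -> (0.0, 0.0); a present value v ->
    (v, 1.0).  A genuinely measured 0.0 therefore stays distinguishable from
    a missing cell through its mask.
    """
    order = list(order)
    if not order:
        raise ValueError("feature order must be nonempty")
    values = np.zeros(len(order))
    masks = np.zeros(len(order))
    for j, name in enumerate(order):
        v = row.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        values[j] = float(v)
        masks[j] = 1.0
    return values, masks


def _encode_columns(
    cohort: CohortTable, specs: list[FeatureSpec], role: str
) -> tuple[np.ndarray, list[str]]:
    cols = [s for s in specs if s.role == role]
    n = cohort.n
    values = np.zeros((n, len(cols)))
    masks = np.zeros((n, len(cols)))
    for j, spec in enumerate(cols):
        if spec.name not in cohort.data.columns:
            continue  # column absent from this cohort: all-missing
        col = cohort.data[spec.name].to_numpy(dtype=np.float64)
        present = ~np.isnan(col)
        v = col[present]
        if spec.normalize:
            v = minmax_normalize(v, spec.lo, spec.hi)
        values[present, j] = v
        masks[present, j] = 1.0
    return np.hstack([values, masks]), [s.name for s in cols]


def build_design_blocks(cohort: CohortTable, specs: list[FeatureSpec]) -> DesignBlocks:
    """Build the shared and domain-private value-mask blocks for a cohort.

    Shared features are normalized then mask-encoded; private features are
    mask-encoded without scaling.  Column order follows the spec order with
    values-then-masks concatenation, so each block is N x 2d.
    """
    _check_role_partition(specs)
    declared = {s.name for s in specs}
    extra = [c for c in cohort.data.columns if c not in declared]
    if extra:
        raise SchemaError(
            f"cohort columns {extra} not covered by the feature specs"
        )
    shared, shared_names = _encode_columns(cohort, specs, "shared")
    private, private_names = _encode_columns(cohort, specs, f"{cohort.domain}_private")
    return DesignBlocks(
        shared=shared,
        private=private,
        shared_features=shared_names,
        private_features=private_names,
    )
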