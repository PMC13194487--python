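"""Cumulative-threshold codec for GOLD severity stages.

A GOLD stage k in {1,...,4} is represented by the binary vector of the three
cumulative indicators ((k >= 2), (k >= 3), (k >= 4)), which preserves the
ordering of stages: GOLD 1 -> (0,0,0), GOLD 2 -> (1,0,0), GOLD 3 -> (1,1,0),
GOLD 4 -> (1,1,1).  Decoding counts the threshold probabilities strictly
above 0.5, which tolerates non-monotone probability vectors from independent
sigmoid outputs (an exact 0.5 favors the milder stage).
"""

from __future__ import annotations

import numpy as np

N_THRESHOLDS = 3
N_STAGES = 4


def encode_stage(gold: int) -> np.ndarray:
    """Encode one GOLD stage (1-4) as its 3-bit cumulative threshold vector."""
    if gold not in (1, 2, 3, 4):
        raise ValueError(f"GOLD stage must be in 1-4, got {gold!r}")
    return (np.arange(2, 5) <= gold).astype(np.float64)


def encode_stages(golds) -> np.ndarray:
    """Vectorized :func:`encode_stage`: (N,) stages -> (N, 3) binary matrix."""
    g = np.asarray(golds, dtype=np.int64)
    if g.size and not np.isin(g, (1, 2, 3, 4)).all():
        bad = g[~np.isin(g, (1, 2, 3, 4))][0]
        raise ValueError(f"GOLD stage must be in 1-4, got {bad}")
    return (g[:, None] >= np.arange(2, 5)[None, :]).astype(np.float64)


def decode_thresholds(probs) -> "int | np.ndarray":
    """Decode threshold probabilities to stages: 1 + #{p_k > 0.5}.

    Accepts a single 3-vector (returns an int) or an (N, 3) matrix (returns
    an (N,) int array).  Entries must lie in [0, 1].
    """
    p = np.asarray(probs, dtype=np.float64)
    if p.shape[-1] != N_THRESHOLDS:
        raise ValueError(f"expected {N_THRESHOLDS} threshold probabilities, got shape {p.shape}")
    if ((p < 0.0) | (p > 1.0)).any():
        raise ValueError("threshold probabilities must lie in [0, 1]")
    stages = 1 + (p > 0.5).sum(axis=-1)
    if p.ndim == 1:
        return int(stages)
    return stages.astype(np.int64)
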