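"""Variance-based global sensitivity analysis (Sobol' indices).

Self-contained Saltelli-style sampling and the standard estimators:
first-order indices after Saltelli (2010), total-order indices after
Jansen (1999).  Sampling uses two independent uniform matrices A and B
plus the d cross matrices AB_i, for a cost of N * (d + 2) model runs.

Only what this package needs - no groups, no second-order indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SobolSample:
    """Evaluation design: rows of ``points`` are parameter vectors in the
    unit hypercube, ordered [A (N rows), B (N rows), AB_1 ... AB_d]."""

    points: np.ndarray
    n: int
    d: int


def saltelli_sample(n: int, d: int, seed: int) -> SobolSample:
    if n < 2:
        raise ValueError("need at least 2 base samples")
    rng = np.random.default_rng(seed)
    a = rng.uniform(size=(n, d))
    b = rng.uniform(size=(n, d))
    blocks = [a, b]
    for i in range(d):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append(ab)
    return SobolSample(points=np.vstack(blocks), n=n, d=d)


@dataclass(frozen=True)
class SobolIndices:
    first_order: np.ndarray
    total_order: np.ndarray
    first_order_ci: np.ndarray  # (d, 2) bootstrap 95% interval
    total_order_ci: np.ndarray


def sobol_indices(
    outputs: np.ndarray, n: int, d: int,
    n_bootstrap: int = 200, seed: int = 0, clip: bool = True,
) -> SobolIndices:
    """Estimate first- and total-order indices from model outputs evaluated
    on a ``saltelli_sample`` design (same ordering)."""
    outputs = np.asarray(outputs, dtype=float)
    if outputs.shape != (n * (d + 2),):
        raise ValueError(f"expected {n * (d + 2)} outputs, got {outputs.shape}")
    f_a = outputs[:n]
    f_b = outputs[n : 2 * n]
    f_ab = outputs[2 * n :].reshape(d, n)

    def estimate(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fa, fb, fab = f_a[idx], f_b[idx], f_ab[:, idx]
        var = np.var(np.concatenate([fa, fb]), ddof=0)
        if var <= 0.0:
            return np.zeros(d), np.zeros(d)
        s1 = np.mean(fb * (fab - fa), axis=1) / var
        st = 0.5 * np.mean((fa - fab) ** 2, axis=1) / var
        return s1, st

    all_idx = np.arange(n)
    s1, st = estimate(all_idx)
    rng = np.random.default_rng(seed)
    boots_s1 = np.empty((n_bootstrap, d))
    boots_st = np.empty((n_bootstrap, d))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        boots_s1[b], boots_st[b] = estimate(idx)
    s1_ci = np.percentile(boots_s1, [2.5, 97.5], axis=0).T
    st_ci = np.percentile(boots_st, [2.5, 97.5], axis=0).T
    if clip:
        s1 = np.clip(s1, 0.0, None)
        st = np.clip(st, 0.0, None)
    return SobolIndices(
        first_order=s1, total_order=st,
        first_order_ci=s1_ci, total_order_ci=st_ci,
    )


def scale_loguniform(unit: np.ndarray, low: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Map unit-hypercube points to log-uniform samples over [low, high]."""
    return low * (high / low) ** unit
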