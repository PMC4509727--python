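"""Species-accumulation (rarefaction) curves and saturation depth.

For a sample with taxon counts N_1..N_S summing to N, the expected number
of distinct taxa in a uniform random subsample of d reads drawn without
replacement is the classic hypergeometric rarefaction formula

    E[S(d)] = Σ_i ( 1 − C(N − N_i, d) / C(N, d) ),

with C(a, b) = 0 when a < b.  Binomial ratios are evaluated in log space
(log-gamma) to stay exact to ~1e-9 well past the depths where direct
factorials overflow.  A Monte-Carlo mode subsamples explicitly and is
useful as an independent check; both modes are provided because standard
ecology packages offer both.

``saturation_depth`` reports the smallest depth at which the curve
reaches a fraction (default 99%) of its final richness — the basis for
"reads needed per sample" recommendations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "AccumulationCurve",
    "rarefy_analytic",
    "rarefy_montecarlo",
    "saturation_depth",
    "default_depth_grid",
    "curves_for_matrix",
]


@dataclass
class AccumulationCurve:
    depths: np.ndarray  # increasing ints
    expected_taxa: np.ndarray
    mode: str  # "analytic" | "montecarlo"
    reps: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        self.expected_taxa = np.asarray(self.expected_taxa, dtype=np.float64)
        if len(self.depths) != len(self.expected_taxa):
            raise ValueError("depths and expected_taxa must have equal length")
        if len(self.depths) and (np.diff(self.depths) <= 0).any():
            raise ValueError("depths must be strictly increasing")

    def to_frame(self, sample_id: str = "sample") -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": sample_id, "depth": self.depths, "expected_taxa": self.expected_taxa}
        )


def _validate_counts(counts: Mapping[str, int] | Sequence[int]) -> np.ndarray:
    vals = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts, dtype=np.int64
    )
    if (vals < 0).any():
        raise ValueError("taxon counts must be non-negative")
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("no non-zero taxon counts")
    return vals


def _log_choose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy_analytic(
    counts: Mapping[str, int] | Sequence[int], depths: Sequence[int]
) -> AccumulationCurve:
    """Exact expected richness at each depth (hypergeometric formula)."""
    vals = _validate_counts(counts)
    n_total = int(vals.sum())
    depths = np.asarray(sorted(set(int(d) for d in depths)), dtype=np.int64)
    if len(depths) == 0:
        raise ValueError("no depths requested")
    if depths[0] < 1:
        raise ValueError("depths must be >= 1")
    if depths[-1] > n_total:
        raise ValueError(f"depth {depths[-1]} exceeds total reads {n_total}")
    expected = np.empty(len(depths))
    for i, d in enumerate(depths):
        rem = n_total - vals  # reads outside each taxon
        with np.errstate(invalid="ignore"):
            log_ratio = _log_choose(rem.astype(np.float64), float(d)) - _log_choose(
                np.array([float(n_total)]), float(d)
            )
        p_absent = np.where(rem >= d, np.exp(log_ratio), 0.0)
        expected[i] = float(np.sum(1.0 - p_absent))
    return AccumulationCurve(depths=depths, expected_taxa=expected, mode="analytic")


def rarefy_montecarlo(
    counts: Mapping[str, int] | Sequence[int],
    depths: Sequence[int],
    reps: int = 100,
    seed: int = 0,
) -> AccumulationCurve:
    """Mean distinct-taxon count over *reps* subsamples without replacement."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    vals = _validate_counts(counts)
    n_total = int(vals.sum())
    depths = np.asarray(sorted(set(int(d) for d in depths)), dtype=np.int64)
    if len(depths) == 0 or depths[0] < 1:
        raise ValueError("depths must be non-empty and >= 1")
    if depths[-1] > n_total:
        raise ValueError(f"depth {depths[-1]} exceeds total reads {n_total}")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(vals.size), vals)
    sums = np.zeros(len(depths))
    for _ in range(reps):
        perm = rng.permutation(pool)
        for i, d in enumerate(depths):
            sums[i] += np.unique(perm[:d]).size
    return AccumulationCurve(
        depths=depths, expected_taxa=sums / reps, mode="montecarlo", reps=reps, seed=seed
    )


def saturation_depth(curve: AccumulationCurve, fraction: float = 0.99) -> int | None:
    """Smallest depth whose expected richness reaches *fraction* of the
    curve's final value; None if never reached."""
    if len(curve.depths) == 0:
        raise ValueError("empty curve")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    target = fraction * curve.expected_taxa[-1]
    hit = np.nonzero(curve.expected_taxa >= target)[0]
    return int(curve.depths[hit[0]]) if hit.size else None


def default_depth_grid(total: int, n_points: int = 50, cap: int = 5000) -> list[int]:
    """Log-spaced depth grid from 1 to min(total, cap)."""
    top = min(total, cap)
    grid = np.unique(np.round(np.geomspace(1, top, n_points)).astype(int))
    return [int(d) for d in grid]


def curves_for_matrix(
    counts: pd.DataFrame,
    mode: str = "analytic",
    reps: int = 100,
    seed: int = 0,
    n_points: int = 50,
    cap: int = 5000,
) -> pd.DataFrame:
    """Per-sample accumulation curves for a taxa × samples count table."""
    frames = []
    for s in counts.columns:
        col = counts[s]
        col = col[col > 0]
        if col.empty:
            continue
        depths = default_depth_grid(int(col.sum()), n_points=n_points, cap=cap)
        if mode == "analytic":
            curve = rarefy_analytic(col.to_dict(), depths)
        elif mode == "montecarlo":
            curve = rarefy_montecarlo(col.to_dict(), depths, reps=reps, seed=seed)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        frames.append(curve.to_frame(sample_id=str(s)))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample_id", "depth", "expected_taxa"]
    )
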