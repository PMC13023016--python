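"""Scan-pair and test-retest statistics, plus acquisition-timing arithmetic.

Paired displacement maps (induced motion vs baseline, or test vs retest)
are compared with ordinary least squares (slope, intercept, R^2), the root
mean square deviation between the raw paired values, and Spearman's rank
correlation.  Group contrasts of the per-scan summaries use the Wilcoxon
signed-rank test with a Bonferroni correction across slices.  Heart-rate
variability during a scan is summarized by the RMSSD of the PPG beat-to-beat
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedMaps",
    "PPGTrace",
    "ProtocolParams",
    "RegressionResult",
    "WilcoxonResult",
    "ProtocolTiming",
    "pair_regression",
    "spearman_reproducibility",
    "wilcoxon_bonferroni",
    "rmssd",
    "percent_change",
    "protocol_timing",
]


@dataclass
class PairedMaps:
    """Two voxelwise scalar maps over the same mask (e.g. test vs retest)."""

    map1: np.ndarray
    map2: np.ndarray
    mask: np.ndarray | None = None
    labels: tuple[str, str] = ("map1", "map2")

    def __post_init__(self) -> None:
        self.map1 = np.asarray(self.map1, dtype=float)
        self.map2 = np.asarray(self.map2, dtype=float)
        if self.map1.shape != self.map2.shape:
            raise ValueError("paired maps must share a shape")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.map1.shape:
                raise ValueError("mask shape mismatch")
        if len(self.values1) < 3:
            raise ValueError("need at least 3 paired voxels")

    @property
    def values1(self) -> np.ndarray:
        return self.map1[self.mask] if self.mask is not None else self.map1.ravel()

    @property
    def values2(self) -> np.ndarray:
        return self.map2[self.mask] if self.mask is not None else self.map2.ravel()


@dataclass
class PPGTrace:
    """Photo-plethysmography beat times in ms, strictly increasing."""

    beat_times_ms: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times_ms, dtype=float)
        if t.ndim != 1 or len(t) < 3:
            raise ValueError("PPG trace needs at least 3 beats")
        if not np.all(np.diff(t) > 0):
            raise ValueError("beat times must be strictly increasing")
        self.beat_times_ms = t

    @property
    def rr_intervals_ms(self) -> np.ndarray:
        return np.diff(self.beat_times_ms)

    @property
    def mean_rr_ms(self) -> float:
        return float(self.rr_intervals_ms.mean())


@dataclass
class ProtocolParams:
    """Acquisition protocol: gated stimulated-echo train parameters."""

    heart_rate_bpm: float
    n_echoes: int = 10
    coverage: float = 1.10
    n_encodings: int = 8
    n_averages: int = 4
    beats_per_preparation: int = 2

    def __post_init__(self) -> None:
        for name in (
            "heart_rate_bpm",
            "n_echoes",
            "coverage",
            "n_encodings",
            "n_averages",
            "beats_per_preparation",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    rmsd: float
    n: int


@dataclass
class WilcoxonResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    effect_size_r: float
    n: int
    method: str


@dataclass
class ProtocolTiming:
    temporal_resolution_ms: float
    scan_duration_s: float
    total_images: int


def pair_regression(pair: PairedMaps) -> RegressionResult:
    """OLS of map2 on map1 plus the RMSD between the raw paired values.

    R^2 = 1 - SS_res/SS_tot for the regression of map2 on map1.  The RMSD is
    ``sqrt(mean((map1 - map2)**2))`` — deviation between the paired values
    themselves, not regression residuals.  Zero variance in map1 leaves R^2
    undefined (NaN) and is flagged via a ValueError.
    """
    x, y = pair.values1, pair.values2
    if np.var(x) == 0:
        raise ValueError("zero variance in map1: R^2 undefined")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmsd = float(np.sqrt(np.mean((x - y) ** 2)))
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        rmsd=rmsd,
        n=len(x),
    )


def spearman_reproducibility(pair: PairedMaps) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x, y = pair.values1, pair.values2
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant map: Spearman undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def wilcoxon_bonferroni(
    x, y=None, n_comparisons: int = 3
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test with Bonferroni correction.

    ``x`` is either the paired differences or the first sample (with ``y``
    the second).  The exact null distribution is used for up to 25 nonzero
    differences; beyond that, the normal approximation with continuity
    correction.  ``p_adjusted = min(1, p_raw * n_comparisons)`` — the
    default of 3 corrects across the three imaged slices.  The effect size
    is ``r = |Z| / sqrt(N)`` with Z recovered from the two-sided p-value.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    method = "exact" if n <= 25 else "approx"
    res = stats.wilcoxon(
        d,
        correction=(method == "approx"),
        method=method,
        alternative="two-sided",
    )
    p_raw = float(res.pvalue)
    z = float(stats.norm.isf(min(p_raw, 1.0) / 2.0)) if p_raw < 1.0 else 0.0
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_raw=p_raw,
        p_adjusted=min(1.0, p_raw * n_comparisons),
        effect_size_r=z / np.sqrt(n),
        n=n,
        method=method,
    )


def rmssd(trace) -> float:
    """Root mean square of successive RR-interval differences (ms)."""
    if not isinstance(trace, PPGTrace):
        trace = PPGTrace(np.asarray(trace, dtype=float))
    rr = trace.rr_intervals_ms
    dd = np.diff(rr)
    if len(dd) == 0:
        raise ValueError("need at least 3 beats for RMSSD")
    return float(np.sqrt(np.mean(dd**2)))


def percent_change(old: float, new: float, mode: str = "simple") -> float:
    """Percent change between two summary values.

    ``simple``: ``100 * (new - old) / old``; ``symmetric``: absolute change
    over the midpoint, ``100 * |new - old| / ((old + new) / 2)`` (bounded by
    200%, symmetric in its arguments).
    """
    if mode == "simple":
        if old == 0:
            raise ValueError("simple percent change undefined for old == 0")
        return 100.0 * (new - old) / old
    if mode == "symmetric":
        if old + new == 0:
            raise ValueError("symmetric percent change undefined for old + new == 0")
        return 100.0 * abs(new - old) / ((old + new) / 2.0)
    raise ValueError(f"unknown mode {mode!r}")


def protocol_timing(params: ProtocolParams) -> ProtocolTiming:
    """Temporal resolution, scan duration, and image count for the protocol.

    The echo spacing is set at prescription so the echo train covers
    ``coverage`` (e.g. 110%) of the cardiac cycle: temporal resolution =
    ``coverage * RR / n_echoes``.  One preparation is played every
    ``beats_per_preparation`` RR intervals, once per encoding direction and
    average, giving scan duration
    ``n_encodings * n_averages * beats_per_preparation * RR``.  Total images
    = ``n_echoes * n_encodings * n_averages``.
    """
    rr_ms = 60000.0 / params.heart_rate_bpm
    return ProtocolTiming(
        temporal_resolution_ms=params.coverage * rr_ms / params.n_echoes,
        scan_duration_s=(
            params.n_encodings
            * params.n_averages
            * params.beats_per_preparation
            * rr_ms
            / 1000.0
        ),
        total_images=params.n_echoes * params.n_encodings * params.n_averages,
    )
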