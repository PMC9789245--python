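"""Recruitment curves, ROC/AUC selectivity, and waveform RMSE comparison.

A branch's recruitment curve is the empirical CDF of its fiber thresholds
over a stimulus-amplitude grid.  Selectivity of a stimulation configuration
is summarized by the ROC curve of the target branch's recruitment (TPR)
against the worst-case non-target recruitment (FPR = max over non-target
branches at each amplitude) and its area under the curve: AUC 1 means the
target saturates before any non-target fiber fires, 0.5 means target and
worst non-target are indistinguishable, 0 means the target never activates.

Endpoint convention (the ROC curve from recruitment data need not reach
(0,0) or (1,1)): the curve is prepended with (0, TPR at FPR=0) and (0,0),
and extended horizontally from its last point to FPR=1, then integrated by
trapezoids over the full FPR range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RecruitmentCurve",
    "RocResult",
    "recruitment",
    "default_amplitude_grid",
    "roc_points",
    "auc",
    "rmse",
]


@dataclass(frozen=True)
class RecruitmentCurve:
    """Fraction of converged fibers active at each stimulus amplitude."""

    branch: str
    amplitudes: np.ndarray
    fraction_active: np.ndarray
    n_fibers: int = 0
    n_excluded: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        f = np.asarray(self.fraction_active, dtype=float)
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "fraction_active", f)
        if len(a) != len(f):
            raise ValueError("grid and fractions must have equal length")
        if np.any(np.diff(a) <= 0):
            raise ValueError("amplitude grid must be strictly increasing")
        if np.any(f < 0) or np.any(f > 1) or np.any(np.diff(f) < 0):
            raise ValueError("fractions must be non-decreasing in [0, 1]")


def recruitment(thresholds, amplitudes, branch: str = "") -> RecruitmentCurve:
    """Empirical recruitment curve from per-fiber threshold results.

    ``thresholds`` is a list of :class:`~vestfem.neural.ThresholdResult`;
    unconverged fibers (no activation up to the search cap) are excluded
    from the denominator and counted in ``n_excluded``.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    conv = [t for t in thresholds if t.converged]
    n_exc = len(list(thresholds)) - len(conv)
    if not conv:
        raise ValueError("no converged thresholds to build a recruitment curve")
    thr = np.sort([t.threshold_amplitude for t in conv])
    frac = np.searchsorted(thr, amplitudes, side="right") / len(thr)
    return RecruitmentCurve(branch, amplitudes, frac, len(thr), n_exc)


def default_amplitude_grid(thresholds, n: int = 100) -> np.ndarray:
    """Logarithmic amplitude grid spanning the observed thresholds +-20 %."""
    vals = np.array(
        [t.threshold_amplitude for t in thresholds if t.converged and np.isfinite(t.threshold_amplitude)]
    )
    if len(vals) == 0:
        raise ValueError("no converged thresholds")
    lo, hi = 0.8 * vals.min(), 1.2 * vals.max()
    return np.logspace(np.log10(lo), np.log10(hi), n)


@dataclass(frozen=True)
class RocResult:
    points: np.ndarray            # (n, 2) of (FPR, TPR), ordered by amplitude
    auc: float
    worst_case_branch: str

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", p)
        if np.any(np.diff(p[:, 0]) < -1e-12) or np.any(np.diff(p[:, 1]) < -1e-12):
            raise ValueError("ROC points must be componentwise non-decreasing")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


def roc_points(target: RecruitmentCurve, nontargets) -> np.ndarray:
    """(FPR, TPR) per amplitude with the worst-case (max) non-target FPR."""
    nontargets = list(nontargets)
    if not nontargets:
        raise ValueError("at least one non-target curve required")
    for nt in nontargets:
        if len(nt.amplitudes) != len(target.amplitudes) or not np.allclose(
            nt.amplitudes, target.amplitudes
        ):
            raise ValueError("recruitment curves must share the amplitude grid")
    fpr = np.max([nt.fraction_active for nt in nontargets], axis=0)
    return np.column_stack([fpr, target.fraction_active])


def worst_case_branch(nontargets) -> str:
    """Non-target branch with the highest final recruitment fraction."""
    finals = [nt.fraction_active[-1] for nt in nontargets]
    return list(nontargets)[int(np.argmax(finals))].branch


def auc(points) -> float:
    """Trapezoidal area under an ROC point set over FPR in [0, 1].

    The first point is anchored through (0, 0) (vertical rise to the TPR
    already reached at zero FPR), and the final TPR extends horizontally to
    FPR = 1; the result is clamped to [0, 1].
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    order = np.lexsort((p[:, 1], p[:, 0]))
    p = p[order]
    pts = [(0.0, 0.0)]
    if p[0, 0] > 0:
        pts.append((0.0, 0.0))
    else:
        pts.append((0.0, p[p[:, 0] == 0][:, 1].max()))
    pts.extend(map(tuple, p))
    pts.append((1.0, p[-1, 1]))
    q = np.array(pts)
    area = float(np.trapezoid(q[:, 1], q[:, 0]))
    return min(1.0, max(0.0, area))


def rmse(series_a, series_b, times, onset: float, stim_end: float) -> float:
    """Root-mean-square difference over the stimulus evaluation window.

    The window runs from 40 us before stimulus onset to 40 us after the
    stimulus ends and must be covered by ``times``.
    """
    series_a = np.asarray(series_a, dtype=float)
    series_b = np.asarray(series_b, dtype=float)
    times = np.asarray(times, dtype=float)
    if series_a.shape != series_b.shape or series_a.shape[-1] != len(times):
        raise ValueError("series must share the time grid")
    t0, t1 = onset - 40e-6, stim_end + 40e-6
    dt = times[1] - times[0]
    if t0 < times[0] - 0.5 * dt or t1 > times[-1] + 0.5 * dt:
        raise ValueError("evaluation window outside the series support")
    mask = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
    d = series_a[..., mask] - series_b[..., mask]
    return float(np.sqrt(np.mean(d * d)))
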