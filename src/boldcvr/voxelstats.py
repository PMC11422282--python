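"""Voxelwise CO2-response statistics.

Each voxel's time series is converted to % BOLD change about its own
baseline-window mean; the baseline window (acquisitions 1-50) is then
compared to the challenge window (acquisitions 51-100) with a two-tailed
Welch t-test ("heteroscedastic variance assumptions"), the per-subject map of
p-values is filtered with a Benjamini-Hochberg step-up at q = 0.05 over all
masked voxels jointly, and a voxel counts as *activated* when it is
FDR-significant AND its window-mean change is positive AND at least the 1%
baseline-fluctuation threshold.

Timepoints within a window are treated as independent samples, mirroring the
analysis this package reimplements; with temporally autocorrelated noise that
choice inflates the per-voxel test (documented, deliberately not corrected
here -- see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BoldSeries

__all__ = [
    "WindowDesign",
    "ActivationResult",
    "percent_change",
    "voxel_window_test",
    "fdr_filter",
    "activation_map",
    "analyze_subject",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowDesign:
    """1-based inclusive acquisition windows of the block design."""

    baseline: tuple[int, int] = (1, 50)
    challenge: tuple[int, int] = (51, 100)
    recovery: tuple[int, int] | None = (101, 150)

    def __post_init__(self) -> None:
        windows = [self.baseline, self.challenge]
        if self.recovery is not None:
            windows.append(self.recovery)
        prev_end = 0
        for name, (a, b) in zip(("baseline", "challenge", "recovery"), windows):
            if a < 1 or b < a:
                raise ValueError(f"{name} window {a}-{b} is invalid")
            if b - a + 1 < 2:
                raise ValueError(f"{name} window {a}-{b} has fewer than 2 volumes")
            if a <= prev_end:
                raise ValueError("windows must be disjoint and ordered")
            prev_end = b

    def validate_length(self, n_volumes: int) -> None:
        last = self.recovery[1] if self.recovery is not None else self.challenge[1]
        if last > n_volumes:
            raise ValueError(
                f"window design extends to volume {last} but series has "
                f"{n_volumes}"
            )

    @staticmethod
    def _slice(window: tuple[int, int]) -> slice:
        return slice(window[0] - 1, window[1])

    @property
    def baseline_slice(self) -> slice:
        return self._slice(self.baseline)

    @property
    def challenge_slice(self) -> slice:
        return self._slice(self.challenge)


@dataclass
class ActivationResult:
    """Per-voxel maps (NaN outside the mask) plus the thresholds used."""

    delta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    fdr_rejected: np.ndarray
    activated: np.ndarray
    mask: np.ndarray
    degenerate: np.ndarray
    alpha: float
    q: float
    percent_threshold: float

    def summary(self) -> dict:
        return {
            "masked_voxels": int(self.mask.sum()),
            "fdr_rejected_voxels": int(self.fdr_rejected.sum()),
            "activated_voxels": int(self.activated.sum()),
            "degenerate_voxels": int(self.degenerate.sum()),
            "alpha": self.alpha,
            "q": self.q,
            "percent_threshold": self.percent_threshold,
        }


def percent_change(
    series: BoldSeries | np.ndarray,
    design: WindowDesign,
    brain_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel % BOLD change about the baseline-window mean.

    Returns ``(pct, valid_mask)`` where ``pct`` has the series' shape with
    zeros outside ``valid_mask``.  Masked voxels whose baseline mean is not
    positive are dropped from the mask with a logged count.
    """
    data = series.data if isinstance(series, BoldSeries) else np.asarray(series)
    design.validate_length(data.shape[-1])
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != data.shape[:-1]:
        raise ValueError(
            f"mask shape {brain_mask.shape} does not match volume "
            f"{data.shape[:-1]}"
        )
    b = data[..., design.baseline_slice].mean(axis=-1)
    valid = brain_mask & (b > 0)
    n_dropped = int(brain_mask.sum() - valid.sum())
    if n_dropped:
        logger.warning(
            "percent_change: dropped %d voxel(s) with nonpositive baseline mean",
            n_dropped,
        )
    pct = np.zeros_like(data)
    pct[valid] = 100.0 * (data[valid] - b[valid, np.newaxis]) / b[valid, np.newaxis]
    return pct, valid


def _welch(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t-test along the last axis: returns (delta, t, p,
    degenerate).  ``delta = mean(x) - mean(y)``; zero variance in both groups
    gives t=0, p=1 for equal means and |t|=inf, p=0 (degenerate) otherwise."""
    nx, ny = x.shape[-1], y.shape[-1]
    mx, my = x.mean(axis=-1), y.mean(axis=-1)
    vx, vy = x.var(axis=-1, ddof=1), y.var(axis=-1, ddof=1)
    delta = mx - my
    se2 = vx / nx + vy / ny
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    t = np.atleast_1d(np.asarray(t))
    t[degenerate & (delta == 0)] = 0.0
    bad = degenerate & (delta != 0)
    t[bad] = np.sign(delta[bad]) * np.inf
    p = np.ones_like(delta)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    p[degenerate & (delta != 0)] = 0.0
    degenerate = degenerate & (delta != 0)
    return delta, t, p, degenerate


def voxel_window_test(
    pct: np.ndarray,
    design: WindowDesign,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Welch test of challenge vs baseline window per voxel.

    ``pct`` is a (..., T) % BOLD array.  Returns full-shape maps
    ``(delta, t, p, degenerate)`` with NaN (p: 1) outside the mask.
    ``delta`` is challenge-window mean minus baseline-window mean.
    """
    pct = np.asarray(pct)
    design.validate_length(pct.shape[-1])
    if mask is None:
        mask = np.ones(pct.shape[:-1], dtype=bool)
    base = pct[mask][..., design.baseline_slice]
    chal = pct[mask][..., design.challenge_slice]
    d_m, t_m, p_m, deg_m = _welch(chal, base)
    shape = pct.shape[:-1]
    delta = np.full(shape, np.nan)
    t = np.full(shape, np.nan)
    p = np.ones(shape)
    degenerate = np.zeros(shape, dtype=bool)
    delta[mask], t[mask], p[mask], degenerate[mask] = d_m, t_m, p_m, deg_m
    return delta, t, p, degenerate


def fdr_filter(
    p: np.ndarray,
    q: float = 0.05,
    mask: np.ndarray | None = None,
    method: str = "fdr_bh",
) -> np.ndarray:
    """False-positive control across all masked voxels jointly.

    Benjamini-Hochberg step-up at level ``q`` by default (guarantees the
    on-average false-discovery rate bound); ``method`` accepts any
    statsmodels ``multipletests`` method name (e.g. ``fdr_by``) as a
    pluggable alternative.  Returns a boolean rejection map.
    """
    p = np.asarray(p)
    if mask is None:
        mask = np.ones(p.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    pv = p[mask]
    if pv.size == 0:
        raise ValueError("empty mask: no p-values to filter")
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values outside [0, 1]")
    reject, *_ = multipletests(pv, alpha=q, method=method)
    out = np.zeros(p.shape, dtype=bool)
    out[mask] = reject
    return out


def activation_map(
    delta: np.ndarray,
    fdr_rejected: np.ndarray,
    percent_threshold: float = 1.0,
) -> np.ndarray:
    """Activated = FDR-significant AND positive AND >= the % threshold.

    Decreases never count: the volume of activation is defined over
    *increases* in BOLD signal only.
    """
    delta = np.asarray(delta)
    with np.errstate(invalid="ignore"):
        return (
            np.asarray(fdr_rejected, dtype=bool)
            & (delta > 0)
            & (delta >= percent_threshold)
        )


def analyze_subject(
    series: BoldSeries | np.ndarray,
    design: WindowDesign,
    brain_mask: np.ndarray,
    alpha: float = 0.05,
    q: float = 0.05,
    percent_threshold: float = 1.0,
    fdr_method: str = "fdr_bh",
) -> ActivationResult:
    """Full per-subject voxel pipeline: % change -> Welch -> FDR -> map."""
    pct, valid = percent_change(series, design, brain_mask)
    delta, t, p, degenerate = voxel_window_test(pct, design, valid)
    rejected = fdr_filter(p, q=q, mask=valid, method=fdr_method)
    activated = activation_map(delta, rejected, percent_threshold)
    return ActivationResult(
        delta=delta,
        t=t,
        p=p,
        fdr_rejected=rejected,
        activated=activated,
        mask=valid,
        degenerate=degenerate,
        alpha=alpha,
        q=q,
        percent_threshold=percent_threshold,
    )
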