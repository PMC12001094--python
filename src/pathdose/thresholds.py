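"""Benchmark doses (BMD) and trend-change doses (TCD) from fitted curves.

The BMD is the lowest dose at which the fitted pathway curve leaves the
band y0 +/- z*SD, where y0 is the model's fitted response at the control
(lowest) dose, SD is the residual standard deviation of the selected model
and z encodes the benchmark response (default 1). The first-crossing rule
also covers biphasic curves, where the band may be exited, re-entered and
exited again.

TCDs are the doses at maxima, minima and inflection points of the fitted
curve, located from analytic derivatives of the spline coefficients (a
linear best model has none). TCD1 is the lowest TCD.

Confidence intervals for both come from a subsampling bootstrap: each
replicate refits the selected model kind on a dose-stratified 60% subsample
of the samples and recomputes the thresholds; the CI is the 2.5/97.5
percentile band over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .datasets import GeneSet
from .model import CandidateModel, PathwayCurve, fit_candidate, predict_curves
from .preprocess import DoseScale, TransformedDataset

__all__ = [
    "ThresholdEstimate",
    "BootstrapResult",
    "compute_bmd",
    "compute_tcds",
    "bootstrap_ci",
    "summarize_thresholds",
]


@dataclass(frozen=True)
class ThresholdEstimate:
    """A BMD or TCD point estimate, with bootstrap CI once attached.

    All doses are on the modeling dose scale; use :meth:`natural` with the
    dataset's :class:`DoseScale` to report in original units.
    """

    kind: str                       # "BMD" | "TCD"
    dose: float
    tcd_type: str | None = None     # "maximum" | "minimum" | "inflection"
    direction: str | None = None    # BMD: "up" | "down" (side of first exit)
    z: float | None = None          # BMD only
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None
    boot_fraction: float | None = None
    n_boot_defined: int | None = None

    def natural(self, scale: DoseScale) -> dict:
        """Report-ready dict with doses back-transformed to natural units."""
        def bt(x):
            return None if x is None else float(scale.to_natural(np.asarray([x]))[0])

        return {
            "kind": self.kind,
            "tcd_type": self.tcd_type,
            "dose": bt(self.dose),
            "ci_low": bt(self.ci_low),
            "ci_high": bt(self.ci_high),
            "direction": self.direction,
            "z": self.z,
            "n_boot": self.n_boot,
            "boot_fraction": self.boot_fraction,
        }


def compute_bmd(
    curve: PathwayCurve, y0: float | None = None, sd: float = 1.0, z: float = 1.0
) -> ThresholdEstimate | None:
    """First dose at which the curve exits the band y0 +/- z*sd.

    Scans the dense grid in ascending dose and linearly interpolates the
    crossing between the bracketing grid points. Returns None when the band
    is never exited (e.g. a flat curve). ``y0`` defaults to the curve value
    at the lowest dose.
    """
    d, y = np.asarray(curve.doses, float), np.asarray(curve.response, float)
    if np.any(np.diff(d) <= 0):
        raise ValueError("curve dose grid must be sorted ascending")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if y0 is None:
        y0 = float(y[0])
    dev = np.abs(y - y0)
    band = z * sd
    outside = dev >= band
    if not outside.any():
        return None
    i = int(np.argmax(outside))
    if i == 0:
        dose = float(d[0])
    else:
        # Linear interpolation of |y - y0| between grid points i-1 and i.
        f0, f1 = dev[i - 1], dev[i]
        t = (band - f0) / (f1 - f0) if f1 > f0 else 1.0
        dose = float(d[i - 1] + t * (d[i] - d[i - 1]))
    direction = "up" if y[i] >= y0 else "down"
    return ThresholdEstimate(kind="BMD", dose=dose, direction=direction, z=z)


def _sign_change_roots(fun, grid: np.ndarray) -> list[float]:
    """Roots of `fun` located by strict sign changes on `grid` + brentq."""
    vals = fun(grid)
    roots = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0 and (i == 0 or vals[i - 1] * b < 0):
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(float(brentq(fun, grid[i], grid[i + 1])))
    return roots


def compute_tcds(curve: PathwayCurve, boundary_tol: float = 1e-6) -> list[ThresholdEstimate]:
    """Maxima, minima and inflection points of the fitted curve.

    Derivatives are analytic from the spline coefficients. Turning points
    are strict sign changes of f', inflections strict sign changes of f'';
    boundary doses are excluded. Sorted ascending by dose (TCD1 first).
    Linear and null best models yield an empty list.
    """
    if curve.kind in ("null", "linear_mixed") or curve.spline is None:
        return []
    lo, hi = float(curve.doses[0]), float(curve.doses[-1])
    span = hi - lo
    grid = np.linspace(lo, hi, max(len(curve.doses), 400))
    inner = lambda x: lo + boundary_tol * span < x < hi - boundary_tol * span

    s1 = curve.spline.derivative(1)
    s2 = curve.spline.derivative(2)
    out: list[ThresholdEstimate] = []
    for root in _sign_change_roots(lambda x: s1(np.asarray(x)), grid):
        if not inner(root):
            continue
        kind = "maximum" if float(s2(root)) < 0 else "minimum"
        if float(s2(root)) == 0.0:  # flat second derivative: classify by slope sign
            eps = span / (10 * len(grid))
            kind = "maximum" if float(s1(root - eps)) > 0 else "minimum"
        out.append(ThresholdEstimate(kind="TCD", dose=float(root), tcd_type=kind))
    for root in _sign_change_roots(lambda x: s2(np.asarray(x)), grid):
        if not inner(root):
            continue
        out.append(ThresholdEstimate(kind="TCD", dose=float(root), tcd_type="inflection"))
    out.sort(key=lambda t: t.dose)
    return out


@dataclass
class BootstrapResult:
    """Bootstrap CIs for the BMD and each TCD of one pathway."""

    bmd: ThresholdEstimate | None
    tcds: list[ThresholdEstimate]
    n_boot: int
    fraction: float
    n_failed_fit: int
    n_bmd_undefined: int
    bmd_available: bool


def _stratified_subsample(
    rng: np.random.Generator, model_doses: np.ndarray, fraction: float
) -> np.ndarray:
    """Indices of ceil(fraction*n) samples, allocated across dose levels by
    largest remainder so every dose level keeps representation."""
    n = model_doses.size
    m = int(np.ceil(fraction * n))
    levels, inverse = np.unique(model_doses, return_inverse=True)
    counts = np.bincount(inverse)
    quota_f = counts * m / n
    quota = np.floor(quota_f).astype(int)
    short = m - quota.sum()
    if short > 0:
        order = np.argsort(-(quota_f - quota), kind="stable")
        quota[order[:short]] += 1
    quota = np.minimum(np.maximum(quota, 1), counts)
    # Trim overshoot (from the minimum-1 floor) off the largest quotas.
    while quota.sum() > m:
        quota[int(np.argmax(quota))] -= 1
    picked = []
    for lv in range(levels.size):
        members = np.flatnonzero(inverse == lv)
        picked.append(rng.choice(members, size=quota[lv], replace=False))
    return np.sort(np.concatenate(picked))


def bootstrap_ci(
    dataset: TransformedDataset,
    geneset: GeneSet,
    selected: CandidateModel,
    point_bmd: ThresholdEstimate | None,
    point_tcds: list[ThresholdEstimate],
    z: float = 1.0,
    n_boot: int = 1000,
    fraction: float = 0.6,
    seed: int = 0,
    grid_size: int = 200,
) -> BootstrapResult:
    """Percentile bootstrap CIs for the BMD and TCDs.

    Each replicate draws a dose-stratified subsample of samples (columns)
    without replacement, refits the originally selected model kind (warm
    started from the full-data variance estimates), and recomputes the
    thresholds. Replicates where a threshold is undefined are dropped for
    that threshold and counted; if more than half the replicates fail, the
    CI is reported as unavailable. Fully reproducible for a given seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    samples = np.array(dataset.samples)
    bmd_reps: list[float] = []
    tcd_reps: list[list[ThresholdEstimate]] = []
    n_failed = 0
    for _ in range(n_boot):
        idx = _stratified_subsample(rng, dataset.model_doses, fraction)
        sub = dataset.subset_samples(list(samples[idx]))
        try:
            cand = fit_candidate(
                sub, geneset, selected.kind, basis=selected.basis,
                theta0=selected.fit.theta, extra_starts=False,
            )
            curve, _, _ = predict_curves(cand, sub, grid_size=grid_size)
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
            continue
        est = compute_bmd(curve, sd=cand.sigma_resid, z=z)
        if est is not None:
            bmd_reps.append(est.dose)
        tcd_reps.append(compute_tcds(curve))

    def pct_ci(vals: list[float]) -> tuple[float, float] | None:
        if len(vals) < max(2, (n_boot - n_failed) // 2):
            return None
        lo, hi = np.percentile(np.asarray(vals), [2.5, 97.5])
        return float(lo), float(hi)

    bmd_out = None
    bmd_available = False
    if point_bmd is not None:
        ci = pct_ci(bmd_reps)
        bmd_available = ci is not None
        bmd_out = replace(
            point_bmd,
            ci_low=ci[0] if ci else None,
            ci_high=ci[1] if ci else None,
            n_boot=n_boot,
            boot_fraction=fraction,
            n_boot_defined=len(bmd_reps),
        )
    tcd_out: list[ThresholdEstimate] = []
    for t in point_tcds:
        matched = []
        for reps in tcd_reps:
            same = [r.dose for r in reps if r.tcd_type == t.tcd_type]
            if same:
                matched.append(min(same, key=lambda d: abs(d - t.dose)))
        ci = pct_ci(matched)
        tcd_out.append(
            replace(
                t,
                ci_low=ci[0] if ci else None,
                ci_high=ci[1] if ci else None,
                n_boot=n_boot,
                boot_fraction=fraction,
                n_boot_defined=len(matched),
            )
        )
    return BootstrapResult(
        bmd=bmd_out,
        tcds=tcd_out,
        n_boot=n_boot,
        fraction=fraction,
        n_failed_fit=n_failed,
        n_bmd_undefined=n_boot - n_failed - len(bmd_reps),
        bmd_available=bmd_available,
    )


def summarize_thresholds(
    bmds: list[float], tcd1s: list[float], scale: DoseScale | None = None
) -> dict:
    """Cumulative distributions of pathway BMDs and first TCDs.

    Takes model-scale doses of the significant pathways with defined
    thresholds and returns sorted vectors, empirical CDF levels and medians,
    back-transformed to natural units when a dose scale is given.
    """
    def summarize(vals: list[float]) -> dict:
        arr = np.sort(np.asarray(vals, dtype=float))
        if scale is not None:
            arr = scale.to_natural(arr)
        if arr.size == 0:
            return {"values": [], "cdf": [], "median": None}
        return {
            "values": arr.tolist(),
            "cdf": (np.arange(1, arr.size + 1) / arr.size).tolist(),
            "median": float(np.median(arr)),
        }

    return {"bmd": summarize(bmds), "tcd1": summarize(tcd1s)}
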