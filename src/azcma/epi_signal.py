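"""Quantification of 5mC and H3K9me3 signals over genomic windows.

Per-cytosine bisulfite calls are aggregated into windowed methylation levels
(methylated / (methylated + unmethylated)); ChIP peaks are post-processed
into blocks (drop peaks shorter than 2 kb, then merge retained peaks closer
than 2 kb); ChIP signal is normalised in two steps (library size, then the
median of non-peak control windows); and the two regression models of the
treatment response are fitted: a proportional linear model for 5mC
(treated = K x untreated) and an asymptotic exponential decay
``y = a - b * exp(-c * x)`` for H3K9me3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .intervals import IntervalSet

WINDOW_COLUMNS = ["chrom", "start", "end", "value", "n_sites"]


# ---------------------------------------------------------------------------
# Windowed methylation
# ---------------------------------------------------------------------------


def window_methylation(
    calls: pd.DataFrame,
    window_bp: int = 200,
    step_bp: int | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Aggregate per-cytosine calls into windowed methylation levels.

    ``calls`` needs columns ``chrom, pos (1-based), methylated, unmethylated``.
    Windows start at multiples of ``step_bp`` (default: non-overlapping tiling
    with ``step_bp == window_bp``).  A window with no covered cytosine has a
    missing (NaN) level, never 0.  When ``chrom_lengths`` is given, the full
    window grid is emitted; otherwise only windows containing calls.
    """
    step_bp = window_bp if step_bp is None else step_bp
    if not (window_bp >= step_bp >= 1):
        raise ValueError("need window_bp >= step_bp >= 1")
    pos0 = calls["pos"].to_numpy(dtype=np.int64) - 1
    meth = calls["methylated"].to_numpy(dtype=np.int64)
    unmeth = calls["unmethylated"].to_numpy(dtype=np.int64)
    chrom = calls["chrom"].to_numpy()

    parts = []
    n_shifts = -(-window_bp // step_bp)  # ceil
    for j in range(n_shifts):
        w = (pos0 // step_bp - j) * step_bp
        ok = (w >= 0) & (pos0 < w + window_bp)
        parts.append(pd.DataFrame({"chrom": chrom[ok], "start": w[ok],
                                   "m": meth[ok], "u": unmeth[ok]}))
    contrib = pd.concat(parts, ignore_index=True)
    grouped = contrib.groupby(["chrom", "start"], sort=True).agg(
        m=("m", "sum"), u=("u", "sum"), n_sites=("m", "size")
    ).reset_index()

    if chrom_lengths is not None:
        grids = [
            pd.DataFrame({"chrom": c, "start": np.arange(0, length, step_bp)})
            for c, length in sorted(chrom_lengths.items())
        ]
        grid = pd.concat(grids, ignore_index=True)
        grouped = grid.merge(grouped, on=["chrom", "start"], how="left")
        grouped[["m", "u", "n_sites"]] = grouped[["m", "u", "n_sites"]].fillna(0)

    denom = grouped["m"] + grouped["u"]
    value = np.where(denom > 0, grouped["m"] / denom.replace(0, np.nan), np.nan)
    out = pd.DataFrame(
        {
            "chrom": grouped["chrom"],
            "start": grouped["start"].astype(np.int64),
            "end": grouped["start"].astype(np.int64) + window_bp,
            "value": value,
            "n_sites": grouped["n_sites"].astype(np.int64),
        }
    )
    if chrom_lengths is not None:
        out["end"] = np.minimum(out["end"], out["chrom"].map(chrom_lengths).astype(np.int64))
    return out


def mean_level(windows: pd.DataFrame, regions: IntervalSet | None = None) -> float:
    """Mean of defined window values, optionally restricted to windows that
    overlap ``regions``.  Missing windows are excluded, never imputed as 0."""
    df = windows
    if regions is not None:
        keep = np.zeros(len(df), dtype=bool)
        for chrom, sub in df.groupby("chrom", sort=False):
            keep[sub.index.to_numpy()] = regions.overlaps_windows(
                str(chrom), sub["start"].to_numpy(), sub["end"].to_numpy()
            )
        df = df[keep]
    vals = df["value"].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined window values in the requested region set")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# Peak post-processing and ChIP normalisation
# ---------------------------------------------------------------------------


def filter_merge_peaks(
    peaks: IntervalSet, min_len_bp: int = 2000, merge_gap_bp: int = 2000
) -> IntervalSet:
    """Post-process called peaks into blocks.

    Peaks shorter than ``min_len_bp`` are dropped first; surviving peaks
    separated by a gap below ``merge_gap_bp`` are then merged.  The operation
    is idempotent.
    """
    return peaks.filter_min_length(min_len_bp).merge_close(merge_gap_bp)


def normalize_chip(
    windows: pd.DataFrame, blocks: IntervalSet, library_scale: float = 1e6
) -> pd.DataFrame:
    """Two-step ChIP signal normalisation.

    Step 1 rescales by total signal (a library-size proxy, per
    ``library_scale``); step 2 divides by the median of windows that do not
    intersect any block, so the non-peak median is exactly 1 afterwards.
    """
    out = windows.copy()
    vals = out["value"].to_numpy(dtype=float)
    total = np.nansum(vals)
    if total <= 0:
        raise ValueError("total signal must be positive")
    vals = vals / total * library_scale

    in_block = np.zeros(len(out), dtype=bool)
    for chrom, sub in out.groupby("chrom", sort=False):
        in_block[sub.index.to_numpy()] = blocks.overlaps_windows(
            str(chrom), sub["start"].to_numpy(), sub["end"].to_numpy()
        )
    control = vals[~in_block]
    control = control[~np.isnan(control)]
    if control.size == 0:
        raise ValueError("no control windows outside blocks")
    med = np.median(control)
    if med <= 0:
        raise ValueError("non-peak median is not positive; cannot scale")
    out["value"] = vals / med
    return out


# ---------------------------------------------------------------------------
# Co-localisation
# ---------------------------------------------------------------------------


@dataclass
class OverlapReport:
    shared_bp: int
    fraction_of_a: float
    fraction_of_b: float


def colocalization(a: IntervalSet, b: IntervalSet) -> OverlapReport:
    """Shared bp between two interval sets and the fraction of each covered."""
    shared = a.intersect(b).total_bp
    fa = shared / a.total_bp if a.total_bp else 0.0
    fb = shared / b.total_bp if b.total_bp else 0.0
    return OverlapReport(shared_bp=shared, fraction_of_a=fa, fraction_of_b=fb)


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float


@dataclass
class DecayFit:
    a: float
    b: float
    c: float
    r_squared: float
    linear_r_squared: float


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
    )


def _decay(x, a, b, c):
    return a - b * np.exp(-c * x)


def fit_exp_decay(x, y, n_restarts: int = 8, seed: int = 0) -> DecayFit:
    """Nonlinear least squares for the saturating decay ``y = a - b e^{-cx}``.

    Initialised at ``a0 = max(y)``, ``b0 = max(y) - min(y)`` (or the y-spread
    floor), ``c0 = 1/mean(x)``, with seeded jittered restarts; the best
    converged fit by residual sum of squares is returned together with its
    R^2 and, for model comparison on the same data, the R^2 of a straight
    line.  Raises ``RuntimeError`` if no restart converges.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4 or x.size != y.size:
        raise ValueError("need >= 4 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x values must spread")
    rng = np.random.default_rng(seed)
    a0 = float(np.max(y))
    b0 = max(float(np.ptp(y)), 1e-6)
    c0 = 1.0 / max(float(np.mean(np.abs(x))), 1e-12)
    eps = 1e-12
    starts = [np.array([a0, b0, c0])]
    # near-linear data live in the c -> 0 limit (a - b e^{-cx} ~ (a-b) + bcx);
    # seed one start on that tangent so the fit is never beaten by a line
    lin = stats.linregress(x, y)
    if lin.slope > 0:
        c_small = 1e-3 * c0
        b_lin = lin.slope / c_small
        starts.append(np.array([lin.intercept + b_lin, b_lin, c_small]))
    best = None
    for k in range(n_restarts):
        if k < len(starts):
            p0 = np.maximum(starts[k], eps)
        else:
            p0 = np.maximum(starts[0] * rng.lognormal(0.0, 0.5, size=3), eps)
        try:
            popt, _ = optimize.curve_fit(
                _decay, x, y, p0=p0, bounds=([eps, eps, eps], [np.inf] * 3), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - _decay(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("exponential-decay fit failed to converge in all restarts")
    sse, (a, b, c) = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and sse < 1e-20 else 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
    try:
        lin_r2 = fit_linear(x, y).r_squared
    except ValueError:
        lin_r2 = np.nan
    return DecayFit(a=float(a), b=float(b), c=float(c), r_squared=r2, linear_r_squared=lin_r2)


def percent_reduction(before: float, after: float) -> float:
    """Percentage drop from ``before`` to ``after``: 100 (before-after)/before."""
    if before <= 0:
        raise ValueError("baseline level must be positive")
    return 100.0 * (before - after) / before
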