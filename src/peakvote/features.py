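"""Chromatographic peak-quality features.

Nine features describe each precursor peak group: two come from the MS1
report (isotope dot product, average mass error in ppm) and seven are
computed from the XIC isotope traces inside the integration interval —
signal-to-noise ratio, jagging score, the spread of FWHM across isotopes,
shape similarity (mean pairwise Pearson correlation), the apex-relative
intensity at the integration boundaries, and the co-elution score/count
derived from pairwise cross-correlation lags.

All sub-computations may report "missing" (``None``) on degenerate input;
:func:`extract_features` replaces every missing value with 0 so any group
yields a finite nine-vector.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from ._domain import FEATURE_NAMES, IsotopeTrace, PeakFeatures, PrecursorPeakGroup

__all__ = [
    "FEATURE_NAMES",
    "compute_fwhm",
    "jagging_score",
    "shape_similarity",
    "coelution",
    "snr",
    "boundary_intensity",
    "extract_features",
]


def compute_fwhm(trace: IsotopeTrace) -> Optional[tuple[float, float, float]]:
    """Full width at half maximum of the in-boundary peak.

    The apex is the maximum intensity inside the integration interval and the
    half-max level is apex/2. The outermost up-crossing (left) and
    down-crossing (right) of that level are located by linear interpolation;
    if the trace never falls to half-max on a side, the crossing is the
    boundary itself.

    Returns ``(fwhm, left_cross, right_cross)`` in minutes, or ``None`` when
    the window has fewer than two samples or a non-positive apex.
    """
    t, y = trace.window()
    if t.size < 2:
        return None
    apex = float(y.max())
    if apex <= 0:
        return None
    half = apex / 2.0

    above = np.flatnonzero(y >= half)
    i, j = above[0], above[-1]
    if i == 0:
        left = float(t[0])
    else:
        # linear interpolation between the last point below and first at/above
        left = float(np.interp(half, [y[i - 1], y[i]], [t[i - 1], t[i]]))
    if j == t.size - 1:
        right = float(t[-1])
    else:
        # descending segment: interpolate on reversed intensities
        right = float(np.interp(half, [y[j + 1], y[j]], [t[j + 1], t[j]]))
    return right - left, left, right


def jagging_score(trace: IsotopeTrace) -> Optional[int]:
    """Number of sampled points dipping below half-max inside the peak.

    Counts points whose intensity is strictly below the half-maximum level
    and whose time lies strictly between the outermost half-max crossings.
    A smooth unimodal peak scores 0; dips within the peak raise the count.
    Returns ``None`` when the FWHM itself is undefined.
    """
    res = compute_fwhm(trace)
    if res is None:
        return None
    _, left, right = res
    t, y = trace.window()
    half = float(y.max()) / 2.0
    inside = (t > left) & (t < right)
    return int(np.count_nonzero(y[inside] < half))


def _common_grid(traces: Sequence[IsotopeTrace]) -> tuple[np.ndarray, list[np.ndarray]]:
    """In-boundary samples of all traces on a shared time grid.

    When the traces already share identical in-boundary time vectors (the
    usual Skyline case) those are used as-is; otherwise every trace is
    linearly interpolated onto the union of in-boundary time points.
    """
    windows = [tr.window() for tr in traces]
    t0 = windows[0][0]
    if all(w[0].size == t0.size and np.array_equal(w[0], t0) for w in windows):
        return t0, [w[1] for w in windows]
    grid = np.unique(np.concatenate([w[0] for w in windows]))
    ys = [np.interp(grid, tr.times, tr.intensities) for tr in traces]
    return grid, ys


def shape_similarity(traces: Sequence[IsotopeTrace]) -> Optional[float]:
    """Mean pairwise Pearson correlation of the isotope trace shapes.

    A pair in which either trace has zero variance over the shared window is
    degenerate and contributes 0. Returns ``None`` with fewer than two traces.
    """
    if len(traces) < 2:
        return None
    grid, ys = _common_grid(traces)
    if grid.size < 2:
        return None
    vals = []
    for a in range(len(ys)):
        for b in range(a + 1, len(ys)):
            sa, sb = np.std(ys[a]), np.std(ys[b])
            if sa == 0 or sb == 0:
                vals.append(0.0)
            else:
                vals.append(float(np.corrcoef(ys[a], ys[b])[0, 1]))
    return float(np.mean(vals))


def coelution(traces: Sequence[IsotopeTrace]) -> tuple[Optional[float], Optional[int]]:
    """Co-elution score and count from pairwise cross-correlation lags.

    For each unordered pair of isotope traces the windowed signals are
    mean-centered and their discrete cross-correlation computed over all lags
    up to the window length; the best-aligned lag is the argmax (ties go to
    the smallest ``|lag|``). The score is the mean over pairs of
    ``|lag*| x median sampling interval`` (minutes) — 0 when all isotopes
    peak together — and the count is the number of pairs whose best lag is
    exactly 0.
    """
    if len(traces) < 2:
        return None, None
    grid, ys = _common_grid(traces)
    n = grid.size
    if n < 2:
        return None, None
    dt = float(np.median(np.diff(grid)))
    lags = np.arange(-(n - 1), n)
    shifts = []
    zero_count = 0
    for a in range(len(ys)):
        for b in range(a + 1, len(ys)):
            ca = ys[a] - ys[a].mean()
            cb = ys[b] - ys[b].mean()
            # per-lag overlap normalization removes the bias toward lag 0;
            # lags are capped at half the window so near-empty overlaps
            # cannot dominate
            overlap = n - np.abs(lags)
            corr = np.correlate(ca, cb, mode="full") / overlap
            keep = np.abs(lags) <= n // 2
            corr, pair_lags = corr[keep], lags[keep]
            best = corr.max()
            cand = pair_lags[corr >= best - 1e-9 * max(abs(best), 1.0)]
            # smallest |lag| wins ties; negative before positive for determinism
            lag_star = int(min(cand, key=lambda l: (abs(l), l)))
            shifts.append(abs(lag_star) * dt)
            if lag_star == 0:
                zero_count += 1
    return float(np.mean(shifts)), zero_count


def snr(trace: IsotopeTrace) -> Optional[float]:
    """Signal-to-noise ratio: in-boundary apex over the noise floor.

    The noise floor is the median intensity of the samples outside the
    integration interval; when no outside samples exist or the floor is 0 it
    falls back to the smallest positive in-boundary intensity. Returns
    ``None`` when the trace has no positive intensity at all.
    """
    t, y = trace.window()
    if y.size == 0 or y.max() <= 0:
        return None
    apex = float(y.max())
    outside_mask = (trace.times < trace.boundary_start) | (trace.times > trace.boundary_end)
    outside = trace.intensities[outside_mask]
    floor = float(np.median(outside)) if outside.size else 0.0
    if floor <= 0:
        pos = y[y > 0]
        floor = float(pos.min())
    return apex / floor


def boundary_intensity(traces: Sequence[IsotopeTrace]) -> Optional[float]:
    """Apex-relative intensity at the integration boundaries, averaged over isotopes.

    Per trace: ``(I(start) + I(end)) / (2 * apex)`` with the boundary
    intensities linearly interpolated; a well-integrated peak is near 0, a
    peak cut mid-flank or integrated off-peak is near 1. Traces with a
    non-positive apex are skipped; if none remain the feature is missing.
    """
    vals = []
    for tr in traces:
        _, y = tr.window()
        i_start = float(np.interp(tr.boundary_start, tr.times, tr.intensities))
        i_end = float(np.interp(tr.boundary_end, tr.times, tr.intensities))
        # boundary values join the apex candidates so collapsed or
        # off-sample windows stay well-defined
        apex = max(float(y.max()) if y.size else 0.0, i_start, i_end)
        if apex <= 0:
            continue
        vals.append((i_start + i_end) / (2.0 * apex))
    if not vals:
        return None
    return float(np.clip(np.mean(vals), 0.0, 1.0))


def _zero_if_missing(value: Optional[float]) -> float:
    return 0.0 if value is None or not np.isfinite(value) else float(value)


def extract_features(group: PrecursorPeakGroup) -> PeakFeatures:
    """Compute the nine-feature vector for one precursor peak group.

    idotp and the average mass error are copied from the report fields (the
    mass error is the mean of per-isotope signed ppm errors when those exist).
    snr is the mean of the per-trace ratios, fwhm_sd the population standard
    deviation of per-isotope FWHM values, jagging the sum over isotopes, and
    the multi-trace features as defined above. Any sub-result that is
    missing becomes 0, so the contract is total: every group yields a finite
    nine-vector.
    """
    if isinstance(group.mass_error_ppm, dict):
        errs = [v for v in group.mass_error_ppm.values() if v is not None and np.isfinite(v)]
        mass_error = float(np.mean(errs)) if errs else None
    else:
        mass_error = group.mass_error_ppm

    traces = sorted(group.traces, key=lambda t: t.isotope_index)

    snrs = [s for s in (snr(tr) for tr in traces) if s is not None]
    fwhms = [r[0] for r in (compute_fwhm(tr) for tr in traces) if r is not None]
    jags = [j for j in (jagging_score(tr) for tr in traces) if j is not None]

    if len(traces) >= 2:
        shape = shape_similarity(traces)
        co_score, co_count = coelution(traces)
    else:
        shape, co_score, co_count = None, None, None

    return PeakFeatures(
        idotp=_zero_if_missing(group.idotp),
        avg_mass_error_ppm=_zero_if_missing(mass_error),
        snr=_zero_if_missing(float(np.mean(snrs)) if snrs else None),
        jagging=float(sum(jags)) if jags else 0.0,
        fwhm_sd=_zero_if_missing(float(np.std(fwhms)) if fwhms else None),
        shape_similarity=_zero_if_missing(shape),
        boundary_intensity=_zero_if_missing(boundary_intensity(traces) if traces else None),
        coelution_score=_zero_if_missing(co_score),
        coelution_count=float(co_count) if co_count is not None else 0.0,
    )
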