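"""Focal adhesion dynamics: length measurement, track linking, phase rates.

The paper-style metrics are: elongation rate (µm/min, length slope during
assembly), loading rate (Pa/min, stress slope during the same phase),
disassembly rate (µm/min), lifetime (min, total time present in the
movie) and peak stress; adhesions are classed *stable* when their
(uncensored) lifetime exceeds 30 min, otherwise *unstable*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = ["LengthMeasurement", "FATrack", "PhaseRates", "measure_length",
           "link_track", "phase_rates", "summarize_condition",
           "measure_scene_tracks", "read_manual_annotations"]

STABLE_LIFETIME_MIN = 30.0
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class LengthMeasurement:
    """One adhesion length measurement in one frame."""

    length: float                 # µm, major-axis FWHM-equivalent
    centroid: tuple[float, float]  # (x, y) µm
    axis_ratio: float
    peak_intensity: float
    background: float


def _moment_length(weights: np.ndarray, q: float) -> tuple[float, float]:
    """Major/minor FWHM from intensity moments of a blob truncated at q·peak.

    For a Gaussian blob restricted to the elliptical region above
    q × peak, the second moment along a principal axis is
    σ² · [1 − (1 − ln q)·q] / (1 − q); the correction inverts that
    truncation so the returned FWHM (2√(2 ln 2)·σ) is unbiased for
    Gaussian-shaped adhesions.
    """
    total = weights.sum()
    ys, xs = np.mgrid[0:weights.shape[0], 0:weights.shape[1]]
    cy = (ys * weights).sum() / total
    cx = (xs * weights).sum() / total
    mxx = ((xs - cx) ** 2 * weights).sum() / total
    myy = ((ys - cy) ** 2 * weights).sum() / total
    mxy = ((xs - cx) * (ys - cy) * weights).sum() / total
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals = np.linalg.eigvalsh(cov)
    evals = np.clip(evals, 1e-12, None)
    trunc = (1.0 - (1.0 - np.log(q)) * q) / (1.0 - q)
    sig = np.sqrt(evals / trunc)
    return FWHM_FACTOR * sig[1], FWHM_FACTOR * sig[0]  # (major, minor) px


def measure_length(paxillin_frame: np.ndarray,
                   seed_point: tuple[float, float],
                   pixel_size: float = 0.1,
                   window: float = 3.0,
                   moment_fraction: float = 0.1,
                   min_area_px: int = 4,
                   _max_enlarge: int = 3) -> LengthMeasurement | None:
    """Measure one adhesion's length around a seed point.

    The adhesion is segmented within a ±``window`` µm crop by Otsu
    thresholding seeded at ``seed_point`` (x, y in µm); the local
    background is the median outside the segmented object, and the final
    length is the major-axis FWHM estimated from truncation-corrected
    intensity moments of the background-subtracted blob (sub-pixel, and
    exact for the Gaussian-shaped adhesions of the synthetic generator).
    Returns ``None`` (a gap) when no object stands above threshold.
    """
    px = pixel_size
    r0 = int(round(seed_point[1] / px))
    c0 = int(round(seed_point[0] / px))
    half = int(round(window / px))
    ny, nx = paxillin_frame.shape
    rlo, rhi = max(0, r0 - half), min(ny, r0 + half + 1)
    clo, chi = max(0, c0 - half), min(nx, c0 + half + 1)
    crop = np.asarray(paxillin_frame[rlo:rhi, clo:chi], dtype=float)
    if crop.size == 0 or np.ptp(crop) < 1e-9:
        return None
    thr = threshold_otsu(crop)
    binary = crop > thr
    if binary.sum() < min_area_px or binary.all():
        return None
    labels = label(binary, connectivity=2)
    # component nearest the seed (within 1 µm)
    sr, sc = r0 - rlo, c0 - clo
    rr, cc = np.nonzero(binary)
    dist = np.hypot(rr - sr, cc - sc)
    if dist.min() * px > 1.0:
        return None
    lab = labels[rr[np.argmin(dist)], cc[np.argmin(dist)]]
    comp = labels == lab
    if comp.sum() < min_area_px:
        return None
    background = float(np.median(crop[~ndimage.binary_dilation(
        comp, iterations=3)])) if (~comp).sum() > 10 else float(crop.min())
    smoothed = ndimage.gaussian_filter(crop, 1.0)
    peak = float(smoothed[comp].max())
    # reject windows whose "object" does not stand above the noise floor
    outside = crop[~ndimage.binary_dilation(comp, iterations=3)]
    noise_sd = 1.4826 * float(np.median(np.abs(outside - np.median(outside)))) \
        if outside.size > 10 else 0.0
    if peak - background <= 4.0 * noise_sd or peak - background <= 0:
        return None
    # weights: background-subtracted intensity above moment_fraction of peak,
    # on the connected component containing the seed (isolates neighbours)
    excess = crop - background
    region = excess >= moment_fraction * (peak - background)
    comp_region = label(region, connectivity=2)
    lab2 = comp_region[rr[np.argmin(dist)], cc[np.argmin(dist)]]
    if lab2 == 0:
        region_sel = region
    else:
        region_sel = comp_region == lab2
    weights = np.where(region_sel, np.clip(excess, 0.0, None), 0.0)
    if weights.sum() <= 0:
        return None
    # a region touching the crop border means the window truncates the
    # adhesion: re-measure with an enlarged window
    rsel_r, rsel_c = np.nonzero(region_sel)
    touches = (rsel_r.min() == 0 or rsel_c.min() == 0 or
               rsel_r.max() == region_sel.shape[0] - 1 or
               rsel_c.max() == region_sel.shape[1] - 1)
    full_window = (rlo == 0 and clo == 0 and rhi == ny and chi == nx)
    if touches and _max_enlarge > 0 and not full_window:
        return measure_length(paxillin_frame, seed_point, pixel_size,
                              window=1.6 * window,
                              moment_fraction=moment_fraction,
                              min_area_px=min_area_px,
                              _max_enlarge=_max_enlarge - 1)
    major_px, minor_px = _moment_length(weights, moment_fraction)
    ys, xs = np.mgrid[0:crop.shape[0], 0:crop.shape[1]]
    cy = (ys * weights).sum() / weights.sum()
    cx = (xs * weights).sum() / weights.sum()
    return LengthMeasurement(
        length=major_px * px,
        centroid=((clo + cx) * px, (rlo + cy) * px),
        axis_ratio=float(major_px / max(minor_px, 1e-9)),
        peak_intensity=peak, background=background)


@dataclass
class PhaseRates:
    """Assembly/disassembly kinetics of one track."""

    elongation_rate: float         # µm/min, NaN when no growth phase
    loading_rate: float            # Pa/min, NaN without stress data
    disassembly_rate: float        # µm/min, NaN when no shrinkage phase
    growth_window: tuple[float, float] | None
    decay_window: tuple[float, float] | None
    n_breakpoints: int
    flagged: bool = False


@dataclass
class FATrack:
    """One adhesion's time series plus derived dynamics metrics."""

    times: np.ndarray              # min, absolute movie time
    lengths: np.ndarray            # µm
    stresses: np.ndarray | None    # Pa (local stress at the adhesion)
    frame_interval: float          # min
    censored_start: bool = False
    censored_end: bool = False
    track_id: int = -1
    rates: PhaseRates | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.stresses is not None:
            self.stresses = np.asarray(self.stresses, dtype=float)
        if len(self.times) != len(self.lengths):
            raise ValueError("times and lengths must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.lengths[np.isfinite(self.lengths)] <= 0):
            raise ValueError("lengths must be positive where present")

    @property
    def censored(self) -> bool:
        return self.censored_start or self.censored_end

    @property
    def lifetime(self) -> float:
        """Total time present in the movie (min): n_frames × interval."""
        return len(self.times) * self.frame_interval

    @property
    def peak_stress(self) -> float:
        if self.stresses is None:
            return np.nan
        return float(np.nanmax(self.stresses))

    @property
    def stability(self) -> str:
        return "stable" if self.lifetime > STABLE_LIFETIME_MIN else "unstable"


def link_track(measurements: list[tuple[int, float | None]],
               stresses: list[float | None] | None = None,
               frame_interval: float = 0.5,
               n_frames: int | None = None,
               max_gap: int = 2,
               min_frames: int = 3,
               track_id: int = -1) -> list[FATrack]:
    """Link per-frame measurements into adhesion tracks.

    ``measurements`` is a time-ordered list of ``(frame_index, length_um)``
    with ``None`` lengths marking gaps; ``stresses`` optionally supplies
    the local stress per listed frame. Gaps of ≤ ``max_gap`` frames are
    linearly interpolated; longer gaps split the series into separate
    tracks; segments of fewer than ``min_frames`` frames are rejected.
    Censoring flags are set for tracks touching the movie boundaries
    (frame 0, or ``n_frames − 1`` when ``n_frames`` is given).
    ``frame_interval`` is in minutes.
    """
    frames = [f for f, L in measurements if L is not None]
    if not frames:
        return []
    lengths = {f: L for f, L in measurements if L is not None}
    stress_map = {}
    if stresses is not None:
        for (f, L), s in zip(measurements, stresses):
            if L is not None and s is not None:
                stress_map[f] = s

    # split at gaps longer than max_gap
    segments: list[list[int]] = [[frames[0]]]
    for f in frames[1:]:
        if f - segments[-1][-1] - 1 > max_gap:
            segments.append([f])
        else:
            segments[-1].append(f)

    tracks: list[FATrack] = []
    for seg in segments:
        full = np.arange(seg[0], seg[-1] + 1)
        if len(full) < min_frames:
            continue
        known = np.array(seg)
        L = np.interp(full, known, [lengths[f] for f in seg])
        if stress_map:
            sk = [f for f in seg if f in stress_map]
            S = np.interp(full, sk, [stress_map[f] for f in sk]) if sk else None
        else:
            S = None
        tracks.append(FATrack(
            times=full * frame_interval, lengths=L, stresses=S,
            frame_interval=frame_interval,
            censored_start=seg[0] == 0,
            censored_end=n_frames is not None and seg[-1] >= n_frames - 1,
            track_id=track_id))
    return tracks


def _piecewise_fit(t: np.ndarray, y: np.ndarray,
                   breaks: tuple[float, ...]) -> tuple[np.ndarray, float]:
    """Continuous piecewise-linear least squares with fixed breakpoints."""
    cols = [np.ones_like(t), t] + [np.clip(t - b, 0.0, None) for b in breaks]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(((A @ coef - y) ** 2).sum())
    return coef, rss


def _bic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-12) / n) + k * np.log(n)


def phase_rates(track: FATrack, max_candidates: int = 25,
                min_slope: float = 0.01) -> PhaseRates:
    """Assembly and disassembly rates from a piecewise-linear length fit.

    The length-vs-time series is fit with 0, 1 or 2 breakpoints (model
    chosen by BIC). The growth phase is the segment with the largest
    positive slope (elongation rate, µm/min); the disassembly phase the
    segment with the most negative slope (its |slope| is the disassembly
    rate); the loading rate is the least-squares stress slope over the
    growth-phase time window. A track with no segment steeper than
    ``min_slope`` µm/min is flagged (rates NaN).
    """
    t, y = track.times, track.lengths
    n = len(t)
    if n < 4:
        return PhaseRates(np.nan, np.nan, np.nan, None, None, 0, flagged=True)

    interior = t[2:-2] if n > 6 else t[1:-1]
    if len(interior) > max_candidates:
        cand = np.quantile(interior, np.linspace(0, 1, max_candidates))
    else:
        cand = interior

    best = None
    _, rss0 = _piecewise_fit(t, y, ())
    best = (_bic(rss0, n, 2), (), rss0)
    for b1 in cand:
        _, rss = _piecewise_fit(t, y, (b1,))
        score = _bic(rss, n, 4)
        if score < best[0]:
            best = (score, (b1,), rss)
    for i, b1 in enumerate(cand):
        for b2 in cand[i + 1:]:
            if b2 - b1 < 2 * track.frame_interval:
                continue
            _, rss = _piecewise_fit(t, y, (b1, b2))
            score = _bic(rss, n, 6)
            if score < best[0]:
                best = (score, (b1, b2), rss)

    breaks = best[1]
    coef, _ = _piecewise_fit(t, y, breaks)
    edges = [t[0], *breaks, t[-1]]
    slopes = np.cumsum(coef[1:])  # slope in segment i = b + Σ hinge coefs
    windows = list(zip(edges[:-1], edges[1:]))

    i_grow = int(np.argmax(slopes))
    i_decay = int(np.argmin(slopes))
    growth = windows[i_grow] if slopes[i_grow] > min_slope else None
    decay = windows[i_decay] if slopes[i_decay] < -min_slope else None

    elong = float(slopes[i_grow]) if growth else np.nan
    disas = float(-slopes[i_decay]) if decay else np.nan

    loading = np.nan
    if growth and track.stresses is not None:
        # trim the window ends: breakpoint placement error that lets the
        # window overhang the stress plateau only ever biases the slope low
        g0, g1 = growth
        trim = 0.1 * (g1 - g0)
        sel = (t >= g0 + trim) & (t <= g1 - trim) & \
            np.isfinite(track.stresses)
        if sel.sum() < 3:
            sel = (t >= g0) & (t <= g1) & np.isfinite(track.stresses)
        if sel.sum() >= 2:
            loading = float(np.polyfit(t[sel], track.stresses[sel], 1)[0])

    rates = PhaseRates(elong, loading, disas, growth, decay,
                       n_breakpoints=len(breaks), flagged=growth is None)
    track.rates = rates
    return rates


def summarize_condition(tracks: list[FATrack], condition: str,
                        include_censored: bool = False,
                        min_uncensored: int = 5,
                        histogram_bins: int = 12):
    """Per-condition summary of FA dynamics metrics.

    Returns ``(summary, per_track)`` DataFrames. ``summary`` holds mean,
    SE and n for elongation rate, loading rate, disassembly rate and
    lifetime (censored tracks excluded from lifetime statistics unless
    ``include_censored``; an all-track lifetime mean is reported alongside
    for comparison), plus the stable/unstable split with per-class mean
    peak stress. Histogram arrays for lifetime/elongation/loading are
    attached as ``summary.attrs['histograms']``.
    """
    if not tracks:
        raise ValueError("no tracks to summarize")
    rows = []
    for tr in tracks:
        if tr.rates is None:
            phase_rates(tr)
        rows.append({
            "track_id": tr.track_id,
            "condition": condition,
            "lifetime_min": tr.lifetime,
            "elongation_rate_um_min": tr.rates.elongation_rate,
            "loading_rate_pa_min": tr.rates.loading_rate,
            "disassembly_rate_um_min": tr.rates.disassembly_rate,
            "peak_stress_pa": tr.peak_stress,
            "censored": tr.censored,
            "stability": tr.stability,
            "flagged": tr.rates.flagged,
        })
    per_track = pd.DataFrame(rows)
    uncens = per_track[~per_track["censored"]]
    if len(uncens) == 0:
        raise ValueError("all tracks are censored")
    if len(uncens) < min_uncensored:
        raise ValueError(f"need >= {min_uncensored} uncensored tracks "
                         f"(got {len(uncens)})")

    lifetime_pool = per_track if include_censored else uncens

    def _stat(series: pd.Series) -> tuple[float, float, int]:
        v = series.dropna().to_numpy()
        if len(v) == 0:
            return np.nan, np.nan, 0
        return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v))) \
            if len(v) > 1 else 0.0, len(v)

    entries = {}
    for name, pool in [("lifetime_min", lifetime_pool),
                       ("elongation_rate_um_min", per_track),
                       ("loading_rate_pa_min", per_track),
                       ("disassembly_rate_um_min", per_track)]:
        m, se, nn = _stat(pool[name])
        entries[f"{name}_mean"] = m
        entries[f"{name}_se"] = se
        entries[f"{name}_n"] = nn
    m_all, se_all, n_all = _stat(per_track["lifetime_min"])
    entries["lifetime_incl_censored_mean"] = m_all
    entries["lifetime_incl_censored_n"] = n_all
    for cls in ("stable", "unstable"):
        sub = per_track[per_track["stability"] == cls]
        m, se, nn = _stat(sub["peak_stress_pa"])
        entries[f"peak_stress_{cls}_mean"] = m
        entries[f"peak_stress_{cls}_n"] = nn
    entries["n_tracks"] = len(per_track)
    entries["condition"] = condition
    summary = pd.DataFrame([entries])

    hists = {}
    for name in ("lifetime_min", "elongation_rate_um_min",
                 "loading_rate_pa_min"):
        v = per_track[name].dropna().to_numpy()
        if len(v):
            try:
                hists[name] = np.histogram(v, bins=histogram_bins)
            except ValueError:  # (near-)degenerate range
                hists[name] = np.histogram(v, bins=1,
                                           range=(v[0] - 0.5, v[0] + 0.5))
    summary.attrs["histograms"] = hists
    return summary, per_track


def measure_scene_tracks(scene, measure: bool = True,
                         max_gap: int = 2) -> list[FATrack]:
    """Run the length-measurement pipeline over a synthetic adhesion scene.

    Renders each frame of the scene once (streaming, so large cohorts
    never hold the stack in memory), measures every live adhesion with
    :func:`measure_length` at its known position, and links the
    measurements into :class:`FATrack` objects with the scene's noisy
    stress traces attached. With ``measure=False`` the generator's own
    noisy length traces are used instead of image measurement.
    """
    params = scene.params
    per_track: dict[int, list[tuple[int, float | None]]] = \
        {tr.track_id: [] for tr in scene.tracks}
    frames_by_track = {tr.track_id: scene.track_frames(tr)
                       for tr in scene.tracks}
    if measure:
        live_by_frame: dict[int, list] = {}
        for tr in scene.tracks:
            for f in frames_by_track[tr.track_id]:
                live_by_frame.setdefault(int(f), []).append(tr)
        for f in range(params.n_frames):
            if f not in live_by_frame:
                continue
            img = scene.render_frame(f)
            for tr in live_by_frame[f]:
                m = measure_length(img, tr.center, pixel_size=scene.pixel_size)
                per_track[tr.track_id].append(
                    (f, m.length if m is not None else None))
    else:
        for tr in scene.tracks:
            for f, L in zip(frames_by_track[tr.track_id],
                            scene.length_traces[tr.track_id]):
                per_track[tr.track_id].append((int(f), float(L)))

    out: list[FATrack] = []
    for tr in scene.tracks:
        frames = frames_by_track[tr.track_id]
        stress = {int(f): float(s) for f, s in
                  zip(frames, scene.stress_traces[tr.track_id])}
        meas = per_track[tr.track_id]
        stresses = [stress.get(f) for f, _ in meas]
        out.extend(link_track(meas, stresses,
                              frame_interval=params.frame_interval_min,
                              n_frames=params.n_frames, max_gap=max_gap,
                              track_id=tr.track_id))
    return out


def read_manual_annotations(path, frame_interval: float,
                            n_frames: int | None = None) -> list[FATrack]:
    """Import hand-measured lengths (track_id, frame, length_um[, x, y]).

    Provides exact parity with manual annotation: rows are grouped by
    ``track_id``, ordered by ``frame`` and linked with the same gap rules
    as the automated path. ``frame_interval`` in minutes.
    """
    df = pd.read_csv(path)
    required = {"track_id", "frame", "length_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV needs columns {sorted(required)}")
    tracks: list[FATrack] = []
    for tid, sub in df.groupby("track_id"):
        sub = sub.sort_values("frame")
        meas = [(int(f), float(L)) for f, L in
                zip(sub["frame"], sub["length_um"])]
        tracks.extend(link_track(meas, frame_interval=frame_interval,
                                 n_frames=n_frames, track_id=int(tid)))
    return tracks
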