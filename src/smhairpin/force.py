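"""AFM single-molecule force-spectroscopy analysis.

Detects specific unbinding events in retraction force-distance curves,
fits the worm-like-chain (WLC) polymer model

    F(x) = (kB*T / Lp) * [ 1/4 (1 - x/Lc)^-2 - 1/4 + x/Lc ]

to the final force ramp of each event, filters events by tether contour
length, and summarises rupture forces with Gaussian histogram fits.  The
contour length Lc acts as the specificity fingerprint: a single PEG tether
of ~33 nm links the probe molecule to the tip, so specific ruptures occur
at that tether length while nonspecific adhesion stays within ~10 nm of
the surface.

The analysis stages are sklearn-style estimators (``RuptureDetector``,
``WLCFitter``, ``SpecificFilter``, ``GaussianHistogramFit``) so they can
be composed and parameterised with ``get_params``/``set_params``; the
module-level functions are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import ks_2samp
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import ROOM_TEMPERATURE_K, kbt
from .errors import AnalysisError, FitError, ParameterError

__all__ = [
    "ForceDistanceCurve",
    "WLCParams",
    "RuptureSegment",
    "RuptureEvent",
    "GaussianFitResult",
    "wlc_force",
    "wlc_extension",
    "detect_rupture",
    "fit_wlc",
    "filter_specific",
    "fit_gaussian_hist",
    "aggregate_replicates",
    "ks_compare",
    "RuptureDetector",
    "WLCFitter",
    "SpecificFilter",
    "GaussianHistogramFit",
    "analyze_curves",
    "events_to_frame",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ForceDistanceCurve:
    """One retraction trace: tip-surface separation (nm) vs force (pN)."""

    distance: np.ndarray
    force: np.ndarray
    retraction_speed: float = 500.0  # nm/s
    spring_constant: float = 25.0    # pN/nm
    id: str = ""

    def __post_init__(self):
        self.distance = np.asarray(self.distance, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.distance.shape != self.force.shape:
            raise ParameterError("distance and force must have equal length")
        if self.distance.size < 50:
            raise ParameterError(
                f"curve {self.id!r}: need >= 50 samples, got {self.distance.size}"
            )
        if not (np.all(np.isfinite(self.distance)) and np.all(np.isfinite(self.force))):
            raise ParameterError(f"curve {self.id!r}: non-finite values")
        if np.any(np.diff(self.distance) <= 0):
            raise ParameterError(f"curve {self.id!r}: distance must be strictly increasing")


@dataclass(frozen=True)
class WLCParams:
    """Worm-like-chain parameters: persistence length Lp and contour length Lc (nm)."""

    Lp: float
    Lc: float
    temperature: float = ROOM_TEMPERATURE_K

    def __post_init__(self):
        if not 0 < self.Lp < self.Lc:
            raise ParameterError(f"require 0 < Lp < Lc, got Lp={self.Lp}, Lc={self.Lc}")


@dataclass
class RuptureSegment:
    """The final force ramp of a curve, ending at a rupture drop.

    ``x``/``f`` are baseline-corrected samples from ramp start to the last
    attached sample.  ``x_rupture`` is the midpoint of the interval between
    the last attached and first detached sample (rupture occurred somewhere
    inside it).  ``drop_pn`` is the magnitude of the force drop.
    """

    x: np.ndarray
    f: np.ndarray
    x_rupture: float
    drop_pn: float
    noise_sd: float
    curve_id: str = ""


@dataclass
class RuptureEvent:
    """One fitted specific unbinding event."""

    Fr: float              # rupture force, pN (WLC model force at x_rupture)
    x_rupture: float       # nm
    params: WLCParams
    rss: float             # residual sum of squares of the fit, pN^2
    curve_id: str = ""

    def __post_init__(self):
        if self.Fr <= 0:
            raise ParameterError(f"Fr must be positive, got {self.Fr}")
        if self.x_rupture >= self.params.Lc:
            raise ParameterError("x_rupture must lie below Lc")

    @property
    def Lc(self) -> float:
        return self.params.Lc

    @property
    def Lp(self) -> float:
        return self.params.Lp


@dataclass
class GaussianFitResult:
    """Least-squares Gaussian fit to a histogram of values."""

    mean: float
    sd: float
    n: int
    bin_width: float
    rss: float = 0.0

    def __post_init__(self):
        if self.sd < 0:
            raise ParameterError("sd must be >= 0")
        if self.n < 1:
            raise ParameterError("n must be >= 1")


# ---------------------------------------------------------------------------
# the WLC model
# ---------------------------------------------------------------------------

def wlc_force(x, params: WLCParams):
    """WLC interpolation formula: force (pN) at extension ``x`` (nm).

    Diverges as x -> Lc; raises for x outside [0, Lc).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= params.Lc):
        raise ParameterError(f"extension must satisfy 0 <= x < Lc={params.Lc}")
    t = x / params.Lc
    prefactor = kbt(params.temperature) / params.Lp
    out = prefactor * (0.25 * (1.0 - t) ** -2 - 0.25 + t)
    return out if out.ndim else float(out)


def wlc_extension(force_pn: float, params: WLCParams, tol: float = 1e-10) -> float:
    """Invert the WLC model: extension x (nm) at which F(x) equals ``force_pn``.

    Bisection on the strictly increasing F(x); used by the synthetic-data
    generator to place rupture points on a distance-sampled curve.
    """
    if force_pn < 0:
        raise ParameterError("force must be >= 0")
    if force_pn == 0:
        return 0.0
    lo, hi = 0.0, params.Lc * (1.0 - 1e-12)
    # plain bisection: F is monotonic and cheap, ~50 iterations reach 1e-10 Lc
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if wlc_force(mid, params) < force_pn:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _wlc_f(x, lp, lc, kbt_val):
    # unchecked vectorized WLC used inside least-squares (lc > max(x) enforced by bounds)
    t = np.clip(x / lc, 0.0, 1.0 - 1e-9)
    return (kbt_val / lp) * (0.25 * (1.0 - t) ** -2 - 0.25 + t)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class RuptureDetector(BaseEstimator, TransformerMixin):
    """Detect the final specific unbinding event in retraction curves.

    The baseline (far-from-surface force) is the median of the last
    ``baseline_fraction`` of the trace and is subtracted.  A rupture
    candidate is a drop of the smoothed force exceeding a noise-scaled
    threshold, from a level itself well above the noise, down to baseline,
    at a tip-surface distance beyond ``min_distance_nm`` (which excludes
    short-range nonspecific adhesion).  When several drops qualify the one
    at the largest distance is taken (the last unbinding of the serial
    tether geometry).

    Parameters
    ----------
    min_distance_nm : exclusion zone for nonspecific adhesion (default 10).
    k_drop : drop threshold in units of the smoothed-difference noise SD.
    k_level : pre-drop force level threshold in units of smoothed noise SD.
    min_drop_pn : absolute floor for the drop magnitude, pN.
    smooth_window : moving-average window (samples).
    baseline_fraction : tail fraction of the trace used for baseline/noise.
    """

    def __init__(self, min_distance_nm=10.0, k_drop=6.0, k_level=5.0,
                 min_drop_pn=15.0, smooth_window=7, baseline_fraction=0.2):
        self.min_distance_nm = min_distance_nm
        self.k_drop = k_drop
        self.k_level = k_level
        self.min_drop_pn = min_drop_pn
        self.smooth_window = smooth_window
        self.baseline_fraction = baseline_fraction

    def fit(self, X, y=None):  # stateless; present for pipeline compatibility
        return self

    def transform(self, X):
        """Map curves to rupture segments; curves without events are dropped."""
        segments = []
        for curve in X:
            seg = self.detect(curve)
            if seg is not None:
                segments.append(seg)
        return segments

    def detect(self, curve: ForceDistanceCurve) -> RuptureSegment | None:
        x = curve.distance
        f = curve.force.copy()
        n = f.size
        w = int(self.smooth_window)

        tail = max(int(n * self.baseline_fraction), 10)
        baseline = np.median(f[-tail:])
        f -= baseline
        noise = 1.4826 * np.median(np.abs(f[-tail:] - np.median(f[-tail:])))
        noise = max(noise, 1e-6)
        sigma_s = noise / np.sqrt(w)

        kernel = np.ones(w) / w
        fs = np.convolve(f, kernel, mode="same")

        # drop size between smoothed levels w samples apart
        drop = fs[:-w] - fs[w:]
        idx = np.arange(drop.size)
        drop_thresh = max(self.k_drop * np.sqrt(2.0) * sigma_s, self.min_drop_pn)
        cand = (
            (drop > drop_thresh)
            & (fs[:-w] > self.k_level * sigma_s)
            & (x[:-w] >= self.min_distance_nm)
        )
        # require the post-drop level to sit at baseline
        post_ok = np.zeros_like(cand)
        for i in idx[cand]:
            j0, j1 = i + w, min(i + 2 * w, n)
            post_ok[i] = np.mean(fs[j0:j1]) < 3.0 * sigma_s if j1 > j0 else False
        cand &= post_ok
        if not np.any(cand):
            return None

        # last contiguous run of candidates = last unbinding
        runs = np.flatnonzero(cand)
        last_run_end = runs[-1]
        run_start = last_run_end
        while run_start - 1 in set(runs):
            run_start -= 1
        run = runs[(runs >= run_start) & (runs <= last_run_end)]
        i_star = run[np.argmax(drop[run])]

        # locate the last attached raw sample inside the drop window
        pre_level = fs[i_star]
        half = 0.5 * pre_level
        window = slice(max(i_star - w, 0), min(i_star + 2 * w, n - 1))
        above = np.flatnonzero(f[window] > half)
        if above.size == 0:
            return None
        j = window.start + above[-1]
        if j + 1 >= n:
            return None
        x_rupture = 0.5 * (x[j] + x[j + 1])

        # ramp start: walk back to where the smoothed force leaves the noise band
        s = j
        while s > 0 and fs[s - 1] > 2.0 * sigma_s:
            s -= 1
        if j - s + 1 < 10:
            return None
        return RuptureSegment(
            x=x[s:j + 1].copy(),
            f=f[s:j + 1].copy(),
            x_rupture=x_rupture,
            drop_pn=float(drop[i_star]),
            noise_sd=noise,
            curve_id=curve.id,
        )


class WLCFitter(BaseEstimator, TransformerMixin):
    """Nonlinear least-squares WLC fit of rupture segments.

    Lp is fitted freely within ``lp_bounds`` by default (the PEG persistence
    length is not known a priori); pass ``fix_lp`` to constrain it.  The
    rupture force is the fitted model force evaluated at the segment's
    rupture distance.
    """

    def __init__(self, temperature=ROOM_TEMPERATURE_K, lp_bounds=(0.1, 2.0),
                 fix_lp=None, max_lc_factor=5.0):
        self.temperature = temperature
        self.lp_bounds = lp_bounds
        self.fix_lp = fix_lp
        self.max_lc_factor = max_lc_factor

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        events = []
        for seg in X:
            try:
                events.append(self.fit_segment(seg))
            except FitError:
                continue
        return events

    def fit_segment(self, segment: RuptureSegment) -> RuptureEvent:
        x, f = segment.x, segment.f
        if x.size < 10:
            raise FitError("segment too short for WLC fit", {"n": int(x.size)})
        if np.ptp(f) < 1e-9 or np.max(f) <= 0:
            raise FitError("degenerate (flat) segment", {"curve_id": segment.curve_id})
        kbt_val = kbt(self.temperature)
        x_max = max(np.max(x), segment.x_rupture)
        lc_lo, lc_hi = x_max * 1.001, x_max * self.max_lc_factor

        if self.fix_lp is not None:
            def model(xv, lc):
                return _wlc_f(xv, self.fix_lp, lc, kbt_val)
            p0, bounds = [x_max / 0.9], ([lc_lo], [lc_hi])
        else:
            def model(xv, lp, lc):
                return _wlc_f(xv, lp, lc, kbt_val)
            lp0 = min(max(0.4, self.lp_bounds[0]), self.lp_bounds[1])
            p0 = [lp0, x_max / 0.9]
            bounds = ([self.lp_bounds[0], lc_lo], [self.lp_bounds[1], lc_hi])

        try:
            popt, _ = curve_fit(model, x, f, p0=p0, bounds=bounds, maxfev=10000)
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"WLC fit failed: {exc}", {"curve_id": segment.curve_id})
        if self.fix_lp is not None:
            lp, lc = self.fix_lp, popt[0]
        else:
            lp, lc = popt
        params = WLCParams(Lp=float(lp), Lc=float(lc), temperature=self.temperature)
        rss = float(np.sum((model(x, *popt) - f) ** 2))
        fr = float(wlc_force(min(segment.x_rupture, lc * (1 - 1e-9)), params))
        if fr <= 0:
            raise FitError("non-positive fitted rupture force",
                           {"curve_id": segment.curve_id})
        return RuptureEvent(Fr=fr, x_rupture=segment.x_rupture, params=params,
                            rss=rss, curve_id=segment.curve_id)


class SpecificFilter(BaseEstimator, TransformerMixin):
    """Keep events whose contour length falls in the expected tether window
    and whose rupture force exceeds the instrument noise floor."""

    def __init__(self, lc_window=(23.0, 43.0), noise_floor_pn=20.0):
        self.lc_window = lc_window
        self.noise_floor_pn = noise_floor_pn

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        lo, hi = self.lc_window
        kept = [ev for ev in X if lo <= ev.Lc <= hi and ev.Fr > self.noise_floor_pn]
        self.n_kept_ = len(kept)
        self.n_rejected_ = len(X) - len(kept)
        return kept


class GaussianHistogramFit(BaseEstimator):
    """Least-squares Gaussian fit to a histogram of scalar values.

    Follows the field's convention of fitting the binned force histogram
    rather than the raw sample: bin with Freedman-Diaconis width by default
    (``bin_width`` overrides), then fit A*exp(-(v-mu)^2/(2 sd^2)) to bin
    counts.  Fitted attributes: ``mean_``, ``sd_``, ``n_``, ``bin_width_``,
    ``rss_``.
    """

    def __init__(self, bin_width=None):
        self.bin_width = bin_width

    def fit(self, values, y=None):
        values = np.asarray(values, dtype=float)
        if values.size < 20:
            raise FitError(f"need >= 20 values, got {values.size}")
        if self.bin_width is None:
            edges = np.histogram_bin_edges(values, bins="fd")
            if edges.size < 2 or edges[1] - edges[0] <= 0:
                raise FitError("degenerate histogram (zero spread)")
        else:
            lo, hi = values.min(), values.max() + self.bin_width
            edges = np.arange(lo, hi + self.bin_width, self.bin_width)
        counts, edges = np.histogram(values, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        populated = counts > 0
        if populated.sum() < 3:
            raise FitError("fewer than 3 populated bins",
                           {"populated": int(populated.sum())})

        def gauss(v, a, mu, sd):
            return a * np.exp(-0.5 * ((v - mu) / sd) ** 2)

        p0 = [counts.max(), float(np.mean(values)), float(np.std(values) + 1e-12)]
        try:
            popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"Gaussian histogram fit failed: {exc}")
        self.mean_ = float(popt[1])
        self.sd_ = float(abs(popt[2]))
        self.n_ = int(values.size)
        self.bin_width_ = float(edges[1] - edges[0])
        self.rss_ = float(np.sum((gauss(centers, *popt) - counts) ** 2))
        return self

    def result_(self) -> GaussianFitResult:
        return GaussianFitResult(mean=self.mean_, sd=self.sd_, n=self.n_,
                                 bin_width=self.bin_width_, rss=self.rss_)


# ---------------------------------------------------------------------------
# functional wrappers and pipeline helpers
# ---------------------------------------------------------------------------

def detect_rupture(curve: ForceDistanceCurve, **opts) -> RuptureSegment | None:
    """Detect the specific unbinding drop in one curve (None = non-event)."""
    return RuptureDetector(**opts).detect(curve)


def fit_wlc(segment: RuptureSegment, temperature=ROOM_TEMPERATURE_K, **opts) -> RuptureEvent:
    """Fit the WLC model to one rupture segment."""
    return WLCFitter(temperature=temperature, **opts).fit_segment(segment)


def filter_specific(events, lc_window=(23.0, 43.0), noise_floor_pn=20.0):
    """Keep events with Lc in ``lc_window`` and Fr above ``noise_floor_pn``."""
    return SpecificFilter(lc_window=lc_window, noise_floor_pn=noise_floor_pn).transform(events)


def fit_gaussian_hist(values, bin_width=None) -> GaussianFitResult:
    """Gaussian least-squares fit to the histogram of ``values``."""
    return GaussianHistogramFit(bin_width=bin_width).fit(values).result_()


def aggregate_replicates(results) -> tuple[float, float]:
    """Mean and sample SD of replicate Gaussian-fit means (>= 2 replicates)."""
    means = [r.mean if isinstance(r, GaussianFitResult) else float(r) for r in results]
    if len(means) < 2:
        raise AnalysisError(f"need >= 2 replicates, got {len(means)}")
    return float(np.mean(means)), float(np.std(means, ddof=1))


def ks_compare(group_a, group_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (D statistic, p-value)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 20 or b.size < 20:
        raise AnalysisError("both groups need >= 20 values for the KS comparison")
    res = ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def analyze_curves(curves, lc_window=(23.0, 43.0), noise_floor_pn=20.0,
                   temperature=ROOM_TEMPERATURE_K, detector_opts=None,
                   fitter_opts=None) -> dict:
    """Run the full pipeline: detect -> WLC fit -> Lc filter -> Gaussian stats.

    Returns a dict with the kept events, yield, and Gaussian fits of the
    force and contour-length histograms (None where a fit is impossible).
    """
    detector = RuptureDetector(**(detector_opts or {}))
    fitter = WLCFitter(temperature=temperature, **(fitter_opts or {}))
    filt = SpecificFilter(lc_window=lc_window, noise_floor_pn=noise_floor_pn)

    segments = detector.transform(curves)
    events = fitter.transform(segments)
    kept = filt.transform(events)

    def _maybe_gauss(vals):
        try:
            return fit_gaussian_hist(vals)
        except FitError:
            return None

    n_curves = len(curves) if hasattr(curves, "__len__") else sum(1 for _ in curves)
    return {
        "events": kept,
        "n_curves": n_curves,
        "n_detected": len(segments),
        "n_fitted": len(events),
        "n_specific": len(kept),
        "yield": len(kept) / max(n_curves, 1),
        "force_fit": _maybe_gauss([ev.Fr for ev in kept]),
        "lc_fit": _maybe_gauss([ev.Lc for ev in kept]),
    }


def events_to_frame(events) -> pd.DataFrame:
    """Tabulate rupture events (one row per event)."""
    return pd.DataFrame(
        [{"curve_id": ev.curve_id, "Fr_pN": ev.Fr, "Lc_nm": ev.Lc,
          "Lp_nm": ev.Lp, "x_rupture_nm": ev.x_rupture, "rss": ev.rss}
         for ev in events]
    )
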