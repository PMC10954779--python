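"""Time-density curves and gamma-variate perfusion modelling.

In digital subtraction angiography (DSA) a contrast bolus transits the
vasculature while a cine sequence is acquired. Contrast *darkens* the image,
so the contrast density at a pixel is ``baseline - intensity``. The
time-density curve (TDC) of a pixel is classically described by a gamma
variate,

    C(t) = K (t - t0)^alpha exp(-(t - t0) / beta),   t > t0,

which this module fits in its peak-referenced ("simplified") form

    y(t) = ymax * u^alpha * exp(alpha (1 - u)),   u = (t - t0) / (tmax - t0),

with y = 0 for t <= t0. The simplified form is linear in (log ymax, alpha)
after taking logs, which makes the fit a 1-D search over the arrival time t0
with a closed-form inner regression.

Five perfusion parameters are derived from the fitted curve:

* MAX — peak contrast density ``ymax`` (a.u.)
* TTP — time to peak ``tmax``, measured from the start of the sequence (s)
* CBV — area under the fitted curve (a.u.·s)
* MTT — first moment of the fitted curve about ``t0`` (s)
* CBF — CBV / MTT (a.u./s), the central-volume relation

No arterial-input-function deconvolution is performed; all quantities are
relative (arbitrary contrast units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special

__all__ = [
    "FrameSequence",
    "TimeDensityCurve",
    "TDCFitConfig",
    "GammaVariateFit",
    "PerfusionParams",
    "extract_tdc",
    "fit_gamma_variate",
    "compute_perfusion_params",
    "gamma_variate",
    "gamma_variate_area",
]


def gamma_variate(t, K, t0, alpha, beta):
    """Standard-form gamma variate ``K (t-t0)^alpha exp(-(t-t0)/beta)``."""
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - t0, 0.0, None)
    with np.errstate(invalid="ignore"):
        out = K * dt**alpha * np.exp(-dt / beta)
    return np.where(t > t0, out, 0.0)


def gamma_variate_area(K: float, alpha: float, beta: float) -> float:
    """Closed-form area under the standard gamma variate: K β^{α+1} Γ(α+1)."""
    return K * beta ** (alpha + 1.0) * special.gamma(alpha + 1.0)


@dataclass(frozen=True)
class FrameSequence:
    """A time-ordered stack of 2D grayscale frames.

    Parameters
    ----------
    data : ndarray, shape (n_frames, rows, cols)
        Raw intensities; contrast reduces intensity (DSA convention).
    cine_rate_fps : float
        Acquisition rate; frame k is at ``t = k / cine_rate_fps`` seconds.
    pixel_spacing_mm : float
        Isotropic in-plane pixel spacing.
    """

    data: np.ndarray
    cine_rate_fps: float = 4.0
    pixel_spacing_mm: float = 0.154

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("frame data must be (n_frames, rows, cols)")
        if self.cine_rate_fps <= 0:
            raise ValueError("cine_rate_fps must be positive")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.cine_rate_fps


@dataclass(frozen=True)
class TimeDensityCurve:
    """Contrast density versus time at a single pixel."""

    t: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if t.ndim != 1 or t.shape != d.shape:
            raise ValueError("t and d must be 1-D arrays of equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "d", d)


@dataclass(frozen=True)
class TDCFitConfig:
    """Tunables of TDC extraction and gamma-variate fitting.

    baseline_frames
        Number of leading pre-contrast frames averaged for the baseline.
    peak_fraction
        Only samples with density > peak_fraction * peak enter the
        log-linear regression (low-density samples have unstable logs).
    noise_floor_k
        A curve whose peak is below ``noise_floor_k`` robust noise SDs is
        declared bolus-free (fit invalid).
    t0_grid_step_s
        Step of the 1-D arrival-time grid search, in seconds.
    """

    baseline_frames: int = 2
    peak_fraction: float = 0.1
    noise_floor_k: float = 3.0
    t0_grid_step_s: float = 0.05


@dataclass(frozen=True)
class GammaVariateFit:
    """Peak-referenced gamma-variate fit of one TDC."""

    ymax: float
    t0: float
    tmax: float
    alpha: float
    r2: float
    valid: bool
    reason: str = ""

    @property
    def beta(self) -> float:
        """Standard-form scale parameter, (tmax - t0) / alpha."""
        return (self.tmax - self.t0) / self.alpha

    @property
    def K(self) -> float:
        """Standard-form amplitude, ymax e^alpha / (tmax - t0)^alpha."""
        return self.ymax * math.exp(self.alpha) / (self.tmax - self.t0) ** self.alpha

    def __call__(self, t):
        """Evaluate the fitted curve at times ``t``."""
        t = np.asarray(t, dtype=float)
        u = (t - self.t0) / (self.tmax - self.t0)
        with np.errstate(invalid="ignore", divide="ignore"):
            y = self.ymax * u**self.alpha * np.exp(self.alpha * (1.0 - u))
        return np.where(u > 0, y, 0.0)


@dataclass(frozen=True)
class PerfusionParams:
    """The five per-pixel perfusion parameters."""

    cbf: float
    cbv: float
    mtt: float
    ttp: float
    max: float
    valid: bool = True

    def as_dict(self) -> dict[str, float]:
        return {"CBF": self.cbf, "CBV": self.cbv, "MTT": self.mtt,
                "TTP": self.ttp, "MAX": self.max}

    @classmethod
    def invalid(cls) -> "PerfusionParams":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, valid=False)


def extract_tdc(frames: FrameSequence, pixel: tuple[int, int],
                baseline_frames: int = 2) -> TimeDensityCurve:
    """Extract the time-density curve of one pixel.

    The baseline is the mean of the first ``baseline_frames`` (pre-contrast)
    frames; density is ``baseline - intensity`` clipped at zero.
    """
    r, c = pixel
    rows, cols = frames.frame_shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise IndexError(f"pixel {pixel} outside frame shape {(rows, cols)}")
    b = max(1, int(baseline_frames))
    series = frames.data[:, r, c]
    baseline = series[:b].mean()
    d = np.clip(baseline - series, 0.0, None)
    return TimeDensityCurve(frames.times, d)


def _robust_noise_sd(d: np.ndarray) -> float:
    """Robust noise SD from successive differences (1.4826 MAD / sqrt 2).

    Zero differences are excluded: densities are clipped at zero, so runs
    of clipped samples would drag the MAD toward zero and mask pure noise.
    """
    if len(d) < 3:
        return 0.0
    diffs = np.abs(np.diff(d))
    diffs = diffs[diffs > 0]
    if len(diffs) == 0:
        return 0.0
    return 1.4826 * float(np.median(diffs)) / math.sqrt(2.0)


def _linearized_fit(t, d, lnd, fit_ok, t0s, tmax, peak):
    """Inner log-linear regression for a batch of t0 candidates.

    For each candidate t0 the simplified form gives
    ``ln y = ln ymax + alpha * (ln u + 1 - u)``; alpha and ln ymax follow
    from weighted least squares over samples above the peak-fraction
    threshold. Returns (rss, alpha, lny0) per candidate; the residual sum
    of squares is evaluated against the *raw* curve at all samples.
    """
    t0s = np.atleast_1d(np.asarray(t0s, dtype=float))
    denom = tmax - t0s  # (m,)
    u = (t[None, :] - t0s[:, None]) / denom[:, None]  # (m, n)
    pos = u > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        lnu = np.where(pos, np.log(np.where(pos, u, 1.0)), 0.0)
    z = lnu + 1.0 - u  # regressor
    w = (pos & fit_ok[None, :]).astype(float)

    sw = w.sum(axis=1)
    sz = (w * z).sum(axis=1)
    szz = (w * z * z).sum(axis=1)
    sy = (w * lnd[None, :]).sum(axis=1)
    szy = (w * z * lnd[None, :]).sum(axis=1)
    det = sw * szz - sz * sz
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = (sw * szy - sz * sy) / det
        lny0 = (sy - alpha * sz) / np.where(sw > 0, sw, 1.0)

    bad = (sw < 3) | ~np.isfinite(alpha) | (alpha <= 0) | ~np.isfinite(lny0)
    alpha = np.where(bad, 1.0, alpha)
    lny0 = np.where(bad, 0.0, lny0)

    with np.errstate(invalid="ignore", over="ignore"):
        yhat = np.where(pos, np.exp(lny0[:, None] + alpha[:, None] * z), 0.0)
    rss = ((yhat - d[None, :]) ** 2).sum(axis=1)
    rss = np.where(bad | ~np.isfinite(rss), np.inf, rss)
    return rss, alpha, lny0


def fit_gamma_variate(tdc: TimeDensityCurve,
                      config: TDCFitConfig | None = None) -> GammaVariateFit:
    """Fit the simplified gamma variate to one time-density curve.

    ``ymax`` and ``tmax`` are initialized at the raw peak; alpha and the
    amplitude come from the log-linearized least squares; the arrival time
    ``t0`` is found by a 1-D grid search (with parabolic refinement)
    minimizing the residual sum of squares on the raw curve.
    """
    config = config or TDCFitConfig()
    t, d = tdc.t, tdc.d
    if len(t) < 6:
        raise ValueError("need at least 6 samples to fit a gamma variate")

    p = int(np.argmax(d))
    ymax0 = float(d[p])
    tmax = float(t[p])
    sd = _robust_noise_sd(d)
    if np.mean(d == 0) >= 0.3:
        # Heavily zero-clipped curve: the difference-MAD of half-clipped
        # Gaussian noise underestimates sigma by a factor 0.654.
        sd /= 0.654
    floor = config.noise_floor_k * sd
    if ymax0 <= max(floor, 1e-12):
        return GammaVariateFit(0.0, 0.0, 0.0, 0.0, 0.0, False, "no bolus detected")

    step = config.t0_grid_step_s
    fit_ok = d > config.peak_fraction * ymax0
    lnd = np.where(fit_ok, np.log(np.where(fit_ok, d, 1.0)), 0.0)
    t0s = np.arange(t[0], tmax - step + 1e-12, step)
    if len(t0s) == 0:
        return GammaVariateFit(0.0, 0.0, 0.0, 0.0, 0.0, False,
                               "peak too early for t0 search")

    rss, alpha, lny0 = _linearized_fit(t, d, lnd, fit_ok, t0s, tmax, ymax0)
    i = int(np.argmin(rss))
    if not np.isfinite(rss[i]):
        return GammaVariateFit(0.0, 0.0, 0.0, 0.0, 0.0, False,
                               "t0 search did not converge")
    best = (rss[i], float(t0s[i]), float(alpha[i]), float(lny0[i]))

    # Parabolic refinement between grid points (skipped at an exact minimum).
    if 0 < i < len(t0s) - 1 and rss[i] > 0:
        r0, r1, r2_ = rss[i - 1], rss[i], rss[i + 1]
        den = r0 - 2 * r1 + r2_
        if np.isfinite(r0) and np.isfinite(r2_) and den > 0:
            t0_ref = t0s[i] + 0.5 * step * (r0 - r2_) / den
            t0_ref = float(np.clip(t0_ref, t0s[0], tmax - step))
            rr, aa, ll = _linearized_fit(t, d, lnd, fit_ok, [t0_ref], tmax, ymax0)
            if np.isfinite(rr[0]) and rr[0] < best[0]:
                best = (rr[0], t0_ref, float(aa[0]), float(ll[0]))

    rss_b, t0_b, alpha_b, lny0_b = best
    ymax = float(np.exp(lny0_b))
    # Amplitude refit on the raw scale: the log-space intercept underweights
    # the peak, so rescale by linear least squares against the unit-amplitude
    # basis (never increases the residual).
    u = (t - t0_b) / (tmax - t0_b)
    pos = u > 0
    with np.errstate(invalid="ignore"):
        g = np.where(pos, np.where(pos, u, 1.0) ** alpha_b
                     * np.exp(alpha_b * (1.0 - u)), 0.0)
    gg = float((g * g).sum())
    if gg > 0:
        scale = float((g * d).sum()) / gg
        if scale > 0:
            rss_scaled = float(((scale * g - d) ** 2).sum())
            if rss_scaled <= rss_b:
                ymax, rss_b = scale, rss_scaled
    tss = float(((d - d.mean()) ** 2).sum())
    r2 = 1.0 - rss_b / tss if tss > 0 else 0.0
    r2 = float(min(1.0, max(0.0, r2)))
    return GammaVariateFit(ymax, t0_b, tmax, alpha_b, r2, True)


def compute_perfusion_params(fit: GammaVariateFit,
                             config: TDCFitConfig | None = None) -> PerfusionParams:
    """Derive the five perfusion parameters from a fitted curve.

    CBV and MTT are computed by adaptive quadrature on the fitted form;
    CBF = CBV / MTT (central-volume relation, so CBF·MTT == CBV exactly).
    An invalid fit yields all-NaN parameters flagged invalid.
    """
    if not fit.valid:
        return PerfusionParams.invalid()
    ymax, t0, tmax, alpha = fit.ymax, fit.t0, fit.tmax, fit.alpha
    span = tmax - t0

    def _y(s: float) -> float:  # scalar fast path for quadpack
        u = (s - t0) / span
        return ymax * u**alpha * math.exp(alpha * (1.0 - u)) if u > 0 else 0.0

    # Integrate over [t0, t0 + many decay scales]; the gamma variate decays
    # as exp(-t/beta), so 50 beta past the peak is far below quadrature tol.
    upper = fit.tmax + 50.0 * fit.beta
    cbv, _ = integrate.quad(_y, fit.t0, upper, limit=200)
    moment, _ = integrate.quad(lambda s: (s - t0) * _y(s), fit.t0, upper,
                               limit=200)
    if cbv <= 0:
        return PerfusionParams.invalid()
    mtt = moment / cbv
    cbf = cbv / mtt
    return PerfusionParams(cbf=cbf, cbv=cbv, mtt=mtt, ttp=fit.tmax,
                           max=fit.ymax, valid=True)
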