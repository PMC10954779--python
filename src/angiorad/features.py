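"""Self-contained 2D radiomics feature bank (1,459 features per case).

For each of the five perfusion maps, 58 features (18 first-order, 24 GLCM,
16 GLRLM) are computed on the original map and on each of the four
single-level wavelet sub-bands (LL, LH, HL, HH), giving 290 per map; nine
2D shape features of the ROI are added once (attached to the TTP map),
for 5 x 290 + 9 = 1,459 named features per case.

Feature definitions follow the standard image-biomarker conventions:
gray levels are discretized with a fixed bin width referenced to the ROI
minimum; co-occurrence matrices are symmetric, distance-1, computed at the
four 2D angles and features averaged over angles; run-length matrices are
computed for the four 2D directions (masked-out pixels break runs) and
averaged; shape axis lengths are 4*sqrt(eigenvalues) of the masked
pixel-coordinate covariance in physical units.

Feature names follow the grammar ``<MAP><imagetype>_<class>_<FeatureName>``,
e.g. ``MAXwavelet.LH_firstorder_Energy`` or
``TTPoriginal_shape2D_MinorAxisLength``.

Degenerate inputs (single gray level, single-pixel masks) use documented
conventions — Correlation 1, Imc1/Imc2 0, MCC 1, skewness/kurtosis 0, axis
lengths 0 — and are logged, never silently NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.spatial.distance import pdist

from .maps import MAP_NAMES, ParameterMapSet

__all__ = [
    "FIRSTORDER_NAMES", "GLCM_NAMES", "GLRLM_NAMES", "SHAPE2D_NAMES",
    "IMAGE_TYPES", "FeatureConfig", "DiscretizedImage", "discretize",
    "firstorder_features", "glcm_features", "glrlm_features",
    "shape2d_features", "wavelet_subbands", "extract_all", "feature_names",
]

logger = logging.getLogger(__name__)

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)
GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)
SHAPE2D_NAMES = (
    "MeshSurface", "PixelSurface", "Perimeter", "PerimeterSurfaceRatio",
    "Sphericity", "MaximumDiameter", "MajorAxisLength", "MinorAxisLength",
    "Elongation",
)
IMAGE_TYPES = ("original", "wavelet.LL", "wavelet.LH", "wavelet.HL",
               "wavelet.HH")
_CLASSES = (("firstorder", FIRSTORDER_NAMES), ("glcm", GLCM_NAMES),
            ("glrlm", GLRLM_NAMES))

# GLCM angles / GLRLM directions as (row, col) offsets: 0, 45, 90, 135 deg.
_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction tunables.

    ``bin_widths`` maps each perfusion map to its discretization width in
    raw units; perfusion maps live on heterogeneous scales (a.u. for
    CBF/CBV/MAX, seconds for MTT/TTP), so widths are per map. The wavelet
    is an orthogonal Coiflet-1 with periodized single-level decimation, so
    sub-bands align exactly with the majority-rule 2x-downsampled ROI mask.
    """

    bin_widths: dict[str, float] = field(default_factory=lambda: {
        "CBF": 25.0, "CBV": 25.0, "MTT": 0.25, "TTP": 0.25, "MAX": 25.0})
    wavelet: str = "coif1"
    wavelet_mode: str = "periodization"


@dataclass(frozen=True)
class DiscretizedImage:
    """Integer gray levels 1..Ng over a mask (0 outside the mask)."""

    levels: np.ndarray
    mask: np.ndarray
    ng: int
    bin_width: float

    def __post_init__(self):
        if self.ng < 1:
            raise ValueError("Ng must be >= 1")


def discretize(image: np.ndarray, mask: np.ndarray,
               bin_width: float) -> DiscretizedImage:
    """Fixed-bin-width discretization referenced to the masked minimum.

    level = floor((x - min) / bin_width) + 1; a constant image maps to
    all-ones with Ng = 1. Translation of the raw values leaves levels
    unchanged.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(image, dtype=float)[mask]
    lev = np.zeros(mask.shape, dtype=np.int64)
    lev[mask] = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    return DiscretizedImage(lev, mask, int(lev.max()), bin_width)


# ---------------------------------------------------------------------------
# First-order
# ---------------------------------------------------------------------------

def firstorder_features(values: np.ndarray, spacing_mm: float = 1.0,
                        bin_width: float = 25.0) -> dict[str, float]:
    """The 18 first-order statistics of the masked values.

    Energy is the raw sum of squares; TotalEnergy scales it by the physical
    pixel area. Entropy and Uniformity are computed on the fixed-bin-width
    histogram. Skewness and kurtosis use population moments (kurtosis is
    not excess-corrected); a degenerate distribution yields 0 for both.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty value set")
    n = x.size
    mean = x.mean()
    var = float(np.var(x))  # population variance
    energy = float(np.sum(x * x))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    # Histogram probabilities on the discretization grid
    lev = np.floor((x - x.min()) / bin_width).astype(np.int64)
    p = np.bincount(lev).astype(float) / n
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p * p).sum())

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if var > 0:
        m = x - mean
        skew = float(np.mean(m**3) / var**1.5)
        kurt = float(np.mean(m**4) / var**2)
    else:
        skew = kurt = 0.0
        if n > 1:
            logger.debug("degenerate first-order distribution (zero variance)")
    if n == 1:
        logger.debug("single-pixel mask: Skewness/Kurtosis set to 0")

    return {
        "Energy": energy,
        "TotalEnergy": float(spacing_mm**2 * energy),
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_matrix(disc: DiscretizedImage, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric, normalized distance-1 co-occurrence matrix for one angle."""
    lev = disc.levels
    dr, dc = offset
    rows, cols = lev.shape
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    a = lev[r0:r1, c0:c1]
    b = lev[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    ok = (a > 0) & (b > 0)
    ng = disc.ng
    counts = np.bincount((a[ok] - 1) * ng + (b[ok] - 1),
                         minlength=ng * ng).reshape(ng, ng).astype(float)
    counts = counts + counts.T  # symmetric
    total = counts.sum()
    return counts / total if total > 0 else counts


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    """The 24 co-occurrence features of one normalized symmetric GLCM."""
    ng_full = P.shape[0]
    px_full = P.sum(axis=1)
    present = px_full > 0
    P = P[np.ix_(present, present)]
    ivals = np.nonzero(present)[0] + 1.0  # actual gray values of kept rows
    ng = len(ivals)
    px = P.sum(axis=1)

    I = ivals[:, None] * np.ones((1, ng))
    J = I.T
    mu = float((ivals * px).sum())
    sigma2 = float(((ivals - mu) ** 2 * px).sum())

    eps = np.finfo(float).tiny
    logP = np.log2(np.where(P > 0, P, 1.0))

    diff = np.abs(I - J)
    ksum = I + J
    # p_{x-y} and p_{x+y} distributions over observed values
    dvals = np.unique(diff)
    pdiff = np.array([P[diff == k].sum() for k in dvals])
    svals = np.unique(ksum)
    psum = np.array([P[ksum == k].sum() for k in svals])

    da = float((dvals * pdiff).sum())
    contrast = float((diff**2 * P).sum())
    autocorr = float((I * J * P).sum())
    joint_entropy = float(-(P * logP).sum())

    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    pxy = px[:, None] * px[None, :]
    hxy1 = float(-(P * np.log2(np.where(pxy > 0, pxy, 1.0))).sum())
    pos = pxy > 0
    hxy2 = float(-(pxy[pos] * np.log2(pxy[pos])).sum())

    if ng > 1 and sigma2 > 0:
        correlation = (autocorr - mu * mu) / sigma2
    else:
        correlation = 1.0
    if hx > 0:
        imc1 = (joint_entropy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - joint_entropy)))) \
        if ng > 1 else 0.0

    if ng > 1:
        B = P / px[:, None]
        C = P / px[None, :]
        Q = B @ C.T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = math.sqrt(max(0.0, min(1.0, ev[1]))) if len(ev) > 1 else 1.0
    else:
        mcc = 1.0

    offdiag = diff > 0
    inv_var = float((P[offdiag] / diff[offdiag] ** 2).sum()) if offdiag.any() else 0.0

    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu,
        "ClusterProminence": float(((I + J - 2 * mu) ** 4 * P).sum()),
        "ClusterShade": float(((I + J - 2 * mu) ** 3 * P).sum()),
        "ClusterTendency": float(((I + J - 2 * mu) ** 2 * P).sum()),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(pdiff[pdiff > 0]
                                     * np.log2(pdiff[pdiff > 0])).sum()),
        "DifferenceVariance": float(((dvals - da) ** 2 * pdiff).sum()),
        "JointEnergy": float((P * P).sum()),
        "JointEntropy": joint_entropy,
        "Imc1": float(imc1),
        "Imc2": float(imc2),
        "Idm": float((P / (1.0 + diff**2)).sum()),
        "Idmn": float((P / (1.0 + (diff / ng_full) ** 2)).sum()),
        "Id": float((P / (1.0 + diff)).sum()),
        "Idn": float((P / (1.0 + diff / ng_full)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((svals * psum).sum()),
        "SumEntropy": float(-(psum[psum > 0] * np.log2(psum[psum > 0])).sum()),
        "SumSquares": sigma2,
        "MCC": float(mcc),
    }


def glcm_features(disc: DiscretizedImage) -> dict[str, float]:
    """24 co-occurrence features, averaged over the four 2D angles."""
    per_angle = []
    for off in _OFFSETS:
        P = _glcm_matrix(disc, off)
        if P.sum() > 0:
            per_angle.append(_glcm_features_single(P))
    if not per_angle:
        logger.debug("no co-occurring pixel pairs; degenerate GLCM conventions")
        d = _glcm_features_single(np.ones((1, 1)))
        return d
    return {k: float(np.mean([d[k] for d in per_angle])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _lines(lev: np.ndarray, offset: tuple[int, int]) -> list[np.ndarray]:
    """Scan lines of the level image along one direction."""
    if offset == (0, 1):
        return [lev[r] for r in range(lev.shape[0])]
    if offset == (-1, 0):
        return [lev[:, c] for c in range(lev.shape[1])]
    if offset == (-1, 1):  # 45 deg: anti-diagonals
        f = np.flipud(lev)
        return [f.diagonal(k) for k in range(-f.shape[0] + 1, f.shape[1])]
    if offset == (-1, -1):  # 135 deg: diagonals
        return [lev.diagonal(k) for k in range(-lev.shape[0] + 1, lev.shape[1])]
    raise ValueError(f"unsupported direction {offset}")


def _glrlm_matrix(disc: DiscretizedImage, offset: tuple[int, int]) -> np.ndarray:
    """Run-length matrix P[i-1, j-1] = #runs of level i, length j.

    Masked-out pixels (level 0) break runs and are not counted.
    """
    lines = _lines(disc.levels, offset)
    # Concatenate all lines with 0 separators, then find runs in one pass.
    seq = np.concatenate([np.concatenate(([0], ln)) for ln in lines] + [[0]])
    change = np.nonzero(np.diff(seq) != 0)[0]
    starts = change + 1
    # run k spans [starts[k], starts[k+1]); last element is the sentinel 0
    lengths = np.diff(np.concatenate((starts, [len(seq)])))
    values = seq[starts]
    keep = values > 0
    values, lengths = values[keep], lengths[keep]
    ng = disc.ng
    maxlen = int(lengths.max()) if len(lengths) else 1
    P = np.zeros((ng, maxlen))
    np.add.at(P, (values - 1, lengths - 1), 1.0)
    return P


def _glrlm_features_single(P: np.ndarray, n_pixels: int) -> dict[str, float]:
    ng, maxlen = P.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, maxlen + 1, dtype=float)[None, :]
    nr = P.sum()
    p = P / nr
    rg = P.sum(axis=1)  # per gray level
    rl = P.sum(axis=0)  # per run length
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    pz = p[p > 0]
    return {
        "ShortRunEmphasis": float((P / j**2).sum() / nr),
        "LongRunEmphasis": float((P * j**2).sum() / nr),
        "GrayLevelNonUniformity": float((rg**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((rg**2).sum() / nr**2),
        "RunLengthNonUniformity": float((rl**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((rl**2).sum() / nr**2),
        "RunPercentage": float(nr / n_pixels),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        "RunVariance": float(((j - mu_j) ** 2 * p).sum()),
        "RunEntropy": float(-(pz * np.log2(pz)).sum()),
        "LowGrayLevelRunEmphasis": float((P / i**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((P * i**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((P / (i**2 * j**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((P * i**2 / j**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((P * j**2 / i**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((P * i**2 * j**2).sum() / nr),
    }


def glrlm_features(disc: DiscretizedImage) -> dict[str, float]:
    """16 run-length features, averaged over the four 2D directions."""
    n_pixels = int(disc.mask.sum())
    per_dir = []
    for off in _OFFSETS:
        P = _glrlm_matrix(disc, off)
        if P.sum() > 0:
            per_dir.append(_glrlm_features_single(P, n_pixels))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# Shape (2D)
# ---------------------------------------------------------------------------

def shape2d_features(mask: np.ndarray, spacing_mm: float = 1.0) -> dict[str, float]:
    """The 9 ROI shape descriptors, in physical units.

    Mesh surface and perimeter come from the marching-squares boundary of
    the mask; axis lengths are 4*sqrt(eigenvalues) of the pixel-coordinate
    covariance. A single-pixel mask yields axis lengths 0 (flagged).
    """
    from skimage import measure

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    npix = int(mask.sum())
    pixel_area = spacing_mm**2

    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    perimeter = 0.0
    signed_area = 0.0
    verts = []
    for cont in contours:
        closed = np.vstack([cont, cont[:1]])
        seg = np.diff(closed, axis=0)
        perimeter += float(np.sqrt((seg**2).sum(axis=1)).sum())
        x, y = closed[:, 0], closed[:, 1]
        signed_area += 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
        verts.append(cont)
    perimeter *= spacing_mm
    mesh_surface = abs(signed_area) * pixel_area

    allv = np.vstack(verts) * spacing_mm
    if len(allv) > 400:
        from scipy.spatial import ConvexHull
        try:
            allv = allv[ConvexHull(allv).vertices]
        except Exception:  # collinear degenerate boundary
            pass
    max_diam = float(pdist(allv).max()) if len(allv) > 1 else 0.0

    coords = np.argwhere(mask) * spacing_mm
    if npix > 1:
        cov = np.cov(coords.T)
        ev = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
        minor, major = 4.0 * np.sqrt(ev[0]), 4.0 * np.sqrt(ev[1])
        elong = math.sqrt(ev[0] / ev[1]) if ev[1] > 0 else 1.0
    else:
        logger.debug("single-pixel mask: axis lengths set to 0")
        major = minor = 0.0
        elong = 1.0

    sphericity = (2.0 * math.sqrt(math.pi * mesh_surface) / perimeter
                  if perimeter > 0 else 1.0)
    return {
        "MeshSurface": mesh_surface,
        "PixelSurface": npix * pixel_area,
        "Perimeter": perimeter,
        "PerimeterSurfaceRatio": perimeter / mesh_surface if mesh_surface else 0.0,
        "Sphericity": sphericity,
        "MaximumDiameter": max_diam,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "Elongation": float(elong),
    }


# ---------------------------------------------------------------------------
# Wavelet
# ---------------------------------------------------------------------------

def wavelet_subbands(image: np.ndarray, wavelet: str = "coif1",
                     mode: str = "periodization") -> dict[str, np.ndarray]:
    """Single-level decimated 2D DWT sub-bands {LL, LH, HL, HH}.

    With an orthogonal wavelet in periodization mode each sub-band has
    ceil(n/2) x ceil(m/2) coefficients and total coefficient energy equals
    image energy (Parseval). ``symmetric`` mode is supported by central
    cropping of the padded sub-bands.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError("image must be 2D with both sides >= 2")
    cA, (cH, cV, cD) = pywt.dwt2(image, wavelet, mode=mode)
    bands = {"LL": cA, "LH": cH, "HL": cV, "HH": cD}
    target = (-(-image.shape[0] // 2), -(-image.shape[1] // 2))
    if cA.shape != target:  # non-periodized modes over-produce coefficients
        o0 = (cA.shape[0] - target[0]) // 2
        o1 = (cA.shape[1] - target[1]) // 2
        bands = {k: v[o0:o0 + target[0], o1:o1 + target[1]]
                 for k, v in bands.items()}
    return bands


def _downsample_mask(mask: np.ndarray) -> np.ndarray:
    """Majority-rule 2x downsampling (>= 2 of each 2x2 block)."""
    r, c = mask.shape
    pr, pc = r + (r % 2), c + (c % 2)
    padded = np.zeros((pr, pc), dtype=int)
    padded[:r, :c] = mask
    blocks = padded.reshape(pr // 2, 2, pc // 2, 2).sum(axis=(1, 3))
    out = blocks >= 2
    if not out.any():
        out = blocks >= 1  # fall back for very thin ROIs
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def feature_names() -> list[str]:
    """The canonical ordered list of the 1,459 feature names."""
    names = []
    for map_name in MAP_NAMES:
        for image_type in IMAGE_TYPES:
            for cls, feats in _CLASSES:
                names += [f"{map_name}{image_type}_{cls}_{f}" for f in feats]
    names += [f"TTPoriginal_shape2D_{f}" for f in SHAPE2D_NAMES]
    return names


def _bbox(mask: np.ndarray) -> tuple[slice, slice]:
    rr, cc = np.nonzero(mask)
    return slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1)


def _restrict(disc: DiscretizedImage, mask: np.ndarray) -> DiscretizedImage:
    """Restrict a discretized image to a sub-mask, keeping level values."""
    lev = np.where(mask, disc.levels, 0)
    return DiscretizedImage(lev, mask, max(int(lev.max()), 1), disc.bin_width)


def extract_all(mapset: ParameterMapSet, mask: np.ndarray,
                config: FeatureConfig | None = None) -> dict[str, float]:
    """Extract the full 1,459-feature vector for one case.

    The effective ROI is ``mask & validity``: pixels with failed fits never
    enter the statistics. The crop, the wavelet decimation grid, and the
    discretization reference are all anchored to the fitted-map region
    (the validity mask) rather than to the rater's contour, so two raters'
    feature vectors for one case differ only through which pixels their
    contours select — not through grid or binning artifacts. In-box pixels
    outside the fitted region are filled with its mean before the wavelet
    transform (they are excluded from every statistic by the sub-band
    mask). Output order is deterministic.
    """
    config = config or FeatureConfig()
    valid = mapset.validity
    mask = np.asarray(mask, dtype=bool) & valid
    if not mask.any():
        raise ValueError("no valid pixels inside the ROI")
    sl = _bbox(valid)
    valid_bb = valid[sl]
    mask_bb = mask[sl]
    valid_half = _downsample_mask(valid_bb)
    mask_half = _downsample_mask(mask_bb) & valid_half
    if not mask_half.any():
        mask_half = valid_half
    spacing = mapset.spacing_mm

    out: dict[str, float] = {}
    for map_name in MAP_NAMES:
        img = mapset.maps[map_name][sl]
        bw = config.bin_widths.get(map_name, 25.0)
        filled = np.where(valid_bb, img, img[valid_bb].mean())

        images = {"original": (filled, valid_bb, mask_bb, spacing)}
        if min(filled.shape) >= 2:
            bands = wavelet_subbands(filled, config.wavelet, config.wavelet_mode)
            for band, arr in bands.items():
                # decimation doubles the physical pixel pitch
                images[f"wavelet.{band}"] = (arr, valid_half, mask_half,
                                             2.0 * spacing)
        else:
            raise ValueError("ROI bounding box too small for the wavelet "
                             "transform (needs >= 2 pixels per side)")

        for image_type in IMAGE_TYPES:
            arr, ref, m, sp = images[image_type]
            v = arr[m]
            disc = _restrict(discretize(arr, ref, bw), m)
            fo = firstorder_features(v, sp, bw)
            gl = glcm_features(disc)
            rl = glrlm_features(disc)
            prefix = f"{map_name}{image_type}"
            for f in FIRSTORDER_NAMES:
                out[f"{prefix}_firstorder_{f}"] = fo[f]
            for f in GLCM_NAMES:
                out[f"{prefix}_glcm_{f}"] = gl[f]
            for f in GLRLM_NAMES:
                out[f"{prefix}_glrlm_{f}"] = rl[f]

    shape = shape2d_features(mask, spacing)
    for f in SHAPE2D_NAMES:
        out[f"TTPoriginal_shape2D_{f}"] = shape[f]
    return out
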