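"""Seeded synthetic DSA cases and cohorts.

Generates bolus-passage cine sequences whose per-pixel time-density curves
follow gamma variates with region-dependent parameters (diffuse tissue
background, a parent-artery band, and an elliptical aneurysm sac), plus two
raters' sac masks with controllable disagreement and a case/control cohort
with covariates suitable for propensity matching.

The rupture-group (PIR) effect is injected as multiplicative changes to the
sac bolus — a higher amplitude (stronger peak contrast, MAX) and a longer
washout scale (contrast retention) — and an enlarged sac minor axis. With
all multipliers at 1 the two groups are exchangeable (null configuration).

Contrast *darkens* the image: frames are ``baseline - sum(region curves)``
plus Gaussian noise. All randomness flows from an integer seed through
``numpy.random.default_rng``; identical (spec, seed) gives identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .perfusion import FrameSequence, gamma_variate

__all__ = [
    "AcquisitionSpec",
    "GammaBolus",
    "BolusModel",
    "CaseSpec",
    "EffectConfig",
    "SyntheticCase",
    "SyntheticCohort",
    "GeometryError",
    "generate_case",
    "generate_cohort",
    "perturb_mask",
    "ellipse_mask",
    "write_case",
    "read_case",
    "read_dicom_sequence",
]

GROUPS = ("PIR", "PIU")
LOCATIONS = ("ICA", "MCA", "VA")
SEXES = ("M", "F")
PED_COUNTS = ("single", "multiple")


class GeometryError(ValueError):
    """Sac geometry does not fit inside the frame."""


@dataclass(frozen=True)
class AcquisitionSpec:
    """Cine acquisition geometry and timing."""

    cine_rate_fps: float = 4.0
    n_frames: int = 32
    rows: int = 128
    cols: int = 128
    pixel_spacing_mm: float = 0.154

    def __post_init__(self):
        if self.cine_rate_fps <= 0:
            raise ValueError("cine_rate_fps must be positive")
        if self.n_frames < 8:
            raise ValueError("need at least 8 frames")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.cine_rate_fps


@dataclass(frozen=True)
class GammaBolus:
    """Gamma-variate bolus parameters for one region."""

    K: float
    t0: float
    alpha: float
    beta: float

    def __post_init__(self):
        if self.K < 0 or self.t0 < 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("require K >= 0, t0 >= 0, alpha > 0, beta > 0")

    def curve(self, t) -> np.ndarray:
        return gamma_variate(t, self.K, self.t0, self.alpha, self.beta)


@dataclass(frozen=True)
class BolusModel:
    """Per-region bolus parameters plus imaging noise and baseline.

    Defaults place the sac peak (``t0 + alpha*beta`` = 2.6 s) well inside a
    32-frame, 4 fps window, with a fast-washout artery and a weak diffuse
    tissue blush; noise_sd ~4% of the sac peak density.
    """

    background: GammaBolus = field(default_factory=lambda: GammaBolus(80.0, 0.9, 2.0, 0.6))
    artery: GammaBolus = field(default_factory=lambda: GammaBolus(400.0, 0.8, 1.5, 0.4))
    sac: GammaBolus = field(default_factory=lambda: GammaBolus(300.0, 1.0, 2.0, 0.8))
    noise_sd: float = 4.0
    baseline_intensity: float = 1000.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class EffectConfig:
    """Multiplicative group effect applied to PIR cases.

    sac_k_mult scales the sac bolus amplitude (higher MAX), sac_beta_mult
    its washout scale (contrast retention), minor_axis_mult the sac minor
    semi-axis (larger aneurysm). All 1.0 = null configuration.
    """

    sac_k_mult: float = 1.6
    sac_beta_mult: float = 1.0
    minor_axis_mult: float = 1.4

    def __post_init__(self):
        if min(self.sac_k_mult, self.sac_beta_mult, self.minor_axis_mult) <= 0:
            raise ValueError("effect multipliers must be positive")

    @property
    def is_null(self) -> bool:
        return (self.sac_k_mult == 1.0 and self.sac_beta_mult == 1.0
                and self.minor_axis_mult == 1.0)

    @classmethod
    def null(cls) -> "EffectConfig":
        return cls(1.0, 1.0, 1.0)


@dataclass(frozen=True)
class CaseSpec:
    """One synthetic subject: covariates, sac geometry, group effect."""

    case_id: str
    group: str
    age: float
    sex: str
    aneurysm_size_mm: float
    location: str
    ped_count: str
    sac_center: tuple[float, float] = (64.0, 64.0)
    sac_semi_axes_px: tuple[float, float] = (12.0, 8.0)  # (major, minor)
    sac_orientation_rad: float = 0.0
    sac_k_mult: float = 1.0
    sac_beta_mult: float = 1.0
    minor_axis_mult: float = 1.0

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.sex not in SEXES or self.location not in LOCATIONS \
                or self.ped_count not in PED_COUNTS:
            raise ValueError("covariate level outside declared sets")
        a, b = self.sac_semi_axes_px
        if not a >= b > 0:
            raise ValueError("semi-axes must satisfy major >= minor > 0")
        if min(self.sac_k_mult, self.sac_beta_mult, self.minor_axis_mult) <= 0:
            raise ValueError("multipliers must be positive")

    @property
    def effective_semi_axes(self) -> tuple[float, float]:
        """Semi-axes after the group effect (minor axis scaled for PIR)."""
        a, b = self.sac_semi_axes_px
        if self.group == "PIR":
            b = min(a, b * self.minor_axis_mult)
        return a, b


@dataclass(frozen=True)
class SyntheticCase:
    """Rendered frames, two raters' masks, and the generating truth."""

    frames: FrameSequence
    mask_rater1: np.ndarray
    mask_rater2: np.ndarray
    spec: CaseSpec
    bolus: BolusModel

    def __post_init__(self):
        if not self.mask_rater1.any() or not self.mask_rater2.any():
            raise ValueError("rater masks must be nonempty")


def ellipse_mask(rows: int, cols: int, center: tuple[float, float],
                 semi_axes: tuple[float, float], orientation: float) -> np.ndarray:
    """Filled rotated ellipse as a boolean mask."""
    rr, cc = np.mgrid[0:rows, 0:cols]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(orientation), np.sin(orientation)
    x = dr * ca + dc * sa
    y = -dr * sa + dc * ca
    a, b = semi_axes
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def perturb_mask(mask: np.ndarray, severity: float, rng: np.random.Generator) -> np.ndarray:
    """Simulate a second rater by dilating/eroding a random boundary arc.

    severity in [0, ~2] controls the angular fraction of the boundary
    touched (one pixel deep per pass); 0 returns the mask unchanged.
    """
    if severity <= 0:
        return mask.copy()
    out = mask.copy()
    com = np.array(ndimage.center_of_mass(mask))
    passes = max(1, int(round(severity)))
    frac = min(0.95, 0.35 * severity / passes)
    for _ in range(passes):
        grow = bool(rng.integers(0, 2))
        if grow:
            shell = ndimage.binary_dilation(out) & ~out
        else:
            shell = out & ~ndimage.binary_erosion(out)
        coords = np.argwhere(shell)
        if len(coords) == 0:
            break
        theta = np.arctan2(coords[:, 0] - com[0], coords[:, 1] - com[1])
        theta0 = rng.uniform(-np.pi, np.pi)
        width = frac * 2 * np.pi
        dtheta = (theta - theta0) % (2 * np.pi)
        sel = coords[dtheta <= width]
        if grow:
            out[sel[:, 0], sel[:, 1]] = True
        else:
            keep = out.sum() - len(sel)
            if keep < 3:  # never erode a mask away entirely
                continue
            out[sel[:, 0], sel[:, 1]] = False
    if not out.any():
        return mask.copy()
    return out


def _artery_mask(acq: AcquisitionSpec, spec: CaseSpec) -> np.ndarray:
    """Parent-artery band tangent to the sac, along the sac orientation."""
    rows, cols = acq.rows, acq.cols
    rr, cc = np.mgrid[0:rows, 0:cols]
    a, b = spec.effective_semi_axes
    th = spec.sac_orientation_rad
    # Offset the band one minor axis + margin from the sac centre, normal
    # to the major axis.
    nr, nc = np.cos(th + np.pi / 2), np.sin(th + np.pi / 2)
    cr = spec.sac_center[0] + nr * (b + 5.0)
    cc0 = spec.sac_center[1] + nc * (b + 5.0)
    dist = np.abs((rr - cr) * nr + (cc - cc0) * nc)
    return dist <= 3.0


def generate_case(spec: CaseSpec, acq: AcquisitionSpec | None = None,
                  bolus: BolusModel | None = None, seed: int = 0,
                  rater_severity: float = 1.0,
                  sac_texture_sd: float = 0.0) -> SyntheticCase:
    """Render one synthetic DSA case.

    Frames are ``baseline - sum(region curves) + N(0, noise_sd)``; region
    curves are gamma variates on the background (whole frame), parent
    artery band, and sac ellipse. PIR multipliers from the spec are applied
    to the sac amplitude, washout scale, and minor axis. The rater-2 mask
    is a boundary-arc perturbation of the rater-1 (exact) sac mask.

    ``sac_texture_sd > 0`` modulates the sac amplitude by a smooth
    log-normal spatial field (median 1), emulating heterogeneous
    intra-aneurysmal filling; at the default 0 every sac pixel follows the
    sac gamma variate exactly.
    """
    acq = acq or AcquisitionSpec()
    bolus = bolus or BolusModel()
    rng = np.random.default_rng(seed)

    sac = bolus.sac
    if spec.group == "PIR":
        sac = replace(sac, K=sac.K * spec.sac_k_mult,
                      beta=sac.beta * spec.sac_beta_mult)
    a, b = spec.effective_semi_axes
    r0, c0 = spec.sac_center
    if not (a <= r0 <= acq.rows - 1 - a and a <= c0 <= acq.cols - 1 - a):
        raise GeometryError(
            f"sac (center {spec.sac_center}, major semi-axis {a:.1f}) "
            f"does not fit in a {acq.rows}x{acq.cols} frame")

    sac_mask = ellipse_mask(acq.rows, acq.cols, (r0, c0), (a, b),
                            spec.sac_orientation_rad)
    artery = _artery_mask(acq, spec) & ~sac_mask
    t = acq.times

    sac_field = sac_mask.astype(float)
    if sac_texture_sd > 0:
        smooth = ndimage.gaussian_filter(
            rng.normal(size=(acq.rows, acq.cols)),
            sigma=3.0 * min(acq.rows, acq.cols) / 128.0)
        smooth *= sac_texture_sd / max(smooth.std(), 1e-12)
        sac_field *= np.exp(smooth - smooth.mean())

    frames = np.full((acq.n_frames, acq.rows, acq.cols),
                     bolus.baseline_intensity, dtype=float)
    frames -= bolus.background.curve(t)[:, None, None]
    frames -= bolus.artery.curve(t)[:, None, None] * artery[None, :, :]
    frames -= sac.curve(t)[:, None, None] * sac_field[None, :, :]
    if bolus.noise_sd > 0:
        frames += rng.normal(0.0, bolus.noise_sd, frames.shape)

    mask2 = perturb_mask(sac_mask, rater_severity, rng)
    seq = FrameSequence(frames, acq.cine_rate_fps, acq.pixel_spacing_mm)
    return SyntheticCase(seq, sac_mask, mask2, spec,
                         replace(bolus, sac=sac))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

# Covariate distributions are typical of flow-diverter cohorts: age
# ~N(53, 8); aneurysm size ~N(group mean, 7.5) with PIR mean 21.6 mm vs
# control 17.1 mm; location and PED-count multinomials near the observed
# frequencies. Under the null configuration both groups share the control
# distributions (exchangeability).
_SIZE_MEAN = {"PIR": 21.6, "PIU": 17.1}
_LOC_P = {"PIR": (0.75, 0.125, 0.125), "PIU": (0.52, 0.125, 0.355)}
_P_MULTIPLE_PED = 0.08


@dataclass(frozen=True)
class SyntheticCohort:
    """Case specs + covariate table; frames rendered lazily per case.

    Each case carries its own jittered bolus (real cohorts are
    heterogeneous in injection and hemodynamics); rendering a case is
    deterministic given its spawned per-case seed.
    """

    case_specs: dict[str, CaseSpec]
    covariates: pd.DataFrame
    acq: AcquisitionSpec
    bolus: BolusModel
    case_seeds: dict[str, int]
    rater_severity: float = 1.0
    case_boluses: dict[str, BolusModel] = field(default_factory=dict)
    sac_texture_sd: float = 0.2

    def render(self, case_id: str) -> SyntheticCase:
        """Render frames + masks for one case (deterministic per case)."""
        bolus = self.case_boluses.get(case_id, self.bolus)
        return generate_case(self.case_specs[case_id], self.acq, bolus,
                             seed=self.case_seeds[case_id],
                             rater_severity=self.rater_severity,
                             sac_texture_sd=self.sac_texture_sd)

    def render_all(self, case_ids=None) -> dict[str, SyntheticCase]:
        ids = list(case_ids) if case_ids is not None else list(self.case_specs)
        return {cid: self.render(cid) for cid in ids}


def _draw_covariates(rng: np.random.Generator, group: str, null: bool) -> dict:
    g = "PIU" if null else group
    age = float(np.clip(rng.normal(53.0, 8.0), 18.0, 85.0))
    size = float(np.clip(rng.normal(_SIZE_MEAN[g], 7.5), 4.0, 45.0))
    sex = SEXES[int(rng.integers(0, 2))]
    location = rng.choice(LOCATIONS, p=_LOC_P[g])
    ped = PED_COUNTS[int(rng.random() < _P_MULTIPLE_PED)]
    return dict(age=age, sex=sex, aneurysm_size_mm=size,
                location=str(location), ped_count=ped)


def generate_cohort(n_pir: int = 16, pool_size: int = 292,
                    effect: EffectConfig | None = None,
                    acq: AcquisitionSpec | None = None,
                    bolus: BolusModel | None = None,
                    seed: int = 0, rater_severity: float = 1.0,
                    min_pool_ratio: int = 3,
                    bolus_jitter_sd: float = 0.15,
                    sac_texture_sd: float = 0.2) -> SyntheticCohort:
    """Generate n_pir rupture cases plus a candidate-control pool.

    Covariates are drawn from overlapping group distributions so propensity
    matching is feasible. Sac geometry (center jitter, axes jitter ±20%,
    random orientation) is independent of the size covariate and scales
    with the frame size; the PIR multipliers come from ``effect``.

    Between-case heterogeneity — without which every case would be a
    statistical clone and rater-agreement ICCs would be meaningless — comes
    from (a) log-normal per-case jitter of the bolus parameters
    (``bolus_jitter_sd`` on amplitudes, half of it on timing/shape) applied
    identically in both groups, and (b) a smooth within-sac amplitude
    texture field (``sac_texture_sd``).
    """
    if pool_size < min_pool_ratio * n_pir:
        raise ValueError(
            f"pool_size must be >= {min_pool_ratio} * n_pir "
            f"({min_pool_ratio * n_pir}), got {pool_size}")
    effect = effect if effect is not None else EffectConfig()
    acq = acq or AcquisitionSpec()
    bolus = bolus or BolusModel()
    rng = np.random.default_rng(seed)
    scale = min(acq.rows, acq.cols) / 128.0

    specs: dict[str, CaseSpec] = {}
    rows = []
    ids = ([f"PIR_{i:03d}" for i in range(n_pir)]
           + [f"CTL_{i:03d}" for i in range(pool_size)])
    for cid in ids:
        group = "PIR" if cid.startswith("PIR") else "PIU"
        cov = _draw_covariates(rng, group, effect.is_null)
        a = 12.0 * scale * rng.uniform(0.8, 1.2)
        b = 8.0 * scale * rng.uniform(0.8, 1.2)
        a, b = max(a, b), min(a, b)
        jit = 0.06 * min(acq.rows, acq.cols)
        center = (acq.rows / 2 + rng.uniform(-jit, jit),
                  acq.cols / 2 + rng.uniform(-jit, jit))
        mults = dict(sac_k_mult=effect.sac_k_mult,
                     sac_beta_mult=effect.sac_beta_mult,
                     minor_axis_mult=effect.minor_axis_mult) \
            if group == "PIR" else {}
        spec = CaseSpec(case_id=cid, group=group, **cov,
                        sac_center=center, sac_semi_axes_px=(a, b),
                        sac_orientation_rad=float(rng.uniform(0, np.pi)),
                        **mults)
        specs[cid] = spec
        rows.append(dict(case_id=cid, group=group, **cov))

    boluses = {}
    if bolus_jitter_sd > 0:
        half = bolus_jitter_sd / 2.0
        for cid in ids:
            def jit(g: GammaBolus) -> GammaBolus:
                return GammaBolus(
                    K=g.K * float(np.exp(rng.normal(0, bolus_jitter_sd))),
                    t0=max(0.5, g.t0 + float(rng.normal(0, half * g.t0))),
                    alpha=g.alpha * float(np.exp(rng.normal(0, half))),
                    beta=g.beta * float(np.exp(rng.normal(0, half))))
            boluses[cid] = replace(bolus, background=jit(bolus.background),
                                   artery=jit(bolus.artery),
                                   sac=jit(bolus.sac))

    seeds = {cid: int(s) for cid, s in
             zip(ids, rng.integers(0, 2**31 - 1, size=len(ids)))}
    table = pd.DataFrame(rows).set_index("case_id")
    return SyntheticCohort(specs, table, acq, bolus, seeds, rater_severity,
                           boluses, sac_texture_sd)


# ---------------------------------------------------------------------------
# Disk round-trip and optional DICOM ingestion
# ---------------------------------------------------------------------------

def write_case(case: SyntheticCase, directory) -> Path:
    """Write one case: frames as NPZ, masks as PNG, sidecar JSON."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "frames.npz", frames=case.frames.data)
    for name, m in (("mask_rater1", case.mask_rater1),
                    ("mask_rater2", case.mask_rater2)):
        Image.fromarray((m.astype(np.uint8)) * 255).save(directory / f"{name}.png")
    sidecar = {"cine_rate_fps": case.frames.cine_rate_fps,
               "pixel_spacing_mm": case.frames.pixel_spacing_mm,
               "case_id": case.spec.case_id, "group": case.spec.group}
    (directory / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def read_case(directory) -> tuple[FrameSequence, np.ndarray, np.ndarray]:
    """Read frames + two rater masks written by :func:`write_case`."""
    from PIL import Image

    directory = Path(directory)
    sidecar = json.loads((directory / "sidecar.json").read_text())
    with np.load(directory / "frames.npz") as z:
        frames = z["frames"]
    seq = FrameSequence(frames, sidecar["cine_rate_fps"],
                        sidecar["pixel_spacing_mm"])
    m1 = np.asarray(Image.open(directory / "mask_rater1.png")) > 0
    m2 = np.asarray(Image.open(directory / "mask_rater2.png")) > 0
    return seq, m1, m2


def read_dicom_sequence(path) -> FrameSequence:
    """Ingest a real multi-frame DICOM cine with the same downstream contract."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    data = ds.pixel_array.astype(float)
    if data.ndim != 3:
        raise ValueError("expected a multi-frame (cine) DICOM")
    rate = float(getattr(ds, "CineRate", 0) or 0)
    if rate <= 0 and getattr(ds, "FrameTime", None):
        rate = 1000.0 / float(ds.FrameTime)
    if rate <= 0:
        raise ValueError("DICOM lacks CineRate/FrameTime")
    spacing = getattr(ds, "PixelSpacing", None) or getattr(
        ds, "ImagerPixelSpacing", None)
    if spacing is None:
        raise ValueError("DICOM lacks pixel spacing")
    return FrameSequence(data, rate, float(spacing[0]))
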