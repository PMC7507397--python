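"""Preprocessing chain for raw optical recordings.

Steps, in the order the pipeline applies them: channel quality screening on
raw intensity (mean/SD ratio below 2 marks a channel missing), conversion
to optical density, moving-window motion-artifact detection with
cubic-spline correction, and the modified Beer-Lambert inversion to
hemoglobin concentration changes.

No band-pass filtering is applied anywhere in this module; the wavelet
analysis downstream operates on the unfiltered concentration series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from . import constants
from .errors import ConfigError, StageError, ValidationError
from .signal_synthesis import HyperscanRecording

__all__ = [
    "ChannelQuality",
    "BeerLambertConstants",
    "ArtifactParams",
    "reject_low_snr",
    "intensity_to_od",
    "detect_motion_artifacts",
    "correct_motion",
    "od_to_hb",
]

_EPS_SD = 1e-12


@dataclass(frozen=True)
class ChannelQuality:
    participant: int
    channel: int  # 1-based
    snr_ratio: float
    rejected: bool


@dataclass(frozen=True)
class BeerLambertConstants:
    extinction: np.ndarray = field(
        default_factory=lambda: constants.EXTINCTION_MM_CM.copy()
    )
    dpf: tuple[float, float] = (
        constants.DIFFERENTIAL_PATHLENGTH_FACTOR,
        constants.DIFFERENTIAL_PATHLENGTH_FACTOR,
    )
    distance: float = constants.SOURCE_DETECTOR_DISTANCE_CM

    def __post_init__(self) -> None:
        eps = np.asarray(self.extinction, dtype=float)
        if eps.shape != (2, 2):
            raise ConfigError("extinction must be a 2x2 (wavelength x chromophore) matrix")
        if abs(np.linalg.det(eps)) < 1e-12:
            raise ConfigError("extinction matrix is singular")
        if any(d <= 0 for d in self.dpf) or self.distance <= 0:
            raise ConfigError("dpf and distance must be positive")


@dataclass(frozen=True)
class ArtifactParams:
    """Detection thresholds.

    ``amp_threshold`` is in multiples of the channel's robust windowed
    excursion (median peak-to-peak over the moving window), which tolerates
    slow physiological drift; ``slope_threshold`` is in multiples of the
    robust first-difference SD per second.
    """

    window: float = 1.0  # seconds
    amp_threshold: float = 8.0  # high enough not to flag large oscillations
    slope_threshold: float = 60.0  # artifacts are far sharper than hemodynamics
    correction: str = "spline"

    def __post_init__(self) -> None:
        if self.window <= 0 or self.amp_threshold <= 0 or self.slope_threshold <= 0:
            raise ValidationError("artifact thresholds must be positive")
        if self.correction not in ("spline", "none"):
            raise ValidationError("correction must be 'spline' or 'none'")


def _robust_sd(x: np.ndarray) -> float:
    """Robust noise SD from first differences (insensitive to drifts and
    baseline shifts): 1.4826 * MAD(diff) / sqrt(2)."""
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def reject_low_snr(
    rec: HyperscanRecording, threshold: float = 2.0
) -> tuple[HyperscanRecording, list[ChannelQuality]]:
    """Screen channels on raw intensity: a channel whose mean/SD ratio (at
    either wavelength) falls below ``threshold`` is marked missing.

    Returns a copy of the recording with updated ``bad_channels`` plus the
    per-channel quality report.
    """
    if rec.stage != "intensity":
        raise StageError("reject_low_snr requires intensity-stage data")
    if not np.all(rec.data > 0):
        raise StageError("intensity data must be strictly positive")
    mean = rec.data.mean(axis=-1)
    sd = rec.data.std(axis=-1)
    # relative epsilon keeps the ratio (and rejection) gain-invariant
    ratio = mean / np.maximum(sd, _EPS_SD * np.abs(mean))
    worst = ratio.min(axis=-1)  # (2, n_ch): worst wavelength decides
    rejected = worst < threshold
    out = rec.copy_with(bad_channels=rec.bad_channels | rejected)
    report = [
        ChannelQuality(
            participant=p,
            channel=c + 1,
            snr_ratio=float(worst[p, c]),
            rejected=bool(rejected[p, c]),
        )
        for p in range(2)
        for c in range(rec.n_channels)
    ]
    return out, report


def intensity_to_od(rec: HyperscanRecording) -> HyperscanRecording:
    """Optical density change ``OD(t) = -ln(I(t) / mean(I))`` per channel
    and wavelength.  Invariant under constant gain changes."""
    if rec.stage != "intensity":
        raise StageError("intensity_to_od requires intensity-stage data")
    if not np.all(rec.data > 0):
        bad = np.argwhere((rec.data <= 0).any(axis=-1))
        raise ValidationError(
            "non-positive intensity on (participant, channel, wavelength) "
            + ", ".join(str(tuple(int(v) for v in b)) for b in bad[:10])
        )
    od = -np.log(rec.data / rec.data.mean(axis=-1, keepdims=True))
    out = rec.copy_with(stage="od", data=od)
    return out


def detect_motion_artifacts(
    rec: HyperscanRecording, params: ArtifactParams | None = None
) -> np.ndarray:
    """Flag motion-contaminated samples in optical-density data.

    A sample is flagged when the peak-to-peak excursion within the moving
    window exceeds ``amp_threshold`` times the channel's median windowed
    excursion, or the instantaneous slope exceeds ``slope_threshold``
    robust first-difference SDs per second; the flag mask is then dilated
    by one window.  Returns a boolean mask (2, n_channels, n_times)
    combined across wavelengths.
    """
    params = params or ArtifactParams()
    if rec.stage != "od":
        raise StageError("detect_motion_artifacts requires od-stage data")
    w = max(int(round(params.window * rec.fs)), 2)
    mask = np.zeros((2, rec.n_channels, rec.n_times), dtype=bool)
    for p in range(2):
        for c in range(rec.n_channels):
            for wl in range(2):
                x = rec.data[p, c, wl]
                rsd = max(_robust_sd(x), _EPS_SD)
                p2p = ndimage.maximum_filter1d(x, w) - ndimage.minimum_filter1d(x, w)
                typical = max(float(np.median(p2p)), _EPS_SD)
                slope = np.abs(np.gradient(x)) * rec.fs
                flags = (p2p > params.amp_threshold * typical) | (
                    slope > params.slope_threshold * rsd
                )
                mask[p, c] |= flags
    structure = np.ones(2 * w + 1, dtype=bool)
    for p in range(2):
        for c in range(rec.n_channels):
            if mask[p, c].any():
                mask[p, c] = ndimage.binary_dilation(mask[p, c], structure=structure)
    return mask


def _runs(mask_1d: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) half-open intervals."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask_1d.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def correct_motion(
    rec: HyperscanRecording,
    mask: np.ndarray,
    params: ArtifactParams | None = None,
) -> HyperscanRecording:
    """Replace flagged segments with a cubic-spline estimate from flanking
    clean data; persistent baseline jumps across a flagged segment are also
    removed by re-leveling the subsequent samples.

    A channel flagged in its entirety is marked missing.  With
    ``correction="none"`` the recording is returned unchanged.
    """
    params = params or ArtifactParams()
    if rec.stage != "od":
        raise StageError("correct_motion requires od-stage data")
    if mask.shape != (2, rec.n_channels, rec.n_times):
        raise ValidationError("mask shape does not match the recording")
    if params.correction == "none":
        return rec.copy_with()

    out = rec.copy_with()
    w = max(int(round(params.window * rec.fs)), 2)
    n = rec.n_times
    for p in range(2):
        for c in range(rec.n_channels):
            m = mask[p, c]
            if not m.any():
                continue
            if m.all():
                out.bad_channels[p, c] = True
                continue
            for wl in range(2):
                x = out.data[p, c, wl]
                rsd = max(_robust_sd(x), _EPS_SD)
                for a, b in _runs(m):
                    pre = x[max(0, a - w) : a]
                    post = x[b : b + w]
                    if pre.size and post.size:
                        jump = float(post.mean() - pre.mean())
                        if abs(jump) > 2.0 * rsd:
                            x[b:] -= jump
                            post = x[b : b + w]
                    # anchor points from flanking clean data
                    left_i = np.arange(max(0, a - w), a)
                    right_i = np.arange(b, min(n, b + w))
                    anchors_i = np.concatenate([left_i, right_i])
                    if anchors_i.size < 2:
                        fill = x[anchors_i].mean() if anchors_i.size else 0.0
                        x[a:b] = fill
                        continue
                    cs = CubicSpline(anchors_i, x[anchors_i])
                    x[a:b] = cs(np.arange(a, b))
                out.data[p, c, wl] = x
    return out


def od_to_hb(
    rec: HyperscanRecording, blc: BeerLambertConstants | None = None
) -> HyperscanRecording:
    """Invert the modified Beer-Lambert relation: per channel, solve the
    2x2 system ``dOD_w = sum_c eps[w, c] * dC_c * d * DPF_w`` for
    (HbO, HbR) concentration changes (mM) at every sample."""
    blc = blc or BeerLambertConstants()
    if rec.stage != "od":
        raise StageError("od_to_hb requires od-stage data")
    eps = np.asarray(blc.extinction, dtype=float)
    path = np.array([blc.distance * blc.dpf[0], blc.distance * blc.dpf[1]])
    system = eps * path[:, None]  # (wavelength, chromophore)
    inv = np.linalg.inv(system)
    # data: (2, n_ch, wavelength, t) -> concentrations (2, n_ch, chromophore, t)
    hb = np.einsum("cw,pkwt->pkct", inv, rec.data)
    return rec.copy_with(stage="hb", data=hb)
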