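"""Color-temperature estimation and correction (automatic white balancing).

The color sensor exposes a single color-temperature setting ``KW``; the
camera maps it to a red gain ``ΓR = ΓK`` and a blue gain ``ΓB = 1/ΓK`` with

    ΓK(KW) = sqrt(2 (KW − KW_min) / (KW_max − KW_min)),

so equal gains (ΓK = 1) occur at the center of the sensor range.  The AWB
controller drives ``KW`` toward the color temperature of the dominant
illuminant by watching the mean chromaticity of gray pixels: a reddish cast
means the illuminant is warmer than the current setting, a bluish cast
cooler.  Offline, the same controller runs on a *virtual camera* with a
wider range (2000–9000 K) to neutralize casts the physical sensor could not
correct during recording.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from . import color
from .config import MAX_INTENSITY, GamutTarget, WhiteBalanceConfig

log = logging.getLogger(__name__)

__all__ = [
    "CameraState",
    "GamutEstimate",
    "gain_model",
    "estimate_scaler",
    "gamut_errors",
    "awb_step",
    "apply_cast",
    "ColorCorrection",
    "color_correct_offline",
]


@dataclass
class CameraState:
    """White-balance / exposure state of the (possibly virtual) color sensor."""

    kw: float = 4500.0
    kw_min: float = 2500.0
    kw_max: float = 6500.0
    tau: float = 33.0
    tau_min: float = 0.1
    tau_max: float = 666.0
    tau_delta: float = 1.0
    gain: float = 1.0
    gain_min: float = 1.0
    gain_max: float = 16.0

    def __post_init__(self):
        if not (self.kw_min < self.kw <= self.kw_max):
            raise ValueError(
                f"KW={self.kw} outside ({self.kw_min}, {self.kw_max}]"
            )


@dataclass
class GamutEstimate:
    """Mean gray chromaticity with the derived scaler and errors."""

    r: float
    g: float
    b: float
    scaler: float
    error: float            # E, squared gamut distance before correction
    expected_error: float   # E*, predicted distance after applying the scaler


def gain_model(kw: float, kw_min: float, kw_max: float) -> tuple[float, float, float]:
    """Red/blue channel gains for a color-temperature setting.

    Returns ``(ΓR, ΓB, ΓK)``.  ``kw`` must be strictly above ``kw_min``
    (ΓK would vanish there and the blue gain diverge).
    """
    if not kw_min < kw <= kw_max:
        raise ValueError(f"KW={kw} outside ({kw_min}, {kw_max}]")
    gk = math.sqrt(2.0 * (kw - kw_min) / (kw_max - kw_min))
    return gk, 1.0 / gk, gk


def _kw_from_gain(gk: float, kw_min: float, kw_max: float) -> float:
    """Inverse of the gain model: setting whose overall gain is ``gk``."""
    return kw_min + (kw_max - kw_min) * gk * gk / 2.0


def estimate_scaler(mean_chrom: tuple[float, float, float], target: GamutTarget) -> float | None:
    """Relative color-temperature scaler γ from observed gray chromaticity.

    γ² is the red/blue cross ratio ``(r̄·b̄W)/(r̄W·b̄)``; the unknown overall
    intensity cancels.  Returns ``None`` (no estimate, keep the current
    setting) when the red or blue component vanishes.
    """
    r_w, _, b_w = mean_chrom
    if r_w <= 0 or b_w <= 0:
        return None
    return math.sqrt((target.r * b_w) / (r_w * target.b))


def gamut_errors(
    mean_chrom: tuple[float, float, float], scaler: float, target: GamutTarget
) -> tuple[float, float]:
    """Actual and predicted squared gamut errors ``(E, E*)``.

    ``E`` is the squared chromaticity distance of the gray-pixel mean to the
    neutral gamut point.  ``E*`` is the same distance after applying the
    gain change implied by γ (red × γ, blue / γ, per the sensor's gain
    model) and renormalizing the chromaticities.
    """
    r_w, g_w, b_w = mean_chrom
    e = (target.r - r_w) ** 2 + (target.g - g_w) ** 2 + (target.b - b_w) ** 2
    r_s = r_w * scaler
    b_s = b_w / scaler
    total = r_s + g_w + b_s
    e_star = (
        (target.r - r_s / total) ** 2
        + (target.g - g_w / total) ** 2
        + (target.b - b_s / total) ** 2
    )
    return e, e_star


def awb_step(
    chrom: color.ChromaticityImage,
    state: CameraState,
    target: GamutTarget | None = None,
    cfg: WhiteBalanceConfig | None = None,
) -> tuple[CameraState, GamutEstimate | None]:
    """One white-balance controller update.

    Selects gray pixels, estimates the scaler γ, and — when the numerically
    stable update test ``(E > 1.758e-8) ∧ (E − E* > 1e-15)`` passes —
    converts γ into a new ``KW`` through the inverse of the gain model,
    clamped to the sensor range.  Otherwise (or when no gray pixels are
    found) the state is returned unchanged.
    """
    target = target or GamutTarget()
    cfg = cfg or WhiteBalanceConfig()
    mask = color.select_gray_pixels(chrom, target)
    if not mask.any():
        log.warning("awb_step: no gray pixels selected; keeping KW=%.0f", state.kw)
        return state, None
    means = chrom.chromaticity[mask].mean(axis=0)
    scaler = estimate_scaler(tuple(means), target)
    if scaler is None:
        return state, None
    e, e_star = gamut_errors(tuple(means), scaler, target)
    est = GamutEstimate(*means, scaler=scaler, error=e, expected_error=e_star)
    if not (e > cfg.error_threshold and e - e_star > cfg.error_margin):
        return state, est
    _, _, gk = gain_model(state.kw, state.kw_min, state.kw_max)
    new_kw = _kw_from_gain(scaler * gk, state.kw_min, state.kw_max)
    new_kw = min(max(new_kw, state.kw_min + 1.0), state.kw_max)
    return replace(state, kw=new_kw), est


def apply_cast(
    linear: np.ndarray,
    k_illuminant: float,
    k_setting: float,
    kw_min: float,
    kw_max: float,
) -> np.ndarray:
    """Simulate recording a scene of illuminant ``k_illuminant`` at setting ``k_setting``.

    The camera applies gains for its setting while the light requires gains
    for the true illuminant, leaving the net factor ΓK(set)/ΓK(ill) on red
    and its inverse on blue.  A matched setting yields a neutral image.
    """
    _, _, gk_set = gain_model(k_setting, kw_min, kw_max)
    _, _, gk_ill = gain_model(k_illuminant, kw_min, kw_max)
    out = np.array(linear, dtype=np.float64, copy=True)
    out[..., 0] *= gk_set / gk_ill
    out[..., 2] *= gk_ill / gk_set
    return out


@dataclass
class ColorCorrection:
    """Result of the offline virtual-camera color correction."""

    linear: np.ndarray        # corrected linear RGB texture in [0, 1]
    raw: np.ndarray           # 8-bit gamma-compressed version
    kw: float                 # converged virtual color temperature KW+
    iterations: int
    history: list[float]      # KW trace, one entry per accepted update


def _virtual_render(equal_gain: np.ndarray, gk: float) -> np.ndarray:
    out = np.array(equal_gain, copy=True)
    out[..., 0] *= gk
    out[..., 2] /= gk
    return out


def color_correct_offline(
    texture: np.ndarray,
    k_recorded: float,
    cfg: WhiteBalanceConfig | None = None,
    target: GamutTarget | None = None,
) -> ColorCorrection:
    """Neutralize the color cast of a recorded texture image.

    The texture (8-bit gamma RGB, or float linear RGB) recorded at sensor
    setting ``k_recorded`` is first converted to the equal-gain internal
    representation (red divided by ΓK at the recorded temperature on the
    *virtual* range, blue multiplied by it).  The AWB controller then runs
    on the virtual camera until the update either stops, settles within
    ±1 K, or — after at least 20 jittering repetitions — is frozen at the
    mean of the three smallest recent updates that lie within 10 K of their
    predecessor.

    Saturation handling on output: pixels overexposed in the input are left
    untouched; a channel pushed above 1 saturates all three channels; a
    channel below 1e-8 zeroes the pixel; everything is clipped to [0, 1].
    """
    cfg = cfg or WhiteBalanceConfig()
    target = target or GamutTarget()
    if not (cfg.virtual_kw_min < k_recorded <= cfg.virtual_kw_max):
        raise ValueError(
            f"recorded color temperature {k_recorded} outside the virtual "
            f"range ({cfg.virtual_kw_min}, {cfg.virtual_kw_max}]"
        )
    texture = np.asarray(texture)
    if texture.dtype.kind in "ui":
        linear = color.linearize(texture)
    else:
        linear = np.asarray(texture, dtype=np.float64)

    kmin, kmax = cfg.virtual_kw_min, cfg.virtual_kw_max
    _, _, gk_rec = gain_model(k_recorded, kmin, kmax)
    equal_gain = np.array(linear, copy=True)
    equal_gain[..., 0] /= gk_rec
    equal_gain[..., 2] *= gk_rec

    state = CameraState(kw=k_recorded, kw_min=kmin, kw_max=kmax)
    history = [state.kw]
    iterations = 0
    for iterations in range(1, cfg.max_iterations + 1):
        _, _, gk = gain_model(state.kw, kmin, kmax)
        rendered = _virtual_render(equal_gain, gk)
        chrom = color.to_chromaticity(rendered)
        new_state, _ = awb_step(chrom, state, target, cfg)
        delta = new_state.kw - state.kw
        if new_state.kw == state.kw:
            break
        state = new_state
        history.append(state.kw)
        if abs(delta) <= cfg.jitter_band:
            break
        if iterations >= cfg.jitter_repetitions:
            recent = np.asarray(history[-(cfg.jitter_repetitions + 1):])
            deltas = np.abs(np.diff(recent))
            close = np.flatnonzero(deltas < cfg.jitter_close)
            if close.size >= 3:
                best = close[np.argsort(deltas[close])[:3]]
                state = replace(state, kw=float(np.mean(recent[best + 1])))
                break

    kw_plus = state.kw
    _, _, gk_final = gain_model(kw_plus, kmin, kmax)
    corrected = _virtual_render(equal_gain, gk_final)

    # Saturation handling.
    input_intensity = linear.sum(axis=-1)
    overexposed_in = input_intensity >= target.i_max * MAX_INTENSITY
    corrected[overexposed_in] = linear[overexposed_in]
    blown = (corrected > 1.0).any(axis=-1) & ~overexposed_in
    corrected[blown] = 1.0
    dead = (corrected < cfg.underexposed_channel).any(axis=-1) & ~blown & ~overexposed_in
    corrected[dead] = 0.0
    np.clip(corrected, 0.0, 1.0, out=corrected)

    return ColorCorrection(
        linear=corrected,
        raw=color.compress(corrected),
        kw=kw_plus,
        iterations=iterations,
        history=history,
    )
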