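"""Synthetic facial-expression corpus and questionnaire generator.

Emulates a TENS-style elicitation protocol: each subject experiences five
stimulation levels; within a level a latent pain intensity p(t) in [0, 1]
rises, plateaus and decays (trapezoid).  The latent intensity drives FACS
action-unit activations monotonically, the AUs drive a schematic grayscale
face render, and the PSPI label of every frame follows from the AUs — so the
corpus carries exact ground truth for every downstream stage.

Per-level questionnaire responses (subjective pain score SPS 0-5, SAM valence
and arousal 1-9) have means linear in level plus Gaussian noise, clipped to
their scales.

The renders are schematic (bars, ellipses and shading on a light face oval),
not photorealistic; they exercise the geometry/intensity cues the pipeline
relies on, nothing more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .pspi import AUVector, MANIFEST_COLUMNS, bin_pain_state, compute_pspi

__all__ = [
    "FaceRenderParams",
    "ProtocolParams",
    "SurveyParams",
    "latent_trace",
    "aus_from_latent",
    "render_face",
    "region_masks",
    "simulate_corpus",
    "simulate_survey",
]

# Per-AU slope of activation vs latent intensity.  Spread so that a 5-level
# protocol with the default peaks produces all four pain states (none, trace,
# weak, strong): AU4 leads, the eyes close (AU43) only near maximal pain.
DEFAULT_AU_GAIN = {"au4": 1.0, "au6": 0.7, "au7": 0.6, "au9": 0.5, "au10": 0.4, "au43": 0.6}

# Nominal feature geometry in normalized [0, 1] face coordinates (y down).
DEFAULT_GEOMETRY = {
    "brow_y": 0.27,
    "brow_h": 0.04,
    "brow_drop": 0.06,          # max downward brow shift at AU4 = 5
    "brow_x": ((0.18, 0.42), (0.58, 0.82)),
    "eye_y": 0.45,
    "eye_cx": (0.30, 0.70),
    "eye_hw": 0.09,             # half width
    "eye_hh": 0.040,            # open half height
    "nose_x": (0.44, 0.56),
    "nose_y": (0.52, 0.60),
    "mouth_x": (0.35, 0.65),
    "mouth_y": 0.70,
    "mouth_h": 0.03,
    "mouth_raise": 0.05,        # max upward lip shift at AU10 = 5
    "cheek_cx": (0.24, 0.76),
    "cheek_cy": 0.58,
    "cheek_r": 0.055,
}


@dataclass(frozen=True)
class FaceRenderParams:
    """Rendering controls for the schematic face."""

    image_size: int = 64
    noise_sigma: float = 0.01
    au_gain: dict = field(default_factory=lambda: dict(DEFAULT_AU_GAIN))
    geometry: dict = field(default_factory=lambda: dict(DEFAULT_GEOMETRY))

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if any(v < 0 for v in self.au_gain.values()):
            raise ValueError("au_gain components must be >= 0")


@dataclass(frozen=True)
class ProtocolParams:
    """Stimulation protocol: subjects x 5 levels x trapezoidal latent traces.

    frames_per_level defaults to 12, emulating 3-5 fps over a short stimulus;
    peak intensities are nondecreasing in level.
    """

    n_subjects: int = 2
    n_levels: int = 5
    frames_per_level: int = 12
    ramp_fraction: float = 1 / 3
    peak_intensity_per_level: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames_per_level < 3:
            raise ValueError("frames_per_level must be >= 3")
        if len(self.peak_intensity_per_level) != self.n_levels:
            raise ValueError("need one peak intensity per level")
        peaks = np.asarray(self.peak_intensity_per_level, dtype=float)
        if (np.diff(peaks) < 0).any():
            raise ValueError("peak intensities must be nondecreasing across levels")
        if not (0 <= self.ramp_fraction < 0.5):
            raise ValueError("ramp_fraction must be in [0, 0.5)")


@dataclass(frozen=True)
class SurveyParams:
    """Linear-in-level questionnaire model with Gaussian response noise."""

    n_subjects: int = 41
    sps_intercept: float = 1.0
    sps_slope: float = 0.5
    valence_intercept: float = 7.0
    valence_slope: float = -0.5
    arousal_intercept: float = 3.0
    arousal_slope: float = 0.5
    response_noise_sd: float = 0.6
    seed: int = 0


def latent_trace(protocol: ProtocolParams, subject: int, level: int) -> np.ndarray:
    """Trapezoidal latent pain intensity for one (subject, level) sequence.

    Rise and fall each span floor(ramp_fraction * frames) frames, linearly
    interpolated from 0 to the level's peak and back; the remainder holds the
    peak.  Deterministic: the trapezoid has no noise (noise enters at render
    time only).
    """
    if not (1 <= level <= protocol.n_levels):
        raise ValueError(f"level must be 1..{protocol.n_levels}, got {level}")
    n = protocol.frames_per_level
    peak = float(protocol.peak_intensity_per_level[level - 1])
    r = math.floor(protocol.ramp_fraction * n)
    rise = np.linspace(0.0, peak, r) if r else np.empty(0)
    fall = np.linspace(peak, 0.0, r) if r else np.empty(0)
    plateau = np.full(n - 2 * r, peak)
    return np.concatenate([rise, plateau, fall])


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def aus_from_latent(p: float, params: FaceRenderParams | None = None) -> AUVector:
    """Map a latent intensity p in [0, 1] to an AU vector.

    Graded AU_k = round(5 * clip(gain_k * p, 0, 1)) with round-half-away-from-
    zero; AU43 = 1 iff gain_43 * p >= 0.5.  Monotone in p for fixed gains.
    """
    if not (0 <= p <= 1):
        raise ValueError(f"latent intensity must be in [0, 1], got {p}")
    params = params or FaceRenderParams()
    g = params.au_gain
    vals = {k: _round_half_away(5.0 * min(max(g[k] * p, 0.0), 1.0)) for k in
            ("au4", "au6", "au7", "au9", "au10")}
    au43 = int(g["au43"] * p >= 0.5)
    return AUVector(**vals, au43=au43)


def _px(v: float, size: int) -> int:
    return int(round(v * (size - 1)))


def region_masks(params: FaceRenderParams) -> dict[str, np.ndarray]:
    """Boolean masks for the declared feature regions (brow/eye/nose/mouth/cheek).

    Regions are disjoint by construction; each feature's deformation stays
    inside its own region for every admissible AU value.
    """
    s = params.image_size
    geo = params.geometry
    masks = {k: np.zeros((s, s), dtype=bool) for k in ("brow", "eye", "nose", "mouth", "cheek")}
    y0 = _px(geo["brow_y"] - 0.02, s)
    y1 = _px(geo["brow_y"] + geo["brow_h"] + geo["brow_drop"] + 0.01, s)
    for (xa, xb) in geo["brow_x"]:
        masks["brow"][y0:y1 + 1, _px(xa, s):_px(xb, s) + 1] = True
    ey0 = _px(geo["eye_y"] - geo["eye_hh"] - 0.01, s)
    ey1 = _px(geo["eye_y"] + geo["eye_hh"] + 0.01, s)
    for cx in geo["eye_cx"]:
        masks["eye"][ey0:ey1 + 1, _px(cx - geo["eye_hw"] - 0.01, s):_px(cx + geo["eye_hw"] + 0.01, s) + 1] = True
    masks["nose"][_px(geo["nose_y"][0], s):_px(geo["nose_y"][1], s) + 1,
                  _px(geo["nose_x"][0], s):_px(geo["nose_x"][1], s) + 1] = True
    my0 = _px(geo["mouth_y"] - geo["mouth_raise"] - 0.01, s)
    my1 = _px(geo["mouth_y"] + geo["mouth_h"] + 0.01, s)
    masks["mouth"][my0:my1 + 1, _px(geo["mouth_x"][0], s):_px(geo["mouth_x"][1], s) + 1] = True
    cr = geo["cheek_r"]
    for cx in geo["cheek_cx"]:
        masks["cheek"][_px(geo["cheek_cy"] - cr, s):_px(geo["cheek_cy"] + cr, s) + 1,
                       _px(cx - cr, s):_px(cx + cr, s) + 1] = True
    return masks


def render_face(au: AUVector, params: FaceRenderParams | None = None,
                seed: int = 0) -> np.ndarray:
    """Render an AU vector to a float grayscale image in [0, 1].

    Deformations are monotone in the AUs: brows lower and darken with AU4,
    eye aperture shrinks with AU7 and closes with AU43, nose-wrinkle contrast
    rises with AU9, the upper-lip band rises and darkens with AU10, cheek
    shading deepens with AU6.  Additive Gaussian pixel noise (std
    ``noise_sigma``) is applied after drawing, then the image is clipped.
    """
    params = params or FaceRenderParams()
    s = params.image_size
    geo = params.geometry
    img = np.full((s, s), 0.85, dtype=np.float64)

    yy, xx = np.mgrid[0:s, 0:s] / (s - 1)
    # face oval backdrop
    oval = ((xx - 0.5) / 0.46) ** 2 + ((yy - 0.5) / 0.50) ** 2 > 1.0
    img[oval] = 0.30

    # brows: drop and darken with AU4
    a4 = au.au4 / 5.0
    by = geo["brow_y"] + geo["brow_drop"] * a4
    shade = 0.45 - 0.30 * a4
    for (xa, xb) in geo["brow_x"]:
        img[_px(by, s):_px(by + geo["brow_h"], s) + 1, _px(xa, s):_px(xb, s) + 1] = shade

    # eyes: aperture shrinks with AU7, zero when AU43
    aperture = geo["eye_hh"] * (1.0 - 0.8 * au.au7 / 5.0) * (0 if au.au43 else 1)
    for cx in geo["eye_cx"]:
        if aperture > 0:
            ell = (((xx - cx) / geo["eye_hw"]) ** 2 +
                   ((yy - geo["eye_y"]) / aperture) ** 2) <= 1.0
            img[ell] = 0.10
        else:  # closed lid: thin dark line
            img[_px(geo["eye_y"], s), _px(cx - geo["eye_hw"], s):_px(cx + geo["eye_hw"], s) + 1] = 0.25

    # nose wrinkle: line contrast rises with AU9
    a9 = au.au9 / 5.0
    if a9 > 0:
        xa, xb = (_px(v, s) for v in geo["nose_x"])
        for fy in np.linspace(*geo["nose_y"], 3):
            img[_px(fy, s), xa:xb + 1] = 0.85 - 0.6 * a9

    # mouth / upper-lip band: rises and darkens with AU10
    a10 = au.au10 / 5.0
    my = geo["mouth_y"] - geo["mouth_raise"] * a10
    xa, xb = (_px(v, s) for v in geo["mouth_x"])
    img[_px(my, s):_px(my + geo["mouth_h"], s) + 1, xa:xb + 1] = 0.40 - 0.25 * a10

    # cheek shading with AU6
    a6 = au.au6 / 5.0
    if a6 > 0:
        cr = geo["cheek_r"]
        for cx in geo["cheek_cx"]:
            disk = ((xx - cx) ** 2 + (yy - geo["cheek_cy"]) ** 2) <= cr ** 2
            img[disk] -= 0.35 * a6

    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def simulate_corpus(protocol: ProtocolParams | None = None,
                    render: FaceRenderParams | None = None,
                    out_dir: str | Path = "corpus") -> pd.DataFrame:
    """Write a full synthetic corpus (PNG frames + manifest + AU sidecar).

    Returns the manifest DataFrame; ``manifest.csv`` and ``aus.csv`` are
    written next to the frames.  Fully reproducible from ``protocol.seed``:
    every frame's render seed is derived from (seed, subject, level, frame).
    """
    protocol = protocol or ProtocolParams()
    render = render or FaceRenderParams()
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create corpus directory {out}: {e}") from e

    rows, au_rows = [], []
    for subj in range(protocol.n_subjects):
        for level in range(1, protocol.n_levels + 1):
            trace = latent_trace(protocol, subj, level)
            for t, p in enumerate(trace):
                au = aus_from_latent(float(p), render)
                frame_seed = ((protocol.seed * 1_000_003 + subj * 7919
                               + level * 613 + t) % (2**31 - 1))
                img = render_face(au, render, seed=frame_seed)
                name = f"s{subj:02d}_l{level}_f{t:03d}.png"
                Image.fromarray((img * 255).round().astype(np.uint8), mode="L").save(out / name)
                pspi = compute_pspi(au)
                rows.append({
                    "frame_path": name, "subject_id": f"s{subj:02d}", "level": level,
                    "frame_index": t, "pspi": pspi,
                    "pain_state": bin_pain_state(pspi).value, "latent": float(p),
                })
                au_rows.append({"frame_path": name, **{k: getattr(au, k) for k in
                                ("au4", "au6", "au7", "au9", "au10", "au43")}})
    manifest = pd.DataFrame(rows)
    manifest[MANIFEST_COLUMNS].to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(au_rows).to_csv(out / "aus.csv", index=False)
    # latent sidecar: ground truth for evaluation, not part of the manifest dialect
    manifest[["frame_path", "latent"]].to_csv(out / "latent.csv", index=False)
    return manifest


def simulate_survey(params: SurveyParams | None = None) -> pd.DataFrame:
    """Per-(subject, level) questionnaire table with linear level effects.

    Columns: subject, gender, age_group, level, sps, valence, arousal.  Means
    are linear in level before clipping to the scale ranges (SPS 0-5, SAM
    1-9); noise is i.i.d. Gaussian.  Deterministic given ``params.seed``.
    """
    params = params or SurveyParams()
    rng = np.random.default_rng(params.seed)
    genders = rng.choice(["F", "M"], size=params.n_subjects)
    ages = rng.choice(["20s", "40s", "50s", "60s"], size=params.n_subjects)
    rows = []
    for i in range(params.n_subjects):
        for level in range(1, 6):
            noise = rng.normal(0.0, 1.0, size=3) * params.response_noise_sd
            sps = params.sps_intercept + params.sps_slope * level + noise[0]
            val = params.valence_intercept + params.valence_slope * level + noise[1]
            aro = params.arousal_intercept + params.arousal_slope * level + noise[2]
            rows.append({
                "subject": f"p{i:03d}", "gender": genders[i], "age_group": ages[i],
                "level": level,
                "sps": float(np.clip(sps, 0, 5)),
                "valence": float(np.clip(val, 1, 9)),
                "arousal": float(np.clip(aro, 1, 9)),
            })
    return pd.DataFrame(rows)
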