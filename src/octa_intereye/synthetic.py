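"""Synthetic paired-eye angiograms and metrics-level cohorts.

Clinical OCTA images cannot be shipped with the package, so every downstream
stage is exercised on synthetic data with known ground truth:

* ``generate_angiogram_pair`` draws a right/left pair of en-face images for
  one patient: a capillary mesh of correlated random-walk strokes laid down
  until a target coverage fraction is reached, a few bright arcade ("big")
  vessels radiating from the image border, a foveal avascular zone cleared
  of capillaries around the image center, and Gaussian pixel noise.  The
  ground truth (vessel masks, FAZ polygon, realized capillary fraction) is
  returned alongside.

* ``generate_metrics_cohort`` skips the imaging and simulates per-eye metric
  values directly from the additive model the cohort analysis assumes:
  stage effects, a left-eye offset, per-stage interaction offsets, covariate
  terms, a patient-level random intercept and residual noise.

* ``make_fixture`` provides deterministic oracle shapes (Sierpinski carpet,
  filled disc, line, checkerboard, square polygon) whose fractal dimension /
  area / perimeter are known in closed form.

All randomness flows from one integer seed through numpy seed sequences
split per eye / per patient, so identical parameters reproduce bit-identical
outputs regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk

STAGES = ("no_dr", "mild", "moderate", "severe", "pdr")

# Cohort demographics emulate the study population: mean age 57.2 +/- 13.1 y,
# HbA1c 7.34 +/- 1.32 %, 66% male.
AGE_MEAN, AGE_SD = 57.2, 13.1
HBA1C_MEAN, HBA1C_SD = 7.34, 1.32
MALE_FRACTION = 111 / 168


@dataclass(frozen=True)
class ImageGenParams:
    """Parameters of the synthetic en-face angiogram generator.

    Defaults emulate a fovea-centered 6x6 mm scan sampled at 500x500 px
    (0.012 mm/px) with SCP-like capillary coverage (~0.22 of the 6-mm disc)
    and a FAZ of ~0.25 mm^2.
    """

    image_size: int = 500
    pixel_pitch: float = 0.012            # mm per pixel
    capillary_fraction: float = 0.22      # target coverage in the 6-mm disc
    n_big_vessels: int = 3
    big_vessel_width: int = 6             # px
    big_vessel_fraction: float = 0.035    # target arcade coverage of the field
    faz_mean_radius: float = 0.28         # mm
    faz_irregularity: float = 0.15        # radial perturbation amplitude, [0, 1)
    # intensities chosen so the two global thresholds separate the three
    # tissue classes with margin: background < mean+0.5*sd < capillary <
    # mean+1.3*sd < big vessel across the supported coverage range
    vessel_intensity_mean: float = 80.0
    background_intensity_mean: float = 25.0
    big_vessel_intensity_mean: float = 230.0
    noise_sd: float = 5.0                 # 8-bit intensity units
    left_capillary_delta: float = 0.0     # additive left-eye coverage offset
    left_faz_irregularity: float | None = None  # override for the left eye
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.capillary_fraction < 1.0:
            raise ValueError("capillary_fraction must be in (0, 1)")
        left = self.capillary_fraction + self.left_capillary_delta
        if not 0.0 < left < 1.0:
            raise ValueError("left-eye capillary fraction out of (0, 1)")
        if not 0.0 < self.faz_mean_radius < 1.5:
            raise ValueError("faz_mean_radius must be in (0, 1.5) mm")
        if not 0.0 <= self.faz_irregularity < 1.0:
            raise ValueError("faz_irregularity must be in [0, 1)")
        if self.image_size * self.pixel_pitch < 6.0:
            raise ValueError("field of view must cover 6 mm (image_size * pixel_pitch)")
        if self.n_big_vessels < 0 or self.big_vessel_width < 1:
            raise ValueError("invalid big-vessel configuration")
        if not 0.0 <= self.big_vessel_fraction < 0.2:
            raise ValueError("big_vessel_fraction must be in [0, 0.2)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth behind one synthetic eye."""

    vessel_mask: np.ndarray       # capillaries plus big vessels
    big_vessel_mask: np.ndarray
    faz_polygon: np.ndarray       # (n, 2) closed (x, y) vertex list
    true_capillary_fraction: float  # realized coverage: 6-mm disc, FAZ and big vessels excluded


def _faz_polygon(rng: np.random.Generator, params: ImageGenParams,
                 center: tuple[float, float], irregularity: float) -> np.ndarray:
    """FAZ boundary from 72 radial spokes with smoothed radius perturbation."""
    n = 72
    angles = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    u = rng.uniform(-1.0, 1.0, size=n)
    if irregularity > 0:
        # 5-point circular moving average keeps the boundary simple
        kernel = np.ones(5) / 5.0
        u = np.convolve(np.concatenate([u[-2:], u, u[:2]]), kernel, mode="valid")
    radii_px = params.faz_mean_radius * (1.0 + irregularity * u) / params.pixel_pitch
    x = center[0] + radii_px * np.cos(angles)
    y = center[1] + radii_px * np.sin(angles)
    return np.column_stack([x, y])


def _polygon_mask(poly: np.ndarray, size: int) -> np.ndarray:
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    return mask


def _big_vessels(rng: np.random.Generator, params: ImageGenParams,
                 center: tuple[float, float]) -> np.ndarray:
    """Smooth bright curves radiating inward from the image border.

    Curves are steered away from the fovea so the FAZ stays avascular, like
    the arcade vessels that arc around the macula.  Batches of
    ``n_big_vessels`` curves are drawn until the dilated arcade covers
    ``big_vessel_fraction`` of the field: a stable macrovessel content keeps
    the bright tail of the intensity histogram (what the 1.3-sd threshold
    isolates) consistent across eyes.
    """
    size = params.image_size
    path = np.zeros((size, size), dtype=bool)
    if params.n_big_vessels == 0 or params.big_vessel_fraction == 0:
        return path
    # the dilated footprint is ~ path length x width
    target_path_px = int(params.big_vessel_fraction * size * size
                         / params.big_vessel_width)
    avoid_px = (params.faz_mean_radius + 0.5) / params.pixel_pitch
    for n_drawn in range(200):
        if n_drawn >= params.n_big_vessels and path.sum() >= target_path_px:
            break
        edge = rng.integers(0, 4)
        t = rng.uniform(0.1, 0.9) * size
        pos = np.array({0: (t, 0.0), 1: (t, size - 1.0),
                        2: (0.0, t), 3: (size - 1.0, t)}[int(edge)])
        # initial heading: inward
        target = np.array([center[0], center[1]]) + rng.normal(0, size / 4, 2)
        angle = float(np.arctan2(target[1] - pos[1], target[0] - pos[0]))
        n_steps = int(size * 1.4)
        for _ in range(n_steps):
            angle += rng.normal(0.0, 0.03)
            to_center = np.array(center) - pos
            dist = float(np.hypot(*to_center))
            if dist < avoid_px:
                # deflect: rotate heading away from the foveal center
                away = float(np.arctan2(-to_center[1], -to_center[0]))
                angle += 0.3 * np.sin(away - angle + np.pi) * (-1)
                angle = away + np.clip(angle - away, -np.pi / 2, np.pi / 2)
            pos = pos + np.array([np.cos(angle), np.sin(angle)])
            xi, yi = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= xi < size and 0 <= yi < size):
                break
            path[yi, xi] = True
    if path.any() and params.big_vessel_width > 1:
        path = ndimage.binary_dilation(path, structure=disk(params.big_vessel_width // 2))
    return path


def _capillary_mesh(rng: np.random.Generator, params: ImageGenParams,
                    target_fraction: float, region: np.ndarray,
                    forbidden: np.ndarray) -> np.ndarray:
    """Random-walk strokes accumulated until ``region`` coverage hits target.

    ``region`` is the reference area for the coverage fraction (6-mm disc
    minus FAZ minus big vessels); ``forbidden`` pixels (the FAZ) are never
    drawn on.  Strokes are laid over the whole field so vessels continue
    naturally past the grid boundary.
    """
    size = params.image_size
    mesh = np.zeros((size, size), dtype=bool)
    region_px = int(region.sum())
    target_px = int(round(target_fraction * region_px))
    stroke_len = 64
    max_batches = 500_000
    for _ in range(max_batches):
        covered = int((mesh & region).sum())
        if covered >= target_px:
            break
        # adaptive batching: many strokes while far from the target, single
        # strokes near it, so the realized coverage lands within one stroke
        # (<1e-3 of the region) of the requested fraction
        batch = int(np.clip((target_px - covered) // (4 * stroke_len), 1, 25))
        for _ in range(batch):
            start = rng.uniform(0, size, size=2)
            turns = rng.normal(0.0, 0.25, size=stroke_len)
            turns[0] = rng.uniform(-np.pi, np.pi)
            angles = np.cumsum(turns)
            steps = np.column_stack([np.cos(angles), np.sin(angles)])
            pts = start + np.cumsum(steps, axis=0)
            ij = np.round(pts).astype(int)
            keep = ((ij[:, 0] >= 0) & (ij[:, 0] < size)
                    & (ij[:, 1] >= 0) & (ij[:, 1] < size))
            ij = ij[keep]
            mesh[ij[:, 1], ij[:, 0]] = True
    mesh &= ~forbidden
    return mesh


def _render_eye(rng: np.random.Generator, params: ImageGenParams,
                capillary_fraction: float, faz_irregularity: float):
    from .segmentation import EnFaceImage  # local import to avoid cycle at module load

    size = params.image_size
    center = ((size - 1) / 2.0, (size - 1) / 2.0)

    faz_poly = _faz_polygon(rng, params, center, faz_irregularity)
    faz_mask = _polygon_mask(faz_poly, size)
    big = _big_vessels(rng, params, center)
    big &= ~faz_mask

    yy, xx = np.mgrid[0:size, 0:size]
    r_mm = np.hypot(xx - center[0], yy - center[1]) * params.pixel_pitch
    disc = r_mm <= 3.0
    region = disc & ~faz_mask & ~big

    caps = _capillary_mesh(rng, params, capillary_fraction, region, faz_mask)
    caps &= ~big  # big-vessel pixels take the big-vessel label

    img = np.full((size, size), params.background_intensity_mean, dtype=np.float64)
    img[caps] = params.vessel_intensity_mean
    img[big] = params.big_vessel_intensity_mean
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    realized = float((caps & region).sum() / region.sum())
    truth = GroundTruth(vessel_mask=caps | big, big_vessel_mask=big,
                        faz_polygon=faz_poly, true_capillary_fraction=realized)
    image = EnFaceImage(pixels=img, pixel_pitch=params.pixel_pitch)
    return image, truth


def generate_angiogram_pair(params: ImageGenParams):
    """Synthetic right/left en-face image pair with ground truth.

    The two eyes share all parameters; the left eye's target capillary
    fraction is offset by ``left_capillary_delta`` (to plant an intereye
    deficit) and may use a different FAZ irregularity.  Returns
    ``(right, left, truth_right, truth_left)``.
    """
    rng_r = np.random.default_rng([params.seed, 0])
    rng_l = np.random.default_rng([params.seed, 1])
    right, truth_r = _render_eye(rng_r, params, params.capillary_fraction,
                                 params.faz_irregularity)
    left_irr = (params.faz_irregularity if params.left_faz_irregularity is None
                else params.left_faz_irregularity)
    left, truth_l = _render_eye(rng_l, params,
                                params.capillary_fraction + params.left_capillary_delta,
                                left_irr)
    right = replace(right, eye_side="right")
    left = replace(left, eye_side="left")
    return right, left, truth_r, truth_l


# ---------------------------------------------------------------------------
# metrics-level cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortGenParams:
    """Additive-model generator for per-eye metric values.

    ``response = grand_mean + stage_effect + (side_effect +
    interaction_effect[stage]) * I(left) + covariate terms + patient
    intercept + residual``, one row per eye, two rows per patient, both eyes
    sharing the patient's DR stage.  Defaults emulate SCP vessel density:
    grand mean 0.218, left-eye offset -0.009, between-patient SD 0.015,
    within-eye SD 0.008, 34 patients per stage (~170 patients).
    """

    n_per_stage: int = 34
    grand_mean: float = 0.218
    stage_effects: tuple[float, float, float, float, float] = (0.0, 0.009, 0.0, -0.005, -0.006)
    side_effect: float = -0.009
    interaction_effects: tuple[float, float, float, float, float] = (0.0,) * 5
    patient_sd: float = 0.015
    residual_sd: float = 0.008
    age_effect: float = 0.0      # per year, age centered at 57.2
    hba1c_effect: float = 0.0    # per %, centered at 7.34
    sex_effect: float = 0.0      # male vs female
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_stage < 2:
            raise ValueError("n_per_stage must be >= 2")
        if self.patient_sd < 0:
            raise ValueError("patient_sd must be >= 0")
        if not self.residual_sd > 0:
            raise ValueError("residual_sd must be > 0")
        if len(self.stage_effects) != 5 or len(self.interaction_effects) != 5:
            raise ValueError("stage_effects and interaction_effects need 5 entries")


def generate_metrics_cohort(params: CohortGenParams) -> pd.DataFrame:
    """Simulate a metrics-level cohort table (one row per eye).

    Columns: ``patient_id, side, stage, age, sex, hba1c, response``.
    Per-patient randomness is drawn from a seed stream split by patient
    index, so the table is reproducible row-for-row.
    """
    rows = []
    pidx = 0
    for s_i, stage in enumerate(STAGES):
        for _ in range(params.n_per_stage):
            rng = np.random.default_rng([params.seed, 7, pidx])
            age = rng.normal(AGE_MEAN, AGE_SD)
            hba1c = rng.normal(HBA1C_MEAN, HBA1C_SD)
            sex = "male" if rng.uniform() < MALE_FRACTION else "female"
            b_patient = rng.normal(0.0, params.patient_sd) if params.patient_sd > 0 else 0.0
            base = (params.grand_mean + params.stage_effects[s_i]
                    + params.age_effect * (age - AGE_MEAN)
                    + params.hba1c_effect * (hba1c - HBA1C_MEAN)
                    + params.sex_effect * (sex == "male")
                    + b_patient)
            eps = rng.normal(0.0, params.residual_sd, size=2)
            right = base + eps[0]
            left = (base + params.side_effect + params.interaction_effects[s_i] + eps[1])
            pid = f"P{pidx:04d}"
            rows.append((pid, "right", stage, age, sex, hba1c, right))
            rows.append((pid, "left", stage, age, sex, hba1c, left))
            pidx += 1
    return pd.DataFrame(rows, columns=["patient_id", "side", "stage", "age",
                                       "sex", "hba1c", "response"])


# ---------------------------------------------------------------------------
# oracle fixtures
# ---------------------------------------------------------------------------

FixtureName = Literal["sierpinski_carpet", "filled_disc", "line",
                      "checkerboard", "square_polygon"]


def make_fixture(name: FixtureName, size: int):
    """Deterministic oracle shapes with closed-form properties.

    ``sierpinski_carpet``: binary grid, ``size`` a power of 3, with
    ``8**level`` foreground pixels and box-counting dimension log8/log3.
    ``filled_disc``: disc of radius ``size//2 - 1``.  ``line``: one-pixel
    horizontal line.  ``checkerboard``: alternating pixels (coverage 1/2).
    ``square_polygon``: (x, y) vertices of an axis-aligned square of side
    ``size`` (shoelace area size^2, perimeter 4*size).
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if name == "sierpinski_carpet":
        level = int(round(np.log(size) / np.log(3)))
        if 3 ** level != size:
            raise ValueError("sierpinski_carpet size must be a power of 3")
        cell = np.ones((1, 1), dtype=bool)
        motif = np.ones((3, 3), dtype=bool)
        motif[1, 1] = False
        for _ in range(level):
            cell = np.kron(motif, cell)
        return cell
    if name == "filled_disc":
        radius = size // 2 - 1
        if radius < 1:
            raise ValueError("filled_disc size too small")
        c = (size - 1) / 2.0
        yy, xx = np.mgrid[0:size, 0:size]
        return np.hypot(xx - c, yy - c) <= radius
    if name == "line":
        grid = np.zeros((size, size), dtype=bool)
        grid[size // 2, :] = True
        return grid
    if name == "checkerboard":
        yy, xx = np.mgrid[0:size, 0:size]
        return (xx + yy) % 2 == 0
    if name == "square_polygon":
        a = float(size)
        return np.array([(0.0, 0.0), (a, 0.0), (a, a), (0.0, a)])
    raise ValueError(f"unknown fixture {name!r}")
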