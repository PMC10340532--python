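"""Synthetic ground-truth data generators.

Every generator is a pure function of its parameters and a seed, so the
whole analysis pipeline can be exercised and validated without any
external data.  The generators emulate:

* fields of thin bright filaments (microtubules, ~6 px wide) over a
  noisy background, with occasional round aggregate blobs to exercise
  the circularity filter;
* plate-reader donor/acceptor emissions whose background-corrected
  ratio follows the measured control values of the conformational
  sensor (uninhibited enzyme 1.64 +/- 0.02, antibody-inhibited
  1.34 +/- 0.03, Aurora-B-phosphorylated 1.10 +/- 0.01);
* duplicate-replicate compound screens with a small planted-inhibitor
  fraction;
* duplicate-well viability tables from the three-parameter log-logistic
  dose-response model; and
* binomial micronucleus counts out of a fixed number of scored
  binucleate cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plates import (
    Channel,
    FluorescenceImage,
    PlateLayout,
    WellReading,
    WellRole,
    builtin_layout,
    subseed,
)

__all__ = [
    "Filament",
    "FilamentTruth",
    "FretEffectModel",
    "render_mt_field",
    "render_from_truth",
    "simulate_depol_plate",
    "simulate_fret_plate",
    "simulate_duplicate_screen",
    "simulate_viability",
    "simulate_binucleate_counts",
    "log_logistic3",
]


# ---------------------------------------------------------------------------
# Filament field rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Filament:
    center: tuple[float, float]   # (row, col)
    angle: float                  # radians
    length: float                 # px, already clipped to image bounds
    width: float = 6.0            # px


@dataclass(frozen=True)
class Blob:
    center: tuple[float, float]
    radius: float


@dataclass
class FilamentTruth:
    """Ground truth of one rendered field."""

    filaments: list[Filament]
    blobs: list[Blob] = field(default_factory=list)

    @property
    def total_length(self) -> float:
        return float(sum(f.length for f in self.filaments))


# Intensity profile across a filament: flat top out to w/2 - 0.5 px from
# the axis, then a Gaussian shoulder of sigma 0.4 px, so the half-maximum
# width equals the nominal width and the profile reaches background
# within about one pixel.
_SHOULDER_SIGMA = 0.4


def _profile(dist: np.ndarray, width: float) -> np.ndarray:
    inner = width / 2.0 - 0.5
    excess = np.maximum(dist - inner, 0.0)
    return np.exp(-(excess ** 2) / (2.0 * _SHOULDER_SIGMA ** 2))


def _paint_segment(canvas: np.ndarray, fil: Filament, amplitude: float) -> None:
    r0, c0 = fil.center
    dr, dc = math.sin(fil.angle), math.cos(fil.angle)
    half = fil.length / 2.0
    margin = fil.width / 2.0 + 2.0
    rows = np.arange(
        max(0, int(r0 - half - margin)), min(canvas.shape[0], int(r0 + half + margin) + 1)
    )
    cols = np.arange(
        max(0, int(c0 - half - margin)), min(canvas.shape[1], int(c0 + half + margin) + 1)
    )
    if rows.size == 0 or cols.size == 0:
        return
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    # signed coordinates along / across the segment axis
    pr, pc = rr - r0, cc - c0
    along = pr * dr + pc * dc
    across = np.abs(pr * dc - pc * dr)
    t = np.clip(along, -half, half)
    dist = np.hypot(pr - t * dr, pc - t * dc)
    # distance from the capped segment; use the cross-axis profile
    d = np.where(np.abs(along) <= half, across, dist)
    canvas[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1] += amplitude * _profile(
        d, fil.width
    )


def _paint_blob(canvas: np.ndarray, blob: Blob, amplitude: float) -> None:
    r0, c0 = blob.center
    margin = blob.radius + 2.0
    rows = np.arange(max(0, int(r0 - margin)), min(canvas.shape[0], int(r0 + margin) + 1))
    cols = np.arange(max(0, int(c0 - margin)), min(canvas.shape[1], int(c0 + margin) + 1))
    if rows.size == 0 or cols.size == 0:
        return
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    d = np.hypot(rr - r0, cc - c0)
    inner = blob.radius - 0.5
    excess = np.maximum(d - inner, 0.0)
    canvas[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1] += amplitude * np.exp(
        -(excess ** 2) / (2.0 * _SHOULDER_SIGMA ** 2)
    )


def sample_filaments(
    rng: np.random.Generator,
    n_filaments: int,
    shape: tuple[int, int],
    length_distribution: tuple[float, float] = (50.0, 130.0),
    width_px: float = 6.0,
) -> list[Filament]:
    """Sample filament geometry; centers chosen so filaments lie in bounds."""
    lo, hi = length_distribution
    fils = []
    for _ in range(n_filaments):
        length = float(rng.uniform(lo, hi))
        angle = float(rng.uniform(0.0, math.pi))
        half = length / 2.0
        margin_r = abs(math.sin(angle)) * half + width_px
        margin_c = abs(math.cos(angle)) * half + width_px
        r = float(rng.uniform(margin_r, shape[0] - margin_r))
        c = float(rng.uniform(margin_c, shape[1] - margin_c))
        fils.append(Filament((r, c), angle, length, width_px))
    return fils


def render_from_truth(
    truth: FilamentTruth,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] = (512, 672),
    snr: float = 30.0,
    background: float = 150.0,
    read_noise_sd: float = 5.0,
    noise: bool = True,
    bit_depth: int = 12,
    pixel_size: float = 0.003,
) -> FluorescenceImage:
    """Render an image from fixed ground truth geometry.

    The filament amplitude is ``snr`` times the background noise scale
    (shot noise plus read noise).  With ``noise=False`` the noiseless
    expectation (background + signal) is returned.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    noise_scale = math.sqrt(background + read_noise_sd ** 2)
    amplitude = snr * noise_scale
    canvas = np.zeros(shape, dtype=float)
    for fil in truth.filaments:
        _paint_segment(canvas, fil, amplitude)
    for blob in truth.blobs:
        _paint_blob(canvas, blob, amplitude)
    expectation = background + canvas
    if noise:
        if rng is None:
            raise ValueError("rng required when noise=True")
        img = rng.poisson(expectation).astype(float)
        img += rng.normal(0.0, read_noise_sd, size=shape)
    else:
        img = expectation
    max_gray = 2 ** bit_depth - 2
    return FluorescenceImage(
        np.clip(np.round(img), 0, max_gray), bit_depth, pixel_size
    )


def render_mt_field(
    n_filaments: int,
    seed: int = 0,
    length_distribution: tuple[float, float] = (50.0, 130.0),
    width_px: float = 6.0,
    snr: float = 30.0,
    n_blobs: int = 0,
    blob_radius: float = 8.0,
    shape: tuple[int, int] = (512, 672),
    noise: bool = True,
    **render_kw: float,
) -> tuple[FluorescenceImage, FilamentTruth]:
    """Render a field of bright filaments (plus optional round blobs) over
    a noisy background and return the image with its ground truth."""
    if n_filaments < 0:
        raise ValueError("n_filaments must be >= 0")
    if width_px <= 0:
        raise ValueError("width must be > 0")
    rng = np.random.default_rng(seed)
    fils = sample_filaments(rng, n_filaments, shape, length_distribution, width_px)
    blobs = [
        Blob(
            (
                float(rng.uniform(blob_radius + 2, shape[0] - blob_radius - 2)),
                float(rng.uniform(blob_radius + 2, shape[1] - blob_radius - 2)),
            ),
            blob_radius,
        )
        for _ in range(n_blobs)
    ]
    truth = FilamentTruth(fils, blobs)
    img = render_from_truth(
        truth, rng, shape=shape, snr=snr, noise=noise, **render_kw
    )
    return img, truth


# ---------------------------------------------------------------------------
# Depolymerization plate simulation
# ---------------------------------------------------------------------------

_DEFAULT_RESIDUAL = {
    WellRole.FCP_CONTROL: 1.0,       # no enzyme: polymer untouched
    WellRole.ANTIBODY_CONTROL: 1.0,  # enzyme fully inhibited
    WellRole.AURORA_CONTROL: 1.0,
    WellRole.FMCAK_CONTROL: 0.1,     # active enzyme removes ~90% of polymer
    WellRole.COMPOUND: 0.1,          # inactive compounds leave the enzyme active
}


def _truncate_to_length(fils: list[Filament], target: float) -> list[Filament]:
    """Keep filaments (in order) until the running total reaches ``target``;
    the filament crossing the target is shortened so the total is exact.
    Models all-or-none depolymerization of individual microtubules."""
    kept: list[Filament] = []
    acc = 0.0
    for f in fils:
        if acc + f.length <= target + 1e-9:
            kept.append(f)
            acc += f.length
        else:
            remainder = target - acc
            if remainder > 1e-9:
                kept.append(Filament(f.center, f.angle, remainder, f.width))
            break
    return kept


def simulate_depol_plate(
    layout: PlateLayout,
    residual_fractions: dict[str, float] | None = None,
    seed: int = 0,
    n_filaments: int = 30,
    blob_fraction: float = 0.05,
    timepoints: tuple[int, ...] = (0, 30, 60),
    **render_kw,
) -> tuple[dict[str, dict[int, FluorescenceImage]], dict[str, dict[int, FilamentTruth]]]:
    """Simulate per-well image time series for a depolymerization plate.

    Each well renders the same microtubule field at t=0 and a reduced
    field at t=60 whose total true length is ``residual_fraction`` times
    the baseline; t=30 sits at the geometric mean of the two totals.
    Per-well residual fractions default to 1.0 for enzyme-free or
    inhibited controls and 0.1 for active-enzyme wells.  Buffer blanks
    get background-only images.
    """
    fractions: dict[str, float] = {}
    for w, a in layout.wells.items():
        if a.role is WellRole.BUFFER_BLANK:
            continue
        fractions[w] = _DEFAULT_RESIDUAL[a.role]
    if residual_fractions:
        unknown = set(residual_fractions) - set(layout.wells)
        if unknown:
            raise ValueError(f"residual fractions for wells not in layout: {sorted(unknown)}")
        for w, f in residual_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"residual fraction for {w} must be in [0, 1]")
            fractions[w] = f

    images: dict[str, dict[int, FluorescenceImage]] = {}
    truths: dict[str, dict[int, FilamentTruth]] = {}
    shape = render_kw.pop("shape", (512, 672))
    for w, a in layout.wells.items():
        rng = np.random.default_rng(subseed(seed, "depol", w))
        if a.role is WellRole.BUFFER_BLANK:
            truth0 = FilamentTruth([], [])
            images[w] = {
                t: render_from_truth(truth0, rng, shape=shape, **render_kw)
                for t in timepoints
            }
            truths[w] = {t: truth0 for t in timepoints}
            continue
        fils = sample_filaments(rng, n_filaments, shape)
        n_blobs = int(round(blob_fraction * n_filaments))
        blobs = [
            Blob(
                (
                    float(rng.uniform(10, shape[0] - 10)),
                    float(rng.uniform(10, shape[1] - 10)),
                ),
                8.0,
            )
            for _ in range(n_blobs)
        ]
        base = FilamentTruth(fils, blobs)
        frac = fractions[w]
        total0 = base.total_length
        targets = {0: total0, 60: frac * total0, 30: math.sqrt(frac) * total0}
        images[w], truths[w] = {}, {}
        for t in timepoints:
            truth_t = FilamentTruth(
                _truncate_to_length(fils, targets.get(t, frac * total0)), blobs
            )
            images[w][t] = render_from_truth(truth_t, rng, shape=shape, **render_kw)
            truths[w][t] = truth_t
    return images, truths


# ---------------------------------------------------------------------------
# FRET plate simulation
# ---------------------------------------------------------------------------

@dataclass
class FretEffectModel:
    """Statistical model of per-well conformational FRET ratios.

    Control means/SDs default to the measured control values of the
    sensor; the FCP (direct donor-acceptor fusion) mean is set to 4.0 to
    represent its "very high FRET" and is configurable.  Compound wells
    behave like uninhibited-enzyme wells times an optional multiplicative
    effect.  The donor signal and the per-channel background are
    deterministic reader constants, so the realized ratio of every
    simulated well is exactly recoverable by background-corrected
    division.
    """

    fmcak: tuple[float, float] = (1.64, 0.02)
    antibody: tuple[float, float] = (1.34, 0.03)
    aurora: tuple[float, float] = (1.10, 0.01)
    fcp: tuple[float, float] = (4.0, 0.08)
    hit_effect: float = 0.7       # multiplicative ratio shift of a true inhibitor
    hit_fraction: float = 0.005   # fraction of library compounds that are true hits
    donor_signal: float = 1000.0  # reader units above background
    background: tuple[float, float] = (40.0, 50.0)  # (B_F, B_D)

    def __post_init__(self) -> None:
        for name in ("fmcak", "antibody", "aurora", "fcp"):
            mean, sd = getattr(self, name)
            if mean <= 0:
                raise ValueError(f"{name} ratio mean must be > 0")
            if sd < 0:
                raise ValueError(f"{name} ratio SD must be >= 0")
        if self.hit_effect <= 0:
            raise ValueError("hit_effect must be > 0")
        if not 0.0 <= self.hit_fraction <= 1.0:
            raise ValueError("hit_fraction must be in [0, 1]")

    def role_params(self, role: WellRole) -> tuple[float, float]:
        return {
            WellRole.FMCAK_CONTROL: self.fmcak,
            WellRole.ANTIBODY_CONTROL: self.antibody,
            WellRole.AURORA_CONTROL: self.aurora,
            WellRole.FCP_CONTROL: self.fcp,
            WellRole.COMPOUND: self.fmcak,
        }[role]


def simulate_fret_plate(
    layout: PlateLayout,
    model: FretEffectModel | None = None,
    seed: int = 0,
    effects: dict[str, float] | None = None,
) -> tuple[list[WellReading], dict[str, float]]:
    """Simulate FRET- and donor-channel readings for one plate.

    Returns the readings plus the per-well true ratios.  Buffer blanks
    carry background-only intensities.  ``effects`` maps compound ids to
    multiplicative shifts of the well's true ratio.
    """
    model = model or FretEffectModel()
    effects = effects or {}
    rng = np.random.default_rng(subseed(seed, "fret"))
    b_f, b_d = model.background
    readings: list[WellReading] = []
    truth: dict[str, float] = {}
    for w, a in sorted(layout.wells.items()):
        if a.role is WellRole.BUFFER_BLANK:
            readings.append(WellReading(w, Channel.FRET_EM, b_f))
            readings.append(WellReading(w, Channel.DONOR_EM, b_d))
            continue
        mean, sd = model.role_params(a.role)
        ratio = float(rng.normal(mean, sd)) if sd > 0 else mean
        if a.role is WellRole.COMPOUND and a.compound_id in effects:
            ratio *= effects[a.compound_id]
        ratio = max(ratio, 1e-6)
        truth[w] = ratio
        d = model.donor_signal
        readings.append(WellReading(w, Channel.FRET_EM, b_f + ratio * d))
        readings.append(WellReading(w, Channel.DONOR_EM, b_d + d))
    return readings, truth


# ---------------------------------------------------------------------------
# Duplicate compound screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenSim:
    """One simulated duplicate screen: per-replicate plate sets."""

    compound_ids: list[str]
    true_hit_ids: set[str]
    effects: dict[str, float]
    layouts: list[PlateLayout]
    # replicates[r][p] = (readings, truth) for plate p of replicate r
    replicates: list[list[tuple[list[WellReading], dict[str, float]]]]


def simulate_duplicate_screen(
    n_compounds: int,
    true_hit_ids: set[str] | None = None,
    effect_size: float | None = None,
    seed: int = 0,
    model: FretEffectModel | None = None,
) -> ScreenSim:
    """Simulate a duplicate 384-well FRET screen of ``n_compounds``.

    Compounds are laid out on as many 384-well pilot plates as needed
    (352 compound wells per plate).  Both replicates share the same true
    effects but carry independent measurement noise.  If ``true_hit_ids``
    is None, hits are drawn at the model's ``hit_fraction``; their ratio
    is multiplied by ``effect_size`` (default: the model's
    ``hit_effect``).
    """
    model = model or FretEffectModel()
    ids = [f"CB{i + 1:05d}" for i in range(n_compounds)]
    rng = np.random.default_rng(subseed(seed, "screen-design"))
    if true_hit_ids is None:
        n_hits = rng.binomial(n_compounds, model.hit_fraction)
        true_hit_ids = set(rng.choice(ids, size=n_hits, replace=False))
    else:
        unknown = true_hit_ids - set(ids)
        if unknown:
            raise ValueError(f"true hit ids not in compound list: {sorted(unknown)}")
    eff = effect_size if effect_size is not None else model.hit_effect
    effects = {cid: eff for cid in true_hit_ids}

    per_plate = len(builtin_layout("pilot384").compound_wells)
    layouts = [
        builtin_layout("pilot384", ids[i : i + per_plate])
        for i in range(0, n_compounds, per_plate)
    ]
    replicates = []
    for rep in range(2):
        plates = [
            simulate_fret_plate(
                lay, model, seed=subseed(seed, "rep", rep, "plate", p), effects=effects
            )
            for p, lay in enumerate(layouts)
        ]
        replicates.append(plates)
    return ScreenSim(ids, set(true_hit_ids), effects, layouts, replicates)


# ---------------------------------------------------------------------------
# Viability and count data
# ---------------------------------------------------------------------------

def log_logistic3(dose: np.ndarray, top: float, bottom: float, log_ic50: float) -> np.ndarray:
    """Three-parameter log-logistic response with unit Hill slope:
    ``bottom + (top - bottom) / (1 + 10**(log10(dose) - log_ic50))``."""
    x = np.log10(np.asarray(dose, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (x - log_ic50))


def simulate_viability(
    doses: np.ndarray | list[float],
    top: float = 1.0,
    bottom: float = 0.0,
    log_ic50: float = -8.0,
    cv: float = 0.1,
    n_replicates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate duplicate-well normalized viability at the given doses.

    Responses are ``model(dose) * (1 + Normal(0, cv))``, clipped at 0.
    Returns a tidy table with columns dose, replicate, response.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    mu = log_logistic3(doses, top, bottom, log_ic50)
    for rep in range(n_replicates):
        noise = rng.normal(0.0, cv, size=doses.size) if cv > 0 else np.zeros(doses.size)
        resp = np.maximum(mu * (1.0 + noise), 0.0)
        for d, r in zip(doses, resp):
            rows.append({"dose": d, "replicate": rep, "response": float(r)})
    return pd.DataFrame(rows)


def simulate_binucleate_counts(
    p_micronucleus: float,
    n_cells: int = 100,
    n_repeats: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Binomial counts of micronucleated cells out of ``n_cells`` scored
    binucleates, one count per biological repeat."""
    if not 0.0 <= p_micronucleus <= 1.0:
        raise ValueError("p_micronucleus must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return rng.binomial(n_cells, p_micronucleus, size=n_repeats)
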