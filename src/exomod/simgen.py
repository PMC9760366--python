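"""Synthetic screening data with ground truth.

Two generators back the test- and desk-scale workflows:

* :func:`generate_screen_plate` emits plate tables emulating an
  AlphaScreen-based extracellular-vesicle assay (raw counts per well,
  nuclei counts, vehicle and assay-control wells) under multiplicative
  log-normal well noise.
* :func:`generate_field_image` draws 16-bit three-channel epifluorescence
  fields (Hoechst nuclei / FITC granules / TRITC-phalloidin cytoplasm)
  with non-overlapping elliptical cells, Gaussian granule spots inside
  the cytoplasm, and granule-like artifact spots outside every cell.

:func:`generate_reference_screen` returns the deterministic 14-compound
two-cell-line fixture whose qualitative effect classes mirror the
published breast-cancer screen (hits, activators, dose-response ladders,
and matched intracellular LBPA levels).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError, SimulationError

PLATE_COLUMNS = [
    "well", "row", "col", "condition", "compound", "dose",
    "replicate", "alpha_counts", "nuclei", "context",
]

#: condition labels used for non-compound wells
VEHICLE = "vehicle"
POS_CTRL = "pos_ctrl"
NEG_CTRL = "neg_ctrl"


# ---------------------------------------------------------------------------
# configs


@dataclass
class ScreenSimConfig:
    """Parameters of one simulated screen plate.

    ``effect_multiplier`` scales the released-exosome signal of each test
    compound (1.0 = inert); ``viability_factor`` is the surviving cell
    fraction, which scales both the signal and the nuclei count. Both
    accept a scalar (applied to every compound) or one value per compound.
    Well-to-well noise is multiplicative log-normal with unit mean and
    coefficient of variation ``noise_cv``, drawn independently for the
    alpha counts and the nuclei count of each well.
    """

    n_compounds: int = 14
    wells_per_condition: int = 6
    baseline_alpha: float = 100_000.0
    baseline_nuclei: float = 5_000.0
    effect_multiplier: float | Sequence[float] = 1.0
    viability_factor: float | Sequence[float] = 1.0
    noise_cv: float = 0.03
    seed: int = 0
    context: str = "MDA-MB-453"
    compound_names: Sequence[str] | None = None
    # assay-control wells: exosome-rich supernatant vs. medium-only background
    pos_ctrl_multiplier: float = 2.0
    neg_ctrl_multiplier: float = 0.02

    def multipliers(self) -> np.ndarray:
        return _per_compound(self.effect_multiplier, self.n_compounds, "effect_multiplier")

    def viabilities(self) -> np.ndarray:
        return _per_compound(self.viability_factor, self.n_compounds, "viability_factor")

    def names(self) -> list[str]:
        if self.compound_names is not None:
            if len(self.compound_names) != self.n_compounds:
                raise ConfigError("compound_names length must equal n_compounds")
            return list(self.compound_names)
        return [f"C{i + 1:02d}" for i in range(self.n_compounds)]

    def validate(self) -> None:
        if self.n_compounds < 0:
            raise ConfigError("n_compounds must be non-negative")
        if self.wells_per_condition < 2:
            raise ConfigError("wells_per_condition must be >= 2")
        for name in ("baseline_alpha", "baseline_nuclei", "noise_cv",
                     "pos_ctrl_multiplier", "neg_ctrl_multiplier"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigError(f"{name} must be finite, got {v!r}")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.baseline_alpha < 0 or self.baseline_nuclei <= 0:
            raise ConfigError("baselines must be positive")
        m = self.multipliers()
        v = self.viabilities()
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ConfigError("effect_multiplier values must be finite and >= 0")
        if not np.all(np.isfinite(v)) or np.any(v <= 0) or np.any(v > 1):
            raise ConfigError("viability_factor values must lie in (0, 1]")


def _per_compound(value, n: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ConfigError(f"{name} must be scalar or length {n}")
    return arr


@dataclass
class ImageSimConfig:
    """Parameters of one simulated three-channel field.

    Geometry is in pixels; intensities are 16-bit grey levels added on top
    of ``background_level``. ``granules_per_cell`` is a Poisson mean;
    ``n_artifact_spots`` granule-like spots are placed away from every
    cell to exercise the artifact-rejection path of the quantifier.
    """

    field_shape: tuple[int, int] = (512, 512)
    n_cells: int = 12
    granules_per_cell: float = 5.0
    granule_radius_px: float = 3.0
    granule_intensity: float = 3000.0
    nucleus_radius_px: float = 14.0
    cell_radius_px: float = 34.0
    background_level: float = 200.0
    background_noise_sd: float = 10.0
    n_artifact_spots: int = 5
    nucleus_intensity: float = 7000.0
    cytoplasm_intensity: float = 2500.0
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.field_shape
        if rows < 16 or cols < 16:
            raise ConfigError("field_shape too small")
        for name in ("granules_per_cell", "granule_radius_px", "granule_intensity",
                     "nucleus_radius_px", "cell_radius_px", "background_level",
                     "background_noise_sd", "nucleus_intensity", "cytoplasm_intensity"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v!r}")
        if self.granule_radius_px <= 0 or self.nucleus_radius_px <= 0 or self.cell_radius_px <= 0:
            raise ConfigError("all radii must be > 0")
        if self.nucleus_radius_px >= self.cell_radius_px:
            raise ConfigError("nucleus_radius_px must be smaller than cell_radius_px")
        peak = self.background_level + max(
            self.granule_intensity, self.nucleus_intensity, self.cytoplasm_intensity)
        if peak > 65535:
            raise ConfigError("intensities exceed the 16-bit range")
        if self.n_cells < 0 or self.n_artifact_spots < 0:
            raise ConfigError("counts must be non-negative")


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class PlateGroundTruth:
    """True per-condition effects behind a simulated plate."""

    condition_effects: pd.DataFrame  # condition, compound, multiplier, viability, effect_class
    noise_cv: float
    seed: int


@dataclass
class ImageGroundTruth:
    """Every simulated object, exactly once, in pixel coordinates."""

    cells: list[dict] = field(default_factory=list)       # label, center, axes, angle, nucleus_radius
    granules: list[dict] = field(default_factory=list)    # cell_label, centroid, area
    artifacts: list[dict] = field(default_factory=list)   # centroid, area

    def granules_per_cell(self) -> dict[int, int]:
        counts = {c["label"]: 0 for c in self.cells}
        for g in self.granules:
            counts[g["cell_label"]] += 1
        return counts

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ImageGroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass
class FieldImage:
    """One acquired field: rows x cols x 3 uint16, channel order
    (Hoechst/nuclei, FITC/granules, TRITC/cytoplasm)."""

    pixels: np.ndarray
    well: str = ""
    field_index: int = 0
    channel_roles: tuple[str, str, str] = ("nuclei", "granule", "cytoplasm")

    @property
    def nuclei_channel(self) -> np.ndarray:
        return self.pixels[..., 0]

    @property
    def granule_channel(self) -> np.ndarray:
        return self.pixels[..., 1]

    @property
    def cytoplasm_channel(self) -> np.ndarray:
        return self.pixels[..., 2]

    def save_tiff(self, path) -> None:
        # multi-page, page order = channel order
        tifffile.imwrite(path, np.moveaxis(self.pixels, -1, 0),
                         photometric="minisblack")

    @classmethod
    def load_tiff(cls, path, well: str = "", field_index: int = 0) -> "FieldImage":
        arr = tifffile.imread(path)
        if arr.ndim != 3 or arr.shape[0] != 3:
            raise ValueError(f"expected 3-page TIFF, got shape {arr.shape}")
        return cls(np.moveaxis(arr, 0, -1), well=well, field_index=field_index)


# ---------------------------------------------------------------------------
# plate generation


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean log-normal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def _well_id(index: int) -> tuple[str, str, int]:
    """Sequential row-major position on (a stack of) 96-well plates."""
    pos = index % 96
    row = "ABCDEFGH"[pos // 12]
    col = pos % 12 + 1
    return f"{row}{col:02d}", row, col


def generate_screen_plate(
    config: ScreenSimConfig,
) -> tuple[pd.DataFrame, PlateGroundTruth]:
    """Simulate one screen plate.

    Returns a raw well table (one record per well, ``PLATE_COLUMNS``) and
    the ground truth behind it. Raw alpha counts follow
    ``baseline_alpha * multiplier * viability * LN(1, cv)`` and nuclei
    ``round(baseline_nuclei * viability * LN(1, cv))``. The plate always
    carries vehicle wells (multiplier 1) plus positive/negative
    assay-control wells for Z'-factor QC.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.wells_per_condition

    conditions: list[tuple[str, str, float, float]] = [
        (VEHICLE, VEHICLE, 1.0, 1.0),
        (POS_CTRL, POS_CTRL, config.pos_ctrl_multiplier, 1.0),
        (NEG_CTRL, NEG_CTRL, config.neg_ctrl_multiplier, 1.0),
    ]
    for name, mult, viab in zip(config.names(), config.multipliers(), config.viabilities()):
        conditions.append((name, name, float(mult), float(viab)))

    records = []
    index = 0
    for condition, compound, mult, viab in conditions:
        alpha_noise = _lognormal_factors(rng, config.noise_cv, n)
        nuc_noise = _lognormal_factors(rng, config.noise_cv, n)
        for rep in range(n):
            well, row, col = _well_id(index)
            index += 1
            alpha = config.baseline_alpha * mult * viab * alpha_noise[rep]
            nuclei = int(round(config.baseline_nuclei * viab * nuc_noise[rep]))
            records.append((well, row, col, condition, compound, 1.0,
                            rep + 1, alpha, nuclei, config.context))

    table = pd.DataFrame.from_records(records, columns=PLATE_COLUMNS)
    effects = pd.DataFrame(
        {
            "condition": [c[0] for c in conditions],
            "compound": [c[1] for c in conditions],
            "multiplier": [c[2] for c in conditions],
            "viability": [c[3] for c in conditions],
            "effect_class": [_effect_class(c[2]) for c in conditions],
        }
    )
    truth = PlateGroundTruth(condition_effects=effects, noise_cv=config.noise_cv,
                             seed=config.seed)
    return table, truth


def _effect_class(multiplier: float) -> str:
    if multiplier < 0.8:
        return "inhibitor"
    if multiplier > 1.2:
        return "activator"
    return "inert"


# ---------------------------------------------------------------------------
# field image generation

_MAX_PLACEMENT_TRIES = 200


def generate_field_image(
    config: ImageSimConfig,
) -> tuple[FieldImage, ImageGroundTruth]:
    """Simulate one three-channel field with ground truth.

    Cells are non-overlapping ellipses, each containing one nuclear disk;
    granules are Gaussian spots confined to the cytoplasm of their cell
    with a minimum centre separation of one granule diameter (they model
    resolvable puncta); artifact spots are identical Gaussian spots placed
    away from every cell. Gaussian read noise is added to all channels.

    Raises :class:`SimulationError` (carrying the achieved count) when the
    requested number of cells cannot be placed without overlap.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.field_shape

    ch_nuc = np.full((rows, cols), config.background_level, dtype=float)
    ch_gran = np.full((rows, cols), config.background_level, dtype=float)
    ch_cyto = np.full((rows, cols), config.background_level, dtype=float)

    truth = ImageGroundTruth()
    yy, xx = np.mgrid[0:rows, 0:cols]

    # --- place cells (rejection sampling, bounded retries)
    centers: list[tuple[float, float]] = []
    margin = config.cell_radius_px + 2
    min_sep = 2.1 * config.cell_radius_px
    for label in range(1, config.n_cells + 1):
        placed = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            cy = rng.uniform(margin, rows - margin)
            cx = rng.uniform(margin, cols - margin)
            if all((cy - py) ** 2 + (cx - px) ** 2 >= min_sep**2 for py, px in centers):
                placed = True
                break
        if not placed:
            raise SimulationError(
                f"could only place {label - 1} of {config.n_cells} cells "
                f"without overlap in a {rows}x{cols} field",
                achieved=label - 1,
            )
        centers.append((cy, cx))
        a = config.cell_radius_px
        b = config.cell_radius_px * rng.uniform(0.75, 1.0)
        theta = rng.uniform(0, math.pi)
        truth.cells.append(
            {"label": label, "center": [cy, cx], "axes": [a, b],
             "angle": theta, "nucleus_radius": config.nucleus_radius_px}
        )

        # cytoplasm: filled ellipse; nucleus: disk at the centre
        ct, st = math.cos(theta), math.sin(theta)
        u = (yy - cy) * ct + (xx - cx) * st
        v = -(yy - cy) * st + (xx - cx) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        ch_cyto[inside] += config.cytoplasm_intensity * rng.uniform(0.85, 1.15)
        nucleus = (yy - cy) ** 2 + (xx - cx) ** 2 <= config.nucleus_radius_px**2
        ch_nuc[nucleus] += config.nucleus_intensity * rng.uniform(0.85, 1.15)

        # --- granules inside the cytoplasm of this cell
        n_gran = int(rng.poisson(config.granules_per_cell))
        placed_pts: list[tuple[float, float]] = []
        for _ in range(n_gran):
            pt = _sample_granule_site(
                rng, (cy, cx), (a, b), theta, config, placed_pts)
            if pt is None:
                continue  # crowded cell: truth records only what was drawn
            placed_pts.append(pt)
            area = _draw_spot(ch_gran, yy, xx, pt, config)
            truth.granules.append(
                {"cell_label": label, "centroid": [pt[0], pt[1]], "area": area})

    # --- artifact spots outside every cell
    keepout = 1.3 * config.cell_radius_px
    for _ in range(config.n_artifact_spots):
        for _ in range(_MAX_PLACEMENT_TRIES):
            py = rng.uniform(4, rows - 4)
            px = rng.uniform(4, cols - 4)
            if all((py - cy) ** 2 + (px - cx) ** 2 >= keepout**2 for cy, cx in centers):
                area = _draw_spot(ch_gran, yy, xx, (py, px), config)
                truth.artifacts.append({"centroid": [py, px], "area": area})
                break
        else:
            raise SimulationError("could not place artifact spot outside cells")

    # --- read noise, 16-bit quantization
    pixels = np.stack([ch_nuc, ch_gran, ch_cyto], axis=-1)
    if config.background_noise_sd > 0:
        pixels = pixels + rng.normal(0.0, config.background_noise_sd, pixels.shape)
    pixels = np.clip(np.round(pixels), 0, 65535).astype(np.uint16)
    return FieldImage(pixels=pixels), truth


def _sample_granule_site(rng, center, axes, theta, config, existing):
    """A point in the cytoplasm (inside the shrunken ellipse, outside the
    nucleus, one diameter away from sibling granules), or None."""
    cy, cx = center
    a, b = axes
    r = config.granule_radius_px
    a_in, b_in = a - r - 1, b - r - 1
    ct, st = math.cos(theta), math.sin(theta)
    min_sep2 = (2 * r + 1) ** 2
    inner2 = (config.nucleus_radius_px + r) ** 2
    for _ in range(_MAX_PLACEMENT_TRIES):
        # uniform in the shrunken ellipse via polar transform
        rho = math.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * math.pi)
        u = a_in * rho * math.cos(phi)
        v = b_in * rho * math.sin(phi)
        py = cy + u * ct - v * st
        px = cx + u * st + v * ct
        if (py - cy) ** 2 + (px - cx) ** 2 <= inner2:
            continue
        if any((py - gy) ** 2 + (px - gx) ** 2 < min_sep2 for gy, gx in existing):
            continue
        return py, px
    return None


def _draw_spot(channel, yy, xx, point, config) -> float:
    """Add a Gaussian spot; return its nominal (half-maximum) area in px."""
    py, px = point
    sigma = config.granule_radius_px / 1.5
    d2 = (yy - py) ** 2 + (xx - px) ** 2
    channel += config.granule_intensity * np.exp(-d2 / (2 * sigma * sigma))
    return float(2 * math.pi * math.log(2) * sigma * sigma)


# ---------------------------------------------------------------------------
# deterministic reference screen (two cell-line contexts)

MDA_CONTEXT = "MDA-MB-453"
MCF7_CONTEXT = "MCF7"

#: the 14 test compounds of the reference screen
TEST_COMPOUNDS = [
    "docetaxel", "biscurcumin", "primaquine", "doxorubicin", "dinaciclib",
    "exemestane", "alendronate", "fasudil", "dasatinib", "neratinib",
    "tamoxifen", "afatinib", "fulvestrant", "omeprazole",
]

#: assay controls run alongside the test set
CONTROL_COMPOUNDS = ["Go6983", "GW4869", "spiroepoxide"]

# per-context true effect multipliers on the extracellular (ExoScreen)
# signal. Inhibitors sit well below the 80% cut-off, activators well above
# 120%; magnitudes are invented, classes follow the published screen.
_EXO_MULT = {
    MDA_CONTEXT: {
        "docetaxel": 0.55, "biscurcumin": 0.65, "primaquine": 0.60,
        "doxorubicin": 0.70, "dinaciclib": 1.45, "exemestane": 1.35,
        "alendronate": 1.50, "fasudil": 1.40, "dasatinib": 1.55,
        "neratinib": 1.30, "tamoxifen": 1.35, "afatinib": 1.45,
        "fulvestrant": 1.30, "omeprazole": 1.25,
        "Go6983": 0.45, "GW4869": 0.50, "spiroepoxide": 0.50,
    },
    MCF7_CONTEXT: {
        "docetaxel": 0.60, "biscurcumin": 0.55, "primaquine": 0.65,
        "doxorubicin": 0.60, "dinaciclib": 0.70, "exemestane": 1.40,
        "alendronate": 1.55, "fasudil": 1.35, "dasatinib": 1.50,
        "neratinib": 1.30, "tamoxifen": 1.35, "afatinib": 1.40,
        "fulvestrant": 1.30, "omeprazole": 1.25,
        "Go6983": 0.45, "GW4869": 0.50, "spiroepoxide": 0.50,
    },
}

# per-context true multipliers on intracellular LBPA granules per cell.
# Release inhibitors retain vesicles (high), biogenesis inhibitors deplete
# them (low), biogenesis activators raise both readouts; compounds with
# no corroborating intracellular change sit at 1.0.
_LBPA_MULT = {
    MDA_CONTEXT: {
        "docetaxel": 1.6, "biscurcumin": 1.55, "primaquine": 1.6,
        "doxorubicin": 1.5, "dinaciclib": 1.0, "exemestane": 1.0,
        "alendronate": 1.5, "fasudil": 1.45, "dasatinib": 1.5,
        "neratinib": 1.0, "tamoxifen": 1.45, "afatinib": 1.0,
        "fulvestrant": 1.0, "omeprazole": 1.0,
        "Go6983": 1.7, "GW4869": 0.5, "spiroepoxide": 0.45,
    },
    MCF7_CONTEXT: {
        "docetaxel": 1.6, "biscurcumin": 1.6, "primaquine": 1.55,
        "doxorubicin": 1.5, "dinaciclib": 1.5, "exemestane": 1.45,
        "alendronate": 1.5, "fasudil": 1.0, "dasatinib": 1.5,
        "neratinib": 1.0, "tamoxifen": 1.0, "afatinib": 1.0,
        "fulvestrant": 1.0, "omeprazole": 1.0,
        "Go6983": 1.7, "GW4869": 0.5, "spiroepoxide": 0.45,
    },
}

# MCF7 dose-response ladders (multiplier per dose, doses in relative units).
# Biscurcumin falls at every dose; doxorubicin and dinaciclib rebound at
# the highest dose; docetaxel and primaquine show no dose trend.
_DOSE_LEVELS = [0.25, 0.5, 1.0, 2.0]
_DOSE_MULT = {
    "biscurcumin": [0.85, 0.70, 0.55, 0.45],
    "doxorubicin": [0.80, 0.65, 0.55, 0.75],
    "dinaciclib": [0.85, 0.70, 0.60, 0.80],
    "docetaxel": [0.60, 0.62, 0.58, 0.61],
    "primaquine": [0.65, 0.63, 0.66, 0.64],
}

_FIXTURE_SEED = 20220914
_FIXTURE_NOISE_CV = 0.03
_FIXTURE_LBPA_BASE = 4.0  # granules per cell, vehicle level


@dataclass
class ReferenceScreen:
    """The deterministic two-context reference screen.

    ``exoscreen``: raw well table (``PLATE_COLUMNS``) for both contexts;
    ``lbpa``: well-level granules-per-cell table for the same conditions;
    ``dose_response``: MCF7 dose-ladder wells for the five hits;
    ``classes``: per (context, compound) true qualitative class — metadata
    only, never consumed by the analysis code.
    """

    exoscreen: pd.DataFrame
    lbpa: pd.DataFrame
    dose_response: pd.DataFrame
    classes: pd.DataFrame


def generate_reference_screen() -> ReferenceScreen:
    """Build the deterministic 14-compound, two-context fixture.

    Regenerating always yields identical tables (internal fixed seed)."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    n = 6
    exo_frames, lbpa_rows, class_rows = [], [], []

    for context in (MDA_CONTEXT, MCF7_CONTEXT):
        mults = _EXO_MULT[context]
        names = TEST_COMPOUNDS + CONTROL_COMPOUNDS
        cfg = ScreenSimConfig(
            n_compounds=len(names),
            wells_per_condition=n,
            effect_multiplier=[mults[c] for c in names],
            viability_factor=0.95,  # all concentrations pre-selected non-toxic
            noise_cv=_FIXTURE_NOISE_CV,
            seed=int(rng.integers(2**31)),
            context=context,
            compound_names=names,
        )
        table, _ = generate_screen_plate(cfg)
        exo_frames.append(table)

        lmults = _LBPA_MULT[context]
        for condition in [VEHICLE] + names:
            lm = 1.0 if condition == VEHICLE else lmults[condition]
            noise = _lognormal_factors(rng, _FIXTURE_NOISE_CV, n)
            for rep in range(n):
                lbpa_rows.append(
                    (f"L{len(lbpa_rows) + 1:03d}", condition, condition, 1.0,
                     rep + 1, _FIXTURE_LBPA_BASE * lm * noise[rep], context))
        for compound in names:
            em, lm = mults[compound], lmults[compound]
            if em < 0.8:
                cls = "release_inhibitor" if lm > 1.2 else "biogenesis_inhibitor"
            elif em > 1.2:
                cls = "biogenesis_activator" if lm > 1.2 else "activator_uncorroborated"
            else:
                cls = "inert"
            class_rows.append((context, compound,
                               "control" if compound in CONTROL_COMPOUNDS else "test",
                               cls))

    dose_rows = []
    for compound, series in _DOSE_MULT.items():
        for dose, mult in zip(_DOSE_LEVELS, series):
            noise = _lognormal_factors(rng, _FIXTURE_NOISE_CV, n)
            for rep in range(n):
                dose_rows.append((compound, dose, rep + 1,
                                  100.0 * mult * noise[rep], MCF7_CONTEXT))

    exoscreen = pd.concat(exo_frames, ignore_index=True)
    lbpa = pd.DataFrame(
        lbpa_rows,
        columns=["well", "condition", "compound", "dose", "replicate",
                 "granules_per_cell", "context"],
    )
    dose_response = pd.DataFrame(
        dose_rows, columns=["compound", "dose", "replicate", "percent", "context"])
    classes = pd.DataFrame(class_rows,
                           columns=["context", "compound", "role", "true_class"])
    return ReferenceScreen(exoscreen=exoscreen, lbpa=lbpa,
                           dose_response=dose_response, classes=classes)
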