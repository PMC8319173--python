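"""Synthetic data with known ground truth for the speck screening pipeline.

Three generators, all seed-reproducible from a single integer:

* :func:`generate_field` renders a two-channel microscopy field (nuclear
  stain + ASC reporter) of blob-like macrophages, a chosen fraction of
  which carry a single bright ~1 um speck, plus a minority of
  over-bright reporter cells that the imaging pipeline must reject.
* :func:`generate_plate` / :func:`generate_screen` draw 384-well plate
  datasets with vehicle-stimulated maximum-speck negative controls,
  half-maximal and fully inhibiting MCC950 positive controls, and 280
  library wells carrying planted inhibition/activation effects.
* :func:`generate_dose_response` draws six-point semi-log
  concentration-response series from a four-parameter logistic with
  multiplicative noise; presets encode the validated reference
  compounds (MCC950, PU H71, MPC-3100, momelotinib, CEP-33779, ACHP,
  MLN120B) in both priming and activation modes.

Every random draw flows from ``numpy.random.default_rng(seed)``; equal
spec + seed gives bit-identical images and value-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .imaging import FieldImagePair
from .qc import PlateLayout, well_name

__all__ = [
    "IntensityLevels",
    "FieldSpec",
    "CellTruth",
    "FieldTruth",
    "DoseResponseSpec",
    "ScreenSpec",
    "PlateDataset",
    "PlacementError",
    "DOSE_RESPONSE_PRESETS",
    "stimulated_field_spec",
    "unstimulated_field_spec",
    "dose_response_preset",
    "four_pl",
    "generate_field",
    "generate_well_fields",
    "generate_plate",
    "generate_screen",
    "generate_dose_response",
]


class PlacementError(RuntimeError):
    """Nuclei cannot be placed without overlap at the given geometry."""


class IntensityLevels(BaseModel):
    """Mean intensities (arbitrary camera units) of the rendered classes."""

    background: float = 100.0
    nucleus: float = 1000.0
    cytoplasm: float = 300.0
    speck: float = 3000.0
    bright_cell: float = 4000.0


class FieldSpec(BaseModel):
    """Geometry, composition and noise of one synthetic field.

    Defaults emulate a 10x wide-field sCMOS acquisition of iBMDMs seeded
    at screening density: a 2048 x 2048 px field at 0.65 um/px holds the
    ~1700 cells that 10,000 cells/well spread over two fields of a
    384-well well imply.
    """

    width_px: int = Field(default=2048, ge=8)
    height_px: int = Field(default=2048, ge=8)
    pixel_size_um: float = Field(default=0.65, gt=0)
    n_cells: int = Field(default=1700, ge=0)
    speck_fraction: float = Field(default=0.425, ge=0, le=1)
    bright_cell_fraction: float = Field(default=0.05, ge=0, le=1)
    nucleus_radius_um: float = Field(default=5.0, gt=0)
    cell_radius_um: float = Field(default=11.0, gt=0)
    speck_diameter_um: float = Field(default=1.0, gt=0)
    intensity_levels: IntensityLevels = Field(default_factory=IntensityLevels)
    noise_sd: float = Field(default=20.0, ge=0)
    binomial_counts: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "FieldSpec":
        if self.speck_fraction + self.bright_cell_fraction > 1:
            raise ValueError("speck_fraction + bright_cell_fraction must be <= 1")
        if self.cell_radius_um < self.nucleus_radius_um:
            raise ValueError("cell_radius_um must be >= nucleus_radius_um")
        return self


def stimulated_field_spec(**overrides) -> FieldSpec:
    """Default LPS + nigericin stimulated field (~35-50% speck-positive)."""
    return FieldSpec(**overrides)


def unstimulated_field_spec(**overrides) -> FieldSpec:
    """Basal field: diffuse reporter, essentially no specks."""
    overrides.setdefault("speck_fraction", 0.01)
    return FieldSpec(**overrides)


@dataclass(frozen=True)
class CellTruth:
    cell_id: int
    centroid_xy_px: tuple[float, float]  # (x, y) = (col, row)
    has_speck: bool
    is_bright: bool


@dataclass(frozen=True)
class FieldTruth:
    """Per-cell ground truth emitted alongside a synthetic field."""

    cells: list[CellTruth]

    @property
    def n_cells_total(self) -> int:
        return len(self.cells)

    @property
    def n_speck_positive(self) -> int:
        return sum(c.has_speck for c in self.cells)

    @property
    def n_bright(self) -> int:
        return sum(c.is_bright for c in self.cells)

    @property
    def pct_speck_positive(self) -> float:
        if not self.cells:
            return 0.0
        return 100.0 * self.n_speck_positive / self.n_cells_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in self.cells],
                "x_px": [c.centroid_xy_px[0] for c in self.cells],
                "y_px": [c.centroid_xy_px[1] for c in self.cells],
                "has_speck": [c.has_speck for c in self.cells],
                "is_bright": [c.is_bright for c in self.cells],
            }
        )


def _place_centers(
    rng: np.random.Generator, spec: FieldSpec
) -> np.ndarray:
    """Rejection-sample non-overlapping nucleus centers on a hash grid."""
    n = spec.n_cells
    if n == 0:
        return np.empty((0, 2))
    r_px = spec.nucleus_radius_um / spec.pixel_size_um
    min_sep = 2.0 * r_px + 2.0
    margin = spec.cell_radius_um / spec.pixel_size_um + 1.0
    lo_x, hi_x = margin, spec.width_px - margin
    lo_y, hi_y = margin, spec.height_px - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise PlacementError(
            f"field {spec.width_px}x{spec.height_px} px too small for cell "
            f"radius {spec.cell_radius_um} um at {spec.pixel_size_um} um/px"
        )
    cell = min_sep
    nx = int((spec.width_px) // cell) + 1
    ny = int((spec.height_px) // cell) + 1
    grid: dict[tuple[int, int], list[int]] = {}
    centers: list[tuple[float, float]] = []
    attempts, max_attempts = 0, 200 * n + 1000
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {n} non-overlapping nuclei of radius "
                f"{spec.nucleus_radius_um} um in a {spec.width_px}x"
                f"{spec.height_px} px field (placed {len(centers)}); "
                "reduce n_cells or enlarge the field"
            )
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        gx, gy = int(x // cell), int(y // cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for idx in grid.get((gx + dx, gy + dy), ()):
                    cx, cy = centers[idx]
                    if (cx - x) ** 2 + (cy - y) ** 2 < min_sep**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((gx, gy), []).append(len(centers))
            centers.append((x, y))
    return np.asarray(centers)


def _disk_mask(radius_px: float) -> np.ndarray:
    r = int(math.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx**2 + yy**2) <= radius_px**2


def _paint(img: np.ndarray, mask: np.ndarray, cx: float, cy: float, value: float) -> None:
    """Composite a disk patch at (cx, cy) with per-pixel maximum."""
    r = mask.shape[0] // 2
    ix, iy = int(round(cx)), int(round(cy))
    x0, x1 = ix - r, ix + r + 1
    y0, y1 = iy - r, iy + r + 1
    mx0, my0 = max(0, -x0), max(0, -y0)
    x0, y0 = max(0, x0), max(0, y0)
    x1, y1 = min(img.shape[1], x1), min(img.shape[0], y1)
    sub = mask[my0 : my0 + (y1 - y0), mx0 : mx0 + (x1 - x0)]
    region = img[y0:y1, x0:x1]
    region[sub] = np.maximum(region[sub], value)


def _realize_counts(rng: np.random.Generator, spec: FieldSpec) -> tuple[int, int]:
    if spec.binomial_counts:
        n_bright = int(rng.binomial(spec.n_cells, spec.bright_cell_fraction))
        n_speck = int(rng.binomial(spec.n_cells - n_bright, spec.speck_fraction))
    else:
        n_bright = round(spec.n_cells * spec.bright_cell_fraction)
        n_speck = round(spec.n_cells * spec.speck_fraction)
        n_speck = min(n_speck, spec.n_cells - n_bright)
    return n_bright, n_speck


def generate_field(spec: FieldSpec) -> tuple[FieldImagePair, FieldTruth]:
    """Render one two-channel field and its per-cell ground truth.

    The nuclear channel holds non-overlapping nucleus disks; the
    reporter channel holds a diffuse cytoplasm disk per cell, one bright
    punctum per speck-positive cell (placed inside the pseudo-cell
    region an analyzer would reconstruct) and uniformly saturating
    signal over the footprint of over-bright cells.  Bright cells never
    carry a rendered speck.  Speck counts are deterministic
    (``round(n_cells * speck_fraction)``, cells chosen by seeded
    permutation) unless ``binomial_counts`` is set.
    """
    rng = np.random.default_rng(spec.seed)
    lv = spec.intensity_levels
    centers = _place_centers(rng, spec)
    n_bright, n_speck = _realize_counts(rng, spec)
    order = rng.permutation(spec.n_cells)
    bright_ids = set(order[:n_bright].tolist())
    speck_ids = set(order[n_bright : n_bright + n_speck].tolist())

    nuc = np.full((spec.height_px, spec.width_px), lv.background, dtype=np.float32)
    rep = np.full_like(nuc, lv.background)
    px = spec.pixel_size_um
    nuc_mask = _disk_mask(spec.nucleus_radius_um / px)
    cell_mask = _disk_mask(spec.cell_radius_um / px)
    speck_r_px = max(1.0, spec.speck_diameter_um / px / 2.0)
    speck_mask = _disk_mask(speck_r_px)

    cells: list[CellTruth] = []
    for i, (cx, cy) in enumerate(centers):
        is_bright = i in bright_ids
        has_speck = i in speck_ids
        _paint(nuc, nuc_mask, cx, cy, lv.nucleus)
        _paint(rep, cell_mask, cx, cy, lv.bright_cell if is_bright else lv.cytoplasm)
        if has_speck:
            # punctum placed well inside the cell footprint so that the
            # reconstructed pseudo-cell region contains its centroid
            rho = rng.uniform(0.0, 0.7 * spec.cell_radius_um / px)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            _paint(rep, speck_mask, cx + rho * math.cos(theta),
                   cy + rho * math.sin(theta), lv.speck)
        cells.append(CellTruth(i, (float(cx), float(cy)), has_speck, is_bright))

    if spec.noise_sd > 0:
        nuc += rng.normal(0.0, spec.noise_sd, nuc.shape).astype(np.float32)
        rep += rng.normal(0.0, spec.noise_sd, rep.shape).astype(np.float32)
        np.clip(nuc, 0.0, None, out=nuc)
        np.clip(rep, 0.0, None, out=rep)

    pair = FieldImagePair(nuclear_channel=nuc, reporter_channel=rep,
                          pixel_size_um=spec.pixel_size_um)
    return pair, FieldTruth(cells=cells)


def generate_well_fields(
    spec: FieldSpec, n_fields: int = 2
) -> tuple[list[FieldImagePair], list[FieldTruth]]:
    """Generate the fields imaged from one well (field seeds spawned from spec.seed)."""
    ss = np.random.SeedSequence(spec.seed)
    pairs, truths = [], []
    for child in ss.spawn(n_fields):
        sub = spec.model_copy(update={"seed": int(child.generate_state(1)[0] % 2**31)})
        p, t = generate_field(sub)
        pairs.append(p)
        truths.append(t)
    return pairs, truths


# ---------------------------------------------------------------------------
# concentration-response series


def four_pl(x, bottom: float, top: float, ic50: float, hill: float):
    """Descending four-parameter logistic: top at low x, bottom at high x."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


class DoseResponseSpec(BaseModel):
    """Six-point semi-log concentration-response series specification.

    ``top`` is pinned at 100% of control; responses are percent speck
    formation relative to the stimulated control.  Replicate noise is
    multiplicative Gaussian with coefficient of variation ``noise_cv``,
    truncated at zero.
    """

    top: Literal[100] = 100
    bottom: float = Field(default=0.0, ge=0, le=100)
    ic50: float = Field(gt=0, description="molar")
    hill: float = Field(default=1.0, gt=0)
    start_conc: float = Field(gt=0, description="molar, highest concentration")
    n_points: int = Field(default=6, ge=2)
    dilution_factor: float = Field(default=math.sqrt(10.0), gt=1)
    n_replicates: int = Field(default=3, ge=1)
    noise_cv: float = Field(default=0.10, ge=0)
    seed: int = 0
    compound_id: str = "compound"
    mode: Literal["priming", "activation"] = "priming"


#: (ic50 molar, bottom %) per mode for the screen's validated reference
#: compounds; MCC950 is the assay positive control (equipotent in the
#: priming and activation protocols), the rest are the six annotated
#: hits taken forward for validation.
DOSE_RESPONSE_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "MCC950": {"priming": (45e-9, 0.0), "activation": (45e-9, 0.0)},
    "PU H71": {"priming": (0.097e-6, 40.0), "activation": (0.2e-6, 40.0)},
    "MPC-3100": {"priming": (0.7e-6, 0.0), "activation": (2e-6, 0.0)},
    "momelotinib": {"priming": (0.6e-6, 0.0), "activation": (1e-6, 50.0)},
    "CEP-33779": {"priming": (1e-6, 50.0), "activation": (2e-6, 50.0)},
    "ACHP": {"priming": (0.1e-6, 0.0), "activation": (0.2e-6, 10.0)},
    "MLN120B": {"priming": (1.8e-6, 0.0), "activation": (2e-6, 10.0)},
}


def dose_response_preset(
    compound: str, mode: str = "priming", seed: int = 0, **overrides
) -> DoseResponseSpec:
    """Spec for a reference compound: six half-log points bracketing the IC50."""
    try:
        ic50, bottom = DOSE_RESPONSE_PRESETS[compound][mode]
    except KeyError as exc:
        raise KeyError(
            f"no preset for compound {compound!r} mode {mode!r}; "
            f"known: {sorted(DOSE_RESPONSE_PRESETS)}"
        ) from exc
    params = dict(
        bottom=bottom,
        ic50=ic50,
        start_conc=ic50 * 10**1.5,
        seed=seed,
        compound_id=compound,
        mode=mode,
    )
    params.update(overrides)
    return DoseResponseSpec(**params)


def generate_dose_response(spec: DoseResponseSpec) -> pd.DataFrame:
    """Draw a replicate concentration-response table from a 4PL.

    Concentrations form the descending geometric series
    ``start_conc / dilution_factor**k``; each replicate response is the
    noiseless 4PL mean times ``max(0, 1 + noise_cv * z)`` with standard
    normal ``z``.
    """
    rng = np.random.default_rng(spec.seed)
    conc = spec.start_conc / spec.dilution_factor ** np.arange(spec.n_points)
    mean = four_pl(conc, spec.bottom, spec.top, spec.ic50, spec.hill)
    rows = []
    for rep in range(1, spec.n_replicates + 1):
        mult = np.maximum(0.0, 1.0 + spec.noise_cv * rng.standard_normal(spec.n_points))
        for c, y in zip(conc, mean * mult):
            rows.append((spec.compound_id, spec.mode, c, y, rep))
    return pd.DataFrame(
        rows, columns=["compound_id", "mode", "conc_M", "response_pct", "replicate"]
    )


# ---------------------------------------------------------------------------
# plate and screen datasets


class EffectSizes(BaseModel):
    """Planted effect magnitudes (percent of the stimulated signal)."""

    inhibition_low: float = 40.0
    inhibition_high: float = 100.0
    activation_low: float = 40.0
    activation_high: float = 100.0


class ScreenSpec(BaseModel):
    """Specification of a synthetic single-concentration screen.

    Control distributions reflect the assay's observed behaviour: the
    maximum-speck negative control sits at ~40% speck-positive cells
    (the middle of the stimulated 35-50% range) with 5% CV, MCC950 at
    5 uM abolishes specks and at 50 nM halves them — noise levels at
    which the simulated plates reproduce the screen's reported QC
    metrics (robust Z' ~0.8 for the 5 uM control, SSMD ~19, CV 5%).
    """

    n_compounds: int = Field(default=280, ge=1)
    inhibitor_fraction: float = Field(default=0.02, ge=0, le=1)
    activator_fraction: float = Field(default=0.01, ge=0, le=1)
    effect_sizes: EffectSizes = Field(default_factory=EffectSizes)
    control_noise_cv: float = Field(default=0.05, gt=0)
    neg_ctrl_mean: float = Field(default=40.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ScreenSpec":
        if self.inhibitor_fraction + self.activator_fraction > 1:
            raise ValueError("inhibitor + activator fractions must sum to <= 1")
        return self


#: (mean, sd) of raw %-speck-positive readouts for the non-library roles,
#: relative to a negative-control mean of 40 with 6% CV.
def _role_distributions(spec: ScreenSpec) -> dict[str, tuple[float, float]]:
    m = spec.neg_ctrl_mean
    cv = spec.control_noise_cv
    return {
        "neg_ctrl_max": (m, m * cv),
        "pos_ctrl_mcc950_50nM": (0.5 * m, 0.5 * m * cv),
        "pos_ctrl_mcc950_5uM": (0.05 * m, 0.4),
        "cells_alone": (0.025 * m, 0.3),
        "vehicle_only": (0.04 * m, 0.4),
    }


@dataclass(frozen=True)
class PlateDataset:
    """One 384-well plate: layout plus the per-well results table.

    ``table`` columns: plate_id, well, role, compound_id, true_effect,
    value.  ``true_effect`` is the planted percent inhibition (negative
    for activators, 0 for inactive library wells, NaN for controls).
    """

    plate_id: str
    layout: PlateLayout
    table: pd.DataFrame

    @property
    def truth(self) -> pd.DataFrame:
        """Planted-effect table for library wells."""
        lib = self.table[self.table["role"] == "library"]
        return lib[["plate_id", "well", "compound_id", "true_effect"]].reset_index(
            drop=True
        )


def generate_plate(
    screen_spec: ScreenSpec,
    layout: PlateLayout | None = None,
    plate_id: str = "P0001",
    compound_offset: int = 0,
    n_library_compounds: int | None = None,
) -> PlateDataset:
    """Draw one plate of well-level readouts with planted library effects.

    Library wells beyond ``n_library_compounds`` (when the final plate
    of a campaign is not full) are dispensed as vehicle-only mock
    library wells at the negative-control level with effect 0.
    """
    layout = layout or PlateLayout.default()
    rng = np.random.default_rng(screen_spec.seed)
    dists = _role_distributions(screen_spec)
    lib_wells = layout.library_wells
    n_lib = len(lib_wells) if n_library_compounds is None else min(
        n_library_compounds, len(lib_wells)
    )

    # planted effects: percent inhibition (+) or activation (-)
    es = screen_spec.effect_sizes
    u = rng.random(n_lib)
    effects = np.zeros(n_lib)
    inh = u < screen_spec.inhibitor_fraction
    act = (u >= screen_spec.inhibitor_fraction) & (
        u < screen_spec.inhibitor_fraction + screen_spec.activator_fraction
    )
    effects[inh] = rng.uniform(es.inhibition_low, es.inhibition_high, inh.sum())
    effects[act] = -rng.uniform(es.activation_low, es.activation_high, act.sum())

    rows = []
    lib_idx = 0
    for row in range(16):
        for col in range(24):
            w = well_name(row, col)
            role = layout.roles[w]
            if role == "library" and lib_idx < n_lib:
                eff = effects[lib_idx]
                mean = max(0.0, screen_spec.neg_ctrl_mean * (1.0 - eff / 100.0))
                val = mean * max(
                    0.0, 1.0 + screen_spec.control_noise_cv * rng.standard_normal()
                )
                cid = f"CPD{compound_offset + lib_idx + 1:06d}"
                rows.append((plate_id, w, role, cid, eff, val))
                lib_idx += 1
            elif role == "library":
                mean, _ = dists["neg_ctrl_max"]
                val = mean * max(
                    0.0, 1.0 + screen_spec.control_noise_cv * rng.standard_normal()
                )
                rows.append((plate_id, w, role, "DMSO", 0.0, val))
            else:
                mean, sd = dists[role]
                val = max(0.0, mean + sd * rng.standard_normal())
                rows.append((plate_id, w, role, "", float("nan"), val))
    table = pd.DataFrame(
        rows, columns=["plate_id", "well", "role", "compound_id", "true_effect", "value"]
    )
    return PlateDataset(plate_id=plate_id, layout=layout, table=table)


def generate_screen(
    spec: ScreenSpec, layout: PlateLayout | None = None
) -> list[PlateDataset]:
    """Generate a whole campaign: plates of 280 compounds until n_compounds."""
    layout = layout or PlateLayout.default()
    cap = len(layout.library_wells)
    n_plates = math.ceil(spec.n_compounds / cap)
    ss = np.random.SeedSequence(spec.seed)
    plates = []
    for i, child in enumerate(ss.spawn(n_plates)):
        sub = spec.model_copy(
            update={"seed": int(child.generate_state(1)[0] % 2**31)}
        )
        remaining = spec.n_compounds - i * cap
        plates.append(
            generate_plate(
                sub,
                layout,
                plate_id=f"P{i + 1:04d}",
                compound_offset=i * cap,
                n_library_compounds=min(cap, remaining),
            )
        )
    return plates
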