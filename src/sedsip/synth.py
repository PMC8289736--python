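"""Synthetic-data generators with known ground truth.

Three generators emulate the study conditions so that every pipeline stage
is testable without raw data:

* a CsCl gradient experiment: each taxon's DNA bands as a Gaussian in
  buoyant density, centred by its GC content and 13C atom fraction, and
  per-fraction taxon proportions are sampled to read counts by a
  multinomial at the sequencing depth;
* a microcosm time series: substrate-responsive taxa multiply their base
  abundance by a per-time-point response profile in the substrate
  treatment only, with (Dirichlet-)multinomial count sampling over
  triplicate microcosms;
* a NanoSIMS acquisition: elliptical cells on a background, per-pixel
  Poisson ion counts per plane, the C2-family split into 12C2-/13C12C-/
  13C2- by random isotope pairing (13C2- generated then discarded, as the
  instrument does not detect it), optional inter-plane drift and dead-time
  distortion.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gradient import (
    AbundanceTable,
    TREATMENT_C12,
    TREATMENT_C13,
    TREATMENT_NO_SUBSTRATE,
)
from .nanosims import IonCountStack, RoiSet

#: 13C atom fraction of unlabelled biomass used as the density-model zero point
NATURAL_ABUNDANCE_13C = 0.0107
#: slightly higher default for simulated biomass (at% 1.08)
NATURAL_ABUNDANCE_BIOMASS = 0.0108


# ---------------------------------------------------------------------------
# gradient / microcosm generators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthTaxon:
    """Generative description of one ASV.

    ``atom_fraction_13c`` is the 13C atom fraction its DNA carries in the
    13C treatment (unlabelled taxa stay at natural abundance);
    ``response_profile`` maps time points to abundance multipliers applied
    in the substrate treatment of the microcosm generator.
    """

    asv_id: str
    group_id: str = ""
    gc_content: float = 0.5
    atom_fraction_13c: float = NATURAL_ABUNDANCE_13C
    base_abundance: float = 0.01
    response_profile: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if not 0.2 <= self.gc_content <= 0.8:
            raise ValueError(f"gc_content out of [0.2, 0.8]: {self.gc_content}")
        if not NATURAL_ABUNDANCE_13C <= self.atom_fraction_13c <= 1.0:
            raise ValueError("atom_fraction_13c out of range")
        if self.base_abundance < 0:
            raise ValueError("base_abundance must be >= 0")


@dataclass(frozen=True)
class DensityModel:
    """Linear buoyant-density model: rho0 + gc_slope*GC + label shift.

    The constants are literature conventions for CsCl gradients (an
    unlabelled 50%-GC genome bands near 1.709 g/ml; full 13C labelling
    adds ~0.036 g/ml), configurable and not asserted as measured values.
    """

    rho0: float = 1.660
    gc_slope: float = 0.098
    full_label_shift: float = 0.036

    def __post_init__(self) -> None:
        if min(self.rho0, self.gc_slope, self.full_label_shift) <= 0:
            raise ValueError("density-model constants must be positive")


def buoyant_density(taxon: SynthTaxon, model: DensityModel = DensityModel(),
                    atom_fraction: float | None = None) -> float:
    """Deterministic band centre (g/ml) of a taxon's DNA.

    rho = rho0 + gc_slope*GC + full_label_shift * (x - x_nat)/(1 - x_nat)
    with x the 13C atom fraction (``atom_fraction`` overrides the taxon's
    configured value, e.g. to force natural abundance in the 12C arm).
    """
    x = taxon.atom_fraction_13c if atom_fraction is None else atom_fraction
    label_term = (x - NATURAL_ABUNDANCE_13C) / (1.0 - NATURAL_ABUNDANCE_13C)
    return model.rho0 + model.gc_slope * taxon.gc_content + model.full_label_shift * label_term


@dataclass
class SynthGradientConfig:
    """Full generative specification of a gradient experiment.

    The density grid spans the recovered range of the fractionation
    (~20 fractions; densities below ~1.713 g/ml are where low-GC
    unlabelled DNA bands).  ``uniform_carryover`` spreads that fraction of
    every taxon's DNA uniformly across the gradient, emulating smearing /
    carryover so that heavy control fractions are not empty.
    """

    taxa: list[SynthTaxon] = field(default_factory=list)
    n_fractions: int = 20
    density_min: float = 1.690
    density_max: float = 1.760
    band_sigma: float = 0.004
    depth: int = 20000
    timepoints: tuple[int, ...] = (4, 10, 13, 24)
    seed: int = 0
    density_model: DensityModel = field(default_factory=DensityModel)
    uniform_carryover: float = 0.02

    def __post_init__(self) -> None:
        if self.n_fractions < 5:
            raise ValueError("need at least 5 fractions")
        if self.depth < 1000:
            raise ValueError("depth must be >= 1000")
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be positive")
        if not 0.0 <= self.uniform_carryover < 1.0:
            raise ValueError("uniform_carryover must be in [0, 1)")
        if self.density_max <= self.density_min:
            raise ValueError("degenerate density grid")

    @property
    def density_grid(self) -> np.ndarray:
        return np.linspace(self.density_min, self.density_max, self.n_fractions)


def expected_fraction_proportions(
    config: SynthGradientConfig, treatment: str
) -> np.ndarray:
    """Expected taxon proportions per fraction (taxa x fractions).

    Each taxon's DNA mass is spread as a Gaussian over the density grid,
    centred at its buoyant density (natural abundance forced in the 12C
    arm), normalised per taxon, mixed with the uniform carryover term, and
    the per-fraction composition renormalised (sequencing sees
    proportions, not absolute mass).
    """
    grid = config.density_grid
    mass = np.empty((len(config.taxa), grid.size))
    for i, taxon in enumerate(config.taxa):
        x = taxon.atom_fraction_13c if treatment == TREATMENT_C13 else NATURAL_ABUNDANCE_13C
        centre = buoyant_density(taxon, config.density_model, atom_fraction=x)
        band = np.exp(-0.5 * ((grid - centre) / config.band_sigma) ** 2)
        total = band.sum()
        if total == 0:
            band = np.full_like(grid, 1.0 / grid.size)
        else:
            band = band / total
        band = (1.0 - config.uniform_carryover) * band + config.uniform_carryover / grid.size
        mass[i] = taxon.base_abundance * band
    col = mass.sum(axis=0)
    if (col == 0).any():
        raise ValueError("a fraction has zero expected mass; degenerate config")
    return mass / col


def simulate_gradient_experiment(
    config: SynthGradientConfig,
) -> tuple[AbundanceTable, dict]:
    """Simulate the gradient amplicon counts for both treatments.

    Returns a counts-mode AbundanceTable (samples = treatment x time point
    x fraction) and a ground-truth manifest recording the labelled taxa,
    expected per-fraction proportions and seed.
    """
    if not config.taxa:
        raise ValueError("config has no taxa")
    rng = np.random.default_rng(config.seed)
    grid = config.density_grid
    asv_ids = [t.asv_id for t in config.taxa]
    expected = {
        tr: expected_fraction_proportions(config, tr)
        for tr in (TREATMENT_C13, TREATMENT_C12)
    }
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for tr in (TREATMENT_C13, TREATMENT_C12):
        for tp in config.timepoints:
            gradient_id = f"{tr}_d{tp}"
            for f, dens in enumerate(grid):
                sid = f"{gradient_id}_f{f:02d}"
                counts = rng.multinomial(config.depth, expected[tr][:, f])
                columns[sid] = counts
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "gradient_id": gradient_id,
                        "treatment": tr,
                        "timepoint_days": tp,
                        "density": float(dens),
                        "replicate": "",
                    }
                )
    data = pd.DataFrame(columns, index=asv_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    table = AbundanceTable(data=data, meta=meta, mode="counts")
    labelled = [t.asv_id for t in config.taxa
                if t.atom_fraction_13c > NATURAL_ABUNDANCE_13C]
    truth = {
        "labelled_asvs": labelled,
        "groups": {t.asv_id: t.group_id for t in config.taxa},
        "expected_proportions": {tr: expected[tr].tolist() for tr in expected},
        "density_grid": grid.tolist(),
        "seed": config.seed,
    }
    return table, truth


def simulate_microcosm_timeseries(
    taxa: Sequence[SynthTaxon],
    timepoints: Sequence[int] = (0, 4, 10, 13, 24, 31),
    replicates: int = 3,
    depth: int = 20000,
    overdispersion: float = 0.0,
    substrate: str = "DNA",
    seed: int = 0,
) -> tuple[AbundanceTable, dict]:
    """Simulate microcosm amplicon counts for substrate vs no-substrate arms.

    Responder taxa multiply their base abundance by their response-profile
    entry in the substrate arm only.  ``overdispersion`` > 0 draws each
    replicate's composition from a Dirichlet with concentration
    p/overdispersion before the multinomial (0 = pure multinomial, which
    keeps the null calibration exact).
    """
    if replicates < 3:
        raise ValueError("need >= 3 replicate microcosms per arm")
    if not taxa:
        raise ValueError("no taxa")
    rng = np.random.default_rng(seed)
    asv_ids = [t.asv_id for t in taxa]
    base = np.array([t.base_abundance for t in taxa], dtype=float)
    if base.sum() == 0:
        raise ValueError("all base abundances are zero")
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    responders = []
    for tr in (substrate, TREATMENT_NO_SUBSTRATE):
        for tp in timepoints:
            mult = np.ones(len(taxa))
            if tr == substrate:
                for i, t in enumerate(taxa):
                    if t.response_profile:
                        mult[i] = t.response_profile.get(tp, 1.0)
            p = base * mult
            p = p / p.sum()
            for r in range(replicates):
                sid = f"{tr}_d{tp}_r{r + 1}"
                if overdispersion > 0:
                    conc = np.clip(p / overdispersion, 1e-12, None)
                    p_rep = rng.dirichlet(conc)
                else:
                    p_rep = p
                columns[sid] = rng.multinomial(depth, p_rep)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "gradient_id": f"{tr}_d{tp}",
                        "treatment": tr,
                        "timepoint_days": tp,
                        "density": float("nan"),
                        "replicate": f"r{r + 1}",
                    }
                )
    for t in taxa:
        if t.response_profile and any(v > 1.0 for v in t.response_profile.values()):
            responders.append(t.asv_id)
    data = pd.DataFrame(columns, index=asv_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    table = AbundanceTable(data=data, meta=meta, mode="counts")
    truth = {
        "responders": responders,
        "substrate": substrate,
        "timepoints": list(timepoints),
        "seed": seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# NanoSIMS generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthCell:
    """Elliptical cell: centre (y, x) px, semi-axes (a, b) px, orientation deg."""

    center: tuple[float, float]
    axes: tuple[float, float] = (6.5, 5.0)
    orientation_deg: float = 0.0
    true_atom_fraction: float = NATURAL_ABUNDANCE_BIOMASS
    carbon_rate: float = 50.0
    cn_rate: float = 100.0
    p_rate: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_atom_fraction <= 1.0:
            raise ValueError("true_atom_fraction must be in [0, 1]")
        if min(self.carbon_rate, self.cn_rate, self.p_rate) < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class SynthNanoSimsConfig:
    """Full generative specification of a NanoSIMS acquisition."""

    height: int = 512
    width: int = 512
    planes: int = 10
    cells: list[SynthCell] = field(default_factory=list)
    background_carbon_rate: float = 0.5
    background_cn_rate: float = 0.5
    background_p_rate: float = 0.1
    background_atom_fraction: float = NATURAL_ABUNDANCE_BIOMASS
    drift_per_plane: tuple[int, int] = (0, 0)
    apply_dead_time_distortion: bool = False
    dwell_time_s: float = 10e-3
    dead_time_s: float = 44e-9
    field_size_um: float = 60.0
    allow_overlap: bool = False
    seed: int = 0


def _ellipse_mask(h: int, w: int, cell: SynthCell) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = cell.center
    th = math.radians(cell.orientation_deg)
    dy, dx = yy - cy, xx - cx
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    a, b = cell.axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def simulate_nanosims_stack(
    config: SynthNanoSimsConfig,
) -> tuple[IonCountStack, RoiSet, dict]:
    """Simulate a raw multilayer ion-count stack with known per-cell truth.

    Per pixel and plane the C2-family ion count is Poisson at the local
    carbon rate; each ion is assigned to 12C2-/13C12C-/13C2- with
    probabilities (1-x)^2, 2x(1-x), x^2 by random pairing of two carbon
    atoms at local atom fraction x.  13C2- ions are generated and then
    DISCARDED (not recorded), matching the detector configuration.  CN-
    and 31P- channels are Poisson at their own rates.  Plane k is
    translated by k * drift_per_plane with zero fill.  Optionally the
    non-paralyzable dead-time distortion m = n/(1 + n*tau/T) (rounded back
    to integers) is applied to emulate raw detector output.

    Returns the raw stack, the true cell masks as a RoiSet (plane-0
    frame), and a truth manifest with per-cell atom fractions and the
    discarded 13C2- totals.
    """
    h, w = config.height, config.width
    rng = np.random.default_rng(config.seed)

    carbon = np.full((h, w), float(config.background_carbon_rate))
    cn = np.full((h, w), float(config.background_cn_rate))
    p_map = np.full((h, w), float(config.background_p_rate))
    xmap = np.full((h, w), float(config.background_atom_fraction))
    labels = np.zeros((h, w), dtype=np.int32)
    for i, cell in enumerate(config.cells, start=1):
        mask = _ellipse_mask(h, w, cell)
        if not config.allow_overlap and (labels[mask] > 0).any():
            raise ValueError(f"cell {i} overlaps an earlier cell")
        labels[mask] = i
        carbon[mask] = cell.carbon_rate
        cn[mask] = cell.cn_rate
        p_map[mask] = cell.p_rate
        xmap[mask] = cell.true_atom_fraction

    dy0, dx0 = config.drift_per_plane
    species = {
        "C2": np.zeros((config.planes, h, w), dtype=np.int64),
        "C13C12": np.zeros((config.planes, h, w), dtype=np.int64),
        "CN": np.zeros((config.planes, h, w), dtype=np.int64),
        "P": np.zeros((config.planes, h, w), dtype=np.int64),
    }
    discarded_c13c13 = 0
    for k in range(config.planes):
        dy, dx = k * dy0, k * dx0
        car_k = _shift_image(carbon, dy, dx)
        x_k = _shift_image(xmap, dy, dx)
        n_family = rng.poisson(car_k)
        p12 = (1.0 - x_k) ** 2
        p_mix = 2.0 * x_k * (1.0 - x_k)
        c2 = rng.binomial(n_family, p12)
        rest = n_family - c2
        with np.errstate(divide="ignore", invalid="ignore"):
            p_cond = np.where(p12 < 1.0, p_mix / (1.0 - p12), 0.0)
        c13c12 = rng.binomial(rest, p_cond)
        discarded_c13c13 += int((rest - c13c12).sum())
        species["C2"][k] = c2
        species["C13C12"][k] = c13c12
        species["CN"][k] = rng.poisson(_shift_image(cn, dy, dx))
        species["P"][k] = rng.poisson(_shift_image(p_map, dy, dx))

    if config.apply_dead_time_distortion:
        ratio = config.dead_time_s / config.dwell_time_s
        for sp, arr in species.items():
            distorted = arr / (1.0 + arr * ratio)
            species[sp] = np.rint(distorted).astype(np.int64)

    stack = IonCountStack(
        counts={sp: arr for sp, arr in species.items()},
        dwell_time_s=config.dwell_time_s,
        dead_time_s=config.dead_time_s,
        field_size_um=config.field_size_um,
        corrected=False,
    )
    rois = RoiSet(labels=labels, provenance="synthetic-truth")
    truth = {
        "cells": [
            {
                "roi_id": i + 1,
                "true_atom_fraction": c.true_atom_fraction,
                "true_atpct": 100.0 * c.true_atom_fraction,
                "pixels": int((labels == i + 1).sum()),
            }
            for i, c in enumerate(config.cells)
        ],
        "discarded_c13c13_ions": discarded_c13c13,
        "drift_per_plane": list(config.drift_per_plane),
        "seed": config.seed,
    }
    return stack, rois, truth


def _shift_image(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate a 2-D array by (dy, dx) with edge-value fill.

    Edge fill (rather than zero fill) keeps the background rate defined
    everywhere so drifted planes remain realistic acquisitions.
    """
    if dy == 0 and dx == 0:
        return arr
    out = np.roll(np.roll(arr, dy, axis=0), dx, axis=1)
    if dy > 0:
        out[:dy, :] = arr[0, :]
    elif dy < 0:
        out[dy:, :] = arr[-1, :]
    if dx > 0:
        out[:, :dx] = out[:, dx][:, None]
    elif dx < 0:
        out[:, dx:] = out[:, dx - 1][:, None]
    return out
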