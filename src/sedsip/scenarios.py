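"""Study-condition scenario builders.

These functions pin the synthetic-data configurations that emulate the
study's experimental conditions: the gradient experiment with a small set
of strongly 13C-labelled ASVs from four taxon groups over a large
unlabelled background community, the microcosm substrate-response series,
and the NanoSIMS acquisitions of labelled (7.5 at% 13C) and
natural-abundance (1.08 at% 13C) cell populations.  Tests and the
reproduction script build on them; only the random seed varies between
runs.
"""

from __future__ import annotations

import numpy as np

from .synth import (
    NATURAL_ABUNDANCE_BIOMASS,
    SynthCell,
    SynthGradientConfig,
    SynthNanoSimsConfig,
    SynthTaxon,
)

#: taxon groups recovered as DNA-foragers in marine sediments
LABELLED_GROUPS = ("Izemoplasma", "Lutibacter", "Shewanella", "Fusibacteraceae")

#: at% 13C of the labelled single-cell population
LABELLED_CELL_ATPCT = 7.5
#: at% 13C of the natural-abundance control population
CONTROL_CELL_ATPCT = 1.08


def gradient_sip_scenario(
    seed: int = 0,
    n_labelled: int = 12,
    n_background: int = 200,
    depth: int = 20000,
) -> SynthGradientConfig:
    """Gradient experiment with planted labelled ASVs over a background.

    The labelled ASVs (``n_labelled``, split evenly over four groups) have
    low GC content (0.31-0.34) and near-complete 13C labelling, so their
    13C-treatment band centres fall inside the heavy windows, with base
    abundances spread so their heavy-window shares range from a few
    percent up to ~25% against near-zero control shares.  Background taxa
    are unlabelled with GC 0.30-0.65.  Community structure is drawn from
    ``seed`` and count sampling from ``seed + 1``.
    """
    rng = np.random.default_rng(seed)
    taxa: list[SynthTaxon] = []
    base_labelled = np.geomspace(0.11, 0.008, n_labelled) if n_labelled else np.array([])
    gcs = np.linspace(0.31, 0.34, n_labelled)
    for i in range(n_labelled):
        taxa.append(
            SynthTaxon(
                asv_id=f"ASV_L{i + 1:02d}",
                group_id=LABELLED_GROUPS[i % len(LABELLED_GROUPS)],
                gc_content=float(gcs[i]),
                atom_fraction_13c=0.98,
                base_abundance=float(base_labelled[i]),
            )
        )
    remaining = 1.0 - base_labelled.sum()
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=n_background)
    weights = weights / weights.sum() * remaining
    bg_gc = rng.uniform(0.30, 0.72, size=n_background)
    for i in range(n_background):
        taxa.append(
            SynthTaxon(
                asv_id=f"ASV_B{i + 1:03d}",
                group_id=f"background_{i % 10}",
                gc_content=float(bg_gc[i]),
                base_abundance=float(weights[i]),
            )
        )
    return SynthGradientConfig(taxa=taxa, depth=depth, seed=seed + 1,
                               uniform_carryover=0.01)


def null_gradient_scenario(seed: int = 0, n_background: int = 200,
                           depth: int = 20000) -> SynthGradientConfig:
    """Same community structure but zero labelled taxa (null calibration)."""
    cfg = gradient_sip_scenario(seed=seed, n_labelled=0, n_background=n_background,
                                depth=depth)
    return cfg


def microcosm_scenario(
    seed: int = 0,
    n_background: int = 40,
    n_responders: int = 5,
    response_fold: float = 10.0,
    response_timepoints: tuple[int, ...] = (10, 13, 24),
    timepoints: tuple[int, ...] = (0, 4, 10, 13, 24, 31),
) -> tuple[list[SynthTaxon], tuple[int, ...]]:
    """Microcosm community with substrate responders at known time points."""
    rng = np.random.default_rng(seed)
    taxa: list[SynthTaxon] = []
    profile = {tp: response_fold for tp in response_timepoints}
    for i in range(n_responders):
        taxa.append(
            SynthTaxon(
                asv_id=f"ASV_R{i + 1:02d}",
                group_id="responder",
                gc_content=0.4,
                base_abundance=0.01,
                response_profile=dict(profile),
            )
        )
    weights = rng.lognormal(0.0, 1.0, size=n_background)
    weights = weights / weights.sum() * (1.0 - 0.01 * n_responders)
    for i in range(n_background):
        taxa.append(
            SynthTaxon(
                asv_id=f"ASV_M{i + 1:03d}",
                group_id="background",
                gc_content=0.5,
                base_abundance=float(weights[i]),
            )
        )
    return taxa, timepoints


def _cell_grid(n_cells: int, height: int, width: int,
               margin: int = 40) -> list[tuple[float, float]]:
    cols = int(np.ceil(np.sqrt(n_cells * width / height)))
    rows = int(np.ceil(n_cells / cols))
    ys = np.linspace(margin, height - margin, rows)
    xs = np.linspace(margin, width - margin, cols)
    centres = [(float(y), float(x)) for y in ys for x in xs]
    return centres[:n_cells]


def _cell_population_scenario(
    n_cells: int,
    atpct: float,
    seed: int,
    height: int,
    width: int,
    planes: int,
    carbon_rate: float,
    drift_per_plane: tuple[int, int],
) -> SynthNanoSimsConfig:
    rng = np.random.default_rng(seed)
    cells = [
        SynthCell(
            center=c,
            axes=(6.5, 5.0),
            orientation_deg=float(rng.uniform(0, 180)),
            true_atom_fraction=atpct / 100.0,
            carbon_rate=carbon_rate,
            cn_rate=2.0 * carbon_rate,
            p_rate=0.4 * carbon_rate,
        )
        for c in _cell_grid(n_cells, height, width)
    ]
    return SynthNanoSimsConfig(
        height=height,
        width=width,
        planes=planes,
        cells=cells,
        background_carbon_rate=0.02 * carbon_rate,
        background_cn_rate=0.02 * carbon_rate,
        background_p_rate=0.01 * carbon_rate,
        background_atom_fraction=NATURAL_ABUNDANCE_BIOMASS,
        drift_per_plane=drift_per_plane,
        apply_dead_time_distortion=True,
        seed=seed,
    )


def labelled_cell_scenario(
    seed: int = 0,
    n_cells: int = 51,
    height: int = 512,
    width: int = 512,
    planes: int = 10,
    carbon_rate: float = 50.0,
    drift_per_plane: tuple[int, int] = (1, 1),
) -> SynthNanoSimsConfig:
    """51 labelled cells at 7.5 at% 13C, ~100-px ellipses, 10 planes."""
    return _cell_population_scenario(
        n_cells, LABELLED_CELL_ATPCT, seed, height, width, planes,
        carbon_rate, drift_per_plane,
    )


def control_cell_scenario(
    seed: int = 0,
    n_cells: int = 25,
    height: int = 512,
    width: int = 512,
    planes: int = 10,
    carbon_rate: float = 50.0,
    drift_per_plane: tuple[int, int] = (1, 1),
) -> SynthNanoSimsConfig:
    """25 natural-abundance control cells at 1.08 at% 13C."""
    return _cell_population_scenario(
        n_cells, CONTROL_CELL_ATPCT, seed, height, width, planes,
        carbon_rate, drift_per_plane,
    )
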