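"""Single-cell 13C quantification from NanoSIMS ion-count image stacks.

The instrument rasters a Cs+ beam over the sample and counts negative
secondary ions per pixel, plane by plane, in parallel for several species
(12C2-, 13C12C-, 12C14N-, 31P-, 32S-, secondary electrons).  This module
implements the evaluation chain:

1. per-pixel dead-time correction of the raw counts (non-paralyzable
   detector model, m / (1 - m*tau/T));
2. integer-pixel drift correction of the plane stack by cross-correlation
   on a reference species (the CN- biomass channel by default);
3. accumulation (pixel-wise sum over planes on the mutually valid region);
4. conversion of the C2-family ion counts to a 13C atom-fraction image,
   at% 13C = 100 * 13C12C- / (2*12C2- + 13C12C-), i.e. the isotope
   fraction 13C/(12C+13C) inferred from the detected dimer species
   (13C2- is not in the detector set; this ratio is nevertheless an
   unbiased estimator of the atom fraction under random pairing);
5. per-cell (region of interest) quantification by ratio of summed counts,
   with the Poisson counting error
   sigma_Pois = sqrt(n12C^2*n13C + n13C^2*n12C) / (n12C + n13C)^2
   expressed in at% units;
6. an enrichment call against a natural-abundance control population:
   a cell is 13C-enriched iff its at% exceeds the upper bound of the
   control confidence interval AND 3*sigma_Pois is smaller than its
   distance to the control mean.

A delta-notation utility converts between at% 13C and delta13C (permille
vs Vienna Pee Dee Belemnite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.signal import fftconvolve

#: recognised ion species keys
SPECIES = ("C2", "C13C12", "CN", "P", "S", "SE")
#: 13C/12C isotope ratio of the Vienna Pee Dee Belemnite reference
R_VPDB = 0.0111802


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class IonCountStack:
    """Multilayer per-species ion-count images plus acquisition metadata.

    ``counts`` maps species keys to (planes, height, width) arrays.  Raw
    stacks are integer-valued; after dead-time correction counts are
    fractional and ``corrected`` is set.  ``valid`` is a per-plane boolean
    mask marking pixels that carry data (False e.g. for the zero-filled
    margin introduced by drift correction).
    """

    counts: dict[str, np.ndarray]
    dwell_time_s: float = 10e-3
    dead_time_s: float = 44e-9
    field_size_um: float = 60.0
    corrected: bool = False
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("stack has no species")
        unknown = set(self.counts) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species key(s): {sorted(unknown)}")
        shapes = {k: v.shape for k, v in self.counts.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"species shapes differ: {shapes}")
        shape = next(iter(shapes.values()))
        if len(shape) != 3 or shape[0] < 1:
            raise ValueError(f"counts must be (planes, h, w), got {shape}")
        for k, v in self.counts.items():
            if (np.asarray(v) < 0).any():
                raise ValueError(f"negative counts in species {k}")
        if not self.corrected:
            for k, v in self.counts.items():
                arr = np.asarray(v)
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError(f"raw stack must be integer-valued ({k})")
        if not self.dwell_time_s > self.dead_time_s >= 0:
            raise ValueError("need dwell_time > dead_time >= 0")
        if self.valid is None:
            self.valid = np.ones(shape, dtype=bool)
        elif self.valid.shape != shape:
            raise ValueError("valid mask shape mismatch")

    @property
    def planes(self) -> int:
        return next(iter(self.counts.values())).shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        s = next(iter(self.counts.values())).shape
        return (s[1], s[2])

    def require_isotope_species(self) -> None:
        for sp in ("C2", "C13C12"):
            if sp not in self.counts:
                raise ValueError(f"isotope analysis needs species {sp}")


@dataclass(frozen=True)
class DriftTrack:
    """Per-plane integer (dy, dx) shifts relative to plane 0."""

    shifts: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.shifts[0] != (0, 0):
            raise ValueError("plane 0 shift must be (0, 0)")


@dataclass
class AccumulatedImages:
    """Per-species plane-summed 2-D images with a shared validity mask."""

    images: dict[str, np.ndarray]
    valid: np.ndarray
    dwell_time_s: float
    dead_time_s: float
    field_size_um: float


@dataclass
class IsotopeMap:
    """Per-pixel at% 13C image in [0, 100] with a validity mask.

    Pixels with zero total carbon counts are invalid, never silently 0.
    """

    atpct: np.ndarray
    valid: np.ndarray


@dataclass
class RoiSet:
    """Label image defining cell regions (0 = background, 1..K = cells)."""

    labels: np.ndarray
    min_pixels: int = 10
    provenance: str = "manual"

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or (lab < 0).any():
            raise ValueError("labels must be a 2-D non-negative integer image")
        ids = np.unique(lab)
        ids = ids[ids > 0]
        if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ValueError("ROI labels must be contiguous positive integers")
        small = [int(i) for i in ids if (lab == i).sum() < self.min_pixels]
        if small:
            raise ValueError(f"ROI(s) below {self.min_pixels} pixels: {small}")
        self.labels = lab.astype(np.int32)

    @property
    def roi_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]


@dataclass(frozen=True)
class CellIsotopeResult:
    """Per-cell isotope quantification (ratio of summed counts)."""

    roi_id: int
    n12c: float
    n13c: float
    atpct: float
    sigma_pois: float
    enriched: bool | None = None
    margin: float | None = None
    excluded_fraction: float = 0.0


@dataclass(frozen=True)
class ControlReference:
    """Natural-abundance reference built from control-cell at% values."""

    n_cells: int
    mean_atpct: float
    sd_atpct: float
    ci_level: float
    upper_bound: float
    mode: str = "mean_ci"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def dead_time_correct(stack: IonCountStack) -> IonCountStack:
    """Correct per-pixel counts for detector dead time.

    Uses the non-paralyzable pulse-counting model: with observed count m
    per dwell interval T and dead time tau, the corrected count is
    m / (1 - m*tau/T).  Saturation (m*tau/T >= 1) and re-correction of an
    already corrected stack are errors.
    """
    if stack.corrected:
        raise ValueError("stack is already dead-time corrected")
    tau, T = stack.dead_time_s, stack.dwell_time_s
    out: dict[str, np.ndarray] = {}
    for sp, arr in stack.counts.items():
        arr = np.asarray(arr, dtype=float)
        load = arr * (tau / T)
        if (load >= 1.0).any():
            idx = np.unravel_index(int(np.argmax(load)), arr.shape)
            raise ValueError(
                f"dead-time saturation in species {sp} at (plane, y, x)={idx}: "
                f"m*tau/T = {load[idx]:.3f} >= 1"
            )
        out[sp] = arr / (1.0 - load)
    return IonCountStack(
        counts=out,
        dwell_time_s=T,
        dead_time_s=tau,
        field_size_um=stack.field_size_um,
        corrected=True,
        valid=stack.valid.copy(),
    )


def _xcorr_shift(reference: np.ndarray, moving: np.ndarray) -> tuple[int, int]:
    """Integer (dy, dx) such that ``moving`` ~ ``reference`` shifted by it."""
    a = reference - reference.mean()
    b = moving - moving.mean()
    corr = fftconvolve(b, a[::-1, ::-1], mode="full")
    peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
    dy = int(peak[0] - (reference.shape[0] - 1))
    dx = int(peak[1] - (reference.shape[1] - 1))
    return dy, dx


def _shift_plane(arr: np.ndarray, dy: int, dx: int) -> tuple[np.ndarray, np.ndarray]:
    """Translate by (dy, dx) with zero fill; returns (shifted, valid_mask)."""
    h, w = arr.shape
    out = np.zeros_like(arr)
    valid = np.zeros((h, w), dtype=bool)
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = arr[ys_src, xs_src]
    valid[ys, xs] = True
    return out, valid


def align_planes(
    stack: IonCountStack, reference_species: str = "CN"
) -> tuple[IonCountStack, DriftTrack]:
    """Drift-correct the plane stack by integer-pixel cross-correlation.

    The shift of each plane of the reference species against plane 0 is
    estimated from the cross-correlation peak; all species are shifted
    identically, out-of-frame pixels are marked invalid (counts are never
    wrapped).  A shift of half the frame or more is an alignment failure.
    """
    if reference_species not in stack.counts:
        raise ValueError(f"reference species {reference_species!r} not in stack")
    ref = np.asarray(stack.counts[reference_species], dtype=float)
    n_planes = ref.shape[0]
    h, w = ref.shape[1:]
    shifts: list[tuple[int, int]] = [(0, 0)]
    for k in range(1, n_planes):
        dy, dx = _xcorr_shift(ref[0], ref[k])
        if abs(dy) >= min(h, w) / 2 or abs(dx) >= min(h, w) / 2:
            raise ValueError(
                f"alignment failure: plane {k} shift ({dy}, {dx}) exceeds half frame"
            )
        shifts.append((dy, dx))
    track = DriftTrack(tuple(shifts))

    out = {sp: np.array(arr, dtype=float, copy=True) for sp, arr in stack.counts.items()}
    valid = stack.valid.copy()
    for k, (dy, dx) in enumerate(track.shifts):
        if (dy, dx) == (0, 0):
            continue
        mask_k = None
        for sp in out:
            out[sp][k], mask_k = _shift_plane(out[sp][k], -dy, -dx)
        vshift, mask_k = _shift_plane(valid[k].astype(float), -dy, -dx)
        valid[k] = (vshift > 0) & mask_k
    aligned = IonCountStack(
        counts=out,
        dwell_time_s=stack.dwell_time_s,
        dead_time_s=stack.dead_time_s,
        field_size_um=stack.field_size_um,
        corrected=stack.corrected,
        valid=valid,
    )
    return aligned, track


def accumulate_stack(stack: IonCountStack) -> AccumulatedImages:
    """Pixel-wise sum over planes, restricted to pixels valid in every plane."""
    valid_all = stack.valid.all(axis=0)
    images = {
        sp: np.where(valid_all, np.asarray(arr, dtype=float).sum(axis=0), 0.0)
        for sp, arr in stack.counts.items()
    }
    return AccumulatedImages(
        images=images,
        valid=valid_all,
        dwell_time_s=stack.dwell_time_s,
        dead_time_s=stack.dead_time_s,
        field_size_um=stack.field_size_um,
    )


def atomic_counts_from_c2(
    c2_img: np.ndarray, c13c12_img: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Atomic-equivalent 12C/13C counts from the detected dimer species.

    Each 12C2- ion carries two 12C atoms and each 13C12C- ion one 13C
    atom, so n12C = 2*C2 and n13C = C13C12.  The resulting isotope
    fraction n13C/(n12C + n13C) is the instrument's printed ratio
    13C12C-/(2*12C2- + 13C12C-), which is unbiased for the true atom
    fraction x under random isotope pairing even though 13C2- ions are not
    detected (the 13C12C- channel under-collects 13C and the denominator
    under-collects total carbon by exactly compensating factors of 1-x).
    """
    c2 = np.asarray(c2_img, dtype=float)
    c13 = np.asarray(c13c12_img, dtype=float)
    if c2.shape != c13.shape:
        raise ValueError(f"shape mismatch: {c2.shape} vs {c13.shape}")
    return 2.0 * c2, c13.copy()


def isotope_fraction_map(n12c_img: np.ndarray, n13c_img: np.ndarray) -> IsotopeMap:
    """Per-pixel at% 13C = 100 * n13C/(n12C + n13C); zero-total pixels invalid."""
    n12 = np.asarray(n12c_img, dtype=float)
    n13 = np.asarray(n13c_img, dtype=float)
    if n12.shape != n13.shape:
        raise ValueError(f"shape mismatch: {n12.shape} vs {n13.shape}")
    total = n12 + n13
    valid = total > 0
    atpct = np.zeros_like(total)
    np.divide(100.0 * n13, total, out=atpct, where=valid)
    return IsotopeMap(atpct=atpct, valid=valid)


def poisson_sigma(n12c: float, n13c: float) -> float:
    """Poisson counting error of the isotope fraction, in at% units.

    sigma = sqrt(n12C^2 * n13C + n13C^2 * n12C) / (n12C + n13C)^2, scaled
    by 100; the delta-method standard deviation of 100*n13/(n12+n13) for
    independent Poisson counts.
    """
    n12 = float(n12c)
    n13 = float(n13c)
    if n12 < 0 or n13 < 0:
        raise ValueError("counts must be non-negative")
    total = n12 + n13
    if total == 0:
        raise ValueError("sigma undefined for zero total counts")
    return 100.0 * math.sqrt(n12 * n12 * n13 + n13 * n13 * n12) / (total * total)


def roi_quantify(
    acc: AccumulatedImages,
    rois: RoiSet,
    control: ControlReference | None = None,
    sigma_mult: float = 3.0,
) -> list[CellIsotopeResult]:
    """Per-cell isotope quantification by ratio of summed counts.

    Counts are summed over the ROI pixels first and the at% and Poisson
    sigma are computed from the totals (ratio of sums, not mean of
    per-pixel ratios), matching a counting-statistics error model on whole
    cells.  Pixels invalid in the accumulated images are excluded and the
    excluded fraction recorded; an entirely invalid ROI is an error.  When
    ``control`` is given, the dual-criterion enrichment call is attached.
    """
    for sp in ("C2", "C13C12"):
        if sp not in acc.images:
            raise ValueError(f"accumulated images lack species {sp}")
    if rois.labels.shape != acc.valid.shape:
        raise ValueError("ROI label image shape does not match images")
    c2, c13 = acc.images["C2"], acc.images["C13C12"]
    results: list[CellIsotopeResult] = []
    for roi_id in rois.roi_ids:
        mask = rois.labels == roi_id
        usable = mask & acc.valid
        n_total = int(mask.sum())
        n_used = int(usable.sum())
        if n_used == 0:
            raise ValueError(f"ROI {roi_id} lies entirely on invalid pixels")
        n12, n13 = atomic_counts_from_c2(c2[usable].sum(), c13[usable].sum())
        n12, n13 = float(n12), float(n13)
        if n12 + n13 == 0:
            raise ValueError(f"ROI {roi_id} has zero carbon counts")
        atpct = 100.0 * n13 / (n12 + n13)
        sigma = poisson_sigma(n12, n13)
        res = CellIsotopeResult(
            roi_id=roi_id,
            n12c=n12,
            n13c=n13,
            atpct=atpct,
            sigma_pois=sigma,
            excluded_fraction=1.0 - n_used / n_total,
        )
        if control is not None:
            res = CellIsotopeResult(
                **{**res.__dict__,
                   "enriched": call_enrichment(res, control, sigma_mult),
                   "margin": atpct - control.mean_atpct},
            )
        results.append(res)
    return results


def build_control_reference(
    control_atpcts: Sequence[float],
    ci_level: float = 0.999,
    mode: str = "mean_ci",
) -> ControlReference:
    """Summarise natural-abundance control cells into an enrichment reference.

    ``mode="mean_ci"`` (default) sets the upper bound to the upper limit of
    the two-sided Student-t confidence interval of the control *mean* at
    ``ci_level``; ``mode="population"`` uses mean + z-quantile * sd, a
    tolerance-style bound on single-cell values.
    """
    vals = np.asarray(control_atpcts, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 control cells")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    q = 1.0 - (1.0 - ci_level) / 2.0
    if mode == "mean_ci":
        upper = mean + float(stats.t.ppf(q, vals.size - 1)) * sd / math.sqrt(vals.size)
    elif mode == "population":
        upper = mean + float(stats.norm.ppf(q)) * sd
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ControlReference(
        n_cells=int(vals.size),
        mean_atpct=mean,
        sd_atpct=sd,
        ci_level=ci_level,
        upper_bound=upper,
        mode=mode,
    )


def call_enrichment(
    cell: CellIsotopeResult,
    control: ControlReference,
    sigma_mult: float = 3.0,
) -> bool:
    """Dual-criterion 13C enrichment call.

    True iff (1) the cell's at% exceeds the control confidence-interval
    upper bound and (2) sigma_mult * sigma_Pois is smaller than the
    distance between the cell and the control mean.
    """
    margin = cell.atpct - control.mean_atpct
    return bool(cell.atpct > control.upper_bound and sigma_mult * cell.sigma_pois < margin)


def quantify_stack(
    stack: IonCountStack,
    rois: RoiSet,
    control: ControlReference | None = None,
    reference_species: str = "CN",
    sigma_mult: float = 3.0,
) -> tuple[list[CellIsotopeResult], IsotopeMap, DriftTrack]:
    """Full pipeline: dead-time correct, align, accumulate, quantify ROIs.

    Accepts a raw stack (corrects it) or an already corrected one.  Order
    of operations is fixed: the dead-time effect is per dwell interval, so
    it is corrected per plane before any pixels are moved; alignment then
    never mixes corrected and uncorrected pixels.
    """
    stack.require_isotope_species()
    if not stack.corrected:
        stack = dead_time_correct(stack)
    if stack.planes > 1 and reference_species in stack.counts:
        stack, track = align_planes(stack, reference_species)
    else:
        track = DriftTrack(((0, 0),) * stack.planes)
    acc = accumulate_stack(stack)
    n12_img, n13_img = atomic_counts_from_c2(acc.images["C2"], acc.images["C13C12"])
    iso = isotope_fraction_map(n12_img, n13_img)
    iso.valid &= acc.valid
    cells = roi_quantify(acc, rois, control=control, sigma_mult=sigma_mult)
    return cells, iso, track


# ---------------------------------------------------------------------------
# delta notation
# ---------------------------------------------------------------------------


def delta_to_atom_percent(delta_permil: float, r_vpdb: float = R_VPDB) -> float:
    """Convert delta13C (permille vs VPDB) to atom percent 13C.

    R = r_vpdb * (delta/1000 + 1); at% = 100 * R / (1 + R).
    """
    if r_vpdb <= 0:
        raise ValueError("reference ratio must be positive")
    if delta_permil <= -1000.0:
        raise ValueError("delta must exceed -1000 permille")
    r = r_vpdb * (delta_permil / 1000.0 + 1.0)
    return 100.0 * r / (1.0 + r)


def atom_percent_to_delta(atpct: float, r_vpdb: float = R_VPDB) -> float:
    """Inverse of :func:`delta_to_atom_percent`."""
    if not 0.0 < atpct < 100.0:
        raise ValueError("at% must be in (0, 100)")
    frac = atpct / 100.0
    r = frac / (1.0 - frac)
    return (r / r_vpdb - 1.0) * 1000.0


# ---------------------------------------------------------------------------
# optional, non-canonical segmentation for synthetic tests
# ---------------------------------------------------------------------------


def segment_cells_otsu(acc: AccumulatedImages, species: str = "CN",
                       min_pixels: int = 10) -> RoiSet:
    """Otsu-threshold segmentation of the biomass channel into ROIs.

    Convenience for synthetic data only; real cell ROIs are drawn manually
    on the CN-/P- maps and supplied as label images.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label as sk_label

    img = acc.images[species]
    thr = threshold_otsu(img[acc.valid])
    binary = (img > thr) & acc.valid
    lab = sk_label(binary)
    # drop undersized components and relabel contiguously
    ids, counts = np.unique(lab[lab > 0], return_counts=True)
    keep = {int(i) for i, c in zip(ids, counts) if c >= min_pixels}
    relabel = np.zeros_like(lab)
    for new, old in enumerate(sorted(keep), start=1):
        relabel[lab == old] = new
    return RoiSet(labels=relabel, min_pixels=min_pixels, provenance="otsu-synthetic")
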