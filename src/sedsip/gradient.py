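"""Detection of isotopically labelled ASVs from CsCl density-gradient profiles.

This module implements a "serial group comparison" workflow for DNA stable
isotope probing (DNA-SIP): per-ASV relative abundances from heavy
buoyant-density windows of the 13C-substrate gradients are compared against
the matching windows of 12C control gradients with a rank-sum test, per
time point and per window.  An ASV is called 13C-labelled when it is
significantly *enriched* (two-sided p below alpha and higher mean in the
treatment) at a minimum number of time points.  The same machinery detects
substrate-responsive ASVs in microcosm time series (substrate vs
no-substrate microcosms instead of density windows).

Abundance tables are ASV x sample matrices with per-sample metadata
(gradient, treatment, time point in days, buoyant density in g/ml).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical treatment labels for the gradient experiment
TREATMENT_C13 = "C13"
TREATMENT_C12 = "C12"
#: canonical control label for microcosm comparisons
TREATMENT_NO_SUBSTRATE = "no_substrate"

META_COLUMNS = ("gradient_id", "treatment", "timepoint_days", "density", "replicate")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FractionSample:
    """One sequenced sample: a gradient fraction or a microcosm subsample.

    ``density`` is the CsCl buoyant density of the fraction in g/ml
    (refractometer reading); it is NaN for microcosm samples, which have no
    gradient dimension.
    """

    sample_id: str
    gradient_id: str
    treatment: str
    timepoint_days: int
    density: float = float("nan")
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.timepoint_days < 0:
            raise ValueError(f"timepoint_days must be >= 0, got {self.timepoint_days}")
        if not math.isnan(self.density) and self.density <= 1.0:
            raise ValueError(
                f"buoyant density must exceed 1.0 g/ml, got {self.density} "
                f"for sample {self.sample_id!r}"
            )


@dataclass
class AbundanceTable:
    """ASV-by-sample abundance matrix with sample metadata.

    ``data`` is indexed by ASV id with one column per sample id; ``meta`` is
    indexed by sample id with columns gradient_id, treatment,
    timepoint_days, density, replicate.  ``mode`` is ``"counts"`` (raw
    reads) or ``"relative"`` (per-sample proportions summing to one).
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"mode must be 'counts' or 'relative', got {self.mode!r}")
        if not self.data.index.is_unique:
            raise ValueError("ASV ids must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("sample ids must be unique")
        missing = [s for s in self.data.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")

    # -- convenience accessors -------------------------------------------

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def samples(self) -> list[FractionSample]:
        out = []
        for sid in self.data.columns:
            row = self.meta.loc[sid]
            out.append(
                FractionSample(
                    sample_id=str(sid),
                    gradient_id=str(row["gradient_id"]),
                    treatment=str(row["treatment"]),
                    timepoint_days=int(row["timepoint_days"]),
                    density=float(row["density"]),
                    replicate="" if pd.isna(row.get("replicate", "")) else str(row["replicate"]),
                )
            )
        return out

    def validate_relative(self, atol: float = 1e-9) -> None:
        """Check the full-table relative-mode invariant (columns sum to 1)."""
        if self.mode != "relative":
            raise ValueError("table is not in relative mode")
        sums = self.data.sum(axis=0).to_numpy()
        bad = np.where(np.abs(sums - 1.0) > atol)[0]
        if bad.size:
            raise ValueError(
                f"relative-abundance columns must sum to 1; offending samples: "
                f"{[self.data.columns[i] for i in bad[:5]]}"
            )

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        """Column subset (keeps mode; subset columns need not sum to 1)."""
        return AbundanceTable(
            data=self.data.loc[:, list(sample_ids)].copy(),
            meta=self.meta.loc[list(sample_ids)].copy(),
            mode=self.mode,
        )


@dataclass(frozen=True)
class WindowSpec:
    """A heavy-density window: fractions with density in [density_min, density_max]."""

    name: str
    density_min: float
    density_max: float
    min_fractions: int = 3
    max_fractions: int = 5

    def __post_init__(self) -> None:
        if not self.density_min < self.density_max:
            raise ValueError("density_min must be < density_max")
        if not 1 <= self.min_fractions <= self.max_fractions:
            raise ValueError("need 1 <= min_fractions <= max_fractions")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.density_min + self.density_max)


#: the two heavy windows used for the gradient comparisons
DEFAULT_WINDOWS = (
    WindowSpec("window1", 1.725, 1.741),
    WindowSpec("window2", 1.735, 1.746),
)


@dataclass(frozen=True)
class FilterParams:
    """Prevalence/abundance filters applied before group comparison.

    All cutoffs are fractions of 1 on relative abundances.  An ASV is kept
    iff it exceeds ``abundance_cutoff`` in at least
    ``ceil(prevalence_cutoff * n_samples_total)`` samples (pooled over both
    groups) and its median relative abundance exceeds ``max_median_cutoff``
    in at least one of the two groups.  ``replace_zero=False`` leaves zeros
    untouched in the medians; ``True`` substitutes half the smallest
    non-zero value of the pooled data before computing medians.
    """

    abundance_cutoff: float = 0.001
    prevalence_cutoff: float = 0.1
    max_median_cutoff: float = 0.001
    replace_zero: bool = False

    def __post_init__(self) -> None:
        for name in ("abundance_cutoff", "prevalence_cutoff", "max_median_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


#: cutoffs used for the gradient (SIP) comparisons
SIP_FILTERS = FilterParams(0.001, 0.1, 0.001, False)
#: cutoffs used for the microcosm (substrate-response) comparisons
MICROCOSM_FILTERS = FilterParams(0.05, 0.1, 0.001, False)


@dataclass(frozen=True)
class LabelCall:
    """One ASV x window x time point comparison outcome (audit record)."""

    asv_id: str
    timepoint_days: int
    window_name: str
    p_value: float
    mean_treatment: float
    mean_control: float
    n_treatment: int
    n_control: int
    significant: bool
    direction: str  # "up", "down" or "none"


@dataclass(frozen=True)
class LabelSummary:
    """Per-ASV roll-up over time points."""

    asv_id: str
    timepoints_significant: int
    timepoints_tested: int
    labelled: bool
    group_id: str = ""


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    u_statistic: float
    direction: str
    mean_treatment: float
    mean_control: float
    n_treatment: int
    n_control: int
    significant: bool
    method_used: str


@dataclass
class DetectionResult:
    """Output of a full labelling / responder detection run."""

    summaries: list[LabelSummary]
    calls: list[LabelCall]
    alpha: float
    min_timepoints: int
    window_rule: str = "any"

    @property
    def labelled_asvs(self) -> list[str]:
        return [s.asv_id for s in self.summaries if s.labelled]

    def summaries_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.summaries])

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.calls])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def normalize_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Convert a counts table to per-sample relative abundances.

    Zero counts map to zero relative abundance; an all-zero sample column
    is an error (its proportions are undefined).
    """
    if table.mode != "counts":
        raise ValueError("normalize_relative_abundance expects a counts table")
    sums = table.data.sum(axis=0)
    zero_cols = sums.index[sums == 0].tolist()
    if zero_cols:
        raise ValueError(f"all-zero sample column(s): {zero_cols}")
    rel = table.data.div(sums, axis=1)
    return AbundanceTable(data=rel, meta=table.meta.copy(), mode="relative")


def select_window(
    table: AbundanceTable,
    window: WindowSpec,
    treatment: str,
    timepoint: int,
) -> AbundanceTable:
    """Select the heavy-window fraction samples of one treatment/time point.

    Membership is inclusive on both density bounds.  Fewer than
    ``window.min_fractions`` matches is an error; more than
    ``window.max_fractions`` keeps the fractions closest to the window
    midpoint, ties broken toward higher density.
    """
    if table.mode != "relative":
        raise ValueError("select_window expects a relative-abundance table")
    meta = table.meta
    mask = (meta["treatment"] == treatment) & (meta["timepoint_days"] == timepoint)
    cand = meta.index[mask]
    if len(cand) == 0:
        raise ValueError(
            f"no samples for treatment={treatment!r} at day {timepoint}"
        )
    dens = meta.loc[cand, "density"].astype(float)
    if dens.isna().any():
        missing = dens.index[dens.isna()].tolist()
        raise ValueError(f"samples without density metadata: {missing}")
    in_win = cand[(dens >= window.density_min) & (dens <= window.density_max)]
    if len(in_win) < window.min_fractions:
        raise ValueError(
            f"window {window.name!r} has {len(in_win)} fraction(s) for "
            f"{treatment} day {timepoint}; needs >= {window.min_fractions}"
        )
    if len(in_win) > window.max_fractions:
        d = meta.loc[in_win, "density"].astype(float)
        # closest to midpoint first; ties broken toward higher density
        order = sorted(in_win, key=lambda s: (abs(d[s] - window.midpoint), -d[s]))
        in_win = pd.Index(order[: window.max_fractions])
    # keep original column order
    keep = [s for s in table.sample_ids if s in set(in_win)]
    return table.subset_samples(keep)


def _ceil_prevalence(prevalence_cutoff: float, n_samples: int) -> int:
    return max(1, math.ceil(prevalence_cutoff * n_samples))


def filter_taxa(
    treat: AbundanceTable,
    ctrl: AbundanceTable,
    params: FilterParams,
) -> list[str]:
    """ASVs retained for testing, per the prevalence/abundance cutoffs.

    Prevalence is computed over the union of both groups' samples with a
    ceiling rule; the median criterion is group-wise with "at least one
    group" logic.
    """
    if treat.asv_ids != ctrl.asv_ids:
        raise ValueError("treatment and control tables have mismatched ASV ids")
    t = treat.data.to_numpy(dtype=float)
    c = ctrl.data.to_numpy(dtype=float)
    pooled = np.concatenate([t, c], axis=1)
    if params.replace_zero:
        nonzero = pooled[pooled > 0]
        if nonzero.size:
            half_min = 0.5 * nonzero.min()
            t = np.where(t == 0, half_min, t)
            c = np.where(c == 0, half_min, c)
    need = _ceil_prevalence(params.prevalence_cutoff, pooled.shape[1])
    prevalent = (pooled > params.abundance_cutoff).sum(axis=1) >= need
    med_ok = (np.median(t, axis=1) > params.max_median_cutoff) | (
        np.median(c, axis=1) > params.max_median_cutoff
    )
    keep = prevalent & med_ok
    return [a for a, k in zip(treat.asv_ids, keep) if k]


def compare_groups_wilcoxon(
    treat_values: Sequence[float],
    ctrl_values: Sequence[float],
    alpha: float = 0.05,
    method: str = "auto",
    paired: bool = False,
) -> WilcoxonResult:
    """Two-sided rank test of treatment vs control relative abundances.

    ``method`` selects the p-value flavour:

    * ``"auto"`` — exact Mann-Whitney null distribution when the combined n
      is at most 20 (full permutation enumeration over midranks when ties
      are present), otherwise the normal approximation with tie correction
      and continuity correction;
    * ``"exact"`` — same small-sample behaviour as "auto" (large tied
      samples fall back to the approximation);
    * ``"normal"`` — tie-corrected normal approximation *without*
      continuity correction (the flavour used by the Rhea serial group
      comparisons; at triplicate group sizes the extreme configuration
      yields p = 0.0495).

    ``paired=True`` switches to the Wilcoxon signed-rank test (requires
    equal group sizes and an explicit pairing by position); provided for
    sensitivity analysis, as gradient fractions are unpaired.

    ``significant`` requires p <= alpha *and* an enrichment direction
    (mean treatment above mean control).
    """
    x = np.asarray(treat_values, dtype=float)
    y = np.asarray(ctrl_values, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError(f"need >= 3 values per group, got {x.size} and {y.size}")
    if (x < 0).any() or (y < 0).any() or (x > 1).any() or (y > 1).any():
        raise ValueError("relative abundances must lie in [0, 1]")
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")

    mean_t, mean_c = float(x.mean()), float(y.mean())
    if mean_t > mean_c:
        direction = "up"
    elif mean_t < mean_c:
        direction = "down"
    else:
        direction = "none"

    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        # degenerate: no rank information at all
        return WilcoxonResult(1.0, x.size * y.size / 2.0, "none", mean_t, mean_c,
                              x.size, y.size, False, "degenerate")

    if paired:
        if x.size != y.size:
            raise ValueError("paired signed-rank test requires equal group sizes")
        d = x - y
        if np.all(d == 0):
            return WilcoxonResult(1.0, 0.0, "none", mean_t, mean_c,
                                  x.size, y.size, False, "signed-rank")
        res = stats.wilcoxon(x, y, alternative="two-sided")
        p = float(res.pvalue)
        u = float(res.statistic)
        method_used = "signed-rank"
    else:
        has_ties = np.unique(combined).size < combined.size
        if method == "normal":
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            )
            method_used = "normal"
        elif not has_ties and combined.size <= 20:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            method_used = "exact"
        elif has_ties and combined.size <= 20:
            # full enumeration of all C(n, n1) group assignments (the
            # resample cap exceeds C(20,10), so this is never randomized)
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided",
                method=stats.PermutationMethod(n_resamples=200_000),
            )
            method_used = "exact-permutation"
        else:
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            )
            method_used = "normal-tie-corrected"
        p = float(min(res.pvalue, 1.0))
        u = float(res.statistic)

    significant = bool(p <= alpha and direction == "up")
    return WilcoxonResult(p, u, direction, mean_t, mean_c,
                          x.size, y.size, significant, method_used)


def _detect(
    table: AbundanceTable,
    group_selectors: Mapping[int, tuple],
    windows: Sequence[WindowSpec] | None,
    params: FilterParams,
    alpha: float,
    min_timepoints: int,
    window_rule: str,
    method: str,
    fdr: bool,
) -> DetectionResult:
    """Shared serial-comparison engine for gradient and microcosm modes.

    ``group_selectors`` maps each time point to a callable pair producing
    (treatment table, control table) or raising ValueError when a group is
    unavailable; gradient mode wraps select_window, microcosm mode selects
    replicate microcosms.
    """
    if window_rule not in ("any", "all"):
        raise ValueError("window_rule must be 'any' or 'all'")
    calls: list[LabelCall] = []
    sig_by_asv: dict[str, set[int]] = {a: set() for a in table.asv_ids}
    tested_timepoints: list[int] = []

    for tp, selector in group_selectors.items():
        window_tables = []
        try:
            window_tables = selector()
        except ValueError as exc:
            logger.warning("day %s skipped: %s", tp, exc)
            continue
        if not window_tables:
            logger.warning("day %s skipped: no evaluable windows", tp)
            continue
        tested_timepoints.append(tp)
        sig_windows: dict[str, set[str]] = {}
        n_windows = len(window_tables)
        for win_name, treat_tbl, ctrl_tbl in window_tables:
            kept = filter_taxa(treat_tbl, ctrl_tbl, params)
            records = []
            for asv in kept:
                res = compare_groups_wilcoxon(
                    treat_tbl.data.loc[asv].to_numpy(),
                    ctrl_tbl.data.loc[asv].to_numpy(),
                    alpha=alpha,
                    method=method,
                )
                records.append((asv, res))
            if fdr and records:
                padj = stats.false_discovery_control(
                    [r.p_value for _, r in records], method="bh"
                )
                records = [
                    (a, replace(r, p_value=float(q),
                                significant=bool(q <= alpha and r.direction == "up")))
                    for (a, r), q in zip(records, padj)
                ]
            for asv, res in records:
                calls.append(
                    LabelCall(
                        asv_id=asv,
                        timepoint_days=tp,
                        window_name=win_name,
                        p_value=res.p_value,
                        mean_treatment=res.mean_treatment,
                        mean_control=res.mean_control,
                        n_treatment=res.n_treatment,
                        n_control=res.n_control,
                        significant=res.significant,
                        direction=res.direction,
                    )
                )
                if res.significant:
                    sig_windows.setdefault(asv, set()).add(win_name)
        for asv, wins in sig_windows.items():
            ok = len(wins) >= 1 if window_rule == "any" else len(wins) == n_windows
            if ok:
                sig_by_asv[asv].add(tp)

    n_tested = len(tested_timepoints)
    summaries = [
        LabelSummary(
            asv_id=a,
            timepoints_significant=len(sig_by_asv[a]),
            timepoints_tested=n_tested,
            labelled=len(sig_by_asv[a]) >= min_timepoints,
        )
        for a in table.asv_ids
    ]
    summaries.sort(key=lambda s: (-s.timepoints_significant, s.asv_id))
    return DetectionResult(summaries, calls, alpha, min_timepoints, window_rule)


def detect_labelled_asvs(
    table: AbundanceTable,
    windows: Sequence[WindowSpec] = DEFAULT_WINDOWS,
    timepoints: Sequence[int] = (4, 10, 13, 24),
    params: FilterParams = SIP_FILTERS,
    alpha: float = 0.05,
    min_timepoints: int = 3,
    window_rule: str = "any",
    method: str = "auto",
    fdr: bool = False,
    treatment: str = TREATMENT_C13,
    control: str = TREATMENT_C12,
) -> DetectionResult:
    """Call 13C-labelled ASVs from a gradient-fraction abundance table.

    For each time point, heavy-window fraction sets of the 13C treatment
    are compared to the matching windows of the 12C control; an ASV counts
    as significant at that time point under ``window_rule`` ("any": at
    least one window; "all": every evaluable window), and is labelled when
    significant at >= ``min_timepoints`` time points.  Time points where a
    treatment is missing or a window cannot be formed are skipped with a
    warning and excluded from the tested denominator.
    """
    if table.mode == "counts":
        table = normalize_relative_abundance(table)

    def make_selector(tp: int):
        def run():
            out = []
            for w in windows:
                try:
                    treat_tbl = select_window(table, w, treatment, tp)
                    ctrl_tbl = select_window(table, w, control, tp)
                except ValueError as exc:
                    logger.warning("day %s window %s skipped: %s", tp, w.name, exc)
                    continue
                out.append((w.name, treat_tbl, ctrl_tbl))
            if not out:
                raise ValueError("no evaluable window had both treatments")
            return out
        return run

    selectors = {tp: make_selector(tp) for tp in timepoints}
    return _detect(table, selectors, windows, params, alpha,
                   min_timepoints, window_rule, method, fdr)


def detect_substrate_responders(
    table: AbundanceTable,
    substrate: str,
    timepoints: Sequence[int] = (0, 4, 10, 13, 24, 31),
    params: FilterParams = MICROCOSM_FILTERS,
    alpha: float = 0.05,
    min_timepoints: int = 2,
    method: str = "normal",
    fdr: bool = False,
    control: str = TREATMENT_NO_SUBSTRATE,
) -> DetectionResult:
    """Call substrate-responsive ASVs from a microcosm time series.

    Replicate microcosms that received the substrate are compared against
    no-substrate control microcosms within each time point; at least three
    replicates per group are required, otherwise the time point is skipped
    with a warning.  Defaults use the microcosm-mode abundance cutoff
    (0.05) and the Rhea-style normal-approximation p-value, which is the
    only flavour able to reach significance at triplicate group sizes.
    """
    if table.mode == "counts":
        table = normalize_relative_abundance(table)
    meta = table.meta

    def make_selector(tp: int):
        def run():
            t_ids = meta.index[(meta["treatment"] == substrate)
                               & (meta["timepoint_days"] == tp)]
            c_ids = meta.index[(meta["treatment"] == control)
                               & (meta["timepoint_days"] == tp)]
            if len(t_ids) < 3 or len(c_ids) < 3:
                raise ValueError(
                    f"need >= 3 replicates per group, got {len(t_ids)} "
                    f"{substrate!r} and {len(c_ids)} {control!r}"
                )
            return [("microcosm",
                     table.subset_samples(list(t_ids)),
                     table.subset_samples(list(c_ids)))]
        return run

    selectors = {tp: make_selector(tp) for tp in timepoints}
    return _detect(table, selectors, None, params, alpha,
                   min_timepoints, "any", method, fdr)


def aggregate_group_calls(
    summaries: Iterable[LabelSummary],
    asv_to_group: Mapping[str, str],
) -> pd.DataFrame:
    """Roll labelled ASVs up to taxon groups.

    Returns one row per group containing at least one labelled ASV, with
    the labelled-ASV count and ids.  A labelled ASV without a group
    assignment is an error.
    """
    labelled = [s for s in summaries if s.labelled]
    missing = [s.asv_id for s in labelled if not (s.group_id or asv_to_group.get(s.asv_id))]
    if missing:
        raise ValueError(f"labelled ASV(s) without group assignment: {missing}")
    rows: dict[str, list[str]] = {}
    for s in labelled:
        group = s.group_id or asv_to_group[s.asv_id]
        rows.setdefault(group, []).append(s.asv_id)
    out = pd.DataFrame(
        [
            {"group_id": g, "n_labelled_asvs": len(a), "asv_ids": ",".join(sorted(a))}
            for g, a in sorted(rows.items())
        ]
    )
    return out
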