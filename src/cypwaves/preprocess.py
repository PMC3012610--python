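"""Single-color microarray signal conditioning.

The conditioning chain mirrors common practice for single-channel intensity
data: raw fluorescence values are floored at a small positive constant
(default 5 units), a baseline array is chosen as the one with the median of
the per-array median signals, every other array is normalized to that
baseline through a monotone non-linear curve fitted on rank-invariant
probes, duplicate spots are averaged, and probes failing quality control
(saturated in any instance, or never above background in any instance) are
removed.

Rank-invariant probe selection follows the iterative scheme of Schadt-style
invariant-set normalization: starting from all probes, each round ranks the
current set on both arrays and keeps only probes whose rank differs by at
most a fixed fraction of the current set size, until a fixed point.  The
normalization curve is a piecewise-linear running median through the
invariant (target, baseline) pairs, forced monotone, evaluated by linear
interpolation with linear extension beyond the fitted range.

All fitting and mapping happens in log2 space: intensity noise is
multiplicative, so curves fitted on the log scale are stable across the
signal range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_FLOOR = 5.0
DEFAULT_THRESHOLD_FRACTION = 0.02
DEFAULT_MAX_ITER = 30


class NormalizationError(ValueError):
    """Raised when the normalization procedure cannot proceed."""


@dataclass(frozen=True)
class NormCurve:
    """Monotone piecewise-linear normalization curve in log2 space.

    ``x`` are observed (target-array) log2 control points, strictly
    increasing; ``y`` the corrected (baseline-scale) values, non-decreasing.
    Evaluation interpolates linearly and extends the terminal segments
    linearly beyond the fitted range.
    """

    x: np.ndarray
    y: np.ndarray

    def __call__(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        x, y = self.x, self.y
        if len(x) == 1:
            return y[0] + (values - x[0])
        out = np.interp(values, x, y)
        lo = values < x[0]
        if lo.any():
            s = _segment_slope(x[0], y[0], x[1], y[1])
            out[lo] = y[0] + s * (values[lo] - x[0])
        hi = values > x[-1]
        if hi.any():
            s = _segment_slope(x[-2], y[-2], x[-1], y[-1])
            out[hi] = y[-1] + s * (values[hi] - x[-1])
        return out


def _segment_slope(x0, y0, x1, y1) -> float:
    dx = x1 - x0
    return (y1 - y0) / dx if dx > 0 else 1.0


@dataclass
class NormalizationModel:
    """Baseline array plus per-array invariant sets and curves."""

    baseline_array_id: str
    invariant_probes: dict[str, frozenset[str]] = field(default_factory=dict)
    curves: dict[str, NormCurve] = field(default_factory=dict)
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    max_iter: int = DEFAULT_MAX_ITER


@dataclass
class ProbeMatrix:
    """Duplicate-averaged probe x array matrix with aggregated QC flags.

    ``values`` holds normalized linear-scale signals; ``saturated`` and
    ``above_background`` are per probe x array any-spot indicators.
    """

    values: pd.DataFrame
    saturated: pd.DataFrame
    above_background: pd.DataFrame

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def arrays(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class QCReport:
    """Probe-filter accounting: retained = input - saturated - background."""

    n_input_probes: int
    n_removed_saturated: int
    n_removed_background: int

    @property
    def n_retained(self) -> int:
        return self.n_input_probes - self.n_removed_saturated - self.n_removed_background

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input_probes": self.n_input_probes,
            "n_removed_saturated": self.n_removed_saturated,
            "n_removed_background": self.n_removed_background,
            "n_retained": self.n_retained,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def floor_signal(table: pd.DataFrame, floor: float = DEFAULT_FLOOR) -> pd.DataFrame:
    """Replace every signal below ``floor`` with ``floor`` (applied pre-normalization)."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    out = table.copy()
    out["signal"] = out["signal"].clip(lower=floor)
    return out


def array_order(table: pd.DataFrame) -> list[str]:
    """Array ids in first-appearance order (the array index convention)."""
    return list(dict.fromkeys(table["array_id"]))


def select_baseline_array(table: pd.DataFrame) -> str:
    """The array whose per-array median signal is the median of all medians.

    With an even number of arrays the lower-median array is taken; any
    remaining tie resolves to the lowest array index (first appearance).
    """
    if len(table) == 0:
        raise NormalizationError("empty intensity table")
    order = array_order(table)
    medians = table.groupby("array_id")["signal"].median().reindex(order)
    k = len(medians)
    target = np.sort(medians.to_numpy())[(k - 1) // 2]  # lower median
    for array_id, med in medians.items():
        if med == target:
            return array_id
    raise AssertionError("unreachable")


def probe_level_log2(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per probe x array: mean log2 signal over spots, plus any-spot flags.

    Returns ``(log2_means, any_saturated, any_above_background)``.
    """
    work = table.copy()
    work["_log2"] = np.log2(work["signal"])
    g = work.groupby(["probe_id", "array_id"], sort=False)
    log2m = g["_log2"].mean().unstack("array_id")
    sat = g["saturated"].any().unstack("array_id")
    abg = g["above_background"].any().unstack("array_id")
    cols = array_order(table)
    return log2m[cols], sat[cols], abg[cols]


def rank_invariant_probes(
    target: pd.Series,
    baseline: pd.Series,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    max_iter: int = DEFAULT_MAX_ITER,
) -> frozenset[str]:
    """Iteratively select probes whose intensity rank matches across two arrays.

    ``target`` and ``baseline`` are probe-indexed value vectors on the same
    probe universe.  Each round ranks the surviving set on both arrays
    (average ranks on ties) and keeps probes with
    ``|rank_target - rank_baseline| <= threshold_fraction * set size``,
    stopping at a fixed point or after ``max_iter`` rounds.

    Raises
    ------
    NormalizationError
        If the selection would become empty (advising a larger threshold).
    """
    if not target.index.equals(baseline.index):
        baseline = baseline.reindex(target.index)
        if baseline.isna().any():
            raise NormalizationError("target and baseline probe universes differ")
    current = target.index.to_numpy()
    t_all = target.to_numpy(dtype=float)
    b_all = baseline.to_numpy(dtype=float)
    mask = np.ones(len(current), dtype=bool)
    for _ in range(max_iter):
        t_rank = rankdata(t_all[mask], method="average")
        b_rank = rankdata(b_all[mask], method="average")
        keep = np.abs(t_rank - b_rank) <= threshold_fraction * mask.sum()
        if keep.sum() == 0:
            raise NormalizationError(
                "rank-invariant selection became empty; increase threshold_fraction"
            )
        if keep.all():
            break
        new_mask = mask.copy()
        new_mask[np.flatnonzero(mask)[~keep]] = False
        mask = new_mask
    return frozenset(current[mask])


def default_window(n_pairs: int) -> int:
    """Running-median window: min(101, ~10% of the invariant set), odd, >= 3."""
    w = min(101, max(3, int(np.ceil(0.1 * n_pairs))))
    return w if w % 2 == 1 else w + 1


def fit_normalization_curve(
    target_log2: np.ndarray,
    baseline_log2: np.ndarray,
    window: int | None = None,
) -> NormCurve:
    """Fit the piecewise-linear running-median curve through invariant pairs.

    Pairs are sorted by target value; control points pair each target value
    with the running median of baseline values over a centered window, with
    monotonicity enforced by a cumulative maximum.
    """
    t = np.asarray(target_log2, dtype=float)
    b = np.asarray(baseline_log2, dtype=float)
    if t.shape != b.shape or t.ndim != 1:
        raise ValueError("target and baseline must be 1-D arrays of equal length")
    if window is None:
        window = default_window(len(t))
    if len(t) < window:
        raise NormalizationError(
            f"need at least window={window} invariant pairs, got {len(t)}"
        )
    order = np.argsort(t, kind="stable")
    t_sorted, b_sorted = t[order], b[order]
    # centered running median; near the ends the window shrinks symmetrically
    # so that monotone input maps through exactly
    half = window // 2
    n = len(b_sorted)
    running = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        running[i] = np.median(b_sorted[i - h : i + h + 1])
    # collapse duplicate x to keep control-point x strictly increasing
    x_unique, inverse = np.unique(t_sorted, return_inverse=True)
    y_unique = np.bincount(inverse, weights=running) / np.bincount(inverse)
    y_monotone = np.maximum.accumulate(y_unique)
    return NormCurve(x=x_unique, y=y_monotone)


def fit_normalization(
    table: pd.DataFrame,
    baseline_array_id: str | None = None,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    max_iter: int = DEFAULT_MAX_ITER,
    window: int | None = None,
) -> NormalizationModel:
    """Fit the full normalization model on a floored intensity table.

    Saturated instances are excluded from curve fitting (their probe-level
    values are unreliable) but stay in the table for flag propagation.
    """
    log2m, sat, _ = probe_level_log2(table)
    if baseline_array_id is None:
        baseline_array_id = select_baseline_array(table)
    if baseline_array_id not in log2m.columns:
        raise NormalizationError(f"baseline array {baseline_array_id!r} not in table")
    model = NormalizationModel(
        baseline_array_id=baseline_array_id,
        threshold_fraction=threshold_fraction,
        max_iter=max_iter,
    )
    base_vals = log2m[baseline_array_id]
    base_sat = sat[baseline_array_id]
    for array_id in log2m.columns:
        if array_id == baseline_array_id:
            continue
        usable = ~(sat[array_id] | base_sat)
        inv = rank_invariant_probes(
            log2m.loc[usable, array_id],
            base_vals[usable],
            threshold_fraction=threshold_fraction,
            max_iter=max_iter,
        )
        inv_list = [p for p in log2m.index if p in inv]
        curve = fit_normalization_curve(
            log2m.loc[inv_list, array_id].to_numpy(),
            base_vals.loc[inv_list].to_numpy(),
            window=window,
        )
        model.invariant_probes[array_id] = inv
        model.curves[array_id] = curve
    return model


def normalize_arrays(table: pd.DataFrame, model: NormalizationModel) -> pd.DataFrame:
    """Map every instance value through its array's curve (baseline unchanged).

    Adds ``log2_norm`` and ``signal_norm`` columns.
    """
    out = table.copy()
    log2_raw = np.log2(out["signal"].to_numpy(dtype=float))
    log2_norm = np.empty_like(log2_raw)
    for array_id, idx in out.groupby("array_id", sort=False).indices.items():
        if array_id == model.baseline_array_id:
            log2_norm[idx] = log2_raw[idx]
        elif array_id in model.curves:
            log2_norm[idx] = model.curves[array_id](log2_raw[idx])
        else:
            raise NormalizationError(f"array {array_id!r} missing from model")
    out["log2_norm"] = log2_norm
    out["signal_norm"] = np.exp2(log2_norm)
    return out


def average_duplicates(table: pd.DataFrame) -> ProbeMatrix:
    """Average duplicate spots per probe x array on the normalized linear scale.

    Flags aggregate per probe x array instance: saturated if any spot
    saturated, above background if any spot above background.
    """
    value_col = "signal_norm" if "signal_norm" in table.columns else "signal"
    g = table.groupby(["probe_id", "array_id"], sort=False)
    values = g[value_col].mean().unstack("array_id")
    sat = g["saturated"].any().unstack("array_id")
    abg = g["above_background"].any().unstack("array_id")
    cols = array_order(table)
    return ProbeMatrix(values=values[cols], saturated=sat[cols], above_background=abg[cols])


def qc_filter_probes(matrix: ProbeMatrix) -> tuple[ProbeMatrix, QCReport]:
    """Remove saturated and never-above-background probes.

    A probe is removed when saturated in any instance (counted first), or —
    among the remainder — when above background in no instance; the two
    removal categories are therefore disjoint.
    """
    sat_any = matrix.saturated.any(axis=1)
    bg_never = ~matrix.above_background.any(axis=1) & ~sat_any
    keep = ~sat_any & ~bg_never
    report = QCReport(
        n_input_probes=len(matrix.probes),
        n_removed_saturated=int(sat_any.sum()),
        n_removed_background=int(bg_never.sum()),
    )
    filtered = ProbeMatrix(
        values=matrix.values.loc[keep],
        saturated=matrix.saturated.loc[keep],
        above_background=matrix.above_background.loc[keep],
    )
    return filtered, report


def preprocess_pipeline(
    table: pd.DataFrame,
    floor: float = DEFAULT_FLOOR,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    max_iter: int = DEFAULT_MAX_ITER,
    window: int | None = None,
    baseline_array_id: str | None = None,
) -> tuple[ProbeMatrix, QCReport, NormalizationModel]:
    """Full conditioning chain: floor, normalize, average duplicates, QC filter."""
    floored = floor_signal(table, floor=floor)
    model = fit_normalization(
        floored,
        baseline_array_id=baseline_array_id,
        threshold_fraction=threshold_fraction,
        max_iter=max_iter,
        window=window,
    )
    normalized = normalize_arrays(floored, model)
    matrix = average_duplicates(normalized)
    filtered, report = qc_filter_probes(matrix)
    return filtered, report, model
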