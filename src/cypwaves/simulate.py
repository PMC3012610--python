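"""Seeded synthetic data emulating the developmental expression study design.

The microarray generator emulates a single-color embryo time course: six
sampling times (3, 6, 12, 24, 36, 48 hours post-fertilization), four
independently maintained dishes as biological replicates, and every probe
printed twice per array.  Probes are drawn from five temporal archetypes:

``maternal_decay``
    maternally deposited transcript decaying log-linearly from 3 hpf;
``unimodal_wave``
    a single Gaussian wave of zygotic expression (one "wave" of development);
``bimodal``
    elevated expression at both the first and last sampling times;
``flat``
    constant expression (not differentially expressed);
``below_background``
    spots indistinguishable from background, flagged as such.

Signals are built in log2 space (baseline ~ Normal(8, 2) log2 units) with
multiplicative (log-normal) replicate and spot noise, then distorted per
array by a monotone affine warp ``y = a + b*x`` emulating between-array
intensity differences, exponentiated to linear fluorescence units, and
clipped at a 16-bit scanner ceiling with a saturation flag.  The paired
:class:`SyntheticTruth` records every planted label and parameter and serves
as ground truth for recovery tests downstream.

qPCR generators produce serial-dilution plasmid standards and sample Ct
tables from a known standard-curve model, and oocyte panels with planted
maternal transcript copy numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Column order of the long-format intensity table TSV dialect.
INTENSITY_COLUMNS = (
    "probe_id",
    "spot_index",
    "array_id",
    "timepoint_hpf",
    "replicate",
    "signal",
    "saturated",
    "above_background",
)

ARCHETYPES = ("maternal_decay", "unimodal_wave", "bimodal", "flat", "below_background")

#: Archetypes that constitute true temporal differential expression.
DE_ARCHETYPES = frozenset({"maternal_decay", "unimodal_wave", "bimodal"})

SATURATION_CEILING = 65535.0


class ConfigError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass(frozen=True)
class ArrayDesign:
    """The sampling design: timepoints x replicates, spots per probe."""

    timepoints_hpf: tuple[float, ...] = (3.0, 6.0, 12.0, 24.0, 36.0, 48.0)
    replicates: tuple[str, ...] = ("A", "B", "C", "D")
    spots_per_probe: int = 2
    n_probes: int = 2000

    def __post_init__(self) -> None:
        if len(self.timepoints_hpf) < 2:
            raise ConfigError("need at least 2 timepoints")
        if len(self.replicates) < 2:
            raise ConfigError("need at least 2 replicates")
        if self.spots_per_probe < 1:
            raise ConfigError("spots_per_probe must be >= 1")

    @property
    def array_ids(self) -> list[str]:
        return [
            f"{_fmt_time(t)}hpf_{r}" for t in self.timepoints_hpf for r in self.replicates
        ]

    @property
    def n_arrays(self) -> int:
        return len(self.timepoints_hpf) * len(self.replicates)


def _fmt_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of one temporal archetype.

    ``decay_slope`` is in log2 units per hour (maternal decay); wave
    parameters are the Gaussian amplitude (log2 units; ``None`` draws
    amplitudes uniformly from ``amplitude_range`` per probe), center (hpf)
    and width (hours, the Gaussian sigma).
    """

    kind: str
    decay_slope: float = -0.15
    amplitude: float | None = None
    amplitude_range: tuple[float, float] = (1.0, 3.5)
    center: float = 24.0
    width: float = 6.0

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPES:
            raise ConfigError(f"unknown archetype kind {self.kind!r}")
        if self.amplitude is not None and self.amplitude < 0:
            raise ConfigError("amplitude must be >= 0")
        if self.width <= 0:
            raise ConfigError("width must be > 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth paired with a generated intensity table.

    ``probes`` has one row per probe: archetype label and parameters, the
    DE flag, planted cluster id, and the below-background indicator.
    ``arrays`` records the per-array monotone warp ``y = a + b*x``.
    """

    probes: pd.DataFrame
    arrays: pd.DataFrame
    saturated_probes: frozenset[str] = field(default_factory=frozenset)
    background_probes: frozenset[str] = field(default_factory=frozenset)

    def de_probe_ids(self) -> list[str]:
        return self.probes.loc[self.probes["de"], "probe_id"].tolist()

    def probes_of_kind(self, kind: str) -> list[str]:
        return self.probes.loc[self.probes["archetype"] == kind, "probe_id"].tolist()


def _archetype_counts(mix: Mapping[str, float], n: int) -> dict[str, int]:
    total = float(sum(mix.values()))
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"archetype proportions sum to {total}, expected 1")
    # largest-remainder apportionment: exact counts, deterministic
    raw = {k: v * n for k, v in mix.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(mix, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


def _resolve_specs(archetype_mix) -> tuple[list[ArchetypeSpec], list[float]]:
    specs: list[ArchetypeSpec] = []
    props: list[float] = []
    for key, prop in archetype_mix.items():
        spec = key if isinstance(key, ArchetypeSpec) else ArchetypeSpec(kind=key)
        specs.append(spec)
        props.append(float(prop))
    return specs, props


def generate_timecourse(
    design: ArrayDesign | None = None,
    archetype_mix: Mapping | None = None,
    noise: tuple[float, float] = (0.25, 0.10),
    distortion: str | Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a full probe-level time-course with known ground truth.

    Parameters
    ----------
    design
        Sampling design; default is the 6-timepoint x 4-replicate embryo
        series with duplicate spots.
    archetype_mix
        Mapping of archetype kind (or :class:`ArchetypeSpec`) to proportion;
        proportions must sum to 1.  Default plants 15% maternal decay, 25%
        unimodal waves, 5% bimodal, 50% flat and 5% below-background probes.
    noise
        ``(sigma_rep, sigma_spot)``: biological-replicate and spot-level
        standard deviations in log2 units.
    distortion
        ``"identity"`` for no between-array warp, or a mapping with
        ``offset_range`` and ``slope_range`` for the per-array affine warp
        ``y = a + b*x`` (defaults a ~ U(-0.5, 0.5), b ~ U(0.8, 1.25)).
    seed
        Seed for all randomness; identical seeds give identical outputs.

    Returns
    -------
    (table, truth)
        ``table`` is the long-format intensity table (one row per probe x
        spot x array); ``truth`` the planted :class:`SyntheticTruth`.
    """
    design = design or ArrayDesign()
    if archetype_mix is None:
        archetype_mix = {
            "maternal_decay": 0.15,
            "unimodal_wave": 0.25,
            "bimodal": 0.05,
            "flat": 0.50,
            "below_background": 0.05,
        }
    specs, props = _resolve_specs(archetype_mix)
    counts = _archetype_counts(
        {i: p for i, p in enumerate(props)}, design.n_probes
    )
    sigma_rep, sigma_spot = noise
    rng = np.random.default_rng(seed)

    n = design.n_probes
    width = len(str(max(n - 1, 1)))
    probe_ids = np.array([f"P{i:0{width}d}" for i in range(n)])
    spec_index = np.repeat(np.arange(len(specs)), [counts[i] for i in range(len(specs))])
    spec_index = rng.permutation(spec_index)

    times = np.asarray(design.timepoints_hpf, dtype=float)
    t0, t_last = times[0], times[-1]
    n_t, n_r, n_s = len(times), len(design.replicates), design.spots_per_probe

    baseline = rng.normal(8.0, 2.0, size=n)
    effect = np.zeros((n, n_t))
    amplitude = np.full(n, np.nan)
    center = np.full(n, np.nan)
    wave_width = np.full(n, np.nan)
    slope = np.full(n, np.nan)
    kinds = np.array([specs[i].kind for i in spec_index])

    for si, spec in enumerate(specs):
        mask = spec_index == si
        m = int(mask.sum())
        if m == 0:
            continue
        if spec.kind == "maternal_decay":
            slope[mask] = spec.decay_slope
            effect[mask] = spec.decay_slope * (times - t0)[None, :]
        elif spec.kind in ("unimodal_wave", "bimodal"):
            if spec.amplitude is None:
                amp = rng.uniform(*spec.amplitude_range, size=m)
            else:
                amp = np.full(m, spec.amplitude)
            amplitude[mask] = amp
            wave_width[mask] = spec.width
            if spec.kind == "unimodal_wave":
                center[mask] = spec.center
                bump = np.exp(-((times - spec.center) ** 2) / (2 * spec.width**2))
                effect[mask] = amp[:, None] * bump[None, :]
            else:
                bump = np.exp(-((times - t0) ** 2) / (2 * spec.width**2)) + np.exp(
                    -((times - t_last) ** 2) / (2 * spec.width**2)
                )
                effect[mask] = amp[:, None] * bump[None, :]
        # flat and below_background: no temporal effect

    # per-array monotone warp
    if distortion == "identity":
        warp_a = np.zeros(design.n_arrays)
        warp_b = np.ones(design.n_arrays)
    else:
        dist = dict(distortion or {})
        a_lo, a_hi = dist.get("offset_range", (-0.5, 0.5))
        b_lo, b_hi = dist.get("slope_range", (0.8, 1.25))
        warp_a = rng.uniform(a_lo, a_hi, size=design.n_arrays)
        warp_b = rng.uniform(b_lo, b_hi, size=design.n_arrays)

    true_log2 = baseline[:, None] + effect  # (n, n_t)
    rep_noise = rng.normal(0.0, sigma_rep, size=(n, n_t, n_r)) if sigma_rep > 0 else np.zeros((n, n_t, n_r))
    spot_noise = (
        rng.normal(0.0, sigma_spot, size=(n, n_t, n_r, n_s)) if sigma_spot > 0 else np.zeros((n, n_t, n_r, n_s))
    )
    log2_vals = true_log2[:, :, None, None] + rep_noise[:, :, :, None] + spot_noise

    warp = (warp_a.reshape(n_t, n_r), warp_b.reshape(n_t, n_r))
    log2_warped = warp[0][None, :, :, None] + warp[1][None, :, :, None] * log2_vals
    linear = np.exp2(log2_warped)

    below_bg = kinds == "below_background"
    if below_bg.any():
        m = int(below_bg.sum())
        from scipy.stats import truncnorm

        bg_draw = truncnorm.rvs(
            a=(0.0 - 4.0) / 1.0, b=np.inf, loc=4.0, scale=1.0,
            size=(m, n_t, n_r, n_s), random_state=rng,
        )
        linear[below_bg] = bg_draw

    saturated = linear > SATURATION_CEILING
    linear = np.minimum(linear, SATURATION_CEILING)

    # long-format table, fixed ordering: probe-major, then timepoint, replicate, spot
    arr_ids = np.array(design.array_ids).reshape(n_t, n_r)
    idx = pd.MultiIndex.from_product(
        [probe_ids, times, list(design.replicates), range(n_s)],
        names=["probe_id", "timepoint_hpf", "replicate", "spot_index"],
    )
    table = pd.DataFrame(index=idx).reset_index()
    table["array_id"] = [
        f"{_fmt_time(t)}hpf_{r}" for t, r in zip(table["timepoint_hpf"], table["replicate"])
    ]
    table["signal"] = linear.reshape(-1)
    table["saturated"] = saturated.reshape(-1)
    table["above_background"] = ~np.repeat(below_bg, n_t * n_r * n_s)
    table = table[list(INTENSITY_COLUMNS)]

    sat_probes = frozenset(probe_ids[saturated.any(axis=(1, 2, 3))])
    truth_probes = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "archetype": kinds,
            "de": np.isin(kinds, list(DE_ARCHETYPES)),
            "cluster_id": spec_index,
            "baseline_log2": baseline,
            "decay_slope": slope,
            "amplitude": amplitude,
            "center_hpf": center,
            "width_h": wave_width,
        }
    )
    truth_arrays = pd.DataFrame(
        {"array_id": arr_ids.reshape(-1), "warp_offset": warp_a, "warp_slope": warp_b}
    )
    truth = SyntheticTruth(
        probes=truth_probes,
        arrays=truth_arrays,
        saturated_probes=sat_probes,
        background_probes=frozenset(probe_ids[below_bg]),
    )
    return table, truth


def true_timepoint_means(truth: SyntheticTruth, design: ArrayDesign | None = None) -> pd.DataFrame:
    """Noise-free log2 expression per probe x timepoint implied by the truth."""
    design = design or ArrayDesign()
    times = np.asarray(design.timepoints_hpf, dtype=float)
    t0, t_last = times[0], times[-1]
    out = np.tile(truth.probes["baseline_log2"].to_numpy()[:, None], (1, len(times)))
    kinds = truth.probes["archetype"].to_numpy()
    slope = truth.probes["decay_slope"].to_numpy()
    amp = truth.probes["amplitude"].to_numpy()
    ctr = truth.probes["center_hpf"].to_numpy()
    wid = truth.probes["width_h"].to_numpy()
    m = kinds == "maternal_decay"
    out[m] += slope[m, None] * (times - t0)[None, :]
    m = kinds == "unimodal_wave"
    out[m] += amp[m, None] * np.exp(-((times[None, :] - ctr[m, None]) ** 2) / (2 * wid[m, None] ** 2))
    m = kinds == "bimodal"
    bump = lambda c: np.exp(-((times[None, :] - c) ** 2) / (2 * wid[m, None] ** 2))  # noqa: E731
    out[m] += amp[m, None] * (bump(t0) + bump(t_last))
    return pd.DataFrame(out, index=truth.probes["probe_id"].to_numpy(), columns=times)


def generate_qc_flag_fixture(
    n_probes: int = 21893,
    n_saturated: int = 10,
    n_background: int = 82,
    design: ArrayDesign | None = None,
    seed: int = 0,
):
    """Probe x array matrix with planted QC flag patterns, at full array scale.

    Builds the aggregated (duplicate-averaged) representation directly:
    ``n_saturated`` probes saturate in at least one instance, a disjoint set
    of ``n_background`` probes is never above background, and every other
    probe is above background in at least one instance.  Used as the worked
    example for the QC filter at the real array's probe count.
    """
    from .preprocess import ProbeMatrix

    if n_saturated + n_background > n_probes:
        raise ConfigError("flagged probes exceed probe count")
    design = design or ArrayDesign(n_probes=n_probes)
    rng = np.random.default_rng(seed)
    width = len(str(n_probes - 1))
    probes = [f"P{i:0{width}d}" for i in range(n_probes)]
    arrays = design.array_ids
    n_a = len(arrays)

    values = np.exp2(rng.normal(8.0, 2.0, size=(n_probes, n_a)))
    saturated = np.zeros((n_probes, n_a), dtype=bool)
    above_bg = np.ones((n_probes, n_a), dtype=bool)

    order = rng.permutation(n_probes)
    sat_idx = order[:n_saturated]
    bg_idx = order[n_saturated : n_saturated + n_background]
    for i in sat_idx:  # saturated in one to three random instances
        cols = rng.choice(n_a, size=rng.integers(1, 4), replace=False)
        saturated[i, cols] = True
        values[i, cols] = SATURATION_CEILING
    above_bg[bg_idx, :] = False
    # a sprinkle of retained probes above background in only one instance:
    patchy = order[n_saturated + n_background : n_saturated + n_background + 50]
    above_bg[patchy, :] = False
    above_bg[patchy, rng.integers(0, n_a, size=len(patchy))] = True

    frame = pd.DataFrame(values, index=probes, columns=arrays)
    return ProbeMatrix(
        values=frame,
        saturated=pd.DataFrame(saturated, index=probes, columns=arrays),
        above_background=pd.DataFrame(above_bg, index=probes, columns=arrays),
    )


def generate_oocyte_samples(
    genes: Sequence[str],
    maternal_set: Sequence[str],
    seed: int = 0,
    n_samples: int = 3,
    maternal_copies: float | Mapping[str, float] = 1000.0,
    background_copies: float = 1.0,
    reference_copies: float = 5000.0,
    cv: float = 0.2,
    reference_gene: str = "ARNT2",
) -> pd.DataFrame:
    """True transcript copy numbers for unfertilized-egg samples.

    Maternally deposited genes get positive planted copy numbers; all others
    sit near zero.  The reference transcript (ARNT2) is always included.
    With ``cv = 0`` the table is exactly the planted values.
    """
    maternal = set(maternal_set)
    unknown = maternal - set(genes)
    if unknown:
        raise ConfigError(f"maternal_set genes not in panel: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    all_genes = list(genes)
    if reference_gene not in all_genes:
        all_genes.append(reference_gene)
    rows = []
    for sample_i in range(1, n_samples + 1):
        sample = f"egg{sample_i}"
        for gene in all_genes:
            if gene == reference_gene:
                base = reference_copies
            elif gene in maternal:
                base = (
                    maternal_copies[gene]
                    if isinstance(maternal_copies, Mapping)
                    else maternal_copies
                )
            else:
                base = background_copies
            noise = np.exp(rng.normal(0.0, cv)) if cv > 0 else 1.0
            rows.append({"gene": gene, "sample": sample, "true_copies": base * noise})
    return pd.DataFrame(rows)


def generate_qpcr_panel(
    genes: Sequence[str],
    true_counts: pd.DataFrame,
    curve: tuple[float, float] = (-3.3219, 40.0),
    sigma_ct: float = 0.15,
    seed: int = 0,
    standard_levels: Sequence[float] = tuple(10.0**k for k in range(1, 8)),
    standard_replicates: int = 3,
) -> pd.DataFrame:
    """Ct table with serial-dilution standards for a panel of genes.

    ``true_counts`` must have columns ``gene``, ``sample``, ``true_copies``.
    Every Ct is drawn as ``intercept + slope*log10(copies) + N(0, sigma_ct)``.
    Standards cover 10-fold dilutions (default 10^1..10^7 copies) in
    triplicate and carry their known copy numbers; sample rows leave
    ``known_copies`` empty.
    """
    slope, intercept = curve
    if slope >= 0:
        raise ConfigError(f"standard-curve slope must be negative, got {slope}")
    counts = true_counts[true_counts["gene"].isin(list(genes))]
    if (counts["true_copies"] <= 0).any():
        bad = counts.loc[counts["true_copies"] <= 0, "gene"].unique()
        raise ConfigError(f"non-positive copy numbers for {list(bad)}")
    rng = np.random.default_rng(seed)

    def ct_of(copies: float) -> float:
        ct = intercept + slope * np.log10(copies)
        return ct + (rng.normal(0.0, sigma_ct) if sigma_ct > 0 else 0.0)

    rows = []
    for gene in genes:
        for level in standard_levels:
            for rep in range(1, standard_replicates + 1):
                rows.append(
                    {
                        "gene": gene,
                        "sample": f"std_{level:g}",
                        "replicate": rep,
                        "Ct": ct_of(level),
                        "known_copies": level,
                    }
                )
    for _, row in counts.iterrows():
        rows.append(
            {
                "gene": row["gene"],
                "sample": row["sample"],
                "replicate": 1,
                "Ct": ct_of(row["true_copies"]),
                "known_copies": np.nan,
            }
        )
    return pd.DataFrame(rows)


def write_intensity_table(table: pd.DataFrame, path) -> None:
    """Write the long-format intensity table in its TSV dialect."""
    table.to_csv(path, sep="\t", index=False)


def read_intensity_table(path) -> pd.DataFrame:
    """Read an intensity table TSV, validating the column set."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing intensity column(s) {missing}")
    return df
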