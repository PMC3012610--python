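"""Absolute quantification by qPCR with plasmid standard curves.

For each gene, a standard curve is fitted by least squares of threshold
cycle (Ct) on log10 of known plasmid copy number across a 10-fold serial
dilution series.  The slope gives the amplification efficiency
``E = 10^(-1/slope) - 1`` (a perfect doubling per cycle corresponds to a
slope of -3.3219 and E = 1).  Unknown samples are converted to absolute
molecule counts by inverting the curve, ``copies = 10^((Ct - intercept) /
slope)``, and expressed relative to the ARNT2 reference transcript, whose
developmental expression is substantially more stable than the classic
beta-actin control.  Per-gene concordance between platforms (microarray vs
qPCR, both reference-normalized) is summarized by Pearson correlation and a
linear fit across timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_REFERENCE_GENE = "ARNT2"


class CalibrationError(ValueError):
    """Raised when a standard curve cannot be fitted or is unusable."""


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit Ct = intercept + slope * log10(copies) with efficiency."""

    gene: str
    slope: float
    intercept: float
    r_squared: float
    ct_range: tuple[float, float]  # calibrated Ct range of the standards

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, E = 10^(-1/slope) - 1 (1.0 = doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(standards: pd.DataFrame, gene: str = "") -> StandardCurve:
    """Fit a standard curve from a serial-dilution table.

    ``standards`` needs columns ``known_copies`` and ``Ct`` (rows with
    missing ``known_copies`` are ignored); at least three distinct dilution
    levels are required and the fitted slope must be negative.
    """
    std = standards.dropna(subset=["known_copies"])
    if std.empty:
        raise CalibrationError("no standards provided")
    copies = std["known_copies"].to_numpy(dtype=float)
    if (copies <= 0).any():
        raise CalibrationError("standard copy numbers must be positive")
    if len(np.unique(copies)) < 3:
        raise CalibrationError("need at least 3 distinct dilution levels")
    x = np.log10(copies)
    y = std["Ct"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise CalibrationError(f"standard-curve slope is non-negative ({fit.slope:.3f})")
    return StandardCurve(
        gene=gene,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        ct_range=(float(y.min()), float(y.max())),
    )


def molecule_count(curve: StandardCurve, ct: float | np.ndarray) -> np.ndarray:
    """Absolute copies from Ct: ``10^((Ct - intercept) / slope)``.

    Strictly decreasing in Ct for the (required) negative slope.  Values are
    returned even outside the calibrated range; use
    :func:`is_extrapolated` to flag them.
    """
    ct = np.asarray(ct, dtype=float)
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def is_extrapolated(curve: StandardCurve, ct: float | np.ndarray) -> np.ndarray:
    """True where a Ct lies outside the standards' calibrated Ct range."""
    ct = np.asarray(ct, dtype=float)
    lo, hi = curve.ct_range
    return (ct < lo) | (ct > hi)


def quantify_samples(
    ct_table: pd.DataFrame, curves: dict[str, StandardCurve] | None = None
) -> pd.DataFrame:
    """Convert a Ct table to absolute molecule counts per gene and sample.

    ``ct_table`` follows the qPCR CSV dialect (columns gene, sample,
    replicate, Ct, known_copies); standards (rows with ``known_copies``) are
    used to fit per-gene curves unless ``curves`` is supplied, and are
    excluded from the returned sample quantifications.  Output columns:
    gene, sample, replicate, Ct, copies, extrapolated.
    """
    if curves is None:
        curves = {
            gene: fit_standard_curve(sub, gene=gene)
            for gene, sub in ct_table.groupby("gene", sort=False)
        }
    samples = ct_table[ct_table["known_copies"].isna()] if "known_copies" in ct_table else ct_table
    rows = []
    for _, row in samples.iterrows():
        gene = row["gene"]
        if gene not in curves:
            raise CalibrationError(f"no standard curve for gene {gene!r}")
        curve = curves[gene]
        ct = float(row["Ct"])
        rows.append(
            {
                "gene": gene,
                "sample": row["sample"],
                "replicate": row.get("replicate", 1),
                "Ct": ct,
                "copies": float(molecule_count(curve, ct)),
                "extrapolated": bool(is_extrapolated(curve, ct)),
            }
        )
    return pd.DataFrame(rows)


def normalize_to_reference(
    counts: pd.DataFrame, reference_gene: str = DEFAULT_REFERENCE_GENE
) -> pd.DataFrame:
    """Express molecule counts relative to the reference gene per sample.

    ``counts`` needs columns gene, sample, copies (replicate optional).  The
    ratio divides each gene's count by the reference count in the same
    sample (and replicate, when present); the ratio is invariant to any
    global scale factor applied to a sample.  A zero reference count is an
    error for that sample.
    """
    keys = ["sample", "replicate"] if "replicate" in counts.columns else ["sample"]
    ref = counts[counts["gene"] == reference_gene].set_index(keys)["copies"]
    if ref.empty:
        raise CalibrationError(f"reference gene {reference_gene!r} absent from counts")
    if (ref == 0).any():
        bad = ref.index[ref == 0].tolist()
        raise CalibrationError(f"reference count is zero in sample(s) {bad}")
    out = counts[counts["gene"] != reference_gene].copy()
    idx = pd.MultiIndex.from_frame(out[keys]) if len(keys) > 1 else out[keys[0]]
    out["normalized"] = out["copies"].to_numpy() / ref.reindex(idx).to_numpy()
    if out["normalized"].isna().any():
        missing = out.loc[out["normalized"].isna(), "sample"].unique().tolist()
        raise CalibrationError(f"reference count missing for sample(s) {missing}")
    return out


def summarize_replicates(
    normalized: pd.DataFrame, aggregate: str = "mean"
) -> pd.DataFrame:
    """Mean (or median) and SD of normalized ratios across biological replicates."""
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    g = normalized.groupby(["gene", "sample"], sort=False)["normalized"]
    agg = g.mean() if aggregate == "mean" else g.median()
    out = pd.DataFrame({"normalized": agg, "sd": g.std(ddof=1)})
    return out.reset_index()


@dataclass(frozen=True)
class ConcordanceReport:
    gene: str
    pearson_r: float
    slope: float
    intercept: float
    n: int
    concordant: bool


def platform_concordance(
    array_values: pd.DataFrame,
    qpcr_values: pd.DataFrame,
    r_threshold: float = 0.9,
) -> list[ConcordanceReport]:
    """Per-gene linearity between reference-normalized array and qPCR series.

    Both inputs are gene x timepoint tables (same genes and timepoints, each
    already normalized to the reference transcript).  Genes need at least
    three paired timepoints; a constant series has undefined correlation and
    is flagged non-concordant with ``r = nan``.
    """
    common = array_values.index.intersection(qpcr_values.index)
    reports = []
    for gene in common:
        a = array_values.loc[gene].to_numpy(dtype=float)
        q = qpcr_values.loc[gene].to_numpy(dtype=float)
        mask = ~(np.isnan(a) | np.isnan(q))
        if mask.sum() < 3:
            raise CalibrationError(f"{gene}: need >= 3 paired timepoints")
        a, q = a[mask], q[mask]
        if np.allclose(a, a[0]) or np.allclose(q, q[0]):
            reports.append(ConcordanceReport(gene, np.nan, np.nan, np.nan, int(mask.sum()), False))
            continue
        fit = stats.linregress(a, q)
        r = float(fit.rvalue)
        reports.append(
            ConcordanceReport(
                gene=gene,
                pearson_r=r,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                n=int(mask.sum()),
                concordant=bool(r >= r_threshold),
            )
        )
    return reports
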