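"""Temporal differential expression over the developmental time series.

Standard per-timepoint ANOVA ignores the autocorrelation between successive
developmental stages, so the primary caller is an empirical-Bayes model in
the style of Bayesian estimation of temporal regulation: for each probe the
vector of timepoint mean differences relative to the reference timepoint
(3 hpf) is modelled as a two-component multivariate-normal mixture,

* null: ``d ~ N(0, Sigma0)`` where ``Sigma0 = sigma_g^2 * C`` is the
  replicate-noise covariance (``C = (I + J)/n`` accounts for the shared
  reference mean; ``sigma_g^2`` is the probe's residual variance shrunk
  toward the pooled average),
* differentially expressed: ``d ~ N(0, Sigma0 + Sigma1)`` with ``Sigma1`` an
  empirically estimated signal covariance free to carry temporal
  autocorrelation.

The mixture weight and ``Sigma1`` are estimated by expectation-maximization
over all probes; each probe's posterior probability of the second component
is its probability of differential expression.  A naive one-way ANOVA across
timepoints is provided as a comparator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_ARRAY_ID_RE = re.compile(r"^(?P<t>\d+(?:\.\d+)?)hpf_(?P<rep>.+)$")


class DesignError(ValueError):
    """Raised for incomplete or degenerate time-course designs."""


@dataclass
class TimeCourseMatrix:
    """Probe x (timepoint, replicate) log2 values, median-centered per probe.

    ``data`` carries a two-level column MultiIndex (timepoint_hpf,
    replicate); the design must be complete (every cell present) with at
    least two replicates per timepoint.
    """

    data: pd.DataFrame
    reference_timepoint: float

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.data.columns.get_level_values(0).unique())

    @property
    def n_replicates(self) -> int:
        return len(self.data.columns.get_level_values(1).unique())

    def values_by_timepoint(self) -> np.ndarray:
        """Array of shape (probes, timepoints, replicates), timepoints sorted."""
        tps = self.timepoints
        reps = sorted(self.data.columns.get_level_values(1).unique())
        cols = pd.MultiIndex.from_product([tps, reps], names=self.data.columns.names)
        return self.data[cols].to_numpy().reshape(len(self.data), len(tps), len(reps))


@dataclass
class DEResult:
    """Per-probe DE calls: posterior probability, ANOVA p, significance."""

    frame: pd.DataFrame  # columns: posterior, anova_p, significant
    alpha: float = 0.01

    @property
    def posterior(self) -> pd.Series:
        return self.frame["posterior"]

    @property
    def anova_p(self) -> pd.Series:
        return self.frame["anova_p"]

    @property
    def significant(self) -> pd.Series:
        return self.frame["significant"]


def _parse_columns(columns) -> pd.MultiIndex:
    if isinstance(columns, pd.MultiIndex):
        return columns
    parsed = []
    for c in columns:
        m = _ARRAY_ID_RE.match(str(c))
        if m is None:
            raise DesignError(
                f"cannot parse array id {c!r}; expected '<time>hpf_<replicate>'"
            )
        parsed.append((float(m.group("t")), m.group("rep")))
    return pd.MultiIndex.from_tuples(parsed, names=["timepoint_hpf", "replicate"])


def log_median_center(values: pd.DataFrame, reference_timepoint: float | None = None) -> TimeCourseMatrix:
    """log2-transform and median-center normalized signals per probe.

    ``values`` is a probe x array matrix of positive linear signals; columns
    are array ids of the form ``<time>hpf_<replicate>`` or an equivalent
    (timepoint, replicate) MultiIndex.  The design reference timepoint
    defaults to the earliest (3 hpf in the embryo series).
    """
    if (values.to_numpy() <= 0).any():
        raise DesignError("non-positive signal encountered; floor the data first")
    cols = _parse_columns(values.columns)
    data = pd.DataFrame(np.log2(values.to_numpy()), index=values.index, columns=cols)
    tps = sorted(cols.get_level_values(0).unique())
    reps = sorted(cols.get_level_values(1).unique())
    expected = {(t, r) for t in tps for r in reps}
    if set(map(tuple, cols)) != expected:
        raise DesignError("incomplete design: every timepoint x replicate cell is required")
    data = data.sub(data.median(axis=1), axis=0)
    ref = reference_timepoint if reference_timepoint is not None else tps[0]
    if ref not in tps:
        raise DesignError(f"reference timepoint {ref} not in design")
    return TimeCourseMatrix(data=data, reference_timepoint=ref)


def _difference_vectors(tc: TimeCourseMatrix) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean differences vs reference and residual variances.

    Returns ``(d, s2, n)`` where ``d`` has shape (probes, T-1), ``s2`` the
    per-probe pooled within-timepoint variance, ``n`` replicates/timepoint.
    """
    x = tc.values_by_timepoint()
    tps = tc.timepoints
    n = x.shape[2]
    if n < 2:
        raise DesignError("need >= 2 replicates per timepoint")
    if len(tps) < 2:
        raise DesignError("need >= 2 timepoints")
    means = x.mean(axis=2)
    ref_idx = tps.index(tc.reference_timepoint)
    other = [i for i in range(len(tps)) if i != ref_idx]
    d = means[:, other] - means[:, [ref_idx]]
    resid = x - means[:, :, None]
    s2 = (resid**2).sum(axis=(1, 2)) / (len(tps) * (n - 1))
    return d, s2, n


def betr_probability(
    tc: TimeCourseMatrix,
    shrinkage: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 200,
    initial_weight: float = 0.1,
) -> pd.Series:
    """Posterior probability of temporal differential expression per probe.

    Probes with zero residual variance are degenerate (identical across all
    arrays) and get a missing (NaN) probability.

    Parameters
    ----------
    shrinkage
        Weight pulling each probe's residual variance toward the pooled
        average (moderates unstable per-probe variances).
    tol, max_iter
        EM convergence tolerance on the mixture weight, and iteration cap.
    initial_weight
        Starting mixture weight for the DE component.
    """
    d, s2, n = _difference_vectors(tc)
    k = d.shape[1]
    probes = tc.data.index
    posterior = np.full(len(probes), np.nan)
    ok = s2 > 0
    if not ok.any():
        return pd.Series(posterior, index=probes, name="posterior")

    d_ok = d[ok]
    s2_shrunk = (1 - shrinkage) * s2[ok] + shrinkage * s2[ok].mean()
    c_mat = (np.eye(k) + np.ones((k, k))) / n
    sigma0 = s2_shrunk[:, None, None] * c_mat[None, :, :]

    def mvn_loglik(cov: np.ndarray) -> np.ndarray:
        sign, logdet = np.linalg.slogdet(cov)
        sol = np.linalg.solve(cov, d_ok[:, :, None])[:, :, 0]
        maha = np.einsum("ij,ij->i", d_ok, sol)
        return -0.5 * (k * np.log(2 * np.pi) + logdet + maha)

    # initial signal covariance: moment estimate over all probes, PSD-projected
    emp = np.einsum("ij,ik->jk", d_ok, d_ok) / len(d_ok)
    sigma1 = _psd_project(emp - sigma0.mean(axis=0))

    p = float(initial_weight)
    loglik0 = mvn_loglik(sigma0)
    w = np.full(len(d_ok), p)
    for _ in range(max_iter):
        loglik1 = mvn_loglik(sigma0 + sigma1[None, :, :])
        log_num = np.log(p) + loglik1
        log_den = np.logaddexp(np.log1p(-p) + loglik0, log_num)
        w = np.exp(log_num - log_den)
        p_new = float(np.clip(w.mean(), 1e-6, 1 - 1e-6))
        wsum = w.sum()
        if wsum > 1e-12:
            outer = np.einsum("i,ij,ik->jk", w, d_ok, d_ok) / wsum
            sigma1 = _psd_project(outer - np.einsum("i,ijk->jk", w, sigma0) / wsum)
        if abs(p_new - p) < tol:
            p = p_new
            loglik1 = mvn_loglik(sigma0 + sigma1[None, :, :])
            log_num = np.log(p) + loglik1
            log_den = np.logaddexp(np.log1p(-p) + loglik0, log_num)
            w = np.exp(log_num - log_den)
            break
        p = p_new
    posterior[ok] = w
    return pd.Series(posterior, index=probes, name="posterior")


def _psd_project(mat: np.ndarray) -> np.ndarray:
    """Nearest positive-semidefinite matrix by eigenvalue clipping."""
    sym = (mat + mat.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def anova_pvalue(tc: TimeCourseMatrix) -> pd.Series:
    """Naive per-probe one-way fixed-effects ANOVA across timepoints.

    Probes with zero between- and zero within-timepoint variance get a
    missing p-value.
    """
    x = tc.values_by_timepoint()
    g, t, n = x.shape
    if t < 2:
        raise DesignError("ANOVA requires >= 2 timepoints")
    if n < 2:
        raise DesignError("ANOVA requires >= 2 replicates per timepoint")
    grand = x.mean(axis=(1, 2))
    group_means = x.mean(axis=2)
    ssb = n * ((group_means - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((x - group_means[:, :, None]) ** 2).sum(axis=(1, 2))
    df_b, df_w = t - 1, t * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = stats.f.sf(f, df_b, df_w)
    degenerate = (ssw == 0) & (ssb == 0)
    perfect = (ssw == 0) & (ssb > 0)  # infinite F: exact separation
    p[degenerate] = np.nan
    p[perfect] = 0.0
    return pd.Series(p, index=tc.data.index, name="anova_p")


def call_significant(
    posterior: pd.Series,
    anova_p: pd.Series | None = None,
    alpha: float = 0.01,
) -> DEResult:
    """Call probes significant where ``1 - posterior < alpha``.

    Mirrors reading a DE probability against a "p < alpha" criterion.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if anova_p is None:
        anova_p = pd.Series(np.nan, index=posterior.index)
    significant = (1 - posterior) < alpha
    significant[posterior.isna()] = False
    frame = pd.DataFrame(
        {"posterior": posterior, "anova_p": anova_p, "significant": significant}
    )
    return DEResult(frame=frame, alpha=alpha)


def summary_counts(result: DEResult) -> dict[str, float]:
    sig = result.significant
    return {
        "n_probes": int(len(sig)),
        "n_significant": int(sig.sum()),
        "fraction_significant": float(sig.mean()) if len(sig) else 0.0,
    }


def benjamini_hochberg(pvalues: pd.Series) -> pd.Series:
    """BH-adjusted q-values (optional multiple-testing correction)."""
    p = pvalues.to_numpy(dtype=float)
    mask = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    pm = p[mask]
    m = len(pm)
    order = np.argsort(pm)
    ranked = pm[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    q[mask] = out
    return pd.Series(q, index=pvalues.index, name="q_value")
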