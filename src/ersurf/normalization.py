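"""Variance stabilization and batch-effect removal.

Raw MS intensities carry multiplicative noise: the spread of replicate
differences grows with signal. The arsinh (generalized-log) transform
``h(x) = arsinh(a_s + b_s x)`` with per-sample calibration ``(a_s, b_s)``
behaves like log for large x but stays finite near zero, making replicate
variance approximately intensity-independent. Calibration is fitted by a
trimmed alternating least-squares scheme: alternate per-protein row means
of the transformed values with a per-sample affine fit against those
means, discarding the largest residuals so a minority of differentially
abundant proteins does not drag the calibration.

Batch effects are removed afterwards on the transformed (additive) scale
by per-protein linear models that include the biological design, so only
the batch term is subtracted and condition contrasts stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .qc import IntensityMatrix

LN2 = np.log(2.0)


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationModel:
    """Fitted calibration: per-sample (a_s, b_s), convergence info."""

    a: pd.Series
    b: pd.Series
    iterations: int
    converged: bool
    objective: float
    trim_fraction: float
    batch_coefficients: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "a": self.a.to_dict(),
            "b": self.b.to_dict(),
            "iterations": self.iterations,
            "converged": self.converged,
            "objective": self.objective,
            "trim_fraction": self.trim_fraction,
        }


#: Gaussian prior sd for the calibration offset a_s (in glog units). The
#: offset is informed only by the lowest-intensity points of a sample, so
#: its maximum-likelihood estimate is noisy; shrinking it toward 0 keeps
#: sample-to-sample offset scatter from leaking into low-intensity values.
A_PRIOR_SD = 0.2


def _calibration_nll(params: np.ndarray, x: np.ndarray, mu: np.ndarray) -> float:
    """Profile negative log-likelihood of one sample's calibration.

    For h(x) = arsinh(a + b x) with Gaussian residuals against the row
    means mu and the noise variance profiled out:

        nll = (n/2)·ln Σ r² − Σ ln h'(x),   h'(x) = b / sqrt(1 + (a+bx)²)

    The Jacobian term −Σ ln h' is essential: without it the alternating
    fit's global optimum is the degenerate transform that compresses all
    samples onto a constant (zero residuals, zero information).
    """
    a, theta = params
    b = np.exp(theta)
    u = a + b * x
    r = np.arcsinh(u) - mu
    sse = float(r @ r)
    n = x.size
    if not np.isfinite(sse) or sse <= 0:
        return np.inf, np.zeros(2)
    one_plus_u2 = 1.0 + u * u
    log_jac = n * theta - 0.5 * float(np.sum(np.log(one_plus_u2)))
    nll = 0.5 * n * np.log(sse) - log_jac + 0.5 * (a / A_PRIOR_SD) ** 2
    w = 1.0 / np.sqrt(one_plus_u2)
    rw = r * w
    grad_a = (
        (n / sse) * float(np.sum(rw))
        + float(np.sum(u / one_plus_u2))
        + a / A_PRIOR_SD**2
    )
    grad_theta = (
        (n / sse) * float(np.sum(rw * b * x))
        - n
        + float(np.sum(u * b * x / one_plus_u2))
    )
    return nll, np.array([grad_a, grad_theta])


def _calibration_fit(
    x: np.ndarray, mu: np.ndarray, a0: float, b0: float, trim: float
) -> tuple[float, float]:
    """Fit arsinh(a + b·x) ≈ mu for one sample by minimizing the profile
    likelihood in (a, log b); the ``trim`` fraction of points with the
    largest residuals under the incoming parameters is excluded first."""
    if trim > 0 and x.size >= 20:
        resid = np.abs(np.arcsinh(a0 + b0 * x) - mu)
        keep = resid <= np.quantile(resid, 1.0 - trim)
        if keep.sum() >= 10:
            x, mu = x[keep], mu[keep]
    res = optimize.minimize(
        _calibration_nll,
        x0=np.array([a0, np.log(b0)]),
        args=(x, mu),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-10},
    )
    a, theta = res.x
    return float(a), float(np.exp(theta))


def vsn_transform(
    matrix: IntensityMatrix,
    trim_fraction: float = 0.1,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[IntensityMatrix, NormalizationModel]:
    """Variance-stabilize an intensity matrix.

    Each value is transformed as ``h(x) = arsinh(a_s + b_s x) / ln 2`` so
    output differences read in log2-like units. Missing cells stay
    missing and are excluded from calibration. Every sample needs at
    least 10 present values to calibrate.

    Returns the transformed matrix and the fitted model.
    """
    if matrix.n_samples < 2:
        raise NormalizationError("need at least 2 samples")
    X = matrix.values.to_numpy(float)
    present = ~np.isnan(X)
    low = present.sum(axis=0) < 10
    if low.any():
        bad = list(matrix.values.columns[low])
        raise NormalizationError(f"samples with <10 present values: {bad}")

    n_samples = X.shape[1]
    # Start with b_s = C/median(x_s): quantified intensities sit in the
    # logarithmic regime of arsinh, with the glog "elbow" roughly two
    # orders of magnitude below the median, i.e. near the detection
    # limit. The arsinh family leaves the overall scale free (rescaling
    # every b_s shifts all transformed values equally in the log regime),
    # so the mean log b is pinned to its initial value at every
    # iteration; only the relative calibration is fitted.
    scale_anchor = 100.0
    b = np.array(
        [scale_anchor / np.nanmedian(X[:, s]) for s in range(n_samples)]
    )
    a = np.zeros(n_samples)
    log_scale = float(np.mean(np.log(b)))

    converged = False
    iterations = 0
    objective = np.nan
    for iterations in range(1, max_iter + 1):
        H = np.arcsinh(a + b * X)
        mu = np.nanmean(H, axis=1)
        a_new = np.empty_like(a)
        b_new = np.empty_like(b)
        sse = 0.0
        for s in range(n_samples):
            rows = present[:, s] & np.isfinite(mu)
            xs = X[rows, s]
            ms = mu[rows]
            a_s, b_s = _calibration_fit(xs, ms, a[s], b[s], trim_fraction)
            a_new[s], b_new[s] = a_s, b_s
            sse += float(np.sum((np.arcsinh(a_s + b_s * xs) - ms) ** 2))
        # pin the free overall scale
        gamma = float(np.exp(log_scale - np.mean(np.log(b_new))))
        a_new *= gamma
        b_new *= gamma
        objective = sse
        delta = max(
            np.max(np.abs(b_new - b) / b),
            np.max(np.abs(a_new - a) / (1.0 + np.abs(a))),
        )
        a, b = a_new, b_new
        if delta < tol:
            converged = True
            break

    H = np.arcsinh(a + b * X) / LN2
    out = IntensityMatrix(
        values=pd.DataFrame(H, index=matrix.values.index, columns=matrix.values.columns),
        samples=matrix.samples,
        unique_peptides=matrix.unique_peptides,
        log=dict(matrix.log, vsn_iterations=iterations),
        scale="log2",
    )
    model = NormalizationModel(
        a=pd.Series(a, index=matrix.values.columns),
        b=pd.Series(b, index=matrix.values.columns),
        iterations=iterations,
        converged=converged,
        objective=objective,
        trim_fraction=trim_fraction,
    )
    return out, model


def _design_dummies(samples: pd.DataFrame, covariates) -> pd.DataFrame:
    """Intercept + treatment-coded dummies for the given metadata columns."""
    parts = [pd.Series(1.0, index=samples.index, name="intercept")]
    for cov in covariates:
        levels = sorted(samples[cov].unique())
        for lev in levels[1:]:
            parts.append(
                (samples[cov] == lev).astype(float).rename(f"{cov}[{lev}]")
            )
    return pd.concat(parts, axis=1)


def remove_batch_effects(
    matrix: IntensityMatrix,
    covariates=("bait", "genotype"),
    batch_column: str = "batch",
    model: NormalizationModel | None = None,
) -> IntensityMatrix:
    """Subtract per-protein batch offsets on the transformed scale.

    Per protein, fits OLS with the biological design (intercept + dummies
    for each covariate) plus batch indicators, and subtracts only the
    fitted batch terms; missing cells stay missing. A single batch level
    is the identity. Batch labels perfectly confounded with a design
    covariate are rejected, naming the pair.
    """
    samples = matrix.samples
    batches = sorted(samples[batch_column].unique())
    if len(batches) < 2:
        return matrix

    design = _design_dummies(samples, covariates)
    batch_dummies = pd.concat(
        [
            (samples[batch_column] == lev).astype(float).rename(f"batch[{lev}]")
            for lev in batches[1:]
        ],
        axis=1,
    )
    full = pd.concat([design, batch_dummies], axis=1)
    if np.linalg.matrix_rank(full.to_numpy()) < full.shape[1]:
        # identify which batch level aligns with which covariate level
        for bcol in batch_dummies.columns:
            for dcol in design.columns[1:]:
                v1, v2 = batch_dummies[bcol].to_numpy(), design[dcol].to_numpy()
                if np.array_equal(v1, v2) or np.array_equal(v1, 1 - v2):
                    raise NormalizationError(
                        f"batch confounded with design covariate: {bcol} vs {dcol}"
                    )
        raise NormalizationError("design plus batch matrix is rank deficient")

    X = matrix.values.to_numpy(float).copy()
    F = full.to_numpy()
    n_design = design.shape[1]
    batch_part = F[:, n_design:]
    coefs = np.full((X.shape[0], batch_part.shape[1]), np.nan)
    skipped = 0
    for i in range(X.shape[0]):
        obs = ~np.isnan(X[i])
        Fi = F[obs]
        if Fi.shape[0] < F.shape[1] or np.linalg.matrix_rank(Fi) < F.shape[1]:
            skipped += 1
            continue
        beta, *_ = np.linalg.lstsq(Fi, X[i, obs], rcond=None)
        gamma = beta[n_design:]
        coefs[i] = gamma
        X[i, obs] -= batch_part[obs] @ gamma

    out = IntensityMatrix(
        values=pd.DataFrame(X, index=matrix.values.index, columns=matrix.values.columns),
        samples=matrix.samples,
        unique_peptides=matrix.unique_peptides,
        log=dict(matrix.log, batch_skipped_proteins=skipped),
        scale=matrix.scale,
    )
    coef_table = pd.DataFrame(
        coefs, index=matrix.values.index, columns=list(batch_dummies.columns)
    )
    if model is not None:
        model.batch_coefficients = coef_table
    out.log["batch_levels"] = batches
    return out


def variance_stabilization_diagnostic(matrix: IntensityMatrix) -> pd.DataFrame:
    """Within-replicate spread per intensity decile.

    Groups samples by condition (bait, genotype), pools deviations of each
    value from its protein's group mean, bins proteins into deciles of
    their row mean, and reports the pooled standard deviation per decile.
    Flat sd across deciles (max/min ratio near 1) is the signature of a
    variance-stabilized matrix.
    """
    X = matrix.values.to_numpy(float)
    samples = matrix.samples
    groups = {}
    for name in samples.index:
        key = (samples.at[name, "bait"], samples.at[name, "genotype"])
        groups.setdefault(key, []).append(matrix.values.columns.get_loc(name))
    if not any(len(cols) >= 2 for cols in groups.values()):
        raise NormalizationError("need at least one condition with >=2 replicates")

    row_mean = np.nanmean(X, axis=1)
    dev_sq = np.zeros(X.shape[0])
    dev_df = np.zeros(X.shape[0])
    for cols in groups.values():
        if len(cols) < 2:
            continue
        sub = X[:, cols]
        n_obs = np.sum(~np.isnan(sub), axis=1)
        gmean = np.nansum(sub, axis=1) / np.maximum(n_obs, 1)
        d = sub - gmean[:, None]
        ok = n_obs >= 2
        dev_sq[ok] += np.nansum(d[ok] ** 2, axis=1)
        dev_df[ok] += n_obs[ok] - 1

    usable = dev_df > 0
    order_vals = row_mean[usable]
    edges = np.quantile(order_vals, np.linspace(0, 1, 11))
    rows = []
    for d in range(10):
        lo, hi = edges[d], edges[d + 1]
        if d < 9:
            sel = usable & (row_mean >= lo) & (row_mean < hi)
        else:
            sel = usable & (row_mean >= lo) & (row_mean <= hi)
        ss, df = dev_sq[sel].sum(), dev_df[sel].sum()
        sd = float(np.sqrt(ss / df)) if df > 0 else np.nan
        rows.append(
            {"decile": d + 1, "mean_low": lo, "mean_high": hi,
             "n_proteins": int(sel.sum()), "replicate_sd": sd}
        )
    return pd.DataFrame(rows)
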