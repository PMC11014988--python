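"""Empirical-Bayes moderated differential abundance.

Per protein, an ordinary least-squares linear model is fitted on the
(log2-scale, normalized) intensities that are present, and a contrast of
its coefficients gives the log2 fold change. With only a few replicates
the per-protein residual variance s² is noisy, so variances are shrunk
toward a pooled prior: s² is modeled as s0²·F(df, d0), the prior
(d0, s0²) is estimated by matching the first two moments of log s² via
digamma/trigamma identities, and the posterior variance
s²_post = (d0·s0² + df·s²)/(d0 + df) replaces s² in the t statistic,
which then has d0 + df degrees of freedom. This is the standard
moderated-t construction used throughout quantitative proteomics and
transcriptomics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


class DifferentialError(ValueError):
    pass


@dataclass
class ModerationResult:
    d0: float
    s0_sq: float
    s2_post: np.ndarray


def fit_contrasts(
    matrix_values: pd.DataFrame,
    design: pd.DataFrame,
    contrast,
) -> pd.DataFrame:
    """Per-protein OLS fit and contrast estimate.

    Parameters
    ----------
    matrix_values : DataFrame
        Proteins × samples, log2-like scale, NaN = missing.
    design : DataFrame
        Samples × coefficients design matrix (rows aligned with the
        columns of ``matrix_values``).
    contrast : array-like
        Linear combination of design coefficients, length = n columns.

    Returns a table indexed by protein id with columns ``log2fc, s2,
    df_resid, unscaled_se, n_obs, reason`` — ``reason`` is empty for
    successful fits, otherwise explains the NA (rank-deficient design on
    the protein's missingness pattern, or no residual df).
    """
    if list(design.index) != list(matrix_values.columns):
        design = design.reindex(matrix_values.columns)
        if design.isna().any().any():
            raise DifferentialError("design rows do not match sample columns")
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != (design.shape[1],):
        raise DifferentialError(
            f"contrast length {contrast.size} != design columns {design.shape[1]}"
        )
    X = design.to_numpy(float)
    Y = matrix_values.to_numpy(float)
    k = X.shape[1]

    out = {
        "log2fc": np.full(Y.shape[0], np.nan),
        "s2": np.full(Y.shape[0], np.nan),
        "df_resid": np.zeros(Y.shape[0]),
        "unscaled_se": np.full(Y.shape[0], np.nan),
        "n_obs": np.zeros(Y.shape[0], dtype=int),
        "reason": np.array([""] * Y.shape[0], dtype=object),
    }

    # group proteins by missingness pattern so XtX inverses are reused
    obs_mask = ~np.isnan(Y)
    patterns: dict[bytes, list[int]] = {}
    for i in range(Y.shape[0]):
        patterns.setdefault(obs_mask[i].tobytes(), []).append(i)

    for key, rows in patterns.items():
        obs = np.frombuffer(key, dtype=bool)
        n = int(obs.sum())
        out_rows = np.array(rows)
        out["n_obs"][out_rows] = n
        Xi = X[obs]
        if n == 0 or np.linalg.matrix_rank(Xi) < k:
            out["reason"][out_rows] = "rank_deficient"
            continue
        df = n - k
        xtx_inv = np.linalg.pinv(Xi.T @ Xi)
        hat = xtx_inv @ Xi.T
        unscaled_se = float(np.sqrt(contrast @ xtx_inv @ contrast))
        Yi = Y[np.ix_(out_rows, np.where(obs)[0])]
        beta = hat @ Yi.T  # k × nrows
        fc = contrast @ beta
        resid = Yi.T - Xi @ beta
        rss = np.sum(resid**2, axis=0)
        out["log2fc"][out_rows] = fc
        out["unscaled_se"][out_rows] = unscaled_se
        out["df_resid"][out_rows] = df
        if df >= 1:
            out["s2"][out_rows] = rss / df
        else:
            out["reason"][out_rows] = "no_residual_df"
    return pd.DataFrame(out, index=matrix_values.index)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise DifferentialError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def moderate_variances(s2, df) -> ModerationResult:
    """Estimate the variance prior (d0, s0²) and shrink variances.

    Uses the moment-matching estimator on z = log s²: with s² ~ s0²·F(df,
    d0), E[z] and Var[z] are analytic in digamma/trigamma, so the prior
    follows from the sample mean and variance of z (trigamma inverted by
    Newton iteration). Zero or non-finite s² are excluded from
    estimation; their posterior variance still shrinks toward the prior.
    d0 may be infinite when the observed spread of z is no larger than
    expected from chi-square sampling alone, in which case s²_post = s0²
    for every protein.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 10:
        raise DifferentialError("need at least 10 positive finite s2 values")
    if np.all(s2[np.isfinite(s2)] == 0):
        raise DifferentialError("all s2 are zero: no variance information")

    z = np.log(s2[ok])
    dfo = df[ok]
    e = z - special.digamma(dfo / 2.0) + np.log(dfo / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    evar_resid = evar - float(np.mean(special.polygamma(1, dfo / 2.0)))
    if evar_resid > 0:
        d0 = 2.0 * _trigamma_inverse(evar_resid)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))

    s2_post = posterior_variances(s2, df, d0, s0_sq)
    return ModerationResult(d0=d0, s0_sq=s0_sq, s2_post=s2_post)


def posterior_variances(s2, df, d0: float, s0_sq: float) -> np.ndarray:
    """s²_post = (d0·s0² + df·s²)/(d0 + df), with the d0 → ∞ and d0 = 0
    limits handled explicitly."""
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    if d0 == 0:
        return s2.copy()
    s2_filled = np.where(np.isfinite(s2), s2, 0.0)
    return (d0 * s0_sq + df * s2_filled) / (d0 + df)


def moderated_t(
    log2fc, s2_post, unscaled_se, df_resid, d0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistic and two-sided p-value.

    t = log2fc / (sqrt(s²_post) · unscaled_se), on d0 + df_resid degrees
    of freedom (normal in the d0 → ∞ limit). s²_post = 0 yields infinite
    t, reported as p = 0 with a warning.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s2_post = np.asarray(s2_post, dtype=float)
    unscaled_se = np.broadcast_to(np.asarray(unscaled_se, dtype=float), log2fc.shape)
    df_resid = np.broadcast_to(np.asarray(df_resid, dtype=float), log2fc.shape)

    se = np.sqrt(s2_post) * unscaled_se
    zero_se = se == 0
    if np.any(zero_se & np.isfinite(log2fc)):
        warnings.warn("zero posterior variance: reporting p = 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    total_df = df_resid + (0.0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, p


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order kept).

    NaN entries (untested proteins) are ignored for the adjustment and
    stay NaN.
    """
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise DifferentialError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[finite]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[finite] = qv
    return q


def differential_table(
    matrix_values: pd.DataFrame, design: pd.DataFrame, contrast
) -> tuple[pd.DataFrame, float, float]:
    """End-to-end per-contrast analysis: OLS, moderation, BH adjustment.

    Returns ``(table, d0, s0_sq)``; the table has columns ``log2fc, s2,
    df_resid, s2_post, t, p, q, n_obs, reason``.
    """
    fits = fit_contrasts(matrix_values, design, contrast)
    tested = fits["reason"] == ""
    mod = moderate_variances(
        fits.loc[tested, "s2"].to_numpy(), fits.loc[tested, "df_resid"].to_numpy()
    )
    s2_post = np.full(len(fits), np.nan)
    s2_post[tested.to_numpy()] = mod.s2_post
    t = np.full(len(fits), np.nan)
    p = np.full(len(fits), np.nan)
    t_sub, p_sub = moderated_t(
        fits.loc[tested, "log2fc"].to_numpy(),
        mod.s2_post,
        fits.loc[tested, "unscaled_se"].to_numpy(),
        fits.loc[tested, "df_resid"].to_numpy(),
        mod.d0,
    )
    t[tested.to_numpy()] = t_sub
    p[tested.to_numpy()] = p_sub
    table = fits.assign(s2_post=s2_post, t=t, p=p, q=adjust_bh(p))
    return table, mod.d0, mod.s0_sq
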