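"""Negative-binomial Wald differential expression with covariates.

This engine is a documented stand-in for a full DESeq2-style analysis,
not a re-implementation of it: dispersions are method-of-moments without
shrinkage, there is no independent filtering and no outlier handling.
The downstream threshold cascades are engine-agnostic and accept
externally computed DE tables with the same columns.

Model per gene: counts ~ NB(mu, alpha) with log link,
log mu = X beta + log(size factor).  The Wald statistic on the contrast
coefficient is referred to a t distribution with (samples - parameters)
degrees of freedom — a small-sample reference that keeps the test close
to nominal at the replicate numbers typical of sorted-population designs.
Continuous covariates (age in years, post-mortem delay in hours) enter in
raw units.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix
from .normalize import size_factors as _size_factors

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 10.0

DE_COLUMNS = ("base_mean", "log2fc", "se", "stat", "pvalue", "padj")


def bh_adjust(p_values) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjustment.

    NA entries propagate as NA and are excluded from the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    if ok.sum():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(adj, index=p_values.index, name="padj")
    return adj


def design_matrix(metadata: pd.DataFrame, variable: str,
                  blocking: Sequence[str] = (), reference: str | None = None
                  ) -> tuple[np.ndarray, list[str], dict]:
    """Intercept + blocking covariates + the tested variable (last column).

    A categorical tested variable must have exactly two levels; the
    coefficient then measures the non-reference level relative to the
    reference.  A numeric variable contributes its raw values (slope test).
    """
    cols = [np.ones(len(metadata))]
    names = ["intercept"]
    for b in blocking:
        vals = metadata[b]
        if pd.api.types.is_numeric_dtype(vals):
            cols.append(vals.to_numpy(dtype=float))
            names.append(b)
        else:
            levels = sorted(pd.unique(vals.astype(str)))
            for lev in levels[1:]:
                cols.append((vals.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{b}[{lev}]")
    vals = metadata[variable]
    info: dict = {"variable": variable}
    if pd.api.types.is_numeric_dtype(vals):
        v = vals.to_numpy(dtype=float)
        if np.ptp(v) == 0:
            raise ValueError(f"covariate {variable!r} is constant")
        cols.append(v)
        names.append(variable)
        info["kind"] = "continuous"
    else:
        levels = sorted(pd.unique(vals.astype(str)))
        if len(levels) != 2:
            raise ValueError(
                f"factor {variable!r} must have exactly 2 levels, got {levels}")
        ref = reference if reference is not None else levels[0]
        if ref not in levels:
            raise ValueError(f"reference {ref!r} not a level of {variable!r}")
        other = [lev for lev in levels if lev != ref][0]
        cols.append((vals.astype(str) == other).to_numpy(dtype=float))
        names.append(f"{variable}[{other} vs {ref}]")
        info.update(kind="factor", numerator=other, denominator=ref)
        counts = vals.astype(str).value_counts()
        if (counts < 2).any():
            raise ValueError(
                f"factor {variable!r}: every level needs >= 2 samples")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"confounded design: {variable!r} is collinear with the "
            f"blocking covariates {tuple(blocking)}")
    return X, names, info


def _moment_dispersions(norm: np.ndarray, groups: np.ndarray,
                        inv_sf_mean: float) -> np.ndarray:
    """Method-of-moments dispersion from within-group variance of
    size-factor-normalized counts: Var(q) ~ mu * mean(1/s) + alpha mu^2."""
    G = norm.shape[0]
    mu = norm.mean(axis=1)
    ss = np.zeros(G)
    dof = 0
    for g in np.unique(groups):
        sub = norm[:, groups == g]
        if sub.shape[1] >= 2:
            ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
            dof += sub.shape[1] - 1
    if dof == 0:
        return np.full(G, DISPERSION_FLOOR)
    var_w = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_w - mu * inv_sf_mean) / mu**2
    alpha[~np.isfinite(alpha)] = DISPERSION_FLOOR
    return np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEIL)


def _irls(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
          alpha: np.ndarray, max_iter: int = 50, tol: float = 1e-8
          ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NB log-link IRLS over all genes at once.

    y: genes x samples; X: samples x p; offset: per-sample log size factor;
    alpha: per-gene dispersion.  Returns (beta genes x p, covariance
    genes x p x p from the final weighted information matrix).
    """
    G, S = y.shape
    p = X.shape[1]
    pinv = np.linalg.pinv(X)
    eta0 = np.log((y + 0.5)) - offset[None, :]
    beta = (pinv @ eta0.T).T  # G x p
    a = alpha[:, None]
    for _ in range(max_iter):
        eta = beta @ X.T + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + a * mu)  # G x S working weights
        z = (eta - offset[None, :]) + (y - mu) / mu
        A = np.einsum("gs,sp,sq->gpq", W, X, X, optimize=True)
        b = np.einsum("gs,gs,sp->gp", W, z, X, optimize=True)
        A[:, np.arange(p), np.arange(p)] += 1e-10  # guard singular fits
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.abs(new_beta - beta).max()
        beta = new_beta
        if delta < tol:
            break
    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + a * mu)
    A = np.einsum("gs,sp,sq->gpq", W, X, X, optimize=True)
    A[:, np.arange(p), np.arange(p)] += 1e-10
    cov = np.linalg.inv(A)
    return beta, cov


def nb_wald_test(counts, metadata: pd.DataFrame, variable: str, *,
                 blocking: Sequence[str] = (), reference: str | None = None,
                 size_factors: pd.Series | None = None,
                 dispersions: np.ndarray | None = None) -> pd.DataFrame:
    """Per-gene NB regression Wald test on ``variable``.

    Returns a DE table indexed by gene with columns base_mean, log2fc
    (log2 units; for a factor, numerator over reference level), se, stat,
    pvalue, padj.  Genes with all-zero counts get NA p-values and are
    excluded from the BH correction.
    """
    df = counts.to_frame() if isinstance(counts, CountMatrix) else counts
    meta = metadata.set_index("sample_id").loc[list(df.columns)].reset_index() \
        if "sample_id" in metadata.columns and not metadata.index.equals(df.columns) \
        else metadata
    X, names, info = design_matrix(meta, variable, blocking, reference)
    y = df.to_numpy(dtype=float)
    sf = (_size_factors(df) if size_factors is None
          else size_factors.reindex(df.columns)).to_numpy(dtype=float)
    norm = y / sf[None, :]
    nonzero = y.sum(axis=1) > 0
    if dispersions is None:
        cat_cols = [c for c in (variable, *blocking)
                    if not pd.api.types.is_numeric_dtype(meta[c])]
        if cat_cols:
            groups = meta[cat_cols].astype(str).agg("|".join, axis=1).to_numpy()
        else:
            groups = np.zeros(len(meta), dtype=int)
        alpha = _moment_dispersions(norm, groups, float(np.mean(1.0 / sf)))
    else:
        alpha = np.clip(np.asarray(dispersions, dtype=float),
                        DISPERSION_FLOOR, DISPERSION_CEIL)

    G = y.shape[0]
    ci = X.shape[1] - 1  # tested coefficient is last
    log2fc = np.full(G, np.nan)
    se = np.full(G, np.nan)
    stat = np.full(G, np.nan)
    pval = np.full(G, np.nan)
    if nonzero.any():
        beta, cov = _irls(y[nonzero], X, np.log(sf), alpha[nonzero])
        b = beta[:, ci]
        s = np.sqrt(np.maximum(cov[:, ci, ci], 0.0))
        t = np.divide(b, s, out=np.zeros_like(b), where=s > 0)
        df_resid = max(y.shape[1] - X.shape[1], 1)
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df=df_resid)
        log2fc[nonzero] = b / LN2
        se[nonzero] = s / LN2
        stat[nonzero] = t
        pval[nonzero] = p
    out = pd.DataFrame({
        "base_mean": norm.mean(axis=1),
        "log2fc": log2fc,
        "se": se,
        "stat": stat,
        "pvalue": pval,
    }, index=df.index.copy())
    out["padj"] = bh_adjust(out["pvalue"])
    out.attrs["design"] = {"variable": variable, "blocking": tuple(blocking),
                           "coefficients": names, **info}
    return out
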