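"""QC and normalization chain for aptamer proteomics matrices.

The canonical order is: per-sample QC on scale factors, log2 transform,
per-protein Z standardization, covariate residualization (one ordinary
least-squares fit per protein, keeping the residuals), and — for the bulk
differential-regulation route — empirical-Bayes batch adjustment (ComBat)
plus a principal-component vs confounder scan.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ProteinMatrix, SampleMetadata, align

#: sample acceptance window for QC scale factors (closed interval)
QC_RANGE = (0.4, 2.5)


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# QC

def qc_filter_samples(
    matrix: ProteinMatrix,
    scale_factors: Mapping[str, float] | pd.Series,
    lo: float = QC_RANGE[0],
    hi: float = QC_RANGE[1],
) -> tuple[ProteinMatrix, pd.DataFrame]:
    """Drop samples whose QC scale factor falls outside ``[lo, hi]``.

    Returns the filtered matrix and a report of removed samples with the
    offending factor.  Bounds are inclusive.
    """
    factors = pd.Series(scale_factors, dtype=float)
    missing = [s for s in matrix.sample_ids if s not in factors.index]
    if missing:
        raise PreprocessError(f"no scale factor for samples: {missing}")
    factors = factors.loc[matrix.sample_ids]
    bad = (factors < lo) | (factors > hi)
    report = pd.DataFrame({
        "sample_id": factors.index[bad],
        "scale_factor": factors[bad].to_numpy(),
        "reason": [
            f"scale factor outside [{lo}, {hi}]" for _ in range(int(bad.sum()))
        ],
    })
    kept = matrix.subset_samples(factors.index[~bad])
    return kept, report.reset_index(drop=True)


# ---------------------------------------------------------------------------
# transforms

def log2_transform(matrix: ProteinMatrix) -> ProteinMatrix:
    matrix.require_state("raw")
    return ProteinMatrix(np.log2(matrix.values), transform_state="log2")


def standardize(matrix: ProteinMatrix, on_zero_variance: str = "error") -> ProteinMatrix:
    """Per-protein Z-score with the sample (n-1) standard deviation."""
    matrix.require_state("log2", "residualized", "standardized")
    vals = matrix.values
    sd = vals.std(axis=0, ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        if on_zero_variance == "drop":
            vals = vals.drop(columns=zero)
            sd = sd.drop(index=zero)
        else:
            raise PreprocessError(f"zero-variance protein(s): {zero}")
    z = (vals - vals.mean(axis=0)) / sd
    return ProteinMatrix(z, transform_state="standardized")


def log2_and_standardize(matrix: ProteinMatrix,
                         on_zero_variance: str = "error") -> ProteinMatrix:
    """log2-transform raw RFU then Z-standardize each protein."""
    return standardize(log2_transform(matrix), on_zero_variance=on_zero_variance)


# ---------------------------------------------------------------------------
# covariate residualization

def _encode_covariates(meta: pd.DataFrame, covariates: Iterable[str],
                       on_constant: str = "error") -> pd.DataFrame:
    """Build a design frame: numerics pass through, dates become days since
    the earliest date, categoricals are dummy-coded against the first level
    in alphabetical order.  Constant covariates raise (default) or are
    silently dropped (``on_constant="drop"``)."""
    cols = {}
    for cov in covariates:
        if cov not in meta.columns:
            raise PreprocessError(f"covariate {cov!r} not in metadata")
        s = meta[cov]
        if pd.api.types.is_numeric_dtype(s):
            cols[cov] = s.astype(float)
        else:
            parsed = pd.to_datetime(s, errors="coerce", format="mixed")
            if parsed.notna().all():
                cols[cov] = (parsed - parsed.min()).dt.days.astype(float)
            else:
                levels = sorted(s.dropna().astype(str).unique())
                if len(levels) < 2:
                    if on_constant == "drop":
                        continue
                    raise PreprocessError(
                        f"covariate {cov!r} is constant across samples"
                    )
                for lev in levels[1:]:
                    cols[f"{cov}[{lev}]"] = (s.astype(str) == lev).astype(float)
                # preserve missingness
                cols[f"{cov}[{levels[1]}]"] = cols[f"{cov}[{levels[1]}]"].where(
                    s.notna()
                )
    design = pd.DataFrame(cols, index=meta.index)
    const = [c for c in design.columns if design[c].nunique(dropna=True) <= 1]
    if const:
        if on_constant == "drop":
            design = design.drop(columns=const)
        else:
            raise PreprocessError(f"constant covariate column(s): {const}")
    return design


def residualize_covariates(
    matrix: ProteinMatrix,
    metadata: SampleMetadata,
    covariates: Iterable[str],
) -> tuple[ProteinMatrix, pd.DataFrame]:
    """Replace each protein by its OLS residuals on the covariates.

    One linear model per protein (Gaussian link), intercept included;
    samples with missing covariate values are dropped and reported.
    """
    matrix.require_state("log2", "standardized")
    matrix, metadata, _ = align(matrix, metadata)
    design = _encode_covariates(metadata.table, list(covariates))
    complete = design.notna().all(axis=1)
    dropped = design.index[~complete].tolist()
    design = design.loc[complete]
    Y = matrix.values.loc[design.index].to_numpy()
    X = np.column_stack([np.ones(len(design)), design.to_numpy()])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    out = pd.DataFrame(resid, index=design.index, columns=matrix.protein_ids)
    report = pd.DataFrame({
        "sample_id": dropped,
        "reason": ["missing covariate value"] * len(dropped),
    })
    return ProteinMatrix(out, transform_state="residualized"), report


# ---------------------------------------------------------------------------
# ComBat batch adjustment

def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _it_sol(z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            conv: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the parametric empirical-Bayes posterior means for one batch."""
    n = (~np.isnan(z)).sum(axis=0)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = np.nansum((z - g_new) ** 2, axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            (np.abs(g_new - g_old) / np.abs(g_old)).max(),
            (np.abs(d_new - d_old) / np.abs(d_old)).max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_adjust(
    matrix: ProteinMatrix,
    metadata: SampleMetadata,
    batch: str = "batch",
    protect: Iterable[str] = (),
    shrink: bool = True,
) -> ProteinMatrix:
    """Empirical-Bayes location/scale batch adjustment (ComBat).

    Per protein: fit batch means alongside protected covariates, standardize,
    estimate per-batch additive and multiplicative effects, shrink them
    toward their across-protein means via parametric normal / inverse-gamma
    priors (``shrink=False`` uses the unshrunk per-batch estimates, the
    closed-form location/scale adjustment), then remove them.  Protected
    effects (e.g. disease status) are preserved in expectation.
    """
    matrix.require_state("log2", "standardized")
    matrix, metadata, _ = align(matrix, metadata)
    batches = metadata[batch].astype(str)
    levels = sorted(batches.unique())
    if len(levels) < 2:
        # nothing to remove
        return matrix.copy()
    counts = batches.value_counts()
    singles = counts[counts < 2].index.tolist()
    if singles:
        raise PreprocessError(f"batch(es) with a single sample: {singles}")

    n, p = matrix.values.shape
    Y = matrix.values.to_numpy()
    B = np.column_stack([(batches == lev).to_numpy(float) for lev in levels])
    if protect:
        mod = _encode_covariates(metadata.table, list(protect)).to_numpy()
    else:
        mod = np.empty((n, 0))
    X = np.column_stack([B, mod])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PreprocessError(
            "batch is confounded with a protected covariate (singular design)"
        )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    n_per = B.sum(axis=0)
    grand = (n_per / n) @ beta[: len(levels)]
    stand_mean = np.tile(grand, (n, 1))
    if protect:
        stand_mean = stand_mean + mod @ beta[len(levels):]
    var_pooled = ((Y - X @ beta) ** 2).sum(axis=0) / n
    if (var_pooled == 0).any():
        raise PreprocessError("zero pooled variance for some protein(s)")
    Z = (Y - stand_mean) / np.sqrt(var_pooled)

    gamma_hat = np.vstack([Z[B[:, i] == 1].mean(axis=0) for i in range(len(levels))])
    delta_hat = np.vstack([
        Z[B[:, i] == 1].var(axis=0, ddof=1) for i in range(len(levels))
    ])
    if shrink:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i in range(len(levels)):
            g_bar = gamma_hat[i].mean()
            t2 = gamma_hat[i].var(ddof=1)
            a, b = _aprior(delta_hat[i]), _bprior(delta_hat[i])
            zi = np.where(B[:, i][:, None] == 1, Z, np.nan)
            gamma_star[i], delta_star[i] = _it_sol(
                zi, gamma_hat[i], delta_hat[i], g_bar, t2, a, b
            )
    else:
        gamma_star, delta_star = gamma_hat, delta_hat

    adj = Z.copy()
    for i in range(len(levels)):
        rows = B[:, i] == 1
        adj[rows] = (Z[rows] - gamma_star[i]) / np.sqrt(delta_star[i])
    adj = adj * np.sqrt(var_pooled) + stand_mean
    out = pd.DataFrame(adj, index=matrix.sample_ids, columns=matrix.protein_ids)
    return ProteinMatrix(out, matrix.transform_state)


# ---------------------------------------------------------------------------
# PC / confounder scan

def pc_confounder_scan(
    matrix: ProteinMatrix,
    metadata: SampleMetadata,
    k: int = 5,
    confounders: Iterable[str] | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Test the top-k principal components against candidate confounders.

    PCs come from the SVD of the column-centered matrix.  Categorical
    confounders are tested with a one-way ANOVA F-test, numeric ones with a
    Pearson correlation t-test.  ``flagged`` marks pairs whose
    Benjamini-Hochberg-adjusted p-value falls below ``alpha``.
    """
    matrix, metadata, _ = align(matrix, metadata)
    if k > min(matrix.n_samples, matrix.n_proteins):
        raise PreprocessError("k exceeds matrix rank bound")
    cols = ["pc", "confounder", "kind", "statistic", "p", "p_adj", "flagged"]
    if k == 0:
        return pd.DataFrame(columns=cols)
    if confounders is None:
        confounders = [
            c for c in metadata.table.columns
            if c not in ("latent_severity",)
        ]
    X = matrix.values.to_numpy()
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * s[:k]

    rows = []
    for j in range(k):
        pc = scores[:, j]
        for cov in confounders:
            series = metadata.table[cov]
            ok = series.notna().to_numpy()
            if ok.sum() < 3 or series[ok].nunique() < 2:
                continue
            if pd.api.types.is_numeric_dtype(series):
                r, p = stats.pearsonr(pc[ok], series[ok].astype(float))
                rows.append((f"PC{j+1}", cov, "numeric", r, p))
            else:
                groups = [
                    pc[ok][series[ok].astype(str).to_numpy() == lev]
                    for lev in sorted(series[ok].astype(str).unique())
                ]
                groups = [g for g in groups if len(g) >= 2]
                if len(groups) < 2:
                    continue
                f, p = stats.f_oneway(*groups)
                rows.append((f"PC{j+1}", cov, "categorical", f, p))
    report = pd.DataFrame(rows, columns=cols[:5])
    if len(report):
        from .diffexpr import bh_adjust

        report["p_adj"] = bh_adjust(report["p"].to_numpy())
        report["flagged"] = report["p_adj"] < alpha
    else:
        report["p_adj"] = []
        report["flagged"] = []
    return report
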