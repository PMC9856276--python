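"""Per-protein differential-regulation scans.

One regression per protein against a clinical outcome: a binomial-link
model with disease status as the outcome and the protein (plus covariates,
by default age, sex and cohort) as predictors, or a Gaussian-link model
for continuous outcomes (MoCA, MDS-UPDRS III, severity score).  P-values
are Wald tests; multiplicity is controlled with Benjamini-Hochberg over
the proteins whose fits converged.  A targeted mode runs univariate fits
with no covariates and no adjustment, for testing pre-specified candidate
biomarker panels.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datamodel import ProteinMatrix, SampleMetadata, align

DEFAULT_COVARIATES = ("age", "sex", "cohort")
CONTINUOUS_OUTCOMES = ("moca", "updrs3", "severity", "ledd")


class DiffExprError(ValueError):
    pass


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise DiffExprError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _outcome_vector(metadata: SampleMetadata, outcome: str) -> pd.Series:
    if outcome == "status":
        return metadata.status_binary().astype(float)
    if outcome not in metadata.table.columns:
        raise DiffExprError(f"outcome {outcome!r} not in metadata")
    return metadata.table[outcome].astype(float)


def _gaussian_scan(Y: np.ndarray, y: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized per-protein OLS of outcome on protein + covariates.

    Uses Frisch-Waugh-Lovell: residualize outcome and every protein on the
    covariate block once, then each protein's slope / SE / Wald t follow
    from a simple regression with the full model's residual degrees of
    freedom.  Identical to per-protein full OLS fits.
    """
    n, k = C.shape
    Q, _ = np.linalg.qr(C)
    ry = y - Q @ (Q.T @ y)
    RX = Y - Q @ (Q.T @ Y)
    sxx = (RX ** 2).sum(axis=0)
    beta = (RX * ry[:, None]).sum(axis=0) / sxx
    dof = n - k - 1
    rss = (ry ** 2).sum() - beta ** 2 * sxx
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / sxx)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, p


def _logistic_scan_one(x: np.ndarray, y: np.ndarray, C: np.ndarray
                       ) -> tuple[float, float, float, bool]:
    X = np.column_stack([C, x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception:
            return np.nan, np.nan, np.nan, False
    beta, se = fit.params[-1], fit.bse[-1]
    if not (np.isfinite(beta) and np.isfinite(se)) or se > 1e3:
        return np.nan, np.nan, np.nan, False
    p = 2 * stats.norm.sf(abs(beta / se))
    return float(beta), float(se), float(max(p, 1e-300)), True


def protein_glm_scan(
    matrix: ProteinMatrix,
    metadata: SampleMetadata,
    outcome: str = "status",
    covariates: Iterable[str] | None = DEFAULT_COVARIATES,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-protein regression scan with covariate adjustment.

    Returns one row per protein: ``beta``, ``se``, ``p``, ``p_adj``
    (Benjamini-Hochberg over converged fits), ``direction`` (sign of
    beta) and ``converged``.  Samples missing the outcome or a covariate
    are dropped for this scan only.
    """
    matrix, metadata, _ = align(matrix, metadata)
    matrix.require_state("log2", "standardized", "residualized")
    y = _outcome_vector(metadata, outcome)

    from .preprocess import _encode_covariates

    covariates = [c for c in (covariates or []) if c != outcome]
    if covariates:
        # a covariate constant in this dataset (e.g. cohort in a
        # single-cohort scan) carries no information and is dropped
        design = _encode_covariates(metadata.table, covariates,
                                    on_constant="drop")
    else:
        design = pd.DataFrame(index=metadata.table.index)
    ok = y.notna() & design.notna().all(axis=1)
    if ok.sum() < len(design.columns) + 3:
        raise DiffExprError("too few complete samples for the scan")
    y_v = y[ok].to_numpy()
    C = np.column_stack([np.ones(int(ok.sum()))] + (
        [design.loc[ok].to_numpy()] if covariates else []
    ))
    Y = matrix.values.loc[ok.index[ok]].to_numpy()

    proteins = matrix.protein_ids
    if outcome == "status":
        if len(np.unique(y_v)) < 2:
            raise DiffExprError("both classes must be present")
        rows = [_logistic_scan_one(Y[:, j], y_v, C) for j in range(len(proteins))]
        beta, se, p, conv = map(np.array, zip(*rows))
        conv = conv.astype(bool)
    else:
        beta, se, p = _gaussian_scan(Y, y_v, C)
        p = np.maximum(p, 1e-300)
        conv = np.isfinite(p)
    result = pd.DataFrame({
        "protein_id": proteins,
        "outcome": outcome,
        "beta": beta,
        "se": se,
        "p": p,
        "converged": conv,
    })
    if adjust:
        padj = np.full(len(result), np.nan)
        padj[conv] = bh_adjust(p[conv])
        result["p_adj"] = padj
    result["direction"] = np.sign(result["beta"])
    return result


def targeted_panel_scan(
    matrix: ProteinMatrix,
    metadata: SampleMetadata,
    panel: Iterable[str],
    outcomes: Sequence[str] = ("status", "moca", "updrs3"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate candidate-biomarker scan: no covariates, no adjustment.

    One row per (panel protein, outcome).  Proteins absent from the matrix
    appear with ``tested = False``.  P-values are reported as independent
    results.
    """
    panel = [str(p) for p in panel]
    if not panel:
        raise DiffExprError("empty panel")
    present = [p for p in panel if p in set(matrix.protein_ids)]
    frames = []
    for outcome in outcomes:
        if present:
            sub = matrix.subset_proteins(present)
            res = protein_glm_scan(
                sub, metadata, outcome, covariates=None, adjust=False
            )
            res["tested"] = res["converged"]
        else:
            res = pd.DataFrame(columns=["protein_id", "outcome", "beta", "se",
                                        "p", "converged", "direction", "tested"])
        for p in panel:
            if p not in present:
                res = pd.concat([res, pd.DataFrame([{
                    "protein_id": p, "outcome": outcome, "beta": np.nan,
                    "se": np.nan, "p": np.nan, "converged": False,
                    "direction": np.nan, "tested": False,
                }])], ignore_index=True)
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["tested"] & (out["p"] < alpha)
    return out


def significance_matrix(scan: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Proteins x outcomes matrix of ``+`` / ``-`` / ``.`` calls.

    ``+``/``-`` mark significant positive/negative directions at ``alpha``;
    ``.`` marks tested but non-significant; blank marks untested.
    """
    def cell(rows: pd.DataFrame) -> str:
        r = rows.iloc[0]
        if not r.get("tested", True):
            return ""
        if r["p"] < alpha:
            return "+" if r["beta"] > 0 else "-"
        return "."

    mat = scan.groupby(["protein_id", "outcome"], sort=False).apply(
        cell, include_groups=False
    ).unstack("outcome")
    return mat.fillna("")
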