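"""Single-score compression of a protein panel and replication testing.

A panel of proteins is collapsed to one number per sample either as the
mean of the panel members' Z-scores ("meanz") or as the first left
singular vector of the standardized panel submatrix (the "eigengene"),
then regressed on clinical outcomes in a replication set: logistic
regression for disease status, ordinary linear regression for continuous
measures such as MoCA and MDS-UPDRS III.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import ProteinMatrix, SampleMetadata, align


class SignatureError(ValueError):
    pass


@dataclass
class SignatureScore:
    """Per-sample scalar signature for one panel."""

    scores: pd.Series  # index = sample ids
    method: str  # "meanz" | "eigengene"
    panel: list[str]  # members actually used
    dropped: list[str] = field(default_factory=list)  # requested but absent
    #: fraction of panel variance captured (eigengene only)
    explained_variance: float | None = None


def _panel_z(matrix: ProteinMatrix, panel: Iterable[str]) -> tuple[pd.DataFrame, list[str], list[str]]:
    panel = [str(p) for p in panel]
    present = [p for p in panel if p in set(matrix.protein_ids)]
    dropped = [p for p in panel if p not in set(matrix.protein_ids)]
    if not present:
        raise SignatureError("no panel protein present in the matrix")
    sub = matrix.values.loc[:, present]
    sd = sub.std(axis=0, ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        raise SignatureError(f"constant panel protein(s): {const}")
    z = (sub - sub.mean(axis=0)) / sd
    return z, present, dropped


def meanz_score(matrix: ProteinMatrix, panel: Iterable[str]) -> SignatureScore:
    """Mean of the panel members' per-protein Z-scores."""
    z, present, dropped = _panel_z(matrix, panel)
    return SignatureScore(
        scores=z.mean(axis=1).rename("score"),
        method="meanz", panel=present, dropped=dropped,
    )


def eigengene_score(matrix: ProteinMatrix, panel: Iterable[str]) -> SignatureScore:
    """First-singular-vector (eigengene) summary of the panel.

    Scores are scaled to unit sample variance and sign-anchored so they
    correlate positively with the mean-Z score of the same panel (the raw
    SVD sign is arbitrary).
    """
    z, present, dropped = _panel_z(matrix, panel)
    if len(present) < 2:
        raise SignatureError("eigengene needs at least 2 panel proteins")
    if matrix.n_samples < 2:
        raise SignatureError("eigengene needs at least 2 samples")
    U, s, _ = np.linalg.svd(z.to_numpy(), full_matrices=False)
    if s[0] == 0:
        raise SignatureError("panel submatrix has rank 0")
    eg = U[:, 0] * s[0]
    meanz = z.mean(axis=1).to_numpy()
    if np.dot(eg, meanz) < 0:
        eg = -eg
    eg = eg / eg.std(ddof=1)
    return SignatureScore(
        scores=pd.Series(eg, index=matrix.sample_ids, name="score"),
        method="eigengene", panel=present, dropped=dropped,
        explained_variance=float(s[0] ** 2 / (s ** 2).sum()),
    )


def signature_association(
    signature: SignatureScore | pd.Series,
    metadata: SampleMetadata,
    outcome: str,
    covariates: Iterable[str] = (),
) -> tuple[float, float, float]:
    """Slope of the outcome on the signature score with Wald SE and p.

    ``status`` uses a logistic link (case = 1); any other outcome is fit
    with an identity link.  Samples missing the outcome or a covariate
    are dropped.  A perfectly separated logistic fit raises instead of
    returning an unstable estimate.
    """
    scores = signature.scores if isinstance(signature, SignatureScore) else signature
    common = [s for s in scores.index if s in set(metadata.sample_ids)]
    if not common:
        raise SignatureError("no overlap between scores and metadata")
    meta = metadata.subset(common).table
    x = scores.loc[common].astype(float)

    from .preprocess import _encode_covariates

    design = pd.DataFrame({"score": x})
    if covariates:
        design = pd.concat(
            [design, _encode_covariates(meta, list(covariates))], axis=1
        )
    if outcome == "status":
        y = (meta["status"] == "case").astype(float)
    else:
        if outcome not in meta.columns:
            raise SignatureError(f"outcome {outcome!r} not in metadata")
        y = meta[outcome].astype(float)
    ok = design.notna().all(axis=1) & y.notna()
    design, y = design.loc[ok], y.loc[ok]
    X = sm.add_constant(design, has_constant="add")

    if outcome == "status":
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SignatureError(f"logistic fit failed: {exc}") from exc
        if not np.isfinite(fit.bse["score"]) or fit.bse["score"] > 1e3:
            raise SignatureError("complete separation in logistic fit")
    else:
        fit = sm.OLS(y, X).fit()
    return (
        float(fit.params["score"]),
        float(fit.bse["score"]),
        float(fit.pvalues["score"]),
    )
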