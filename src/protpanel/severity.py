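"""Composite disease-severity scoring and stratified classification.

Cases are scored by an equal-weight composite of their standardized motor
and (reversed) cognitive measures: ``score = mean(z(updrs3), z(30 - moca))``
over cases, so higher = more severe.  Cases are then stratified either by
quantile (bottom 15% mild / top 10% severe by default, intermediate in
between) or by a median split, and the panel sweep is re-evaluated on
each stratum's cases against all controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ProteinMatrix, SampleMetadata, align
from .discovery import PanelClassifier, evaluate_on_modality, evaluate_roc

DEFAULT_MILD_FRAC = 0.15
DEFAULT_SEVERE_FRAC = 0.10


class SeverityError(ValueError):
    pass


def severity_score(metadata: SampleMetadata,
                   weights: tuple[float, float] = (0.5, 0.5)
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Composite severity score for cases with complete clinical measures.

    ``weights`` are the (updrs3, reversed-moca) weights of the composite;
    both components are z-scored across scorable cases first, so the score
    is invariant to affine rescaling of either clinical scale.  Returns
    the scores and a report of excluded cases.
    """
    t = metadata.table
    cases = t[t["status"] == "case"]
    for col in ("moca", "updrs3"):
        if col not in t.columns:
            raise SeverityError(f"metadata lacks {col!r}")
    ok = cases["moca"].notna() & cases["updrs3"].notna()
    excluded = pd.DataFrame({
        "sample_id": cases.index[~ok],
        "reason": ["missing moca or updrs3"] * int((~ok).sum()),
    })
    scorable = cases[ok]
    if len(scorable) < 2:
        raise SeverityError("fewer than 2 cases with complete clinical scores")

    def z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if sd == 0:
            return x * 0.0
        return (x - x.mean()) / sd

    w_up, w_moca = weights
    comp = (w_up * z(scorable["updrs3"].astype(float))
            + w_moca * z(30.0 - scorable["moca"].astype(float)))
    comp = comp / (w_up + w_moca)
    scores = pd.DataFrame({"sample_id": scorable.index, "score": comp.to_numpy()})
    return scores.reset_index(drop=True), excluded.reset_index(drop=True)


def stratify(scores: pd.DataFrame, scheme: str = "quantile",
             mild_frac: float = DEFAULT_MILD_FRAC,
             severe_frac: float = DEFAULT_SEVERE_FRAC) -> pd.DataFrame:
    """Label scored cases mild / intermediate / severe (or below / above).

    Quantile scheme: the bottom ``mild_frac`` of cases (by score) are
    mild, the top ``severe_frac`` severe, the rest intermediate; counts
    are rounded.  Median scheme: below / above the median, with the odd
    middle sample on the below side.  Ties break by sample id.
    """
    if scheme not in ("quantile", "median"):
        raise SeverityError(f"unknown scheme {scheme!r}")
    out = scores.sort_values(["score", "sample_id"]).reset_index(drop=True)
    n = len(out)
    if scheme == "median":
        n_below = (n + 1) // 2
        out["stratum"] = ["below"] * n_below + ["above"] * (n - n_below)
        return out
    if not (0 < mild_frac < 1 and 0 < severe_frac < 1
            and mild_frac + severe_frac <= 1):
        raise SeverityError("fractions must be in (0,1) with sum <= 1")
    n_mild = int(round(mild_frac * n))
    n_severe = int(round(severe_frac * n))
    strata = (["mild"] * n_mild
              + ["intermediate"] * (n - n_mild - n_severe)
              + ["severe"] * n_severe)
    out["stratum"] = strata
    return out


@dataclass
class StratumResult:
    stratum: str
    best_N: int
    auc: float
    ci_low: float
    ci_high: float
    p_perm: float
    n_cases: int
    n_controls: int


def stratified_evaluation(
    panels: Sequence[PanelClassifier],
    test_matrix: ProteinMatrix,
    test_metadata: SampleMetadata,
    strata: pd.DataFrame,
    n_permutations: int = 10_000,
    n_bootstrap: int = 2000,
    seed: int = 0,
    missing: str = "drop_and_refit",
) -> pd.DataFrame:
    """Evaluate a panel sweep within each severity stratum.

    For each stratum, the test set is restricted to that stratum's cases
    plus all controls; each swept panel is scored there and the best AUC
    wins, reported with its panel size N, permutation p and bootstrap CI.
    Empty strata (or strata with no overlap with the test matrix) are
    skipped.
    """
    test_matrix, test_metadata, _ = align(test_matrix, test_metadata)
    controls = [s for s in test_metadata.sample_ids
                if test_metadata.table.loc[s, "status"] == "control"]
    rows = []
    for stratum in pd.unique(strata["stratum"]):
        case_ids = strata.loc[strata["stratum"] == stratum, "sample_id"]
        case_ids = [s for s in case_ids if s in set(test_matrix.sample_ids)]
        if not case_ids or not controls:
            continue
        ids = case_ids + controls
        sub_matrix = test_matrix.subset_samples(ids)
        y = test_metadata.subset(ids).status_binary().to_numpy()
        best_clf, best_auc, best_scores = None, -np.inf, None
        for clf in panels:
            scores, _ = evaluate_on_modality(clf, sub_matrix, missing=missing)
            from .discovery import roc_auc

            auc = roc_auc(scores.to_numpy(), y)
            if auc > best_auc:
                best_clf, best_auc, best_scores = clf, auc, scores
        roc = evaluate_roc(best_scores.to_numpy(), y,
                           n_permutations=n_permutations,
                           n_bootstrap=n_bootstrap, seed=seed)
        rows.append(StratumResult(
            stratum=stratum, best_N=best_clf.N, auc=roc.auc,
            ci_low=roc.ci_low, ci_high=roc.ci_high, p_perm=roc.p_perm,
            n_cases=len(case_ids), n_controls=len(controls),
        ).__dict__)
    return pd.DataFrame(rows)
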