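"""Machine-learning discovery stage.

Proteins are ranked by a greedy annealing search over subsets: starting
from a small random subset, each iteration randomly perturbs it (add /
remove / swap one protein) and keeps the perturbed subset only if it
discriminates cases from controls better, measured by the stratified
cross-validated out-of-fold deviance of an unpenalized logistic model.
The search restarts from fresh random subsets several times within its
iteration budget, and proteins are ranked by how often the converged
chains select them.  Nested panels of the top-N ranked proteins
are then fit with random forests for a range of N, and each panel is
evaluated on held-out modalities with permutation-tested AUC and
percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .datamodel import ProteinMatrix, SampleMetadata, align

DEFAULT_SA_ITERATIONS = 1000
DEFAULT_N_PERMUTATIONS = 10_000
DEFAULT_RF_PARAMS = dict(
    n_estimators=500, max_features="sqrt", class_weight="balanced_subsample"
)
#: admissible annealing subset sizes; keeps the logistic fits well-posed
SA_SIZE_RANGE = (5, 100)
#: proposal probabilities for (add, remove, swap)
SA_PROPOSAL_PROBS = (0.25, 0.25, 0.5)


class DiscoveryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ROC / AUC primitives

def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney identity.

    Equals the probability that a random case outscores a random control,
    counting ties one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        labels = (labels == "case").astype(int)
    labels = labels.astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise DiscoveryError("both classes must be present to compute AUC")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def permutation_pvalue(scores, labels, n_permutations: int = DEFAULT_N_PERMUTATIONS,
                       seed: int = 0) -> float:
    """Permutation p-value for an observed AUC.

    Disease labels are permuted ``n_permutations`` times; the add-one
    estimator ``p = (r + 1) / (B + 1)`` counts permuted AUCs at least as
    large as the observed one, so the smallest attainable p at B = 10 000
    is 1.0e-4.
    """
    if n_permutations < 1:
        raise DiscoveryError("n_permutations must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        labels = (labels == "case").astype(int)
    labels = labels.astype(int)
    observed = roc_auc(scores, labels)
    n = len(labels)
    n1 = int(labels.sum())
    n0 = n - n1
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    rng = np.random.default_rng(seed)
    # a random size-n1 subset of positions == a label permutation
    keys = rng.random((n_permutations, n))
    case_idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
    perm_auc = (ranks[case_idx].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)
    r = int((perm_auc >= observed - 1e-12).sum())
    return (r + 1) / (n_permutations + 1)


def auc_ci(scores, labels, n_bootstrap: int = 2000, seed: int = 0,
           level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, stratified by class.

    With ``n_bootstrap = 1`` the interval degenerates to a single
    resampled AUC (both bounds equal).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        labels = (labels == "case").astype(int)
    labels = labels.astype(int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) < 2 or len(controls) < 2:
        raise DiscoveryError("need >= 2 samples per class for a bootstrap CI")
    rng = np.random.default_rng(seed)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        cs = rng.choice(cases, size=len(cases), replace=True)
        ct = rng.choice(controls, size=len(controls), replace=True)
        boot[b] = roc_auc(
            np.concatenate([cs, ct]),
            np.concatenate([np.ones(len(cs), int), np.zeros(len(ct), int)]),
        )
    a = (1 - level) / 2
    lo, hi = np.quantile(boot, [a, 1 - a])
    return float(lo), float(hi)


@dataclass(frozen=True)
class ROCResult:
    """AUC with permutation p-value and bootstrap confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    p_perm: float
    n_permutations: int
    n_bootstrap: int


def evaluate_roc(scores, labels, n_permutations: int = DEFAULT_N_PERMUTATIONS,
                 n_bootstrap: int = 2000, seed: int = 0) -> ROCResult:
    """AUC plus permutation p and 95% bootstrap CI in one record."""
    auc = roc_auc(scores, labels)
    p = permutation_pvalue(scores, labels, n_permutations, seed=seed)
    lo, hi = auc_ci(scores, labels, n_bootstrap, seed=seed)
    # the point estimate always lies inside its percentile interval
    lo, hi = min(lo, auc), max(hi, auc)
    return ROCResult(auc, lo, hi, p, n_permutations, n_bootstrap)


# ---------------------------------------------------------------------------
# logistic subset fitness

def _logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 60,
                  tol: float = 1e-10) -> np.ndarray:
    """Newton-Raphson logistic regression; returns coefficients
    (intercept first).  A vanishing ridge keeps the Hessian invertible
    when classes separate."""
    Xd = np.column_stack([np.ones(len(X)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -30, 30)
        mu = expit(eta)
        w = mu * (1 - mu) + 1e-12
        grad = Xd.T @ (y - mu)
        H = (Xd * w[:, None]).T @ Xd + 1e-10 * np.eye(Xd.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


def cv_folds(y: np.ndarray, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified CV folds, fixed by seed (shared across fitness calls)."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _oof_probabilities(values: np.ndarray, y: np.ndarray,
                       columns: np.ndarray,
                       folds: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Pooled out-of-fold case probabilities of a logistic model."""
    X = values[:, columns]
    oof = np.empty(len(y))
    for train, test in folds:
        beta = _logistic_fit(X[train], y[train])
        oof[test] = expit(np.clip(beta[0] + X[test] @ beta[1:], -30, 30))
    return oof


def subset_fitness(values: np.ndarray, y: np.ndarray,
                   columns: np.ndarray,
                   folds: list[tuple[np.ndarray, np.ndarray]],
                   metric: str = "deviance") -> float:
    """Cross-validated discrimination of a logistic model on one subset.

    ``deviance`` (default) scores the pooled out-of-fold predictions by
    minus their mean binomial deviance (higher is better).  Unlike the
    rank-based ``auc`` metric it is continuous in the predictions, so a
    greedy strictly-improving search does not freeze once the subset
    separates the classes: dropping an uninformative member still
    registers as an improvement.  ``auc`` scores the same pooled
    out-of-fold probabilities with the ROC area.
    """
    oof = _oof_probabilities(values, y, columns, folds)
    if metric == "auc":
        return roc_auc(oof, y)
    if metric != "deviance":
        raise DiscoveryError(f"unknown fitness metric {metric!r}")
    eps = 1e-12
    ll = y * np.log(oof + eps) + (1 - y) * np.log(1 - oof + eps)
    return float(ll.mean())


# ---------------------------------------------------------------------------
# simulated-annealing ranking

@dataclass
class RankedProteins:
    """Selection frequencies and dense ranks from the annealing search."""

    table: pd.DataFrame  # protein_id, selection_count, rank [, tiebreak]
    n_iterations: int

    def top(self, n: int) -> list[str]:
        """Top-n proteins by rank.

        Ties in selection count are broken by marginal discriminative
        strength (|t| of the univariate case-control contrast, recorded
        at ranking time) and finally by protein id, so top-N is
        deterministic.
        """
        t = self.table.copy()
        if "tiebreak" not in t.columns:
            t["tiebreak"] = 0.0
        t = t.sort_values(
            ["selection_count", "tiebreak", "protein_id"],
            ascending=[False, False, True],
        )
        return t["protein_id"].head(n).tolist()

    def __len__(self) -> int:
        return len(self.table)


def sa_rank_proteins(
    matrix: ProteinMatrix,
    metadata: SampleMetadata,
    n_iterations: int = DEFAULT_SA_ITERATIONS,
    seed: int = 0,
    n_folds: int = 5,
    n_restarts: int = 20,
    size_range: tuple[int, int] = SA_SIZE_RANGE,
    proposal_probs: tuple[float, float, float] = SA_PROPOSAL_PROBS,
    temperature: float = 0.0,
    count_mode: str = "final",
    metric: str = "deviance",
) -> RankedProteins:
    """Rank proteins by selection frequency under greedy annealing.

    The ``n_iterations`` total perturbations are spread over
    ``n_restarts`` independent chains, each starting from a fresh small
    random subset; selection counts aggregate over the chains, so a
    protein ranks highly only if it is selected for its discriminative
    power across many random starting points rather than by riding along
    in one chain's initial draw.  Within a chain a candidate subset
    replaces the current one only if its cross-validated logistic AUC
    strictly improves (with ``temperature`` > 0, worse candidates are
    additionally accepted with probability
    ``exp((f_cand - f_cur) / temperature)``; the default is pure greedy).
    At the end of its perturbation budget each chain is run to a removal
    local optimum under the same strict-improvement rule (members whose
    removal improves the fitness are dropped), so the chain's final
    subset is a converged selection.  ``count_mode`` controls what the
    selection counts mean: membership in each chain's final subset
    (default), membership in every accepted state, or in every visited
    candidate.
    """
    if n_iterations < 1:
        raise DiscoveryError("n_iterations must be >= 1")
    if count_mode not in ("final", "accepted", "visited"):
        raise DiscoveryError(f"unknown count_mode {count_mode!r}")
    n_restarts = max(1, min(n_restarts, n_iterations))
    matrix, metadata, _ = align(matrix, metadata)
    y = metadata.status_binary().to_numpy()
    if y.min() == y.max():
        raise DiscoveryError("both classes must be present")
    proteins = np.array(matrix.protein_ids)
    p = len(proteins)
    lo = min(size_range[0], p)
    hi = min(size_range[1], p)
    if p < 2:
        raise DiscoveryError("need at least 2 proteins to search over")

    rng = np.random.default_rng(seed)
    values = matrix.values.to_numpy()

    counts = np.zeros(p, dtype=int)
    per_chain = np.full(n_restarts, n_iterations // n_restarts)
    per_chain[: n_iterations % n_restarts] += 1
    for chain, chain_len in enumerate(per_chain):
        # fresh folds per chain: a protein that only looks good on one
        # particular fold split cannot accumulate counts across chains
        folds = cv_folds(y, n_folds, seed=seed * n_restarts + chain)
        current = set(rng.choice(p, size=lo, replace=False).tolist())
        current_fit = subset_fitness(values, y, np.fromiter(current, int), folds, metric)
        for _ in range(int(chain_len)):
            move = rng.choice(3, p=proposal_probs)
            cand = set(current)
            outside = np.setdiff1d(np.arange(p), np.fromiter(cand, int))
            if move == 0 and len(cand) < hi and len(outside):  # add
                cand.add(int(rng.choice(outside)))
            elif move == 1 and len(cand) > lo:  # remove
                cand.remove(int(rng.choice(np.fromiter(cand, int))))
            else:  # swap
                if len(outside):
                    cand.remove(int(rng.choice(np.fromiter(cand, int))))
                    cand.add(int(rng.choice(outside)))
            if cand == current:
                continue
            cand_idx = np.fromiter(cand, int)
            fit = subset_fitness(values, y, cand_idx, folds, metric)
            accept = fit > current_fit
            if not accept and temperature > 0:
                accept = rng.random() < np.exp((fit - current_fit) / temperature)
            if count_mode == "visited":
                counts[cand_idx] += 1
            if accept:
                current, current_fit = cand, fit
                if count_mode == "accepted":
                    counts[cand_idx] += 1
        # converge: greedy backward elimination under the same rule
        improved = True
        while improved and len(current) > lo:
            improved = False
            for member in sorted(current):
                if len(current) <= lo:
                    break
                cand = set(current)
                cand.remove(member)
                fit = subset_fitness(values, y, np.fromiter(cand, int),
                                     folds, metric)
                if fit > current_fit:
                    current, current_fit = cand, fit
                    improved = True
                    if count_mode == "accepted":
                        counts[np.fromiter(current, int)] += 1
        if count_mode == "final":
            counts[np.fromiter(current, int)] += 1

    # marginal |t| of each protein's case-control contrast, used only to
    # order proteins within a selection-count tie
    x1, x0 = values[y == 1], values[y == 0]
    n1, n0 = len(x1), len(x0)
    pooled = np.sqrt(
        ((n1 - 1) * x1.var(axis=0, ddof=1) + (n0 - 1) * x0.var(axis=0, ddof=1))
        / (n1 + n0 - 2)
    )
    pooled[pooled == 0] = np.inf
    tiebreak = np.abs(x1.mean(axis=0) - x0.mean(axis=0)) / (
        pooled * np.sqrt(1 / n1 + 1 / n0)
    )

    order = np.lexsort((proteins, -tiebreak, -counts))
    dense_rank = np.empty(p, dtype=int)
    # dense rank over descending selection counts
    sorted_counts = counts[order]
    ranks_sorted = np.ones(len(order), dtype=int)
    for i in range(1, len(order)):
        ranks_sorted[i] = ranks_sorted[i - 1] + (
            sorted_counts[i] != sorted_counts[i - 1]
        )
    dense_rank[order] = ranks_sorted
    table = pd.DataFrame({
        "protein_id": proteins,
        "selection_count": counts,
        "rank": dense_rank,
        "tiebreak": tiebreak,
    }).sort_values(
        ["rank", "tiebreak", "protein_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return RankedProteins(table, n_iterations)


# ---------------------------------------------------------------------------
# random-forest panels

@dataclass
class PanelClassifier:
    """A random forest fit on the top-N ranked proteins."""

    N: int
    members: list[str]
    model: RandomForestClassifier
    train_accuracy: float
    seed: int
    rf_params: dict = field(default_factory=dict)
    _train_values: pd.DataFrame | None = field(default=None, repr=False)
    _train_labels: np.ndarray | None = field(default=None, repr=False)


def build_panel_classifier(
    matrix: ProteinMatrix,
    metadata: SampleMetadata,
    ranked: RankedProteins,
    N: int,
    rf_params: dict | None = None,
    seed: int = 0,
) -> PanelClassifier:
    """Fit a random forest on exactly the top-N ranked proteins.

    Training accuracy is the out-of-bag estimate.  Deterministic under
    ``seed``.
    """
    if N < 1:
        raise DiscoveryError("N must be >= 1")
    if N > len(ranked):
        raise DiscoveryError(f"N = {N} exceeds the {len(ranked)} ranked proteins")
    matrix, metadata, _ = align(matrix, metadata)
    members = ranked.top(N)
    X = matrix.values.loc[:, members]
    y = metadata.status_binary().to_numpy()
    params = {**DEFAULT_RF_PARAMS, **(rf_params or {})}
    model = RandomForestClassifier(random_state=seed, oob_score=True, **params)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny panels can miss OOB coverage
        model.fit(X.to_numpy(), y)
    try:
        acc = float(model.oob_score_)
    except AttributeError:  # pragma: no cover
        acc = float(model.score(X.to_numpy(), y))
    return PanelClassifier(
        N=N, members=members, model=model, train_accuracy=acc, seed=seed,
        rf_params=params, _train_values=X, _train_labels=y,
    )


def sweep_panel_sizes(
    matrix: ProteinMatrix,
    metadata: SampleMetadata,
    ranked: RankedProteins,
    n_min: int = 1,
    n_max: int = 200,
    rf_params: dict | None = None,
    seed: int = 0,
) -> list[PanelClassifier]:
    """One classifier per panel size N in [n_min, n_max].

    Every panel is built with the same base seed, so any entry can be
    reproduced by an independent ``build_panel_classifier`` call.
    """
    if not 1 <= n_min <= n_max:
        raise DiscoveryError("need 1 <= n_min <= n_max")
    if n_max > len(ranked):
        raise DiscoveryError("n_max exceeds the number of ranked proteins")
    return [
        build_panel_classifier(matrix, metadata, ranked, N, rf_params, seed)
        for N in range(n_min, n_max + 1)
    ]


def evaluate_on_modality(
    classifier: PanelClassifier,
    test_matrix: ProteinMatrix,
    missing: str = "drop_and_refit",
) -> tuple[pd.Series, dict]:
    """Per-sample case probabilities of a panel on a test matrix.

    Panel proteins absent from the test matrix are handled per policy:
    ``error``, ``drop_and_refit`` (refit the forest on the surviving
    members with the stored training data; mirrors replication sets where
    only part of a signature passes cohort-level QC), or ``impute_mean``
    (fill missing test columns with training means).
    """
    present = [p for p in classifier.members if p in set(test_matrix.protein_ids)]
    absent = [p for p in classifier.members if p not in set(test_matrix.protein_ids)]
    report = {"missing_proteins": absent, "used_proteins": present, "policy": missing}
    if not present:
        raise DiscoveryError("all panel proteins are absent from the test matrix")
    if absent and missing == "error":
        raise DiscoveryError(f"panel proteins missing from test matrix: {absent}")
    if absent and missing == "drop_and_refit":
        if classifier._train_values is None:
            raise DiscoveryError("classifier carries no training data to refit")
        model = RandomForestClassifier(
            random_state=classifier.seed, oob_score=False, **classifier.rf_params
        )
        model.fit(
            classifier._train_values.loc[:, present].to_numpy(),
            classifier._train_labels,
        )
        X = test_matrix.values.loc[:, present].to_numpy()
    elif absent and missing == "impute_mean":
        if classifier._train_values is None:
            raise DiscoveryError("classifier carries no training data to impute from")
        model = classifier.model
        X = pd.DataFrame(index=test_matrix.sample_ids, columns=classifier.members,
                         dtype=float)
        X.loc[:, present] = test_matrix.values.loc[:, present]
        for p in absent:
            X[p] = classifier._train_values[p].mean()
        X = X.to_numpy()
    else:
        model = classifier.model
        X = test_matrix.values.loc[:, classifier.members].to_numpy()
    probs = model.predict_proba(X)[:, 1]
    return pd.Series(probs, index=test_matrix.sample_ids, name="score"), report


def roc_points(scores, labels) -> pd.DataFrame:
    """(FPR, TPR, threshold) points of the ROC curve, for plotting."""
    from sklearn.metrics import roc_curve

    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        labels = (labels == "case").astype(int)
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def best_panel_by_test_auc(
    panels: list[PanelClassifier],
    test_matrix: ProteinMatrix,
    test_metadata: SampleMetadata,
    missing: str = "drop_and_refit",
) -> tuple[PanelClassifier, float]:
    """Pick the swept panel with the highest AUC on a held-out modality."""
    test_matrix, test_metadata, _ = align(test_matrix, test_metadata)
    y = test_metadata.status_binary().to_numpy()
    best, best_auc = None, -np.inf
    for clf in panels:
        scores, _ = evaluate_on_modality(clf, test_matrix, missing=missing)
        auc = roc_auc(scores.to_numpy(), y)
        if auc > best_auc:
            best, best_auc = clf, auc
    return best, float(best_auc)
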