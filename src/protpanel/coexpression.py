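"""Weighted co-expression network modules for proteins.

A WGCNA-style pipeline adapted to protein panels: unsigned soft-power
adjacency ``a_ij = |cor(x_i, x_j)|^power`` (default power 2), topological
overlap similarity, average-linkage hierarchical clustering on the TOM
dissimilarity with a static height cut, a minimum admissible module size
(default 30 proteins; smaller clusters fall into the unassigned "grey"
bin), merging of near-identical module eigengenes, and a block-wise mode
for wide matrices.  Each module is summarized by its eigengene (first
principal component of the standardized member submatrix) and a hub
protein — the member with the strongest eigengene correlation (|kME|).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datamodel import ProteinMatrix, SampleMetadata

DEFAULT_POWER = 2
DEFAULT_MIN_SIZE = 30
DEFAULT_BLOCK_SIZE = 5000
DEFAULT_CUT_HEIGHT = 0.85
DEFAULT_MERGE_CORR = 0.8
GREY = "grey"

#: module label sequence (largest module first), after the WGCNA convention
_MODULE_COLOURS = (
    "turquoise blue brown yellow green red black pink magenta purple "
    "greenyellow tan salmon cyan midnightblue lightcyan grey60 lightgreen "
    "lightyellow royalblue darkred darkgreen darkturquoise darkgrey orange "
    "darkorange white skyblue saddlebrown steelblue paleturquoise violet "
    "darkolivegreen darkmagenta"
).split()


class CoexpressionError(ValueError):
    pass


def adjacency_tom(matrix: ProteinMatrix, power: float = DEFAULT_POWER,
                  signed: bool = False, on_constant: str = "error",
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Soft-power adjacency and topological overlap matrix.

    ``a_ij = |cor|^power`` (unsigned; ``signed`` keeps the sign convention
    ``((1 + cor)/2)^power``), zero diagonal.  The topological overlap is

        TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

    with connectivity ``k_i = sum_{j != i} a_ij`` and unit diagonal.
    """
    matrix.require_state("log2", "standardized", "residualized")
    if matrix.n_proteins < 3:
        raise CoexpressionError("need at least 3 proteins for a network")
    vals = matrix.values
    sd = vals.std(axis=0, ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        if on_constant == "drop":
            vals = vals.drop(columns=const)
        else:
            raise CoexpressionError(f"constant protein(s): {const}")
    ids = list(vals.columns)
    corr = np.corrcoef(vals.to_numpy(), rowvar=False)
    if signed:
        A = ((1.0 + corr) / 2.0) ** power
    else:
        A = np.abs(corr) ** power
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return (
        pd.DataFrame(A, index=ids, columns=ids),
        pd.DataFrame(tom, index=ids, columns=ids),
    )


def _cut_block(tom: np.ndarray, ids: list[str], min_size: int,
               cut_height: float, method: str) -> list[list[str]]:
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method=method)
    labels = fcluster(Z, t=cut_height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for pid, lab in zip(ids, labels):
        clusters.setdefault(int(lab), []).append(pid)
    return [m for m in clusters.values() if len(m) >= min_size]


def detect_modules(tom: pd.DataFrame, min_size: int = DEFAULT_MIN_SIZE,
                   block_size: int = DEFAULT_BLOCK_SIZE,
                   cut_height: float = DEFAULT_CUT_HEIGHT,
                   linkage_method: str = "average") -> pd.Series:
    """Partition proteins into modules by clustering the TOM dissimilarity.

    Average-linkage hierarchical clustering on ``1 - TOM`` cut at a static
    height; clusters below ``min_size`` are assigned ``grey``.  Matrices
    wider than ``block_size`` are pre-split into TOM-similarity blocks
    (k-means on the TOM rows) and clustered per block.  Module labels are
    colour names assigned by decreasing module size.
    """
    if block_size < min_size:
        raise CoexpressionError("block_size must be >= min_size")
    if min_size < 2:
        raise CoexpressionError("min_size must be >= 2")
    ids = list(tom.index)
    T = tom.to_numpy()
    if len(ids) <= block_size:
        blocks = [np.arange(len(ids))]
    else:
        from sklearn.cluster import KMeans

        n_blocks = int(np.ceil(len(ids) / block_size))
        km = KMeans(n_clusters=n_blocks, n_init=4, random_state=0).fit(T)
        blocks = [np.where(km.labels_ == b)[0] for b in range(n_blocks)]
    modules: list[list[str]] = []
    for idx in blocks:
        if len(idx) < min_size:
            continue
        sub_ids = [ids[i] for i in idx]
        modules.extend(
            _cut_block(T[np.ix_(idx, idx)], sub_ids, min_size,
                       cut_height, linkage_method)
        )
    modules.sort(key=lambda m: (-len(m), m[0]))
    assignment = pd.Series(GREY, index=ids, name="module")
    for i, members in enumerate(modules):
        label = (_MODULE_COLOURS[i] if i < len(_MODULE_COLOURS)
                 else f"module{i + 1}")
        assignment.loc[members] = label
    return assignment


@dataclass
class ModuleSet:
    """Module assignments with eigengenes, hubs and kME correlations."""

    assignment: pd.Series  # protein_id -> module label ("grey" = none)
    power: float
    min_size: int
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)
    hubs: dict[str, str] = field(default_factory=dict)
    kme: pd.DataFrame = field(default_factory=pd.DataFrame)

    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]

    def members(self, module: str) -> list[str]:
        return self.assignment.index[self.assignment == module].tolist()


def _module_eigengene(z: pd.DataFrame) -> pd.Series:
    """First PC of a standardized member submatrix, unit variance,
    sign-anchored to positive mean member correlation."""
    if z.shape[1] == 1:
        eg = z.iloc[:, 0].to_numpy()
    else:
        U, s, _ = np.linalg.svd(z.to_numpy(), full_matrices=False)
        eg = U[:, 0] * s[0]
    mean_member = z.mean(axis=1).to_numpy()
    if np.dot(eg, mean_member) < 0:
        eg = -eg
    sd = eg.std(ddof=1)
    if sd == 0:
        raise CoexpressionError("degenerate (constant) module eigengene")
    return pd.Series(eg / sd, index=z.index)


def module_eigengene_and_hub(matrix: ProteinMatrix, assignment: pd.Series,
                             power: float = DEFAULT_POWER,
                             min_size: int = DEFAULT_MIN_SIZE) -> ModuleSet:
    """Eigengenes, kME table and hub proteins for an assignment.

    kME is the Pearson correlation of every protein with every module
    eigengene; the hub of a module is its member with maximal |kME|
    (ties broken lexicographically).  Size-1 modules degrade to the
    member's own Z-score.
    """
    labels = [m for m in assignment.unique() if m != GREY]
    if not labels:
        raise CoexpressionError("no non-grey modules in the assignment")
    vals = matrix.values
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    eigengenes = {}
    for mod in labels:
        members = assignment.index[assignment == mod].tolist()
        eigengenes[mod] = _module_eigengene(z.loc[:, members])
    # stable ordering: by size desc then label
    order = sorted(labels, key=lambda m: (-(assignment == m).sum(), m))
    eg = pd.DataFrame({m: eigengenes[m] for m in order})
    zn = z.to_numpy()
    egn = eg.to_numpy()
    n = len(z)
    kme_arr = (zn - zn.mean(0)).T @ ((egn - egn.mean(0))) / (
        (n - 1) * np.outer(zn.std(0, ddof=1), egn.std(0, ddof=1))
    )
    kme = pd.DataFrame(kme_arr, index=z.columns, columns=eg.columns)
    hubs = {}
    for mod in order:
        members = assignment.index[assignment == mod].tolist()
        km = kme.loc[members, mod].abs()
        best = km[km == km.max()].index.min()
        hubs[mod] = best
    return ModuleSet(
        assignment=assignment.copy(), power=power, min_size=min_size,
        eigengenes=eg, hubs=hubs, kme=kme,
    )


def merge_close_modules(matrix: ProteinMatrix, assignment: pd.Series,
                        threshold: float = DEFAULT_MERGE_CORR,
                        power: float = DEFAULT_POWER,
                        min_size: int = DEFAULT_MIN_SIZE) -> pd.Series:
    """Merge modules whose eigengenes correlate above ``threshold``.

    Iterates until no pair of module eigengenes exceeds the threshold;
    the merged module keeps the larger member's label.
    """
    assignment = assignment.copy()
    while True:
        labels = [m for m in assignment.unique() if m != GREY]
        if len(labels) < 2:
            return assignment
        ms = module_eigengene_and_hub(matrix, assignment, power, min_size)
        corr = ms.eigengenes.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            return assignment
        keep, drop = ms.eigengenes.columns[i], ms.eigengenes.columns[j]
        assignment[assignment == drop] = keep


def find_modules(matrix: ProteinMatrix, power: float = DEFAULT_POWER,
                 min_size: int = DEFAULT_MIN_SIZE,
                 block_size: int = DEFAULT_BLOCK_SIZE,
                 cut_height: float = DEFAULT_CUT_HEIGHT,
                 merge_threshold: float = DEFAULT_MERGE_CORR,
                 signed: bool = False) -> ModuleSet:
    """Full module pipeline: adjacency -> TOM -> cut -> merge -> summaries."""
    _, tom = adjacency_tom(matrix, power=power, signed=signed)
    assignment = detect_modules(tom, min_size=min_size, block_size=block_size,
                                cut_height=cut_height)
    if (assignment != GREY).any():
        assignment = merge_close_modules(
            matrix, assignment, threshold=merge_threshold,
            power=power, min_size=min_size,
        )
        return module_eigengene_and_hub(matrix, assignment, power, min_size)
    return ModuleSet(assignment=assignment, power=power, min_size=min_size)


def module_trait_association(moduleset: ModuleSet, metadata: SampleMetadata,
                             traits: Iterable[str] = ("status", "updrs3", "moca"),
                             covariates: Iterable[str] = ()) -> pd.DataFrame:
    """Regress each module eigengene on each clinical trait.

    Logistic regression for ``status``, ordinary linear regression for
    continuous traits; one row per module with ``<trait>_beta`` and
    ``<trait>_p`` columns (Table-style layout: one column pair per trait).
    """
    from .signature import SignatureScore, signature_association

    rows = []
    for mod in moduleset.modules():
        row: dict[str, float | str] = {"module": mod}
        sig = SignatureScore(
            scores=moduleset.eigengenes[mod], method="eigengene",
            panel=moduleset.members(mod),
        )
        for trait in traits:
            beta, _se, p = signature_association(
                sig, metadata, trait, covariates=covariates
            )
            row[f"{trait}_beta"] = beta
            row[f"{trait}_p"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("module")
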