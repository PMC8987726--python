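"""Weighted correlation network analysis and bait-gene-guided candidate
mining.

The network follows the weighted-correlation recipe: soft-thresholded
(power 8, unsigned by default) Pearson correlation of log2(FPKM+1)
profiles, topological overlap (TOM) similarity, average-linkage
hierarchical clustering of 1−TOM, and eigengene-based module merging at a
dissimilarity cut of 0.25.  Module detection uses a static quantile cut to
find tight cores followed by an iterated module-eigengene (kME)
refinement; see the methods note for why a plain high-quantile static cut
is not usable at a dozen samples.

Candidate mining localizes previously characterized pathway genes
("baits") to modules and extracts the CYP450-annotated genes sharing those
modules, prioritized by elicitor-induced upregulation and correlation to
the baits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

#: Module labels in size-rank order, following the field's color convention
#: ("grey" is reserved for unassigned genes).
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)

GREY = "grey"


@dataclass
class ModuleAssignment:
    """Gene→module map plus per-module eigengenes (unit-norm, one column
    per module; grey has none) and the merge history."""

    labels: pd.Series
    eigengenes: pd.DataFrame
    merge_history: List[Tuple[str, str]] = field(default_factory=list)

    def modules(self) -> List[str]:
        return [m for m in self.eigengenes.columns]

    def genes_in(self, module: str) -> List[str]:
        return list(self.labels.index[self.labels == module])


def _validate_expr(expr: pd.DataFrame) -> None:
    if expr.index.duplicated().any():
        raise ValueError("gene ids must be unique")
    if (expr.values < 0).any():
        raise ValueError("expression values must be non-negative")


def prefilter(expr: pd.DataFrame, min_nonzero_frac: float = 0.5
              ) -> pd.DataFrame:
    """Drop zero-variance genes and genes detected in fewer than
    ``min_nonzero_frac`` of samples."""
    _validate_expr(expr)
    nonzero = (expr.values > 0).mean(axis=1) >= min_nonzero_frac
    variable = expr.values.std(axis=1) > 0
    out = expr.loc[nonzero & variable]
    if out.shape[0] < 3:
        raise ValueError(
            f"only {out.shape[0]} genes survive prefiltering; need >= 3")
    return out


def _log_corr(expr: pd.DataFrame, log_transform: bool = True) -> np.ndarray:
    X = np.log2(expr.values + 1.0) if log_transform else expr.values
    sd = X.std(axis=1)
    if (sd == 0).any():
        raise ValueError("constant gene encountered; run prefilter first")
    return np.corrcoef(X)


def adjacency(expr: pd.DataFrame, power: float = 8,
              kind: str = "unsigned", log_transform: bool = True
              ) -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency.

    unsigned: a_ij = |cor|^power; signed: a_ij = ((1+cor)/2)^power.
    Diagonal is 1; values lie in [0, 1].
    """
    C = _log_corr(expr, log_transform)
    if kind == "unsigned":
        A = np.abs(C) ** power
    elif kind == "signed":
        A = ((1.0 + C) / 2.0) ** power
    else:
        raise ValueError(f"kind must be 'unsigned' or 'signed', got {kind!r}")
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=expr.index, columns=expr.index)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity.

    TOM_ij = (Σ_u a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij) with the
    sum over u ∉ {i, j} and k the (diagonal-free) connectivity; diagonal 1.
    """
    A = adj.values.astype(float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    k = A.sum(axis=1) - 1.0
    shared = A @ A - 2.0 * A  # removes the u=i and u=j terms (diag of A is 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + A) / (np.minimum.outer(k, k) + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------

def _standardize(expr: pd.DataFrame) -> np.ndarray:
    X = np.log2(expr.values + 1.0)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized expression,
    unit-norm and sign-oriented so the mean member correlation is positive."""
    Xs = _standardize(expr)
    out = {}
    for module in sorted(set(labels) - {GREY}):
        idx = np.flatnonzero((labels == module).values)
        sub = Xs[idx]
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        e = vt[0]
        if (sub @ e).mean() < 0:
            e = -e
        out[module] = e / np.linalg.norm(e)
    return pd.DataFrame(out, index=expr.columns)


def _kme(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """|correlation| of every gene with every module eigengene."""
    Xs = _standardize(expr)
    Xn = Xs / np.linalg.norm(Xs, axis=1, keepdims=True)
    E = eigengenes.values - eigengenes.values.mean(axis=0, keepdims=True)
    En = E / np.linalg.norm(E, axis=0, keepdims=True)
    return pd.DataFrame(np.abs(Xn @ En), index=expr.index,
                        columns=eigengenes.columns)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def detect_modules(
    tom: pd.DataFrame,
    expr: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    kme_threshold: float = 0.75,
    max_refine_iter: int = 3,
) -> ModuleAssignment:
    """Average-linkage clustering of 1−TOM with kME refinement.

    Cores come from a static cut of the dendrogram at dissimilarity
    ``cut_height`` (module assembly happens well below it, while merges
    among unconnected genes sit above); every gene is then (re)assigned
    to the module whose eigengene it correlates with best, provided
    |kME| ≥ ``kme_threshold``, iterating until stable.  Clusters below
    ``min_module_size`` are dissolved to grey.  Labels are size-ranked
    module colors, so the assignment is invariant to gene input order.
    """
    genes = tom.index
    D = 1.0 - tom.values
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    clusters = fcluster(Z, t=cut_height, criterion="distance")
    lab = pd.Series(clusters, index=genes)
    sizes = lab.value_counts()
    lab[lab.map(sizes) < min_module_size] = -1

    for _ in range(max_refine_iter):
        active = sorted(set(lab) - {-1})
        if not active:
            break
        tmp = lab.map(lambda c: GREY if c == -1 else f"m{c}")
        eig = module_eigengenes(expr.loc[genes], tmp)
        if eig.empty:
            break
        kme = _kme(expr.loc[genes], eig)
        best = kme.idxmax(axis=1)
        bestv = kme.max(axis=1)
        new = np.where(bestv >= kme_threshold,
                       best.str.lstrip("m").astype(int), -1)
        new = pd.Series(new, index=genes)
        sizes = new.value_counts()
        new[new.map(sizes) < min_module_size] = -1
        if new.equals(lab):
            break
        lab = new

    # size-ranked color labels (ties broken by the cluster's first gene
    # position is avoided by sorting on size then smallest member id)
    final_sizes = lab[lab != -1].value_counts()
    order = sorted(final_sizes.index,
                   key=lambda c: (-final_sizes[c],
                                  min(genes[lab == c].tolist())))
    colors = {c: (MODULE_COLORS[i] if i < len(MODULE_COLORS)
                  else f"module{i + 1}")
              for i, c in enumerate(order)}
    labels = lab.map(lambda c: GREY if c == -1 else colors[c])
    labels.name = "module"
    eig = module_eigengenes(expr.loc[genes], labels)
    return ModuleAssignment(labels=labels, eigengenes=eig)


def merge_modules(assignment: ModuleAssignment, expr: pd.DataFrame,
                  cut_height: float = 0.25) -> ModuleAssignment:
    """Iteratively merge modules whose eigengene dissimilarity 1−cor is
    below ``cut_height``, recomputing eigengenes after every merge."""
    labels = assignment.labels.copy()
    history = list(assignment.merge_history)
    while True:
        modules = sorted(set(labels) - {GREY})
        if len(modules) < 2:
            break
        eig = module_eigengenes(expr, labels)
        E = eig.values - eig.values.mean(axis=0, keepdims=True)
        En = E / np.linalg.norm(E, axis=0, keepdims=True)
        C = En.T @ En
        diss = 1.0 - C
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= cut_height:
            break
        keep, absorb = sorted([eig.columns[i], eig.columns[j]],
                              key=lambda m: -np.sum(labels == m))
        labels[labels == absorb] = keep
        history.append((absorb, keep))
    eig = module_eigengenes(expr, labels)
    return ModuleAssignment(labels=labels, eigengenes=eig,
                            merge_history=history)


# ---------------------------------------------------------------------------
# Bait localization and candidate mining
# ---------------------------------------------------------------------------

def locate_baits(assignment: ModuleAssignment,
                 baits: Sequence[str]) -> pd.DataFrame:
    """Module of each bait gene; baits absent from the matrix are listed
    with module 'missing' rather than raising."""
    rows = []
    for bait in baits:
        if bait in assignment.labels.index:
            rows.append({"bait": bait, "module": assignment.labels[bait]})
        else:
            rows.append({"bait": bait, "module": "missing"})
    return pd.DataFrame(rows)


def bait_modules(assignment: ModuleAssignment,
                 baits: Sequence[str]) -> List[str]:
    """Distinct modules (grey included, flagged once) containing baits."""
    located = locate_baits(assignment, baits)
    return sorted(set(located.module) - {"missing"})


@dataclass(frozen=True)
class CandidateGene:
    gene: str
    module: str
    clan: str
    family: str
    max_bait_cor: float
    n_up_treatments: int
    priority: float


def mine_candidates(
    assignment: ModuleAssignment,
    expr: pd.DataFrame,
    baits: Sequence[str],
    annotations: pd.DataFrame,
    target_modules: Optional[Sequence[str]] = None,
    deg_results: Optional[Mapping[str, pd.DataFrame]] = None,
    min_bait_cor: Optional[float] = None,
) -> pd.DataFrame:
    """Extract and prioritize CYP450 candidates from bait modules.

    ``annotations`` is indexed by gene id with columns ``is_cyp450``,
    ``clan`` and ``family``.  ``deg_results`` maps treatment name → a
    deg_screen table (with a ``direction`` column) against the control.
    Priority = (number of treatments with upregulation) + max |cor| with
    the in-module baits, so upregulation dominates and correlation breaks
    ranks within it; exact ties fall back to the gene id.
    """
    if target_modules is None:
        target_modules = [m for m in bait_modules(assignment, baits)
                          if m != GREY]
    if not target_modules:
        warnings.warn("no bait-containing modules; nothing to mine")
        return pd.DataFrame(columns=[
            "gene", "module", "clan", "family", "max_bait_cor",
            "n_up_treatments", "priority"])
    Xs = _standardize(expr)
    Xn = pd.DataFrame(Xs / np.linalg.norm(Xs, axis=1, keepdims=True),
                      index=expr.index)
    rows = []
    for module in target_modules:
        members = assignment.genes_in(module)
        module_baits = [b for b in baits if b in members]
        cyps = [g for g in members
                if g in annotations.index
                and bool(annotations.loc[g, "is_cyp450"])]
        for gene in cyps:
            cor = max(
                (abs(float(Xn.loc[gene] @ Xn.loc[b])) for b in module_baits),
                default=0.0)
            if min_bait_cor is not None and cor < min_bait_cor:
                continue
            n_up = 0
            if deg_results:
                for table in deg_results.values():
                    if gene in table.index and \
                            table.loc[gene, "direction"] == "up":
                        n_up += 1
            rows.append({
                "gene": gene, "module": module,
                "clan": str(annotations.loc[gene].get("clan", "")),
                "family": str(annotations.loc[gene].get("family", "")),
                "max_bait_cor": cor, "n_up_treatments": n_up,
                "priority": n_up + cor,
            })
    df = pd.DataFrame(rows, columns=[
        "gene", "module", "clan", "family", "max_bait_cor",
        "n_up_treatments", "priority"])
    return df.sort_values(["priority", "gene"],
                          ascending=[False, True]).reset_index(drop=True)


def edge_list(tom: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """TOM edge list (gene_a, gene_b, tom) above a threshold, for export
    to network-visualization tools."""
    A = tom.values
    iu = np.triu_indices(A.shape[0], 1)
    mask = A[iu] >= threshold
    return pd.DataFrame({
        "gene_a": tom.index.values[iu[0][mask]],
        "gene_b": tom.columns.values[iu[1][mask]],
        "tom": A[iu][mask],
    })
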