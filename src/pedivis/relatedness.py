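"""Additive-genetic, mitochondrial, and custom relatedness matrices.

The kinship coefficient phi(i, j) is the probability that one allele sampled
at random from i and one from j at the same autosomal locus are identical by
descent.  It satisfies the classic recursion (parents before children):

    phi(i, i) = 1/2 * (1 + phi(mother_i, father_i))
    phi(i, j) = 1/2 * (phi(mother_i, j) + phi(father_i, j))   (j not a
                descendant of i)

with phi over a missing parent equal to 0 — founders are taken non-inbred
and mutually unrelated.  The additive (numerator) relationship matrix is
2 * phi; its diagonal is 1 + F where F, the inbreeding coefficient, is the
kinship of the individual's parents.

The mitochondrial matrix is the 0/1 indicator of a shared matrilineal
founder: mitochondria are maternally inherited, so two individuals carry the
same mitochondrial lineage exactly when following mother links upward lands
on the same root.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

import numpy as np

from .ped_model import PedigreeTable, parent_graph, validate

import networkx as nx


@dataclass
class RelatednessMatrix:
    """Symmetric, id-indexed coefficient matrix with a kind tag."""

    ids: List[str]
    values: np.ndarray
    kind: str = "custom"  # additive | mitochondrial | custom

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix dimensions do not match id list")
        self._index: Dict[str, int] = {pid: i for i, pid in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def __getitem__(self, key) -> float:
        i, j = key
        return self.loc(i, j)


def _topological_ids(ped: PedigreeTable) -> List[str]:
    g = parent_graph(ped)
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        raise ValueError("pedigree contains an ancestry cycle") from None


def kinship_matrix(ped: PedigreeTable) -> RelatednessMatrix:
    """Kinship coefficients phi for every pair, by the parents-first recursion.

    O(n^2) time and memory; requires an acyclic pedigree (a cycle raises).
    """
    order = _topological_ids(ped)
    n = len(order)
    pos = {pid: k for k, pid in enumerate(order)}
    phi = np.zeros((n, n))

    moms: List[Optional[int]] = []
    dads: List[Optional[int]] = []
    for pid in order:
        ind = ped.get(pid)
        moms.append(pos[ind.momID] if ind.momID in pos else None)
        dads.append(pos[ind.dadID] if ind.dadID in pos else None)

    for i in range(n):
        m, d = moms[i], dads[i]
        # off-diagonals against everyone already placed (all potential
        # ancestors precede i in topological order)
        for j in range(i):
            pm = phi[m, j] if m is not None else 0.0
            pd_ = phi[d, j] if d is not None else 0.0
            phi[i, j] = phi[j, i] = 0.5 * (pm + pd_)
        par_phi = phi[m, d] if (m is not None and d is not None) else 0.0
        phi[i, i] = 0.5 * (1.0 + par_phi)

    # back to input row order
    perm = [pos[pid] for pid in ped.ids]
    phi = phi[np.ix_(perm, perm)]
    return RelatednessMatrix(ids=list(ped.ids), values=phi, kind="custom")


def additive_matrix(ped: PedigreeTable) -> RelatednessMatrix:
    """Numerator relationship matrix A = 2 * phi (kind ``additive``)."""
    k = kinship_matrix(ped)
    return RelatednessMatrix(ids=k.ids, values=2.0 * k.values, kind="additive")


def inbreeding_coefficients(ped: PedigreeTable) -> Dict[str, float]:
    """F_i = 2*phi(i,i) - 1 for every individual."""
    k = kinship_matrix(ped)
    return {pid: 2.0 * k.values[i, i] - 1.0 for i, pid in enumerate(k.ids)}


def matrilineal_founder(ped: PedigreeTable, person: str) -> str:
    """Follow mother links upward until the mother is missing or absent."""
    cur = person
    seen = {cur}
    while True:
        mom = ped.get(cur).momID
        if mom is None or mom not in ped or mom in seen:
            return cur
        cur = mom
        seen.add(cur)


def mitochondrial_matrix(ped: PedigreeTable) -> RelatednessMatrix:
    """0/1 indicator of shared matrilineal founder (kind ``mitochondrial``).

    The unit entries form an equivalence relation: the matrix is
    block-diagonal under a permutation grouping matrilines together.
    """
    roots = [matrilineal_founder(ped, pid) for pid in ped.ids]
    arr = np.array(roots)
    values = (arr[:, None] == arr[None, :]).astype(float)
    return RelatednessMatrix(ids=list(ped.ids), values=values, kind="mitochondrial")


def highlight_set(mat: RelatednessMatrix, focal: str, threshold: float) -> Set[str]:
    """Ids whose coefficient with ``focal`` is at least ``threshold``."""
    if focal not in mat._index:
        raise KeyError(f"unknown focal id: {focal!r}")
    row = mat.values[mat._index[focal]]
    return {pid for pid, v in zip(mat.ids, row) if v >= threshold}


def submatrix(mat: RelatednessMatrix, ids: Sequence[str]) -> RelatednessMatrix:
    """Restrict and reorder rows/columns to ``ids``; kind is preserved."""
    try:
        idx = [mat._index[i] for i in ids]
    except KeyError as e:
        raise KeyError(f"id not in matrix: {e.args[0]!r}") from None
    return RelatednessMatrix(
        ids=list(ids), values=mat.values[np.ix_(idx, idx)], kind=mat.kind
    )


def gene_drop_kinship(
    ped: PedigreeTable, n_replicates: int = 100_000, seed: int = 20240101
) -> tuple:
    """Monte-Carlo kinship estimate by gene dropping, with standard errors.

    Each founder receives two uniquely labelled alleles; every non-founder
    inherits one allele drawn uniformly at random from each parent,
    independently across replicates.  The kinship estimate for (i, j) is the
    mean over replicates of the identity-by-state fraction among the four
    cross-individual allele pairings (identity of labels == identity by
    descent here, since founder labels are unique).

    Returns ``(ids, phi_hat, se)`` with ``se`` the per-entry standard error
    of the Monte-Carlo mean.  Intended as an independent cross-check of
    :func:`kinship_matrix` on small pedigrees, not as a production path.
    """
    order = _topological_ids(ped)
    n = len(order)
    pos = {pid: k for k, pid in enumerate(order)}
    rng = np.random.default_rng(seed)

    a = np.empty((n, 2, n_replicates), dtype=np.int32)
    next_label = 0
    for i, pid in enumerate(order):
        ind = ped.get(pid)
        m = pos[ind.momID] if ind.momID in pos else None
        d = pos[ind.dadID] if ind.dadID in pos else None
        if m is None and d is None:
            a[i, 0, :] = next_label
            a[i, 1, :] = next_label + 1
            next_label += 2
        else:
            if m is not None:
                pick = rng.integers(0, 2, n_replicates)
                a[i, 0, :] = a[m, pick, np.arange(n_replicates)]
            else:
                a[i, 0, :] = next_label
                next_label += 1
            if d is not None:
                pick = rng.integers(0, 2, n_replicates)
                a[i, 1, :] = a[d, pick, np.arange(n_replicates)]
            else:
                a[i, 1, :] = next_label
                next_label += 1

    phi_hat = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                ibd = 0.5 * (1.0 + (a[i, 0] == a[i, 1]))
            else:
                ibd = 0.25 * (
                    (a[i, 0] == a[j, 0]).astype(np.float64)
                    + (a[i, 0] == a[j, 1])
                    + (a[i, 1] == a[j, 0])
                    + (a[i, 1] == a[j, 1])
                )
            phi_hat[i, j] = phi_hat[j, i] = ibd.mean()
            se[i, j] = se[j, i] = ibd.std(ddof=1) / np.sqrt(n_replicates)

    perm = [pos[pid] for pid in ped.ids]
    return list(ped.ids), phi_hat[np.ix_(perm, perm)], se[np.ix_(perm, perm)]
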