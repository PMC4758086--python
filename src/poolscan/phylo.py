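"""Population trees from allele-frequency genetic distances.

Distances between populations are computed from per-SNP alternate-allele
frequencies (biallelic loci, pairwise-complete over loci):

- Nei's Da:  Da(i,j) = 1 - (1/L) * sum over loci of
  [sqrt(p_i p_j) + sqrt(q_i q_j)], bounded in [0, 1] and robust for closely
  related populations (the default);
- Nei's standard D:  D(i,j) = -ln( J_ij / sqrt(J_ii J_jj) ) with J the mean
  over loci of the summed allele-frequency products.

Trees are built by canonical neighbor-joining: Q-criterion agglomeration
with the standard branch-length formulas.  On an additive (tree-like) input
matrix the output path lengths reproduce the input exactly.  Negative
branch lengths are clamped to zero (counted, logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .diversity import FrequencyTable

logger = logging.getLogger("poolscan")


@dataclass
class DistanceMatrix:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.names = tuple(self.names)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match names")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)


@dataclass
class PopulationTree:
    tree: dendropy.Tree
    n_clamped: int = 0  # negative NJ branch lengths clamped to zero

    def leaf_names(self) -> set[str]:
        return {l.taxon.label for l in self.tree.leaf_node_iter()}

    def path_length(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        ta = self.tree.taxon_namespace.get_taxon(a)
        tb = self.tree.taxon_namespace.get_taxon(b)
        return pdm.distance(ta, tb)


def nei_distance(freqs: FrequencyTable, measure: str = "Da") -> DistanceMatrix:
    """Genetic distance matrix between populations from allele frequencies.

    Loci with a missing frequency in either population of a pair are
    excluded pairwise; a pair with zero usable loci is an error.
    """
    if measure not in ("Da", "D_standard"):
        raise ValueError("measure must be 'Da' or 'D_standard'")
    names = freqs.pop_names
    if len(names) < 2:
        raise ValueError("need >= 2 populations")
    P = freqs.freq_matrix()  # alt freq
    Q = 1.0 - P
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(P[i]) | np.isnan(P[j]))
            if not ok.any():
                raise ValueError(
                    f"no usable loci for pair ({names[i]}, {names[j]})"
                )
            pi, pj, qi, qj = P[i][ok], P[j][ok], Q[i][ok], Q[j][ok]
            if measure == "Da":
                d = 1.0 - np.mean(np.sqrt(pi * pj) + np.sqrt(qi * qj))
            else:
                jij = np.mean(pi * pj + qi * qj)
                jii = np.mean(pi**2 + qi**2)
                jjj = np.mean(pj**2 + qj**2)
                d = -np.log(jij / np.sqrt(jii * jjj))
            D[i, j] = D[j, i] = max(d, 0.0)
    return DistanceMatrix(D, tuple(names))


def neighbor_joining(D: DistanceMatrix) -> PopulationTree:
    """Canonical neighbor-joining tree from a distance matrix.

    Ties in the Q criterion are broken by lexicographic pair order (on each
    node's smallest descendant leaf name).  Negative branch lengths are
    clamped to zero after construction.
    """
    n = len(D.names)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    # each active node: (tiebreak label, newick fragment without outer length)
    labels = list(D.names)
    frags = [_quote(name) for name in D.names]
    d = D.values.astype(float).copy()
    active = list(range(n))
    n_clamped = 0

    def fmt(length: float) -> tuple[str, int]:
        clamped = 1 if length < 0 else 0
        return f"{max(length, 0.0):.10g}", clamped

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                if q[ai, aj] <= qmin + 1e-12:
                    key = tuple(sorted((labels[active[ai]], labels[active[aj]])))
                    if best is None or key < best[0]:
                        best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        si, ci = fmt(li)
        sj, cj = fmt(lj)
        n_clamped += ci + cj
        # new node
        new_frag = f"({frags[i]}:{si},{frags[j]}:{sj})"
        new_label = min(labels[i], labels[j])
        new_d = 0.5 * (d[i, [a for a in active]] + d[j, [a for a in active]] - dij)
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for idx, a in enumerate(active):
            d[k, a] = d[a, k] = new_d[idx]
        d[k, k] = 0.0
        frags.append(new_frag)
        labels.append(new_label)
        active = [a for a in active if a not in (i, j)] + [k]

    if len(active) == 2:
        i, j = active
        half, c = fmt(d[i, j] / 2.0)
        n_clamped += 2 * c
        newick = f"({frags[i]}:{half},{frags[j]}:{half});"
    else:
        i, j, k = active
        dij, dik, djk = d[i, j], d[i, k], d[j, k]
        li = 0.5 * (dij + dik - djk)
        lj = 0.5 * (dij + djk - dik)
        lk = 0.5 * (dik + djk - dij)
        parts = []
        for node, length in ((i, li), (j, lj), (k, lk)):
            s, c = fmt(length)
            n_clamped += c
            parts.append(f"{frags[node]}:{s}")
        newick = f"({','.join(parts)});"

    if n_clamped:
        logger.warning("neighbor joining clamped %d negative branch lengths", n_clamped)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return PopulationTree(tree=tree, n_clamped=n_clamped)


def _quote(name: str) -> str:
    if any(c in name for c in "(),:;[] '\t"):
        return "'" + name.replace("'", "''") + "'"
    return name
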