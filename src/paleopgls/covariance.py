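"""Among-tip trait covariance structures under BM, Pagel's lambda, and OU.

For tips i, j on a rooted, calibrated (generally non-ultrametric) tree:

* Brownian motion: ``V[i, j] = s_ij``, the root-to-MRCA path length; the
  diagonal is the root-to-tip depth.
* Pagel's lambda: the BM matrix with off-diagonal entries multiplied by
  ``lambda`` in [0, 1] (0 = star phylogeny, 1 = pure BM).
* Ornstein-Uhlenbeck with attraction strength ``alpha``, stationary at the
  root: ``V[i, j] = exp(-alpha * d_ij) * (1 - exp(-2 * alpha * s_ij)) /
  (2 * alpha)`` with d_ij the patristic distance. As alpha -> 0 this
  converges to the BM matrix entrywise.

All matrices are defined up to the regression's profiled scale sigma^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PhyloCovariance",
    "tree_depths",
    "bm_covariance",
    "lambda_transform",
    "ou_covariance",
]


@dataclass(frozen=True)
class PhyloCovariance:
    """A tip-ordered covariance matrix with its model tag and parameter."""

    tip_order: tuple[str, ...]
    matrix: np.ndarray  # (n, n), symmetric PSD
    model: str  # "BM", "lambda", or "OU"
    parameter: float | None = None  # lambda or alpha

    @property
    def n(self) -> int:
        return len(self.tip_order)

    def assert_positive_definite(self, rtol: float = 1e-10) -> None:
        """Raise LinAlgError if the matrix is not numerically positive
        definite (smallest eigenvalue <= rtol * largest)."""
        np.linalg.cholesky(self.matrix)
        w = np.linalg.eigvalsh(self.matrix)
        if w[0] <= rtol * w[-1]:
            raise np.linalg.LinAlgError(
                f"covariance matrix is numerically singular "
                f"(eigenvalue ratio {w[0] / w[-1]:.3e})"
            )


def tree_depths(tree: dendropy.Tree):
    """Tip labels, root-to-tip depths t, and root-to-MRCA depth matrix S.

    The root's own (seed) edge is ignored. S[i, i] = t[i].
    """
    labels: list[str] = []
    index: dict[int, int] = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            raise ValueError("tree has an unlabeled tip")
        index[id(leaf)] = len(labels)
        labels.append(leaf.taxon.label)
    n = len(labels)
    if len(set(labels)) != n:
        raise ValueError("tip labels are not unique")

    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            length = node.edge.length or 0.0
            if length < -1e-12:
                raise ValueError("negative branch length")
            depth[id(node)] = depth[id(node.parent_node)] + length

    S = np.zeros((n, n))
    # postorder: below[node] = tip indices; tips in different child subtrees
    # have this node as MRCA, at this node's depth
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = [i]
            S[i, i] = depth[id(node)]
            continue
        groups = [below.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i in groups[gi]:
                    for j in groups[gj]:
                        S[i, j] = S[j, i] = d
        below[id(node)] = [i for g in groups for i in g]
    return labels, np.diag(S).copy(), S


def bm_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Shared-path-length (Brownian motion) covariance of a rooted tree."""
    if tree.seed_node is None:
        raise ValueError("tree has no root")
    labels, _, S = tree_depths(tree)
    return PhyloCovariance(tuple(labels), S, model="BM")


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal entries of a BM covariance by lambda."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = cov.matrix * lam
    np.fill_diagonal(V, np.diag(cov.matrix))
    return PhyloCovariance(cov.tip_order, V, model="lambda", parameter=float(lam))


def ou_covariance(tree: dendropy.Tree, alpha: float) -> PhyloCovariance:
    """Ornstein-Uhlenbeck covariance, stationary at the root.

    Valid on non-ultrametric (fossil) trees; tips decorrelate with
    patristic distance at rate alpha (per My).
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    labels, t, S = tree_depths(tree)
    D = t[:, None] + t[None, :] - 2.0 * S  # patristic distances
    V = np.exp(-alpha * D) * (1.0 - np.exp(-2.0 * alpha * S)) / (2.0 * alpha)
    return PhyloCovariance(tuple(labels), V, model="OU", parameter=float(alpha))
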