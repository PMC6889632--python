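"""Fossil tree ensembles: polytomy resolution, time calibration, conspecific tips.

Base topologies are informal supertrees read from Newick, typically with
polytomies and no branch lengths. An ensemble tree is produced by

1. stochastically dichotomizing every polytomy, uniformly at random over
   the (2k-3)!! rooted binary resolutions of each degree-k polytomy;
2. time-calibrating branch lengths from stratigraphic tip age ranges under
   a birth-death-sampling model: each tip age is drawn uniformly in its
   range and each node age is the oldest descendant age plus an exponential
   offset with rate (b + mu + psi), the sum of the birth, extinction and
   fossil-sampling rates;
3. adding a constant (default 1 My) to every branch so that zero-length
   branches from the resolution step do not erase node structure;
4. replacing each species tip that has multiple specimens with a polytomy
   of (near) zero-length specimen tips, so conspecifics share maximal
   evolutionary history and carry minimal independent weight.

Trees are ``dendropy.Tree`` objects with branch lengths in My; node ages
(Ma, time before present) are stored on ``node.age`` by the calibrator.
A "uniform" calibration mode that sets every branch length to 1 is provided
as a branch-length-agnostic null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import dendropy
import numpy as np

__all__ = [
    "CalibrationParams",
    "CalibrationError",
    "parse_newick",
    "write_newick",
    "resolve_polytomies",
    "calibrate_tree",
    "expand_conspecific_tips",
    "generate_tree_ensemble",
    "tip_labels",
]


class CalibrationError(ValueError):
    """A tip lacks usable age information or a rate is invalid."""


@dataclass(frozen=True)
class CalibrationParams:
    """Rates (per lineage-My) and options for stochastic time calibration.

    The combined rate b + mu + psi governs the exponential node-age offsets.
    ``from_sampling_rate`` builds the parameter set under the assumption that
    the birth (diversification) rate equals the extinction rate, with both
    estimated from the fossil sampling rate.
    """

    sampling_rate: float  # psi
    extinction_rate: float  # mu
    birth_rate: float  # b
    branch_constant: float = 1.0  # My added to every branch after calibration
    mode: str = "stochastic"  # or "uniform"

    def __post_init__(self) -> None:
        if self.mode not in ("stochastic", "uniform"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        if self.mode == "stochastic":
            for name in ("sampling_rate", "extinction_rate", "birth_rate"):
                if not getattr(self, name) > 0:
                    raise CalibrationError(
                        f"{name} must be > 0 in stochastic mode"
                    )

    @property
    def total_rate(self) -> float:
        return self.birth_rate + self.extinction_rate + self.sampling_rate

    @classmethod
    def from_sampling_rate(cls, psi: float, **kwargs) -> "CalibrationParams":
        """Extinction = diversification = psi (extinct-clade assumption)."""
        return cls(sampling_rate=psi, extinction_rate=psi, birth_rate=psi, **kwargs)


def parse_newick(text: str) -> dendropy.Tree:
    """Parse one Newick string into a rooted tree (polytomies allowed)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _resolve_node(tree: dendropy.Tree, node: dendropy.Node,
                  rng: np.random.Generator) -> None:
    """Replace one polytomy by a uniformly random binary resolution.

    Builds a rooted binary tree over the child subtrees by sequential
    uniform edge insertion (root edge included): after j subtrees the tree
    has 2j-1 insertion points, so each of the (2k-3)!! resolutions arises
    from exactly one insertion sequence and is equally likely.
    """
    children = list(node.child_nodes())
    for ch in children:
        node.remove_child(ch)

    root = children[0]
    edges = [root]  # nodes whose parent-edge is an insertion point
    for child in children[1:]:
        pick = edges[int(rng.integers(len(edges)))]
        joint = dendropy.Node()
        joint.edge.length = 0.0
        if pick is root:
            root = joint
        else:
            parent = pick.parent_node
            parent.remove_child(pick)
            parent.add_child(joint)
        joint.add_child(pick)
        joint.add_child(child)
        edges.append(joint)
        edges.append(child)
    # the top join is always a fresh internal node (k >= 3): graft its two
    # subtrees directly onto the original polytomy node
    for ch in list(root.child_nodes()):
        root.remove_child(ch)
        node.add_child(ch)


def resolve_polytomies(tree: dendropy.Tree,
                       rng: np.random.Generator) -> dendropy.Tree:
    """Return a copy of ``tree`` with every polytomy randomly dichotomized.

    The tip set and every input bipartition are preserved; new internal
    branches have length 0 (calibration assigns real durations later).
    Binary input is returned (as a copy) unchanged.
    """
    out = tree.clone(depth=1)
    for node in list(out.preorder_node_iter()):
        if len(node.child_nodes()) > 2:
            _resolve_node(out, node, rng)
    return out


def _fallback_range(leaf, ranges, all_ranges):
    """Sister-taxon pooled range, else the whole-tree range."""
    parent = leaf.parent_node
    while parent is not None:
        sisters = [
            t.taxon.label
            for t in parent.leaf_iter()
            if t is not leaf and t.taxon.label in ranges
        ]
        if sisters:
            los, his = zip(*(ranges[s] for s in sisters))
            return (min(los), max(his))
        parent = parent.parent_node
    if not all_ranges:
        raise CalibrationError(
            f"no age range for tip {leaf.taxon.label!r} and no other tip "
            "has one to fall back on"
        )
    los, his = zip(*all_ranges)
    return (min(los), max(his))


def calibrate_tree(
    tree: dendropy.Tree,
    tip_age_ranges: dict[str, tuple[float, float]],
    params: CalibrationParams,
    rng: np.random.Generator,
    allow_age_fallback: bool = True,
) -> dendropy.Tree:
    """Assign node ages and branch lengths from fossil age ranges.

    Tip ages are drawn uniformly in their stratigraphic range; each internal
    node age is the maximum descendant age plus an Exp(b + mu + psi) offset;
    branch lengths are age differences, and ``branch_constant`` is then added
    to every branch. In ``uniform`` mode every branch length is simply 1.
    Topology is never modified. Returns a calibrated copy.
    """
    out = tree.clone(depth=1)
    if params.mode == "uniform":
        for edge in out.preorder_edge_iter():
            if edge.head_node is not out.seed_node:
                edge.length = 1.0
        _set_ages_from_lengths(out)
        return out

    rate = params.total_rate
    known = list(tip_age_ranges.values())
    for node in out.postorder_node_iter():
        if node.is_leaf():
            if node.taxon is None:
                raise CalibrationError("unlabeled tip cannot be calibrated")
            label = node.taxon.label
            if label in tip_age_ranges:
                lo, hi = tip_age_ranges[label]
            elif allow_age_fallback:
                lo, hi = _fallback_range(node, tip_age_ranges, known)
            else:
                raise CalibrationError(f"no age range for tip {label!r}")
            if hi < lo:
                raise CalibrationError(
                    f"tip {label!r}: age_max {hi} < age_min {lo}"
                )
            node.age = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        else:
            oldest = max(ch.age for ch in node.child_nodes())
            node.age = oldest + float(rng.exponential(1.0 / rate))
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = (
                node.parent_node.age - node.age + params.branch_constant
            )
    return out


def _set_ages_from_lengths(tree: dendropy.Tree) -> None:
    """Recompute node.age from branch lengths (root = deepest path)."""
    tree.seed_node.depth = 0.0
    max_depth = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.depth = node.parent_node.depth + (node.edge.length or 0.0)
            max_depth = max(max_depth, node.depth)
    for node in tree.preorder_node_iter():
        node.age = max_depth - node.depth


def expand_conspecific_tips(
    tree: dendropy.Tree,
    species_to_specimens: dict[str, list[str]],
    epsilon: float = 1e-6,
) -> dendropy.Tree:
    """Replace multi-specimen species tips by polytomies of specimen tips.

    Each new specimen branch has length ``epsilon`` (0 gives the exact
    zero-length construction, at the cost of a singular trait covariance
    when the phylogenetic signal is saturated). Species with one specimen
    have their tip relabeled to the specimen id. Species in the map but
    absent from the tree raise a mapping error.
    """
    out = tree.clone(depth=1)
    present = set(tip_labels(out))
    missing = set(species_to_specimens) - present
    if missing:
        raise KeyError(
            f"specimens mapped to species absent from tree: {sorted(missing)}"
        )
    ns = out.taxon_namespace
    for leaf in list(out.leaf_node_iter()):
        label = leaf.taxon.label
        if label not in species_to_specimens:
            continue
        specimens = species_to_specimens[label]
        if len(specimens) == 1:
            leaf.taxon = ns.require_taxon(label=specimens[0])
            continue
        age = getattr(leaf, "age", 0.0)
        leaf.taxon = None
        for spec_id in specimens:
            child = dendropy.Node(taxon=ns.require_taxon(label=spec_id))
            child.edge.length = float(epsilon)
            child.age = age
            leaf.add_child(child)
    return out


def generate_tree_ensemble(
    base_topologies: list[dendropy.Tree],
    n_per_topology: int,
    tip_age_ranges: dict[str, tuple[float, float]],
    params: CalibrationParams,
    seed: int,
    species_to_specimens: dict[str, list[str]] | None = None,
    epsilon: float = 1e-6,
) -> Iterator[tuple[int, dendropy.Tree]]:
    """Yield (topology_index, tree) pairs, ``n_per_topology`` per topology.

    Each tree is independently resolved and calibrated; the stream is
    deterministic given ``seed`` (each tree gets its own child generator
    keyed by topology and replicate index).
    """
    if n_per_topology < 1:
        raise ValueError("n_per_topology must be >= 1")
    for topo_idx, base in enumerate(base_topologies):
        for rep in range(n_per_topology):
            rng = np.random.default_rng([seed, topo_idx, rep])
            tree = resolve_polytomies(base, rng)
            tree = calibrate_tree(tree, tip_age_ranges, params, rng)
            if species_to_specimens is not None:
                tree = expand_conspecific_tips(
                    tree, species_to_specimens, epsilon=epsilon
                )
            yield topo_idx, tree
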