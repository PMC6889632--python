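"""Synthetic fossil datasets with known allometric truth.

The generator is the testing twin of the analysis: it produces a
clade-structured fossil tree with polytomies, stratigraphic age ranges per
tip, conspecific specimen groups, and bivariate log-scale limb traits
generated under the same covariance families the regression fits (BM,
Pagel's lambda, OU), with a known slope, intercept and signal parameter.
Named subclades can be given intercept/slope offsets to create deviating
allometric trends for the PANCOVA machinery to detect.

Default scales mirror a theropod-like study system: ~110 species sampled
between 230 and 66 Ma, ~1.5 specimens per species, log10 femur lengths a
few hundred mm, mild negative allometry (b0 = 0.9) with strong
phylogenetic signal (lambda0 = 0.93).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .covariance import bm_covariance, lambda_transform, ou_covariance
from .specimens import SpecimenRecord, write_measurements
from .trees import write_newick

__all__ = [
    "CladeEffect",
    "SimulationConfig",
    "simulate_birth_death_tree",
    "simulate_traits",
    "select_clade",
    "inject_polytomies",
    "make_synthetic_dataset",
    "SyntheticDataset",
]


@dataclass(frozen=True)
class CladeEffect:
    """A subclade whose allometry deviates from the background trend."""

    name: str
    delta_intercept: float = 0.0
    delta_slope: float = 0.0
    n_tips: int = 20  # target clade size; nearest subtree is used


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study system (see module docstring)."""

    n_species: int = 110
    birth_rate: float = 0.08  # per lineage-My
    death_rate: float = 0.05
    root_age_ma: float = 230.0
    youngest_age_ma: float = 66.0
    age_slack_my: float = 2.0  # uniform +/- slack on true tip ages
    multi_specimen_fraction: float = 0.25
    specimens_per_multi: int = 3
    intercept: float = 0.05  # a0
    slope: float = 0.9  # b0 (negative allometry)
    signal_model: str = "lambda"  # "lambda" or "ou"
    signal: float = 0.93  # lambda0 in [0,1] or alpha0 > 0
    residual_scale: float = 0.06  # sigma0, log10 units (V normalized)
    bm_sigma2: float = 0.0015  # per-My rate of the log FL random walk
    log_fl_root: float = 2.2  # ~160 mm femur at the root
    intra_fl_sd: float = 0.04  # log10 spread of conspecific sizes
    intra_hl_sd: float = 0.015  # individual scatter of HL around the line
    measurement_sd: float = 0.0  # extra iid noise on HL; off by default
    juvenile_fraction: float = 0.5  # of non-largest conspecifics
    polytomy_fraction: float = 0.25  # internal branches collapsed
    clade_effects: tuple[CladeEffect, ...] = ()
    n_null_clades: int = 3  # labeled clades with no effect
    null_clade_size: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.signal_model == "lambda" and not 0 <= self.signal <= 1:
            raise ValueError("lambda0 must be in [0, 1]")
        if self.signal_model == "ou" and not self.signal > 0:
            raise ValueError("alpha0 must be > 0")
        if not self.residual_scale >= 0:
            raise ValueError("residual scale must be >= 0")


def simulate_birth_death_tree(
    config: SimulationConfig,
    rng: np.random.Generator,
    max_tries: int = 500,
) -> dendropy.Tree:
    """Forward birth-death simulation keeping extinct (fossil) tips.

    Runs from a single root lineage for root_age - youngest_age My;
    extinct lineages become fossil tips, survivors are tips at the end of
    the window. If more than ``n_species`` tips arise, a uniform random
    subset of exactly ``n_species`` is kept; if the clade dies out or stays
    too small the simulation retries up to ``max_tries`` times.

    Tips carry ``node.age`` (Ma) and ``node.true_age_range``.
    """
    duration = config.root_age_ma - config.youngest_age_ma
    if duration <= 0:
        raise ValueError("root age must exceed the youngest sampled age")
    cap = max(4 * config.n_species, 64)
    for _ in range(max_tries):
        tree = _one_bd_run(config, rng, duration, cap)
        if tree is not None:
            return tree
    raise RuntimeError(
        f"birth-death clade died before reaching {config.n_species} tips "
        f"in {max_tries} tries; increase birth rate or root age"
    )


def _one_bd_run(config, rng, duration, cap):
    b, d = config.birth_rate, config.death_rate
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    root.birth_time = 0.0
    active = [root]
    done: list[tuple[dendropy.Node, float]] = []
    t = 0.0
    while active and len(active) + len(done) <= cap:
        total = len(active) * (b + d)
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        node = active.pop(int(rng.integers(len(active))))
        if rng.random() < b / (b + d):
            for _ in range(2):
                child = dendropy.Node()
                child.birth_time = t
                node.add_child(child)
                active.append(child)
            node.death_time = t
        else:
            done.append((node, t))
    for node in active:
        done.append((node, duration))

    tips = [nd for nd, _ in done if nd.is_leaf()]
    if len(tips) < config.n_species:
        return None
    # assign branch lengths and ages
    for node, end in done:
        node.end_time = end
    for node in tree.preorder_node_iter():
        end = getattr(node, "death_time", getattr(node, "end_time", None))
        if end is None:  # internal node created but never split? impossible
            end = duration
        if node.parent_node is not None:
            node.edge.length = end - node.birth_time
        node.age = config.root_age_ma - end

    keep = set(int(k) for k in
               rng.choice(len(tips), size=config.n_species, replace=False))
    labels = []
    counter = 0
    for k, tip in enumerate(tips):
        if k in keep:
            counter += 1
            label = f"sp{counter:03d}"
            labels.append(label)
        else:
            label = f"unsampled{k}"  # pruned below; extraction needs a taxon
        tip.taxon = ns.require_taxon(label=label)
    ages = {tip.taxon.label: tip.age for tip in tips if tip.taxon is not None}
    out = tree.extract_tree_with_taxa_labels(labels=labels)
    for leaf in out.leaf_node_iter():
        age = ages[leaf.taxon.label]
        lo = max(0.0, age - rng.uniform(0, config.age_slack_my))
        hi = age + rng.uniform(0, config.age_slack_my)
        leaf.age = age
        leaf.true_age_range = (lo, hi)
    return out


def select_clade(tree: dendropy.Tree, n_tips: int,
                 exclude: set[str] = frozenset()) -> set[str]:
    """Tip labels of the internal subtree whose size is closest to n_tips.

    Subtrees overlapping ``exclude`` or covering (almost) the whole tree
    are not considered.
    """
    total = len(tree.leaf_nodes())
    best, best_cost = None, None
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        tips = {leaf.taxon.label for leaf in node.leaf_iter()}
        if tips & exclude or len(tips) > 0.6 * total or len(tips) < 2:
            continue
        cost = abs(len(tips) - n_tips)
        if best_cost is None or cost < best_cost:
            best, best_cost = tips, cost
    if best is None:
        raise ValueError("no eligible subtree for a clade of that size")
    return best


def _simulate_bm(tree, rng, sigma2, root_value):
    values = {id(tree.seed_node): root_value}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = max(node.edge.length or 0.0, 0.0)
        values[id(node)] = values[id(node.parent_node)] + rng.normal(
            0.0, np.sqrt(sigma2 * bl)
        )
    return {
        leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()
    }


def simulate_traits(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator,
    clade_members: dict[str, set[str]] | None = None,
) -> dict[str, tuple[float, float]]:
    """Simulate (log_fl, log_hl) per tip of a calibrated tree.

    log FL evolves by Brownian motion; residuals e are multivariate normal
    with covariance sigma0^2 * V where V is the lambda- or alpha-structured
    covariance of the tree (normalized to unit mean diagonal so sigma0 is
    in trait units); log HL = a0 + b0 * log_fl + e, with clade offsets
    applied to (a0, b0) for tips of flagged clades.
    """
    log_fl = _simulate_bm(tree, rng, config.bm_sigma2, config.log_fl_root)
    labels = list(log_fl)

    bm = bm_covariance(tree)
    if config.signal_model == "ou":
        cov = ou_covariance(tree, config.signal)
    else:
        cov = lambda_transform(bm, config.signal)
    order = list(cov.tip_order)
    V = cov.matrix.copy()
    scale = np.mean(np.diag(V))
    if scale > 0:
        V = V / scale
    if config.residual_scale > 0:
        L = np.linalg.cholesky(V + 1e-12 * np.eye(len(order)))
        e = config.residual_scale * (L @ rng.standard_normal(len(order)))
    else:
        e = np.zeros(len(order))
    resid = dict(zip(order, e))

    effects = {}
    if clade_members:
        for eff in config.clade_effects:
            for tip in clade_members.get(eff.name, ()):
                effects[tip] = eff

    out = {}
    for tip in labels:
        a, b = config.intercept, config.slope
        if tip in effects:
            a += effects[tip].delta_intercept
            b += effects[tip].delta_slope
        hl = a + b * log_fl[tip] + resid[tip]
        if config.measurement_sd > 0:
            hl += rng.normal(0.0, config.measurement_sd)
        out[tip] = (log_fl[tip], hl)
    return out


def inject_polytomies(tree: dendropy.Tree, fraction: float,
                      rng: np.random.Generator) -> dendropy.Tree:
    """Collapse a random fraction of internal branches into polytomies."""
    out = tree.clone(depth=1)
    internal = [
        nd for nd in out.preorder_internal_node_iter()
        if nd.parent_node is not None
    ]
    k = int(round(fraction * len(internal)))
    if k:
        chosen = rng.choice(len(internal), size=k, replace=False)
        for i in chosen:
            internal[i].edge.collapse()
    return out


@dataclass
class SyntheticDataset:
    """In-memory bundle plus (optionally) the files a real study would ship."""

    records: list[SpecimenRecord]
    base_topology: dendropy.Tree  # species-level, with polytomies, no lengths
    species_tree: dendropy.Tree  # the true calibrated tree
    age_ranges: dict[str, tuple[float, float]]
    clade_members: dict[str, set[str]]
    truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


def make_synthetic_dataset(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
) -> SyntheticDataset:
    """Generate a full synthetic study: tree, ages, specimens, truth.

    Writes (when ``out_dir`` is given) exactly the formats the analysis
    consumes — measurements.csv, topology.nwk, ages.csv — plus truth.json
    recording every generative parameter.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_birth_death_tree(config, rng)

    clade_members: dict[str, set[str]] = {}
    used: set[str] = set()
    for eff in config.clade_effects:
        tips = select_clade(tree, eff.n_tips, exclude=used)
        clade_members[eff.name] = tips
        used |= tips
    for i in range(config.n_null_clades):
        try:
            tips = select_clade(tree, config.null_clade_size, exclude=used)
        except ValueError:
            break
        clade_members[f"nullclade{i + 1}"] = tips
        used |= tips

    traits = simulate_traits(tree, config, rng, clade_members)
    age_ranges = {
        leaf.taxon.label: leaf.true_age_range for leaf in tree.leaf_node_iter()
    }

    species = sorted(traits)
    n_multi = int(round(config.multi_specimen_fraction * len(species)))
    multi = set(
        rng.choice(species, size=n_multi, replace=False)
    ) if n_multi else set()

    effect_by_name = {e.name: e for e in config.clade_effects}
    records: list[SpecimenRecord] = []
    for si, sp in enumerate(species):
        labels = frozenset(c for c, tips in clade_members.items() if sp in tips)
        lo, hi = age_ranges[sp]
        genus = f"gen{si + 1:03d}"
        fl0, hl0 = traits[sp]
        # conspecific (ontogenetic) growth follows the species' own
        # allometric slope, including any clade offset
        slope_sp = config.slope + sum(
            effect_by_name[c].delta_slope
            for c in labels if c in effect_by_name
        )
        k = config.specimens_per_multi if sp in multi else 1
        offsets = np.sort(rng.normal(0.0, config.intra_fl_sd, size=k))
        for j, off in enumerate(offsets[::-1]):  # largest first
            fl = fl0 + off
            hl = hl0 + slope_sp * off
            if j > 0 and config.intra_hl_sd > 0:
                # individual scatter keeps conspecific contrasts from being
                # exactly collinear (which would pin the GLS fit)
                hl += rng.normal(0.0, config.intra_hl_sd)
            if sp in multi and j > 0:
                status = "juvenile" if rng.random() < config.juvenile_fraction \
                    else "subadult"
            else:
                status = "adult"
            records.append(SpecimenRecord(
                specimen_id=f"{sp}_{j + 1}",
                species=sp,
                genus=genus,
                clade_labels=labels,
                fl_mm=float(10.0 ** fl),
                hl_mm=float(10.0 ** hl),
                age_min_ma=lo,
                age_max_ma=hi,
                onto_status=status,
            ))

    base = inject_polytomies(tree, config.polytomy_fraction, rng)
    for edge in base.preorder_edge_iter():
        edge.length = None  # base topologies carry no branch lengths

    truth = {
        "intercept": config.intercept,
        "slope": config.slope,
        "signal_model": config.signal_model,
        "signal": config.signal,
        "residual_scale": config.residual_scale,
        "n_species": len(species),
        "n_specimens": len(records),
        "clade_effects": [asdict(e) for e in config.clade_effects],
        "clade_members": {c: sorted(t) for c, t in clade_members.items()},
        "seed": config.seed,
    }

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths["measurements"] = out_dir / "measurements.csv"
        write_measurements(records, paths["measurements"])
        paths["topology"] = out_dir / "topology.nwk"
        paths["topology"].write_text(write_newick(base) + "\n")
        paths["ages"] = out_dir / "ages.csv"
        with open(paths["ages"], "w") as fh:
            fh.write("tip,age_min_ma,age_max_ma\n")
            for tip, (lo, hi) in sorted(age_ranges.items()):
                fh.write(f"{tip},{lo},{hi}\n")
        paths["truth"] = out_dir / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=2))

    return SyntheticDataset(
        records=records, base_topology=base, species_tree=tree,
        age_ranges=age_ranges, clade_members=clade_members, truth=truth,
        paths=paths,
    )
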