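"""Phylogenetic ANCOVA: which subclades deviate from the main allometry?

For a candidate clade, two nested generalized least-squares models are
compared under a common phylogenetic covariance V:

    null:  log HL ~ 1 + log FL
    full:  log HL ~ 1 + log FL + clade + clade : log FL

The F statistic ((RSS0 - RSS1)/q) / (RSS1/(n - p1)) is computed in the
whitened space, with q = 2 for the joint intercept-and-slope test (the
default; intercept-only and slope-only variants are available). Testing is
repeated over a subset of trees per topology; the per-tree p-values are
dependent (they reuse the same specimens), so they are combined with a
dependence-corrected Stouffer rule,

    zbar = sum(z_i) / sqrt(m + m (m - 1) rho),

where rho is the mean pairwise correlation of the z-scores across trees
(1 = perfectly dependent tests add no evidence). A clade "consistently"
deviates when its pooled p-value is below the threshold in every topology;
such clades are removed and the procedure is iterated until no clade is
newly excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .covariance import bm_covariance, lambda_transform, ou_covariance
from .pooling import pool_by_topology, pool_model_fits
from .regression import ModelFit, fit_pgls_bm_lambda, fit_pgls_ou

logger = logging.getLogger(__name__)

__all__ = [
    "DeviationTestResult",
    "pancova_f_test",
    "pool_dependent_pvalues",
    "estimate_z_correlation",
    "clade_deviation_tests",
    "iterative_exclusion",
    "per_clade_regressions",
]


@dataclass(frozen=True)
class DeviationTestResult:
    """PANCOVA outcome for one clade within one topology."""

    clade: str
    topology: int
    f_stats: tuple[float, ...]
    p_values: tuple[float, ...]
    pooled_p: float
    df_num: int
    df_den: int
    consistent: bool = False  # significant in ALL topologies (set later)


def _whiten(y, X, V):
    L = linalg.cholesky(np.asarray(V, dtype=float), lower=True)
    return (linalg.solve_triangular(L, y, lower=True),
            linalg.solve_triangular(L, X, lower=True))


def _rss(yw, Xw):
    beta, res, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < Xw.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient PANCOVA design")
    r = yw - Xw @ beta
    return float(r @ r)


def pancova_f_test(y, x, V, group, terms: str = "both"):
    """Nested GLS F test of a clade effect on the allometric line.

    ``group`` is a boolean membership indicator. ``terms`` selects the
    tested effect: "both" (intercept and slope, q = 2), "intercept", or
    "slope". Returns (F, p).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    g = np.asarray(group, dtype=float)
    n = len(y)
    n_in = int(g.sum())
    if n_in < 2 or n - n_in < 2:
        raise ValueError(
            f"clade must have >= 2 members and >= 2 non-members "
            f"(got {n_in} of {n})"
        )
    if V is None:
        V = np.eye(n)
    elif hasattr(V, "matrix"):
        V = V.matrix

    X0 = np.column_stack([np.ones(n), x])
    extra = {
        "both": [g, g * x],
        "intercept": [g],
        "slope": [g * x],
    }
    if terms not in extra:
        raise ValueError(f"unknown terms {terms!r}")
    X1 = np.column_stack([X0] + extra[terms])
    q = X1.shape[1] - X0.shape[1]
    df_den = n - X1.shape[1]
    if df_den < 1:
        raise ValueError("not enough observations for the full design")

    yw, X0w = _whiten(y, X0, V)
    _, X1w = _whiten(y, X1, V)
    rss0 = _rss(yw, X0w)
    rss1 = _rss(yw, X1w)
    zero = 1e-12 * max(float(yw @ yw), np.finfo(float).tiny)
    rss0 = 0.0 if rss0 <= zero else rss0
    rss1 = 0.0 if rss1 <= zero else rss1
    if rss1 <= 0:
        # saturated/noiseless full model: infinite F unless the reduction
        # is also zero, in which case there is no evidence at all
        if rss0 - rss1 <= 1e-14 * max(rss0, 1.0):
            return 0.0, 1.0
        return np.inf, 0.0
    f = ((rss0 - rss1) / q) / (rss1 / df_den)
    f = max(f, 0.0)  # guard tiny negative from roundoff
    p = float(stats.f.sf(f, q, df_den))
    return float(f), p


def pool_dependent_pvalues(pvals, rho: float = 0.5, method: str = "stouffer"):
    """Combine dependent one-sided p-values from repeated tree-wise tests.

    ``rho`` is the assumed/estimated mean pairwise correlation of the
    underlying z-scores, clipped to [0, 1]; rho = 1 reduces to the mean
    z (perfect dependence), rho = 0 to the classical Stouffer rule.
    ``method="harmonic"`` returns the harmonic mean p-value instead
    (rho is then ignored), as a sensitivity alternative.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to pool")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    tiny = np.finfo(float).tiny
    if np.any(p == 0):
        logger.warning("p-value of 0 clipped to smallest positive float")
        p = np.clip(p, tiny, 1.0)
    if method == "harmonic":
        return float(len(p) / np.sum(1.0 / p))
    if method != "stouffer":
        raise ValueError(f"unknown method {method!r}")
    rho = float(np.clip(rho, 0.0, 1.0))
    m = len(p)
    z = stats.norm.isf(p)
    denom = np.sqrt(m + m * (m - 1) * rho)
    return float(stats.norm.sf(z.sum() / denom))


def estimate_z_correlation(z_matrix) -> float:
    """Mean pairwise correlation between trees (columns), clipped to [0, 1].

    Rows are replicate test units (candidate clades); columns are trees.
    Needs >= 3 rows to be meaningful; otherwise returns nan.
    """
    Z = np.asarray(z_matrix, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 3 or Z.shape[1] < 2:
        return float("nan")
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(Z, rowvar=False)
    iu = np.triu_indices_from(C, k=1)
    vals = C[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(np.clip(vals.mean(), 0.0, 1.0))


def _records_frame(records):
    ids = [r.specimen_id for r in records]
    return (
        ids,
        np.array([r.log_fl for r in records]),
        np.array([r.log_hl for r in records]),
    )


def _prune(tree, keep_labels):
    sub = tree.extract_tree_with_taxa_labels(labels=keep_labels)
    return sub


def _null_covariance(tree, y, x, model, method):
    """Covariance for the PANCOVA fits: signal estimated once under the
    null model per tree and shared by both nested designs."""
    if model == "ols":
        return None
    if model == "ou":
        fits = fit_pgls_ou(y, x, tree, method=method)
        fit = fits[0]
        alpha = fit.signal if fit.converged and fit.signal else 1e-6
        return ou_covariance(tree, alpha)
    fits = fit_pgls_bm_lambda(y, x, tree=tree, method=method)
    fit = fits[0]
    lam = fit.signal if fit.converged and fit.signal is not None else 1.0
    return lambda_transform(bm_covariance(tree), lam)


def clade_deviation_tests(
    records,
    ensemble,
    clade_list,
    model: str = "bm_lambda",
    method: str = "reml",
    n_subset: int = 200,
    threshold: float = 0.05,
    terms: str = "both",
    rho: float | None = None,
    pool_method: str = "stouffer",
) -> list[DeviationTestResult]:
    """Run PANCOVA for every candidate clade over a tree subset per topology.

    ``ensemble`` is an iterable of (topology_index, tree) whose tips are the
    specimen ids of ``records``; the first ``n_subset`` trees per topology
    are used. When ``rho`` is None it is estimated from the z-score matrix
    across clades (falling back to 0.5 when too few clades). Clades lacking
    two members/non-members are skipped with a log message.
    """
    records = list(records)
    ids, x, y = _records_frame(records)
    keep = set(ids)
    membership = {
        c: np.array([c in r.clade_labels for r in records]) for c in clade_list
    }
    testable = [
        c for c in clade_list
        if 2 <= membership[c].sum() <= len(records) - 2
    ]
    for c in clade_list:
        if c not in testable:
            logger.info("clade %s skipped: too few members or non-members", c)
    if not testable:
        return []

    per_topo: dict[int, dict[str, list[tuple[float, float]]]] = {}
    counts: dict[int, int] = {}
    for topo, tree in ensemble:
        if counts.get(topo, 0) >= n_subset:
            continue
        counts[topo] = counts.get(topo, 0) + 1
        sub = _prune(tree, keep)
        order = [leaf.taxon.label for leaf in sub.leaf_node_iter()]
        pos = {sid: i for i, sid in enumerate(ids)}
        idx = np.array([pos[lab] for lab in order])
        yo, xo = y[idx], x[idx]
        V = _null_covariance(sub, yo, xo, model, method)
        slot = per_topo.setdefault(topo, {c: [] for c in testable})
        for c in testable:
            go = membership[c][idx]
            f, p = pancova_f_test(yo, xo, V, go, terms=terms)
            slot[c].append((f, p))

    results: list[DeviationTestResult] = []
    n = len(records)
    q = {"both": 2, "intercept": 1, "slope": 1}[terms]
    for topo, tests in sorted(per_topo.items()):
        if rho is None:
            Z = np.array([
                stats.norm.isf(np.clip([p for _, p in tests[c]],
                                       np.finfo(float).tiny, 1.0))
                for c in testable
            ])
            rho_t = estimate_z_correlation(Z)
            if not np.isfinite(rho_t):
                rho_t = 0.5
        else:
            rho_t = rho
        for c in testable:
            fs = tuple(f for f, _ in tests[c])
            ps = tuple(p for _, p in tests[c])
            pooled = pool_dependent_pvalues(ps, rho=rho_t, method=pool_method)
            results.append(DeviationTestResult(
                clade=c, topology=topo, f_stats=fs, p_values=ps,
                pooled_p=pooled, df_num=q, df_den=n - 2 - q,
            ))
    # mark consistency across topologies
    topos = sorted(per_topo)
    consistent = {
        c for c in testable
        if all(
            r.pooled_p < threshold
            for r in results if r.clade == c
        )
    }
    from dataclasses import replace

    return [
        replace(r, consistent=r.clade in consistent) for r in results
    ]


def iterative_exclusion(
    records,
    ensemble,
    clade_list,
    threshold: float = 0.05,
    model: str = "bm_lambda",
    method: str = "reml",
    n_subset: int = 200,
    terms: str = "both",
    rho: float | None = None,
    forced_exclusions=(),
    min_remaining: int = 10,
    refit: bool = True,
):
    """Iteratively exclude clades that consistently deviate from the trend.

    Each round tests every remaining candidate clade over the tree subset;
    clades with pooled p < threshold in *all* topologies are excluded and
    the next round starts from the reduced dataset. ``forced_exclusions``
    removes named specimens or clades up front (e.g. a single-specimen
    autapomorphic taxon that PANCOVA cannot test). Returns
    (kept_records, rounds_log, final_pools) where final_pools is the pooled
    main regression on the kept set over the whole ensemble (None when
    ``refit`` is False).
    """
    ensemble = list(ensemble)
    records = list(records)
    rounds: list[dict] = []

    forced = set(forced_exclusions)
    if forced:
        before = len(records)
        records = [
            r for r in records
            if r.specimen_id not in forced
            and r.species not in forced
            and not (r.clade_labels & forced)
        ]
        rounds.append({
            "round": 0,
            "excluded": sorted(forced),
            "reason": "forced manual exclusion",
            "n_removed": before - len(records),
        })

    candidates = list(clade_list)
    round_no = 0
    while True:
        if len(records) < min_remaining:
            raise RuntimeError(
                f"exclusion would leave {len(records)} specimens "
                f"(< {min_remaining}); aborting"
            )
        results = clade_deviation_tests(
            records, ensemble, candidates, model=model, method=method,
            n_subset=n_subset, threshold=threshold, terms=terms, rho=rho,
        )
        hits = sorted({r.clade for r in results if r.consistent})
        round_no += 1
        rounds.append({
            "round": round_no,
            "excluded": hits,
            "reason": f"pooled p < {threshold} in all topologies",
            "tests": results,
        })
        if not hits:
            break
        keep = [r for r in records if not (r.clade_labels & set(hits))]
        if len(keep) < min_remaining:
            raise RuntimeError(
                f"excluding {hits} would leave {len(keep)} specimens "
                f"(< {min_remaining}); aborting"
            )
        records = keep
        candidates = [c for c in candidates if c not in hits]

    final_pools = None
    if refit:
        ids = [r.specimen_id for r in records]
        y = np.array([r.log_hl for r in records])
        x = np.array([r.log_fl for r in records])
        pos = {sid: i for i, sid in enumerate(ids)}
        fits = []
        for topo, tree in ensemble:
            sub = _prune(tree, set(ids))
            order = [leaf.taxon.label for leaf in sub.leaf_node_iter()]
            idx = np.array([pos[lab] for lab in order])
            if model == "ou":
                fl = fit_pgls_ou(y[idx], x[idx], sub, method=method)
            elif model == "ols":
                from .regression import fit_ols

                fl = [fit_ols(y[idx], x[idx], method=method)]
            else:
                fl = fit_pgls_bm_lambda(y[idx], x[idx], tree=sub, method=method)
            for f in fl:
                fits.append((topo, f))
        final_pools = pool_by_topology(fits, include_nonconverged=True)
    return records, rounds, final_pools


def per_clade_regressions(
    records,
    ensemble,
    clade_list,
    model: str = "bm_lambda",
    method: str = "reml",
    min_n: int = 3,
) -> pd.DataFrame:
    """Pooled PGLS regression within each clade on its induced subtrees.

    Clades with fewer than ``min_n`` specimens are reported as skipped.
    Where signal estimation falls back, the fixed lambda = 1 and OLS
    (lambda = 0) rows are pooled and reported separately.
    """
    records = list(records)
    rows = []
    for clade in clade_list:
        members = [r for r in records if clade in r.clade_labels]
        if len(members) < min_n:
            rows.append({
                "clade": clade, "group": "skipped", "topology": None,
                "m": 0, "n": len(members), "intercept": np.nan,
                "slope": np.nan, "slope_ci_low": np.nan,
                "slope_ci_high": np.nan, "signal_mean": np.nan,
                "note": f"fewer than {min_n} specimens",
            })
            continue
        ids = [r.specimen_id for r in members]
        y = np.array([r.log_hl for r in members])
        x = np.array([r.log_fl for r in members])
        pos = {sid: i for i, sid in enumerate(ids)}
        grouped: dict[str, list[tuple[int, ModelFit]]] = {}
        for topo, tree in ensemble:
            sub = _prune(tree, set(ids))
            order = [leaf.taxon.label for leaf in sub.leaf_node_iter()]
            idx = np.array([pos[lab] for lab in order])
            if model == "ou":
                fits = fit_pgls_ou(y[idx], x[idx], sub, method=method)
            else:
                fits = fit_pgls_bm_lambda(y[idx], x[idx], tree=sub,
                                          method=method)
            for f in fits:
                if f.converged and not f.signal_fixed:
                    key = "estimated"
                elif f.model == "OLS":
                    key = "fixed_lambda_0"
                else:
                    key = "fixed_lambda_1"
                grouped.setdefault(key, []).append((topo, f))
        for key, fits in grouped.items():
            if len(fits) < 2:
                continue
            pooled = pool_model_fits([f for _, f in fits],
                                     include_nonconverged=True)
            s, a = pooled["slope"], pooled["intercept"]
            rows.append({
                "clade": clade, "group": key, "topology": "all",
                "m": pooled["m"], "n": len(members),
                "intercept": a.qbar, "slope": s.qbar,
                "slope_ci_low": s.ci[0], "slope_ci_high": s.ci[1],
                "signal_mean": pooled["signal_mean"], "note": "",
            })
    return pd.DataFrame(rows)
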