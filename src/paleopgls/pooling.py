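"""Pooling regression estimates across a tree ensemble by Rubin's rules.

Each calibrated tree is one plausible phylogenetic hypothesis; the per-tree
fits are treated as analyses of multiply-imputed data and pooled:

    Qbar = mean(Q_i)
    Wbar = mean(Var_i)                  (within-fit variance)
    B    = sample variance of Q_i       (between-fit variance)
    T    = Wbar + (1 + 1/m) * B         (total variance)
    df   = (m - 1) * (1 + Wbar / ((1 + 1/m) * B))^2

with a t-based confidence interval Qbar +/- t_df * sqrt(T). The signal
parameter (Pagel's lambda or OU alpha) is pooled as a simple mean. The
classic (large-m) Rubin degrees of freedom are the default; the
Barnard-Rubin small-sample correction is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regression import ModelFit

__all__ = ["PooledFit", "rubin_pool", "pool_model_fits", "pool_by_topology"]


class PoolingError(ValueError):
    pass


@dataclass(frozen=True)
class PooledFit:
    """Rubin-pooled estimate across an ensemble of fits."""

    m: int
    qbar: float
    wbar: float
    between: float
    total_var: float
    df: float
    ci: tuple[float, float]
    conf_level: float = 0.95
    signal_mean: float | None = None

    @property
    def se(self) -> float:
        return math.sqrt(self.total_var)


def rubin_pool(
    estimates,
    conf_level: float = 0.95,
    small_sample_df: bool = False,
    n_complete: int | None = None,
) -> PooledFit:
    """Pool (estimate, variance) pairs by Rubin's multiple-imputation rules.

    ``estimates`` is a sequence of (Q_i, Var_i). With all Q_i identical
    (B = 0) the total variance collapses to Wbar and df is infinite.
    ``small_sample_df`` applies the Barnard-Rubin correction, which needs
    ``n_complete`` (the per-fit sample size) to form the observed-data df.
    """
    est = list(estimates)
    m = len(est)
    if m < 2:
        raise PoolingError(f"need at least 2 fits to pool, got {m}")
    q = np.array([e[0] for e in est], dtype=float)
    w = np.array([e[1] for e in est], dtype=float)
    if np.any(w < 0):
        raise PoolingError("negative within-fit variance")
    qbar = float(q.mean())
    wbar = float(w.mean())
    b = float(q.var(ddof=1))
    t = wbar + (1.0 + 1.0 / m) * b

    if b == 0.0:
        df = math.inf
    else:
        r = (1.0 + 1.0 / m) * b / wbar if wbar > 0 else math.inf
        df = (m - 1) * (1.0 + 1.0 / r) ** 2 if math.isfinite(r) else float(m - 1)
        if small_sample_df:
            if n_complete is None:
                raise PoolingError("small_sample_df requires n_complete")
            # Barnard & Rubin (1999) adjusted df
            df_com = n_complete - 2
            frac = (1.0 + 1.0 / m) * b / t
            df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - frac)
            df = 1.0 / (1.0 / df + 1.0 / df_obs)

    tq = stats.t.ppf(0.5 + conf_level / 2.0, df) if math.isfinite(df) else \
        stats.norm.ppf(0.5 + conf_level / 2.0)
    half = float(tq) * math.sqrt(t)
    return PooledFit(
        m=m, qbar=qbar, wbar=wbar, between=b, total_var=float(t), df=float(df),
        ci=(qbar - half, qbar + half), conf_level=conf_level,
    )


def pool_model_fits(
    fits: list[ModelFit],
    conf_level: float = 0.95,
    include_nonconverged: bool = False,
    small_sample_df: bool = False,
) -> dict:
    """Pool slope and intercept of per-tree fits; signal by simple mean.

    Non-converged fits (failed optima) are excluded by default and counted
    in the reported attrition rate. Returns a dict with keys ``slope``,
    ``intercept`` (PooledFit), ``signal_mean``, ``m``, ``attrition``.
    """
    usable = [f for f in fits if include_nonconverged or f.converged]
    if len(usable) < 2:
        raise PoolingError(
            f"only {len(usable)} converged fits of {len(fits)}; cannot pool"
        )
    n = usable[0].n
    slope = rubin_pool(
        [(f.slope, f.se_slope ** 2) for f in usable],
        conf_level=conf_level, small_sample_df=small_sample_df, n_complete=n,
    )
    intercept = rubin_pool(
        [(f.intercept, f.se_intercept ** 2) for f in usable],
        conf_level=conf_level, small_sample_df=small_sample_df, n_complete=n,
    )
    signals = [f.signal for f in usable if f.signal is not None]
    signal_mean = float(np.mean(signals)) if signals else None
    from dataclasses import replace

    slope = replace(slope, signal_mean=signal_mean)
    return {
        "slope": slope,
        "intercept": intercept,
        "signal_mean": signal_mean,
        "m": len(usable),
        "attrition": 1.0 - len(usable) / len(fits),
        "n": n,
    }


def pool_by_topology(
    fits,
    conf_level: float = 0.95,
    include_nonconverged: bool = False,
) -> dict:
    """Per-topology pools plus a grand pool over all fits.

    ``fits`` is an iterable of (topology_index, ModelFit). Returns a map
    from topology index to the pooled dict of :func:`pool_model_fits`,
    plus the key ``"all"`` for the grand pool.
    """
    by_topo: dict[int, list[ModelFit]] = {}
    for topo, fit in fits:
        by_topo.setdefault(topo, []).append(fit)
    out = {}
    everything: list[ModelFit] = []
    for topo in sorted(by_topo):
        group = by_topo[topo]
        if len(group) < 2:
            raise PoolingError(f"topology {topo} has fewer than 2 fits")
        out[topo] = pool_model_fits(group, conf_level=conf_level,
                                    include_nonconverged=include_nonconverged)
        everything.extend(group)
    out["all"] = pool_model_fits(everything, conf_level=conf_level,
                                 include_nonconverged=include_nonconverged)
    return out


def pooled_table(pools: dict, dataset: str = "", model: str = "") -> pd.DataFrame:
    """Flatten pool_by_topology output into a results table."""
    rows = []
    for topo, pooled in pools.items():
        s, a = pooled["slope"], pooled["intercept"]
        rows.append({
            "dataset": dataset,
            "model": model,
            "topology": topo,
            "m": pooled["m"],
            "n": pooled["n"],
            "intercept": a.qbar,
            "slope": s.qbar,
            "slope_ci_low": s.ci[0],
            "slope_ci_high": s.ci[1],
            "signal_mean": pooled["signal_mean"],
            "attrition": pooled["attrition"],
        })
    return pd.DataFrame(rows)
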