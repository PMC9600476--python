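"""Spearman correlation network among taxa, VFAs and lactation traits.

All unordered variable pairs (within and across roles) are tested with
Spearman's rank correlation; the two-sided p-value uses the large-sample t
approximation with average ranks for ties.  P values are BH-adjusted over
every pair tested in the run, and an edge is retained when |rho| is
strictly greater than 0.2 and the adjusted p is below 0.05.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import bh_adjust

__all__ = ["build_correlation_network", "RHO_THRESHOLD", "P_ADJ_THRESHOLD"]

logger = logging.getLogger(__name__)

RHO_THRESHOLD = 0.2
P_ADJ_THRESHOLD = 0.05


def build_correlation_network(
    variables: pd.DataFrame,
    roles: dict[str, str] | None = None,
    rho_threshold: float = RHO_THRESHOLD,
    p_adj_threshold: float = P_ADJ_THRESHOLD,
    exact_small_n: bool = False,
) -> pd.DataFrame:
    """Thresholded Spearman edge list over all variable pairs.

    ``roles`` tags each column (e.g. taxon / vfa / milk_trait); untagged
    columns get role "variable".  Missing values are handled
    pairwise-complete; pairs with fewer than 3 complete observations are
    skipped.  With ``exact_small_n`` the permutation p-value is used for
    pairs with fewer than 10 complete observations.

    Returns a frame with columns node_a, node_b, role_a, role_b, rho,
    p_adj, sign — canonically ordered so output is deterministic.
    """
    roles = roles or {}
    cols = []
    for c in variables.columns:
        x = variables[c].to_numpy(dtype=float)
        finite = x[~np.isnan(x)]
        if finite.size == 0 or np.all(finite == finite[0]):
            msg = f"variable {c!r} has zero variance; excluded from the network"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        cols.append(c)

    rows = []
    pvals = []
    for a, b in combinations(cols, 2):
        x = variables[a].to_numpy(dtype=float)
        y = variables[b].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            logger.warning("pair (%s, %s): <3 complete observations; skipped", a, b)
            continue
        xs, ys = x[ok], y[ok]
        if np.all(xs == xs[0]) or np.all(ys == ys[0]):
            continue  # degenerate after pairwise deletion
        if exact_small_n and ok.sum() < 10:
            res = stats.spearmanr(xs, ys)
            rho = float(res.statistic)
            perm = stats.permutation_test(
                (xs,),
                lambda x_: stats.spearmanr(x_, ys).statistic,
                permutation_type="pairings",
                n_resamples=9999,
                alternative="two-sided",
                random_state=0,
            )
            p = float(perm.pvalue)
        else:
            rho, p = stats.spearmanr(xs, ys)
            rho, p = float(rho), float(p)
        rows.append((a, b, roles.get(a, "variable"), roles.get(b, "variable"), rho))
        pvals.append(p)

    if not rows:
        return pd.DataFrame(
            columns=["node_a", "node_b", "role_a", "role_b", "rho", "p_adj", "sign"]
        )
    p_adj = bh_adjust(pvals)
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "role_a", "role_b", "rho"])
    df["p_adj"] = p_adj
    keep = (np.abs(df["rho"]) > rho_threshold) & (df["p_adj"] < p_adj_threshold)
    df = df[keep].copy()
    df["sign"] = np.where(df["rho"] > 0, "positive", "negative")
    df = df.sort_values(["node_a", "node_b"], kind="mergesort").reset_index(drop=True)
    return df
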