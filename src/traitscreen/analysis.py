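"""Downstream statistics on the screening results.

Given the per-factor, per-environment sensitivity indices, this module
(1) partitions factors into null / low / impactful groups by their mean
main effect on yield against a 0.02 t/ha threshold, (2) clusters the
impactful factors against the eight integrated outputs with Ward linkage,
(3) decomposes each factor's impact variance across the controllable
management factors (site, sowing date, CO2, nitrogen) as eta-squared shares
of an additive fixed-effects model, pooling climate and interactions into
the residual, (4) types each environment's drought pattern from its water
stress trajectory (ET1 stress-free .. ET4 season-long severe), and
(5) regresses standardized impacts on seasonal stress indices within each
environment type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "IMPACT_THRESHOLD",
    "classify_traits",
    "cluster_impactful",
    "ClusterResult",
    "VarianceDecomposition",
    "eta_squared",
    "DroughtThresholds",
    "drought_type",
    "stress_regression",
]

IMPACT_THRESHOLD = 0.02  # t/ha mean main effect separating low from impactful
_NULL_TOL = 1e-12


def classify_traits(mu_star: pd.DataFrame, threshold: float = IMPACT_THRESHOLD) -> pd.Series:
    """Partition factors into ``null`` / ``low`` / ``impactful`` groups.

    ``mu_star`` holds raw yield main effects (t/ha), factors in rows and
    environments in columns.  ``null``: zero effect in every environment;
    ``low``: mean effect at or below the threshold (boundary inclusive);
    ``impactful``: mean effect above it.
    """
    arr = mu_star.to_numpy(dtype=float)
    if np.nanmin(arr) < -_NULL_TOL:
        raise ValueError("mu* must be non-negative")
    mean = np.nanmean(arr, axis=1)
    peak = np.nanmax(arr, axis=1)
    group = np.where(peak <= _NULL_TOL, "null",
                     np.where(mean <= threshold, "low", "impactful"))
    return pd.Series(group, index=mu_star.index, name="group")


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.Series  # trait -> flat cluster id (1..k)
    standardized: pd.DataFrame

    def to_newick(self) -> str:
        """Dendrogram as nested Newick text with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)
        names = list(self.labels.index)

        def emit(node, parent_h: float) -> str:
            length = max(0.0, parent_h - node.dist)
            if node.is_leaf():
                return f"{names[node.id]}:{length:.6g}"
            return (f"({emit(node.left, node.dist)},{emit(node.right, node.dist)})"
                    f":{length:.6g}")

        return emit(tree, tree.dist) + ";"


def cluster_impactful(matrix: pd.DataFrame, k: int = 3) -> ClusterResult:
    """Ward clustering of impactful traits against the integrated outputs.

    Impacts are standardized per output column (z-score; a constant column
    maps to zeros) so traits are compared on effect *pattern*, not output
    units.  Deterministic; returns the full merge tree and a cut at ``k``.
    """
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the number of traits ({len(matrix)})")
    z = matrix.copy().astype(float)
    for col in z.columns:
        sd = z[col].std(ddof=1)
        z[col] = 0.0 if not sd > 0 else (z[col] - z[col].mean()) / sd
    link = hierarchy.linkage(z.to_numpy(), method="ward")
    flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return ClusterResult(linkage=link,
                         labels=pd.Series(flat, index=matrix.index, name="cluster"),
                         standardized=z)


@dataclass
class VarianceDecomposition:
    """eta-squared shares of an additive main-effects ANOVA on trait impact."""

    eta2: dict[str, float]
    residual: float
    degenerate: bool = False  # impacts constant: zero total sum of squares

    def shares(self) -> dict[str, float]:
        return {**self.eta2, "residual": self.residual}


def eta_squared(impacts: pd.Series, factors: pd.DataFrame) -> VarianceDecomposition:
    """Decompose impact variance into per-factor eta-squared shares.

    ``impacts`` is one trait's main effect across environments; ``factors``
    the aligned categorical design (site, sowing, CO2, nitrogen).  The grid
    must be balanced (each factor-level combination equally replicated), in
    which case each factor's marginal sum of squares equals its sequential
    sum of squares and eta2_e = SS_e / TSS is order-free.  Climate (year)
    and all interactions are pooled into the residual share.
    """
    if len(impacts) != len(factors):
        raise ValueError("impacts and factors must align")
    combos = factors.groupby(list(factors.columns)).size()
    n_cells = int(np.prod([factors[c].nunique() for c in factors.columns]))
    if combos.nunique() != 1 or len(combos) != n_cells:
        raise ValueError("unbalanced factor grid: eta-squared requires equal replication")

    y = impacts.to_numpy(dtype=float)
    grand = y.mean()
    tss = float(((y - grand) ** 2).sum())
    if tss <= 0.0:
        return VarianceDecomposition({c: 0.0 for c in factors.columns}, 0.0,
                                     degenerate=True)
    eta2 = {}
    for col in factors.columns:
        ss = 0.0
        for _, idx in factors.groupby(col).groups.items():
            sub = y[factors.index.get_indexer(idx)]
            ss += len(sub) * (sub.mean() - grand) ** 2
        eta2[col] = ss / tss
    residual = 1.0 - sum(eta2.values())
    return VarianceDecomposition(eta2, residual)


@dataclass(frozen=True)
class DroughtThresholds:
    """Mean-stress cutoffs for the environment-type rules (configurable)."""

    low: float = 0.2
    severe: float = 0.5


def drought_type(
    veg_stress: float,
    grainfill_stress: float,
    thresholds: DroughtThresholds = DroughtThresholds(),
) -> str:
    """Classify a season's water-stress pattern as ET1..ET4.

    Rule-based on the mean water deficit (1 - supply/demand) in the
    vegetative (emergence to flowering) and grain-fill (flowering to
    maturity) windows:

    - ET1 "low": both windows below the low cutoff (stress-free or brief);
    - ET4 "severe": both windows at or above the severe cutoff
      (deficit from early stages throughout grain filling);
    - ET2 "mild-late": remaining cases where stress is concentrated in
      grain filling;
    - ET3 "mild-early": remaining cases where stress peaks in the
      vegetative window and is relieved later.
    """
    if not (0.0 <= veg_stress <= 1.0 and 0.0 <= grainfill_stress <= 1.0):
        raise ValueError("stress means must lie in [0, 1]")
    t = thresholds
    if veg_stress < t.low and grainfill_stress < t.low:
        return "ET1"
    if veg_stress >= t.severe and grainfill_stress >= t.severe:
        return "ET4"
    return "ET2" if grainfill_stress >= veg_stress else "ET3"


def drought_type_from_trajectory(
    trajectory: np.ndarray,
    flowering_index: int,
    thresholds: DroughtThresholds = DroughtThresholds(),
) -> str:
    """ET label from a daily stress trajectory split at flowering."""
    traj = np.asarray(trajectory, dtype=float)
    if len(traj) < 2 or not 0 < flowering_index < len(traj):
        raise ValueError("trajectory must span both windows around flowering")
    return drought_type(float(traj[:flowering_index].mean()),
                        float(traj[flowering_index:].mean()), thresholds)


def stress_regression(
    data: pd.DataFrame,
    impact_col: str = "mu_star_std",
    stress_col: str = "stress",
    type_col: str = "env_type",
) -> pd.DataFrame:
    """Per-environment-type OLS of standardized impact on a stress index.

    Returns one row per type with slope, intercept, Pearson r and n.
    Types with fewer than 3 environments or a constant stress index are
    rejected — the fit would be meaningless.
    """
    rows = []
    for label, sub in data.groupby(type_col):
        if len(sub) < 3:
            raise ValueError(f"environment type {label}: need >= 3 environments")
        x = sub[stress_col].to_numpy(float)
        y = sub[impact_col].to_numpy(float)
        if np.ptp(x) == 0.0:
            raise ValueError(f"environment type {label}: constant stress index")
        fit = stats.linregress(x, y)
        rows.append({"env_type": label, "slope": fit.slope,
                     "intercept": fit.intercept, "r": fit.rvalue, "n": len(sub)})
    return pd.DataFrame(rows).set_index("env_type")
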