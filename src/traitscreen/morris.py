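"""Morris elementary-effects screening: OAT trajectory design and indices.

The Morris method discretizes each of g factors onto an n-level grid on
[0, 1] and walks r one-at-a-time (OAT) trajectories of g+1 points, each step
moving exactly one factor by the fixed increment delta = n / (2(n-1)).  The
finite difference of the model output across a step, divided by the signed
step, is an *elementary effect*; across trajectories, the mean absolute
elementary effect (mu*) measures a factor's overall influence and their
standard deviation (sigma) flags non-linearity and interactions.

Trajectories are generated with the classic randomized-orientation scheme
(random grid base point, random move directions and factor order).  When a
candidate pool larger than r is requested, the r kept trajectories are the
greedy maximum-dispersion subset under the summed pairwise inter-trajectory
distance (sum over all point pairs of their Euclidean distance), which
spreads the design through the factor space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MorrisDesign",
    "ElementaryEffects",
    "SensitivityIndices",
    "build_design",
    "elementary_effects",
    "aggregate_indices",
    "standardize_by_environment",
]


@dataclass(frozen=True)
class MorrisDesign:
    """r OAT trajectories of g+1 points on an n-level grid over [0, 1]^g.

    ``rows`` stacks trajectories contiguously (shape (r*(g+1), g));
    ``moved_factor[t, k]`` and ``signed_step[t, k]`` describe transition k of
    trajectory t (from row k to row k+1 within the trajectory).
    """

    g: int
    n_levels: int
    r: int
    delta: float
    rows: np.ndarray
    moved_factor: np.ndarray  # (r, g) int
    signed_step: np.ndarray  # (r, g) float, +/- delta

    def __post_init__(self) -> None:
        if self.rows.shape != (self.r * (self.g + 1), self.g):
            raise ValueError("row block has wrong shape")

    @property
    def n_rows(self) -> int:
        return self.r * (self.g + 1)

    def trajectory(self, t: int) -> np.ndarray:
        s = t * (self.g + 1)
        return self.rows[s : s + self.g + 1]

    def to_frame(self, factor_names: list[str] | None = None) -> pd.DataFrame:
        """Tabular export: one row per design point, with trajectory bookkeeping.

        ``moved_factor`` on a row names the factor whose move *produced* that
        row (empty for trajectory base points), so the design can be farmed
        out, simulated elsewhere, and re-imported against output values.
        """
        names = factor_names or [f"f{i}" for i in range(self.g)]
        if len(names) != self.g:
            raise ValueError("factor_names length mismatch")
        rec = []
        for t in range(self.r):
            for k in range(self.g + 1):
                rec.append({
                    "trajectory": t,
                    "step": k,
                    "moved_factor": "" if k == 0 else names[self.moved_factor[t, k - 1]],
                    "signed_step": 0.0 if k == 0 else self.signed_step[t, k - 1],
                })
        frame = pd.DataFrame(rec)
        levels = pd.DataFrame(self.rows, columns=names)
        return pd.concat([frame, levels], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MorrisDesign":
        meta = {"trajectory", "step", "moved_factor", "signed_step"}
        names = [c for c in df.columns if c not in meta]
        g = len(names)
        r = df["trajectory"].nunique()
        rows = df.sort_values(["trajectory", "step"])[names].to_numpy(float)
        moved = np.zeros((r, g), dtype=int)
        steps = np.zeros((r, g))
        by_name = {n: i for i, n in enumerate(names)}
        for t, sub in df.sort_values(["trajectory", "step"]).groupby("trajectory"):
            for k, (_, row) in enumerate(sub.iloc[1:].iterrows()):
                moved[t, k] = by_name[row["moved_factor"]]
                steps[t, k] = row["signed_step"]
        n_levels = _infer_levels(rows)
        delta = n_levels / (2 * (n_levels - 1))
        return cls(g=g, n_levels=n_levels, r=r, delta=delta, rows=rows,
                   moved_factor=moved, signed_step=steps)


def _infer_levels(rows: np.ndarray) -> int:
    vals = np.unique(np.round(rows, 12))
    for n in range(2, 64):
        grid = np.linspace(0.0, 1.0, n)
        if np.all(np.isclose(vals[:, None], grid[None, :], atol=1e-9).any(axis=1)):
            return n
    raise ValueError("rows are not on a recognizable level grid")


def _random_trajectory(g: int, n_levels: int, delta: float, rng: np.random.Generator):
    """One OAT trajectory: base point, random directions, random move order."""
    grid_step = 1.0 / (n_levels - 1)
    # base coordinates restricted so that base + delta stays on the grid
    max_base = int(round((1.0 - delta) / grid_step))
    base = rng.integers(0, max_base + 1, size=g) * grid_step
    direction = rng.choice([-1.0, 1.0], size=g)
    # a downward move starts from base + delta so every point stays in [0, 1]
    start = np.where(direction > 0, base, base + delta)
    order = rng.permutation(g)
    rows = np.empty((g + 1, g))
    rows[0] = start
    point = start.copy()
    steps = np.empty(g)
    for k, i in enumerate(order):
        point = point.copy()
        steps[k] = direction[i] * delta
        point[i] += steps[k]
        rows[k + 1] = point
    return rows, order, steps


def _trajectory_distance_matrix(stack: np.ndarray) -> np.ndarray:
    """Summed point-pair Euclidean distances between all trajectory pairs.

    ``stack`` has shape (N, g+1, g).  Computed blockwise from the full point
    distance matrix to stay vectorized without materializing huge arrays.
    """
    n, m, g = stack.shape
    flat = stack.reshape(n * m, g)
    sq = np.einsum("ij,ij->i", flat, flat)
    dist = np.zeros((n, n))
    block = max(1, 2_000_000 // (n * m))
    for s in range(0, n * m, block * m):
        e = min(n * m, s + block * m)
        d2 = sq[s:e, None] + sq[None, :] - 2.0 * flat[s:e] @ flat.T
        np.maximum(d2, 0.0, out=d2)
        part = np.sqrt(d2).reshape(-1, m, n, m).sum(axis=(1, 3))
        dist[s // m : e // m] = part
    # blockwise summation can differ by an ulp across the diagonal; enforce
    # exact symmetry so tie-breaking in the greedy selection is well defined
    return 0.5 * (dist + dist.T)


def _greedy_select(dist: np.ndarray, r: int) -> np.ndarray:
    """Greedy subset of size r maximizing the summed pairwise dispersion."""
    n = dist.shape[0]
    if r >= n:
        return np.arange(n)
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    chosen = [int(i), int(j)]
    mask = np.ones(n, dtype=bool)
    mask[chosen] = False
    gain = dist[chosen].sum(axis=0)
    while len(chosen) < r:
        cand = np.flatnonzero(mask)
        nxt = int(cand[np.argmax(gain[cand])])
        chosen.append(nxt)
        mask[nxt] = False
        gain += dist[nxt]
    return np.array(sorted(chosen))


def build_design(
    g: int,
    n_levels: int = 6,
    r: int = 100,
    n_candidates: int | None = None,
    seed: int | None = None,
) -> MorrisDesign:
    """Generate a Morris OAT screening design.

    Parameters
    ----------
    g : number of independent factors (>= 1).
    n_levels : grid levels per factor; even, >= 2.  The step is
        delta = n_levels / (2 (n_levels - 1)), i.e. 0.6 for 6 levels.
    r : number of trajectories kept.
    n_candidates : size of the random candidate pool from which the r most
        dispersed trajectories are selected; ``None`` (default) generates
        exactly r trajectories with no selection.
    seed : reproducible for a fixed seed.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    if n_levels < 2 or n_levels % 2 != 0:
        raise ValueError("n_levels must be an even integer >= 2")
    if r < 1:
        raise ValueError("r must be >= 1")
    n_candidates = r if n_candidates is None else n_candidates
    if n_candidates < r:
        raise ValueError("n_candidates must be >= r")

    rng = np.random.default_rng(seed)
    delta = n_levels / (2.0 * (n_levels - 1))
    cand_rows, cand_order, cand_steps = [], [], []
    for _ in range(n_candidates):
        rows, order, steps = _random_trajectory(g, n_levels, delta, rng)
        cand_rows.append(rows)
        cand_order.append(order)
        cand_steps.append(steps)
    stack = np.stack(cand_rows)

    if n_candidates > r:
        keep = _greedy_select(_trajectory_distance_matrix(stack), r)
    else:
        keep = np.arange(r)

    rows = stack[keep].reshape(r * (g + 1), g)
    moved = np.stack([cand_order[i] for i in keep])
    steps = np.stack([cand_steps[i] for i in keep])
    return MorrisDesign(g=g, n_levels=n_levels, r=r, delta=delta, rows=rows,
                        moved_factor=moved, signed_step=steps)


@dataclass(frozen=True)
class ElementaryEffects:
    """Signed elementary effects, one per factor per trajectory.

    ``matrix[i, t]`` is the effect of factor i in trajectory t, in output
    units per full normalized factor range; NaN marks a missing effect
    (failed simulation).
    """

    matrix: np.ndarray  # (g, r)
    output: str = ""
    environment: str = ""


def elementary_effects(
    design: MorrisDesign,
    y: np.ndarray,
    output: str = "",
    environment: str = "",
) -> ElementaryEffects:
    """Finite-difference elementary effects from outputs at every design row.

    ``y`` is indexed like ``design.rows``; NaN entries propagate to missing
    effects with a warning rather than aborting the screen.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.n_rows:
        raise ValueError(f"need one output per design row ({design.n_rows})")
    ee = np.full((design.g, design.r), np.nan)
    for t in range(design.r):
        base = t * (design.g + 1)
        for k in range(design.g):
            i = design.moved_factor[t, k]
            ee[i, t] = (y[base + k + 1] - y[base + k]) / design.signed_step[t, k]
    n_missing = int(np.isnan(ee).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} elementary effects missing (failed simulations)",
            stacklevel=2,
        )
    return ElementaryEffects(matrix=ee, output=output, environment=environment)


@dataclass(frozen=True)
class SensitivityIndices:
    """Per-factor mu* (mean |EE|) and sigma (sample SD of signed EE)."""

    mu_star: np.ndarray  # (g,)
    sigma: np.ndarray  # (g,)
    n_effects: np.ndarray  # (g,) effects actually available
    standardized: bool = False


def aggregate_indices(ee: ElementaryEffects, standardized: bool = False) -> SensitivityIndices:
    """Collapse elementary effects to mu* and sigma per factor.

    mu* is the mean absolute effect; sigma the sample (ddof=1) standard
    deviation of the signed effects.  Missing effects are ignored, with the
    available count recorded; a factor with no effect at all is an error.
    """
    m = ee.matrix
    n_eff = np.sum(~np.isnan(m), axis=1)
    if np.any(n_eff == 0):
        bad = np.flatnonzero(n_eff == 0).tolist()
        raise ValueError(f"no elementary effects available for factors {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu_star = np.nanmean(np.abs(m), axis=1)
        sigma = np.where(n_eff >= 2, np.nanstd(m, axis=1, ddof=1), 0.0)
    return SensitivityIndices(mu_star=mu_star, sigma=sigma, n_effects=n_eff,
                              standardized=standardized)


def standardize_by_environment(
    outputs: pd.DataFrame,
    value_cols: list[str],
    env_col: str = "environment",
) -> pd.DataFrame:
    """z-score output columns within each environment.

    Sensitivity indices in raw output units are not comparable across
    environments of very different productivity, so outputs are standardized
    (mean 0, sample SD 1) per environment before computing standardized
    effects.  A constant output within an environment standardizes to all
    zeros; an environment with a single genotype is an error.
    """
    out = outputs.copy()
    counts = outputs.groupby(env_col).size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"environments with a single genotype: {bad}")
    for col in value_cols:
        grp = out.groupby(env_col)[col]
        mean = grp.transform("mean")
        sd = grp.transform("std")  # sample sd, ddof=1
        z = (out[col] - mean) / sd
        out[col] = z.where(sd > 0, 0.0)
    return out
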