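"""Validation of accelerometry metrics against ordinal clinical ratings.

Sensor-derived tremor power has no a-priori clinical anchor, so it is
validated against the Clinical Rating Scale for Tremor (CRST Part A): per
subject, a physician rates tremor 0–4 in the rest, postural and action
conditions of the dominant arm.  Agreement is quantified with Spearman's
rank correlation r_s (ordinal scale, monotone relationship expected), with a
Fisher-z 95% confidence interval and a two-tailed p-value.  No
multiple-testing adjustment is applied by default; an optional Holm
correction is available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, StatsError

#: |r_s| thresholds for the qualitative strength labels.
DEFAULT_STRENGTH_THRESHOLDS = (0.4, 0.6)  # weak < 0.4 <= moderate < 0.6 <= strong

#: CRST Part A conditions (rows of the validation grid).
CRST_CONDITIONS = ("rest", "posture", "action", "total")

#: Accelerometry positions (columns of the validation grid).
GRID_POSITIONS = ("rest", "posture", "action", "bimanual", "wing")

#: The wing position is reported in the grid although the CRST does not
#: rate it; its column correlates against the postural CRST-adjacent rows
#: exactly like the others.

#: Canonical grid names for the pipeline's position labels (dominant arm).
POSITION_ALIASES = {
    "rest": "rest",
    "posture_unimanual_dominant": "posture",
    "posture_bimanual": "bimanual",
    "wing": "wing",
    "action_loading": "action",
}


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation with CI, p and a qualitative strength label."""

    r_s: float
    ci_low: float
    ci_high: float
    p_two_tailed: float
    n: int
    strength: str


def classify_correlation(
    r_s: float, thresholds: tuple[float, float] = DEFAULT_STRENGTH_THRESHOLDS
) -> str:
    """Label |r_s|: weak below the first threshold, strong at/above the second."""
    a = abs(r_s)
    if a > 1 + 1e-12:
        raise StatsError(f"|r_s| = {a} exceeds 1")
    lo, hi = thresholds
    if a < lo:
        return "weak"
    if a < hi:
        return "moderate"
    return "strong"


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise StatsError("constant input: correlation undefined")
    return float(a @ b) / denom


def _perm_p(
    rx: np.ndarray, ry: np.ndarray, r_obs: float, rng: np.random.Generator,
    n_mc: int,
) -> float:
    """Two-tailed permutation p for Spearman's r_s on pre-ranked data.

    Exhaustive for n <= 7 (<= 5040 orderings), seeded Monte-Carlo otherwise.
    """
    n = rx.size
    target = abs(r_obs) - 1e-12
    if math.factorial(n) <= 5040:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_pearson(rx, ry[list(perm)])) >= target:
                hits += 1
        return hits / total
    hits = 1  # include the observed ordering
    for _ in range(n_mc):
        if abs(_pearson(rx, ry[rng.permutation(n)])) >= target:
            hits += 1
    return hits / (n_mc + 1)


def spearman(
    x,
    y,
    p_method: str = "auto",
    n_permutations: int = 100_000,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman rank correlation with Fisher-z CI and two-tailed p.

    Ranks use mean-rank tie handling; r_s is the Pearson correlation of the
    ranks.  The p-value uses the t approximation with n−2 df for n ≥ 10 and
    a permutation test (exhaustive for n ≤ 7, seeded Monte-Carlo otherwise)
    for smaller samples; ``p_method`` ∈ {"auto", "t", "permutation"} forces
    one or the other.  The 95% CI is Fisher z ± 1.96/√(n−3), the standard
    large-sample interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 4:
        raise StatsError(f"need n >= 4 observations, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatsError("inputs must be finite")

    rx, ry = _rank(x), _rank(y)
    r = _pearson(rx, ry)
    r = max(-1.0, min(1.0, r))

    if p_method not in ("auto", "t", "permutation"):
        raise ConfigurationError(f"unknown p_method {p_method!r}")
    use_t = p_method == "t" or (p_method == "auto" and n >= 10)
    if use_t:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p = 2 * float(sps.t.sf(abs(t), df=n - 2))
    else:
        p = _perm_p(rx, ry, r, np.random.default_rng(seed), n_permutations)
    p = min(1.0, max(p, np.nextafter(0, 1)))

    if n > 3 and abs(r) < 1.0:
        z = math.atanh(r)
        half = 1.959963984540054 / math.sqrt(n - 3)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    else:
        ci_low, ci_high = (r, r) if abs(r) >= 1.0 else (-1.0, 1.0)
    return CorrelationResult(
        r_s=r,
        ci_low=ci_low,
        ci_high=ci_high,
        p_two_tailed=p,
        n=n,
        strength=classify_correlation(r),
    )


def fold_ratio(a: float, b: float) -> float:
    """Fold change a/b (b must be positive)."""
    if b <= 0:
        raise StatsError(f"fold denominator must be positive, got {b}")
    return a / b


def cohort_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-position mean and SD (n−1 denominator) of each tremor metric.

    ``metrics`` is long format with columns ``subject_id``, ``position`` and
    one column per metric (e.g. ``peak_frequency_hz``, ``peak_power``,
    ``total_power``).  Requires at least 2 subjects per position.
    """
    required = {"subject_id", "position"}
    if not required.issubset(metrics.columns):
        raise StatsError(f"metrics table must have columns {sorted(required)}")
    counts = metrics.groupby("position")["subject_id"].nunique()
    low = counts[counts < 2]
    if not low.empty:
        raise StatsError(
            f"SD undefined with a single subject in position(s): "
            f"{', '.join(low.index)}"
        )
    value_cols = [
        c
        for c in metrics.columns
        if c not in required and pd.api.types.is_numeric_dtype(metrics[c])
    ]
    out = metrics.groupby("position")[value_cols].agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out


def correlation_matrix(
    crst: pd.DataFrame,
    metrics: pd.DataFrame,
    metric_field: str = "total_power",
    p_method: str = "auto",
    seed: int = 0,
    holm: bool = False,
) -> pd.DataFrame:
    """Grid of Spearman correlations: CRST conditions × accelerometry positions.

    ``crst`` has columns ``subject_id, rest, posture, action[, total]``
    (integer 0–4 items; ``total`` defaults to their sum).  ``metrics`` is long
    format with ``subject_id, position`` and the chosen ``metric_field``,
    dominant-arm values.  Each cell is one :class:`CorrelationResult`; raw
    two-tailed p-values by default (``holm=True`` applies a Holm adjustment
    across the grid).
    """
    crst = crst.copy()
    if "total" not in crst.columns:
        crst["total"] = crst[["rest", "posture", "action"]].sum(axis=1)
    for cond in ("rest", "posture", "action"):
        vals = crst[cond]
        if not ((vals >= 0) & (vals <= 4) & (vals == vals.round())).all():
            raise StatsError(f"CRST {cond} items must be integers in 0..4")

    metrics = metrics.copy()
    metrics["position"] = metrics["position"].map(
        lambda p: POSITION_ALIASES.get(str(p), str(p))
    )
    wide = metrics.pivot_table(
        index="subject_id", columns="position", values=metric_field
    )
    positions = [p for p in GRID_POSITIONS if p in wide.columns]
    # prefix the accelerometry columns: CRST conditions share names with them
    wide = wide.rename(columns={p: f"acc_{p}" for p in wide.columns})
    joined = crst.set_index("subject_id").join(wide, how="inner")
    if len(joined) < 4:
        raise StatsError(
            f"only {len(joined)} subjects after joining CRST with metrics; need >= 4"
        )

    rows = []
    results: list[CorrelationResult] = []
    for cond in CRST_CONDITIONS:
        for pos in positions:
            res = spearman(
                joined[cond].to_numpy(),
                joined[f"acc_{pos}"].to_numpy(),
                p_method=p_method,
                seed=seed,
            )
            results.append(res)
            rows.append(
                {
                    "crst_condition": cond,
                    "position": pos,
                    "r_s": res.r_s,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p_two_tailed,
                    "n": res.n,
                    "strength": res.strength,
                }
            )
    table = pd.DataFrame(rows)
    if holm:
        p = table["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        table["p_holm"] = adj
    return table
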