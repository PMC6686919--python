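"""Proteome-size contrasts between pathway-positive and pathway-negative groups.

The screen's headline statistic: do proteomes lacking an energy-reserve
pathway tend to be smaller?  Groups are compared with an unpaired two-tailed
t test (pooled-variance Student form by default, Welch as an option) at a
configurable significance level (default 0.05).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientGroupError, InvalidParameterError
from .pathway_caller import PathwayCallMatrix


class TTestVariant(enum.Enum):
    POOLED = "pooled"  # classical Student: pooled variance, df = nx + ny - 2
    WELCH = "welch"  # unequal variances, Satterthwaite df


@dataclass(frozen=True)
class GroupComparison:
    """Result of one pathway-positive vs pathway-negative size contrast."""

    pathway_id: str
    n_with: int
    n_without: int
    mean_with: float
    mean_without: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    alpha: float
    significant: bool


def two_sample_t(
    x, y, variant: TTestVariant = TTestVariant.POOLED
) -> tuple[float, float, float]:
    """Unpaired two-tailed t test; returns ``(t, df, p)``.

    POOLED: ``t = (mean_x - mean_y) / (s_p * sqrt(1/n_x + 1/n_y))`` with
    ``df = n_x + n_y - 2``; WELCH uses per-group variances and Satterthwaite
    degrees of freedom.  Two identical constant groups give ``t = 0, p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidParameterError("each group needs at least 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidParameterError("groups must contain finite values")
    nx, ny = x.size, y.size
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        # degenerate limit: no within-group spread
        df = float(nx + ny - 2) if variant is TTestVariant.POOLED else float("nan")
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), df, 0.0
    if variant is TTestVariant.POOLED:
        res = stats.ttest_ind(x, y, equal_var=True)
        df = float(nx + ny - 2)
    else:
        res = stats.ttest_ind(x, y, equal_var=False)
        df = float((vx / nx + vy / ny) ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)))
    return float(res.statistic), df, float(res.pvalue)


def compare_by_pathway(
    matrix: PathwayCallMatrix,
    pathway_id: str,
    alpha: float = 0.05,
    variant: TTestVariant = TTestVariant.POOLED,
) -> GroupComparison:
    """Compare proteome sizes between proteomes with and without a pathway.

    For ``pathway_id="polyp"`` the contrast is polyP-complete (all of
    PPK1/PPK2/PPX) vs polyP-absent (none of the three); proteomes with a
    partial complement are excluded.  For every other pathway the split
    follows the boolean call column.
    """
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    df = matrix.data
    if pathway_id in ("polyp", "polyp_status"):
        with_sizes = df.loc[df["polyp_status"] == "complete", "proteome_size"]
        without_sizes = df.loc[df["polyp_status"] == "absent", "proteome_size"]
        label = "polyp"
    else:
        if pathway_id not in df.columns:
            raise InvalidParameterError(f"unknown pathway {pathway_id!r}")
        mask = df[pathway_id].astype(bool)
        with_sizes = df.loc[mask, "proteome_size"]
        without_sizes = df.loc[~mask, "proteome_size"]
        label = pathway_id
    if len(with_sizes) < 2 or len(without_sizes) < 2:
        raise InsufficientGroupError(
            f"pathway {label!r}: groups of size {len(with_sizes)} vs {len(without_sizes)}"
        )
    t, dof, p = two_sample_t(with_sizes, without_sizes, variant=variant)
    return GroupComparison(
        pathway_id=label,
        n_with=int(len(with_sizes)),
        n_without=int(len(without_sizes)),
        mean_with=float(with_sizes.mean()),
        mean_without=float(without_sizes.mean()),
        t_statistic=t,
        degrees_of_freedom=dof,
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
    )


def compare_all(
    matrix: PathwayCallMatrix,
    alpha: float = 0.05,
    variant: TTestVariant = TTestVariant.POOLED,
) -> pd.DataFrame:
    """Run the size contrast for every pathway (skipping those with a group
    of fewer than two proteomes); one row per comparison."""
    rows = []
    targets = list(matrix.pathway_ids)
    if "polyp_status" in matrix.data.columns:
        targets.append("polyp")
    for pathway_id in targets:
        try:
            c = compare_by_pathway(matrix, pathway_id, alpha=alpha, variant=variant)
        except InsufficientGroupError:
            continue
        rows.append(
            {
                "pathway_id": c.pathway_id,
                "n_with": c.n_with,
                "n_without": c.n_without,
                "mean_with": c.mean_with,
                "mean_without": c.mean_without,
                "t_statistic": c.t_statistic,
                "df": c.degrees_of_freedom,
                "p_value": c.p_value,
                "significant": c.significant,
            }
        )
    return pd.DataFrame(rows)


def report(comparisons: pd.DataFrame, alpha: float = 0.05) -> str:
    """Human-readable summary of the size contrasts."""
    lines = [f"Proteome-size contrasts (two-tailed t test, alpha = {alpha}):"]
    for _, r in comparisons.iterrows():
        verdict = "significant" if r["significant"] else "not significant"
        lines.append(
            f"  {r['pathway_id']}: {r['mean_with']:.0f} proteins/proteome "
            f"(n={r['n_with']}) with vs {r['mean_without']:.0f} (n={r['n_without']}) "
            f"without; t={r['t_statistic']:.3f}, df={r['df']:.1f}, "
            f"p={r['p_value']:.3g} ({verdict})"
        )
    return "\n".join(lines)
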