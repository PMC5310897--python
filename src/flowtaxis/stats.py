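"""Group comparison: one-way ANOVA with a Tukey-Kramer post-hoc test.

Skewed metrics can be log10-transformed before testing (automatically, when
the pooled-residual sample skewness exceeds a cutoff) and the group means
are then reported back-transformed (geometric means).  Pairwise adjusted
p-values come from the studentized range distribution with k groups and
N - k error degrees of freedom, valid for unequal group sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

PAIRWISE_COLUMNS = ["group_a", "group_b", "mean_diff", "q", "p_adj", "tier"]

_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    """Figure-style significance symbols: * / ** / *** at 0.05 / 0.01 / 0.001."""
    for cut, symbol in _TIERS:
        if p < cut:
            return symbol
    return ""


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    else:
        out = {f"group{i}": np.asarray(v, dtype=float) for i, v in enumerate(groups)}
    if len(out) < 2:
        raise ValueError("need >= 2 groups")
    for k, v in out.items():
        if v.ndim != 1 or v.size < 2:
            raise ValueError(f"group {k!r} needs >= 2 values")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {k!r} contains non-finite values")
    return out


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Degenerate conventions: all values identical -> (F=0, p=1); zero
    within-group variance with unequal means -> (F=inf, p=0).
    """
    g = _as_groups(groups)
    allv = np.concatenate(list(g.values()))
    grand = allv.mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in g.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in g.values())
    df_b, df_w = len(g) - 1, allv.size - len(g)
    if ssw <= 1e-300:
        return (0.0, 1.0) if ssb <= 1e-300 else (math.inf, 0.0)
    F = (ssb / df_b) / (ssw / df_w)
    return float(F), float(sps.f.sf(F, df_b, df_w))


def tukey_kramer(groups, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey-Kramer comparison table.

    For each pair, q = |mean_a - mean_b| / sqrt(MSW/2 * (1/n_a + 1/n_b));
    the adjusted p is the studentized-range survival function with k groups
    and N - k degrees of freedom.  Returns k(k-1)/2 rows with columns
    ``group_a, group_b, mean_diff, q, p_adj, tier``.
    """
    g = _as_groups(groups)
    labels = list(g)
    k = len(labels)
    N = sum(v.size for v in g.values())
    df_w = N - k
    msw = sum(((v - v.mean()) ** 2).sum() for v in g.values()) / df_w
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = g[labels[i]], g[labels[j]]
            diff = a.mean() - b.mean()
            if msw <= 1e-300:
                q = 0.0 if diff == 0 else math.inf
                p = 1.0 if diff == 0 else 0.0
            else:
                se = math.sqrt(msw / 2 * (1 / a.size + 1 / b.size))
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_w))
                if not np.isfinite(p):
                    raise RuntimeError(
                        f"studentized-range evaluation failed for q={q:.4g}, "
                        f"k={k}, df={df_w}")
                p = min(max(p, 0.0), 1.0)
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "mean_diff": float(diff), "q": float(q),
                         "p_adj": p, "tier": significance_tier(p)})
    return pd.DataFrame(rows, columns=PAIRWISE_COLUMNS)


def skew_transform(groups, cutoff: float = 1.0, force: bool | None = None,
                   ) -> tuple[dict[str, np.ndarray], bool]:
    """Optionally log10-transform skewed data.

    The transform is applied when the absolute sample skewness of the pooled
    within-group residuals exceeds ``cutoff`` (or unconditionally /
    never when ``force`` is True / False).  Nonpositive values with the
    transform requested raise an error naming the offending group.
    Returns ``(groups, applied)``.
    """
    g = _as_groups(groups)
    if force is None:
        resid = np.concatenate([v - v.mean() for v in g.values()])
        apply_it = abs(float(sps.skew(resid))) > cutoff
    else:
        apply_it = bool(force)
    if not apply_it:
        return g, False
    for k, v in g.items():
        if np.any(v <= 0):
            raise ValueError(f"log10 transform requested but group {k!r} "
                             "contains nonpositive values")
    return {k: np.log10(v) for k, v in g.items()}, True


@dataclass
class ComparisonResult:
    """One metric's full group comparison."""

    metric: str
    F: float
    anova_p: float
    pairwise: pd.DataFrame
    transform_applied: str                  # "none" | "log10"
    group_means: dict[str, float]           # back-transformed when log10
    group_n: dict[str, int]

    def report(self) -> str:
        """Human-readable text block."""
        lines = [f"metric: {self.metric}",
                 f"transform: {self.transform_applied}",
                 f"ANOVA: F = {self.F:.4g}, p = {self.anova_p:.4g} "
                 f"{significance_tier(self.anova_p)}"]
        kind = "geometric mean" if self.transform_applied == "log10" else "mean"
        for k, m in self.group_means.items():
            lines.append(f"  {k}: {kind} = {m:.4g} (n = {self.group_n[k]})")
        lines.append("pairwise (Tukey-Kramer):")
        for _, r in self.pairwise.iterrows():
            lines.append(f"  {r.group_a} vs {r.group_b}: diff = {r.mean_diff:.4g}, "
                         f"p = {r.p_adj:.4g} {r.tier}")
        return "\n".join(lines)


def compare_groups(groups, metric: str = "metric", alpha: float = 0.05,
                   transform: str = "auto", skew_cutoff: float = 1.0,
                   ) -> ComparisonResult:
    """Full comparison for one metric: skew handling, ANOVA, Tukey-Kramer.

    ``transform`` is ``auto`` (skewness criterion), ``log10`` (forced) or
    ``none``.  With log10, reported group means are back-transformed
    (geometric) means; the pairwise mean differences stay on the log scale.
    """
    if transform not in ("auto", "log10", "none"):
        raise ValueError("transform must be auto, log10 or none")
    force = {"auto": None, "log10": True, "none": False}[transform]
    g_raw = _as_groups(groups)
    g, applied = skew_transform(g_raw, cutoff=skew_cutoff, force=force)
    F, p = anova_oneway(g)
    pairwise = tukey_kramer(g, alpha=alpha)
    if applied:
        means = {k: float(10 ** v.mean()) for k, v in g.items()}
    else:
        means = {k: float(v.mean()) for k, v in g.items()}
    return ComparisonResult(metric=metric, F=F, anova_p=p, pairwise=pairwise,
                            transform_applied="log10" if applied else "none",
                            group_means=means,
                            group_n={k: int(v.size) for k, v in g_raw.items()})
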