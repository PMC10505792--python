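"""Group-comparison statistics: one-way ANOVA with Dunnett many-to-one or
Tukey all-pairs multiple-comparison adjustment, mean ± SD summaries and
significance stars.

The statistical unit is always the colony (one value per colony per
readout), never the nucleus.

Dunnett's adjusted p-value is the tail probability of the maximum of k
correlated |t| statistics sharing the control mean and a pooled variance,

    p_adj = P( max_j |T_j| >= |t_obs| ),

evaluated here by deterministic 2-D Gauss quadrature: probabilists'
Gauss–Hermite over the standardised control mean and Gauss–Legendre over
the probability transform of the pooled-SD chi distribution. The inner
product over comparisons is accumulated with log1p/expm1 so small tail
probabilities keep full relative precision (and the family-wise p never
drops below a marginal p). Tukey's all-pairs p uses the studentized-range
distribution with the Tukey–Kramer standard error for unbalanced groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats as sps
from scipy.special import ndtr

STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p: float) -> str:
    """Significance stars: *p<0.05, **p<0.01, ***p<0.001, ****p<0.0001, else ns."""
    for level, mark in STAR_LEVELS:
        if p < level:
            return mark
    return "ns"


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class GroupComparison:
    """Result bundle of a post-hoc multiple-comparison procedure."""

    method: str  # "dunnett" | "tukey"
    groups: dict[str, np.ndarray]
    control: str | None
    anova: AnovaResult
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    # comparisons columns: comparison, group, estimate, statistic, p_unadj,
    # p_adj, stars

    def summary(self) -> str:
        lines = [
            f"{self.method.capitalize()} comparison"
            + (f" vs control {self.control!r}" if self.control else " (all pairs)"),
            f"ANOVA: F({self.anova.df_between}, {self.anova.df_within}) = "
            f"{self.anova.F:.4g}, p = {self.anova.p:.4g}",
            "",
        ]
        lines.append(
            self.comparisons.to_string(
                index=False, float_format=lambda x: f"{x:.4g}"
            )
        )
        return "\n".join(lines)


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        return {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    return {f"group{i}": np.asarray(v, dtype=float) for i, v in enumerate(groups)}


def one_way_anova(groups) -> AnovaResult:
    """Classic fixed-effects one-way ANOVA decomposition.

    ``groups`` is a dict label -> samples or a sequence of sample lists.
    """
    g = list(_as_groups(groups).values())
    if len(g) < 2:
        raise ValueError("need at least two groups")
    for v in g:
        if len(v) < 2:
            raise ValueError("every group needs n >= 2")
    n_tot = sum(len(v) for v in g)
    grand = np.concatenate(g).mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in g)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in g)
    dfb, dfw = len(g) - 1, n_tot - len(g)
    if ssw == 0:
        raise ValueError("zero within-group variance; F undefined")
    F = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(float(F), dfb, dfw, float(sps.f.sf(F, dfb, dfw)))


def pooled_variance(groups) -> tuple[float, int]:
    g = list(_as_groups(groups).values())
    dfw = sum(len(v) - 1 for v in g)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in g)
    return ssw / dfw, dfw


def dunnett_sf(
    t: float,
    df: int,
    n_control: int,
    n_treat: np.ndarray,
    n_hermite: int = 96,
    n_chi: int = 64,
) -> float:
    """P(max_j |T_j| >= t) for Dunnett's many-to-one statistics.

    Deterministic quadrature: conditioning on the control mean Z0 and the
    pooled SD factor U = S/sigma makes the treatment statistics independent
    truncated normals; the outer expectations use Gauss–Hermite (Z0) and
    Gauss–Legendre on the chi quantile transform (U).
    """
    if t <= 0:
        return 1.0
    n_treat = np.asarray(n_treat, dtype=float)
    z_nodes, z_w = hermegauss(n_hermite)
    z_w = z_w / np.sqrt(2 * np.pi)
    p_nodes, p_w = np.polynomial.legendre.leggauss(n_chi)
    p_nodes = 0.5 * (p_nodes + 1.0)  # (0, 1)
    p_w = 0.5 * p_w
    u_nodes = sps.chi.ppf(p_nodes, df) / np.sqrt(df)

    c = np.sqrt(1.0 / n_treat + 1.0 / n_control)  # (k,)
    sn = np.sqrt(n_treat)
    # shapes: (n_chi, n_hermite, k)
    center = (z_nodes[None, :, None] / np.sqrt(n_control)) * sn[None, None, :]
    half = t * u_nodes[:, None, None] * (c * sn)[None, None, :]
    # per-comparison exceedance: delta = P(Z outside [center-half, center+half])
    delta = ndtr(-(center + half)) + ndtr(center - half)
    delta = np.clip(delta, 0.0, 1.0)
    # 1 - prod(1 - delta), accumulated in log space for tail accuracy
    log_keep = np.log1p(-np.clip(delta, 0.0, 1.0 - 1e-16)).sum(axis=2)
    integrand = -np.expm1(log_keep)  # (n_chi, n_hermite)
    val = float(p_w @ integrand @ z_w)
    return min(max(val, 0.0), 1.0)


def dunnett_test(groups, control: str) -> GroupComparison:
    """Many-to-one comparisons of every treatment group against a control,
    with family-wise adjusted two-sided p-values."""
    gd = _as_groups(groups)
    if control not in gd:
        raise ValueError(f"control label {control!r} not among groups")
    anova = one_way_anova(gd)
    s2, dfw = pooled_variance(gd)
    ctrl = gd[control]
    treat = {k: v for k, v in gd.items() if k != control}
    n_treat = np.array([len(v) for v in treat.values()], dtype=float)
    rows = []
    for name, v in treat.items():
        se = np.sqrt(s2 * (1.0 / len(v) + 1.0 / len(ctrl)))
        est = v.mean() - ctrl.mean()
        tstat = est / se
        p_un = 2.0 * sps.t.sf(abs(tstat), dfw)
        p_adj = dunnett_sf(abs(tstat), dfw, len(ctrl), n_treat)
        # the family-wise tail dominates each marginal exactly; clip so
        # quadrature error can never report p_adj below p_unadj
        p_adj = min(1.0, max(p_adj, p_un))
        rows.append(
            (
                f"{name} vs {control}",
                name,
                float(est),
                float(tstat),
                float(p_un),
                float(p_adj),
                stars(p_adj),
            )
        )
    comp = pd.DataFrame(
        rows,
        columns=[
            "comparison",
            "group",
            "estimate",
            "statistic",
            "p_unadj",
            "p_adj",
            "stars",
        ],
    )
    return GroupComparison("dunnett", gd, control, anova, comp)


def tukey_hsd(groups) -> GroupComparison:
    """All-pairs comparisons with studentized-range (Tukey–Kramer) adjustment."""
    gd = _as_groups(groups)
    if len(gd) < 3:
        raise ValueError("Tukey's test needs at least three groups")
    anova = one_way_anova(gd)
    s2, dfw = pooled_variance(gd)
    k = len(gd)
    names = list(gd)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = gd[names[i]], gd[names[j]]
            est = a.mean() - b.mean()
            se_t = np.sqrt(s2 * (1.0 / len(a) + 1.0 / len(b)))
            q = abs(est) / np.sqrt(s2 * (1.0 / len(a) + 1.0 / len(b)) / 2.0)
            p_un = 2.0 * sps.t.sf(abs(est) / se_t, dfw)
            p_adj = float(sps.studentized_range.sf(q, k, dfw))
            p_adj = min(max(p_adj, 0.0), 1.0)
            rows.append(
                (
                    f"{names[i]} vs {names[j]}",
                    names[i],
                    float(est),
                    float(q),
                    float(p_un),
                    p_adj,
                    stars(p_adj),
                )
            )
    comp = pd.DataFrame(
        rows,
        columns=[
            "comparison",
            "group",
            "estimate",
            "statistic",
            "p_unadj",
            "p_adj",
            "stars",
        ],
    )
    return GroupComparison("tukey", gd, None, anova, comp)


def summarize(groups, comparison: GroupComparison | None = None) -> pd.DataFrame:
    """Per-group n, mean and sample SD, with stars vs control when a
    comparison result is supplied."""
    gd = _as_groups(groups)
    star_map = {}
    if comparison is not None:
        star_map = dict(
            zip(comparison.comparisons["group"], comparison.comparisons["stars"])
        )
    rows = []
    for name, v in gd.items():
        if len(v) < 1:
            raise ValueError("empty group")
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        rows.append((name, len(v), float(v.mean()), sd, star_map.get(name, "")))
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sd", "stars"])


def comparison_to_frame(
    comparison: GroupComparison, readout: str = ""
) -> pd.DataFrame:
    """`stats.csv` layout: group summaries merged with adjusted comparisons."""
    summ = summarize(comparison.groups, comparison)
    summ.insert(0, "readout", readout)
    comp = comparison.comparisons.copy()
    merged = summ.merge(
        comp[["group", "comparison", "p_adj"]], on="group", how="left"
    )
    merged["method"] = comparison.method
    return merged[
        ["readout", "group", "n", "mean", "sd", "comparison", "p_adj", "stars", "method"]
    ]
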