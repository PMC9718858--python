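"""Group-level statistical battery with animal-level units.

Main-figure comparisons use one value per animal (the mean over all of
that animal's neurons); the test family is gated by Shapiro-Wilk
normality at alpha = 0.05 (parametric Student's t only when every group
passes, otherwise Mann-Whitney U, exact for small tie-free samples).
Pooled neuron-level rate distributions are compared with the two-sample
Kolmogorov-Smirnov test; the three plaque-distance bins with
Kruskal-Wallis followed by Dunn's pairwise test (tie-corrected, Holm
adjustment); and binned pair correlations with a two-way ANOVA
(distance/rate bin x genotype, type-II sums of squares).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "GroupComparisonResult",
    "choose_test",
    "compare_group_means",
    "compare_rate_distributions",
    "dunn_test",
    "compare_distance_bins",
    "anova_binned_pairs",
    "aggregate_per_animal",
]

ALPHA = 0.05
#: Mann-Whitney uses the exact null distribution up to this per-group n.
EXACT_MW_MAX_N = 10


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of one two-group (or omnibus) comparison."""

    test_name: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    alpha: float = ALPHA
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def choose_test(*groups: np.ndarray, alpha: float = ALPHA) -> str:
    """'parametric' iff every group passes Shapiro-Wilk normality at alpha.

    Groups with n < 3 (or zero variance, for which Shapiro-Wilk is
    undefined) force the nonparametric branch with a warning.
    """
    if len(groups) < 2:
        raise InvalidParameterError("need at least two groups")
    for g in groups:
        x = np.asarray(g, dtype=float)
        if x.size < 3 or np.ptp(x) == 0:
            warnings.warn(
                "group too small or degenerate for normality testing; "
                "falling back to nonparametric",
                stacklevel=2,
            )
            return "nonparametric"
        if scipy.stats.shapiro(x).pvalue <= alpha:
            return "nonparametric"
    return "parametric"


def compare_group_means(
    wt: np.ndarray,
    app: np.ndarray,
    force: str | None = None,
    exact_max_n: int = EXACT_MW_MAX_N,
) -> GroupComparisonResult:
    """Two-tailed WT-vs-APP comparison of per-animal means.

    Normality-gated: Student's t when both groups look Gaussian,
    otherwise Mann-Whitney U (exact null for tie-free groups of at most
    ``exact_max_n`` animals, the study's regime of 5-9 mice per group).
    """
    x = np.asarray(wt, dtype=float)
    y = np.asarray(app, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidParameterError("both groups must be non-empty")
    kind = force or choose_test(x, y)
    if kind == "parametric":
        res = scipy.stats.ttest_ind(x, y)
        return GroupComparisonResult(
            "student_t", float(res.statistic), float(res.pvalue), (x.size, y.size)
        )
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= exact_max_n and not has_ties) else "auto"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparisonResult(
        "mann_whitney_u",
        float(res.statistic),
        float(res.pvalue),
        (x.size, y.size),
        extra={"method": method},
    )


def compare_rate_distributions(
    wt_rates: np.ndarray, app_rates: np.ndarray
) -> GroupComparisonResult:
    """Two-sample KS test on pooled neuron-level event rates."""
    x = np.asarray(wt_rates, dtype=float)
    y = np.asarray(app_rates, dtype=float)
    if x.size < 5 or y.size < 5:
        raise InvalidParameterError("need >= 5 neurons per group for the KS test")
    res = scipy.stats.ks_2samp(x, y)
    return GroupComparisonResult(
        "ks_2samp", float(res.statistic), float(res.pvalue), (x.size, y.size)
    )


def dunn_test(
    groups: dict[str, np.ndarray], p_adjust: str = "holm"
) -> pd.DataFrame:
    """Dunn's pairwise rank comparison after a Kruskal-Wallis omnibus.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    with the tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided
    normal p-values adjusted for multiplicity (Holm by default).
    """
    names = list(groups)
    if len(names) < 2:
        raise InvalidParameterError("need at least two groups")
    sizes = {k: np.asarray(v, dtype=float).size for k, v in groups.items()}
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in names])
    n_total = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for k in names:
        mean_ranks[k] = ranks[start : start + sizes[k]].mean()
        start += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            i, j = names[a], names[b]
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else np.nan
            p = 2.0 * scipy.stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({"group_a": i, "group_b": j, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_raw"].to_numpy(), method=p_adjust)[1]
    return out


def compare_distance_bins(
    groups: dict[str, np.ndarray], p_adjust: str = "holm"
) -> tuple[GroupComparisonResult, pd.DataFrame]:
    """Kruskal-Wallis omnibus across distance bins plus Dunn post hocs."""
    nonempty = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v)}
    if len(nonempty) < 3:
        raise InvalidParameterError("need 3 non-empty groups")
    if any(v.size < 2 for v in nonempty.values()):
        raise InvalidParameterError("each group needs n >= 2")
    h, p = scipy.stats.kruskal(*nonempty.values())
    omnibus = GroupComparisonResult(
        "kruskal_wallis", float(h), float(p), tuple(v.size for v in nonempty.values())
    )
    return omnibus, dunn_test(nonempty, p_adjust=p_adjust)


def anova_binned_pairs(df: pd.DataFrame, value: str = "rho",
                       factor: str = "bin") -> pd.DataFrame:
    """Two-way ANOVA of binned pair correlations: factor x genotype.

    Type-II sums of squares on a fully crossed design; raises on empty
    cells or a saturated design with no residual degrees of freedom.
    Returns a table with F and p for the factor, genotype and their
    interaction.
    """
    for col in (value, factor, "genotype"):
        if col not in df.columns:
            raise InvalidInputError(f"missing column {col!r}")
    data = df.dropna(subset=[value]).copy()
    if data[factor].nunique() < 2 or data["genotype"].nunique() < 2:
        raise InvalidParameterError("need >= 2 levels per factor")
    cells = data.groupby([factor, "genotype"], observed=True).size()
    full = data[factor].nunique() * data["genotype"].nunique()
    if len(cells) < full:
        raise InvalidParameterError("empty factor cell; unbalanced design unsupported")
    if len(data) <= full:
        raise InvalidParameterError("no residual degrees of freedom (1 obs per cell)")
    model = smf.ols(f"{value} ~ C(Q('{factor}')) * C(genotype)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            f"C(Q('{factor}'))": factor,
            "C(genotype)": "genotype",
            f"C(Q('{factor}')):C(genotype)": f"{factor}:genotype",
        }
    )
    return table


def aggregate_per_animal(
    neurons: pd.DataFrame, value: str = "rate_hz"
) -> pd.DataFrame:
    """One mean per animal over all its neurons (FOVs pooled equally).

    Every neuron weighs equally within its animal regardless of which
    FOV it came from.  Requires an ``animal_id`` tag on every row.
    """
    if "animal_id" not in neurons.columns or neurons["animal_id"].isna().any():
        raise InvalidInputError("every neuron must carry an animal_id tag")
    keep = [c for c in ("genotype", "cell_type") if c in neurons.columns]
    agg = {value: "mean", **{c: "first" for c in keep}}
    out = neurons.groupby("animal_id", sort=True).agg(agg).reset_index()
    return out.rename(columns={value: f"mean_{value}"})
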