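"""Normality-routed group comparison of per-ROI texture features.

The statistical stage mirrors a conventional dermatology-imaging workflow:
per-group Shapiro-Wilk normality checks route each feature either to
one-way ANOVA (all groups normal at alpha) or to the Kruskal-Wallis rank
test; a significant omnibus test is followed by pairwise post-hoc
comparisons (Tukey HSD after ANOVA, Dunn's z-test with Bonferroni
correction after Kruskal-Wallis), from which an ordering string such as
``"MM > DN > BN"`` is assembled when all pairwise differences at alpha are
consistent.  Two-group inputs degenerate to Student's t / Mann-Whitney U
under the same router.

Dunn's test is implemented here (rank sums with tie correction); Tukey HSD
comes from statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

FEATURE_COLUMNS = ["LngREmph", "Entropy", "DifEntrp", "TI", "BI"]


@dataclass(frozen=True)
class GroupSample:
    """Per-ROI values of one feature for one lesion group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError(f"group {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PairwiseComparison:
    a: str
    b: str
    p_adjusted: float
    direction: str  # ">", "<" (central tendency of a vs b)

    @property
    def as_text(self) -> str:
        return f"{self.a} {self.direction} {self.b}"


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one omnibus comparison with optional post-hoc detail."""

    feature: str
    test_used: str  # anova | kruskal_wallis | t_test | mann_whitney
    p_value: float
    pairwise: tuple[PairwiseComparison, ...] = ()
    ordering: str = "n.s."
    posthoc: str = "none"
    lighting: str = ""
    normality_p: dict = field(default_factory=dict)


def test_normality(sample: GroupSample | Sequence[float]) -> float:
    """Shapiro-Wilk p-value for one group (3 <= n <= 5000)."""
    values = sample.values if isinstance(sample, GroupSample) else np.asarray(sample, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={values.size}")
    return float(stats.shapiro(values).pvalue)


def _dunn_bonferroni(samples: Sequence[GroupSample]) -> list[PairwiseComparison]:
    """Dunn's pairwise z-test on joint ranks, Bonferroni-adjusted.

    Uses the tie-corrected variance of mean-rank differences:
    SE^2 = [N(N+1)/12 - T/(12(N-1))] (1/n_a + 1/n_b) with
    T = sum(t^3 - t) over tie groups.
    """
    values = np.concatenate([s.values for s in samples])
    labels = np.concatenate([[s.label] * s.n for s in samples])
    ranks = stats.rankdata(values)
    n_total = values.size
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    mean_ranks = {s.label: float(ranks[labels == s.label].mean()) for s in samples}
    ns = {s.label: s.n for s in samples}
    pairs = list(combinations([s.label for s in samples], 2))
    out = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / ns[a] + 1.0 / ns[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out.append(
            PairwiseComparison(
                a=a,
                b=b,
                p_adjusted=float(min(1.0, p * len(pairs))),
                direction=">" if mean_ranks[a] > mean_ranks[b] else "<",
            )
        )
    return out


def _tukey_hsd(samples: Sequence[GroupSample], alpha: float) -> list[PairwiseComparison]:
    values = np.concatenate([s.values for s in samples])
    labels = np.concatenate([[s.label] * s.n for s in samples])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    means = {s.label: float(s.values.mean()) for s in samples}
    pairs = list(combinations(res.groupsunique, 2))
    out = []
    for (a, b), p in zip(pairs, np.atleast_1d(res.pvalues)):
        out.append(
            PairwiseComparison(
                a=str(a),
                b=str(b),
                p_adjusted=float(p),
                direction=">" if means[str(a)] > means[str(b)] else "<",
            )
        )
    return out


# display order for ordering strings: most to least advanced lesion, the
# convention of clinical texture tables ("MM > DN > BN" / "MM < DN < BN")
_DISPLAY_ORDER = ["MM", "invasive", "DN", "in_situ", "BN"]


def _display_rank(label: str) -> tuple[int, str]:
    try:
        return (_DISPLAY_ORDER.index(label), label)
    except ValueError:
        return (len(_DISPLAY_ORDER), label)


def _ordering_string(
    samples: Sequence[GroupSample],
    pairwise: Sequence[PairwiseComparison],
    alpha: float,
    use_ranks: bool,
) -> str:
    """Total order like ``"MM > DN > BN"`` (or ``"MM < DN < BN"``) when
    every pair separates at alpha; otherwise the significant pairs;
    ``"n.s."`` if none do.  Groups are listed most-advanced-lesion first."""
    if use_ranks:
        values = np.concatenate([s.values for s in samples])
        ranks = stats.rankdata(values)
        offs = np.cumsum([0] + [s.n for s in samples])
        center = {s.label: float(ranks[offs[i]:offs[i + 1]].mean())
                  for i, s in enumerate(samples)}
    else:
        center = {s.label: float(s.values.mean()) for s in samples}
    sig = [pc for pc in pairwise if pc.p_adjusted < alpha]
    if not sig:
        return "n.s."
    if len(sig) == len(pairwise):
        display = sorted(center, key=_display_rank)
        centers = [center[g] for g in display]
        if all(a > b for a, b in zip(centers, centers[1:])):
            return " > ".join(display)
        if all(a < b for a, b in zip(centers, centers[1:])):
            return " < ".join(display)
        order = sorted(center, key=center.get, reverse=True)
        return " > ".join(order)
    lines = []
    for pc in sig:
        a, b = sorted((pc.a, pc.b), key=_display_rank)
        cmp = ">" if center[a] > center[b] else "<"
        lines.append(f"{a} {cmp} {b}")
    return "; ".join(lines)


def compare_groups(
    samples: Sequence[GroupSample],
    alpha: float = 0.05,
    feature: str = "",
    lighting: str = "",
) -> ComparisonResult:
    """Normality-routed omnibus comparison with post-hoc orderings.

    ANOVA (with Tukey HSD post-hoc) is used iff every group passes
    Shapiro-Wilk at ``alpha``; otherwise Kruskal-Wallis (with Dunn's test,
    Bonferroni-corrected).  Two groups degenerate to t-test / Mann-Whitney.
    Post-hoc comparisons run only when the omnibus p-value is below alpha.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels: {labels}")
    for s in samples:
        if s.n < 3:
            raise ValueError(f"group {s.label!r} has n={s.n} < 3")
    normality = {s.label: test_normality(s) for s in samples}
    all_normal = all(p > alpha for p in normality.values())
    arrays = [s.values for s in samples]

    if len(samples) == 2:
        if all_normal:
            test_used = "t_test"
            p = float(stats.ttest_ind(*arrays).pvalue)
        else:
            test_used = "mann_whitney"
            p = float(stats.mannwhitneyu(*arrays, alternative="two-sided").pvalue)
    elif all_normal:
        test_used = "anova"
        p = float(stats.f_oneway(*arrays).pvalue)
    else:
        test_used = "kruskal_wallis"
        p = float(stats.kruskal(*arrays).pvalue)

    pairwise: list[PairwiseComparison] = []
    ordering = "n.s."
    posthoc = "none"
    use_ranks = test_used in ("kruskal_wallis", "mann_whitney")
    if p < alpha:
        if len(samples) == 2:
            a, b = samples
            if use_ranks:
                ca = float(stats.rankdata(np.concatenate(arrays))[: a.n].mean())
                cb = float(stats.rankdata(np.concatenate(arrays))[a.n :].mean())
            else:
                ca, cb = float(a.values.mean()), float(b.values.mean())
            pairwise = [PairwiseComparison(a.label, b.label, p, ">" if ca > cb else "<")]
            posthoc = "omnibus"
        elif test_used == "anova":
            pairwise = _tukey_hsd(samples, alpha)
            posthoc = "tukey_hsd"
        else:
            pairwise = _dunn_bonferroni(samples)
            posthoc = "dunn_bonferroni"
        ordering = _ordering_string(samples, pairwise, alpha, use_ranks)
    return ComparisonResult(
        feature=feature,
        test_used=test_used,
        p_value=p,
        pairwise=tuple(pairwise),
        ordering=ordering,
        posthoc=posthoc,
        lighting=lighting,
        normality_p=normality,
    )


def compare_two_groups(
    a: GroupSample, b: GroupSample, alpha: float = 0.05, feature: str = "", lighting: str = ""
) -> ComparisonResult:
    """Two-group router: t-test when both groups are normal, else
    Mann-Whitney U (e.g. melanoma in situ vs invasive)."""
    return compare_groups([a, b], alpha=alpha, feature=feature, lighting=lighting)


def _group_samples(df: pd.DataFrame, feature: str) -> list[GroupSample]:
    order = ["BN", "DN", "MM"]
    present = [g for g in order if g in set(df["group_label"])]
    present += [g for g in sorted(set(df["group_label"])) if g not in present]
    return [
        GroupSample(g, df.loc[df["group_label"] == g, feature].to_numpy())
        for g in present
    ]


def analyze_features(df: pd.DataFrame, alpha: float = 0.05) -> list[ComparisonResult]:
    """Run the full comparison grid: every feature within every lighting mode."""
    results = []
    for lighting in sorted(df["lighting"].unique()):
        sub = df[df["lighting"] == lighting]
        for feature in FEATURE_COLUMNS:
            results.append(
                compare_groups(
                    _group_samples(sub, feature), alpha=alpha,
                    feature=feature, lighting=str(lighting),
                )
            )
    return results


def group_statistics(df: pd.DataFrame) -> pd.DataFrame:
    """Per (lighting, group, feature) mean, SD (sample) and n."""
    rows = []
    for (lighting, group), sub in df.groupby(["lighting", "group_label"]):
        for feature in FEATURE_COLUMNS:
            v = sub[feature].to_numpy()
            rows.append(
                {
                    "lighting": lighting,
                    "group_label": group,
                    "feature": feature,
                    "n": v.size,
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def summarize_table(
    results: Sequence[ComparisonResult],
    group_stats: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Assemble the machine-readable report from comparisons + group stats.

    Requires one comparison per feature per lighting mode present in
    ``group_stats``; raises if any combination is missing.
    """
    lightings = sorted(group_stats["lighting"].unique())
    have = {(r.lighting, r.feature) for r in results}
    missing = [
        (lg, ft) for lg in lightings for ft in FEATURE_COLUMNS if (lg, ft) not in have
    ]
    if missing:
        raise ValueError(f"missing feature/lighting comparisons: {missing}")
    comparisons = []
    for r in results:
        gs = group_stats[
            (group_stats["lighting"] == r.lighting) & (group_stats["feature"] == r.feature)
        ]
        comparisons.append(
            {
                "lighting": r.lighting,
                "feature": r.feature,
                "test": r.test_used,
                "posthoc": r.posthoc,
                "p_value": r.p_value,
                "significant": bool(r.p_value < alpha),
                "ordering": r.ordering,
                "groups": {
                    rec.group_label: {"n": int(rec.n), "mean": rec.mean, "sd": rec.sd}
                    for rec in gs.itertuples(index=False)
                },
                "pairwise": [
                    {"a": pc.a, "b": pc.b, "p_adjusted": pc.p_adjusted,
                     "direction": pc.direction}
                    for pc in r.pairwise
                ],
            }
        )
    return {"alpha": alpha, "comparisons": comparisons}


def render_report_markdown(report: dict) -> str:
    """Human-readable table: per-group mean +/- SD, omnibus p, orderings."""
    lines = ["# Texture feature group comparison", ""]
    by_lighting: dict[str, list[dict]] = {}
    for comp in report["comparisons"]:
        by_lighting.setdefault(comp["lighting"], []).append(comp)
    for lighting, comps in by_lighting.items():
        lines.append(f"## {lighting} light")
        lines.append("")
        groups = sorted({g for c in comps for g in c["groups"]})
        header = ["Feature"] + groups + ["test", "p", "ordering"]
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        for c in comps:
            cells = [c["feature"]]
            for g in groups:
                st = c["groups"].get(g)
                cells.append(f"{st['mean']:.3g} ± {st['sd']:.3g}" if st else "—")
            note = c["ordering"] if c["significant"] else "n.s."
            cells += [c["test"], f"{c['p_value']:.3g}", note]
            lines.append("| " + " | ".join(cells) + " |")
        lines.append("")
    return "\n".join(lines)
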