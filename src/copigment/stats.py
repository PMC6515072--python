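"""Group-comparison decision tree and PCA of the color variables.

The decision tree mirrors a standard analytical-chemistry workflow:
Shapiro-Wilk on pooled model residuals plus Levene's test select between
a parametric branch (one-way ANOVA with Tukey HSD) and a nonparametric
branch (Kruskal-Wallis with pairwise rank-sum tests, Holm-adjusted).
Groups are summarised by a compact letter display: groups sharing a
letter are not significantly different post hoc at the chosen alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

__all__ = [
    "BranchDecision",
    "ComparisonResult",
    "PCAResult",
    "choose_branch",
    "compare_groups",
    "compact_letters",
    "run_pca",
]


@dataclass(frozen=True)
class BranchDecision:
    branch: str  # 'parametric' | 'nonparametric'
    shapiro_p: float
    levene_p: float
    flags: frozenset = frozenset()


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError(f"group {label!r} needs at least 2 replicate values")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite value in group {label!r}")
        out[str(label)] = arr
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def choose_branch(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    levene_center: str = "mean",
) -> BranchDecision:
    """Choose parametric vs nonparametric testing for a set of groups.

    Normality is assessed by Shapiro-Wilk on pooled residuals (values
    minus their group mean) — per-group testing at n = 3 would be vacuous
    — and homoscedasticity by Levene's test (classic mean-centered form by
    default).  The parametric branch requires both p-values >= alpha.
    Degenerate inputs (a zero-variance group, or any group with n < 3)
    force the nonparametric branch with an explanatory flag.
    """
    g = _as_groups(groups)
    flags = set()
    if any(np.ptp(v) == 0.0 for v in g.values()):
        flags.add("zero_variance_group")
    if any(v.size < 3 for v in g.values()):
        flags.add("group_too_small_for_normality_test")
    if flags:
        return BranchDecision("nonparametric", np.nan, np.nan, frozenset(flags))
    residuals = np.concatenate([v - v.mean() for v in g.values()])
    shapiro_p = float(sps.shapiro(residuals).pvalue)
    levene_p = float(sps.levene(*g.values(), center=levene_center).pvalue)
    branch = "parametric" if (shapiro_p >= alpha and levene_p >= alpha) else "nonparametric"
    return BranchDecision(branch, shapiro_p, levene_p, frozenset(flags))


def _tukey_pvalues(g: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """All-pairs Tukey HSD p-values from the studentized range distribution."""
    labels = list(g)
    k = len(labels)
    ns = {l: g[l].size for l in labels}
    df = sum(ns.values()) - k
    mse = sum(float(np.sum((g[l] - g[l].mean()) ** 2)) for l in labels) / df
    out = {}
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0.0:
            out[(a, b)] = 1.0 if g[a].mean() == g[b].mean() else 0.0
            continue
        q = abs(g[a].mean() - g[b].mean()) / se
        out[(a, b)] = float(studentized_range.sf(q, k, df))
    return out


def _holm(pvalues: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    pairs = sorted(pvalues, key=pvalues.get)
    m = len(pairs)
    adj, running = {}, 0.0
    for i, pair in enumerate(pairs):
        running = max(running, min(1.0, (m - i) * pvalues[pair]))
        adj[pair] = running
    return adj


def compact_letters(
    labels: Sequence[str],
    pairwise_p: Mapping[tuple[str, str], float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Groups sharing a letter are not significantly different (adjusted
    p >= alpha for every pair inside the letter's set).
    """
    def p_of(a: str, b: str) -> float:
        return pairwise_p.get((a, b), pairwise_p.get((b, a), 1.0))

    letter_sets: list[set[str]] = [set(labels)]
    for a, b in itertools.combinations(labels, 2):
        if p_of(a, b) >= alpha:
            continue
        for s in [s for s in letter_sets if a in s and b in s]:
            letter_sets.remove(s)
            for dropped in (a, b):
                new = s - {dropped}
                # absorb: keep only maximal sets
                if new and not any(new <= other for other in letter_sets):
                    letter_sets.append(new)
    # stable letter assignment: order sets by first group appearance
    order = {l: i for i, l in enumerate(labels)}
    letter_sets.sort(key=lambda s: min(order[l] for l in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    display = {l: "" for l in labels}
    for i, s in enumerate(letter_sets):
        ch = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for l in labels:
            if l in s:
                display[l] += ch
    return display


@dataclass(frozen=True)
class ComparisonResult:
    branch: str
    shapiro_p: float
    levene_p: float
    omnibus_test: str
    omnibus_p: float
    posthoc_test: str
    pairwise_p: Mapping[tuple[str, str], float]  # adjusted
    letters: Mapping[str, str]
    alpha: float
    flags: frozenset = frozenset()

    def any_significant(self) -> bool:
        return any(p < self.alpha for p in self.pairwise_p.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group_a": a, "group_b": b, "p_adjusted": p}
            for (a, b), p in self.pairwise_p.items()
        ]
        return pd.DataFrame(rows)


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    branch: Optional[str] = None,
    alpha: float = 0.05,
    p_adjust: str = "holm",
    levene_center: str = "mean",
) -> ComparisonResult:
    """Omnibus test plus all-pairs post hoc with a compact letter display.

    Parametric branch: one-way ANOVA and Tukey HSD (inherently multiplicity
    adjusted).  Nonparametric branch: Kruskal-Wallis and pairwise two-sided
    rank-sum (Mann-Whitney) tests with Holm adjustment (``p_adjust='none'``
    disables adjustment).  If ``branch`` is None the decision tree of
    :func:`choose_branch` is applied.
    """
    g = _as_groups(groups)
    labels = list(g)
    if branch is None:
        decision = choose_branch(g, alpha=alpha, levene_center=levene_center)
    else:
        if branch not in ("parametric", "nonparametric"):
            raise ValueError("branch must be 'parametric' or 'nonparametric'")
        decision = BranchDecision(branch, np.nan, np.nan)
    flags = set(decision.flags)

    degenerate = np.ptp(np.concatenate(list(g.values()))) == 0.0
    if decision.branch == "parametric":
        omnibus_test, posthoc_test = "anova", "tukey_hsd"
        omnibus_p = float(sps.f_oneway(*g.values()).pvalue)
        pairwise = _tukey_pvalues(g)
    else:
        omnibus_test, posthoc_test = "kruskal_wallis", f"pairwise_ranksum_{p_adjust}"
        if degenerate:
            # identical constant data: no evidence of any difference
            omnibus_p = 1.0
            pairwise = {p: 1.0 for p in itertools.combinations(labels, 2)}
            flags.add("all_values_identical")
        else:
            try:
                omnibus_p = float(sps.kruskal(*g.values()).pvalue)
            except ValueError:  # all numbers identical
                omnibus_p = 1.0
                flags.add("all_values_identical")
            raw = {}
            for a, b in itertools.combinations(labels, 2):
                if np.ptp(np.concatenate([g[a], g[b]])) == 0.0:
                    raw[(a, b)] = 1.0
                else:
                    raw[(a, b)] = float(
                        sps.mannwhitneyu(g[a], g[b], alternative="two-sided").pvalue
                    )
            pairwise = _holm(raw) if p_adjust == "holm" else raw
    letters = compact_letters(labels, pairwise, alpha=alpha)
    return ComparisonResult(
        branch=decision.branch,
        shapiro_p=decision.shapiro_p,
        levene_p=decision.levene_p,
        omnibus_test=omnibus_test,
        omnibus_p=omnibus_p,
        posthoc_test=posthoc_test,
        pairwise_p=pairwise,
        letters=letters,
        alpha=alpha,
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA: standardized loadings, scores and
    explained-variance fractions."""

    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # observations x components
    explained_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def run_pca(table: pd.DataFrame) -> PCAResult:
    """PCA of standardized variables (correlation structure).

    Each column is centered and scaled to unit variance, then decomposed
    by SVD.  Sign convention: within each component the largest-magnitude
    loading is made positive, so results are deterministic.  A
    zero-variance column raises, naming the column.
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("PCA needs at least 2 observations and 2 variables")
    x = table.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("PCA input contains non-finite values")
    std = x.std(axis=0, ddof=1)
    dead = np.where(std == 0.0)[0]
    if dead.size:
        names = ", ".join(str(table.columns[i]) for i in dead)
        raise ValueError(f"zero-variance variable(s): {names}")
    z = (x - x.mean(axis=0)) / std
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    explained = s**2 / float(np.sum(s**2))
    comp = [f"PC{i + 1}" for i in range(vt.shape[0])]
    loadings = pd.DataFrame(vt.T, index=table.columns, columns=comp)
    scores = pd.DataFrame(u * s, index=table.index, columns=comp)
    return PCAResult(loadings=loadings, scores=scores, explained_fraction=explained)
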