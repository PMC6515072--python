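"""Copigmentation statistics: blank subtraction, dose-ratio series,
effectiveness (Cp) slopes, effect classification, best-copigment counting
and family aggregation.

The effectiveness of a copigment is the slope of a color parameter
(A520 or a CIELAB quantity) regressed on the copigment/pigment mass
ratio.  For A520, a* and C*ab a larger slope means a larger impact on
color; for L*, b* and hab a smaller (more negative) slope does.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .colorimetry import (
    COLOR_PARAMETERS,
    ColorCoordinates,
    GridMismatchError,
    Spectrum,
)

__all__ = [
    "DIRECTION_RULE",
    "EffectDirectionRule",
    "RatioSeries",
    "CpResult",
    "EffectLabels",
    "BestCount",
    "subtract_blank",
    "mass_ratio",
    "estimate_cp",
    "classify_effects",
    "best_copigment_count",
    "aggregate_family",
]


@dataclass(frozen=True)
class EffectDirectionRule:
    """Orientation of each color parameter: does a larger or a smaller
    Cp indicate a greater impact on color?"""

    higher_is_better: frozenset = frozenset({"A520", "a*", "C*ab"})
    lower_is_better: frozenset = frozenset({"L*", "b*", "hab"})

    def __post_init__(self) -> None:
        both = self.higher_is_better | self.lower_is_better
        if both != set(COLOR_PARAMETERS) or (
            self.higher_is_better & self.lower_is_better
        ):
            raise ValueError(
                "direction rule must cover each of the six parameters exactly once"
            )

    def orientation(self, parameter: str) -> int:
        """+1 if larger Cp means greater impact, -1 if smaller does."""
        if parameter in self.higher_is_better:
            return 1
        if parameter in self.lower_is_better:
            return -1
        raise KeyError(f"unknown color parameter {parameter!r}")


#: Default orientation: higher Cp better for A520, a*, C*ab; lower for L*, b*, hab.
DIRECTION_RULE = EffectDirectionRule()


def subtract_blank(mix: Spectrum, blank: Spectrum) -> Spectrum:
    """Subtract the copigment-only blank from the mix spectrum, pointwise.

    Both spectra must be on the identical wavelength grid and share
    condition metadata (copigment, dose, pH, ethanol).  The result has
    role ``corrected`` and carries a ``negative_absorbance`` flag if the
    subtraction went below zero anywhere.
    """
    if mix.meta.condition_key() != blank.meta.condition_key():
        raise ValueError(
            f"metadata mismatch between mix {mix.sample_id!r} "
            f"{mix.meta.condition_key()} and blank {blank.sample_id!r} "
            f"{blank.meta.condition_key()}"
        )
    if mix.wavelengths.size != blank.wavelengths.size or not np.allclose(
        mix.wavelengths, blank.wavelengths
    ):
        raise GridMismatchError(
            f"mix {mix.sample_id!r} and blank {blank.sample_id!r} are on "
            f"different wavelength grids; resample both first"
        )
    corrected = mix.absorbance - blank.absorbance
    out = replace(
        mix,
        absorbance=corrected,
        meta=replace(mix.meta, role="corrected"),
    )
    if np.any(corrected < 0):
        out = out.with_flags("negative_absorbance")
    return out


def mass_ratio(copigment_dose_g_per_l: float, pigment_mg_per_l: float) -> float:
    """Copigment/pigment mass-concentration ratio.

    The dose is in g/L and the pigment concentration in mg/L, so
    0.1 g/L over 50 mg/L gives ratio 2.
    """
    if pigment_mg_per_l <= 0:
        raise ValueError("pigment concentration must be > 0")
    if copigment_dose_g_per_l < 0:
        raise ValueError("copigment dose must be >= 0")
    return copigment_dose_g_per_l * 1000.0 / pigment_mg_per_l


@dataclass
class RatioSeries:
    """Color coordinates across copigment/pigment ratios for one
    copigment under one condition.

    ``replicates`` maps replicate index -> {ratio -> ColorCoordinates};
    ratio 0 is the pigment-only control.
    """

    copigment: str
    family: str
    ph: float
    ethanol_pct: float
    pigment_mg_per_l: float
    replicates: dict = field(default_factory=dict)

    def add(self, replicate: int, ratio: float, color: ColorCoordinates) -> None:
        if ratio < 0:
            raise ValueError("ratios must be nonnegative")
        self.replicates.setdefault(replicate, {})[ratio] = color

    def points(self, parameter: str):
        """Yield (replicate, ratios, values) triples for one parameter.

        NaN values (undefined hue of achromatic points) are dropped with a
        warning rather than imputed.
        """
        for rep in sorted(self.replicates):
            items = sorted(self.replicates[rep].items())
            ratios = np.array([r for r, _ in items], dtype=float)
            values = np.array([c.parameter(parameter) for _, c in items])
            keep = np.isfinite(values)
            if not keep.all():
                warnings.warn(
                    f"dropping {int((~keep).sum())} undefined {parameter} "
                    f"value(s) for {self.copigment!r} replicate {rep}",
                    stacklevel=2,
                )
            yield rep, ratios[keep], values[keep]


@dataclass(frozen=True)
class CpResult:
    """Slope-based copigmentation effectiveness for one color parameter.

    ``cp`` is the mean of per-replicate OLS slopes of the parameter on the
    mass ratio; ``sd`` the sample standard deviation of those slopes;
    ``r2`` the coefficient of determination of the pooled fit (NaN marks
    the degenerate zero-variance case).
    """

    parameter: str
    cp: float
    intercept: float
    r2: float
    sd: float
    n_replicates: int
    flags: frozenset = frozenset()


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept via the normal equations."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise ValueError("all ratios identical; slope undefined")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    return slope, float(ym - slope * xm)


def estimate_cp(series: RatioSeries, parameter: str) -> CpResult:
    """Estimate Cp for one color parameter of a ratio series.

    Per replicate: OLS of the parameter value on the ratio, free intercept,
    with the ratio-0 control included.  Cp is the mean of replicate slopes
    and sd their sample standard deviation; r-squared comes from a single
    pooled fit over all replicates.
    """
    if parameter not in COLOR_PARAMETERS:
        raise KeyError(f"unknown color parameter {parameter!r}")
    slopes = []
    all_x, all_y = [], []
    flags = set()
    for rep, x, y in series.points(parameter):
        if np.unique(x).size < 2:
            raise ValueError(
                f"replicate {rep} of {series.copigment!r} has fewer than 2 "
                f"distinct ratios; cannot fit a slope"
            )
        slope, _ = _ols_slope(x, y)
        slopes.append(slope)
        all_x.append(x)
        all_y.append(y)
    if not slopes:
        raise ValueError(f"no usable replicates for parameter {parameter!r}")
    x = np.concatenate(all_x)
    y = np.concatenate(all_y)
    pooled_slope, intercept = _ols_slope(x, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # constant response: slope 0 by construction, r2 undefined
        r2 = math.nan
        flags.add("degenerate_r2")
    else:
        resid = y - (intercept + pooled_slope * x)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    cp = float(np.mean(slopes))
    sd = float(np.std(slopes, ddof=1)) if len(slopes) > 1 else 0.0
    if len(slopes) == 1:
        flags.add("single_replicate")
    return CpResult(
        parameter=parameter,
        cp=cp,
        intercept=intercept,
        r2=r2,
        sd=sd,
        n_replicates=len(slopes),
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class EffectLabels:
    """Hyper/hypochromic and batho/hypsochromic classification of a set of
    Cp values, with the underlying magnitudes."""

    hyperchromic: bool
    hypochromic: bool
    bathochromic: bool
    hypsochromic: bool
    magnitudes: Mapping[str, float]


def classify_effects(cp_by_parameter: Mapping[str, "CpResult | float"]) -> EffectLabels:
    """Classify the color effect from Cp values of the six parameters.

    Hyperchromic: Cp(A520) > 0 and Cp(L*) < 0 (more color, darker);
    hypochromic is the sign reversal.  Bathochromic: Cp(b*) < 0 (shift
    toward blue); hypsochromic: Cp(b*) > 0.
    """
    cp = {}
    for name in COLOR_PARAMETERS:
        if name not in cp_by_parameter:
            raise KeyError(f"missing Cp for parameter {name!r}")
        value = cp_by_parameter[name]
        cp[name] = value.cp if isinstance(value, CpResult) else float(value)
    return EffectLabels(
        hyperchromic=cp["A520"] > 0 and cp["L*"] < 0,
        hypochromic=cp["A520"] < 0 and cp["L*"] > 0,
        bathochromic=cp["b*"] < 0,
        hypsochromic=cp["b*"] > 0,
        magnitudes=cp,
    )


@dataclass(frozen=True)
class BestCount:
    """Win tally for one focal copigment over condition x parameter cells."""

    copigment: str
    wins: int
    ties: int
    total: int

    @property
    def fraction(self) -> float:
        return self.wins / self.total


def best_copigment_count(
    cp_table: pd.DataFrame,
    focal: str,
    rule: EffectDirectionRule = DIRECTION_RULE,
    condition: str = "condition",
) -> BestCount:
    """Count the condition x parameter cells where ``focal`` is strictly best.

    ``cp_table`` is tidy with columns [condition, 'copigment', 'parameter',
    'cp'].  In each cell the focal copigment wins iff its Cp is strictly
    better than every competitor under the rule's orientation; exact ties
    are counted as non-wins and reported separately.  The table must be
    complete over conditions x copigments x parameters.
    """
    required = {condition, "copigment", "parameter", "cp"}
    if not required.issubset(cp_table.columns):
        raise ValueError(f"cp table must have columns {sorted(required)}")
    copigments = sorted(cp_table["copigment"].unique())
    if focal not in copigments:
        raise ValueError(f"focal copigment {focal!r} not present in table")
    wins = ties = total = 0
    grouped = cp_table.groupby([condition, "parameter"])
    expected_cells = (
        cp_table[condition].nunique() * cp_table["parameter"].nunique()
    )
    if len(grouped) != expected_cells:
        raise ValueError("cp table is not complete over conditions x parameters")
    for (cond, parameter), cell in grouped:
        if sorted(cell["copigment"]) != copigments:
            raise ValueError(
                f"missing copigment entries in cell ({cond!r}, {parameter!r})"
            )
        oriented = cell.set_index("copigment")["cp"] * rule.orientation(parameter)
        total += 1
        best = oriented.max()
        if oriented[focal] == best:
            if (oriented == best).sum() > 1:
                ties += 1  # tie broken against the focal copigment
            else:
                wins += 1
    return BestCount(copigment=focal, wins=wins, ties=ties, total=total)


@dataclass(frozen=True)
class FamilyAggregate:
    """Mean +/- sample SD at one level of the product/origin/family tree."""

    level: str  # 'product' | 'origin' | 'family'
    name: str
    mean: float
    sd: float
    n: int
    singleton: bool = False


def aggregate_family(
    values: pd.DataFrame,
    value: str = "value",
) -> pd.DataFrame:
    """Two-level aggregation of per-product values into origin and family rows.

    ``values`` is tidy with columns ['family', 'origin', 'product', value].
    Origin aggregate: mean +/- sample SD (n-1) of its product values.
    Family aggregate: mean +/- sample SD of its *origin means* (unweighted
    two-level convention).  Singleton groups get SD = 0 and a flag.
    """
    required = {"family", "origin", "product", value}
    if not required.issubset(values.columns):
        raise ValueError(f"need columns {sorted(required)}")
    if values.empty:
        raise ValueError("empty value table")
    origin_to_family = values.drop_duplicates("origin").set_index("origin")["family"]
    if values.groupby("product")["origin"].nunique().max() > 1:
        raise ValueError("each product must belong to exactly one origin")
    if values.groupby("origin")["family"].nunique().max() > 1:
        raise ValueError("each origin must belong to exactly one family")

    rows = []
    origin_means: dict[str, list[float]] = {}
    for origin, grp in values.groupby("origin", sort=False):
        vals = grp[value].to_numpy(dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            FamilyAggregate("origin", origin, mean, sd, vals.size, vals.size == 1)
        )
        origin_means.setdefault(origin_to_family[origin], []).append(mean)
    for fam, means in origin_means.items():
        arr = np.asarray(means)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        rows.append(
            FamilyAggregate("family", fam, float(arr.mean()), sd, arr.size,
                            arr.size == 1)
        )
    return pd.DataFrame(
        {
            "level": [r.level for r in rows],
            "name": [r.name for r in rows],
            "mean": [r.mean for r in rows],
            "sd": [r.sd for r in rows],
            "n": [r.n for r in rows],
            "singleton": [r.singleton for r in rows],
        }
    )
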