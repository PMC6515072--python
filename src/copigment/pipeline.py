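"""End-to-end orchestration: spectra -> colors -> Cp -> stats -> PCA.

``run_pipeline`` is deterministic given the dataset and config: every
output table carries the config hash in a header comment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .colorimetry import (
    COLOR_PARAMETERS,
    ObserverIlluminant,
    default_grid,
    resample_to_grid,
    spectrum_color,
)
from .copigmentation import (
    DIRECTION_RULE,
    RatioSeries,
    classify_effects,
    estimate_cp,
    mass_ratio,
    subtract_blank,
)
from .io import PairedDataset, config_hash, write_table
from .stats import compare_groups, run_pca

__all__ = ["PipelineResult", "build_ratio_series", "color_table", "cp_table",
           "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure with the stage name attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _corrected_colors(
    dataset: PairedDataset, grid: ObserverIlluminant
) -> pd.DataFrame:
    """Colors of blank-corrected mixes and of controls, one row per sample."""
    rows = []
    for _, pair in dataset.pairs.iterrows():
        mix = dataset.spectrum(pair["mix_id"])
        blank = dataset.spectrum(pair["blank_id"])
        corrected = subtract_blank(
            resample_to_grid(mix, grid), resample_to_grid(blank, grid)
        )
        color = spectrum_color(corrected, grid)
        meta = mix.meta
        rows.append(
            {
                "sample_id": mix.sample_id,
                "role": "corrected",
                "copigment": meta.copigment,
                "family": meta.family,
                "dose_g_per_L": meta.dose_g_per_l,
                "ratio": mass_ratio(meta.dose_g_per_l, meta.pigment_mg_per_l),
                "pH": meta.ph,
                "ethanol_pct": meta.ethanol_pct,
                "replicate": meta.replicate,
                "A520": color.a520,
                "L*": color.L,
                "a*": color.a,
                "b*": color.b,
                "hab": color.hab,
                "C*ab": color.C,
                "flags": ";".join(sorted(color.flags)),
            }
        )
    seen = set()
    for _, pair in dataset.pairs.iterrows():
        cid = pair["control_id"]
        if cid in seen:
            continue
        seen.add(cid)
        control = dataset.spectrum(cid)
        color = spectrum_color(control, grid)
        meta = control.meta
        rows.append(
            {
                "sample_id": cid,
                "role": "control",
                "copigment": "",
                "family": "reference",
                "dose_g_per_L": 0.0,
                "ratio": 0.0,
                "pH": meta.ph,
                "ethanol_pct": meta.ethanol_pct,
                "replicate": meta.replicate,
                "A520": color.a520,
                "L*": color.L,
                "a*": color.a,
                "b*": color.b,
                "hab": color.hab,
                "C*ab": color.C,
                "flags": ";".join(sorted(color.flags)),
            }
        )
    return pd.DataFrame(rows)


def color_table(
    dataset: PairedDataset, grid: Optional[ObserverIlluminant] = None
) -> pd.DataFrame:
    """Per-sample color coordinates of corrected mixes and controls."""
    try:
        return _corrected_colors(dataset, grid or default_grid())
    except Exception as exc:  # re-raise with stage context
        raise PipelineError("colorimetry", exc) from exc


def build_ratio_series(colors: pd.DataFrame) -> list[RatioSeries]:
    """Group the color table into per-copigment, per-condition ratio series.

    The ratio-0 entry of every replicate is the pigment-only control of
    the same condition.
    """
    from .colorimetry import ColorCoordinates

    def coords(row) -> ColorCoordinates:
        return ColorCoordinates(
            a520=row["A520"], X=math.nan, Y=math.nan, Z=math.nan,
            L=row["L*"], a=row["a*"], b=row["b*"],
            C=row["C*ab"], hab=row["hab"],
        )

    controls = colors[colors["role"] == "control"]
    mixes = colors[colors["role"] == "corrected"]
    series_list = []
    for (cop, fam, ph, eth), grp in mixes.groupby(
        ["copigment", "family", "pH", "ethanol_pct"]
    ):
        series = RatioSeries(
            copigment=cop, family=fam, ph=ph, ethanol_pct=eth,
            pigment_mg_per_l=math.nan,
        )
        for _, row in grp.iterrows():
            series.add(int(row["replicate"]), float(row["ratio"]), coords(row))
        cond_controls = controls[
            (controls["pH"] == ph) & (controls["ethanol_pct"] == eth)
        ]
        for _, row in cond_controls.iterrows():
            series.add(int(row["replicate"]), 0.0, coords(row))
        series_list.append(series)
    return series_list


def cp_table(series_list: list[RatioSeries]) -> pd.DataFrame:
    """Cp estimates for the six parameters of every ratio series."""
    rows = []
    for series in series_list:
        for parameter in COLOR_PARAMETERS:
            try:
                res = estimate_cp(series, parameter)
            except Exception as exc:
                raise PipelineError("estimate_cp", exc) from exc
            rows.append(
                {
                    "copigment": series.copigment,
                    "family": series.family,
                    "pH": series.ph,
                    "ethanol_pct": series.ethanol_pct,
                    "parameter": parameter,
                    "cp": res.cp,
                    "sd": res.sd,
                    "r2": res.r2,
                    "n_replicates": res.n_replicates,
                }
            )
    return pd.DataFrame(rows)


def replicate_slopes(series_list: list[RatioSeries]) -> pd.DataFrame:
    """Per-replicate slopes, the raw material for group comparisons."""
    from .copigmentation import _ols_slope

    rows = []
    for series in series_list:
        for parameter in COLOR_PARAMETERS:
            for rep, x, y in series.points(parameter):
                if np.unique(x).size < 2:
                    continue
                slope, _ = _ols_slope(x, y)
                rows.append(
                    {
                        "copigment": series.copigment,
                        "pH": series.ph,
                        "ethanol_pct": series.ethanol_pct,
                        "parameter": parameter,
                        "replicate": rep,
                        "slope": slope,
                    }
                )
    return pd.DataFrame(rows)


def group_stats(slopes: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Compare copigments per condition x parameter: branch, p's, letters."""
    rows = []
    for (ph, eth, parameter), grp in slopes.groupby(["pH", "ethanol_pct", "parameter"]):
        groups = {
            cop: sub["slope"].to_numpy() for cop, sub in grp.groupby("copigment")
        }
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            continue
        try:
            result = compare_groups(groups, alpha=alpha)
        except Exception as exc:
            raise PipelineError("group_stats", exc) from exc
        for cop, letter in result.letters.items():
            rows.append(
                {
                    "pH": ph,
                    "ethanol_pct": eth,
                    "parameter": parameter,
                    "copigment": cop,
                    "branch": result.branch,
                    "omnibus_p": result.omnibus_p,
                    "letters": letter,
                }
            )
    columns = ["pH", "ethanol_pct", "parameter", "copigment", "branch",
               "omnibus_p", "letters"]
    return pd.DataFrame(rows, columns=columns)


def pca_table(colors: pd.DataFrame):
    """PCA of the six color variables over copigment x dose condition means."""
    mixes = colors[colors["role"] == "corrected"]
    obs = (
        mixes.groupby(["copigment", "family", "pH", "ethanol_pct", "ratio"])[
            list(COLOR_PARAMETERS)
        ]
        .mean()
        .dropna(axis=0)
    )
    try:
        return obs, run_pca(obs)
    except Exception as exc:
        raise PipelineError("pca", exc) from exc


@dataclass
class PipelineResult:
    colors: pd.DataFrame
    cp: pd.DataFrame
    slopes: pd.DataFrame
    stats: pd.DataFrame
    pca_observations: pd.DataFrame
    pca_scores: pd.DataFrame
    pca_loadings: pd.DataFrame
    effects: pd.DataFrame


def run_pipeline(
    dataset: PairedDataset,
    out_dir: Optional[str] = None,
    config: Optional[dict] = None,
    alpha: float = 0.05,
) -> PipelineResult:
    """Run colorimetry, Cp estimation, group statistics and PCA.

    If ``out_dir`` is given, writes colors.csv, cp_table.csv,
    group_stats.csv, pca_scores.csv, pca_loadings.csv and effects.csv,
    each stamped with the config hash.
    """
    colors = color_table(dataset)
    series_list = build_ratio_series(colors)
    cp = cp_table(series_list)
    slopes = replicate_slopes(series_list)
    stats = group_stats(slopes, alpha=alpha)

    effect_rows = []
    for (cop, ph, eth), grp in cp.groupby(["copigment", "pH", "ethanol_pct"]):
        labels = classify_effects(dict(zip(grp["parameter"], grp["cp"])))
        effect_rows.append(
            {
                "copigment": cop,
                "pH": ph,
                "ethanol_pct": eth,
                "hyperchromic": labels.hyperchromic,
                "hypochromic": labels.hypochromic,
                "bathochromic": labels.bathochromic,
                "hypsochromic": labels.hypsochromic,
            }
        )
    effects = pd.DataFrame(effect_rows)

    observations, pca = pca_table(colors)
    result = PipelineResult(
        colors=colors,
        cp=cp,
        slopes=slopes,
        stats=stats,
        pca_observations=observations.reset_index(),
        pca_scores=pca.scores.reset_index(),
        pca_loadings=pca.loadings.reset_index(names="variable"),
        effects=effects,
    )
    if out_dir is not None:
        digest = config_hash(config or {})
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(result.colors, out / "colors.csv", digest)
        write_table(result.cp, out / "cp_table.csv", digest)
        write_table(result.stats, out / "group_stats.csv", digest)
        write_table(result.pca_scores, out / "pca_scores.csv", digest)
        write_table(result.pca_loadings, out / "pca_loadings.csv", digest)
        write_table(result.effects, out / "effects.csv", digest)
    return result
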