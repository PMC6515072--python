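"""Synthetic model-wine spectra with known copigmentation structure.

The generator produces the three spectrum roles the pipeline expects
(mix, copigment-only blank, pigment-only control) over a dose grid and a
pH x ethanol condition grid, together with a ground-truth record of the
bound fraction and the analytic A520 slope per condition.

The spectral model is a deliberate stand-in, not a chemical model: a
single Gaussian pigment band near 520 nm whose amplitude is scaled by the
flavylium fraction (pH), amplified by the bound fraction (hyperchromic
gain) and displaced by it (bathochromic shift), plus a colored
short-wavelength blank tail per unit dose and i.i.d. Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .colorimetry import SampleMeta, Spectrum
from .copigmentation import mass_ratio, _ols_slope

__all__ = [
    "CopigmentSpec",
    "SynthConfig",
    "SynthDataset",
    "flavylium_fraction",
    "bound_fraction",
    "pigment_band",
    "blank_tail",
    "generate_experiment",
]


def flavylium_fraction(ph: float, pkh: float) -> float:
    """Fraction of pigment in the colored flavylium form.

    f = 1 / (1 + 10**(pH - pKh)): strictly decreasing in pH, 0.5 at
    pH = pKh.
    """
    return 1.0 / (1.0 + 10.0 ** (ph - pkh))


def bound_fraction(dose: float, k0: float, beta: float, ethanol_pct: float) -> float:
    """Fraction of pigment bound in copigment complexes (simple isotherm).

    K_eff = K0 * exp(-beta * (ethanol - 12)); theta = K_eff*d / (1 + K_eff*d).
    Zero at dose 0, strictly increasing in dose, decreasing in ethanol for
    beta > 0.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    k_eff = k0 * math.exp(-beta * (ethanol_pct - 12.0))
    return k_eff * dose / (1.0 + k_eff * dose)


@dataclass(frozen=True)
class CopigmentSpec:
    """Per-copigment generative parameters."""

    name: str = "synthetic-copigment"
    family: str = "GT"
    k0: float = 3.0  # binding strength per (g/L)
    alpha_h: float = 0.8  # hyperchromic gain per bound fraction
    delta_lambda: float = 8.0  # bathochromic shift, nm per bound fraction
    blank_amp: float = 0.5  # blank tail amplitude at 400 nm per (g/L)
    blank_decay: float = 60.0  # blank tail decay constant, nm


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth generative parameters for one synthetic experiment."""

    pigment_mg_per_l: float = 50.0
    lambda_max: float = 520.0  # band position of the unbound pigment, nm
    band_width: float = 40.0  # Gaussian sigma, nm
    band_amp: float = 0.6  # peak absorbance per (50 mg/L pigment), AU
    pkh: float = 2.6  # flavylium hydration constant (literature-typical)
    beta: float = 0.15  # ethanol sensitivity of binding, per %
    noise: float = 0.002  # AU, i.i.d. per wavelength point
    replicates: int = 3
    doses: tuple = (0.0, 0.1, 0.2, 0.4)  # g/L, must include 0
    ph_values: tuple = (3.5,)
    ethanol_values: tuple = (12.0,)
    copigments: tuple = (CopigmentSpec(),)
    wavelength_step: float = 2.0  # nm, generated sampling over 400-800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pigment_mg_per_l <= 0:
            raise ValueError("pigment concentration must be > 0")
        if min(self.band_width, self.band_amp) <= 0:
            raise ValueError("band width and amplitude must be > 0")
        if self.noise < 0 or self.replicates < 1:
            raise ValueError("noise must be >= 0 and replicates >= 1")
        if 0.0 not in self.doses:
            raise ValueError("dose grid must include 0 (the control)")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be nonnegative")
        if any(c.k0 < 0 or c.alpha_h < 0 for c in self.copigments):
            raise ValueError("binding strength and hyperchromic gain must be >= 0")
        if not self.ph_values or not self.ethanol_values:
            raise ValueError("condition grid must be non-empty")


@dataclass
class SynthDataset:
    """Generated spectra plus manifest and ground truth."""

    spectra: list  # list[Spectrum]
    manifest: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SynthConfig

    def by_id(self, sample_id: str) -> Spectrum:
        return self._index[sample_id]

    def __post_init__(self) -> None:
        self._index = {s.sample_id: s for s in self.spectra}
        if len(self._index) != len(self.spectra):
            raise ValueError("duplicate sample ids in generated dataset")


def pigment_band(
    wl: np.ndarray, cfg: SynthConfig, ph: float, theta: float, cop: CopigmentSpec
) -> np.ndarray:
    """Noise-free pigment absorbance band at bound fraction theta."""
    f = flavylium_fraction(ph, cfg.pkh)
    amp = cfg.band_amp * (cfg.pigment_mg_per_l / 50.0) * f * (1.0 + cop.alpha_h * theta)
    center = cfg.lambda_max + cop.delta_lambda * theta
    return amp * np.exp(-((wl - center) ** 2) / (2.0 * cfg.band_width**2))


def blank_tail(wl: np.ndarray, dose: float, cop: CopigmentSpec) -> np.ndarray:
    """Noise-free copigment-only absorbance: short-wavelength tail per g/L."""
    return dose * cop.blank_amp * np.exp(-(wl - 400.0) / cop.blank_decay)


def _analytic_a520(cfg: SynthConfig, ph: float, theta: float, cop: CopigmentSpec) -> float:
    f = flavylium_fraction(ph, cfg.pkh)
    amp = cfg.band_amp * (cfg.pigment_mg_per_l / 50.0) * f * (1.0 + cop.alpha_h * theta)
    shift = cop.delta_lambda * theta + (cfg.lambda_max - 520.0)
    return amp * math.exp(-(shift**2) / (2.0 * cfg.band_width**2))


def generate_experiment(cfg: SynthConfig) -> SynthDataset:
    """Generate the full mix/blank/control spectrum set for a config.

    Deterministic given the config (including its seed): the same config
    yields bit-identical datasets.  Ground truth records, per copigment x
    condition, the bound fraction at each dose and the analytic (noise
    free) least-squares slope of A520 on the mass ratio.
    """
    rng = np.random.default_rng(cfg.seed)
    wl = np.arange(400.0, 800.0 + 1e-9, cfg.wavelength_step)
    spectra: list[Spectrum] = []
    manifest_rows = []
    truth_rows = []

    def emit(sample_id: str, clean: np.ndarray, meta: SampleMeta) -> None:
        noisy = clean + rng.normal(0.0, cfg.noise, wl.size) if cfg.noise > 0 else clean
        spectra.append(Spectrum(sample_id, wl, noisy, meta))
        manifest_rows.append(
            {
                "sample_id": sample_id,
                "role": meta.role,
                "copigment": meta.copigment,
                "family": meta.family,
                "dose_g_per_L": meta.dose_g_per_l,
                "pigment_mg_per_L": meta.pigment_mg_per_l,
                "pH": meta.ph,
                "ethanol_pct": meta.ethanol_pct,
                "replicate": meta.replicate,
            }
        )

    for ph in cfg.ph_values:
        for eth in cfg.ethanol_values:
            cond = f"pH{ph:g}_et{eth:g}"
            for rep in range(1, cfg.replicates + 1):
                control = pigment_band(wl, cfg, ph, 0.0, cfg.copigments[0])
                emit(
                    f"control_{cond}_r{rep}",
                    control,
                    SampleMeta(
                        role="control",
                        copigment="",
                        family="reference",
                        dose_g_per_l=0.0,
                        pigment_mg_per_l=cfg.pigment_mg_per_l,
                        ph=ph,
                        ethanol_pct=eth,
                        replicate=rep,
                    ),
                )
            for cop in cfg.copigments:
                ratios, clean520 = [], []
                for dose in cfg.doses:
                    theta = bound_fraction(dose, cop.k0, cfg.beta, eth)
                    ratios.append(mass_ratio(dose, cfg.pigment_mg_per_l))
                    clean520.append(_analytic_a520(cfg, ph, theta, cop))
                    truth_rows.append(
                        {
                            "copigment": cop.name,
                            "pH": ph,
                            "ethanol_pct": eth,
                            "dose_g_per_L": dose,
                            "bound_fraction": theta,
                            "a520_clean": clean520[-1],
                        }
                    )
                    if dose == 0.0:
                        continue
                    band = pigment_band(wl, cfg, ph, theta, cop)
                    tail = blank_tail(wl, dose, cop)
                    base = SampleMeta(
                        role="mix",
                        copigment=cop.name,
                        family=cop.family,
                        dose_g_per_l=dose,
                        pigment_mg_per_l=cfg.pigment_mg_per_l,
                        ph=ph,
                        ethanol_pct=eth,
                        replicate=1,
                    )
                    for rep in range(1, cfg.replicates + 1):
                        meta = SampleMeta(**{**asdict(base), "replicate": rep})
                        emit(f"mix_{cop.name}_{cond}_d{dose:g}_r{rep}", band + tail, meta)
                        blank_meta = SampleMeta(**{**asdict(meta), "role": "blank"})
                        emit(f"blank_{cop.name}_{cond}_d{dose:g}_r{rep}", tail, blank_meta)
                slope, _ = _ols_slope(np.asarray(ratios), np.asarray(clean520))
                for row in truth_rows:
                    if (
                        row["copigment"] == cop.name
                        and row["pH"] == ph
                        and row["ethanol_pct"] == eth
                    ):
                        row.setdefault("a520_slope_analytic", slope)

    return SynthDataset(
        spectra=spectra,
        manifest=pd.DataFrame(manifest_rows),
        ground_truth=pd.DataFrame(truth_rows),
        config=cfg,
    )
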