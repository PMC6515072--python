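"""Delimited-text readers and writers, manifest validation and run config.

Everything on disk is plain text: spectra as long-format CSV
(sample_id, wavelength_nm, absorbance), the manifest as CSV with one row
per sample, configs as JSON or YAML.  Output tables carry a header
comment with the config hash and package version so results are
traceable.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colorimetry import FAMILIES, ROLES, SampleMeta, Spectrum
from .synth import CopigmentSpec, SynthConfig, SynthDataset

__all__ = [
    "ManifestError",
    "ValidationReport",
    "PairedDataset",
    "read_spectra",
    "write_spectra",
    "write_manifest",
    "read_manifest",
    "load_and_validate",
    "write_dataset",
    "load_config",
    "config_hash",
    "write_table",
]

MANIFEST_COLUMNS = [
    "sample_id",
    "role",
    "copigment",
    "family",
    "dose_g_per_L",
    "pigment_mg_per_L",
    "pH",
    "ethanol_pct",
    "replicate",
]


class ManifestError(ValueError):
    """Manifest fails validation (duplicates, bad vocabulary, unresolved
    pairings)."""


def read_spectra(path: os.PathLike | str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a long-format spectra CSV into {sample_id: (wavelengths, absorbance)}."""
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "wavelength_nm", "absorbance"}
    if not required.issubset(df.columns):
        raise ValueError(f"spectra file must have columns {sorted(required)}")
    out = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("wavelength_nm")
        out[str(sid)] = (
            grp["wavelength_nm"].to_numpy(dtype=float),
            grp["absorbance"].to_numpy(dtype=float),
        )
    return out


def write_spectra(spectra: Iterable[Spectrum], path: os.PathLike | str) -> None:
    frames = [
        pd.DataFrame(
            {
                "sample_id": s.sample_id,
                "wavelength_nm": s.wavelengths,
                "absorbance": s.absorbance,
            }
        )
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_manifest(manifest: pd.DataFrame, path: os.PathLike | str) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: os.PathLike | str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest lacks columns: {missing}")
    df["copigment"] = df["copigment"].fillna("")
    return df


@dataclass
class ValidationReport:
    warnings: list = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)


@dataclass
class PairedDataset:
    """Validated dataset with every mix paired to its blank and control."""

    spectra: dict  # sample_id -> Spectrum
    manifest: pd.DataFrame
    pairs: pd.DataFrame  # mix_id, blank_id, control_id
    report: ValidationReport

    def spectrum(self, sample_id: str) -> Spectrum:
        return self.spectra[sample_id]


def _meta_from_row(row: pd.Series) -> SampleMeta:
    return SampleMeta(
        role=str(row["role"]),
        copigment=str(row["copigment"]),
        family=str(row["family"]),
        dose_g_per_l=float(row["dose_g_per_L"]),
        pigment_mg_per_l=float(row["pigment_mg_per_L"]),
        ph=float(row["pH"]),
        ethanol_pct=float(row["ethanol_pct"]),
        replicate=int(row["replicate"]),
    )


def load_and_validate(
    manifest_path: os.PathLike | str, spectra_path: os.PathLike | str
) -> PairedDataset:
    """Load manifest + spectra and resolve every mix to a blank and control.

    Errors: duplicate sample ids, unknown roles/families, manifest rows
    without spectra, and mixes lacking a blank (same copigment, dose, pH,
    ethanol, replicate) or a control (same pH, ethanol, replicate).
    Warnings (collected, not fatal): negative absorbance values.
    """
    manifest = read_manifest(manifest_path)
    raw = read_spectra(spectra_path)
    report = ValidationReport()

    dup = manifest["sample_id"][manifest["sample_id"].duplicated()]
    if not dup.empty:
        raise ManifestError(f"duplicate sample_id(s): {sorted(set(dup))}")
    bad_roles = set(manifest["role"]) - set(ROLES)
    if bad_roles:
        raise ManifestError(f"unknown role(s): {sorted(bad_roles)}")
    bad_fams = set(manifest["family"]) - set(FAMILIES)
    if bad_fams:
        raise ManifestError(f"unknown family(s): {sorted(bad_fams)}")
    missing = [sid for sid in manifest["sample_id"] if sid not in raw]
    if missing:
        raise ManifestError(f"manifest rows without spectra: {missing}")

    spectra = {}
    for _, row in manifest.iterrows():
        sid = str(row["sample_id"])
        wl, ab = raw[sid]
        spec = Spectrum(sid, wl, ab, _meta_from_row(row))
        if np.any(ab < 0):
            spec = spec.with_flags("negative_absorbance")
            report.warn(f"{sid}: negative absorbance values")
        spectra[sid] = spec

    def key(row, fields):
        return tuple(row[f] for f in fields)

    blank_index: dict[tuple, str] = {}
    control_index: dict[tuple, str] = {}
    for _, row in manifest.iterrows():
        if row["role"] == "blank":
            blank_index[
                key(row, ["copigment", "dose_g_per_L", "pH", "ethanol_pct", "replicate"])
            ] = str(row["sample_id"])
        elif row["role"] == "control":
            control_index[key(row, ["pH", "ethanol_pct", "replicate"])] = str(
                row["sample_id"]
            )

    pair_rows, orphans = [], []
    for _, row in manifest.iterrows():
        if row["role"] != "mix":
            continue
        bkey = key(row, ["copigment", "dose_g_per_L", "pH", "ethanol_pct", "replicate"])
        ckey = key(row, ["pH", "ethanol_pct", "replicate"])
        blank_id = blank_index.get(bkey)
        control_id = control_index.get(ckey)
        if blank_id is None or control_id is None:
            what = []
            if blank_id is None:
                what.append("blank")
            if control_id is None:
                what.append("control")
            orphans.append(f"{row['sample_id']} (missing {' and '.join(what)})")
            continue
        pair_rows.append(
            {
                "mix_id": str(row["sample_id"]),
                "blank_id": blank_id,
                "control_id": control_id,
            }
        )
    if orphans:
        raise ManifestError(f"mix rows without resolvable pairing: {orphans}")

    return PairedDataset(
        spectra=spectra,
        manifest=manifest,
        pairs=pd.DataFrame(pair_rows),
        report=report,
    )


def write_dataset(dataset: SynthDataset, out_dir: os.PathLike | str) -> dict[str, Path]:
    """Write a synthetic dataset as the same files the pipeline ingests.

    Ground truth goes to a separate file so blind analysis runs are
    possible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "spectra": out / "spectra.csv",
        "manifest": out / "manifest.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    write_spectra(dataset.spectra, paths["spectra"])
    write_manifest(dataset.manifest, paths["manifest"])
    dataset.ground_truth.to_csv(paths["ground_truth"], index=False)
    return paths


def load_config(path: os.PathLike | str) -> dict:
    """Load a JSON or YAML run config by file extension."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def synth_config_from_dict(raw: dict) -> SynthConfig:
    """Build a SynthConfig (with nested CopigmentSpec entries) from a dict."""
    raw = dict(raw)
    cops = raw.pop("copigments", None)
    kwargs = {}
    for name in (
        "pigment_mg_per_l", "lambda_max", "band_width", "band_amp", "pkh",
        "beta", "noise", "replicates", "wavelength_step", "seed",
    ):
        if name in raw:
            kwargs[name] = raw.pop(name)
    for name in ("doses", "ph_values", "ethanol_values"):
        if name in raw:
            kwargs[name] = tuple(raw.pop(name))
    if raw:
        raise ValueError(f"unknown config key(s): {sorted(raw)}")
    if cops is not None:
        kwargs["copigments"] = tuple(CopigmentSpec(**c) for c in cops)
    return SynthConfig(**kwargs)


def config_hash(config: dict | SynthConfig) -> str:
    """Short deterministic hash of a run configuration."""
    if isinstance(config, SynthConfig):
        from dataclasses import asdict

        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: os.PathLike | str, config_digest: str = "unconfigured"
) -> None:
    """Write a result table with a traceability header comment."""
    with open(path, "w") as fh:
        fh.write(f"# copigment {__version__}; config_hash={config_digest}\n")
        df.to_csv(fh, index=False)
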