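"""Loaders for the packaged reference tables of printed Cp values.

Three delimited fixtures ship with the package:

* ``cp_by_origin.csv`` — per-product values for 36 commercial tannins plus
  the epicatechin reference, with the family/origin hierarchy.
* ``cp_by_ph.csv`` — Cp slopes and r² for five copigments plus the
  reference at pH 3.1 / 3.5 / 3.9.
* ``cp_by_ethanol.csv`` — the same at 10 / 12 / 14 % ethanol.

Loaders return tidy frames with one row per (condition, copigment,
parameter) using the canonical parameter names ``A520, L*, a*, b*, hab,
C*ab``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_origin_table", "load_ph_cp_table", "load_ethanol_cp_table"]

_PARAM_BY_PREFIX = {
    "A520": "A520",
    "L": "L*",
    "a": "a*",
    "b": "b*",
    "hab": "hab",
    "Cab": "C*ab",
}


def _read(name: str) -> pd.DataFrame:
    path = resources.files("copigment.data") / name
    with path.open() as fh:
        return pd.read_csv(fh, comment="#")


def _melt(df: pd.DataFrame, id_vars: list[str], stats: tuple[str, ...]) -> pd.DataFrame:
    frames = []
    for prefix, parameter in _PARAM_BY_PREFIX.items():
        cols = {f"{prefix}_{s}": s for s in stats}
        if not all(c in df.columns for c in cols):
            raise ValueError(f"fixture lacks columns for parameter {parameter!r}")
        sub = df[id_vars + list(cols)].rename(columns=cols)
        sub.insert(len(id_vars), "parameter", parameter)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def load_origin_table() -> pd.DataFrame:
    """Tidy per-product table: family, origin, product, parameter, cp, sd."""
    wide = _read("cp_by_origin.csv")
    return _melt(wide, ["family", "origin", "product"], ("cp", "sd"))


def load_ph_cp_table() -> pd.DataFrame:
    """Tidy pH table: ph, copigment, family, parameter, cp, sd, r2."""
    wide = _read("cp_by_ph.csv")
    return _melt(wide, ["ph", "copigment", "family"], ("cp", "sd", "r2"))


def load_ethanol_cp_table() -> pd.DataFrame:
    """Tidy ethanol table: ethanol_pct, copigment, family, parameter, cp, sd, r2."""
    wide = _read("cp_by_ethanol.csv")
    return _melt(wide, ["ethanol_pct", "copigment", "family"], ("cp", "sd", "r2"))
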