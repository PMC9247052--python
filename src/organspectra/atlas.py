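"""Per-organ spectral fingerprint atlas.

For every organ class: the per-pig mean reflectance curves, the overall mean
across all annotation rows of that organ, a +/-1 SD band (sample SD, n-1
denominator, across rows), and the counts A (number of animals) and
n (number of measurements).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hsi_core import SpectraTable, WavelengthGrid

__all__ = ["OrganFingerprint", "FingerprintAtlas", "compute_atlas", "export_atlas", "read_atlas_csv"]


@dataclass
class OrganFingerprint:
    organ: str
    overall_mean: np.ndarray
    sd: np.ndarray
    per_pig_means: dict[str, np.ndarray]
    n_animals: int
    n_measurements: int

    def __post_init__(self) -> None:
        if np.any(self.sd < 0):
            raise ValueError("SD band must be non-negative")
        if self.n_animals != len(self.per_pig_means):
            raise ValueError("n_animals must equal the number of per-pig curves")


@dataclass
class FingerprintAtlas:
    organs: dict[str, OrganFingerprint]
    grid: WavelengthGrid

    def __len__(self) -> int:
        return len(self.organs)


def compute_atlas(table: SpectraTable) -> FingerprintAtlas:
    """Group the spectra table by organ and summarize each group.

    Overall mean and SD are taken across annotation rows (not across
    per-pig means); SD of a single row is the zero vector.
    """
    if len(table) == 0:
        raise ValueError("spectra table is empty")
    bands = table.grid.band_columns
    organs: dict[str, OrganFingerprint] = {}
    for organ, group in table.df.groupby("organ", sort=True):
        values = group[bands].to_numpy(dtype=float)
        per_pig = {
            str(pig): sub[bands].to_numpy(dtype=float).mean(axis=0)
            for pig, sub in group.groupby("pig_id", sort=True)
        }
        sd = values.std(axis=0, ddof=1) if len(values) > 1 else np.zeros(values.shape[1])
        organs[str(organ)] = OrganFingerprint(
            organ=str(organ),
            overall_mean=values.mean(axis=0),
            sd=sd,
            per_pig_means=per_pig,
            n_animals=len(per_pig),
            n_measurements=len(values),
        )
    return FingerprintAtlas(organs, table.grid)


def export_atlas(atlas: FingerprintAtlas, path) -> list[Path]:
    """Write one CSV per organ plus an ``index.json`` with A/n counts.

    Each CSV has columns ``wavelength_nm, overall_mean, sd`` and one
    ``pig_<id>`` column per animal.  Returns the written CSV paths.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    if not atlas.organs:
        warnings.warn("exporting an empty atlas: no organ CSVs written")
    written: list[Path] = []
    index = {}
    for organ, fp in atlas.organs.items():
        df = pd.DataFrame({"wavelength_nm": atlas.grid.values})
        df["overall_mean"] = fp.overall_mean
        df["sd"] = fp.sd
        for pig, curve in fp.per_pig_means.items():
            df[f"pig_{pig}"] = curve
        out = root / f"{organ}.csv"
        df.to_csv(out, index=False, float_format="%.12g")
        written.append(out)
        index[organ] = {"n_animals": fp.n_animals, "n_measurements": fp.n_measurements}
    (root / "index.json").write_text(json.dumps(index, indent=1))
    return written


def read_atlas_csv(path) -> pd.DataFrame:
    """Round-trip reader for one exported organ CSV."""
    return pd.read_csv(path)
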