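"""Secondary-structure propensity (SSP) from Cα/Cβ secondary chemical shifts.

The secondary shift of a nucleus is the observed shift minus its residue's
random-coil reference.  The raw propensity per residue is

    SSP(j) = d(delta Cα)(j) - d(delta Cβ)(j)      [ppm]

— consecutive positive values indicate α-helix, negative values β-sheet.  A
neighbour correction (centred moving average over a 3-residue window,
skipping missing entries) smooths assignment noise, and dividing by the
packaged full-helix difference of 3.5 ppm (= +3.1 Cα − (−0.4) Cβ) converts
the profile to a fractional helical propensity in [−1, 1].

Per-region helicity is estimated against a helix-stabilised reference
profile (e.g. recorded in TFE): the ratio of mean propensities over the
region.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    EmptyProfileError,
    UndefinedReferenceError,
    UnknownResidueError,
)

logger = logging.getLogger(__name__)

#: ppm difference (ΔδCα − ΔδCβ) of a fully helical residue; the SSP
#: normalisation constant
FULL_HELIX_DIFFERENCE = 3.5


@dataclass
class ShiftTable:
    """Per-residue Cα/Cβ chemical shifts (ppm); NaN marks missing values.

    Columns: residue_number, residue_type, CA_shift_ppm, CB_shift_ppm.
    Residue numbers must be strictly increasing; glycine carries no Cβ.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"residue_number", "residue_type", "CA_shift_ppm", "CB_shift_ppm"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"shift table lacks columns {sorted(missing)}")
        nums = self.data["residue_number"].to_numpy()
        if np.any(np.diff(nums) <= 0):
            raise ValueError("residue numbers must be strictly increasing")
        gly = self.data["residue_type"].str.upper() == "G"
        if self.data.loc[gly, "CB_shift_ppm"].notna().any():
            raise ValueError("glycine rows must not carry a Cβ shift")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ShiftTable":
        return cls(pd.read_csv(path))


def secondary_shifts(
    shifts: ShiftTable, rc_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Secondary shifts Δδ = observed − random-coil reference, per nucleus.

    ``rc_table`` is indexed by one-letter residue type with columns CA_ppm /
    CB_ppm; defaults to the packaged reference set.  Missing observations
    propagate as NaN.  Proline rows are flagged (amide-detected experiments
    often miss them).
    """
    if rc_table is None:
        from .cg_model import random_coil_shifts

        rc_table = random_coil_shifts()
    rows = []
    for _, row in shifts.data.iterrows():
        aa = str(row["residue_type"]).upper()
        if aa not in rc_table.index:
            raise UnknownResidueError(
                f"residue {aa!r} at position {row['residue_number']} not in the "
                "random-coil reference"
            )
        rows.append(
            {
                "residue_number": int(row["residue_number"]),
                "residue_type": aa,
                "delta_ca_ppm": row["CA_shift_ppm"] - rc_table.loc[aa, "CA_ppm"],
                "delta_cb_ppm": row["CB_shift_ppm"] - rc_table.loc[aa, "CB_ppm"],
                "proline": aa == "P",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SspProfile:
    """Raw and normalised secondary-structure propensity per residue."""

    residue_numbers: np.ndarray
    raw_ppm: np.ndarray         # ΔδCα − ΔδCβ before smoothing
    smoothed_ppm: np.ndarray    # neighbour-corrected raw values
    normalized: np.ndarray      # smoothed / 3.5 ppm, clipped to [−1, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_number": self.residue_numbers,
                "raw_ppm": self.raw_ppm,
                "smoothed_ppm": self.smoothed_ppm,
                "ssp": self.normalized,
            }
        )


def _masked_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average skipping NaN entries; NaN where the whole
    window is missing."""
    half = window // 2
    out = np.full_like(x, np.nan, dtype=float)
    for i in range(len(x)):
        seg = x[max(0, i - half) : i + half + 1]
        good = np.isfinite(seg)
        if good.any():
            out[i] = seg[good].mean()
    return out


def ssp_profile(
    deltas: pd.DataFrame,
    window: int = 3,
    normalization_ppm: float = FULL_HELIX_DIFFERENCE,
) -> SspProfile:
    """Neighbour-corrected, normalised SSP profile from secondary shifts.

    raw(j) = ΔδCα(j) − ΔδCβ(j); a missing Cβ (glycine) leaves raw = ΔδCα.
    Values clipped during normalisation are logged.
    """
    if len(deltas) < window:
        raise ValueError(f"need at least {window} residues")
    dca = deltas["delta_ca_ppm"].to_numpy(dtype=float)
    dcb = deltas["delta_cb_ppm"].to_numpy(dtype=float)
    raw = np.where(np.isfinite(dcb), dca - np.nan_to_num(dcb), dca)
    if not np.any(np.isfinite(raw)):
        raise EmptyProfileError("no usable Cα shifts in the table")
    smoothed = _masked_moving_average(raw, window)
    normalized = smoothed / normalization_ppm
    n_clip = np.count_nonzero(np.abs(normalized) > 1)
    if n_clip:
        logger.info("clipping %d SSP values outside [-1, 1]", n_clip)
    return SspProfile(
        residue_numbers=deltas["residue_number"].to_numpy(),
        raw_ppm=raw,
        smoothed_ppm=smoothed,
        normalized=np.clip(normalized, -1.0, 1.0),
    )


def helicity_from_ssp(
    native: SspProfile,
    reference: SspProfile,
    regions: list[tuple[int, int]],
) -> dict[tuple[int, int], float]:
    """Per-region helicity of a native profile against a helix-stabilised
    reference.

    For each (first, last) residue-number range (inclusive), helicity =
    mean(native SSP) / mean(reference SSP), clipped to [0, 1].  The
    reference must be positive on average over every region.
    """
    out = {}
    for first, last in regions:
        m_nat = (native.residue_numbers >= first) & (native.residue_numbers <= last)
        m_ref = (reference.residue_numbers >= first) & (reference.residue_numbers <= last)
        if not m_nat.any() or not m_ref.any():
            raise ValueError(f"region {first}-{last} outside the profiles")
        ref_mean = np.nanmean(reference.normalized[m_ref])
        if not ref_mean > 0:
            raise UndefinedReferenceError(
                f"reference propensity non-positive over region {first}-{last}"
            )
        nat_mean = np.nanmean(native.normalized[m_nat])
        out[(first, last)] = float(np.clip(nat_mean / ref_mean, 0.0, 1.0))
    return out
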