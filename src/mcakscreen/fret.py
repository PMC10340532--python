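"""Background-corrected FRET ratio analysis.

The conformational sensor emits in two channels under donor excitation:
the acceptor (FRET) emission I_F and the donor emission I_D.  The FRET
ratio I_F/I_D is computed after subtracting the per-channel background
measured on buffer-only wells of the same plate.  A high ratio reports
the closed/active enzyme conformation; inhibition opens the molecule
and lowers the ratio.  96- and 384-well dialects differ only in layout;
the spectrometer dialect (emission at 525 nm over 475 nm) shares the
same formula without separate background wells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plates import Channel, PlateLayout, WellReading, WellRole

__all__ = [
    "fret_ratio",
    "spectrum_fret_ratio",
    "average_replicate_ratios",
    "plate_background",
    "compute_plate_ratios",
    "PlateBaselines",
    "plate_baselines",
]


def fret_ratio(i_f: float, i_d: float, b_f: float = 0.0, b_d: float = 0.0) -> float:
    """Background-corrected FRET ratio ``(I_F - B_F) / (I_D - B_D)``.

    A non-positive corrected donor marks the well invalid: the function
    returns NaN rather than raising, so invalid wells can be flagged and
    excluded from baselines instead of aborting a plate.
    """
    denom = i_d - b_d
    if denom <= 0:
        return math.nan
    return (i_f - b_f) / denom


def spectrum_fret_ratio(emission_at_525: float, emission_at_475: float) -> float:
    """Spectrometer dialect: acceptor emission at 525 nm over donor
    emission at 475 nm, no separate background wells."""
    return fret_ratio(emission_at_525, emission_at_475)


def average_replicate_ratios(ratios: list[float] | np.ndarray) -> float:
    """Mean of replicate ratio readings (readings are done in triplicate);
    invalid (NaN) replicates are excluded, and all-invalid input is NaN."""
    arr = np.asarray(ratios, dtype=float)
    valid = arr[np.isfinite(arr)]
    return float(valid.mean()) if valid.size else math.nan


def plate_background(
    readings: list[WellReading], layout: PlateLayout
) -> tuple[float, float]:
    """Per-channel background: mean of the buffer-blank wells.

    Returns (B_F, B_D); (0, 0) with a warning when the plate has no
    blanks.
    """
    blanks = set(layout.wells_with_role(WellRole.BUFFER_BLANK))
    by_channel: dict[Channel, list[float]] = {Channel.FRET_EM: [], Channel.DONOR_EM: []}
    for r in readings:
        if r.well in blanks and r.channel in by_channel:
            by_channel[r.channel].append(r.intensity)
    if not by_channel[Channel.FRET_EM] or not by_channel[Channel.DONOR_EM]:
        warnings.warn(
            "no buffer-blank wells on plate; background set to 0",
            stacklevel=2,
        )
        return 0.0, 0.0
    return (
        float(np.mean(by_channel[Channel.FRET_EM])),
        float(np.mean(by_channel[Channel.DONOR_EM])),
    )


def compute_plate_ratios(
    readings: list[WellReading],
    layout: PlateLayout,
    background: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Background-corrected ratio for every non-blank well of a plate.

    Returns a table with columns well, role, compound_id, ratio, valid.
    When ``background`` is not supplied it is estimated from the plate's
    buffer blanks.
    """
    if background is None:
        background = plate_background(readings, layout)
    b_f, b_d = background
    per_well: dict[str, dict[Channel, float]] = {}
    for r in readings:
        per_well.setdefault(r.well, {})[r.channel] = r.intensity
    rows = []
    for well, a in sorted(layout.wells.items()):
        if a.role is WellRole.BUFFER_BLANK:
            continue
        chans = per_well.get(well, {})
        if Channel.FRET_EM not in chans or Channel.DONOR_EM not in chans:
            raise ValueError(f"missing FRET/donor reading for well {well}")
        ratio = fret_ratio(chans[Channel.FRET_EM], chans[Channel.DONOR_EM], b_f, b_d)
        rows.append(
            {
                "well": well,
                "role": a.role.value,
                "compound_id": a.compound_id,
                "ratio": ratio,
                "valid": bool(np.isfinite(ratio)),
            }
        )
    return pd.DataFrame(rows, columns=["well", "role", "compound_id", "ratio", "valid"])


@dataclass(frozen=True)
class PlateBaselines:
    """Per-role control ratio statistics of one plate."""

    stats: dict[str, tuple[float, float, int]]  # role -> (mean, sd, n)

    def mean(self, role: WellRole | str) -> float:
        role = role.value if isinstance(role, WellRole) else role
        return self.stats[role][0]

    def sd(self, role: WellRole | str) -> float:
        role = role.value if isinstance(role, WellRole) else role
        return self.stats[role][1]

    def __contains__(self, role: object) -> bool:
        role = role.value if isinstance(role, WellRole) else role
        return role in self.stats


def plate_baselines(ratios: pd.DataFrame, layout: PlateLayout) -> PlateBaselines:
    """Mean/SD of the ratio for each control role present on the plate.

    Only valid wells of that role on the same plate contribute; the SD is
    the sample SD (n-1) and requires at least two wells (NaN otherwise).
    """
    stats: dict[str, tuple[float, float, int]] = {}
    control_roles = [
        WellRole.FCP_CONTROL,
        WellRole.FMCAK_CONTROL,
        WellRole.ANTIBODY_CONTROL,
        WellRole.AURORA_CONTROL,
    ]
    for role in control_roles:
        sub = ratios[(ratios["role"] == role.value) & ratios["valid"]]
        if len(sub) == 0:
            continue
        vals = sub["ratio"].to_numpy()
        sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else math.nan
        stats[role.value] = (float(vals.mean()), sd, int(vals.size))
    return PlateBaselines(stats)
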