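"""Screen-level analysis: assay quality, hit calling and screen summaries.

Covers the Z'-factor and CV assay-quality statistics, threshold-based
hit calling for the image and FRET assays, duplicate-replicate
intersection, rescreen confirmation, the FCP counter screen (which
flags compounds that perturb the fluorophores themselves), and the
small pieces of assay-setup arithmetic (dilutions, molar ratios).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fret import PlateBaselines
from .plates import PlateLayout, WellRole

__all__ = [
    "HitClass",
    "HitCall",
    "AssayQuality",
    "ScreenSummary",
    "z_prime",
    "cv_percent",
    "assay_quality",
    "call_image_well",
    "call_fret_well",
    "call_fret_plate",
    "call_image_plate",
    "intersect_replicates",
    "counter_screen_filter",
    "confirm_hits",
    "hit_rate",
    "dilution_concentration",
    "molar_ratio_integer",
    "summarize_screen",
]


class HitClass(str, enum.Enum):
    INHIBITOR = "INHIBITOR"
    ACTIVATOR = "ACTIVATOR"
    NONE = "NONE"


@dataclass(frozen=True)
class HitCall:
    """Classification of one compound well in one assay replicate."""

    compound_id: str
    assay: str                # "IMAGE" or "FRET"
    hit_class: HitClass
    metric: float             # percent polymer remaining, or percent ratio change
    replicate: int = 0


@dataclass(frozen=True)
class AssayQuality:
    z_prime: float
    cv_percent: float
    positive_control: str
    negative_control: str


def z_prime(pc_values, nc_values) -> float:
    """Z'-factor: ``1 - 3*(SD_PC + SD_NC) / |mean_PC - mean_NC|``.

    SDs are sample SDs (n-1); with control groups as small as four wells
    this choice matters.  Requires at least two values per group; equal
    group means make the statistic undefined and return NaN.
    """
    pc = np.asarray(pc_values, dtype=float)
    nc = np.asarray(nc_values, dtype=float)
    if pc.size < 2 or nc.size < 2:
        raise ValueError("z_prime needs at least two values per control group")
    sep = abs(pc.mean() - nc.mean())
    if sep == 0:
        return math.nan
    return 1.0 - 3.0 * (pc.std(ddof=1) + nc.std(ddof=1)) / sep


def cv_percent(values) -> float:
    """Coefficient of variation, 100 * sample SD / mean; NaN if mean is 0."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("cv_percent needs at least two values")
    mean = arr.mean()
    if mean == 0:
        return math.nan
    return 100.0 * arr.std(ddof=1) / mean


def assay_quality(
    pc_values,
    nc_values,
    positive_control: str = "FMCAK_CONTROL",
    negative_control: str = "ANTIBODY_CONTROL",
) -> AssayQuality:
    """Z' and CV for a plate; the CV is reported over the positive-control
    wells (the uninhibited-enzyme wells by default)."""
    return AssayQuality(
        z_prime=z_prime(pc_values, nc_values),
        cv_percent=cv_percent(pc_values),
        positive_control=positive_control,
        negative_control=negative_control,
    )


def call_image_well(
    percent_remaining: float,
    inhibitor_threshold: float = 50.0,
    activator_threshold: float = 10.0,
) -> HitClass:
    """Image-assay call from percent polymer remaining at 60 min.

    Strictly more than 50% polymer remaining means the enzyme was
    blocked (inhibitor); strictly less than 10% means enhanced
    depolymerization (activator).  The boundaries themselves are NONE.
    """
    if percent_remaining > inhibitor_threshold:
        return HitClass.INHIBITOR
    if percent_remaining < activator_threshold:
        return HitClass.ACTIVATOR
    return HitClass.NONE


def call_fret_well(
    ratio: float, fmcak_baseline: float, threshold_pct: float = 15.0
) -> tuple[HitClass, float]:
    """FRET-assay call from a well ratio against the same-plate enzyme
    baseline.

    Returns (class, percent change).  A ratio decrease of 15% or more is
    an inhibitor, an increase of 15% or more an activator; the boundary
    is inclusive.  Invalid (NaN) ratios return NONE with NaN change.
    """
    if fmcak_baseline <= 0:
        raise ValueError("baseline ratio must be > 0")
    if not np.isfinite(ratio):
        return HitClass.NONE, math.nan
    change = 100.0 * (ratio - fmcak_baseline) / fmcak_baseline
    if change <= -threshold_pct:
        return HitClass.INHIBITOR, change
    if change >= threshold_pct:
        return HitClass.ACTIVATOR, change
    return HitClass.NONE, change


def call_fret_plate(
    ratios: pd.DataFrame,
    baselines: PlateBaselines,
    threshold_pct: float = 15.0,
    replicate: int = 0,
) -> dict[str, HitCall]:
    """Call every compound well of a plate against the plate's own
    uninhibited-enzyme (FMCAK) control mean."""
    if WellRole.FMCAK_CONTROL not in baselines:
        raise ValueError("plate has no FMCAK control wells to baseline against")
    baseline = baselines.mean(WellRole.FMCAK_CONTROL)
    calls: dict[str, HitCall] = {}
    comp = ratios[ratios["role"] == WellRole.COMPOUND.value]
    for _, rec in comp.iterrows():
        cls, change = call_fret_well(rec["ratio"], baseline, threshold_pct)
        calls[rec["compound_id"]] = HitCall(
            rec["compound_id"], "FRET", cls, change, replicate
        )
    return calls


def call_image_plate(
    percent_remaining: dict[str, float],
    layout: PlateLayout,
    inhibitor_threshold: float = 50.0,
    activator_threshold: float = 10.0,
    replicate: int = 0,
) -> dict[str, HitCall]:
    """Image-assay calls for all compound wells given per-well percent
    polymer remaining."""
    calls: dict[str, HitCall] = {}
    for well, cid in layout.compound_wells.items():
        if well not in percent_remaining:
            continue
        pct = percent_remaining[well]
        cls = call_image_well(pct, inhibitor_threshold, activator_threshold)
        calls[cid] = HitCall(cid, "IMAGE", cls, pct, replicate)
    return calls


def hit_set(calls: dict[str, HitCall]) -> set[str]:
    return {c for c, call in calls.items() if call.hit_class is not HitClass.NONE}


def intersect_replicates(
    calls_rep1: dict[str, HitCall], calls_rep2: dict[str, HitCall]
) -> set[str]:
    """Compounds called the same non-NONE class in both replicates."""
    out = set()
    for cid, c1 in calls_rep1.items():
        c2 = calls_rep2.get(cid)
        if c2 is None:
            continue
        if c1.hit_class is not HitClass.NONE and c1.hit_class is c2.hit_class:
            out.add(cid)
    return out


def counter_screen_filter(
    hits: set[str], fcp_calls: dict[str, HitCall]
) -> set[str]:
    """Drop hits that also scored against the FCP counter-screen reagent.

    A compound that shifts the ratio of the enzyme-free donor-acceptor
    fusion is perturbing the fluorophores, not the enzyme.
    """
    flagged = hit_set(fcp_calls)
    return {c for c in hits if c not in flagged}


def confirm_hits(
    primary_hits: set[str],
    rescreen_calls: dict[str, HitCall],
    fcp_calls: dict[str, HitCall] | None = None,
) -> set[str]:
    """Hits confirmed by an independent rescreen and, when supplied, the
    FCP counter screen: a compound is confirmed iff it was a primary hit,
    is called non-NONE in the rescreen, and is not counter-screen
    flagged."""
    confirmed = primary_hits & hit_set(rescreen_calls)
    if fcp_calls is not None:
        confirmed = counter_screen_filter(confirmed, fcp_calls)
    return confirmed


def _round_half_away(x: float, ndigits: int) -> float:
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def hit_rate(n_hits: int, n_compounds: int) -> float:
    """Hit rate as a percentage, rounded to 1 decimal (half away from 0)."""
    if n_compounds <= 0:
        raise ValueError("n_compounds must be > 0")
    return _round_half_away(100.0 * n_hits / n_compounds, 1)


def dilution_concentration(
    stock_conc: float, stock_vol: float, final_vol: float
) -> float:
    """Final concentration after dilution, rounded to 2 decimals.

    E.g. a 25 uM stock diluted 10.9 uL into a 30 uL final volume gives
    9.08 uM; 2.5% DMSO diluted 20 uL into 55 uL gives 0.91%.
    """
    if not (final_vol >= stock_vol > 0):
        raise ValueError("need final_vol >= stock_vol > 0")
    return _round_half_away(stock_conc * stock_vol / final_vol, 2)


def molar_ratio_integer(substrate_conc: float, enzyme_conc: float) -> int:
    """Integer part of the substrate:enzyme molar ratio.

    Inputs must share units (e.g. molar): 0.2e-6 M tubulin over 3e-9 M
    enzyme gives 66.
    """
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be > 0")
    if substrate_conc < 0:
        raise ValueError("substrate concentration must be >= 0")
    return int(substrate_conc / enzyme_conc)


@dataclass
class ScreenSummary:
    """Counts and rates summarizing one screening campaign."""

    n_compounds: int
    hits_per_assay: dict[str, int]
    overlap: int
    hit_rate_percent: dict[str, float]
    confirmed: int = 0
    counter_screen_flagged: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "assay": assay,
                "n_compounds": self.n_compounds,
                "n_hits": n,
                "hit_rate_percent": self.hit_rate_percent[assay],
                "overlap": self.overlap,
                "confirmed": self.confirmed,
                "counter_screen_flagged": self.counter_screen_flagged,
            }
            for assay, n in self.hits_per_assay.items()
        ]
        return pd.DataFrame(rows)


def summarize_screen(
    calls_by_assay: dict[str, dict[str, HitCall]],
    n_compounds: int,
    confirmed: set[str] | None = None,
    counter_flagged: set[str] | None = None,
) -> ScreenSummary:
    hits = {assay: hit_set(calls) for assay, calls in calls_by_assay.items()}
    sets = list(hits.values())
    overlap = len(set.intersection(*sets)) if len(sets) > 1 else 0
    return ScreenSummary(
        n_compounds=n_compounds,
        hits_per_assay={a: len(h) for a, h in hits.items()},
        overlap=overlap,
        hit_rate_percent={a: hit_rate(len(h), n_compounds) for a, h in hits.items()},
        confirmed=len(confirmed) if confirmed is not None else 0,
        counter_screen_flagged=len(counter_flagged) if counter_flagged is not None else 0,
    )
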