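"""Gating and FRET summary statistics for per-cell flow-cytometry tables.

An event table is a pandas DataFrame with one row per acquired cell and
columns ``donor``, ``acceptor``, ``fret`` and ``viability`` (arbitrary
cytometer units). The per-well screen score is the normalized FRET intensity,

    normalized_fret = %FRET+  x  FRET MFI,

the percentage of gated cells above the FRET-positive threshold multiplied by
the median FRET intensity (MFI) of that positive subpopulation. Gates are
rectangular thresholds; the FRET-positive threshold can be anchored on pooled
negative-control wells (:func:`auto_fret_threshold`), which is the
reproducible default for simulated screens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import SchemaError, UndefinedValueError

REQUIRED_COLUMNS = ("donor", "acceptor", "fret", "viability")


@dataclass(frozen=True)
class GateSpec:
    """Rectangular gating thresholds, all in channel units.

    ``viability_cutoff`` with ``viability_keep`` selects live cells (a
    dead-cell dye such as Draq7 stains dead cells bright, hence the default
    keep-below). ``donor_min``/``acceptor_min`` implement the double-positive
    reporter gate. ``fret_threshold`` splits gated cells into FRET-negative
    and FRET-positive.
    """

    fret_threshold: float
    viability_cutoff: float = np.inf
    viability_keep: Literal["below", "above"] = "below"
    donor_min: float = -np.inf
    acceptor_min: float = -np.inf

    def __post_init__(self) -> None:
        if self.viability_keep not in ("below", "above"):
            raise SchemaError(
                f"viability_keep must be 'below' or 'above', got {self.viability_keep!r}"
            )
        if np.isnan(self.fret_threshold):
            raise SchemaError("fret_threshold must be a number")


@dataclass(frozen=True)
class FretSummary:
    """Per-well FRET readout; ``normalized_fret`` is exactly the product."""

    percent_fret_positive: float  # [0, 100]
    fret_mfi: float
    normalized_fret: float
    n_events_gated: int
    well: str | None = None
    no_positive_events: bool = False


def _check_schema(events: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"event table missing required columns: {missing}")


def gate_events(events: pd.DataFrame, gates: GateSpec) -> pd.DataFrame:
    """Apply viability and double-positive gates; row order is preserved.

    The FRET-positive threshold is *not* applied here — it defines the
    positive subpopulation inside the gated set, not membership of it.
    """
    _check_schema(events)
    if len(events) == 0:
        warnings.warn("gating an empty event table", stacklevel=2)
        return events.copy()
    if gates.viability_keep == "below":
        keep = events["viability"] <= gates.viability_cutoff
    else:
        keep = events["viability"] >= gates.viability_cutoff
    keep &= events["donor"] >= gates.donor_min
    keep &= events["acceptor"] >= gates.acceptor_min
    gated = events.loc[keep].copy()
    gated.attrs = dict(events.attrs)
    return gated


def fret_positive_fraction(events: pd.DataFrame, gates: GateSpec) -> float:
    """%FRET+ of the gated population, on the 0-100 scale."""
    gated = gate_events(events, gates)
    if len(gated) == 0:
        raise UndefinedValueError("%FRET+ undefined: no events pass the gates")
    return 100.0 * float((gated["fret"] >= gates.fret_threshold).mean())


def fret_mfi(
    events: pd.DataFrame,
    gates: GateSpec,
    scope: Literal["positive", "gated"] = "positive",
) -> float:
    """Median FRET intensity (MFI).

    ``scope="positive"`` (default) takes the median over FRET-positive events
    only; ``"gated"`` over all gated events. With zero FRET-positive events
    the MFI is 0, so the normalized score of an aggregate-free well is 0
    rather than an error.
    """
    gated = gate_events(events, gates)
    if scope == "gated":
        if len(gated) == 0:
            raise UndefinedValueError("MFI undefined: no events pass the gates")
        return float(gated["fret"].median())
    positive = gated.loc[gated["fret"] >= gates.fret_threshold, "fret"]
    if len(positive) == 0:
        return 0.0
    return float(positive.median())


def normalized_fret(percent_fret_positive: float, mfi: float) -> float:
    """The screen score: %FRET+ (0-100 scale) times FRET MFI."""
    if not 0.0 <= percent_fret_positive <= 100.0:
        raise UndefinedValueError(
            f"percent_fret_positive must be in [0,100], got {percent_fret_positive}"
        )
    if mfi < 0:
        raise UndefinedValueError(f"MFI must be >= 0, got {mfi}")
    return percent_fret_positive * mfi


def summarize_well(
    events: pd.DataFrame,
    gates: GateSpec,
    mfi_scope: Literal["positive", "gated"] = "positive",
) -> FretSummary:
    """Gate one well and compute its full FRET summary."""
    gated = gate_events(events, gates)
    n = len(gated)
    if n == 0:
        return FretSummary(0.0, 0.0, 0.0, 0, well=events.attrs.get("well"), no_positive_events=True)
    percent = 100.0 * float((gated["fret"] >= gates.fret_threshold).mean())
    mfi = fret_mfi(gated, replace(gates, viability_cutoff=np.inf, donor_min=-np.inf,
                                  acceptor_min=-np.inf), scope=mfi_scope)
    return FretSummary(
        percent_fret_positive=percent,
        fret_mfi=mfi,
        normalized_fret=percent * mfi,
        n_events_gated=n,
        well=events.attrs.get("well"),
        no_positive_events=percent == 0.0,
    )


def summarize_plate(
    plate: dict[str, pd.DataFrame],
    gates: GateSpec,
    mfi_scope: Literal["positive", "gated"] = "positive",
) -> pd.DataFrame:
    """Per-well summaries for a whole plate, one row per well."""
    rows = []
    for well, events in plate.items():
        s = summarize_well(events, gates, mfi_scope=mfi_scope)
        rows.append(
            {
                "well": well,
                "percent_fret_positive": s.percent_fret_positive,
                "fret_mfi": s.fret_mfi,
                "normalized_fret": s.normalized_fret,
                "n_events_gated": s.n_events_gated,
            }
        )
    return pd.DataFrame(rows)


def auto_fret_threshold(
    negative_wells: Iterable[pd.DataFrame],
    gates: GateSpec | None = None,
    percentile: float = 99.5,
) -> float:
    """Control-anchored FRET-positive threshold.

    Pools the (viability/double-positive gated) FRET channel of the
    no-induction control wells and returns its ``percentile`` — by default the
    99.5th, so ~0.5% gate leakage is expected on true negatives.
    """
    pooled: list[np.ndarray] = []
    for events in negative_wells:
        if gates is not None:
            events = gate_events(events, gates)
        else:
            _check_schema(events)
        pooled.append(events["fret"].to_numpy())
    if not pooled or sum(len(p) for p in pooled) == 0:
        raise UndefinedValueError("no negative-control events to anchor the gate on")
    return float(np.percentile(np.concatenate(pooled), percentile))


def mfi_fold_change(
    treated: pd.DataFrame, control: pd.DataFrame, channel: str
) -> float:
    """Median fold change of one channel between two event tables.

    Used for per-channel readouts such as an acidic-compartment dye or
    dextran uptake: ``median(channel | treated) / median(channel | control)``.
    """
    for name, table in (("treated", treated), ("control", control)):
        if channel not in table.columns:
            raise SchemaError(f"{name} table has no channel {channel!r}")
        if len(table) == 0:
            raise SchemaError(f"{name} table is empty")
    denom = float(control[channel].median())
    if denom == 0:
        raise UndefinedValueError("control median is 0; fold change undefined")
    return float(treated[channel].median()) / denom
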