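"""Synthetic flow-cytometry plates with known per-well aggregation fractions.

The generator emulates a seeded-aggregation FRET screen: each well holds a
two-component mixture of FRET-negative cells and FRET-positive
(aggregate-bearing) cells. Channel intensities are log-normal per channel and
subpopulation; FRET-positive cells show sensitized emission (bright FRET
channel) with partial donor quenching. A compound's effect is a multiplicative
factor on the well's true positive fraction, one factor per concentration
tier, so recovery of planted effects can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..errors import ConfigurationError

EVENT_COLUMNS = ("event_id", "donor", "acceptor", "fret", "viability")

#: roles a well can take in the plate layout
ROLES = ("compound", "vehicle", "negative-control", "positive-control")


@dataclass(frozen=True)
class ChannelModel:
    """Log-normal intensity model for one channel.

    ``neg``/``pos`` are ``(mu, sigma)`` of the underlying normal on the
    natural-log scale, for the FRET-negative and FRET-positive subpopulations.
    """

    neg: tuple[float, float]
    pos: tuple[float, float]


def default_channel_params() -> dict[str, ChannelModel]:
    """Well-separated fluorescence populations in arbitrary cytometer units.

    FRET-negative cells have a dim FRET channel (median ~100 a.u.);
    aggregate-bearing cells are ~10x brighter (median ~1000 a.u.) with the
    donor partially quenched (median 1000 -> 600 a.u.).
    """
    ln = np.log
    return {
        "donor": ChannelModel(neg=(ln(1000.0), 0.35), pos=(ln(600.0), 0.35)),
        "acceptor": ChannelModel(neg=(ln(800.0), 0.35), pos=(ln(800.0), 0.35)),
        "fret": ChannelModel(neg=(ln(100.0), 0.45), pos=(ln(1000.0), 0.45)),
    }


@dataclass(frozen=True)
class PlateSimConfig:
    """Configuration for one simulated screening plate.

    Parameters
    ----------
    n_wells_per_compound
        Replicate wells per compound and concentration tier.
    n_compounds
        Number of library compounds. Compounds are named ``C001``.. unless
        effects name others explicitly.
    n_events_per_well
        Acquired events (cells) per well.
    concentrations
        Nominal dose tiers (µM labels; values are labels only).
    baseline_positive_fraction
        Fraction of aggregate-bearing cells in induced vehicle wells.
    compound_effects
        compound -> multiplicative effect on the positive fraction, either a
        scalar (applied at every tier) or a tier -> factor map. 1.0 = inert,
        <1 inhibitor, >1 exacerbator. Unlisted compounds are inert.
    channel_params
        Per-channel log-normal models (see :class:`ChannelModel`).
    viability_live, viability_dead
        ``(mu, sigma)`` log-normal parameters of the viability dye for live
        and dead cells; dead cells stain bright.
    dead_fraction
        Fraction of dead cells per well, independent of FRET status.
    n_control_wells
        Wells per control role (vehicle, negative-control, positive-control).
    """

    n_wells_per_compound: int = 1
    n_compounds: int = 80
    n_events_per_well: int = 10_000
    concentrations: tuple[float, ...] = (2.0, 4.0, 10.0)
    baseline_positive_fraction: float = 0.30
    compound_effects: Mapping[str, float | Mapping[float, float]] = field(
        default_factory=dict
    )
    channel_params: Mapping[str, ChannelModel] = field(
        default_factory=default_channel_params
    )
    viability_live: tuple[float, float] = (np.log(50.0), 0.5)
    viability_dead: tuple[float, float] = (np.log(5000.0), 0.4)
    dead_fraction: float = 0.05
    n_control_wells: int = 6
    seed: int = 0

    def compound_names(self) -> list[str]:
        named = list(self.compound_effects)
        width = max(3, len(str(self.n_compounds)))
        autos = (f"C{i:0{width}d}" for i in range(1, self.n_compounds + 1))
        names = list(named)
        for name in autos:
            if len(names) >= self.n_compounds:
                break
            if name not in names:
                names.append(name)
        if len(names) > self.n_compounds:
            raise ConfigurationError(
                f"{len(named)} compounds named in compound_effects exceed "
                f"n_compounds={self.n_compounds}"
            )
        return names

    def effect(self, compound: str, tier: float) -> float:
        eff = self.compound_effects.get(compound, 1.0)
        if isinstance(eff, Mapping):
            eff = eff.get(tier, 1.0)
        return float(eff)

    def validate(self) -> None:
        if not 0.0 <= self.baseline_positive_fraction <= 1.0:
            raise ConfigurationError(
                f"baseline_positive_fraction must be in [0,1], got "
                f"{self.baseline_positive_fraction}"
            )
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ConfigurationError("dead_fraction must be in [0,1]")
        if self.n_events_per_well < 1:
            raise ConfigurationError("n_events_per_well must be >= 1")
        if self.n_compounds < 1 or self.n_wells_per_compound < 1:
            raise ConfigurationError("compound/well counts must be >= 1")
        for compound in self.compound_effects:
            for tier in self.concentrations:
                if self.effect(compound, tier) <= 0:
                    raise ConfigurationError(
                        f"effect for {compound!r} at {tier} must be > 0"
                    )
        for name, model in self.channel_params.items():
            for mu, sigma in (model.neg, model.pos):
                if sigma <= 0:
                    raise ConfigurationError(
                        f"channel {name!r}: log-scale sigma must be > 0"
                    )


@dataclass(frozen=True)
class PlateTruth:
    """Ground truth of a simulated plate: the true positive fraction per well."""

    true_fraction: Mapping[str, float]
    config: PlateSimConfig

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"well": list(self.true_fraction), "true_fraction": list(self.true_fraction.values())}
        )


def build_layout(config: PlateSimConfig) -> pd.DataFrame:
    """Deterministic plate layout: compound wells first, then control blocks.

    Columns: ``well``, ``compound``, ``concentration`` (empty for controls),
    ``role``.
    """
    rows: list[tuple[str, str, float | None, str]] = []
    for compound in config.compound_names():
        for tier in config.concentrations:
            for _ in range(config.n_wells_per_compound):
                rows.append(("", compound, tier, "compound"))
    control_blocks = [
        ("DMSO", "vehicle"),
        ("no-PFF", "negative-control"),
        ("PFF", "positive-control"),
    ]
    for label, role in control_blocks:
        for _ in range(config.n_control_wells):
            rows.append(("", label, None, role))
    width = len(str(len(rows)))
    layout = pd.DataFrame(rows, columns=["well", "compound", "concentration", "role"])
    layout["well"] = [f"W{i + 1:0{max(3, width)}d}" for i in range(len(layout))]
    return layout


def _true_fraction(config: PlateSimConfig, compound: str, tier: float | None, role: str) -> float:
    if role == "negative-control":
        return 0.0
    if role in ("vehicle", "positive-control"):
        return config.baseline_positive_fraction
    frac = config.baseline_positive_fraction * config.effect(compound, float(tier))
    return float(np.clip(frac, 0.0, 1.0))


def _simulate_well(
    config: PlateSimConfig, fraction: float, rng: np.random.Generator
) -> pd.DataFrame:
    n = config.n_events_per_well
    positive = rng.random(n) < fraction
    dead = rng.random(n) < config.dead_fraction
    cols: dict[str, np.ndarray] = {"event_id": np.arange(n)}
    for name, model in config.channel_params.items():
        mu = np.where(positive, model.pos[0], model.neg[0])
        sigma = np.where(positive, model.pos[1], model.neg[1])
        cols[name] = rng.lognormal(mean=mu, sigma=sigma)
    mu_v = np.where(dead, config.viability_dead[0], config.viability_live[0])
    sd_v = np.where(dead, config.viability_dead[1], config.viability_live[1])
    cols["viability"] = rng.lognormal(mean=mu_v, sigma=sd_v)
    events = pd.DataFrame(cols)
    events["true_positive"] = positive  # ground-truth helper column, dropped on write
    return events


def simulate_plate(
    config: PlateSimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, PlateTruth]:
    """Simulate one screening plate.

    Returns ``(plate, layout, truth)`` where ``plate`` maps well id to an
    event table with columns ``event_id, donor, acceptor, fret, viability``
    (plus a ``true_positive`` ground-truth column).

    All randomness descends from ``config.seed``: a root ``SeedSequence`` is
    spawned once per well, in layout order, so adding channels or changing a
    single well's parameters never perturbs the other wells.
    """
    config.validate()
    layout = build_layout(config)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(layout))
    plate: dict[str, pd.DataFrame] = {}
    fractions: dict[str, float] = {}
    for (_, row), child in zip(layout.iterrows(), children):
        frac = _true_fraction(config, row["compound"], row["concentration"], row["role"])
        rng = np.random.default_rng(child)
        events = _simulate_well(config, frac, rng)
        events.attrs["well"] = row["well"]
        plate[row["well"]] = events
        fractions[row["well"]] = frac
    return plate, layout, PlateTruth(true_fraction=fractions, config=config)


def expected_gated_fraction(
    config: PlateSimConfig, fret_threshold: float, true_fraction: float
) -> float:
    """Closed-form expected measured %positive/100 for a well, given the gate.

    A threshold gate leaks: a fraction of true negatives sits above it and a
    fraction of true positives below. Under the configured log-normals the
    measured fraction converges to

        f·P(pos ≥ t) + (1 − f)·P(neg ≥ t),

    which is the right oracle for recovery tests (not f itself).
    """
    from scipy.stats import lognorm

    model = config.channel_params["fret"]
    p_pos = float(lognorm.sf(fret_threshold, s=model.pos[1], scale=np.exp(model.pos[0])))
    p_neg = float(lognorm.sf(fret_threshold, s=model.neg[1], scale=np.exp(model.neg[0])))
    return true_fraction * p_pos + (1.0 - true_fraction) * p_neg


def with_planted_inhibitors(
    config: PlateSimConfig,
    inhibitors: Sequence[str],
    effect: float = 0.1,
) -> PlateSimConfig:
    """Convenience: plant the same inhibitory effect for a set of compounds."""
    effects = dict(config.compound_effects)
    effects.update({name: effect for name in inhibitors})
    return replace(config, compound_effects=effects)
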