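"""Screen statistics: z-scores, hit calling, and Z'-factor assay quality.

Per concentration tier, each compound's normalized FRET score x is
standardized against the compound-well sample of that tier,

    z = (x - mu_sample) / sigma_sample        (sigma with ddof=1),

control wells are scored against the same sample distribution without being
part of it, and a compound is an inhibitor hit when z <= -threshold at every
tier (exacerbator: z >= +threshold at every tier); the default threshold is
1.5. Assay quality uses the standard Z'-factor,

    Z' = 1 - 3 (sigma_p + sigma_n) / |mu_p - mu_n|,

over the maximal-induction (p) and no-induction (n) control bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDistributionError,
    IncompleteDoseSeriesError,
    UndefinedValueError,
)

DEFAULT_THRESHOLD = 1.5


@dataclass(frozen=True)
class SampleStats:
    """Mean/SD of the compound-score sample a well is standardized against."""

    mean: float
    sd: float
    n: int

    @classmethod
    def from_scores(cls, scores: Sequence[float], ddof: int = 1) -> "SampleStats":
        x = np.asarray(scores, dtype=float)
        if x.size < 2:
            raise DegenerateDistributionError(
                f"need >= 2 scores to estimate a sample SD, got {x.size}"
            )
        sd = float(x.std(ddof=ddof))
        if sd == 0:
            raise DegenerateDistributionError("zero-variance score sample")
        return cls(mean=float(x.mean()), sd=sd, n=int(x.size))


@dataclass(frozen=True)
class ControlStats:
    """Control bands for Z': p = maximal induction, n = no induction."""

    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float

    @classmethod
    def from_scores(
        cls, positive: Sequence[float], negative: Sequence[float]
    ) -> "ControlStats":
        p = np.asarray(positive, dtype=float)
        n = np.asarray(negative, dtype=float)
        return cls(
            mu_p=float(p.mean()),
            sigma_p=float(p.std(ddof=1)) if p.size > 1 else 0.0,
            mu_n=float(n.mean()),
            sigma_n=float(n.std(ddof=1)) if n.size > 1 else 0.0,
        )


def zscores(scores: Sequence[float], ddof: int = 1) -> np.ndarray:
    """Standardize scores against their own mean and SD."""
    stats = SampleStats.from_scores(scores, ddof=ddof)
    return (np.asarray(scores, dtype=float) - stats.mean) / stats.sd


def score_against(values: Sequence[float] | float, stats: SampleStats) -> np.ndarray:
    """z for wells outside the sample (controls), using the sample mu/sigma."""
    if stats.sd <= 0:
        raise DegenerateDistributionError("sample SD must be > 0")
    return (np.asarray(values, dtype=float) - stats.mean) / stats.sd


def build_screen_table(
    summaries: pd.DataFrame,
    layout: pd.DataFrame,
    score_column: str = "normalized_fret",
    replicate: str | None = None,
) -> pd.DataFrame:
    """Join per-well scores to the layout and z-score per concentration tier.

    The standardization sample is the compound wells of each tier; control
    wells are excluded from it and carry NaN z here (score them against a
    tier's compound distribution with :func:`control_z`).

    Returns rows ``well, compound, concentration, role, score, z``
    (plus ``replicate`` when given).
    """
    merged = layout.merge(summaries[["well", score_column]], on="well", how="left")
    if merged[score_column].isna().any():
        missing = merged.loc[merged[score_column].isna(), "well"].tolist()
        raise UndefinedValueError(f"wells without summaries: {missing}")
    merged = merged.rename(columns={score_column: "score"})
    merged["z"] = np.nan
    is_compound = merged["role"] == "compound"
    for tier, idx in merged.loc[is_compound].groupby("concentration").groups.items():
        merged.loc[idx, "z"] = zscores(merged.loc[idx, "score"].to_numpy())
    if replicate is not None:
        merged["replicate"] = replicate
    return merged


def control_z(
    screen: pd.DataFrame, role: str = "negative-control"
) -> pd.DataFrame:
    """Score control wells against each tier's compound-sample distribution.

    Returns one row per (control well, tier) with the control's z under that
    tier's compound mu/sigma — the convention that places no-induction
    controls well below the compound cloud.
    """
    out = []
    compounds = screen[screen["role"] == "compound"]
    controls = screen[screen["role"] == role]
    if controls.empty:
        raise UndefinedValueError(f"no wells with role {role!r}")
    for tier, group in compounds.groupby("concentration"):
        stats = SampleStats.from_scores(group["score"].to_numpy())
        z = score_against(controls["score"].to_numpy(), stats)
        out.append(
            pd.DataFrame(
                {
                    "well": controls["well"].to_numpy(),
                    "concentration": tier,
                    "z": z,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def aggregate_replicates(screens: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average per-replicate z per compound x tier (z computed per replicate first)."""
    stacked = pd.concat(screens, ignore_index=True)
    compounds = stacked[stacked["role"] == "compound"]
    return (
        compounds.groupby(["compound", "concentration"], as_index=False)
        .agg(score=("score", "mean"), z=("z", "mean"))
    )


def call_hits(
    screen: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    tiers: Literal["all"] | float = "all",
) -> pd.DataFrame:
    """Call inhibitor/exacerbator hits from per-compound, per-tier z-scores.

    ``screen`` needs columns ``compound, concentration, z`` (compound rows
    only, or a ``role`` column to filter on). With ``tiers="all"`` (default) an
    inhibitor hit requires z <= -threshold at *every* tier and an exacerbator
    z >= +threshold at every tier; passing a single tier value applies the
    rule at that tier only.

    Returns one row per compound with per-tier z columns ``z@<tier>``,
    per-tier pass flags, ``direction`` (inhibitor | exacerbator | none) and
    the overall ``hit`` flag.
    """
    if "role" in screen.columns:
        screen = screen[screen["role"] == "compound"]
    wide = screen.pivot_table(index="compound", columns="concentration", values="z")
    if wide.isna().any(axis=None):
        offenders = {
            comp: [str(t) for t in wide.columns[row.isna()]]
            for comp, row in wide.iterrows()
            if row.isna().any()
        }
        raise IncompleteDoseSeriesError(
            f"compounds missing z at tiers: {offenders}"
        )
    tier_values = list(wide.columns) if tiers == "all" else [tiers]
    missing = [t for t in tier_values if t not in wide.columns]
    if missing:
        raise IncompleteDoseSeriesError(f"requested tiers absent from screen: {missing}")

    sub = wide[tier_values]
    inhib = (sub <= -threshold).all(axis=1)
    exac = (sub >= threshold).all(axis=1)
    out = wide.copy()
    out.columns = [f"z@{t:g}" for t in wide.columns]
    for t in tier_values:
        out[f"pass_inhibitor@{t:g}"] = wide[t] <= -threshold
        out[f"pass_exacerbator@{t:g}"] = wide[t] >= threshold
    out["direction"] = np.where(inhib, "inhibitor", np.where(exac, "exacerbator", "none"))
    out["hit"] = inhib | exac
    return out.reset_index().sort_values("compound", ignore_index=True)


def z_prime(controls: ControlStats) -> float:
    """Z'-factor: 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n|; 1 is a perfect assay."""
    sep = abs(controls.mu_p - controls.mu_n)
    if sep == 0:
        raise UndefinedValueError("Z' undefined: control means are equal")
    if controls.sigma_p < 0 or controls.sigma_n < 0:
        raise UndefinedValueError("control SDs must be >= 0")
    return 1.0 - 3.0 * (controls.sigma_p + controls.sigma_n) / sep


def rank_waterfall(screen: pd.DataFrame, tier: float = 10.0) -> pd.DataFrame:
    """Compounds sorted ascending by z at one tier; ties break alphabetically."""
    if "role" in screen.columns:
        screen = screen[screen["role"] == "compound"]
    at_tier = screen[screen["concentration"] == tier]
    if at_tier.empty:
        raise IncompleteDoseSeriesError(f"no compound rows at tier {tier}")
    return (
        at_tier.sort_values(["z", "compound"], kind="mergesort")
        .reset_index(drop=True)[["compound", "concentration", "score", "z"]]
    )
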