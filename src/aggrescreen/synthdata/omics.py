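"""Synthetic label-free-quantification matrices with planted differential sets.

Emulates the downstream shape of an LFQ experiment: a feature x sample
intensity matrix over a control group and one or more treatment groups, where
a chosen ("planted") subset of features carries a group-specific log2 shift of
fixed magnitude and random sign, on top of i.i.d. Gaussian noise on the log2
scale. Matrices are returned on the raw intensity scale (2**log2) so the full
normalize -> fold-change -> set-overlap pipeline can run end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from ..omicsets import OmicsMatrix


@dataclass(frozen=True)
class OmicsSimConfig:
    n_features: int = 2000
    groups: Mapping[str, int] = field(
        default_factory=lambda: {"control": 3, "drugA": 3, "drugB": 3}
    )
    control_group: str = "control"
    effect_sd: float = 1.0  # magnitude of planted log2 shifts
    noise_sd: float = 0.25  # residual log2 scale
    planted_sets: Mapping[str, frozenset[int]] = field(default_factory=dict)
    baseline_mean: float = 20.0  # log2 intensity scale of the instrument
    baseline_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if self.control_group not in self.groups:
            raise ConfigurationError(
                f"control group {self.control_group!r} missing from groups"
            )
        for name, reps in self.groups.items():
            if reps < 2:
                raise ConfigurationError(
                    f"group {name!r} has {reps} replicates; >= 2 required"
                )
        for name, planted in self.planted_sets.items():
            if name not in self.groups or name == self.control_group:
                raise ConfigurationError(
                    f"planted set for {name!r} does not match a treatment group"
                )
            bad = [i for i in planted if not 0 <= i < self.n_features]
            if bad:
                raise ConfigurationError(
                    f"planted features out of range for {name!r}: {sorted(bad)[:5]}"
                )
        if self.noise_sd < 0 or self.effect_sd < 0:
            raise ConfigurationError("effect_sd and noise_sd must be >= 0")


@dataclass(frozen=True)
class OmicsTruth:
    """Planted per-treatment altered features and their signed log2 shifts."""

    planted_sets: Mapping[str, frozenset[int]]
    shifts: pd.DataFrame  # features x treatments, signed log2 shift
    config: OmicsSimConfig = field(repr=False)

    def planted_ids(self, treatment: str) -> frozenset[str]:
        return frozenset(self.shifts.index[sorted(self.planted_sets[treatment])])


def planted_sets_with_overlap(
    treatments: Sequence[str],
    n_features: int,
    set_size: int,
    overlap: float,
    seed: int = 0,
) -> dict[str, frozenset[int]]:
    """Two planted sets of ``set_size`` features with a target Venn overlap.

    ``overlap`` is the Venn-style shared fraction |A∩B|/|A∪B|; the shared
    block has ``k = round(2·set_size·overlap/(1+overlap))`` features, the
    closest integer realization of that target.
    """
    if len(treatments) != 2:
        raise ConfigurationError("overlap construction is defined for two treatments")
    if not 0.0 <= overlap <= 1.0:
        raise ConfigurationError("overlap must be in [0,1]")
    k = round(2 * set_size * overlap / (1 + overlap))
    need = 2 * set_size - k
    if need > n_features:
        raise ConfigurationError(
            f"need {need} distinct features for two sets of {set_size} "
            f"with overlap {overlap}, have {n_features}"
        )
    rng = np.random.default_rng(seed)
    pool = rng.choice(n_features, size=need, replace=False)
    shared = pool[:k]
    a_only = pool[k : set_size]
    b_only = pool[set_size :]
    return {
        treatments[0]: frozenset(np.concatenate([shared, a_only]).tolist()),
        treatments[1]: frozenset(np.concatenate([shared, b_only]).tolist()),
    }


def simulate_omics(config: OmicsSimConfig) -> tuple[OmicsMatrix, OmicsTruth]:
    """Simulate an LFQ matrix; returns ``(matrix, truth)``.

    The matrix is on the raw intensity scale with samples named
    ``<group>_r<replicate>`` and features ``F00001``...
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_base, rng_shift, rng_noise = (np.random.default_rng(s) for s in root.spawn(3))

    width = max(5, len(str(config.n_features)))
    features = [f"F{i + 1:0{width}d}" for i in range(config.n_features)]
    baseline = rng_base.normal(config.baseline_mean, config.baseline_sd, config.n_features)

    treatments = [g for g in config.groups if g != config.control_group]
    shifts = pd.DataFrame(0.0, index=features, columns=treatments)
    for treatment in treatments:
        for idx in sorted(config.planted_sets.get(treatment, ())):
            sign = 1.0 if rng_shift.random() < 0.5 else -1.0
            shifts.iloc[idx, shifts.columns.get_loc(treatment)] = sign * config.effect_sd

    columns: dict[str, np.ndarray] = {}
    annotations: list[tuple[str, str, int]] = []
    for group, reps in config.groups.items():
        shift = shifts[group].to_numpy() if group in shifts.columns else 0.0
        for r in range(1, reps + 1):
            sample = f"{group}_r{r}"
            log2 = baseline + shift + rng_noise.normal(0, config.noise_sd, config.n_features)
            columns[sample] = np.power(2.0, log2)
            annotations.append((sample, group, r))

    values = pd.DataFrame(columns, index=pd.Index(features, name="feature"))
    samples = pd.DataFrame(
        annotations, columns=["sample", "treatment", "replicate"]
    ).set_index("sample")
    matrix = OmicsMatrix(values=values, samples=samples)
    truth = OmicsTruth(
        planted_sets={k: frozenset(v) for k, v in config.planted_sets.items()},
        shifts=shifts,
        config=config,
    )
    return matrix, truth
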