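"""SYNTHETIC stand-in for a published kinase-inhibitor screen score table.

The original screen scored an 80-compound kinase-inhibitor library (plus
controls) at three concentration tiers by normalized FRET intensity and
ranked compounds by z-score, with documented outcomes: four inhibitor hits
(SB203580, GF109203X, SB202190, U-0126) beyond z = −1.5 at every tier, five
exacerbators (rapamycin, 5-iodotubericidin, erbstatin analogue, LY294002,
KN-62) beyond +1.5, rapamycin holding a mean z of 4.49 across tiers, and
no-induction control wells averaging z = −1.88 against the compound
distribution.

The deposited score table itself is not redistributable here, so this module
*constructs* a synthetic score table with exactly that structure: per tier,
a z-target vector is assembled (named compounds pinned to documented-scale
values, null compounds filling in so that the vector has mean 0 and sample
SD 1), then mapped affinely onto a positive normalized-FRET score scale.
Because z-scoring is affine-invariant, running the screen statistics on
these scores reproduces the embedded z-values exactly — which makes the
table a fixture for exercising the z-score → hit-call → control-z pipeline,
not a reproduction of the original measurements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import ConfigurationError

TIERS = (2.0, 4.0, 10.0)

#: documented inhibitor hits and the z targets pinned for them, per tier
INHIBITORS: dict[str, tuple[float, float, float]] = {
    "SB203580": (-1.8, -2.0, -2.2),
    "GF109203X": (-1.6, -1.7, -1.9),
    "SB202190": (-1.9, -2.1, -2.3),
    "U-0126": (-1.55, -1.65, -1.8),
}

#: documented exacerbators; rapamycin pinned flat at 4.49, others dose-dependent
EXACERBATORS: dict[str, tuple[float, float, float]] = {
    "rapamycin": (4.49, 4.49, 4.49),
    "5-iodotubericidin": (1.55, 1.8, 2.2),
    "erbstatin-analogue": (1.6, 1.7, 2.0),
    "LY294002": (1.55, 1.7, 1.9),
    "KN-62": (1.6, 1.8, 2.1),
}

NEGATIVE_CONTROL_Z = -1.88
LIBRARY_SIZE = 80

_SCORE_LOC = 50_000.0  # a.u., arbitrary positive normalized-FRET scale
_SCORE_SCALE = 8_000.0


def _null_fill(pinned: np.ndarray, n_null: int, rng: np.random.Generator) -> np.ndarray:
    """Null-compound z values making the full vector mean 0, sample SD 1.

    Draws nulls from a centered normal, then rescales/shifts the null block
    so the concatenated vector is exactly standardized; the affine adjustment
    must leave every null inside the (−1.5, 1.5) no-hit band.
    """
    for attempt in range(512):
        nulls = rng.normal(0.0, 0.6, n_null)
        nulls -= nulls.mean()
        n_total = n_null + pinned.size
        # solve b: Var_total(concat(b*nulls, pinned)) = 1 with mean 0
        target_ss = (n_total - 1) * 1.0
        shift = -pinned.sum() / n_null  # mean of nulls after shift
        resid = target_ss - np.sum(pinned**2) - n_null * shift**2
        if resid <= 0:
            continue
        b = np.sqrt(resid / np.sum(nulls**2))
        candidate = b * nulls + shift
        if np.all(np.abs(candidate) < 1.5):
            full = np.concatenate([candidate, pinned])
            assert abs(full.mean()) < 1e-12 and abs(full.std(ddof=1) - 1) < 1e-12
            return candidate
    raise ConfigurationError("could not construct a standardized null block")


def standin_screen_table(
    n_compounds: int = LIBRARY_SIZE,
    n_negative_controls: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Build the synthetic screen score table.

    Returns rows ``well, compound, concentration, role, score`` — compound
    wells for ``n_compounds`` compounds at the three tiers plus
    ``n_negative_controls`` no-induction control wells whose scores sit at
    z = −1.88 (mean; ±0.01 alternating spread) under each tier's compound
    distribution.
    """
    named = {**INHIBITORS, **EXACERBATORS}
    if n_compounds < len(named) + 2:
        raise ConfigurationError(f"need at least {len(named) + 2} compounds")
    n_null = n_compounds - len(named)
    width = max(3, len(str(n_null)))
    null_names = [f"null-{i + 1:0{width}d}" for i in range(n_null)]
    compounds = null_names + list(named)

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for t_idx, tier in enumerate(TIERS):
        pinned = np.array([named[c][t_idx] for c in named])
        nulls = _null_fill(pinned, n_null, rng)
        z = np.concatenate([nulls, pinned])
        scores = _SCORE_LOC + _SCORE_SCALE * z
        for compound, score in zip(compounds, scores):
            rows.append(
                {
                    "compound": compound,
                    "concentration": tier,
                    "role": "compound",
                    "score": float(score),
                }
            )
        spread = 0.01 * np.resize([1.0, -1.0], n_negative_controls)
        if n_negative_controls % 2:
            spread[-1] = 0.0
        for i, s in enumerate(spread):
            rows.append(
                {
                    "compound": "no-PFF",
                    "concentration": tier,
                    "role": "negative-control",
                    "score": float(_SCORE_LOC + _SCORE_SCALE * (NEGATIVE_CONTROL_Z + s)),
                }
            )
    table = pd.DataFrame(rows)
    table.insert(0, "well", [f"W{i + 1:04d}" for i in range(len(table))])
    return table
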