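"""Readers/writers and the end-to-end screen runner.

On-disk formats are deliberately plain: one event CSV per well (columns
``event_id, donor, acceptor, fret, viability``), a plate-layout CSV
(``well, compound, concentration, role``), per-well summary TSVs, screen and
hit TSVs, 16-bit TIFF images (one file per channel), omics TSVs, and JSON
reports. Every writer has a matching reader and round-trips losslessly at the
written precision.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import ConfigurationError, SchemaError, UndefinedValueError
from .flowfret import (
    GateSpec,
    REQUIRED_COLUMNS,
    auto_fret_threshold,
    summarize_plate,
)
from .screenstats import (
    ControlStats,
    build_screen_table,
    call_hits,
    control_z,
    rank_waterfall,
    z_prime,
)
from .synthdata.plates import ROLES

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------- plates

def write_plate(
    plate: Mapping[str, pd.DataFrame], layout: pd.DataFrame, outdir: str | Path
) -> Path:
    """One CSV per well plus ``layout.csv``; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for well, events in plate.items():
        cols = [c for c in ("event_id", *REQUIRED_COLUMNS) if c in events.columns]
        events[cols].to_csv(outdir / f"{well}.csv", index=False, float_format=FLOAT_FORMAT)
    layout.to_csv(outdir / "layout.csv", index=False)
    return outdir


def read_layout(path: str | Path) -> pd.DataFrame:
    layout = pd.read_csv(path)
    required = {"well", "compound", "concentration", "role"}
    missing = required - set(layout.columns)
    if missing:
        raise SchemaError(f"layout missing columns: {sorted(missing)}")
    if layout["well"].duplicated().any():
        dupes = layout.loc[layout["well"].duplicated(), "well"].tolist()
        raise SchemaError(f"duplicate wells in layout: {dupes}")
    bad_roles = sorted(set(layout["role"]) - set(ROLES))
    if bad_roles:
        raise SchemaError(f"unknown roles {bad_roles}; allowed roles: {list(ROLES)}")
    return layout


def load_plate(
    events_dir: str | Path, layout_path: str | Path | None = None
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Read a plate directory; validates schema, roles and well coverage."""
    events_dir = Path(events_dir)
    layout_path = Path(layout_path) if layout_path else events_dir / "layout.csv"
    layout = read_layout(layout_path)
    plate: dict[str, pd.DataFrame] = {}
    for well in layout["well"]:
        path = events_dir / f"{well}.csv"
        if not path.exists():
            raise SchemaError(f"layout well {well!r} has no event file at {path}")
        events = pd.read_csv(path)
        missing = [c for c in REQUIRED_COLUMNS if c not in events.columns]
        if missing:
            raise SchemaError(f"well {well!r} event table missing columns: {missing}")
        events.attrs["well"] = well
        plate[well] = events
    return plate, layout


# ---------------------------------------------------------------- images

def write_image_channels(
    channels: Mapping[str, np.ndarray], outdir: str | Path, prefix: str = "frame"
) -> dict[str, Path]:
    """Each channel as a 16-bit TIFF (values rounded and clipped to uint16)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, img in channels.items():
        data = np.clip(np.rint(np.asarray(img, dtype=float)), 0, 65535).astype(np.uint16)
        path = outdir / f"{prefix}_{name}.tif"
        tifffile.imwrite(path, data)
        paths[name] = path
    return paths


def read_image(path: str | Path) -> np.ndarray:
    """Single-channel 2-D image from TIFF or PNG, as float."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img, dtype=float)
    if img.ndim == 3 and img.shape[0] == 1:
        img = img[0]
    if img.ndim != 2:
        raise SchemaError(f"{path} is not a single-channel 2-D image (shape {img.shape})")
    return img


# ---------------------------------------------------------------- omics

def write_omics(matrix, outdir: str | Path, prefix: str = "omics") -> dict[str, Path]:
    """Matrix TSV (features × samples), annotation TSV, optional flags TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": outdir / f"{prefix}_matrix.tsv",
        "samples": outdir / f"{prefix}_samples.tsv",
    }
    matrix.values.to_csv(paths["values"], sep="\t", float_format=FLOAT_FORMAT)
    matrix.samples.to_csv(paths["samples"], sep="\t")
    if matrix.flags is not None:
        paths["flags"] = outdir / f"{prefix}_flags.tsv"
        matrix.flags.to_frame().to_csv(paths["flags"], sep="\t")
    return paths


def read_omics(
    values_path: str | Path,
    samples_path: str | Path,
    flags_path: str | Path | None = None,
    log_scale: bool = False,
):
    from .omicsets import OmicsMatrix

    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    flags = None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col=0).iloc[:, 0].astype(bool)
    return OmicsMatrix(values=values, samples=samples, flags=flags, log_scale=log_scale)


# ---------------------------------------------------------------- tables & reports

def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# aggrescreen v{__version__}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(payload: Mapping[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------- run config & screen

_RUNCONFIG_KEYS = {
    "events_dir",
    "layout",
    "output_dir",
    "viability_cutoff",
    "viability_keep",
    "donor_min",
    "acceptor_min",
    "fret_threshold",
    "gate_percentile",
    "mfi_scope",
    "threshold",
    "tiers",
    "seed",
}


@dataclass(frozen=True)
class RunConfig:
    """End-to-end screen run configuration (YAML-loadable).

    With ``fret_threshold`` unset, the gate is auto-anchored at
    ``gate_percentile`` of the pooled negative-control FRET channel.
    ``tiers`` is ``"all"`` (hit must pass every tier) or a single tier value.
    """

    events_dir: str
    output_dir: str
    layout: str | None = None
    viability_cutoff: float = np.inf
    viability_keep: str = "below"
    donor_min: float = -np.inf
    acceptor_min: float = -np.inf
    fret_threshold: float | None = None
    gate_percentile: float = 99.5
    mfi_scope: str = "positive"
    threshold: float = 1.5
    tiers: str | float = "all"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "events_dir" not in raw or "output_dir" not in raw:
            raise ConfigurationError("config requires events_dir and output_dir")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Provenance and QC of one screen run; serialized as JSON."""

    version: str
    config_hash: str
    seed: int
    n_wells: int
    gates: dict[str, Any]
    z_prime: float | None
    control_z_mean: float | None
    control_z_sd: float | None
    n_hits: int
    hit_compounds: list[str]
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        return write_json(asdict(self), path)


def run_screen(config: RunConfig) -> RunReport:
    """Gate → summarize → z-score → hit-call → QC, writing every stage table.

    Deterministic given inputs and config. Z' is computed on normalized FRET
    scores of positive-control (maximal induction) vs negative-control wells;
    the control-z summary scores negative controls against the 10 µM-tier
    compound distribution (or the single configured tier).
    """
    plate, layout = load_plate(config.events_dir, config.layout)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    fret_threshold = config.fret_threshold
    if fret_threshold is None:
        negatives = [
            plate[w] for w in layout.loc[layout["role"] == "negative-control", "well"]
        ]
        if not negatives:
            raise ConfigurationError(
                "no fret_threshold configured and no negative-control wells to anchor on"
            )
        pre_gates = GateSpec(
            fret_threshold=np.inf,
            viability_cutoff=config.viability_cutoff,
            viability_keep=config.viability_keep,  # type: ignore[arg-type]
            donor_min=config.donor_min,
            acceptor_min=config.acceptor_min,
        )
        fret_threshold = auto_fret_threshold(
            negatives, gates=pre_gates, percentile=config.gate_percentile
        )
    gates = GateSpec(
        fret_threshold=fret_threshold,
        viability_cutoff=config.viability_cutoff,
        viability_keep=config.viability_keep,  # type: ignore[arg-type]
        donor_min=config.donor_min,
        acceptor_min=config.acceptor_min,
    )

    summaries = summarize_plate(plate, gates, mfi_scope=config.mfi_scope)  # type: ignore[arg-type]
    screen = build_screen_table(summaries, layout)
    tiers = config.tiers if config.tiers == "all" else float(config.tiers)
    hits = call_hits(screen, threshold=config.threshold, tiers=tiers)
    waterfall_tier = (
        max(t for t in screen["concentration"].dropna().unique())
        if tiers == "all"
        else tiers
    )
    waterfall = rank_waterfall(screen, tier=waterfall_tier)

    zp = None
    pos = screen.loc[screen["role"] == "positive-control", "score"]
    neg = screen.loc[screen["role"] == "negative-control", "score"]
    if len(pos) >= 2 and len(neg) >= 2:
        try:
            zp = z_prime(ControlStats.from_scores(pos, neg))
        except UndefinedValueError:
            warnings.warn("Z' undefined: control means equal", stacklevel=2)

    cz_mean = cz_sd = None
    if (screen["role"] == "negative-control").any():
        cz = control_z(screen)
        cz = cz[cz["concentration"] == waterfall_tier]
        cz_mean, cz_sd = float(cz["z"].mean()), float(cz["z"].std(ddof=1))

    outputs = {
        "summaries": str(write_table(summaries, outdir / "summaries.tsv")),
        "screen": str(write_table(screen, outdir / "screen.tsv")),
        "hits": str(write_table(hits, outdir / "hits.tsv")),
        "waterfall": str(write_table(waterfall, outdir / "waterfall.tsv")),
    }
    report = RunReport(
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
        n_wells=len(layout),
        gates={
            "fret_threshold": float(gates.fret_threshold),
            "viability_cutoff": float(gates.viability_cutoff),
            "viability_keep": gates.viability_keep,
            "donor_min": float(gates.donor_min),
            "acceptor_min": float(gates.acceptor_min),
        },
        z_prime=zp,
        control_z_mean=cz_mean,
        control_z_sd=cz_sd,
        n_hits=int(hits["hit"].sum()),
        hit_compounds=hits.loc[hits["hit"], "compound"].tolist(),
        outputs=outputs,
    )
    report.to_json(outdir / "report.json")
    return report
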