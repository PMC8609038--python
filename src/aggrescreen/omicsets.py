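"""Downstream omics computations: normalization, fold changes, set overlap.

The container is :class:`OmicsMatrix` — a feature × sample intensity frame
with sample annotations (treatment, replicate) and optional per-feature
significance flags. The pipeline mirrors standard label-free-quantification
post-processing: log2 transform and per-sample median centering, group-mean
log2 fold changes, "altered" feature sets defined by significance plus a
|log2FC| ≥ 0.5 cutoff, Venn-style overlap percentages between treatments'
altered sets, pairwise-complete replicate Pearson correlation, and average-
linkage hierarchical clustering of log2FC profiles on correlation distance.

Significance is expected to be supplied externally (the field's multi-sample
testing frameworks are their own tools); :func:`welch_flags` is a simple
internal stand-in — per-feature Welch t-test with Benjamini–Hochberg
adjustment — intended for synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, SchemaError, UndefinedValueError

DEFAULT_FC_CUTOFF = 0.5


@dataclass
class OmicsMatrix:
    """Feature × sample log- or raw-intensity matrix with annotations.

    ``values``: DataFrame, features as index (unique ids), samples as columns.
    ``samples``: DataFrame indexed by sample with at least a ``treatment``
    column. ``flags``: optional boolean Series per feature (significance).
    ``log_scale`` records whether values are already log2 (so normalization
    never double-logs).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    flags: pd.Series | None = None
    log_scale: bool = False
    median_centered: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate feature ids: {dupes[:5]}")
        unannotated = [s for s in self.values.columns if s not in self.samples.index]
        if unannotated:
            raise SchemaError(f"samples without annotation: {unannotated}")
        if "treatment" not in self.samples.columns:
            raise SchemaError("sample annotations need a 'treatment' column")
        if self.flags is not None and self.flags.dtype != bool:
            raise SchemaError("significance flags must be boolean")

    def group_columns(self, treatment: str) -> list[str]:
        cols = [
            s for s in self.values.columns
            if self.samples.loc[s, "treatment"] == treatment
        ]
        if not cols:
            raise SchemaError(f"no samples with treatment {treatment!r}")
        return cols

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.samples["treatment"]))


@dataclass(frozen=True)
class AlteredSet:
    """Features significant AND with |log2FC| at or beyond the cutoff."""

    treatment: str
    features: frozenset[str]
    cutoff: float

    def __len__(self) -> int:
        return len(self.features)


def normalize_lfq(matrix: OmicsMatrix) -> OmicsMatrix:
    """Log2-transform and median-center each sample.

    Raw matrices are log2-transformed first; matrices already on the log
    scale are only median-centered, which makes the operation idempotent.
    Each sample's median (over observed values) is exactly 0 afterwards.
    """
    values = matrix.values
    if not matrix.log_scale:
        if (values <= 0).any(axis=None):
            raise UndefinedValueError(
                "raw intensities must be > 0 (or NaN) for the log2 transform"
            )
        values = np.log2(values)
    counts = values.notna().sum(axis=0)
    thin = counts[counts < 2]
    if len(thin):
        raise UndefinedValueError(
            f"samples with < 2 observed values: {thin.index.tolist()}"
        )
    centered = values - values.median(axis=0, skipna=True)
    return replace(matrix, values=centered, log_scale=True, median_centered=True)


def _ensure_normalized(matrix: OmicsMatrix) -> OmicsMatrix:
    return matrix if matrix.median_centered else normalize_lfq(matrix)


def log2fc(matrix: OmicsMatrix, treatment: str, control: str) -> pd.Series:
    """Per-feature log2 fold change: mean(treatment) − mean(control).

    Computed on normalized values (the matrix is normalized on the fly if
    needed). Features observed in fewer than 2 replicates of either group are
    NaN — flagged missing, excluded downstream.
    """
    matrix = _ensure_normalized(matrix)
    t_cols = matrix.group_columns(treatment)
    c_cols = matrix.group_columns(control)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ConfigurationError("both groups need >= 2 replicates")
    t = matrix.values[t_cols]
    c = matrix.values[c_cols]
    fc = t.mean(axis=1) - c.mean(axis=1)
    under = (t.notna().sum(axis=1) < 2) | (c.notna().sum(axis=1) < 2)
    fc[under] = np.nan
    fc.name = f"log2fc_{treatment}_vs_{control}"
    return fc


def welch_flags(
    matrix: OmicsMatrix, treatment: str, control: str, alpha: float = 0.05
) -> pd.Series:
    """Significance stand-in for synthetic data: per-feature Welch t-test
    (treatment vs control) with Benjamini–Hochberg adjustment at ``alpha``.

    Real analyses should supply flags from their own testing framework.
    """
    matrix = _ensure_normalized(matrix)
    t = matrix.values[matrix.group_columns(treatment)].to_numpy()
    c = matrix.values[matrix.group_columns(control)].to_numpy()
    _, p = sps.ttest_ind(t, c, axis=1, equal_var=False, nan_policy="omit")
    p = np.where(np.isnan(p), 1.0, p)
    rejected = sps.false_discovery_control(p, method="bh") <= alpha
    return pd.Series(rejected, index=matrix.values.index, name="significant")


def altered_set(
    matrix: OmicsMatrix,
    treatment: str,
    control: str,
    min_abs_log2fc: float = DEFAULT_FC_CUTOFF,
    flags: pd.Series | None = None,
) -> AlteredSet:
    """Features with significance flag AND |log2FC| ≥ cutoff (boundary in).

    ``flags`` defaults to the matrix's own flags; with neither supplied the
    call fails, pointing to :func:`welch_flags` as the synthetic-data
    stand-in.
    """
    if flags is None:
        flags = matrix.flags
    if flags is None:
        raise ConfigurationError(
            "no significance flags: supply per-feature flags (or use "
            "welch_flags() as a stand-in on synthetic data)"
        )
    fc = log2fc(matrix, treatment, control)
    flags = flags.reindex(fc.index).fillna(False).astype(bool)
    selected = fc.index[flags & (fc.abs() >= min_abs_log2fc)]
    return AlteredSet(
        treatment=treatment, features=frozenset(selected), cutoff=min_abs_log2fc
    )


def overlap_percent(a: AlteredSet | frozenset, b: AlteredSet | frozenset) -> float:
    """Venn-style shared percentage: 100·|A∩B| / |A∪B|."""
    sa = a.features if isinstance(a, AlteredSet) else frozenset(a)
    sb = b.features if isinstance(b, AlteredSet) else frozenset(b)
    union = sa | sb
    if not union:
        raise UndefinedValueError("overlap undefined for two empty sets")
    return 100.0 * len(sa & sb) / len(union)


def overlap_fractions(a: AlteredSet | frozenset, b: AlteredSet | frozenset) -> dict[str, float]:
    """Per-set shared percentages 100·|A∩B|/|A| and 100·|A∩B|/|B|."""
    sa = a.features if isinstance(a, AlteredSet) else frozenset(a)
    sb = b.features if isinstance(b, AlteredSet) else frozenset(b)
    if not sa or not sb:
        raise UndefinedValueError("per-set overlap undefined for an empty set")
    inter = len(sa & sb)
    return {"of_a": 100.0 * inter / len(sa), "of_b": 100.0 * inter / len(sb)}


def replicate_correlation(matrix: OmicsMatrix, min_shared: int = 3) -> pd.DataFrame:
    """Sample × sample Pearson correlation over pairwise-complete features.

    Pairs sharing fewer than ``min_shared`` observed features are NaN
    (flagged missing). Symmetric with unit diagonal.
    """
    if matrix.values.shape[1] < 2:
        raise UndefinedValueError("need >= 2 samples")
    corr = matrix.values.corr(method="pearson", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree over sample log2FC profiles."""

    linkage: np.ndarray
    labels: tuple[str, ...]

    def cut(self, k: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

        return walk(tree) + ";"


def cluster_samples(profiles: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering of log2FC profiles (columns = samples).

    Average linkage on correlation distance 1 − r, pairwise-complete. Label
    order does not affect the merge partitions.
    """
    if profiles.shape[1] < 3:
        raise UndefinedValueError("need >= 3 profiles to cluster")
    corr = profiles.corr(method="pearson", min_periods=3)
    if corr.isna().any(axis=None):
        raise UndefinedValueError("profile pairs with < 3 shared features")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(linkage=linkage, labels=tuple(profiles.columns))


def log2fc_profiles(
    matrix: OmicsMatrix, control: str, per_replicate: bool = True
) -> pd.DataFrame:
    """log2FC profile per sample (vs the control group mean) or per treatment.

    With ``per_replicate`` each non-control sample is its own profile
    (sample value − control mean); otherwise one group-mean profile per
    treatment.
    """
    matrix = _ensure_normalized(matrix)
    c_mean = matrix.values[matrix.group_columns(control)].mean(axis=1)
    if per_replicate:
        cols = [s for s in matrix.values.columns if matrix.samples.loc[s, "treatment"] != control]
        return matrix.values[cols].sub(c_mean, axis=0)
    out = {}
    for treatment in matrix.treatments:
        if treatment == control:
            continue
        out[treatment] = log2fc(matrix, treatment, control)
    return pd.DataFrame(out)
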