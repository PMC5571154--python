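"""Community-structure summaries: group means, top taxa, abundant core,
PCA ordination and alpha diversity.

The "abundant core" is the smallest set of top-ranked OTUs whose mean
relative abundances cumulatively cover a stated fraction (default 80%) of
reads — the headline metric uses all digester samples across plants.
Ordination defaults to Hellinger-transformed PCA with a deterministic sign
convention so that repeated runs and downstream comparisons agree exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, EmptyResultError, InvariantError
from .normalize import AbundanceTable
from .tables_io import CountTable

logger = logging.getLogger("immigratio")

PCA_TRANSFORMS = ("hellinger", "log1p_scaled", "none")
ALPHA_METRICS = ("observed", "shannon", "inv_simpson")


@dataclass
class GroupMeanTable:
    """Mean relative abundances per taxon per metadata group (heatmap content)."""

    means: pd.DataFrame = field(repr=False)  # taxon x group
    group_by: str = "plant"
    n_samples: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.means.copy()
        out.index.name = "taxon"
        return out


@dataclass
class CoreResult:
    """Cumulative-coverage ranking of OTUs by mean relative abundance."""

    ranked_otus: list
    mean_abund: np.ndarray
    cum_frac: np.ndarray
    core_size: int
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranked_otus) + 1),
                "otu_id": self.ranked_otus,
                "mean_abund": self.mean_abund,
                "cum_frac": self.cum_frac,
            }
        ).set_index("rank")


@dataclass
class OrdinationResult:
    """PCA scores/loadings with explained-variance fractions."""

    scores: pd.DataFrame = field(repr=False)     # sample x component
    loadings: pd.DataFrame = field(repr=False)   # taxon x component
    var_explained: np.ndarray = None
    transform: str = "hellinger"

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out.index.name = "sample_id"
        ve = pd.DataFrame(
            [self.var_explained], index=pd.Index(["var_explained"], name="sample_id"),
            columns=self.scores.columns,
        )
        return pd.concat([out, ve])


def group_means(abund: AbundanceTable, samples: pd.DataFrame, group_by) -> GroupMeanTable:
    """Arithmetic mean of relative abundances per metadata group.

    ``group_by`` is a metadata column name (or list of names, joined by "/").
    Every sample must belong to exactly one group; empty groups are absent.
    """
    keys = [group_by] if isinstance(group_by, str) else list(group_by)
    for k in keys:
        if k not in samples.columns:
            raise ArgumentError(f"unknown group_by key {k!r}; have {list(samples.columns)}")
    meta = samples.set_index("sample_id").loc[abund.sample_ids]
    labels = meta[keys[0]].astype(str) if len(keys) == 1 else meta[keys].astype(str).agg(
        "/".join, axis=1
    )
    means = abund.abund.T.groupby(labels.to_numpy()).mean().T
    n = labels.value_counts().to_dict()
    return GroupMeanTable(means=means, group_by="/".join(keys), n_samples=n)


def top_taxa(gm: GroupMeanTable, n: int) -> list:
    """Top ``n`` taxa ranked by the unweighted mean of group means.

    The ranking averages across groups (mean across plants, not across
    samples); ties break by taxon label ascending.
    """
    if n < 1:
        raise ArgumentError(f"n must be >= 1, got {n}")
    overall = gm.means.mean(axis=1)
    order = sorted(overall.index, key=lambda t: (-overall[t], str(t)))
    return order[:n]


def abundant_core(
    abund: AbundanceTable,
    samples: pd.DataFrame | None = None,
    scope=None,
    threshold: float = 0.8,
) -> CoreResult:
    """Rank OTUs by mean abundance over the scoped samples; find the core.

    ``scope`` selects samples: None (all), a list of sample ids, or a boolean
    mask/callable over the metadata frame.  ``core_size`` is the smallest k
    whose cumulative (normalized) mean-abundance fraction reaches
    ``threshold``.
    """
    if not 0 < threshold <= 1:
        raise ArgumentError(f"threshold must be in (0, 1], got {threshold}")
    a = abund.abund
    if scope is not None:
        if callable(scope):
            if samples is None:
                raise ArgumentError("callable scope requires the metadata frame")
            mask = samples.apply(scope, axis=1).to_numpy(dtype=bool)
            ids = samples.loc[mask, "sample_id"].tolist()
        else:
            ids = list(scope)
        ids = [s for s in ids if s in a.columns]
        if not ids:
            raise EmptyResultError("scope selects no samples")
        a = a[ids]
    means = a.mean(axis=1)
    total = float(means.sum())
    if total <= 0:
        raise EmptyResultError("scoped table has zero total abundance")
    order = sorted(means.index, key=lambda t: (-means[t], str(t)))
    ranked = means.loc[order]
    cum = np.cumsum(ranked.to_numpy()) / total
    cum[-1] = 1.0  # exact by construction; clamp fp error
    core_size = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    if threshold == 1.0:
        core_size = int((ranked.to_numpy() > 0).sum())
    return CoreResult(
        ranked_otus=list(ranked.index),
        mean_abund=ranked.to_numpy(),
        cum_frac=cum,
        core_size=core_size,
        threshold=threshold,
    )


def _transform_matrix(X: np.ndarray, transform: str, depth: int | None) -> np.ndarray:
    if transform == "hellinger":
        return np.sqrt(X)
    if transform == "log1p_scaled":
        scale = depth if depth else 10_000
        return np.log1p(X * scale)
    if transform == "none":
        return X
    raise ArgumentError(f"transform must be one of {PCA_TRANSFORMS}, got {transform!r}")


def pca(abund: AbundanceTable, transform: str = "hellinger", n_components: int = 2) -> OrdinationResult:
    """Principal component analysis of transformed community profiles.

    Samples are observations (rows), taxa variables (columns).  After the
    per-sample transform, taxa are mean-centered and an SVD taken.  Each
    component's sign is fixed so its largest-magnitude loading is positive,
    making the orientation deterministic.
    """
    a = abund.abund
    n_samples, n_taxa = a.shape[1], a.shape[0]
    if n_samples < 2:
        raise ArgumentError("PCA needs at least 2 samples")
    max_comp = min(n_samples, n_taxa)
    if n_components > max_comp:
        raise ArgumentError(
            f"n_components={n_components} exceeds min(n_samples, n_taxa)={max_comp}"
        )
    X = _transform_matrix(a.T.to_numpy(dtype=float), transform, abund.depth)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic orientation: largest |loading| positive per component
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U[:, :n_components] * S[:n_components]
    total_var = float((S**2).sum())
    var_explained = (S[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=a.columns, columns=comp_names),
        loadings=pd.DataFrame(Vt[:n_components].T, index=a.index, columns=comp_names),
        var_explained=var_explained,
        transform=transform,
    )


def alpha_diversity(counts: CountTable, metric: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity on (ideally even-depth) counts.

    observed = number of nonzero OTUs; shannon = -sum p ln p over nonzero p;
    inv_simpson = 1 / sum p^2.  Warns when column sums are unequal (diversity
    comparisons assume even depth).
    """
    if metric not in ALPHA_METRICS:
        raise ArgumentError(f"metric must be one of {ALPHA_METRICS}, got {metric!r}")
    c = counts.counts
    sums = c.sum(axis=0)
    if (sums == 0).any():
        raise InvariantError(f"all-zero samples: {list(sums.index[sums == 0])}")
    if sums.nunique() > 1:
        logger.warning("alpha_diversity: unequal column sums; rarefy first for comparability")
    values = {}
    for s in c.columns:
        p = c[s].to_numpy(dtype=float)
        p = p[p > 0] / p.sum()
        if metric == "observed":
            values[s] = float(len(p))
        elif metric == "shannon":
            values[s] = float(-(p * np.log(p)).sum())
        else:
            values[s] = float(1.0 / (p**2).sum())
    return pd.Series(values, name=metric)
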