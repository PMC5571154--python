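"""Digester-vs-influent abundance ratios and growth classification.

The central statistic: for each OTU, the ratio of its mean relative read
abundance across a digester process group (mesophilic, thermophilic, or
mesophilic with thermal hydrolysis pre-treatment) to its mean relative
abundance in the influent streams (primary and surplus sludge, combined
50:50 by default, mirroring the feed's organic mass ratio).  At steady
state, a non-growing population washed through a reactor can at best hold
its influent abundance, so ratios at or below 1 flag immigrating /
non-growing populations while ratios well above 1 flag in-situ growers.
The abundance-weighted distribution of log10 ratios is bimodal in ordinary
digesters; its split is located with a weighted two-component Gaussian
mixture.  THP digesters, whose feed biomass is lysed, lack the immigration
mode and serve as the no-immigration control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mixture import WeightedGMM2
from .exceptions import ArgumentError, EmptyResultError, InvariantError
from .normalize import AbundanceTable
from .structure import CoreResult
from .tables_io import INFLUENT_TYPES

logger = logging.getLogger("immigratio")

#: Half of one read at the default rarefaction depth of 10 000.
DEFAULT_PSEUDO = 5e-5
PROCESS_GROUPS = ("mesophilic", "thermophilic", "thp")
GROWTH_CLASSES = ("growing", "intermediate", "non_growing")


@dataclass
class RatioTable:
    """Per-OTU immigration statistics for one digester process group.

    ``frame`` columns: mean_primary, mean_surplus, mean_influent,
    mean_digester, ratio, weight, growth_class (empty until
    :func:`classify_growth`), optionally taxonomy.  ``weight`` equals
    ``mean_digester`` exactly; ``ratio = mean_digester /
    max(mean_influent, pseudo)``.
    """

    frame: pd.DataFrame = field(repr=False)
    group: str = ""
    pseudo: float = DEFAULT_PSEUDO
    influent_combine: str = "mean_of_streams"
    grow_threshold: float | None = None
    die_threshold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.sort_values(
            ["mean_digester", "ratio"], ascending=[False, False], kind="mergesort"
        ).copy()
        out.insert(0, "group", self.group)
        out.index.name = "otu_id"
        return out


@dataclass
class WeightedRatioHist:
    """Histogram of log10 ratios with abundance-weighted, unit-sum mass."""

    bin_edges: np.ndarray
    mass: np.ndarray
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "mass": self.mass,
            }
        )


@dataclass
class SplitResult:
    """Detected split of the weighted log-ratio distribution."""

    split: float
    method: str
    bimodal: bool
    component_means: np.ndarray | None = None
    component_sigmas: np.ndarray | None = None
    component_weights: np.ndarray | None = None
    fallback_used: bool = False
    #: ratio at the dominant component's mean (the single mode when unimodal)
    mode_ratio: float | None = None

    def to_frame(self) -> pd.DataFrame:
        row = {
            "split": self.split,
            "method": self.method,
            "bimodal": self.bimodal,
            "fallback_used": self.fallback_used,
        }
        if self.component_means is not None:
            for k in range(2):
                row[f"mean_log10_{k + 1}"] = self.component_means[k]
                row[f"sigma_log10_{k + 1}"] = self.component_sigmas[k]
                row[f"weight_{k + 1}"] = self.component_weights[k]
        return pd.DataFrame([row], index=pd.Index([0], name="row"))


def compute_ratios(
    abund: AbundanceTable,
    samples: pd.DataFrame,
    group: str,
    influent_combine: str = "mean_of_streams",
    pseudo: float = DEFAULT_PSEUDO,
    taxonomy: pd.Series | None = None,
    plant: str | None = None,
) -> RatioTable:
    """Per-OTU digester/influent mean-abundance ratios for one process group.

    mean_digester is the arithmetic mean over the group's digester samples;
    the influent mean is either the 50:50 mean of the primary- and
    surplus-stream means (``mean_of_streams``, default) or the mean over all
    influent samples pooled (``pooled``).  ``pseudo`` regularizes the
    denominator so digester-only OTUs get large finite ratios.  ``plant``
    optionally restricts digester samples to one plant (per-plant mode).
    """
    if group not in PROCESS_GROUPS:
        raise ArgumentError(f"group must be one of {PROCESS_GROUPS}, got {group!r}")
    if influent_combine not in ("mean_of_streams", "pooled"):
        raise ArgumentError(
            f"influent_combine must be 'mean_of_streams' or 'pooled', got {influent_combine!r}"
        )
    if pseudo <= 0:
        raise ArgumentError(f"pseudo must be > 0, got {pseudo}")
    meta = samples.set_index("sample_id").loc[abund.sample_ids]
    dig_mask = (meta.sample_type == "digester") & (meta.process_type == group)
    if plant is not None:
        dig_mask &= meta.plant == plant
    dig_ids = list(meta.index[dig_mask])
    if not dig_ids:
        raise EmptyResultError(f"no digester samples in group {group!r}"
                               + (f" at plant {plant!r}" if plant else ""))
    prim_ids = list(meta.index[meta.sample_type == "primary"])
    surp_ids = list(meta.index[meta.sample_type == "surplus"])
    if not prim_ids and not surp_ids:
        raise EmptyResultError("no influent (primary/surplus) samples present")
    a = abund.abund
    mean_dig = a[dig_ids].mean(axis=1)
    mean_prim = a[prim_ids].mean(axis=1) if prim_ids else pd.Series(0.0, index=a.index)
    mean_surp = a[surp_ids].mean(axis=1) if surp_ids else pd.Series(0.0, index=a.index)
    if influent_combine == "mean_of_streams":
        streams = [m for m, ids in ((mean_prim, prim_ids), (mean_surp, surp_ids)) if ids]
        mean_inf = sum(streams) / len(streams)
    else:
        mean_inf = a[prim_ids + surp_ids].mean(axis=1)
    ratio = mean_dig / np.maximum(mean_inf, pseudo)
    frame = pd.DataFrame(
        {
            "mean_primary": mean_prim,
            "mean_surplus": mean_surp,
            "mean_influent": mean_inf,
            "mean_digester": mean_dig,
            "ratio": ratio,
            "weight": mean_dig,
            "growth_class": pd.Series("", index=a.index, dtype=object),
        }
    )
    if taxonomy is not None:
        frame.insert(0, "taxonomy", taxonomy.reindex(a.index).fillna(""))
    logger.info(
        "compute_ratios[%s%s]: %d digester, %d primary, %d surplus samples, %d OTUs",
        group, f"/{plant}" if plant else "", len(dig_ids), len(prim_ids),
        len(surp_ids), len(a.index),
    )
    return RatioTable(frame=frame, group=group, pseudo=pseudo,
                      influent_combine=influent_combine)


def weighted_ratio_distribution(
    rt: RatioTable, n_bins: int = 50, log10_range: tuple | None = None
) -> WeightedRatioHist:
    """Abundance-weighted histogram of log10 ratios, mass normalized to 1.

    OTUs with zero weight (absent from the digesters) carry no mass and are
    excluded.  The bin grid is widened if needed so every finite ratio is
    covered.
    """
    f = rt.frame
    keep = f.weight > 0
    if not keep.any():
        raise EmptyResultError("all OTU weights are zero")
    logr = np.log10(f.loc[keep.to_numpy(), "ratio"].to_numpy())
    w = f.loc[keep.to_numpy(), "weight"].to_numpy(dtype=float)
    lo, hi = log10_range if log10_range is not None else (-3.0, 4.0)
    lo = min(lo, float(np.floor(logr.min() * 10) / 10))
    hi = max(hi, float(np.ceil(logr.max() * 10) / 10) + 1e-9)
    edges = np.linspace(lo, hi, n_bins + 1)
    mass, edges = np.histogram(logr, bins=edges, weights=w)
    mass = mass / mass.sum()
    return WeightedRatioHist(bin_edges=edges, mass=mass, group=rt.group)


def detect_split(
    rt: RatioTable,
    method: str = "gmm2",
    fixed_value: float = 10.0,
    seed: int = 0,
    n_restarts: int = 50,
    tol: float = 1e-8,
    min_component_weight: float = 0.02,
) -> SplitResult:
    """Locate the split of the weighted log-ratio distribution.

    ``gmm2`` fits a two-component Gaussian mixture to log10(ratio) with
    observation weights equal to the OTU digester abundances and returns the
    ratio at which the weighted posteriors cross.  The distribution is
    flagged bimodal when (a) the component means are separated by more than
    2 pooled standard deviations, (b) each component carries at least
    ``min_component_weight`` of the read mass (a component holding a
    fraction of a percent of the reads is not a mode of the distribution),
    and (c) the fitted mixture density has two local maxima separated by a
    valley dropping below half the minor peak (a "shoulder" fit of a
    unimodal distribution fails this); otherwise (or when
    the posteriors never cross) the fixed value is returned as a fallback
    with a warning.  ``fixed`` returns ``fixed_value`` unconditionally.
    """
    if method == "fixed":
        return SplitResult(split=float(fixed_value), method="fixed", bimodal=False)
    if method != "gmm2":
        raise ArgumentError(f"method must be 'gmm2' or 'fixed', got {method!r}")
    f = rt.frame
    keep = (f.weight > 0).to_numpy()
    if keep.sum() < 10:
        raise ArgumentError("gmm2 needs >= 10 OTUs with positive weight")
    logr = np.log10(f.loc[keep, "ratio"].to_numpy())
    w = f.loc[keep, "weight"].to_numpy(dtype=float)
    if np.unique(logr).size < 2:
        raise ArgumentError("fewer than 2 distinct ratios; no split to detect")
    gmm = WeightedGMM2(n_restarts=n_restarts, tol=tol, random_state=seed).fit(
        logr, sample_weight=w
    )
    pooled_sd = float(np.sqrt(np.sum(gmm.weights_ * gmm.sigmas_**2)))
    separation = float(abs(gmm.means_[1] - gmm.means_[0]))
    bimodal = (separation > 2.0 * pooled_sd
               and float(gmm.weights_.min()) >= min_component_weight
               and gmm.density_dip() <= 0.5)
    mode_ratio = float(10.0 ** gmm.means_[int(np.argmax(gmm.weights_))])
    crossing = gmm.equal_posterior_point() if bimodal else None
    if crossing is None:
        logger.warning(
            "detect_split[%s]: distribution not bimodal (separation %.3f, pooled sd "
            "%.3f, min component weight %.4f) or no posterior crossing; "
            "falling back to fixed split %g",
            rt.group, separation, pooled_sd, float(gmm.weights_.min()), fixed_value,
        )
        return SplitResult(
            split=float(fixed_value), method="gmm2", bimodal=False,
            component_means=gmm.means_, component_sigmas=gmm.sigmas_,
            component_weights=gmm.weights_, fallback_used=True,
            mode_ratio=mode_ratio,
        )
    return SplitResult(
        split=float(10.0**crossing), method="gmm2", bimodal=True,
        component_means=gmm.means_, component_sigmas=gmm.sigmas_,
        component_weights=gmm.weights_, mode_ratio=mode_ratio,
    )


def classify_growth(
    rt: RatioTable, grow_threshold: float = 10.0, die_threshold: float = 1.0
) -> RatioTable:
    """Label each OTU growing / intermediate / non_growing by its ratio.

    ratio > grow_threshold -> growing; ratio <= die_threshold -> non_growing
    (inclusive, so a ratio of exactly 1 counts as non-growing); in between ->
    intermediate.  Returns a new RatioTable with thresholds recorded.
    """
    if not die_threshold < grow_threshold:
        raise ArgumentError(
            f"die_threshold ({die_threshold}) must be < grow_threshold ({grow_threshold})"
        )
    frame = rt.frame.copy()
    r = frame.ratio.to_numpy()
    cls = np.where(r > grow_threshold, "growing",
                   np.where(r <= die_threshold, "non_growing", "intermediate"))
    frame["growth_class"] = cls
    return RatioTable(
        frame=frame, group=rt.group, pseudo=rt.pseudo,
        influent_combine=rt.influent_combine,
        grow_threshold=grow_threshold, die_threshold=die_threshold,
    )


def core_growth_summary(core: CoreResult, rt: RatioTable) -> pd.DataFrame:
    """Growth-class tally of the abundant-core OTUs.

    For the ``core.core_size`` top-ranked OTUs: counts, percentage of the
    core, and each class's share of the core's read mass.  Errors if a core
    OTU is missing from the ratio table (different scopes).
    """
    core_otus = core.ranked_otus[: core.core_size]
    missing = [o for o in core_otus if o not in rt.frame.index]
    if missing:
        raise InvariantError(f"core OTUs missing from the ratio table: {missing[:10]}")
    sub = rt.frame.loc[core_otus]
    if (sub.growth_class == "").any():
        raise InvariantError("run classify_growth before core_growth_summary")
    mass = dict(zip(core_otus, core.mean_abund[: core.core_size]))
    rows = []
    total_mass = float(sum(mass.values()))
    for cls in GROWTH_CLASSES:
        otus = sub.index[sub.growth_class == cls]
        cls_mass = float(sum(mass[o] for o in otus))
        rows.append(
            {
                "growth_class": cls,
                "n_otus": int(len(otus)),
                "pct_of_core": 100.0 * len(otus) / len(core_otus),
                "core_read_mass_frac": cls_mass / total_mass if total_mass else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("growth_class")
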