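"""Synthetic source-sink community generator with ground truth.

Emulates the statistical structure the immigration analysis assumes: two
influent streams (primary and surplus sludge) with log-normal rank-abundance
profiles and partial OTU overlap, feeding digester communities that mix

* immigrating populations — stream OTUs whose steady-state digester mass is
  their 50:50 feed fraction times a survival factor s = 1/(1 + b*theta)
  (decay rate b, sludge retention time theta), drawn from ``survival_range``;
* in-situ growers — a fraction of OTUs, preferentially absent or rare in the
  streams, injected as feed-independent mass.

The grower mass block is scaled so the total unnormalized digester mass is
exactly 1; a pure immigrant's analytic expected ratio then equals its
survival s exactly, and is <= 1 whenever s <= 1 — the generator reproduces
the "ratios close to 1 or below" regime for non-growing populations by
construction.  THP mode sets survival to ~0 (lysed feed biomass), removing
the immigration mode.  Per-sample noise is Dirichlet-multinomial; all
randomness flows from ``SimConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._mixture import WeightedGMM2
from .exceptions import ArgumentError, InvariantError
from .immigration import SplitResult, detect_split
from .tables_io import CountTable, ValidatedDataset, validate_dataset
from .taxonomy import join_lineage

logger = logging.getLogger("immigratio")

GROUP_MODES = {"mesophilic": "standard", "thermophilic": "standard", "thp": "thp"}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults emulate the surveyed full-scale systems: read depth 10 000;
    ~1/2-scale sample counts (the survey had up to ~280 digester samples per
    process group and 121/137 primary/surplus samples); survival factors
    from s = 1/(1 + b*theta) with decay b in [0.05, 2] per day and sludge
    retention times of 10-55 days; growers sized so ~300 of them carry most
    of the digester read mass (the abundant core).
    """

    n_otus: int = 2000
    n_plants: int = 3                      # plants per process group
    digester_samples_per_group: int = 80
    primary_samples: int = 60
    surplus_samples: int = 60
    depth: int = 10_000
    lognormal_sigma: float = 2.0           # rank-abundance spread of the streams
    stream_membership: float = 0.65        # P(an OTU occurs in a given stream)
    grower_fraction: float = 0.15
    grower_sigma: float = 0.5              # log-normal spread of grower masses
    enrichment_range: tuple = (50.0, 200.0)
    survival_range: tuple = (0.01, 0.67)
    thp_survival: float = 1e-3
    dirichlet_concentration: float = 500.0
    srt_days: tuple = (10.0, 55.0)         # provenance of survival_range
    unclassified_genus_frac: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 10:
            raise ArgumentError("n_otus must be >= 10")
        if self.depth < 1:
            raise ArgumentError("depth must be >= 1")
        for name in ("enrichment_range", "survival_range", "srt_days"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ArgumentError(f"{name} must be ordered, got {(lo, hi)}")
        for name in ("grower_fraction", "stream_membership", "thp_survival",
                     "unclassified_genus_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ArgumentError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.survival_range
        if not (0 <= lo and hi <= 1):
            raise ArgumentError(f"survival_range must be within [0, 1], got {(lo, hi)}")


@dataclass
class SimTruth:
    """Ground truth: stream compositions and per-group per-OTU labels.

    Each group frame has columns: is_grower, survival, grower_mass,
    digester_fraction, expected_ratio (analytic, pseudo-free, +inf for
    growers absent from both streams) and expected_ratio_reg (regularized
    with ``pseudo`` so it is finite, comparable to the measured ratio).
    """

    stream_primary: pd.Series = field(repr=False)
    stream_surplus: pd.Series = field(repr=False)
    groups: dict = field(default_factory=dict, repr=False)
    pseudo: float = 5e-5

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for g, df in self.groups.items():
            f = df.copy()
            f.insert(0, "group", g)
            frames.append(f)
        out = pd.concat(frames)
        out.index.name = "otu_id"
        return out


def _otu_ids(n: int) -> pd.Index:
    return pd.Index([f"OTU_{i + 1}" for i in range(n)], name="otu_id")


def simulate_stream_profiles(cfg: SimConfig, rng: np.random.Generator | None = None):
    """True compositions of the two influent streams.

    Each stream occupies a random OTU subset (partial overlap between
    streams); member abundances are log-normal(0, lognormal_sigma),
    normalized to 1.  Deterministic under the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ids = _otu_ids(cfg.n_otus)
    profiles = []
    for _stream in ("primary", "surplus"):
        member = rng.random(cfg.n_otus) < cfg.stream_membership
        if member.sum() < 10:  # degenerate membership draw; force a floor
            member[rng.choice(cfg.n_otus, size=10, replace=False)] = True
        vals = np.zeros(cfg.n_otus)
        vals[member] = rng.lognormal(mean=0.0, sigma=max(cfg.lognormal_sigma, 1e-12),
                                     size=int(member.sum()))
        profiles.append(pd.Series(vals / vals.sum(), index=ids))
    return tuple(profiles)


def simulate_digester_profile(
    streams, cfg: SimConfig, mode: str = "standard",
    rng: np.random.Generator | None = None, pseudo: float = 5e-5,
):
    """True digester composition plus per-OTU ground truth for one group.

    Unnormalized mass = feed fraction (50:50 stream mean) x survival for
    stream members, plus feed-independent grower mass for the grower subset;
    the grower block is scaled so total mass is exactly 1, keeping immigrant
    expected ratios equal to their survivals.
    """
    if mode not in ("standard", "thp"):
        raise ArgumentError(f"mode must be 'standard' or 'thp', got {mode!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    primary, surplus = streams
    ids = primary.index
    n = len(ids)
    feed = ((primary + surplus) / 2.0).to_numpy()
    member = feed > 0

    n_growers = int(round(cfg.grower_fraction * n))
    if mode == "thp" and n_growers == 0:
        raise InvariantError(
            "thp mode with grower_fraction=0 leaves a reactor with ~no biomass"
        )
    # growers preferentially from OTUs absent from the streams, then rarest
    absent = np.flatnonzero(~member)
    present_by_rarity = np.flatnonzero(member)[np.argsort(feed[member], kind="stable")]
    pool = np.concatenate([rng.permutation(absent), present_by_rarity])
    grower_idx = np.sort(pool[:n_growers])
    is_grower = np.zeros(n, dtype=bool)
    is_grower[grower_idx] = True

    survival = np.zeros(n)
    if mode == "thp":
        survival[member] = cfg.thp_survival
    else:
        lo, hi = cfg.survival_range
        survival[member] = rng.uniform(lo, hi, size=int(member.sum()))
    immigrant_mass = feed * survival
    total_immigrant = float(immigrant_mass.sum())

    grower_mass = np.zeros(n)
    if n_growers:
        budget = 1.0 - total_immigrant
        if budget <= 0:
            logger.warning("simulate_digester_profile: no mass budget for growers "
                           "(total surviving immigrant mass %.3f)", total_immigrant)
        else:
            lo, hi = cfg.enrichment_range
            enrich = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_growers))
            raw = enrich * rng.lognormal(0.0, cfg.grower_sigma, size=n_growers)
            grower_mass[grower_idx] = budget * raw / raw.sum()

    mass = immigrant_mass + grower_mass
    total = float(mass.sum())
    if total <= 0:
        raise InvariantError("degenerate digester composition: zero total mass")
    comp = pd.Series(mass / total, index=ids)

    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.where(feed > 0, comp.to_numpy() / feed,
                            np.where(comp.to_numpy() > 0, np.inf, 0.0))
    expected_reg = comp.to_numpy() / np.maximum(feed, pseudo)
    truth = pd.DataFrame(
        {
            "is_grower": is_grower,
            "survival": survival,
            "grower_mass": grower_mass,
            "digester_fraction": comp.to_numpy(),
            "expected_ratio": expected,
            "expected_ratio_reg": expected_reg,
        },
        index=ids,
    )
    return comp, truth


def sample_reads(
    composition: pd.Series, cfg: SimConfig, n_samples: int,
    rng: np.random.Generator | None = None, prefix: str = "S",
) -> pd.DataFrame:
    """Dirichlet-multinomial read counts: ``n_samples`` columns at ``depth``.

    Per sample a Dirichlet perturbation with concentration
    ``dirichlet_concentration * composition`` (restricted to the positive
    support) is drawn, then a multinomial of ``depth`` reads.
    """
    if cfg.depth < 1:
        raise ArgumentError("depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = composition.to_numpy(dtype=float)
    support = p > 0
    alpha = cfg.dirichlet_concentration * p[support]
    cols = {}
    for i in range(n_samples):
        q = rng.dirichlet(alpha)
        counts = np.zeros(len(p), dtype=np.int64)
        counts[support] = rng.multinomial(cfg.depth, q / q.sum())
        cols[f"{prefix}{i + 1:03d}"] = counts
    return pd.DataFrame(cols, index=composition.index)


def _synthesize_taxonomy(ids: pd.Index, cfg: SimConfig, rng: np.random.Generator) -> pd.Series:
    phyla = ["Firmicutes", "Proteobacteria", "Chloroflexi", "Actinobacteria",
             "Bacteroidetes", "Spirochaetes", "Synergistetes", "Thermotogae",
             "Cloacimonetes", "Fermentibacteria"]
    n = len(ids)
    n_genera = max(n // 5, 1)
    phylum = rng.integers(0, len(phyla), size=n)
    genus = rng.integers(0, n_genera, size=n)
    unclassified = rng.random(n) < cfg.unclassified_genus_frac
    rows = []
    for i in range(n):
        p = phyla[phylum[i]]
        lineage = [
            "Bacteria", p, f"{p}_c{genus[i] % 4 + 1}", f"{p}_o{genus[i] % 7 + 1}",
            f"{p}_f{genus[i] % 11 + 1}",
            None if unclassified[i] else f"Genus_{genus[i] + 1:04d}",
            None,
        ]
        rows.append(join_lineage(lineage))
    return pd.Series(rows, index=ids, name="Taxonomy")


def make_dataset(cfg: SimConfig, pseudo: float = 5e-5):
    """End-to-end synthetic dataset: counts + metadata + ground truth.

    Emits primary and surplus samples (process_type na) and, for each of the
    three process groups, ``n_plants`` plants with
    ``digester_samples_per_group`` digester samples.  THP digesters use thp
    mode (no live immigration).  Returns ``(ValidatedDataset, SimTruth)``;
    regeneration with the same seed is bit-identical.
    """
    rng = np.random.default_rng(cfg.seed)
    primary, surplus = simulate_stream_profiles(cfg, rng)
    group_comps, truths = {}, {}
    for group, mode in GROUP_MODES.items():
        comp, truth = simulate_digester_profile((primary, surplus), cfg, mode=mode,
                                                rng=rng, pseudo=pseudo)
        group_comps[group] = comp
        truths[group] = truth

    count_blocks, meta_rows = [], []
    plant_names = {
        "mesophilic": [f"Meso{i + 1}" for i in range(cfg.n_plants)],
        "thermophilic": [f"Thermo{i + 1}" for i in range(cfg.n_plants)],
        "thp": [f"THP{i + 1}" for i in range(cfg.n_plants)],
    }
    all_plants = [p for names in plant_names.values() for p in names]

    for stype, comp, n_samp, prefix in (
        ("primary", primary, cfg.primary_samples, "PRI"),
        ("surplus", surplus, cfg.surplus_samples, "SUR"),
    ):
        block = sample_reads(comp, cfg, n_samp, rng=rng, prefix=prefix)
        count_blocks.append(block)
        for i, sid in enumerate(block.columns):
            meta_rows.append(
                {"sample_id": sid, "plant": all_plants[i % len(all_plants)],
                 "reactor": "", "sample_type": stype, "process_type": "na",
                 "date": f"2014-{i % 12 + 1:02d}-01"}
            )

    for group, comp in group_comps.items():
        prefix = {"mesophilic": "MES", "thermophilic": "THE", "thp": "THP"}[group]
        block = sample_reads(comp, cfg, cfg.digester_samples_per_group, rng=rng,
                             prefix=prefix)
        count_blocks.append(block)
        plants = plant_names[group]
        for i, sid in enumerate(block.columns):
            meta_rows.append(
                {"sample_id": sid, "plant": plants[i % len(plants)],
                 "reactor": f"R{i % 2 + 1}", "sample_type": "digester",
                 "process_type": group, "date": f"201{4 + i % 3}-{i % 12 + 1:02d}-15"}
            )

    counts = pd.concat(count_blocks, axis=1)
    taxonomy = _synthesize_taxonomy(counts.index, cfg, rng)
    ct = CountTable(counts, taxonomy)
    samples = pd.DataFrame(meta_rows)
    dataset = validate_dataset(ct, samples)
    truth = SimTruth(stream_primary=primary, stream_surplus=surplus,
                     groups=truths, pseudo=pseudo)
    return dataset, truth


def oracle_split(truth: SimTruth, group: str, seed: int = 12345) -> float:
    """Grid-search split of the analytic weighted log-ratio distribution.

    Fits the weighted two-component mixture to log10 of the regularized
    analytic ratios (weights = true digester fractions) and locates the
    posterior crossing by dense grid search — independent of the analytic
    crossing solver used by ``detect_split``.  Returns 10 when the analytic
    distribution itself is unimodal.
    """
    df = truth.groups[group]
    keep = df.digester_fraction > 0
    logr = np.log10(df.loc[keep, "expected_ratio_reg"].to_numpy())
    w = df.loc[keep, "digester_fraction"].to_numpy()
    gmm = WeightedGMM2(n_restarts=20, random_state=seed).fit(logr, sample_weight=w)
    pooled_sd = float(np.sqrt(np.sum(gmm.weights_ * gmm.sigmas_**2)))
    if (abs(gmm.means_[1] - gmm.means_[0]) <= 2.0 * pooled_sd
            or float(gmm.weights_.min()) < 0.02 or gmm.density_dip() > 0.5):
        return 10.0
    x = gmm.grid_split()
    return 10.0 if x is None else float(10.0**x)


def evaluate_recovery(
    rt, truth: SimTruth, split: SplitResult | None = None, seed: int = 0
) -> dict:
    """Score classified ratio tables against the ground truth.

    ``rt`` is a classified :class:`RatioTable` or a dict group -> RatioTable.
    Growing predictions are correct for true growers, non_growing for true
    immigrants; intermediate predictions count against the true class.
    Reports the 2x3 confusion matrix, per-class recalls, pooled balanced
    accuracy and, per group, |log10(detected split / grid-search oracle)|.
    """
    tables = rt if isinstance(rt, dict) else {rt.group: rt}
    confusion = pd.DataFrame(
        0, index=pd.Index(["grower", "immigrant"], name="truth"),
        columns=["growing", "intermediate", "non_growing"],
    )
    split_errors = {}
    for group, table in tables.items():
        if group not in truth.groups:
            raise InvariantError(f"no ground truth for group {group!r}")
        tdf = truth.groups[group]
        missing = table.frame.index.difference(tdf.index)
        if len(missing):
            raise InvariantError(
                f"ratio table OTUs absent from the truth: {list(missing[:5])}"
            )
        cls = table.frame.growth_class
        if (cls == "").any():
            raise InvariantError("run classify_growth before evaluate_recovery")
        is_grower = tdf.loc[table.frame.index, "is_grower"].to_numpy()
        for truth_label, mask in (("grower", is_grower), ("immigrant", ~is_grower)):
            for pred in confusion.columns:
                confusion.loc[truth_label, pred] += int(
                    ((cls == pred).to_numpy() & mask).sum()
                )
        det = split if split is not None else detect_split(table, seed=seed)
        if det.bimodal:
            split_errors[group] = abs(np.log10(det.split / oracle_split(truth, group)))
    recalls = {
        "grower": confusion.loc["grower", "growing"] / max(confusion.loc["grower"].sum(), 1),
        "immigrant": confusion.loc["immigrant", "non_growing"]
        / max(confusion.loc["immigrant"].sum(), 1),
    }
    return {
        "confusion": confusion,
        "recall_growers": float(recalls["grower"]),
        "recall_immigrants": float(recalls["immigrant"]),
        "balanced_accuracy": float((recalls["grower"] + recalls["immigrant"]) / 2.0),
        "split_log10_error": split_errors,
        "n_otus_scored": int(confusion.to_numpy().sum()),
    }


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
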