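"""Domain restriction, even-depth rarefaction, relative abundances, filtering.

Rarefaction is a draw *without replacement* (multivariate hypergeometric)
from each sample's reads, matching the semantics of subsampling to an even
depth: no OTU can exceed its observed count and column sums hit the target
depth exactly.  The abundance filter ("at least 0.1% in a single sample")
defines the reporting universe only — columns are deliberately not
renormalized afterwards, so reported fractions stay fractions of total
(domain) reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, EmptyResultError, InvariantError
from .tables_io import CountTable

logger = logging.getLogger("immigratio")

DOMAINS = ("all", "bacteria", "archaea")


@dataclass
class AbundanceTable:
    """Per-sample relative read abundances (fractions of reads).

    Attributes
    ----------
    abund : pandas.DataFrame
        Fractions, index = OTU (or taxon label) ids, columns = sample ids.
        Each column sums to 1 when ``normalized`` is True; after the
        abundance filter columns may sum to less than 1.
    depth : int or None
        Even read depth the counts were rarefied to upstream, if any.
    domain : {"all", "bacteria", "archaea"}
        Domain restriction applied upstream.
    normalized : bool
        Whether columns still sum to 1 (False after filtering).
    """

    abund: pd.DataFrame = field(repr=False)
    depth: int | None = None
    domain: str = "all"
    normalized: bool = True

    def __post_init__(self) -> None:
        arr = self.abund.to_numpy()
        if arr.size and ((arr < -1e-12).any() or (arr > 1 + 1e-9).any()):
            raise InvariantError("abundances must lie in [0, 1]")
        if self.normalized and arr.size:
            sums = arr.sum(axis=0)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                raise InvariantError(
                    f"columns must sum to 1: {list(self.abund.columns[bad][:5])}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abund.columns)

    def select_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.abund.loc[:, list(sample_ids)], self.depth,
                              self.domain, self.normalized)


def domain_filter(counts: CountTable, domain: str, tax: pd.DataFrame) -> CountTable:
    """Restrict a count table to OTUs of one domain (kingdom rank).

    ``domain="all"`` is the identity.  Errors if the restriction leaves any
    sample with zero reads (that sample has no information in the domain).
    """
    if domain not in DOMAINS:
        raise ArgumentError(f"domain must be one of {DOMAINS}, got {domain!r}")
    if domain == "all":
        return counts
    kingdom = tax.loc[counts.counts.index, "kingdom"]
    keep = kingdom.fillna("").str.lower() == domain
    out = counts.counts.loc[keep.to_numpy()]
    sums = out.sum(axis=0)
    empty = sums[sums == 0]
    if len(empty):
        raise InvariantError(
            f"samples with no {domain} reads after domain filter: {list(empty.index)}"
        )
    return CountTable(out, counts.taxonomy.loc[out.index])


def rarefy(counts: CountTable, depth: int, seed: int, on_shortfall: str = "drop") -> CountTable:
    """Subsample every sample to an even depth without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning (``on_shortfall="drop"``, default) or raise
    (``on_shortfall="error"``).  Fixed seed gives bit-identical output;
    samples are drawn in column order from a single
    ``numpy.random.default_rng(seed)`` stream.
    """
    if depth < 1:
        raise ArgumentError(f"depth must be >= 1, got {depth}")
    if on_shortfall not in ("drop", "error"):
        raise ArgumentError(f"on_shortfall must be 'drop' or 'error', got {on_shortfall!r}")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for sample in counts.counts.columns:
        col = counts.counts[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            if on_shortfall == "error":
                raise InvariantError(
                    f"sample {sample!r} has {total} reads, below depth {depth}"
                )
            dropped.append(sample)
            continue
        if total == depth:
            cols[sample] = col
        else:
            cols[sample] = rng.multivariate_hypergeometric(col, depth)
    if dropped:
        logger.warning("rarefy: dropped %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    if not cols:
        raise EmptyResultError(f"all samples fall below depth {depth}")
    out = pd.DataFrame(cols, index=counts.counts.index).astype(np.int64)
    return CountTable(out, counts.taxonomy)


def to_relative(counts: CountTable, domain: str = "all") -> AbundanceTable:
    """Divide each sample column by its read total.

    The result is invariant under uniform count scaling.  ``domain`` is
    recorded as metadata (use :func:`domain_filter` first to restrict).
    """
    sums = counts.counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise InvariantError(f"all-zero samples cannot be normalized: {list(zero.index)}")
    depths = sums.unique()
    depth = int(depths[0]) if len(depths) == 1 else None
    abund = counts.counts.div(sums, axis=1)
    return AbundanceTable(abund=abund, depth=depth, domain=domain)


def abundance_filter(abund: AbundanceTable, min_frac: float = 0.001):
    """Keep OTUs reaching ``min_frac`` relative abundance in >= 1 sample.

    The threshold is inclusive.  Columns are NOT renormalized: the filter
    defines which OTUs are reported, not the denominator.  Returns the
    filtered table and the list of kept OTU ids.
    """
    if not 0 <= min_frac <= 1:
        raise ArgumentError(f"min_frac must be in [0, 1], got {min_frac}")
    keep = (abund.abund >= min_frac).any(axis=1) if min_frac > 0 else pd.Series(
        True, index=abund.abund.index
    )
    kept = list(abund.abund.index[keep])
    if not kept:
        logger.warning("abundance_filter: no OTU reaches %g in any sample", min_frac)
    out = AbundanceTable(
        abund=abund.abund.loc[keep.to_numpy()],
        depth=abund.depth,
        domain=abund.domain,
        normalized=bool(min_frac == 0 and abund.normalized),
    )
    return out, kept
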