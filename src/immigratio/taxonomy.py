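"""Lineage parsing, curated-taxonomy overlay, and rank aggregation.

Lineage strings are 7-rank, semicolon-separated, optionally with
Greengenes/SILVA-style ``k__``/``p__``... prefixes.  Placeholder tokens
(blank, ``uncultured``, ``unclassified`` and friends) map to the UNCLASSIFIED
sentinel, and lineages are prefix-closed: once a rank is unclassified every
lower rank is too.  A curation overlay in the MiDAS spirit (a table assigning
provisional names such as "T78" to abundant unclassified lineages) can be
applied on top of the parsed taxonomy.

The UNCLASSIFIED sentinel is ``None`` (NaN in DataFrames).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, InvariantError, ParseError
from .normalize import AbundanceTable

logger = logging.getLogger("immigratio")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Tokens treated as "no classification at this rank".  Matching is
#: case-insensitive and prefix-stripped; the list is explicit and
#: configurable because classified-read fractions depend on it.
DEFAULT_PLACEHOLDERS = frozenset(
    {
        "",
        "uncultured",
        "unclassified",
        "unknown",
        "uncultured bacterium",
        "uncultured organism",
        "incertae sedis",
        "incertae_sedis",
        "ambiguous_taxa",
    }
)

_PREFIX_RE = re.compile(r"^[a-zA-Z]__")


def parse_lineage(s: str, placeholders=DEFAULT_PLACEHOLDERS) -> tuple:
    """Parse one lineage string into a 7-tuple of labels (None = unclassified).

    Prefixes like ``g__`` are stripped; placeholder tokens become None; the
    prefix-closure invariant is enforced by truncating everything below the
    first unclassified rank.

    >>> parse_lineage("k__Bacteria;p__Chloroflexi;;;;;")[:2]
    ('Bacteria', 'Chloroflexi')
    """
    if s is None or (isinstance(s, float) and np.isnan(s)):
        s = ""
    parts = [p.strip() for p in str(s).split(";")]
    if len(parts) > len(RANKS):
        raise ParseError(f"lineage has {len(parts)} fields (max {len(RANKS)}): {s!r}")
    parts += [""] * (len(RANKS) - len(parts))
    labels: list = []
    for raw in parts:
        label = _PREFIX_RE.sub("", raw).strip()
        norm = label.lower().replace("-", " ")
        if norm in placeholders or norm.startswith("incertae"):
            labels.append(None)
        else:
            labels.append(label)
    # prefix closure: truncate below the first unclassified rank
    for i, lab in enumerate(labels):
        if lab is None:
            for j in range(i, len(labels)):
                labels[j] = None
            break
    return tuple(labels)


def parse_taxonomy(taxonomy: pd.Series, placeholders=DEFAULT_PLACEHOLDERS) -> pd.DataFrame:
    """Parse all lineage strings into an OTU x rank DataFrame."""
    rows = [parse_lineage(s, placeholders) for s in taxonomy]
    return pd.DataFrame(rows, index=taxonomy.index, columns=list(RANKS), dtype=object)


def join_lineage(row) -> str:
    """Reassemble a ranks row into a prefixed lineage string."""
    prefixes = "kpcofgs"
    return ";".join(
        f"{p}__{lab}" if lab is not None and not pd.isna(lab) else f"{p}__"
        for p, lab in zip(prefixes, row)
    )


@dataclass
class OverrideTable:
    """Curation rows: (otu_id or lineage-prefix pattern, rank, new label, note).

    Exact ``otu_id`` rows take precedence over pattern rows.  A pattern row
    matches an OTU when its semicolon-separated labels equal the OTU's
    leading ranks.
    """

    rows: pd.DataFrame = field(repr=False)

    COLUMNS = ("otu_or_pattern", "rank", "label", "note")

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in ("otu_or_pattern", "rank", "label") if c not in df.columns]
        if missing:
            raise InvariantError(f"override table missing columns {missing}")
        if "note" not in df.columns:
            df = df.assign(note="")
        bad = df[~df["rank"].isin(RANKS)]
        if len(bad):
            raise InvariantError(f"override rows with unknown rank: {bad['rank'].tolist()}")
        conflicts = df.groupby(["otu_or_pattern", "rank"])["label"].nunique()
        conflicts = conflicts[conflicts > 1]
        if len(conflicts):
            key = conflicts.index[0]
            rows = df[(df.otu_or_pattern == key[0]) & (df["rank"] == key[1])]
            raise InvariantError(
                f"conflicting override rows for {key}: {rows.label.tolist()}"
            )
        self.rows = df.drop_duplicates(subset=["otu_or_pattern", "rank"]).reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        return self.rows.set_index("otu_or_pattern")


def read_overrides(path) -> OverrideTable:
    """Read a curation sheet (TSV with otu_or_pattern, rank, label, note)."""
    return OverrideTable(pd.read_csv(path, sep="\t", dtype=str).fillna(""))


def apply_overrides(tax: pd.DataFrame, ov: OverrideTable) -> pd.DataFrame:
    """Apply a curation overlay to a parsed taxonomy frame.

    Overriding a rank resets all lower ranks to unclassified unless they are
    also overridden for the same OTU (a genus override must not leave a stale
    species label).  Returns a new frame; an audit line is logged per applied
    row.  Idempotent.
    """
    out = tax.copy()
    otu_lineages = {otu: tuple(out.loc[otu]) for otu in out.index}
    # collect (otu, rank) -> label, exact rows winning over patterns
    assignments: dict[tuple[str, str], tuple[str, bool]] = {}
    for _, row in ov.rows.iterrows():
        target, rank, label = row["otu_or_pattern"], row["rank"], row["label"]
        if target in out.index:
            assignments[(target, rank)] = (label, True)
        else:
            pattern = tuple(x if x else None for x in (p.strip() for p in target.split(";")))
            pattern = tuple(_PREFIX_RE.sub("", p) if p else None for p in pattern)
            n = len(pattern)
            for otu, lin in otu_lineages.items():
                lin_head = tuple(None if pd.isna(x) else x for x in lin[:n])
                if lin_head == pattern:
                    key = (otu, rank)
                    if key not in assignments or not assignments[key][1]:
                        assignments[key] = (label, False)
    by_otu: dict[str, dict[str, str]] = {}
    for (otu, rank), (label, _exact) in assignments.items():
        by_otu.setdefault(otu, {})[rank] = label
    for otu, rank_map in by_otu.items():
        deepest = max(RANKS.index(r) for r in rank_map)
        for r, lab in rank_map.items():
            if out.at[otu, r] != lab:
                logger.info("override applied: %s %s -> %s", otu, r, lab)
            out.at[otu, r] = lab
        for i in range(deepest + 1, len(RANKS)):
            if RANKS[i] not in rank_map:
                out.at[otu, RANKS[i]] = None
    return out


def classified_fraction(abund: AbundanceTable, tax: pd.DataFrame, rank: str) -> float:
    """Fraction of total read abundance classified at ``rank``.

    Sums abundance over all samples and OTUs carrying a label at the rank,
    divided by the total abundance; at even depth this equals the mean
    per-sample classified read fraction.
    """
    if rank not in RANKS:
        raise ArgumentError(f"unknown rank {rank!r}; use one of {RANKS}")
    a = abund.abund
    missing = a.index.difference(tax.index)
    if len(missing):
        raise InvariantError(f"taxonomy missing OTUs: {list(missing[:5])}")
    labels = tax.loc[a.index, rank]
    classified = labels.notna().to_numpy()
    total = float(a.to_numpy().sum())
    if total == 0:
        raise InvariantError("abundance table has zero total mass")
    return float(a.to_numpy()[classified].sum()) / total


def aggregate_to_rank(
    abund: AbundanceTable, tax: pd.DataFrame, rank: str, fallback: str = "otu_id"
) -> AbundanceTable:
    """Sum abundances per taxon label at ``rank``.

    OTUs unclassified at the rank keep their OTU id as label
    (``fallback="otu_id"``, the default, which conserves column sums exactly)
    or are dropped (``fallback="drop"``).
    """
    if rank not in RANKS:
        raise ArgumentError(f"unknown rank {rank!r}; use one of {RANKS}")
    if fallback not in ("otu_id", "drop"):
        raise ArgumentError(f"fallback must be 'otu_id' or 'drop', got {fallback!r}")
    a = abund.abund
    labels = tax.loc[a.index, rank].copy()
    if fallback == "otu_id":
        labels = labels.where(labels.notna(), labels.index.to_series())
        grouped = a.groupby(labels.to_numpy()).sum()
    else:
        keep = labels.notna()
        grouped = a.loc[keep.to_numpy()].groupby(labels[keep].to_numpy()).sum()
    grouped = grouped.sort_index()
    return AbundanceTable(abund=grouped, depth=abund.depth, domain=abund.domain,
                          normalized=(fallback == "otu_id") and abund.normalized)
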