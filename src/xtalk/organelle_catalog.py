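"""Harmonization of multi-source organelle protein lists.

Proteins localized to the endoplasmic reticulum (ER), mitochondria, and
cytosol are typically curated from several annotation databases, each with
its own symbol conventions and partial coverage.  This module merges such
lists into a single catalog keyed by canonical symbol, keeping for every
protein the full set of supporting compartments and sources, and assigns a
single *primary* compartment per protein under an explicit, configurable
policy (the upstream curation step this replaces is usually manual and
undocumented).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical compartment vocabulary, in no particular order.
COMPARTMENTS = ("ER", "mitochondria", "cytosol")

#: Default priority used to break ties when assigning a primary compartment.
DEFAULT_PRIORITY = ("mitochondria", "ER", "cytosol")

_SYNONYMS = {
    "er": "ER",
    "endoplasmic reticulum": "ER",
    "endoplasmic_reticulum": "ER",
    "mitochondria": "mitochondria",
    "mitochondrion": "mitochondria",
    "mito": "mitochondria",
    "cytosol": "cytosol",
    "cytoplasm": "cytosol",
    "cyto": "cytosol",
}


def canonical_compartment(value: str) -> str | None:
    """Map a raw compartment string to the canonical vocabulary.

    Returns ``None`` for values outside the three-compartment vocabulary.
    """
    return _SYNONYMS.get(str(value).strip().lower())


@dataclass(frozen=True)
class CatalogRecord:
    """One harmonized protein: compartment membership with source support."""

    symbol: str
    #: compartment -> set of sources supporting that localization
    support: Mapping[str, frozenset]
    primary: str | None = None

    @property
    def compartments(self) -> frozenset:
        return frozenset(self.support)

    @property
    def sources(self) -> frozenset:
        out: set = set()
        for srcs in self.support.values():
            out |= srcs
        return frozenset(out)


@dataclass
class ProteinCatalog:
    """Symbol-unique catalog of compartment-labeled proteins."""

    records: dict = field(default_factory=dict)  # symbol -> CatalogRecord
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.records

    def __iter__(self):
        return iter(self.symbols)

    @property
    def symbols(self) -> list:
        return sorted(self.records)

    def primary_map(self) -> dict:
        """symbol -> primary compartment (falls back to the sole compartment)."""
        out = {}
        for sym, rec in self.records.items():
            if rec.primary is not None:
                out[sym] = rec.primary
            elif len(rec.support) == 1:
                out[sym] = next(iter(rec.support))
            else:
                raise ValueError(
                    f"protein {sym!r} is multi-localized and has no primary "
                    "compartment; run assign_primary_compartment first"
                )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sym in self.symbols:
            rec = self.records[sym]
            rows.append(
                {
                    "symbol": sym,
                    "compartments": ";".join(sorted(rec.compartments)),
                    "sources": ";".join(sorted(rec.sources)),
                    "primary": rec.primary if rec.primary is not None else "",
                }
            )
        return pd.DataFrame(rows, columns=["symbol", "compartments", "sources", "primary"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ProteinCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        records = {}
        for row in df.itertuples(index=False):
            comps = [c for c in str(row.compartments).split(";") if c]
            sources = frozenset(s for s in str(row.sources).split(";") if s)
            support = {c: sources for c in comps}
            primary = row.primary or None
            records[row.symbol] = CatalogRecord(row.symbol, support, primary)
        return cls(records)


def harmonize(
    raw_tables: Sequence[pd.DataFrame],
    alias_map: Mapping[str, str] | None = None,
) -> ProteinCatalog:
    """Merge raw (symbol, compartment, source) tables into one catalog.

    Aliases are mapped to canonical symbols first; rows sharing a canonical
    symbol are then merged with union semantics over compartments and
    sources.  Rows with a compartment outside the ER/mitochondria/cytosol
    vocabulary are rejected with a logged warning and counted in
    ``ProteinCatalog.n_rejected``.  Symbols are compared case-sensitively
    after alias mapping.
    """
    alias_map = dict(alias_map or {})
    support: dict = {}  # symbol -> {compartment -> set(sources)}
    n_rejected = 0
    for table in raw_tables:
        for row in table.itertuples(index=False):
            raw_symbol = str(row.symbol)
            comp = canonical_compartment(row.compartment)
            if comp is None:
                n_rejected += 1
                logger.warning(
                    "rejecting row (%s, %s, %s): unknown compartment",
                    raw_symbol, row.compartment, row.source,
                )
                continue
            symbol = alias_map.get(raw_symbol, raw_symbol)
            support.setdefault(symbol, {}).setdefault(comp, set()).add(str(row.source))
    if n_rejected:
        logger.warning("harmonize: rejected %d rows with unknown compartments", n_rejected)
    records = {
        sym: CatalogRecord(sym, {c: frozenset(srcs) for c, srcs in comp_map.items()})
        for sym, comp_map in support.items()
    }
    return ProteinCatalog(records, n_rejected=n_rejected)


def assign_primary_compartment(
    catalog: ProteinCatalog,
    policy: str = "source_majority",
    priority_order: Sequence[str] = DEFAULT_PRIORITY,
) -> ProteinCatalog:
    """Give every protein exactly one primary compartment.

    ``source_majority`` picks the compartment with the most supporting
    sources, breaking ties by ``priority_order``; ``priority_order`` alone
    picks the highest-priority compartment present.  Multi-compartment
    membership is retained alongside the primary label.
    """
    if policy not in {"source_majority", "priority_order"}:
        raise ValueError(f"unknown policy {policy!r}")
    prio = {c: i for i, c in enumerate(priority_order)}
    missing = set(COMPARTMENTS) - set(prio)
    if missing:
        raise ValueError(f"priority_order must rank all compartments; missing {sorted(missing)}")
    records = {}
    for sym, rec in catalog.records.items():
        comps = sorted(rec.support)
        if policy == "source_majority":
            primary = min(comps, key=lambda c: (-len(rec.support[c]), prio[c]))
        else:
            primary = min(comps, key=lambda c: prio[c])
        records[sym] = CatalogRecord(sym, rec.support, primary)
    return ProteinCatalog(records, n_rejected=catalog.n_rejected)


def compartment_counts(catalog: ProteinCatalog, by: str = "primary") -> dict:
    """Count proteins per compartment.

    ``by="primary"`` counts each protein once, under its primary compartment
    (the counts sum to the number of records); ``by="membership"`` counts a
    multi-localized protein once per compartment.
    """
    counts = {c: 0 for c in COMPARTMENTS}
    for rec in catalog.records.values():
        if by == "primary":
            if rec.primary is not None:
                counts[rec.primary] += 1
            elif len(rec.support) == 1:
                counts[next(iter(rec.support))] += 1
            else:
                raise ValueError(
                    f"protein {rec.symbol!r} has no primary compartment; "
                    "assign one or count by='membership'"
                )
        elif by == "membership":
            for c in rec.support:
                counts[c] += 1
        else:
            raise ValueError(f"unknown counting mode {by!r}")
    return counts
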