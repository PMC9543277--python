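"""The global brood parasite-host interaction list and its summaries.

Obligate avian brood parasites lay their eggs in the nests of other
species; the documented parasite-host relationships form a global bipartite
edge list (parasite_species, host_species).  This module reads and
validates that list, reports declared parasites that lack any documented
host (these are excluded from network analyses), and computes the standard
species-level summary statistics: per-parasite host-count distribution
(median, IQR, max), per-host parasite-count distribution, and the fractions
of species with more than one partner.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .species import normalize_species_name

logger = logging.getLogger(__name__)


class InteractionFormatError(ValueError):
    """Malformed interaction CSV or invalid edges."""


@dataclass(frozen=True)
class InteractionTable:
    """A set of directed parasite -> host edges between distinct species."""

    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for p, h in self.edges:
            if p == h:
                raise InteractionFormatError(
                    f"self-interaction: {p!r} cannot host itself"
                )

    @property
    def parasite_ids(self) -> set[str]:
        return {p for p, _ in self.edges}

    @property
    def host_ids(self) -> set[str]:
        return {h for _, h in self.edges}

    @property
    def species_ids(self) -> set[str]:
        return self.parasite_ids | self.host_ids

    def __len__(self) -> int:
        return len(self.edges)

    def hosts_of(self, parasite: str) -> set[str]:
        return {h for p, h in self.edges if p == parasite}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.edges), columns=["parasite_species", "host_species"]
        )


def read_interactions(path, synonyms: dict[str, str] | None = None) -> InteractionTable:
    """Read a CSV with columns parasite_species, host_species.

    Species names are normalised (and synonym-mapped); exact duplicate
    pairs are collapsed with a logged count; a row whose parasite equals
    its host is rejected.
    """
    df = pd.read_csv(path)
    required = {"parasite_species", "host_species"}
    missing = required - set(df.columns)
    if missing:
        raise InteractionFormatError(f"missing columns: {sorted(missing)}")
    if df.empty:
        warnings.warn(f"{path}: empty interaction table", stacklevel=2)
        return InteractionTable(frozenset())
    pairs = []
    for idx, row in df.iterrows():
        p = normalize_species_name(row["parasite_species"], synonyms)
        h = normalize_species_name(row["host_species"], synonyms)
        if p == h:
            raise InteractionFormatError(
                f"row {idx}: parasite equals host ({p!r})"
            )
        pairs.append((p, h))
    edges = frozenset(pairs)
    dups = len(pairs) - len(edges)
    if dups:
        logger.info("collapsed %d duplicate interaction rows", dups)
    return InteractionTable(edges)


def drop_hostless_parasites(
    table: InteractionTable, declared_parasites: set[str]
) -> tuple[InteractionTable, set[str]]:
    """Report declared parasite species with no documented host.

    The table itself never contains hostless parasites (they have no
    edges); the job of this operation is to surface them so richness maps
    and summaries can exclude them.  ``declared_parasites`` must cover all
    parasites that do appear in edges.
    """
    undeclared = table.parasite_ids - set(declared_parasites)
    if undeclared:
        raise ValueError(
            f"parasites present in edges but not declared: {sorted(undeclared)}"
        )
    excluded = set(declared_parasites) - table.parasite_ids
    if excluded:
        logger.info(
            "%d declared parasite species have no documented host and are "
            "excluded from analyses", len(excluded),
        )
    return table, excluded


@dataclass(frozen=True)
class SpeciesSummary:
    """Partner-count statistics for both sides of the bipartite edge list.

    Quartiles (hence IQR = Q3 - Q1) use linear interpolation between order
    statistics; fractions are also reported rounded to the nearest whole
    percent, the convention for published summaries.
    """

    n_parasites: int
    n_hosts: int
    n_interactions: int
    parasite_host_counts: dict[str, int]
    host_parasite_counts: dict[str, int]
    parasite_median: float
    parasite_iqr: float
    parasite_max: int
    host_median: float
    host_iqr: float
    host_max: int
    frac_parasites_multi_host: float
    frac_hosts_multi_parasite: float

    @property
    def pct_parasites_multi_host(self) -> int:
        return round(self.frac_parasites_multi_host * 100)

    @property
    def pct_hosts_multi_parasite(self) -> int:
        return round(self.frac_hosts_multi_parasite * 100)

    def report(self) -> str:
        return "\n".join(
            [
                f"parasite species: {self.n_parasites}",
                f"host species: {self.n_hosts}",
                f"interactions: {self.n_interactions}",
                f"hosts per parasite: median {self.parasite_median:g} "
                f"(IQR = {self.parasite_iqr:g}), max {self.parasite_max}",
                f"parasites per host: median {self.host_median:g} "
                f"(IQR = {self.host_iqr:g}), max {self.host_max}",
                f"parasites with >1 host: {self.pct_parasites_multi_host}%",
                f"hosts with >1 parasite: {self.pct_hosts_multi_parasite}%",
            ]
        )


def _count_stats(counts: np.ndarray) -> tuple[float, float, int, float]:
    q1, med, q3 = np.percentile(counts, [25, 50, 75], method="linear")
    return float(med), float(q3 - q1), int(counts.max()), float((counts > 1).mean())


def species_summaries(table: InteractionTable) -> SpeciesSummary:
    """Compute partner-count distributions for parasites and hosts."""
    if not table.edges:
        raise ValueError("cannot summarise an empty interaction table")
    df = table.to_frame()
    by_parasite = df.groupby("parasite_species").size()
    by_host = df.groupby("host_species").size()
    p_med, p_iqr, p_max, p_frac = _count_stats(by_parasite.to_numpy())
    h_med, h_iqr, h_max, h_frac = _count_stats(by_host.to_numpy())
    return SpeciesSummary(
        n_parasites=len(by_parasite),
        n_hosts=len(by_host),
        n_interactions=len(table),
        parasite_host_counts=by_parasite.to_dict(),
        host_parasite_counts=by_host.to_dict(),
        parasite_median=p_med,
        parasite_iqr=p_iqr,
        parasite_max=p_max,
        host_median=h_med,
        host_iqr=h_iqr,
        host_max=h_max,
        frac_parasites_multi_host=p_frac,
        frac_hosts_multi_parasite=h_frac,
    )
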