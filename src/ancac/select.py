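"""Organism selection.

An analysis always runs over a *selection* of organisms.  Selections are
built from explicit id lists, taxon subtrees (at any of the seven supported
ranks), physiology trait patterns, or membership in a COG of choice, and
successive criteria combine into one selection — by set union by default, so
consecutive selections grow a superset of organisms; an intersection mode is
available for conjunctive queries.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .dataio import Dataset, RANKS
from .errors import DataError

log = logging.getLogger("ancac")

#: The two shipped trait patterns plus a parameterized thermophile pattern.
TRAIT_PATTERNS = ("aerobia", "anaerobia", "thermophile_ogt_ge")

_THERMO_RE = re.compile(r"^thermophile_ogt_ge[\(:]?\s*([0-9.]+)\s*\)?$")


@dataclass(frozen=True)
class Selection:
    """An organism set plus the provenance of the criteria that built it."""

    organism_ids: frozenset[str]
    provenance: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.organism_ids)

    def __contains__(self, organism_id: str) -> bool:
        return organism_id in self.organism_ids


def select_all(dataset: Dataset) -> Selection:
    return Selection(frozenset(dataset.organisms), ("all",))


def select_by_ids(dataset: Dataset, ids: Iterable[str]) -> Selection:
    ids = set(ids)
    unknown = ids - set(dataset.organisms)
    if unknown:
        raise DataError(f"unknown organism id(s) {sorted(unknown)}")
    return Selection(frozenset(ids), (f"ids:{len(ids)} organisms",))


def select_by_taxon(dataset: Dataset, rank: str, taxon: str) -> Selection:
    """All organisms whose lineage at ``rank`` equals ``taxon`` (case-insensitive)."""
    if rank not in RANKS:
        raise DataError(f"unsupported rank {rank!r}; supported: {', '.join(RANKS)}")
    if not dataset.has_taxonomy:
        raise DataError("no taxonomy attached to the dataset")
    want = taxon.lower()
    hits = frozenset(
        org_id for org_id, org in dataset.organisms.items()
        if org.lineage.get(rank, "").lower() == want)
    if not hits:
        log.warning("taxon %r not found at rank %r: empty selection", taxon, rank)
    return Selection(hits, (f"taxon:{rank}={taxon}",))


def select_by_trait(dataset: Dataset, pattern: str,
                    ogt_threshold: float | None = None) -> Selection:
    """Select by a pre-defined trait pattern.

    ``aerobia`` matches strict aerobes and ``anaerobia`` strict anaerobes;
    facultative and unknown organisms belong to neither, so the two patterns
    never overlap.  ``thermophile_ogt_ge`` (threshold given either as
    ``thermophile_ogt_ge(80)`` or via ``ogt_threshold``) selects organisms
    with a recorded optimum growth temperature at or above the threshold.
    """
    if not dataset.has_traits:
        raise DataError(f"trait pattern {pattern!r} requires a loaded trait table")
    pattern = pattern.strip().lower()
    m = _THERMO_RE.match(pattern)
    if m:
        pattern, ogt_threshold = "thermophile_ogt_ge", float(m.group(1))
    if pattern == "aerobia":
        hits = {o for o, org in dataset.organisms.items() if org.oxygen_class == "aerobe"}
        label = "trait:aerobia"
    elif pattern == "anaerobia":
        hits = {o for o, org in dataset.organisms.items() if org.oxygen_class == "anaerobe"}
        label = "trait:anaerobia"
    elif pattern == "thermophile_ogt_ge":
        if ogt_threshold is None:
            raise DataError("thermophile_ogt_ge needs a temperature threshold")
        if not any(org.ogt_celsius is not None for org in dataset.organisms.values()):
            raise DataError("thermophile pattern requires OGT values in the trait table")
        hits = {o for o, org in dataset.organisms.items()
                if org.ogt_celsius is not None and org.ogt_celsius >= ogt_threshold}
        label = f"trait:thermophile_ogt_ge({ogt_threshold:g})"
    else:
        raise DataError(f"unknown trait pattern {pattern!r}; "
                        f"known patterns: {', '.join(TRAIT_PATTERNS)}")
    if not hits:
        log.warning("trait pattern %s matched no organism", label)
    return Selection(frozenset(hits), (label,))


def select_by_cog(dataset: Dataset, cog_id: str) -> Selection:
    """Organisms contributing at least one member sequence to the COG."""
    if cog_id not in dataset.cogs:
        raise DataError(f"unknown COG {cog_id!r}")
    hits = frozenset(org for org, _ in dataset.cogs[cog_id].member_ids)
    return Selection(hits, (f"cog:{cog_id}",))


def combine(selections: Sequence[Selection], mode: str = "union") -> Selection:
    """Merge consecutive selections (union by default, intersect optional)."""
    if not selections:
        raise DataError("combine needs at least one selection")
    if mode not in ("union", "intersect"):
        raise DataError(f"unknown combine mode {mode!r}")
    ids = set(selections[0].organism_ids)
    for sel in selections[1:]:
        if mode == "union":
            ids |= sel.organism_ids
        else:
            ids &= sel.organism_ids
    provenance = tuple(p for sel in selections for p in sel.provenance)
    return Selection(frozenset(ids), provenance)


def parse_selection_spec(dataset: Dataset, spec: str) -> Selection:
    """Parse one ``--select`` argument: ``taxon:<rank>=<name>``,
    ``trait:<pattern>``, ``cog:<id>`` or ``ids:<file>`` (one id per line)."""
    kind, _, arg = spec.partition(":")
    if kind == "taxon":
        rank, _, taxon = arg.partition("=")
        if not taxon:
            raise DataError(f"bad taxon selector {spec!r}; expected taxon:<rank>=<name>")
        return select_by_taxon(dataset, rank.strip(), taxon.strip())
    if kind == "trait":
        return select_by_trait(dataset, arg)
    if kind == "cog":
        return select_by_cog(dataset, arg.strip())
    if kind == "ids":
        ids = [ln.strip() for ln in Path(arg).read_text().splitlines()
               if ln.strip() and not ln.startswith("#")]
        return select_by_ids(dataset, ids)
    raise DataError(f"unknown selector kind {kind!r} in {spec!r}")
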