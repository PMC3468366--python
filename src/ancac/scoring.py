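"""APSF scoring engine.

The central statistic is the *average percentage of the selected sequence
features* (APSF): for a set of sequences in scope, 100 times the pooled count
of the selected features divided by the pooled usable total of that feature
type.  Pooling sums pre-computed per-sequence counts, so long sequences weigh
in proportionally (length-weighted), as opposed to averaging per-sequence
percentages; the latter is available as an explicit alternative.

A *frequency score* divides a scope's APSF by a reference APSF taken either
over the whole database or over all sequences of the selected organisms.
Scores above 1 mean the features are overrepresented in that scope.

Scoring runs per COG (optionally per taxon subgroup at a chosen rank), or in
batch mode over user-defined COG groups parsed from a small line-oriented
grammar (``NAME : FEATURES : COG_LIST``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dataio import Dataset, RANKS, SequenceRecord
from .errors import BatchFormatError, DataError, UndefinedScoreError
from .features import AA20, CODONS, NT4, STOP_CODONS, get_counts
from .select import Selection, select_all

log = logging.getLogger("ancac")

FEATURE_TYPES = ("amino_acid", "nucleotide", "codon")

_ALPHABETS = {"amino_acid": frozenset(AA20),
              "nucleotide": frozenset(NT4),
              "codon": frozenset(CODONS)}

NORMALIZATIONS = ("none", "whole_database", "selected_organisms")


# ---------------------------------------------------------------------------
# Query / result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Query:
    """One scoring request, mirroring the tool's input choices."""

    feature_type: str
    features: frozenset[str]
    selection: Selection
    normalization: str = "none"
    subgroup_rank: str | None = None
    cog_scope: tuple[str, ...] | None = None    # None = all COGs
    include_stops: bool = False
    mean_of_sequences: bool = False

    def __post_init__(self):
        validate_features(self.feature_type, self.features, self.include_stops)
        if self.normalization not in NORMALIZATIONS:
            raise DataError(f"unknown normalization {self.normalization!r}")
        if self.subgroup_rank is not None and self.subgroup_rank not in RANKS:
            raise DataError(f"unsupported subgroup rank {self.subgroup_rank!r}")


@dataclass
class ScoreRow:
    """One output ranking line."""

    group_label: str
    subgroup: str | None
    selected_feature_count: int
    total_feature_count: int
    apsf: float
    score: float
    description: str
    n_sequences: int
    n_skipped: int


@dataclass(frozen=True)
class ApsfResult:
    selected: int
    total: int
    apsf: float
    n_sequences: int
    n_skipped: int


def validate_features(feature_type: str, features: Iterable[str],
                      include_stops: bool = False) -> frozenset[str]:
    if feature_type not in FEATURE_TYPES:
        raise DataError(f"unknown feature type {feature_type!r}")
    feats = frozenset(features)
    if not feats:
        raise DataError("empty feature set")
    bad = feats - _ALPHABETS[feature_type]
    if bad:
        raise DataError(f"invalid {feature_type} feature(s) {sorted(bad)}")
    if feature_type == "codon" and not include_stops and feats & set(STOP_CODONS):
        raise DataError("stop codons can only be selected with include_stops=True")
    return feats


# ---------------------------------------------------------------------------
# The APSF core
# ---------------------------------------------------------------------------

def _seq_counts(dataset: Dataset, rec: SequenceRecord, feature_type: str,
                features: frozenset[str], include_stops: bool) -> tuple[int, int] | None:
    """(selected, total) for one sequence, or None if it must be skipped."""
    if feature_type != "amino_acid" and not rec.nt_seq:
        return None
    fc = get_counts(dataset, rec)
    if feature_type == "amino_acid":
        return (sum(fc.aa_counts.get(f, 0) for f in features), fc.aa_total)
    if feature_type == "nucleotide":
        return (sum(fc.nt_counts.get(f, 0) for f in features), fc.nt_total)
    total = fc.codon_total if include_stops else fc.sense_codon_total
    return (sum(fc.codon_counts.get(f, 0) for f in features), total)


def apsf(dataset: Dataset, records: Iterable[SequenceRecord], feature_type: str,
         features: Iterable[str], include_stops: bool = False,
         mean_of_sequences: bool = False) -> ApsfResult:
    """Pooled APSF over a sequence scope.

    Records lacking the needed sequence kind (no CDS for nucleotide/codon
    queries) are skipped and tallied in ``n_skipped``.  An empty effective
    scope raises :class:`UndefinedScoreError` carrying that tally.
    """
    feats = validate_features(feature_type, features, include_stops)
    selected = total = n_sequences = n_skipped = 0
    pct_sum = 0.0
    for rec in records:
        pair = _seq_counts(dataset, rec, feature_type, feats, include_stops)
        if pair is None or pair[1] == 0:
            n_skipped += 1
            continue
        selected += pair[0]
        total += pair[1]
        pct_sum += 100.0 * pair[0] / pair[1]
        n_sequences += 1
    if total == 0:
        raise UndefinedScoreError(
            f"no usable {feature_type} features in scope ({n_skipped} record(s) skipped)",
            n_skipped=n_skipped)
    value = pct_sum / n_sequences if mean_of_sequences else 100.0 * selected / total
    return ApsfResult(selected, total, value, n_sequences, n_skipped)


def _scope(dataset: Dataset, selection: Selection,
           cog_ids: Iterable[str] | None = None) -> list[SequenceRecord]:
    wanted = None if cog_ids is None else set(cog_ids)
    return [rec for rec in dataset.sequences
            if rec.organism_id in selection.organism_ids
            and (wanted is None or rec.cog_id in wanted)]


def reference_apsf(dataset: Dataset, query: Query) -> ApsfResult:
    """The normalization denominator.

    ``whole_database``: pooled APSF over every sequence of the dataset.
    ``selected_organisms``: pooled APSF over all sequences of the selected
    organisms, across all COGs.  Both are global — they do not depend on the
    COG or subgroup being scored.
    """
    if query.normalization == "none":
        raise DataError("reference_apsf called without a normalization mode")
    if query.normalization == "whole_database":
        records: Iterable[SequenceRecord] = dataset.sequences
    else:
        records = _scope(dataset, query.selection)
    return apsf(dataset, records, query.feature_type, query.features,
                query.include_stops, query.mean_of_sequences)


def _subgroups(dataset: Dataset, selection: Selection,
               rank: str) -> dict[str, frozenset[str]]:
    """taxon name -> organism ids of the selection, at the given rank."""
    if not dataset.has_taxonomy:
        raise DataError("taxonomic subgrouping requires a loaded taxonomy table")
    groups: dict[str, set[str]] = {}
    missing = 0
    for org_id in selection.organism_ids:
        taxon = dataset.organisms[org_id].lineage.get(rank)
        if taxon is None:
            missing += 1
            continue
        groups.setdefault(taxon, set()).add(org_id)
    if missing:
        log.warning("%d organism(s) lack rank %r and were left out of subgrouping",
                    missing, rank)
    return {t: frozenset(o) for t, o in groups.items()}


def _finish_rows(rows: list[ScoreRow]) -> list[ScoreRow]:
    rows.sort(key=lambda r: (-r.score, r.group_label, r.subgroup or ""))
    return rows


def score_cogs(dataset: Dataset, query: Query) -> list[ScoreRow]:
    """One ranking row per COG (× per taxon subgroup when subgrouping).

    Only sequences from selected organisms enter a COG's scope.  With a
    normalization mode active the score is APSF / reference APSF; otherwise
    the score simply equals the APSF.  Rows come back sorted score-descending
    with ties broken by COG id; COGs (or subgroups) whose effective scope is
    empty are omitted and tallied in the log.
    """
    if query.cog_scope is None:
        cog_ids: Sequence[str] = sorted(dataset.cogs)
    else:
        unknown = set(query.cog_scope) - set(dataset.cogs)
        if unknown:
            raise DataError(f"unknown COG(s) {sorted(unknown)}")
        cog_ids = list(query.cog_scope)

    ref = None
    if query.normalization != "none":
        ref = reference_apsf(dataset, query)
        if ref.apsf == 0:
            raise UndefinedScoreError("reference APSF is zero; scores undefined")

    if query.subgroup_rank is not None:
        subsets = sorted(_subgroups(dataset, query.selection, query.subgroup_rank).items())
    else:
        subsets = [(None, query.selection.organism_ids)]

    by_cog: dict[str, list[SequenceRecord]] = {c: [] for c in cog_ids}
    for rec in _scope(dataset, query.selection, by_cog):
        by_cog[rec.cog_id].append(rec)

    rows: list[ScoreRow] = []
    omitted = 0
    for cog_id in cog_ids:
        desc = dataset.cogs[cog_id].description
        for taxon, org_ids in subsets:
            records = [r for r in by_cog[cog_id] if r.organism_id in org_ids]
            try:
                res = apsf(dataset, records, query.feature_type, query.features,
                           query.include_stops, query.mean_of_sequences)
            except UndefinedScoreError:
                omitted += 1
                continue
            score = res.apsf / ref.apsf if ref is not None else res.apsf
            rows.append(ScoreRow(cog_id, taxon, res.selected, res.total, res.apsf,
                                 score, desc, res.n_sequences, res.n_skipped))
    if omitted:
        log.info("%d COG/subgroup scope(s) had no usable sequences and were omitted",
                 omitted)
    return _finish_rows(rows)


# ---------------------------------------------------------------------------
# Batch mode
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BatchGroup:
    """One parsed batch line: a named feature set over a group of COGs."""

    name: str
    features: frozenset[str]
    cog_ids: tuple[str, ...]


_COG_TOKEN_RE = re.compile(r"^[A-Za-z]+[0-9]+$")


def parse_batch(text: str, dataset: Dataset | None = None,
                feature_type: str = "amino_acid") -> list[BatchGroup]:
    """Parse batch-query text: one ``NAME : FEATURES : COG_LIST`` per line.

    Features are comma-separated, COG ids comma- or whitespace-separated;
    blank lines and ``#`` comments are ignored.  With a dataset given, COG
    ids are checked against its catalogue.
    """
    groups: list[BatchGroup] = []
    seen_names: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(":")]
        if len(parts) != 3:
            raise BatchFormatError(
                f"expected NAME:FEATURES:COG_LIST, got {raw.strip()!r}", lineno)
        name, feat_part, cog_part = parts
        if not name or not feat_part or not cog_part:
            raise BatchFormatError(f"empty field in {raw.strip()!r}", lineno)
        if name in seen_names:
            raise BatchFormatError(f"duplicate group name {name!r}", lineno)
        seen_names.add(name)
        features = frozenset(f.strip() for f in feat_part.split(",") if f.strip())
        try:
            validate_features(feature_type, features)
        except DataError as exc:
            raise BatchFormatError(str(exc), lineno) from exc
        cog_ids = tuple(tok for tok in re.split(r"[,\s]+", cog_part) if tok)
        for tok in cog_ids:
            if not _COG_TOKEN_RE.match(tok):
                raise BatchFormatError(f"bad COG id {tok!r}", lineno)
        if dataset is not None:
            unknown = sorted(set(cog_ids) - set(dataset.cogs))
            if unknown:
                raise BatchFormatError(f"unknown COG(s) {unknown}", lineno)
        groups.append(BatchGroup(name, features, cog_ids))
    return groups


def score_batch(dataset: Dataset, groups: Sequence[BatchGroup],
                selection: Selection | None = None,
                normalization: str = "whole_database",
                subgroup_rank: str | None = None,
                feature_type: str = "amino_acid",
                include_stops: bool = False) -> list[ScoreRow]:
    """Cumulative scores for user-defined COG groups.

    Each group's APSF pools over *all* member sequences of all its COGs
    (within the selection, and per taxon subgroup when subgrouping); the
    normalization reference is the same global one used for per-COG scoring.
    Groups with an empty effective scope are omitted with a warning.
    """
    if selection is None:
        selection = select_all(dataset)
    rows: list[ScoreRow] = []
    for group in groups:
        unknown = sorted(set(group.cog_ids) - set(dataset.cogs))
        if unknown:
            raise DataError(f"group {group.name!r}: unknown COG(s) {unknown}")
        query = Query(feature_type, group.features, selection, normalization,
                      subgroup_rank, tuple(group.cog_ids), include_stops)
        ref = None
        if normalization != "none":
            ref = reference_apsf(dataset, query)
            if ref.apsf == 0:
                raise UndefinedScoreError(
                    f"group {group.name!r}: reference APSF is zero")
        if subgroup_rank is not None:
            subsets = sorted(_subgroups(dataset, selection, subgroup_rank).items())
        else:
            subsets = [(None, selection.organism_ids)]
        pooled = _scope(dataset, selection, group.cog_ids)
        desc = f"group of {len(group.cog_ids)} COGs"
        emitted = False
        for taxon, org_ids in subsets:
            records = [r for r in pooled if r.organism_id in org_ids]
            try:
                res = apsf(dataset, records, feature_type, group.features,
                           include_stops)
            except UndefinedScoreError:
                continue
            score = res.apsf / ref.apsf if ref is not None else res.apsf
            rows.append(ScoreRow(group.name, taxon, res.selected, res.total,
                                 res.apsf, score, desc, res.n_sequences,
                                 res.n_skipped))
            emitted = True
        if not emitted:
            log.warning("group %r has no usable sequences in scope; row omitted",
                        group.name)
    return _finish_rows(rows)
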