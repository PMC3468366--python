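"""Composition-analysis recipes built on the scoring engine.

Four analyses connect sequence composition with function or physiology:

* ranking COGs by positively charged residues (K, R, H), which surfaces
  ribosomal proteins whose tails contact the rRNA phosphate backbone;
* the cognate-bias analysis — is an amino acid underrepresented in the
  enzymes of its own biosynthetic pathway? — run as a batch query per
  amino acid with per-species subgrouping;
* thermophily regressions: the proteome ratio (E+K)/(Q+H) and the AGR share
  of arginine codons (AGA+AGG over all six Arg codons), each regressed on
  optimum growth temperature (OGT);
* pooled genomic GC content compared between trait-defined organism groups
  (aerobes vs. anaerobes).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from scipy import stats

from .dataio import Dataset
from .errors import DataError, UndefinedScoreError
from .features import AA20, AGR_CODONS, ARG_CODONS, get_counts
from .scoring import BatchGroup, ScoreRow, score_batch, score_cogs, Query
from .select import Selection, select_all, select_by_trait

# ---------------------------------------------------------------------------
# Positively charged residues (ribosomal-protein signature)
# ---------------------------------------------------------------------------

POSITIVE_AA = frozenset("KRH")


def positively_charged_ranking(dataset: Dataset,
                               selection: Selection | None = None) -> list[ScoreRow]:
    """Rank all COGs by their relative frequency of K, R and H.

    Normalized against all sequences of the database, so a score of e.g. 1.4
    means 40% more positive residues than the database-wide average.
    """
    if selection is None:
        selection = select_all(dataset)
    query = Query("amino_acid", POSITIVE_AA, selection,
                  normalization="whole_database")
    return score_cogs(dataset, query)


# ---------------------------------------------------------------------------
# Cognate bias
# ---------------------------------------------------------------------------

def load_cognate_map(path: str | Path) -> dict[str, list[str]]:
    """Read an amino-acid → pathway-COGs map (TSV: aa, comma-separated COGs)."""
    mapping: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise DataError(f"cognate map line {lineno}: expected aa<TAB>COG list")
            aa = row[0].strip().upper()
            if aa not in AA20:
                raise DataError(f"cognate map line {lineno}: {aa!r} is not an amino acid")
            if aa in mapping:
                raise DataError(f"cognate map line {lineno}: duplicate amino acid {aa!r}")
            cogs = [tok for tok in row[1].replace(",", " ").split() if tok]
            if not cogs:
                raise DataError(f"cognate map line {lineno}: no COGs listed")
            mapping[aa] = cogs
    return mapping


def cognate_bias(dataset: Dataset, cognate_map: Mapping[str, list[str]],
                 selection: Selection | None = None,
                 normalization: str = "whole_database",
                 subgroup_rank: str | None = "species") -> pd.DataFrame:
    """Relative frequency of each amino acid in its own biosynthesis COGs.

    Returns a species × amino-acid table of frequency scores (NaN where a
    species contributes no sequence to the listed COGs).  Scores below 1
    support the cognate-bias hypothesis: the amino acid is underrepresented
    in the enzymes that make it.
    """
    if not cognate_map:
        raise DataError("empty cognate map")
    groups = [BatchGroup(aa, frozenset(aa), tuple(cogs))
              for aa, cogs in sorted(cognate_map.items())]
    rows = score_batch(dataset, groups, selection, normalization, subgroup_rank)
    if subgroup_rank is None:
        data = {r.group_label: {"all": r.score} for r in rows}
    else:
        data: dict[str, dict[str, float]] = {}
        for r in rows:
            data.setdefault(r.group_label, {})[r.subgroup] = r.score
    frame = pd.DataFrame(data).sort_index()
    return frame[sorted(frame.columns)]


# ---------------------------------------------------------------------------
# Per-organism composition statistics
# ---------------------------------------------------------------------------

def _organism_records(dataset: Dataset, organism_id: str):
    if organism_id not in dataset.organisms:
        raise DataError(f"unknown organism {organism_id!r}")
    recs = [r for r in dataset.sequences if r.organism_id == organism_id]
    if not recs:
        raise DataError(f"organism {organism_id!r} has no sequences")
    return recs


def ekqh_ratio(dataset: Dataset, organism_id: str) -> float:
    """(E+K)/(Q+H) over the organism's pooled residue counts.

    The ratio rises with growth temperature: thermophilic proteomes carry
    more glutamate and lysine at the expense of glutamine and histidine.
    """
    e = k = q = h = 0
    for rec in _organism_records(dataset, organism_id):
        fc = get_counts(dataset, rec)
        e += fc.aa_counts.get("E", 0)
        k += fc.aa_counts.get("K", 0)
        q += fc.aa_counts.get("Q", 0)
        h += fc.aa_counts.get("H", 0)
    if q + h == 0:
        raise UndefinedScoreError(f"organism {organism_id}: Q+H count is zero")
    return (e + k) / (q + h)


def agr_fraction(dataset: Dataset, organism_id: str) -> float:
    """Percentage of arginine codons that are AGR (AGA or AGG).

    Pooled over all the organism's CDS; thermophiles tend to favour the AGR
    pair over the CGN quartet.
    """
    agr = arg = 0
    for rec in _organism_records(dataset, organism_id):
        fc = get_counts(dataset, rec)
        agr += sum(fc.codon_counts.get(c, 0) for c in AGR_CODONS)
        arg += sum(fc.codon_counts.get(c, 0) for c in ARG_CODONS)
    if arg == 0:
        raise UndefinedScoreError(f"organism {organism_id}: no arginine codons")
    return 100.0 * agr / arg


# ---------------------------------------------------------------------------
# OGT regressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares of a composition value on OGT."""

    slope: float            # value units per degC
    intercept: float
    r: float                # Pearson correlation of the pairs
    n: int
    stderr: float = 0.0     # standard error of the slope
    dropped: int = 0        # organisms missing a value or an OGT
    degenerate: bool = False  # zero variance in the response


def _linear_fit(xs, ys) -> tuple[float, float, float, float]:
    """OLS kernel (slope, intercept, r, slope stderr); no sample-size gate."""
    res = stats.linregress(xs, ys)
    return (float(res.slope), float(res.intercept), float(res.rvalue),
            float(res.stderr))


def ogt_regression(values: Mapping[str, float],
                   ogts: Mapping[str, float | None]) -> RegressionResult:
    """Regress per-organism composition values on optimum growth temperature.

    Organisms missing either quantity are dropped (and counted); fewer than
    three complete pairs is an error.  A zero-variance response is reported
    as a degenerate fit with slope 0 and r set to 0.
    """
    pairs = [(ogts[o], v) for o, v in values.items()
             if o in ogts and ogts[o] is not None and v is not None
             and not math.isnan(v)]
    dropped = len(values) - len(pairs)
    if len(pairs) < 3:
        raise DataError(f"need at least 3 complete (value, OGT) pairs, have {len(pairs)}")
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    if len(set(xs)) == 1:
        raise DataError("all OGTs identical; regression undefined")
    if len(set(ys)) == 1:
        return RegressionResult(0.0, ys[0], 0.0, len(pairs), 0.0, dropped,
                                degenerate=True)
    slope, intercept, r, stderr = _linear_fit(xs, ys)
    return RegressionResult(slope, intercept, r, len(pairs), stderr, dropped)


def ekqh_vs_ogt(dataset: Dataset) -> tuple[dict[str, float], RegressionResult]:
    """(E+K)/(Q+H) per organism and its regression on OGT (units per degC)."""
    values = {o: ekqh_ratio(dataset, o) for o in sorted(dataset.organisms)
              if any(r.organism_id == o for r in dataset.sequences)}
    ogts = {o: org.ogt_celsius for o, org in dataset.organisms.items()}
    return values, ogt_regression(values, ogts)


def agr_vs_ogt(dataset: Dataset) -> tuple[dict[str, float], RegressionResult]:
    """AGR fraction of arginine codons per organism, regressed on OGT.

    The regression runs on the 0–1 fraction scale (slope in fraction per
    degC); the returned per-organism values are percentages as printed.
    """
    values: dict[str, float] = {}
    for o in sorted(dataset.organisms):
        try:
            values[o] = agr_fraction(dataset, o)
        except (DataError, UndefinedScoreError):
            continue
    ogts = {o: org.ogt_celsius for o, org in dataset.organisms.items()}
    fit = ogt_regression({o: v / 100.0 for o, v in values.items()}, ogts)
    return values, fit


# ---------------------------------------------------------------------------
# GC content by trait
# ---------------------------------------------------------------------------

def _pooled_gc(dataset: Dataset, selection: Selection) -> float:
    gc = total = 0
    for rec in dataset.sequences:
        if rec.organism_id not in selection.organism_ids or not rec.nt_seq:
            continue
        fc = get_counts(dataset, rec)
        gc += fc.nt_counts.get("G", 0) + fc.nt_counts.get("C", 0)
        total += fc.nt_total
    if total == 0:
        raise UndefinedScoreError("selection has no coding sequence; GC undefined")
    return 100.0 * gc / total


def _mean_gc(dataset: Dataset, selection: Selection) -> float:
    per_org = []
    for org_id in sorted(selection.organism_ids):
        try:
            per_org.append(_pooled_gc(dataset, Selection(frozenset([org_id]))))
        except UndefinedScoreError:
            continue
    if not per_org:
        raise UndefinedScoreError("selection has no coding sequence; GC undefined")
    return sum(per_org) / len(per_org)


def gc_by_trait(dataset: Dataset, pattern_a: str = "aerobia",
                pattern_b: str = "anaerobia",
                per_organism_mean: bool = False) -> tuple[float, float]:
    """GC percentage of two trait-defined organism groups.

    Pools G+C over all CDS of each selection (matching the scoring engine's
    length-weighted pooling); ``per_organism_mean`` switches to the mean of
    per-organism GC values instead.
    """
    sel_a = select_by_trait(dataset, pattern_a)
    sel_b = select_by_trait(dataset, pattern_b)
    for pattern, sel in ((pattern_a, sel_a), (pattern_b, sel_b)):
        if not sel.organism_ids:
            raise DataError(f"trait pattern {pattern!r} selects no organisms")
    calc = _mean_gc if per_organism_mean else _pooled_gc
    return calc(dataset, sel_a), calc(dataset, sel_b)
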