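"""Per-sequence feature counting.

Everything the scoring engine consumes is pre-computed here, once per
sequence: counts of the 20 amino acids, the 4 nucleotides and the 64 codons,
together with the usable totals per feature type.  Ambiguity policy: ``X``
and ``*`` residues contribute to neither amino-acid counts nor the residue
total; ``N`` bases and any triplet containing ``N`` are likewise excluded.
Stop codons are counted in ``codon_counts`` but a sense-only total is exposed
separately, because coding-usage percentages are normally taken over sense
codons.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import TYPE_CHECKING

from Bio.Data import CodonTable

from .errors import DataError, UndefinedScoreError

if TYPE_CHECKING:  # pragma: no cover
    from .dataio import Dataset, SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NT4 = "ACGT"
CODONS = tuple("".join(p) for p in product(NT4, repeat=3))
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(c for c in CODONS if c not in STOP_CODONS)

_std_table = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, with '*' for the three stop codons.
CODON_TO_AA = {**_std_table.forward_table, **{c: "*" for c in STOP_CODONS}}
#: one-letter amino acid -> tuple of synonymous codons (plus '*' -> stops).
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], tuple())
    AA_TO_CODONS[CODON_TO_AA[_codon]] += (_codon,)

ARG_CODONS = AA_TO_CODONS["R"]          # CGT CGC CGA CGG AGA AGG
AGR_CODONS = ("AGA", "AGG")


@dataclass
class FeatureCounts:
    """Pre-computed counts and usable totals for one sequence."""

    aa_counts: dict[str, int]
    aa_total: int
    nt_counts: dict[str, int]
    nt_total: int
    codon_counts: dict[str, int]
    codon_total: int

    @property
    def sense_codon_total(self) -> int:
        """Codons counted, stop codons excluded."""
        return self.codon_total - sum(self.codon_counts.get(c, 0) for c in STOP_CODONS)

    @property
    def gc_percent(self) -> float:
        return gc_fraction(self.nt_counts)


def count_amino_acids(aa_seq: str) -> tuple[dict[str, int], int]:
    """Count standard residues; ``X`` and ``*`` are excluded from the total."""
    counts: dict[str, int] = {}
    total = 0
    for pos, ch in enumerate(aa_seq):
        if ch in ("X", "*"):
            continue
        if ch not in AA20:
            raise DataError(f"invalid amino-acid character {ch!r} at position {pos + 1}")
        counts[ch] = counts.get(ch, 0) + 1
        total += 1
    return counts, total


def count_nucleotides(nt_seq: str) -> tuple[dict[str, int], int]:
    """Count A/C/G/T; ``N`` is excluded from counts and total."""
    counts: dict[str, int] = {}
    total = 0
    for pos, ch in enumerate(nt_seq):
        if ch == "N":
            continue
        if ch not in NT4:
            raise DataError(f"invalid nucleotide character {ch!r} at position {pos + 1}")
        counts[ch] = counts.get(ch, 0) + 1
        total += 1
    return counts, total


def count_codons(nt_seq: str) -> tuple[dict[str, int], int]:
    """Count frame-0, non-overlapping triplets.

    A trailing incomplete triplet is dropped; triplets containing ``N`` are
    excluded from both counts and total.  Stop codons are counted (see
    :attr:`FeatureCounts.sense_codon_total` for the sense-only total).
    """
    bad = set(nt_seq) - set("ACGTN")
    if bad:
        raise DataError(f"invalid nucleotide character(s) {sorted(bad)}")
    counts: dict[str, int] = {}
    total = 0
    for i in range(0, len(nt_seq) - len(nt_seq) % 3, 3):
        codon = nt_seq[i:i + 3]
        if "N" in codon:
            continue
        counts[codon] = counts.get(codon, 0) + 1
        total += 1
    return counts, total


def gc_fraction(nt_counts: dict[str, int]) -> float:
    """G+C percentage of counted bases; undefined on an empty count map."""
    total = sum(nt_counts.get(b, 0) for b in NT4)
    if total == 0:
        raise UndefinedScoreError("GC content undefined: no counted bases")
    gc = nt_counts.get("G", 0) + nt_counts.get("C", 0)
    return 100.0 * gc / total


def compute_counts(record: "SequenceRecord") -> FeatureCounts:
    aa_counts, aa_total = count_amino_acids(record.aa_seq)
    nt_counts, nt_total = count_nucleotides(record.nt_seq)
    codon_counts, codon_total = count_codons(record.nt_seq)
    return FeatureCounts(aa_counts, aa_total, nt_counts, nt_total,
                         codon_counts, codon_total)


def get_counts(dataset: "Dataset", record: "SequenceRecord") -> FeatureCounts:
    """Cached per-sequence counts, filled lazily on the dataset."""
    fc = dataset.counts.get(record.key)
    if fc is None:
        fc = compute_counts(record)
        dataset.counts[record.key] = fc
    return fc


# ---------------------------------------------------------------------------
# CDS / protein consistency
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    """Outcome of translating a CDS and comparing it to the stored protein."""

    status: str                       # "consistent" | "mismatch" | "skipped"
    mismatches: list[tuple[int, str, str]]   # (1-based position, aa_seq, translated)
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "consistent"


def verify_cds_consistency(record: "SequenceRecord") -> ConsistencyReport:
    """Translate the CDS with the standard genetic code and compare.

    A terminal stop codon is ignored.  Mismatches are reported as warnings in
    the returned report, never raised: real ortholog data contains
    exceptions (alternative starts, selenocysteine, annotation slips).
    """
    if not record.nt_seq:
        return ConsistencyReport("skipped", [], "no CDS stored")
    usable = record.nt_seq[:len(record.nt_seq) - len(record.nt_seq) % 3]
    translated = "".join(
        CODON_TO_AA.get(usable[i:i + 3], "X") for i in range(0, len(usable), 3))
    if translated.endswith("*"):
        translated = translated[:-1]
    aa = record.aa_seq
    if aa.endswith("*"):
        aa = aa[:-1]
    mismatches: list[tuple[int, str, str]] = []
    for i in range(max(len(aa), len(translated))):
        a = aa[i] if i < len(aa) else "-"
        t = translated[i] if i < len(translated) else "-"
        if a != t:
            mismatches.append((i + 1, a, t))
    if mismatches:
        return ConsistencyReport("mismatch", mismatches,
                                 f"{len(mismatches)} mismatching position(s)")
    return ConsistencyReport("consistent", [])


# ---------------------------------------------------------------------------
# On-disk count cache (one TSV row per sequence)
# ---------------------------------------------------------------------------

_CACHE_COLUMNS = (["organism_id", "protein_gi", "aa_total", "nt_total", "codon_total"]
                  + [f"aa_{a}" for a in AA20] + [f"nt_{b}" for b in NT4]
                  + [f"codon_{c}" for c in CODONS])


def write_counts_cache(dataset: "Dataset", path: str | Path) -> None:
    """Persist per-sequence counts as a TSV sidecar."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CACHE_COLUMNS)
        for rec in sorted(dataset.sequences, key=lambda r: r.key):
            fc = get_counts(dataset, rec)
            row = [rec.organism_id, rec.protein_gi,
                   fc.aa_total, fc.nt_total, fc.codon_total]
            row += [fc.aa_counts.get(a, 0) for a in AA20]
            row += [fc.nt_counts.get(b, 0) for b in NT4]
            row += [fc.codon_counts.get(c, 0) for c in CODONS]
            writer.writerow(row)


def load_counts_cache(dataset: "Dataset", path: str | Path) -> int:
    """Load a count cache written by :func:`write_counts_cache`.

    Rows for sequences absent from the dataset are ignored.  Returns the
    number of cache entries attached.
    """
    n = 0
    keys = {rec.key for rec in dataset.sequences}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _CACHE_COLUMNS:
            raise DataError(f"{path}: not a counts cache (unexpected columns)")
        for row in reader:
            key = (row["organism_id"], row["protein_gi"])
            if key not in keys:
                continue
            fc = FeatureCounts(
                aa_counts={a: int(row[f"aa_{a}"]) for a in AA20 if int(row[f"aa_{a}"])},
                aa_total=int(row["aa_total"]),
                nt_counts={b: int(row[f"nt_{b}"]) for b in NT4 if int(row[f"nt_{b}"])},
                nt_total=int(row["nt_total"]),
                codon_counts={c: int(row[f"codon_{c}"]) for c in CODONS
                              if int(row[f"codon_{c}"])},
                codon_total=int(row["codon_total"]),
            )
            dataset.counts[key] = fc
            n += 1
    return n
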