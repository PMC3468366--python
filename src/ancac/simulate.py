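"""Synthetic ortholog datasets with controllable composition structure.

The generator emits complete fixture bundles — dataset XML, taxonomy TSV,
trait TSV and a ground-truth table — whose composition biases are known by
construction, so every scoring operation and analysis recipe can be exercised
offline and checked against the generating parameters:

* proteins are drawn residue-by-residue from a background amino-acid
  distribution, optionally enriched (or depleted) for chosen feature sets in
  designated COGs;
* each protein is back-translated by sampling synonymous codons from a
  per-organism distribution tilted to hit a target GC fraction, with the
  AGR share of arginine codons (AGA+AGG among the six) pinned separately
  when requested;
* optimum growth temperatures are drawn per organism, and the AGR target
  and/or the (E+K)/(Q+H) ratio can be tied to OGT through a linear model
  with Gaussian noise — the signal the thermophily regressions recover.

Everything is driven by one seeded generator with a fixed draw order
(organisms, then COGs, then positions), so equal seeds give byte-identical
fixture files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .dataio import (CogRecord, Dataset, OrganismRecord, RANKS, SequenceRecord,
                     write_nucocog_xml)
from .errors import DataError, SimulationError
from .features import AA20, AA_TO_CODONS, AGR_CODONS, STOP_CODONS

#: Background amino-acid frequencies, an average microbial proteome
#: composition (normalized on use).
BACKGROUND_AA_FREQS: dict[str, float] = {
    "A": 0.078, "R": 0.054, "N": 0.041, "D": 0.054, "C": 0.014,
    "Q": 0.039, "E": 0.063, "G": 0.072, "H": 0.022, "I": 0.057,
    "L": 0.096, "K": 0.058, "M": 0.024, "F": 0.040, "P": 0.048,
    "S": 0.062, "T": 0.054, "W": 0.011, "Y": 0.032, "V": 0.069,
}

_AA_LIST = list(AA20)
_AA_INDEX = {a: i for i, a in enumerate(_AA_LIST)}
_GC_COUNT = {codon: codon.count("G") + codon.count("C")
             for codons in AA_TO_CODONS.values() for codon in codons}


@dataclass(frozen=True)
class Enrichment:
    """Multiply the frequency of a feature set in designated COGs.

    ``factor`` above 1 enriches, below 1 depletes; the remaining frequencies
    are renormalized.
    """

    cog_ids: tuple[str, ...]
    features: frozenset[str]
    factor: float


@dataclass(frozen=True)
class BiasSpec:
    """Full specification of one synthetic dataset."""

    n_organisms: int = 20
    n_cogs: int = 100
    seq_len_codons: int = 300
    background_aa_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(BACKGROUND_AA_FREQS))
    enriched: tuple[Enrichment, ...] = ()
    per_organism_gc: Mapping[str, float] | float | None = 0.5
    per_organism_agr: Mapping[str, float] | float | None = None
    ogt_model: tuple[float, float, float] | None = None      # AGR = a*OGT + b + N(0, s)
    ekqh_ogt_model: tuple[float, float, float] | None = None  # ratio = a*OGT + b + N(0, s)
    ogt_range: tuple[float, float] = (25.0, 65.0)
    oxygen_cycle: tuple[str, ...] = ("aerobe", "anaerobe")
    source: str = "cog"
    seed: int = 0

    def validate(self) -> None:
        if self.n_organisms < 1 or self.n_cogs < 1:
            raise SimulationError("need at least one organism and one COG")
        if self.seq_len_codons < 10:
            raise SimulationError("seq_len_codons must be >= 10")
        freqs = dict(self.background_aa_freqs)
        if set(freqs) != set(AA20):
            raise SimulationError("background_aa_freqs must cover exactly the 20 amino acids")
        if any(f < 0 for f in freqs.values()) or sum(freqs.values()) <= 0:
            raise SimulationError("background_aa_freqs must be non-negative and sum > 0")
        for enr in self.enriched:
            if enr.factor <= 0:
                raise SimulationError("enrichment factor must be > 0")
            if not enr.features <= set(AA20):
                raise SimulationError(f"enrichment features {sorted(enr.features)} invalid")


def organism_id(i: int) -> str:
    return f"org{i + 1:03d}"


def cog_id(j: int) -> str:
    return f"COG{j + 1:04d}"


# ---------------------------------------------------------------------------
# Codon distributions: GC tilt + AGR pinning
# ---------------------------------------------------------------------------

def _tilted(codons: Sequence[str], beta: float) -> np.ndarray:
    w = np.array([np.exp(beta * _GC_COUNT[c]) for c in codons])
    return w / w.sum()


def _codon_dists(beta: float, agr_target: float | None) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    """Per-symbol synonymous-codon distributions at GC tilt ``beta``.

    Symbols are the 20 amino acids plus ``*`` for the stop position.  When an
    AGR target is given, arginine's AGR pair carries exactly that probability
    mass, split within each block by the same GC tilt.
    """
    dists: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for sym, codons in AA_TO_CODONS.items():
        if sym == "R" and agr_target is not None:
            cgn = tuple(c for c in codons if c not in AGR_CODONS)
            p = np.concatenate([(1.0 - agr_target) * _tilted(cgn, beta),
                                agr_target * _tilted(AGR_CODONS, beta)])
            dists[sym] = (cgn + AGR_CODONS, p)
        else:
            dists[sym] = (codons, _tilted(codons, beta))
    return dists


def _expected_gc(beta: float, sym_weights: Mapping[str, float],
                 agr_target: float | None) -> float:
    dists = _codon_dists(beta, agr_target)
    gc = 0.0
    for sym, w in sym_weights.items():
        codons, p = dists[sym]
        gc += w * float(np.dot(p, [_GC_COUNT[c] for c in codons])) / 3.0
    return gc


def solve_codon_dists(aa_freqs: np.ndarray, gc_target: float | None,
                      agr_target: float | None, stop_weight: float,
                      who: str = "organism") -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    """Find the GC tilt whose expected coding GC hits the target.

    The expectation mixes the amino-acid distribution with one stop codon per
    sequence (``stop_weight``).  The tilt is solved by bisection; a target
    outside the achievable range raises :class:`SimulationError`.
    """
    if gc_target is None:
        return _codon_dists(0.0, agr_target)
    weights = {a: float(aa_freqs[_AA_INDEX[a]]) * (1.0 - stop_weight) for a in AA20}
    weights["*"] = stop_weight
    lo, hi = -40.0, 40.0
    g_lo, g_hi = _expected_gc(lo, weights, agr_target), _expected_gc(hi, weights, agr_target)
    if not (g_lo <= gc_target <= g_hi):
        raise SimulationError(
            f"{who}: GC target {gc_target:.4f} infeasible "
            f"(achievable range {g_lo:.4f}..{g_hi:.4f} with AGR={agr_target})")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _expected_gc(mid, weights, agr_target) < gc_target:
            lo = mid
        else:
            hi = mid
    return _codon_dists(0.5 * (lo + hi), agr_target)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _resolve(value, org: str, default=None):
    if value is None:
        return default
    if isinstance(value, Mapping):
        return value.get(org, default)
    return float(value)


def _aa_vector(freqs: Mapping[str, float]) -> np.ndarray:
    v = np.array([freqs[a] for a in _AA_LIST], dtype=float)
    return v / v.sum()


def _adjust_ekqh(v: np.ndarray, target_ratio: float) -> np.ndarray:
    """Scale E,K vs Q,H so the pooled (E+K)/(Q+H) expectation hits the target."""
    v = v.copy()
    ek = v[_AA_INDEX["E"]] + v[_AA_INDEX["K"]]
    qh = v[_AA_INDEX["Q"]] + v[_AA_INDEX["H"]]
    alpha = target_ratio * qh / ek
    for a in "EK":
        v[_AA_INDEX[a]] *= alpha
    return v / v.sum()


def _lineage(i: int, n: int) -> dict[str, str]:
    kingdom = "Archaea" if i < n // 2 else "Bacteria"
    return {
        "superkingdom": kingdom,
        "phylum": f"{kingdom[:4]}phylum{i % 4 + 1}",
        "class": f"Class{i % 4 + 1}",
        "order": f"Order{i % 8 + 1}",
        "family": f"Family{i % 8 + 1}",
        "genus": f"Genus{i + 1:03d}",
        "species": f"Genus{i + 1:03d} synthetica",
    }


def generate_dataset(spec: BiasSpec) -> tuple[Dataset, dict]:
    """Generate a dataset and its ground-truth tables from a :class:`BiasSpec`.

    Returns ``(dataset, ground_truth)`` where ``ground_truth`` holds the
    per-organism targets (``organisms``: list of dicts) and the enrichment
    roster (``enrichments``).  The dataset comes with taxonomy and traits
    already attached.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ds = Dataset(source=spec.source, has_taxonomy=True, has_traits=True)

    background = _aa_vector(spec.background_aa_freqs)
    enrich_by_cog: dict[str, Enrichment] = {}
    for enr in spec.enriched:
        for cid in enr.cog_ids:
            enrich_by_cog[cid] = enr

    stop_weight = 1.0 / (spec.seq_len_codons + 1)
    gt_orgs: list[dict] = []
    org_aa: dict[str, np.ndarray] = {}
    org_dists: dict[str, dict] = {}

    for i in range(spec.n_organisms):
        oid = organism_id(i)
        oxygen = spec.oxygen_cycle[i % len(spec.oxygen_cycle)]
        ogt = float(rng.uniform(*spec.ogt_range))
        agr_t = _resolve(spec.per_organism_agr, oid)
        if spec.ogt_model is not None:
            a, b, s = spec.ogt_model
            agr_t = float(np.clip(a * ogt + b + rng.normal(0.0, s), 0.02, 0.98))
        ekqh_t = None
        v = background
        if spec.ekqh_ogt_model is not None:
            a, b, s = spec.ekqh_ogt_model
            ekqh_t = float(max(0.1, a * ogt + b + rng.normal(0.0, s)))
            v = _adjust_ekqh(background, ekqh_t)
        gc_t = _resolve(spec.per_organism_gc, oid)
        org_aa[oid] = v
        org_dists[oid] = solve_codon_dists(v, gc_t, agr_t, stop_weight, who=oid)
        ds.organisms[oid] = OrganismRecord(
            oid, f"Synthetic organism {i + 1}", _lineage(i, spec.n_organisms),
            oxygen, ogt)
        gt_orgs.append({"organism_id": oid, "oxygen_class": oxygen,
                        "ogt": ogt, "gc_target": gc_t, "agr_target": agr_t,
                        "ekqh_target": ekqh_t})

    for j in range(spec.n_cogs):
        cid = cog_id(j)
        ds.cogs[cid] = CogRecord(cid, f"synthetic ortholog group {j + 1}")

    lo = int(round(0.9 * spec.seq_len_codons))
    hi = int(round(1.1 * spec.seq_len_codons))
    gi = 0
    for i in range(spec.n_organisms):
        oid = organism_id(i)
        dists = org_dists[oid]
        base_v = org_aa[oid]
        for j in range(spec.n_cogs):
            cid = cog_id(j)
            v = base_v
            enr = enrich_by_cog.get(cid)
            if enr is not None:
                v = base_v.copy()
                for a in enr.features:
                    v[_AA_INDEX[a]] *= enr.factor
                v = v / v.sum()
            length = int(rng.integers(lo, hi + 1))
            aa_idx = rng.choice(20, size=length, p=v)
            codons = np.empty(length, dtype=object)
            for k in np.unique(aa_idx):
                sym = _AA_LIST[k]
                cods, p = dists[sym]
                mask = aa_idx == k
                picks = rng.choice(len(cods), size=int(mask.sum()), p=p)
                codons[mask] = np.array(cods, dtype=object)[picks]
            stops, p_stop = dists["*"]
            stop = stops[int(rng.choice(len(stops), p=p_stop))]
            aa_seq = "".join(_AA_LIST[k] for k in aa_idx)
            nt_seq = "".join(codons.tolist()) + stop
            gi += 1
            ds.add_sequence(SequenceRecord(oid, cid, f"{900000 + gi}",
                                           f"{800000 + gi}", aa_seq, nt_seq))
    ds.validate()
    ground_truth = {
        "organisms": gt_orgs,
        "enrichments": [{"cog_ids": list(e.cog_ids),
                         "features": "".join(sorted(e.features)),
                         "factor": e.factor} for e in spec.enriched],
    }
    return ds, ground_truth


# ---------------------------------------------------------------------------
# Fixture bundles on disk
# ---------------------------------------------------------------------------

def write_fixture_bundle(dataset: Dataset, ground_truth: dict,
                         out_dir: str | Path) -> list[Path]:
    """Write dataset XML + taxonomy/trait/ground-truth TSVs; return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    xml_path = out_dir / "dataset.xml"
    write_nucocog_xml(dataset, xml_path)

    tax_path = out_dir / "taxonomy.tsv"
    with open(tax_path, "w") as fh:
        fh.write("organism_id\t" + "\t".join(RANKS) + "\n")
        for oid in sorted(dataset.organisms):
            lineage = dataset.organisms[oid].lineage
            fh.write(oid + "\t" + "\t".join(lineage.get(r, "") for r in RANKS) + "\n")

    trait_path = out_dir / "traits.tsv"
    with open(trait_path, "w") as fh:
        fh.write("organism_id\toxygen_class\togt\n")
        for oid in sorted(dataset.organisms):
            org = dataset.organisms[oid]
            ogt = "" if org.ogt_celsius is None else f"{org.ogt_celsius:.4f}"
            fh.write(f"{oid}\t{org.oxygen_class}\t{ogt}\n")

    gt_path = out_dir / "ground_truth.tsv"
    with open(gt_path, "w") as fh:
        for enr in ground_truth.get("enrichments", []):
            fh.write(f"# enrichment\tfeatures={enr['features']}\tfactor={enr['factor']:g}"
                     f"\tcogs={','.join(enr['cog_ids'])}\n")
        cols = ["organism_id", "oxygen_class", "ogt", "gc_target", "agr_target",
                "ekqh_target"]
        fh.write("\t".join(cols) + "\n")
        for row in ground_truth.get("organisms", []):
            cells = []
            for c in cols:
                val = row.get(c)
                cells.append("" if val is None
                             else f"{val:.6f}" if isinstance(val, float) else str(val))
            fh.write("\t".join(cells) + "\n")
    return [xml_path, tax_path, trait_path, gt_path]


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------

def ribosomal_bias_spec(seed: int = 0) -> BiasSpec:
    """20 organisms × 100 COGs × ~300 codons; 5 COGs with K/R/H enriched 1.5×.

    The analogue of ranking COGs by positively charged residues: the five
    designated COGs play the role of ribosomal-protein clusters.
    """
    return BiasSpec(
        enriched=(Enrichment(tuple(cog_id(j) for j in range(5)),
                             frozenset("KRH"), 1.5),),
        seed=seed)


def cognate_bias_spec(seed: int = 0, depletion: float = 0.7
                      ) -> tuple[BiasSpec, dict[str, list[str]]]:
    """A cognate-bias dataset plus its amino-acid → pathway-COG map.

    Three amino acids (K, L, E) each own ten designated "biosynthesis" COGs
    in which their frequency is multiplied by ``depletion``; sequences are
    ~500 codons so per-species sampling noise stays small.  ``depletion=1``
    yields the unbiased control.
    """
    mapping = {"K": [cog_id(j) for j in range(0, 10)],
               "L": [cog_id(j) for j in range(10, 20)],
               "E": [cog_id(j) for j in range(20, 30)]}
    enriched = tuple(Enrichment(tuple(cogs), frozenset(aa), depletion)
                     for aa, cogs in sorted(mapping.items())) if depletion != 1.0 else ()
    return BiasSpec(seq_len_codons=500, enriched=enriched, seed=seed), mapping


def ogt_codon_spec(seed: int = 0, n_organisms: int = 40, slope: float = 0.02,
                   intercept: float = -0.4, sigma: float = 0.05) -> BiasSpec:
    """Organisms whose AGR fraction follows ``slope·OGT + intercept`` + noise.

    OGTs span 25–65 °C; with the defaults the noiseless AGR fraction runs
    from 0.10 to 0.90, comfortably inside the feasible range.
    """
    return BiasSpec(n_organisms=n_organisms, n_cogs=60,
                    ogt_model=(slope, intercept, sigma), seed=seed)


def gc_trait_spec(seed: int = 0, gc_aerobe: float = 0.5394,
                  gc_anaerobe: float = 0.4478) -> BiasSpec:
    """Aerobes and anaerobes generated at distinct coding GC targets."""
    gc = {organism_id(i): (gc_aerobe if i % 2 == 0 else gc_anaerobe)
          for i in range(20)}
    return BiasSpec(n_cogs=60, per_organism_gc=gc, seed=seed)


# ---------------------------------------------------------------------------
# YAML front-end (for the CLI)
# ---------------------------------------------------------------------------

def spec_from_yaml(path: str | Path) -> BiasSpec:
    """Load a :class:`BiasSpec` from a YAML file.

    Scalars map 1:1 onto the dataclass fields; ``enriched`` entries are
    mappings with ``cogs`` (list), ``features`` (string of one-letter codes)
    and ``factor``; the three ``*_model`` entries are ``[slope, intercept,
    sigma]`` lists.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise DataError(f"{path}: spec file must be a mapping")
    known = set(BiasSpec.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise DataError(f"{path}: unknown spec key(s) {sorted(unknown)}")
    kwargs = dict(raw)
    if "enriched" in kwargs:
        entries = []
        for item in kwargs["enriched"]:
            entries.append(Enrichment(tuple(item["cogs"]),
                                      frozenset(str(item["features"])),
                                      float(item["factor"])))
        kwargs["enriched"] = tuple(entries)
    for key in ("ogt_model", "ekqh_ogt_model", "ogt_range", "oxygen_cycle"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return BiasSpec(**kwargs)
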