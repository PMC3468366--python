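# Methods

## The scoring model

The engine treats every sequence as a bag of pre-computed feature counts.
For one member sequence the stored quantities are the counts of the 20
amino acids, the 4 nucleotides and the 64 frame-0 codons, together with the
usable total per feature type.  All scoring sums these integers over the
scope and only then divides:

    APSF(scope, F) = 100 · Σ_s Σ_{f∈F} count_f(s) / Σ_s total(s)

This pooled form is length-weighted: a 1000-residue member influences a
COG's percentage ten times more than a 100-residue one.  The alternative —
the unweighted mean of per-sequence percentages — is exposed as
`mean_of_sequences=True` (`--mean-of-sequences`) for sensitivity checks but
is not the default, because summing stored counts and lengths is the
definition the pooled statistic follows.

Frequency scores divide a scope's APSF by a reference APSF computed the same
way over either (i) every sequence of the dataset or (ii) all sequences of
the selected organisms across all COGs.  The reference is global: it does
not change per COG or per taxon subgroup, so per-species scores in a
subgrouped query are all comparable against one denominator.  A reference of
exactly zero (possible only on degenerate synthetic input) is an error, not
an infinite score.

Ranking sorts by score descending with ties broken by COG id ascending (then
subgroup name).  The tie-break is a repository convention chosen so that
repeated runs produce byte-identical tables.

## Counting rules and degenerate inputs

* Amino acids: `X` and `*` contribute to neither the counts nor the residue
  total.  Nucleotides: `N` is excluded likewise.  Codons: the CDS is read in
  consecutive frame-0 triplets, a trailing partial triplet is dropped, and
  any triplet containing `N` is excluded from counts and total.  Excluding
  ambiguity codes from numerator *and* denominator keeps percentages
  interpretable, but means heavily ambiguous data yield smaller totals; the
  per-query `n_skipped` tally makes the effect visible.
* Stop codons are counted in the per-sequence codon table, but codon-type
  queries use the *sense-codon* total by default, excluding stops from both
  numerator and denominator (`include_stops=True` restores all-triplet
  semantics).  Coding-usage questions — e.g. the arginine AGR share — are
  about sense codons; selecting a stop codon as a feature without the flag
  is rejected rather than silently diluted.
* Records without a CDS are legal (protein-only); nucleotide and codon
  queries skip them and report the skip count.  A scope whose every record
  is skipped has no defined score and raises rather than returning 0.
* RNA `U` is normalized to `T` and sequences are uppercased on read, so all
  downstream counting works over one alphabet.

## Selections

Selections are organism sets with provenance.  Taxon selection matches one
lineage rank case-insensitively against a flat seven-rank table
(superkingdom … species) supplied as TSV — deliberately not the NCBI
`nodes.dmp`/`names.dmp` pair, which would drag in a large parsing dependency
for no analytical gain.  Trait patterns: `aerobia` = strict aerobes,
`anaerobia` = strict anaerobes; facultative and unknown organisms belong to
*neither*, so the two groups are disjoint and a GC comparison between them
is not blurred by ambiguous physiology (edit the trait table to override).
Combining successive criteria takes the set union by default — consecutive
selections grow a superset — with `--combine intersect` for conjunctive
queries.

## The XML dialect

The original nucleotide-containing COG files ship no public schema, so the
reader/writer here define a minimal artifact dialect:

    <dataset source="cog|arcog|combined">
      <organism id="..." name="..."/>
      <cog id="COG####" desc="...">
        <seq org="..." protein_gi="..." gene_gi="...">
          <aa>...</aa><nt>...</nt>
        </seq>
      </cog>
    </dataset>

Unknown attributes are ignored on read so enriched files stay loadable.
Lineages and traits intentionally live in side tables (taxonomy TSV, trait
TSV), not in the XML; dataset equality and the write→parse round-trip are
defined over the XML-carried content.  A per-COG FASTA fallback
(`<COG>.faa`/`<COG>.fna`, headers `organism|protein_gi|gene_gi`, plus an
organism manifest) yields the same in-memory dataset.  The member-listing
TSV's `domain` column carries the COG functional description, since the
model stores no separate per-protein domain name.

## The synthetic-data generator

The generator emulates an ortholog collection with known composition
structure; it is the ground truth against which the analyses are validated.

* **Proteins** are drawn residue-by-residue from a background amino-acid
  distribution (an average microbial proteome composition).  Per-COG
  enrichment multiplies the chosen features' frequencies by a factor and
  renormalizes — factor 1.5 on {K,R,H} mimics ribosomal-protein clusters,
  factor 0.7 on one amino acid in its "pathway" COGs mimics cognate bias.
  Sequence lengths jitter uniformly ±10% around the nominal codon count.
* **Back-translation** samples synonymous codons per residue from a
  per-organism distribution tilted by exp(β·GC(codon)); β is solved by
  bisection so the *expected* coding GC (including the appended stop codon,
  weighted 1/(L+1)) hits the organism's target.  When an AGR target is set,
  the AGA+AGG pair carries exactly that probability mass within arginine,
  split inside each block by the same tilt, and the bisection accounts for
  it.  Targets outside the achievable GC range (about 0.29–0.67 under the
  default composition) raise an error naming the organism.  Exact joint
  multi-constraint optimization is out of scope; the greedy
  GC-first/AGR-within-arginine scheme hits both targets to within binomial
  sampling error, which is what the tolerance checks assert.
* **Physiology**: oxygen classes cycle aerobe/anaerobe by default; OGTs are
  uniform on 25–65 °C.  Linear models with Gaussian noise can tie the AGR
  target (and, optionally, the (E+K)/(Q+H) ratio via scaling E,K against
  Q,H) to OGT — the signal the regressions recover.  Targets are clipped to
  [0.02, 0.98] to stay feasible.
* **Determinism**: one seeded NumPy generator, draws ordered organisms →
  COGs → positions; equal seeds give byte-identical fixture bundles
  (dataset XML + taxonomy TSV + traits TSV + ground-truth TSV).

What the generator does *not* emulate: phylogenetic correlation between
organisms, genuine functional classes, variable COG occupancy, ambiguity
characters, annotation errors, or amino-acid composition differences beyond
those planted.  Passing tests therefore demonstrate that the engine measures
planted biases correctly at realistic scale — not that any biological claim
holds on real data, which requires the external ortholog datasets.

## Study conditions of the validation suite

Chosen once, as the package's standard synthetic conditions:

* *Rank recovery*: 20 organisms × 100 COGs × ~300 codons, 5 COGs enriched
  1.5× for {K,R,H}.  The enriched pooled share (~19%) sits ~12 binomial
  standard deviations above background, so top-5 recovery is essentially
  deterministic.
* *Cognate bias*: same organism/COG grid at ~500 codons; three amino acids
  (K, L, E) each own ten pathway COGs depleted to 0.7×.  At these sizes the
  per-species-cell sampling s.d. is ≈0.05 and the s.d. of the grand mean
  ≈0.01, well inside the assertion bands (0.65–0.75 depleted, 0.97–1.03
  control).  The expected depleted mean is slightly above 0.7 (≈0.73)
  because depletion renormalizes the remaining frequencies upward and the
  depleted COGs also lower the global reference.
* *AGR regression*: 40 organisms × 60 COGs, AGR fraction = 0.02·OGT − 0.4 +
  N(0, 0.05).  The fitted slope's standard error is ≈7·10⁻⁴, so the
  3-standard-error recovery check is comfortably discriminating.
* *GC by oxygen class*: 20 organisms × 60 COGs, aerobes generated at 53.94%
  and anaerobes at 44.78% coding GC.  Pooled estimates land within ~0.1
  percentage point.

The shipped cognate map preset is illustrative scaffolding for the synthetic
pathway COGs; real analyses should supply a curated amino-acid →
biosynthesis-COG table via `--map`, since no canonical assignment ships with
the package.

## Limitations

* Standard genetic code only; no alternative codes, no ORF search (frame 0
  of the stored CDS is trusted).
* Whether historical implementations counted ambiguous characters in the
  stored sequence lengths is unknowable from the outside; the exclusion
  policy here is documented above and applied consistently.
* Rankings carry no significance statistics: scores are descriptive
  ratios, and differences between them are not tested.
* The GC comparison and both OGT regressions are only as meaningful as the
  supplied trait table; the package ships no curated physiology data.
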