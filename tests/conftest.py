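"""Shared fixtures: a hand-countable toy dataset, a six-organism dataset with
taxonomy and traits for selection tests, and a small generated dataset."""

import pytest

from ancac import (CogRecord, Dataset, OrganismRecord, SequenceRecord,
                   generate_dataset)
from ancac.simulate import BiasSpec

TOY_XML = """\
<dataset source="cog">
  <organism id="eco" name="Escherichia coli" />
  <organism id="mja" name="Methanocaldococcus jannaschii" />
  <cog id="COG0001" desc="ribosomal protein">
    <seq org="eco" protein_gi="101" gene_gi="201">
      <aa>MK</aa>
      <nt>ATGAAATAA</nt>
    </seq>
    <seq org="mja" protein_gi="102" gene_gi="202">
      <aa>MKK</aa>
      <nt>ATGAAAAAGTAA</nt>
    </seq>
  </cog>
  <cog id="COG0002" desc="hypothetical enzyme">
    <seq org="eco" protein_gi="103" gene_gi="203">
      <aa>MR</aa>
      <nt>ATGCGT</nt>
    </seq>
    <seq org="mja" protein_gi="104" gene_gi="204">
      <aa>MV</aa>
      <nt>ATGGTT</nt>
    </seq>
  </cog>
</dataset>
"""


@pytest.fixture
def toy_xml_path(tmp_path):
    path = tmp_path / "toy.xml"
    path.write_text(TOY_XML)
    return path


@pytest.fixture
def toy_dataset(toy_xml_path):
    from ancac import parse_nucocog_xml
    return parse_nucocog_xml(toy_xml_path)


def make_dataset(aa_seqs, nt_seqs=None, cog_id="COG0001", organism_prefix="org"):
    """One-COG dataset from bare sequences, one organism per sequence."""
    ds = Dataset()
    ds.cogs[cog_id] = CogRecord(cog_id, "test")
    for i, aa in enumerate(aa_seqs):
        oid = f"{organism_prefix}{i + 1}"
        ds.organisms.setdefault(oid, OrganismRecord(oid, oid))
        nt = nt_seqs[i] if nt_seqs else ""
        ds.add_sequence(SequenceRecord(oid, cog_id, f"p{i + 1}", f"g{i + 1}", aa, nt))
    return ds


@pytest.fixture
def mini_dataset():
    """Six organisms with taxonomy and traits; three COGs of varying coverage.

    org1-org3 are Archaea, org4-org6 Bacteria; traits: three aerobes
    (org1, org2, org6), one anaerobe (org3), one facultative (org4), one
    unknown (org5).  COG0001 spans org1-org5, COG0002 all six, COG0003 only
    org1.
    """
    ds = Dataset()
    ogts = {"org1": 85.0, "org2": 30.0, "org3": 95.0, "org4": 37.0,
            "org5": None, "org6": 25.0}
    oxygen = {"org1": "aerobe", "org2": "aerobe", "org3": "anaerobe",
              "org4": "facultative", "org5": "unknown", "org6": "aerobe"}
    for i in range(6):
        oid = f"org{i + 1}"
        kingdom = "Archaea" if i < 3 else "Bacteria"
        lineage = {"superkingdom": kingdom, "phylum": f"Phy{i % 2 + 1}",
                   "genus": f"Genus{i + 1}", "species": f"Genus{i + 1} sp{i + 1}"}
        ds.organisms[oid] = OrganismRecord(oid, f"Organism {i + 1}", lineage,
                                           oxygen[oid], ogts[oid])
    ds.has_taxonomy = ds.has_traits = True
    members = {"COG0001": ["org1", "org2", "org3", "org4", "org5"],
               "COG0002": ["org1", "org2", "org3", "org4", "org5", "org6"],
               "COG0003": ["org1"]}
    gi = 0
    for cog_id, orgs in members.items():
        ds.cogs[cog_id] = CogRecord(cog_id, f"fixture {cog_id}")
        for oid in orgs:
            gi += 1
            ds.add_sequence(SequenceRecord(oid, cog_id, f"p{gi}", f"g{gi}",
                                           "MKRV", "ATGAAACGTGTT"))
    return ds


@pytest.fixture(scope="session")
def small_synth():
    """A small generated dataset shared across property tests."""
    spec = BiasSpec(n_organisms=6, n_cogs=10, seq_len_codons=60, seed=42)
    ds, gt = generate_dataset(spec)
    return ds
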