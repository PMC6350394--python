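import pytest

from begenomics.genome_io import CdsFeature, ChromosomeRecord


def make_genbank(
    sequence: str,
    locus: str = "TESTLOC",
    cds: list[tuple[str, list[str]]] | None = None,
    topology: str = "linear",
) -> str:
    """Hand-assemble a minimal GenBank flat file for parser tests.

    ``cds`` is a list of (location string, qualifier lines), e.g.
    ``[("complement(join(10..21,30..41))", ['/product="x"'])]``.
    """
    lines = [
        f"LOCUS       {locus}             {len(sequence)} bp    DNA     "
        f"{topology}   BCT 01-JAN-2000",
        f"DEFINITION  Testibacter exemplaris {locus}.",
        f"ACCESSION   {locus}",
        f"VERSION     {locus}.1",
        "SOURCE      Testibacter exemplaris",
        "  ORGANISM  Testibacter exemplaris",
        "            Bacteria.",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(sequence)}",
        '                     /organism="Testibacter exemplaris"',
        '                     /mol_type="genomic DNA"',
    ]
    for location, quals in cds or []:
        lines.append(f"     CDS             {location}")
        lines.extend(f"                     {q}" for q in quals)
    lines.append("ORIGIN")
    for i in range(0, len(sequence), 60):
        chunk = sequence[i : i + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks.lower()}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def simple_record() -> ChromosomeRecord:
    """60 bp record with one forward CDS spanning the whole sequence."""
    seq = "ATGTTCTTTAACTACTATATCATTAACAATGGCGGCGGCGGCGGCGGCGGCGGCGGGTAA"
    return ChromosomeRecord(
        accession="TEST_0001",
        organism="Testibacter exemplaris",
        sequence=seq,
        cds_list=[CdsFeature(start=1, end=60, strand="+", product="hypothetical protein")],
    )
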