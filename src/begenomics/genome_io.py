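"""Reading annotated chromosome records and assigning comparison groups.

GenBank flat files are the interchange format: each LOCUS becomes one
:class:`ChromosomeRecord` carrying the upper-cased nucleotide sequence and an
ordered list of CDS features with strand, joined location parts, product
annotation, ``codon_start`` and the pseudo-gene flag.  Coordinates are 1-based
inclusive throughout, following the GenBank convention.

Organisms with several replicons are reduced to a single representative, the
largest non-plasmid replicon, and every organism is assigned to the
"Common BE" or "Other" comparison group from a genus-level grouping table
(publication counts from the built-environment literature survey).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, UndefinedSequenceError
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

COMMON_BE = "Common BE"
OTHER = "Other"

#: default publication-count threshold for calling a genus "Common BE"
DEFAULT_THRESHOLD = 6

_COMPLEMENT = str.maketrans("ACGTRYKMBDHVN", "TGCAYRMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CdsFeature:
    """One protein-coding feature on a chromosome (1-based inclusive coords)."""

    start: int
    end: int
    strand: str  # "+" or "-"
    product: str = ""
    codon_start: int = 1
    pseudo: bool = False
    #: (start, end) pairs in ascending genomic order for joined locations
    location_parts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.location_parts:
            self.location_parts = [(self.start, self.end)]
        for s, e in self.location_parts:
            if s > e:
                raise ValueError(f"CDS part start {s} > end {e}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.codon_start not in (1, 2, 3):
            raise ValueError(f"codon_start must be 1, 2 or 3, got {self.codon_start}")

    def extract(self, sequence: str) -> str:
        """Strand-resolved coding sequence with ``codon_start`` applied.

        Parts are concatenated in genomic order; minus-strand features are
        reverse-complemented afterwards, which matches the GenBank
        ``complement(join(...))`` semantics.
        """
        s = "".join(sequence[a - 1 : b] for a, b in self.location_parts)
        if self.strand == "-":
            s = reverse_complement(s)
        return s[self.codon_start - 1 :]


@dataclass
class ChromosomeRecord:
    """One replicon: sequence plus CDS annotations."""

    accession: str
    organism: str
    sequence: str
    cds_list: list[CdsFeature] = field(default_factory=list)
    circular: bool = False
    is_plasmid: bool = False
    genus_override: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def genus(self) -> str:
        if self.genus_override:
            return self.genus_override
        genus = self.organism.split()[0] if self.organism.split() else ""
        if not genus:
            raise ValueError(f"{self.accession}: cannot derive genus from empty organism name")
        return genus


def read_genbank(path, collect_stats: dict | None = None) -> list[ChromosomeRecord]:
    """Parse a GenBank flat file into :class:`ChromosomeRecord` objects.

    A LOCUS without a readable ORIGIN sequence block is a hard error naming
    the locus.  A CDS feature whose location could not be parsed is skipped
    with a warning; pass ``collect_stats`` (a dict) to receive the count under
    ``"skipped_features"``.
    """
    records: list[ChromosomeRecord] = []
    skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Biopython location warnings handled below
        parsed = list(SeqIO.parse(str(path), "genbank"))
    for rec in parsed:
        try:
            seq = str(rec.seq).upper()
        except UndefinedSequenceError as exc:
            raise ValueError(f"LOCUS {rec.name}: missing sequence (no ORIGIN block)") from exc
        if not seq:
            raise ValueError(f"LOCUS {rec.name}: missing sequence (no ORIGIN block)")
        cds_list: list[CdsFeature] = []
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if feat.location is None:
                logger.warning("%s: skipping CDS with unparseable location", rec.name)
                skipped += 1
                continue
            parts = sorted(
                (int(p.start) + 1, int(p.end)) for p in feat.location.parts
            )
            strand = "-" if feat.location.strand == -1 else "+"
            q = feat.qualifiers
            cds_list.append(
                CdsFeature(
                    start=parts[0][0],
                    end=parts[-1][1],
                    strand=strand,
                    product=q.get("product", [""])[0],
                    codon_start=int(q.get("codon_start", ["1"])[0]),
                    pseudo="pseudo" in q or "pseudogene" in q,
                    location_parts=parts,
                )
            )
        topology = rec.annotations.get("topology", "linear")
        source_org = rec.annotations.get("organism") or rec.description or rec.name
        records.append(
            ChromosomeRecord(
                accession=rec.id if rec.id != "<unknown id>" else rec.name,
                organism=source_org,
                sequence=seq,
                cds_list=cds_list,
                circular=topology == "circular",
                is_plasmid="plasmid" in rec.description.lower(),
            )
        )
    if collect_stats is not None:
        collect_stats["skipped_features"] = collect_stats.get("skipped_features", 0) + skipped
    return records


def write_genbank(records: list[ChromosomeRecord], path) -> None:
    """Serialize records back to a GenBank flat file (round-trip safe)."""
    out = []
    for r in records:
        feats = []
        for c in r.cds_list:
            locs = [SimpleLocation(a - 1, b, strand=(-1 if c.strand == "-" else 1))
                    for a, b in c.location_parts]
            loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
            quals = {"product": [c.product], "codon_start": [str(c.codon_start)]}
            if c.pseudo:
                quals["pseudo"] = [None]
            feats.append(SeqFeature(loc, type="CDS", qualifiers=quals))
        rec = SeqRecord(
            Seq(r.sequence),
            id=r.accession,
            name=r.accession.split(".")[0][:16],
            description=r.organism,
            features=feats,
            annotations={
                "molecule_type": "DNA",
                "topology": "circular" if r.circular else "linear",
                "organism": r.organism,
                "date": "01-JAN-2000",
            },
        )
        out.append(rec)
    SeqIO.write(out, str(path), "genbank")


def select_largest_replicon(records: list[ChromosomeRecord]) -> ChromosomeRecord:
    """Representative replicon of one organism: the largest chromosome.

    Plasmid-annotated replicons are set aside unless nothing else exists.
    Ties on length are broken by lexicographically smallest accession, so the
    choice is order-independent.
    """
    if not records:
        raise ValueError("select_largest_replicon: empty record list")
    pool = [r for r in records if not r.is_plasmid] or list(records)
    return min(pool, key=lambda r: (-r.length, r.accession))


def read_grouping_table(path) -> pd.DataFrame:
    """Read the genus grouping TSV: genus, publication_count, group, env_flags."""
    df = pd.read_csv(path, sep="\t", dtype={"genus": str})
    required = {"genus", "publication_count"}
    if not required.issubset(df.columns):
        raise ValueError(f"grouping table must contain columns {sorted(required)}")
    if df["genus"].duplicated().any():
        dupes = df.loc[df["genus"].duplicated(), "genus"].tolist()
        raise ValueError(f"grouping table has duplicate genera: {dupes}")
    if "env_flags" not in df.columns:
        df["env_flags"] = ""
    df["env_flags"] = df["env_flags"].fillna("")
    return df.set_index("genus")


def parse_env_flags(flags: str) -> set[str]:
    return {f for f in str(flags).split(";") if f}


def assign_groups(
    records: list[ChromosomeRecord],
    grouping: pd.DataFrame,
    threshold: int = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Label each record "Common BE" or "Other" from genus publication counts.

    A genus is "Common BE" when it appears in at least ``threshold`` of the
    surveyed publications.  Genera absent from the table default to "Other"
    with a warning.  Returns the feature-table skeleton (one row per record).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    rows = []
    for r in records:
        genus = r.genus
        if genus in grouping.index:
            count = int(grouping.loc[genus, "publication_count"])
            flags = grouping.loc[genus, "env_flags"]
        else:
            logger.warning("genus %r not in grouping table; defaulting to %s", genus, OTHER)
            count, flags = 0, ""
        rows.append(
            {
                "accession": r.accession,
                "organism": r.organism,
                "genus": genus,
                "publication_count": count,
                "group": COMMON_BE if count >= threshold else OTHER,
                "env_flags": flags,
                "size_bp": r.length,
            }
        )
    return pd.DataFrame(rows)
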