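"""Synthetic chromosomes, annotations and 16S-like alignments with known truth.

The generator emulates exactly the statistical structure the downstream
analyses assume, so every pipeline stage can be exercised with a known
answer and no downloads:

* a circular chromosome with a replication origin and terminus and
  strand-asymmetric G/C composition of tunable strength ``k`` -- on the
  leading-strand arc P(G) = gc/2*(1+k) and P(C) = gc/2*(1-k), reversed on the
  lagging arc, A and T splitting the remainder evenly;
* non-overlapping CDSs on alternating strands, a subset annotated as
  ribosomal proteins (the HEG set), whose Phe/Tyr/Ile/Asn codons are drawn
  with C-ending probability ``p_f = c_f*e^S / (1 - c_f + c_f*e^S)`` where
  S is the spec's ``s_true`` for HEG genes and 0 otherwise;
* sets of aligned sequences diverged from a common ancestor under the K80
  substitution model at a chosen expected pairwise distance.

Bases outside the tracked codon families are i.i.d. -- a deliberate
non-biological simplification sufficient for the statistics under test.
All outputs are deterministic functions of the spec and its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .codon_selection import FAMILIES, CodonFamilyCounts
from .diversity16s import AlignedSet
from .genome_io import CdsFeature, ChromosomeRecord, reverse_complement

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _c_ending_probability(s: float, c: float) -> float:
    es = math.exp(s)
    return c * es / (1.0 - c + c * es)


@dataclass
class GenomeSpec:
    """Ground-truth parameters of one synthetic chromosome."""

    length: int = 2_000_000
    gc: float = 0.5
    skew_strength: float = 0.0  # k in [0, 1]
    ori_pos: float = 0.0
    ter_pos: float = 0.5
    n_heg: int = 20
    n_other: int = 80
    s_true: float = 0.0
    codons_per_family_per_gene: int = 25
    background_c: float = 0.5
    seed: int = 0
    accession: str = ""
    organism: str = "Synthetibacter simulans"

    def __post_init__(self) -> None:
        if not (0.0 <= self.skew_strength <= 1.0):
            raise ValueError("skew_strength must lie in [0, 1]")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must lie in (0, 1)")
        if self.ori_pos == self.ter_pos:
            raise ValueError("ori_pos and ter_pos must differ")
        if not self.accession:
            self.accession = f"SYN_{self.seed:08d}"

    @property
    def gene_length(self) -> int:
        # ATG + family codons + TAA
        return 3 * (2 + 4 * self.codons_per_family_per_gene)


def _background_sequence(spec: GenomeSpec, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. background with strand-dependent G/C composition, as ASCII bytes."""
    gc, k = spec.gc, spec.skew_strength
    at = (1.0 - gc) / 2.0
    # probabilities ordered A, C, G, T
    leading = np.array([at, gc / 2 * (1 - k), gc / 2 * (1 + k), at])
    lagging = np.array([at, gc / 2 * (1 + k), gc / 2 * (1 - k), at])
    ori = int(spec.ori_pos * spec.length) % spec.length
    ter = int(spec.ter_pos * spec.length) % spec.length
    u = rng.random(spec.length)
    seq = np.empty(spec.length, dtype=np.uint8)
    is_leading = np.zeros(spec.length, dtype=bool)
    if ori < ter:
        is_leading[ori:ter] = True
    else:
        is_leading[ori:] = True
        is_leading[:ter] = True
    for mask, probs in ((is_leading, leading), (~is_leading, lagging)):
        seq[mask] = _BASES[np.searchsorted(np.cumsum(probs), u[mask], side="right")]
    return seq


def _gene_sequence(spec: GenomeSpec, s_gene: float, rng: np.random.Generator) -> str:
    cpf = spec.codons_per_family_per_gene
    p = _c_ending_probability(s_gene, spec.background_c)
    codons: list[str] = []
    for c_codon, t_codon in FAMILIES.values():
        last_is_c = rng.random(cpf) < p
        codons.extend(c_codon if hit else t_codon for hit in last_is_c)
    order = rng.permutation(len(codons))
    return "ATG" + "".join(codons[i] for i in order) + "TAA"


def generate_chromosome(spec: GenomeSpec) -> ChromosomeRecord:
    """Draw one annotated chromosome; deterministic under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_heg + spec.n_other
    seq = _background_sequence(spec, rng)
    cds_list: list[CdsFeature] = []
    if n_genes > 0:
        spacing = spec.length // n_genes
        if spec.gene_length + 20 > spacing:
            raise ValueError(
                f"genes do not fit: need length >= {n_genes * (spec.gene_length + 20)} bp "
                f"for {n_genes} genes of {spec.gene_length} bp"
            )
        heg_idx = set(rng.choice(n_genes, size=spec.n_heg, replace=False).tolist())
        for i in range(n_genes):
            is_heg = i in heg_idx
            gene = _gene_sequence(spec, spec.s_true if is_heg else 0.0, rng)
            strand = "+" if i % 2 == 0 else "-"
            inserted = gene if strand == "+" else reverse_complement(gene)
            offset = i * spacing + 10
            seq[offset : offset + len(gene)] = np.frombuffer(
                inserted.encode("ascii"), dtype=np.uint8
            )
            product = (
                f"50S ribosomal protein L{(i % 36) + 1}"
                if is_heg
                else "hypothetical protein"
            )
            cds_list.append(
                CdsFeature(
                    start=offset + 1,
                    end=offset + len(gene),
                    strand=strand,
                    product=product,
                )
            )
    return ChromosomeRecord(
        accession=spec.accession,
        organism=spec.organism,
        sequence=seq.tobytes().decode("ascii"),
        cds_list=cds_list,
        circular=True,
    )


def generate_codon_counts(
    s_true: float,
    n_heg_per_family: int = 2000,
    n_background_per_family: int = 100_000,
    background_c: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> CodonFamilyCounts:
    """Draw family counts directly from the binomial codon-usage model.

    This is the sufficient-statistic view of :func:`generate_chromosome`: HEG
    C-ending counts are Binomial(n, p(s_true)) and the whole-genome
    background contains the HEG codons plus Binomial draws at the neutral
    proportion, preserving the HEG-within-background nesting of real
    chromosomes.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if n_heg_per_family > n_background_per_family:
        raise ValueError("HEG codons cannot outnumber the whole-genome codons")
    p = _c_ending_probability(s_true, background_c)
    heg: dict[str, tuple[int, int]] = {}
    background: dict[str, tuple[int, int]] = {}
    n_rest = n_background_per_family - n_heg_per_family
    for fam in FAMILIES:
        k = int(rng.binomial(n_heg_per_family, p))
        rest_c = int(rng.binomial(n_rest, background_c))
        heg[fam] = (k, n_heg_per_family - k)
        background[fam] = (k + rest_c, (n_heg_per_family - k) + (n_rest - rest_c))
    return CodonFamilyCounts(heg=heg, background=background)


@dataclass
class AlignmentSpec:
    """Parameters of one simulated genus alignment."""

    n_taxa: int = 10
    divergence: float = 0.02  # expected pairwise K80 distance d*
    kappa: float = 2.0  # transition/transversion rate ratio
    length: int = 1500
    genus: str = "Synthetibacter"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be positive")


def _k80_substitution_probs(d: float, kappa: float) -> tuple[float, float]:
    """(transition, per-target transversion) probabilities after distance d."""
    e1 = math.exp(-4.0 * d / (kappa + 2.0))
    e2 = math.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_ts, p_tv_each


# index order A, C, G, T; transitions are A<->G and C<->T
_TS_PARTNER = np.array([2, 3, 0, 1])
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def generate_aligned_set(spec: AlignmentSpec) -> AlignedSet:
    """Evolve ``n_taxa`` sequences from one ancestor under K80.

    Each taxon sits at branch length d*/2 from the ancestor, so the expected
    pairwise distance between any two taxa is d*.  Deterministic under the
    spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.divergence > 0.75:
        logger.warning(
            "divergence %.2f is near saturation for length %d; distance "
            "estimates may be unstable", spec.divergence, spec.length,
        )
    ancestor = rng.integers(0, 4, size=spec.length)
    p_ts, p_tv = _k80_substitution_probs(spec.divergence / 2.0, spec.kappa)
    seqs = []
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    for _ in range(spec.n_taxa):
        u = rng.random(spec.length)
        pick = rng.integers(0, 2, size=spec.length)
        out = ancestor.copy()
        ts = u < p_ts
        tv = (u >= p_ts) & (u < p_ts + 2 * p_tv)
        out[ts] = _TS_PARTNER[ancestor[ts]]
        out[tv] = _TV_PARTNERS[ancestor[tv], pick[tv]]
        seqs.append(letters[out].tobytes().decode("ascii"))
    labels = [f"{spec.genus}_t{i + 1:03d}" for i in range(spec.n_taxa)]
    return AlignedSet(sequences=seqs, labels=labels, genera=[spec.genus] * spec.n_taxa)


def ground_truth_row(spec: GenomeSpec) -> dict:
    """One row of the ground-truth TSV emitted next to generated GenBank files."""
    return {
        "accession": spec.accession,
        "k": spec.skew_strength,
        "s_true": spec.s_true,
        "gc": spec.gc,
        "seed": spec.seed,
    }
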