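"""Strength of translationally selected codon usage bias (the S value).

Four amino acids -- Phe (TTC/TTT), Tyr (TAC/TAT), Ile (ATC/ATT) and
Asn (AAC/AAT) -- are each encoded by a C-ending and a T-ending codon read by
a single tRNA species that pairs more efficiently with the C-ending codon.
Under translational selection, highly expressed genes (HEG: ribosomal
proteins and translation elongation factors) over-use the C-ending codon
relative to the genomic background.  S measures that shift on a log-odds
scale: with background C-ending proportion ``c_f`` in family *f*, the
C-ending proportion in HEG is modeled as

    p_f = c_f * exp(S) / (1 - c_f + c_f * exp(S))

i.e. the HEG odds of a C-ending codon equal the background odds times
``exp(S)``.  HEG C-ending counts ``k_f`` of ``n_f`` family codons are treated
as Binomial(n_f, p_f) and a single shared S is fit by maximum likelihood
across the retained families.  S = 0 means no selected bias; typical fast
growers reach S of 1-2.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .genome_io import CdsFeature, ChromosomeRecord

logger = logging.getLogger(__name__)

#: the four two-codon families, C-ending codon first
FAMILIES: dict[str, tuple[str, str]] = {
    "Phe": ("TTC", "TTT"),
    "Tyr": ("TAC", "TAT"),
    "Ile": ("ATC", "ATT"),
    "Asn": ("AAC", "AAT"),
}

STOP_CODONS = ("TAA", "TAG", "TGA")

#: products naming ribosomal proteins or elongation factors (case-insensitive)
HEG_PATTERNS = (
    r"ribosomal protein",
    r"elongation factor (tu|g|ts|p)(\b|$)",
)
#: modifier enzymes etc. that mention HEG products but are not themselves HEG
HEG_NEGATIVE_PATTERNS = (
    r"methyltransferase",
    r"acetyltransferase",
    r"hydroxylase",
    r"kinase",
    r"pseudouridine",
    r"arginine transferase",
    r"modification",
)

S_BOUNDS = (-10.0, 10.0)
S_TOL = 1e-6


def identify_heg(
    cds_list: list[CdsFeature],
    patterns: tuple[str, ...] = HEG_PATTERNS,
    negative_patterns: tuple[str, ...] = HEG_NEGATIVE_PATTERNS,
) -> list[CdsFeature]:
    """Select the highly expressed gene set from product annotations.

    Non-pseudo CDSs whose product matches a positive pattern and no negative
    pattern.  The negative list removes modification enzymes such as
    "ribosomal protein L11 methyltransferase".
    """
    pos = [re.compile(p, re.IGNORECASE) for p in patterns]
    neg = [re.compile(p, re.IGNORECASE) for p in negative_patterns]
    heg = []
    for cds in cds_list:
        if cds.pseudo:
            continue
        if any(p.search(cds.product) for p in pos) and not any(
            p.search(cds.product) for p in neg
        ):
            heg.append(cds)
    return heg


# -- fast codon counting -----------------------------------------------------

def _codon_codes(codons) -> np.ndarray:
    return np.array(
        [(ord(a) << 16) | (ord(b) << 8) | ord(c) for a, b, c in codons], dtype=np.int64
    )


_FAMILY_NAMES = list(FAMILIES)
_C_CODES = _codon_codes(FAMILIES[f][0] for f in _FAMILY_NAMES)
_T_CODES = _codon_codes(FAMILIES[f][1] for f in _FAMILY_NAMES)
_STOP_CODES = _codon_codes(STOP_CODONS)


def _codons_of(coding: str) -> np.ndarray:
    """Packed 3-byte integer codes of the complete codons of a CDS string."""
    n = len(coding) - len(coding) % 3
    if n == 0:
        return np.empty(0, dtype=np.int64)
    b = np.frombuffer(coding[:n].encode("ascii"), dtype=np.uint8).astype(np.int64)
    b = b.reshape(-1, 3)
    return (b[:, 0] << 16) | (b[:, 1] << 8) | b[:, 2]


def count_two_codon_families(
    cds_features: list[CdsFeature],
    record: ChromosomeRecord,
) -> dict[str, tuple[int, int]]:
    """Accumulate (C-ending, T-ending) codon counts per family over a gene set.

    Reading frame starts at ``codon_start``; a trailing partial codon is
    truncated with a warning; the terminal stop codon is excluded; codons with
    ambiguous bases never match a family and are thereby skipped.  A gene with
    an internal stop codon is skipped entirely (likely mis-annotation).
    """
    c_tot = np.zeros(len(_FAMILY_NAMES), dtype=np.int64)
    t_tot = np.zeros(len(_FAMILY_NAMES), dtype=np.int64)
    for cds in cds_features:
        coding = cds.extract(record.sequence)
        if len(coding) % 3:
            logger.warning(
                "%s: CDS %d..%d length not divisible by 3; truncating partial codon",
                record.accession, cds.start, cds.end,
            )
        codons = _codons_of(coding)
        if codons.size == 0:
            continue
        if codons[-1] in _STOP_CODES:
            codons = codons[:-1]
        if np.isin(codons, _STOP_CODES).any():
            logger.warning(
                "%s: CDS %d..%d has internal stop codon; gene skipped",
                record.accession, cds.start, cds.end,
            )
            continue
        c_tot += (codons[:, None] == _C_CODES).sum(axis=0)
        t_tot += (codons[:, None] == _T_CODES).sum(axis=0)
    return {
        f: (int(c_tot[i]), int(t_tot[i])) for i, f in enumerate(_FAMILY_NAMES)
    }


@dataclass
class CodonFamilyCounts:
    """C-/T-ending codon counts per family, for HEG and whole-genome CDS sets."""

    heg: dict[str, tuple[int, int]]
    background: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for f, (c, t) in self.heg.items():
            if c < 0 or t < 0:
                raise ValueError(f"negative count in family {f}")

    def swapped(self) -> "CodonFamilyCounts":
        """Counts with C and T roles exchanged in both gene sets."""
        return CodonFamilyCounts(
            heg={f: (t, c) for f, (c, t) in self.heg.items()},
            background={f: (t, c) for f, (c, t) in self.background.items()},
        )


def counts_for_record(record: ChromosomeRecord) -> tuple[CodonFamilyCounts, int]:
    """HEG and whole-genome family counts for one chromosome.

    The background is all annotated non-pseudo CDSs (HEG included; they are a
    negligible fraction of total codons in real genomes).  Returns the counts
    and the number of HEG genes found.
    """
    non_pseudo = [c for c in record.cds_list if not c.pseudo]
    heg = identify_heg(non_pseudo)
    counts = CodonFamilyCounts(
        heg=count_two_codon_families(heg, record),
        background=count_two_codon_families(non_pseudo, record),
    )
    return counts, len(heg)


@dataclass
class SValueResult:
    s: float
    heg_gene_count: int | None
    background_proportions: dict[str, float]
    log_likelihood: float
    #: per-family log-odds-ratio diagnostics, ln[(k/(n-k)) / (c/(1-c))]
    family_log_odds: dict[str, float] = field(default_factory=dict)


def _neg_log_likelihood(s: float, k: np.ndarray, n: np.ndarray, c: np.ndarray) -> float:
    es = np.exp(s)
    p = c * es / (1.0 - c + c * es)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())


def estimate_s(
    counts: CodonFamilyCounts,
    heg_gene_count: int | None = None,
    bounds: tuple[float, float] = S_BOUNDS,
    tol: float = S_TOL,
) -> SValueResult | None:
    """Maximum-likelihood S from family counts; ``None`` when HEG is empty.

    Families with zero whole-genome usage are dropped.  A degenerate HEG
    family (all C-ending or all T-ending) gets a 0.5 pseudocount on both of
    its HEG codon counts so the likelihood stays finite without biasing
    typical genomes.
    """
    ks, ns, cs, fams = [], [], [], []
    for f in counts.background:
        bc, bt = counts.background[f]
        if bc + bt == 0:
            continue
        hc, ht = counts.heg.get(f, (0, 0))
        k, n = float(hc), float(hc + ht)
        if n > 0 and (k == 0 or k == n):
            k, n = k + 0.5, n + 1.0
        ks.append(k)
        ns.append(n)
        cs.append(bc / (bc + bt))
        fams.append(f)
    k = np.array(ks)
    n = np.array(ns)
    c = np.array(cs)
    if len(fams) == 0 or n.sum() == 0:
        logger.warning("estimate_s: no usable HEG codon counts; S missing")
        return None
    res = minimize_scalar(
        _neg_log_likelihood,
        bounds=bounds,
        args=(k, n, c),
        method="bounded",
        options={"xatol": tol},
    )
    s_hat = float(res.x)
    log_odds = {
        f: float(np.log((ki / (ni - ki)) / (ci / (1 - ci))))
        if 0 < ki < ni
        else float("nan")
        for f, ki, ni, ci in zip(fams, k, n, c)
    }
    return SValueResult(
        s=s_hat,
        heg_gene_count=heg_gene_count,
        background_proportions={f: float(ci) for f, ci in zip(fams, c)},
        log_likelihood=-float(res.fun),
        family_log_odds=log_odds,
    )


def s_value_for_record(record: ChromosomeRecord) -> SValueResult | None:
    """Convenience: HEG selection, codon counting and ML estimation in one call."""
    counts, n_heg = counts_for_record(record)
    if n_heg == 0:
        logger.warning("%s: no HEG annotations found; S missing", record.accession)
        return None
    return estimate_s(counts, heg_gene_count=n_heg)
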