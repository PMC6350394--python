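"""Intra-genus 16S rRNA diversity: K80 distances, Dmean and Faith's PD.

Works on a genus-labeled multiple alignment of 16S sequences (the style of
'The All-Species Living Tree' datasets) plus an optional newick tree.  Three
per-genus indices are computed:

* ``N``     -- the number of taxa available for the genus;
* ``Dmean`` -- the mean Kimura two-parameter (K80) distance over all pairs,
  an index of intra-genus sequence diversity (defined for N > 2);
* ``PD``    -- Faith's phylogenetic diversity, the total branch length of the
  minimal subtree spanning the genus's taxa (root-inclusive).

K80 separates transitions (A<->G, C<->T) from transversions:
``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` with P and Q the transition and
transversion proportions over compared columns.  Columns where either
sequence has a gap or ambiguity are dropped pair by pair (pairwise deletion,
the default of the classic distance implementations).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_UNAMBIG = frozenset("ACGT")


@dataclass
class AlignedSet:
    """Equal-length gapped sequences with taxon ids and genus labels."""

    sequences: list[str]
    labels: list[str]
    genera: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("AlignedSet requires at least one sequence")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        if not (len(self.sequences) == len(self.labels) == len(self.genera)):
            raise ValueError("sequences, labels and genera must align")

    def subset_by_genus(self, genus: str) -> "AlignedSet":
        idx = [i for i, g in enumerate(self.genera) if g == genus]
        return AlignedSet(
            sequences=[self.sequences[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            genera=[self.genera[i] for i in idx],
        )


def read_alignment(path) -> AlignedSet:
    """Read an aligned multi-FASTA whose headers carry the genus.

    Header convention: ``>taxon_id Genus species ...`` -- the genus is the
    first word of the description after the id (LTP-style headers that embed
    the binomial).  Sequences are upper-cased, U mapped to T.
    """
    from Bio import SeqIO

    seqs, labels, genera = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc_words = rec.description.split()
        genus = desc_words[1] if len(desc_words) > 1 else rec.id
        seqs.append(str(rec.seq).upper().replace("U", "T"))
        labels.append(rec.id)
        genera.append(genus)
    return AlignedSet(sequences=seqs, labels=labels, genera=genera)


def k80_distance(seq_a: str, seq_b: str) -> float:
    """Pairwise K80 distance with pairwise deletion of gap/ambiguous columns.

    Returns ``nan`` with a warning when the distance is saturated (a log
    argument is non-positive); raises when no columns are comparable.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    n = transitions = transversions = 0
    for a, b in zip(seq_a, seq_b):
        if a not in _UNAMBIG or b not in _UNAMBIG:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        raise ValueError("no comparable columns between the two sequences")
    p = transitions / n
    q = transversions / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        logger.warning("K80 distance saturated (P=%.3f, Q=%.3f); missing value", p, q)
        return float("nan")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class GenusDiversity:
    genus: str
    n_taxa: int
    dmean: float = float("nan")
    pd: float = float("nan")
    n_pairs_dropped: int = 0


def dmean(genus_set: AlignedSet) -> GenusDiversity:
    """Mean pairwise K80 distance within one genus (requires N > 2).

    Saturated pairs are excluded from the mean; the number dropped is
    reported on the result.
    """
    genus = genus_set.genera[0]
    n = len(genus_set.sequences)
    if n <= 2:
        raise ValueError(f"genus {genus}: Dmean needs more than 2 taxa (got {n})")
    dists = []
    dropped = 0
    for a, b in itertools.combinations(genus_set.sequences, 2):
        d = k80_distance(a, b)
        if math.isnan(d):
            dropped += 1
        else:
            dists.append(d)
    value = float(np.mean(dists)) if dists else float("nan")
    return GenusDiversity(genus=genus, n_taxa=n, dmean=value, n_pairs_dropped=dropped)


def faith_pd(tree: dendropy.Tree, taxa: list[str]) -> float:
    """Faith's PD: branch-length sum of the minimal subtree spanning ``taxa``.

    Root-inclusive: edges on the path from the root down to the spanned clade
    are counted, so even a single taxon has PD equal to its root-to-leaf
    path length.
    """
    want = set(taxa)
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon}
    missing = sorted(want - leaf_labels)
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    total = 0.0
    spans: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            hit = node.taxon is not None and node.taxon.label in want
        else:
            hit = any(spans[id(ch)] for ch in node.child_nodes())
        spans[id(node)] = hit
        if hit and node.parent_node is not None and node.edge.length:
            total += node.edge.length
    return total


def genus_diversity_table(
    alignment: AlignedSet,
    tree: dendropy.Tree | None = None,
    min_taxa: int = 3,
) -> pd.DataFrame:
    """Per-genus N / Dmean / PD table (Table S7 shape).

    Genera with fewer than ``min_taxa`` aligned taxa are skipped with a
    notice.  PD is filled only when a tree is supplied and all of the genus's
    taxa appear in it.
    """
    rows = []
    for genus in sorted(set(alignment.genera)):
        sub = alignment.subset_by_genus(genus)
        if len(sub.sequences) < min_taxa:
            logger.info("genus %s skipped: only %d taxa", genus, len(sub.sequences))
            continue
        gd = dmean(sub)
        if tree is not None:
            try:
                gd.pd = faith_pd(tree, sub.labels)
            except ValueError as exc:
                logger.warning("genus %s: PD unavailable (%s)", genus, exc)
        rows.append(
            {"genus": gd.genus, "N": gd.n_taxa, "dmean": gd.dmean, "pd": gd.pd,
             "pairs_dropped": gd.n_pairs_dropped}
        )
    return pd.DataFrame(rows, columns=["genus", "N", "dmean", "pd", "pairs_dropped"])


def index_correlations(per_genus: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the (N, Dmean, PD) diversity indices.

    Computed over genera with all three indices defined; an index with zero
    variance yields missing correlations for its pairs.
    """
    cols = ["N", "dmean", "pd"]
    complete = per_genus[cols].dropna()
    if len(complete) < 3:
        raise ValueError("need at least 3 genera with all three indices defined")
    return complete.corr(method="pearson")
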