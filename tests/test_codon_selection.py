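"""HEG selection, two-codon family counting and the S-value estimator."""

import math

import numpy as np
import pytest

from begenomics.codon_selection import (
    CodonFamilyCounts,
    count_two_codon_families,
    estimate_s,
    identify_heg,
    s_value_for_record,
)
from begenomics.genome_io import CdsFeature, ChromosomeRecord, reverse_complement


def _cds(product, pseudo=False):
    return CdsFeature(start=1, end=9, strand="+", product=product, pseudo=pseudo)


class TestIdentifyHeg:
    @pytest.mark.parametrize(
        "product, selected",
        [
            ("30S ribosomal protein S12", True),
            ("50S ribosomal protein L7/L12", True),
            ("elongation factor Tu", True),
            ("translation elongation factor G", True),
            ("elongation factor Ts", True),
            ("elongation factor P", True),
            ("DNA gyrase subunit A", False),
            ("ribosomal protein L11 methyltransferase", False),
            ("ribosomal protein S6 modification protein", False),
            ("50S ribosomal protein L16 3-hydroxylase", False),
            ("ribosomal protein S6 kinase", False),
            ("hypothetical protein", False),
        ],
    )
    def test_pattern_matching(self, product, selected):
        got = identify_heg([_cds(product)])
        assert (len(got) == 1) is selected

    def test_pseudo_genes_excluded(self):
        assert identify_heg([_cds("30S ribosomal protein S12", pseudo=True)]) == []


def _record_with(seq, cds_list):
    return ChromosomeRecord(accession="X", organism="Testibacter sp.",
                            sequence=seq, cds_list=cds_list)


class TestCountFamilies:
    def test_manual_codon_walk_forward(self):
        # codons: ATG TTC TTT AAC TAA -> Phe c=1 t=1, Asn c=1, stop excluded
        seq = "ATGTTCTTTAACTAA"
        rec = _record_with(seq, [CdsFeature(start=1, end=15, strand="+")])
        counts = count_two_codon_families(rec.cds_list, rec)
        assert counts["Phe"] == (1, 1)
        assert counts["Asn"] == (1, 0)
        assert counts["Tyr"] == (0, 0)
        assert counts["Ile"] == (0, 0)

    def test_reverse_strand_symmetry(self):
        fwd = "ATGTTCTTTAACTAA"
        seq = reverse_complement(fwd)
        rec = _record_with(seq, [CdsFeature(start=1, end=15, strand="-")])
        counts = count_two_codon_families(rec.cds_list, rec)
        assert counts["Phe"] == (1, 1)
        assert counts["Asn"] == (1, 0)

    def test_empty_gene_set(self):
        rec = _record_with("ATGTTCTAA", [])
        counts = count_two_codon_families([], rec)
        assert all(v == (0, 0) for v in counts.values())

    def test_partial_trailing_codon_truncated(self, caplog):
        seq = "ATGTTCAA"  # 8 bases: ATG TTC + trailing AA
        rec = _record_with(seq, [CdsFeature(start=1, end=8, strand="+")])
        with caplog.at_level("WARNING"):
            counts = count_two_codon_families(rec.cds_list, rec)
        assert counts["Phe"] == (1, 0)
        assert "truncating" in caplog.text

    def test_internal_stop_skips_gene(self, caplog):
        seq = "ATGTAATTCTAA"  # stop at codon 2
        rec = _record_with(seq, [CdsFeature(start=1, end=12, strand="+")])
        with caplog.at_level("WARNING"):
            counts = count_two_codon_families(rec.cds_list, rec)
        assert counts["Phe"] == (0, 0)
        assert "internal stop" in caplog.text

    def test_ambiguous_codons_skipped(self):
        seq = "ATGTTNTTCTAA"  # TTN is ambiguous, TTC counts
        rec = _record_with(seq, [CdsFeature(start=1, end=12, strand="+")])
        counts = count_two_codon_families(rec.cds_list, rec)
        assert counts["Phe"] == (1, 0)

    def test_codon_start_shifts_frame(self):
        seq = "GGATGTTCTAA"  # codon_start=3 -> ATG TTC TAA
        rec = _record_with(seq, [CdsFeature(start=1, end=11, strand="+", codon_start=3)])
        counts = count_two_codon_families(rec.cds_list, rec)
        assert counts["Phe"] == (1, 0)


def _counts(heg, background):
    return CodonFamilyCounts(heg=heg, background=background)


def _grid_search_s(counts, step=1e-4):
    """Independent oracle: dense grid over the S range, vectorized likelihood."""
    ks, ns, cs = [], [], []
    for f, (bc, bt) in counts.background.items():
        if bc + bt == 0:
            continue
        hc, ht = counts.heg[f]
        k, n = float(hc), float(hc + ht)
        if n > 0 and (k == 0 or k == n):
            k, n = k + 0.5, n + 1.0
        ks.append(k)
        ns.append(n)
        cs.append(bc / (bc + bt))
    k = np.array(ks)[:, None]
    n = np.array(ns)[:, None]
    c = np.array(cs)[:, None]
    grid = np.arange(-10.0, 10.0 + step, step)[None, :]
    es = np.exp(grid)
    p = np.clip(c * es / (1 - c + c * es), 1e-12, 1 - 1e-12)
    ll = (k * np.log(p) + (n - k) * np.log1p(-p)).sum(axis=0)
    return float(grid[0, np.argmax(ll)])


class TestEstimateS:
    def test_no_shift_gives_zero(self):
        heg = {f: (50, 50) for f in ("Phe", "Tyr", "Ile", "Asn")}
        background = {f: (5000, 5000) for f in ("Phe", "Tyr", "Ile", "Asn")}
        res = estimate_s(_counts(heg, background))
        assert res.s == pytest.approx(0.0, abs=1e-4)

    def test_single_family_closed_form(self):
        # c=0.5 so the HEG odds equal e^S directly: S = ln(73/27)
        heg = {"Phe": (73, 27), "Tyr": (0, 0), "Ile": (0, 0), "Asn": (0, 0)}
        background = {"Phe": (5000, 5000), "Tyr": (0, 0), "Ile": (0, 0), "Asn": (0, 0)}
        res = estimate_s(_counts(heg, background))
        assert res.s == pytest.approx(math.log(73 / 27), abs=1e-4)
        assert res.s == pytest.approx(_grid_search_s(_counts(heg, background)), abs=1e-3)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            heg, background = {}, {}
            for f in ("Phe", "Tyr", "Ile", "Asn"):
                n_bg = int(rng.integers(1000, 20000))
                c_bg = int(rng.integers(1, n_bg))
                n_heg = int(rng.integers(10, 500))
                k = int(rng.integers(0, n_heg + 1))
                heg[f] = (k, n_heg - k)
                background[f] = (c_bg, n_bg - c_bg)
            counts = _counts(heg, background)
            assert estimate_s(counts).s == pytest.approx(
                _grid_search_s(counts), abs=1e-3
            )

    def test_antisymmetry_under_ct_swap(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            heg, background = {}, {}
            for f in ("Phe", "Tyr", "Ile", "Asn"):
                heg[f] = (int(rng.integers(1, 200)), int(rng.integers(1, 200)))
                background[f] = (int(rng.integers(100, 5000)), int(rng.integers(100, 5000)))
            counts = _counts(heg, background)
            s_fwd = estimate_s(counts).s
            s_rev = estimate_s(counts.swapped()).s
            assert s_rev == pytest.approx(-s_fwd, abs=1e-4)

    def test_monotone_in_heg_c_counts(self):
        background = {f: (5000, 5000) for f in ("Phe", "Tyr", "Ile", "Asn")}
        last = -np.inf
        for k in (20, 40, 60, 80):
            heg = {f: (k, 100 - k) for f in ("Phe", "Tyr", "Ile", "Asn")}
            s = estimate_s(_counts(heg, background)).s
            assert s > last
            last = s

    def test_degenerate_family_pseudocount_keeps_s_finite(self):
        heg = {"Phe": (100, 0), "Tyr": (0, 0), "Ile": (0, 0), "Asn": (0, 0)}
        background = {"Phe": (5000, 5000), "Tyr": (0, 0), "Ile": (0, 0), "Asn": (0, 0)}
        res = estimate_s(_counts(heg, background))
        assert np.isfinite(res.s)
        # pseudocount: k=100.5 of n=101 -> ln(100.5/0.5)
        assert res.s == pytest.approx(math.log(100.5 / 0.5), abs=1e-3)

    def test_all_zero_heg_returns_missing(self, caplog):
        heg = {f: (0, 0) for f in ("Phe", "Tyr", "Ile", "Asn")}
        background = {f: (100, 100) for f in ("Phe", "Tyr", "Ile", "Asn")}
        with caplog.at_level("WARNING"):
            assert estimate_s(_counts(heg, background)) is None

    def test_zero_usage_families_dropped(self):
        heg = {"Phe": (73, 27), "Tyr": (0, 0), "Ile": (0, 0), "Asn": (0, 0)}
        background = {"Phe": (500, 500), "Tyr": (0, 0), "Ile": (0, 0), "Asn": (0, 0)}
        res = estimate_s(_counts(heg, background))
        assert set(res.background_proportions) == {"Phe"}


def test_s_value_for_record_without_heg_annotations(caplog):
    rec = ChromosomeRecord(
        accession="X", organism="Testibacter sp.", sequence="ATGTTCTAA" * 10,
        cds_list=[CdsFeature(start=1, end=9, strand="+", product="hypothetical protein")],
    )
    with caplog.at_level("WARNING"):
        assert s_value_for_record(rec) is None
    assert "no HEG" in caplog.text
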