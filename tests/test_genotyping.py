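"""Primer design, Tm, genomic mapping, restriction-site scanning."""

import itertools
import math

import numpy as np
import pytest

from editscan._dna import revcomp
from editscan.discover import TalenMonomer, pair_talens
from editscan.enzymes import EnzymeDef, builtin_enzymes, load_enzyme_table
from editscan.errors import FormatError, UsageError
from editscan.genome import Genome, TargetRegion
from editscan.genotyping import (PrimerOptions, classify_uniqueness,
                                 design_primer_pairs, map_primer,
                                 melting_temperature, rank_primer_pairs,
                                 scan_restriction_sites,
                                 spacer_restriction_sites)
from editscan.offtargets import build_index

from conftest import region_of


# independent nearest-neighbor oracle: SantaLucia 1998 unified parameters,
# two-state model with CT/4, SantaLucia 1998 entropy salt correction
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}


def oracle_tm(seq: str, na_M: float = 0.05, ct_M: float = 50e-9) -> float:
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds += -2.8
    for i in range(len(seq) - 1):
        step = seq[i : i + 2]
        h, s = _NN.get(step) or _NN[revcomp(step)]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_M)
    R = 1.987
    return 1000.0 * dh / (ds + R * math.log(ct_M / 4.0)) - 273.15


def random_region(seed, length=1000, chrom="chr1"):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    genome = Genome({chrom: seq})
    return genome, region_of(genome, chrom, 0, length)


class TestMeltingTemperature:
    @pytest.mark.parametrize("seq", [
        "AGCGGATAACAATTTCACACAGGA",
        "ACGTACGTACGTACGTAC",
        "GGGCCCGGGCCCGGGCCCGG",
        "ATATATATATATATATAT",
    ])
    def test_matches_independent_nn_oracle(self, seq):
        assert melting_temperature(seq) == pytest.approx(oracle_tm(seq), abs=0.5)

    def test_duplex_symmetry(self):
        for seq in ("ACGTTGACCTGAGTCAAG", "TTTTCCCCGGGGAAAATT"):
            assert melting_temperature(seq) == pytest.approx(
                melting_temperature(revcomp(seq)), abs=1e-6)

    def test_gc_monotonicity_at_fixed_length(self):
        low = melting_temperature("ATATATATATATATATATATAT")
        high = melting_temperature("ATATATATATGCGCGCGCGCGC")
        assert high > low

    def test_non_dna_rejected(self):
        with pytest.raises(FormatError):
            melting_temperature("ACGTACGTACGTACGN")


class TestPrimerDesign:
    def test_all_emitted_pairs_satisfy_constraints(self):
        genome, region = random_region(1)
        opts = PrimerOptions()
        pairs = design_primer_pairs(region, 500, opts)
        assert pairs
        for p in pairs:
            assert opts.min_len <= len(p.left_seq) <= opts.max_len
            assert opts.min_len <= len(p.right_seq) <= opts.max_len
            assert opts.min_product <= p.product_size <= opts.max_product
            assert opts.min_tm <= p.tm_left <= opts.max_tm
            assert opts.min_tm <= p.tm_right <= opts.max_tm
            assert p.left_end <= 500 - opts.min_dist_from_cut
            assert p.right_start >= 500 + opts.min_dist_from_cut
            assert p.left_start < 500 < p.right_end  # spans the cut
            # sequences match the genome (right primer on minus strand)
            assert p.left_seq == genome.slice("chr1", p.left_start, p.left_end)
            assert p.right_seq == revcomp(
                genome.slice("chr1", p.right_start, p.right_end))

    def test_cut_near_edge_gives_empty_with_diagnostic(self, caplog):
        genome, region = random_region(2)
        assert design_primer_pairs(region, 30) == []

    def test_tightening_product_range_shrinks_set(self):
        genome, region = random_region(3)
        wide = PrimerOptions(max_pairs=None)
        narrow = PrimerOptions(min_product=200, max_product=210, max_pairs=None)
        key = lambda p: (p.left_start, len(p.left_seq), p.right_start,
                         len(p.right_seq))
        wide_set = {key(p) for p in design_primer_pairs(region, 500, wide)}
        narrow_set = {key(p) for p in design_primer_pairs(region, 500, narrow)}
        assert narrow_set <= wide_set

    def test_sorted_by_penalty(self):
        genome, region = random_region(4)
        pairs = design_primer_pairs(region, 500)
        assert [p.penalty for p in pairs] == sorted(p.penalty for p in pairs)


class TestMapPrimer:
    def plant_genome(self, copies, primer="ACGTTGACCTGAGTCAAGCATG"):
        rng = np.random.default_rng(9)
        seq = list("".join(rng.choice(list("ACGT"), size=20000)))
        positions = [1000 + 700 * i for i in range(copies)]
        for pos in positions:
            seq[pos : pos + len(primer)] = primer
        return Genome({"chr1": "".join(seq)}), primer, positions

    def test_planted_three_copies_found(self):
        genome, primer, positions = self.plant_genome(3)
        idx = build_index(genome, 9)
        res = map_primer(primer, genome, idx)
        plus = [h for h in res.hits if h[2] == "+"]
        assert {h[1] for h in plus} >= set(positions)
        # brute-force substring oracle
        seq = genome.sequences["chr1"]
        expected = set()
        start = seq.find(primer)
        while start != -1:
            expected.add(start)
            start = seq.find(primer, start + 1)
        assert {h[1] for h in plus} == expected
        assert not res.capped

    def test_cap_semantics(self):
        genome, primer, _ = self.plant_genome(25)
        idx = build_index(genome, 9)
        res = map_primer(primer, genome, idx, cap=10)
        assert len(res.hits) == 10 and res.capped

    def test_minus_strand_hit(self):
        primer = "ACGTTGACCTGAGTCAAGCATG"
        genome = Genome({"chr1": "T" * 100 + revcomp(primer) + "G" * 100})
        idx = build_index(genome, 9)
        res = map_primer(primer, genome, idx)
        assert res.hits == (("chr1", 100, "-"),)


class TestRankPrimerPairs:
    def test_duplicate_amplicon_demotes_pair(self):
        rng = np.random.default_rng(17)
        seq = list("".join(rng.choice(list("ACGT"), size=30000)))
        genome0 = Genome({"chr1": "".join(seq)})
        region = region_of(genome0, "chr1", 0, 1000)
        pairs = design_primer_pairs(region, 500, PrimerOptions(max_pairs=10))
        assert len(pairs) >= 2
        victim = pairs[0]
        # replant the victim amplicon (unchanged length) elsewhere
        amp = "".join(seq[victim.left_start : victim.right_end])
        seq[20000 : 20000 + len(amp)] = amp
        genome = Genome({"chr1": "".join(seq)})
        idx = build_index(genome, 9)
        ranked = rank_primer_pairs(pairs, genome, idx)
        victim_ranked = next(p for p in ranked if p is victim)
        assert victim_ranked.off_products >= 1
        clean = [p for p in ranked if p.off_products == 0]
        assert all(p.specificity_rank < victim_ranked.specificity_rank
                   for p in clean)

    def test_zero_offproduct_pairs_order_by_penalty(self):
        genome, region = random_region(23, length=2000)
        pairs = design_primer_pairs(region, 1000, PrimerOptions(max_pairs=8))
        idx = build_index(genome, 9)
        ranked = rank_primer_pairs(pairs, genome, idx)
        zero = [p for p in ranked if p.off_products == 0 and
                p.left_hits + p.right_hits == 2]
        assert [p.penalty for p in zero] == sorted(p.penalty for p in zero)


ECORI = EnzymeDef("EcoRI", "GAATTC", ("NEB",))


class TestRestriction:
    def region(self, seq):
        g = Genome({"chr1": seq})
        return region_of(g, "chr1", 0, len(seq))

    def test_palindrome_reported_once_on_plus(self):
        sites = scan_restriction_sites(self.region("AAGAATTCAA"), [ECORI])
        assert [(s.enzyme, s.start, s.strand) for s in sites] == [("EcoRI", 2, "+")]

    def test_min_site_len_excludes_enzyme(self):
        kpn = EnzymeDef("KpnI", "GGTACC")
        sites = scan_restriction_sites(self.region("AAGGTACCAA"), [kpn], 8)
        assert sites == []

    def test_degenerate_expansions_all_found(self):
        # GRCGYC: R in {A,G}, Y in {C,T} -> 4 concrete expansions
        expansions = [f"G{r}CG{y}C" for r in "AG" for y in "CT"]
        seq = "TTTT".join([""] + expansions + [""])
        enz = EnzymeDef("AcyI", "GRCGYC")
        sites = scan_restriction_sites(self.region(seq), [enz])
        plus = [s for s in sites if s.strand == "+"]
        # regex-expansion oracle
        import re
        expected = sorted(m.start() for m in re.finditer("G[AG]CG[CT]C", seq))
        assert sorted(s.start for s in plus) == expected
        assert len(plus) == 4

    def test_non_palindromic_minus_strand_found(self):
        enz = EnzymeDef("FakeI", "GGGAAT")
        # revcomp(GGGAAT) = ATTCCC present on plus => minus-strand site
        sites = scan_restriction_sites(self.region("TTATTCCCTT"), [enz])
        assert [(s.start, s.strand) for s in sites] == [(2, "-")]

    def test_invalid_iupac_letter_names_enzyme(self):
        with pytest.raises(FormatError, match="BadI"):
            EnzymeDef("BadI", "GAXTTC")

    def test_uniqueness_classification(self):
        region = self.region("GAATTCTTTTGAATTCTTGGTACC")
        kpn = EnzymeDef("KpnI", "GGTACC")
        sites = classify_uniqueness(
            scan_restriction_sites(region, [ECORI, kpn]), region)
        by_enzyme = {}
        for s in sites:
            by_enzyme.setdefault(s.enzyme, []).append(s.unique_in_region)
        assert by_enzyme["EcoRI"] == [False, False]
        assert by_enzyme["KpnI"] == [True]

    def test_spacer_containment(self):
        left = TalenMonomer("chr1", 0, "+", "TGACCTGAGTCAAGC")
        right = TalenMonomer("chr1", 31, "-", "TCAGGATGTGCCAAG")
        g = Genome({"chr1": "TGACCTGAGTCAAGC" + "AGAATTCAGTCAGGTC" +
                    revcomp("TCAGGATGTGCCAAG") + "AA"})
        region = region_of(g, "chr1", 0, 48)
        (pair,) = pair_talens([left, right], 14, 20, region)
        sites = spacer_restriction_sites(pair, [ECORI])
        assert [(s.enzyme, s.start) for s in sites] == [("EcoRI", 16)]
        # a site straddling the spacer boundary is not reported
        assert all(pair.spacer_start <= s.start and s.end <= pair.spacer_end
                   for s in sites)

    def test_empty_enzyme_list(self):
        left = TalenMonomer("chr1", 0, "+", "T" * 15)
        right = TalenMonomer("chr1", 31, "-", "T" * 15)
        g = Genome({"chr1": "T" * 15 + "A" * 16 + "A" * 15 + "AA"})
        region = region_of(g, "chr1", 0, 48)
        (pair,) = pair_talens([left, right], 14, 20, region)
        assert spacer_restriction_sites(pair, []) == []


class TestEnzymeTable:
    def test_builtin_supplier_filter(self):
        all_enz = builtin_enzymes()
        neb = builtin_enzymes("NEB")
        assert len(all_enz) >= 30
        assert all("NEB" in e.supplier_tags for e in neb)

    def test_load_user_table(self, tmp_path):
        p = tmp_path / "enz.tsv"
        p.write_text("EcoRI\tGAATTC\tNEB,Thermo\nHincII\tGTYRAC\tNEB\n")
        enz = load_enzyme_table(p)
        assert [e.name for e in enz] == ["EcoRI", "HincII"]
        assert enz[0].supplier_tags == ("NEB", "Thermo")
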