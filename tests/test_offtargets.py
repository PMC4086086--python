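"""Off-target search: index completeness, mismatch models, TALEN pairing."""

import numpy as np
import pytest

from editscan._dna import revcomp
from editscan.discover import CrisprCandidate, scan_crispr, scan_talen_monomers, pair_talens
from editscan.errors import DataError, UsageError
from editscan.genome import Genome, TargetRegion
from editscan.offtargets import (OffTargetHit, brute_force_crispr_offtargets,
                                 brute_force_offtargets, build_index,
                                 crispr_window_predicate,
                                 find_crispr_offtargets,
                                 find_talen_monomer_hits, find_talen_offtargets,
                                 index_k_for, talen_window_predicate)
from editscan.synthetic import (PlantSpec, crispr_decoy_plant, crispr_site_plant,
                                synth_genome, talen_monomer_plant,
                                talen_pair_plant)

from conftest import PROTO, region_of


def candidate_at(genome, start, strand="+", chrom="chr1"):
    region = region_of(genome, chrom, start - 5, start + 28)
    for c in scan_crispr(region):
        if c.start == start and c.strand == strand:
            return c
    raise AssertionError("no candidate at planted locus")


def hit_key(h: OffTargetHit):
    return (h.chrom, h.start, h.strand, h.mismatch_count, h.mismatch_positions,
            h.is_self)


class TestSeedIndex:
    def test_trivial_posting(self):
        idx = build_index(Genome({"a": "ACGTACGT"}), 8)
        assert idx.lookup("ACGTACGT") == [("a", 0)]

    def test_all_n_genome_empty_postings(self):
        assert build_index(Genome({"a": "N" * 50}), 8).postings == {}

    def test_empty_genome_rejected(self):
        with pytest.raises(DataError):
            build_index(Genome({}), 8)

    def test_postings_equal_bruteforce_enumeration(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        idx = build_index(Genome({"c": seq}), 12)
        expected = {}
        for i in range(len(seq) - 11):
            expected.setdefault(seq[i : i + 12], []).append(("c", i))
        assert idx.postings == expected

    def test_k_bounds(self):
        g = Genome({"a": "ACGT" * 10})
        with pytest.raises(UsageError):
            build_index(g, 3)
        with pytest.raises(UsageError):
            build_index(g, 17)


@pytest.fixture(scope="module")
def decoy_battery():
    """20 decoys of one candidate, one single-mismatch per protospacer position."""
    site = crispr_site_plant(100, PROTO, "TGG", "s")
    spec = PlantSpec(30000, seed=2)
    spec.add(site)
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for i in range(1, 21):
        spec.add(crispr_decoy_plant(
            site, 400 + 400 * i, [(i, swap[PROTO[i - 1]])], f"d{i}"))
    genome, _ = synth_genome(spec)
    cand = candidate_at(genome, 100)
    return genome, cand, build_index(genome, index_k_for(20, 2))


class TestCrisprOfftargets:
    def test_planted_duplicate_in_all_modes(self):
        site = crispr_site_plant(500, PROTO, "TGG", "s")
        spec = PlantSpec(8000, seed=1)
        spec.add(site)
        spec.add(crispr_decoy_plant(site, 4000, [], "copy"))
        genome, _ = synth_genome(spec)
        cand = candidate_at(genome, 500)
        idx = build_index(genome, index_k_for(20, 2))
        for mode in ("all_upstream", "seed_exact", "perfect_only"):
            hits = find_crispr_offtargets(cand, genome, idx, mode, 2)
            non_self = [h for h in hits if not h.is_self]
            assert [(h.start, h.mismatch_count) for h in non_self] == [(4000, 0)]

    def test_single_mismatch_decoys_at_every_position(self, decoy_battery):
        genome, cand, idx = decoy_battery
        all_hits = find_crispr_offtargets(cand, genome, idx, "all_upstream", 2)
        seed_hits = find_crispr_offtargets(cand, genome, idx, "seed_exact", 2)
        perfect = find_crispr_offtargets(cand, genome, idx, "perfect_only", 2)
        pos = lambda hits: sorted(h.mismatch_positions[0] for h in hits
                                  if not h.is_self)
        assert pos(all_hits) == list(range(1, 21))
        assert pos(seed_hits) == list(range(1, 10))
        assert [h for h in perfect if not h.is_self] == []

    def test_wrong_pam_never_reported(self):
        site = crispr_site_plant(500, PROTO, "TGG", "s")
        spec = PlantSpec(8000, seed=3)
        spec.add(site)
        # same 20-mer but PAM ACG (not NGG)
        from editscan.synthetic import sequence_plant
        spec.add(sequence_plant(4000, PROTO + "ACG", "badpam"))
        genome, _ = synth_genome(spec)
        cand = candidate_at(genome, 500)
        idx = build_index(genome, index_k_for(20, 2))
        for mode in ("all_upstream", "seed_exact", "perfect_only"):
            hits = find_crispr_offtargets(cand, genome, idx, mode, 2)
            assert all(h.start != 4000 for h in hits)

    def test_self_hit_unique_and_perfect(self, planted_crispr):
        genome, truth, site = planted_crispr
        cand = candidate_at(genome, 1000)
        idx = build_index(genome, index_k_for(20, 2))
        hits = find_crispr_offtargets(cand, genome, idx, "all_upstream", 2)
        selfs = [h for h in hits if h.is_self]
        assert len(selfs) == 1
        assert selfs[0].start == 1000 and selfs[0].mismatch_count == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_indexed_equals_bruteforce_all_modes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20_000, 40_000))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        genome = Genome({"chr1": seq})
        region = region_of(genome, "chr1", 2000, 2600)
        cands = scan_crispr(region)[:15]
        assert cands
        idx = build_index(genome, index_k_for(20, 2))
        for cand in cands:
            for mode in ("all_upstream", "seed_exact", "perfect_only"):
                fast = find_crispr_offtargets(cand, genome, idx, mode, 2)
                slow = brute_force_crispr_offtargets(cand, genome, mode, 2)
                assert sorted(map(hit_key, fast)) == sorted(map(hit_key, slow))

    def test_generic_bruteforce_agrees_on_small_genome(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        genome = Genome({"chr1": seq})
        region = region_of(genome, "chr1", 100, 200)
        cands = scan_crispr(region)
        assert cands
        cand = cands[0]
        idx = build_index(genome, index_k_for(20, 2))
        pred = crispr_window_predicate(cand.protospacer, "all_upstream", 2)
        slow = brute_force_offtargets(
            cand.site, genome, pred, (cand.chrom, cand.start, cand.strand),
        )
        fast = find_crispr_offtargets(cand, genome, idx, "all_upstream", 2)
        assert sorted(map(hit_key, slow)) == sorted(map(hit_key, fast))

    def test_query_in_genome_has_perfect_hit(self):
        genome = Genome({"c": "TTTACGTACGTTGACCTGAGTCAAGCATGGAAA"})
        pred = lambda w: () if w == "ACGTTGACCTGAGTCAAGCATGG"[:len(w)] else None
        hits = brute_force_offtargets("ACGTTGACCTGAGTCAAGCATGG", genome, pred)
        assert any(h.mismatch_count == 0 for h in hits)

    def test_empty_means_no_hits(self):
        genome = Genome({"c": "ACGT" * 5})
        assert brute_force_offtargets("T" * 30, genome, lambda w: None) == []


class TestModeNesting:
    def test_perfect_subset_seed_subset_all(self, planted_crispr):
        genome, truth, site = planted_crispr
        cand = candidate_at(genome, 1000)
        idx = build_index(genome, index_k_for(20, 2))
        sets = {}
        for mode in ("perfect_only", "seed_exact", "all_upstream"):
            sets[mode] = set(map(hit_key, find_crispr_offtargets(
                cand, genome, idx, mode, 2)))
        assert sets["perfect_only"] <= sets["seed_exact"] <= sets["all_upstream"]


class TestStrandSymmetry:
    def test_hits_mirror_on_reverse_complement_genome(self, planted_crispr):
        genome, truth, site = planted_crispr
        cand = candidate_at(genome, 1000)
        idx = build_index(genome, index_k_for(20, 2))
        fwd = find_crispr_offtargets(cand, genome, idx, "all_upstream", 2)

        n = len(genome.sequences["chr1"])
        rc_genome = Genome({"chr1": revcomp(genome.sequences["chr1"])})
        rc_idx = build_index(rc_genome, index_k_for(20, 2))
        rc_cand = CrisprCandidate("chr1", n - cand.end, "-", cand.protospacer,
                                  cand.pam)
        rev = find_crispr_offtargets(rc_cand, rc_genome, rc_idx, "all_upstream", 2)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted((n - h.start - 23, flip[h.strand], h.mismatch_count,
                           h.mismatch_positions) for h in rev)
        assert mirrored == sorted((h.start, h.strand, h.mismatch_count,
                                   h.mismatch_positions) for h in fwd)


LEFT = "TGACCTGAGTCAAGC"
RIGHT = "TCAGGATGTGCCAAG"


class TestTalenOfftargets:
    def build(self, extra_plants, seed=9, n=30000):
        spec = PlantSpec(n, seed=seed)
        spec.add(talen_pair_plant(2000, LEFT, "GAATTCAGTCAGGTCA", RIGHT, "t1"))
        for p in extra_plants:
            spec.add(p)
        genome, truth = synth_genome(spec)
        region = region_of(genome, "chr1", 1990, 2060)
        mons = scan_talen_monomers(region, 15)
        pairs = pair_talens(mons, 14, 20, region)
        pair = next(p for p in pairs if p.left.start == 2000
                    and p.right.start == 2031)
        idx = build_index(genome, index_k_for(15, 2))
        return genome, pair, idx

    def test_lone_monomer_copy_gives_no_paired_offtarget(self):
        genome, pair, idx = self.build([talen_monomer_plant(9000, LEFT, "+", "lone")])
        hits, paired = find_talen_offtargets(pair, genome, idx, 2, 14, 20)
        non_self = [h for h in hits if not h.is_self]
        assert [(h.start, h.strand) for h in non_self] == [(9000, "+")]
        assert paired == []

    def test_replanted_pair_is_paired_offtarget(self):
        genome, pair, idx = self.build(
            [talen_pair_plant(9000, LEFT, "A" * 16, RIGHT, "copy")])
        hits, paired = find_talen_offtargets(pair, genome, idx, 2, 14, 20)
        assert [(p.left_hit.start, p.right_hit.start, p.gap_len)
                for p in paired] == [(9000, 9031, 16)]

    def test_five_prime_c_copy_not_a_hit(self):
        # replanted left half-site whose 5' T became C: binding impossible
        from editscan.synthetic import sequence_plant
        broken = "C" + LEFT[1:]
        genome, pair, idx = self.build(
            [sequence_plant(9000, broken, "broken", kind="other")])
        hits, _ = find_talen_offtargets(pair, genome, idx, 2, 14, 20)
        assert all(h.start != 9000 for h in hits if h.strand == "+")

    def test_monomer_hits_equal_bruteforce(self):
        genome, pair, idx = self.build(
            [talen_pair_plant(9000, LEFT, "A" * 16, RIGHT, "copy")])
        for mono, strand in ((pair.left, "+"), (pair.right, "-")):
            fast = find_talen_monomer_hits(
                mono.sequence, genome, idx, 2,
                (mono.chrom, mono.start, strand))
            slow = brute_force_offtargets(
                mono.sequence, genome,
                talen_window_predicate(mono.sequence, 2),
                (mono.chrom, mono.start, strand))
            assert sorted(map(hit_key, fast)) == sorted(map(hit_key, slow))
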