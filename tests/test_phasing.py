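import itertools

import numpy as np
import pytest

from homoeoseq.config import PhasingParams
from homoeoseq.io import GeneReads
from homoeoseq.phasing import (
    Fragment,
    PhaseBlock,
    build_fragments,
    edit_homoeolog_sequences,
    filter_and_label,
    mec_score,
    phase_block,
)


def frag(sites, alleles, name="f"):
    return Fragment(name, np.array(sites), np.array(alleles, dtype=np.int8))


def brute_force_mec(fragments, n_sites):
    best = None
    for bits in itertools.product((0, 1), repeat=n_sites):
        s = mec_score(fragments, np.array(bits, dtype=np.int8))
        best = s if best is None or s < best else best
    return best


class TestBuildFragments:
    def _reads(self, starts, seqs, pair_ids, quals=None):
        seq = np.array(seqs, dtype=np.uint8)
        if quals is None:
            quals = np.full(seq.shape, 30, dtype=np.uint8)
        return GeneReads(start=np.array(starts), seq=seq, qual=quals,
                         pair_id=np.array(pair_ids))

    def test_sites_never_covered_together_split_components(self):
        # two reads, each covering one site: two singleton components -> none kept
        reads = self._reads([0, 10], [[1, 0, 0], [0, 1, 0]], [0, 1])
        frags, comps = build_fragments(reads, np.array([0, 11]),
                                       np.array([0, 0]), np.array([1, 1]))
        assert frags == [] and comps == []

    def test_mate_pair_merged_into_single_fragment(self):
        # sites at 1 and 11; mate 1 covers site 0, mate 2 covers site 1
        reads = self._reads([0, 10], [[0, 1, 0], [0, 1, 0]], [0, 0])
        frags, comps = build_fragments(reads, np.array([1, 11]),
                                       np.array([0, 0]), np.array([1, 1]))
        assert len(frags) == 1
        assert np.array_equal(frags[0].sites, [0, 1])
        assert np.array_equal(frags[0].alleles, [1, 1])
        assert len(comps) == 1 and np.array_equal(comps[0], [0, 1])

    def test_base_matching_neither_allele_becomes_gap(self):
        reads = self._reads([0], [[3, 0, 1]], [0])   # base 3 at site 0: not ref(0)/alt(1)
        frags, _ = build_fragments(reads, np.array([0, 2]),
                                   np.array([0, 0]), np.array([1, 1]))
        assert frags == []                           # one informative site left -> dropped

    def test_conflicting_mates_gap_the_shared_site(self):
        reads = self._reads([0, 0], [[0, 1, 0], [1, 1, 0]], [0, 0])
        frags, _ = build_fragments(reads, np.array([0, 1]),
                                   np.array([0, 0]), np.array([1, 1]))
        assert frags == []                           # site 0 gapped, one site left


class TestPhaseBlock:
    def test_concordant_fragments_mec_zero(self):
        frags = [frag([0, 1, 2], [0, 0, 0])] * 5 + [frag([0, 1, 2], [1, 1, 1])] * 5
        hap, mec = phase_block(frags, np.arange(3))
        assert mec == 0
        assert np.array_equal(hap, [0, 0, 0])

    def test_one_discordant_fragment_costs_one(self):
        frags = [frag([0, 1], [0, 0]) for _ in range(10)] + [frag([0, 1], [0, 1])]
        _, mec = phase_block(frags, np.arange(2))
        assert mec == 1

    def test_exhaustive_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            frags = []
            true = rng.integers(0, 2, size=n)
            for i in range(int(rng.integers(2, 20))):
                k = int(rng.integers(2, min(n, 4) + 1))
                sites = np.sort(rng.choice(n, size=k, replace=False))
                hap = true if rng.random() < 0.5 else 1 - true
                alleles = hap[sites].copy()
                flips = rng.random(k) < 0.15
                alleles[flips] = 1 - alleles[flips]
                frags.append(frag(sites, alleles, f"f{i}"))
            _, mec = phase_block(frags, np.arange(n))
            assert mec == brute_force_mec(frags, n)

    def test_heuristic_matches_exhaustive_on_planted_instances(self, rng):
        forced = PhasingParams(exhaustive_site_limit=2)
        for _ in range(60):
            n = int(rng.integers(3, 11))
            true = rng.integers(0, 2, size=n)
            frags = []
            for i in range(int(rng.integers(5, 31))):
                k = int(rng.integers(2, min(n, 5) + 1))
                sites = np.sort(rng.choice(n, size=k, replace=False))
                hap = true if rng.random() < 0.5 else 1 - true
                alleles = hap[sites].copy()
                flips = rng.random(k) < 0.1
                alleles[flips] = 1 - alleles[flips]
                frags.append(frag(sites, alleles, f"f{i}"))
            _, mec_h = phase_block(frags, np.arange(n), forced)
            _, mec_e = phase_block(frags, np.arange(n))
            assert mec_h == mec_e


def _block(hap, mec=0, positions=None):
    n = len(hap)
    positions = np.arange(n) * 10 if positions is None else np.asarray(positions)
    return PhaseBlock(
        transcript="g", block_id=1, site_positions=positions,
        ref_alleles=np.zeros(n, dtype=np.uint8),
        alt_alleles=np.ones(n, dtype=np.uint8),
        haplotype=np.array(hap, dtype=np.int8), mec=mec, n_fragments=10,
    )


class TestFilterAndLabel:
    def test_perfect_reference_haplotype_labelled_a(self):
        block = filter_and_label(_block([0] * 10))
        assert block is not None
        assert block.labels == ("A", "B")
        assert block.reference_concordance == 1.0

    def test_eighty_percent_concordance_rejected(self):
        assert filter_and_label(_block([0] * 8 + [1] * 2)) is None

    def test_mec_above_ten_rejected(self):
        assert filter_and_label(_block([0] * 10, mec=11)) is None
        assert filter_and_label(_block([0] * 10, mec=10)) is not None

    def test_complement_haplotype_labelled_b_first(self):
        block = filter_and_label(_block([1] * 10))
        assert block.labels == ("B", "A")
        assert np.array_equal(block.a_haplotype, np.zeros(10))

    def test_relaxing_thresholds_never_shrinks_retention(self):
        blocks = [_block([0] * 9 + [1], mec=m) for m in range(0, 14)]
        strict = PhasingParams()
        loose = PhasingParams(max_mec=13, min_reference_concordance=0.8)
        kept_strict = {i for i, b in enumerate(blocks)
                       if filter_and_label(_block([0] * 9 + [1], mec=b.mec), strict)}
        kept_loose = {i for i, b in enumerate(blocks)
                      if filter_and_label(_block([0] * 9 + [1], mec=b.mec), loose)}
        assert kept_strict <= kept_loose


class TestEditSequences:
    def test_zero_phased_sites_one_fixed_variant(self):
        ref = np.zeros(30, dtype=np.uint8)
        out = edit_homoeolog_sequences("g", ref, [], np.array([7]),
                                       np.array([2], dtype=np.uint8))
        (rec,) = out.records
        assert np.array_equal(rec.seq_a, rec.seq_b)
        assert rec.seq_a[7] == 2 and ref[7] == 0

    def test_haplotypes_differ_exactly_at_phased_sites(self):
        ref = np.zeros(50, dtype=np.uint8)
        block = filter_and_label(_block([0, 0, 0, 0, 0], positions=[5, 15, 25, 35, 45]))
        out = edit_homoeolog_sequences("g", ref, [block])
        (rec,) = out.records
        diffs = np.flatnonzero(rec.seq_a != rec.seq_b)
        assert np.array_equal(diffs, [5, 15, 25, 35, 45])
        assert (rec.seq_a[diffs] == 0).all() and (rec.seq_b[diffs] == 1).all()

    def test_fixed_sites_identical_in_both(self):
        ref = np.zeros(50, dtype=np.uint8)
        block = filter_and_label(_block([0, 0], positions=[10, 20]))
        out = edit_homoeolog_sequences("g", ref, [block], np.array([30]),
                                       np.array([3], dtype=np.uint8))
        (rec,) = out.records
        assert rec.seq_a[30] == rec.seq_b[30] == 3

    def test_two_blocks_split_into_tiling_records(self):
        ref = np.zeros(100, dtype=np.uint8)
        b1 = filter_and_label(_block([0, 0], positions=[10, 20]))
        b2 = filter_and_label(_block([0, 0], positions=[70, 80]))
        b2.block_id = 2
        out = edit_homoeolog_sequences("g", ref, [b1, b2])
        r1, r2 = out.records
        assert r1.start == 0 and r2.end == 100
        assert r1.end == r2.start == (21 + 70) // 2    # midpoint between blocks
        assert r1.name_a == "g.block1.A" and r2.name_b == "g.block2.B"

    def test_overlapping_blocks_rejected(self):
        ref = np.zeros(100, dtype=np.uint8)
        b1 = filter_and_label(_block([0, 0], positions=[10, 40]))
        b2 = filter_and_label(_block([0, 0], positions=[30, 60]))
        with pytest.raises(ValueError, match="overlap"):
            edit_homoeolog_sequences("g", ref, [b1, b2])
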