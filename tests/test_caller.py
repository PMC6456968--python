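"""Variant caller unit and property tests.

The scalar `window_filter` / `call_position` are the reference semantics;
the vectorised whole-sample path must agree with them exactly.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from homoeoseq.caller import (
    CallerParams,
    Genotype,
    call_position,
    call_variants,
    pileup_counts,
    window_filter,
    _genotype_vector,
    _window_accept,
)
from homoeoseq.io import GeneReads, ReadSet

P = CallerParams()


def _read(seq_codes, quals, ref_codes):
    return (np.asarray(seq_codes, dtype=np.uint8),
            np.asarray(quals, dtype=np.uint8),
            np.asarray(ref_codes, dtype=np.uint8))


class TestWindowFilter:
    def test_central_quality_below_twenty_rejected(self):
        seq, qual, ref = _read([0] * 21, [30] * 21, [0] * 21)
        qual[10] = 19
        assert not window_filter(seq, qual, ref, 10, P)
        qual[10] = 20
        assert window_filter(seq, qual, ref, 10, P)

    def test_perfect_read_accepted(self):
        seq, qual, ref = _read([1] * 50, [30] * 50, [1] * 50)
        assert window_filter(seq, qual, ref, 25, P)

    def test_mismatch_count_boundary_at_six(self):
        seq, qual, ref = _read([0] * 21, [30] * 21, [0] * 21)
        for pos in (5, 6, 7, 8, 9, 11):        # 6 mismatches inside [5, 16)
            seq[pos] = 1
        assert window_filter(seq, qual, ref, 10, P)
        seq[12] = 1                            # 7th mismatch
        assert not window_filter(seq, qual, ref, 10, P)

    def test_window_truncated_at_read_ends(self):
        seq, qual, ref = _read([0] * 8, [30] * 8, [0] * 8)
        assert window_filter(seq, qual, ref, 0, P)
        qual[:] = 15
        qual[0] = 30
        # truncated window [0, 6): mean (30 + 5*15)/6 = 17.5 >= 15
        assert window_filter(seq, qual, ref, 0, P)

    def test_average_quality_rule(self):
        seq, qual, ref = _read([0] * 21, [30] * 21, [0] * 21)
        qual[5:16] = 14
        qual[10] = 20                          # window mean 14.5 < 15, central passes
        assert not window_filter(seq, qual, ref, 10, P)

    @given(st.data())
    def test_vectorised_filter_matches_scalar(self, data):
        rl = 20
        n = data.draw(st.integers(1, 6))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        seq = rng.integers(0, 4, size=(n, rl)).astype(np.uint8)
        qual = rng.integers(5, 41, size=(n, rl)).astype(np.uint8)
        ref = rng.integers(0, 4, size=(n, rl)).astype(np.uint8)
        accept = _window_accept(seq, qual, ref, P)
        for i in range(n):
            for j in range(rl):
                assert accept[i, j] == window_filter(seq[i], qual[i], ref[i], j, P)


def _oracle(ref_base, bases, params=P):
    """Independent rule-table implementation of per-column genotyping."""
    cov = len(bases)
    if cov < params.min_coverage:
        return None
    from collections import Counter
    counts = Counter(bases)
    alts = {b: c for b, c in counts.items() if b != ref_base}
    if not alts:
        return Genotype.HOM_REF
    # ties broken toward the alphabetically first base, as argmax does
    alt, count = max(sorted(alts.items()), key=lambda kv: kv[1])
    freq = count / cov
    supported = count >= params.required_variant_count and (
        freq >= params.min_variant_frequency or count >= params.sufficient_variant_count)
    if not supported:
        return Genotype.HOM_REF
    if freq >= params.hom_frequency:
        return Genotype.HOM_ALT
    if freq >= params.min_variant_frequency and \
            counts[ref_base] / cov >= params.min_variant_frequency:
        return Genotype.HET
    return Genotype.HOM_REF


class TestCallPosition:
    def test_below_minimum_coverage_no_call(self):
        assert call_position("A", ["G"] * 7, P) is None

    def test_low_count_variant_not_supported(self):
        # coverage 10 with 2 alternative bases: 20% passes the frequency rule
        # but the 4-read support floor fails -> HOM_REF
        call = call_position("A", ["A"] * 8 + ["G"] * 2, P)
        assert call.genotype == Genotype.HOM_REF

    def test_het_and_hom_alt_boundaries(self):
        het = call_position("A", ["A"] * 20 + ["G"] * 20, P)
        assert het.genotype == Genotype.HET and het.alt == "G"
        hom = call_position("A", ["A"] * 2 + ["G"] * 38, P)
        assert hom.genotype == Genotype.HOM_ALT

    def test_exhaustive_two_allele_columns_match_oracle(self):
        # every ref/alt composition up to 12 reads
        for cov in range(1, 13):
            for n_alt in range(0, cov + 1):
                bases = ["A"] * (cov - n_alt) + ["G"] * n_alt
                call = call_position("A", bases, P)
                want = _oracle("A", bases)
                got = None if call is None else call.genotype
                assert got == want, (cov, n_alt)

    @given(st.lists(st.sampled_from("ACGT"), min_size=0, max_size=12))
    def test_random_columns_match_oracle(self, bases):
        call = call_position("C", bases, P)
        got = None if call is None else call.genotype
        assert got == _oracle("C", bases)

    @given(st.integers(0, 40), st.integers(0, 40))
    def test_adding_alt_reads_never_flips_hom_alt_to_hom_ref(self, n_ref, n_alt):
        bases = ["A"] * n_ref + ["G"] * n_alt
        before = call_position("A", bases, P)
        after = call_position("A", bases + ["G"], P)
        if before is not None and before.genotype == Genotype.HOM_ALT:
            assert after.genotype == Genotype.HOM_ALT


class TestCallVariants:
    def _readset(self, rng, ref_codes, n_reads=60, rl=30, qual_low=5, qual_high=41):
        L = len(ref_codes)
        starts = rng.integers(0, L - rl + 1, size=n_reads)
        offs = np.arange(rl)
        seq = ref_codes[starts[:, None] + offs].copy()
        muts = rng.random(seq.shape) < 0.08
        seq[muts] = (seq[muts] + rng.integers(1, 4, size=int(muts.sum()))) % 4
        qual = rng.integers(qual_low, qual_high, size=seq.shape).astype(np.uint8)
        gr = GeneReads(start=starts, seq=seq.astype(np.uint8), qual=qual,
                       pair_id=np.arange(n_reads))
        return ReadSet(variety="v", tissue="t", genes={"g": gr})

    def test_vectorised_pileup_matches_scalar_filters(self, rng):
        ref_codes = rng.integers(0, 4, size=120).astype(np.uint8)
        rs = self._readset(rng, ref_codes)
        counts = pileup_counts(rs.genes["g"], ref_codes, P)
        # recompute with the scalar window filter
        want = np.zeros_like(counts)
        gr = rs.genes["g"]
        for i in range(gr.n_reads):
            ref_seg = ref_codes[gr.start[i]:gr.start[i] + gr.seq.shape[1]]
            for j in range(gr.seq.shape[1]):
                if window_filter(gr.seq[i], gr.qual[i], ref_seg, j, P):
                    want[gr.start[i] + j, gr.seq[i, j]] += 1
        assert np.array_equal(counts, want)

    def test_genotype_vector_matches_call_position(self, rng):
        ref_codes = rng.integers(0, 4, size=80).astype(np.uint8)
        counts = rng.integers(0, 15, size=(80, 4)).astype(np.int64)
        geno, cov, alt, alt_count = _genotype_vector(counts, ref_codes, P)
        for pos in range(80):
            bases = []
            for code in range(4):
                bases += ["ACGT"[code]] * int(counts[pos, code])
            call = call_position("ACGT"[ref_codes[pos]], bases, P)
            if call is None:
                assert geno[pos] == Genotype.MISSING
            else:
                assert geno[pos] == call.genotype

    def test_zero_read_transcript_all_missing(self):
        ref = {"g": np.zeros(50, dtype=np.uint8)}
        rs = ReadSet(variety="v", tissue="t", genes={})
        cs = call_variants(rs, ref, P)
        assert (cs.genotype["g"] == Genotype.MISSING).all()
        assert cs.variant_positions("g").size == 0
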