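"""Per-position variant calling from gapless transcript alignments.

Implements CLC-style SNP calling semantics: every read base passes a
quality-window filter (window length 11 centred on the base, truncated at
read ends; central phred >= 20, window mean phred >= 15, at most 6
gaps+mismatches inside the window), and a position is genotyped from the
filtered pileup when coverage >= 8. An alternative allele is *supported*
when its filtered count is >= 4 and either its frequency is >= 10% or its
count reaches 1000 (at which point the frequency requirement is waived).
Genotypes: HOM_ALT when the alternative frequency is >= 90%, HET when both
alleles reach 10%, HOM_REF otherwise. Positions with coverage >= 8 and no
supported alternative are recorded as homozygous-reference calls — the
"sufficient information" cells the multi-variety genotype matrix needs.

Only substitutions are called. The scalar :func:`window_filter` and
:func:`call_position` are the reference semantics; :func:`call_variants`
is an exactly equivalent vectorised path over read arrays (the equivalence
is exercised by the test suite's brute-force oracles).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .config import CallerParams
from .io import GeneReads, ReadSet, seq_to_codes


class Genotype(IntEnum):
    HOM_REF = 0
    HOM_ALT = 1
    HET = 2
    MISSING = 3


@dataclass
class VariantCall:
    """One per-variety, per-position call."""

    transcript: str
    pos: int                   # 0-based
    ref: str
    alt: str | None
    genotype: Genotype
    coverage: int
    alt_count: int

    @property
    def frequency(self) -> float:
        return self.alt_count / self.coverage if self.coverage else 0.0


@dataclass
class CallSet:
    """Dense per-position calls for one sample, as arrays per transcript.

    For each transcript: ``genotype`` (uint8 Genotype codes, MISSING where
    coverage < min_coverage), ``coverage``, ``alt`` (uint8 base code of the
    top alternative, 255 where none) and ``alt_count``.
    """

    sample: str
    genotype: dict[str, np.ndarray]
    coverage: dict[str, np.ndarray]
    alt: dict[str, np.ndarray]
    alt_count: dict[str, np.ndarray]

    def variant_positions(self, transcript: str) -> np.ndarray:
        g = self.genotype[transcript]
        return np.flatnonzero((g == Genotype.HET) | (g == Genotype.HOM_ALT))


# ---------------------------------------------------------------------------
# window filter

def window_filter(seq: np.ndarray, qual: np.ndarray, ref_segment: np.ndarray,
                  variant_offset: int, params: CallerParams) -> bool:
    """Accept or reject one read base under the quality-window rule.

    ``seq``/``qual``/``ref_segment`` are per-base arrays for the read's
    aligned span; the window is truncated at read ends.
    """
    rl = len(seq)
    if not (0 <= variant_offset < rl):
        raise ValueError("variant_offset outside read")
    if qual[variant_offset] < params.min_central_quality:
        return False
    half = params.window_length // 2
    lo = max(0, variant_offset - half)
    hi = min(rl, variant_offset + half + 1)
    if qual[lo:hi].mean() < params.min_average_quality:
        return False
    mismatches = int(np.count_nonzero(seq[lo:hi] != ref_segment[lo:hi]))
    return mismatches <= params.max_gap_mismatch


def _window_accept(seq: np.ndarray, qual: np.ndarray, ref_rows: np.ndarray,
                   params: CallerParams) -> np.ndarray:
    """Vectorised window filter over an (n_reads, read_length) stack."""
    n, rl = seq.shape
    if n == 0:
        return np.zeros((0, rl), dtype=bool)
    half = params.window_length // 2
    j = np.arange(rl)
    lo = np.maximum(j - half, 0)
    hi = np.minimum(j + half, rl - 1)
    wlen = (hi - lo + 1).astype(np.float64)

    def windowed_sum(values: np.ndarray) -> np.ndarray:
        c = np.cumsum(values, axis=1, dtype=np.int64)
        upper = c[:, hi]
        lower = np.where(lo > 0, c[:, np.maximum(lo - 1, 0)], 0)
        return upper - lower

    mism = (seq != ref_rows)
    q = qual.astype(np.int64)
    ok_central = q >= params.min_central_quality
    ok_avg = windowed_sum(q) >= params.min_average_quality * wlen[None, :]
    ok_mism = windowed_sum(mism) <= params.max_gap_mismatch
    return ok_central & ok_avg & ok_mism


# ---------------------------------------------------------------------------
# per-column genotyping

def call_position(ref_base: str, bases: list[str], params: CallerParams) -> VariantCall | None:
    """Genotype a single filtered pileup column (scalar reference semantics).

    Returns None when coverage is below the minimum; otherwise a call whose
    genotype may be HOM_REF (no supported alternative).
    """
    cov = len(bases)
    if cov < params.min_coverage:
        return None
    ref_code = int(seq_to_codes(ref_base)[0])
    counts = np.zeros(4, dtype=np.int64)
    for b in bases:
        counts[int(seq_to_codes(b)[0])] += 1
    geno, alt_code, alt_count = _genotype_one(counts, ref_code, cov, params)
    alt = "ACGT"[alt_code] if alt_code >= 0 else None
    return VariantCall(transcript="", pos=-1, ref=ref_base, alt=alt,
                       genotype=geno, coverage=cov, alt_count=alt_count)


def _genotype_one(counts: np.ndarray, ref_code: int, cov: int,
                  params: CallerParams) -> tuple[Genotype, int, int]:
    alt_counts = counts.copy()
    alt_counts[ref_code] = -1
    alt_code = int(np.argmax(alt_counts))
    alt_count = int(counts[alt_code])
    if alt_count == 0:
        return Genotype.HOM_REF, -1, 0
    freq = alt_count / cov
    supported = alt_count >= params.required_variant_count and (
        freq >= params.min_variant_frequency
        or alt_count >= params.sufficient_variant_count
    )
    if not supported:
        return Genotype.HOM_REF, -1, alt_count
    ref_freq = counts[ref_code] / cov
    if freq >= params.hom_frequency:
        return Genotype.HOM_ALT, alt_code, alt_count
    if freq >= params.min_variant_frequency and ref_freq >= params.min_variant_frequency:
        return Genotype.HET, alt_code, alt_count
    return Genotype.HOM_REF, -1, alt_count


def _genotype_vector(counts: np.ndarray, ref_codes: np.ndarray,
                     params: CallerParams):
    """Vectorised genotyping of an (L, 4) filtered count matrix."""
    L = counts.shape[0]
    cov = counts.sum(axis=1)
    idx = np.arange(L)
    ref_count = counts[idx, ref_codes]
    masked = counts.copy()
    masked[idx, ref_codes] = -1
    alt_code = masked.argmax(axis=1).astype(np.uint8)
    alt_count = counts[idx, alt_code]

    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(cov > 0, alt_count / np.maximum(cov, 1), 0.0)
        ref_freq = np.where(cov > 0, ref_count / np.maximum(cov, 1), 0.0)
    supported = (
        (alt_count >= params.required_variant_count)
        & ((freq >= params.min_variant_frequency)
           | (alt_count >= params.sufficient_variant_count))
    )
    geno = np.full(L, Genotype.HOM_REF, dtype=np.uint8)
    hom_alt = supported & (freq >= params.hom_frequency)
    het = supported & ~hom_alt & (freq >= params.min_variant_frequency) \
        & (ref_freq >= params.min_variant_frequency)
    geno[hom_alt] = Genotype.HOM_ALT
    geno[het] = Genotype.HET
    missing = cov < params.min_coverage
    geno[missing] = Genotype.MISSING
    emitted_alt = np.where(hom_alt | het, alt_code, 255).astype(np.uint8)
    return geno, cov, emitted_alt, alt_count.astype(np.int64)


# ---------------------------------------------------------------------------
# whole-sample calling

def pileup_counts(reads: GeneReads, ref_codes: np.ndarray,
                  params: CallerParams) -> np.ndarray:
    """Filtered (L, 4) base-count matrix for one transcript."""
    L = len(ref_codes)
    counts = np.zeros((L, 4), dtype=np.int64)
    if reads.n_reads == 0:
        return counts
    rl = reads.seq.shape[1]
    pos = reads.start[:, None] + np.arange(rl)
    if pos.max() >= L or pos.min() < 0:
        raise ValueError("read alignment extends outside the reference transcript")
    ref_rows = ref_codes[pos]
    accept = _window_accept(reads.seq, reads.qual, ref_rows, params)
    np.add.at(counts, (pos[accept], reads.seq[accept].astype(np.intp)), 1)
    return counts


def call_variants(readset: ReadSet, reference: dict[str, np.ndarray],
                  params: CallerParams | None = None) -> CallSet:
    """Call every position of every transcript for one sample.

    ``reference`` maps transcript id to uint8 code arrays. Transcripts with
    no reads yield all-MISSING vectors. Deterministic: pure function of the
    inputs.
    """
    params = params or CallerParams()
    genotype, coverage, alt, alt_count = {}, {}, {}, {}
    for name, ref_codes in reference.items():
        if name in readset.genes and readset.genes[name].n_reads:
            counts = pileup_counts(readset.genes[name], ref_codes, params)
        else:
            counts = np.zeros((len(ref_codes), 4), dtype=np.int64)
        g, c, a, ac = _genotype_vector(counts, ref_codes, params)
        genotype[name], coverage[name], alt[name], alt_count[name] = g, c, a, ac
    return CallSet(sample=readset.variety, genotype=genotype,
                   coverage=coverage, alt=alt, alt_count=alt_count)


def callset_variants(callset: CallSet, reference: dict[str, np.ndarray]):
    """Yield VCF-ready variant rows (transcript, pos, ref, alt, genotype, DP, alt_count)."""
    for name in sorted(callset.genotype):
        g = callset.genotype[name]
        for pos in callset.variant_positions(name):
            yield (
                name, int(pos),
                "ACGT"[reference[name][pos]],
                "ACGT"[callset.alt[name][pos]],
                int(g[pos]),
                int(callset.coverage[name][pos]),
                int(callset.alt_count[name][pos]),
            )


def write_callset_tsv(path, callset: CallSet, reference: dict[str, np.ndarray]) -> None:
    """Serialise a CallSet (positions with any coverage) to TSV."""
    with open(path, "w") as fh:
        fh.write(f"# sample={callset.sample}\n")
        fh.write("transcript\tpos\tref\tgenotype\talt\talt_count\tcoverage\n")
        for name in sorted(callset.genotype):
            g = callset.genotype[name]
            cov = callset.coverage[name]
            alt = callset.alt[name]
            alt_count = callset.alt_count[name]
            ref = reference[name]
            for pos in np.flatnonzero(cov > 0):
                alt_base = "ACGT"[alt[pos]] if alt[pos] != 255 else "."
                fh.write(
                    f"{name}\t{int(pos)}\t{'ACGT'[ref[pos]]}\t{int(g[pos])}\t"
                    f"{alt_base}\t{int(alt_count[pos])}\t{int(cov[pos])}\n"
                )


def read_callset_tsv(path, reference: dict[str, np.ndarray]) -> CallSet:
    """Read a CallSet back; positions absent from the file are MISSING."""
    sample = ""
    genotype = {n: np.full(len(r), Genotype.MISSING, dtype=np.uint8)
                for n, r in reference.items()}
    coverage = {n: np.zeros(len(r), dtype=np.int64) for n, r in reference.items()}
    alt = {n: np.full(len(r), 255, dtype=np.uint8) for n, r in reference.items()}
    alt_count = {n: np.zeros(len(r), dtype=np.int64) for n, r in reference.items()}
    code = {b: i for i, b in enumerate("ACGT")}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                _, _, val = line[1:].strip().partition("=")
                sample = val
                continue
            if not line or line.startswith("transcript\t"):
                continue
            name, pos, _ref, geno, alt_base, ac, cov = line.split("\t")
            pos = int(pos)
            genotype[name][pos] = int(geno)
            coverage[name][pos] = int(cov)
            alt_count[name][pos] = int(ac)
            if alt_base != ".":
                alt[name][pos] = code[alt_base]
    return CallSet(sample=sample, genotype=genotype, coverage=coverage,
                   alt=alt, alt_count=alt_count)


def filter_sam_records(hits, params: CallerParams, read_length: int):
    """Alignment-record pre-filter: minimum similarity and aligned-length fraction."""
    kept = []
    for h in hits:
        if h.length < params.min_aligned_fraction * read_length:
            continue
        if h.identity < 100.0 * params.min_similarity:
            continue
        kept.append(h)
    return kept
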