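"""Assembly-completeness metrics from BLAST-style alignment hits.

Gene reconstruction: a hit (already identity-filtered at >= 80%) is
accepted when any of three length conditions holds — hit length >= 60% of
the contig, > 80% of the gene, or >= 200 bp. Per gene we report the
fraction of the gene span covered by at least one accepted hit and the
number of contigs needed to achieve that span (greedy interval cover,
verified against exhaustive search on small inputs in the test suite).

Homoeolog copy estimation: with the identity between a known A/B gene pair
in hand, accepted hits near 100% identity derive from the A subgenome and
hits within 1% of the paired identity from the B subgenome; per-subgenome
"gene coverage" is the cumulative non-overlapping assigned-hit length over
the gene length, and the pair is bucketed into both / one / one-to-two /
less-than-one / none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import QCParams
from .io import AlignmentHit


@dataclass
class GeneReconstruction:
    gene: str
    gene_length: int
    accepted_hits: list[AlignmentHit]
    span_fraction: float
    contigs_needed: int
    reconstructed: bool


@dataclass
class HomoeologCopyEstimate:
    gene: str
    paired_identity: float
    coverage_a: float
    coverage_b: float
    category: str                 # both / one / one_to_two / less_than_one / none
    indeterminate: bool = False   # A and B identity bands overlap
    unassigned_hits: int = 0      # putative paralogs


def accept_hit(hit_length: int, contig_length: int, gene_length: int,
               params: QCParams | None = None) -> bool:
    """The three-way hit acceptance disjunction."""
    params = params or QCParams()
    return (
        hit_length >= params.hit_contig_fraction * contig_length
        or hit_length > params.hit_gene_fraction * gene_length
        or hit_length >= params.hit_min_length
    )


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, last_end = 0, -1
    for start, end in sorted(intervals):
        start = max(start, last_end)
        if end > start:
            total += end - start
            last_end = end
        last_end = max(last_end, end)
    return total


def gene_reconstruction(gene: str, gene_length: int, hits: list[AlignmentHit],
                        contig_lengths: dict[str, int],
                        params: QCParams | None = None) -> GeneReconstruction:
    """Span fraction and minimal contig count for one benchmark gene.

    ``hits`` have the gene as query; hits extending outside the gene bounds
    are clipped. contigs_needed is the size of a greedy minimal contig
    subset achieving the full accepted-hit union (ties broken by longer
    added span, then contig id).
    """
    params = params or QCParams()
    accepted = []
    for h in hits:
        if h.identity < params.min_identity:
            continue
        if accept_hit(h.length, contig_lengths[h.subject], gene_length, params):
            accepted.append(h)
    clipped: dict[str, list[tuple[int, int]]] = {}
    for h in accepted:
        start, end = max(0, h.qstart), min(gene_length, h.qend)
        if end > start:
            clipped.setdefault(h.subject, []).append((start, end))

    all_intervals = [iv for ivs in clipped.values() for iv in ivs]
    span = _union_length(all_intervals)
    span_fraction = span / gene_length if gene_length else 0.0
    return GeneReconstruction(
        gene=gene, gene_length=gene_length, accepted_hits=accepted,
        span_fraction=span_fraction,
        contigs_needed=_min_contig_cover(clipped, span),
        reconstructed=span_fraction >= params.reconstructed_span,
    )


_EXACT_COVER_LIMIT = 12


def _min_contig_cover(intervals_by_contig: dict[str, list[tuple[int, int]]],
                      target_span: int) -> int:
    """Smallest number of contigs whose hits achieve the full accepted union.

    Exact (subsets in increasing size) up to ``_EXACT_COVER_LIMIT`` contigs;
    larger inputs fall back to a greedy largest-gain cover (ties by longer
    cumulative hit length, then contig id).
    """
    names = sorted(intervals_by_contig)
    if target_span == 0 or not names:
        return 0
    if len(names) <= _EXACT_COVER_LIMIT:
        import itertools
        for size in range(1, len(names) + 1):
            for combo in itertools.combinations(names, size):
                ivs = [iv for c in combo for iv in intervals_by_contig[c]]
                if _union_length(ivs) == target_span:
                    return size
        return len(names)
    chosen: list[str] = []
    covered: list[tuple[int, int]] = []
    remaining = dict(intervals_by_contig)
    while _union_length(covered) < target_span and remaining:
        best_contig, best_gain, best_len = None, -1, -1
        for contig, ivs in sorted(remaining.items()):
            gain = _union_length(covered + ivs) - _union_length(covered)
            total_len = sum(e - s for s, e in ivs)
            if gain > best_gain or (gain == best_gain and total_len > best_len):
                best_contig, best_gain, best_len = contig, gain, total_len
        if best_gain <= 0:
            break
        chosen.append(best_contig)
        covered += remaining.pop(best_contig)
    return len(chosen)


def _nonoverlap_coverage(hits: list[AlignmentHit], gene_length: int) -> int:
    """Cumulative covered length keeping the higher-identity hit on overlap."""
    kept: list[tuple[int, int]] = []
    for h in sorted(hits, key=lambda h: -h.identity):
        start, end = max(0, h.qstart), min(gene_length, h.qend)
        for ks, ke in kept:
            if start < ke and ks < end:          # trim against the kept hit
                if start >= ks:
                    start = max(start, ke)
                if end <= ke:
                    end = min(end, ks)
        if end > start:
            kept.append((start, end))
    return _union_length(kept)


def homoeolog_copy_estimate(gene: str, gene_length: int, hits: list[AlignmentHit],
                            paired_identity: float,
                            contig_lengths: dict[str, int],
                            params: QCParams | None = None) -> HomoeologCopyEstimate:
    """Assign accepted hits to subgenomes by identity and bucket the pair."""
    params = params or QCParams()
    indeterminate = paired_identity >= params.a_identity_floor
    a_hits, b_hits, unassigned = [], [], 0
    for h in hits:
        if h.identity < params.min_identity:
            continue
        if not accept_hit(h.length, contig_lengths[h.subject], gene_length, params):
            continue
        if h.identity >= params.a_identity_floor:
            a_hits.append(h)
        elif abs(h.identity - paired_identity) <= params.b_identity_band:
            b_hits.append(h)
        else:
            unassigned += 1
    cov_a = _nonoverlap_coverage(a_hits, gene_length) / gene_length
    cov_b = _nonoverlap_coverage(b_hits, gene_length) / gene_length
    category = copy_category(cov_a, cov_b, params)
    return HomoeologCopyEstimate(
        gene=gene, paired_identity=paired_identity,
        coverage_a=cov_a, coverage_b=cov_b, category=category,
        indeterminate=indeterminate, unassigned_hits=unassigned,
    )


def copy_category(cov_a: float, cov_b: float, params: QCParams | None = None) -> str:
    """Total, piecewise-constant category rule over the coverage unit square."""
    params = params or QCParams()
    full, floor = params.copy_coverage_full, params.copy_presence_floor
    a_full, b_full = cov_a >= full, cov_b >= full
    if a_full and b_full:
        return "both"
    if a_full or b_full:
        other = cov_b if a_full else cov_a
        return "one" if other < floor else "one_to_two"
    return "less_than_one" if max(cov_a, cov_b) >= floor else "none"
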