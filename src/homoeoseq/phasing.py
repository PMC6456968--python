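"""Read-backed phasing of heterozygous sites into homoeolog haplotypes.

Fragments (one per read pair, mates merged) carry 0/1 alleles over the
heterozygous sites they cover; connected components of the site-covisibility
graph define candidate blocks. Each block is resolved into two complementary
haplotypes by minimising the error-correction (MEC) score — the total number
of fragment alleles that must be flipped for every fragment to be consistent
with one of the two haplotypes. The search is exhaustive over the
2^(n_sites - 1) bipartitions up to ``exhaustive_site_limit`` sites, and a
spanning-tree-seeded greedy with single-site flip refinement beyond.

Retained blocks (MEC <= 10, one haplotype matching the all-reference
pattern at >= 90% of sites) are labelled: the reference-like haplotype is
the A-subgenome, its complement the B-subgenome. The reference transcript
is then edited into homoeolog-specific A and B sequences; homozygous
alternative ("fixed") variants are substituted in both. Transcripts whose
phase resolves into two or more discontinuous blocks are split into
per-block records that tile the transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PhasingParams
from .io import GeneReads


@dataclass
class Fragment:
    """Alleles observed by one read pair over >= 2 heterozygous sites."""

    name: str
    sites: np.ndarray    # site indices (into the transcript's het-site list), sorted
    alleles: np.ndarray  # 0 = reference allele, 1 = alternative

    def __post_init__(self) -> None:
        order = np.argsort(self.sites, kind="stable")
        self.sites = np.asarray(self.sites)[order]
        self.alleles = np.asarray(self.alleles)[order]
        if len(self.sites) != len(set(self.sites.tolist())):
            raise ValueError("fragment covers a site twice")


@dataclass
class PhaseBlock:
    transcript: str
    block_id: int
    site_positions: np.ndarray       # transcript coordinates, ascending
    ref_alleles: np.ndarray          # uint8 base codes
    alt_alleles: np.ndarray
    haplotype: np.ndarray            # 0/1 per site for haplotype 1; hap 2 is the complement
    mec: int
    n_fragments: int
    reference_concordance: float = np.nan
    labels: tuple[str, str] = ("unassigned", "unassigned")

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    @property
    def a_haplotype(self) -> np.ndarray | None:
        """0/1 vector of the A-labelled haplotype (None when unassigned)."""
        if self.labels[0] == "A":
            return self.haplotype
        if self.labels[1] == "A":
            return 1 - self.haplotype
        return None


@dataclass
class SplitRecord:
    """One (possibly split) homoeolog-specific sequence pair."""

    transcript: str
    block_id: int
    start: int
    end: int
    seq_a: np.ndarray
    seq_b: np.ndarray
    phased_positions: np.ndarray
    fixed_positions: np.ndarray

    @property
    def name_a(self) -> str:
        return f"{self.transcript}.block{self.block_id}.A"

    @property
    def name_b(self) -> str:
        return f"{self.transcript}.block{self.block_id}.B"


@dataclass
class HomoeologSequenceSet:
    transcript: str
    records: list[SplitRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# fragment construction

def build_fragments(reads: GeneReads, het_positions: np.ndarray,
                    ref_alleles: np.ndarray, alt_alleles: np.ndarray
                    ) -> tuple[list[Fragment], list[np.ndarray]]:
    """Extract per-pair fragments and the site-connectivity components.

    A base matching neither the reference nor the alternative allele of its
    site is recorded as a gap; mates disagreeing at a shared site also gap
    that site (conservative evidence handling). Fragments informative for
    fewer than two sites are discarded. Components are returned as sorted
    arrays of site indices; singleton sites are excluded.
    """
    het_positions = np.asarray(het_positions)
    n_sites = len(het_positions)
    per_pair: dict[int, dict[int, int]] = {}
    if reads.n_reads and n_sites:
        rl = reads.seq.shape[1]
        lo = np.searchsorted(het_positions, reads.start, side="left")
        hi = np.searchsorted(het_positions, reads.start + rl, side="left")
        for i in range(reads.n_reads):
            if hi[i] == lo[i]:
                continue
            pid = int(reads.pair_id[i])
            entry = per_pair.setdefault(pid, {})
            for s in range(lo[i], hi[i]):
                base = int(reads.seq[i, het_positions[s] - reads.start[i]])
                if base == int(ref_alleles[s]):
                    allele = 0
                elif base == int(alt_alleles[s]):
                    allele = 1
                else:
                    allele = -1  # gap
                if s in entry and entry[s] != allele:
                    entry[s] = -1  # mate conflict -> gap
                else:
                    entry.setdefault(s, allele)
    fragments = []
    for pid, entry in per_pair.items():
        sites = np.array([s for s, a in sorted(entry.items()) if a >= 0], dtype=np.int64)
        if len(sites) < 2:
            continue
        alleles = np.array([entry[s] for s in sites], dtype=np.int8)
        fragments.append(Fragment(name=f"p{pid}", sites=sites, alleles=alleles))

    parent = np.arange(n_sites)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for frag in fragments:
        root = find(int(frag.sites[0]))
        for s in frag.sites[1:]:
            r2 = find(int(s))
            if r2 != root:
                parent[r2] = root
    comps: dict[int, list[int]] = {}
    covered = set()
    for frag in fragments:
        covered.update(int(s) for s in frag.sites)
    for s in sorted(covered):
        comps.setdefault(find(s), []).append(s)
    components = [np.array(sorted(v)) for v in comps.values() if len(v) >= 2]
    components.sort(key=lambda c: int(c[0]))
    return fragments, components


# ---------------------------------------------------------------------------
# MEC optimisation

def mec_score(fragments: list[Fragment], haplotype: np.ndarray,
              site_index: dict[int, int] | None = None) -> int:
    """MEC of a haplotype assignment: sum over fragments of the smaller
    mismatch count against the haplotype and its complement."""
    total = 0
    for frag in fragments:
        idx = frag.sites if site_index is None else \
            np.array([site_index[int(s)] for s in frag.sites])
        h = haplotype[idx]
        m1 = int(np.count_nonzero(frag.alleles != h))
        total += min(m1, len(frag.sites) - m1)
    return total


def _dedupe(fragments: list[Fragment], site_index: dict[int, int]):
    patterns: dict[tuple, int] = {}
    for frag in fragments:
        key = (tuple(site_index[int(s)] for s in frag.sites), tuple(int(a) for a in frag.alleles))
        patterns[key] = patterns.get(key, 0) + 1
    return [(np.array(sites, dtype=np.int64), np.array(alleles, dtype=np.int8), count)
            for (sites, alleles), count in patterns.items()]


def _phase_exhaustive(unique_frags, n: int) -> tuple[np.ndarray, int]:
    # site 0 is fixed to allele 0: haplotypes are complementary, so half the
    # bipartition space is redundant
    masks = np.arange(1 << max(n - 1, 0), dtype=np.uint64)
    total = np.zeros(len(masks), dtype=np.int64)
    for sites, alleles, count in unique_frags:
        k = len(sites)
        m1 = np.zeros(len(masks), dtype=np.int64)
        for s, a in zip(sites, alleles):
            if s == 0:
                bit = np.zeros(len(masks), dtype=np.int64)
            else:
                bit = ((masks >> np.uint64(s - 1)) & np.uint64(1)).astype(np.int64)
            m1 += (bit != int(a)).astype(np.int64)
        total += count * np.minimum(m1, k - m1)
    best = int(np.argmin(total))
    hap = np.zeros(n, dtype=np.int8)
    for s in range(1, n):
        hap[s] = (best >> (s - 1)) & 1
    return hap, int(total[best])


def _phase_greedy(fragments: list[Fragment], sites: np.ndarray,
                  site_index: dict[int, int]) -> np.ndarray:
    """Spanning-tree majority-linkage seed for large blocks."""
    n = len(sites)
    # pairwise agreement weights: positive when two sites tend to share a
    # haplotype with equal alleles
    weights: dict[tuple[int, int], int] = {}
    for frag in fragments:
        loc = [site_index[int(s)] for s in frag.sites]
        for i in range(len(loc)):
            for j in range(i + 1, len(loc)):
                key = (min(loc[i], loc[j]), max(loc[i], loc[j]))
                agree = 1 if frag.alleles[i] == frag.alleles[j] else -1
                weights[key] = weights.get(key, 0) + agree
    # maximum spanning tree on |weight|
    edges = sorted(weights.items(), key=lambda kv: -abs(kv[1]))
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for (u, v), w in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            adj[u].append((v, w))
            adj[v].append((u, w))
    hap = np.full(n, -1, dtype=np.int8)
    for root in range(n):
        if hap[root] >= 0:
            continue
        hap[root] = 0
        stack = [root]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if hap[v] < 0:
                    hap[v] = hap[u] if w >= 0 else 1 - hap[u]
                    stack.append(v)
    return hap


def phase_block(fragments: list[Fragment], sites: np.ndarray,
                params: PhasingParams | None = None) -> tuple[np.ndarray, int]:
    """Resolve one connectivity component into a haplotype and its MEC.

    Returns (haplotype bits over ``sites`` in order, achieved MEC). The
    haplotype is normalised so its first site carries allele 0.
    """
    params = params or PhasingParams()
    sites = np.asarray(sites)
    n = len(sites)
    if n < 2:
        raise ValueError("a phase block needs at least two sites")
    site_index = {int(s): i for i, s in enumerate(sites)}
    block_frags = [f for f in fragments if int(f.sites[0]) in site_index]
    if n <= params.exhaustive_site_limit:
        hap, mec = _phase_exhaustive(_dedupe(block_frags, site_index), n)
    else:
        seeds = [_phase_greedy(block_frags, sites, site_index),
                 np.zeros(n, dtype=np.int8)]
        restart_rng = np.random.default_rng(n * 9973 + len(block_frags))
        seeds += [restart_rng.integers(0, 2, size=n).astype(np.int8)
                  for _ in range(8)]
        hap, mec = None, None
        for seed in seeds:
            cand, score = _local_search(block_frags, seed, site_index)
            if mec is None or score < mec:
                hap, mec = cand, score
            if mec == 0:
                break
        if hap[0] == 1:
            hap = 1 - hap
    return hap.astype(np.int8), int(mec)


def _local_search(fragments: list[Fragment], hap: np.ndarray,
                  site_index: dict[int, int]) -> tuple[np.ndarray, int]:
    """Hill climbing over single-site flips and suffix flips (segmental
    switch errors are the typical local optimum of single-flip search)."""
    hap = hap.copy()
    n = len(hap)
    mec = mec_score(fragments, hap, site_index)
    improved = True
    while improved:
        improved = False
        for s in range(n):
            hap[s] ^= 1
            trial = mec_score(fragments, hap, site_index)
            if trial < mec:
                mec, improved = trial, True
            else:
                hap[s] ^= 1
        for s in range(1, n):
            hap[s:] ^= 1
            trial = mec_score(fragments, hap, site_index)
            if trial < mec:
                mec, improved = trial, True
            else:
                hap[s:] ^= 1
    return hap, mec


# ---------------------------------------------------------------------------
# filtering, labelling, editing

def filter_and_label(block: PhaseBlock, params: PhasingParams | None = None
                     ) -> PhaseBlock | None:
    """Apply the MEC and reference-concordance filters and assign A/B labels.

    The reference haplotype pattern is all-reference (all zeros): the
    haplotype carrying >= ``min_reference_concordance`` reference alleles
    passes the filter, and is labelled A-genome when its match is >=
    ``min_subgenome_match`` (its complement is the B-genome). Ties or
    sub-threshold matches leave the block unlabelled (rejected or excluded
    from expression, respectively). Returns None on rejection.
    """
    params = params or PhasingParams()
    if block.mec > params.max_mec:
        return None
    match1 = float(np.mean(block.haplotype == 0))
    match2 = 1.0 - match1
    best = max(match1, match2)
    block.reference_concordance = best
    if best < params.min_reference_concordance:
        return None
    if best >= params.min_subgenome_match and match1 != match2:
        block.labels = ("A", "B") if match1 >= match2 else ("B", "A")
    else:
        block.labels = ("unassigned", "unassigned")
    return block


def edit_homoeolog_sequences(transcript: str, ref_codes: np.ndarray,
                             blocks: list[PhaseBlock],
                             fixed_sites: np.ndarray | None = None,
                             fixed_alts: np.ndarray | None = None
                             ) -> HomoeologSequenceSet:
    """Edit the reference into A/B homoeolog sequences, splitting between blocks.

    ``blocks`` are retained, labelled, non-overlapping blocks of this
    transcript; ``fixed_sites``/``fixed_alts`` are homozygous-alternative
    positions substituted identically in both outputs. With >= 2 blocks the
    transcript is split into per-block records whose regions abut at the
    midpoints between neighbouring blocks and tile the transcript.
    """
    L = len(ref_codes)
    fixed_sites = np.asarray(fixed_sites if fixed_sites is not None else [], dtype=np.int64)
    fixed_alts = np.asarray(fixed_alts if fixed_alts is not None else [], dtype=np.uint8)
    base = ref_codes.copy()
    if fixed_sites.size:
        base[fixed_sites] = fixed_alts

    out = HomoeologSequenceSet(transcript=transcript)
    blocks = sorted(blocks, key=lambda b: int(b.site_positions[0]))
    for i in range(1, len(blocks)):
        if blocks[i].site_positions[0] <= blocks[i - 1].site_positions[-1]:
            raise ValueError("overlapping phase blocks")

    if not blocks:
        if fixed_sites.size:
            out.records.append(SplitRecord(
                transcript=transcript, block_id=0, start=0, end=L,
                seq_a=base.copy(), seq_b=base.copy(),
                phased_positions=np.empty(0, dtype=np.int64),
                fixed_positions=fixed_sites,
            ))
        return out

    boundaries = [0]
    for i in range(1, len(blocks)):
        left_end = int(blocks[i - 1].site_positions[-1]) + 1
        right_start = int(blocks[i].site_positions[0])
        boundaries.append((left_end + right_start) // 2)
    boundaries.append(L)

    for i, block in enumerate(blocks):
        start, end = boundaries[i], boundaries[i + 1]
        seq_a = base[start:end].copy()
        seq_b = base[start:end].copy()
        a_hap = block.a_haplotype
        hap = a_hap if a_hap is not None else block.haplotype
        rel = block.site_positions - start
        a_allele = np.where(hap == 0, block.ref_alleles, block.alt_alleles)
        b_allele = np.where(hap == 0, block.alt_alleles, block.ref_alleles)
        seq_a[rel] = a_allele
        seq_b[rel] = b_allele
        out.records.append(SplitRecord(
            transcript=transcript, block_id=block.block_id,
            start=start, end=end, seq_a=seq_a, seq_b=seq_b,
            phased_positions=block.site_positions.copy(),
            fixed_positions=fixed_sites[(fixed_sites >= start) & (fixed_sites < end)],
        ))
    return out


def phase_transcript(transcript: str, reads: GeneReads,
                     het_positions: np.ndarray, ref_alleles: np.ndarray,
                     alt_alleles: np.ndarray,
                     params: PhasingParams | None = None) -> list[PhaseBlock]:
    """Fragments -> components -> phased, filtered, labelled blocks."""
    params = params or PhasingParams()
    fragments, components = build_fragments(reads, het_positions, ref_alleles, alt_alleles)
    blocks: list[PhaseBlock] = []
    pos_arr = np.asarray(het_positions)
    for block_id, comp in enumerate(components, start=1):
        hap, mec = phase_block(fragments, comp, params)
        block = PhaseBlock(
            transcript=transcript, block_id=block_id,
            site_positions=pos_arr[comp],
            ref_alleles=np.asarray(ref_alleles)[comp],
            alt_alleles=np.asarray(alt_alleles)[comp],
            haplotype=hap, mec=mec,
            n_fragments=sum(1 for f in fragments if int(f.sites[0]) in set(comp.tolist())),
        )
        kept = filter_and_label(block, params)
        if kept is not None:
            blocks.append(kept)
    return blocks
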