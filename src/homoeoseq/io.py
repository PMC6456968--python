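"""Readers and writers for the standard formats the pipeline touches.

Internal conventions: coordinates are 0-based, half-open; VCF emission and
ingestion convert to/from 1-based. Sequences are handled either as python
strings (interchange) or as uint8 code arrays with A,C,G,T -> 0..3
(computation). Tabular alignments default to the 12-column BLAST outfmt-6
order with identity as a percentage in [0, 100].
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed input file (carries the offending line number when known)."""


# ---------------------------------------------------------------------------
# sequence codes

_BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_LETTER = np.frombuffer(_BASES.encode(), dtype=np.uint8)
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array with A,C,G,T -> 0,1,2,3."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise FormatError(f"non-ACGT character {bad!r} in sequence")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return _LETTER[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{identifier: sequence}`` mapping.

    Identifiers must be unique; sequences are uppercased on read. An empty
    file (no records) is a format error.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA identifier {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for FASTA record {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str]) -> None:
    recs = (SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items())
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# tabular alignment hits (BLAST outfmt-6 and a minimal SAM subset)

@dataclass
class AlignmentHit:
    """One alignment hit in internal (0-based half-open) coordinates."""

    query: str
    subject: str
    identity: float          # percent, 0..100
    length: int              # alignment length in bp
    qstart: int              # 0-based inclusive
    qend: int                # exclusive
    sstart: int
    send: int
    strand: int = 1          # +1 forward, -1 reverse on the subject
    mismatches: int = 0
    gap_opens: int = 0
    evalue: float = 0.0
    bitscore: float = 0.0


_DIALECTS = ("blast-tab-12", "sam-min")


def read_alignment_table(path: str | os.PathLike, dialect: str = "blast-tab-12") -> list[AlignmentHit]:
    """Parse an alignment table into a hit list.

    ``blast-tab-12`` is the standard 12-column tabular layout (qseqid sseqid
    pident length mismatch gapopen qstart qend sstart send evalue bitscore);
    reverse-strand subject coordinates (start > end) are normalised to
    ascending with ``strand == -1``. ``sam-min`` reads a minimal SAM subset,
    skipping unmapped records; identity is derived from the NM tag when
    present.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "blast-tab-12":
        return _read_blast_tab(path)
    return _read_sam_hits(path)


def _read_blast_tab(path: str | os.PathLike) -> list[AlignmentHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, found {len(cols)}"
                )
            try:
                (q, s, pident, length, mism, gapo,
                 qs, qe, ss, se, ev, bits) = cols
                qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
                hit = AlignmentHit(
                    query=q, subject=s, identity=float(pident), length=int(length),
                    qstart=qs - 1, qend=qe,
                    sstart=min(ss, se) - 1, send=max(ss, se),
                    strand=1 if se >= ss else -1,
                    mismatches=int(mism), gap_opens=int(gapo),
                    evalue=float(ev), bitscore=float(bits),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def _read_sam_hits(path: str | os.PathLike) -> list[AlignmentHit]:
    hits = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            alen = rec.query_alignment_length
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            identity = 100.0 * (1.0 - nm / alen) if alen else 0.0
            hits.append(AlignmentHit(
                query=rec.query_name,
                subject=rec.reference_name,
                identity=identity,
                length=alen,
                qstart=rec.query_alignment_start,
                qend=rec.query_alignment_end,
                sstart=rec.reference_start,
                send=rec.reference_end,
                strand=-1 if rec.is_reverse else 1,
                mismatches=int(nm),
            ))
    return hits


# ---------------------------------------------------------------------------
# read alignments for the pipeline (gapless substitution-only dialect)

@dataclass
class GeneReads:
    """Gapless reads aligned to one transcript, as parallel arrays.

    ``seq`` and ``qual`` are (n_reads, read_length) uint8 arrays; ``start``
    holds 0-based leftmost positions; reads sharing a ``pair_id`` are mates.
    ``origin`` is the true subgenome of origin (0 = A, 1 = B) when known from
    simulation, else -1.
    """

    start: np.ndarray
    seq: np.ndarray
    qual: np.ndarray
    pair_id: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.origin is None:
            self.origin = np.full(len(self.start), -1, dtype=np.int8)

    @property
    def n_reads(self) -> int:
        return len(self.start)


@dataclass
class ReadSet:
    """All reads of one sample (variety x tissue), grouped by transcript."""

    variety: str
    tissue: str
    genes: dict[str, GeneReads]

    def n_pairs(self) -> int:
        return sum(int(g.pair_id.max()) + 1 if g.n_reads else 0 for g in self.genes.values())


_READS_TSV_HEADER = "transcript\tpair_id\tmate\tstart\tseq\tqual"


def write_reads_tsv(path: str | os.PathLike, readset: ReadSet) -> None:
    """Write a ReadSet in the internal TSV alignment dialect."""
    with open(path, "w") as fh:
        fh.write(f"# variety={readset.variety}\ttissue={readset.tissue}\n")
        fh.write(_READS_TSV_HEADER + "\n")
        for gene in sorted(readset.genes):
            gr = readset.genes[gene]
            order = np.lexsort((np.arange(gr.n_reads), gr.pair_id))
            mate_seen: dict[int, int] = {}
            for i in order:
                pid = int(gr.pair_id[i])
                mate = mate_seen.get(pid, 0) + 1
                mate_seen[pid] = mate
                qual = "".join(chr(q + 33) for q in gr.qual[i])
                fh.write(
                    f"{gene}\t{pid}\t{mate}\t{int(gr.start[i])}\t"
                    f"{codes_to_seq(gr.seq[i])}\t{qual}\n"
                )


def read_reads_tsv(path: str | os.PathLike) -> ReadSet:
    variety = tissue = ""
    per_gene: dict[str, list[tuple[int, int, str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split("\t"):
                    key, _, val = tok.strip().partition("=")
                    if key == "variety":
                        variety = val
                    elif key == "tissue":
                        tissue = val
                continue
            if line.startswith("transcript\t"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, found {len(cols)}")
            gene, pid, _mate, start, seq, qual = cols
            per_gene.setdefault(gene, []).append((int(pid), int(start), seq, qual))
    genes = {}
    for gene, rows in per_gene.items():
        starts = np.array([r[1] for r in rows], dtype=np.int64)
        seqs = np.vstack([seq_to_codes(r[2]) for r in rows])
        quals = np.vstack([
            np.frombuffer(r[3].encode("ascii"), dtype=np.uint8) - 33 for r in rows
        ]).astype(np.uint8)
        pids = np.array([r[0] for r in rows], dtype=np.int64)
        genes[gene] = GeneReads(start=starts, seq=seqs, qual=quals, pair_id=pids)
    return ReadSet(variety=variety, tissue=tissue, genes=genes)


def write_sam(path: str | os.PathLike, readset: ReadSet, reference_lengths: Mapping[str, int]) -> None:
    """Write a ReadSet as plain-text SAM (gapless alignments, full-length match CIGAR)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        tid = {name: i for i, name in enumerate(reference_lengths)}
        for gene in sorted(readset.genes):
            gr = readset.genes[gene]
            for i in range(gr.n_reads):
                a = pysam.AlignedSegment()
                a.query_name = f"{readset.variety}.{readset.tissue}.{gene}.p{int(gr.pair_id[i])}"
                a.query_sequence = codes_to_seq(gr.seq[i])
                a.reference_id = tid[gene]
                a.reference_start = int(gr.start[i])
                a.mapping_quality = 60
                a.cigarstring = f"{gr.seq.shape[1]}M"
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in gr.qual[i])
                )
                a.flag = 0
                out.write(a)


def write_fastq_pair(prefix: str | os.PathLike, readset: ReadSet) -> tuple[str, str]:
    """Write a ReadSet as a FASTQ pair; mate 2 is reverse-complemented.

    Within each pair the leftmost read is written as mate 1, matching the
    forward/reverse layout of a standard paired-end library.
    """
    p1, p2 = f"{prefix}_R1.fastq", f"{prefix}_R2.fastq"
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for gene in sorted(readset.genes):
            gr = readset.genes[gene]
            pairs: dict[int, list[int]] = {}
            for i in range(gr.n_reads):
                pairs.setdefault(int(gr.pair_id[i]), []).append(i)
            for pid in sorted(pairs):
                idx = sorted(pairs[pid], key=lambda i: int(gr.start[i]))
                if len(idx) != 2:
                    continue
                i1, i2 = idx
                name = f"{readset.variety}.{readset.tissue}.{gene}.p{pid}"
                q1 = "".join(chr(q + 33) for q in gr.qual[i1])
                q2 = "".join(chr(q + 33) for q in gr.qual[i2][::-1])
                f1.write(f"@{name}/1\n{codes_to_seq(gr.seq[i1])}\n+\n{q1}\n")
                f2.write(f"@{name}/2\n{codes_to_seq(revcomp_codes(gr.seq[i2]))}\n+\n{q2}\n")
    return p1, p2


# ---------------------------------------------------------------------------
# VCF

_GENOTYPE_TO_GT = {1: (1, 1), 2: (0, 1)}  # HOM_ALT, HET (codes from caller)


def write_vcf(path: str | os.PathLike, variants: Iterable[tuple[str, int, str, str, int, int, int]],
              reference_lengths: Mapping[str, int], sample: str) -> None:
    """Write variant rows (HET / HOM_ALT) as a single-sample VCF v4.2.

    ``variants`` yields (transcript, pos0, ref, alt, genotype_code, coverage,
    alt_count) tuples with 0-based positions; genotype codes follow
    :mod:`homoeoseq.caller` (1 = HOM_ALT, 2 = HET).
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Filtered read depth">')
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternative allele frequency">')
    for name, length in reference_lengths.items():
        header.add_line(f"##contig=<ID={name},length={int(length)}>")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for transcript, pos, ref, alt, geno, cov, alt_count in variants:
            rec = out.new_record(
                contig=transcript, start=int(pos), stop=int(pos) + 1,
                alleles=(ref, alt),
            )
            rec.info["AF"] = round(alt_count / cov, 6) if cov else 0.0
            rec.samples[sample]["GT"] = _GENOTYPE_TO_GT[int(geno)]
            rec.samples[sample]["DP"] = int(cov)
            out.write(rec)


def read_vcf(path: str | os.PathLike) -> list[tuple[str, int, str, str, int, int]]:
    """Read a single-sample VCF back to (transcript, pos0, ref, alt, genotype_code, DP) rows."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            gt = rec.samples[sample]["GT"]
            geno = 2 if set(gt) == {0, 1} else 1
            dp = rec.samples[sample]["DP"]
            rows.append((rec.contig, rec.start, rec.ref, rec.alts[0], geno, int(dp)))
    return rows
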