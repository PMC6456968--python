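"""Multi-variety genotype matrix and the five-way SNP taxonomy.

Every candidate position (non-reference in at least one variety, with
sufficient information — coverage >= 8 — in at least ``min_informative_varieties``)
is classified from its non-MISSING genotype cells:

* all HOM_ALT                      -> MISASSEMBLY (reference is wrong everywhere)
* all HET                          -> INTER_HOMOEOLOG (constitutive A/B difference)
* only homozygous, both present    -> SIMPLE (diploid, locus-specific behaviour)
* HET plus one homozygous class    -> HEMI (varietal variation on one subgenome)
* HET plus both homozygous classes -> MULTI_GENOTYPE

A *carrier* is any variety calling a non-reference nucleotide (HET or
HOM_ALT); carriers drive the frequency binning, rarity and array-candidate
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .caller import CallSet, Genotype
from .config import TaxonomyParams

CLASS_NAMES = ("SIMPLE", "HEMI", "INTER_HOMOEOLOG", "MULTI_GENOTYPE", "MISASSEMBLY")
VARIETAL_CLASSES = ("SIMPLE", "HEMI", "MULTI_GENOTYPE")


class ClassificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# matrix construction

def build_genotype_matrix(callsets: dict[str, CallSet],
                          reference: dict[str, np.ndarray],
                          params: TaxonomyParams | None = None) -> pd.DataFrame:
    """Assemble the positions x varieties genotype matrix from per-variety calls.

    Rows are positions where at least one variety made a supported
    non-reference call; cells are Genotype codes with MISSING wherever
    coverage < ``min_coverage``. Rows with fewer than
    ``min_informative_varieties`` non-MISSING cells are dropped. The
    returned frame carries a ``ref`` and majority ``alt`` allele column next
    to one int8 column per variety.
    """
    params = params or TaxonomyParams()
    varieties = list(callsets)
    rows_index, geno_rows, ref_col, alt_col = [], [], [], []
    transcripts = sorted(reference)
    for name in transcripts:
        ref_codes = reference[name]
        candidate = np.zeros(len(ref_codes), dtype=bool)
        for cs in callsets.values():
            g = cs.genotype[name]
            candidate |= (g == Genotype.HET) | (g == Genotype.HOM_ALT)
        positions = np.flatnonzero(candidate)
        if positions.size == 0:
            continue
        geno = np.stack([callsets[v].genotype[name][positions] for v in varieties], axis=1)
        cov = np.stack([callsets[v].coverage[name][positions] for v in varieties], axis=1)
        geno = np.where(cov < params.min_coverage, np.uint8(Genotype.MISSING), geno)
        informative = (geno != Genotype.MISSING).sum(axis=1)
        carriers = ((geno == Genotype.HET) | (geno == Genotype.HOM_ALT)).sum(axis=1)
        keep = (informative >= params.min_informative_varieties) & (carriers >= 1)
        for i in np.flatnonzero(keep):
            pos = int(positions[i])
            alts = [callsets[v].alt[name][pos] for v in varieties
                    if callsets[v].alt[name][pos] != 255]
            alt_code = int(np.bincount(alts).argmax()) if alts else 255
            rows_index.append((name, pos))
            geno_rows.append(geno[i])
            ref_col.append("ACGT"[ref_codes[pos]])
            alt_col.append("ACGT"[alt_code] if alt_code != 255 else "N")
    if not rows_index:
        df = pd.DataFrame(columns=["ref", "alt", *varieties])
        df.index = pd.MultiIndex.from_tuples([], names=["transcript", "pos"])
        return df
    df = pd.DataFrame(
        np.vstack(geno_rows).astype(np.int8),
        index=pd.MultiIndex.from_tuples(rows_index, names=["transcript", "pos"]),
        columns=varieties,
    )
    df.insert(0, "ref", ref_col)
    df.insert(1, "alt", alt_col)
    return df


def matrix_genotypes(matrix: pd.DataFrame) -> np.ndarray:
    """The int8 genotype block of a matrix frame (varieties only)."""
    cols = [c for c in matrix.columns if c not in ("ref", "alt")]
    return matrix[cols].to_numpy(dtype=np.int8)


# ---------------------------------------------------------------------------
# classification

def classify_position(row: np.ndarray) -> str:
    """Classify one genotype-matrix row (array of Genotype codes)."""
    row = np.asarray(row)
    informative = row[row != Genotype.MISSING]
    if informative.size == 0:
        raise ClassificationError("row has no informative cells")
    n_ref = int(np.count_nonzero(informative == Genotype.HOM_REF))
    n_alt = int(np.count_nonzero(informative == Genotype.HOM_ALT))
    n_het = int(np.count_nonzero(informative == Genotype.HET))
    if n_alt + n_het == 0:
        raise ClassificationError("row is homozygous reference everywhere (not a SNP)")
    n = informative.size
    if n_alt == n:
        return "MISASSEMBLY"
    if n_het == n:
        return "INTER_HOMOEOLOG"
    if n_het == 0:
        return "SIMPLE"                      # homozygous only, both classes present
    if n_ref > 0 and n_alt > 0:
        return "MULTI_GENOTYPE"
    return "HEMI"                            # HET plus exactly one homozygous class


def classify_matrix(matrix: pd.DataFrame,
                    params: TaxonomyParams | None = None) -> pd.DataFrame:
    """Vectorised classification, carriers, frequency, bin and rarity per row."""
    params = params or TaxonomyParams()
    geno = matrix_genotypes(matrix)
    n_ref = (geno == Genotype.HOM_REF).sum(axis=1)
    n_alt = (geno == Genotype.HOM_ALT).sum(axis=1)
    n_het = (geno == Genotype.HET).sum(axis=1)
    informative = n_ref + n_alt + n_het
    if np.any(n_alt + n_het == 0):
        raise ClassificationError("matrix contains all-reference rows")
    cls = np.empty(len(geno), dtype=object)
    cls[:] = "HEMI"
    cls[(n_het > 0) & (n_ref > 0) & (n_alt > 0)] = "MULTI_GENOTYPE"
    cls[n_het == 0] = "SIMPLE"
    cls[n_het == informative] = "INTER_HOMOEOLOG"
    cls[n_alt == informative] = "MISASSEMBLY"
    carriers = n_alt + n_het
    freq = carriers / informative
    bins = frequency_bin(freq, params)
    out = pd.DataFrame({
        "ref": matrix["ref"], "alt": matrix["alt"],
        "snp_class": cls,
        "carriers": carriers,
        "informative": informative,
        "frequency": freq,
        "bin": bins,
        "rare": carriers <= params.rare_max_carriers,
    }, index=matrix.index)
    return out


def snp_frequency(row: np.ndarray, params: TaxonomyParams | None = None) -> tuple[float, int]:
    """Non-reference frequency of one row and its histogram bin index.

    frequency = carriers / informative cells; the bin is the half-open
    interval ``[origin + k*width, origin + (k+1)*width)`` containing it
    (frequency 1.0 falls in the top bin).
    """
    params = params or TaxonomyParams()
    row = np.asarray(row)
    informative = row[row != Genotype.MISSING]
    carriers = int(np.count_nonzero(
        (informative == Genotype.HET) | (informative == Genotype.HOM_ALT)))
    freq = carriers / informative.size
    return freq, int(frequency_bin(np.asarray([freq]), params)[0])


def frequency_bin(freq: np.ndarray, params: TaxonomyParams) -> np.ndarray:
    k = np.floor((freq - params.bin_origin) / params.bin_width).astype(int)
    return np.clip(k, 0, params.n_bins - 1)


def bin_interval(k: int, params: TaxonomyParams | None = None) -> tuple[float, float]:
    params = params or TaxonomyParams()
    return (params.bin_origin + k * params.bin_width,
            params.bin_origin + (k + 1) * params.bin_width)


def is_rare(row: np.ndarray, params: TaxonomyParams | None = None) -> bool:
    """Rare iff the non-reference allele is carried by <= ``rare_max_carriers`` varieties."""
    params = params or TaxonomyParams()
    row = np.asarray(row)
    carriers = int(np.count_nonzero((row == Genotype.HET) | (row == Genotype.HOM_ALT)))
    if carriers == 0:
        raise ClassificationError("row has no carriers (not a SNP)")
    return carriers <= params.rare_max_carriers


# ---------------------------------------------------------------------------
# summaries and selection

def partition_summary(counts: dict[str, int]) -> pd.DataFrame:
    """Partition table (counts + percentages to 2 decimals) from class counts.

    Also exposes ``total`` and the varietal-SNP subtotal
    (SIMPLE + HEMI + MULTI_GENOTYPE) in ``DataFrame.attrs``.
    """
    total = sum(counts.values())
    rows = []
    for name in CLASS_NAMES:
        c = int(counts.get(name, 0))
        pct = round(100.0 * c / total, 2) if total else 0.0
        rows.append((name, c, pct))
    df = pd.DataFrame(rows, columns=["snp_class", "count", "percent"]).set_index("snp_class")
    df.attrs["total"] = total
    df.attrs["varietal_subtotal"] = sum(int(counts.get(n, 0)) for n in VARIETAL_CLASSES)
    return df


def summarize_partition(classified: pd.DataFrame) -> pd.DataFrame:
    """Partition table over a classified-row frame (output of classify_matrix)."""
    counts = classified["snp_class"].value_counts().to_dict()
    return partition_summary(counts)


def hemi_rarity_report(classified: pd.DataFrame,
                       params: TaxonomyParams | None = None) -> pd.DataFrame:
    """Rare vs non-rare counts per class (the non-rare HEMI count is reported
    independently of the MULTI_GENOTYPE partition row; the two statistics
    describe different things and are both emitted)."""
    params = params or TaxonomyParams()
    rows = []
    for name in CLASS_NAMES:
        sub = classified[classified["snp_class"] == name]
        rare = int(sub["rare"].sum())
        rows.append((name, len(sub), rare, len(sub) - rare))
    return pd.DataFrame(rows, columns=["snp_class", "count", "rare", "non_rare"]
                        ).set_index("snp_class")


def select_array_candidates(classified: pd.DataFrame,
                            params: TaxonomyParams | None = None) -> pd.DataFrame:
    """Genotyping-array candidates: SIMPLE or HEMI rows confirmed in at least
    ``selection_min_carriers`` varieties; constitutive (inter-homoeolog) and
    misassembly rows are excluded."""
    params = params or TaxonomyParams()
    mask = classified["snp_class"].isin(("SIMPLE", "HEMI")) \
        & (classified["carriers"] >= params.selection_min_carriers)
    return classified[mask]
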