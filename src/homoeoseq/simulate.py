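"""Synthetic allotetraploid (AABB) transcriptome generator.

The generator emulates the data structure of an inbred tetraploid-wheat
RNA-seq panel: per gene, a pair of homoeolog transcripts (A and B subgenome
copies) diverged by point substitutions; a panel of inbred varieties whose
reads all map onto a single assembled reference contig per gene, so that
constitutive A/B differences surface as heterozygous-looking calls; and
paired-end reads plus negative-binomial homoeolog-specific counts with a
configurable A/B expression bias across tissues.

Injected site classes (ground truth for the downstream classifier):

* ``inter_homoeolog`` — the divergent sites between the A and B copies;
  heterozygous in every variety.
* ``hemi`` — a varietal substitution on one subgenome in a carrier subset;
  carriers look heterozygous, non-carriers homozygous reference.
* ``simple`` — a varietal substitution on a gene whose B homoeolog is
  absent from all varieties (`single_copy` genes, the substitution-only
  realisation of a homoeolog-segment deletion), so reads behave diploid:
  carriers are homozygous alternative.
* ``multi_genotype`` — a hemi mechanism plus additional carriers homozygous
  for the alternative allele (substituted on both subgenomes).
* ``misassembly`` — the reference carries a base no variety has, so every
  variety is homozygous alternative.

Everything is deterministic given ``params.seed``; per-sample read sets are
re-derivable on demand (:meth:`SimulatedDataset.reads`), so the dataset
object stays small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .config import DEFAULT_VARIETIES, ConfigError
from .io import GeneReads, ReadSet

CLASS_NAMES = ("SIMPLE", "HEMI", "INTER_HOMOEOLOG", "MULTI_GENOTYPE", "MISASSEMBLY")

# genotype codes shared with the caller
HOM_REF, HOM_ALT, HET, MISSING = 0, 1, 2, 3


class ParameterError(ValueError):
    pass


@dataclass
class SimulationParams:
    """Study conditions for the synthetic panel.

    ``homoeolog_divergence`` is the per-bp substitution rate between the A
    and B copies (0.02 gives ~98% identity, inside the 95-100% band typical
    of wheat homoeologs). ``depth`` is mean coverage per homoeolog per
    sample. ``class_rates`` are per-bp injection rates for the varietal SNP
    classes; inter-homoeolog sites are the divergent sites themselves.
    ``carriers_distribution`` gives P(k carriers) for k = 1..n_varieties-1;
    the default is proportional to 1/k, making rare variants the most
    frequent class as observed in elite inbred panels.
    """

    n_genes: int = 200
    gene_length: tuple[int, int] = (500, 2000)
    homoeolog_divergence: float = 0.02
    n_varieties: int = 13
    class_rates: dict[str, float] = field(default_factory=lambda: {
        "simple": 0.006,
        "hemi": 0.006,
        "multi_genotype": 0.0015,
        "misassembly": 0.0008,
    })
    single_copy_fraction: float = 0.2
    carriers_distribution: tuple[float, ...] | None = None
    read_length: int = 100
    fragment_mean: float = 550.0
    fragment_sd: float = 40.0
    depth: float = 30.0
    base_error_rate: float = 0.001
    tissues: tuple[str, ...] = ("grain", "leaf", "root")
    expr_mean: float = 500.0
    expr_sigma: float = 0.5
    tissue_sigma: float = 0.5
    expr_dispersion: float = 0.05
    bias_fraction: float = 0.2
    bias_log2fc: float = 2.0
    varieties: tuple[str, ...] = DEFAULT_VARIETIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_varieties < 2:
            raise ParameterError("n_varieties must be >= 2")
        if len(self.varieties) != self.n_varieties:
            if self.varieties == DEFAULT_VARIETIES:
                # panel resized away from the default 13: synthesise names
                self.varieties = tuple(f"var{i + 1:02d}" for i in range(self.n_varieties))
            else:
                raise ParameterError("varieties length must equal n_varieties")
        if self.depth <= 0:
            raise ParameterError("depth must be > 0")
        if self.expr_dispersion <= 0:
            raise ParameterError("expr_dispersion must be > 0")
        if not (0.0 <= self.bias_fraction <= 1.0):
            raise ParameterError("bias_fraction must be in [0, 1]")
        rates = dict(self.class_rates)
        inter = rates.pop("inter_homoeolog", None)
        if inter is not None and abs(inter - self.homoeolog_divergence) > 1e-12:
            raise ParameterError(
                "class_rates['inter_homoeolog'] is an alias of homoeolog_divergence"
            )
        for name, rate in rates.items():
            if name not in ("simple", "hemi", "multi_genotype", "misassembly"):
                raise ParameterError(f"unknown class rate {name!r}")
            if not (0.0 <= rate <= 1.0):
                raise ParameterError(f"class rate {name} outside [0, 1]")
        self.class_rates = rates
        if not (0.0 <= self.homoeolog_divergence <= 1.0):
            raise ParameterError("homoeolog_divergence outside [0, 1]")
        if self.homoeolog_divergence > 0.05:
            warnings.warn(
                "homoeolog_divergence > 0.05 leaves the 95-100% identity band",
                UserWarning, stacklevel=2,
            )
        if self.fragment_mean < self.read_length:
            raise ParameterError("fragment_mean must be >= read_length")
        if self.gene_length[0] < 300:
            raise ParameterError("minimum gene length is 300 bp (assembly contig floor)")
        if self.carriers_distribution is not None:
            p = np.asarray(self.carriers_distribution, dtype=float)
            if len(p) > self.n_varieties:
                raise ParameterError("carriers_distribution longer than variety panel")
            if (p < 0).any() or p.sum() <= 0:
                raise ParameterError("carriers_distribution must be a sub-probability vector")

    def carrier_probs(self, k_max: int) -> np.ndarray:
        """Normalised P(number of carriers = 1..k_max)."""
        if self.carriers_distribution is None:
            p = 1.0 / np.arange(1, k_max + 1)
        else:
            p = np.asarray(self.carriers_distribution[:k_max], dtype=float)
        return p / p.sum()


@dataclass
class ClassSite:
    """One injected ground-truth site."""

    gene: str
    pos: int
    snp_class: str
    alt: int                       # alternative base code
    carriers: tuple[int, ...]      # variety indices carrying the alt allele
    subgenome: int = -1            # hemi/multi: which copy carries it (0=A,1=B)
    hom_carriers: tuple[int, ...] = ()  # multi: carriers homozygous-alt


@dataclass
class GeneTruth:
    name: str
    length: int
    single_copy: bool
    ref: np.ndarray                # assembled reference contig (uint8 codes)
    a_seq: np.ndarray              # true A-subgenome transcript
    b_seq: np.ndarray | None       # true B copy (None when deleted)
    divergent_sites: np.ndarray    # positions where A and B differ
    sites: list[ClassSite]

    def variety_haplotypes(self, variety_index: int) -> tuple[np.ndarray, np.ndarray | None]:
        """A and B transcript sequences carried by one variety (both chromosome
        copies of a subgenome are identical in an inbred line)."""
        a = self.a_seq.copy()
        b = None if self.b_seq is None else self.b_seq.copy()
        for site in self.sites:
            if site.snp_class == "MISASSEMBLY":
                continue  # varieties keep the true base; the reference differs
            if variety_index not in site.carriers:
                continue
            if site.snp_class == "SIMPLE":
                a[site.pos] = site.alt
            elif site.snp_class == "HEMI":
                (a if site.subgenome == 0 else b)[site.pos] = site.alt
            elif site.snp_class == "MULTI_GENOTYPE":
                if variety_index in site.hom_carriers:
                    a[site.pos] = site.alt
                    if b is not None:
                        b[site.pos] = site.alt
                else:
                    (a if site.subgenome == 0 else b)[site.pos] = site.alt
        return a, b


@dataclass
class SimulatedDataset:
    """Ground truth plus deterministic on-demand read generation."""

    params: SimulationParams
    genes: dict[str, GeneTruth]
    bias: pd.DataFrame            # index gene, columns: biased, log2_ratio, per-tissue ratio
    _hap_cache: dict = field(default_factory=dict, repr=False)

    @property
    def varieties(self) -> tuple[str, ...]:
        return self.params.varieties

    def truth_sites(self) -> pd.DataFrame:
        """All injected sites (including inter-homoeolog) as a tidy table."""
        rows = []
        for g in self.genes.values():
            for pos in g.divergent_sites:
                if not g.single_copy:
                    rows.append((g.name, int(pos), "INTER_HOMOEOLOG",
                                 ",".join(self.varieties)))
            for s in g.sites:
                rows.append((g.name, s.pos, s.snp_class,
                             ",".join(self.varieties[i] for i in s.carriers)))
        df = pd.DataFrame(rows, columns=["gene", "pos", "snp_class", "carriers"])
        return df.sort_values(["gene", "pos"], kind="stable").reset_index(drop=True)

    def expected_genotypes(self) -> pd.DataFrame:
        """Expected genotype-matrix rows ((gene, pos) x varieties) at infinite depth."""
        n = self.params.n_varieties
        index, rows, classes = [], [], []
        for g in self.genes.values():
            if not g.single_copy:
                for pos in g.divergent_sites:
                    index.append((g.name, int(pos)))
                    rows.append(np.full(n, HET, dtype=np.int8))
                    classes.append("INTER_HOMOEOLOG")
            for s in g.sites:
                geno = np.full(n, HOM_REF, dtype=np.int8)
                if s.snp_class == "MISASSEMBLY":
                    geno[:] = HOM_ALT
                elif s.snp_class == "SIMPLE":
                    geno[list(s.carriers)] = HOM_ALT
                elif s.snp_class == "HEMI":
                    geno[list(s.carriers)] = HET
                elif s.snp_class == "MULTI_GENOTYPE":
                    geno[list(s.carriers)] = HET
                    geno[list(s.hom_carriers)] = HOM_ALT
                index.append((g.name, s.pos))
                rows.append(geno)
                classes.append(s.snp_class)
        df = pd.DataFrame(
            np.vstack(rows),
            index=pd.MultiIndex.from_tuples(index, names=["gene", "pos"]),
            columns=list(self.varieties),
        )
        df["snp_class"] = classes
        return df.sort_index()

    def _haplotypes(self, gene: str, variety_index: int):
        key = (gene, variety_index)
        if key not in self._hap_cache:
            self._hap_cache[key] = self.genes[gene].variety_haplotypes(variety_index)
        return self._hap_cache[key]

    def tissue_ratio(self, gene: str, tissue: str) -> float:
        """True A:(A+B) expression fraction for a gene in a tissue."""
        lfc = float(self.bias.loc[gene, f"log2_ratio_{tissue}"])
        return 1.0 / (1.0 + 2.0 ** (-lfc))

    def reads(self, variety: str, tissue: str) -> ReadSet:
        """Simulate (deterministically) the paired-end reads of one sample."""
        return simulate_reads(self.params, self, variety, tissue)

    def reference(self) -> dict[str, str]:
        from .io import codes_to_seq
        return {g.name: codes_to_seq(g.ref) for g in self.genes.values()}


# ---------------------------------------------------------------------------
# gene construction

def simulate_homoeolog_pair(params: SimulationParams, gene_index: int,
                            length: int | None = None,
                            rng: np.random.Generator | None = None):
    """Draw one homoeolog transcript pair and its divergent-site list.

    Returns ``(a_seq, b_seq, divergent_positions)`` as code arrays; the
    expected per-gene identity is ``1 - homoeolog_divergence``.
    """
    if rng is None:
        rng = np.random.default_rng([params.seed, 11, gene_index])
    if length is None:
        length = int(rng.integers(params.gene_length[0], params.gene_length[1] + 1))
    if length < 300:
        raise ParameterError("gene length must be >= 300 bp")
    a = rng.integers(0, 4, size=length).astype(np.uint8)
    b = a.copy()
    div = np.flatnonzero(rng.random(length) < params.homoeolog_divergence)
    if div.size:
        b[div] = (a[div] + rng.integers(1, 4, size=div.size)) % 4
    return a, b, div


def _sample_positions(rng, length: int, rate: float, occupied: set[int]) -> list[int]:
    pos = np.flatnonzero(rng.random(length) < rate)
    return [int(p) for p in pos if int(p) not in occupied]


def _build_gene(params: SimulationParams, gene_index: int) -> GeneTruth:
    rng = np.random.default_rng([params.seed, 11, gene_index])
    name = f"gene{gene_index + 1:05d}"
    length = int(rng.integers(params.gene_length[0], params.gene_length[1] + 1))
    single_copy = bool(rng.random() < params.single_copy_fraction)
    a = rng.integers(0, 4, size=length).astype(np.uint8)
    b = a.copy()
    div = np.flatnonzero(rng.random(length) < params.homoeolog_divergence)
    if div.size:
        b[div] = (a[div] + rng.integers(1, 4, size=div.size)) % 4

    occupied: set[int] = set(int(p) for p in div)
    n = params.n_varieties
    sites: list[ClassSite] = []
    rates = params.class_rates

    def alt_for(base: int) -> int:
        return int((base + rng.integers(1, 4)) % 4)

    def draw_carriers(k_min: int = 1) -> tuple[int, ...]:
        k_max = n - 1
        probs = params.carrier_probs(k_max)
        k = int(rng.choice(np.arange(1, k_max + 1), p=probs))
        k = max(k, k_min)
        return tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))

    if single_copy:
        for pos in _sample_positions(rng, length, rates.get("simple", 0.0), occupied):
            occupied.add(pos)
            sites.append(ClassSite(name, pos, "SIMPLE", alt_for(a[pos]), draw_carriers()))
    else:
        for pos in _sample_positions(rng, length, rates.get("hemi", 0.0), occupied):
            occupied.add(pos)
            sites.append(ClassSite(
                name, pos, "HEMI", alt_for(a[pos]), draw_carriers(),
                subgenome=int(rng.integers(0, 2)),
            ))
        for pos in _sample_positions(rng, length, rates.get("multi_genotype", 0.0), occupied):
            occupied.add(pos)
            carriers = draw_carriers(k_min=2)
            n_hom = int(rng.integers(1, len(carriers)))
            hom = tuple(sorted(rng.choice(carriers, size=n_hom, replace=False).tolist()))
            sites.append(ClassSite(
                name, pos, "MULTI_GENOTYPE", alt_for(a[pos]), carriers,
                subgenome=int(rng.integers(0, 2)), hom_carriers=hom,
            ))
    # misassembly: the assembled reference carries a base nobody has
    ref = a.copy()
    for pos in _sample_positions(rng, length, rates.get("misassembly", 0.0), occupied):
        occupied.add(pos)
        true_base = int(a[pos])
        wrong = alt_for(true_base)
        ref[pos] = wrong
        # alt allele (what varieties carry, relative to the reference) = true base
        sites.append(ClassSite(name, pos, "MISASSEMBLY", true_base,
                               tuple(range(n))))
    sites.sort(key=lambda s: s.pos)
    return GeneTruth(
        name=name, length=length, single_copy=single_copy, ref=ref,
        a_seq=a, b_seq=None if single_copy else b,
        divergent_sites=div, sites=sites,
    )


def simulate_variety_panel(params: SimulationParams) -> SimulatedDataset:
    """Build the full ground-truth panel: genes, injected sites, expression bias."""
    genes = {}
    for i in range(params.n_genes):
        g = _build_gene(params, i)
        genes[g.name] = g
    bias = _draw_bias(params, list(genes))
    return SimulatedDataset(params=params, genes=genes, bias=bias)


def _draw_bias(params: SimulationParams, gene_names: list[str]) -> pd.DataFrame:
    rng = np.random.default_rng([params.seed, 23])
    n = len(gene_names)
    biased = rng.random(n) < params.bias_fraction
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    lfc = np.where(biased, sign * params.bias_log2fc, 0.0)
    df = pd.DataFrame({"biased": biased, "log2_ratio": lfc}, index=pd.Index(gene_names, name="gene"))
    for t in params.tissues:
        df[f"log2_ratio_{t}"] = lfc  # bias is constitutive across tissues
    return df


# ---------------------------------------------------------------------------
# reads

def simulate_reads(params: SimulationParams, data: SimulatedDataset,
                   variety: str, tissue: str) -> ReadSet:
    """Paired-end reads for one sample, with true-origin labels.

    Pair counts are Poisson around ``depth * length / read_length`` for a
    two-copy gene (half that for single-copy genes); the subgenome of origin
    is Bernoulli with the tissue's true A fraction; base errors are i.i.d.
    at ``base_error_rate`` and flagged with phred 10 (clean bases are
    phred 30).
    """
    if params.fragment_mean < params.read_length:
        raise ParameterError("fragment_mean must be >= read_length")
    v_idx = params.varieties.index(variety)
    t_idx = params.tissues.index(tissue)
    rl = params.read_length
    genes: dict[str, GeneReads] = {}
    for g_idx, (gname, g) in enumerate(data.genes.items()):
        rng = np.random.default_rng([params.seed, 37, v_idx, t_idx, g_idx])
        L = g.length
        copies = 1 if g.single_copy else 2
        lam = params.depth * L * copies / (2.0 * rl)
        n_pairs = int(rng.poisson(lam))
        if n_pairs == 0:
            genes[gname] = GeneReads(
                start=np.empty(0, dtype=np.int64),
                seq=np.empty((0, rl), dtype=np.uint8),
                qual=np.empty((0, rl), dtype=np.uint8),
                pair_id=np.empty(0, dtype=np.int64),
                origin=np.empty(0, dtype=np.int8),
            )
            continue
        if g.single_copy:
            origin_pair = np.zeros(n_pairs, dtype=np.int8)
        else:
            p_a = data.tissue_ratio(gname, tissue)
            origin_pair = (rng.random(n_pairs) >= p_a).astype(np.int8)  # 0=A, 1=B
        frag = rng.normal(params.fragment_mean, params.fragment_sd, size=n_pairs)
        frag = np.clip(np.rint(frag), rl, L).astype(np.int64)
        # pair placement is clipped into the transcript so per-base coverage
        # is ~uniform (terminal coverage ramps of real libraries are not
        # modelled; see the package methods note)
        start = rng.integers(-(frag - rl), L - rl + 1)
        s1 = np.clip(start, 0, L - rl)
        s2 = np.clip(start + frag - rl, 0, L - rl)
        a_hap, b_hap = data._haplotypes(gname, v_idx)
        haps = (a_hap,) if b_hap is None else (a_hap, b_hap)

        starts = np.empty(2 * n_pairs, dtype=np.int64)
        starts[0::2], starts[1::2] = s1, s2
        origin = np.repeat(origin_pair, 2)
        pair_id = np.repeat(np.arange(n_pairs, dtype=np.int64), 2)
        offs = np.arange(rl)
        seq = np.empty((2 * n_pairs, rl), dtype=np.uint8)
        for h_idx, hap in enumerate(haps):
            mask = origin == h_idx
            if mask.any():
                seq[mask] = hap[starts[mask, None] + offs]
        qual = np.full((2 * n_pairs, rl), 30, dtype=np.uint8)
        if params.base_error_rate > 0:
            total = seq.size
            n_err = rng.binomial(total, params.base_error_rate)
            if n_err:
                flat = rng.choice(total, size=n_err, replace=False)
                seq.ravel()[flat] = (seq.ravel()[flat] + rng.integers(1, 4, size=n_err)) % 4
                qual.ravel()[flat] = 10
        genes[gname] = GeneReads(start=starts, seq=seq, qual=qual,
                                 pair_id=pair_id, origin=origin)
    return ReadSet(variety=variety, tissue=tissue, genes=genes)


def merge_readsets(readsets: Iterable[ReadSet]) -> ReadSet:
    """Concatenate read sets (e.g. the three tissues of one variety)."""
    readsets = list(readsets)
    variety = readsets[0].variety
    genes: dict[str, GeneReads] = {}
    all_names = sorted({g for rs in readsets for g in rs.genes})
    for gname in all_names:
        parts = [rs.genes[gname] for rs in readsets if gname in rs.genes]
        offset, pids = 0, []
        for p in parts:
            pids.append(p.pair_id + offset)
            offset += int(p.pair_id.max()) + 1 if p.n_reads else 0
        genes[gname] = GeneReads(
            start=np.concatenate([p.start for p in parts]),
            seq=np.vstack([p.seq for p in parts]),
            qual=np.vstack([p.qual for p in parts]),
            pair_id=np.concatenate(pids),
            origin=np.concatenate([p.origin for p in parts]),
        )
    return ReadSet(variety=variety, tissue="pooled", genes=genes)


# ---------------------------------------------------------------------------
# counts

def simulate_counts(params: SimulationParams, data: SimulatedDataset | None = None,
                    n_replicates: int = 5):
    """Negative-binomial homoeolog counts over tissues x pseudo-replicates.

    Returns ``(counts, truth, depths)``: a DataFrame with rows indexed by
    (gene, block, subgenome) and columns (tissue, replicate); a per-gene
    truth table with the baseline mean and true log2(A/B); and the per-column
    sequencing-depth multipliers the counts were scaled by (recoverable via
    median-of-ratios size factors).
    """
    rng = np.random.default_rng([params.seed, 53])
    if data is not None:
        gene_names = list(data.genes)
        lfc = data.bias["log2_ratio"].to_numpy()
    else:
        gene_names = [f"gene{i + 1:05d}" for i in range(params.n_genes)]
        biased = rng.random(len(gene_names)) < params.bias_fraction
        sign = np.where(rng.random(len(gene_names)) < 0.5, 1.0, -1.0)
        lfc = np.where(biased, sign * params.bias_log2fc, 0.0)
    n_genes = len(gene_names)
    tissues = params.tissues
    n_cols = len(tissues) * n_replicates
    depths = rng.uniform(0.75, 1.25, size=n_cols)

    mu_log = np.log(params.expr_mean) - 0.5 * params.expr_sigma ** 2
    base = rng.lognormal(mu_log, params.expr_sigma, size=n_genes)
    tissue_fac = rng.lognormal(-0.5 * params.tissue_sigma ** 2, params.tissue_sigma,
                               size=(n_genes, len(tissues)))

    mean_a = base[:, None] * tissue_fac * 2.0 ** (lfc[:, None] / 2.0)
    mean_b = base[:, None] * tissue_fac * 2.0 ** (-lfc[:, None] / 2.0)

    cols = pd.MultiIndex.from_tuples(
        [(t, f"rep{r + 1}") for t in tissues for r in range(n_replicates)],
        names=["tissue", "group"],
    )
    col_tissue = np.repeat(np.arange(len(tissues)), n_replicates)

    def draw(mean_gt: np.ndarray) -> np.ndarray:
        mu = mean_gt[:, col_tissue] * depths[None, :]
        alpha = params.expr_dispersion
        if alpha < 1e-12:
            return rng.poisson(mu)
        size = 1.0 / alpha
        return rng.negative_binomial(size, size / (size + mu))

    counts_a = draw(mean_a)
    counts_b = draw(mean_b)
    index = pd.MultiIndex.from_tuples(
        [(g, "b1", s) for s in ("A", "B") for g in gene_names],
        names=["gene", "block", "subgenome"],
    )
    counts = pd.DataFrame(
        np.vstack([counts_a, counts_b]), index=index, columns=cols
    ).sort_index()
    truth = pd.DataFrame({
        "base_mean": base,
        "log2_ratio": lfc,
        "biased": lfc != 0.0,
    }, index=pd.Index(gene_names, name="gene"))
    return counts, truth, depths
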