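"""Parameter blocks for every pipeline stage, plus a flat text config format.

Each stage owns a frozen-ish dataclass of thresholds; `PipelineConfig`
bundles them and round-trips losslessly through a flat ``section.key=value``
text file so every threshold in a run is auditable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Mapping


class ConfigError(ValueError):
    pass


# Pseudo-replicate grouping of the 13 varieties used for expression testing:
# read counts are merged into five artificial replicates.
DEFAULT_REPLICATE_SCHEME: dict[str, tuple[str, ...]] = {
    "rep1": ("Altar84", "Capeiti8", "Claudio"),
    "rep2": ("Creso", "Edmore", "Kofa"),
    "rep3": ("Meridiano", "Neodur", "Saragolla"),
    "rep4": ("Strongfield", "Svevo"),
    "rep5": ("Valnova", "Yavaros79"),
}

DEFAULT_VARIETIES: tuple[str, ...] = tuple(
    v for group in DEFAULT_REPLICATE_SCHEME.values() for v in group
)


@dataclass
class CallerParams:
    """Quality-window and count filters for per-position variant calling.

    The window/quality/count defaults reproduce the CLC-style calling setup:
    an 11 bp quality window centred on the candidate base (at most 6 gaps +
    mismatches inside it, central phred >= 20, window mean >= 15), minimum
    filtered coverage 8, minimum variant frequency 10%, a 4-read absolute
    support floor, and a 1000-read support level at which the frequency
    requirement is waived. ``hom_frequency`` is the homozygous-alternative
    boundary; it is not part of the published setup and is exposed here,
    symmetric with the 10% heterozygote bound.
    """

    window_length: int = 11
    max_gap_mismatch: int = 6
    min_central_quality: int = 20
    min_average_quality: int = 15
    min_coverage: int = 8
    min_variant_frequency: float = 0.10
    sufficient_variant_count: int = 1000
    required_variant_count: int = 4
    hom_frequency: float = 0.90
    # SAM ingestion pre-filters (minimum similarity / aligned-length fraction)
    min_similarity: float = 0.8
    min_aligned_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.window_length % 2 == 0:
            raise ConfigError("window_length must be odd and positive")
        if not (0.0 < self.min_variant_frequency < self.hom_frequency <= 1.0):
            raise ConfigError("require 0 < min_variant_frequency < hom_frequency <= 1")
        if self.min_coverage < 1 or self.required_variant_count < 1:
            raise ConfigError("count thresholds must be positive")


@dataclass
class TaxonomyParams:
    """Thresholds for building the genotype matrix and classifying SNPs.

    ``min_informative_varieties`` defaults to 5 (the matrix-building rule);
    frequency-distribution reports use 7. A carrier is any variety calling a
    non-reference nucleotide (HET or HOM_ALT). The frequency histogram uses
    ``n_bins`` half-open bins of width ``bin_width`` starting at
    ``bin_origin`` (so bin 1 is [0.18, 0.31), the published worked example).
    """

    min_coverage: int = 8
    min_informative_varieties: int = 5
    rare_max_carriers: int = 1
    selection_min_carriers: int = 3
    n_bins: int = 7
    bin_origin: float = 0.05
    bin_width: float = 0.13

    def __post_init__(self) -> None:
        if self.min_informative_varieties < 1:
            raise ConfigError("min_informative_varieties must be >= 1")
        if self.bin_origin + self.n_bins * self.bin_width > 1.0 + self.bin_width + 1e-9:
            raise ConfigError("bin scheme extends past frequency 1")
        if self.bin_width <= 0 or self.n_bins < 1:
            raise ConfigError("bin_width must be > 0 and n_bins >= 1")


@dataclass
class PhasingParams:
    """Block retention and subgenome-labelling thresholds.

    Blocks are kept when the minimum-error-correction score is <= ``max_mec``
    and one haplotype matches the all-reference pattern at >=
    ``min_reference_concordance`` of its sites; that haplotype is labelled
    A-genome when its match is >= ``min_subgenome_match`` (the two 90% rules
    are one coherent criterion with separate knobs). Exhaustive bipartition
    search is used up to ``exhaustive_site_limit`` sites, a greedy +
    local-flip heuristic beyond.
    """

    max_mec: int = 10
    min_reference_concordance: float = 0.90
    min_subgenome_match: float = 0.90
    exhaustive_site_limit: int = 15

    def __post_init__(self) -> None:
        for name in ("min_reference_concordance", "min_subgenome_match"):
            v = getattr(self, name)
            if not (0.5 < v <= 1.0):
                raise ConfigError(f"{name} must be in (0.5, 1]")
        if self.max_mec < 0:
            raise ConfigError("max_mec must be >= 0")


@dataclass
class DEParams:
    """Differential-expression thresholds and the pseudo-replicate scheme."""

    glm_alpha: float = 0.001
    tissue_alpha: float = 0.01
    lfc_cap: float = 7.0
    multiple_testing_glm: str = "BH"
    multiple_testing_tissue: str = "Bonferroni"
    pseudo_replicate_scheme: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATE_SCHEME)
    )
    # total-count size above which the per-tissue exact test switches to a
    # normal approximation
    exact_test_limit: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("glm_alpha", "tissue_alpha"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ConfigError(f"{name} must be in (0, 1)")
        all_members = [v for g in self.pseudo_replicate_scheme.values() for v in g]
        if len(all_members) != len(set(all_members)):
            raise ConfigError("pseudo_replicate_scheme assigns a variety twice")
        if self.multiple_testing_glm != "BH" or self.multiple_testing_tissue != "Bonferroni":
            raise ConfigError("unsupported multiple-testing method")


@dataclass
class QCParams:
    """Assembly-completeness thresholds.

    A hit is accepted when any of the three length conditions holds (>=
    ``hit_contig_fraction`` of the contig, > ``hit_gene_fraction`` of the
    gene, or >= ``hit_min_length`` bp). ``a_identity_floor`` fixes "identity
    close to 100%" for A-subgenome hit assignment; B hits deviate at most
    ``b_identity_band`` percent from the known paired identity.
    """

    min_identity: float = 80.0
    hit_contig_fraction: float = 0.60
    hit_gene_fraction: float = 0.80
    hit_min_length: int = 200
    reconstructed_span: float = 0.80
    a_identity_floor: float = 99.0
    b_identity_band: float = 1.0
    copy_coverage_full: float = 0.80
    copy_presence_floor: float = 0.20

    def __post_init__(self) -> None:
        for name in ("hit_contig_fraction", "hit_gene_fraction",
                     "reconstructed_span", "copy_coverage_full"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must be in (0, 1]")
        for name in ("min_identity", "a_identity_floor"):
            if not (0.0 < getattr(self, name) <= 100.0):
                raise ConfigError(f"{name} must be in (0, 100]")


_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass
class PipelineConfig:
    caller: CallerParams = field(default_factory=CallerParams)
    taxonomy: TaxonomyParams = field(default_factory=TaxonomyParams)
    phasing: PhasingParams = field(default_factory=PhasingParams)
    de: DEParams = field(default_factory=DEParams)
    qc: QCParams = field(default_factory=QCParams)
    rng_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.log_level not in _LOG_LEVELS:
            raise ConfigError(f"log_level must be one of {_LOG_LEVELS}")

    # -- flat key=value serialisation ------------------------------------

    def to_text(self) -> str:
        lines = []
        for section in ("caller", "taxonomy", "phasing", "de", "qc"):
            block = getattr(self, section)
            for f in fields(block):
                lines.append(f"{section}.{f.name}={_format_value(getattr(block, f.name))}")
        lines.append(f"rng_seed={self.rng_seed}")
        lines.append(f"log_level={self.log_level}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        sections: dict[str, dict[str, str]] = {}
        top: dict[str, str] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected key=value")
            key, _, value = line.partition("=")
            key = key.strip()
            if "." in key:
                section, _, name = key.partition(".")
                sections.setdefault(section, {})[name] = value.strip()
            else:
                top[key] = value.strip()
        kwargs = {}
        for section, klass in (("caller", CallerParams), ("taxonomy", TaxonomyParams),
                               ("phasing", PhasingParams), ("de", DEParams), ("qc", QCParams)):
            raw = sections.get(section, {})
            block_kwargs = {}
            for f in fields(klass):
                if f.name in raw:
                    block_kwargs[f.name] = _parse_value(raw[f.name], f, klass)
            kwargs[section] = klass(**block_kwargs)
        return cls(
            rng_seed=int(top.get("rng_seed", 0)),
            log_level=top.get("log_level", "INFO"),
            **kwargs,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def read(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_text(fh.read())


def _format_value(value) -> str:
    if isinstance(value, dict):  # replicate scheme
        return ";".join(f"{g}:{'|'.join(members)}" for g, members in value.items())
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_value(raw: str, f: dataclasses.Field, klass) -> object:
    default = getattr(klass(), f.name)
    if isinstance(default, dict):
        scheme = {}
        for part in raw.split(";"):
            if not part:
                continue
            group, _, members = part.partition(":")
            scheme[group] = tuple(m for m in members.split("|") if m)
        return scheme
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


def scheme_members(scheme: Mapping[str, tuple[str, ...]]) -> list[str]:
    return [v for g in scheme.values() for v in g]
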