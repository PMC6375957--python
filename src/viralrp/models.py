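"""Core domain types shared by every pipeline stage.

Coordinate convention: every coordinate exposed by this package is 0-based,
half-open.  The only exceptions are ``DomainHit.ali_from``/``ali_to``, which
keep the 1-based inclusive convention of the HMMER per-domain table they come
from; conversion happens at the point of use.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

#: Canonical ecosystem labels, in reporting order.  Labels outside this list
#: are allowed and appended alphabetically in reports.
ECOSYSTEMS = ("aquatic", "animal-associated", "soil", "other", "unknown")

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file was syntactically valid text but violated the expected format."""


class ValidationError(ValueError):
    """A record violated a domain invariant (coordinates, counts, alphabet)."""


@dataclass
class ViralContig:
    """A viral genome fragment with its sample annotation."""

    contig_id: str
    sequence: str
    sample_id: str = ""
    ecosystem: str = "unknown"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValidationError(
                f"contig {self.contig_id}: invalid characters {sorted(bad)}"
            )

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


@dataclass
class GeneCall:
    """A protein-coding gene on a contig (0-based half-open span).

    The span includes the terminal stop codon when present; ``stop_trimmed``
    records that the trailing stop was removed from ``protein``.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str = ""
    stop_trimmed: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if (self.end - self.start) % 3 != 0:
            raise ValidationError(
                f"gene {self.gene_id}: span length not divisible by 3"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class DomainHit:
    """One profile-vs-protein match from a domain search table.

    ``ali_from``/``ali_to`` are 1-based inclusive protein coordinates, kept
    as printed by hmmsearch.
    """

    protein_id: str
    contig_id: str
    domain_name: str
    profile_accession: str
    e_value: float
    bit_score: float
    ali_from: int
    ali_to: int
    coverage_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValidationError(
                f"hit {self.protein_id}/{self.domain_name}: e_value must be > 0"
            )
        if self.ali_from > self.ali_to:
            raise ValidationError(
                f"hit {self.protein_id}/{self.domain_name}: ali_from > ali_to"
            )


@dataclass
class SnpRecord:
    """One biallelic polymorphic site on a contig (0-based position)."""

    contig_id: str
    pos: int
    ref_base: str
    alt_base: str
    coverage: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValidationError(
                f"SNP {self.contig_id}:{self.pos}: ref equals alt ({self.ref_base})"
            )
        if self.alt_count > self.coverage:
            raise ValidationError(
                f"SNP {self.contig_id}:{self.pos}: alt_count {self.alt_count} "
                f"exceeds coverage {self.coverage}"
            )
        if self.coverage < 0 or self.alt_count < 0:
            raise ValidationError(
                f"SNP {self.contig_id}:{self.pos}: negative counts"
            )


@dataclass
class PipelineConfig:
    """All thresholds of the screening / lifestyle / host / selection stages.

    Defaults follow the published screening procedure where one is stated
    (RP E-value 1e-5, S1 exclusion, integrase bit score 30, host p-value
    0.001, coverage >= 10x with >= 1 SNP); the SNP usability sub-thresholds
    and spacer-match stringency are package defaults and are echoed in every
    output header.
    """

    rp_evalue_max: float = 1e-5
    excluded_domains: frozenset = frozenset({"S1"})
    lifestyle_domains: frozenset = frozenset(
        {"Mu-transpos_C", "Phage_int_SAM_5", "Phage_integrase"}
    )
    lifestyle_bitscore_min: float = 30.0
    host_p_max: float = 0.001
    pnps_min_coverage: float = 10.0
    pnps_min_snps: int = 1
    snp_min_alt_reads: int = 4
    snp_min_alt_freq: float = 0.01
    kmer_order: int = 8
    kmer_pseudocount: float = 1.0
    spacer_min_len: int = 20
    spacer_max_mismatch: int = 1
    genetic_code: str = "Standard"
    identity_denominator: str = "query"  # or "alignment"
    coverage_rule: str = "mean"  # or "per_site"
    pnps_pseudocount: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.excluded_domains = frozenset(self.excluded_domains)
        self.lifestyle_domains = frozenset(self.lifestyle_domains)
        for name in (
            "rp_evalue_max",
            "lifestyle_bitscore_min",
            "pnps_min_coverage",
            "snp_min_alt_reads",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config: {name} must be strictly positive")
        for name in ("host_p_max", "snp_min_alt_freq"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"config: {name} must be in (0,1)")
        if self.kmer_order < 0:
            raise ValidationError("config: kmer_order must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["excluded_domains"] = sorted(self.excluded_domains)
        data["lifestyle_domains"] = sorted(self.lifestyle_domains)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class RpIdentity:
    """A ribosomal protein in the unified nomenclature.

    The leading lowercase letter marks the taxonomic range (b bacterial,
    e eukaryotic/archaeal, u universal); the capital letter the subunit
    (S small, L large).  Ribosome-associated factors such as HPF carry no
    prefix and map to subunit "other".
    """

    rp_name: str
    subunit: str = field(init=False)
    taxon_prefix: str = field(init=False)

    def __post_init__(self) -> None:
        name = self.rp_name
        if len(name) >= 2 and name[0] in "beu" and name[1] in "SL":
            self.taxon_prefix = name[0]
            self.subunit = "small" if name[1] == "S" else "large"
        else:
            self.taxon_prefix = "none"
            self.subunit = "other"


@dataclass
class RpDetection:
    """One confident ribosomal-protein detection on a viral contig."""

    hit: DomainHit
    rp: RpIdentity
    contig_id: str
    ecosystem: str = "unknown"


@dataclass
class LifestyleCall:
    """Temperate/lytic-presumed call for one contig with its evidence."""

    contig_id: str
    temperate: bool
    evidence: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.temperate != bool(self.evidence):
            raise ValidationError(
                f"lifestyle call {self.contig_id}: temperate flag inconsistent "
                "with evidence"
            )


@dataclass
class HostPrediction:
    """A host call for one contig.

    ``score`` is the spacer match count (method="spacer") or the mean
    per-nucleotide log-likelihood (method="kmer"); ``p_value`` is set for
    k-mer calls only.
    """

    contig_id: str
    host_id: Optional[str]
    method: str
    score: float
    p_value: Optional[float] = None
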