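"""Per-gene pN/pS from metagenomic SNPs.

pN/pS compares the density of observed non-synonymous polymorphisms per
non-synonymous site (pN) to synonymous polymorphisms per synonymous site
(pS) within the read population mapped to one gene.  A ratio below 1
indicates purifying selection on the protein; above 1, diversifying
selection or pseudogenization in progress.

Site counting is the unweighted Nei–Gojobori enumeration: at each codon
position, each of the three possible single-nucleotide substitutions is
classified against the genetic code, and the position contributes the
synonymous fraction (out of 3) to S and the complement to N, so that
N + S = 3 per sense codon.  Substitutions creating a stop codon count as
non-synonymous; the terminal stop codon is excluded throughout.  Counting
is carried out in exact rational arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence, Union

from Bio.Data import CodonTable

from .io import extract_cds
from .models import GeneCall, PipelineConfig, SnpRecord, ValidationError

log = logging.getLogger(__name__)

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _codon_to_aa(code_name: str) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_name[code_name]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@dataclass
class CodonSiteCounts:
    """Expected non-synonymous (N) and synonymous (S) sites of one CDS."""

    gene_id: str
    n_sites: Fraction
    s_sites: Fraction


@dataclass
class PnpsResult:
    """Per-gene pN/pS with inclusion bookkeeping.

    ``included`` records whether the gene passes the well-sampled rule
    (coverage and SNP-count thresholds); ``ratio`` is None when pS = 0, in
    which case ``exclusion_reason`` is ``zero_ps`` and the gene drops out
    of ratio aggregation even if otherwise included.
    """

    gene_id: str
    n_obs: int
    s_obs: int
    n_sites: Fraction
    s_sites: Fraction
    mean_coverage: float
    pn: Optional[Fraction]
    ps: Optional[Fraction]
    ratio: Optional[Fraction]
    included: bool
    exclusion_reason: str  # low_coverage | no_snps | zero_ps | none


@dataclass
class SelectionSummary:
    n_genes: int
    n_included: int
    n_ratio_defined: int
    mean_ratio: Optional[float]
    frac_le_threshold: Optional[float]
    ratio_threshold: float
    exclusion_counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Site counting and variant classification
# ---------------------------------------------------------------------------

def _check_cds(cds: str, code: Mapping[str, str], gene_id: str = "?") -> str:
    """Validate a CDS and return it with any terminal stop codon removed."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS {gene_id}: length not divisible by 3")
    bad = set(cds) - set(BASES)
    if bad:
        raise ValidationError(
            f"CDS {gene_id}: ambiguous or invalid bases {sorted(bad)}"
        )
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and code[codons[-1]] == "*":
        codons = codons[:-1]
    for i, codon in enumerate(codons):
        if code[codon] == "*":
            raise ValidationError(f"CDS {gene_id}: internal stop at codon {i}")
    return "".join(codons)


def codon_site_counts(cds: str, gene_id: str = "?",
                      code_name: str = "Standard") -> CodonSiteCounts:
    """Nei–Gojobori expected site counts by per-codon enumeration.

    Each codon position contributes (synonymous substitutions among the 3
    possible)/3 to S and the rest to N; stop-creating substitutions are
    non-synonymous; a terminal stop codon is excluded.
    """
    code = _codon_to_aa(code_name)
    sense = _check_cds(cds, code, gene_id)
    n = Fraction(0)
    s = Fraction(0)
    for i in range(0, len(sense), 3):
        codon = sense[i:i + 3]
        aa = code[codon]
        for pos in range(3):
            syn = sum(
                1 for b in BASES
                if b != codon[pos]
                and code[codon[:pos] + b + codon[pos + 1:]] == aa
            )
            s += Fraction(syn, 3)
            n += Fraction(3 - syn, 3)
    return CodonSiteCounts(gene_id=gene_id, n_sites=n, s_sites=s)


def classify_variant(cds: str, pos: int, alt: str,
                     code_name: str = "Standard") -> str:
    """Classify a single-nucleotide change in CDS frame.

    ``pos`` is 0-based on the coding strand of the CDS (terminal stop codon
    allowed but flagged by callers via position); returns "synonymous" or
    "nonsynonymous" — a change to or from a stop codon is non-synonymous.
    """
    cds = cds.upper()
    alt = alt.upper()
    if not (0 <= pos < len(cds)):
        raise ValidationError(f"variant position {pos} outside CDS (len {len(cds)})")
    if alt not in BASES:
        raise ValidationError(f"invalid alt base {alt!r}")
    if alt == cds[pos]:
        raise ValidationError(f"alt base equals reference at position {pos}")
    code = _codon_to_aa(code_name)
    ci = pos // 3 * 3
    codon = cds[ci:ci + 3]
    mutant = codon[:pos % 3] + alt + codon[pos % 3 + 1:]
    return "synonymous" if code[codon] == code[mutant] else "nonsynonymous"


# ---------------------------------------------------------------------------
# SNP usability and strand mapping
# ---------------------------------------------------------------------------

def call_usable_snps(snps: Sequence[SnpRecord], gene: GeneCall,
                     contig_seq: str, config: PipelineConfig
                     ) -> list[SnpRecord]:
    """Filter SNPs down to usable, in-gene, deduplicated sites.

    Keeps SNPs inside the gene span whose alternative allele is supported
    by at least ``snp_min_alt_reads`` reads at frequency at least
    ``snp_min_alt_freq``; at multiallelic sites only the record with the
    largest alt count is kept.  A reference base disagreeing with the
    contig is an error.
    """
    by_pos: dict[int, SnpRecord] = {}
    for snp in snps:
        if snp.contig_id != gene.contig_id:
            continue
        if not (gene.start <= snp.pos < gene.end):
            continue
        if snp.ref_base != contig_seq[snp.pos]:
            raise ValidationError(
                f"SNP at {snp.contig_id}:{snp.pos}: ref {snp.ref_base} "
                f"disagrees with contig base {contig_seq[snp.pos]}"
            )
        if snp.alt_count < config.snp_min_alt_reads:
            continue
        if snp.coverage == 0 or snp.alt_count / snp.coverage < config.snp_min_alt_freq:
            continue
        prev = by_pos.get(snp.pos)
        if prev is None or snp.alt_count > prev.alt_count:
            by_pos[snp.pos] = snp
    return [by_pos[p] for p in sorted(by_pos)]


def snp_in_cds_frame(snp: SnpRecord, gene: GeneCall) -> tuple[int, str]:
    """Map a contig-space SNP into (CDS position, CDS-strand alt base)."""
    if gene.strand == "+":
        return snp.pos - gene.start, snp.alt_base
    return gene.end - 1 - snp.pos, _COMP[snp.alt_base]


# ---------------------------------------------------------------------------
# Per-gene computation and aggregation
# ---------------------------------------------------------------------------

def compute_pnps(gene: GeneCall, usable_snps: Sequence[SnpRecord],
                 contig_seq: str, config: PipelineConfig,
                 coverage: Union[float, Mapping[int, int], None] = None
                 ) -> PnpsResult:
    """pN/pS for one gene from pre-filtered SNPs.

    ``coverage`` may be a gene-wide mean, a per-site map (averaged over the
    gene span under the default mean rule, or reduced by min under
    ``config.coverage_rule == "per_site"``), or None, in which case the
    mean coverage of the usable SNPs themselves is used (0 when there are
    none).  SNPs falling in the terminal stop codon are flagged and left
    out of the observed counts, mirroring their exclusion from the site
    denominators.
    """
    cds = extract_cds(gene, contig_seq)
    counts = codon_site_counts(cds, gene.gene_id, config.genetic_code)
    code = _codon_to_aa(config.genetic_code)
    sense_len = len(_check_cds(cds, code, gene.gene_id))

    n_obs = s_obs = 0
    for snp in usable_snps:
        pos, alt = snp_in_cds_frame(snp, gene)
        if pos >= sense_len:
            log.warning("gene %s: SNP in terminal stop codon ignored in counts",
                        gene.gene_id)
            continue
        kind = classify_variant(cds, pos, alt, config.genetic_code)
        if kind == "synonymous":
            s_obs += 1
        else:
            n_obs += 1

    if coverage is None:
        mean_cov = (sum(s.coverage for s in usable_snps) / len(usable_snps)
                    if usable_snps else 0.0)
    elif isinstance(coverage, Mapping):
        vals = [coverage.get(p, 0) for p in range(gene.start, gene.end)]
        mean_cov = (min(vals) if config.coverage_rule == "per_site"
                    else sum(vals) / len(vals))
    else:
        mean_cov = float(coverage)

    pseudo = 1 if config.pnps_pseudocount else 0
    pn = ps = ratio = None
    if counts.n_sites > 0:
        pn = Fraction(n_obs + pseudo) / counts.n_sites
    if counts.s_sites > 0:
        ps = Fraction(s_obs + pseudo) / counts.s_sites
    if pn is not None and ps is not None and ps > 0:
        ratio = pn / ps

    included = True
    reason = "none"
    if n_obs + s_obs < config.pnps_min_snps:
        included, reason = False, "no_snps"
    elif mean_cov < config.pnps_min_coverage:
        included, reason = False, "low_coverage"
    elif ratio is None:
        reason = "zero_ps"

    return PnpsResult(
        gene_id=gene.gene_id, n_obs=n_obs, s_obs=s_obs,
        n_sites=counts.n_sites, s_sites=counts.s_sites,
        mean_coverage=mean_cov, pn=pn, ps=ps, ratio=ratio,
        included=included, exclusion_reason=reason,
    )


def run_pnps(contigs: Mapping[str, str], genes: Sequence[GeneCall],
             snps: Sequence[SnpRecord], config: PipelineConfig
             ) -> list[PnpsResult]:
    """Full selection stage: filter SNPs and compute pN/pS for every gene."""
    by_contig: dict[str, list[SnpRecord]] = {}
    for snp in snps:
        by_contig.setdefault(snp.contig_id, []).append(snp)
    results = []
    for gene in genes:
        seq = contigs[gene.contig_id]
        usable = call_usable_snps(by_contig.get(gene.contig_id, []),
                                  gene, seq, config)
        results.append(compute_pnps(gene, usable, seq, config))
    log.info("pN/pS: %d genes, %d included",
             len(results), sum(r.included for r in results))
    return results


def aggregate_selection(results: Sequence[PnpsResult],
                        ratio_threshold: float = 0.20) -> SelectionSummary:
    """Dataset-level selection summary over well-sampled genes.

    The mean ratio and the fraction at or below ``ratio_threshold`` are
    taken over genes that are included and have a defined ratio (pS > 0).
    """
    defined = [r for r in results if r.included and r.ratio is not None]
    counts: dict[str, int] = {}
    for r in results:
        counts[r.exclusion_reason] = counts.get(r.exclusion_reason, 0) + 1
    mean_ratio = frac = None
    if defined:
        ratios = [float(r.ratio) for r in defined]
        mean_ratio = sum(ratios) / len(ratios)
        frac = sum(x <= ratio_threshold for x in ratios) / len(ratios)
    return SelectionSummary(
        n_genes=len(results),
        n_included=sum(r.included for r in results),
        n_ratio_defined=len(defined),
        mean_ratio=mean_ratio,
        frac_le_threshold=frac,
        ratio_threshold=ratio_threshold,
        exclusion_counts=counts,
    )
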