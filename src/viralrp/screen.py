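"""Ribosomal-protein screening: hit filtering, nomenclature, identity.

The screen keeps domain hits with an independent E-value at or below the
configured cutoff whose domain belongs to the shipped ribosomal-protein
profile list, and drops domains on the exclusion list.  The S1 domain is
excluded by default: it is repeated within bS1 and occurs in many
non-ribosomal RNA-binding proteins, so an S1 match alone is functionally
ambiguous.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .models import (
    DomainHit,
    PipelineConfig,
    RpDetection,
    RpIdentity,
    ValidationError,
)

log = logging.getLogger(__name__)

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@lru_cache(maxsize=1)
def load_rp_table() -> dict[str, str]:
    """The shipped domain-name -> unified-RP-name mapping (editable TSV)."""
    text = (resources.files("viralrp") / "data" / "rp_domains.tsv").read_text()
    table = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        domain, rp, _acc = line.split("\t")
        table[domain] = rp
    return table


def map_rp_name(domain_name: str,
                table: Optional[Mapping[str, str]] = None) -> RpIdentity:
    """Map a profile domain name to the unified ribosomal-protein identity."""
    table = table if table is not None else load_rp_table()
    if domain_name not in table:
        raise LookupError(
            f"unknown ribosomal-protein domain {domain_name!r}; known domains: "
            f"{sorted(table)}"
        )
    return RpIdentity(rp_name=table[domain_name])


def filter_rp_hits(hits: Sequence[DomainHit], config: PipelineConfig,
                   ecosystem_of: Optional[Mapping[str, str]] = None,
                   table: Optional[Mapping[str, str]] = None
                   ) -> list[RpDetection]:
    """Filter raw domain hits down to confident RP detections.

    Keeps hits with ``e_value <= rp_evalue_max`` whose domain is in the RP
    profile table and not excluded; hits on domains outside the table (for
    example lifestyle markers) are skipped and counted.  Order is stable.
    """
    table = table if table is not None else load_rp_table()
    detections = []
    n_unknown = n_excluded = n_evalue = 0
    for hit in hits:
        if hit.domain_name in config.excluded_domains:
            n_excluded += 1
            continue
        if hit.domain_name not in table:
            n_unknown += 1
            if hit.domain_name in config.lifestyle_domains:
                log.debug("skipping lifestyle-domain hit %s", hit.domain_name)
            else:
                log.warning("skipping hit on unknown domain %s", hit.domain_name)
            continue
        if hit.e_value > config.rp_evalue_max:
            n_evalue += 1
            continue
        eco = "unknown"
        if ecosystem_of is not None:
            eco = ecosystem_of.get(hit.contig_id, "unknown")
        detections.append(RpDetection(
            hit=hit, rp=map_rp_name(hit.domain_name, table),
            contig_id=hit.contig_id, ecosystem=eco,
        ))
    log.info(
        "RP screen: %d hits in, %d detections out "
        "(%d excluded-domain, %d above E-value %.3g, %d unknown-domain)",
        len(hits), len(detections), n_excluded, n_evalue, config.rp_evalue_max,
    )
    return detections


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(query: str, subject: str,
                      denominator: str = "query") -> float:
    """Percent identity between two proteins under global BLOSUM62 alignment.

    Identity is the number of identical aligned positions divided by the
    query length ("over the protein length", with the viral protein as
    query); ``denominator="alignment"`` divides by the alignment length
    instead.
    """
    query, subject = query.upper(), subject.upper()
    if not query or not subject:
        raise ValidationError("pairwise_identity: empty sequence")
    for name, seq in (("query", query), ("subject", subject)):
        bad = set(seq) - _AA
        if bad:
            raise ValidationError(
                f"pairwise_identity: non-amino-acid characters in {name}: "
                f"{sorted(bad)}"
            )
    alignment = _aligner().align(query, subject)[0]
    a, b = str(alignment[0]), str(alignment[1])
    identical = sum(x == y and x != "-" for x, y in zip(a, b))
    denom = len(query) if denominator == "query" else len(a)
    return 100.0 * identical / denom
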