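"""Temperate-phage flagging from lifestyle-marker domain hits.

A contig is called putatively temperate when it carries at least one hit on
an integrase/transposase marker domain (Mu-transpos_C, Phage_int_SAM_5 or
Phage_integrase by default) with a bit score at or above the threshold
(default 30).  Absence of such hits is a valid lytic-presumed call, not an
error: most virome contigs are genome fragments and integrase genes may
simply not be on the fragment.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from .models import DomainHit, LifestyleCall, PipelineConfig

log = logging.getLogger(__name__)


def flag_temperate(hits: Sequence[DomainHit], config: PipelineConfig,
                   contig_ids: Optional[Iterable[str]] = None
                   ) -> dict[str, LifestyleCall]:
    """Per-contig temperate calls from lifestyle-domain hits.

    ``contig_ids`` extends the output to contigs with no hits at all
    (called non-temperate); otherwise only contigs appearing in ``hits``
    are reported.
    """
    evidence: dict[str, list[DomainHit]] = {}
    universe = set(contig_ids) if contig_ids is not None else set()
    for hit in hits:
        universe.add(hit.contig_id)
        if (hit.domain_name in config.lifestyle_domains
                and hit.bit_score >= config.lifestyle_bitscore_min):
            evidence.setdefault(hit.contig_id, []).append(hit)
    calls = {
        cid: LifestyleCall(
            contig_id=cid,
            temperate=cid in evidence,
            evidence=evidence.get(cid, []),
        )
        for cid in sorted(universe)
    }
    n_temp = sum(c.temperate for c in calls.values())
    log.info(
        "lifestyle: %d contigs, %d temperate (bit score >= %s on %s)",
        len(calls), n_temp, config.lifestyle_bitscore_min,
        sorted(config.lifestyle_domains),
    )
    return calls
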