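"""Host prediction: CRISPR-spacer matching and k-mer Markov likelihood.

Spacer matching reports every placement of a spacer (both strands) on a
contig within a mismatch budget — a near-literal record of past infection.
The k-mer route trains an order-k Markov model per candidate host genome
(both strands, pseudocounted) and assigns a contig to the candidate with
the highest mean per-nucleotide log-likelihood; significance comes from a
Gaussian null fitted to the same contig's scores under decoy models, with a
one-sided upper-tail p-value.  Spacer evidence takes precedence over k-mer
evidence when both are available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import norm

from .models import HostPrediction, PipelineConfig, ValidationError, ViralContig

log = logging.getLogger(__name__)

_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3; anything else (N) as -1."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# CRISPR spacer matching
# ---------------------------------------------------------------------------

@dataclass
class SpacerMatch:
    host_id: str
    position: int  # 0-based start on the contig, forward coordinates
    strand: str
    mismatches: int


def match_spacers(spacers: Sequence[tuple[str, str]], contig: ViralContig,
                  max_mismatch: int = 1, min_len: int = 20
                  ) -> list[SpacerMatch]:
    """All placements of each spacer on the contig within the mismatch budget.

    Both orientations are scanned; N positions count as mismatches.  Spacers
    shorter than ``min_len`` are skipped with a warning.
    """
    ctg = encode(contig.sequence)
    matches: list[SpacerMatch] = []
    for host_id, spacer in spacers:
        if len(spacer) < min_len:
            log.warning(
                "spacer from %s shorter than %d nt (%d); skipped",
                host_id, min_len, len(spacer),
            )
            continue
        if len(spacer) > len(ctg):
            continue
        for strand, sp_seq in (("+", spacer.upper()),
                               ("-", reverse_complement(spacer))):
            sp = encode(sp_seq)
            windows = sliding_window_view(ctg, len(sp))
            mm = ((windows != sp) | (windows < 0)).sum(axis=1)
            for pos in np.nonzero(mm <= max_mismatch)[0]:
                matches.append(SpacerMatch(
                    host_id=host_id, position=int(pos), strand=strand,
                    mismatches=int(mm[pos]),
                ))
    return matches


# ---------------------------------------------------------------------------
# Order-k Markov host models
# ---------------------------------------------------------------------------

@dataclass
class HostKmerModel:
    """Order-k Markov model over {A,C,G,T}, trained on both genome strands.

    ``log_p`` has shape (4**order, 4): log P(next base | k-mer context).
    Contexts never observed fall back to the uniform distribution through
    the pseudocount.
    """

    host_id: str
    order: int
    log_p: np.ndarray
    pseudocount: float = 1.0


def _context_index(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Context indices and validity mask for transitions enc[i:i+k] -> enc[i+k]."""
    n = len(enc) - k
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    idx = np.zeros(n, dtype=np.int64)
    valid = enc[k:] >= 0
    for j in range(k):
        col = enc[j:j + n]
        idx = idx * 4 + np.maximum(col, 0)
        valid &= col >= 0
    return idx, valid


def train_kmer_model(host_id: str, genome: str, order: int = 8,
                     pseudocount: float = 1.0) -> HostKmerModel:
    """Train an order-k Markov model from a host genome (both strands)."""
    if order < 0:
        raise ValidationError("kmer order must be >= 0")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    if len(genome) <= 4 ** order:
        log.warning(
            "genome %s (%d nt) is short relative to 4^%d contexts; "
            "transition estimates will be dominated by the pseudocount",
            host_id, len(genome), order,
        )
    counts = np.zeros((4 ** order, 4), dtype=np.float64)
    enc = encode(genome)
    rc = np.where(enc[::-1] >= 0, 3 - enc[::-1], -1).astype(np.int8)
    for strand in (enc, rc):
        idx, valid = _context_index(strand, order)
        np.add.at(counts, (idx[valid], strand[order:][valid]), 1.0)
    p = counts + pseudocount
    p /= p.sum(axis=1, keepdims=True)
    return HostKmerModel(host_id=host_id, order=order, log_p=np.log(p),
                         pseudocount=pseudocount)


def score_contig(contig_seq: str, model: HostKmerModel) -> Optional[float]:
    """Mean per-nucleotide log-likelihood of the contig under the model.

    Positions whose context window or target base contains an ambiguous
    nucleotide are skipped; returns None when nothing is scoreable.
    """
    enc = encode(contig_seq)
    idx, valid = _context_index(enc, model.order)
    if not valid.any():
        return None
    return float(model.log_p[idx[valid], enc[model.order:][valid]].mean())


def predict_host_kmer(contig: ViralContig,
                      candidate_models: Sequence[HostKmerModel],
                      decoy_models: Sequence[HostKmerModel],
                      config: PipelineConfig) -> Optional[HostPrediction]:
    """Best-candidate host call with a decoy-Gaussian p-value.

    Requires at least 5 decoy models for a stable null; the call is made
    only when the one-sided tail probability of the best candidate score
    under the decoy Gaussian is at or below ``config.host_p_max``.
    """
    if len(decoy_models) < 5:
        log.warning("contig %s: fewer than 5 decoy models; no k-mer call",
                    contig.contig_id)
        return None
    cand_scores = [(m.host_id, score_contig(contig.sequence, m))
                   for m in candidate_models]
    cand_scores = [(h, s) for h, s in cand_scores if s is not None]
    if not cand_scores:
        log.warning("contig %s: no scoreable positions; no k-mer call",
                    contig.contig_id)
        return None
    best_host, best_score = max(cand_scores, key=lambda hs: hs[1])
    decoy_scores = [score_contig(contig.sequence, m) for m in decoy_models]
    decoy_scores = [s for s in decoy_scores if s is not None]
    if len(decoy_scores) < 5:
        return None
    mu = float(np.mean(decoy_scores))
    sd = float(np.std(decoy_scores, ddof=1))
    if sd <= 0 or not math.isfinite(sd):
        return None
    p_value = float(norm.sf((best_score - mu) / sd))
    if p_value > config.host_p_max:
        return None
    return HostPrediction(
        contig_id=contig.contig_id, host_id=best_host, method="kmer",
        score=best_score, p_value=p_value,
    )


# ---------------------------------------------------------------------------
# Combined prediction with spacer precedence
# ---------------------------------------------------------------------------

def predict_hosts(contigs: Sequence[ViralContig],
                  host_genomes: Sequence[tuple[str, str]],
                  spacers: Sequence[tuple[str, str]],
                  config: PipelineConfig,
                  decoy_genomes: Optional[Sequence[tuple[str, str]]] = None
                  ) -> dict[str, HostPrediction]:
    """Spacer-first host prediction for a set of contigs.

    A contig matched by at least one spacer is assigned the host with the
    most spacer matches (score = match count); remaining contigs fall back
    to the k-mer route.  When no decoy genomes are supplied, decoys are
    built by seeded per-nucleotide shuffles of the host genomes, which
    preserve composition but erase higher-order structure.
    """
    if decoy_genomes is None:
        rng = np.random.default_rng(config.rng_seed)
        decoy_genomes = [
            (f"decoy_{hid}", "".join(rng.permutation(list(genome))))
            for hid, genome in host_genomes
        ]
    models = [train_kmer_model(h, g, config.kmer_order, config.kmer_pseudocount)
              for h, g in host_genomes]
    decoys = [train_kmer_model(h, g, config.kmer_order, config.kmer_pseudocount)
              for h, g in decoy_genomes]
    predictions: dict[str, HostPrediction] = {}
    for contig in contigs:
        sp_matches = match_spacers(
            spacers, contig,
            max_mismatch=config.spacer_max_mismatch,
            min_len=config.spacer_min_len,
        )
        if sp_matches:
            per_host: dict[str, int] = {}
            for m in sp_matches:
                per_host[m.host_id] = per_host.get(m.host_id, 0) + 1
            host, count = max(per_host.items(), key=lambda kv: (kv[1], kv[0]))
            predictions[contig.contig_id] = HostPrediction(
                contig_id=contig.contig_id, host_id=host, method="spacer",
                score=float(count),
            )
            continue
        kmer = predict_host_kmer(contig, models, decoys, config)
        if kmer is not None:
            predictions[contig.contig_id] = kmer
    log.info("host prediction: %d/%d contigs assigned (p <= %g for k-mer)",
             len(predictions), len(contigs), config.host_p_max)
    return predictions
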