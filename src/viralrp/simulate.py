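"""Synthetic virome generator with ground truth.

Emulates the statistical structure of a virus–host metagenomic survey at
desk scale so every pipeline stage can be exercised against known truth:

* hosts are order-2 Markov nucleotide sources with Dirichlet-perturbed
  transition rows, so host assignment from k-mer composition is learnable;
* each phage contig is drawn from its true host's source (the genomic
  signature a real prophage/virulent phage shares with its host), with
  0–2 ribosomal-protein ORFs embedded at random positions and strands;
* RP and lifestyle-marker domain hits are emitted into an hmmsearch-style
  per-domain table, planted clear of the screening thresholds, alongside
  decoy rows (excluded S1 domains, above-threshold E-values, sub-threshold
  integrase bit scores) that a correct screen must reject;
* CRISPR spacers are literal 30-nt copies from phage into the true host's
  spacer set for a configurable fraction of contigs;
* polymorphism tables are generated per RP gene by proposal thinning under
  a target non-synonymous acceptance rate omega: candidate substitutions
  arise uniformly over (position, alt base), synonymous proposals are
  always accepted and non-synonymous ones with probability min(omega, 1)
  (for omega > 1 the thinning is applied to synonymous proposals instead),
  which makes omega identifiable from pN/pS without a full
  population-genetic model.

All randomness flows from a single seed; identical configurations and
seeds produce byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as vio
from .models import (
    DomainHit,
    GeneCall,
    SnpRecord,
    ValidationError,
    ViralContig,
)
from .pnps import BASES, _codon_to_aa
from .screen import load_rp_table

_LIFESTYLE_DOMAINS = ("Mu-transpos_C", "Phage_int_SAM_5", "Phage_integrase")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic virome.

    Defaults describe a small survey that is still informative for every
    stage: 10 hosts with 300 kb genome segments (ample training data for
    the order-8 host models), 50 phage contigs of 20 kb, roughly half of
    them carrying one ribosomal-protein gene of 100 sense codons (the
    detected viral RPs are small proteins, tens to ~100 aa), a 20%
    temperate fraction, strong purifying selection (omega 0.1, the regime
    observed for virus-carried RP genes), one candidate substitution per
    100 coding nucleotides, and 50x coverage.
    """

    n_hosts: int = 10
    n_contigs: int = 50
    contig_len_nt: int = 20_000
    host_genome_len: int = 300_000
    rp_gene_len_codons: int = 100
    p_rp: float = 0.5
    p_second_rp: float = 0.05
    p_temperate: float = 0.2
    p_decoy_hit: float = 0.5
    omega: float = 0.1
    snp_rate: float = 0.01
    mean_coverage: float = 50.0
    spacer_fraction: float = 0.5
    spacer_len: int = 30
    n_decoy_hosts: int = 8
    dirichlet_alpha: float = 3.0
    ecosystem_weights: dict = field(default_factory=lambda: {
        "aquatic": 0.5, "animal-associated": 0.3, "soil": 0.1, "other": 0.1,
    })
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_rp", "p_second_rp", "p_temperate", "p_decoy_hit",
                     "spacer_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"simulation config: {name} not in [0,1]")
        if self.omega < 0 or self.snp_rate < 0:
            raise ValidationError("simulation config: omega and snp_rate must be >= 0")
        if self.rp_gene_len_codons < 10:
            raise ValidationError(
                "simulation config: rp_gene_len_codons < 10 gives unstable "
                "site counts"
            )
        for name in ("n_hosts", "n_contigs", "contig_len_nt",
                     "host_genome_len"):
            if getattr(self, name) < 0:
                raise ValidationError(f"simulation config: {name} must be >= 0")


@dataclass
class SyntheticDataset:
    """A complete synthetic survey plus its ground truth."""

    contigs: list[ViralContig]
    genes: list[GeneCall]
    domain_hits: list[DomainHit]
    snps: list[SnpRecord]
    hosts: list[tuple[str, str]]
    decoy_hosts: list[tuple[str, str]]
    spacers: list[tuple[str, str]]
    truth_contigs: pd.DataFrame  # contig_id, host_id, temperate, rp_names, spacer_planted
    truth_genes: pd.DataFrame    # gene_id, contig_id, rp_name, omega
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Markov nucleotide sources
# ---------------------------------------------------------------------------

def _host_transition_rows(rng: np.random.Generator, alpha: float) -> np.ndarray:
    """Order-2 transition matrix (16 contexts x 4 bases) for one host."""
    return rng.dirichlet([alpha] * 4, size=16)


def sample_markov2(rows: np.ndarray, length: int,
                   rng: np.random.Generator) -> str:
    """Sample a nucleotide sequence from an order-2 Markov source."""
    if length <= 0:
        return ""
    cum = rows.cumsum(axis=1).tolist()
    u = rng.random(length)
    out = [int(rng.integers(4)), int(rng.integers(4))][:length]
    prev2, prev1 = (out + [0, 0])[0], (out + [0, 0])[1 if length > 1 else 0]
    for i in range(2, length):
        row = cum[prev2 * 4 + prev1]
        ui = u[i]
        b = 0 if ui < row[0] else 1 if ui < row[1] else 2 if ui < row[2] else 3
        out.append(b)
        prev2, prev1 = prev1, b
    return "".join(BASES[b] for b in out)


# ---------------------------------------------------------------------------
# ORF construction and SNP simulation
# ---------------------------------------------------------------------------

def random_orf(n_codons: int, rng: np.random.Generator,
               code_name: str = "Standard") -> str:
    """ATG + (n_codons - 1) random sense codons + one stop codon."""
    code = _codon_to_aa(code_name)
    sense = sorted(c for c, aa in code.items() if aa != "*")
    stops = sorted(c for c, aa in code.items() if aa == "*")
    body = [sense[int(rng.integers(len(sense)))] for _ in range(n_codons - 1)]
    return "ATG" + "".join(body) + stops[int(rng.integers(len(stops)))]


def simulate_snps(gene: GeneCall, cds: str, omega: float, snp_rate: float,
                  mean_coverage: float,
                  rng: np.random.Generator) -> list[SnpRecord]:
    """Polymorphisms for one gene under acceptance-thinned proposals.

    Proposals are uniform over (coding position, alt base) across the sense
    codons; synonymous proposals are accepted with probability 1 and
    non-synonymous with min(omega, 1) (roles swap for omega > 1).  Each
    accepted SNP receives coverage ~ Poisson(mean_coverage) and an alt read
    count ~ Binomial(coverage, f) with f uniform in [0.05, 0.5], keeping
    the contig consensus the major allele.  At most one SNP per site.
    Returned records are in contig coordinates on the contig strand.
    """
    code = _codon_to_aa("Standard")
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValidationError(f"gene {gene.gene_id}: CDS length not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    sense = codons[:-1] if codons and code[codons[-1]] == "*" else codons
    for i, codon in enumerate(sense):
        if code[codon] == "*":
            raise ValidationError(
                f"gene {gene.gene_id}: internal stop at codon {i}"
            )
    sense_len = 3 * len(sense)
    if sense_len == 0 or snp_rate == 0:
        return []

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    k = int(rng.poisson(snp_rate * sense_len))
    occupied: set[int] = set()
    records: list[SnpRecord] = []
    p_syn, p_non = (1.0, min(omega, 1.0)) if omega <= 1 else (1.0 / omega, 1.0)
    for _ in range(k):
        pos = int(rng.integers(sense_len))
        ref = cds[pos]
        alts = [b for b in BASES if b != ref]
        alt = alts[int(rng.integers(3))]
        if pos in occupied:
            continue
        ci = pos // 3 * 3
        codon = cds[ci:ci + 3]
        mutant = codon[:pos % 3] + alt + codon[pos % 3 + 1:]
        syn = code[codon] == code[mutant]
        if rng.random() >= (p_syn if syn else p_non):
            continue
        coverage = int(rng.poisson(mean_coverage))
        f = rng.uniform(0.05, 0.5)
        alt_count = int(rng.binomial(coverage, f)) if coverage > 0 else 0
        occupied.add(pos)
        if gene.strand == "+":
            contig_pos, ref_c, alt_c = gene.start + pos, ref, alt
        else:
            contig_pos = gene.end - 1 - pos
            ref_c, alt_c = comp[ref], comp[alt]
        records.append(SnpRecord(
            contig_id=gene.contig_id, pos=contig_pos,
            ref_base=ref_c, alt_base=alt_c,
            coverage=coverage, alt_count=alt_count,
        ))
    records.sort(key=lambda r: r.pos)
    return records


# ---------------------------------------------------------------------------
# Domain-hit fabrication
# ---------------------------------------------------------------------------

def _rp_hit(protein_id: str, contig_id: str, domain: str, prot_len: int,
            rng: np.random.Generator, accession: str) -> DomainHit:
    # planted well past the 1e-5 screen threshold
    e_value = 10.0 ** -rng.uniform(6.0, 30.0)
    ali_from = 1 + int(rng.integers(0, max(prot_len // 10, 1)))
    ali_to = prot_len - int(rng.integers(0, max(prot_len // 10, 1)))
    return DomainHit(
        protein_id=protein_id, contig_id=contig_id, domain_name=domain,
        profile_accession=accession, e_value=float(e_value),
        bit_score=float(rng.uniform(50, 200)),
        ali_from=ali_from, ali_to=max(ali_to, ali_from),
        coverage_frac=(max(ali_to, ali_from) - ali_from + 1) / prot_len,
    )


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic survey; deterministic given the seed."""
    rng = np.random.default_rng(config.rng_seed)
    rp_table = load_rp_table()
    rp_domains = sorted(d for d, rp in rp_table.items() if d != "S1")
    acc_of = _accessions()

    hosts: list[tuple[str, str]] = []
    host_rows = []
    for h in range(config.n_hosts):
        rows = _host_transition_rows(rng, config.dirichlet_alpha)
        host_rows.append(rows)
        hosts.append((f"host_{h:02d}",
                      sample_markov2(rows, config.host_genome_len, rng)))
    decoy_hosts = [
        (f"decoy_{d:02d}",
         sample_markov2(_host_transition_rows(rng, config.dirichlet_alpha),
                        config.host_genome_len, rng))
        for d in range(config.n_decoy_hosts)
    ]

    eco_labels = sorted(config.ecosystem_weights)
    eco_p = np.array([config.ecosystem_weights[k] for k in eco_labels])
    eco_p = eco_p / eco_p.sum() if eco_p.sum() > 0 else None

    contigs: list[ViralContig] = []
    genes: list[GeneCall] = []
    domain_hits: list[DomainHit] = []
    snps: list[SnpRecord] = []
    spacers: list[tuple[str, str]] = []
    truth_c = []
    truth_g = []

    for c in range(config.n_contigs):
        cid = f"contig_{c:04d}"
        host_idx = int(rng.integers(config.n_hosts)) if config.n_hosts else -1
        seq = sample_markov2(
            host_rows[host_idx] if host_idx >= 0
            else _host_transition_rows(rng, config.dirichlet_alpha),
            config.contig_len_nt, rng,
        )
        ecosystem = (str(rng.choice(eco_labels, p=eco_p))
                     if eco_p is not None else "unknown")
        contig = ViralContig(
            contig_id=cid, sequence=seq,
            sample_id=f"{ecosystem}_s1", ecosystem=ecosystem,
        )

        n_rp = 0
        if rng.random() < config.p_rp:
            n_rp = 2 if rng.random() < config.p_second_rp else 1
        gene_len = 3 * (config.rp_gene_len_codons + 1)  # incl. stop codon
        rp_names = []
        used_spans: list[tuple[int, int]] = []
        for g in range(n_rp):
            start = _free_slot(used_spans, contig.length_nt, gene_len, rng)
            if start is None:
                break
            used_spans.append((start, start + gene_len))
            strand = "+" if rng.random() < 0.5 else "-"
            orf = random_orf(config.rp_gene_len_codons, rng)
            insert = orf if strand == "+" else _revcomp(orf)
            seq = seq[:start] + insert + seq[start + gene_len:]
            gene = GeneCall(
                gene_id=f"{cid}_{g + 1}", contig_id=cid,
                start=start, end=start + gene_len, strand=strand,
            )
            domain = rp_domains[int(rng.integers(len(rp_domains)))]
            prot_len = config.rp_gene_len_codons
            domain_hits.append(_rp_hit(gene.gene_id, cid, domain, prot_len,
                                       rng, acc_of.get(domain, "PF99999")))
            rp_names.append(rp_table[domain])
            genes.append(gene)
            truth_g.append({
                "gene_id": gene.gene_id, "contig_id": cid,
                "rp_name": rp_table[domain], "omega": config.omega,
            })
            snps.extend(simulate_snps(
                gene, orf, config.omega, config.snp_rate,
                config.mean_coverage, rng,
            ))
        contig.sequence = seq
        for gene in genes:
            if gene.contig_id == cid and not gene.protein:
                gene.protein = vio.translate_gene(gene, seq)

        temperate = rng.random() < config.p_temperate
        if temperate:
            domain = _LIFESTYLE_DOMAINS[int(rng.integers(len(_LIFESTYLE_DOMAINS)))]
            domain_hits.append(DomainHit(
                protein_id=f"{cid}_int", contig_id=cid, domain_name=domain,
                profile_accession="PF00589", e_value=float(10.0 ** -rng.uniform(6, 20)),
                bit_score=float(rng.uniform(35, 120)),
                ali_from=1, ali_to=150, coverage_frac=0.9,
            ))
        elif rng.random() < 0.3:
            # sub-threshold integrase-like noise the lifestyle screen must reject
            domain = _LIFESTYLE_DOMAINS[int(rng.integers(len(_LIFESTYLE_DOMAINS)))]
            domain_hits.append(DomainHit(
                protein_id=f"{cid}_int", contig_id=cid, domain_name=domain,
                profile_accession="PF00589", e_value=float(10.0 ** -rng.uniform(1, 4)),
                bit_score=float(rng.uniform(10, 25)),
                ali_from=1, ali_to=80, coverage_frac=0.4,
            ))

        if n_rp == 0 and rng.random() < config.p_decoy_hit:
            # decoy rows that a correct RP screen rejects
            if rng.random() < 0.5:
                domain_hits.append(DomainHit(
                    protein_id=f"{cid}_x1", contig_id=cid, domain_name="S1",
                    profile_accession="PF00575",
                    e_value=float(10.0 ** -rng.uniform(8, 25)),
                    bit_score=float(rng.uniform(40, 150)),
                    ali_from=1, ali_to=70, coverage_frac=0.9,
                ))
            else:
                domain = rp_domains[int(rng.integers(len(rp_domains)))]
                domain_hits.append(DomainHit(
                    protein_id=f"{cid}_x1", contig_id=cid, domain_name=domain,
                    profile_accession=acc_of.get(domain, "PF99999"),
                    e_value=float(10.0 ** -rng.uniform(1.0, 4.5)),
                    bit_score=float(rng.uniform(5, 20)),
                    ali_from=1, ali_to=50, coverage_frac=0.5,
                ))

        spacer_planted = False
        if host_idx >= 0 and rng.random() < config.spacer_fraction \
                and contig.length_nt >= config.spacer_len:
            start = int(rng.integers(contig.length_nt - config.spacer_len + 1))
            spacer = contig.sequence[start:start + config.spacer_len]
            if rng.random() < 0.5:
                spacer = _revcomp(spacer)
            spacers.append((hosts[host_idx][0], spacer))
            spacer_planted = True

        contigs.append(contig)
        truth_c.append({
            "contig_id": cid,
            "host_id": hosts[host_idx][0] if host_idx >= 0 else "",
            "temperate": temperate,
            "rp_names": ",".join(rp_names),
            "n_rp": len(rp_names),
            "spacer_planted": spacer_planted,
            "ecosystem": ecosystem,
        })

    return SyntheticDataset(
        contigs=contigs, genes=genes, domain_hits=domain_hits, snps=snps,
        hosts=hosts, decoy_hosts=decoy_hosts, spacers=spacers,
        truth_contigs=pd.DataFrame(
            truth_c, columns=["contig_id", "host_id", "temperate", "rp_names",
                              "n_rp", "spacer_planted", "ecosystem"]),
        truth_genes=pd.DataFrame(
            truth_g, columns=["gene_id", "contig_id", "rp_name", "omega"]),
        config=config,
    )


def _free_slot(used: list[tuple[int, int]], contig_len: int, gene_len: int,
               rng: np.random.Generator, tries: int = 50) -> Optional[int]:
    if contig_len < gene_len:
        return None
    for _ in range(tries):
        start = int(rng.integers(contig_len - gene_len + 1))
        if all(start + gene_len <= s or start >= e for s, e in used):
            return start
    return None


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def _accessions() -> dict[str, str]:
    text = (Path(__file__).parent / "data" / "rp_domains.tsv").read_text()
    out = {}
    for line in text.splitlines()[1:]:
        if line.strip():
            domain, _rp, acc = line.split("\t")
            out[domain] = acc
    return out


# ---------------------------------------------------------------------------
# On-disk representation
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write the dataset in the formats the pipeline reads, plus truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vio.write_fasta([(c.contig_id, c.sequence) for c in dataset.contigs],
                    outdir / "contigs.fna")
    vio.write_gff3(dataset.genes, outdir / "genes.gff3")
    if dataset.genes:
        vio.write_fasta([(g.gene_id, g.protein) for g in dataset.genes
                         if g.protein],
                        outdir / "proteins.faa")
    plens = {g.gene_id: len(g.protein) for g in dataset.genes}
    vio.write_domtblout(dataset.domain_hits, outdir / "hits.domtblout", plens)
    vio.write_snp_table(dataset.snps, outdir / "snps.tsv")
    vio.write_fasta(dataset.hosts, outdir / "hosts.fna")
    if dataset.decoy_hosts:
        vio.write_fasta(dataset.decoy_hosts, outdir / "decoy_hosts.fna")
    if dataset.spacers:
        vio.write_fasta(
            [(f"{hid}|spacer_{i:04d}", s)
             for i, (hid, s) in enumerate(dataset.spacers)],
            outdir / "spacers.fna",
        )
    vio.write_metadata(dataset.contigs, outdir / "metadata.tsv")
    dataset.truth_contigs.to_csv(outdir / "truth_contigs.tsv", sep="\t",
                                 index=False)
    dataset.truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t",
                               index=False)
    cfg = dataclasses.asdict(dataset.config)
    import yaml

    with open(outdir / "simulation_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def read_spacers_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a spacer FASTA whose ids are ``<host_id>|<spacer_id>``."""
    return [(rid.split("|")[0], seq) for rid, seq in vio.read_fasta(path)]
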