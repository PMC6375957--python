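"""Readers and writers for the formats the pipeline touches.

All 1-based formats (GFF3, VCF POS, hmmsearch alignment columns) are
converted to the internal 0-based half-open convention at this boundary,
except the alignment columns of :class:`~viralrp.models.DomainHit`, which
retain the printed 1-based inclusive values for format fidelity.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    DomainHit,
    FormatError,
    GeneCall,
    SnpRecord,
    ValidationError,
    ViralContig,
)

log = logging.getLogger(__name__)

SNP_COLUMNS = ["contig", "pos", "ref", "alt", "coverage", "alt_count"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, uppercased sequence), ...]`` in file order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# GFF3 gene calls
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path,
              contigs: Optional[Mapping[str, str]] = None) -> list[GeneCall]:
    """Read CDS features from a GFF3 file as :class:`GeneCall` objects.

    Each CDS feature must carry an ``ID`` attribute; the seqid column names
    the parent contig.  When ``contigs`` (contig_id -> sequence) is given,
    the protein is translated from the spanned sequence with the terminal
    stop trimmed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        ids = feat.attributes.get("ID")
        if not ids:
            raise FormatError(f"{path}: CDS at {feat.seqid}:{feat.start} lacks ID")
        gene = GeneCall(
            gene_id=ids[0],
            contig_id=feat.seqid,
            start=feat.start - 1,  # GFF3 is 1-based inclusive
            end=feat.end,
            strand=feat.strand,
        )
        if contigs is not None:
            if gene.contig_id not in contigs:
                raise FormatError(
                    f"{path}: gene {gene.gene_id} references unknown contig "
                    f"{gene.contig_id}"
                )
            gene.protein = translate_gene(gene, contigs[gene.contig_id])
        genes.append(gene)
    return genes


def write_gff3(genes: Sequence[GeneCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig_id}\tviralrp\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )


def extract_cds(gene: GeneCall, contig_seq: str) -> str:
    """Return the coding sequence of a gene in reading-frame orientation."""
    if gene.end > len(contig_seq):
        raise ValidationError(
            f"gene {gene.gene_id}: span exceeds contig length {len(contig_seq)}"
        )
    sub = contig_seq[gene.start:gene.end]
    if gene.strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return sub


def translate_gene(gene: GeneCall, contig_seq: str) -> str:
    cds = extract_cds(gene, contig_seq)
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
        gene.stop_trimmed = True
    else:
        gene.stop_trimmed = False
    return prot


# ---------------------------------------------------------------------------
# hmmsearch per-domain table (domtblout)
# ---------------------------------------------------------------------------

# column indices in the 23-column per-domain table
_DOMTBL_MIN_COLS = 23


def _default_contig_of(protein_id: str) -> str:
    # prodigal-style protein ids: <contig>_<gene number>
    return protein_id.rsplit("_", 1)[0]


def parse_domtblout(path: str | Path,
                    contig_of: Optional[Mapping[str, str]] = None
                    ) -> list[DomainHit]:
    """Parse an hmmsearch ``--domtblout`` file into :class:`DomainHit` rows.

    No filtering is applied; the independent (per-domain) E-value and the
    per-domain bit score are taken.  ``contig_of`` maps protein ids to
    contig ids; without it, prodigal-style ids (``<contig>_<n>``) are
    assumed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _DOMTBL_MIN_COLS:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} columns, "
                    f"got {len(cols)}"
                )
            try:
                qlen = int(cols[5])
                hit = DomainHit(
                    protein_id=cols[0],
                    contig_id=(contig_of[cols[0]] if contig_of is not None
                               else _default_contig_of(cols[0])),
                    domain_name=cols[3],
                    profile_accession=cols[4],
                    e_value=float(cols[12]),
                    bit_score=float(cols[13]),
                    ali_from=int(cols[17]),
                    ali_to=int(cols[18]),
                    coverage_frac=(int(cols[16]) - int(cols[15]) + 1) / qlen
                    if qlen > 0 else 0.0,
                )
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
            hits.append(hit)
    log.info("parsed %d domain hits from %s", len(hits), path)
    return hits


def write_domtblout(hits: Sequence[DomainHit], path: str | Path,
                    protein_lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write hits in the hmmsearch per-domain tabular layout (one domain/row)."""
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  "
                 "acc description of target\n#\n")
        for h in hits:
            tlen = (protein_lengths or {}).get(h.protein_id, h.ali_to)
            qlen = max(h.ali_to, 1)
            fh.write(
                f"{h.protein_id} - {tlen} {h.domain_name} {h.profile_accession} "
                f"{qlen} {h.e_value:.2g} {h.bit_score:.1f} 0.0 1 1 "
                f"{h.e_value:.2g} {h.e_value:.2g} {h.bit_score:.1f} 0.0 "
                f"1 {qlen} {h.ali_from} {h.ali_to} {h.ali_from} {h.ali_to} "
                f"0.99 -\n"
            )


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """Read variant evidence from a TSV (0-based ``pos``) or a minimal VCF.

    The TSV dialect has header ``contig pos ref alt coverage alt_count``.
    Files ending in ``.vcf`` are parsed with pysam; POS is converted to
    0-based, coverage comes from ``INFO/DP`` and the alt read count from
    ``INFO/AO``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".vcf":
        return _read_snp_vcf(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(SnpRecord(
                contig_id=str(row.contig), pos=int(row.pos),
                ref_base=str(row.ref).upper(), alt_base=str(row.alt).upper(),
                coverage=int(row.coverage), alt_count=int(row.alt_count),
            ))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    return records


def _read_snp_vcf(path: Path) -> list[SnpRecord]:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for idx, rec in enumerate(vcf.fetch()):
            if not rec.alts:
                continue
            try:
                records.append(SnpRecord(
                    contig_id=rec.chrom, pos=rec.pos - 1,
                    ref_base=rec.ref.upper(), alt_base=rec.alts[0].upper(),
                    coverage=int(rec.info.get("DP", 0)),
                    alt_count=int(_scalar(rec.info.get("AO", 0))),
                ))
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}: record {idx}: {exc}") from exc
    return records


def _scalar(v):
    if isinstance(v, (tuple, list)):
        return v[0]
    return v


def write_snp_table(snps: Sequence[SnpRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.contig_id, s.pos, s.ref_base, s.alt_base, s.coverage, s.alt_count)
         for s in snps],
        columns=SNP_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Contig metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read per-contig metadata TSV (contig_id, sample_id, ecosystem)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("contig_id", "sample_id", "ecosystem"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    return {
        str(r.contig_id): (str(r.sample_id), str(r.ecosystem))
        for r in df.itertuples(index=False)
    }


def write_metadata(contigs: Sequence[ViralContig], path: str | Path) -> None:
    df = pd.DataFrame(
        [(c.contig_id, c.sample_id, c.ecosystem) for c in contigs],
        columns=["contig_id", "sample_id", "ecosystem"],
    )
    df.to_csv(path, sep="\t", index=False)
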