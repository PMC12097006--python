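"""Seek-mode candidate selection and per-protein annotation inputs.

Type 1 candidates are proteins with at least one hit against the seek
profile database (profile-HMM screening).  Type 2 candidates are the
remaining proteins with at least one alignment hit against the seek
filtered protein database at or below an E-value cutoff (1e-70 by
default, inclusive).  Type 3 is their union; the two sets are disjoint
by construction.

Also here: gene geometry (start/stop codon presence and contig-end
distances) from gene-caller output, best-hit family prediction with
the signed length difference against the family mean, literal motif
search with an X wildcard, and transmembrane/signal-peptide table
parsing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import IO, Iterable

from Bio.Seq import Seq

from .swissprot import FamilyRecord

logger = logging.getLogger(__name__)

DEFAULT_TYPE2_EVALUE = 1e-70
# Bacterial/archaeal translation table 11 codon sets.
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
DEFAULT_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_GENE_HEADER_RE = re.compile(r"^(?P<contig>.+)_(?P<start>\d+)_(?P<end>\d+)_(?P<strand>[+-])$")


@dataclass
class GeneCall:
    """One predicted gene with its contig geometry."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_seq: str
    nt_seq: str
    has_start_codon: bool
    has_stop_codon: bool
    dist_to_contig_start: int
    dist_to_contig_end: int


@dataclass(frozen=True)
class DomainHit:
    """One per-domain profile hit from a domain table."""

    protein_id: str
    profile_accession: str
    profile_short_name: str
    evalue: float
    bitscore: float
    ali_from: int
    ali_to: int


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise alignment hit (tabular alignment output)."""

    query_id: str
    subject_id: str
    pident: float
    evalue: float
    bitscore: float


@dataclass
class FamilyPrediction:
    """Family of a protein's best database hit, with length comparison."""

    predicted_family_name: str
    family_mean_length: float
    protein_length: int
    length_difference: float  # protein_length - family mean, signed


# ---------------------------------------------------------------------------
# Screening-output parsers
# ---------------------------------------------------------------------------

def parse_domtblout(stream: IO[str] | Iterable[str],
                    evalue_field: str = "domain") -> list[DomainHit]:
    """Parse a HMMER per-domain table (protein queries scanned against
    profiles).

    ``evalue_field`` selects the independent per-domain E-value
    (``"domain"``, default) or the full-sequence E-value (``"full"``).
    """
    if evalue_field not in ("domain", "full"):
        raise ValueError("evalue_field must be 'domain' or 'full'")
    hits: list[DomainHit] = []
    for line in stream:
        if line.startswith("#") or not line.strip():
            continue
        f = line.split()
        if len(f) < 19:
            logger.warning("skipping short domain-table line: %s", line.rstrip())
            continue
        evalue = float(f[12]) if evalue_field == "domain" else float(f[6])
        bitscore = float(f[13]) if evalue_field == "domain" else float(f[7])
        hits.append(DomainHit(
            protein_id=f[3],
            profile_accession=f[1].split(".")[0],
            profile_short_name=f[0],
            evalue=evalue,
            bitscore=bitscore,
            ali_from=int(f[17]),
            ali_to=int(f[18]),
        ))
    return hits


def parse_alignment_tabular(stream: IO[str] | Iterable[str]) -> list[AlignmentHit]:
    """Parse tabular alignment output with columns
    qseqid, sseqid, pident, evalue, bitscore."""
    hits: list[AlignmentHit] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 5:
            raise ValueError(f"alignment table line {lineno}: expected >=5 columns")
        hits.append(AlignmentHit(query_id=f[0], subject_id=f[1],
                                 pident=float(f[2]), evalue=float(f[3]),
                                 bitscore=float(f[4])))
    return hits


# ---------------------------------------------------------------------------
# Gene geometry
# ---------------------------------------------------------------------------

def parse_gene_header(header: str) -> tuple[str, int, int, str]:
    m = _GENE_HEADER_RE.match(header.split()[0])
    if m is None:
        raise ValueError(f"cannot parse gene header: {header!r}")
    return m.group("contig"), int(m.group("start")), int(m.group("end")), m.group("strand")


def annotate_gene_geometry(pred_fasta: Iterable[tuple[str, str]],
                           contigs: dict[str, str],
                           start_codons: frozenset[str] = DEFAULT_START_CODONS,
                           stop_codons: frozenset[str] = DEFAULT_STOP_CODONS,
                           ) -> list[GeneCall]:
    """Geometry annotation of gene-caller output.

    *pred_fasta* yields (header, protein sequence) pairs whose headers
    follow the ``contig_start_end_strand`` convention with 1-based
    inclusive contig coordinates.  Start/stop codon presence is judged
    on the oriented nucleotide gene (reverse complement for minus-strand
    genes); contig-end distances are ``start - 1`` and
    ``contig_length - end``.
    """
    calls: list[GeneCall] = []
    for header, protein_seq in pred_fasta:
        gene_id = header.split()[0]
        contig_id, start, end, strand = parse_gene_header(header)
        if contig_id not in contigs:
            raise ValueError(f"gene {gene_id}: unknown contig {contig_id!r}")
        contig_seq = contigs[contig_id]
        if start < 1 or end > len(contig_seq) or start > end:
            raise ValueError(
                f"gene {gene_id}: coordinates {start}..{end} exceed contig "
                f"{contig_id} (length {len(contig_seq)})")
        nt = contig_seq[start - 1:end].upper()
        if strand == "-":
            nt = str(Seq(nt).reverse_complement())
        calls.append(GeneCall(
            gene_id=gene_id, contig_id=contig_id, start=start, end=end,
            strand=strand, protein_seq=protein_seq, nt_seq=nt,
            has_start_codon=nt[:3] in start_codons,
            has_stop_codon=len(nt) >= 3 and nt[-3:] in stop_codons,
            dist_to_contig_start=start - 1,
            dist_to_contig_end=len(contig_seq) - end,
        ))
    return calls


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------

def select_type1(proteins: set[str], spd_hits: list[DomainHit]) -> set[str]:
    """Proteins with at least one profile hit (protein set 1)."""
    return {h.protein_id for h in spd_hits if h.protein_id in proteins}


def select_type2(proteins: set[str], set1: set[str],
                 sfpd_hits: list[AlignmentHit],
                 evalue_cutoff: float = DEFAULT_TYPE2_EVALUE) -> set[str]:
    """Profile-negative proteins with an alignment hit at or below the
    E-value cutoff (protein set 2); disjoint from set 1 by construction."""
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    return {h.query_id for h in sfpd_hits
            if h.query_id in proteins and h.query_id not in set1
            and h.evalue <= evalue_cutoff}


def select_type3(proteins: set[str], spd_hits: list[DomainHit],
                 sfpd_hits: list[AlignmentHit],
                 evalue_cutoff: float = DEFAULT_TYPE2_EVALUE,
                 ) -> tuple[set[str], set[str], set[str]]:
    """(set1, set2, union) under the type 1/2 rules."""
    set1 = select_type1(proteins, spd_hits)
    set2 = select_type2(proteins, set1, sfpd_hits, evalue_cutoff)
    return set1, set2, set1 | set2


# ---------------------------------------------------------------------------
# Family prediction
# ---------------------------------------------------------------------------

def best_hit(hits: list[AlignmentHit]) -> AlignmentHit | None:
    """Lowest E-value; ties broken by higher bitscore, then lexicographic
    subject id."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def predict_family(protein_id: str, swissprot_hits: list[AlignmentHit],
                   accession_to_family: dict[str, FamilyRecord],
                   protein_length: int) -> FamilyPrediction | None:
    """Family of the lowest-E-value database hit for *protein_id*, with
    the signed difference between the protein length and the family's
    mean member length.  None when no hit exists or the best hit's
    subject carries no family."""
    own = [h for h in swissprot_hits if h.query_id == protein_id]
    top = best_hit(own)
    if top is None:
        return None
    fam = accession_to_family.get(top.subject_id)
    if fam is None:
        return None
    return FamilyPrediction(
        predicted_family_name=fam.family_name,
        family_mean_length=fam.mean_length,
        protein_length=protein_length,
        length_difference=protein_length - fam.mean_length,
    )


# ---------------------------------------------------------------------------
# Motifs and topology
# ---------------------------------------------------------------------------

def find_motifs(protein_seq: str,
                motifs: list[str]) -> list[tuple[str, list[int]]]:
    """All (possibly overlapping) 1-based match positions of each motif.

    Motifs are literal amino-acid strings where ``X`` matches any
    residue; no other pattern syntax is supported, keeping matches
    auditable.  Only motifs with at least one match are reported.
    """
    seq = protein_seq.upper()
    out: list[tuple[str, list[int]]] = []
    for motif in motifs:
        if not motif:
            raise ValueError("empty motif pattern")
        pat = motif.upper()
        m = len(pat)
        positions = [i + 1 for i in range(len(seq) - m + 1)
                     if all(p == "X" or p == seq[i + j]
                            for j, p in enumerate(pat))]
        if positions:
            out.append((motif, positions))
    return out


def parse_topology(stream: IO[str] | Iterable[str]) -> dict[str, tuple[bool, int]]:
    """Parse a short-format topology table (ID, TM count, SP flag,
    prediction string) into protein id -> (signal_peptide, tm_count).
    Malformed rows are skipped with a warning."""
    out: dict[str, tuple[bool, int]] = {}
    for line in stream:
        line = line.strip()
        if not line or line.upper().startswith("SEQ"):
            continue
        f = line.split()
        if len(f) < 3:
            logger.warning("skipping malformed topology row: %s", line)
            continue
        try:
            tm = int(f[1])
        except ValueError:
            logger.warning("skipping malformed topology row: %s", line)
            continue
        out[f[0]] = (f[2].upper() == "Y", tm)
    return out


def passes_candidate_filter(has_domain_hit: bool, signal_peptide: bool,
                            best_pident: float | None,
                            max_pident: float = 80.0) -> bool:
    """Manual-triage predicate used for novel-enzyme shortlisting:
    domain evidence present, no signal peptide, and best database
    identity at or below *max_pident* percent (unknown identity
    passes)."""
    if not has_domain_hit or signal_peptide:
        return False
    return best_pident is None or best_pident <= max_pident
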