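"""Contig-binning taxonomy route.

Contigs longer than a cutoff are binned externally (embedding/clustering
binners); taxonomy is then inferred protein-by-protein: a protein must
score at least one hit against the taxonomy profile database (the
gate), after which the organisms on the header of its lowest-E-value
hit against the taxonomy filtered protein database become its taxa.
Each bin takes the taxon or taxa of maximum frequency over its
proteins, and is quantified as the fraction of preprocessed reads
mapping to its contigs.  A post-filter discards bins with more than one
species and merges same-species bins by summing relative abundances.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import IO, Iterable

from .krakenroute import parse_read_map
from .seek import AlignmentHit, DomainHit, best_hit
from .taxdb import Lineage, TaxDb

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONTIG_LEN = 1000

# A taxon is an NCBI taxid when resolvable, else the raw organism
# string; both count by identity.
Taxon = int | str


@dataclass
class BinAssignment:
    """One bin with its contigs, modal taxa and read-based abundance."""

    bin_id: str
    contig_ids: set[str]
    taxa: list[tuple[Taxon, int]] = field(default_factory=list)  # all tied at max freq
    mapped_reads: int = 0
    relative_abundance: float = 0.0


def filter_contigs_by_length(contigs: dict[str, str] | dict[str, int],
                             min_len: int = DEFAULT_MIN_CONTIG_LEN) -> set[str]:
    """Contig ids with length strictly greater than *min_len*.
    Values may be sequences or integer lengths."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    out: set[str] = set()
    for cid, v in contigs.items():
        length = v if isinstance(v, int) else len(v)
        if length > min_len:
            out.add(cid)
    return out


def read_bin_tsv(stream: IO[str] | Iterable[str]) -> dict[str, set[str]]:
    """Two-column contig_id<TAB>bin_id map -> bin_id: contig set."""
    bins: dict[str, set[str]] = defaultdict(set)
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 2:
            raise ValueError(f"bin map line {lineno}: expected 2 columns")
        bins[f[1]].add(f[0])
    return dict(bins)


# ---------------------------------------------------------------------------
# Protein-level taxa
# ---------------------------------------------------------------------------

def protein_taxa(tpd_hits: list[DomainHit], tfpd_hits: list[AlignmentHit],
                 header_index: dict[str, list[str]],
                 taxdb: TaxDb | None = None) -> dict[str, list[Taxon]]:
    """Taxa per protein under the two-stage gate.

    A protein needs at least one profile hit (TPD) and at least one
    filtered-database hit (TFPD); it then inherits every organism on
    the header of its best TFPD hit (lowest E-value; ties by higher
    bitscore then lexicographic subject id), each contributing
    frequency 1.  Organisms resolvable in the taxonomy database become
    taxids; the rest stay as name strings and are logged.
    """
    gated = {h.protein_id for h in tpd_hits}
    by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in tfpd_hits:
        by_query[h.query_id].append(h)
    out: dict[str, list[Taxon]] = {}
    for pid, hits in by_query.items():
        if pid not in gated:
            continue
        top = best_hit(hits)
        organisms = header_index.get(top.subject_id, [])
        taxa: list[Taxon] = []
        for org in organisms:
            taxid = taxdb.resolve_name(org) if taxdb is not None else None
            if taxid is None:
                logger.info("organism %r unresolved; keeping as name taxon", org)
                taxa.append(org)
            else:
                taxa.append(taxid)
        if taxa:
            out[pid] = taxa
    return out


def assign_bin_taxa(bin_contigs: set[str],
                    gene_index: dict[str, list[str]],
                    protein_taxa_map: dict[str, list[Taxon]],
                    ) -> list[tuple[Taxon, int]]:
    """Modal taxa of one bin: count every taxon over the bin's
    proteins and return ALL taxa tied at the maximum frequency (empty
    when no protein carries taxa)."""
    counts: Counter[Taxon] = Counter()
    for contig in bin_contigs:
        for pid in gene_index.get(contig, []):
            counts.update(protein_taxa_map.get(pid, []))
    if not counts:
        return []
    top = max(counts.values())
    winners = [(t, n) for t, n in counts.items() if n == top]
    winners.sort(key=lambda tn: str(tn[0]))
    return winners


def build_bin_assignments(bins: dict[str, set[str]],
                          gene_index: dict[str, list[str]],
                          protein_taxa_map: dict[str, list[Taxon]],
                          ) -> list[BinAssignment]:
    """BinAssignment records (taxa only; quantify separately)."""
    return [BinAssignment(bin_id=bid, contig_ids=set(contigs),
                          taxa=assign_bin_taxa(contigs, gene_index,
                                               protein_taxa_map))
            for bid, contigs in sorted(bins.items())]


# ---------------------------------------------------------------------------
# Quantification and post-filtering
# ---------------------------------------------------------------------------

def quantify_bins(bins: list[BinAssignment], sam_path,
                  total_preprocessed_reads: int) -> list[BinAssignment]:
    """Fill each bin's mapped read count (primary alignments to its
    contigs) and relative abundance against the preprocessed-read
    total.  Reads mapping to contigs outside every bin count toward no
    bin."""
    if total_preprocessed_reads <= 0:
        raise ValueError("total_preprocessed_reads must be positive")
    contig_to_bin: dict[str, BinAssignment] = {}
    for b in bins:
        b.mapped_reads = 0
        for cid in b.contig_ids:
            contig_to_bin[cid] = b
    for _read, contig in parse_read_map(sam_path):
        b = contig_to_bin.get(contig)
        if b is not None:
            b.mapped_reads += 1
    for b in bins:
        b.relative_abundance = b.mapped_reads / total_preprocessed_reads
    return bins


@dataclass
class SpeciesReportRow:
    """Post-filtered species with its merged bins and summed abundance."""

    taxon: Taxon
    name: str
    rank: str
    bin_ids: list[str]
    relative_abundance: float


def postfilter_merge(bins: list[BinAssignment], rank: str = "species",
                     taxdb: TaxDb | None = None) -> list[SpeciesReportRow]:
    """Post-filter and merge quantified bins at one rank.

    Bins assigned more than one taxon at *rank* are discarded; the
    remaining bins group by taxon, and a taxon spanning several bins
    receives the sum of their relative abundances (the bins are
    "merged").  Taxa at other ranks pass through with their rank label
    preserved.
    """
    groups: dict[Taxon, list[BinAssignment]] = defaultdict(list)
    for b in bins:
        taxa = [t for t, _ in b.taxa]
        if not taxa:
            continue
        at_rank = [t for t in taxa if _rank_of(t, taxdb) == rank]
        if len(at_rank) > 1:
            continue  # ambiguous at the target rank: discard the bin
        if len(taxa) > 1 and not at_rank:
            continue
        target = at_rank[0] if at_rank else taxa[0]
        groups[target].append(b)
    rows: list[SpeciesReportRow] = []
    for taxon in sorted(groups, key=str):
        members = groups[taxon]
        rows.append(SpeciesReportRow(
            taxon=taxon,
            name=(taxdb.name.get(taxon, str(taxon))
                  if taxdb is not None and isinstance(taxon, int) else str(taxon)),
            rank=_rank_of(taxon, taxdb),
            bin_ids=sorted(b.bin_id for b in members),
            relative_abundance=sum(b.relative_abundance for b in members),
        ))
    return rows


def _rank_of(taxon: Taxon, taxdb: TaxDb | None) -> str:
    if taxdb is not None and isinstance(taxon, int) and taxon in taxdb:
        return taxdb.rank.get(taxon, "no rank")
    # Name-only taxa default to species: the report still carries them.
    return "species"


def resolve_lineage(taxid: int, taxdb: TaxDb) -> Lineage:
    """Full root-to-leaf lineage of a taxid (canonical rank order)."""
    return taxdb.lineage(taxid)


def write_species_report(rows: list[SpeciesReportRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tname\trank\tbin_ids\trelative_abundance\n")
        for r in rows:
            fh.write(f"{r.taxon}\t{r.name}\t{r.rank}\t{','.join(r.bin_ids)}\t"
                     f"{r.relative_abundance:.10g}\n")
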