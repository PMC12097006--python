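"""Profile-database and filtered-protein-database construction.

Selected families contribute the Pfam profiles of their
maximum-frequency profile sets; those profile blocks are lifted from
the Pfam HMM text into a screening database (the seek or taxonomy
profile database).  The families' protein names, reduced by a
frequency threshold, then filter a large protein FASTA (nr- or
UniRef-style headers) down to the seek/taxonomy filtered protein
database for alignment screening.
"""

from __future__ import annotations

import logging
import re
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import IO, Iterable

from .swissprot import FamilyRecord, resolve_families

logger = logging.getLogger(__name__)

_BRACKET_RE = re.compile(r"\[([^\[\]]+)\]")
_TAX_RE = re.compile(r"\bTax=(.+?)(?=\s+\w+=|$)")
_TAXID_RE = re.compile(r"\bTaxID=(\S+)")


@dataclass
class FamilySelection:
    """Which families (by code) and/or extra user names drive filtering."""

    family_codes: list[int] = field(default_factory=list)
    extra_names: list[str] = field(default_factory=list)
    names_only_mode: bool = False
    name_threshold_pct: float = 0.0


@dataclass
class FilteredDatabase:
    """Summary of one protein-FASTA filtering pass."""

    kept_headers: list[str]
    kept_count: int
    source_count: int
    names_used: set[str]


def threshold_filter_names(name_frequencies: dict[str, int],
                           threshold_pct: float) -> set[str]:
    """Names whose frequency reaches ``threshold_pct`` percent of the
    maximum name frequency.

    The threshold computes the minimum frequency a name needs to
    survive: ``threshold_pct/100 * max(frequencies)``, compared
    inclusively.  Zero threshold keeps every name.
    """
    if not 0 <= threshold_pct <= 100:
        raise ValueError(f"threshold_pct must be in [0, 100], got {threshold_pct}")
    if not name_frequencies:
        return set()
    if any(f < 0 for f in name_frequencies.values()):
        raise ValueError("name frequencies must be non-negative")
    cutoff = threshold_pct / 100.0 * max(name_frequencies.values())
    return {n for n, f in name_frequencies.items() if f >= cutoff}


def selection_names(selection: FamilySelection, kb: list[FamilyRecord]) -> set[str]:
    """The set of protein names a selection filters with: user names
    alone in names-only mode, else the union of the user names and each
    selected family's threshold-surviving names."""
    names = set(selection.extra_names)
    if selection.names_only_mode:
        return names
    for fam in resolve_families(kb, selection.family_codes):
        names |= threshold_filter_names(fam.name_frequencies,
                                        selection.name_threshold_pct)
    return names


# ---------------------------------------------------------------------------
# Profile database extraction
# ---------------------------------------------------------------------------

def selection_profile_accessions(selection: FamilySelection,
                                 kb: list[FamilyRecord]) -> set[str]:
    """Union of Pfam accessions over the selected families'
    maximum-frequency profile sets."""
    accs: set[str] = set()
    for fam in resolve_families(kb, selection.family_codes):
        for ps in fam.max_profile_sets:
            accs |= set(ps.entries)
    return accs


def collect_profile_db(selection: FamilySelection, kb: list[FamilyRecord],
                       pfam_stream: IO[str] | Iterable[str],
                       out_stream: IO[str]) -> tuple[set[str], list[str]]:
    """Copy the profile text blocks for the selection's accessions into
    *out_stream*, each block once, in database order.

    Returns (emitted accession set, missing accession list).  Unknown
    family codes raise; accessions absent from the database are only
    warned about and reported in the missing list.
    """
    wanted = selection_profile_accessions(selection, kb)
    emitted: set[str] = set()
    block: list[str] = []
    block_acc: str | None = None
    for line in pfam_stream:
        line = line.rstrip("\n")
        if line.startswith("HMMER3"):
            block = [line]
            block_acc = None
            continue
        block.append(line)
        if line.startswith("ACC "):
            block_acc = line.split(None, 1)[1].strip().split(".")[0]
        elif line.strip() == "//":
            if block_acc in wanted and block_acc not in emitted:
                out_stream.write("\n".join(block) + "\n")
                emitted.add(block_acc)
            block = []
            block_acc = None
    missing = sorted(wanted - emitted)
    for acc in missing:
        logger.warning("profile %s not found in the HMM database", acc)
    return emitted, missing


# ---------------------------------------------------------------------------
# Name matching & FASTA filtering
# ---------------------------------------------------------------------------

def match_name(header_description: str, name: str) -> bool:
    """Case-insensitive substring match of a protein name against a
    header description.

    A name padded with leading/trailing spaces (the convention for
    abbreviations, e.g. ``" CA "``) only matches where those spaces are
    present, i.e. at token boundaries; the description is virtually
    padded so boundary tokens still match.
    """
    desc = header_description.lower()
    needle = name.lower()
    if needle != needle.strip():
        return needle in f" {desc} "
    return needle in desc


def _description(header: str) -> str:
    """Description part of a FASTA header: everything after the first
    whitespace (empty when the header is a bare identifier)."""
    parts = header.split(None, 1)
    return parts[1] if len(parts) > 1 else ""


def _filter_chunk(records: list[tuple[str, str]],
                  names: tuple[str, ...]) -> list[tuple[str, str]]:
    kept = []
    for header, seq in records:
        desc = _description(header)
        if any(match_name(desc, n) for n in names):
            kept.append((header, seq))
    return kept


def _read_fasta(stream: IO[str] | Iterable[str]):
    header: str | None = None
    seq: list[str] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(seq)
            header = line[1:]
            seq = []
        elif line:
            if header is None:
                raise ValueError(f"FASTA parse error at line {lineno}: "
                                 "sequence data before first header")
            seq.append(line)
    if header is not None:
        yield header, "".join(seq)


def filter_protein_fasta(fasta_stream: IO[str] | Iterable[str],
                         names: set[str], out_stream: IO[str],
                         workers: int = 1,
                         chunk_size: int = 2000) -> FilteredDatabase:
    """Keep every FASTA record whose description matches at least one
    name; write the survivors to *out_stream* in input order.

    The stream is split into chunks filtered independently (in parallel
    when ``workers > 1``) and concatenated in chunk order, so the output
    is byte-identical regardless of the worker count.
    """
    if not names:
        raise ValueError("names must be non-empty")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    name_tup = tuple(sorted(names))
    records = list(_read_fasta(fasta_stream))
    chunks = [records[i:i + chunk_size] for i in range(0, len(records), chunk_size)]
    if workers == 1 or len(chunks) <= 1:
        results = [_filter_chunk(c, name_tup) for c in chunks]
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(_filter_chunk, chunks,
                                    [name_tup] * len(chunks)))
    kept_headers: list[str] = []
    for chunk in results:
        for header, seq in chunk:
            kept_headers.append(header)
            out_stream.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                out_stream.write(seq[i:i + 60] + "\n")
    return FilteredDatabase(kept_headers=kept_headers,
                            kept_count=len(kept_headers),
                            source_count=len(records),
                            names_used=set(names))


def write_filter_manifest(db: FilteredDatabase, path) -> None:
    """Manifest TSV accompanying a filtered database."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"kept_count\t{db.kept_count}\n")
        fh.write(f"source_count\t{db.source_count}\n")
        fh.write(f"names_used\t{','.join(sorted(db.names_used))}\n")


# ---------------------------------------------------------------------------
# Header taxonomy extraction
# ---------------------------------------------------------------------------

def detect_header_dialect(header: str) -> str:
    """``uniref`` when the identifier starts with "UniRef", else ``nr``."""
    return "uniref" if header.lstrip(">").startswith("UniRef") else "nr"


def extract_header_taxa(header: str, dialect: str | None = None) -> list[str]:
    """Organism names carried by a protein FASTA header.

    nr dialect: every bracketed organism across the ``\\x01``-separated
    sub-headers of a redundant entry.  UniRef dialect: the ``Tax=``
    field value.  Duplicates are preserved; no organism yields an empty
    list.
    """
    header = header.lstrip(">")
    if dialect is None:
        dialect = detect_header_dialect(header)
    if dialect == "uniref":
        m = _TAX_RE.search(header)
        return [m.group(1).strip()] if m else []
    if dialect == "nr":
        taxa: list[str] = []
        for sub in header.split("\x01"):
            taxa.extend(m.group(1).strip() for m in _BRACKET_RE.finditer(sub))
        return taxa
    raise ValueError(f"unknown header dialect: {dialect!r}")
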