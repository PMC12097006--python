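"""Family knowledge base built from Swiss-Prot flat-file records.

Each reviewed protein record contributes its accession, full names,
organism, sequence length, Pfam domain annotations and — when a
similarity comment states family membership — a family label.  Proteins
sharing a family label form a protein group; the group yields the
family's name-frequency table, mean/median member length and the
Pfam profile set(s) of maximum frequency among its members.

A *profile set* is the multiset of Pfam accessions observed in one
protein (accession coupled with its per-protein domain count).  Two
sets are identical iff their accessions and frequencies match exactly.
"""

from __future__ import annotations

import logging
import re
import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable

logger = logging.getLogger(__name__)

# Region qualifiers in similarity comments that split one record's
# family membership into section-specific families.
_REGION_NOTES = (
    "In the C-terminal section",
    "In the central section",
    "In the N-terminal section",
)

_FAMILY_RE = re.compile(r"Belongs to the (.+?) family", re.IGNORECASE)
_PFAM_ACC_RE = re.compile(r"^PF\d+")


@dataclass
class ProteinEntry:
    """One Swiss-Prot record, reduced to the fields the KB needs."""

    accession: str
    names: list[str]
    organism: str
    length: int
    pfam_accessions: list[str] = field(default_factory=list)
    family_label: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if self.length <= 0:
            raise ValueError(f"{self.accession}: length must be positive")


class ProfileSet:
    """Multiset of Pfam accessions with per-protein domain counts."""

    __slots__ = ("entries",)

    def __init__(self, entries: dict[str, int] | None = None):
        entries = dict(entries or {})
        for acc, freq in entries.items():
            if freq < 1:
                raise ValueError(f"profile frequency must be >= 1 ({acc}: {freq})")
        self.entries = entries

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileSet):
            return NotImplemented
        return self.entries == other.entries

    def __hash__(self) -> int:
        return hash(frozenset(self.entries.items()))

    def __bool__(self) -> bool:
        return bool(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __repr__(self) -> str:
        return f"ProfileSet({self.entries!r})"

    def sort_key(self) -> str:
        return self.serialize()

    def serialize(self) -> str:
        """Canonical text form ``PFx:2;PFy:1`` (accessions sorted)."""
        return ";".join(f"{a}:{self.entries[a]}" for a in sorted(self.entries))

    @classmethod
    def deserialize(cls, text: str) -> "ProfileSet":
        if not text:
            return cls({})
        entries: dict[str, int] = {}
        for tok in text.split(";"):
            acc, _, freq = tok.partition(":")
            entries[acc] = int(freq)
        return cls(entries)


@dataclass
class FamilyRecord:
    """One protein family with its group-derived assets."""

    family_code: int
    family_name: str
    member_accessions: set[str]
    mean_length: float
    median_length: float
    name_frequencies: dict[str, int]
    max_profile_sets: list[ProfileSet]
    max_set_frequency: int


@dataclass
class PfamProfileMeta:
    """Accession / short name / model length of one Pfam profile."""

    accession: str
    short_name: str
    profile_length: int


# ---------------------------------------------------------------------------
# Swiss-Prot flat-file parsing
# ---------------------------------------------------------------------------

def _iter_records(stream: Iterable[str]):
    record: list[str] = []
    for line in stream:
        line = line.rstrip("\n")
        if line.strip() == "//":
            if record:
                yield record
            record = []
        else:
            record.append(line)
    if record:
        yield record


def _parse_de_names(de_lines: list[str], include_short: bool) -> list[str]:
    """Full names from RecName/AltName blocks, order preserved."""
    names: list[str] = []
    wanted = ("Full=",) if not include_short else ("Full=", "Short=")
    for line in de_lines:
        body = line[5:].strip()
        for prefix in ("RecName:", "AltName:", "SubName:"):
            if body.startswith(prefix):
                body = body[len(prefix):].strip()
                break
        for part in body.split(";"):
            part = part.strip()
            for key in wanted:
                if part.startswith(key):
                    name = part[len(key):].strip()
                    # strip evidence tags like {ECO:...}
                    name = re.sub(r"\s*\{.*?\}", "", name).strip()
                    if name:
                        names.append(name)
    return names


def _parse_family_label(cc_text: str) -> str | None:
    """Family label from a similarity comment, region-qualified when the
    comment carries a section note."""
    m = _FAMILY_RE.search(cc_text)
    if m is None:
        return None
    name = m.group(1).strip()
    for note in _REGION_NOTES:
        if note.lower() in cc_text.lower().split("belongs to")[0].lower():
            return f"{name} [{note}]"
    return name


def parse_flatfile(stream: IO[str] | Iterable[str],
                   include_short_names: bool = False) -> list[ProteinEntry]:
    """Parse Swiss-Prot DAT records into :class:`ProteinEntry` objects.

    Only the fields the knowledge base consumes are read: ID, AC (first
    accession), DE full names (short names behind *include_short_names*),
    OS, DR Pfam cross-references and CC similarity comments, plus the SQ
    length line.  Records missing an accession or a sequence-length line
    are skipped with a warning; malformed cross-reference lines are
    ignored.
    """
    entries: list[ProteinEntry] = []
    for record in _iter_records(stream):
        accession: str | None = None
        organism_parts: list[str] = []
        de_lines: list[str] = []
        pfam: list[str] = []
        length: int | None = None
        cc_sim_lines: list[str] = []
        in_similarity = False
        for line in record:
            code = line[:2]
            body = line[5:] if len(line) > 5 else ""
            if code == "AC" and accession is None:
                first = body.split(";")[0].strip()
                if first:
                    accession = first
            elif code == "DE":
                de_lines.append(line)
            elif code == "OS":
                organism_parts.append(body.strip().rstrip("."))
            elif code == "DR":
                fields = [f.strip().rstrip(".") for f in body.split(";")]
                if fields and fields[0] == "Pfam":
                    if len(fields) < 2 or not _PFAM_ACC_RE.match(fields[1]):
                        logger.warning("ignoring malformed Pfam cross-reference: %s", line)
                        continue
                    acc = fields[1].split(".")[0]
                    count = 1
                    if len(fields) >= 4:
                        try:
                            count = max(1, int(fields[3]))
                        except ValueError:
                            count = 1
                    pfam.extend([acc] * count)
            elif code == "CC":
                text = body.strip()
                if text.startswith("-!-"):
                    in_similarity = text.startswith("-!- SIMILARITY:")
                    if in_similarity:
                        cc_sim_lines.append(text[len("-!- SIMILARITY:"):].strip())
                elif in_similarity:
                    cc_sim_lines.append(text)
            elif code == "SQ":
                m = re.search(r"SEQUENCE\s+(\d+)\s+AA", body)
                if m:
                    length = int(m.group(1))
        if accession is None or length is None:
            ident = accession or (record[0] if record else "<empty>")
            logger.warning("skipping record without accession/length: %s", ident)
            continue
        family_label = None
        if cc_sim_lines:
            family_label = _parse_family_label(" ".join(cc_sim_lines))
        entries.append(ProteinEntry(
            accession=accession,
            names=_parse_de_names(de_lines, include_short_names),
            organism=" ".join(organism_parts),
            length=length,
            pfam_accessions=pfam,
            family_label=family_label,
        ))
    return entries


# ---------------------------------------------------------------------------
# Family knowledge base
# ---------------------------------------------------------------------------

def build_profile_set(entry: ProteinEntry) -> ProfileSet:
    """Profile set of one protein: each Pfam accession with its domain count."""
    return ProfileSet(dict(Counter(entry.pfam_accessions)))


def build_family_kb(entries: list[ProteinEntry],
                    count_names_once_per_protein: bool = False) -> list[FamilyRecord]:
    """Group labelled entries into families and derive their assets.

    Family codes are consecutive integers in order of first appearance of
    each distinct family label.  Name frequencies count each full name per
    DE occurrence by default (once per protein behind the flag).  The
    maximum-frequency profile sets are every distinct non-empty set whose
    member count ties the maximum; ties are ordered by their canonical
    serialized form.
    """
    order: list[str] = []
    groups: dict[str, list[ProteinEntry]] = {}
    for e in entries:
        if e.family_label is None:
            continue
        if e.family_label not in groups:
            groups[e.family_label] = []
            order.append(e.family_label)
        groups[e.family_label].append(e)

    records: list[FamilyRecord] = []
    for code, label in enumerate(order):
        members = groups[label]
        lengths = [m.length for m in members]
        name_freq: Counter[str] = Counter()
        for m in members:
            names = dict.fromkeys(m.names) if count_names_once_per_protein else m.names
            name_freq.update(names)
        set_freq: Counter[ProfileSet] = Counter()
        for m in members:
            ps = build_profile_set(m)
            if ps:
                set_freq[ps] += 1
        if set_freq:
            max_freq = max(set_freq.values())
            max_sets = sorted((s for s, f in set_freq.items() if f == max_freq),
                              key=ProfileSet.sort_key)
        else:
            max_freq = 0
            max_sets = []
        records.append(FamilyRecord(
            family_code=code,
            family_name=label,
            member_accessions={m.accession for m in members},
            mean_length=statistics.fmean(lengths),
            median_length=float(statistics.median(lengths)),
            name_frequencies=dict(name_freq),
            max_profile_sets=max_sets,
            max_set_frequency=max_freq,
        ))
    return records


# ---------------------------------------------------------------------------
# Pfam HMM metadata
# ---------------------------------------------------------------------------

def parse_pfam_metadata(stream: IO[str] | Iterable[str]) -> list[PfamProfileMeta]:
    """Accession, short name and model length per profile block of a
    HMMER3 text database.  The accession version suffix is stripped.
    Blocks missing ACC or LENG are skipped with a warning."""
    metas: list[PfamProfileMeta] = []
    name = acc = None
    leng: int | None = None
    n_blocks = 0
    for line in stream:
        line = line.rstrip("\n")
        if line.startswith("HMMER3"):
            name = acc = None
            leng = None
            n_blocks += 1
        elif line.startswith("NAME "):
            name = line.split(None, 1)[1].strip()
        elif line.startswith("ACC "):
            acc = line.split(None, 1)[1].strip().split(".")[0]
        elif line.startswith("LENG "):
            leng = int(line.split(None, 1)[1].strip())
        elif line.strip() == "//":
            if acc is None or leng is None:
                logger.warning("skipping profile block missing ACC/LENG (NAME=%s)", name)
            else:
                metas.append(PfamProfileMeta(acc, name or "", leng))
            name = acc = None
            leng = None
    return metas


# ---------------------------------------------------------------------------
# KB serialization (two TSV assets)
# ---------------------------------------------------------------------------

def write_family_kb(kb: list[FamilyRecord], families_path, assets_path) -> None:
    """Write families.tsv (code, name, mean, median, members) and
    family_assets.tsv (code, name:freq list, tied profile sets joined
    with ``|``)."""
    with open(families_path, "w") as fh:
        fh.write("family_code\tfamily_name\tmean_length\tmedian_length\tmembers\n")
        for fam in kb:
            members = ",".join(sorted(fam.member_accessions))
            fh.write(f"{fam.family_code}\t{fam.family_name}\t"
                     f"{fam.mean_length:.6f}\t{fam.median_length:.6f}\t{members}\n")
    with open(assets_path, "w") as fh:
        fh.write("family_code\tname_frequencies\tmax_profile_sets\tmax_set_frequency\n")
        for fam in kb:
            names = ",".join(f"{n}:{f}" for n, f in
                             sorted(fam.name_frequencies.items()))
            sets = "|".join(s.serialize() for s in fam.max_profile_sets)
            fh.write(f"{fam.family_code}\t{names}\t{sets}\t{fam.max_set_frequency}\n")


def load_family_kb(families_path, assets_path) -> list[FamilyRecord]:
    """Inverse of :func:`write_family_kb`."""
    base: dict[int, FamilyRecord] = {}
    with open(families_path) as fh:
        next(fh)
        for line in fh:
            code_s, name, mean_s, median_s, members = line.rstrip("\n").split("\t")
            base[int(code_s)] = FamilyRecord(
                family_code=int(code_s), family_name=name,
                member_accessions=set(members.split(",")) if members else set(),
                mean_length=float(mean_s), median_length=float(median_s),
                name_frequencies={}, max_profile_sets=[], max_set_frequency=0)
    with open(assets_path) as fh:
        next(fh)
        for line in fh:
            code_s, names, sets, freq_s = line.rstrip("\n").split("\t")
            fam = base[int(code_s)]
            if names:
                for tok in names.split(","):
                    n, _, f = tok.rpartition(":")
                    fam.name_frequencies[n] = int(f)
            if sets:
                fam.max_profile_sets = [ProfileSet.deserialize(s)
                                        for s in sets.split("|")]
            fam.max_set_frequency = int(freq_s)
    return [base[c] for c in sorted(base)]


def resolve_families(kb: list[FamilyRecord],
                     codes: Iterable[int] = (),
                     names: Iterable[str] = ()) -> list[FamilyRecord]:
    """Resolve families by code and/or exact name; unknown ones raise."""
    by_code = {f.family_code: f for f in kb}
    by_name = {f.family_name: f for f in kb}
    out: list[FamilyRecord] = []
    seen: set[int] = set()
    for c in codes:
        if c not in by_code:
            raise KeyError(f"unknown family code: {c}")
        if c not in seen:
            out.append(by_code[c])
            seen.add(c)
    for n in names:
        if n not in by_name:
            raise KeyError(f"unknown family name: {n!r}")
        fam = by_name[n]
        if fam.family_code not in seen:
            out.append(fam)
            seen.add(fam.family_code)
    return out
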