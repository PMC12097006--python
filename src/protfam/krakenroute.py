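"""Read-classification taxonomy route.

Reads are classified against a k-mer database; species abundances are
re-estimated at species rank; a user threshold (absolute reads,
relative percent, or Shannon-index-driven automatic) then prunes
low-abundance species without reassigning their reads.  Surviving
species propagate from reads to contigs by majority vote (ties leave a
contig unassigned), contigs group into one bin per species, and each
bin inherits the species' estimated abundance.
"""

from __future__ import annotations

import math
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import IO, Callable, Iterable

import pysam

from .taxdb import TaxDb

# Re-estimation defaults surfaced as configuration: read length used by
# the abundance re-estimator and its minimum-read cutoff.
BRACKEN_READ_LENGTH = 100
BRACKEN_MIN_READS = 10

_INT_RE = re.compile(r"^\d+$")
_FLOAT_RE = re.compile(r"^\d*\.\d+$|^\d+\.\d*$")


@dataclass(frozen=True)
class ReadClassification:
    """One classified read: taxid 0 means unclassified."""

    read_id: str
    taxid: int
    rank: str = "no rank"


@dataclass
class AbundanceProfile:
    """Species abundance records: (name, taxid, reads, fraction)."""

    records: list[tuple[str, int, int, float]] = field(default_factory=list)

    def taxids(self) -> set[int]:
        return {t for _, t, _, _ in self.records}

    def by_taxid(self) -> dict[int, tuple[str, int, int, float]]:
        return {t: (n, t, r, f) for n, t, r, f in self.records}

    def fractions(self) -> list[float]:
        return [f for _, _, _, f in self.records]


@dataclass(frozen=True)
class ThresholdSpec:
    """Abundance filter: absolute reads, relative percent, or automatic
    (Shannon-index-driven, gut or non-gut calibration)."""

    kind: str  # absolute | relative | auto_nongut | auto_gut
    value: float | None = None

    def __post_init__(self):
        if self.kind == "absolute":
            if self.value is None or self.value < 0 or self.value != int(self.value):
                raise ValueError("absolute threshold must be a non-negative integer")
        elif self.kind == "relative":
            if self.value is None or not 0 < self.value <= 100:
                raise ValueError("relative threshold must be a percent in (0, 100]")
        elif self.kind in ("auto_nongut", "auto_gut"):
            if self.value is not None:
                raise ValueError("automatic thresholds carry no value")
        else:
            raise ValueError(f"unknown threshold kind: {self.kind!r}")


@dataclass
class ContigTaxonomy:
    """Species vote outcome for one contig; None species means the vote
    was tied or empty and the contig is excluded from binning."""

    contig_id: str
    species_taxid: int | None
    vote_counts: dict[int, int]


@dataclass
class SpeciesBin:
    """One bin of contigs sharing an assigned species."""

    species_taxid: int
    species_name: str
    contig_ids: set[str]
    reads: int
    fraction: float


# ---------------------------------------------------------------------------
# Threshold parsing and application
# ---------------------------------------------------------------------------

def parse_threshold_token(token: str) -> ThresholdSpec:
    """``"100"`` -> absolute reads; ``"5.0"`` -> relative percent;
    ``"gut"``/``"non-gut"`` -> automatic."""
    token = token.strip()
    if not token:
        raise ValueError("empty threshold token")
    if token == "non-gut":
        return ThresholdSpec("auto_nongut")
    if token == "gut":
        return ThresholdSpec("auto_gut")
    if _FLOAT_RE.match(token):
        return ThresholdSpec("relative", float(token))
    if _INT_RE.match(token):
        return ThresholdSpec("absolute", int(token))
    raise ValueError(f"cannot parse threshold token: {token!r}")


def parse_threshold_list(tokens: str) -> list[ThresholdSpec]:
    """Comma-separated threshold list; the first entry drives binning,
    the rest produce secondary filtered species lists."""
    return [parse_threshold_token(t) for t in tokens.split(",") if t.strip()]


def shannon_index(profile: AbundanceProfile) -> float:
    """Shannon diversity H = -sum p_i ln p_i over the profile's
    fractions renormalized to sum 1."""
    fracs = [f for f in profile.fractions() if f > 0]
    if not fracs:
        raise ValueError("profile has no positive fractions")
    total = sum(fracs)
    return -sum((f / total) * math.log(f / total) for f in fracs)


def default_auto_threshold(shannon: float, gut: bool) -> ThresholdSpec:
    """Placeholder Shannon-to-threshold mapping (NON-CANONICAL).

    The published calibration for gut/non-gut samples is not
    reproduced here; this linear stand-in (relative percent falling
    with diversity, floored at 0.01%) exists so the automatic kinds are
    exercisable.  Supply your own policy via ``apply_threshold``'s
    *auto_policy* for real analyses.
    """
    base = 2.0 if gut else 4.0
    pct = max(0.01, min(100.0, base / (1.0 + shannon)))
    return ThresholdSpec("relative", round(pct, 4))


AutoPolicy = Callable[[float, bool], ThresholdSpec]


def apply_threshold(profile: AbundanceProfile, spec: ThresholdSpec,
                    auto_policy: AutoPolicy = default_auto_threshold,
                    ) -> AbundanceProfile:
    """Drop species below the threshold; fractions are NOT renormalized
    (pruned species' reads are not reassigned).  Automatic kinds first
    resolve to a concrete threshold through *auto_policy* using the
    profile's Shannon index."""
    if spec.kind in ("auto_nongut", "auto_gut"):
        spec = auto_policy(shannon_index(profile), spec.kind == "auto_gut")
    if spec.kind == "absolute":
        kept = [r for r in profile.records if r[2] >= spec.value]
    else:
        kept = [r for r in profile.records if 100.0 * r[3] >= spec.value]
    return AbundanceProfile(records=kept)


# ---------------------------------------------------------------------------
# Classifier-output parsing
# ---------------------------------------------------------------------------

def parse_per_read(stream: IO[str] | Iterable[str],
                   rank_of: dict[int, str] | None = None,
                   ) -> list[ReadClassification]:
    """Per-read classifier output: C/U flag, read id, taxid, ..."""
    rank_of = rank_of or {}
    out: list[ReadClassification] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ValueError(f"per-read line {lineno}: expected >=3 columns")
        taxid = int(f[2])
        out.append(ReadClassification(read_id=f[1], taxid=taxid,
                                      rank=rank_of.get(taxid, "no rank")))
    return out


_REPORT_RANK = {
    "R": "root", "D": "superkingdom", "K": "kingdom", "P": "phylum",
    "C": "class", "O": "order", "F": "family", "G": "genus", "S": "species",
    "U": "unclassified",
}


def parse_report(stream: IO[str] | Iterable[str]) -> dict[int, tuple[str, str]]:
    """Classifier report -> taxid: (rank, name).  Sub-rank codes like
    ``S1`` map to ``species subgroup`` naming below species."""
    out: dict[int, tuple[str, str]] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise ValueError(f"report line {lineno}: expected 6 columns")
        code = f[3]
        base = _REPORT_RANK.get(code[0], "no rank")
        rank = base if len(code) == 1 else f"below {base}"
        out[int(f[4])] = (rank, f[5].strip())
    return out


def parse_bracken(stream: IO[str] | Iterable[str]) -> AbundanceProfile:
    """Species abundance report (7 columns: name, taxid, rank, assigned
    reads, added reads, estimated reads, fraction)."""
    records: list[tuple[str, int, int, float]] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("name\t"):
            continue
        f = line.split("\t")
        if len(f) != 7:
            raise ValueError(f"abundance report line {lineno}: expected 7 columns")
        records.append((f[0], int(f[1]), int(f[5]), float(f[6])))
    return AbundanceProfile(records=records)


def parse_kraken_outputs(per_read_stream, report_stream, bracken_stream,
                         ) -> tuple[list[ReadClassification], AbundanceProfile]:
    """Parse the three classifier artifacts together, resolving per-read
    ranks from the report's taxonomy column."""
    report = parse_report(report_stream)
    rank_of = {t: r for t, (r, _) in report.items()}
    classifications = parse_per_read(per_read_stream, rank_of)
    return classifications, parse_bracken(bracken_stream)


# ---------------------------------------------------------------------------
# Read mapping and contig voting
# ---------------------------------------------------------------------------

def parse_read_map(sam_path) -> list[tuple[str, str]]:
    """(read_id, contig_id) pairs from primary alignments in a SAM file;
    unmapped, secondary and supplementary records are ignored."""
    pairs: list[tuple[str, str]] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            pairs.append((rec.query_name, rec.reference_name))
    return pairs


def lift_to_species(taxid: int, taxdb: TaxDb | None) -> int | None:
    """Species-rank ancestor of a taxid (identity for species-rank
    nodes); None when no species ancestor exists or no taxdb is given
    and the rank is unknown."""
    if taxdb is None or taxid not in taxdb:
        return None
    return taxdb.ancestor_at_rank(taxid, "species")


def assign_contig_species(read_map: list[tuple[str, str]],
                          classifications: list[ReadClassification],
                          kept_species: set[int],
                          taxdb: TaxDb | None = None,
                          ) -> list[ContigTaxonomy]:
    """Majority-vote species assignment of contigs from their mapped
    reads.

    Only reads whose classification is (or lifts to) a surviving
    species vote; reads classified above species rank contribute
    nothing.  A unique argmax assigns the species; a tie or an empty
    vote leaves the contig unassigned.
    """
    cls_by_read = {c.read_id: c for c in classifications}
    votes: dict[str, Counter[int]] = defaultdict(Counter)
    contig_order: list[str] = []
    for read_id, contig_id in read_map:
        if contig_id not in votes:
            contig_order.append(contig_id)
        votes[contig_id]  # touch so every mapped contig appears
        cls = cls_by_read.get(read_id)
        if cls is None or cls.taxid == 0:
            continue
        taxid = cls.taxid
        if cls.rank != "species":
            lifted = lift_to_species(taxid, taxdb)
            if lifted is None:
                continue
            taxid = lifted
        if taxid in kept_species:
            votes[contig_id][taxid] += 1
    out: list[ContigTaxonomy] = []
    for contig_id in contig_order:
        counts = votes[contig_id]
        assigned: int | None = None
        if counts:
            top = max(counts.values())
            winners = [t for t, n in counts.items() if n == top]
            if len(winners) == 1:
                assigned = winners[0]
        out.append(ContigTaxonomy(contig_id=contig_id,
                                  species_taxid=assigned,
                                  vote_counts=dict(counts)))
    return out


def bin_by_species(contig_taxa: list[ContigTaxonomy],
                   profile: AbundanceProfile) -> list[SpeciesBin]:
    """Group species-assigned contigs into one bin per species, each
    carrying the species' estimated reads and fraction.  The profile
    must already be filtered; an assigned species missing from it
    violates the pipeline order and raises."""
    by_taxid = profile.by_taxid()
    grouped: dict[int, set[str]] = defaultdict(set)
    for ct in contig_taxa:
        if ct.species_taxid is not None:
            grouped[ct.species_taxid].add(ct.contig_id)
    bins: list[SpeciesBin] = []
    for taxid in sorted(grouped):
        if taxid not in by_taxid:
            raise ValueError(
                f"species {taxid} assigned to contigs but absent from the "
                "filtered abundance profile")
        name, _, reads, fraction = by_taxid[taxid]
        bins.append(SpeciesBin(species_taxid=taxid, species_name=name,
                               contig_ids=grouped[taxid],
                               reads=reads, fraction=fraction))
    return bins
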