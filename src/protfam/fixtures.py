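"""Deterministic synthetic-data generator with planted ground truth.

Builds a toy metagenomic "world" — a community of species with known
relative abundances, contigs, reads, predicted genes, protein families
with planted Pfam domain architectures, and screening outputs with
planted candidate sets — then emits every input format the pipeline
consumes, mutually consistent with a machine-readable truth manifest.

Sequences are random with planted codon/domain anchors; no biological
realism beyond GC bias and codon structure is attempted.  Everything is
reproducible byte-for-byte from (seed, parameters); the ``corrupt``
knobs inject controlled, logged noise for threshold/precision tests.
"""

from __future__ import annotations

import copy
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from Bio.Seq import Seq

_BASES = "ACGT"
_BIAS_WEIGHTS = {
    "none": (0.25, 0.25, 0.25, 0.25),
    "AT": (0.35, 0.15, 0.15, 0.35),
    "GC": (0.15, 0.35, 0.35, 0.15),
}
_START = ("ATG", "GTG", "TTG")
_STOP = ("TAA", "TAG", "TGA")
_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_NONSTOP = [c for c in _ALL_CODONS if c not in _STOP]
_PLAIN = [c for c in _ALL_CODONS if c not in _STOP and c not in _START]

READ_LENGTH = 100

# Planted protein-family blueprint for the Swiss-Prot/Pfam fixtures.
# (family CC note, region note or None, dominant architecture,
#  full names of members, n members with the dominant set, n deviants)
_FAMILY_BLUEPRINT = [
    ("alpha-amylase", None, {"PF90001": 2, "PF90002": 1},
     ["Alpha-amylase", "1,4-alpha-D-glucan glucanohydrolase"], 3, 1),
    ("carbonic anhydrase", None, {"PF90003": 1},
     ["Carbonic anhydrase 2", "Carbonate dehydratase"], 3, 1),
    ("DNA polymerase", None, {"PF90004": 1},
     ["DNA polymerase I"], 2, 0),
    ("DNA polymerase", "In the C-terminal section", {"PF90005": 1},
     ["DNA polymerase I C-terminal region"], 2, 0),
]

_PFAM_META = {
    "PF90001": ("Amyl_dom", 210),
    "PF90002": ("Amyl_C", 95),
    "PF90003": ("CA_dom", 180),
    "PF90004": ("Pol_core", 320),
    "PF90005": ("Pol_Cterm", 140),
    "PF90006": ("Orphan_dom", 77),
}


@dataclass
class PlantedWorld:
    """All planted state; files are a pure function of this object."""

    seed: int
    params: dict[str, Any]
    # taxonomy
    nodes: list[tuple[int, int, str]]          # taxid, parent, rank
    names: list[tuple[int, str, str]]          # taxid, name, name class
    # community
    species: list[dict[str, Any]]              # name, taxid, genus_taxid, reads, fraction
    contigs: dict[str, str]                    # contig_id -> sequence
    contig_species: dict[str, int]             # contig_id -> species taxid
    reads: list[dict[str, Any]]                # read_id, contig, pos, taxid(classified), rank
    genes: list[dict[str, Any]]                # gene geometry + planted flags + role
    # protein-family fixtures
    sprot_records: list[dict[str, Any]]
    family_truth: list[dict[str, Any]]
    # screening fixtures
    spd_hits: list[tuple[str, str, float]]     # protein, profile acc, evalue
    tpd_hits: list[tuple[str, str, float]]
    sfpd_hits: list[tuple[str, str, float, float]]   # q, s, evalue, pident
    tfpd_hits: list[tuple[str, str, float, float]]
    sprot_hits: list[tuple[str, str, float, float]]
    subjects: list[dict[str, Any]]             # filtered-database subject proteins
    topology: dict[str, tuple[bool, int]]      # protein -> (SP, TM)
    noise_log: list[dict[str, Any]] = field(default_factory=list)

    # -- planted truths -----------------------------------------------------
    def true_profile(self) -> list[tuple[str, int, int, float]]:
        return [(s["name"], s["taxid"], s["reads"], s["fraction"])
                for s in self.species]

    def planted_sets(self) -> dict[str, set[str]]:
        sets: dict[str, set[str]] = {"type1": set(), "type2": set(),
                                     "type2_reject": set(), "none": set()}
        for g in self.genes:
            role = g["role"]
            key = "type2" if role == "type2_boundary" else role
            sets[key].add(g["gene_id"])
        return sets

    def manifest(self) -> dict[str, Any]:
        sets = self.planted_sets()
        return {
            "seed": self.seed,
            "params": self.params,
            "species": [dict(name=s["name"], taxid=s["taxid"],
                             reads=s["reads"], fraction=s["fraction"])
                        for s in self.species],
            "contigs": [dict(contig_id=c, length=len(seq),
                             species_taxid=self.contig_species[c])
                        for c, seq in self.contigs.items()],
            "n_reads": len(self.reads),
            "genes": [{k: g[k] for k in
                       ("gene_id", "contig_id", "start", "end", "strand",
                        "has_start_codon", "has_stop_codon", "role")}
                      for g in self.genes],
            "families": self.family_truth,
            "seek_sets": {k: sorted(v) for k, v in sets.items()},
            "candidate_survivors": sorted(self.candidate_survivors()),
            "noise": self.noise_log,
        }

    def candidate_survivors(self) -> set[str]:
        """Planted manual-triage survivors: profile-hit proteins with no
        signal peptide and best-hit identity <= 80 percent."""
        best_pid: dict[str, float] = {}
        for q, _s, _e, pid in self.sprot_hits:
            best_pid[q] = min(best_pid.get(q, 100.0), pid)
        survivors = set()
        for g in self.genes:
            pid = g["gene_id"]
            if g["role"] != "type1":
                continue
            sp, _tm = self.topology.get(pid, (False, 0))
            if sp:
                continue
            if best_pid.get(pid, 100.0) <= 80.0:
                survivors.add(pid)
        return survivors


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def _random_seq(rng: random.Random, length: int, bias: str) -> str:
    w = _BIAS_WEIGHTS[bias]
    return "".join(rng.choices(_BASES, weights=w, k=length))


def _plant_gene(rng: random.Random, n_codons: int,
                has_start: bool, has_stop: bool) -> str:
    codons = [rng.choice(_START) if has_start else rng.choice(_PLAIN)]
    codons += [rng.choice(_NONSTOP) for _ in range(n_codons - 2)]
    codons.append(rng.choice(_STOP) if has_stop else rng.choice(_PLAIN))
    return "".join(codons)


def generate_world(seed: int, n_species: int = 10,
                   n_contigs_per_species: int = 3,
                   reads_per_contig: int = 20,
                   bias: str = "none") -> PlantedWorld:
    """Build the planted world.  All counts must be >= 1; *bias* shifts
    contig base content (``none``/``AT``/``GC``)."""
    if bias not in _BIAS_WEIGHTS:
        raise ValueError(f"unknown bias: {bias!r}")
    if min(n_species, n_contigs_per_species, reads_per_contig) < 1:
        raise ValueError("all counts must be >= 1")
    rng = random.Random(seed)

    # --- taxonomy: root(1) -> Bacteria(2) -> genus(50+g) -> species(100+i)
    nodes = [(1, 1, "no rank"), (2, 1, "superkingdom")]
    names = [(1, "root", "scientific name"),
             (2, "Bacteria", "scientific name")]
    species: list[dict[str, Any]] = []
    n_genera = (n_species + 2) // 3
    for g in range(n_genera):
        nodes.append((50 + g, 2, "genus"))
        names.append((50 + g, f"Genus{g}", "scientific name"))
    for i in range(n_species):
        g = i // 3
        taxid = 100 + i
        name = f"Genus{g} species{i}"
        nodes.append((taxid, 50 + g, "species"))
        names.append((taxid, name, "scientific name"))
        species.append(dict(name=name, taxid=taxid, genus_taxid=50 + g,
                            reads=0, fraction=0.0))
    # strain children for the first two species (read-lifting exercise)
    strain_of: dict[int, int] = {}
    for i in range(min(2, n_species)):
        st = 200 + i
        nodes.append((st, 100 + i, "strain"))
        names.append((st, f"Genus{i // 3} species{i} str. K{i}", "scientific name"))
        strain_of[100 + i] = st

    # --- contigs, reads, genes
    contigs: dict[str, str] = {}
    contig_species: dict[str, int] = {}
    reads: list[dict[str, Any]] = []
    genes: list[dict[str, Any]] = []
    cix = rix = 0
    for sp in species:
        for _ in range(n_contigs_per_species):
            cid = f"contig{cix}"
            cix += 1
            length = rng.randrange(1400, 2201, 2)
            seq = list(_random_seq(rng, length, bias))
            # two planted genes per contig, one per half
            for half, lo in enumerate((100, length // 2 + 50)):
                n_codons = rng.randint(30, 60)
                glen = 3 * n_codons
                start = rng.randint(lo, lo + 60)
                end = start + glen - 1
                strand = rng.choice("+-")
                has_start = rng.random() < 0.7
                has_stop = rng.random() < 0.7
                oriented = _plant_gene(rng, n_codons, has_start, has_stop)
                placed = (oriented if strand == "+"
                          else str(Seq(oriented).reverse_complement()))
                seq[start - 1:end] = placed
                protein = str(Seq(oriented).translate(table=11)).rstrip("*")
                gene_id = f"{cid}_{start}_{end}_{strand}"
                genes.append(dict(gene_id=gene_id, contig_id=cid, start=start,
                                  end=end, strand=strand,
                                  has_start_codon=has_start,
                                  has_stop_codon=has_stop,
                                  protein_seq=protein, role="none"))
            contigs[cid] = "".join(seq)
            contig_species[cid] = sp["taxid"]
            for _ in range(reads_per_contig):
                rid = f"read{rix}"
                rix += 1
                pos = rng.randint(1, len(contigs[cid]) - READ_LENGTH + 1)
                taxid = sp["taxid"]
                rank = "species"
                # a few reads of the first species land on strain nodes
                if sp["taxid"] in strain_of and rng.random() < 0.15:
                    taxid = strain_of[sp["taxid"]]
                    rank = "below species"
                reads.append(dict(read_id=rid, contig_id=cid, pos=pos,
                                  taxid=taxid, rank=rank))
                sp["reads"] += 1
    total_reads = sum(s["reads"] for s in species)
    for sp in species:
        sp["fraction"] = sp["reads"] / total_reads
        sp["true_fraction"] = sp["fraction"]  # survives corruption

    # --- seek roles over the predicted proteins
    gene_order = list(range(len(genes)))
    rng.shuffle(gene_order)
    n = len(gene_order)
    n1 = max(1, int(0.30 * n))
    n2 = max(1, int(0.20 * n))
    nb = 1 if n > n1 + n2 else 0
    nr = max(1, int(0.10 * n)) if n > n1 + n2 + nb else 0
    for k, gi in enumerate(gene_order):
        if k < n1:
            genes[gi]["role"] = "type1"
        elif k < n1 + n2:
            genes[gi]["role"] = "type2"
        elif k < n1 + n2 + nb:
            genes[gi]["role"] = "type2_boundary"
        elif k < n1 + n2 + nb + nr:
            genes[gi]["role"] = "type2_reject"

    # --- Swiss-Prot records and family truth
    sprot_records: list[dict[str, Any]] = []
    family_truth: list[dict[str, Any]] = []
    acc_no = 90000
    for fam_i, (fam, region, arch, fnames, n_dom, n_dev) in enumerate(_FAMILY_BLUEPRINT):
        label = f"{fam} [{region}]" if region else fam
        members = []
        for m in range(n_dom + n_dev):
            acc = f"P{acc_no}"
            acc_no += 1
            length = rng.randint(200, 600)
            if m < n_dom:
                pfam = dict(arch)
            else:  # deviant architecture: one extra orphan domain
                pfam = dict(arch)
                pfam["PF90006"] = 1
            sprot_records.append(dict(
                accession=acc, entry_name=f"FAM{fam_i}_{m}",
                names=list(fnames), organism=species[m % n_species]["name"],
                length=length, pfam=pfam, family=fam, region=region))
            members.append(dict(accession=acc, length=length, pfam=pfam))
        family_truth.append(dict(
            family_label=label,
            members=[m["accession"] for m in members],
            lengths=[m["length"] for m in members],
            dominant_set={k: v for k, v in arch.items()},
            dominant_count=n_dom,
            names=list(fnames)))

    # --- filtered-database subject proteins (nr + uniref headers)
    subjects: list[dict[str, Any]] = []
    for i, sp in enumerate(species):
        subjects.append(dict(
            sid=f"NRS{i}", dialect="nr", organisms=[sp["name"]],
            desc=f"hypothetical protein [{sp['name']}]",
            seq="".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=120))))
    if len(species) >= 2:
        subjects.append(dict(
            sid="NRM0", dialect="nr",
            organisms=[species[0]["name"], species[1]["name"]],
            desc=(f"multispecies protein [{species[0]['name']}]\x01NRM0b "
                  f"multispecies protein [{species[1]['name']}]"),
            seq="".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=120))))
    for i, sp in enumerate(species[:3]):
        subjects.append(dict(
            sid=f"UniRef50_U{i}", dialect="uniref", organisms=[sp["name"]],
            desc=(f"uncharacterized protein n=1 Tax={sp['name']} "
                  f"TaxID={sp['taxid']} RepID=U{i}_X"),
            seq="".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=120))))

    # --- screening hits
    spd_hits: list[tuple[str, str, float]] = []
    tpd_hits: list[tuple[str, str, float]] = []
    sfpd_hits: list[tuple[str, str, float, float]] = []
    tfpd_hits: list[tuple[str, str, float, float]] = []
    sprot_hits: list[tuple[str, str, float, float]] = []
    topology: dict[str, tuple[bool, int]] = {}
    sid_of_species = {sp["taxid"]: f"NRS{i}" for i, sp in enumerate(species)}
    fam_accs = [r["accession"] for r in sprot_records]
    for g in genes:
        pid = g["gene_id"]
        role = g["role"]
        if role == "type1":
            spd_hits.append((pid, "PF90001", 10 ** -rng.randint(15, 60)))
        elif role == "type2":
            sfpd_hits.append((pid, f"NRS{rng.randrange(len(species))}",
                              10 ** -rng.randint(75, 120), rng.uniform(40, 95)))
        elif role == "type2_boundary":
            sfpd_hits.append((pid, "NRS0", 1e-70, rng.uniform(40, 95)))
        elif role == "type2_reject":
            sfpd_hits.append((pid, f"NRS{rng.randrange(len(species))}",
                              10 ** -rng.randint(30, 60), rng.uniform(40, 95)))
        # taxonomy gate: most proteins get a TPD hit + a TFPD best hit to
        # their true species (plus a worse decoy), ~10% stay gate-negative
        if rng.random() >= 0.10:
            tpd_hits.append((pid, "PF90004", 10 ** -rng.randint(10, 50)))
            true_sid = sid_of_species[contig_species[g["contig_id"]]]
            tfpd_hits.append((pid, true_sid,
                              10 ** -rng.randint(60, 110), rng.uniform(60, 99)))
            decoy = f"NRS{rng.randrange(len(species))}"
            if decoy != true_sid:
                tfpd_hits.append((pid, decoy,
                                  10 ** -rng.randint(5, 30), rng.uniform(30, 60)))
        # annotation extras for seek candidates
        if role in ("type1", "type2", "type2_boundary"):
            sprot_hits.append((pid, rng.choice(fam_accs),
                               10 ** -rng.randint(30, 80), rng.uniform(30, 95)))
            topology[pid] = (rng.random() < 0.25, rng.randint(0, 3))

    return PlantedWorld(
        seed=seed,
        params=dict(n_species=n_species,
                    n_contigs_per_species=n_contigs_per_species,
                    reads_per_contig=reads_per_contig, bias=bias),
        nodes=nodes, names=names, species=species, contigs=contigs,
        contig_species=contig_species, reads=reads, genes=genes,
        sprot_records=sprot_records, family_truth=family_truth,
        spd_hits=spd_hits, tpd_hits=tpd_hits, sfpd_hits=sfpd_hits,
        tfpd_hits=tfpd_hits, sprot_hits=sprot_hits, subjects=subjects,
        topology=topology)


# ---------------------------------------------------------------------------
# Controlled corruption
# ---------------------------------------------------------------------------

FALSE_SPECIES_ABUNDANCE_BOUND = 0.01  # every planted false species stays below

def corrupt(world: PlantedWorld, false_species_rate: float = 0.0,
            misclassified_read_rate: float = 0.0,
            spurious_hit_rate: float = 0.0) -> PlantedWorld:
    """Return a degraded copy of the world with logged noise.

    ``false_species_rate`` adds ``round(rate * n_species)`` spurious
    species, each classified on unmapped reads and kept below
    :data:`FALSE_SPECIES_ABUNDANCE_BOUND` relative abundance.
    ``misclassified_read_rate`` reassigns that fraction of reads to a
    different true species.  ``spurious_hit_rate`` adds profile hits to
    that fraction of role-free proteins.  All rates must be in [0, 1);
    with every rate zero the copy is identical to the input.
    """
    for r in (false_species_rate, misclassified_read_rate, spurious_hit_rate):
        if not 0 <= r < 1:
            raise ValueError("rates must be in [0, 1)")
    w = copy.deepcopy(world)
    if not (false_species_rate or misclassified_read_rate or spurious_hit_rate):
        return w
    rng = random.Random((world.seed * 7919 + 17) % (2 ** 31))
    total_true = sum(s["reads"] for s in w.species)

    n_false = round(false_species_rate * len(w.species))
    false_reads_each = max(1, int(0.004 * total_true))
    for j in range(n_false):
        taxid = 900 + j
        name = f"Falsum speciosum{j}"
        if j == 0:
            w.nodes.append((99, 2, "genus"))
            w.names.append((99, "Falsum", "scientific name"))
        w.nodes.append((taxid, 99, "species"))
        w.names.append((taxid, name, "scientific name"))
        for k in range(false_reads_each):
            w.reads.append(dict(read_id=f"noise_read{j}_{k}", contig_id=None,
                                pos=0, taxid=taxid, rank="species"))
        w.species.append(dict(name=name, taxid=taxid, genus_taxid=99,
                              reads=false_reads_each,
                              fraction=0.0, false=True))
        w.noise_log.append(dict(kind="false_species", taxid=taxid, name=name,
                                reads=false_reads_each,
                                abundance_bound=FALSE_SPECIES_ABUNDANCE_BOUND))
    # recompute fractions over the inflated total
    new_total = sum(s["reads"] for s in w.species)
    for s in w.species:
        s["fraction"] = s["reads"] / new_total
    assert all(s["fraction"] < FALSE_SPECIES_ABUNDANCE_BOUND
               for s in w.species if s.get("false"))

    n_mis = round(misclassified_read_rate * total_true)
    if n_mis:
        true_taxids = [s["taxid"] for s in world.species]
        mapped = [r for r in w.reads if r["contig_id"] is not None]
        for r in rng.sample(mapped, n_mis):
            old = r["taxid"]
            choices = [t for t in true_taxids if t != old]
            r["taxid"] = rng.choice(choices)
            r["rank"] = "species"
            w.noise_log.append(dict(kind="misclassified_read",
                                    read_id=r["read_id"],
                                    from_taxid=old, to_taxid=r["taxid"]))
        # species read counts/fractions follow the classifier's view
        counts: dict[int, int] = {s["taxid"]: 0 for s in w.species}
        strain_parent = {t: p for t, p, rk in w.nodes if rk == "strain"}
        for r in w.reads:
            t = strain_parent.get(r["taxid"], r["taxid"])
            if t in counts:
                counts[t] += 1
        for s in w.species:
            s["reads"] = counts[s["taxid"]]
            s["fraction"] = s["reads"] / new_total

    if spurious_hit_rate:
        free = sorted(g["gene_id"] for g in w.genes if g["role"] == "none")
        n_sp = round(spurious_hit_rate * len(w.genes))
        for pid in rng.sample(free, min(n_sp, len(free))):
            w.spd_hits.append((pid, "PF90006", 10 ** -rng.randint(6, 12)))
            w.noise_log.append(dict(kind="spurious_hit", protein=pid))
    return w


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def _write_sprot(world: PlantedWorld, path: Path) -> None:
    with open(path, "w") as fh:
        for r in world.sprot_records:
            fh.write(f"ID   {r['entry_name']}            Reviewed;"
                     f"         {r['length']} AA.\n")
            fh.write(f"AC   {r['accession']};\n")
            first, *rest = r["names"]
            fh.write(f"DE   RecName: Full={first};\n")
            for alt in rest:
                fh.write(f"DE   AltName: Full={alt};\n")
            fh.write(f"OS   {r['organism']}.\n")
            for acc, cnt in sorted(r["pfam"].items()):
                short = _PFAM_META[acc][0]
                fh.write(f"DR   Pfam; {acc}; {short}; {cnt}.\n")
            if r["region"]:
                fh.write(f"CC   -!- SIMILARITY: {r['region']}; belongs to the "
                         f"{r['family']} family.\n")
            else:
                fh.write(f"CC   -!- SIMILARITY: Belongs to the "
                         f"{r['family']} family.\n")
            fh.write(f"SQ   SEQUENCE   {r['length']} AA;  11111 MW;  "
                     "0000000000000000 CRC64;\n")
            fh.write("//\n")


def _write_pfam_hmm(path: Path) -> None:
    with open(path, "w") as fh:
        for i, (acc, (short, leng)) in enumerate(sorted(_PFAM_META.items())):
            fh.write("HMMER3/f [3.4 | synthetic]\n")
            fh.write(f"NAME  {short}\n")
            fh.write(f"ACC   {acc}.{i + 1}\n")
            fh.write(f"DESC  Synthetic profile {short}\n")
            fh.write(f"LENG  {leng}\n")
            fh.write("ALPH  amino\n")
            fh.write("//\n")


def _write_domtbl(hits, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# synthetic per-domain hits\n")
        for pid, acc, ev in hits:
            short, leng = _PFAM_META[acc][0], _PFAM_META[acc][1]
            score = 50.0
            fh.write(f"{short} {acc}.1 {leng} {pid} - 150 {ev:.3g} {score:.1f} 0.1 "
                     f"1 1 {ev:.3g} {ev:.3g} {score:.1f} 0.1 1 {leng} 5 120 3 125 "
                     f"0.90 -\n")


def _write_diamond(hits, path: Path) -> None:
    with open(path, "w") as fh:
        for q, s, ev, pident in hits:
            fh.write(f"{q}\t{s}\t{pident:.1f}\t{ev:.3g}\t{200.0:.1f}\n")


def _write_sam(world: PlantedWorld, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid, seq in world.contigs.items():
            fh.write(f"@SQ\tSN:{cid}\tLN:{len(seq)}\n")
        for r in world.reads:
            if r["contig_id"] is None:
                continue
            seq = world.contigs[r["contig_id"]][r["pos"] - 1:
                                                r["pos"] - 1 + READ_LENGTH]
            fh.write(f"{r['read_id']}\t0\t{r['contig_id']}\t{r['pos']}\t60\t"
                     f"{len(seq)}M\t*\t0\t0\t{seq}\t*\n")


def _species_read_counts(world: PlantedWorld) -> dict[int, int]:
    """Classifier-view species counts (strain reads count to their species)."""
    strain_parent = {t: p for t, p, rk in world.nodes if rk == "strain"}
    counts: dict[int, int] = {s["taxid"]: 0 for s in world.species}
    for r in world.reads:
        t = strain_parent.get(r["taxid"], r["taxid"])
        if t in counts:
            counts[t] += 1
    return counts


def _write_kraken(world: PlantedWorld, per_read: Path, report: Path,
                  bracken: Path) -> None:
    with open(per_read, "w") as fh:
        for r in world.reads:
            fh.write(f"C\t{r['read_id']}\t{r['taxid']}\t{READ_LENGTH}\t"
                     f"{r['taxid']}:1\n")
    counts = _species_read_counts(world)
    strain_counts: dict[int, int] = {}
    for r in world.reads:
        if r["rank"] == "below species":
            strain_counts[r["taxid"]] = strain_counts.get(r["taxid"], 0) + 1
    total = sum(counts.values())
    rank_of = {t: rk for t, _p, rk in world.nodes}
    name_of = {t: n for t, n, cls in world.names if cls == "scientific name"}
    parent_of = {t: p for t, p, _rk in world.nodes}
    with open(report, "w") as fh:
        fh.write(f"100.00\t{total}\t0\tR\t1\troot\n")
        fh.write(f"100.00\t{total}\t0\tD\t2\t  Bacteria\n")
        genera = sorted({s["genus_taxid"] for s in world.species})
        for g in genera:
            greads = sum(counts[s["taxid"]] for s in world.species
                         if s["genus_taxid"] == g)
            fh.write(f"{100 * greads / total:.2f}\t{greads}\t0\tG\t{g}\t"
                     f"    {name_of[g]}\n")
            for s in world.species:
                if s["genus_taxid"] != g:
                    continue
                t = s["taxid"]
                fh.write(f"{100 * counts[t] / total:.2f}\t{counts[t]}\t"
                         f"{counts[t]}\tS\t{t}\t      {name_of[t]}\n")
                for st, n in sorted(strain_counts.items()):
                    if parent_of.get(st) == t and rank_of.get(st) == "strain":
                        fh.write(f"{100 * n / total:.2f}\t{n}\t{n}\tS1\t{st}\t"
                                 f"        {name_of[st]}\n")
    with open(bracken, "w") as fh:
        fh.write("name\ttaxonomy_id\ttaxonomy_lvl\tkraken_assigned_reads\t"
                 "added_reads\tnew_est_reads\tfraction_total_reads\n")
        for s in world.species:
            t = s["taxid"]
            fh.write(f"{s['name']}\t{t}\tS\t{counts[t]}\t0\t{counts[t]}\t"
                     f"{counts[t] / total:.8f}\n")


def _write_taxdump(world: PlantedWorld, nodes: Path, names: Path) -> None:
    with open(nodes, "w") as fh:
        for taxid, parent, rank in world.nodes:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names, "w") as fh:
        for taxid, name, cls in world.names:
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\t{cls}\t|\n")


def emit_inputs(world: PlantedWorld, outdir) -> dict[str, Path]:
    """Write every pipeline input format plus ``manifest.json``; returns
    a name -> path map.  Pure function of the world state."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("swissprot", "swissprot.dat"), ("pfam_hmm", "pfam.hmm"),
        ("proteins_nr", "proteins_nr.fasta"),
        ("proteins_uniref", "proteins_uniref.fasta"),
        ("contigs", "contigs.fasta"), ("genes", "genes.faa"),
        ("sam", "reads.sam"), ("kraken_per_read", "kraken_per_read.tsv"),
        ("kraken_report", "kraken_report.tsv"),
        ("bracken", "bracken_report.tsv"), ("bins", "bins.tsv"),
        ("spd_domtbl", "spd_domtblout.tsv"), ("tpd_domtbl", "tpd_domtblout.tsv"),
        ("sfpd_diamond", "sfpd_diamond.tsv"),
        ("tfpd_diamond", "tfpd_diamond.tsv"),
        ("sprot_diamond", "swissprot_diamond.tsv"),
        ("topology", "phobius.tsv"), ("nodes", "nodes.dmp"),
        ("names", "names.dmp"), ("gold", "gold_standard.tsv"),
        ("manifest", "manifest.json"),
    ]}
    _write_sprot(world, paths["swissprot"])
    _write_pfam_hmm(paths["pfam_hmm"])
    with open(paths["proteins_nr"], "w") as fh:
        for s in world.subjects:
            if s["dialect"] == "nr":
                fh.write(f">{s['sid']} {s['desc']}\n{_wrap(s['seq'])}\n")
    with open(paths["proteins_uniref"], "w") as fh:
        for s in world.subjects:
            if s["dialect"] == "uniref":
                fh.write(f">{s['sid']} {s['desc']}\n{_wrap(s['seq'])}\n")
    with open(paths["contigs"], "w") as fh:
        for cid, seq in world.contigs.items():
            fh.write(f">{cid}\n{_wrap(seq)}\n")
    with open(paths["genes"], "w") as fh:
        for g in world.genes:
            fh.write(f">{g['gene_id']}\n{_wrap(g['protein_seq'])}\n")
    _write_sam(world, paths["sam"])
    _write_kraken(world, paths["kraken_per_read"], paths["kraken_report"],
                  paths["bracken"])
    with open(paths["bins"], "w") as fh:
        species_order = [s["taxid"] for s in world.species]
        for cid in world.contigs:
            t = world.contig_species[cid]
            fh.write(f"{cid}\tbin{species_order.index(t)}\n")
    _write_domtbl(world.spd_hits, paths["spd_domtbl"])
    _write_domtbl(world.tpd_hits, paths["tpd_domtbl"])
    _write_diamond(world.sfpd_hits, paths["sfpd_diamond"])
    _write_diamond(world.tfpd_hits, paths["tfpd_diamond"])
    _write_diamond(world.sprot_hits, paths["sprot_diamond"])
    with open(paths["topology"], "w") as fh:
        fh.write("SEQENCE ID\tTM\tSP\tPREDICTION\n")
        for pid in sorted(world.topology):
            sp, tm = world.topology[pid]
            fh.write(f"{pid}\t{tm}\t{'Y' if sp else '0'}\to\n")
    with open(paths["gold"], "w") as fh:
        fh.write("species\ttaxid\trelative_abundance\n")
        for s in world.species:
            if not s.get("false"):
                fh.write(f"{s['name']}\t{s['taxid']}\t"
                         f"{s['true_fraction']:.10f}\n")
    _write_taxdump(world, paths["nodes"], paths["names"])
    with open(paths["manifest"], "w") as fh:
        json.dump(world.manifest(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
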