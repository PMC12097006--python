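"""Binning route: gates, modal bin taxa, quantification, post-filter."""

import io
import random
from collections import Counter

import pytest

from protfam.binroute import (BinAssignment, assign_bin_taxa,
                              build_bin_assignments, filter_contigs_by_length,
                              postfilter_merge, protein_taxa, quantify_bins,
                              read_bin_tsv, resolve_lineage)
from protfam.seek import AlignmentHit, DomainHit
from protfam.taxdb import TaxDb


def _ahit(q, s, ev, bits=100.0):
    return AlignmentHit(query_id=q, subject_id=s, pident=50.0, evalue=ev,
                        bitscore=bits)


def _dhit(p):
    return DomainHit(protein_id=p, profile_accession="PF1",
                     profile_short_name="PF1", evalue=1e-20, bitscore=50.0,
                     ali_from=1, ali_to=10)


class TestContigLengthFilter:
    def test_strictly_greater(self):
        contigs = {"a": 999, "b": 1000, "c": 1001}
        assert filter_contigs_by_length(contigs, 1000) == {"c"}

    def test_zero_cutoff_keeps_nonempty(self):
        assert filter_contigs_by_length({"a": 1, "b": 5}, 0) == {"a", "b"}

    def test_accepts_sequences(self):
        assert filter_contigs_by_length({"a": "ACGT"}, 3) == {"a"}

    def test_random_lengths_match_comparison_oracle(self):
        rng = random.Random(41)
        for _ in range(100):
            lens = {f"c{i}": rng.randint(0, 3000) for i in range(20)}
            cutoff = rng.randint(0, 2500)
            assert filter_contigs_by_length(lens, cutoff) == \
                {c for c, ln in lens.items() if ln > cutoff}


class TestProteinTaxa:
    HEADERS = {"s1": ["Escherichia coli"], "s2": ["Bacillus sp."],
               "multi": ["Escherichia coli", "Bacillus sp."]}

    def test_gate_and_best_hit(self):
        taxa = protein_taxa([_dhit("p1")],
                            [_ahit("p1", "s2", 1e-10), _ahit("p1", "s1", 1e-50)],
                            self.HEADERS)
        assert taxa == {"p1": ["Escherichia coli"]}

    def test_no_profile_hit_no_taxa(self):
        taxa = protein_taxa([], [_ahit("p1", "s1", 1e-50)], self.HEADERS)
        assert taxa == {}

    def test_multi_organism_subject_attributes_both(self):
        taxa = protein_taxa([_dhit("p1")], [_ahit("p1", "multi", 1e-50)],
                            self.HEADERS)
        assert taxa == {"p1": ["Escherichia coli", "Bacillus sp."]}

    def test_gate_monotonicity(self):
        """Removing profile hits can only shrink the taxon-bearing set."""
        tfpd = [_ahit("p1", "s1", 1e-50), _ahit("p2", "s2", 1e-40)]
        full = protein_taxa([_dhit("p1"), _dhit("p2")], tfpd, self.HEADERS)
        reduced = protein_taxa([_dhit("p1")], tfpd, self.HEADERS)
        assert set(reduced) <= set(full)

    def test_organisms_resolve_to_taxids(self, fixture_dir):
        taxdb = TaxDb(fixture_dir / "nodes.dmp", fixture_dir / "names.dmp")
        headers = {"s1": ["Genus0 species0"], "s2": ["Unknown organismus"]}
        taxa = protein_taxa([_dhit("p1"), _dhit("p2")],
                            [_ahit("p1", "s1", 1e-50),
                             _ahit("p2", "s2", 1e-50)],
                            headers, taxdb)
        assert taxa["p1"] == [100]
        assert taxa["p2"] == ["Unknown organismus"]  # name-only fallback


class TestAssignBinTaxa:
    def test_mode(self):
        gene_index = {"c1": ["p1", "p2", "p3"]}
        ptaxa = {"p1": ["t1"], "p2": ["t1"], "p3": ["t2"]}
        assert assign_bin_taxa({"c1"}, gene_index, ptaxa) == [("t1", 2)]

    def test_ties_all_assigned(self):
        gene_index = {"c1": ["p1", "p2"]}
        ptaxa = {"p1": ["t1"], "p2": ["t2"]}
        assert assign_bin_taxa({"c1"}, gene_index, ptaxa) == \
            [("t1", 1), ("t2", 1)]

    def test_no_taxa_empty(self):
        assert assign_bin_taxa({"c1"}, {"c1": ["p1"]}, {}) == []

    def test_random_bins_match_counting_oracle(self):
        rng = random.Random(43)
        for _ in range(1000):
            contigs = {f"c{i}" for i in range(rng.randint(1, 4))}
            gene_index = {c: [f"{c}_p{j}" for j in range(rng.randint(0, 4))]
                          for c in contigs}
            ptaxa = {}
            for c in contigs:
                for p in gene_index[c]:
                    if rng.random() < 0.8:
                        ptaxa[p] = [f"t{rng.randint(1, 4)}"
                                    for _ in range(rng.randint(1, 2))]
            got = assign_bin_taxa(contigs, gene_index, ptaxa)
            oracle = Counter()
            for c in contigs:
                for p in gene_index[c]:
                    oracle.update(ptaxa.get(p, []))
            if not oracle:
                assert got == []
            else:
                mx = max(oracle.values())
                assert dict(got) == {t: n for t, n in oracle.items()
                                     if n == mx}


class TestQuantifyBins:
    def test_planted_proportions_exact(self, world, fixture_dir, manifest):
        with open(fixture_dir / "bins.tsv") as fh:
            raw = read_bin_tsv(fh)
        bins = [BinAssignment(bin_id=b, contig_ids=cs)
                for b, cs in sorted(raw.items())]
        total = manifest["n_reads"]
        quantify_bins(bins, fixture_dir / "reads.sam", total)
        reads_per_species = {s["taxid"]: s["reads"]
                             for s in manifest["species"]}
        species_order = [s["taxid"] for s in manifest["species"]]
        for b in bins:
            taxid = species_order[int(b.bin_id.removeprefix("bin"))]
            assert b.mapped_reads == reads_per_species[taxid]
            assert b.relative_abundance == \
                pytest.approx(reads_per_species[taxid] / total, abs=1e-12)

    def test_reads_outside_bins_ignored(self, fixture_dir, manifest):
        bins = [BinAssignment(bin_id="b0", contig_ids={"contig0"})]
        quantify_bins(bins, fixture_dir / "reads.sam", manifest["n_reads"])
        assert 0 < bins[0].mapped_reads < manifest["n_reads"]

    def test_zero_mapped(self, fixture_dir):
        bins = [BinAssignment(bin_id="b0", contig_ids={"nonexistent"})]
        quantify_bins(bins, fixture_dir / "reads.sam", 100)
        assert bins[0].mapped_reads == 0
        assert bins[0].relative_abundance == 0.0


class TestPostfilterMerge:
    def _bin(self, bid, taxa, ab):
        return BinAssignment(bin_id=bid, contig_ids={bid + "_c"},
                             taxa=[(t, 1) for t in taxa],
                             relative_abundance=ab)

    def test_merge_and_discard(self):
        bins = [self._bin("b1", ["s1"], 0.2), self._bin("b2", ["s1"], 0.1),
                self._bin("b3", ["s2", "s3"], 0.3)]
        rows = postfilter_merge(bins)
        assert len(rows) == 1
        (row,) = rows
        assert row.taxon == "s1" and row.bin_ids == ["b1", "b2"]
        assert row.relative_abundance == pytest.approx(0.3, abs=1e-12)

    def test_all_multi_species_empty_report(self):
        bins = [self._bin("b1", ["s1", "s2"], 0.5),
                self._bin("b2", ["s3", "s4"], 0.5)]
        assert postfilter_merge(bins) == []

    def test_conservation_of_single_species_abundance(self):
        rng = random.Random(47)
        for _ in range(100):
            bins = [self._bin(f"b{i}",
                              [f"s{rng.randint(1, 4)}"
                               for _ in range(rng.randint(1, 3))],
                              rng.random())
                    for i in range(rng.randint(1, 10))]
            # deduplicate taxa within a bin (frequency-tied list semantics)
            for b in bins:
                b.taxa = [(t, 1) for t in dict.fromkeys(t for t, _ in b.taxa)]
            rows = postfilter_merge(bins)
            survivors = [b for b in bins if len(b.taxa) == 1]
            assert sum(r.relative_abundance for r in rows) == pytest.approx(
                sum(b.relative_abundance for b in survivors), abs=1e-12)
            multi = {b.bin_id for b in bins if len(b.taxa) > 1}
            reported = {bid for r in rows for bid in r.bin_ids}
            assert not (multi & reported)

    def test_non_species_ranks_preserved(self, fixture_dir):
        taxdb = TaxDb(fixture_dir / "nodes.dmp", fixture_dir / "names.dmp")
        bins = [BinAssignment(bin_id="b1", contig_ids={"c"},
                              taxa=[(50, 3)], relative_abundance=0.4)]
        rows = postfilter_merge(bins, taxdb=taxdb)
        assert rows[0].rank == "genus" and rows[0].name == "Genus0"


class TestLineage:
    def test_planted_leaf_full_path(self, fixture_dir):
        taxdb = TaxDb(fixture_dir / "nodes.dmp", fixture_dir / "names.dmp")
        lin = resolve_lineage(100, taxdb)
        assert lin.names() == ["root", "Bacteria", "Genus0",
                               "Genus0 species0"]
        assert [r for r, _n, _t in lin.ranked_names] == \
            ["no rank", "superkingdom", "genus", "species"]

    def test_root_single_element(self, fixture_dir):
        taxdb = TaxDb(fixture_dir / "nodes.dmp", fixture_dir / "names.dmp")
        assert resolve_lineage(1, taxdb).names() == ["root"]

    def test_unknown_taxid_raises(self, fixture_dir):
        taxdb = TaxDb(fixture_dir / "nodes.dmp", fixture_dir / "names.dmp")
        with pytest.raises(KeyError):
            resolve_lineage(424242, taxdb)


class TestEndToEnd:
    def test_bin_taxa_recover_planted_species(self, world, fixture_dir,
                                              manifest):
        """Gate + best-hit + mode chain recovers each bin's true species."""
        from protfam.seek import parse_domtblout, parse_alignment_tabular
        from protfam import familydb
        taxdb = TaxDb(fixture_dir / "nodes.dmp", fixture_dir / "names.dmp")
        with open(fixture_dir / "tpd_domtblout.tsv") as fh:
            tpd = parse_domtblout(fh)
        with open(fixture_dir / "tfpd_diamond.tsv") as fh:
            tfpd = parse_alignment_tabular(fh)
        header_index = {}
        with open(fixture_dir / "proteins_nr.fasta") as fh:
            for header, _s in familydb._read_fasta(fh):
                header_index[header.split()[0]] = \
                    familydb.extract_header_taxa(header)
        ptaxa = protein_taxa(tpd, tfpd, header_index, taxdb)
        gene_index = {}
        for g in world.genes:
            gene_index.setdefault(g["contig_id"], []).append(g["gene_id"])
        with open(fixture_dir / "bins.tsv") as fh:
            raw = read_bin_tsv(fh)
        assignments = build_bin_assignments(raw, gene_index, ptaxa)
        species_order = [s["taxid"] for s in manifest["species"]]
        for a in assignments:
            true_taxid = species_order[int(a.bin_id.removeprefix("bin"))]
            assert [t for t, _f in a.taxa] == [true_taxid]
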