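"""Read-classification route: thresholds, votes, species binning."""

import math
import random
from collections import Counter

import pytest

from protfam.krakenroute import (AbundanceProfile, ReadClassification,
                                 ThresholdSpec, apply_threshold,
                                 assign_contig_species, bin_by_species,
                                 parse_kraken_outputs, parse_read_map,
                                 parse_threshold_list, parse_threshold_token,
                                 shannon_index)
from protfam.taxdb import TaxDb


def _profile(*recs):
    return AbundanceProfile(records=[(f"sp{t}", t, r, f) for t, r, f in recs])


class TestThresholdToken:
    @pytest.mark.parametrize("token,kind,value", [
        ("5.0", "relative", 5.0),
        ("0.01", "relative", 0.01),
        ("100", "absolute", 100),
        ("1000", "absolute", 1000),
        ("0", "absolute", 0),
        ("non-gut", "auto_nongut", None),
        ("gut", "auto_gut", None),
    ])
    def test_tokens(self, token, kind, value):
        spec = parse_threshold_token(token)
        assert (spec.kind, spec.value) == (kind, value)

    def test_bad_tokens_rejected(self):
        for bad in ("", "abc", "-5", "1e-3"):
            with pytest.raises(ValueError):
                parse_threshold_token(bad)

    def test_comma_list(self):
        specs = parse_threshold_list("5.0,100,non-gut")
        assert [s.kind for s in specs] == ["relative", "absolute",
                                           "auto_nongut"]


class TestShannon:
    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_uniform_profile_equals_ln_k(self, k):
        p = _profile(*[(100 + i, 10, 1.0 / k) for i in range(k)])
        assert shannon_index(p) == pytest.approx(math.log(k), abs=1e-9)

    def test_single_species_zero(self):
        assert shannon_index(_profile((1, 10, 1.0))) == pytest.approx(0.0)

    def test_random_profiles_match_summation_oracle(self):
        rng = random.Random(17)
        for _ in range(100):
            fracs = [rng.uniform(0.01, 1) for _ in range(rng.randint(1, 12))]
            total = sum(fracs)
            p = _profile(*[(100 + i, 1, f) for i, f in enumerate(fracs)])
            oracle = 0.0
            for f in fracs:
                q = f / total
                oracle -= q * math.log(q)
            assert shannon_index(p) == pytest.approx(oracle, abs=1e-12)

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError):
            shannon_index(_profile())


class TestApplyThreshold:
    def test_relative_keeps_above(self):
        p = _profile((1, 900, 0.9), (2, 60, 0.06), (3, 40, 0.04))
        kept = apply_threshold(p, ThresholdSpec("relative", 5.0))
        assert kept.taxids() == {1, 2}
        # fractions not renormalized: pruned reads are not reassigned
        assert kept.records[0][3] == 0.9

    def test_absolute_zero_is_identity(self):
        p = _profile((1, 5, 0.5), (2, 5, 0.5))
        assert apply_threshold(p, ThresholdSpec("absolute", 0)).records == \
            p.records

    def test_idempotent(self):
        p = _profile((1, 900, 0.9), (2, 60, 0.06), (3, 40, 0.04))
        spec = ThresholdSpec("absolute", 50)
        once = apply_threshold(p, spec)
        assert apply_threshold(once, spec).records == once.records

    def test_auto_kind_resolves_via_policy(self):
        p = _profile((1, 900, 0.9), (2, 100, 0.1))
        policy = lambda h, gut: ThresholdSpec("relative", 50.0)
        kept = apply_threshold(p, ThresholdSpec("auto_nongut"), policy)
        assert kept.taxids() == {1}

    def test_random_profiles_match_scan_oracle(self):
        rng = random.Random(23)
        for _ in range(200):
            recs = [(100 + i, rng.randint(0, 2000), rng.random())
                    for i in range(rng.randint(1, 15))]
            p = _profile(*recs)
            if rng.random() < 0.5:
                spec = ThresholdSpec("absolute", rng.randint(0, 1500))
                oracle = {t for t, r, _f in recs if r >= spec.value}
            else:
                spec = ThresholdSpec("relative", rng.uniform(0.01, 100))
                oracle = {t for t, _r, f in recs if 100 * f >= spec.value}
            kept = apply_threshold(p, spec)
            assert kept.taxids() == oracle
            assert set(kept.records) <= set(p.records)  # always a subset
            # raising the threshold never adds species
            if spec.kind == "absolute":
                higher = ThresholdSpec("absolute", int(spec.value) + 10)
            else:
                higher = ThresholdSpec("relative",
                                       min(100.0, spec.value * 1.5 + 0.01))
            assert apply_threshold(p, higher).taxids() <= oracle


class TestContigVote:
    def _vote(self, votes):
        """Run a single-contig vote through the full machinery."""
        read_map, cls = [], []
        i = 0
        for taxid, n in votes.items():
            for _ in range(n):
                rid = f"r{i}"
                i += 1
                read_map.append((rid, "c1"))
                cls.append(ReadClassification(rid, taxid, "species"))
        out = assign_contig_species(read_map, cls, set(votes))
        return out[0].species_taxid if out else None

    def test_majority(self):
        assert self._vote({1: 3, 2: 1}) == 1

    def test_tie_unassigned(self):
        assert self._vote({1: 2, 2: 2}) is None

    def test_no_species_votes_unassigned(self):
        read_map = [("r1", "c1")]
        cls = [ReadClassification("r1", 50, "genus")]
        (ct,) = assign_contig_species(read_map, cls, {100})
        assert ct.species_taxid is None and ct.vote_counts == {}

    def test_filtered_species_do_not_vote(self):
        read_map = [("r1", "c1"), ("r2", "c1")]
        cls = [ReadClassification("r1", 1, "species"),
               ReadClassification("r2", 2, "species")]
        (ct,) = assign_contig_species(read_map, cls, kept_species={2})
        assert ct.species_taxid == 2

    def test_strain_reads_lift_to_species(self, fixture_dir):
        taxdb = TaxDb(fixture_dir / "nodes.dmp", fixture_dir / "names.dmp")
        read_map = [("r1", "c1"), ("r2", "c1")]
        cls = [ReadClassification("r1", 200, "below species"),
               ReadClassification("r2", 100, "species")]
        (ct,) = assign_contig_species(read_map, cls, {100}, taxdb)
        assert ct.species_taxid == 100 and ct.vote_counts == {100: 2}

    def test_random_vote_tables_match_argmax_oracle(self):
        rng = random.Random(29)
        for _ in range(1000):
            votes = {100 + t: rng.randint(1, 6)
                     for t in range(rng.randint(0, 5))}
            got = self._vote(votes)
            if not votes:
                assert got is None
                continue
            mx = max(votes.values())
            winners = [t for t, n in votes.items() if n == mx]
            assert got == (winners[0] if len(winners) == 1 else None)


class TestBinBySpecies:
    def _taxa(self, mapping):
        from protfam.krakenroute import ContigTaxonomy
        return [ContigTaxonomy(c, t, {}) for c, t in mapping.items()]

    def test_group_by(self):
        p = _profile((1, 50, 0.5), (2, 50, 0.5))
        bins = bin_by_species(self._taxa({"c1": 1, "c2": 1, "c3": 2}), p)
        assert {b.species_taxid: b.contig_ids for b in bins} == \
            {1: {"c1", "c2"}, 2: {"c3"}}
        assert all(b.reads == 50 for b in bins)

    def test_unassigned_contigs_not_binned(self):
        p = _profile((1, 10, 1.0))
        bins = bin_by_species(self._taxa({"c1": 1, "c2": None}), p)
        assert len(bins) == 1 and bins[0].contig_ids == {"c1"}

    def test_no_assigned_contigs_zero_bins(self):
        assert bin_by_species(self._taxa({"c1": None}), _profile()) == []

    def test_species_missing_from_profile_raises(self):
        with pytest.raises(ValueError):
            bin_by_species(self._taxa({"c1": 7}), _profile((1, 1, 1.0)))

    def test_bins_partition_assigned_contigs(self):
        rng = random.Random(37)
        for _ in range(50):
            taxids = list(range(1, rng.randint(2, 6)))
            p = _profile(*[(t, 10, 1 / len(taxids)) for t in taxids])
            mapping = {f"c{i}": rng.choice(taxids + [None])
                       for i in range(rng.randint(1, 20))}
            bins = bin_by_species(self._taxa(mapping), p)
            seen = Counter()
            for b in bins:
                seen.update(b.contig_ids)
            assigned = {c for c, t in mapping.items() if t is not None}
            assert set(seen) == assigned
            assert all(v == 1 for v in seen.values())  # never in two bins


class TestParsing:
    def test_fixture_round_trip(self, world, fixture_dir, manifest):
        with open(fixture_dir / "kraken_per_read.tsv") as pr, \
             open(fixture_dir / "kraken_report.tsv") as rp, \
             open(fixture_dir / "bracken_report.tsv") as br:
            cls, profile = parse_kraken_outputs(pr, rp, br)
        assert len(cls) == manifest["n_reads"]
        assert profile.taxids() == {s["taxid"] for s in manifest["species"]}
        # per-read species counts aggregate to the report reads
        taxdb = TaxDb(fixture_dir / "nodes.dmp", fixture_dir / "names.dmp")
        counts = Counter()
        for c in cls:
            sp = taxdb.ancestor_at_rank(c.taxid, "species")
            if sp is not None:
                counts[sp] += 1
        assert {t: r for _n, t, r, _f in profile.records} == dict(counts)

    def test_per_read_ranks_resolved_from_report(self, fixture_dir):
        with open(fixture_dir / "kraken_per_read.tsv") as pr, \
             open(fixture_dir / "kraken_report.tsv") as rp, \
             open(fixture_dir / "bracken_report.tsv") as br:
            cls, _ = parse_kraken_outputs(pr, rp, br)
        ranks = {c.rank for c in cls}
        assert "species" in ranks

    def test_sam_primary_counts_match_manifest(self, world, fixture_dir,
                                               manifest):
        pairs = parse_read_map(fixture_dir / "reads.sam")
        per_contig = Counter(c for _r, c in pairs)
        expect = Counter()
        for r in world.reads:
            if r["contig_id"] is not None:
                expect[r["contig_id"]] += 1
        assert per_contig == expect


class TestPerfectRecovery:
    def test_planted_community_recovered_exactly(self, world, fixture_dir,
                                                 manifest):
        taxdb = TaxDb(fixture_dir / "nodes.dmp", fixture_dir / "names.dmp")
        with open(fixture_dir / "kraken_per_read.tsv") as pr, \
             open(fixture_dir / "kraken_report.tsv") as rp, \
             open(fixture_dir / "bracken_report.tsv") as br:
            cls, profile = parse_kraken_outputs(pr, rp, br)
        filtered = apply_threshold(profile, ThresholdSpec("absolute", 0))
        read_map = parse_read_map(fixture_dir / "reads.sam")
        contig_taxa = assign_contig_species(read_map, cls,
                                            filtered.taxids(), taxdb)
        bins = bin_by_species(contig_taxa, filtered)
        planted = {s["taxid"]: s["reads"] for s in manifest["species"]}
        assert {b.species_taxid for b in bins} == set(planted)
        for b in bins:
            assert b.reads == planted[b.species_taxid]
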