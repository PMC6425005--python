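"""Cleavage-motif scanner, domain/reference filters, redundancy collapse."""

import re

import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from prospect import (
    DomainHit,
    ProteinRecord,
    cleavage_patterns,
    filter_by_domains,
    has_repetitive_sites,
    remove_redundancy,
    scan_cleavage_sites,
    screen_against_reference,
)
from prospect.screen import CleavageSite

from conftest import random_records


# --- independent oracle: all-substrings brute force --------------------------
# A full match of any pattern uses only residues from {R,K,G}, so candidate
# substrings live inside maximal {R,K,G}-runs; each is tested with an
# anchored regex, then the same leftmost/longest/lowest-id/non-overlap
# resolution is applied.

def brute_force_sites(seq):
    patterns = [re.compile(p) for p in cleavage_patterns()]
    candidates = []  # (start, end, pid)
    n = len(seq)
    i = 0
    while i < n:
        if seq[i] not in "RKG":
            i += 1
            continue
        j = i
        while j < n and seq[j] in "RKG":
            j += 1
        for a in range(i, j):
            for b in range(a + 1, j + 1):
                sub = seq[a:b]
                for pid, pat in enumerate(patterns):
                    if pat.fullmatch(sub):
                        candidates.append((a, b, pid))
                        break  # lowest pid for this substring
        i = j
    sites = []
    pos = 0
    while pos < n:
        here = [(b, pid) for a, b, pid in candidates if a == pos]
        if not here:
            pos += 1
            continue
        end, pid = min(here, key=lambda t: (-t[0], t[1]))
        sites.append((pos, end, pid))
        pos = end
    return sites


class TestPatterns:
    def test_exactly_ten_patterns(self):
        assert len(cleavage_patterns()) == 10

    def test_first_pattern_matches_dibasic_with_donor_glycine(self):
        pat = re.compile(cleavage_patterns()[0])
        assert pat.fullmatch("GKR")
        assert pat.fullmatch("RGKRK")

    def test_no_pattern_matches_a_non_basic_motif(self):
        assert not any(re.fullmatch(p, "GAG") for p in cleavage_patterns())


class TestScanner:
    def test_single_site_with_donor_glycine(self):
        (site,) = scan_cleavage_sites("AAAGKRAAA")
        assert site.span == (3, 6)
        assert site.core == "GKR"
        assert site.g_donor

    def test_no_sites_in_hydrophobic_sequence(self):
        assert scan_cleavage_sites("AILV") == []

    def test_empty_input(self):
        assert scan_cleavage_sites("") == []

    def test_sites_are_sorted_and_non_overlapping(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(150))
            sites = scan_cleavage_sites(seq)
            for a, b in zip(sites, sites[1:]):
                assert a.end <= b.start
            for s in sites:
                assert seq[s.start : s.end] == s.core

    def test_matches_brute_force_oracle_on_random_sequences(self, rng):
        for _ in range(1000):
            length = rng.randint(0, 200)
            seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(length))
            got = [(s.start, s.end, s.pattern_id) for s in scan_cleavage_sites(seq)]
            assert got == brute_force_sites(seq), seq

    def test_matches_oracle_on_basic_rich_sequences(self, rng):
        # stress the flank resolution with a K/R/G-heavy alphabet
        for _ in range(300):
            seq = "".join(rng.choice("KRGAKRG") for _ in range(rng.randint(0, 60)))
            got = [(s.start, s.end, s.pattern_id) for s in scan_cleavage_sites(seq)]
            assert got == brute_force_sites(seq), seq

    def test_invariant_under_appending_neutral_residues(self, rng):
        # padding with non-{R,K,G} characters must not change the site set
        for _ in range(100):
            seq = "".join(rng.choice("KRGAST") for _ in range(30))
            base = [(s.start, s.end, s.pattern_id) for s in scan_cleavage_sites(seq)]
            padded = [
                (s.start - 3, s.end - 3, s.pattern_id)
                for s in scan_cleavage_sites("QWH" + seq + "YPN")
            ]
            assert padded == base


class TestRepetitiveGate:
    def site(self, start=0):
        return CleavageSite(start=start, end=start + 3, core="GKR", pattern_id=0, g_donor=True)

    def test_single_site_satisfies_the_default_gate(self):
        assert has_repetitive_sites([self.site()], min_sites=1)

    def test_no_sites_fails(self):
        assert not has_repetitive_sites([], min_sites=1)

    def test_stricter_reading_requires_two(self):
        assert not has_repetitive_sites([self.site()], min_sites=2)
        assert has_repetitive_sites([self.site(0), self.site(10)], min_sites=2)


class TestDomainFilter:
    def rec(self, rid="c"):
        return ProteinRecord(id=rid, sequence="FMRFGKRFMRFGKR")

    def hit(self, evalue, accession="PF00001.2", rid="c"):
        return DomainHit(rid, accession, "dom", evalue, 0, 5)

    def test_confident_hit_removes_record(self):
        kept, removed = filter_by_domains([self.rec()], [self.hit(1e-12)], 1e-10)
        assert kept == [] and len(removed) == 1
        assert "PF00001" in removed[0][1]

    def test_weak_hit_keeps_record(self):
        kept, removed = filter_by_domains([self.rec()], [self.hit(1e-05)], 1e-10)
        assert len(kept) == 1 and removed == []

    def test_allowlisted_accession_is_exempt(self):
        # the FMRFamide-related-peptide model must not discard precursors
        kept, _ = filter_by_domains(
            [self.rec()], [self.hit(1e-20, "PF01581.5")], 1e-10, allowlist=["PF01581"]
        )
        assert len(kept) == 1

    def test_tightening_threshold_is_monotone(self, rng):
        records = random_records(rng, 30)
        hits = [self.hit(10.0 ** rng.uniform(-20, 0), rid=r.id) for r in records]
        strict, _ = filter_by_domains(records, hits, 1e-12)
        loose, _ = filter_by_domains(records, hits, 1e-06)
        assert {r.id for r in loose} <= {r.id for r in strict}


class TestRedundancy:
    def test_identical_sequences_collapse(self):
        a = ProteinRecord(id="a", sequence="FMRFGKRFMRF")
        b = ProteinRecord(id="b", sequence="FMRFGKRFMRF")
        clusters = remove_redundancy([a, b], 0.95)
        assert len(clusters.representatives) == 1
        assert clusters.membership["b"] == clusters.membership["a"]

    def test_half_identity_stays_apart(self):
        a = ProteinRecord(id="a", sequence="AAAAAAAAAA")
        b = ProteinRecord(id="b", sequence="AAAAACCCCC")
        clusters = remove_redundancy([a, b], 0.95)
        assert len(clusters.representatives) == 2

    def test_every_member_identity_to_representative_verified_by_oracle(self, rng):
        records = random_records(rng, 100, min_len=20, max_len=60)
        # salt in some near-duplicates so clusters actually form
        for i in range(0, 30, 2):
            seq = list(records[i].sequence)
            seq[0] = "A"
            records.append(ProteinRecord(id=f"dup{i}", sequence="".join(seq)))
        clusters = remove_redundancy(records, 0.95)
        m = substitution_matrices.load("BLOSUM62")
        aligner = PairwiseAligner(
            mode="local", substitution_matrix=m, open_gap_score=-12, extend_gap_score=-1
        )
        by_id = {r.id: r.sequence for r in records}
        n_members = 0
        for member, rep in clusters.membership.items():
            if member == rep:
                continue
            n_members += 1
            aln = aligner.align(by_id[member], by_id[rep])[0]
            ident = sum(
                sum(1 for x, y in zip(by_id[member][qa:qb], by_id[rep][sa:sb]) if x == y)
                for (qa, qb), (sa, sb) in zip(aln.aligned[0], aln.aligned[1])
            )
            assert ident / min(len(by_id[member]), len(by_id[rep])) >= 0.95
        assert n_members >= 10  # the oracle actually exercised members

    def test_representatives_map_to_themselves(self, rng):
        records = random_records(rng, 20)
        clusters = remove_redundancy(records, 0.95)
        for rep in clusters.representatives:
            assert clusters.membership[rep] == rep


class TestReferenceScreen:
    def make_candidate(self, rid="cand"):
        return ProteinRecord(id=rid, sequence="QWERTYIPASDFHKLMNVCW")

    def test_self_similar_candidate_is_kept(self):
        cand = self.make_candidate()
        ref = ProteinRecord(id="ref", sequence=cand.sequence)
        kept, _ = screen_against_reference([cand], [ref], 1e-03)
        assert kept == [cand]

    def test_unrelated_candidate_is_removed(self):
        cand = ProteinRecord(id="cand", sequence="PPPPPPPPPP")
        ref = ProteinRecord(id="ref", sequence="WWWWWCCCCC")
        kept, removed = screen_against_reference([cand], [ref], 1e-03)
        assert kept == [] and len(removed) == 1

    def test_imported_hit_table_thresholds(self, tmp_path):
        from prospect import SimilarityHit

        cand_hit = SimilarityHit("kept", "ref", 100.0, 10, 0, 0, 0, 10, 0, 10, 1e-05, 30.0)
        weak_hit = SimilarityHit("lost", "ref", 100.0, 10, 0, 0, 0, 10, 0, 10, 0.1, 12.0)
        records = [
            ProteinRecord(id="kept", sequence="FMRFGKRFMRF"),
            ProteinRecord(id="lost", sequence="FMRFGKRFMRF"),
        ]
        kept, removed = screen_against_reference(
            records, None, 1e-03, hit_table=[cand_hit, weak_hit]
        )
        assert [r.id for r in kept] == ["kept"]
        assert [r.id for r, _ in removed] == ["lost"]

    def test_empty_reference_is_a_configuration_error(self):
        from prospect import ConfigError

        with pytest.raises(ConfigError):
            screen_against_reference([self.make_candidate()], [], 1e-03)
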