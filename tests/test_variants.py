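"""PAM scanning, VCF intersection, allele substitution and target ranking."""

import numpy as np
import pandas as pd
import pytest

from editnas import (SNV, VariantEffectRecord, generate_windows,
                     intersect_variants, predict_variant_effect,
                     rank_least_variant_targets, scan_pam_sites)
from editnas.exceptions import RefMismatchError, ReferenceError_
from editnas.sequences import reverse_complement
from editnas.variants import read_snvs, variant_effect_table, window_span


def brute_force_scan(seq, start, end):
    """Oracle: check every position for GG (forward) / CC (reverse) context."""
    fwd = [p for p in range(start, min(end, len(seq))) if seq[p + 1: p + 3] == "GG"]
    rev = [p for p in range(start, min(end, len(seq))) if p >= 2 and seq[p - 2: p] == "CC"]
    return fwd, rev


class TestScanPamSites:
    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        bed = pd.DataFrame([("c1", 50, 350)], columns=["chrom", "start", "end"])
        sites = scan_pam_sites({"c1": seq}, bed)
        fwd, rev = brute_force_scan(seq, 50, 350)
        got_fwd = sorted(s.pam_start_genomic for s in sites if s.strand == "+")
        got_rev = sorted(s.pam_start_genomic for s in sites if s.strand == "-")
        assert got_fwd == fwd and got_rev == rev
        # scanned forward sites carry GG at window positions 34-35
        for s in sites:
            assert s.has_valid_pam

    def test_no_g_or_c_no_sites(self):
        bed = pd.DataFrame([("c1", 0, 100)], columns=["chrom", "start", "end"])
        assert scan_pam_sites({"c1": "AT" * 50}, bed) == []

    def test_palindromic_pair_both_strands(self):
        # CCNGG: reverse hit at the N (CC before it) and forward hit at the N
        seq = "A" * 100 + "CCAGG" + "A" * 100
        bed = pd.DataFrame([("c1", 95, 115)], columns=["chrom", "start", "end"])
        sites = scan_pam_sites({"c1": seq}, bed)
        strands = {(s.pam_start_genomic, s.strand) for s in sites}
        assert (102, "+") in strands   # A at 102, GG at 103-104
        assert (102, "-") in strands   # CC at 100-101 precedes 102
        assert len(sites) == 2

    def test_missing_chromosome(self):
        bed = pd.DataFrame([("cX", 0, 10)], columns=["chrom", "start", "end"])
        with pytest.raises(ReferenceError_):
            scan_pam_sites({"c1": "ACGT" * 10}, bed)

    def test_scan_against_fixture_truth(self, genome_fixture):
        sites = scan_pam_sites(genome_fixture["fasta"], genome_fixture["bed"])
        t = genome_fixture["truth"]
        n_fwd = sum(1 for s in sites if s.strand == "+")
        n_rev = sum(1 for s in sites if s.strand == "-")
        assert n_fwd == t["n_sites_forward"]
        assert n_rev == t["n_sites_reverse"]


class TestIntersectVariants:
    def test_fixture_pair_count_matches_truth(self, genome_fixture):
        sites = scan_pam_sites(genome_fixture["fasta"], genome_fixture["bed"])
        pairs = intersect_variants(sites, str(genome_fixture["vcf"]))
        assert len(pairs) == genome_fixture["truth"]["n_pairs"]

    def test_matches_bruteforce_interval_check(self, genome_fixture):
        sites = scan_pam_sites(genome_fixture["fasta"], genome_fixture["bed"])
        snvs = read_snvs(genome_fixture["vcf"])
        pairs = intersect_variants(sites, snvs)
        expected = sum(1 for s in sites for v in snvs
                       if window_span(s)[0] <= v.pos < window_span(s)[1])
        assert len(pairs) == expected

    def test_distant_variant_excluded(self):
        seq = "A" * 200 + "TGG" + "A" * 300
        bed = pd.DataFrame([("c1", 195, 210)], columns=["chrom", "start", "end"])
        sites = scan_pam_sites({"c1": seq}, bed)
        far = SNV("v1", "c1", 400, "A", "C")
        near = SNV("v2", "c1", 200, "T", "C")
        pairs = intersect_variants(sites, [far, near])
        assert all(v.variant_id == "v2" for _, v in pairs)

    def test_window_boundary_position(self):
        seq = "A" * 200 + "TGG" + "A" * 300
        bed = pd.DataFrame([("c1", 195, 205)], columns=["chrom", "start", "end"])
        sites = [s for s in scan_pam_sites({"c1": seq}, bed)
                 if s.strand == "+" and s.pam_start_genomic == 200]
        lo, hi = window_span(sites[0])
        first = SNV("v", "c1", lo, "A", "G")
        pairs = intersect_variants(sites, [first])
        from editnas.variants import window_position_of

        assert window_position_of(sites[0], lo) == 1
        assert len(pairs) == 1


class TestPredictVariantEffect:
    def test_ref_equals_alt_zero_effect(self, tiny_trained_model):
        seq = "A" * 200 + "TGG" + "A" * 300
        bed = pd.DataFrame([("c1", 195, 205)], columns=["chrom", "start", "end"])
        site = [s for s in scan_pam_sites({"c1": seq}, bed)
                if s.pam_start_genomic == 200 and s.strand == "+"][0]
        rec = predict_variant_effect(tiny_trained_model, site,
                                     SNV("v", "c1", 190, "A", "A"))
        assert np.all(rec.abs_diff == 0.0)
        assert rec.mean_abs_diff == 0.0

    def test_ref_mismatch_raises(self, tiny_trained_model):
        seq = "A" * 200 + "TGG" + "A" * 300
        bed = pd.DataFrame([("c1", 195, 205)], columns=["chrom", "start", "end"])
        site = [s for s in scan_pam_sites({"c1": seq}, bed)
                if s.pam_start_genomic == 200 and s.strand == "+"][0]
        with pytest.raises(RefMismatchError):
            predict_variant_effect(tiny_trained_model, site,
                                   SNV("v", "c1", 190, "C", "G"))

    def test_minus_strand_allele_complemented(self, tiny_trained_model):
        # CC at 198-199 -> minus-strand PAM at 200; forward A reads T in-window
        seq = "A" * 198 + "CC" + "A" * 300
        bed = pd.DataFrame([("c1", 195, 205)], columns=["chrom", "start", "end"])
        site = [s for s in scan_pam_sites({"c1": seq}, bed)
                if s.strand == "-" and s.pam_start_genomic == 200][0]
        rec = predict_variant_effect(tiny_trained_model, site,
                                     SNV("v", "c1", 210, "A", "G"))
        wp = rec.window_position
        assert site.window[wp - 1] == "T"  # complement of forward A
        assert rec.mean_abs_diff >= 0.0

    def test_window_position_bounds(self):
        with pytest.raises(RefMismatchError):
            VariantEffectRecord("s", "v", 0, (0.5,) * 6, (0.5,) * 6)


class TestRanking:
    def _rec(self, sid, vid, diff):
        ref = (0.5,) * 6
        alt = tuple(0.5 + diff for _ in range(6))
        return VariantEffectRecord(sid, vid, 1, ref, alt)

    def test_snv_free_sites_rank_first(self):
        recs = [self._rec("sA", "v1", 0.2)]
        ranked = rank_least_variant_targets(recs, all_sites=["sA", "sB"])
        assert ranked.iloc[0]["site_id"] == "sB"
        assert bool(ranked.iloc[0]["no_snv"])
        assert ranked.iloc[0]["score"] == 0.0

    def test_site_score_is_mean_over_snvs(self):
        recs = [self._rec("s", "v1", 0.1), self._rec("s", "v2", 0.3)]
        ranked = rank_least_variant_targets(recs)
        assert ranked.iloc[0]["score"] == pytest.approx(0.2)

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(9)
        recs = []
        scores = {}
        for i in range(10):
            sid = f"site{i}"
            diffs = rng.uniform(0, 0.4, size=rng.integers(1, 4))
            scores[sid] = float(np.mean(diffs))
            recs += [self._rec(sid, f"v{i}_{j}", d) for j, d in enumerate(diffs)]
        rng.shuffle(recs)
        ranked = rank_least_variant_targets(recs)
        oracle = [sid for sid, _ in sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))]
        assert list(ranked["site_id"]) == oracle

    def test_stable_under_reordering(self):
        recs = [self._rec("a", "v1", 0.1), self._rec("b", "v2", 0.1),
                self._rec("c", "v3", 0.05)]
        r1 = rank_least_variant_targets(recs)
        r2 = rank_least_variant_targets(list(reversed(recs)))
        assert list(r1["site_id"]) == list(r2["site_id"])


def test_variant_effect_table_end_to_end(tiny_trained_model, genome_fixture):
    sites = scan_pam_sites(genome_fixture["fasta"], genome_fixture["bed"])
    table = variant_effect_table(tiny_trained_model, sites,
                                 str(genome_fixture["vcf"]))
    assert len(table) == genome_fixture["truth"]["n_pairs"]
    for task in ("ins1", "del_freq"):
        assert np.allclose(table[f"absdiff_{task}"],
                           (table[f"ref_{task}"] - table[f"alt_{task}"]).abs())
    assert (table["mean_abs_diff"] >= 0).all()
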