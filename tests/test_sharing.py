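"""Private alleles, sharing with focal individuals, propS bins, IBS."""

import numpy as np
import pytest

from ghostalleles import (
    MISSING,
    RarefactionSpec,
    allele_frequencies,
    focal_unique_alleles,
    ibs_matrix,
    private_alleles,
    shared_private_report,
    shared_private_richness,
)
from ghostalleles.sharing import PrivateAlleleSet, percent_shared

from conftest import make_matrix, make_popmap
from test_diversity import enumeration_oracle


def brute_force_privates(calls, groups):
    """Nested-loop oracle: (site, allele) pairs observed in exactly one group."""
    sets = {g: set() for g in groups}
    n_sites = calls.shape[1]
    for j in range(n_sites):
        for allele in (0, 1):
            owners = []
            for g, rows in groups.items():
                count = 0
                for i in rows:
                    d = calls[i, j]
                    if d == MISSING:
                        continue
                    count += d if allele == 1 else 2 - d
                if count > 0:
                    owners.append(g)
            if len(owners) == 1:
                sets[owners[0]].add((j, allele))
    return sets


class TestPrivateAlleles:
    def test_allele_in_two_groups_is_not_private(self):
        calls = np.array([[1], [0], [1], [0]], dtype=np.int8)
        G = make_matrix(calls)
        pm = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]})
        priv = private_alleles(allele_frequencies(G, pm))
        assert priv.sets["a"] == set() and priv.sets["b"] == set()

    def test_singleton_counts_as_private(self):
        calls = np.array([[1], [0], [0], [0]], dtype=np.int8)
        G = make_matrix(calls)
        pm = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]})
        priv = private_alleles(allele_frequencies(G, pm))
        assert priv.sets["a"] == {(0, 1)}

    def test_focal_samples_never_veto_privateness(self):
        calls = np.array([[1], [0], [0], [0], [2]], dtype=np.int8)
        G = make_matrix(calls)
        pm_with = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]}, focals=["s4"])
        pm_without = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]})
        G4 = G.subset_samples(["s0", "s1", "s2", "s3"])
        p1 = private_alleles(allele_frequencies(G, pm_with))
        p2 = private_alleles(allele_frequencies(G4, pm_without))
        assert p1.sets == p2.sets

    def test_matches_brute_force_nested_loop(self):
        rng = np.random.default_rng(13)
        calls = rng.integers(-1, 3, size=(16, 50)).astype(np.int8)
        G = make_matrix(calls)
        groups = {
            "g1": [f"s{i}" for i in range(5)],
            "g2": [f"s{i}" for i in range(5, 9)],
            "g3": [f"s{i}" for i in range(9, 13)],
            "g4": [f"s{i}" for i in range(13, 16)],
        }
        pm = make_popmap(groups)
        priv = private_alleles(allele_frequencies(G, pm))
        expected = brute_force_privates(
            calls, {g: [G.sample_index(s) for s in m] for g, m in groups.items()}
        )
        assert {g: s for g, s in priv.sets.items()} == expected

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="private to multiple"):
            PrivateAlleleSet(sets={"a": {(0, 1)}, "b": {(0, 1)}})

    def test_needs_two_reference_groups(self):
        calls = np.zeros((2, 3), dtype=np.int8)
        G = make_matrix(calls)
        pm = make_popmap({"a": ["s0", "s1"]})
        with pytest.raises(ValueError, match=">= 2 reference"):
            private_alleles(allele_frequencies(G, pm))


class TestPercentRule:
    def test_two_decimal_rounding(self):
        assert percent_shared(2632, 184) == 6.99
        assert percent_shared(188, 21) == 11.17

    def test_shared_cannot_exceed_private(self):
        with pytest.raises(ValueError):
            percent_shared(3, 4)

    def test_zero_denominator_undefined(self):
        assert np.isnan(percent_shared(0, 0))


class TestSharedPrivateReport:
    def build(self):
        # 4 sites; groups a (2 samples), b (2 samples); focal f
        # site0: ALT private to a (focal het)        -> shared
        # site1: ALT private to b (focal lacks it)   -> not shared
        # site2: REF private to a (focal hom REF)    -> shared, hom
        # site3: focal missing                       -> excluded from survey
        calls = np.array(
            [
                [1, 0, 0, 1],  # a1
                [1, 0, 1, 1],  # a2
                [0, 1, 2, 1],  # b1
                [0, 1, 2, 1],  # b2
                [1, 0, 0, MISSING],  # f
            ],
            dtype=np.int8,
        )
        G = make_matrix(calls)
        pm = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]}, focals=["s4"])
        return G, pm

    def test_counts_zygosity_and_percentages(self):
        G, pm = self.build()
        rep = shared_private_report(G, pm, "s4")
        assert rep.loci_surveyed == 3
        a = rep.per_group["a"]
        assert (a["N_PA"], a["S_PA"], a["S_PA_pct"]) == (2, 2, 100.0)
        zyg = {(d["pos"], d["allele"]): d["zygosity"] for d in a["shared_detail"]}
        assert zyg == {(100, 1): "het", (300, 0): "hom"}

    def test_counts_match_brute_force(self):
        G, pm = self.build()
        rep = shared_private_report(G, pm, "s4")
        surveyed = [j for j in range(4) if G.calls[4, j] != MISSING]
        sub = G.calls[:, surveyed]
        expected = brute_force_privates(sub, {"a": [0, 1], "b": [2, 3]})
        for grp in ("a", "b"):
            assert rep.per_group[grp]["N_PA"] == len(expected[grp])
            carried = 0
            for j, allele in expected[grp]:
                d = sub[4, j]
                if d != MISSING and (d >= 1 if allele == 1 else d <= 1):
                    carried += 1
            assert rep.per_group[grp]["S_PA"] == carried

    def test_focal_missing_everywhere_at_private_sites(self):
        calls = np.array(
            [[1, 1], [0, 0], [0, 0], [0, 0], [MISSING, MISSING]], dtype=np.int8
        )
        G = make_matrix(calls)
        pm = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]}, focals=["s4"])
        with pytest.raises(ValueError):
            # zero surveyed loci leaves nothing to recompute privates over
            shared_private_report(G, pm, "s4")

    def test_unknown_focal_is_fatal(self, small_panel):
        G, pm, _ = small_panel
        with pytest.raises(ValueError, match="not in genotype"):
            shared_private_report(G, pm, "nobody")

    def test_percentage_recomputes_from_report_columns(self, small_panel):
        G, pm, _ = small_panel
        rep = shared_private_report(G, pm, "GI-1")
        for grp, rec in rep.per_group.items():
            if rec["N_PA"]:
                assert rec["S_PA_pct"] == round(100 * rec["S_PA"] / rec["N_PA"], 2)

    def test_surveys_are_per_focal(self, small_panel):
        G, pm, _ = small_panel
        r1 = shared_private_report(G, pm, "GI-1")
        r2 = shared_private_report(G, pm, "GI-2")
        assert r1.loci_surveyed != r2.loci_surveyed or r1.per_group != r2.per_group


class TestFreqBins:
    def test_bins_match_brute_force_tally(self, small_panel):
        G, pm, _ = small_panel
        rep = shared_private_report(G, pm, "GI-1")
        fi = G.sample_index("GI-1")
        surveyed = G.calls[fi, :] != MISSING
        Gs = G.subset_sites(surveyed)
        freq = allele_frequencies(Gs, pm)
        priv = private_alleles(freq)
        for grp in pm.groups:
            r = freq.row(grp)
            priv_count = np.zeros(10, int)
            shared_count = np.zeros(10, int)
            for j, allele in priv.sets[grp]:
                cop = freq.copies[r, j]
                cnt = freq.allele_count(grp, j, allele)
                f = cnt / cop
                b = min(int(np.ceil(f * 10)) - 1, 9)
                priv_count[b] += 1
                d = int(Gs.calls[Gs.sample_index("GI-1"), j])
                if d >= 1 if allele == 1 else d <= 1:
                    shared_count[b] += 1
            for b, row in enumerate(rep.per_group[grp]["propS_bins"]):
                assert row["n_private"] == priv_count[b]
                assert row["n_shared"] == shared_count[b]
                if priv_count[b] == 0:
                    assert np.isnan(row["propS"])
                else:
                    assert row["propS"] == pytest.approx(shared_count[b] / priv_count[b])

    def test_all_shared_bin_is_one(self):
        calls = np.array([[2], [2], [0], [0], [1]], dtype=np.int8)
        G = make_matrix(calls)
        pm = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]}, focals=["s4"])
        rep = shared_private_report(G, pm, "s4")
        bins = rep.per_group["a"]["propS_bins"]
        assert bins[-1]["propS"] == 1.0  # ALT at frequency 1.0 in a, carried

    def test_global_denominator_option(self):
        calls = np.array([[2, 1], [2, 0], [0, 0], [0, 0], [1, 0]], dtype=np.int8)
        G = make_matrix(calls)
        pm = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]}, focals=["s4"])
        rep = shared_private_report(G, pm, "s4", global_denominator=True)
        bins = rep.per_group["a"]["propS_bins"]
        total_priv = sum(b["n_private"] for b in bins)
        for b in bins:
            if b["n_private"]:
                assert b["propS"] == pytest.approx(b["n_shared"] / total_priv)


class TestSharedPrivateRichness:
    def test_no_carried_privates_gives_zero(self):
        calls = np.array([[1], [1], [0], [0], [0]], dtype=np.int8)
        G = make_matrix(calls)
        pm = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]}, focals=["s4"])
        out = shared_private_richness(G, pm, "s4", RarefactionSpec(g=2, tolerance=0.0))
        assert out["a"] == 0.0

    def test_single_locus_five_sixths(self):
        # group a copies {A x2, B x2}, group b {A x4}, focal AB carries B
        calls = np.array([[1], [1], [0], [0], [1]], dtype=np.int8)
        G = make_matrix(calls)
        pm = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]}, focals=["s4"])
        out = shared_private_richness(G, pm, "s4", RarefactionSpec(g=2, tolerance=0.0))
        assert out["a"] == pytest.approx(5 / 6)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(14)
        from test_diversity import dosages_for_counts

        for _ in range(10):
            n_a, n_b = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            alt_a = int(rng.integers(0, 2 * n_a + 1))
            alt_b = int(rng.integers(0, 2 * n_b + 1))
            fd = int(rng.integers(0, 3))
            g = int(rng.integers(1, min(2 * n_a, 2 * n_b, 8) + 1))
            col = dosages_for_counts(alt_a, n_a) + dosages_for_counts(alt_b, n_b) + [fd]
            G = make_matrix(np.array(col, dtype=np.int8)[:, None])
            pm = make_popmap(
                {
                    "a": [f"s{i}" for i in range(n_a)],
                    "b": [f"s{i}" for i in range(n_a, n_a + n_b)],
                },
                focals=[f"s{n_a + n_b}"],
            )
            out = shared_private_richness(
                G, pm, f"s{n_a + n_b}", RarefactionSpec(g=g, tolerance=0.0)
            )
            carried = set()
            if fd >= 1:
                carried.add("G")
            if fd <= 1:
                carried.add("A")
            oracle = enumeration_oracle(
                {
                    "a": ["G"] * alt_a + ["A"] * (2 * n_a - alt_a),
                    "b": ["G"] * alt_b + ["A"] * (2 * n_b - alt_b),
                },
                g,
                focal_carried=carried,
            )
            for grp in ("a", "b"):
                assert out[grp] == pytest.approx(float(oracle[grp][2]), rel=1e-12, abs=1e-12)

    def test_endpoint_equals_plain_share_rate(self):
        rng = np.random.default_rng(15)
        calls = rng.integers(0, 3, size=(5, 60)).astype(np.int8)
        G = make_matrix(calls)
        pm = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]}, focals=["s4"])
        out = shared_private_richness(G, pm, "s4", RarefactionSpec(g=4, tolerance=0.0))
        rep = shared_private_report(G, pm, "s4")
        for grp in ("a", "b"):
            assert out[grp] == pytest.approx(rep.per_group[grp]["S_PA"] / 60, abs=1e-12)


class TestFocalUnique:
    def test_reference_singleton_excludes_allele(self):
        calls = np.array([[1], [0], [0], [0], [2]], dtype=np.int8)
        G = make_matrix(calls)
        pm = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]}, focals=["s4"])
        out = focal_unique_alleles(G, pm)
        assert out["alleles"] == set()

    def test_homozygous_focal_only_allele(self):
        calls = np.array([[0], [0], [0], [0], [2]], dtype=np.int8)
        G = make_matrix(calls)
        pm = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]}, focals=["s4"])
        out = focal_unique_alleles(G, pm)
        assert out["alleles"] == {(0, 1)}
        assert out["per_focal"]["s4"][(0, 1)] == "hom"
        assert out["hom_fraction"]["s4"] == 1.0

    def test_intersection_across_focals(self):
        calls = np.array(
            [[0, 0], [0, 0], [0, 0], [0, 0], [1, 1], [0, 1]], dtype=np.int8
        )
        G = make_matrix(calls)
        pm = make_popmap({"a": ["s0", "s1"], "b": ["s2", "s3"]}, focals=["s4", "s5"])
        out = focal_unique_alleles(G, pm)
        assert out["alleles"] == {(0, 1), (1, 1)}
        assert out["intersection"] == {(1, 1)}

    def test_matches_brute_force_on_panel(self, small_panel):
        G, pm, _ = small_panel
        out = focal_unique_alleles(G, pm)
        ref_rows = [G.sample_index(s) for s in pm.assignments]
        for allele in (0, 1):
            for j in range(G.n_sites):
                count = 0
                for i in ref_rows:
                    d = G.calls[i, j]
                    if d != MISSING:
                        count += d if allele == 1 else 2 - d
                focal_has = any(
                    G.calls[G.sample_index(f), j] != MISSING
                    and (
                        G.calls[G.sample_index(f), j] >= 1
                        if allele == 1
                        else G.calls[G.sample_index(f), j] <= 1
                    )
                    for f in pm.focal_samples
                )
                expected_in = count == 0 and focal_has
                assert ((j, allele) in out["alleles"]) == expected_in


class TestIbs:
    def test_identical_vectors_give_one(self):
        calls = np.array([[0, 1, 2, 1], [0, 1, 2, 1]], dtype=np.int8)
        M, _ = ibs_matrix(make_matrix(calls))
        assert M[0, 1] == 1.0

    def test_opposite_homozygotes_give_zero(self):
        calls = np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8)
        M, _ = ibs_matrix(make_matrix(calls))
        assert M[0, 1] == 0.0

    def test_het_vs_hom_half_by_allele_matching(self):
        # {A,B} vs {B,B}: one of two alleles matches -> 0.5
        calls = np.array([[1], [2]], dtype=np.int8)
        M, _ = ibs_matrix(make_matrix(calls))
        shared = len({"A", "B"} & {"B"})  # one allele type in common, 1 copy
        assert M[0, 1] == pytest.approx(0.5) and shared == 1

    def test_symmetric_unit_diagonal_and_missing_excluded(self, small_panel):
        G, pm, _ = small_panel
        M, names = ibs_matrix(G, pm.focal_samples + ["coyote_1"])
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)
        assert ((M >= 0) & (M <= 1)).all()
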