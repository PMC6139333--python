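import math

import numpy as np
import pytest

import oracles
from conftest import random_alignment
from abcoal.data_model import LocusAlignment, MultilocusDataset
from abcoal.sumstats import (
    StatConfig,
    assemble_vector,
    expected_shared_parallel,
    fu_li,
    fus_fs,
    ka_ks,
    locus_stat_block,
    pair_locus_stats,
    phi_st,
    shared_fixed,
    species_locus_stats,
    stat_vector,
    summary_report,
    tajimas_d,
)

TOL = 1e-10


def _masked_species(al, species):
    cols = oracles.masked_columns(al.sequences)
    seqs = [
        s for s, sp in zip(al.sequences, al.species_labels) if sp == species
    ]
    return oracles.apply_mask(seqs, cols)


@pytest.fixture(scope="module")
def alignments():
    rng = np.random.default_rng(11)
    out = []
    for i in range(120):
        out.append(
            random_alignment(
                rng,
                (int(rng.integers(3, 8)), int(rng.integers(3, 8))),
                int(rng.integers(12, 40)),
                theta_like=float(rng.uniform(0.02, 0.3)),
                missing=float(rng.choice([0.0, 0.02])),
                locus_id=f"a{i}",
            )
        )
    return out


class TestOracleAgreement:
    """Each statistic equals an independent brute-force/exact oracle on many
    random small alignments (the core correctness battery)."""

    def test_species_diversity_statistics(self, alignments):
        for al in alignments:
            st = species_locus_stats(al, "sp0")
            seqs = _masked_species(al, "sp0")
            assert st.S == oracles.seg_sites(seqs)
            assert st.eta == oracles.eta_total(seqs)
            assert st.h == oracles.hap_count(seqs)
            assert st.hd == pytest.approx(oracles.hap_diversity(seqs), abs=TOL)
            assert st.k == pytest.approx(oracles.mean_pair_diff(seqs), abs=TOL)
            assert st.pi == pytest.approx(
                oracles.mean_pair_diff(seqs) / len(seqs[0]), abs=TOL
            )
            assert st.theta_w == pytest.approx(oracles.watterson_theta(seqs), abs=TOL)

    def test_tajimas_d(self, alignments):
        for al in alignments:
            seqs = _masked_species(al, "sp0")
            expect = oracles.tajimas_d(seqs)
            got = tajimas_d(al, "sp0")
            if math.isnan(expect):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=TOL)

    def test_fu_li_starred(self, alignments):
        for al in alignments:
            seqs = _masked_species(al, "sp0")
            ed, ef = oracles.fu_li_star(seqs)
            d, f = fu_li(al, "sp0", mode="starred")
            for got, expect in ((d, ed), (f, ef)):
                if math.isnan(expect):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(expect, abs=TOL)

    def test_fu_li_outgroup(self, alignments):
        rng = np.random.default_rng(7)
        for al in alignments[:40]:
            og = "".join("ACGT"[b] for b in rng.integers(0, 4, al.length))
            cols = oracles.masked_columns(al.sequences)
            seqs = _masked_species(al, "sp0")
            ed, ef = oracles.fu_li_outgroup(seqs, "".join(og[i] for i in cols))
            d, f = fu_li(al, "sp0", mode="outgroup", outgroup=og)
            for got, expect in ((d, ed), (f, ef)):
                if math.isnan(expect):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(expect, abs=TOL)

    def test_fus_fs_exact_arithmetic(self, alignments):
        for al in alignments:
            seqs = _masked_species(al, "sp0")
            expect = oracles.fus_fs_exact(seqs)
            got = fus_fs(al, "sp0")
            if math.isnan(expect):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-8)

    def test_phi_st_against_ssd_oracle(self, alignments):
        for al in alignments:
            cols = oracles.masked_columns(al.sequences)
            ga = oracles.apply_mask(
                [s for s, sp in zip(al.sequences, al.species_labels) if sp == "sp0"],
                cols,
            )
            gb = oracles.apply_mask(
                [s for s, sp in zip(al.sequences, al.species_labels) if sp == "sp1"],
                cols,
            )
            expect = oracles.amova_phi_st([ga, gb])
            got, _ = phi_st(al, "sp0", "sp1")
            if math.isnan(expect):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=TOL)

    def test_shared_fixed_against_site_scan(self, alignments):
        for al in alignments:
            cols = oracles.masked_columns(al.sequences)
            ga = oracles.apply_mask(
                [s for s, sp in zip(al.sequences, al.species_labels) if sp == "sp0"],
                cols,
            )
            gb = oracles.apply_mask(
                [s for s, sp in zip(al.sequences, al.species_labels) if sp == "sp1"],
                cols,
            )
            assert shared_fixed(al, "sp0", "sp1") == oracles.shared_fixed_counts(ga, gb)

    def test_ka_ks_against_independent_ng(self):
        rng = np.random.default_rng(5)
        checked = 0
        base_codons = [c for c, aa in oracles._CODE.items() if aa != "*"]
        while checked < 100:
            n_cod = int(rng.integers(3, 8))
            anc = "".join(rng.choice(base_codons) for _ in range(n_cod))
            seqs = []
            for _ in range(4):
                s = list(anc)
                for _ in range(rng.poisson(2)):
                    p = int(rng.integers(len(s)))
                    s[p] = "ACGT"[int(rng.integers(4))]
                seqs.append("".join(s))
            al = LocusAlignment("kk", seqs, ["sp0", "sp0", "sp1", "sp1"])
            try:
                res = ka_ks(al, "sp0", "sp1", frame=0)
            except ValueError:
                continue  # consensus stop or no codons: oracle n/a by design
            pairs = [(seqs[i], seqs[j]) for i in (0, 1) for j in (2, 3)]
            eka, eks = oracles.ng_ka_ks(pairs)
            assert res.ka == pytest.approx(eka, abs=TOL)
            assert res.ks == pytest.approx(eks, abs=TOL)
            checked += 1


class TestHandWorkedExamples:
    def test_two_sequences_two_differences(self):
        s1 = "A" * 100
        s2 = "A" * 98 + "GT"
        al = LocusAlignment("t", [s1, s2], ["x", "x"])
        st = species_locus_stats(al, "x")
        assert (st.k, st.pi, st.S) == (2.0, 0.02, 2)
        assert st.theta_w_site == pytest.approx(0.02)  # a_1 = 1

    def test_watterson_n4(self):
        # n = 4, S = 11 -> theta_W per locus = 11 / (11/6) = 6
        rng = np.random.default_rng(3)
        for _ in range(500):
            al = random_alignment(rng, (4,), 40, theta_like=0.12)
            if species_locus_stats(al, "sp0").S == 11:
                break
        else:
            pytest.fail("no random alignment with S = 11 found")
        assert species_locus_stats(al, "sp0").theta_w == pytest.approx(6.0)

    def test_haplotype_diversity_formula(self):
        # counts (2,1,1), n=4 -> (4/3) * (1 - 6/16) = 0.8333...
        al = LocusAlignment("h", ["AAA", "AAA", "AAT", "ATA"], ["x"] * 4)
        assert species_locus_stats(al, "x").hd == pytest.approx(
            (4 / 3) * (1 - 6 / 16)
        )

    def test_monomorphic_statistics_undefined(self):
        al = LocusAlignment("m", ["ACGT"] * 5, ["x"] * 5)
        st = species_locus_stats(al, "x")
        assert math.isnan(st.d_taj) and math.isnan(st.fs)
        assert math.isnan(st.d_fl) and math.isnan(st.f_fl)
        assert st.S == 0 and st.h == 1

    def test_all_singletons_give_negative_d_star(self):
        seqs = []
        base = "A" * 12
        for i in range(6):
            s = list(base)
            s[i] = "G"
            seqs.append("".join(s))
        al = LocusAlignment("s", seqs, ["x"] * 6)
        d, _ = fu_li(al, "x", mode="starred")
        assert d < 0

    def test_fs_saturation_rule(self):
        # h_obs = 1 makes S' = P(K >= 1) = 1 exactly; the clip turns the
        # logit into a large finite positive value and flags it
        from abcoal.sumstats import _fs_from

        fs, clipped = _fs_from(k=1.0, h=1, n=5)
        assert clipped and np.isfinite(fs) and fs > 20
        # and an ordinary star-like sample stays finite and unclipped
        seqs = []
        for i in range(5):
            s = list("A" * 10)
            s[i] = "T"
            seqs.append("".join(s))
        al = LocusAlignment("f", seqs, ["x"] * 5)
        assert np.isfinite(fus_fs(al, "x"))

    def test_expected_shared_parallel(self):
        assert expected_shared_parallel(10, 10, 100) == pytest.approx(1.0)
        assert expected_shared_parallel(0, 7, 100) == 0.0
        assert expected_shared_parallel(52, 40, 715) == pytest.approx(2.909, abs=5e-4)
        with pytest.raises(ValueError):
            expected_shared_parallel(1, 1, 0)

    def test_expected_shared_parallel_monte_carlo(self):
        # uniform independent placement of s1 and s2 site sets
        rng = np.random.default_rng(9)
        s1, s2, L = 12, 9, 60
        hits = [
            len(
                set(rng.choice(L, s1, replace=False))
                & set(rng.choice(L, s2, replace=False))
            )
            for _ in range(4000)
        ]
        mc = np.mean(hits)
        se = np.std(hits) / math.sqrt(len(hits))
        assert abs(expected_shared_parallel(s1, s2, L) - mc) < 4 * se

    def test_ka_ks_hand_worked_three_codons(self):
        # A: ATG GGA TTT vs B: ATG GGG TTA (two identical copies per species)
        # syn sites: ATG 0; GGA 1; GGG 1; TTT 1/3; TTA 2/3
        # pooled over 4 identical pairs: S = 4*(0 + 1 + 1/2) = 6, N = 36 - 6 = 30
        # one syn diff and one nonsyn diff per pair -> ps = 2/3, pn = 2/15
        # Ks = -3/4 ln(1/9), Ka = -3/4 ln(37/45)
        al = LocusAlignment(
            "codons",
            ["ATGGGATTT", "ATGGGATTT", "ATGGGGTTA", "ATGGGGTTA"],
            ["A", "A", "B", "B"],
        )
        res = ka_ks(al, "A", "B", frame=0)
        assert res.ks == pytest.approx(0.75 * math.log(9), abs=TOL)
        assert res.ka == pytest.approx(0.75 * math.log(45 / 37), abs=TOL)
        assert res.ratio == pytest.approx(
            (0.75 * math.log(45 / 37)) / (0.75 * math.log(9)), abs=TOL
        )

    def test_ka_ks_structural_cases(self):
        al = LocusAlignment("same", ["ATGGGA"] * 4, ["A", "A", "B", "B"])
        res = ka_ks(al, "A", "B")
        assert res.ka == 0 and res.ks == 0 and math.isnan(res.ratio)
        al = LocusAlignment(
            "syn", ["GGAGGA", "GGAGGA", "GGAGGG", "GGAGGG"], ["A", "A", "B", "B"]
        )
        res = ka_ks(al, "A", "B")
        assert res.ks > 0 and res.ka == 0
        with pytest.raises(ValueError):
            ka_ks(al, "A", "B", frame=5)


class TestPhiSt:
    def test_complete_differentiation(self):
        al = LocusAlignment(
            "f", ["AAAA"] * 4 + ["TTTT"] * 4, ["A"] * 4 + ["B"] * 4
        )
        phi, _ = phi_st(al, "A", "B")
        assert phi == pytest.approx(1.0)

    def test_fully_mixed_identical_spectra(self, rng):
        phi, p = phi_st(
            LocusAlignment(
                "m",
                ["AAAA", "AATT", "AAAA", "AATT", "AAAA", "AATT", "AAAA", "AATT"],
                ["A", "A", "A", "A", "B", "B", "B", "B"],
            ),
            "A",
            "B",
            n_perm=199,
            rng=rng,
        )
        assert phi < 0.05 and p > 0.5

    def test_permutation_p_uniform_under_exchangeability(self):
        rng = np.random.default_rng(31)
        pvals = []
        for _ in range(300):
            # groups big enough that permutation Phi values are almost never
            # tied (ties would make p conservative, not uniform)
            al = random_alignment(rng, (10, 10), 60, theta_like=0.15, locus_id="u")
            _, p = phi_st(al, "sp0", "sp1", n_perm=99, rng=rng)
            pvals.append(p)
        from scipy import stats

        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_group_error(self, rng):
        al = random_alignment(rng, (4,), 20)
        with pytest.raises(ValueError):
            phi_st(al)


class TestPartitionProperty:
    def test_every_site_classified_exactly_once(self, rng):
        for _ in range(30):
            al = random_alignment(rng, (4, 5), 25, theta_like=0.2)
            s1, s2, sp, fp = shared_fixed(al, "sp0", "sp1")
            cols = oracles.masked_columns(al.sequences)
            ga = oracles.apply_mask(
                [s for s, l in zip(al.sequences, al.species_labels) if l == "sp0"], cols
            )
            gb = oracles.apply_mask(
                [s for s, l in zip(al.sequences, al.species_labels) if l == "sp1"], cols
            )
            mono_same = sum(
                1
                for ca, cb in zip(zip(*ga), zip(*gb))
                if len(set(ca)) == 1 and len(set(cb)) == 1 and ca[0] == cb[0]
            )
            assert s1 + s2 + sp + fp + mono_same == len(cols)


class TestStatVector:
    def test_layout_size_and_determinism(self, small_dataset):
        v1 = stat_vector(small_dataset)
        v2 = stat_vector(small_dataset)
        assert len(v1.names) == 36
        assert v1.names == v2.names
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_identical_species_samples_zero_deviations(self):
        seqs = ["ACGTACGTAA", "ACGAACGTAT", "ACGTACGTAT"]
        loci = [
            LocusAlignment(
                f"l{i}", seqs * 3, sum([["sp0"] * 3, ["sp1"] * 3, ["sp2"] * 3], [])
            )
            for i in range(2)
        ]
        ds = MultilocusDataset(loci=loci, species=["sp0", "sp1", "sp2"])
        v = stat_vector(ds)
        s = v.as_series()
        for name in v.names:
            if name.startswith(("dS_", "dh_", "dk_", "dtajd_", "dfs_")):
                assert s[name] == 0
            if name.startswith("phist_"):
                # identical groups have SSD_among = 0 exactly, so the
                # variance-component estimator gives -1/(n-1) (its known
                # small-sample bias), here with n = 3 copies per species
                assert s[name] == pytest.approx(-0.5)
            if name.startswith("dxy_"):
                # cross-pair mean over identical groups includes the n
                # self-identical pairs: dxy = k * (n-1)/n
                assert s[name] == pytest.approx(s["k_sp0"] * 2 / 3)

    def test_entries_equal_external_across_locus_means(self, small_dataset):
        v = stat_vector(small_dataset)
        s = v.as_series()
        per_locus_S = [
            species_locus_stats(al, "sp1").S for al in small_dataset.loci
        ]
        assert s["S_sp1"] == pytest.approx(np.mean(per_locus_S))
        per_locus_phi = [
            phi_st(al, "sp0", "sp2")[0] for al in small_dataset.loci
        ]
        assert s["phist_sp0_sp2"] == pytest.approx(
            np.nanmean(np.nan_to_num(per_locus_phi))
        )

    def test_pruned_layout_preserves_order(self, small_dataset):
        full = StatConfig().layout(small_dataset.species)
        cfg = StatConfig(names=tuple(full[i] for i in (5, 1, 30)))
        v = stat_vector(small_dataset, cfg)
        assert v.names == [full[1], full[5], full[30]]

    def test_imputation_counted_not_silent(self):
        mono = LocusAlignment("m", ["ACGT"] * 6, ["sp0", "sp0", "sp1", "sp1", "sp2", "sp2"])
        ds = MultilocusDataset(loci=[mono], species=["sp0", "sp1", "sp2"])
        v = stat_vector(ds)
        assert v.n_imputed > 0
        assert not np.isnan(v.values).any()


class TestSummaryReport:
    def test_shapes_and_undefined_markers(self, small_dataset):
        rep = summary_report(small_dataset, n_perm=49, frame=None, seed=1)
        assert len(rep["diversity"]) == small_dataset.n_loci * 3
        assert len(rep["pairwise"]) == small_dataset.n_loci * 3
        mono = LocusAlignment(
            "m", ["ACGT"] * 6, ["sp0", "sp0", "sp1", "sp1", "sp2", "sp2"]
        )
        ds = MultilocusDataset(loci=[mono], species=["sp0", "sp1", "sp2"])
        rep = summary_report(ds, n_perm=0, frame=None)
        assert rep["diversity"]["d_taj"].isna().all()

    def test_means_match_external_recomputation(self, small_dataset):
        rep = summary_report(small_dataset, n_perm=0, frame=None)
        t1 = rep["diversity"]
        manual = t1[t1.species == "sp0"]["pi"].mean()
        assert rep["diversity_means"].loc["sp0", ("pi", "mean")] == pytest.approx(manual)
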