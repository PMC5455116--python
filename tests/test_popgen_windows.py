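"""Window statistics, density tracks and selection-region merging."""

import numpy as np
import pandas as pd
import pytest

from domesticscan.popgen_windows import (
    SelectionRegion,
    WindowStat,
    density_track,
    fst_hudson,
    harmonic,
    pi_from_counts,
    selection_regions,
    snp_windows,
    tajimas_d,
    tally_sites,
    watterson_theta,
)
from domesticscan.variant_io import Call, GeneModel, Genotype, VariantRecord

from _oracles import fst_hudson_per_site, pi_pair_enumeration, theta_direct


def sites_frame(ks, ns, chrom="c", start=100, spacing=10):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": [start + i * spacing for i in range(len(ks))],
            "ref": "A",
            "alt": "G",
            "k": ks,
            "n": ns,
        }
    )


class TestEstimators:
    def test_watterson_limits(self):
        assert watterson_theta(0, 10) == 0.0
        assert watterson_theta(7, 2) == pytest.approx(7.0)  # a1(2) = 1
        assert watterson_theta(10, 10) == pytest.approx(10 / sum(1 / i for i in range(1, 10)))
        assert watterson_theta(5, 1) is None

    def test_pi_single_heterozygous_pair(self):
        assert pi_from_counts([1], [2]) == pytest.approx(1.0)

    def test_pi_monomorphic_window_is_zero(self):
        assert pi_from_counts([0, 0, 0], [8, 8, 8]) == 0.0

    def test_tajima_zero_when_pi_equals_theta(self):
        n, S = 12, 9
        assert tajimas_d(S / harmonic(n), S, n) == pytest.approx(0.0, abs=1e-12)

    def test_tajima_undefined_cases(self):
        assert tajimas_d(1.0, 0, 20) is None
        assert tajimas_d(1.0, 5, 3) is None

    def test_tajima_sign_matches_frequency_spectrum(self):
        n, S = 80, 50
        d_rare = tajimas_d(pi_from_counts([1] * S, [n] * S), S, n)
        d_common = tajimas_d(pi_from_counts([n // 2] * S, [n] * S), S, n)
        assert d_rare < 0 < d_common

    def test_tajima_sign_equals_sign_of_pi_minus_theta(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 60))
            S = int(rng.integers(1, 80))
            ks = rng.integers(1, n, S)
            pi = pi_from_counts(ks, [n] * S)
            d = tajimas_d(pi, S, n)
            diff = pi - S / harmonic(n)
            if abs(diff) > 1e-12:
                assert np.sign(d) == np.sign(diff)

    def test_fst_limits(self):
        assert fst_hudson([5, 3], [10, 10], [5, 3], [10, 10]) == pytest.approx(0.0)
        assert fst_hudson([10, 10], [10, 10], [0, 0], [10, 10]) == pytest.approx(1.0)
        assert fst_hudson([1], [1], [1], [10]) is None  # group below n=2

    def test_fst_matches_per_site_enumeration(self, rng):
        for _ in range(50):
            S = int(rng.integers(1, 40))
            n1 = int(rng.integers(2, 30))
            n2 = int(rng.integers(2, 30))
            k1 = rng.integers(0, n1 + 1, S)
            k2 = rng.integers(0, n2 + 1, S)
            ours = fst_hudson(k1, [n1] * S, k2, [n2] * S)
            oracle = fst_hudson_per_site(k1, [n1] * S, k2, [n2] * S)
            if oracle is None:
                assert ours is None
            else:
                assert ours == pytest.approx(oracle, abs=1e-12)

    def test_pi_matches_pair_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 20))
            S = int(rng.integers(1, 30))
            ks = [int(x) for x in rng.integers(0, n + 1, S)]
            assert pi_from_counts(ks, [n] * S) == pytest.approx(
                pi_pair_enumeration(ks, n), abs=1e-9
            )

    def test_n2_window_has_pi_theta_S_all_equal(self, rng):
        for _ in range(20):
            S = int(rng.integers(1, 30))
            ks = [1] * S
            pi = pi_from_counts(ks, [2] * S)
            assert pi == pytest.approx(S) == pytest.approx(watterson_theta(S, 2))


class TestTally:
    def _records(self, genotypes, pos=100):
        """One record per accession carrying its own call."""
        out = {}
        for i, gt in enumerate(genotypes):
            acc = f"a{i}"
            out[acc] = [
                VariantRecord("c", pos, "A", "G", {acc: Call(gt, 9, 50.0)})
            ]
        return out

    def test_counts_match_genotypes(self):
        recs = self._records([Genotype.HOM_ALT, Genotype.HET, Genotype.HOM_REF])
        df = tally_sites(recs, ["a0", "a1", "a2"])
        assert len(df) == 1
        assert (df.k.iloc[0], df.n.iloc[0]) == (3, 6)

    def test_absent_record_counts_as_hom_ref(self):
        recs = self._records([Genotype.HOM_ALT])
        recs["a1"] = []
        df = tally_sites(recs, ["a0", "a1"])
        assert (df.k.iloc[0], df.n.iloc[0]) == (2, 4)

    def test_all_missing_site_dropped(self):
        recs = self._records([Genotype.MISSING, Genotype.MISSING])
        assert len(tally_sites(recs, ["a0", "a1"])) == 0

    def test_random_matrix_matches_bruteforce(self, rng):
        n_acc, n_sites = 8, 30
        gts = rng.integers(0, 4, (n_sites, n_acc))  # 0 ref,1 het,2 hom,3 missing
        mapping = [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING]
        recs = {f"a{a}": [] for a in range(n_acc)}
        for s in range(n_sites):
            for a in range(n_acc):
                g = mapping[gts[s, a]]
                if g is Genotype.HOM_REF:
                    continue  # variant-only VCF: hom-ref rows absent
                acc = f"a{a}"
                recs[acc].append(
                    VariantRecord("c", 100 + s, "A", "G", {acc: Call(g, 9, 50.0)})
                )
        df = tally_sites(recs, [f"a{a}" for a in range(n_acc)])
        got = {(r.pos): (r.k, r.n) for r in df.itertuples(index=False)}
        for s in range(n_sites):
            k = int(np.sum(gts[s] == 1) + 2 * np.sum(gts[s] == 2))
            n = 2 * int(np.sum(gts[s] != 3))
            if k == 0 or n < 4:
                assert 100 + s not in got
            else:
                assert got[100 + s] == (k, n)


class TestWindows:
    def test_exactly_one_full_window(self):
        df = sites_frame([1] * 500, [8] * 500)
        ws = snp_windows(df, 500, 100)
        assert len(ws) == 1 and not ws[0].partial and ws[0].n_sites == 500

    def test_window_starts_by_index_arithmetic(self):
        # 700 sites: full windows start at indices 0, 100, 200; emission stops
        # once a window reaches the final site (all sites covered)
        df = sites_frame([1] * 700, [8] * 700)
        ws = snp_windows(df, 500, 100)
        assert [w.start_site for w in ws] == [0, 100, 200]
        assert not any(w.partial for w in ws)
        # 650 sites: the terminal window is partial
        ws = snp_windows(sites_frame([1] * 650, [8] * 650), 500, 100)
        assert [w.start_site for w in ws] == [0, 100, 200]
        assert [w.partial for w in ws] == [False, False, True]
        assert ws[-1].n_sites == 450

    def test_empty_chromosome_yields_no_windows(self):
        df = sites_frame([], [])
        assert snp_windows(df, 500, 100) == []

    def test_every_site_covered_by_some_window(self, rng):
        total = int(rng.integers(1, 1300))
        df = sites_frame([1] * total, [8] * total)
        ws = snp_windows(df, 500, 100)
        covered = set()
        for w in ws:
            covered.update(range(w.start_site, w.start_site + w.n_sites))
        assert covered == set(range(total))

    def test_invalid_window_step_rejected(self):
        with pytest.raises(ValueError):
            snp_windows(sites_frame([1], [8]), 100, 200)


class TestDensityTrack:
    def test_counts_and_boundary_rule(self):
        pos = pd.DataFrame({"chrom": ["c"] * 11, "pos": list(range(1, 11)) + [1_000_000]})
        track = density_track(pos, {"c": 2_500_000})
        assert list(track.value) == [11, 0, 0]  # pos 1e6 belongs to bin 1
        assert track.start.tolist() == [1, 1_000_001, 2_000_001]
        assert track.end.tolist() == [1_000_000, 2_000_000, 2_500_000]

    def test_bin_totals_sum_to_input(self, rng):
        pos = pd.DataFrame(
            {"chrom": "c", "pos": rng.integers(1, 5_000_000, 1000)}
        )
        track = density_track(pos, {"c": 5_000_000})
        assert track.value.sum() == 1000
        # histogram oracle
        expected = np.histogram(pos.pos - 1, bins=5, range=(0, 5_000_000))[0]
        assert list(track.value) == list(expected)


def _window(chrom, first, last, d, partial=False):
    return WindowStat(chrom, 0, 0, first, last, 500, 500, 80, 0.0, None, d, None, partial)


class TestSelectionRegions:
    def test_no_window_passes(self):
        assert selection_regions([_window("c", 1, 10, 0.0)]) == []

    def test_overlapping_windows_merge(self):
        ws = [_window("c", 1000, 5000, -3.5), _window("c", 4000, 9000, -3.2)]
        regions = selection_regions(ws)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.length, r.direction) == (1000, 9000, 8001, "purifying")

    def test_threshold_strictness(self):
        # purifying requires strictly below the low cutoff; balancing is inclusive
        assert selection_regions([_window("c", 1, 10, -3.0)]) == []
        assert selection_regions([_window("c", 1, 10, -3.0001)])[0].direction == "purifying"
        assert selection_regions([_window("c", 1, 10, 2.0)])[0].direction == "balancing"
        assert selection_regions([_window("c", 1, 10, 1.999)]) == []

    def test_partial_windows_excluded_by_default(self):
        ws = [_window("c", 1, 10, -4.0, partial=True)]
        assert selection_regions(ws) == []
        assert len(selection_regions(ws, include_partial=True)) == 1

    def test_resident_genes_reported(self):
        genes = [
            GeneModel("inside", "c", "+", 2000, 3000),
            GeneModel("outside", "c", "+", 50_000, 51_000),
            GeneModel("other_chrom", "d", "+", 2000, 3000),
        ]
        regions = selection_regions([_window("c", 1000, 9000, -3.5)], genes=genes)
        assert regions[0].genes == ("inside",)
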