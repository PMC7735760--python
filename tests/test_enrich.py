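"""Feature assignment, motif windows, Fisher/Storey statistics, controls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from samosa import enrich
from samosa.cluster import ClusterAssignment
from samosa.io import FeatureSet, ModificationTrack, Molecule


def _mol(mol_id, chrom, start, end, strand="+"):
    L = end - start
    return Molecule(mol_id, chrom, start, end, strand, "A" * L, np.ones(L))


class TestAssignMolecules:
    def test_gap_within_expansion_is_hit(self):
        mols = [_mol("m1", "chr1", 1000, 2000)]
        feats = FeatureSet.from_intervals([("chr1", 2500, 2600, "f")])
        hits = enrich.assign_molecules(mols, feats, max_dist=1000)
        assert list(hits["molecule_id"]) == ["m1"]
        assert hits["rel_start"].iloc[0] == 1000 - 2500

    def test_boundary_gap_exactly_max_dist_is_hit(self):
        mols = [_mol("m1", "chr1", 1000, 2000)]
        feats = FeatureSet.from_intervals([("chr1", 3000, 3100, "f")])
        assert len(enrich.assign_molecules(mols, feats, max_dist=1000)) == 1
        feats2 = FeatureSet.from_intervals([("chr1", 3001, 3100, "f")])
        assert len(enrich.assign_molecules(mols, feats2, max_dist=1000)) == 0

    def test_matches_all_pairs_oracle(self):
        """Chromosome-indexed overlap vs a direct all-pairs double loop."""
        rng = np.random.default_rng(0)
        chroms = ["c1", "c2", "c3"]
        mols = [
            _mol(f"m{i}", chroms[int(rng.integers(3))],
                 s := int(rng.integers(0, 50_000)), s + int(rng.integers(1, 3000)))
            for i in range(300)
        ]
        feats = FeatureSet.from_intervals(
            [
                (chroms[int(rng.integers(3))],
                 s := int(rng.integers(0, 50_000)), s + int(rng.integers(1, 500)),
                 f"f{i}")
                for i in range(100)
            ]
        )
        got = enrich.assign_molecules(mols, feats, max_dist=750)
        got_pairs = set(zip(got["molecule_id"], got["feature_index"]))
        want = set()
        for fi, f in enumerate(feats):
            for m in mols:
                if (m.ref_name == f.chrom and m.ref_end >= f.start - 750
                        and m.ref_start <= f.end + 750):
                    want.add((m.molecule_id, fi))
        assert got_pairs == want


class TestMotifWindows:
    @staticmethod
    def setup_asym():
        track = np.linspace(0, 1, 2000)  # asymmetric posterior gradient
        mol = _mol("m1", "chr1", 0, 2000)
        tracks = {"m1": ModificationTrack("m1", track)}
        return mol, tracks

    def test_minus_strand_motif_mirrors_plus(self):
        mol, tracks = self.setup_asym()
        plus = FeatureSet.from_intervals([("chr1", 990, 1010, "tf", 0, "+")])
        minus = FeatureSet.from_intervals([("chr1", 990, 1010, "tf", 0, "-")])
        wp = enrich.motif_windows([mol], tracks, plus)
        wm = enrich.motif_windows([mol], tracks, minus)
        assert wp.matrix.shape == (1, 500)
        np.testing.assert_allclose(wp.matrix[0], wm.matrix[0][::-1])

    def test_minus_strand_molecule_converted_to_reference(self):
        track = np.linspace(0, 1, 2000)
        mol = _mol("m1", "chr1", 0, 2000, strand="-")
        tracks = {"m1": ModificationTrack("m1", track)}
        motifs = FeatureSet.from_intervals([("chr1", 990, 1010, "tf", 0, "+")])
        w = enrich.motif_windows([mol], tracks, motifs)
        # read-orientation gradient is decreasing along the reference
        assert w.matrix[0, 0] > w.matrix[0, -1]

    def test_insufficient_flank_excluded(self):
        mol, tracks = self.setup_asym()
        motifs = FeatureSet.from_intervals([("chr1", 90, 110, "edge")])
        w = enrich.motif_windows([mol], tracks, motifs)
        assert w.matrix.shape[0] == 0 and w.n_excluded == 1

    def test_planted_accessible_centre_peaks_in_column_means(self):
        rng = np.random.default_rng(1)
        mols, tracks = [], {}
        for i in range(60):
            track = np.clip(rng.normal(0.2, 0.05, 1000), 0, 1)
            track[450:550] = np.clip(rng.normal(0.9, 0.05, 100), 0, 1)
            mid = f"m{i}"
            mols.append(_mol(mid, "chr1", 0, 1000))
            tracks[mid] = ModificationTrack(mid, track)
        motifs = FeatureSet.from_intervals([("chr1", 495, 505, "tf")])
        w = enrich.motif_windows(mols, tracks, motifs)
        means = w.matrix.mean(axis=0)
        assert 200 <= np.argmax(means) <= 300
        assert means[250] > means[50] + 0.4


class TestCutProfile:
    def test_fragment_ends_at_expected_offsets(self):
        mol = _mol("m1", "chr1", 0, 500)
        motifs = FeatureSet.from_intervals([("chr1", 245, 255, "tf")])
        offsets, profile, n = enrich.cut_profile([mol], motifs, halfwidth=1000)
        assert n == 1
        nz = offsets[profile > 0]
        np.testing.assert_array_equal(nz, [-250, 250])

    def test_no_hits_zero_profile(self):
        mol = _mol("m1", "chr1", 0, 500)
        motifs = FeatureSet.from_intervals([("chr2", 245, 255, "tf")])
        _, profile, n = enrich.cut_profile([mol], motifs)
        assert n == 0 and not profile.any()


class TestStateCluster:
    def test_planted_states_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(2)
        rows, cats = [], []
        for i in range(150):
            occluded = i % 2 == 0
            base = np.clip(rng.normal(0.25, 0.1, 500), 0, 1)
            if not occluded:
                base[175:325] = np.clip(rng.normal(0.85, 0.1, 150), 0, 1)
            rows.append(base)
            cats.append("occluded" if occluded else "accessible")
        win = enrich.MotifWindowMatrix(
            [f"m{i}" for i in range(150)], np.vstack(rows), cats
        )
        assignment, profiles = enrich.state_cluster(win, resolution=0.1, seed=3)
        assert adjusted_rand_score(cats, assignment.labels) >= 0.8
        assert profiles.shape[1] == 500

    def test_identical_rows_single_cluster(self):
        win = enrich.MotifWindowMatrix(
            [f"m{i}" for i in range(60)],
            np.tile(np.linspace(0, 1, 500), (60, 1)),
            ["x"] * 60,
        )
        assignment, _ = enrich.state_cluster(win, resolution=0.5, seed=0)
        assert assignment.n_clusters == 1


def two_sided_fisher_oracle(a, b, c, d):
    """Enumerate all tables with the observed margins; sum pmf <= observed."""
    r1, n, K = a + b, a + b + c + d, a + c
    support = np.arange(max(0, r1 + K - n), min(r1, K) + 1)
    pmf = hypergeom.pmf(support, n, K, r1)
    obs = hypergeom.pmf(a, n, K, r1)
    return float(pmf[pmf <= obs * (1 + 1e-9)].sum())


class TestFisher:
    def test_balanced_table(self):
        oddsratio, p = enrich.fisher_test(enrich.ContingencyTable(10, 10, 10, 10))
        assert oddsratio == 1.0 and p == 1.0

    def test_cross_table_or16(self):
        oddsratio, p = enrich.fisher_test(enrich.ContingencyTable(8, 2, 2, 8))
        assert oddsratio == 16.0
        assert p == pytest.approx(two_sided_fisher_oracle(8, 2, 2, 8))

    def test_infinite_odds_ratio(self):
        oddsratio, p = enrich.fisher_test(enrich.ContingencyTable(5, 0, 0, 5))
        assert np.isinf(oddsratio)
        assert p == pytest.approx(2.0 / 252.0)

    def test_empty_margin(self):
        oddsratio, p = enrich.fisher_test(enrich.ContingencyTable(0, 0, 3, 7))
        assert np.isnan(oddsratio) and p == 1.0

    def test_exhaustive_grid_matches_enumeration(self):
        """Every table with N <= 40 agrees with the hypergeometric oracle."""
        for n in range(1, 41):
            for r1 in range(n + 1):
                for k in range(n + 1):
                    a_lo = max(0, r1 + k - n)
                    a_hi = min(r1, k)
                    for a in range(a_lo, a_hi + 1):
                        b, c = r1 - a, k - a
                        d = n - a - b - c
                        _, p = enrich.fisher_test(
                            enrich.ContingencyTable(a, b, c, d)
                        )
                        if min(r1, n - r1, k, n - k) == 0:
                            assert p == 1.0
                            continue
                        want = two_sided_fisher_oracle(a, b, c, d)
                        assert p == pytest.approx(want, rel=1e-7), (a, b, c, d)


class TestStorey:
    def test_all_ones(self):
        np.testing.assert_array_equal(
            enrich.storey_qvalues(np.ones(30)), np.ones(30)
        )

    def test_pi0_one_equals_benjamini_hochberg(self):
        rng = np.random.default_rng(0)
        p = np.concatenate([rng.uniform(0, 1e-3, 20), rng.uniform(0, 1, 200)])
        q = enrich.storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_uniform_pi0_near_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=10_000)
        assert 0.9 <= enrich.estimate_pi0(p) <= 1.0

    def test_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = rng.beta(0.5, 3.0, size=int(rng.integers(25, 400)))
            q = enrich.storey_qvalues(p)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)
            assert np.all((q >= 0) & (q <= 1))

    def test_small_sets_reduce_to_bh(self):
        p = np.array([0.01, 0.2, 0.8])
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(enrich.storey_qvalues(p), bh)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            enrich.storey_qvalues(np.array([0.5, 1.5]))


class TestMatchedControls:
    @staticmethod
    def genome(rng, n_chrom=1, length=200_000):
        # GC content drifting along the chromosome so candidates span bins
        out = {}
        for c in range(n_chrom):
            probs = np.linspace(0.2, 0.8, length)
            gc = rng.random(length) < probs
            pick = np.where(
                gc, rng.choice(list("GC"), length), rng.choice(list("AT"), length)
            )
            out[f"chr{c}"] = "".join(pick)
        return out

    def test_narrow_target_gc_sampled_from_matching_bin(self):
        rng = np.random.default_rng(0)
        genome = {"chr0": "".join(rng.choice(list("ACGT"), 100_000))}
        cands = FeatureSet.from_intervals(
            [("chr0", s, s + 200) for s in range(0, 99_000, 97)]
        )
        gcs = np.array(
            [enrich.interval_gc(genome["chr0"][f.start:f.end]) for f in cands]
        )
        # targets: candidates whose GC already sits in the 0.50 bin
        bin50 = (gcs >= 0.50) & (gcs < 0.525)
        targets = FeatureSet(cands.df[bin50].head(30))
        ctrl = enrich.matched_controls(cands, targets, genome, seed=1)
        cgc = np.array(
            [enrich.interval_gc(genome["chr0"][f.start:f.end]) for f in ctrl]
        )
        assert len(ctrl) == len(targets)
        assert np.all((cgc >= 0.50) & (cgc < 0.525))

    def test_gc_histogram_total_variation(self):
        rng = np.random.default_rng(1)
        genome = self.genome(rng)
        cands = FeatureSet.from_intervals(
            [("chr0", s, s + 150) for s in range(0, 199_000, 60)]
        )
        target_idx = rng.choice(len(cands), 1000, replace=False)
        targets = FeatureSet(cands.df.iloc[np.sort(target_idx)])
        ctrl = enrich.matched_controls(cands, targets, genome, seed=2)

        def hist(fs):
            gc = np.array(
                [enrich.interval_gc(genome[f.chrom][f.start:f.end]) for f in fs]
            )
            bins = np.minimum((gc / 0.025).astype(int), 39)
            return np.bincount(bins, minlength=40) / len(gc)

        tvd = 0.5 * np.abs(hist(targets) - hist(ctrl)).sum()
        assert tvd <= 0.05

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        genome = self.genome(rng)
        cands = FeatureSet.from_intervals(
            [("chr0", s, s + 150) for s in range(0, 190_000, 400)]
        )
        targets = FeatureSet(cands.df.iloc[::10])
        a = enrich.matched_controls(cands, targets, genome, seed=7)
        b = enrich.matched_controls(cands, targets, genome, seed=7)
        pd.testing.assert_frame_equal(a.df, b.df)


class TestEnrichmentScan:
    @staticmethod
    def planted(seed, n, enrich_factor=1.0):
        """Molecules with random clusters; category X oversamples cluster 0."""
        rng = np.random.default_rng(seed)
        ids = [f"m{i}" for i in range(n)]
        clusters = rng.integers(0, 4, size=n)
        weights = np.where(clusters == 0, enrich_factor, 1.0)
        cat_x = rng.random(n) < 0.3 * weights / weights.mean()
        rows = [(ids[i], "X") for i in range(n) if cat_x[i]]
        rows += [(ids[i], "Y") for i in range(n) if rng.random() < 0.4]
        assignment = ClusterAssignment(ids, clusters)
        cats = pd.DataFrame(rows, columns=["molecule_id", "category"])
        return assignment, cats

    def test_planted_enrichment_detected(self):
        assignment, cats = self.planted(0, 20_000, enrich_factor=2.0)
        table = enrich.enrichment_scan(assignment, cats)
        row = table[(table["cluster"] == 0) & (table["category"] == "X")].iloc[0]
        assert row["odds_ratio"] > 1.0
        assert row["q_value"] < 0.1 and row["significant"]

    def test_single_cluster_single_category_one_row(self):
        a = ClusterAssignment(["m0", "m1", "m2"], np.zeros(3, int))
        table = enrich.enrichment_scan(a, {"m0": ["X"], "m1": ["X"], "m2": ["X"]})
        assert len(table) == 1

    def test_qvalues_monotone_within_table(self):
        assignment, cats = self.planted(4, 5000, enrich_factor=1.5)
        table = enrich.enrichment_scan(assignment, cats)
        srt = table.sort_values("p_value")
        assert np.all(np.diff(srt["q_value"]) >= -1e-12)

    def test_null_scan_controls_fdr(self):
        """Empirical FDR over 200 seeded null replicates stays near nominal."""
        fdps = []
        for seed in range(200):
            assignment, cats = self.planted(1000 + seed, 500, enrich_factor=1.0)
            table = enrich.enrichment_scan(assignment, cats, fdr=0.1)
            n_rej = int(table["significant"].sum())
            fdps.append(1.0 if n_rej > 0 else 0.0)  # every rejection is false
        assert np.mean(fdps) <= 0.15
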