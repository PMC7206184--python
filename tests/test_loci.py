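"""LD clumping, gene annotation, matched null sets and enrichment."""

import numpy as np
import pandas as pd
import pytest

from lvgwas.loci import (
    ClumpConfig,
    MatchTolerances,
    annotate_nearest_gene,
    clump_loci,
    enrichment_report,
    gene_panel_overlap,
    ld_r2,
    matched_null_sets,
    matching_properties,
    permutation_enrichment_p,
)
from lvgwas.synthetic import SimulationConfig, make_gene_map, simulate_genotypes
from tests.conftest import make_panel


def _stats_for(panel, p_values):
    v = panel.variants
    return pd.DataFrame(
        {
            "CHR": v["chrom"],
            "POS": v["pos"],
            "ID": v["id"],
            "EA": v["alt"],
            "NEA": v["ref"],
            "EAF": panel.dosages.mean(axis=0) / 2,
            "BETA": np.zeros(len(v)),
            "SE": np.ones(len(v)),
            "P": np.asarray(p_values, dtype=float),
        }
    )


def reference_clump(stats, panel, cfg):
    """Straightforward re-implementation with a full precomputed r2 matrix."""
    p = stats["P"].to_numpy()
    pos = stats["POS"].to_numpy()
    chrom = stats["CHR"].to_numpy()
    r = np.corrcoef(panel.dosages.T) ** 2
    sig = sorted(np.flatnonzero(p < cfg.p_threshold), key=lambda j: p[j])
    taken = set()
    loci = []
    for lead in sig:
        if lead in taken:
            continue
        taken.add(lead)
        members, secondary = [], []
        for j in sig:
            if j in taken or chrom[j] != chrom[lead]:
                continue
            if abs(pos[j] - pos[lead]) <= cfg.window_kb * 1000:
                (members if r[lead, j] >= cfg.r2_threshold else secondary).append(j)
                taken.add(j)
        loci.append((lead, sorted(members), sorted(secondary)))
    return loci


class TestLdR2:
    def test_self_and_duplicate_are_one(self, rng):
        d = rng.integers(0, 3, size=(100, 2)).astype(float)
        d[:, 1] = d[:, 0]
        panel = make_panel(d)
        assert ld_r2(panel, 0, 0) == pytest.approx(1.0)
        assert ld_r2(panel, 0, 1) == pytest.approx(1.0)

    def test_independent_variants_expected_r2(self, rng):
        n, m = 500, 40
        panel = make_panel(rng.integers(0, 3, size=(n, m)).astype(float))
        vals = [ld_r2(panel, i, j) for i in range(m) for j in range(i + 1, m)]
        # E[r^2] = 1/(n-1) under independence
        assert np.mean(vals) == pytest.approx(1 / (n - 1), abs=1 / (n - 1))

    def test_monomorphic_rejected(self, rng):
        d = rng.integers(0, 3, size=(50, 2)).astype(float)
        d[:, 1] = 1.0
        with pytest.raises(ValueError):
            ld_r2(make_panel(d), 0, 1)


class TestClumping:
    def test_tight_cluster_forms_single_locus(self, rng):
        base = rng.integers(0, 3, size=(400, 1)).astype(float)
        noise = rng.normal(0, 0.1, size=(400, 3))
        d = np.clip(base + noise, 0, 2)
        panel = make_panel(d, pos=np.array([10_000, 40_000, 90_000]) + 0)
        stats = _stats_for(panel, [1e-10, 1e-12, 1e-9])
        loci = clump_loci(stats, panel, ClumpConfig())
        assert len(loci) == 1
        assert loci[0].lead_snp == "snp1"  # smallest p
        assert set(loci[0].member_snps) == {"snp0", "snp2"}

    def test_distant_snps_form_two_loci(self, rng):
        d = rng.integers(0, 3, size=(300, 2)).astype(float)
        panel = make_panel(d, pos=np.array([100_000, 700_000]))
        stats = _stats_for(panel, [1e-9, 1e-10])
        loci = clump_loci(stats, panel, ClumpConfig())
        assert len(loci) == 2

    def test_empty_stats_empty_set(self, small_panel):
        stats = _stats_for(small_panel, np.full(small_panel.n_variants, 0.5))
        assert clump_loci(stats, small_panel, ClumpConfig()) == []

    def test_lead_snps_pairwise_independent(self, small_panel, rng):
        p = 10.0 ** rng.uniform(-12, -2, small_panel.n_variants)
        cfg = ClumpConfig(p_threshold=1e-6, r2_threshold=0.2, window_kb=30)
        stats = _stats_for(small_panel, p)
        loci = clump_loci(stats, small_panel, cfg)
        idmap = {v: j for j, v in enumerate(small_panel.variants["id"])}
        pos = small_panel.variants["pos"].to_numpy()
        chrom = small_panel.variants["chrom"].to_numpy()
        for a in loci:
            for b in loci:
                if a.lead_snp == b.lead_snp:
                    continue
                ia, ib = idmap[a.lead_snp], idmap[b.lead_snp]
                if chrom[ia] != chrom[ib]:
                    continue
                far = abs(pos[ia] - pos[ib]) > cfg.window_kb * 1000
                assert far or ld_r2(small_panel, ia, ib) < cfg.r2_threshold

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_reference_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 300, 20
        cfg = SimulationConfig(
            n_samples=n, n_variants=m, ld_block_size=5, within_block_r=0.7,
            seed=seed, maf_range=(0.1, 0.5), n_causal=2,
        )
        panel = simulate_genotypes(cfg)
        # force everything onto one chromosome with a tight span
        panel.variants["chrom"] = 1
        panel.variants["pos"] = np.sort(rng.choice(10**6, size=m, replace=False))
        p = 10.0 ** rng.uniform(-12, 0, m)
        stats = _stats_for(panel, p)
        ccfg = ClumpConfig(p_threshold=1e-4, r2_threshold=0.2, window_kb=200)
        got = clump_loci(stats, panel, ccfg)
        want = reference_clump(stats, panel, ccfg)
        ids = panel.variants["id"].to_numpy()
        got_tuples = [
            (x.lead_snp, sorted(x.member_snps), sorted(x.secondary_snps)) for x in got
        ]
        want_tuples = [
            (ids[l], sorted(ids[j] for j in mm), sorted(ids[j] for j in ss))
            for l, mm, ss in want
        ]
        assert got_tuples == want_tuples


class TestNearestGene:
    GMAP = pd.DataFrame(
        {
            "chrom": [1, 1, 1],
            "start": [1000, 5000, 9000],
            "end": [2000, 6000, 10_000],
            "gene": ["A", "B", "C"],
            "panel_flag": [0, 1, 0],
        }
    )

    def _locus(self, pos):
        from lvgwas.loci import Locus

        return Locus(lead_snp="x", chrom=1, lead_pos=pos, lead_p=1e-9)

    def test_inside_gene_distance_zero(self):
        (res,) = annotate_nearest_gene([self._locus(1500)], self.GMAP)
        assert res.nearest_gene == "A" and res.nearest_gene_distance == 0

    def test_equidistant_tie_prefers_lower_start(self):
        (res,) = annotate_nearest_gene([self._locus(3500)], self.GMAP)
        assert res.nearest_gene == "A"
        assert res.nearest_gene_tie

    def test_agrees_with_linear_scan_oracle(self, rng):
        genes = pd.DataFrame(
            {
                "chrom": np.ones(30, dtype=int),
                "start": np.sort(rng.choice(10**6, 30, replace=False)),
                "end": 0,
                "gene": [f"g{i}" for i in range(30)],
                "panel_flag": 0,
            }
        )
        genes["end"] = genes["start"] + rng.integers(100, 5000, 30)
        for pos in rng.choice(10**6, 50, replace=False):
            (res,) = annotate_nearest_gene([self._locus(int(pos))], genes)
            dists = [
                0 if s <= pos <= e else min(abs(s - pos), abs(e - pos))
                for s, e in zip(genes["start"], genes["end"])
            ]
            assert res.nearest_gene_distance == min(dists)


class TestMatchedNullSets:
    def _props(self, rng, m=400):
        return pd.DataFrame(
            {
                "id": [f"snp{i}" for i in range(m)],
                "maf": rng.uniform(0.01, 0.5, m),
                "n_ld_buddies": rng.integers(0, 30, m),
                "dist_to_nearest_gene": rng.integers(0, 200_000, m),
                "gene_density": rng.integers(1, 12, m),
            }
        )

    def test_all_matches_fall_in_bins(self, rng):
        props = self._props(rng)
        leads = np.array([3, 77, 200])
        tol = MatchTolerances()
        sets = matched_null_sets(leads, props, n_sets=50, tolerances=tol, seed=1)
        for k, li in enumerate(leads):
            lead = props.iloc[li]
            chosen = props.iloc[sets[:, k]]
            assert (np.abs(chosen["maf"] - lead["maf"]) <= 8 * tol.maf_abs + 1e-12).all()
            assert not (sets[:, k] == li).any()  # leads excluded from pools

    def test_infinite_tolerance_reduces_to_uniform_sampling(self, rng):
        props = self._props(rng)
        leads = np.array([0])
        tol = MatchTolerances(maf_abs=np.inf, buddies_rel=np.inf,
                              gene_dist_rel=np.inf, gene_density_rel=np.inf)
        sets = matched_null_sets(leads, props, n_sets=3000, tolerances=tol, seed=2)
        sampled_maf = props.iloc[sets[:, 0]]["maf"]
        assert sampled_maf.mean() == pytest.approx(props["maf"].mean(), abs=0.02)

    def test_exact_duplicate_pool_matches_perfectly(self):
        row = {"maf": 0.2, "n_ld_buddies": 5, "dist_to_nearest_gene": 100, "gene_density": 3}
        props = pd.DataFrame([row] * 101)
        props.insert(0, "id", [f"snp{i}" for i in range(101)])
        sets = matched_null_sets(np.array([0]), props, n_sets=20, seed=3)
        chosen = props.iloc[sets[:, 0]]
        assert (chosen["maf"] == 0.2).all()

    def test_reproducible_under_seed(self, rng):
        props = self._props(rng)
        a = matched_null_sets(np.array([5, 9]), props, n_sets=30, seed=4)
        b = matched_null_sets(np.array([5, 9]), props, n_sets=30, seed=4)
        assert np.array_equal(a, b)

    def test_empty_pool_raises(self):
        props = pd.DataFrame(
            {
                "id": ["a", "b"],
                "maf": [0.01, 0.49],
                "n_ld_buddies": [0, 500],
                "dist_to_nearest_gene": [0, 10**7],
                "gene_density": [1, 50],
            }
        )
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                matched_null_sets(np.array([0]), props, n_sets=100, seed=5)


class TestEnrichment:
    def test_overlap_radius_boundaries(self):
        gmap = pd.DataFrame(
            {"chrom": [1], "start": [1_000_000], "end": [1_010_000],
             "gene": ["CMP0"], "panel_flag": [1]}
        )
        near = gene_panel_overlap([1], [1_000_000 - 499_999], gmap, ["CMP0"], 500)
        far = gene_panel_overlap([1], [1_000_000 - 500_001], gmap, ["CMP0"], 500)
        assert near == 1 and far == 0

    def test_overlap_matches_interval_oracle(self, rng):
        gmap = pd.DataFrame(
            {
                "chrom": np.ones(5, dtype=int),
                "start": np.sort(rng.choice(10**7, 5, replace=False)),
                "end": 0,
                "gene": [f"g{i}" for i in range(5)],
                "panel_flag": 1,
            }
        )
        gmap["end"] = gmap["start"] + 10_000
        snps = rng.choice(10**7, 10, replace=False)
        got = gene_panel_overlap(np.ones(10, dtype=int), snps, gmap, list(gmap["gene"]), 100)
        want = sum(
            any(s - 100_000 <= p <= e + 100_000 for s, e in zip(gmap["start"], gmap["end"]))
            for p in snps
        )
        assert got == want

    def test_permutation_p_extremes(self):
        nulls = np.arange(10_000)
        p_hi = permutation_enrichment_p(10_001, nulls)
        assert p_hi == pytest.approx(1 / 10_001)
        assert float(f"{p_hi:.1e}") == 1.0e-4  # printed two-significant-figure form
        assert permutation_enrichment_p(-1, nulls) == 1.0

    def test_enrichment_report_schema(self):
        rep = enrichment_report(5, np.array([1, 2, 3]))
        assert set(rep.columns) == {"observed", "null_mean", "null_sd", "n_sets", "p_one_tailed"}

    def test_super_uniform_under_random_panel(self, rng):
        """With a random (non-associated) gene panel the permutation p is
        super-uniform: P(p <= a) <= a plus grid/Monte-Carlo slack."""
        cfg = SimulationConfig(
            n_samples=300, n_variants=300, within_block_r=0.3, seed=44,
            maf_range=(0.05, 0.5), n_causal=10,
        )
        panel = simulate_genotypes(cfg)
        gmap = make_gene_map(panel, n_genes=60, n_panel_genes=10, seed=44)
        props = matching_properties(panel, gmap, window_kb=100)
        chrom = panel.variants["chrom"].to_numpy()
        pos = panel.variants["pos"].to_numpy()
        all_genes = gmap["gene"].tolist()
        n_reps, n_sets = 200, 99
        pvals = []
        for rep in range(n_reps):
            leads = rng.choice(panel.n_variants, size=4, replace=False)
            panel_genes = list(rng.choice(all_genes, size=8, replace=False))
            nulls_idx = matched_null_sets(
                leads, props, n_sets=n_sets,
                tolerances=MatchTolerances(0.5, 10, 10, 10), seed=rep,
            )
            obs = gene_panel_overlap(chrom[leads], pos[leads], gmap, panel_genes, 100)
            nulls = np.array(
                [
                    gene_panel_overlap(chrom[s], pos[s], gmap, panel_genes, 100)
                    for s in nulls_idx
                ]
            )
            pvals.append(permutation_enrichment_p(obs, nulls))
        pvals = np.array(pvals)
        for alpha in (0.05, 0.2, 0.5):
            slack = 1 / (n_sets + 1) + 3 * np.sqrt(alpha * (1 - alpha) / n_reps)
            assert (pvals <= alpha).mean() <= alpha + slack
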