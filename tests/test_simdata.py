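"""Synthetic-data generators: determinism, planted structure, ground truth."""

import numpy as np
import pytest
from scipy import stats

from polyorigin import simdata
from polyorigin.phylogeny import COMMON_ANCESTOR, gap_filter, trim_alignment
from polyorigin.simdata import (
    HYBRID,
    MATERNAL_TIP_1,
    MATERNAL_TIP_2,
    PATERNAL,
    SimulationConfig,
    hybridize,
    simulate_expression,
    simulate_ortholog_groups,
    simulate_plastid_snps,
    simulate_progenitors,
    simulate_reads,
)


class TestProgenitors:
    def test_zero_divergence_gives_identical_parents(self):
        cfg = SimulationConfig(seed=3, ancestral_length=2_000, divergence_per_branch=0.0)
        prog = simulate_progenitors(cfg)
        for genome in prog.genomes.values():
            assert genome == prog.ancestor

    def test_mismatch_fraction_tracks_rate(self):
        cfg = SimulationConfig(seed=7, ancestral_length=100_000, divergence_per_branch=0.02)
        prog = simulate_progenitors(cfg)
        for label, genome in prog.genomes.items():
            mismatch = np.mean(
                [a != b for a, b in zip(prog.ancestor, genome)]
            )
            assert mismatch == pytest.approx(0.02, abs=0.005)
            # recorded ground-truth positions are exactly the mismatches
            observed = {i for i, (a, b) in enumerate(zip(prog.ancestor, genome)) if a != b}
            assert observed == set(prog.mutation_positions[label].tolist())

    def test_same_seed_same_output(self):
        cfg = SimulationConfig(seed=11, ancestral_length=3_000)
        assert simulate_progenitors(cfg).genomes == simulate_progenitors(cfg).genomes

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(ancestral_length=0)
        with pytest.raises(ValueError):
            SimulationConfig(divergence_per_branch=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(downsizing_fraction=1.0)


class TestHybridize:
    def test_zero_fraction_is_concatenation(self):
        h = hybridize("ACGT" * 10, "TTTT" * 5)
        assert h.sequence == "ACGT" * 10 + "TTTT" * 5
        assert len(h.sequence) == 60

    def test_downsizing_arithmetic_exact(self):
        a = "A" * 100_000
        b = "C" * 100_000
        h = hybridize(a, b, downsizing_fraction=0.10, seed=5)
        assert len(h.sequence) == 180_000
        assert h.subgenome_length(0) == 90_000
        assert h.subgenome_length(1) == 90_000

    def test_origin_map_partitions_every_base(self):
        h = hybridize("ACGT" * 250, "GGCC" * 300, downsizing_fraction=0.2, seed=9)
        assert h.origin.size == len(h.sequence)
        assert set(np.unique(h.origin)) == {0, 1}
        # origin 0 bases come from parent A's alphabet, origin 1 from B's
        seq = np.array(list(h.sequence))
        assert set(seq[h.origin == 0]) <= set("ACGT")
        assert set(seq[h.origin == 1]) <= set("GC")

    def test_full_fraction_rejected(self):
        with pytest.raises(ValueError):
            hybridize("ACGT", "ACGT", downsizing_fraction=1.0)


class TestReads:
    def test_forced_count_and_exact_substrings(self):
        genome = simulate_progenitors(
            SimulationConfig(seed=2, ancestral_length=2_000)
        ).ancestor
        reads = simulate_reads(genome, coverage=5, read_length=100, seed=4)
        assert len(reads) == 100  # ceil(5 * 2000 / 100)
        for r in reads[:20]:
            assert r.sequence in genome
            assert r.quality == "I" * 100

    def test_error_rate_realized(self):
        genome = simulate_progenitors(
            SimulationConfig(seed=2, ancestral_length=20_000)
        ).ancestor
        reads = simulate_reads(genome, coverage=10, read_length=100,
                               error_rate=0.01, seed=6)
        # same seed without errors regenerates the identical source windows,
        # so the realized error rate is a direct pairwise mismatch count
        mismatches = total = 0
        clean = simulate_reads(genome, coverage=10, read_length=100,
                               error_rate=0.0, seed=6)
        for noisy, ref in zip(reads, clean):
            mismatches += sum(a != b for a, b in zip(noisy.sequence, ref.sequence))
            total += len(ref.sequence)
        assert mismatches / total == pytest.approx(0.01, abs=0.002)

    def test_determinism_and_validation(self):
        genome = "ACGTACGTAC" * 50
        a = simulate_reads(genome, 3, 50, 0.05, seed=8)
        b = simulate_reads(genome, 3, 50, 0.05, seed=8)
        assert [(r.read_id, r.sequence) for r in a] == [(r.read_id, r.sequence) for r in b]
        with pytest.raises(ValueError):
            simulate_reads(genome, 0, 50)
        with pytest.raises(ValueError):
            simulate_reads("ACGT", 5, read_length=10)


class TestPlastid:
    def test_default_regions_reproduced_exactly(self):
        sim = simulate_plastid_snps(SimulationConfig(seed=1))
        sets = {lab: s.records for lab, s in sim.snp_sets.items()}
        # planted counts: every exclusive region matches the template
        for region, n in simdata.DEFAULT_PLASTID_REGIONS.items():
            inside = set.intersection(*(set(sets[sp]) for sp in region))
            outside = set.union(
                *(set(sets[sp]) for sp in sets if sp not in region)
            )
            assert len(inside - outside) == n

    def test_hybrid_never_carries_paternal_private_snps(self):
        sim = simulate_plastid_snps(SimulationConfig(seed=2))
        paternal_private = (
            set(sim.snp_sets[PATERNAL].records)
            - set(sim.snp_sets[HYBRID].records)
            - set(sim.snp_sets[MATERNAL_TIP_1].records)
            - set(sim.snp_sets[MATERNAL_TIP_2].records)
        )
        assert len(paternal_private) == 336
        tree_sim = simulate_plastid_snps(
            SimulationConfig(seed=2, plastid_regions="tree", plastid_snps_per_branch=50)
        )
        assert not (
            set(tree_sim.snp_sets[HYBRID].records)
            & set(tree_sim.snp_sets[PATERNAL].records)
        )

    def test_positions_unique_across_all_snps(self):
        sim = simulate_plastid_snps(SimulationConfig(seed=3))
        positions = [
            rec[1] for s in sim.snp_sets.values() for rec in s.records
        ]
        by_record = {rec for s in sim.snp_sets.values() for rec in s.records}
        assert len({r[1] for r in by_record}) == len(by_record)
        assert max(positions) <= 156_000


class TestOrthologs:
    def test_pure_mix_gives_single_label(self):
        sim = simulate_ortholog_groups(
            SimulationConfig(seed=4, n_ortholog_groups=20, topology_mix=(1.0, 0.0, 0.0))
        )
        assert set(sim.truth.topology) == {MATERNAL_TIP_1}

    def test_mix_counts_within_binomial_bounds(self):
        mix = (0.42, 0.36, 0.22)
        sim = simulate_ortholog_groups(
            SimulationConfig(seed=3, n_ortholog_groups=1000, topology_mix=mix)
        )
        counts = sim.truth.topology.value_counts()
        for label, p in zip(
            (MATERNAL_TIP_1, MATERNAL_TIP_2, COMMON_ANCESTOR), mix
        ):
            lo, hi = stats.binom.ppf([0.005, 0.995], 1000, p)
            assert lo <= counts[label] <= hi

    def test_gap_free_groups_pass_filters(self, ortholog_sim):
        for g in ortholog_sim.groups:
            trimmed = trim_alignment(g.alignment)
            assert trimmed == g.alignment  # no terminal gaps to trim
            assert gap_filter(trimmed)

    def test_gap_classes_behave_as_planted(self):
        sim = simulate_ortholog_groups(
            SimulationConfig(seed=9, n_ortholog_groups=120,
                             gap_fraction=0.5, gap_heavy_fraction=0.25)
        )
        truth = sim.truth.set_index("group_id")
        seen = {"heavy": 0, "light": 0}
        for g in sim.groups:
            cls = truth.loc[g.group_id, "gap_class"]
            trimmed = trim_alignment(g.alignment)
            if cls == "heavy":
                assert not gap_filter(trimmed)
                seen["heavy"] += 1
            elif cls == "light":
                assert gap_filter(trimmed)
                seen["light"] += 1
        assert seen["heavy"] > 5 and seen["light"] > 5

    def test_composition_corruption_planted(self):
        sim = simulate_ortholog_groups(
            SimulationConfig(seed=5, n_ortholog_groups=100, corrupt_fraction=0.3)
        )
        truth = sim.truth.set_index("group_id")
        for g in sim.groups:
            expected = dict(sim.rule.expected_copies)
            matches = dict(g.species_counts()) == expected
            assert matches != bool(truth.loc[g.group_id, "corrupted"])

    def test_determinism(self):
        cfg = SimulationConfig(seed=6, n_ortholog_groups=10)
        a = simulate_ortholog_groups(cfg)
        b = simulate_ortholog_groups(cfg)
        assert [g.alignment for g in a.groups] == [g.alignment for g in b.groups]


class TestExpression:
    def test_zero_noise_limit_gives_r_of_one(self):
        sim = simulate_expression(SimulationConfig(seed=7, planted_correlation=1.0))
        m = sim.metabolite.to_numpy()
        for g in sim.planted_ids:
            r = np.corrcoef(sim.expression.loc[g].to_numpy(), m)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_mean_r_near_planted(self):
        rs = []
        for seed in range(200):
            sim = simulate_expression(
                SimulationConfig(seed=seed, n_background_genes=0, n_planted_genes=1)
            )
            m = sim.metabolite.to_numpy()
            x = sim.expression.loc[sim.planted_ids[0]].to_numpy()
            rs.append(np.corrcoef(x, m)[0, 1])
        assert np.mean(rs) == pytest.approx(0.95, abs=0.03)

    def test_background_rarely_exceeds_09(self):
        sim = simulate_expression(
            SimulationConfig(seed=8, n_background_genes=500, n_planted_genes=0)
        )
        m = sim.metabolite.to_numpy()
        x = sim.expression.to_numpy()
        xc = x - x.mean(axis=1, keepdims=True)
        mc = m - m.mean()
        r = (xc @ mc) / (np.sqrt((xc**2).sum(axis=1)) * np.sqrt((mc**2).sum()))
        assert np.mean(np.abs(r) > 0.9) < 0.05

    def test_all_values_nonnegative_and_validated(self):
        sim = simulate_expression(SimulationConfig(seed=9))
        assert (sim.expression.to_numpy() >= 0).all()
        with pytest.raises(ValueError):
            SimulationConfig(planted_correlation=1.5)
        with pytest.raises(ValueError):
            simulate_expression(SimulationConfig(expression_samples=("a", "b")))
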