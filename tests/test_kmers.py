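"""K-mer counting, genome sizing and attribution arithmetic."""

import numpy as np
import pytest

from polyorigin import kmers
from polyorigin.kmers import (
    FilteredKmerSet,
    KmerSpectrum,
    attribute_subgenome,
    count_kmers,
    downsizing_report,
    estimate_genome_size,
    expected_contribution_from_sizes,
    kmer_to_string,
    venn_partition,
    whole_genome_reduction_percent,
)


def brute_force_canonical_kmers(seq: str, k: int) -> list[str]:
    """Hand oracle: enumerate windows and canonicalize via string revcomp."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(c not in comp for c in w):
            continue
        rc = "".join(comp[c] for c in reversed(w))
        out.append(min(w, rc))
    return out


class TestCounting:
    def test_hand_enumerated_example(self):
        # ACGTACGT, k=3: windows ACG CGT GTA TAC ACG CGT; CGT and TAC
        # canonicalize to ACG and GTA
        counts = count_kmers("ACGTACGT", k=3)
        decoded = {
            kmer_to_string(km, 3): int(d) for km, d in zip(counts.kmers, counts.depths)
        }
        assert decoded == {"ACG": 4, "GTA": 2}
        spec = counts.spectrum()
        assert spec.total_instances == 6

    @pytest.mark.parametrize("k", [3, 5, 7, 31])
    def test_matches_brute_force_oracle(self, k, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=300, p=[0.24] * 4 + [0.04]))
        counts = count_kmers(seq, k=k)
        oracle = brute_force_canonical_kmers(seq, k)
        decoded = {
            kmer_to_string(km, k): int(d) for km, d in zip(counts.kmers, counts.depths)
        }
        expected: dict[str, int] = {}
        for w in oracle:
            expected[w] = expected.get(w, 0) + 1
        assert decoded == expected

    def test_revcomp_symmetry(self):
        seq = "ACGGTTACCGTAGGCATTTACG"
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        a, b = count_kmers(seq, k=5), count_kmers(rc, k=5)
        assert np.array_equal(a.kmers, b.kmers)
        assert np.array_equal(a.depths, b.depths)

    def test_all_n_sequence_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="no valid k-mer"):
            counts = count_kmers("N" * 50, k=31)
        assert counts.kmers.size == 0
        assert counts.spectrum().histogram == {}

    def test_even_k_and_empty_input_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            count_kmers("ACGTACGTACGT", k=4)
        with pytest.raises(ValueError, match="no input"):
            count_kmers([])

    def test_string_engine_large_k_agrees_with_semantics(self):
        seq = "ACGT" * 30
        counts = count_kmers(seq, k=33)
        oracle = brute_force_canonical_kmers(seq, 33)
        expected: dict[str, int] = {}
        for w in oracle:
            expected[w] = expected.get(w, 0) + 1
        assert {str(km): int(d) for km, d in zip(counts.kmers, counts.depths)} == expected

    def test_reads_do_not_bridge_boundaries(self):
        joined = count_kmers(["ACGTA", "CGTAC"], k=5)
        assert int(joined.depths.sum()) == 2  # one window per read


class TestGenomeSize:
    def test_uniform_depth_closed_form(self):
        # 1e5 distinct k-mers all at depth 50 -> size exactly 1e5
        spec = KmerSpectrum(31, {50: 100_000})
        est = estimate_genome_size(spec, error_cutoff=5)
        assert est.size_bases == pytest.approx(100_000)
        assert est.modal_depth == 50

    def test_auto_cutoff_separates_error_peak(self):
        # error k-mers at depth 1-2, genome peak at depth 30
        # counts fall 5000 -> 800 -> 10 -> 0, so the valley bottoms at depth 4
        spec = KmerSpectrum(31, {1: 5000, 2: 800, 3: 10, 29: 400, 30: 900, 31: 420})
        est = estimate_genome_size(spec, "auto")
        assert est.cutoff == 4
        assert est.modal_depth == 30
        expected = (29 * 400 + 30 * 900 + 31 * 420) / 30
        assert est.size_bases == pytest.approx(expected)

    def test_modal_tie_breaks_low(self):
        spec = KmerSpectrum(31, {10: 100, 20: 100})
        assert estimate_genome_size(spec, 5).modal_depth == 10

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_genome_size(KmerSpectrum(31, {}))
        with pytest.raises(ValueError, match="no homozygous peak"):
            estimate_genome_size(KmerSpectrum(31, {1: 10, 2: 5}), error_cutoff=5)


def _fset(label, values, k=31):
    return FilteredKmerSet(label, k, np.unique(np.asarray(values, dtype=np.uint64)))


class TestVennPartition:
    def test_mixed_k_rejected(self):
        with pytest.raises(ValueError, match="share k"):
            venn_partition([_fset("a", [1], k=31), _fset("b", [1], k=21)])

    def test_partition_sums_to_union(self, rng):
        sets = [
            _fset(lab, rng.integers(0, 500, size=200)) for lab in ("a", "b", "c", "d")
        ]
        part = venn_partition(sets)
        union = np.unique(np.concatenate([s.members for s in sets]))
        assert part.union_size == union.size
        for s in sets:
            assert part.marginal(s.species_label) == len(s)


class TestAttribution:
    def test_disjoint_construction_forces_fraction(self):
        pat = _fset("pat", np.arange(300))
        mat = _fset("mat", np.arange(1000, 1700))
        hyb = _fset("hyb", np.concatenate([pat.members, mat.members]))
        report = attribute_subgenome(hyb, pat, mat)
        assert report.paternal_fraction == pytest.approx(30.0)
        assert report.n_shared_both == 0 and report.n_private_hybrid == 0

    def test_swapping_parents_swaps_fractions(self):
        pat = _fset("pat", np.arange(300))
        mat = _fset("mat", np.arange(1000, 1700))
        hyb = _fset("hyb", np.concatenate([pat.members, mat.members]))
        fwd = attribute_subgenome(hyb, pat, mat)
        rev = attribute_subgenome(hyb, mat, pat)
        assert fwd.paternal_fraction == pytest.approx(rev.maternal_fraction)

    def test_maternal_lineage_union(self):
        pat = _fset("pat", np.arange(100))
        m1 = _fset("m1", np.arange(500, 650))
        m2 = _fset("m2", np.arange(600, 750))
        hyb = _fset("hyb", np.concatenate([pat.members, np.arange(500, 750)]))
        report = attribute_subgenome(hyb, pat, [m1, m2])
        assert report.n_maternal_diagnostic == 250
        assert report.paternal_fraction == pytest.approx(100 * 100 / 350)

    def test_shared_and_private_kmers_excluded_from_denominator(self):
        # normalizing printed exclusive-sharing percentages 29 and 41
        # reproduces the 41.4/58.6 attribution
        pat = _fset("pat", np.arange(0, 2900))  # 29% of hybrid
        mat = _fset("mat", np.arange(10_000, 14_100))  # 41%
        both = np.arange(20_000, 20_500)  # shared with both: excluded
        private = np.arange(30_000, 32_500)  # hybrid-only: excluded
        hyb = _fset(
            "hyb",
            np.concatenate([pat.members, mat.members, both, private]),
        )
        pat = _fset("pat", np.concatenate([pat.members, both]))
        mat = _fset("mat", np.concatenate([mat.members, both]))
        report = attribute_subgenome(hyb, pat, mat)
        assert round(report.paternal_fraction, 1) == 41.4
        assert round(report.maternal_fraction, 1) == 58.6

    def test_no_diagnostic_kmers_is_an_error(self):
        shared = np.arange(100)
        with pytest.raises(ValueError, match="no diagnostic"):
            attribute_subgenome(
                _fset("h", shared), _fset("p", shared), _fset("m", shared)
            )


class TestContributionArithmetic:
    def test_expected_contributions_from_sizes(self):
        assert expected_contribution_from_sizes(2.18, 3.19) == (40.6, 59.4)
        assert expected_contribution_from_sizes(2.22, 2.59) == (46.2, 53.8)
        assert expected_contribution_from_sizes(1.0, 1.0) == (50.0, 50.0)

    def test_downsizing_report_tetraploid(self):
        rep = downsizing_report(41.4, 4.99, 2.18, 3.19)
        assert rep.paternal_contribution_gb == 2.07
        assert rep.maternal_contribution_gb == 2.92
        assert rep.paternal_downsizing_gb == 0.11
        assert rep.maternal_downsizing_gb == 0.27

    def test_downsizing_report_with_upsizing(self):
        rep = downsizing_report(40.3, 4.41, 2.22, 2.59)
        assert rep.paternal_contribution_gb == 1.78
        assert rep.maternal_contribution_gb == 2.63
        assert rep.paternal_downsizing_gb == 0.44
        assert rep.maternal_downsizing_gb == -0.04
        assert "upsizing" in rep.summary()

    def test_downsizing_report_balanced(self):
        rep = downsizing_report(50.0, 2.0, 1.0, 1.0)
        assert rep.paternal_contribution_gb == 1.0
        assert rep.paternal_downsizing_gb == 0.0

    def test_whole_genome_reduction(self):
        assert whole_genome_reduction_percent(4.99, 2.18, 3.26) == 8.3
        assert whole_genome_reduction_percent(4.99, 2.18, 3.12) == 5.8

    def test_validation(self):
        with pytest.raises(ValueError):
            expected_contribution_from_sizes(0.0, 1.0)
        with pytest.raises(ValueError):
            downsizing_report(0.0, 1.0, 1.0, 1.0)
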