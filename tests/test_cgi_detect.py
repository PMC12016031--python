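"""Island predictors, composition features, and the geometric null."""

import math

import numpy as np
import pytest

from islandmap import (
    CpGIsland,
    DistanceModel,
    SequenceRecord,
    cluster_cpgs,
    cluster_pvalue,
    cpg_positions,
    gc_content,
    geometric_prob,
    inter_cpg_distances,
    island_features,
    oe_ratio,
    predict_density_cgis,
    predict_position_cgis,
    recovery_rate,
)
from islandmap.errors import UndefinedContentError, UndefinedRatioError
from tests.conftest import random_sequence


class TestComposition:
    @pytest.mark.parametrize("seq,expected", [("ATAT", 0.0), ("ACGT", 0.5), ("GCGC", 1.0)])
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == expected

    def test_gc_excludes_n(self):
        assert gc_content("GCNN") == 1.0
        with pytest.raises(UndefinedContentError):
            gc_content("NNNN")

    @pytest.mark.parametrize("seq,expected", [("CGCGCGCG", 2.0), ("CCGG", 1.0)])
    def test_oe_ratio(self, seq, expected):
        assert oe_ratio(seq) == pytest.approx(expected)

    def test_oe_degenerate(self):
        with pytest.raises(UndefinedRatioError):
            oe_ratio("CCCC")  # no G: expected count degenerate
        with pytest.raises(UndefinedRatioError):
            oe_ratio("AAAA")
        assert oe_ratio("CAAG") == 0.0  # C and G present, no CpG

    def test_oe_matches_recount_oracle(self, rng):
        seq = random_sequence(rng, 1000)
        n_c, n_g = seq.count("C"), seq.count("G")
        n_cpg = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
        assert oe_ratio(seq) == pytest.approx(n_cpg * len(seq) / (n_c * n_g))

    def test_island_features_examples(self):
        rec = SequenceRecord("c", "CGCGCGCG")
        isl = island_features(CpGIsland("c", 0, 8, "density"), rec)
        assert (len(isl), isl.gc_content, isl.oe_ratio, isl.cpg_density, isl.n_cpg) == (
            8, 1.0, 2.0, 50.0, 4,
        )
        rec = SequenceRecord("c", "ACGTACGTACGT")
        isl = island_features(CpGIsland("c", 0, 12, "density"), rec)
        assert isl.oe_ratio == pytest.approx(4.0)
        assert isl.cpg_density == pytest.approx(25.0)


class TestDistances:
    @pytest.mark.parametrize(
        "positions,expected", [([0, 2, 4], [1, 1]), ([10, 100], [89]), ([5], [])]
    )
    def test_inter_cpg_distances(self, positions, expected):
        assert list(inter_cpg_distances(positions)) == expected

    def test_geometric_prob(self):
        m = DistanceModel(p=0.25, source_length=100, source_cpg_count=25)
        assert geometric_prob(1, m) == pytest.approx(0.25)
        m2 = DistanceModel(p=0.1, source_length=100, source_cpg_count=10)
        assert geometric_prob(3, m2) == pytest.approx(0.081)
        with pytest.raises(ValueError):
            geometric_prob(0, m)

    def test_geometric_normalization(self):
        m = DistanceModel(p=0.05, source_length=1000, source_cpg_count=50)
        total = sum(geometric_prob(d, m) for d in range(1, 10**6 + 1))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_cluster_pvalue_is_product_of_terms(self, rng):
        m = DistanceModel(p=0.08, source_length=5000, source_cpg_count=400)
        pos = np.cumsum(rng.integers(2, 30, size=12))
        expected = math.prod(geometric_prob(int(d), m) for d in inter_cpg_distances(pos))
        assert cluster_pvalue(pos, m) == pytest.approx(expected, rel=1e-12)

    def test_cluster_pvalue_non_increasing_with_members(self):
        m = DistanceModel(p=0.1, source_length=1000, source_cpg_count=100)
        pos = [0, 4, 9, 15, 30]
        pvals = [cluster_pvalue(pos[: k + 2], m) for k in range(len(pos) - 1)]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))
        assert cluster_pvalue([0, 2], DistanceModel(0.25, 100, 25)) == pytest.approx(0.25)
        assert cluster_pvalue([0, 2, 4], DistanceModel(0.25, 100, 25)) == pytest.approx(0.0625)


def oracle_segmentation(positions, d_max):
    """Exhaustive check of the cluster definition: every index range (i, j)
    that satisfies all internal gaps <= d_max and is maximal on both sides."""
    positions = list(positions)
    n = len(positions)
    gaps = [positions[k + 1] - positions[k] - 1 for k in range(n - 1)]
    clusters = []
    for i in range(n):
        for j in range(i + 2, n + 1):
            if all(g <= d_max for g in gaps[i : j - 1]):
                left_max = i == 0 or gaps[i - 1] > d_max
                right_max = j == n or gaps[j - 1] > d_max
                if left_max and right_max:
                    clusters.append((i, j))
    return clusters


class TestClusterCpgs:
    def test_split_on_large_gap(self):
        assert cluster_cpgs([0, 2, 4, 100, 103], 25) == [(0, 3), (3, 5)]

    def test_all_gaps_exceed_threshold(self):
        assert cluster_cpgs([0, 50, 100], 25) == []
        assert cluster_cpgs([7], 25) == []

    def test_matches_exhaustive_segmentation_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 60))
            pos = np.cumsum(rng.integers(2, 40, size=n))
            d_max = int(rng.integers(1, 30))
            assert cluster_cpgs(pos, d_max) == oracle_segmentation(pos, d_max)


class TestDensityPredictor:
    def test_single_planted_cg_block(self):
        seq = "A" * 300 + "CG" * 150 + "A" * 300
        rec = SequenceRecord("c", seq)
        islands = predict_density_cgis(rec)
        assert len(islands) == 1
        (isl,) = islands
        assert (isl.start, isl.end) == (300, 600)
        assert isl.gc_content == 1.0 and isl.oe_ratio == pytest.approx(2.0)

    def test_short_block_rejected_by_min_length(self):
        seq = "A" * 300 + "CG" * 75 + "A" * 300
        assert predict_density_cgis(SequenceRecord("c", seq)) == []

    def test_window_wider_than_min_len_rejected(self):
        with pytest.raises(ValueError):
            predict_density_cgis(SequenceRecord("c", "ACGT" * 100), min_len=50, window=100)

    def test_emitted_islands_re_satisfy_thresholds(self, small_simulation):
        """Self-verification: every island re-measured on its final coordinates
        passes the length, GC, and O/E thresholds and is flush with CGs."""
        _, records, _ = small_simulation
        rec = records[0]
        islands = predict_density_cgis(rec)
        assert islands, "simulation should yield density islands"
        for isl in islands:
            sub = rec.sequence[isl.start : isl.end]
            assert len(sub) >= 200
            assert gc_content(sub) >= 0.5
            assert oe_ratio(sub) >= 0.6
            assert sub.startswith("CG") and sub.endswith("CG")

    def test_windows_containing_n_disqualified(self):
        # an N inside an otherwise perfect CG block must not join islands
        seq = "A" * 250 + "CG" * 60 + "N" + "CG" * 60 + "A" * 250
        for isl in predict_density_cgis(SequenceRecord("c", seq)):
            assert "N" not in SequenceRecord("c", seq).sequence[isl.start : isl.end]

    def test_oe_of_iid_uniform_windows_near_one(self, rng):
        """On i.i.d. uniform bases the expected O/E of long windows is ~1."""
        vals = []
        for _ in range(100):
            vals.append(oe_ratio(random_sequence(rng, 10_000)))
        assert 0.9 <= float(np.mean(vals)) <= 1.1


class TestPositionPredictor:
    def test_dense_block_in_cpg_free_background(self, rng):
        background = list("AT" * 5000)
        block = "CG" * 20
        seq = "".join(background[:4000]) + block + "".join(background[4000:])
        rec = SequenceRecord("c", seq)
        islands = predict_position_cgis(rec, 25, alpha=1e-5)
        assert len(islands) == 1
        (isl,) = islands
        assert (isl.start, isl.end) == (4000, 4000 + 40)
        assert isl.n_cpg == 20

    def test_alpha_one_is_cluster_passthrough(self, small_simulation):
        _, records, _ = small_simulation
        rec = records[0]
        clusters = cluster_cpgs(cpg_positions(rec), 25)
        islands = predict_position_cgis(rec, 25, alpha=1.0)
        assert len(islands) == len(clusters)

    def test_island_coordinates_span_member_cpgs(self, small_simulation):
        _, records, _ = small_simulation
        rec = records[0]
        for isl in predict_position_cgis(rec, 25, alpha=1.0):
            assert rec.sequence[isl.start : isl.start + 2] == "CG"
            assert rec.sequence[isl.end - 2 : isl.end] == "CG"

    def test_maximality_of_emitted_islands(self, small_simulation):
        """All internal gaps <= d_max; flanking gaps to outside CpGs > d_max."""
        _, records, _ = small_simulation
        rec = records[0]
        pos = cpg_positions(rec)
        d_max = 25
        for isl in predict_position_cgis(rec, d_max, alpha=1.0):
            members = pos[(pos >= isl.start) & (pos + 2 <= isl.end)]
            assert np.all(inter_cpg_distances(members) <= d_max)
            i = np.searchsorted(pos, members[0])
            j = np.searchsorted(pos, members[-1])
            if i > 0:
                assert members[0] - pos[i - 1] - 1 > d_max
            if j < len(pos) - 1:
                assert pos[j + 1] - members[-1] - 1 > d_max

    def test_nesting_under_threshold_growth(self, small_simulation):
        """Each d=12 island is contained in some d=50 island (alpha disabled)."""
        _, records, _ = small_simulation
        rec = records[0]
        small = predict_position_cgis(rec, 12, alpha=1.0)
        large = predict_position_cgis(rec, 50, alpha=1.0)
        assert small, "expected clusters at d=12"
        for s in small:
            assert any(l.start <= s.start and s.end <= l.end for l in large)

    def test_fewer_than_two_cpgs_yields_nothing(self):
        assert predict_position_cgis(SequenceRecord("c", "ATATCGATAT"), 25) == []


class TestPlantedRecovery:
    def test_both_predictors_recover_planted_islands(self, small_simulation):
        _, records, truth = small_simulation
        rec = records[0]
        dens = predict_density_cgis(rec)
        posl = predict_position_cgis(rec, 25)
        assert recovery_rate(truth.islands, dens) >= 0.8
        assert recovery_rate(truth.islands, posl) >= 0.8
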