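import itertools
import math

import numpy as np
import pytest

from rarecode import motif_scan as ms
from rarecode import synthetic_data as sd
from rarecode.io_core import FormatError, TranscriptModel


# ---------------------------------------------------------------- oracles

def brute_force_distribution(pwm: ms.PWM, granularity: float):
    """Null score distribution by full 4^L enumeration: per-word discretized
    score, weighted by background word probability."""
    iscores = ms.discretize_log_odds(pwm, granularity)
    masses: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=pwm.length):
        k = int(sum(iscores[i, b] for i, b in enumerate(word)))
        p = math.prod(pwm.background[b] for b in word)
        masses[k] = masses.get(k, 0.0) + p
    return masses


def brute_force_pvalue(pwm: ms.PWM, granularity: float, window: str) -> float:
    iscores = ms.discretize_log_odds(pwm, granularity)
    k = sum(iscores[i, ms.NT_INDEX[c]] for i, c in enumerate(window))
    masses = brute_force_distribution(pwm, granularity)
    return sum(m for kk, m in masses.items() if kk >= k)


def random_pwm(rng: np.random.Generator, length: int) -> ms.PWM:
    m = rng.dirichlet(np.full(4, 0.5), size=length)
    return ms.PWM(f"rand{length}", m)


# ------------------------------------------------------------------ tests

class TestLoadPwm:
    def test_probability_matrix_L6(self, tmp_path, urich_pwm):
        p = tmp_path / "m.txt"
        rows = urich_pwm.matrix.T  # 4 rows x 6 cols
        p.write_text(
            "\n".join(f"{nt} " + " ".join(f"{v:.3f}" for v in row)
                      for nt, row in zip("ACGU", rows))
        )
        pwm = ms.load_pwm(p)
        assert pwm.length == 6
        np.testing.assert_allclose(pwm.matrix, urich_pwm.matrix, atol=1e-3)

    def test_count_matrix_with_pseudocount(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("8 0 0 0\n")  # one position, counts
        pwm = ms.load_pwm(p, pseudocount=1.0)
        np.testing.assert_allclose(pwm.matrix[0], [9 / 12, 1 / 12, 1 / 12, 1 / 12])

    def test_three_row_matrix_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0.5 0.5 0.7\n0.2 0.2 0.1\n0.3 0.3 0.2\n")
        with pytest.raises(FormatError):
            ms.load_pwm(p)

    def test_transposed_orientation_detected(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("\n".join("0.7 0.1 0.1 0.1" for _ in range(6)))
        assert ms.load_pwm(p).length == 6

    def test_ambiguous_4x4_rejected(self, tmp_path):
        p = tmp_path / "amb.txt"
        p.write_text("\n".join("0.25 0.25 0.25 0.25" for _ in range(4)))
        with pytest.raises(FormatError, match="ambiguous"):
            ms.load_pwm(p)


class TestScoreDistribution:
    def test_uniform_L1_single_point(self):
        pwm = ms.PWM("u", np.array([[0.25] * 4]))
        dist = ms.score_distribution(pwm)
        assert len(dist.grid) == 1
        assert dist.grid[0] == 0
        assert dist.pmf[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_L4(self, seed):
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng, 4)
        dist = ms.score_distribution(pwm, granularity=0.01)
        oracle = brute_force_distribution(pwm, 0.01)
        assert set(dist.grid.tolist()) == set(oracle)
        for k, pmf in zip(dist.grid, dist.pmf):
            assert pmf == pytest.approx(oracle[int(k)], abs=1e-12)

    def test_total_mass_one(self, urich_dist):
        assert float(urich_dist.pmf.sum()) == pytest.approx(1.0, abs=1e-9)

    def test_survival_monotone(self, urich_dist):
        sf = urich_dist.sf
        assert (np.diff(sf) <= 1e-15).all()

    def test_zero_background_with_nonzero_motif_rejected(self):
        pwm = ms.PWM("z", np.array([[0.5, 0.5, 0.0, 0.0]]),
                     background=np.array([0.5, 0.0, 0.25, 0.25]))
        with pytest.raises(ValueError, match="zero-background"):
            ms.score_distribution(pwm)


class TestPvalueCutoff:
    def test_alpha_one_gives_minimum_support(self, urich_dist):
        cutoff = ms.pvalue_cutoff(urich_dist, 1.0)
        assert cutoff == pytest.approx(float(urich_dist.grid[0]) * urich_dist.granularity)

    def test_matches_enumeration_quantile(self):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, 2)
        dist = ms.score_distribution(pwm, 0.01)
        cutoff = ms.pvalue_cutoff(dist, 0.25)
        masses = brute_force_distribution(pwm, 0.01)
        ks = sorted(masses)
        # smallest k with survival <= alpha
        expected = next(
            k for k in ks
            if sum(m for kk, m in masses.items() if kk >= k) <= 0.25
        )
        assert cutoff == pytest.approx(expected * 0.01)

    def test_cutoff_monotone_in_alpha(self, urich_dist):
        assert ms.pvalue_cutoff(urich_dist, 0.005) >= ms.pvalue_cutoff(urich_dist, 0.01)

    def test_unattainable_alpha_warns(self, urich_dist):
        with pytest.warns(UserWarning, match="minimal attainable"):
            cutoff = ms.pvalue_cutoff(urich_dist, 1e-12)
        assert cutoff == pytest.approx(float(urich_dist.grid[-1]) * urich_dist.granularity)


class TestScanRegion:
    def test_quartile_plus_utr(self):
        tx = TranscriptModel("g", "ATG" * 400, "A" * 200)
        region = ms.extract_scan_region(tx)
        assert region.length == 500
        assert region.cds_span == (900, 1200)
        assert region.utr_span == (1200, 1400)

    def test_ceiling_rule_401_codons(self):
        tx = TranscriptModel("g", "ATG" * 401)
        region = ms.extract_scan_region(tx)
        assert region.length == 101 * 3

    def test_empty_utr_allowed_empty_cds_not(self):
        # 2 codons -> last ceil(0.25 * 2) = 1 codon, no UTR
        assert ms.extract_scan_region(TranscriptModel("g", "ATGTTT")).length == 3
        with pytest.raises(ValueError, match="empty CDS"):
            ms.extract_scan_region(TranscriptModel("g", ""))


class TestScan:
    def test_polyg_region_has_no_hits(self, urich_pwm, urich_dist):
        hits = ms.scan("G" * 120, urich_pwm, urich_dist)
        assert hits.hits == ()

    def test_planted_consensus_recovered(self, urich_pwm, urich_dist):
        utr, truth = sd.plant_motifs(
            sd.synth_background(400, seed=9), "TTTTTT", [20, 150, 333],
            seed=9, pwm=urich_pwm, dist=urich_dist,
        )
        hits = ms.scan(utr, urich_pwm, urich_dist)
        starts = {h.start for h in hits.hits if h.hit_class == "significant"}
        assert hits.n_significant >= 3
        assert set(truth.planted["positions"]) <= starts

    def test_region_shorter_than_motif_is_empty_not_error(self, urich_pwm, urich_dist):
        assert ms.scan("TTT", urich_pwm, urich_dist).hits == ()

    @pytest.mark.parametrize("length", [3, 5, 6])
    def test_agrees_with_brute_force_oracle(self, length):
        """Hit positions, classes and exact p-values match a full 4^L
        enumeration scorer on random PWMs."""
        rng = np.random.default_rng(length)
        pwm = random_pwm(rng, length)
        dist = ms.score_distribution(pwm, 0.01)
        seq = sd.synth_background(300, seed=length)
        hits = ms.scan(seq, pwm, dist)
        expected = []
        for start in range(len(seq) - length + 1):
            p = brute_force_pvalue(pwm, 0.01, seq[start:start + length])
            if p < 0.01:
                klass = "significant" if p < 0.005 else "suboptimal"
                expected.append((start, p, klass))
        assert [(h.start, h.hit_class) for h in hits.hits] == \
               [(s, k) for s, _, k in expected]
        for hit, (_, p, _) in zip(hits.hits, expected):
            assert hit.pvalue == pytest.approx(p, abs=1e-9)

    def test_lower_alpha_never_more_hits(self, urich_pwm, urich_dist):
        seq = sd.synth_background(500, seed=4, composition=(0.15, 0.15, 0.15, 0.55))
        loose = ms.scan(seq, urich_pwm, urich_dist, alphas=(0.01, 0.05))
        tight = ms.scan(seq, urich_pwm, urich_dist, alphas=(0.001, 0.005))
        assert len(tight.hits) <= len(loose.hits)
        assert tight.n_significant <= loose.n_significant

    def test_insertion_outside_hits_preserves_count(self, urich_pwm, urich_dist):
        seq = sd.synth_background(200, seed=7)
        seq = seq[:50] + "TTTTTT" + seq[56:]
        base = ms.scan(seq, urich_pwm, urich_dist)
        # insert a neutral G-run far from every hit window
        edited = seq[:150] + "GGGGGGGG" + seq[150:]
        assert all(h.start + 6 <= 150 or h.start >= 150 for h in base.hits)
        again = ms.scan(edited, urich_pwm, urich_dist)
        assert len(again.hits) == len(base.hits)

    def test_merge_overlaps_keeps_best_per_cluster(self, urich_pwm, urich_dist):
        # one T-run: full 6/6 matches at 20-22 plus single-mismatch windows
        # at 19 and 23, all mutually overlapping
        seq = "G" * 20 + "TTTTTTTT" + "G" * 20
        full = ms.scan(seq, urich_pwm, urich_dist)
        merged = ms.scan(seq, urich_pwm, urich_dist, merge_overlaps=True)
        assert len(full.hits) == 5
        assert len(merged.hits) == 1
        assert merged.hits[0].score == max(h.score for h in full.hits)

    def test_granularity_halving_stable(self, urich_pwm):
        seq = sd.synth_background(400, seed=12, composition=(0.2, 0.2, 0.2, 0.4))
        coarse = ms.scan(seq, urich_pwm, ms.score_distribution(urich_pwm, 0.01))
        fine = ms.scan(seq, urich_pwm, ms.score_distribution(urich_pwm, 0.005))
        assert [(h.start, h.hit_class) for h in coarse.hits] == \
               [(h.start, h.hit_class) for h in fine.hits]


class TestDensity:
    @pytest.mark.parametrize("n,length,expected", [(6, 300, 20.0), (0, 300, 0.0), (5, 400, 12.5)])
    def test_sites_per_kilobase(self, n, length, expected, urich_pwm, urich_dist):
        seq = "G" * (length - 6 * n) + "TTTTTT" * n if n else "G" * length
        hits = ms.scan(seq, urich_pwm, urich_dist)
        # build the exact count via planted non-overlapping sites instead
        fake = ms.MotifHitSet("g", tuple(
            ms.MotifHit(i * 6, 10.0, 1e-4, "significant") for i in range(n)
        ), length)
        assert ms.site_density(fake) == pytest.approx(expected)

    def test_zero_length_region_is_error(self):
        with pytest.raises(ValueError):
            ms.site_density(ms.MotifHitSet("g", (), 0))

    def test_density_scales_inversely_with_length(self):
        h1 = ms.MotifHitSet("g", (ms.MotifHit(0, 1.0, 1e-4, "significant"),), 100)
        h2 = ms.MotifHitSet("g", (ms.MotifHit(0, 1.0, 1e-4, "significant"),), 200)
        assert ms.site_density(h1) == pytest.approx(2 * ms.site_density(h2))


class TestFrameRarityProfile:
    def test_homopolymer_word_identical_in_all_frames(self, weights):
        prof = ms.frame_rarity_profile("TTTTTT", "TTT", "TTT", weights)
        codon_sets = [set(prof[f]["codons"]) for f in range(3)]
        assert codon_sets[0] == codon_sets[1] == codon_sets[2] == {"TTT"}
        # same single codon in every frame, hence identical class sets
        assert len({frozenset(prof[f]["classes"]) for f in range(3)}) == 1

    def test_frame_shift_changes_codon_identity(self, weights):
        prof = ms.frame_rarity_profile("TTTGTT", "ACG", "ACG", weights)
        assert prof[0]["codons"] != prof[1]["codons"]

    def test_rare_decomposition_counted(self, weights):
        # build a hexamer from two family-minimum codons: frame 0 reports 2 rare
        from rarecode import codon_usage as cu
        rare_codons = [
            min(fam, key=lambda c: weights[c])
            for fam in (cu.SYNONYM_FAMILIES["F"], cu.SYNONYM_FAMILIES["K"])
        ]
        word = "".join(rare_codons)
        prof = ms.frame_rarity_profile(word, "ACG", "ACG", weights)
        assert prof[0]["n_rare"] == 2

    def test_insufficient_flank_names_frame(self, weights):
        with pytest.raises(ValueError, match="frame 2"):
            ms.frame_rarity_profile("TTTTTT", "G", "GG", weights)
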