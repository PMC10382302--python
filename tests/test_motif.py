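"""PWM information content, LLR scoring, exact score distributions,
scanning, and the strong-motif / isolation analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chromcooc.motif import (
    PWM,
    Background,
    cluster_representatives,
    fimo_binding_map,
    information_score,
    llr_score,
    motif_binding_map,
    peak_motif_score,
    read_fimo_tsv,
    read_meme,
    reverse_complement,
    scan_regions,
    score_distribution,
    score_peaks,
    select_representative,
    strong_motif_partition,
    write_meme,
)
from chromcooc.synth import simulate_motif_dataset

from conftest import make_network


def uniform_pwm(L, name="U"):
    return PWM.from_array(name, np.full((L, 4), 0.25))


def deterministic_pwm(word, name="D"):
    rows = []
    for b in word:
        row = [0.0] * 4
        row["ACGT".index(b)] = 1.0
        rows.append(row)
    return PWM.from_array(name, rows)


class TestInformationScore:
    def test_uniform_is_zero(self):
        assert information_score(uniform_pwm(5)) == pytest.approx(0.0)

    def test_deterministic_is_two_bits_per_column(self):
        assert information_score(deterministic_pwm("ACG")) == pytest.approx(6.0)

    def test_half_half_column_contributes_one_bit(self):
        pwm = PWM.from_array("H", [[0.5, 0.5, 0.0, 0.0]])
        assert information_score(pwm) == pytest.approx(1.0)

    def test_bounded_by_two_L(self):
        rng = np.random.default_rng(0)
        m = rng.dirichlet(np.ones(4), size=8)
        pwm = PWM.from_array("R", m)
        assert 0.0 <= information_score(pwm) <= 16.0


class TestRepresentative:
    def test_single_and_extremes(self):
        u, d = uniform_pwm(4), deterministic_pwm("ACGT")
        assert select_representative([u]) is u
        assert select_representative([u, d]) is d

    def test_argmax_of_hand_computed_scores(self):
        pwms = [
            PWM.from_array("a", [[0.5, 0.5, 0, 0]] * 2),      # 2 bits
            PWM.from_array("b", [[1, 0, 0, 0], [0.25] * 4]),  # 2 bits
            PWM.from_array("c", [[1, 0, 0, 0]] * 2),          # 4 bits
        ]
        assert select_representative(pwms).name == "c"
        # tie between a and b broken lexicographically
        assert select_representative(pwms[:2]).name == "a"

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            select_representative([])


class TestLLR:
    def test_consensus_under_uniform_background(self):
        pwm = deterministic_pwm("ACGT")
        # pseudocount shifts 2 bits/position by log2((1+eps)/(0.25+eps))
        assert llr_score("ACGT", pwm) == pytest.approx(8.0, abs=0.01)

    def test_background_pwm_scores_zero_everywhere(self):
        pwm = uniform_pwm(6)
        for word in ("AAAAAA", "ACGTAC", "TTTTTT"):
            assert llr_score(word, pwm) == pytest.approx(0.0, abs=1e-9)

    def test_equals_naive_position_sum(self):
        rng = np.random.default_rng(1)
        pwm = PWM.from_array("R", rng.dirichlet(np.ones(4), size=7))
        word = "GATTACA"
        q = pwm.log_odds()
        naive = sum(q[n, "ACGT".index(b)] for n, b in enumerate(word))
        assert llr_score(word, pwm) == pytest.approx(naive)

    def test_additivity_over_concatenated_blocks(self):
        rng = np.random.default_rng(2)
        a = PWM.from_array("a", rng.dirichlet(np.ones(4), size=3))
        b = PWM.from_array("b", rng.dirichlet(np.ones(4), size=4))
        ab = PWM.from_array("ab", np.vstack([a.array, b.array]))
        assert llr_score("ACGTGCA", ab) == pytest.approx(
            llr_score("ACG", a) + llr_score("TGCA", b)
        )

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            llr_score("ACNG", uniform_pwm(4))


class TestPeakScore:
    def test_single_consensus_occurrence(self):
        pwm = deterministic_pwm("ACGT")
        seq = "GGGG" + "ACGT" + "GGGG"
        assert peak_motif_score(seq, pwm) == pytest.approx(8.0, abs=0.01)

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(3)
        pwm = PWM.from_array("R", rng.dirichlet(np.ones(4), size=6))
        seq = "".join(rng.choice(list("ACGT"), size=60))
        assert peak_motif_score(seq, pwm) == pytest.approx(
            peak_motif_score(reverse_complement(seq), pwm)
        )

    def test_matches_window_brute_force(self):
        rng = np.random.default_rng(4)
        pwm = PWM.from_array("R", rng.dirichlet(np.ones(4), size=5))
        seq = "".join(rng.choice(list("ACGT"), size=40))
        best = max(
            llr_score(w, pwm)
            for s in (seq, reverse_complement(seq))
            for w in (s[i:i + 5] for i in range(len(s) - 4))
        )
        assert peak_motif_score(seq, pwm) == pytest.approx(best)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            peak_motif_score("ACG", uniform_pwm(5))


class TestScoreDistribution:
    def test_single_position_support(self):
        pwm = PWM.from_array("p", [[0.7, 0.1, 0.1, 0.1]])
        dist = score_distribution(pwm, bins=1000)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.count_nonzero(dist.pmf) <= 4

    @pytest.mark.parametrize("L", [3, 5, 6])
    def test_survival_matches_enumeration(self, L):
        """DP survival function sandwiches the exact brute-force one within
        the discretization granularity."""
        rng = np.random.default_rng(L)
        pwm = PWM.from_array("R", rng.dirichlet(np.full(4, 0.6), size=L))
        bg = Background()
        dist = score_distribution(pwm, bg, bins=2000)
        q = pwm.log_odds(bg)
        scores = np.array([
            sum(q[n, w[n]] for n in range(L))
            for w in itertools.product(range(4), repeat=L)
        ])
        probs = np.full(scores.size, 0.25 ** L)
        guard = L * dist.eps
        for t in np.quantile(scores, [0.01, 0.1, 0.5, 0.9, 0.99, 0.999]):
            exact = probs[scores >= t].sum()
            assert dist.sf(t - guard) + 1e-3 >= exact >= dist.sf(t + guard) - 1e-3

    def test_top_score_probability_lower_bound(self):
        rng = np.random.default_rng(9)
        pwm = PWM.from_array("R", rng.dirichlet(np.ones(4), size=4))
        dist = score_distribution(pwm)
        top = float(dist.support[np.nonzero(dist.pmf)[0][-1]])
        assert dist.sf(top) >= 0.25 ** 4 - 1e-12

    def test_threshold_monotone_in_p(self):
        pwm = deterministic_pwm("ACGTA")
        dist = score_distribution(pwm)
        assert dist.threshold(1e-4) >= dist.threshold(1e-2)


class TestScanning:
    def test_planted_consensus_single_hit(self):
        pwm = deterministic_pwm("ACGTACGT")
        seq = "GG" * 30 + "ACGTACGT" + "GG" * 30
        genome = {"chrT": seq}
        net = make_network([(0, 1)], length=len(seq), gap=10)
        regions = {0: net.regions[0].interval}
        hits = scan_regions(genome, regions, pwm, p_threshold=1e-4)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1 and fwd[0].offset == 60
        assert fwd[0].score_pvalue <= 1e-4

    def test_all_ambiguous_sequence_yields_no_hits(self):
        pwm = deterministic_pwm("ACGT")
        genome = {"chrT": "N" * 200}
        net = make_network([(0, 1)], length=200, gap=10)
        hits = scan_regions(genome, {0: net.regions[0].interval}, pwm)
        assert hits == []

    def test_agreement_with_exhaustive_scan(self):
        rng = np.random.default_rng(6)
        pwm = PWM.from_array("R", rng.dirichlet(np.full(4, 0.3), size=6))
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        genome = {"chrT": seq}
        from chromcooc.intervals import GenomicInterval

        hits = scan_regions(genome, {0: GenomicInterval("chrT", 0, 1000)},
                            pwm, p_threshold=1e-3)
        dist = score_distribution(pwm)
        thr = dist.threshold(1e-3)
        expected = set()
        for strand, s in (("+", seq), ("-", None)):
            for i in range(len(seq) - 5):
                w = seq[i:i + 6]
                scores = [llr_score(w, pwm),
                          llr_score(reverse_complement(w), pwm)]
                for strand_idx, sc in enumerate(scores):
                    if sc >= thr:
                        expected.add((i, "+-"[strand_idx]))
            break
        assert {(h.offset, h.strand) for h in hits} == expected

    def test_motif_binding_map(self):
        net = make_network([(0, 1)])
        from chromcooc.motif import MotifHit

        hits = {"M1": [MotifHit(0, 5, "+", 10.0, 1e-5),
                       MotifHit(0, 9, "-", 9.0, 5e-5)]}
        bm = motif_binding_map(hits, net)
        assert bm.bound["M1"] == {0}


class TestFimoReader:
    def test_roundtrip_and_threshold(self, tmp_path):
        p = tmp_path / "fimo.tsv"
        p.write_text(
            "motif_id\tsequence_name\tstart\tstop\tstrand\tscore\tp-value\n"
            "M1\tchrT\t6001\t6008\t+\t11.2\t1e-05\n"
            "M1\tchrT\t100\t107\t-\t8.0\t5e-03\n"
        )
        df = read_fimo_tsv(p)
        assert df.loc[0, "start"] == 6000  # converted to 0-based
        net = make_network([(0, 1)], length=1000, gap=5000)
        bm = fimo_binding_map(df, net, p_threshold=1e-4)
        assert bm.bound["M1"] == {1}  # second hit fails the threshold


class TestMemeIO:
    def test_write_read_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        pwms = [
            PWM.from_array("M1", rng.dirichlet(np.ones(4), size=6)),
            deterministic_pwm("ACGT", name="M2"),
        ]
        path = tmp_path / "motifs.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        assert [p.name for p in back] == ["M1", "M2"]
        np.testing.assert_allclose(back[0].array, pwms[0].array, atol=2e-5)

    def test_cluster_representatives(self, tmp_path):
        pwms = [uniform_pwm(4, "weak"), deterministic_pwm("ACGT", "strong")]
        reps = cluster_representatives(pwms, {"c1": ["weak", "strong"]})
        assert reps["c1"].name == "strong"
        with pytest.raises(ValueError):
            cluster_representatives(pwms, {"c2": ["missing"]})


class TestStrongMotifPartition:
    def _peaks(self, scores, isolated_flags, net):
        rows = []
        for k, (s, iso) in enumerate(zip(scores, isolated_flags)):
            rid = 2 if iso else 0  # region 2 is degree-0, region 0 has edges
            iv = net.regions[rid].interval
            rows.append(("F", iv.chrom, iv.start, iv.end, s))
        return pd.DataFrame(rows, columns=["factor", "chrom", "start", "end", "score"])

    def test_top_decile_threshold(self):
        net = make_network([(0, 1)])
        # add a lonely degree-0 region
        from chromcooc.network import InteractionNetwork, Region
        from chromcooc.intervals import GenomicInterval

        regions = dict(net.regions)
        regions[2] = Region(2, GenomicInterval("chrT", 50_000, 51_000))
        net = InteractionNetwork(regions, net.edges)
        peaks = self._peaks(range(1, 11), [True] * 5 + [False] * 5, net)
        out = strong_motif_partition(peaks, net).iloc[0]
        # scores 1..10: only the 10 passes the 90th percentile
        assert out.n_isolated == 5 and out.n_interacting == 5
        assert out.frac_strong_isolated == 0.0
        assert out.frac_strong_interacting == pytest.approx(0.2)

    def test_all_isolated_reports_nan_interacting(self):
        net = make_network([(0, 1)])
        from chromcooc.network import InteractionNetwork, Region
        from chromcooc.intervals import GenomicInterval

        regions = {2: Region(2, GenomicInterval("chrT", 0, 1000))}
        lonely = InteractionNetwork(regions, [])
        peaks = pd.DataFrame(
            [("F", "chrT", 0, 1000, s) for s in range(12)],
            columns=["factor", "chrom", "start", "end", "score"],
        )
        out = strong_motif_partition(peaks, lonely).iloc[0]
        assert out.n_interacting == 0 and np.isnan(out.frac_strong_interacting)

    def test_planted_direction_recovered(self):
        """Weaker motifs planted in interacting regions: the isolated
        strong-motif fraction must come out on top."""
        data = simulate_motif_dataset(p_iso=0.6, p_int=0.2, seed=5)
        scored = score_peaks(data.genome, data.peaks, {data.pwm.name: data.pwm})
        out = strong_motif_partition(scored, data.network).iloc[0]
        assert out.frac_strong_isolated > out.frac_strong_interacting
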