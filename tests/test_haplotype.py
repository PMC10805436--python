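"""EHH/iHS and the folded beta balancing-selection score."""

import math

import numpy as np
import pytest

from coevoscan import haplotype
from coevoscan.io import GeneticMap
from coevoscan.simulate import sim_balanced_cluster_panel, sim_sweep_panel
from conftest import make_panel


class TestEhh:
    def test_equals_one_at_core(self):
        panel = make_panel([[1, 0, 1], [1, 1, 0], [0, 0, 1], [0, 1, 1]])
        curve = haplotype.ehh(panel, core=1, allele=1, side="right")
        assert curve.values[0] == 1.0

    def test_identical_carriers_stay_at_one(self):
        panel = make_panel([[1, 0, 1], [1, 0, 1], [0, 1, 0], [0, 0, 1]])
        curve = haplotype.ehh(panel, core=0, allele=1, side="right")
        assert np.all(curve.values == 1.0)

    def test_four_carriers_split_two_and_two(self):
        # C(2,2)+C(2,2) over C(4,2) = 2/6 = 1/3 at the first site out
        panel = make_panel([
            [1, 0], [1, 0], [1, 1], [1, 1], [0, 0], [0, 1]])
        curve = haplotype.ehh(panel, core=0, allele=1, side="right")
        assert curve.values[1] == pytest.approx(1 / 3)

    def test_monotone_and_bounded(self, rng):
        for _ in range(20):
            haps = (rng.random((12, 15)) < 0.5).astype(np.uint8)
            haps[:, 7] = np.repeat([0, 1], 6)  # guarantee carriers both sides
            panel = make_panel(haps)
            for allele in (0, 1):
                for side in ("left", "right"):
                    c = haplotype.ehh(panel, 7, allele, side)
                    assert np.all(np.diff(c.values) <= 1e-12)
                    assert np.all((c.values >= 0) & (c.values <= 1))

    def test_too_few_carriers(self):
        panel = make_panel([[1, 0], [0, 0], [0, 1]])
        with pytest.raises(ValueError):
            haplotype.ehh(panel, core=0, allele=1, side="right")


class TestIhs:
    def test_label_swap_negates_raw_score(self):
        panel, truth = sim_sweep_panel(n_chrom=60, n_sites=101, seed=9)
        core = truth.params["core_index"]
        direct = haplotype.ihs(panel, None, core)
        flipped = panel.take_sites(range(panel.n_sites))
        flipped.haplotypes = flipped.haplotypes.copy()
        flipped.haplotypes[:, core] = 1 - flipped.haplotypes[:, core]
        mirror = haplotype.ihs(flipped, None, core)
        assert direct.status == "ok"
        assert mirror.ihs_raw == pytest.approx(-direct.ihs_raw, abs=1e-12)

    def test_sweep_core_scores_negative(self):
        vals = []
        for seed in range(8):
            panel, truth = sim_sweep_panel(n_chrom=100, seed=seed)
            sc = haplotype.ihs(panel, None, truth.params["core_index"])
            assert sc.status == "ok"
            vals.append(sc.ihs_raw)
        assert np.mean(vals) < 0
        assert max(vals) < 0

    def test_low_maf_core_skipped(self):
        panel, _ = sim_sweep_panel(n_chrom=100, seed=1)
        panel.haplotypes[:, 50] = 0
        panel.haplotypes[:4, 50] = 1  # derived_freq 0.04 < 0.05
        sc = haplotype.ihs(panel, None, 50)
        assert sc.status == "maf"

    def test_edge_core_skipped_not_truncated(self):
        # identical derived carriers: EHH never decays, so the core is skipped
        haps = np.zeros((20, 11), dtype=np.uint8)
        haps[:10, :] = 1
        panel = make_panel(haps)
        sc = haplotype.ihs(panel, None, 5)
        assert sc.status == "edge"

    def test_uses_genetic_map_distances(self):
        panel, truth = sim_sweep_panel(n_chrom=80, n_sites=101, seed=3)
        core = truth.params["core_index"]
        pos = panel.positions
        gmap = GeneticMap({"7": [(int(pos[0]), 0.0), (int(pos[-1]), 1.0)]})
        with_map = haplotype.ihs(panel, gmap, core)
        without = haplotype.ihs(panel, None, core)
        # both integrate the same curves over different distance scales;
        # the log-ratio differs once the map is non-uniform in cM/bp
        assert with_map.status == without.status == "ok"


class TestStandardize:
    def test_bins_have_mean_zero_sd_one(self, rng):
        scores = []
        for i in range(400):
            q = float(rng.uniform(0.05, 0.95))
            s = haplotype.IhsScore(i, i + 1, q)
            s.ihs_raw = float(rng.normal(q, 1.0))  # frequency-dependent mean
            scores.append(s)
        haplotype.standardize_ihs(scores, n_bins=5)
        # group scores by realized standardization output and check moments
        z = np.array([s.ihs_std for s in scores])
        assert abs(z.mean()) < 0.2 and np.isfinite(z).all()

    def test_single_bin_two_scores(self):
        scores = []
        for i, raw in enumerate((-1.0, 1.0)):
            s = haplotype.IhsScore(i, i + 1, 0.5)
            s.ihs_raw = raw
            scores.append(s)
        haplotype.standardize_ihs(scores, n_bins=1, min_bin=1)
        assert [s.ihs_std for s in scores] == pytest.approx([-1.0, 1.0])

    def test_small_bins_merged(self, rng):
        # 25 scores at low frequency, 5 at high: the small bin must merge
        scores = []
        for i in range(25):
            s = haplotype.IhsScore(i, i + 1, 0.10)
            s.ihs_raw = float(rng.normal())
            scores.append(s)
        for i in range(5):
            s = haplotype.IhsScore(100 + i, 101 + i, 0.90)
            s.ihs_raw = float(rng.normal())
            scores.append(s)
        haplotype.standardize_ihs(scores, n_bins=10, min_bin=20)
        z = np.array([s.ihs_std for s in scores])
        assert abs(z.mean()) < 1e-9 and z.std() == pytest.approx(1.0, abs=1e-9)


def beta_oracle(folded, pos, core, n, half_width=1000, p=2.0):
    """Spreadsheet-style direct transcription of the beta formulas."""
    f_c = folded[core]
    num = 0.0
    for i in range(len(folded)):
        if i != core and abs(pos[i] - pos[core]) <= half_width:
            num += (1 - abs(folded[i] - f_c) / 0.5) ** p
    denom = 0.0
    s_count = 0
    for k in range(1, n):
        fk = min(k / n, 1 - k / n)
        denom += ((1 - abs(fk - f_c) / 0.5) ** p) / k
    for i in range(len(folded)):
        if i != core and abs(pos[i] - pos[core]) <= half_width:
            s_count += 1
    a_n = sum(1.0 / k for k in range(1, n))
    return num / denom - s_count / a_n


class TestBeta:
    def test_empty_window_gives_zero(self):
        b = haplotype.beta_score(np.array([0.4]), np.array([100]), 0, n=10)
        assert b.theta_beta == b.theta_w == b.beta == 0.0

    def test_matching_frequency_weight_is_one(self):
        b = haplotype.beta_score(np.array([0.4, 0.4]), np.array([100, 200]), 0, n=10)
        # single window SNP with w=1: theta_beta = 1/denominator
        oracle = beta_oracle([0.4, 0.4], [100, 200], 0, 10)
        assert b.beta == pytest.approx(oracle, abs=1e-12)

    def test_three_snp_window_matches_direct_transcription(self):
        folded = np.array([0.4, 0.4, 0.1, 0.3])
        pos = np.array([500, 600, 700, 1200])
        b = haplotype.beta_score(folded, pos, 0, n=10)
        assert b.beta == pytest.approx(beta_oracle(folded, pos, 0, 10), abs=1e-12)

    def test_monomorphic_core_rejected(self):
        with pytest.raises(ValueError):
            haplotype.beta_score(np.array([0.0, 0.2]), np.array([1, 2]), 0, n=10)

    def test_invariant_to_unfolding(self, rng):
        # folding is applied upstream: beta_scan folds the derived frequency,
        # so flipping 0/1 coding at any window site leaves beta unchanged
        panel, truth = sim_balanced_cluster_panel(seed=4)
        core = truth.params["core_index"]
        b1 = haplotype.beta_scan(panel)
        flipped = panel.take_sites(range(panel.n_sites))
        flipped.haplotypes = flipped.haplotypes.copy()
        j = (core + 1) % panel.n_sites
        flipped.haplotypes[:, j] = 1 - flipped.haplotypes[:, j]
        b2 = haplotype.beta_scan(flipped)
        s1 = {b.pos: b.beta for b in b1}
        s2 = {b.pos: b.beta for b in b2}
        for pos in set(s1) & set(s2) - {panel.sites[j].pos}:
            assert s2[pos] == pytest.approx(s1[pos], abs=1e-12)

    def test_planted_cluster_beats_neutral(self):
        planted, neutral = [], []
        for seed in range(40):
            p, t = sim_balanced_cluster_panel(cluster=True, seed=seed)
            planted.append(haplotype.beta_score(
                np.minimum(p.derived_freq, 1 - p.derived_freq), p.positions,
                t.params["core_index"], p.n_haplotypes).beta)
            p, t = sim_balanced_cluster_panel(cluster=False, seed=1000 + seed)
            f = np.minimum(p.derived_freq, 1 - p.derived_freq)
            if f[t.params["core_index"]] > 0:
                neutral.append(haplotype.beta_score(
                    f, p.positions, t.params["core_index"], p.n_haplotypes).beta)
        assert np.mean(planted) > np.mean(neutral)


class TestTopFraction:
    def test_linear_interpolation_threshold_and_strict_flags(self):
        thr, flags = haplotype.empirical_top_fraction(np.arange(1.0, 201.0), 0.01)
        assert thr == pytest.approx(198.01)
        assert np.nonzero(flags)[0].tolist() == [198, 199]  # values 199 and 200

    def test_all_equal_flags_nothing(self):
        thr, flags = haplotype.empirical_top_fraction(np.full(500, 1.5), 0.01)
        assert not flags.any()

    def test_iid_flag_count_bounded(self, rng):
        _, flags = haplotype.empirical_top_fraction(rng.normal(size=1000), 0.01)
        assert flags.sum() <= 10

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            haplotype.empirical_top_fraction(np.arange(50.0), 0.01)
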