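"""Hypergeometric/binomial enrichment machinery against brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import ripscan as rs
from ripscan.stats import flank_kr_background, proteome_kr_background


def enumerate_upper_tail(k, n, K, N):
    """Exhaustive oracle: fraction of n-subsets of an N-urn (K successes)
    containing at least k successes."""
    urn = [1] * K + [0] * (N - K)
    total = hits = 0
    for combo in itertools.combinations(range(N), n):
        total += 1
        if sum(urn[i] for i in combo) >= k:
            hits += 1
    return hits / total


class TestHypergeom:
    def test_k_zero_is_one(self):
        assert rs.hypergeom_upper_tail(0, 5, 3, 10) == 1.0

    def test_all_successes_frozen_value(self):
        # drawing all 5 successes out of 10: exactly 1 of C(10,5)=252 draws
        assert rs.hypergeom_upper_tail(5, 5, 5, 10) == pytest.approx(1 / 252)

    @pytest.mark.parametrize("N", [6, 9, 12])
    def test_agrees_with_enumeration(self, N):
        for K in range(N + 1):
            for n in range(1, N + 1):
                for k in range(0, min(n, K) + 1):
                    expect = enumerate_upper_tail(k, n, K, N)
                    got = rs.hypergeom_upper_tail(k, n, K, N)
                    assert got == pytest.approx(expect, abs=1e-12), (k, n, K, N)

    def test_monotone_in_k(self):
        vals = [rs.hypergeom_upper_tail(k, 10, 30, 100) for k in range(11)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_pmf_normalization_small_configs(self):
        for N in range(2, 10):
            for K in range(N + 1):
                for n in range(1, N + 1):
                    kmax = min(n, K)
                    total = sum(
                        rs.hypergeom_upper_tail(k, n, K, N)
                        - (rs.hypergeom_upper_tail(k + 1, n, K, N)
                           if k + 1 <= kmax else 0.0)
                        for k in range(kmax + 1))
                    assert total == pytest.approx(1.0, abs=1e-10)

    def test_binomial_limit_large_background(self):
        # N -> infinity at fixed K/N: the tail approaches the binomial tail
        N, frac, n, k = 10**7, 0.3, 40, 18
        hg = rs.hypergeom_upper_tail(k, n, int(N * frac), N)
        bi = float(sps.binom.sf(k - 1, n, frac))
        assert hg == pytest.approx(bi, abs=1e-6)

    def test_bound_violations_rejected(self):
        with pytest.raises(ValueError):
            rs.hypergeom_upper_tail(6, 5, 5, 10)
        with pytest.raises(ValueError):
            rs.hypergeom_upper_tail(2, 5, 1, 10)


class TestFoldAndBonferroni:
    def test_reported_fold_values(self):
        assert rs.fold_enrichment(38, 57, 0.50) == pytest.approx(4 / 3, abs=5e-3)
        assert rs.fold_enrichment(38, 57, 0.45) == pytest.approx(1.48, abs=5e-3)
        assert rs.fold_enrichment(0, 57, 0.5) == 0.0
        assert rs.fold_enrichment(10, 20, 0.5) == 1.0

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            rs.fold_enrichment(3, 10, 0.0)

    def test_bonferroni_scale_cap_order(self):
        assert rs.bonferroni([0.01], 5) == [0.05]
        assert rs.bonferroni([0.5], 10) == [1.0]
        ps = [0.3, 0.001, 0.02]
        adj = rs.bonferroni(ps, 4)
        assert adj == [1.0, 0.004, 0.08]
        assert [x for _, x in sorted(zip(ps, adj))] == sorted(adj)

    def test_family_too_small_rejected(self):
        with pytest.raises(ValueError):
            rs.bonferroni([0.1, 0.2], 1)

    def test_adjusted_rejections_never_exceed_raw(self, rng):
        ps = rng.random(50)
        adj = rs.bonferroni(list(ps), 50)
        assert sum(a < 0.05 for a in adj) <= sum(p < 0.05 for p in ps)


class TestProteinLevel:
    @staticmethod
    def _sample_with_feature(n_pos, n_total):
        recs = []
        for i in range(n_total):
            seq = "A" * 30 + ("RRIL" if i < n_pos else "AAAA") + "A" * 30
            recs.append((rs.ProteinRecord(id=f"S{i}", sequence=seq), None))
        return recs

    @staticmethod
    def _background(n_pos, n_total):
        recs = []
        for i in range(n_total):
            seq = "A" * 30 + ("RRIL" if i < n_pos else "AAAA") + "A" * 30
            recs.append(rs.ProteinRecord(id=f"B{i}", sequence=seq))
        return rs.BackgroundSet(label="proteome", records=recs)

    @staticmethod
    def _feature(rec, ann):
        return "RRIL" in rec.sequence

    def test_constructed_counts_echoed_and_analytic_tail(self):
        sample = self._sample_with_feature(50, 50)
        background = self._background(50, 1000)
        res = rs.protein_level_enrichment(sample, background, self._feature,
                                          feature_name="RRIL")
        assert (res.k, res.n, res.K, res.N) == (50, 50, 50, 1000)
        assert res.fold == pytest.approx((50 / 50) / (50 / 1000))  # 20x
        assert res.p_raw < 1e-20

    def test_feature_everywhere_uninformative(self):
        sample = self._sample_with_feature(10, 10)
        background = self._background(500, 500)
        res = rs.protein_level_enrichment(sample, background, self._feature)
        assert res.fold == pytest.approx(1.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_proportion_mode_uses_binomial(self):
        sample = self._sample_with_feature(38, 57)
        res = rs.protein_level_enrichment(sample, 0.50, self._feature,
                                          feature_name="RRIL")
        assert res.mode == "binomial-proportion"
        assert res.fold == pytest.approx(4 / 3, abs=5e-3)
        assert res.p_raw == pytest.approx(float(sps.binom.sf(37, 57, 0.5)))

    def test_tmd_window_against_tmdless_background_rejected(self):
        sample = self._sample_with_feature(5, 5)
        background = self._background(10, 10)
        with pytest.raises(ValueError, match="TMD"):
            rs.protein_level_enrichment(sample, background, self._feature,
                                        window_label="tmd")


class TestResidueLevel:
    @staticmethod
    def _profile(seq, tffd, tmd):
        rec = rs.ProteinRecord(id="P1", sequence=seq)
        ann = rs.DomainAnnotation(
            protein_id="P1", tffd=tffd,
            tmds=[rs.TMDSpan(start=tmd[0], end=tmd[1])])
        return rs.charge_profile(rec, ann)

    def test_window_tail_matches_enumeration_scaled(self):
        # 6 K/R in a 15-residue window vs a tiny enumerable background
        k, n, K, N = 4, 6, 5, 12
        expect = enumerate_upper_tail(k, n, K, N)
        got = rs.hypergeom_upper_tail(k, n, K, N)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_no_charge_gives_p_one(self):
        seq = "A" * 60 + "L" * 21 + "A" * 60
        prof = self._profile(seq, (1, 30), (61, 81))
        res = rs.residue_level_enrichment(prof, 20, background_kr=100,
                                          background_total=1000)
        assert res.k == 0 and res.p_raw == 1.0

    def test_empty_window_skipped_with_reason(self):
        seq = "K" * 200
        prof = self._profile(seq, (50, 100), (60, 80))
        res = rs.residue_level_enrichment(prof, 20, background_kr=10,
                                          background_total=100)
        assert res.skipped is not None and res.p_adjusted == 1.0

    def test_planted_window_is_most_significant(self, rng):
        """With K/R planted into the 10-residue flank, the 10-residue
        window should usually give the smallest p among (5, 10, 15, 20)."""
        spec = rs.SyntheticSpec(n_proteins=1, charge_plan=(6, 10),
                                position_class_probs={"C": 1.0})
        wins = []
        for rep in range(100):
            recs, anns, _ = rs.generate_cohort(spec, seed=1000 + rep)
            prof = rs.charge_profile(recs[0], anns[0])
            ps = {k: rs.residue_level_enrichment(
                      prof, k, background_kr=100, background_total=1000).p_raw
                  for k in (5, 10, 15, 20)}
            wins.append(min(ps, key=ps.get) == 10)
        assert np.mean(wins) >= 0.9


class TestBackgroundScopes:
    def test_flank_background_counts(self):
        seq = "K" * 5 + "L" * 20 + "R" * 5
        rec = rs.ProteinRecord(id="M1", sequence=seq)
        bg = rs.BackgroundSet(label="membrane_proteome", records=[rec],
                              tmds={"M1": [rs.TMDSpan(start=6, end=25)]})
        kr, total = flank_kr_background(bg, k=5)
        assert (kr, total) == (10, 10)

    def test_proteome_background_counts(self):
        recs = [rs.ProteinRecord(id="P1", sequence="KKRA"),
                rs.ProteinRecord(id="P2", sequence="AAAA")]
        bg = rs.BackgroundSet(label="proteome", records=recs)
        assert proteome_kr_background(bg) == (3, 8)
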