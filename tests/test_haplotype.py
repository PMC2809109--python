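"""EM haplotype inference and case-control haplotype association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from priorihap.haplotype import (
    MAX_WINDOW,
    em_haplotype_freqs,
    haplotype_assoc,
    window_scan,
)

from conftest import make_genotypes, make_phenos
from _oracles import oracle_freqs_for_window


def make_markers(marker_ids, minor="A", major="G"):
    a1, a2 = sorted([minor, major])
    return pd.DataFrame(
        {
            "marker_id": list(marker_ids),
            "chromosome": "1",
            "position_bp": [1 + i * 1000 for i in range(len(marker_ids))],
            "allele1": a1,
            "allele2": a2,
            "minor_allele": minor,
        }
    )


def _em(dosage, **kw):
    G = make_genotypes(dosage)
    return em_haplotype_freqs(G, G.marker_ids, make_markers(G.marker_ids), **kw)


class TestEM:
    def test_single_marker_half_half(self):
        # 25/50/25 genotype counts: minor-allele frequency exactly 0.5
        dosage = np.array([0.0] * 25 + [1.0] * 50 + [2.0] * 25)[:, None]
        em = _em(dosage)
        f = dict(zip(em.haplotype_strings, em.state.frequencies))
        assert f["A"] == pytest.approx(0.5, abs=1e-9)
        assert f["G"] == pytest.approx(0.5, abs=1e-9)
        assert em.state.converged

    def test_complete_homozygous_data_is_direct_counting(self):
        # no heterozygotes, no missing: haplotypes observed directly
        dosage = np.array(
            [[2.0, 2.0]] * 6 + [[0.0, 0.0]] * 10 + [[2.0, 0.0]] * 4
        )
        em = _em(dosage)
        f = dict(zip(em.haplotype_strings, em.state.frequencies))
        assert f["AA"] == pytest.approx(12 / 40, abs=1e-12)
        assert f["GG"] == pytest.approx(20 / 40, abs=1e-12)
        assert f["AG"] == pytest.approx(8 / 40, abs=1e-12)

    def test_double_het_resolved_by_homozygote_evidence(self):
        # 30 AA/AA + 30 GG/GG + 40 double het: the only assignment giving
        # the homozygote patterns positive mass puts the double hets in
        # cis, so the MLE is (0.5, 0.5, 0, 0)
        dosage = np.array(
            [[2.0, 2.0]] * 30 + [[0.0, 0.0]] * 30 + [[1.0, 1.0]] * 40
        )
        em = _em(dosage)
        f = dict(zip(em.haplotype_strings, em.state.frequencies))
        assert f["AA"] == pytest.approx(0.5, abs=1e-3)
        assert f["GG"] == pytest.approx(0.5, abs=1e-3)
        assert f.get("AG", 0.0) == pytest.approx(0.0, abs=1e-3)
        assert f.get("GA", 0.0) == pytest.approx(0.0, abs=1e-3)

    def test_frequencies_simplex_and_posterior_rows_sum_to_two(self):
        rng = np.random.default_rng(97)
        dosage = rng.integers(0, 3, size=(60, 3)).astype(float)
        dosage[rng.random(dosage.shape) < 0.05] = np.nan
        em = _em(dosage)
        f = em.state.frequencies
        assert (f >= -1e-12).all()
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        assert em.expected_counts.sum(axis=1) == pytest.approx(
            np.full(len(em.used_individual_ids), 2.0), abs=1e-9
        )

    def test_matches_grid_search_oracle(self):
        # small instances where a dense lattice search is feasible
        rng = np.random.default_rng(101)
        for rep in range(3):
            # draws from a 2-marker population with three haplotypes
            haps = np.array([0b00, 0b01, 0b11])
            probs = np.array([0.5, 0.3, 0.2])
            pick = rng.choice(3, size=(50, 2), p=probs)
            h = haps[pick]
            dosage = (
                ((h[:, 0][:, None] >> np.arange(1, -1, -1)) & 1)
                + ((h[:, 1][:, None] >> np.arange(1, -1, -1)) & 1)
            ).astype(float)
            if rep == 2:
                dosage[rng.random(dosage.shape) < 0.05] = np.nan
            em = _em(dosage)
            universe, f_oracle = oracle_freqs_for_window(dosage)
            assert np.array_equal(universe, em.haplotype_codes)
            tv = 0.5 * np.abs(f_oracle - em.state.frequencies).sum()
            assert tv < 1e-3

    def test_majority_missing_individual_excluded(self):
        dosage = np.array([[1.0, 1.0, 0.0]] * 10 + [[np.nan, np.nan, 0.0]])
        em = _em(dosage)
        assert len(em.used_individual_ids) == 10
        # missing at exactly half stays in
        dosage2 = np.array([[1.0, 1.0]] * 10 + [[np.nan, 1.0]])
        em2 = _em(dosage2)
        assert len(em2.used_individual_ids) == 11

    def test_window_width_limits(self):
        dosage = np.zeros((4, MAX_WINDOW + 1))
        G = make_genotypes(dosage)
        with pytest.raises(ValueError, match="window width"):
            em_haplotype_freqs(G, G.marker_ids, make_markers(G.marker_ids))


class TestAssoc:
    def _unambiguous_em(self, case_carrier_homs, n_case, ctrl_carrier_homs, n_ctrl):
        """Single-marker cohort of homozygotes only: counts are exact."""
        dosage = np.array(
            [2.0] * case_carrier_homs + [0.0] * (n_case - case_carrier_homs)
            + [2.0] * ctrl_carrier_homs + [0.0] * (n_ctrl - ctrl_carrier_homs)
        )[:, None]
        em = _em(dosage)
        phenos = make_phenos(["case"] * n_case + ["control"] * n_ctrl)
        return em, phenos

    def test_closed_form_two_by_two(self):
        # haplotype chromosome counts a=20 b=116 / c=60 d=1600
        em, phenos = self._unambiguous_em(10, 68, 30, 830)
        res = haplotype_assoc(em, phenos, pool_threshold=0.0)
        row = res.table.set_index("haplotype").loc["A"]
        a, b, c, d = 20.0, 116.0, 60.0, 1600.0
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert row["case_count"] == pytest.approx(a, abs=1e-9)
        assert row["control_count"] == pytest.approx(c, abs=1e-9)
        assert row["chi2"] == pytest.approx(chi2, rel=1e-12)
        assert row["p"] == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)
        assert row["odds_ratio"] == pytest.approx((a * d) / (b * c), rel=1e-12)
        assert row["case_odds"] == pytest.approx((20 / 136) / (1 - 20 / 136), rel=1e-12)

    def test_single_marker_equals_allelic_chi2_with_hets(self):
        # with heterozygotes the single-marker EM posterior is still exact
        dosage = np.array(
            [2.0] * 5 + [1.0] * 20 + [0.0] * 43  # cases: 30 minor alleles
            + [2.0] * 10 + [1.0] * 60 + [0.0] * 760  # controls: 80
        )[:, None]
        em = _em(dosage)
        phenos = make_phenos(["case"] * 68 + ["control"] * 830)
        row = haplotype_assoc(em, phenos, pool_threshold=0.0).table.set_index(
            "haplotype"
        ).loc["A"]
        table = np.array([[30, 136 - 30], [80, 1660 - 80]], dtype=float)
        chi2_ref = stats.chi2_contingency(table, correction=False)[0]
        assert row["chi2"] == pytest.approx(chi2_ref, rel=1e-9)

    def test_haldane_correction_on_empty_cell(self):
        em, phenos = self._unambiguous_em(10, 68, 0, 830)
        row = haplotype_assoc(em, phenos, pool_threshold=0.0).table.set_index(
            "haplotype"
        ).loc["A"]
        assert np.isfinite(row["odds_ratio"]) and row["odds_ratio"] > 1
        assert np.isfinite(row["ci_low"]) and np.isfinite(row["ci_high"])
        expected_or = (20.5 * 1660.5) / (116.5 * 0.5)
        assert row["odds_ratio"] == pytest.approx(expected_or, rel=1e-12)

    def test_rare_haplotypes_pooled(self):
        # two-marker window where one haplotype sits below 1%
        dosage = np.array(
            [[2.0, 0.0]] * 99 + [[0.0, 2.0]] * 100 + [[2.0, 2.0]] * 1
        )
        em = _em(dosage)
        phenos = make_phenos(["case"] * 100 + ["control"] * 100)
        res = haplotype_assoc(em, phenos, pool_threshold=0.01)
        assert "pooled_rare" in set(res.table["haplotype"])
        pooled = res.table.set_index("haplotype").loc["pooled_rare"]
        assert bool(pooled["pooled_flag"])
        # AA appears only in the 2 double-homozygote individuals: freq 1%
        assert "AA" not in set(res.table["haplotype"])

    def test_null_window_large_p(self):
        rng = np.random.default_rng(103)
        dosage = rng.binomial(2, 0.3, size=(400, 2)).astype(float)
        em = _em(dosage)
        phenos = make_phenos(
            rng.permutation(["case"] * 200 + ["control"] * 200).tolist()
        )
        res = haplotype_assoc(em, phenos)
        # no planted effect: smallest p should not be extreme
        assert res.min_p > 1e-4


class TestWindowScan:
    def test_recovers_planted_risk_haplotype(self, small_cohort):
        G, phenos, markers, truth = small_cohort
        anchor = truth.risk_block_marker_ids[:4]
        scan = window_scan(
            G, markers, phenos, anchor, min_width=2, max_width=4
        )
        assert scan.best is not None
        assert scan.best.min_p < 1e-4
        # the best window lies in the risk block
        assert set(scan.best.window_marker_ids) <= set(truth.risk_block_marker_ids)

    def test_windows_respect_anchor_and_widths(self, small_cohort):
        G, phenos, markers, truth = small_cohort
        anchor = truth.risk_block_marker_ids[2:5]
        scan = window_scan(G, markers, phenos, anchor, min_width=2, max_width=3)
        anchor_set = set(anchor)
        for r in scan.results:
            assert 2 <= len(r.window_marker_ids) <= 3
            assert anchor_set & set(r.window_marker_ids)
            # contiguity in G's marker order
            idx = [G.marker_ids.index(m) for m in r.window_marker_ids]
            assert idx == list(range(idx[0], idx[0] + len(idx)))

    def test_empty_width_range(self, small_cohort):
        G, phenos, markers, truth = small_cohort
        scan = window_scan(
            G, markers, phenos, truth.risk_block_marker_ids, min_width=5, max_width=4
        )
        assert scan.results == [] and scan.best is None

    def test_anchor_smaller_than_min_width_rejected(self, small_cohort):
        G, phenos, markers, truth = small_cohort
        with pytest.raises(ValueError, match="anchor"):
            window_scan(
                G, markers, phenos, truth.risk_block_marker_ids[:1],
                min_width=2, max_width=3,
            )
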