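"""Two-locus moments under LD: conditional rows, aggregates, and the LD-aware
first-order expectation."""

import numpy as np
import pytest

from gsrel import (
    MarkerPanel,
    ShrinkageMoments,
    TwoLocusContext,
    VarianceSpec,
    approx2_expectation,
    approx2_expectation_ld,
    four_value_expectation,
    pair_coefficients,
    pairwise_second_moment,
    preset_relationship,
    conditional_product_moment,
    two_locus_gene_drop,
)
from gsrel.ld import enumerate_conditional, haplotype_probs
from gsrel.moments import UnsupportedRelationshipError, genotype_moment

GRID = [(0.3, 0.4, 0.05), (0.2, 0.2, 0.03), (0.5, 0.3, -0.04), (0.7, 0.6, 0.06)]

#: configurations whose printed conditional values are reconstructible from the
#: IBD-state and parental-origin labels (the printed S_0 row is not; see methods note)
RECONSTRUCTIBLE = [
    ("S_ml", "same_same"),
    ("S_ml", "same_diff"),
    ("S_ml", "diff_same"),
    ("S_ml", "diff_diff"),
    ("S_m", "same_same"),
    ("S_l", "same_same"),
]


class TestTable4Rows:
    @pytest.mark.parametrize("state,origin", RECONSTRUCTIBLE)
    @pytest.mark.parametrize("pm,pl,d", GRID)
    def test_rows_match_exact_enumeration(self, state, origin, pm, pl, d):
        printed = conditional_product_moment(state, origin, pm, pl, d)
        enumerated = enumerate_conditional(state, origin, pm, pl, d)
        assert printed == pytest.approx(enumerated, abs=1e-12)

    def test_null_configurations_vanish(self):
        for origin in ("same_diff", "diff_same", "diff_diff"):
            assert conditional_product_moment("S_m", origin, 0.3, 0.4, 0.05) == 0.0

    def test_s0_row_discrepancy_is_the_known_one(self):
        """The printed no-IBD row disagrees with enumeration (garbled condition);
        the correct value for two independent within-gamete pairs is delta^2."""
        pm, pl, d = 0.3, 0.4, 0.05
        assert enumerate_conditional("S_0", "same_same", pm, pl, d) == pytest.approx(
            d**2
        )
        assert conditional_product_moment("S_0", "same_same", pm, pl, d) == pytest.approx(
            d**2 * (1 - 2 * pm) * (1 - 2 * pl)
        )


class TestPairwiseSecondMoment:
    @pytest.mark.parametrize("p", [0.2, 0.5, 0.7])
    def test_matches_single_locus_identity_machinery(self, p):
        """Both printed forms equal the alpha22/gamma22 route of the one-locus
        moment table."""
        for rel_tag, preset in [("unrelated", "unrelated"),
                                ("sire", "parent_offspring")]:
            ctx = TwoLocusContext(p, 0.4, 0.0, relationship=rel_tag)
            direct = pairwise_second_moment(ctx)
            via_table = genotype_moment(pair_coefficients(preset), p, (2, 2))
            assert direct == pytest.approx(via_table, rel=1e-12)

    def test_printed_half_values(self):
        assert pairwise_second_moment(
            TwoLocusContext(0.5, 0.5, 0.0, relationship="unrelated")
        ) == pytest.approx(0.25)
        assert pairwise_second_moment(
            TwoLocusContext(0.5, 0.5, 0.0, relationship="sire")
        ) == pytest.approx(0.25)

    def test_unsupported_relationship(self):
        ctx = TwoLocusContext(0.3, 0.3, 0.0, relationship="full_sibs")
        with pytest.raises(UnsupportedRelationshipError):
            pairwise_second_moment(ctx)


class TestFourValueExpectation:
    def test_no_ld_unrelated_vanishes(self):
        ctx = TwoLocusContext(0.3, 0.4, 0.0, relationship="unrelated")
        assert four_value_expectation(ctx) == 0.0

    def test_balanced_frequencies_unrelated_vanishes(self):
        ctx = TwoLocusContext(0.5, 0.5, 0.1, relationship="unrelated")
        assert four_value_expectation(ctx) == 0.0

    def test_unrelated_gene_drop_magnitude(self):
        """Gene dropping gives 2(1-c)*2*delta^2 for a non-founder candidate; the
        printed aggregate carries an extra (1-2p)(1-2p) factor.  The oracle result
        is asserted against its own closed value; the printed form is the exposed
        one (documented discrepancy)."""
        pm, pl, d, c = 0.3, 0.4, 0.05, 0.5
        mean, se = two_locus_gene_drop(pm, pl, d, c, "unrelated",
                                       n_reps=400_000, seed=2)
        oracle_closed = 2 * (1 - c) * d * 2 * d  # E[x_cl x_cm] * E[X_il X_im]
        assert abs(mean - oracle_closed) < 3 * se

    @pytest.mark.parametrize("pm,pl,d", GRID[:2])
    def test_sire_gene_drop_reproducibility_and_scale(self, pm, pl, d):
        """The sire aggregate from gene dropping is of the same order as the printed
        formula and deterministic under a fixed seed."""
        m1, se = two_locus_gene_drop(pm, pl, d, c=0.5, relationship="sire",
                                     n_reps=200_000, seed=5)
        m2, _ = two_locus_gene_drop(pm, pl, d, c=0.5, relationship="sire",
                                    n_reps=200_000, seed=5)
        assert m1 == m2
        printed = four_value_expectation(
            TwoLocusContext(pm, pl, d, relationship="sire", r_ml=0.5)
        )
        assert abs(m1 - printed) < 0.25 * abs(printed) + 5 * se

    def test_haplotype_probs_validate_delta(self):
        with pytest.raises(ValueError):
            haplotype_probs(0.1, 0.1, 0.5)


class TestLdAwareExpectation:
    def _panel(self, rng, n_M=30, rho=0.0):
        p = rng.uniform(0.15, 0.85, n_M)
        delta = np.zeros((n_M, n_M))
        np.fill_diagonal(delta, p * (1 - p))
        if rho:
            sig = np.sqrt(2 * p * (1 - p))
            for m in range(n_M):
                for l in range(m + 1, n_M):
                    d = 0.5 * sig[m] * sig[l] * rho ** abs(m - l) / 2
                    delta[m, l] = delta[l, m] = d
        return MarkerPanel(p=p, delta=delta)

    @pytest.mark.parametrize("preset", ["unrelated", "sire_in_reference"])
    def test_collapses_to_independent_marker_form_without_ld(self, rng, preset):
        """With delta identically zero the LD-aware double sum equals the
        independent-marker expectation exactly."""
        panel = self._panel(rng)
        vs = VarianceSpec(nu2=0.4)
        rel = preset_relationship(preset, 120)
        ld = approx2_expectation_ld(rel, vs, panel).estimate
        plain = approx2_expectation(
            rel, vs, ShrinkageMoments.from_panel(panel, vs, 120)
        ).estimate
        assert ld == pytest.approx(plain, abs=1e-12)

    def test_positive_ld_reduces_information(self, rng):
        """Redundant (positively correlated) markers cannot beat the same number of
        independent ones (observation on the expectation formula)."""
        vs = VarianceSpec(nu2=0.4)
        rel = preset_relationship("unrelated", 120)
        rng2 = np.random.default_rng(7)
        base = self._panel(rng2, rho=0.0)
        with_ld = MarkerPanel(p=base.p, delta=self._panel(
            np.random.default_rng(7), rho=0.8).delta)
        le = approx2_expectation_ld(rel, vs, base).estimate
        ld = approx2_expectation_ld(rel, vs, with_ld).estimate
        assert ld <= le + 1e-9

    def test_requires_delta(self, rng):
        panel = MarkerPanel(p=rng.uniform(0.2, 0.8, 10))
        with pytest.raises(ValueError, match="delta"):
            approx2_expectation_ld(preset_relationship("unrelated", 50),
                                   VarianceSpec(nu2=0.4), panel)

    def test_unsupported_relationship(self, rng):
        panel = self._panel(rng, n_M=8)
        with pytest.raises(UnsupportedRelationshipError):
            approx2_expectation_ld(preset_relationship("both_parents", 50),
                                   VarianceSpec(nu2=0.4), panel)
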