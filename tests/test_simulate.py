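"""Mechanism simulators against their closed-form retention laws.

Independent oracles: under ends-out segregant simulation a marker at
distance d on an arm of length L is retained with probability 1 - d/L;
under selection-filtered ends-in DSBR with a break at s, with probability
(L-d)/(L-s) for d > s and 1 for d < s; the far arm follows 1 - d/L in
both cases.
"""

import numpy as np
import pytest

from hrtract import (
    make_default_map,
    mmr_acceptance_probability,
    retention_profile,
    simulate_double_event_mixture,
    simulate_ends_in,
    simulate_ends_out,
    simulate_random_integration,
    simulate_ssa,
)
from hrtract.markers import Dsb, SimParams

from conftest import three_sigma_binomial

N_ORACLE = 100_000


def _freqs(table, **kw):
    return {r.marker_id: r.freq for r in retention_profile(table, **kw).rows}


def ends_out_expected(marker, L=1000.0):
    return 1.0 - marker.distance / L


class TestEndsOutSegregant:
    def test_matches_uniform_crossover_closed_form(self, default_map):
        table = simulate_ends_out(
            default_map, SimParams(n_clones=N_ORACLE, seed=101), mode="SEGREGANT"
        )
        freqs = _freqs(table)
        for m in default_map.genotyped_markers:
            p = ends_out_expected(m)
            assert abs(freqs[m.id] - p) <= three_sigma_binomial(p, N_ORACLE)

    def test_fitted_line_converges_to_minus_one_over_L(self, default_map):
        from hrtract import fit_retention_model

        table = simulate_ends_out(default_map, SimParams(n_clones=N_ORACLE, seed=102))
        profile = retention_profile(table)
        for arm in ("LEFT", "RIGHT"):
            fit = fit_retention_model(profile, arm, "LINEAR")
            assert fit.params["slope"] == pytest.approx(-1.0 / 1000, rel=0.02)
            assert fit.params["intercept"] == pytest.approx(1.0, rel=0.02)

    def test_colony_mode_sector_calls_bracket_heteroduplex(self, default_map):
        table = simulate_ends_out(
            default_map, SimParams(n_clones=200, seed=103), mode="COLONY"
        )
        for clone in table.clones:
            tr = clone.trace
            for m in default_map.genotyped_markers:
                lo, hi = (
                    sorted((tr.x_top_left, tr.x_bot_left))
                    if m.arm == "LEFT"
                    else sorted((tr.x_top_right, tr.x_bot_right))
                )
                expected = "V" if m.distance < lo else ("S" if m.distance < hi else "C")
                assert clone.calls[m.id] == expected

    def test_reproducible_under_seed(self, default_map):
        p = SimParams(n_clones=50, seed=7)
        a = simulate_ends_out(default_map, p, mode="COLONY")
        b = simulate_ends_out(default_map, p, mode="COLONY")
        assert [c.calls for c in a.clones] == [c.calls for c in b.clones]
        assert a.meta["attempts"] == b.meta["attempts"]

    def test_rejects_dsb_params(self, default_map):
        with pytest.raises(ValueError):
            simulate_ends_out(
                default_map, SimParams(n_clones=1, dsb=Dsb("RIGHT", 266))
            )

    def test_monotone_retention_in_distance(self, default_map):
        n = 10_000
        table = simulate_ends_out(default_map, SimParams(n_clones=n, seed=104))
        profile = retention_profile(table)
        for arm in ("LEFT", "RIGHT"):
            d, f = profile.arm_points(arm)
            for i in range(len(d) - 1):
                sigma_diff = (
                    f[i] * (1 - f[i]) / n + f[i + 1] * (1 - f[i + 1]) / n
                ) ** 0.5
                assert f[i + 1] <= f[i] + 3 * sigma_diff


class TestMmrRejection:
    def test_acceptance_probability_closed_form(self):
        p = SimParams(n_clones=1, r_reject=0.2, n_mismatches=5)
        assert mmr_acceptance_probability(p) == pytest.approx(0.8**5)
        p2 = p.with_(host="PROFICIENT", host_suppression=50.0)
        assert mmr_acceptance_probability(p2) == pytest.approx(0.8**5 / 50)

    def test_attempts_scale_with_rejection(self, default_map):
        n = 2000
        clean = simulate_ends_out(default_map, SimParams(n_clones=n, seed=105))
        assert clean.meta["attempts"] == n
        rejected = simulate_ends_out(
            default_map,
            SimParams(n_clones=n, seed=105, r_reject=0.3, n_mismatches=15),
        )
        assert rejected.meta["attempts"] > n
        rate = n / rejected.meta["attempts"]
        expected = 0.7**15
        assert rate == pytest.approx(expected, rel=0.25)

    def test_rejection_does_not_change_geometry(self, default_map):
        """Event-level MMR rejection alters efficiency, never tract geometry."""
        n = 20_000
        base = _freqs(
            simulate_ends_out(default_map, SimParams(n_clones=n, seed=106))
        )
        mmr = _freqs(
            simulate_ends_out(
                default_map,
                SimParams(n_clones=n, seed=107, r_reject=0.3, n_mismatches=15),
            )
        )
        for m in default_map.genotyped_markers:
            p = ends_out_expected(m)
            sigma_diff = 3 * (2 * p * (1 - p) / n) ** 0.5
            assert abs(base[m.id] - mmr[m.id]) <= sigma_diff


class TestSsa:
    def test_never_sectored(self, default_map):
        table = simulate_ssa(default_map, SimParams(n_clones=2000, seed=108))
        for clone in table.clones:
            assert "S" not in clone.calls.values()

    def test_marginal_law_matches_ends_out_segregant(self, default_map):
        """Same single-crossover marginal: two-proportion z-tests all quiet."""
        from scipy import stats

        n = 20_000
        eo = simulate_ends_out(default_map, SimParams(n_clones=n, seed=109))
        ssa = simulate_ssa(default_map, SimParams(n_clones=n, seed=110))
        pe, ps = retention_profile(eo), retention_profile(ssa)
        for re_, rs in zip(pe.rows, ps.rows):
            pooled = (re_.n_retained + rs.n_retained) / (re_.n_total + rs.n_total)
            se = (pooled * (1 - pooled) * (1 / re_.n_total + 1 / rs.n_total)) ** 0.5
            z = (re_.freq - rs.freq) / se
            p = 2 * stats.norm.sf(abs(z))
            assert p > 0.01, f"{re_.marker_id}: z={z:.2f}"

    def test_outermost_marker_at_arm_end_never_retained(self):
        mm = make_default_map()
        mm.markers = list(mm.markers) + [
            type(mm.markers[0])("edge", "RIGHT", 1000, "SNP")
        ]
        table = simulate_ssa(mm, SimParams(n_clones=3000, seed=111))
        freqs = _freqs(table)
        assert freqs["edge"] == 0.0


class TestEndsIn:
    def test_requires_dsb(self, map_with_right_half_site):
        with pytest.raises(ValueError):
            simulate_ends_in(map_with_right_half_site, SimParams(n_clones=1))

    def test_plateau_right(self, map_with_right_half_site):
        table = simulate_ends_in(
            map_with_right_half_site,
            SimParams(n_clones=1000, seed=112, dsb=Dsb("RIGHT", 266)),
        )
        freqs = _freqs(table)
        assert freqs["SspI"] == 1.0
        assert freqs["SacI"] == 1.0

    def test_plateau_left(self, map_with_left_half_site):
        table = simulate_ends_in(
            map_with_left_half_site,
            SimParams(n_clones=1000, seed=113, dsb=Dsb("LEFT", 569)),
        )
        freqs = _freqs(table)
        assert freqs["AseI"] == 1.0
        assert freqs["NcoI"] == 1.0

    def test_dsbr_distal_retention_closed_form(self, map_with_right_half_site):
        s, L = 266.0, 1000.0
        table = simulate_ends_in(
            map_with_right_half_site,
            SimParams(n_clones=N_ORACLE, seed=114, dsb=Dsb("RIGHT", 266), p_alt=0.0),
        )
        freqs = _freqs(table)
        for m in map_with_right_half_site.genotyped_markers:
            if m.arm == "RIGHT":
                p = 1.0 if m.distance < s else (L - m.distance) / (L - s)
            else:
                p = 1.0 - m.distance / L
            assert abs(freqs[m.id] - p) <= three_sigma_binomial(p, N_ORACLE)

    def test_no_half_site_when_p_alt_zero(self, map_with_right_half_site):
        table = simulate_ends_in(
            map_with_right_half_site,
            SimParams(n_clones=500, seed=115, dsb=Dsb("RIGHT", 266), p_alt=0.0),
        )
        assert not any(c.half_site_present for c in table.clones)

    def test_alt_loses_all_distal_markers(self, map_with_right_half_site):
        table = simulate_ends_in(
            map_with_right_half_site,
            SimParams(n_clones=500, seed=116, dsb=Dsb("RIGHT", 266), p_alt=1.0),
        )
        for clone in table.clones:
            assert clone.half_site_present
            for mid in ("RHP", "XbaI", "SbfI"):
                assert clone.calls[mid] == "C"

    def test_attempts_reflect_selection_filter(self, map_with_right_half_site):
        # P(tract covers cassette) = L_other / (L_other + s) for DSBR-only
        n = 20_000
        table = simulate_ends_in(
            map_with_right_half_site,
            SimParams(n_clones=n, seed=117, dsb=Dsb("RIGHT", 266), p_alt=0.0),
        )
        rate = n / table.meta["attempts"]
        assert rate == pytest.approx(1000.0 / 1266.0, rel=0.05)


class TestRandomIntegration:
    def test_all_markers_retained_everywhere(self, default_map):
        table = simulate_random_integration(default_map, SimParams(n_clones=38))
        assert len(table) == 38
        for clone in table.clones:
            assert set(clone.calls.values()) == {"V"}

    def test_empty_table(self, default_map):
        table = simulate_random_integration(default_map, SimParams(n_clones=0))
        assert len(table) == 0

    def test_flat_profile(self, default_map):
        from hrtract import fit_retention_model

        table = simulate_random_integration(default_map, SimParams(n_clones=38))
        profile = retention_profile(table)
        for arm in ("LEFT", "RIGHT"):
            fit = fit_retention_model(profile, arm, "LINEAR")
            assert fit.params["slope"] == pytest.approx(0.0, abs=1e-12)
            assert fit.params["intercept"] == pytest.approx(1.0, abs=1e-12)


class TestAlternativeCrossoverLaw:
    def test_fixed_tract_sector_span_never_exceeds_tract(self, default_map):
        t = 150.0
        table = simulate_ends_out(
            default_map,
            SimParams(n_clones=2000, seed=119, crossover_law="FIXED_TRACT", tract_length=t),
            mode="COLONY",
        )
        for clone in table.clones:
            tr = clone.trace
            assert abs(tr.x_top_left - tr.x_bot_left) <= t + 1e-9
            assert abs(tr.x_top_right - tr.x_bot_right) <= t + 1e-9

    def test_fixed_tract_requires_length(self):
        with pytest.raises(ValueError):
            SimParams(n_clones=1, crossover_law="FIXED_TRACT")


class TestSpellCheck:
    def test_patches_snp_sectors_but_not_hairpins(self, default_map):
        from hrtract import spell_check_heteroduplex

        table = simulate_ends_out(
            default_map, SimParams(n_clones=2000, seed=120), mode="COLONY"
        )
        patched = spell_check_heteroduplex(table, p_patch=1.0, seed=121)
        hairpins = {"LHP", "RHP"}
        for orig, new in zip(table.clones, patched.clones):
            for mid, call in orig.calls.items():
                if call != "S":
                    assert new.calls[mid] == call
                elif mid in hairpins:
                    assert new.calls[mid] == "S"  # refractory to mismatch repair
                else:
                    assert new.calls[mid] in ("V", "C")

    def test_zero_patch_probability_is_identity(self, default_map):
        from hrtract import spell_check_heteroduplex

        table = simulate_ends_out(
            default_map, SimParams(n_clones=100, seed=122), mode="COLONY"
        )
        patched = spell_check_heteroduplex(table, p_patch=0.0, seed=123)
        assert [c.calls for c in patched.clones] == [c.calls for c in table.clones]


class TestSelectionSoundness:
    @pytest.mark.parametrize("q", [0.0, 0.5])
    def test_every_clone_selected_and_attempts_accounted(self, default_map, q):
        table = simulate_double_event_mixture(
            default_map, SimParams(n_clones=300, seed=118), q=q
        )
        assert all(c.selected for c in table.clones)
        assert table.meta["attempts"] >= len(table)
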