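"""Ra/RED screening, uncertainty propagation and polymer comparison."""

import numpy as np
import pytest

from hspscreen import (
    ComponentRecord,
    GroupSummary,
    HSPVector,
    PolymerRecord,
    RoSpec,
    Verdict,
    compare_polymers,
    propagate_uncertainty,
    resolve_ro,
    screen,
)
from hspscreen.core import ra_distance
from hspscreen.errors import ValidationError
from hspscreen.screening import COMPONENT_LEVEL, SUMMARY_LEVEL


@pytest.fixture()
def cutin_polymer(cutin):
    return PolymerRecord(name="cutin", hsp=cutin, ro=RoSpec.from_solvent("hexane"))


class TestResolveRo:
    def test_reference_solvent(self, cutin, solvent_table):
        ro = resolve_ro(cutin, RoSpec.from_solvent("hexane"), solvent_table)
        assert ro == pytest.approx(11.295, abs=5e-4)

    def test_numeric_pass_through(self, cutin):
        assert resolve_ro(cutin, RoSpec.numeric(10.7)) == 10.7

    def test_degenerate_reference_errors_downstream(self, cutin, solvent_table, group_summaries):
        table = solvent_table
        # a "solvent" coinciding with the polymer gives Ro = 0
        from hspscreen.estimation import SolventTable

        table = SolventTable(entries={**table.entries, "self": cutin})
        polymer = PolymerRecord("cutin", cutin, RoSpec.from_solvent("self"))
        with pytest.raises(ValidationError, match="Ro"):
            screen(polymer, group_summaries, solvents=table)


class TestScreenSummaryLevel:
    def test_fats_row(self, cutin_polymer, group_summaries):
        report = screen(cutin_polymer, group_summaries)
        assert report.mode == SUMMARY_LEVEL
        fats = report.row("fats")
        assert fats.mean_ra == pytest.approx(8.132, abs=5e-4)
        assert fats.red == pytest.approx(0.72, abs=5e-3)
        assert fats.verdict is Verdict.COMPATIBLE

    def test_carbohydrates_row(self, cutin_polymer, group_summaries):
        report = screen(cutin_polymer, group_summaries)
        carbs = report.row("carbohydrates")
        assert carbs.mean_ra == pytest.approx(22.18, abs=5e-3)
        assert carbs.red == pytest.approx(1.96, abs=5e-3)
        assert carbs.verdict is Verdict.INCOMPATIBLE

    def test_red_consistency_invariant(self, cutin_polymer, group_summaries):
        report = screen(cutin_polymer, group_summaries)
        for row in report.rows:
            assert row.red == pytest.approx(row.mean_ra / report.ro_value, rel=1e-12)

    def test_red_scales_inversely_with_ro(self, cutin_polymer, group_summaries):
        r1 = screen(cutin_polymer, group_summaries, ro=RoSpec.numeric(10.0))
        r2 = screen(cutin_polymer, group_summaries, ro=RoSpec.numeric(20.0))
        for a, b in zip(r1.rows, r2.rows):
            assert a.red == pytest.approx(2.0 * b.red, rel=1e-12)

    def test_empty_database_rejected(self, cutin_polymer):
        with pytest.raises(ValidationError):
            screen(cutin_polymer, [])

    def test_jensen_gap_vs_published_group_averages(self, cutin_polymer, group_summaries):
        """Ra at the group-mean HSP must not exceed the published
        component-averaged Ra by more than one-decimal rounding slack."""
        report = screen(cutin_polymer, group_summaries)
        for summary in group_summaries:
            row = report.row(summary.group)
            assert row.mean_ra <= summary.mean_ra + 0.2


class TestScreenComponentLevel:
    def test_group_mean_of_ra(self, cutin_polymer, cutin):
        records = [
            ComponentRecord("a", "fats", HSPVector(16, 4, 6)),
            ComponentRecord("b", "fats", HSPVector(17, 4, 8)),
        ]
        report = screen(cutin_polymer, records)
        assert report.mode == COMPONENT_LEVEL
        ras = [ra_distance(cutin, r.hsp) for r in records]
        assert report.row("fats").mean_ra == pytest.approx(np.mean(ras))
        assert report.row("fats").sd_ra == pytest.approx(np.std(ras, ddof=1))

    def test_polymer_identical_to_single_component(self, cutin):
        polymer = PolymerRecord("p", cutin, RoSpec.numeric(11.3))
        report = screen(polymer, [ComponentRecord("c", "g", cutin)])
        row = report.row("g")
        assert row.mean_ra == 0.0
        assert row.red == 0.0
        assert row.verdict is Verdict.COMPATIBLE

    def test_mixed_database_rejected(self, cutin_polymer, cutin, group_summaries):
        mixed = [group_summaries[0], ComponentRecord("c", "g", cutin)]
        with pytest.raises(ValidationError, match="homogeneous"):
            screen(cutin_polymer, mixed)


class TestPropagateUncertainty:
    def test_zero_sds_give_zero(self, cutin):
        g = GroupSummary("g", 3, HSPVector(16, 4, 6), sd_hsp=(0, 0, 0))
        sd_ra, sd_red = propagate_uncertainty(g, cutin, ro=11.3)
        assert sd_ra == 0.0
        assert sd_red == 0.0

    def test_delta_matches_finite_difference_gradient(self, cutin, group_summaries):
        """First-order propagation equals the finite-difference gradient
        composed with independent sds (fats group, published sds)."""
        fats = group_summaries[1]
        sd_ra, _ = propagate_uncertainty(fats, cutin, ro=11.3, method="delta")
        eps = 1e-7
        grads = []
        mean = fats.mean_hsp.as_array()
        for k in range(3):
            hi, lo = mean.copy(), mean.copy()
            hi[k] += eps
            lo[k] -= eps
            grads.append(
                (ra_distance(cutin, HSPVector(*hi)) - ra_distance(cutin, HSPVector(*lo)))
                / (2 * eps)
            )
        expected = np.sqrt(sum((g * s) ** 2 for g, s in zip(grads, fats.sd_hsp)))
        assert sd_ra == pytest.approx(expected, abs=1e-6)

    def test_monte_carlo_reproducible_under_seed(self, cutin, group_summaries):
        fats = group_summaries[1]
        a = propagate_uncertainty(fats, cutin, ro=11.3, method="monte_carlo", seed=42)
        b = propagate_uncertainty(fats, cutin, ro=11.3, method="monte_carlo", seed=42)
        c = propagate_uncertainty(fats, cutin, ro=11.3, method="monte_carlo", seed=43)
        assert a == b
        assert a != c

    def test_monte_carlo_agrees_with_delta_within_band(self, cutin, group_summaries):
        """For published sd magnitudes the two methods agree within 30%."""
        for g in group_summaries:
            sd_delta, _ = propagate_uncertainty(g, cutin, ro=11.3, method="delta")
            sd_mc, _ = propagate_uncertainty(
                g, cutin, ro=11.3, method="monte_carlo", seed=7, n_draws=20000
            )
            assert sd_delta == pytest.approx(sd_mc, rel=0.30)

    def test_too_few_draws_rejected(self, cutin, group_summaries):
        with pytest.raises(ValidationError, match="n_draws"):
            propagate_uncertainty(
                group_summaries[0], cutin, ro=11.3, method="monte_carlo", n_draws=50
            )

    def test_sd_red_is_sd_ra_over_ro(self, cutin, group_summaries):
        sd_ra, sd_red = propagate_uncertainty(group_summaries[0], cutin, ro=11.3)
        assert sd_red == pytest.approx(sd_ra / 11.3, rel=1e-12)


class TestComparePolymers:
    def test_single_polymer_equals_its_report(self, cutin_polymer, group_summaries):
        comparison = compare_polymers([cutin_polymer], group_summaries)
        single = screen(cutin_polymer, group_summaries)
        assert comparison.reports[0].rows == single.rows
        assert set(comparison.ranking.values()) == {"cutin"}

    def test_identical_polymers_identical_columns(self, cutin, group_summaries):
        a = PolymerRecord("a", cutin, RoSpec.numeric(11.3))
        b = PolymerRecord("b", cutin, RoSpec.numeric(11.3))
        comparison = compare_polymers([a, b], group_summaries)
        for g in [r.group for r in comparison.reports[0].rows]:
            assert comparison.reports[0].row(g).red == comparison.reports[1].row(g).red

    def test_composition_oracle(self, cutin_polymer, group_summaries):
        """Comparison columns equal per-polymer screen() runs."""
        pla = PolymerRecord("PLA", HSPVector(17.9, 9.2, 5.9), RoSpec.numeric(10.7))
        comparison = compare_polymers([cutin_polymer, pla], group_summaries)
        for polymer in (cutin_polymer, pla):
            direct = screen(polymer, group_summaries)
            col = [r for r in comparison.reports if r.polymer.name == polymer.name][0]
            assert col.rows == direct.rows

    def test_missing_ro_names_polymer(self, cutin_polymer, group_summaries):
        from hspscreen.errors import MissingValueError

        pla = PolymerRecord("PLA", HSPVector(17.9, 9.2, 5.9), ro=None)
        with pytest.raises(MissingValueError, match="PLA"):
            compare_polymers([cutin_polymer, pla], group_summaries)
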