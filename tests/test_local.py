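"""Factor matching, nearest successful neighbors and local clr diagnosis."""

import json

import numpy as np
import pytest

from cndiag import (
    FactorSpec,
    GeneratorConfig,
    Specimen,
    aitchison_distance,
    clr_inverse,
    clr_transform,
    filter_successful,
    local_clr_differences,
    local_diagnosis_report,
    match_factors,
    nearest_neighbors,
    select_reference_neighbor,
)
from cndiag.local import match_with_broadening
from cndiag.synthetic import (
    engineer_deficiency,
    profile_from_composition,
    sample_compositions,
)

from conftest import random_compositions


class TestFilterSuccessful:
    def test_floor_is_strict(self, specimen_factory):
        comps = random_compositions(3, seed=4)
        specimens = [
            Specimen(s.id, s.profile, dbh_cm=dbh)
            for s, dbh in zip(specimen_factory(comps), (4.9, 5.0, 5.43))
        ]
        kept = filter_successful(specimens, dbh_floor=5.0)
        assert [s.dbh_cm for s in kept] == [5.43]

    def test_quadrant_filter_and_floor_zero(self, specimen_factory):
        specimens = specimen_factory(random_compositions(4, seed=5), dbh=6.0)
        quadrants = {s.id: ("TN" if i % 2 == 0 else "FP") for i, s in enumerate(specimens)}
        kept = filter_successful(specimens, dbh_floor=0.0, quadrants=quadrants)
        assert len(kept) == 2

    def test_empty_set_errors(self, specimen_factory):
        specimens = specimen_factory(random_compositions(3, seed=6), dbh=2.0)
        with pytest.raises(ValueError, match="empty successful set"):
            filter_successful(specimens, dbh_floor=5.0)


class TestMatchFactors:
    def make(self, comps, clones, ages):
        return [
            Specimen(f"M{i}", profile_from_composition(c), clone=cl, age_yr=a, dbh_cm=6.0)
            for i, (c, cl, a) in enumerate(zip(comps, clones, ages))
        ]

    def test_exact_and_window_enumeration(self):
        comps = random_compositions(4, seed=7)
        query = self.make(comps[:1], ["A"], [1.0])[0]
        candidates = self.make(comps[1:], ["A", "A", "B"], [1.05, 1.3, 1.0])
        spec = FactorSpec(exact=("clone",), windows={"age_yr": 0.1})
        matched = match_factors(query, candidates, spec)
        assert [c.age_yr for c in matched] == [1.05]

    def test_empty_spec_matches_all(self):
        comps = random_compositions(3, seed=8)
        query = self.make(comps[:1], ["A"], [1.0])[0]
        candidates = self.make(comps[1:], ["B", "C"], [2.0, 3.0])
        assert len(match_factors(query, candidates, FactorSpec(exact=(), windows={}))) == 2

    def test_no_match_errors_with_hint(self):
        comps = random_compositions(2, seed=9)
        query = self.make(comps[:1], ["A"], [1.0])[0]
        candidates = self.make(comps[1:], ["B"], [1.0])
        with pytest.raises(ValueError, match="broadening"):
            match_factors(query, candidates, FactorSpec(exact=("clone",), windows={}))

    def test_broadening_eventually_matches(self):
        comps = random_compositions(2, seed=10)
        query = self.make(comps[:1], ["A"], [1.0])[0]
        candidates = self.make(comps[1:], ["B"], [1.5])
        matched, used = match_with_broadening(
            query, candidates, FactorSpec(exact=("clone",), windows={"age_yr": 0.1})
        )
        assert len(matched) == 1
        assert "clone" not in used.exact


class TestNearestNeighbors:
    def test_identical_candidate_first_with_zero_distance(self, specimen_factory):
        comps = random_compositions(5, seed=11)
        query = specimen_factory(comps[:1], prefix="Q")[0]
        pool = specimen_factory([comps[0]] + comps[1:], prefix="P")
        report = nearest_neighbors(query, pool, k=3)
        assert report.neighbors[0].id == "P0000"
        assert report.neighbors[0].epsilon == 0.0

    def test_k_larger_than_pool_returns_pool(self, specimen_factory):
        pool = specimen_factory(random_compositions(4, seed=12))
        query = specimen_factory(random_compositions(1, seed=13), prefix="Q")[0]
        assert len(nearest_neighbors(query, pool, k=10).neighbors) == 4

    def test_matches_brute_force_full_sort(self, specimen_factory):
        comps = random_compositions(51, seed=14)
        query = specimen_factory(comps[:1], prefix="Q")[0]
        pool = specimen_factory(comps[1:], prefix="P")
        report = nearest_neighbors(query, pool, k=10)
        brute = sorted(
            ((aitchison_distance(query.composition, c.composition), c.id) for c in pool)
        )[:10]
        assert [(n.epsilon, n.id) for n in report.neighbors] == pytest.approx(brute)

    def test_distances_non_decreasing_and_stable_under_growth(self, specimen_factory):
        comps = random_compositions(41, seed=15)
        query = specimen_factory(comps[:1], prefix="Q")[0]
        pool = specimen_factory(comps[1:], prefix="P")
        small = nearest_neighbors(query, pool[:20], k=5)
        big = nearest_neighbors(query, pool, k=5)
        eps_small = [n.epsilon for n in small.neighbors]
        eps_big = [n.epsilon for n in big.neighbors]
        assert eps_small == sorted(eps_small)
        assert eps_big[-1] <= eps_small[-1]  # more candidates never worsen the k-th


class TestLocalDifferences:
    def test_self_difference_zero(self, site1_comp):
        d, eps = local_clr_differences(clr_transform(site1_comp), clr_transform(site1_comp))
        assert eps == 0.0 and all(v == 0.0 for v in d.values())

    def test_antisymmetry(self, site1_comp, site2_comp):
        d1, e1 = local_clr_differences(clr_transform(site1_comp), clr_transform(site2_comp))
        d2, e2 = local_clr_differences(clr_transform(site2_comp), clr_transform(site1_comp))
        assert e1 == pytest.approx(e2)
        for p in d1:
            assert d1[p] == pytest.approx(-d2[p])

    def test_against_neighbor_at_norm_means(self, site1_comp, norms):
        # a neighbor sitting exactly at the regional norm composition:
        # differences are site clr minus norm means (vector-subtraction oracle)
        ref = clr_transform(clr_inverse(norms.means - norms.means.mean()))
        d, _ = local_clr_differences(clr_transform(site1_comp), ref)
        expected = clr_transform(site1_comp).values - (norms.means - norms.means.mean())
        assert np.allclose(list(d.values()), expected, atol=1e-9)
        nutrients_only = {p: v for p, v in d.items() if p != "Fv"}
        assert max(nutrients_only, key=nutrients_only.get) == "Mn"
        assert min(nutrients_only, key=nutrients_only.get) == "Fe"


class TestSelectReference:
    def test_single_neighbor_under_both_objectives(self, specimen_factory):
        comps = random_compositions(2, seed=16)
        query = specimen_factory(comps[:1], prefix="Q")[0]
        pool = specimen_factory(comps[1:], prefix="P")
        report = nearest_neighbors(query, pool, k=1)
        for objective in ("distance", "parsimony"):
            assert select_reference_neighbor(report, objective).selected.id == "P0000"

    def test_zero_distance_neighbor_wins_min_distance(self, specimen_factory):
        comps = random_compositions(4, seed=17)
        query = specimen_factory(comps[:1], prefix="Q")[0]
        pool = specimen_factory([comps[0]] + comps[1:], prefix="P")
        sel = select_reference_neighbor(nearest_neighbors(query, pool, k=4), "distance")
        assert sel.selected.epsilon == 0.0

    def test_objectives_can_diverge(self, specimen_factory):
        # neighbor X: close, but the query is short of two nutrients vs it;
        # neighbor Y: farther, yet the query shows no shortages vs it.
        # Constructed in clr space (moving mass between Zn/Cu and Fv) so the
        # closure does not leak small shortages into the other nutrients.
        from cndiag.synthetic import profile_from_composition

        base = random_compositions(1, seed=18)[0]
        query = specimen_factory([base], prefix="Q")[0]
        qclr = query.clr.values.copy()
        i_zn, i_cu, i_fv = (query.clr.parts.index(p) for p in ("Zn", "Cu", "Fv"))

        x_clr = qclr.copy()  # X richer in Zn/Cu by 0.1 clr units
        x_clr[[i_zn, i_cu]] += 0.1
        x_clr[i_fv] -= 0.2
        y_clr = qclr.copy()  # Y poorer in Zn/Cu by 0.5 clr units
        y_clr[[i_zn, i_cu]] -= 0.5
        y_clr[i_fv] += 1.0
        pool = [
            Specimen("X", profile_from_composition(clr_inverse(x_clr)), dbh_cm=6.0),
            Specimen("Y", profile_from_composition(clr_inverse(y_clr)), dbh_cm=6.0),
        ]
        report = nearest_neighbors(query, pool, k=2)
        by_dist = select_reference_neighbor(report, "distance").selected.id
        by_cost = select_reference_neighbor(report, "parsimony").selected.id
        assert by_dist == "X" and by_cost == "Y"


class TestDiagnosisReport:
    def test_engineered_shortage_is_most_negative(self, specimen_factory):
        """A nutrient knocked down in the query ranks as the strongest
        shortage in >= 95% of seeded trials.

        Each trial perturbs one nutrient of a population draw whose
        unperturbed twin sits in the successful pool — the situation local
        diagnosis is built for: a defective specimen with healthy,
        factor-matched neighbors of near-identical composition.
        """
        hits = trials = 0
        nutrients = ("N", "K", "B", "Zn", "Fe")
        for seed in range(40):
            comps = sample_compositions(GeneratorConfig(n=21, seed=100 + seed))
            pool = specimen_factory(comps, dbh=6.0)
            for part in nutrients:
                trials += 1
                prof = engineer_deficiency(profile_from_composition(comps[0]), part, 0.6)
                query = Specimen("Q", prof, clone="C0", age_yr=1.0, dbh_cm=3.0)
                report = local_diagnosis_report(query, pool, k=10)
                hits += report["local"]["ranking"][0] == part
        assert trials == 200
        assert hits / trials >= 0.95

    def test_balanced_query_flags_no_corrective_action(self, specimen_factory):
        comps = random_compositions(12, seed=19)
        pool = specimen_factory(comps, dbh=6.0)
        query = Specimen("Q", pool[0].profile, clone="C0", age_yr=1.0, dbh_cm=6.2)
        report = local_diagnosis_report(query, pool, k=5)
        assert report["no_corrective_action"]
        assert report["selected_neighbor"]["epsilon"] == pytest.approx(0.0)

    def test_report_bundles_regional_and_serializes(self, specimen_factory, norms):
        comps = random_compositions(15, seed=20)
        pool = specimen_factory(comps[1:], dbh=6.0)
        query = Specimen(
            "Q", profile_from_composition(comps[0]), clone="C0", age_yr=1.0, dbh_cm=3.5
        )
        report = local_diagnosis_report(query, pool, k=10, norms=norms)
        assert report["selected_neighbor"]["attainable_dbh_cm"] == 6.0
        assert set(report["regional"]["cnd_indices"]) == set(
            report["local"]["clr_differences"]
        )
        assert json.loads(json.dumps(report)) == report
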