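"""Mixture engine: exposure ratios, Hazard Indexes, alerts, ranking, invariants."""

import math

import pytest

import hazmix as hx
from conftest import quantitative_scenario

CNS = "central_nervous_system_damage"


def brute_force_class_hi(scenario, db, class_id):
    """Independent one-line-per-step oracle: sum 100*C/OEL over activators.

    Assumes each concentration shares the unit of the substance's selected
    OEL (true for generated scenarios); OEL precedence re-derived inline.
    """
    total = 0.0
    for rec in scenario.records:
        s = db.substances[rec.cas]
        if class_id not in s.class_ids or rec.concentration is None:
            continue
        for kind in ("eight_hour", "ceiling", "short_term"):
            if kind in s.oels:
                assert rec.unit == s.oels[kind].unit
                total += 100.0 * rec.concentration / s.oels[kind].value
                break
    return total


# ---------------------------------------------------------------- ratios

def test_exposure_ratio_direct_and_zero(toy_db):
    benzene = toy_db["71-43-2"]
    rec = hx.ExposureRecord(cas="71-43-2", concentration=0.5, unit="ppm")
    assert hx.exposure_ratio(rec, benzene).ratio_percent == pytest.approx(50.0)
    zero = hx.ExposureRecord(cas="71-43-2", concentration=0.0, unit="ppm")
    assert hx.exposure_ratio(zero, benzene).ratio_percent == 0.0


def test_exposure_ratio_reconciles_units_via_molecular_weight():
    # 10 ppm of toluene is 37.69 mg/m3: against an OEL stated in mg/m3 the
    # ratio must land at 100% regardless of the measurement unit
    s = hx.Substance(cas="108-88-3", name="Toluene",
                     oels={"eight_hour": hx.OELValue("eight_hour", 37.69,
                                                     "mg_per_m3")},
                     molecular_weight=92.14)
    rec = hx.ExposureRecord(cas="108-88-3", concentration=10.0, unit="ppm")
    assert hx.exposure_ratio(rec, s).ratio_percent == pytest.approx(100.0, abs=0.1)


def test_exposure_ratio_unit_mismatch_without_mw_names_substance():
    s = hx.Substance(cas="71-43-2", name="Benzene",
                     oels={"eight_hour": hx.OELValue("eight_hour", 3.25,
                                                     "mg_per_m3")})
    rec = hx.ExposureRecord(cas="71-43-2", concentration=1.0, unit="ppm")
    with pytest.raises(hx.UnitConversionError, match="71-43-2"):
        hx.exposure_ratio(rec, s)


# ---------------------------------------------------------------- class HI

def test_hi_of_two_substances_each_at_their_oel(toy_db):
    sc = quantitative_scenario([("108-88-3", 20.0), ("67-64-1", 500.0)])
    r = hx.compute_class_hi(sc, CNS, toy_db)
    assert r.hi_percent == pytest.approx(200.0)
    assert r.risky is True


def test_hi_sums_arbitrary_ratios(toy_db):
    # ratios 30%, 50%, 40% -> HI 120%
    sc = quantitative_scenario([("71-43-2", 0.3), ("108-88-3", 10.0),
                                ("67-64-1", 200.0)])
    r = hx.compute_class_hi(sc, CNS, toy_db)
    assert r.hi_percent == pytest.approx(120.0)
    assert r.risky is True
    assert [c.ratio_percent for c in r.contributions] == sorted(
        (c.ratio_percent for c in r.contributions), reverse=True)


def test_hi_exactly_100_is_not_risky(toy_db):
    sc = quantitative_scenario([("71-43-2", 0.5), ("108-88-3", 10.0)])
    r = hx.compute_class_hi(sc, CNS, toy_db)
    assert r.hi_percent == pytest.approx(100.0)
    assert r.risky is False  # strictly greater than 100% only


def test_hi_refused_for_alert_class(toy_db):
    sc = quantitative_scenario([("71-43-2", 0.5)])
    with pytest.raises(hx.HazmixError, match="alert class"):
        hx.compute_class_hi(sc, "carcinogenicity_mutagenicity", toy_db)


def test_hi_refused_when_nothing_activates_the_class(toy_db):
    sc = quantitative_scenario([("67-64-1", 10.0)])
    with pytest.raises(hx.HazmixError, match="activates"):
        hx.compute_class_hi(sc, "ototoxicity", toy_db)


def test_non_activating_substances_contribute_nothing(toy_db):
    with_extra = quantitative_scenario([("108-88-3", 10.0), ("67-64-1", 100.0)])
    alone = quantitative_scenario([("108-88-3", 10.0)])
    hi_extra = hx.compute_class_hi(with_extra, "ototoxicity", toy_db)
    hi_alone = hx.compute_class_hi(alone, "ototoxicity", toy_db)
    assert hi_extra.hi_percent == hi_alone.hi_percent
    assert hi_extra.cas_list == ("108-88-3",)


# ---------------------------------------------------------------- alerts

def test_single_carcinogen_yields_one_finding(toy_db):
    sc = quantitative_scenario([("71-43-2", 0.5)])
    findings = [f for f in hx.detect_alerts(sc, toy_db) if not f.informational]
    assert len(findings) == 1
    f = findings[0]
    assert f.class_id == "carcinogenicity_mutagenicity"
    assert f.cas_list == ("71-43-2",)
    assert f.message_key == "cmr_present"


def test_alert_finding_collects_all_activating_substances(case_study):
    db, scenario = case_study
    findings = {f.class_id: f for f in hx.detect_alerts(scenario, db)}
    assert set(findings["developmental_damage"].cas_list) == {"78-93-3",
                                                              "108-88-3"}
    assert set(findings["carcinogenicity_mutagenicity"].cas_list) == {
        "108-10-1", "79-01-6"}


def test_no_alert_substances_means_no_findings(toy_db):
    sc = quantitative_scenario([("67-64-1", 10.0)])
    assert hx.detect_alerts(sc, toy_db) == []


def test_ototoxic_substance_triggers_informational_message(toy_db):
    sc = quantitative_scenario([("108-88-3", 1.0)])
    info = [f for f in hx.detect_alerts(sc, toy_db) if f.informational]
    assert len(info) == 1
    assert info[0].class_id == "ototoxicity"
    assert info[0].message_key == "ototoxicant_present"


# ---------------------------------------------------------------- analyses

def test_four_substances_sharing_a_class_at_30_percent_each(case_study):
    db, _ = case_study
    sc = quantitative_scenario(
        [(cas, 0.3 * db[cas].oels["eight_hour"].value)
         for cas in db.substances])
    report = hx.analyze_quantitative(sc, db)
    by_id = {r.class_id: r for r in report.class_results}
    assert by_id[CNS].hi_percent == pytest.approx(120.0)
    assert report.any_risk is True


def test_single_substance_below_oel_shows_no_risk(toy_db):
    sc = quantitative_scenario([("67-64-1", 100.0)])  # 20% of its OEL
    report = hx.analyze_quantitative(sc, toy_db)
    assert report.any_risk is False
    assert not any(r.risky for r in report.class_results)


def test_alert_classes_listed_first_with_not_applicable_hi(case_study):
    db, scenario = case_study
    report = hx.analyze_quantitative(scenario, db)
    results = report.class_results
    alert = [r for r in results if not r.additive]
    assert {r.class_id for r in alert} == {"developmental_damage",
                                           "carcinogenicity_mutagenicity"}
    assert all(r.hi_percent is None and r.contributions == () for r in alert)
    # every alert row precedes every additive row
    first_additive = next(i for i, r in enumerate(results) if r.additive)
    assert all(not r.additive for r in results[:first_additive])


def test_empty_or_unresolvable_scenarios_error(toy_db):
    with pytest.raises(hx.ScenarioError):
        hx.MixtureScenario(records=(), mode="quantitative")
    sc = quantitative_scenario([("50-00-0", 1.0)])  # formaldehyde, not in db
    with pytest.raises(hx.DatabaseError, match="50-00-0"):
        hx.analyze_quantitative(sc, toy_db)


def test_missing_concentration_hard_error_unless_allowed(toy_db):
    sc = hx.MixtureScenario(
        records=(hx.ExposureRecord(cas="108-88-3", concentration=10.0, unit="ppm"),
                 hx.ExposureRecord(cas="67-64-1")),
        mode="quantitative")
    with pytest.raises(hx.ScenarioError, match="67-64-1"):
        hx.analyze_quantitative(sc, toy_db)
    report = hx.analyze_quantitative(sc, toy_db, allow_missing=True)
    assert any(w.startswith("missing_concentration:67-64-1") for w in report.warnings)
    by_id = {r.class_id: r for r in report.class_results}
    assert by_id[CNS].hi_percent == pytest.approx(50.0)  # lower bound
    assert "67-64-1" in by_id[CNS].cas_list  # still counted as activating


def test_substance_without_usable_oel_excluded_with_warning():
    no_oel = hx.Substance(cas="7440-02-0", name="Nickel",
                          class_ids=frozenset({CNS}))
    other = hx.Substance(
        cas="108-88-3", name="Toluene",
        oels={"eight_hour": hx.OELValue("eight_hour", 20.0, "ppm")},
        class_ids=frozenset({CNS}))
    db = hx.SubstanceDatabase(jurisdiction="T", oel_name="t",
                              substances={s.cas: s for s in (no_oel, other)})
    sc = quantitative_scenario([("7440-02-0", 1.0), ("108-88-3", 10.0)])
    report = hx.analyze_quantitative(sc, db)
    assert any(w.startswith("excluded_no_oel:7440-02-0") for w in report.warnings)
    by_id = {r.class_id: r for r in report.class_results}
    assert by_id[CNS].hi_percent == pytest.approx(50.0)
    assert set(by_id[CNS].cas_list) == {"7440-02-0", "108-88-3"}


def test_oel_fallback_surfaces_in_report_warnings(toy_db):
    sc = quantitative_scenario([("7664-41-7", 10.0)])  # ceiling-only substance
    report = hx.analyze_quantitative(sc, toy_db)
    assert any(w.startswith("oel_fallback:7664-41-7") for w in report.warnings)


def test_qualitative_counts_and_sharing(toy_db):
    sc = hx.MixtureScenario(
        records=tuple(hx.ExposureRecord(cas=c)
                      for c in ("71-43-2", "108-88-3", "67-64-1")),
        mode="qualitative")
    report = hx.analyze_qualitative(sc, toy_db)
    by_id = {r.class_id: r for r in report.class_results}
    ocular = by_id["ocular_damage"]
    assert ocular.substance_count == 2 and ocular.shared
    assert set(ocular.cas_list) == {"108-88-3", "67-64-1"}
    cns = by_id[CNS]
    assert cns.substance_count == 3 and cns.shared


def test_qualitative_majority_class_ranks_first_among_additive(synth_db):
    # 15 substances, 13 sharing one class: that class tops the additive ranking
    base = hx.generate_substance_db(hx.GeneratorSpec(n_substances=15, seed=3,
                                                     class_density=0.2,
                                                     alert_density=0.1))
    subs = {}
    for i, (cas, s) in enumerate(sorted(base.substances.items())):
        cls = set(s.class_ids)
        cls.discard("metabolic_acidosis")
        if i < 13:
            cls.add("metabolic_acidosis")
        subs[cas] = hx.Substance(cas=cas, name=s.name, oels=s.oels,
                                 class_ids=frozenset(cls),
                                 molecular_weight=s.molecular_weight,
                                 synthetic=True)
    db = hx.SubstanceDatabase(jurisdiction="synthetic", oel_name="s",
                              substances=subs)
    sc = hx.MixtureScenario(records=tuple(hx.ExposureRecord(cas=c)
                                          for c in sorted(subs)),
                            mode="qualitative")
    report = hx.analyze_qualitative(sc, db)
    additive = [r for r in report.class_results if r.additive]
    assert additive[0].class_id == "metabolic_acidosis"
    assert additive[0].substance_count == 13


def test_single_substance_qualitative_has_no_shared_class(toy_db):
    sc = hx.MixtureScenario(records=(hx.ExposureRecord(cas="108-88-3"),),
                            mode="qualitative")
    report = hx.analyze_qualitative(sc, toy_db)
    assert all(r.substance_count == 1 and not r.shared
               for r in report.class_results)


# ---------------------------------------------------------------- ranking

def _hi_result(class_id, hi, additive=True):
    return hx.ClassHIResult(class_id=class_id, additive=additive,
                            hi_percent=hi, contributions=(),
                            cas_list=("71-43-2",), risky=bool(hi and hi > 100))


def test_rank_alert_first_then_decreasing_hi():
    ranked = hx.rank_results([
        _hi_result("bbb", 120.0), _hi_result("aaa", 50.0),
        _hi_result("zzz_alert", None, additive=False)])
    assert [r.class_id for r in ranked] == ["zzz_alert", "bbb", "aaa"]


def test_rank_ties_break_alphabetically():
    ranked = hx.rank_results([_hi_result("bbb", 50.0), _hi_result("aaa", 50.0)])
    assert [r.class_id for r in ranked] == ["aaa", "bbb"]
    assert hx.rank_results([]) == []


# ---------------------------------------------------------------- invariants

def _scenarios(db, count, max_n, seed0=100, regime=(0.0, 1.5)):
    eligible = sum(1 for s in db.substances.values() if s.oels)
    for k in range(count):
        n = 1 + (k % min(max_n, eligible))
        yield hx.generate_scenario(db, n, regime=regime, seed=seed0 + k)


def test_engine_matches_brute_force_oracle(synth_db, registry):
    for sc in _scenarios(synth_db, 50, 10):
        report = hx.analyze_quantitative(sc, synth_db)
        for r in report.class_results:
            if not r.additive:
                continue
            expected = brute_force_class_hi(sc, synth_db, r.class_id)
            assert r.hi_percent == pytest.approx(expected, rel=1e-9)


def test_homogeneity_scaling_concentrations_scales_hi(synth_db):
    for k in (0.5, 2.0, 7.3):
        for sc in _scenarios(synth_db, 10, 6):
            scaled = hx.MixtureScenario(
                records=tuple(hx.ExposureRecord(cas=r.cas,
                                                concentration=r.concentration * k,
                                                unit=r.unit)
                              for r in sc.records),
                mode="quantitative")
            base = {r.class_id: r.hi_percent
                    for r in hx.analyze_quantitative(sc, synth_db).class_results
                    if r.additive}
            got = {r.class_id: r.hi_percent
                   for r in hx.analyze_quantitative(scaled, synth_db).class_results
                   if r.additive}
            assert got.keys() == base.keys()
            for cid in base:
                assert got[cid] == pytest.approx(k * base[cid], rel=1e-12)


def test_monotonicity_adding_a_substance_never_decreases_hi(synth_db):
    for sc in _scenarios(synth_db, 20, 8):
        if len(sc.records) < 2:
            continue
        smaller = hx.MixtureScenario(records=sc.records[:-1], mode="quantitative")
        full = {r.class_id: r.hi_percent
                for r in hx.analyze_quantitative(sc, synth_db).class_results
                if r.additive}
        part = {r.class_id: r.hi_percent
                for r in hx.analyze_quantitative(smaller, synth_db).class_results
                if r.additive}
        for cid, hi in part.items():
            assert full[cid] >= hi - 1e-12


def test_decomposition_hi_sums_over_scenario_partitions(synth_db):
    for sc in _scenarios(synth_db, 20, 8):
        if len(sc.records) < 2:
            continue
        cut = len(sc.records) // 2
        parts = [hx.MixtureScenario(records=sc.records[:cut], mode="quantitative"),
                 hx.MixtureScenario(records=sc.records[cut:], mode="quantitative")]
        whole = {r.class_id: r.hi_percent
                 for r in hx.analyze_quantitative(sc, synth_db).class_results
                 if r.additive}
        summed: dict[str, float] = {}
        for part in parts:
            for r in hx.analyze_quantitative(part, synth_db).class_results:
                if r.additive:
                    summed[r.class_id] = summed.get(r.class_id, 0.0) + r.hi_percent
        assert summed.keys() == whole.keys()
        for cid in whole:
            assert summed[cid] == pytest.approx(whole[cid], rel=1e-9)


def test_conservation_contributions_sum_to_hi(synth_db):
    for sc in _scenarios(synth_db, 30, 10):
        for r in hx.analyze_quantitative(sc, synth_db).class_results:
            if r.additive:
                s = math.fsum(c.ratio_percent for c in r.contributions)
                assert r.hi_percent == pytest.approx(s, rel=1e-9, abs=1e-12)


def test_risky_flips_strictly_above_threshold(toy_db):
    # single benzene record with OEL 1 ppm: concentration == HI/100
    for conc, expect in [(0.99999, False), (1.0, False), (1.00001, True)]:
        sc = quantitative_scenario([("71-43-2", conc)])
        r = hx.compute_class_hi(sc, CNS, toy_db)
        assert r.risky is expect, (conc, r.hi_percent)


def test_alert_classes_never_carry_a_numeric_hi(synth_db, registry):
    alert_ids = set(registry.alert_class_ids)
    for sc in _scenarios(synth_db, 30, 10):
        for report in (hx.analyze_quantitative(sc, synth_db),
                       hx.analyze_qualitative(sc, synth_db)):
            for r in report.class_results:
                if r.class_id in alert_ids:
                    assert not r.additive
                    if isinstance(r, hx.ClassHIResult):
                        assert r.hi_percent is None


def test_activated_classes_identical_across_modes(synth_db):
    for sc in _scenarios(synth_db, 20, 10):
        quant = hx.analyze_quantitative(sc, synth_db)
        qual = hx.analyze_qualitative(sc, synth_db)
        assert ({r.class_id for r in quant.class_results}
                == {r.class_id for r in qual.class_results})
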