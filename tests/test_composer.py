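"""Rule-of-Four composition, contraindication vetoes, and the audit contract."""

import pytest

from gerotcm.composer import (
    ComposerConfig,
    CompositionError,
    PatientProfile,
    check_contraindications,
    compose_prescription,
    shortlist_herbs,
    ROLES,
)
from gerotcm.datamodel import Compound, ConfigError, Herb, TCMDatabase
from gerotcm.synthetic import PlantedSignal, SynthConfig, generate


def _profile(**kw):
    kw.setdefault("age", 55)
    kw.setdefault("sex", "f")
    return PatientProfile(**kw)


def _herb(hid, **kw):
    kw.setdefault("pinyin_name", hid.upper())
    kw.setdefault("compounds", frozenset())
    return Herb(hid, **kw)


class TestCheckContraindications:
    def test_blocklisted_toxin_vetoed(self):
        h = _herb("h1", toxicity_flags=frozenset({"contains:aconitine"}))
        v = check_contraindications(h, _profile())
        assert not v.approved and "aconitine" in v.reason

    def test_ephedrine_vetoed_by_default(self):
        h = _herb("h1", toxicity_flags=frozenset({"contains:ephedrine"}))
        assert not check_contraindications(h, _profile()).approved

    def test_condition_tag_match_vetoed(self):
        h = _herb("h1", contraindication_tags=frozenset({"hypertension"}))
        v = check_contraindications(h, _profile(conditions=frozenset({"Hypertension"})))
        assert not v.approved and "hypertension" in v.reason

    def test_clean_herb_approved(self):
        h = _herb("h1", temperature="warm")
        v = check_contraindications(h, _profile())
        assert v.approved and not v.warning

    def test_unannotated_herb_approved_with_warning(self):
        v = check_contraindications(_herb("h1"), _profile())
        assert v.approved and v.warning

    def test_blocklist_override(self):
        h = _herb("h1", toxicity_flags=frozenset({"contains:ephedrine"}))
        v = check_contraindications(h, _profile(), toxin_blocklist=frozenset({"aconitine"}))
        assert v.approved


class TestShortlist:
    def test_truncation_and_order(self, planted_db):
        db, sigs, truth = planted_db
        genes = sigs.signatures[0].gene_set
        top1 = shortlist_herbs(db, genes, size=1)
        assert top1 == [truth.top_herb]
        top5 = shortlist_herbs(db, genes, size=5)
        assert len(top5) == 5 and top5[0] == truth.top_herb

    def test_size_validation(self, planted_db):
        db, sigs, _ = planted_db
        with pytest.raises(ConfigError):
            shortlist_herbs(db, sigs.signatures[0].gene_set, size=0)


def _constructed_db():
    """Four herbs, each the unique optimum for its role.

    jun_h targets the most signature genes; chen_h covers the residual;
    zuo_h is the only toxin-free herb with temperature opposing hot;
    shi_h uniquely shares the liver meridian with jun_h at neutral temp.
    """
    genes = [f"G{i}" for i in range(10)]
    compounds = {
        "c_jun": Compound("c_jun", "", frozenset(genes[:6])),
        "c_chen": Compound("c_chen", "", frozenset(genes[6:10])),
        "c_weak1": Compound("c_weak1", "", frozenset(genes[:1])),
        "c_weak2": Compound("c_weak2", "", frozenset(genes[1:2])),
        "c_weak3": Compound("c_weak3", "", frozenset(genes[2:3])),
        "c_x": Compound("c_x", "", frozenset({genes[0], "OFF1"})),
    }
    herbs = {
        "jun_h": _herb("jun_h", compounds=frozenset({"c_jun", "c_weak1", "c_weak2", "c_weak3"}),
                       temperature="hot", meridians=frozenset({"liver"})),
        "chen_h": _herb("chen_h", compounds=frozenset({"c_chen", "c_weak1", "c_weak2"}),
                        temperature="hot", meridians=frozenset({"lung"})),
        "zuo_h": _herb("zuo_h", compounds=frozenset({"c_weak1", "c_weak2"}),
                       temperature="cold", meridians=frozenset({"spleen"})),
        "shi_h": _herb("shi_h", compounds=frozenset({"c_weak1"}),
                       temperature="neutral", meridians=frozenset({"liver"})),
        "filler": _herb("filler", compounds=frozenset({"c_x"}), temperature="hot"),
    }
    return TCMDatabase(compounds=compounds, herbs=herbs, formulas={}), frozenset(genes)


class TestComposePrescription:
    def test_constructed_optima_selected(self):
        db, genes = _constructed_db()
        p = compose_prescription(db, genes, _profile())
        assert p.assignments == {
            "jun": "jun_h", "chen": "chen_h", "zuo": "zuo_h", "shi": "shi_h"
        }

    def test_deterministic(self):
        db, genes = _constructed_db()
        p1 = compose_prescription(db, genes, _profile())
        p2 = compose_prescription(db, genes, _profile())
        assert p1.assignments == p2.assignments
        assert [r.herb_id for r in p1.audit] == [r.herb_id for r in p2.audit]

    def test_four_distinct_herbs(self):
        db, genes = _constructed_db()
        p = compose_prescription(db, genes, _profile())
        assert set(p.assignments) == set(ROLES)
        assert len(set(p.assignments.values())) == 4

    def test_veto_reroutes_selection(self):
        db, genes = _constructed_db()
        profile = _profile(conditions=frozenset({"migraine"}))
        db.herbs["jun_h"] = _herb(
            "jun_h", compounds=db.herbs["jun_h"].compounds,
            temperature="hot", meridians=frozenset({"liver"}),
            contraindication_tags=frozenset({"migraine"}),
        )
        p = compose_prescription(db, genes, profile)
        assert "jun_h" not in p.assignments.values()
        assert any(r.herb_id == "jun_h" and not r.approved for r in p.audit)

    def test_exhaustion_raises_with_complete_audit(self):
        db, genes = _constructed_db()
        profile = _profile(conditions=frozenset({"everything"}))
        for hid in list(db.herbs):
            h = db.herbs[hid]
            db.herbs[hid] = _herb(
                hid, compounds=h.compounds, temperature=h.temperature,
                meridians=h.meridians,
                contraindication_tags=frozenset({"everything"}),
            )
        with pytest.raises(CompositionError) as exc:
            compose_prescription(db, genes, profile)
        audit = exc.value.audit
        assert audit and all(not rec.approved for rec in audit)

    def test_termination_bound(self):
        db, genes = _constructed_db()
        cfg = ComposerConfig(max_veto_rounds=3)
        p = compose_prescription(db, genes, _profile(), cfg)
        assert len(p.audit) <= 4 * cfg.max_veto_rounds

    def test_mock_policy_injection_keeps_contract(self):
        """A custom policy slots into the loop; vetoes still apply."""
        db, genes = _constructed_db()

        def reverse_policy(db_, gs, prof, chosen, shortlist):
            return list(reversed(shortlist))

        cfg = ComposerConfig(policies={"jun": reverse_policy})
        p = compose_prescription(db, genes, _profile(), cfg)
        assert set(p.assignments) == set(ROLES)
        assert len(set(p.assignments.values())) == 4
        considered = {r.herb_id for r in p.audit}
        assert all(hid in considered for hid in p.assignments.values())

    def test_no_vetoed_herb_over_random_instances(self):
        """Random databases/profiles: prescriptions never contain vetoed herbs."""
        conditions = ["hypertension", "pregnancy", "liver disease", "diabetes"]
        composed = failed = 0
        for seed in range(25):
            cfg = SynthConfig(
                n_background_genes=800, n_compounds=120, n_herbs=25, n_formulas=5,
                signature_length=40, target_set_size=(3, 15),
                planted=(PlantedSignal(0, 15, 3),),
                annotation_fill=0.9, toxicity_rate=0.25, contraindication_rate=0.4,
                seed=1000 + seed,
            )
            db, sigs, _ = generate(cfg)
            profile = _profile(conditions=frozenset(conditions[seed % 4 :]))
            try:
                p = compose_prescription(db, sigs.signatures[0].gene_set, profile)
            except CompositionError as e:
                assert all(not r.approved for r in e.audit[-1:])
                failed += 1
                continue
            composed += 1
            assert len(set(p.assignments.values())) == 4
            vetoed = {r.herb_id for r in p.audit if not r.approved}
            assert vetoed.isdisjoint(p.assignments.values())
        assert composed > 0  # the contract must be exercised, not vacuous


class TestProfileAndConfig:
    def test_profile_normalization(self):
        p = PatientProfile(age=40, sex="F", conditions=frozenset({" Hypertension "}))
        assert p.sex == "f" and p.conditions == frozenset({"hypertension"})

    def test_profile_age_positive(self):
        with pytest.raises(ConfigError):
            PatientProfile(age=0, sex="m")

    def test_config_bounds(self):
        with pytest.raises(ConfigError):
            ComposerConfig(shortlist_size=3)
        with pytest.raises(ConfigError):
            ComposerConfig(max_veto_rounds=0)

    def test_prescription_serialization(self):
        db, genes = _constructed_db()
        p = compose_prescription(db, genes, _profile())
        doc = p.to_dict()
        assert set(doc["assignments"]) == set(ROLES)
        assert "NOT FOR CLINICAL USE" in doc["dosage_note"]
        md = p.to_markdown(db)
        assert "Jun (Monarch)" in md
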