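"""Database-wide screening and coverage rankings."""

import pytest
from hypothesis import given, settings, strategies as st

from gerotcm.datamodel import Compound, Formula, GeneSignature, Herb, TCMDatabase
from gerotcm.enrichment import EnrichmentConfig
from gerotcm.screening import (
    multi_tissue_compounds,
    rank_formulas_by_coverage,
    rank_herbs_by_coverage,
    rank_herbs_by_gene_targeting,
    screen_compounds,
)
from gerotcm.signatures import ContractError


def _sig(genes, tissue):
    return GeneSignature(species="human", tissue=tissue, direction="up", genes=tuple(genes))


def _multi_planted_db():
    """Three 10-gene signatures over a 200-gene universe; compound cA hits all
    three signatures, cB only the first, the rest are off-signature."""
    genes = [f"G{i:03d}" for i in range(200)]
    sigs = [_sig(genes[i * 10 : (i + 1) * 10], f"t{i}") for i in range(3)]
    all_sig = genes[:30]
    compounds = {
        "cA": Compound("cA", "everywhere", frozenset(genes[0:5] + genes[10:15] + genes[20:25])),
        "cB": Compound("cB", "one-tissue", frozenset(genes[0:5] + genes[100:110])),
    }
    for i in range(30):
        cid = f"n{i:02d}"
        compounds[cid] = Compound(cid, cid, frozenset(genes[60 + 2 * i : 62 + 2 * i]))
    db = TCMDatabase(compounds=compounds, herbs={}, formulas={})
    return db, sigs


class TestScreenCompounds:
    def test_empty_signature_set(self, toy_db):
        report = screen_compounds(toy_db, [], EnrichmentConfig())
        assert report.results == {} and report.significant == {}

    def test_planted_compounds_all_recovered(self, planted_db):
        db, sigs, truth = planted_db
        report = screen_compounds(db, sigs, EnrichmentConfig(alpha=0.01))
        label = sigs.signatures[0].label
        planted = truth.planted_compounds[0]
        assert planted <= report.significant[label]
        # false positives stay within a loose BH expectation
        assert len(report.significant[label] - planted) <= 5

    def test_significant_sets_order_invariant(self, planted_db):
        db, sigs, _ = planted_db
        reversed_db = TCMDatabase(
            compounds=dict(reversed(list(db.compounds.items()))),
            herbs=dict(db.herbs),
            formulas=dict(db.formulas),
        )
        r1 = screen_compounds(db, sigs, EnrichmentConfig())
        r2 = screen_compounds(reversed_db, sigs, EnrichmentConfig())
        assert r1.significant == r2.significant


class TestMultiTissueCompounds:
    def test_k1_is_union(self, planted_db):
        db, sigs, _ = planted_db
        report = screen_compounds(db, sigs, EnrichmentConfig())
        union = frozenset().union(*report.significant.values())
        assert multi_tissue_compounds(report, 1) == union

    def test_k2_selects_multi_signature_plants(self):
        db, sigs = _multi_planted_db()
        cfg = EnrichmentConfig(background_n=200, alpha=0.01)
        report = screen_compounds(db, sigs, cfg)
        assert multi_tissue_compounds(report, 2) == frozenset({"cA"})
        assert "cB" in multi_tissue_compounds(report, 1)

    def test_nesting_in_k(self):
        db, sigs = _multi_planted_db()
        report = screen_compounds(db, sigs, EnrichmentConfig(background_n=200))
        sets = [multi_tissue_compounds(report, k) for k in (1, 2, 3)]
        assert sets[2] <= sets[1] <= sets[0]

    def test_k_out_of_range(self):
        db, sigs = _multi_planted_db()
        report = screen_compounds(db, sigs, EnrichmentConfig(background_n=200))
        with pytest.raises(ContractError):
            multi_tissue_compounds(report, 4)


class TestFormulaCoverage:
    def test_empty_reference(self, toy_db):
        ranking = rank_formulas_by_coverage(toy_db, [])
        assert all(cnt == 0 for _, _, cnt in ranking.rows)

    def test_toy_example(self, toy_db):
        # F1 = herbA{c1,c2} + herbB{c3} vs {c1, c3, c9} -> covers c1, c3
        ranking = rank_formulas_by_coverage(toy_db, ["c1", "c3", "c9"])
        top_id, covered, count = ranking.rows[0]
        assert (top_id, count) == ("F1", 2)
        assert covered == frozenset({"c1", "c3"})

    def test_agrees_with_brute_force(self, planted_db):
        db, _, truth = planted_db
        ref = truth.planted_compounds[0]
        ranking = rank_formulas_by_coverage(db, ref)
        for fid, covered, count in ranking.rows:
            manual = set()
            for hid in db.formulas[fid].herbs:
                manual |= db.herbs[hid].compounds & ref
            assert covered == manual and count == len(manual)
        counts = [cnt for _, _, cnt in ranking.rows]
        assert counts == sorted(counts, reverse=True)

    def test_herb_coverage_ranking(self, toy_db):
        ranking = rank_herbs_by_coverage(toy_db, ["c2", "c4"])
        assert ranking.rows[0][:1] + (ranking.rows[0][2],) == ("herbC", 2)


class TestHerbGeneTargeting:
    def test_toy_counts(self, toy_db):
        # herbA: c1 targets SCD/LBP (hit), c2 targets ACSM1 (miss) -> score 1
        ranking = rank_herbs_by_gene_targeting(toy_db, ["SCD", "LBP", "NNMT"])
        scores = {hid: cnt for hid, _, cnt in ranking.rows}
        assert scores == {"herbA": 1, "herbB": 0, "herbC": 1}

    def test_zero_for_untargeting_herb(self, toy_db):
        ranking = rank_herbs_by_gene_targeting(toy_db, ["TP53"])
        scores = {hid: cnt for hid, _, cnt in ranking.rows}
        assert scores["herbA"] == 0 and scores["herbB"] == 1

    def test_constructed_top_herb_ranks_first(self, planted_db):
        db, sigs, truth = planted_db
        genes = sigs.signatures[truth.top_herb_signature].gene_set
        ranking = rank_herbs_by_gene_targeting(db, genes)
        assert ranking.rows[0][0] == truth.top_herb

    def test_distinct_gene_metric(self, toy_db):
        ranking = rank_herbs_by_gene_targeting(
            toy_db, ["SCD", "LBP", "NNMT"], metric="distinct-gene-count"
        )
        scores = {hid: cnt for hid, _, cnt in ranking.rows}
        assert scores["herbA"] == 2  # SCD and LBP via c1

    def test_empty_gene_set_rejected(self, toy_db):
        with pytest.raises(ContractError):
            rank_herbs_by_gene_targeting(toy_db, [])


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.data())
def test_adding_herb_never_decreases_coverage(data):
    """Formula coverage is monotone in the herb set."""
    n_compounds = data.draw(st.integers(3, 10))
    cids = [f"c{i}" for i in range(n_compounds)]
    compounds = {c: Compound(c, c, frozenset({"G1"})) for c in cids}
    herb_sets = data.draw(
        st.lists(st.sets(st.sampled_from(cids), min_size=1), min_size=2, max_size=5)
    )
    herbs = {
        f"h{i}": Herb(f"h{i}", f"H{i}", frozenset(s)) for i, s in enumerate(herb_sets)
    }
    ref = frozenset(data.draw(st.sets(st.sampled_from(cids))))
    base = frozenset(list(herbs)[:-1])
    db = TCMDatabase(
        compounds=compounds,
        herbs=herbs,
        formulas={
            "f_small": Formula("f_small", "S", base),
            "f_big": Formula("f_big", "B", base | {list(herbs)[-1]}),
        },
    )
    ranking = rank_formulas_by_coverage(db, ref)
    counts = {fid: cnt for fid, _, cnt in ranking.rows}
    assert counts["f_big"] >= counts["f_small"]
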