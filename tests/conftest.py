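import pytest

from gerotcm.datamodel import Compound, Formula, Herb, TCMDatabase
from gerotcm.synthetic import PlantedSignal, SynthConfig, generate


@pytest.fixture(scope="session")
def toy_db() -> TCMDatabase:
    """Hand-built database small enough to verify everything by eye.

    herbA = {c1, c2}, herbB = {c3}, herbC = {c2, c4};
    formula F1 = {herbA, herbB}, F2 = {herbC}.
    """
    compounds = {
        "c1": Compound("c1", "compound one", frozenset({"SCD", "LBP"})),
        "c2": Compound("c2", "compound two", frozenset({"ACSM1"})),
        "c3": Compound("c3", "compound three", frozenset({"TP53", "EGFR"})),
        "c4": Compound("c4", "compound four", frozenset({"NNMT", "CFD"})),
        "c9": Compound("c9", "orphan", frozenset({"BRCA1"})),
    }
    herbs = {
        "herbA": Herb("herbA", "HERB A", frozenset({"c1", "c2"}), temperature="hot",
                      meridians=frozenset({"liver"})),
        "herbB": Herb("herbB", "HERB B", frozenset({"c3"}), temperature="cold",
                      meridians=frozenset({"lung"})),
        "herbC": Herb("herbC", "HERB C", frozenset({"c2", "c4"}), temperature="neutral",
                      meridians=frozenset({"liver", "kidney"})),
    }
    formulas = {
        "F1": Formula("F1", "FORMULA ONE", frozenset({"herbA", "herbB"})),
        "F2": Formula("F2", "FORMULA TWO", frozenset({"herbC"})),
    }
    return TCMDatabase(compounds=compounds, herbs=herbs, formulas=formulas)


@pytest.fixture(scope="session")
def planted_db():
    """Synthetic database with 40 compounds planted for signature 0 (seed 11)."""
    cfg = SynthConfig(
        n_compounds=400,
        n_herbs=50,
        n_formulas=15,
        planted=(PlantedSignal(signature_index=0, n_compounds=40, overlap_boost=10),),
        plant_top_herb_for_signature=0,
        seed=11,
    )
    return generate(cfg)
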