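"""Seeded generator of synthetic TCM databases with planted ground truth.

Emulates the structure of a compound-target / herb-compound / formula-herb
database joined with herb annotations: compounds draw target genes uniformly
from a synthetic background universe (symbols ``G000001``...), herbs draw
compounds, formulas draw herbs.  Selected compounds can be *planted* as
enriched for a signature — a configurable number of that signature's genes
is forced into their target sets — giving every downstream module a known
ground truth: which compounds a screen must recover, which herb must rank
first for a gene set, how much two signatures overlap.

Background symbols are synthetic on purpose: the statistics only need set
cardinalities, and made-up symbols avoid accidental biological claims.
Identical seeds produce byte-identical databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    Compound,
    ConfigError,
    Formula,
    GeneSignature,
    Herb,
    TCMDatabase,
    VALID_TEMPERATURES,
)
from .signatures import SignatureSet

_TASTES = ("sweet", "bitter", "sour", "pungent", "salty", "bland")
_MERIDIANS = ("liver", "lung", "spleen", "kidney", "heart", "stomach", "bladder")
_CONDITIONS = ("hypertension", "pregnancy", "liver disease", "diabetes", "arrhythmia")
_TOXINS = ("contains:aconitine", "contains:ephedrine", "hepatotoxic", "nephrotoxic")


@dataclass(frozen=True)
class PlantedSignal:
    """Enrichment planted for one signature."""

    signature_index: int
    n_compounds: int
    #: number of signature genes forced into each planted compound's targets
    overlap_boost: int


@dataclass(frozen=True)
class SynthConfig:
    #: size of the gene universe; default mirrors the 25,332-gene background
    #: of the default enrichment configuration
    n_background_genes: int = 25_332
    n_compounds: int = 500
    target_set_size: tuple[int, int] = (5, 40)
    n_herbs: int = 60
    compounds_per_herb: tuple[int, int] = (3, 15)
    n_formulas: int = 25
    herbs_per_formula: tuple[int, int] = (2, 10)
    n_signatures: int = 3
    signature_length: int = 100
    planted: tuple[PlantedSignal, ...] = ()
    #: number of genes shared by every pair of signatures (a common core)
    cross_signature_overlap: int = 0
    #: probability that an herb carries TCM annotations
    annotation_fill: float = 0.7
    #: probability an annotated herb carries a toxicity flag
    toxicity_rate: float = 0.1
    #: probability an annotated herb carries a contraindication tag
    contraindication_rate: float = 0.15
    #: if set, herb H000001 is constructed to strictly lead the
    #: compound-count ranking for this signature's gene set
    plant_top_herb_for_signature: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", tuple(self.planted))
        for name in ("n_background_genes", "n_compounds", "n_herbs", "n_formulas",
                     "n_signatures", "signature_length"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.cross_signature_overlap > self.signature_length:
            raise ConfigError("cross_signature_overlap exceeds signature_length")
        if self.n_signatures * self.signature_length > self.n_background_genes:
            raise ConfigError("background too small for the requested signatures")
        for p in self.planted:
            if not 0 <= p.signature_index < self.n_signatures:
                raise ConfigError(f"planted signature index {p.signature_index} out of range")
            if p.overlap_boost > self.signature_length:
                raise ConfigError("overlap_boost exceeds signature_length")
            if p.overlap_boost > self.target_set_size[1]:
                raise ConfigError("overlap_boost exceeds maximum target set size")


@dataclass
class GroundTruth:
    """What the generator planted, for use as test oracles."""

    planted_compounds: dict[int, frozenset[str]] = field(default_factory=dict)
    signature_overlaps: dict[tuple[int, int], int] = field(default_factory=dict)
    top_herb: Optional[str] = None
    top_herb_signature: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "planted_compounds": {
                str(k): sorted(v) for k, v in self.planted_compounds.items()
            },
            "signature_overlaps": {
                f"{i},{j}": n for (i, j), n in self.signature_overlaps.items()
            },
            "top_herb": self.top_herb,
            "top_herb_signature": self.top_herb_signature,
        }


def _gene(i: int) -> str:
    return f"G{i:06d}"


def generate(config: SynthConfig) -> tuple[TCMDatabase, SignatureSet, GroundTruth]:
    """Generate a database, signature set and ground truth from a config.

    Raises ``ConfigError`` for infeasible configurations and ``AssertionError``
    if the generation-time self-audit finds the emitted database inconsistent
    with the recorded ground truth (which would be a generator bug).
    """
    rng = np.random.default_rng(config.seed)
    background = [_gene(i) for i in range(1, config.n_background_genes + 1)]
    bg_arr = np.array(background)

    # --- signatures: a shared core plus disjoint tissue-specific remainders
    core = list(rng.choice(bg_arr, size=config.cross_signature_overlap, replace=False))
    remaining = np.array(sorted(set(background) - set(core)))
    rest_len = config.signature_length - config.cross_signature_overlap
    picks = rng.choice(remaining, size=(config.n_signatures, rest_len), replace=False)
    signatures = []
    for s in range(config.n_signatures):
        genes = tuple(core) + tuple(picks[s])
        signatures.append(
            GeneSignature(
                species="human",
                tissue=f"synthetic-{s}",
                direction="up",
                genes=genes,
                source=f"synthetic(seed={config.seed})",
            )
        )
    sig_set = SignatureSet(signatures=signatures, label=f"synthetic-seed{config.seed}")

    truth = GroundTruth()
    for i in range(config.n_signatures):
        for j in range(i + 1, config.n_signatures):
            truth.signature_overlaps[(i, j)] = len(
                signatures[i].gene_set & signatures[j].gene_set
            )

    # --- compounds: null compounds draw targets uniformly from background
    lo, hi = config.target_set_size
    compound_ids = [f"C{i:05d}" for i in range(1, config.n_compounds + 1)]
    compounds: dict[str, Compound] = {}
    planted_for: dict[str, int] = {}  # compound id -> signature index
    cursor = 0
    for p in config.planted:
        for _ in range(p.n_compounds):
            if cursor >= len(compound_ids):
                raise ConfigError("more planted compounds than n_compounds")
            planted_for[compound_ids[cursor]] = p.signature_index
            cursor += 1
        truth.planted_compounds[p.signature_index] = frozenset(
            cid for cid, s in planted_for.items() if s == p.signature_index
        )

    boost_by_sig = {p.signature_index: p.overlap_boost for p in config.planted}
    for cid in compound_ids:
        size = int(rng.integers(lo, hi + 1))
        if cid in planted_for:
            s = planted_for[cid]
            boost = boost_by_sig[s]
            sig_genes = np.array(signatures[s].genes)
            forced = list(rng.choice(sig_genes, size=boost, replace=False))
            off_sig = np.array(sorted(set(background) - signatures[s].gene_set))
            n_rest = max(size - boost, 0)
            rest = list(rng.choice(off_sig, size=n_rest, replace=False))
            targets = frozenset(forced + rest)
        else:
            targets = frozenset(rng.choice(bg_arr, size=size, replace=False))
        compounds[cid] = Compound(cid, f"compound {cid}", targets)

    # --- herbs
    cid_arr = np.array(compound_ids)
    herbs: dict[str, Herb] = {}
    temps = sorted(VALID_TEMPERATURES)
    for i in range(1, config.n_herbs + 1):
        hid = f"H{i:06d}"
        k = int(rng.integers(config.compounds_per_herb[0], config.compounds_per_herb[1] + 1))
        k = min(k, len(compound_ids))
        members = set(rng.choice(cid_arr, size=k, replace=False))
        annotated = rng.random() < config.annotation_fill
        tox: set[str] = set()
        contra: set[str] = set()
        if annotated and rng.random() < config.toxicity_rate:
            tox.add(str(rng.choice(_TOXINS)))
        if annotated and rng.random() < config.contraindication_rate:
            contra.add(str(rng.choice(_CONDITIONS)))
        herbs[hid] = Herb(
            herb_id=hid,
            pinyin_name=f"HERB {i}",
            compounds=frozenset(members),
            temperature=str(rng.choice(temps)) if annotated else None,
            tastes=frozenset({str(rng.choice(_TASTES))}) if annotated else None,
            meridians=(
                frozenset(rng.choice(_MERIDIANS, size=2, replace=False)) if annotated else None
            ),
            toxicity_flags=frozenset(tox),
            animal_derived=bool(rng.random() < 0.08) if annotated else None,
            contraindication_tags=frozenset(contra),
        )

    # --- optional constructed ranking winner
    if config.plant_top_herb_for_signature is not None:
        s = config.plant_top_herb_for_signature
        planted_here = truth.planted_compounds.get(s, frozenset())
        if not planted_here:
            raise ConfigError("plant_top_herb requires planted compounds for that signature")
        top_id = "H000001"
        h = herbs[top_id]
        herbs[top_id] = Herb(
            herb_id=h.herb_id, pinyin_name=h.pinyin_name,
            compounds=h.compounds | planted_here,
            temperature=h.temperature, tastes=h.tastes, meridians=h.meridians,
            toxicity_flags=frozenset(), animal_derived=h.animal_derived,
            contraindication_tags=frozenset(),
        )
        truth.top_herb = top_id
        truth.top_herb_signature = s

    # --- formulas
    hid_arr = np.array(sorted(herbs))
    formulas: dict[str, Formula] = {}
    for i in range(1, config.n_formulas + 1):
        fid = f"F{i:04d}"
        k = int(rng.integers(config.herbs_per_formula[0], config.herbs_per_formula[1] + 1))
        k = min(k, len(herbs))
        members = frozenset(rng.choice(hid_arr, size=k, replace=False))
        formulas[fid] = Formula(fid, f"FORMULA {i}", members)

    db = TCMDatabase(compounds=compounds, herbs=herbs, formulas=formulas)
    _self_audit(db, signatures, truth, config)
    return db, sig_set, truth


def _count_targeting_compounds(db: TCMDatabase, hid: str, genes: frozenset[str]) -> int:
    return sum(1 for cid in db.herbs[hid].compounds if db.compounds[cid].targets & genes)


def _self_audit(
    db: TCMDatabase,
    signatures: Sequence[GeneSignature],
    truth: GroundTruth,
    config: SynthConfig,
) -> None:
    """Verify the emitted database is consistent with the ground truth."""
    for s, cids in truth.planted_compounds.items():
        boost = {p.signature_index: p.overlap_boost for p in config.planted}[s]
        for cid in cids:
            got = len(db.compounds[cid].targets & signatures[s].gene_set)
            assert got >= boost, f"planted compound {cid} overlaps only {got} < {boost}"
    if truth.top_herb is not None:
        genes = signatures[truth.top_herb_signature].gene_set
        scores = {h: _count_targeting_compounds(db, h, genes) for h in db.herbs}
        assert all(
            scores[truth.top_herb] > v for h, v in scores.items() if h != truth.top_herb
        ), "constructed top herb does not strictly lead the ranking"
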