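"""Core entity types and I/O for TCM compound/herb/formula databases.

The central container is :class:`TCMDatabase`, a cross-referenced collection
of compounds (each with a protein-target gene set), herbs (each a set of
compounds plus traditional annotations: thermal nature, taste, meridian
tropism, toxicity), and formulas (sets of herbs).  Databases load from a
native JSON document, from a synthetic-generator dump, or from a
BATMAN-TCM2-style relational dump with a configurable column mapping.

Gene symbols are normalized by uppercasing and whitespace-trimming only;
mitochondrial symbols such as ``MT-ND4L`` are kept verbatim and no
ortholog or alias mapping is applied, so human and mouse lists intersect
purely by symbol.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

VALID_SPECIES = frozenset({"human", "mouse", "macaque", "cross-species"})
VALID_DIRECTIONS = frozenset({"up", "down"})
VALID_TEMPERATURES = frozenset({"hot", "warm", "neutral", "cool", "cold"})


class DataError(ValueError):
    """Raised when an input file or record violates the data contract."""


class ConfigError(ValueError):
    """Raised for invalid configuration (unknown dialect, bad thresholds...)."""


def normalize_symbol(symbol: str) -> str:
    """Uppercase and trim a gene symbol.  ``'scd '`` -> ``'SCD'``."""
    return symbol.strip().upper()


def _dedup_keep_first(symbols: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for s in symbols:
        if s and s not in seen:
            seen.add(s)
            out.append(s)
    return out


@dataclass(frozen=True)
class GeneSignature:
    """An ordered list of gene symbols tagged by species, tissue and direction.

    ``genes`` preserves input order (signatures are ranked by importance);
    symbols are uppercase and unique.
    """

    species: str
    tissue: str
    direction: str
    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if self.species not in VALID_SPECIES:
            raise DataError(f"unknown species {self.species!r}")
        if self.direction not in VALID_DIRECTIONS:
            raise DataError(f"direction must be 'up' or 'down', got {self.direction!r}")
        norm = _dedup_keep_first(normalize_symbol(g) for g in self.genes)
        if not norm:
            raise DataError("signature has no genes")
        object.__setattr__(self, "genes", tuple(norm))

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    @property
    def label(self) -> str:
        return f"{self.species}:{self.tissue}:{self.direction}"

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class Compound:
    compound_id: str
    name: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "targets", frozenset(normalize_symbol(t) for t in self.targets if t.strip())
        )


@dataclass(frozen=True)
class Herb:
    """An herb: a set of constituent compounds plus TCM annotations.

    Annotation fields default to ``None`` meaning *unknown*, never to a safe
    value; consumers that require an annotation must treat ``None`` as
    ineligible or flag it, not assume neutrality.
    """

    herb_id: str
    pinyin_name: str
    compounds: frozenset[str]
    temperature: Optional[str] = None
    tastes: Optional[frozenset[str]] = None
    meridians: Optional[frozenset[str]] = None
    toxicity_flags: frozenset[str] = frozenset()
    animal_derived: Optional[bool] = None
    contraindication_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pinyin_name", self.pinyin_name.strip().upper())
        object.__setattr__(self, "compounds", frozenset(self.compounds))
        if self.temperature is not None and self.temperature not in VALID_TEMPERATURES:
            raise DataError(f"herb {self.herb_id}: unknown temperature {self.temperature!r}")
        for attr in ("tastes", "meridians"):
            v = getattr(self, attr)
            if v is not None:
                object.__setattr__(self, attr, frozenset(x.strip().lower() for x in v))
        object.__setattr__(
            self, "toxicity_flags", frozenset(x.strip().lower() for x in self.toxicity_flags)
        )
        object.__setattr__(
            self,
            "contraindication_tags",
            frozenset(x.strip().lower() for x in self.contraindication_tags),
        )


@dataclass(frozen=True)
class Formula:
    formula_id: str
    name: str
    herbs: frozenset[str]
    source_text: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", self.name.strip().upper())
        object.__setattr__(self, "herbs", frozenset(self.herbs))
        if not self.herbs:
            raise DataError(f"formula {self.formula_id} has no herbs")


@dataclass
class TCMDatabase:
    """Cross-referenced compounds, herbs and formulas with reverse indexes.

    Referential integrity is enforced at construction: herbs referencing
    unknown compounds and formulas referencing unknown herbs are rejected.
    Reverse indexes (target gene -> compounds, compound -> herbs,
    herb -> formulas) are built eagerly and always agree with the forward
    maps.
    """

    compounds: dict[str, Compound] = field(default_factory=dict)
    herbs: dict[str, Herb] = field(default_factory=dict)
    formulas: dict[str, Formula] = field(default_factory=dict)
    dropped_records: int = 0

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self.target_to_compounds: dict[str, set[str]] = {}
        self.compound_to_herbs: dict[str, set[str]] = {}
        self.herb_to_formulas: dict[str, set[str]] = {}
        for cid, c in self.compounds.items():
            for t in c.targets:
                self.target_to_compounds.setdefault(t, set()).add(cid)
        for hid, h in self.herbs.items():
            for cid in h.compounds:
                if cid not in self.compounds:
                    raise DataError(f"herb {hid} references unknown compound {cid}")
                self.compound_to_herbs.setdefault(cid, set()).add(hid)
        for fid, f in self.formulas.items():
            for hid in f.herbs:
                if hid not in self.herbs:
                    raise DataError(f"formula {fid} references unknown herb {hid}")
                self.herb_to_formulas.setdefault(hid, set()).add(fid)

    def herb_targets(self, herb_id: str) -> frozenset[str]:
        """Union of target genes over an herb's compounds."""
        h = self.herbs[herb_id]
        out: set[str] = set()
        for cid in h.compounds:
            out |= self.compounds[cid].targets
        return frozenset(out)

    def formula_compounds(self, formula_id: str) -> frozenset[str]:
        """Union of compound ids over a formula's herbs."""
        f = self.formulas[formula_id]
        out: set[str] = set()
        for hid in f.herbs:
            out |= self.herbs[hid].compounds
        return frozenset(out)

    def summary(self) -> dict[str, int]:
        return {
            "compounds": len(self.compounds),
            "herbs": len(self.herbs),
            "formulas": len(self.formulas),
            "dropped_records": self.dropped_records,
        }


def _build_database(
    compounds: Sequence[Compound],
    herbs: Sequence[Herb],
    formulas: Sequence[Formula],
) -> TCMDatabase:
    """Assemble a database, dropping entities that break referential integrity."""
    dropped = 0
    cmap = {c.compound_id: c for c in compounds}
    hmap: dict[str, Herb] = {}
    for h in herbs:
        missing = h.compounds - cmap.keys()
        if missing:
            logger.warning("dropping herb %s: unknown compounds %s", h.herb_id, sorted(missing))
            dropped += 1
            continue
        hmap[h.herb_id] = h
    fmap: dict[str, Formula] = {}
    for f in formulas:
        missing = f.herbs - hmap.keys()
        if missing:
            logger.warning("dropping formula %s: unknown herbs %s", f.formula_id, sorted(missing))
            dropped += 1
            continue
        fmap[f.formula_id] = f
    if not cmap:
        raise DataError("database contains no valid compounds")
    return TCMDatabase(compounds=cmap, herbs=hmap, formulas=fmap, dropped_records=dropped)


# ---------------------------------------------------------------------------
# Native JSON dialect


def _herb_from_record(rec: Mapping) -> Herb:
    def fset(key):
        v = rec.get(key)
        return None if v is None else frozenset(v)

    return Herb(
        herb_id=rec["herb_id"],
        pinyin_name=rec.get("pinyin_name", rec["herb_id"]),
        compounds=frozenset(rec.get("compounds", ())),
        temperature=rec.get("temperature"),
        tastes=fset("tastes"),
        meridians=fset("meridians"),
        toxicity_flags=frozenset(rec.get("toxicity_flags", ())),
        animal_derived=rec.get("animal_derived"),
        contraindication_tags=frozenset(rec.get("contraindication_tags", ())),
    )


def _load_native_json(doc: Mapping) -> TCMDatabase:
    compounds = [
        Compound(rec["compound_id"], rec.get("name", rec["compound_id"]), frozenset(rec["targets"]))
        for rec in doc.get("compounds", ())
    ]
    herbs = [_herb_from_record(rec) for rec in doc.get("herbs", ())]
    formulas = [
        Formula(
            rec["formula_id"],
            rec.get("name", rec["formula_id"]),
            frozenset(rec["herbs"]),
            rec.get("source_text"),
        )
        for rec in doc.get("formulas", ())
    ]
    return _build_database(compounds, herbs, formulas)


def database_to_dict(db: TCMDatabase) -> dict:
    """Serialize a database to the native JSON document structure.

    Output is canonical: entities and set members are sorted, so
    serialization is deterministic and load/write round-trips are
    byte-identical.
    """
    out: dict = {"compounds": [], "herbs": [], "formulas": []}
    for cid in sorted(db.compounds):
        c = db.compounds[cid]
        out["compounds"].append(
            {"compound_id": c.compound_id, "name": c.name, "targets": sorted(c.targets)}
        )
    for hid in sorted(db.herbs):
        h = db.herbs[hid]
        rec = {
            "herb_id": h.herb_id,
            "pinyin_name": h.pinyin_name,
            "compounds": sorted(h.compounds),
            "temperature": h.temperature,
            "tastes": None if h.tastes is None else sorted(h.tastes),
            "meridians": None if h.meridians is None else sorted(h.meridians),
            "toxicity_flags": sorted(h.toxicity_flags),
            "animal_derived": h.animal_derived,
            "contraindication_tags": sorted(h.contraindication_tags),
        }
        out["herbs"].append(rec)
    for fid in sorted(db.formulas):
        f = db.formulas[fid]
        out["formulas"].append(
            {
                "formula_id": f.formula_id,
                "name": f.name,
                "herbs": sorted(f.herbs),
                "source_text": f.source_text,
            }
        )
    return out


def write_database(db: TCMDatabase, path: str | Path) -> None:
    """Write a database as native JSON (canonical ordering, 2-space indent)."""
    Path(path).write_text(json.dumps(database_to_dict(db), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# BATMAN-TCM2-style relational dump


DEFAULT_BATMAN2_COLUMNS = {
    "compound_id": "compound_id",
    "compound_name": "compound_name",
    "target_symbol": "target_symbol",
    "herb_pinyin": "herb_pinyin",
    "formula_pinyin": "formula_pinyin",
}


def _load_batman2_dump(path: Path, column_map: Optional[Mapping[str, str]] = None) -> TCMDatabase:
    """Load a flat TSV of formula/herb/compound/target cross-references.

    One row per (formula, herb, compound, target) link; empty cells mean the
    link level is absent (e.g. an herb-compound row with no formula).  Column
    names are remappable because hosted dump versions differ from the
    original web release.
    """
    import pandas as pd

    cols = dict(DEFAULT_BATMAN2_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ConfigError(f"dump is missing columns {missing}; supply a column_map")

    targets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    herb_compounds: dict[str, set[str]] = {}
    formula_herbs: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        cid = rec[cols["compound_id"]].strip()
        if cid:
            targets.setdefault(cid, set())
            if rec[cols["compound_name"]].strip():
                names[cid] = rec[cols["compound_name"]].strip()
            t = rec[cols["target_symbol"]].strip()
            if t:
                targets[cid].add(t)
        herb = rec[cols["herb_pinyin"]].strip().upper()
        if herb and cid:
            herb_compounds.setdefault(herb, set()).add(cid)
        formula = rec[cols["formula_pinyin"]].strip().upper()
        if formula and herb:
            formula_herbs.setdefault(formula, set()).add(herb)

    compounds = [Compound(cid, names.get(cid, cid), frozenset(ts)) for cid, ts in targets.items()]
    herbs = [Herb(h, h, frozenset(cs)) for h, cs in herb_compounds.items()]
    formulas = [Formula(f, f, frozenset(hs)) for f, hs in formula_herbs.items()]
    return _build_database(compounds, herbs, formulas)


def load_database(
    path: str | Path,
    dialect: str = "native-json",
    column_map: Optional[Mapping[str, str]] = None,
) -> TCMDatabase:
    """Load a TCM database from disk.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``native-json`` / ``synthetic-json`` (same JSON document structure) or
        ``batman2-dump`` (flat TSV of cross-references).
    column_map
        Optional column-name remapping for the ``batman2-dump`` dialect.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if dialect in ("native-json", "synthetic-json"):
        with open(path) as fh:
            return _load_native_json(json.load(fh))
    if dialect == "batman2-dump":
        return _load_batman2_dump(path, column_map)
    raise ConfigError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Signature files


def read_signature(
    path: str | Path,
    species: str = "human",
    tissue: str = "",
    direction: str = "up",
    source: str = "",
) -> GeneSignature:
    """Read a gene signature from a bare gene list or a 5-column TSV.

    Bare lists are one symbol per line.  TSV files carry columns
    ``species  tissue  direction  rank  gene_symbol`` (header optional);
    the species/tissue/direction arguments then act as filters when the
    file mixes several signatures, and as defaults otherwise.  Symbols are
    uppercased, trimmed, and deduplicated keeping first occurrence.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in (ln.strip() for ln in text.splitlines()) if ln and not ln.startswith("#")]
    if not lines:
        raise DataError(f"empty signature file: {path}")
    if "\t" in lines[0]:
        rows = [ln.split("\t") for ln in lines]
        if rows[0][0].lower() == "species":
            rows = rows[1:]
        genes = []
        for r in rows:
            if len(r) < 5:
                raise DataError(f"signature TSV row has {len(r)} columns, expected 5: {r}")
            sp, ts, dr, _rank, gene = (x.strip() for x in r[:5])
            if species and sp and sp != species:
                continue
            if tissue and ts and ts != tissue:
                continue
            if dr and dr != direction:
                continue
            genes.append(gene)
            if not tissue:
                tissue = ts
        if not genes:
            raise DataError(f"no rows in {path} match species={species} tissue={tissue}")
    else:
        genes = lines
    return GeneSignature(
        species=species,
        tissue=tissue or path.stem,
        direction=direction,
        genes=tuple(genes),
        source=source or str(path),
    )


def write_signature_tsv(sig: GeneSignature, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\ttissue\tdirection\trank\tgene_symbol\n")
        for i, g in enumerate(sig.genes, start=1):
            fh.write(f"{sig.species}\t{sig.tissue}\t{sig.direction}\t{i}\t{g}\n")


_TABLE1_TISSUES = ("liver", "lung", "muscle")


def load_packaged_signature(tissue: str) -> GeneSignature:
    """Load one of the packaged cross-species aging signatures.

    These are the liver (33 genes), lung (27) and muscle (22) lists of genes
    upregulated with age in both humans and mice, shipped with the package.
    """
    if tissue not in _TABLE1_TISSUES:
        raise ConfigError(f"no packaged signature for tissue {tissue!r}; have {_TABLE1_TISSUES}")
    ref = resources.files("gerotcm.data").joinpath(f"table1_{tissue}.txt")
    genes = tuple(ln.strip() for ln in ref.read_text().splitlines() if ln.strip())
    return GeneSignature(
        species="cross-species",
        tissue=tissue,
        direction="up",
        genes=genes,
        source=f"packaged:table1_{tissue}",
    )


def load_packaged_signatures() -> list[GeneSignature]:
    """All three packaged cross-species signatures (liver, lung, muscle)."""
    return [load_packaged_signature(t) for t in _TABLE1_TISSUES]
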