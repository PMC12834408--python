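"""Rule-of-Four (Jun-Chen-Zuo-Shi) prescription composition.

A prescription assigns four distinct herbs to the four traditional roles:
Jun (Monarch, primary therapeutic action), Chen (Minister, secondary
targets), Zuo (Assistant, attenuates adverse effects) and Shi (Envoy,
balances the formula and directs it to a meridian).  Herbs are drawn from a
shortlist ranked by how many of their compounds target the supplied gene
set.  Every candidate passes a contraindication check against the patient
profile and a toxin blocklist; a vetoed herb triggers reselection, up to a
per-role round cap.  All verdicts are kept in an audit trail.

Role selection is a pluggable policy interface.  The default policies are
deterministic heuristics, so the whole loop is testable without a language
model; an LLM-backed policy can be injected through the same interface.

The emitted prescription is a research artifact, not medical advice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .datamodel import ConfigError, Herb, TCMDatabase
from .screening import rank_herbs_by_gene_targeting

ROLES = ("jun", "chen", "zuo", "shi")

#: Substances whose presence in an herb always triggers a veto by default.
#: Overridable via ComposerConfig.toxin_blocklist.
DEFAULT_TOXIN_BLOCKLIST = frozenset({"ephedrine", "aconitine"})

_OPPOSING_TEMPERATURE = {
    "hot": {"cold", "cool"},
    "warm": {"cool", "cold"},
    "cool": {"warm", "hot"},
    "cold": {"hot", "warm"},
    "neutral": set(),
}


class CompositionError(RuntimeError):
    """Raised when veto rounds are exhausted for a role; carries the audit."""

    def __init__(self, message: str, audit: list["VetoRecord"]):
        super().__init__(message)
        self.audit = audit


@dataclass(frozen=True)
class PatientProfile:
    age: float
    sex: str
    conditions: frozenset[str] = frozenset()
    complaints: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ConfigError("age must be positive")
        object.__setattr__(self, "sex", self.sex.strip().lower())
        object.__setattr__(
            self, "conditions", frozenset(c.strip().lower() for c in self.conditions)
        )
        object.__setattr__(
            self, "complaints", frozenset(c.strip().lower() for c in self.complaints)
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PatientProfile":
        return cls(
            age=d["age"],
            sex=d.get("sex", "unspecified"),
            conditions=frozenset(d.get("conditions", ())),
            complaints=frozenset(d.get("complaints", ())),
        )


@dataclass(frozen=True)
class Verdict:
    approved: bool
    reason: str = ""
    warning: str = ""  # set when annotations were absent and approval is provisional


@dataclass(frozen=True)
class VetoRecord:
    herb_id: str
    role: str
    approved: bool
    reason: str
    round: int


# A role policy ranks the remaining candidate herb ids (most preferred
# first) given the database, gene set, profile, and herbs chosen so far.
RolePolicy = Callable[
    [TCMDatabase, frozenset[str], PatientProfile, dict[str, str], Sequence[str]],
    list[str],
]


@dataclass(frozen=True)
class ComposerConfig:
    shortlist_size: int = 20
    max_veto_rounds: int = 5
    toxin_blocklist: frozenset[str] = DEFAULT_TOXIN_BLOCKLIST
    policies: Optional[dict[str, RolePolicy]] = None

    def __post_init__(self) -> None:
        if self.shortlist_size < 4:
            raise ConfigError("shortlist_size must be >= 4")
        if self.max_veto_rounds < 1:
            raise ConfigError("max_veto_rounds must be >= 1")
        object.__setattr__(
            self, "toxin_blocklist", frozenset(t.lower() for t in self.toxin_blocklist)
        )


@dataclass
class Prescription:
    """Four role-labelled herbs with rationale and the full veto audit."""

    assignments: dict[str, str]  # role -> herb_id
    profile: PatientProfile
    rationale: dict[str, str] = field(default_factory=dict)
    audit: list[VetoRecord] = field(default_factory=list)
    dosage_note: str = (
        "Dosage and course duration are template placeholders derived from "
        "herb annotations. NOT FOR CLINICAL USE: this composition is a "
        "computational research output and has not been validated in any "
        "laboratory or clinical setting."
    )

    def to_dict(self) -> dict:
        return {
            "assignments": dict(self.assignments),
            "patient": {
                "age": self.profile.age,
                "sex": self.profile.sex,
                "conditions": sorted(self.profile.conditions),
                "complaints": sorted(self.profile.complaints),
            },
            "rationale": dict(self.rationale),
            "audit": [
                {
                    "herb_id": r.herb_id,
                    "role": r.role,
                    "approved": r.approved,
                    "reason": r.reason,
                    "round": r.round,
                }
                for r in self.audit
            ],
            "dosage_note": self.dosage_note,
        }

    def to_markdown(self, db: TCMDatabase) -> str:
        lines = ["# Prescription (Rule of Four)", ""]
        role_names = {"jun": "Jun (Monarch)", "chen": "Chen (Minister)",
                      "zuo": "Zuo (Assistant)", "shi": "Shi (Envoy)"}
        for role in ROLES:
            hid = self.assignments[role]
            herb = db.herbs[hid]
            lines.append(f"## {role_names[role]}: {herb.pinyin_name}")
            lines.append(self.rationale.get(role, ""))
            lines.append("")
        lines.append(f"> {self.dosage_note}")
        return "\n".join(lines)


def shortlist_herbs(
    db: TCMDatabase,
    gene_set: Iterable[str],
    size: int = 20,
) -> list[str]:
    """Top herbs ranked by number of compounds targeting the gene set."""
    if size < 1:
        raise ConfigError("size must be >= 1")
    ranking = rank_herbs_by_gene_targeting(db, gene_set)
    ranked = [eid for eid, _, cnt in ranking.rows if cnt > 0]
    return ranked[:size]


def check_contraindications(
    herb: Herb,
    profile: PatientProfile,
    toxin_blocklist: frozenset[str] = DEFAULT_TOXIN_BLOCKLIST,
) -> Verdict:
    """Approve or veto an herb for a patient.

    Veto if any contraindication tag matches a patient condition, or if any
    toxicity flag names a blocklisted substance (matched as substring, so
    the flag ``contains:aconitine`` trips the ``aconitine`` entry).  An herb
    with no annotations at all is approved with a warning — absence of
    evidence is surfaced, never treated as safety.
    """
    hits = herb.contraindication_tags & profile.conditions
    if hits:
        return Verdict(False, f"contraindicated for condition(s): {', '.join(sorted(hits))}")
    for flag in herb.toxicity_flags:
        for toxin in sorted(toxin_blocklist):
            if toxin in flag:
                return Verdict(False, f"blocklisted toxin: {toxin} (flag {flag!r})")
    if (
        not herb.contraindication_tags
        and not herb.toxicity_flags
        and herb.temperature is None
    ):
        return Verdict(True, "no annotation conflicts", warning="herb annotations absent")
    return Verdict(True, "no annotation conflicts")


# ---------------------------------------------------------------------------
# Default role policies.  Each returns candidate herb ids, most preferred
# first; the veto loop walks the list.  `chosen` maps role -> herb_id for
# roles already filled.


def _herb_genes(db: TCMDatabase, hid: str, gene_set: frozenset[str]) -> frozenset[str]:
    return db.herb_targets(hid) & gene_set


def _policy_jun(db, gene_set, profile, chosen, shortlist):
    return list(shortlist)


def _policy_chen(db, gene_set, profile, chosen, shortlist):
    """Maximize coverage of signature genes Jun leaves uncovered."""
    jun_genes = _herb_genes(db, chosen["jun"], gene_set) if "jun" in chosen else frozenset()
    residual = gene_set - jun_genes
    order = {h: i for i, h in enumerate(shortlist)}
    return sorted(
        shortlist,
        key=lambda h: (-len(_herb_genes(db, h, residual)), order[h]),
    )


def _policy_zuo(db, gene_set, profile, chosen, shortlist):
    """Prefer non-toxic herbs whose thermal nature opposes Jun/Chen."""
    temps = [
        db.herbs[chosen[r]].temperature
        for r in ("jun", "chen")
        if r in chosen and db.herbs[chosen[r]].temperature is not None
    ]
    # sorted() keeps tie-breaks independent of set iteration order
    majority = max(sorted(set(temps)), key=temps.count) if temps else None
    opposing = _OPPOSING_TEMPERATURE.get(majority, set()) if majority else set()
    order = {h: i for i, h in enumerate(shortlist)}

    def key(h):
        herb = db.herbs[h]
        opposes = herb.temperature in opposing if herb.temperature else False
        return (not opposes, len(herb.toxicity_flags) > 0, order[h])

    return sorted(shortlist, key=key)


def _policy_shi(db, gene_set, profile, chosen, shortlist):
    """Prefer herbs sharing a meridian with Jun, then neutral temperature."""
    jun_meridians = (
        db.herbs[chosen["jun"]].meridians if "jun" in chosen else None
    ) or frozenset()
    order = {h: i for i, h in enumerate(shortlist)}

    def key(h):
        herb = db.herbs[h]
        shares = bool((herb.meridians or frozenset()) & jun_meridians)
        neutral = herb.temperature == "neutral"
        return (not shares, not neutral, order[h])

    return sorted(shortlist, key=key)


DEFAULT_POLICIES: dict[str, RolePolicy] = {
    "jun": _policy_jun,
    "chen": _policy_chen,
    "zuo": _policy_zuo,
    "shi": _policy_shi,
}

_ROLE_DESCRIPTIONS = {
    "jun": "primary action: highest-ranked approved herb on the target gene set",
    "chen": "secondary action: best coverage of target genes left by Jun",
    "zuo": "harmonizing: thermal nature opposing Jun/Chen, minimal toxicity",
    "shi": "guiding: shares a meridian with Jun, preferring neutral nature",
}


def compose_prescription(
    db: TCMDatabase,
    gene_set: Iterable[str],
    profile: PatientProfile,
    config: Optional[ComposerConfig] = None,
) -> Prescription:
    """Assemble a four-herb prescription for a patient.

    Roles are filled sequentially (Jun, Chen, Zuo, Shi).  For each role the
    policy ranks the unchosen shortlist herbs; candidates are checked for
    contraindications in order, with at most ``max_veto_rounds`` candidates
    considered per role.  Exhaustion raises :class:`CompositionError`
    carrying the complete audit trail.
    """
    config = config or ComposerConfig()
    genes = frozenset(gene_set)
    shortlist = shortlist_herbs(db, genes, config.shortlist_size)
    if not shortlist:
        raise CompositionError("shortlist is empty: no herb targets the gene set", [])
    policies = dict(DEFAULT_POLICIES)
    if config.policies:
        policies.update(config.policies)

    chosen: dict[str, str] = {}
    audit: list[VetoRecord] = []
    rationale: dict[str, str] = {}

    for role in ROLES:
        remaining = [h for h in shortlist if h not in chosen.values()]
        candidates = policies[role](db, genes, profile, chosen, remaining)
        selected = None
        for rnd, hid in enumerate(candidates[: config.max_veto_rounds], start=1):
            verdict = check_contraindications(
                db.herbs[hid], profile, config.toxin_blocklist
            )
            audit.append(VetoRecord(hid, role, verdict.approved, verdict.reason, rnd))
            if verdict.approved:
                selected = hid
                covered = sorted(_herb_genes(db, hid, genes))
                note = f" [{verdict.warning}]" if verdict.warning else ""
                rationale[role] = (
                    f"{_ROLE_DESCRIPTIONS[role]}; targets {len(covered)} signature "
                    f"gene(s): {', '.join(covered) if covered else 'none'}{note}"
                )
                break
        if selected is None:
            raise CompositionError(
                f"veto rounds exhausted for role {role!r} "
                f"({min(len(candidates), config.max_veto_rounds)} candidates vetoed)",
                audit,
            )
        chosen[role] = selected

    return Prescription(assignments=chosen, profile=profile, rationale=rationale, audit=audit)
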