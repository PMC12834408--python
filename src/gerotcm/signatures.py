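"""Set algebra over gene signatures.

Cross-species conservation (genes present in both the human and mouse list
for a tissue), cross-tissue sharing (genes present in at least *k* of a set
of signatures), and the container type :class:`SignatureSet`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .datamodel import DataError, GeneSignature


class ContractError(ValueError):
    """Raised when operation preconditions are violated."""


@dataclass
class SignatureSet:
    """A labelled collection of signatures sharing a direction.

    (species, tissue) pairs must be unique within the set.
    """

    signatures: list[GeneSignature]
    label: str = ""

    def __post_init__(self) -> None:
        if self.signatures:
            directions = {s.direction for s in self.signatures}
            if len(directions) > 1:
                raise DataError(f"mixed directions in signature set: {sorted(directions)}")
            keys = [(s.species, s.tissue) for s in self.signatures]
            if len(set(keys)) != len(keys):
                raise DataError("duplicate (species, tissue) pair in signature set")

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)


def cross_species_intersect(human_sig: GeneSignature, mouse_sig: GeneSignature) -> GeneSignature:
    """Genes conserved between a human and a mouse signature of one tissue.

    The result keeps the human list's order (lists are ranked by importance)
    and is tagged species ``cross-species``.  Tissue and direction must
    match.
    """
    if human_sig.tissue != mouse_sig.tissue:
        raise ContractError(
            f"tissue mismatch: {human_sig.tissue!r} vs {mouse_sig.tissue!r}"
        )
    if human_sig.direction != mouse_sig.direction:
        raise ContractError(
            f"direction mismatch: {human_sig.direction!r} vs {mouse_sig.direction!r}"
        )
    mouse_genes = mouse_sig.gene_set
    shared = tuple(g for g in human_sig.genes if g in mouse_genes)
    if not shared:
        # empty signatures are not representable; callers get the marker type
        return EmptySignature(
            species="cross-species",
            tissue=human_sig.tissue,
            direction=human_sig.direction,
        )
    return GeneSignature(
        species="cross-species",
        tissue=human_sig.tissue,
        direction=human_sig.direction,
        genes=shared,
        source=f"intersect({human_sig.source} ∩ {mouse_sig.source})",
    )


@dataclass(frozen=True)
class EmptySignature:
    """Marker for an empty intersection (a GeneSignature may not be empty)."""

    species: str
    tissue: str
    direction: str
    genes: tuple[str, ...] = ()
    source: str = ""

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset()

    def __len__(self) -> int:
        return 0


@dataclass
class SharedGenes:
    """Result of a k-of-n membership selection over a signature set."""

    k: int
    #: (gene, count, member tissue labels) sorted by count desc then gene.
    rows: list[tuple[str, int, tuple[str, ...]]] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return [g for g, _, _ in self.rows]

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.rows)


def genes_in_k_signatures(signature_set: SignatureSet | list[GeneSignature], k: int) -> SharedGenes:
    """Genes present in at least ``k`` of the signatures.

    ``k=1`` is the union, ``k=n`` the n-way intersection.  Output is sorted
    by membership count (descending) then lexicographically, so results are
    deterministic regardless of input order.
    """
    sigs = list(signature_set)
    if not 1 <= k <= len(sigs):
        raise ContractError(f"k={k} out of range for {len(sigs)} signatures")
    counts: Counter[str] = Counter()
    members: dict[str, list[str]] = {}
    for sig in sigs:
        for g in sig.gene_set:
            counts[g] += 1
            members.setdefault(g, []).append(sig.tissue)
    rows = [
        (g, c, tuple(sorted(members[g])))
        for g, c in counts.items()
        if c >= k
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return SharedGenes(k=k, rows=rows)
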