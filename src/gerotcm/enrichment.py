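"""One-sided Fisher exact enrichment of compound target sets.

Each compound is tested against a gene signature over a fixed gene universe
(default 25,332 genes, the number of distinct genes the signature generator
can emit).  The 2x2 table is

    =====================  ============  ===============
                           in signature  not in signature
    ---------------------  ------------  ---------------
    in target set          a             b
    not in target set      c             d
    =====================  ============  ===============

with ``d`` filled in from the universe size.  The one-sided (enrichment)
p-value is the upper hypergeometric tail ``P(X >= a)`` with population
``background_n``, ``|signature|`` successes, and ``|targets|`` draws.
Families of raw p-values are corrected with Benjamini-Hochberg (default) or
Bonferroni; compounds with no in-universe targets are untestable and are
excluded from the correction family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ConfigError

CORRECTIONS = ("benjamini-hochberg", "bonferroni", "none")

#: Size of the default gene universe: the number of distinct genes the
#: transcriptomic signature generator can produce.
DEFAULT_BACKGROUND_N = 25_332


@dataclass(frozen=True)
class EnrichmentConfig:
    """Parameters of the enrichment screen.

    alpha applies to the *adjusted* p-value.  Two presets mirror the two
    screening regimes: 0.01 for cross-species screens, 0.001 for
    multi-tissue screens (see :func:`preset`).
    """

    background_n: int = DEFAULT_BACKGROUND_N
    alpha: float = 0.01
    correction: str = "benjamini-hochberg"
    restrict_to_background: bool = True
    background_genes: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if self.background_n <= 0:
            raise ConfigError("background_n must be positive")
        if self.correction not in CORRECTIONS:
            raise ConfigError(f"correction must be one of {CORRECTIONS}")
        if self.background_genes is not None:
            object.__setattr__(self, "background_genes", frozenset(self.background_genes))


def preset(name: str) -> EnrichmentConfig:
    """Named screen configurations: ``cross-species`` or ``multi-tissue``."""
    if name == "cross-species":
        return EnrichmentConfig(alpha=0.01)
    if name == "multi-tissue":
        return EnrichmentConfig(alpha=0.001)
    raise ConfigError(f"unknown preset {name!r}")


@dataclass
class EnrichmentResult:
    """One compound x signature test."""

    compound_id: str
    signature: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float  # inf when b*c == 0 and a*d > 0; nan when 0/0
    p_raw: float
    p_adjusted: Optional[float] = None
    significant: Optional[bool] = None
    untestable: bool = False

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    num, den = a * d, b * c
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def fisher_enrichment(
    targets: Iterable[str],
    signature_genes: Iterable[str],
    config: EnrichmentConfig,
    compound_id: str = "",
    signature_label: str = "",
) -> EnrichmentResult:
    """One-sided Fisher exact test of a target set against a signature.

    When an explicit background gene list is configured (and restriction is
    on), both sets are first intersected with it.  An empty target or
    signature set after restriction yields an untestable result with
    ``a=0, p_raw=1``.
    """
    tset = frozenset(targets)
    sset = frozenset(signature_genes)
    if config.restrict_to_background and config.background_genes is not None:
        tset &= config.background_genes
        sset &= config.background_genes
    n = config.background_n
    if len(sset) + len(tset) > n:
        raise ConfigError(
            f"background_n={n} smaller than |signature|+|targets|="
            f"{len(sset)}+{len(tset)}"
        )
    a = len(tset & sset)
    b = len(tset) - a
    c = len(sset) - a
    d = n - a - b - c
    if not tset or not sset:
        return EnrichmentResult(
            compound_id, signature_label, a, b, c, d,
            odds_ratio=_odds_ratio(a, b, c, d), p_raw=1.0, untestable=True,
        )
    # upper tail P(X >= a), hypergeom(M=n, n=|signature|, N=|targets|)
    p_raw = float(stats.hypergeom.sf(a - 1, n, len(sset), len(tset)))
    p_raw = min(p_raw, 1.0)
    return EnrichmentResult(
        compound_id, signature_label, a, b, c, d,
        odds_ratio=_odds_ratio(a, b, c, d), p_raw=p_raw,
    )


def adjust_pvalues(p_values: Sequence[float], method: str = "benjamini-hochberg") -> list[float]:
    """Multiple-testing adjustment preserving input order; values capped at 1."""
    if len(p_values) == 0:
        raise ConfigError("empty p-value list")
    arr = np.asarray(p_values, dtype=float)
    if np.any((arr <= 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ConfigError("p-values must lie in (0, 1]")
    if method == "none":
        return [float(p) for p in arr]
    if method == "benjamini-hochberg":
        sm = "fdr_bh"
    elif method == "bonferroni":
        sm = "bonferroni"
    else:
        raise ConfigError(f"unknown correction method {method!r}")
    _, adj, _, _ = multipletests(arr, method=sm)
    return [float(p) for p in np.minimum(adj, 1.0)]


def adjust_family(results: list[EnrichmentResult], config: EnrichmentConfig) -> None:
    """Adjust a correction family of results in place and set significance.

    Untestable results are excluded from the family; they get
    ``p_adjusted=1`` and are never significant.
    """
    testable = [r for r in results if not r.untestable]
    if testable:
        adj = adjust_pvalues([r.p_raw for r in testable], config.correction)
        for r, p in zip(testable, adj):
            r.p_adjusted = p
            r.significant = p < config.alpha
    for r in results:
        if r.untestable:
            r.p_adjusted = 1.0
            r.significant = False
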