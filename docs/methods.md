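# Methods

`gerotcm` turns a cross-referenced herbal-medicine database (compounds with
protein-target gene sets, herbs as compound sets, formulas as herb sets)
plus a collection of aging gene signatures into ranked geroprotector
candidates: enriched compounds, covering formulas, newly designed herb
combinations, and four-role prescriptions. This note records the models,
the defaults and why, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Signature set algebra

A signature is an ordered list of gene symbols for one (species, tissue,
direction). Symbols are normalized by uppercasing and trimming only —
mitochondrial names like `MT-ND4L` stay verbatim and no ortholog or alias
mapping is applied, so human and mouse lists intersect purely by symbol.
Cross-species conservation is the plain intersection, ordered by the human
list (lists are ranked by importance, and the human ranking is the one a
downstream human-tissue screen cares about). Cross-tissue sharing selects
genes present in at least *k* signatures; output is sorted by membership
count, then lexicographically, because the source lists imply no canonical
order for the selection. The package ships the three cross-species lists
(liver 33, lung 27, muscle 22 genes) as plain-text fixtures; at `k=2` they
yield the 13-gene conserved aging panel, at `k=3` only `ACSM1`.

Only the up-regulated direction is used by the default pipeline (the aging
screens that motivate the package consider genes elevated in old tissue);
the set algebra itself is direction-agnostic.

## Enrichment model

A compound's target set *T* is tested against a signature *S* over a fixed
gene universe of size *N* (default **25,332**, the number of distinct genes
the upstream signature generator can emit). The 2×2 table is
(a, b; c, d) = (|T∩S|, |T\S|, |S\T|, N−a−b−c), and the p-value is the
one-sided upper hypergeometric tail

    p = P(X ≥ a),  X ~ Hypergeom(N, |S|, |T|),

computed with `scipy.stats.hypergeom.sf`. Only the enrichment direction is
offered: the screen asks "does this compound hit the signature more than
chance", and a two-sided option would invite misreading depletion as
signal. The odds ratio (a·d)/(b·c) is reported with explicit `inf`
(b·c = 0, a·d > 0) and `nan` (0/0) handling.

When an explicit background gene list is supplied, targets and signature
are intersected with it first; otherwise *N* is taken on faith as a count.
Compounds with no in-universe targets are *untestable*: they are reported
with a = 0, p = 1, and are excluded from the multiple-testing family so
they cannot dilute the correction.

The config requires `N ≥ |S| + |T|` (after restriction). Strictly only
a + b + c ≤ N is needed, but the stronger precondition is cheap, matches
how the universe is meant to dominate both sets, and fails loudly on
misconfigured universes.

Correction is Benjamini–Hochberg by default, applied **per signature across
all testable compounds** (each signature is one correction family);
Bonferroni is available. BH is the field-standard choice for screening and
the permissive default is documented rather than silent. Two alpha presets
mirror the two screening regimes the package targets: `cross-species`
(α = 0.01) and `multi-tissue` (α = 0.001).

## Screening and coverage ranking

`screen_compounds` iterates compounds in sorted-id order (results are
independent of container ordering), tests each against each signature,
adjusts within the signature family, and records significant sets.
Multi-signature selection keeps compounds significant in ≥ *k* signatures;
it is antitone in *k* by construction.

Formula ranking is unweighted presence/absence coverage: a formula covers a
reference compound iff some member herb contains it. No dosage or
concentration weighting is attempted — the data model carries none. Herb
ranking against a gene set counts, by default, the herb's *compounds* with
at least one target in the set ("compound-count"); the alternative
"distinct-gene-count" metric (number of distinct set genes hit) is a flag,
since either reading is defensible for "most compounds targeting these
genes". Ties everywhere break lexicographically by entity id.

## Greedy formula design

Designing a new formula to capture a compound set is maximum coverage:
pick herbs one at a time, each maximizing newly covered target compounds,
subject to constraints (herb cap, animal-derived exclusion, explicit
include/exclude). Greedy guarantees ≥ (1 − 1/e) ≈ 0.632 of the optimal
same-size coverage; the test suite verifies this against exhaustive subset
search on instances of ≤ 12 herbs (in practice greedy is optimal on almost
every random instance at that scale). Ties break toward the herb with
fewer total compounds — the parsimony/safety reading: when two herbs add
the same signal, prefer the one dragging in less else — then by id.
Selection never pads with zero-gain herbs, including in the fixed-size
(`design_k_herbs`) variant; a short result is flagged in the audit instead.
Herbs lacking an `animal_derived` annotation remain eligible under the
animal-derived exclusion but are counted in the audit, because dumps often
lack the flag and silently dropping them would empty the pool.

## Rule-of-Four composer

The composer fills the four traditional roles sequentially from a
shortlist (default size 20, ranked by the compound-count metric above):

* **Jun (Monarch)** — highest-ranked approved herb: primary action.
* **Chen (Minister)** — approved herb maximizing coverage of signature
  genes Jun leaves uncovered. "Secondary symptoms" has no canonical
  gene-level meaning; residual coverage is one explicit reading, labelled
  as such.
* **Zuo (Assistant)** — approved herb whose thermal nature opposes the
  Jun/Chen majority (hot↔cold, warm↔cool), preferring zero toxicity flags.
* **Shi (Envoy)** — approved herb sharing a meridian with Jun, preferring
  neutral temperature.

Every candidate passes a contraindication check: veto on any
contraindication-tag/condition match, and on any toxicity flag naming a
blocklisted substance (default blocklist: **ephedrine, aconitine**;
substring-matched so `contains:aconitine` trips it; fully overridable). An
herb with no annotations at all is approved *with a warning* — absence of
annotation is surfaced, never treated as evidence of safety. Each role
considers at most `max_veto_rounds` (default 5) candidates; exhaustion
raises a composition failure carrying the complete audit trail, so a run
can always show why it refused. Total contraindication checks are bounded
by 4 × `max_veto_rounds`.

Role policies are a plain callable interface; an LLM-backed policy can be
injected in place of any default, and the veto loop and audit contract are
unchanged (tested with a mock policy). The defaults are deterministic on
purpose: same database, gene set and profile always give the same
prescription. Dosage/duration fields in the output are template text with
a mandatory non-clinical disclaimer; no dose computation is attempted.

## Synthetic benchmark generator

The generator emits a database + signature set + ground truth from a seeded
config. Defaults: 25,332 background genes (the real universe size),
100-gene signatures, 500 compounds with 5–40 targets, 60 herbs with 3–15
compounds, 25 formulas with 2–10 herbs — a sparse miniature of a real
herb-compound-target dump, scaled so a full screen runs in seconds.
Background symbols are synthetic (`G000001`…): the statistics depend only
on set sizes, and fake symbols avoid accidental biological claims.

Null compounds draw targets uniformly from the background. *Planted*
compounds additionally receive `overlap_boost` genes sampled from their
signature (remaining targets drawn off-signature), giving a known positive
set: with boost 10 against a 100-gene signature over 25,332 genes the raw
p is below 10⁻²⁰, so recovery at adjusted p < 0.01 is expected to be
complete. An optional construction makes one herb the strict leader of the
gene-targeting ranking. A generation-time self-audit asserts the emitted
database is consistent with the recorded ground truth.

What the synthetic benchmarks show: correct tail probabilities, correct
family handling, FDR control under independence, greedy near-optimality,
composer contract compliance. What they do not show: real dumps have
heavy-tailed compound degree distributions, correlated target sets
(chemical families), promiscuous hub targets, and annotation errors — none
of which the generator mimics beyond configurable ranges. Passing here
means the machinery is right, not that a particular real-database screen
will reproduce any published compound list; for that, run
`gerotcm reproduce-crossspecies` against the actual dump.

### Null calibration and discreteness

The exact test is discrete and conservative: under the null most compounds
have a = 0 and hence p = 1 exactly (≈ 91% at the default degree ranges).
The empirical p-value CDF therefore sits far *below* the uniform CDF, and a
two-sided uniformity test would reject for any correct implementation. The
calibration checks are accordingly one-sided: a KS test against
anti-conservatism (empirical CDF exceeding uniform) and a binomial upper
bound on the significant fraction at α. These are the properties that
matter for a screen — the false-positive rate is controlled, never
inflated.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use: the full 2×2 grid with
universe ≤ 50 (161,550 tables) against exact integer enumeration; a
2,000-compound null screen; 10–20 seeded replicates of a 300-compound
screen with 20 planted positives; 100–200 random design instances with
≤ 12 herbs (exhaustive optimum by subset search); and 50–100 random
patient/database pairs for the composer. These sizes make every oracle
exactly computable while keeping a full run under a minute.

## Known limitations

* Enrichment ignores mechanism of action (agonist vs antagonist) — the
  underlying databases do not provide it — so a "hit" may act in the wrong
  direction.
* Coverage rankings treat all compounds equally; no potency, dosage or
  bioavailability weighting.
* The composer's Zuo/Shi heuristics are simple, auditable stand-ins for
  practitioner judgment, not a model of it.
* No clinical claim of any kind attaches to any output; prescriptions are
  research artifacts with an explicit non-clinical disclaimer.
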