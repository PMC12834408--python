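# gerotcm

Screening and design of geroprotective Traditional Chinese Medicine (TCM)
formulas from aging gene signatures.

TCM formulas are multi-herb, multi-compound interventions, which makes them
natural candidates for targeting a polygenic process like aging — and hard
to screen with single-compound pharmacology. `gerotcm` is the downstream
half of an AI-assisted discovery loop: given tissue-specific aging gene
signatures (produced upstream by a generative omics model, an aging clock,
or differential expression — they are inputs here) and a cross-referenced
TCM database (compound→protein-target, herb→compound, formula→herb, plus
herb annotations), it

1. **intersects signatures** across species and tissues to find conserved
   aging genes,
2. **screens every compound** for target-set enrichment against each
   signature — a one-sided Fisher exact test over a fixed gene universe
   (*N* = 25,332 by default), Benjamini–Hochberg corrected per signature:
   for a compound with target set *T* and signature *S*,
   *p* = P(X ≥ |T∩S|) with X ~ Hypergeom(N, |S|, |T|),
3. **ranks herbs and formulas** by how many of the enriched compounds they
   contain,
4. **designs new formulas** by greedy maximum coverage of the enriched
   compound set under constraints (herb cap, animal-derived exclusion),
   with the classic (1 − 1/e) optimality guarantee, and
5. **composes four-role (Jun-Chen-Zuo-Shi) prescriptions** for a patient
   profile, with a contraindication veto loop (ephedrine- and
   aconitine-containing herbs are always vetoed by default) and a full
   audit trail.

It is written for computational pharmacology / network-pharmacology
researchers. Nothing it prints is clinical advice.

A seeded synthetic-database generator with planted ground truth makes the
whole pipeline testable offline; real databases (e.g. a BATMAN-TCM2-style
dump) are loaded through the same interfaces.

## Worked example

The package ships the three cross-species aging signatures (genes
up-regulated with age in both humans and mice) for liver (33 genes), lung
(27) and muscle (22). Genes shared by at least two tissues:

```console
$ gerotcm signatures shared --k 2 --table1
gene    count   member_tissues
ACSM1   3       liver,lung,muscle
C3      2       liver,lung
CFD     2       lung,muscle
KRT15   2       liver,muscle
LBP     2       liver,muscle
...
```

13 genes in total — the conserved aging panel (`--k 3` leaves only
`ACSM1`, present in all three tissues).

An end-to-end run on a synthetic database with 25 compounds planted as
enriched for signature 0 (each forced to share 10 targets with the
100-gene signature):

```console
$ gerotcm simulate --seed 7 --config demo_cfg.json --out demo/
$ gerotcm screen --db demo/database.json \
    --signature demo/signature_synthetic-0.tsv \
    --signature demo/signature_synthetic-1.tsv \
    --signature demo/signature_synthetic-2.tsv --k 1 --out demo_screen/
{
  "significant_per_signature": {
    "human:synthetic-0:up": 25,
    "human:synthetic-1:up": 0,
    "human:synthetic-2:up": 0
  },
  "compounds_in_ge_1_signatures": 25
}
```

All 25 planted compounds are recovered at adjusted p < 0.01 and nothing
else: the null signatures show zero false positives. Designing a formula
to capture those 25 compounds:

```console
$ gerotcm design --db demo/database.json \
    --compounds demo_screen/multi_signature_compounds.txt
{
  "herbs": ["H000015", "H000023", "H000017", ...],
  "coverage": 18,
  "target_size": 25
}
```

Greedy selection stops after 13 herbs covering 18 of the 25 target
compounds — the remaining 7 are in no herb, so no formula can capture
them. Composing a prescription for a 62-year-old with hypertension against
the same signature genes:

```console
$ gerotcm compose --db demo/database.json \
    --genes genes.txt --profile patient.json
{
  "jun": "H000017",
  "chen": "H000015",
  "zuo": "H000029",
  "shi": "H000023"
}
```

Jun is the approved herb with the most signature-targeting compounds, Chen
covers the genes Jun missed, Zuo opposes their thermal nature with no
toxicity flags, Shi shares Jun's meridian; any herb contraindicated for
hypertension was vetoed and logged in the audit trail
(`--out` writes `prescription.json`, `prescription.md`, `audit.tsv`).

To run the same screen/rank pipeline on a real relational dump:

```sh
gerotcm reproduce-crossspecies --db batman2_dump.tsv --out repro/
gerotcm reproduce-crossspecies --db batman2_dump.tsv --correction bonferroni --out repro_bonf/
```

which screens the packaged signatures at α = 0.01, selects compounds
significant in ≥ 2 tissues, and ranks formulas and herbs — the second call
gives the correction-method sensitivity comparison.

## Layout

| module | what it does |
|---|---|
| `gerotcm.datamodel` | entity types, database container, JSON/TSV readers and writers, packaged signature fixtures |
| `gerotcm.signatures` | cross-species intersection, k-of-n shared-gene selection |
| `gerotcm.enrichment` | one-sided Fisher exact test, BH/Bonferroni correction, screen presets |
| `gerotcm.screening` | database-wide screens, multi-signature compound selection, coverage rankings |
| `gerotcm.design` | greedy and fixed-size formula design, exhaustive reference search |
| `gerotcm.composer` | Rule-of-Four prescription composition with veto loop and audit |
| `gerotcm.synthetic` | seeded generator with planted enrichment and ground truth |
| `gerotcm.cli` | the `gerotcm` console entry point |

See `docs/methods.md` for the statistical model, defaults and their
rationale, and known limitations; `docs/database-schema.json` for the
native database format.
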