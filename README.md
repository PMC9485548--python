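# bodyfunc

Rule- and dictionary-based extraction of **body-function (BF) mentions** —
muscle *strength*, *range of motion* (ROM), and *reflexes* — from noisy,
highly formatted, OCR'd clinical text pages, together with its evaluation
machinery and a synthetic page generator.

Body functions in the ICF sense (physiological functions of body systems)
are documented during physical exams in telegraphic, heavily formatted
language: section headers ("MOTOR:", "REFLEXES:"), slot-value lines
("Muscle strength: 5/5"), and short narrative sentences. A BF **mention**
is a BF *type* plus at least one *qualifier* (the measured value: "5/5",
"decreased", "45 degrees") and optionally one or more *body locations*,
all within the scope of a phrase or sentence. Each qualifier additionally
carries a ternary functioning **polarity**: `+1` at-or-above-level, `-1`
below-level, `0` ambiguous.

The package is aimed at clinical-NLP practitioners working with
disability-adjudication or rehabilitation documents, where OCR noise
(deleted spaces, munged multi-column layouts, repeated page headers and
footers) breaks conventional sentence-based pipelines.

## What it does

- **lexicon** — category-tagged TSV dictionaries (type terms, locations,
  qualifiers with polarity attributes, confounders, section names) with
  deterministic variant expansion and case-insensitive greedy
  longest-match lookup. Packaged mini-lexicons ship with the code.
- **decompose** — lines, sections (deliberately rigid: line-initial names
  only), slot values (`label: value`, never crossing a line, never ending
  in a period), sentences, tokens; all with exact character offsets.
- **extract** — evidence annotation (dictionary + numeric patterns
  `d/d`, `d degrees`, `[0-4]+`), confounder masking (pain scores, vision
  fractions, straight-leg-raise), per-sentence mention assembly,
  **context expansion** (a bare header like `Strength:` supplies the
  missing type for qualifier-only body lines, yielding discontiguous
  mentions), and assertion filtering (historical / hypothetical /
  conditional scopes, filtered sections).
- **polarity** — the qualifier-polarity rules: dictionary attribute first;
  strength fraction `+1` iff numerator = denominator; ROM degrees `+1`
  iff 45 or 50; reflex score `+1` only for `2+`; clonus on a reflex
  mention `-1`; attribute-less dictionary qualifier `0`.
- **evaluate** — entity-based (overlap or exact, one-to-one greedy) and
  token-based precision/recall/F1 against brat-style `.ann` gold,
  per-class polarity accuracy `100 * TP/(TP+FN)`, inter-annotator macro F1.
- **synthgen** — seeded generator of synthetic exam pages with gold
  standoff annotations and OCR corruption (space deletion, two-column
  munging with `PossibleBF` re-tagging). Stands in for restricted
  clinical corpora; byte-identical per seed.
- **triage** — per-line structural features, standardized PCA, BF-term
  frequency ranking, stratified sampling.

## Worked example

```python
import bodyfunc as bf
from bodyfunc.lexicon import Category

lexicons = bf.load_default_lexicons()
text = """MOTOR:
Strength 5/5 in the right arm.
Muscle strength: 4/5
REFLEXES:
Right 2+, Left 3+.
History of decreased ROM in the left knee.
"""
page = bf.decompose(text, page_id="example",
                    allow=lexicons[Category.SECTION_ALLOW],
                    filter_lex=lexicons[Category.SECTION_FILTER])
for m in bf.extract_page(page, lexicons):
    spans = " + ".join(repr(text[s:e]) for s, e in m.fragments)
    print(f"{m.bf_type.value:8s} polarity={m.polarity:+d} context={m.from_context} {spans}")
```

prints

```
STRENGTH polarity=+1 context=False 'Strength 5/5' + 'right arm'
STRENGTH polarity=-1 context=False 'Muscle strength' + '4/5'
REFLEX   polarity=+1 context=True 'REFLEXES' + 'Right 2+'
REFLEX   polarity=-1 context=True 'REFLEXES' + 'Left 3+'
```

Reading the output: the narrative sentence yields a strength mention with
a unit fraction (`5/5` → polarity +1) and a merged laterality+anatomy
location; the slot-value line contributes its label as the type and its
value as a below-level qualifier; the bare `REFLEXES:` header donates the
type to the two qualifier-only readings beneath it (discontiguous,
`context=True`), with only the brisk-normal `2+` scored +1. The final
sentence is recognized but suppressed as historical, so it is not
emitted.

The same flow from the shell:

```bash
bodyfunc generate --seed 1 --n-pages 5 --out demo/pages
bodyfunc extract demo/pages demo/sys
# -> {"pages": 5, "mentions": 17, "STRENGTH": 1, "ROM": 7, "REFLEX": 9}
bodyfunc evaluate demo/pages demo/sys
# -> per-label precision/recall/F1 (1.0 throughout on a clean corpus)
```

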