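# perturbkit

Human-like text perturbation and robustness evaluation for health-language
tasks.

Clinical and patient-generated text is rarely clean: users type under
stress or fatigue, dictation introduces same-sounding word confusions, and
sensitive details get redacted. `perturbkit` generates those three kinds of
degradation — **typographical errors**, **homophone substitutions** and
**redactions** — at calibrated levels, evaluates any text model on original
vs perturbed inputs through pluggable adapters, and runs the robustness
classification and statistical chain over the results. It is aimed at
health-NLP researchers and evaluators who need reproducible noise injection
and a principled answer to "how much does performance move, and is the
movement real?".

## The model

Perturbation is budgeted in words. For a text of `N` word tokens and a
level `ℓ ∈ (0, 1]`, the engine perturbs

```
t = max(1, round(ℓ · N))        (round half-up)
```

words, drawn only from *valid* words — adjectives, adverbs, verbs and nouns
by coarse POS tag. A 10-word sentence with 5 valid words at `ℓ = 0.10`
perturbs 1 word, i.e. 20% of its valid words. If `t` exceeds the valid-word
supply the example is *budget-infeasible*; a corpus retention rule keeps
only records feasible for **all nine** grid conditions (typos and
redactions at 10/30/50%, homophones at 10/20/30%).

* Typos apply one operator (insert / delete / substitute / adjacent
  transpose) to 20–50% of a chosen word's letters (at least one).
* Homophone swaps replace a word with its first differently-spelled
  homophone from a provider (bundled static dictionary, or a sounds-like
  HTTP lookup); words without homophones are reselected.
* Redaction deletes the chosen words and collapses the whitespace.

Performance under a condition is compared to the unperturbed baseline via
the relative change `Δ = (perturbed − original)/original` and binned:

| bin | rule |
|---|---|
| increase | Δ > 0 |
| stable | −0.05 ≤ Δ ≤ 0 |
| decrease | −0.50 ≤ Δ < −0.05 |
| catastrophic | Δ < −0.50 |

Bin counts feed Pearson χ² independence tests; per-condition metric values
feed tie-corrected Friedman tests, Conover post hoc pairs with Bonferroni
correction, and one-way repeated-measures ANOVA. Classification tasks are
scored with accuracy and macro precision/recall/F1; question answering
with ROUGE-L (the analysis metric) and smoothed BLEU.

## Worked example

```python
import perturbkit as pk

text = ("How did voxelotor affect the patient’s scleral icterus and "
        "overall quality of life in the given discharge summary?")
lex = pk.load_medical_lexicon()
anns = pk.annotate_tokens(text, lexicon=lex)
print(len(anns), sum(a.is_valid for a in anns))        # 18 words, 12 valid

idx = {a.text: i for i, a in enumerate(anns)}
print(pk.apply_redaction(text, anns, [idx["icterus"], idx["life"]]))
# How did voxelotor affect the patient’s scleral and overall quality of
# in the given discharge summary?

prov = pk.DictionaryProvider()
print(pk.apply_homophone("did", prov), pk.apply_homophone("in", prov))
# deed inn

print(pk.classify_robustness(0.80, 0.30))   # catastrophic (Δ = −0.625)
```

End-to-end from the shell, with a synthetic fixture corpus and the perfect
(oracle) mock adapter:

```
perturbkit fixtures --kind sentiment --n 50 --out sentiment.jsonl
perturbkit perturb  --input sentiment.jsonl --task sentiment_binary --out corpus/
# -> retained 50 records (0 dropped) -> corpus/corpus.jsonl
perturbkit evaluate --corpus corpus/corpus.jsonl --adapter oracle --out results.csv
perturbkit analyze  --results results.csv --out report/
```

`analyze --reference` runs the contingency chain on the bundled published
robustness counts (270 condition cells of three models on three health
tasks) and prints:

```
chi-squared by model: chi2(6) = 81.25, p = 1.97e-15
chi-squared by task: chi2(6) = 44.74, p = 5.27e-08
```

i.e. robustness category frequencies are far from independent of which
model, and which task, was perturbed.

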