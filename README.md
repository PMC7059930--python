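# narsent

Automated analysis of narrative language samples: dictionary-based
sentiment tagging, verb-abstraction classification (DAV / IAV / SV with
the weighted score `DAV + 2·IAV + 3·SV`), morphosyntactic frequency
profiling, and an assumption-gated two-group statistical battery —
plus a synthetic-corpus generator so the whole pipeline is testable
without clinical data.

## Pipeline

1. **transcripts_io** — reads CHAT (`.cha`) transcripts (speaker
   filtering, documented cleaning of retracing/event/pause codes) and
   annotated token tables (TSV: `utterance_index, surface, lemma,
   msd_tag, probability, sense_id`); morphological analysis and
   disambiguation happen upstream and are consumed via this format.
2. **lexicons** — sentiment lexicon (lemma → positive/negative) and a
   three-tier verb-abstraction lexicon (sense / lemma / inferred
   default). Toy fixtures ship in `narsent/data/`; real dictionaries
   load through the same TSV format.
3. **annotation** — selects the maximum-probability interpretation per
   token and attaches sentiment (any part of speech) and verb-class
   labels (verbal tags only, sense tier first).
4. **features** — per participant × task feature vectors: token and
   utterance counts, MLU, sentiment counts, DAV/IAV/SV counts, the
   abstraction score, and ~60 morphosyntactic class/category counts.
5. **stats** — gated Student-t / Mann-Whitney comparisons with effect
   sizes (d = 2t/√df, r = |Z|/√N), recomputation from printed group
   summaries, Pearson correlations, 2×2 mixed ANOVA with classical η²
   and Bonferroni post-hocs, and a Bonferroni multi-variable screen.
6. **synthetic** — negative-binomial count generator moment-matched to
   the published group summaries; realises counts as token streams over
   closed vocabularies so annotation + feature extraction recover the
   generating counts exactly. Includes power curves.

## CLI

```sh
# generate a synthetic corpus (CHAT + token tables + features + metadata)
narsent simulate --seed 1 --n-per-group 25 --out-dir out/sim

# attach sentiment / verb-class columns to token tables
narsent annotate --tokens out/sim/tokens/ASD001_book.tsv \
    --sentiment-lexicon src/narsent/data/toy_sentiment.tsv \
    --lcm-sense src/narsent/data/toy_lcm_sense.tsv \
    --lcm-lemma src/narsent/data/toy_lcm_lemma.tsv \
    --lcm-default src/narsent/data/toy_lcm_default.tsv \
    --out-dir out/annotated

# aggregate into the feature table
narsent score --annotated out/annotated/ASD001_book.annotated.tsv \
    --metadata out/sim/metadata.csv --out out/features.csv

# run the full statistical report
narsent compare --features out/sim/features.csv \
    --out-json out/report.json --out-text out/report.txt
```

Exit codes: 0 success, 1 validation/processing error, 2 usage error.

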