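# pmir — evidence-quality retrieval for precision-medicine literature

Clinicians practicing precision medicine ask questions of the form *"what is
the evidence for treatment t in patients with disease d carrying gene variant
g?"*. A plain relevance-ranked literature search answers the wrong question:
a narrative review or an editorial can be highly *relevant* yet carry little
*clinical evidence*, while a meta-analysis or a large randomized trial is
what actually informs the decision. `pmir` implements a two-stage retrieval
pipeline that separates these concerns, together with TREC-style evaluation
and a fully synthetic benchmark so every stage can be exercised end to end
without any external corpus.

## The method

**Stage 1 — baseline retriever.** Titles and abstracts are indexed as
separate fields of an Okapi BM25 inverted index
(idf = ln(1 + (N − df + ½)/(df + ½)), k1 = 1.2, b = 0.75). For a topic
(d, g, t), the disease and gene terms are expanded to synonym sets
{d₁…d_m}, {g₁…g_m} (d₁ = d); each synonym is weighted by its normalized
document frequency w(sᵢ) = df(sᵢ)/max_j df(sⱼ), down-weighting rare variant
spellings. The query is a boolean that **must** match the disease and the
treatment (treatments are never expanded) and **should** match the gene and
the keywords "trial" and "patient", each concept scored as a `dis_max` over
its weighted synonym clauses (tie_breaker 0.8, title boosted 3.0 over
abstract 1.0). Up to 10,000 candidates are retained per topic.

**Stage 2 — evidence reranker.** Each candidate is described by four
features: the retrieval score *es*, a pluggable text-pair score *pb* ∈ [0,1],
a manually rated publication-type score *ty* ∈ [−2,2] (meta-analysis,
systematic review and clinical trial +2; erratum and retraction −2), and the
citation-count quantile *ct* ∈ [0,1]. *Automatic* presets rank by a fixed
weighted sum of max-normalized features. *Full* presets rank by

    r = w_LR · LR(es, pb, ty, ct) + w_FB · FB(q, a)

where LR is an ordinary least-squares fit to expert annotations and FB is a
trainable text-pair scorer fitted by **top-1 expert-in-the-loop active
learning**: each iteration annotates the highest-ranked unannotated document
per topic (tiers 0–4, normalized to [0,1]), refits FB (and LR) on all
annotations so far, and re-ranks the cached candidate pool. The loop stops
at 22 iterations or once the mean annotated relevance has stayed below its
running maximum for three consecutive iterations. The default FB backend is
a hashed bag-of-words ridge regressor over the tokens shared by query and
article; an optional transformer backend (biomedical BERT, Adam, lr 4×10⁻⁵,
batch 16, 10 epochs) is provided for reference and needs `torch` +
`transformers`.

**Evaluation.** P@10, R-precision, NDCG@k under standard (0,1,2,3,4) and
exponential (0,1,2,4,8) tier gains, and inferred NDCG under the stratified
assessment protocol (top 30 ranks fully judged, 25 % Bernoulli sample of
ranks 31–100), plus the pool sampler itself.

**Synthetic benchmark.** A generator builds corpora whose topic-bearing
documents mention concepts through synonyms at a controlled substitution
rate, with MEDLINE-like publication-type frequencies, log-normal citation
counts, and a simulated expert whose tier is a monotone function of
concept-match quality, publication-type score, and citation quantile.

## Worked example

```python
from pmir import (GeneratorConfig, generate_benchmark, make_oracle,
                  run_baseline, run_full, evaluate_runs)
from pmir.active import LoopConfig

bench = generate_benchmark(GeneratorConfig(n_docs=2000, n_topics=5, seed=42))
base = run_baseline(bench.articles, bench.topics, bench.synonym_table)
full = run_full(bench.articles, bench.topics, bench.synonym_table,
                make_oracle(bench), loop_config=LoopConfig(max_iterations=10),
                truth_qrels=bench.qrels, index=base.index)
print(evaluate_runs(full.rankings, bench.qrels, ("p10", "ndcg30-std", "ndcg30-exp")).round(4))
```

prints

```
       p10  ndcg30-std  ndcg30-exp
topic
1      1.0      0.9586      0.9212
2      1.0      0.9619      0.9373
3      1.0      0.9132      0.8697
4      1.0      0.9607      0.9358
5      1.0      0.9788      0.9714
mean   1.0      0.9546      0.9271
```

Per-topic rows are the metric values of the final reranked run against the
benchmark's truth judgments; the `mean` row is the topic-wise average. The
loop history shows the learning curve rising then plateauing:

```
iter 1: +5 annotations, mean tier/4 = 0.850, NDCG@30(exp) = 0.724
iter 2: +5 annotations, mean tier/4 = 0.750, NDCG@30(exp) = 0.902
iter 3: +5 annotations, mean tier/4 = 0.767, NDCG@30(exp) = 0.909
iter 4: +5 annotations, mean tier/4 = 0.800, NDCG@30(exp) = 0.927
```

The same pipeline is available from the shell:

```bash
pmir synth --out-dir bench --n-docs 2000 --n-topics 5 --seed 42
pmir retrieve --corpus bench/corpus.jsonl --topics bench/topics.tsv \
              --synonyms bench/synonyms.tsv --out baseline.txt
pmir evaluate --run baseline.txt --qrels bench/qrels.txt --out metrics.tsv
pmir full-run --out-dir out --preset full-3 --seed 42
```

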