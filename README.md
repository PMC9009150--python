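# netscreen

Pan-cancer analysis of neutrophil extracellular traps (NETs) from bulk
transcriptomes: single-sample enrichment scoring of a NET gene signature,
survival-direction classification of cancer types, and a co-expression
screen that nominates the key NET-associated regulatory gene, with a
synthetic pan-cancer generator carrying planted ground truth so every
stage can be validated end to end.

## The problem

Neutrophils can expel web-like chromatin structures (NETs) into the tumor
microenvironment. Whether NETs help or harm the patient differs by cancer
type, and the genes that co-vary with NET formation differ between
cancers where NETs predict shorter versus longer survival. Given a
gene × sample expression matrix (log2-scale, FPKM-like), per-sample
clinical annotation, and a NET gene signature, the pipeline:

1. **Scores** each tumor with a GSVA-style single-sample enrichment
   statistic of the signature (the *NET score*). For gene *i* with
   sample standard deviation *sᵢ*, a Gaussian-kernel CDF
   F̂ᵢ(xᵢⱼ) = n⁻¹ Σₖ Φ((xᵢⱼ − xᵢₖ)/hᵢ), hᵢ = sᵢ/4, is estimated; genes
   are ranked per sample by F̂, converted to the symmetric rank statistic
   zᵢⱼ = |p/2 − rᵢⱼ|, and a weighted Kolmogorov–Smirnov-like walk over
   the ranked list gives the signed max-deviation score in [−1, 1].
2. **Classifies** each cancer type as *favorable*, *poor*, or *neutral*
   NET-related survival: samples are split at the maximally selected
   log-rank cutpoint of the NET score; a type is favorable/poor when the
   log-rank p < 0.05 and the high-score group has the longer/shorter
   Kaplan–Meier median survival. A univariate Cox model on the group
   indicator reports the hazard ratio HR = exp(β).
3. **Screens** every candidate gene against the NET score per cancer
   type (Pearson |R| > 0.35, p < 0.05 ⇒ a NET-associated regulatory
   gene, *NRG*), keeps genes recurrent in ≥5 types of one survival
   class (*core* NRGs), and shortlists genes positively correlated in
   >5 types of one class but <2 of the other (*class-exclusive*).
4. **Nominates** the key gene: the poor-exclusive NRG significantly
   over-expressed in poor-class tumors (the SPP1/osteopontin pattern),
   then quantifies the joint effect of NET score × key gene on survival
   (high/high vs low/low Cox contrast) and on an in-silico EMT score,
   Σ z(mesenchymal) − Σ z(epithelial) per sample.

Supporting statistics (ssGSEA hallmark scores, marker-mean cell-type
scores, pre-ranked GSEA with permutation NES, Welch differential
expression with Benjamini–Hochberg control, Mann–Whitney group
comparison, hypergeometric over-representation) live in
`enrichment_scoring` and `association_stats`.

The synthetic generator (`netscreen.synthetic_data`) emulates the
structure this analysis assumes — a latent per-sample NET activity
driving the signature, class-restricted planted NRGs, an over-expressed
key gene in poor-survival types, EMT programs coupled to NET × key gene,
exponential survival with class-specific hazard signs — and returns the
ground truth for recovery tests.

## Worked example

Simulate a small five-type cohort (2 favorable, 2 poor, 1 neutral; 120
tumors per type) and run the full screen. The screen thresholds are
scaled to the small layout (recurrence in ≥2 types, exclusivity >1 vs 0):

```bash
cat > synth.yaml <<EOF
n_fav: 2
n_poor: 2
n_neutral: 1
samples_per_type: 120
normals_per_type: 10
n_genes: 250
n_signature: 12
n_planted_nrg_per_class: 10
n_emt_per_program: 6
EOF
cat > screen.yaml <<EOF
recurrence_min: 2
exclusive_in_min: 2
exclusive_out_max: 0
EOF

netscreen simulate --config synth.yaml --seed 11 --out-dir data
netscreen run --expr data/expression.tsv --clinical data/clinical.tsv \
    --gmt data/sets.gmt --config screen.yaml --seed 11 --out-dir results
```

which prints

```
wrote 250 genes x 650 samples to data
nominee: PRG01
combined high/high vs low/low HR=1.309 (p=0.0475)
```

`PRG01` is the generator's planted key gene (the SPP1 analog), so the
screen recovered it; the joint NET-high/gene-high stratum carries a
30.9% higher death hazard than the double-low stratum. Inspecting the
written tables:

```
$ head -4 results/survival_class.tsv
# config=7c7f9a5d4179 seed=11
cancer_type  n    class      cutoff   logrank_p  hr     n_high  n_low
FAV01        120  favorable  -0.2968  5.50e-07   0.316  76      44
FAV02        120  favorable  -0.6240  4.71e-05   0.322  103     17
```

Both planted favorable types are classified favorable with HR < 1
(high NET score protective), and `results/nominee.tsv` ranks PRG01
first with a pooled log2 fold change of 0.75 and BH-adjusted
p = 4.6 × 10⁻¹⁴ in poor-class tumors. Other outputs: `net_scores.tsv`,
`nrg_pairs.tsv`, `screen_summary.tsv`, `shortlist.tsv`,
`combined_strata.tsv`, and a `run_log.txt` tagged with the config hash.

The same steps are available as library calls
(`netscreen.generate`, `netscreen.run_pipeline`); see `docs/methods.md`
for the model details and design choices.

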