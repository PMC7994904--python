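# dracoscreen

Analysis toolkit for pooled CRISPR-Cas9 knockout **dropout screens** run
under escalating drug pressure, built around two complementary gene-ranking
strategies — **terrace ranking** and **DRACO** (decisive ranking of CRISPR
outputs) — plus the drug-combination **efficacy-level ranking** used to
grade follow-up viability experiments. A synthetic-screen generator with
known ground truth makes every stage testable end to end.

## Who this is for

Functional-genomics groups running GeCKO-style genome-scale knockout
screens (≈6 sgRNAs per gene, ≥500× read coverage) to find genes whose loss
sensitizes cells to a drug, and who then validate hits with 96-well
viability assays of drug combinations.

## The methods

Counts for each sgRNA *i* in sample *s* are depth-normalized,

N_i,s = (count_i,s / total_s) · 10⁷,

guides with baseline (T0) counts below ~50 reads are flagged as noise and
removed everywhere, and each drug/vehicle pair at the same timepoint gives
a per-guide log fold-change

L_FC(i) = log₂((N_i,drug + 1) / (N_i,vehicle + 1)).

Per gene *g* with guide set S_g:

- **μ_LFC(g)** — arithmetic mean of the guide L_FC values;
- **concordance k(g)** — number of guide L_FC values whose sign matches
  sign(μ_LFC);
- **terrace rank** — k(g) ∈ {1,…,6}; genes are plotted grouped by rank and
  ordered by μ_LFC within rank (the terrace chart);
- **DRACO** — keep genes with k(g) ≥ 4 ("four of six"), then score each
  survivor by its single most extreme guide: the max-|L_FC| guide reported
  at its actual signed value. The concordance gate protects the per-guide
  ranking from single hyper-efficient or off-target guides; the per-guide
  ranking protects real hits from being averaged away by inefficient
  guides.

Candidate lists (e.g. the 25 most-depleted genes per method per late
timepoint) can be merged with provenance tracking, and two screens can be
compared by top-list overlap and by Pearson/Kendall/Spearman agreement
over an aligned oncogene panel.

For validation plates, viability is blank-subtracted absorbance relative
to vehicle; a combination's **additive gap** is killing(combo) −
killing(best single agent) in percentage points, mapped to efficacy levels
1–5 (gap ≥ 20 ⇒ level ≥ 3, gap ≥ 30 ⇒ level 5) with a two-tailed t-test
against the best single agent deciding whether the combo is "effective".

## Worked example

```python
from dracoscreen import (
    SimConfig, simulate_screen_dataset, flag_noisy_guides, normalize_counts,
    compute_lfc, draco_select, select_top,
)

cfg = SimConfig()          # 2,000 genes x 6 guides, 500x coverage
lib, truth, counts = simulate_screen_dataset(cfg, seed=1)

mask = flag_noisy_guides(counts)               # T0 reads < 50 are noise
norm = normalize_counts(counts)                # reads per 1e7
rec = compute_lfc(norm, "DRUG_T3", "VEH_T3", mask=mask, library=lib)
hits = draco_select(rec, lib)                  # four-of-six filter
top = select_top(hits, "draco", "depleted", n=10)
print(mask.n_flagged, len(hits), top.genes[:3])
```

prints

```
153 1240 ['GENE0110', 'GENE0418', 'GENE1879']
```

meaning 153 of 12,100 guides were below the baseline noise threshold,
1,240 genes passed the four-of-six concordance gate for this contrast, and
the three listed genes have the most negative single-guide fold-changes —
all three carry a simulated strong drug-interaction effect
(`truth.genes.loc[top.genes[:3], "label"]` is `strong_dropout` for each).

The same pipeline is available from the shell:

```bash
dracoscreen simulate --seed 1 --out-dir sim/
dracoscreen rank --counts sim/counts.tsv --library sim/library.tsv \
    --samples sim/samples.tsv --drug DRUG_T3 --control VEH_T3 \
    --method draco --n 25 --out hits.tsv
```

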