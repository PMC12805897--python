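# segtail

Computational toolkit for **template-encoded segmented poly(A) tails** in
synthetic mRNA. Long homopolymeric poly(A) stretches recombine and shorten
during plasmid amplification in *E. coli*, which caps the tail length that
can be encoded in a DNA template. Interrupting the tail with short
heteronucleotide spacers (e.g. a single cytosine every 15 adenines)
stabilizes the template and can substantially raise protein output. This
package implements the analysis side of that engineering problem, for people
designing and characterizing mRNA reporter constructs:

* a **design grammar** for segmented tails — parse, validate, render and
  characterize patterns such as `A30(CA15)11` (an A₃₀ head plus eleven
  C + A₁₅ repeats, 206 nt in total) or explicit forms such as
  `A30-GCATATGACT-A70`;
* **plasmid-instability QC** — classify sequenced colony tails against the
  reference design (`intact` / `shortened` / `altered`) and report the
  altered-clone percentage with a 95% Wilson interval;
* a **kinetic expression model** — the linear cascade
  mRNA → inactive protein → fluorophore,

  ```
  d[mRNA]/dt     = −λ_RNA·[mRNA]
  d[inactive]/dt =  k_trans·[mRNA] − k_mat·[inactive]
  d[fluor]/dt    =  k_mat·[inactive] − λ_fluor·[fluor]
  ```

  with exact closed-form trajectories, a numeric oracle, and
  t₀.₅ = ln 2 / λ conversions;
* **hierarchical fitting** — globally shared maturation/decay rates per cell
  line, locally fit (λ_RNA, k_trans) per variant and replicate, mean absolute
  error at both levels, deterministic multi-start search; yields per-variant
  mRNA half-lives and production rates with replicate mean ± SD;
* **summaries and statistics** — AUC (sum or trapezoid) per time course,
  fold-change versus a reference variant, and the normality-gated group
  comparison (Shapiro–Wilk gate → ANOVA + Tukey or Kruskal–Wallis + Dunn);
* a **synthetic-data generator** — reporter time courses with cell-line
  presets (A549: mRNA t₀.₅ 400 min, fluorophore t₀.₅ 259 min; HEK293T:
  350 / 179 min), three technical replicates, multiplicative log-normal
  noise, and colony sets with controlled instability — so the whole pipeline
  is testable without any external data.

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.

## Worked example

```python
import numpy as np
from segtail import (
    parse_pattern, total_length, design_report,
    make_preset, default_variant_panel, SimulationDesign,
    simulate_experiment, fit_global,
)

# --- tail design -----------------------------------------------------------
design = parse_pattern("A30(CA15)11", name="S14")
report = design_report(design)
print(total_length(design), report["longest_adenine_run"], report["n_spacers"])
# 206 30 11   -> a 206-nt tail, 30-nt leading tract, 11 single-C spacers

# --- simulate a fluorescence experiment and recover the kinetics -----------
sim = SimulationDesign(
    cell_line=make_preset("HEK293T"),        # mRNA t1/2 350 min, protein 179 min
    variants=default_variant_panel(10),
    n_replicates=3,
    seed=11,
)
result = fit_global(simulate_experiment(sim))
print(round(result.protein_half_life, 1))
# 171.0   -> recovered fluorophore half-life in minutes (generated with 179)
print(round(result.replicate_summary["half_life_mean"].median(), 1))
# 354.6   -> median recovered mRNA half-life in minutes (generated with 350)
```

The fit recovers the generating fluorophore half-life to within a few
percent at 5% measurement noise; per-variant mRNA half-lives and production
rates (with replicate SDs) are in `result.per_variant` and
`result.replicate_summary`.

A thin CLI wraps the same functions:

```bash
segtail design parse --pattern "A30(CA15)11"
segtail simulate colonies --reference-pattern S8 --n 30 --p-shorten 0.15 -o clones.fasta
segtail stability classify --reference-pattern S8 --clones clones.fasta -o report.tsv
segtail simulate courses --preset A549 --seed 1 -o courses.csv
segtail fit run --data courses.csv -o fit.json
segtail summarize auc --data courses.csv --method sum --reference v01 -o summary.tsv
```

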