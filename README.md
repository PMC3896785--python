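# kinmotif

Kinetic-motif profiling of adaptive enzyme networks.

Small signalling circuits can show *perfect adaptation*: after a step
change in input they respond with a transient pulse, then return almost
exactly to their pre-stimulus output. The textbook example is E. coli
chemotaxis, where a negative feedback loop through the demethylase CheB
resets CheA activity (and hence CheY-P) after a change in attractant.
For a mechanistic model of such a circuit, a single best-fitting
parameter set says little — many sets work, and many more do not. This
package takes the global view: sample the kinetic parameter space at
scale, keep the sets that actually adapt, and ask *statistically* which
parameter value ranges those solutions are biased towards ("kinetic
motifs") and which part of the dynamics each motif serves.

The pipeline, for a three-node enzyme network with Michaelis–Menten
kinetics (nodes A, B, C with active fractions in [0, 1]; the
negative-feedback-loop-with-buffer preset mirrors chemotaxis):

1. **Sample** n kinetic parameter sets by Latin hypercube on the log10
   scale (rate constants k ∈ [10⁻¹, 10¹], Michaelis constants
   K ∈ [10⁻³, 10²]).
2. **Screen**: for each set, find the steady state at input I₁ = 0.5,
   step to I₂ = 0.6, and score the output-node response:
   sensitivity = (|O_p − O₁|/O₁)/(|I₂ − I₁|/I₁) and
   precision = [(|O₂ − O₁|/O₁)/(|I₂ − I₁|/I₁)]⁻¹. Sets with degenerate
   steady states, oscillations or over-long transients are discarded; a
   *kinetic solution* has sensitivity > 1 and precision > 10.
3. **Enrich**: bin each parameter into decade value classes and test each
   class with the strict-tail hypergeometric p-value
   P(X > x | y, M, N) < 10⁻³; the significant classes of a parameter form
   its kinetic motif.
4. **Associate**: for each motif, compare sensitivity and precision
   scores of motif vs non-motif sets (tie-corrected Mann–Whitney z,
   labelled at z > 3.29) to build a bipartite motif–functionality
   network, and test pairwise Pearson cooperation (log10 scale) between
   motif parameters over the solution sets.

See `docs/methods.md` for the model equations, numerical strategy,
filter calibration and known limitations.

## Worked example

```python
from kinmotif import build_nfblb_model
from kinmotif.screen import default_range_spec, latin_hypercube_sample, run_screen
from kinmotif.profiler import MotifProfiler

model = build_nfblb_model()
spec = default_range_spec(model)
matrix = latin_hypercube_sample(20_000, spec, seed=7)
screened = run_screen(model, matrix)
results = MotifProfiler(screened).fit()
print(results.summary())
```

prints (abridged):

```
Kinetic motif profile
======================================================================
screened sets N = 20000, kinetic solutions M = 17
OK-classified sets: 7903 (39.5%)

Enrichment (alpha = 0.001, strict tail)
----------------------------------------------------------------------
parameter class       interval     x       y          p sig
K_BA         1    [1E-3,1E-2]    11    4000    9.1E-06 *
k_FBB        3     [1E-1,1E0]    17   10000   <2.2E-16 *
K_FBB        1    [1E-3,1E-2]    12    4000    8.5E-07 *
...

Functional association (z_crit = 3.29)
----------------------------------------------------------------------
parameter          motif    Pr_m   Pr_~m     z_PR    Sn_m   Sn_~m     z_SN function
K_BA        [1E-3,1E-2]   23.86   58.53    -7.11    0.05    0.02     8.82 SN
k_FBB        [1E-1,1E0]   36.77   64.36    -5.51    0.03    0.02     7.89 SN
K_FBB       [1E-3,1E-2]   85.06   43.10     7.41    0.02    0.02    -2.86 PR

bipartite degree: precision <- 1 motifs, sensitivity <- 3 motifs
correlated pairs (p < 0.05): 2
  K_AB -- K_FCC: r = +0.59, p = 1.2E-02
  K_AB -- k_FBB: r = -0.49, p = 4.7E-02
```

Reading: of 20,000 sampled sets, 39.5% survive the trajectory filters
and 17 adapt perfectly. Solutions are strongly biased towards small
K_BA and K_FBB (first decade) and mid-range k_FBB — e.g. all 17
solutions have k_FBB in [0.1, 1], which only a quarter of random draws
do, hence p < 2.2·10⁻¹⁶. The association columns are the motif and
non-motif group score medians and their rank-test z: the K_FBB motif
group is more precise (z_PR = +7.4, label PR), while the K_BA and
k_FBB motifs mark sensitive-but-less-precise sets (label SN) — the two
functions pull against each other, visible as opposed z signs in every
row. At this sample size only 17 solutions feed the enrichment tests;
the study-scale run uses n = 10⁵ (see below).

The same pipeline is scriptable from a shell:

```
kinmotif run-all --n 20000 --seed 7 --out runs/demo
```

which writes `parameters.csv`, `outcomes.csv`, `enrichment.csv`,
`motifs.json`, `association.csv`, `correlations.csv`,
`network.graphml`/`network.json`, `summary.json` and a config echo into
the output directory. `kinmotif sample|screen|enrich|associate|cooperate`
run the stages separately (long screens checkpoint and `--resume`), and
`kinmotif fixture` emits synthetic screened matrices with planted biases
for testing the statistical layer.

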