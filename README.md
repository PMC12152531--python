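# fibrilgold

Quantification of immunogold labelling on electron micrographs of amyloid
fibrils: from annotated coordinates (gold-particle centres, fibril
segments) to per-fibril binding scores and statistical comparisons across
samples.

## Who this is for

Groups doing immunogold transmission EM who annotate micrographs (e.g. in
Napari) and want a reproducible, scriptable way to turn those annotations
into antibody-binding measurements — for example, to ask whether an
anti-amyloid antibody binds fibrils from one mouse model more weakly than
fibrils from others.

## The method

**Binding rule.** A gold particle with centre $p$ is *bound* to a fibril
(a straight segment) when the shortest distance from $p$ to the segment is
at most

$$t = r + a + \tfrac{d}{2}$$

with $r$ the gold-particle radius, $a$ the length of the
primary + secondary antibody complex, and $d$ the fibril width. With the
default geometry ($r = 5$ nm, $a = 30$ nm, $d = 17$ nm) the threshold is
$t = 43.5$ nm (≈ 44 nm). A particle within threshold of several fibrils is
assigned to the closest one only, so each particle counts once.

**Binding score.** Each fibril's score is its number of assigned particles
divided by its length $L$ (particles per nm). Fibrils are the unit of
analysis.

**Statistics.** Sample score distributions are compared with a two-step
gated procedure: a per-group Shapiro–Wilk test routes the analysis to
one-way ANOVA + Tukey HSD (all groups normal) or Kruskal–Wallis $H$ +
Mann–Whitney $U$ with Bonferroni correction (otherwise). Post hoc tests run
only when the omnibus $p < 0.05$. In reference mode only the $k-1$ pairs
involving the reference group are tested and the Bonferroni factor is
$m = k-1$. Significance uses asterisk notation (\*: $p<0.05$, \*\*:
$p<0.01$, \*\*\*: $p<0.001$). All statistics use complete data; the
1.5 × IQR outlier rule in the violin plots is display-only.

**Synthetic ground truth.** A generator produces annotation sets with a
known planted binding rate $\lambda$ (particles per nm of fibril) and a
uniform background density $\rho$ (particles per nm²). For isolated
fibrils the expected mean score has the closed form
$\lambda + 2\rho t + \pi\rho t^2/\bar L$, which the pipeline's output is
tested against.

## Worked example

```bash
python examples/simulate_and_score.py
```

prints:

```
binding threshold r + a + d/2 = 43.5 nm
generated 60 fibrils, 821 particles
bound particles: 490 / 821
mean fibril score: 0.02120 particles/nm
closed-form expectation: 0.02102 particles/nm
```

The sample was generated with planted rate $\lambda = 0.02$/nm and
background $\rho = 10^{-5}$/nm²; the measured mean score (0.0212) agrees
with the closed-form expectation (0.0210) up to single-field Monte-Carlo
noise. `examples/compare_groups.py` runs a six-sample comparison (five
strong binders at $\lambda = 0.02$/nm, one weak reference at 0.002/nm) and
reports, via the Kruskal–Wallis route, adjusted $p < 10^{-46}$ (\*\*\*) for
every comparison against the reference. `examples/plot_figures.py` renders
the annotation overlay (fibril bands of width $d$, particle circles of
radius $r+a$ — a circle touching a band is exactly the binding criterion)
and the violin figure.

## Command line

The same workflow is available as a thin CLI:

```bash
fibrilgold simulate --out-dir sim --seed 1 --sample-label demo
fibrilgold score --particles sim/particles.csv --fibrils sim/fibrils.csv \
    --out demo_scores.csv --sample-label demo
fibrilgold compare a_scores.csv b_scores.csv ref_scores.csv \
    --reference ref --violin violins.png
```

Input dialects, config keys and exit codes are documented in the module
docstrings (`fibrilgold.annotations`, `fibrilgold.cli`).

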