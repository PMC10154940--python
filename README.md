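# ornametrics

Outline-based shape complexity, sexual-dimorphism morphometrics, and
phylogenetic comparative regression — the analysis chain needed to ask
whether building a structurally *complex* male ornament (as opposed to a
merely large one) costs development time across species.

The motivating system is sepsid flies (Diptera: Sepsidae), whose males
carry three sexually dimorphic ornaments — armoured fore femora, fourth
abdominal sternite brushes, and genital claspers — ranging from unmodified
to extravagant across species. All adult cuticle is built from a closed
energy budget during pupal metamorphosis, so developmental costs of
ornament size and complexity can be read off sex differences in larval and
pupal durations. The package is aimed at comparative morphologists and
evolutionary biologists who have trait outlines, per-individual
morphometric panels, and a phylogeny.

## The core quantities

**Congruence complexity of an outline.** A closed trace is expanded in
elliptic Fourier descriptors (harmonic *n* contributes a quadruple
(a_n, b_n, c_n, d_n); harmonic 1 is an ellipse). The outline is
reconstructed twice — at h_low = 8 and h_high = 1000 harmonics — and the
two filled regions are compared by polygon boolean operations:

    complexity = area(symmetric difference) / area(intersection)

(non-congruent over congruent area). Band-limited shapes score 0; the more
outline detail lives above the low band, the larger the score. The ratio is
invariant under translation, rotation and uniform scaling. Male sternite
and fore-femur scores are normalized by the conspecific female score
(male/female); claspers are male-only and never normalized.

**Cross-species sex differences.** Per-individual records are reduced to
species × sex means; male − female differences (scutum width, ellipsoid
pupal volume (π/6)·w²·l, larval/pupal/total durations, trait areas and
complexities) are tested across species with one-sample t-tests, and trait
sizes are correlated with development times (Pearson).

**PGLS with Pagel's λ.** Development-time differences are regressed on
complexity differences with body-size covariates under generalized least
squares whose error covariance follows shared branch lengths
(Brownian motion), off-diagonals scaled by λ ∈ [0, 1] estimated by maximum
likelihood:  β̂ = (XᵀV(λ)⁻¹X)⁻¹XᵀV(λ)⁻¹y, with sequential ANOVA in the
given term order.

A fully seeded synthetic-data layer (spectrally exact perturbed-ellipse
outlines, Yule trees, Brownian trait evolution, 18-species × 2-sex study
panels) provides ground-truthed inputs for every stage.

## Worked example

```python
import ornametrics as om

# score a synthetic outline: ellipse + harmonic-20 ripple, amplitude 0.05
spec = om.ShapeSpec(semi_axes=(2.0, 1.0), perturbations=((20, 0.05, 0.3),),
                    allow_self_intersection=True)
s = om.complexity_score(om.make_shape(spec))
print(f"complexity = {s.value:.4f}")
# complexity = 0.0499  (congruent 6.207, non-congruent 0.310)
```

The score ≈ 0.05 says the mismatch fringe between the 8- and 1000-harmonic
reconstructions is 5% of their overlap — numerically equal, by design, to
the injected relative amplitude. An unperturbed ellipse scores 0.

```python
from ornametrics.morphometrics import sex_difference_tests

ind, means, tree = om.make_species_panel(om.PanelSpec(seed=1))
tt = sex_difference_tests(om.summarize_panel(ind)).set_index("quantity")
print(tt.loc[["scutum_mm", "larval_h", "pupal_h"]].round(3))
```

```
           mean_diff  ci_low  ci_high      t      p
quantity
scutum_mm     -0.130  -0.185   -0.075 -5.009  0.000
larval_h      -1.365  -3.680    0.950 -1.244  0.230
pupal_h        7.422   2.382   12.462  3.107  0.006
```

The synthetic panel reproduces its design: females larger (scutum
difference −0.13 mm, p < 0.001), larval periods equal between the sexes,
and male pupal periods ~7.4 h longer (p = 0.006).

```python
res = om.PGLS.from_dataframe(
    means, "pupal_h_diff",
    ["sternite_complexity_diff", "scutum_mm_male", "scutum_mm_diff"],
    tree).fit("ML")
print(res.summary())
```

```
PGLS regression results
============================================================
response: pupal_h_diff    n species: 18
lambda (ML): 0.0000    sigma^2: 106.731    logLik: -65.312
------------------------------------------------------------
                           coef     se       t       p
intercept                 41.48  23.75   1.747  0.1026
sternite_complexity_diff  -28.5  95.94 -0.2971  0.7707
scutum_mm_male           -31.25  21.69  -1.441  0.1716
scutum_mm_diff            31.28  34.58  0.9048  0.3809
```

This panel was generated *without* a complexity→duration effect, and the
fit correctly finds none (p = 0.77) and no phylogenetic signal (λ̂ = 0).
Setting `PanelSpec(complexity_cost_slope=...)` injects a known cost, which
the same model then detects.

A console script mirrors the library: `ornametrics score|batch|simulate
shapes|tree|panel|pgls|run` (see `ornametrics --help`); `ornametrics run
--config run.yaml` executes the full score → summarize → test → PGLS
pipeline with byte-reproducible outputs and a JSON-lines run log.

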