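"""Synthetic fixtures with known ground truth.

Three generators cover the pipeline's inputs end to end:

* :func:`make_shape` — spectrally controlled outlines: an ellipse plus
  harmonic perturbations injected directly into the elliptic Fourier
  quadruples, so the energy above any harmonic band is exact by
  construction.  These stand in for traced trait outlines; no attempt is
  made to mimic real clasper silhouettes.
* :func:`make_tree` / :func:`simulate_brownian` — ultrametric Yule trees
  (depth normalized to 1) and multivariate-normal tip draws with covariance
  ``sigma2 * pagel_transform(brownian_vcv(tree), lam)`` — exactly the
  generative model PGLS assumes.
* :func:`make_species_panel` — an 18-species x 2-sex study panel whose
  default effect sizes are the magnitudes a sepsid-fly developmental study
  reports: female-biased body size (scutum difference −0.134 mm), male-biased
  pupal duration (+7.42 h), near-zero larval difference, male-biased trait
  complexity, and trait areas scaling allometrically with body size.
  Species means receive Brownian phylogenetic structure; individuals are
  drawn around their species x sex mean.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .efa import EFASeries, reconstruct
from .outlines import Outline
from .phylo import PhyloTree, brownian_vcv, pagel_transform

__all__ = ["ShapeSpec", "PanelSpec", "make_shape", "make_tree",
           "simulate_brownian", "make_species_panel"]


# -- shapes ----------------------------------------------------------------

@dataclass(frozen=True)
class ShapeSpec:
    """Ellipse plus exact harmonic perturbations.

    ``perturbations`` is a list of ``(harmonic n >= 2, amplitude, phase)``;
    each adds ``amplitude * (cos(phase), sin(phase))``-weighted energy to
    harmonic n's quadruple.  Amplitudes beyond ``minor_axis / (2 n)`` can
    self-intersect the outline; exceeding that bound raises unless
    ``allow_self_intersection`` is set.
    """

    semi_axes: tuple[float, float] = (2.0, 1.0)
    perturbations: tuple[tuple[int, float, float], ...] = ()
    n_points: int = 4096
    center: tuple[float, float] = (0.0, 0.0)
    allow_self_intersection: bool = False

    def __post_init__(self):
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        for n, amp, _ in self.perturbations:
            if n < 2:
                raise ValueError(f"perturbation harmonics must be >= 2, got {n}")
            if amp < 0:
                raise ValueError(f"amplitudes must be >= 0, got {amp}")


def shape_efa(spec: ShapeSpec) -> EFASeries:
    """Exact EFA series of the specified shape (by construction)."""
    n_max = max([1] + [n for n, _, _ in spec.perturbations])
    harmonics = np.zeros((n_max, 4))
    a, b = spec.semi_axes
    harmonics[0] = (a, 0.0, 0.0, b)  # axis-aligned ellipse at harmonic 1
    minor = min(a, b)
    for n, amp, phase in spec.perturbations:
        if amp >= minor / (2 * n):
            msg = (f"amplitude {amp} at harmonic {n} exceeds the safe bound "
                   f"{minor / (2 * n):.4g}; outline may self-intersect")
            if not spec.allow_self_intersection:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        harmonics[n - 1] += amp * np.array(
            [np.cos(phase), np.sin(phase), -np.sin(phase), np.cos(phase)])
    return EFASeries(spec.center, harmonics,
                     n_points_fit=max(4096, 4 * n_max), perimeter=float("nan"))


def make_shape(spec: ShapeSpec) -> Outline:
    """Sample the band-limited curve at ``n_points`` equal parameter steps."""
    efa = shape_efa(spec)
    n_points = max(spec.n_points, 64, 2 * efa.n_max)
    out = reconstruct(efa, efa.n_max, n_points)
    return out.with_source("synthetic-shape")


# -- trees and Brownian draws ---------------------------------------------

def make_tree(n_tips: int, seed: int) -> PhyloTree:
    """Ultrametric Yule (pure-birth) tree on ``n_tips``, depth scaled to 1."""
    import random

    from dendropy.simulate import treesim

    if n_tips < 2:
        raise ValueError(f"need n_tips >= 2, got {n_tips}")
    rng = random.Random(int(seed))
    taxa = dendropy.TaxonNamespace([f"sp{i + 1:02d}" for i in range(n_tips)])
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=rng)
    tree.seed_node.edge.length = 0.0
    # the simulator stops at the instant of the n-th split, leaving a
    # zero-length cherry; continue the pure-birth process by the waiting
    # time to the (n+1)-th speciation so the present sits strictly between
    # splits and V(lambda=1) is non-singular
    dt = rng.expovariate(1.0 * n_tips)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + dt
    return PhyloTree(tree).scale_depth_to(1.0)


def simulate_brownian(tree: PhyloTree, beta: float, x, sigma2: float,
                      lam: float, seed: int) -> pd.Series:
    """Tip response ``y = beta * x + eps`` with phylogenetic noise.

    ``eps ~ MVN(0, sigma2 * pagel_transform(brownian_vcv(tree), lam))``.
    ``x`` is a species-indexed covariate (Series or array in tip order).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    labels = tree.tip_labels
    if isinstance(x, pd.Series):
        x = x.loc[labels].to_numpy(float)
    else:
        x = np.asarray(x, dtype=float)
    V = pagel_transform(brownian_vcv(tree).to_numpy(float), lam)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(labels)))
    rng = np.random.default_rng(seed)
    eps = np.sqrt(sigma2) * (L @ rng.standard_normal(len(labels)))
    return pd.Series(beta * x + eps, index=labels, name="y")


# -- study panels ----------------------------------------------------------

@dataclass(frozen=True)
class PanelSpec:
    """Design of a synthetic cross-species study panel.

    Sex effects are male − female shifts applied at the species-mean level;
    each comes with an across-species sd.  Defaults emulate an 18-species
    sepsid panel: female-biased size dimorphism, male-biased pupal duration,
    male-biased ornament complexity, and trait areas scaling with body size.
    """

    n_species: int = 18
    n_per_sex: int = 10
    # female baselines (across-species mean, sd of species means)
    scutum_mm: tuple[float, float] = (1.05, 0.20)
    larval_h: tuple[float, float] = (210.0, 30.0)
    pupal_h: tuple[float, float] = (158.0, 25.0)
    # male - female effects (mean, across-species sd)
    scutum_diff_mm: tuple[float, float] = (-0.134, 0.085)
    larval_diff_h: tuple[float, float] = (-0.55, 4.6)
    pupal_diff_h: tuple[float, float] = (7.42, 9.0)
    complexity_diff: dict = field(default_factory=lambda: {
        "sternite": (0.029, 0.032),
        "fore_femur": (0.024, 0.016),
        "clasper": (0.231, 0.070),
    })
    female_complexity: tuple[float, float] = (0.08, 0.03)
    #: log-log slope of trait area on scutum width plus residual sd —
    #: chosen so area-size correlations land in the moderate-to-strong
    #: range seen in real morphological scaling
    allometric_slope: float = 2.0
    allometric_sd: float = 0.25
    #: extra pupal-duration-difference slope on sternite complexity
    #: difference (h per unit complexity); 0 = no built-in ornament cost
    complexity_cost_slope: float = 0.0
    # individual-level noise sds
    ind_scutum_sd: float = 0.04
    ind_duration_sd: float = 6.0
    ind_complexity_sd: float = 0.02
    ind_area_rel_sd: float = 0.10
    lam: float = 0.0
    tree: PhyloTree | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 3:
            raise ValueError("need at least 3 species")
        for name in ("ind_scutum_sd", "ind_duration_sd", "ind_complexity_sd",
                     "ind_area_rel_sd", "allometric_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _phylo_noise(tree: PhyloTree, sd: float, lam: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Across-species deviations with the requested phylogenetic structure."""
    n = tree.n_tips
    if sd == 0:
        return np.zeros(n)
    V = pagel_transform(brownian_vcv(tree).to_numpy(float), lam)
    # normalize mean diagonal to 1 so `sd` is the marginal sd
    V = V / np.mean(np.diag(V))
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    return sd * (L @ rng.standard_normal(n))


TRAITS = ("sternite", "fore_femur", "clasper")


def make_species_panel(spec: PanelSpec):
    """Generate one synthetic study panel.

    Returns ``(individuals, species_means, tree)``: a per-individual tidy
    table matching the morphometrics input schema, the species x sex means
    wide table derived from it, and the phylogeny used.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree or make_tree(spec.n_species, seed=int(
        np.random.default_rng(spec.seed + 1).integers(2**31 - 1)))
    species = tree.tip_labels

    def species_level(mean_sd):
        mean, sd = mean_sd
        return mean + _phylo_noise(tree, sd, spec.lam, rng)

    scutum_f = np.clip(species_level(spec.scutum_mm), 0.4, None)
    scutum_m = np.clip(scutum_f + species_level(spec.scutum_diff_mm), 0.3, None)
    larval_f = np.clip(species_level(spec.larval_h), 24.0, None)
    larval_m = np.clip(larval_f + species_level(spec.larval_diff_h), 24.0, None)
    pupal_f = np.clip(species_level(spec.pupal_h), 24.0, None)

    compl_f = {t: np.clip(species_level(spec.female_complexity), 1e-3, None)
               for t in TRAITS}
    compl_m = {t: np.clip(compl_f[t] + species_level(spec.complexity_diff[t]),
                          1e-3, None)
               for t in TRAITS}
    sternite_cdiff = compl_m["sternite"] - compl_f["sternite"]
    pupal_m = np.clip(pupal_f + species_level(spec.pupal_diff_h)
                      + spec.complexity_cost_slope * sternite_cdiff, 24.0, None)

    def trait_area(scutum):
        # log-log allometry on body size
        log_area = (spec.allometric_slope * np.log(scutum)
                    + rng.normal(0.0, spec.allometric_sd, len(scutum)))
        return 0.6 * np.exp(log_area)   # mm^2 scale factor

    rows = []
    for sex, scutum, larval, pupal, compl in (
            ("female", scutum_f, larval_f, pupal_f, compl_f),
            ("male", scutum_m, larval_m, pupal_m, compl_m)):
        areas = {t: trait_area(scutum) for t in TRAITS}
        for i, sp in enumerate(species):
            for _ in range(spec.n_per_sex):
                scut = max(scutum[i] + rng.normal(0, spec.ind_scutum_sd), 0.2)
                larv = max(larval[i] + rng.normal(0, spec.ind_duration_sd), 1.0)
                pup = max(pupal[i] + rng.normal(0, spec.ind_duration_sd), 1.0)
                # pupal case shaped like the adult: width/length tied to scutum
                pw = max(scut * (0.62 + rng.normal(0, 0.02)), 0.05)
                pl = max(scut * (2.1 + rng.normal(0, 0.05)), 0.1)
                row = {
                    "species": sp, "sex": sex,
                    "larval_h": larv, "pupal_h": pup, "total_h": larv + pup,
                    "pupal_width_mm": pw, "pupal_length_mm": pl,
                    "scutum_mm": scut,
                }
                for t in TRAITS:
                    if t == "clasper" and sex == "female":
                        continue  # claspers only occur in males
                    area = max(areas[t][i] *
                               (1 + rng.normal(0, spec.ind_area_rel_sd)), 1e-4)
                    comp = max(compl[t][i] +
                               rng.normal(0, spec.ind_complexity_sd), 0.0)
                    row[f"{t}_area_mm2"] = area
                    row[f"{t}_complexity"] = comp
                rows.append(row)
    individuals = pd.DataFrame(rows)

    from .morphometrics import summarize_panel

    summary = summarize_panel(individuals)
    means_wide = summary.means.pivot(index="species", columns="sex")
    means_wide.columns = [f"{q}_{sex}" for q, sex in means_wide.columns]
    species_means = means_wide.join(summary.differences)
    return individuals, species_means, tree
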