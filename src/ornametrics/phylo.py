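"""Phylogenetic generalized least squares with Pagel's lambda.

Cross-species trait regressions violate the independence assumption of
ordinary least squares because closely related species inherit similar trait
values.  Under Brownian-motion trait evolution on a rooted tree with branch
lengths, the expected covariance of two species' residuals is the shared
root-to-ancestor path length; PGLS fits a linear model whose error
covariance is that matrix, optionally scaled off-diagonal by Pagel's lambda
in [0, 1] (lambda = 0: no phylogenetic signal, equivalent to OLS on an
ultrametric tree; lambda = 1: pure Brownian motion).  Lambda is estimated by
maximum likelihood by default.

The model/results split follows the statsmodels convention: build a
:class:`PGLS` model from species-indexed data and a tree, call ``fit()``,
and read estimates, standard errors, the lambda profile and a sequential
ANOVA off the returned :class:`PGLSResults`.

>>> model = PGLS.from_dataframe(df, "pupal_h_diff",
...                             ["sternite_complexity_diff", "scutum_mm_male"],
...                             tree)
>>> res = model.fit()          # ML lambda
>>> res.params, res.pvalues, res.lam
>>> print(res.summary())
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["PhyloTree", "read_newick", "brownian_vcv", "pagel_transform",
           "PGLS", "PGLSResults", "pgls_fit", "lambda_profile"]


class PhyloTree:
    """Rooted phylogeny with branch lengths; thin wrapper over dendropy.

    Tip labels must be unique and map one-to-one onto species labels in the
    data; :meth:`pruned_to` drops unmatched tips (with a warning) the way a
    comparative analysis drops species missing from the published tree.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def tip_depths(self) -> pd.Series:
        """Root-to-tip path lengths."""
        self._tree.calc_node_root_distances(
            return_leaf_distances_only=False)
        return pd.Series({leaf.taxon.label: leaf.root_distance
                          for leaf in self._tree.leaf_node_iter()})

    def pruned_to(self, labels) -> "PhyloTree":
        """Subtree containing only the given tip labels (order-insensitive)."""
        labels = list(labels)
        present = set(self.tip_labels)
        keep = [l for l in labels if l in present]
        dropped = sorted(set(labels) - present)
        if dropped:
            warnings.warn(f"species not in tree, dropped: {dropped}",
                          stacklevel=2)
        if len(keep) < 2:
            raise ValueError("fewer than 2 species overlap the tree")
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in set(keep)]
        clone.retain_taxa(taxa)
        return PhyloTree(clone)

    def scale_depth_to(self, depth: float = 1.0) -> "PhyloTree":
        clone = self._tree.clone(depth=1)
        current = max(self.tip_depths())
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= depth / current
        return PhyloTree(clone)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick",
                                    suppress_rooting=True).strip()

    def __repr__(self) -> str:
        return f"<PhyloTree with {self.n_tips} tips>"


def read_newick(source) -> PhyloTree:
    """Parse a rooted Newick tree with branch lengths from a path or string."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"invalid Newick: {exc}") from exc
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("tree must have at least 2 tips")
    return PhyloTree(tree)


def brownian_vcv(tree: PhyloTree) -> pd.DataFrame:
    """Brownian-motion variance-covariance matrix of the tips.

    ``V[i, j]`` is the root-to-MRCA shared path length of tips i and j;
    the diagonal holds root-to-tip depths.  Computed from tip depths and
    patristic distances via ``V[i,j] = (depth_i + depth_j - d_ij) / 2``.
    """
    labels = tree.tip_labels
    depths = tree.tip_depths().loc[labels].to_numpy(float)
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace
            if t.label in set(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[a],
                                                       taxa[labels[j]])
    V = 0.5 * (depths[:, None] + depths[None, :] - D)
    np.fill_diagonal(V, depths)
    V = np.maximum(V, 0.0)
    return pd.DataFrame(V, index=labels, columns=labels)


def pagel_transform(V, lam: float):
    """Scale off-diagonal covariances by Pagel's lambda; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    arr = np.asarray(V, dtype=float)
    out = lam * arr
    np.fill_diagonal(out, np.diag(arr))
    if isinstance(V, pd.DataFrame):
        return pd.DataFrame(out, index=V.index, columns=V.columns)
    return out


@dataclass
class PGLSResults:
    """Estimates and diagnostics of one fitted PGLS regression."""

    model: "PGLS"
    params: pd.Series
    bse: pd.Series
    lam: float
    sigma2: float
    llf: float
    nobs: int
    df_resid: int
    lambda_mode: str
    resid: pd.Series = field(repr=False, default=None)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df_resid),
            index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        half = stats.t.ppf(1 - alpha / 2, self.df_resid) * self.bse
        return pd.DataFrame({"low": self.params - half,
                             "high": self.params + half})

    def anova(self) -> pd.DataFrame:
        """Sequential (type-I) ANOVA in the model's term order.

        Sums of squares are generalized (whitened-space) SS; they and the
        residual SS add up to the total SS about the GLS intercept-only fit.
        """
        m = self.model
        yw, Xw = m.whiten(self.lam)
        terms = list(m.exog_names)
        rss = []
        for k in range(1, len(terms) + 1):
            beta, *_ = np.linalg.lstsq(Xw[:, :k], yw, rcond=None)
            r = yw - Xw[:, :k] @ beta
            rss.append(float(r @ r))
        rss_full = rss[-1]
        df_resid = self.df_resid
        ms_resid = rss_full / df_resid
        rows = []
        for k, term in enumerate(terms[1:], start=1):  # skip intercept
            ss = rss[k - 1] - rss[k]
            F = ss / ms_resid
            rows.append({"term": term, "df": 1, "ss": ss, "F": F,
                         "p": float(stats.f.sf(F, 1, df_resid))})
        rows.append({"term": "residual", "df": df_resid, "ss": rss_full,
                     "F": np.nan, "p": np.nan})
        return pd.DataFrame(rows).set_index("term")

    def summary(self) -> str:
        buf = io.StringIO()
        m = self.model
        buf.write("PGLS regression results\n")
        buf.write("=" * 60 + "\n")
        buf.write(f"response: {m.endog_name}    n species: {self.nobs}\n")
        buf.write(f"lambda ({self.lambda_mode}): {self.lam:.4f}    "
                  f"sigma^2: {self.sigma2:.6g}    logLik: {self.llf:.3f}\n")
        buf.write("-" * 60 + "\n")
        tab = pd.DataFrame({"coef": self.params, "se": self.bse,
                            "t": self.tvalues, "p": self.pvalues})
        buf.write(tab.to_string(float_format=lambda v: f"{v: .4g}"))
        buf.write("\n" + "-" * 60 + "\n")
        buf.write(self.anova().to_string(float_format=lambda v: f"{v: .4g}"))
        return buf.getvalue()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"coef": self.params, "se": self.bse,
                           "t": self.tvalues, "p": self.pvalues})
        df.attrs.update(lam=self.lam, sigma2=self.sigma2, llf=self.llf)
        return df


class PGLS:
    """Phylogenetic generalized least squares regression model.

    Parameters
    ----------
    endog : species-indexed response vector (pd.Series)
    exog : species-indexed design matrix (pd.DataFrame), without intercept
        unless ``add_intercept=False``
    tree : PhyloTree covering at least the species in the data; extra tips
        are pruned, species missing from the tree are dropped with a warning
    """

    def __init__(self, endog: pd.Series, exog: pd.DataFrame, tree: PhyloTree,
                 add_intercept: bool = True):
        data = pd.concat([endog.rename("__y__"), exog], axis=1).dropna()
        species = [s for s in data.index if s in set(tree.tip_labels)]
        missing = sorted(set(data.index) - set(species))
        if missing:
            warnings.warn(f"species not in tree, dropped: {missing}",
                          stacklevel=2)
        p = exog.shape[1] + int(add_intercept)
        if len(species) < p + 2:
            raise ValueError(
                f"need >= {p + 2} species with complete data on the tree, "
                f"have {len(species)}")
        data = data.loc[species]
        self.tree = tree.pruned_to(species)
        # order V to match the data
        self.V = brownian_vcv(self.tree).loc[species, species].to_numpy(float)
        self.endog = data["__y__"]
        X = data.drop(columns="__y__")
        if add_intercept:
            X.insert(0, "intercept", 1.0)
        if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
            raise ValueError("singular design matrix")
        self.exog = X
        self.endog_name = endog.name or "y"
        self.exog_names = list(X.columns)
        self.nobs = len(species)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       predictors: list[str], tree: PhyloTree,
                       species_col: str | None = None) -> "PGLS":
        if species_col is not None:
            data = data.set_index(species_col)
        return cls(data[response], data[list(predictors)], tree)

    # -- likelihood machinery -------------------------------------------
    def _chol(self, lam: float) -> np.ndarray:
        Vl = pagel_transform(self.V, lam)
        # tiny relative jitter keeps Cholesky stable when recent splits make
        # two tips' covariances numerically identical
        jitter = 1e-10 * float(np.mean(np.diag(Vl)))
        return np.linalg.cholesky(Vl + jitter * np.eye(len(Vl)))

    def whiten(self, lam: float):
        """Response and design premultiplied by L^-1 where V(lam) = L L^T."""
        L = self._chol(lam)
        yw = np.linalg.solve(L, self.endog.to_numpy(float))
        Xw = np.linalg.solve(L, self.exog.to_numpy(float))
        return yw, Xw

    def _gls(self, lam: float):
        L = self._chol(lam)
        y = np.linalg.solve(L, self.endog.to_numpy(float))
        X = np.linalg.solve(L, self.exog.to_numpy(float))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid_w = y - X @ beta
        rss = float(resid_w @ resid_w)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        return beta, rss, logdet, X

    def loglik(self, lam: float) -> float:
        """Profile (ML) Gaussian log-likelihood at a fixed lambda."""
        n = self.nobs
        _, rss, logdet, _ = self._gls(lam)
        sigma2 = rss / n
        return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)

    def lambda_profile(self, grid=None) -> pd.DataFrame:
        """Log-likelihood over a lambda grid; max marked in ``attrs``."""
        if grid is None:
            grid = np.linspace(0.0, 1.0, 21)
        grid = np.asarray(list(grid), dtype=float)
        ll = np.array([self.loglik(l) for l in grid])
        out = pd.DataFrame({"lam": grid, "loglik": ll})
        out.attrs["lam_hat"] = float(grid[int(np.argmax(ll))])
        return out

    def _mle_lambda(self) -> float:
        res = optimize.minimize_scalar(lambda l: -self.loglik(l),
                                       bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-6})
        # compare against the boundaries; break near-ties toward smaller lambda
        cand = sorted({0.0, float(res.x), 1.0})
        lls = [self.loglik(l) for l in cand]
        best = max(lls)
        for l, ll in zip(cand, lls):
            if ll >= best - 1e-8:
                return l
        return float(res.x)

    def fit(self, lam: float | str = "ML") -> PGLSResults:
        """Estimate the regression; ``lam`` is a fixed value or ``"ML"``."""
        if isinstance(lam, str):
            if lam.upper() != "ML":
                raise ValueError(f"lam must be a number in [0,1] or 'ML', got {lam}")
            mode, lam_hat = "ML", self._mle_lambda()
        else:
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"lambda must be in [0, 1], got {lam}")
            mode, lam_hat = "fixed", float(lam)
        beta, rss, logdet, Xw = self._gls(lam_hat)
        n, p = self.nobs, self.exog.shape[1]
        df_resid = n - p
        sigma2 = rss / df_resid          # unbiased, for SEs
        XtX_inv = np.linalg.inv(Xw.T @ Xw)
        bse = np.sqrt(sigma2 * np.diag(XtX_inv))
        fitted = self.exog.to_numpy(float) @ beta
        resid = pd.Series(self.endog.to_numpy(float) - fitted,
                          index=self.endog.index, name="resid")
        return PGLSResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            lam=lam_hat, sigma2=sigma2, llf=self.loglik(lam_hat),
            nobs=n, df_resid=df_resid, lambda_mode=mode, resid=resid)


# -- functional surface ----------------------------------------------------

def pgls_fit(y: pd.Series, X: pd.DataFrame, tree: PhyloTree,
             lam: float | str = "ML", add_intercept: bool = True) -> PGLSResults:
    """One-call PGLS: build the model and fit it."""
    return PGLS(y, X, tree, add_intercept=add_intercept).fit(lam)


def lambda_profile(y: pd.Series, X: pd.DataFrame, tree: PhyloTree,
                   grid=None) -> pd.DataFrame:
    """Log-likelihood profile over lambda for a given regression."""
    return PGLS(y, X, tree).lambda_profile(grid)
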