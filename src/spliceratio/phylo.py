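"""Phylogenetic generalized least squares (PGLS) with Pagel's lambda.

Cross-species trait regressions must account for shared ancestry: under
Brownian trait evolution on a tree, the covariance of two species' values
equals the branch length they share from the root to their most recent
common ancestor.  Pagel's lambda scales the off-diagonal covariances —
lambda = 0 means evolutionary independence (diagonal covariance), lambda =
1 the full Brownian structure — and is estimated here by maximizing the
model likelihood over [0, 1].

The reported quantities for a fit of y on x are the GLS slope (beta), its
two-sided p-value from the t statistic with n - 2 degrees of freedom, the
adjusted R-squared (against the intercept-only GLS model under the same
covariance), and the fitted lambda.

Trees are handled through dendropy; Newick is the on-disk format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import SpliceRatioError


# -- Newick handling --------------------------------------------------------

def parse_newick(
    source: str | Path, default_length: float = 1.0
) -> dendropy.Tree:
    """Parse a Newick tree; missing branch lengths default with a warning.

    Raises :class:`SpliceRatioError` on malformed text or duplicate tip
    labels.
    """
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise SpliceRatioError(f"newick parse error: {exc}") from exc

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise SpliceRatioError(f"duplicate tip labels: {dupes}")

    defaulted = 0
    for node in tree.preorder_node_iter():
        if node.edge.length is None:
            if node.parent_node is None:
                node.edge.length = 0.0
            else:
                node.edge.length = default_length
                defaulted += 1
        elif node.edge.length < 0:
            raise SpliceRatioError(
                f"negative branch length {node.edge.length}"
            )
    if defaulted:
        warnings.warn(
            f"{defaulted} branch length(s) missing; defaulted to "
            f"{default_length}",
            stacklevel=2,
        )
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_to(tree: dendropy.Tree, species: set[str]) -> dendropy.Tree:
    """Induced subtree on the given tip set; path lengths are preserved.

    Unary nodes created by the pruning are collapsed with their edge
    lengths summed, so patristic distances among kept tips are unchanged.
    """
    tips = set(tip_labels(tree))
    keep = tips & set(species)
    if not keep:
        raise SpliceRatioError(
            f"no requested species found in tree; missing: {sorted(species)}"
        )
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    return pruned


# -- covariance and GLS ------------------------------------------------------

def phylo_covariance(
    tree: dendropy.Tree, lam: float = 1.0
) -> tuple[np.ndarray, list[str]]:
    """Brownian covariance over tips under the Pagel-lambda transform.

    ``C[i, j]`` for i != j is lambda times the root-to-MRCA shared branch
    length; ``C[i, i]`` is the full root-to-tip length.  Returns the matrix
    and the tip-label order of its rows.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    index = {id(leaf): k for k, leaf in enumerate(leaves)}
    n = len(leaves)

    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.edge.length is not None and node.edge.length < 0:
            raise SpliceRatioError(f"negative branch length {node.edge.length}")
        parent_depth = depth[id(node.parent_node)] if node.parent_node else 0.0
        depth[id(node)] = parent_depth + (node.edge.length or 0.0)

    C = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = index[id(node)]
            below[id(node)] = [k]
            C[k, k] = depth[id(node)]
            continue
        child_sets = [below.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for i, si in enumerate(child_sets):
            for sj in child_sets[i + 1 :]:
                for a in si:
                    C[a, sj] = d
                    C[sj, a] = d
        below[id(node)] = [k for s in child_sets for k in s]

    if lam != 1.0:
        off = ~np.eye(n, dtype=bool)
        C = C.copy()
        C[off] *= lam
    return C, labels


@dataclass
class PGLSFit:
    """Result of a bivariate PGLS regression."""

    beta: float
    intercept: float
    se_beta: float
    p_beta: float
    r2_adj: float
    lambda_hat: float
    n_species: int
    loglik: float


def _gls(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """GLS solve via Cholesky; returns (coef, rss, cho_factor)."""
    try:
        cho = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise SpliceRatioError(f"singular phylogenetic covariance: {exc}") from exc
    Vi_X = linalg.cho_solve(cho, X)
    Vi_y = linalg.cho_solve(cho, y)
    XtViX = X.T @ Vi_X
    coef = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ coef
    rss = float(resid @ linalg.cho_solve(cho, resid))
    return coef, rss, cho, XtViX


def _loglik(lam: float, C: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    V = C.copy()
    off = ~np.eye(n, dtype=bool)
    V[off] *= lam
    _, rss, cho, _ = _gls(X, y, V)
    sigma2 = rss / n
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)


def pgls_fit(
    x,
    y,
    tree: dendropy.Tree,
    species: list[str] | None = None,
    lam: float | str = "ml",
) -> PGLSFit:
    """PGLS regression of y on x under the tree's Brownian covariance.

    ``species`` gives the tip label for each observation; defaults to the
    tree's leaf order.  ``lam`` is a fixed value in [0, 1] or ``"ml"`` for
    maximum-likelihood estimation (bounded search, tolerance 1e-6,
    endpoints checked so boundary optima are returned exactly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C_full, labels = phylo_covariance(tree, lam=1.0)
    if species is None:
        species = labels
    if len(x) != len(species) or len(y) != len(species):
        raise ValueError("x, y and species must have equal lengths")
    pos = {lab: k for k, lab in enumerate(labels)}
    missing = [s for s in species if s not in pos]
    if missing:
        raise SpliceRatioError(f"species not in tree: {missing}")
    order = [pos[s] for s in species]
    C = C_full[np.ix_(order, order)]
    n = len(y)
    if n < 3:
        raise ValueError("PGLS needs at least 3 species")
    if np.ptp(x) == 0:
        raise SpliceRatioError("constant predictor: slope is unidentifiable")

    X = np.column_stack([np.ones(n), x])

    if lam == "ml":
        res = optimize.minimize_scalar(
            lambda L: -_loglik(L, C, X, y),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        candidates = [0.0, 1.0, float(res.x)]
        lls = [_loglik(L, C, X, y) for L in candidates]
        lam_hat = candidates[int(np.argmax(lls))]
        ll = max(lls)
    else:
        lam_hat = float(lam)
        if not 0.0 <= lam_hat <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        ll = _loglik(lam_hat, C, X, y)

    V = C.copy()
    off = ~np.eye(n, dtype=bool)
    V[off] *= lam_hat
    coef, rss, cho, XtViX = _gls(X, y, V)
    s2 = rss / (n - 2)
    cov_coef = s2 * np.linalg.inv(XtViX)
    se_beta = float(np.sqrt(cov_coef[1, 1]))
    t = coef[1] / se_beta
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)

    X0 = np.ones((n, 1))
    _, rss0, _, _ = _gls(X0, y, V)
    r2 = 1.0 - rss / rss0 if rss0 > 0 else float("nan")
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)

    return PGLSFit(
        beta=float(coef[1]),
        intercept=float(coef[0]),
        se_beta=se_beta,
        p_beta=float(p),
        r2_adj=float(r2_adj),
        lambda_hat=float(lam_hat),
        n_species=n,
        loglik=float(ll),
    )


class PGLS(BaseEstimator, RegressorMixin):
    """Scikit-learn style wrapper around :func:`pgls_fit`.

    Parameters
    ----------
    tree:
        A dendropy tree or Newick text/path.
    species:
        Tip label per observation; defaults to the tree's leaf order.
    lam:
        Fixed Pagel's lambda in [0, 1], or ``"ml"``.

    Attributes
    ----------
    coef_, intercept_, lambda_, pvalue_, se_, r2_adj_, n_species_, loglik_
    """

    def __init__(self, tree=None, species: list[str] | None = None, lam="ml"):
        self.tree = tree
        self.species = species
        self.lam = lam

    def _resolve_tree(self) -> dendropy.Tree:
        if self.tree is None:
            raise SpliceRatioError("PGLS requires a tree")
        if isinstance(self.tree, dendropy.Tree):
            return self.tree
        return parse_newick(self.tree)

    def fit(self, X, y) -> "PGLS":
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("PGLS supports a single predictor")
            X = X[:, 0]
        fit = pgls_fit(X, y, self._resolve_tree(), species=self.species, lam=self.lam)
        self.fit_ = fit
        self.coef_ = np.array([fit.beta])
        self.intercept_ = fit.intercept
        self.lambda_ = fit.lambda_hat
        self.pvalue_ = fit.p_beta
        self.se_ = fit.se_beta
        self.r2_adj_ = fit.r2_adj
        self.n_species_ = fit.n_species
        self.loglik_ = fit.loglik
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise SpliceRatioError("PGLS is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.intercept_ + self.coef_[0] * X
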