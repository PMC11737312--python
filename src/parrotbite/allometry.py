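"""Phylogenetically controlled allometric regression.

Log-log trait relationships are fit by generalized least squares under a
Brownian-motion model of residual covariance: for an ultrametric tree the
expected covariance between species i and j is the branch length they share
from the root to their most recent common ancestor. Pagel's lambda scales the
off-diagonal entries of that matrix, interpolating between an ordinary
regression (lambda = 0, no phylogenetic signal in the residuals) and the full
Brownian expectation (lambda = 1); it is estimated by profiling the maximum
likelihood over [0, 1].

Fitted exponents are compared against isometric (geometric-similarity)
expectations with one-sample t-tests: a force should scale as mass^(2/3) and
as length^2 under isometry.

The method-comparison ANCOVA (`phylo_ancova`) tests whether two ways of
obtaining a bite force (e.g. calculated from dissection vs measured with a
transducer) differ once body mass and phylogeny are controlled for. Species
appearing under both methods contribute two rows whose phylogenetic
covariance is that of the species; the residual (1 - lambda) share of the
variance is independent between the two rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

__all__ = [
    "PhyloCovariance",
    "AllometricFit",
    "CoefficientTest",
    "AncovaReport",
    "ISOMETRIC_EXPONENTS",
    "InvalidRowError",
    "normalize_species",
    "log10_table",
    "brownian_covariance",
    "pgls_fit",
    "isometry_t_test",
    "phylo_ancova",
    "align_species",
]

logger = logging.getLogger(__name__)

#: Expected scaling exponents under geometric similarity: a force scales as
#: an area, i.e. mass^(2/3) (0.66 as conventionally rounded) or length^2.
ISOMETRIC_EXPONENTS: dict[str, float] = {
    "force~mass": 0.66,
    "force~length": 2.0,
    "force~scar_length": 2.0,
}

# lambda = 1 makes the covariance of duplicated species rows exactly
# singular in the ANCOVA, so the ML search stays strictly inside [0, 1).
_LAMBDA_EPS = 1e-6


class InvalidRowError(ValueError):
    """A trait row cannot be log-transformed or validated."""


def normalize_species(label: str) -> str:
    """Canonical species key: stripped, underscored, case-folded."""
    return "_".join(str(label).strip().split()).replace(" ", "_").casefold()


@dataclass(frozen=True)
class PhyloCovariance:
    """An ultrametric tree plus its Brownian shared-branch-length matrix."""

    tree: dendropy.Tree
    matrix: np.ndarray
    tip_order: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.tip_order)

    def reordered(self, labels) -> "PhyloCovariance":
        """Covariance restricted/reordered to ``labels`` (tip-label subset)."""
        index = {t: i for i, t in enumerate(self.tip_order)}
        try:
            idx = np.array([index[l] for l in labels])
        except KeyError as exc:
            raise KeyError(f"label {exc.args[0]!r} is not a tree tip") from exc
        return PhyloCovariance(
            tree=self.tree,
            matrix=self.matrix[np.ix_(idx, idx)],
            tip_order=tuple(labels),
        )


def brownian_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Shared root-to-MRCA branch lengths of every tip pair.

    ``C[i, j]`` is the depth of the most recent common ancestor of tips i
    and j; the diagonal holds the root-to-tip depths. Requires a rooted tree
    with branch lengths on every non-root edge and nonzero depth.
    """
    root = tree.seed_node
    if root is None:
        raise ValueError("tree has no root")
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = []
    for lf in leaves:
        if lf.taxon is not None and lf.taxon.label is not None:
            labels.append(lf.taxon.label)
        elif getattr(lf, "label", None):
            labels.append(lf.label)
        else:
            raise ValueError("tree has an unlabeled tip")
    if len(set(labels)) != len(labels):
        raise ValueError("tree tip labels are not unique")
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)

    depth: dict[int, float] = {}
    tipsets: dict[int, list[int]] = {}
    C = np.zeros((n, n))
    for node in tree.preorder_node_iter():
        if node is root:
            depth[id(node)] = node.edge.length or 0.0
        else:
            if node.edge.length is None:
                raise ValueError("tree has an edge without a branch length")
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            tipsets[id(node)] = [i]
            C[i, i] = depth[id(node)]
        else:
            child_sets = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    ia = np.array(child_sets[a])
                    ib = np.array(child_sets[b])
                    C[np.ix_(ia, ib)] = d
                    C[np.ix_(ib, ia)] = d
            tipsets[id(node)] = [i for s in child_sets for i in s]
    if np.max(np.diag(C)) <= 0:
        raise ValueError("tree has zero depth")
    return PhyloCovariance(tree=tree, matrix=C, tip_order=tuple(labels))


@dataclass(frozen=True)
class AllometricFit:
    """One log-log regression: slope/intercept, inference and signal."""

    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    t_intercept: float
    t_slope: float
    p_intercept: float
    p_slope: float
    r_squared: float
    r_squared_generalized: float
    lam: float
    df: int
    n_species: int
    sigma2: float
    loglik: float
    x_mean: float
    ssx: float


def _pagel_V(C: np.ndarray, lam: float) -> np.ndarray:
    d = np.diag(np.diag(C))
    return lam * (C - d) + d


def _gls_solve(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """Cholesky GLS solve; returns beta, residuals, e'V^-1 e, log|V|."""
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise np.linalg.LinAlgError(
            f"phylogenetic covariance is singular (condition number {cond:.3g})"
        ) from exc
    Xt = solve_triangular(L, X, lower=True)
    yt = solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = y - X @ beta
    rt = solve_triangular(L, resid, lower=True)
    quad = float(rt @ rt)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    XtX = Xt.T @ Xt
    return beta, resid, quad, logdet, XtX, yt, Xt


def _ml_loglik(X, y, C, lam) -> float:
    n = len(y)
    V = _pagel_V(C, lam)
    _, _, quad, logdet, _, _, _ = _gls_solve(X, y, V)
    sigma2 = quad / n
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def _fit_lambda(X, y, C, lam):
    """Resolve lambda: fixed value or ML profile over [0, 1)."""
    if isinstance(lam, str):
        if lam.upper() != "ML":
            raise ValueError("lam must be a number in [0, 1] or 'ML'")
        res = optimize.minimize_scalar(
            lambda l: -_ml_loglik(X, y, C, l),
            bounds=(0.0, 1.0 - _LAMBDA_EPS),
            method="bounded",
            options={"xatol": 1e-8},
        )
        # the profile can be monotone; compare against the boundary values
        cands = [(res.x, -res.fun)]
        for b in (0.0, 1.0 - _LAMBDA_EPS):
            cands.append((b, _ml_loglik(X, y, C, b)))
        lam_hat, ll = max(cands, key=lambda t: t[1])
        return float(lam_hat), float(ll)
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return lam, np.nan


def _gls_inference(X, y, C, lam_hat):
    n, p = X.shape
    V = _pagel_V(C, lam_hat)
    beta, resid, quad, logdet, XtX, yt, Xt = _gls_solve(X, y, V)
    df = n - p
    sigma2 = quad / df
    cov_beta = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    # generalized R^2: improvement over the GLS intercept-only model,
    # measured in the V-metric
    ones = np.ones((n, 1))
    _, _, quad0, _, _, _, _ = _gls_solve(ones, y, V)
    r2_gen = 1.0 - quad / quad0 if quad0 > 0 else np.nan
    # OLS-style R^2 on the raw residuals (what a plain regression reports)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_ols = 1.0 - float(resid @ resid) / sst if sst > 0 else np.nan
    sigma2_ml = quad / n
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
    return beta, se, tvals, pvals, df, sigma2, r2_ols, r2_gen, loglik


def pgls_fit(x, y, cov: PhyloCovariance | None = None, lam="ML") -> AllometricFit:
    """Fit ``y = a + b x`` by phylogenetic GLS with Pagel's lambda.

    Parameters
    ----------
    x, y : array-like
        Log-transformed traits, aligned to ``cov.tip_order`` when ``cov``
        is given.
    cov : PhyloCovariance, optional
        Brownian covariance of the species. ``None`` fits an ordinary
        least-squares regression (equivalent to lambda = 0).
    lam : float or "ML"
        Fixed lambda in [0, 1], or "ML" to profile the likelihood.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equally long")
    n = len(x)
    if n < 3:
        raise ValueError("at least 3 species are required")
    if cov is None:
        C = np.eye(n)
        lam_use: float | str = 0.0
    else:
        if cov.n != n:
            raise ValueError("covariance size does not match the data")
        C = np.asarray(cov.matrix, dtype=float)
        lam_use = lam
    X = np.column_stack([np.ones(n), x])
    if isinstance(lam_use, str):
        lam_hat, _ = _fit_lambda(X, y, C, lam_use)
    else:
        lam_hat = float(lam_use)
    beta, se, tvals, pvals, df, sigma2, r2_ols, r2_gen, loglik = _gls_inference(
        X, y, C, lam_hat
    )
    return AllometricFit(
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
        slope=float(beta[1]),
        slope_se=float(se[1]),
        t_intercept=float(tvals[0]),
        t_slope=float(tvals[1]),
        p_intercept=float(pvals[0]),
        p_slope=float(pvals[1]),
        r_squared=float(r2_ols),
        r_squared_generalized=float(r2_gen),
        lam=float(lam_hat),
        df=int(df),
        n_species=int(n),
        sigma2=float(sigma2),
        loglik=float(loglik),
        x_mean=float(x.mean()),
        ssx=float(np.sum((x - x.mean()) ** 2)),
    )


def isometry_t_test(slope: float, slope_se: float, expected: float, df: int):
    """One-sample t-test of a fitted exponent against an isometric value.

    Returns ``(t, p)`` with ``t = (slope - expected) / slope_se`` and a
    two-sided p-value from the t distribution with ``df`` degrees of freedom.
    """
    if slope_se <= 0:
        raise ValueError("slope_se must be > 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    t = (slope - expected) / slope_se
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def log10_table(traits: pd.DataFrame, fields=None, species_col="species") -> pd.DataFrame:
    """Base-10 log transform of trait columns.

    Adds ``log10_<field>`` columns. Missing (NaN) optional values are left
    missing, to be dropped per relationship downstream; non-positive values
    raise :class:`InvalidRowError` naming the species and field.
    """
    out = traits.copy()
    if fields is None:
        fields = [
            c
            for c in traits.columns
            if c != species_col and pd.api.types.is_numeric_dtype(traits[c])
        ]
    errors = []
    for f in fields:
        vals = pd.to_numeric(out[f], errors="coerce")
        bad = out.index[(vals <= 0) & out[f].notna()]
        for i in bad:
            sp = out.at[i, species_col] if species_col in out.columns else f"row {i}"
            errors.append(f"{sp}: {f} = {out.at[i, f]!r} is not positive")
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"log10_{f}"] = np.where(vals > 0, np.log10(vals), np.nan)
    if errors:
        raise InvalidRowError(
            "non-positive trait values cannot be log-transformed:\n  "
            + "\n  ".join(errors)
        )
    return out


def align_species(
    traits: pd.DataFrame, cov: PhyloCovariance, species_col: str = "species"
):
    """Match trait rows to tree tips and reorder both consistently.

    Labels are compared after space/underscore normalization and case
    folding. Trait rows without a matching tip (and tips without a trait
    row) are dropped with a logged warning, never silently.
    """
    tipkey = {normalize_species(t): t for t in cov.tip_order}
    keep_rows = []
    matched_tips = []
    for i, row in traits.iterrows():
        key = normalize_species(row[species_col])
        if key in tipkey:
            keep_rows.append(i)
            matched_tips.append(tipkey[key])
        else:
            logger.warning("species %r has no matching tree tip; dropped", row[species_col])
    unmatched_tips = set(cov.tip_order) - set(matched_tips)
    for t in sorted(unmatched_tips):
        logger.warning("tree tip %r has no trait row; dropped", t)
    if len(matched_tips) != len(set(matched_tips)):
        raise InvalidRowError("duplicate species after normalization")
    aligned = traits.loc[keep_rows].reset_index(drop=True)
    return aligned, cov.reordered(matched_tips)


@dataclass(frozen=True)
class CoefficientTest:
    """One regression coefficient with its t-test and 95% interval."""

    estimate: float
    se: float
    t: float
    p: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class AncovaReport:
    """Method-comparison ANCOVA: interaction test, then the method effect."""

    interaction: CoefficientTest
    simplified: bool
    method_effect: CoefficientTest
    covariate: CoefficientTest
    lam: float
    n_obs: int
    n_species: int
    alpha: float

    def to_dict(self) -> dict:
        """JSON-ready representation of the full model report."""
        from dataclasses import asdict

        return asdict(self)


def _coef_test(beta, se, df, j) -> CoefficientTest:
    t = beta[j] / se[j]
    p = 2 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * se[j]
    return CoefficientTest(
        estimate=float(beta[j]),
        se=float(se[j]),
        t=float(t),
        p=float(p),
        ci_low=float(beta[j] - half),
        ci_high=float(beta[j] + half),
    )


def phylo_ancova(
    data: pd.DataFrame,
    cov: PhyloCovariance,
    y_col: str = "log10_bite_force",
    x_col: str = "log10_body_mass",
    group_col: str = "bite_force_source",
    species_col: str = "species",
    alpha: float = 0.05,
    lam="ML",
) -> AncovaReport:
    """Compare two bite-force determination methods, controlling for body
    mass and phylogeny.

    Fits ``y ~ x * method`` by GLS on the duplicated-species Brownian
    covariance; if the interaction is not significant at ``alpha`` the model
    is simplified to ``y ~ x + method`` and the method main effect is tested
    on the refit. With a significant interaction the method effect reported
    is the full model's main-effect coefficient (the offset at x = 0).
    """
    levels = sorted(pd.unique(data[group_col]))
    if len(levels) != 2:
        raise ValueError(
            f"{group_col!r} must have exactly two levels, got {levels!r}"
        )
    tip_index = {normalize_species(t): i for i, t in enumerate(cov.tip_order)}
    try:
        sp_idx = np.array(
            [tip_index[normalize_species(s)] for s in data[species_col]]
        )
    except KeyError as exc:
        raise KeyError(f"species {exc.args[0]!r} is not a tree tip") from exc
    C = np.asarray(cov.matrix, dtype=float)[np.ix_(sp_idx, sp_idx)]
    y = np.asarray(data[y_col], dtype=float)
    x = np.asarray(data[x_col], dtype=float)
    g = (np.asarray(data[group_col]) == levels[1]).astype(float)
    n = len(y)

    X_full = np.column_stack([np.ones(n), x, g, x * g])
    lam_full, _ = (
        _fit_lambda(X_full, y, C, lam) if isinstance(lam, str) else (float(lam), None)
    )
    beta, se, tvals, pvals, df, *_ = _gls_inference(X_full, y, C, lam_full)
    interaction = _coef_test(beta, se, df, 3)

    simplified = interaction.p >= alpha
    if simplified:
        X_add = np.column_stack([np.ones(n), x, g])
        lam_add, _ = (
            _fit_lambda(X_add, y, C, lam) if isinstance(lam, str) else (float(lam), None)
        )
        beta_a, se_a, _, _, df_a, *_ = _gls_inference(X_add, y, C, lam_add)
        method = _coef_test(beta_a, se_a, df_a, 2)
        covariate = _coef_test(beta_a, se_a, df_a, 1)
        lam_report = lam_add
    else:
        method = _coef_test(beta, se, df, 2)
        covariate = _coef_test(beta, se, df, 1)
        lam_report = lam_full

    return AncovaReport(
        interaction=interaction,
        simplified=bool(simplified),
        method_effect=method,
        covariate=covariate,
        lam=float(lam_report),
        n_obs=int(n),
        n_species=int(len(np.unique(sp_idx))),
        alpha=float(alpha),
    )
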