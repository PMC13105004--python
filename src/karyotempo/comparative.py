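"""Cross-clade analyses of dysploidy rates.

Given a table of per-clade rates with kingdom and higher-taxon labels, this
module asks how much of the rate variation group identity explains: one-way
ANOVA, a one-way random-intercept REML variance-components model with its
intraclass correlation (ICC), label-permutation significance tests, the
max/min fold range, and phylogenetic generalised least squares (PGLS) of
rates on covariates under a Brownian-motion covariance.

Decomposition operates on log10 rates by default: rates are multiplicative
quantities and cross-clade summaries are geometric means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .trees import TimeTree

__all__ = [
    "VarDecompResult",
    "PGLSResult",
    "log_rates",
    "geometric_means",
    "fold_range",
    "anova_oneway",
    "reml_variance_components",
    "permutation_test",
    "variance_decomposition",
    "pgls",
]


@dataclass
class VarDecompResult:
    F: float
    df: tuple[int, int]
    p_anova: float
    sigma2_between: float
    sigma2_within: float
    icc: float
    pct_between: float
    p_perm: float

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df_between": self.df[0],
            "df_within": self.df[1],
            "p_anova": self.p_anova,
            "sigma2_between": self.sigma2_between,
            "sigma2_within": self.sigma2_within,
            "icc": self.icc,
            "pct_between": self.pct_between,
            "p_perm": self.p_perm,
        }


@dataclass
class PGLSResult:
    slope: float
    intercept: float
    slope_se: float
    t_slope: float
    p_slope: float
    n: int


def log_rates(table: pd.DataFrame, rate_col: str = "rate_myr") -> pd.DataFrame:
    """Add a ``log10_rate`` column; errors on non-positive rates by clade name."""
    rates = table[rate_col]
    bad = table.loc[rates <= 0, "clade"].tolist() if "clade" in table else list(rates[rates <= 0].index)
    if bad:
        raise ValueError(f"non-positive rates for clades {bad[:5]}; cannot log-transform")
    out = table.copy()
    out["log10_rate"] = np.log10(rates)
    return out


def geometric_means(table: pd.DataFrame, by: str, rate_col: str = "rate_myr") -> pd.Series:
    """Per-group geometric mean rate, ``10^(mean of log10 rates)``."""
    logs = np.log10(table[rate_col])
    return 10.0 ** logs.groupby(table[by]).mean()


def fold_range(table: pd.DataFrame, rate_col: str = "rate_myr") -> float:
    """Max rate over min rate across clades."""
    rates = np.asarray(table[rate_col], dtype=float)
    if rates.size < 2:
        raise ValueError("need >= 2 clades for a fold range")
    return float(rates.max() / rates.min())


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups))
    return codes, len(uniques)


def _anova_F(values: np.ndarray, codes: np.ndarray, G: int) -> tuple[float, int, int]:
    N = values.size
    grand = values.mean()
    sums = np.bincount(codes, weights=values, minlength=G)
    ns = np.bincount(codes, minlength=G)
    means = sums / ns
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((values - means[codes]) ** 2))
    df_b, df_w = G - 1, N - G
    ms_b = ss_between / df_b
    if ss_within == 0:
        warnings.warn("zero within-group variance; F reported as +inf")
        return np.inf, df_b, df_w
    ms_w = ss_within / df_w
    return ms_b / ms_w, df_b, df_w


def anova_oneway(values, groups) -> dict:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within."""
    values = np.asarray(values, dtype=float)
    codes, G = _group_codes(groups)
    if G < 2:
        raise ValueError("need >= 2 groups")
    if values.size - G < 1:
        raise ValueError("need >= 1 residual degree of freedom")
    F, df_b, df_w = _anova_F(values, codes, G)
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return {"F": float(F), "df": (df_b, df_w), "p_anova": p}


def reml_variance_components(values, groups) -> dict:
    """REML fit of the one-way random-intercept model.

    ``y_ij = μ + a_i + e_ij`` with ``a_i ~ N(0, σ²_b)``, ``e_ij ~ N(0, σ²_w)``.
    The restricted likelihood is profiled over μ and σ²_w, leaving a 1-D
    search over the variance ratio θ = σ²_b/σ²_w with the boundary θ = 0
    permitted, so a zero between-group component is an honest estimate, not an
    optimiser failure. Unbalanced designs are handled exactly.
    """
    y = np.asarray(values, dtype=float)
    codes, G = _group_codes(groups)
    if G < 2:
        raise ValueError("need >= 2 groups")
    N = y.size
    ns = np.bincount(codes, minlength=G).astype(float)
    sums = np.bincount(codes, weights=y, minlength=G)
    means = sums / ns
    ssw = float(np.sum((y - means[codes]) ** 2))

    def neg_restricted_ll(theta: float) -> float:
        w = ns / (1.0 + ns * theta)
        sw = w.sum()
        mu = float(np.sum(w * means) / sw)
        q = ssw + float(np.sum(w * (means - mu) ** 2))
        sigma_w2 = q / (N - 1)
        return 0.5 * (
            (N - 1) * np.log(sigma_w2) + np.sum(np.log1p(ns * theta)) + np.log(sw)
        )

    # boundary candidate plus a log-scale interior search
    res = minimize_scalar(
        lambda u: neg_restricted_ll(np.exp(u)), bounds=(-14.0, 14.0), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"REML optimisation failed: {res}")
    theta = float(np.exp(res.x))
    if neg_restricted_ll(0.0) <= res.fun:
        theta = 0.0
    w = ns / (1.0 + ns * theta)
    mu = float(np.sum(w * means) / w.sum())
    q = ssw + float(np.sum(w * (means - mu) ** 2))
    sigma_w2 = q / (N - 1)
    sigma_b2 = theta * sigma_w2
    icc = sigma_b2 / (sigma_b2 + sigma_w2) if (sigma_b2 + sigma_w2) > 0 else 0.0
    return {
        "sigma2_between": float(sigma_b2),
        "sigma2_within": float(sigma_w2),
        "icc": float(icc),
    }


def permutation_test(
    values,
    groups,
    statistic: str = "F",
    n_perm: int = 9999,
    seed: int = 0,
) -> float:
    """Label-permutation p-value for a grouping statistic (``F`` or ``icc``).

    Labels are permuted uniformly at random; the add-one estimator
    ``p = (#{stat_perm >= stat_obs} + 1) / (n_perm + 1)`` bounds the smallest
    attainable p at ``1/(n_perm+1)``. The p-value depends only on the ordering
    the statistic induces, so monotone transforms of it leave p unchanged.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    values = np.asarray(values, dtype=float)
    codes, G = _group_codes(groups)
    if G < 2:
        raise ValueError("permutation test needs >= 2 groups")
    rng = np.random.default_rng(seed)

    if statistic == "F":
        def stat(c):
            return _anova_F(values, c, G)[0]
    elif statistic == "icc":
        def stat(c):
            return reml_variance_components(values, c)["icc"]
    else:
        raise ValueError("statistic must be 'F' or 'icc'")

    obs = stat(codes)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if stat(perm) >= obs:
            count += 1
    return (count + 1.0) / (n_perm + 1.0)


def variance_decomposition(
    table: pd.DataFrame,
    level: str = "kingdom",
    *,
    rate_col: str = "rate_myr",
    use_log10: bool = True,
    n_perm: int = 9999,
    seed: int = 0,
    perm_statistic: str = "F",
) -> VarDecompResult:
    """ANOVA + REML + permutation test of rates against one label level.

    Nesting is handled by running each level separately (pass
    ``level='kingdom'`` and ``level='higher_taxon'`` in turn).
    """
    values = np.log10(table[rate_col]) if use_log10 else table[rate_col]
    values = np.asarray(values, dtype=float)
    groups = table[level]
    a = anova_oneway(values, groups)
    r = reml_variance_components(values, groups)
    p_perm = permutation_test(values, groups, perm_statistic, n_perm=n_perm, seed=seed)
    return VarDecompResult(
        F=a["F"],
        df=a["df"],
        p_anova=a["p_anova"],
        sigma2_between=r["sigma2_between"],
        sigma2_within=r["sigma2_within"],
        icc=r["icc"],
        pct_between=100.0 * r["icc"],
        p_perm=p_perm,
    )


def brownian_covariance(tree: TimeTree, labels: list[str]) -> np.ndarray:
    """V_ij = root-to-MRCA path length for tips i, j (Brownian covariance up
    to a σ² factor, which cancels in GLS estimates)."""
    order = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    depths: dict[int, float] = {}
    tipsets: dict[int, list[int]] = {}
    for node in tree.tree.preorder_node_iter():
        el = node.edge.length or 0.0
        parent = node.parent_node
        depths[id(node)] = (depths[id(parent)] if parent else 0.0) + el
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            if lab not in order:
                raise KeyError(f"tree tip {lab!r} has no observation")
            i = order[lab]
            V[i, i] = depths[id(node)]
            tipsets[id(node)] = [i]
        else:
            groups = [tipsets[id(c)] for c in node.child_nodes()]
            d = depths[id(node)]
            for a_idx in range(len(groups)):
                for b_idx in range(a_idx + 1, len(groups)):
                    for i in groups[a_idx]:
                        for j in groups[b_idx]:
                            V[i, j] = V[j, i] = d
            tipsets[id(node)] = [i for g in groups for i in g]
    return V


def pgls(y, x, tree: TimeTree) -> PGLSResult:
    """Phylogenetic GLS of y on x under plain Brownian covariance.

    ``y`` and ``x`` may be pandas Series indexed by tip label (aligned to the
    tree) or arrays in the tree's tip order. Estimates
    ``β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y``; the residual variance uses ``n − 2`` degrees of
    freedom and the slope is tested two-sided against Student's t. On a star
    phylogeny V is proportional to the identity and PGLS reduces to OLS.
    """
    labels = tree.tip_labels
    if hasattr(y, "reindex"):
        y = y.reindex(labels).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
    if hasattr(x, "reindex"):
        x = x.reindex(labels).to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    n = y.size
    if n < 3 or n != len(labels) or x.size != n:
        raise ValueError("need n >= 3 matched observations")
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("missing values in y or x")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: singular design")
    V = brownian_covariance(tree, labels)
    try:
        Lc = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance (zero-distance tips?)") from exc
    X = np.column_stack([np.ones(n), x])
    Xs = np.linalg.solve(Lc, X)
    ys = np.linalg.solve(Lc, y)
    XtX = Xs.T @ Xs
    beta = np.linalg.solve(XtX, Xs.T @ ys)
    resid = ys - Xs @ beta
    sigma2 = float(resid @ resid) / (n - 2)
    cov_beta = sigma2 * np.linalg.inv(XtX)
    se = float(np.sqrt(cov_beta[1, 1]))
    t = float(beta[1] / se)
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return PGLSResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_se=se,
        t_slope=t,
        p_slope=p,
        n=n,
    )
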