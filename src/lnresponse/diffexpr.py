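"""Covariate-adjusted moderated differential expression.

The model is a per-gene linear model on log2 expression with a shared
intra-patient correlation: repeated samples from the same patient are
handled by generalized least squares under block equicorrelation with a
single consensus correlation ``rho`` pooled across genes (the
duplicate-correlation device), rather than per-gene random-effect fits.
Residual variances are then shrunk across genes by empirical Bayes: the
prior ``(d0, s0^2)`` is estimated by moment-matching the marginal
distribution of ``log s_g^2`` through digamma/trigamma inversion, and the
moderated t statistic uses the posterior variance

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

on ``d0 + d_g`` degrees of freedom.  The response-group contrast is
oriented so that a positive log-fold-change means higher expression in
non-responders.

`ModeratedLinearModel` / `ModeratedDEResults` follow the model/results
idiom: build the model from the expression matrix, design and patient
blocks, call ``fit()``, and read estimates, signatures and a ``summary()``
off the results object.  Thin functional wrappers (`moderated_de`,
`bonferroni_signatures`, `ratio_score`, `gsea_compare`) expose the same
operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import digamma, polygamma

__all__ = [
    "ModeratedLinearModel", "ModeratedDEResults", "SignatureSet",
    "GseaResult", "build_design", "estimate_consensus_correlation",
    "estimate_variance_prior", "moderated_de", "bonferroni_signatures",
    "ratio_score", "gsea_compare",
]

D0_CAP = 1e6  # prior dof above this is reported as the infinity sentinel


@dataclass
class SignatureSet:
    """Per-drug up/down differential signature (up = higher in
    non-responders)."""

    drug: str
    up: List[str]
    down: List[str]
    stats: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if set(self.up) & set(self.down):
            raise ValueError("up and down signatures must be disjoint")

    def to_gene_sets(self) -> Dict[str, List[str]]:
        return {f"{self.drug}_up": list(self.up),
                f"{self.drug}_down": list(self.down)}


@dataclass
class GseaResult:
    es: float
    nes: float
    p: float
    set_size: int
    running_sum: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# design

def build_design(cohort: pd.DataFrame,
                 covariates: Sequence[str] = ("sex", "sledai",
                                              "prednisone_dose", "drug_dose"),
                 drop_degenerate: bool = True) -> pd.DataFrame:
    """Design matrix: intercept, non-responder indicator, then covariates.

    Sex enters as a female indicator, doses and scores as continuous
    values.  Constant covariate columns (e.g. a dose that is zero for every
    sample of a drug) are dropped with a warning when ``drop_degenerate``.
    Race is deliberately not part of the default design.
    """
    X = pd.DataFrame(index=cohort.index)
    X["intercept"] = 1.0
    X["response"] = (cohort["response"] == "non-responder").astype(float)
    for cov in covariates:
        if cov not in cohort.columns:
            raise ValueError(f"covariate {cov!r} absent from cohort table")
        col = cohort[cov]
        X[cov] = (col == "F").astype(float) if col.dtype == object else \
            col.astype(float)
    const = [c for c in X.columns[1:] if X[c].nunique() <= 1]
    if const:
        if not drop_degenerate:
            raise ValueError(f"constant design columns: {const}")
        warnings.warn(f"dropping constant design columns: {const}")
        X = X.drop(columns=const)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


# ---------------------------------------------------------------------------
# consensus intra-patient correlation

def estimate_consensus_correlation(expr: pd.DataFrame, blocks: Sequence,
                                   design: pd.DataFrame,
                                   trim: float = 0.1) -> float:
    """Pooled intra-block (intra-patient) residual correlation.

    Per gene, residuals from the fixed-effect OLS fit yield a
    method-of-moments intra-block correlation whose moment equations
    account exactly for the projection onto the design's orthogonal
    complement (naive ANOVA-on-residuals estimators are biased low because
    between-patient covariates absorb between-patient variance).  The
    consensus value is the tanh of the trimmed mean of the
    atanh-transformed per-gene correlations.
    """
    blocks = np.asarray(blocks)
    X = design.to_numpy(float)
    Y = expr.to_numpy(float)
    _, sizes = np.unique(blocks, return_counts=True)
    if (sizes >= 2).sum() < 2:
        warnings.warn("fewer than two patients with repeated samples; "
                      "consensus correlation set to 0")
        return 0.0

    n, p = X.shape
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    M = np.eye(n) - H
    R = Y @ M  # genes x samples residuals (M symmetric)

    uniq, inv = np.unique(blocks, return_inverse=True)
    B = (inv[:, None] == inv[None, :]).astype(float)  # block indicator
    W = B - np.eye(n)  # within-block off-diagonal pairs
    MBM = M @ B @ M
    a1 = float((M * W).sum())
    a2 = float((MBM * W).sum())
    d1 = float(n - p)
    d2 = float(np.trace(MBM))

    # per gene: sum of within-block residual cross-products and total SS
    block_sums = np.zeros((R.shape[0], uniq.size))
    np.add.at(block_sums.T, inv, R.T)
    A = ((block_sums ** 2).sum(axis=1) - (R ** 2).sum(axis=1))
    D = (R ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(D > 0, A / D, 0.0)
        denom = (a2 - a1) - t * (d2 - d1)
        rho_g = np.where(np.abs(denom) > 1e-12,
                         (t * d1 - a1) / denom, 0.0)
    rho_g = np.clip(rho_g, -0.99, 0.99)
    pooled = np.tanh(scipy.stats.trim_mean(np.arctanh(rho_g), trim))
    lower = -1.0 / (sizes.max() - 1.0)
    return float(np.clip(pooled, lower + 1e-6, 0.999))


# ---------------------------------------------------------------------------
# empirical-Bayes variance prior

def _trigamma_inverse(y: float, tol: float = 1e-8, maxit: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(maxit):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < tol * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df) -> Tuple[float, float]:
    """Moment-match the scaled inverse-chi-square variance prior.

    Given per-gene residual variances ``s2`` on ``df`` residual degrees of
    freedom (scalar or per-gene; ``inf`` means the variances are exact),
    returns ``(d0, s0_squared)``.  ``d0 = inf`` is the no-excess-variability
    sentinel (all gene variances compatible with a single value).
    """
    s2 = np.asarray(s2, float)
    df = np.broadcast_to(np.asarray(df, float), s2.shape)
    keep = (s2 > 0) & np.isfinite(s2)
    if keep.sum() < 2:
        raise ValueError("need at least two positive variances")
    s2, df = s2[keep], df[keep]

    finite = np.isfinite(df)
    corr = np.zeros_like(s2)
    tri = np.zeros_like(s2)
    corr[finite] = digamma(df[finite] / 2.0) - np.log(df[finite] / 2.0)
    tri[finite] = polygamma(1, df[finite] / 2.0)
    e = np.log(s2) - corr
    target = e.var(ddof=1) - tri.mean()
    # no excess variability across genes: infinite prior dof, and the prior
    # variance is simply the (geometric) mean observed variance
    if target <= 0:
        return np.inf, float(np.exp(np.log(s2).mean()))
    x = _trigamma_inverse(target)  # x = d0 / 2
    d0 = 2.0 * x
    if d0 > D0_CAP:
        return np.inf, float(np.exp(np.log(s2).mean()))
    s02 = float(np.exp(e.mean() + digamma(x) - np.log(x)))
    return float(d0), s02


# ---------------------------------------------------------------------------
# model / results

class ModeratedLinearModel:
    """Per-gene GLS with consensus intra-patient correlation and
    empirical-Bayes variance moderation.

    Parameters
    ----------
    expr : genes x samples log2 expression (DataFrame).
    design : samples x covariates design matrix (see `build_design`);
        the tested coefficient defaults to the ``response`` column.
    blocks : patient identifier per sample (repeated-measures blocks).
    """

    def __init__(self, expr: pd.DataFrame, design: pd.DataFrame,
                 blocks: Optional[Sequence] = None, coef: str = "response"):
        if list(expr.columns) != list(design.index):
            raise ValueError("expression columns and design rows must align")
        if coef not in design.columns:
            raise ValueError(f"tested coefficient {coef!r} not in design")
        self.expr = expr
        self.design = design
        self.blocks = (np.asarray(blocks) if blocks is not None
                       else np.arange(expr.shape[1]))
        if len(self.blocks) != expr.shape[1]:
            raise ValueError("blocks must align with samples")
        self.coef = coef

    @classmethod
    def from_cohort(cls, expr: pd.DataFrame, cohort: pd.DataFrame,
                    covariates: Sequence[str] = ("sex", "sledai",
                                                 "prednisone_dose",
                                                 "drug_dose")):
        design = build_design(cohort.loc[expr.columns], covariates)
        return cls(expr, design, cohort.loc[expr.columns, "patient_id"])

    def estimate_correlation(self) -> float:
        return estimate_consensus_correlation(self.expr, self.blocks,
                                              self.design)

    def _whiten(self, rho: float) -> Tuple[np.ndarray, np.ndarray]:
        X = self.design.to_numpy(float)
        Y = self.expr.to_numpy(float)
        if rho == 0.0:
            return X, Y
        Xw, Yw = X.copy(), Y.copy()
        uniq, inv = np.unique(self.blocks, return_inverse=True)
        for b in range(uniq.size):
            idx = np.flatnonzero(inv == b)
            mb = idx.size
            a = 1.0 / np.sqrt(1.0 - rho)
            c = 1.0 / np.sqrt(1.0 - rho + mb * rho)
            for M in (Xw, Yw.T):
                blockvals = M[idx]
                mean = blockvals.mean(axis=0, keepdims=True)
                M[idx] = a * (blockvals - mean) + c * mean
        return Xw, Yw

    def fit(self, rho: Optional[float] = None,
            prior_df: Optional[float] = None) -> "ModeratedDEResults":
        """Fit the GLS + moderation model.

        ``rho=None`` estimates the consensus correlation first;
        ``prior_df`` overrides the estimated d0 (0 disables shrinkage).
        """
        if rho is None:
            rho = self.estimate_correlation()
        Xw, Yw = self._whiten(rho)
        n, p = Xw.shape
        if n <= p:
            raise ValueError("zero residual degrees of freedom")
        d_resid = n - p

        constant = self.expr.to_numpy().std(axis=1) == 0.0
        if constant.any():
            warnings.warn(f"{int(constant.sum())} constant gene rows flagged "
                          "and skipped")

        XtX_inv = np.linalg.inv(Xw.T @ Xw)
        H = XtX_inv @ Xw.T
        beta = Yw @ H.T  # genes x p
        resid = Yw - beta @ Xw.T
        s2 = (resid ** 2).sum(axis=1) / d_resid
        j = list(self.design.columns).index(self.coef)
        se_unscaled = np.sqrt(XtX_inv[j, j])
        logfc = beta[:, j]

        usable = ~constant & (s2 > 0)
        if prior_df is None:
            d0, s02 = estimate_variance_prior(s2[usable], d_resid)
        elif prior_df == 0:
            d0, s02 = 0.0, float(np.median(s2[usable]))
        else:
            d0 = float(prior_df)
            _, s02 = estimate_variance_prior(s2[usable], d_resid)

        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_total = np.inf
        else:
            s2_post = (d0 * s02 + d_resid * s2) / (d0 + d_resid)
            df_total = d0 + d_resid

        with np.errstate(divide="ignore", invalid="ignore"):
            t = logfc / (se_unscaled * np.sqrt(s2_post))
        if np.isinf(df_total):
            pvals = 2.0 * scipy.stats.norm.sf(np.abs(t))
        else:
            pvals = 2.0 * scipy.stats.t.sf(np.abs(t), df_total)
        t[constant] = np.nan
        pvals[constant] = np.nan

        m = int((~constant).sum())
        table = pd.DataFrame({
            "gene": self.expr.index,
            "logFC": logfc,
            "s2": s2,
            "df_resid": float(d_resid),
            "s2_post": s2_post,
            "t": t,
            "p": pvals,
            "p_bonferroni": np.minimum(1.0, pvals * m),
            "direction": np.where(logfc > 0, "up", "down"),
            "valid": ~constant,
        }).set_index("gene", drop=False)
        return ModeratedDEResults(self, table, rho=rho, d0=d0, s02=s02,
                                  df_total=df_total)


@dataclass
class ModeratedDEResults:
    """Estimates, moderation hyperparameters and signature extraction."""

    model: ModeratedLinearModel
    table: pd.DataFrame
    rho: float
    d0: float
    s02: float
    df_total: float

    def signatures(self, drug: str = "", alpha: float = 0.05) -> SignatureSet:
        return bonferroni_signatures(self.table, drug=drug, alpha=alpha)

    def summary(self, top: int = 10) -> str:
        t = self.table[self.table["valid"]].sort_values("p")
        n_sig = int((t["p_bonferroni"] < 0.05).sum())
        lines = [
            "Moderated differential expression (GLS + empirical Bayes)",
            "=" * 60,
            f"genes: {len(self.table)}   samples: {self.model.expr.shape[1]}",
            f"consensus intra-patient correlation rho: {self.rho:.4f}",
            f"prior dof d0: {self.d0:.4g}   prior variance s0^2: {self.s02:.4g}",
            f"residual dof per gene: {t['df_resid'].iloc[0]:.0f}   "
            f"total dof: {self.df_total:.4g}",
            f"genes with Bonferroni p < 0.05: {n_sig}",
            "-" * 60,
            f"{'gene':<12}{'logFC':>9}{'t':>9}{'p':>12}{'p_bonf':>12}",
        ]
        for _, r in t.head(top).iterrows():
            lines.append(f"{r['gene']:<12}{r['logFC']:>9.3f}{r['t']:>9.2f}"
                         f"{r['p']:>12.3e}{r['p_bonferroni']:>12.3e}")
        return "\n".join(lines)


def moderated_de(expr: pd.DataFrame, design: pd.DataFrame,
                 rho: float = 0.0, blocks: Optional[Sequence] = None,
                 prior_df: Optional[float] = None) -> ModeratedDEResults:
    """Functional wrapper around `ModeratedLinearModel.fit`."""
    return ModeratedLinearModel(expr, design, blocks).fit(
        rho=rho, prior_df=prior_df)


def bonferroni_signatures(table: pd.DataFrame, drug: str = "",
                          alpha: float = 0.05) -> SignatureSet:
    """Split genes with Bonferroni p strictly below alpha by sign of logFC."""
    if len(table) == 0:
        raise ValueError("empty results table")
    sig = table[table["valid"] & (table["p_bonferroni"] < alpha)]
    up = sig[sig["logFC"] > 0]["gene"].tolist()
    down = sig[sig["logFC"] < 0]["gene"].tolist()
    return SignatureSet(drug=drug, up=up, down=down, stats=sig.copy())


# ---------------------------------------------------------------------------
# ratio score

def ratio_score(sample_expr: pd.DataFrame, signature: SignatureSet,
                offset: float = 0.0) -> pd.Series:
    """Per-sample ratio of mean up-gene to mean down-gene log2 expression.

    ``offset`` re-anchors the matrix (added before the ratio) when
    down-gene means are not strictly positive.
    """
    if not signature.up or not signature.down:
        raise ValueError("signature up and down lists must be non-empty")
    up = [g for g in signature.up if g in sample_expr.index]
    down = [g for g in signature.down if g in sample_expr.index]
    if not up or not down:
        raise ValueError("signature genes absent from the expression matrix")
    mat = sample_expr + offset
    down_mean = mat.loc[down].mean(axis=0)
    if (down_mean <= 0).any():
        raise ValueError(
            "down-gene mean expression <= 0; pass a positive `offset` to "
            "re-anchor the matrix before taking the ratio")
    scores = mat.loc[up].mean(axis=0) / down_mean
    scores.name = f"{signature.drug}_ratio_score"
    return scores


# ---------------------------------------------------------------------------
# GSEA

def _running_sum(order_is_hit: np.ndarray, weights: np.ndarray,
                 weight_exponent: float) -> np.ndarray:
    n = order_is_hit.size
    n_hit = int(order_is_hit.sum())
    w = np.abs(weights) ** weight_exponent
    w_hit = np.where(order_is_hit, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:  # all hit weights zero: fall back to unweighted hits
        w_hit = order_is_hit.astype(float)
        denom = float(n_hit)
    steps = w_hit / denom - (~order_is_hit) / float(n - n_hit)
    return np.cumsum(steps)


def gsea_compare(ranked_genes: pd.Series, gene_set: Iterable[str],
                 weight_exponent: float = 1.0, n_perm: int = 1000,
                 seed: int = 0) -> GseaResult:
    """Weighted Kolmogorov-Smirnov enrichment of a gene set in a ranking.

    ``ranked_genes`` maps gene -> ranking weight (e.g. log fold change);
    genes are sorted by decreasing weight internally.  The enrichment score
    is the extreme deviation of the running sum (hits increment by
    ``|w|^p / sum_set |w|^p``, misses decrement by ``1/(N - N_set)``); the
    permutation p-value and NES come from gene-label permutations.
    """
    ranked = ranked_genes.sort_values(ascending=False)
    universe = ranked.index.to_numpy()
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    if not gene_set <= set(universe):
        raise ValueError("gene set must be a subset of the ranked universe")
    if len(gene_set) >= universe.size:
        raise ValueError("gene set equals the ranked universe")

    is_hit = np.isin(universe, list(gene_set))
    weights = ranked.to_numpy(float)
    rs = _running_sum(is_hit, weights, weight_exponent)
    es = float(rs[np.argmax(np.abs(rs))])

    rng = np.random.default_rng(seed)
    n_hit = int(is_hit.sum())
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        perm_hit = np.zeros(universe.size, bool)
        perm_hit[rng.choice(universe.size, n_hit, replace=False)] = True
        prs = _running_sum(perm_hit, weights, weight_exponent)
        perm_es[i] = prs[np.argmax(np.abs(prs))]

    same = perm_es * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
    n_same = int(same.sum())
    p = (1.0 + (np.abs(perm_es[same]) >= abs(es)).sum()) / (1.0 + n_same)
    mean_same = np.abs(perm_es[same]).mean() if n_same else np.nan
    nes = es / mean_same if n_same and mean_same > 0 else np.nan
    return GseaResult(es=es, nes=float(nes), p=float(p),
                      set_size=n_hit, running_sum=rs)
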