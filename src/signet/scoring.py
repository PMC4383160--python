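"""Gene and interaction scoring for active-module detection.

Per-gene differential-expression p-values are modelled as a beta-uniform
mixture (BUM): density ``f(x) = lam + (1 - lam) * a * x**(a - 1)`` on (0, 1],
where the beta(a, 1) component (0 < a < 1) captures signal concentrated near
zero and the uniform component captures noise.  From a fitted BUM and a chosen
false-discovery rate the significance threshold tau follows, and each gene
receives the log-likelihood-ratio-style node score

    score(x) = (a - 1) * (log x - log tau)

which is positive exactly for p-values below tau.  Interactions are scored by
the sample covariance of the two expression profiles, corr(X, Y) * std(X) *
std(Y); a subnetwork's edge total is the sum of the per-edge scores
standardized against the full network's edge-score background.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import CASE, CONTROL, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BUMFit", "ScoringConfig", "ScoredNetwork",
    "compute_pvalues", "fit_bum", "bum_tau", "node_score",
    "calibrate_fdr", "edge_score", "subnetwork_edge_score", "score_network",
]


@dataclass(frozen=True)
class BUMFit:
    """Maximum-likelihood beta-uniform mixture fit over a p-value vector.

    ``a``   shape of the beta(a, 1) signal component, 0 < a < 1;
    ``lam`` weight of the uniform noise component, 0 <= lam < 1;
    ``loglik`` maximized log-likelihood; ``n`` number of p-values fitted.
    """

    a: float
    lam: float
    loglik: float
    n: int

    @property
    def pi_upper(self) -> float:
        """Upper bound on the noise density at x=1: lam + (1-lam)*a."""
        return self.lam + (1.0 - self.lam) * self.a

    def cdf(self, x):
        """Model CDF  F(x) = lam*x + (1-lam)*x**a."""
        x = np.asarray(x, dtype=float)
        return self.lam * x + (1.0 - self.lam) * x ** self.a


@dataclass
class ScoringConfig:
    """Knobs of the scoring stage.

    ``fdr`` may be None, meaning calibrate per region so that about
    ``target_positive_fraction`` of nodes score positive (the criterion used
    to pick the per-region FDR values shipped in ``REGION_FDR_DEFAULTS``).
    """

    fdr: float | None = None
    target_positive_fraction: float = 0.15
    edge_threshold: float = 0.8
    test: str = "welch"  # or "student"

    def __post_init__(self):
        if self.fdr is not None and not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must lie in (0,1)")
        if not 0.0 < self.target_positive_fraction < 1.0:
            raise ValueError("target_positive_fraction must lie in (0,1)")
        if self.edge_threshold < 0:
            raise ValueError("edge_threshold must be >= 0")


#: FDR values used for the six brain regions of the Alzheimer study
#: (GSE5281 on the HPRD network); documented real-data defaults.
REGION_FDR_DEFAULTS = {
    "HIP": 0.008, "EC": 0.004, "MTG": 0.0007,
    "PC": 0.01, "SFG": 0.06, "VCX": 0.09,
}


def compute_pvalues(expr: ExpressionMatrix, test: str = "welch") -> pd.Series:
    """Two-sided per-gene t-test of case vs control expression.

    Welch's unequal-variance t-test by default (``test="student"`` pools the
    variances).  Genes whose test is undefined — zero variance in both groups,
    hence no evidence either way — get p = 1.
    """
    if test not in {"welch", "student"}:
        raise ValueError(f"unknown test {test!r}")
    expr.validate(require_unique=False)
    ctrl = expr.samples(CONTROL).to_numpy(dtype=float)
    case = expr.samples(CASE).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=(test == "student"))
        p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    return pd.Series(p, index=expr.data.index, name="pvalue")


def _neg_loglik(params, logp):
    a, lam = params
    # density lam + (1-lam) * a * exp((a-1) * log x)
    dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * logp)
    if np.any(dens <= 0):
        return np.inf
    return -float(np.sum(np.log(dens)))


_BUM_STARTS = [(0.1, 0.5), (0.3, 0.3), (0.5, 0.7), (0.7, 0.9), (0.2, 0.05)]
_BUM_BOUNDS = [(1e-6, 1.0 - 1e-6), (0.0, 1.0 - 1e-9)]


def fit_bum(pvals) -> BUMFit:
    """Fit the beta-uniform mixture by bounded maximum likelihood.

    L-BFGS-B from several fixed starting points; deterministic given the
    input.  The pure-uniform model (lam -> 1, log-likelihood 0) is nested, so
    the returned log-likelihood is never below 0 up to optimizer tolerance.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < 100:
        logger.warning("fitting BUM on only %d p-values; estimates may be unstable",
                       p.size)
    logp = np.log(p)
    best = None
    for start in _BUM_STARTS:
        res = optimize.minimize(_neg_loglik, start, args=(logp,),
                                method="L-BFGS-B", bounds=_BUM_BOUNDS)
        if best is None or res.fun < best.fun:
            best = res
    # nested uniform boundary: density 1 everywhere, loglik 0
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("BUM fit failed to converge from all starts")
    a, lam = float(best.x[0]), float(best.x[1])
    loglik = -float(best.fun)
    if loglik < 0.0:
        a, lam, loglik = 0.5, 1.0 - 1e-9, 0.0
    return BUMFit(a=a, lam=lam, loglik=loglik, n=int(p.size))


def bum_tau(fit: BUMFit, fdr: float) -> float:
    """Significance threshold tau at the given false-discovery rate.

    Inverts the BUM FDR curve: with pi_UB = lam + (1-lam)*a,

        tau = [ (pi_UB - fdr*lam) / (fdr*(1-lam)) ] ** (1 / (a - 1)).

    tau increases with fdr and reaches 1 as fdr approaches pi_UB.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must lie in (0,1)")
    a, lam = fit.a, fit.lam
    if not (0.0 < a < 1.0 and 0.0 <= lam < 1.0):
        raise ValueError(f"invalid BUM fit (a={a}, lam={lam})")
    pi_ub = fit.pi_upper
    base = (pi_ub - fdr * lam) / (fdr * (1.0 - lam))
    if base <= 0.0:
        raise ValueError(
            f"fdr={fdr} too small for this fit: requires fdr < pi_UB/lam = "
            f"{pi_ub / lam if lam > 0 else math.inf:.6g}"
        )
    tau = base ** (1.0 / (a - 1.0))
    if not 0.0 < tau <= 1.0:
        raise ValueError(
            f"fdr={fdr} exceeds the model's maximum FDR pi_UB={pi_ub:.6g}; "
            "no tau in (0,1] controls it"
        )
    return float(tau)


def node_score(x, a: float, tau: float):
    """Node score (a - 1) * (log x - log tau); positive iff x < tau.

    Accepts a scalar or array of p-values; natural logarithm.
    """
    if not 0.0 < a < 1.0:
        raise ValueError("a must lie in (0,1)")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0,1)")
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    out = (a - 1.0) * (np.log(arr) - math.log(tau))
    return float(out) if np.isscalar(x) else out


def calibrate_fdr(pvals, fit: BUMFit,
                  target_positive_fraction: float = 0.15) -> tuple[float, float]:
    """Pick (fdr, tau) so a target fraction of genes scores positive.

    tau* is placed halfway between the k-th and (k+1)-th smallest p-value,
    k = ceil(target * n), so exactly k genes satisfy p < tau* on tie-free
    input; the matching FDR is read off the model curve
    FDR(tau) = pi_UB * tau / F(tau).
    """
    if not 0.0 < target_positive_fraction < 1.0:
        raise ValueError("target_positive_fraction must lie in (0,1)")
    p = np.sort(np.asarray(pvals, dtype=float).ravel())
    n = p.size
    if n == 0:
        raise ValueError("empty p-value vector")
    if p[0] == p[-1]:
        raise ValueError("degenerate p-value vector (all values equal)")
    k = math.ceil(target_positive_fraction * n)
    upper = p[k] if k < n else min(1.0, p[-1] + (p[-1] - p[0]))
    tau = 0.5 * (p[k - 1] + upper)
    tau = min(max(tau, np.nextafter(0.0, 1.0)), 1.0 - np.finfo(float).epsneg)
    fdr = float(fit.pi_upper * tau / fit.cdf(tau))
    return fdr, float(tau)


def edge_score(x_profile, y_profile) -> float:
    """Interaction score: sample covariance corr(X,Y)*std(X)*std(Y).

    Positive scores indicate activation-like co-expression, negative ones
    inhibition-like.  If either profile has zero variance the score is 0
    (degenerate genes never drive module selection).
    """
    x = np.asarray(x_profile, dtype=float)
    y = np.asarray(y_profile, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        logger.warning("zero-variance expression profile; edge score set to 0")
        return 0.0
    return float(np.cov(x, y, ddof=1)[0, 1])


def subnetwork_edge_score(edge_scores, edge_mean: float, edge_sd: float) -> float:
    """Background-standardized edge total: sum of (score - mean)/sd.

    ``edge_mean``/``edge_sd`` are the full network's edge-score statistics;
    an empty edge set scores 0.
    """
    if not np.isfinite(edge_sd) or edge_sd <= 0.0:
        raise ValueError("edge score background sd must be positive")
    arr = np.asarray(list(edge_scores), dtype=float)
    if arr.size == 0:
        return 0.0
    return float(np.sum((arr - edge_mean) / edge_sd))


@dataclass
class ScoredNetwork:
    """A matched PPI network with node scores, edge scores and background stats.

    ``edge_mean``/``edge_sd`` are computed once over the FULL matched
    network's edges and frozen; subnetwork edge totals are always
    standardized against this background.
    """

    graph: nx.Graph
    node_score: dict[str, float]
    pvalue: dict[str, float]
    edge_score: dict[tuple[str, str], float]
    edge_mean: float
    edge_sd: float
    tau: float
    fdr: float
    fit: BUMFit
    expr: ExpressionMatrix | None = None
    region: str = ""

    @staticmethod
    def edge_key(u: str, v: str) -> tuple[str, str]:
        return (u, v) if u <= v else (v, u)

    def z(self, u: str, v: str) -> float:
        """Background-standardized score of one edge."""
        if not np.isfinite(self.edge_sd) or self.edge_sd <= 0.0:
            raise ValueError("edge score background sd must be positive")
        return (self.edge_score[self.edge_key(u, v)] - self.edge_mean) / self.edge_sd

    def strength(self, u: str, v: str) -> float:
        """Edge strength |z| used by the strong/weak threshold rule."""
        return abs(self.z(u, v))

    def induced_edges(self, nodes) -> list[tuple[str, str]]:
        node_set = set(nodes)
        return sorted(
            self.edge_key(u, v)
            for u, v in self.graph.edges(node_set)
            if u in node_set and v in node_set
        )

    def positive_nodes(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.node_score[n] > 0.0)

    def restrict(self, keep) -> "ScoredNetwork":
        """Scored network on a node subset; background stats stay frozen."""
        keep = set(keep)
        g = self.graph.subgraph(keep).copy()
        return ScoredNetwork(
            graph=g,
            node_score={n: self.node_score[n] for n in g.nodes},
            pvalue={n: self.pvalue[n] for n in g.nodes},
            edge_score={self.edge_key(u, v): self.edge_score[self.edge_key(u, v)]
                        for u, v in g.edges},
            edge_mean=self.edge_mean,
            edge_sd=self.edge_sd,
            tau=self.tau,
            fdr=self.fdr,
            fit=self.fit,
            expr=self.expr,
            region=self.region,
        )


def score_network(expr: ExpressionMatrix, ppi: nx.Graph,
                  config: ScoringConfig | None = None) -> ScoredNetwork:
    """Score a matched (expression, network) pair end to end.

    Computes per-gene p-values, fits the BUM model, derives tau from the
    configured FDR (or calibrates the FDR to the target positive fraction),
    scores nodes and edges, and freezes the background edge statistics.
    """
    config = config or ScoringConfig()
    expr.validate()
    missing = [n for n in ppi.nodes if n not in expr.data.index]
    if missing:
        raise ValueError(
            f"{len(missing)} network node(s) lack expression rows (e.g. {missing[:3]}); "
            "run match_network first"
        )
    pvals = compute_pvalues(expr, test=config.test)
    fit = fit_bum(pvals.to_numpy())
    if config.fdr is None:
        fdr, tau = calibrate_fdr(pvals.to_numpy(), fit,
                                 config.target_positive_fraction)
    else:
        fdr = config.fdr
        tau = bum_tau(fit, fdr)
    scores = node_score(pvals.to_numpy(), fit.a, tau)
    node_scores = {g: float(s) for g, s in zip(pvals.index, scores)}

    values = expr.data.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    row_of = {g: i for i, g in enumerate(expr.data.index)}
    nsamp = values.shape[1]
    edge_scores: dict[tuple[str, str], float] = {}
    edges = [ScoredNetwork.edge_key(u, v) for u, v in ppi.edges]
    if edges:
        iu = np.array([row_of[u] for u, _ in edges])
        iv = np.array([row_of[v] for _, v in edges])
        covs = np.sum(centered[iu] * centered[iv], axis=1) / (nsamp - 1)
        sds = values.std(axis=1, ddof=1)
        zero_var = (sds[iu] == 0.0) | (sds[iv] == 0.0)
        covs[zero_var] = 0.0
        edge_scores = {e: float(c) for e, c in zip(edges, covs)}
        arr = np.array(list(edge_scores.values()))
        edge_mean = float(arr.mean())
        edge_sd = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
        if not np.isfinite(edge_sd) or edge_sd <= 0.0:
            logger.warning("degenerate edge-score background (sd=%s); "
                           "normalized edge scores undefined", edge_sd)
            edge_sd = float("nan")
    else:
        edge_mean, edge_sd = 0.0, float("nan")

    n_pos = sum(s > 0 for s in node_scores.values())
    logger.info("region %s: fdr=%.4g tau=%.4g a=%.3f lam=%.3f positives=%d/%d",
                expr.region or "-", fdr, tau, fit.a, fit.lam, n_pos,
                len(node_scores))
    return ScoredNetwork(
        graph=ppi, node_score=node_scores,
        pvalue={g: float(p) for g, p in pvals.items()},
        edge_score=edge_scores, edge_mean=edge_mean, edge_sd=edge_sd,
        tau=tau, fdr=fdr, fit=fit, expr=expr, region=expr.region,
    )
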