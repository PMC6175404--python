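"""Post-hoc posterior summaries and prediction metrics.

All quantities are empirical averages over the stored (thinned, post-burn-in)
chain samples: inclusion probabilities per composition, model-averaged
("marginal mean") coefficients that count zero whenever a component is
excluded, the combined posterior summary PS that blends inclusion frequency
with relative effect magnitude, model-averaged predictive probabilities, and
classification metrics (error rate, Brier score, AUC with a DeLong CI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .model import Chain

__all__ = [
    "InclusionSummary", "ComponentSummary",
    "inclusion_probabilities", "marginal_mean_coefficients",
    "combined_posterior_summary", "dimensionality_percentiles",
    "predict", "classification_metrics", "summary_table",
]


@dataclass
class InclusionSummary:
    """Per-cluster inclusion probabilities by composition.

    p_any = p_singleton + p_couple holds exactly (same chain, same counts).
    log_ratio = log(p_couple / p_singleton), NaN when either probability is 0.
    """

    pair_ids: tuple
    p_any: np.ndarray
    p_singleton: np.ndarray
    p_couple: np.ndarray

    @property
    def log_ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            lr = np.log(self.p_couple / self.p_singleton)
        lr[(self.p_couple == 0) | (self.p_singleton == 0)] = np.nan
        return lr


@dataclass
class ComponentSummary:
    """Marginal mean and combined posterior summary per component."""

    pair_ids: tuple
    mean_a: np.ndarray
    mean_b: np.ndarray
    ps_a: np.ndarray
    ps_b: np.ndarray


def inclusion_probabilities(chain: Chain) -> InclusionSummary:
    """Empirical frequencies of singleton / couple inclusion per cluster."""
    if len(chain) == 0:
        raise ValueError("chain is empty")
    p = chain.p
    n_single = np.zeros(p)
    n_couple = np.zeros(p)
    for s in chain.samples:
        for j in s.config.singletons:
            n_single[j] += 1
        for j in s.config.couples:
            n_couple[j] += 1
    M = len(chain)
    return InclusionSummary(chain.pair_ids, (n_single + n_couple) / M,
                            n_single / M, n_couple / M)


def _coefficient_matrices(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Dense M x p matrices of intensity and shape effects, zero when excluded."""
    M, p = len(chain), chain.p
    A = np.zeros((M, p))
    B = np.zeros((M, p))
    for m, s in enumerate(chain.samples):
        idx = np.array(s.config.included, dtype=int)
        if idx.size:
            A[m, idx] = s.coeffs.a
        cidx = np.array(s.config.couples, dtype=int)
        if cidx.size:
            B[m, cidx] = s.coeffs.b
    return A, B


def marginal_mean_coefficients(chain: Chain) -> ComponentSummary:
    """Model-averaged coefficients: mean over all M stored models, with zero
    contributed by models excluding the component."""
    if len(chain) == 0:
        raise ValueError("chain is empty")
    A, B = _coefficient_matrices(chain)
    empty = np.full(chain.p, np.nan)
    return ComponentSummary(chain.pair_ids, A.mean(axis=0), B.mean(axis=0),
                            empty, empty)


def combined_posterior_summary(chain: Chain) -> ComponentSummary:
    """Combined posterior summary PS per component.

    For each stored model m a component contributes
    |beta_m| / (sum_j |beta_mj|) * (1/k'), where the normalizing sum and the
    count k' run over the components of the same source only: the k' = k
    included intensity measures for an intensity PS, the k' = k_C included
    shape measures for a shape PS.  Models excluding the component (or with
    k' = 0) contribute zero; PS is the average over all M models.  Summing PS
    within a source therefore yields the chain average of 1/k' over the
    models that include at least one component from that source.
    """
    if len(chain) == 0:
        raise ValueError("chain is empty")
    A, B = _coefficient_matrices(chain)
    M = len(chain)
    ps = []
    for C in (A, B):
        absC = np.abs(C)
        tot = absC.sum(axis=1)
        kprime = (C != 0).sum(axis=1)
        ok = (kprime > 0) & (tot > 0)
        W = np.zeros_like(C)
        W[ok] = absC[ok] / tot[ok, None] / kprime[ok, None]
        ps.append(W.sum(axis=0) / M)
    mm = marginal_mean_coefficients(chain)
    return ComponentSummary(chain.pair_ids, mm.mean_a, mm.mean_b, ps[0], ps[1])


def dimensionality_percentiles(chain: Chain, percentiles,
                               which: str = "k") -> np.ndarray:
    """Nearest-rank empirical percentiles of the stored dimensionality trace.

    ``which`` selects the trace: 'k', 'k_C' or 'k_I'.
    """
    if len(chain) == 0:
        raise ValueError("chain is empty")
    trace = {"k": chain.k_trace, "k_C": chain.kC_trace,
             "k_I": chain.kI_trace}[which]()
    xs = np.sort(trace)
    M = xs.size
    out = []
    for q in np.atleast_1d(percentiles):
        rank = max(1, int(np.ceil(q / 100.0 * M)))  # nearest-rank definition
        out.append(xs[rank - 1])
    return np.array(out)


def predict(chain: Chain, new_design) -> np.ndarray:
    """Model-averaged case probabilities for new individuals.

    For each stored model, the logistic probability from its configuration
    and coefficients; the returned value is the plain average over models.
    """
    if len(chain) == 0:
        raise ValueError("chain is empty")
    if new_design.p != chain.p or tuple(new_design.pair_ids) != tuple(chain.pair_ids):
        raise ValueError("new design pairs do not match the chain's pairs")
    acc = np.zeros(new_design.n)
    for s in chain.samples:
        eta = np.full(new_design.n, s.coeffs.beta0)
        idx = np.array(s.config.included, dtype=int)
        if idx.size:
            eta += new_design.U[:, idx] @ s.coeffs.a
        cidx = np.array(s.config.couples, dtype=int)
        if cidx.size:
            eta += new_design.V[:, cidx] @ s.coeffs.b
        np.clip(eta, -700, 700, out=eta)
        acc += 1.0 / (1.0 + np.exp(-eta))
    return acc / len(chain)


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------

def _delong_auc_var(probs: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """AUC (Mann-Whitney with midranks) and its DeLong variance."""
    pos = probs[y == 1]
    neg = probs[y == 0]
    m, n = pos.size, neg.size
    ranks_all = rankdata(np.concatenate([pos, neg]))
    ranks_pos = rankdata(pos)
    ranks_neg = rankdata(neg)
    # placement values: V10_i = fraction of negatives below positive i
    v10 = (ranks_all[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def classification_metrics(probs: np.ndarray, y: np.ndarray,
                           cutoff: float = 0.5) -> dict:
    """Error rate at the cutoff, Brier score, and AUC with a 95% DeLong CI.

    An individual is assigned to the case group when its probability exceeds
    the cutoff.  The Brier score is the mean squared difference between the
    probability and the true class label.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    if probs.shape != y.shape:
        raise ValueError("probs and y must have the same length")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: outcome contains a single class")
    pred = (probs > cutoff).astype(int)
    error_rate = float(np.mean(pred != y))
    brier = float(np.mean((probs - y) ** 2))
    auc, var = _delong_auc_var(probs, y)
    half = norm.ppf(0.975) * np.sqrt(var)
    ci = (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))
    return {"error_rate": error_rate, "brier": brier, "auc": auc, "auc_ci": ci}


def summary_table(chain: Chain) -> pd.DataFrame:
    """One row per cluster: inclusion probabilities, mean effects, PS."""
    inc = inclusion_probabilities(chain)
    comp = combined_posterior_summary(chain)
    return pd.DataFrame({
        "pair_id": list(chain.pair_ids),
        "p_any": inc.p_any,
        "p_singleton": inc.p_singleton,
        "p_couple": inc.p_couple,
        "log_ratio": inc.log_ratio,
        "mean_a": comp.mean_a,
        "mean_b": comp.mean_b,
        "PS_a": comp.ps_a,
        "PS_b": comp.ps_b,
    })
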