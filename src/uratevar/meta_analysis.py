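"""Inverse-variance weighted meta-analysis with heterogeneity gating.

Per-cohort estimates are pooled with fixed-effect weights 1/SE²; Cochran's Q
measures between-study heterogeneity, and when its chi-square p-value falls
below the gate (0.05 by default) pooling switches to a DerSimonian–Laird
random-effects model. Pooled p-values are two-sided Wald tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MetaResult",
    "fixed_effect_meta",
    "cochran_q",
    "random_effects_meta",
    "auto_meta",
]


@dataclass
class MetaResult:
    beta_pooled: float
    se_pooled: float
    p_pooled: float
    q: float
    df: int
    p_het: float
    tau2: float
    model_used: str  # "fixed" or "random"
    k: int


def _as_arrays(estimates: Iterable) -> tuple[np.ndarray, np.ndarray]:
    """Accept (beta, se) pairs or objects with .beta/.se attributes."""
    betas, ses = [], []
    for est in estimates:
        if hasattr(est, "beta"):
            betas.append(float(est.beta))
            ses.append(float(est.se))
        else:
            b, s = est
            betas.append(float(b))
            ses.append(float(s))
    if not betas:
        raise ValueError("meta-analysis requires at least one estimate")
    beta = np.array(betas)
    se = np.array(ses)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    return beta, se


def _wald_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def fixed_effect_meta(estimates: Sequence) -> MetaResult:
    """Fixed-effect inverse-variance pooling (weights 1/SE²)."""
    beta, se = _as_arrays(estimates)
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    se_pooled = float(1.0 / np.sqrt(np.sum(w)))
    k = len(beta)
    if k >= 2:
        q, df, p_het = cochran_q(estimates)
    else:
        q, df, p_het = 0.0, 0, 1.0
    return MetaResult(
        beta_pooled=pooled, se_pooled=se_pooled, p_pooled=_wald_p(pooled, se_pooled),
        q=q, df=df, p_het=p_het, tau2=0.0, model_used="fixed", k=k,
    )


def cochran_q(estimates: Sequence) -> tuple[float, int, float]:
    """Cochran's Q = sum w_i (beta_i - beta_fixed)², chi-square on k-1 df."""
    beta, se = _as_arrays(estimates)
    if len(beta) < 2:
        raise ValueError("cochran_q requires at least two estimates")
    w = 1.0 / se**2
    pooled = np.sum(w * beta) / np.sum(w)
    q = float(np.sum(w * (beta - pooled) ** 2))
    df = len(beta) - 1
    return q, df, float(stats.chi2.sf(q, df))


def random_effects_meta(estimates: Sequence) -> MetaResult:
    """DerSimonian–Laird random-effects pooling.

    tau² = max(0, (Q - df) / (sum w - sum w²/sum w)) with fixed-effect
    weights w; estimates are re-weighted by 1/(SE² + tau²).
    """
    beta, se = _as_arrays(estimates)
    if len(beta) < 2:
        raise ValueError("random_effects_meta requires at least two estimates")
    q, df, p_het = cochran_q(estimates)
    w = 1.0 / se**2
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * beta) / np.sum(w_star))
    se_pooled = float(1.0 / np.sqrt(np.sum(w_star)))
    return MetaResult(
        beta_pooled=pooled, se_pooled=se_pooled, p_pooled=_wald_p(pooled, se_pooled),
        q=q, df=df, p_het=p_het, tau2=float(tau2), model_used="random", k=len(beta),
    )


def auto_meta(
    estimates: Sequence,
    het_threshold: float = 0.05,
    force_model: str | None = None,
) -> MetaResult:
    """Fixed-effect pooling unless heterogeneity is significant.

    With k = 1 the single estimate passes through. Otherwise Cochran's Q is
    computed and the random-effects model is used when P_Het < het_threshold.
    ``force_model`` ("fixed"/"random") overrides the gate.
    """
    beta, se = _as_arrays(estimates)
    if force_model not in (None, "fixed", "random"):
        raise ValueError(f"unknown model: {force_model!r}")
    if len(beta) == 1:
        return fixed_effect_meta(estimates)
    if force_model == "fixed":
        return fixed_effect_meta(estimates)
    if force_model == "random":
        return random_effects_meta(estimates)
    _, _, p_het = cochran_q(estimates)
    if p_het < het_threshold:
        return random_effects_meta(estimates)
    return fixed_effect_meta(estimates)
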