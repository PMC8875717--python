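"""AIC-based ranking of fitted solubility models.

AIC = N ln(RSS/N) + 2k with RSS in mole-fraction space.  The parameter
count k defaults to the bookkeeping used in the source analysis: 3 for the
Apelblat model, 2 for λh, van't Hoff and the Wilson rules, and 4 for NRTL
and UNIQUAC (the count its printed AIC values verifiably used, even though
only two interaction energies are optimised for those models).  Akaike
weights ω_i = exp((AIC_min − AIC_i)/2) / Σ_j exp((AIC_min − AIC_j)/2)
normalise the relative likelihoods across the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fitting import FitResult

__all__ = ["aic", "akaike_weights", "rank_models", "ModelComparison"]


def aic(rss: float, n: int, k: int) -> float:
    """Akaike information criterion N ln(RSS/N) + 2k."""
    if rss <= 0:
        raise ValueError(f"rss must be positive, got {rss}")
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    return n * float(np.log(rss / n)) + 2 * k


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights for a set of AIC values; sums to 1."""
    a = np.asarray(aics, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AIC value")
    if np.any(~np.isfinite(a)):
        raise ValueError("AIC values must be finite")
    rel = np.exp((a.min() - a) / 2.0)
    return rel / rel.sum()


@dataclass(frozen=True)
class ModelComparison:
    """Per-model AIC bookkeeping, sorted by AIC ascending (best first)."""

    names: tuple[str, ...]
    rss: tuple[float, ...]
    k: tuple[int, ...]
    n: int
    aic: tuple[float, ...]
    delta_aic: tuple[float, ...]
    rel_likelihood: tuple[float, ...]
    weights: tuple[float, ...]

    @property
    def best(self) -> str:
        return self.names[0]

    def rows(self) -> list[dict]:
        return [
            {
                "model": nm,
                "1e4_RSS": round(1e4 * r, 5),
                "k": kk,
                "AIC": round(a, 4),
                "rel_likelihood": rl,
                "akaike_weight": round(w, 5),
            }
            for nm, r, kk, a, rl, w in zip(
                self.names, self.rss, self.k, self.aic, self.rel_likelihood, self.weights
            )
        ]


def rank_models(results: Sequence[FitResult]) -> ModelComparison:
    """Rank fitted models on one dataset by AIC.

    All results must come from the same dataset (equal n); each result's
    ``k_aic`` supplies its parameter count.
    """
    if not results:
        raise ValueError("need at least one fit result")
    ns = {r.n_points for r in results}
    if len(ns) != 1:
        raise ValueError(f"fit results mix sample sizes {sorted(ns)}")
    n = ns.pop()
    aics = np.array([aic(r.rss, n, r.k_aic) for r in results])
    w = akaike_weights(aics)
    rel = np.exp((aics.min() - aics) / 2.0)
    order = np.argsort(aics, kind="stable")
    return ModelComparison(
        names=tuple(results[i].model_name for i in order),
        rss=tuple(results[i].rss for i in order),
        k=tuple(results[i].k_aic for i in order),
        n=n,
        aic=tuple(float(aics[i]) for i in order),
        delta_aic=tuple(float(aics[i] - aics.min()) for i in order),
        rel_likelihood=tuple(float(rel[i]) for i in order),
        weights=tuple(float(w[i]) for i in order),
    )
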