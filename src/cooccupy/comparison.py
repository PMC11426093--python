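"""elpd-based ranking of the four hypothesis fits.

Model performance is the expected log pointwise predictive density (elpd)
estimated by Pareto-smoothed importance-sampling leave-one-out
cross-validation (PSIS-LOO) from each fit's pointwise log-likelihood matrix.
A difference in elpd of more than 4 is treated as a notable performance gap;
among models within 4 elpd of the best, the simplest (fewest free species-B
detection vectors: H1 < H2 = H3 < H4, ties toward presence-conditioning H2)
is selected by parsimony.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import PosteriorFit

__all__ = ["LooResult", "elpd_loo", "waic", "ComparisonTable", "compare"]

PARETO_K_WARN = 0.7
PARETO_K_BAD = 1.0
NOTABLE_DELTA = 4.0
# parsimony order: fewer free detection vectors first, H2 before H3 on ties
_SIMPLICITY_RANK = {"H1": 0, "H2": 1, "H3": 2, "H4": 3}


@dataclass
class LooResult:
    """PSIS-LOO estimate: total elpd, its SE, per-site contributions and the
    Pareto shape diagnostics."""

    elpd: float
    se: float
    elpd_i: np.ndarray
    pareto_k: np.ndarray
    method: str = "psis-loo"

    @property
    def n_sites(self) -> int:
        return self.elpd_i.size


def _check_loglik(pointwise_loglik: np.ndarray) -> np.ndarray:
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 3:  # (chains, draws, sites)
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, sites)")
    if ll.shape[0] < 2:
        raise ValueError("need at least 2 posterior draws")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    return ll


def waic(pointwise_loglik: np.ndarray) -> LooResult:
    """WAIC with the variance-based effective-parameter penalty, on the elpd
    scale (cross-check and fallback for PSIS-LOO)."""
    ll = _check_loglik(pointwise_loglik)
    S = ll.shape[0]
    lpd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lpd_i - p_i
    n = elpd_i.size
    return LooResult(
        elpd=float(elpd_i.sum()),
        se=float(np.sqrt(n) * elpd_i.std(ddof=1)),
        elpd_i=elpd_i,
        pareto_k=np.full(n, np.nan),
        method="waic",
    )


def elpd_loo(pointwise_loglik: np.ndarray, warn: bool = True) -> LooResult:
    """PSIS-LOO elpd from a (draws, sites) or (chains, draws, sites)
    log-likelihood matrix.

    Importance ratios are the inverse likelihoods; their upper tail is
    smoothed by a generalized-Pareto fit per site.  elpd_i is the log of the
    smoothed-weight average predictive density, and SE = sqrt(n) * SD(elpd_i).
    Sites with Pareto k > 0.7 are flagged; if any k > 1 the estimate is
    unreliable and the result falls back to WAIC.
    """
    import arviz as az

    ll = _check_loglik(pointwise_loglik)
    S, n = ll.shape
    if np.all(ll.max(axis=0) == ll.min(axis=0)):
        # degenerate posterior (identical draws): weights are uniform
        elpd_i = ll[0]
        return LooResult(
            elpd=float(elpd_i.sum()),
            se=float(np.sqrt(n) * elpd_i.std(ddof=1)),
            elpd_i=elpd_i,
            pareto_k=np.zeros(n),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, k = az.psislw(-ll.T)  # (sites, draws) normalized log weights
    k = np.asarray(k, dtype=float)
    if np.any(k > PARETO_K_BAD):
        if warn:
            warnings.warn(
                f"{int((k > PARETO_K_BAD).sum())} site(s) with Pareto k > 1; "
                "PSIS-LOO unreliable, falling back to WAIC",
                stacklevel=2,
            )
        out = waic(ll)
        out.pareto_k = k
        return out
    if warn and np.any(k > PARETO_K_WARN):
        warnings.warn(
            f"{int((k > PARETO_K_WARN).sum())} site(s) with Pareto k > "
            f"{PARETO_K_WARN}; elpd_loo may be optimistic there",
            stacklevel=2,
        )
    elpd_i = logsumexp(lw.T + ll, axis=0)
    return LooResult(
        elpd=float(elpd_i.sum()),
        se=float(np.sqrt(n) * elpd_i.std(ddof=1)),
        elpd_i=elpd_i,
        pareto_k=k,
    )


@dataclass
class ComparisonTable:
    """Ranking of hypothesis fits by elpd with parsimony-based selection."""

    table: pd.DataFrame
    selected: str
    loo: dict[str, LooResult] = field(default_factory=dict)

    def __repr__(self):
        return f"ComparisonTable(selected={self.selected!r})\n{self.table}"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare(fits: Sequence[PosteriorFit]) -> ComparisonTable:
    """Rank fits by PSIS-LOO elpd and select by the Δelpd > 4 / parsimony rule.

    All fits must be of the same data (site set and histories); the best
    model has Δelpd = 0, others negative.  Δse is the SE of the pointwise
    elpd differences vs the best model.  The selected model is the simplest
    one within 4 elpd of the top-ranked model.
    """
    if not fits:
        raise ValueError("no fits to compare")
    sig = fits[0].data_signature
    for f in fits[1:]:
        if f.data_signature != sig:
            raise ValueError("fits were made on different data; cannot compare")
    ids = [f.hypothesis.id for f in fits]

    loo = {f.hypothesis.id: elpd_loo(f.loglik) for f in fits}
    order = sorted(ids, key=lambda h: -loo[h].elpd)
    best = order[0]
    best_i = loo[best].elpd_i
    rows = []
    for h in order:
        res = loo[h]
        d_i = res.elpd_i - best_i
        n = d_i.size
        delta = float(d_i.sum())
        delta_se = 0.0 if h == best else float(np.sqrt(n) * d_i.std(ddof=1))
        rows.append(
            {
                "hypothesis": h,
                "n_detection_vectors": next(
                    f.hypothesis.n_free_detection_vectors for f in fits if f.hypothesis.id == h
                ),
                "elpd": res.elpd,
                "se": res.se,
                "delta_elpd": delta,
                "delta_se": delta_se,
                "max_pareto_k": float(np.nanmax(res.pareto_k)) if res.pareto_k.size else np.nan,
                "method": res.method,
            }
        )
    table = pd.DataFrame(rows)

    within = [h for h in order if loo[best].elpd - loo[h].elpd <= NOTABLE_DELTA]
    selected = min(within, key=lambda h: _SIMPLICITY_RANK[h])
    return ComparisonTable(table=table, selected=selected, loo=loo)
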