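"""Conditional two-species occupancy model: hypotheses and exact likelihood.

The model follows the dominant/subordinate co-occurrence framework: a
dominant species A (here the leopard) and a subordinate species B (an
ungulate prey) each occupy a site with probability psi^A, psi^B (latent
states z^A, z^B).  Per survey occasion t,

    D^A_t ~ Bernoulli(p^A * z^A)

while the subordinate's detection may depend on the dominant's latent state
and same-occasion detection:

    z^A = 0            : D^B_t ~ Bernoulli(p^B  * z^B)
    z^A = 1, D^A_t = 0 : D^B_t ~ Bernoulli(r^Ba * z^B)
    z^A = 1, D^A_t = 1 : D^B_t ~ Bernoulli(r^BA * z^B)

Four nested hypotheses tie these detection parameters together:

    H1: p^B = r^Ba = r^BA   (B independent of A)
    H2: p^B != r^Ba = r^BA  (conditional on A's presence)
    H3: p^B = r^Ba != r^BA  (conditional on A's same-occasion detection)
    H4: p^B != r^Ba != r^BA (conditional on both)

All probabilities are logistic regressions: occupancy on standardized
(lat, lon), detection on standardized (DR, DS, logRH, logRC).  The
likelihood marginalizes the four latent states (z^A, z^B) exactly, which
both enables brute-force oracle checks and yields the pointwise
log-likelihood matrix needed for LOO model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, xlogy

from .covariates import DesignMatrix
from .records import DetectionHistory

__all__ = [
    "HypothesisSpec",
    "HYPOTHESES",
    "ParamSet",
    "link_probabilities",
    "site_log_likelihood",
    "dataset_log_likelihood",
    "LikelihoodEngine",
]

N_OCC_COEF = 3  # intercept + lat + lon
N_DET_COEF = 5  # intercept + DR + DS + logRH + logRC


@dataclass(frozen=True)
class HypothesisSpec:
    """One of the four detection-dependence structures.

    ``vector_of`` maps each detection role of species B (pB, rBa, rBA) to the
    name of the coefficient vector that parameterizes it; tied roles share one
    name, so the tie is structural (a single set of unknowns), not a runtime
    equality constraint.
    """

    id: str
    vector_of: Mapping[str, str]

    @property
    def b_vectors(self) -> tuple[str, ...]:
        """Distinct coefficient vectors for species B's detection, in role order."""
        seen: list[str] = []
        for role in ("pB", "rBa", "rBA"):
            v = self.vector_of[role]
            if v not in seen:
                seen.append(v)
        return tuple(seen)

    @property
    def n_free_detection_vectors(self) -> int:
        return len(self.b_vectors)

    @property
    def detection_conditional(self) -> bool:
        """True when r^Ba and r^BA are distinct (H3/H4)."""
        return self.vector_of["rBa"] != self.vector_of["rBA"]

    def blocks(self) -> tuple[tuple[str, str], ...]:
        """Ordered (name, design) coefficient blocks for this hypothesis."""
        return (
            ("psiA", "occ"),
            ("psiB", "occ"),
            ("pA", "det"),
            *((v, "det") for v in self.b_vectors),
        )

    @property
    def n_coef(self) -> int:
        return sum(N_OCC_COEF if kind == "occ" else N_DET_COEF for _, kind in self.blocks())

    def coef_names(self) -> list[str]:
        occ = ("int", "lat", "lon")
        det = ("int", "DR", "DS", "logRH", "logRC")
        out = []
        for name, kind in self.blocks():
            out += [f"{name}_{c}" for c in (occ if kind == "occ" else det)]
        return out


HYPOTHESES: dict[str, HypothesisSpec] = {
    "H1": HypothesisSpec("H1", {"pB": "pB", "rBa": "pB", "rBA": "pB"}),
    "H2": HypothesisSpec("H2", {"pB": "pB", "rBa": "rB", "rBA": "rB"}),
    "H3": HypothesisSpec("H3", {"pB": "pB", "rBa": "pB", "rBA": "rBA"}),
    "H4": HypothesisSpec("H4", {"pB": "pB", "rBa": "rBa", "rBA": "rBA"}),
}


@dataclass
class ParamSet:
    """Named logit-scale coefficient vectors for one hypothesis.

    Keys are the block names from :meth:`HypothesisSpec.blocks`; tied
    detection roles resolve to the same stored vector (aliases, not copies).
    """

    hypothesis: HypothesisSpec
    coef: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for name, kind in self.hypothesis.blocks():
            want = N_OCC_COEF if kind == "occ" else N_DET_COEF
            if name not in self.coef:
                raise ValueError(f"missing coefficient vector {name!r}")
            v = np.asarray(self.coef[name], dtype=float)
            if v.shape != (want,):
                raise ValueError(f"{name!r} must have shape ({want},), got {v.shape}")
            self.coef[name] = v

    def vector(self, role: str) -> np.ndarray:
        """Coefficient vector for a detection role, resolving ties."""
        if role in ("psiA", "psiB", "pA"):
            return self.coef[role]
        return self.coef[self.hypothesis.vector_of[role]]

    def to_flat(self) -> np.ndarray:
        return np.concatenate([self.coef[name] for name, _ in self.hypothesis.blocks()])

    @classmethod
    def from_flat(cls, hypothesis: HypothesisSpec, theta: np.ndarray) -> "ParamSet":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (hypothesis.n_coef,):
            raise ValueError(f"expected {hypothesis.n_coef} coefficients, got {theta.shape}")
        coef, k = {}, 0
        for name, kind in hypothesis.blocks():
            size = N_OCC_COEF if kind == "occ" else N_DET_COEF
            coef[name] = theta[k : k + size].copy()
            k += size
        return cls(hypothesis=hypothesis, coef=coef)

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis.id,
            "coef": {k: v.tolist() for k, v in self.coef.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParamSet":
        return cls(
            hypothesis=HYPOTHESES[d["hypothesis"]],
            coef={k: np.asarray(v, dtype=float) for k, v in d["coef"].items()},
        )


def _with_intercept(X: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((X.shape[0], 1)), X])


def link_probabilities(
    params: ParamSet, dm: DesignMatrix, site: int | None = None
) -> dict[str, np.ndarray | float]:
    """Per-site probabilities via the logistic link.

    Returns a dict with keys psiA, psiB, pA, pB, rBa, rBA; tied roles return
    identical values.  With ``site`` given, scalars for that site; otherwise
    arrays over all sites.
    """
    Zo = _with_intercept(dm.X_occ)
    Zd = _with_intercept(dm.X_det)
    if site is not None:
        Zo, Zd = Zo[site : site + 1], Zd[site : site + 1]
    out: dict[str, np.ndarray | float] = {}
    for role, Z in (("psiA", Zo), ("psiB", Zo), ("pA", Zd), ("pB", Zd), ("rBa", Zd), ("rBA", Zd)):
        p = expit(Z @ params.vector(role))
        out[role] = float(p[0]) if site is not None else p
    return out


def _suffstats(histA: np.ndarray, histB: np.ndarray):
    """Sufficient statistics of one or many sites' paired histories.

    With site-level detection probabilities the per-site likelihood depends
    on the histories only through occasion counts in the four (D^A, D^B)
    cells plus the number of surveyed occasions; this is what makes the
    sampler's likelihood evaluations cheap.
    """
    histA = np.atleast_2d(np.asarray(histA, dtype=float))
    histB = np.atleast_2d(np.asarray(histB, dtype=float))
    if histA.shape != histB.shape:
        raise ValueError("species A and B histories must share shape")
    mA, mB = np.isnan(histA), np.isnan(histB)
    if np.any(mA != mB):
        raise ValueError("species A and B histories must share the missing pattern")
    obs = ~mA
    bad = lambda h: np.any(obs & ~np.isin(np.nan_to_num(h), (0.0, 1.0)))
    if bad(histA) or bad(histB):
        raise ValueError("observed history entries must be 0 or 1")
    A = np.where(obs, histA, 0.0)
    B = np.where(obs, histB, 0.0)
    return {
        "n11": (A * B).sum(axis=1),
        "n10": (A * (1 - B) * obs).sum(axis=1),
        "n01": ((1 - A) * B * obs).sum(axis=1),
        "n00": ((1 - A) * (1 - B) * obs).sum(axis=1),
        "sA": A.sum(axis=1),
        "sB": B.sum(axis=1),
        "n": obs.sum(axis=1).astype(float),
    }


def _loglik_from_probs(pr: dict, st: dict, conditional: bool) -> np.ndarray:
    """Exact marginal log-likelihood over the four (z^A, z^B) latent states."""
    psiA, psiB = pr["psiA"], pr["psiB"]
    pA, pB, rBa, rBA = pr["pA"], pr["pB"], pr["rBa"], pr["rBA"]
    sA, sB, n = st["sA"], st["sB"], st["n"]

    logLA1 = xlogy(sA, pA) + xlogy(n - sA, 1.0 - pA)
    if conditional:
        logLB1_zA1 = (
            xlogy(st["n11"], rBA)
            + xlogy(st["n10"], 1.0 - rBA)
            + xlogy(st["n01"], rBa)
            + xlogy(st["n00"], 1.0 - rBa)
        )
    else:
        logLB1_zA1 = xlogy(sB, rBa) + xlogy(n - sB, 1.0 - rBa)
    logLB1_zA0 = xlogy(sB, pB) + xlogy(n - sB, 1.0 - pB)

    IA0 = (sA == 0).astype(float)  # z^A = 0 is impossible once A was detected
    IB0 = (sB == 0).astype(float)
    lik = (
        psiA * np.exp(logLA1) * (psiB * np.exp(logLB1_zA1) + (1.0 - psiB) * IB0)
        + (1.0 - psiA) * IA0 * (psiB * np.exp(logLB1_zA0) + (1.0 - psiB) * IB0)
    )
    with np.errstate(divide="ignore"):
        return np.log(lik)


def site_log_likelihood(
    params: ParamSet,
    hyp: HypothesisSpec,
    histA_row: np.ndarray,
    histB_row: np.ndarray,
    dm: DesignMatrix,
    site: int,
) -> float:
    """Exact marginal log-likelihood of one site's paired detection histories.

    Missing occasions (NaN in both rows) contribute factor 1; a detection of
    species A makes the z^A = 0 branch impossible, and likewise for B.
    """
    st = _suffstats(histA_row, histB_row)
    pr = link_probabilities(params, dm, site=site)
    return float(_loglik_from_probs(pr, st, hyp.detection_conditional)[0])


class LikelihoodEngine:
    """Precompiled dataset likelihood for one hypothesis.

    Precomputes sufficient statistics and design matrices once, then
    evaluates the per-site log-likelihood for a flat coefficient vector (or a
    batch of them, e.g. one per MCMC chain) with a handful of vectorized
    operations.
    """

    def __init__(
        self,
        histA: DetectionHistory,
        histB: DetectionHistory,
        dm: DesignMatrix,
        hyp: HypothesisSpec,
    ):
        if histA.sites != histB.sites:
            raise ValueError("species A and B histories cover different sites")
        if list(dm.site_ids) != list(histA.sites):
            raise ValueError("design matrix site order does not match histories")
        self.hyp = hyp
        self.n_sites = histA.n_sites
        self.stats = _suffstats(histA.matrix, histB.matrix)
        self.Zo = _with_intercept(dm.X_occ)
        self.Zd = _with_intercept(dm.X_det)
        self._slices = {}
        k = 0
        for name, kind in hyp.blocks():
            size = N_OCC_COEF if kind == "occ" else N_DET_COEF
            self._slices[name] = slice(k, k + size)
            k += size
        self.n_coef = k

    def _probs(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        # theta: (B, d); each prob: (B, n)
        get = lambda name, Z: expit(theta[:, self._slices[name]] @ Z.T)
        pr = {
            "psiA": get("psiA", self.Zo),
            "psiB": get("psiB", self.Zo),
            "pA": get("pA", self.Zd),
        }
        for role in ("pB", "rBa", "rBA"):
            vec = self.hyp.vector_of[role]
            if vec not in pr:
                pr[vec] = get(vec, self.Zd)
            pr[role] = pr[vec]
        return pr

    def pointwise(self, theta: np.ndarray) -> np.ndarray:
        """Per-site log-likelihood; theta (d,) -> (n,), (B, d) -> (B, n)."""
        theta = np.asarray(theta, dtype=float)
        squeeze = theta.ndim == 1
        if squeeze:
            theta = theta[None, :]
        out = _loglik_from_probs(self._probs(theta), self.stats, self.hyp.detection_conditional)
        return out[0] if squeeze else out

    def total(self, theta: np.ndarray) -> np.ndarray | float:
        pw = self.pointwise(theta)
        return float(pw.sum()) if pw.ndim == 1 else pw.sum(axis=1)


def dataset_log_likelihood(
    params: ParamSet,
    hyp: HypothesisSpec,
    histories: tuple[DetectionHistory, DetectionHistory],
    dm: DesignMatrix,
) -> tuple[float, np.ndarray]:
    """Total log-likelihood and the per-site vector (sites are independent)."""
    histA, histB = histories
    eng = LikelihoodEngine(histA, histB, dm, hyp)
    pw = eng.pointwise(params.to_flat())
    return float(pw.sum()), pw
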