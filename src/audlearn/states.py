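"""Latent performance states via 1-D Gaussian mixtures.

Block coefficient values pooled over a cohort are modelled as a K-component
univariate Gaussian mixture fitted by EM.  The component count is chosen by
the Bayesian information criterion

    BIC = ln(n) * 3K - 2 ln(L-hat)

where each component contributes three parameters (weight, mean, sd) and
``n`` is a caller-supplied sample size: by convention here it is the number
of *participants*, not the number of pooled block values — the two differ
by the blocks-per-participant factor, and both conventions appear in
practice, so the argument is explicit.

Block coefficients are ratios of small counts and therefore cluster on a
few rational values (a block with 3 targets can only score 0, 1/3, 2/3, 1);
a component can collapse onto such an atom.  A variance floor keeps EM
well-posed while still permitting near-point components, matching reported
states with (near-)zero spread.

With K = 3 the components, ordered by descending mean, are labelled
high / med / low performance, and each block is assigned to the component
with the largest posterior probability (weights included; exact ties break
toward the larger-mean component).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MixtureModel",
    "fit_gmm_em",
    "bic",
    "scan_k",
    "elbow_k",
    "assign_states",
    "label_components",
    "state_labels",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: Default variance floor: sd floor 1e-3, small enough for near-point
#: components yet bounding the likelihood.
VAR_FLOOR = 1e-6


@dataclass
class MixtureModel:
    """A fitted 1-D Gaussian mixture."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    coefficient: str | None = None
    converged: bool = False
    n_iter: int = 0
    degenerate: bool = False
    var_floor: float = VAR_FLOOR
    loglik_trace: np.ndarray | None = field(default=None, repr=False)

    def component_log_pdf(self, x: np.ndarray) -> np.ndarray:
        """(n, k) matrix of per-component log densities."""
        x = np.asarray(x, dtype=float).reshape(-1, 1)
        return (
            -0.5 * ((x - self.means) / self.sds) ** 2
            - np.log(self.sds)
            - 0.5 * _LOG_2PI
        )

    def responsibilities(self, x) -> np.ndarray:
        """Posterior P(Z=k | x) including the mixture weights; rows sum to 1."""
        log_joint = self.component_log_pdf(x) + np.log(self.weights)
        log_norm = _logsumexp_rows(log_joint)
        return np.exp(log_joint - log_norm[:, None])

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "variances": (self.sds**2).tolist(),
            "log_likelihood": self.log_likelihood,
            "coefficient": self.coefficient,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "degenerate": self.degenerate,
            "var_floor": self.var_floor,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(
            k=int(d["k"]),
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            log_likelihood=float(d["log_likelihood"]),
            coefficient=d.get("coefficient"),
            converged=bool(d.get("converged", False)),
            n_iter=int(d.get("n_iter", 0)),
            degenerate=bool(d.get("degenerate", False)),
            var_floor=float(d.get("var_floor", VAR_FLOOR)),
        )

    @classmethod
    def from_json(cls, path) -> "MixtureModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1)
    return m + np.log(np.exp(a - m[:, None]).sum(axis=1))


def _em_once(
    x: np.ndarray,
    k: int,
    means0: np.ndarray,
    sd0: float,
    tol: float,
    max_iter: int,
    var_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int, np.ndarray]:
    n = x.size
    weights = np.full(k, 1.0 / k)
    means = means0.astype(float).copy()
    variances = np.full(k, max(sd0**2, var_floor))
    xcol = x[:, None]

    trace = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sds = np.sqrt(variances)
        log_joint = (
            -0.5 * ((xcol - means) / sds) ** 2
            - np.log(sds)
            - 0.5 * _LOG_2PI
            + np.log(weights)
        )
        log_norm = _logsumexp_rows(log_joint)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_joint - log_norm[:, None])

        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)  # guard emptied components
        weights = nk / n
        means = (resp * xcol).sum(axis=0) / nk
        variances = np.maximum((resp * (xcol - means) ** 2).sum(axis=0) / nk, var_floor)

        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12):
            converged = True
            break
        prev_ll = ll
    return weights, means, np.sqrt(variances), trace[-1], converged, it, np.array(trace)


def fit_gmm_em(
    values: Sequence[float],
    k: int,
    *,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    var_floor: float = VAR_FLOOR,
    n_init: int = 10,
    coefficient: str | None = None,
) -> MixtureModel:
    """Fit a K-component 1-D Gaussian mixture by EM.

    Initialisation uses quantile-spread means with the pooled sd and uniform
    weights; ``n_init - 1`` further restarts jitter the quantile means with
    seeds derived from ``seed``, and the restart with the best final
    log-likelihood wins.  Convergence is declared when the relative change
    in log-likelihood drops below ``tol``.  Component variances are floored
    at ``var_floor`` after every M-step.
    """
    x = np.asarray(values, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.size <= k:
        raise ValueError(f"need more than k={k} observations, got {x.size}")

    pooled_sd = float(x.std())
    if k == 1:
        mean = float(x.mean())
        sd = math.sqrt(max(pooled_sd**2, var_floor))
        ll = float(
            np.sum(-0.5 * ((x - mean) / sd) ** 2 - math.log(sd) - 0.5 * _LOG_2PI)
        )
        return MixtureModel(
            k=1,
            weights=np.array([1.0]),
            means=np.array([mean]),
            sds=np.array([sd]),
            log_likelihood=ll,
            coefficient=coefficient,
            converged=True,
            n_iter=0,
            loglik_trace=np.array([ll]),
        )

    quantile_means = np.quantile(x, (np.arange(k) + 0.5) / k)
    jitter_scale = max(pooled_sd, math.sqrt(var_floor))
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_init)]

    best = None
    for r, rng in enumerate(rngs):
        means0 = quantile_means.copy()
        if r > 0:
            means0 = means0 + rng.normal(scale=0.5 * jitter_scale, size=k)
        fit = _em_once(x, k, means0, max(pooled_sd, 1e-3), tol, max_iter, var_floor)
        if best is None or fit[3] > best[3]:
            best = fit

    weights, means, sds, ll, converged, n_iter, trace = best
    order = np.argsort(means)  # ascending mean: stable, comparable output
    degenerate = bool(
        np.any(np.diff(np.sort(means)) < 1e-6) or np.any(weights < 1e-8)
    )
    return MixtureModel(
        k=k,
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        log_likelihood=ll,
        coefficient=coefficient,
        converged=converged,
        n_iter=n_iter,
        degenerate=degenerate,
        var_floor=var_floor,
        loglik_trace=trace,
    )


def bic(model: MixtureModel, n: int) -> float:
    """ln(n) * 3K - 2 * log-likelihood; ``n`` is the sample-size convention
    chosen by the caller (participants, by default, in :func:`scan_k`)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.log(n) * 3 * model.k - 2.0 * model.log_likelihood


def scan_k(
    values: Sequence[float],
    k_max: int = 10,
    *,
    n: int,
    seed: int = 0,
    **fit_kwargs,
) -> list[tuple[int, MixtureModel, float]]:
    """Fit mixtures for K = 1..k_max and score each with BIC(n)."""
    x = np.asarray(values, dtype=float).ravel()
    if k_max >= x.size:
        raise ValueError("k_max must be smaller than the number of values")
    out = []
    for k in range(1, k_max + 1):
        model = fit_gmm_em(x, k, seed=seed + k, **fit_kwargs)
        out.append((k, model, bic(model, n)))
    return out


def elbow_k(scan: Sequence[tuple[int, MixtureModel, float]]) -> int:
    """Largest-second-difference elbow of the BIC curve (advisory only;
    pipeline defaults keep K fixed rather than auto-selecting)."""
    ks = [k for k, _, _ in scan]
    bics = np.array([b for _, _, b in scan])
    if len(ks) < 3:
        return ks[int(np.argmin(bics))]
    second = bics[:-2] - 2 * bics[1:-1] + bics[2:]
    return ks[int(np.argmax(second)) + 1]


def assign_states(model: MixtureModel, values) -> np.ndarray:
    """Maximum-posterior component index per value; posterior ties (to
    within 1e-9 relative, absorbing rounding of symmetric cases) break
    toward the component with the larger mean."""
    resp = model.responsibilities(np.asarray(values, dtype=float))
    order = np.argsort(-model.means, kind="stable")  # descending mean first
    ordered = resp[:, order]
    near_max = ordered >= ordered.max(axis=1, keepdims=True) * (1 - 1e-9)
    picked = np.argmax(near_max, axis=1)  # first (largest-mean) near-tie
    return order[picked]


def label_components(model: MixtureModel) -> dict[int, str]:
    """Map the three component indices to high / med / low by descending
    mean; requires K = 3 and distinct means."""
    if model.k != 3:
        raise ValueError(f"state labelling needs K=3, got K={model.k}")
    if len(np.unique(model.means)) != 3:
        raise ValueError("component means are not distinct; labelling is ambiguous")
    order = np.argsort(-model.means)
    return {int(comp): name for comp, name in zip(order, ("high", "med", "low"))}


def state_labels(model: MixtureModel, values) -> list[str]:
    """Assign each value to a named state (high/med/low)."""
    mapping = label_components(model)
    return [mapping[int(c)] for c in assign_states(model, values)]
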