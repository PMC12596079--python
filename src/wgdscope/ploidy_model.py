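"""Site-frequency-spectrum ploidy model selection.

Within one individual, the distribution of alternate-allele read
fractions across biallelic sites (the intragenomic SFS) is expected to be
unimodal at 0.5 for a diploid, bimodal at 1/3 and 2/3 for a triploid, and
trimodal at 1/4, 1/2 and 3/4 for a tetraploid.  Each fixed-ploidy
hypothesis is modelled as a Gaussian mixture with means pinned at those
fractions, equal component weights, and a single shared standard
deviation fitted by maximum likelihood.  A free three-component mixture
fitted by EM provides the unconstrained baseline; for each fixed model k
the gap delta_k = logL_free - logL_k measures misfit, and the selection
statistic is 1/delta_k — the larger, the closer the fixed model comes to
the free fit.  The model with the largest 1/delta wins, ties broken
toward lower ploidy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .ploidy_spectrum import AlleleDepthSite

PLOIDY_MEANS: dict[str, tuple[float, ...]] = {
    "diploid": (0.5,),
    "triploid": (1 / 3, 2 / 3),
    "tetraploid": (0.25, 0.5, 0.75),
}
#: tie-break order: lower ploidy first
_MODEL_ORDER = ("diploid", "triploid", "tetraploid")

SD_FLOOR = 1e-3
SD_CEIL = 0.5
DELTA_FLOOR = 1e-4
AMBIGUITY_TOL = 1e-6


@dataclass(frozen=True)
class BaseFreqSet:
    """Alternate-allele fractions for one scaffold (or the whole genome)."""

    freqs: np.ndarray
    scaffold: str = "genome-wide"

    def __post_init__(self) -> None:
        arr = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", arr)
        if arr.size and (arr.min() <= 0.0 or arr.max() >= 1.0):
            raise ValueError("base frequencies must lie strictly in (0, 1)")

    def __len__(self) -> int:
        return int(self.freqs.size)


@dataclass(frozen=True)
class MixtureModel:
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    kind: str  # free | diploid | triploid | tetraploid


@dataclass
class PloidyFit:
    """Model-selection result for one frequency set."""

    logL_free: float
    logL_fixed: dict[str, float]
    n_sites: int
    delta: dict[str, float] = field(init=False)
    inv_delta: dict[str, float] = field(init=False)
    best_model: str = field(init=False)
    ambiguous_with: str | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.delta = {k: self.logL_free - v for k, v in self.logL_fixed.items()}
        self.inv_delta = {
            k: 1.0 / max(d, DELTA_FLOOR) for k, d in self.delta.items()
        }
        ranked = sorted(
            _MODEL_ORDER, key=lambda k: (-self.inv_delta[k], _MODEL_ORDER.index(k))
        )
        self.best_model = ranked[0]
        runner = ranked[1]
        if abs(self.delta[self.best_model] - self.delta[runner]) < AMBIGUITY_TOL:
            self.ambiguous_with = runner


def extract_base_freqs(
    sites: Sequence[AlleleDepthSite],
    min_f: float = 0.1,
    max_f: float = 0.9,
    scaffold: str = "genome-wide",
) -> BaseFreqSet:
    """Alt-allele fraction per site, retained iff within [min_f, max_f].

    The default band [0.1, 0.9] removes near-fixed and error-dominated
    sites whose tail likelihoods would otherwise swamp the mixture fits.
    """
    if not (0.0 <= min_f < max_f <= 1.0):
        raise ValueError("need 0 <= min_f < max_f <= 1")
    vals = []
    for s in sites:
        total = s.depth_ref + s.depth_alt
        f = s.depth_alt / total
        if min_f <= f <= max_f:
            vals.append(f)
    if not vals:
        raise ValueError("no sites retained; SFS models undefined")
    return BaseFreqSet(freqs=np.array(vals), scaffold=scaffold)


def _mixture_loglik(x: np.ndarray, means: np.ndarray, sds: np.ndarray,
                    weights: np.ndarray) -> float:
    """Sum over sites of log sum_k w_k N(x | mu_k, sd_k)."""
    z = (x[:, None] - means[None, :]) / sds[None, :]
    comp = (
        -0.5 * z * z
        - np.log(sds[None, :])
        - 0.5 * np.log(2 * np.pi)
        + np.log(weights[None, :])
    )
    return float(np.sum(logsumexp(comp, axis=1)))


def fixed_model_loglik(freqs: BaseFreqSet, kind: str) -> tuple[float, float]:
    """ML log-likelihood of a fixed-ploidy mixture and its fitted shared sd.

    Means and (equal) weights are pinned by ``kind``; the single shared
    standard deviation is chosen by a bounded 1-D search over
    [1e-3, 0.5], making the fit deterministic.
    """
    if kind not in PLOIDY_MEANS:
        raise ValueError(f"unknown fixed model kind {kind!r}")
    x = freqs.freqs
    if x.size < 10:
        raise ValueError("need >= 10 frequency values to fit")
    means = np.array(PLOIDY_MEANS[kind])
    weights = np.full(means.size, 1.0 / means.size)

    def neg(sd: float) -> float:
        return -_mixture_loglik(x, means, np.full(means.size, sd), weights)

    res = minimize_scalar(
        neg, bounds=(SD_FLOOR, SD_CEIL), method="bounded",
        options={"xatol": 1e-6},
    )
    logL = -float(res.fun)
    if not np.isfinite(logL):
        raise ArithmeticError(f"non-finite likelihood for {kind} model")
    return logL, float(res.x)


def free_model_fit(
    freqs: BaseFreqSet, n_components: int = 3, seed: int | None = None,
    tol: float = 1e-6, max_iter: int = 1000,
) -> tuple[MixtureModel, float]:
    """EM fit of a free Gaussian mixture (3 components by default).

    Initialization is deterministic: component means at the 25th/50th/75th
    percentiles of the data (evenly spaced percentiles for other
    ``n_components``), equal weights, all sds at the sample sd.  ``seed``
    is accepted for interface symmetry but the fit involves no randomness.
    Convergence when the log-likelihood improves by < ``tol``.
    """
    x = freqs.freqs
    if x.size < 10:
        raise ValueError("need >= 10 frequency values to fit")
    qs = np.linspace(0, 100, n_components + 2)[1:-1]
    means = np.percentile(x, qs)
    sds = np.full(n_components, max(x.std(ddof=0), SD_FLOOR))
    weights = np.full(n_components, 1.0 / n_components)

    # E/M steps in linear space: safe here because the data live in
    # (0, 1) and sds are floored, so component densities cannot all
    # underflow at once; the mixture density is clamped regardless.
    xcol = x[:, None]
    prev = -np.inf
    logL = prev
    for it in range(max_iter):
        z = (xcol - means) / sds
        comp = np.exp(-0.5 * z * z) * (weights / (sds * np.sqrt(2 * np.pi)))
        dens = np.maximum(comp.sum(axis=1), 1e-300)
        logL = float(np.log(dens).sum())
        if not np.isfinite(logL):
            raise ArithmeticError(f"EM diverged at iteration {it}")
        if logL - prev < tol and it > 0:
            break
        prev = logL
        resp = comp / dens[:, None]
        nk = np.maximum(resp.sum(axis=0), 1e-300)
        means = resp.T @ x / nk
        var = (resp * (xcol - means) ** 2).sum(axis=0) / nk
        sds = np.maximum(np.sqrt(var), SD_FLOOR)
        weights = nk / x.size
    model = MixtureModel(
        means=tuple(means), sds=tuple(sds), weights=tuple(weights), kind="free"
    )
    return model, logL


def classify_ploidy(freqs: BaseFreqSet, seed: int | None = None) -> PloidyFit:
    """Fit the free and all fixed models and select by 1/delta-logL.

    delta is floored at 1e-4 before inversion so that an essentially
    exact fixed model yields a large finite statistic instead of a
    division blow-up.
    """
    _, logL_free = free_model_fit(freqs, seed=seed)
    logL_fixed = {k: fixed_model_loglik(freqs, k)[0] for k in _MODEL_ORDER}
    return PloidyFit(logL_free=logL_free, logL_fixed=logL_fixed, n_sites=len(freqs))


def per_scaffold_classification(
    sites: Sequence[AlleleDepthSite],
    top_n: int = 100,
    min_sites: int = 500,
    seed: int | None = None,
    min_f: float = 0.1,
    max_f: float = 0.9,
):
    """Classify the ``top_n`` most variant-dense scaffolds independently.

    Returns a pandas DataFrame sorted by biallelic-site count descending,
    one row per retained scaffold, with per-model log-likelihoods,
    1/delta statistics, the winning model and a flag column
    (``ok`` / ``insufficient`` / ``ambiguous``).
    """
    import pandas as pd

    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    by_scaffold: dict[str, list[AlleleDepthSite]] = {}
    for s in sites:
        by_scaffold.setdefault(s.scaffold, []).append(s)
    ranked = sorted(by_scaffold.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:top_n]

    rows = []
    for scaffold, scaffold_sites in ranked:
        row: dict = {"scaffold": scaffold, "n_sites": len(scaffold_sites)}
        if len(scaffold_sites) < min_sites:
            row.update(best_model=None, flag="insufficient")
            rows.append(row)
            continue
        freqs = extract_base_freqs(
            scaffold_sites, min_f=min_f, max_f=max_f, scaffold=scaffold
        )
        if len(freqs) < min_sites:
            row.update(best_model=None, flag="insufficient")
            rows.append(row)
            continue
        fit = classify_ploidy(freqs, seed=seed)
        row.update(
            logL_free=fit.logL_free,
            logL_di=fit.logL_fixed["diploid"],
            logL_tri=fit.logL_fixed["triploid"],
            logL_tet=fit.logL_fixed["tetraploid"],
            inv_delta_di=fit.inv_delta["diploid"],
            inv_delta_tri=fit.inv_delta["triploid"],
            inv_delta_tet=fit.inv_delta["tetraploid"],
            best_model=fit.best_model,
            flag=(
                f"ambiguous:{fit.ambiguous_with}" if fit.ambiguous_with else "ok"
            ),
        )
        rows.append(row)
    return pd.DataFrame(rows)
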