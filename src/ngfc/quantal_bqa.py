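"""Bayesian quantal analysis (BQA) and uniquantal event separation.

The generative model: a connection has ``N`` functional release sites,
each releasing independently with a condition-specific probability ``p``
(set by the extracellular Ca2+/Mg2+ ratio). A trial amplitude is the sum
of the released quanta (mean ``q`` pA, coefficient of variation ``cv``)
plus Gaussian baseline noise. ``N`` and ``q`` are shared across
conditions; ``p`` is condition-specific. The posterior is obtained by
discrete marginalization over ``N`` combined with ensemble MCMC over the
continuous parameters ``(q, p_1..p_C, cv, noise)``.

Each k-quantum mixture component is moment-matched by a Gaussian
``N(k q, k (q cv)^2 + noise^2)``, a standard approximation for quantal
amplitude distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, InferenceError, StatisticsError

__all__ = [
    "AmplitudeDataset",
    "BqaPriors",
    "QuantalPosterior",
    "bqa_fit",
    "EventFeatureSet",
    "kmeans_event_separation",
    "stability_correlation",
]


@dataclass
class AmplitudeDataset:
    """Per-condition IPSC amplitude samples (pA, magnitudes) of one connection."""

    amplitudes: dict                      # condition -> array of pA
    times: dict = field(default_factory=dict)  # condition -> elapsed time, s

    def __post_init__(self):
        self.amplitudes = {c: np.asarray(a, dtype=float) for c, a in self.amplitudes.items()}
        for c, a in self.amplitudes.items():
            if a.size < 20:
                warnings.warn(
                    f"condition {c!r} has only {a.size} trials; >= 20 recommended",
                    stacklevel=2,
                )

    @property
    def conditions(self):
        return sorted(self.amplitudes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, amps in self.amplitudes.items():
            times = self.times.get(cond, np.full(amps.size, np.nan))
            for i, (a, t) in enumerate(zip(amps, times)):
                rows.append({"condition": cond, "trial_index": i,
                             "time_s": t, "amplitude_pA": a})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AmplitudeDataset":
        amplitudes, times = {}, {}
        for cond, grp in df.groupby("condition"):
            grp = grp.sort_values("trial_index")
            amplitudes[cond] = grp["amplitude_pA"].to_numpy()
            if "time_s" in grp:
                times[cond] = grp["time_s"].to_numpy()
        return cls(amplitudes=amplitudes, times=times)


@dataclass
class BqaPriors:
    """Weakly informative default priors of the BQA model.

    ``n_prior = "occam"`` weights P(N) proportional to 1/N (uniform on
    log N). The site count behaves as a scale parameter: a model with 2N
    sites of half the quantal size reproduces the same amplitude peaks
    (the sub-harmonic ambiguity of quantal analysis), and a flat prior
    lets that mode capture the posterior median. ``"uniform"`` is
    available for sensitivity checks.
    """

    n_max: int = 30                 # support of N: 1..n_max
    n_prior: str = "occam"          # "occam" (1/N) or "uniform"
    q_range: tuple = (0.5, 20.0)    # log-uniform, pA
    cv_range: tuple = (0.05, 1.0)   # log-uniform
    noise_range: tuple = (0.1, 10.0)  # log-uniform, pA

    def __post_init__(self):
        if self.n_max < 1:
            raise ConfigurationError("n_max must be >= 1")
        if self.n_prior not in ("occam", "uniform"):
            raise ConfigurationError("n_prior must be 'occam' or 'uniform'")

    def log_n_prior(self) -> np.ndarray:
        """Normalized log prior over N = 1..n_max."""
        n = np.arange(1, self.n_max + 1, dtype=float)
        w = 1.0 / n if self.n_prior == "occam" else np.ones_like(n)
        return np.log(w / w.sum())


def _condition_loglik(y, n_max, q, p, cv, noise):
    """log L(y | N) for every N in 1..n_max; returns (n_max,) array."""
    k = np.arange(0, n_max + 1)
    mu = k * q
    var = k * (q * cv) ** 2 + noise**2
    # component log-densities: (K+1, n_y)
    comp = -0.5 * ((y[None, :] - mu[:, None]) ** 2 / var[:, None]
                   + np.log(2 * np.pi * var[:, None]))
    # binomial log-weights for all N at once: W[n-1, k] = log C(n,k) p^k (1-p)^(n-k)
    n = np.arange(1, n_max + 1)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logc = (gammaln(n + 1) - gammaln(k[None, :] + 1) - gammaln(n - k[None, :] + 1))
    W = logc + k[None, :] * np.log(p) + (n - k[None, :]) * np.log1p(-p)
    W[k[None, :] > n] = -np.inf
    m = W[:, :, None] + comp[None, :, :]          # (n_max, K+1, n_y)
    mx = m.max(axis=1, keepdims=True)
    out = mx[:, 0, :] + np.log(np.exp(m - mx).sum(axis=1))
    return out.sum(axis=1)


class _BqaLogProb:
    """Log posterior over transformed continuous parameters.

    theta = (log q, logit p_1..p_C, log cv, log noise); N marginalized
    with a uniform prior on 1..n_max.
    """

    def __init__(self, data: AmplitudeDataset, priors: BqaPriors):
        self.conds = data.conditions
        self.y = [data.amplitudes[c] for c in self.conds]
        self.priors = priors
        self.log_pn = priors.log_n_prior()

    def unpack(self, theta):
        q = np.exp(theta[0])
        ps = 1.0 / (1.0 + np.exp(-theta[1 : 1 + len(self.conds)]))
        cv = np.exp(theta[-2])
        noise = np.exp(theta[-1])
        return q, ps, cv, noise

    def loglik_by_n(self, theta):
        q, ps, cv, noise = self.unpack(theta)
        pr = self.priors
        if not (pr.q_range[0] <= q <= pr.q_range[1]):
            return None
        if not (pr.cv_range[0] <= cv <= pr.cv_range[1]):
            return None
        if not (pr.noise_range[0] <= noise <= pr.noise_range[1]):
            return None
        if np.any(ps <= 1e-6) or np.any(ps >= 1 - 1e-6):
            return None
        ll = np.zeros(pr.n_max)
        for y, p in zip(self.y, ps):
            ll += _condition_loglik(y, pr.n_max, q, p, cv, noise)
        return ll

    def __call__(self, theta):
        ll = self.loglik_by_n(theta)
        if ll is None:
            return -np.inf
        # log-uniform priors on q, cv, noise are flat in the transformed
        # coordinates; logistic Jacobian makes p uniform in (0,1)
        jac = np.sum(np.log(1.0 / (1.0 + np.exp(-theta[1:-2]))
                            * (1.0 - 1.0 / (1.0 + np.exp(-theta[1:-2])))))
        return float(np.logaddexp.reduce(ll + self.log_pn) + jac)


@dataclass
class QuantalPosterior:
    """Posterior over (Nfrs, q, per-condition p, cv, noise)."""

    conditions: list
    samples: pd.DataFrame         # continuous parameters, one row per draw
    n_pmf: np.ndarray             # posterior pmf of N on 1..n_max
    n_max: int

    def __post_init__(self):
        total = float(self.n_pmf.sum())
        if not np.isfinite(total) or total <= 0:
            raise InferenceError("posterior over N is degenerate")
        self.n_pmf = self.n_pmf / total

    @property
    def n_support(self) -> np.ndarray:
        return np.arange(1, self.n_max + 1)

    def median_n(self) -> int:
        cdf = np.cumsum(self.n_pmf)
        return int(self.n_support[np.searchsorted(cdf, 0.5)])

    def median(self, param: str) -> float:
        return float(self.samples[param].median())

    def credible_interval(self, param: str, level: float = 0.95):
        a = (1 - level) / 2
        s = self.samples[param]
        return float(s.quantile(a)), float(s.quantile(1 - a))

    def summary(self) -> dict:
        out = {
            "n_frs_median": self.median_n(),
            "n_frs_mean": float(self.n_support @ self.n_pmf),
            "q_median_pA": self.median("q"),
            "cv_median": self.median("cv"),
            "noise_median_pA": self.median("noise"),
        }
        for c in self.conditions:
            out[f"p_{c}_median"] = self.median(f"p_{c}")
        return out


def bqa_fit(
    data: AmplitudeDataset,
    priors: BqaPriors = None,
    n_walkers: int = 16,
    n_burn: int = 300,
    n_steps: int = 400,
    seed: int = 0,
) -> QuantalPosterior:
    """Fit the binomial-quantal model across release-probability conditions.

    Requires at least two conditions recorded from the same connection so
    that ``N`` and ``q`` are identified separately from ``p``.
    """
    priors = priors or BqaPriors()
    conds = data.conditions
    if len(conds) < 2:
        raise InferenceError("BQA needs >= 2 release-probability conditions")
    for c in conds:
        if data.amplitudes[c].size < 2:
            raise InferenceError(f"condition {c!r} has fewer than 2 trials")

    logprob = _BqaLogProb(data, priors)
    ndim = 3 + len(conds)
    rng = np.random.default_rng(seed)

    # moment-based initial guess: mean/max amplitude scales
    pooled = np.concatenate([data.amplitudes[c] for c in conds])
    q0 = float(np.clip(np.std(pooled) / 2.0, *priors.q_range))
    p0 = []
    biggest = max(float(np.mean(np.abs(data.amplitudes[c]))) for c in conds)
    for c in conds:
        m = float(np.mean(np.abs(data.amplitudes[c])))
        p0.append(np.clip(0.8 * m / max(biggest, 1e-9), 0.05, 0.95))
    center = np.concatenate([
        [np.log(q0)],
        np.log(np.array(p0) / (1 - np.array(p0))),
        [np.log(0.3)],
        [np.log(np.clip(np.std(pooled) / 5.0, *priors.noise_range))],
    ])
    p_init = center + 0.2 * rng.normal(size=(n_walkers, ndim))
    ok = np.array([np.isfinite(logprob(p)) for p in p_init])
    for i in np.flatnonzero(~ok):
        for _ in range(100):
            cand = center + 0.05 * rng.normal(size=ndim)
            if np.isfinite(logprob(cand)):
                p_init[i] = cand
                break
        else:
            raise InferenceError("could not initialize walkers in the prior support")

    sampler = emcee.EnsembleSampler(n_walkers, ndim, logprob)
    state = emcee.State(p_init, random_state=np.random.RandomState(seed).get_state())
    state = sampler.run_mcmc(state, n_burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, n_steps, progress=False)
    chain = sampler.get_chain(flat=True, thin=2)

    # posterior over N: average conditional P(N | theta) over draws
    n_pmf = np.zeros(priors.n_max)
    rows = []
    for theta in chain:
        ll = logprob.loglik_by_n(theta)
        if ll is None:
            continue
        ll = ll + logprob.log_pn
        w = np.exp(ll - np.logaddexp.reduce(ll))
        n_pmf += w
        q, ps, cv, noise = logprob.unpack(theta)
        row = {"q": q, "cv": cv, "noise": noise}
        row.update({f"p_{c}": p for c, p in zip(conds, ps)})
        rows.append(row)
    if not rows:
        raise InferenceError("no valid posterior draws; check data scale vs priors")
    return QuantalPosterior(
        conditions=conds,
        samples=pd.DataFrame(rows),
        n_pmf=n_pmf,
        n_max=priors.n_max,
    )


# ---------------------------------------------------------------------------
# uniquantal event separation
# ---------------------------------------------------------------------------

@dataclass
class EventFeatureSet:
    """Per-event (initial slope, peak amplitude, area) features."""

    slope: np.ndarray
    amplitude: np.ndarray
    area: np.ndarray

    def __post_init__(self):
        self.slope = np.asarray(self.slope, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        n = self.slope.size
        if self.amplitude.size != n or self.area.size != n:
            raise ConfigurationError("feature arrays must share a length")
        mat = self.matrix()
        if not np.all(np.isfinite(mat)):
            raise ConfigurationError("features must be finite")

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.slope, self.amplitude, self.area])


SEMANTIC_LABELS = ("failure", "uniquantal", "multiquantal")


def kmeans_event_separation(features: EventFeatureSet, k: int = 3, seed: int = 0):
    """Separate events into failures / uniquantal / multiquantal groups.

    K-means (k-means++ with a fixed seed) on the standardized three-feature
    space; clusters are ranked by their mean raw amplitude and mapped to
    semantic labels in that order. Returns ``(labels, uniquantal_mean)``
    where labels is an array of strings and ``uniquantal_mean`` the mean
    amplitude of the middle (uniquantal) cluster.
    """
    mat = features.matrix()
    if mat.shape[0] < k:
        raise StatisticsError(f"need at least {k} events for k={k} clustering")
    if np.unique(mat, axis=0).shape[0] < k:
        raise StatisticsError("fewer distinct feature points than clusters")
    X = StandardScaler().fit_transform(mat)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    order = np.argsort([features.amplitude[raw == c].mean() for c in range(k)],
                       kind="stable")
    if k == 3:
        names = SEMANTIC_LABELS
    else:
        names = tuple(f"cluster_{i}" for i in range(k))
    remap = {int(c): names[rank] for rank, c in enumerate(order)}
    labels = np.array([remap[int(c)] for c in raw], dtype=object)
    uni_name = names[1] if k >= 2 else names[0]
    uni_mean = float(features.amplitude[labels == uni_name].mean())
    return labels, uni_mean


def stability_correlation(amplitudes, times):
    """Pearson correlation of amplitude against elapsed time.

    A stability check: long recordings should show no drift (|r| small);
    returns ``(r, p)`` with a two-sided p-value.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    times = np.asarray(times, dtype=float)
    if amplitudes.size != times.size:
        raise ConfigurationError("amplitudes and times must have equal length")
    if amplitudes.size < 3:
        raise StatisticsError("need >= 3 points for a correlation")
    if np.std(amplitudes) == 0 or np.std(times) == 0:
        raise StatisticsError("zero variance in amplitudes or times")
    r, p = stats.pearsonr(amplitudes, times)
    return float(r), float(p)
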