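"""Capacity estimation from the Visual Array (change-detection) Task.

Two estimators are provided.

1. Cowan's formula, per set size N:  k = N * (p(H) + p(CR) - 1), where p(H)
   is the hit rate on change trials and p(CR) the correct-rejection rate on
   no-change trials.  Valid when N exceeds the true capacity; it can return
   negative values when false alarms outnumber hits (reported as-is, with a
   warning).

2. A three-parameter attend-or-lapse / in-memory-or-guess model with
   capacity ``k`` (items), attending probability ``z`` and guessing bias
   ``g`` (probability of responding "change" when uninformed).  With
   m = min(k, N)/N,

       p(hit)         = z*(m + (1-m)*g) + (1-z)*g
       p(false alarm) = z*(1-m)*g       + (1-z)*g

   Parameters are estimated jointly across set sizes for a cohort of
   participants by a hierarchical Metropolis-within-Gibbs sampler: each
   participant's (log k, logit z, logit g) is drawn from population normals
   whose means and variances get conjugate Gibbs updates, while the
   participant-level parameters get adaptive random-walk Metropolis updates.
   ``z`` can be fixed (not sampled) for control analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VATCounts",
    "ThreeParamTheta",
    "MCMCConfig",
    "PosteriorSummary",
    "cowan_k",
    "predicted_response_probs",
    "vat_log_likelihood",
    "fit_mcmc",
    "geweke_diagnostic",
    "read_vat_trials",
    "write_vat_trials",
    "counts_from_trials",
]

_P_CLAMP = 1e-9


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class ThreeParamTheta:
    """(k, z, g) for one participant in one condition."""

    k: float
    z: float
    g: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        for name in ("z", "g"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class VATCounts:
    """Hit / correct-rejection counts per set size for one participant."""

    set_sizes: np.ndarray
    n_change: np.ndarray
    hits: np.ndarray
    n_same: np.ndarray
    correct_rejections: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("set_sizes", "n_change", "hits", "n_same", "correct_rejections"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError(f"{name} must be 1-D")
            arrays[name] = arr
        lengths = {a.shape[0] for a in arrays.values()}
        if len(lengths) != 1 or 0 in lengths:
            raise ValueError("all count arrays must share one non-zero length")
        if (arrays["hits"] > arrays["n_change"]).any():
            raise ValueError("hits exceed change-trial count")
        if (arrays["correct_rejections"] > arrays["n_same"]).any():
            raise ValueError("correct rejections exceed same-trial count")
        if any((arrays[n] < 0).any() for n in arrays):
            raise ValueError("negative counts")
        for name, arr in arrays.items():
            setattr(self, name, arr)

    @classmethod
    def from_trials(cls, set_size, is_change, response_change) -> "VATCounts":
        """Aggregate per-trial records into per-set-size counts."""
        df = pd.DataFrame(
            {
                "set_size": np.asarray(set_size, dtype=np.int64),
                "is_change": np.asarray(is_change, dtype=np.int64),
                "response_change": np.asarray(response_change, dtype=np.int64),
            }
        )
        sizes = np.sort(df["set_size"].unique())
        rows = []
        for n in sizes:
            sub = df[df["set_size"] == n]
            change = sub[sub["is_change"] == 1]
            same = sub[sub["is_change"] == 0]
            rows.append(
                (
                    n,
                    len(change),
                    int(change["response_change"].sum()),
                    len(same),
                    int((same["response_change"] == 0).sum()),
                )
            )
        arr = np.array(rows, dtype=np.int64)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])

    def cowan_by_set_size(self) -> dict[int, float]:
        """Cowan's k per set size from the observed hit/CR rates."""
        out = {}
        for i, n in enumerate(self.set_sizes):
            p_hit = self.hits[i] / self.n_change[i] if self.n_change[i] else np.nan
            p_cr = (
                self.correct_rejections[i] / self.n_same[i] if self.n_same[i] else np.nan
            )
            out[int(n)] = cowan_k(int(n), p_hit, p_cr)
        return out


def cowan_k(N: int, p_hit: float, p_cr: float) -> float:
    """Cowan's single-set-size capacity estimate N*(p(H) + p(CR) - 1).

    Negative values (hits below false alarms) are a known pathology of the
    formula; they are returned unclamped with a warning.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    for name, p in (("p_hit", p_hit), ("p_cr", p_cr)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    k = N * (p_hit + p_cr - 1.0)
    if k < 0:
        warnings.warn(
            f"cowan_k is negative ({k:.3f}): false alarms exceed hits", stacklevel=2
        )
    return float(k)


def predicted_response_probs(theta: ThreeParamTheta, N: int):
    """(p_hit, p_false_alarm) under the three-parameter model at set size N.

    Continuous k is allowed; the probed-item-in-memory probability
    min(k, N)/N is piecewise linear in k and capped at 1.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    m = min(theta.k, N) / N
    p_hit = theta.z * (m + (1 - m) * theta.g) + (1 - theta.z) * theta.g
    p_fa = theta.z * (1 - m) * theta.g + (1 - theta.z) * theta.g
    return float(p_hit), float(p_fa)


def vat_log_likelihood(counts: VATCounts, theta: ThreeParamTheta) -> float:
    """Binomial log likelihood of hit/CR counts across set sizes."""
    return float(
        _loglik_vec(
            np.array([theta.k]),
            np.array([theta.z]),
            np.array([theta.g]),
            counts.set_sizes[None, :].astype(float),
            counts.n_change[None, :].astype(float),
            counts.hits[None, :].astype(float),
            counts.n_same[None, :].astype(float),
            counts.correct_rejections[None, :].astype(float),
        )[0]
    )


def _loglik_vec(k, z, g, N, n_change, hits, n_same, cr):
    """Vectorised log likelihood; participant-row arrays, set-size columns."""
    m = np.minimum(k[:, None], N) / N
    ph = z[:, None] * (m + (1 - m) * g[:, None]) + (1 - z[:, None]) * g[:, None]
    pf = z[:, None] * (1 - m) * g[:, None] + (1 - z[:, None]) * g[:, None]
    ph = np.clip(ph, _P_CLAMP, 1 - _P_CLAMP)
    pf = np.clip(pf, _P_CLAMP, 1 - _P_CLAMP)
    ll = (
        hits * np.log(ph)
        + (n_change - hits) * np.log1p(-ph)
        + (n_same - cr) * np.log(pf)
        + cr * np.log1p(-pf)
    )
    return ll.sum(axis=1)


@dataclass
class MCMCConfig:
    """Sampler settings.

    ``proposal_eps_lower``/``proposal_eps_upper`` bound the Robbins-Monro
    learning rate used during burn-in to adapt the log proposal scales toward
    an acceptance rate of ~0.70; ``fix_z`` freezes every participant's z at
    the given value and skips its updates.
    """

    n_iterations: int = 10_000
    burn_in: int = 1_000
    proposal_eps_lower: float = 0.035
    proposal_eps_upper: float = 0.05
    seed: int = 0
    fix_z: float | None = None
    target_acceptance: float = 0.70
    adapt_batch: int = 50

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("require 0 <= burn_in < n_iterations")
        if not 0 < self.proposal_eps_lower <= self.proposal_eps_upper:
            raise ValueError("require 0 < eps_lower <= eps_upper")
        if self.fix_z is not None and not 0.0 <= self.fix_z <= 1.0:
            raise ValueError("fix_z must be a probability")


@dataclass
class PosteriorSummary:
    """Posterior means/s.d.s per participant plus chain diagnostics."""

    participants: pd.DataFrame  # columns k_mean, k_sd, z_mean, z_sd, g_mean, g_sd
    acceptance_rate: float
    geweke: dict[str, float]
    n_retained: int
    hyper_chains: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.acceptance_rate <= 1.0:
            raise ValueError("acceptance rate outside [0, 1]")

    def population_means(self) -> dict[str, float]:
        """Mean over participants of the posterior means of k, z, g."""
        return {
            p: float(self.participants[f"{p}_mean"].mean()) for p in ("k", "z", "g")
        }


# weakly-informative hyperpriors on the transformed scales
_HYPER_PRIOR = {
    "a": (np.log(4.0), 1.0),  # population mean of log k centred on log 4
    "b": (_logit(0.9), 1.5),  # logit z
    "c": (0.0, 1.5),  # logit g
}
_SIGMA_PRIOR = (2.0, 0.5)  # inverse-gamma (shape, scale) on population variances
_INIT_STEP = {"a": 0.15, "b": 0.30, "c": 0.30}


def _stack_counts(data: dict) -> tuple[list, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Align per-participant counts on the union of set sizes (absent = 0 trials)."""
    pids = list(data)
    all_sizes = sorted({int(n) for c in data.values() for n in c.set_sizes})
    S, P = len(all_sizes), len(pids)
    idx = {n: j for j, n in enumerate(all_sizes)}
    N = np.tile(np.array(all_sizes, dtype=float), (P, 1))
    n_change = np.zeros((P, S))
    hits = np.zeros((P, S))
    n_same = np.zeros((P, S))
    cr = np.zeros((P, S))
    for i, pid in enumerate(pids):
        c = data[pid]
        for j, n in enumerate(c.set_sizes):
            col = idx[int(n)]
            n_change[i, col] = c.n_change[j]
            hits[i, col] = c.hits[j]
            n_same[i, col] = c.n_same[j]
            cr[i, col] = c.correct_rejections[j]
    return pids, N, n_change, hits, n_same, cr


def fit_mcmc(
    data: dict,
    config: MCMCConfig | None = None,
    hierarchical: bool = True,
    keep_participant_chains: bool = False,
) -> PosteriorSummary:
    """Fit the three-parameter model to a cohort by Metropolis-within-Gibbs.

    ``data`` maps participant id -> :class:`VATCounts`.  Participant
    parameters are sampled on transformed scales (log k, logit z, logit g)
    with elementwise random-walk Metropolis proposals whose scales adapt
    during burn-in; population means and variances get conjugate normal /
    inverse-gamma Gibbs updates.  With ``hierarchical=False`` the population
    parameters are held at their prior centres (flat-ish independent fits).
    Fully reproducible given ``config.seed``.
    """
    if config is None:
        config = MCMCConfig()
    if not data:
        raise ValueError("no participants supplied")
    rng = np.random.default_rng(config.seed)
    pids, N, n_change, hits, n_same, cr = _stack_counts(data)
    P = len(pids)

    # data-driven initialisation
    n_change_s = np.maximum(n_change, 1)
    n_same_s = np.maximum(n_same, 1)
    p_hit0 = (hits + 0.5) / (n_change_s + 1.0)
    p_cr0 = (cr + 0.5) / (n_same_s + 1.0)
    cowan0 = (N * (p_hit0 + p_cr0 - 1.0)).mean(axis=1)
    max_n = float(N.max())
    k0 = np.clip(cowan0, 0.5, max_n)
    if N.min() >= np.median(k0):
        warnings.warn(
            "no set size is plausibly below capacity; z may be poorly identified",
            stacklevel=2,
        )
    fa_rate = 1.0 - p_cr0.mean(axis=1)
    g0 = np.clip(fa_rate * 2.0, 0.05, 0.95)  # FA ~ (1-m)*g-ish rough moment start
    # accuracy at the smallest set size: if it is below capacity, acc ~ z + (1-z)/2
    j_min = int(np.argmin(N[0]))
    acc_min = (hits[:, j_min] + cr[:, j_min] + 1.0) / (
        n_change[:, j_min] + n_same[:, j_min] + 2.0
    )
    z0 = np.clip(2.0 * acc_min - 1.0, 0.5, 0.98)

    a = np.log(k0)
    b = _logit(z0)
    c = _logit(g0)
    fix_z = config.fix_z is not None
    if fix_z:
        b = np.full(P, _logit(np.clip(config.fix_z, 1e-6, 1 - 1e-6)))

    mu = {blk: float(v.mean()) for blk, v in (("a", a), ("b", b), ("c", c))}
    sig2 = {
        blk: float(max(v.var(), 0.05)) for blk, v in (("a", a), ("b", b), ("c", c))
    }

    params = {"a": a, "b": b, "c": c}
    blocks = ["a", "c"] if fix_z else ["a", "b", "c"]
    # z mixes slowest (near-ceiling accuracies identify it weakly); give its
    # block a second Metropolis sweep per iteration
    sweep = blocks if fix_z else ["a", "b", "c", "b"]
    step = {blk: np.full(P, _INIT_STEP[blk]) for blk in blocks}

    def loglik(pa, pb, pc):
        return _loglik_vec(np.exp(pa), _expit(pb), _expit(pc), N, n_change, hits, n_same, cr)

    cur_ll = loglik(params["a"], params["b"], params["c"])
    for _ in range(10):
        if np.isfinite(cur_ll).all():
            break
        bad = ~np.isfinite(cur_ll)
        params["a"][bad] = np.log(np.clip(rng.normal(4.0, 1.0, bad.sum()), 0.5, max_n))
        cur_ll = loglik(params["a"], params["b"], params["c"])
    else:
        raise RuntimeError("could not find a finite starting point in 10 attempts")

    a0_ig, b0_ig = _SIGMA_PRIOR
    n_keep = config.n_iterations - config.burn_in
    hyper_names = [f"mu_{blk}" for blk in blocks] + [f"sigma_{blk}" for blk in blocks]
    hyper_store = np.empty((n_keep, len(hyper_names)))
    sums = {blk: np.zeros(P) for blk in "abc"}
    sums_nat = {p: np.zeros(P) for p in "kzg"}
    sumsq_nat = {p: np.zeros(P) for p in "kzg"}
    part_chains = (
        {p: np.empty((n_keep, P)) for p in "kzg"} if keep_participant_chains else None
    )
    accepted = 0
    proposed = 0
    batch_acc = {blk: np.zeros(P) for blk in blocks}
    batch_n = 0

    for it in range(config.n_iterations):
        in_burn = it < config.burn_in
        for blk in sweep:
            theta = params[blk]
            prop = theta + step[blk] * rng.standard_normal(P)
            trial = {k_: v.copy() for k_, v in params.items()}
            trial[blk] = prop
            new_ll = loglik(trial["a"], trial["b"], trial["c"])
            d_prior = ((theta - mu[blk]) ** 2 - (prop - mu[blk]) ** 2) / (2 * sig2[blk])
            log_alpha = new_ll - cur_ll + d_prior
            accept = np.log(rng.random(P)) < log_alpha
            theta[accept] = prop[accept]
            cur_ll = np.where(accept, new_ll, cur_ll)
            if in_burn:
                batch_acc[blk] += accept
            else:
                accepted += int(accept.sum())
                proposed += P
        if in_burn:
            batch_n += 1
            if batch_n == config.adapt_batch:
                # Robbins-Monro rate bounded by the configured window; run at
                # the upper bound (the lower bound matters when users shrink it)
                lr = config.proposal_eps_upper
                for blk in blocks:
                    n_sweeps = sweep.count(blk)
                    rate = batch_acc[blk] / (config.adapt_batch * n_sweeps)
                    step[blk] *= np.exp(lr * (rate - config.target_acceptance) / 0.3)
                    batch_acc[blk][:] = 0.0
                batch_n = 0

        if hierarchical:
            for blk in blocks:
                m0, s0 = _HYPER_PRIOR[blk]
                theta = params[blk]
                prec = P / sig2[blk] + 1.0 / s0**2
                mean = (theta.sum() / sig2[blk] + m0 / s0**2) / prec
                mu[blk] = mean + rng.standard_normal() / np.sqrt(prec)
                shape = a0_ig + P / 2.0
                scale = b0_ig + 0.5 * float(((theta - mu[blk]) ** 2).sum())
                sig2[blk] = scale / rng.gamma(shape)

        if not in_burn:
            j = it - config.burn_in
            for col, blk in enumerate(blocks):
                hyper_store[j, col] = mu[blk]
                hyper_store[j, len(blocks) + col] = np.sqrt(sig2[blk])
            k_nat = np.exp(params["a"])
            z_nat = _expit(params["b"])
            g_nat = _expit(params["c"])
            for name, vals in (("k", k_nat), ("z", z_nat), ("g", g_nat)):
                sums_nat[name] += vals
                sumsq_nat[name] += vals**2
                if part_chains is not None:
                    part_chains[name][j] = vals

    rows = {}
    for p in "kzg":
        mean = sums_nat[p] / n_keep
        var = np.maximum(sumsq_nat[p] / n_keep - mean**2, 0.0)
        rows[f"{p}_mean"] = mean
        rows[f"{p}_sd"] = np.sqrt(var)
    participants = pd.DataFrame(rows, index=pd.Index(pids, name="participant_id"))
    hyper_chains = pd.DataFrame(hyper_store, columns=hyper_names)
    # diagnose on thinned chains: segment spectral estimates are biased low
    # on strongly autocorrelated draws, inflating |z|
    thin = max(1, n_keep // 1000)
    geweke = {
        name: geweke_diagnostic(hyper_chains[name].to_numpy()[::thin])
        for name in hyper_names
    }
    summary = PosteriorSummary(
        participants=participants,
        acceptance_rate=accepted / proposed if proposed else 0.0,
        geweke=geweke,
        n_retained=n_keep,
        hyper_chains=hyper_chains,
    )
    if part_chains is not None:
        summary.participant_chains = {
            p: pd.DataFrame(arr, columns=pids) for p, arr in part_chains.items()
        }
    return summary


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density at frequency zero via an AR model (Yule-Walker, AIC).

    Autoregressive spectral estimation handles the slowly-decaying
    autocorrelation of hierarchical-model chains better than short lag
    windows; the order is chosen by AIC up to min(20, n/10).
    """
    n = len(x)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1 :] / n
    if acov[0] <= 0:
        return 0.0
    max_order = min(20, n // 10)
    best = (n * np.log(acov[0]), 0.0, acov[0])  # aic, sum(phi), innovation var
    # Levinson-Durbin recursion
    phi = np.zeros(max_order + 1)
    prev = np.zeros(max_order + 1)
    sigma2 = acov[0]
    for p in range(1, max_order + 1):
        kappa = (acov[p] - np.dot(phi[1:p], acov[1:p][::-1])) / sigma2
        prev[1:p] = phi[1:p]
        phi[1:p] = prev[1:p] - kappa * prev[1:p][::-1]
        phi[p] = kappa
        sigma2 *= 1.0 - kappa**2
        if sigma2 <= 0:
            break
        aic = n * np.log(sigma2) + 2.0 * p
        if aic < best[0]:
            best = (aic, float(phi[1 : p + 1].sum()), float(sigma2))
    _, phi_sum, innov = best
    denom = (1.0 - phi_sum) ** 2
    if denom <= 1e-12:
        denom = 1e-12
    return float(innov / denom)


def geweke_diagnostic(chain, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    Means of the first ``first`` and last ``last`` fractions of the chain are
    compared with standard errors from spectral density estimates at zero
    frequency; |z| < 1.96 is the conventional pass.  A constant chain returns
    z = 0.
    """
    chain = np.asarray(chain, dtype=float)
    if chain.ndim != 1:
        raise ValueError("chain must be 1-D")
    n = len(chain)
    if n < 100:
        raise ValueError(f"chain too short for the diagnostic: {n} < 100")
    seg1 = chain[: max(int(first * n), 2)]
    seg2 = chain[n - max(int(last * n), 2) :]
    var = _spectral_density_zero(seg1) / len(seg1) + _spectral_density_zero(seg2) / len(
        seg2
    )
    diff = seg1.mean() - seg2.mean()
    if var <= 0:
        return 0.0
    return float(diff / np.sqrt(var))


# --- trial CSV dialect --------------------------------------------------------

VAT_COLUMNS = ["participant_id", "condition", "set_size", "is_change", "response_change"]


def read_vat_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [col for col in VAT_COLUMNS if col not in df.columns]
    if missing:
        raise ValueError(f"VAT trial file missing columns {missing}")
    return df


def write_vat_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=VAT_COLUMNS)


def counts_from_trials(df: pd.DataFrame, condition: str | None = None) -> dict:
    """Aggregate a trial table into {participant_id: VATCounts}."""
    if condition is not None:
        df = df[df["condition"] == condition]
    if df.empty:
        raise ValueError("no trials after filtering")
    return {
        pid: VATCounts.from_trials(sub["set_size"], sub["is_change"], sub["response_change"])
        for pid, sub in df.groupby("participant_id")
    }
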