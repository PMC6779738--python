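"""Bayesian many-to-one mixed stock analysis (MSA) by Gibbs sampling.

A juvenile feeding-ground sample is modelled as a finite mixture over k
source rookeries ("stocks"). Each stock k has unknown haplotype frequencies
q_k, informed by its baseline counts x_k through a Dirichlet prior/posterior,
and the mixture sample is multinomial with per-haplotype probabilities
sum_k theta_k * q_kh, where theta is the vector of stock contributions on
the k-simplex. The Gibbs sweep alternates:

1. q_k ~ Dirichlet(beta + x_k)              (baseline uncertainty propagated)
2. z_i | theta, q  for each mixture animal: P(z_i = k) ∝ theta_k q_k,h(i)
3. theta | z ~ Dirichlet(alpha + assignment counts)

with alpha the contribution prior (default symmetric 1/k: equal prior mean
per source with total prior weight one — weakly informative and free of
abundance weighting) and beta a symmetric 1/H Dirichlet on baseline
frequencies. Chains are over-dispersed: chain c starts with 95% of theta
mass on stock c mod k. Convergence is judged by the Gelman-Rubin potential
scale reduction factor (threshold 1.2); summaries report posterior means
with equal-tailed 95% intervals, optionally aggregated to regional stocks
by summing member contributions draw-by-draw.

The temporal-change statistic is simply dC = C_late - C_early on the
posterior mean contributions of the two time partitions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DataError
from .haplotypes import HaplotypeCounts

logger = logging.getLogger(__name__)

#: Gelman-Rubin threshold below which chains are declared converged.
RHAT_THRESHOLD = 1.2


@dataclass(frozen=True)
class Rookery:
    """One baseline source population: name, region, haplotype counts."""

    name: str
    region: str
    counts: Mapping[str, int]


@dataclass(frozen=True)
class BaselineSet:
    """Ordered rookery baselines over a shared haplotype universe."""

    rookeries: tuple[Rookery, ...]
    haplotype_universe: tuple[str, ...]

    def __post_init__(self) -> None:
        rooks = tuple(self.rookeries)
        if not rooks:
            raise DataError("baseline set needs at least one rookery")
        names = [r.name for r in rooks]
        if len(set(names)) != len(names):
            raise DataError("rookery names are not unique")
        universe = tuple(str(h) for h in self.haplotype_universe)
        uni = set(universe)
        for r in rooks:
            extra = set(r.counts) - uni
            if extra:
                raise DataError(
                    f"rookery {r.name!r} counts haplotypes outside the universe: {sorted(extra)}"
                )
        object.__setattr__(self, "rookeries", rooks)
        object.__setattr__(self, "haplotype_universe", universe)

    @property
    def k(self) -> int:
        return len(self.rookeries)

    @property
    def stock_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.rookeries)

    @property
    def regions(self) -> dict[str, str]:
        """Rookery name -> region name."""
        return {r.name: r.region for r in self.rookeries}

    def counts_matrix(self) -> np.ndarray:
        """(k, H) baseline haplotype counts in universe order."""
        index = {h: j for j, h in enumerate(self.haplotype_universe)}
        out = np.zeros((self.k, len(self.haplotype_universe)))
        for i, r in enumerate(self.rookeries):
            for h, c in r.counts.items():
                out[i, index[h]] = c
        return out

    @classmethod
    def from_csv(cls, path: str | Path) -> "BaselineSet":
        df = pd.read_csv(path, comment="#")
        required = {"rookery", "region", "haplotype", "count"}
        if not required <= set(df.columns):
            raise DataError(f"{path}: expected columns {sorted(required)}")
        universe = tuple(dict.fromkeys(df["haplotype"].astype(str)))
        rookeries = []
        for (name, region), sub in df.groupby(["rookery", "region"], sort=False):
            counts = dict(zip(sub["haplotype"].astype(str), sub["count"].astype(int)))
            rookeries.append(Rookery(str(name), str(region), counts))
        return cls(tuple(rookeries), universe)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            (r.name, r.region, h, c)
            for r in self.rookeries
            for h, c in r.counts.items()
        ]
        pd.DataFrame(rows, columns=["rookery", "region", "haplotype", "count"]).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class MixtureObservations:
    """Feeding-ground haplotype counts split into retained and orphan tallies.

    Orphan haplotypes — present in the mixture but absent from every
    baseline — carry no information about source and are excluded from the
    likelihood, but their tally is preserved for reporting.
    """

    retained: Mapping[str, int]
    orphans: Mapping[str, int]

    @property
    def n(self) -> int:
        return sum(self.retained.values())

    @property
    def n_orphans(self) -> int:
        return sum(self.orphans.values())


@dataclass(frozen=True)
class PosteriorDraws:
    """Kept theta draws per chain, plus sampler metadata."""

    chains: tuple[np.ndarray, ...]  # each (kept_iterations, k)
    stock_names: tuple[str, ...]
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        chains = tuple(np.asarray(c, dtype=float) for c in self.chains)
        if len(chains) < 2:
            raise DataError("posterior draws need >= 2 chains for diagnostics")
        k = len(self.stock_names)
        for c in chains:
            if c.ndim != 2 or c.shape[1] != k:
                raise DataError("chain shape does not match number of stocks")
            if np.any(c < -1e-12) or np.any(np.abs(c.sum(axis=1) - 1.0) > 1e-9):
                raise DataError("theta draws must lie on the probability simplex")
        object.__setattr__(self, "chains", chains)

    @property
    def k(self) -> int:
        return len(self.stock_names)

    def pooled(self) -> np.ndarray:
        """All kept draws stacked across chains, shape (m*n, k)."""
        return np.vstack(self.chains)

    def to_csv(self, path: str | Path) -> None:
        frames = []
        for c_idx, chain in enumerate(self.chains):
            df = pd.DataFrame(chain, columns=list(self.stock_names))
            df.insert(0, "iteration", np.arange(len(chain)))
            df.insert(0, "chain", c_idx)
            frames.append(df.melt(["chain", "iteration"], var_name="stock", value_name="theta"))
        pd.concat(frames).to_csv(path, index=False)


@dataclass(frozen=True)
class ContributionSummary:
    """Posterior mean and equal-tailed 95% interval per stock or region."""

    labels: tuple[str, ...]
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if not (len(self.labels) == mean.size == lo.size == hi.size):
            raise DataError("summary arrays must match labels")
        if np.any(mean < lo - 1e-9) or np.any(mean > hi + 1e-9):
            raise DataError("posterior mean outside its credible interval")
        if abs(mean.sum() - 1.0) > 0.02:
            raise DataError(f"posterior means sum to {mean.sum():.4f}, expected ~1")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.mean))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit": self.labels, "mean": self.mean, "lo95": self.lower, "hi95": self.upper}
        )


def prepare_mixture(counts: HaplotypeCounts, baselines: BaselineSet) -> MixtureObservations:
    """Split mixture counts into baseline-supported and orphan haplotypes."""
    universe = set(baselines.haplotype_universe)
    retained = {h: c for h, c in counts.counts.items() if h in universe}
    orphans = {h: c for h, c in counts.counts.items() if h not in universe}
    if not retained:
        raise DataError(
            f"mixture {counts.label!r}: every haplotype is orphaned; no informative data"
        )
    if orphans:
        logger.warning(
            "mixture %s: %d individual(s) with orphan haplotypes excluded: %s",
            counts.label, sum(orphans.values()), sorted(orphans),
        )
    return MixtureObservations(retained, orphans)


@dataclass(frozen=True)
class GelmanRubinResult:
    """Per-stock potential scale reduction factors and the overall flag."""

    rhat: np.ndarray
    stock_names: tuple[str, ...]
    converged: bool


def _initial_theta(k: int, chain_index: int) -> np.ndarray:
    if k == 1:
        return np.ones(1)
    theta = np.full(k, 0.05 / (k - 1))
    theta[chain_index % k] = 0.95
    return theta


def gibbs_msa(
    mixture: MixtureObservations,
    baselines: BaselineSet,
    theta_prior: Sequence[float] | None = None,
    n_iter: int = 50_000,
    burn_in: int = 25_000,
    n_chains: int | None = None,
    seed: int = 0,
    beta: Sequence[float] | None = None,
    fixed_q: bool = False,
) -> PosteriorDraws:
    """Run the Gibbs sampler for stock contributions theta.

    Parameters
    ----------
    theta_prior
        Dirichlet parameters on theta; default symmetric 1/k (uniform prior
        mean, total weight 1).
    n_iter, burn_in
        Sweeps per chain and how many to discard; kept draws are the
        post-burn-in theta rows, thinning 1.
    n_chains
        Default min(k, 8), at least 2 (diagnostics need multiple chains).
    beta
        Dirichlet parameters on each stock's haplotype frequencies; default
        symmetric 1/H over the baseline universe.
    fixed_q
        Freeze q_k at the observed baseline frequencies instead of
        resampling each sweep. Used for conjugate closed-form checks; the
        default (False) propagates baseline sampling uncertainty.

    Returns
    -------
    PosteriorDraws
        Bit-reproducible for fixed (seed, n_iter, n_chains).
    """
    k = baselines.k
    H = len(baselines.haplotype_universe)
    if not (n_iter > burn_in >= 0):
        raise DataError("need n_iter > burn_in >= 0")
    if n_chains is None:
        n_chains = max(2, min(k, 8))
    if n_chains < 2:
        raise DataError("need at least 2 chains")
    alpha = (
        np.full(k, 1.0 / k) if theta_prior is None else np.asarray(theta_prior, dtype=float)
    )
    if alpha.shape != (k,) or np.any(alpha <= 0):
        raise DataError("theta_prior must be k positive reals")
    beta_vec = (
        np.full(H, 1.0 / H) if beta is None else np.asarray(beta, dtype=float)
    )
    if beta_vec.shape != (H,) or np.any(beta_vec <= 0):
        raise DataError("beta must be H positive reals")

    x = baselines.counts_matrix()  # (k, H)
    hap_index = {h: j for j, h in enumerate(baselines.haplotype_universe)}
    m = np.zeros(H)
    for h, c in mixture.retained.items():
        if h not in hap_index:
            raise DataError(f"retained mixture haplotype {h!r} not in baseline universe")
        m[hap_index[h]] = c
    active = np.flatnonzero(m > 0)
    if active.size == 0 and mixture.n > 0:
        raise DataError("mixture has counts but none map to the universe")

    if fixed_q:
        row_tot = x.sum(axis=1, keepdims=True)
        if np.any(row_tot == 0):
            raise DataError("fixed_q requires every rookery to have baseline counts")
        q_fixed = x / row_tot
        # Prior positivity normally guarantees support; frozen frequencies must
        # be checked explicitly.
        if np.any(q_fixed[:, active].sum(axis=0) == 0):
            raise DataError("fixed_q: a retained mixture haplotype has no baseline support")

    n_keep = n_iter - burn_in
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    chains = []
    for c_idx in range(n_chains):
        rng = np.random.default_rng(seeds[c_idx])
        theta = _initial_theta(k, c_idx)
        kept = np.empty((n_keep, k))
        gamma_shape = beta_vec + x  # (k, H), constant across sweeps
        for it in range(n_iter):
            if fixed_q:
                q = q_fixed
            else:
                g = rng.gamma(gamma_shape)
                q = g / g.sum(axis=1, keepdims=True)
            assign = np.zeros(k)
            for j in active:
                w = theta * q[:, j]
                tot = w.sum()
                assert tot > 0, "zero-probability deadlock; prior positivity violated"
                assign += rng.multinomial(int(m[j]), w / tot)
            g_theta = rng.gamma(alpha + assign)
            theta = g_theta / g_theta.sum()
            if it >= burn_in:
                kept[it - burn_in] = theta
        chains.append(kept)
    meta = {
        "n_iter": n_iter,
        "burn_in": burn_in,
        "n_chains": n_chains,
        "seed": seed,
        "theta_prior": alpha.tolist(),
        "beta": beta_vec.tolist(),
        "fixed_q": fixed_q,
        "n_mixture": int(m.sum()),
        "n_orphans": mixture.n_orphans,
    }
    return PosteriorDraws(tuple(chains), baselines.stock_names, meta)


def gelman_rubin(draws: PosteriorDraws) -> GelmanRubinResult:
    """Per-stock Gelman-Rubin potential scale reduction factor R-hat.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance of chain means scaled by n.
    All R-hat below 1.2 is taken as convergence. W = 0 with separated chain
    means signals divergence (R-hat = inf); W = B = 0 defines R-hat = 1.
    """
    n = min(c.shape[0] for c in draws.chains)
    if n < 10:
        raise DataError("gelman_rubin needs >= 10 kept iterations per chain")
    stacked = np.stack([c[:n] for c in draws.chains])  # (m, n, k)
    W = stacked.var(axis=1, ddof=1).mean(axis=0)
    chain_means = stacked.mean(axis=1)  # (m, k)
    B = n * chain_means.var(axis=0, ddof=1)
    rhat = np.empty(draws.k)
    for s in range(draws.k):
        if W[s] == 0:
            rhat[s] = 1.0 if B[s] == 0 else np.inf
        else:
            rhat[s] = np.sqrt(((n - 1) / n * W[s] + B[s] / n) / W[s])
    return GelmanRubinResult(rhat, draws.stock_names, bool(np.all(rhat < RHAT_THRESHOLD)))


def summarize(
    draws: PosteriorDraws, check_convergence: bool = True
) -> ContributionSummary:
    """Pool chains and report per-stock posterior mean and 95% interval.

    Quantiles use linear interpolation between order statistics. By default
    refuses non-converged chains; pass ``check_convergence=False`` to
    override with a warning.
    """
    diag = gelman_rubin(draws)
    if not diag.converged:
        msg = f"chains not converged (max R-hat {np.nanmax(diag.rhat):.3f})"
        if check_convergence:
            raise ConvergenceError(msg)
        warnings.warn(msg + "; summarizing anyway", stacklevel=2)
    pooled = draws.pooled()
    if pooled.size == 0:
        raise DataError("no draws to summarize")
    return ContributionSummary(
        draws.stock_names,
        pooled.mean(axis=0),
        np.quantile(pooled, 0.025, axis=0),
        np.quantile(pooled, 0.975, axis=0),
    )


def aggregate_regions(
    draws: PosteriorDraws,
    mapping: Mapping[str, str],
    check_convergence: bool = True,
) -> ContributionSummary:
    """Summarize contributions at the regional level.

    Region values are computed per draw as the sum of member-stock theta
    entries, then summarized — sum-then-summarize, so regional intervals
    reflect the joint posterior, not sums of marginal quantiles.
    """
    unmapped = [s for s in draws.stock_names if s not in mapping]
    if unmapped:
        raise DataError(f"stocks without a region mapping: {unmapped}")
    regions = tuple(dict.fromkeys(mapping[s] for s in draws.stock_names))
    members = {
        reg: [i for i, s in enumerate(draws.stock_names) if mapping[s] == reg]
        for reg in regions
    }
    region_chains = tuple(
        np.stack([c[:, members[reg]].sum(axis=1) for reg in regions], axis=1)
        for c in draws.chains
    )
    region_draws = PosteriorDraws(region_chains, regions, dict(draws.meta))
    return summarize(region_draws, check_convergence=check_convergence)


def delta_c(
    summary_early: ContributionSummary, summary_late: ContributionSummary
) -> pd.Series:
    """Temporal change in recruitment: dC = C_late - C_early per unit.

    C is the posterior mean contribution of a stock or region in each time
    partition, so dC lies in [-1, 1].
    """
    if summary_early.labels != summary_late.labels:
        raise DataError(
            "delta_c: summaries must cover the same units in the same order"
        )
    return pd.Series(
        summary_late.mean - summary_early.mean, index=list(summary_early.labels), name="delta_c"
    )
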