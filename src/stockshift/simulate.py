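"""Synthetic data generators matching the statistical structure of the analysis.

Field data for this kind of study are (a) strongly differentiated rookery
baselines — maternally inherited mtDNA plus natal homing keeps haplotype
frequency vectors distinct between rookeries; (b) feeding-ground mixture
samples that are multinomial draws from a contribution-weighted blend of
those baselines, at two time partitions with possibly different
contribution vectors; (c) recapture structure (an individual's haplotype
never changes between captures); and (d) nest-count time series following
noisy exponential growth. Every generator here is a pure function of its
parameters and a seed; a scenario derives independent child seeds from one
master seed so any stage can be regenerated in isolation.

Defaults mirror the study conditions: nine rookeries in four regions,
twelve haplotypes, Dirichlet concentration 0.2 for strongly structured
baselines, mixture partitions of 120 (early) and 160 (late) animals,
a 12% recapture rate, and juvenile sizes of 30-75 cm SCL with half below
the 50 cm recent-recruit cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError
from .haplotypes import HaplotypeCounts, HaplotypePanel, ObservationRecord, ObservationTable
from .mixed_stock import BaselineSet, Rookery
from .demography import NestSeries

_DEF_STOCKS = (
    ("R1", "north-west"),
    ("R2", "north-west"),
    ("R3", "north-west"),
    ("R4", "south-west"),
    ("R5", "east"),
    ("R6", "east"),
    ("R7", "east"),
    ("R8", "south-atlantic"),
    ("R9", "south-atlantic"),
)

# Regional trajectory shaped like the study (north-west rising, east falling,
# south-west flat, south-atlantic minor), spread over the member stocks.
_DEF_THETA_EARLY = (0.04, 0.04, 0.04, 0.43, 0.14, 0.14, 0.12, 0.03, 0.02)
_DEF_THETA_LATE = (0.13, 0.13, 0.12, 0.42, 0.06, 0.06, 0.06, 0.01, 0.01)


@dataclass(frozen=True)
class SimulationScenario:
    """Full parameterization of a synthetic two-partition feeding-ground study."""

    stocks: tuple[tuple[str, str], ...] = _DEF_STOCKS  # (name, region)
    n_haplotypes: int = 12
    concentration: float = 0.2
    n_per_rookery: int = 200
    theta_early: tuple[float, ...] = _DEF_THETA_EARLY
    theta_late: tuple[float, ...] = _DEF_THETA_LATE
    n_early: int = 120
    n_late: int = 160
    early_years: tuple[int, ...] = (2006, 2007)
    late_years: tuple[int, ...] = (2015, 2016)
    recapture_rate: float = 0.12
    frac_small: float = 0.5  # fraction of animals below the 50 cm cutoff
    nest_r_true: float = 0.05
    nest_start: float = 500.0
    nest_years: int = 20
    nest_cv: float = 0.2
    seed: int = 20160101

    def __post_init__(self) -> None:
        k = len(self.stocks)
        for theta in (self.theta_early, self.theta_late):
            if len(theta) != k:
                raise DataError("theta length must equal number of stocks")
            if any(t < 0 for t in theta) or abs(sum(theta) - 1.0) > 1e-9:
                raise DataError("theta must lie on the simplex")
        if self.n_haplotypes < k:
            raise DataError("need at least as many haplotypes as stocks")
        if min(self.n_early, self.n_late, self.n_per_rookery) < 1:
            raise DataError("sample sizes must be positive")
        if not 0 <= self.recapture_rate < 1:
            raise DataError("recapture_rate must be in [0, 1)")


def _child_seed(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def generate_panel(
    n_haplotypes: int, length: int = 474, seed: int = 0, prefix: str = "H"
) -> HaplotypePanel:
    """Synthetic equal-length haplotype sequences with guaranteed uniqueness.

    A random A/C/G/T backbone is mutated at a disjoint block of positions
    per haplotype, so every pair differs at >= 2 sites and all pairwise
    distances are positive.
    """
    if n_haplotypes * 2 > length:
        raise DataError("sequence too short for the requested number of haplotypes")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    backbone = rng.choice(bases, size=length)
    entries = {}
    for i in range(n_haplotypes):
        seq = backbone.copy()
        for pos in (2 * i, 2 * i + 1):  # disjoint two-site block per haplotype
            current = seq[pos]
            seq[pos] = rng.choice([b for b in "ACGT" if b != current])
        entries[f"{prefix}{i + 1:02d}"] = "".join(seq)
    return HaplotypePanel(entries)


def generate_baselines(
    k: int,
    n_haplotypes: int,
    concentration: float = 0.2,
    n_per_rookery: int = 200,
    seed: int = 0,
    stocks: Sequence[tuple[str, str]] | None = None,
    haplotype_names: Sequence[str] | None = None,
) -> tuple[BaselineSet, np.ndarray]:
    """Draw differentiated rookery baselines and their true frequency vectors.

    Per stock, true haplotype frequencies ~ symmetric Dirichlet with the
    given concentration (low values, e.g. 0.2, concentrate mass on few
    haplotypes per stock and yield strong differentiation; high values
    approach panmixia), then observed counts ~ multinomial(n_per_rookery).

    Returns the BaselineSet together with the (k, H) true frequency matrix.
    """
    if k < 1 or n_haplotypes < k:
        raise DataError("need k >= 1 and H >= k")
    if concentration <= 0:
        raise DataError("concentration must be positive")
    if stocks is None:
        stocks = [(f"R{i + 1}", "region-1") for i in range(k)]
    if len(stocks) != k:
        raise DataError("stocks must list k (name, region) pairs")
    if haplotype_names is None:
        haplotype_names = [f"H{j + 1:02d}" for j in range(n_haplotypes)]
    rng = np.random.default_rng(seed)
    freqs = rng.dirichlet(np.full(n_haplotypes, concentration), size=k)
    rookeries = []
    for i, (name, region) in enumerate(stocks):
        counts = rng.multinomial(n_per_rookery, freqs[i])
        rookeries.append(
            Rookery(name, region, {h: int(c) for h, c in zip(haplotype_names, counts) if c})
        )
    return BaselineSet(tuple(rookeries), tuple(haplotype_names)), freqs


def structured_frequencies(
    k: int,
    haps_per_stock: int = 3,
    dominant: Sequence[float] = (0.55, 0.25, 0.08),
    background: float = 0.02,
) -> np.ndarray:
    """Deterministic well-separated stock frequency vectors.

    Each stock concentrates most of its mass on its own block of
    ``haps_per_stock`` haplotypes (at the ``dominant`` frequencies) with a
    small shared ``background`` on every other haplotype, then rows are
    normalized. Unlike a low-concentration Dirichlet draw — which is
    strongly differentiated only on average — this construction guarantees
    pairwise separation, which recovery benchmarks presuppose.
    """
    if len(dominant) != haps_per_stock:
        raise DataError("dominant must list one frequency per own-block haplotype")
    H = k * haps_per_stock
    freqs = np.full((k, H), background)
    for i in range(k):
        freqs[i, i * haps_per_stock : (i + 1) * haps_per_stock] = dominant
    return freqs / freqs.sum(axis=1, keepdims=True)


def baselines_from_frequencies(
    freqs: np.ndarray,
    n_per_rookery: int = 200,
    seed: int = 0,
    stocks: Sequence[tuple[str, str]] | None = None,
    haplotype_names: Sequence[str] | None = None,
) -> BaselineSet:
    """Multinomial baseline counts from given per-stock frequency vectors."""
    freqs = np.asarray(freqs, dtype=float)
    k, H = freqs.shape
    if stocks is None:
        stocks = [(f"R{i + 1}", "region-1") for i in range(k)]
    if haplotype_names is None:
        haplotype_names = [f"H{j + 1:02d}" for j in range(H)]
    rng = np.random.default_rng(seed)
    rookeries = tuple(
        Rookery(
            name,
            region,
            {h: int(c) for h, c in zip(haplotype_names, rng.multinomial(n_per_rookery, freqs[i])) if c},
        )
        for i, (name, region) in enumerate(stocks)
    )
    return BaselineSet(rookeries, tuple(haplotype_names))


def generate_mixture(
    true_freqs: np.ndarray,
    theta: Sequence[float],
    n: int,
    seed: int = 0,
    haplotype_names: Sequence[str] | None = None,
    label: str = "mixture",
) -> tuple[HaplotypeCounts, np.ndarray]:
    """Sample a feeding-ground mixture with known stock contributions.

    Each of n individuals draws a stock of origin ~ categorical(theta), then
    a haplotype ~ categorical(that stock's true frequencies). Returns the
    haplotype counts and the per-individual true origins (stock indices) for
    recovery scoring.
    """
    freqs = np.asarray(true_freqs, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if freqs.ndim != 2 or theta.shape != (freqs.shape[0],):
        raise DataError("theta length must match the number of stocks in true_freqs")
    if np.any(theta < 0) or abs(theta.sum() - 1.0) > 1e-9:
        raise DataError("theta must lie on the simplex")
    if n < 1:
        raise DataError("n must be >= 1")
    if haplotype_names is None:
        haplotype_names = [f"H{j + 1:02d}" for j in range(freqs.shape[1])]
    rng = np.random.default_rng(seed)
    origins = rng.choice(freqs.shape[0], size=n, p=theta)
    counts = np.zeros(freqs.shape[1], dtype=int)
    for k_idx, n_k in zip(*np.unique(origins, return_counts=True)):
        counts += rng.multinomial(n_k, freqs[k_idx])
    tally = {h: int(c) for h, c in zip(haplotype_names, counts) if c}
    return HaplotypeCounts(label, tally), origins


def _draw_scl(rng: np.random.Generator, n: int, frac_small: float) -> np.ndarray:
    small = rng.random(n) < frac_small
    scl = np.where(
        small, rng.uniform(30.0, 50.0, size=n), rng.uniform(50.0, 75.0, size=n)
    )
    return np.round(scl, 1)


@dataclass(frozen=True)
class TemporalStudy:
    """Synthetic two-partition study: observation tables plus ground truth."""

    early: ObservationTable
    late: ObservationTable
    baselines: BaselineSet
    true_freqs: np.ndarray
    origins_early: np.ndarray
    origins_late: np.ndarray
    scenario: SimulationScenario

    def combined(self) -> ObservationTable:
        """All capture events in one table (recaptures appear in both partitions)."""
        return ObservationTable(
            tuple(self.early.records) + tuple(self.late.records),
            year_range=self.early.year_range,
        )


def generate_temporal_study(scenario: SimulationScenario) -> TemporalStudy:
    """Simulate the full two-partition feeding-ground sampling design.

    Early-partition animals are drawn under theta_early, late under
    theta_late. A recapture_rate fraction of early animals is re-observed in
    a late year with the same haplotype and a larger SCL. Haplotype names
    carry through from the baseline universe.
    """
    k = len(scenario.stocks)
    H = scenario.n_haplotypes
    baselines, freqs = generate_baselines(
        k,
        H,
        scenario.concentration,
        scenario.n_per_rookery,
        seed=_child_seed(scenario.seed, 0).integers(2**31),
        stocks=scenario.stocks,
    )
    hap_names = baselines.haplotype_universe
    mix_early, origins_early = generate_mixture(
        freqs, scenario.theta_early, scenario.n_early,
        seed=_child_seed(scenario.seed, 1).integers(2**31),
        haplotype_names=hap_names, label="early",
    )
    mix_late, origins_late = generate_mixture(
        freqs, scenario.theta_late, scenario.n_late,
        seed=_child_seed(scenario.seed, 2).integers(2**31),
        haplotype_names=hap_names, label="late",
    )
    rng = _child_seed(scenario.seed, 3)

    def table_from_mixture(
        counts: HaplotypeCounts, years: tuple[int, ...], start_id: int
    ) -> list[ObservationRecord]:
        haps = [h for h, c in counts.counts.items() for _ in range(c)]
        rng.shuffle(haps)
        n = len(haps)
        yrs = rng.choice(list(years), size=n)
        scl = _draw_scl(rng, n, scenario.frac_small)
        return [
            ObservationRecord(f"T{start_id + i:04d}", int(yrs[i]), float(scl[i]), haps[i])
            for i in range(n)
        ]

    early_records = table_from_mixture(mix_early, scenario.early_years, 0)
    late_records = table_from_mixture(mix_late, scenario.late_years, len(early_records))

    # Recaptures: early animals re-observed in a late year, same haplotype,
    # grown by 5-20 cm (capped just under the 75 cm juvenile limit).
    n_recap = int(round(scenario.recapture_rate * len(early_records)))
    recap_idx = rng.choice(len(early_records), size=n_recap, replace=False)
    recap_records = []
    for i in recap_idx:
        rec = early_records[i]
        new_scl = min(74.9, rec.scl_cm + float(rng.uniform(5.0, 20.0)))
        recap_records.append(
            ObservationRecord(
                rec.individual_id,
                int(rng.choice(list(scenario.late_years))),
                round(new_scl, 1),
                rec.haplotype,
            )
        )

    year_range = (min(scenario.early_years) - 1, max(scenario.late_years) + 1)
    early = ObservationTable(tuple(early_records), year_range=year_range)
    late = ObservationTable(tuple(late_records + recap_records), year_range=year_range)
    return TemporalStudy(early, late, baselines, freqs, origins_early, origins_late, scenario)


def generate_nest_series(
    r_true: float,
    start: float,
    n_years: int,
    cv_noise: float,
    seed: int = 0,
    rookery: str = "synthetic",
    first_year: int = 1996,
) -> NestSeries:
    """Exponential nest-count series with multiplicative lognormal noise.

    counts(t) = start * (1 + r_true)^t * eps_t, with eps_t lognormal of mean
    1 and coefficient of variation cv_noise, rounded to whole nests.
    """
    if start <= 0:
        raise DataError("start must be positive")
    if n_years < 4:
        raise DataError("nest series needs >= 4 years")
    if cv_noise < 0:
        raise DataError("cv_noise must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(n_years)
    expected = start * (1.0 + r_true) ** t
    if cv_noise > 0:
        sigma2 = np.log1p(cv_noise**2)
        eps = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n_years)
    else:
        eps = np.ones(n_years)
    counts = np.maximum(0, np.round(expected * eps)).astype(int)
    years = tuple(range(first_year, first_year + n_years))
    return NestSeries(rookery, years, tuple(float(c) for c in counts))
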