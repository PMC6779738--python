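"""Rookery recovery metrics and the recovery-recruitment statistical layer.

A rookery's recovery is characterized by its annual population growth rate r
estimated from a nest-count time series,

    r = (N_L / N_F)^(1 / (n - 3)) - 1,

where N_F and N_L are the mean counts over the first and last three years
and n is the series length (the exponent is the number of year steps between
the two three-year window centres). Regional rates are means of member
rookery rates weighted by adult female abundance N, and the product Nr
serves as a proxy for annual reproductive output. The statistical layer
relates the temporal change in estimated recruitment (dC, from the mixed
stock analysis) to Nr and geography: Spearman rank correlation with an
exact permutation p-value at small n, logistic regression of
increase/decrease on Nr, and multiple linear regression with bidirectional
stepwise selection on a Gaussian AIC.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DataError, UndefinedStatisticError

logger = logging.getLogger(__name__)

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class NestSeries:
    """Annual nest counts for one rookery over consecutive years."""

    rookery: str
    years: tuple[int, ...]
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        counts = tuple(float(c) for c in self.counts)
        if len(years) != len(counts):
            raise DataError(f"{self.rookery}: years and counts differ in length")
        if len(years) < 4:
            raise DataError(f"{self.rookery}: nest series needs >= 4 years, got {len(years)}")
        if any(b - a != 1 for a, b in zip(years, years[1:])):
            raise DataError(f"{self.rookery}: years must be consecutive")
        if any(c < 0 for c in counts):
            raise DataError(f"{self.rookery}: negative nest count")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.years)

    @classmethod
    def many_from_csv(cls, path: str | Path) -> dict[str, "NestSeries"]:
        """Read ``rookery,year,nests`` CSV into one series per rookery."""
        df = pd.read_csv(path, comment="#")
        if not {"rookery", "year", "nests"} <= set(df.columns):
            raise DataError(f"{path}: expected columns rookery,year,nests")
        out = {}
        for name, sub in df.groupby("rookery", sort=False):
            sub = sub.sort_values("year")
            out[str(name)] = cls(str(name), tuple(sub["year"]), tuple(sub["nests"]))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rookery": self.rookery, "year": self.years, "nests": self.counts})


def growth_rate_from_nests(series: NestSeries) -> float:
    """Annual growth rate from the first/last three-year mean nest counts.

    Raises
    ------
    UndefinedStatisticError
        If the first three years average zero nests (rate undefined).
    """
    n = len(series)
    n_first = float(np.mean(series.counts[:3]))
    n_last = float(np.mean(series.counts[-3:]))
    if n_first == 0:
        raise UndefinedStatisticError(
            f"{series.rookery}: first three years have zero nests; growth rate undefined"
        )
    return (n_last / n_first) ** (1.0 / (n - 3)) - 1.0


def weighted_mean_growth(
    rates: Mapping[str, float], weights: Mapping[str, float]
) -> float:
    """Abundance-weighted mean of per-rookery growth rates."""
    if set(rates) != set(weights):
        raise DataError("rates and weights must cover the same rookeries")
    w = np.array([weights[k] for k in rates], dtype=float)
    r = np.array([rates[k] for k in rates], dtype=float)
    if np.any(w < 0):
        raise DataError("weights must be non-negative")
    if w.sum() == 0:
        raise DataError("all weights are zero")
    return float(np.sum(w * r) / w.sum())


def round_half_away(x: float) -> int:
    """Round half away from zero, the convention used for printed Nr values."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def reproductive_output(n_females: float, r: float) -> float:
    """Reproductive-output proxy Nr = adult female abundance x growth rate.

    Returned at full precision; use :func:`round_half_away` for display.
    """
    if n_females < 0:
        raise DataError("abundance must be non-negative")
    return float(n_females) * float(r)


def great_circle_distance(
    a: tuple[float, float], b: tuple[float, float]
) -> float:
    """Haversine distance in km between (lat, lon) points in degrees."""
    for lat, lon in (a, b):
        if not -90 <= lat <= 90:
            raise DataError(f"latitude {lat} outside [-90, 90]")
        if not -180 <= lon <= 180:
            raise DataError(f"longitude {lon} outside [-180, 180]")
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    s = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    exact: bool  # True when p came from full rank-permutation enumeration


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 8
) -> SpearmanResult:
    """Spearman rank correlation with an exact small-sample p-value.

    rho is the Pearson correlation of mid-ranks (tie-corrected). The
    two-sided p-value is computed by full enumeration of all n! permutations
    of the y-ranks for n <= ``exact_max_n`` (the null distribution of rho is
    then exact, important at the tiny sample sizes of regional analyses);
    larger samples use the usual t approximation with n - 2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise DataError("spearman needs equal-length inputs with n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise UndefinedStatisticError("spearman: zero rank variance")
    rho = _rank_pearson(rx, ry)
    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_pearson(rx, np.array(perm))) >= abs(rho) - 1e-12:
                count += 1
        return SpearmanResult(rho, count / total, exact=True)
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, min(1.0, p), exact=False)


@dataclass(frozen=True)
class RegressionReport:
    """Fitted model terms, coefficients, p-values, AIC and the selection trace."""

    terms: tuple[str, ...]
    coefficients: Mapping[str, float]
    p_values: Mapping[str, float]
    aic: float
    trace: tuple[tuple[tuple[str, ...], float], ...] = ()
    warnings: tuple[str, ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coefficients": dict(self.coefficients),
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "aic": float(self.aic),
            "trace": [{"terms": list(t), "aic": float(a)} for t, a in self.trace],
            "warnings": list(self.warnings),
        }


def logistic_increase_model(
    delta_c: Mapping[str, float], nr: Mapping[str, float]
) -> RegressionReport:
    """Logistic regression of recruitment increase (dC > 0) on Nr.

    The binary response is 1 where dC > 0 and 0 otherwise; ties at exactly
    dC = 0 are classed as "not increased". Fitting is by IRLS through a
    binomial GLM; complete separation is flagged in the report (with
    coefficients from a capped-iteration fit) rather than raised.
    """
    if set(delta_c) != set(nr):
        raise DataError("delta_c and nr must cover the same rookeries")
    units = list(delta_c)
    y = np.array([1.0 if delta_c[u] > 0 else 0.0 for u in units])
    x = np.array([nr[u] for u in units], dtype=float)
    n_pos = int(y.sum())
    if n_pos < 2 or len(y) - n_pos < 2:
        raise DataError(
            f"logistic model needs >= 2 rookeries per class, got {n_pos} increased / "
            f"{len(y) - n_pos} not"
        )
    X = sm.add_constant(x)
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
        for w in caught:
            if "separation" in str(w.message).lower() or "converge" in str(w.message).lower():
                notes.append(str(w.message))
    coef = {"intercept": float(fit.params[0]), "nr": float(fit.params[1])}
    pvals = {"intercept": float(fit.pvalues[0]), "nr": float(fit.pvalues[1])}
    if not np.all(np.isfinite(list(pvals.values()))):
        notes.append("Wald p-values unreliable (likely separation)")
    return RegressionReport(
        ("intercept", "nr"), coef, pvals, float(fit.aic), warnings=tuple(notes)
    )


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _gaussian_aic(y: np.ndarray, X: np.ndarray, n_terms: int) -> float:
    n = y.size
    rss = max(_ols_rss(y, X), 1e-300)  # keep AIC finite on perfect fits
    return n * math.log(rss / n) + 2 * (n_terms + 1)


def stepwise_ols(
    response: Mapping[str, float] | Sequence[float],
    candidates: Mapping[str, Sequence[float]],
) -> RegressionReport:
    """Multiple linear regression with bidirectional stepwise-AIC selection.

    Starts from the full model and repeatedly applies the single-term
    addition or deletion that lowers the Gaussian AIC
    ``n*ln(RSS/n) + 2*(p+1)`` the most, stopping when no move strictly
    decreases it (R's ``step`` behaviour up to an additive constant). Ties
    break deterministically toward the first-listed candidate. The visited
    (terms, AIC) pairs are recorded in the trace.
    """
    if isinstance(response, Mapping):
        y = np.array([response[k] for k in response], dtype=float)
    else:
        y = np.asarray(response, dtype=float)
    names = list(candidates)
    cols = {name: np.asarray(candidates[name], dtype=float) for name in names}
    n = y.size
    for name, v in cols.items():
        if v.size != n:
            raise DataError(f"candidate {name!r} has length {v.size}, expected {n}")
    if n <= len(names) + 1:
        raise DataError("stepwise_ols needs n > number of candidates + 1")

    full = np.column_stack([np.ones(n)] + [cols[m] for m in names])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        collinear = [
            name
            for i, name in enumerate(names)
            if np.linalg.matrix_rank(np.delete(full, i + 1, axis=1)) == np.linalg.matrix_rank(full)
        ]
        raise DataError(f"rank-deficient design; collinear terms: {collinear}")

    def design(terms: tuple[str, ...]) -> np.ndarray:
        return np.column_stack([np.ones(n)] + [cols[t] for t in terms])

    current: tuple[str, ...] = tuple(names)
    current_aic = _gaussian_aic(y, design(current), len(current))
    trace: list[tuple[tuple[str, ...], float]] = [(current, current_aic)]
    while True:
        moves: list[tuple[float, tuple[str, ...]]] = []
        for t in current:  # deletions first, then additions, in listed order
            cand = tuple(u for u in current if u != t)
            moves.append((_gaussian_aic(y, design(cand), len(cand)), cand))
        for t in names:
            if t not in current:
                cand = current + (t,)
                moves.append((_gaussian_aic(y, design(cand), len(cand)), cand))
        if not moves:
            break
        best_aic, best_terms = min(moves, key=lambda m: m[0])  # stable: first wins ties
        if best_aic < current_aic - 1e-12:
            current, current_aic = best_terms, best_aic
            trace.append((current, current_aic))
        else:
            break

    X = design(current)
    fit = sm.OLS(y, X).fit()
    term_names = ("intercept",) + current
    coef = dict(zip(term_names, map(float, fit.params)))
    pvals = dict(zip(term_names, map(float, fit.pvalues)))
    return RegressionReport(term_names, coef, pvals, current_aic, trace=tuple(trace))


# -- demographic table ------------------------------------------------------

DEMOGRAPHY_COLUMNS = ["unit", "region", "N", "D_km", "r", "Nr", "dC_lt75", "dC_lt50"]


def load_demographic_table(path: str | Path) -> pd.DataFrame:
    """Read a per-unit demographic table (regions use region == '-')."""
    df = pd.read_csv(path, comment="#")
    missing = set(DEMOGRAPHY_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if (df["N"] < 0).any() or (df["D_km"] < 0).any():
        raise DataError("N and D_km must be non-negative")
    bad = df[(df["dC_lt75"].abs() > 1) | (df["dC_lt50"].abs() > 1)]
    if len(bad):
        raise DataError(f"dC outside [-1, 1] for {list(bad['unit'])}")
    return df


def caribbean_rookery_table() -> pd.DataFrame:
    """The packaged Atlantic green turtle demographic table.

    Per-region and per-rookery adult female abundance N, minimum distance to
    the Lac Bay feeding ground D (km), annual growth rate r, reproductive
    output Nr, and temporal recruitment change dC for the <75 cm and <50 cm
    size classes.
    """
    from importlib.resources import files

    return load_demographic_table(files("stockshift.data") / "caribbean_rookeries.csv")
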