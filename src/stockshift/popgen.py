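"""Diversity indices, AMOVA-based phi-ST and Mantel tests on haplotype samples.

Genetic divergence between sample partitions is measured with the two-level
AMOVA fixation index phi-ST, which weights haplotype mismatches by an
inter-haplotype distance. The distance model is the plain count of pairwise
nucleotide differences (positions where either sequence carries an ambiguous
base are skipped), treated as the squared inter-individual distance in the
variance decomposition — the conventional choice for short mtDNA fragments
where per-site multiple hits are negligible. Significance comes from random
reassignment of individuals to groups of the original sizes; Mantel tests
correlate a genetic divergence matrix with any other labelled matrix
(here: years apart) under simultaneous row/column permutation.

Permutation p-values use the add-one rule p = (1 + #{perm >= obs}) / (B + 1)
and are reproducible bit-for-bit given a seed. Negative phi-ST estimates are
reported as computed, never clamped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, UndefinedStatisticError
from .haplotypes import UNAMBIGUOUS, HaplotypeCounts, HaplotypePanel

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class LabeledMatrix:
    """Square symmetric matrix with a zero diagonal and ordered labels.

    Base container for pairwise-statistic matrices; entries may be negative
    (phi-ST) or NaN (undefined cells, which consumers must mask).
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise DataError(
                f"matrix shape {values.shape} does not match {len(labels)} labels"
            )
        if len(set(labels)) != len(labels):
            raise DataError("matrix labels are not unique")
        finite = np.isfinite(values)
        sym = np.where(finite & finite.T, values, 0.0)
        if not np.allclose(sym, sym.T, atol=1e-9):
            raise DataError("matrix is not symmetric")
        if not np.allclose(np.diag(np.nan_to_num(values)), 0.0, atol=1e-9):
            raise DataError("matrix diagonal is not zero")
        object.__setattr__(self, "labels", labels)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledMatrix":
        df = pd.read_csv(path, index_col=0, comment="#")
        return cls(tuple(df.index.astype(str)), df.to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)


class DistanceMatrix(LabeledMatrix):
    """LabeledMatrix restricted to non-negative (true distance) entries."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.nanmin(self.values) < -1e-12:
            raise DataError("distance matrix has negative entries")


@dataclass(frozen=True)
class DivergenceResult:
    """phi-ST with its permutation p-value."""

    phi_st: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise DataError(f"p-value {self.p_value} outside (0, 1]")
        if self.n_permutations < 1:
            raise DataError("n_permutations must be >= 1")


@dataclass(frozen=True)
class MantelResult:
    """Matrix correlation r, its square, and the permutation p-value."""

    r: float
    r_squared: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if abs(self.r_squared - self.r**2) > 1e-9:
            raise DataError("r_squared inconsistent with r")


def pairwise_differences(panel: HaplotypePanel) -> DistanceMatrix:
    """Count nucleotide differences between every pair of panel haplotypes.

    Only positions where both sequences carry an unambiguous base (A/C/G/T)
    are compared; gaps and IUPAC ambiguity codes are skipped.
    """
    names = panel.names
    seqs = [panel.entries[n] for n in names]
    k = len(names)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            diffs = sum(
                1
                for a, b in zip(seqs[i], seqs[j])
                if a in UNAMBIGUOUS and b in UNAMBIGUOUS and a != b
            )
            d[i, j] = d[j, i] = diffs
    return DistanceMatrix(names, d)


def haplotype_diversity(counts: HaplotypeCounts) -> float:
    """Unbiased haplotype (gene) diversity h = n/(n-1) * (1 - sum p_i^2)."""
    n = counts.n
    if n < 2:
        raise DataError(f"haplotype diversity needs n >= 2, got n={n}")
    p = np.array(list(counts.counts.values()), dtype=float) / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def nucleotide_diversity(
    counts: HaplotypeCounts, distances: DistanceMatrix, seq_length: int
) -> float:
    """Per-site nucleotide diversity pi from haplotype frequencies and distances.

    pi = sum_i sum_j p_i p_j d_ij / L over all ordered haplotype pairs, i.e.
    the sample-frequency-weighted mean number of pairwise differences per
    site.
    """
    if seq_length <= 0:
        raise DataError("seq_length must be positive")
    missing = [h for h in counts.counts if h not in distances.labels]
    if missing:
        raise DataError(f"haplotypes missing from distance matrix: {missing}")
    idx = [distances.labels.index(h) for h in counts.counts]
    p = np.array(list(counts.counts.values()), dtype=float) / counts.n
    d = distances.values[np.ix_(idx, idx)]
    return float(p @ d @ p / seq_length)


def _align_counts(
    groups: Sequence[HaplotypeCounts], distances: LabeledMatrix
) -> np.ndarray:
    """Stack group counts as rows over the distance-matrix haplotype order."""
    out = np.zeros((len(groups), len(distances.labels)))
    index = {h: i for i, h in enumerate(distances.labels)}
    for g, counts in enumerate(groups):
        for h, c in counts.counts.items():
            if h not in index:
                raise DataError(f"haplotype {h!r} missing from distance matrix")
            out[g, index[h]] = c
    return out


def _phi_from_count_rows(rows: np.ndarray, d2: np.ndarray) -> float:
    """Two-level AMOVA phi-ST from per-group haplotype count vectors.

    ``d2`` holds squared inter-haplotype distances. Sums of squared
    deviations follow the standard quadratic-form identities:
    SSD(total) = c'Dc / 2N and SSD(within) = sum_g c_g'Dc_g / 2n_g.
    Returns NaN when the variance decomposition is degenerate (zero total
    variance or an exactly-zero denominator under permutation).
    """
    n_g = rows.sum(axis=1)
    n_tot = n_g.sum()
    G = rows.shape[0]
    total = rows.sum(axis=0)
    ssd_total = total @ d2 @ total / (2.0 * n_tot)
    ssd_within = sum(
        rows[g] @ d2 @ rows[g] / (2.0 * n_g[g]) for g in range(G) if n_g[g] > 0
    )
    if ssd_total < _EPS:
        return np.nan
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (n_tot - G)
    ms_among = ssd_among / (G - 1)
    n_prime = (n_tot - np.sum(n_g**2) / n_tot) / (G - 1)
    sigma_a = (ms_among - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    if abs(denom) < _EPS:
        return np.nan
    return float(sigma_a / denom)


def phi_st(
    group_a: HaplotypeCounts, group_b: HaplotypeCounts, distances: DistanceMatrix
) -> float:
    """AMOVA phi-ST between two sample partitions.

    phi-ST = sigma^2_among / (sigma^2_among + sigma^2_within) from the
    two-level variance decomposition of squared pairwise distances. Negative
    estimates (within-group variance exceeding total) are reported as
    computed.

    Raises
    ------
    UndefinedStatisticError
        When all individuals are genetically identical (zero total variance).
    """
    if group_a.n + group_b.n < 4:
        raise DataError("phi_st needs a combined sample of at least 4")
    rows = _align_counts([group_a, group_b], distances)
    phi = _phi_from_count_rows(rows, distances.values)
    if np.isnan(phi):
        raise UndefinedStatisticError(
            f"phi_st undefined for {group_a.label!r} vs {group_b.label!r}: no variation"
        )
    return phi


def phi_st_permutation_test(
    group_a: HaplotypeCounts,
    group_b: HaplotypeCounts,
    distances: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
) -> DivergenceResult:
    """Permutation test of phi-ST by random reassignment of individuals.

    Individuals from both partitions are pooled and reassigned uniformly at
    random to two groups of the original sizes; the p-value is the add-one
    upper tail p = (1 + #{phi_perm >= phi_obs}) / (n_perm + 1). Degenerate
    permutations (undefined phi) are counted as ties, which can only make
    the test conservative.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    observed = phi_st(group_a, group_b, distances)
    rows = _align_counts([group_a, group_b], distances)
    d2 = distances.values
    n_a = int(rows[0].sum())
    pooled = np.repeat(np.arange(d2.shape[0]), rows.sum(axis=0).astype(int))
    rng = np.random.default_rng(seed)
    n_hap = d2.shape[0]
    n_ge = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        ca = np.bincount(pooled[:n_a], minlength=n_hap).astype(float)
        cb = np.bincount(pooled[n_a:], minlength=n_hap).astype(float)
        phi_p = _phi_from_count_rows(np.vstack([ca, cb]), d2)
        if np.isnan(phi_p) or phi_p >= observed - _EPS:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return DivergenceResult(observed, p, n_perm)


def pairwise_phi_matrix(
    partitions: Sequence[HaplotypeCounts], distances: DistanceMatrix
) -> LabeledMatrix:
    """Matrix of pairwise phi-ST values over three or more partitions.

    Cells where phi-ST is undefined (no variation in the pooled pair) are
    flagged as NaN and logged; consumers such as the Mantel test exclude
    them pairwise.
    """
    if len(partitions) < 3:
        raise DataError("pairwise_phi_matrix needs at least 3 partitions")
    for p in partitions:
        if p.n == 0:
            raise DataError(f"partition {p.label!r} is empty")
    labels = tuple(p.label for p in partitions)
    k = len(partitions)
    out = np.zeros((k, k))
    n_undefined = 0
    for i, j in itertools.combinations(range(k), 2):
        try:
            val = phi_st(partitions[i], partitions[j], distances)
        except UndefinedStatisticError:
            val = np.nan
            n_undefined += 1
        out[i, j] = out[j, i] = val
    if n_undefined:
        logger.warning("pairwise_phi_matrix: %d undefined cell(s) flagged NaN", n_undefined)
    return LabeledMatrix(labels, out)


def year_distance_matrix(labels_to_years: dict[str, int | float]) -> DistanceMatrix:
    """Absolute time differences (years) between labelled partitions."""
    labels = tuple(labels_to_years)
    years = np.array([labels_to_years[l] for l in labels], dtype=float)
    return DistanceMatrix(labels, np.abs(years[:, None] - years[None, :]))


def linearize_phi(mat: LabeledMatrix) -> LabeledMatrix:
    """Slatkin-linearized divergence phi/(1-phi); optional Mantel input."""
    vals = mat.values.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = vals / (1.0 - vals)
    np.fill_diagonal(vals, 0.0)
    return LabeledMatrix(mat.labels, vals)


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _masked_pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        return np.nan
    sx, sy = x.std(), y.std()
    if sx < _EPS or sy < _EPS:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(
    mat_a: LabeledMatrix,
    mat_b: LabeledMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
) -> MantelResult:
    """Mantel test of association between two labelled matrices.

    r is the Pearson correlation over the n(n-1)/2 upper-triangle pairs;
    significance comes from simultaneous row/column permutations of
    ``mat_a``, with the one-sided (greater) add-one p-value. NaN cells in
    either matrix are excluded pairwise, with a logged count.

    Raises
    ------
    UndefinedStatisticError
        If either upper triangle has zero variance among the usable pairs.
    """
    if mat_a.labels != mat_b.labels:
        raise DataError("mantel_test: matrices must share labels and order")
    n = len(mat_a.labels)
    if n < 3:
        raise DataError("mantel_test needs at least 3 items")
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    ua, ub = _upper(mat_a.values), _upper(mat_b.values)
    n_masked = int(np.sum(~(np.isfinite(ua) & np.isfinite(ub))))
    if n_masked:
        logger.warning("mantel_test: excluding %d undefined pair(s)", n_masked)
    r_obs = _masked_pearson(ua, ub)
    if np.isnan(r_obs):
        raise UndefinedStatisticError("mantel_test: zero variance or too few usable pairs")
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        a_perm = mat_a.values[np.ix_(perm, perm)]
        r_p = _masked_pearson(_upper(a_perm), ub)
        if np.isnan(r_p) or r_p >= r_obs - _EPS:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return MantelResult(r_obs, r_obs**2, p, n_perm)
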