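"""Aggregation readouts: volume-weighted ECDF, mean size, bootstrap CIs.

An aggregation experiment yields one size ``N_i`` (particles per aggregate,
``N_i >= 1``; singlets count as aggregates of size 1) for every aggregate in
the imaged volume.  Because a large aggregate holds many more particles than
a singlet, distributions are volume-weighted: each aggregate contributes in
proportion to the number of particles it contains.

* volume-weighted ECDF:  F̂(x) = Σ_{N_i <= x} N_i / Σ N_i
* volume-weighted average size:  ⟨N⟩ = Σ N_i² / Σ N_i
* uncertainty: percentile intervals over bootstrap resamples of the
  aggregates (10,000 replicates by default),
* dilution series: the "aggregation threshold" is the smallest dilution
  factor whose 95% CI still separates from the buffer-only control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AggregateTable",
    "VolumeWeightedECDF",
    "BootstrapResult",
    "volume_weighted_ecdf",
    "volume_weighted_mean",
    "bootstrap_mean_ci",
    "aggregation_threshold",
]


@dataclass
class AggregateTable:
    """Per-aggregate sizes for one sample at one dilution.

    ``sizes`` are particles per aggregate (reals >= 1; fractional values are
    allowed when segmentation is run without integer rounding).  A table may
    be empty (a background-only stack); the statistics below then raise.
    """

    sizes: np.ndarray
    sample_label: str = ""
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float).ravel()
        if self.sizes.size and self.sizes.min() < 1.0:
            raise ValueError("all aggregate sizes must be >= 1 particle")
        if not 0 < self.dilution_factor <= 1:
            raise ValueError(
                f"dilution_factor must lie in (0, 1], got {self.dilution_factor}"
            )

    def __len__(self) -> int:
        return int(self.sizes.size)


class VolumeWeightedECDF:
    """Right-continuous step function N -> cumulative volume fraction."""

    def __init__(self, sizes: np.ndarray):
        sizes = np.asarray(sizes, dtype=float)
        if sizes.size == 0:
            raise ValueError("cannot build an ECDF from an empty table")
        order = np.argsort(sizes, kind="stable")
        s = sizes[order]
        # collapse ties into atoms
        atoms, idx = np.unique(s, return_index=True)
        mass = np.add.reduceat(s, idx)
        self.atoms = atoms
        cum = np.cumsum(mass)
        self.cumulative = cum / cum[-1]  # exact 1.0 at the top atom

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.atoms, x, side="right")
        padded = np.concatenate(([0.0], self.cumulative))
        out = padded[idx]
        return out if out.ndim else float(out)

    @property
    def steps(self) -> tuple[np.ndarray, np.ndarray]:
        """(atom locations, cumulative volume fraction at each atom)."""
        return self.atoms, self.cumulative


def volume_weighted_ecdf(table: AggregateTable) -> VolumeWeightedECDF:
    """The volume-weighted ECDF of a table; raises on an empty table."""
    return VolumeWeightedECDF(table.sizes)


def volume_weighted_mean(table: AggregateTable) -> float:
    """⟨N⟩ = Σ N_i² / Σ N_i, in particles per aggregate."""
    if len(table) == 0:
        raise ValueError("cannot compute the volume-weighted mean of an empty table")
    s = table.sizes
    return float((s * s).sum() / s.sum())


@dataclass
class BootstrapResult:
    """Percentiles of ⟨N⟩ over bootstrap resamples of one table."""

    point_estimate: float
    ci_low: float          # 2.5th percentile
    ci_high: float         # 97.5th percentile
    q25: float
    median: float
    q75: float
    n_replicates: int
    seed: int
    sample_label: str = ""
    dilution_factor: float = 1.0
    replicate_means: np.ndarray | None = field(default=None, repr=False)


def bootstrap_mean_ci(table: AggregateTable, n_replicates: int = 10_000,
                      seed: int = 0, keep_replicates: bool = False) -> BootstrapResult:
    """Empirical-bootstrap percentile CI for the volume-weighted mean size.

    Each replicate resamples ``len(table)`` aggregates with replacement from
    the observed sizes and recomputes ⟨N⟩; the interval is the (2.5, 97.5)
    percentile band of the replicate means.  Deterministic for a given seed.
    """
    n = len(table)
    if n < 2:
        raise ValueError("bootstrap needs a table with at least 2 aggregates")
    if n_replicates < 100:
        warnings.warn(
            f"n_replicates={n_replicates} is very small for percentile intervals",
            stacklevel=2,
        )
    if n < 300:
        warnings.warn(
            f"table has {n} aggregates; at least ~300 are advisable for stable CIs",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    sizes = table.sizes
    means = np.empty(n_replicates)
    # chunk the replicate x sample index matrix to bound memory
    chunk = max(1, int(5_000_000 // max(n, 1)))
    for start in range(0, n_replicates, chunk):
        stop = min(start + chunk, n_replicates)
        idx = rng.integers(0, n, size=(stop - start, n))
        s = sizes[idx]
        means[start:stop] = (s * s).sum(axis=1) / s.sum(axis=1)
    lo, q25, med, q75, hi = np.percentile(means, [2.5, 25, 50, 75, 97.5])
    return BootstrapResult(
        point_estimate=volume_weighted_mean(table),
        ci_low=float(lo), ci_high=float(hi),
        q25=float(q25), median=float(med), q75=float(q75),
        n_replicates=n_replicates, seed=seed,
        sample_label=table.sample_label, dilution_factor=table.dilution_factor,
        replicate_means=means if keep_replicates else None,
    )


def aggregation_threshold(series, control: AggregateTable,
                          n_replicates: int = 10_000, seed: int = 0,
                          criterion=None):
    """Dilution factor at which aggregation is last distinguishable from control.

    ``series`` is an iterable of ``(dilution_factor, AggregateTable)``.  By
    default a sample "shows aggregation" when the lower bound of its 95%
    bootstrap CI on ⟨N⟩ exceeds the upper bound of the control's CI; the
    criterion is configurable as ``criterion(sample_result, control_result)``.
    Returns the smallest such dilution factor (the most dilute sample still
    distinguishable from the control), or None if no sample separates.
    """
    series = list(series)
    if not series:
        raise ValueError("series must contain at least one (dilution, table) pair")
    if criterion is None:
        criterion = lambda s, c: s.ci_low > c.ci_high  # noqa: E731
    seeds = np.random.SeedSequence(seed).generate_state(len(series) + 1) % (2**31)
    control_res = bootstrap_mean_ci(control, n_replicates, seed=int(seeds[0]))
    separable = []
    for (dilution, table), s in zip(series, seeds[1:]):
        res = bootstrap_mean_ci(table, n_replicates, seed=int(s))
        if criterion(res, control_res):
            separable.append(dilution)
    return min(separable) if separable else None
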