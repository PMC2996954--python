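"""Copy-number-variable region detection from probe-level CN matrices.

A probe x subject matrix of real-valued copy-number estimates (diploid
baseline 2) is scanned for probes whose across-subject dispersion exceeds a
cutoff: a run of consecutive high-dispersion probes is a candidate CNVR.
The default dispersion cutoff is a per-probe standard deviation of 0.25.
The module also selects copy-number-invariant windows (usable as
normalization references) and median-smooths individual probe profiles into
integer copy states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CNMatrix",
    "CNVRegion",
    "InvariantRegion",
    "per_probe_dispersion",
    "call_cnv_regions",
    "select_invariant_region",
    "smooth_individual_states",
]


@dataclass
class CNMatrix:
    """Probe-level copy numbers.

    probes: DataFrame with columns chrom, position (1-based bp, strictly
    increasing within a chromosome), probe_id — aligned with the rows of
    ``values`` (probes x subjects).
    """
    probes: pd.DataFrame
    subjects: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probes), len(self.subjects)):
            raise ValueError("values shape does not match probes x subjects")
        for _, grp in self.probes.groupby("chrom", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("probe positions must be strictly increasing")
        if np.isnan(self.values).any():
            raise ValueError("CN matrix contains missing cells")


@dataclass
class CNVRegion:
    chrom: str
    start: int            # bp, 1-based inclusive
    end: int              # bp, 1-based inclusive
    probe_count: int
    mean_probe_std: float
    max_probe_std: float
    first_probe: int      # 0-based probe index into the matrix
    last_probe: int


@dataclass
class InvariantRegion:
    chrom: str
    start: int
    end: int
    probe_count: int
    mean_probe_std: float
    first_probe: int
    last_probe: int


def per_probe_dispersion(matrix: CNMatrix) -> np.ndarray:
    """Sample standard deviation (n-1 denominator) of each probe row."""
    if len(matrix.subjects) < 2:
        raise ValueError("dispersion requires at least 2 subjects")
    return matrix.values.std(axis=1, ddof=1)


def call_cnv_regions(std_vector: np.ndarray, probes: pd.DataFrame,
                     cutoff: float = 0.25, min_probes: int = 3,
                     merge_gap: int = 0) -> list[CNVRegion]:
    """Maximal runs of consecutive probes with dispersion above ``cutoff``.

    Runs separated by at most ``merge_gap`` sub-threshold probes are merged
    (the bridged probes count toward the region).  Runs spanning fewer than
    ``min_probes`` probes are discarded.  Region bounds are the first and
    last probe positions of the run.  Chromosome boundaries are never
    crossed.
    """
    std_vector = np.asarray(std_vector, dtype=float)
    if len(std_vector) != len(probes):
        raise ValueError("std_vector not aligned with probes")
    regions: list[CNVRegion] = []
    chrom_codes = probes["chrom"].to_numpy()
    positions = probes["position"].to_numpy()
    hot = np.flatnonzero(std_vector > cutoff)
    if hot.size == 0:
        return regions
    # group super-threshold probes: same chrom, index gap - 1 <= merge_gap
    run_start = hot[0]
    prev = hot[0]
    groups: list[tuple[int, int]] = []
    for idx in hot[1:]:
        if idx - prev - 1 <= merge_gap and chrom_codes[idx] == chrom_codes[prev]:
            prev = idx
        else:
            groups.append((run_start, prev))
            run_start = prev = idx
    groups.append((run_start, prev))
    for first, last in groups:
        count = last - first + 1
        if count < min_probes:
            continue
        span = std_vector[first:last + 1]
        regions.append(CNVRegion(
            chrom=str(chrom_codes[first]),
            start=int(positions[first]),
            end=int(positions[last]),
            probe_count=count,
            mean_probe_std=float(span.mean()),
            max_probe_std=float(span.max()),
            first_probe=int(first),
            last_probe=int(last),
        ))
    return regions


def select_invariant_region(matrix: CNMatrix, window_probes: int) -> tuple[InvariantRegion, float]:
    """Sliding window of ``window_probes`` probes minimizing mean per-probe
    STD — the analogue of selecting a copy-number-invariant reference locus.
    Ties break to the leftmost window.  Returns (region, mean STD)."""
    stds = per_probe_dispersion(matrix)
    n = len(stds)
    if window_probes > n or window_probes < 1:
        raise ValueError("window_probes must be in [1, probe count]")
    window_means = np.convolve(stds, np.ones(window_probes) / window_probes,
                               mode="valid")
    best = int(np.argmin(window_means))  # argmin takes the first minimum
    first, last = best, best + window_probes - 1
    region = InvariantRegion(
        chrom=str(matrix.probes["chrom"].iloc[first]),
        start=int(matrix.probes["position"].iloc[first]),
        end=int(matrix.probes["position"].iloc[last]),
        probe_count=window_probes,
        mean_probe_std=float(window_means[best]),
        first_probe=first,
        last_probe=last,
    )
    return region, float(window_means[best])


def smooth_individual_states(profile: np.ndarray, window: int = 5) -> np.ndarray:
    """Running-median smoothing of one subject's probe profile, then rounding
    to integer copy states.

    The window is centred and truncated at the edges.  Exact .5 ties round
    away from the diploid baseline 2 (1.5 -> 1, 2.5 -> 3); states are
    clamped at 0.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(profile, dtype=float)
    half = window // 2
    n = len(x)
    smoothed = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        smoothed[i] = np.median(x[lo:hi])
    states = np.floor(smoothed + 0.5)               # .5 rounds up by default
    ties = np.isclose(smoothed - np.floor(smoothed), 0.5)
    below = ties & (smoothed < 2.0)                 # ...but down when below 2
    states[below] = np.floor(smoothed[below])
    return np.maximum(states, 0).astype(int)
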