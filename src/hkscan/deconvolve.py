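"""Gaussian deconvolution of Sort-seq bin counts.

Cells carrying a variant library are sorted into fluorescence bins whose
gates are evenly spaced on the log10(GFP) axis, and each bin is deep
sequenced.  The fraction of a bin's reads belonging to a variant, scaled
by the fraction of all sorted cells that landed in that bin, estimates
the fraction of the whole population that is "this variant, in this
bin".  Across bins that quantity traces out the variant's fluorescence
distribution, which is close to Gaussian in log10 units; a weighted
least-squares Gaussian fit then yields the variant's peak fluorescence
mu (log10 GFP), one value per sorting condition (+signal "on" and
-signal "off").  Fold induction compares the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BinCountTable",
    "FrequencyProfile",
    "GaussianFit",
    "bin_centers",
    "compute_bin_frequencies",
    "aggregate_replicates",
    "fit_gaussian_profile",
    "fold_induction",
    "deconvolve",
]

SD_FLOOR = 1e-6  # avoids infinite weights on zero-SD bins
MIN_NONZERO_BINS = 4
DEFAULT_MIN_READS = 20  # mean reads across bins below this -> low-coverage flag


@dataclass
class BinCountTable:
    """Read counts per variant per sort bin, plus sorted-cell totals.

    Each sample key is a ``(reporter, condition, replicate)`` triple with
    condition in ``{"on", "off"}``.  ``reads[key]`` is a DataFrame indexed
    by variant key (variant label, ``"WT"`` or ``"nonsense"``) with one
    integer column per bin (1-based bin index).  ``cells_sorted[key]`` has
    one entry per bin and ``bin_edges[key]`` has ``n_bins + 1`` strictly
    increasing log10-fluorescence gate boundaries; the outermost bins are
    half-open (cells beyond the outer edges fall into them).
    """

    reads: dict[tuple[str, str, int], pd.DataFrame]
    cells_sorted: dict[tuple[str, str, int], np.ndarray]
    bin_edges: dict[tuple[str, str, int], np.ndarray]

    def __post_init__(self) -> None:
        for key, df in self.reads.items():
            if key not in self.cells_sorted or key not in self.bin_edges:
                raise ValueError(f"sample {key}: missing cell counts or gate edges")
            edges = np.asarray(self.bin_edges[key], dtype=float)
            cells = np.asarray(self.cells_sorted[key], dtype=float)
            self.bin_edges[key] = edges
            self.cells_sorted[key] = cells
            if (df.to_numpy() < 0).any():
                raise ValueError(f"sample {key}: negative read counts")
            if (cells < 0).any():
                raise ValueError(f"sample {key}: negative cell counts")
            if np.any(np.diff(edges) <= 0):
                raise ValueError(f"sample {key}: gate edges not strictly increasing")
            if len(edges) != df.shape[1] + 1:
                raise ValueError(
                    f"sample {key}: {len(edges)} edges inconsistent with {df.shape[1]} bins"
                )
            if len(cells) != df.shape[1]:
                raise ValueError(f"sample {key}: cell counts do not cover every bin")

    @property
    def keys(self) -> list[tuple[str, str, int]]:
        return sorted(self.reads)

    @property
    def reporters(self) -> list[str]:
        return sorted({k[0] for k in self.reads})

    @property
    def conditions(self) -> list[str]:
        return sorted({k[1] for k in self.reads})

    def replicates(self, reporter: str, condition: str) -> list[int]:
        return sorted(k[2] for k in self.reads if k[:2] == (reporter, condition))

    @property
    def n_bins(self) -> int:
        return next(iter(self.reads.values())).shape[1]

    @property
    def variant_keys(self) -> list[str]:
        keys: set[str] = set()
        for df in self.reads.values():
            keys.update(df.index)
        return sorted(keys)


@dataclass
class FrequencyProfile:
    """Replicate-averaged per-bin frequencies for every variant key.

    ``mean_freq`` and ``sd_freq`` are DataFrames (variant key x bin);
    frequencies are fractions of the total sorted population, so a
    variant's profile integrates to roughly its library abundance.
    """

    mean_freq: pd.DataFrame
    sd_freq: pd.DataFrame
    bin_centers: np.ndarray
    qc_flags: set[str] = field(default_factory=set)


@dataclass
class GaussianFit:
    """A fitted log10-fluorescence peak: A * exp(-(x - mu)^2 / (2 sigma^2))."""

    mu: float
    sigma: float
    amplitude: float
    converged: bool
    residual_norm: float = np.nan
    qc_flags: frozenset[str] = frozenset()


def bin_centers(edges: np.ndarray) -> np.ndarray:
    """Bin centers in log10 units from gate edges.

    Interior bins use the midpoint of their two edges.  The outermost
    bins are half-open, so their nominal centers are taken at the inner
    edge minus/plus half the adjacent bin's width.
    """
    edges = np.asarray(edges, dtype=float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    if len(centers) >= 3:
        centers[0] = edges[1] - (edges[2] - edges[1]) / 2.0
        centers[-1] = edges[-2] + (edges[-2] - edges[-3]) / 2.0
    return centers


def compute_bin_frequencies(
    table: BinCountTable, reporter: str, condition: str
) -> dict[int, pd.DataFrame]:
    """Per-replicate frequency profiles for one reporter/condition.

    For variant v in bin b::

        freq(v, b) = reads(v, b) / reads_total(b) * cells_sorted(b) / cells_total

    with ``cells_total`` the sum of sorted cells over bins of that
    replicate.  An empty bin (no reads or no cells) contributes zero
    frequency for every variant.  Summed over variants, each bin's
    frequencies recover ``cells_sorted(b) / cells_total``.
    """
    out: dict[int, pd.DataFrame] = {}
    for rep in table.replicates(reporter, condition):
        key = (reporter, condition, rep)
        reads = table.reads[key]
        cells = table.cells_sorted[key]
        cells_total = cells.sum()
        if cells_total <= 0:
            raise ValueError(f"sample {key}: no sorted cells")
        reads_total = reads.to_numpy().sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(reads_total > 0, (cells / cells_total) / reads_total, 0.0)
        out[rep] = reads * scale
    if not out:
        raise KeyError(f"no replicates for ({reporter!r}, {condition!r})")
    return out


def aggregate_replicates(
    profiles: dict[int, pd.DataFrame],
    centers: np.ndarray,
    sd_floor: float = SD_FLOOR,
) -> FrequencyProfile:
    """Mean and sample SD of per-bin frequencies across replicates.

    With a single replicate the mean is the profile itself and the SD is
    set to ``sd_floor`` with a QC flag, so downstream weights stay finite.
    """
    frames = [profiles[r] for r in sorted(profiles)]
    stacked = np.stack([f.to_numpy(dtype=float) for f in frames])
    mean = pd.DataFrame(stacked.mean(axis=0), index=frames[0].index, columns=frames[0].columns)
    flags: set[str] = set()
    if len(frames) >= 2:
        sd = pd.DataFrame(
            stacked.std(axis=0, ddof=1), index=frames[0].index, columns=frames[0].columns
        )
    else:
        sd = pd.DataFrame(sd_floor, index=frames[0].index, columns=frames[0].columns)
        flags.add("single_replicate")
    return FrequencyProfile(mean_freq=mean, sd_freq=sd, bin_centers=np.asarray(centers, float), qc_flags=flags)


def _gaussian(x: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian_profile(
    mean_freq: np.ndarray,
    sd_freq: np.ndarray,
    centers: np.ndarray,
    sd_floor: float = SD_FLOOR,
    span_pad: float = 1.0,
) -> GaussianFit:
    """Weighted nonlinear least-squares Gaussian fit to one bin profile.

    Weights are 1/max(sd, sd_floor).  Initialization: mu0 = frequency-
    weighted mean of bin centers, sigma0 = weighted SD floored at half a
    bin width, A0 = max frequency.  Bounds: mu within the gate span
    extended by ``span_pad`` log10 units, sigma in [0.05, 5].  Fewer than
    four bins with nonzero mean frequency, or optimizer failure, yields a
    non-converged fit (never an exception).
    """
    y = np.asarray(mean_freq, dtype=float)
    sd = np.maximum(np.asarray(sd_freq, dtype=float), sd_floor)
    x = np.asarray(centers, dtype=float)

    nonzero = int((y > 0).sum())
    if nonzero < MIN_NONZERO_BINS:
        return GaussianFit(np.nan, np.nan, np.nan, False, qc_flags=frozenset({"too_few_bins"}))

    w = y / y.sum()
    mu0 = float(np.dot(w, x))
    bin_w = float(np.median(np.diff(x)))
    sigma0 = float(np.sqrt(np.dot(w, (x - mu0) ** 2)))
    sigma0 = max(sigma0, bin_w / 2.0)
    a0 = float(y.max())
    lo = [0.0, x.min() - span_pad, 0.05]
    hi = [np.inf, x.max() + span_pad, 5.0]
    p0 = [a0, float(np.clip(mu0, lo[1], hi[1])), float(np.clip(sigma0, lo[2], hi[2]))]

    try:
        popt, _ = curve_fit(
            _gaussian,
            x,
            y,
            p0=p0,
            sigma=sd,
            absolute_sigma=True,
            bounds=(lo, hi),
            ftol=1e-8,
            xtol=1e-8,
            gtol=1e-8,
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return GaussianFit(np.nan, np.nan, np.nan, False, qc_flags=frozenset({"fit_failed"}))

    amplitude, mu, sigma = (float(v) for v in popt)
    resid = (y - _gaussian(x, amplitude, mu, sigma)) / sd
    flags: set[str] = set()
    if not (x.min() - span_pad < mu < x.max() + span_pad) or sigma <= 0:
        flags.add("boundary")
    return GaussianFit(
        mu=mu,
        sigma=sigma,
        amplitude=amplitude,
        converged=True,
        residual_norm=float(np.linalg.norm(resid)),
        qc_flags=frozenset(flags),
    )


def fold_induction(fit_on: GaussianFit, fit_off: GaussianFit, mode: str = "linear") -> float:
    """Fold induction between the +signal and -signal peaks.

    ``mode="linear"`` (default) returns the linear-units fluorescence
    ratio ``10**(mu_on - mu_off)``; ``mode="literal"`` returns the raw
    ratio of the log10-scale means ``mu_on / mu_off``.  Non-converged
    inputs yield NaN.
    """
    if mode not in ("linear", "literal"):
        raise ValueError(f"unknown fold-induction mode {mode!r}")
    if not (fit_on.converged and fit_off.converged):
        return np.nan
    if mode == "linear":
        return float(10.0 ** (fit_on.mu - fit_off.mu))
    return float(fit_on.mu / fit_off.mu)


def deconvolve(
    table: BinCountTable,
    min_reads: float = DEFAULT_MIN_READS,
    fi_mode: str = "linear",
    sd_floor: float = SD_FLOOR,
) -> pd.DataFrame:
    """Full deconvolution of a bin-count table to per-variant measurements.

    Returns a tidy DataFrame with one row per (variant key, reporter) and
    columns ``mu_on, sigma_on, converged_on, mu_off, sigma_off,
    converged_off, fold_induction, mean_reads_on, mean_reads_off,
    qc_flags``.  Variants whose mean read total across bins (averaged
    over replicates) falls below ``min_reads`` in a condition are flagged
    ``low_coverage`` and their classification downstream is suppressed.
    """
    rows = []
    for reporter in table.reporters:
        per_cond: dict[str, pd.DataFrame] = {}
        for condition in table.conditions:
            reps = table.replicates(reporter, condition)
            if not reps:
                continue
            profiles = compute_bin_frequencies(table, reporter, condition)
            center_stack = np.stack(
                [bin_centers(table.bin_edges[(reporter, condition, r)]) for r in reps]
            )
            prof = aggregate_replicates(profiles, center_stack.mean(axis=0), sd_floor=sd_floor)
            read_stack = np.stack(
                [table.reads[(reporter, condition, r)].to_numpy(dtype=float) for r in reps]
            )
            mean_reads = pd.Series(
                read_stack.sum(axis=2).mean(axis=0), index=prof.mean_freq.index
            )
            recs = {}
            y_all = prof.mean_freq.to_numpy(dtype=float)
            sd_all = prof.sd_freq.to_numpy(dtype=float)
            for i, vk in enumerate(prof.mean_freq.index):
                fit = fit_gaussian_profile(y_all[i], sd_all[i], prof.bin_centers, sd_floor=sd_floor)
                flags = set(fit.qc_flags) | prof.qc_flags
                if mean_reads[vk] < min_reads:
                    flags.add("low_coverage")
                recs[vk] = (fit, mean_reads[vk], flags)
            per_cond[condition] = recs
        if not per_cond:
            continue
        all_keys = sorted(set().union(*(set(r) for r in per_cond.values())))
        for vk in all_keys:
            fit_on, reads_on, flags_on = per_cond.get("on", {}).get(
                vk, (GaussianFit(np.nan, np.nan, np.nan, False), np.nan, {"missing"})
            )
            fit_off, reads_off, flags_off = per_cond.get("off", {}).get(
                vk, (GaussianFit(np.nan, np.nan, np.nan, False), np.nan, {"missing"})
            )
            rows.append(
                {
                    "variant": vk,
                    "reporter": reporter,
                    "mu_on": fit_on.mu,
                    "sigma_on": fit_on.sigma,
                    "converged_on": fit_on.converged,
                    "mu_off": fit_off.mu,
                    "sigma_off": fit_off.sigma,
                    "converged_off": fit_off.converged,
                    "fold_induction": fold_induction(fit_on, fit_off, mode=fi_mode),
                    "mean_reads_on": reads_on,
                    "mean_reads_off": reads_off,
                    "qc_flags": ";".join(sorted(flags_on | flags_off)),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["fi_mode"] = fi_mode
    return df
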