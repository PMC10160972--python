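"""Wild-type-relative activity and cross-talk classification.

Peak fluorescence values from the deconvolution stage are compared
against wild type in log10 units.  Cross-talk toward a noncognate
response regulator is the +signal increase over wild type, normalized
by any increase toward the cognate regulator (which may reflect
nonspecific effects of a substitution on expression level or overall
kinase activity rather than rewired specificity).  Variants are
classified at fold-change thresholds (3-, 5-, 10-fold by default) and
summarized as overlap sets and position-by-residue matrices for
heatmaps and logos.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .library import AA_ALPHABET, DomainRegion, Variant

DEFAULT_THRESHOLDS = (3.0, 5.0, 10.0)
COGNATE_REPORTER = "OmpR"


def _mu(measurements: pd.DataFrame, variant: str, reporter: str, condition: str) -> float:
    sel = measurements[
        (measurements["variant"] == variant) & (measurements["reporter"] == reporter)
    ]
    if sel.empty:
        raise KeyError(f"no measurement for {variant!r} / {reporter!r}")
    row = sel.iloc[0]
    if not row[f"converged_{condition}"]:
        return np.nan
    return float(row[f"mu_{condition}"])


def relative_fluorescence(
    measurements: pd.DataFrame, reporter: str, condition: str = "on"
) -> pd.Series:
    """Per-variant log10 fluorescence change vs wild type.

    Returns ``mu_variant - mu_WT`` for the given reporter/condition,
    indexed by variant label (the ``"WT"`` row itself maps to 0).  NaN
    where either fit failed to converge.
    """
    sub = measurements[measurements["reporter"] == reporter]
    if "WT" not in set(sub["variant"]):
        raise KeyError(f"wild-type measurement missing for reporter {reporter!r}")
    mu = sub.set_index("variant")[f"mu_{condition}"].astype(float)
    conv = sub.set_index("variant")[f"converged_{condition}"].astype(bool)
    mu = mu.where(conv)
    delta = mu - mu["WT"]
    delta.name = f"delta_log10_{reporter}_{condition}"
    return delta


def crosstalk_scores(
    measurements: pd.DataFrame,
    noncognate_reporter: str,
    cognate_reporter: str = COGNATE_REPORTER,
    norm_mode: str = "clip",
    min_reads: Optional[float] = None,
) -> pd.Series:
    """Cognate-normalized cross-talk score, log10 units.

    ``score = delta_X - max(0, delta_cognate)`` in ``"clip"`` mode
    (only cognate *increases* are subtracted, so a variant is not
    credited with cross-talk merely for losing cognate activity), or
    ``delta_X - delta_cognate`` in ``"raw"`` mode.  Deltas are +signal
    log10 changes vs wild type.  NaN where any required fit failed or
    (when ``min_reads`` is given) where the variant is low-coverage.
    """
    if norm_mode not in ("clip", "raw"):
        raise ValueError(f"unknown normalization mode {norm_mode!r}")
    delta_x = relative_fluorescence(measurements, noncognate_reporter, "on")
    delta_c = relative_fluorescence(measurements, cognate_reporter, "on")
    delta_c = delta_c.reindex(delta_x.index)
    if norm_mode == "clip":
        score = delta_x - delta_c.clip(lower=0.0)
    else:
        score = delta_x - delta_c
    if min_reads is not None:
        sub = measurements[measurements["reporter"] == noncognate_reporter]
        low = sub.set_index("variant")["mean_reads_on"].astype(float) < min_reads
        score = score.mask(low.reindex(score.index, fill_value=False))
    score = score.drop(index="WT", errors="ignore")
    score.name = f"crosstalk_score_{noncognate_reporter}"
    return score


def classify_crosstalk(
    scores: pd.Series, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Inclusive threshold calls: ``score >= log10(threshold)``.

    One boolean column per fold threshold.  NaN scores are never
    called.  Calls are monotone in the threshold by construction.
    """
    calls = {}
    for t in thresholds:
        if t <= 1:
            raise ValueError("thresholds must exceed 1-fold")
        calls[t] = scores >= np.log10(t)
    return pd.DataFrame(calls, index=scores.index)


def classify_and_overlap(
    calls_r1: pd.Series, calls_r2: pd.Series, threshold: Optional[float] = None
) -> tuple[int, int, int]:
    """Partition counts (only R1, only R2, both) of cross-talk calls.

    Accepts boolean call Series over the same variant universe (or
    score Series together with ``threshold``, applied inclusively).
    """
    if threshold is not None:
        calls_r1 = calls_r1 >= np.log10(threshold)
        calls_r2 = calls_r2 >= np.log10(threshold)
    calls_r1, calls_r2 = calls_r1.align(calls_r2, fill_value=False)
    calls_r1 = calls_r1.fillna(False).astype(bool)
    calls_r2 = calls_r2.fillna(False).astype(bool)
    both = int((calls_r1 & calls_r2).sum())
    return int(calls_r1.sum()) - both, int(calls_r2.sum()) - both, both


@dataclass
class PositionProfile:
    """All 20 residue values at one position, ranked for logo rendering."""

    position: int
    wt_aa: str
    values: pd.Series  # index: the 20 amino acids
    ranked_aas: list[str]  # descending value, ties alphabetical


def build_position_profiles(
    values: pd.Series, region: DomainRegion, fill_value: float = np.nan
) -> tuple[pd.DataFrame, list[PositionProfile]]:
    """Arrange per-variant values as a 20 x L matrix plus ranked profiles.

    ``values`` is indexed by variant label.  Rows are the 20 amino acids
    in fixed alphabetical order, columns the region's positions;
    wild-type cells hold 0 (a variant equal to wild type by definition).
    Missing variants are filled with ``fill_value`` and reported in the
    matrix attrs under ``"missing"``.
    """
    matrix = pd.DataFrame(
        fill_value, index=pd.Index(list(AA_ALPHABET), name="aa"),
        columns=pd.Index(list(region.positions), name="position"), dtype=float,
    )
    missing = []
    for position in region.positions:
        wt = region.aa_at(position)
        matrix.loc[wt, position] = 0.0
        for mut in AA_ALPHABET:
            if mut == wt:
                continue
            label = f"{wt}{position}{mut}"
            if label in values.index:
                matrix.loc[mut, position] = float(values[label])
            else:
                missing.append(label)
    matrix.attrs["missing"] = missing

    profiles = []
    for position in region.positions:
        col = matrix[position]
        order = sorted(
            AA_ALPHABET, key=lambda a: (-(col[a] if np.isfinite(col[a]) else -np.inf), a)
        )
        profiles.append(
            PositionProfile(
                position=position,
                wt_aa=region.aa_at(position),
                values=col.copy(),
                ranked_aas=order,
            )
        )
    return matrix, profiles


def cognate_within_fold_fraction(
    measurements: pd.DataFrame,
    fold: float = 5.0,
    reporter: str = COGNATE_REPORTER,
    condition: str = "on",
) -> float:
    """Fraction of variants whose cognate output is within ``fold`` of wild type.

    Computed over variants with a converged fit, as
    ``|mu - mu_WT| <= log10(fold)``; the quantity behind "most
    substitutions retain near-wild-type activity".
    """
    delta = relative_fluorescence(measurements, reporter, condition).drop(
        index="WT", errors="ignore"
    )
    delta = delta.dropna()
    if delta.empty:
        raise ValueError("no converged variant measurements")
    return float((delta.abs() <= np.log10(fold)).mean())


def reduced_fold_induction_fraction(
    measurements: pd.DataFrame, reporter: str = COGNATE_REPORTER
) -> float:
    """Fraction of variants with fold induction below wild type's.

    Strict comparison, no margin: ``FI(variant) < FI(WT)``, over
    variants whose on and off fits both converged.
    """
    sub = measurements[measurements["reporter"] == reporter].set_index("variant")
    fi = sub["fold_induction"].astype(float)
    if "WT" not in fi.index or not np.isfinite(fi["WT"]):
        raise KeyError(f"wild-type fold induction unavailable for {reporter!r}")
    wt = fi["WT"]
    fi = fi.drop(index="WT").dropna()
    if fi.empty:
        raise ValueError("no converged variant fold-induction values")
    return float((fi < wt).mean())
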