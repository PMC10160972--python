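"""Ortholog-constraint statistics for cross-talk residues.

If single substitutions that create cross-talk between paralogous
signaling systems are selected against, those residues should appear
less often at the equivalent positions in orthologs from species that
carry both systems.  This module maps reference residue positions to
alignment columns, counts how many orthologs carry each substitution,
and compares the count distributions of cross-talk versus
non-cross-talk substitutions with a two-sample Kolmogorov–Smirnov test
and a presence/absence Fisher's exact test.  It also implements the
species-scaled enrichment statistic contrasting species with and
without the paralogous systems, and the "corresponding residue" test
asking whether substitutions that mimic another kinase's residue are
more likely to cross-talk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .library import DomainRegion, Variant

GAP = "-"

#: Switch from the exact to the asymptotic KS null distribution above this size.
KS_EXACT_MAX_N = 25


@dataclass
class OrthologAlignment:
    """A multiple sequence alignment of kinase orthologs with species flags.

    ``sequences`` maps sequence id to an aligned row (equal lengths, gap
    character ``-``).  ``reference_id`` names the row in reference
    (E. coli) coordinates.  ``species`` is indexed by sequence id with
    boolean columns ``has_RstBA``, ``has_CpxAR``, ``has_duplication``.
    """

    sequences: dict[str, str]
    reference_id: str
    species: pd.DataFrame

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.reference_id not in self.sequences:
            raise ValueError(f"reference row {self.reference_id!r} not in alignment")
        missing = set(self.sequences) - {self.reference_id} - set(self.species.index)
        if missing:
            raise ValueError(f"species metadata missing for {sorted(missing)[:5]}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def ortholog_ids(self) -> list[str]:
        return [s for s in self.sequences if s != self.reference_id]


@dataclass
class TestResult:
    """Outcome of a two-sample or contingency test."""

    method: str
    statistic: float
    p_value: float
    sample_sizes: tuple[int, ...] = ()
    table: Optional[np.ndarray] = None
    flags: frozenset[str] = frozenset()


def map_reference_columns(aln: OrthologAlignment, region: DomainRegion) -> dict[int, int]:
    """Map each reference residue position to its alignment column (0-based).

    The reference row is scanned left to right; gaps in the reference are
    skipped (insertion columns have no reference position).  The region's
    residues must occur, in order, as the ``start``.. ``end`` stretch of
    the ungapped reference; a mismatch is an error.
    """
    ref = aln.sequences[aln.reference_id]
    ungapped_pos = 0  # 1-based residue counter
    mapping: dict[int, int] = {}
    for col, ch in enumerate(ref):
        if ch == GAP:
            continue
        ungapped_pos += 1
        protein_pos = region.start + ungapped_pos - 1
        if protein_pos > region.end:
            break
        if ch.upper() != region.aa_at(protein_pos):
            raise ValueError(
                f"reference residue {ch} at column {col} does not match region "
                f"{region.aa_at(protein_pos)}{protein_pos}"
            )
        mapping[protein_pos] = col
    if set(mapping) != set(region.positions):
        missing = sorted(set(region.positions) - set(mapping))
        raise ValueError(f"region positions unmappable in reference row: {missing[:5]}")
    return mapping


def count_substitutions(
    aln: OrthologAlignment,
    mapping: dict[int, int],
    variants: Sequence[Variant],
    species_filter: Optional[Iterable[str]] = None,
) -> pd.Series:
    """Count orthologs carrying each substitution at its aligned column.

    For every variant, counts the non-reference sequences (optionally
    restricted to ``species_filter`` ids) whose residue at the mapped
    column equals the variant's mutant amino acid.  Gap characters are
    never counted.  Returns a Series indexed by variant label.
    """
    ids = aln.ortholog_ids if species_filter is None else [
        s for s in aln.ortholog_ids if s in set(species_filter)
    ]
    if ids:
        mat = np.array([list(aln.sequences[s].upper()) for s in ids])
    else:
        mat = np.empty((0, aln.n_columns), dtype="<U1")
    counts = {}
    for v in variants:
        col = mapping[v.position]
        counts[v.label] = int((mat[:, col] == v.mut_aa).sum()) if len(ids) else 0
    return pd.Series(counts, name="count")


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    D is the maximum absolute difference between the two empirical CDFs.
    The p-value uses the exact small-sample null when
    ``min(n, m) <= 25`` and the asymptotic Kolmogorov distribution
    otherwise.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("KS test requires two nonempty samples")
    method = "exact" if min(len(x), len(y)) <= KS_EXACT_MAX_N else "asymp"
    with warnings.catch_warnings():
        # with heavy ties scipy falls back from exact to asymp by design
        warnings.filterwarnings(
            "ignore", message="ks_2samp: Exact calculation unsuccessful"
        )
        res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return TestResult(
        method=f"ks_2samp[{method}]",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        sample_sizes=(len(x), len(y)),
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table ``[[a, b], [c, d]]``.

    The two-sided p-value sums hypergeometric probabilities of all
    tables (margins fixed) no more probable than the observed one.  The
    statistic is the unconditional sample odds ratio (a*d)/(b*c);
    division by zero yields ``inf`` with an ``or_infinite`` flag.  A
    degenerate table (an all-zero row or column) has p = 1 and an
    undefined odds ratio, flagged ``or_undefined``.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("Fisher test requires a nonnegative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    flags: set[str] = set()
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return TestResult(
            method="fisher_exact",
            statistic=np.nan,
            p_value=1.0,
            table=t,
            flags=frozenset({"or_undefined"}),
        )
    if b * c == 0:
        oddsratio = np.inf
        flags.add("or_infinite")
    else:
        oddsratio = (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(
        method="fisher_exact",
        statistic=float(oddsratio),
        p_value=float(min(p, 1.0)),
        table=t,
        flags=frozenset(flags),
    )


def constraint_tests(
    counts: pd.Series, is_crosstalk: pd.Series
) -> tuple[TestResult, TestResult]:
    """Compare ortholog substitution counts of cross-talk vs other variants.

    Returns ``(ks, fisher)``: the KS test on the two count
    distributions, and Fisher's exact test on the 2x2 table::

                       present (count > 0)   absent (count == 0)
        cross-talk              a                     b
        non-cross-talk          c                     d

    so an odds ratio below 1 means cross-talk substitutions are more
    often completely absent from the orthologs.
    """
    mask = is_crosstalk.reindex(counts.index).astype(bool)
    ct = counts[mask].to_numpy(dtype=float)
    other = counts[~mask].to_numpy(dtype=float)
    if len(ct) == 0 or len(other) == 0:
        raise ValueError("both the cross-talk and non-cross-talk partitions must be nonempty")
    ks = ks_two_sample(ct, other)
    table = [
        [int((ct > 0).sum()), int((ct == 0).sum())],
        [int((other > 0).sum()), int((other == 0).sum())],
    ]
    return ks, fisher_exact(table)


def enrichment(
    count_without: float, count_with: float, n_without: int, n_with: int
) -> float:
    """Species-scaled excess of substitution occurrences.

    ``count_without - count_with * (n_without / n_with)``: the number of
    occurrences among species lacking the paralogous systems, minus the
    occurrences among species carrying both scaled to the same number of
    species.  Zero under exactly proportional per-species rates;
    positive when the substitution is relatively more common where the
    systems are absent.
    """
    if n_with <= 0:
        raise ValueError("n_with must be positive")
    if min(count_without, count_with, n_without) < 0:
        raise ValueError("counts and species numbers must be nonnegative")
    return float(count_without - count_with * (n_without / n_with))


def corresponding_residue_test(
    crosstalk_by_reporter: dict[str, pd.Series],
    region: DomainRegion,
    other_regions: dict[str, DomainRegion],
    correspondence: Optional[dict[str, dict[int, int]]] = None,
) -> TestResult:
    """Does mimicking the other kinase's residue predict cross-talk?

    For each noncognate reporter the other kinase's domain is paired
    position-by-position with the reference domain (a gapless pairing of
    the equal-length domains by default, or an explicit per-reporter
    ``correspondence`` mapping reference position -> other-kinase
    position).  Each (variant, reporter) pair contributes one row of a
    2x2 table::

                                 cross-talk   no cross-talk
        mut_aa == corresponding        a            b
        mut_aa != corresponding        c            d

    pooled over the reporters, then tested with Fisher's exact test.
    Variants at unmappable positions are excluded.
    """
    a = b = c = d = 0
    for reporter, calls in crosstalk_by_reporter.items():
        other = other_regions[reporter]
        if correspondence is not None:
            pos_map = correspondence[reporter]
        else:
            if other.length != region.length:
                raise ValueError(
                    f"{other.protein_id}: lengths differ; supply an explicit correspondence"
                )
            pos_map = {
                p: other.start + (p - region.start) for p in region.positions
            }
        for label, is_ct in calls.items():
            v = Variant.from_label(label)
            if v.position not in pos_map:
                continue
            match = v.mut_aa == other.aa_at(pos_map[v.position])
            if match and is_ct:
                a += 1
            elif match:
                b += 1
            elif is_ct:
                c += 1
            else:
                d += 1
    res = fisher_exact([[a, b], [c, d]])
    return TestResult(
        method="corresponding_residue[fisher_exact]",
        statistic=res.statistic,
        p_value=res.p_value,
        table=res.table,
        flags=res.flags,
    )
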