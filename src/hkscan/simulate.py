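"""Synthetic FACS-seq experiment and ortholog-alignment generator.

Emulates the study design end to end so every downstream stage can be
exercised without external data: a complete single-substitution library
over a 60-residue kinase domain; per-variant ground-truth log10
fluorescence for three reporters (the cognate OmpR readout plus the
noncognate CpxR and RstA readouts) in +signal ("on") and -signal
("off") conditions; log-normal cell fluorescence sorted into eight
gates evenly spaced on the log10(GFP) axis; multinomial read sampling
per bin across three replicates; and ortholog alignments in which
designated cross-talk residues are depleted in species carrying both
paralogous systems.

All randomness flows from a single integer seed via
``numpy.random.default_rng``; identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .deconvolve import BinCountTable
from .evostats import OrthologAlignment
from .library import (
    AA_ALPHABET,
    DomainRegion,
    Variant,
    enumerate_single_substitutions,
    translate_codon,
)

REPORTERS = ("OmpR", "RstA", "CpxR")
COGNATE_REPORTER = "OmpR"
NONCOGNATE_REPORTERS = ("CpxR", "RstA")
CONDITIONS = ("on", "off")

#: Variant classes.  R1 denotes the CpxR readout, R2 the RstA readout.
CLASSES = (
    "neutral",
    "loss_of_function",
    "constitutive",
    "crosstalk_gain_R1",
    "crosstalk_gain_R2",
    "crosstalk_gain_both",
)
_CLASS_REPORTERS = {
    "crosstalk_gain_R1": ("CpxR",),
    "crosstalk_gain_R2": ("RstA",),
    "crosstalk_gain_both": ("CpxR", "RstA"),
}

#: Default class mix, mirroring the observed library composition: ~1.8%
#: of substitutions gain cross-talk toward CpxR only, ~18.1% toward RstA
#: only, ~2.5% toward both; ~19% lose cognate activity beyond 5-fold and
#: ~10% become constitutively active; the rest are neutral.
DEFAULT_CLASS_FRACTIONS = {
    "neutral": 0.486,
    "loss_of_function": 0.190,
    "constitutive": 0.100,
    "crosstalk_gain_R1": 0.018,
    "crosstalk_gain_R2": 0.181,
    "crosstalk_gain_both": 0.025,
}

#: Default effect sizes (linear fold changes applied in log10 space).
#: Cross-talk gains of 30-fold match the strongest reported noncognate
#: increases; 0.02 is a ~50-fold loss of cognate output; constitutive
#: variants raise the -signal state to the +signal level.
DEFAULT_EFFECT_SIZES = {
    "loss_of_function": 0.02,
    "constitutive": 14.0,
    "crosstalk": 30.0,
}

#: Wild-type true peaks, log10 GFP.  The cognate reporter induces
#: ~14-fold with signal; noncognate reporters stay at baseline.
DEFAULT_WT_MU = {
    ("OmpR", "off"): 2.20,
    ("OmpR", "on"): 2.20 + np.log10(14.0),
    ("RstA", "off"): 2.00,
    ("RstA", "on"): 2.00,
    ("CpxR", "off"): 2.00,
    ("CpxR", "on"): 2.00,
}


def _backtranslate(aa_sequence: str) -> str:
    """A deterministic coding sequence: alphabetically first codon per residue."""
    by_aa: dict[str, str] = {}
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                aa = translate_codon(codon)
                if aa != "*" and aa not in by_aa:
                    by_aa[aa] = codon
    # itertools order already yields the alphabetically first codon
    return "".join(by_aa[a] for a in aa_sequence)


def default_reference_region(seed: int = 20260101) -> DomainRegion:
    """A synthetic 60-residue stand-in for the EnvZ DHp domain (230-289).

    The deposited domain sequence is not bundled with this package, so a
    deterministic synthetic sequence in the same coordinates stands in;
    every analysis here depends only on the coordinates and alphabet,
    not on the particular residues.
    """
    rng = np.random.default_rng(seed)
    aa = "".join(rng.choice(list(AA_ALPHABET), size=60))
    return DomainRegion(
        protein_id="EnvZ_synthetic",
        start=230,
        end=289,
        aa_sequence=aa,
        nt_sequence=_backtranslate(aa),
    )


def default_other_kinase_regions(
    region: DomainRegion, seed: int = 20260102, identity: float = 0.4
) -> dict[str, DomainRegion]:
    """Synthetic stand-ins for the CpxA and RstB DHp domains.

    Each is derived from ``region`` by resampling a (1 - identity)
    fraction of positions, keyed by the noncognate reporter it serves
    (CpxR -> CpxA-like, RstA -> RstB-like).
    """
    rng = np.random.default_rng(seed)
    out = {}
    for reporter, name in (("CpxR", "CpxA_synthetic"), ("RstA", "RstB_synthetic")):
        aa = list(region.aa_sequence)
        for i in range(len(aa)):
            if rng.random() > identity:
                choices = [a for a in AA_ALPHABET if a != aa[i]]
                aa[i] = rng.choice(choices)
        out[reporter] = DomainRegion(
            protein_id=name, start=region.start, end=region.end, aa_sequence="".join(aa)
        )
    return out


@dataclass
class GroundTruth:
    """True per-variant peaks and class labels for a simulated library.

    ``true_mu`` is indexed by variant key (labels plus ``"WT"``) with a
    ``(reporter, condition)`` column MultiIndex, in log10 GFP units.
    """

    region: DomainRegion
    true_mu: pd.DataFrame
    class_label: pd.Series
    wt_mu: dict[tuple[str, str], float]
    effect_sizes: dict[str, float]

    def planted_crosstalk(self, reporter: str) -> pd.Index:
        """Variant labels planted with a cross-talk gain toward ``reporter``."""
        classes = [c for c, reps in _CLASS_REPORTERS.items() if reporter in reps]
        return self.class_label.index[self.class_label.isin(classes)]


def generate_ground_truth(
    region: DomainRegion,
    class_fractions: Optional[dict[str, float]] = None,
    effect_sizes: Optional[dict[str, float]] = None,
    seed: int = 0,
    wt_mu: Optional[dict[tuple[str, str], float]] = None,
) -> GroundTruth:
    """Assign every single substitution a class and true peak values.

    Class counts are the rounded fractions of the library size (the
    remainder goes to ``neutral``); the assignment of classes to
    variants is a seeded permutation.  Effects are applied exactly: a
    cross-talk gain of fold f sets the noncognate +signal peak to
    wild type + log10(f), a loss of function multiplies the cognate
    +signal output by the loss factor, and a constitutive variant raises
    the cognate -signal state by the constitutive factor.
    """
    fractions = dict(DEFAULT_CLASS_FRACTIONS)
    if class_fractions is not None:
        unknown = set(class_fractions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")
        fractions = {c: 0.0 for c in CLASSES}
        fractions.update(class_fractions)
    vals = np.array([fractions.get(c, 0.0) for c in CLASSES])
    if (vals < 0).any() or (vals > 1).any() or not np.isclose(vals.sum(), 1.0):
        raise ValueError("class fractions must lie in [0, 1] and sum to 1")
    effects = dict(DEFAULT_EFFECT_SIZES)
    if effect_sizes:
        effects.update(effect_sizes)
    wt = dict(DEFAULT_WT_MU) if wt_mu is None else dict(wt_mu)

    variants = enumerate_single_substitutions(region)
    labels = [v.label for v in variants]
    n = len(variants)

    counts = {c: int(round(fractions.get(c, 0.0) * n)) for c in CLASSES if c != "neutral"}
    total_special = sum(counts.values())
    if total_special > n:
        raise ValueError("class fractions allocate more variants than exist")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    class_label = pd.Series("neutral", index=pd.Index(labels, name="variant"))
    i = 0
    for c in CLASSES:
        if c == "neutral":
            continue
        take = counts.get(c, 0)
        class_label.iloc[order[i : i + take]] = c
        i += take

    cols = pd.MultiIndex.from_product([REPORTERS, CONDITIONS], names=["reporter", "condition"])
    keys = pd.Index(labels + ["WT"], name="variant")
    mu = pd.DataFrame(
        np.tile([wt[(r, c)] for r, c in cols], (len(keys), 1)), index=keys, columns=cols
    )
    lof = class_label.index[class_label == "loss_of_function"]
    mu.loc[lof, (COGNATE_REPORTER, "on")] += np.log10(effects["loss_of_function"])
    const = class_label.index[class_label == "constitutive"]
    mu.loc[const, (COGNATE_REPORTER, "off")] += np.log10(effects["constitutive"])
    for cls, reps in _CLASS_REPORTERS.items():
        members = class_label.index[class_label == cls]
        for r in reps:
            mu.loc[members, (r, "on")] += np.log10(effects["crosstalk"])

    return GroundTruth(
        region=region, true_mu=mu, class_label=class_label, wt_mu=wt, effect_sizes=effects
    )


@dataclass
class SortConfig:
    """Parameters of the simulated sort.

    Defaults follow the reported scale of the experiment: eight gates
    evenly spaced in log10(GFP), up to ~2 million cells sorted per
    sample, 1-2 million reads per bin, three replicates.  ``gate_span``
    of ``None`` sets the gates per sample from the pooled population's
    log10-fluorescence percentiles (``gate_percentiles``), emulating a
    sorter whose detector is adjusted until the whole population is on
    scale; the outermost (half-open) bins catch the residual tails.
    The default 0.1-99.9 percentile span keeps minority subpopulations
    (e.g. rare strong cross-talk gains) inside the gated range — tighter
    spans push a large fraction of their cells into the half-open tail
    bins and bias the density fit.
    """

    n_bins: int = 8
    n_cells_total: int = 2_000_000
    reads_per_bin: int = 1_000_000
    sigma_cell: float = 0.4
    sigma_rep: float = 0.02
    n_replicates: int = 3
    gate_span: Optional[tuple[float, float]] = None
    gate_percentiles: tuple[float, float] = (0.1, 99.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("need at least two bins")
        if min(self.n_cells_total, self.reads_per_bin, self.n_replicates) <= 0:
            raise ValueError("counts must be positive")
        if self.gate_span is not None and not self.gate_span[0] < self.gate_span[1]:
            raise ValueError("gate_span must be increasing")
        if not 0 <= self.gate_percentiles[0] < self.gate_percentiles[1] <= 100:
            raise ValueError("gate_percentiles must be increasing within [0, 100]")


def simulate_sort_experiment(truth: GroundTruth, cfg: SortConfig) -> BinCountTable:
    """Sort the library and sequence each bin, in silico.

    Per (reporter, condition, replicate): each replicate carries one
    additive log10 shift ~ Normal(0, sigma_rep) shared by all variants
    (day-to-day cytometer drift); the library enters the sorter with
    uniform expected abundance (multinomial cell counts); each cell's
    log10 fluorescence is Normal(true_mu + shift, sigma_cell); cells are
    gated into ``n_bins`` bins; each bin's reads are a multinomial draw
    of size ``reads_per_bin`` over its cell composition.
    """
    rng = np.random.default_rng(cfg.seed)
    keys = list(truth.true_mu.index)
    n_keys = len(keys)
    key_idx = np.arange(n_keys)

    reads: dict[tuple[str, str, int], pd.DataFrame] = {}
    cells_sorted: dict[tuple[str, str, int], np.ndarray] = {}
    bin_edges: dict[tuple[str, str, int], np.ndarray] = {}

    for reporter in REPORTERS:
        for condition in CONDITIONS:
            mus = truth.true_mu[(reporter, condition)].to_numpy(dtype=float)
            for rep in range(1, cfg.n_replicates + 1):
                shift = rng.normal(0.0, cfg.sigma_rep)
                cell_counts = rng.multinomial(cfg.n_cells_total, np.full(n_keys, 1.0 / n_keys))
                fluor = rng.normal(
                    np.repeat(mus + shift, cell_counts), cfg.sigma_cell
                )
                if cfg.gate_span is None:
                    low, high = np.percentile(fluor, list(cfg.gate_percentiles))
                else:
                    low, high = cfg.gate_span
                edges = np.linspace(low, high, cfg.n_bins + 1)
                bins = np.digitize(fluor, edges[1:-1])  # 0..n_bins-1, tails included
                vidx = np.repeat(key_idx, cell_counts)
                comp = np.bincount(
                    vidx * cfg.n_bins + bins, minlength=n_keys * cfg.n_bins
                ).reshape(n_keys, cfg.n_bins)
                per_bin_cells = comp.sum(axis=0)
                read_mat = np.zeros((n_keys, cfg.n_bins), dtype=np.int64)
                for b in range(cfg.n_bins):
                    if per_bin_cells[b] > 0:
                        read_mat[:, b] = rng.multinomial(
                            cfg.reads_per_bin, comp[:, b] / per_bin_cells[b]
                        )
                key = (reporter, condition, rep)
                reads[key] = pd.DataFrame(
                    read_mat, index=pd.Index(keys, name="variant"),
                    columns=pd.RangeIndex(1, cfg.n_bins + 1, name="bin"),
                )
                cells_sorted[key] = per_bin_cells.astype(float)
                bin_edges[key] = edges

    return BinCountTable(reads=reads, cells_sorted=cells_sorted, bin_edges=bin_edges)


def simulate_ortholog_alignment(
    region: DomainRegion,
    crosstalk_set: Iterable[Union[Variant, str]],
    n_species_with: int = 1019,
    n_species_without: int = 4732,
    depletion_factor: float = 1.0,
    seed: int = 0,
    conservation: float = 0.0,
    dirichlet_alpha: float = 5.0,
    dup_prob_with: float = 0.05,
    dup_prob_without: float = 0.12,
    reference_id: str = "reference",
) -> OrthologAlignment:
    """Ortholog alignment with planted depletion of cross-talk residues.

    Each column's baseline residue distribution is a
    Dirichlet(``dirichlet_alpha``) draw over the 20 residues, optionally
    mixed with extra weight ``conservation`` on the reference residue.
    The default (no extra conservation, alpha = 5) yields dispersed,
    column-specific integer counts whose two-sample KS null closely
    matches the continuous reference distribution; stronger conservation
    piles counts onto few small values, whose ties make the KS test
    conservative.  In the
    ``n_species_with`` species flagged as carrying both paralogous
    systems, the frequency of every residue in ``crosstalk_set`` is
    multiplied by ``depletion_factor`` and the column renormalized;
    species lacking one or both systems sample from the baseline
    (relaxed selection).  Species rows are independent draws (no
    phylogenetic correlation).  Duplication flags are Bernoulli with a
    higher rate in species lacking the systems.
    """
    if not 0.0 <= depletion_factor <= 1.0:
        raise ValueError("depletion_factor must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    L = region.length
    aa = np.array(list(AA_ALPHABET))
    ct_by_pos: dict[int, set[str]] = {}
    for item in crosstalk_set:
        v = item if isinstance(item, Variant) else Variant.from_label(item)
        ct_by_pos.setdefault(v.position, set()).add(v.mut_aa)

    with_rows = np.empty((n_species_with, L), dtype="<U1")
    without_rows = np.empty((n_species_without, L), dtype="<U1")
    for j, position in enumerate(region.positions):
        base = rng.dirichlet(np.full(20, dirichlet_alpha))
        base = (1.0 - conservation) * base
        base[AA_ALPHABET.index(region.aa_at(position))] += conservation
        depleted = base.copy()
        for mut in ct_by_pos.get(position, ()):
            depleted[AA_ALPHABET.index(mut)] *= depletion_factor
        depleted /= depleted.sum()
        if n_species_with:
            with_rows[:, j] = rng.choice(aa, size=n_species_with, p=depleted)
        if n_species_without:
            without_rows[:, j] = rng.choice(aa, size=n_species_without, p=base)

    sequences = {reference_id: region.aa_sequence}
    meta_rows = []
    for i in range(n_species_with):
        sid = f"sp_with_{i:05d}"
        sequences[sid] = "".join(with_rows[i])
        meta_rows.append((sid, True, True, bool(rng.random() < dup_prob_with)))
    # species lacking at least one system: equal thirds of (neither, CpxAR only, RstBA only)
    for i in range(n_species_without):
        sid = f"sp_without_{i:05d}"
        sequences[sid] = "".join(without_rows[i])
        category = rng.integers(3)
        has_rstba = category == 2
        has_cpxar = category == 1
        meta_rows.append((sid, bool(has_rstba), bool(has_cpxar), bool(rng.random() < dup_prob_without)))

    species = pd.DataFrame(
        meta_rows, columns=["species_id", "has_RstBA", "has_CpxAR", "has_duplication"]
    ).set_index("species_id")
    return OrthologAlignment(sequences=sequences, reference_id=reference_id, species=species)
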