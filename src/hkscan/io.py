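"""Plain-text readers and writers for every pipeline artifact.

All tables are TSV with ``#``-prefixed header comments recording the
tool version, the seed and a hash of the configuration, so any output
file can be traced back to the run that produced it.  Sequences and
alignments are FASTA (via Biopython).  A CSV reader for deposited
per-variant Gaussian-fit mean tables (variant label plus one mean per
condition) lets externally published measurement files flow into the
scoring stage directly.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .deconvolve import BinCountTable
from .evostats import OrthologAlignment
from .library import DomainRegion

PathLike = Union[str, Path]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(seed: Optional[int] = None, config: Optional[dict] = None) -> str:
    lines = [f"# hkscan {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    return "\n".join(lines) + "\n"


def write_tsv(
    df: pd.DataFrame,
    path: PathLike,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
    index: bool = False,
) -> None:
    """Write a DataFrame as TSV with the provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(seed=seed, config=config))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------- FASTA


def read_region_fasta(
    path: PathLike, protein_id: str, start: int, nt_path: Optional[PathLike] = None
) -> DomainRegion:
    """Load a reference region from FASTA (amino acid, optional nucleotide)."""
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if protein_id not in records:
        raise KeyError(f"{protein_id!r} not found in {path}")
    aa = records[protein_id]
    nt = None
    if nt_path is not None:
        nt_records = {r.id: str(r.seq) for r in SeqIO.parse(str(nt_path), "fasta")}
        nt = nt_records.get(protein_id)
    return DomainRegion(
        protein_id=protein_id, start=start, end=start + len(aa) - 1,
        aa_sequence=aa, nt_sequence=nt,
    )


def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_alignment(aln: OrthologAlignment, fasta_path: PathLike, species_path: PathLike,
                    seed: Optional[int] = None, config: Optional[dict] = None) -> None:
    """Alignment rows to FASTA plus species metadata to TSV."""
    write_fasta(aln.sequences, fasta_path)
    write_tsv(aln.species.reset_index(), species_path, seed=seed, config=config)


def read_alignment(fasta_path: PathLike, species_path: PathLike,
                   reference_id: str) -> OrthologAlignment:
    sequences = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    species = read_tsv(species_path).set_index("species_id")
    for col in ("has_RstBA", "has_CpxAR", "has_duplication"):
        species[col] = species[col].astype(bool)
    return OrthologAlignment(sequences=sequences, reference_id=reference_id, species=species)


# ----------------------------------------------------------- count tables

COUNT_COLUMNS = ["reporter", "condition", "replicate", "bin", "variant", "reads"]
BIN_COLUMNS = ["reporter", "condition", "replicate", "bin", "cells_sorted", "edge_low", "edge_high"]


def write_count_table(
    table: BinCountTable,
    counts_path: PathLike,
    bins_path: PathLike,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    """Serialize a bin-count table as two TSVs (read counts + gate metadata)."""
    count_rows = []
    bin_rows = []
    for key in table.keys:
        reporter, condition, rep = key
        reads = table.reads[key]
        edges = table.bin_edges[key]
        cells = table.cells_sorted[key]
        long = reads.stack()
        long = long[long > 0]
        for (variant, b), n in long.items():
            count_rows.append((reporter, condition, rep, b, variant, int(n)))
        for b in range(1, reads.shape[1] + 1):
            bin_rows.append(
                (reporter, condition, rep, b, float(cells[b - 1]), edges[b - 1], edges[b])
            )
    write_tsv(pd.DataFrame(count_rows, columns=COUNT_COLUMNS), counts_path,
              seed=seed, config=config)
    write_tsv(pd.DataFrame(bin_rows, columns=BIN_COLUMNS), bins_path,
              seed=seed, config=config)


def _check_columns(df: pd.DataFrame, required: list[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_count_table(counts_path: PathLike, bins_path: PathLike) -> BinCountTable:
    """Load and validate the two-TSV bin-count format.

    Malformed rows (negative counts, non-monotone gate edges, bins
    without metadata) raise errors naming the offending lines.
    """
    counts = read_tsv(counts_path)
    bins = read_tsv(bins_path)
    _check_columns(counts, COUNT_COLUMNS, counts_path)
    _check_columns(bins, BIN_COLUMNS, bins_path)

    bad = counts.index[counts["reads"] < 0]
    if len(bad):
        raise ValueError(f"{counts_path}: negative read counts at data rows {list(bad[:5])}")
    bad = bins.index[bins["cells_sorted"] < 0]
    if len(bad):
        raise ValueError(f"{bins_path}: negative cell counts at data rows {list(bad[:5])}")

    reads: dict[tuple[str, str, int], pd.DataFrame] = {}
    cells_sorted: dict[tuple[str, str, int], np.ndarray] = {}
    bin_edges: dict[tuple[str, str, int], np.ndarray] = {}
    variants = sorted(counts["variant"].unique())
    for (reporter, condition, rep), sub_bins in bins.groupby(
        ["reporter", "condition", "replicate"]
    ):
        key = (str(reporter), str(condition), int(rep))
        sub_bins = sub_bins.sort_values("bin")
        n_bins = len(sub_bins)
        if list(sub_bins["bin"]) != list(range(1, n_bins + 1)):
            raise ValueError(f"{bins_path}: sample {key} bins are not 1..{n_bins}")
        edges = np.concatenate([sub_bins["edge_low"].to_numpy(),
                                sub_bins["edge_high"].to_numpy()[-1:]])
        inner_ok = np.allclose(sub_bins["edge_high"].to_numpy()[:-1],
                               sub_bins["edge_low"].to_numpy()[1:])
        if not inner_ok or np.any(np.diff(edges) <= 0):
            raise ValueError(f"{bins_path}: sample {key} gate edges not increasing/contiguous")
        mat = pd.DataFrame(
            0, index=pd.Index(variants, name="variant"),
            columns=pd.RangeIndex(1, n_bins + 1, name="bin"), dtype=np.int64,
        )
        sub_counts = counts[
            (counts["reporter"] == reporter)
            & (counts["condition"] == condition)
            & (counts["replicate"] == rep)
        ]
        out_of_range = sub_counts.index[(sub_counts["bin"] < 1) | (sub_counts["bin"] > n_bins)]
        if len(out_of_range):
            raise ValueError(
                f"{counts_path}: sample {key} bin index out of range at data rows "
                f"{list(out_of_range[:5])}"
            )
        for _, row in sub_counts.iterrows():
            mat.loc[row["variant"], int(row["bin"])] += int(row["reads"])
        reads[key] = mat
        cells_sorted[key] = sub_bins["cells_sorted"].to_numpy(dtype=float)
        bin_edges[key] = edges
    if not reads:
        raise ValueError(f"{counts_path}: no samples found")
    return BinCountTable(reads=reads, cells_sorted=cells_sorted, bin_edges=bin_edges)


# -------------------------------------------------- measurements & results


def write_measurements(measurements: pd.DataFrame, path: PathLike,
                       seed: Optional[int] = None, config: Optional[dict] = None) -> None:
    write_tsv(measurements, path, seed=seed, config=config)


def read_measurements(path: PathLike) -> pd.DataFrame:
    df = read_tsv(path)
    for col in ("converged_on", "converged_off"):
        df[col] = df[col].astype(bool)
    df["qc_flags"] = df["qc_flags"].fillna("")
    return df


def load_deposited_means(
    path: PathLike,
    reporter: str,
    variant_col: str = "variant",
    mu_on_col: str = "mu_on",
    mu_off_col: str = "mu_off",
) -> pd.DataFrame:
    """Read a deposited per-variant Gaussian-fit mean CSV into measurement form.

    Deposited tables carry one row per variant with the fitted log10
    means for the induced and uninduced conditions; the column names are
    mapped via the ``*_col`` arguments.  The returned frame matches the
    deconvolution output schema (fits marked converged, fold induction
    in linear mode) so scoring functions accept it unchanged.
    """
    raw = pd.read_csv(path, comment="#")
    for col in (variant_col, mu_on_col, mu_off_col):
        if col not in raw.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = pd.DataFrame(
        {
            "variant": raw[variant_col].astype(str),
            "reporter": reporter,
            "mu_on": raw[mu_on_col].astype(float),
            "sigma_on": np.nan,
            "converged_on": np.isfinite(raw[mu_on_col].astype(float)),
            "mu_off": raw[mu_off_col].astype(float),
            "sigma_off": np.nan,
            "converged_off": np.isfinite(raw[mu_off_col].astype(float)),
            "mean_reads_on": np.nan,
            "mean_reads_off": np.nan,
            "qc_flags": "",
        }
    )
    df["fold_induction"] = 10.0 ** (df["mu_on"] - df["mu_off"])
    return df


def write_test_results(results: dict[str, object], path: PathLike,
                       seed: Optional[int] = None, config: Optional[dict] = None) -> None:
    """Statistical test results as a TSV of (name, method, statistic, p, table)."""
    rows = []
    for name, res in results.items():
        table = "" if getattr(res, "table", None) is None else json.dumps(
            np.asarray(res.table).tolist()
        )
        rows.append(
            {
                "name": name,
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "table": table,
                "flags": ";".join(sorted(res.flags)) if getattr(res, "flags", None) else "",
            }
        )
    write_tsv(pd.DataFrame(rows), path, seed=seed, config=config)
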