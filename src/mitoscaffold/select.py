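"""Mitochondrial contig selection and depth-of-coverage copy classes.

In a whole-genome short-read assembly of plant tissue, mitochondrial
contigs can be told apart from nuclear ones by (1) carrying known
mitochondrial genes and (2) sitting in the depth-of-coverage band those
gene-carrying contigs define (the organelle is present at many copies
per cell, so its contigs are far deeper than single-copy nuclear
sequence). Relative coverage within the selected set then estimates
each contig's genomic multiplicity: repeats collapse into one contig at
twice (or more) the median depth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from statistics import median

import pandas as pd


class SelectionError(ValueError):
    pass


@dataclass
class Contig:
    """An assembly contig with coverage and selection metadata."""

    id: str
    sequence: str
    mean_cov: float = 0.0
    gene_hits: list[str] = field(default_factory=list)
    selected: bool = False
    selection_reason: str = ""
    cov_ratio: float | None = None
    copy_class: str | None = None
    repeat_like: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SelectParams:
    min_len: int = 2_000
    cov_range: tuple[float, float] | None = None  # derived from gene-hit contigs if None
    assembler_min_contig: int = 500

    def __post_init__(self) -> None:
        if self.min_len < self.assembler_min_contig:
            raise ValueError("min_len must be >= assembler_min_contig")
        if self.cov_range is not None and self.cov_range[0] > self.cov_range[1]:
            raise ValueError("cov_range lower bound exceeds upper bound")


@dataclass(frozen=True)
class ClassBands:
    """Coverage-ratio bands for copy classification.

    The narrative partition they reproduce, at a median of 89x: low
    32-71x, single 79-107x, repeat-like 120-204x with integer multiples
    and in-between (intermediate) values distinguished.
    """

    low_below: float = 0.80
    single_below: float = 1.25
    multiple_tol: float = 0.15


def select_mito_contigs(
    contigs: list[Contig], params: SelectParams | None = None
) -> set[str]:
    """Two-criterion mitochondrial contig selection (mutates ``contigs``).

    Criterion 1: any contig with >= 1 mitochondrial gene hit, regardless
    of length or coverage. The coverage range [min, max] of those
    contigs then defines criterion 2: length >= ``min_len`` and mean
    coverage inside the range (boundaries inclusive). With no gene-hit
    contig the range is undefined and ``cov_range`` must be supplied.
    """
    params = params or SelectParams()
    crit1 = [c for c in contigs if c.gene_hits]
    if params.cov_range is not None:
        lo, hi = params.cov_range
    elif crit1:
        lo = min(c.mean_cov for c in crit1)
        hi = max(c.mean_cov for c in crit1)
    else:
        raise SelectionError(
            "no contig carries a mitochondrial gene hit, so the coverage range "
            "is undefined; supply SelectParams(cov_range=(lo, hi)) explicitly"
        )
    selected: set[str] = set()
    for c in contigs:
        if c.gene_hits:
            c.selected = True
            c.selection_reason = "gene_hit:" + ",".join(c.gene_hits)
        elif c.length >= params.min_len and lo <= c.mean_cov <= hi:
            c.selected = True
            c.selection_reason = f"coverage_in_range[{lo:g},{hi:g}]"
        else:
            c.selected = False
            c.selection_reason = ""
        if c.selected:
            selected.add(c.id)
    return selected


def classify_ratio(ratio: float, bands: ClassBands) -> tuple[str, bool]:
    """Map a coverage ratio to a copy class and a repeat-like flag."""
    if ratio < bands.low_below:
        return "low", False
    if ratio < bands.single_below:
        return "single", False
    k = round(ratio)
    if abs(ratio - k) <= bands.multiple_tol and k >= 2:
        return f"multiple({k})", True
    k_low = math.floor(ratio) if ratio >= 1 else 1
    if abs(ratio - (k_low + 1)) <= bands.multiple_tol:
        return f"multiple({k_low + 1})", True
    return f"intermediate({k_low},{k_low + 1})", True


def assign_copy_class(
    contigs: list[Contig], bands: ClassBands | None = None
) -> float:
    """Assign coverage ratios and copy classes to the selected contigs.

    The reference point is the median coverage of the selected set
    (single-copy expectation). Contigs at >= ``single_below`` times the
    median are flagged repeat-like and become eligible for placement in
    more than one scaffold. Returns the median coverage used.
    """
    bands = bands or ClassBands()
    sel = [c for c in contigs if c.selected]
    if len(sel) < 3:
        raise SelectionError("copy classification needs >= 3 selected contigs")
    med = median(c.mean_cov for c in sel)
    if med <= 0:
        raise SelectionError("median coverage of selected contigs is zero")
    for c in sel:
        c.cov_ratio = c.mean_cov / med
        c.copy_class, c.repeat_like = classify_ratio(c.cov_ratio, bands)
    return med


def compute_mean_coverage(
    contigs: list[Contig],
    short_reads,
    map_params=None,
) -> pd.DataFrame:
    """Mean short-read depth per contig (aligned bases / contig length).

    Uses the same mapping contract as polishing (length fraction 0.9,
    similarity 0.95, best single location, ambiguous reads dropped).
    Updates ``mean_cov`` on the contigs and returns a coverage table.
    """
    from .io import SeqRecord
    from .polish import MapParams, map_short_reads

    if not contigs:
        raise SelectionError("compute_mean_coverage needs at least one contig")
    map_params = map_params or MapParams(
        length_fraction=0.9, similarity=0.95, include_decoys=False
    )
    reads = list(short_reads)
    if not reads:
        warnings.warn("no short reads supplied; all coverages set to 0")
        for c in contigs:
            c.mean_cov = 0.0
    else:
        refs = [SeqRecord(c.id, c.sequence) for c in contigs]
        pileups = map_short_reads(reads, refs, map_params)
        for c in contigs:
            c.mean_cov = pileups[c.id].mean_depth
    return pd.DataFrame(
        {
            "contig_id": [c.id for c in contigs],
            "length": [c.length for c in contigs],
            "mean_cov": [c.mean_cov for c in contigs],
        }
    )


def selection_table(contigs: list[Contig]) -> pd.DataFrame:
    rows = [
        {
            "contig_id": c.id,
            "length": c.length,
            "mean_cov": c.mean_cov,
            "cov_ratio": c.cov_ratio,
            "copy_class": c.copy_class,
            "repeat_like": c.repeat_like,
            "selected": c.selected,
            "reason": c.selection_reason,
        }
        for c in contigs
    ]
    return pd.DataFrame(rows)


def coverage_from_table(contigs: list[Contig], table: pd.DataFrame) -> None:
    """Attach mean coverages from a (contig_id, mean_cov) table in place."""
    cov = dict(zip(table["contig_id"], table["mean_cov"]))
    for c in contigs:
        if c.id in cov:
            c.mean_cov = float(cov[c.id])


def gene_hits_from_table(contigs: list[Contig], table: pd.DataFrame) -> None:
    """Attach gene hits from a (contig_id, gene) table in place."""
    hits: dict[str, list[str]] = {}
    for _, row in table.iterrows():
        hits.setdefault(str(row["contig_id"]), []).append(str(row["gene"]))
    for c in contigs:
        c.gene_hits = hits.get(c.id, [])
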