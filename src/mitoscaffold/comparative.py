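"""Mitogenome copy-number estimation and cross-genome repeat analysis.

Copy number per cell follows from two depths: the mean mapping
coverage of short reads on the mitogenome, and the coverage the same
read set represents for one haploid nuclear genome (input bases /
haploid genome size). Their ratio is the number of mitogenome copies
per (haploid) cell. The cross-genome analysis asks whether bigger
mitogenomes carry proportionally more interspersed repeats, via the
Pearson correlation of mitogenome size against repeat proportion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats as _stats

from .io import SeqRecord
from .repeats import RepeatParams, find_repeats, repeat_proportion


@dataclass(frozen=True)
class CopyNumberInputs:
    mean_mito_cov: float  # X, mean short-read depth on the mitogenome
    input_bases: float  # bp of sequencing input
    haploid_genome_size: float  # bp

    def __post_init__(self) -> None:
        if min(self.mean_mito_cov, self.input_bases, self.haploid_genome_size) <= 0:
            raise ValueError("copy-number inputs must all be positive")


def round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def estimate_copy_number(inputs: CopyNumberInputs) -> tuple[float, float]:
    """Mitogenome copies per cell: mito coverage over nuclear coverage.

    Nuclear coverage of the input is input_bases / haploid_genome_size.
    Returns (raw, rounded-to-2-significant-figures); the ratio is
    invariant to rescaling input bases and genome size together.
    """
    nuclear_cov = inputs.input_bases / inputs.haploid_genome_size
    raw = inputs.mean_mito_cov / nuclear_cov
    return raw, round_sig(raw, 2)


def pearson_correlation(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Product-moment r with the two-sided p from the t transform (n-2 df)."""
    if len(xs) != len(ys) or len(xs) < 3:
        raise ValueError("need paired samples with n >= 3")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("degenerate (zero-variance) input")
    r, p = _stats.pearsonr(xs, ys)
    return float(r), float(p)


@dataclass(frozen=True)
class GenomeRepeatRecord:
    species: str
    size_mbp: float
    repeat_proportion: float
    group: str = ""


def size_vs_repeat_table(
    genomes: dict[str, list[SeqRecord]],
    min_len: int = 24,
    mode: str = "union",
    groups: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, tuple[float, float] | None]:
    """Repeat proportion vs genome size across assemblies.

    Runs the repeat finder on each genome, returns the scatter table
    (size in Mbp, repeat proportion) and, with >= 3 genomes, the
    Pearson (r, p); with fewer the correlation is skipped with a
    warning.
    """
    records = []
    for label, seqs in genomes.items():
        total = sum(len(s) for s in seqs)
        fams = find_repeats(seqs, RepeatParams(min_len=min_len))
        prop = repeat_proportion(fams, seqs, mode=mode)
        records.append(
            GenomeRepeatRecord(
                label, total / 1e6, prop, (groups or {}).get(label, "")
            )
        )
    df = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "size_mbp": [r.size_mbp for r in records],
            "repeat_proportion": [r.repeat_proportion for r in records],
            "group": [r.group for r in records],
        }
    )
    if len(records) < 3:
        warnings.warn("fewer than 3 genomes; correlation skipped")
        return df, None
    corr = pearson_correlation(list(df["size_mbp"]), list(df["repeat_proportion"]))
    return df, corr


# Published total assembly sizes (Mbp) of gymnosperm mitogenomes, for
# context in cross-genome comparisons (angiosperm outgroups excluded).
GYMNOSPERM_MITOGENOME_SIZES_MBP = {
    "Abies alba": 1.43,
    "Abies firma": 1.33,
    "Cycas debaoensis": 0.41,
    "Cycas taitungensis": 0.41,
    "Ginkgo biloba": 0.35,
    "Larix sibirica": 11.66,
    "Picea abies": 4.90,
    "Picea glauca": 5.99,
    "Picea sitchensis": 5.52,
    "Pinus taeda": 1.19,
    "Taxus cuspidata": 0.47,
    "Welwitschia mirabilis": 0.98,
}
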