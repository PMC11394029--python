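"""Tumor mutational burden (TMB): coding somatic mutations per megabase.

TMB = (consensus, PON-filtered coding mutations) / (exome target size in Mb).
The default denominator is 57 Mb, a canine whole-exome target size; coding
mutations are nonsynonymous plus synonymous variants (a switch restricts to
nonsynonymous only), excluding the mitochondrial contig and unplaced
scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .variant_consensus import EFFECT_LABELS, NormalizedVariant

__all__ = [
    "TMBResult",
    "DEFAULT_DENOMINATOR_MB",
    "DEFAULT_EXCLUDED_CONTIGS",
    "DEFAULT_EXCLUDED_PATTERNS",
    "count_coding_mutations",
    "compute_tmb",
    "write_tmb",
    "read_tmb",
]

DEFAULT_DENOMINATOR_MB = 57.0
DEFAULT_EXCLUDED_CONTIGS = frozenset({"chrM", "MT", "chrMT"})
#: Substrings marking unplaced/unaligned scaffolds.
DEFAULT_EXCLUDED_PATTERNS = ("chrUn", "_random", "_alt")

CODING_EFFECTS = frozenset({"nonsynonymous", "synonymous"})


@dataclass(frozen=True)
class TMBResult:
    sample: str
    n_coding: int
    denominator_mb: float
    tmb: float


def _excluded(chrom: str, contigs: frozenset[str], patterns: Sequence[str]) -> bool:
    return chrom in contigs or any(p in chrom for p in patterns)


def count_coding_mutations(
    variants: Iterable[NormalizedVariant],
    excluded_contigs: Iterable[str] = DEFAULT_EXCLUDED_CONTIGS,
    excluded_patterns: Sequence[str] = DEFAULT_EXCLUDED_PATTERNS,
    nonsynonymous_only: bool = False,
) -> int:
    """Count coding consensus mutations outside excluded contigs.

    Raises on any effect label outside the known vocabulary, listing the
    offending variants.
    """
    contigs = frozenset(excluded_contigs)
    effects = frozenset({"nonsynonymous"}) if nonsynonymous_only else CODING_EFFECTS
    bad = [v for v in variants if v.effect not in EFFECT_LABELS]
    if bad:
        raise ValueError(
            "unknown effect labels: "
            + "; ".join(f"{v.chrom}:{v.pos} {v.effect!r}" for v in bad[:10])
        )
    return sum(
        1
        for v in variants
        if v.effect in effects and not _excluded(v.chrom, contigs, excluded_patterns)
    )


def compute_tmb(
    n_coding: int,
    denominator_mb: float = DEFAULT_DENOMINATOR_MB,
    sample: str = "",
) -> TMBResult:
    """Mutations per megabase of sequenced coding genome."""
    if denominator_mb <= 0:
        raise ValueError("denominator_mb must be > 0")
    if n_coding < 0:
        raise ValueError("n_coding must be >= 0")
    return TMBResult(sample, n_coding, denominator_mb, n_coding / denominator_mb)


_TMB_COLUMNS = ["sample", "n_coding", "denominator_mb", "tmb"]


def write_tmb(results: Iterable[TMBResult], path: str | Path | TextIO) -> None:
    rows = [(r.sample, r.n_coding, r.denominator_mb, f"{r.tmb:.6g}") for r in results]
    pd.DataFrame(rows, columns=_TMB_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tmb(path: str | Path | TextIO) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TMB_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TMB TSV missing columns {sorted(missing)}")
    return df
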