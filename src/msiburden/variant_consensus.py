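"""Multi-caller somatic consensus and Panel-of-Normals filtering.

Three callers' somatic call-sets are merged by majority vote: a variant is
kept when at least two of the three callers report it.  Variant identity is
the normalized (trimmed, left-aligned) CHROM/POS/REF/ALT key; genotype and
quality fields play no role.  Artifacts recorded in a Panel of Normals (PON,
variants seen in the cohort's healthy tissues) are removed afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "NormalizedVariant",
    "VariantKey",
    "normalize_variant",
    "consensus_vote",
    "apply_pon",
    "read_vcf",
    "write_vcf",
    "write_audit",
    "EFFECT_LABELS",
]

logger = logging.getLogger("msiburden.consensus")

EFFECT_LABELS = ("nonsynonymous", "synonymous", "noncoding", "other")

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class NormalizedVariant:
    """A left-aligned, minimal-representation SNV or indel (1-based POS)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    callers: frozenset[str] = frozenset()
    effect: str = "other"
    in_pon: bool = False

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("null variant: ref == alt")
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (VCF convention)")
        if self.effect not in EFFECT_LABELS:
            raise ValueError(f"unknown effect label {self.effect!r}")


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Callable[[str, int], str] | None = None,
) -> tuple[str, int, str, str]:
    """Reduce a VCF-style allele pair to its minimal left-most representation.

    Trims the shared suffix, then the shared prefix (keeping the mandatory
    anchor base for indels), and — when a ``reference`` base accessor
    ``(chrom, 1-based pos) -> base`` is supplied — left-aligns indels by
    repeatedly substituting the preceding reference base.  Idempotent.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"null variant at {chrom}:{pos} ({ref}>{alt})")

    def trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
        # suffix first, then prefix; always keep >= 1 base on each side
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        return pos, ref, alt

    pos, ref, alt = trim(pos, ref, alt)
    if reference is not None and len(ref) != len(alt):
        # classic left-align: while the alleles end with the same base, drop
        # it and prepend the previous reference base
        while True:
            if ref[-1] == alt[-1] and pos > 1:
                prev = reference(chrom, pos - 1).upper()
                ref, alt = prev + ref[:-1], prev + alt[:-1]
                pos -= 1
                pos, ref, alt = trim(pos, ref, alt)
            else:
                break
    if ref == alt:  # defensive; trim() preserves ref != alt
        raise ValueError(f"null variant at {chrom}:{pos}")
    return chrom, pos, ref, alt


def consensus_vote(
    callsets: Mapping[str, Sequence[NormalizedVariant]],
    min_callers: int = 2,
) -> list[NormalizedVariant]:
    """Majority vote across callers.

    Returns the variants supported by at least ``min_callers`` distinct
    callers, sorted by (chrom, pos, ref, alt), with the ``callers`` field
    recording the full support set.  Duplicate keys within one caller's list
    are deduplicated with a warning.  The result is invariant under
    permutation of the input call-sets.
    """
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    support: dict[VariantKey, set[str]] = {}
    effects: dict[VariantKey, str] = {}
    for caller, variants in callsets.items():
        seen: set[VariantKey] = set()
        for v in variants:
            if v.key in seen:
                logger.warning("caller %s: duplicate variant %s deduplicated",
                               caller, v.key)
                continue
            seen.add(v.key)
            support.setdefault(v.key, set()).add(caller)
            effects.setdefault(v.key, v.effect)
    out = [
        NormalizedVariant(*key, callers=frozenset(callers), effect=effects[key])
        for key, callers in support.items()
        if len(callers) >= min_callers
    ]
    return sorted(out, key=lambda v: v.key)


def apply_pon(
    variants: Sequence[NormalizedVariant],
    pon: Iterable[VariantKey],
) -> tuple[list[NormalizedVariant], list[NormalizedVariant]]:
    """Remove PON-listed variants.

    Returns ``(kept, removed)``; removed records carry ``in_pon=True`` for
    the audit trail.
    """
    pon_keys = set(pon)
    kept, removed = [], []
    for v in variants:
        if v.key in pon_keys:
            removed.append(replace(v, in_pon=True))
        else:
            kept.append(v)
    return kept, removed


# ---------------------------------------------------------------------------
# VCF / TSV interfaces

VCF_HEADER_LINES = (
    "##fileformat=VCFv4.2",
    '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Functional effect class">',
    '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting callers">',
)


def read_vcf(
    path: str | Path,
    caller: str | None = None,
    effect_tag: str = "EFFECT",
    reference: Callable[[str, int], str] | None = None,
) -> list[NormalizedVariant]:
    """Read and normalize a (possibly multi-allelic) VCF 4.2 call-set."""
    out: list[NormalizedVariant] = []
    callers = frozenset([caller]) if caller else frozenset()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            effect = rec.info.get(effect_tag, "other")
            if isinstance(effect, tuple):
                effect = effect[0]
            for alt in rec.alts or ():
                chrom, pos, ref, a = normalize_variant(
                    rec.chrom, rec.pos, rec.ref, alt, reference
                )
                out.append(
                    NormalizedVariant(chrom, pos, ref, a,
                                      callers=callers, effect=str(effect))
                )
    return out


def write_vcf(
    variants: Sequence[NormalizedVariant],
    path: str | Path,
    contigs: Sequence[str] | None = None,
) -> None:
    """Write variants as minimal VCF 4.2 (site-level, no samples)."""
    if contigs is None:
        contigs = sorted({v.chrom for v in variants})
    with open(path, "w") as fh:
        for line in VCF_HEADER_LINES:
            fh.write(line + "\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: v.key):
            info = f"EFFECT={v.effect}"
            if v.callers:
                info += ";CALLERS=" + ",".join(sorted(v.callers))
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")


def write_audit(
    kept: Sequence[NormalizedVariant],
    removed: Sequence[NormalizedVariant],
    path: str | Path,
) -> None:
    """TSV audit table over all consensus variants (kept + PON-removed)."""
    rows = [
        (v.chrom, v.pos, v.ref, v.alt, ",".join(sorted(v.callers)),
         int(v.in_pon), v.effect)
        for v in sorted([*kept, *removed], key=lambda v: v.key)
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "callers", "in_pon", "effect"],
    ).to_csv(path, sep="\t", index=False)
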