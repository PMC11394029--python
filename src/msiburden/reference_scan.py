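"""Microsatellite discovery in a reference genome.

A microsatellite locus is a maximal tandem run of a primitive 1-5 bp motif
meeting a per-unit-length minimum copy number.  Coordinates are 0-based
half-open (BED convention) throughout; conversion to 1-based happens only at
VCF boundaries elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from Bio import SeqIO

__all__ = [
    "MicrosatelliteLocus",
    "DEFAULT_MIN_REPEATS",
    "canonical_motif",
    "primitive_unit",
    "scan_sequence",
    "scan_fasta",
    "write_sites",
    "read_sites",
    "FastaParseError",
]

#: Default minimum number of full tandem copies per motif length.  Mirrors
#: common msisensor-style scan settings: homopolymers need 10 copies,
#: dinucleotides 5, longer motifs 4.
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 4, 5: 4}

_VALID_BASES = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised when a sequence contains characters other than A/C/G/T/N."""


@dataclass(frozen=True, order=True)
class MicrosatelliteLocus:
    """A reference tandem-repeat region.

    ``end - start == unit_len * ref_repeats`` always holds: partial trailing
    copies are trimmed and the interval covers full motif copies only.
    ``motif`` is stored in canonical form (lexicographically smallest rotation
    of the primitive unit), so locus identity is reading-frame independent.
    """

    chrom: str
    start: int
    end: int
    motif: str
    ref_repeats: int

    @property
    def unit_len(self) -> int:
        return len(self.motif)

    @property
    def locus_key(self) -> str:
        """Stable cohort-wide identifier ``chrom:start:motif``."""
        return f"{self.chrom}:{self.start}:{self.motif}"

    def __post_init__(self) -> None:
        if not 1 <= len(self.motif) <= 5:
            raise ValueError(f"motif length must be 1-5, got {self.motif!r}")
        if self.end - self.start != len(self.motif) * self.ref_repeats:
            raise ValueError(
                f"interval [{self.start},{self.end}) inconsistent with "
                f"{self.ref_repeats} copies of {self.motif!r}"
            )


def primitive_unit(motif: str) -> str:
    """Smallest repeating unit of ``motif`` (e.g. ``ATAT`` -> ``AT``)."""
    if not motif:
        raise ValueError("empty motif")
    n = len(motif)
    for d in range(1, n + 1):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            return motif[:d]
    return motif  # pragma: no cover - d == n always matches


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation of the primitive form of ``motif``.

    Idempotent; gives every reading frame of a repeat the same identity
    (``TA`` and ``AT`` are the same dinucleotide repeat).
    """
    unit = primitive_unit(motif)
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _candidate_runs(seq: str, min_repeats: Mapping[int, int]) -> list[tuple[int, int, int]]:
    """All maximal tandem-run candidates as (start, end, unit_len).

    For each unit length u, a maximal interval where seq[i] == seq[i-u] is a
    periodic run; every one of its u phase alignments yields a candidate
    trimmed to full copies (a non-leftmost alignment can win when the
    leftmost one collides with an adjacent run during overlap resolution).
    Runs whose motif is non-primitive are skipped — they are reported at the
    smaller primitive unit length instead.
    """
    n = len(seq)
    out: set[tuple[int, int, int]] = set()
    for u, min_rep in sorted(min_repeats.items()):
        run_start = 0
        while run_start + u <= n:
            # extend the periodic run beginning at run_start
            i = run_start + u
            while i < n and seq[i] == seq[i - u] and seq[i] != "N":
                i += 1
            length = i - run_start
            if "N" not in seq[run_start : run_start + min(u, length)]:
                for phase in range(u):
                    copies = (length - phase) // u
                    if copies < min_rep:
                        continue
                    start = run_start + phase
                    if len(primitive_unit(seq[start : start + u])) == u:
                        out.add((start, start + copies * u, u))
            # next run starts after the first position that broke periodicity
            run_start = max(run_start + 1, i - u + 1)
    return sorted(out)


def _resolve_overlaps(cands: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Greedy overlap resolution: longer run wins; tie -> smaller unit length,
    then smaller start."""
    order = sorted(cands, key=lambda c: (-(c[1] - c[0]), c[2], c[0]))
    chosen: list[tuple[int, int, int]] = []
    for c in order:
        if all(c[1] <= k[0] or c[0] >= k[1] for k in chosen):
            chosen.append(c)
    return sorted(chosen)


def scan_sequence(
    seq: str,
    chrom: str,
    min_repeats: Mapping[int, int] | None = None,
) -> list[MicrosatelliteLocus]:
    """Find all microsatellite loci in one sequence.

    Parameters
    ----------
    seq
        Nucleotide string over ``{A, C, G, T, N}`` (case-insensitive).
        Runs never cross an ``N``.
    chrom
        Sequence name used in the emitted loci.
    min_repeats
        Minimum full copy number per motif length (default
        :data:`DEFAULT_MIN_REPEATS`).

    Returns
    -------
    Sorted, non-overlapping loci.  When candidate runs overlap the longer
    total run is kept; ties prefer the smaller unit length, then the smaller
    start coordinate.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise FastaParseError(
            f"{chrom}: invalid nucleotide characters {sorted(bad)!r}"
        )
    loci = []
    for start, end, u in _resolve_overlaps(_candidate_runs(seq, min_repeats)):
        motif = canonical_motif(seq[start : start + u])
        loci.append(
            MicrosatelliteLocus(chrom, start, end, motif, (end - start) // u)
        )
    return loci


def scan_fasta(
    path: str | Path,
    min_repeats: Mapping[int, int] | None = None,
) -> list[MicrosatelliteLocus]:
    """Scan every record of a FASTA file (wrapped or unwrapped)."""
    loci: list[MicrosatelliteLocus] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        loci.extend(scan_sequence(str(rec.seq), rec.id, min_repeats))
    return loci


_SITE_COLUMNS = ("chrom", "start", "end", "motif", "ref_repeats")


def write_sites(loci: Iterable[MicrosatelliteLocus], sink: str | Path | TextIO) -> None:
    """Write a 5-column site list TSV (0-based half-open intervals).

    Input must be sorted by (chrom, start) and non-overlapping per chromosome.
    """
    loci = list(loci)
    for a, b in zip(loci, loci[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"unsorted or overlapping loci: {a} vs {b}")
        if a.chrom == b.chrom and b.start < a.start:
            raise ValueError(f"loci not sorted by start: {a} vs {b}")
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w") if own else sink
    try:
        fh.write("\t".join(_SITE_COLUMNS) + "\n")
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.motif}\t{loc.ref_repeats}\n"
            )
    finally:
        if own:
            fh.close()


def read_sites(source: str | Path | TextIO) -> list[MicrosatelliteLocus]:
    """Read a site list written by :func:`write_sites`."""
    own = isinstance(source, (str, Path))
    fh = open(source) if own else source
    try:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _SITE_COLUMNS:
            raise ValueError(f"unexpected site list header: {header!r}")
        loci = []
        for line in fh:
            chrom, start, end, motif, reps = line.rstrip("\n").split("\t")
            loci.append(
                MicrosatelliteLocus(chrom, int(start), int(end), motif, int(reps))
            )
        return loci
    finally:
        if own:
            fh.close()
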