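"""Per-locus tumor vs. matched-normal instability testing.

At each microsatellite locus the read support over repeat copy-numbers is
compared between tumor and normal tissue with a chi-square homogeneity test
(low-expectation bins pooled).  A locus is called unstable when the tumor
distribution differs significantly from the normal one; per-sample calls are,
by default, Benjamini-Hochberg corrected across the loci tested in that
sample so that a microsatellite-stable genome yields an empty call set with
high probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy.special import chdtrc

__all__ = [
    "RepeatHistogram",
    "InstabilityCall",
    "SampleMSIProfile",
    "test_locus",
    "call_sample",
    "call_cohort",
    "write_calls",
    "read_calls",
    "read_histograms",
    "write_histograms",
]

logger = logging.getLogger("msiburden.call")

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_COV = 20
#: Default multiple-testing correction across loci within a sample.
DEFAULT_FDR = "bh"


@dataclass(frozen=True)
class RepeatHistogram:
    """Read support per repeat copy-number at one locus in one tissue."""

    locus: str
    sample: str
    tissue: str  # "tumor" | "normal"
    counts: Mapping[int, int]

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts.values()))

    def __post_init__(self) -> None:
        if self.tissue not in ("tumor", "normal"):
            raise ValueError(f"tissue must be tumor/normal, got {self.tissue!r}")
        if any(k < 0 or v < 0 for k, v in self.counts.items()):
            raise ValueError("repeat numbers and read counts must be >= 0")


@dataclass(frozen=True)
class InstabilityCall:
    locus: str
    sample: str
    statistic: float
    p_value: float
    unstable: bool
    reason: str = ""


@dataclass
class SampleMSIProfile:
    """Set of loci called unstable in one sample."""

    sample: str
    histotype: str
    raw_unstable: set[str] = field(default_factory=set)

    @property
    def raw_event_count(self) -> int:
        return len(self.raw_unstable)


def _pool_low_expectation(table: np.ndarray) -> np.ndarray:
    """Merge adjacent repeat-length bins until every expected cell is >= 5.

    ``table`` is 2 x K (tumor, normal) over ordered repeat lengths.  The
    deficient bin with the smallest expected minimum is merged into its
    smaller-total adjacent neighbour (left on ties), which keeps pooling
    symmetric in the two tissues and deterministic.
    """
    t = table.astype(float)
    while t.shape[1] > 1:
        rows = t.sum(axis=1, keepdims=True)
        cols = t.sum(axis=0, keepdims=True)
        grand = t.sum()
        if grand == 0:
            break
        expected = rows @ cols / grand
        mins = expected.min(axis=0)
        if (mins >= 5).all():
            break
        j = int(np.argmin(mins))
        if j == 0:
            k = 1
        elif j == t.shape[1] - 1:
            k = j - 1
        else:
            k = j - 1 if cols[0, j - 1] <= cols[0, j + 1] else j + 1
        lo, hi = min(j, k), max(j, k)
        t[:, lo] += t[:, hi]
        t = np.delete(t, hi, axis=1)
    return t


def _chi2_homogeneity(tumor: np.ndarray, normal: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square homogeneity test on two count vectors.

    Bins with expected count < 5 are pooled into neighbours first; if a
    single bin remains the distributions are untestable and p = 1.
    """
    t = _pool_low_expectation(np.vstack([tumor, normal]))
    k = t.shape[1]
    if k < 2:
        return 0.0, 1.0
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    grand = t.sum()
    expected = rows @ cols / grand
    stat = float(((t - expected) ** 2 / expected).sum())
    return stat, float(chdtrc(k - 1, stat))


def test_locus(
    tumor: RepeatHistogram,
    normal: RepeatHistogram,
    alpha: float = DEFAULT_ALPHA,
    min_cov: int = DEFAULT_MIN_COV,
) -> InstabilityCall:
    """Two-sided chi-square comparison of tumor and normal repeat histograms.

    Loci where either tissue has fewer than ``min_cov`` reads are reported as
    stable with p = 1 (reason ``insufficient coverage``).  The test is
    symmetric: swapping tissues leaves the p-value unchanged.
    """
    if tumor.locus != normal.locus or tumor.sample != normal.sample:
        raise ValueError(
            f"mismatched histograms: {tumor.locus}/{tumor.sample} vs "
            f"{normal.locus}/{normal.sample}"
        )
    if tumor.total_reads < min_cov or normal.total_reads < min_cov:
        return InstabilityCall(
            tumor.locus, tumor.sample, 0.0, 1.0, False, "insufficient coverage"
        )
    support = sorted(set(tumor.counts) | set(normal.counts))
    t = np.array([tumor.counts.get(r, 0) for r in support], dtype=float)
    n = np.array([normal.counts.get(r, 0) for r in support], dtype=float)
    stat, p = _chi2_homogeneity(t, n)
    return InstabilityCall(tumor.locus, tumor.sample, stat, p, p <= alpha)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_sample(
    tumor_hists: Sequence[RepeatHistogram],
    normal_hists: Sequence[RepeatHistogram],
    sample: str,
    histotype: str,
    alpha: float = DEFAULT_ALPHA,
    min_cov: int = DEFAULT_MIN_COV,
    fdr: str | None = DEFAULT_FDR,
) -> tuple[SampleMSIProfile, list[InstabilityCall]]:
    """Call every locus of one sample and collect its unstable set.

    Tumor loci without a matched normal histogram are skipped (and logged);
    a duplicate locus within one tissue is an error.  With ``fdr="bh"``
    (default) significance is decided on Benjamini-Hochberg adjusted
    p-values across the sample's testable loci; ``fdr=None`` applies the raw
    per-locus threshold.
    """
    by_locus_n: dict[str, RepeatHistogram] = {}
    for h in normal_hists:
        if h.locus in by_locus_n:
            raise ValueError(f"duplicate normal histogram for locus {h.locus}")
        by_locus_n[h.locus] = h
    seen_t: set[str] = set()
    calls: list[InstabilityCall] = []
    for th in tumor_hists:
        if th.locus in seen_t:
            raise ValueError(f"duplicate tumor histogram for locus {th.locus}")
        seen_t.add(th.locus)
        nh = by_locus_n.get(th.locus)
        if nh is None:
            logger.info("sample %s: locus %s has no normal histogram; skipped",
                        sample, th.locus)
            continue
        calls.append(test_locus(th, nh, alpha=alpha, min_cov=min_cov))

    if fdr == "bh" and calls:
        tested = [i for i, c in enumerate(calls) if not c.reason]
        if tested:
            adj = _bh_adjust(np.array([calls[i].p_value for i in tested]))
            for i, a in zip(tested, adj):
                c = calls[i]
                calls[i] = InstabilityCall(
                    c.locus, c.sample, c.statistic, c.p_value, a <= alpha
                )
    elif fdr not in (None, "bh"):
        raise ValueError(f"unknown fdr method {fdr!r}")

    profile = SampleMSIProfile(
        sample, histotype, {c.locus for c in calls if c.unstable}
    )
    return profile, calls


def call_cohort(
    hist_df: pd.DataFrame,
    histotypes: Mapping[str, str],
    alpha: float = DEFAULT_ALPHA,
    min_cov: int = DEFAULT_MIN_COV,
    fdr: str | None = DEFAULT_FDR,
) -> tuple[list[SampleMSIProfile], list[InstabilityCall]]:
    """Run :func:`call_sample` for every sample in a histogram table.

    ``hist_df`` has columns locus_key, sample, tissue, repeat_count,
    read_count; ``histotypes`` maps sample id to histotype label.
    """
    required = {"locus_key", "sample", "tissue", "repeat_count", "read_count"}
    missing = required - set(hist_df.columns)
    if missing:
        raise ValueError(f"histogram table missing columns {sorted(missing)}")
    profiles: list[SampleMSIProfile] = []
    all_calls: list[InstabilityCall] = []
    for sample, sdf in hist_df.groupby("sample", sort=True):
        sample = str(sample)
        if sample not in histotypes:
            raise ValueError(f"sample {sample!r} missing from sample sheet")
        # aggregate counts over plain arrays (hot path for large cohorts)
        loci = sdf["locus_key"].to_numpy()
        tissues = sdf["tissue"].to_numpy()
        reps = sdf["repeat_count"].to_numpy()
        reads = sdf["read_count"].to_numpy()
        counts: dict[tuple[str, str], dict[int, int]] = {}
        order: dict[str, list[str]] = {"tumor": [], "normal": []}
        for locus, tissue, rep, read in zip(loci, tissues, reps, reads):
            key = (locus, tissue)
            if key not in counts:
                counts[key] = {}
                order[tissue].append(locus)
            counts[key][int(rep)] = counts[key].get(int(rep), 0) + int(read)
        hists = {
            tissue: [RepeatHistogram(l, sample, tissue, counts[(l, tissue)])
                     for l in sorted(order[tissue])]
            for tissue in ("tumor", "normal")
        }
        profile, calls = call_sample(
            hists["tumor"], hists["normal"], sample,
            histotypes[sample], alpha=alpha, min_cov=min_cov, fdr=fdr,
        )
        profiles.append(profile)
        all_calls.extend(calls)
    return profiles, all_calls


# ---------------------------------------------------------------------------
# TSV interfaces

_HIST_COLUMNS = ["locus_key", "sample", "tissue", "repeat_count", "read_count"]
_CALL_COLUMNS = ["locus_key", "sample", "statistic", "p_value", "unstable"]


def read_histograms(path: str | Path | TextIO) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_HIST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"histogram TSV missing columns {sorted(missing)}")
    return df


def write_histograms(df: pd.DataFrame, path: str | Path | TextIO) -> None:
    df.to_csv(path, sep="\t", index=False, columns=_HIST_COLUMNS)


def write_calls(calls: Iterable[InstabilityCall], path: str | Path | TextIO) -> None:
    rows = [
        (c.locus, c.sample, f"{c.statistic:.6g}", f"{c.p_value:.6g}", int(c.unstable))
        for c in calls
    ]
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path | TextIO) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calls TSV missing columns {sorted(missing)}")
    df["unstable"] = df["unstable"].astype(bool)
    return df
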