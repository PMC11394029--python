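"""Recurrent-locus panel, per-sample MSI burden, and MSI category calls.

The cohort's unstable-locus calls are filtered to the loci recurrently
affected in at least ``min_samples`` distinct samples (the recurrent panel;
histotypes whose event load would swamp the filter can be excluded from the
support counting but still receive scores).  Each sample's MSI burden is the
fraction of panel loci unstable in that sample.  Categories:

* ``MSS``       — no unstable loci at all (raw event count 0);
* ``EXCLUDED``  — only patient-specific events (raw events, none on the panel);
* ``MSI-H``     — burden above the cohort mean burden;
* ``MSI-L``     — burden at or below the mean.

By default the mean is taken over the classifiable samples (those with at
least one panel locus affected); a switch averages over all samples instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .instability_caller import SampleMSIProfile

__all__ = [
    "RecurrentPanel",
    "BurdenRecord",
    "CATEGORIES",
    "build_panel",
    "msi_burden",
    "classify_cohort",
    "write_panel",
    "read_panel",
    "write_burden",
    "read_burden",
    "write_summary",
]

CATEGORIES = ("MSI-H", "MSI-L", "MSS", "EXCLUDED")
DEFAULT_MIN_SAMPLES = 5


@dataclass(frozen=True)
class RecurrentPanel:
    """Loci unstable in >= min_samples distinct (non-excluded) samples."""

    loci: frozenset[str]
    per_locus_support: Mapping[str, int]
    min_samples: int
    excluded_histotypes: frozenset[str] = frozenset()

    @property
    def size(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class BurdenRecord:
    sample: str
    histotype: str
    n_recurrent_affected: int
    panel_size: int
    burden: float  # fraction in [0, 1]
    raw_event_count: int
    category: str | None = None

    @property
    def burden_pct(self) -> float:
        return 100.0 * self.burden


def build_panel(
    profiles: Sequence[SampleMSIProfile],
    min_samples: int = DEFAULT_MIN_SAMPLES,
    excluded_histotypes: Iterable[str] = (),
) -> RecurrentPanel:
    """Count per-locus sample support and keep recurrent loci.

    Support counts distinct samples (events at one locus in one sample count
    once); samples of excluded histotypes contribute nothing to support.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    excluded = frozenset(excluded_histotypes)
    support: dict[str, int] = {}
    for p in profiles:
        if p.histotype in excluded:
            continue
        for locus in p.raw_unstable:
            support[locus] = support.get(locus, 0) + 1
    loci = frozenset(k for k, n in support.items() if n >= min_samples)
    return RecurrentPanel(loci, support, min_samples, excluded)


def msi_burden(profile: SampleMSIProfile, panel: RecurrentPanel) -> BurdenRecord:
    """Fraction of panel loci unstable in one sample (category left unset)."""
    if panel.size == 0:
        raise ValueError("empty recurrent panel: no burden is defined")
    affected = len(profile.raw_unstable & panel.loci)
    return BurdenRecord(
        sample=profile.sample,
        histotype=profile.histotype,
        n_recurrent_affected=affected,
        panel_size=panel.size,
        burden=affected / panel.size,
        raw_event_count=profile.raw_event_count,
    )


def classify_cohort(
    records: Sequence[BurdenRecord],
    threshold_population: str = "classified",
) -> tuple[list[BurdenRecord], float | None]:
    """Assign MSI categories; returns (records, threshold).

    The threshold is the mean burden over the classifiable samples
    (``n_recurrent_affected >= 1``), or over all samples when
    ``threshold_population="all"``.  MSI-H requires burden strictly above the
    threshold.  A cohort with no classifiable sample gets MSS/EXCLUDED labels
    only and a ``None`` threshold.
    """
    if threshold_population not in ("classified", "all"):
        raise ValueError(f"unknown threshold population {threshold_population!r}")
    classifiable = [r for r in records if r.n_recurrent_affected >= 1]
    if classifiable:
        pop = records if threshold_population == "all" else classifiable
        threshold = sum(r.burden for r in pop) / len(pop)
    else:
        threshold = None
    out = []
    for r in records:
        if r.raw_event_count == 0:
            cat = "MSS"
        elif r.n_recurrent_affected == 0:
            cat = "EXCLUDED"
        else:
            cat = "MSI-H" if r.burden > threshold else "MSI-L"
        out.append(replace(r, category=cat))
    return out, threshold


# ---------------------------------------------------------------------------
# TSV / JSON interfaces

_BURDEN_COLUMNS = [
    "sample", "histotype", "n_recurrent_affected", "panel_size",
    "burden_pct", "raw_event_count", "category",
]


def write_panel(panel: RecurrentPanel, path: str | Path | TextIO) -> None:
    rows = sorted(
        (k, panel.per_locus_support.get(k, 0)) for k in panel.loci
    )
    pd.DataFrame(rows, columns=["locus_key", "support"]).to_csv(
        path, sep="\t", index=False
    )


def read_panel(path: str | Path | TextIO, min_samples: int = DEFAULT_MIN_SAMPLES) -> RecurrentPanel:
    df = pd.read_csv(path, sep="\t")
    support = dict(zip(df["locus_key"], df["support"].astype(int)))
    return RecurrentPanel(frozenset(support), support, min_samples)


def write_burden(records: Sequence[BurdenRecord], path: str | Path | TextIO) -> None:
    rows = [
        (r.sample, r.histotype, r.n_recurrent_affected, r.panel_size,
         f"{r.burden_pct:.6g}", r.raw_event_count, r.category or "")
        for r in sorted(records, key=lambda r: r.sample)
    ]
    pd.DataFrame(rows, columns=_BURDEN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_burden(path: str | Path | TextIO) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_BURDEN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"burden TSV missing columns {sorted(missing)}")
    return df


def write_summary(
    records: Sequence[BurdenRecord],
    threshold: float | None,
    panel: RecurrentPanel,
    path: str | Path,
) -> dict:
    """JSON cohort summary: threshold, panel size, category counts."""
    counts = {c: sum(1 for r in records if r.category == c) for c in CATEGORIES}
    summary = {
        "n_samples": len(records),
        "panel_size": panel.size,
        "min_samples": panel.min_samples,
        "excluded_histotypes": sorted(panel.excluded_histotypes),
        "threshold_burden_pct": None if threshold is None else 100.0 * threshold,
        "category_counts": counts,
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
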