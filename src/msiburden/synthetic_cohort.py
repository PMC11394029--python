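"""Seeded synthetic tumor-normal cohorts with planted ground truth.

The generator emulates the statistical structure a cohort-level MSI analysis
assumes, at desk scale:

* a small multi-chromosome reference carrying planted microsatellites — a
  shared "panel" of recurrently unstable loci plus background loci that only
  ever acquire patient-specific events;
* per-histotype locus instability rates spanning orders of magnitude
  (B-cell-lymphoma-like 0.19 down to T-cell-lymphoma-like 0.001);
* tumor/normal repeat-length read histograms with a symmetric +-1 stutter
  kernel, tumor distributions shifted at unstable loci;
* a linear-with-noise TMB coupling ``TMB = base + slope * burden + eps``
  (truncated at 0) realised as per-sample coding-mutation counts;
* three imperfect callers with configurable sensitivities and false-call
  rates, a fraction of artifacts shared with the Panel of Normals.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .reference_scan import MicrosatelliteLocus, scan_sequence, write_sites
from .variant_consensus import NormalizedVariant, VariantKey, write_vcf

__all__ = [
    "HistotypeSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_config",
    "PAPER_SCALE_TEMPLATE",
    "generate_reference",
    "generate_cohort",
    "generate_caller_vcfs",
    "closed_form_r",
    "generate_tmb_shift_groups",
    "write_simulation",
]

BASES = np.array(list("ACGT"))

#: Histotype template: (label, cohort share at 1x, panel-locus instability
#: rate, patient-specific background rate).  Sizes mirror a 692-sample
#: canine pan-cancer cohort; rates span the orders of magnitude seen there
#: (median burden ~19% in B-cell lymphoma down to ~0.05% in T-cell
#: lymphoma), with mid histotypes at 3-6% so the recurrence filter is
#: satisfiable at desk scale.
PAPER_SCALE_TEMPLATE: tuple[tuple[str, int, float, float], ...] = (
    ("melanoma", 137, 0.05, 0.002),
    ("mammary_carcinoma", 136, 0.06, 0.002),
    ("b_cell_lymphoma", 103, 0.19, 0.004),
    ("osteosarcoma", 98, 0.05, 0.002),
    ("t_cell_lymphoma", 65, 0.001, 0.001),
    ("hemangiosarcoma", 64, 0.06, 0.002),
    ("glioma", 52, 0.04, 0.002),
    ("mast_cell_tumor", 28, 0.03, 0.002),
    ("pulmonary_adenocarcinoma", 5, 0.10, 0.002),
    ("urinary_carcinoma", 4, 0.05, 0.002),
)


@dataclass(frozen=True)
class HistotypeSpec:
    label: str
    n_samples: int
    locus_instability_rate: float  # per panel locus
    patient_specific_rate: float  # per background locus

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for r in (self.locus_instability_rate, self.patient_specific_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    histotypes: tuple[HistotypeSpec, ...] = ()
    panel_size: int = 120
    n_background_loci: int = 240
    coverage: float = 100.0
    shift_magnitude: int = 3
    stutter_prob: float = 0.1  # per side, +-1 repeat
    tmb_base: float = 0.5
    tmb_slope: float = 8.0
    tmb_noise_sd: float = 0.25
    denominator_mb: float = 57.0
    caller_sensitivities: tuple[float, float, float] = (0.95, 0.95, 0.95)
    caller_fp_rate: float = 0.02  # expected false calls per true variant
    pon_contamination_rate: float = 0.5
    noncoding_fraction: float = 0.2  # extra noncoding variants per sample

    def __post_init__(self) -> None:
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.n_background_loci < 0:
            raise ValueError("n_background_loci must be >= 0")
        if not self.histotypes:
            raise ValueError("at least one histotype is required")
        for r in (*self.caller_sensitivities, self.caller_fp_rate,
                  self.pon_contamination_rate, self.stutter_prob):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates/probabilities must lie in [0, 1]")
        if self.shift_magnitude < 1:
            raise ValueError("shift_magnitude must be >= 1")

    @property
    def n_samples(self) -> int:
        return sum(h.n_samples for h in self.histotypes)


def default_config(seed: int = 0, scale: float = 0.2, **overrides) -> SimulationConfig:
    """The default cohort at a given scale of the 692-sample template."""
    hist = tuple(
        HistotypeSpec(label, max(1, round(n * scale)), rate, ps)
        for label, n, rate, ps in PAPER_SCALE_TEMPLATE
    )
    return SimulationConfig(seed=seed, histotypes=hist, **overrides)


@dataclass
class GroundTruth:
    """Planted truth for one generated cohort."""

    panel_loci: list[str]
    background_loci: list[str]
    samples: list[str]
    histotype_by_sample: dict[str, str]
    unstable_by_sample: dict[str, set[str]]  # panel + background events
    true_burden: dict[str, float]  # vs. the planted panel
    true_category: dict[str, str]
    true_threshold: float | None
    n_coding: dict[str, int]
    true_tmb: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["unstable_by_sample"] = {
            k: sorted(v) for k, v in self.unstable_by_sample.items()
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)


# ---------------------------------------------------------------------------
# reference generation

def _random_flank(rng: np.random.Generator, length: int, forbidden_first: str = "",
                  forbidden_last: str = "") -> str:
    """Random sequence with no base repeated more than 3 times in a row.

    Keeping homopolymer runs short guarantees the flank itself contains no
    microsatellite at the default scan thresholds; the first/last base can be
    constrained so a flank never extends an adjacent planted repeat.
    """
    out: list[str] = []
    while len(out) < length:
        b = str(rng.choice(BASES))
        if len(out) >= 3 and out[-1] == out[-2] == out[-3] == b:
            continue
        if not out and b in forbidden_first:
            continue
        if len(out) == length - 1 and b in forbidden_last:
            continue
        out.append(b)
    return "".join(out)


_MOTIF_POOL = ("A", "C", "AT", "AG", "AC", "AAT", "AAG", "AAAT", "AAAG")
_COPIES_BY_LEN = {1: (10, 16), 2: (6, 12), 3: (5, 9), 4: (4, 7)}


def generate_reference(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    loci_per_chrom: int = 40,
    flank_len: int = 30,
) -> tuple[dict[str, str], list[MicrosatelliteLocus]]:
    """Synthesize a reference carrying exactly the planted microsatellites.

    Returns ``(sequences by chromosome, planted site list)``.  Scanning the
    FASTA at default parameters recovers the planted loci exactly: flanks are
    repeat-free and junction bases are chosen so they cannot extend a planted
    run.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_total = config.panel_size + config.n_background_loci
    seqs: dict[str, str] = {}
    planted: list[MicrosatelliteLocus] = []
    placed = 0
    chrom_idx = 0
    while placed < n_total:
        chrom_idx += 1
        chrom = f"chr{chrom_idx}"
        n_here = min(loci_per_chrom, n_total - placed)
        # random flanks occasionally contain an accidental short-motif repeat;
        # rebuild the chromosome until the scanner recovers exactly the plant
        for _attempt in range(100):
            parts: list[str] = []
            chrom_loci: list[MicrosatelliteLocus] = []
            pos = 0
            prev_forbidden = ""
            for _ in range(n_here):
                motif = _MOTIF_POOL[rng.integers(len(_MOTIF_POOL))]
                lo, hi = _COPIES_BY_LEN[len(motif)]
                copies = int(rng.integers(lo, hi + 1))
                # flank may not end with the motif's last base (would shift
                # the run's left edge) nor begin with the previous motif's
                # first base (would extend the previous run)
                flank = _random_flank(rng, flank_len,
                                      forbidden_first=prev_forbidden,
                                      forbidden_last=motif[-1])
                parts.append(flank)
                pos += len(flank)
                run = motif * copies
                chrom_loci.append(
                    MicrosatelliteLocus(chrom, pos, pos + len(run), motif, copies)
                )
                parts.append(run)
                pos += len(run)
                prev_forbidden = motif[0]
            parts.append(_random_flank(rng, flank_len, forbidden_first=prev_forbidden))
            seq = "".join(parts)
            recovered = scan_sequence(seq, chrom)
            if [(l.start, l.end, l.motif) for l in recovered] == [
                (l.start, l.end, l.motif) for l in chrom_loci
            ]:
                break
        else:  # pragma: no cover - rebuild converges in a handful of tries
            raise RuntimeError(f"could not build a clean chromosome {chrom}")
        seqs[chrom] = seq
        planted.extend(chrom_loci)
        placed += n_here
    return seqs, sorted(planted, key=lambda l: (int(l.chrom[3:]), l.start))


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class CohortData:
    histograms: pd.DataFrame  # locus_key, sample, tissue, repeat_count, read_count
    sample_sheet: pd.DataFrame  # sample, histotype
    truth: GroundTruth
    reference: dict[str, str] = field(default_factory=dict)
    planted: list[MicrosatelliteLocus] = field(default_factory=list)


def _histogram_rows(
    rng: np.random.Generator,
    sample: str,
    tissue: str,
    locus_keys: Sequence[str],
    centers: np.ndarray,
    coverage: float,
    stutter: float,
) -> list[tuple]:
    """Multinomial read histograms around per-locus centers, vectorized."""
    n = len(locus_keys)
    cov = rng.poisson(coverage, size=n)
    kernel = np.array([stutter, 1.0 - 2.0 * stutter, stutter])
    counts = rng.multinomial(cov, kernel)  # n x 3 over offsets -1, 0, +1
    rows = []
    for i, key in enumerate(locus_keys):
        for off in range(3):
            c = int(counts[i, off])
            if c > 0:
                rep = int(centers[i]) + off - 1
                rows.append((key, sample, tissue, max(rep, 0), c))
    return rows


def generate_cohort(
    config: SimulationConfig,
    with_histograms: bool = True,
    reference: tuple[dict[str, str], list[MicrosatelliteLocus]] | None = None,
) -> CohortData:
    """Generate a full cohort: histograms, sample sheet and ground truth.

    With ``with_histograms=False`` only the ground truth (unstable sets,
    burden, categories, mutation counts, TMB) is drawn — useful for large
    statistical checks that do not exercise the read-level model.
    """
    rng = np.random.default_rng(config.seed)
    if reference is None:
        seqs, planted = generate_reference(config, rng)
    else:
        seqs, planted = reference
    keys = [l.locus_key for l in sorted(planted, key=lambda l: (l.chrom, l.start))]
    # deterministic assignment: panel loci drawn without replacement
    order = rng.permutation(len(keys))
    panel_keys = sorted(keys[i] for i in order[: config.panel_size])
    background_keys = sorted(keys[i] for i in order[config.panel_size :])
    ref_repeats = {l.locus_key: l.ref_repeats for l in planted}

    samples, hist_by_sample = [], {}
    unstable: dict[str, set[str]] = {}
    rows: list[tuple] = []
    for spec in config.histotypes:
        for j in range(spec.n_samples):
            sid = f"{spec.label}_{j:03d}"
            samples.append(sid)
            hist_by_sample[sid] = spec.label
            u_panel = np.asarray(panel_keys)[
                rng.random(len(panel_keys)) < spec.locus_instability_rate
            ]
            u_bg = np.asarray(background_keys)[
                rng.random(len(background_keys)) < spec.patient_specific_rate
            ]
            unstable[sid] = set(map(str, u_panel)) | set(map(str, u_bg))
            if with_histograms:
                all_keys = panel_keys + background_keys
                centers = np.array([ref_repeats[k] for k in all_keys])
                rows.extend(
                    _histogram_rows(rng, sid, "normal", all_keys, centers,
                                    config.coverage, config.stutter_prob)
                )
                t_centers = np.array([
                    max(ref_repeats[k] - config.shift_magnitude, 1)
                    if k in unstable[sid] else ref_repeats[k]
                    for k in all_keys
                ])
                rows.extend(
                    _histogram_rows(rng, sid, "tumor", all_keys, t_centers,
                                    config.coverage, config.stutter_prob)
                )

    panel_set = set(panel_keys)
    true_burden = {
        s: len(unstable[s] & panel_set) / config.panel_size for s in samples
    }
    # true categories under the generator's own mean-over-classified threshold
    classifiable = [s for s in samples if unstable[s] & panel_set]
    threshold = (
        sum(true_burden[s] for s in classifiable) / len(classifiable)
        if classifiable else None
    )
    category = {}
    for s in samples:
        if not unstable[s]:
            category[s] = "MSS"
        elif not (unstable[s] & panel_set):
            category[s] = "EXCLUDED"
        else:
            category[s] = "MSI-H" if true_burden[s] > threshold else "MSI-L"

    # TMB coupling: counts implied by a linear-with-noise model, truncated
    eps = rng.normal(0.0, config.tmb_noise_sd, size=len(samples))
    n_coding, true_tmb = {}, {}
    for s, e in zip(samples, eps):
        tmb = max(config.tmb_base + config.tmb_slope * true_burden[s] + e, 0.0)
        n = int(round(tmb * config.denominator_mb))
        n_coding[s] = n
        true_tmb[s] = n / config.denominator_mb

    truth = GroundTruth(
        panel_loci=panel_keys,
        background_loci=background_keys,
        samples=samples,
        histotype_by_sample=hist_by_sample,
        unstable_by_sample=unstable,
        true_burden=true_burden,
        true_category=category,
        true_threshold=threshold,
        n_coding=n_coding,
        true_tmb=true_tmb,
    )
    hist_df = pd.DataFrame(
        rows, columns=["locus_key", "sample", "tissue", "repeat_count", "read_count"]
    )
    sheet = pd.DataFrame(
        {"sample": samples, "histotype": [hist_by_sample[s] for s in samples]}
    )
    return CohortData(hist_df, sheet, truth, seqs, planted)


# ---------------------------------------------------------------------------
# caller call-sets

CALLER_NAMES = ("caller_A", "caller_B", "caller_C")
_EFFECT_CHOICES = ("nonsynonymous", "synonymous")


def _draw_variant(rng: np.random.Generator, chroms: Sequence[str],
                  chrom_len: dict[str, int], effect: str) -> NormalizedVariant:
    chrom = chroms[int(rng.integers(len(chroms)))]
    pos = int(rng.integers(1, chrom_len[chrom] + 1))
    ref, alt = rng.choice(BASES, size=2, replace=False)
    return NormalizedVariant(chrom, pos, str(ref), str(alt), effect=effect)


def generate_caller_vcfs(
    config: SimulationConfig,
    truth: GroundTruth,
    reference: dict[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, list[NormalizedVariant]]], set[VariantKey],
           dict[str, list[NormalizedVariant]]]:
    """Per-sample call-sets for three imperfect callers, plus the PON.

    Returns ``(callsets, pon_keys, truth_variants)`` where ``callsets`` maps
    sample -> caller -> variant list.  Each true variant enters caller *i*
    independently with probability ``caller_sensitivities[i]``; each caller
    additionally reports private false positives (Poisson, expected
    ``caller_fp_rate`` per true variant); a ``pon_contamination_rate``
    fraction of artifacts is also recorded in the PON.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    chroms = sorted(reference)
    chrom_len = {c: len(reference[c]) for c in chroms}
    sens = config.caller_sensitivities
    pon: set[VariantKey] = set()
    callsets: dict[str, dict[str, list[NormalizedVariant]]] = {}
    truths: dict[str, list[NormalizedVariant]] = {}
    for sample in truth.samples:
        n_cod = truth.n_coding[sample]
        n_noncod = rng.poisson(config.noncoding_fraction * max(n_cod, 1))
        true_vars: dict[VariantKey, NormalizedVariant] = {}
        while len(true_vars) < n_cod:
            v = _draw_variant(rng, chroms, chrom_len,
                              _EFFECT_CHOICES[int(rng.random() < 0.4)])
            true_vars.setdefault(v.key, v)
        while len(true_vars) < n_cod + n_noncod:
            v = _draw_variant(rng, chroms, chrom_len, "noncoding")
            true_vars.setdefault(v.key, v)
        truths[sample] = list(true_vars.values())
        per_caller: dict[str, list[NormalizedVariant]] = {}
        for i, caller in enumerate(CALLER_NAMES):
            detected = [v for v in true_vars.values() if rng.random() < sens[i]]
            n_fp = rng.poisson(config.caller_fp_rate * max(n_cod, 1))
            for _ in range(n_fp):
                fp = _draw_variant(rng, chroms, chrom_len, "other")
                if fp.key in true_vars:
                    continue
                detected.append(fp)
                if rng.random() < config.pon_contamination_rate:
                    pon.add(fp.key)
            per_caller[caller] = detected
        callsets[sample] = per_caller
    return callsets, pon, truths


def closed_form_r(config: SimulationConfig, burden_sd: float) -> float:
    """Pearson correlation implied by the linear TMB coupling.

    r = slope * sigma_burden / sqrt(slope^2 sigma_burden^2 + sigma_noise^2);
    exact for the untruncated model, approximate once truncation at zero or
    count rounding bites.
    """
    s = config.tmb_slope * burden_sd
    return s / float(np.sqrt(s * s + config.tmb_noise_sd**2))


def generate_tmb_shift_groups(
    n1: int = 30,
    n2: int = 30,
    delta: float = 0.86,
    sd: float = 1.0,
    base: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two TMB-like groups with a planted location shift of ``delta``.

    The default effect size d = 0.86 at n = 30 per group gives the
    rank-sum test ~0.9 power at alpha = 0.05 (t-test power formula with
    asymptotic relative efficiency 0.955).  ``delta=0`` generates the null.
    """
    if rng is None:
        rng = np.random.default_rng()
    x = np.maximum(rng.normal(base, sd, n1), 0.0)
    y = np.maximum(rng.normal(base + delta, sd, n2), 0.0)
    return x, y


# ---------------------------------------------------------------------------
# file emission

def write_simulation(config: SimulationConfig, outdir: str | Path,
                     with_vcfs: bool = True) -> CohortData:
    """Emit a complete simulated input set under ``outdir``.

    Writes reference.fa, sites.tsv (planted), hist.tsv, samples.tsv,
    ground_truth.json, and (optionally) per-sample caller VCFs plus pon.vcf.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    write_fasta(cohort.reference, outdir / "reference.fa")
    write_sites(
        sorted(cohort.planted, key=lambda l: (l.chrom, l.start)),
        outdir / "sites.tsv",
    )
    cohort.histograms.to_csv(outdir / "hist.tsv", sep="\t", index=False)
    cohort.sample_sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    cohort.truth.to_json(outdir / "ground_truth.json")
    if with_vcfs:
        callsets, pon, _ = generate_caller_vcfs(config, cohort.truth,
                                                cohort.reference)
        vcf_dir = outdir / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        contigs = sorted(cohort.reference)
        for sample, per_caller in callsets.items():
            for caller, variants in per_caller.items():
                write_vcf(variants, vcf_dir / f"{sample}.{caller}.vcf", contigs)
        write_vcf(
            [NormalizedVariant(*k) for k in sorted(pon)],
            outdir / "pon.vcf", contigs,
        )
    return cohort
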