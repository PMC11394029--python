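"""Synthetic cohort generator: determinism, planted-truth consistency."""

import numpy as np
import pytest

from msiburden.reference_scan import scan_sequence
from msiburden.synthetic_cohort import (
    HistotypeSpec,
    SimulationConfig,
    closed_form_r,
    default_config,
    generate_caller_vcfs,
    generate_cohort,
    generate_reference,
    generate_tmb_shift_groups,
    write_simulation,
)
from msiburden.variant_consensus import consensus_vote


def tiny_config(seed=0, **kw):
    defaults = dict(
        seed=seed,
        histotypes=(
            HistotypeSpec("hi", 6, 0.3, 0.01),
            HistotypeSpec("lo", 6, 0.01, 0.01),
        ),
        panel_size=10,
        n_background_loci=10,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestReference:
    def test_scanner_recovers_planted_loci_exactly(self):
        config = tiny_config()
        seqs, planted = generate_reference(config)
        recovered = []
        for chrom in sorted(seqs):
            recovered.extend(scan_sequence(seqs[chrom], chrom))
        assert {(l.chrom, l.start, l.end, l.motif) for l in recovered} == {
            (l.chrom, l.start, l.end, l.motif) for l in planted
        }
        assert len(planted) == config.panel_size + config.n_background_loci

    def test_zero_background_site_list_is_panel_size(self):
        config = tiny_config(n_background_loci=0)
        _, planted = generate_reference(config)
        assert len(planted) == config.panel_size

    def test_same_seed_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            write_simulation(tiny_config(seed=7), tmp_path / d, with_vcfs=False)
        for name in ("reference.fa", "sites.tsv", "hist.tsv", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name

    def test_panel_size_validation(self):
        with pytest.raises(ValueError):
            tiny_config(panel_size=0)


class TestCohort:
    def test_null_cohort_all_stable(self):
        config = tiny_config(histotypes=(HistotypeSpec("h", 8, 0.0, 0.0),))
        cohort = generate_cohort(config, with_histograms=False)
        assert all(b == 0.0 for b in cohort.truth.true_burden.values())
        assert all(c == "MSS" for c in cohort.truth.true_category.values())

    def test_saturated_histotype_burden_one(self):
        config = tiny_config(histotypes=(HistotypeSpec("h", 4, 1.0, 0.0),))
        cohort = generate_cohort(config, with_histograms=False)
        assert all(b == 1.0 for b in cohort.truth.true_burden.values())

    def test_histograms_consistent_with_truth(self):
        """Shifted tumor modes appear exactly at planted unstable loci."""
        config = tiny_config(coverage=200, shift_magnitude=3)
        cohort = generate_cohort(config)
        df = cohort.histograms
        ref_reps = {l.locus_key: l.ref_repeats for l in cohort.planted}
        for sample in cohort.truth.samples[:4]:
            for locus in cohort.truth.panel_loci:
                sub = df[(df["sample"] == sample) & (df["locus_key"] == locus)
                         & (df["tissue"] == "tumor")]
                mode = int(sub.loc[sub["read_count"].idxmax(), "repeat_count"])
                expected = ref_reps[locus] - (
                    config.shift_magnitude
                    if locus in cohort.truth.unstable_by_sample[sample] else 0
                )
                assert mode == max(expected, 1)

    def test_tmb_consistent_with_counts(self):
        cohort = generate_cohort(tiny_config(), with_histograms=False)
        for s in cohort.truth.samples:
            assert cohort.truth.true_tmb[s] == pytest.approx(
                cohort.truth.n_coding[s] / 57.0
            )


class TestCallers:
    def test_perfect_callers_reproduce_truth(self):
        config = tiny_config(caller_sensitivities=(1.0, 1.0, 1.0), caller_fp_rate=0.0)
        cohort = generate_cohort(config, with_histograms=False)
        callsets, pon, truths = generate_caller_vcfs(
            config, cohort.truth, cohort.reference)
        assert pon == set()
        for s in cohort.truth.samples:
            cons = consensus_vote(callsets[s])
            assert {v.key for v in cons} == {v.key for v in truths[s]}

    def test_two_perfect_callers_suffice(self):
        config = tiny_config(caller_sensitivities=(1.0, 1.0, 0.0), caller_fp_rate=0.0)
        cohort = generate_cohort(config, with_histograms=False)
        callsets, _, truths = generate_caller_vcfs(
            config, cohort.truth, cohort.reference)
        for s in cohort.truth.samples[:4]:
            cons = consensus_vote(callsets[s])
            assert {v.key for v in cons} == {v.key for v in truths[s]}

    def test_consensus_recall_near_closed_form(self):
        """sens (0.9,0.9,0.9): recall ~ 3*0.81*0.1 + 0.729 = 0.972."""
        config = tiny_config(
            caller_sensitivities=(0.9, 0.9, 0.9), caller_fp_rate=0.0,
            tmb_base=3.0, tmb_slope=0.0, tmb_noise_sd=0.0,
            histotypes=(HistotypeSpec("h", 12, 0.1, 0.0),),
        )
        cohort = generate_cohort(config, with_histograms=False)
        callsets, _, truths = generate_caller_vcfs(
            config, cohort.truth, cohort.reference)
        found = total = 0
        for s in cohort.truth.samples:
            keys = {v.key for v in consensus_vote(callsets[s])}
            total += len(truths[s])
            found += sum(1 for v in truths[s] if v.key in keys)
        assert total > 1500
        assert found / total == pytest.approx(0.972, abs=0.02)


class TestCoupling:
    def test_closed_form_r_matches_large_sample(self):
        config = default_config(seed=3, scale=1.0)
        cohort = generate_cohort(config, with_histograms=False)
        burdens = np.array([cohort.truth.true_burden[s] for s in cohort.truth.samples])
        tmbs = np.array([cohort.truth.true_tmb[s] for s in cohort.truth.samples])
        target = closed_form_r(config, float(burdens.std()))
        observed = np.corrcoef(burdens, tmbs)[0, 1]
        assert observed == pytest.approx(target, abs=0.1)

    def test_shift_groups_null_and_alternative(self, rng):
        x, y = generate_tmb_shift_groups(delta=0.0, rng=rng)
        assert len(x) == len(y) == 30
        x2, y2 = generate_tmb_shift_groups(delta=5.0, rng=rng)
        assert np.median(y2) > np.median(x2)


def test_default_template_spans_orders_of_magnitude():
    config = default_config()
    rates = [h.locus_instability_rate for h in config.histotypes]
    assert max(rates) / min(rates) >= 100
    assert config.n_samples == 139  # 0.2x of the 692-sample template
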