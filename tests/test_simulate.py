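"""Simulator determinism, label consistency, validation and expectations."""

import dataclasses
import math

import numpy as np
import pytest

from artsrna import (
    ConfigError,
    ReadSet,
    SimConfig,
    collapse,
    map_exact,
    simulate_library,
    study_config,
    truth_expectations,
)
from artsrna.pipeline import estimate_statistics, recovery_table
from artsrna.simulate import make_study_references


def pure_config(seed=5, n_reads=500, **overrides):
    """Config with a single active class (guide by default)."""
    spec, target, site = make_study_references()
    base = dict(
        seed=seed,
        n_reads=n_reads,
        precursor=spec,
        target=target,
        target_site=site,
        w_guide_accurate=1.0,
        w_guide_jitter=0.0,
        w_star=0.0,
        w_degradation=0.0,
        w_phased=0.0,
        w_background=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


def test_identical_seed_identical_library(tmp_path):
    cfg = study_config(11, n_reads=2_000)
    lib1, truth1 = simulate_library(cfg)
    lib2, truth2 = simulate_library(cfg)
    assert lib1.reads == lib2.reads
    assert truth1.records == truth2.records
    from artsrna import write_fasta

    p1 = write_fasta(lib1, tmp_path / "a.fasta")
    p2 = write_fasta(lib2, tmp_path / "b.fasta")
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seed_different_library():
    lib1, _ = simulate_library(study_config(1, n_reads=2_000))
    lib2, _ = simulate_library(study_config(2, n_reads=2_000))
    assert lib1.reads != lib2.reads


def test_labels_consistent_with_sequences():
    cfg = study_config(3, n_reads=3_000, phased_share=0.1, phase_fidelity=0.7)
    lib, truth = simulate_library(cfg)
    guide, star = cfg.guide, cfg.star_seq
    phase_pos = set(cfg.phase_position_list())
    pre, tgt = cfg.precursor.ref.sequence, cfg.target.sequence
    assert sum(truth.class_counts.values()) == cfg.n_reads
    for (seq, _), (_, label, ref, start, strand) in zip(lib.reads, truth.records):
        if label == "guide_accurate":
            assert seq == guide
        elif label == "star":
            assert seq == star
        elif label in ("guide_jitter", "degradation"):
            assert pre[start : start + len(seq)] == seq
        elif label == "phased_in":
            origin = start + 2 if strand == "-" else start
            assert origin in phase_pos
        elif label == "phased_off":
            origin = start + 2 if strand == "-" else start
            assert (origin - cfg.cleavage.p0) % 21 != 0
        else:  # background: maps nowhere, by construction
            assert seq not in pre and seq not in tgt


def test_background_reads_never_map():
    cfg = pure_config(w_guide_accurate=0.0, w_background=1.0, n_reads=200)
    lib, _ = simulate_library(cfg)
    refs = [cfg.precursor.ref, cfg.target]
    assert map_exact(collapse(lib), refs) == []


@pytest.mark.parametrize(
    "overrides,message",
    [
        (dict(w_background=0.5), "sum"),
        (dict(n_reads=0), "n_reads"),
        (dict(phase_fidelity=1.5), "fidelity"),
        (dict(w_guide_accurate=0.5, w_guide_jitter=0.5), "jitter table"),
    ],
)
def test_config_validation_errors(overrides, message):
    with pytest.raises(ConfigError, match=message):
        simulate_library(pure_config(**overrides))


def test_jitter_cell_out_of_bounds_rejected():
    cfg = pure_config(
        w_guide_accurate=0.5, w_guide_jitter=0.5, jitter=(((-200, 21), 1.0),)
    )
    with pytest.raises(ConfigError, match="bounds"):
        cfg.validate()


def test_jitter_accurate_cell_rejected():
    cfg = pure_config(w_guide_accurate=0.5, w_guide_jitter=0.5, jitter=(((0, 21), 1.0),))
    with pytest.raises(ConfigError, match="accurate cell"):
        cfg.validate()


def test_all_accurate_expectations():
    exp = truth_expectations(pure_config())
    assert exp["exact_mature_fraction"] == pytest.approx(1.0)
    assert exp["windowed_accuracy"] == pytest.approx(1.0)
    assert exp["star_rpm"] == 0.0
    assert exp["guide_rpm"] == pytest.approx(1e6)


def test_all_accurate_end_to_end():
    cfg = pure_config(n_reads=1_000)
    lib, _ = simulate_library(cfg)
    est = estimate_statistics(lib, cfg)
    assert est["exact_mature_fraction"] == pytest.approx(1.0)
    assert est["star_rpm"] == 0.0
    assert math.isnan(est["register1_proportion"])


def test_pure_phased_fidelity_one_end_to_end():
    cfg = pure_config(w_guide_accurate=0.0, w_phased=1.0, phase_fidelity=1.0,
                      n_reads=1_000)
    lib, _ = simulate_library(cfg)
    est = estimate_statistics(lib, cfg)
    assert est["register1_proportion"] == 1.0


def test_fidelity_zero_register1_expectation_zero():
    cfg = pure_config(w_guide_accurate=0.0, w_phased=1.0, phase_fidelity=0.0)
    assert truth_expectations(cfg)["register1_proportion"] == 0.0


def test_expectations_match_monte_carlo_means():
    cfg = study_config(0, n_reads=4_000, phased_share=0.15, phase_fidelity=0.4)
    exp = truth_expectations(cfg)
    keys = ("exact_mature_fraction", "windowed_accuracy", "register1_proportion")
    seeds = range(20, 28)
    means = {k: [] for k in keys}
    for seed in seeds:
        lib, _ = simulate_library(dataclasses.replace(cfg, seed=seed))
        est = estimate_statistics(lib, cfg)
        for k in keys:
            means[k].append(est[k])
    n_eff = {
        "exact_mature_fraction": exp["denominator_share"] * cfg.n_reads,
        "windowed_accuracy": exp["denominator_share"] * cfg.n_reads,
        "register1_proportion": exp["phased_qualifying_share"] * cfg.n_reads,
    }
    for k in keys:
        p = exp[k]
        se = math.sqrt(p * (1 - p) / n_eff[k] / len(list(seeds)))
        assert abs(np.mean(means[k]) - p) < 3 * se, k


def test_recovery_table_within_bounds():
    cfg = study_config(17, n_reads=10_000, phased_share=0.1)
    table = recovery_table(cfg)
    assert bool(table["within_bound"].all())


def test_five_prime_u_enforcement():
    cfg = dataclasses.replace(pure_config(), require_5prime_u=True)
    assert cfg.guide.startswith("T")
    cfg.validate()  # synthetic guides carry the canonical 5'U


def test_cell_frequencies_match_jitter_distribution():
    """Chi-square goodness of fit of observed (offset, length) cell counts
    against the exact mixture expectations at n = 50,000."""
    from scipy import stats

    from artsrna import classify_forms

    cfg = study_config(55, n_reads=50_000)
    expected_freq = truth_expectations(cfg)["cell_frequencies"]
    lib, _ = simulate_library(cfg)
    hits = map_exact(collapse(lib), [cfg.precursor.ref, cfg.target])
    cls = classify_forms(hits, cfg.precursor)

    observed, expected = [], []
    other_obs, other_exp = 0.0, 0.0
    for cell, freq in expected_freq.items():
        e = freq * cls.denominator
        o = cls.cells.get(cell, 0.0)
        if e >= 5.0:
            observed.append(o)
            expected.append(e)
        else:  # lump sparse cells (degradation support) to keep chi-square valid
            other_obs += o
            other_exp += e
    observed.append(other_obs)
    expected.append(other_exp)
    result = stats.chisquare(observed, np.array(expected) / sum(expected) * sum(observed))
    assert result.pvalue > 0.01
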