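"""Shared fixtures: the default synthetic study and a full pipeline run.

Session-scoped so the (cheap but not free) generation and end-to-end run are
done once for the whole suite.
"""

from __future__ import annotations

from pathlib import Path

import pytest

import lnctrace as lt

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_sim():
    """Default-config synthetic study: (config, annotation, truth, counts, exon)."""
    config = lt.SimulationConfig(seed=DEFAULT_SEED)
    annotation = lt.generate_annotation(config)
    truth = lt.design_truth(config, annotation)
    counts, exon = lt.simulate_counts(config, annotation, truth)
    return config, annotation, truth, counts, exon


@pytest.fixture(scope="session")
def default_de(default_sim):
    """Prefiltered matrix, normalization and hyperplasia DE for both genotypes."""
    _, _, _, counts, _ = default_sim
    filtered = lt.prefilter(counts)
    norm = lt.normalize(filtered)
    disp = lt.estimate_dispersions(filtered, norm.size_factors)
    de = {
        gt: lt.nb_wald_test(filtered, (gt, wk), norm.size_factors, disp)
        for gt, wk in (("WT", 6), ("KO", 8))
    }
    return filtered, norm, de


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The default study exported to disk."""
    out = tmp_path_factory.mktemp("fixture")
    paths = lt.export_fixture(lt.SimulationConfig(seed=DEFAULT_SEED), out)
    return paths


@pytest.fixture(scope="session")
def pipeline_runs(fixture_dir, tmp_path_factory):
    """Two identical end-to-end runs of the default study (for determinism)."""
    base = tmp_path_factory.mktemp("runs")
    cfg_path = base / "config.yaml"
    lines = [f"{k}: {v}" for k, v in (
        ("counts", fixture_dir["counts"]),
        ("samples", fixture_dir["samples"]),
        ("annotation", fixture_dir["annotation"]),
        ("gmt", fixture_dir["gmt"]),
        ("exon_counts", fixture_dir["exon_counts"]),
        ("out_dir", base / "run1"),
        ("seed", DEFAULT_SEED),
    )]
    cfg_path.write_text("\n".join(lines) + "\n")
    config1 = lt.validate_config(cfg_path)
    report = lt.run_all(config1)
    config2 = lt.validate_config(cfg_path)
    config2.out_dir = base / "run2"
    lt.run_all(config2)
    return base / "run1", base / "run2", report
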