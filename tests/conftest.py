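"""Shared fixtures: small seeded synthetic experiments and gene sets."""

import numpy as np
from hypothesis import settings
import pandas as pd
import pytest

from ptoa.synthetic import ExpressionExperiment, SimConfig, simulate_experiment

# deterministic property-test runs regardless of environment
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_experiment():
    """Modest paired experiment with a planted decaying signal."""
    cfg = SimConfig(n_genes=400, n_probes=480, de_counts=(40, 8, 2), seed=11)
    exp, truth = simulate_experiment(cfg)
    return cfg, exp, truth


@pytest.fixture(scope="session")
def zero_noise_experiment():
    """Noiseless limit: paired differences equal planted effects exactly."""
    cfg = SimConfig(n_genes=50, n_probes=50, de_counts=(5, 2, 1), noise_sd=0.0, seed=7)
    exp, truth = simulate_experiment(cfg)
    return cfg, exp, truth


def make_paired_experiment(diffs_by_probe, base=8.0, timepoint="2w", detection=None):
    """Hand-built paired experiment from explicit per-probe difference vectors.

    ``diffs_by_probe`` maps probe_id -> sequence of within-animal
    (ipsi - contra) differences; all probes must use the same number of
    animals.  Contralateral samples sit at ``base``.
    """
    probes = list(diffs_by_probe)
    n = len(next(iter(diffs_by_probe.values())))
    cols, rows = {}, []
    for a in range(n):
        animal = f"{timepoint}_m{a + 1:02d}"
        cols[f"{animal}_ipsi"] = [base + diffs_by_probe[p][a] for p in probes]
        cols[f"{animal}_contra"] = [base] * len(probes)
        rows += [
            {"sample_id": f"{animal}_ipsi", "animal_id": animal, "limb": "ipsi", "timepoint": timepoint},
            {"sample_id": f"{animal}_contra", "animal_id": animal, "limb": "contra", "timepoint": timepoint},
        ]
    matrix = pd.DataFrame(cols, index=pd.Index(probes, name="probe_id"))
    samples = pd.DataFrame(rows).set_index("sample_id")
    probe_map = pd.Series({p: f"GENE_{p}" for p in probes}, name="gene_symbol")
    probe_map.index.name = "probe_id"
    det = None
    if detection is not None:
        det = pd.DataFrame(detection, index=matrix.index, columns=matrix.columns)
    return ExpressionExperiment(matrix=matrix, samples=samples, probe_map=probe_map, detection=det)

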