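"""Shared fixtures: small simulated SIP datasets and a normalization helper."""

from __future__ import annotations

import numpy as np
import pytest

import sipmet as sm

# Gradient window wide enough that heavy peaks (up to GC 0.7 at AFE 0.5,
# ~1.756 g/mL) sit >=3 band-widths inside the collected range.
WIDE_GRID = tuple(np.linspace(1.66, 1.78, 20))


def sequin_abundance(ds: sm.SyntheticDataset) -> sm.AbundanceTable:
    """Sequin-regression normalization of a synthetic dataset."""
    models = sm.fit_library_models(ds.coverage, ds.sequin_ref)
    return sm.scale_to_absolute(ds.coverage, models, ds.standard_ids)


def qsip_point_estimates(ds: sm.SyntheticDataset) -> dict[str, float]:
    """Noise-tolerant qSIP point estimates for every genome of a dataset."""
    abund = sequin_abundance(ds)
    design = sm.validate_design(ds.meta)
    cm = sm.condition_mean_bd(sm.replicate_weighted_bd(abund, ds.meta), design)
    gc = {g.genome_id: g.gc for g in ds.genomes}
    return {g: sm.qsip_afe(cm.loc[g, "w_lab"], cm.loc[g, "w_light"], gc[g])
            for g in ds.truth}


@pytest.fixture()
def helpers():
    return {"sequin_abundance": sequin_abundance,
            "qsip_point_estimates": qsip_point_estimates}


@pytest.fixture(scope="session")
def noiseless_ds() -> sm.SyntheticDataset:
    """3v3 replicates, no noise: one 13C-labeled genome among unlabeled ones."""
    genomes = [
        sm.SimGenomeSpec("ecoli", gc=0.504, true_afe=0.32, total_abundance=120.0),
        sm.SimGenomeSpec("bg_low", gc=0.45, true_afe=0.0, total_abundance=80.0),
        sm.SimGenomeSpec("bg_high", gc=0.62, true_afe=0.0, total_abundance=40.0),
    ]
    cfg = sm.SimConfig(genomes=genomes, coverage_noise_cv=0.0, seed=11)
    return sm.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_ds() -> sm.SyntheticDataset:
    """Same design with multiplicative coverage noise (cv = 0.2)."""
    genomes = [
        sm.SimGenomeSpec("ecoli", gc=0.504, true_afe=0.32, total_abundance=120.0),
        sm.SimGenomeSpec("bg_low", gc=0.45, true_afe=0.0, total_abundance=80.0),
        sm.SimGenomeSpec("bg_high", gc=0.62, true_afe=0.0, total_abundance=40.0),
    ]
    cfg = sm.SimConfig(genomes=genomes, coverage_noise_cv=0.2, seed=12)
    return sm.simulate_dataset(cfg)
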