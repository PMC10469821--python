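"""Synthetic density-gradient SIP datasets with known ground-truth AFE.

The generator emulates an isopycnic-centrifugation SIP experiment: each
genome's DNA mass is spread over a discrete buoyant-density grid as a
Gaussian centered at the density its GC content and labeling level imply
(unlabeled center in control replicates; shifted, or a mass-weighted mixture
of components, in treatment replicates).  Coverage is mass times a
per-library depth factor with multiplicative lognormal noise; sequin
internal standards respond linearly through the same per-library factor, and
pre-centrifugation spike-ins peak at their reference densities.  Because the
labeled center density inverts the qSIP molecular-weight equations exactly,
a noiseless dataset round-trips through sequin normalization and the qSIP
estimator to the configured truth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CoverageTable,
    FractionMeta,
    GenomeRecord,
    SequinReference,
    SpikeInReference,
)
from .qsip import IsotopeParams, invert_afe, theoretical_density

DENSITY_GRID_DEFAULT = tuple(np.linspace(1.67, 1.77, 16))
PEAK_SD_DEFAULT = 0.006  # g/mL; a genome spans roughly 4-6 fractions
READ_LENGTH_DEFAULT = 150  # bp, for Poisson coverage thinning


def effective_mixture_afe(components: Sequence[tuple[float, float]]) -> float:
    """Mass-weighted mean AFE of a mixture of (mass, afe) components."""
    if not components:
        raise ValueError("empty mixture")
    masses = np.array([m for m, _ in components], dtype=float)
    afes = np.array([a for _, a in components], dtype=float)
    if np.any(masses <= 0):
        raise ValueError("component masses must be positive")
    return float((masses * afes).sum() / masses.sum())


def labeled_center_density(gc: float, true_afe: float,
                           params: IsotopeParams = IsotopeParams()) -> float:
    """Peak buoyant density of DNA with the given GC and atom fraction excess.

    Inverts the qSIP equations so that the simulated weighted-BD shift maps
    back to exactly the configured AFE: rho = rho_light * M_lab / M_light.
    """
    return theoretical_density(gc) * invert_afe(true_afe, gc, params)


@dataclass(frozen=True)
class SimGenomeSpec:
    """One simulated genome: identity, GC, abundance, and labeling level.

    ``mixture`` optionally lists (mass_fraction, component_afe) pairs whose
    mass fractions sum to 1, emulating blends of unlabeled and labeled DNA
    of the same organism; the effective AFE is the mass-weighted mean.
    """

    genome_id: str
    gc: float
    length_bp: int = 3_000_000
    total_abundance: float = 100.0
    true_afe: float = 0.0
    mixture: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must be in [0, 1]")
        if not 0 <= self.true_afe <= 0.98:
            raise ValueError("true_afe must be in [0, 0.98]")
        if self.mixture is not None:
            masses = [m for m, _ in self.mixture]
            if abs(sum(masses) - 1.0) > 1e-9:
                raise ValueError("mixture mass fractions must sum to 1")

    @property
    def effective_afe(self) -> float:
        if self.mixture is None:
            return self.true_afe
        return effective_mixture_afe(self.mixture)


def default_sequins(n_groups: int = 4, per_group: int = 3) -> list[SequinReference]:
    """Sequin mix: concentration groups spanning three orders of magnitude."""
    out = []
    for g in range(n_groups):
        conc = 10.0 ** g
        for i in range(per_group):
            out.append(SequinReference(f"sequin_g{g}_{i}", conc, group_label=f"G{g}"))
    return out


def default_spikeins(grid: Sequence[float], n: int = 6) -> list[SpikeInReference]:
    """Spike-ins with distinct expected peaks spread across the gradient."""
    lo, hi = min(grid), max(grid)
    peaks = np.linspace(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo), n)
    out = []
    for i, rho in enumerate(peaks):
        gc = float(np.clip((rho - 1.660) / 0.098, 0.0, 1.0))
        out.append(SpikeInReference(f"spikein_{i}", float(rho), gc=gc))
    return out


@dataclass
class SimConfig:
    """Study design and noise model of a simulated SIP experiment."""

    genomes: list[SimGenomeSpec]
    n_control_reps: int = 3
    n_treatment_reps: int = 3
    isotope: str = "13C"
    density_grid: tuple[float, ...] = DENSITY_GRID_DEFAULT
    peak_sd: float = PEAK_SD_DEFAULT
    spikein_peak_sd: float = 0.003  # narrow bands keep the argmax peak call unambiguous
    coverage_noise_cv: float = 0.0
    library_response_sd: float = 0.3  # lognormal sigma of per-library depth factor
    sequins: list[SequinReference] = field(default_factory=default_sequins)
    spikeins: list[SpikeInReference] | None = None
    spikein_abundance: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.density_grid, dtype=float)
        if not np.all(np.diff(grid) > 0):
            raise ValueError("density_grid must be strictly increasing")
        if not self.peak_sd > 0:
            raise ValueError("peak_sd must be positive")
        if self.n_control_reps < 1 or self.n_treatment_reps < 1:
            raise ValueError("need >= 1 replicate per condition")
        if self.spikeins is None:
            self.spikeins = default_spikeins(self.density_grid)


@dataclass
class SyntheticDataset:
    coverage: CoverageTable
    meta: list[FractionMeta]
    genomes: list[GenomeRecord]
    sequin_ref: list[SequinReference]
    spikein_ref: list[SpikeInReference]
    truth: dict[str, float]
    config: SimConfig

    @property
    def standard_ids(self) -> set[str]:
        return ({s.sequin_id for s in self.sequin_ref}
                | {s.spikein_id for s in self.spikein_ref})


def _gaussian_profile(grid: np.ndarray, center: float, sd: float) -> np.ndarray:
    """Gaussian weights renormalized over the truncated grid (mass-conserving)."""
    w = np.exp(-0.5 * ((grid - center) / sd) ** 2)
    s = w.sum()
    if s == 0:  # center far outside the gradient: put mass in nearest fraction
        w = np.zeros_like(grid)
        w[int(np.argmin(np.abs(grid - center)))] = 1.0
        return w
    return w / s


def _mass_profile(spec: SimGenomeSpec, grid: np.ndarray, sd: float,
                  params: IsotopeParams, labeled: bool) -> np.ndarray:
    components = ((1.0, 0.0),) if not labeled else (
        spec.mixture if spec.mixture is not None else ((1.0, spec.true_afe),))
    out = np.zeros_like(grid)
    for mass_frac, afe in components:
        center = labeled_center_density(spec.gc, afe, params)
        out += mass_frac * _gaussian_profile(grid, center, sd)
    return out * spec.total_abundance


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic SIP dataset (coverage + metadata + truth)."""
    rng = np.random.default_rng(config.seed)
    params = IsotopeParams.for_isotope(config.isotope)
    grid = np.asarray(config.density_grid, dtype=float)
    n_frac = len(grid)

    samples = ([(f"C{r+1}", "control", r + 1) for r in range(config.n_control_reps)]
               + [(f"T{r+1}", "treatment", r + 1) for r in range(config.n_treatment_reps)])
    meta: list[FractionMeta] = []
    lib_ids: list[str] = []

    genome_ids = [g.genome_id for g in config.genomes]
    if len(set(genome_ids)) != len(genome_ids):
        raise ValueError("duplicate genome_id in config")

    rows = {}
    dna_mass = {}
    for sample_id, condition, rep in samples:
        labeled = condition == "treatment"
        g_mass = np.stack([
            _mass_profile(g, grid, config.peak_sd, params, labeled)
            for g in config.genomes
        ])  # genomes x fractions
        s_mass = np.stack([
            _gaussian_profile(grid, s.expected_peak_density, config.spikein_peak_sd)
            * config.spikein_abundance
            for s in config.spikeins
        ]) if config.spikeins else np.zeros((0, n_frac))
        dna_mass[sample_id] = g_mass.sum(axis=0) + s_mass.sum(axis=0)
        response = rng.lognormal(mean=0.0, sigma=config.library_response_sd, size=n_frac)
        for k in range(n_frac):
            lib = f"{sample_id}_f{k+1:02d}"
            lib_ids.append(lib)
            meta.append(FractionMeta(
                library_id=lib, sample_id=sample_id, replicate=rep,
                condition=condition, isotope=config.isotope, fraction_index=k + 1,
                density=float(grid[k]), dna_conc=float(dna_mass[sample_id][k]),
            ))
            col = {}
            noise_g = _lognormal_noise(rng, config.coverage_noise_cv, len(config.genomes))
            for i, g in enumerate(config.genomes):
                col[g.genome_id] = g_mass[i, k] * response[k] * noise_g[i]
            noise_q = _lognormal_noise(rng, config.coverage_noise_cv, len(config.sequins))
            for i, s in enumerate(config.sequins):
                col[s.sequin_id] = s.known_concentration * response[k] * noise_q[i]
            noise_s = _lognormal_noise(rng, config.coverage_noise_cv, len(config.spikeins))
            for i, s in enumerate(config.spikeins):
                col[s.spikein_id] = s_mass[i, k] * response[k] * noise_s[i]
            rows[lib] = col

    df = pd.DataFrame(rows)  # features x libraries, column order = lib_ids
    coverage = CoverageTable(df[lib_ids])
    genomes = [GenomeRecord(g.genome_id, g.gc, g.length_bp,
                            completeness_pct=100.0, contamination_pct=0.0)
               for g in config.genomes]
    truth = {g.genome_id: g.effective_afe for g in config.genomes}
    return SyntheticDataset(
        coverage=coverage, meta=meta, genomes=genomes,
        sequin_ref=list(config.sequins), spikein_ref=list(config.spikeins),
        truth=truth, config=config,
    )


def disturb_gradient(ds: SyntheticDataset, sample_id: str,
                     mode: str = "swap_adjacent", seed: int = 0) -> SyntheticDataset:
    """Permute one sample's abundance-to-fraction assignment (metadata intact).

    ``swap_adjacent`` swaps the two fractions carrying the peaks of two
    neighboring spike-ins (a deterministic involution that inverts their
    observed order); without spike-ins it swaps the two middle fractions.
    ``shuffle`` applies a seeded random permutation.  Emulates a physically
    disturbed density gradient, which spike-in QC should flag.
    """
    sample_meta = [m for m in ds.meta if m.sample_id == sample_id]
    if not sample_meta:
        raise ValueError(f"unknown sample {sample_id!r}")
    libs = [m.library_id for m in sample_meta]
    rho = np.array([m.density for m in sample_meta])
    perm = list(range(len(libs)))
    if mode == "swap_adjacent":
        spikes = sorted(ds.spikein_ref, key=lambda s: s.expected_peak_density)
        peak_fracs = [int(np.argmin(np.abs(rho - s.expected_peak_density)))
                      for s in spikes]
        pair = None
        mid = len(peak_fracs) // 2
        for i in sorted(range(len(peak_fracs) - 1), key=lambda i: abs(i - mid)):
            if peak_fracs[i] != peak_fracs[i + 1]:
                pair = (peak_fracs[i], peak_fracs[i + 1])
                break
        if pair is None:
            mid = len(libs) // 2
            pair = (mid - 1, mid)
        perm[pair[0]], perm[pair[1]] = perm[pair[1]], perm[pair[0]]
    elif mode == "shuffle":
        rng = np.random.default_rng(seed)
        while True:
            rng.shuffle(perm)
            if perm != sorted(perm):
                break
    else:
        raise ValueError(f"unknown disturbance mode {mode!r}")
    out = copy.deepcopy(ds)
    out.coverage.df[libs] = ds.coverage.df[[libs[i] for i in perm]].to_numpy()
    return out


def dilute_coverage(ds: SyntheticDataset, genome_id: str, factor: float,
                    seed: int = 0, read_length: int = READ_LENGTH_DEFAULT) -> SyntheticDataset:
    """Thin one genome's coverage to ``factor`` of its level (read subsampling).

    Coverage is converted to an equivalent read count (coverage x length /
    read length), Poisson-thinned, and converted back, so low-coverage
    fractions can drop to exactly zero.
    """
    if not 0 < factor <= 1:
        raise ValueError("factor must be in (0, 1]")
    if genome_id not in ds.coverage.df.index:
        raise ValueError(f"unknown genome {genome_id!r}")
    out = copy.deepcopy(ds)
    if factor == 1.0:
        return out
    length = next(g.length_bp for g in ds.genomes if g.genome_id == genome_id)
    rng = np.random.default_rng(seed)
    cov = ds.coverage.df.loc[genome_id].to_numpy(dtype=float)
    reads = rng.poisson(factor * cov * length / read_length)
    out.coverage.df.loc[genome_id] = reads * read_length / length
    return out
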