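"""Coverage -> abundance normalization and spike-in quality control.

The primary route scales per-library genome coverage into absolute
concentration units by regressing the known concentrations of sequin
internal standards against their observed coverages (one model per fraction
library), after a coefficient-of-variation gate on sequin concentration
groups and optional Cook's-distance outlier removal.  Alternative abundance
measures (relative coverage, relative abundance x DNA concentration) are
provided for comparison.  Pre-centrifugation spike-ins provide a per-sample
sanity check: their coverage peaks must appear in the expected density order
along the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import (
    AbundanceTable,
    CoverageTable,
    FractionMeta,
    GenomeRecord,
    SequinReference,
    SpikeInReference,
    meta_frame,
)

COV_THRESHOLD_DEFAULT = 250.0  # percent


@dataclass
class ScalingModel:
    """Per-library linear map from coverage to absolute concentration."""

    library_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points_used: int
    removed_sequin_ids: list[str] = field(default_factory=list)
    method: str = "ols_cooks"  # "ols" | "ols_cooks" | "robust"

    def __post_init__(self) -> None:
        if self.n_points_used < 3:
            raise ValueError("scaling model needs >= 3 points")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")

    def predict(self, coverage):
        return self.slope * np.asarray(coverage, dtype=float) + self.intercept


def coefficient_of_variation(values) -> float:
    """CoV as a percentage: 100 * sample sd / mean."""
    v = np.asarray(list(values), dtype=float)
    mean = v.mean()
    if mean == 0:
        return float("inf")
    return float(100.0 * v.std(ddof=1) / mean)


def filter_sequins_by_cov(
    coverages: Mapping[str, float],
    groups: Mapping[str, str],
    cov_threshold: float = COV_THRESHOLD_DEFAULT,
) -> set[str]:
    """Drop whole sequin concentration groups whose coverage CoV exceeds the gate.

    ``coverages`` maps sequin_id -> coverage within one library; ``groups``
    maps sequin_id -> concentration-group label.  Groups whose CoV (%)
    exceeds ``cov_threshold`` are removed before regression.
    """
    if not cov_threshold > 0:
        raise ValueError("cov_threshold must be positive")
    by_group: dict[str, list[str]] = {}
    for sid in coverages:
        by_group.setdefault(groups[sid], []).append(sid)
    retained: set[str] = set()
    for members in by_group.values():
        vals = [coverages[s] for s in members]
        if len(vals) < 2 or coefficient_of_variation(vals) <= cov_threshold:
            retained.update(members)
    if not retained:
        raise ValueError("insufficient sequins for scaling: all concentration groups removed by CoV gate")
    return retained


def fit_sequin_regression(
    cov: Mapping[str, float] | pd.Series,
    conc: Mapping[str, float] | pd.Series,
    library_id: str = "",
    method: str = "ols",
    cooks_filter: bool = True,
    cooks_rule: str = "4/n",
    log_transform: bool = False,
) -> ScalingModel:
    """Fit concentration = slope * coverage + intercept over sequins.

    With ``cooks_filter`` (OLS only), points whose Cook's distance exceeds
    the cutoff are removed and the model refit once.  ``cooks_rule`` is
    ``"4/n"`` (conventional outlier rule) or ``"n/4"`` (the alternative
    literal reading); ``method="robust"`` uses iteratively reweighted least
    squares with a Huber loss instead.  ``log_transform`` fits the model on
    log10 coverage vs log10 concentration.
    """
    cov = pd.Series(cov, dtype=float)
    conc = pd.Series(conc, dtype=float).loc[cov.index]
    if len(cov) < 3:
        raise ValueError(f"library {library_id!r}: need >= 3 sequin points, got {len(cov)}")
    if cov.nunique() == 1:
        raise ValueError(f"library {library_id!r}: degenerate regression (zero-variance coverage)")
    if method not in ("ols", "robust"):
        raise ValueError(f"unknown regression method {method!r}")
    if log_transform:
        keep = (cov > 0) & (conc > 0)
        cov, conc = np.log10(cov[keep]), np.log10(conc[keep])
        if len(cov) < 3:
            raise ValueError(f"library {library_id!r}: <3 positive points for log-log fit")

    x = sm.add_constant(cov.to_numpy())
    y = conc.to_numpy()
    removed: list[str] = []
    if method == "robust":
        fit = sm.RLM(y, x, M=sm.robust.norms.HuberT()).fit()
        resid = y - fit.fittedvalues
        ss_res = float((resid ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        tag = "robust"
    else:
        fit = sm.OLS(y, x).fit()
        ss_tot = float(((y - y.mean()) ** 2).sum())
        exact_fit = fit.ssr <= 1e-12 * max(ss_tot, 1.0)
        if cooks_filter and not exact_fit:
            n = len(cov)
            cutoff = 4.0 / n if cooks_rule == "4/n" else n / 4.0
            cooks = fit.get_influence().cooks_distance[0]
            mask = cooks <= cutoff
            if mask.sum() >= 3 and not mask.all():
                removed = list(cov.index[~mask])
                cov, y = cov[mask], y[mask]
                x = sm.add_constant(cov.to_numpy())
                fit = sm.OLS(y, x).fit()
            elif mask.sum() < 3:
                raise ValueError(f"library {library_id!r}: <3 points remain after Cook's filtering")
        r2 = float(fit.rsquared)
        tag = "ols_cooks" if cooks_filter else "ols"
    return ScalingModel(
        library_id=library_id, slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r_squared=r2, n_points_used=len(cov), removed_sequin_ids=removed, method=tag,
    )


def fit_library_models(
    cov: CoverageTable,
    sequin_ref: Sequence[SequinReference],
    method: str = "ols",
    cooks_filter: bool = True,
    cooks_rule: str = "4/n",
    cov_threshold: float = COV_THRESHOLD_DEFAULT,
    log_transform: bool = False,
) -> dict[str, ScalingModel]:
    """One scaling model per library: CoV gate, then sequin regression."""
    conc = {s.sequin_id: s.known_concentration for s in sequin_ref}
    groups = {s.sequin_id: (s.group_label if s.group_label is not None else str(s.known_concentration))
              for s in sequin_ref}
    present = [s for s in conc if s in cov.df.index]
    if len(present) < 3:
        raise ValueError("fewer than 3 sequins present in the coverage table")
    models = {}
    for lib in cov.libraries:
        lib_cov = {s: float(cov.df.at[s, lib]) for s in present}
        retained = filter_sequins_by_cov(lib_cov, groups, cov_threshold)
        models[lib] = fit_sequin_regression(
            {s: lib_cov[s] for s in retained}, {s: conc[s] for s in retained},
            library_id=lib, method=method, cooks_filter=cooks_filter,
            cooks_rule=cooks_rule, log_transform=log_transform,
        )
    return models


def _drop_standards(cov: CoverageTable, standard_ids: set[str]) -> pd.DataFrame:
    return cov.df.drop(index=[i for i in standard_ids if i in cov.df.index])


def scale_to_absolute(
    cov: CoverageTable,
    models: Mapping[str, ScalingModel],
    standard_ids: set[str] | None = None,
) -> AbundanceTable:
    """Apply per-library scaling models; clamp negative predictions to zero.

    Sequin/spike-in rows (``standard_ids``) are dropped from the output.
    """
    missing = [lib for lib in cov.libraries if lib not in models]
    if missing:
        raise ValueError(f"no scaling model for libraries: {missing}")
    df = _drop_standards(cov, standard_ids or set())
    cols = {lib: np.clip(models[lib].predict(df[lib].to_numpy()), 0.0, None)
            for lib in df.columns}
    return AbundanceTable(pd.DataFrame(cols, index=df.index), method="sequin")


def relative_coverage(cov: CoverageTable, standard_ids: set[str] | None = None) -> AbundanceTable:
    """Per-library coverage fractions over genomes (columns sum to 1)."""
    df = _drop_standards(cov, standard_ids or set())
    sums = df.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero coverage column: {zero.index[0]!r}")
    return AbundanceTable(df / sums, method="rel_coverage")


def abundance_by_dna(
    cov: CoverageTable,
    meta: Sequence[FractionMeta],
    genomes: Sequence[GenomeRecord] | None = None,
    basis: str = "relative_coverage",
    standard_ids: set[str] | None = None,
) -> AbundanceTable:
    """Relative coverage or relative abundance multiplied by DNA concentration.

    ``relative_abundance`` weights coverage by genome length (reads-
    proportional) before normalizing each column to 1; it therefore requires
    genome records.
    """
    if basis not in ("relative_coverage", "relative_abundance"):
        raise ValueError(f"unknown basis {basis!r}")
    mf = meta_frame(meta)
    missing = set(cov.libraries) - set(mf.index)
    if missing:
        raise ValueError(f"missing dna_conc (no metadata) for libraries: {sorted(missing)}")
    df = _drop_standards(cov, standard_ids or set())
    if basis == "relative_abundance":
        if genomes is None:
            raise ValueError("relative_abundance basis requires genome records (lengths)")
        lengths = pd.Series({g.genome_id: float(g.length_bp) for g in genomes})
        weighted = df.mul(lengths.loc[df.index], axis=0)
        sums = weighted.sum(axis=0)
        if (sums == 0).any():
            raise ValueError(f"all-zero coverage column: {sums[sums == 0].index[0]!r}")
        rel = weighted / sums
        tag = "relabund_x_dna"
    else:
        sums = df.sum(axis=0)
        if (sums == 0).any():
            raise ValueError(f"all-zero coverage column: {sums[sums == 0].index[0]!r}")
        rel = df / sums
        tag = "relcov_x_dna"
    dna = mf.loc[list(df.columns), "dna_conc"]
    return AbundanceTable(rel.mul(dna, axis=1), method=tag)


@dataclass
class QCReport:
    """Spike-in peak-order check for one sample."""

    sample_id: str
    passed: bool
    observed_peak_order: list[str]
    expected_peak_order: list[str]
    notes: list[str] = field(default_factory=list)


def spikein_qc(
    cov: CoverageTable,
    ref: Sequence[SpikeInReference],
    meta: Sequence[FractionMeta],
    models: Mapping[str, ScalingModel] | None = None,
) -> list[QCReport]:
    """Check, per sample, that spike-in coverage peaks occur in the expected density order.

    The observed peak of a spike-in is the density of the fraction where its
    abundance (sequin-scaled when ``models`` is given, otherwise raw
    coverage) is maximal.  A sample passes iff the ranking of observed peak
    densities matches the ranking of expected peak densities and every
    spike-in is detected.
    """
    ids = [s.spikein_id for s in ref]
    present = [s for s in ids if s in cov.df.index]
    if len(present) < 2:
        raise ValueError("need >= 2 spike-ins with coverage rows for QC")
    expected_order = [s.spikein_id for s in sorted(ref, key=lambda s: s.expected_peak_density)
                      if s.spikein_id in present]
    mf = meta_frame(meta)
    reports = []
    for sample_id, sub in mf.loc[[l for l in cov.libraries if l in mf.index]].groupby("sample_id", sort=False):
        libs = sub.index.to_list()
        rho = sub["density"].to_numpy(dtype=float)
        notes: list[str] = []
        observed_peak: dict[str, float] = {}
        for sid in present:
            y = cov.df.loc[sid, libs].to_numpy(dtype=float)
            if models is not None:
                y = np.clip(np.array([models[l].predict(v) for l, v in zip(libs, y)]), 0.0, None)
            if y.sum() == 0:
                notes.append(f"spike-in not detected: {sid}")
                continue
            observed_peak[sid] = float(rho[int(np.argmax(y))])
        detected = [s for s in expected_order if s in observed_peak]
        observed_order = sorted(detected, key=lambda s: observed_peak[s])
        passed = (len(detected) == len(expected_order)
                  and observed_order == [s for s in expected_order if s in observed_peak])
        if passed and len(detected) >= 2:
            # equal observed peak densities mean indistinguishable order -> fail
            peaks = [observed_peak[s] for s in observed_order]
            if len(set(peaks)) != len(peaks):
                passed = False
                notes.append("tied spike-in peak positions")
        reports.append(QCReport(
            sample_id=sample_id, passed=bool(passed),
            observed_peak_order=observed_order, expected_peak_order=expected_order,
            notes=notes,
        ))
    return reports


def qc_frame(reports: Sequence[QCReport]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": r.sample_id, "pass": r.passed,
        "observed_peak_order": ",".join(r.observed_peak_order),
        "expected_peak_order": ",".join(r.expected_peak_order),
        "notes": ";".join(r.notes),
    } for r in reports]).set_index("sample_id")
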