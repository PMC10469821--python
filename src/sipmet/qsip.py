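"""Core quantitative SIP (qSIP) and delta-BD models.

The qSIP model converts the shift in a genome's abundance-weighted mean
buoyant density (W) between unlabeled control and isotope-amended treatment
gradients into an estimate of atom fraction excess (AFE), via the molecular
weight of the genome's DNA.  For a genome with GC content ``G`` (fraction in
[0, 1]):

    M_light    = 0.496 * G + 307.691                    [g/mol, unlabeled]
    M_lab      = M_light * (W_lab / W_light)            [g/mol, labeled]
    M_heavymax = M_light + 9.974564 - 0.4987282 * G     [g/mol, fully labeled]

    AFE = (M_lab - M_light) / (M_heavymax - M_light) * (1 - a_nat)

where ``a_nat`` is the natural abundance of the heavy isotope (0.01111233
for 13C, 0.002000429 for 18O).  The delta-BD model instead divides the
weighted-BD shift by I_max, the maximum linear BD shift at 100% labeling.

Uncertainty is quantified by bootstrap resampling of biological replicates
within each condition; multiplicity over many genomes is handled either by
Bonferroni-widened percentile intervals or by false-coverage-rate (FCR)
adjusted intervals over the selected set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import AbundanceTable, FractionMeta, SampleDesign, meta_frame

# Natural abundance of the heavy isotope in unlabeled DNA.
NATURAL_ABUNDANCE = {"13C": 0.01111233, "18O": 0.002000429}

# M_heavymax - M_light = HEAVYMAX_OFFSET - HEAVYMAX_GC_COEFF * G
HEAVYMAX_OFFSET = 9.974564
HEAVYMAX_GC_COEFF = 0.4987282

# Linear GC -> buoyant density relation for unlabeled DNA (g/mL).
DENSITY_INTERCEPT = 1.660
DENSITY_GC_SLOPE = 0.098


@dataclass(frozen=True)
class IsotopeParams:
    """Isotope-specific constants of the qSIP model (overridable)."""

    isotope: str = "13C"
    natural_abundance_term: float = NATURAL_ABUNDANCE["13C"]
    heavymax_offset: float = HEAVYMAX_OFFSET
    heavymax_gc_coeff: float = HEAVYMAX_GC_COEFF

    def __post_init__(self) -> None:
        if not 0.0 < self.natural_abundance_term < 1.0:
            raise ValueError("natural_abundance_term must be in (0, 1)")

    @classmethod
    def for_isotope(cls, isotope: str) -> "IsotopeParams":
        if isotope not in NATURAL_ABUNDANCE:
            raise ValueError(f"unknown isotope {isotope!r}; expected one of {sorted(NATURAL_ABUNDANCE)}")
        return cls(isotope=isotope, natural_abundance_term=NATURAL_ABUNDANCE[isotope])


@dataclass(frozen=True)
class DeltaBDParams:
    """Delta-BD model parameter: maximum BD shift at 100% labeling (g/mL).

    No universal default exists; I_max depends on the isotope and the
    density-gradient medium and must be supplied by the user.
    """

    i_max: float

    def __post_init__(self) -> None:
        if not self.i_max > 0:
            raise ValueError("I_max must be positive")


def _check_gc(gc) -> np.ndarray:
    gc = np.asarray(gc, dtype=float)
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("GC content must lie in [0, 1]")
    return gc


def m_light(gc):
    """Molecular weight (g/mol) of unlabeled DNA with GC fraction ``gc``."""
    gc = _check_gc(gc)
    out = 0.496 * gc + 307.691
    return float(out) if out.ndim == 0 else out


def m_heavymax(gc, params: IsotopeParams = IsotopeParams()):
    """Theoretical maximum molecular weight (g/mol) at full heavy labeling."""
    gc = _check_gc(gc)
    out = m_light(gc) + params.heavymax_offset - params.heavymax_gc_coeff * gc
    return float(out) if np.ndim(out) == 0 else out


def m_lab(m_light_val, w_lab, w_light):
    """Molecular weight (g/mol) in the treatment condition.

    Scales M_light by the relative shift in weighted buoyant density:
    ``M_lab = M_light * ((W_lab - W_light)/W_light + 1)``.
    """
    w_light = np.asarray(w_light, dtype=float)
    if np.any(w_light <= 0):
        raise ValueError("W_light must be positive")
    out = np.asarray(m_light_val, dtype=float) * ((np.asarray(w_lab, dtype=float) - w_light) / w_light + 1.0)
    return float(out) if out.ndim == 0 else out


def qsip_afe(w_lab, w_light, gc, params: IsotopeParams = IsotopeParams()):
    """Atom fraction excess from the weighted-BD shift (qSIP model).

    The point estimate is not clamped at zero; negative values simply mean
    the treatment W fell below the control W.
    """
    ml = m_light(gc)
    mh = m_heavymax(gc, params)
    mlab = m_lab(ml, w_lab, w_light)
    denom = np.asarray(mh, dtype=float) - np.asarray(ml, dtype=float)
    if np.any(denom == 0):
        raise ValueError("M_heavymax equals M_light; AFE undefined")
    out = (mlab - ml) / denom * (1.0 - params.natural_abundance_term)
    return float(out) if np.ndim(out) == 0 else out


def invert_afe(afe, gc, params: IsotopeParams = IsotopeParams()):
    """W_lab / W_light ratio producing a given AFE (inverse of the qSIP model)."""
    gc = _check_gc(gc)
    afe = np.asarray(afe, dtype=float)
    if np.any((afe < 0) | (afe > 1 - params.natural_abundance_term)):
        raise ValueError("AFE must lie in [0, 1 - natural abundance term]")
    ml = m_light(gc)
    mh = m_heavymax(gc, params)
    mlab = ml + afe / (1.0 - params.natural_abundance_term) * (mh - ml)
    out = mlab / ml
    return float(out) if out.ndim == 0 else out


def deltabd_afe(w_lab, w_light, params: DeltaBDParams):
    """Atom fraction excess from the delta-BD model: (W_lab - W_light)/I_max."""
    out = (np.asarray(w_lab, dtype=float) - np.asarray(w_light, dtype=float)) / params.i_max
    return float(out) if out.ndim == 0 else out


def theoretical_density(gc):
    """Expected buoyant density (g/mL) of unlabeled DNA with GC fraction ``gc``."""
    gc = _check_gc(gc)
    out = DENSITY_INTERCEPT + DENSITY_GC_SLOPE * gc
    return float(out) if out.ndim == 0 else out


def weighted_mean_bd(y, rho) -> float:
    """Abundance-weighted mean buoyant density over the fractions of one replicate.

    ``sum_k rho_k * y_k / sum_k y_k``; a single value regardless of whether
    the abundance profile is monomodal or multimodal.  Returns NaN if the
    genome is absent (all-zero) in the replicate.
    """
    y = np.asarray(y, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if y.shape != rho.shape:
        raise ValueError("y and rho must have the same length")
    if np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    tot = y.sum()
    if tot == 0:
        return float("nan")
    return float((rho * y).sum() / tot)


def replicate_weighted_bd(abund: AbundanceTable, meta: Sequence[FractionMeta]) -> pd.DataFrame:
    """Per-genome, per-sample weighted mean BD (W_ij).

    Returns a DataFrame (genomes x sample_ids); NaN where the genome has zero
    total abundance in that sample's fractions.
    """
    mf = meta_frame(meta)
    missing = set(abund.libraries) - set(mf.index)
    if missing:
        raise ValueError(f"libraries without fraction metadata: {sorted(missing)}")
    out = {}
    for sample_id, sub in mf.loc[list(abund.libraries)].groupby("sample_id", sort=False):
        libs = sub.index.to_list()
        y = abund.df[libs].to_numpy(dtype=float)
        rho = sub["density"].to_numpy(dtype=float)
        tot = y.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = (y * rho).sum(axis=1) / tot
        w[tot == 0] = np.nan
        out[sample_id] = w
    return pd.DataFrame(out, index=abund.df.index)


def condition_mean_bd(w_ij: pd.DataFrame, design: SampleDesign, weights: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean weighted BD per condition (columns ``w_light``, ``w_lab``).

    By default the unweighted arithmetic mean over replicates with a defined
    W_ij; pass per-sample abundance totals as ``weights`` for
    abundance-weighted pooling.  NaN where a genome is absent from every
    replicate of a condition.
    """
    def _mean(samples: Sequence[str]) -> pd.Series:
        sub = w_ij[list(samples)]
        if weights is None:
            return sub.mean(axis=1)
        wt = weights[list(samples)].where(sub.notna())
        return (sub * wt).sum(axis=1, min_count=1) / wt.sum(axis=1)

    return pd.DataFrame({
        "w_light": _mean(design.control_samples),
        "w_lab": _mean(design.treatment_samples),
    })


@dataclass
class AFEEstimate:
    """Per-genome AFE point estimate with a bootstrap confidence interval."""

    genome_id: str
    method: str  # "qsip" | "deltabd"
    afe: float
    ci_low: float
    ci_high: float
    ci_level_used: float
    n_boot: int
    labeled: bool
    threshold_used: float = 0.0
    n_discarded: int = 0
    unstable: bool = False
    boot_samples: np.ndarray | None = field(default=None, repr=False, compare=False)


def _percentile_ci(samples: np.ndarray, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo, hi = np.percentile(samples, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def bootstrap_afe(
    abund: AbundanceTable,
    meta: Sequence[FractionMeta],
    design: SampleDesign,
    gc: Mapping[str, float],
    genomes: Iterable[str] | None = None,
    method: str = "qsip",
    params: IsotopeParams | None = None,
    deltabd: DeltaBDParams | None = None,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    threshold: float = 0.0,
    seed: int = 0,
) -> list[AFEEstimate]:
    """Bootstrap AFE estimates by resampling replicates within each condition.

    Whole replicates (biological samples) are resampled with replacement,
    independently in control and treatment; W_light/W_lab and AFE are
    recomputed for each draw.  The point estimate comes from the original
    data; intervals are percentile intervals at ``ci_level``.  Draws in which
    a genome is absent from every resampled replicate of a condition are
    discarded; if more than half the draws are discarded the estimate is
    flagged unstable.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if method not in ("qsip", "deltabd"):
        raise ValueError(f"unknown AFE method {method!r}")
    if method == "deltabd" and deltabd is None:
        raise ValueError("deltabd method requires DeltaBDParams (I_max has no default)")
    if params is None:
        params = IsotopeParams.for_isotope(design.isotope)

    rng = np.random.default_rng(seed)
    w_ij = replicate_weighted_bd(abund, meta)
    ctrl = w_ij[list(design.control_samples)].to_numpy(dtype=float)
    treat = w_ij[list(design.treatment_samples)].to_numpy(dtype=float)
    n_c, n_t = ctrl.shape[1], treat.shape[1]
    idx_c = rng.integers(0, n_c, size=(n_boot, n_c))
    idx_t = rng.integers(0, n_t, size=(n_boot, n_t))

    def _afe(w_lab, w_light, g):
        if method == "qsip":
            return qsip_afe(w_lab, w_light, g, params)
        return deltabd_afe(w_lab, w_light, deltabd)

    wanted = list(genomes) if genomes is not None else list(abund.df.index)
    pos = {g: i for i, g in enumerate(abund.df.index)}
    out: list[AFEEstimate] = []
    for g in wanted:
        if g not in pos:
            raise ValueError(f"genome {g!r} not in abundance table")
        i = pos[g]
        wl = np.nanmean(ctrl[i]) if np.any(np.isfinite(ctrl[i])) else np.nan
        wt = np.nanmean(treat[i]) if np.any(np.isfinite(treat[i])) else np.nan
        if not (np.isfinite(wl) and np.isfinite(wt)):
            out.append(AFEEstimate(g, method, float("nan"), float("nan"), float("nan"),
                                   ci_level, n_boot, False, threshold, n_boot, True))
            continue
        with np.errstate(invalid="ignore"):
            bl = np.nanmean(ctrl[i][idx_c], axis=1)
            bt = np.nanmean(treat[i][idx_t], axis=1)
        ok = np.isfinite(bl) & np.isfinite(bt)
        n_disc = int(n_boot - ok.sum())
        point = float(_afe(wt, wl, gc[g]))
        if ok.sum() == 0:
            out.append(AFEEstimate(g, method, point, float("nan"), float("nan"),
                                   ci_level, n_boot, False, threshold, n_disc, True))
            continue
        samples = np.asarray(_afe(bt[ok], bl[ok], gc[g]), dtype=float)
        lo, hi = _percentile_ci(samples, ci_level)
        out.append(AFEEstimate(
            genome_id=g, method=method, afe=point, ci_low=lo, ci_high=hi,
            ci_level_used=ci_level, n_boot=n_boot, labeled=bool(lo > threshold),
            threshold_used=threshold, n_discarded=n_disc,
            unstable=n_disc > n_boot / 2, boot_samples=samples,
        ))
    return out


def adjust_ci(
    estimates: Sequence[AFEEstimate],
    method: str = "fcr",
    q_or_alpha: float = 0.05,
    threshold: float | None = None,
) -> list[AFEEstimate]:
    """Multiplicity-adjust bootstrap confidence intervals over ``m`` genomes.

    ``bonferroni``: every interval is recomputed at level ``1 - alpha/m``.
    ``fcr`` (false coverage rate): genomes whose unadjusted interval lies
    above the threshold are selected (R of m); intervals for the selected are
    recomputed at level ``1 - R*q/m``.  Labeled flags are re-derived from the
    adjusted intervals.
    """
    ests = list(estimates)
    m = len(ests)
    if m == 0:
        raise ValueError("no estimates to adjust")
    if method not in ("fcr", "bonferroni"):
        raise ValueError(f"unknown adjustment {method!r}")
    levels = {e.ci_level_used for e in ests}
    if len(levels) != 1:
        raise ValueError("estimates must share ci_level")
    base_level = levels.pop()

    def _recompute(e: AFEEstimate, level: float) -> AFEEstimate:
        if e.boot_samples is None or len(e.boot_samples) == 0:
            return replace(e, labeled=False)
        level = min(level, 1.0 - 1e-12)
        lo, hi = _percentile_ci(e.boot_samples, level)
        thr = e.threshold_used if threshold is None else threshold
        return replace(e, ci_low=lo, ci_high=hi, ci_level_used=level,
                       labeled=bool(lo > thr), threshold_used=thr)

    if method == "bonferroni":
        level = 1.0 - (1.0 - base_level) / m
        return [_recompute(e, level) for e in ests]

    def _selected(e: AFEEstimate) -> bool:
        thr = e.threshold_used if threshold is None else threshold
        return np.isfinite(e.ci_low) and e.ci_low > thr

    r = sum(_selected(e) for e in ests)
    level = 1.0 - r * q_or_alpha / m
    out = []
    for e in ests:
        if _selected(e):
            out.append(_recompute(e, level))
        else:
            thr = e.threshold_used if threshold is None else threshold
            out.append(replace(e, labeled=False, threshold_used=thr))
    return out


def estimates_frame(estimates: Sequence[AFEEstimate]) -> pd.DataFrame:
    """Tabular view of AFE estimates (one row per genome)."""
    rows = [{
        "genome_id": e.genome_id, "method": e.method, "afe": e.afe,
        "ci_low": e.ci_low, "ci_high": e.ci_high,
        "ci_level_used": e.ci_level_used, "labeled": e.labeled,
        "threshold_used": e.threshold_used, "n_boot": e.n_boot,
        "n_discarded": e.n_discarded, "unstable": e.unstable,
    } for e in estimates]
    return pd.DataFrame(rows).set_index("genome_id")
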