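"""Incorporator identification: HR-SIP, MW-HR-SIP, filters, and scoring.

HR-SIP tests, genome by genome, whether absolute abundance in a "heavy"
buoyant-density window is greater in the isotope treatment than in the
unlabeled control; MW-HR-SIP repeats the test across several overlapping
heavy windows and calls a genome labeled if any window is significant after
Benjamini-Hochberg correction over all window x genome tests.  Both scan a
grid of sparsity thresholds (minimum presence across window fractions) and
keep the threshold that rejects the most hypotheses.

The default two-group test is a one-sided Welch t-test on log1p-transformed
per-sample window totals (the biological replicate is the unit of
replication); any callable ``test(treat, ctrl) -> p_value`` can be
substituted (e.g., a negative-binomial Wald test).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AbundanceTable, CoverageTable, FractionMeta, SampleDesign, meta_frame
from .qsip import AFEEstimate, IsotopeParams, adjust_ci, bootstrap_afe

HEAVY_WINDOW_START = 1.71  # g/mL; theoretical E. coli peak is 1.709 at GC 0.504
MW_WINDOWS_DEFAULT = ((1.71, 1.74), (1.72, 1.75), (1.73, 1.76))
SPARSITY_GRID_DEFAULT = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass(frozen=True)
class WindowSpec:
    density_low: float
    density_high: float

    def __post_init__(self) -> None:
        if not self.density_low < self.density_high:
            raise ValueError("density_low must be < density_high")

    def contains(self, density) -> np.ndarray:
        d = np.asarray(density, dtype=float)
        return (d >= self.density_low) & (d <= self.density_high)


@dataclass
class IncorporatorCall:
    genome_id: str
    method: str  # hrsip | mwhrsip | qsip | deltabd | sequential | consensus
    labeled: bool
    p_value: float | None = None
    p_adj: float | None = None
    window_hit: WindowSpec | None = None
    sparsity_used: float | None = None
    note: str = ""


def diff_abundance_test(treat, ctrl, test: Callable | None = None) -> float:
    """One-sided p-value for treatment > control abundance in a heavy window.

    Default backend: Welch (unequal-variance) t-test on log1p-transformed
    values.  Degenerate inputs (both groups constant and equal) return 1.0.
    """
    treat = np.asarray(treat, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if len(treat) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 values per group")
    if test is not None:
        return float(test(treat, ctrl))
    lt, lc = np.log1p(treat), np.log1p(ctrl)
    if np.ptp(lt) == 0 and np.ptp(lc) == 0:
        # degenerate: no within-group variance; perfect separation counts as
        # evidence, exact equality as none
        return 1.0 if lt[0] <= lc[0] else 0.0
    import warnings

    with warnings.catch_warnings():
        # near-identical groups trigger a scipy precision warning; the NaN
        # fallback below already handles that case
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(lt, lc, equal_var=False, alternative="greater").pvalue
    return 1.0 if np.isnan(p) else float(p)


@dataclass
class _WindowData:
    """Per-genome window-fraction values and per-sample totals for one window."""

    treat_frac: np.ndarray   # genomes x (treatment window fractions)
    ctrl_frac: np.ndarray    # genomes x (control window fractions)
    treat_totals: np.ndarray  # genomes x treatment samples
    ctrl_totals: np.ndarray   # genomes x control samples
    index: pd.Index


def _window_values(
    abund: AbundanceTable,
    meta: Sequence[FractionMeta],
    design: SampleDesign,
    window: WindowSpec,
) -> _WindowData:
    mf = meta_frame(meta).loc[list(abund.libraries)]
    in_win = window.contains(mf["density"].to_numpy())
    if not in_win.any():
        raise ValueError(f"window {window} overlaps no fractions")

    def _per_condition(samples):
        libs = mf.index[in_win & mf["sample_id"].isin(samples).to_numpy()]
        if len(libs) == 0:
            raise ValueError(f"window {window} overlaps no fractions in one condition")
        frac = abund.df[libs].to_numpy(dtype=float)
        totals = abund.df[libs].T.groupby(mf.loc[libs, "sample_id"]).sum().T
        return frac, totals.to_numpy(dtype=float)

    t_frac, t_tot = _per_condition(design.treatment_samples)
    c_frac, c_tot = _per_condition(design.control_samples)
    return _WindowData(t_frac, c_frac, t_tot, c_tot, abund.df.index)


def _sparsity_pvalues(
    wd: _WindowData, sparsity_pct: float, test: Callable | None,
) -> np.ndarray:
    """Raw p-values per genome; NaN for genomes failing the presence filter.

    "Present" means strictly positive abundance; a genome must be present in
    more than ``sparsity_pct`` percent of all window fractions (both
    conditions pooled) to be tested.  The two-group test compares per-sample
    window totals between conditions.
    """
    both = np.concatenate([wd.treat_frac, wd.ctrl_frac], axis=1)
    presence = 100.0 * (both > 0).mean(axis=1)
    p = np.full(both.shape[0], np.nan)
    for i in range(both.shape[0]):
        if presence[i] > sparsity_pct:
            p[i] = diff_abundance_test(wd.treat_totals[i], wd.ctrl_totals[i], test=test)
    return p


def _bh(p: np.ndarray, alpha: float) -> np.ndarray:
    """BH-adjusted p-values, NaN-preserving."""
    adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        adj[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[1]
    return adj


def _best_sparsity(
    wd: _WindowData,
    sparsity_grid: Sequence[float], alpha: float, test: Callable | None,
) -> tuple[float, np.ndarray]:
    """Pick the sparsity threshold with the most BH rejections (ties -> smallest)."""
    best = None
    for s in sparsity_grid:
        p = _sparsity_pvalues(wd, s, test)
        n_rej = int(np.nansum(_bh(p, alpha) <= alpha))
        if best is None or n_rej > best[0]:
            best = (n_rej, s, p)
    return best[1], best[2]


def hr_sip(
    abund: AbundanceTable,
    meta: Sequence[FractionMeta],
    design: SampleDesign,
    window: WindowSpec | None = None,
    sparsity_grid: Sequence[float] = SPARSITY_GRID_DEFAULT,
    alpha: float = 0.05,
    test: Callable | None = None,
) -> list[IncorporatorCall]:
    """HR-SIP: one heavy window from 1.71 g/mL to the maximum treatment density."""
    if window is None:
        mf = meta_frame(meta)
        max_rho = float(mf.loc[mf["sample_id"].isin(design.treatment_samples), "density"].max())
        window = WindowSpec(HEAVY_WINDOW_START, max_rho)
    wd = _window_values(abund, meta, design, window)
    index = wd.index
    s, p = _best_sparsity(wd, sparsity_grid, alpha, test)
    p_adj = _bh(p, alpha)
    calls = []
    for i, g in enumerate(index):
        testable = np.isfinite(p[i])
        calls.append(IncorporatorCall(
            genome_id=g, method="hrsip",
            labeled=bool(testable and p_adj[i] <= alpha),
            p_value=float(p[i]) if testable else None,
            p_adj=float(p_adj[i]) if testable else None,
            window_hit=window if testable and p_adj[i] <= alpha else None,
            sparsity_used=s, note="" if testable else "untestable (sparsity filter)",
        ))
    return calls


def mw_hr_sip(
    abund: AbundanceTable,
    meta: Sequence[FractionMeta],
    design: SampleDesign,
    windows: Sequence[tuple[float, float]] = MW_WINDOWS_DEFAULT,
    sparsity_grid: Sequence[float] = SPARSITY_GRID_DEFAULT,
    alpha: float = 0.05,
    test: Callable | None = None,
) -> list[IncorporatorCall]:
    """MW-HR-SIP over overlapping heavy windows.

    Per window the sparsity threshold is chosen as in HR-SIP; BH correction
    is then applied across the pooled window x genome p-values, and a genome
    is labeled if significant in ANY window.  ``window_hit`` records the most
    significant window.
    """
    specs = [WindowSpec(lo, hi) for lo, hi in windows]
    index = abund.df.index
    per_window = []  # (spec, sparsity, raw p per genome)
    for spec in specs:
        wd = _window_values(abund, meta, design, spec)
        s, p = _best_sparsity(wd, sparsity_grid, alpha, test)
        per_window.append((spec, s, p))
    pooled = np.concatenate([p for _, _, p in per_window])
    pooled_adj = _bh(pooled, alpha)
    n = len(index)
    calls = []
    for i, g in enumerate(index):
        entries = []
        for w, (spec, s, p) in enumerate(per_window):
            if np.isfinite(p[i]):
                entries.append((float(pooled_adj[w * n + i]), float(p[i]), spec, s))
        if not entries:
            calls.append(IncorporatorCall(g, "mwhrsip", False,
                                          note="untestable (sparsity filter)"))
            continue
        adj, raw, spec, s = min(entries, key=lambda e: (e[0], e[1]))
        labeled = adj <= alpha
        calls.append(IncorporatorCall(
            genome_id=g, method="mwhrsip", labeled=bool(labeled),
            p_value=raw, p_adj=adj, window_hit=spec if labeled else None,
            sparsity_used=s,
        ))
    return calls


def coverage_filter(
    cov: CoverageTable,
    meta: Sequence[FractionMeta],
    min_mean_total_coverage: float = 10.0,
    genomes: Iterable[str] | None = None,
) -> list[str]:
    """Genomes whose mean (over samples) total per-sample coverage is >= threshold.

    "Total coverage" is the sum of per-fraction coverages within one sample;
    the boundary is inclusive.
    """
    if min_mean_total_coverage < 0:
        raise ValueError("threshold must be >= 0")
    ids = list(genomes) if genomes is not None else list(cov.df.index)
    mf = meta_frame(meta).loc[list(cov.libraries)]
    totals = cov.df.loc[ids].T.groupby(mf["sample_id"]).sum().T  # genome x sample
    mean_total = totals.mean(axis=1)
    return [g for g in ids if mean_total[g] >= min_mean_total_coverage]


def afe_threshold_call(est: AFEEstimate, min_afe: float = 0.0) -> bool:
    """Labeled iff the lower CI bound exceeds the minimum AFE threshold."""
    if not np.isfinite(est.ci_low):
        return False
    return bool(est.ci_low > min_afe)


def sequential_workflow(
    abund: AbundanceTable,
    meta: Sequence[FractionMeta],
    design: SampleDesign,
    gc: Mapping[str, float],
    windows: Sequence[tuple[float, float]] = MW_WINDOWS_DEFAULT,
    sparsity_grid: Sequence[float] = SPARSITY_GRID_DEFAULT,
    alpha: float = 0.05,
    adjust: str = "fcr",
    q_or_alpha: float = 0.05,
    min_afe: float = 0.0,
    params: IsotopeParams | None = None,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
    test: Callable | None = None,
) -> tuple[list[IncorporatorCall], list[AFEEstimate]]:
    """MW-HR-SIP as a first-pass filter, then bootstrap qSIP on the survivors.

    Restricting the second stage to stage-1 positives shrinks the number of
    simultaneously-adjusted intervals (m = number of candidates), increasing
    power; final labeled = positive in both stages.
    """
    stage1 = mw_hr_sip(abund, meta, design, windows=windows,
                       sparsity_grid=sparsity_grid, alpha=alpha, test=test)
    candidates = [c.genome_id for c in stage1 if c.labeled]
    stage1_by_id = {c.genome_id: c for c in stage1}
    if not candidates:
        calls = [IncorporatorCall(c.genome_id, "sequential", False,
                                  p_value=c.p_value, p_adj=c.p_adj,
                                  note="no stage-1 candidates")
                 for c in stage1]
        return calls, []
    ests = bootstrap_afe(abund, meta, design, gc, genomes=candidates,
                         params=params, n_boot=n_boot, ci_level=ci_level,
                         threshold=min_afe, seed=seed)
    ests = adjust_ci(ests, method=adjust, q_or_alpha=q_or_alpha, threshold=min_afe)
    labeled2 = {e.genome_id for e in ests if e.labeled}
    calls = []
    for c in stage1:
        final = c.genome_id in labeled2
        calls.append(IncorporatorCall(
            genome_id=c.genome_id, method="sequential", labeled=final,
            p_value=c.p_value, p_adj=c.p_adj, window_hit=c.window_hit,
            sparsity_used=c.sparsity_used,
            note="" if c.labeled else "not a stage-1 candidate",
        ))
    return calls, ests


def consensus(
    calls_a: Sequence[IncorporatorCall],
    calls_b: Sequence[IncorporatorCall],
    mode: str = "intersection",
) -> list[IncorporatorCall]:
    """Combine two call sets over the same genome universe.

    ``intersection`` labels genomes called by both methods (false positives
    of unrelated methods rarely coincide); ``union`` labels genomes called by
    either.
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    a = {c.genome_id: c for c in calls_a}
    b = {c.genome_id: c for c in calls_b}
    if set(a) != set(b):
        raise ValueError("call sets cover different genome universes")
    out = []
    for g in a:
        la, lb = a[g].labeled, b[g].labeled
        labeled = (la and lb) if mode == "intersection" else (la or lb)
        out.append(IncorporatorCall(g, "consensus", bool(labeled),
                                    note=f"{mode} of {a[g].method}+{b[g].method}"))
    return out


@dataclass
class PerformanceReport:
    true_positives: int
    false_positives: int
    true_negatives: int
    false_negatives: int

    @property
    def specificity(self) -> float:
        denom = self.false_positives + self.true_negatives
        return self.true_negatives / denom if denom else float("nan")

    @property
    def sensitivity(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        return balanced_accuracy(self.specificity, self.sensitivity)


def balanced_accuracy(specificity: float, sensitivity: float) -> float:
    """Mean of specificity and sensitivity."""
    return (specificity + sensitivity) / 2.0


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (printed-table convention), not banker's."""
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"), rounding=ROUND_HALF_UP))


def performance_metrics(
    calls: Sequence[IncorporatorCall] | Mapping[str, bool],
    truth: Iterable[str],
) -> PerformanceReport:
    """Confusion counts and rates of a call set against known labeled genomes.

    ``truth`` is the set of genome IDs that are truly labeled; every called
    genome must have defined truth (a genome outside the universe is an
    error in the caller, not here).
    """
    if isinstance(calls, Mapping):
        labeled = dict(calls)
    else:
        labeled = {c.genome_id: c.labeled for c in calls}
    truth_set = set(truth)
    tp = sum(1 for g, l in labeled.items() if l and g in truth_set)
    fp = sum(1 for g, l in labeled.items() if l and g not in truth_set)
    fn = sum(1 for g, l in labeled.items() if not l and g in truth_set)
    tn = sum(1 for g, l in labeled.items() if not l and g not in truth_set)
    return PerformanceReport(tp, fp, tn, fn)


def calls_frame(calls: Sequence[IncorporatorCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "genome_id": c.genome_id, "method": c.method, "labeled": c.labeled,
        "p_value": c.p_value, "p_adj": c.p_adj,
        "window": (f"{c.window_hit.density_low}-{c.window_hit.density_high}"
                   if c.window_hit else ""),
        "sparsity_used": c.sparsity_used, "note": c.note,
    } for c in calls]).set_index("genome_id")
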