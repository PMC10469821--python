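"""End-to-end pipeline: QC -> normalization -> AFE -> incorporator calls.

Configuration is a plain mapping (typically loaded from YAML); every output
TSV carries a provenance header line with the package version, a hash of the
configuration, and the seed, so identical config + inputs reproduce
byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .datamodel import (
    AbundanceTable,
    CoverageTable,
    read_coverage_table,
    read_fraction_meta,
    read_genome_meta,
    read_sequin_reference,
    read_spikein_reference,
    validate_design,
    write_coverage_table,
)
from .incorporators import (
    IncorporatorCall,
    calls_frame,
    consensus,
    coverage_filter,
    hr_sip,
    mw_hr_sip,
    performance_metrics,
    sequential_workflow,
)
from .normalization import (
    abundance_by_dna,
    fit_library_models,
    qc_frame,
    relative_coverage,
    scale_to_absolute,
    spikein_qc,
)
from .qsip import (
    DeltaBDParams,
    IsotopeParams,
    adjust_ci,
    bootstrap_afe,
    estimates_frame,
)

log = logging.getLogger("sipmet")

DEFAULT_CONFIG: dict[str, Any] = {
    "normalization": {
        "method": "sequin",          # sequin | rel_coverage | relabund_x_dna | relcov_x_dna | unscaled
        "regression": "ols",         # ols | robust
        "cooks_filter": True,
        "cooks_rule": "4/n",
        "cov_threshold": 250.0,
        "log_transform": False,
    },
    "qc": {"enabled": True},
    "afe": {
        "methods": ["qsip"],         # qsip and/or deltabd
        "i_max": None,               # required for deltabd
        "n_boot": 1000,
        "ci_level": 0.95,
        "adjust": "fcr",             # fcr | bonferroni | none
        "q_or_alpha": 0.05,
        "seed": 0,
    },
    "identify": {
        "methods": ["sequential"],   # hrsip | mwhrsip | sequential | consensus
        "alpha": 0.05,
        "min_afe": 0.0,
        "min_coverage": 0.0,
    },
}


def _merged(base: Mapping, override: Mapping | None) -> dict:
    out = {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    design: Any
    qc_reports: list
    abundance: AbundanceTable
    estimates: dict[str, list]
    calls: dict[str, list[IncorporatorCall]]
    performance: dict[str, Any] = field(default_factory=dict)
    excluded_samples: dict[str, str] = field(default_factory=dict)


def run_pipeline(
    coverage: CoverageTable,
    meta,
    genomes,
    sequin_ref=None,
    spikein_ref=None,
    truth: Mapping[str, float] | None = None,
    config: Mapping | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute QC, normalization, AFE estimation, and incorporator calling."""
    cfg = _merged(DEFAULT_CONFIG, config)
    chash = config_hash(cfg)
    seed = int(cfg["afe"]["seed"])
    header = f"sipmet {__version__} config={chash} seed={seed}"
    gc = {g.genome_id: g.gc for g in genomes}
    standard_ids = ({s.sequin_id for s in sequin_ref or []}
                    | {s.spikein_id for s in spikein_ref or []})

    design = validate_design(meta)
    params = IsotopeParams.for_isotope(design.isotope)

    # --- QC: spike-in peak order, before any normalization -----------------
    qc_reports = []
    if cfg["qc"]["enabled"] and spikein_ref:
        qc_reports = spikein_qc(coverage, spikein_ref, meta)
        for r in qc_reports:
            if not r.passed:
                log.warning("QC failure, excluding sample %s: %s", r.sample_id, r.notes)
                design = design.exclude(r.sample_id, "spike-in QC failure")
    kept_samples = set(design.control_samples) | set(design.treatment_samples)
    meta = [m for m in meta if m.sample_id in kept_samples]
    coverage = CoverageTable(coverage.df[[m.library_id for m in meta]])

    # --- Normalization -----------------------------------------------------
    norm = cfg["normalization"]
    method = norm["method"]
    if method == "sequin":
        if not sequin_ref:
            raise ValueError("normalization stage: sequin method requires a sequin reference")
        models = fit_library_models(
            coverage, sequin_ref, method=norm["regression"],
            cooks_filter=norm["cooks_filter"], cooks_rule=norm["cooks_rule"],
            cov_threshold=norm["cov_threshold"], log_transform=norm["log_transform"],
        )
        abundance = scale_to_absolute(coverage, models, standard_ids)
    elif method == "rel_coverage":
        abundance = relative_coverage(coverage, standard_ids)
    elif method in ("relabund_x_dna", "relcov_x_dna"):
        basis = "relative_abundance" if method == "relabund_x_dna" else "relative_coverage"
        abundance = abundance_by_dna(coverage, meta, genomes, basis, standard_ids)
    elif method == "unscaled":
        abundance = AbundanceTable(
            coverage.df.drop(index=[i for i in standard_ids if i in coverage.df.index]),
            method="unscaled")
    else:
        raise ValueError(f"normalization stage: unknown method {method!r}")

    # --- Coverage filter ---------------------------------------------------
    ident = cfg["identify"]
    genome_cov = CoverageTable(coverage.df.drop(
        index=[i for i in standard_ids if i in coverage.df.index]))
    kept = coverage_filter(genome_cov, meta, float(ident["min_coverage"]))
    abundance = abundance.subset_features(kept)

    # --- AFE estimation ----------------------------------------------------
    afe_cfg = cfg["afe"]
    estimates: dict[str, list] = {}
    for m in afe_cfg["methods"]:
        deltabd = DeltaBDParams(float(afe_cfg["i_max"])) if m == "deltabd" else None
        ests = bootstrap_afe(
            abundance, meta, design, gc, method=m, params=params, deltabd=deltabd,
            n_boot=int(afe_cfg["n_boot"]), ci_level=float(afe_cfg["ci_level"]),
            threshold=float(ident["min_afe"]), seed=seed,
        )
        if afe_cfg["adjust"] != "none":
            ests = adjust_ci(ests, method=afe_cfg["adjust"],
                             q_or_alpha=float(afe_cfg["q_or_alpha"]))
        estimates[m] = ests

    # --- Incorporator identification ---------------------------------------
    calls: dict[str, list[IncorporatorCall]] = {}
    for m in ident["methods"]:
        if m == "hrsip":
            calls[m] = hr_sip(abundance, meta, design, alpha=float(ident["alpha"]))
        elif m == "mwhrsip":
            calls[m] = mw_hr_sip(abundance, meta, design, alpha=float(ident["alpha"]))
        elif m == "sequential":
            seq_calls, seq_ests = sequential_workflow(
                abundance, meta, design, gc, alpha=float(ident["alpha"]),
                adjust=afe_cfg["adjust"] if afe_cfg["adjust"] != "none" else "fcr",
                q_or_alpha=float(afe_cfg["q_or_alpha"]),
                min_afe=float(ident["min_afe"]), params=params,
                n_boot=int(afe_cfg["n_boot"]), ci_level=float(afe_cfg["ci_level"]),
                seed=seed,
            )
            calls[m] = seq_calls
            estimates.setdefault("sequential_qsip", seq_ests)
        elif m == "consensus":
            pass  # built after the loop from mwhrsip + qsip
        else:
            raise ValueError(f"identify stage: unknown method {m!r}")
    for m, ests in estimates.items():
        if m in ("qsip", "deltabd"):
            calls[m] = [IncorporatorCall(e.genome_id, m, e.labeled) for e in ests]
    if "consensus" in ident["methods"]:
        if "mwhrsip" not in calls or "qsip" not in calls:
            raise ValueError("identify stage: consensus requires mwhrsip and qsip calls")
        calls["consensus"] = consensus(calls["mwhrsip"], calls["qsip"])

    # --- Scoring against truth --------------------------------------------
    performance = {}
    if truth is not None:
        truly_labeled = {g for g, a in truth.items() if a > 0}
        for m, cs in calls.items():
            performance[m] = performance_metrics(cs, truly_labeled)

    result = PipelineResult(
        design=design, qc_reports=qc_reports, abundance=abundance,
        estimates=estimates, calls=calls, performance=performance,
        excluded_samples=dict(design.excluded),
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir), header, cfg)
    return result


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t")


def _write_outputs(result: PipelineResult, outdir: Path, header: str, cfg: Mapping) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_used.json").write_text(json.dumps(cfg, indent=2, default=str))
    write_coverage_table(result.abundance, outdir / "abundance.tsv", header=header)
    if result.qc_reports:
        _write_tsv(qc_frame(result.qc_reports), outdir / "qc_report.tsv", header)
    for m, ests in result.estimates.items():
        if ests:
            _write_tsv(estimates_frame(ests), outdir / f"afe_{m}.tsv", header)
    for m, cs in result.calls.items():
        _write_tsv(calls_frame(cs), outdir / f"calls_{m}.tsv", header)
    if result.performance:
        rows = [{"method": m, "TP": p.true_positives, "FP": p.false_positives,
                 "TN": p.true_negatives, "FN": p.false_negatives,
                 "specificity": p.specificity, "sensitivity": p.sensitivity,
                 "balanced_accuracy": p.balanced_accuracy}
                for m, p in result.performance.items()]
        _write_tsv(pd.DataFrame(rows).set_index("method"),
                   outdir / "performance.tsv", header)


def run_pipeline_from_paths(
    coverage_path, meta_path, genome_path,
    sequin_path=None, spikein_path=None, truth_path=None,
    config: Mapping | None = None, outdir=None,
) -> PipelineResult:
    """File-based entry point used by the CLI."""
    coverage = read_coverage_table(coverage_path)
    meta = read_fraction_meta(meta_path)
    genomes = read_genome_meta(genome_path)
    sequin_ref = read_sequin_reference(sequin_path) if sequin_path else None
    spikein_ref = read_spikein_reference(spikein_path) if spikein_path else None
    truth = None
    if truth_path:
        tdf = pd.read_csv(truth_path, sep="\t", comment="#")
        truth = dict(zip(tdf["genome_id"], tdf["true_afe"].astype(float)))
    return run_pipeline(coverage, meta, genomes, sequin_ref, spikein_ref,
                        truth=truth, config=config, outdir=outdir)


def evaluate(calls_path, truth_path):
    """Score a calls TSV against a truth table (genome_id, true_afe)."""
    calls = pd.read_csv(calls_path, sep="\t", comment="#")
    tdf = pd.read_csv(truth_path, sep="\t", comment="#")
    truth = dict(zip(tdf["genome_id"], tdf["true_afe"].astype(float)))
    missing = set(calls["genome_id"]) - set(truth)
    if missing:
        raise ValueError(f"truth table missing called genomes: {sorted(missing)[:5]}")
    labeled = dict(zip(calls["genome_id"], calls["labeled"].astype(bool)))
    return performance_metrics(labeled, {g for g, a in truth.items() if a > 0})
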