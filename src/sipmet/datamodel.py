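"""Domain types and tab-separated readers/writers for SIP metagenomics tables.

All on-disk tables are TSV with a header row; coverage/abundance matrices put
feature IDs (genomes, sequins, spike-ins) in the first column and one column
per fraction library.  Lines starting with ``#`` are treated as comments so
that outputs can carry a provenance header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

CONDITIONS = ("control", "treatment")
ISOTOPES = ("13C", "18O")


@dataclass(frozen=True)
class GenomeRecord:
    """A genome (MAG) with the metadata used by the qSIP model and dereplication."""

    genome_id: str
    gc: float
    length_bp: int
    completeness_pct: float | None = None
    contamination_pct: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"{self.genome_id}: gc must be in [0, 1], got {self.gc}")
        if self.length_bp <= 0:
            raise ValueError(f"{self.genome_id}: length_bp must be positive")
        if self.completeness_pct is not None and not 0 <= self.completeness_pct <= 100:
            raise ValueError(f"{self.genome_id}: completeness_pct out of [0, 100]")
        if self.contamination_pct is not None and self.contamination_pct < 0:
            raise ValueError(f"{self.genome_id}: contamination_pct must be >= 0")


@dataclass(frozen=True)
class FractionMeta:
    """One fraction library: position on the gradient plus sample bookkeeping."""

    library_id: str
    sample_id: str
    replicate: int
    condition: str  # "control" | "treatment"
    isotope: str    # "13C" | "18O"
    fraction_index: int
    density: float  # buoyant density, g/mL
    dna_conc: float = 0.0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"{self.library_id}: condition must be one of {CONDITIONS}")
        if self.isotope not in ISOTOPES:
            raise ValueError(f"{self.library_id}: isotope must be one of {ISOTOPES}")
        if self.replicate < 1 or self.fraction_index < 1:
            raise ValueError(f"{self.library_id}: replicate and fraction_index must be >= 1")
        if not self.density > 0:
            raise ValueError(f"{self.library_id}: density must be positive")
        if self.dna_conc < 0:
            raise ValueError(f"{self.library_id}: dna_conc must be >= 0")


@dataclass(frozen=True)
class SequinReference:
    """A post-fractionation internal standard with known concentration."""

    sequin_id: str
    known_concentration: float
    group_label: str | None = None

    def __post_init__(self) -> None:
        if not self.known_concentration > 0:
            raise ValueError(f"{self.sequin_id}: known_concentration must be positive")


@dataclass(frozen=True)
class SpikeInReference:
    """A pre-centrifugation spike-in with a predictable peak density."""

    spikein_id: str
    expected_peak_density: float
    gc: float = 0.5
    label_fraction_13c: float = 0.0

    def __post_init__(self) -> None:
        if not self.expected_peak_density > 0:
            raise ValueError(f"{self.spikein_id}: expected_peak_density must be positive")
        if not 0 <= self.label_fraction_13c <= 1:
            raise ValueError(f"{self.spikein_id}: label_fraction_13C must be in [0, 1]")


@dataclass(frozen=True)
class PairwiseSimilarity:
    """One gANI / alignment-fraction comparison between two genomes (0-100 scales)."""

    id_a: str
    id_b: str
    gani: float
    af: float

    def __post_init__(self) -> None:
        if not 0 <= self.gani <= 100:
            raise ValueError("gani must be in [0, 100]")
        if not 0 <= self.af <= 100:
            raise ValueError("af must be in [0, 100]")


@dataclass
class SampleDesign:
    """Control/treatment grouping of samples with exclusions and warnings."""

    control_samples: tuple[str, ...]
    treatment_samples: tuple[str, ...]
    isotope: str
    excluded: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.control_samples:
            raise ValueError("no control condition samples in design")
        if not self.treatment_samples:
            raise ValueError("no treatment condition samples in design")
        if set(self.control_samples) & set(self.treatment_samples):
            raise ValueError("samples cannot belong to both conditions")

    @property
    def replicate_counts(self) -> tuple[int, int]:
        return len(self.control_samples), len(self.treatment_samples)

    def exclude(self, sample_id: str, reason: str) -> "SampleDesign":
        """Return a design with one sample removed (e.g., after QC failure)."""
        if sample_id not in self.control_samples + self.treatment_samples:
            raise ValueError(f"unknown sample {sample_id!r}")
        return SampleDesign(
            control_samples=tuple(s for s in self.control_samples if s != sample_id),
            treatment_samples=tuple(s for s in self.treatment_samples if s != sample_id),
            isotope=self.isotope,
            excluded={**self.excluded, sample_id: reason},
            warnings=list(self.warnings),
        )


class _Matrix:
    """Feature x library matrix backed by a pandas DataFrame."""

    def __init__(self, df: pd.DataFrame):
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate feature ID: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate library ID: {dup!r}")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("matrix values must be numeric")
        if np.any(vals < 0):
            raise ValueError("matrix values must be non-negative")
        self.df = df.astype(float)

    @property
    def features(self) -> list[str]:
        return list(self.df.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.df.columns)

    def subset_features(self, ids: Iterable[str]):
        return type(self)(self.df.loc[list(ids)], *self._extra())

    def drop_features(self, ids: Iterable[str]):
        return type(self)(self.df.drop(index=[i for i in ids if i in self.df.index]), *self._extra())

    def _extra(self) -> tuple:
        return ()


class CoverageTable(_Matrix):
    """Mean coverage per feature (genome/sequin/spike-in) per fraction library."""


ABUNDANCE_METHODS = ("sequin", "rel_coverage", "relabund_x_dna", "relcov_x_dna", "unscaled")


class AbundanceTable(_Matrix):
    """Per-fraction abundance y_ijk under a named normalization method."""

    def __init__(self, df: pd.DataFrame, method: str = "unscaled"):
        if method not in ABUNDANCE_METHODS:
            raise ValueError(f"unknown abundance method {method!r}")
        super().__init__(df)
        self.method = method

    def _extra(self) -> tuple:
        return (self.method,)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def _numeric_matrix(raw: pd.DataFrame, path) -> pd.DataFrame:
    id_col = raw.columns[0]
    df = raw.set_index(id_col)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        df[col] = converted
    df.index.name = None
    return df


def read_coverage_table(path) -> CoverageTable:
    """Read a TSV coverage matrix (first column = feature IDs)."""
    return CoverageTable(_numeric_matrix(_read_tsv(path), path))


def write_coverage_table(table: _Matrix, path, header: str | None = None) -> None:
    """Write a coverage/abundance matrix as TSV, optionally with a # header line."""
    fh = path if hasattr(path, "write") else open(path, "w")
    try:
        if header:
            fh.write(f"# {header}\n")
        table.df.rename_axis("feature_id").to_csv(fh, sep="\t")
    finally:
        if fh is not path:
            fh.close()


def read_abundance_table(path, method: str = "unscaled") -> AbundanceTable:
    return AbundanceTable(_numeric_matrix(_read_tsv(path), path), method=method)


_META_COLS = ["library_id", "sample_id", "replicate", "condition", "isotope",
              "fraction_index", "density", "dna_conc"]


def read_fraction_meta(path) -> list[FractionMeta]:
    raw = _read_tsv(path)
    missing = set(_META_COLS) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing fraction metadata columns {sorted(missing)}")
    out = [FractionMeta(
        library_id=r.library_id, sample_id=r.sample_id, replicate=int(r.replicate),
        condition=r.condition, isotope=r.isotope, fraction_index=int(r.fraction_index),
        density=float(r.density), dna_conc=float(r.dna_conc),
    ) for r in raw.itertuples()]
    seen: set[tuple[str, int]] = set()
    for m in out:
        key = (m.sample_id, m.fraction_index)
        if key in seen:
            raise ValueError(f"duplicate (sample_id, fraction_index): {key}")
        seen.add(key)
    return out


def write_fraction_meta(meta: Sequence[FractionMeta], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        meta_frame(meta).reset_index().to_csv(fh, sep="\t", index=False)


def meta_frame(meta: Sequence[FractionMeta]) -> pd.DataFrame:
    """Fraction metadata as a DataFrame indexed by library_id."""
    if not meta:
        raise ValueError("no metadata: fraction metadata is empty")
    df = pd.DataFrame([m.__dict__ for m in meta]).set_index("library_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate library_id in fraction metadata")
    return df


def read_genome_meta(path) -> list[GenomeRecord]:
    raw = _read_tsv(path)

    def _opt(v):
        return None if pd.isna(v) else float(v)

    return [GenomeRecord(
        genome_id=r.genome_id, gc=float(r.gc), length_bp=int(float(r.length)),
        completeness_pct=_opt(getattr(r, "completeness", None)),
        contamination_pct=_opt(getattr(r, "contamination", None)),
    ) for r in raw.itertuples()]


def write_genome_meta(genomes: Sequence[GenomeRecord], path, header: str | None = None) -> None:
    rows = [{"genome_id": g.genome_id, "gc": g.gc, "length": g.length_bp,
             "completeness": g.completeness_pct, "contamination": g.contamination_pct}
            for g in genomes]
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_sequin_reference(path) -> list[SequinReference]:
    raw = _read_tsv(path)
    return [SequinReference(r.sequin_id, float(r.concentration),
                            getattr(r, "group", None))
            for r in raw.itertuples()]


def write_sequin_reference(ref: Sequence[SequinReference], path) -> None:
    pd.DataFrame([{"sequin_id": s.sequin_id, "concentration": s.known_concentration,
                   "group": s.group_label} for s in ref]).to_csv(path, sep="\t", index=False)


def read_spikein_reference(path) -> list[SpikeInReference]:
    raw = _read_tsv(path)
    return [SpikeInReference(r.spikein_id, float(r.expected_peak_density),
                             float(r.gc), float(r.label_fraction))
            for r in raw.itertuples()]


def write_spikein_reference(ref: Sequence[SpikeInReference], path) -> None:
    pd.DataFrame([{"spikein_id": s.spikein_id,
                   "expected_peak_density": s.expected_peak_density,
                   "gc": s.gc, "label_fraction": s.label_fraction_13c}
                  for s in ref]).to_csv(path, sep="\t", index=False)


def read_pairwise_similarity(path) -> list[PairwiseSimilarity]:
    raw = _read_tsv(path)
    return [PairwiseSimilarity(r.id_a, r.id_b, float(r.gani), float(r.af))
            for r in raw.itertuples()]


# ---------------------------------------------------------------------------
# Experiment-design validation
# ---------------------------------------------------------------------------

def validate_design(meta: Sequence[FractionMeta], required_isotope: str | None = None) -> SampleDesign:
    """Group libraries into a control/treatment SampleDesign with sanity checks.

    Raises if either condition has no samples; records a warning for samples
    with fewer than two fractions (a weighted mean BD from one fraction
    carries no gradient information).
    """
    if not meta:
        raise ValueError("fraction metadata is empty")
    isotopes = {m.isotope for m in meta}
    if required_isotope is not None and isotopes != {required_isotope}:
        raise ValueError(f"expected isotope {required_isotope!r}, found {sorted(isotopes)}")
    by_sample: dict[str, list[FractionMeta]] = {}
    for m in meta:
        by_sample.setdefault(m.sample_id, []).append(m)
    control, treatment = [], []
    warnings = []
    for sample_id, fracs in by_sample.items():
        conds = {f.condition for f in fracs}
        if len(conds) != 1:
            raise ValueError(f"sample {sample_id!r} has mixed conditions {sorted(conds)}")
        (control if conds.pop() == "control" else treatment).append(sample_id)
        if len(fracs) < 2:
            warnings.append(f"sample {sample_id!r} has fewer than 2 fractions")
    if not control:
        raise ValueError("no control condition samples in design")
    if not treatment:
        raise ValueError("no treatment condition samples in design")
    return SampleDesign(
        control_samples=tuple(control), treatment_samples=tuple(treatment),
        isotope=sorted(isotopes)[0], warnings=warnings,
    )


# ---------------------------------------------------------------------------
# MAG dereplication
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MagCluster:
    members: tuple[str, ...]
    representative: str


def cluster_mags(
    sim: Sequence[PairwiseSimilarity],
    ids: Sequence[str],
    quality: Mapping[str, GenomeRecord],
    gani_min: float = 96.5,
    af_min: float = 30.0,
) -> list[MagCluster]:
    """Single-linkage species-level dereplication of MAGs.

    An edge joins two genomes iff the minimum over both comparison
    orientations of gANI is >= ``gani_min`` AND of AF is >= ``af_min``
    (inclusive thresholds).  Clusters are the connected components; genomes
    with no qualifying edge are singletons.  The representative is the member
    with the highest completeness, ties broken by lowest contamination, then
    by greatest length.
    """
    id_set = set(ids)
    if len(id_set) != len(ids):
        raise ValueError("duplicate ids")
    # min of both orientations when a pair is reported twice
    pair_vals: dict[tuple[str, str], tuple[float, float]] = {}
    for s in sim:
        for x in (s.id_a, s.id_b):
            if x not in id_set:
                raise ValueError(f"similarity record references unknown id {x!r}")
        key = (min(s.id_a, s.id_b), max(s.id_a, s.id_b))
        if key in pair_vals:
            g0, a0 = pair_vals[key]
            pair_vals[key] = (min(g0, s.gani), min(a0, s.af))
        else:
            pair_vals[key] = (s.gani, s.af)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for (a, b), (g, a_frac) in pair_vals.items():
        if a != b and g >= gani_min and a_frac >= af_min:
            graph.add_edge(a, b)

    def _rank(genome_id: str):
        q = quality[genome_id]
        comp = q.completeness_pct if q.completeness_pct is not None else -np.inf
        cont = q.contamination_pct if q.contamination_pct is not None else np.inf
        return (-comp, cont, -q.length_bp, genome_id)

    clusters = []
    for comp_nodes in nx.connected_components(graph):
        members = tuple(sorted(comp_nodes))
        for m in members:
            if m not in quality:
                raise ValueError(f"no quality record for {m!r}")
        rep = min(members, key=_rank)
        clusters.append(MagCluster(members=members, representative=rep))
    clusters.sort(key=lambda c: c.members)
    return clusters
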