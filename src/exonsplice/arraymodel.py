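"""Domain types and tabular I/O for the exon-array probe hierarchy.

The array is modeled as a three-level hierarchy: individual 25-mer probes
belong to probe sets (up to four probes targeting one exon region), and probe
sets belong to transcript clusters (the gene-level unit).  Background
(antigenomic) probes live in the same probe table, distinguished by
``is_background``, and carry only a GC count.

All interchange files are TSV (tab-separated, UTF-8, ``.`` decimal, header
row); the empty string encodes a missing value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Algorithm",
    "AnnotationIndex",
    "ConfigError",
    "ConsistencyError",
    "EventType",
    "ExpressionMatrix",
    "FormatError",
    "GeneResult",
    "IntensityMatrix",
    "Level",
    "ProbeAnnotation",
    "ProbeSetAnnotation",
    "SampleDesign",
    "SpliceResult",
    "read_annotation",
    "read_design",
    "read_intensities",
    "read_results",
    "write_annotation",
    "write_design",
    "write_intensities",
    "write_results",
]


class FormatError(ValueError):
    """A file or value does not conform to the expected tabular format."""


class ConsistencyError(ValueError):
    """Tables are individually well-formed but mutually inconsistent."""


class ConfigError(ValueError):
    """A configuration value is out of range or self-contradictory."""


class Level(str, enum.Enum):
    PROBESET = "probeset"
    TRANSCRIPT_CLUSTER = "transcript_cluster"


class Algorithm(str, enum.Enum):
    RMA = "rma"
    ITERPLIER = "iterplier"


class EventType(str, enum.Enum):
    NONE = "none"
    CASSETTE = "cassette"
    INTRON_RETENTION = "intron_retention"
    APA = "apa"
    APS = "aps"


@dataclass(frozen=True)
class ProbeAnnotation:
    """One probe: a PM probe mapped to a probe set, or a background probe.

    ``probeset_id`` is ``None`` exactly when ``is_background`` is true.
    ``gc_count`` is the number of G+C bases in the 25-mer (0-25); it drives
    GC-binned background matching for detection p-values.
    """

    probe_id: str
    probeset_id: str | None
    gc_count: int
    is_background: bool

    def __post_init__(self) -> None:
        if not 0 <= self.gc_count <= 25:
            raise FormatError(
                f"probe {self.probe_id!r}: gc_count {self.gc_count} outside 0-25"
            )
        if self.is_background != (self.probeset_id is None):
            raise ConsistencyError(
                f"probe {self.probe_id!r}: is_background must be true iff "
                f"probeset_id is empty"
            )


@dataclass(frozen=True)
class ProbeSetAnnotation:
    """One probe set with its position along the transcript.

    ``exon_index`` / ``rank_in_exon`` are 1-based ordinals in 5'->3' sense
    orientation.  ``known_event`` records a curated alternative-splicing
    annotation; constitutive probe sets never carry one.
    """

    probeset_id: str
    tc_id: str
    exon_index: int
    n_exons: int
    rank_in_exon: int
    n_probesets_in_exon: int
    is_constitutive: bool
    known_event: EventType = EventType.NONE
    crosshyb: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.exon_index <= self.n_exons:
            raise FormatError(
                f"probe set {self.probeset_id!r}: exon_index {self.exon_index} "
                f"outside 1..{self.n_exons}"
            )
        if not 1 <= self.rank_in_exon <= self.n_probesets_in_exon:
            raise FormatError(
                f"probe set {self.probeset_id!r}: rank_in_exon "
                f"{self.rank_in_exon} outside 1..{self.n_probesets_in_exon}"
            )
        if self.is_constitutive and self.known_event is not EventType.NONE:
            raise ConsistencyError(
                f"probe set {self.probeset_id!r}: constitutive probe sets "
                f"cannot carry a known event"
            )

    @property
    def is_terminal_exon(self) -> bool:
        return self.exon_index in (1, self.n_exons)


@dataclass(frozen=True)
class SampleDesign:
    """One array: its sample id, condition label and replicate number."""

    sample_id: str
    group: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise FormatError(
                f"sample {self.sample_id!r}: replicate must be positive"
            )


def validate_design(design: Sequence[SampleDesign]) -> tuple[str, str]:
    """Check the two-group >=2-replicate contract; return (group1, group2).

    Group order follows first appearance in the design table, so the first
    listed condition is the reference (group1) for every downstream contrast.
    """
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise ConsistencyError("duplicate sample_id in design")
    groups: list[str] = []
    for d in design:
        if d.group not in groups:
            groups.append(d.group)
    if len(groups) != 2:
        raise ConfigError(
            f"design must contain exactly two groups, found {groups!r}"
        )
    for g in groups:
        n = sum(1 for d in design if d.group == g)
        if n < 2:
            raise ConfigError(f"group {g!r} has {n} samples; need at least 2")
    return groups[0], groups[1]


@dataclass
class IntensityMatrix:
    """Linear-scale probe intensities, probes x samples; strictly positive."""

    data: pd.DataFrame  # index: probe_id, columns: sample_id, float values

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ConsistencyError("duplicate probe_id in intensity matrix")
        if self.data.columns.has_duplicates:
            raise ConsistencyError("duplicate sample_id in intensity matrix")
        vals = self.data.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            bad = np.argwhere(~(np.isfinite(vals) & (vals > 0)))
            r, c = bad[0]
            raise FormatError(
                f"intensity at probe {self.data.index[r]!r}, sample "
                f"{self.data.columns[c]!r} is not a positive finite number"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ExpressionMatrix:
    """Summarized log2 expression at probe-set or transcript-cluster level."""

    data: pd.DataFrame  # index: feature_id, columns: sample_id
    level: Level
    algorithm: Algorithm

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise FormatError("expression matrix contains non-finite values")
        if self.data.index.has_duplicates:
            raise ConsistencyError("duplicate feature id in expression matrix")


@dataclass
class GeneResult:
    """Per-transcript-cluster differential-expression call."""

    tc_id: str
    log2fc_rma: float
    p_rma: float
    q_rma: float
    log2fc_iterplier: float
    p_iterplier: float
    q_iterplier: float
    consensus: bool
    direction: str  # "up" | "down" | ""


@dataclass
class SpliceResult:
    """Per-probe-set splice-index call with filter provenance.

    ``f1``..``f5`` record removal by the five false-positive filters (a flag
    is true when either algorithm's run removed the probe set, so
    ``passed == not any(f1..f5)`` is the dual-run pass).  ``category`` is the
    event-group classification, filled for consensus probe sets.
    """

    probeset_id: str
    tc_id: str
    si_rma: float
    p_rma: float
    q_rma: float
    si_iterplier: float
    p_iterplier: float
    q_iterplier: float
    f1: bool
    f2: bool
    f3: bool
    f4: bool
    f5: bool
    passed: bool
    consensus: bool
    category: str = ""
    event_type: str = ""


# ---------------------------------------------------------------------------
# annotation index
# ---------------------------------------------------------------------------


@dataclass
class AnnotationIndex:
    """Validated annotation with the lookup maps downstream stages need."""

    probes: list[ProbeAnnotation]
    probesets: list[ProbeSetAnnotation]
    probeset_by_id: dict[str, ProbeSetAnnotation] = field(init=False)
    probes_of_probeset: dict[str, list[str]] = field(init=False)
    probesets_of_tc: dict[str, list[str]] = field(init=False)
    gc_of_probe: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.probes:
            if p.probe_id in seen:
                raise ConsistencyError(f"duplicate probe_id {p.probe_id!r}")
            seen.add(p.probe_id)
        self.probeset_by_id = {}
        for ps in self.probesets:
            if ps.probeset_id in self.probeset_by_id:
                raise ConsistencyError(
                    f"duplicate probeset_id {ps.probeset_id!r}"
                )
            self.probeset_by_id[ps.probeset_id] = ps
        self.probes_of_probeset = {ps.probeset_id: [] for ps in self.probesets}
        self.gc_of_probe = {}
        for p in self.probes:
            self.gc_of_probe[p.probe_id] = p.gc_count
            if p.probeset_id is not None:
                if p.probeset_id not in self.probes_of_probeset:
                    raise ConsistencyError(
                        f"probe {p.probe_id!r} references unknown probe set "
                        f"{p.probeset_id!r}"
                    )
                self.probes_of_probeset[p.probeset_id].append(p.probe_id)
        self.probesets_of_tc = {}
        for ps in self.probesets:
            self.probesets_of_tc.setdefault(ps.tc_id, []).append(
                ps.probeset_id
            )

    @property
    def pm_probes(self) -> list[ProbeAnnotation]:
        return [p for p in self.probes if not p.is_background]

    @property
    def background_probes(self) -> list[ProbeAnnotation]:
        return [p for p in self.probes if p.is_background]

    def tc_of_probeset(self, probeset_id: str) -> str:
        try:
            return self.probeset_by_id[probeset_id].tc_id
        except KeyError:
            raise ConsistencyError(
                f"unknown probeset_id {probeset_id!r}"
            ) from None


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_PROBE_COLS = ["probe_id", "probeset_id", "gc_count", "is_background"]
_PROBESET_COLS = [
    "probeset_id",
    "tc_id",
    "exon_index",
    "n_exons",
    "rank_in_exon",
    "n_probesets_in_exon",
    "is_constitutive",
    "known_event",
    "crosshyb",
]
_DESIGN_COLS = ["sample_id", "group", "replicate"]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_bool(value: str, where: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise FormatError(f"{where}: cannot parse boolean from {value!r}")


def _parse_int(value: str, where: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"{where}: cannot parse integer from {value!r}") from None


def read_annotation(
    probes_path: str | Path, probesets_path: str | Path
) -> tuple[list[ProbeAnnotation], list[ProbeSetAnnotation]]:
    """Read and cross-validate the probe and probe-set annotation tables.

    Raises :class:`FormatError` for malformed cells and
    :class:`ConsistencyError` for dangling references or duplicate ids; the
    message names the offending row and field.
    """
    pdf = _read_tsv(probes_path, _PROBE_COLS)
    sdf = _read_tsv(probesets_path, _PROBESET_COLS)

    probesets = []
    for i, row in enumerate(sdf.itertuples(index=False), start=2):
        where = f"{probesets_path} line {i}"
        try:
            ev = EventType(row.known_event) if row.known_event else EventType.NONE
        except ValueError:
            raise FormatError(
                f"{where}: unknown event type {row.known_event!r}"
            ) from None
        probesets.append(
            ProbeSetAnnotation(
                probeset_id=row.probeset_id,
                tc_id=row.tc_id,
                exon_index=_parse_int(row.exon_index, where),
                n_exons=_parse_int(row.n_exons, where),
                rank_in_exon=_parse_int(row.rank_in_exon, where),
                n_probesets_in_exon=_parse_int(row.n_probesets_in_exon, where),
                is_constitutive=_parse_bool(row.is_constitutive, where),
                known_event=ev,
                crosshyb=_parse_bool(row.crosshyb, where),
            )
        )

    probes = []
    for i, row in enumerate(pdf.itertuples(index=False), start=2):
        where = f"{probes_path} line {i}"
        probes.append(
            ProbeAnnotation(
                probe_id=row.probe_id,
                probeset_id=row.probeset_id or None,
                gc_count=_parse_int(row.gc_count, where),
                is_background=_parse_bool(row.is_background, where),
            )
        )

    AnnotationIndex(probes, probesets)  # cross-validation side effect
    return probes, probesets


def write_annotation(
    probes: Iterable[ProbeAnnotation],
    probesets: Iterable[ProbeSetAnnotation],
    probes_path: str | Path,
    probesets_path: str | Path,
) -> None:
    pdf = pd.DataFrame(
        [
            {
                "probe_id": p.probe_id,
                "probeset_id": p.probeset_id or "",
                "gc_count": p.gc_count,
                "is_background": str(p.is_background).lower(),
            }
            for p in probes
        ],
        columns=_PROBE_COLS,
    )
    sdf = pd.DataFrame(
        [
            {
                "probeset_id": s.probeset_id,
                "tc_id": s.tc_id,
                "exon_index": s.exon_index,
                "n_exons": s.n_exons,
                "rank_in_exon": s.rank_in_exon,
                "n_probesets_in_exon": s.n_probesets_in_exon,
                "is_constitutive": str(s.is_constitutive).lower(),
                "known_event": s.known_event.value,
                "crosshyb": str(s.crosshyb).lower(),
            }
            for s in probesets
        ],
        columns=_PROBESET_COLS,
    )
    pdf.to_csv(probes_path, sep="\t", index=False)
    sdf.to_csv(probesets_path, sep="\t", index=False)


def read_design(path: str | Path) -> list[SampleDesign]:
    df = _read_tsv(path, _DESIGN_COLS)
    design = [
        SampleDesign(
            sample_id=row.sample_id,
            group=row.group,
            replicate=_parse_int(row.replicate, f"{path} line {i}"),
        )
        for i, row in enumerate(df.itertuples(index=False), start=2)
    ]
    validate_design(design)
    return design


def write_design(design: Iterable[SampleDesign], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample_id": d.sample_id, "group": d.group, "replicate": d.replicate}
            for d in design
        ],
        columns=_DESIGN_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_intensities(
    path: str | Path, design: Sequence[SampleDesign]
) -> IntensityMatrix:
    """Read a probe x sample intensity TSV, ordering columns as in the design."""
    df = _read_tsv(path, ["probe_id"])
    sample_ids = [d.sample_id for d in design]
    missing = [s for s in sample_ids if s not in df.columns]
    if missing:
        raise ConsistencyError(
            f"{path}: design sample(s) {missing} absent from intensity file"
        )
    out = df.set_index("probe_id")[sample_ids]
    try:
        out = out.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric intensity value ({exc})") from None
    return IntensityMatrix(out)


def write_intensities(mat: IntensityMatrix, path: str | Path) -> None:
    out = mat.data.copy()
    out.insert(0, "probe_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


_GENE_RESULT_COLS = [
    "tc_id",
    "log2fc_rma",
    "p_rma",
    "q_rma",
    "log2fc_iterplier",
    "p_iterplier",
    "q_iterplier",
    "consensus",
    "direction",
]
_SPLICE_RESULT_COLS = [
    "probeset_id",
    "tc_id",
    "si_rma",
    "p_rma",
    "q_rma",
    "si_iterplier",
    "p_iterplier",
    "q_iterplier",
    "f1",
    "f2",
    "f3",
    "f4",
    "f5",
    "passed",
    "consensus",
    "category",
    "event_type",
]


def write_results(
    gene_results: Sequence[GeneResult],
    splice_results: Sequence[SpliceResult],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Serialize results to ``gene_results.tsv`` / ``splice_results.tsv``.

    Rows are sorted by id and columns have a fixed order, so identical inputs
    always produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gdf = pd.DataFrame(
        [vars(g) for g in sorted(gene_results, key=lambda g: g.tc_id)],
        columns=_GENE_RESULT_COLS,
    )
    sdf = pd.DataFrame(
        [vars(s) for s in sorted(splice_results, key=lambda s: s.probeset_id)],
        columns=_SPLICE_RESULT_COLS,
    )
    for df in (gdf, sdf):
        for col in df.columns:
            if df[col].dtype == bool:
                df[col] = df[col].map(lambda b: str(b).lower())
    gpath = out_dir / "gene_results.tsv"
    spath = out_dir / "splice_results.tsv"
    gdf.to_csv(gpath, sep="\t", index=False, float_format="%.10g")
    sdf.to_csv(spath, sep="\t", index=False, float_format="%.10g")
    return gpath, spath


def read_results(
    out_dir: str | Path,
) -> tuple[list[GeneResult], list[SpliceResult]]:
    """Read back result TSVs written by :func:`write_results`."""
    out_dir = Path(out_dir)
    gdf = _read_tsv(out_dir / "gene_results.tsv", _GENE_RESULT_COLS)
    sdf = _read_tsv(out_dir / "splice_results.tsv", _SPLICE_RESULT_COLS)
    genes = []
    for i, row in enumerate(gdf.itertuples(index=False), start=2):
        d = row._asdict()
        for col in ("log2fc_rma", "p_rma", "q_rma", "log2fc_iterplier",
                    "p_iterplier", "q_iterplier"):
            d[col] = float(d[col])
        d["consensus"] = _parse_bool(d["consensus"], f"gene_results line {i}")
        genes.append(GeneResult(**d))
    splices = []
    for i, row in enumerate(sdf.itertuples(index=False), start=2):
        d = row._asdict()
        for col in ("si_rma", "p_rma", "q_rma", "si_iterplier",
                    "p_iterplier", "q_iterplier"):
            d[col] = float(d[col])
        for col in ("f1", "f2", "f3", "f4", "f5", "passed", "consensus"):
            d[col] = _parse_bool(d[col], f"splice_results line {i}")
        splices.append(SpliceResult(**d))
    return genes, splices
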