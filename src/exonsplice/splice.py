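"""Differential expression, the five-filter cascade, splice index, consensus.

Conventions, fixed package-wide:

* Contrasts are **group2 minus group1** on the log2 scale, where group1 is
  the first condition listed in the design (the reference, e.g. normoxia).
  A cassette exon skipped under the treatment therefore has negative SI.
* Significance is a two-sided Welch t-test on per-sample log2 values (genes)
  or per-sample log2 NI (probe sets), with an epsilon variance floor for
  degenerate data.  Raw p-values drive consensus; BH q-values are reported
  alongside but never used for calling.
* A consensus call requires the fold-change and p-value thresholds to be met
  under BOTH summarization algorithms with agreeing sign (and, at probe-set
  level, survival of all five filters under both runs).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .arraymodel import (
    AnnotationIndex,
    ConfigError,
    ConsistencyError,
    EventType,
    ExpressionMatrix,
    GeneResult,
    ProbeAnnotation,
    ProbeSetAnnotation,
    SampleDesign,
    SpliceResult,
    validate_design,
)

__all__ = [
    "Category",
    "Thresholds",
    "apply_filters",
    "assemble_results",
    "classify_events",
    "consensus",
    "differential_expression",
    "splice_index",
    "welch_test",
]

VAR_FLOOR = 1e-8


class Category(str, enum.Enum):
    TERMINAL_UTR_PROBESET = "terminal_utr_probeset"
    TERMINAL_EXON_PROBESET = "terminal_exon_probeset"
    CONSTITUTIVE_EXON = "constitutive_exon"
    KNOWN_AS_EVENT = "known_as_event"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Thresholds:
    fold_threshold: float = 2.0
    p_threshold: float = 0.01
    dabg_alpha: float = 0.05
    dabg_sample_fraction: float = 0.5
    tc_undetected_fraction: float = 0.5
    gene_fc_cap: float = 10.0
    ni_cap_log2: float = float(np.log2(5.0))

    def __post_init__(self) -> None:
        for name in (
            "fold_threshold",
            "p_threshold",
            "dabg_alpha",
            "gene_fc_cap",
            "ni_cap_log2",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("dabg_sample_fraction", "tc_undetected_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0,1)")

    @property
    def log2_fold(self) -> float:
        return float(np.log2(self.fold_threshold))


# ---------------------------------------------------------------------------
# Welch t machinery
# ---------------------------------------------------------------------------


def welch_test(
    group1: np.ndarray, group2: np.ndarray, var_floor: float = VAR_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided Welch t-test; returns (group2 - group1 mean, p).

    Degenerate rows (zero variance in both groups) get p = 1 when the means
    agree; otherwise the variance floor yields a p-value near zero.
    """
    x = np.atleast_2d(np.asarray(group1, dtype=float))
    y = np.atleast_2d(np.asarray(group2, dtype=float))
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    diff = m2 - m1
    se2 = v1 / n1 + v2 / n2
    se2_floored = np.maximum(se2, var_floor)
    t = diff / np.sqrt(se2_floored)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2**2 / (
            v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1))
        )
    df = np.where(np.isfinite(df) & (df > 0), df, n1 + n2 - 2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = (se2 <= 0) & (diff == 0)
    p = np.where(degenerate, 1.0, np.minimum(p, 1.0))
    return diff, p


def _group_columns(
    expr_cols: Sequence[str], design: Sequence[SampleDesign]
) -> tuple[list[str], list[str]]:
    group1, group2 = validate_design(design)
    cols = set(expr_cols)
    missing = [d.sample_id for d in design if d.sample_id not in cols]
    if missing:
        raise ConsistencyError(f"design sample(s) {missing} absent from matrix")
    g1 = [d.sample_id for d in design if d.group == group1]
    g2 = [d.sample_id for d in design if d.group == group2]
    return g1, g2


def _bh(p: np.ndarray) -> np.ndarray:
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    expr: ExpressionMatrix, design: Sequence[SampleDesign]
) -> pd.DataFrame:
    """Per-feature log2 fold change (group2 - group1) and Welch p/q values."""
    g1, g2 = _group_columns(expr.data.columns, design)
    diff, p = welch_test(
        expr.data[g1].to_numpy(dtype=float), expr.data[g2].to_numpy(dtype=float)
    )
    return pd.DataFrame(
        {"log2fc": diff, "p": p, "q": _bh(p)}, index=expr.data.index
    )


def splice_index(
    ps_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    annotation: tuple[list[ProbeAnnotation], list[ProbeSetAnnotation]],
    design: Sequence[SampleDesign],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Splice index per probe set, plus the per-sample log2 NI matrix.

    ``log2 NI = log2(probe-set expression) - log2(transcript-cluster
    expression)`` per sample; ``SI`` is the group2-minus-group1 difference of
    mean log2 NI, tested with the same Welch construction as genes.
    """
    index = AnnotationIndex(*annotation)
    tc_of = {}
    for ps_id in ps_expr.data.index:
        tc = index.tc_of_probeset(ps_id)
        if tc not in gene_expr.data.index:
            raise ConsistencyError(
                f"transcript cluster {tc!r} (of probe set {ps_id!r}) missing "
                f"from gene-level expression"
            )
        tc_of[ps_id] = tc
    tc_rows = gene_expr.data.loc[[tc_of[ps] for ps in ps_expr.data.index]]
    ni_log2 = pd.DataFrame(
        ps_expr.data.to_numpy(dtype=float) - tc_rows.to_numpy(dtype=float),
        index=ps_expr.data.index,
        columns=ps_expr.data.columns,
    )
    g1, g2 = _group_columns(ni_log2.columns, design)
    si, p = welch_test(
        ni_log2[g1].to_numpy(dtype=float), ni_log2[g2].to_numpy(dtype=float)
    )
    result = pd.DataFrame(
        {"si": si, "p": p, "q": _bh(p)}, index=ni_log2.index
    )
    return result, ni_log2


# ---------------------------------------------------------------------------
# the five-filter false-positive cascade
# ---------------------------------------------------------------------------


def apply_filters(
    gene_expr: ExpressionMatrix,
    ps_expr: ExpressionMatrix,
    dabg_table: pd.DataFrame,
    annotation: tuple[list[ProbeAnnotation], list[ProbeSetAnnotation]],
    design: Sequence[SampleDesign],
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Compute removal flags f1..f5 for every probe set of one algorithm run.

    f1  probe set undetected (DABG p > alpha in > half the samples) in
        either treatment group;
    f2  its transcript cluster undetected: more than half of the TC's probe
        sets are undetected in some group (propagated to all probe sets);
    f3  annotated cross-hybridization risk;
    f4  gene-level |fold change| above the cap (propagated);
    f5  extreme gene-level normalized intensity (|log2 NI| above the cap)
        in any sample.

    All five flags are always computed (no short-circuiting) so reports show
    every reason for removal; ``passed`` is true iff all flags are false.
    """
    th = thresholds or Thresholds()
    probes, probesets = annotation
    index = AnnotationIndex(probes, probesets)
    ps_ids = list(ps_expr.data.index)
    missing = [ps for ps in ps_ids if ps not in dabg_table.index]
    if missing:
        raise ConsistencyError(
            f"probe set(s) missing from DABG table (first: {missing[0]!r})"
        )
    g1, g2 = _group_columns(dabg_table.columns, design)

    dab = dabg_table.loc[ps_ids]
    undet = {}
    for cols in (g1, g2):
        frac = (dab[cols].to_numpy(dtype=float) > th.dabg_alpha).sum(axis=1)
        undet[tuple(cols)] = frac > th.dabg_sample_fraction * len(cols)
    undetected_any_group = undet[tuple(g1)] | undet[tuple(g2)]
    undet_df = pd.DataFrame(
        {"g1": undet[tuple(g1)], "g2": undet[tuple(g2)]}, index=ps_ids
    )
    f1 = pd.Series(undetected_any_group, index=ps_ids)

    # f2: fraction of the TC's probe sets undetected, per group
    tc_of = {ps: index.tc_of_probeset(ps) for ps in ps_ids}
    tc_ser = pd.Series(tc_of)
    tc_flag = {}
    grouped = undet_df.groupby(tc_ser)
    for tc, sub in grouped:
        n = len(sub)
        tc_flag[tc] = bool(
            (sub["g1"].sum() > th.tc_undetected_fraction * n)
            or (sub["g2"].sum() > th.tc_undetected_fraction * n)
        )
    f2 = pd.Series([tc_flag[tc_of[ps]] for ps in ps_ids], index=ps_ids)

    f3 = pd.Series(
        [index.probeset_by_id[ps].crosshyb for ps in ps_ids], index=ps_ids
    )

    gene_fc = differential_expression(gene_expr, design)["log2fc"]
    cap = np.log2(th.gene_fc_cap)
    tc_extreme = {tc: bool(abs(fc) > cap) for tc, fc in gene_fc.items()}
    f4 = pd.Series(
        [tc_extreme.get(tc_of[ps], False) for ps in ps_ids], index=ps_ids
    )

    _, ni_log2 = splice_index(ps_expr, gene_expr, annotation, design)
    f5 = pd.Series(
        (np.abs(ni_log2.to_numpy(dtype=float)) > th.ni_cap_log2).any(axis=1),
        index=ps_ids,
    )

    out = pd.DataFrame({"f1": f1, "f2": f2, "f3": f3, "f4": f4, "f5": f5})
    out["passed"] = ~out[["f1", "f2", "f3", "f4", "f5"]].any(axis=1)
    return out


# ---------------------------------------------------------------------------
# consensus and classification
# ---------------------------------------------------------------------------


def _hits(
    results: pd.DataFrame,
    thresholds: Thresholds,
    effect_col: str,
    filters: pd.DataFrame | None,
) -> pd.Series:
    ok = (np.abs(results[effect_col]) > thresholds.log2_fold) & (
        results["p"] < thresholds.p_threshold
    )
    if filters is not None:
        ok &= filters["passed"].reindex(results.index).fillna(False)
    return ok


def consensus(
    results_rma: pd.DataFrame,
    results_iterplier: pd.DataFrame,
    thresholds: Thresholds | None = None,
    effect_col: str = "log2fc",
    filters_rma: pd.DataFrame | None = None,
    filters_iterplier: pd.DataFrame | None = None,
) -> list[str]:
    """Ids passing fold + p thresholds under both algorithms, sign agreeing.

    Pass filter tables for probe-set level calls (both runs must survive the
    cascade); omit them at gene level.
    """
    th = thresholds or Thresholds()
    shared = results_rma.index.intersection(results_iterplier.index)
    a = results_rma.loc[shared]
    b = results_iterplier.loc[shared]
    hit = _hits(a, th, effect_col, filters_rma) & _hits(
        b, th, effect_col, filters_iterplier
    )
    agree = np.sign(a[effect_col]) == np.sign(b[effect_col])
    return sorted(shared[hit & agree])


def classify_events(
    probeset_ids: Sequence[str],
    annotation: tuple[list[ProbeAnnotation], list[ProbeSetAnnotation]],
) -> dict[str, tuple[Category, EventType]]:
    """Assign each probe set to one of the four event groups.

    Precedence: curated event annotation beats positional evidence; a sole
    probe set in a terminal exon marks a UTR-length change; one of several
    probe sets in a terminal exon marks a terminal-exon change; constitutive
    annotation comes last.  Anything else is reported as unclassified.
    """
    index = AnnotationIndex(*annotation)
    out: dict[str, tuple[Category, EventType]] = {}
    for ps_id in probeset_ids:
        if ps_id not in index.probeset_by_id:
            raise ConsistencyError(f"unknown probeset_id {ps_id!r}")
        ps = index.probeset_by_id[ps_id]
        if ps.known_event is not EventType.NONE:
            out[ps_id] = (Category.KNOWN_AS_EVENT, ps.known_event)
        elif ps.is_terminal_exon and ps.n_probesets_in_exon == 1:
            out[ps_id] = (Category.TERMINAL_UTR_PROBESET, EventType.NONE)
        elif ps.is_terminal_exon:
            out[ps_id] = (Category.TERMINAL_EXON_PROBESET, EventType.NONE)
        elif ps.is_constitutive:
            out[ps_id] = (Category.CONSTITUTIVE_EXON, EventType.NONE)
        else:
            out[ps_id] = (Category.UNCLASSIFIED, EventType.NONE)
    return out


# ---------------------------------------------------------------------------
# result assembly
# ---------------------------------------------------------------------------


def assemble_results(
    gene_de: Mapping[str, pd.DataFrame],
    splice_si: Mapping[str, pd.DataFrame],
    filters: Mapping[str, pd.DataFrame],
    annotation: tuple[list[ProbeAnnotation], list[ProbeSetAnnotation]],
    thresholds: Thresholds | None = None,
) -> tuple[list[GeneResult], list[SpliceResult]]:
    """Merge the two algorithms' statistics into final result records.

    ``gene_de``, ``splice_si`` and ``filters`` are keyed ``"rma"`` /
    ``"iterplier"``.  Serialized filter flags are the OR of the two runs, so
    ``passed`` means survival under both.
    """
    th = thresholds or Thresholds()
    index = AnnotationIndex(*annotation)
    g_rma, g_ipl = gene_de["rma"], gene_de["iterplier"]
    s_rma, s_ipl = splice_si["rma"], splice_si["iterplier"]
    f_rma, f_ipl = filters["rma"], filters["iterplier"]

    gene_cons = set(consensus(g_rma, g_ipl, th, effect_col="log2fc"))
    gene_results = []
    for tc in g_rma.index.intersection(g_ipl.index):
        a, b = g_rma.loc[tc], g_ipl.loc[tc]
        cons = tc in gene_cons
        direction = ""
        if cons:
            direction = "up" if a["log2fc"] > 0 else "down"
        gene_results.append(
            GeneResult(
                tc_id=tc,
                log2fc_rma=float(a["log2fc"]),
                p_rma=float(a["p"]),
                q_rma=float(a["q"]),
                log2fc_iterplier=float(b["log2fc"]),
                p_iterplier=float(b["p"]),
                q_iterplier=float(b["q"]),
                consensus=cons,
                direction=direction,
            )
        )

    ps_cons = set(
        consensus(
            s_rma,
            s_ipl,
            th,
            effect_col="si",
            filters_rma=f_rma,
            filters_iterplier=f_ipl,
        )
    )
    categories = classify_events(sorted(ps_cons), annotation)
    splice_results = []
    for ps in s_rma.index.intersection(s_ipl.index):
        a, b = s_rma.loc[ps], s_ipl.loc[ps]
        fa = f_rma.loc[ps]
        fb = f_ipl.loc[ps]
        flags = {f: bool(fa[f] or fb[f]) for f in ("f1", "f2", "f3", "f4", "f5")}
        cons = ps in ps_cons
        cat, ev = categories.get(ps, (None, None))
        splice_results.append(
            SpliceResult(
                probeset_id=ps,
                tc_id=index.tc_of_probeset(ps),
                si_rma=float(a["si"]),
                p_rma=float(a["p"]),
                q_rma=float(a["q"]),
                si_iterplier=float(b["si"]),
                p_iterplier=float(b["p"]),
                q_iterplier=float(b["q"]),
                **flags,
                passed=not any(flags.values()),
                consensus=cons,
                category=cat.value if cons else "",
                event_type=ev.value if cons and ev is not EventType.NONE else "",
            )
        )
    return gene_results, splice_results
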