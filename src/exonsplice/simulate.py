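"""Probe-level intensity simulator with planted expression and splicing events.

The generative model mirrors what the downstream analysis assumes.  For PM
probe *i* of probe set *p* in transcript cluster *t*, sample *s* in group *g*:

    log2 signal  mu = beta_t + Delta_t * [g = group2] + a_i
                      + delta_p * [g = group2] + eps,   eps ~ N(0, noise_sd)
    observed     y  = 2**mu + B

with additive background ``B = 2**(bg_intercept + bg_gc_slope * gc + eps_b)``.
Background (antigenomic) probes receive ``B`` only.  ``delta_p`` is non-zero
only for event-carrying probe sets:

* cassette: one internal probe set shifts by ``-event_delta`` in group2
  (exon skipped under the treatment-like condition);
* intron retention: an extra intron probe set is appended to an internal
  exon and is expressed in group2 only;
* alternative polyadenylation (APA): the last probe set shifts by
  ``+event_delta``;
* alternative promoter (APS): the first probe set shifts by ``-event_delta``;
* terminal UTR: a terminal probe set shifts (random sign) but carries no
  curated event annotation - it is recognizable only by its position.

Event-carrying probe sets are never flagged as cross-hybridizing, so the
cross-hybridization filter exercises only unplanted probe sets.

A ground-truth ledger (:class:`SimTruth`) records every planted gene effect
and per-probe-set inclusion shift (group2 minus group1, log2 units) for
parameter-recovery testing.  All draws derive from ``SimConfig.seed``;
identical configs produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .arraymodel import (
    ConfigError,
    ConsistencyError,
    EventType,
    IntensityMatrix,
    ProbeAnnotation,
    ProbeSetAnnotation,
    SampleDesign,
    validate_design,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "balanced_noiseless_cassette",
    "huvec_like",
    "make_design",
    "read_truth",
    "simulate_annotation",
    "simulate_intensities",
    "write_truth",
]

#: truth-ledger label for positionally marked terminal-UTR events
TERMINAL_UTR = "terminal_utr"

_EVENT_KINDS = (
    EventType.CASSETTE.value,
    EventType.INTRON_RETENTION.value,
    EventType.APA.value,
    EventType.APS.value,
    TERMINAL_UTR,
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated array experiment (all log2-scale effects)."""

    n_tcs: int = 200
    exons_per_tc: tuple[int, int] = (4, 8)
    probesets_per_exon: tuple[int, int] = (1, 3)
    probes_per_probeset: tuple[int, int] = (2, 4)
    n_background_probes: int = 400
    de_fraction: float = 0.0
    de_log2fc: float = 1.5
    as_fraction: float = 0.0
    event_mix: dict[str, float] = field(
        default_factory=lambda: {
            EventType.CASSETTE.value: 0.4,
            EventType.INTRON_RETENTION.value: 0.1,
            EventType.APA.value: 0.2,
            EventType.APS.value: 0.2,
            TERMINAL_UTR: 0.1,
        }
    )
    event_delta: float = 1.0
    affinity_sd: float = 0.5
    noise_sd: float = 0.25
    base_log2_range: tuple[float, float] = (7.0, 12.0)
    bg_intercept: float | None = 3.5
    bg_gc_slope: float = 0.05
    crosshyb_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fraction", "as_fraction", "crosshyb_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        for name in ("affinity_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_tcs < 1:
            raise ConfigError("n_tcs must be >= 1")
        lo, hi = self.exons_per_tc
        if lo < 1 or hi < lo:
            raise ConfigError(f"degenerate exons_per_tc range {self.exons_per_tc}")
        lo, hi = self.probes_per_probeset
        if lo < 1 or hi > 4 or hi < lo:
            raise ConfigError(
                "probes_per_probeset must lie within [1,4] "
                f"(probe sets hold up to four probes), got {self.probes_per_probeset}"
            )
        lo, hi = self.probesets_per_exon
        if lo < 1 or hi < lo:
            raise ConfigError(
                f"degenerate probesets_per_exon range {self.probesets_per_exon}"
            )
        if self.as_fraction > 0:
            bad = set(self.event_mix) - set(_EVENT_KINDS)
            if bad:
                raise ConfigError(f"unknown event kinds in event_mix: {sorted(bad)}")
            if sum(self.event_mix.values()) <= 0:
                raise ConfigError("event_mix weights must sum to > 0")


def huvec_like(seed: int = 0, **overrides) -> SimConfig:
    """The desk-scale default fixture: 2000 TCs, 3 vs 3, moderate noise."""
    cfg = SimConfig(
        n_tcs=2000,
        de_fraction=0.05,
        de_log2fc=1.5,
        as_fraction=0.02,
        event_delta=1.0,
        noise_sd=0.25,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def make_design(
    groups: tuple[str, str] = ("normoxia", "hypoxia"), n_per_group: int = 3
) -> list[SampleDesign]:
    design = [
        SampleDesign(sample_id=f"{g}_{r}", group=g, replicate=r)
        for g in groups
        for r in range(1, n_per_group + 1)
    ]
    validate_design(design)
    return design


# ---------------------------------------------------------------------------
# structural plan (shared by annotation and intensity generation)
# ---------------------------------------------------------------------------


@dataclass
class _PsPlan:
    probeset_id: str
    tc_id: str
    exon_index: int
    n_exons: int
    rank_in_exon: int
    n_probesets_in_exon: int
    n_probes: int
    is_constitutive: bool
    known_event: EventType
    crosshyb: bool
    delta: float  # group2 inclusion shift, log2
    truth_kind: str  # "" or one of _EVENT_KINDS
    intron_like: bool  # expressed in group2 only


@dataclass
class _Plan:
    probesets: list[_PsPlan]
    tc_ids: list[str]
    gene_log2fc: dict[str, float]
    bg_gc: np.ndarray  # gc counts of background probes


def _plan(config: SimConfig) -> _Plan:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    tc_ids = [f"tc{t:06d}" for t in range(config.n_tcs)]

    n_de = int(round(config.de_fraction * config.n_tcs))
    n_as = int(round(config.as_fraction * config.n_tcs))
    de_tcs = set(rng.choice(config.n_tcs, size=n_de, replace=False).tolist())
    as_tcs = rng.choice(config.n_tcs, size=n_as, replace=False).tolist()
    de_sign = {t: (1.0 if rng.random() < 0.5 else -1.0) for t in sorted(de_tcs)}

    kinds = sorted(config.event_mix)
    weights = np.array([config.event_mix[k] for k in kinds], dtype=float)
    weights = weights / weights.sum() if weights.sum() > 0 else weights
    event_of_tc: dict[int, str] = {
        int(t): str(rng.choice(kinds, p=weights)) for t in as_tcs
    }

    probesets: list[_PsPlan] = []
    gene_log2fc = {}
    for t in range(config.n_tcs):
        tc = tc_ids[t]
        gene_log2fc[tc] = de_sign.get(t, 0.0) * config.de_log2fc if t in de_tcs else 0.0
        lo, hi = config.exons_per_tc
        n_exons = int(rng.integers(max(lo, 3), hi + 1))  # >=3 keeps an internal exon
        ps_per_exon = []
        for _ in range(n_exons):
            if config.probesets_per_exon[1] == 1 or rng.random() < 0.85:
                k = config.probesets_per_exon[0]
            else:
                k = int(
                    rng.integers(
                        max(2, config.probesets_per_exon[0]),
                        config.probesets_per_exon[1] + 1,
                    )
                )
            ps_per_exon.append(k)

        event = event_of_tc.get(t)
        tc_ps: list[_PsPlan] = []
        counter = 0
        for e in range(1, n_exons + 1):
            for r in range(1, ps_per_exon[e - 1] + 1):
                counter += 1
                internal = 1 < e < n_exons
                tc_ps.append(
                    _PsPlan(
                        probeset_id=f"{tc}_ps{counter:03d}",
                        tc_id=tc,
                        exon_index=e,
                        n_exons=n_exons,
                        rank_in_exon=r,
                        n_probesets_in_exon=ps_per_exon[e - 1],
                        n_probes=int(
                            rng.integers(
                                config.probes_per_probeset[0],
                                config.probes_per_probeset[1] + 1,
                            )
                        ),
                        is_constitutive=bool(internal and rng.random() < 0.7),
                        known_event=EventType.NONE,
                        crosshyb=False,
                        delta=0.0,
                        truth_kind="",
                        intron_like=False,
                    )
                )

        if event is not None:
            _plant_event(tc_ps, event, config, rng)

        for ps in tc_ps:
            if ps.truth_kind == "" and rng.random() < config.crosshyb_fraction:
                ps.crosshyb = True
        probesets.extend(tc_ps)

    bg_gc = rng.integers(6, 21, size=config.n_background_probes)
    return _Plan(probesets, tc_ids, gene_log2fc, np.asarray(bg_gc))


def _plant_event(
    tc_ps: list[_PsPlan], event: str, config: SimConfig, rng: np.random.Generator
) -> None:
    n_exons = tc_ps[0].n_exons
    delta = config.event_delta
    if event == EventType.CASSETTE.value:
        internal = [p for p in tc_ps if 1 < p.exon_index < n_exons]
        ps = internal[int(rng.integers(len(internal)))]
        ps.known_event = EventType.CASSETTE
        ps.is_constitutive = False
        ps.delta = -delta
        ps.truth_kind = event
    elif event == EventType.INTRON_RETENTION.value:
        host_exon = int(rng.integers(2, n_exons))  # internal exon hosts the intron
        siblings = [p for p in tc_ps if p.exon_index == host_exon]
        new_rank = len(siblings) + 1
        for p in siblings:
            p.n_probesets_in_exon = new_rank
        intron = _PsPlan(
            probeset_id=f"{tc_ps[0].tc_id}_ps{len(tc_ps) + 1:03d}i",
            tc_id=tc_ps[0].tc_id,
            exon_index=host_exon,
            n_exons=n_exons,
            rank_in_exon=new_rank,
            n_probesets_in_exon=new_rank,
            n_probes=int(
                rng.integers(
                    config.probes_per_probeset[0], config.probes_per_probeset[1] + 1
                )
            ),
            is_constitutive=False,
            known_event=EventType.INTRON_RETENTION,
            crosshyb=False,
            delta=delta,
            truth_kind=event,
            intron_like=True,
        )
        tc_ps.insert(tc_ps.index(siblings[-1]) + 1, intron)
    elif event == EventType.APA.value:
        ps = tc_ps[-1]
        ps.known_event = EventType.APA
        ps.is_constitutive = False
        ps.delta = delta
        ps.truth_kind = event
    elif event == EventType.APS.value:
        ps = tc_ps[0]
        ps.known_event = EventType.APS
        ps.is_constitutive = False
        ps.delta = -delta
        ps.truth_kind = event
    elif event == TERMINAL_UTR:
        ps = tc_ps[0] if rng.random() < 0.5 else tc_ps[-1]
        ps.is_constitutive = False
        ps.delta = delta if rng.random() < 0.5 else -delta
        ps.truth_kind = event  # position-only marking: known_event stays NONE
    else:  # pragma: no cover - guarded by SimConfig validation
        raise ConfigError(f"unknown event kind {event!r}")


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def simulate_annotation(
    config: SimConfig,
) -> tuple[list[ProbeAnnotation], list[ProbeSetAnnotation]]:
    """Generate the probe / probe-set / transcript-cluster hierarchy."""
    plan = _plan(config)
    probesets = [
        ProbeSetAnnotation(
            probeset_id=p.probeset_id,
            tc_id=p.tc_id,
            exon_index=p.exon_index,
            n_exons=p.n_exons,
            rank_in_exon=p.rank_in_exon,
            n_probesets_in_exon=p.n_probesets_in_exon,
            is_constitutive=p.is_constitutive,
            known_event=p.known_event,
            crosshyb=p.crosshyb,
        )
        for p in plan.probesets
    ]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    probes: list[ProbeAnnotation] = []
    for p in plan.probesets:
        for j in range(1, p.n_probes + 1):
            probes.append(
                ProbeAnnotation(
                    probe_id=f"{p.probeset_id}_p{j}",
                    probeset_id=p.probeset_id,
                    gc_count=int(rng.integers(6, 21)),
                    is_background=False,
                )
            )
    for b, gc in enumerate(plan.bg_gc):
        probes.append(
            ProbeAnnotation(
                probe_id=f"bg{b:05d}",
                probeset_id=None,
                gc_count=int(gc),
                is_background=True,
            )
        )
    return probes, probesets


@dataclass
class SimTruth:
    """Ledger of planted effects, keyed the same way as analysis results."""

    gene: pd.DataFrame  # tc_id, true_log2fc
    probeset: pd.DataFrame  # probeset_id, tc_id, event_kind, true_si
    seed: int


def simulate_intensities(
    annotation: tuple[list[ProbeAnnotation], list[ProbeSetAnnotation]],
    design: Sequence[SampleDesign],
    config: SimConfig,
) -> tuple[IntensityMatrix, SimTruth]:
    """Draw linear-scale intensities for the given annotation and design.

    The annotation must come from :func:`simulate_annotation` with the same
    config (the structural plan, including event placement, is re-derived
    from ``config.seed``).
    """
    probes, probesets = annotation
    plan = _plan(config)
    if [p.probeset_id for p in probesets] != [p.probeset_id for p in plan.probesets]:
        raise ConsistencyError(
            "annotation does not match this config's structural plan; "
            "pass the annotation produced by simulate_annotation(config)"
        )
    group1, group2 = validate_design(design)
    sample_ids = [d.sample_id for d in design]
    is_g2 = np.array([d.group == group2 for d in design])
    n_samples = len(design)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo, hi = config.base_log2_range
    beta = {tc: lo + (hi - lo) * rng.random() for tc in plan.tc_ids}

    ps_plan = {p.probeset_id: p for p in plan.probesets}
    pm = [p for p in probes if not p.is_background]
    bg = [p for p in probes if p.is_background]

    n_pm = len(pm)
    base = np.empty(n_pm)
    delta = np.empty(n_pm)
    gene_fc = np.empty(n_pm)
    intron = np.zeros(n_pm, dtype=bool)
    for i, p in enumerate(pm):
        plan_ps = ps_plan[p.probeset_id]
        base[i] = beta[plan_ps.tc_id]
        delta[i] = plan_ps.delta
        gene_fc[i] = plan.gene_log2fc[plan_ps.tc_id]
        intron[i] = plan_ps.intron_like

    affinity = rng.normal(0.0, config.affinity_sd, size=n_pm)
    eps = rng.normal(0.0, config.noise_sd, size=(n_pm, n_samples))
    mu = (
        base[:, None]
        + affinity[:, None]
        + (gene_fc[:, None] + delta[:, None]) * is_g2[None, :]
        + eps
    )
    signal = np.exp2(mu)
    signal[np.ix_(intron, ~is_g2)] = 0.0  # intron probe sets silent in group1

    gc_all = np.array([p.gc_count for p in pm + bg], dtype=float)
    if config.bg_intercept is not None:
        eps_b = rng.normal(0.0, config.noise_sd, size=(len(gc_all), n_samples))
        background = np.exp2(
            config.bg_intercept + config.bg_gc_slope * gc_all[:, None] + eps_b
        )
    else:
        background = np.zeros((len(gc_all), n_samples))

    values = np.vstack([signal, np.zeros((len(bg), n_samples))]) + background
    if config.bg_intercept is None:
        # keep the matrix strictly positive for background probes
        values[n_pm:, :] = 1.0
    mat = IntensityMatrix(
        pd.DataFrame(
            values,
            index=[p.probe_id for p in pm + bg],
            columns=sample_ids,
        )
    )

    gene_truth = pd.DataFrame(
        {
            "tc_id": plan.tc_ids,
            "true_log2fc": [plan.gene_log2fc[tc] for tc in plan.tc_ids],
        }
    )
    ps_truth = pd.DataFrame(
        {
            "probeset_id": [p.probeset_id for p in plan.probesets],
            "tc_id": [p.tc_id for p in plan.probesets],
            "event_kind": [p.truth_kind for p in plan.probesets],
            "true_si": [p.delta for p in plan.probesets],
        }
    )
    return mat, SimTruth(gene=gene_truth, probeset=ps_truth, seed=config.seed)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    gene = truth.gene.assign(
        feature_kind="tc",
        feature_id=truth.gene["tc_id"],
        event_kind="",
        true_si=np.nan,
    )
    ps = truth.probeset.assign(
        feature_kind="probeset",
        feature_id=truth.probeset["probeset_id"],
        true_log2fc=np.nan,
    )
    cols = ["feature_kind", "feature_id", "tc_id", "event_kind", "true_log2fc", "true_si"]
    pd.concat([gene[cols], ps[cols]]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_truth(path: str | Path, seed: int = -1) -> SimTruth:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    gene = df[df["feature_kind"] == "tc"]
    ps = df[df["feature_kind"] == "probeset"]
    return SimTruth(
        gene=pd.DataFrame(
            {"tc_id": gene["feature_id"], "true_log2fc": gene["true_log2fc"].astype(float)}
        ).reset_index(drop=True),
        probeset=pd.DataFrame(
            {
                "probeset_id": ps["feature_id"],
                "tc_id": ps["tc_id"],
                "event_kind": ps["event_kind"],
                "true_si": ps["true_si"].astype(float),
            }
        ).reset_index(drop=True),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# hand-constructed exact fixture
# ---------------------------------------------------------------------------


def balanced_noiseless_cassette(
    n_pairs: int = 2,
    n_null_tcs: int = 8,
    event_delta: float = 1.0,
    n_de_pairs: int = 0,
    gene_delta: float = 1.0,
    n_exons: int = 5,
    probes_per_probeset: int = 3,
    n_background_probes: int = 120,
    seed: int = 7,
    groups: tuple[str, str] = ("normoxia", "hypoxia"),
) -> tuple[
    list[ProbeAnnotation],
    list[ProbeSetAnnotation],
    list[SampleDesign],
    IntensityMatrix,
    SimTruth,
]:
    """A noiseless cassette-exon fixture on which the full pipeline is exact.

    Quantile normalization equalizes column distributions, so a one-sided
    planted shift would leak into its own estimate.  Here every planted
    cassette (shift ``-event_delta`` in group2) is paired with a mirror
    transcript cluster whose cassette probes carry affinities lowered by
    ``event_delta`` and shift ``+event_delta``, making all columns share one
    value multiset.  Quantile normalization is then the identity and the
    splice index of planted probe sets equals ``-/+event_delta`` exactly.
    ``n_de_pairs`` adds whole-transcript pairs shifted by ``+/-gene_delta``
    under the same mirroring, for exact gene-level fold-change recovery.

    PM probes carry no additive background (summarize with background
    correction disabled); background probes are constant across arrays.
    """
    rng = np.random.default_rng(seed)
    design = make_design(groups=groups, n_per_group=3)
    is_g2 = np.array([d.group == groups[1] for d in design])

    probes: list[ProbeAnnotation] = []
    probesets: list[ProbeSetAnnotation] = []
    rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    truth_rows: list[dict] = []
    cassette_exon = (n_exons + 1) // 2

    gene_fc: dict[str, float] = {}

    def add_tc(
        tc_id: str,
        beta: float,
        affinities: np.ndarray,
        delta_ps: dict[int, float],
        gene_shift: float = 0.0,
    ):
        gene_fc[tc_id] = gene_shift
        k = 0
        for e in range(1, n_exons + 1):
            ps_id = f"{tc_id}_ps{e:03d}"
            ev = EventType.CASSETTE if delta_ps.get(e) else EventType.NONE
            probesets.append(
                ProbeSetAnnotation(
                    probeset_id=ps_id,
                    tc_id=tc_id,
                    exon_index=e,
                    n_exons=n_exons,
                    rank_in_exon=1,
                    n_probesets_in_exon=1,
                    is_constitutive=(1 < e < n_exons and ev is EventType.NONE),
                    known_event=ev,
                )
            )
            d = delta_ps.get(e, 0.0)
            truth_rows.append(
                {
                    "probeset_id": ps_id,
                    "tc_id": tc_id,
                    "event_kind": EventType.CASSETTE.value if d else "",
                    "true_si": d,
                }
            )
            for j in range(probes_per_probeset):
                pid = f"{ps_id}_p{j + 1}"
                probes.append(
                    ProbeAnnotation(pid, ps_id, int(rng.integers(6, 21)), False)
                )
                probe_ids.append(pid)
                log2_val = beta + affinities[k] + (d + gene_shift) * is_g2
                rows.append(np.exp2(log2_val))
                k += 1

    tc_ids = []
    for pair in range(n_pairs):
        beta = 8.0 + 0.5 * pair
        aff = rng.normal(0.0, 0.4, size=n_exons * probes_per_probeset)
        tc_a, tc_b = f"tcA{pair:03d}", f"tcB{pair:03d}"
        add_tc(tc_a, beta, aff, {cassette_exon: -event_delta})
        # mirror: cassette probes sit one event_delta lower and shift upward
        aff_b = aff.copy()
        lo = (cassette_exon - 1) * probes_per_probeset
        aff_b[lo : lo + probes_per_probeset] -= event_delta
        add_tc(tc_b, beta, aff_b, {cassette_exon: +event_delta})
        tc_ids += [tc_a, tc_b]
    for pair in range(n_de_pairs):
        beta = 9.0 + 0.4 * pair
        aff = rng.normal(0.0, 0.4, size=n_exons * probes_per_probeset)
        tc_c, tc_d = f"tcC{pair:03d}", f"tcD{pair:03d}"
        add_tc(tc_c, beta, aff, {}, gene_shift=+gene_delta)
        add_tc(tc_d, beta, aff + gene_delta, {}, gene_shift=-gene_delta)
        tc_ids += [tc_c, tc_d]
    for t in range(n_null_tcs):
        tc = f"tcN{t:03d}"
        add_tc(
            tc,
            7.0 + 0.3 * t,
            rng.normal(0.0, 0.4, size=n_exons * probes_per_probeset),
            {},
        )
        tc_ids.append(tc)

    bg_vals = []
    for b in range(n_background_probes):
        gc = int(rng.integers(6, 21))
        probes.append(ProbeAnnotation(f"bg{b:05d}", None, gc, True))
        probe_ids.append(f"bg{b:05d}")
        bg_vals.append(np.full(len(design), np.exp2(3.5 + 0.05 * gc)))
    rows.extend(bg_vals)

    mat = IntensityMatrix(
        pd.DataFrame(rows, index=probe_ids, columns=[d.sample_id for d in design])
    )
    truth = SimTruth(
        gene=pd.DataFrame(
            {"tc_id": tc_ids, "true_log2fc": [gene_fc[tc] for tc in tc_ids]}
        ),
        probeset=pd.DataFrame(truth_rows),
        seed=seed,
    )
    return probes, probesets, design, mat, truth
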