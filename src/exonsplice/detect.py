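"""Detection-above-background (DABG) p-values from GC-matched background probes.

Each array carries a pool of antigenomic background probes.  A PM probe's
detection p-value is its rank against the background probes of matching GC
content: ``p = (count of background intensities >= intensity, + 1) / (n + 1)``,
which is super-uniform under exchangeability with the pool (ties count
against the probe).  Probe p-values are combined per probe set with Fisher's
method.  GC bins holding fewer than ``min_bin_size`` background probes are
merged with neighboring bins before lookup.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .arraymodel import (
    AnnotationIndex,
    ConfigError,
    IntensityMatrix,
    ProbeAnnotation,
    ProbeSetAnnotation,
    SampleDesign,
)

__all__ = ["BackgroundPool", "dabg", "dabg_probe_p", "dabg_probeset_p"]

DEFAULT_MIN_BIN_SIZE = 25


@dataclass
class BackgroundPool:
    """GC-binned, sorted background intensities for one array."""

    bin_of_gc: dict[int, int]
    sorted_pools: list[np.ndarray]

    @classmethod
    def build(
        cls,
        intensities: np.ndarray,
        gc_counts: np.ndarray,
        min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
    ) -> "BackgroundPool":
        intensities = np.asarray(intensities, dtype=float)
        gc_counts = np.asarray(gc_counts, dtype=int)
        if intensities.size == 0:
            raise ConfigError("no background probes available for DABG")
        # greedy left-to-right merge of per-GC bins until each holds enough
        gcs = np.sort(np.unique(gc_counts))
        counts = {g: int((gc_counts == g).sum()) for g in gcs}
        groups: list[list[int]] = []
        current: list[int] = []
        total = 0
        for g in gcs:
            current.append(int(g))
            total += counts[g]
            if total >= min_bin_size:
                groups.append(current)
                current, total = [], 0
        if current:
            if groups:
                groups[-1].extend(current)  # short tail joins its neighbor
            else:
                groups.append(current)
        bin_of_gc: dict[int, int] = {}
        pools: list[np.ndarray] = []
        for b, grp in enumerate(groups):
            mask = np.isin(gc_counts, grp)
            pools.append(np.sort(intensities[mask]))
            for g in grp:
                bin_of_gc[g] = b
        # out-of-range GC values map to the nearest bin
        lo, hi = int(gcs[0]), int(gcs[-1])
        for g in range(0, 26):
            if g not in bin_of_gc:
                bin_of_gc[g] = bin_of_gc[lo] if g < lo else bin_of_gc[hi]
        return cls(bin_of_gc=bin_of_gc, sorted_pools=pools)

    def probe_p(self, intensity: float, gc: int) -> float:
        pool = self.sorted_pools[self.bin_of_gc[int(gc)]]
        n_ge = pool.size - np.searchsorted(pool, intensity, side="left")
        return float((n_ge + 1) / (pool.size + 1))

    def probe_p_vector(self, intensities: np.ndarray, gcs: np.ndarray) -> np.ndarray:
        intensities = np.asarray(intensities, dtype=float)
        bins = np.array([self.bin_of_gc[int(g)] for g in gcs])
        out = np.empty(intensities.shape, dtype=float)
        for b, pool in enumerate(self.sorted_pools):
            mask = bins == b
            if mask.any():
                n_ge = pool.size - np.searchsorted(
                    pool, intensities[mask], side="left"
                )
                out[mask] = (n_ge + 1) / (pool.size + 1)
        return out


def dabg_probe_p(intensity: float, gc: int, bg_pool: BackgroundPool) -> float:
    """Rank-based detection p-value for a single probe on one array."""
    return bg_pool.probe_p(intensity, gc)


def dabg_probeset_p(probe_ps: Sequence[float]) -> float:
    """Fisher's combination of per-probe detection p-values."""
    p = np.asarray(probe_ps, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one probe p-value")
    if p.size == 1:
        return float(p[0])
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def dabg(
    raw: IntensityMatrix,
    annotation: tuple[list[ProbeAnnotation], list[ProbeSetAnnotation]],
    design: Sequence[SampleDesign],
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
) -> pd.DataFrame:
    """Per-probe-set, per-array DABG p-values (computed on raw intensities).

    Returns a probe-set x sample DataFrame of p-values in (0, 1].
    """
    probes, probesets = annotation
    index = AnnotationIndex(probes, probesets)
    bg = index.background_probes
    if not bg:
        raise ConfigError("annotation contains no background probes")
    sample_ids = [d.sample_id for d in design]
    pos = {pid: i for i, pid in enumerate(raw.data.index)}
    bg_rows = np.array([pos[p.probe_id] for p in bg if p.probe_id in pos])
    if bg_rows.size == 0:
        raise ConfigError("background probes absent from intensity matrix")
    bg_gc = np.array([p.gc_count for p in bg if p.probe_id in pos])

    pm = [p for p in index.pm_probes if p.probe_id in pos]
    pm_rows = np.array([pos[p.probe_id] for p in pm])
    pm_gc = np.array([p.gc_count for p in pm])
    vals = raw.data[sample_ids].to_numpy(dtype=float)

    # map PM probes into their probe set, batching Fisher by probe count
    ps_ids = sorted(
        ps for ps, members in index.probes_of_probeset.items() if members
    )
    ps_pos = {ps: i for i, ps in enumerate(ps_ids)}
    probe_of_ps: dict[str, list[int]] = {ps: [] for ps in ps_ids}
    for i, p in enumerate(pm):
        probe_of_ps[p.probeset_id].append(i)

    out = np.ones((len(ps_ids), len(sample_ids)))
    probe_p = np.empty((len(pm), len(sample_ids)))
    for j in range(len(sample_ids)):
        pool = BackgroundPool.build(vals[bg_rows, j], bg_gc, min_bin_size)
        probe_p[:, j] = pool.probe_p_vector(vals[pm_rows, j], pm_gc)

    by_size: dict[int, list[str]] = {}
    for ps, members in probe_of_ps.items():
        by_size.setdefault(len(members), []).append(ps)
    for size, ps_list in by_size.items():
        rows = np.array([probe_of_ps[ps] for ps in ps_list])  # (F, size)
        block = probe_p[rows]  # (F, size, S)
        if size == 1:
            combined = block[:, 0, :]
        else:
            x = -2.0 * np.log(block).sum(axis=1)
            combined = stats.chi2.sf(x, df=2 * size)
        for i, ps in enumerate(ps_list):
            out[ps_pos[ps]] = combined[i]
    return pd.DataFrame(out, index=ps_ids, columns=sample_ids)
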