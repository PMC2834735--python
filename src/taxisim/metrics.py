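"""Chemotactic-effect statistic, box-plot summaries and parameter scans.

The chemotactic effect of a run is the population mean of each agent's
local ligand concentration averaged over the final window (50 s by
default) of the simulation — a single number integrating both how fast
the population climbs the gradient and how well it holds the crest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .swarm import PopulationRecord, SimulationConfig, simulate, with_controller

__all__ = ["BoxplotSummary", "ScanResult", "chemotactic_effect",
           "boxplot_summary", "boxplot_series", "scan_parameters"]


def chemotactic_effect(record: PopulationRecord, window: float = 50.0) -> float:
    """Mean local [L] (µM) over all agents in the final ``window`` seconds."""
    t_end = record.times[-1]
    if window > t_end - record.times[0]:
        raise ValueError(
            f"window {window} s exceeds record span {t_end - record.times[0]} s")
    mask = record.times >= t_end - window
    return float(record.local_L[mask].mean())


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number summary with 1.5·IQR whiskers.

    Whiskers extend to the most extreme datum within 1.5 box heights of
    the box; values beyond are listed as outliers.
    """

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    mean: float
    n: int


def boxplot_summary(values) -> BoxplotSummary:
    """Summarize a sample with linearly interpolated quartiles."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return BoxplotSummary(
        q1=float(q1), median=float(med), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=np.sort(x[(x < lo_fence) | (x > hi_fence)]),
        mean=float(x.mean()), n=int(x.size),
    )


def boxplot_series(record: PopulationRecord):
    """Per-time box-plot table of the local-[L] distribution.

    Returns a DataFrame (t_s, q1, median, q3, lo, hi, n_outliers, mean).
    """
    import pandas as pd

    rows = []
    for t, vals in zip(record.times, record.local_L):
        s = boxplot_summary(vals)
        rows.append((t, s.q1, s.median, s.q3, s.whisker_low, s.whisker_high,
                     len(s.outliers), s.mean))
    return pd.DataFrame(rows, columns=["t_s", "q1", "median", "q3", "lo",
                                       "hi", "n_outliers", "mean"])


@dataclass(frozen=True)
class ScanResult:
    """Chemotactic effect tabulated over a controller-parameter grid."""

    param_names: tuple
    grids: tuple                 # one array per scanned parameter
    effects: np.ndarray          # mean over seed replicates, grid-shaped
    per_seed: np.ndarray         # (*grid shape, n_seeds)
    seeds: tuple

    def to_frame(self):
        import pandas as pd

        combos = list(itertools.product(*[range(len(g)) for g in self.grids]))
        rows = []
        for idx in combos:
            row = {name: self.grids[d][i]
                   for d, (name, i) in enumerate(zip(self.param_names, idx))}
            row["effect_uM"] = self.effects[idx]
            row["sem_uM"] = (self.per_seed[idx].std(ddof=1)
                             / np.sqrt(len(self.seeds))
                             if len(self.seeds) > 1 else 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


def scan_parameters(base: SimulationConfig, grids: dict,
                    n_seeds: int = 3, window: float = 50.0) -> ScanResult:
    """Grid-scan controller parameters, averaging the effect over seeds.

    ``grids`` maps controller attribute names (e.g. ``omega1``, ``A``) to
    value sequences.  Common random numbers are used: the same seed set
    (derived from ``base.seed``) is applied at every grid point, so that
    comparisons across the grid are not dominated by seed noise.
    """
    names = tuple(grids)
    axes = tuple(np.asarray(grids[k], dtype=float) for k in names)
    shape = tuple(len(a) for a in axes)
    seeds = tuple(int(base.seed) + 1000 * i for i in range(n_seeds))
    per_seed = np.empty(shape + (n_seeds,))
    for idx in itertools.product(*[range(s) for s in shape]):
        params = {name: float(axes[d][i])
                  for d, (name, i) in enumerate(zip(names, idx))}
        cfg = with_controller(base, **params)
        for j, seed in enumerate(seeds):
            rec = simulate(replace(cfg, seed=seed))
            per_seed[idx + (j,)] = chemotactic_effect(rec, window)
    return ScanResult(param_names=names, grids=axes,
                      effects=per_seed.mean(axis=-1), per_seed=per_seed,
                      seeds=seeds)
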