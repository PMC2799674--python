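"""Array preprocessing: quantile normalization, probe-set summarization, replicate QC.

Probe intensities are quantile-normalized across arrays, collapsed into
per-array probe-set signals with a symmetric trimmed mean of log2
intensities, linearly scaled so each array's trimmed-mean signal hits a
target constant (TGT, 500 by default), and checked for within-condition
replicate agreement via Pearson correlation of log2 signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExperimentDesign, FormatError, IntensityMatrix, ProbeMap

__all__ = [
    "SignalMatrix",
    "quantile_normalize",
    "summarize_probesets",
    "replicate_correlation",
    "SET_TRIM",
    "ARRAY_TRIM",
]

# symmetric trim fractions: within-set summarization and per-array scaling
SET_TRIM = 0.20
ARRAY_TRIM = 0.02


@dataclass
class SignalMatrix:
    """Probe-set level signals: probe sets (rows) x arrays (columns), scaled units."""

    probeset_ids: list[str]
    array_ids: list[str]
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape != (len(self.probeset_ids), len(self.array_ids)):
            raise FormatError("signal shape does not match labels")
        if not np.all(np.isfinite(self.signals)) or np.any(self.signals <= 0):
            raise FormatError("signals must be positive and finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.signals, index=self.probeset_ids, columns=self.array_ids)

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "probeset_id"
        df.to_csv(path, sep="\t", float_format="%.12g")

    def row(self, probeset_id: str) -> np.ndarray:
        return self.signals[self.probeset_ids.index(probeset_id)]


def quantile_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Force identical value distributions across arrays.

    Each column's sorted values are replaced by the across-array mean of
    the corresponding rank, restored to the column's original order.
    Tied values within a column receive the mean of the reference values
    of the ranks they jointly occupy.
    """
    v = m.values
    n, k = v.shape
    order = np.argsort(v, axis=0, kind="stable")
    sorted_v = np.take_along_axis(v, order, axis=0)
    reference = sorted_v.mean(axis=1)
    out = np.empty_like(v)
    for j in range(k):
        col_sorted = sorted_v[:, j]
        # group consecutive equal values; each group shares the mean reference
        group = np.concatenate(([0], np.cumsum(col_sorted[1:] != col_sorted[:-1])))
        sums = np.bincount(group, weights=reference)
        counts = np.bincount(group)
        out[order[:, j], j] = (sums / counts)[group]
    return IntensityMatrix(list(m.probe_ids), list(m.array_ids), out)


def _trimmed_mean(a: np.ndarray, proportion: float, axis: int = 0) -> np.ndarray:
    return stats.trim_mean(a, proportiontocut=proportion, axis=axis)


def summarize_probesets(
    m: IntensityMatrix,
    probe_map: ProbeMap,
    tgt: float = 500.0,
    set_trim: float = SET_TRIM,
    array_trim: float = ARRAY_TRIM,
) -> SignalMatrix:
    """Collapse probes to probe-set signals and scale each array to the target mean.

    Per probe set and array: signal = 2**(set_trim-trimmed mean of the log2
    probe intensities).  Each array's signals are then multiplied by one
    scalar so that the array_trim-trimmed mean of its signals equals ``tgt``.
    Probe sets with no probes present in the matrix are dropped with a warning.
    """
    if tgt <= 0:
        raise ValueError("tgt must be positive")
    row_of = {p: i for i, p in enumerate(m.probe_ids)}
    missing = [p for p in m.probe_ids if p not in probe_map]
    if missing:
        raise FormatError(f"probe {missing[0]!r} in matrix is absent from probe map")
    log_v = np.log2(m.values)
    probeset_ids: list[str] = []
    rows: list[np.ndarray] = []
    for ps in probe_map.probeset_ids:
        idx = [row_of[p] for p in probe_map.probes_of(ps) if p in row_of]
        if not idx:
            warnings.warn(f"probe set {ps!r} has no probes in the matrix; omitted")
            continue
        probeset_ids.append(ps)
        rows.append(_trimmed_mean(log_v[idx, :], set_trim, axis=0))
    signals = np.power(2.0, np.vstack(rows))
    scale = tgt / _trimmed_mean(signals, array_trim, axis=0)
    return SignalMatrix(probeset_ids, list(m.array_ids), signals * scale)


def replicate_correlation(
    s: SignalMatrix, design: ExperimentDesign, threshold: float = 0.98
) -> pd.DataFrame:
    """Pearson r of log2 signals for every within-cell array pair.

    Returns one row per replicate pair with columns array_1, array_2,
    genotype, treatment, r, flagged.  A zero-variance array yields r = NaN
    and is flagged as degenerate rather than raising.
    """
    col = {a: i for i, a in enumerate(s.array_ids)}
    log_s = np.log2(s.signals)
    records = []
    for (genotype, treatment), arrays in design.cells().items():
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                a, b = arrays[i], arrays[j]
                x, y = log_s[:, col[a]], log_s[:, col[b]]
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    r, flagged = float("nan"), True
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                    flagged = r < threshold
                records.append(
                    {
                        "array_1": a,
                        "array_2": b,
                        "genotype": genotype,
                        "treatment": treatment,
                        "r": r,
                        "flagged": flagged,
                    }
                )
    if not records:
        raise FormatError("design has no within-cell replicate pairs")
    return pd.DataFrame(records)
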