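"""Per-probe balanced two-way fixed-effects ANOVA with BH false-discovery control.

Each probe's log2 intensities are decomposed into genotype (cultivar),
treatment and interaction effects over a balanced 2x2xr design.  With a
balanced design the Type I/II/III sums of squares coincide, so the
closed-form decomposition is used:

    SS_A  = 2r * sum_a (ybar_a  - ybar)^2
    SS_B  = 2r * sum_b (ybar_b  - ybar)^2
    SS_AB =  r * sum_ab (ybar_ab - ybar_a - ybar_b + ybar)^2
    SSE   = within-cell squared deviations

    F_effect = (SS_effect / 1) / (SSE / (4(r-1)))

p-values come from F(1, 4(r-1)); per-effect q-values across probes are
Benjamini-Hochberg step-up adjusted p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExperimentDesign, FormatError, IntensityMatrix, TREATMENT_LEVELS

__all__ = ["fit_two_way_anova", "anova_all_probes", "bh_fdr"]

EFFECTS = ("cultivar", "treatment", "interaction")


def _anova_from_cells(cells: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized closed-form ANOVA.

    cells: array (..., 2, 2, r) of log2 responses, axis -3 = genotype,
    axis -2 = treatment.  Returns (F, p, degenerate) where F and p have
    shape (..., 3) ordered (cultivar, treatment, interaction).
    """
    r = cells.shape[-1]
    if cells.shape[-3:-1] != (2, 2):
        raise ValueError("expected a 2x2 factorial")
    if r < 2:
        raise ValueError("need r >= 2 replicates per cell")
    cell_means = cells.mean(axis=-1)                        # (..., 2, 2)
    a_means = cell_means.mean(axis=-1)                      # (..., 2) genotype
    b_means = cell_means.mean(axis=-2)                      # (..., 2) treatment
    grand = cell_means.mean(axis=(-1, -2))                  # (...)
    ss_a = 2 * r * ((a_means - grand[..., None]) ** 2).sum(axis=-1)
    ss_b = 2 * r * ((b_means - grand[..., None]) ** 2).sum(axis=-1)
    inter = (
        cell_means
        - a_means[..., :, None]
        - b_means[..., None, :]
        + grand[..., None, None]
    )
    ss_ab = r * (inter ** 2).sum(axis=(-1, -2))
    sse = ((cells - cell_means[..., None]) ** 2).sum(axis=(-1, -2, -3))
    df_err = 4 * (r - 1)
    ss = np.stack([ss_a, ss_b, ss_ab], axis=-1)             # (..., 3)
    degenerate = sse == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ss / (sse[..., None] / df_err)
    p = stats.f.sf(F, 1, df_err)
    # SSE = 0: no residual variance -> p is 1 where the effect SS is also 0,
    # 0 where the effect SS is positive; F left infinite/NaN but flagged.
    if np.any(degenerate):
        deg = np.broadcast_to(degenerate[..., None], ss.shape)
        p = np.where(deg & (ss == 0), 1.0, p)
        p = np.where(deg & (ss > 0), 0.0, p)
    return F, p, degenerate


def fit_two_way_anova(cell_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ANOVA for one probe: a (2, 2, r) array of log2 intensities.

    Axis 0 is genotype (A, B), axis 1 treatment (control, treated), axis 2
    replicates.  Returns (F, p), each length 3 in the order cultivar,
    treatment, interaction.
    """
    cells = np.asarray(cell_values, dtype=float)
    if cells.ndim != 3 or cells.shape[:2] != (2, 2):
        raise ValueError(f"expected shape (2, 2, r), got {cells.shape}")
    if cells.shape[2] < 2:
        raise ValueError("need r >= 2 replicates per cell")
    F, p, _ = _anova_from_cells(cells)
    return F, p


def anova_all_probes(m: IntensityMatrix, design: ExperimentDesign) -> pd.DataFrame:
    """Two-way ANOVA for every probe of a quantile-normalized matrix.

    Intensities are log2-transformed internally.  Returns a DataFrame with
    probe_id, F/p/q per effect and a degenerate flag; q columns are BH
    adjusted within each effect across all probes.
    """
    r = design.require_balanced()
    cells = design.cells()
    col = {a: i for i, a in enumerate(m.array_ids)}
    for arrays in cells.values():
        for a in arrays:
            if a not in col:
                raise FormatError(f"design array {a!r} missing from intensity matrix")
    log_v = np.log2(m.values)
    n = len(m.probe_ids)
    stacked = np.empty((n, 2, 2, r))
    for gi, g in enumerate(design.genotypes):
        for ti, t in enumerate(TREATMENT_LEVELS):
            idx = [col[a] for a in cells[(g, t)]]
            stacked[:, gi, ti, :] = log_v[:, idx]
    F, p, degenerate = _anova_from_cells(stacked)
    out = pd.DataFrame({"probe_id": m.probe_ids})
    for k, eff in enumerate(EFFECTS):
        out[f"F_{eff}"] = F[:, k]
        out[f"p_{eff}"] = p[:, k]
    for eff in EFFECTS:
        out[f"q_{eff}"] = bh_fdr(out[f"p_{eff}"].to_numpy())
    out["degenerate"] = degenerate
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i}(p_(j) * m / j), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
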