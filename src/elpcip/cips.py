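"""Core Intersectional Probeset (CIP) calling and quadrant classification.

A probe is a "core" probe when it is significant (raw p <= alpha) for the
genotype effect, the treatment effect and their interaction simultaneously.
A probe set is called a CIP when it contains at least ``min_core_probes``
core probes.  Each CIP is then placed in one of four expression quadrants
by the signs of its genotype-preference and treatment-response deltas on
probe-set level log2 signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import EFFECTS
from .io import ExperimentDesign, FormatError, ProbeMap, TREATMENT_LEVELS
from .preprocess import SignalMatrix

__all__ = [
    "VENN_REGIONS",
    "QUADRANTS",
    "venn_regions",
    "call_cips",
    "classify_quadrant",
    "quadrant_summary",
]

# the 7 non-empty regions of the 3-set Venn diagram, plus "none"
VENN_REGIONS = (
    "cultivar",
    "treatment",
    "interaction",
    "cultivar+treatment",
    "cultivar+interaction",
    "treatment+interaction",
    "cultivar+treatment+interaction",
    "none",
)

QUADRANTS = ("prefA_up", "prefA_down", "prefB_up", "prefB_down", "unclassified")


def venn_regions(records: pd.DataFrame, alpha: float = 0.01) -> dict[str, int]:
    """Count probes in each exclusive significance region of the three effects."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    sig = {eff: (records[f"p_{eff}"] <= alpha).to_numpy() for eff in EFFECTS}
    counts = dict.fromkeys(VENN_REGIONS, 0)
    keys = np.array(
        [
            "+".join([e for e, flag in zip(EFFECTS, flags) if flag]) or "none"
            for flags in zip(sig["cultivar"], sig["treatment"], sig["interaction"])
        ]
    )
    uniq, n = np.unique(keys, return_counts=True)
    counts.update(dict(zip(uniq.tolist(), n.tolist())))
    return counts


def core_probe_mask(records: pd.DataFrame, alpha: float) -> np.ndarray:
    """Boolean mask of triple-significant (core) probes."""
    mask = np.ones(len(records), dtype=bool)
    for eff in EFFECTS:
        mask &= (records[f"p_{eff}"] <= alpha).to_numpy()
    return mask


def call_cips(
    records: pd.DataFrame,
    probe_map: ProbeMap,
    alpha: float = 0.01,
    min_core_probes: int = 3,
    signals: SignalMatrix | None = None,
    design: ExperimentDesign | None = None,
) -> pd.DataFrame:
    """Call CIPs from per-probe ANOVA records.

    Returns one row per called probe set with columns probeset_id,
    n_probes_total, n_core_probes and, when ``signals`` and ``design`` are
    supplied, quadrant / cultivar_delta / treatment_delta.
    """
    missing = [p for p in records["probe_id"] if p not in probe_map]
    if missing:
        raise FormatError(f"probe {missing[0]!r} absent from probe map")
    core = set(records.loc[core_probe_mask(records, alpha), "probe_id"])
    present = set(records["probe_id"])
    rows = []
    for ps in probe_map.probeset_ids:
        probes = [p for p in probe_map.probes_of(ps) if p in present]
        n_core = sum(p in core for p in probes)
        if n_core >= min_core_probes:
            rows.append(
                {
                    "probeset_id": ps,
                    "n_probes_total": len(probes),
                    "n_core_probes": n_core,
                }
            )
    out = pd.DataFrame(rows, columns=["probeset_id", "n_probes_total", "n_core_probes"])
    if signals is not None:
        if design is None:
            raise ValueError("design is required when signals are given")
        quads, cds, tds = [], [], []
        for ps in out["probeset_id"]:
            quadrant, cd, td = classify_quadrant(signals.row(ps), signals.array_ids, design)
            quads.append(quadrant)
            cds.append(cd)
            tds.append(td)
        out["quadrant"] = quads
        out["cultivar_delta"] = cds
        out["treatment_delta"] = tds
    return out


def classify_quadrant(
    signal_row: np.ndarray, array_ids: list[str], design: ExperimentDesign
) -> tuple[str, float, float]:
    """Quadrant of one probe set from the signs of its main-effect deltas.

    cultivar_delta = mean log2 signal over genotype-A arrays minus over
    genotype-B arrays; treatment_delta = mean over treated minus control.
    A delta of exactly zero makes the set unclassified.
    """
    col = {a: i for i, a in enumerate(array_ids)}
    missing = [a for a in design.array_ids if a not in col]
    if missing:
        raise FormatError(f"array {missing[0]!r} missing from signals")
    log_s = np.log2(np.asarray(signal_row, dtype=float))
    d = design.frame
    g_a = [col[a] for a in d.loc[d["genotype"] == design.genotype_a, "array_id"]]
    g_b = [col[a] for a in d.loc[d["genotype"] != design.genotype_a, "array_id"]]
    tr = [col[a] for a in d.loc[d["treatment"] == TREATMENT_LEVELS[1], "array_id"]]
    ct = [col[a] for a in d.loc[d["treatment"] == TREATMENT_LEVELS[0], "array_id"]]
    cultivar_delta = float(log_s[g_a].mean() - log_s[g_b].mean())
    treatment_delta = float(log_s[tr].mean() - log_s[ct].mean())
    if cultivar_delta == 0.0 or treatment_delta == 0.0:
        quadrant = "unclassified"
    elif cultivar_delta > 0:
        quadrant = "prefA_up" if treatment_delta > 0 else "prefA_down"
    else:
        quadrant = "prefB_up" if treatment_delta > 0 else "prefB_down"
    return quadrant, cultivar_delta, treatment_delta


def quadrant_summary(cips: pd.DataFrame) -> dict[str, int]:
    """Count called CIPs per quadrant (all five labels always present)."""
    counts = dict.fromkeys(QUADRANTS, 0)
    if len(cips) and "quadrant" in cips.columns:
        vc = cips["quadrant"].value_counts()
        for q in QUADRANTS:
            counts[q] = int(vc.get(q, 0))
    return counts


@dataclass(frozen=True)
class CipRecord:
    """One called probe set (convenience record form of the CIP table)."""

    probeset_id: str
    n_probes_total: int
    n_core_probes: int
    quadrant: str = "unclassified"
    cultivar_delta: float = 0.0
    treatment_delta: float = 0.0
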