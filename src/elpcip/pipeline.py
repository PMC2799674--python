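"""End-to-end driver: intensities -> normalization -> ANOVA -> CIPs -> quadrants."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .anova import anova_all_probes
from .cips import call_cips, quadrant_summary, venn_regions
from .io import ExperimentDesign, IntensityMatrix, PipelineConfig, ProbeMap
from .preprocess import SignalMatrix, quantile_normalize, replicate_correlation, summarize_probesets


@dataclass
class PipelineResult:
    normalized: IntensityMatrix
    signals: SignalMatrix
    anova: pd.DataFrame
    venn: dict[str, int]
    cips: pd.DataFrame
    quadrant_counts: dict[str, int]
    qc: pd.DataFrame


def run_pipeline(
    intensities: IntensityMatrix,
    design: ExperimentDesign,
    probe_map: ProbeMap,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full expression stage of the pipeline on one dataset."""
    cfg = config or PipelineConfig()
    normalized = quantile_normalize(intensities)
    signals = summarize_probesets(normalized, probe_map, tgt=cfg.tgt)
    qc = replicate_correlation(signals, design)
    records = anova_all_probes(normalized, design)
    venn = venn_regions(records, alpha=cfg.alpha)
    cips = call_cips(
        records,
        probe_map,
        alpha=cfg.alpha,
        min_core_probes=cfg.min_core_probes,
        signals=signals,
        design=design,
    )
    return PipelineResult(
        normalized=normalized,
        signals=signals,
        anova=records,
        venn=venn,
        cips=cips,
        quadrant_counts=quadrant_summary(cips),
        qc=qc,
    )
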