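"""Seeded synthetic scenarios with the statistical structure the pipeline assumes.

A scenario emulates a balanced two-genotype x two-treatment x r-replicate
array experiment: a genome pair differing by SNPs and small InDels, probe
sets tiling gene regions of genome A, log2-scale probe intensities with
planted genotype/treatment/interaction effects on a subset of probe sets
(the true expression-level polymorphisms), polymorphism-attenuated probes,
an annotation category enriched among the planted sets, promoters carrying
a planted motif, and InDels placed around planted genes.  Everything is
reproducible from one integer seed; each sub-generator draws from its own
stream so adding one generator never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES
from .io import (
    ExperimentDesign,
    GeneModel,
    IndelInterval,
    IntensityMatrix,
    ProbeMap,
    ProbeMapEntry,
    write_fasta,
    write_gff3,
    write_indels,
)

__all__ = [
    "GenomePair",
    "SimScenario",
    "TruthTable",
    "SimulatedData",
    "generate_genome_pair",
    "generate_probes",
    "make_design",
    "generate_intensities",
    "generate_annotations",
    "generate_promoters",
    "generate_indels",
    "simulate_scenario",
    "write_scenario",
    "evaluate_recovery",
]

QUADRANT_LABELS = ("prefA_up", "prefA_down", "prefB_up", "prefB_down")
# quadrant mix modelled on a two-genotype oxidative-stress response where
# genotype-A-preferred transcripts are mostly stress-induced and
# genotype-B-preferred ones mostly stress-repressed
DEFAULT_QUADRANT_WEIGHTS = (645, 101, 223, 93)


@dataclass
class GenomePair:
    """Two genome sequences related by a recorded variant list.

    Variants are (position in seq_a coordinates, kind, length) with kind in
    {snp, ins, del}; applying them left-to-right to seq_a yields seq_b.
    Insertions add bases immediately before the stated position.
    """

    seq_a: str
    seq_b: str
    variants: list[tuple[int, str, int]]


@dataclass
class SimScenario:
    """All knobs of one synthetic study, reproducible from rng_seed."""

    rng_seed: int = 0
    n_probesets: int = 200
    probes_per_set: int = 11
    probe_length: int = 25
    r: int = 3                       # replicates per genotype x treatment cell
    baseline_mean: float = 8.0       # log2 probe-set baseline
    baseline_sd: float = 1.0
    affinity_sd: float = 0.5         # per-probe offset around the set baseline
    noise_sd: float = 0.3            # residual log2 noise
    delta_cultivar: float = 1.5      # planted |effect| sizes, log2 units
    delta_treatment: float = 1.5
    delta_interaction: float = 1.0
    cip_fraction: float = 0.1        # fraction of probe sets planted as true ELPs
    polymorphic_fraction: float = 0.05
    attenuation: float = 2.0         # log2 loss of polymorphic probes in genotype B
    quadrant_weights: tuple[int, int, int, int] = DEFAULT_QUADRANT_WEIGHTS
    n_categories: int = 20
    annotation_rate: float = 0.1
    enriched_odds: float = 10.0
    motif: str = "AGTCAAAC"          # W-box, planted in promoters of planted genes
    promoter_length: int = 200
    indel_fraction_cip: float = 0.5  # planted genes receiving an InDel
    indel_fraction_background: float = 0.1
    upstream_window: int = 1000
    gene_span: int = 400             # bp of each synthetic gene body
    intergenic: int = 1200           # bp flanking each gene on either side
    genotypes: tuple[str, str] = ("NIP", "9311")
    genome_indel_rate: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("baseline_sd", "affinity_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cip_fraction", "polymorphic_fraction", "annotation_rate",
                     "indel_fraction_cip", "indel_fraction_background"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def snp_rate(self) -> float:
        """Per-bp SNP rate giving ~polymorphic_fraction of probes a variant."""
        return self.polymorphic_fraction / self.probe_length

    @property
    def genome_length(self) -> int:
        return self.n_probesets * (self.gene_span + 2 * self.intergenic)


@dataclass
class TruthTable:
    """Ground truth of one scenario.

    probesets: probeset_id, gene_id, is_cip, quadrant
    probes:    probe_id, is_polymorphic
    genes:     gene_id, is_cip_gene, has_motif, has_indel
    """

    probesets: pd.DataFrame
    probes: pd.DataFrame
    genes: pd.DataFrame
    enriched_category: str = ""

    def cip_probesets(self) -> set[str]:
        return set(self.probesets.loc[self.probesets["is_cip"], "probeset_id"])

    def cip_genes(self) -> set[str]:
        return set(self.probesets.loc[self.probesets["is_cip"], "gene_id"])


@dataclass
class SimulatedData:
    """Everything one scenario produces, ready for the pipeline."""

    scenario: SimScenario
    genome_pair: GenomePair
    probes: dict[str, str]
    probe_map: ProbeMap
    design: ExperimentDesign
    intensities: IntensityMatrix
    gene_models: list[GeneModel]
    promoters: dict[str, str]
    annotations: pd.DataFrame
    indels: list[IndelInterval]
    truth: TruthTable


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def generate_genome_pair(
    length: int, snp_rate: float, indel_rate: float, seed: int | np.random.Generator
) -> GenomePair:
    """Random genome A plus a derived genome B with recorded SNP/InDel truth."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    for name, rate in (("snp_rate", snp_rate), ("indel_rate", indel_rate)):
        if not (0.0 <= rate <= 0.1):
            raise ValueError(f"{name} must lie in [0, 0.1]")
    rng = _rng(seed)
    seq_a = _random_dna(rng, length)
    draws = rng.random(length)
    snp_pos = np.flatnonzero(draws < snp_rate)
    indel_draws = rng.random(length)
    indel_pos = np.flatnonzero(indel_draws < indel_rate)
    events: dict[int, tuple[str, int]] = {int(p): ("snp", 1) for p in snp_pos}
    for p in indel_pos:
        p = int(p)
        if p in events:
            continue  # SNPs win collisions at the same base
        kind = "ins" if rng.random() < 0.5 else "del"
        events[p] = (kind, int(rng.integers(1, 6)))
    variants: list[tuple[int, str, int]] = []
    out: list[str] = []
    cursor = 0
    last_end = -1
    for pos in sorted(events):
        kind, vlen = events[pos]
        footprint = vlen if kind == "del" else 1
        if pos < last_end or pos + footprint > length:
            continue  # skip variants overlapping a previous one or the edge
        out.append(seq_a[cursor:pos])
        if kind == "snp":
            old = seq_a[pos]
            out.append(rng.choice([b for b in BASES if b != old]))
            cursor = pos + 1
        elif kind == "ins":
            out.append(_random_dna(rng, vlen) + seq_a[pos])
            cursor = pos + 1
        else:
            cursor = pos + vlen
        last_end = pos + footprint
        variants.append((pos, kind, vlen))
    out.append(seq_a[cursor:])
    return GenomePair(seq_a, "".join(out), variants)


@dataclass
class ProbeSim:
    """Probes placed on genome A plus their polymorphism ground truth."""

    probes: dict[str, str]
    probe_map: ProbeMap
    polymorphic: dict[str, bool]
    regions: list[tuple[int, int]]  # gene-body interval used for each probe set


def generate_probes(
    genome_pair: GenomePair,
    n_probesets: int,
    probes_per_set: int,
    probe_length: int,
    seed: int | np.random.Generator,
    gene_span: int = 400,
    intergenic: int = 1200,
) -> ProbeSim:
    """Tile each probe set across its own gene region of genome A.

    A probe is marked polymorphic iff its footprint overlaps >= 1 recorded
    variant of the genome pair.
    """
    rng = _rng(seed)
    block = gene_span + 2 * intergenic
    if len(genome_pair.seq_a) < n_probesets * block:
        raise ValueError(
            f"genome too short: need {n_probesets * block} bp, have {len(genome_pair.seq_a)}"
        )
    if gene_span < probe_length:
        raise ValueError("gene span shorter than a probe")
    starts = np.array([p for p, _k, _l in genome_pair.variants])
    ends = np.array(
        [p + (l if k == "del" else 1) for p, k, l in genome_pair.variants]
    )
    order = np.argsort(starts) if len(starts) else np.array([], dtype=int)
    starts, ends = starts[order], ends[order]

    def overlaps_variant(s: int, e: int) -> bool:
        if len(starts) == 0:
            return False
        i = np.searchsorted(starts, e)  # variants starting before probe end
        return bool(np.any(ends[:i] > s))

    probes: dict[str, str] = {}
    entries: list[ProbeMapEntry] = []
    polymorphic: dict[str, bool] = {}
    regions: list[tuple[int, int]] = []
    for si in range(n_probesets):
        ps_id = f"PS{si:04d}"
        region_start = si * block + intergenic
        region_end = region_start + gene_span
        regions.append((region_start, region_end))
        offsets = rng.integers(0, gene_span - probe_length + 1, size=probes_per_set)
        for pi, off in enumerate(sorted(int(o) for o in offsets)):
            probe_id = f"{ps_id}_P{pi:02d}"
            s = region_start + off
            probes[probe_id] = genome_pair.seq_a[s : s + probe_length]
            entries.append(ProbeMapEntry(probe_id, ps_id, pi))
            polymorphic[probe_id] = overlaps_variant(s, s + probe_length)
    return ProbeSim(probes, ProbeMap(entries), polymorphic, regions)


def make_design(
    r: int = 3, genotypes: Sequence[str] = ("NIP", "9311")
) -> ExperimentDesign:
    """Balanced 2 genotypes x {control, treated} x r design, one row per array."""
    rows = []
    for g in genotypes:
        for t in ("control", "treated"):
            for k in range(1, r + 1):
                rows.append(
                    {"array_id": f"{g}_{t}_{k}", "genotype": g, "treatment": t, "replicate": k}
                )
    return ExperimentDesign(pd.DataFrame(rows), genotype_a=genotypes[0])


_QUADRANT_SIGNS = {
    "prefA_up": (1.0, 1.0),
    "prefA_down": (1.0, -1.0),
    "prefB_up": (-1.0, 1.0),
    "prefB_down": (-1.0, -1.0),
}


def generate_intensities(
    scenario: SimScenario,
    probe_map: ProbeMap,
    truth: TruthTable,
    design: ExperimentDesign,
    seed: int | np.random.Generator,
) -> IntensityMatrix:
    """Linear-scale intensities from the planted log2 model.

    log2 x = baseline(set) + affinity(probe)
             + s_c*Dc*[genotype A] + s_t*Dt*[treated] + s_c*s_t*Di*[A & treated]
             - attenuation*[probe polymorphic & genotype B] + N(0, noise_sd)

    where the effect terms apply only to planted (CIP) sets and the signs
    (s_c, s_t) encode the planted quadrant.
    """
    rng = _rng(seed)
    r = design.require_balanced()
    del r
    quadrant_of = dict(zip(truth.probesets["probeset_id"], truth.probesets["quadrant"]))
    is_cip = dict(zip(truth.probesets["probeset_id"], truth.probesets["is_cip"]))
    poly = dict(zip(truth.probes["probe_id"], truth.probes["is_polymorphic"]))
    probe_ids = [e.probe_id for e in probe_map.entries]
    arrays = design.frame
    is_a = (arrays["genotype"] == design.genotype_a).to_numpy(dtype=float)
    treated = (arrays["treatment"] == "treated").to_numpy(dtype=float)
    n_arrays = len(arrays)
    baselines = {
        ps: rng.normal(scenario.baseline_mean, scenario.baseline_sd)
        for ps in probe_map.probeset_ids
    }
    log2x = np.empty((len(probe_ids), n_arrays))
    for i, e in enumerate(probe_map.entries):
        ps = e.probeset_id
        x = baselines[ps] + rng.normal(0.0, scenario.affinity_sd)
        row = np.full(n_arrays, x)
        if is_cip.get(ps, False):
            s_c, s_t = _QUADRANT_SIGNS[quadrant_of[ps]]
            row = (
                row
                + s_c * scenario.delta_cultivar * is_a
                + s_t * scenario.delta_treatment * treated
                + s_c * s_t * scenario.delta_interaction * is_a * treated
            )
        if poly.get(e.probe_id, False):
            row = row - scenario.attenuation * (1.0 - is_a)
        log2x[i] = row
    log2x += rng.normal(0.0, scenario.noise_sd, size=log2x.shape)
    return IntensityMatrix(probe_ids, list(arrays["array_id"]), np.power(2.0, log2x))


def generate_annotations(
    truth: TruthTable,
    n_categories: int,
    enriched_odds: float,
    seed: int | np.random.Generator,
    annotation_rate: float = 0.1,
    aspect: str = "BP",
) -> pd.DataFrame:
    """Bernoulli category memberships with one category enriched in planted sets.

    For the enriched category, planted (CIP) items are annotated at odds
    ``enriched_odds`` times the baseline annotation odds; every other
    category-item pair uses the baseline rate.
    """
    if enriched_odds <= 0:
        raise ValueError("enriched_odds must be positive")
    rng = _rng(seed)
    items = list(truth.probesets["probeset_id"])
    cip = truth.cip_probesets()
    p0 = annotation_rate
    odds0 = p0 / (1 - p0)
    p1 = (enriched_odds * odds0) / (1 + enriched_odds * odds0)
    categories = [f"CAT{j:03d}" for j in range(n_categories)]
    enriched = categories[0]
    rows = []
    for cat in categories:
        for item in items:
            p = p1 if (cat == enriched and item in cip) else p0
            if rng.random() < p:
                rows.append({"item_id": item, "category_id": cat, "aspect": aspect})
    truth.enriched_category = enriched
    return pd.DataFrame(rows, columns=["item_id", "category_id", "aspect"])


def generate_promoters(
    truth: TruthTable,
    motif: str,
    length: int,
    seed: int | np.random.Generator,
) -> dict[str, str]:
    """One random promoter per gene; planted genes carry the motif once.

    The motif overwrites the random background at a uniform random offset,
    so every planted-gene promoter contains >= 1 exact occurrence.
    """
    if len(motif) > length:
        raise ValueError("motif longer than the promoter")
    rng = _rng(seed)
    cip_genes = truth.cip_genes()
    out: dict[str, str] = {}
    for gene_id in truth.genes["gene_id"]:
        seq = _random_dna(rng, length)
        if gene_id in cip_genes:
            off = int(rng.integers(0, length - len(motif) + 1))
            seq = seq[:off] + motif + seq[off + len(motif):]
        out[gene_id] = seq
    truth.genes["has_motif"] = truth.genes["gene_id"].isin(cip_genes)
    return out


# upstream : genic : downstream placement mix for planted InDels
INDEL_REGION_WEIGHTS = (0.6429, 0.3214, 0.1071)


def generate_indels(
    truth: TruthTable,
    gene_models: Iterable[GeneModel],
    seed: int | np.random.Generator,
    fraction_cip: float = 0.5,
    fraction_background: float = 0.1,
    upstream_window: int = 1000,
    region_weights: Sequence[float] = INDEL_REGION_WEIGHTS,
) -> list[IndelInterval]:
    """Place one InDel near a random subset of genes, favouring planted genes.

    The region (upstream/genic/downstream of the gene, strand-aware) is
    drawn from ``region_weights``; upstream/downstream InDels land within
    ``upstream_window`` bp of the gene boundary.
    """
    rng = _rng(seed)
    weights = np.asarray(region_weights, dtype=float)
    weights = weights / weights.sum()
    cip_genes = truth.cip_genes()
    out: list[IndelInterval] = []
    carriers: set[str] = set()
    for g in gene_models:
        p = fraction_cip if g.gene_id in cip_genes else fraction_background
        if rng.random() >= p:
            continue
        region = ("upstream", "genic", "downstream")[
            int(rng.choice(3, p=weights))
        ]
        vlen = int(rng.integers(1, 11))
        if region == "genic":
            s = g.start + int(rng.integers(0, max(1, g.end - g.start - vlen)))
        else:
            gap = int(rng.integers(1, upstream_window - vlen + 1))
            five_prime_low = (g.strand == "+") == (region == "upstream")
            if five_prime_low:
                s = g.start - gap - vlen + 1
            else:
                s = g.end + gap - 1
        if s < 0:
            continue
        kind = "insertion" if rng.random() < 0.5 else "deletion"
        out.append(IndelInterval(g.chrom, s, s + vlen, kind))
        carriers.add(g.gene_id)
    truth.genes["has_indel"] = truth.genes["gene_id"].isin(carriers)
    return out


def simulate_scenario(scenario: SimScenario) -> SimulatedData:
    """Generate a complete scenario from one seed.

    Sub-generators draw from independent child streams of the scenario
    seed, in a fixed order, so each component is stable under changes to
    the others.
    """
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(scenario.rng_seed).spawn(7)
    ]
    (g_genome, g_probes, g_truth, g_intens, g_annot, g_prom, g_indel) = streams

    genome_pair = generate_genome_pair(
        scenario.genome_length, scenario.snp_rate, scenario.genome_indel_rate, g_genome
    )
    sim = generate_probes(
        genome_pair,
        scenario.n_probesets,
        scenario.probes_per_set,
        scenario.probe_length,
        g_probes,
        gene_span=scenario.gene_span,
        intergenic=scenario.intergenic,
    )
    probeset_ids = sim.probe_map.probeset_ids
    gene_ids = [f"GENE{i:04d}" for i in range(len(probeset_ids))]
    strands = ["+" if g_truth.random() < 0.5 else "-" for _ in probeset_ids]
    gene_models = [
        GeneModel(gid, "chr1", s, e, strand)
        for gid, (s, e), strand in zip(gene_ids, sim.regions, strands)
    ]
    n_cip = int(round(scenario.cip_fraction * len(probeset_ids)))
    cip_idx = set(
        g_truth.choice(len(probeset_ids), size=n_cip, replace=False).tolist()
    )
    qw = np.asarray(scenario.quadrant_weights, dtype=float)
    qw = qw / qw.sum()
    quadrants = []
    for i in range(len(probeset_ids)):
        if i in cip_idx:
            quadrants.append(QUADRANT_LABELS[int(g_truth.choice(4, p=qw))])
        else:
            quadrants.append("")
    truth = TruthTable(
        probesets=pd.DataFrame(
            {
                "probeset_id": probeset_ids,
                "gene_id": gene_ids,
                "is_cip": [i in cip_idx for i in range(len(probeset_ids))],
                "quadrant": quadrants,
            }
        ),
        probes=pd.DataFrame(
            {
                "probe_id": list(sim.polymorphic),
                "is_polymorphic": list(sim.polymorphic.values()),
            }
        ),
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "is_cip_gene": [i in cip_idx for i in range(len(probeset_ids))],
                "has_motif": False,
                "has_indel": False,
            }
        ),
    )
    design = make_design(scenario.r, scenario.genotypes)
    intensities = generate_intensities(scenario, sim.probe_map, truth, design, g_intens)
    annotations = generate_annotations(
        truth,
        scenario.n_categories,
        scenario.enriched_odds,
        g_annot,
        annotation_rate=scenario.annotation_rate,
    )
    promoters = generate_promoters(
        truth, scenario.motif, scenario.promoter_length, g_prom
    )
    indels = generate_indels(
        truth,
        gene_models,
        g_indel,
        fraction_cip=scenario.indel_fraction_cip,
        fraction_background=scenario.indel_fraction_background,
        upstream_window=scenario.upstream_window,
    )
    return SimulatedData(
        scenario=scenario,
        genome_pair=genome_pair,
        probes=sim.probes,
        probe_map=sim.probe_map,
        design=design,
        intensities=intensities,
        gene_models=gene_models,
        promoters=promoters,
        annotations=annotations,
        indels=indels,
        truth=truth,
    )


def write_scenario(data: SimulatedData, outdir: str | Path) -> None:
    """Write every scenario artifact as the pipeline's on-disk formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.intensities.write(outdir / "intensities.tsv")
    data.design.write(outdir / "design.tsv")
    data.probe_map.write(outdir / "probe_map.tsv")
    write_fasta({"chrA": data.genome_pair.seq_a}, outdir / "genome_a.fa")
    write_fasta({"chrB": data.genome_pair.seq_b}, outdir / "genome_b.fa")
    write_fasta(data.probes, outdir / "probes.fa")
    write_fasta(data.promoters, outdir / "promoters.fa")
    write_gff3(data.gene_models, outdir / "genes.gff3")
    write_indels(data.indels, outdir / "indels.tsv")
    data.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    truth = data.truth.probesets.merge(data.truth.genes, on="gene_id")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def evaluate_recovery(
    called_probesets: Iterable[str], truth: TruthTable
) -> tuple[float, float]:
    """(sensitivity, empirical FDR) of a CIP call set against the planted truth."""
    called = set(called_probesets)
    planted = truth.cip_probesets()
    true_calls = len(called & planted)
    sensitivity = true_calls / len(planted) if planted else 0.0
    fdr = (len(called) - true_calls) / max(1, len(called))
    return sensitivity, fdr
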