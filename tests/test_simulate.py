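"""Synthetic scenario generator: determinism, planted structure, recovery metrics."""

import numpy as np
import pandas as pd
import pytest

from elpcip import (
    SimScenario,
    evaluate_recovery,
    generate_genome_pair,
    generate_intensities,
    generate_probes,
    make_design,
    simulate_scenario,
)
from elpcip.simulate import generate_annotations, generate_promoters, write_scenario


class TestGenomePair:
    def test_zero_rates_identity(self):
        gp = generate_genome_pair(2000, 0.0, 0.0, seed=5)
        assert gp.seq_a == gp.seq_b
        assert gp.variants == []

    def test_same_seed_identical(self):
        a = generate_genome_pair(3000, 0.01, 0.001, seed=11)
        b = generate_genome_pair(3000, 0.01, 0.001, seed=11)
        assert a.seq_a == b.seq_a and a.seq_b == b.seq_b and a.variants == b.variants

    def test_variant_count_binomial(self):
        # 10 kb at snp rate 0.005 -> ~50 SNPs, within +-4 sqrt(50)
        gp = generate_genome_pair(10_000, 0.005, 0.0, seed=3)
        n_snp = sum(1 for _p, k, _l in gp.variants if k == "snp")
        assert abs(n_snp - 50) <= 4 * np.sqrt(50)

    def test_variants_transform_a_into_b(self):
        gp = generate_genome_pair(5000, 0.01, 0.002, seed=9)
        seq = gp.seq_a
        # apply right-to-left so earlier coordinates stay valid
        for pos, kind, vlen in sorted(gp.variants, reverse=True):
            if kind == "snp":
                assert gp.seq_b != gp.seq_a  # at least one substitution applied
            elif kind == "del":
                seq = seq[:pos] + seq[pos + vlen :]
        # deletions accounted for in length difference with insertions
        ins = sum(l for _p, k, l in gp.variants if k == "ins")
        dels = sum(l for _p, k, l in gp.variants if k == "del")
        assert len(gp.seq_b) == len(gp.seq_a) + ins - dels

    @pytest.mark.parametrize("kwargs", [dict(snp_rate=0.5), dict(indel_rate=-0.1)])
    def test_rates_out_of_range(self, kwargs):
        with pytest.raises(ValueError):
            generate_genome_pair(2000, kwargs.get("snp_rate", 0.0), kwargs.get("indel_rate", 0.0), 1)


class TestProbes:
    def test_zero_variant_genome_no_polymorphic_probes(self):
        gp = generate_genome_pair(60_000, 0.0, 0.0, seed=2)
        sim = generate_probes(gp, 20, 11, 25, seed=4, gene_span=400, intergenic=1200)
        assert not any(sim.polymorphic.values())

    def test_probe_counts_and_substrings(self):
        gp = generate_genome_pair(60_000, 0.002, 0.0, seed=2)
        sim = generate_probes(gp, 20, 11, 25, seed=4, gene_span=400, intergenic=1200)
        assert len(sim.probes) == 20 * 11
        assert all(len(s) == 25 for s in sim.probes.values())
        assert all(s in gp.seq_a for s in sim.probes.values())

    def test_probe_over_variant_marked_polymorphic(self):
        gp = generate_genome_pair(60_000, 0.02, 0.0, seed=8)
        sim = generate_probes(gp, 20, 11, 25, seed=4)
        marked = [p for p, is_p in sim.polymorphic.items() if is_p]
        assert marked, "at 2% per-bp SNP rate some probes must overlap a variant"

    def test_genome_too_short(self):
        gp = generate_genome_pair(2000, 0.0, 0.0, seed=1)
        with pytest.raises(ValueError, match="too short"):
            generate_probes(gp, 50, 11, 25, seed=0)


def _truth_and_map(scenario, seed=0):
    data = simulate_scenario(scenario)
    return data


class TestIntensities:
    def test_null_model_equal_cell_means(self):
        sc = SimScenario(rng_seed=1, n_probesets=10, noise_sd=0.0, cip_fraction=0.0,
                         polymorphic_fraction=0.0, genome_indel_rate=0.0)
        data = simulate_scenario(sc)
        log2 = np.log2(data.intensities.values)
        # with no noise, effects or polymorphism every array sees the same value
        assert np.allclose(log2, log2[:, [0]])

    def test_planted_cultivar_delta_exact_without_noise(self):
        sc = SimScenario(rng_seed=3, n_probesets=10, noise_sd=0.0,
                         delta_treatment=0.0, delta_interaction=0.0,
                         delta_cultivar=1.0, cip_fraction=0.3, polymorphic_fraction=0.0,
                         genome_indel_rate=0.0)
        data = simulate_scenario(sc)
        log2 = np.log2(data.intensities.values)
        d = data.design.frame
        a_cols = (d["genotype"] == data.design.genotype_a).to_numpy()
        deltas = log2[:, a_cols].mean(axis=1) - log2[:, ~a_cols].mean(axis=1)
        cips = data.truth.cip_probesets()
        for i, pid in enumerate(data.intensities.probe_ids):
            expected = 0.0
            ps = data.probe_map.probeset_of(pid)
            if ps in cips:
                q = data.truth.probesets.set_index("probeset_id").loc[ps, "quadrant"]
                expected = 1.0 if q.startswith("prefA") else -1.0
            assert deltas[i] == pytest.approx(expected, abs=1e-9)

    def test_same_seed_identical_matrix(self):
        a = simulate_scenario(SimScenario(rng_seed=5, n_probesets=12))
        b = simulate_scenario(SimScenario(rng_seed=5, n_probesets=12))
        np.testing.assert_array_equal(a.intensities.values, b.intensities.values)
        pd.testing.assert_frame_equal(a.annotations, b.annotations)
        assert a.promoters == b.promoters
        assert a.indels == b.indels


class TestAnnotationsPromotersIndels:
    def test_no_planted_signal_at_odds_one(self, small_scenario):
        ann = generate_annotations(small_scenario.truth, 10, enriched_odds=1.0, seed=3)
        # enriched category annotation rate among planted items stays at baseline
        cip = small_scenario.truth.cip_probesets()
        enriched = small_scenario.truth.enriched_category
        k = len(set(ann.loc[ann.category_id == enriched, "item_id"]) & cip)
        assert k <= max(3, 0.35 * len(cip))  # ~baseline 10%, not ~50%

    def test_motif_planted_in_every_cip_promoter(self, small_scenario):
        cip_genes = small_scenario.truth.cip_genes()
        motif = small_scenario.scenario.motif
        assert cip_genes
        for g in cip_genes:
            assert motif in small_scenario.promoters[g]

    def test_motif_longer_than_promoter(self, small_scenario):
        with pytest.raises(ValueError, match="longer"):
            generate_promoters(small_scenario.truth, "A" * 300, 200, seed=0)

    def test_indels_near_their_genes(self, small_scenario):
        window = small_scenario.scenario.upstream_window
        spans = {(g.start, g.end) for g in small_scenario.gene_models}
        for v in small_scenario.indels:
            near = any(
                v.start < e + window and v.end > s - window for s, e in spans
            )
            assert near


class TestRecoveryMetrics:
    def test_arithmetic(self):
        truth = simulate_scenario(SimScenario(rng_seed=2, n_probesets=40, cip_fraction=0.5)).truth
        planted = sorted(truth.cip_probesets())
        assert len(planted) == 20
        called = planted[:18] + ["PSFAKE"]
        sens, fdr = evaluate_recovery(called, truth)
        assert sens == pytest.approx(0.90)
        assert fdr == pytest.approx(1 / 19)

    def test_zero_calls(self, small_scenario):
        assert evaluate_recovery([], small_scenario.truth) == (0.0, 0.0)

    def test_perfect_calls(self, small_scenario):
        planted = small_scenario.truth.cip_probesets()
        assert evaluate_recovery(planted, small_scenario.truth) == (1.0, 0.0)


def test_write_scenario_round_trips(tmp_path, small_scenario):
    from elpcip import read_design, read_intensity_table, read_probe_map

    write_scenario(small_scenario, tmp_path)
    m = read_intensity_table(tmp_path / "intensities.tsv")
    np.testing.assert_allclose(m.values, small_scenario.intensities.values, rtol=1e-9)
    assert read_design(tmp_path / "design.tsv").array_ids == small_scenario.design.array_ids
    assert len(read_probe_map(tmp_path / "probe_map.tsv")) == len(small_scenario.probe_map)
    for name in ("genome_a.fa", "genome_b.fa", "promoters.fa", "genes.gff3",
                 "indels.tsv", "annotations.tsv", "truth.tsv"):
        assert (tmp_path / name).exists()
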