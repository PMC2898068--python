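import dataclasses
import json
import math

import numpy as np
import pytest
from scipy import stats

import rnaconcord as rc


def tiny_config(**overrides):
    return rc.SimulationConfig(**{"n_genes": 30, "seed": 5, **overrides})


# --- determinism --------------------------------------------------------


def test_same_seed_reproduces_truth_exactly():
    a = rc.simulate_truth(tiny_config())
    b = rc.simulate_truth(tiny_config())
    assert a.variants == b.variants
    assert a.artifact_sites == b.artifact_sites
    assert a.exons == b.exons
    assert a.expression == b.expression
    assert a.known_sites == b.known_sites


def test_same_seed_reproduces_bundle_hashes(tmp_path):
    cfg = tiny_config()
    m1 = rc.generate_fixture_bundle(cfg, tmp_path / "a")
    m2 = rc.generate_fixture_bundle(cfg, tmp_path / "b")
    assert m1 == m2


def test_different_seeds_differ():
    a = rc.simulate_truth(tiny_config())
    b = rc.simulate_truth(tiny_config(seed=6))
    assert a.variants != b.variants


# --- truth geometry -----------------------------------------------------


def test_truth_variants_lie_inside_their_exons():
    truth = rc.simulate_truth(tiny_config(het_rate=5e-3))
    for v in truth.variants:
        exon = truth.exons[v.exon_index]
        assert exon.contains(v.chrom, v.pos)
        assert exon.transcript_id == v.transcript_id


def test_expression_table_max_is_100():
    truth = rc.simulate_truth(tiny_config())
    assert max(e.expression_pct for e in truth.expression) == 100.0


def test_high_density_exon_yields_at_least_one_variant():
    truth = rc.simulate_truth(tiny_config(n_genes=1, het_rate=0.2))
    assert len(truth.variants) >= 1


def test_expression_distribution_recovers_lognormal_shape():
    cfg = rc.SimulationConfig(n_genes=10_000, silent_fraction=0.0, seed=17)
    truth = rc.simulate_truth(cfg)
    logs = np.log([e.expression_pct for e in truth.expression])
    # rescaling shifts location only: compare against a normal with the
    # configured sigma and the sample mean
    stat = stats.kstest(logs, "norm", args=(logs.mean(), cfg.expression_sigma))
    assert stat.pvalue > 0.01


# --- gDNA callset -------------------------------------------------------


def test_zero_gdna_depth_gives_empty_callset():
    truth = rc.simulate_truth(tiny_config(het_rate=5e-3, gdna_mean_depth=0.0))
    assert rc.simulate_gdna_callset(truth) == []


def test_high_depth_homozygotes_always_called_with_full_support():
    cfg = tiny_config(n_genes=10, het_rate=2e-3, hom_fraction=1.0,
                      per_base_error=0.0, gdna_mean_depth=1000.0,
                      paralog_hotspot_rate=0.0, end_hotspot_rate=0.0,
                      noise_site_rate=0.0)
    truth = rc.simulate_truth(cfg)
    calls = rc.simulate_gdna_callset(truth)
    assert len(calls) == len(truth.variants) > 0
    assert all(c.alt_support == c.read_depth for c in calls)
    assert all(not c.is_het for c in calls)


def test_het_emission_rate_matches_binomial_tail_oracle():
    # ~10,000 heterozygous sites at Poisson(24) depth; emission requires
    # >= 3 alt-supporting reads
    cfg = rc.SimulationConfig(n_genes=2000, het_rate=5e-3, hom_fraction=0.0,
                              noise_site_rate=0.0, seed=29)
    truth = rc.simulate_truth(cfg)
    calls = rc.simulate_gdna_callset(truth)
    n = len(truth.variants)
    assert n > 8000
    recovered = len(calls) / n
    d = np.arange(0, 200)
    oracle = float(np.sum(stats.poisson.pmf(d, 24.0) * stats.binom.sf(2, d, 0.5)))
    se = math.sqrt(oracle * (1 - oracle) / n)
    assert abs(recovered - oracle) <= 3 * se + 1e-9


# --- cDNA callset -------------------------------------------------------


def test_no_expression_gives_empty_cdna_callset():
    truth = rc.simulate_truth(tiny_config(het_rate=5e-3))
    # silence every transcript by zeroing the expression table's effect
    truth = dataclasses.replace(truth, expression=[
        rc.ExpressionRecord(e.transcript_id, 0.0) for e in truth.expression])
    sim = rc.simulate_cdna_callset(truth)
    assert sim.calls == []


def test_lane_snapshots_are_nested():
    study = rc.simulate_study(rc.SimulationConfig(n_genes=150, seed=9))
    snaps = study.cdna.lane_snapshots
    assert len(snaps) == study.truth.config.lanes
    for earlier, later in zip(snaps, snaps[1:]):
        assert {c.key for c in earlier} <= {c.key for c in later}
        # alt support only accumulates
        later_by_key = {c.key: c for c in later}
        for c in earlier:
            assert later_by_key[c.key].alt_support >= c.alt_support


def test_end_artifact_calls_fail_default_cdna_qc():
    cfg = rc.SimulationConfig(n_genes=300, seed=10, artifact_end_fraction=1.0,
                              end_hotspot_rate=5e-3, end_fp_rate=0.05)
    study = rc.simulate_study(cfg)
    end_positions = {(s.chrom, s.pos) for s in study.truth.artifact_sites if s.kind == "end"}
    emitted = [c for c in study.cdna.calls if c.key in end_positions]
    assert emitted, "construction should emit some end-artifact calls pre-QC"
    assert all(c.alt_end_fraction > 0.2 for c in emitted)
    kept, _ = rc.filter_calls(emitted, rc.FilterParams.for_cdna())
    assert kept == []


def test_allelic_imbalance_recovered_from_zygosity_discordance():
    # deep, artifact-free configuration isolates the imbalance process
    cfg = rc.SimulationConfig(n_genes=1500, het_rate=3e-3, hom_fraction=0.0,
                              allelic_imbalance=0.2, per_base_error=0.0,
                              end_artifact_rate=0.0, paralog_hotspot_rate=0.0,
                              end_hotspot_rate=0.0, noise_site_rate=0.0,
                              silent_fraction=0.0, median_expressed_depth=400.0,
                              seed=31)
    study = rc.simulate_study(cfg)
    res = rc.ConcordanceAnalysis(
        study.gdna_calls, study.cdna.calls, exons=study.truth.exons).fit()
    z = res.zygosity()
    het_pairs = [p for p in res.classified.tp_pairs if p[0].is_het]
    r = z.het_gdna_hom_cdna / len(het_pairs)
    recovered = 2 * r / (1 + r)  # inverts P(hom|detected) = (a/2)/(1 - a/2)
    n = len(het_pairs)
    p_hom = cfg.allelic_imbalance / (2 - cfg.allelic_imbalance)
    se_r = math.sqrt(p_hom * (1 - p_hom) / n)
    assert abs(r - p_hom) <= 3 * se_r


# --- fixture bundle -----------------------------------------------------


def test_bundle_files_consistent_with_truth_json(bundle_dir):
    outdir, cfg, manifest = bundle_dir
    truth_doc = json.loads((outdir / "truth.json").read_text())
    exons = rc.read_exon_annotation(outdir / "exons.bed")
    expr = rc.read_expression_table(outdir / "expression.tsv")
    genes = rc.read_gene_annotations(outdir / "genes.tsv")
    sites = rc.read_position_set(outdir / "known_sites.tsv")
    assert truth_doc["counts"]["exons"] == len(exons)
    assert truth_doc["counts"]["genes"] == len(expr) == len(genes)
    assert truth_doc["counts"]["known_sites"] == len(sites)
    assert truth_doc["counts"]["truth_variants"] == len(truth_doc["variants"])
    assert set(manifest["files"]) >= {
        "exons.bed", "expression.tsv", "genes.tsv", "known_sites.tsv",
        "gdna.pileup.tsv", "cdna.pileup.tsv", "depth.bedgraph", "truth.json",
    }


def test_bundle_drives_full_pipeline_end_to_end(bundle_dir):
    outdir, _, _ = bundle_dir
    model = rc.ConcordanceAnalysis.from_files(
        outdir / "gdna.pileup.tsv", outdir / "cdna.pileup.tsv",
        exons_path=outdir / "exons.bed",
        expression_path=outdir / "expression.tsv",
        genes_path=outdir / "genes.tsv",
        known_sites_path=outdir / "known_sites.tsv",
    )
    res = model.fit()
    c = res.counts
    assert c.tp + c.fn == c.n_gdna and c.tp + c.fp == c.n_cdna
    assert res.by_expression() and res.by_paralog()
    track = rc.DepthTrack.from_bedgraph(outdir / "depth.bedgraph")
    covs = [rc.exon_mean_coverage(track, e) for e in model.exons]
    assert rc.coverage_summary(covs, threshold=5).n_exons == len(model.exons)
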