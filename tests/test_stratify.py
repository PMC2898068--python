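import math

import pytest

import rnaconcord as rc
from rnaconcord.concord import ConcordanceCounts

from conftest import make_call


def annotated(pos, source, tids=("T1",), gids=("G1",), **kw):
    return make_call(pos, source=source, transcript_ids=tids, gene_ids=gids, **kw)


def classified(gdna, cdna):
    return rc.classify_calls(gdna, cdna, "position")


# --- log bins -----------------------------------------------------------


def test_log_bins_powers_of_ten():
    bins = rc.make_log_bins(0.1, 100, 1, expressed_threshold=10.0)
    assert bins.edges == pytest.approx((0.1, 1.0, 10.0, 100.0))


def test_default_bins_have_four_percent_edge():
    bins = rc.default_bins()
    assert any(math.isclose(e, 4.0, rel_tol=1e-9) for e in bins.edges)
    assert bins.edges[0] == pytest.approx(0.04) and bins.edges[-1] == 100.0


@pytest.mark.parametrize("args", [(0.1, 100, 0), (0.0, 100, 2), (50.0, 10.0, 2)])
def test_log_bins_invalid_inputs(args):
    with pytest.raises(ValueError):
        rc.make_log_bins(*args)


def test_threshold_must_coincide_with_an_edge():
    with pytest.raises(ValueError, match="not a bin edge"):
        rc.ExpressionBins(edges=(1.0, 10.0, 100.0), expressed_threshold=4.0)


def test_bin_assignment_intervals():
    bins = rc.ExpressionBins(edges=(1.0, 4.0, 100.0), expressed_threshold=4.0)
    assert bins.assign(0.5) == -1
    assert bins.assign(1.0) == 0
    assert bins.assign(4.0) == 1
    assert bins.assign(100.0) == 1  # last bin closed on both ends


# --- expression stratification ------------------------------------------


def test_single_transcript_degenerate_partition_equals_unstratified():
    gdna = [annotated(p, "gDNA") for p in (10, 20, 30)]
    cdna = [annotated(p, "cDNA") for p in (10, 20, 40)]
    cls = classified(gdna, cdna)
    strata = rc.stratify_by_expression(cls, [rc.ExpressionRecord("T1", 4.0)])
    occupied = [s for s in strata if s.counts.tp + s.counts.fp + s.counts.fn]
    assert len(occupied) == 1
    assert occupied[0].counts == ConcordanceCounts(tp=2, fp=1, fn=1)
    assert occupied[0].sensitivity == cls.counts.sensitivity
    assert occupied[0].specificity == cls.counts.specificity


def test_multi_transcript_call_takes_max_expression():
    cls = classified(
        [annotated(10, "gDNA", tids=("T1", "T2"))],
        [annotated(10, "cDNA", tids=("T1", "T2"))],
    )
    expr = [rc.ExpressionRecord("T1", 1.0), rc.ExpressionRecord("T2", 10.0)]
    bins = rc.ExpressionBins(edges=(0.4, 4.0, 100.0), expressed_threshold=4.0)
    strata = rc.stratify_by_expression(cls, expr, bins)
    assert strata[0].counts.tp == 0  # not in the [0.4, 4) bin
    assert strata[1].counts.tp == 1  # assigned by the 10% transcript


def test_unannotated_call_is_an_error():
    cls = classified([make_call(10, source="gDNA")], [make_call(10, source="cDNA")])
    with pytest.raises(ValueError, match="no transcript annotation"):
        rc.stratify_by_expression(cls, [rc.ExpressionRecord("T1", 4.0)])


def test_expression_strata_counts_sum_to_totals(fitted):
    _, res = fitted
    strata = res.by_expression()
    totals = res.counts
    assert sum(s.counts.tp for s in strata) == totals.tp
    assert sum(s.counts.fp for s in strata) == totals.fp
    assert sum(s.counts.fn for s in strata) == totals.fn
    # every stratum's metrics recompute from its own counts
    for s in strata:
        sens, spec = rc.concordance_metrics(s.counts)
        assert (math.isnan(sens) and math.isnan(s.sensitivity)) or sens == s.sensitivity
        assert (math.isnan(spec) and math.isnan(s.specificity)) or spec == s.specificity


# --- depth windows ------------------------------------------------------


def test_depth_window_identity_when_everything_inside():
    gdna = [annotated(p, "gDNA", depth=30, alt=12) for p in (10, 20)]
    cdna = [annotated(p, "cDNA", depth=30, alt=12) for p in (10, 40)]
    cls = classified(gdna, cdna)
    s = rc.filter_by_depth_window(cls, 3, None)
    assert s.counts == ConcordanceCounts(tp=1, fp=1, fn=1)


def test_depth_window_restricts_cdna_side_only():
    gdna = [annotated(p, "gDNA", depth=25, alt=12) for p in (10, 20)]
    cdna = [annotated(10, "cDNA", depth=10, alt=5), annotated(20, "cDNA", depth=100, alt=40)]
    s = rc.filter_by_depth_window(classified(gdna, cdna), 50, 1200)
    # the depth-10 TP falls outside the window: tp drops, fn rises against full gDNA
    assert (s.counts.tp, s.counts.fp, s.counts.fn) == (1, 0, 1)


def test_depth_window_validates_bounds():
    cls = classified([], [])
    with pytest.raises(ValueError):
        rc.filter_by_depth_window(cls, 0)
    with pytest.raises(ValueError):
        rc.filter_by_depth_window(cls, 50, 10)


# --- paralog partition --------------------------------------------------


def test_paralog_partition_exhaustive_and_any_rule():
    genes = [rc.GeneAnnotation("G1", False), rc.GeneAnnotation("G2", True)]
    gdna = [annotated(10, "gDNA", gids=("G1",)), annotated(20, "gDNA", gids=("G2",))]
    cdna = [annotated(10, "cDNA", gids=("G1",)),
            annotated(30, "cDNA", gids=("G1", "G2"))]  # any paralogous gene taints
    with_p, without_p = rc.partition_by_paralog(classified(gdna, cdna), genes)
    assert (with_p.counts.tp, with_p.counts.fp, with_p.counts.fn) == (0, 1, 1)
    assert (without_p.counts.tp, without_p.counts.fp, without_p.counts.fn) == (1, 0, 0)
    total = classified(gdna, cdna).counts
    assert with_p.counts.tp + without_p.counts.tp == total.tp
    assert with_p.counts.fp + without_p.counts.fp == total.fp
    assert with_p.counts.fn + without_p.counts.fn == total.fn


def test_all_nonparalog_puts_everything_in_one_stratum():
    genes = [rc.GeneAnnotation("G1", False)]
    cls = classified([annotated(10, "gDNA")], [annotated(10, "cDNA")])
    with_p, without_p = rc.partition_by_paralog(cls, genes)
    assert with_p.counts.tp == 0 and without_p.counts.tp == 1


def test_missing_gene_annotation_is_error_listing_ids():
    cls = classified([annotated(10, "gDNA", gids=("GX",))],
                     [annotated(10, "cDNA", gids=("GX",))])
    with pytest.raises(ValueError, match="GX"):
        rc.partition_by_paralog(cls, [rc.GeneAnnotation("G1", False)])


# --- known-site rates ---------------------------------------------------


def test_known_site_rates_empty_and_full_sets():
    cls = classified([annotated(10, "gDNA"), annotated(20, "gDNA")],
                     [annotated(10, "cDNA"), annotated(30, "cDNA")])
    empty = rc.known_site_rates(cls, rc.PositionSet())
    assert (empty["tp"], empty["fp"], empty["fn"], empty["gdna_all"]) == (0, 0, 0, 0)
    full = rc.known_site_rates(cls, rc.PositionSet([("chr1", p) for p in (10, 20, 30)]))
    assert (full["tp"], full["fp"], full["fn"], full["gdna_all"]) == (1, 1, 1, 1)


def test_known_site_rates_match_brute_force(fitted, study):
    _, res = fitted
    rates = res.known_site_rates()
    sites = study.truth.known_sites
    tp_calls = [c for _, c in res.classified.tp_pairs]
    assert rates["tp"] == pytest.approx(
        sum(c.key in sites for c in tp_calls) / len(tp_calls))
    assert all(0 <= r <= 1 for r in rates.values())


# --- lane curves --------------------------------------------------------


def test_identical_snapshots_give_flat_curve():
    gdna = [annotated(p, "gDNA") for p in (10, 20)]
    snap = [annotated(10, "cDNA"), annotated(30, "cDNA")]
    curve = rc.lane_accumulation_curve([snap, snap, snap], gdna)
    assert len({(s.counts.tp, s.counts.fp, s.counts.fn) for s in curve}) == 1
    assert all(s.extras["tp_monotonic"] == 1.0 for s in curve)


def test_single_snapshot_equals_plain_classification():
    gdna = [annotated(p, "gDNA") for p in (10, 20)]
    snap = [annotated(10, "cDNA")]
    (point,) = rc.lane_accumulation_curve([snap], gdna)
    assert point.counts == rc.classify_calls(gdna, snap).counts


def test_empty_snapshot_list_is_error():
    with pytest.raises(ValueError):
        rc.lane_accumulation_curve([], [])


def test_tp_violation_reported_not_fixed():
    gdna = [annotated(p, "gDNA") for p in (10, 20)]
    bigger = [annotated(10, "cDNA"), annotated(20, "cDNA")]
    smaller = [annotated(10, "cDNA")]
    curve = rc.lane_accumulation_curve([bigger, smaller], gdna)
    assert curve[1].extras["tp_monotonic"] == 0.0
    assert curve[1].counts.tp == 1  # reported as observed
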