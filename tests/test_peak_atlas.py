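import numpy as np
import pandas as pd
import pytest

from ipa_atlas.atlas import (
    LibraryInfo,
    PeakSet,
    apply_robustness_filters,
    assign_genes,
    build_atlas,
    cluster_peaks,
    compute_usage,
    distal_utr_usage,
    expression_calls,
    filter_artifact_peaks,
    filter_gene_context,
    mask_ig_adjust_library,
    quantify_tpm,
)

from conftest import make_annotation, make_gene, make_peakset

# toy genome: gene on [0,520) as in make_gene, chromosome of 3 kb
GENOME = {"chr1": "C" * 3000}


def _lib(samples=("s1",), raw=1_000_000, adjusted=1_000_000):
    return LibraryInfo(
        pd.DataFrame({"raw": raw, "adjusted": adjusted}, index=list(samples))
    )


def peak(pid, start, end, strand="+", chrom="chr1"):
    return {"peak_id": pid, "chrom": chrom, "start": start, "end": end, "strand": strand}


class TestArtifactFilters:
    def test_blacklist_overlap_flagged(self):
        ps = make_peakset([peak("p1", 990, 1010)], {"p1": {"s1": 5}})
        ann = make_annotation(make_gene())
        bl = pd.DataFrame([{"chrom": "chr1", "start": 1000, "end": 1100}])
        out = filter_artifact_peaks(ps, bl, GENOME, ann)
        assert out.peaks.loc["p1", "blacklist"]

    def test_internal_priming_on_downstream_a_run(self):
        genome = {"chr1": "C" * 1000 + "AAAAAAA" + "C" * 1000}
        ps = make_peakset([peak("p1", 975, 1000)], {"p1": {"s1": 5}})
        out = filter_artifact_peaks(ps, None, genome, make_annotation(make_gene()))
        assert out.peaks.loc["p1", "internal_priming"]

    def test_internal_priming_seven_scattered_a(self):
        genome = {"chr1": "C" * 1000 + "AACAACAACA" + "C" * 1000}
        ps = make_peakset([peak("p1", 975, 1000)], {"p1": {"s1": 5}})
        out = filter_artifact_peaks(ps, None, genome, make_annotation(make_gene()))
        assert out.peaks.loc["p1", "internal_priming"]

    def test_clean_downstream_not_flagged(self):
        ps = make_peakset([peak("p1", 975, 1000)], {"p1": {"s1": 5}})
        out = filter_artifact_peaks(ps, None, GENOME, make_annotation(make_gene()))
        assert not out.peaks.loc["p1", "internal_priming"]

    def test_minus_strand_internal_priming_uses_sense_downstream(self):
        # sense downstream of a minus-strand 3' end at 1000 is revcomp of [990,1000)
        genome = {"chr1": "C" * 990 + "TTTTTTTTTT" + "C" * 1000}
        ps = make_peakset([peak("p1", 1000, 1025, strand="-")], {"p1": {"s1": 5}})
        out = filter_artifact_peaks(ps, None, genome, make_annotation(make_gene()))
        assert out.peaks.loc["p1", "internal_priming"]

    def test_antisense_single_opposite_gene(self):
        ps = make_peakset([peak("p1", 140, 165, strand="-")], {"p1": {"s1": 5}})
        out = filter_artifact_peaks(ps, None, GENOME, make_annotation(make_gene()))
        assert out.peaks.loc["p1", "antisense"]

    def test_peak_beyond_chromosome_errors(self):
        ps = make_peakset([peak("p1", 2990, 3010)], {"p1": {"s1": 5}})
        with pytest.raises(ValueError, match="beyond chromosome"):
            filter_artifact_peaks(ps, None, GENOME, make_annotation(make_gene()))


class TestIgMasking:
    def test_adjusted_library_arithmetic(self):
        ps = make_peakset(
            [peak("ig", 1000, 1025), peak("p1", 100, 125)],
            {"ig": {"s1": 1_000_000}, "p1": {"s1": 10}},
        )
        ig = pd.DataFrame([{"chrom": "chr1", "start": 900, "end": 1100}])
        raw = pd.Series({"s1": 2_000_000})
        out, lib = mask_ig_adjust_library(ps, ig, raw)
        assert out.peaks.loc["ig", "immunoglobulin"]
        assert lib.table.loc["s1", "adjusted"] == 1_000_000

    def test_empty_ig_removes_only_artifact_counts(self):
        ps = make_peakset(
            [peak("a", 100, 125), peak("b", 300, 325)],
            {"a": {"s1": 40}, "b": {"s1": 10}},
        )
        ps.ensure_flags()
        ps.peaks.loc["a", "blacklist"] = True
        raw = pd.Series({"s1": 100})
        _, lib = mask_ig_adjust_library(ps, None, raw)
        assert lib.table.loc["s1", "adjusted"] == 60

    def test_adjusted_monotone_under_extra_flags(self):
        ps = make_peakset(
            [peak("a", 100, 125), peak("b", 300, 325)],
            {"a": {"s1": 40}, "b": {"s1": 10}},
        )
        raw = pd.Series({"s1": 100})
        _, lib0 = mask_ig_adjust_library(ps, None, raw)
        ps.peaks["blacklist"] = True
        _, lib1 = mask_ig_adjust_library(ps, None, raw)
        assert lib1.table.loc["s1", "adjusted"] <= lib0.table.loc["s1", "adjusted"]


class TestGeneContext:
    def _two_gene_annotation(self, second_strand="-", utr_end_at=150):
        """host gene plus a second gene whose 3'UTR end is placed near the
        host's first intron (for the convergent / upstream-gene rules)."""
        host = make_gene()
        d = utr_end_at
        if second_strand == "-":
            other = make_gene(
                gene_id="gOther",
                strand="-",
                exons=((d, d + 100),),
                cds=((d + 50, d + 80),),
                utr3=((d, d + 50),),
            )
        else:
            other = make_gene(
                gene_id="gOther",
                exons=((d - 100, d + 1),),
                cds=((d - 100, d - 40),),
                utr3=((d - 40, d + 1),),
            )
        return make_annotation(host, other)

    def test_convergent_utr_within_100nt_removed(self):
        ann = self._two_gene_annotation("-", utr_end_at=150 + 80)
        # intronic peak 3' end at 150; opposite-strand utr3_end at 230 -> 80 nt
        ps = assign_genes(make_peakset([peak("p1", 126, 151)], {"p1": {"s1": 5}}), ann)
        out = filter_gene_context(ps, ann)
        assert out.peaks.loc["p1", "convergent_3utr_proximal"]

    def test_convergent_utr_beyond_100nt_kept(self):
        ann = self._two_gene_annotation("-", utr_end_at=150 + 120)
        ps = assign_genes(make_peakset([peak("p1", 126, 151)], {"p1": {"s1": 5}}), ann)
        out = filter_gene_context(ps, ann)
        assert not out.peaks.loc["p1", "convergent_3utr_proximal"]

    def test_upstream_same_strand_within_5000_removed(self):
        host = make_gene(
            exons=((10000, 10100), (16000, 16100), (16200, 16400)),
            cds=((10030, 10100), (16000, 16100), (16200, 16230)),
            utr3=((16230, 16400),),
        )
        other = make_gene(
            gene_id="gUp",
            exons=((9000, 9200),),
            cds=((9000, 9120),),
            utr3=((9120, 9200),),
        )
        ann = make_annotation(host, other)
        # intronic peak at 12000: 12000 - 9199 < 5000 -> flagged
        ps = assign_genes(make_peakset([peak("p1", 11976, 12001)], {"p1": {"s1": 5}}), ann)
        out = filter_gene_context(ps, ann)
        assert out.peaks.loc["p1", "upstream_gene_proximal"]
        # peak at 15000: 15000 - 9199 > 5000 -> kept
        ps2 = assign_genes(make_peakset([peak("p2", 14976, 15001)], {"p2": {"s1": 5}}), ann)
        out2 = filter_gene_context(ps2, ann)
        assert not out2.peaks.loc["p2", "upstream_gene_proximal"]

    def test_ambiguous_gene_flagged(self):
        ann = make_annotation(make_gene())
        ann.overlap_flags = {"gX"}
        ps = assign_genes(make_peakset([peak("p1", 126, 151)], {"p1": {"s1": 5}}), ann)
        out = filter_gene_context(ps, ann)
        assert out.peaks.loc["p1", "ambiguous_gene"]

    def test_smallrna_intronic_peak_flagged(self):
        ann = make_annotation(make_gene())
        ann.smallrna_intervals = [("chr1", 140, 180)]
        ps = assign_genes(make_peakset([peak("p1", 126, 151)], {"p1": {"s1": 5}}), ann)
        out = filter_gene_context(ps, ann)
        assert out.peaks.loc["p1", "smallrna"]


class TestTpm:
    def test_arithmetic(self):
        counts = pd.DataFrame({"s1": [50, 0]}, index=["a", "b"])
        tpm = quantify_tpm(counts, _lib(adjusted=10_000_000))
        assert tpm.loc["a", "s1"] == pytest.approx(5.0)
        assert tpm.loc["b", "s1"] == 0.0

    def test_zero_library_errors(self):
        counts = pd.DataFrame({"s1": [1]}, index=["a"])
        with pytest.raises(ValueError):
            quantify_tpm(counts, _lib(adjusted=0))

    def test_tpm_sum_bounded_by_1e6(self, small_sim, small_atlas):
        atl, _ = small_atlas
        assert (atl.tpm.sum(axis=0) <= 1e6 + 1e-6).all()


def _clustering_input(end3s, strand="+", counts=None):
    rows, cnts, starts = [], {}, {}
    for i, p in enumerate(end3s):
        pid = f"p{i}"
        rows.append(
            {
                "peak_id": pid,
                "chrom": "chr1",
                "start": p - 24 if strand == "+" else p,
                "end": p + 1 if strand == "+" else p + 25,
                "strand": strand,
                "gene_id": "gX",
                "region": "INTRON",
                "intron_index": 0,
            }
        )
        cnts[pid] = {"s1": (counts or {}).get(p, 10)}
        starts[(pid, "s1")] = np.array([p - 40, p - 30, p - 20, p - 10])
    return PeakSet(pd.DataFrame(rows).set_index("peak_id"), pd.DataFrame(cnts).T, starts)


def _oracle_single_linkage(end3s, gap=200):
    """Exhaustive pairing oracle: clusters are connected components of the
    '<=gap apart' graph."""
    end3s = sorted(end3s)
    comps = []
    for p in end3s:
        placed = False
        for comp in comps:
            if any(abs(p - q) <= gap for q in comp):
                comp.append(p)
                placed = True
                break
        if not placed:
            comps.append([p])
    # merge transitively
    merged = True
    while merged:
        merged = False
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                if any(abs(a - b) <= gap for a in comps[i] for b in comps[j]):
                    comps[i] += comps.pop(j)
                    merged = True
                    break
            if merged:
                break
    return sorted(sorted(c) for c in comps)


class TestClustering:
    def test_two_ends_within_200_merge(self):
        atl = cluster_peaks(_clustering_input([100, 250]), _lib())
        assert len(atl.events) == 1

    def test_chain_matches_exhaustive_oracle(self):
        for ends in ([100, 250, 460], [100, 350], [100, 301], [100, 300], [0, 150, 355, 600]):
            atl = cluster_peaks(_clustering_input(ends), _lib())
            assert len(atl.events) == len(_oracle_single_linkage(ends))

    def test_ends_beyond_200_stay_separate(self):
        atl = cluster_peaks(_clustering_input([100, 350]), _lib())
        assert len(atl.events) == 2

    def test_representative_highest_count_tie_distal(self):
        atl = cluster_peaks(
            _clustering_input([100, 250], counts={100: 10, 250: 50}), _lib()
        )
        assert atl.events["rep_pos"].iloc[0] == 250
        atl2 = cluster_peaks(
            _clustering_input([100, 250], counts={100: 10, 250: 10}), _lib()
        )
        assert atl2.events["rep_pos"].iloc[0] == 250  # tie -> distal on + strand

    def test_cluster_counts_sum_members(self):
        atl = cluster_peaks(
            _clustering_input([100, 250], counts={100: 10, 250: 50}), _lib()
        )
        assert atl.counts.iloc[0, 0] == 60

    def test_idempotent(self):
        atl = cluster_peaks(_clustering_input([100, 250, 460, 900]), _lib())
        again = cluster_peaks(atl.as_peakset(), _lib())
        assert len(again.events) == len(atl.events)
        assert set(again.events["rep_pos"]) == set(atl.events["rep_pos"])

    def test_input_order_invariance(self, small_sim):
        cfg, ann, genome, truth, peakset, raw = small_sim
        shuffled = PeakSet(
            peakset.peaks.iloc[::-1].copy(), peakset.counts.iloc[::-1].copy(), peakset.starts
        )
        a1, _ = build_atlas(peakset, ann, genome, raw, truth.blacklist, truth.ig_intervals)
        a2, _ = build_atlas(shuffled, ann, genome, raw, truth.blacklist, truth.ig_intervals)
        assert sorted(a1.events.index) == sorted(a2.events.index)


def _usage_atlas(tpm_by_event):
    """events: dict event_id -> (klass, {sample: tpm})."""
    rows, tpm = [], {}
    for eid, (klass, vals, rep) in tpm_by_event.items():
        rows.append(
            {
                "event_id": eid,
                "gene_id": "gX",
                "chrom": "chr1",
                "start": rep - 24,
                "end": rep + 1,
                "strand": "+",
                "klass": klass,
                "rep_pos": rep,
                "intron_index": 0 if klass == "IPA" else -1,
            }
        )
        tpm[eid] = vals
    events = pd.DataFrame(rows).set_index("event_id")
    tpm = pd.DataFrame(tpm).T.reindex(events.index)
    from ipa_atlas.atlas import Atlas

    return Atlas(events=events, counts=tpm.copy(), tpm=tpm, iqr=tpm * 0 + 10.0)


class TestUsage:
    def test_ipa_usage_over_all_events(self):
        atl = _usage_atlas(
            {
                "i1": ("IPA", {"s1": 5.0}, 150),
                "u1": ("UTR3", {"s1": 15.0}, 450),
            }
        )
        usage = compute_usage(atl)
        assert usage.loc["i1", "s1"] == pytest.approx(0.25)
        assert usage.loc["u1", "s1"] == pytest.approx(1.0)  # sole UTR3 event

    def test_single_isoform_gene_usage_one(self):
        atl = _usage_atlas({"u1": ("UTR3", {"s1": 8.0}, 450)})
        usage = compute_usage(atl)
        assert usage.loc["u1", "s1"] == 1.0

    def test_normalisation_sums(self):
        atl = _usage_atlas(
            {
                "i1": ("IPA", {"s1": 5.0}, 150),
                "u1": ("UTR3", {"s1": 10.0}, 430),
                "u2": ("UTR3", {"s1": 5.0}, 900),
            }
        )
        usage = compute_usage(atl)
        assert usage.loc[["i1", "u1", "u2"], "s1"].sum() > 1.0  # mixed denominators
        assert usage.loc[["u1", "u2"], "s1"].sum() == pytest.approx(1.0)
        total_ipa_denom = usage.loc["i1", "s1"]
        assert total_ipa_denom == pytest.approx(5.0 / 20.0)

    def test_zero_denominator_missing_not_zero(self):
        atl = _usage_atlas({"i1": ("IPA", {"s1": 0.0}, 150)})
        usage = compute_usage(atl)
        assert np.isnan(usage.loc["i1", "s1"])

    def test_usage_in_unit_interval(self, small_atlas):
        atl, _ = small_atlas
        u = atl.usage.to_numpy()
        u = u[~np.isnan(u)]
        assert (u >= 0).all() and (u <= 1).all()


class TestRobustnessFilters:
    def _atlas(self, tpm, usage, iqr, klass="IPA"):
        atl = _usage_atlas({"e": (klass, {"s1": tpm}, 150)})
        atl.usage = pd.DataFrame({"s1": {"e": usage}})
        atl.iqr = pd.DataFrame({"s1": {"e": iqr}})
        return atl

    def test_ipa_kept(self):
        atl = self._atlas(6.0, 0.2, 7.0)
        assert len(apply_robustness_filters(atl).events) == 1

    def test_ipa_zero_iqr_removed(self):
        atl = self._atlas(6.0, 0.2, 0.0)
        assert len(apply_robustness_filters(atl).events) == 0

    def test_utr_boundary_tpm(self):
        atl = self._atlas(2.9, 0.5, 10.0, klass="UTR3")
        assert len(apply_robustness_filters(atl).events) == 0
        atl = self._atlas(3.0, 0.5, 10.0, klass="UTR3")
        assert len(apply_robustness_filters(atl).events) == 1

    def test_same_sample_conjunction(self):
        # high TPM in s1, high usage only in s2 -> fails
        atl = _usage_atlas({"e": ("IPA", {"s1": 9.0, "s2": 1.0}, 150)})
        atl.usage = pd.DataFrame({"s1": {"e": 0.05}, "s2": {"e": 0.5}})
        atl.iqr = pd.DataFrame({"s1": {"e": 9.0}, "s2": {"e": 9.0}})
        assert len(apply_robustness_filters(atl).events) == 0


class TestExpressionCalls:
    def _atlas(self, ipa_tpms, fl_tpms):
        samples = [f"s{i}" for i in range(len(ipa_tpms))]
        atl = _usage_atlas(
            {
                "i1": ("IPA", dict(zip(samples, ipa_tpms)), 150),
                "u1": ("UTR3", dict(zip(samples, fl_tpms)), 450),
            }
        )
        compute_usage(atl)
        return atl, {s: "ct" for s in samples}

    def test_ipa_expressed_three_of_four(self):
        atl, cts = self._atlas([6, 6, 6, 1], [1, 1, 1, 1])
        calls, prev = expression_calls(atl, cts)
        assert calls["call"].iloc[0] == "IPA_EXPRESSED"
        assert prev["ct"] == 1.0

    def test_fl_only(self):
        atl, cts = self._atlas([6, 6, 1, 1], [8, 8, 8, 8])
        calls, _ = expression_calls(atl, cts)
        assert calls["call"].iloc[0] == "FL_ONLY"

    def test_two_of_three_fails_ceiling(self):
        atl, cts = self._atlas([6, 6, 1], [1, 1, 1])
        calls, _ = expression_calls(atl, cts)
        assert calls["call"].iloc[0] == "NOT_EXPRESSED"


class TestDistalUsage:
    def test_single_utr_gene(self):
        atl = _usage_atlas({"u1": ("UTR3", {"s1": 8.0}, 450)})
        d = distal_utr_usage(atl)
        assert d.loc["gX", "s1"] == 1.0

    def test_proximal_distal_split(self):
        atl = _usage_atlas(
            {"u1": ("UTR3", {"s1": 30.0}, 430), "u2": ("UTR3", {"s1": 10.0}, 900)}
        )
        d = distal_utr_usage(atl)
        assert d.loc["gX", "s1"] == pytest.approx(0.25)

    def test_sample_permutation_invariance(self):
        atl = _usage_atlas(
            {
                "u1": ("UTR3", {"s1": 30.0, "s2": 10.0}, 430),
                "u2": ("UTR3", {"s1": 10.0, "s2": 30.0}, 900),
            }
        )
        d = distal_utr_usage(atl)
        atl2 = _usage_atlas(
            {
                "u1": ("UTR3", {"s2": 10.0, "s1": 30.0}, 430),
                "u2": ("UTR3", {"s2": 30.0, "s1": 10.0}, 900),
            }
        )
        d2 = distal_utr_usage(atl2)
        assert d.loc["gX", "s1"] == d2.loc["gX", "s1"]
        assert np.median(d.loc["gX"]) == np.median(d2.loc["gX"])


class TestSyntheticRecovery:
    def test_planted_events_recovered_no_artifacts(self, small_sim, small_atlas):
        cfg, ann, genome, truth, peakset, raw = small_sim
        atl, _ = small_atlas
        ipa = atl.events[atl.events["klass"] == "IPA"]
        strong = [e for e in truth.ipa_events.values() if e.above_threshold]
        hits = sum(
            ((ipa["gene_id"] == e.gene_id) & (abs(ipa["rep_pos"] - e.pos) <= 5)).any()
            for e in strong
        )
        assert hits / len(strong) >= 0.95
        for a in truth.artifacts:
            overlap = (
                (atl.events["chrom"] == a.chrom)
                & (atl.events["start"] < a.end)
                & (atl.events["end"] > a.start)
                & (atl.events["strand"] == a.strand)
            )
            assert not overlap.any()
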