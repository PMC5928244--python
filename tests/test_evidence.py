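import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom

from ipa_atlas import evidence as ev
from ipa_atlas import simulate as sm
from ipa_atlas.atlas import build_atlas


def oracle_nb_conditional_p(up, down, alpha, midp=True):
    """Independent enumeration oracle for the conditional NB split test."""
    a_obs, total = int(sum(up)), int(sum(up) + sum(down))
    r = 2.0 / alpha
    mu = total / 2.0
    p = r / (r + mu)
    weights = [nbinom.pmf(a, r, p) * nbinom.pmf(total - a, r, p) for a in range(total + 1)]
    z = sum(weights)
    tail = sum(weights[a_obs:]) / z
    if midp:
        tail -= 0.5 * weights[a_obs] / z
    return tail


class TestNbExactTest:
    def test_strong_drop_significant(self):
        assert ev.nb_exact_test([200, 190], [5, 6]) < 0.01

    def test_exchangeable_null_large_p(self):
        # upstream sums 42 vs 40, so the one-sided p sits just under 0.5;
        # the enumeration oracle below pins the exact value
        p = ev.nb_exact_test([20, 22], [21, 19])
        assert p > 0.3
        assert ev.nb_exact_test([19, 20], [21, 22]) > 0.5

    @pytest.mark.parametrize(
        "up,down,alpha",
        [((200, 190), (5, 6), 0.02), ((20, 22), (21, 19), 0.05), ((12, 8), (5, 9), 0.3)],
    )
    def test_matches_enumeration_oracle(self, up, down, alpha):
        got = ev.nb_exact_test(up, down, alpha=alpha)
        want = oracle_nb_conditional_p(up, down, alpha)
        assert got == pytest.approx(want, rel=1e-9)

    def test_zero_total_returns_one(self):
        assert ev.nb_exact_test([0, 0], [0, 0]) == 1.0

    def test_one_sided_direction(self):
        assert ev.nb_exact_test([5, 6], [200, 190]) > 0.99


class TestWindows:
    def test_plus_strand_geometry(self):
        up1, up2, down1, down2 = ev.glm_windows(1000, "+")
        for s, e in (up1, up2, down1, down2):
            assert e - s == 100
        assert up2 == (900, 1000)
        assert up1 == (749, 849)  # 51 nt gap to up2
        assert down1 == (1001, 1101)
        assert down2 == (1152, 1252)

    def test_minus_strand_mirrors(self):
        wins_p = ev.glm_windows(1000, "+")
        wins_m = ev.glm_windows(1000, "-")
        # mirror through the cleavage base
        for (ps, pe), (ms, me) in zip(wins_p, wins_m):
            assert (ms, me) == (2 * 1000 - pe + 1, 2 * 1000 - ps + 1)

    def test_window_counts_off_chromosome_none(self):
        cov = np.ones(500)
        assert ev.window_counts(cov, ev.glm_windows(100, "+"), 50) is None

    def test_window_counts_scale_by_read_length(self):
        cov = np.full(3000, 50.0)
        counts = ev.window_counts(cov, ev.glm_windows(1000, "+"), 50)
        assert list(counts) == [100, 100, 100, 100]


@pytest.fixture(scope="module")
def sim_bundle():
    cfg = sm.SimConfig(n_genes=40, seed=5, intron_background=2.0)
    rng = np.random.default_rng(cfg.seed)
    ann, genome, truth = sm.simulate_annotation(cfg, rng)
    peakset, raw = sm.simulate_threeprime(ann, truth, cfg, rng)
    atl, lib = build_atlas(peakset, ann, genome, raw, truth.blacklist, truth.ig_intervals)
    rnaseq = sm.simulate_rnaseq(ann, genome, truth, cfg, rng, samples=["A1", "A2"])
    return cfg, ann, genome, truth, atl, rnaseq


class TestGlmEvidence:
    def test_planted_events_validated(self, sim_bundle):
        cfg, ann, genome, truth, atl, rnaseq = sim_bundle
        glm = ev.evidence_rnaseq_glm(atl, ann, rnaseq.coverage)
        tested = glm[glm["glm_testable"]]
        assert len(tested) > 0
        assert tested["glm_validated"].mean() >= 0.9

    def test_windows_overlapping_exons_untestable(self, sim_bundle):
        cfg, ann, genome, truth, atl, rnaseq = sim_bundle
        # an event right at an intron start would have upstream windows in the exon
        gid = atl.events["gene_id"].iloc[0]
        gene = ann.genes[gid]
        events = atl.events.copy()
        s, e = gene.introns[0]
        fake = events.iloc[[0]].copy()
        fake.index = ["fake:IPA:1"]
        fake["gene_id"] = gid
        fake["chrom"] = gene.chrom
        fake["strand"] = gene.strand
        fake["klass"] = "IPA"
        fake["rep_pos"] = s + 10 if gene.strand == "+" else e - 11
        atl2 = atl.subset(atl.events.index)
        atl2.events = pd.concat([events, fake])
        atl2.counts = pd.concat([atl.counts, atl.counts.iloc[[0]].set_axis(["fake:IPA:1"])])
        atl2.tpm = pd.concat([atl.tpm, atl.tpm.iloc[[0]].set_axis(["fake:IPA:1"])])
        atl2.iqr = pd.concat([atl.iqr, atl.iqr.iloc[[0]].set_axis(["fake:IPA:1"])])
        glm = ev.evidence_rnaseq_glm(atl2, ann, rnaseq.coverage)
        assert not glm.loc["fake:IPA:1", "glm_testable"]


class TestAnnotationEvidence:
    def _atlas_with_event(self, sim_bundle, rep_pos, gene_id=None):
        *_, atl, _ = sim_bundle
        ipa = atl.events[atl.events["klass"] == "IPA"]
        return ipa

    def test_event_near_last_exon_matched(self, sim_bundle):
        cfg, ann, genome, truth, atl, _ = sim_bundle
        # build a fake annotation whose last exon ends 50 nt before each event
        from ipa_atlas.annotation import GeneModel, GenomeAnnotation

        fake_genes = {}
        ipa = atl.events[atl.events["klass"] == "IPA"]
        for i, (eid, row) in enumerate(ipa.iterrows()):
            pos = int(row["rep_pos"])
            if row["strand"] == "+":
                exons = [(pos - 300, pos - 50)]
            else:
                exons = [(pos + 51, pos + 301)]
            fake_genes[f"fk{i}"] = GeneModel(
                gene_id=f"fk{i}",
                chrom=row["chrom"],
                strand=row["strand"],
                start=exons[0][0],
                end=exons[0][1],
                transcripts={f"fk{i}.t": exons},
                exons=exons,
                introns=[],
            )
        fake = GenomeAnnotation(genes=fake_genes)
        matched = ev.evidence_annotation(atl, [fake])
        assert matched == set(ipa.index)

    def test_event_150_beyond_unmatched(self, sim_bundle):
        cfg, ann, genome, truth, atl, _ = sim_bundle
        from ipa_atlas.annotation import GeneModel, GenomeAnnotation

        ipa = atl.events[atl.events["klass"] == "IPA"]
        row = ipa.iloc[0]
        pos = int(row["rep_pos"])
        exons = (
            [(pos - 400, pos - 150)] if row["strand"] == "+" else [(pos + 151, pos + 401)]
        )
        g = GeneModel(
            gene_id="fk",
            chrom=row["chrom"],
            strand=row["strand"],
            start=exons[0][0],
            end=exons[0][1],
            transcripts={"fk.t": exons},
            exons=exons,
            introns=[],
        )
        matched = ev.evidence_annotation(atl, [GenomeAnnotation(genes={"fk": g})])
        assert ipa.index[0] not in matched

    def test_internal_exon_overlap_unmatched(self, sim_bundle):
        cfg, ann, genome, truth, atl, _ = sim_bundle
        # real annotation: events are intronic, not in any last exon
        matched = ev.evidence_annotation(atl, [ann])
        assert matched == set()


class TestExternalEvidence:
    def test_inside_resized_window_matched(self, sim_bundle):
        cfg, ann, genome, truth, atl, _ = sim_bundle
        bed = sm.external_peaks_bed(truth)
        matched = ev.evidence_external_3p(atl, bed)
        ipa = atl.events[atl.events["klass"] == "IPA"]
        expected = set()
        for eid, row in ipa.iterrows():
            for e2 in truth.ipa_events.values():
                if (
                    e2.external_support
                    and e2.gene_id == row["gene_id"]
                    and abs(e2.pos - row["rep_pos"]) <= 5
                ):
                    expected.add(eid)
        assert matched == expected

    def test_opposite_strand_unmatched(self, sim_bundle):
        *_, atl, _ = sim_bundle
        row = atl.events[atl.events["klass"] == "IPA"].iloc[0]
        flipped = "-" if row["strand"] == "+" else "+"
        bed = pd.DataFrame(
            [
                {
                    "chrom": row["chrom"],
                    "start": int(row["rep_pos"]) - 5,
                    "end": int(row["rep_pos"]) + 5,
                    "name": "x",
                    "score": 0,
                    "strand": flipped,
                }
            ]
        )
        assert ev.evidence_external_3p(atl, bed) == set()

    def test_empty_set_no_matches(self, sim_bundle):
        *_, atl, _ = sim_bundle
        assert ev.evidence_external_3p(atl, None) == set()
        assert ev.evidence_external_3p(atl, pd.DataFrame()) == set()


class TestPolyaReads:
    def test_trim_at_four_a_run(self):
        assert ev.trim_polya("GATCAAAA") == "GATC"

    def test_three_a_not_trimmed(self):
        assert ev.trim_polya("GATCAAA") is None

    def test_trimmed_21nt_discarded(self):
        read = "G" * 21 + "AAAA"
        assert ev.trim_polya(read) == "G" * 21
        assert ev.align_trimmed_reads({"r": read}, {"c": "G" * 100}) == []

    def test_five_reads_plus_pas_validated(self, sim_bundle):
        cfg, ann, genome, truth, atl, rnaseq = sim_bundle
        table = ev.evidence_polya_reads(atl, rnaseq.polya_reads, genome)
        ipa = atl.events[atl.events["klass"] == "IPA"]
        for eid, row in ipa.iterrows():
            supported = any(
                t.polya_support
                and t.gene_id == row["gene_id"]
                and abs(t.pos - row["rep_pos"]) <= 5
                for t in truth.ipa_events.values()
            )
            assert bool(table.loc[eid, "polya_validated"]) == supported

    def test_duplicate_coordinates_collapse(self):
        genome = {"c": "ACGTACGTAA" * 20 + "CCCGGGTTTACGCATGCATCGGATCCGGAA" + "T" * 50}
        core = genome["c"][200:226]
        reads = {f"r{i}": core + "AAAAA" for i in range(6)}  # identical -> 1 alignment
        aligned = ev.align_trimmed_reads(reads, genome)
        assert len(aligned) == 1


class TestHighExpression:
    def _atl(self, sim_bundle, tpm, usage):
        *_, atl, _ = sim_bundle
        atl = atl.subset(atl.events.index)
        ipa_ids = atl.events.index[atl.events["klass"] == "IPA"]
        atl.tpm.loc[:, :] = tpm
        atl.usage = atl.tpm * 0 + usage
        return atl, ipa_ids

    def test_high_expression_with_pas(self, sim_bundle):
        cfg, ann, genome, truth, *_ = sim_bundle
        atl, ipa_ids = self._atl(sim_bundle, 12.0, 0.15)
        got = ev.evidence_high_expression(atl, genome)
        assert got == set(ipa_ids)  # planted events all carry an upstream PAS

    def test_below_tpm_boundary_rejected(self, sim_bundle):
        cfg, ann, genome, truth, *_ = sim_bundle
        atl, _ = self._atl(sim_bundle, 9.9, 0.15)
        assert ev.evidence_high_expression(atl, genome) == set()

    def test_no_pas_rejected(self, sim_bundle):
        cfg, ann, genome, truth, *_ = sim_bundle
        atl, ipa_ids = self._atl(sim_bundle, 12.0, 0.15)
        blank = {c: "C" * len(s) for c, s in genome.items()}
        assert ev.evidence_high_expression(atl, blank) == set()


class TestTierAssembly:
    def _table(self, atl, eid, **sources):
        annotated = {eid} if sources.get("annotated") else set()
        glm = pd.DataFrame(
            {
                "glm_p": [0.001],
                "glm_fdr": [0.005],
                "glm_testable": [True],
                "glm_validated": [sources.get("glm", False)],
            },
            index=[eid],
        )
        external = {eid} if sources.get("external") else set()
        polya = pd.DataFrame(
            {
                "polya_reads": [9 if sources.get("polya") else 0],
                "pas": [True],
                "polya_validated": [bool(sources.get("polya"))],
            },
            index=[eid],
        )
        high = {eid} if sources.get("high") else set()
        return ev.build_evidence_table(atl, annotated, glm, external, polya, high)

    def test_precedence_annotation_over_glm(self, sim_bundle):
        *_, atl, _ = sim_bundle
        eid = atl.events.index[atl.events["klass"] == "IPA"][0]
        t = self._table(atl, eid, annotated=True, glm=True)
        assert t.loc[eid, "tier"] == "ANNOTATED"

    def test_polya_only(self, sim_bundle):
        *_, atl, _ = sim_bundle
        eid = atl.events.index[atl.events["klass"] == "IPA"][0]
        t = self._table(atl, eid, polya=True)
        assert t.loc[eid, "tier"] == "POLYA_READS"

    def test_unvalidated_dropped(self, sim_bundle):
        *_, atl, _ = sim_bundle
        eid = atl.events.index[atl.events["klass"] == "IPA"][0]
        t = self._table(atl, eid)
        assert t.loc[eid, "tier"] == "UNVALIDATED"
        conf = ev.build_confident_atlas(atl, t)
        assert eid not in conf.events.index

    def test_tier_total_function(self, sim_bundle):
        cfg, ann, genome, truth, atl, rnaseq = sim_bundle
        glm = ev.evidence_rnaseq_glm(atl, ann, rnaseq.coverage)
        polya = ev.evidence_polya_reads(atl, rnaseq.polya_reads, genome)
        high = ev.evidence_high_expression(atl, genome)
        table = ev.build_evidence_table(
            atl, set(), glm, ev.evidence_external_3p(atl, sm.external_peaks_bed(truth)), polya, high
        )
        n_ipa = (atl.events["klass"] == "IPA").sum()
        assert len(table) == n_ipa
        assert table["tier"].notna().all()
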