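import numpy as np
import pandas as pd
import pytest

from cageatlas import atlas as catlas
from cageatlas import enhancers as cenh
from cageatlas import io as cio
from cageatlas.atlas import Atlas


def toy_atlas(entries, samples=("s1", "s2", "s3")):
    """entries: list of (cluster_id, chrom, summit, strand, counts_per_sample)."""
    rows, counts = [], []
    for cid, chrom, summit, strand, cvec in entries:
        rows.append(
            {"cluster_id": cid, "chrom": chrom, "start": summit, "end": summit + 1,
             "strand": strand, "summit": summit, "annotation_class": "intergenic",
             "gene_id": None, "distance_to_5p": None}
        )
        counts.append(cvec)
    clusters = pd.DataFrame(rows).set_index("cluster_id")
    counts = pd.DataFrame(counts, index=clusters.index, columns=list(samples))
    at = Atlas(clusters=clusters, counts=counts)
    return catlas.normalize_tpm(at, {s: 1_000_000 for s in samples})


def empty_models():
    tx = pd.DataFrame(
        [{"transcript_id": "far", "gene_id": "far", "chrom": "chrZ",
          "start": 0, "end": 100, "strand": "+", "tss5p": 0}]
    )
    return cio.GeneModels(transcripts=tx)


class TestCallEnhancers:
    def test_balanced_pair_called(self):
        at = toy_atlas(
            [("r", "c", 1000, "-", [10, 10, 10]), ("f", "c", 1180, "+", [10, 10, 10])]
        )
        calls = cenh.call_enhancers(at, empty_models())
        assert len(calls) == 1
        assert calls[0].directionality == pytest.approx(0.0)
        assert calls[0].rev_cluster == "r" and calls[0].fwd_cluster == "f"

    def test_one_sided_rejected(self):
        at = toy_atlas(
            [("r", "c", 1000, "-", [0, 0, 0]), ("f", "c", 1180, "+", [10, 10, 10])]
        )
        assert cenh.call_enhancers(at, empty_models()) == []

    def test_boundary_d_inclusive(self):
        # F=90, R=10 -> D = 0.8 kept at the inclusive bound
        at = toy_atlas(
            [("r", "c", 1000, "-", [10, 0, 0]), ("f", "c", 1180, "+", [90, 0, 0])]
        )
        calls = cenh.call_enhancers(at, empty_models())
        assert len(calls) == 1
        assert calls[0].directionality == pytest.approx(0.8)
        # F=91 tips over the bound
        at2 = toy_atlas(
            [("r", "c", 1000, "-", [9, 0, 0]), ("f", "c", 1180, "+", [91, 0, 0])]
        )
        assert cenh.call_enhancers(at2, empty_models()) == []

    def test_pair_window_gate(self):
        at = toy_atlas(
            [("r", "c", 1000, "-", [10, 10, 10]), ("f", "c", 1500, "+", [10, 10, 10])]
        )
        assert cenh.call_enhancers(at, empty_models(), pair_window=400) == []
        assert len(cenh.call_enhancers(at, empty_models(), pair_window=500)) == 1

    def test_wrong_orientation_rejected(self):
        # convergent (fwd left of rev) must not be called
        at = toy_atlas(
            [("f", "c", 1000, "+", [10, 10, 10]), ("r", "c", 1180, "-", [10, 10, 10])]
        )
        assert cenh.call_enhancers(at, empty_models()) == []

    def test_genic_gate(self):
        tx = pd.DataFrame(
            [{"transcript_id": "g_t", "gene_id": "g", "chrom": "c",
              "start": 900, "end": 5000, "strand": "+", "tss5p": 900}]
        )
        models = cio.GeneModels(transcripts=tx)
        at = toy_atlas(
            [("r", "c", 1000, "-", [10, 10, 10]), ("f", "c", 1180, "+", [10, 10, 10])]
        )
        assert cenh.call_enhancers(at, models) == []

    def test_promoter_window_gate(self):
        tx = pd.DataFrame(
            [{"transcript_id": "g_t", "gene_id": "g", "chrom": "c",
              "start": 1600, "end": 5000, "strand": "+", "tss5p": 1600}]
        )
        models = cio.GeneModels(transcripts=tx)  # 5' end 420 bp right of fwd summit
        at = toy_atlas(
            [("r", "c", 1000, "-", [10, 10, 10]), ("f", "c", 1180, "+", [10, 10, 10])]
        )
        assert cenh.call_enhancers(at, models) == []

    def test_min_tpm_gate(self):
        at = toy_atlas(
            [("r", "c", 1000, "-", [0.4, 0, 0]), ("f", "c", 1180, "+", [0.4, 0, 0])]
        )
        assert cenh.call_enhancers(at, empty_models(), min_tpm=2.0) == []

    def test_overlap_resolution_keeps_highest_expression(self):
        at = toy_atlas(
            [
                ("r", "c", 1000, "-", [100, 100, 100]),
                ("f1", "c", 1180, "+", [100, 100, 100]),
                ("f2", "c", 1300, "+", [5, 5, 5]),
            ]
        )
        calls = cenh.call_enhancers(at, empty_models())
        assert len(calls) == 1
        assert calls[0].fwd_cluster == "f1"

    def test_sample_order_invariance(self):
        entries = [
            ("r", "c", 1000, "-", [10, 20, 30]),
            ("f", "c", 1180, "+", [12, 18, 30]),
        ]
        a = cenh.call_enhancers(toy_atlas(entries, ("s1", "s2", "s3")), empty_models())
        shuffled = [(cid, ch, s, st, cv[::-1]) for cid, ch, s, st, cv in entries]
        b = cenh.call_enhancers(toy_atlas(shuffled, ("s3", "s2", "s1")), empty_models())
        assert a[0].directionality == pytest.approx(b[0].directionality)
        assert a[0].region == b[0].region

    def test_d_antisymmetric_under_strand_swap(self):
        at = toy_atlas(
            [("r", "c", 1000, "-", [30, 0, 0]), ("f", "c", 1180, "+", [70, 0, 0])]
        )
        swapped = toy_atlas(
            [("r", "c", 1000, "-", [70, 0, 0]), ("f", "c", 1180, "+", [30, 0, 0])]
        )
        d1 = cenh.call_enhancers(at, empty_models())[0].directionality
        d2 = cenh.call_enhancers(swapped, empty_models())[0].directionality
        assert d1 == pytest.approx(-d2)


class TestRestriction:
    def sheet(self):
        return pd.DataFrame(
            {
                "sample_id": ["m1", "m2", "n1", "n2"],
                "cell_type": ["mast", "mast", "neut", "neut"],
                "replicate": [1, 2, 1, 2],
                "stage_order": [1, 1, 2, 2],
            }
        )

    def test_restricted(self):
        tpm = pd.Series({"m1": 20.0, "m2": 20.0, "n1": 0.0, "n2": 0.0})
        assert cenh.restriction_call(tpm, self.sheet()) == "mast"

    def test_two_types_on_gives_none(self):
        tpm = pd.Series({"m1": 20.0, "m2": 20.0, "n1": 20.0, "n2": 20.0})
        assert cenh.restriction_call(tpm, self.sheet()) is None

    def test_off_leak_blocks_call(self):
        tpm = pd.Series({"m1": 20.0, "m2": 20.0, "n1": 2.0, "n2": 2.0})
        assert cenh.restriction_call(tpm, self.sheet()) is None


class TestLinkGenes:
    def make_linked_atlas(self):
        samples = [f"s{i}" for i in range(6)]
        profile = [100, 5, 80, 10, 60, 30]
        rows = [
            {"cluster_id": "prom_near", "chrom": "c", "start": 50_000, "end": 50_001,
             "strand": "+", "summit": 50_000, "annotation_class": "promoter",
             "gene_id": "NEAR", "distance_to_5p": 0},
            {"cluster_id": "prom_far", "chrom": "c", "start": 700_000, "end": 700_001,
             "strand": "+", "summit": 700_000, "annotation_class": "promoter",
             "gene_id": "FAR", "distance_to_5p": 0},
            {"cluster_id": "prom_other", "chrom": "c", "start": 60_000, "end": 60_001,
             "strand": "+", "summit": 60_000, "annotation_class": "promoter",
             "gene_id": "OTHER", "distance_to_5p": 0},
        ]
        clusters = pd.DataFrame(rows).set_index("cluster_id")
        counts = pd.DataFrame(
            [profile, profile, [7, 7, 7, 7, 7, 7]],
            index=clusters.index, columns=samples,
        )
        at = catlas.normalize_tpm(
            Atlas(clusters=clusters, counts=counts), {s: 1_000_000 for s in samples}
        )
        call = cenh.EnhancerCall(
            region=cio.GenomicInterval("c", 99_000, 99_400),
            center=99_200, fwd_cluster="x", rev_cluster="y",
            directionality=0.0,
            per_sample_tpm=pd.Series(profile, index=samples, dtype=float),
        )
        return at, call

    def test_identical_profile_linked_r1(self):
        at, call = self.make_linked_atlas()
        links = cenh.link_genes(call, at)
        assert links[0][0] == "NEAR"
        assert links[0][1] == pytest.approx(1.0)

    def test_distance_gate(self):
        at, call = self.make_linked_atlas()
        genes = [g for g, _ in cenh.link_genes(call, at, max_dist=500_000)]
        assert "FAR" not in genes

    def test_zero_variance_profile_skipped(self):
        at, call = self.make_linked_atlas()
        genes = [g for g, _ in cenh.link_genes(call, at, min_r=-1.0)]
        assert "OTHER" not in genes  # flat profile has no defined correlation


@pytest.fixture(scope="module")
def calls_and_match(sim_default, atlas_default):
    calls = cenh.call_enhancers(
        atlas_default["filtered"], sim_default["annotation"].models
    )
    cenh.annotate_calls(calls, atlas_default["filtered"], sim_default["sheet"])
    truth = sim_default["truth"]
    matched = {}
    for call in calls:
        for e in truth.enhancer_loci:
            if e["chrom"] == call.region.chrom and abs(e["center"] - call.center) <= 250:
                matched[e["enh_id"]] = call
                break
    return calls, matched


class TestPlantedRecovery:
    def test_precision_and_recall(self, sim_default, calls_and_match):
        truth = sim_default["truth"]
        calls, matched = calls_and_match
        tp = len(matched)
        assert tp / max(len(calls), 1) >= 0.9  # precision
        assert tp / len(truth.enhancer_loci) >= 0.9  # recall

    def test_no_call_overlaps_gene_or_promoter(self, sim_default, calls_and_match):
        models = sim_default["annotation"].models
        calls, _ = calls_and_match
        for call in calls:
            g = models.genes[models.genes["chrom"] == call.region.chrom]
            assert not ((g["start"] < call.region.end) & (call.region.start < g["end"])).any()
            t = models.transcripts[models.transcripts["chrom"] == call.region.chrom]
            assert not (
                (t["tss5p"] - 500 < call.region.end)
                & (call.region.start < t["tss5p"] + 501)
            ).any()

    def test_restriction_recall(self, sim_default, calls_and_match):
        truth = sim_default["truth"]
        _, matched = calls_and_match
        restricted = [e for e in truth.enhancer_loci if e["target_gene"] is None]
        ok = sum(
            1
            for e in restricted
            if e["enh_id"] in matched
            and matched[e["enh_id"]].restricted_to == e["active_cell_types"][0]
        )
        assert ok / len(restricted) >= 0.9

    def test_link_top1_matches_truth(self, sim_default, calls_and_match):
        truth = sim_default["truth"]
        _, matched = calls_and_match
        paired = [e for e in truth.enhancer_loci if e["target_gene"]]
        ok = sum(
            1
            for e in paired
            if e["enh_id"] in matched
            and matched[e["enh_id"]].linked_genes
            and matched[e["enh_id"]].linked_genes[0][0] == e["target_gene"]
        )
        assert ok / len(paired) >= 0.9
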