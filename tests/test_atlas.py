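import numpy as np
import pandas as pd
import pytest

from cageatlas import atlas as catlas
from cageatlas import io as cio


def track(sample_id, rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    df = df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    return cio.CtssTrack(sample_id=sample_id, data=df)


class TestClusterTags:
    def test_gap_arithmetic(self):
        t = track("s", [("chr1", 100, "+", 1), ("chr1", 105, "+", 2), ("chr1", 140, "+", 3)])
        at = catlas.cluster_tags([t], max_gap=20)
        spans = sorted(zip(at.clusters["start"], at.clusters["end"]))
        assert spans == [(100, 106), (140, 141)]

    def test_strand_separation(self):
        t = track("s", [("chr1", 100, "+", 1), ("chr1", 100, "-", 1)])
        assert len(catlas.cluster_tags([t], max_gap=20)) == 2

    def test_zero_gap_equals_distinct_positions(self):
        rng = np.random.default_rng(11)
        rows = [
            (f"chr{rng.integers(1, 3)}", int(rng.integers(0, 5000)),
             "+" if rng.random() < 0.5 else "-", int(rng.integers(1, 9)))
            for _ in range(10_000)
        ]
        dedup = {}
        for c, p, s, n in rows:
            dedup[(c, p, s)] = dedup.get((c, p, s), 0) + n
        t = track("s", [(c, p, s, n) for (c, p, s), n in dedup.items()])
        at = catlas.cluster_tags([t], max_gap=0)
        assert len(at) == len(dedup)

    def test_empty_input(self):
        at = catlas.cluster_tags([], max_gap=20)
        assert len(at) == 0

    def test_partition_property(self, sim_default, atlas_default):
        # every input tag position falls inside exactly one cluster
        raw = atlas_default["raw"]
        c = raw.clusters
        for tr in sim_default["tracks"][:3]:
            for row in tr.data.itertuples():
                hits = c[(c["chrom"] == row.chrom) & (c["strand"] == row.strand)
                         & (c["start"] <= row.pos) & (row.pos < c["end"])]
                assert len(hits) == 1

    def test_counts_conserved(self, sim_default, atlas_default):
        raw = atlas_default["raw"]
        for tr in sim_default["tracks"]:
            assert raw.counts[tr.sample_id].sum() == tr.total

    def test_summit_in_interval(self, atlas_default):
        c = atlas_default["raw"].clusters
        assert ((c["summit"] >= c["start"]) & (c["summit"] < c["end"])).all()

    def test_reclustering_summits_idempotent(self, atlas_default):
        raw = atlas_default["raw"]
        t = track(
            "summits",
            list(
                zip(
                    raw.clusters["chrom"],
                    raw.clusters["summit"],
                    raw.clusters["strand"],
                    np.ones(len(raw), dtype=int),
                )
            ),
        )
        again = catlas.cluster_tags([t], max_gap=20)
        assert len(again) >= len(raw)


class TestNormalizeFilter:
    def test_tpm_arithmetic(self):
        t = track("s", [("chr1", 10, "+", 10)])
        at = catlas.normalize_tpm(catlas.cluster_tags([t], 0), {"s": 2_000_000})
        assert at.tpm.iloc[0, 0] == pytest.approx(5.0)

    def test_all_tags_in_one_cluster(self):
        t = track("s", [("chr1", 10, "+", 7), ("chr1", 11, "+", 3)])
        at = catlas.normalize_tpm(catlas.cluster_tags([t], 5), {"s": 10})
        assert at.tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_tpm_columns_conserve_1e6(self, atlas_default):
        # library sizes equal full-track totals and no tag is outside a cluster
        sums = atlas_default["raw"].tpm.sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-9)

    def test_zero_library_size_errors(self):
        t = track("s", [("chr1", 10, "+", 1)])
        with pytest.raises(ValueError):
            catlas.normalize_tpm(catlas.cluster_tags([t], 0), {"s": 0})

    def test_filter_boundary_inclusive(self):
        t1 = track("a", [("chr1", 10, "+", 499), ("chr1", 500, "+", 500)])
        at = catlas.cluster_tags([t1], 0)
        at = catlas.normalize_tpm(at, {"a": 100_000_000})
        # 499 tags -> 4.99 TPM dropped; 500 tags -> 5.0 TPM kept
        kept = catlas.filter_expressed(at, min_tpm=5.0)
        assert len(kept) == 1
        assert kept.clusters["start"].iloc[0] == 500

    def test_min_tpm_zero_is_identity(self, atlas_default):
        raw = atlas_default["raw"]
        assert len(catlas.filter_expressed(raw, 0.0)) == len(raw)

    def test_filter_requires_tpm(self):
        t = track("s", [("chr1", 10, "+", 1)])
        with pytest.raises(ValueError, match="TPM"):
            catlas.filter_expressed(catlas.cluster_tags([t], 0))

    def test_planted_active_tss_survive_filter(self, sim_default, atlas_default, truth_match):
        truth = sim_default["truth"]
        for tss_id in truth.module_membership:
            assert truth_match[tss_id] is not None, tss_id


def annotate_single(models, chrom, pos, strand):
    t = track("s", [(chrom, pos, strand, 10)])
    at = catlas.normalize_tpm(catlas.cluster_tags([t], 0), {"s": 1000})
    return catlas.annotate_tss(at, models).clusters.iloc[0]


class TestAnnotate:
    def test_promoter_within_500(self, tiny_models):
        row = annotate_single(tiny_models, "chr1", 10_000 - 400, "+")
        assert row["annotation_class"] == "promoter"
        assert row["gene_id"] == "A"
        assert row["distance_to_5p"] == -400

    def test_intragenic_beyond_500(self, tiny_models):
        row = annotate_single(tiny_models, "chr1", 10_600, "+")
        assert row["annotation_class"] == "intragenic"
        assert row["gene_id"] == "A"

    def test_intergenic(self, tiny_models):
        row = annotate_single(tiny_models, "chr1", 20_000, "+")
        assert row["annotation_class"] == "intergenic"
        assert row["gene_id"] is None

    def test_antisense_near_5p_is_not_promoter(self, tiny_models):
        # strand-aware: a minus-strand summit near gene A's plus-strand 5' end
        row = annotate_single(tiny_models, "chr1", 10_000, "-")
        assert row["annotation_class"] == "intergenic"

    def test_minus_strand_promoter(self, tiny_models):
        row = annotate_single(tiny_models, "chr1", 35_999 - 300, "-")
        assert row["annotation_class"] == "promoter"
        assert row["gene_id"] == "B"
        assert row["distance_to_5p"] == 300  # downstream of the - strand 5' end

    def test_tie_break_lexicographic(self):
        tx = pd.DataFrame(
            [
                {"transcript_id": "B_t", "gene_id": "B", "chrom": "chr1",
                 "start": 1000, "end": 2000, "strand": "+", "tss5p": 1000},
                {"transcript_id": "A_t", "gene_id": "A", "chrom": "chr1",
                 "start": 1600, "end": 2600, "strand": "+", "tss5p": 1600},
            ]
        )
        models = cio.GeneModels(transcripts=tx)
        row = annotate_single(models, "chr1", 1300, "+")  # 300 bp from both
        assert row["annotation_class"] == "promoter"
        assert row["gene_id"] == "A"

    def test_every_cluster_exactly_one_class(self, atlas_default):
        classes = atlas_default["filtered"].clusters["annotation_class"]
        assert classes.isin(["promoter", "intragenic", "intergenic"]).all()
        assert not classes.isna().any()

    def test_promoter_class_iff_gene_and_distance(self, atlas_default):
        c = atlas_default["filtered"].clusters
        prom = c[c["annotation_class"] == "promoter"]
        assert prom["gene_id"].notna().all()
        assert (prom["distance_to_5p"].abs() <= 500).all()


class TestRecoveryAndSamples:
    def test_planted_summit_recovery(self, sim_default, atlas_default):
        # >= 95% of planted TSSs map to a cluster whose summit is within 20 bp
        truth = sim_default["truth"]
        filt = atlas_default["filtered"]
        summits = dict(zip(filt.clusters.index, filt.clusters["summit"]))
        match = catlas.match_positions(filt, truth.tss_catalog)
        good = 0
        planted = [t for t in truth.tss_catalog if not t.startswith("B")]
        for tss_id in planted:
            cid = match[tss_id]
            if cid is None:
                continue
            if abs(summits[cid] - truth.tss_catalog[tss_id][1]) <= 20:
                good += 1
        assert good / len(planted) >= 0.95

    def test_per_sample_expressed_ratios(self):
        tx = pd.DataFrame(
            [
                {"transcript_id": "A1", "gene_id": "A", "chrom": "c",
                 "start": 1000, "end": 3000, "strand": "+", "tss5p": 1000},
                {"transcript_id": "A2", "gene_id": "A", "chrom": "c",
                 "start": 1800, "end": 3000, "strand": "+", "tss5p": 1800},
                {"transcript_id": "B1", "gene_id": "B", "chrom": "c",
                 "start": 10_000, "end": 12_000, "strand": "+", "tss5p": 10_000},
            ]
        )
        models = cio.GeneModels(transcripts=tx)
        t = track("s", [("c", 1000, "+", 10), ("c", 1800, "+", 10), ("c", 10_000, "+", 10)])
        at = catlas.annotate_tss(
            catlas.normalize_tpm(catlas.cluster_tags([t], 0), {"s": 30}), models
        )
        res = catlas.per_sample_expressed(at, min_tpm=5.0)
        assert res.loc["s", "n_tss"] == 3
        assert res.loc["s", "n_genes"] == 2
        assert res.loc["s", "ratio"] == pytest.approx(1.5)

    def test_ratio_one_when_all_distinct(self, tiny_models):
        t = track("s", [("chr1", 10_000, "+", 10), ("chr1", 35_999, "-", 10)])
        at = catlas.annotate_tss(
            catlas.normalize_tpm(catlas.cluster_tags([t], 0), {"s": 20}), tiny_models
        )
        res = catlas.per_sample_expressed(at, min_tpm=5.0)
        assert res.loc["s", "ratio"] == pytest.approx(1.0)

    def test_per_sample_ratio_below_atlas_ratio(self, atlas_default):
        # alternate promoters are cell-type partitioned in the simulator
        filt = atlas_default["filtered"]
        res = catlas.per_sample_expressed(filt, min_tpm=5.0)
        gene_assigned = filt.clusters["annotation_class"].isin(["promoter", "intragenic"])
        atlas_ratio = gene_assigned.sum() / filt.clusters.loc[gene_assigned, "gene_id"].nunique()
        assert (res["ratio"] < atlas_ratio).all()

    def test_zero_expressed_gives_none_ratio(self, tiny_models):
        t = track("s", [("chr1", 20_000, "+", 10)])  # intergenic only
        at = catlas.annotate_tss(
            catlas.normalize_tpm(catlas.cluster_tags([t], 0), {"s": 10}), tiny_models
        )
        res = catlas.per_sample_expressed(at, min_tpm=5.0)
        assert res.loc["s", "ratio"] is None


class TestOverlapNoncoding:
    def make_atlas(self, tiny_models):
        t = track(
            "s",
            [("chr1", 20_000, "+", 10), ("chr1", 10_000, "+", 10), ("chr1", 50_000, "-", 10)],
        )
        at = catlas.normalize_tpm(catlas.cluster_tags([t], 0), {"s": 30})
        return catlas.annotate_tss(at, tiny_models)

    def test_intergenic_overlap_reported(self, tiny_models):
        at = self.make_atlas(tiny_models)
        bed = pd.DataFrame(
            [("chr1", 19_500, 20_500, "linc1", "0", "+")], columns=cio.BED6_COLUMNS
        )
        hit = catlas.overlap_noncoding(at, bed)
        assert len(hit) == 1
        assert hit.clusters["start"].iloc[0] == 20_000

    def test_promoter_class_excluded(self, tiny_models):
        at = self.make_atlas(tiny_models)
        bed = pd.DataFrame(
            [("chr1", 9_000, 11_000, "linc1", "0", "+")], columns=cio.BED6_COLUMNS
        )
        assert len(catlas.overlap_noncoding(at, bed)) == 0

    def test_empty_bed(self, tiny_models):
        at = self.make_atlas(tiny_models)
        assert len(catlas.overlap_noncoding(at, pd.DataFrame(columns=cio.BED6_COLUMNS))) == 0

    def test_strand_agnostic(self, tiny_models):
        at = self.make_atlas(tiny_models)
        bed = pd.DataFrame(
            [("chr1", 49_000, 51_000, "linc1", "0", "+")], columns=cio.BED6_COLUMNS
        )
        assert len(catlas.overlap_noncoding(at, bed)) == 1


class TestSerialisation:
    def test_atlas_round_trip(self, atlas_default, tmp_path):
        filt = atlas_default["filtered"]
        p = tmp_path / "atlas.tsv"
        catlas.write_atlas(filt, p)
        back = catlas.read_atlas(p)
        assert list(back.clusters.index) == list(filt.clusters.index)
        pd.testing.assert_frame_equal(
            back.counts, filt.counts, check_dtype=False
        )
        np.testing.assert_allclose(back.tpm.values, filt.tpm.values, rtol=1e-12)
        assert back.clusters["annotation_class"].equals(filt.clusters["annotation_class"])
        assert list(back.library_sizes) == list(filt.library_sizes)
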