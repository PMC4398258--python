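import pandas as pd
import pytest

from cageatlas import atlas as catlas
from cageatlas import io as cio
from cageatlas.simulate import SimConfig, generate_annotation, generate_ctss


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig()  # 5 cell types x 3 replicates, 200 genes, 8 modules, seed 42


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_chromosomes=2,
        chrom_length=200_000,
        n_genes=30,
        n_cell_types=3,
        replicates_per_type=2,
        n_modules=3,
        n_enhancers=6,
        n_background_tss=20,
        library_size_range=(500_000, 1_000_000),
        seed=7,
    )


@pytest.fixture(scope="session")
def sim_default(default_config):
    annotation = generate_annotation(default_config)
    tracks, sheet, truth = generate_ctss(default_config, annotation)
    return {
        "config": default_config,
        "annotation": annotation,
        "tracks": tracks,
        "sheet": sheet,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def atlas_default(sim_default):
    tracks = sim_default["tracks"]
    raw = catlas.cluster_tags(tracks, max_gap=20)
    raw = catlas.normalize_tpm(raw, {t.sample_id: t.total for t in tracks})
    annotated = catlas.annotate_tss(
        catlas.filter_expressed(raw, 5.0), sim_default["annotation"].models
    )
    return {"raw": raw, "filtered": annotated}


@pytest.fixture(scope="session")
def truth_match(sim_default, atlas_default):
    """Truth TSS id -> filtered atlas cluster id (or None)."""
    return catlas.match_positions(
        atlas_default["filtered"], sim_default["truth"].tss_catalog
    )


@pytest.fixture
def tiny_models() -> cio.GeneModels:
    """Two genes on opposite strands for annotation edge cases."""
    tx = pd.DataFrame(
        [
            {"transcript_id": "A_t1", "gene_id": "A", "chrom": "chr1",
             "start": 10_000, "end": 15_000, "strand": "+", "tss5p": 10_000},
            {"transcript_id": "B_t1", "gene_id": "B", "chrom": "chr1",
             "start": 30_000, "end": 36_000, "strand": "-", "tss5p": 35_999},
        ]
    )
    return cio.GeneModels(transcripts=tx)
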