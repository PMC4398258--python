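"""Synthetic CAGE data generator with planted, recoverable structure.

Generates a toy genome annotation plus per-sample stranded CTSS tracks that
stand in for a multi-library 5'-tag experiment: cell-type-specific promoter
modules, alternate promoters of shared genes, balanced bidirectional
transcription at intergenic loci, planted sequence motifs near module TSSs,
library-size variation and negative-binomial tag counts.  Everything planted
is reported in :class:`TruthTables` so downstream recovery can be scored
without touching generator internals.

Count model: negative binomial with mean ``tpm * library_size / 1e6`` and
variance ``mu + dispersion * mu**2`` (Poisson when dispersion is 0).  Each
planted TSS spreads its tags over a 1-20 bp window with geometric decay from
the summit so that tag clustering downstream is non-trivial.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as cio

# geometry constants of the generator (not biology, just plumbing)
_GAP_MIN, _GAP_MAX = 2000, 6000  # intergenic gap, bp
_GENE_MIN, _GENE_MAX = 2500, 8000  # gene body length, bp
_ALT_MIN, _ALT_MAX = 600, 1200  # alternate-promoter offset into the body, bp
_EDGE_MARGIN = 1000  # clearance at chromosome ends, bp
_ENH_HALF_SEP = 90  # divergent summits sit 180 bp apart
_SPREAD_DECAY = 0.55  # geometric tag spread around the summit
_ALT_TPM_SCALE = 0.5  # alternate promoters fire at half the module level
_ENH_TPM = 25.0  # emission level of cell-type-restricted enhancers
_NOISE_TPM_RANGE = (0.1, 1.5)
_TARGET_LOG_SD = 1.2  # lognormal sd of enhancer/target activity per cell type

DEFAULT_MOTIFS = (
    ("M1", "TGACTCAGCA"),
    ("M2", "CACGTGACTT"),
    ("M3", "GGGATTTCCC"),
    ("M4", "TTTCACGCGA"),
    ("M5", "AGATAAGGCA"),
    ("M6", "ACTTCCGGTT"),
    ("M7", "CCAATCAGCG"),
    ("M8", "GTCACGCAAT"),
)


class SimSizingError(ValueError):
    """The configured genome is too small for the requested gene count."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic CAGE experiment.

    Identical configs (including ``seed``) produce byte-identical output
    files; all randomness flows through ``numpy.random.default_rng`` streams
    derived from the seed.
    """

    n_chromosomes: int = 4
    chrom_length: int = 1_000_000
    n_genes: int = 200
    n_cell_types: int = 5
    replicates_per_type: int = 3
    n_modules: int = 8
    alt_promoter_fraction: float = 0.25
    n_enhancers: int = 30
    enhancer_paired_fraction: float = 0.5
    enhancer_balance: float = 0.0
    motif_library: tuple[tuple[str, str], ...] = DEFAULT_MOTIFS
    planted_motif_rate: float = 0.8
    library_size_range: tuple[int, int] = (2_000_000, 4_000_000)
    dispersion: float = 0.05
    baseline_tpm: float = 0.5
    active_tpm: float = 50.0
    noise_tss_rate: float = 2e-5
    n_background_tss: int = 300
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes",
            "chrom_length",
            "n_genes",
            "n_cell_types",
            "replicates_per_type",
            "n_modules",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("alt_promoter_fraction", "enhancer_paired_fraction", "planted_motif_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.enhancer_balance <= 1.0:
            raise ValueError("enhancer_balance must be in [0, 1]")
        lo, hi = self.library_size_range
        if lo <= 0 or lo > hi:
            raise ValueError("library_size_range must satisfy 0 < min <= max")
        if self.n_enhancers < 0 or self.n_background_tss < 0:
            raise ValueError("counts must be non-negative")
        if self.dispersion < 0 or self.noise_tss_rate < 0:
            raise ValueError("dispersion and noise_tss_rate must be >= 0")
        if min(t for t in (self.baseline_tpm, self.active_tpm)) < 0:
            raise ValueError("expression levels must be >= 0")
        if self.n_modules > self.n_cell_types * (self.n_cell_types - 1) and self.n_cell_types > 1:
            raise ValueError(
                "n_modules exceeds the number of distinct cell-type activity patterns"
            )

    @property
    def n_samples(self) -> int:
        return self.n_cell_types * self.replicates_per_type

    @property
    def cell_types(self) -> list[str]:
        return [f"CT{i + 1}" for i in range(self.n_cell_types)]

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "motif_library" in raw:
            raw["motif_library"] = tuple(tuple(m) for m in raw["motif_library"])
        if "library_size_range" in raw:
            raw["library_size_range"] = tuple(raw["library_size_range"])
        return cls(**raw)


def module_patterns(config: SimConfig) -> list[frozenset[int]]:
    """Distinct cell-type activity patterns, one per module.

    Module m is active in a consecutive run of cell types whose length grows
    once all single-type patterns are used, so no two modules share a
    pattern (this is what keeps planted modules separable at a high
    correlation cutoff).
    """
    patterns = []
    for m in range(config.n_modules):
        run = m // config.n_cell_types + 1
        start = m % config.n_cell_types
        patterns.append(frozenset((start + j) % config.n_cell_types for j in range(run)))
    return patterns


@dataclass
class TssSpec:
    tss_id: str
    chrom: str
    summit: int
    strand: str
    width: int
    tpm_by_type: np.ndarray  # length n_cell_types
    gene_id: str | None = None
    module: int | None = None
    motif: str | None = None


@dataclass
class EnhancerSpec:
    enh_id: str
    chrom: str
    center: int
    rev_summit: int
    fwd_summit: int
    d_true: float
    tpm_by_type: np.ndarray
    active_types: list[int]
    target_gene: str | None
    region: tuple[int, int]


@dataclass
class SimPlan:
    tss_specs: list[TssSpec]
    enhancer_specs: list[EnhancerSpec]
    gaps: list[tuple[str, int, int]]  # intergenic gaps without enhancers
    module_cell_types: dict[int, list[int]]


@dataclass
class Annotation:
    config: SimConfig
    models: cio.GeneModels
    sequences: dict[str, str]
    plan: SimPlan


@dataclass
class TruthTables:
    """Planted structure, the sole reference for downstream recovery tests."""

    module_membership: dict[str, int]
    module_cell_types: dict[int, list[int]]
    enhancer_loci: list[dict]
    motif_placements: dict[str, str]
    gene_tss_map: dict[str, list[str]]
    tss_catalog: dict[str, tuple[str, int, str]]  # tss_id -> (chrom, summit, strand)
    stage_profiles: dict[str, list[float]] | None = None

    def to_json(self, path) -> None:
        obj = {
            "module_membership": self.module_membership,
            "module_cell_types": {str(k): v for k, v in self.module_cell_types.items()},
            "enhancer_loci": self.enhancer_loci,
            "motif_placements": self.motif_placements,
            "gene_tss_map": self.gene_tss_map,
            "tss_catalog": {k: list(v) for k, v in self.tss_catalog.items()},
            "stage_profiles": self.stage_profiles,
        }
        cio.write_json(obj, path)

    @classmethod
    def from_json(cls, path) -> "TruthTables":
        obj = cio.read_json(path)
        return cls(
            module_membership=obj["module_membership"],
            module_cell_types={int(k): v for k, v in obj["module_cell_types"].items()},
            enhancer_loci=obj["enhancer_loci"],
            motif_placements=obj["motif_placements"],
            gene_tss_map=obj["gene_tss_map"],
            tss_catalog={k: (v[0], int(v[1]), v[2]) for k, v in obj["tss_catalog"].items()},
            stage_profiles=obj.get("stage_profiles"),
        )


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: SimConfig) -> Annotation:
    """Place non-overlapping genes, reserve intergenic gaps, plant motifs.

    Raises :class:`SimSizingError` naming the required chromosome length when
    the configured genome cannot hold ``n_genes`` without overlap.
    """
    rng = np.random.default_rng([config.seed, 0])
    patterns = module_patterns(config)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    # gene roles: paired-enhancer target genes get bespoke activity profiles,
    # everything else belongs to a coexpression module
    n_paired = int(round(config.n_enhancers * config.enhancer_paired_fraction))
    n_paired = min(n_paired, config.n_genes)
    if config.n_enhancers > config.n_genes:
        raise ValueError("n_enhancers must not exceed n_genes (one gap per gene)")
    target_idx = sorted({int(round(i * config.n_genes / max(n_paired, 1))) for i in range(n_paired)})
    target_idx = [min(i, config.n_genes - 1) for i in target_idx]
    # de-duplicate while preserving count
    seen: set[int] = set()
    targets: list[int] = []
    for i in target_idx:
        while i in seen:
            i += 1
        if i < config.n_genes:
            seen.add(i)
            targets.append(i)
    target_set = set(targets)

    module_of: dict[int, int] = {}
    next_module = 0
    for i in range(config.n_genes):
        if i in target_set:
            continue
        module_of[i] = next_module % config.n_modules
        next_module += 1

    # --- placement: genes round-robin over chromosomes, each preceded by an
    # intergenic gap of >= 2 kb
    gene_rows = []
    gap_by_gene: dict[int, tuple[str, int, int]] = {}
    cursors = {c: _EDGE_MARGIN for c in chrom_names}
    too_small = False
    for i in range(config.n_genes):
        chrom = chrom_names[i % config.n_chromosomes]
        gap = int(rng.integers(_GAP_MIN, _GAP_MAX + 1))
        length = int(rng.integers(_GENE_MIN, _GENE_MAX + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gap_start = cursors[chrom]
        start = gap_start + gap
        end = start + length
        gap_by_gene[i] = (chrom, gap_start, start)
        gene_rows.append(
            {"gene_id": f"G{i + 1:04d}", "chrom": chrom, "start": start, "end": end,
             "strand": strand, "index": i}
        )
        cursors[chrom] = end
        if end + _EDGE_MARGIN > config.chrom_length:
            too_small = True
    if too_small:
        required = max(cursors.values()) + _EDGE_MARGIN
        raise SimSizingError(
            f"chrom_length={config.chrom_length} too small for {config.n_genes} genes "
            f"over {config.n_chromosomes} chromosomes; need >= {required} bp per chromosome"
        )

    # --- transcripts and TSS specs
    tx_rows = []
    tss_specs: list[TssSpec] = []
    baseline = np.full(config.n_cell_types, config.baseline_tpm)

    def pattern_tpm(module: int, level: float) -> np.ndarray:
        tpm = baseline.copy()
        for t in patterns[module]:
            tpm[t] = level
        return tpm

    target_profiles: dict[int, np.ndarray] = {}
    for row in gene_rows:
        i = row["index"]
        gid = row["gene_id"]
        start, end, strand, chrom = row["start"], row["end"], row["strand"], row["chrom"]
        primary_5p = cio.five_prime_end(start, end, strand)
        tx_rows.append(
            {"transcript_id": f"{gid}_t1", "gene_id": gid, "chrom": chrom,
             "start": start, "end": end, "strand": strand, "tss5p": primary_5p}
        )
        if i in target_set:
            w = np.exp(rng.normal(0.0, _TARGET_LOG_SD, size=config.n_cell_types))
            profile = config.active_tpm * w + config.baseline_tpm
            target_profiles[i] = profile
            tss_specs.append(
                TssSpec(
                    tss_id=f"{gid}_p1", chrom=chrom, summit=primary_5p, strand=strand,
                    width=int(rng.integers(1, 21)), tpm_by_type=profile, gene_id=gid,
                )
            )
            continue
        module = module_of[i]
        tss_specs.append(
            TssSpec(
                tss_id=f"{gid}_p1", chrom=chrom, summit=primary_5p, strand=strand,
                width=int(rng.integers(1, 21)),
                tpm_by_type=pattern_tpm(module, config.active_tpm),
                gene_id=gid, module=module,
            )
        )
        if rng.random() < config.alt_promoter_fraction:
            offset = int(rng.integers(_ALT_MIN, _ALT_MAX + 1))
            if strand == "+":
                alt_start, alt_end = start + offset, end
            else:
                alt_start, alt_end = start, end - offset
            alt_5p = cio.five_prime_end(alt_start, alt_end, strand)
            alt_module = (module + config.n_modules // 2) % config.n_modules
            if alt_module == module:
                alt_module = (module + 1) % config.n_modules
            tx_rows.append(
                {"transcript_id": f"{gid}_t2", "gene_id": gid, "chrom": chrom,
                 "start": alt_start, "end": alt_end, "strand": strand, "tss5p": alt_5p}
            )
            tss_specs.append(
                TssSpec(
                    tss_id=f"{gid}_p2", chrom=chrom, summit=alt_5p, strand=strand,
                    width=int(rng.integers(1, 21)),
                    tpm_by_type=pattern_tpm(alt_module, config.active_tpm * _ALT_TPM_SCALE),
                    gene_id=gid, module=alt_module,
                )
            )

    # --- enhancers: paired ones share the activity profile of their target
    # gene and sit in the gap directly upstream of it; restricted ones are on
    # in a single cell type, round-robin
    enhancer_specs: list[EnhancerSpec] = []
    used_gaps: set[int] = set()
    free_gaps = [i for i in range(config.n_genes) if i not in target_set]
    for e in range(config.n_enhancers):
        if e < len(targets):
            gene_i = targets[e]
            profile = target_profiles[gene_i] * 1.0
            active = [t for t in range(config.n_cell_types) if profile[t] >= 5.0]
            target_gene = f"G{gene_i + 1:04d}"
        else:
            gene_i = free_gaps[(e - len(targets)) * max(1, len(free_gaps) // max(1, config.n_enhancers - len(targets))) % len(free_gaps)]
            while gene_i in used_gaps:
                gene_i = (gene_i + 1) % config.n_genes
            t_on = (e - len(targets)) % config.n_cell_types
            profile = np.zeros(config.n_cell_types)
            profile[t_on] = _ENH_TPM * 2  # split over two strands below
            active = [t_on]
            target_gene = None
        used_gaps.add(gene_i)
        chrom, gap_start, gap_end = gap_by_gene[gene_i]
        center = (gap_start + gap_end) // 2
        d_true = config.enhancer_balance * (1.0 if rng.random() < 0.5 else -1.0)
        fwd_share = (1.0 + d_true) / 2.0
        rev_summit = center - _ENH_HALF_SEP
        fwd_summit = center + _ENH_HALF_SEP
        eid = f"E{e + 1:03d}"
        w_rev = int(rng.integers(1, 11))
        w_fwd = int(rng.integers(1, 11))
        enhancer_specs.append(
            EnhancerSpec(
                enh_id=eid, chrom=chrom, center=center, rev_summit=rev_summit,
                fwd_summit=fwd_summit, d_true=d_true, tpm_by_type=profile,
                active_types=active, target_gene=target_gene,
                region=(rev_summit - w_rev, fwd_summit + w_fwd + 1),
            )
        )
        tss_specs.append(
            TssSpec(tss_id=f"{eid}_rev", chrom=chrom, summit=rev_summit, strand="-",
                    width=w_rev, tpm_by_type=profile * (1.0 - fwd_share))
        )
        tss_specs.append(
            TssSpec(tss_id=f"{eid}_fwd", chrom=chrom, summit=fwd_summit, strand="+",
                    width=w_fwd, tpm_by_type=profile * fwd_share)
        )

    gaps_without_enh = [gap_by_gene[i] for i in range(config.n_genes) if i not in used_gaps]

    # --- sequence with planted motif instances
    motif_ids = [m for m, _ in config.motif_library]
    consensi = dict(config.motif_library)
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, bytearray] = {}
    for chrom in chrom_names:
        codes = rng.integers(0, 4, size=config.chrom_length)
        seqs[chrom] = bytearray(base_codes[codes].tobytes())
    motif_placements: dict[str, str] = {}
    if motif_ids:
        for spec in tss_specs:
            if spec.module is None:
                continue
            if rng.random() >= config.planted_motif_rate:
                continue
            motif_id = motif_ids[spec.module % len(motif_ids)]
            consensus = consensi[motif_id]
            offset = int(rng.integers(-250, 251 - len(consensus)))
            pos = spec.summit + offset
            if pos < 0 or pos + len(consensus) > config.chrom_length:
                continue
            seqs[spec.chrom][pos:pos + len(consensus)] = consensus.encode()
            motif_placements[spec.tss_id] = motif_id

    models = cio.GeneModels(
        transcripts=pd.DataFrame(tx_rows).sort_values(
            ["chrom", "start", "transcript_id"], kind="mergesort").reset_index(drop=True)
    )
    plan = SimPlan(
        tss_specs=tss_specs,
        enhancer_specs=enhancer_specs,
        gaps=gaps_without_enh,
        module_cell_types={m: sorted(patterns[m]) for m in range(config.n_modules)},
    )
    # stash motif placements on the plan for truth assembly
    plan.motif_placements = motif_placements  # type: ignore[attr-defined]
    return Annotation(
        config=config,
        models=models,
        sequences={c: bytes(s).decode() for c, s in seqs.items()},
        plan=plan,
    )


# ---------------------------------------------------------------------------
# CTSS emission


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def _spread_weights(width: int) -> np.ndarray:
    w = _SPREAD_DECAY ** np.arange(width)
    return w / w.sum()


def generate_ctss(
    config: SimConfig, annotation: Annotation
) -> tuple[list[cio.CtssTrack], pd.DataFrame, TruthTables]:
    """Emit per-sample CTSS tracks, the sample sheet and the truth tables."""
    rng = np.random.default_rng([config.seed, 1])
    plan = annotation.plan
    n_types = config.n_cell_types

    # sample sheet and library sizes
    lo, hi = config.library_size_range
    rows = []
    for t, cell_type in enumerate(config.cell_types):
        for r in range(config.replicates_per_type):
            rows.append(
                {"sample_id": f"{cell_type}_r{r + 1}", "cell_type": cell_type,
                 "replicate": r + 1, "stage_order": t + 1}
            )
    sheet = pd.DataFrame(rows)
    lib_sizes = rng.integers(lo, hi + 1, size=len(sheet))

    # background (housekeeping-like) TSSs absorb the TPM mass not taken by
    # planted structure, so that emitted counts over a library are an honest
    # tags-per-million scale
    specs = list(plan.tss_specs)
    struct_mass = np.zeros(n_types)
    for spec in specs:
        struct_mass += spec.tpm_by_type

    noise_specs: list[TssSpec] = []
    genome_bp = config.n_chromosomes * config.chrom_length
    n_noise = rng.poisson(config.noise_tss_rate * genome_bp)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    for j in range(n_noise):
        chrom = chrom_names[int(rng.integers(config.n_chromosomes))]
        pos = int(rng.integers(_EDGE_MARGIN, config.chrom_length - _EDGE_MARGIN))
        strand = "+" if rng.random() < 0.5 else "-"
        level = float(rng.uniform(*_NOISE_TPM_RANGE))
        noise_specs.append(
            TssSpec(tss_id=f"noise{j}", chrom=chrom, summit=pos, strand=strand,
                    width=1, tpm_by_type=np.full(n_types, level))
        )
        struct_mass += noise_specs[-1].tpm_by_type

    bg_specs: list[TssSpec] = []
    if config.n_background_tss > 0:
        slots: list[tuple[str, int]] = []
        for chrom, gap_start, gap_end in plan.gaps:
            for off in (700, 1320):
                if gap_start + off + 600 <= gap_end:
                    slots.append((chrom, gap_start + off))
        if len(slots) < config.n_background_tss:
            raise ValueError(
                f"n_background_tss={config.n_background_tss} exceeds available "
                f"intergenic slots ({len(slots)}); lower it or add genes"
            )
        weights = rng.uniform(0.5, 1.5, size=config.n_background_tss)
        weights /= weights.sum()
        remainder = np.clip(1e6 - struct_mass, 0.0, None)
        for j in range(config.n_background_tss):
            chrom, pos = slots[j]
            bg_specs.append(
                TssSpec(tss_id=f"B{j + 1:04d}", chrom=chrom, summit=pos, strand="+",
                        width=int(rng.integers(1, 21)),
                        tpm_by_type=weights[j] * remainder)
            )

    all_specs = specs + bg_specs + noise_specs

    # flatten to per-position mean TPM
    pos_chrom: list[str] = []
    pos_pos: list[int] = []
    pos_strand: list[str] = []
    pos_tpm: list[np.ndarray] = []
    for spec in all_specs:
        weights = _spread_weights(spec.width)
        direction = 1 if spec.strand == "+" else -1
        for o, wt in enumerate(weights):
            pos_chrom.append(spec.chrom)
            pos_pos.append(spec.summit + direction * o)
            pos_strand.append(spec.strand)
            pos_tpm.append(spec.tpm_by_type * wt)
    tpm_matrix = np.vstack(pos_tpm) if pos_tpm else np.zeros((0, n_types))

    # per-sample counts (one rng draw order, fixed by the sample sheet order)
    tracks: list[cio.CtssTrack] = []
    type_index = {ct: t for t, ct in enumerate(config.cell_types)}
    base = pd.DataFrame({"chrom": pos_chrom, "pos": pos_pos, "strand": pos_strand})
    for s, row in enumerate(sheet.itertuples()):
        t = type_index[row.cell_type]
        mean = tpm_matrix[:, t] * (lib_sizes[s] / 1e6)
        counts = _nb_draw(rng, mean, config.dispersion)
        df = base.copy()
        df["count"] = counts
        df = df[df["count"] > 0]
        df = (
            df.groupby(["chrom", "pos", "strand"], as_index=False)["count"].sum()
            .sort_values(["chrom", "pos", "strand"], kind="mergesort")
            .reset_index(drop=True)
        )
        tracks.append(cio.CtssTrack(sample_id=row.sample_id, data=df))

    # truth tables
    module_membership = {s.tss_id: s.module for s in specs if s.module is not None}
    gene_tss_map: dict[str, list[str]] = {}
    for s in specs:
        if s.gene_id is not None:
            gene_tss_map.setdefault(s.gene_id, []).append(s.tss_id)
    catalog = {s.tss_id: (s.chrom, s.summit, s.strand) for s in specs + bg_specs}
    enhancer_loci = [
        {
            "enh_id": e.enh_id, "chrom": e.chrom, "center": e.center,
            "start": e.region[0], "end": e.region[1],
            "active_cell_types": [config.cell_types[t] for t in e.active_types],
            "directionality": e.d_true, "target_gene": e.target_gene,
        }
        for e in plan.enhancer_specs
    ]
    truth = TruthTables(
        module_membership=module_membership,
        module_cell_types=plan.module_cell_types,
        enhancer_loci=enhancer_loci,
        motif_placements=getattr(plan, "motif_placements", {}),
        gene_tss_map=gene_tss_map,
        tss_catalog=catalog,
    )
    return tracks, sheet, truth


def expected_expressed_per_sample(config: SimConfig) -> float:
    """Expected number of TSS clusters at >= 5 TPM in one sample.

    Closed-form expectation over the generator's planting rules; used as an
    oracle by the calibration tests (observed counts should land within
    +/- 15% of this over repeated seeds).
    """
    from scipy.stats import norm

    patterns = module_patterns(config)
    n_paired = min(int(round(config.n_enhancers * config.enhancer_paired_fraction)),
                   config.n_genes)
    n_module_genes = config.n_genes - n_paired
    genes_per_module = n_module_genes / config.n_modules

    # average over cell types of module TSSs active in that type
    per_type_members = np.zeros(config.n_cell_types)
    for m, pat in enumerate(patterns):
        primary = genes_per_module
        alt_in = genes_per_module * config.alt_promoter_fraction  # alts assigned INTO m
        for t in pat:
            per_type_members[t] += primary * (config.active_tpm >= 5.0)
            per_type_members[t] += alt_in * (config.active_tpm * _ALT_TPM_SCALE >= 5.0)
    expected = per_type_members.mean()

    # paired targets and their enhancers: lognormal activity per type
    p_target = 1.0 - norm.cdf(np.log(5.0 / config.active_tpm) / _TARGET_LOG_SD)
    expected += n_paired * p_target
    # each paired enhancer contributes two strand clusters at half the level
    p_enh_half = 1.0 - norm.cdf(np.log(10.0 / config.active_tpm) / _TARGET_LOG_SD)
    expected += n_paired * 2 * p_enh_half
    # restricted enhancers: 2 clusters at _ENH_TPM each in 1/n_types of samples
    n_restricted = config.n_enhancers - n_paired
    if _ENH_TPM >= 5.0:
        expected += n_restricted * 2 / config.n_cell_types
    expected += config.n_background_tss  # background absorbs ~1e6/n_bg TPM each
    return float(expected)


# ---------------------------------------------------------------------------
# stage-ordered trajectory variant

TRAJECTORY_SHAPES = {
    "ramp_up": np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
    "ramp_down": np.array([4.0, 3.0, 2.0, 1.0, 0.0]),
    "pulse": np.array([0.0, 1.0, 4.0, 1.0, 0.0]),
    "late_drop": np.array([4.0, 4.0, 4.0, 4.0, 0.0]),
}


def generate_trajectory(
    config: SimConfig, flat_fraction: float = 0.2
) -> tuple[cio.ExpressionMatrix, pd.DataFrame, TruthTables]:
    """Gene-level TPM matrix over ordered stages with planted shape families.

    Stages map onto the configured cell types in order; shapes are monotone
    ramps, a pulse and a switch-off, interpolated to ``n_cell_types`` stages.
    Truth carries per-gene stage profiles (log2 TPM) and family labels via
    ``module_membership`` (family index; flat genes are absent from it).
    """
    if config.n_cell_types < 3:
        raise ValueError("trajectory generation needs >= 3 ordered stages")
    rng = np.random.default_rng([config.seed, 2])
    n_stages = config.n_cell_types
    families = list(TRAJECTORY_SHAPES)
    xs = np.linspace(0, 4, n_stages)
    shapes = {
        name: np.interp(xs, np.linspace(0, 4, 5), shape)
        for name, shape in TRAJECTORY_SHAPES.items()
    }

    lo, hi = config.library_size_range
    sheet_rows = []
    for t in range(n_stages):
        for r in range(config.replicates_per_type):
            sheet_rows.append(
                {"sample_id": f"S{t + 1}_r{r + 1}", "cell_type": f"stage{t + 1}",
                 "replicate": r + 1, "stage_order": t + 1}
            )
    sheet = pd.DataFrame(sheet_rows)
    lib_sizes = rng.integers(lo, hi + 1, size=len(sheet))

    profiles = np.zeros((config.n_genes, n_stages))
    labels: dict[str, int] = {}
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    n_flat = int(round(config.n_genes * flat_fraction))
    for i, gid in enumerate(gene_ids):
        base = rng.uniform(1.0, 3.0)
        if i < n_flat:
            profiles[i] = base + rng.uniform(-0.1, 0.1, size=n_stages)
        else:
            fam = (i - n_flat) % len(families)
            amp = rng.uniform(3.0, 5.0)
            profiles[i] = base + amp * shapes[families[fam]] / 4.0
            labels[gid] = fam

    tpm_true = 2.0 ** profiles - 1.0
    values = np.zeros((config.n_genes, len(sheet)))
    for s, row in enumerate(sheet.itertuples()):
        t = row.stage_order - 1
        mean = tpm_true[:, t] * (lib_sizes[s] / 1e6)
        counts = _nb_draw(rng, mean, config.dispersion)
        values[:, s] = counts / lib_sizes[s] * 1e6
    matrix = cio.ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sheet["sample_id"].tolist()),
        units="tpm",
    )
    truth = TruthTables(
        module_membership=labels,
        module_cell_types={f: list(range(n_stages)) for f in range(len(families))},
        enhancer_loci=[],
        motif_placements={},
        gene_tss_map={g: [g] for g in gene_ids},
        tss_catalog={},
        stage_profiles={g: profiles[i].tolist() for i, g in enumerate(gene_ids)},
    )
    return matrix, sheet, truth


# ---------------------------------------------------------------------------
# top-level driver


def simulate(config: SimConfig, out_dir) -> dict[str, str]:
    """Run the generator and write all artefacts under ``out_dir``.

    Writes genome.fa, genes.gtf, samples.tsv, truth.json, pwms.jaspar and a
    ctss/ directory with one BED6 track per sample.  Returns the paths.
    """
    import os

    annotation = generate_annotation(config)
    tracks, sheet, truth = generate_ctss(config, annotation)
    os.makedirs(out_dir, exist_ok=True)
    ctss_dir = os.path.join(out_dir, "ctss")
    os.makedirs(ctss_dir, exist_ok=True)
    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "gtf": os.path.join(out_dir, "genes.gtf"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
        "pwms": os.path.join(out_dir, "pwms.jaspar"),
        "ctss_dir": ctss_dir,
    }
    cio.write_fasta(annotation.sequences, paths["genome"])
    cio.write_gtf(annotation.models, paths["gtf"])
    cio.write_sample_sheet(sheet, paths["samples"])
    truth.to_json(paths["truth"])
    cio.write_pwm(
        {mid: consensus_counts(consensus) for mid, consensus in config.motif_library},
        paths["pwms"],
    )
    for track in tracks:
        cio.write_ctss(track, os.path.join(ctss_dir, f"{track.sample_id}.ctss.bed"))
    return paths


def consensus_counts(consensus: str, strength: int = 97) -> np.ndarray:
    """JASPAR-style count matrix for a consensus string (97/1/1/1 columns)."""
    counts = np.ones((4, len(consensus)), dtype=int)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = strength
    return counts


def config_replace(config: SimConfig, **overrides) -> SimConfig:
    return dataclasses.replace(config, **overrides)
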