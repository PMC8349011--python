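"""Synthetic two-species worlds with known ground truth.

The generator builds a pair of toy genomes ("species A", chromosomes
``h1, h2, ...`` and "species B", chromosomes ``m1, m2, ...``) that carry
every structure the comparative pipeline consumes:

* protein-coding genes with log-normal expression shared across species;
* homologous region pairs, copied between genomes with a per-site mutation
  load tuned so alignment identity is uniform over a configurable range
  (so the 80 % identity filter is actually exercised);
* a configurable fraction of regions planted as one-to-multiple homologs
  (a second, independently mutated ref-side copy on a different
  chromosome) to exercise the one-to-one filter;
* per-region repair intensities, log-normal with a tunable cross-species
  correlation on the log scale, optionally coupled to host-gene expression
  (high-expression regions get less species-private noise — the mechanism
  behind the expression/repair-correlation trend);
* XR-seq-like reads: lengths peaked at 26 nt, genic reads biased to the
  transcribed strand with odds ``a`` (TS:NTS), sequences carrying a
  pyrimidine bias at positions 19-21; and RNA-seq-like reads proportional
  to gene expression.

Every planted parameter is recorded in the returned :class:`WorldTruth`
so downstream modules can be tested for parameter recovery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    AlignmentSegment,
    GeneModel,
    GenomicInterval,
    write_coords_table,
    write_fasta,
    write_gtf_genes,
)
from .readstats import FrequencyMatrix

logger = logging.getLogger("xrcompare")

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

# Read-length distribution: support 16-30 nt with the mode at 26 nt, the
# predominant excision product length.
LENGTH_SUPPORT = np.arange(16, 31)
_LENGTH_WEIGHTS = np.array(
    [1, 1, 1, 2, 3, 4, 6, 9, 14, 22, 40, 20, 10, 5, 2], dtype=float
)
LENGTH_PMF = _LENGTH_WEIGHTS / _LENGTH_WEIGHTS.sum()


def default_damage_bias(L: int = 26) -> FrequencyMatrix:
    """CPD-like read composition: uniform except a strong pyrimidine
    enrichment at positions 19-21 (1-based), the lesion location implied by
    incision 6-8 nt from the 3' end."""
    f = np.full((L, 4), 0.25)
    for p in (18, 19, 20):  # 0-based rows for positions 19-21
        f[p] = [0.08, 0.34, 0.10, 0.48]  # A C G T
    return FrequencyMatrix(f)


@dataclass(frozen=True)
class WorldConfig:
    """Ground-truth parameters of a synthetic two-species world."""

    genome_length: int = 5_000_000       # per species, summed over chroms
    n_chroms: int = 2
    n_genes: int = 1_500
    n_homolog_regions: int = 500
    region_length: tuple[int, int] = (500, 5_000)
    repair_correlation: float = 0.8      # Pearson rho of log repair intensity
    tcr_asymmetry_a: float = 2.0         # TS:NTS read odds, species A
    tcr_asymmetry_b: float = 2.3         # TS:NTS read odds, species B
    n_xr_reads: int = 200_000
    n_rna_reads: int = 100_000
    seed: int = 0
    # structural knobs
    frac_genic_regions: float = 0.5
    frac_inverted: float = 0.1
    frac_duplicated: float = 0.1
    identity_range: tuple[float, float] = (75.0, 98.0)
    gene_length: tuple[int, int] = (800, 1_600)
    gene_gap: tuple[int, int] = (100, 700)
    frac_isolated_genes: float = 0.0
    isolated_gap: tuple[int, int] = (21_000, 28_000)
    # signal knobs
    lambda_sigma: float = 1.0
    expression_sigma: float = 1.0
    expression_coupling_shrink: float = 1.0   # 1.0 = no expression coupling
    mix_weights: tuple[float, float, float] = (0.3, 0.5, 0.2)  # region, genic, background
    read_length_L: int = 26

    def __post_init__(self):
        if not (-1.0 <= self.repair_correlation <= 1.0):
            raise ValueError("repair_correlation must be in [-1, 1]")
        if self.tcr_asymmetry_a < 1.0 or self.tcr_asymmetry_b < 1.0:
            raise ValueError("tcr_asymmetry must be >= 1")
        if self.n_homolog_regions * self.region_length[1] > self.genome_length:
            raise ValueError("region count x max length exceeds genome length")
        if not math.isclose(sum(self.mix_weights), 1.0, abs_tol=1e-9):
            raise ValueError("mix_weights must sum to 1")

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.n_chroms

    def chrom_names(self, species: str) -> list[str]:
        prefix = {"a": "h", "b": "m"}[species]
        return [f"{prefix}{i + 1}" for i in range(self.n_chroms)]


# ---------------------------------------------------------------------------
# Scenario presets (the study conditions for each downstream analysis)
# ---------------------------------------------------------------------------

def tcr_world_config(asymmetry: float = 2.0, seed: int = 0, n_genes: int = 300,
                     n_xr_reads: int = 200_000) -> WorldConfig:
    """Isolated-gene world for TS/NTS metagene analysis: few, long genes
    separated by > 20 kb so the isolation filter keeps them all."""
    return WorldConfig(
        genome_length=9_000_000,
        n_chroms=2,
        n_genes=n_genes,
        n_homolog_regions=8,
        region_length=(500, 2_000),
        tcr_asymmetry_a=asymmetry,
        tcr_asymmetry_b=asymmetry,
        n_xr_reads=n_xr_reads,
        seed=seed,
        frac_genic_regions=0.0,
        frac_inverted=0.0,
        frac_duplicated=0.0,
        gene_length=(2_000, 4_000),
        frac_isolated_genes=1.0,
        mix_weights=(0.0, 0.85, 0.15),
    )


def correlation_world_config(rho: float = 0.8, seed: int = 0,
                             n_regions: int = 500,
                             coupling_shrink: float = 1.0) -> WorldConfig:
    """World for cross-species repair-correlation recovery: every region
    hosted by a gene (so the RNA-presence filter keeps them all), no
    duplications, read budget ~500 XR reads per region."""
    return WorldConfig(
        genome_length=5_000_000,
        n_chroms=2,
        n_genes=n_regions,
        n_homolog_regions=n_regions,
        region_length=(500, 5_000),
        repair_correlation=rho,
        n_xr_reads=300_000,
        n_rna_reads=200_000,
        seed=seed,
        frac_genic_regions=1.0,
        frac_inverted=0.0,
        frac_duplicated=0.0,
        gene_length=(1_000, 2_000),
        gene_gap=(200, 1_200),
        expression_coupling_shrink=coupling_shrink,
        mix_weights=(0.85, 0.05, 0.10),
    )


def expression_coupled_world_config(seed: int = 0) -> WorldConfig:
    """Expression-coupled world: species-private repair noise shrinks for
    regions hosted by above-median-expression genes, so highly expressed
    quartiles show stronger cross-species correlation by construction."""
    return correlation_world_config(rho=0.7, seed=seed, coupling_shrink=0.25)


# ---------------------------------------------------------------------------
# World truth
# ---------------------------------------------------------------------------

@dataclass
class WorldTruth:
    """Everything the generator decided, exposed for parameter-recovery
    tests: gene and region tables, planted intensities, the mutation plan,
    and lazily realized genome sequences."""

    config: WorldConfig
    genes: pd.DataFrame
    regions: pd.DataFrame
    dup_segments: pd.DataFrame
    chrom_sizes: dict
    _mutations: dict = field(default_factory=dict, repr=False)
    _genomes: dict = field(default_factory=dict, repr=False)

    # -- structural accessors -------------------------------------------------

    def gene_models(self, species: str) -> list[GeneModel]:
        c, s, e = f"chrom_{species}", f"start_{species}", f"end_{species}"
        return [
            GeneModel(r.gene_id, GenomicInterval(getattr(r, c), getattr(r, s),
                                                 getattr(r, e), r.strand))
            for r in self.genes.itertuples(index=False)
        ]

    def region_intervals(self, species: str) -> list[GenomicInterval]:
        c, s, e = f"chrom_{species}", f"start_{species}", f"end_{species}"
        return [
            GenomicInterval(getattr(r, c), getattr(r, s), getattr(r, e))
            for r in self.regions.itertuples(index=False)
        ]

    def segments(self) -> list[AlignmentSegment]:
        """All alignment segments (originals then planted duplications), as
        a coords table would list them."""
        segs = [
            AlignmentSegment(
                ref=GenomicInterval(r.chrom_a, r.start_a, r.end_a),
                query=GenomicInterval(r.chrom_b, r.start_b, r.end_b),
                identity=r.identity,
                query_strand="+" if r.orientation == "same" else "-",
            )
            for r in self.regions.itertuples(index=False)
        ]
        segs.extend(
            AlignmentSegment(
                ref=GenomicInterval(d.chrom_a, d.start_a, d.end_a),
                query=GenomicInterval(d.chrom_b, d.start_b, d.end_b),
                identity=d.identity,
                query_strand="+",
            )
            for d in self.dup_segments.itertuples(index=False)
        )
        return segs

    # -- genome realization ---------------------------------------------------

    def genome(self, species: str) -> dict[str, np.ndarray]:
        """chrom -> uint8 ASCII array; generated deterministically from the
        config seed on first access."""
        if species not in self._genomes:
            self._realize_genomes()
        return self._genomes[species]

    def _realize_genomes(self) -> None:
        cfg = self.config
        ss = np.random.SeedSequence([cfg.seed, 7919])
        rng_a, rng_b = [np.random.default_rng(s) for s in ss.spawn(2)]
        codes = {}
        for sp, rng in (("a", rng_a), ("b", rng_b)):
            codes[sp] = {
                chrom: rng.integers(0, 4, size, dtype=np.uint8)
                for chrom, size in self.chrom_sizes[sp].items()
            }
        # species B homolog regions = mutated copies of species A regions
        for r in self.regions.itertuples(index=False):
            src = codes["a"][r.chrom_a][r.start_a:r.end_a].copy()
            pos, off = self._mutations[("region", r.region_id)]
            src[pos] = (src[pos] + off) % 4
            if r.orientation == "inverted":
                src = (3 - src)[::-1]
            codes["b"][r.chrom_b][r.start_b:r.end_b] = src
        # planted ref-side duplicates = mutated copies of the B-side region
        for d in self.dup_segments.itertuples(index=False):
            src = codes["b"][d.chrom_b][d.start_b:d.end_b].copy()
            pos, off = self._mutations[("dup", d.region_id)]
            src[pos] = (src[pos] + off) % 4
            codes["a"][d.chrom_a][d.start_a:d.end_a] = src
        self._genomes = {
            sp: {chrom: _DECODE[arr] for chrom, arr in chroms.items()}
            for sp, chroms in codes.items()
        }

    # -- output ---------------------------------------------------------------

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sp in ("a", "b"):
            write_fasta(self.genome(sp), out / f"genome_{sp}.fa")
            write_gtf_genes(self.gene_models(sp), out / f"genes_{sp}.gtf")
        write_coords_table(self.segments(), out / "alignment.coords")
        self.regions.to_csv(out / "truth_regions.tsv", sep="\t", index=False)
        self.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# World construction
# ---------------------------------------------------------------------------

def _exact_subset(rng, candidates: np.ndarray, count: int) -> np.ndarray:
    if count <= 0 or len(candidates) == 0:
        return np.empty(0, dtype=int)
    count = min(count, len(candidates))
    return rng.choice(candidates, size=count, replace=False)


def build_world(config: WorldConfig, out_dir=None) -> WorldTruth:
    """Construct a synthetic world; optionally write its files.

    Raises ValueError when the requested genes/regions/gaps cannot be
    packed into the configured chromosome length.
    """
    cfg = config
    ss = np.random.SeedSequence([cfg.seed, 104729])
    rng, rng_gap_a, rng_gap_b = [np.random.default_rng(s) for s in ss.spawn(3)]
    n_g, n_r, n_c = cfg.n_genes, cfg.n_homolog_regions, cfg.n_chroms

    # -- structural draws ----------------------------------------------------
    gene_len = rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1, n_g)
    gene_strand = np.where(rng.random(n_g) < 0.5, "+", "-")
    expression = np.exp(rng.normal(0.0, cfg.expression_sigma, n_g))
    region_len = rng.integers(cfg.region_length[0], cfg.region_length[1] + 1, n_r)

    inverted = np.zeros(n_r, dtype=bool)
    duplicated = np.zeros(n_r, dtype=bool)
    perm = rng.permutation(n_r)
    n_inv = int(round(cfg.frac_inverted * n_r))
    inverted[perm[:n_inv]] = True
    n_dup = int(round(cfg.frac_duplicated * n_r))
    duplicated[_exact_subset(rng, perm[n_inv:], n_dup)] = True

    genic = np.zeros(n_r, dtype=bool)
    non_inv = np.flatnonzero(~inverted)
    n_genic = int(round(cfg.frac_genic_regions * n_r))
    genic[_exact_subset(rng, non_inv, n_genic)] = True

    # identity / mutation plan (mutation count fixes realized identity exactly)
    identity_target = rng.uniform(*cfg.identity_range, n_r)
    mutations: dict = {}
    identity = np.empty(n_r)
    for r in range(n_r):
        m = int(round(region_len[r] * (1.0 - identity_target[r] / 100.0)))
        pos = rng.choice(region_len[r], size=m, replace=False)
        off = rng.integers(1, 4, m, dtype=np.uint8)
        mutations[("region", r)] = (np.sort(pos), off[np.argsort(pos)])
        identity[r] = 100.0 * (1.0 - m / region_len[r])

    dup_ids = np.flatnonzero(duplicated)
    dup_identity = {}
    for r in dup_ids:
        u = rng.uniform(*cfg.identity_range)
        m = int(round(region_len[r] * (1.0 - u / 100.0)))
        pos = rng.choice(region_len[r], size=m, replace=False)
        off = rng.integers(1, 4, m, dtype=np.uint8)
        mutations[("dup", r)] = (np.sort(pos), off[np.argsort(pos)])
        dup_identity[r] = 100.0 * (1.0 - m / region_len[r])

    # -- chromosome assignment (index order preserved = co-linear pairs) -----
    gpc = max(1, math.ceil(n_g / n_c))
    rpc = max(1, math.ceil(n_r / n_c))
    gene_chrom = np.minimum(np.arange(n_g) // gpc, n_c - 1)
    region_chrom = np.minimum(np.arange(n_r) // rpc, n_c - 1)
    dup_chrom = {r: (region_chrom[r] + 1) % n_c for r in dup_ids}

    # anchor each region at a gene slot on its chromosome
    host = np.full(n_r, -1)
    anchor_slot = np.full(n_r, 0)
    for ci in range(n_c):
        gi = np.flatnonzero(gene_chrom == ci)
        ri = np.flatnonzero(region_chrom == ci)
        for t, r in enumerate(ri):
            slot = int(t * len(gi) / len(ri)) if len(gi) and len(ri) else 0
            anchor_slot[r] = slot
            if genic[r] and len(gi):
                g = gi[slot]
                if host[r] == -1 and not np.any(host == g):
                    host[r] = g
    genic = host >= 0  # genic regions are exactly the hosted ones

    # enlarge host genes and fix the region's offset inside the gene
    gene_len = gene_len.copy()
    region_offset = np.zeros(n_r, dtype=int)
    for r in np.flatnonzero(genic):
        g = host[r]
        gene_len[g] = max(gene_len[g], region_len[r] + 200)
        region_offset[r] = rng.integers(0, gene_len[g] - region_len[r] + 1)

    dup_slot = {}
    for ci in range(n_c):
        d_here = [r for r in dup_ids if dup_chrom[r] == ci]
        gi = np.flatnonzero(gene_chrom == ci)
        for t, r in enumerate(d_here):
            dup_slot[r] = int(t * len(gi) / len(d_here)) if len(gi) else 0

    # -- repair intensities ---------------------------------------------------
    rho = cfg.repair_correlation
    z0 = rng.normal(size=n_r)
    za = rng.normal(size=n_r)
    zb = rng.normal(size=n_r)
    shrink = np.ones(n_r)
    if cfg.expression_coupling_shrink != 1.0:
        med = np.median(expression)
        high = genic & (expression[np.maximum(host, 0)] >= med)
        shrink[high] = cfg.expression_coupling_shrink
    s_shared = math.sqrt(abs(rho))
    s_noise = np.sqrt(np.maximum(1.0 - abs(rho), 0.0) * shrink)
    log_lam_a = cfg.lambda_sigma * (s_shared * z0 + s_noise * za)
    log_lam_b = cfg.lambda_sigma * (
        math.copysign(s_shared, rho if rho != 0 else 1.0) * z0 + s_noise * zb
    )

    # -- layout ---------------------------------------------------------------
    def draw_gap(r) -> int:
        lo, hi = (
            cfg.isolated_gap
            if r.random() < cfg.frac_isolated_genes
            else cfg.gene_gap
        )
        return int(lo + r.random() * (hi - lo))

    coords = {
        "a": {"gene": {}, "region": {}, "dup": {}},
        "b": {"gene": {}, "region": {}},
    }

    for sp, rng_gap in (("a", rng_gap_a), ("b", rng_gap_b)):
        chrom_names = cfg.chrom_names(sp)
        for ci in range(n_c):
            gi = list(np.flatnonzero(gene_chrom == ci))
            ri = list(np.flatnonzero(region_chrom == ci))
            inter = [r for r in ri if not genic[r]]
            if sp == "b":
                inv_here = [r for r in inter if inverted[r]]
                slot_map = {r: anchor_slot[r] for r in inter}
                for r, r_rev in zip(inv_here, reversed(inv_here)):
                    slot_map[r] = anchor_slot[r_rev]
            else:
                slot_map = {r: anchor_slot[r] for r in inter}

            elements: list[tuple[str, int]] = []
            n_slots = len(gi) if gi else 1
            for slot in range(n_slots):
                if gi:
                    elements.append(("gene", gi[slot]))
                at_slot = [r for r in inter if slot_map[r] == slot]
                if sp == "b":
                    at_slot.sort(key=lambda r: (-r if inverted[r] else r))
                elements.extend(("region", r) for r in at_slot)
                if sp == "a":
                    elements.extend(
                        ("dup", r)
                        for r in dup_ids
                        if dup_chrom[r] == ci and dup_slot[r] == slot
                    )
            chrom = chrom_names[ci]
            cursor = draw_gap(rng_gap)
            for kind, idx in elements:
                length = int(gene_len[idx] if kind == "gene" else region_len[idx])
                coords[sp][kind][idx] = (chrom, cursor, cursor + length)
                cursor += length + draw_gap(rng_gap)
            if cursor > cfg.chrom_length:
                raise ValueError(
                    f"infeasible packing: species {sp} chrom {chrom} needs "
                    f"{cursor} bp > {cfg.chrom_length} bp available"
                )

    # genic regions live inside their host gene at a fixed offset
    for sp in ("a", "b"):
        for r in np.flatnonzero(genic):
            chrom, gs, _ge = coords[sp]["gene"][host[r]]
            s = gs + region_offset[r]
            coords[sp]["region"][r] = (chrom, s, s + int(region_len[r]))

    # -- assemble tables -------------------------------------------------------
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{k:05d}" for k in range(n_g)],
            "chrom_a": [coords["a"]["gene"][k][0] for k in range(n_g)],
            "start_a": [coords["a"]["gene"][k][1] for k in range(n_g)],
            "end_a": [coords["a"]["gene"][k][2] for k in range(n_g)],
            "chrom_b": [coords["b"]["gene"][k][0] for k in range(n_g)],
            "start_b": [coords["b"]["gene"][k][1] for k in range(n_g)],
            "end_b": [coords["b"]["gene"][k][2] for k in range(n_g)],
            "strand": gene_strand,
            "length": gene_len,
            "expression": expression,
        }
    )
    for sp in ("a", "b"):
        genes[f"isolated_{sp}"] = _isolation_truth(genes, sp)

    regions = pd.DataFrame(
        {
            "region_id": np.arange(n_r),
            "chrom_a": [coords["a"]["region"][r][0] for r in range(n_r)],
            "start_a": [coords["a"]["region"][r][1] for r in range(n_r)],
            "end_a": [coords["a"]["region"][r][2] for r in range(n_r)],
            "chrom_b": [coords["b"]["region"][r][0] for r in range(n_r)],
            "start_b": [coords["b"]["region"][r][1] for r in range(n_r)],
            "end_b": [coords["b"]["region"][r][2] for r in range(n_r)],
            "length": region_len,
            "identity": identity,
            "orientation": np.where(inverted, "inverted", "same"),
            "genic": genic,
            "host_gene": host,
            "duplicated": duplicated,
            "lambda_a": np.exp(log_lam_a),
            "lambda_b": np.exp(log_lam_b),
        }
    )

    dup_rows = [
        {
            "region_id": int(r),
            "chrom_a": coords["a"]["dup"][r][0],
            "start_a": coords["a"]["dup"][r][1],
            "end_a": coords["a"]["dup"][r][2],
            "chrom_b": coords["b"]["region"][r][0],
            "start_b": coords["b"]["region"][r][1],
            "end_b": coords["b"]["region"][r][2],
            "identity": dup_identity[r],
        }
        for r in dup_ids
    ]
    dup_segments = pd.DataFrame(
        dup_rows,
        columns=["region_id", "chrom_a", "start_a", "end_a",
                 "chrom_b", "start_b", "end_b", "identity"],
    )

    chrom_sizes = {
        sp: {name: cfg.chrom_length for name in cfg.chrom_names(sp)}
        for sp in ("a", "b")
    }
    world = WorldTruth(
        config=cfg,
        genes=genes,
        regions=regions,
        dup_segments=dup_segments,
        chrom_sizes=chrom_sizes,
        _mutations=mutations,
    )
    if out_dir is not None:
        world.write(out_dir)
    return world


def _isolation_truth(genes: pd.DataFrame, species: str, min_gap: int = 20_000) -> np.ndarray:
    """Which genes are >= min_gap away (body-to-body) from every other gene."""
    iso = np.ones(len(genes), dtype=bool)
    c, s, e = f"chrom_{species}", f"start_{species}", f"end_{species}"
    for _chrom, grp in genes.groupby(c):
        idx = grp.index.to_numpy()
        order = np.argsort(grp[s].to_numpy(), kind="stable")
        idx = idx[order]
        starts = genes.loc[idx, s].to_numpy()
        ends = genes.loc[idx, e].to_numpy()
        for k in range(len(idx)):
            if k > 0 and starts[k] - ends[k - 1] < min_gap:
                iso[idx[k]] = iso[idx[k - 1]] = False
            # genes are placed in order and non-overlapping, so neighbors
            # suffice for the body-to-body distance check
    return iso


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _draw_lengths(rng, n: int) -> np.ndarray:
    return rng.choice(LENGTH_SUPPORT, size=n, p=LENGTH_PMF)


def _chrom_size_arrays(world: WorldTruth, species: str):
    sizes = world.chrom_sizes[species]
    names = list(sizes)
    return names, np.array([sizes[n] for n in names], dtype=float)


def simulate_xr_reads(
    world: WorldTruth,
    species: str = "a",
    damage: str = "CPD",
    n_reads: int | None = None,
    asymmetry: float | None = None,
    mix_weights: tuple[float, float, float] | None = None,
    seed=None,
    with_sequence: bool = False,
) -> pd.DataFrame:
    """Simulate an XR-seq BED6 frame for one species.

    Reads come from a three-part mixture: homolog-region reads (regions
    weighted by repair intensity x length, positions uniform within the
    region, strands uniform), genic transcription-coupled reads (genes
    weighted by expression, the transcribed — template — strand chosen with
    probability a/(1+a), i.e. mapping opposite to the gene's annotated
    strand), and uniform genomic background.  Lengths follow the 26-nt-mode
    distribution; with ``with_sequence`` the genomic sequence is attached
    and positions 19-21 are overwritten with draws from the damage-bias
    matrix (reads >= 21 nt).
    """
    cfg = world.config
    rng = np.random.default_rng(seed)
    n_reads = cfg.n_xr_reads if n_reads is None else n_reads
    a = (
        {"a": cfg.tcr_asymmetry_a, "b": cfg.tcr_asymmetry_b}[species]
        if asymmetry is None
        else asymmetry
    )
    w = np.asarray(mix_weights if mix_weights is not None else cfg.mix_weights, float)
    if not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("mix_weights must sum to 1")
    regions, genes = world.regions, world.genes
    if w[0] > 0 and len(regions) == 0:
        raise ValueError("world has no homolog regions to draw reads from")
    if w[1] > 0 and len(genes) == 0:
        raise ValueError("world has no genes to draw reads from")

    comp = rng.choice(3, size=n_reads, p=w)
    lengths = _draw_lengths(rng, n_reads)
    chroms = np.empty(n_reads, dtype=object)
    starts = np.zeros(n_reads, dtype=int)
    strands = np.empty(n_reads, dtype=object)

    c_col = regions[f"chrom_{species}"].to_numpy() if len(regions) else None
    s_col = regions[f"start_{species}"].to_numpy() if len(regions) else None
    lam = regions[f"lambda_{species}"].to_numpy() if len(regions) else None

    m = comp == 0
    if m.any():
        weights = lam * regions["length"].to_numpy()
        ridx = rng.choice(len(regions), size=int(m.sum()), p=weights / weights.sum())
        offs = np.floor(rng.random(int(m.sum())) * regions["length"].to_numpy()[ridx]).astype(int)
        chroms[m] = c_col[ridx]
        starts[m] = s_col[ridx] + offs
        strands[m] = np.where(rng.random(int(m.sum())) < 0.5, "+", "-")

    m = comp == 1
    if m.any():
        n_gen = int(m.sum())
        e = genes["expression"].to_numpy()
        gidx = rng.choice(len(genes), size=n_gen, p=e / e.sum())
        g_start = genes[f"start_{species}"].to_numpy()[gidx]
        g_len = genes["length"].to_numpy()[gidx]
        offs = np.floor(rng.random(n_gen) * g_len).astype(int)
        chroms[m] = genes[f"chrom_{species}"].to_numpy()[gidx]
        starts[m] = g_start + offs
        g_strand = genes["strand"].to_numpy()[gidx]
        ts = rng.random(n_gen) < a / (1.0 + a)
        # TS repair reads map to the template strand = opposite of the gene
        strands[m] = np.where(ts, np.where(g_strand == "+", "-", "+"), g_strand)

    m = comp == 2
    if m.any():
        names, sizes = _chrom_size_arrays(world, species)
        cidx = rng.choice(len(names), size=int(m.sum()), p=sizes / sizes.sum())
        chroms[m] = np.array(names, dtype=object)[cidx]
        starts[m] = np.floor(rng.random(int(m.sum())) * sizes[cidx]).astype(int)
        strands[m] = np.where(rng.random(int(m.sum())) < 0.5, "+", "-")

    # keep reads inside their chromosome without changing their length
    size_of = world.chrom_sizes[species]
    limits = np.array([size_of[c] for c in chroms])
    starts = np.minimum(starts, limits - lengths)
    starts = np.maximum(starts, 0)

    frame = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "name": [f"{species}_{damage}_xr{i}" for i in range(n_reads)],
            "score": "0",
            "strand": strands,
        }
    )
    if with_sequence:
        frame["seq"] = xr_read_sequences(world, species, frame, rng)
    return frame


def xr_read_sequences(world: WorldTruth, species: str, reads: pd.DataFrame, rng) -> list[str]:
    """Fetch oriented read sequences and overwrite positions 19-21 with
    draws from the damage-bias matrix (reads >= 21 nt only)."""
    from .io_core import fetch_sequences

    genome = world.genome(species)
    ivs = [
        GenomicInterval(c, int(s), int(e), st)
        for c, s, e, st in zip(reads["chrom"], reads["start"], reads["end"], reads["strand"])
    ]
    seqs = fetch_sequences(genome, ivs)
    bias = default_damage_bias(world.config.read_length_L)
    bases = np.array(list("ACGT"))
    n = len(seqs)
    draws = {}
    for p in (18, 19, 20):
        cum = np.cumsum(bias.values[p])
        draws[p] = bases[np.searchsorted(cum, rng.random(n))]
    out = []
    for i, s in enumerate(seqs):
        if len(s) >= 21:
            chars = list(s)
            for p in (18, 19, 20):
                chars[p] = draws[p][i]
            s = "".join(chars)
        out.append(s)
    return out


def simulate_rna_reads(
    world: WorldTruth,
    species: str = "a",
    n_reads: int | None = None,
    read_length: int = 100,
    seed=None,
) -> pd.DataFrame:
    """RNA-seq-like reads: genes drawn proportional to expression, reads
    placed uniformly within the gene body on the gene's strand."""
    cfg = world.config
    rng = np.random.default_rng(seed)
    n_reads = cfg.n_rna_reads if n_reads is None else n_reads
    genes = world.genes
    if len(genes) == 0:
        raise ValueError("world has no genes")
    e = genes["expression"].to_numpy(dtype=float)
    if e.sum() <= 0:
        raise ValueError("all gene expressions are zero")
    gidx = rng.choice(len(genes), size=n_reads, p=e / e.sum())
    g_start = genes[f"start_{species}"].to_numpy()[gidx]
    g_len = genes["length"].to_numpy()[gidx]
    span = np.maximum(g_len - read_length, 1)
    offs = np.floor(rng.random(n_reads) * span).astype(int)
    starts = g_start + offs
    ends = starts + np.minimum(read_length, g_len)
    return pd.DataFrame(
        {
            "chrom": genes[f"chrom_{species}"].to_numpy()[gidx],
            "start": starts,
            "end": ends,
            "name": [f"{species}_rna{i}" for i in range(n_reads)],
            "score": "0",
            "strand": genes["strand"].to_numpy()[gidx],
        }
    )


# ---------------------------------------------------------------------------
# Multi-sample count design for PCA
# ---------------------------------------------------------------------------

def simulate_sample_counts(
    world: WorldTruth,
    depth: int = 200_000,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region x sample count matrix for the 10-sample clustering design.

    Eight fibroblast-like samples (2 species x 2 damage types x 2
    replicates) share a fibroblast repair-landscape factor, with smaller
    damage-type and species factors on top; two lymphocyte-like CPD
    replicates carry their own independent cell-type factor, making them
    the expected outgroup.  Counts are Poisson draws around per-sample
    log-normal intensities.
    """
    rng = np.random.default_rng(seed)
    n = len(world.regions)
    base = rng.normal(0, 1.0, n)          # shared mappability/openness
    fib = rng.normal(0, 0.8, n)           # fibroblast repair landscape
    lym = rng.normal(0, 0.8, n)           # lymphocyte repair landscape
    dmg = {"CPD": rng.normal(0, 0.5, n), "64PP": rng.normal(0, 0.5, n)}
    spc = {"human": rng.normal(0, 0.15, n), "lemur": rng.normal(0, 0.15, n)}

    samples, meta = {}, []
    for species in ("human", "lemur"):
        for damage in ("CPD", "64PP"):
            for rep in (1, 2):
                name = f"{species}_fib_{damage}_r{rep}"
                log_lam = base + fib + dmg[damage] + spc[species] + rng.normal(0, 0.05, n)
                samples[name] = log_lam
                meta.append((name, species, damage, "fibroblast", rep))
    for rep in (1, 2):
        name = f"human_lym_CPD_r{rep}"
        samples[name] = base + lym + dmg["CPD"] + rng.normal(0, 0.05, n)
        meta.append((name, "human", "CPD", "lymphocyte", rep))

    counts = {}
    for name, log_lam in samples.items():
        lam = np.exp(log_lam)
        counts[name] = rng.poisson(depth * lam / lam.sum())
    counts_df = pd.DataFrame(counts, index=world.regions["region_id"])
    meta_df = pd.DataFrame(
        meta, columns=["sample", "species", "damage", "celltype", "replicate"]
    )
    return counts_df, meta_df
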