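"""Truth-labeled synthetic fixtures for every stage of the pipeline.

The generator emulates the statistical structure the analyses assume,
not human-genome realism: a small multi-chromosome host genome with a
piecewise-constant GC landscape, an LTR query sequence, reference ERV
copies written into the reference, polymorphic LTR insertions implanted
into carrier haplotypes at configured population frequencies, SNP
haplotypes with founder-block LD plus a designated tag SNP per insertion
at a configured r², uniform single-end reads with substitution errors,
and toy eQTL / GWAS-catalog / hotspot / SV-deletion annotation files.

Everything derives from one seed through named ``SeedSequence`` child
streams, so each artifact is reproducible independently of which other
artifacts are generated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from ._seq import decode, revcomp
from .association import GenotypeTable, ld_r2
from .discovery import ReadBatch
from .errors import ConfigError
from .hotspot import HotspotMap


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults correspond to the package's standard evaluation fixture:
    a 5 Mb genome over three chromosomes, 20 implanted insertions, 50
    diploid individuals in two populations, 100 bp error-free reads at
    10x depth, and a 968 bp LTR (the length of the youngest intact
    HERV-K LTR).
    """

    seed: int = 0
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_500_000, "chr3": 1_500_000}
    )
    gc_block_bp: int = 50_000
    gc_mean: float = 0.41
    gc_sd: float = 0.07
    ltr_length: int = 968
    n_reference_ervs: int = 3
    n_insertions: int = 20
    insertion_freq_min: float = 0.1
    insertion_freq_max: float = 0.9
    known_nonref_fraction: float = 0.7
    min_site_separation: int = 10_000
    n_individuals: int = 50
    n_populations: int = 1
    fst: float = 0.05
    n_snps: int = 2_000
    n_founders: int = 30
    block_bp: int = 50_000
    tag_target_r2: float = 1.0
    read_length: int = 100
    depth: float = 10.0
    error_rate: float = 0.0
    # annotations
    n_tissues: int = 4
    eqtl_base_rate: float = 0.10
    planted_enrichment_fold: float = 5.0
    planted_enrichment_radius: int = 50_000
    n_planted_pairs: int = 1
    gwas_catalog_fraction: float = 0.05
    # hotspot maps (an LD-based coarse map and a denser ChIP-seq-like map)
    hotspot_counts: tuple[int, int] = (40, 120)
    hotspot_width: int = 1_500
    hotspot_min_distance_from_sites: int = 0
    # SV deletions
    planted_deletion_lengths: tuple[int, ...] = (1_500, 800)
    n_background_deletions: int = 10

    def __post_init__(self):
        if not (0 <= self.insertion_freq_min <= self.insertion_freq_max <= 1):
            raise ConfigError("insertion frequencies must satisfy 0 <= min <= max <= 1")
        if not 0 <= self.tag_target_r2 <= 1:
            raise ConfigError("tag_target_r2 must lie in [0, 1]")
        if self.read_length > min(self.chromosomes.values()):
            raise ConfigError("read length exceeds the shortest chromosome")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "chromosomes" in raw:
            raw["chromosomes"] = {str(k): int(v) for k, v in raw["chromosomes"].items()}
        for key in ("hotspot_counts", "planted_deletion_lengths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["hotspot_counts"] = list(self.hotspot_counts)
        raw["planted_deletion_lengths"] = list(self.planted_deletion_lengths)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic files."""

    sites: pd.DataFrame          # site_id, chrom, pos, freq, known
    carrier: np.ndarray          # (n_insertions, n_individuals) int8
    hap_insertion: np.ndarray    # (n_insertions, 2 * n_individuals) int8
    tag_snps: pd.DataFrame       # site_id, snp_id, target_r2, realized_r2
    individual_ids: list[str]
    populations: dict[str, str]
    ref_ervs: pd.DataFrame       # chrom, start, end
    planted_pairs: list[tuple[str, str]]       # (site_id, tissue)
    planted_deletions: pd.DataFrame


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: dict[str, np.ndarray]
    ltr: np.ndarray
    truth: TruthSet
    genotypes: GenotypeTable
    ref_erv_bed: pd.DataFrame
    known_nonref_bed: pd.DataFrame
    eqtl_sets: dict[str, set[str]]
    universe: set[str]
    gwas_catalog: pd.DataFrame
    hotspot_maps: list[HotspotMap]
    sv_deletions: pd.DataFrame
    contig_allowlist: list[str]

    def read_batches(self) -> Iterator[ReadBatch]:
        """Regenerate the cohort's reads (deterministic for the config seed)."""
        yield from simulate_reads(self.config, self.reference, self.truth, self.ltr)


# ------------------------------------------------------------------- helpers


_STREAM_NAMES = ["genome", "loci", "haplotypes", "reads", "annotations"]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAM_NAMES))
    return {n: np.random.default_rng(s) for n, s in zip(_STREAM_NAMES, children)}


def _read_seeds(seed: int, n_individuals: int) -> list[np.random.SeedSequence]:
    reads_child = np.random.SeedSequence(seed).spawn(len(_STREAM_NAMES))[
        _STREAM_NAMES.index("reads")]
    return reads_child.spawn(n_individuals)


def max_attainable_r(f_a: float, f_b: float) -> float:
    """Upper bound on corr(A, B) for Bernoulli margins f_a, f_b."""
    if min(f_a, f_b) <= 0 or max(f_a, f_b) >= 1:
        return 0.0
    return min(
        np.sqrt(f_a * (1 - f_b) / (f_b * (1 - f_a))),
        np.sqrt(f_b * (1 - f_a) / (f_a * (1 - f_b))),
    )


def _sample_separated_positions(
    rng: np.random.Generator, length: int, n: int, min_sep: int, margin: int
) -> np.ndarray:
    """n positions in [margin, length - margin) pairwise >= min_sep apart."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    usable = length - 2 * margin - (n - 1) * min_sep
    if usable <= 0:
        raise ConfigError("chromosome too short for the requested number of loci")
    raw = np.sort(rng.integers(0, usable, size=n))
    return raw + margin + np.arange(n) * min_sep


# ------------------------------------------------------------------ genomes


def simulate_genome(config: SimulationConfig, rng: np.random.Generator
                    ) -> dict[str, np.ndarray]:
    """Random reference background with a piecewise-constant GC landscape."""
    genome: dict[str, np.ndarray] = {}
    for chrom, length in config.chromosomes.items():
        n_blocks = length // config.gc_block_bp + 1
        gc = np.clip(rng.normal(config.gc_mean, config.gc_sd, size=n_blocks), 0.2, 0.7)
        per_base = np.repeat(gc, config.gc_block_bp)[:length]
        u = rng.random(length)
        # order: C, G, A, T by cumulative thresholds
        seq = np.empty(length, dtype=np.uint8)
        seq[:] = 3  # T
        seq[u < per_base / 2] = 1                                   # C
        seq[(u >= per_base / 2) & (u < per_base)] = 2               # G
        seq[(u >= per_base) & (u < per_base + (1 - per_base) / 2)] = 0  # A
        genome[chrom] = seq
    return genome


def simulate_ltr(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=config.ltr_length).astype(np.uint8)


def choose_loci(config: SimulationConfig, rng: np.random.Generator
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Insertion loci and reference-ERV intervals, well separated."""
    chroms = list(config.chromosomes)
    lengths = np.array([config.chromosomes[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    n_total = config.n_insertions + config.n_reference_ervs
    per_chrom = rng.multinomial(n_total, weights)
    rows = []
    for ci, chrom in enumerate(chroms):
        pos = _sample_separated_positions(
            rng, config.chromosomes[chrom], int(per_chrom[ci]),
            config.min_site_separation, margin=20_000,
        )
        rows.extend((chrom, int(p)) for p in pos)
    rng.shuffle(rows)
    ins = rows[: config.n_insertions]
    ref = rows[config.n_insertions :]
    ins.sort()
    ref.sort()
    sites = pd.DataFrame(ins, columns=["chrom", "pos"])
    sites.insert(0, "site_id", [f"ins{i:03d}" for i in range(len(sites))])
    ref_ervs = pd.DataFrame(
        [(c, p, p + config.ltr_length) for c, p in ref],
        columns=["chrom", "start", "end"],
    )
    return sites, ref_ervs


def write_reference_ervs(genome: dict[str, np.ndarray], ltr: np.ndarray,
                         ref_ervs: pd.DataFrame) -> None:
    """Overwrite reference bases with LTR copies (coordinates stay fixed)."""
    for rec in ref_ervs.itertuples():
        genome[rec.chrom][rec.start : rec.end] = ltr


# ----------------------------------------------------------------- haplotypes


def simulate_haplotypes(config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        sites: pd.DataFrame | None = None
                        ) -> tuple[GenotypeTable, TruthSet]:
    """Phased SNP haplotypes with an insertion allele embedded per site.

    Background SNPs get founder-block LD within populations
    (Balding-Nichols allele-frequency divergence across populations).
    The insertion allele of each site is drawn per haplotype at its
    configured frequency, and the nearest SNP is rewritten as a tag SNP
    whose haplotype correlation with the insertion matches
    ``tag_target_r2`` in expectation; the realized r² is recorded.
    """
    streams = _streams(config.seed)
    rng = rng or streams["haplotypes"]
    loci_rng = streams["loci"]
    if sites is None:
        sites, _ = choose_loci(config, loci_rng)

    n = config.n_individuals
    n_hap = 2 * n
    individual_ids = [f"IND{i:04d}" for i in range(n)]
    pops = {ind: f"POP{i % config.n_populations}" for i, ind in enumerate(individual_ids)}
    pop_of_hap = np.array([i // 2 % config.n_populations for i in range(n_hap)])

    # SNP map
    chroms = list(config.chromosomes)
    lengths = np.array([config.chromosomes[c] for c in chroms], dtype=float)
    n_per = rng.multinomial(config.n_snps, lengths / lengths.sum())
    snp_chrom, snp_pos = [], []
    for ci, chrom in enumerate(chroms):
        pos = np.sort(rng.choice(config.chromosomes[chrom], size=n_per[ci], replace=False))
        snp_chrom.extend([chrom] * n_per[ci])
        snp_pos.extend(int(p) for p in pos)
    m = len(snp_pos)
    snps = pd.DataFrame({
        "id": [f"rs{100000 + j}" for j in range(m)],
        "chrom": snp_chrom,
        "pos": snp_pos,
        "ref": "A",
        "alt": "G",
    })

    # global and per-population allele frequencies (Balding-Nichols)
    p_global = rng.uniform(0.05, 0.95, size=m)
    if config.fst > 0 and config.n_populations > 1:
        a = p_global * (1 - config.fst) / config.fst
        b = (1 - p_global) * (1 - config.fst) / config.fst
        p_pop = rng.beta(a[None, :], b[None, :],
                         size=(config.n_populations, m))
    else:
        p_pop = np.tile(p_global, (config.n_populations, 1))

    # founder-block copying within each population
    block_idx = np.zeros(m, dtype=np.int64)
    b0 = 0
    for chrom in chroms:
        sel = np.nonzero(snps["chrom"].to_numpy() == chrom)[0]
        block_idx[sel] = b0 + snps["pos"].to_numpy()[sel] // config.block_bp
        b0 = block_idx[sel].max() + 1 if sel.size else b0
    n_blocks = int(block_idx.max()) + 1 if m else 0
    haplotypes = np.zeros((m, n_hap), dtype=np.int8)
    founders = {
        k: (rng.random((config.n_founders, m)) < p_pop[k][None, :]).astype(np.int8)
        for k in range(config.n_populations)
    }
    col = np.arange(m)
    for h in range(n_hap):
        k = pop_of_hap[h]
        choice = rng.integers(0, config.n_founders, size=n_blocks)
        haplotypes[:, h] = founders[k][choice[block_idx], col]

    # insertion alleles and tag SNPs
    freqs = rng.uniform(config.insertion_freq_min, config.insertion_freq_max,
                        size=len(sites))
    hap_ins = np.zeros((len(sites), n_hap), dtype=np.int8)
    tag_rows = []
    r_target = float(np.sqrt(config.tag_target_r2))
    snp_pos_arr = snps["pos"].to_numpy()
    snp_chrom_arr = snps["chrom"].to_numpy()
    used_tags: set[int] = set()
    for i, rec in enumerate(sites.itertuples()):
        f = float(freqs[i])
        bound = max_attainable_r(f, f)
        if r_target > bound + 1e-12:
            raise ConfigError(
                f"target r = {r_target:.3f} unattainable for frequency {f:.3f}; "
                f"feasible bound is {bound:.3f}"
            )
        hap_ins[i] = (rng.random(n_hap) < f).astype(np.int8)
        cand = np.nonzero(snp_chrom_arr == rec.chrom)[0]
        cand = cand[~np.isin(cand, list(used_tags))]
        if cand.size == 0:
            continue
        j = int(cand[np.argmin(np.abs(snp_pos_arr[cand] - rec.pos))])
        used_tags.add(j)
        p1 = f + r_target * (1 - f)   # P(tag allele | insertion)
        p0 = f * (1 - r_target)       # P(tag allele | no insertion)
        u = rng.random(n_hap)
        haplotypes[j] = np.where(hap_ins[i] == 1, u < p1, u < p0).astype(np.int8)
        realized = ld_r2(
            haplotypes[j, 0::2] + haplotypes[j, 1::2],
            hap_ins[i, 0::2] + hap_ins[i, 1::2],
        )
        tag_rows.append((rec.site_id, snps["id"].iloc[j],
                         config.tag_target_r2, realized))

    dosage = (haplotypes[:, 0::2] + haplotypes[:, 1::2]).astype(np.int8)
    carrier = ((hap_ins[:, 0::2] + hap_ins[:, 1::2]) > 0).astype(np.int8)
    sites = sites.copy()
    sites["freq"] = freqs
    n_known = int(round(config.known_nonref_fraction * len(sites)))
    known = np.zeros(len(sites), dtype=bool)
    if len(sites):
        known[rng.choice(len(sites), size=n_known, replace=False)] = True
    sites["known"] = known
    truth = TruthSet(
        sites=sites,
        carrier=carrier,
        hap_insertion=hap_ins,
        tag_snps=pd.DataFrame(tag_rows, columns=["site_id", "snp_id",
                                                 "target_r2", "realized_r2"]),
        individual_ids=individual_ids,
        populations=pops,
        ref_ervs=pd.DataFrame(columns=["chrom", "start", "end"]),
        planted_pairs=[],
        planted_deletions=pd.DataFrame(columns=["chrom", "start", "end", "length",
                                                "site_id"]),
    )
    genotypes = GenotypeTable(snps=snps, dosage=dosage,
                              individual_ids=individual_ids, populations=pops)
    return genotypes, truth


# -------------------------------------------------------------------- genomes


def build_genomes(config: SimulationConfig, truth: TruthSet
                  ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Reference genome (with reference ERV copies) and the LTR sequence.

    Carrier haplotype sequences are not materialized here; they are
    spliced on demand by :func:`haplotype_sequence` /
    :func:`simulate_reads`.  Raises when two implant loci fall within
    one cluster window of each other.
    """
    streams = _streams(config.seed)
    genome = simulate_genome(config, streams["genome"])
    ltr = simulate_ltr(config, streams["genome"])
    pos = truth.sites.sort_values(["chrom", "pos"])
    for chrom, grp in pos.groupby("chrom"):
        gaps = np.diff(grp["pos"].to_numpy())
        if (gaps < 1000).any():
            raise ConfigError("two implant loci within one cluster window")
    write_reference_ervs(genome, ltr, truth.ref_ervs)
    return genome, ltr


def haplotype_sequence(reference: dict[str, np.ndarray], ltr: np.ndarray,
                       inserts: pd.DataFrame) -> dict[str, np.ndarray]:
    """Splice LTR copies into a reference at the given (chrom, pos) loci."""
    out: dict[str, np.ndarray] = {}
    by_chrom = inserts.groupby("chrom")["pos"].apply(list).to_dict() if len(inserts) else {}
    for chrom, seq in reference.items():
        positions = sorted(by_chrom.get(chrom, []))
        if not positions:
            out[chrom] = seq
            continue
        parts = []
        prev = 0
        for p in positions:
            parts.append(seq[prev:p])
            parts.append(ltr)
            prev = p
        parts.append(seq[prev:])
        out[chrom] = np.concatenate(parts)
    return out


def simulate_reads(config: SimulationConfig, reference: dict[str, np.ndarray],
                   truth: TruthSet, ltr: np.ndarray) -> Iterator[ReadBatch]:
    """Uniform single-end reads per individual, substitution errors only.

    Total read bases per individual are depth x haplotype length, split
    evenly between the two haplotypes.  Deterministic per config seed:
    each individual draws from its own child stream.
    """
    if config.depth <= 0:
        raise ConfigError("depth must be positive")
    L = config.read_length
    child_seeds = _read_seeds(config.seed, len(truth.individual_ids))
    for i, ind in enumerate(truth.individual_ids):
        rng = np.random.default_rng(child_seeds[i])
        reads_parts = []
        for hap in (0, 1):
            carried = truth.sites[truth.hap_insertion[:, 2 * i + hap] == 1]
            seqs = haplotype_sequence(reference, ltr, carried)
            total_len = sum(s.shape[0] for s in seqs.values())
            n_reads_hap = int(round(config.depth * total_len / (2 * L)))
            lens = np.array([seqs[c].shape[0] for c in seqs], dtype=float)
            per_chrom = rng.multinomial(n_reads_hap, lens / lens.sum())
            for (chrom, seq), n_c in zip(seqs.items(), per_chrom):
                if n_c == 0 or seq.shape[0] < L:
                    continue
                starts = rng.integers(0, seq.shape[0] - L + 1, size=n_c)
                reads = seq[starts[:, None] + np.arange(L)[None, :]]
                flip = rng.random(n_c) < 0.5
                if flip.any():
                    reads[flip] = 3 - reads[flip][:, ::-1]  # revcomp (no Ns emitted)
                if config.error_rate > 0:
                    err = rng.random(reads.shape) < config.error_rate
                    shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
                    reads[err] = (reads[err] + shift) % 4
                reads_parts.append(reads)
        allreads = (np.concatenate(reads_parts) if reads_parts
                    else np.empty((0, L), dtype=np.uint8))
        yield ReadBatch(individual_id=ind, reads=allreads)


# ---------------------------------------------------------------- annotations


def emit_annotations(config: SimulationConfig, truth: TruthSet,
                     genotypes: GenotypeTable
                     ) -> tuple[dict[str, set[str]], set[str], pd.DataFrame,
                                list[HotspotMap], pd.DataFrame]:
    """eQTL sets, GWAS catalog, hotspot maps and SV deletions with truth.

    Planted structure: for ``n_planted_pairs`` (site, tissue) pairs, SNPs
    within ``planted_enrichment_radius`` of the site join the tissue's
    eQTL set at fold x the base rate; the first planted deletion length
    (default 1,500 bp, above the 1,000 bp exclusion threshold) spans the
    first site and the second (800 bp) the second site.
    """
    if config.planted_enrichment_fold < 1:
        raise ConfigError("planted enrichment fold must be >= 1")
    rng = _streams(config.seed)["annotations"]
    snp_ids = genotypes.snps["id"].to_numpy()
    snp_chrom = genotypes.snps["chrom"].to_numpy()
    snp_pos = genotypes.snps["pos"].to_numpy()
    universe = set(snp_ids)
    tissues = [f"tissue{t}" for t in range(config.n_tissues)]
    planted_pairs: list[tuple[str, str]] = []
    base = config.eqtl_base_rate
    member_prob = np.full((config.n_tissues, len(snp_ids)), base)
    n_pairs = min(config.n_planted_pairs, len(truth.sites), config.n_tissues)
    for k in range(n_pairs):
        site = truth.sites.iloc[k]
        near = (snp_chrom == site["chrom"]) & (
            np.abs(snp_pos - site["pos"]) <= config.planted_enrichment_radius)
        member_prob[k, near] = min(1.0, config.planted_enrichment_fold * base)
        planted_pairs.append((site["site_id"], tissues[k]))
    eqtl_sets = {
        t: set(snp_ids[rng.random(len(snp_ids)) < member_prob[ti]])
        for ti, t in enumerate(tissues)
    }
    truth.planted_pairs = planted_pairs

    # GWAS catalog: a random slice of the universe plus every tag SNP
    n_cat = int(round(config.gwas_catalog_fraction * len(snp_ids)))
    cat_ids = set(snp_ids[rng.choice(len(snp_ids), size=n_cat, replace=False)]) \
        if n_cat else set()
    cat_ids |= set(truth.tag_snps["snp_id"])
    traits = ["height", "bmi", "immune_disease", "lipid_level", "neuro_trait"]
    rows = [
        (rs, traits[int(rng.integers(0, len(traits)))],
         float(10 ** -rng.uniform(8, 30)), float(np.round(rng.lognormal(0, 0.2), 3)),
         int(rng.integers(10_000_000, 40_000_000)))
        for rs in sorted(cat_ids)
    ]
    gwas = pd.DataFrame(rows, columns=["rsid", "trait", "p", "or_beta", "pubmed_id"])

    # hotspot maps
    maps = []
    for mi, count in enumerate(config.hotspot_counts):
        intervals = _place_hotspots(config, truth, rng, count)
        maps.append(HotspotMap(name=["ld_map", "chip_map"][mi], intervals=intervals))

    # SV deletions
    del_rows = []
    for k, length in enumerate(config.planted_deletion_lengths):
        if k >= len(truth.sites):
            break
        site = truth.sites.iloc[k]
        start = int(site["pos"]) - length // 2
        del_rows.append((site["chrom"], start, start + length, length, site["site_id"]))
    for _ in range(config.n_background_deletions):
        chrom = list(config.chromosomes)[int(rng.integers(0, len(config.chromosomes)))]
        length = int(rng.integers(200, 5_000))
        start = int(rng.integers(0, config.chromosomes[chrom] - length))
        near = truth.sites[(truth.sites["chrom"] == chrom)
                           & (np.abs(truth.sites["pos"] - start) < 20_000)]
        if len(near):
            continue  # keep background deletions clear of implants
        del_rows.append((chrom, start, start + length, length, ""))
    deletions = pd.DataFrame(del_rows,
                             columns=["chrom", "start", "end", "length", "site_id"])
    truth.planted_deletions = deletions[deletions["site_id"] != ""].reset_index(drop=True)
    return eqtl_sets, universe, gwas, maps, deletions


def _place_hotspots(config: SimulationConfig, truth: TruthSet,
                    rng: np.random.Generator, count: int) -> pd.DataFrame:
    chroms = list(config.chromosomes)
    lengths = np.array([config.chromosomes[c] for c in chroms], dtype=float)
    per_chrom = rng.multinomial(count, lengths / lengths.sum())
    rows = []
    keep_away = config.hotspot_min_distance_from_sites
    for ci, chrom in enumerate(chroms):
        n_c = int(per_chrom[ci])
        placed = 0
        attempts = 0
        site_pos = truth.sites.loc[truth.sites["chrom"] == chrom, "pos"].to_numpy()
        while placed < n_c and attempts < 50 * max(n_c, 1):
            attempts += 1
            start = int(rng.integers(0, config.chromosomes[chrom] - config.hotspot_width))
            if keep_away and site_pos.size and np.min(np.abs(site_pos - start)) < keep_away:
                continue
            rows.append((chrom, start, start + config.hotspot_width))
            placed += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ------------------------------------------------------------------- assembly


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Generate the complete in-memory dataset for one configuration."""
    genotypes, truth = simulate_haplotypes(config)
    streams = _streams(config.seed)
    loci_rng = streams["loci"]
    # regenerate loci stream state used by simulate_haplotypes for ref ERVs
    sites_again, ref_ervs = choose_loci(config, loci_rng)
    truth.ref_ervs = ref_ervs
    reference, ltr = build_genomes(config, truth)
    eqtl, universe, gwas, maps, deletions = emit_annotations(config, truth, genotypes)
    known = truth.sites[truth.sites["known"]]
    known_bed = pd.DataFrame({
        "chrom": known["chrom"], "start": known["pos"], "end": known["pos"] + 1,
        "name": known["site_id"],
    }).reset_index(drop=True)
    ref_bed = ref_ervs.copy()
    ref_bed["name"] = [f"refERV{i:02d}" for i in range(len(ref_bed))]
    return SimulatedDataset(
        config=config,
        reference=reference,
        ltr=ltr,
        truth=truth,
        genotypes=genotypes,
        ref_erv_bed=ref_bed,
        known_nonref_bed=known_bed,
        eqtl_sets=eqtl,
        universe=universe,
        gwas_catalog=gwas,
        hotspot_maps=maps,
        sv_deletions=deletions,
        contig_allowlist=list(config.chromosomes),
    )


def write_dataset(ds: SimulatedDataset, out_dir: str | Path,
                  write_reads: bool = True) -> dict[str, Path]:
    """Emit the dataset as plain-text files (FASTA/FASTQ/VCF/BED/TSV/JSON)."""
    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _p(name: str) -> Path:
        paths[name] = out / name
        return paths[name]

    io.write_fasta(_p("reference.fa"), {c: s for c, s in ds.reference.items()})
    io.write_fasta(_p("ltr.fa"), {"LTR": ds.ltr})
    io.write_bed(_p("ref_erv.bed"), ds.ref_erv_bed)
    io.write_bed(_p("known_nonref.bed"), ds.known_nonref_bed)
    truth_bed = ds.truth.sites[["chrom", "pos"]].copy()
    truth_bed["end"] = truth_bed["pos"] + 1
    truth_bed["name"] = ds.truth.sites["site_id"]
    io.write_bed(_p("truth_sites.bed"), truth_bed[["chrom", "pos", "end", "name"]])
    io.write_vcf_genotypes(_p("genotypes.vcf"), ds.genotypes.individual_ids,
                           ds.genotypes.snps, ds.genotypes.dosage,
                           contigs=ds.config.chromosomes)
    pops = pd.DataFrame(sorted(ds.truth.populations.items()),
                        columns=["individual_id", "population"])
    io.write_tsv(_p("populations.tsv"), pops)
    eqtl_long = pd.DataFrame(
        [(t, s) for t in sorted(ds.eqtl_sets) for s in sorted(ds.eqtl_sets[t])],
        columns=["set_name", "snp_id"])
    io.write_tsv(_p("eqtl_sets.tsv"), eqtl_long)
    with open(_p("universe.txt"), "w") as fh:
        fh.write("\n".join(sorted(ds.universe)) + "\n")
    io.write_tsv(_p("gwas_catalog.tsv"), ds.gwas_catalog)
    for m in ds.hotspot_maps:
        io.write_bed(_p(f"hotspots_{m.name}.bed"), m.intervals)
    io.write_sv_vcf(_p("sv_deletions.vcf"),
                    ds.sv_deletions[["chrom", "start", "end", "length"]],
                    contigs=ds.config.chromosomes)
    with open(_p("contigs.txt"), "w") as fh:
        fh.write("\n".join(ds.contig_allowlist) + "\n")
    truth_json = {
        "sites": ds.truth.sites.to_dict(orient="records"),
        "carrier": ds.truth.carrier.tolist(),
        "individual_ids": ds.truth.individual_ids,
        "tag_snps": ds.truth.tag_snps.to_dict(orient="records"),
        "planted_pairs": ds.truth.planted_pairs,
    }
    with open(_p("truth.json"), "w") as fh:
        json.dump(truth_json, fh, indent=1)
    if write_reads:
        reads_dir = out / "reads"
        reads_dir.mkdir(exist_ok=True)
        manifest_rows = []
        for batch in ds.read_batches():
            fq = reads_dir / f"{batch.individual_id}.fastq"
            qual = "I" * ds.config.read_length
            with open(fq, "w") as fh:
                for i in range(batch.reads.shape[0]):
                    fh.write(f"@{batch.read_id(i)}\n{decode(batch.reads[i])}\n+\n{qual}\n")
            manifest_rows.append((batch.individual_id,
                                  ds.truth.populations[batch.individual_id],
                                  str(fq.relative_to(out))))
        io.write_tsv(_p("reads_manifest.tsv"),
                     pd.DataFrame(manifest_rows,
                                  columns=["individual_id", "population", "fastq"]))
    return paths
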