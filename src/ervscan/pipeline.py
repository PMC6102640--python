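"""Stage orchestration: detect -> associate -> enrich -> hotspot.

Each stage is a plain function from in-memory objects to in-memory
results plus TSV/BED/JSON files, so the CLI subcommands and the end-to-end
``run_all`` share one code path.  Every run writes a ``manifest.json``
echoing the parameters, the seed, per-stage counters and SHA-256 digests
of all outputs; re-running with the same inputs and seed reproduces all
outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import (
    GenotypeTable,
    HiSNPSet,
    compute_mds,
    define_hisnps,
    prune_and_thin,
    records_to_frame,
    scan_site,
)
from .discovery import DetectionResult, LtrReference, detect_insertions
from .enrichment import (
    AnnotationSet,
    generic_set_enrichment,
    gwas_lookup,
    per_site_tissue_enrichment,
    snp_density,
)
from .errors import InputError
from .hotspot import HotspotMap, build_matched_pool, resample_null, site_distance_table
from .simulate import SimulatedDataset, SimulationConfig, simulate_all, write_dataset


def _sites_frame(result: DetectionResult) -> pd.DataFrame:
    rows = []
    for site in result.sites:
        rows.append({
            "site_id": site.site_id, "chrom": site.chrom, "pos": site.pos,
            "classification": site.classification,
            "excluded_by_deletion": site.excluded_by_deletion,
            "prevalence": site.prevalence,
            "n_individuals": site.n_individuals,
            "n_points": len(site.member_points),
        })
    return pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "classification",
                                       "excluded_by_deletion", "prevalence",
                                       "n_individuals", "n_points"])


def write_detection(result: DetectionResult, out: Path) -> dict[str, Path]:
    out.mkdir(parents=True, exist_ok=True)
    sites = _sites_frame(result)
    bed = pd.DataFrame({
        "chrom": sites["chrom"], "start": sites["pos"], "end": sites["pos"] + 1,
        "name": sites["site_id"], "score": sites["prevalence"].round(4),
        "strand": ".",
    }) if len(sites) else pd.DataFrame(columns=["chrom", "start", "end", "name",
                                                "score", "strand"])
    paths = {
        "sites.bed": out / "sites.bed",
        "sites.tsv": out / "sites.tsv",
        "presence.tsv": out / "presence.tsv",
        "prevalence.tsv": out / "prevalence.tsv",
    }
    io.write_bed(paths["sites.bed"], bed)
    io.write_tsv(paths["sites.tsv"], sites)
    io.write_presence_matrix(paths["presence.tsv"], result.presence.site_ids,
                             result.presence.individual_ids, result.presence.calls)
    io.write_tsv(paths["prevalence.tsv"], result.prevalence)
    return paths


def stage_associate(
    genotypes: GenotypeTable,
    presence_sites: pd.DataFrame,
    presence_calls: np.ndarray,
    presence_individuals: list[str],
    *,
    mds_k: int = 6,
    window_size: int = 1_000_000,
    alpha: float = 0.05,
    seed: int = 0,
    exclude: set[str] | None = None,
) -> tuple[pd.DataFrame, list[HiSNPSet], np.ndarray]:
    """Per-population logistic scans and hiSNP sets for every usable site.

    Sites flagged ``excluded_by_deletion`` are skipped.  The MDS ancestry
    covariates come from the pruned-and-thinned genotype table.
    """
    keep = [i for i in presence_individuals if not (exclude and i in exclude)]
    if set(keep) - set(genotypes.individual_ids):
        raise InputError("presence matrix contains individuals absent from the VCF")
    genotypes = genotypes.subset_individuals(keep)
    col = {ind: j for j, ind in enumerate(presence_individuals)}
    calls = presence_calls[:, [col[i] for i in keep]]
    thinned = prune_and_thin(genotypes, seed=seed)
    mds = compute_mds(thinned, k=min(mds_k, len(keep) - 1))
    records = []
    usable = presence_sites[~presence_sites["excluded_by_deletion"].astype(bool)]
    for i, rec in zip(usable.index, usable.itertuples()):
        records.extend(scan_site(rec.site_id, calls[i], genotypes, mds))
    frame = records_to_frame(records, genotypes)
    hisnp_sets: list[HiSNPSet] = []
    if not frame.empty:
        for (site_id, pop), _ in frame.groupby(["site_id", "population"], sort=True):
            srow = presence_sites[presence_sites["site_id"] == site_id].iloc[0]
            hisnp_sets.append(define_hisnps(frame, site_id, srow["chrom"],
                                            int(srow["pos"]), pop,
                                            window_size=window_size, alpha=alpha))
    return frame, hisnp_sets, mds


def hisnp_sets_by_site(hisnp_sets: list[HiSNPSet]) -> dict[str, set[str]]:
    """Union of per-population hiSNP sets for each site."""
    out: dict[str, set[str]] = {}
    for hs in hisnp_sets:
        out.setdefault(hs.site_id, set()).update(hs.member_ids)
    return out


def write_association(frame: pd.DataFrame, hisnp_sets: list[HiSNPSet],
                      out: Path, seed: int, window_size: int) -> dict[str, Path]:
    out.mkdir(parents=True, exist_ok=True)
    paths = {"associations.tsv": out / "associations.tsv",
             "hisnps.tsv": out / "hisnps.tsv",
             "hisnp_summary.tsv": out / "hisnp_summary.tsv"}
    io.write_tsv(paths["associations.tsv"], frame)
    rows = []
    summary = []
    for hs in hisnp_sets:
        summary.append({
            "site_id": hs.site_id, "population": hs.population,
            "window_start": hs.window_start, "window_end": hs.window_end,
            "bonferroni_threshold": hs.bonferroni_threshold,
            "n_hisnps": len(hs.members),
            "min_p": hs.members["p_value"].min() if len(hs.members) else float("nan"),
            "window_definition": f"centered, total {window_size} bp", "seed": seed,
        })
        for m in hs.members.itertuples():
            rows.append({"site_id": hs.site_id, "population": hs.population,
                         "snp_id": m.snp_id, "p_value": m.p_value,
                         "beta": m.beta, "odds_ratio": m.odds_ratio,
                         "method": m.method,
                         "bonferroni_threshold": hs.bonferroni_threshold})
    io.write_tsv(paths["hisnps.tsv"], pd.DataFrame(
        rows, columns=["site_id", "population", "snp_id", "p_value", "beta",
                       "odds_ratio", "method", "bonferroni_threshold"]))
    io.write_tsv(paths["hisnp_summary.tsv"], pd.DataFrame(
        summary, columns=["site_id", "population", "window_start", "window_end",
                          "bonferroni_threshold", "n_hisnps", "min_p",
                          "window_definition", "seed"]))
    return paths


def stage_enrich(
    site_sets: dict[str, set[str]],
    eqtl_sets: dict[str, set[str]],
    universe: set[str],
    gwas_catalog: pd.DataFrame,
    sites: pd.DataFrame,
    snp_positions: dict[str, np.ndarray],
    out: Path,
) -> dict[str, Path]:
    """Per-site x tissue and pooled Fisher enrichment, GWAS join, SNP density."""
    out.mkdir(parents=True, exist_ok=True)
    annotations = [AnnotationSet(name, members & universe, universe)
                   for name, members in sorted(eqtl_sets.items())]
    long, matrix = per_site_tissue_enrichment(
        {s: snps & universe for s, snps in site_sets.items()}, annotations)
    pooled: set[str] = set().union(*site_sets.values()) & universe if site_sets else set()
    pooled_df = generic_set_enrichment(pooled, annotations)
    joined, counts = gwas_lookup(site_sets, gwas_catalog)
    with_hisnps = {s for s, snps in site_sets.items() if snps}
    sites = sites.copy()
    sites["group"] = np.where(
        sites["site_id"].isin(with_hisnps), "with_hisnps",
        np.where(sites["prevalence"].between(0.2, 0.8), "common_without", "other"))
    density = snp_density(sites[sites["group"] != "other"], snp_positions)
    paths = {name: out / name for name in
             ["enrichment_long.tsv", "enrichment_matrix.tsv", "pooled_enrichment.tsv",
              "gwas_join.tsv", "gwas_counts.tsv", "density_counts.tsv",
              "density_summary.tsv"]}
    io.write_tsv(paths["enrichment_long.tsv"], long)
    matrix.reset_index().to_csv(paths["enrichment_matrix.tsv"], sep="\t", index=False)
    io.write_tsv(paths["pooled_enrichment.tsv"], pooled_df)
    io.write_tsv(paths["gwas_join.tsv"], joined)
    io.write_tsv(paths["gwas_counts.tsv"], counts)
    io.write_tsv(paths["density_counts.tsv"], density.counts)
    io.write_tsv(paths["density_summary.tsv"], density.summary)
    return paths


def stage_hotspot(
    genome: dict[str, np.ndarray],
    sites: pd.DataFrame,
    maps: list[HotspotMap],
    out: Path,
    *,
    allowlist: list[str] | None = None,
    reps: int = 1000,
    seed: int = 0,
) -> dict[str, Path]:
    """Matched-pool resampling test against each hotspot map."""
    out.mkdir(parents=True, exist_ok=True)
    if allowlist is not None:
        sites = sites[sites["chrom"].isin(allowlist)].reset_index(drop=True)
    pool = build_matched_pool(genome, sites)
    paths: dict[str, Path] = {}
    summary = []
    for mi, hmap in enumerate(maps):
        res = resample_null(pool, sites, hmap, reps=reps, seed=seed + mi)
        dist = site_distance_table(sites, genome, hmap)
        paths[f"distances_{hmap.name}.tsv"] = out / f"distances_{hmap.name}.tsv"
        io.write_tsv(paths[f"distances_{hmap.name}.tsv"], dist)
        paths[f"null_means_{hmap.name}.tsv"] = out / f"null_means_{hmap.name}.tsv"
        pd.DataFrame({"null_mean": res.null_means}).to_csv(
            paths[f"null_means_{hmap.name}.tsv"], sep="\t", index=False)
        summary.append({
            "map": hmap.name, "observed_mean_distance": res.observed_mean_distance,
            "null_mean": float(res.null_means.mean()),
            "empirical_p_upper": res.empirical_p_upper,
            "empirical_p_lower": res.empirical_p_lower,
            "reps": res.reps, "seed": res.seed,
        })
    paths["hotspot_summary.json"] = out / "hotspot_summary.json"
    with open(paths["hotspot_summary.json"], "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    tol = pd.DataFrame(sorted(pool.gc_tolerance.items()),
                       columns=["site_id", "gc_tolerance"])
    tol["n_candidates"] = [len(pool.candidates[s]) for s in tol["site_id"]]
    paths["matched_pool.tsv"] = out / "matched_pool.tsv"
    io.write_tsv(paths["matched_pool.tsv"], tol)
    return paths


def run_all(config: SimulationConfig, out_dir: str | Path, *,
            reps: int = 1000, write_reads: bool = False,
            dataset: SimulatedDataset | None = None) -> dict:
    """Simulate, then run every analysis stage; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = dataset or simulate_all(config)
    sim_paths = write_dataset(ds, out / "sim", write_reads=write_reads)

    detection = detect_insertions(
        ds.read_batches(), ds.reference, LtrReference("LTR", ds.ltr),
        reference_erv_intervals=ds.ref_erv_bed,
        known_nonref_sites=ds.known_nonref_bed,
        sv_deletions=ds.sv_deletions,
        groups=ds.truth.populations,
    )
    det_paths = write_detection(detection, out / "detect")

    sites = _sites_frame(detection)
    frame, hisnp_sets, _ = stage_associate(
        ds.genotypes, sites, detection.presence.calls,
        detection.presence.individual_ids, seed=config.seed)
    assoc_paths = write_association(frame, hisnp_sets, out / "associate",
                                    config.seed, 1_000_000)

    site_sets = hisnp_sets_by_site(hisnp_sets)
    for sid in sites["site_id"]:
        site_sets.setdefault(sid, set())
    snp_positions = {
        c: grp["pos"].to_numpy()
        for c, grp in ds.genotypes.snps.groupby("chrom")
    }
    enr_paths = stage_enrich(site_sets, ds.eqtl_sets, ds.universe,
                             ds.gwas_catalog, sites, snp_positions, out / "enrich")

    hot_paths = stage_hotspot(ds.reference, sites, ds.hotspot_maps, out / "hotspot",
                              allowlist=ds.contig_allowlist, reps=reps,
                              seed=config.seed)

    counters = dict(detection.counters)
    counters["hisnp_sets"] = len(hisnp_sets)
    counters["hisnps_total"] = int(sum(len(h.members) for h in hisnp_sets))
    all_paths = {}
    for group in (sim_paths, det_paths, assoc_paths, enr_paths, hot_paths):
        for name, p in group.items():
            all_paths[str(Path(p).relative_to(out))] = io.sha256_of(p)
    manifest = {
        "subcommand": "run-all",
        "seed": config.seed,
        "parameters": _config_dict(config),
        "counters": counters,
        "outputs": all_paths,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _config_dict(config: SimulationConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["hotspot_counts"] = list(config.hotspot_counts)
    raw["planted_deletion_lengths"] = list(config.planted_deletion_lengths)
    return raw
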