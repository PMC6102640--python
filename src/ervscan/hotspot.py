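"""Matched resampling test of insertion-site distance to recombination hotspots.

Are polymorphic insertions farther from recombination hotspots than
expected by chance?  The null model draws, for each insertion site, a
random 2 kb genomic segment on the *same chromosome* with *identical*
flanking GC content (rounded to 0.1%), and records the mean distance of
the drawn locations to the nearest hotspot.  Repeating the draw (default
1,000 times) gives the null distribution of mean distances; the
empirical p-value for the observed mean is (r + 1) / (reps + 1) where r
counts null means at least as extreme.  The upper tail ("farther than
expected") is the primary result; the lower tail is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError


@dataclass
class HotspotMap:
    """Named set of hotspot intervals, sorted per chromosome."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self):
        df = self.intervals
        if not df.empty and (df["end"] <= df["start"]).any():
            raise InputError(f"hotspot map {self.name!r} has invalid intervals")
        self.intervals = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in self.intervals.groupby("chrom"):
            self._by_chrom[str(chrom)] = (
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
            )

    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray] | None:
        return self._by_chrom.get(chrom)


@dataclass
class MatchedPool:
    """Per-site candidate 2 kb segment centers, chromosome- and GC-matched."""

    site_ids: list[str]
    candidates: dict[str, pd.DataFrame]  # site_id -> chrom, center, gc_percent
    gc_tolerance: dict[str, float]       # widened tolerance actually used (0.0 = exact)
    segment: int = 2000


@dataclass
class ResamplingResult:
    map_name: str
    observed_mean_distance: float
    null_means: np.ndarray
    empirical_p_upper: float
    empirical_p_lower: float
    reps: int
    seed: int

    @property
    def empirical_p(self) -> float:
        """Primary (upper-tail) empirical p-value."""
        return self.empirical_p_upper


# ------------------------------------------------------------------ distances


def distance_to_nearest(site_pos: int, chrom: str, hotspots: HotspotMap) -> float:
    """bp distance from a position to the nearest hotspot interval.

    Zero when the position falls inside an interval; NaN (flagged
    missing) when the chromosome is absent from the map.
    """
    arrs = hotspots.arrays(chrom)
    if arrs is None:
        return float("nan")
    starts, ends = arrs
    return float(_distances_vec(np.asarray([site_pos], dtype=np.int64), starts, ends)[0])


def _distances_vec(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Vectorized distance of positions to nearest [start, end) interval."""
    i = np.searchsorted(starts, pos, side="right") - 1
    # distance past the end of the preceding (or containing) interval
    prev = np.where(i >= 0, np.maximum(pos - (ends[np.maximum(i, 0)] - 1), 0), np.iinfo(np.int64).max)
    j = np.minimum(i + 1, starts.shape[0] - 1)
    nxt = np.where(i + 1 < starts.shape[0], np.maximum(starts[j] - pos, 0), np.iinfo(np.int64).max)
    return np.minimum(prev, nxt).astype(np.float64)


# -------------------------------------------------------------------- GC match


def round_tenth(x: float | np.ndarray) -> np.ndarray | float:
    """Round half-up to one decimal (50.05 -> 50.1), as GC percent is binned."""
    return np.floor(np.asarray(x) * 10.0 + 0.5) / 10.0


def gc_percent_2kb(genome: dict[str, np.ndarray], chrom: str, pos: int,
                   window: int = 2000) -> float:
    """GC percent of the window centered on ``pos``, rounded to 0.1.

    The window is truncated at chromosome edges; an all-N window returns
    NaN (site excluded from matching).  Encoded bases: C=1, G=2, N=4.
    """
    seq = genome[chrom]
    half = window // 2
    lo, hi = max(0, pos - half), min(seq.shape[0], pos + half)
    win = seq[lo:hi]
    non_n = win != 4
    n_valid = int(non_n.sum())
    if n_valid == 0:
        return float("nan")
    gc = int(((win == 1) | (win == 2)).sum())
    return float(round_tenth(100.0 * gc / n_valid))


def tile_gc(genome: dict[str, np.ndarray], segment: int = 2000) -> pd.DataFrame:
    """Non-overlapping ``segment``-bp tiling of every chromosome with GC%.

    Tiling starts at coordinate 0; a trailing partial segment is dropped.
    Returns chrom, start, center, gc_percent (rounded to 0.1; NaN for
    all-N segments).
    """
    rows = []
    for chrom, seq in genome.items():
        n_seg = seq.shape[0] // segment
        if n_seg == 0:
            continue
        tiles = seq[: n_seg * segment].reshape(n_seg, segment)
        gc = ((tiles == 1) | (tiles == 2)).sum(axis=1).astype(np.float64)
        valid = (tiles != 4).sum(axis=1).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(valid > 0, round_tenth(100.0 * gc / np.maximum(valid, 1)), np.nan)
        starts = np.arange(n_seg, dtype=np.int64) * segment
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "center": starts + segment // 2,
            "gc_percent": pct,
        }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "center", "gc_percent"])


def build_matched_pool(
    genome: dict[str, np.ndarray],
    sites: pd.DataFrame,
    segment: int = 2000,
    max_widen_steps: int = 1000,
) -> MatchedPool:
    """Chromosome- and GC-matched candidate segments for each site.

    Candidates share the site's chromosome and have rounded GC identical
    to the site's 2 kb flanking GC.  A site with no exact-GC candidate
    widens its tolerance in ±0.1 steps until at least one segment
    matches; the tolerance used is recorded per site.
    """
    tiles = tile_gc(genome, segment)
    pool: dict[str, pd.DataFrame] = {}
    tol: dict[str, float] = {}
    site_ids: list[str] = []
    for rec in sites.itertuples():
        sid = str(rec.site_id)
        site_ids.append(sid)
        gc = gc_percent_2kb(genome, rec.chrom, int(rec.pos), window=segment)
        if not np.isfinite(gc):
            pool[sid] = tiles.iloc[0:0]
            tol[sid] = float("nan")
            continue
        on_chrom = tiles[(tiles["chrom"] == rec.chrom) & np.isfinite(tiles["gc_percent"])]
        chosen = on_chrom.iloc[0:0]
        used = 0.0
        for step in range(max_widen_steps + 1):
            used = round(0.1 * step, 1)
            sel = np.abs(on_chrom["gc_percent"].to_numpy() - gc) <= used + 1e-9
            if sel.any():
                chosen = on_chrom[sel]
                break
        pool[sid] = chosen.reset_index(drop=True)
        tol[sid] = used
    return MatchedPool(site_ids, pool, tol, segment)


# ------------------------------------------------------------------ resampling


def resample_null(
    pool: MatchedPool,
    sites: pd.DataFrame,
    hotspots: HotspotMap,
    reps: int = 1000,
    seed: int = 0,
) -> ResamplingResult:
    """Matched-null resampling test of mean distance to nearest hotspot.

    Each replicate draws one candidate per site (with replacement across
    replicates) and records the mean of their distances to the nearest
    hotspot.  Sites whose chromosome is absent from the hotspot map are
    excluded (flagged missing).  Empirical p = (r + 1) / (reps + 1).
    """
    if reps < 1:
        raise ConfigError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    observed: list[float] = []
    site_cand_dists: list[np.ndarray] = []
    for rec in sites.itertuples():
        sid = str(rec.site_id)
        arrs = hotspots.arrays(str(rec.chrom))
        if arrs is None:
            continue
        cands = pool.candidates.get(sid)
        if cands is None or cands.empty:
            continue
        starts, ends = arrs
        observed.append(
            float(_distances_vec(np.asarray([int(rec.pos)], np.int64), starts, ends)[0])
        )
        site_cand_dists.append(
            _distances_vec(cands["center"].to_numpy(np.int64), starts, ends)
        )
    if not observed:
        raise InputError("no usable sites: empty pools or chromosomes missing from map")
    obs_mean = float(np.mean(observed))
    n_sites = len(observed)
    draws = np.empty((reps, n_sites), dtype=np.float64)
    for j, dists in enumerate(site_cand_dists):
        idx = rng.integers(0, dists.shape[0], size=reps)
        draws[:, j] = dists[idx]
    null_means = draws.mean(axis=1)
    r_upper = int(np.sum(null_means >= obs_mean))
    r_lower = int(np.sum(null_means <= obs_mean))
    return ResamplingResult(
        map_name=hotspots.name,
        observed_mean_distance=obs_mean,
        null_means=null_means,
        empirical_p_upper=(r_upper + 1) / (reps + 1),
        empirical_p_lower=(r_lower + 1) / (reps + 1),
        reps=reps,
        seed=seed,
    )


def site_distance_table(sites: pd.DataFrame, genome: dict[str, np.ndarray],
                        hotspots: HotspotMap, segment: int = 2000) -> pd.DataFrame:
    """Per-site distance to nearest hotspot plus flanking GC percent."""
    rows = []
    for rec in sites.itertuples():
        rows.append({
            "site_id": str(rec.site_id), "chrom": rec.chrom, "pos": int(rec.pos),
            "distance": distance_to_nearest(int(rec.pos), str(rec.chrom), hotspots),
            "gc_percent": gc_percent_2kb(genome, str(rec.chrom), int(rec.pos), segment),
        })
    return pd.DataFrame(rows)
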