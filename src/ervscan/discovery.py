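"""Discovery of polymorphic ERV insertions from chimeric reads.

The detection model: a read spanning an insertion junction partially
matches the element's LTR.  The non-LTR portion of such a chimeric read
(the *flank*) is extracted, mapped back to the host genome, and the
genomic base adjacent to the trimmed LTR junction is called an insertion
point.  Points within a fixed window (default 1,000 bp) are grouped by
single-linkage chaining into one insertion site; an individual is called
a carrier of a site if at least one of their chimeric reads supports it,
and absence is inferred from the lack of any supporting read.

Sites are then classified against a reference ERV annotation and a list
of previously reported non-reference insertions (both intersected with a
±100 bp pad), sites flanked by large deletions (> 1,000 bp) are excluded
as unreliable, and carrier prevalence is estimated per population group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from ._seq import kmer_codes, kmer_codes_2d, revcomp
from .align import AlignParams, LocalAlignment, SeedExtendAligner
from .errors import ConfigError, InputError

LtrEnd = Literal["left_of_ltr", "right_of_ltr"]
Orientation = Literal["forward", "reverse_complement"]


@dataclass
class LtrReference:
    """The LTR query sequence reads are screened against."""

    name: str
    sequence: np.ndarray  # encoded uint8

    def __post_init__(self):
        if self.sequence.shape[0] == 0:
            raise ConfigError("empty LTR sequence")


@dataclass
class ReadBatch:
    """All reads of one individual, as an equal-length encoded matrix."""

    individual_id: str
    reads: np.ndarray                       # (n_reads, read_len) uint8
    quals: np.ndarray | None = None         # (n_reads, read_len) phred, optional
    read_ids: list[str] | None = None

    def read_id(self, i: int) -> str:
        if self.read_ids is not None:
            return self.read_ids[i]
        return f"{self.individual_id}.r{i}"


@dataclass(frozen=True)
class ChimericFlank:
    read_id: str
    individual_id: str
    flank: np.ndarray           # encoded host-side portion, in read orientation
    ltr_end: LtrEnd
    orientation: Orientation    # orientation of the read's LTR alignment
    junction: Literal["left", "right"]  # which end of `flank` abuts the LTR


@dataclass(frozen=True)
class FlankPlacement:
    flank: ChimericFlank
    chrom: str
    start: int
    end: int
    strand: str
    unique: bool


@dataclass(frozen=True)
class InsertionPoint:
    chrom: str
    pos: int
    orientation: Orientation
    individual_id: str
    read_id: str


@dataclass
class InsertionSite:
    site_id: str
    chrom: str
    pos: int
    member_points: list[InsertionPoint]
    classification: str = "unconfirmed"
    excluded_by_deletion: bool = False
    prevalence: float = float("nan")

    @property
    def n_individuals(self) -> int:
        return len({p.individual_id for p in self.member_points})


@dataclass
class PresenceMatrix:
    site_ids: list[str]
    individual_ids: list[str]
    calls: np.ndarray  # (n_sites, n_individuals) int8 in {0,1}


# ------------------------------------------------------------- read filtering


def quality_filter(batch: ReadBatch, min_mean_phred: float = 20.0) -> ReadBatch:
    """Drop reads whose mean base quality falls below the threshold.

    Batches without quality information pass through unchanged.
    """
    if batch.quals is None:
        return batch
    keep = batch.quals.mean(axis=1) >= min_mean_phred
    ids = [batch.read_id(i) for i in np.nonzero(keep)[0]] if not keep.all() else batch.read_ids
    if keep.all():
        return batch
    return ReadBatch(batch.individual_id, batch.reads[keep], batch.quals[keep], ids)


# ------------------------------------------------------- alignment to the LTR


SCREEN_K = 12  # pre-screen k-mer size; 4^12 bool lookup table (16 MB)


def _ltr_screen_table(ltr: np.ndarray, k: int = SCREEN_K) -> np.ndarray:
    """Boolean membership table over all k-mers of both LTR strands."""
    fwd, vf = kmer_codes(ltr, k)
    rev, vr = kmer_codes(revcomp(ltr), k)
    table = np.zeros(4**k, dtype=bool)
    table[np.concatenate([fwd[vf], rev[vr]]).astype(np.int64)] = True
    return table


def align_reads_to_ltr(
    batch: ReadBatch,
    ltr: LtrReference,
    params: AlignParams | None = None,
    chunk_rows: int = 65536,
    screen_stride: int = 4,
) -> list[tuple[int, LocalAlignment]]:
    """Local alignments of reads against the LTR query.

    A vectorized k-mer table screen discards reads sharing no 12-mer
    with either LTR strand before per-read alignment.  The screen
    samples k-mer starts every ``screen_stride`` bases, which still
    guarantees a hit for any read overlapping the LTR by at least
    ``12 + screen_stride - 1`` exactly matching bases (15 bp at the
    defaults, below the 20 bp minimum aligned length); its rare chance
    matches are rejected by the alignment stage.  Reads with no
    qualifying local alignment are omitted from the result.
    """
    params = params or AlignParams()
    table = _ltr_screen_table(ltr.sequence)
    aligner = SeedExtendAligner({ltr.name: ltr.sequence}, params)
    out: list[tuple[int, LocalAlignment]] = []
    n = batch.reads.shape[0]
    for lo in range(0, n, chunk_rows):
        chunk = batch.reads[lo : lo + chunk_rows]
        codes = kmer_codes_2d(chunk, SCREEN_K, stride=screen_stride)
        rows = np.nonzero(table[codes.astype(np.int64)].any(axis=1))[0]
        for r in rows:
            aln = aligner.align(chunk[r])
            if aln is not None:
                out.append((lo + int(r), aln))
    return out


def extract_chimeric_flanks(
    alignments: Sequence[tuple[int, LocalAlignment]],
    batch: ReadBatch,
    min_flank_length: int = 20,
) -> list[ChimericFlank]:
    """Non-LTR read portions that extend past the LTR-aligned interval.

    One flank is emitted per read end with >= ``min_flank_length`` host
    bases; fully-LTR reads yield nothing.
    """
    flanks: list[ChimericFlank] = []
    for idx, aln in alignments:
        read = batch.reads[idx]
        orientation: Orientation = "forward" if aln.strand == "+" else "reverse_complement"
        rid = batch.read_id(idx)
        left = read[: aln.query_start]
        right = read[aln.query_end :]
        if left.shape[0] >= min_flank_length:
            # read part preceding the LTR: for a forward LTR alignment this
            # flank sits 5' of the LTR start, for a reverse one past its end
            flanks.append(
                ChimericFlank(
                    read_id=rid,
                    individual_id=batch.individual_id,
                    flank=left,
                    ltr_end="left_of_ltr" if orientation == "forward" else "right_of_ltr",
                    orientation=orientation,
                    junction="right",
                )
            )
        if right.shape[0] >= min_flank_length:
            flanks.append(
                ChimericFlank(
                    read_id=rid,
                    individual_id=batch.individual_id,
                    flank=right,
                    ltr_end="right_of_ltr" if orientation == "forward" else "left_of_ltr",
                    orientation=orientation,
                    junction="left",
                )
            )
    return flanks


# ------------------------------------------------------ mapping to the genome


def map_flanks_to_genome(
    flanks: Sequence[ChimericFlank],
    genome_aligner: SeedExtendAligner,
    discard_multimapping: bool = True,
) -> list[FlankPlacement]:
    """Place flanks on the host genome.

    The flank base at the LTR junction must itself be aligned (the
    insertion point is read off it), so placements not reaching that
    flank end are dropped.  Multi-mapping flanks are flagged and, by
    default, discarded.
    """
    placements: list[FlankPlacement] = []
    for fl in flanks:
        aln = genome_aligner.align(fl.flank)
        if aln is None:
            continue
        # junction end of the flank, in flank coordinates
        if fl.junction == "right" and aln.query_end != fl.flank.shape[0]:
            continue
        if fl.junction == "left" and aln.query_start != 0:
            continue
        unique = aln.is_unique
        if discard_multimapping and not unique:
            continue
        placements.append(
            FlankPlacement(
                flank=fl,
                chrom=aln.chrom,
                start=aln.ref_start,
                end=aln.ref_end,
                strand=aln.strand,
                unique=unique,
            )
        )
    return placements


def call_insertion_points(placements: Sequence[FlankPlacement]) -> list[InsertionPoint]:
    """Genomic coordinate of the flank base adjacent to the LTR junction.

    For a forward placement the junction end of the flank keeps its read
    orientation; on the reverse strand the junction end lands on the
    opposite genomic side.  Forward and reverse points carry their stream
    label and are only merged at clustering.
    """
    points: list[InsertionPoint] = []
    for pl in placements:
        junction_on_right = (pl.flank.junction == "right") == (pl.strand == "+")
        pos = pl.end - 1 if junction_on_right else pl.start
        orientation: Orientation = "forward" if pl.strand == "+" else "reverse_complement"
        points.append(
            InsertionPoint(
                chrom=pl.chrom,
                pos=int(pos),
                orientation=orientation,
                individual_id=pl.flank.individual_id,
                read_id=pl.flank.read_id,
            )
        )
    return points


# ----------------------------------------------------------------- clustering


def cluster_insertion_points(
    points: Sequence[InsertionPoint], window: int = 1000
) -> list[InsertionSite]:
    """Single-linkage grouping of insertion points within ``window`` bp.

    Forward and reverse-complement streams are merged before grouping.
    Consecutive sorted points <= window apart are chained transitively;
    the representative position is the median member position (ties to
    the lower coordinate).
    """
    if window <= 0:
        raise ConfigError(f"cluster window must be positive, got {window}")
    by_chrom: dict[str, list[InsertionPoint]] = {}
    for p in points:
        by_chrom.setdefault(p.chrom, []).append(p)
    sites: list[InsertionSite] = []
    for chrom in sorted(by_chrom):
        pts = sorted(by_chrom[chrom], key=lambda p: p.pos)
        cluster: list[InsertionPoint] = [pts[0]]
        for p in pts[1:]:
            if p.pos - cluster[-1].pos <= window:
                cluster.append(p)
            else:
                sites.append(_make_site(chrom, cluster))
                cluster = [p]
        sites.append(_make_site(chrom, cluster))
    return sites


def _make_site(chrom: str, members: list[InsertionPoint]) -> InsertionSite:
    positions = sorted(p.pos for p in members)
    rep = positions[(len(positions) - 1) // 2]  # median, ties to lower
    return InsertionSite(
        site_id=f"{chrom}_{rep}", chrom=chrom, pos=rep, member_points=list(members)
    )


def call_presence_absence(
    sites: Sequence[InsertionSite], individual_ids: Sequence[str]
) -> PresenceMatrix:
    """Binary presence calls: >= 1 supporting chimeric read => present."""
    idx = {ind: j for j, ind in enumerate(individual_ids)}
    calls = np.zeros((len(sites), len(individual_ids)), dtype=np.int8)
    for i, site in enumerate(sites):
        for p in site.member_points:
            j = idx.get(p.individual_id)
            if j is None:
                raise InputError(
                    f"individual {p.individual_id!r} has insertion evidence but is "
                    "not in the declared cohort"
                )
            calls[i, j] = 1
    return PresenceMatrix([s.site_id for s in sites], list(individual_ids), calls)


# ------------------------------------------------------ classification/filter


def _within_padded(pos: int, intervals: pd.DataFrame, pad: int) -> bool:
    if intervals.empty:
        return False
    s = intervals["start"].to_numpy()
    e = intervals["end"].to_numpy()
    return bool(np.any((pos >= s - pad) & (pos < e + pad)))


def classify_sites(
    sites: Sequence[InsertionSite],
    reference_erv_intervals: pd.DataFrame,
    known_nonref_sites: pd.DataFrame,
    pad: int = 100,
) -> list[InsertionSite]:
    """Label each site reference / non_reference_known / unconfirmed.

    A site is *reference* when its position falls within any annotated
    reference ERV interval expanded by ``pad`` bp, else
    *non_reference_known* when within ``pad`` of a previously reported
    non-reference insertion, else *unconfirmed* (indistinguishable from
    e.g. an SVA without targeted sequencing).
    """
    for tbl, label in ((reference_erv_intervals, "reference ERV"), (known_nonref_sites, "known sites")):
        if not tbl.empty and (tbl["end"] < tbl["start"]).any():
            raise InputError(f"malformed {label} intervals: end < start")
    out = []
    for site in sites:
        ref = reference_erv_intervals[reference_erv_intervals["chrom"] == site.chrom] \
            if not reference_erv_intervals.empty else reference_erv_intervals
        known = known_nonref_sites[known_nonref_sites["chrom"] == site.chrom] \
            if not known_nonref_sites.empty else known_nonref_sites
        if _within_padded(site.pos, ref, pad):
            cls = "reference"
        elif _within_padded(site.pos, known, pad):
            cls = "non_reference_known"
        else:
            cls = "unconfirmed"
        out.append(replace_classification(site, cls))
    return out


def replace_classification(site: InsertionSite, cls: str) -> InsertionSite:
    return InsertionSite(
        site_id=site.site_id,
        chrom=site.chrom,
        pos=site.pos,
        member_points=site.member_points,
        classification=cls,
        excluded_by_deletion=site.excluded_by_deletion,
        prevalence=site.prevalence,
    )


def filter_deletion_overlap(
    sites: Sequence[InsertionSite],
    sv_deletions: pd.DataFrame,
    min_del_len: int = 1000,
    pad: int = 1000,
) -> list[InsertionSite]:
    """Flag sites whose flanking region is spanned by a large deletion.

    A deletion longer than ``min_del_len`` overlapping the site position
    ± ``pad`` (the cluster window) makes the presence/absence signal
    unreliable; such sites are marked ``excluded_by_deletion``.
    """
    out = []
    big = sv_deletions[sv_deletions["length"] > min_del_len] if not sv_deletions.empty else sv_deletions
    for site in sites:
        excluded = False
        if not big.empty:
            d = big[big["chrom"] == site.chrom]
            if not d.empty:
                s = d["start"].to_numpy()
                e = d["end"].to_numpy()
                excluded = bool(np.any((s <= site.pos + pad) & (e > site.pos - pad)))
        new = replace_classification(site, site.classification)
        new.excluded_by_deletion = excluded
        out.append(new)
    return out


def estimate_prevalence(
    matrix: PresenceMatrix, groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-site carrier fraction, overall and (optionally) per group.

    Group-averaged prevalence is the unweighted mean of per-group
    prevalences, mirroring a super-population average.
    """
    calls = matrix.calls
    df = pd.DataFrame({"site_id": matrix.site_ids, "prevalence": calls.mean(axis=1)})
    if groups is not None:
        labels = [groups[i] for i in matrix.individual_ids]
        uniq = sorted(set(labels))
        per_group = []
        for g in uniq:
            cols = [j for j, l in enumerate(labels) if l == g]
            if not cols:
                raise InputError(f"empty population group {g!r}")
            col = calls[:, cols].mean(axis=1)
            df[f"prevalence_{g}"] = col
            per_group.append(col)
        df["prevalence_group_avg"] = np.mean(per_group, axis=0)
    return df


# ------------------------------------------------------------------ high level


@dataclass
class DetectionResult:
    sites: list[InsertionSite]
    presence: PresenceMatrix
    prevalence: pd.DataFrame
    counters: dict[str, int]


def detect_insertions(
    batches: Iterable[ReadBatch],
    genome: dict[str, np.ndarray],
    ltr: LtrReference,
    *,
    min_flank_length: int = 20,
    cluster_window: int = 1000,
    min_mean_phred: float = 20.0,
    ltr_params: AlignParams | None = None,
    genome_params: AlignParams | None = None,
    reference_erv_intervals: pd.DataFrame | None = None,
    known_nonref_sites: pd.DataFrame | None = None,
    sv_deletions: pd.DataFrame | None = None,
    groups: dict[str, str] | None = None,
) -> DetectionResult:
    """Run the full per-cohort detection pipeline on read batches."""
    if ltr.sequence.shape[0] < 2 * min_flank_length:
        raise ConfigError("LTR shorter than twice the minimum flank length")
    genome_aligner = SeedExtendAligner(genome, genome_params or AlignParams())
    counters = {"reads_in": 0, "reads_ltr_aligned": 0, "chimeric_flanks": 0,
                "flanks_mapped": 0, "insertion_points": 0}
    all_points: list[InsertionPoint] = []
    individual_ids: list[str] = []
    for batch in batches:
        individual_ids.append(batch.individual_id)
        counters["reads_in"] += batch.reads.shape[0]
        batch = quality_filter(batch, min_mean_phred)
        alns = align_reads_to_ltr(batch, ltr, ltr_params)
        counters["reads_ltr_aligned"] += len(alns)
        flanks = extract_chimeric_flanks(alns, batch, min_flank_length)
        counters["chimeric_flanks"] += len(flanks)
        placements = map_flanks_to_genome(flanks, genome_aligner)
        counters["flanks_mapped"] += len(placements)
        points = call_insertion_points(placements)
        counters["insertion_points"] += len(points)
        all_points.extend(points)
    sites = cluster_insertion_points(all_points, cluster_window) if all_points else []
    counters["sites"] = len(sites)
    if reference_erv_intervals is not None or known_nonref_sites is not None:
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        sites = classify_sites(
            sites,
            reference_erv_intervals if reference_erv_intervals is not None else empty,
            known_nonref_sites if known_nonref_sites is not None else empty,
        )
    if sv_deletions is not None:
        sites = filter_deletion_overlap(sites, sv_deletions, pad=cluster_window)
    presence = call_presence_absence(sites, individual_ids)
    prevalence = estimate_prevalence(presence, groups)
    for site, prev in zip(sites, prevalence["prevalence"]):
        site.prevalence = float(prev)
    return DetectionResult(sites, presence, prevalence, counters)
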