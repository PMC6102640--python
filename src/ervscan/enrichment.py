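"""Annotation enrichment of hiSNP sets and SNP-density comparisons.

The central statistic is a two-sided Fisher exact test on the 2x2 table
(a = hiSNP & annotated, b = hiSNP & not, c = not hiSNP & annotated,
d = neither) over an explicit background SNP universe, with the odds
ratio (a*d)/(c*b).  The p-value is computed by full hypergeometric
enumeration with the point-probability rule: the sum of probabilities of
all tables (with the observed margins) no more likely than the observed
one.  Multiple tests are adjusted with Benjamini-Hochberg FDR.

Also here: the GWAS-catalog rsID join and per-site SNP-density counts in
1 Mb / 500 kb / 100 kb centered windows compared between site groups
with an equal-variance Student's t-test.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

_RSID_RE = re.compile(r"^rs\d+$")


@dataclass
class AnnotationSet:
    """A named SNP set (e.g. the eQTLs of one tissue) over a background universe."""

    name: str
    members: set[str]
    universe: set[str]

    def __post_init__(self):
        if not self.universe:
            raise InputError(f"annotation set {self.name!r} has an empty universe")
        if not self.members <= self.universe:
            raise InputError(f"annotation set {self.name!r}: members not a subset of universe")


@dataclass
class EnrichmentResult:
    query_name: str
    annotation_name: str
    a: int  # query & annotated
    b: int  # query & not annotated
    c: int  # not query & annotated
    d: int  # neither
    odds_ratio: float
    p_value: float
    fdr_q: float = float("nan")
    or_defined: bool = True

    def as_row(self) -> dict:
        return {
            "query": self.query_name, "annotation": self.annotation_name,
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "odds_ratio": self.odds_ratio, "p_value": self.p_value,
            "fdr_q": self.fdr_q, "or_defined": self.or_defined,
        }


# ------------------------------------------------------------- Fisher's exact


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums P(table) over every table with the observed margins whose
    point probability does not exceed the observed one (with a small
    relative tolerance for float ties).
    """
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(p, 1.0)


def _table_odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """(a*d)/(c*b) with zero cells reported as inf/0/NaN and flagged."""
    num, den = a * d, c * b
    if den == 0:
        return (float("nan") if num == 0 else float("inf")), False
    if num == 0:
        return 0.0, False
    return num / den, True


def fisher_enrichment(query_snps: set[str], annotation: AnnotationSet,
                      query_name: str = "query") -> EnrichmentResult:
    """Fisher enrichment of a query SNP set in one annotation set."""
    if not query_snps <= annotation.universe:
        raise InputError("query SNPs must lie inside the annotation universe")
    ann = annotation.members
    a = len(query_snps & ann)
    b = len(query_snps) - a
    c = len(ann) - a
    d = len(annotation.universe) - a - b - c
    odds, defined = _table_odds_ratio(a, b, c, d)
    p = fisher_exact_p(a, b, c, d)
    return EnrichmentResult(query_name, annotation.name, a, b, c, d, odds, p,
                            or_defined=defined)


def apply_bh(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Attach Benjamini-Hochberg q-values across a family of results."""
    ps = np.array([r.p_value for r in results])
    if ps.size:
        qs = stats.false_discovery_control(ps, method="bh")
        for r, q in zip(results, qs):
            r.fdr_q = float(q)
    return results


def pooled_enrichment(all_hisnp_sets: dict[str, set[str]],
                      annotation: AnnotationSet) -> EnrichmentResult:
    """Enrichment of the union of per-site hiSNP sets (duplicates counted once)."""
    pooled: set[str] = set().union(*all_hisnp_sets.values()) if all_hisnp_sets else set()
    return fisher_enrichment(pooled, annotation, query_name="pooled")


def per_site_tissue_enrichment(
    hisnp_sets: dict[str, set[str]], annotations: list[AnnotationSet]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One Fisher test per (site, annotation).

    Returns the long-format table (BH-adjusted across the whole matrix)
    and a sites x annotations matrix of -log10 p, ready for a heat map.
    Sites with an empty hiSNP set yield flagged-undefined rows.
    """
    results: list[EnrichmentResult] = []
    for site, snps in hisnp_sets.items():
        for ann in annotations:
            if not snps:
                results.append(EnrichmentResult(site, ann.name, 0, 0, len(ann.members),
                                                len(ann.universe) - len(ann.members),
                                                float("nan"), float("nan"),
                                                or_defined=False))
            else:
                results.append(fisher_enrichment(snps, ann, query_name=site))
    defined = [r for r in results if np.isfinite(r.p_value)]
    apply_bh(defined)
    columns = ["query", "annotation", "a", "b", "c", "d", "odds_ratio",
               "p_value", "fdr_q", "or_defined"]
    if not results:
        return (pd.DataFrame(columns=columns),
                pd.DataFrame(columns=pd.Index([], name="annotation")))
    long = pd.DataFrame([r.as_row() for r in results], columns=columns)
    matrix = long.pivot(index="query", columns="annotation", values="p_value")
    matrix = -np.log10(matrix)
    return long, matrix


def generic_set_enrichment(
    query_snps: set[str], annotation_sets: list[AnnotationSet], fdr_alpha: float = 0.05
) -> pd.DataFrame:
    """Flat-set Fisher + BH enrichment across many annotation sets.

    A generic replacement for ontology web tools: each named set is
    tested against the same universe and ranked by q-value; rows with
    ``significant`` True have q < ``fdr_alpha``.
    """
    results = [fisher_enrichment(query_snps, ann) for ann in annotation_sets]
    apply_bh(results)
    df = pd.DataFrame([r.as_row() for r in results])
    df["significant"] = df["fdr_q"] < fdr_alpha
    return df.sort_values(["fdr_q", "p_value", "annotation"], kind="stable").reset_index(drop=True)


# ------------------------------------------------------------ GWAS catalog join


def gwas_lookup(hisnp_sets: dict[str, set[str]], catalog: pd.DataFrame
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join hiSNP sets against a GWAS-catalog style table on rsID.

    Returns the joined long table and per-site counts of annotated
    hiSNPs and distinct traits.  Malformed rsIDs in the catalog are
    skipped with a warning.
    """
    if "rsid" not in catalog.columns or "trait" not in catalog.columns:
        raise InputError("GWAS catalog table needs 'rsid' and 'trait' columns")
    ok = catalog["rsid"].astype(str).str.match(_RSID_RE)
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"skipped {n_bad} catalog rows with malformed rsIDs", stacklevel=2)
    cat = catalog[ok]
    rows = []
    for site, snps in hisnp_sets.items():
        hit = cat[cat["rsid"].isin(snps)].copy()
        hit.insert(0, "site_id", site)
        rows.append(hit)
    joined = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["site_id", *catalog.columns])
    counts = (
        joined.groupby("site_id")
        .agg(n_snps=("rsid", "nunique"), n_traits=("trait", "nunique"))
        .reset_index()
        if not joined.empty
        else pd.DataFrame(columns=["site_id", "n_snps", "n_traits"])
    )
    return joined, counts


# ---------------------------------------------------------------- SNP density


@dataclass
class DensityReport:
    counts: pd.DataFrame   # per-site counts per window, with group labels
    summary: pd.DataFrame  # per window: group means, t, p


def snp_density(
    sites: pd.DataFrame,
    snp_positions: dict[str, np.ndarray],
    windows: tuple[int, ...] = (1_000_000, 500_000, 100_000),
    group_col: str = "group",
) -> DensityReport:
    """SNP counts in centered windows, compared between site groups.

    ``sites`` needs columns chrom, pos and a binary group label column
    (e.g. with_hisnps vs common_without).  Counts use binary search on
    sorted per-chromosome SNP positions; group means are compared with
    an equal-variance two-sample t-test per window size.  Groups smaller
    than 2 yield a flagged (NaN) test.
    """
    sorted_pos = {c: np.sort(np.asarray(p)) for c, p in snp_positions.items()}
    rows = []
    for rec in sites.itertuples():
        pos_arr = sorted_pos.get(rec.chrom, np.empty(0))
        row = {"site_id": getattr(rec, "site_id", f"{rec.chrom}:{rec.pos}"),
               "chrom": rec.chrom, "pos": rec.pos,
               group_col: getattr(rec, group_col)}
        for w in windows:
            half = w // 2
            lo = np.searchsorted(pos_arr, rec.pos - half, side="left")
            hi = np.searchsorted(pos_arr, rec.pos + half, side="left")
            row[f"count_{w}"] = int(hi - lo)
        rows.append(row)
    counts = pd.DataFrame(rows)
    labels = sorted(counts[group_col].unique()) if not counts.empty else []
    summary_rows = []
    for w in windows:
        col = counts[f"count_{w}"] if not counts.empty else pd.Series(dtype=float)
        entry: dict = {"window": w}
        groups = [col[counts[group_col] == g].to_numpy(float) for g in labels]
        for g, vals in zip(labels, groups):
            entry[f"mean_{g}"] = float(vals.mean()) if vals.size else float("nan")
        if len(groups) == 2 and all(len(g) >= 2 for g in groups):
            t, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
            entry["t"], entry["p"] = float(t), float(p)
        else:
            entry["t"], entry["p"] = float("nan"), float("nan")
        summary_rows.append(entry)
    return DensityReport(counts, pd.DataFrame(summary_rows))
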