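"""Pooled-sequencing mutation calling: site filters, thresholds, multi-hit
genes, QTL-overlap enrichment, and the mutation-count trend.

Works from per-site, per-population reference/alternate read-count tables
(alignment and pileup generation are upstream of this package).  The calling
pipeline, in order:

1. remove sites where the alternate allele is in the majority (> 50% of
   reads) in at least 6 populations — fixed differences between the parents;
2. on the survivors, remove sites where the alternate allele exceeds 10%
   frequency in 5 or more populations — alignment-artifact error-prone sites;
3. call a mutation in a population when the alternate allele is at > 50%
   frequency (strict) with at least 4 supporting reads;
4. discard SNVs shared between populations descended from the same founder
   (pre-existing variants picked up when founding the replicate lines).

Thresholds compare only populations with defined frequency (depth > 0) at
the site; ties go to retention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

PUTATIVELY_FUNCTIONAL = frozenset({"missense", "putative-LOF", "indel-in-gene"})


@dataclass
class SiteCountTable:
    """Per-site read counts across populations.

    ``sites`` has columns (chrom, pos, ref, alt) with 1-based positions;
    ``ref_counts``/``alt_counts`` are sites × populations arrays.
    """

    sites: pd.DataFrame
    populations: list[str]
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        s = len(self.sites)
        p = len(self.populations)
        if self.ref_counts.shape != (s, p) or self.alt_counts.shape != (s, p):
            raise ValueError("count arrays must be sites × populations")
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("read counts must be >= 0")

    def frequencies(self) -> np.ndarray:
        """Alt-allele frequencies; NaN where depth is zero."""
        depth = self.ref_counts + self.alt_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(depth > 0, self.alt_counts / depth, np.nan)

    def subset_sites(self, mask: np.ndarray) -> "SiteCountTable":
        return SiteCountTable(
            sites=self.sites.loc[mask].reset_index(drop=True),
            populations=list(self.populations),
            ref_counts=self.ref_counts[mask],
            alt_counts=self.alt_counts[mask],
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.sites.copy()
        for j, pop in enumerate(self.populations):
            df[f"pop_{pop}_ref"] = self.ref_counts[:, j]
            df[f"pop_{pop}_alt"] = self.alt_counts[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SiteCountTable":
        df = pd.read_csv(path, sep="\t")
        pops = [c[4:-4] for c in df.columns if c.startswith("pop_") and c.endswith("_ref")]
        return cls(
            sites=df[["chrom", "pos", "ref", "alt"]].copy(),
            populations=pops,
            ref_counts=df[[f"pop_{p}_ref" for p in pops]].to_numpy(),
            alt_counts=df[[f"pop_{p}_alt" for p in pops]].to_numpy(),
        )


def apply_site_filters(
    table: SiteCountTable,
    parental_min_lines: int = 6,
    artifact_freq: float = 0.10,
    artifact_min_pops: int = 5,
) -> tuple[SiteCountTable, pd.DataFrame]:
    """Two-stage site filtering; returns survivors and a removal log.

    Stage 1 (parental differences): alt allele in the majority (> 0.5) in at
    least ``parental_min_lines`` populations.  Stage 2, applied to stage-1
    survivors: alt allele above ``artifact_freq`` (strict) in
    ``artifact_min_pops`` or more populations.  Zero-depth cells have
    undefined frequency and count toward neither rule.
    """
    if not table.populations:
        raise ValueError("need >= 1 population")
    freq = table.frequencies()
    n_majority = np.nansum(freq > 0.5, axis=1).astype(int)
    stage1_hit = n_majority >= parental_min_lines
    n_above = np.nansum(freq > artifact_freq, axis=1).astype(int)
    stage2_hit = (~stage1_hit) & (n_above >= artifact_min_pops)
    log_rows = []
    for i in np.flatnonzero(stage1_hit | stage2_hit):
        log_rows.append(
            {
                "chrom": table.sites.at[i, "chrom"],
                "pos": table.sites.at[i, "pos"],
                "stage": 1 if stage1_hit[i] else 2,
                "n_flagged": int(n_majority[i] if stage1_hit[i] else n_above[i]),
            }
        )
    log = pd.DataFrame(log_rows, columns=["chrom", "pos", "stage", "n_flagged"])
    return table.subset_sites(~(stage1_hit | stage2_hit)), log


def call_mutations(
    table: SiteCountTable, min_freq: float = 0.5, min_support: int = 4
) -> pd.DataFrame:
    """Per-population calls: alt frequency strictly > ``min_freq`` and alt
    read support >= ``min_support``.  The table should already be filtered."""
    freq = table.frequencies()
    with np.errstate(invalid="ignore"):
        hit = (freq > min_freq) & (table.alt_counts >= min_support)
    si, pj = np.nonzero(hit)
    calls = pd.DataFrame(
        {
            "population_id": [table.populations[j] for j in pj],
            "chrom": table.sites["chrom"].to_numpy()[si],
            "pos": table.sites["pos"].to_numpy()[si],
            "ref": table.sites["ref"].to_numpy()[si],
            "alt": table.sites["alt"].to_numpy()[si],
            "frequency": freq[si, pj],
            "support": table.alt_counts[si, pj],
        }
    )
    return calls.reset_index(drop=True)


def remove_shared_founder_snvs(
    calls: pd.DataFrame, population_founder: dict
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop identical SNVs shared by ≥ 2 populations of the same founder.

    Such variants predate the evolution (standing variation in the founder
    clone) and are removed from *all* carrier populations.
    """
    unmapped = set(calls["population_id"]) - set(population_founder)
    if unmapped:
        raise KeyError(f"populations without a founder mapping: {sorted(unmapped)}")
    founder = calls["population_id"].map(population_founder)
    key = calls[["chrom", "pos", "ref", "alt"]].astype(str).agg("|".join, axis=1)
    grp = pd.DataFrame({"key": key, "founder": founder,
                        "pop": calls["population_id"]})
    n_pops = grp.groupby(["founder", "key"])["pop"].transform("nunique")
    shared = n_pops >= 2
    return calls.loc[~shared].reset_index(drop=True), calls.loc[shared].reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene annotation


def read_bed(path: str | Path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open on disk; converted to
    1-based inclusive internally)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene"])
    df["start"] = df["start"] + 1  # 1-based inclusive
    return df[["gene", "chrom", "start", "end"]]


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Gene intervals from GFF3 (1-based inclusive); gene id from ID= or
    Name= in the attributes column of ``gene`` features."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
    )
    genes = df[df["type"] == "gene"].copy()

    def _gid(attrs: str) -> str:
        fields = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        return fields.get("Name", fields.get("ID", attrs))

    genes["gene"] = genes["attributes"].map(_gid)
    return genes[["gene", "chrom", "start", "end"]].reset_index(drop=True)


def assign_genes_and_multihit(
    calls: pd.DataFrame, genes: pd.DataFrame, min_populations: int = 2
) -> tuple[pd.DataFrame, list[str]]:
    """Map calls to genes by position; list multi-hit genes.

    ``genes`` has 1-based inclusive (gene, chrom, start, end) rows.  Calls in
    no interval are classed "noncoding"; calls lacking a ``consequence``
    column get "missense" inside genes.  Overlapping annotations resolve to
    the smallest containing interval (logged).  A multi-hit gene has
    missense / putative-LOF / in-gene-indel calls in ≥ ``min_populations``
    distinct populations.
    """
    trees: dict[str, IntervalTree] = {}
    for _, g in genes.iterrows():
        trees.setdefault(g["chrom"], IntervalTree()).addi(
            int(g["start"]), int(g["end"]) + 1, g["gene"]
        )
    assigned = []
    overlap_hits = 0
    for _, c in calls.iterrows():
        tree = trees.get(c["chrom"])
        hits = sorted(tree[int(c["pos"])], key=lambda iv: iv.end - iv.begin) if tree else []
        if len(hits) > 1:
            overlap_hits += 1
        assigned.append(hits[0].data if hits else None)
    if overlap_hits:
        warnings.warn(
            f"{overlap_hits} calls fell in overlapping annotations; "
            "resolved to the smallest interval"
        )
    out = calls.copy()
    out["gene"] = assigned
    if "consequence" not in out.columns:
        out["consequence"] = np.where(out["gene"].notna(), "missense", "noncoding")
    else:
        out.loc[out["gene"].isna(), "consequence"] = "noncoding"
    functional = out[out["consequence"].isin(PUTATIVELY_FUNCTIONAL) & out["gene"].notna()]
    per_gene = functional.groupby("gene")["population_id"].nunique()
    multihit = sorted(per_gene[per_gene >= min_populations].index)
    return out, multihit


def expected_overlap(
    n_multihit: int, n_qtl_genes: int, n_genome: int, observed: int | None = None
) -> tuple[float, float | None]:
    """Hypergeometric expectation (and tail probability) for the overlap
    between the multi-hit gene list and genes inside QTL confidence
    intervals: E = n_multihit·n_qtl_genes/n_genome; P(overlap ≥ observed)."""
    if n_multihit > n_genome or n_qtl_genes > n_genome:
        raise ValueError("list sizes cannot exceed the genome gene count")
    expect = n_multihit * n_qtl_genes / n_genome
    pval = None
    if observed is not None:
        pval = float(hypergeom.sf(observed - 1, n_genome, n_qtl_genes, n_multihit))
    return float(expect), pval


@dataclass
class TrendResult:
    slope: float
    intercept: float
    p_value: float  # two-sided bootstrap-over-founders p for slope ≠ 0


def mutation_count_trend(
    counts, founder_fitness, founders, n_boot: int = 2000, seed: int | None = None
) -> TrendResult:
    """OLS slope of per-population mutation counts on founder fitness, with a
    founder-cluster bootstrap p-value (populations of a founder resampled
    together, respecting the shared-founder dependence)."""
    y = np.asarray(counts, dtype=float)
    x = np.asarray(founder_fitness, dtype=float)
    founders = np.asarray(founders)
    if np.any(y < 0):
        raise ValueError("counts must be >= 0")
    slope, intercept = np.polyfit(x, y, 1)
    uniq = np.unique(founders)
    members = {f: np.flatnonzero(founders == f) for f in uniq}
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        picked = rng.choice(uniq, size=uniq.size, replace=True)
        idx = np.concatenate([members[f] for f in picked])
        if np.var(x[idx]) == 0:
            continue
        boot.append(np.polyfit(x[idx], y[idx], 1)[0])
    boot = np.asarray(boot)
    # two-sided: twice the smaller tail of the bootstrap distribution vs 0
    p_lo = (1 + int((boot >= 0).sum())) / (1 + boot.size)
    p_hi = (1 + int((boot <= 0).sum())) / (1 + boot.size)
    return TrendResult(
        slope=float(slope), intercept=float(intercept),
        p_value=float(min(1.0, 2 * min(p_lo, p_hi))),
    )


def write_vcf(calls: pd.DataFrame, path: str | Path) -> None:
    """Minimal VCF 4.2 export of a call table (one record per call)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=POP,Number=1,Type=String,Description="Population">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alt frequency">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt read support">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, c in calls.sort_values(["chrom", "pos"]).iterrows():
            info = f"POP={c['population_id']};AF={c['frequency']:.4f};AD={int(c['support'])}"
            fh.write(
                f"{c['chrom']}\t{int(c['pos'])}\t.\t{c['ref']}\t{c['alt']}\t.\tPASS\t{info}\n"
            )
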