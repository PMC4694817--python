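"""Signature selection, subgroup reanalysis, and genomic cluster annotation.

The integrated signature keeps miRNAs that survive Bonferroni correction
(corrected p < alpha) and are reported by at least a minimum fraction of
the corpus (default one third, compared without rounding). Subgroup
reanalysis reruns the whole aggregation on an etiology-filtered
sub-corpus. Cluster annotation groups signature members whose genomic
loci lie within 50 kb on the same strand, with an opposite-orientation
locus breaking the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .corpus import DIRECTIONS, Corpus
from .rra import aggregate

__all__ = [
    "GenomicLocus",
    "select_signature",
    "subgroup_analysis",
    "annotate_clusters",
    "load_loci_bed",
]


@dataclass(frozen=True)
class GenomicLocus:
    """A miRNA gene's genomic interval (0-based half-open, stranded)."""

    mirna: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.mirna}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.mirna}: strand must be '+' or '-'")


def select_signature(results: pd.DataFrame, alpha: float = 0.05,
                     min_fraction: float = 1 / 3,
                     n_studies: int | None = None) -> pd.DataFrame:
    """Filter an aggregation table down to the integrated signature.

    Keeps rows with corrected_p strictly below *alpha* and n_reporting of
    at least min_fraction * n_studies (real-valued comparison, no
    rounding: with 26 studies the support threshold is 26/3, i.e. at
    least 9 studies). Sorted by corrected p ascending. Idempotent.
    """
    if n_studies is None:
        raise ValueError("n_studies (corpus size M) is required")
    support = min_fraction * n_studies
    kept = results[(results["corrected_p"] < alpha)
                   & (results["n_reporting"] >= support)]
    return kept.sort_values(["corrected_p", "mirna"], kind="stable").reset_index(drop=True)


def subgroup_analysis(corpus: Corpus, etiology_filter: set,
                      **aggregate_kwargs) -> dict[str, pd.DataFrame]:
    """Rerun the full aggregation on an etiology-restricted sub-corpus.

    A study matches when its tag set intersects *etiology_filter*. The
    Bonferroni test count is recomputed for the subset (the default
    inside :func:`~mirmeta.rra.aggregate`). Returns one table per
    direction.
    """
    tags = set(etiology_filter)
    sub = corpus.filter(lambda s: bool(s.etiology_tags & tags))
    if len(sub) < 2:
        raise ValueError(
            f"subgroup {sorted(tags)} matches only {len(sub)} study; need >= 2"
        )
    return {d: aggregate(sub, d, **aggregate_kwargs) for d in DIRECTIONS}


def load_loci_bed(path) -> list[GenomicLocus]:
    """Read loci from a BED file (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     usecols=range(6))
    return [
        GenomicLocus(mirna=r["name"], chromosome=r["chrom"], start=int(r["start"]),
                     end=int(r["end"]), strand=r["strand"])
        for _, r in df.iterrows()
    ]


def _cluster_loci(loci: list[GenomicLocus], max_gap: int) -> dict[str, str]:
    """Map mirna -> cluster id for clusters of size >= 2.

    Loci are scanned per chromosome in coordinate order. A chain extends
    while the next locus shares the strand and starts within *max_gap* of
    the previous locus's end; any strand flip breaks the chain, so an
    opposite-orientation locus between two same-strand candidates
    separates them.
    """
    assignments: dict[str, str] = {}
    by_chrom: dict[str, list[GenomicLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    for chrom, items in by_chrom.items():
        items = sorted(items, key=lambda x: (x.start, x.end, x.mirna))
        chains: list[list[GenomicLocus]] = []
        current = [items[0]]
        for locus in items[1:]:
            prev = current[-1]
            gap = locus.start - prev.end
            if locus.strand == prev.strand and gap < max_gap:
                current.append(locus)
            else:
                chains.append(current)
                current = [locus]
        chains.append(current)
        counter = 0
        for chain in chains:
            if len(chain) >= 2:
                counter += 1
                cid = f"{chrom}:{counter}"
                for locus in chain:
                    assignments[locus.mirna] = cid
    return assignments


def annotate_clusters(entries: pd.DataFrame, loci: list[GenomicLocus],
                      max_gap: int = 50_000) -> pd.DataFrame:
    """Attach a cluster_id column to signature entries.

    Clustering runs over *all* provided loci (so a non-signature locus can
    still break a chain via its orientation); entries lacking a locus stay
    unclustered (cluster_id None). Invariant to input order.
    """
    assignments = _cluster_loci(loci, max_gap) if loci else {}
    out = entries.copy()
    out["cluster_id"] = [assignments.get(m) for m in out["mirna"]]
    return out
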