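"""Corpora of per-study miRNA differential-expression lists.

A *corpus* collects, for each published study, its ordered lists of
significantly up- and down-regulated miRNAs (rank 1 = strongest evidence)
together with study metadata (sample pairs, platform size, etiology tags).
This module reads/writes the TSV dialect, validates structure, standardizes
miRNA names against an alias table, and summarizes reporting patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ListEntry",
    "StudyRecord",
    "Corpus",
    "AliasTable",
    "StandardizationReport",
    "CorpusFormatError",
    "load_corpus",
    "write_corpus",
    "load_alias_table",
    "order_by_evidence",
    "standardize_names",
    "corpus_summary",
]

UP = "up"
DOWN = "down"
DIRECTIONS = (UP, DOWN)


class CorpusFormatError(ValueError):
    """Raised when a corpus file or record violates the documented dialect."""


@dataclass(frozen=True)
class ListEntry:
    """One miRNA in a study's ranked list, with optional source statistics."""

    mirna: str
    fold_change: float | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class StudyRecord:
    """One study's metadata plus its ordered up/down DE miRNA lists.

    List position defines rank: ``up_list[0]`` has rank 1. Lists may be
    empty (a study need not report both directions).
    """

    study_id: str
    year: int
    etiology_tags: frozenset = frozenset()
    n_pairs: int = 1
    platform_size: int = 1
    up_list: tuple = ()
    down_list: tuple = ()

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise CorpusFormatError(f"study {self.study_id!r}: n_pairs must be >= 1")
        if self.platform_size < 1:
            raise CorpusFormatError(
                f"study {self.study_id!r}: platform_size must be >= 1"
            )
        for direction, entries in ((UP, self.up_list), (DOWN, self.down_list)):
            names = [e.mirna for e in entries]
            if len(names) != len(set(names)):
                dup = next(n for n in names if names.count(n) > 1)
                raise CorpusFormatError(
                    f"study {self.study_id!r}: duplicate miRNA {dup!r} in "
                    f"{direction} list"
                )

    def direction_list(self, direction: str) -> tuple:
        if direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
        return self.up_list if direction == UP else self.down_list


@dataclass(frozen=True)
class Corpus:
    """A non-empty collection of studies with unique ids."""

    studies: tuple
    alias_version: str = ""

    def __post_init__(self) -> None:
        if not self.studies:
            raise CorpusFormatError("corpus must contain at least one study")
        ids = [s.study_id for s in self.studies]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise CorpusFormatError(f"duplicate study id {dup!r}")

    def __len__(self) -> int:
        return len(self.studies)

    def study(self, study_id: str) -> StudyRecord:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    def filter(self, predicate) -> "Corpus":
        kept = tuple(s for s in self.studies if predicate(s))
        if not kept:
            raise CorpusFormatError("filter removed every study")
        return Corpus(studies=kept, alias_version=self.alias_version)


@dataclass(frozen=True)
class AliasTable:
    """Alias -> canonical miRNA name map (one nomenclature version).

    ``non_mirna`` flags probe names (viral miRNAs, controls) to be dropped
    during standardization. Canonical names map to themselves.
    """

    entries: Mapping[str, str]
    non_mirna: frozenset = frozenset()
    version: str = "miRBase 21"

    def canonical(self, name: str) -> str | None:
        """Canonical name for *name*, or None if unmapped."""
        if name in self.entries:
            return self.entries[name]
        return None


@dataclass
class StandardizationReport:
    """What standardization changed: merges, drops, names left verbatim."""

    unmapped: set = field(default_factory=set)
    dropped_non_mirna: list = field(default_factory=list)
    merges: list = field(default_factory=list)  # (study_id, direction, kept, dropped)


def order_by_evidence(entries: Iterable[ListEntry]) -> list[ListEntry]:
    """Order entries by |fold change| descending, then p ascending, then name.

    Used when a source supplies statistics but no explicit ranks. Entries
    lacking fold change sort after those that have one (p-value evidence is
    weaker ordering information than effect size here).
    """

    def key(e: ListEntry):
        has_fc = e.fold_change is not None and not math.isnan(e.fold_change)
        fc = abs(e.fold_change) if has_fc else -math.inf
        p = e.p_value if (e.p_value is not None and not math.isnan(e.p_value)) else math.inf
        return (0 if has_fc else 1, -fc, p, e.mirna)

    return sorted(entries, key=key)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_STUDY_COLS = ["study_id", "year", "etiology", "n_pairs", "platform_size"]
_LIST_COLS = ["study_id", "direction", "rank", "mirna", "fold_change", "p_value"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing columns {missing}")


def load_corpus(path, alias_version: str = "") -> Corpus:
    """Load a corpus from a directory containing studies.tsv and lists.tsv.

    lists.tsv rows are ordered by their ``rank`` column within each
    (study, direction); rows with no rank are ordered by evidence
    (|fold_change| desc, p asc).
    """
    path = Path(path)
    studies_path = path / "studies.tsv" if path.is_dir() else path
    lists_path = studies_path.parent / "lists.tsv"
    studies_df = pd.read_csv(studies_path, sep="\t", dtype={"study_id": str})
    lists_df = pd.read_csv(lists_path, sep="\t", dtype={"study_id": str, "mirna": str})
    _require_columns(studies_df, _STUDY_COLS, studies_path)
    _require_columns(lists_df, _LIST_COLS[:4], lists_path)
    for opt in ("fold_change", "p_value"):
        if opt not in lists_df.columns:
            lists_df[opt] = float("nan")

    records = []
    for _, row in studies_df.iterrows():
        sid = row["study_id"]
        sub = lists_df[lists_df["study_id"] == sid]
        dir_lists: dict[str, tuple] = {UP: (), DOWN: ()}
        for direction, grp in sub.groupby("direction"):
            if direction not in DIRECTIONS:
                raise CorpusFormatError(
                    f"{lists_path}: study {sid!r} has unknown direction {direction!r}"
                )
            entries = [
                ListEntry(
                    mirna=r["mirna"],
                    fold_change=None if pd.isna(r["fold_change"]) else float(r["fold_change"]),
                    p_value=None if pd.isna(r["p_value"]) else float(r["p_value"]),
                )
                for _, r in grp.iterrows()
            ]
            if grp["rank"].notna().all():
                order = grp["rank"].astype(float).to_numpy().argsort(kind="stable")
                entries = [entries[i] for i in order]
            else:
                entries = order_by_evidence(entries)
            dir_lists[direction] = tuple(entries)
        try:
            records.append(
                StudyRecord(
                    study_id=sid,
                    year=int(row["year"]),
                    etiology_tags=frozenset(
                        t for t in str(row["etiology"]).split(",") if t and t != "nan"
                    ),
                    n_pairs=int(row["n_pairs"]),
                    platform_size=int(row["platform_size"]),
                    up_list=dir_lists[UP],
                    down_list=dir_lists[DOWN],
                )
            )
        except CorpusFormatError:
            raise
    return Corpus(studies=tuple(records), alias_version=alias_version)


def write_corpus(corpus: Corpus, path) -> None:
    """Write studies.tsv and lists.tsv under directory *path*."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    srows, lrows = [], []
    for s in corpus.studies:
        srows.append(
            {
                "study_id": s.study_id,
                "year": s.year,
                "etiology": ",".join(sorted(s.etiology_tags)),
                "n_pairs": s.n_pairs,
                "platform_size": s.platform_size,
            }
        )
        for direction in DIRECTIONS:
            for rank, e in enumerate(s.direction_list(direction), start=1):
                lrows.append(
                    {
                        "study_id": s.study_id,
                        "direction": direction,
                        "rank": rank,
                        "mirna": e.mirna,
                        "fold_change": e.fold_change,
                        "p_value": e.p_value,
                    }
                )
    pd.DataFrame(srows).to_csv(path / "studies.tsv", sep="\t", index=False)
    pd.DataFrame(lrows, columns=_LIST_COLS).to_csv(path / "lists.tsv", sep="\t", index=False)


def load_alias_table(path) -> AliasTable:
    """Load an alias table TSV with columns alias, canonical, is_mirna."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["alias", "canonical"], path)
    entries: dict[str, str] = {}
    non_mirna = set()
    for _, row in df.iterrows():
        alias, canonical = row["alias"], row["canonical"]
        if alias in entries and entries[alias] != canonical:
            raise CorpusFormatError(
                f"{path}: alias {alias!r} maps to both {entries[alias]!r} and {canonical!r}"
            )
        entries[alias] = canonical
        entries.setdefault(canonical, canonical)
        if "is_mirna" in df.columns and str(row.get("is_mirna", "1")) == "0":
            non_mirna.add(alias)
    return AliasTable(entries=entries, non_mirna=frozenset(non_mirna))


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def _standardize_list(
    entries: tuple, aliases: AliasTable, study_id: str, direction: str,
    report: StandardizationReport,
) -> tuple:
    seen: dict[str, ListEntry] = {}
    for e in entries:
        if e.mirna in aliases.non_mirna:
            report.dropped_non_mirna.append((study_id, direction, e.mirna))
            continue
        canonical = aliases.canonical(e.mirna)
        if canonical is None:
            report.unmapped.add(e.mirna)
            canonical = e.mirna
        if canonical in seen:
            # duplicate after collapse: earlier entry has the better rank
            report.merges.append((study_id, direction, canonical, e.mirna))
            continue
        seen[canonical] = replace(e, mirna=canonical)
    return tuple(seen.values())


def standardize_names(
    corpus: Corpus, aliases: AliasTable
) -> tuple[Corpus, StandardizationReport]:
    """Replace every list name by its canonical form.

    Entries collapsing to the same canonical name keep the best (smallest)
    rank; the list is re-ranked densely afterwards. Flagged non-miRNA probes
    are dropped. Unmapped names are kept verbatim and reported. Idempotent.
    """
    report = StandardizationReport()
    new_studies = []
    for s in corpus.studies:
        new_studies.append(
            replace(
                s,
                up_list=_standardize_list(s.up_list, aliases, s.study_id, UP, report),
                down_list=_standardize_list(s.down_list, aliases, s.study_id, DOWN, report),
            )
        )
    return (
        Corpus(studies=tuple(new_studies), alias_version=aliases.version),
        report,
    )


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def corpus_summary(corpus: Corpus) -> dict:
    """Reporting-pattern summary of a (standardized) corpus.

    Returns study counts, sample-pair totals/medians, platform-size median,
    the number of distinct miRNAs reported up / down in at least one study,
    and the number reported in both directions across studies (discordant).
    """
    import statistics

    up_names: set[str] = set()
    down_names: set[str] = set()
    for s in corpus.studies:
        up_names.update(e.mirna for e in s.up_list)
        down_names.update(e.mirna for e in s.down_list)
    pairs = [s.n_pairs for s in corpus.studies]
    platforms = [s.platform_size for s in corpus.studies]
    return {
        "n_studies": len(corpus),
        "total_pairs": sum(pairs),
        "median_pairs": statistics.median(pairs),
        "median_platform_size": statistics.median(platforms),
        "n_up_reported": len(up_names),
        "n_down_reported": len(down_names),
        "n_discordant": len(up_names & down_names),
    }
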