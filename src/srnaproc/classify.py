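"""Read classification by exact matching, and the composition / length
summaries derived from it.

Exact substring search replaces a zero-mismatch short-read aligner: a read
belongs to a class if it occurs verbatim inside one of that class's reference
sequences (miRNA precursors, mature tRNAs, background FASTAs). The miRNA
class is additionally open to isomiR-callable reads — a non-templated 3' tail
is by definition not an exact match to the precursor, yet such reads are
miRNA-derived and must be counted as miRNA for class composition and NTA
denominators. Reads matching several classes are resolved by a fixed
hierarchy (miRNA > tRNA > rRNA > snoRNA > snRNA > piRNA > mRNA > repeat by
default) and contribute their full count to the resolved class only.

Reverse-complement matching is off by default: small-RNA libraries are
stranded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .isomir import IsomirMatcher
from .preprocess import ReadSet
from .references import ReferenceSet

DEFAULT_STRATA = (18, 22, 32)
LENGTH_RANGE = (15, 35)


@dataclass(frozen=True)
class Hit:
    class_label: str
    feature_id: str
    offset: int  # 0-based within the feature sequence


@dataclass
class ReadAssignment:
    sequence: str
    count: int
    hits: list[Hit]
    resolved_class: str  # class label or "unassigned"


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class SubstringIndex:
    """All (class, feature, offset) exact occurrences of a query.

    Backed by a dictionary over every reference substring in the expected
    read-length window; queries outside the window fall back to a linear
    scan, so results are exact for any length.
    """

    def __init__(self, refs: ReferenceSet,
                 min_len: int = LENGTH_RANGE[0],
                 max_len: int = LENGTH_RANGE[1],
                 match_revcomp: bool = False):
        self.min_len = min_len
        self.max_len = max_len
        self.match_revcomp = match_revcomp
        self._features: list[tuple[str, str, str]] = []  # (class, id, seq)
        seen_precursors: set[str] = set()
        for locus in refs.mirna_loci:  # 5p/3p arms share a precursor
            if locus.precursor_id not in seen_precursors:
                seen_precursors.add(locus.precursor_id)
                self._features.append(("miRNA", locus.precursor_id, locus.precursor_seq))
        for gene in refs.trna_genes:
            self._features.append(("tRNA", gene.gene_id, gene.seq))
        for label, entries in refs.background.items():
            for fid, seq in entries:
                self._features.append((label, fid, seq))
        self._table: dict[str, list[Hit]] = {}
        for cls, fid, seq in self._features:
            for L in range(min_len, min(max_len, len(seq)) + 1):
                for off in range(len(seq) - L + 1):
                    self._table.setdefault(seq[off:off + L], []).append(
                        Hit(cls, fid, off))

    def query(self, seq: str) -> list[Hit]:
        if self.min_len <= len(seq) <= self.max_len:
            hits = list(self._table.get(seq, ()))
        else:
            hits = self._scan(seq)
        if self.match_revcomp:
            rc = _revcomp(seq)
            if rc != seq:
                if self.min_len <= len(rc) <= self.max_len:
                    hits += self._table.get(rc, [])
                else:
                    hits += self._scan(rc)
        return hits

    def _scan(self, seq: str) -> list[Hit]:
        hits = []
        for cls, fid, ref in self._features:
            start = ref.find(seq)
            while start != -1:
                hits.append(Hit(cls, fid, start))
                start = ref.find(seq, start + 1)
        return hits


def build_index(refs: ReferenceSet, **kwargs) -> SubstringIndex:
    return SubstringIndex(refs, **kwargs)


def resolve_class(hits: Iterable[Hit], hierarchy: Sequence[str]) -> str:
    """First hierarchy class with at least one hit; else 'unassigned'."""
    present = {h.class_label for h in hits}
    for cls in hierarchy:
        if cls in present:
            return cls
    return "unassigned"


def classify_reads(reads: ReadSet, refs: ReferenceSet,
                   index: SubstringIndex | None = None,
                   matcher: IsomirMatcher | None = None,
                   isomir_rescue: bool = True) -> list[ReadAssignment]:
    """Assign every read of a sample to an RNA class.

    ``isomir_rescue`` extends miRNA-class membership to isomiR-callable reads
    (5' shift <= 2, tail <= 3 nt, no internal mismatch); the stored ``hits``
    remain exact substring matches only.
    """
    index = index or build_index(refs)
    matcher = matcher if matcher is not None else (
        IsomirMatcher(refs.mirna_loci) if isomir_rescue else None)
    hierarchy = refs.class_hierarchy
    out = []
    for seq, count in reads.records:
        hits = index.query(seq)
        present = {h.class_label for h in hits}
        if matcher is not None and "miRNA" not in present and matcher.is_callable(seq):
            present.add("miRNA")
        resolved = next((c for c in hierarchy if c in present), "unassigned")
        out.append(ReadAssignment(seq, count, hits, resolved))
    return out


# ---------------------------------------------------------------------------
# summaries

@dataclass
class CompositionTable:
    """Per-class counts and fractions, overall and per length stratum.

    Fractions are over *assigned* reads within each stratum (a mapped-read
    denominator); the unassigned count is carried alongside with an
    undefined fraction.
    """

    sample_id: str
    table: pd.DataFrame  # columns: stratum, class, count, fraction

    def fraction(self, cls: str, stratum: str = "all") -> float:
        sub = self.table[(self.table["stratum"] == stratum)
                         & (self.table["class"] == cls)]
        return float(sub["fraction"].iloc[0]) if len(sub) else 0.0


def composition(assignments: Sequence[ReadAssignment],
                strata: Sequence[int] = DEFAULT_STRATA,
                sample_id: str = "") -> CompositionTable:
    rows = []
    df = pd.DataFrame({
        "cls": [a.resolved_class for a in assignments],
        "count": [a.count for a in assignments],
        "length": [len(a.sequence) for a in assignments],
    })
    classes = sorted(set(df["cls"]) - {"unassigned"})
    for stratum_label, sub in [("all", df)] + [(str(L), df[df["length"] == L])
                                               for L in strata]:
        assigned = sub[sub["cls"] != "unassigned"]
        denom = assigned["count"].sum()
        counts = assigned.groupby("cls")["count"].sum()
        for cls in classes:
            c = int(counts.get(cls, 0))
            frac = c / denom if denom > 0 else 0.0
            rows.append((stratum_label, cls, c, frac))
        rows.append((stratum_label, "unassigned",
                     int(sub[sub["cls"] == "unassigned"]["count"].sum()), np.nan))
    table = pd.DataFrame(rows, columns=["stratum", "class", "count", "fraction"])
    return CompositionTable(sample_id, table)


def length_histogram(reads, cls: str | None = None,
                     length_range: tuple[int, int] = LENGTH_RANGE) -> pd.Series:
    """Integer histogram of read lengths over ``length_range`` (inclusive),
    optionally restricted to one resolved class."""
    lo, hi = length_range
    idx = pd.RangeIndex(lo, hi + 1, name="length")
    hist = pd.Series(0, index=idx, dtype=int)
    if isinstance(reads, ReadSet):
        pairs = reads.records
    else:
        pairs = [(a.sequence, a.count) for a in reads
                 if cls is None or a.resolved_class == cls]
    for seq, count in pairs:
        if lo <= len(seq) <= hi:
            hist[len(seq)] += count
    return hist


def modal_length(hist: pd.Series) -> tuple[int, bool]:
    """(modal length, tie flag); smallest length wins on ties."""
    if hist.sum() == 0:
        raise ValueError("empty histogram has no mode")
    top = hist.max()
    winners = hist.index[hist == top]
    return int(winners.min()), len(winners) > 1


def class_abundance_ratio(ctrl: CompositionTable,
                          stress: CompositionTable) -> pd.DataFrame:
    """Per-class ratio of stress to control assigned-read fractions.

    Classes absent from the control are reported infinite and flagged;
    classes absent from both are undefined (NaN) and flagged.
    """
    c = ctrl.table[ctrl.table["stratum"] == "all"].set_index("class")["fraction"]
    s = stress.table[stress.table["stratum"] == "all"].set_index("class")["fraction"]
    classes = sorted((set(c.index) | set(s.index)) - {"unassigned"})
    rows = []
    for cls in classes:
        fc = float(c.get(cls, 0.0))
        fs = float(s.get(cls, 0.0))
        if fc == 0.0 and fs == 0.0:
            ratio, flag = np.nan, "undefined"
        elif fc == 0.0:
            ratio, flag = np.inf, "absent_in_control"
            warnings.warn(f"class {cls} absent in control: infinite ratio")
        else:
            ratio, flag = fs / fc, ""
        rows.append((cls, fc, fs, ratio, flag))
    return pd.DataFrame(rows, columns=["class", "fraction_ctrl",
                                       "fraction_stress", "ratio", "flag"]
                        ).set_index("class")
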