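"""isomiR calling: decomposition of miRNA-class reads into a 5' shift, a
templated 3' shift and a non-templated 3' tail (NTA), plus the derived
per-miRNA count, tail-profile, arm-bias and length statistics.

The decomposition model
-----------------------
A read is an isomiR of a mature locus when

* its 5' end starts within +/-2 nt of the annotated mature 5' end,
* its templated body matches the precursor with zero internal mismatches, and
* at most 3 terminal 3' bases are left uncovered — the non-templated tail.

The templated body is the *maximal* exact extension of the read into the
precursor from the candidate start ("templated-priority"): a 3' base that
matches the next template base is always counted as templated extension,
never as a tail. Among valid candidate starts the call with the longest
templated match wins; ties prefer the smallest |5' shift|, then upstream
(negative) over downstream shifts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .preprocess import ReadSet
from .references import MiRNALocus

logger = logging.getLogger(__name__)

MAX_SHIFT5 = 2
MAX_TAIL = 3

#: tail-type labels (U reported instead of T); homopolymer tails are typed by
#: base and mono/multi length, mixed-base tails are pooled under "mixed".
MONO_TYPES = ("A", "C", "G", "U")


@dataclass(frozen=True)
class IsomiRCall:
    """One read decomposed against one mature locus."""

    mature_id: str
    arm: str
    shift5: int            # read 5' start minus mature 5' start
    shift3_templated: int  # templated 3' end minus mature 3' end
    tail: str              # non-templated 3' bases, 5'->3' (DNA alphabet)
    category: str          # canonical | shift5 | shift3 | nta
    count: int = 1

    def __post_init__(self) -> None:
        if abs(self.shift5) > MAX_SHIFT5:
            raise ValueError(f"|shift5| > {MAX_SHIFT5}")
        if len(self.tail) > MAX_TAIL:
            raise ValueError(f"tail longer than {MAX_TAIL}")
        if self.category == "nta" and not self.tail:
            raise ValueError("nta category requires a non-empty tail")


def categorize(shift5: int, shift3: int, tail: str) -> str:
    """Mutually exclusive category, precedence nta > shift5 > shift3."""
    if tail:
        return "nta"
    if shift5 != 0:
        return "shift5"
    if shift3 != 0:
        return "shift3"
    return "canonical"


def call_isomir(seq: str, locus: MiRNALocus,
                max_shift5: int = MAX_SHIFT5,
                max_tail: int = MAX_TAIL) -> IsomiRCall | None:
    """Call one read against one mature locus; None if it is not an isomiR.

    Candidate starts s span mature_start +/- max_shift5 (clipped to the
    precursor). For each s the read's maximal templated extension into the
    precursor is computed greedily; the uncovered read suffix (<= max_tail
    bases) is the tail. Tie-break across candidates: longest templated match,
    then smallest |shift5|, then negative shift5 before positive.
    """
    prec = locus.precursor_seq
    n_prec = len(prec)
    best_key = None
    best = None
    for s in range(locus.mature_start - max_shift5, locus.mature_start + max_shift5 + 1):
        if s < 0 or s >= n_prec:
            continue
        # greedy maximal templated match of the read prefix at precursor[s:]
        limit = min(len(seq), n_prec - s)
        length = 0
        while length < limit and seq[length] == prec[s + length]:
            length += 1
        if length == 0 or len(seq) - length > max_tail:
            continue
        shift5 = s - locus.mature_start
        key = (-length, abs(shift5), 0 if shift5 < 0 else 1)
        if best_key is None or key < best_key:
            best_key = key
            tail = seq[length:]
            shift3 = (s + length) - locus.mature_end
            best = IsomiRCall(locus.mature_id, locus.arm, shift5, shift3, tail,
                              categorize(shift5, shift3, tail))
    return best


def tail_type(tail: str) -> str:
    """Type label of a tail: '' (untailed), one of A/C/G/U for homopolymer
    tails, or 'mixed'."""
    if not tail:
        return ""
    if len(set(tail)) == 1:
        base = tail[0]
        return "U" if base == "T" else base
    return "mixed"


class IsomirMatcher:
    """Finds candidate loci for a read by its 5' prefix, then calls.

    Indexes the k-mer at every admissible start of every locus so that a read
    is only called against loci it can possibly match (the read's templated
    body is at least 12 nt for any read >= 15 nt with a <= 3 nt tail).
    """

    PREFIX_K = 12

    def __init__(self, loci: Sequence[MiRNALocus], max_shift5: int = MAX_SHIFT5):
        self.loci = list(loci)
        self.max_shift5 = max_shift5
        self._prefix: dict[str, list[MiRNALocus]] = {}
        k = self.PREFIX_K
        for locus in self.loci:
            prec = locus.precursor_seq
            seen: set[str] = set()
            for s in range(locus.mature_start - max_shift5,
                           locus.mature_start + max_shift5 + 1):
                if s < 0 or s + k > len(prec):
                    continue
                key = prec[s:s + k]
                if key not in seen:
                    seen.add(key)
                    self._prefix.setdefault(key, []).append(locus)

    def candidates(self, seq: str) -> list[MiRNALocus]:
        if len(seq) < self.PREFIX_K:
            return []
        return self._prefix.get(seq[:self.PREFIX_K], [])

    def call_all(self, seq: str) -> list[IsomiRCall]:
        """All loci this read is an isomiR of (deterministic order)."""
        calls = [c for loc in self.candidates(seq)
                 if (c := call_isomir(seq, loc, self.max_shift5)) is not None]
        calls.sort(key=lambda c: c.mature_id)
        return calls

    def is_callable(self, seq: str) -> bool:
        return any(call_isomir(seq, loc, self.max_shift5) is not None
                   for loc in self.candidates(seq))


CALL_COLUMNS = ("seq", "count", "mature_id", "arm", "shift5", "shift3",
                "tail", "tail_type", "tail_len", "category", "primary")


def call_reads(reads: Iterable[tuple[str, int]],
               loci: Sequence[MiRNALocus],
               matcher: IsomirMatcher | None = None) -> pd.DataFrame:
    """Call every (sequence, count) pair against all matching loci.

    Returns one row per (read, locus) pair. A read matching several loci is
    called against each; the lexicographically smallest mature_id is flagged
    ``primary`` so that genome-wide tabulations can count each read once.
    """
    matcher = matcher or IsomirMatcher(loci)
    rows = []
    for seq, count in reads:
        calls = matcher.call_all(seq)
        for i, c in enumerate(calls):
            rows.append((seq, count, c.mature_id, c.arm, c.shift5,
                         c.shift3_templated, c.tail, tail_type(c.tail),
                         len(c.tail), c.category, i == 0))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            CALL_COLUMNS,
            [str, int, str, str, int, int, str, str, int, str, bool])})
    return df


def mirna_counts(calls: pd.DataFrame) -> pd.Series:
    """Per-mature counts: the summed read counts of all isomiRs of the locus.

    Loci with identical mature sequence each receive the full count of the
    shared reads (counts are per-locus tabulations, not a partition of reads).
    """
    if calls.empty:
        return pd.Series(dtype=int, name="count")
    out = calls.groupby("mature_id")["count"].sum().sort_index()
    out.name = "count"
    return out


# ---------------------------------------------------------------------------
# NTA profiles

@dataclass
class NTAProfile:
    """Tail-type tabulation for one sample at a given scope.

    ``type_counts`` covers mono types A/C/G/U, multi types A_multi/.../U_multi
    (homopolymer, 2-3 nt) and 'mixed'; fractions are of the total miRNA-class
    read count in scope (untailed reads are the complement).
    """

    scope: str
    total: int
    type_counts: pd.Series
    per_feature: pd.DataFrame | None = None  # per-miRNA/per-arm breakdown

    @property
    def fractions(self) -> pd.Series:
        if self.total == 0:
            warnings.warn("NTA fractions undefined: zero reads in scope")
            return self.type_counts * np.nan
        return self.type_counts / self.total

    def fraction(self, type_label: str) -> float:
        return float(self.fractions.get(type_label, 0.0))


def _type_label(row_type: str, tail_len: int) -> str:
    if row_type == "" or row_type == "mixed":
        return row_type
    return row_type if tail_len == 1 else f"{row_type}_multi"


ALL_TYPE_LABELS = tuple(MONO_TYPES) + tuple(f"{t}_multi" for t in MONO_TYPES) + ("mixed",)


def nta_fractions(calls: pd.DataFrame,
                  scope: Literal["global", "per-miRNA", "per-arm"] = "global"
                  ) -> NTAProfile:
    """Tail-type counts and fractions.

    Global and per-arm scopes count each read once (primary locus attribution)
    to avoid double counting across loci sharing a mature sequence; the
    per-miRNA scope tabulates every locus in full.
    """
    df = calls if scope == "per-miRNA" else calls[calls["primary"]]
    labels = [_type_label(t, l) for t, l in zip(df["tail_type"], df["tail_len"])]
    df = df.assign(type_label=labels)
    if scope == "global":
        total = int(df["count"].sum())
        counts = (df[df["type_label"] != ""].groupby("type_label")["count"].sum()
                  .reindex(ALL_TYPE_LABELS, fill_value=0))
        return NTAProfile("global", total, counts)
    group_key = "mature_id" if scope == "per-miRNA" else "arm"
    totals = df.groupby(group_key)["count"].sum()
    tab = (df[df["type_label"] != ""]
           .pivot_table(index=group_key, columns="type_label", values="count",
                        aggfunc="sum", fill_value=0)
           .reindex(columns=ALL_TYPE_LABELS, fill_value=0)
           .reindex(totals.index, fill_value=0))
    tab.insert(0, "total", totals)
    counts = tab[list(ALL_TYPE_LABELS)].sum()
    return NTAProfile(scope, int(totals.sum()), counts, per_feature=tab)


def compare_nta(ctrl: NTAProfile, stress: NTAProfile,
                types: Sequence[str] = MONO_TYPES,
                min_reads: int = 500,
                min_features: int = 10) -> pd.DataFrame:
    """Per-type control-vs-stress comparison.

    Global: two-sided two-proportion score (z) test on pooled tailed/total
    counts. Per-miRNA (when both profiles carry a per-feature table): Wilcoxon
    signed-rank over miRNAs with >= ``min_reads`` reads in both conditions;
    skipped with a warning below ``min_features`` eligible miRNAs.
    """
    rows = []
    for t in types:
        k = np.array([ctrl.type_counts.get(t, 0), stress.type_counts.get(t, 0)])
        n = np.array([ctrl.total, stress.total])
        if n.min() == 0:
            z, p = np.nan, np.nan
        elif k.sum() == 0:
            z, p = 0.0, 1.0
        else:
            z, p = proportions_ztest(k, n)
        frac_c = k[0] / n[0] if n[0] else np.nan
        frac_s = k[1] / n[1] if n[1] else np.nan
        p_wilcoxon = np.nan
        n_eligible = 0
        if ctrl.per_feature is not None and stress.per_feature is not None:
            merged = ctrl.per_feature[["total", t]].join(
                stress.per_feature[["total", t]], how="inner",
                lsuffix="_c", rsuffix="_s")
            eligible = merged[(merged["total_c"] >= min_reads)
                              & (merged["total_s"] >= min_reads)]
            n_eligible = len(eligible)
            if n_eligible < min_features:
                warnings.warn(
                    f"per-miRNA comparison for {t} skipped: "
                    f"{n_eligible} eligible miRNAs (< {min_features})")
            else:
                fc = eligible[f"{t}_c"] / eligible["total_c"]
                fs = eligible[f"{t}_s"] / eligible["total_s"]
                diff = (fs - fc).to_numpy()
                if np.allclose(diff, 0):
                    p_wilcoxon = 1.0
                else:
                    p_wilcoxon = stats.wilcoxon(diff).pvalue
        rows.append({"type": t, "fraction_ctrl": frac_c, "fraction_stress": frac_s,
                     "delta": frac_s - frac_c, "z": z, "p_global": p,
                     "n_eligible_mirnas": n_eligible, "p_per_mirna": p_wilcoxon})
    return pd.DataFrame(rows).set_index("type")


def arm_nta_ratio(calls: pd.DataFrame, tail_type_label: str = "U") -> float:
    """Ratio of the 3p-arm to 5p-arm mono-tail fraction for one tail type.

    Returns inf (with a warning) when the 5p fraction is zero and 0.0 when no
    3p read is tailed; both arms must be represented by at least one read.
    """
    prof = nta_fractions(calls, scope="per-arm")
    tab = prof.per_feature
    if tab is None or not {"5p", "3p"} <= set(tab.index):
        raise ValueError("both arms must have at least one read")
    f5 = tab.loc["5p", tail_type_label] / tab.loc["5p", "total"]
    f3 = tab.loc["3p", tail_type_label] / tab.loc["3p", "total"]
    if f5 == 0:
        if f3 == 0:
            return 0.0
        warnings.warn("5p fraction is zero; arm ratio infinite")
        return float("inf")
    return float(f3 / f5)


# ---------------------------------------------------------------------------
# length statistics

@dataclass
class LengthShiftResult:
    statistic: float
    pvalue: float
    median_ctrl: float
    median_stress: float

    @property
    def shift(self) -> float:
        return self.median_stress - self.median_ctrl


def _expand_lengths(reads) -> np.ndarray:
    if isinstance(reads, ReadSet):
        pairs = reads.records
    elif isinstance(reads, pd.DataFrame):
        pairs = [(s, c) for s, c in zip(reads["seq"], reads["count"])]
    else:
        pairs = list(reads)
    lens = np.array([len(s) for s, _ in pairs], dtype=np.int64)
    counts = np.array([c for _, c in pairs], dtype=np.int64)
    return np.repeat(lens, counts)


def length_shift_test(ctrl_reads, stress_reads) -> LengthShiftResult:
    """Two-sided Mann-Whitney U on count-weighted read lengths."""
    x = _expand_lengths(ctrl_reads)
    y = _expand_lengths(stress_reads)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("length_shift_test: empty read set")
    if len(x) == 1 and len(y) == 1:
        warnings.warn("singleton vs singleton: p = 1 by convention")
        return LengthShiftResult(np.nan, 1.0, float(x[0]), float(y[0]))
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return LengthShiftResult(float(res.statistic), float(res.pvalue),
                             float(np.median(x)), float(np.median(y)))


def premodified_length_distribution(calls: pd.DataFrame,
                                    types: Sequence[str] = MONO_TYPES
                                    ) -> pd.DataFrame:
    """Histogram of templated-body length (read length - tail length) per
    mono tail type, for tailed reads only. Rows: body length; columns: type;
    a 'mode' row-attribute is not stored — use :func:`premodified_modes`."""
    df = calls[(calls["primary"]) & (calls["tail_len"] == 1)]
    rows = {}
    for t in types:
        sub = df[df["tail_type"] == t]
        if len(sub):
            body_len = sub["seq"].str.len() - sub["tail_len"]
            hist = sub.groupby(body_len)["count"].sum()
        else:
            hist = pd.Series(dtype=int)
        rows[t] = hist
    out = pd.DataFrame(rows).fillna(0).astype(int).sort_index()
    out.index.name = "body_length"
    return out


def premodified_modes(hist: pd.DataFrame) -> pd.Series:
    """Modal pre-modified (templated body) length per tail type; NaN for
    empty types, smallest length on ties."""
    modes = {}
    for t in hist.columns:
        col = hist[t]
        modes[t] = float(col.idxmax()) if col.sum() > 0 else np.nan
    return pd.Series(modes, name="modal_body_length")


def nta_expression_correlation(delta_fraction: pd.Series,
                               logfc: pd.Series) -> tuple[float, float]:
    """Spearman correlation between the per-miRNA change in a tail-type
    fraction and the miRNA's expression log fold change."""
    merged = pd.concat([delta_fraction.rename("d"), logfc.rename("l")],
                       axis=1, join="inner").dropna()
    if len(merged) < 10:
        raise ValueError(f"need >= 10 paired observations, got {len(merged)}")
    if merged["d"].nunique() == 1 or merged["l"].nunique() == 1:
        warnings.warn("constant vector: correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(merged["d"], merged["l"])
    return float(rho), float(p)


def fiveprime_isomir_summary(calls: pd.DataFrame,
                             threshold: float = 0.2) -> pd.DataFrame:
    """Per-miRNA fraction of reads with a shifted 5' end; miRNAs above
    ``threshold`` are flagged 5'-isomiR-rich."""
    if calls.empty:
        return pd.DataFrame(columns=["total", "shifted", "fraction", "rich"])
    g = calls.groupby("mature_id")
    total = g["count"].sum()
    shifted = calls[calls["shift5"] != 0].groupby("mature_id")["count"].sum()
    shifted = shifted.reindex(total.index, fill_value=0)
    frac = shifted / total
    return pd.DataFrame({"total": total, "shifted": shifted,
                         "fraction": frac, "rich": frac > threshold})
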