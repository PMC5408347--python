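"""tRNA-fragment (tiRNA) analysis: per-isotype pooling, 32-nt fraction,
coverage, end phasing, half-type classification and normalized fold changes.

Stress-induced tRNA halves are produced by a single endonucleolytic cut in
the anticodon loop (angiogenin-type cleavage). The signature is a sharp
~30-35 nt fragment population whose termini are "phased": 5' halves share a
common 3' terminus at the cleavage site (and start at the tRNA 5' end), and
3' halves share a common 5' terminus (and run to the mature 3' CCA end).

Reads are pooled per isotype (amino acid + anticodon); reads hitting genes of
two or more distinct isotypes cannot be attributed and are excluded (tallied
in a discard ledger). The longest gene of an isotype provides the canonical
coordinate frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ReadAssignment
from .references import ReferenceSet, TRNAGene

TIRNA_LENGTH = 32           # the focal fragment length
EXPLORATORY_WINDOW = (30, 35)
FIVE_PRIME_START_TOL = 2    # fragment must start within this of the 5' end
THREE_PRIME_END_TOL = 3     # ... or end within this of the 3' end (CCA-aware)


@dataclass
class PhasingResult:
    length: int
    n_fragments: int
    modal_end5: int
    modal_end3: int
    phased_fraction_end5: float
    phased_fraction_end3: float


@dataclass
class FragmentProfile:
    """Per-isotype fragment summary in the canonical gene's coordinates."""

    isotype: str
    gene: TRNAGene
    fragments: pd.DataFrame          # columns: start, end, count
    total_count: int = 0
    count_32nt: int = 0
    coverage: np.ndarray = field(default=None, repr=False)
    end5_spectrum: pd.Series = field(default=None, repr=False)
    end3_spectrum: pd.Series = field(default=None, repr=False)
    dominant_fragment: tuple[int, int, int] = (0, 0, 0)
    half_type: str = "internal"
    phased_fraction: float = float("nan")
    cleavage_offset: int | None = None
    phasing: PhasingResult | None = None


def collapse_to_isotype(assignments: Sequence[ReadAssignment],
                        refs: ReferenceSet
                        ) -> tuple[dict[str, pd.DataFrame], int]:
    """Pool tRNA-class reads per isotype.

    A read is kept iff all its tRNA hits fall in genes of exactly one
    isotype; its coordinates are taken from the hit on the canonical
    (longest) gene when present, else from the first hit in gene-id order
    ("mapped by their own offsets" — no realignment of paralog hits).
    Returns (isotype -> fragments DataFrame, cross-isotype discard count).
    """
    gene_isotype = {g.gene_id: g.isotype for g in refs.trna_genes}
    canonical = {iso: refs.canonical_gene(iso).gene_id for iso in refs.isotypes()}
    pooled: dict[str, dict[tuple[int, int], int]] = {}
    discarded = 0
    for a in assignments:
        if a.resolved_class != "tRNA":
            continue
        trna_hits = [h for h in a.hits if h.class_label == "tRNA"]
        if not trna_hits:
            continue
        isotypes = {gene_isotype[h.feature_id] for h in trna_hits}
        if len(isotypes) != 1:
            discarded += a.count
            continue
        iso = isotypes.pop()
        hit = next((h for h in sorted(trna_hits, key=lambda h: h.feature_id)
                    if h.feature_id == canonical[iso]),
                   min(trna_hits, key=lambda h: h.feature_id))
        frag = (hit.offset, hit.offset + len(a.sequence))
        pooled.setdefault(iso, {})
        pooled[iso][frag] = pooled[iso].get(frag, 0) + a.count
    out = {}
    for iso, frags in pooled.items():
        df = pd.DataFrame([(s, e, c) for (s, e), c in sorted(frags.items())],
                          columns=["start", "end", "count"])
        out[iso] = df
    return out, discarded


def classify_half(start: int, end: int, gene: TRNAGene,
                  start_tol: int = FIVE_PRIME_START_TOL,
                  end_tol: int = THREE_PRIME_END_TOL) -> tuple[str, int]:
    """Half-type of one fragment and its cleavage offset.

    five_prime_half: starts at (within ``start_tol`` of) the tRNA 5' end and
    ends inside the anticodon loop. three_prime_half: ends at (within
    ``end_tol`` of, accommodating CCA) the 3' end and starts inside the loop.
    Anything else is internal. The cleavage offset is the signed distance of
    the fragment's loop-side boundary from the anticodon-loop midpoint.
    """
    if not (0 <= start < end <= len(gene.seq)):
        raise ValueError(f"fragment [{start},{end}) outside gene {gene.gene_id}")
    in_loop = lambda pos: gene.loop_start <= pos < gene.loop_end
    mid = gene.loop_midpoint
    if start <= start_tol and in_loop(end):
        return "five_prime_half", end - mid
    if end >= len(gene.seq) - end_tol and in_loop(start):
        return "three_prime_half", start - mid
    boundary = min((start, end), key=lambda b: abs(b - mid))
    return "internal", boundary - mid


def end_phasing(fragments: pd.DataFrame, length: int = TIRNA_LENGTH) -> PhasingResult:
    """Modal termini and phased fractions among fragments of one length.

    The phased fraction at an end is the count share of fragments whose
    terminus equals the modal terminus; which end is biologically relevant
    depends on the half type (5' terminus for 3' halves and vice versa).
    """
    sel = fragments[(fragments["end"] - fragments["start"]) == length]
    n = int(sel["count"].sum())
    if n == 0:
        raise ValueError(f"no fragments of length {length}")
    end5 = sel.groupby("start")["count"].sum()
    end3 = sel.groupby("end")["count"].sum()
    modal5 = int(end5.index[np.argmax(end5.to_numpy())])
    modal3 = int(end3.index[np.argmax(end3.to_numpy())])
    return PhasingResult(length, n, modal5, modal3,
                         float(end5.loc[modal5] / n), float(end3.loc[modal3] / n))


def fraction_32nt(profile: FragmentProfile) -> float:
    """Share of focal-length (32 nt) reads among the isotype's fragments."""
    if profile.total_count == 0:
        warnings.warn(f"{profile.isotype}: zero fragments, 32-nt fraction undefined")
        return float("nan")
    return profile.count_32nt / profile.total_count


def build_profile(isotype: str, fragments: pd.DataFrame,
                  refs: ReferenceSet,
                  length: int = TIRNA_LENGTH) -> FragmentProfile:
    """Assemble the full per-isotype FragmentProfile."""
    gene = refs.canonical_gene(isotype)
    prof = FragmentProfile(isotype, gene, fragments)
    prof.total_count = int(fragments["count"].sum())
    frag_len = fragments["end"] - fragments["start"]
    prof.count_32nt = int(fragments.loc[frag_len == length, "count"].sum())
    cov = np.zeros(len(gene.seq), dtype=np.int64)
    for s, e, c in fragments.itertuples(index=False):
        cov[s:min(e, len(cov))] += c
    prof.coverage = cov
    prof.end5_spectrum = fragments.groupby("start")["count"].sum()
    prof.end3_spectrum = fragments.groupby("end")["count"].sum()
    dom = fragments.loc[fragments["count"].idxmax()] if len(fragments) else None
    if dom is not None:
        prof.dominant_fragment = (int(dom["start"]), int(dom["end"]), int(dom["count"]))
        s, e = prof.dominant_fragment[:2]
        e = min(e, len(gene.seq))
        prof.half_type, prof.cleavage_offset = classify_half(s, e, gene)
    if prof.count_32nt > 0:
        ph = end_phasing(fragments, length)
        prof.phasing = ph
        if prof.half_type == "three_prime_half":
            prof.phased_fraction = ph.phased_fraction_end5
        elif prof.half_type == "five_prime_half":
            prof.phased_fraction = ph.phased_fraction_end3
        else:
            prof.phased_fraction = max(ph.phased_fraction_end5,
                                       ph.phased_fraction_end3)
    return prof


def build_profiles(assignments: Sequence[ReadAssignment],
                   refs: ReferenceSet,
                   length: int = TIRNA_LENGTH
                   ) -> tuple[dict[str, FragmentProfile], int]:
    frag_sets, discarded = collapse_to_isotype(assignments, refs)
    profiles = {iso: build_profile(iso, frags, refs, length)
                for iso, frags in frag_sets.items()}
    return profiles, discarded


def isotype_logfc(ctrl_counts: pd.Series, stress_counts: pd.Series,
                  size_factors: tuple[float, float] | None = None,
                  pseudocount: float = 0.5) -> pd.Series:
    """Per-isotype log2 fold change of median-of-ratios-normalized counts."""
    idx = ctrl_counts.index.union(stress_counts.index)
    kc = ctrl_counts.reindex(idx, fill_value=0).astype(float)
    ks = stress_counts.reindex(idx, fill_value=0).astype(float)
    if size_factors is None:
        from .quant import CountMatrix
        cm = CountMatrix(pd.DataFrame({"ctrl": kc, "stress": ks}).astype(int))
        sf = cm.size_factors()
        sc, ss = float(sf["ctrl"]), float(sf["stress"])
    else:
        sc, ss = size_factors
    out = np.log2((ks / ss + pseudocount) / (kc / sc + pseudocount))
    out.name = "log2fc"
    return out


def profiles_table(profiles: dict[str, FragmentProfile],
                   logfc: pd.Series | None = None) -> pd.DataFrame:
    """Flat per-isotype summary TSV-ready table."""
    rows = []
    for iso in sorted(profiles):
        p = profiles[iso]
        rows.append({
            "isotype": iso,
            "total": p.total_count,
            "n32": p.count_32nt,
            "fraction32": fraction_32nt(p) if p.total_count else np.nan,
            "half_type": p.half_type,
            "modal_start": p.phasing.modal_end5 if p.phasing else -1,
            "modal_end": p.phasing.modal_end3 if p.phasing else -1,
            "phased_fraction": p.phased_fraction,
            "cleavage_offset": p.cleavage_offset,
            "log2fc": float(logfc.get(iso, np.nan)) if logfc is not None else np.nan,
        })
    return pd.DataFrame(rows).set_index("isotype")


def coverage_table(profiles: dict[str, FragmentProfile]) -> pd.DataFrame:
    """Long-format per-position read depth (BedGraph-like)."""
    rows = []
    for iso in sorted(profiles):
        p = profiles[iso]
        for pos, depth in enumerate(p.coverage):
            rows.append((iso, p.gene.gene_id, pos, int(depth)))
    return pd.DataFrame(rows, columns=["isotype", "gene_id", "position", "depth"])
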