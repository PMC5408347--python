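"""Reference annotations for small-RNA read classification.

Three kinds of references are handled:

* miRNA — hairpin precursor sequences (FASTA) plus mature-arm coordinates in a
  miRBase-dialect GFF3 (``miRNA`` features with ``ID``/``Name``/``Derives_from``
  attributes, coordinates 1-based closed *within the precursor*).
* tRNA — mature tRNA sequences (FASTA, sense strand, 3' CCA) plus a structure
  TSV giving isotype, anticodon and the anticodon-loop interval in cloverleaf
  coordinates.
* background classes — plain FASTA per class (rRNA, snoRNA, snRNA, piRNA,
  mRNA, repeat ...), used only as exact-match decoy targets.

Conventions: every sequence is normalised to the uppercase DNA alphabet
(U -> T) on load; all coordinates are 0-based half-open internally (GFF3 and
the structure TSV are converted at the boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Default class precedence used when a read matches several RNA classes.
DEFAULT_HIERARCHY = (
    "miRNA",
    "tRNA",
    "rRNA",
    "snoRNA",
    "snRNA",
    "piRNA",
    "mRNA",
    "repeat",
)


def normalize_seq(seq: str) -> str:
    """Uppercase and map RNA to DNA alphabet (U -> T)."""
    return str(seq).upper().replace("U", "T")


@dataclass(frozen=True)
class MiRNALocus:
    """A mature miRNA's position and arm within its hairpin precursor.

    ``downstream_context`` (the precursor sequence 3' of the mature end) is
    what disambiguates templated 3' extensions from non-templated tails.
    """

    precursor_id: str
    mature_id: str
    arm: str  # "5p" | "3p"
    precursor_seq: str
    mature_start: int  # 0-based
    mature_end: int    # half-open

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"{self.mature_id}: arm must be 5p or 3p, got {self.arm!r}")
        if not (0 <= self.mature_start < self.mature_end <= len(self.precursor_seq)):
            raise ValueError(
                f"{self.mature_id}: mature interval [{self.mature_start},{self.mature_end}) "
                f"outside precursor of length {len(self.precursor_seq)}"
            )
        n = self.mature_end - self.mature_start
        if not (16 <= n <= 28):
            raise ValueError(f"{self.mature_id}: mature length {n} outside [16, 28]")

    @property
    def mature_seq(self) -> str:
        return self.precursor_seq[self.mature_start:self.mature_end]

    @property
    def downstream_context(self) -> str:
        return self.precursor_seq[self.mature_end:]


@dataclass(frozen=True)
class TRNAGene:
    """A mature tRNA with isotype annotation and anticodon-loop interval."""

    gene_id: str
    isotype: str          # "AminoAcid-Anticodon", e.g. "Gly-GCC"
    seq: str              # mature sense sequence ending in CCA
    anticodon_start: int  # 0-based start of the anticodon triplet
    loop_start: int       # anticodon loop, half-open
    loop_end: int

    def __post_init__(self) -> None:
        if not self.seq.endswith("CCA"):
            raise ValueError(f"{self.gene_id}: mature tRNA must end in CCA")
        if not (60 <= len(self.seq) <= 100):
            raise ValueError(f"{self.gene_id}: length {len(self.seq)} outside [60, 100]")
        if not (self.loop_start <= self.anticodon_start
                and self.anticodon_start + 3 <= self.loop_end):
            raise ValueError(
                f"{self.gene_id}: anticodon [{self.anticodon_start},{self.anticodon_start + 3}) "
                f"not inside loop [{self.loop_start},{self.loop_end})"
            )

    @property
    def anticodon(self) -> str:
        return self.seq[self.anticodon_start:self.anticodon_start + 3]

    @property
    def loop_midpoint(self) -> int:
        return (self.loop_start + self.loop_end) // 2


@dataclass
class ReferenceSet:
    """All loaded references plus the class-resolution hierarchy."""

    mirna_loci: list[MiRNALocus] = field(default_factory=list)
    trna_genes: list[TRNAGene] = field(default_factory=list)
    background: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    class_hierarchy: tuple[str, ...] = DEFAULT_HIERARCHY

    def __post_init__(self) -> None:
        self._check_unique("miRNA", [l.mature_id for l in self.mirna_loci])
        self._check_unique("tRNA", [g.gene_id for g in self.trna_genes])
        for label, entries in self.background.items():
            self._check_unique(label, [i for i, _ in entries])
        present = set(self.background)
        if self.mirna_loci:
            present.add("miRNA")
        if self.trna_genes:
            present.add("tRNA")
        missing = present - set(self.class_hierarchy)
        if missing:
            raise ValueError(f"class hierarchy does not cover classes: {sorted(missing)}")

    @staticmethod
    def _check_unique(label: str, ids: Sequence[str]) -> None:
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ids in class {label}: {dupes}")

    # -- convenience lookups -------------------------------------------------
    def mirna_by_id(self) -> dict[str, MiRNALocus]:
        return {l.mature_id: l for l in self.mirna_loci}

    def trna_by_id(self) -> dict[str, TRNAGene]:
        return {g.gene_id: g for g in self.trna_genes}

    def isotypes(self) -> dict[str, list[TRNAGene]]:
        out: dict[str, list[TRNAGene]] = {}
        for g in self.trna_genes:
            out.setdefault(g.isotype, []).append(g)
        return out

    def canonical_gene(self, isotype: str) -> TRNAGene:
        """Longest gene of the isotype (ties broken by gene_id) — the
        coordinate frame fragments of that isotype are reported in."""
        genes = self.isotypes()[isotype]
        return max(genes, key=lambda g: (len(g.seq), g.gene_id))


# ---------------------------------------------------------------------------
# loaders

def _infer_arm(name: str, attrs: Mapping[str, Sequence[str]],
               start: int, end: int, precursor_len: int) -> str:
    """Arm precedence: -5p/-3p name suffix > explicit attribute > midpoint."""
    if name.endswith("-5p"):
        return "5p"
    if name.endswith("-3p"):
        return "3p"
    if "arm" in attrs:
        val = attrs["arm"][0]
        if val in ("5p", "3p"):
            return val
    midpoint = (start + end) / 2
    return "5p" if midpoint < precursor_len / 2 else "3p"


def load_mirna_annotation(precursor_fasta: str | Path,
                          mature_gff3: str | Path) -> list[MiRNALocus]:
    """Load mature miRNA loci from a precursor FASTA + miRBase-dialect GFF3.

    GFF3 coordinates (1-based closed, relative to the precursor) are converted
    to 0-based half-open. Mature records whose interval falls outside their
    precursor are rejected with a warning; an empty result is a hard error.
    """
    precursors = {rec.id: normalize_seq(rec.seq)
                  for rec in SeqIO.parse(str(precursor_fasta), "fasta")}
    db = gffutils.create_db(str(mature_gff3), dbfn=":memory:",
                            keep_order=True, merge_strategy="create_unique")
    loci: list[MiRNALocus] = []
    for feat in db.features_of_type("miRNA", order_by="start"):
        attrs = dict(feat.attributes)
        parent = attrs.get("Derives_from", [feat.seqid])[0]
        name = attrs.get("Name", attrs.get("ID", [f"{parent}-mature"]))[0]
        prec_seq = precursors.get(parent) or precursors.get(feat.seqid)
        if prec_seq is None:
            logger.warning("miRNA %s: precursor %s absent from FASTA; skipped", name, parent)
            continue
        start, end = feat.start - 1, feat.end  # GFF3 -> 0-based half-open
        if not (0 <= start < end <= len(prec_seq)):
            logger.warning("miRNA %s: interval [%d,%d) outside precursor (len %d); skipped",
                           name, start, end, len(prec_seq))
            continue
        arm = _infer_arm(name, attrs, start, end, len(prec_seq))
        prec_id = parent if parent in precursors else feat.seqid
        try:
            loci.append(MiRNALocus(prec_id, name, arm, prec_seq, start, end))
        except ValueError as exc:
            logger.warning("miRNA %s rejected: %s", name, exc)
    if not loci:
        raise ValueError(f"no valid mature miRNA records loaded from {mature_gff3}")
    loci.sort(key=lambda l: (l.precursor_id, l.mature_start, l.mature_id))
    return loci


_TRNA_TSV_COLS = ("gene_id", "isotype", "anticodon",
                  "anticodon_start", "loop_start", "loop_end")


def load_trna_annotation(trna_fasta: str | Path, structure_tsv: str | Path,
                         append_cca: bool = True) -> list[TRNAGene]:
    """Load mature tRNA genes from FASTA + a structure TSV.

    TSV columns: gene_id, isotype, anticodon, anticodon_start, loop_start,
    loop_end (coordinates 0-based, loop half-open). With ``append_cca`` a
    missing 3' CCA is appended. The annotated anticodon must equal the
    triplet at ``anticodon_start`` (sequences are sense strand, so no
    reverse-complement check applies); a mismatch is a hard error.
    """
    import pandas as pd

    seqs = {rec.id: normalize_seq(rec.seq)
            for rec in SeqIO.parse(str(trna_fasta), "fasta")}
    table = pd.read_csv(structure_tsv, sep="\t", dtype={"gene_id": str})
    missing = set(_TRNA_TSV_COLS) - set(table.columns)
    if missing:
        raise ValueError(f"structure TSV missing columns: {sorted(missing)}")
    genes: list[TRNAGene] = []
    for row in table.itertuples(index=False):
        seq = seqs.get(row.gene_id)
        if seq is None:
            raise ValueError(f"tRNA {row.gene_id}: sequence absent from FASTA")
        if append_cca and not seq.endswith("CCA"):
            seq = seq + "CCA"
        anticodon = normalize_seq(row.anticodon)
        found = seq[row.anticodon_start:row.anticodon_start + 3]
        if found != anticodon:
            raise ValueError(
                f"tRNA {row.gene_id}: anticodon mismatch — annotated {anticodon}, "
                f"sequence has {found} at position {row.anticodon_start}"
            )
        genes.append(TRNAGene(row.gene_id, row.isotype, seq,
                              int(row.anticodon_start),
                              int(row.loop_start), int(row.loop_end)))
    if not genes:
        raise ValueError(f"no tRNA genes loaded from {structure_tsv}")
    return genes


def load_background(fastas: Mapping[str, str | Path]) -> dict[str, list[tuple[str, str]]]:
    """Load background-class FASTAs: mapping class label -> [(id, seq), ...]."""
    out: dict[str, list[tuple[str, str]]] = {}
    for label, path in fastas.items():
        out[label] = [(rec.id, normalize_seq(rec.seq))
                      for rec in SeqIO.parse(str(path), "fasta")]
    return out


# ---------------------------------------------------------------------------
# writers (round-trip support; also used by the read simulator)

def write_mirna_annotation(loci: Iterable[MiRNALocus],
                           precursor_fasta: str | Path,
                           mature_gff3: str | Path) -> None:
    loci = list(loci)
    precursors: dict[str, str] = {}
    for l in loci:
        precursors.setdefault(l.precursor_id, l.precursor_seq)
    records = [SeqRecord(Seq(seq), id=pid, description="")
               for pid, seq in precursors.items()]
    SeqIO.write(records, str(precursor_fasta), "fasta")
    with open(mature_gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for pid, seq in precursors.items():
            fh.write(f"{pid}\t.\tmiRNA_primary_transcript\t1\t{len(seq)}\t.\t+\t.\t"
                     f"ID={pid};Name={pid}\n")
        for l in loci:
            fh.write(f"{l.precursor_id}\t.\tmiRNA\t{l.mature_start + 1}\t{l.mature_end}"
                     f"\t.\t+\t.\tID={l.mature_id};Name={l.mature_id};"
                     f"Derives_from={l.precursor_id}\n")


def write_trna_annotation(genes: Iterable[TRNAGene],
                          trna_fasta: str | Path,
                          structure_tsv: str | Path) -> None:
    genes = list(genes)
    records = [SeqRecord(Seq(g.seq), id=g.gene_id, description="") for g in genes]
    SeqIO.write(records, str(trna_fasta), "fasta")
    with open(structure_tsv, "w") as fh:
        fh.write("\t".join(_TRNA_TSV_COLS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.isotype}\t{g.anticodon}\t"
                     f"{g.anticodon_start}\t{g.loop_start}\t{g.loop_end}\n")


def write_background(background: Mapping[str, list[tuple[str, str]]],
                     directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for label, entries in background.items():
        path = directory / f"{label}.fasta"
        records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in entries]
        SeqIO.write(records, str(path), "fasta")
        paths[label] = path
    return paths


def write_reference_set(refs: ReferenceSet, directory: str | Path) -> dict[str, object]:
    """Write a full ReferenceSet under ``directory``; returns the file map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, object] = {
        "mirna_fasta": directory / "mirna_precursors.fasta",
        "mirna_gff3": directory / "mirna_mature.gff3",
        "trna_fasta": directory / "trna.fasta",
        "trna_tsv": directory / "trna_structure.tsv",
    }
    write_mirna_annotation(refs.mirna_loci, files["mirna_fasta"], files["mirna_gff3"])
    write_trna_annotation(refs.trna_genes, files["trna_fasta"], files["trna_tsv"])
    files["background"] = write_background(refs.background, directory / "background")
    return files


def load_reference_set(directory: str | Path,
                       hierarchy: Sequence[str] = DEFAULT_HIERARCHY) -> ReferenceSet:
    """Inverse of :func:`write_reference_set`."""
    directory = Path(directory)
    bg_dir = directory / "background"
    bg_paths = {p.stem: p for p in sorted(bg_dir.glob("*.fasta"))} if bg_dir.is_dir() else {}
    return ReferenceSet(
        mirna_loci=load_mirna_annotation(directory / "mirna_precursors.fasta",
                                         directory / "mirna_mature.gff3"),
        trna_genes=load_trna_annotation(directory / "trna.fasta",
                                        directory / "trna_structure.tsv"),
        background=load_background(bg_paths),
        class_hierarchy=tuple(hierarchy),
    )
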