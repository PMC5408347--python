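"""Synthetic small-RNA library generator with ground truth.

Generates toy references (hairpin precursors with embedded 5p/3p mature arms,
cloverleaf-annotated tRNAs, background decoy classes) and reads with the
statistical structure the downstream analysis assumes:

* class composition (miRNA ~9%/4.7%, tRNA ~7.5%/13% of reads for the
  control/stress conditions, the remainder spread over background classes);
* miRNA bodies with a 22-nt length mode, 5'/3' end shifts, and non-templated
  3' tails at the published mono-A/U/C rates (control 8.4/5.2/6.6%, stress
  5.6/6.5/5.0%), with mono-U biased 2.7x to the 3p arm and mono-C biased to
  the 5p arm;
* tail-type-specific pre-modified body lengths (C on 21-nt bodies, A/U on
  22-nt bodies);
* anticodon-loop tRNA cleavage concentrated in five isotypes (Gly-GCC,
  Gly-CCC, Glu-CTC, Asp-GTC, Val-CAC), phased 32-nt five-prime halves except
  Asp-GTC which yields three-prime halves, doubled under stress.

Every read's generating decomposition is recorded in a truth table. Tails
are non-templated by construction: when a sampled tail base collides with
the next template base the 3' cut is moved by up to 2 nt. Separately, a
configurable fraction of untailed reads is planted as templated +1
extensions whose final base mimics a tail — recorded as templated in the
truth, these exercise the caller's templated-priority rule. A fixed seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import ReadSet, collapse_reads
from .references import MiRNALocus, ReferenceSet, TRNAGene, write_reference_set

BASES = "ACGT"

TARGET_ISOTYPES = ("Gly-GCC", "Gly-CCC", "Glu-CTC", "Asp-GTC", "Val-CAC")
OTHER_ISOTYPES = ("Lys-CTT", "Leu-AAG", "Ser-GCT", "His-GTG", "Met-CAT",
                  "Arg-ACG", "Ala-AGC", "Pro-AGG", "Thr-AGT")
THREE_PRIME_ISOTYPES = ("Asp-GTC",)

CONTROL_CLASS_FRACTIONS = {
    "miRNA": 0.090, "tRNA": 0.075, "rRNA": 0.38, "snoRNA": 0.08,
    "snRNA": 0.05, "piRNA": 0.09, "mRNA": 0.16, "repeat": 0.075,
}
STRESS_CLASS_FRACTIONS = {
    "miRNA": 0.047, "tRNA": 0.130, "rRNA": 0.36, "snoRNA": 0.08,
    "snRNA": 0.05, "piRNA": 0.09, "mRNA": 0.168, "repeat": 0.075,
}

CONTROL_TAIL_FRACTIONS = {
    "A": 0.084, "T": 0.052, "C": 0.066, "G": 0.003,
    "AA": 0.002, "AAA": 0.001, "TT": 0.002, "CC": 0.002, "AT": 0.002,
}
STRESS_TAIL_FRACTIONS = {
    "A": 0.056, "T": 0.065, "C": 0.050, "G": 0.003,
    "AA": 0.0015, "AAA": 0.0005, "TT": 0.002, "CC": 0.0015, "AT": 0.0015,
}

#: 3p-arm : 5p-arm mono-tail fraction ratios (1.0 where unstated)
ARM_RATIOS = {"T": 2.7, "C": 0.5}

CONTROL_SHIFT3_PROBS = {-2: 0.03, -1: 0.15, 0: 0.57, 1: 0.20, 2: 0.05}
STRESS_SHIFT3_PROBS = {-2: 0.02, -1: 0.12, 0: 0.56, 1: 0.23, 2: 0.07}
SHIFT5_PROBS = {-2: 0.01, -1: 0.04, 0: 0.90, 1: 0.04, 2: 0.01}

#: pre-modified (templated body) length preference per mono-tail base
CONTROL_PREMOD_PROBS = {
    "A": {21: 0.30, 22: 0.45, 23: 0.25},
    "T": {21: 0.25, 22: 0.50, 23: 0.25},
    "C": {20: 0.25, 21: 0.55, 22: 0.20},
}
STRESS_PREMOD_PROBS = {
    "A": {21: 0.22, 22: 0.55, 23: 0.23},
    "T": {21: 0.25, 22: 0.50, 23: 0.25},
    "C": {20: 0.25, 21: 0.55, 22: 0.20},
}
GENERIC_BODY_PROBS = {21: 0.25, 22: 0.50, 23: 0.25}


@dataclass
class SimulationSpec:
    """All knobs of one simulated library; the defaults are the study
    conditions the package is exercised against."""

    seed: int
    n_reads: int = 100_000
    condition: str = "control"  # control | stress
    class_fractions: dict[str, float] = field(default_factory=lambda: dict(CONTROL_CLASS_FRACTIONS))
    # miRNA side
    n_loci: int = 30
    canonical_len_probs: dict[int, float] = field(default_factory=lambda: {21: 0.2, 22: 0.6, 23: 0.2})
    shift5_probs: dict[int, float] = field(default_factory=lambda: dict(SHIFT5_PROBS))
    shift3_probs: dict[int, float] = field(default_factory=lambda: dict(CONTROL_SHIFT3_PROBS))
    tail_fractions: dict[str, float] = field(default_factory=lambda: dict(CONTROL_TAIL_FRACTIONS))
    arm_ratios: dict[str, float] = field(default_factory=lambda: dict(ARM_RATIOS))
    premod_probs: dict[str, dict[int, float]] = field(default_factory=lambda: {k: dict(v) for k, v in CONTROL_PREMOD_PROBS.items()})
    next_base_a_rate: float = 0.25   # reference-level ambiguous-next-base rate
    ambiguity_rate: float = 0.1      # planted templated-extension mimics
    expression_sigma: float = 1.0    # log-normal locus abundance shape
    expression_logfc_sigma: float = 0.7  # per-locus stress logFC spread
    couple_c_expression: bool = True     # C-tail loss coupled to expression gain
    c_coupling_strength: float = 0.8
    # tRNA side
    target_isotypes: tuple[str, ...] = TARGET_ISOTYPES
    other_isotypes: tuple[str, ...] = OTHER_ISOTYPES
    three_prime_isotypes: tuple[str, ...] = THREE_PRIME_ISOTYPES
    target_share: float = 0.60       # read share of the five target isotypes
    target_stress_multiplier: float = 2.0
    target_p32: float = 0.80         # phased 32-nt emission rate, targets
    other_p32: float = 0.20          # ... other isotypes (control)
    jitter: float = 0.05             # +/-1 nt cleavage-site jitter
    # misc
    error_rate: float = 0.0          # uniform substitution rate (off: reads
                                     # with errors simply fail perfect matching)

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, not 1")
        if sum(self.tail_fractions.values()) > 1.0:
            raise ValueError("tail fractions sum above 1")
        for d in (self.shift5_probs, self.shift3_probs, self.canonical_len_probs):
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise ValueError("probability table does not sum to 1")
        bad = [p for p in list(self.tail_fractions.values())
               + [self.jitter, self.target_p32, self.other_p32,
                  self.ambiguity_rate, self.next_base_a_rate]
               if not 0.0 <= p <= 1.0]
        if bad:
            raise ValueError(f"probabilities outside [0,1]: {bad}")

    @classmethod
    def control(cls, seed: int, n_reads: int = 100_000, **overrides) -> "SimulationSpec":
        return cls(seed=seed, n_reads=n_reads, condition="control", **overrides)

    @classmethod
    def stress(cls, seed: int, n_reads: int = 100_000, **overrides) -> "SimulationSpec":
        defaults = dict(
            class_fractions=dict(STRESS_CLASS_FRACTIONS),
            shift3_probs=dict(STRESS_SHIFT3_PROBS),
            tail_fractions=dict(STRESS_TAIL_FRACTIONS),
            premod_probs={k: dict(v) for k, v in STRESS_PREMOD_PROBS.items()},
        )
        defaults.update(overrides)
        return cls(seed=seed, n_reads=n_reads, condition="stress", **defaults)


# ---------------------------------------------------------------------------
# references

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _next_base(rng: np.random.Generator, a_rate: float) -> str:
    """First downstream base after a mature end: 'A' with probability
    ``a_rate`` (the controlled templated-ambiguity composition), else one of
    the other bases."""
    if rng.random() < a_rate:
        return "A"
    return str(rng.choice(["C", "G", "T"]))


def make_references(spec: SimulationSpec,
                    out_dir: str | Path | None = None) -> ReferenceSet:
    """Toy references; identical for control and stress specs with the same
    seed (read-level randomness is drawn from a separate stream)."""
    rng = np.random.default_rng([spec.seed, 900])
    lens = sorted(spec.canonical_len_probs)
    len_p = [spec.canonical_len_probs[k] for k in lens]

    loci: list[MiRNALocus] = []
    for i in range(spec.n_loci):
        pid = f"syn-mir-{i:03d}"
        flank5 = _random_seq(rng, int(rng.integers(5, 9)))
        len5 = int(rng.choice(lens, p=len_p))
        len3 = int(rng.choice(lens, p=len_p))
        mature5 = _random_seq(rng, len5)
        nb5 = _next_base(rng, spec.next_base_a_rate)
        loop = nb5 + _random_seq(rng, int(rng.integers(8, 15)))
        mature3 = _random_seq(rng, len3)
        nb3 = _next_base(rng, spec.next_base_a_rate)
        flank3 = nb3 + _random_seq(rng, int(rng.integers(5, 10)))
        prec = flank5 + mature5 + loop + mature3 + flank3
        s5 = len(flank5)
        s3 = len(flank5) + len5 + len(loop)
        loci.append(MiRNALocus(pid, f"syn-miR-{i:03d}-5p", "5p", prec, s5, s5 + len5))
        loci.append(MiRNALocus(pid, f"syn-miR-{i:03d}-3p", "3p", prec, s3, s3 + len3))

    genes: list[TRNAGene] = []
    for iso in spec.target_isotypes + spec.other_isotypes:
        anticodon = iso.split("-")[1]
        body_len = 62 if iso in spec.three_prime_isotypes else 73
        body = list(_random_seq(rng, body_len))
        body[32:35] = list(anticodon)
        seq = "".join(body) + "CCA"
        gid = f"tRNA-{iso}-1"
        genes.append(TRNAGene(gid, iso, seq, 32, 30, 37))
        if rng.random() < 0.5:  # occasional paralog of the same isotype
            para = list(seq[:-3])
            for pos in rng.choice(np.arange(45, body_len - 5), size=2, replace=False):
                cur = para[int(pos)]
                para[int(pos)] = str(rng.choice([b for b in BASES if b != cur]))
            genes.append(TRNAGene(f"tRNA-{iso}-2", iso, "".join(para) + "CCA", 32, 30, 37))

    background = {}
    for label in spec.class_fractions:
        if label in ("miRNA", "tRNA"):
            continue
        background[label] = [(f"{label}-decoy-{j}", _random_seq(rng, 300))
                             for j in range(4)]

    refs = ReferenceSet(mirna_loci=loci, trna_genes=genes, background=background)
    if out_dir is not None:
        write_reference_set(refs, out_dir)
    return refs


# ---------------------------------------------------------------------------
# reads

def _sample_from(rng, table: Mapping) -> object:
    keys = list(table)
    p = np.asarray([table[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _arm_tail_probs(spec: SimulationSpec, arm: str) -> dict[str, float]:
    """Tail table with arm-specific multipliers applied at fixed totals
    (an r-fold 3p:5p bias at a 50/50 arm split)."""
    out = {}
    for tail, f in spec.tail_fractions.items():
        r = spec.arm_ratios.get(tail, 1.0) if len(tail) == 1 else 1.0
        mult = 2 * r / (1 + r) if arm == "3p" else 2 / (1 + r)
        out[tail] = f * mult
    return out


def _group_by_precursor(loci: Sequence[MiRNALocus]) -> list[dict[str, MiRNALocus]]:
    by_prec: dict[str, dict[str, MiRNALocus]] = {}
    for l in loci:
        by_prec.setdefault(l.precursor_id, {})[l.arm] = l
    return [by_prec[p] for p in sorted(by_prec)]


def _precursor_weights(spec: SimulationSpec, n_prec: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(sampling weights, per-precursor stress log2FC). Abundance is drawn
    per precursor — arms then split 50/50 — so arm-specific tail biases stay
    on target regardless of the abundance draw. Base abundances and stress
    fold changes are seeded by the spec seed only, so control and stress
    libraries built from the same seed share them."""
    rng = np.random.default_rng([spec.seed, 901])
    base = rng.lognormal(mean=0.0, sigma=spec.expression_sigma, size=n_prec)
    lfc = rng.normal(0.0, spec.expression_logfc_sigma, size=n_prec)
    w = base * (2.0 ** lfc) if spec.condition == "stress" else base
    return w / w.sum(), lfc


def _locus_c_multipliers(spec: SimulationSpec, weights: np.ndarray,
                         lfc: np.ndarray) -> np.ndarray:
    """Per-locus mono-C tail multipliers that anticorrelate with expression
    change, normalized so the library-wide mono-C fraction stays on target."""
    if spec.condition != "stress" or not spec.couple_c_expression:
        return np.ones_like(weights)
    mult = 2.0 ** (-spec.c_coupling_strength * lfc)
    mult = mult / np.average(mult, weights=weights)
    return np.clip(mult, 0.05, 4.0)


def _adjust_cut(prec: str, start: int, cut: int, tail_base: str) -> int:
    """Move the 3' cut so the first tail base is non-templated."""
    if cut >= len(prec) or prec[cut] != tail_base:
        return cut
    for delta in (-1, 1, -2, 2):
        c = cut + delta
        if start + 12 <= c <= len(prec) and (c == len(prec) or prec[c] != tail_base):
            return c
    return cut  # give up (rare); read stays ambiguous


@dataclass
class SimulatedLibrary:
    spec: SimulationSpec
    refs: ReferenceSet
    sequences: list[str]
    truth: pd.DataFrame

    @property
    def reads(self) -> ReadSet:
        return collapse_reads(self.sequences, sample_id=self.spec.condition)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fastq = out_dir / f"{self.spec.condition}.fastq"
        with open(fastq, "w") as fh:
            for i, seq in enumerate(self.sequences):
                fh.write(f"@r{i:07d}\n{seq}\n+\n{'I' * len(seq)}\n")
        truth_path = out_dir / f"{self.spec.condition}.truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        return {"fastq": fastq, "truth": truth_path}


def simulate_reads(spec: SimulationSpec,
                   refs: ReferenceSet | None = None) -> SimulatedLibrary:
    """Draw one library under the spec; returns sequences plus the per-read
    truth table (read_id, class, feature, arm, shift5, shift3, tail,
    start, end, seq)."""
    refs = refs if refs is not None else make_references(spec)
    cond_code = 1 if spec.condition == "stress" else 0
    rng = np.random.default_rng([spec.seed, 100 + cond_code])

    classes = sorted(spec.class_fractions)
    probs = np.array([spec.class_fractions[c] for c in classes])
    n_per_class = rng.multinomial(spec.n_reads, probs)

    precursors = _group_by_precursor(refs.mirna_loci)
    weights, lfc = _precursor_weights(spec, len(precursors))
    c_mult = _locus_c_multipliers(spec, weights, lfc)
    tail_probs_arm = {arm: _arm_tail_probs(spec, arm) for arm in ("5p", "3p")}

    iso_weights = _isotype_weights(spec)
    seqs: list[str] = []
    rows: list[tuple] = []

    for cls, n in zip(classes, n_per_class):
        if n == 0:
            continue
        if cls == "miRNA":
            _emit_mirna(spec, rng, precursors, weights, c_mult, tail_probs_arm,
                        int(n), seqs, rows)
        elif cls == "tRNA":
            _emit_tirna(spec, rng, refs, iso_weights, int(n), seqs, rows)
        else:
            _emit_background(rng, cls, refs.background[cls], int(n), seqs, rows)

    if spec.error_rate > 0:
        _apply_errors(rng, seqs, spec.error_rate)

    truth = pd.DataFrame(rows, columns=["read_id", "class", "feature", "arm",
                                        "shift5", "shift3", "tail",
                                        "start", "end", "seq"])
    truth["read_id"] = [f"r{i:07d}" for i in range(len(truth))]
    return SimulatedLibrary(spec, refs, seqs, truth)


def _isotype_weights(spec: SimulationSpec) -> dict[str, float]:
    k_t, k_o = len(spec.target_isotypes), len(spec.other_isotypes)
    w_t = spec.target_share / k_t
    w_o = (1.0 - spec.target_share) / k_o
    if spec.condition == "stress":
        w_t *= spec.target_stress_multiplier
    w = {iso: w_t for iso in spec.target_isotypes}
    w.update({iso: w_o for iso in spec.other_isotypes})
    total = sum(w.values())
    return {iso: v / total for iso, v in w.items()}


def _emit_mirna(spec, rng, precursors, weights, c_mult, tail_probs_arm,
                n, seqs, rows) -> None:
    shift5_keys = sorted(spec.shift5_probs)
    shift5_p = np.array([spec.shift5_probs[k] for k in shift5_keys], dtype=float)
    shift3_keys = sorted(spec.shift3_probs)
    shift3_p = np.array([spec.shift3_probs[k] for k in shift3_keys], dtype=float)
    idx = rng.choice(len(precursors), size=n, p=weights)
    arm_draws = rng.random(n)
    s5_draws = rng.choice(shift5_keys, size=n, p=shift5_p / shift5_p.sum())
    for r in range(n):
        arms = precursors[int(idx[r])]
        if len(arms) == 2:
            arm = "5p" if arm_draws[r] < 0.5 else "3p"
        else:
            arm = next(iter(arms))
        locus = arms[arm]
        prec = locus.precursor_seq
        tails = dict(tail_probs_arm[arm])
        if c_mult[int(idx[r])] != 1.0:
            tails["C"] = min(tails["C"] * c_mult[int(idx[r])], 0.5)
        untailed = 1.0 - sum(tails.values())
        u = rng.random()
        tail = ""
        acc = untailed
        if u >= acc:
            for t, f in tails.items():
                acc += f
                if u < acc:
                    tail = t
                    break
        shift5 = int(s5_draws[r])
        start = locus.mature_start + shift5
        if start < 0 or start >= len(prec):
            shift5, start = 0, locus.mature_start
        if tail:
            probs = spec.premod_probs.get(tail[0], GENERIC_BODY_PROBS)
            # rejection over the body length keeps the pre-modified length
            # distribution on target (collision odds are ~uniform across
            # lengths); the deterministic cut shift is a last resort
            for _ in range(6):
                body_len = int(_sample_from(rng, probs))
                cut = min(start + body_len, len(prec))
                if cut == len(prec) or prec[cut] != tail[0]:
                    break
            cut = _adjust_cut(prec, start, cut, tail[0])
        else:
            if rng.random() < spec.ambiguity_rate:
                shift3 = 1  # planted templated-extension mimic
            else:
                shift3 = int(rng.choice(shift3_keys, p=shift3_p / shift3_p.sum()))
            cut = min(max(locus.mature_end + shift3, start + 15), len(prec))
        seq = prec[start:cut] + tail
        seqs.append(seq)
        rows.append((None, "miRNA", locus.mature_id, arm, shift5,
                     cut - locus.mature_end, tail, start, cut, seq))


def _emit_tirna(spec, rng, refs, iso_weights, n, seqs, rows) -> None:
    isotypes = list(iso_weights)
    p = np.array([iso_weights[i] for i in isotypes])
    draws = rng.choice(len(isotypes), size=n, p=p)
    canonical = {iso: refs.canonical_gene(iso) for iso in isotypes}
    other_p32 = spec.other_p32
    if spec.condition == "stress":
        # stress spreads anticodon cleavage beyond the five focal isotypes
        other_p32 = min(1.0, spec.other_p32 * 3.75)
    for r in range(n):
        iso = isotypes[int(draws[r])]
        gene = canonical[iso]
        L = len(gene.seq)
        p32 = spec.target_p32 if iso in spec.target_isotypes else other_p32
        if rng.random() < p32:
            # phased half; jitter slides the whole fragment by 1 nt so the
            # off-mode fraction stays at the focal length
            jit = 1 if rng.random() < spec.jitter else 0
            if iso in spec.three_prime_isotypes:
                start, end = L - 33 + (1 - jit), L - jit
            else:
                start, end = jit, 32 + jit
        else:
            flen = int(rng.integers(18, 32))
            start = int(rng.integers(0, L - flen + 1))
            end = start + flen
        seq = gene.seq[start:end]
        seqs.append(seq)
        rows.append((None, "tRNA", iso, "", 0, 0, "", start, end, seq))


def _emit_background(rng, cls, entries, n, seqs, rows) -> None:
    for _ in range(n):
        fid, ref = entries[int(rng.integers(0, len(entries)))]
        flen = int(rng.integers(15, 36))
        start = int(rng.integers(0, len(ref) - flen + 1))
        seq = ref[start:start + flen]
        seqs.append(seq)
        rows.append((None, cls, fid, "", 0, 0, "", start, start + flen, seq))


def _apply_errors(rng, seqs: list[str], rate: float) -> None:
    for i, seq in enumerate(seqs):
        hits = np.nonzero(rng.random(len(seq)) < rate)[0]
        if len(hits) == 0:
            continue
        chars = list(seq)
        for pos in hits:
            cur = chars[pos]
            chars[pos] = str(rng.choice([b for b in BASES if b != cur]))
        seqs[i] = "".join(chars)
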