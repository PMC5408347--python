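"""Shared fixtures: crafted micro-references and session-scoped simulated
libraries, plus the brute-force isomiR oracle used for equivalence tests."""

from __future__ import annotations

import pytest

from srnaproc.references import MiRNALocus, ReferenceSet, TRNAGene
from srnaproc.simulate import SimulationSpec, make_references, simulate_reads


# ---------------------------------------------------------------------------
# independent oracle: enumerate every (start, templated-length) decomposition

def brute_force_isomir(seq: str, locus: MiRNALocus,
                       max_shift5: int = 2, max_tail: int = 3):
    """Exhaustive isomiR decomposition: every candidate start s and every
    templated prefix length L is enumerated; valid decompositions (exact
    prefix match, <= max_tail uncovered bases) are ranked by longest L, then
    smallest |shift5|, then negative shift5 first. Returns
    (shift5, shift3, tail) or None."""
    prec = locus.precursor_seq
    best_key, best = None, None
    for s in range(locus.mature_start - max_shift5,
                   locus.mature_start + max_shift5 + 1):
        if s < 0 or s >= len(prec):
            continue
        for L in range(1, len(seq) + 1):
            if s + L > len(prec):
                break
            if prec[s:s + L] != seq[:L]:
                break  # prefix property: longer L cannot match either
            if len(seq) - L > max_tail:
                continue
            shift5 = s - locus.mature_start
            key = (-L, abs(shift5), 0 if shift5 < 0 else 1)
            if best_key is None or key < best_key:
                best_key = key
                best = (shift5, (s + L) - locus.mature_end, seq[L:])
    return best


@pytest.fixture(scope="session")
def oracle():
    return brute_force_isomir


# ---------------------------------------------------------------------------
# crafted micro-references with fully known coordinates

@pytest.fixture()
def toy_locus():
    #          0         1         2         3         4         5
    #          0123456789012345678901234567890123456789012345678901234
    prec5 = "ACGTT"
    mature = "GATTACAGATTACAGATTACAG"  # 22 nt
    down = "GTCCATAAGGTTCAAGCTTGGATCC"
    prec = prec5 + mature + down
    return MiRNALocus("toy-mir-1", "toy-miR-1-5p", "5p", prec, 5, 27)


@pytest.fixture()
def toy_trna():
    # 76-nt gene, anticodon GCC at [32,35), loop [30,37)
    seq = ("GGGTCGTTAGCTCAGTTGGTAGAGCAGTTG" "AC" "GCC" "TT"  # 37 nt
           "GGTCGTAGGTTCGAATCCTACACGACCCATGCATGC"             # +36 = 73
           "CCA")
    assert len(seq) == 76 and seq[32:35] == "GCC"
    return TRNAGene("toy-tRNA-Gly-GCC-1", "Gly-GCC", seq, 32, 30, 37)


@pytest.fixture()
def toy_refs(toy_locus, toy_trna):
    return ReferenceSet(
        mirna_loci=[toy_locus],
        trna_genes=[toy_trna],
        background={"rRNA": [("rRNA-1", "ACGT" * 60)]},
    )


# ---------------------------------------------------------------------------
# session-scoped simulated libraries (shared across test modules)

@pytest.fixture(scope="session")
def sim_refs():
    return make_references(SimulationSpec.control(seed=11))


@pytest.fixture(scope="session")
def sim_control(sim_refs):
    return simulate_reads(SimulationSpec.control(seed=11, n_reads=50_000), sim_refs)


@pytest.fixture(scope="session")
def sim_stress(sim_refs):
    return simulate_reads(SimulationSpec.stress(seed=11, n_reads=50_000), sim_refs)
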