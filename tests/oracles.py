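"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: exact rational
allele counting over an enumerated cell mixture, hypergeometric tail
enumeration for Fisher's exact test, and reverse-complement enumeration for
strand collapse.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.stats import hypergeom

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def maf_by_cell_enumeration(alpha: Fraction, beta: Fraction, state: str,
                            config: str, n_cells: int = 1_000_000) -> Fraction:
    """Expected mutant-allele fraction by counting alleles over enumerated cells.

    Builds an integer population of ``n_cells`` cells (normal, tumor+CNA,
    tumor without CNA, with exact Fraction proportions), assigns each class
    its mutant and total allele copies under the clonal null, and returns
    mutant copies / total copies as an exact rational.
    """
    n_tumor_cna = int(alpha * beta * n_cells)
    n_tumor_plain = int(alpha * n_cells) - n_tumor_cna
    n_normal = n_cells - n_tumor_cna - n_tumor_plain
    assert Fraction(n_tumor_cna + n_tumor_plain, n_cells) == alpha

    # (total copies, mutant copies) per cell, by class
    normal = (2, 0)
    plain = (2, 1)  # tumor cell without the CNA: heterozygous mutant
    if state == "CN2":
        cna = (2, 1)
    elif state == "CN1":
        cna = (1, 1) if config == "mutant_retained" else (1, 0)
    elif state == "LOH":
        cna = (2, 2) if config == "mutant_duplicated" else (2, 0)
    else:
        raise ValueError(state)

    total = n_normal * normal[0] + n_tumor_plain * plain[0] + n_tumor_cna * cna[0]
    mutant = n_normal * normal[1] + n_tumor_plain * plain[1] + n_tumor_cna * cna[1]
    return Fraction(mutant, total)


def fisher_two_sided_by_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric point probabilities.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more likely than the observed one.
    """
    N = a + b + c + d
    K = a + b
    n = a + c
    k = np.arange(max(0, K + n - N), min(K, n) + 1)
    pmf = hypergeom.pmf(k, N, K, n)
    p_obs = hypergeom.pmf(a, N, K, n)
    return float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def mutation_label_by_enumeration(ref: str, alt: str, context: str) -> str:
    """Nine-type label computed by explicit pyrimidine-strand enumeration."""
    if ref in "AG":
        ref, alt, context = _COMP[ref], _COMP[alt], revcomp(context)
    if ref == "T":
        return f"T>{alt}"
    return f"C>{alt}_CpG" if context[2] == "G" else f"C>{alt}_nonCpG"


def apobec_by_enumeration(ref: str, alt: str, context: str) -> bool:
    """APOBEC TCW membership by explicit motif enumeration on both strands."""
    forward = ref == "C" and alt in "TG" and context in ("TCA", "TCT")
    rc = revcomp(context)
    backward = ref == "G" and _COMP[alt] in "TG" and rc in ("TCA", "TCT")
    return forward or backward


def all_snv_inputs():
    """Every (ref, alt, context) combination: 12 substitutions x 16 contexts."""
    bases = "ACGT"
    for ref in bases:
        for alt in bases:
            if alt == ref:
                continue
            for left in bases:
                for right in bases:
                    yield ref, alt, left + ref + right
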