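"""Point-mutation signature classification and per-sample summaries.

Substitutions are collapsed to the pyrimidine strand and binned into nine
types: C→A, C→G and C→T each split by whether the mutated cytosine sits in a
CpG dinucleotide, plus T→A, T→C and T→G.  APOBEC-mediated mutations are C→T
or C→G substitutions in a TCW motif (TCA or TCT after strand collapse).
Per-sample summaries report the total number of somatic mutations (TNSM), the
nine type fractions, the fraction of transversions (FT), the fraction of
APOBEC mutations (FA), and the mutation rate per megabase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

NINE_TYPES = (
    "C>A_CpG", "C>A_nonCpG",
    "C>G_CpG", "C>G_nonCpG",
    "C>T_CpG", "C>T_nonCpG",
    "T>A", "T>C", "T>G",
)

#: purine<->pyrimidine changes on the collapsed strand
TRANSVERSION_BASE_TYPES = frozenset({"C>A", "C>G", "T>A", "T>G"})

#: the clinical traits and genomic features of the outcome-association grid
CLINICAL_TRAITS = ("survival", "distant_metastasis", "local_relapse", "copd", "tumor_grade")
GENOMIC_FEATURES = ("TNSM", "FT") + NINE_TYPES + ("cna_genome_fraction", "TP53_status", "KRAS_status")


@dataclass
class SignatureSummary:
    sample: str
    tnsm: int
    fractions: dict[str, float] = field(default_factory=dict)  # keyed by NINE_TYPES
    ft: float = float("nan")    # fraction of transversions
    fa: float = float("nan")    # fraction of APOBEC-mediated mutations
    rate_per_mb: float = float("nan")


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _validate(ref: str, alt: str, context: str) -> None:
    for b in (ref, alt, *context):
        if b not in _COMPLEMENT:
            raise ValueError(f"non-ACGT base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} is not a 3-mer centered on ref {ref!r}")


def _collapse(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Reverse-complement purine-reference mutations to the pyrimidine strand."""
    if ref in ("A", "G"):
        return _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(context)
    return ref, alt, context


def classify_mutation_type(ref: str, alt: str, context: str) -> str:
    """Assign a substitution to one of the nine point-mutation types.

    ``context`` is the reference-strand 3-mer centered on the mutated base.
    C→X types split on CpG status (reference C followed by G after strand
    collapse); T→X types do not.
    """
    _validate(ref, alt, context)
    ref, alt, context = _collapse(ref, alt, context)
    base = f"{ref}>{alt}"
    if ref == "T":
        return base
    return f"{base}_CpG" if context[2] == "G" else f"{base}_nonCpG"


def is_apobec(ref: str, alt: str, context: str) -> bool:
    """True iff the substitution is C→T or C→G in a TCW motif (W = A or T)."""
    _validate(ref, alt, context)
    ref, alt, context = _collapse(ref, alt, context)
    return ref == "C" and alt in ("T", "G") and context in ("TCA", "TCT")


def summarize_sample(mutations, target_mb: float, sample: str = "") -> SignatureSummary:
    """Per-sample signature summary over a list of mutations with contexts.

    Accepts any objects with ``ref``, ``alt`` and ``context`` attributes.
    With no mutations, TNSM is 0 and the fractions are left undefined (NaN).
    """
    if not target_mb > 0:
        raise ValueError("target_mb must be positive")
    muts = list(mutations)
    n = len(muts)
    if n == 0:
        return SignatureSummary(sample=sample, tnsm=0, rate_per_mb=0.0)

    counts = dict.fromkeys(NINE_TYPES, 0)
    n_tv = 0
    n_apobec = 0
    for m in muts:
        label = classify_mutation_type(m.ref, m.alt, m.context)
        counts[label] += 1
        if label.split("_")[0] in TRANSVERSION_BASE_TYPES:
            n_tv += 1
        if is_apobec(m.ref, m.alt, m.context):
            n_apobec += 1
    return SignatureSummary(
        sample=sample,
        tnsm=n,
        fractions={k: v / n for k, v in counts.items()},
        ft=n_tv / n,
        fa=n_apobec / n,
        rate_per_mb=n / target_mb,
    )


def covariate_association(values, groups=None, test: str = "wilcoxon", table=None) -> float:
    """Two-sided association test between a signature summary and a covariate.

    ``wilcoxon``: rank-sum (Mann-Whitney) test between exactly two groups,
    exact when sample sizes permit, normal approximation otherwise (scipy's
    automatic policy).  ``fisher``: exact test on a 2x2 count table passed via
    ``table``.
    """
    if test == "fisher":
        if table is None:
            raise ValueError("fisher test requires a 2x2 table")
        return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])
    if test != "wilcoxon":
        raise ValueError(f"unknown test {test!r}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("wilcoxon rank-sum test requires exactly two groups")
    x = values[labels == uniq[0]]
    y = values[labels == uniq[1]]
    if x.size == 0 or y.size == 0:
        raise ValueError("each group needs at least one observation")
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")[1])


def enumerate_association_tests(traits=CLINICAL_TRAITS, features=GENOMIC_FEATURES):
    """The full trait-by-genomic-feature grid of outcome-association hypotheses.

    With the default five clinical traits and fourteen genomic features this
    enumerates 70 tests, the multiplicity burden controlled downstream by FDR.
    """
    return [(t, f) for t in traits for f in features]
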