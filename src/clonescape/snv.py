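"""Clonality testing for somatic point mutations.

A tumor specimen is a mixture: a fraction alpha of cells are tumor cells and,
within the tumor, a fraction beta may carry a copy-number alteration
overlapping the mutated site.  Under the null hypothesis that a mutation is
clonal (carried by every tumor cell, and therefore predating any overlapping
deletion or LOH), the expected mutant-allele fraction (MAF) of the sequencing
reads has a closed form in (alpha, beta) and the allele configuration.  The
observed mutant read count is compared against that expectation with a
one-sided exact binomial test: a small p-value means the mutant allele is
under-represented, supporting subclonality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

ALLELE_CONFIGS = {
    "CN2": ("none",),
    "CN1": ("mutant_retained", "mutant_lost"),
    "LOH": ("mutant_duplicated", "wildtype_duplicated"),
}

DEFAULT_P_CUTOFF = 0.05


@dataclass
class SomaticSnv:
    """A somatic point mutation with read counts and clonality annotations.

    ``pos`` is 0-based internally; file readers/writers convert to and from
    1-based.  ``beta`` is the CNA cell fraction among tumor cells
    (beta = c / alpha) inherited from the overlapping segment.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    sample: str = ""
    gene: str = ""
    consequence: str = "other"
    context: str = ""
    segment_state: str = "CN2"
    beta: float = 0.0
    allele_config: str = "none"
    expected_maf: float | None = None
    p_clonal: float | None = None
    clonality: str = "unassigned"

    def __post_init__(self) -> None:
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"alt_count ({self.alt_count}) must be within [0, depth={self.depth}]"
            )
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta ({self.beta}) must lie in [0, 1]")


@dataclass
class FsmSummary:
    """Fraction of subclonal mutations for one gene, sample, or cohort."""

    unit: str
    n_clonal: int
    n_subclonal: int
    fsm: float
    p_vs_background: float | None = None


def expected_maf(alpha: float, beta: float, state: str, allele_config: str = "none") -> float:
    """Closed-form expected mutant-allele fraction under the clonal null.

    All tumor cells carry the mutation; a fraction beta of them also carry the
    CNA.  Counting mutant and total allele copies over the cell mixture:

    - CN2 (no CNA, or beta = 0): alpha / 2
    - CN1, wild-type allele deleted (mutant retained): alpha / (2 - alpha*beta)
    - CN1, mutant allele deleted: alpha*(1 - beta) / (2 - alpha*beta)
    - LOH, mutant allele duplicated: alpha*(1 + beta) / 2
    - LOH, wild-type allele duplicated: alpha*(1 - beta) / 2

    AMP and CN0 have no clonal-null MAF here and raise; the caller marks such
    mutations excluded.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha ({alpha}) must lie in (0, 1]")
    if not (0.0 <= beta <= 1.0):
        raise ValueError(f"beta ({beta}) must lie in [0, 1]")
    if state in ("AMP", "CN0"):
        raise ValueError(f"state {state!r} unsupported: mark the mutation excluded")
    if state not in ALLELE_CONFIGS:
        raise ValueError(f"unknown copy state {state!r}")
    if beta == 0.0 or state == "CN2":
        return alpha / 2.0
    if state == "CN1":
        denom = 2.0 - alpha * beta
        if allele_config == "mutant_retained":
            return alpha / denom
        if allele_config == "mutant_lost":
            return alpha * (1.0 - beta) / denom
    elif state == "LOH":
        if allele_config == "mutant_duplicated":
            return alpha * (1.0 + beta) / 2.0
        if allele_config == "wildtype_duplicated":
            return alpha * (1.0 - beta) / 2.0
    raise ValueError(f"allele configuration {allele_config!r} invalid for state {state!r}")


def clonality_test(alt_count: int, depth: int, maf: float) -> float:
    """One-sided exact binomial lower-tail p-value P(X <= alt_count | depth, maf).

    Uniform-or-conservative under the clonal null by binomial discreteness.
    """
    if not (0 <= alt_count <= depth):
        raise ValueError("alt_count must lie in [0, depth]")
    if not (0.0 < maf < 1.0):
        raise ValueError(f"expected MAF {maf} is degenerate; cannot test")
    return float(stats.binom.cdf(alt_count, depth, maf))


def call_clonality(
    snv: SomaticSnv,
    alpha: float,
    alpha_cutoff: float = DEFAULT_P_CUTOFF,
) -> str:
    """Classify one mutation as clonal, subclonal, or excluded.

    Mutations in amplified or homozygously deleted regions are excluded.  When
    the allele configuration is unknown (``none`` in a CN1/LOH segment), both
    configurations are tested and the larger p-value is kept — the
    conservative choice, since either configuration could hold.  Degenerate
    configurations (expected MAF of 0 or 1) are skipped.
    """
    if snv.segment_state in ("AMP", "CN0"):
        snv.clonality = "excluded"
        return "excluded"

    configs = (
        ALLELE_CONFIGS[snv.segment_state]
        if snv.allele_config == "none" and snv.segment_state != "CN2"
        else (snv.allele_config,)
    )
    best = None
    for cfg in configs:
        maf = expected_maf(alpha, snv.beta, snv.segment_state, cfg)
        if not (0.0 < maf < 1.0):
            continue
        p = clonality_test(snv.alt_count, snv.depth, maf)
        if best is None or p > best[0]:
            best = (p, maf, cfg)
    if best is None:  # every configuration degenerate
        snv.clonality = "excluded"
        return "excluded"

    snv.p_clonal, snv.expected_maf, snv.allele_config = best
    snv.clonality = "subclonal" if snv.p_clonal < alpha_cutoff else "clonal"
    return snv.clonality


def fsm(calls) -> float:
    """Fraction of subclonal mutations among classified (non-excluded) calls."""
    counted = [c for c in calls if c in ("clonal", "subclonal")]
    if not counted:
        raise ValueError("all mutations excluded: FSM undefined")
    return sum(c == "subclonal" for c in counted) / len(counted)


def fsm_gene_test(gene_counts, background_counts) -> float:
    """Two-sided Fisher's exact p for a gene's clonal/subclonal split vs background."""
    table = np.asarray([gene_counts, background_counts])
    if table.sum() == 0:
        raise ValueError("empty 2x2 table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def enrichment_2x2(group_a_counts, group_b_counts):
    """Fractions and two-sided Fisher p for a 2x2 feature-by-group table.

    Each argument is (with_feature, without_feature) for one group; returns
    ((frac_a, frac_b), p).
    """
    a1, a0 = group_a_counts
    b1, b0 = group_b_counts
    p = fsm_gene_test(group_a_counts, group_b_counts)
    frac_a = a1 / (a1 + a0) if (a1 + a0) else float("nan")
    frac_b = b1 / (b1 + b0) if (b1 + b0) else float("nan")
    return (frac_a, frac_b), p


def fsm_by_unit(snvs: list[SomaticSnv], key) -> list[FsmSummary]:
    """Per-unit FSM summaries with Fisher tests against the pooled remainder.

    ``key`` maps an SNV to its unit (e.g. gene symbol or sample id); excluded
    and unassigned mutations are ignored.  Units with no classified mutations
    are omitted.
    """
    clonal: dict[str, int] = {}
    sub: dict[str, int] = {}
    for s in snvs:
        if s.clonality not in ("clonal", "subclonal"):
            continue
        u = key(s)
        if not u:
            continue
        d = sub if s.clonality == "subclonal" else clonal
        d[u] = d.get(u, 0) + 1
    total_c = sum(clonal.values())
    total_s = sum(sub.values())
    out = []
    for u in sorted(set(clonal) | set(sub)):
        nc, ns = clonal.get(u, 0), sub.get(u, 0)
        p = fsm_gene_test((nc, ns), (total_c - nc, total_s - ns))
        out.append(FsmSummary(unit=u, n_clonal=nc, n_subclonal=ns,
                              fsm=ns / (nc + ns), p_vs_background=p))
    return out
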