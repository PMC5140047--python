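"""Synthetic tumor genomes and methylation cohorts with known ground truth.

The generator realizes the mixture model the analyses invert: a specimen with
tumor purity alpha, copy-number segments each carried by a fraction beta of
tumor cells (c = alpha*beta of all cells), heterozygous-probe BAFs drawn
around the analytic band positions for the segment's state with truncated
Gaussian noise, and somatic SNVs whose mutant read counts are binomial at the
analytic expected mutant-allele fraction given purity, overlapping CNA, and
the mutation's cancer-cell fraction.  A companion generator produces
Infinium-style methylation matrices with planted probe-trait associations on
top of covariate structure.  Everything is reproducible under a fixed seed.

Defaults reflect the study conditions the analyses target: whole-exome depth
near 100x, purity spread over [0.2, 0.9], a slight majority of subclonal
point mutations, and SNP-array BAF noise of 0.03.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cna import CnaSegment
from .snv import ALLELE_CONFIGS, SomaticSnv, expected_maf

CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23))
_SEGMENT_LENGTH = 5_000_000
_SEGMENT_GAP = 1_000_000

DEFAULT_STATE_WEIGHTS = {"CN2": 0.30, "CN1": 0.30, "CN0": 0.05, "LOH": 0.25, "AMP": 0.10}


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    n_samples: int = 50
    purity_range: tuple[float, float] = (0.2, 0.9)
    n_segments: int = 60
    segment_states: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_WEIGHTS))
    subclonal_cna_prob: float = 0.35
    beta_range: tuple[float, float] = (0.2, 0.9)
    probes_per_segment: int = 200
    baf_noise_sd: float = 0.03
    n_snvs: int = 200
    subclonal_snv_prob: float = 0.55
    subclonal_ccf_range: tuple[float, float] = (0.1, 0.8)
    mean_depth: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        def _check_prob(name, v):
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")

        for name in ("n_samples", "n_segments", "probes_per_segment", "n_snvs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError(f"purity_range must be within (0, 1], got {self.purity_range}")
        lo, hi = self.beta_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError(f"beta_range must be within (0, 1], got {self.beta_range}")
        lo, hi = self.subclonal_ccf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError(
                f"subclonal_ccf_range must be within (0, 1), got {self.subclonal_ccf_range}")
        _check_prob("subclonal_cna_prob", self.subclonal_cna_prob)
        _check_prob("subclonal_snv_prob", self.subclonal_snv_prob)
        if self.baf_noise_sd < 0:
            raise ConfigError(f"baf_noise_sd must be non-negative, got {self.baf_noise_sd}")
        if not self.mean_depth > 0:
            raise ConfigError(f"mean_depth must be positive, got {self.mean_depth}")
        if not self.segment_states:
            raise ConfigError("segment_states must contain at least one state")
        for s, w in self.segment_states.items():
            if s not in DEFAULT_STATE_WEIGHTS:
                raise ConfigError(f"segment_states contains unknown state {s!r}")
            if w < 0:
                raise ConfigError(f"segment_states weight for {s} must be non-negative")
        if sum(self.segment_states.values()) <= 0:
            raise ConfigError("segment_states weights must sum to a positive value")


@dataclass
class TumorSample:
    """Container tying one sample's purity, segments, SNVs and summaries."""

    sample: str
    segments: list[CnaSegment]
    snvs: list[SomaticSnv]
    purity: float | None = None


@dataclass
class GroundTruth:
    sample: str
    alpha: float
    segment_truth: pd.DataFrame   # state, beta, c, clonality per segment
    snv_truth: pd.DataFrame       # clonality, ccf, config, expected maf per SNV


def baf_peak_positions(state: str, c: float) -> tuple[float, float]:
    """Analytic BAF band positions for a CNA carried by a fraction c of all cells.

    These are the closed forms the downstream peak-inversion uses; the
    round-trip (simulate with c, invert bands back to c) is exact at zero
    noise.  CN0 probes retain only normal-cell signal (bands at 0.5); AMP uses
    a single extra copy of one allele as its generic representation.
    """
    if state == "CN2" or c == 0.0:
        return 0.5, 0.5
    if state == "CN1":
        return (1.0 - c) / (2.0 - c), 1.0 / (2.0 - c)
    if state == "LOH":
        return (1.0 - c) / 2.0, (1.0 + c) / 2.0
    if state == "CN0":
        return 0.5, 0.5
    if state == "AMP":
        return 1.0 / (2.0 + c), (1.0 + c) / (2.0 + c)
    raise ConfigError(f"unknown state {state!r}")


def _expected_read_ratio(state: str, c: float) -> float:
    total = {"CN2": 2.0, "CN1": 2.0 - c, "CN0": 2.0 - 2.0 * c,
             "LOH": 2.0, "AMP": 2.0 + c}[state]
    return total / 2.0


def _truncated_normal(rng: np.random.Generator, loc: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0:
        return np.asarray(loc, dtype=float)
    a = (0.0 - loc) / sd
    b = (1.0 - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, random_state=rng)


def _random_context(rng: np.random.Generator, ref: str) -> str:
    bases = "ACGT"
    return bases[rng.integers(4)] + ref + bases[rng.integers(4)]


def simulate_tumor_sample(config: SimulationConfig, sample_index: int
                          ) -> tuple[TumorSample, GroundTruth]:
    """Simulate one tumor sample and its ground truth.

    Purity is drawn uniformly from ``purity_range``; each segment gets a state
    by the configured weights and, with probability ``subclonal_cna_prob``, a
    tumor-cell fraction beta drawn uniformly from ``beta_range`` (else
    beta = 1, clonal).  Probe BAFs sit at the analytic band positions for
    c = alpha*beta plus truncated-to-[0,1] Gaussian noise.  Each SNV lands
    uniformly on the genome, inherits the overlapping segment's state and
    beta (or a diploid background), is clonal with probability
    1 - ``subclonal_snv_prob`` (cancer-cell fraction 1) or subclonal with a
    CCF drawn from ``subclonal_ccf_range``, and receives a Poisson depth and a
    binomial mutant read count at CCF times the clonal-null expected MAF.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, sample_index])
    sid = f"S{sample_index:03d}"

    alpha = float(rng.uniform(*config.purity_range))

    states = list(config.segment_states)
    weights = np.array([config.segment_states[s] for s in states], dtype=float)
    weights /= weights.sum()

    segments: list[CnaSegment] = []
    seg_rows = []
    for i in range(config.n_segments):
        chrom = CHROMOSOMES[i % len(CHROMOSOMES)]
        offset = (i // len(CHROMOSOMES)) * (_SEGMENT_LENGTH + _SEGMENT_GAP)
        start, end = offset, offset + _SEGMENT_LENGTH
        state = states[rng.choice(len(states), p=weights)]
        if state == "CN2":
            beta = 0.0
        elif rng.random() < config.subclonal_cna_prob:
            beta = float(rng.uniform(*config.beta_range))
        else:
            beta = 1.0
        c = alpha * beta
        lo, hi = baf_peak_positions(state, c)
        side = rng.random(config.probes_per_segment) < 0.5
        loc = np.where(side, lo, hi)
        bafs = _truncated_normal(rng, loc, config.baf_noise_sd)
        ratio = _expected_read_ratio(state, c) + rng.normal(0.0, 0.02)
        segments.append(CnaSegment(
            chrom=chrom, start=start, end=end, state=state, sample=sid,
            read_ratio=max(ratio, 1e-3), baf_values=bafs,
        ))
        seg_rows.append({
            "sample": sid, "chrom": chrom, "start": start, "end": end,
            "state": state, "beta": beta, "c": c,
            "clonality": ("none" if state == "CN2"
                          else ("clonal" if beta == 1.0 else "subclonal")),
        })

    # SNVs: place uniformly over the segment-covered genome plus a diploid
    # background with the same footprint
    snvs: list[SomaticSnv] = []
    snv_rows = []
    bases = "ACGT"
    for j in range(config.n_snvs):
        if rng.random() < 0.5:
            k = int(rng.integers(len(segments)))
            seg = segments[k]
            pos = int(rng.integers(seg.start, seg.end))
            chrom, state = seg.chrom, seg.state
            beta = seg_rows[k]["beta"]
        else:  # diploid background between segments
            chrom = CHROMOSOMES[int(rng.integers(len(CHROMOSOMES)))]
            pos = int(rng.integers(0, 200_000_000))
            state, beta = "CN2", 0.0

        clonal = rng.random() >= config.subclonal_snv_prob
        ccf = 1.0 if clonal else float(rng.uniform(*config.subclonal_ccf_range))

        if state in ("AMP", "CN0") or state == "CN2" or beta == 0.0:
            cfg = "none"
            null_maf = alpha / 2.0
        else:
            options = ALLELE_CONFIGS[state]
            cfg = options[int(rng.integers(len(options)))]
            null_maf = expected_maf(alpha, beta, state, cfg)
            if null_maf == 0.0:  # mutation on the lost allele of a clonal CNA
                cfg = options[0]  # is unobservable; keep the retained copy
                null_maf = expected_maf(alpha, beta, state, cfg)

        maf = ccf * null_maf
        depth = max(int(rng.poisson(config.mean_depth)), 1)
        alt = int(rng.binomial(depth, min(maf, 1.0)))
        ref = bases[int(rng.integers(4))]
        alt_base = rng.choice([b for b in bases if b != ref])
        snvs.append(SomaticSnv(
            chrom=chrom, pos=pos, ref=ref, alt=str(alt_base),
            depth=depth, alt_count=alt, sample=sid,
            gene=f"GENE{int(rng.integers(1, 51)):02d}",
            consequence=("nonsynonymous" if rng.random() < 0.7 else "synonymous"),
            context=_random_context(rng, ref),
            segment_state=state, beta=beta,
        ))
        snv_rows.append({
            "sample": sid, "chrom": chrom, "pos": pos,
            "clonality": "clonal" if clonal else "subclonal", "ccf": ccf,
            "state": state, "beta": beta, "allele_config": cfg,
            "expected_maf": maf,
        })

    sample = TumorSample(sample=sid, segments=segments, snvs=snvs)
    truth = GroundTruth(sample=sid, alpha=alpha,
                        segment_truth=pd.DataFrame(seg_rows),
                        snv_truth=pd.DataFrame(snv_rows))
    return sample, truth


def simulate_cohort(config: SimulationConfig) -> tuple[list[TumorSample], list[GroundTruth]]:
    """Simulate ``config.n_samples`` independent tumor samples."""
    pairs = [simulate_tumor_sample(config, i) for i in range(config.n_samples)]
    return [p[0] for p in pairs], [p[1] for p in pairs]


# ---------------------------------------------------------------------------
# Methylation cohort with planted associations
# ---------------------------------------------------------------------------

@dataclass
class MethylationDataset:
    methylation: pd.DataFrame    # probes x samples, beta values
    trait: pd.Series
    covariates: pd.DataFrame     # smoking, age, stage, sex
    annotations: pd.DataFrame    # probe, annotation_cgi, annotation_region
    planted: list[str]           # probe ids carrying a true trait effect


def simulate_methylation_dataset(
    n_samples: int,
    n_probes: int,
    n_assoc: int,
    effect_size: float = 0.05,
    seed: int = 0,
    probe_noise_sd: float = 0.05,
) -> MethylationDataset:
    """Methylation matrix with ``n_assoc`` probes linearly tied to the trait.

    The trait (a mutation-burden-like score) depends on smoking, age and
    stage plus noise.  Every probe carries small random covariate loadings;
    the planted probes additionally shift by ``effect_size`` beta units per
    standard deviation of the trait, so each planted probe has an independent
    marginal association of controlled strength.  Values are clipped to the
    open beta-value range.  Probes carry CGI-class and gene-region annotations
    drawn at Infinium-450K-like proportions.
    """
    if n_assoc > n_probes:
        raise ConfigError(f"n_assoc ({n_assoc}) cannot exceed n_probes ({n_probes})")
    rng = np.random.default_rng(seed)

    covariates = pd.DataFrame({
        "smoking": rng.integers(0, 2, n_samples),
        "age": rng.normal(65.0, 8.0, n_samples).round(1),
        "stage": rng.integers(1, 4, n_samples),
        "sex": rng.integers(0, 2, n_samples),
    }, index=[f"S{i:03d}" for i in range(n_samples)])

    trait = (
        0.5 * covariates["smoking"].to_numpy()
        + 0.02 * (covariates["age"].to_numpy() - 65.0)
        + 0.3 * (covariates["stage"].to_numpy() - 2)
        + rng.normal(0.0, 1.0, n_samples)
    )
    z = (trait - trait.mean()) / trait.std(ddof=0)

    probes = [f"cg{i:08d}" for i in range(n_probes)]
    base = rng.uniform(0.15, 0.85, n_probes)
    smoking_load = rng.normal(0.0, 0.02, n_probes)
    age_load = rng.normal(0.0, 0.002, n_probes)

    M = (
        base[:, None]
        + smoking_load[:, None] * covariates["smoking"].to_numpy()[None, :]
        + age_load[:, None] * (covariates["age"].to_numpy() - 65.0)[None, :]
        + rng.normal(0.0, probe_noise_sd, (n_probes, n_samples))
    )
    planted_idx = rng.choice(n_probes, size=n_assoc, replace=False)
    M[planted_idx] += effect_size * z[None, :]
    np.clip(M, 0.01, 0.99, out=M)

    annotations = pd.DataFrame({
        "probe": probes,
        "annotation_cgi": rng.choice(["CGI", "nonCGI", "open-sea"], n_probes,
                                     p=[0.31, 0.36, 0.33]),
        "annotation_region": rng.choice(["promoter", "body", "3'UTR", "intergenic"],
                                        n_probes, p=[0.30, 0.35, 0.10, 0.25]),
    })
    return MethylationDataset(
        methylation=pd.DataFrame(M, index=probes, columns=covariates.index),
        trait=pd.Series(trait, index=covariates.index, name="TNSM"),
        covariates=covariates,
        annotations=annotations,
        planted=sorted(probes[i] for i in planted_idx),
    )
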