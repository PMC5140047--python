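"""Copy-number-alteration clonality and tumor-purity estimation from BAF.

Heterozygous SNP-array probes inside a deletion or copy-neutral LOH show two
B-allele-frequency (BAF) bands placed symmetrically about 0.5; the band
separation is a monotone function of the fraction of cells carrying the
event.  This module fits the two bands per segment with a constrained EM
mixture, inverts the band positions to a per-CNA cell fraction (pi), takes
the rightmost peak of the pi density as tumor purity (the primary clone),
and labels each CNA clonal or subclonal relative to that purity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

COPY_STATES = ("CN2", "CN1", "CN0", "LOH", "AMP")

#: minimum het probes for a segment to get a peak fit
MIN_PROBES = 50
#: band separation below which a fit is reported as degenerate (no imbalance)
DEGENERATE_SEPARATION = 0.02
#: a density peak must carry at least this share of total pi mass to count
MIN_PEAK_MASS = 0.05
#: relative tolerance of the clonal/subclonal rule: clonal iff c >= (1-rel_tol)*alpha
DEFAULT_REL_TOL = 0.2

# read-ratio thresholds for copy-state assignment (tumor/normal depth ratio)
RATIO_CN0_MAX = 0.3
RATIO_LOW_MAX = 0.9
RATIO_HIGH_MIN = 1.1
#: minimum mu2-mu1 treated as real allelic imbalance
IMBALANCE_MIN = 0.1


class EstimationError(RuntimeError):
    """Raised when a quantity cannot be estimated from the given data."""


@dataclass
class BafPeakFit:
    """Result of the symmetric two-component EM fit on a segment's BAFs."""

    mu1: float
    mu2: float
    weight: float       # mixing weight of the lower-mean component
    sd: float
    loglik: list[float] = field(default_factory=list)
    converged: bool = True
    degenerate: bool = False


@dataclass(eq=False)
class CnaSegment:
    """Genomic interval with copy state and clonality annotations.

    Coordinates are 0-based half-open internally; file readers/writers
    convert to and from 1-based inclusive.
    """

    chrom: str
    start: int
    end: int
    state: str
    sample: str = ""
    read_ratio: float | None = None
    baf_values: np.ndarray | None = None
    mu1: float | None = None
    mu2: float | None = None
    cell_fraction_c: float | None = None
    clonality: str = "unassigned"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end ({self.end}) must exceed start ({self.start})")
        if self.state not in COPY_STATES:
            raise ValueError(f"unknown copy state {self.state!r}")

    @property
    def pi(self) -> float | None:
        """Fraction of all cells carrying the CNA (alias of cell_fraction_c)."""
        return self.cell_fraction_c


@dataclass
class PurityEstimate:
    """Tumor purity as the rightmost peak of the per-CNA cell-fraction density."""

    alpha: float
    pi_values: np.ndarray
    density_peaks: np.ndarray   # ascending peak locations
    bandwidth: float


# ---------------------------------------------------------------------------
# BAF folding and the EM peak fit
# ---------------------------------------------------------------------------

def fold_baf(baf_values) -> np.ndarray:
    """Map each BAF v to min(v, 1-v), removing the arbitrary A/B allele labels."""
    b = np.asarray(baf_values, dtype=float)
    if b.size and (np.nanmin(b) < 0.0 or np.nanmax(b) > 1.0):
        raise ValueError("BAF values must lie in [0, 1]")
    return np.minimum(b, 1.0 - b)


def fit_baf_peaks(
    baf_values,
    max_iter: int = 1000,
    tol: float = 1e-8,
    min_probes: int = MIN_PROBES,
    sd_floor: float = 1e-4,
) -> BafPeakFit | None:
    """Fit a symmetric two-component Gaussian mixture to unfolded BAFs by EM.

    The components have means (mu, 1-mu) with shared variance, so the fit is
    identified by the geometry of heterozygous-probe BAFs.  Returns ``None``
    when fewer than ``min_probes`` values are supplied (the caller marks the
    segment unassigned).  The log-likelihood is non-decreasing across
    iterations; non-convergence returns the best fit so far with a warning.
    """
    b = np.asarray(baf_values, dtype=float)
    b = b[~np.isnan(b)]
    if b.size < min_probes:
        return None
    if b.min() < 0.0 or b.max() > 1.0:
        raise ValueError("BAF values must lie in [0, 1]")

    folded = np.minimum(b, 1.0 - b)
    # init the lower mean from the folded 10th percentile; the 90th sets scale
    mu = float(np.clip(np.quantile(folded, 0.10), 1e-3, 0.5))
    sd = max(float(np.quantile(folded, 0.90) - np.quantile(folded, 0.10)) / 2.0, 0.02)
    w = 0.5

    lls: list[float] = []
    converged = False
    for _ in range(max_iter):
        # E-step
        logp1 = np.log(max(w, 1e-12)) + stats.norm.logpdf(b, mu, sd)
        logp2 = np.log(max(1.0 - w, 1e-12)) + stats.norm.logpdf(b, 1.0 - mu, sd)
        m = np.maximum(logp1, logp2)
        log_total = m + np.log(np.exp(logp1 - m) + np.exp(logp2 - m))
        ll = float(np.sum(log_total))
        r = np.exp(logp1 - log_total)

        # M-step under the mirror constraint: reflect component-2 points
        mu_new = float(np.mean(r * b + (1.0 - r) * (1.0 - b)))
        var_new = float(np.mean(r * (b - mu_new) ** 2 + (1.0 - r) * (b - (1.0 - mu_new)) ** 2))
        sd_new = max(np.sqrt(var_new), sd_floor)
        w_new = float(np.mean(r))
        if mu_new > 0.5:  # keep the labeled component on the low side
            mu_new, w_new = 1.0 - mu_new, 1.0 - w_new
        delta = max(abs(mu_new - mu), abs(sd_new - sd), abs(w_new - w))
        mu, sd, w = mu_new, sd_new, w_new

        if lls and (abs(ll - lls[-1]) < tol or delta < 1e-7):
            lls.append(ll)
            converged = True
            break
        lls.append(ll)
    if not converged:
        warnings.warn("EM did not converge; returning best fit so far", RuntimeWarning)

    mu1, mu2 = mu, 1.0 - mu
    return BafPeakFit(
        mu1=mu1,
        mu2=mu2,
        weight=w,
        sd=sd,
        loglik=lls,
        converged=converged,
        degenerate=(mu2 - mu1) < DEGENERATE_SEPARATION,
    )


# ---------------------------------------------------------------------------
# Cell fraction from peak positions
# ---------------------------------------------------------------------------

def cell_fraction_from_peaks(mu1: float, mu2: float, state: str) -> float:
    """Invert the BAF band positions to the fraction c of all cells with the CNA.

    For a hemizygous deletion (CN1) in a fraction c of all cells the bands sit
    at (1-c)/(2-c) and 1/(2-c), so c = 2d/(1+d) with d = mu2-mu1.  For
    copy-neutral LOH the bands are (1-c)/2 and (1+c)/2, so c = d.  CN0
    segments carry no heterozygous tumor signal and AMP band positions depend
    on the unknown allele-specific copy number, so neither is supported.
    """
    if mu1 > mu2:
        raise ValueError("mu1 must not exceed mu2")
    d = mu2 - mu1
    if state == "CN1":
        c = 2.0 * d / (1.0 + d)
    elif state == "LOH":
        c = d
    elif state == "CN0":
        raise ValueError("CN0 segments have no heterozygous tumor signal; no cell fraction")
    else:
        raise ValueError(f"unsupported copy state for cell-fraction inversion: {state!r}")
    return float(np.clip(c, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Purity: rightmost peak of the pi density
# ---------------------------------------------------------------------------

def estimate_purity(
    pi_values,
    bandwidth_rule: str = "silverman",
    grid_size: int = 512,
    min_peak_mass: float = MIN_PEAK_MASS,
) -> PurityEstimate:
    """Estimate tumor purity as the rightmost peak of the CNA cell-fraction density.

    A Gaussian kernel density (Silverman's rule by default) is evaluated on a
    grid over [0, 1]; each local maximum is a candidate clone.  Peaks carrying
    less than ``min_peak_mass`` of the total density mass are discarded as
    noise.  Purity alpha is the location of the rightmost surviving peak.
    """
    pi = np.asarray(pi_values, dtype=float)
    pi = pi[~np.isnan(pi)]
    if pi.size == 0:
        raise EstimationError("no usable CNAs: cannot estimate purity")

    if pi.size == 1 or np.ptp(pi) < 1e-6:
        loc = float(np.clip(np.median(pi), 0.0, 1.0))
        return PurityEstimate(alpha=loc, pi_values=pi,
                              density_peaks=np.array([loc]), bandwidth=0.0)

    kde = stats.gaussian_kde(pi, bw_method=bandwidth_rule)
    bw = float(kde.factor * pi.std(ddof=1))
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = kde(grid)

    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    peak_idx = np.where(interior)[0] + 1
    if dens[0] > dens[1]:
        peak_idx = np.concatenate([[0], peak_idx])
    if dens[-1] > dens[-2]:
        peak_idx = np.concatenate([peak_idx, [grid_size - 1]])
    if peak_idx.size == 0:
        peak_idx = np.array([int(np.argmax(dens))])

    # watershed the grid at density minima between adjacent peaks and require
    # each peak's basin to carry a minimum share of total mass
    kept = []
    total = float(dens.sum())
    boundaries = [0]
    for a, b_ in zip(peak_idx[:-1], peak_idx[1:]):
        boundaries.append(int(a + np.argmin(dens[a:b_ + 1])))
    boundaries.append(grid_size - 1)
    for i, p in enumerate(peak_idx):
        mass = float(dens[boundaries[i]:boundaries[i + 1] + 1].sum()) / total
        if mass >= min_peak_mass:
            kept.append(p)
    if not kept:
        kept = [int(np.argmax(dens))]

    peaks = np.sort(grid[np.asarray(kept)])
    alpha = float(np.clip(peaks[-1], 1e-6, 1.0))
    return PurityEstimate(alpha=alpha, pi_values=pi, density_peaks=peaks, bandwidth=bw)


def classify_cna_clonality(
    segment: CnaSegment,
    purity: PurityEstimate,
    rel_tol: float = DEFAULT_REL_TOL,
) -> str:
    """Label a CNA clonal iff its cell fraction reaches (1-rel_tol) * purity."""
    if segment.cell_fraction_c is None:
        return "unassigned"
    label = "clonal" if segment.cell_fraction_c >= (1.0 - rel_tol) * purity.alpha else "subclonal"
    segment.clonality = label
    return label


# ---------------------------------------------------------------------------
# Copy-state assignment from the tumor/normal read ratio
# ---------------------------------------------------------------------------

def assign_copy_state(
    read_ratio: float,
    baf_peaks: tuple[float, float],
    cn0_max: float = RATIO_CN0_MAX,
    low_max: float = RATIO_LOW_MAX,
    high_min: float = RATIO_HIGH_MIN,
    imbalance_min: float = IMBALANCE_MIN,
) -> str:
    """Assign a copy state from the tumor/normal sequencing read ratio plus BAF.

    A near-zero ratio is a homozygous deletion (CN0); a reduced ratio with
    allelic imbalance is a hemizygous deletion (CN1); a near-diploid ratio is
    LOH when the BAF bands are split and CN2 when they are not; an elevated
    ratio is an amplification (AMP).  The clonal hemizygous-deletion ratio at
    cell fraction c is (2-c)/2, which motivates the default low threshold.
    """
    if not read_ratio > 0:
        raise ValueError("read ratio must be positive")
    mu1, mu2 = baf_peaks
    imbalanced = (mu2 - mu1) >= imbalance_min
    if read_ratio < cn0_max:
        return "CN0"
    if read_ratio < low_max:
        return "CN1" if imbalanced else "CN2"
    if read_ratio <= high_min:
        return "LOH" if imbalanced else "CN2"
    return "AMP"


# ---------------------------------------------------------------------------
# Per-sample driver
# ---------------------------------------------------------------------------

def analyze_sample_cnas(
    segments: list[CnaSegment],
    rel_tol: float = DEFAULT_REL_TOL,
    min_probes: int = MIN_PROBES,
) -> PurityEstimate:
    """Fit peaks, invert cell fractions, estimate purity, and label clonality.

    Operates in place on ``segments`` (each needs ``baf_values``).  Only CN1
    and LOH segments inform purity: CN0 has no heterozygous tumor signal and
    amplifications are excluded for their amplitude variability.
    """
    pis = []
    informative = []
    for seg in segments:
        if seg.state not in ("CN1", "LOH") or seg.baf_values is None:
            continue
        fit = fit_baf_peaks(seg.baf_values, min_probes=min_probes)
        if fit is None:
            seg.clonality = "unassigned"
            logger.info("segment %s:%d-%d has too few probes; unassigned",
                        seg.chrom, seg.start, seg.end)
            continue
        seg.mu1, seg.mu2 = fit.mu1, fit.mu2
        seg.cell_fraction_c = cell_fraction_from_peaks(fit.mu1, fit.mu2, seg.state)
        pis.append(seg.cell_fraction_c)
        informative.append(seg)

    purity = estimate_purity(pis)
    for seg in informative:
        classify_cna_clonality(seg, purity, rel_tol=rel_tol)
    return purity
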