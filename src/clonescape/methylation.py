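"""Per-CpG-probe association between methylation and mutation-signature traits.

For each probe, the mutation trait (TNSM, FT, FA, or a type fraction) is
regressed on the probe's methylation beta value with covariate adjustment
(smoking status, age, stage, sex by default); the methylation coefficient and
its two-sided t-test p-value are reported.  Genome-wide significance uses a
Bonferroni threshold over the number of probes tested; per-annotation-category
enrichment is summarized as a fold change of significant-probe proportions,
and the share of significant probes with positive effects is reported per
category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CGI_CATEGORIES = ("CGI", "nonCGI", "open-sea")
REGION_CATEGORIES = ("promoter", "body", "3'UTR", "intergenic")


@dataclass
class ProbeAssociation:
    probe: str
    trait: str
    effect: float
    p: float
    significant: bool = False
    annotation_cgi: str = ""
    annotation_region: str = ""


@dataclass
class EnrichmentResult:
    category: str
    k_cat: int
    n_cat: int
    k_all: int
    n_all: int
    fold: float
    frac_positive: float | None = None

    @property
    def fold_display(self) -> float:
        """Fold change rounded to one decimal for display; full precision in .fold."""
        return round(self.fold, 1)


class CollinearDesignError(ValueError):
    """Raised when the regression design matrix is rank-deficient."""


def _design(methylation: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    cols = [np.ones_like(methylation), methylation]
    if covariates is not None:
        cov = pd.get_dummies(covariates, drop_first=True).to_numpy(dtype=float)
        cols.extend(cov.T)
    return np.column_stack(cols)


def probe_association(methylation, trait, covariates: pd.DataFrame | None = None):
    """OLS of trait on methylation plus covariates; returns (effect, p).

    ``effect`` is the methylation coefficient; ``p`` is its two-sided t-test
    p-value.  Rows with missing values are dropped listwise.  A rank-deficient
    design raises ``CollinearDesignError`` so the caller can skip the probe.
    """
    m = np.asarray(methylation, dtype=float)
    t = np.asarray(trait, dtype=float)
    if m.shape != t.shape:
        raise ValueError("methylation and trait must have equal length")
    keep = ~(np.isnan(m) | np.isnan(t))
    if covariates is not None:
        keep &= ~covariates.isna().any(axis=1).to_numpy()
        covariates = covariates.loc[keep]
    m, t = m[keep], t[keep]

    X = _design(m, covariates)
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} complete observations, got {n}")
    if np.linalg.matrix_rank(X) < k:
        raise CollinearDesignError("design matrix is rank deficient")

    coef, _, _, _ = np.linalg.lstsq(X, t, rcond=None)
    resid = t - X @ coef
    df = n - k
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    tstat = coef[1] / se
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return float(coef[1]), float(p)


def associate_probes(
    methylation: pd.DataFrame,
    trait,
    covariates: pd.DataFrame | None = None,
    trait_name: str = "trait",
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Vectorized per-probe association scan (probes x samples matrix).

    Equivalent to running :func:`probe_association` per probe: the trait and
    every probe are residualized on the covariates (Frisch-Waugh-Lovell), so
    the per-probe slope, t-statistic and p match the full multiple regression.
    Constant probes are skipped with a logged reason.
    """
    M = methylation.to_numpy(dtype=float)  # probes x samples
    t = np.asarray(trait, dtype=float)
    n = t.size
    if M.shape[1] != n:
        raise ValueError("methylation columns must match trait length")

    if covariates is None:
        Z = np.ones((n, 1))
    else:
        cov = pd.get_dummies(covariates, drop_first=True).to_numpy(dtype=float)
        Z = np.column_stack([np.ones(n), cov])
    # residualize on [1, covariates]
    Q, _ = np.linalg.qr(Z)
    t_res = t - Q @ (Q.T @ t)
    M_res = M - (M @ Q) @ Q.T

    ss_m = np.einsum("ij,ij->i", M_res, M_res)
    ok = ss_m > 1e-12
    if not ok.all():
        logger.warning("skipping %d constant/collinear probes", int((~ok).sum()))
    slope = np.full(M.shape[0], np.nan)
    pvals = np.full(M.shape[0], np.nan)
    slope[ok] = (M_res[ok] @ t_res) / ss_m[ok]
    df = n - Z.shape[1] - 1
    resid_ss = float(t_res @ t_res) - slope[ok] ** 2 * ss_m[ok]
    sigma2 = np.maximum(resid_ss / df, 0.0)
    se = np.sqrt(sigma2 / ss_m[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = slope[ok] / se
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat), df)

    out = pd.DataFrame(
        {"probe": methylation.index, "trait": trait_name, "effect": slope, "p": pvals}
    )
    if annotations is not None:
        out = out.merge(annotations, on="probe", how="left")
    return out


def bonferroni_threshold(n_probes: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_probes."""
    if n_probes < 1:
        raise ValueError("n_probes must be at least 1")
    return alpha / n_probes


def enrichment_fold_change(k_cat: int, n_cat: int, k_all: int, n_all: int,
                           category: str = "") -> EnrichmentResult:
    """Fold change of the significant-probe proportion in a category vs overall.

    fold = (k_cat/n_cat) / (k_all/n_all).  Full precision is retained in
    ``fold``; ``fold_display`` rounds to one decimal.
    """
    if n_cat <= 0 or n_all <= 0:
        raise ValueError("category and overall totals must be positive")
    if k_cat > n_cat or k_all > n_all:
        raise ValueError("significant counts cannot exceed totals")
    if k_all == 0:
        fold = float("nan")
    else:
        fold = (k_cat / n_cat) / (k_all / n_all)
    return EnrichmentResult(category=category, k_cat=k_cat, n_cat=n_cat,
                            k_all=k_all, n_all=n_all, fold=fold)


def fraction_positive(associations, category: str | None = None,
                      trait: str | None = None) -> float:
    """Share of significant probe associations with a positive effect.

    Optionally restricted to one annotation category (CGI class) and one
    trait.  Raises if nothing is significant in the selection.
    """
    sel = [
        a for a in associations
        if a.significant
        and (category is None or a.annotation_cgi == category)
        and (trait is None or a.trait == trait)
    ]
    if not sel:
        raise ValueError("no significant associations in selection")
    return sum(a.effect > 0 for a in sel) / len(sel)


def benjamini_hochberg(pvalues, q: float = 0.05) -> np.ndarray:
    """Step-up FDR procedure; returns a boolean significance flag per p-value."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p)
    ranked = p[order]
    below = ranked <= q * np.arange(1, n + 1) / n
    flags = np.zeros(n, dtype=bool)
    if below.any():
        cutoff = np.max(np.where(below)[0])
        flags[order[: cutoff + 1]] = True
    return flags


def enrichment_by_category(assoc: pd.DataFrame, threshold: float,
                           category_col: str = "annotation_cgi") -> list[EnrichmentResult]:
    """Per-category enrichment of Bonferroni-significant probes.

    ``assoc`` needs columns ``p``, ``effect`` and the category column.  Each
    category's fold change compares its significant-probe proportion to the
    overall proportion; ``frac_positive`` is the share of its significant
    probes with a positive effect (None when it has none).
    """
    ok = assoc.dropna(subset=["p"])
    sig = ok["p"] < threshold
    k_all, n_all = int(sig.sum()), len(ok)
    results = []
    for cat, grp in ok.groupby(category_col, sort=True):
        gsig = grp["p"] < threshold
        res = enrichment_fold_change(int(gsig.sum()), len(grp), k_all, n_all, category=str(cat))
        if gsig.any():
            res.frac_positive = float((grp.loc[gsig, "effect"] > 0).mean())
        results.append(res)
    return results
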