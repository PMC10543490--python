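"""Plexus volumetry and lifespan regression statistics.

Volumes are regressed on age, sex and total intracranial volume with a
Gaussian generalized linear model (identity link, so the fit is maximum
likelihood / least squares); McFadden's pseudo-R^2 compares the fitted
log-likelihood with the intercept-only model's, and all p-values reported by
one analysis call pass through a single joint Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .image_io import BinaryMask3D, CohortManifest
from .metrics import fdr_adjust

__all__ = [
    "RegressionFit",
    "mask_volume_cm3",
    "fit_glm_gaussian",
    "mcfadden_r2",
    "lifespan_analysis",
    "LifespanResult",
    "metrics_vs_ventricle",
]


def mask_volume_cm3(mask: BinaryMask3D) -> float:
    """Set-voxel count times voxel volume (mm^3), reported in cm^3."""
    return float(mask.data.sum()) * mask.voxel_volume_mm3 / 1000.0


@dataclasses.dataclass
class RegressionFit:
    """Gaussian GLM output: coefficients, Wald inference, log-likelihood."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    n: int
    design: str
    response: np.ndarray

    def coef(self, term: str) -> float:
        return float(self.params[term])

    def conf_int95(self, term: str) -> tuple[float, float]:
        b, se = float(self.params[term]), float(self.bse[term])
        return (b - 1.96 * se, b + 1.96 * se)


def _gaussian_llf(resid: np.ndarray) -> float:
    # profile (ML-variance) Gaussian log-likelihood
    n = len(resid)
    ssr = float((resid**2).sum())
    if ssr <= 0:
        raise ValueError("zero residual variance: log-likelihood unbounded")
    return -n / 2.0 * (np.log(2 * np.pi * ssr / n) + 1.0)


def fit_glm_gaussian(y, X: pd.DataFrame | None, design: str = "") -> RegressionFit:
    """Fit a Gaussian/identity GLM with an intercept.

    ``X`` may be None (or empty) for the intercept-only null model.  The
    log-likelihood uses the maximum-likelihood variance estimate so McFadden
    pseudo-R^2 is well defined for nested Gaussian fits.
    """
    y = np.asarray(y, dtype=np.float64)
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        X = pd.DataFrame(index=range(len(y)))
    X = pd.DataFrame(X).reset_index(drop=True)
    if len(X) != len(y):
        raise ValueError("response and design lengths differ")
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("missing values in the design or response")
    Xc = sm.add_constant(X, has_constant="add")
    n, p = Xc.shape
    if n <= p:
        raise ValueError("need more observations than model terms")
    rank = np.linalg.matrix_rank(Xc.values)
    if rank < p:
        # name the offending columns via tiny R diagonal entries
        _, R = np.linalg.qr(Xc.values)
        bad = [Xc.columns[i] for i in range(p) if abs(R[i, i]) < 1e-8 * max(1, abs(R[0, 0]))]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.GLM(y, Xc, family=sm.families.Gaussian()).fit()
    resid = y - res.fittedvalues
    if np.allclose(resid, 0):
        llf = np.inf  # perfect fit: residual variance 0
    else:
        llf = _gaussian_llf(resid)
    return RegressionFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        llf=float(llf),
        n=n,
        design=design or ("~ " + " + ".join(X.columns) if len(X.columns) else "~ 1"),
        response=y,
    )


def mcfadden_r2(fit: RegressionFit, null_fit: RegressionFit) -> float:
    """McFadden pseudo-R^2 = 1 - llf_model / llf_null."""
    if fit.n != null_fit.n or not np.allclose(fit.response, null_fit.response):
        raise ValueError("fits must share the same response vector")
    return float(1.0 - fit.llf / null_fit.llf)


def _design_from_manifest(meta: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": meta["age"].to_numpy(dtype=float),
            "sex_male": (meta["sex"] == "M").to_numpy(dtype=float),
            "tiv_cm3": meta["tiv_cm3"].to_numpy(dtype=float),
        }
    )


@dataclasses.dataclass
class LifespanResult:
    fits: dict  # modality -> RegressionFit
    null_fits: dict
    mcfadden: dict  # modality -> float
    coefficients: pd.DataFrame  # tidy: modality, term, estimate, se, p, p_fdr, significant
    percent_change_per_decade: dict  # modality -> float


def lifespan_analysis(
    manifest: CohortManifest | pd.DataFrame,
    volumes: pd.DataFrame,
    alpha: float = 0.05,
) -> LifespanResult:
    """Regress per-modality plexus volume on age + sex + TIV across the cohort.

    ``volumes`` has a ``subject_id`` column plus one volume column (cm^3) per
    modality.  All slope/covariate p-values from the three fits are adjusted
    jointly with Benjamini-Hochberg FDR; percent change per decade is
    10 * beta_age / mean(volume) * 100.
    """
    meta = manifest.rows if isinstance(manifest, CohortManifest) else manifest
    if len(meta) < 10:
        raise ValueError("need at least 10 subjects for the lifespan analysis")
    merged = meta.merge(volumes, on="subject_id", validate="one_to_one")
    if len(merged) != len(meta):
        raise ValueError("volumes table does not cover the cohort")
    modalities = [c for c in volumes.columns if c != "subject_id"]
    if not modalities:
        raise ValueError("no volume columns found")
    X = _design_from_manifest(merged)
    for col in X.columns:
        if np.allclose(X[col], X[col].iloc[0]):
            raise ValueError(f"constant covariate column: {col}")

    fits, null_fits, mcf, pct = {}, {}, {}, {}
    records = []
    for m in modalities:
        y = merged[m].to_numpy(dtype=float)
        fit = fit_glm_gaussian(y, X, design=f"{m} ~ age + sex_male + tiv_cm3")
        null = fit_glm_gaussian(y, None, design=f"{m} ~ 1")
        fits[m], null_fits[m] = fit, null
        mcf[m] = mcfadden_r2(fit, null)
        pct[m] = float(10.0 * fit.coef("age") / y.mean() * 100.0)
        for term in ("age", "sex_male", "tiv_cm3"):
            records.append(
                {
                    "modality": m,
                    "term": term,
                    "estimate": fit.coef(term),
                    "se": float(fit.bse[term]),
                    "p": float(fit.pvalues[term]),
                }
            )
    coef = pd.DataFrame.from_records(records)
    coef["p_fdr"] = fdr_adjust(coef["p"].to_numpy())
    coef["significant"] = coef["p_fdr"] < alpha
    return LifespanResult(fits, null_fits, mcf, coef, pct)


def metrics_vs_ventricle(scores: pd.DataFrame, lvv: pd.DataFrame,
                         metric_cols: tuple[str, ...] = ("dice", "hd95_mm", "auc"),
                         alpha: float = 0.05) -> pd.DataFrame:
    """One Gaussian GLM per performance metric against lateral ventricular volume.

    ``scores`` carries subject_id + metric columns; ``lvv`` carries subject_id
    + ``lvv_cm3``.  Slope p-values are FDR-adjusted across metrics.
    """
    merged = scores.merge(lvv[["subject_id", "lvv_cm3"]], on="subject_id",
                          validate="one_to_one")
    if len(merged) != len(scores):
        raise ValueError("subject ids do not match between tables")
    X = pd.DataFrame({"lvv_cm3": merged["lvv_cm3"].to_numpy(dtype=float)})
    records = []
    for col in metric_cols:
        y = merged[col].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            records.append({"metric": col, "slope": 0.0, "se": 0.0, "p": 1.0})
            continue
        fit = fit_glm_gaussian(y, X, design=f"{col} ~ lvv_cm3")
        records.append(
            {
                "metric": col,
                "slope": fit.coef("lvv_cm3"),
                "se": float(fit.bse["lvv_cm3"]),
                "p": float(fit.pvalues["lvv_cm3"]),
            }
        )
    out = pd.DataFrame.from_records(records)
    out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
    out["significant"] = out["p_fdr"] < alpha
    return out
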