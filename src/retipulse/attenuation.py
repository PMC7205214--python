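"""Pulse-wave attenuation statistics.

Assembles per-series amplitude records into (log10 HRW_a, V_Dist, ODF)
observations and fits the study's statistical battery:

* descriptive statistics of amplitude distributions (median, range, IQR,
  skewness, kurtosis, Pearson's second skewness coefficient) and the
  Kruskal-Wallis comparison of vessel types;
* marginal linear mixed models ``log10 HRW_a ~ predictor`` with random
  intercept and predictor slope grouped by eye within subject;
* the interaction mixed model
  ``log10 HRW_a ~ V_Dist * ODF`` (REML), reporting Nakagawa-Schielzeth
  marginal/conditional R^2 and standardized coefficients;
* per-Fourier-coefficient mixed models on V_Dist and ODF jointly;
* the fixed-effects ANOVA comparison of attenuation slopes between vessel
  types.

Mixed models are estimated with statsmodels ``MixedLM``; p-values use the
Wald normal approximation (no small-sample df correction), and 95% CIs are
estimate +/- 1.96 SE.  Amplitudes are log-transformed base 10; records with
zero amplitude are dropped (a zero means no detectable pulse).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .exceptions import DegenerateDataError

__all__ = [
    "DescriptiveStats",
    "TermEstimate",
    "MixedModelResult",
    "assemble_records",
    "descriptive",
    "kruskal_wallis",
    "fit_marginal",
    "fit_interaction",
    "compare_attenuation",
    "fit_coefficient_models",
]

logger = logging.getLogger(__name__)

_PREDICTOR_COLS = {"v_dist": "v_dist_dd", "odf": "odf_g"}


@dataclass
class DescriptiveStats:
    """Distributional summary of one amplitude sample."""

    n: int
    median: float
    range: tuple
    iqr: float
    skewness: float
    kurtosis: float
    pearson_criterion: float
    kurtosis_convention: str = "Pearson (normal = 3), bias-corrected"
    degenerate: bool = False


@dataclass
class TermEstimate:
    """One regression term: estimate, SE, Wald 95% CI and p-value."""

    estimate: float
    se: float
    ci_lo: float
    ci_hi: float
    p: float

    @classmethod
    def from_fit(cls, est, se, p):
        return cls(
            estimate=float(est), se=float(se),
            ci_lo=float(est - 1.96 * se), ci_hi=float(est + 1.96 * se),
            p=float(p),
        )


@dataclass
class MixedModelResult:
    """Interaction mixed model summary."""

    fixed: dict  # term -> TermEstimate (I0, C_VD, C_ODF, C_VDxODF)
    random: dict  # variance components
    r2_conditional: float
    r2_marginal: float
    beta_std: dict  # term -> standardized coefficient
    n_obs: int
    n_groups: int
    converged: bool = True
    random_structure: str = "intercept+slope"
    notes: list = field(default_factory=list)


def assemble_records(fits, geometries=None, run_metadata=None):
    """Build the attenuation record table from per-series harmonic fits.

    Parameters
    ----------
    fits : iterable of HarmonicFit
        Each fit's ``metadata`` must resolve ``v_dist_dd`` — either directly
        or via a pixel coordinate ``point`` plus a geometry looked up by
        ``metadata['vessel']`` in ``geometries`` — and ``odf_g`` (directly or
        via ``run_metadata[(eye_id, run_id)]``).
    geometries : dict, optional
        label -> :class:`~retipulse.geometry.VesselGeometry`.
    run_metadata : dict, optional
        (eye_id, run_id) -> dict with at least ``odf_g``.

    Returns
    -------
    (DataFrame, n_dropped)
        One record per fit; fits with ``hrw_a <= 0`` are dropped and counted.
    """
    from .geometry import v_dist as _v_dist

    rows = []
    n_dropped = 0
    for f in fits:
        meta = dict(f.metadata)
        if "v_dist_dd" not in meta:
            label = meta.get("vessel")
            if geometries is None or label not in geometries:
                raise KeyError(
                    f"cannot resolve v_dist_dd: no geometry for key {label!r}"
                )
            if "point" not in meta:
                raise KeyError("cannot resolve v_dist_dd: metadata lacks 'point'")
            meta["v_dist_dd"] = _v_dist(geometries[label], meta["point"])
        if "odf_g" not in meta:
            key = (meta.get("eye_id"), meta.get("run_id"))
            if run_metadata is None or key not in run_metadata:
                raise KeyError(f"cannot resolve odf_g: no run metadata for {key!r}")
            meta.update(run_metadata[key])
        if f.hrw_a <= 0:
            n_dropped += 1
            continue
        row = {
            "hrw_a": f.hrw_a,
            "log_hrwa": float(np.log10(f.hrw_a)),
            "v_dist_dd": float(meta["v_dist_dd"]),
            "odf_g": float(meta["odf_g"]),
            "vessel_type": meta.get("vessel_type", "vein"),
            "subject_id": meta.get("subject_id", "S00"),
            "eye_id": meta.get("eye_id", "E00"),
        }
        for n in range(f.order):
            row[f"a{n + 1}"] = float(f.a[n])
            row[f"b{n + 1}"] = float(f.b[n])
        rows.append(row)
    if n_dropped:
        logger.info("assemble_records: dropped %d zero-amplitude records",
                    n_dropped)
    return pd.DataFrame(rows), n_dropped


def descriptive(values) -> DescriptiveStats:
    """Median/range/IQR/skewness/kurtosis summary of a sample.

    Skewness is the adjusted Fisher-Pearson sample coefficient; kurtosis is
    Pearson's (normal distribution = 3), both bias-corrected.  The Pearson
    normality criterion is the second skewness coefficient
    ``3 (mean - median) / sd``; it is NaN (and the result flagged
    degenerate) for a constant sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise DegenerateDataError("need at least 4 values")
    sd = x.std(ddof=1)
    med = float(np.median(x))
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
    if sd == 0:
        return DescriptiveStats(
            n=x.size, median=med, range=(float(x.min()), float(x.max())),
            iqr=float(q3 - q1), skewness=0.0, kurtosis=float("nan"),
            pearson_criterion=float("nan"), degenerate=True,
        )
    return DescriptiveStats(
        n=x.size,
        median=med,
        range=(float(x.min()), float(x.max())),
        iqr=float(q3 - q1),
        skewness=float(stats.skew(x, bias=False)),
        kurtosis=float(stats.kurtosis(x, fisher=False, bias=False)),
        pearson_criterion=float(3.0 * (x.mean() - med) / sd),
    )


def kruskal_wallis(groups):
    """Kruskal-Wallis H and chi-square p-value across groups.

    Identical values across all groups give (H, p) = (0, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise DegenerateDataError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _group_key(df: pd.DataFrame) -> pd.Series:
    """Eye nested in subject as a single grouping factor."""
    return df["subject_id"].astype(str) + "/" + df["eye_id"].astype(str)


def _fit_mixedlm(df, formula, re_cols, reml=True):
    """Fit MixedLM with random intercept (+ slopes); fall back to a random
    intercept on convergence or singularity problems.

    Returns (result, structure_label, notes).
    """
    data = df.copy()
    data["_group"] = _group_key(data)
    re_formula = "~" + " + ".join(re_cols) if re_cols else "1"
    notes = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = smf.mixedlm(
                formula, data, groups=data["_group"], re_formula=re_formula
            ).fit(reml=reml)
            bad = (not res.converged) or np.any(~np.isfinite(res.bse_fe))
        except (np.linalg.LinAlgError, ValueError) as exc:
            notes.append(f"random-slope fit failed ({exc}); "
                         "falling back to random intercept")
            bad = True
            res = None
        if bad and re_cols:
            if res is not None:
                notes.append("random-slope fit did not converge; "
                             "falling back to random intercept")
            logger.warning("singular random-effects fit; using random "
                           "intercept only")
            res = smf.mixedlm(
                formula, data, groups=data["_group"], re_formula="1"
            ).fit(reml=reml)
            return res, "intercept", notes
    return res, ("intercept+slope" if re_cols else "intercept"), notes


def _check_varies(df, col):
    if np.ptp(df[col].to_numpy(dtype=float)) == 0:
        raise DegenerateDataError(f"predictor {col!r} does not vary")


def fit_marginal(records: pd.DataFrame, predictor: str) -> dict:
    """Marginal mixed model ``log_hrwa ~ predictor``.

    ``predictor`` is ``'v_dist'`` or ``'odf'`` (or a column name).  Random
    intercept and predictor slope by eye nested in subject.  Returns a dict
    with ``slope`` and ``intercept`` :class:`TermEstimate` entries.
    """
    col = _PREDICTOR_COLS.get(predictor, predictor)
    if len(records) < 10:
        raise DegenerateDataError("need >= 10 records")
    _check_varies(records, col)
    res, structure, notes = _fit_mixedlm(
        records, f"log_hrwa ~ {col}", re_cols=[col]
    )
    return {
        "intercept": TermEstimate.from_fit(
            res.fe_params["Intercept"], res.bse_fe["Intercept"],
            res.pvalues["Intercept"],
        ),
        "slope": TermEstimate.from_fit(
            res.fe_params[col], res.bse_fe[col], res.pvalues[col]
        ),
        "predictor": col,
        "random_structure": structure,
        "notes": notes,
    }


_INTERACTION_TERMS = {
    "Intercept": "I0",
    "v_dist_dd": "C_VD",
    "odf_g": "C_ODF",
    "v_dist_dd:odf_g": "C_VDxODF",
}


def fit_interaction(records: pd.DataFrame) -> MixedModelResult:
    """Interaction mixed model ``log_hrwa ~ v_dist_dd * odf_g`` (REML).

    Random intercept and V_Dist slope by eye nested in subject.  Reports
    Wald-z fixed effects, variance components, Nakagawa-Schielzeth marginal
    and conditional R^2, and standardized coefficients (each term's estimate
    times the SD of its design column over the SD of the response; the
    interaction is standardized by the SD of the product column).
    """
    if len(records) < 20:
        raise DegenerateDataError("need >= 20 records")
    _check_varies(records, "v_dist_dd")
    _check_varies(records, "odf_g")
    res, structure, notes = _fit_mixedlm(
        records, "log_hrwa ~ v_dist_dd * odf_g", re_cols=["v_dist_dd"]
    )

    fixed = {}
    for term, label in _INTERACTION_TERMS.items():
        fixed[label] = TermEstimate.from_fit(
            res.fe_params[term], res.bse_fe[term], res.pvalues[term]
        )

    # variance decomposition (Nakagawa & Schielzeth)
    exog = res.model.exog
    fixed_pred = exog @ res.fe_params.to_numpy()
    var_f = float(np.var(fixed_pred))
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    if structure == "intercept+slope":
        z = np.column_stack(
            [np.ones(len(records)), records["v_dist_dd"].to_numpy(dtype=float)]
        )
        var_r = float(np.mean(np.einsum("ij,jk,ik->i", z, cov_re, z)))
    else:
        var_r = float(cov_re[0, 0])
    var_e = float(res.scale)
    total = var_f + var_r + var_e
    r2_marginal = var_f / total
    r2_conditional = (var_f + var_r) / total

    y_sd = float(records["log_hrwa"].std(ddof=1))
    v = records["v_dist_dd"].to_numpy(dtype=float)
    o = records["odf_g"].to_numpy(dtype=float)
    col_sd = {
        "C_VD": np.std(v, ddof=1),
        "C_ODF": np.std(o, ddof=1),
        "C_VDxODF": np.std(v * o, ddof=1),
    }
    beta_std = {
        label: float(fixed[label].estimate * sd / y_sd)
        for label, sd in col_sd.items()
    }

    random = {
        "var_intercept": float(cov_re[0, 0]),
        "var_slope": float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0,
        "cov_intercept_slope": float(cov_re[0, 1]) if cov_re.shape[0] > 1 else 0.0,
        "var_residual": var_e,
    }
    return MixedModelResult(
        fixed=fixed,
        random=random,
        r2_conditional=r2_conditional,
        r2_marginal=r2_marginal,
        beta_std=beta_std,
        n_obs=len(records),
        n_groups=_group_key(records).nunique(),
        converged=bool(res.converged),
        random_structure=structure,
        notes=notes,
    )


def compare_attenuation(records: pd.DataFrame):
    """F-test of the vessel_type x V_Dist interaction (fixed-effects model).

    Tests whether the attenuation slope of log amplitude on V_Dist differs
    between arteries and veins.  Returns (F, p).
    """
    types = set(records["vessel_type"].unique())
    if len(types) < 2:
        raise DegenerateDataError(
            f"need both vessel types, got {sorted(types)}"
        )
    res = smf.ols("log_hrwa ~ v_dist_dd * C(vessel_type)", records).fit()
    inter = [n for n in res.model.exog_names
             if "v_dist_dd:" in n or ":v_dist_dd" in n]
    wald = res.wald_test(
        [f"{n} = 0" for n in inter], use_f=True, scalar=True
    )
    return float(wald.statistic), float(wald.pvalue)


def fit_coefficient_models(records: pd.DataFrame, coefficients=("a1", "b1", "a2", "b2")):
    """Mixed models of the raw Fourier coefficients on V_Dist and ODF.

    For each coefficient present in ``records``, fits
    ``coef ~ v_dist_dd + odf_g`` with the same random structure as
    :func:`fit_marginal` and returns
    ``{coef: {'v_dist_dd': TermEstimate, 'odf_g': TermEstimate}}``.
    """
    if len(records) < 10:
        raise DegenerateDataError("need >= 10 records")
    _check_varies(records, "v_dist_dd")
    _check_varies(records, "odf_g")
    out = {}
    for coef in coefficients:
        if coef not in records.columns:
            continue
        if np.ptp(records[coef].to_numpy(dtype=float)) == 0:
            raise DegenerateDataError(f"coefficient {coef!r} is constant")
        res, structure, notes = _fit_mixedlm(
            records, f"{coef} ~ v_dist_dd + odf_g", re_cols=["v_dist_dd"]
        )
        out[coef] = {
            "v_dist_dd": TermEstimate.from_fit(
                res.fe_params["v_dist_dd"], res.bse_fe["v_dist_dd"],
                res.pvalues["v_dist_dd"],
            ),
            "odf_g": TermEstimate.from_fit(
                res.fe_params["odf_g"], res.bse_fe["odf_g"],
                res.pvalues["odf_g"],
            ),
            "random_structure": structure,
        }
    if not out:
        raise DegenerateDataError("no Fourier-coefficient columns in records")
    return out
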