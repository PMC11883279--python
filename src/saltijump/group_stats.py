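"""Mass x sex modelling of per-jump kinematics and rank-based comparisons.

Each subject contributes several jumps, so kinematic responses are
modelled with a linear mixed model with subject-level random intercepts:

    response ~ mass + sex (+ mass:sex),  (1 | subject)

fitted by maximum likelihood (not REML, because the compared models differ
in their fixed effects), with the interaction retained or dropped by AIC.
Fixed-effect F tests use a containment approximation for the denominator
degrees of freedom (n_subjects - n_fixed_effects); the method used is
recorded in the fit.  Responses may optionally be natural-log transformed
(jump energetics are multiplicative in mass), and the transformation used
is recorded in the fit.

Body mass between sexes (one value per subject) is compared with the
Mann-Whitney U test: exact p by enumeration up to a pooled sample size of
20 (with midrank ties), normal approximation with tie correction beyond.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import ComparisonError, DesignError

__all__ = [
    "LmmFit",
    "fit_lmm",
    "select_model",
    "MannWhitneyResult",
    "mann_whitney",
    "simulate_records",
]

REQUIRED_COLUMNS = ("subject_id", "sex", "body_mass_mg")


@dataclass
class LmmFit:
    """A fitted mixed model for one kinematic response."""

    response: str
    formula: str
    params: pd.Series
    bse: pd.Series
    n_obs: int
    n_subjects: int
    loglik: float
    aic: float
    k_params: int
    random_intercept_var: float
    residual_var: float
    ftable: pd.DataFrame
    with_interaction: bool
    converged: bool
    log_transformed: bool
    denominator_df_method: str = "containment"

    def coefficient_table(self) -> pd.DataFrame:
        """Estimate / s.e. / df / t / p table for the fixed effects."""
        den_df = max(self.n_subjects - len(self.params), 1)
        t = self.params / self.bse
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "df": den_df,
                "t": t,
                "p": 2 * stats.t.sf(np.abs(t), den_df),
            }
        )


def _check_records(records: pd.DataFrame, response: str) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    if response not in records.columns:
        raise ValueError(f"records has no response column {response!r}")
    sexes = records["sex"].unique()
    if len(sexes) < 2:
        raise DesignError(f"need both sexes in the design, got {list(sexes)}")
    per_sex = records.groupby("sex")["subject_id"].nunique()
    if (per_sex < 2).any():
        raise DesignError(f"need >= 2 subjects per sex, got {per_sex.to_dict()}")
    mass_sd = records.groupby("subject_id")["body_mass_mg"].std(ddof=0)
    if (mass_sd.fillna(0) > 1e-9).any():
        raise ValueError("body mass must be constant within subject")


def fit_lmm(
    records: pd.DataFrame,
    response: str,
    with_interaction: bool = False,
    log_transform: bool = False,
) -> LmmFit:
    """ML fit of ``response ~ mass + sex (+ mass:sex)`` with subject intercepts.

    ``records`` needs columns ``subject_id``, ``sex``, ``body_mass_mg``
    and the response.  Sex is treatment-coded with female as the
    reference level, so the sex coefficient is the male offset.
    """
    _check_records(records, response)
    data = records.copy()
    yname = response
    if log_transform:
        if (data[response] <= 0).any():
            raise ValueError("log transform requires strictly positive responses")
        yname = f"log_{response}"
        data[yname] = np.log(data[response])
    op = "*" if with_interaction else "+"
    formula = f"Q('{yname}') ~ body_mass_mg {op} C(sex, Treatment('female'))"

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data, groups=data["subject_id"])
        try:
            fit = model.fit(reml=False, method="lbfgs")
        except Exception:
            fit = model.fit(reml=False)
    converged = bool(getattr(fit, "converged", True)) and not any(
        issubclass(w.category, ConvergenceWarning) for w in caught
    )

    fe = fit.fe_params
    fe_bse = fit.bse_fe
    k = len(fe) + 2  # fixed effects + random-intercept and residual variances
    aic = 2 * k - 2 * fit.llf
    n_subjects = data["subject_id"].nunique()
    den_df = max(n_subjects - len(fe), 1)

    rows = []
    for term in fe.index:
        if term == "Intercept":
            continue
        F = float((fe[term] / fe_bse[term]) ** 2)
        rows.append(
            {
                "term": term,
                "num_df": 1,
                "den_df": den_df,
                "F": F,
                "p": float(stats.f.sf(F, 1, den_df)),
            }
        )
    ftable = pd.DataFrame(rows).set_index("term") if rows else pd.DataFrame()

    return LmmFit(
        response=response,
        formula=formula,
        params=fe,
        bse=fe_bse,
        n_obs=len(data),
        n_subjects=n_subjects,
        loglik=float(fit.llf),
        aic=float(aic),
        k_params=k,
        random_intercept_var=float(np.asarray(fit.cov_re).ravel()[0]),
        residual_var=float(fit.scale),
        ftable=ftable,
        with_interaction=with_interaction,
        converged=converged,
        log_transformed=log_transform,
    )


def select_model(fit_full: LmmFit, fit_reduced: LmmFit) -> tuple[LmmFit, float]:
    """AIC choice between nested fits; ties go to the reduced model.

    Returns (selected fit, delta_aic = AIC_full - AIC_reduced).
    """
    if fit_full.response != fit_reduced.response:
        raise ComparisonError(
            f"fits model different responses: {fit_full.response!r} vs "
            f"{fit_reduced.response!r}"
        )
    if fit_full.log_transformed != fit_reduced.log_transformed:
        raise ComparisonError("fits use different response transformations")
    delta = fit_full.aic - fit_reduced.aic
    if delta < -1e-9:
        return fit_full, delta
    return fit_reduced, delta


@dataclass
class MannWhitneyResult:
    U: float
    p: float
    method: str  # "exact" or "normal"
    U_a: float = float("nan")
    U_b: float = float("nan")


def _u_statistics(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """U_a and U_b with midrank handling of ties."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = len(a)
    u_a = float(np.sum(ranks[:na]) - na * (na + 1) / 2)
    return u_a, len(a) * len(b) - u_a


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test, U = min(U_a, U_b).

    Exact p by enumerating all group labelings of the pooled midranks for
    pooled n <= 20; tie-corrected normal approximation (with continuity
    correction) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = len(a), len(b)
    u_a, u_b = _u_statistics(a, b)
    u = min(u_a, u_b)

    n = na + nb
    if n <= 20:
        ranks = stats.rankdata(np.concatenate([a, b]))
        offset = na * (na + 1) / 2
        nprod = na * nb
        idx = np.array(list(itertools.combinations(range(n), na)))
        u_all = ranks[idx].sum(axis=1) - offset
        u_min_all = np.minimum(u_all, nprod - u_all)
        p = float(np.mean(u_min_all <= u + 1e-9))
        return MannWhitneyResult(U=u, p=min(p, 1.0), method="exact", U_a=u_a, U_b=u_b)

    # normal approximation with tie correction
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    mu = na * nb / 2
    sigma2 = na * nb / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(U=u, p=1.0, method="normal", U_a=u_a, U_b=u_b)
    z = (u - mu + 0.5) / np.sqrt(sigma2)  # continuity-corrected, u <= mu
    p = float(min(2 * stats.norm.cdf(z), 1.0))
    return MannWhitneyResult(U=u, p=p, method="normal", U_a=u_a, U_b=u_b)


def simulate_records(
    n_female_subjects: int = 12,
    n_male_subjects: int = 10,
    jumps_per_subject: int = 3,
    beta_intercept: float = 1.0,
    beta_mass: float = 0.6,
    beta_sex_male: float = -0.5,
    beta_interaction: float = 0.0,
    subject_sd: float = 0.3,
    residual_sd: float = 0.2,
    seed=None,
) -> pd.DataFrame:
    """Synthetic jump records with known fixed effects, for calibration.

    Body mass (mg) is drawn per subject around sex-typical means; the
    response is beta_0 + beta_mass*mass + beta_sex*[male]
    + beta_int*mass*[male] + subject intercept + residual noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for sex, n_subj, mass_mu, mass_sd in (
        ("female", n_female_subjects, 10.4, 2.0),
        ("male", n_male_subjects, 4.9, 1.8),
    ):
        is_male = 1.0 if sex == "male" else 0.0
        for s in range(n_subj):
            mass = max(float(rng.normal(mass_mu, mass_sd)), 0.5)
            u = rng.normal(0.0, subject_sd)
            subject = f"{sex[0]}{s + 1:02d}"
            for j in range(jumps_per_subject):
                y = (
                    beta_intercept
                    + beta_mass * mass
                    + beta_sex_male * is_male
                    + beta_interaction * mass * is_male
                    + u
                    + rng.normal(0.0, residual_sd)
                )
                rows.append(
                    {
                        "subject_id": subject,
                        "sex": sex,
                        "body_mass_mg": mass,
                        "response": y,
                        "jump": j + 1,
                    }
                )
    return pd.DataFrame(rows)
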